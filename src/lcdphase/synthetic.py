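"""Seeded generators for every fixture the analysis operators need.

Each generator is a pure function of (parameters, seed) and returns its
ground truth alongside the fixture (via a :class:`FixtureManifest`), so tests
recover planted values instead of recomputing them.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .contacts import SolvatedFrame
from .phase import DA_PER_A3_TO_MG_ML, DensityProfile
from .sequences import ALPHABET, ProteinSequence
from .system import SystemConfiguration, Trajectory
from .wetquant import FrapTrace

__all__ = [
    "FixtureManifest",
    "make_tanh_slab",
    "make_planted_contact_traj",
    "make_solvated_frame",
    "make_frap_trace",
    "make_droplet_image",
    "make_random_lcd",
]


@dataclass(frozen=True)
class FixtureManifest:
    """Generator provenance plus planted ground truth, serializable to JSON."""

    generator: str
    parameters: dict
    seed: int | None
    ground_truth: dict

    def to_json(self) -> str:
        def default(o):
            if isinstance(o, np.ndarray):
                return o.tolist()
            if isinstance(o, (np.integer, np.floating)):
                return o.item()
            raise TypeError(type(o))

        return json.dumps(dataclasses.asdict(self), default=default, indent=2)


# ---------------------------------------------------------------------------
# Coexistence fixtures


def _tanh_profile(z, lz, c_dense, c_dilute, halfwidth, width):
    mid = lz / 2.0
    return c_dilute + (c_dense - c_dilute) * 0.5 * (
        np.tanh((z - (mid - halfwidth)) / width)
        - np.tanh((z - (mid + halfwidth)) / width)
    )


def make_tanh_slab(
    c_dense: float,
    c_dilute: float,
    interface_width: float,
    box: tuple[float, float, float],
    seed: int,
    slab_halfwidth: float | None = None,
    bead_mass: float = 1.0,
    n_frames: int = 1,
) -> tuple[Trajectory, DensityProfile, FixtureManifest]:
    """Sample bead positions from a planted tanh coexistence profile.

    z-coordinates are drawn by inverse-CDF sampling from
    ``c(z) = c_dil + (c_den - c_dil)/2 [tanh((z-z1)/w) - tanh((z-z2)/w)]``
    (slab centered in the box), x/y uniformly.  The expected bead count per
    frame is the profile's mass integral divided by ``bead_mass``; each frame
    is an independent Poisson realization, so the analyzed profile converges
    to the planted one.  Beads are emitted as single-bead chains.
    """
    if c_dense < c_dilute:
        raise ValueError("c_dense must be >= c_dilute")
    if c_dilute < 0 or interface_width <= 0:
        raise ValueError("need c_dilute >= 0 and interface_width > 0")
    rng = np.random.Generator(np.random.Philox(seed))
    lx, ly, lz = box
    if slab_halfwidth is None:
        slab_halfwidth = lz / 8.0
    zgrid = np.linspace(0.0, lz, 4096)
    dens = _tanh_profile(zgrid, lz, c_dense, c_dilute, slab_halfwidth,
                         interface_width)
    dens_da = dens / DA_PER_A3_TO_MG_ML  # Da / A^3
    cdf = np.concatenate([[0.0], np.cumsum((dens_da[1:] + dens_da[:-1]) / 2.0
                                           * np.diff(zgrid))])
    total_mass = cdf[-1] * lx * ly  # Da per frame
    n_common = max(1, int(round(total_mass / bead_mass)))
    bead_mass = total_mass / n_common  # keep the mass integral exact
    frames = []
    for _ in range(n_frames):
        u = rng.random(n_common) * cdf[-1]
        z = np.interp(u, cdf, zgrid)
        xy = rng.random((n_common, 2)) * np.array([lx, ly])
        frames.append(np.column_stack([xy, z]))
    traj = Trajectory(
        frames=np.asarray(frames),
        boxes=np.asarray(box, dtype=float),
        times=np.arange(n_frames, dtype=float),
        chains=[(i, i + 1) for i in range(n_common)],
        bead_codes=["G"] * n_common,
        provenance={"bead_mass": bead_mass},
    )
    analytic = DensityProfile(
        bin_centers=zgrid,
        concentration=dens,
        n_frames=0,
        centering_mode="analytic",
        box=np.asarray(box, dtype=float),
        total_mass=total_mass,
    )
    manifest = FixtureManifest(
        generator="make_tanh_slab",
        parameters={
            "c_dense": c_dense, "c_dilute": c_dilute,
            "interface_width": interface_width, "box": list(box),
            "slab_halfwidth": slab_halfwidth, "bead_mass": bead_mass,
            "n_frames": n_frames,
        },
        seed=seed,
        ground_truth={"c_dense": c_dense, "c_dilute": c_dilute},
    )
    return traj, analytic, manifest


# ---------------------------------------------------------------------------
# Contact fixtures


def make_planted_contact_traj(
    pairs: Sequence[tuple[int, int]],
    distances: Sequence[float],
    n_frames: int,
    box: tuple[float, float, float],
    chain_length: int = 12,
    n_chains: int = 2,
    sequence: str | None = None,
    grid_spacing: float = 30.0,
) -> tuple[Trajectory, FixtureManifest]:
    """Trajectory in which residue pairs (i, j) of chains 0 and 1 sit at the
    listed inter-chain distances in every frame, all other inter-residue
    distances far beyond any contact cutoff.

    Residues are laid out on a sparse grid (``grid_spacing`` apart along x,
    chains separated along y), then residue ``j`` of chain 1 is moved next to
    residue ``i`` of chain 0.  The geometry is not bond-consistent (analysis
    fixture only).
    """
    if len(pairs) != len(distances):
        raise ValueError("pairs and distances must have equal length")
    if n_chains < 2:
        raise ValueError("need at least two chains")
    seq = sequence if sequence is not None else "G" * chain_length
    if len(seq) != chain_length:
        raise ValueError("sequence length must equal chain_length")
    lx, ly, lz = box
    if chain_length * grid_spacing > lx:
        raise ValueError("box x too small for the grid layout")
    positions = np.zeros((n_chains * chain_length, 3))
    for c in range(n_chains):
        for k in range(chain_length):
            positions[c * chain_length + k] = (
                (k + 0.5) * grid_spacing % lx,
                (c + 0.5) * (ly / n_chains),
                lz / 2.0,
            )
    used_targets = set()
    for (i, j), d in zip(pairs, distances):
        if not (0 <= i < chain_length and 0 <= j < chain_length):
            raise ValueError(f"pair ({i}, {j}) outside chain")
        if j in used_targets:
            raise ValueError("each chain-1 residue can be planted once")
        used_targets.add(j)
        anchor = positions[i]
        positions[chain_length + j] = anchor + np.array([0.0, d, 0.0])
    traj = Trajectory(
        frames=np.tile(positions, (n_frames, 1, 1)),
        boxes=np.asarray(box, dtype=float),
        times=np.arange(n_frames, dtype=float),
        chains=[(c * chain_length, (c + 1) * chain_length)
                for c in range(n_chains)],
        bead_codes=list(seq) * n_chains,
    )
    manifest = FixtureManifest(
        generator="make_planted_contact_traj",
        parameters={
            "pairs": [list(p) for p in pairs], "distances": list(distances),
            "n_frames": n_frames, "box": list(box),
            "chain_length": chain_length, "n_chains": n_chains,
        },
        seed=None,
        ground_truth={"contact_pairs": [list(p) for p in pairs]},
    )
    return traj, manifest


def make_solvated_frame(
    residue_positions: np.ndarray,
    water_counts_within_cutoff: Sequence[int],
    cutoff: float,
    box: tuple[float, float, float],
    seed: int,
    n_distractors: int = 50,
) -> tuple[SolvatedFrame, FixtureManifest]:
    """A frame with exactly the requested number of solvent particles within
    ``cutoff`` of each residue, plus distractor waters far from all residues."""
    residue_positions = np.asarray(residue_positions, dtype=float)
    counts = list(water_counts_within_cutoff)
    if any(c < 0 for c in counts):
        raise ValueError("water counts must be non-negative")
    if len(counts) != len(residue_positions):
        raise ValueError("one count per residue required")
    box_arr = np.asarray(box, dtype=float)
    # residues must be isolated for the planted counts to be exact
    for a in range(len(residue_positions)):
        for b in range(a + 1, len(residue_positions)):
            d = residue_positions[a] - residue_positions[b]
            d -= box_arr * np.round(d / box_arr)
            if np.linalg.norm(d) <= 2.0 * cutoff:
                raise ValueError("residues closer than twice the cutoff")
    rng = np.random.Generator(np.random.Philox(seed))
    waters = []
    for pos, count in zip(residue_positions, counts):
        placed = 0
        while placed < count:
            u = rng.normal(size=3)
            u /= np.linalg.norm(u)
            r = cutoff * 0.9 * rng.random() ** (1.0 / 3.0)
            waters.append(pos + r * u)
            placed += 1
    # distractors: rejection-sample far from every residue (bounded retries)
    placed = 0
    for _ in range(200 * max(1, n_distractors)):
        if placed >= n_distractors:
            break
        cand = rng.random(3) * box_arr
        d = residue_positions - cand
        d -= box_arr * np.round(d / box_arr)
        if np.min(np.linalg.norm(d, axis=1)) > 2.0 * cutoff:
            waters.append(cand)
            placed += 1
    else:
        if placed < n_distractors:
            raise RuntimeError("could not place distractor waters")
    frame = SolvatedFrame(
        protein_positions=residue_positions,
        solvent_positions=np.asarray(waters).reshape(-1, 3),
        box=box_arr,
    )
    manifest = FixtureManifest(
        generator="make_solvated_frame",
        parameters={"cutoff": cutoff, "box": list(box),
                    "n_distractors": n_distractors},
        seed=seed,
        ground_truth={"water_counts": counts},
    )
    return frame, manifest


# ---------------------------------------------------------------------------
# FRAP and droplet fixtures


def make_frap_trace(
    plateau: float,
    rate: float,
    noise_sd: float,
    n_frames: int,
    seed: int,
    dt: float = 1.0,
    bleach_index: int = 5,
    background: float = 20.0,
    whole_level: float = 120.0,
) -> tuple[FrapTrace, FixtureManifest]:
    """FRAP trace whose normalized recovery is
    ``plateau * (1 - exp(-rate * t))`` after the bleach (1 before), plus
    optional Gaussian noise on the bleached-ROI signal."""
    if rate < 0 or not 0 <= plateau <= 1.5:
        raise ValueError("rate must be >= 0 and plateau in [0, 1.5]")
    if bleach_index < 1 or bleach_index >= n_frames:
        raise ValueError("bleach_index must lie inside the trace")
    rng = np.random.Generator(np.random.Philox(seed))
    times = np.arange(n_frames) * dt
    signal = whole_level - background
    recovery = np.ones(n_frames)
    t_post = times[bleach_index:] - times[bleach_index]
    recovery[bleach_index:] = plateau * (1.0 - np.exp(-rate * t_post))
    roi3 = np.full(n_frames, background)
    roi2 = np.full(n_frames, whole_level)
    roi1 = roi3 + signal * recovery
    if noise_sd > 0:
        roi1 = roi1 + rng.normal(scale=noise_sd, size=n_frames)
    trace = FrapTrace(
        times=times, roi_bleached=roi1, roi_whole=roi2,
        roi_background=roi3, bleach_index=bleach_index,
    )
    manifest = FixtureManifest(
        generator="make_frap_trace",
        parameters={"rate": rate, "noise_sd": noise_sd, "n_frames": n_frames,
                    "dt": dt, "bleach_index": bleach_index},
        seed=seed,
        ground_truth={"plateau": plateau, "rate": rate},
    )
    return trace, manifest


def make_droplet_image(
    ellipses: Sequence[tuple[float, float, float, float, float]],
    intensity: float = 200.0,
    background: float = 20.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    shape: tuple[int, int] = (256, 256),
    supersample: int = 4,
) -> tuple[np.ndarray, "np.ndarray", FixtureManifest]:
    """Render anti-aliased ellipses ``(row, col, semi_major, semi_minor,
    angle_rad)`` on a constant background.

    Ground truth: expected roundness = semi_minor / semi_major per ellipse.
    """
    import pandas as pd

    rng = np.random.Generator(np.random.Philox(seed))
    s = supersample
    big = np.zeros((shape[0] * s, shape[1] * s))
    rr, cc = np.mgrid[0 : shape[0] * s, 0 : shape[1] * s]
    rows = []
    for (r0, c0, a, b, theta) in ellipses:
        if a <= 0 or b <= 0 or b > a:
            raise ValueError("need semi_major >= semi_minor > 0")
        dr = (rr / s - r0)
        dc = (cc / s - c0)
        u = dc * math.cos(theta) + dr * math.sin(theta)
        v = -dc * math.sin(theta) + dr * math.cos(theta)
        big[(u / a) ** 2 + (v / b) ** 2 <= 1.0] = 1.0
        rows.append(
            {"row": r0, "col": c0, "semi_major": a, "semi_minor": b,
             "area": math.pi * a * b, "roundness": b / a}
        )
    mask = big.reshape(shape[0], s, shape[1], s).mean(axis=(1, 3))
    image = background + intensity * mask
    if noise_sd > 0:
        image = image + rng.normal(scale=noise_sd, size=shape)
    truth = pd.DataFrame(rows)
    manifest = FixtureManifest(
        generator="make_droplet_image",
        parameters={"intensity": intensity, "background": background,
                    "noise_sd": noise_sd, "shape": list(shape)},
        seed=seed,
        ground_truth={"roundness": truth["roundness"].tolist()},
    )
    return image, truth, manifest


# ---------------------------------------------------------------------------
# Sequence fixtures


def make_random_lcd(
    length: int,
    composition: dict[str, float],
    seed: int,
    exact: bool = False,
) -> ProteinSequence:
    """Random sequence drawn from a residue-type composition.

    ``exact=True`` fixes the residue counts to ``round(length * fraction)``
    (largest-remainder rounding) and shuffles; otherwise a multinomial draw.
    """
    if length < 1:
        raise ValueError("length must be >= 1")
    codes = list(composition)
    if any(c not in ALPHABET for c in codes):
        raise ValueError("composition contains unknown residue codes")
    weights = np.array([composition[c] for c in codes], dtype=float)
    if np.any(weights < 0) or weights.sum() <= 0:
        raise ValueError("composition weights must be non-negative, sum > 0")
    weights = weights / weights.sum()
    rng = np.random.Generator(np.random.Philox(seed))
    if exact:
        ideal = weights * length
        counts = np.floor(ideal).astype(int)
        order = np.argsort(-(ideal - counts))
        for k in order[: length - counts.sum()]:
            counts[k] += 1
        residues = [c for c, n in zip(codes, counts) for _ in range(n)]
        rng.shuffle(residues)
    else:
        draws = rng.choice(len(codes), size=length, p=weights)
        residues = [codes[d] for d in draws]
    return ProteinSequence(
        id=f"random_lcd_seed{seed}", residues="".join(residues)
    )
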