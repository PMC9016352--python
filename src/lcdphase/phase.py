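"""Slab coexistence analysis: z-density profiles, dense/dilute concentrations,
transfer free energy, condensate detection and variant ranking.

The dense-phase concentration is read from a window around the slab center,
the dilute-phase (saturation) concentration from the region far from the
interface; the excess free energy of moving a chain from the dilute to the
dense phase is ``dG_trans = -R T ln(c_dense / c_dilute)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .system import Trajectory

__all__ = [
    "largest_cluster_fraction",
    "DensityProfile",
    "PhaseMetrics",
    "density_profile",
    "phase_concentrations",
    "delta_g_trans",
    "detect_condensate",
    "compute_phase_metrics",
    "rank_variants",
    "DA_PER_A3_TO_MG_ML",
]

R_KJ_MOL_K = 8.314e-3
#: 1 Da/Angstrom^3 in mg/mL
DA_PER_A3_TO_MG_ML = 1660.539


@dataclass
class DensityProfile:
    """Frame-averaged, slab-centered concentration profile along z."""

    bin_centers: np.ndarray  # A
    concentration: np.ndarray  # mg/mL
    n_frames: int
    centering_mode: str
    box: np.ndarray  # (3,) A of the analyzed frames
    total_mass: float  # Da per frame

    @property
    def bin_width(self) -> float:
        return float(self.bin_centers[1] - self.bin_centers[0])

    @property
    def z_mid(self) -> float:
        return float(self.box[2]) / 2.0

    def mass_integral(self) -> float:
        """Sum of concentration * bin volume, back in Da."""
        bin_volume = self.box[0] * self.box[1] * self.bin_width
        return float(
            np.sum(self.concentration) * bin_volume / DA_PER_A3_TO_MG_ML
        )


@dataclass
class PhaseMetrics:
    name: str
    c_dense: float  # mg/mL
    c_dilute: float  # mg/mL
    delta_g_trans: float | None  # kJ/mol
    has_condensate: bool
    dense_halfwidth: float
    dilute_margin: float


def _center_offsets(z, masses, lz, window: float):
    """Periodic center of the densest sliding window of width ``window``."""
    nb = max(16, int(round(lz / 2.0)))  # ~2 A scan resolution
    hist, edges = np.histogram(z % lz, bins=nb, range=(0.0, lz), weights=masses)
    w = max(1, int(round(window / (lz / nb))))
    kernel = np.ones(w)
    # circular convolution to allow windows across the boundary
    smoothed = np.real(
        np.fft.ifft(np.fft.fft(hist) * np.conj(np.fft.fft(
            np.concatenate([kernel, np.zeros(nb - w)])
        )))
    )
    imax = int(np.argmax(smoothed))
    coarse = (edges[imax] + window / 2.0) % lz
    # refine: mass-weighted mean of the minimum-image displacement from the
    # coarse center (translation-equivariant, stable when the slab is wider
    # than the scan window)
    dz = (z - coarse + lz / 2.0) % lz - lz / 2.0
    return (coarse + np.average(dz, weights=masses)) % lz


def density_profile(
    traj: Trajectory,
    masses: np.ndarray,
    n_bins: int = 120,
    discard_fraction: float = 0.0,
    centering: str = "window",
    window: float = 100.0,
) -> DensityProfile:
    """Mass concentration vs z, averaged over frames.

    Each frame is centered before averaging: with ``centering="window"`` the
    periodic center of mass of the densest ``window``-Angstrom sliding window
    is moved to the box midpoint; ``centering="none"`` skips the shift.
    The discarded leading fraction of frames is treated as equilibration.
    """
    if n_bins < 10:
        raise ValueError("n_bins must be >= 10")
    first = int(math.floor(discard_fraction * traj.n_frames))
    if first >= traj.n_frames:
        raise ValueError("no frames left after discard_fraction")
    masses = np.asarray(masses, dtype=np.float64)
    if masses.shape != (traj.n_beads,):
        raise ValueError("masses must have one entry per bead")
    box = traj.boxes[first]
    if not np.allclose(traj.boxes[first:], box):
        raise ValueError("analysis frames must share one box (production only)")
    lz = float(box[2])
    edges = np.linspace(0.0, lz, n_bins + 1)
    accum = np.zeros(n_bins)
    n_used = 0
    for f in range(first, traj.n_frames):
        z = traj.frames[f][:, 2]
        if centering == "window":
            zc = _center_offsets(z, masses, lz, window)
            z = (z - zc + lz / 2.0) % lz
        elif centering != "none":
            raise ValueError(f"unknown centering mode {centering!r}")
        hist, _ = np.histogram(z % lz, bins=edges, weights=masses)
        accum += hist
        n_used += 1
    bin_volume = box[0] * box[1] * (lz / n_bins)
    conc = accum / n_used / bin_volume * DA_PER_A3_TO_MG_ML
    return DensityProfile(
        bin_centers=0.5 * (edges[:-1] + edges[1:]),
        concentration=conc,
        n_frames=n_used,
        centering_mode=centering,
        box=np.asarray(box, dtype=np.float64),
        total_mass=float(masses.sum()),
    )


def _window_masks(profile: DensityProfile, dense_halfwidth, dilute_margin):
    dz = np.abs(profile.bin_centers - profile.z_mid)
    dense = dz <= dense_halfwidth
    dilute = dz >= dilute_margin
    return dense, dilute


def phase_concentrations(
    profile: DensityProfile,
    dense_halfwidth: float = 50.0,
    dilute_margin: float = 250.0,
) -> tuple[float, float]:
    """(c_dense, c_dilute) in mg/mL from window means around/away from the
    slab center.  Requires a centered profile."""
    if dense_halfwidth >= dilute_margin:
        raise ValueError(
            "dense window overlaps dilute region: "
            f"dense_halfwidth {dense_halfwidth} >= dilute_margin {dilute_margin}"
        )
    dense, dilute = _window_masks(profile, dense_halfwidth, dilute_margin)
    if not dense.any():
        raise ValueError("dense window contains no bins")
    if not dilute.any():
        raise ValueError("dilute window empty: dilute_margin beyond box")
    return (
        float(profile.concentration[dense].mean()),
        float(profile.concentration[dilute].mean()),
    )


def delta_g_trans(
    c_dense: float, c_dilute: float, temperature: float = 310.0
) -> float:
    """Excess transfer free energy ``-R T ln(c_dense/c_dilute)`` in kJ/mol."""
    if c_dense <= 0 or c_dilute <= 0:
        raise ValueError("concentrations must be > 0 (phase not defined)")
    return -R_KJ_MOL_K * temperature * math.log(c_dense / c_dilute)


def detect_condensate(
    profile: DensityProfile,
    peak_ratio_threshold: float = 10.0,
    dilute_margin: float = 250.0,
) -> bool:
    """True iff the peak bin exceeds ``threshold`` times the dilute mean.

    An empty (all-zero) dilute region with a nonzero peak counts as a
    condensate."""
    _, dilute = _window_masks(profile, 0.0, dilute_margin)
    if not dilute.any():
        raise ValueError("dilute_margin beyond box")
    peak = float(profile.concentration.max())
    dilute_mean = float(profile.concentration[dilute].mean())
    if dilute_mean == 0.0:
        return peak > 0.0
    return peak >= peak_ratio_threshold * dilute_mean


def compute_phase_metrics(
    profile: DensityProfile,
    name: str = "",
    temperature: float = 310.0,
    dense_halfwidth: float = 50.0,
    dilute_margin: float = 250.0,
    peak_ratio_threshold: float = 10.0,
) -> PhaseMetrics:
    """Bundle concentrations, transfer free energy and the condensate flag."""
    c_dense, c_dilute = phase_concentrations(profile, dense_halfwidth, dilute_margin)
    has = detect_condensate(profile, peak_ratio_threshold, dilute_margin)
    dg = None
    if has and c_dense > 0 and c_dilute > 0:
        dg = delta_g_trans(c_dense, c_dilute, temperature)
    return PhaseMetrics(
        name=name,
        c_dense=c_dense,
        c_dilute=c_dilute,
        delta_g_trans=dg,
        has_condensate=has,
        dense_halfwidth=dense_halfwidth,
        dilute_margin=dilute_margin,
    )


def rank_variants(
    metrics: list[tuple[str, PhaseMetrics]] | list[PhaseMetrics],
    tie_tolerance: float = 0.15,
) -> list[list[str]]:
    """Rank variants by ascending saturation concentration (strongest
    condensation first); dissolved variants rank last.

    Returns tiers: each inner list holds names whose ``c_dilute`` values are
    indistinguishable within the relative ``tie_tolerance``.  The sort is
    stable in the input order.
    """
    items: list[tuple[str, PhaseMetrics]] = [
        m if isinstance(m, tuple) else (m.name, m) for m in metrics
    ]
    if len(items) < 2:
        raise ValueError("need at least 2 variants to rank")
    names = [n for n, _ in items]
    if len(set(names)) != len(names):
        raise ValueError("duplicate variant names")
    condensed = [(n, m) for n, m in items if m.has_condensate]
    dissolved = [(n, m) for n, m in items if not m.has_condensate]
    condensed.sort(key=lambda nm: nm[1].c_dilute)
    tiers: list[list[str]] = []
    for n, m in condensed:
        if tiers:
            prev = next(
                mm for nn, mm in condensed if nn == tiers[-1][0]
            )
            ref = max(prev.c_dilute, 1e-300)
            if abs(m.c_dilute - prev.c_dilute) / ref <= tie_tolerance:
                tiers[-1].append(n)
                continue
        tiers.append([n])
    if dissolved:
        tiers.append([n for n, _ in dissolved])
    return tiers


def largest_cluster_fraction(
    config_or_traj,
    ff,
    rule_factor: float = 2.0 ** (1.0 / 6.0),
) -> np.ndarray:
    """Fraction of chains in the largest connected cluster, per frame.

    Two chains are connected when any inter-chain bead pair is closer than
    ``rule_factor * sigma_ij`` (the HPS contact rule by default).  Returns a
    scalar for a single configuration, an array over frames for a
    trajectory.  This is the reduced-system dissolution observable: a stable
    condensate keeps the fraction near 1, a dissolving one sheds chains.
    """
    from . import _kernels

    def one_frame(pos, box, chains, sigma):
        n_chains = len(chains)
        chain_of = np.empty(len(pos), dtype=np.int64)
        for c, (start, end) in enumerate(chains):
            chain_of[start:end] = c
        cutoff = rule_factor * float(sigma.max())
        pairs = _kernels.neighbor_pairs(
            np.ascontiguousarray(pos), np.asarray(box, dtype=float), cutoff
        )
        # union-find over chains
        parent = list(range(n_chains))

        def find(a):
            while parent[a] != a:
                parent[a] = parent[parent[a]]
                a = parent[a]
            return a

        for i, j in pairs:
            ci, cj = chain_of[i], chain_of[j]
            if ci == cj:
                continue
            d = pos[i] - pos[j]
            d -= box * np.round(d / box)
            sij = 0.5 * (sigma[i] + sigma[j])
            if float(d @ d) < (rule_factor * sij) ** 2:
                ra, rb = find(ci), find(cj)
                if ra != rb:
                    parent[ra] = rb
        sizes = np.bincount([find(c) for c in range(n_chains)],
                            minlength=n_chains)
        return sizes.max() / n_chains

    if isinstance(config_or_traj, Trajectory):
        traj = config_or_traj
        _, _, sigma, _ = ff.params_for(traj.bead_codes)
        return np.array([
            one_frame(traj.frames[f], traj.boxes[f], traj.chains, sigma)
            for f in range(traj.n_frames)
        ])
    config = config_or_traj
    _, _, sigma, _ = ff.params_for(config.bead_codes)
    return one_frame(config.positions, config.box, config.chains, sigma)
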