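"""Residue contact maps, difference maps, type-resolved contact profiles and
solvation histograms.

Two contact rules are supported: a fixed distance cutoff (4.5 A, the
Martini-style rule used for explicit-solvent condensate trajectories) and the
HPS rule ``r < 2^(1/6) sigma_ij`` with ``sigma_ij`` the arithmetic mean bead
diameter.  Contacts are strict inequalities.  Intra-chain pairs closer in
sequence than the exclusion (default two residues either side) are omitted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .forcefield import ForceField, TWO_POW_16
from .system import Trajectory

__all__ = [
    "ContactRule",
    "ContactMap",
    "TypeContactProfile",
    "SolvationHistogram",
    "SolvatedFrame",
    "contact_map",
    "contact_difference",
    "type_resolved_contacts",
    "solvation_histogram",
]


@dataclass(frozen=True)
class ContactRule:
    """``FIXED_CUTOFF`` with a distance in Angstrom, or ``SIGMA_CUTOFF``
    (requires a force field for the bead diameters)."""

    kind: str  # "FIXED_CUTOFF" | "SIGMA_CUTOFF"
    cutoff: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in {"FIXED_CUTOFF", "SIGMA_CUTOFF"}:
            raise ValueError(f"unknown contact rule {self.kind!r}")
        if self.kind == "FIXED_CUTOFF" and (self.cutoff is None or self.cutoff <= 0):
            raise ValueError("FIXED_CUTOFF requires a positive cutoff")

    @classmethod
    def fixed(cls, cutoff: float = 4.5) -> "ContactRule":
        return cls("FIXED_CUTOFF", cutoff)

    @classmethod
    def sigma(cls) -> "ContactRule":
        return cls("SIGMA_CUTOFF")


@dataclass
class ContactMap:
    """Symmetric L x L contact probabilities in full-length numbering.

    ``inter`` averages over ordered chain pairs and frames; ``intra`` over
    chains and frames with near-diagonal pairs (|i-j| <= exclusion) flagged
    absent (NaN), not zero.  ``matrix`` is the combined per-opportunity
    average the condensate maps mix (inter plus intra beyond the exclusion).
    """

    inter: np.ndarray
    intra: np.ndarray
    residue_numbers: np.ndarray
    rule: ContactRule
    exclusion: int
    n_frames: int
    n_chains: int

    @property
    def matrix(self) -> np.ndarray:
        n = self.n_chains
        n_pairs = max(1, n * (n - 1) // 2)
        intra = np.where(np.isnan(self.intra), 0.0, self.intra)
        return (self.inter * n_pairs + intra * n) / (n_pairs + n)


def _pair_cutoffs(rule: ContactRule, codes: Sequence[str], ff: ForceField | None):
    length = len(codes)
    if rule.kind == "FIXED_CUTOFF":
        return np.full((length, length), rule.cutoff)
    if ff is None:
        raise ValueError("SIGMA_CUTOFF rule requires a force field")
    _, _, sigma, _ = ff.params_for(codes)
    return TWO_POW_16 * 0.5 * (sigma[:, None] + sigma[None, :])


def _min_image_dists(a: np.ndarray, b: np.ndarray, box: np.ndarray) -> np.ndarray:
    d = a[:, None, :] - b[None, :, :]
    d -= box * np.round(d / box)
    return np.sqrt(np.sum(d * d, axis=-1))


def contact_map(
    traj: Trajectory,
    rule: ContactRule = ContactRule.fixed(4.5),
    exclusion: int = 2,
    ff: ForceField | None = None,
) -> ContactMap:
    """Contact probabilities averaged over frames and chains.

    All chains must share one sequence.  For each frame, residues i and j of
    an ordered pair of distinct chains score an inter-chain contact when their
    bead distance is below the rule's cutoff (minimum image); intra-chain
    contacts are tallied per chain with the sequence-separation exclusion.
    """
    if exclusion < 0:
        raise ValueError("exclusion must be >= 0")
    chains = traj.chains
    lengths = {end - start for start, end in chains}
    if len(lengths) != 1:
        raise ValueError("all chains must have the same length")
    length = lengths.pop()
    codes = traj.bead_codes[chains[0][0] : chains[0][1]]
    for start, end in chains:
        if traj.bead_codes[start:end] != codes:
            raise ValueError("all chains must share one sequence")
    cutoffs = _pair_cutoffs(rule, codes, ff)
    n_chains = len(chains)

    inter_events = np.zeros((length, length))
    intra_events = np.zeros((length, length))
    near = np.abs(np.subtract.outer(np.arange(length), np.arange(length))) <= exclusion
    for f in range(traj.n_frames):
        box = traj.boxes[f]
        coords = [traj.frames[f][start:end] for start, end in chains]
        for a in range(n_chains):
            for b in range(n_chains):
                if a == b:
                    d = _min_image_dists(coords[a], coords[a], box)
                    contact = (d < cutoffs) & ~near
                    intra_events += contact
                elif a < b:
                    d = _min_image_dists(coords[a], coords[b], box)
                    contact = d < cutoffs
                    # an unordered chain pair is one opportunity; either
                    # orientation (i of a with j of b, or i of b with j of a)
                    # realizes the (i, j) contact
                    inter_events += contact | contact.T
    n_pairs = max(1, n_chains * (n_chains - 1) // 2)
    inter = inter_events / (traj.n_frames * n_pairs)
    intra = intra_events / (traj.n_frames * n_chains)
    intra[near] = np.nan
    numbers = np.arange(length) + getattr(traj, "offset", 1)
    return ContactMap(
        inter=inter,
        intra=intra,
        residue_numbers=numbers,
        rule=rule,
        exclusion=exclusion,
        n_frames=traj.n_frames,
        n_chains=n_chains,
    )


def contact_difference(map_a: ContactMap, map_b: ContactMap) -> np.ndarray:
    """Entrywise ``P(A) - P(B)`` on the combined maps; absent entries stay NaN
    in the intra channel and are defined in the combined view."""
    if map_a.rule != map_b.rule:
        raise ValueError("contact rules differ")
    if map_a.exclusion != map_b.exclusion:
        raise ValueError("exclusions differ")
    if map_a.inter.shape != map_b.inter.shape:
        raise ValueError("map shapes differ")
    return map_a.matrix - map_b.matrix


@dataclass
class TypeContactProfile:
    """Partner amino-acid-type distribution of contacts made by a residue
    selection; probabilities sum to 1 when any contact exists."""

    probabilities: dict[str, float]
    n_contacts: int
    normalized: bool

    def as_array(self, order: Sequence[str]) -> np.ndarray:
        return np.array([self.probabilities.get(c, 0.0) for c in order])


def type_resolved_contacts(
    traj: Trajectory,
    source_sites: Iterable[int],
    rule: ContactRule = ContactRule.fixed(4.5),
    exclusion: int = 2,
    ff: ForceField | None = None,
    offset: int = 1,
) -> TypeContactProfile:
    """Contacts from the source residues (full-length numbering, identical in
    every chain) to all partner residues, tallied by partner type.

    Returns an empty, flagged profile when no contact occurs anywhere.
    """
    sources = sorted(set(source_sites))
    if not sources:
        raise ValueError("source_sites must be nonempty")
    chains = traj.chains
    length = chains[0][1] - chains[0][0]
    codes = traj.bead_codes[chains[0][0] : chains[0][1]]
    local = [s - offset for s in sources]
    if any(not 0 <= s < length for s in local):
        raise ValueError("source site outside chain sequence")
    cutoffs = _pair_cutoffs(rule, codes, ff)
    counts: dict[str, int] = {}
    total = 0
    for f in range(traj.n_frames):
        box = traj.boxes[f]
        coords = [traj.frames[f][start:end] for start, end in chains]
        for a in range(len(chains)):
            src = coords[a][local]
            for b in range(len(chains)):
                d = _min_image_dists(src, coords[b], box)
                contact = d < cutoffs[local]
                if a == b:
                    sep = np.abs(
                        np.subtract.outer(np.asarray(local), np.arange(length))
                    )
                    contact &= sep > exclusion
                for _, j in zip(*np.nonzero(contact)):
                    counts[codes[j]] = counts.get(codes[j], 0) + 1
                    total += 1
    if total == 0:
        return TypeContactProfile(probabilities={}, n_contacts=0, normalized=False)
    return TypeContactProfile(
        probabilities={c: k / total for c, k in counts.items()},
        n_contacts=total,
        normalized=True,
    )


# ---------------------------------------------------------------------------
# Solvation


@dataclass
class SolvatedFrame:
    """Protein bead positions plus tagged solvent particle positions."""

    protein_positions: np.ndarray  # (L, 3)
    solvent_positions: np.ndarray  # (W, 3)
    box: np.ndarray


@dataclass
class SolvationHistogram:
    """Distribution of solvent counts within the cutoff of selected residues."""

    counts: np.ndarray  # support 0..max
    frequencies: np.ndarray
    cutoff: float

    def mean(self) -> float:
        return float(np.sum(self.counts * self.frequencies))


def solvation_histogram(
    frames: Sequence[SolvatedFrame],
    selection: Iterable[int],
    cutoff: float = 5.0,
) -> SolvationHistogram:
    """Histogram of the number of solvent particles within ``cutoff`` of each
    selected residue (0-based indices into the protein beads), per frame."""
    if cutoff <= 0:
        raise ValueError("cutoff must be > 0")
    sel = sorted(set(selection))
    if not sel:
        raise ValueError("selection must be nonempty")
    tallies: list[int] = []
    for frame in frames:
        if len(frame.solvent_positions) == 0:
            raise ValueError("frame contains no solvent particles")
        box = np.asarray(frame.box, dtype=np.float64)
        d = _min_image_dists(
            np.asarray(frame.protein_positions)[sel],
            np.asarray(frame.solvent_positions),
            box,
        )
        tallies.extend((d < cutoff).sum(axis=1).tolist())
    counts = np.arange(max(tallies) + 1)
    freq = np.bincount(tallies, minlength=len(counts)).astype(float)
    freq /= freq.sum()
    return SolvationHistogram(counts=counts, frequencies=freq, cutoff=cutoff)
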