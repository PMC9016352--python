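"""Bead configurations and trajectories in periodic orthorhombic boxes."""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = ["SystemConfiguration", "Trajectory"]


@dataclass
class SystemConfiguration:
    """Bead positions with chain topology.

    ``chains`` holds half-open ``(start, end)`` bead-index ranges; consecutive
    beads within a chain are bonded.  ``bead_codes`` is one residue code per
    bead.  Set ``validate=False`` for analysis fixtures that are not meant to
    be simulable (e.g. planted-contact geometries with broken bonds).
    """

    positions: np.ndarray  # (N, 3) Angstrom
    box: np.ndarray  # (3,) Angstrom
    chains: list[tuple[int, int]]
    bead_codes: list[str]
    validate: bool = True

    def __post_init__(self) -> None:
        self.positions = np.ascontiguousarray(self.positions, dtype=np.float64)
        self.box = np.asarray(self.box, dtype=np.float64)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ValueError("positions must have shape (N, 3)")
        if self.box.shape != (3,) or np.any(self.box <= 0):
            raise ValueError("box must be three positive lengths")
        n = len(self.positions)
        if len(self.bead_codes) != n:
            raise ValueError("bead_codes length must match positions")
        covered = np.zeros(n, dtype=bool)
        for start, end in self.chains:
            if not (0 <= start < end <= n):
                raise ValueError(f"invalid chain range ({start}, {end})")
            if covered[start:end].any():
                raise ValueError("chains overlap")
            covered[start:end] = True
        if not covered.all():
            raise ValueError("chains must cover all beads")
        if self.validate:
            self.check_bonds()

    @property
    def n_beads(self) -> int:
        return len(self.positions)

    def bonds(self) -> np.ndarray:
        """(n_bonds, 2) array of bonded bead index pairs."""
        out = []
        for start, end in self.chains:
            for i in range(start, end - 1):
                out.append((i, i + 1))
        return np.asarray(out, dtype=np.int64).reshape(-1, 2)

    def bond_lengths(self) -> np.ndarray:
        bonds = self.bonds()
        if len(bonds) == 0:
            return np.empty(0)
        d = self.positions[bonds[:, 0]] - self.positions[bonds[:, 1]]
        d -= self.box * np.round(d / self.box)
        return np.linalg.norm(d, axis=1)

    def check_bonds(self, max_factor: float = 2.0, r0: float = 3.8) -> None:
        lengths = self.bond_lengths()
        if len(lengths) and lengths.max() > max_factor * r0:
            raise ValueError(
                f"bond length {lengths.max():.2f} A exceeds "
                f"{max_factor} * r0 = {max_factor * r0:.2f} A"
            )

    def chain_index(self) -> np.ndarray:
        """Per-bead chain id."""
        idx = np.empty(self.n_beads, dtype=np.int64)
        for c, (start, end) in enumerate(self.chains):
            idx[start:end] = c
        return idx

    def copy(self) -> "SystemConfiguration":
        return SystemConfiguration(
            self.positions.copy(), self.box.copy(), list(self.chains),
            list(self.bead_codes), validate=False,
        )


@dataclass
class Trajectory:
    """Ordered frames sharing one topology.

    ``frames`` has shape (n_frames, N, 3); ``boxes`` (n_frames, 3) because the
    slab protocol extends the box between phases; ``times`` in ps, strictly
    increasing.
    """

    frames: np.ndarray
    boxes: np.ndarray
    times: np.ndarray
    chains: list[tuple[int, int]]
    bead_codes: list[str]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.float64)
        self.boxes = np.asarray(self.boxes, dtype=np.float64)
        self.times = np.asarray(self.times, dtype=np.float64)
        if self.frames.ndim != 3:
            raise ValueError("frames must have shape (n_frames, N, 3)")
        nf = len(self.frames)
        if self.boxes.shape == (3,):
            self.boxes = np.tile(self.boxes, (nf, 1))
        if self.boxes.shape != (nf, 3) or len(self.times) != nf:
            raise ValueError("boxes/times inconsistent with frames")
        if nf > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        if len(self.bead_codes) != self.frames.shape[1]:
            raise ValueError("bead_codes length must match frame width")

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def n_beads(self) -> int:
        return self.frames.shape[1]

    def configuration(self, i: int) -> SystemConfiguration:
        return SystemConfiguration(
            self.frames[i], self.boxes[i], list(self.chains),
            list(self.bead_codes), validate=False,
        )

    def __iter__(self):
        return (self.configuration(i) for i in range(self.n_frames))
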