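"""The HPS one-bead-per-residue energy model.

Three terms:

* Ashbaugh-Hatch van der Waals: a Lennard-Jones potential whose attractive
  part is scaled by the arithmetic-mean hydrophobicity ``lambda_ij``; below
  the LJ minimum (``2^(1/6) sigma_ij``) the full repulsive core is kept and
  shifted by ``(1 - lambda_ij) eps`` so the potential is continuous.
* Debye-Hueckel screened electrostatics between integer bead charges.
* Harmonic bonds ``1/2 k (r - r0)^2`` between consecutive residues.

Internal units: kJ/mol, Angstrom, Da, ps; charges in elementary charges.
"""

from __future__ import annotations

import csv
import hashlib
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np

from .sequences import CANONICAL_AA, PHOSPHOSERINE

__all__ = [
    "BeadTypeParams",
    "ForceField",
    "EnergyBreakdown",
    "make_forcefield",
    "debye_length",
    "vdw_pair_energy",
    "elec_pair_energy",
    "total_energy",
    "forces",
    "KCAL_TO_KJ",
    "COULOMB_KJ_A",
    "KB_KJ_MOL_K",
]

KCAL_TO_KJ = 4.184
#: e^2 / (4 pi eps0) in kJ/mol * Angstrom
COULOMB_KJ_A = 1389.35
KB_KJ_MOL_K = 8.31446e-3
TWO_POW_16 = 2.0 ** (1.0 / 6.0)

_REQUIRED_CODES = sorted(CANONICAL_AA) + [PHOSPHOSERINE]


@dataclass(frozen=True)
class BeadTypeParams:
    code: str
    mass: float  # Da
    charge: float  # e
    sigma: float  # Angstrom
    lam: float  # dimensionless hydrophobicity

    def __post_init__(self) -> None:
        if self.mass <= 0:
            raise ValueError(f"{self.code}: mass must be > 0")
        if self.sigma <= 0:
            raise ValueError(f"{self.code}: sigma must be > 0")
        if not 0.0 <= self.lam <= 1.1:
            raise ValueError(f"{self.code}: lambda outside [0, 1.1]")


@dataclass(frozen=True)
class ForceField:
    """Bead-type parameters plus global interaction constants."""

    bead_types: dict[str, BeadTypeParams]
    epsilon: float  # kJ/mol (Ashbaugh-Hatch depth scale)
    bond_k: float  # kJ/(mol A^2)
    bond_r0: float  # A
    dielectric: float
    debye_length: float  # A
    cutoff_vdw: float  # A
    cutoff_elec: float  # A
    temperature: float  # K
    ionic_strength: float  # mol/L

    def __post_init__(self) -> None:
        if self.epsilon <= 0 or self.bond_r0 <= 0 or self.debye_length <= 0:
            raise ValueError("epsilon, bond_r0 and debye_length must be > 0")
        max_sigma = max(t.sigma for t in self.bead_types.values())
        switch = TWO_POW_16 * max_sigma
        if self.cutoff_vdw <= switch or self.cutoff_elec <= switch:
            raise ValueError(
                f"cutoffs must exceed 2^(1/6)*max sigma = {switch:.2f} A"
            )

    def params_for(self, codes) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """(mass, charge, sigma, lambda) arrays for a bead-code sequence."""
        try:
            rows = [self.bead_types[c] for c in codes]
        except KeyError as exc:
            raise KeyError(f"unknown residue code {exc.args[0]!r}") from None
        return (
            np.array([r.mass for r in rows]),
            np.array([r.charge for r in rows]),
            np.array([r.sigma for r in rows]),
            np.array([r.lam for r in rows]),
        )

    @property
    def coulomb_prefactor(self) -> float:
        """e^2/(4 pi eps0 D) in kJ/mol*A per unit charge product."""
        return COULOMB_KJ_A / self.dielectric

    def content_hash(self) -> str:
        text = repr(sorted(self.bead_types.items())) + repr(
            (self.epsilon, self.bond_k, self.bond_r0, self.dielectric,
             self.debye_length, self.cutoff_vdw, self.cutoff_elec)
        )
        return hashlib.sha256(text.encode()).hexdigest()[:16]


def debye_length(
    temperature: float, ionic_strength: float, dielectric: float
) -> float:
    """Debye screening length in Angstrom.

    ``kappa^-1 = sqrt(eps0 * D * kB * T / (2 * NA * e^2 * I))`` with the ionic
    strength ``I`` in mol/L of monovalent salt.
    """
    if ionic_strength <= 0:
        raise ValueError("ionic strength must be > 0")
    eps0 = 8.8541878128e-12  # F/m
    kb = 1.380649e-23  # J/K
    e = 1.602176634e-19  # C
    na = 6.02214076e23
    i_m3 = ionic_strength * 1000.0 * na  # ions / m^3 per unit charge
    lam_m = math.sqrt(eps0 * dielectric * kb * temperature / (2.0 * e * e * i_m3))
    return lam_m * 1e10


def make_forcefield(
    param_table_path: str | Path | None = None,
    temperature: float = 310.0,
    ionic_strength: float = 0.1,
    *,
    epsilon_kcal: float = 0.2,
    bond_k: float = 10.0,
    bond_r0: float = 3.8,
    dielectric: float = 80.0,
    cutoff_vdw: float = 25.0,
    cutoff_elec: float = 35.0,
) -> ForceField:
    """Load a bead parameter table and assemble a :class:`ForceField`.

    The table must cover the 20 canonical residues plus phosphoserine.  The
    Debye length is computed from ``ionic_strength`` (mol/L) and
    ``temperature`` via Debye-Hueckel screening.
    """
    if param_table_path is None:
        ctx = resources.as_file(
            resources.files("lcdphase.data") / "hps_params.csv"
        )
        with ctx as p:
            return make_forcefield(
                p, temperature, ionic_strength, epsilon_kcal=epsilon_kcal,
                bond_k=bond_k, bond_r0=bond_r0, dielectric=dielectric,
                cutoff_vdw=cutoff_vdw, cutoff_elec=cutoff_elec,
            )
    bead_types: dict[str, BeadTypeParams] = {}
    with open(param_table_path) as fh:
        for row in csv.DictReader(r for r in fh if not r.lstrip().startswith("#")):
            code = row["code"].strip()
            bead_types[code] = BeadTypeParams(
                code=code,
                mass=float(row["mass"]),
                charge=float(row["charge"]),
                sigma=float(row["sigma_A"]),
                lam=float(row["lambda"]),
            )
    missing = [c for c in _REQUIRED_CODES if c not in bead_types]
    if missing:
        raise ValueError(
            f"parameter table {param_table_path} missing residue types: "
            + ", ".join(missing)
        )
    return ForceField(
        bead_types=bead_types,
        epsilon=epsilon_kcal * KCAL_TO_KJ,
        bond_k=bond_k,
        bond_r0=bond_r0,
        dielectric=dielectric,
        debye_length=debye_length(temperature, ionic_strength, dielectric),
        cutoff_vdw=cutoff_vdw,
        cutoff_elec=cutoff_elec,
        temperature=temperature,
        ionic_strength=ionic_strength,
    )


# ---------------------------------------------------------------------------
# Pair energies (scalar reference implementations)


def _lj(r: float, sigma: float, eps: float) -> float:
    sr6 = (sigma / r) ** 6
    return 4.0 * eps * (sr6 * sr6 - sr6)


def vdw_pair_energy(
    r: float, code_i: str, code_j: str, ff: ForceField, shift: bool = False
) -> float:
    """Ashbaugh-Hatch pair energy in kJ/mol.

    ``Phi = LJ + (1 - lambda_ij) eps`` for ``r <= 2^(1/6) sigma_ij``, else
    ``lambda_ij * LJ``; both branches give ``-lambda_ij * eps`` at the switch.
    With ``shift=True`` the tail value at the cutoff is subtracted (the form
    used during dynamics) and the energy is zero beyond the cutoff.
    """
    if r <= 0:
        raise ValueError("r must be > 0")
    _, _, sig, lam = ff.params_for([code_i, code_j])
    sigma_ij = 0.5 * (sig[0] + sig[1])
    lam_ij = 0.5 * (lam[0] + lam[1])
    if shift and r >= ff.cutoff_vdw:
        return 0.0
    if r <= TWO_POW_16 * sigma_ij:
        val = _lj(r, sigma_ij, ff.epsilon) + (1.0 - lam_ij) * ff.epsilon
    else:
        val = lam_ij * _lj(r, sigma_ij, ff.epsilon)
    if shift:
        val -= lam_ij * _lj(ff.cutoff_vdw, sigma_ij, ff.epsilon)
    return val


def elec_pair_energy(
    r: float, code_i: str, code_j: str, ff: ForceField, shift: bool = False
) -> float:
    """Debye-Hueckel screened Coulomb pair energy in kJ/mol:
    ``q_i q_j e^2 exp(-r/kappa^-1) / (4 pi eps0 D r)``."""
    if r <= 0:
        raise ValueError("r must be > 0")
    _, q, _, _ = ff.params_for([code_i, code_j])
    if q[0] == 0.0 or q[1] == 0.0:
        return 0.0
    if shift and r >= ff.cutoff_elec:
        return 0.0
    pref = ff.coulomb_prefactor * q[0] * q[1]
    val = pref * math.exp(-r / ff.debye_length) / r
    if shift:
        val -= pref * math.exp(-ff.cutoff_elec / ff.debye_length) / ff.cutoff_elec
    return val


# ---------------------------------------------------------------------------
# System-level energies and forces (numba-accelerated)


@dataclass(frozen=True)
class EnergyBreakdown:
    bond: float
    vdw: float
    elec: float

    @property
    def total(self) -> float:
        return self.bond + self.vdw + self.elec


def _check_box(config, ff: ForceField) -> None:
    # minimum-image is only valid if the box holds at least two cutoffs
    min_dim = float(np.min(config.box))
    if min_dim < 2.0 * max(ff.cutoff_vdw, ff.cutoff_elec):
        raise ValueError(
            f"box dimension {min_dim:.1f} A smaller than twice the largest "
            f"cutoff ({max(ff.cutoff_vdw, ff.cutoff_elec):.1f} A)"
        )


def total_energy(
    config, ff: ForceField, use_neighbor_list: bool = True
) -> EnergyBreakdown:
    """Potential energy with per-term breakdown (bond, vdw, elec), kJ/mol.

    Nonbonded terms are truncated-and-shifted at their cutoffs; directly
    bonded pairs are excluded from the nonbonded sum.  The neighbor-list and
    all-pairs paths agree to floating-point accumulation accuracy.
    """
    from . import _kernels

    _check_box(config, ff)
    mass, charge, sigma, lam = ff.params_for(config.bead_codes)
    bonds = config.bonds()
    pos = np.ascontiguousarray(config.positions, dtype=np.float64)
    box = np.asarray(config.box, dtype=np.float64)
    args = (
        pos, box, sigma, lam, charge,
        ff.epsilon, ff.coulomb_prefactor, ff.debye_length,
        ff.cutoff_vdw, ff.cutoff_elec,
        _kernels.bond_exclusion_mask(len(pos), bonds),
    )
    if use_neighbor_list:
        pairs = _kernels.neighbor_pairs(pos, box, max(ff.cutoff_vdw, ff.cutoff_elec))
        e_vdw, e_el, _ = _kernels.nonbonded_pairs(pairs, *args, compute_forces=False)
    else:
        e_vdw, e_el, _ = _kernels.nonbonded_all(*args, compute_forces=False)
    e_bond = _kernels.bond_energy_forces(
        pos, box, bonds, ff.bond_k, ff.bond_r0, compute_forces=False
    )[0]
    return EnergyBreakdown(bond=float(e_bond), vdw=float(e_vdw), elec=float(e_el))


def forces(config, ff: ForceField, use_neighbor_list: bool = True) -> np.ndarray:
    """Analytic forces, kJ/mol/A, shape (N, 3)."""
    from . import _kernels

    _check_box(config, ff)
    mass, charge, sigma, lam = ff.params_for(config.bead_codes)
    bonds = config.bonds()
    pos = np.ascontiguousarray(config.positions, dtype=np.float64)
    box = np.asarray(config.box, dtype=np.float64)
    args = (
        pos, box, sigma, lam, charge,
        ff.epsilon, ff.coulomb_prefactor, ff.debye_length,
        ff.cutoff_vdw, ff.cutoff_elec,
        _kernels.bond_exclusion_mask(len(pos), bonds),
    )
    if use_neighbor_list:
        pairs = _kernels.neighbor_pairs(pos, box, max(ff.cutoff_vdw, ff.cutoff_elec))
        _, _, f = _kernels.nonbonded_pairs(pairs, *args, compute_forces=True)
    else:
        _, _, f = _kernels.nonbonded_all(*args, compute_forces=True)
    _, fb = _kernels.bond_energy_forces(
        pos, box, bonds, ff.bond_k, ff.bond_r0, compute_forces=True
    )
    return f + fb
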