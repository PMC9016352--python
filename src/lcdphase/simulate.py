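"""Langevin dynamics with the slab coexistence protocol.

The slab method simulates liquid-liquid coexistence by (i) growing all chains
inside a small sub-volume, (ii) equilibrating the resulting compact
condensate, (iii) extending the box along z, and (iv) running constant-volume
production so a dense slab equilibrates against its own dilute phase.

Integration uses the BAOAB splitting of Langevin dynamics.  Defaults follow
common usage of the HPS model: 10 fs timestep, friction 0.01 ps^-1, 310 K.
Runs are deterministic for a given (seed, inputs) pair on one platform; the
random stream is a counter-based Philox generator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from . import _kernels
from .forcefield import KB_KJ_MOL_K, ForceField
from .system import SystemConfiguration, Trajectory

__all__ = [
    "Phase",
    "SimulationSchedule",
    "SimulationUnstableError",
    "initialize_compact",
    "extend_to_slab",
    "run_langevin",
    "slab_schedule",
    "PRESETS",
]

#: kinetic-energy conversion: Da * (A/ps)^2 -> kJ/mol
KE_UNIT = 0.01
_FORCE_LIMIT = 1.0e6  # kJ/mol/A; far beyond any physical force here


class SimulationUnstableError(RuntimeError):
    """Raised when forces overflow (overlapping beads or too-long timestep)."""

    def __init__(self, message: str, config: SystemConfiguration | None = None):
        super().__init__(message)
        self.config = config


@dataclass(frozen=True)
class Phase:
    label: str
    n_steps: int
    new_lz: float | None = None  # extend box to this Lz before the phase

    def __post_init__(self) -> None:
        if self.n_steps < 0:
            raise ValueError("n_steps must be >= 0")


@dataclass(frozen=True)
class SimulationSchedule:
    timestep_fs: float = 10.0
    temperature: float = 310.0
    friction: float = 0.01  # ps^-1
    seed: int = 0
    phases: tuple[Phase, ...] = ()
    stride: int = 1000
    #: force-capped, strongly-thermostatted warmup to relax initial overlaps
    soft_start_steps: int = 2000
    soft_cap: float = 1000.0  # kJ/mol/A
    soft_start_friction: float = 5.0  # ps^-1

    def __post_init__(self) -> None:
        if self.timestep_fs <= 0:
            raise ValueError("timestep must be > 0")
        if self.stride < 1:
            raise ValueError("stride must be >= 1")

    def manifest(self) -> dict:
        return {
            "timestep_fs": self.timestep_fs,
            "temperature_K": self.temperature,
            "friction_per_ps": self.friction,
            "seed": self.seed,
            "stride": self.stride,
            "soft_start_steps": self.soft_start_steps,
            "soft_cap": self.soft_cap,
            "phases": [
                {"label": p.label, "n_steps": p.n_steps, "new_lz": p.new_lz}
                for p in self.phases
            ],
        }


#: reduced-scale and full-scale slab presets; the "paper" preset is
#: cluster-scale and not meant for a workstation.
PRESETS = {
    "desk": {
        "n_chains": 50,
        "box": (160.0, 160.0, 1200.0),
        "sub_lz": 300.0,
        "equilibration_steps": 500_000,
        "production_steps": 2_000_000,
    },
    "paper": {
        "n_chains": 100,
        "box": (212.0, 212.0, 2800.0),
        "sub_lz": 500.0,
        "equilibration_steps": 500_000,
        "production_steps": 58_000_000,  # >= 5.8 us at 10 fs/step
    },
}


def slab_schedule(
    preset: str | dict = "desk",
    seed: int = 0,
    temperature: float = 310.0,
    stride: int = 2000,
    **overrides,
) -> tuple[dict, SimulationSchedule]:
    """Resolve a preset into (system parameters, schedule)."""
    params = dict(PRESETS[preset] if isinstance(preset, str) else preset)
    params.update(overrides)
    schedule = SimulationSchedule(
        temperature=temperature,
        seed=seed,
        stride=stride,
        phases=(
            Phase("equilibration", params["equilibration_steps"]),
            Phase("production", params["production_steps"],
                  new_lz=params["box"][2]),
        ),
    )
    return params, schedule


# ---------------------------------------------------------------------------
# Chain construction


def initialize_compact(
    n_chains: int,
    sequence,
    ff: ForceField,
    sub_box: tuple[float, float, float],
    seed: int = 0,
    box: tuple[float, float, float] | None = None,
    clash_factor: float = 0.8,
    max_restarts: int = 200,
) -> SystemConfiguration:
    """Grow ``n_chains`` copies of ``sequence`` as self-avoiding walks inside
    ``sub_box`` (centered in ``box``), bond length = ``ff.bond_r0``.

    No two non-bonded beads end up closer than ``clash_factor * min sigma``.
    Raises ``RuntimeError`` when the requested density cannot be packed within
    the retry budget.
    """
    rng = np.random.Generator(np.random.Philox(seed))
    codes = list(sequence.residues)
    length = len(codes)
    _, _, sigma, _ = ff.params_for(codes)
    min_dist = clash_factor * float(sigma.min())
    box = np.asarray(box if box is not None else sub_box, dtype=np.float64)
    sub = np.asarray(sub_box, dtype=np.float64)
    if np.any(sub > box + 1e-9):
        raise ValueError("sub_box must fit inside box")
    lo = (box - sub) / 2.0
    hi = lo + sub
    r0 = ff.bond_r0

    # coarse occupancy grid for clash checks (keys wrap periodically)
    cell = max(min_dist, 1.0)
    ncells = np.maximum(1, (box // cell).astype(int))
    grid: dict[tuple[int, int, int], list[np.ndarray]] = {}

    def cell_key(p):
        return tuple(int(c) for c in (np.floor(p / cell).astype(int) % ncells))

    def clashes(p, own_chain=None, n_own=0) -> bool:
        kx, ky, kz = cell_key(p)
        for ox in (-1, 0, 1):
            for oy in (-1, 0, 1):
                for oz in (-1, 0, 1):
                    key = (
                        (kx + ox) % int(ncells[0]),
                        (ky + oy) % int(ncells[1]),
                        (kz + oz) % int(ncells[2]),
                    )
                    for q in grid.get(key, ()):
                        d = p - q
                        d -= box * np.round(d / box)
                        if float(d @ d) < min_dist * min_dist:
                            return True
        if own_chain is not None and n_own > 1:
            # check against the growing chain itself, skipping the bonded
            # predecessor
            d = own_chain[: n_own - 1] - p
            d -= box * np.round(d / box)
            if float(np.min(np.sum(d * d, axis=1))) < min_dist * min_dist:
                return True
        return False

    positions = np.empty((n_chains * length, 3))
    for c in range(n_chains):
        for attempt in range(max_restarts + 1):
            chain = np.empty((length, 3))
            chain[0] = lo + rng.random(3) * sub
            ok = not clashes(chain[0])
            i = 1
            local_tries = 0
            while ok and i < length:
                u = rng.normal(size=3)
                u /= np.linalg.norm(u)
                cand = chain[i - 1] + r0 * u
                if (
                    np.all(cand >= lo)
                    and np.all(cand <= hi)
                    and not clashes(cand, chain, i)
                ):
                    chain[i] = cand
                    i += 1
                    local_tries = 0
                else:
                    local_tries += 1
                    if local_tries > 200:
                        ok = False
            if ok and i == length:
                break
        else:
            raise RuntimeError(
                f"could not place chain {c} after {max_restarts} restarts: "
                "sub_box too dense"
            )
        start = c * length
        positions[start : start + length] = chain
        for p in chain:
            grid.setdefault(cell_key(p), []).append(p)

    chains = [(c * length, (c + 1) * length) for c in range(n_chains)]
    return SystemConfiguration(
        positions=positions,
        box=box,
        chains=chains,
        bead_codes=codes * n_chains,
    )


def extend_to_slab(
    config: SystemConfiguration, new_lz: float
) -> SystemConfiguration:
    """Extend the box along z, recentering the condensate at ``new_lz / 2``.

    All pairwise geometry within the old box is preserved (rigid shift after
    periodic unwrapping around the circular mean of z).
    """
    lz = float(config.box[2])
    if new_lz < lz:
        raise ValueError(f"new_Lz {new_lz} smaller than current Lz {lz}")
    out = config.copy()
    z = out.positions[:, 2]
    # make each chain whole across the old periodic z boundary so no bond is
    # cut when the wrap at lz disappears
    for start, end in out.chains:
        for i in range(start + 1, end):
            dz = z[i] - z[i - 1]
            z[i] = z[i - 1] + dz - lz * round(dz / lz)
    # circular mean locates the condensate even if it straddles the boundary
    theta = 2.0 * np.pi * (z % lz) / lz
    mean_theta = math.atan2(np.mean(np.sin(theta)), np.mean(np.cos(theta)))
    z_center = (mean_theta / (2.0 * np.pi)) * lz % lz
    # move whole chains by box multiples so their centers sit within half a
    # box of the condensate center, then recenter at new_lz / 2
    for start, end in out.chains:
        mean_z = z[start:end].mean()
        z[start:end] -= lz * np.round((mean_z - z_center) / lz)
    # refine with the arithmetic center so the condensate sits exactly at
    # the new midplane (the circular mean is only a coarse locator)
    out.positions[:, 2] = z - z.mean() + new_lz / 2.0
    out.box = np.array([config.box[0], config.box[1], float(new_lz)])
    return out


# ---------------------------------------------------------------------------
# Langevin integrator


class _ForceEngine:
    """Neighbor-listed force/energy evaluation with displacement-triggered
    rebuilds (Verlet skin)."""

    def __init__(self, ff: ForceField, codes, bonds, skin: float = 3.0):
        self.ff = ff
        self.skin = skin
        mass, charge, sigma, lam = ff.params_for(codes)
        self.mass = mass
        self.charge = charge
        self.sigma = sigma
        self.lam = lam
        self.bonds = bonds
        self.excl = _kernels.bond_exclusion_mask(len(mass), bonds)
        self.rc = max(ff.cutoff_vdw, ff.cutoff_elec)
        self._pairs = None
        self._ref_pos = None

    def _maybe_rebuild(self, pos, box):
        if self._pairs is None or self._ref_pos is None:
            rebuild = True
        else:
            disp = pos - self._ref_pos
            disp -= box * np.round(disp / box)
            rebuild = float(np.max(np.abs(disp))) > self.skin / 2.0
        if rebuild:
            self._pairs = _kernels.neighbor_pairs(pos, box, self.rc, self.skin)
            self._ref_pos = pos.copy()

    def invalidate(self):
        self._pairs = None

    def __call__(self, pos, box):
        self._maybe_rebuild(pos, box)
        ff = self.ff
        e_vdw, e_el, f = _kernels.nonbonded_pairs(
            self._pairs, pos, box, self.sigma, self.lam, self.charge,
            ff.epsilon, ff.coulomb_prefactor, ff.debye_length,
            ff.cutoff_vdw, ff.cutoff_elec, self.excl, True,
        )
        e_b, f_b = _kernels.bond_energy_forces(
            pos, box, self.bonds, ff.bond_k, ff.bond_r0, True
        )
        return e_vdw + e_el + e_b, f + f_b


def run_langevin(
    config: SystemConfiguration,
    ff: ForceField,
    schedule: SimulationSchedule,
) -> Trajectory:
    """Integrate Langevin dynamics over the schedule's phases.

    Frames are saved every ``schedule.stride`` steps (plus the initial frame
    and the final frame of every phase).  With ``friction = 0`` the integrator
    reduces to velocity Verlet (NVE check mode).
    """
    rng = np.random.Generator(np.random.Philox(schedule.seed))
    dt = schedule.timestep_fs * 1e-3  # ps
    kt = KB_KJ_MOL_K * schedule.temperature
    gamma = schedule.friction

    state = config.copy()
    engine = _ForceEngine(ff, state.bead_codes, state.bonds())
    mass = engine.mass[:, None]
    # Maxwell-Boltzmann velocities; unit care: kT[kJ/mol]/m[Da] -> (A/ps)^2 / KE_UNIT / 2...
    # v_sigma = sqrt(kT / (KE_UNIT * m)) in A/ps
    v_sigma = np.sqrt(kt / (KE_UNIT * mass))
    vel = rng.normal(size=state.positions.shape) * v_sigma

    c1 = math.exp(-gamma * dt)
    c2 = math.sqrt(max(0.0, 1.0 - c1 * c1))
    gamma_soft = max(gamma, schedule.soft_start_friction)
    c1s = math.exp(-gamma_soft * dt)
    c2s = math.sqrt(max(0.0, 1.0 - c1s * c1s))

    frames = [state.positions.copy()]
    boxes = [state.box.copy()]
    times = [0.0]
    temps: list[float] = []
    pes: list[float] = []

    def record(t):
        frames.append(state.positions.copy())
        boxes.append(state.box.copy())
        times.append(t)

    def check(f, where):
        if not np.all(np.isfinite(f)) or np.max(np.abs(f)) > _FORCE_LIMIT:
            raise SimulationUnstableError(
                f"force overflow during {where}: check timestep/overlaps",
                config=state,
            )

    t = 0.0
    global_step = 0

    def soften(f):
        if global_step >= schedule.soft_start_steps:
            return f
        mag = np.linalg.norm(f, axis=1, keepdims=True)
        scale = np.minimum(1.0, schedule.soft_cap / np.maximum(mag, 1e-12))
        return f * scale

    pe, force = engine(state.positions, state.box)
    check(force, "initialization")
    force = soften(force)
    # force in kJ/mol/A; acceleration a = F/m * KE_UNIT gives A/ps^2...
    # dv = F/m * dt in Da-units requires the same 0.01 conversion as KE
    acc_unit = 1.0 / KE_UNIT

    for phase in schedule.phases:
        if phase.new_lz is not None:
            state = extend_to_slab(state, phase.new_lz)
            engine.invalidate()
            pe, force = engine(state.positions, state.box)
            check(force, f"{phase.label} box extension")
        for step in range(phase.n_steps):
            soft = global_step < schedule.soft_start_steps
            vel += 0.5 * dt * force / mass * acc_unit
            state.positions += 0.5 * dt * vel
            if soft:
                vel = c1s * vel + c2s * v_sigma * rng.normal(size=vel.shape)
            elif gamma > 0.0:
                vel = c1 * vel + c2 * v_sigma * rng.normal(size=vel.shape)
            state.positions += 0.5 * dt * vel
            pe, force = engine(state.positions, state.box)
            check(force, phase.label)
            force = soften(force)
            vel += 0.5 * dt * force / mass * acc_unit
            t += dt
            global_step += 1
            if (step + 1) % schedule.stride == 0 or step + 1 == phase.n_steps:
                record(t)
                ke = 0.5 * KE_UNIT * float(np.sum(engine.mass * np.sum(vel**2, axis=1)))
                temps.append(2.0 * ke / (3.0 * state.n_beads * KB_KJ_MOL_K))
                pes.append(float(pe))

    # wrap frames into their boxes for analysis convenience
    frames_arr = np.asarray(frames)
    boxes_arr = np.asarray(boxes)
    frames_arr %= boxes_arr[:, None, :]
    return Trajectory(
        frames=frames_arr,
        boxes=boxes_arr,
        times=np.asarray(times),
        chains=list(state.chains),
        bead_codes=list(state.bead_codes),
        provenance={
            "schedule": schedule.manifest(),
            "forcefield_hash": ff.content_hash(),
            "mean_temperature_K": float(np.mean(temps)) if temps else None,
            "instantaneous_temperatures_K": temps,
            "potential_energies_kJ_mol": pes,
        },
    )
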