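"""Langevin engine: chain construction, slab extension, determinism,
thermostat statistics and NVE energy conservation."""

import numpy as np
import pytest
from scipy import stats

from lcdphase.forcefield import KB_KJ_MOL_K
from lcdphase.sequences import ProteinSequence
from lcdphase.simulate import (
    Phase,
    SimulationSchedule,
    extend_to_slab,
    initialize_compact,
    run_langevin,
)
from lcdphase.system import SystemConfiguration


def free_bead(code="G", box=80.0):
    return SystemConfiguration(
        np.array([[box / 2, box / 2, box / 2]]),
        np.array([box, box, box]), [(0, 1)], [code],
    )


def dimer(ff, stretch=0.0, box=80.0):
    return SystemConfiguration(
        np.array([
            [box / 2, box / 2, box / 2],
            [box / 2 + ff.bond_r0 + stretch, box / 2, box / 2],
        ]),
        np.array([box, box, box]), [(0, 2)], ["G", "G"],
    )


class TestInitializeCompact:
    def test_single_chain_bonds_at_r0(self, ff):
        seq = ProteinSequence("penta", "GGGGG")
        cfg = initialize_compact(1, seq, ff, (60.0, 60.0, 60.0), seed=7,
                                 box=(80.0, 80.0, 80.0))
        lengths = cfg.bond_lengths()
        assert len(lengths) == 4
        assert np.allclose(lengths, ff.bond_r0, atol=1e-6)

    def test_multi_chain_clash_free(self, ff):
        seq = ProteinSequence("mix", "GSNQAYFRDE" * 4)
        cfg = initialize_compact(6, seq, ff, (70.0, 70.0, 70.0), seed=3)
        assert cfg.n_beads == 240
        # pairwise scan: no non-bonded pair below 0.8 * min sigma
        pos, box = cfg.positions, cfg.box
        d = pos[:, None, :] - pos[None, :, :]
        d -= box * np.round(d / box)
        r = np.sqrt((d**2).sum(-1))
        np.fill_diagonal(r, np.inf)
        for a, b in cfg.bonds():
            r[a, b] = r[b, a] = np.inf
        min_sigma = min(ff.bead_types[c].sigma for c in set(seq.residues))
        assert r.min() >= 0.8 * min_sigma - 1e-9

    def test_impossible_density_errors_not_hangs(self, ff):
        seq = ProteinSequence("long", "G" * 100)
        with pytest.raises(RuntimeError, match="too dense"):
            initialize_compact(
                40, seq, ff, (15.0, 15.0, 15.0), seed=1, max_restarts=3
            )

    def test_sub_box_must_fit(self, ff):
        seq = ProteinSequence("g", "GG")
        with pytest.raises(ValueError, match="sub_box"):
            initialize_compact(1, seq, ff, (90.0, 90.0, 90.0), seed=1,
                               box=(80.0, 80.0, 80.0))


class TestExtendToSlab:
    def _blob(self, rng):
        # compact blob of single-bead chains near the box center
        pos = 45.0 + rng.random((30, 3)) * 10.0
        return SystemConfiguration(
            pos, np.array([100.0, 100.0, 100.0]),
            [(i, i + 1) for i in range(30)], ["G"] * 30, validate=False,
        )

    def test_pairwise_distances_preserved(self, rng):
        cfg = self._blob(rng)
        d0 = np.linalg.norm(
            cfg.positions[:, None] - cfg.positions[None, :], axis=-1
        )
        out = extend_to_slab(cfg, 500.0)
        d1 = np.linalg.norm(
            out.positions[:, None] - out.positions[None, :], axis=-1
        )
        assert np.allclose(d0, d1, atol=1e-9)
        assert out.box[2] == 500.0
        assert np.allclose(out.positions[:, :2], cfg.positions[:, :2])

    def test_condensate_recentered_at_midplane(self, rng):
        cfg = self._blob(rng)
        out = extend_to_slab(cfg, 600.0)
        assert out.positions[:, 2].mean() == pytest.approx(300.0, abs=1e-6)

    def test_idempotent_at_same_target(self, rng):
        cfg = self._blob(rng)
        once = extend_to_slab(cfg, 400.0)
        twice = extend_to_slab(once, 400.0)
        assert np.allclose(once.positions, twice.positions, atol=1e-9)

    def test_shrinking_rejected(self, rng):
        cfg = self._blob(rng)
        with pytest.raises(ValueError, match="smaller"):
            extend_to_slab(cfg, 50.0)

    def test_chain_spanning_boundary_stays_bonded(self):
        # a 3-bead chain wrapped across z = 0 must come out whole
        pos = np.array([
            [50.0, 50.0, 99.0], [50.0, 50.0, 1.0], [50.0, 50.0, 4.0]
        ])
        cfg = SystemConfiguration(
            pos, np.array([100.0, 100.0, 100.0]), [(0, 3)],
            ["G", "G", "G"], validate=False,
        )
        out = extend_to_slab(cfg, 300.0)
        gaps = np.abs(np.diff(out.positions[:, 2]))
        assert gaps.max() < 5.0  # no bond ripped across the old boundary


class TestRunLangevin:
    def test_zero_steps_returns_initial_frame(self, ff):
        traj = run_langevin(
            free_bead(), ff,
            SimulationSchedule(seed=1, phases=(Phase("p", 0),)),
        )
        assert traj.n_frames == 1
        assert traj.times[0] == 0.0

    def test_identical_seed_bitwise_reproducible(self, ff):
        sch = SimulationSchedule(
            seed=11, phases=(Phase("p", 500),), stride=100,
            soft_start_steps=0,
        )
        t1 = run_langevin(dimer(ff), ff, sch)
        t2 = run_langevin(dimer(ff), ff, sch)
        assert np.array_equal(t1.frames, t2.frames)

    def test_different_seeds_diverge(self, ff):
        t1 = run_langevin(dimer(ff), ff, SimulationSchedule(
            seed=1, phases=(Phase("p", 200),), stride=200, soft_start_steps=0))
        t2 = run_langevin(dimer(ff), ff, SimulationSchedule(
            seed=2, phases=(Phase("p", 200),), stride=200, soft_start_steps=0))
        assert not np.allclose(t1.frames[-1], t2.frames[-1])

    def test_topology_conserved_across_frames(self, ff):
        traj = run_langevin(dimer(ff), ff, SimulationSchedule(
            seed=5, phases=(Phase("p", 2000),), stride=200,
            soft_start_steps=0))
        assert traj.frames.shape[1] == 2
        assert traj.chains == [(0, 2)]
        # bonds never exceed 2 * r0 at saved frames
        for i in range(traj.n_frames):
            d = traj.frames[i, 0] - traj.frames[i, 1]
            d -= traj.boxes[i] * np.round(d / traj.boxes[i])
            assert np.linalg.norm(d) < 2 * ff.bond_r0

    def test_free_bead_kinetic_energy_maxwellian(self, ff):
        """Mean kinetic energy of a free bead matches (3/2) kT within three
        standard errors (friction raised so samples decorrelate)."""
        kt = KB_KJ_MOL_K * 310.0
        means = []
        for seed in (1, 2, 3):
            sch = SimulationSchedule(
                seed=seed, friction=2.0, phases=(Phase("p", 60_000),),
                stride=100, soft_start_steps=0,
            )
            traj = run_langevin(free_bead(), ff, sch)
            temps = np.array(traj.provenance["instantaneous_temperatures_K"])
            means.append(temps.mean())
        means = np.array(means) * 1.5 * KB_KJ_MOL_K  # KE per bead
        expected = 1.5 * kt
        # ~600 effectively independent samples per seed at friction 2/ps
        se = expected * np.sqrt(2.0 / 3.0) / np.sqrt(500 * len(means))
        assert abs(means.mean() - expected) < 3 * se

    def test_dimer_bond_length_boltzmann_distributed(self, ff):
        """Sampled bond lengths follow the classical harmonic-bond radial
        density r^2 exp(-k (r - r0)^2 / 2 kT) (KS p > 0.01, 3 seeds)."""
        kt = KB_KJ_MOL_K * 310.0
        r = np.linspace(1.0, 7.0, 3001)
        pdf = r**2 * np.exp(-ff.bond_k * (r - ff.bond_r0) ** 2 / (2 * kt))
        cdf = np.cumsum(pdf)
        cdf /= cdf[-1]
        pvals = []
        for seed in (1, 2, 3):
            sch = SimulationSchedule(
                seed=seed, friction=2.0, phases=(Phase("p", 60_000),),
                stride=120, soft_start_steps=0,
            )
            traj = run_langevin(dimer(ff), ff, sch)
            d = traj.frames[:, 0] - traj.frames[:, 1]
            d -= traj.boxes[:, None, :].squeeze() * np.round(
                d / traj.boxes[:, None, :].squeeze()
            )
            samples = np.linalg.norm(d, axis=1)[5:]
            res = stats.ks_1samp(
                samples, lambda x: np.interp(x, r, cdf)
            )
            pvals.append(res.pvalue)
        assert all(p > 0.01 for p in pvals), pvals

    def test_nve_energy_conservation(self, ff):
        """With friction 0 and a short timestep the integrator conserves
        total energy to < 0.1% of the potential-energy scale."""
        cfg = dimer(ff, stretch=0.5)
        sch = SimulationSchedule(
            timestep_fs=1.0, friction=0.0, seed=9,
            phases=(Phase("nve", 100_000),), stride=1000,
            soft_start_steps=0,
        )
        traj = run_langevin(cfg, ff, sch)
        pes = np.array(traj.provenance["potential_energies_kJ_mol"])
        temps = np.array(traj.provenance["instantaneous_temperatures_K"])
        kes = 1.5 * traj.n_beads * KB_KJ_MOL_K * temps
        total = pes + kes
        scale = np.abs(pes).mean()
        assert np.abs(total - total[0]).max() < 1e-3 * scale


class TestScheduleValidation:
    def test_negative_steps_rejected(self):
        with pytest.raises(ValueError):
            Phase("p", -1)

    def test_nonpositive_timestep_rejected(self):
        with pytest.raises(ValueError):
            SimulationSchedule(timestep_fs=0.0)
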