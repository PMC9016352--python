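"""Energy model: pair potentials, Debye screening, neighbor-list equivalence
and analytic forces."""

import math

import numpy as np
import pytest

from lcdphase.forcefield import (
    COULOMB_KJ_A,
    TWO_POW_16,
    debye_length,
    elec_pair_energy,
    forces,
    make_forcefield,
    total_energy,
    vdw_pair_energy,
)
from lcdphase.system import SystemConfiguration

ALL_CODES = list("ACDEFGHIKLMNPQRSTVWY") + ["s"]


def random_config(rng, n=60, box=(70.0, 70.0, 70.0), spacing=True):
    """Random beads as single-bead chains; optional core-overlap avoidance."""
    box = np.asarray(box, dtype=float)
    pos = rng.random((n, 3)) * box
    if spacing:
        # nudge points apart so energies/forces stay in a benign range
        for _ in range(60):
            d = pos[:, None, :] - pos[None, :, :]
            d -= box * np.round(d / box)
            r = np.sqrt((d**2).sum(-1))
            np.fill_diagonal(r, np.inf)
            i, j = np.unravel_index(np.argmin(r), r.shape)
            if r[i, j] > 4.5:
                break
            pos[i] += rng.normal(size=3)
            pos[i] %= box
    codes = [ALL_CODES[k] for k in rng.integers(0, len(ALL_CODES), n)]
    return SystemConfiguration(
        pos, box, [(i, i + 1) for i in range(n)], codes, validate=False
    )


class TestMakeForcefield:
    def test_missing_residue_type_named(self, tmp_path):
        table = tmp_path / "partial.csv"
        table.write_text(
            "code,mass,charge,sigma_A,lambda\nA,71.08,0,5.04,0.73\n"
        )
        with pytest.raises(ValueError, match="missing residue types"):
            make_forcefield(table)

    def test_quadrupled_ionic_strength_halves_debye_length(self):
        lam1 = debye_length(310.0, 0.1, 80.0)
        lam4 = debye_length(310.0, 0.4, 80.0)
        assert lam4 == pytest.approx(lam1 / 2.0, rel=1e-12)

    def test_debye_length_matches_closed_form(self):
        # hand-computed Debye length, 100 mM 1:1 salt, 310 K, D = 80
        eps0, kb, e, na = 8.8541878128e-12, 1.380649e-23, 1.602176634e-19, 6.02214076e23
        expected = math.sqrt(
            eps0 * 80 * kb * 310 / (2 * e * e * 0.1 * 1000 * na)
        ) * 1e10
        assert debye_length(310.0, 0.1, 80.0) == pytest.approx(expected, rel=0.05)

    def test_nonpositive_ionic_strength_rejected(self):
        with pytest.raises(ValueError):
            debye_length(310.0, 0.0, 80.0)


class TestPairPotentials:
    @pytest.mark.parametrize("pair", [("S", "F"), ("G", "R"), ("s", "D")])
    def test_continuity_at_switch_equals_minus_lambda_eps(self, ff, pair):
        i, j = pair
        sigma = 0.5 * (ff.bead_types[i].sigma + ff.bead_types[j].sigma)
        lam = 0.5 * (ff.bead_types[i].lam + ff.bead_types[j].lam)
        r = TWO_POW_16 * sigma
        below = vdw_pair_energy(r * (1 - 1e-13), i, j, ff)
        above = vdw_pair_energy(r * (1 + 1e-13), i, j, ff)
        assert below == pytest.approx(above, abs=1e-10)
        assert below == pytest.approx(-lam * ff.epsilon, abs=1e-10)

    def test_lambda_one_pair_is_plain_lennard_jones(self, ff):
        # F-F has lambda 1: the potential is plain LJ on both branches
        sigma = ff.bead_types["F"].sigma
        for r in [0.9 * sigma, sigma, 1.3 * sigma, 2.2 * sigma]:
            sr6 = (sigma / r) ** 6
            lj = 4.0 * ff.epsilon * (sr6**2 - sr6)
            assert vdw_pair_energy(r, "F", "F", ff) == pytest.approx(lj, abs=1e-12)

    def test_value_at_sigma_is_one_minus_lambda_eps(self, ff):
        sigma = 0.5 * (ff.bead_types["S"].sigma + ff.bead_types["G"].sigma)
        lam = 0.5 * (ff.bead_types["S"].lam + ff.bead_types["G"].lam)
        assert vdw_pair_energy(sigma, "S", "G", ff) == pytest.approx(
            (1 - lam) * ff.epsilon, abs=1e-12
        )

    def test_shifted_form_vanishes_at_cutoff(self, ff):
        v = vdw_pair_energy(ff.cutoff_vdw - 1e-9, "F", "F", ff, shift=True)
        assert v == pytest.approx(0.0, abs=1e-10)

    def test_pair_energy_symmetry(self, ff):
        for r in (4.0, 7.0, 12.0):
            assert vdw_pair_energy(r, "K", "E", ff) == vdw_pair_energy(r, "E", "K", ff)
            assert elec_pair_energy(r, "K", "E", ff) == elec_pair_energy(r, "E", "K", ff)

    def test_neutral_partner_gives_zero_electrostatics(self, ff):
        for r in (3.0, 10.0, 30.0):
            assert elec_pair_energy(r, "G", "D", ff) == 0.0

    def test_screening_at_one_debye_length(self, ff):
        r = ff.debye_length
        coulomb = ff.coulomb_prefactor * (-1.0) * (-1.0) / r
        assert elec_pair_energy(r, "D", "E", ff) == pytest.approx(
            coulomb * math.exp(-1.0), rel=1e-12
        )

    def test_like_charges_repel_by_hand_formula(self):
        # two aspartates, 10 A apart, D = 80, Debye length 10 A
        ff = make_forcefield()
        object.__setattr__(ff, "debye_length", 10.0)
        expected = COULOMB_KJ_A / 80.0 * math.exp(-1.0) / 10.0
        val = elec_pair_energy(10.0, "D", "D", ff)
        assert val == pytest.approx(expected, rel=1e-12)
        assert val > 0

    def test_unknown_code_rejected(self, ff):
        with pytest.raises(KeyError):
            vdw_pair_energy(5.0, "Z", "A", ff)


class TestTotalEnergy:
    def test_bonded_dimer_at_r0_has_zero_bond_term(self, ff):
        cfg = SystemConfiguration(
            np.array([[30.0, 35.0, 35.0], [30.0 + ff.bond_r0, 35.0, 35.0]]),
            np.array([80.0, 80.0, 80.0]),
            [(0, 2)], ["G", "G"],
        )
        assert total_energy(cfg, ff).bond == pytest.approx(0.0, abs=1e-12)

    def test_lambda_zero_square_lattice_beyond_switch_has_zero_vdw(self, ff):
        # arginine has lambda 0; beyond 2^(1/6) sigma the tail branch is 0
        sigma = ff.bead_types["R"].sigma
        a = TWO_POW_16 * sigma + 1.0
        pos = np.array(
            [[0, 0, 0], [a, 0, 0], [0, a, 0], [a, a, 0]], dtype=float
        ) + 30.0
        cfg = SystemConfiguration(
            pos, np.array([90.0, 90.0, 90.0]),
            [(i, i + 1) for i in range(4)], ["R"] * 4, validate=False,
        )
        assert total_energy(cfg, ff).vdw == pytest.approx(0.0, abs=1e-12)

    def test_neighbor_list_matches_brute_force(self, ff, rng):
        for _ in range(5):
            cfg = random_config(rng, n=120)
            e_nl = total_energy(cfg, ff, use_neighbor_list=True)
            e_bf = total_energy(cfg, ff, use_neighbor_list=False)
            assert e_nl.total == pytest.approx(e_bf.total, rel=1e-8)
            assert e_nl.vdw == pytest.approx(e_bf.vdw, rel=1e-8)
            assert e_nl.elec == pytest.approx(e_bf.elec, rel=1e-8, abs=1e-10)

    def test_small_box_rejected(self, ff):
        cfg = SystemConfiguration(
            np.array([[5.0, 5.0, 5.0]]), np.array([30.0, 30.0, 30.0]),
            [(0, 1)], ["G"],
        )
        with pytest.raises(ValueError, match="twice the largest cutoff"):
            total_energy(cfg, ff)

    def test_translation_invariance_under_minimum_image(self, ff, rng):
        cfg = random_config(rng, n=40)
        e0 = total_energy(cfg, ff).total
        shifted = cfg.copy()
        shifted.positions += np.array([13.7, -22.1, 55.9])
        assert total_energy(shifted, ff).total == pytest.approx(e0, rel=1e-10)

    def test_phospho_swap_changes_only_local_terms(self, ff):
        # an isolated S->SEP swap leaves the energy of a distant pair alone
        pos = np.array([
            [10.0, 10.0, 10.0], [14.0, 10.0, 10.0],  # close pair A
            [50.0, 50.0, 50.0], [54.5, 50.0, 50.0],  # close pair B (S / s)
        ])
        box = np.array([100.0, 100.0, 100.0])
        chains = [(i, i + 1) for i in range(4)]
        base = total_energy(
            SystemConfiguration(pos, box, chains, ["F", "F", "S", "G"],
                                validate=False), ff
        )
        swapped = total_energy(
            SystemConfiguration(pos, box, chains, ["F", "F", "s", "G"],
                                validate=False), ff
        )
        # pair A energy (F-F at 4 A) is unchanged; only pair B differs
        pair_a = vdw_pair_energy(4.0, "F", "F", ff, shift=True)
        assert base.total != swapped.total
        assert base.vdw - pair_a == pytest.approx(
            vdw_pair_energy(4.5, "S", "G", ff, shift=True), abs=1e-9
        )


class TestForces:
    def test_isolated_bead_feels_nothing(self, ff):
        cfg = SystemConfiguration(
            np.array([[40.0, 40.0, 40.0]]), np.array([80.0, 80.0, 80.0]),
            [(0, 1)], ["W"],
        )
        assert np.allclose(forces(cfg, ff), 0.0)

    def test_stretched_dimer_follows_hookes_law(self, ff):
        delta = 0.05
        cfg = SystemConfiguration(
            np.array([[30.0, 40.0, 40.0],
                      [30.0 + ff.bond_r0 + delta, 40.0, 40.0]]),
            np.array([80.0, 80.0, 80.0]),
            [(0, 2)], ["G", "G"],
        )
        f = forces(cfg, ff)
        assert f[0, 0] == pytest.approx(ff.bond_k * delta, rel=1e-9)
        assert np.allclose(f[0], -f[1])

    def test_matches_central_differences(self, ff, rng):
        cfg = random_config(rng, n=50)
        f = forces(cfg, ff)
        h = 1e-5
        idx = rng.integers(0, 50, size=8)
        for i in idx:
            for k in range(3):
                plus = cfg.copy()
                plus.positions[i, k] += h
                minus = cfg.copy()
                minus.positions[i, k] -= h
                num = -(total_energy(plus, ff).total
                        - total_energy(minus, ff).total) / (2 * h)
                scale = max(abs(num), 1e-3)
                assert abs(f[i, k] - num) / scale < 1e-4

    def test_net_force_vanishes(self, ff, rng):
        cfg = random_config(rng, n=80)
        assert np.abs(forces(cfg, ff).sum(axis=0)).max() < 1e-7
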