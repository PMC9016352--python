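"""Contact maps, difference maps, type-resolved profiles and solvation
histograms on planted-geometry fixtures."""

import numpy as np
import pytest

from lcdphase.contacts import (
    ContactRule,
    contact_difference,
    contact_map,
    solvation_histogram,
    type_resolved_contacts,
)
from lcdphase.forcefield import TWO_POW_16
from lcdphase.synthetic import (
    make_planted_contact_traj,
    make_solvated_frame,
)

BOX = (400.0, 200.0, 100.0)


class TestContactMap:
    def test_planted_pair_has_probability_one(self):
        traj, _ = make_planted_contact_traj(
            [(2, 7)], [4.4], n_frames=3, box=BOX
        )
        cmap = contact_map(traj, ContactRule.fixed(4.5))
        assert cmap.inter[2, 7] == 1.0
        assert cmap.inter[7, 2] == 1.0
        assert cmap.inter.sum() == 2.0  # nothing else in contact

    def test_pair_at_cutoff_excluded_strict_inequality(self):
        traj, _ = make_planted_contact_traj(
            [(2, 7)], [4.5], n_frames=2, box=BOX
        )
        cmap = contact_map(traj, ContactRule.fixed(4.5))
        assert cmap.inter[2, 7] == 0.0

    def test_empty_pair_list_gives_zero_map(self):
        traj, _ = make_planted_contact_traj([], [], n_frames=2, box=BOX)
        cmap = contact_map(traj, ContactRule.fixed(4.5))
        assert np.nansum(cmap.matrix) == 0.0

    def test_intra_chain_near_diagonal_excluded(self):
        # residues i and i+2 of the same chain 3 A apart are masked out
        traj, _ = make_planted_contact_traj([], [], n_frames=1, box=BOX)
        frames = traj.frames.copy()
        frames[0, 4] = frames[0, 2] + np.array([0.0, 3.0, 0.0])  # chain 0: 2,4
        traj.frames = frames
        cmap = contact_map(traj, ContactRule.fixed(4.5), exclusion=2)
        assert np.isnan(cmap.intra[2, 4])
        with_excl_zero = contact_map(traj, ContactRule.fixed(4.5), exclusion=0)
        assert with_excl_zero.intra[2, 4] > 0

    def test_map_is_symmetric(self):
        traj, _ = make_planted_contact_traj(
            [(1, 5), (3, 9)], [4.0, 3.0], n_frames=2, box=BOX
        )
        cmap = contact_map(traj, ContactRule.fixed(4.5))
        assert np.array_equal(cmap.inter, cmap.inter.T)

    def test_sigma_rule_threshold_arithmetic(self, ff):
        # sigma_i = sigma_j = 6.0 A (SEP bead) -> threshold 6.735 A
        traj_in, _ = make_planted_contact_traj(
            [(2, 7)], [6.7], n_frames=1, box=BOX, sequence="s" * 12
        )
        traj_out, _ = make_planted_contact_traj(
            [(2, 7)], [6.8], n_frames=1, box=BOX, sequence="s" * 12
        )
        assert TWO_POW_16 * 6.0 == pytest.approx(6.735, abs=1e-3)
        m_in = contact_map(traj_in, ContactRule.sigma(), ff=ff)
        m_out = contact_map(traj_out, ContactRule.sigma(), ff=ff)
        assert m_in.inter[2, 7] == 1.0
        assert m_out.inter[2, 7] == 0.0

    def test_sigma_rule_requires_forcefield(self):
        traj, _ = make_planted_contact_traj([(1, 2)], [4.0], 1, BOX)
        with pytest.raises(ValueError, match="force field"):
            contact_map(traj, ContactRule.sigma())

    def test_rigid_translation_leaves_map_unchanged(self):
        traj, _ = make_planted_contact_traj(
            [(2, 7), (4, 11)], [4.4, 2.0], n_frames=2, box=BOX
        )
        shifted_frames = (traj.frames + np.array([123.0, 45.0, 67.0]))
        shifted = type(traj)(
            frames=shifted_frames, boxes=traj.boxes, times=traj.times,
            chains=traj.chains, bead_codes=traj.bead_codes,
        )
        a = contact_map(traj, ContactRule.fixed(4.5))
        b = contact_map(shifted, ContactRule.fixed(4.5))
        assert np.array_equal(a.inter, b.inter)

    def test_doubling_frames_leaves_probabilities_unchanged(self):
        traj, _ = make_planted_contact_traj([(2, 7)], [4.0], 2, BOX)
        doubled = type(traj)(
            frames=np.concatenate([traj.frames, traj.frames]),
            boxes=np.concatenate([traj.boxes, traj.boxes]),
            times=np.arange(4, dtype=float),
            chains=traj.chains, bead_codes=traj.bead_codes,
        )
        a = contact_map(traj, ContactRule.fixed(4.5))
        b = contact_map(doubled, ContactRule.fixed(4.5))
        assert np.array_equal(a.inter, b.inter)


class TestContactDifference:
    def _map(self, pairs, dists, frames=2):
        traj, _ = make_planted_contact_traj(pairs, dists, frames, BOX)
        return contact_map(traj, ContactRule.fixed(4.5))

    def test_self_difference_is_zero(self):
        a = self._map([(2, 7)], [4.0])
        diff = contact_difference(a, a)
        assert np.nanmax(np.abs(diff)) == 0.0

    def test_antisymmetry(self):
        a = self._map([(2, 7)], [4.0])
        b = self._map([(3, 9)], [3.0])
        assert np.allclose(
            contact_difference(a, b), -contact_difference(b, a),
            equal_nan=True,
        )

    def test_planted_probabilities_subtract_exactly(self):
        a = self._map([(2, 7)], [4.0])
        b = self._map([(2, 7), (3, 9)], [4.0, 3.0])
        diff = contact_difference(a, b)
        assert diff[2, 7] == 0.0
        assert diff[3, 9] == pytest.approx(-b.matrix[3, 9])

    def test_mismatched_rules_rejected(self):
        traj, _ = make_planted_contact_traj([(2, 7)], [4.0], 1, BOX)
        a = contact_map(traj, ContactRule.fixed(4.5))
        b = contact_map(traj, ContactRule.fixed(5.0))
        with pytest.raises(ValueError, match="rules"):
            contact_difference(a, b)


class TestTypeResolvedContacts:
    def test_source_serine_touching_only_arginine(self):
        # shared chain sequence: serine at index 2, arginine at index 7;
        # the planted geometry puts only the serine/arginine pair in contact
        seq = "GGSGGGGRGGGG"
        traj, _ = make_planted_contact_traj(
            [(2, 7)], [4.0], n_frames=2, box=BOX,
            sequence=seq,
        )
        prof = type_resolved_contacts(
            traj, source_sites=[3], offset=1, rule=ContactRule.fixed(4.5)
        )
        assert prof.normalized
        assert prof.probabilities == {"R": 1.0}

    def test_no_contacts_gives_flagged_empty_profile(self):
        traj, _ = make_planted_contact_traj([], [], 1, BOX)
        prof = type_resolved_contacts(traj, source_sites=[1], offset=1)
        assert not prof.normalized
        assert prof.probabilities == {}

    def test_probabilities_sum_to_one(self):
        traj, _ = make_planted_contact_traj(
            [(2, 7), (5, 9)], [4.0, 4.0], n_frames=3, box=BOX
        )
        prof = type_resolved_contacts(traj, source_sites=[3, 6], offset=1)
        assert sum(prof.probabilities.values()) == pytest.approx(1.0, abs=1e-9)

    def test_empty_selection_rejected(self):
        traj, _ = make_planted_contact_traj([], [], 1, BOX)
        with pytest.raises(ValueError, match="nonempty"):
            type_resolved_contacts(traj, source_sites=[])


class TestSolvationHistogram:
    RES = np.array([[50.0, 50.0, 50.0], [150.0, 50.0, 50.0]])

    def test_planted_counts_recovered_exactly(self):
        frame, manifest = make_solvated_frame(
            self.RES, [7, 0], cutoff=5.0, box=(200.0, 100.0, 100.0), seed=3
        )
        hist = solvation_histogram([frame], selection=[0, 1], cutoff=5.0)
        assert hist.frequencies[7] == 0.5
        assert hist.frequencies[0] == 0.5
        assert hist.frequencies.sum() == pytest.approx(1.0)

    def test_zero_request_gives_delta_at_zero(self):
        frame, _ = make_solvated_frame(
            self.RES, [0, 0], cutoff=5.0, box=(200.0, 100.0, 100.0), seed=4
        )
        hist = solvation_histogram([frame], [0, 1], cutoff=5.0)
        assert hist.frequencies[0] == 1.0

    def test_tiny_cutoff_counts_nothing(self):
        frame, _ = make_solvated_frame(
            self.RES, [5, 2], cutoff=5.0, box=(200.0, 100.0, 100.0), seed=5
        )
        hist = solvation_histogram([frame], [0, 1], cutoff=1e-6)
        assert hist.frequencies[0] == 1.0

    def test_negative_request_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            make_solvated_frame(
                self.RES, [-1, 0], cutoff=5.0, box=(200.0, 100.0, 100.0),
                seed=6,
            )

    def test_no_solvent_rejected(self):
        from lcdphase.contacts import SolvatedFrame

        frame = SolvatedFrame(
            protein_positions=self.RES,
            solvent_positions=np.empty((0, 3)),
            box=np.array([200.0, 100.0, 100.0]),
        )
        with pytest.raises(ValueError, match="no solvent"):
            solvation_histogram([frame], [0], cutoff=5.0)
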