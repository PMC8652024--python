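"""Knob/hole detection: centers, contacts, knobs, classification,
complementarity."""

import numpy as np
import pytest

from kihscan.helix_model import HelixSegment
from kihscan.kih_core import (Knob, classify_knob, compute_centers,
                              contact_map, find_knobs, pair_interfaces,
                              side_chain_center)

from conftest import analyze, make_residue


def _helices(*chains):
    """chains: (chain_id, [residues]) -> HelixSegments with sequential ids."""
    return [HelixSegment(i + 1, cid, list(res))
            for i, (cid, res) in enumerate(chains)]


class TestSideChainCenter:
    def test_single_cb(self):
        r = make_residue("A", 1, ca=(0, 0, 0), cb=(1, 2, 3))
        c = side_chain_center(r)
        np.testing.assert_allclose(c.position, [1, 2, 3])
        assert c.n_atoms == 1

    def test_glycine_uses_ca(self):
        r = make_residue("A", 1, name="GLY", ca=(0, 0, 0))
        c = side_chain_center(r)
        np.testing.assert_allclose(c.position, [0, 0, 0])

    def test_centroid_is_unweighted_mean(self):
        r = make_residue("A", 1, ca=(9, 9, 9), cb=(0, 0, 0),
                         extra=[(2, 0, 0), (0, 2, 0), (0, 0, 2)])
        c = side_chain_center(r)
        np.testing.assert_allclose(c.position, [0.5, 0.5, 0.5])
        assert c.n_atoms == 4


class TestContactMap:
    def test_three_four_five_triangle(self):
        ha = _helices(("A", [make_residue("A", 1, cb=(0, 0, 0))]),
                      ("B", [make_residue("B", 1, cb=(3, 4, 0))]))
        centers = compute_centers(ha)
        contacts = contact_map(ha, centers, 7.0)
        assert len(contacts) == 1
        assert contacts[0].distance == pytest.approx(5.0)

    def test_boundary_is_inclusive(self):
        ha = _helices(("A", [make_residue("A", 1, cb=(0, 0, 0))]),
                      ("B", [make_residue("B", 1, cb=(7.0, 0, 0))]))
        contacts = contact_map(ha, compute_centers(ha), 7.0)
        assert len(contacts) == 1

    def test_same_helix_excluded(self):
        ha = _helices(("A", [make_residue("A", 1, cb=(0, 0, 0)),
                             make_residue("A", 2, cb=(3, 0, 0))]))
        assert contact_map(ha, compute_centers(ha), 7.0) == []

    def test_rejects_nonpositive_cutoff(self):
        with pytest.raises(ValueError):
            contact_map([], {}, 0.0)


def _knob_scenario(distances_b, distances_c=()):
    """Chain A residue 1 vs residues on helices B (and C) at given
    x-distances."""
    a = [make_residue("A", 1, cb=(0, 0, 0))]
    b = [make_residue("B", i + 1, cb=(d, 0, 0))
         for i, d in enumerate(distances_b)]
    c = [make_residue("C", i + 1, cb=(0, d, 0))
         for i, d in enumerate(distances_c)]
    helices = _helices(("A", a), ("B", b), *((("C", c),) if c else ()))
    centers = compute_centers(helices)
    contacts = contact_map(helices, centers, 7.0)
    return find_knobs(contacts, centers, 7.0), centers


class TestFindKnobs:
    def test_four_contacts_make_knob(self):
        knobs, _ = _knob_scenario([4, 5, 5.5, 6])
        mine = [k for k in knobs if k.knob_residue.chain_id == "A"]
        assert len(mine) == 1
        assert {r.seq_id for r in mine[0].hole_residues} == {1, 2, 3, 4}

    def test_three_contacts_do_not(self):
        knobs, _ = _knob_scenario([4, 5, 6])
        assert not any(k.knob_residue.chain_id == "A" for k in knobs)

    def test_split_contacts_counted_per_helix(self):
        knobs, _ = _knob_scenario([4, 5], [4, 5])
        assert not any(k.knob_residue.chain_id == "A" for k in knobs)

    def test_hole_is_four_nearest(self):
        knobs, _ = _knob_scenario([4, 5, 5, 6, 6.5, 7])
        mine = [k for k in knobs if k.knob_residue.chain_id == "A"][0]
        assert sorted(d for d in mine.hole_distances) == [4, 5, 5, 6]

    def test_distance_tie_broken_by_residue_number(self):
        # four at 5.0 plus two tied at 6.0: lower-numbered tied residue wins
        knobs, _ = _knob_scenario([5, 5, 5, 6, 6])
        mine = [k for k in knobs if k.knob_residue.chain_id == "A"][0]
        assert {r.seq_id for r in mine.hole_residues} == {1, 2, 3, 4}


class TestClassifyKnob:
    def _knob(self, ca, cb, hole_center, hole_residues, centers):
        r = make_residue("A", 1, ca=ca, cb=cb)
        centers = dict(centers)
        centers[r.key] = side_chain_center(r, 1)
        k = Knob(knob_residue=r, knob_helix=1, hole_helix=2,
                 hole_residues=hole_residues,
                 hole_center=np.asarray(hole_center, float),
                 hole_distances=[0.0] * 4)
        return classify_knob(k, centers, 7.0)

    def test_collinear_is_zero_degrees(self):
        hole = [make_residue("B", i, cb=(6, 0, 0)) for i in range(1, 5)]
        centers = {r.key: side_chain_center(r, 2) for r in hole}
        k = self._knob((0, 0, 0), (2, 0, 0), (6, 0, 0), hole, centers)
        assert k.packing_angle == pytest.approx(0.0, abs=1e-9)
        assert k.knob_type == 4  # CA within cutoff of all four hole centers

    def test_perpendicular_is_type_1(self):
        hole = [make_residue("B", i, cb=(6, 0, 0)) for i in range(1, 5)]
        centers = {r.key: side_chain_center(r, 2) for r in hole}
        k = self._knob((0, 0, 0), (0, 2, 0), (6, 0, 0), hole, centers)
        assert k.packing_angle == pytest.approx(90.0)
        assert k.knob_type == 1

    def test_glycine_angle_undefined(self):
        hole = [make_residue("B", i, cb=(6, 0, 0)) for i in range(1, 5)]
        centers = {r.key: side_chain_center(r, 2) for r in hole}
        k = self._knob((0, 0, 0), None, (6, 0, 0), hole, centers)
        assert k.packing_angle is None and k.knob_type == 1

    def test_dimer_core_knobs_point_into_hole(self, dimer_result):
        knobs = [k for a in dimer_result.assemblies for k in a.knobs()]
        assert knobs and all(k.knob_type >= 3 for k in knobs)


class TestPairInterfaces:
    def test_dimer_is_complementary(self, dimer_result):
        ifaces = dimer_result.assemblies[0].interfaces
        assert len(ifaces) == 1
        assert ifaces[0].is_coiled_coil
        assert len(ifaces[0].complementary_pairs) >= 2

    def test_one_directional_knobs_rejected(self):
        a = make_residue("A", 1, cb=(0, 0, 0))
        b = [make_residue("B", i, cb=(4 + 0.1 * i, 0, 0)) for i in range(1, 5)]
        helices = _helices(("A", [a]), ("B", b))
        centers = compute_centers(helices)
        knobs = find_knobs(contact_map(helices, centers, 7.0), centers, 7.0)
        # A has a knob into B, but no B residue has 4 contacts on A
        assert any(k.knob_helix == 1 for k in knobs)
        ifaces = pair_interfaces(knobs)
        assert not any(i.is_coiled_coil for i in ifaces)

    def test_empty_knob_list(self):
        assert pair_interfaces([]) == []

    def test_reciprocity_is_symmetric(self, dimer_result):
        iface = dimer_result.assemblies[0].interfaces[0]
        assert iface.complementary_pairs
        for k1, k2 in iface.complementary_pairs:
            # mutual hole membership is what makes the pair complementary

            assert k2.knob_residue.key in {r.key for r in k1.hole_residues}
            assert k1.knob_residue.key in {r.key for r in k2.hole_residues}
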