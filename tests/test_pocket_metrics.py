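import copy

import numpy as np
import pytest

from pocketgauge.pocket_metrics import (
    ca_distance,
    deviation_matrix,
    pocket_matrix,
    pocket_verdict,
    sidechain_distance,
)
from pocketgauge.structure_io import Atom, Residue, Structure
from pocketgauge.synthetic_data import axis_angle_rotation, make_toy_pocket


def _two_residue_structure(d=7.5):
    res = []
    for num, x in ((1, 0.0), (2, d)):
        ca = np.array([x, 0.0, 0.0])
        atoms = [
            Atom(name="N", element="N", coords=ca + [0, 1.4, 0]),
            Atom(name="CA", element="C", coords=ca),
            Atom(name="C", element="C", coords=ca + [0, 0, 1.5]),
            Atom(name="O", element="O", coords=ca + [0, 1.0, 2.2]),
            Atom(name="CB", element="C", coords=ca + [0, -1.5, 0]),
        ]
        res.append(Residue(chain_id="A", number=num, icode="", name="ALA", atoms=atoms))
    return Structure(id="pair", chains={"A": res})


class TestCaDistance:
    def test_same_residue_zero(self):
        s = _two_residue_structure()
        assert ca_distance(s, "A", 1, 1) == 0.0

    def test_planted_separation(self):
        assert ca_distance(_two_residue_structure(7.5), "A", 1, 2) == pytest.approx(7.5)

    def test_missing_residue_names_culprit(self):
        s = _two_residue_structure()
        with pytest.raises(ValueError, match="99"):
            ca_distance(s, "A", 1, 99)

    def test_invariant_under_rigid_transform(self, pocket_structure):
        s = copy.deepcopy(pocket_structure)
        base = ca_distance(s, "A", 228, 578)
        rot = axis_angle_rotation((1, 1, 0), 77.0)
        for r in s.chains["A"]:
            for a in r.atoms:
                a.coords = rot @ a.coords + np.array([5.0, -3.0, 1.0])
        assert ca_distance(s, "A", 228, 578) == pytest.approx(base, abs=1e-9)


class TestSidechainDistance:
    def test_min_heavy_uses_closest_atom_pair(self, pocket_structure):
        # planted Arg NH1 – Glu OE1 pair sits exactly 3.0 Å apart
        d = sidechain_distance(pocket_structure, "A", 578, 629, definition="min-heavy")
        assert d == pytest.approx(3.0, abs=1e-9)

    def test_overlapping_sidechains_give_zero(self):
        s = _two_residue_structure(d=7.5)
        # move residue 2's CB onto residue 1's CB
        cb1 = s.residue("A", 1).atom("CB").coords
        s.residue("A", 2).atom("CB").coords = cb1.copy()
        assert sidechain_distance(s, "A", 1, 2, definition="min-heavy") == 0.0

    def test_min_heavy_never_exceeds_centroid_distance_plus_radius(self, pocket_structure):
        for i, j in ((228, 578), (578, 629), (228, 629)):
            dmin = sidechain_distance(pocket_structure, "A", i, j, "min-heavy")
            dcen = sidechain_distance(pocket_structure, "A", i, j, "centroid")
            radius = 0.0
            for num in (i, j):
                r = pocket_structure.residue("A", num)
                sc = np.array([a.coords for a in r.heavy_atoms() if a.name not in ("N", "CA", "C", "O", "OXT")])
                radius = max(radius, np.linalg.norm(sc - sc.mean(axis=0), axis=1).max())
            assert dmin <= dcen + 2 * radius + 1e-9

    def test_glycine_falls_back_to_ca_with_warning(self):
        s = _two_residue_structure()
        gly = s.residue("A", 2)
        gly.name = "GLY"
        gly.atoms = [a for a in gly.atoms if a.name != "CB"]
        with pytest.warns(UserWarning, match="no side-chain"):
            d = sidechain_distance(s, "A", 1, 2)
        assert d > 0


class TestPocketMatrix:
    def test_single_pair_matches_pairwise_op(self, pocket_structure):
        m = pocket_matrix(pocket_structure, "A", [228, 578])
        assert m.values[0, 1] == pytest.approx(ca_distance(pocket_structure, "A", 228, 578))

    def test_symmetric_zero_diagonal(self, pocket_structure):
        m = pocket_matrix(pocket_structure, "A", [228, 578, 629])
        assert np.allclose(m.values, m.values.T)
        assert np.allclose(np.diag(m.values), 0.0)
        assert (m.values >= 0).all()

    def test_planted_geometry_reproduced(self, pocket_structure):
        m = pocket_matrix(pocket_structure, "A", [228, 578, 629])
        expected = {(0, 1): 12.7, (0, 2): 10.0, (1, 2): 6.0}
        for (i, j), d in expected.items():
            assert m.values[i, j] == pytest.approx(d, abs=1e-6)

    def test_triangle_inequality_for_calpha(self, pocket_structure):
        m = pocket_matrix(pocket_structure, "A", [228, 578, 629]).values
        for i in range(3):
            for j in range(3):
                for k in range(3):
                    assert m[i, j] <= m[i, k] + m[k, j] + 1e-9

    def test_unresolvable_residue_masked_with_warning(self, pocket_structure):
        with pytest.warns(UserWarning, match="unresolvable"):
            m = pocket_matrix(pocket_structure, "A", [228, 578, 999])
        assert np.isnan(m.values[2]).all()
        assert np.isfinite(m.values[0, 1])

    def test_fewer_than_two_resolvable_errors(self, pocket_structure):
        with pytest.raises(ValueError):
            with pytest.warns(UserWarning):
                pocket_matrix(pocket_structure, "A", [228, 998, 999])


class TestDeviationMatrix:
    def test_self_deviation_is_zero_and_antisymmetric(self, pocket_structure):
        m = pocket_matrix(pocket_structure, "A", [228, 578, 629])
        assert np.allclose(deviation_matrix(m, m).values, 0.0)
        other = make_toy_pocket({(228, 578): 20.0, (228, 629): 14.0, (578, 629): 9.0})
        mo = pocket_matrix(other, "A", [228, 578, 629])
        fwd = deviation_matrix(mo, m).values
        rev = deviation_matrix(m, mo).values
        assert np.allclose(fwd, -rev)
        assert fwd[0, 1] == pytest.approx(20.0 - 12.7, abs=1e-6)

    def test_label_mismatch_errors(self, pocket_structure):
        a = pocket_matrix(pocket_structure, "A", [228, 578])
        b = pocket_matrix(pocket_structure, "A", [228, 629])
        with pytest.raises(ValueError, match="label"):
            deviation_matrix(a, b)


class TestPocketVerdict:
    @pytest.mark.parametrize(
        "distance,category",
        [(12.0, "formed"), (14.0, "formed"), (14.5, "loose"), (18.0, "loose"), (20.3, "unformed")],
    )
    def test_category_thresholds(self, distance, category):
        s = make_toy_pocket({(228, 578): distance})
        v = pocket_verdict(s, "A")
        assert v.indicator_distance == pytest.approx(distance, abs=1e-6)
        assert v.category == category

    def test_monotone_in_distance(self):
        order = {"formed": 0, "loose": 1, "unformed": 2}
        cats = [
            pocket_verdict(make_toy_pocket({(228, 578): d}), "A").category
            for d in (8.0, 12.0, 14.0, 15.0, 18.0, 19.0, 25.0)
        ]
        ranks = [order[c] for c in cats]
        assert ranks == sorted(ranks)

    def test_bad_thresholds_rejected(self, pocket_structure):
        with pytest.raises(ValueError):
            pocket_verdict(pocket_structure, "A", thresholds=(18.0, 14.0))
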