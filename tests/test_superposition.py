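import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import minimize

from pocketgauge.residue_mapping import map_residues
from pocketgauge.superposition import domain_rmsd_table, kabsch, rmsd_between
from pocketgauge.synthetic_data import ToySpec, axis_angle_rotation, make_toy_protein


def brute_force_min_rmsd(a, b, restarts=12, seed=0):
    """Independent oracle: minimise RMSD directly over axis-angle parameters."""
    a = a - a.mean(axis=0)
    b = b - b.mean(axis=0)

    def objective(rvec):
        angle = np.linalg.norm(rvec)
        rot = axis_angle_rotation(rvec if angle > 0 else (0, 0, 1), np.degrees(angle))
        d = a @ rot.T - b
        return np.sqrt(np.einsum("ij,ij->i", d, d).mean())

    rng = np.random.default_rng(seed)
    best = np.inf
    for _ in range(restarts):
        x0 = rng.uniform(-np.pi, np.pi, size=3)
        res = minimize(objective, x0, method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 5000})
        best = min(best, res.fun)
    return best


class TestKabsch:
    def test_identical_sets_give_zero_and_identity(self):
        rng = np.random.default_rng(1)
        a = rng.normal(size=(6, 3))
        res = kabsch(a, a)
        assert res.rmsd == pytest.approx(0.0, abs=1e-10)
        assert np.allclose(res.rotation, np.eye(3), atol=1e-10)
        assert np.allclose(res.translation, 0.0, atol=1e-10)

    def test_planted_rigid_transform_recovered(self):
        rng = np.random.default_rng(2)
        a = rng.normal(size=(10, 3)) * 5
        rot = axis_angle_rotation((1, -2, 0.5), 63.0)
        b = a @ rot.T + np.array([4.0, -1.0, 2.5])
        res = kabsch(a, b)
        assert res.rmsd <= 1e-8
        assert np.linalg.norm(res.rotation - rot) <= 1e-6

    def test_matches_brute_force_on_noisy_points(self):
        rng = np.random.default_rng(3)
        a = rng.normal(size=(8, 3)) * 3
        b = a + rng.normal(0.0, 0.5, size=a.shape)
        assert kabsch(a, b).rmsd == pytest.approx(brute_force_min_rmsd(a, b), abs=1e-4)

    @given(st.integers(min_value=0, max_value=50))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_rmsd_invariant_under_rigid_transform(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(size=(7, 3)) * 4
        b = a + rng.normal(0.0, 1.0, size=a.shape)
        base = kabsch(a, b).rmsd
        rot = axis_angle_rotation(rng.normal(size=3), rng.uniform(0, 360))
        moved = a @ rot.T + rng.normal(size=3) * 10
        assert kabsch(moved, b).rmsd == pytest.approx(base, abs=1e-8)

    def test_rotation_is_always_proper(self):
        rng = np.random.default_rng(4)
        a = rng.normal(size=(5, 3))
        b = a * np.array([1, 1, -1])  # mirrored target tempts a reflection
        res = kabsch(a, b)
        assert np.linalg.det(res.rotation) == pytest.approx(1.0, abs=1e-8)
        assert np.allclose(res.rotation @ res.rotation.T, np.eye(3), atol=1e-8)

    def test_uniform_weights_equal_unweighted(self):
        rng = np.random.default_rng(5)
        a = rng.normal(size=(9, 3))
        b = a + rng.normal(0.0, 0.3, size=a.shape)
        assert kabsch(a, b, weights=np.full(9, 2.5)).rmsd == pytest.approx(kabsch(a, b).rmsd)

    def test_degenerate_inputs_rejected(self):
        line = np.array([[0.0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]])
        with pytest.raises(ValueError, match="collinear|degenerate"):
            kabsch(line, line + 1.0)
        with pytest.raises(ValueError):
            kabsch(np.zeros((2, 3)), np.zeros((2, 3)))


class TestStructureRmsd:
    def test_model_vs_itself_is_zero(self, clean_toy):
        model, _, _ = clean_toy
        mapping = map_residues(model, model, "A", "A")
        for sel in ("heavy", "calpha"):
            assert rmsd_between(model, model, mapping, sel).rmsd == pytest.approx(0.0, abs=1e-10)

    def test_displaced_domain_zero_alone_positive_globally(self, displaced_toy):
        model, reference, truth = displaced_toy
        mapping = map_residues(model, reference, "A", "A")
        table = domain_rmsd_table(model, reference, mapping, truth["scheme"])
        # separate superposition absorbs D2's rigid displacement
        assert table.rows["D2"][1] == pytest.approx(0.0, abs=1e-8)
        assert table.rows["D1"][1] == pytest.approx(0.0, abs=1e-8)
        assert table.rows["Full-length"][1] > 1.0

    def test_self_table_all_zero_with_full_counts(self, clean_toy):
        model, _, truth = clean_toy
        mapping = map_residues(model, model, "A", "A")
        table = domain_rmsd_table(model, model, mapping, truth["scheme"])
        n_res = len(model.chains["A"])
        for name, (rh, rc, nh, nc) in table.rows.items():
            assert rh == pytest.approx(0.0, abs=1e-10)
            assert rc == pytest.approx(0.0, abs=1e-10)
        assert table.rows["Full-length"][3] == n_res
        assert table.rows["Full-length"][2] == 5 * n_res  # N, CA, C, O, CB

    def test_separate_superposition_never_beats_global_fit(self, displaced_toy):
        model, reference, truth = displaced_toy
        mapping = map_residues(model, reference, "A", "A")
        table = domain_rmsd_table(model, reference, mapping, truth["scheme"])
        # RMSD of each domain's atoms under the full-length fit
        from pocketgauge.residue_mapping import pair_atoms

        heavy = pair_atoms(mapping, "heavy")
        a = np.array([x.coords for x, _ in heavy.pairs])
        b = np.array([y.coords for _, y in heavy.pairs])
        sup = kabsch(a, b)
        moved = sup.transform(a)
        scheme = truth["scheme"]
        for dom in scheme.ranges:
            sel = np.array([scheme.domain_of(mid[1]) == dom for mid, _ in heavy.residue_ids])
            if sel.sum() < 3:
                continue
            d = moved[sel] - b[sel]
            global_fit_rmsd = np.sqrt(np.einsum("ij,ij->i", d, d).mean())
            assert table.rows[dom][0] <= global_fit_rmsd + 1e-9

    def test_raw_rmsd_without_superposition(self, clean_toy):
        import copy

        model, _, _ = clean_toy
        shifted = copy.deepcopy(model)
        for r in shifted.chains["A"]:
            for a in r.atoms:
                a.coords = a.coords + np.array([3.0, 0.0, 0.0])
        mapping = map_residues(model, shifted, "A", "A")
        raw = rmsd_between(model, shifted, mapping, "calpha", superpose=False)
        assert raw.rmsd == pytest.approx(3.0, abs=1e-10)
        assert rmsd_between(model, shifted, mapping, "calpha", superpose=True).rmsd <= 1e-8
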