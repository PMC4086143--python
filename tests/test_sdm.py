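from itertools import product

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from protstab import build_esst, calibrate, environment_class, fit_model_tree, sdm_raw_score
from protstab.environment import EnvironmentFeatures
from protstab.sdm import (ESST, AA_INDEX, BURIAL_STATES, EnvironmentClass,
                          ModelTree, NotFittedError, SS_STATES)
from protstab.structure_io import STANDARD_AA


def _env(ss="helix", rsa=0.5):
    return EnvironmentFeatures(rsa=rsa, ss_class=ss,
                               sidechain_hbond_satisfied=True, sasa_abs=0.0)


class TestEnvironmentClass:
    @pytest.mark.parametrize("rsa,burial", [
        (0.0, "buried"), (0.069, "buried"), (0.07, "intermediate"),
        (0.24, "intermediate"), (0.25, "exposed"), (1.0, "exposed"),
    ])
    def test_burial_thresholds_inclusive_upward(self, rsa, burial):
        assert environment_class(_env("coil", rsa)).burial == burial

    def test_nine_classes_have_distinct_indices(self):
        indices = {EnvironmentClass(ss, b).index
                   for ss in SS_STATES for b in BURIAL_STATES}
        assert indices == set(range(9))


class TestEsst:
    def test_zero_observations_give_uniform_distributions(self):
        esst = ESST.from_counts(np.zeros((9, 20)), pseudocount=1.0)
        np.testing.assert_allclose(esst.table, 1.0 / 20)
        np.testing.assert_allclose(esst.background, 1.0 / 20)

    def test_direct_formula_on_concentrated_counts(self):
        counts = np.zeros((9, 20))
        counts[0, AA_INDEX["A"]] = 100
        esst = ESST.from_counts(counts, pseudocount=1.0)
        assert esst.table[0, AA_INDEX["A"]] == pytest.approx(101 / 120)

    @given(st.integers(0, 2 ** 31 - 1), st.floats(0.1, 10.0))
    @settings(max_examples=25, deadline=None)
    def test_rows_normalize_for_any_counts(self, seed, pseudocount):
        counts = np.random.default_rng(seed).integers(0, 500, size=(9, 20))
        esst = ESST.from_counts(counts.astype(float), pseudocount)
        np.testing.assert_allclose(esst.table.sum(axis=1), 1.0, atol=1e-9)
        assert (esst.table > 0).all()
        assert esst.background.sum() == pytest.approx(1.0, abs=1e-9)

    def test_build_from_labelled_observations(self):
        obs = pd.DataFrame([{"aa": "A", "ss": "helix", "burial": "buried"}] * 10)
        esst = build_esst(obs, pseudocount=1.0)
        env = EnvironmentClass("helix", "buried")
        assert esst.p("A", env) == pytest.approx(11 / 30)

    def test_empty_observations_rejected(self):
        with pytest.raises(ValueError):
            build_esst(pd.DataFrame(columns=["aa", "ss", "burial"]))


class TestRawScore:
    def test_identity_mutation_scores_zero(self, demo_esst):
        env = EnvironmentClass("helix", "buried")
        for aa in STANDARD_AA:
            assert sdm_raw_score(demo_esst, aa, aa, env) == 0.0

    def test_uniform_table_is_uninformative(self):
        esst = ESST.from_counts(np.zeros((9, 20)), pseudocount=1.0)
        env = EnvironmentClass("coil", "exposed")
        for wt, mut in [("A", "W"), ("G", "P"), ("K", "E")]:
            assert sdm_raw_score(esst, wt, mut, env) == pytest.approx(0.0, abs=1e-12)

    def test_antisymmetry_sampled_pairs(self, demo_esst):
        env = EnvironmentClass("strand", "intermediate")
        for wt, mut in [("A", "W"), ("D", "K"), ("C", "S"), ("F", "G")]:
            assert sdm_raw_score(demo_esst, wt, mut, env) == pytest.approx(
                -sdm_raw_score(demo_esst, mut, wt, env))

    def test_scale_is_linear(self, demo_esst):
        env = EnvironmentClass("helix", "exposed")
        s1 = sdm_raw_score(demo_esst, "A", "W", env, scale=1.0)
        s2 = sdm_raw_score(demo_esst, "A", "W", env, scale=2.5)
        assert s2 == pytest.approx(2.5 * s1)


def _piecewise_data(seed, n=400, noise=0.05):
    rng = np.random.default_rng(seed)
    raw = rng.uniform(-3, 3, n)
    rsa = rng.uniform(0, 1, n)
    y = np.where(rsa < 0.3, raw, 3 * raw) + rng.normal(0, noise, n)
    return np.column_stack([raw, rsa]), y


class TestModelTree:
    def test_exact_linear_data_collapses_to_single_leaf(self):
        rng = np.random.default_rng(0)
        X = np.column_stack([rng.uniform(-2, 2, 200), rng.uniform(0, 1, 200)])
        y = 2.0 * X[:, 0] + 1.0
        tree = fit_model_tree(X, y, min_leaf=20, max_depth=4)
        assert tree.root.is_leaf
        np.testing.assert_allclose(tree.root.coef, [1.0, 2.0, 0.0], atol=1e-6)

    def test_piecewise_rsa_gate_recovered(self):
        X, y = _piecewise_data(seed=42)
        tree = fit_model_tree(X, y, min_leaf=20, max_depth=4)
        assert not tree.root.is_leaf
        assert tree.root.feature == 1  # splits on rsa
        assert 0.25 <= tree.root.threshold <= 0.35
        # leaf slopes via local finite differences well inside each region
        slope_buried = (calibrate(tree, 1.05, 0.1) - calibrate(tree, 0.95, 0.1)) / 0.1
        slope_exposed = (calibrate(tree, 1.05, 0.9) - calibrate(tree, 0.95, 0.9)) / 0.1
        assert slope_buried == pytest.approx(1.0, abs=0.1)
        assert slope_exposed == pytest.approx(3.0, abs=0.1)

    def test_too_few_points_give_single_constant_leaf(self):
        X = np.array([[0.0, 0.1], [1.0, 0.2], [2.0, 0.3]])
        y = np.array([1.0, 2.0, 3.0])
        tree = fit_model_tree(X, y, min_leaf=20)
        assert tree.root.is_leaf
        assert calibrate(tree, 5.0, 0.5) == pytest.approx(2.0)

    def test_constant_targets_give_constant_tree(self):
        rng = np.random.default_rng(1)
        X = rng.uniform(size=(100, 2))
        tree = fit_model_tree(X, np.full(100, 1.7))
        assert tree.root.is_leaf
        assert calibrate(tree, -4.0, 0.99) == pytest.approx(1.7)

    @pytest.mark.parametrize("seed", range(5))
    def test_tree_never_worse_than_global_linear_fit(self, seed):
        X, y = _piecewise_data(seed, n=300, noise=0.3)
        tree = fit_model_tree(X, y, min_leaf=20, max_depth=4)
        tree_mse = np.mean((tree.predict(X) - y) ** 2)
        A = np.column_stack([np.ones(len(y)), X])
        coef, *_ = np.linalg.lstsq(A, y, rcond=None)
        linear_mse = np.mean((A @ coef - y) ** 2)
        assert tree_mse <= linear_mse + 1e-12

    def test_calibration_routing_is_deterministic(self):
        X, y = _piecewise_data(seed=3)
        tree = fit_model_tree(X, y)
        v1 = calibrate(tree, 0.7, 0.6)
        assert all(calibrate(tree, 0.7, 0.6) == v1 for _ in range(5))

    def test_unfitted_tree_raises(self):
        with pytest.raises(NotFittedError):
            calibrate(ModelTree(), 0.0, 0.0)

    def test_serialization_round_trip(self):
        X, y = _piecewise_data(seed=5)
        tree = fit_model_tree(X, y)
        clone = ModelTree.from_dict(tree.to_dict())
        pts = np.random.default_rng(0).uniform(-3, 3, size=(50, 2))
        pts[:, 1] = np.abs(pts[:, 1]) / 3
        np.testing.assert_array_equal(tree.predict(pts), clone.predict(pts))
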