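import numpy as np
import pytest

from protstab import SVRModel, assemble_features, train_consensus, train_mcsm_component
from protstab.config import SvrConfig
from protstab.evaluation import pearson_r
from protstab.predictors import (FEATURE_WIDTH, NotFittedError, grid_search_svr,
                                 predict_consensus, unpack_features)


class TestAssembleFeatures:
    def test_fixed_layout(self):
        v = assemble_features(1.0, -2.0, "helix", np.zeros(8))
        np.testing.assert_array_equal(v, [1.0, -2.0, 1, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0])
        assert v.shape == (FEATURE_WIDTH,)

    @pytest.mark.parametrize("ss", ["helix", "strand", "coil"])
    def test_onehot_sums_to_one_and_round_trips(self, ss):
        pharm = np.arange(8) - 3
        v = assemble_features(0.5, 1.5, ss, pharm)
        assert v[2:5].sum() == 1.0
        m, s, ss_out, p = unpack_features(v)
        assert (m, s, ss_out) == (0.5, 1.5, ss)
        np.testing.assert_array_equal(p, pharm)

    def test_missing_component_named(self):
        with pytest.raises(ValueError, match="sdm_calibrated"):
            assemble_features(1.0, None, "helix", np.zeros(8))

    def test_unknown_ss_class_rejected(self):
        with pytest.raises(ValueError, match="turn"):
            assemble_features(1.0, 0.0, "turn", np.zeros(8))


class TestSvrModel:
    def test_nonpositive_hyperparameters_rejected(self):
        for kwargs in ({"C": 0.0}, {"gamma": -1.0}, {"epsilon": 0.0}):
            with pytest.raises(ValueError):
                SVRModel(**kwargs)

    def test_dual_feasibility_after_training(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(80, 3))
        y = X[:, 0] - 0.5 * X[:, 1] + rng.normal(0, 0.2, 80)
        m = SVRModel(C=10.0, gamma=0.5, epsilon=0.1).fit(X, y)
        feas = m.dual_feasibility()
        assert feas["sum_dual"] < 1e-6
        assert feas["box_violation"] == 0.0

    def test_epsilon_tube_with_attainable_function(self):
        # all targets within the tube of a constant: nothing becomes a
        # support vector and every training prediction stays inside epsilon
        rng = np.random.default_rng(1)
        X = rng.normal(size=(50, 2))
        y = 0.5 + 0.04 * np.sin(np.arange(50))
        m = SVRModel(C=10.0, gamma=0.1, epsilon=0.1).fit(X, y)
        assert len(m.dual_coef_) == 0 or np.allclose(m.dual_coef_, 0.0)
        assert np.all(np.abs(m.predict(X) - y) <= 0.1 + 1e-8)

    def test_prediction_is_deterministic_and_persists(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(60, 4))
        y = np.sin(X[:, 0])
        m = SVRModel(C=10.0, gamma=1.0, epsilon=0.1).fit(X, y)
        q = rng.normal(size=(10, 4))
        p1, p2 = m.predict(q), m.predict(q)
        np.testing.assert_array_equal(p1, p2)
        clone = SVRModel.from_dict(m.to_dict())
        np.testing.assert_allclose(clone.predict(q), p1, atol=1e-12)

    def test_unfitted_predict_raises(self):
        with pytest.raises(NotFittedError):
            SVRModel().predict(np.zeros((1, 2)))

    def test_standardization_makes_fit_affine_invariant(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(100, 3))
        y = np.sin(X[:, 0]) + 0.3 * X[:, 1]
        q = rng.normal(size=(20, 3))
        m1 = SVRModel(C=10.0, gamma=0.3, epsilon=0.1).fit(X, y)
        scale = np.array([10.0, 0.2, 5.0])
        shift = np.array([3.0, -1.0, 100.0])
        m2 = SVRModel(C=10.0, gamma=0.3, epsilon=0.1).fit(X * scale + shift, y)
        np.testing.assert_allclose(m2.predict(q * scale + shift), m1.predict(q),
                                   atol=1e-6)


class TestNonlinearRecovery:
    def test_sine_signal_recovered_on_held_out_data(self):
        rng = np.random.default_rng(7)
        X = np.zeros((300, FEATURE_WIDTH))
        X[:, 0] = rng.uniform(-3, 3, 300)
        y = np.sin(X[:, 0]) + rng.normal(0, 0.05, 300)
        model, info = grid_search_svr(X[:200], y[:200], SvrConfig())
        held_out = predict_consensus(model, X[200:])
        assert pearson_r(held_out, y[200:]) > 0.9

    def test_constant_targets_predicted_within_epsilon(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(40, FEATURE_WIDTH))
        y = np.full(40, 1.3)
        m = train_consensus(X, y, C=10.0, gamma=0.1, epsilon=0.1)
        assert np.all(np.abs(m.predict(X) - 1.3) <= 0.1 + 1e-8)


class TestMcsmComponent:
    def _signature_panel(self, n, seed, width=60):
        rng = np.random.default_rng(seed)
        X = rng.poisson(8, size=(n, width)).astype(float)
        return X, rng

    def test_linear_signal_in_two_components_recovered(self):
        X, rng = self._signature_panel(200, 11)
        y = 0.4 * X[:, 5] - 0.3 * X[:, 17] + rng.normal(0, 0.1, 200)
        m = train_mcsm_component(X[:150], y[:150],
                                 hyperparams={"C": 10.0, "gamma": 0.01, "epsilon": 0.1})
        assert pearson_r(m.predict(X[150:]), y[150:]) > 0.9

    def test_permuted_labels_carry_no_signal(self):
        # large held-out set so that the no-signal bound is ~3.5 sigma
        X, rng = self._signature_panel(300, 12)
        y = 0.4 * X[:, 5] - 0.3 * X[:, 17] + rng.normal(0, 0.1, 300)
        y_perm = rng.permutation(y[:100])
        m = train_mcsm_component(X[:100], y_perm,
                                 hyperparams={"C": 10.0, "gamma": 0.01, "epsilon": 0.1})
        r = pearson_r(m.predict(X[100:]), y[100:])
        assert abs(r) < 0.25

    def test_too_small_training_set_rejected(self):
        X, _rng = self._signature_panel(10, 13)
        with pytest.raises(ValueError, match="at least 20"):
            train_mcsm_component(X, np.zeros(10))

    def test_constant_targets_reproduced(self):
        X, _rng = self._signature_panel(40, 14)
        m = train_mcsm_component(X, np.full(40, -0.7),
                                 hyperparams={"C": 10.0, "gamma": 0.01, "epsilon": 0.1})
        assert np.all(np.abs(m.predict(X) + 0.7) <= 0.1 + 1e-8)
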