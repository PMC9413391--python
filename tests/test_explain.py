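import itertools
import math

import numpy as np
import pytest

from afsync.explain import (
    rank_report,
    shap_for_dataset,
    shap_global,
    shapley_exact,
    shapley_sampled,
    value_function,
)
from afsync.model import DenseAF, TrainConfig


def _linear_predict(w, b=0.0):
    w = np.asarray(w, dtype=float)
    return lambda X: np.atleast_2d(X) @ w + b


def _permutation_oracle(predict_fn, x, background):
    """Direct average of marginal contributions over all M! permutations."""
    m = x.size
    shap = np.zeros(m)
    for perm in itertools.permutations(range(m)):
        mask = np.zeros(m, dtype=bool)
        prev = value_function(predict_fn, x, mask, background)
        for i in perm:
            mask[i] = True
            cur = value_function(predict_fn, x, mask, background)
            shap[i] += cur - prev
            prev = cur
    return shap / math.factorial(m)


class TestValueFunction:
    def test_full_subset_is_model_prediction(self, rng):
        f = _linear_predict([1.0, -2.0, 0.5])
        x = np.array([1.0, 2.0, 3.0])
        bg = rng.normal(size=(20, 3))
        full = value_function(f, x, np.ones(3, dtype=bool), bg)
        assert full == pytest.approx(float(f(x[None, :])[0]))

    def test_empty_subset_is_base_value(self, rng):
        f = _linear_predict([1.0, -2.0, 0.5])
        bg = rng.normal(size=(20, 3))
        base = value_function(f, np.zeros(3), np.zeros(3, dtype=bool), bg)
        assert base == pytest.approx(float(np.mean(f(bg))))

    def test_singleton_background(self):
        f = _linear_predict([2.0, 1.0])
        bg = np.array([[10.0, 20.0]])
        v = value_function(f, np.array([1.0, 2.0]), np.array([True, False]), bg)
        assert v == pytest.approx(2.0 * 1.0 + 1.0 * 20.0)

    def test_empty_background_rejected(self):
        with pytest.raises(ValueError):
            value_function(_linear_predict([1.0]), np.array([1.0]),
                           np.array([True]), np.empty((0, 1)))


class TestShapleyExact:
    def test_dummy_axiom_ignored_feature_gets_zero(self, rng):
        f = _linear_predict([1.5, 0.0, -1.0])  # feature 1 is ignored
        x, bg = rng.normal(size=3), rng.normal(size=(15, 3))
        shap = shapley_exact(f, x, bg)
        assert shap[1] == pytest.approx(0.0, abs=1e-12)

    def test_linear_model_closed_form(self, rng):
        w = np.array([1.5, -2.0, 0.7, 0.0, 3.1])
        f = _linear_predict(w, b=0.3)
        x = rng.normal(size=5)
        bg = rng.normal(size=(30, 5))
        shap = shapley_exact(f, x, bg)
        np.testing.assert_allclose(shap, w * (x - bg.mean(axis=0)), atol=1e-6)

    def test_matches_permutation_oracle_on_nonlinear_model(self, rng):
        f = lambda X: np.tanh(np.atleast_2d(X) @ np.array([1.0, -1.0, 0.5]))
        x, bg = rng.normal(size=3), rng.normal(size=(10, 3))
        np.testing.assert_allclose(shapley_exact(f, x, bg),
                                   _permutation_oracle(f, x, bg), atol=1e-10)

    def test_efficiency(self, rng):
        model = DenseAF(8, (8, 4), TrainConfig(seed=3))
        x, bg = rng.normal(size=8), rng.normal(size=(12, 8))
        shap = shapley_exact(model.predict_proba, x, bg)
        full = model.predict_proba(x[None, :])[0]
        base = float(np.mean(model.predict_proba(bg)))
        assert shap.sum() == pytest.approx(full - base, abs=1e-6)

    def test_symmetry_of_interchangeable_features(self, rng):
        # f symmetric in features 0 and 1; x and background symmetric too
        f = lambda X: np.atleast_2d(X)[:, 0] * np.atleast_2d(X)[:, 1]
        x = np.array([2.0, 2.0, 1.0])
        bg_half = rng.normal(size=(8, 3))
        bg = np.vstack([bg_half, bg_half[:, [1, 0, 2]]])  # symmetrize
        shap = shapley_exact(f, x, bg)
        assert shap[0] == pytest.approx(shap[1], abs=1e-10)

    def test_large_m_refused(self):
        with pytest.raises(ValueError, match="shapley_sampled"):
            shapley_exact(_linear_predict(np.ones(16)), np.zeros(16),
                          np.zeros((2, 16)))


class TestShapleySampled:
    def test_close_to_exact_on_ten_features(self, rng):
        model = DenseAF(10, (8,), TrainConfig(seed=5))
        x, bg = rng.normal(size=10), rng.normal(size=(16, 10))
        exact = shapley_exact(model.predict_proba, x, bg)
        est = shapley_sampled(model.predict_proba, x, bg,
                              n_permutations=2000, seed=0)
        assert np.max(np.abs(est.values - exact)) < 0.01

    def test_seed_reproducibility(self, rng):
        f = _linear_predict([1.0, -1.0, 0.5, 2.0])
        x, bg = rng.normal(size=4), rng.normal(size=(10, 4))
        a = shapley_sampled(f, x, bg, 200, seed=9)
        b = shapley_sampled(f, x, bg, 200, seed=9)
        np.testing.assert_array_equal(a.values, b.values)

    def test_efficiency_within_monte_carlo_error(self, rng):
        model = DenseAF(8, (4,), TrainConfig(seed=1))
        x, bg = rng.normal(size=8), rng.normal(size=(10, 8))
        est = shapley_sampled(model.predict_proba, x, bg, 500, seed=2)
        full = model.predict_proba(x[None, :])[0]
        base = float(np.mean(model.predict_proba(bg)))
        gap = abs(est.values.sum() - (full - base))
        # efficiency holds exactly per permutation, so the gap is only
        # floating-point accumulation
        assert gap < 1e-8

    def test_error_shrinks_with_more_permutations(self, rng):
        model = DenseAF(8, (6,), TrainConfig(seed=7))
        x, bg = rng.normal(size=8), rng.normal(size=(12, 8))
        exact = shapley_exact(model.predict_proba, x, bg)
        errs = [np.max(np.abs(shapley_sampled(model.predict_proba, x, bg, n,
                                              seed=4).values - exact))
                for n in (100, 1600)]
        assert errs[1] < errs[0]

    def test_too_few_permutations_rejected(self):
        with pytest.raises(ValueError):
            shapley_sampled(_linear_predict([1.0]), np.zeros(1),
                            np.zeros((2, 1)), n_permutations=10)


class TestGlobalAggregation:
    def test_published_percent_of_max_ratios(self):
        # one record per "feature profile": globals are the printed values
        glob, pct = shap_global(np.array([[0.0196, -0.0164, 0.0120]]))
        assert pct[0] == 100
        assert pct[1] == 84
        assert pct[2] == 61

    def test_single_feature_is_100pct(self):
        _, pct = shap_global(np.array([[0.42], [-0.1]]))
        assert pct[0] == 100

    def test_record_order_invariance(self, rng):
        vals = rng.normal(size=(30, 5))
        g1, _ = shap_global(vals)
        g2, _ = shap_global(vals[::-1])
        np.testing.assert_allclose(g1, g2)


class TestRankReport:
    NAMES = ["RRi_mean", "RRi_std", "PQa_mean_aVR", "PQi_std_V2"]

    def test_threshold_at_quarter_of_max(self):
        glob = np.array([0.0196, 0.0164, 0.0120, 0.003])
        rep = rank_report(glob, self.NAMES, threshold_fraction=0.25)
        assert rep.threshold == pytest.approx(0.0049)
        assert "PQi_std_V2" not in rep.flagged
        assert rep.flagged[:2] == ["RRi_mean", "RRi_std"]

    def test_all_equal_all_flagged(self):
        rep = rank_report(np.full(4, 0.01), self.NAMES)
        assert len(rep.flagged) == 4

    def test_rr_features_excluded_from_lead_summary(self):
        glob = np.array([0.02, 0.016, 0.012, 0.011])
        rep = rank_report(glob, self.NAMES)
        assert set(rep.per_lead["lead"]) == {"aVR", "V2"}
        assert set(rep.per_family["family"]) == {"PQa_mean", "PQi_std"}


def test_shap_for_dataset_routes_by_dimension(rng):
    model = DenseAF(6, (4,), TrainConfig(seed=0))
    X = rng.normal(size=(3, 6))
    bg = rng.normal(size=(8, 6))
    vals = shap_for_dataset(model.predict_proba, X, bg)
    assert vals.shape == (3, 6)
    exact0 = shapley_exact(model.predict_proba, X[0], bg)
    np.testing.assert_allclose(vals[0], exact0)
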