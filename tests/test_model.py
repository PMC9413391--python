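import itertools
import math

import numpy as np
import pytest

from afsync.model import (
    Architecture,
    DenseAF,
    TrainConfig,
    class_weights_from_labels,
    enumerate_architectures,
    grid_search,
    weighted_bce_loss,
)


def _brute_force_count(options, max_depth=3):
    """Oracle: enumerate all width tuples and keep the non-increasing ones."""
    count = 0
    for k in range(1, max_depth + 1):
        for tup in itertools.product(options, repeat=k):
            if all(a >= b for a, b in zip(tup, tup[1:])):
                count += 1
    return count


class TestEnumerateArchitectures:
    @pytest.mark.parametrize("options,expected", [
        ([4, 8, 16], 19),
        ([4, 8, 16, 32, 64], 55),
        ([4, 8, 16, 32, 64, 128], 83),
        ([4], 3),
    ])
    def test_counts(self, options, expected):
        archs = enumerate_architectures(options)
        assert len(archs) == expected
        assert len(archs) == _brute_force_count(options)
        m = len(options)
        closed_form = sum(math.comb(m + k - 1, k) for k in (1, 2, 3))
        assert len(archs) == closed_form

    def test_depth_breakdown_for_three_options(self):
        archs = enumerate_architectures([4, 8, 16])
        by_depth = {k: sum(1 for a in archs if len(a.widths) == k) for k in (1, 2, 3)}
        assert by_depth == {1: 3, 2: 6, 3: 10}

    def test_all_shrinking_and_unique(self):
        archs = enumerate_architectures([4, 8, 16, 32, 64, 128])
        assert len({a.widths for a in archs}) == len(archs)
        for a in archs:
            assert all(x >= y for x, y in zip(a.widths, a.widths[1:]))

    def test_empty_options_rejected(self):
        with pytest.raises(ValueError):
            enumerate_architectures([])

    def test_growing_architecture_rejected(self):
        with pytest.raises(ValueError):
            Architecture((8, 16))


class TestBuildModel:
    def test_layer_shapes_for_optimal_12lead(self):
        model = DenseAF(50, (128, 8, 8))
        assert model.params["W0"].shape == (50, 128)
        assert model.params["W1"].shape == (128, 8)
        assert model.params["W2"].shape == (8, 8)
        assert model.params["W3"].shape == (8, 1)
        assert model.params["gamma"].shape == (50,)

    def test_forward_output_in_unit_interval(self, rng):
        model = DenseAF(6, (8, 4))
        p = model.predict_proba(rng.normal(0, 3, (40, 6)))
        assert np.all((p > 0) & (p < 1))

    def test_same_seed_identical_parameters(self):
        a = DenseAF(26, (16, 8), TrainConfig(seed=5))
        b = DenseAF(26, (16, 8), TrainConfig(seed=5))
        for k in a.params:
            np.testing.assert_array_equal(a.params[k], b.params[k])

    def test_zero_weights_give_half_probability(self):
        model = DenseAF(6, (4,))
        for k in model.params:
            model.params[k][:] = 0.0
        model.params["gamma"][:] = 1.0
        assert model.predict_proba(np.ones((1, 6)))[0] == pytest.approx(0.5)

    def test_prediction_deterministic(self, rng):
        model = DenseAF(6, (8,))
        X = rng.normal(size=(10, 6))
        np.testing.assert_array_equal(model.predict_proba(X), model.predict_proba(X))


class TestLoss:
    def test_perfect_predictions_near_zero(self):
        y = np.array([1.0, 0.0, 1.0])
        assert weighted_bce_loss(np.array([1.0, 0.0, 1.0]), y, (0.92, 0.08)) < 1e-6

    def test_single_af_sample_hand_value(self):
        loss = weighted_bce_loss(np.array([0.5]), np.array([1.0]), (0.92, 0.08))
        assert loss == pytest.approx(0.92 * np.log(2.0))

    def test_weights_from_8pct_prevalence(self):
        labels = np.array([1] * 8 + [0] * 92)
        assert class_weights_from_labels(labels) == pytest.approx((0.92, 0.08))

    def test_equal_weights_halve_unweighted_bce(self, rng):
        p = rng.uniform(0.05, 0.95, 200)
        y = (rng.random(200) < 0.5).astype(float)
        ours = weighted_bce_loss(p, y, (0.5, 0.5))
        unweighted = -np.mean(y * np.log(p) + (1 - y) * np.log(1 - p))
        assert ours == pytest.approx(0.5 * unweighted)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            weighted_bce_loss(np.array([0.5]), np.array([1.0, 0.0]), (0.5, 0.5))


def _separable_data(rng, n=2000, dim=6, gap=6.0):
    y = (rng.random(n) < 0.5).astype(float)
    X = rng.normal(0, 1.0, (n, dim))
    X[:, 0] += gap * y
    return X, y


class TestTraining:
    def test_separable_classes_learned(self, rng):
        X, y = _separable_data(rng)
        Xv, yv = _separable_data(rng, n=600)
        model = DenseAF(6, (8,), TrainConfig(seed=1, max_epochs=60))
        model.fit(X, y, Xv, yv)
        from afsync.evaluate import balanced_accuracy
        bac = balanced_accuracy(model.predict_proba(Xv) > 0.5, yv)
        assert bac >= 99.0

    def test_early_stopping_on_plateaued_validation_loss(self, rng):
        # heavily overlapping classes: validation loss bottoms out early
        X, y = _separable_data(rng, n=400, gap=0.3)
        Xv, yv = _separable_data(rng, n=200, gap=0.3)
        model = DenseAF(6, (4,), TrainConfig(seed=2, max_epochs=400))
        model.fit(X, y, Xv, yv)
        assert model.epochs_run < 400
        # checkpoint is the minimal validation loss seen
        assert model.best_val_loss == pytest.approx(min(model.history["val_loss"]))

    def test_epoch_budget_respected(self, rng):
        X, y = _separable_data(rng, n=200)
        model = DenseAF(6, (4,), TrainConfig(seed=3, max_epochs=5, patience=100))
        model.fit(X, y, X, y)
        assert model.epochs_run <= 5

    def test_single_class_training_rejected(self, rng):
        X = rng.normal(size=(50, 6))
        with pytest.raises(ValueError):
            DenseAF(6, (4,)).fit(X, np.zeros(50), X, np.zeros(50))

    def test_training_reproducible(self, rng):
        X, y = _separable_data(rng, n=300)
        out = []
        for _ in range(2):
            m = DenseAF(6, (4,), TrainConfig(seed=7, max_epochs=15))
            m.fit(X, y, X, y)
            out.append(m.predict_proba(X[:20]))
        np.testing.assert_array_equal(out[0], out[1])


class TestPersistence:
    def test_hdf5_round_trip(self, tmp_path, rng):
        X, y = _separable_data(rng, n=300)
        model = DenseAF(6, (8, 4), TrainConfig(seed=4, max_epochs=10),
                        feature_names=[f"f{i}" for i in range(6)], lead_set="single:II")
        model.fit(X, y, X, y)
        model.p_thr = 0.37
        path = tmp_path / "model.h5"
        model.save(path)
        back = DenseAF.load(path)
        assert back.architecture.widths == (8, 4)
        assert back.p_thr == 0.37
        assert back.feature_names == model.feature_names
        np.testing.assert_array_equal(back.predict_proba(X[:10]),
                                      model.predict_proba(X[:10]))


class TestGridSearch:
    def test_run_count_and_ranking(self, rng):
        X, y = _separable_data(rng, n=300)
        Xv, yv = _separable_data(rng, n=150)
        archs = enumerate_architectures([4])  # [4], [4,4], [4,4,4]
        results, best = grid_search(archs, 2, X, y, Xv, yv,
                                    TrainConfig(seed=0, max_epochs=10))
        assert len(results) == 6
        bacs = results["val_bac"].to_numpy()
        assert np.all(bacs[:-1] >= bacs[1:])  # descending
        assert best.p_thr is not None
        # tie-break: among equal-BAC rows, parameter counts ascend
        top = results[results["val_bac"] == bacs[0]]
        np_col = top["n_params"].to_numpy()
        assert np.all(np_col[:-1] <= np_col[1:])
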