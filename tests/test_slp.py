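"""Feature assembly, perceptron training, prediction and pooled evaluation."""

import numpy as np
import pytest

from thermospec import (DEFAULT_STRESS_SCHEDULE, FeatureMatrix, PointCloud,
                        SLPConfig, SLPResults, assemble_features,
                        make_linear_cloud, train_slp)
from thermospec.slp import DivergenceError, SLPRegressor


def day_cloud(day, n, seed, channels=(10, 20)):
    rng = np.random.default_rng(seed)
    x = rng.uniform(0, 1, (n, len(channels)))
    y = 20 + x @ np.arange(1, len(channels) + 1)
    return PointCloud(x=x, y=y, rows=np.zeros(n, dtype=int),
                      cols=np.arange(n), day=day, channels=tuple(channels))


class TestAssembleFeatures:
    def test_column_counts(self):
        clouds = [day_cloud(1, 30, 0), day_cloud(7, 30, 1)]
        assert assemble_features(clouds, [10, 20]).p == 2
        assert assemble_features(clouds, [10, 20], include_day=True).p == 3

    def test_day_feature_minmax_endpoints(self):
        clouds = [day_cloud(d, 10, d) for d in (1, 3, 7)]
        fm = assemble_features(clouds, [10], include_day=True)
        np.testing.assert_allclose(np.unique(fm.x[:, 1]), [0.0, 2 / 6, 1.0], atol=1e-12)
        assert fm.x[fm.day == 1, 1].max() == 0.0
        assert fm.x[fm.day == 7, 1].min() == 1.0

    def test_row_conservation(self):
        sizes = [11, 23, 7, 30, 14, 9, 18]
        clouds = [day_cloud(d + 1, n, d) for d, n in enumerate(sizes)]
        fm = assemble_features(clouds, [10, 20])
        assert fm.n == sum(sizes)

    def test_empty_channel_list_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            assemble_features([day_cloud(1, 10, 0)], [])

    def test_zero_variance_channel_rejected(self):
        cloud = day_cloud(1, 20, 0)
        cloud.x[:, 0] = 0.7
        with pytest.raises(ValueError, match="zero variance"):
            FeatureMatrix(cloud.x, cloud.y, np.ones(20, dtype=int), (10, 20))


class TestTraining:
    def test_noiseless_matches_normal_equations(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(0, 1, (500, 1))
        y = 2.0 * x[:, 0] + 20.0
        fm = FeatureMatrix(x, y, np.ones(500, dtype=int), (143,))
        model = train_slp(fm, config=SLPConfig(val_fraction=0.0, seed=0))
        # closed-form least squares on the same standardised features
        xs = (x - fm.means) / fm.stds
        A = np.column_stack([xs, np.ones(500)])
        coef, *_ = np.linalg.lstsq(A, y, rcond=None)
        assert model.weights[0] == pytest.approx(coef[0], abs=1e-3)
        assert model.bias == pytest.approx(coef[1], abs=1e-3)
        assert model.history_train[-1] < 1e-3

    def test_constant_targets(self):
        rng = np.random.default_rng(1)
        x = rng.uniform(0, 1, (50, 2))
        fm = FeatureMatrix(x, np.full(50, 21.5), np.ones(50, dtype=int), (1, 2))
        model = train_slp(fm, config=SLPConfig(val_fraction=0.0))
        np.testing.assert_allclose(model.weights, 0.0, atol=1e-9)
        assert model.bias == pytest.approx(21.5)

    def test_same_seed_bit_identical(self):
        clouds, _, _ = make_linear_cloud(800, temp_noise_sd=0.1, seed=4)
        fm = assemble_features(clouds, [143])
        a = train_slp(fm, config=SLPConfig(seed=9))
        b = train_slp(fm, config=SLPConfig(seed=9))
        assert a.history_train == b.history_train
        assert a.history_val == b.history_val
        np.testing.assert_array_equal(a.weights, b.weights)
        assert a.bias == b.bias

    def test_train_loss_monotone_under_line_search(self):
        clouds, _, _ = make_linear_cloud(600, temp_noise_sd=0.2, seed=5)
        fm = assemble_features(clouds, [143])
        model = train_slp(fm, config=SLPConfig(val_fraction=0.0, max_epochs=100))
        h = model.history_train
        assert all(b <= a + 1e-12 for a, b in zip(h, h[1:]))

    @pytest.mark.filterwarnings("ignore:overflow")
    def test_divergence_reported_with_epoch(self):
        clouds, _, _ = make_linear_cloud(200, temp_noise_sd=0.1, seed=6)
        fm = assemble_features(clouds, [143])
        with pytest.raises(DivergenceError, match="epoch"):
            train_slp(fm, config=SLPConfig(learning_rate=50.0, val_fraction=0.0,
                                           patience=500))

    def test_too_few_rows_rejected(self):
        rng = np.random.default_rng(2)
        fm = FeatureMatrix(rng.uniform(0, 1, (5, 1)), rng.uniform(18, 25, 5),
                           np.ones(5, dtype=int), (0,))
        with pytest.raises(ValueError, match=">= 10"):
            SLPRegressor(fm, config=SLPConfig(val_fraction=0.0))

    def test_parameter_recovery_noise_floor(self):
        """Held-out pooled RMSE stays within 1.5x the 0.1 degC noise floor."""
        for seed in range(5):
            clouds, *_ = make_linear_cloud(5000, temp_noise_sd=0.1, seed=seed)
            fm = assemble_features(clouds, [143])
            rng = np.random.default_rng(seed)
            perm = rng.permutation(fm.n)
            train, test = fm.rows(perm[1000:]), fm.rows(perm[:1000])
            model = train_slp(train, config=SLPConfig(seed=seed))
            rmse, _ = model.evaluate(test)
            assert rmse <= 0.15


class TestPredictEvaluate:
    def manual_results(self, weights, bias, channels=(0,), include_day=False):
        p = len(weights)
        return SLPResults(
            weights=np.array(weights, dtype=float), bias=bias,
            means=np.zeros(p), stds=np.ones(p), channels=tuple(channels),
            include_day=include_day, config=SLPConfig(),
            history_train=[0.0], history_val=[], epochs_run=1,
        )

    def feature(self, x, y=None, channels=(0,), day=1):
        x = np.atleast_2d(np.asarray(x, dtype=float))
        n = x.shape[0]
        y = np.zeros(n) if y is None else np.asarray(y, dtype=float)
        return FeatureMatrix(x, y, np.full(n, day, dtype=int), tuple(channels))

    def test_identity_standardisation_hand_value(self):
        model = self.manual_results([2.0], 1.0)
        out = model.predict(self.feature([[3.0], [0.0]]))
        np.testing.assert_allclose(out, [7.0, 1.0])

    def test_zero_weights_constant_bias(self):
        model = self.manual_results([0.0, 0.0], 19.5, channels=(0, 1))
        out = model.predict(self.feature(np.random.default_rng(0).uniform(0, 9, (6, 2)),
                                         channels=(0, 1)))
        np.testing.assert_allclose(out, 19.5)

    def test_batch_equals_per_row(self):
        model = self.manual_results([1.5, -0.5], 20.0, channels=(3, 4))
        rng = np.random.default_rng(1)
        x = rng.uniform(0, 1, (8, 2))
        batch = model.predict(self.feature(x, channels=(3, 4)))
        single = [model.predict(self.feature(row[None, :], channels=(3, 4)))[0]
                  for row in x]
        np.testing.assert_allclose(batch, single)

    def test_column_mismatch_rejected(self):
        model = self.manual_results([1.0], 0.0, channels=(0,))
        with pytest.raises(ValueError, match="columns"):
            model.predict(self.feature([[1.0, 2.0]], channels=(0, 1)))

    def test_perfect_predictions_zero_rmse(self):
        model = self.manual_results([1.0], 0.0)
        fm = self.feature([[1.0], [2.0]], y=[1.0, 2.0])
        pooled, per_day = model.evaluate(fm)
        assert pooled == 0.0

    def test_pooled_rmse_matches_flat_brute_force(self):
        """Pooled multi-day loss == sqrt(sum of squared errors / total n)."""
        model = self.manual_results([1.2], 0.3)
        rng = np.random.default_rng(2)
        sizes = {1: 13, 3: 27, 6: 8}
        xs, ys, ds = [], [], []
        for d, n in sizes.items():
            xs.append(rng.uniform(0, 1, (n, 1)))
            ys.append(rng.uniform(18, 25, n))
            ds.append(np.full(n, d))
        fm = FeatureMatrix(np.vstack(xs), np.concatenate(ys),
                           np.concatenate(ds), (0,))
        pooled, per_day = model.evaluate(fm)
        pred = fm.x[:, 0] * 1.2 + 0.3
        flat = np.sqrt(np.sum((pred - fm.y) ** 2) / fm.n)
        assert pooled == pytest.approx(flat, abs=1e-12)
        # record-weighted root of per-day squared errors reproduces the pooled value
        recomposed = np.sqrt(
            sum(per_day[d] ** 2 * n for d, n in sizes.items()) / fm.n
        )
        assert pooled == pytest.approx(recomposed, abs=1e-12)

    def test_single_day_pooled_equals_day_rmse(self):
        model = self.manual_results([1.0], 0.0)
        fm = self.feature([[1.0], [3.0]], y=[2.0, 2.0], day=4)
        pooled, per_day = model.evaluate(fm)
        assert pooled == per_day[4]

    def test_row_order_invariance(self):
        model = self.manual_results([1.1], 0.2)
        rng = np.random.default_rng(3)
        x = rng.uniform(0, 1, (40, 1))
        y = rng.uniform(18, 25, 40)
        day = rng.integers(1, 8, 40)
        fm = FeatureMatrix(x, y, day, (0,))
        perm = rng.permutation(40)
        fm2 = FeatureMatrix(x[perm], y[perm], day[perm], (0,))
        assert model.evaluate(fm)[0] == pytest.approx(model.evaluate(fm2)[0], abs=1e-12)

    def test_empty_evaluation_rejected(self):
        model = self.manual_results([1.0], 0.0)
        fm = FeatureMatrix(np.zeros((0, 1)), np.zeros(0), np.zeros(0, dtype=int), (0,))
        with pytest.raises(ValueError, match="empty"):
            model.evaluate(fm)


class TestSerialization:
    def test_json_round_trip(self, tmp_path):
        clouds, _, _ = make_linear_cloud(400, seed=8)
        fm = assemble_features(clouds, [143])
        model = train_slp(fm, config=SLPConfig(seed=1))
        model.to_json(tmp_path / "model.json")
        back = SLPResults.from_json(tmp_path / "model.json")
        np.testing.assert_array_equal(back.weights, model.weights)
        assert back.bias == model.bias
        np.testing.assert_array_equal(back.means, model.means)
        pooled_a, _ = model.evaluate(fm)
        pooled_b, _ = back.evaluate(fm)
        assert pooled_a == pooled_b
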