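"""Moment-line predictor, residual truncation and the per-day study row."""

import numpy as np
import pytest

from thermospec import (CloudRegression, CloudRegressionResults, PointCloud,
                        day_report, fit_predictor, ndblue_map, rmse)


def cloud_of(x, y, day=1, channel=143):
    x = np.asarray(x, dtype=float)
    return PointCloud(x=x[:, None], y=np.asarray(y, dtype=float),
                      rows=np.zeros(len(x), dtype=int),
                      cols=np.arange(len(x)), day=day, channels=(channel,))


def random_cloud(rng, n=60):
    x = rng.uniform(0, 1, n)
    y = 20 - 5 * x + rng.normal(0, 0.3, n)
    return cloud_of(x, y)


class TestFitPredictor:
    def test_symmetric_affine_cloud(self):
        res = fit_predictor(cloud_of([0, 1, 2], [10, 11, 12]))
        assert (res.ex, res.ey) == (1.0, 11.0)
        assert res.sy / res.sx == pytest.approx(1.0)
        assert res.sign == 1
        assert res.predict(3.0) == pytest.approx(13.0)

    def test_anticorrelated_sign_rule(self):
        res = fit_predictor(cloud_of([0, 1, 2], [12, 11, 10]))
        assert res.sign == -1
        assert res.predict(3.0) == pytest.approx(9.0)

    def test_literal_unsigned_form(self):
        res = fit_predictor(cloud_of([0, 1, 2], [12, 11, 10]), signed_slope=False)
        assert res.sign == 1
        assert res.predict(3.0) == pytest.approx(13.0)

    @pytest.mark.parametrize("alpha,beta", [(2.5, -3.0), (-0.7, 21.0)])
    def test_noiseless_affine_exact(self, alpha, beta):
        x = np.linspace(0, 1, 50)
        res = fit_predictor(cloud_of(x, alpha * x + beta))
        np.testing.assert_allclose(res.predict(x), alpha * x + beta, atol=1e-10)
        assert res.rmse() == pytest.approx(0.0, abs=1e-10)
        assert abs(res.plcc) == pytest.approx(1.0, abs=1e-12)

    def test_centroid_and_unit_step(self):
        rng = np.random.default_rng(1)
        res = fit_predictor(random_cloud(rng))
        assert res.predict(res.ex) == pytest.approx(res.ey)
        assert res.predict(res.ex + res.sx) == pytest.approx(res.ey + res.sign * res.sy)

    def test_batch_equals_scalar(self):
        rng = np.random.default_rng(2)
        res = fit_predictor(random_cloud(rng))
        xs = rng.uniform(0, 1, 10)
        np.testing.assert_allclose(res.predict(xs), [res.predict(float(v)) for v in xs])

    def test_degenerate_inputs(self):
        with pytest.raises(ValueError, match="constant"):
            fit_predictor(cloud_of([1, 1, 1], [1, 2, 3]))
        with pytest.raises(ValueError, match="too small"):
            fit_predictor(cloud_of([1], [1]))

    def test_summary_mentions_key_quantities(self):
        res = fit_predictor(cloud_of([0, 1, 2], [10, 11, 12]))
        text = res.summary()
        assert "PLCC" in text and "slope" in text and "RMSE" in text


class TestTruncation:
    def line_through(self, x, y):
        """A unit line y(x) = x as an explicitly constructed fitted result."""
        cloud = cloud_of(x, y)
        model = CloudRegression(cloud)
        return CloudRegressionResults(model=model, ex=0.0, ey=0.0, sx=1.0,
                                      sy=1.0, sign=1, plcc=1.0, n=cloud.n)

    def test_hand_worked_thresholds(self):
        # residuals against y = x are exactly {+1.0, +0.4, -0.2}
        res = self.line_through([0, 1, 2], [1.0, 1.4, 1.8])
        np.testing.assert_allclose(res.resid(), [1.0, 0.4, -0.2])
        t = res.truncate(0.5, 0.5)
        assert t.threshold_up == pytest.approx(0.5)
        assert t.threshold_down == pytest.approx(0.1)
        np.testing.assert_allclose(t.kept.y, [1.4])
        assert t.n_removed == 2

    def test_full_fractions_keep_everything(self):
        rng = np.random.default_rng(3)
        res = fit_predictor(random_cloud(rng))
        t = res.truncate(1.0, 1.0)
        assert t.n_removed == 0
        assert t.n_kept == res.n

    def test_zero_fractions_keep_only_exact_fits(self):
        res = self.line_through([0, 1, 2], [1.0, 1.0, 2.0])  # residuals 1, 0, 0
        t = res.truncate(0.0, 0.0)
        assert t.n_kept == 2

    def test_fraction_bounds_enforced(self):
        rng = np.random.default_rng(4)
        res = fit_predictor(random_cloud(rng))
        with pytest.raises(ValueError):
            res.truncate(1.5, 0.5)
        with pytest.raises(ValueError):
            res.truncate(0.5, -0.1)

    def test_partition_and_monotonicity(self):
        """Over 50 random clouds and an (a, b) grid: exact partition, kept
        size monotone in a and in b."""
        rng = np.random.default_rng(5)
        grid = [0.0, 0.25, 0.5, 0.75, 1.0]
        for _ in range(50):
            cloud = random_cloud(rng)
            res = fit_predictor(cloud)
            prev_by_b = {}
            for a in grid:
                prev = -1
                for b in grid:
                    t = res.truncate(a, b)
                    assert t.n_kept + t.n_removed == cloud.n
                    assert t.n_kept >= prev            # monotone in b
                    prev = t.n_kept
                    assert t.n_kept >= prev_by_b.get(b, -1)   # monotone in a
                    prev_by_b[b] = t.n_kept

    def test_symmetric_truncation_never_raises_fixed_line_rmse(self):
        """For the symmetric a = b variant the study uses, fixed-line RMSE on
        the kept records never exceeds the full-cloud RMSE.  (Strongly
        asymmetric a != b pairs can violate this: the two cutoffs are
        fractions of different one-sided extremes, so a kept record on the
        loose side may out-square a removed record on the tight side.)"""
        rng = np.random.default_rng(5)
        for _ in range(50):
            cloud = random_cloud(rng)
            res = fit_predictor(cloud)
            full_rmse = res.rmse()
            for a in (0.1, 0.25, 0.5, 0.75, 0.9):
                t = res.truncate(a, a)
                if t.n_kept:
                    kept_rmse = float(np.sqrt(np.mean(res.resid(t.kept) ** 2)))
                    assert kept_rmse <= full_rmse + 1e-12


class TestRmse:
    def test_identical_sequences(self):
        assert rmse([1.0, 2.0], [1.0, 2.0]) == 0.0

    def test_symmetric_residuals(self):
        assert rmse([0.1, -0.1], [0.0, 0.0]) == pytest.approx(0.1)

    def test_hand_value(self):
        assert rmse([3.0, 4.0], [0.0, 0.0]) == pytest.approx(np.sqrt(12.5))

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            rmse([], [])


class TestDayReport:
    def test_exact_channel_gives_perfect_prediction(self, affine_channel_scene):
        """When one channel is an exact affine image of temperature, the day
        report finds it, with unit PLCC and zero RMSE at any (a, b)."""
        cube, tir, _ = affine_channel_scene
        index = ndblue_map(cube)
        row = day_report(cube, tir, index, day=1, thr=0.4, a=0.7, b=0.7)
        assert abs(row["plcc"]) == pytest.approx(1.0, abs=1e-6)
        assert row["rmse_c"] == pytest.approx(0.0, abs=1e-4)
        assert row["rmse_in_c"] == pytest.approx(0.0, abs=1e-4)
        assert row["best_channel"] == 143

    def test_unit_fractions_are_no_op(self, default_scene):
        cube, tir, _ = default_scene
        index = ndblue_map(cube)
        row = day_report(cube, tir, index, day=1, thr=0.4, a=1.0, b=1.0)
        assert row["rmse_in_c"] == pytest.approx(row["rmse_c"])
        assert np.isnan(row["rmse_out_c"])
        assert row["mask_in_pix"] == row["cloud_n"]

    def test_removed_records_fit_worse(self):
        """Residual-magnitude partition: RMSE-out >= RMSE-in at a = b = 0.5."""
        from thermospec import SceneConfig, make_scene
        wins = 0
        for seed in range(10):
            cube, tir, _ = make_scene(SceneConfig(shape=(48, 48), seed=100 + seed))
            index = ndblue_map(cube)
            row = day_report(cube, tir, index, day=1, thr=0.3, a=0.5, b=0.5)
            if row["mask_in_pix"] < row["cloud_n"]:
                wins += int(row["rmse_out_c"] >= row["rmse_in_c"])
            else:
                wins += 1          # nothing removed: vacuously consistent
        assert wins == 10

    def test_fixed_channel_respected(self, default_scene):
        cube, tir, _ = default_scene
        index = ndblue_map(cube)
        row = day_report(cube, tir, index, day=1, thr=0.3, a=1.0, b=1.0, channel=100)
        assert row["best_channel"] == 100
        assert row["wavelength_nm"] == pytest.approx(cube.wavelength_of(100))
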