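"""Masking calibration, normalization, RMSE, baselines, congeniality."""

import numpy as np
import pandas as pd
import pytest

from tsignn import (LabelRule, SyntheticSpec, apply_mcar_mask,
                    baseline_impute, congeniality_eval, denormalize,
                    generate_regular, normalize, rmse_masked, run_experiment)

from conftest import series_from


class TestMcarMask:
    def test_rate_bounds(self, small_series):
        for bad in (0.0, 1.0, -0.1, 1.5):
            with pytest.raises(ValueError):
                apply_mcar_mask(small_series, bad, seed=0)

    def test_vanishing_rate_masks_nothing(self):
        s = series_from(np.random.default_rng(0).random((10, 2)))
        _, mask = apply_mcar_mask(s, 1e-12, seed=0)
        assert mask.n_masked == 0

    def test_realized_fraction_within_binomial_bound(self):
        s = series_from(np.random.default_rng(1).random((1000, 6)))
        rate = 0.3
        sigma = np.sqrt(rate * (1 - rate) / 6000)
        _, mask = apply_mcar_mask(s, rate, seed=17)
        assert abs(mask.n_masked / 6000 - rate) <= 3 * sigma

    def test_determinism_and_seed_sensitivity(self):
        s = series_from(np.random.default_rng(2).random((1000, 6)))
        _, m1 = apply_mcar_mask(s, 0.3, seed=5)
        _, m2 = apply_mcar_mask(s, 0.3, seed=5)
        _, m3 = apply_mcar_mask(s, 0.3, seed=6)
        np.testing.assert_array_equal(m1.mask, m2.mask)
        assert (m1.mask != m3.mask).sum() >= 1

    def test_label_column_protected(self, small_series):
        masked, mask = apply_mcar_mask(small_series, 0.5, seed=3,
                                       label_protected=True, label_name="x0")
        assert not mask.mask[:, 0].any()
        assert not np.isnan(masked.values[:, 0]).any()

    def test_only_observed_cells_maskable(self):
        vals = np.random.default_rng(3).random((50, 2))
        vals[0, 0] = np.nan
        s = series_from(vals)
        _, mask = apply_mcar_mask(s, 0.9, seed=0)
        assert not mask.mask[0, 0]


class TestNormalize:
    def test_midpoint_scales_to_half(self):
        s = series_from(np.array([[0.0], [10.0], [5.0]]))
        scaled, _ = normalize(s)
        np.testing.assert_allclose(scaled.values[:, 0], [0.0, 1.0, 0.5])

    def test_unit_interval_feature_unchanged(self):
        vals = np.array([[0.0], [1.0], [0.25]])
        scaled, _ = normalize(series_from(vals))
        np.testing.assert_allclose(scaled.values, vals)

    def test_round_trip_inverse(self, rng):
        vals = rng.normal(5, 3, size=(30, 4))
        vals[rng.random((30, 4)) < 0.2] = np.nan
        s = series_from(vals)
        scaled, stats = normalize(s)
        back = denormalize(scaled, stats)
        obs = ~np.isnan(vals)
        np.testing.assert_allclose(back.values[obs], vals[obs], atol=1e-12)

    def test_constant_feature_scales_to_zero_with_warning(self):
        s = series_from(np.full((5, 1), 3.3))
        with pytest.warns(UserWarning, match="constant"):
            scaled, _ = normalize(s)
        np.testing.assert_array_equal(scaled.values, 0.0)

    def test_zscore_option(self, rng):
        vals = rng.normal(5, 3, size=(200, 2))
        scaled, stats = normalize(series_from(vals), method="zscore")
        np.testing.assert_allclose(scaled.values.mean(axis=0), 0.0, atol=1e-9)
        np.testing.assert_allclose(scaled.values.std(axis=0), 1.0, atol=1e-9)
        back = denormalize(scaled, stats)
        np.testing.assert_allclose(back.values, vals, atol=1e-10)

    def test_stats_reusable_on_held_out_data(self, rng):
        train = series_from(rng.random((20, 2)) * 4)
        test = series_from(rng.random((10, 2)) * 4)
        _, stats = normalize(train)
        scaled_test, _ = normalize(test, stats)
        np.testing.assert_allclose(
            scaled_test.values, (test.values - stats.minimum) / stats.span)


class TestRmse:
    def test_perfect_imputation_is_zero(self, masked_scaled):
        _, truth, mask = masked_scaled
        assert rmse_masked(truth, truth, mask) == 0.0

    def test_hand_arithmetic(self):
        truth = series_from(np.array([[1.0], [3.0]]))
        imputed = series_from(np.array([[2.0], [2.0]]))
        mask_obj = apply_mcar_mask(truth, 0.5, seed=0)[1]
        mask_obj.mask = np.array([[True], [True]])
        assert rmse_masked(imputed, truth, mask_obj) == pytest.approx(1.0)

    def test_matches_naive_loop(self, rng):
        truth = series_from(rng.random((50, 4)))
        imputed = series_from(rng.random((50, 4)))
        _, mask = apply_mcar_mask(truth, 0.4, seed=9)
        total, count = 0.0, 0
        for t in range(50):
            for j in range(4):
                if mask.mask[t, j]:
                    total += (imputed.values[t, j] - truth.values[t, j]) ** 2
                    count += 1
        assert rmse_masked(imputed, truth, mask) == pytest.approx(
            np.sqrt(total / count), abs=1e-12)

    def test_empty_mask_rejected(self, masked_scaled):
        _, truth, mask = masked_scaled
        empty = type(mask)(np.zeros_like(mask.mask), 0.3, 0, True)
        with pytest.raises(ValueError):
            rmse_masked(truth, truth, empty)


class TestCongeniality:
    def test_perfect_imputation_zero_gap(self):
        spec = SyntheticSpec(n_timesteps=120, n_features=4, n_factors=2,
                             label_rule=LabelRule("linear", noise_sd=0.2),
                             seed=5)
        s = generate_regular(spec)
        r2_orig, r2_imp = congeniality_eval(s, s, "label", seed=0)
        assert r2_orig == r2_imp  # identical data, identical split and fits

    def test_noiseless_linear_label_gives_unit_r2(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=(100, 3))
        label = x @ np.array([1.0, -1.0, 0.0])
        s = series_from(np.column_stack([x, label]),
                        names=["x0", "x1", "x2", "label"])
        (_, r2_linear), _ = congeniality_eval(s, s, "label", seed=0)
        assert r2_linear == pytest.approx(1.0, abs=1e-9)

    def test_linear_r2_matches_population_value(self):
        # label = sum of features + noise; with identity loading and phi = 0
        # the population R^2 is var(signal) / (var(signal) + noise^2)
        f, label_noise = 3, 1.0
        spec = SyntheticSpec(n_timesteps=4000, n_features=f, n_factors=f,
                             ar_coefficient=0.0, loading="identity",
                             noise_sd=0.05,
                             label_rule=LabelRule("linear",
                                                  noise_sd=label_noise),
                             seed=21)
        s = generate_regular(spec)
        var_signal = f * (1.0 + 0.05 ** 2)
        expected = var_signal / (var_signal + label_noise ** 2)
        (_, r2_linear), _ = congeniality_eval(s, s, "label", seed=0)
        assert r2_linear == pytest.approx(expected, abs=0.05)

    def test_degenerate_label_rejected(self):
        vals = np.column_stack([np.random.default_rng(0).random(20),
                                np.ones(20)])
        s = series_from(vals, names=["x0", "label"])
        with pytest.raises(ValueError, match="degenerate"):
            congeniality_eval(s, s, "label", seed=0)


class TestBaselines:
    def test_mean_fill(self):
        s = series_from(np.array([[2.0], [np.nan], [4.0]]))
        out = baseline_impute(s, "mean")
        assert out.values[1, 0] == pytest.approx(3.0)

    def test_linear_interpolation_midpoint(self):
        s = series_from(np.array([[0.0], [np.nan], [1.0]]))
        out = baseline_impute(s, "linear_interp")
        assert out.values[1, 0] == pytest.approx(0.5)

    def test_boundary_fill_by_nearest(self):
        s = series_from(np.array([[np.nan], [2.0], [3.0], [np.nan]]))
        out = baseline_impute(s, "linear_interp")
        assert out.values[0, 0] == pytest.approx(2.0)
        assert out.values[3, 0] == pytest.approx(3.0)

    def test_knn_matches_hand_weighted_average(self):
        # rows 0 and 2 are the complete neighbors of row 4's missing cell
        vals = np.array([[0.0, 0.0, 1.0],
                         [5.0, 5.0, 9.0],
                         [1.0, 1.0, 3.0],
                         [6.0, 5.5, 8.0],
                         [0.5, 0.5, np.nan]])
        out = baseline_impute(series_from(vals), "knn", knn_neighbors=2)
        d0 = np.sqrt(2 * 0.5 ** 2)
        d2 = np.sqrt(2 * 0.5 ** 2)
        expected = (1.0 / d0 + 3.0 / d2) / (1 / d0 + 1 / d2)
        assert out.values[4, 2] == pytest.approx(expected)

    @pytest.mark.parametrize("method", ["spline_interp", "cubic_interp"])
    def test_smooth_interpolators_recover_smooth_signal(self, method):
        t = np.linspace(0, 4 * np.pi, 200)
        vals = np.sin(t)[:, None].copy()
        holes = np.random.default_rng(4).random(200) < 0.3
        masked = vals.copy()
        masked[holes] = np.nan
        out = baseline_impute(series_from(masked), method)
        assert np.abs(out.values[holes, 0] - vals[holes, 0]).max() < 0.1

    def test_unknown_method_rejected(self, small_series):
        with pytest.raises(ValueError, match="unknown method"):
            baseline_impute(small_series, "oracle")

    def test_all_missing_feature_rejected(self):
        s = series_from(np.array([[np.nan], [np.nan]]))
        with pytest.raises(ValueError, match="zero observed"):
            baseline_impute(s, "mean")

    def test_mean_rmse_approaches_population_sd(self):
        # closed-form cross-check: on standardized data the mean baseline's
        # masked-cell RMSE converges to the feature standard deviation
        rng = np.random.default_rng(8)
        vals = rng.normal(size=(3000, 3))
        vals = (vals - vals.mean(0)) / vals.std(0)
        s = series_from(vals)
        rmses = []
        for seed in range(5):
            masked, mask = apply_mcar_mask(s, 0.3, seed=seed)
            rmses.append(rmse_masked(baseline_impute(masked, "mean"), s, mask))
        assert np.median(rmses) == pytest.approx(1.0, abs=0.05)


class TestRunExperiment:
    def test_grid_shape_and_rmse_positive(self, small_series):
        table = run_experiment(small_series, ["mean", "linear_interp"],
                               rates=(0.3, 0.6), seeds=(0,), label="label")
        assert len(table) == 4
        assert (table["rmse"] > 0).all()
        assert set(table.columns) >= {"method", "rate", "seed", "rmse",
                                      "r2_gbr_orig", "r2_lr_imp"}

    def test_higher_rate_does_not_reduce_mean_error(self, small_series):
        rows = []
        for seed in range(5):
            t = run_experiment(small_series, ["mean"], rates=(0.3, 0.6),
                               seeds=(seed,))
            rows.append(t.set_index("rate")["rmse"])
        med = pd.concat(rows, axis=1).median(axis=1)
        assert med[0.6] >= med[0.3]

    def test_failures_recorded_not_raised(self):
        tiny = series_from(np.random.default_rng(0).random((6, 2)))

        def boom(series, seed):
            raise RuntimeError("synthetic failure")

        table = run_experiment(tiny, ["mean", "tsignn"], rates=(0.3,),
                               seeds=(0,), imputers={"tsignn": boom})
        assert len(table) == 2
        failed = table[table["method"] == "tsignn"]
        assert failed["error"].str.contains("synthetic failure").all()
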