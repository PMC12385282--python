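"""Split protocol, GPR/PLSR/SVR fitting, metrics, LOD, improvement arithmetic."""

import numpy as np
import pytest

from pestmap.quantification import (
    ConfigError,
    SpectralDataset,
    compute_metrics,
    double_cross_validation,
    gpr_fit,
    gpr_predict,
    label_summary,
    limit_of_detection,
    lod_from_calibration,
    plsr_factory,
    plsr_fit,
    relative_improvement,
    split_calibration_test,
    svr_fit,
)
from pestmap.synthetic import make_concentration_series


def linear_dataset(n_groups=12, rows_per_group=2, d=8, noise=0.0, seed=0,
                   n_levels=4):
    """y is an exact linear function of one latent feature.

    Groups cycle through ``n_levels`` concentration levels so each level
    holds several whole groups (as the stratified split requires).
    """
    rng = np.random.default_rng(seed)
    n = n_groups * rows_per_group
    levels = np.linspace(0.0, 0.06, n_levels)
    y = np.repeat(levels[np.arange(n_groups) % n_levels], rows_per_group)
    direction = rng.uniform(0.2, 1.0, d)
    X = 0.4 + np.outer(y, direction) + noise * rng.standard_normal((n, d))
    groups = np.repeat(np.arange(n_groups), rows_per_group)
    wl = 1000.0 + 10.0 * np.arange(d)
    return SpectralDataset(X, y, wl, groups)


class TestSplit:
    def test_counts_84_36_on_study_design(self):
        ds = make_concentration_series(seed=3)
        cal, test = split_calibration_test(ds, 0.70, seed=3)
        assert (len(cal), len(test)) == (84, 36)

    def test_label_means_balanced_at_0p030(self):
        ds = make_concentration_series(seed=5)
        cal, test = split_calibration_test(ds, 0.70, seed=5)
        assert label_summary(ds)["mean"] == pytest.approx(0.030, abs=1e-12)
        assert label_summary(cal)["mean"] == pytest.approx(0.030, abs=1e-12)
        assert label_summary(test)["mean"] == pytest.approx(0.030, abs=1e-12)

    def test_same_seed_reproduces_split(self):
        ds = make_concentration_series(seed=1)
        a = split_calibration_test(ds, 0.70, seed=9)
        b = split_calibration_test(ds, 0.70, seed=9)
        assert np.array_equal(a[0].X, b[0].X)
        assert np.array_equal(a[1].y, b[1].y)

    def test_groups_never_straddle_the_split(self):
        ds = make_concentration_series(seed=2)
        cal, test = split_calibration_test(ds, 0.70, seed=2)
        assert set(cal.groups.tolist()).isdisjoint(test.groups.tolist())

    def test_bad_fraction_rejected(self):
        ds = linear_dataset()
        with pytest.raises(ConfigError):
            split_calibration_test(ds, 1.5)


class TestMetrics:
    def test_perfect_prediction(self):
        y = np.array([0.0, 0.02, 0.04, 0.06])
        r2, rmse = compute_metrics(y, y)
        assert r2 == pytest.approx(1.0) and rmse == pytest.approx(0.0)

    def test_mean_prediction_gives_zero_r2(self):
        y = np.array([0.0, 0.02, 0.04, 0.06])
        r2, _ = compute_metrics(y, np.full(4, y.mean()))
        assert r2 == pytest.approx(0.0)

    def test_constant_offset_hand_arithmetic(self):
        y = np.array([0.0, 0.02, 0.04, 0.06])
        r2, rmse = compute_metrics(y, y + 0.001)
        assert rmse == pytest.approx(0.001)
        assert r2 == pytest.approx(0.998, abs=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            compute_metrics(np.ones(4), np.ones(4))


class TestLod:
    def test_zero_residual_sd(self):
        assert limit_of_detection(0.0, 2.0) == 0.0

    @pytest.mark.parametrize("rho,slope,expected", [
        (0.001, 1.0, 0.0033),
        (1.0, 3.3, 1.0),
    ])
    def test_direct_values(self, rho, slope, expected):
        assert limit_of_detection(rho, slope) == pytest.approx(expected)

    def test_linear_in_rho_and_inverse_in_slope(self, rng):
        rho, slope = rng.uniform(0.001, 1), rng.uniform(0.5, 3)
        base = limit_of_detection(rho, slope)
        assert limit_of_detection(3 * rho, slope) == pytest.approx(3 * base)
        assert limit_of_detection(rho, 2 * slope) == pytest.approx(base / 2)

    def test_zero_slope_rejected(self):
        with pytest.raises(ValueError):
            limit_of_detection(0.1, 0.0)

    def test_perfect_calibration_has_zero_lod(self):
        y = np.linspace(0, 0.06, 10)
        assert lod_from_calibration(y, y) == pytest.approx(0.0, abs=1e-12)


class TestImprovement:
    def test_printed_table_arithmetic(self):
        # RMSEV 0.0037 -> 0.0012 and R2v 0.97 -> 0.99
        assert relative_improvement(0.0037, 0.0012, "lower-better") == \
            pytest.approx(67.57, abs=0.005)
        assert relative_improvement(0.97, 0.99, "higher-better") == \
            pytest.approx(2.06, abs=0.005)

    def test_equal_metrics_no_improvement(self):
        assert relative_improvement(0.5, 0.5, "lower-better") == 0.0

    def test_zero_reference_rejected(self):
        with pytest.raises(ValueError):
            relative_improvement(0.0, 0.1)


class TestGpr:
    def test_interpolates_noiseless_linear_data(self):
        ds = linear_dataset(n_groups=10, d=1)
        model = gpr_fit(ds, kernel_menu=("se",), inner_folds=5, n_restarts=2)
        pred = model.predict(ds.X)
        assert np.allclose(pred, ds.y, atol=1e-6)

    def test_constant_target_predicts_constant(self):
        ds = linear_dataset(n_groups=10, d=3)
        ds = SpectralDataset(ds.X, np.full(len(ds), 0.03), ds.wavelengths, ds.groups)
        model = gpr_fit(ds, kernel_menu=("se",), inner_folds=5, n_restarts=1)
        assert np.allclose(model.predict(ds.X), 0.03, atol=1e-8)

    def test_predictions_deterministic_and_variance_nonneg(self):
        ds = linear_dataset(n_groups=10, d=4, noise=0.002, seed=3)
        model = gpr_fit(ds, kernel_menu=("se", "matern52"), inner_folds=5,
                        n_restarts=1, seed=0)
        q = ds.X[:5]
        m1, s1 = gpr_predict(model, q)
        m2, s2 = gpr_predict(model, q)
        assert np.array_equal(m1, m2) and np.array_equal(s1, s2)
        assert np.all(s1 >= 0)

    def test_far_query_reverts_to_prior_mean(self):
        ds = linear_dataset(n_groups=10, d=2)
        model = gpr_fit(ds, kernel_menu=("se",), inner_folds=5, n_restarts=1)
        far = np.full((1, 2), 1e4)
        mean, _ = gpr_predict(model, far)
        assert mean[0] == pytest.approx(ds.y.mean(), abs=0.01)

    def test_wavelength_mismatch_rejected(self):
        ds = linear_dataset(n_groups=10, d=4)
        model = gpr_fit(ds, kernel_menu=("se",), inner_folds=5, n_restarts=1)
        with pytest.raises(ValueError):
            gpr_predict(model, np.ones((2, 7)))


class TestBaselines:
    def test_plsr_rank_one_exact(self):
        ds = linear_dataset(n_groups=10, d=6)
        model = plsr_fit(ds, max_components=5, inner_folds=5)
        r2, rmse = compute_metrics(ds.y, model.predict(ds.X))
        assert r2 == pytest.approx(1.0, abs=1e-9)
        assert model.chosen_params["n_components"] == 1

    def test_svr_near_zero_error_on_noiseless_linear(self):
        ds = linear_dataset(n_groups=10, d=4)
        model = svr_fit(ds, grid={"C": [10.0, 100.0], "gamma": [0.1, 1.0],
                                  "epsilon": [1e-4]}, inner_folds=5)
        _, rmse = compute_metrics(ds.y, model.predict(ds.X))
        assert rmse < 0.002

    def test_plsr_on_synthetic_series_generalizes(self):
        ds = make_concentration_series(seed=11, leaf_effect_sd=0.0)
        rep = double_cross_validation(ds, plsr_factory(), seed=11)
        assert rep.r2_val >= 0.9


class TestDoubleCv:
    def test_noiseless_linear_is_perfect(self):
        ds = linear_dataset(n_groups=12, d=5)
        rep = double_cross_validation(ds, plsr_factory(), seed=0)
        assert rep.r2_val == pytest.approx(1.0, abs=1e-9)
        assert rep.rmse_val == pytest.approx(0.0, abs=1e-9)

    def test_reproducible_with_fixed_seed(self):
        ds = make_concentration_series(seed=4, leaf_effect_sd=0.0)
        a = double_cross_validation(ds, plsr_factory(), seed=2)
        b = double_cross_validation(ds, plsr_factory(), seed=2)
        assert a.r2_val == b.r2_val and a.rmse_val == b.rmse_val

    def test_shuffled_labels_have_no_skill(self, rng):
        ds = make_concentration_series(seed=6, leaf_effect_sd=0.0)
        r2s = []
        for rep in range(20):
            # permute labels at the leaf level to preserve group structure
            leaves = np.unique(ds.groups)
            leaf_y = {g: ds.y[ds.groups == g][0] for g in leaves}
            shuffled = rng.permutation([leaf_y[g] for g in leaves])
            y_perm = np.array([shuffled[np.where(leaves == g)[0][0]]
                               for g in ds.groups])
            ds_perm = SpectralDataset(ds.X, y_perm, ds.wavelengths, ds.groups)
            r2s.append(double_cross_validation(ds_perm, plsr_factory(),
                                               seed=rep).r2_val)
        assert np.mean(r2s) < 0.3

    def test_metrics_invariant_to_test_row_order(self):
        y_true = np.array([0.0, 0.02, 0.04, 0.06, 0.02])
        y_pred = y_true + np.array([0.001, -0.002, 0.0, 0.003, -0.001])
        perm = np.array([3, 0, 4, 1, 2])
        r2_a, rmse_a = compute_metrics(y_true, y_pred)
        r2_b, rmse_b = compute_metrics(y_true[perm], y_pred[perm])
        assert r2_a == pytest.approx(r2_b, abs=1e-12)
        assert rmse_a == pytest.approx(rmse_b, abs=1e-15)


def test_dataset_csv_round_trip(tmp_path):
    ds = make_concentration_series(seed=8, leaves_per_level=3)
    path = tmp_path / "series.csv"
    ds.to_csv(path)
    back = SpectralDataset.from_csv(path)
    assert np.allclose(back.X, ds.X)
    assert np.array_equal(back.y, ds.y)
    assert np.array_equal(back.groups, ds.groups)
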