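"""SIMPLISMA selection, MCR-ALS factorisation, diagnostics, ROI selection."""

import numpy as np
import pytest
import scipy.optimize

from pestmap._nnls import nnls_multi_rhs
from pestmap.hypercube import EmptySelectionError, Hypercube, RoiMask, unfold
from pestmap.unmixing import (
    ConfigError,
    DegenerateDataError,
    MCRConfig,
    component_proportions,
    explained_variance,
    extract_mean_spectra,
    fit_mcr_als,
    lack_of_fit,
    match_components,
    select_residue_regions,
    simplisma_init,
)


def best_cosine_match(S, truth):
    """Max cosine similarity of each true spectrum to any resolved one."""
    sims = np.zeros((truth.shape[0], S.shape[0]))
    for i, t in enumerate(truth):
        for j, s in enumerate(S):
            sims[i, j] = t @ s / (np.linalg.norm(t) * np.linalg.norm(s))
    return sims.max(axis=1)


class TestNnlsCore:
    def test_matches_scipy_per_column(self, rng):
        for _ in range(20):
            A = rng.standard_normal((8, 3))
            B = rng.standard_normal((8, 5))
            X = nnls_multi_rhs(A, B)
            assert X.min() >= 0
            for j in range(5):
                ref = scipy.optimize.nnls(A, B[:, j])[0]
                r_ours = np.linalg.norm(A @ X[:, j] - B[:, j])
                r_ref = np.linalg.norm(A @ ref - B[:, j])
                assert r_ours <= r_ref + 1e-9


class TestDiagnostics:
    def test_perfect_model_zero_lof_full_r2(self, rng):
        D = rng.uniform(0, 1, (6, 4))
        assert lack_of_fit(D, D) == pytest.approx(0.0)
        assert explained_variance(D, D) == pytest.approx(100.0)

    def test_zero_model_is_total_lack_of_fit(self, rng):
        D = rng.uniform(0.1, 1, (6, 4))
        assert lack_of_fit(D, np.zeros_like(D)) == pytest.approx(100.0)
        assert explained_variance(D, np.zeros_like(D)) == pytest.approx(0.0)

    def test_hand_evaluated_ten_percent(self):
        D = np.ones((2, 2))
        model = np.full((2, 2), 0.9)  # residuals all 0.1
        assert lack_of_fit(D, model) == pytest.approx(10.0)
        assert explained_variance(D, model) == pytest.approx(99.0)

    def test_lof_r2_identity(self, rng):
        D = rng.uniform(0, 1, (10, 7))
        model = D + 0.03 * rng.standard_normal(D.shape)
        lof = lack_of_fit(D, model)
        r2 = explained_variance(D, model)
        assert r2 == pytest.approx(100.0 * (1 - (lof / 100.0) ** 2), abs=1e-9)

    def test_all_zero_data_rejected(self):
        with pytest.raises(DegenerateDataError):
            lack_of_fit(np.zeros((2, 2)), np.zeros((2, 2)))


class TestSimplisma:
    def test_k1_matches_exhaustive_purity_maximum(self, rng):
        D = rng.uniform(0, 1, (15, 9))
        offset = 3.0
        _, sel = simplisma_init(D, 1, offset, return_indices=True)
        mu, sigma = D.mean(axis=0), D.std(axis=0)
        delta = offset / 100.0 * mu.max()
        assert sel[0] == int(np.argmax(sigma / (mu + delta)))

    def test_constant_column_never_selected_first(self, rng):
        D = rng.uniform(0, 1, (15, 6))
        D[:, 2] = 0.7  # zero variance -> zero purity
        _, sel = simplisma_init(D, 1, return_indices=True)
        assert sel[0] != 2

    def test_recovers_two_components_from_pure_pixels(self, rng):
        # 6x8 matrix: component 0 dominates bands 0-3, component 1 bands 4-7
        S = np.array([
            [1.0, 0.9, 0.8, 0.7, 0.05, 0.02, 0.01, 0.0],
            [0.0, 0.02, 0.05, 0.1, 0.7, 0.8, 0.9, 1.0],
        ])
        C = np.array([[1.0, 0.0], [0.0, 1.0], [0.5, 0.5],
                      [0.8, 0.2], [0.3, 0.7], [0.6, 0.4]])
        D = C @ S
        S0, sel = simplisma_init(D, 2, return_indices=True)
        # selected pure bands must be dominated by different components
        dominance = S[0] / (S[0] + S[1] + 1e-12)
        shares = sorted([dominance[sel[0]], dominance[sel[1]]])
        assert shares[0] < 0.1 and shares[1] > 0.9
        assert np.all(best_cosine_match(S0, S) >= 0.99)

    def test_k_exceeding_bands_rejected(self, rng):
        with pytest.raises(ConfigError):
            simplisma_init(rng.uniform(0, 1, (5, 3)), 4)

    def test_constant_matrix_rejected(self):
        with pytest.raises(DegenerateDataError):
            simplisma_init(np.full((5, 4), 0.3), 2)


class TestMcrAls:
    def test_noiseless_exact_recovery_with_pure_features(self, rng):
        # random non-negative factors with pure pixels and pure bands
        k, npix, nb = 2, 20, 12
        S = rng.uniform(0.1, 1.0, (k, nb))
        S[0, 3], S[1, 3] = 1.0, 0.0
        S[1, 9], S[0, 9] = 1.0, 0.0
        C = rng.uniform(0, 1, (npix, k))
        C[0], C[1] = [1.0, 0.0], [0.0, 1.0]
        D = C @ S
        res = fit_mcr_als(D, MCRConfig(tol=1e-8, max_iter=500))
        assert res.lof_percent < 1e-6
        assert np.all(best_cosine_match(res.S, S) >= 0.999)
        assert res.C.min() >= 0 and res.S.min() >= 0

    def test_true_spectra_init_is_fixed_point(self, noiseless_scene):
        dm = noiseless_scene.truth.values.reshape(-1, len(noiseless_scene.wavelengths))
        res = fit_mcr_als(
            dm, MCRConfig(init="reference"), reference_spectra=noiseless_scene.S
        )
        assert res.converged
        assert res.n_iter <= 2
        assert res.lof_percent < 1e-6

    def test_one_percent_noise_lof_near_one_percent(self, noisy_scene):
        dm = noisy_scene.truth.values.reshape(-1, len(noisy_scene.wavelengths))
        res = fit_mcr_als(dm, MCRConfig())
        assert res.lof_percent < 1.78
        assert res.r2_percent >= 99.0

    def test_lof_trace_monotone_nonincreasing(self, rng):
        D = np.abs(rng.standard_normal((40, 15))) + \
            rng.uniform(0, 1, (40, 1)) * rng.uniform(0, 1, (1, 15))
        res = fit_mcr_als(D, MCRConfig(tol=1e-7, max_iter=200))
        trace = np.array(res.lof_trace)
        assert np.all(np.diff(trace) <= 1e-9)

    def test_extra_components_do_not_improve_lof(self, noisy_scene):
        # the model-order signal: beyond the true rank the fit stalls
        dm = noisy_scene.truth.values.reshape(-1, len(noisy_scene.wavelengths))
        lof2 = fit_mcr_als(dm, MCRConfig(n_components=2)).lof_percent
        lof3 = fit_mcr_als(dm, MCRConfig(n_components=3)).lof_percent
        assert lof3 <= lof2 + 1e-6
        assert lof2 - lof3 < 0.1  # no meaningful gain from a third component

    def test_spectra_normalized_to_unit_maximum(self, noisy_scene):
        dm = noisy_scene.truth.values.reshape(-1, len(noisy_scene.wavelengths))
        res = fit_mcr_als(dm, MCRConfig())
        assert np.allclose(res.S.max(axis=1), 1.0)

    def test_r2_lof_identity_on_fit(self, noisy_scene):
        dm = noisy_scene.truth.values.reshape(-1, len(noisy_scene.wavelengths))
        res = fit_mcr_als(dm, MCRConfig())
        assert res.r2_percent == pytest.approx(
            100.0 * (1 - (res.lof_percent / 100.0) ** 2), abs=1e-9)

    def test_reference_init_requires_spectra(self, rng):
        with pytest.raises(ConfigError):
            fit_mcr_als(rng.uniform(0, 1, (5, 4)), MCRConfig(init="reference"))

    def test_non_finite_data_rejected(self):
        D = np.ones((3, 3))
        D[0, 0] = np.inf
        with pytest.raises(DegenerateDataError):
            fit_mcr_als(D, MCRConfig())


class TestProportions:
    def test_equal_columns_split_evenly(self):
        C = np.tile([[0.3], [0.5]], (1, 2))
        assert np.allclose(component_proportions(C), [50.0, 50.0])

    def test_three_to_one_ratio(self):
        C = np.array([[3.0, 1.0], [3.0, 1.0]])
        assert np.allclose(component_proportions(C), [75.0, 25.0])

    def test_single_component_is_everything(self):
        assert component_proportions(np.ones((4, 1))) == pytest.approx([100.0])

    def test_sums_to_hundred(self, rng):
        C = rng.uniform(0, 1, (30, 4))
        assert component_proportions(C).sum() == pytest.approx(100.0, abs=1e-9)

    def test_all_zero_rejected(self):
        with pytest.raises(DegenerateDataError):
            component_proportions(np.zeros((3, 2)))


class TestResidueRegions:
    def test_top_fraction_selects_largest(self):
        amap = np.arange(10, dtype=float).reshape(2, 5)
        roi = select_residue_regions(amap, 0.2)
        assert roi.n_pixels == 2
        assert roi.mask[1, 4] and roi.mask[1, 3]

    def test_fraction_one_selects_all(self):
        roi = select_residue_regions(np.ones((3, 3)), 1.0)
        assert roi.n_pixels == 9

    def test_ties_broken_in_scan_order(self):
        roi = select_residue_regions(np.ones((2, 2)), 0.5)
        assert np.array_equal(roi.mask, [[True, True], [False, False]])

    def test_nan_background_excluded(self):
        amap = np.array([[np.nan, 5.0], [1.0, np.nan]])
        roi = select_residue_regions(amap, 0.5)
        assert roi.n_pixels == 1 and roi.mask[0, 1]

    def test_bad_fraction_rejected(self):
        with pytest.raises(ConfigError):
            select_residue_regions(np.ones((2, 2)), 0.0)


class TestExtraction:
    def test_single_pixel_mask_returns_its_spectrum(self, small_cube):
        mask = np.zeros(small_cube.spatial_shape, dtype=bool)
        mask[1, 2] = True
        out = extract_mean_spectra(small_cube, [RoiMask(mask)])
        assert np.allclose(out[0], small_cube.values[1, 2])

    def test_two_pixel_mask_averages(self, small_cube):
        mask = np.zeros(small_cube.spatial_shape, dtype=bool)
        mask[0, 0] = mask[3, 4] = True
        out = extract_mean_spectra(small_cube, [RoiMask(mask)])
        expected = (small_cube.values[0, 0] + small_cube.values[3, 4]) / 2
        assert np.allclose(out[0], expected)

    def test_data_matrix_source_agrees_with_cube(self, small_cube):
        mask = np.zeros(small_cube.spatial_shape, dtype=bool)
        mask[0, 1] = mask[2, 2] = mask[3, 0] = True
        dm = unfold(small_cube)
        a = extract_mean_spectra(small_cube, [RoiMask(mask)])
        b = extract_mean_spectra(dm, [RoiMask(mask)])
        assert np.allclose(a, b)

    def test_no_masks_rejected(self, small_cube):
        with pytest.raises(EmptySelectionError):
            extract_mean_spectra(small_cube, [])


def test_match_components_pairs_by_correlation(rng):
    truth = rng.uniform(0, 1, (2, 20))
    noisy = truth[::-1] + 0.01 * rng.standard_normal((2, 20))
    perm = match_components(noisy, truth)
    assert list(perm) == [1, 0]
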