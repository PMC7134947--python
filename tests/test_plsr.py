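import numpy as np
import pytest
from plsr_oracle import loo_press_oracle, nipals_pls1_oracle

from hyperphen.plsr import (
    CVStats,
    PLSRModel,
    _loo_predictions,
    _nipals,
    fit_plsr,
    predict,
    resample_validate,
    rmse_percent,
    vip_scores,
)
from hyperphen.simulate import TraitCoupling, simulate_trait_dataset


@pytest.fixture
def small_xy(rng):
    X = rng.normal(size=(10, 5))
    y = rng.normal(size=10) + X[:, 0]
    return X, y


class TestNipalsOracle:
    def test_matches_textbook_oracle(self, small_xy):
        """W, P and composed coefficients agree with an independently
        coded textbook NIPALS to 1e-8 (n=10, p=5, 2 LVs)."""
        X, y = small_xy
        Wo, Po, qo, Bo = nipals_pls1_oracle(X, y, 2)
        W, P, q, _, _ = _nipals(X - X.mean(0), y - y.mean(), 2)
        from hyperphen.plsr import _compose_coefficients

        B = _compose_coefficients(W, P, q)
        np.testing.assert_allclose(W, Wo, atol=1e-8)
        np.testing.assert_allclose(P, Po, atol=1e-8)
        np.testing.assert_allclose(B, Bo, atol=1e-8)

    def test_matches_sklearn(self, small_xy):
        """Cross-check against scikit-learn's PLS (centered, unscaled)."""
        X, y = small_xy
        from sklearn.cross_decomposition import PLSRegression

        sk = PLSRegression(n_components=3, scale=False).fit(X, y[:, None])
        W, P, q, _, _ = _nipals(X - X.mean(0), y - y.mean(), 3)
        from hyperphen.plsr import _compose_coefficients

        np.testing.assert_allclose(_compose_coefficients(W, P, q),
                                   sk.coef_.ravel(), atol=1e-8)

    def test_loo_press_matches_fold_by_fold_oracle(self, small_xy):
        """The vectorized kernel-form LOO equals refitting every fold
        from scratch with the textbook oracle."""
        X, y = small_xy
        np.testing.assert_allclose(
            np.sqrt(np.mean((_loo_predictions(X, y, 3) - y[:, None]) ** 2,
                            axis=0)),
            loo_press_oracle(X, y, 3),
            atol=1e-8,
        )


class TestFitPlsr:
    def test_exact_rank_one_structure(self, rng):
        """y proportional to a single spectral component: PRESS selects
        one LV and LOO predictions reproduce y."""
        t = rng.normal(size=40)
        X = np.outer(t, rng.normal(size=12))
        y = 3.0 * t + 1.0
        m = fit_plsr(X, y)
        assert m.n_lv == 1
        assert m.press_curve[0] < 1e-8
        np.testing.assert_allclose(predict(m, X), y, atol=1e-8)

    def test_selected_lv_minimizes_press(self, rng):
        X = rng.normal(size=(30, 12))
        y = X[:, :3] @ [1.0, -2.0, 0.5] + 0.1 * rng.normal(size=30)
        m = fit_plsr(X, y)
        assert np.all(m.press_curve[m.n_lv - 1] <= m.press_curve + 1e-15)

    def test_pure_noise_has_no_cv_skill(self):
        """y independent of X: cross-validated R2 stays near/below zero."""
        rng = np.random.default_rng(42)
        X = rng.normal(size=(60, 30))
        y = rng.normal(size=60)
        stats, _ = resample_validate(X, y, n_resamples=200, seed=0)
        assert stats.r2_cv <= 0.15

    def test_constant_y_rejected(self, rng):
        with pytest.raises(ValueError, match="constant"):
            fit_plsr(rng.normal(size=(10, 4)), np.full(10, 2.0))

    def test_too_few_samples_rejected(self, rng):
        with pytest.raises(ValueError, match="4"):
            fit_plsr(rng.normal(size=(3, 4)), np.arange(3.0))

    def test_column_shift_invariance(self, small_xy):
        """Adding a constant to every spectrum column is absorbed by
        the centering and leaves predictions unchanged."""
        X, y = small_xy
        m1 = fit_plsr(X, y)
        m2 = fit_plsr(X + 5.0, y)
        np.testing.assert_allclose(predict(m1, X), predict(m2, X + 5.0),
                                   atol=1e-8)

    def test_row_order_invariance(self, small_xy):
        X, y = small_xy
        perm = np.random.default_rng(1).permutation(len(y))
        m1 = fit_plsr(X, y)
        m2 = fit_plsr(X[perm], y[perm])
        np.testing.assert_allclose(m1.coefficients, m2.coefficients,
                                   atol=1e-10)
        np.testing.assert_allclose(np.sort(m1.press_curve),
                                   np.sort(m2.press_curve), atol=1e-10)


class TestPredict:
    def test_mean_spectrum_predicts_mean_trait(self, small_xy):
        X, y = small_xy
        m = fit_plsr(X, y)
        assert predict(m, m.x_mean)[0] == pytest.approx(m.y_mean)

    def test_grid_mismatch_is_error(self, small_xy):
        X, y = small_xy
        m = fit_plsr(X, y)
        with pytest.raises(ValueError, match="bands"):
            predict(m, np.ones((2, 7)))


class TestVIP:
    def test_sum_of_squares_equals_band_count(self, small_xy):
        X, y = small_xy
        m = fit_plsr(X, y)
        assert float(np.sum(m.vip**2)) == pytest.approx(m.p, abs=1e-8)

    def test_single_lv_reduction(self, rng):
        """With one LV, VIP_j = sqrt(p)*|w_j1|/||w_1||."""
        t = rng.normal(size=30)
        X = np.outer(t, rng.normal(size=8))
        m = fit_plsr(X, 2.0 * t)
        assert m.n_lv == 1
        np.testing.assert_allclose(
            m.vip, np.sqrt(m.p) * np.abs(m.weights[:, 0]), atol=1e-10
        )

    def test_high_snr_support_localization(self):
        coup = TraitCoupling.band_localized(239, [50, 120, 200],
                                            [5.0, -4.0, 6.0])
        X, y, _, _ = simulate_trait_dataset(200, coup, seed=1, target_r2=0.95)
        m = fit_plsr(X, y)
        top3 = np.argsort(-m.vip)[:3]
        assert all(min(abs(b - s) for s in (50, 120, 200)) <= 1 for b in top3)

    def test_undefined_vip_for_zero_variance_model(self, small_xy):
        X, y = small_xy
        m = fit_plsr(X, y)
        m.explained_y = np.zeros_like(m.explained_y)
        with pytest.raises(ValueError, match="VIP"):
            vip_scores(m)


class TestResampleValidate:
    def test_noiseless_linear_model_is_perfect(self, rng):
        X = rng.normal(size=(40, 6))
        y = X @ np.array([1.0, -1.0, 0.5, 0.0, 2.0, 0.3]) + 4.0
        stats, preds = resample_validate(X, y, n_resamples=150, seed=2)
        assert stats.r2_cv == pytest.approx(1.0, abs=1e-6)
        assert stats.rmse == pytest.approx(0.0, abs=1e-4)
        assert stats.bias == pytest.approx(0.0, abs=1e-5)
        np.testing.assert_allclose(preds, y, atol=1e-4)

    def test_determinism_under_seed(self, small_xy):
        X, y = small_xy
        s1, p1 = resample_validate(X, y, n_resamples=50, seed=7)
        s2, p2 = resample_validate(X, y, n_resamples=50, seed=7)
        assert s1 == s2
        np.testing.assert_array_equal(p1, p2)

    def test_holdout_too_small_rejected(self, small_xy):
        X, y = small_xy
        with pytest.raises(ValueError, match="holdout"):
            resample_validate(X, y, holdout_fraction=0.01)


class TestReportedStatistics:
    @pytest.mark.parametrize(
        "rmse,lo,hi,expected",
        [
            (38.7, 13.4, 359.3, 11.2),   # Vc,max, umol m-2 s-1
            (35.3, 54.9, 362.1, 11.5),   # J1800, umol m-2 s-1
            (0.02, 0.1, 0.3, 10.0),      # chlorophyll, mg m-2
            (0.37, 1.7, 3.7, 18.5),      # Chl a:b
            (3.33, 0.024, 0.064, 8325.0),  # phiCO2
        ],
    )
    def test_rmse_percent_is_range_normalized(self, rmse, lo, hi, expected):
        """RMSE% = 100*RMSE/(max-min) reproduces the published per-trait
        values to the printed precision."""
        assert round(rmse_percent(rmse, lo, hi), 1) == pytest.approx(expected)

    def test_rmse_percent_needs_positive_range(self):
        with pytest.raises(ValueError):
            rmse_percent(1.0, 2.0, 2.0)

    def test_cvstats_warns_when_cv_beats_train(self):
        with pytest.warns(UserWarning, match="unusual"):
            CVStats(r2_train=0.2, r2_cv=0.8, rmse=1.0, rmse_pct=5.0,
                    bias=0.0, n_lv=2)


def test_model_json_round_trip(tmp_path, small_xy):
    X, y = small_xy
    m = fit_plsr(X, y, trait_name="vcmax",
                 wavelength_grid=500.0 + np.arange(5.0))
    path = m.to_json(tmp_path / "m.json")
    back = PLSRModel.from_json(path)
    np.testing.assert_allclose(back.coefficients, m.coefficients, atol=1e-12)
    np.testing.assert_allclose(back.vip, m.vip, atol=1e-12)
    assert back.n_lv == m.n_lv and back.trait_name == "vcmax"
    np.testing.assert_allclose(predict(back, X), predict(m, X), atol=1e-12)
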