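"""Model contracts: OLS kinetics, logistic IRLS, LOOCV, AUC, bootstrap, limits, CCC."""

import warnings

import numpy as np
import pytest
from scipy.special import expit

from saucelife import imgen, models


@pytest.fixture(scope="module")
def separable_study():
    """A strongly separated (t, S, y) dataset: noiseless rule with a wide margin."""
    rng = np.random.default_rng(10)
    t = np.linspace(0, 200, 36)
    low = rng.uniform(150, 185, size=18)
    high = rng.uniform(215, 255, size=18)
    S = rng.permutation(np.concatenate([low, high]))
    y = (S >= 200).astype(int)
    return t, S, y


@pytest.fixture(scope="module")
def noisy_study():
    """A learnable but overlapping dataset for evaluation tests."""
    rng = np.random.default_rng(11)
    t = np.linspace(0, 200, 36)
    S = rng.normal(200, 25, size=36)
    y = imgen.simulate_labels((-26.0, -0.01, 0.15), t, S, seed=12)
    if np.unique(y).size < 2:  # pragma: no cover - guard, not expected
        raise RuntimeError("fixture degenerate")
    return t, S, y


class TestFitQuadratic:
    def test_exact_recovery_without_noise(self):
        t = np.linspace(0, 200, 36)
        S = 200 + 0.2 * t - 0.0005 * t**2
        fit = models.fit_quadratic(t, S)
        assert np.allclose(fit.beta, (200.0, 0.2, -0.0005), atol=1e-8)
        assert fit.r2 == pytest.approx(1.0)
        assert fit.rmse == pytest.approx(0.0, abs=1e-9)

    def test_constant_response_convention(self):
        t = np.linspace(0, 100, 12)
        fit = models.fit_quadratic(t, np.full(12, 180.0))
        assert abs(fit.beta[1]) < 1e-10 and abs(fit.beta[2]) < 1e-12
        assert fit.rmse == pytest.approx(0.0, abs=1e-9)
        assert fit.r2 == 0.0
        assert "zero_total_variance" in fit.flags

    def test_residuals_orthogonal_to_design(self):
        rng = np.random.default_rng(3)
        t = np.linspace(0, 200, 30)
        S = 150 + 0.5 * t - 0.001 * t**2 + rng.normal(0, 10, 30)
        fit = models.fit_quadratic(t, S)
        resid = S - models.predict_saturation(fit, t)
        for col in (np.ones_like(t), t, t**2):
            assert abs(resid @ col) < 1e-6 * np.abs(col).sum()

    def test_too_few_distinct_times_rejected(self):
        with pytest.raises(ValueError, match="rank-deficient"):
            models.fit_quadratic([0.0, 0.0, 1.0, 1.0], [1.0, 2.0, 3.0, 4.0])

    def test_p_beta2_detects_curvature(self):
        rng = np.random.default_rng(4)
        t = np.linspace(0, 200, 36)
        curved = 140 + 0.9 * t - 0.0018 * t**2 + rng.normal(0, 5, 36)
        straight = 140 + 0.9 * t + rng.normal(0, 5, 36)
        assert models.fit_quadratic(t, curved).p_beta2 < 0.001
        assert models.fit_quadratic(t, straight).p_beta2 > 0.01


class TestPredictSaturation:
    def test_intercept_at_time_zero(self):
        t = np.linspace(0, 100, 10)
        fit = models.fit_quadratic(t, 150 + 2 * t)
        assert models.predict_saturation(fit, 0.0) == pytest.approx(fit.beta[0])

    def test_matches_noiseless_trajectory(self):
        beta = (200.0, 0.2, -0.0005)
        t = np.array([0.0, 50.0, 100.0, 187.5])
        fit = models.PolyFit(beta=beta, r2=1.0, rmse=0.0, p_beta2=0.0,
                             se=(0, 0, 0), df_resid=1, n=4)
        assert np.allclose(
            models.predict_saturation(fit, t),
            imgen.simulate_trajectory(beta, t),
        )
        assert models.predict_saturation(fit, 100.0) == pytest.approx(215.0)


class TestLogisticFit:
    def test_two_by_two_table_closed_form(self):
        # x=0: 10 pos / 30 neg; x=1: 30 pos / 10 neg
        x = np.array([0.0] * 40 + [1.0] * 40)
        y = np.array([1] * 10 + [0] * 30 + [1] * 30 + [0] * 10)
        fit = models.logistic_fit(x, y)
        assert fit.alpha[0] == pytest.approx(np.log(1 / 3), abs=1e-6)
        assert fit.alpha[1] == pytest.approx(np.log(9), abs=1e-6)

    def test_score_equations_hold_at_convergence(self, noisy_study):
        t, S, y = noisy_study
        fit = models.fit_logistic(t, S, y)
        p = models.predict_prob(fit, t, S)
        X = np.column_stack([np.ones_like(t), t, S])
        assert np.all(np.abs(X.T @ (y - p)) < 1e-5)

    def test_matches_statsmodels(self, noisy_study):
        import statsmodels.api as sm

        t, S, y = noisy_study
        fit = models.fit_logistic(t, S, y)
        ref = sm.Logit(y, sm.add_constant(np.column_stack([t, S]))).fit(disp=0)
        assert np.allclose(fit.alpha, ref.params, rtol=1e-5, atol=1e-7)
        assert np.allclose(fit.se, ref.bse, rtol=1e-3)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            models.fit_logistic(np.arange(10.0), np.arange(10.0), np.ones(10))

    def test_separation_flagged_not_fatal(self, separable_study):
        t, S, y = separable_study
        fit = models.fit_logistic(t, S, y)
        assert fit.separation
        assert np.isfinite(fit.alpha).all()


class TestPredictProb:
    def test_half_at_zero_linear_predictor(self):
        fit = models.LogitFit(
            alpha=np.array([-30.0, -0.01, 0.15]), se=np.zeros(3), cov=np.eye(3),
            log_likelihood=0.0, converged=True, separation=False, n=0,
        )
        assert models.predict_prob(fit, 100.0, 31.0 / 0.15) == pytest.approx(0.5, abs=1e-6)
        assert models.predict_prob(fit, 100.0, 250.0) == pytest.approx(expit(6.5))

    def test_monotone_in_saturation_when_alpha2_positive(self, noisy_study):
        t, S, y = noisy_study
        fit = models.fit_logistic(t, S, y)
        assert fit.alpha[2] > 0
        grid = np.linspace(100, 255, 50)
        p = models.predict_prob(fit, np.full_like(grid, 120.0), grid)
        assert np.all(np.diff(p) > 0)


class TestLoocv:
    def test_fold_structure(self, noisy_study):
        t, S, y = noisy_study
        res = models.loocv(t, S, y)
        assert res.n_folds == 36
        assert len(res.probabilities) == 36
        assert not res.flagged_folds
        assert 0.0 <= res.accuracy <= 1.0 and 0.0 <= res.auc <= 1.0

    def test_perfectly_separable_data_scores_one(self, separable_study):
        t, S, y = separable_study
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = models.loocv(t, S, y)
        assert res.accuracy == 1.0
        assert res.auc == 1.0

    def test_no_leakage_of_held_out_label(self, noisy_study):
        t, S, y = noisy_study
        res = models.loocv(t, S, y)
        y_flip = y.copy()
        y_flip[7] = 1 - y_flip[7]
        res_flip = models.loocv(t, S, y_flip)
        assert res_flip.probabilities[7] == pytest.approx(res.probabilities[7], abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            models.loocv(np.arange(10.0), np.arange(10.0), np.zeros(10, dtype=int))


class TestRocAuc:
    def test_perfectly_ordered_scores(self):
        y = np.array([0, 0, 0, 1, 1, 1])
        assert models.roc_auc(np.arange(6.0), y) == 1.0

    def test_all_tied_scores_give_half(self):
        y = np.array([0, 1, 0, 1, 1])
        assert models.roc_auc(np.full(5, 0.5), y) == pytest.approx(0.5)

    def test_matches_trapezoid_integration(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(0)
        for _ in range(10):
            scores = rng.random(50).round(1)  # rounding forces ties
            labels = rng.integers(0, 2, 50)
            if np.unique(labels).size < 2:
                continue
            assert models.roc_auc(scores, labels) == pytest.approx(
                roc_auc_score(labels, scores), abs=1e-12
            )

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            models.roc_auc(np.arange(4.0), np.ones(4, dtype=int))


class TestBootstrapCurve:
    def test_band_ordering_and_determinism(self, noisy_study):
        t, S, y = noisy_study
        grid = np.linspace(150, 255, 21)
        c1 = models.bootstrap_curve(t, S, y, 120.0, grid, n_boot=200, seed=9)
        c2 = models.bootstrap_curve(t, S, y, 120.0, grid, n_boot=200, seed=9)
        assert (c1["lower95"] <= c1["upper95"]).all()
        assert c1.equals(c2)

    def test_larger_sample_narrows_band(self):
        grid = np.linspace(150, 255, 21)
        widths = {n: [] for n in (36, 72)}
        for seed in range(10):
            rng = np.random.default_rng(100 + seed)
            for n in (36, 72):
                t = np.linspace(0, 200, n)
                S = rng.normal(200, 25, n)
                y = imgen.simulate_labels((-26.0, -0.01, 0.15), t, S, seed=200 + seed)
                if np.unique(y).size < 2:
                    continue
                c = models.bootstrap_curve(t, S, y, 120.0, grid, n_boot=150, seed=seed)
                widths[n].append(np.median(c["upper95"] - c["lower95"]))
        assert np.median(widths[72]) < np.median(widths[36])

    def test_too_few_resamples_rejected(self, noisy_study):
        t, S, y = noisy_study
        with pytest.raises(ValueError):
            models.bootstrap_curve(t, S, y, 120.0, np.linspace(0, 255, 5), n_boot=50)


class TestAcceptabilityLimit:
    def _fit(self, alpha):
        return models.LogitFit(
            alpha=np.asarray(alpha, dtype=float), se=np.zeros(3), cov=np.eye(3),
            log_likelihood=0.0, converged=True, separation=False, n=0,
        )

    def test_closed_form_root(self):
        s_star = models.acceptability_limit(self._fit((-30.0, -0.01, 0.15)), 100.0)
        assert s_star == pytest.approx(31.0 / 0.15)

    def test_probability_half_at_limit(self, noisy_study):
        t, S, y = noisy_study
        fit = models.fit_logistic(t, S, y)
        for td in (90.0, 150.0, 180.0):
            s_star = models.acceptability_limit(fit, td)
            assert models.predict_prob(fit, td, s_star) == pytest.approx(0.5, abs=1e-10)

    def test_limit_is_affine_in_time(self, noisy_study):
        t, S, y = noisy_study
        fit = models.fit_logistic(t, S, y)
        s1, s2, s3 = (models.acceptability_limit(fit, td) for td in (50.0, 100.0, 150.0))
        assert s3 - s2 == pytest.approx(s2 - s1, abs=1e-10)
        assert (s2 - s1) / 50.0 == pytest.approx(-fit.alpha[1] / fit.alpha[2], abs=1e-12)

    def test_out_of_scale_flagged(self):
        with pytest.warns(UserWarning, match="outside"):
            models.acceptability_limit(self._fit((-100.0, 0.0, 0.15)), 0.0)

    def test_zero_slope_rejected(self):
        with pytest.raises(ValueError):
            models.acceptability_limit(self._fit((-30.0, -0.01, 0.0)), 100.0)


class TestCcc:
    def test_equal_scores_collapse_to_score(self):
        assert models.ccc([0.7, 0.7, 0.7], [0.68, 0.25, 0.25]) == pytest.approx(0.7)

    def test_single_component(self):
        assert models.ccc([0.42], [3.0]) == pytest.approx(0.42)

    def test_weighted_mean_of_reported_sub_scores(self):
        c = models.ccc([0.68, 0.882, 0.929], [0.68, 0.25, 0.25])
        expected = (0.68 * 0.68 + 0.25 * 0.882 + 0.25 * 0.929) / 1.18
        assert c == pytest.approx(expected, abs=1e-12)
        assert c == pytest.approx(0.7756, abs=5e-4)

    def test_out_of_range_sub_score_rejected(self):
        with pytest.raises(ValueError):
            models.ccc([1.2, 0.5], [1.0, 1.0])
        with pytest.raises(ValueError):
            models.ccc([0.5, 0.5], [-1.0, 1.0])

    def test_bounded_by_sub_score_range(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            c = rng.random(4)
            w = rng.random(4) + 0.01
            val = models.ccc(c, w)
            assert c.min() - 1e-12 <= val <= c.max() + 1e-12
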