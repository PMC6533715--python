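"""Validation statistics: correlations, Steiger, Welch/Games-Howell,
logistic regression and cross-validated ROC."""

import numpy as np
import pytest
from scipy import stats as sps
from scipy.special import expit

from esilung import (
    best_threshold,
    chi_squared,
    cv_roc,
    fit_logistic,
    games_howell,
    pearson_r,
    predict_proba,
    steiger_z,
    steiger_z_bootstrap,
    welch_anova,
)
from esilung.exceptions import DomainError


class TestPearson:
    def test_collinear(self):
        x = np.arange(10.0)
        assert pearson_r(x, 2 * x + 1) == pytest.approx(1.0)
        assert pearson_r(x, -x) == pytest.approx(-1.0)

    def test_bivariate_normal_simulation(self):
        rng = np.random.default_rng(0)
        n = 10_000
        x = rng.standard_normal(n)
        y = 0.8 * x + np.sqrt(1 - 0.64) * rng.standard_normal(n)
        assert abs(pearson_r(x, y) - 0.8) <= 0.02

    def test_zero_variance_rejected(self):
        with pytest.raises(DomainError):
            pearson_r(np.ones(10), np.arange(10.0))


class TestSteiger:
    def test_equal_correlations_give_zero(self):
        res = steiger_z(0.5, 0.5, 0.3, 100)
        assert res.z == 0.0
        assert res.p == 1.0

    def test_reported_contrast_is_significant(self):
        """With the published CT-metric correlations (r=0.81 vs ESI,
        r=-0.50 vs FEV1, r(ESI,FEV1)=-0.74, n=194) the difference in
        dependent correlations is overwhelmingly significant."""
        res = steiger_z(0.81, -0.50, -0.74, 194)
        assert res.p < 0.001

    def test_type_one_error_near_nominal(self):
        """Under a true null (both correlations equal by construction),
        rejections at alpha=0.05 stay within [0.03, 0.07]."""
        rng = np.random.default_rng(1)
        n, reps = 200, 2000
        rho = 0.4
        cov = np.array([[1.0, rho, rho], [rho, 1.0, 0.3], [rho, 0.3, 1.0]])
        chol = np.linalg.cholesky(cov)
        rejections = 0
        for _ in range(reps):
            x = rng.standard_normal((n, 3)) @ chol.T
            c = np.corrcoef(x, rowvar=False)
            res = steiger_z(c[0, 1], c[0, 2], c[1, 2], n)
            rejections += res.p < 0.05
        assert 0.03 <= rejections / reps <= 0.07

    def test_bootstrap_variant_agrees_in_sign(self):
        rng = np.random.default_rng(2)
        n = 300
        x = rng.standard_normal(n)
        k = 0.8 * x + 0.6 * rng.standard_normal(n)
        h = 0.2 * x + 0.98 * rng.standard_normal(n)
        boot = steiger_z_bootstrap(x, k, h, n_boot=500, seed=0)
        classical = steiger_z(pearson_r(x, k), pearson_r(x, h),
                              pearson_r(k, h), n)
        assert np.sign(boot.z) == np.sign(classical.z)
        assert boot.p < 0.05 and classical.p < 0.05

    def test_invalid_correlation_matrix_rejected(self):
        with pytest.raises(DomainError):
            steiger_z(0.95, -0.95, 0.95, 100)


class TestWelchAnova:
    def test_identical_groups(self):
        res = welch_anova([(5.0, 1.0, 20), (5.0, 1.0, 20)])
        assert res.f_star == 0.0
        assert res.p == 1.0

    def test_published_group_summaries_significant(self):
        res = welch_anova([(1.1, 1.5, 57), (3.1, 2.6, 58), (6.8, 2.5, 79)])
        assert res.p < 0.001

    def test_matches_reference_implementation(self):
        """Raw-data agreement with pingouin's Welch ANOVA on random data."""
        import pandas as pd
        import pingouin as pg

        rng = np.random.default_rng(3)
        for _ in range(100):
            groups = [rng.normal(rng.uniform(-1, 1), rng.uniform(0.5, 2),
                                 rng.integers(5, 40)) for _ in range(3)]
            res = welch_anova(groups)
            df = pd.DataFrame({
                "y": np.concatenate(groups),
                "g": np.repeat([0, 1, 2], [len(g) for g in groups]),
            })
            ref = pg.welch_anova(data=df, dv="y", between="g")
            assert res.f_star == pytest.approx(float(ref["F"][0]), abs=1e-8)
            assert res.p == pytest.approx(float(ref["p_unc"][0]), abs=1e-8)

    def test_type_one_error_near_nominal(self):
        rng = np.random.default_rng(4)
        reps, rejections = 2000, 0
        for _ in range(reps):
            groups = [rng.normal(0, sd, n) for sd, n in
                      ((1.0, 25), (2.0, 35), (0.5, 20))]
            rejections += welch_anova(groups).p < 0.05
        assert 0.03 <= rejections / reps <= 0.07


class TestGamesHowell:
    def test_identical_groups_p_one(self):
        g = np.arange(10.0)
        table = games_howell([g, g.copy(), g.copy()])
        assert np.allclose(table["p"], 1.0, atol=1e-6)

    def test_matches_reference_implementation(self):
        import pandas as pd
        import pingouin as pg

        rng = np.random.default_rng(5)
        groups = [rng.normal(m, sd, n) for m, sd, n in
                  ((0.0, 1.0, 30), (1.0, 2.0, 25), (2.5, 0.8, 40))]
        mine = games_howell(groups)
        df = pd.DataFrame({
            "y": np.concatenate(groups),
            "g": np.repeat([0, 1, 2], [len(g) for g in groups]),
        })
        ref = pg.pairwise_gameshowell(data=df, dv="y", between="g")
        for (_, row), (_, rrow) in zip(mine.iterrows(), ref.iterrows()):
            assert row["p"] == pytest.approx(float(rrow["pval"]), abs=0.01)
            assert abs(row["mean_diff"]) == pytest.approx(
                abs(float(rrow["diff"])), abs=1e-9)

    def test_p_monotone_in_mean_difference(self):
        ps = []
        for diff in (0.2, 0.5, 1.0, 2.0):
            rng = np.random.default_rng(6)
            a = rng.normal(0, 1, 30)
            b = rng.normal(0, 1, 30) + diff
            ps.append(float(games_howell([a, b])["p"][0]))
        assert ps == sorted(ps, reverse=True)


class TestChiSquared:
    def test_closed_form_diagonal(self):
        stat, df, p = chi_squared([[10, 0], [0, 10]])
        assert stat == pytest.approx(20.0)
        assert df == 1

    def test_independent_table(self):
        stat, df, p = chi_squared([[5, 5], [5, 5]])
        assert stat == 0.0
        assert p == 1.0

    def test_matches_reference_on_random_tables(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            table = rng.integers(1, 50, (3, 3))
            stat, df, p = chi_squared(table)
            ref = sps.chi2_contingency(table, correction=False)
            assert stat == pytest.approx(ref.statistic, abs=1e-8)
            assert p == pytest.approx(ref.pvalue, abs=1e-8)

    def test_zero_marginal_rejected(self):
        with pytest.raises(DomainError):
            chi_squared([[0, 0], [5, 5]])


class TestLogistic:
    def test_symmetric_data_zero_intercept(self):
        # balanced +/-1 design with symmetric labels
        x = np.array([-1.0, -1.0, 1.0, 1.0] * 10)
        y = np.array([0, 1, 0, 1] * 10)
        fit = fit_logistic(x, y)
        assert abs(fit.intercept) <= 1e-6

    def test_gradient_zero_at_optimum(self):
        """Numeric-gradient oracle: the log-likelihood gradient vanishes at
        the returned coefficients."""
        rng = np.random.default_rng(8)
        x = rng.normal(0, 2, 300)
        y = (rng.random(300) < expit(0.5 + 0.8 * x)).astype(float)
        fit = fit_logistic(x, y)
        assert fit.converged

        def loglik(b0, b1):
            eta = b0 + b1 * x
            return float(np.sum(y * eta - np.log1p(np.exp(eta))))

        eps = 1e-6
        g0 = (loglik(fit.intercept + eps, fit.slope)
              - loglik(fit.intercept - eps, fit.slope)) / (2 * eps)
        g1 = (loglik(fit.intercept, fit.slope + eps)
              - loglik(fit.intercept, fit.slope - eps)) / (2 * eps)
        assert abs(g0) <= 1e-4 and abs(g1) <= 1e-4

    def test_matches_statsmodels(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(9)
        x = rng.normal(0, 1.5, 400)
        y = (rng.random(400) < expit(-0.3 + 1.1 * x)).astype(float)
        fit = fit_logistic(x, y)
        ref = sm.Logit(y, sm.add_constant(x)).fit(disp=0)
        assert fit.intercept == pytest.approx(ref.params[0], abs=1e-6)
        assert fit.slope == pytest.approx(ref.params[1], abs=1e-6)

    def test_monotone_probabilities(self):
        rng = np.random.default_rng(10)
        x = rng.normal(0, 1, 200)
        y = (rng.random(200) < expit(2 * x)).astype(float)
        fit = fit_logistic(x, y)
        assert fit.slope > 0
        grid = np.linspace(-3, 3, 50)
        assert np.all(np.diff(predict_proba(fit, grid)) > 0)

    def test_separation_flagged_and_still_ranks(self):
        x = np.concatenate([np.arange(10.0), np.arange(20.0, 30.0)])
        y = np.concatenate([np.zeros(10), np.ones(10)])
        fit = fit_logistic(x, y)
        assert fit.separation
        probs = predict_proba(fit, x)
        assert probs[y == 1].min() > probs[y == 0].max()


class TestCvRoc:
    def test_perfect_separation_auc_one(self):
        x = np.concatenate([np.random.default_rng(0).uniform(0, 1, 30),
                            np.random.default_rng(1).uniform(2, 3, 30)])
        y = np.concatenate([np.zeros(30, int), np.ones(30, int)])
        roc = cv_roc(x, y, k_folds=5, seed=0)
        assert roc.auc == pytest.approx(1.0)
        assert np.allclose(roc.fold_aucs, 1.0)
        thr, sens, spec = best_threshold(roc)
        assert sens == 1.0 and spec == 1.0

    def test_auc_equals_mann_whitney_identity(self):
        rng = np.random.default_rng(11)
        x = np.concatenate([rng.normal(0, 1, 60), rng.normal(1, 1, 50)])
        y = np.concatenate([np.zeros(60, int), np.ones(50, int)])
        roc = cv_roc(x, y, k_folds=10, seed=3)
        # recompute pooled held-out probabilities exactly as cv_roc does
        from sklearn.model_selection import StratifiedKFold

        pooled = np.empty_like(x)
        for train, test in StratifiedKFold(10, shuffle=True,
                                           random_state=3).split(
                                               x.reshape(-1, 1), y):
            fit = fit_logistic(x[train], y[train])
            pooled[test] = predict_proba(fit, x[test])
        u = sps.mannwhitneyu(pooled[y == 1], pooled[y == 0],
                             alternative="two-sided").statistic
        assert roc.auc == pytest.approx(u / (60 * 50), abs=1e-9)

    def test_null_auc_near_half(self):
        """Labels independent of the score: mean held-out AUC ~ 0.5."""
        rng = np.random.default_rng(12)
        aucs = []
        for _ in range(200):
            x = rng.normal(0, 1, 80)
            y = np.zeros(80, int)
            y[rng.choice(80, 40, replace=False)] = 1
            aucs.append(cv_roc(x, y, k_folds=4, seed=0).auc)
        assert abs(np.mean(aucs) - 0.5) <= 0.02

    def test_small_class_rejected(self):
        x = np.arange(20.0)
        y = np.array([0] * 15 + [1] * 5)
        with pytest.raises(DomainError):
            cv_roc(x, y, k_folds=10)


class TestBestThreshold:
    def test_hand_built_roc_matches_brute_force(self):
        from esilung.stats import ROCResult

        thr = np.array([np.inf, 0.9, 0.7, 0.5, 0.3, 0.1])
        sens = np.array([0.0, 0.3, 0.6, 0.8, 0.9, 1.0])
        spec = np.array([1.0, 0.95, 0.9, 0.75, 0.4, 0.0])
        roc = ROCResult(thresholds=thr, sensitivities=sens,
                        specificities=spec, auc=0.8,
                        fold_aucs=np.array([0.8]))
        j = sens + spec - 1
        k_brute = int(np.argmax(j))
        t, se, sp = best_threshold(roc)
        assert (se, sp) == (sens[k_brute], spec[k_brute])

    def test_threshold_in_unit_interval_for_probabilities(self):
        rng = np.random.default_rng(13)
        x = np.concatenate([rng.normal(0, 1, 40), rng.normal(1.5, 1, 40)])
        y = np.concatenate([np.zeros(40, int), np.ones(40, int)])
        roc = cv_roc(x, y, k_folds=4, seed=1)
        t, _, _ = best_threshold(roc)
        assert 0.0 <= t <= 1.0
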