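"""Logit IRLS, Hosmer-Lemeshow, Spearman, subset tables, moment checks."""

import itertools
import math

import numpy as np
import pytest
from scipy import optimize, stats

from gobypass import (fit_logit, hosmer_lemeshow, moment_check, predict_proba,
                      spearman_matrix, subset_model_table)


def simulate_logit(n, beta, intercept, seed, k=None):
    rng = np.random.default_rng(seed)
    beta = np.asarray(beta, dtype=float)
    X = rng.normal(size=(n, k or len(beta)))
    eta = intercept + X[:, :len(beta)] @ beta
    y = (rng.uniform(size=n) < 1 / (1 + np.exp(-eta))).astype(float)
    return X, y


class TestFitLogit:
    def test_two_by_two_closed_form_slope(self):
        """Single binary predictor: the MLE slope is the log odds ratio."""
        a, b, c, d = 30, 10, 12, 25   # (x=1,y=1), (x=1,y=0), (x=0,y=1), (x=0,y=0)
        x = np.array([1.0] * (a + b) + [0.0] * (c + d)).reshape(-1, 1)
        y = np.array([1.0] * a + [0.0] * b + [1.0] * c + [0.0] * d)
        fit = fit_logit(x, y)
        assert fit.converged and not fit.separation_warning
        assert fit.coefficients[0] == pytest.approx(
            math.log(a * d / (b * c)), abs=1e-6)
        assert fit.intercept == pytest.approx(math.log(c / d), abs=1e-6)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_irls_matches_brute_force_likelihood_maximum(self, seed):
        """On small instances the IRLS optimum agrees with direct
        Nelder-Mead maximisation of the Bernoulli log-likelihood."""
        X, y = simulate_logit(50, [1.0, -0.7], 0.3, seed)
        if len(np.unique(y)) < 2:
            pytest.skip("degenerate draw")
        fit = fit_logit(X, y)
        assert not fit.separation_warning

        def nll(b):
            eta = b[0] + X @ b[1:]
            p = 1 / (1 + np.exp(-np.clip(eta, -700, 700)))
            p = np.clip(p, 1e-12, 1 - 1e-12)
            return -np.sum(y * np.log(p) + (1 - y) * np.log(1 - p))

        res = optimize.minimize(nll, np.zeros(3), method="Nelder-Mead",
                                options=dict(xatol=1e-10, fatol=1e-12,
                                             maxiter=20000, maxfev=20000))
        assert fit.intercept == pytest.approx(res.x[0], abs=1e-4)
        np.testing.assert_allclose(fit.coefficients, res.x[1:], atol=1e-4)

    def test_matches_reference_glm_implementation(self):
        """Cross-check coefficients and deviance against statsmodels."""
        sm = pytest.importorskip("statsmodels.api")
        X, y = simulate_logit(300, [0.8, -1.1, 0.4], -0.2, 11)
        fit = fit_logit(X, y)
        ref = sm.Logit(y, sm.add_constant(X)).fit(disp=0)
        np.testing.assert_allclose(
            np.r_[fit.intercept, fit.coefficients], ref.params, atol=1e-5)
        assert fit.deviance == pytest.approx(-2 * ref.llf, rel=1e-8)

    def test_null_lr_calibration(self):
        """Outcome independent of predictors: the LR chi2 stays below the
        0.95 quantile of chi2(df) in at least 90% of replicates."""
        below = 0
        crit = stats.chi2.ppf(0.95, 2)
        for rep in range(200):
            rng = np.random.default_rng(1000 + rep)
            X = rng.normal(size=(500, 2))
            y = (rng.uniform(size=500) < 0.4).astype(float)
            fit = fit_logit(X, y)
            below += fit.lr_chi2 < crit
        assert below >= 180

    def test_perfect_separation_is_flagged_and_capped(self):
        x = np.linspace(-2, 2, 40).reshape(-1, 1)
        y = (x.ravel() > 0).astype(float)
        fit = fit_logit(x, y)
        assert fit.separation_warning
        assert np.max(np.abs(np.r_[fit.intercept, fit.coefficients])) == \
            pytest.approx(25.0)
        assert np.isfinite(fit.deviance) and np.isfinite(fit.aic)
        assert fit.pct_correct == 100.0

    def test_one_class_outcome_degenerate_not_raised(self):
        X = np.random.default_rng(0).normal(size=(30, 2))
        fit = fit_logit(X, np.ones(30))
        assert fit.degenerate and fit.separation_warning
        assert fit.lr_chi2 == 0.0
        assert np.isfinite(fit.deviance)

    def test_deviance_and_aic_identities(self):
        X, y = simulate_logit(200, [0.5], 0.1, 5)
        fit = fit_logit(X, y)
        assert fit.deviance == pytest.approx(-2 * fit.log_likelihood)
        assert fit.aic == pytest.approx(fit.deviance + 2 * (1 + 1))
        assert fit.lr_df == 1


class TestHosmerLemeshow:
    def test_statistic_zero_when_probabilities_match_frequencies(self):
        """Groups whose predicted probability equals the group event
        frequency contribute nothing."""
        p, y = [], []
        for g in range(10):
            prob = (g + 1) / 20.0
            n_g, n_event = 20, int(round(20 * (g + 1) / 20.0))
            p += [prob] * n_g
            y += [1.0] * n_event + [0.0] * (n_g - n_event)
        res = hosmer_lemeshow(np.array(p), np.array(y), n_groups=10)
        assert res.statistic == pytest.approx(0.0, abs=1e-9)

    def test_df_is_groups_minus_two(self):
        rng = np.random.default_rng(2)
        p = rng.uniform(0.1, 0.9, 200)
        y = (rng.uniform(size=200) < p).astype(float)
        res = hosmer_lemeshow(p, y, n_groups=10)
        assert res.df == 8
        assert len(res.group_table) == 10

    def test_null_p_value_uniformity(self):
        """Well-specified data: HL p-values are near-uniform over seeds."""
        pvals = []
        for rep in range(200):
            rng = np.random.default_rng(5000 + rep)
            x = rng.normal(size=1000)
            eta = -0.3 + 0.9 * x
            y = (rng.uniform(size=1000) < 1 / (1 + np.exp(-eta))).astype(float)
            fit = fit_logit(x.reshape(-1, 1), y)
            res = hosmer_lemeshow(predict_proba(fit, x.reshape(-1, 1)), y)
            pvals.append(res.p_value)
        ks = np.max(np.abs(np.sort(pvals) - np.arange(1, 201) / 200.0))
        assert ks < 0.1

    def test_degenerate_groups_merged(self):
        # half the sample predicted at exactly zero risk -> groups merge
        p = np.r_[np.zeros(50), np.linspace(0.2, 0.8, 50)]
        y = np.r_[np.zeros(50), (np.linspace(0.2, 0.8, 50) > 0.5) * 1.0]
        res = hosmer_lemeshow(p, y, n_groups=10)
        assert res.n_groups_merged >= 1
        assert np.isfinite(res.statistic)

    def test_too_few_observations_rejected(self):
        with pytest.raises(ValueError):
            hosmer_lemeshow(np.array([0.5] * 5), np.array([1.0] * 5), 10)


class TestSpearman:
    def test_self_correlation_is_one(self):
        x = np.random.default_rng(1).normal(size=30)
        res = spearman_matrix({"a": x, "b": x.copy()})
        assert res.matrix.loc["a", "b"] == pytest.approx(1.0)

    def test_opposite_monotone_is_minus_one(self):
        res = spearman_matrix({"up": np.arange(20.0),
                               "down": -np.arange(20.0)})
        assert res.matrix.loc["up", "down"] == pytest.approx(-1.0)

    def test_matches_rank_pearson_brute_force_with_ties(self):
        rng = np.random.default_rng(8)
        a = rng.integers(0, 5, 60).astype(float)   # heavy ties
        b = rng.normal(size=60)
        res = spearman_matrix({"a": a, "b": b})
        ra = stats.rankdata(a)
        rb = stats.rankdata(b)
        expected = np.corrcoef(ra, rb)[0, 1]
        assert res.matrix.loc["a", "b"] == pytest.approx(expected, rel=1e-12)

    def test_matches_scipy_spearmanr(self):
        rng = np.random.default_rng(15)
        a = rng.normal(size=50)
        b = 0.5 * a + rng.normal(size=50)
        res = spearman_matrix({"a": a, "b": b})
        assert res.matrix.loc["a", "b"] == pytest.approx(
            stats.spearmanr(a, b).statistic, rel=1e-12)

    def test_constant_column_flagged_not_silent(self):
        res = spearman_matrix({"a": np.arange(10.0),
                               "c": np.ones(10)})
        assert ("a", "c") in res.undefined_pairs
        assert math.isnan(res.matrix.loc["a", "c"])


class TestSubsetTable:
    def test_row_count_for_two_predictors(self):
        X, y = simulate_logit(80, [1.0, -0.5], 0.0, 3)
        table = subset_model_table(X, y, ["a", "b"])
        assert len(table) == 3

    def test_strong_predictor_wins_single_variable_aic(self):
        rng = np.random.default_rng(4)
        a = rng.normal(size=500)
        b = rng.normal(size=500)
        eta = 2.5 * a
        y = (rng.uniform(size=500) < 1 / (1 + np.exp(-eta))).astype(float)
        table = subset_model_table(np.column_stack([a, b]), y, ["a", "b"])
        singles = table[table.df == 1]
        assert singles.iloc[0].predictors == "a"

    def test_aic_identity_and_refit_agreement_on_every_row(self):
        X, y = simulate_logit(120, [0.8, -0.6, 0.3], 0.2, 6)
        names = ["a", "b", "c"]
        table = subset_model_table(X, y, names)
        assert len(table) == 7
        cols = {n: j for j, n in enumerate(names)}
        for row in table.itertuples():
            subset = row.predictors.split("+")
            # AIC identity: aic - deviance = 2 (k + 1)
            assert row.aic - row.deviance == pytest.approx(
                2 * (len(subset) + 1))
            assert row.df == len(subset)
            # independent refit reproduces the tabulated AIC
            refit = fit_logit(X[:, [cols[n] for n in subset]], y, subset)
            assert refit.aic == pytest.approx(row.aic, rel=1e-8)

    def test_sorted_by_size_then_aic(self):
        X, y = simulate_logit(100, [0.5, 0.5, 0.5], 0.0, 7)
        table = subset_model_table(X, y, ["a", "b", "c"])
        assert list(table.df) == sorted(table.df, reverse=True)
        for _, grp in table.groupby("df"):
            assert list(grp.aic) == sorted(grp.aic)


class TestMomentCheck:
    def test_symmetric_sample_has_zero_skewness(self):
        x = np.array([-2.0, -1.0, 0.0, 1.0, 2.0])
        res = moment_check(x)
        assert res.skewness == pytest.approx(0.0, abs=1e-12)
        assert not res.flagged

    def test_normal_sample_moments(self):
        x = np.random.default_rng(12).normal(size=10_000)
        res = moment_check(x)
        assert abs(res.skewness) < 0.08
        assert abs(res.excess_kurtosis) < 0.15
        assert not res.flagged

    def test_exponential_sample_is_flagged(self):
        x = np.random.default_rng(13).exponential(size=10_000)
        res = moment_check(x)
        assert res.skewness == pytest.approx(2.0, abs=0.25)
        assert res.flagged
        assert "mean may not represent" in res.reason

    def test_matches_scipy_formulas(self):
        x = np.random.default_rng(14).gamma(2.0, size=500)
        res = moment_check(x)
        assert res.skewness == pytest.approx(stats.skew(x), rel=1e-12)
        assert res.excess_kurtosis == pytest.approx(
            stats.kurtosis(x), rel=1e-12)

    def test_zero_variance_flagged(self):
        res = moment_check(np.ones(10))
        assert res.flagged and res.reason == "zero variance"
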