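import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import kstest, nbinom
from statsmodels.stats.multitest import multipletests

from deltate import nbglm
from deltate.dataio import SampleTable
from deltate.nbglm import (ALPHA_MIN, DesignError, bh_adjust, build_design,
                           cox_reid_loglik, fit_dispersion_trend, fit_glm_irls,
                           likelihood_ratio_test, moments_dispersion,
                           nb_loglik, profile_dispersion_mle,
                           shrink_dispersion_map, wald_test)


class TestBuildDesign:
    def test_two_by_two_interaction_design(self, two_by_two_samples):
        d = build_design(two_by_two_samples)
        assert d.values.shape == (8, 4)
        assert d.columns == ["Intercept", "Condition_2_vs_1",
                             "SeqType_RIBO_vs_RNA", "Condition2.SeqTypeRIBO"]
        assert d.reference_levels == {"condition": "1", "seqtype": "RNA"}
        # interaction column = product of the condition and seqtype indicators
        np.testing.assert_array_equal(d.values[:, 3],
                                      d.values[:, 1] * d.values[:, 2])

    def test_batch_column_precedes_condition(self, batched_samples):
        d = build_design(batched_samples, with_batch=True)
        assert d.values.shape == (8, 5)
        assert d.columns[1] == "Batch_2_vs_1"
        assert d.columns[2] == "Condition_2_vs_1"

    def test_confounded_batch_is_rank_deficient(self, two_by_two_samples):
        df = two_by_two_samples.data.copy()
        df["batch"] = df["condition"]
        with pytest.raises(DesignError, match="non-full-rank"):
            build_design(SampleTable(df), with_batch=True)

    def test_condition_reference_override(self, two_by_two_samples):
        d = build_design(two_by_two_samples, condition_ref="2")
        assert "Condition_1_vs_2" in d.columns
        assert "Condition1.SeqTypeRIBO" in d.columns


class TestMomentsDispersion:
    def test_poisson_limit_hits_floor(self):
        # normalised counts with variance == mean -> floored at 1e-8
        y = np.array([8, 10, 12, 9, 11])  # var 2.5 < mean 10
        assert moments_dispersion(y, np.ones(5)) == ALPHA_MIN

    def test_closed_form(self):
        # construct m = 10, v = 110 exactly -> alpha0 = (110-10)/100 = 1.0
        y = np.array([10 - np.sqrt(110), 10, 10 + np.sqrt(110)])
        m, v = y.mean(), y.var(ddof=1)
        assert m == pytest.approx(10) and v == pytest.approx(110)
        expected = (v - m) / m**2
        assert moments_dispersion(y, np.ones(3)) == pytest.approx(expected)

    def test_monte_carlo_recovery(self):
        rng = np.random.default_rng(5)
        alpha, mu, n = 0.2, 100.0, 5000
        r = 1 / alpha
        y = rng.negative_binomial(r, r / (r + mu), size=n)
        est = moments_dispersion(y, np.ones(n))
        assert est == pytest.approx(alpha, rel=0.2)

    def test_all_zero_row_is_nan(self):
        assert np.isnan(moments_dispersion(np.zeros(4), np.ones(4)))


def _poisson_group_counts(rng, samples, means):
    df = samples.data
    y = np.empty(len(df))
    for j in range(len(df)):
        grp = 2 * int(df["condition"][j] == "2") + int(df["seqtype"][j] == "RIBO")
        y[j] = rng.poisson(means[grp])
    return y


class TestFitGlmIrls:
    def test_saturated_fit_recovers_group_means(self, two_by_two_samples):
        """With 4 groups and 4 coefficients the MLE fitted means equal the
        observed group means of normalised counts, for any dispersion."""
        rng = np.random.default_rng(2)
        design = build_design(two_by_two_samples)
        y = _poisson_group_counts(rng, two_by_two_samples, [50, 500, 120, 80])
        for alpha in (1e-6, 0.1, 2.0):
            fit = fit_glm_irls(y, design, np.ones(8), alpha)
            assert fit.converged
            df = two_by_two_samples.data
            for cond in ("1", "2"):
                for seq in ("RIBO", "RNA"):
                    m = ((df["condition"] == cond) & (df["seqtype"] == seq)).to_numpy()
                    np.testing.assert_allclose(fit.mu[m], y[m].mean(),
                                               rtol=1e-6)

    def test_interaction_equals_log2_te_ratio(self, two_by_two_samples):
        """Saturated identity: the interaction coefficient is the log2 ratio
        of (ribo mean / rna mean) between conditions."""
        rng = np.random.default_rng(3)
        design = build_design(two_by_two_samples)
        df = two_by_two_samples.data
        for _ in range(20):
            y = _poisson_group_counts(rng, two_by_two_samples,
                                      rng.uniform(20, 2000, 4))
            fit = fit_glm_irls(y, design, np.ones(8), alpha=0.05)
            def gmean(cond, seq):
                m = ((df["condition"] == cond) & (df["seqtype"] == seq)).to_numpy()
                return y[m].mean()
            expected = np.log2((gmean("2", "RIBO") / gmean("2", "RNA"))
                               / (gmean("1", "RIBO") / gmean("1", "RNA")))
            idx = design.column_index("Condition2.SeqTypeRIBO")
            assert fit.beta[idx] == pytest.approx(expected, abs=1e-6)

    def test_loglik_beats_grid_oracle(self):
        """IRLS log-likelihood >= a dense grid search over beta (2 coef)."""
        rng = np.random.default_rng(4)
        X = np.column_stack([np.ones(4), [0, 0, 1, 1]])
        design = nbglm.DesignMatrix(["Intercept", "b"], X, {})
        grid = np.linspace(-4, 6, 501)
        B = np.array(np.meshgrid(grid, grid)).reshape(2, -1)  # 2 x G
        for _ in range(10):
            y = rng.integers(0, 50, size=4).astype(float)
            if np.all(y == 0):
                continue
            alpha = rng.uniform(0.01, 1.0)
            sf = np.ones(4)
            fit = fit_glm_irls(y, design, sf, alpha)
            mu = np.exp(X @ B)  # 4 x G
            r = 1 / alpha
            from scipy.special import gammaln
            ll = (gammaln(y[:, None] + r) - gammaln(r) - gammaln(y[:, None] + 1)
                  + r * np.log(r / (r + mu)) + y[:, None] * np.log(
                      np.clip(mu, 1e-12, None) / (r + mu))).sum(axis=0)
            assert fit.loglik >= ll.max() - 1e-4

    def test_all_zero_gene_flagged(self, two_by_two_samples):
        design = build_design(two_by_two_samples)
        fit = fit_glm_irls(np.zeros(8), design, np.ones(8), 0.1)
        assert not fit.converged
        assert np.all(np.isnan(fit.beta))

    def test_size_factor_invariance(self, two_by_two_samples):
        """Doubling one sample's counts and its size factor leaves the
        coefficients unchanged."""
        rng = np.random.default_rng(6)
        design = build_design(two_by_two_samples)
        y = _poisson_group_counts(rng, two_by_two_samples, [100, 150, 80, 60])
        sf = np.ones(8)
        fit = fit_glm_irls(y, design, sf, 0.1)
        y2, sf2 = y.copy(), sf.copy()
        y2[3] *= 2
        sf2[3] *= 2
        fit2 = fit_glm_irls(y2, design, sf2, 0.1)
        np.testing.assert_allclose(fit2.beta, fit.beta, atol=1e-6)


class TestProfileDispersion:
    def test_poisson_data_hits_lower_bound(self, two_by_two_samples):
        rng = np.random.default_rng(8)
        design = build_design(two_by_two_samples)
        y = rng.poisson(200, 8).astype(float)
        fit = fit_glm_irls(y, design, np.ones(8), ALPHA_MIN)
        alpha, at_bound = profile_dispersion_mle(y, design, np.ones(8), fit.mu)
        assert alpha < 1e-3  # at or near the 1e-8 floor given only 8 samples

    def test_matches_dense_grid_scan(self):
        """Optimum within 1e-3 (log scale) of a dense scan of the objective."""
        rng = np.random.default_rng(9)
        X = np.column_stack([np.ones(6), [0, 0, 0, 1, 1, 1]])
        design = nbglm.DesignMatrix(["Intercept", "b"], X, {})
        sf = np.ones(6)
        for _ in range(5):
            r = 1 / 0.3
            mu_true = rng.uniform(50, 300)
            y = rng.negative_binomial(r, r / (r + mu_true), 6).astype(float)
            if np.all(y == 0):
                continue
            fit = fit_glm_irls(y, design, sf, 0.3)
            alpha, _ = profile_dispersion_mle(y, design, sf, fit.mu)
            la_grid = np.linspace(np.log(ALPHA_MIN), np.log(10.0), 40001)
            vals = [cox_reid_loglik(np.exp(la), y, X, fit.mu) for la in la_grid]
            la_best = la_grid[int(np.argmax(vals))]
            assert abs(np.log(alpha) - la_best) < 1e-3 or \
                cox_reid_loglik(alpha, y, X, fit.mu) >= max(vals) - 1e-8

    def test_consistency_monte_carlo(self):
        """alpha-hat within 15% of truth for a 200-sample intercept-only fit."""
        rng = np.random.default_rng(10)
        n, alpha_true, mu = 200, 0.5, 150.0
        X = np.ones((n, 1))
        design = nbglm.DesignMatrix(["Intercept"], X, {})
        r = 1 / alpha_true
        y = rng.negative_binomial(r, r / (r + mu), n).astype(float)
        sf = np.ones(n)
        fit = fit_glm_irls(y, design, sf, moments_dispersion(y, sf))
        alpha, _ = profile_dispersion_mle(y, design, sf, fit.mu)
        assert alpha == pytest.approx(alpha_true, rel=0.15)


class TestDispersionTrend:
    def test_recovers_noise_free_trend(self):
        mu = np.linspace(5, 2000, 300)
        d = 0.02 + 3.0 / mu
        a0, a1 = fit_dispersion_trend(mu, d)
        assert a0 == pytest.approx(0.02, rel=0.05)
        assert a1 == pytest.approx(3.0, rel=0.05)

    def test_flat_trend(self):
        mu = np.linspace(10, 1000, 200)
        d = np.full(200, 0.1)
        a0, a1 = fit_dispersion_trend(mu, d)
        assert a0 == pytest.approx(0.1, rel=0.02)
        assert a1 == pytest.approx(0.0, abs=0.05)

    def test_few_genes_falls_back_to_median(self):
        mu = np.linspace(10, 100, 10)
        d = np.full(10, 0.3)
        with pytest.warns(UserWarning, match="median"):
            a0, a1 = fit_dispersion_trend(mu, d)
        assert a0 == pytest.approx(0.3)
        assert a1 == 0.0


class TestShrinkDispersion:
    def _setup(self, n_genes=60, n=8, seed=11):
        rng = np.random.default_rng(seed)
        X = np.column_stack([np.ones(n), np.repeat([0, 1], n // 2)])
        design = nbglm.DesignMatrix(["Intercept", "b"], X, {})
        sf = np.ones(n)
        counts = np.empty((n_genes, n))
        mu_mat = np.empty((n_genes, n))
        genewise = np.empty(n_genes)
        base = np.empty(n_genes)
        for g in range(n_genes):
            mu = rng.uniform(50, 500)
            alpha = 0.05 + 2.0 / mu
            r = 1 / alpha
            counts[g] = rng.negative_binomial(r, r / (r + mu), n)
            fit = fit_glm_irls(counts[g], design, sf,
                               moments_dispersion(counts[g], sf))
            mu_mat[g] = fit.mu
            genewise[g], _ = profile_dispersion_mle(counts[g], design, sf, fit.mu)
            base[g] = counts[g].mean()
        return counts, design, sf, mu_mat, genewise, base

    def test_map_matches_grid_oracle(self):
        counts, design, sf, mu_mat, genewise, base = self._setup()
        trend = fit_dispersion_trend(base, genewise)
        disp = shrink_dispersion_map(counts, design, sf, mu_mat, genewise,
                                     trend, base)
        a0, a1 = trend
        prior_var = max(disp.prior_sd**2, 0.25)
        for g in [0, 7, 23]:
            if disp.outlier[g]:
                continue
            log_tr = np.log(max(a0 + a1 / base[g], ALPHA_MIN))
            la_grid = np.linspace(np.log(ALPHA_MIN), np.log(10.0), 20001)
            y, mu = counts[g], mu_mat[g]
            vals = [cox_reid_loglik(np.exp(la), y, design.values, mu)
                    - (la - log_tr)**2 / (2 * prior_var) for la in la_grid]
            la_best = la_grid[int(np.argmax(vals))]
            assert abs(np.log(disp.map[g]) - la_best) < 2e-3

    def test_outlier_keeps_genewise_estimate(self):
        counts, design, sf, mu_mat, genewise, base = self._setup(n_genes=55)
        genewise = genewise.copy()
        trend = fit_dispersion_trend(base, genewise)
        a0, a1 = trend
        # plant a 20x-above-trend outlier
        genewise[3] = 20.0 * (a0 + a1 / base[3])
        disp = shrink_dispersion_map(counts, design, sf, mu_mat, genewise,
                                     trend, base)
        assert disp.outlier[3]
        assert disp.map[3] == genewise[3]

    def test_dispersions_within_bounds(self):
        counts, design, sf, mu_mat, genewise, base = self._setup(n_genes=50)
        trend = fit_dispersion_trend(base, genewise)
        disp = shrink_dispersion_map(counts, design, sf, mu_mat, genewise,
                                     trend, base)
        assert np.all(disp.map >= ALPHA_MIN) and np.all(disp.map <= 10.0)


class TestWaldTest:
    def _fit(self, lfc, se):
        return nbglm.GeneFit(beta=np.array([0.0, lfc]), se=np.array([0.1, se]),
                             mu=np.ones(4), loglik=0.0, converged=True,
                             base_mean=10.0, columns=["Intercept", "c"])

    def test_null_point(self):
        out = wald_test(self._fit(0.0, 0.5), "c")
        assert out.stat == 0.0
        assert out.pvalue == pytest.approx(1.0)

    def test_normal_quantile_identity(self):
        out = wald_test(self._fit(1.959964, 1.0), "c")
        assert out.pvalue == pytest.approx(0.05, abs=1e-4)

    def test_matches_quadrature_oracle(self):
        from scipy.integrate import quad
        rng = np.random.default_rng(12)
        for _ in range(10):
            lfc, se = rng.normal(0, 2), rng.uniform(0.1, 2)
            out = wald_test(self._fit(lfc, se), "c")
            tail, _ = quad(lambda x: np.exp(-x**2 / 2) / np.sqrt(2 * np.pi),
                           abs(lfc / se), np.inf)
            assert out.pvalue == pytest.approx(2 * tail, abs=1e-8)

    def test_unknown_coefficient(self):
        with pytest.raises(DesignError, match="unknown"):
            wald_test(self._fit(1.0, 1.0), "nope")


class TestLikelihoodRatioTest:
    def _fit(self, loglik, cols):
        return nbglm.GeneFit(beta=np.zeros(len(cols)), se=np.ones(len(cols)),
                             mu=np.ones(4), loglik=loglik, converged=True,
                             base_mean=1.0, columns=cols)

    def test_identical_models_give_p_one(self):
        f = self._fit(-12.3, ["Intercept", "c"])
        out = likelihood_ratio_test(f, f, df=1)
        assert out.stat == 0.0 and out.pvalue == pytest.approx(1.0)

    def test_chi_square_quantile_identity(self):
        full = self._fit(-10.0, ["Intercept", "c"])
        reduced = self._fit(-10.0 - 3.841459 / 2, ["Intercept"])
        out = likelihood_ratio_test(full, reduced, df=1)
        assert out.pvalue == pytest.approx(0.05, abs=1e-4)

    def test_non_nested_rejected(self):
        full = self._fit(-1.0, ["Intercept", "c"])
        other = self._fit(-2.0, ["Intercept", "z"])
        with pytest.raises(DesignError, match="nested"):
            likelihood_ratio_test(full, other, df=1)

    def test_null_lrt_pvalues_uniform(self, two_by_two_samples):
        """LRT p-values on null genes (no interaction effect) ~ Uniform."""
        rng = np.random.default_rng(13)
        design = build_design(two_by_two_samples)
        reduced = design.subset(["Intercept", "Condition_2_vs_1",
                                 "SeqType_RIBO_vs_RNA"])
        sf = np.ones(8)
        pvals = []
        for _ in range(400):
            mu, alpha = 200.0, 0.05
            r = 1 / alpha
            y = rng.negative_binomial(r, r / (r + mu), 8).astype(float)
            full_fit = fit_glm_irls(y, design, sf, alpha)
            red_fit = fit_glm_irls(y, reduced, sf, alpha)
            pvals.append(likelihood_ratio_test(full_fit, red_fit, 1).pvalue)
        assert kstest(pvals, "uniform").pvalue > 0.01


class TestBHAdjust:
    def test_single_pvalue(self):
        np.testing.assert_allclose(bh_adjust([0.03]), [0.03])

    def test_stepup_example(self):
        # brute force: p*m/rank with reverse cumulative minimum
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]),
                                   [0.04, 0.04, 0.04, 0.04])

    def test_matches_statsmodels_oracle(self):
        rng = np.random.default_rng(14)
        for _ in range(20):
            p = rng.uniform(0, 1, rng.integers(1, 50))
            expected = multipletests(p, method="fdr_bh")[1]
            np.testing.assert_allclose(bh_adjust(p), expected, rtol=1e-12)

    def test_na_propagated_and_excluded_from_m(self):
        p = np.array([0.01, np.nan, 0.04])
        adj = bh_adjust(p)
        assert np.isnan(adj[1])
        np.testing.assert_allclose(adj[[0, 2]],
                                   multipletests([0.01, 0.04],
                                                 method="fdr_bh")[1])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1,
                    max_size=30))
    def test_monotone_in_sorted_order(self, pvals):
        p = np.sort(np.asarray(pvals))
        adj = bh_adjust(p)
        assert np.all(np.diff(adj) >= -1e-15)
        assert np.all(adj >= p - 1e-15) and np.all(adj <= 1.0)
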