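"""Tests for ANOVA, Tukey, Kruskal-Wallis, chi-squared, allele association,
meta-analysis and logistic models."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst
from scipy import stats as sps

from grstrat.stats import (
    GroupSummaries,
    allele_assoc_2x2,
    anova_oneway,
    chi2_rxc,
    glm_interaction,
    kruskal_wallis,
    logistic_adjusted,
    meta_fixed,
    pooled_mean,
    pooled_mean_sd,
    tukey_from_summary,
    tukey_hsd,
)


# ---------------------------------------------------------------------------
# ANOVA


class TestAnova:
    def test_identical_groups(self):
        r = anova_oneway([1, 1, 1, 1], ["a", "a", "b", "b"])
        assert r.statistic == 0.0
        assert r.pvalue == 1.0

    def test_textbook_f(self):
        # groups (1,2,3) vs (4,5,6): SSB = 13.5, MSW = 1 -> F = 13.5
        r = anova_oneway([1, 2, 3, 4, 5, 6], ["a"] * 3 + ["b"] * 3)
        assert r.statistic == pytest.approx(13.5)
        assert r.pvalue == pytest.approx(sps.f.sf(13.5, 1, 4))

    def test_matches_scipy(self, rng):
        vals = rng.normal(size=90)
        groups = np.repeat(["a", "b", "c"], 30)
        r = anova_oneway(vals, groups)
        f, p = sps.f_oneway(vals[:30], vals[30:60], vals[60:])
        assert r.statistic == pytest.approx(f)
        assert r.pvalue == pytest.approx(p)

    def test_single_group_errors(self):
        with pytest.raises(ValueError):
            anova_oneway([1, 2, 3], ["a", "a", "a"])


# ---------------------------------------------------------------------------
# Tukey


class TestTukey:
    def test_zero_difference_p_one(self):
        s = GroupSummaries(("a", "b"), (10, 10), (5.0, 5.0), (1.0, 1.0))
        r = tukey_from_summary(s)
        assert r.pvalue("a", "b") == pytest.approx(1.0)

    def test_monotone_in_difference(self):
        base = dict(n=(20, 20, 20), sd=(1.0, 1.0, 1.0))
        pvals = []
        for delta in (0.1, 0.5, 1.0, 2.0):
            s = GroupSummaries(("a", "b", "c"), mean=(0.0, delta, -1.0), **base)
            pvals.append(tukey_from_summary(s).pvalue("a", "b"))
        assert pvals == sorted(pvals, reverse=True)

    def test_matches_scipy_equal_n(self, rng):
        groups = [rng.normal(loc=m, size=25) for m in (0.0, 0.4, 1.0)]
        mine = tukey_hsd(np.concatenate(groups), np.repeat(["a", "b", "c"], 25))
        ref = sps.tukey_hsd(*groups)
        assert mine.pvalue("a", "b") == pytest.approx(ref.pvalue[0, 1], abs=1e-9)
        assert mine.pvalue("a", "c") == pytest.approx(ref.pvalue[0, 2], abs=1e-9)
        assert mine.pvalue("b", "c") == pytest.approx(ref.pvalue[1, 2], abs=1e-9)

    def test_matches_scipy_unequal_n(self, rng):
        groups = [rng.normal(size=n) for n in (15, 40, 23)]
        vals = np.concatenate(groups)
        labs = np.concatenate([np.repeat(g, len(v)) for g, v in
                               zip("abc", groups)])
        mine = tukey_hsd(vals, labs)
        ref = sps.tukey_hsd(*groups)
        assert mine.pvalue("a", "b") == pytest.approx(ref.pvalue[0, 1], abs=1e-9)

    def test_summary_equals_raw_exactly(self, rng):
        vals = rng.normal(size=60)
        labs = np.repeat(["x", "y", "z"], 20)
        raw = tukey_hsd(vals, labs)
        summ = tukey_from_summary(GroupSummaries.from_raw(vals, labs))
        for a, b in (("x", "y"), ("x", "z"), ("y", "z")):
            assert raw.pvalue(a, b) == pytest.approx(summ.pvalue(a, b), rel=1e-12)

    def test_equal_means_all_p_one(self):
        s = GroupSummaries(("a", "b", "c"), (10, 12, 14), (2.0, 2.0, 2.0),
                           (1.0, 1.2, 0.9))
        r = tukey_from_summary(s)
        assert (r.pairs["pvalue"] > 0.999).all()

    def test_printed_significance_pattern(self):
        # healthy + 4 clusters, from printed n / mean / sd rows
        s = GroupSummaries(
            ("healthy", "A", "B", "C", "D"),
            (565, 142, 120, 111, 102),
            (12.71, 14.15, 12.52, 12.33, 10.67),
            (2.10, 1.31, 2.16, 1.95, 1.44),
        )
        r = tukey_from_summary(s)
        assert r.pvalue("healthy", "A") < 1e-10
        assert r.pvalue("healthy", "D") < 1e-10
        assert r.pvalue("healthy", "B") > 0.5
        assert r.pvalue("healthy", "C") > 0.05

    def test_single_group_errors(self):
        with pytest.raises(ValueError):
            tukey_from_summary(GroupSummaries(("a",), (5,), (0.0,), (1.0,)))

    def test_negative_sd_rejected(self):
        with pytest.raises(ValueError):
            GroupSummaries(("a", "b"), (5, 5), (0.0, 0.0), (1.0, -0.1))

    @given(hst.integers(0, 2 ** 32 - 1))
    @settings(max_examples=20, deadline=None)
    def test_pvalues_valid_and_symmetric(self, seed):
        rng = np.random.default_rng(seed)
        ns = rng.integers(3, 20, size=3)
        s = GroupSummaries(("a", "b", "c"), tuple(int(n) for n in ns),
                           tuple(rng.normal(size=3)),
                           tuple(rng.uniform(0.1, 2.0, size=3)))
        r = tukey_from_summary(s)
        assert ((r.pairs["pvalue"] >= 0) & (r.pairs["pvalue"] <= 1)).all()
        assert r.pvalue("a", "b") == r.pvalue("b", "a")


# ---------------------------------------------------------------------------
# Kruskal-Wallis


class TestKruskal:
    def test_identical_groups(self):
        h, p = kruskal_wallis([2, 2, 2, 2], ["a", "a", "b", "b"])
        assert h == 0.0 and p == 1.0

    def test_hand_ranked(self):
        vals = [1, 2, 3, 10, 11, 12]
        labs = ["a"] * 3 + ["b"] * 3
        h, p = kruskal_wallis(vals, labs)
        # ranks 1..6, no ties: H = 12/(n(n+1)) * sum n_i (rbar_i - rbar)^2
        expected = 12.0 / (6 * 7) * (3 * (2 - 3.5) ** 2 + 3 * (5 - 3.5) ** 2)
        assert h == pytest.approx(expected)

    def test_monotone_invariance(self, rng):
        vals = rng.normal(size=40)
        labs = np.repeat(["a", "b"], 20)
        h1, p1 = kruskal_wallis(vals, labs)
        h2, p2 = kruskal_wallis(np.exp(vals), labs)
        assert h1 == pytest.approx(h2)
        assert p1 == pytest.approx(p2)


# ---------------------------------------------------------------------------
# chi-squared with adjusted residuals


class TestChi2:
    def test_printed_female_residuals(self):
        table = [[197, 250, 219], [123, 145, 224]]
        r = chi2_rxc(table)
        np.testing.assert_array_equal(np.round(r.adjusted_residuals[0], 1),
                                      [1.7, 2.9, -4.4])

    def test_independence_gives_zero(self):
        table = np.outer([10, 20], [3, 7]) # exact independence
        r = chi2_rxc(table)
        assert r.statistic == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_allclose(r.adjusted_residuals, 0.0, atol=1e-12)

    def test_matches_scipy(self, rng):
        table = rng.integers(5, 80, size=(3, 4))
        r = chi2_rxc(table)
        stat, p, dof, exp = sps.chi2_contingency(table, correction=False)
        assert r.statistic == pytest.approx(stat)
        assert r.pvalue == pytest.approx(p)
        np.testing.assert_allclose(r.expected, exp)

    @given(hst.integers(0, 2 ** 32 - 1))
    @settings(max_examples=30, deadline=None)
    def test_2x2_residual_squared_equals_chi2(self, seed):
        rng = np.random.default_rng(seed)
        table = rng.integers(1, 60, size=(2, 2))
        r = chi2_rxc(table)
        np.testing.assert_allclose(r.adjusted_residuals ** 2, r.statistic,
                                   rtol=1e-9)

    def test_zero_margin_errors(self):
        with pytest.raises(ValueError):
            chi2_rxc([[0, 0], [3, 4]])


# ---------------------------------------------------------------------------
# allele association


class TestAlleleAssoc:
    def test_equal_frequencies(self):
        r = allele_assoc_2x2(50, 100, 50, 100)
        assert r.or_point == pytest.approx(1.0)
        assert r.pvalue == pytest.approx(1.0)

    def test_cross_product_by_hand(self):
        r = allele_assoc_2x2(30, 100, 15, 100)
        assert r.or_point == pytest.approx(30 * 85 / (70 * 15))
        assert round(r.or_point, 2) == 2.43

    def test_zero_cell_corrected(self):
        r = allele_assoc_2x2(0, 50, 10, 50)
        assert math.isfinite(r.or_point) and r.or_point > 0
        assert math.isfinite(r.log_or_se)

    def test_chi2_matches_scipy(self):
        table = np.array([[30, 70], [15, 85]])
        _, p, _, _ = sps.chi2_contingency(table, correction=False)
        r = allele_assoc_2x2(30, 100, 15, 100)
        assert r.pvalue == pytest.approx(p)

    def test_zero_total_errors(self):
        with pytest.raises(ValueError):
            allele_assoc_2x2(0, 0, 5, 10)

    def test_type_one_error_rate(self):
        # null: both arms at the same allele frequency
        rng = np.random.default_rng(42)
        rej = 0
        reps = 2000
        for _ in range(reps):
            a = rng.binomial(1000, 0.3)
            c = rng.binomial(1000, 0.3)
            if allele_assoc_2x2(int(a), 1000, int(c), 1000).pvalue < 0.05:
                rej += 1
        assert abs(rej / reps - 0.05) < 0.012


# ---------------------------------------------------------------------------
# meta-analysis


class TestMeta:
    def test_single_study_identity(self):
        m = meta_fixed([(0.4, 0.1)])
        assert m.pooled_log_or == pytest.approx(0.4)
        assert m.pooled_se == pytest.approx(0.1)

    def test_two_identical_studies(self):
        m = meta_fixed([(0.5, 0.2), (0.5, 0.2)])
        assert m.or_point == pytest.approx(math.exp(0.5))
        assert m.pooled_se == pytest.approx(0.2 / math.sqrt(2))
        assert m.q == pytest.approx(0.0)
        assert m.i2 == 0.0

    def test_hand_computed_weights(self):
        lo1, se1, lo2, se2 = 0.3, 0.1, 0.8, 0.25
        w1, w2 = 1 / se1 ** 2, 1 / se2 ** 2
        expected = (w1 * lo1 + w2 * lo2) / (w1 + w2)
        m = meta_fixed([(lo1, se1), (lo2, se2)])
        assert m.pooled_log_or == pytest.approx(expected)

    @given(hst.lists(hst.tuples(hst.floats(-2, 2), hst.floats(0.05, 1.0)),
                     min_size=1, max_size=6))
    @settings(max_examples=50, deadline=None)
    def test_pooled_within_study_range(self, studies):
        m = meta_fixed(studies)
        los = [s[0] for s in studies]
        assert min(los) - 1e-9 <= m.pooled_log_or <= max(los) + 1e-9

    def test_bad_se_rejected(self):
        with pytest.raises(ValueError):
            meta_fixed([(0.1, 0.0)])


# ---------------------------------------------------------------------------
# logistic models


def simulate_logit(rng, n, beta_g, beta_cov=0.3):
    g = rng.binomial(2, 0.3, n).astype(float)
    cov = rng.normal(size=n)
    eta = -0.5 + beta_g * g + beta_cov * cov
    y = rng.random(n) < 1 / (1 + np.exp(-eta))
    return y.astype(float), g, cov


class TestLogistic:
    def test_parameter_recovery(self):
        rng = np.random.default_rng(7)
        y, g, cov = simulate_logit(rng, 4000, beta_g=0.5)
        r = logistic_adjusted(y, g, cov)
        assert r.converged and not r.separation
        assert abs(r.log_or - 0.5) < 3 * r.se

    def test_null_coverage(self):
        hits = 0
        reps = 40
        for seed in range(reps):
            rng = np.random.default_rng(seed)
            y, g, cov = simulate_logit(rng, 800, beta_g=0.0)
            r = logistic_adjusted(y, g, cov)
            hits += abs(r.log_or) < 3 * r.se
        assert hits >= int(0.9 * reps)

    def test_matches_2x2_oracle_without_covariates(self):
        # binary dosage, saturated model: logistic OR == cross-product OR
        y = np.array([1.0] * 30 + [0.0] * 70 + [1.0] * 15 + [0.0] * 85)
        g = np.array([1.0] * 100 + [0.0] * 100)
        r = logistic_adjusted(y, g)
        assert r.or_point == pytest.approx(30 * 85 / (70 * 15), rel=1e-4)

    def test_separation_flagged(self):
        y = np.array([1.0] * 20 + [0.0] * 20)
        g = np.array([2.0] * 20 + [0.0] * 20)
        r = logistic_adjusted(y, g)
        assert r.separation
        assert math.isnan(r.or_point)


class TestInteraction:
    def test_constant_dosage_dropped(self, rng):
        y = rng.integers(0, 2, 100).astype(float)
        a = rng.binomial(2, 0.4, 100).astype(float)
        b = np.ones(100)
        r = glm_interaction(y, a, b)
        assert r.dropped
        assert "constant" in r.reason

    def test_recovery(self):
        rng = np.random.default_rng(3)
        n = 6000
        a = rng.binomial(2, 0.4, n).astype(float)
        b = rng.binomial(2, 0.4, n).astype(float)
        eta = -0.8 + 0.1 * a + 0.1 * b + 0.6 * a * b
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
        r = glm_interaction(y, a, b)
        assert not r.dropped
        assert abs(r.coef - 0.6) < 3 * r.se

    def test_null_rejection_rate(self):
        rej = 0
        reps = 60
        for seed in range(reps):
            rng = np.random.default_rng(10_000 + seed)
            n = 600
            a = rng.binomial(2, 0.4, n).astype(float)
            b = rng.binomial(2, 0.4, n).astype(float)
            eta = -0.3 + 0.2 * a + 0.2 * b
            y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
            r = glm_interaction(y, a, b)
            rej += r.pvalue < 0.05
        assert rej / reps < 0.15


# ---------------------------------------------------------------------------
# pooled summaries


class TestPooled:
    def test_weighted_mean(self):
        assert pooled_mean([565, 965, 673], [12.71, 12.50, 12.46]) == \
            pytest.approx(12.5417, abs=1e-4)

    def test_pooled_mean_sd_matches_raw(self, rng):
        a = rng.normal(0, 1, 40)
        b = rng.normal(2, 3, 60)
        m, sd = pooled_mean_sd(
            [40, 60], [a.mean(), b.mean()], [a.std(ddof=1), b.std(ddof=1)])
        both = np.concatenate([a, b])
        assert m == pytest.approx(both.mean())
        assert sd == pytest.approx(both.std(ddof=1))
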