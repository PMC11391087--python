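import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from neurocohort import (adjusted_residuals, anova_from_summary,
                         benjamini_hochberg, chi_square_test,
                         cohens_d_pairwise, default_sim_config, eta2_to_d,
                         generate_cohort, manova_wilks, oneway_anova,
                         pairwise_comparisons, pearson_correlation)
from neurocohort.inference import StatsError
from neurocohort import printed

DEFICIT_TABLE = printed.DEFICIT_STRATA_COUNTS


def _random_tables(n, shape=(3, 4), seed=0):
    rng = np.random.default_rng(seed)
    return [rng.integers(1, 60, size=shape) for _ in range(n)]


class TestChiSquare:
    def test_deficit_strata_table(self):
        res = chi_square_test(DEFICIT_TABLE)
        assert res.chi2 == pytest.approx(40.56, abs=0.01)
        assert res.df == 9
        assert res.p < 0.001

    def test_proportional_table_is_null(self):
        t = np.outer([10, 20, 30], [2, 3, 5])
        res = chi_square_test(t)
        assert res.chi2 == pytest.approx(0.0, abs=1e-12)
        assert res.cramers_v == pytest.approx(0.0, abs=1e-9)

    def test_matches_direct_formula_and_scipy(self):
        for t in _random_tables(25):
            res = chi_square_test(t)
            # elementwise-sum oracle
            N = t.sum()
            E = np.outer(t.sum(1), t.sum(0)) / N
            oracle = sum((t[i, j] - E[i, j]) ** 2 / E[i, j]
                         for i in range(t.shape[0])
                         for j in range(t.shape[1]))
            assert res.chi2 == pytest.approx(oracle, abs=1e-10)
            chi2, p, df, _ = sps.chi2_contingency(t, correction=False)
            assert res.chi2 == pytest.approx(chi2, rel=1e-12)
            assert res.p == pytest.approx(p, rel=1e-9)
            assert res.df == df

    def test_permutation_invariance(self):
        t = DEFICIT_TABLE
        res = chi_square_test(t)
        perm = chi_square_test(t[::-1][:, ::-1])
        assert perm.chi2 == pytest.approx(res.chi2, rel=1e-12)
        assert perm.cramers_v == pytest.approx(res.cramers_v, rel=1e-12)
        np.testing.assert_allclose(perm.adjusted_residuals,
                                   res.adjusted_residuals[::-1][:, ::-1])

    def test_zero_marginal_rejected(self):
        with pytest.raises(StatsError, match="marginal"):
            chi_square_test([[0, 0], [3, 4]])

    def test_negative_counts_rejected(self):
        with pytest.raises(StatsError):
            chi_square_test([[1, -2], [3, 4]])


class TestAdjustedResiduals:
    def test_deficit_strata_posthocs(self):
        """The childhood-ADHD column shows the published post-hoc pattern:
        excess 3-or-more-deficit cases, shortfall of zero-deficit cases."""
        resid, _, flags = adjusted_residuals(DEFICIT_TABLE)
        assert resid[3, 0] > 0 and flags[3, 0]       # 3plus x cADHD
        assert resid[0, 0] < 0 and flags[0, 0]       # 0 x cADHD
        assert resid[0, 2] > 0 and flags[0, 2]       # 0 x Non-cAP

    def test_proportional_table_zero_residuals(self):
        t = np.outer([10, 20, 30], [2, 3, 5])
        resid, _, flags = adjusted_residuals(t)
        np.testing.assert_allclose(resid, 0.0, atol=1e-9)
        assert not flags.any()

    def test_null_calibration(self):
        """Under independence, adjusted residuals are ~N(0,1): about 5%
        of cells exceed |z| = 1.96."""
        rng = np.random.default_rng(97)
        P = np.outer([0.1, 0.2, 0.3, 0.4], [0.25, 0.25, 0.3, 0.2]).ravel()
        exceed = total = 0
        for _ in range(3000):
            t = rng.multinomial(400, P).reshape(4, 4)
            if (t.sum(0) == 0).any() or (t.sum(1) == 0).any():
                continue
            resid, _, _ = adjusted_residuals(t)
            exceed += int((np.abs(resid) > 1.96).sum())
            total += resid.size
        assert abs(exceed / total - 0.05) < 0.005


class TestAnova:
    def test_identical_groups_give_zero_F(self):
        vals = [1, 2, 3, 1, 2, 3]
        res = oneway_anova(vals, ["a"] * 3 + ["b"] * 3)
        assert res.F == pytest.approx(0.0, abs=1e-12)
        assert res.d == pytest.approx(0.0, abs=1e-9)

    def test_two_group_F_equals_t_squared(self):
        rng = np.random.default_rng(101)
        for _ in range(10):
            a = rng.standard_normal(12)
            b = rng.standard_normal(17) + 0.4
            res = oneway_anova(np.concatenate([a, b]),
                               ["a"] * 12 + ["b"] * 17)
            t = sps.ttest_ind(a, b, equal_var=True).statistic
            assert res.F == pytest.approx(t * t, abs=1e-9)

    def test_matches_scipy_f_oneway(self):
        rng = np.random.default_rng(103)
        samples = [rng.standard_normal(n) + mu
                   for n, mu in [(10, 0), (14, 0.3), (30, -0.2), (8, 0.5)]]
        vals = np.concatenate(samples)
        groups = np.repeat(list("abcd"), [10, 14, 30, 8])
        res = oneway_anova(vals, groups)
        F, p = sps.f_oneway(*samples)
        assert res.F == pytest.approx(F, rel=1e-10)
        assert res.p == pytest.approx(p, rel=1e-9)

    def test_summary_identity_with_raw(self):
        """ANOVA from per-group (n, mean, sd) reproduces the raw-data
        ANOVA exactly: same decomposition, same floating point."""
        rng = np.random.default_rng(107)
        for _ in range(5):
            groups = np.repeat(list("abcd"), [39, 79, 255, 69])
            vals = rng.standard_normal(len(groups)) + \
                np.repeat(rng.uniform(0, 1, 4), [39, 79, 255, 69])
            raw = oneway_anova(vals, groups)
            ns, means, sds = [], [], []
            for g in "abcd":
                x = vals[groups == g]
                ns.append(len(x))
                means.append(x.mean())
                sds.append(x.std(ddof=1))
            summ = anova_from_summary(ns, means, sds)
            assert summ == raw

    def test_group_of_one_rejected(self):
        with pytest.raises(StatsError):
            oneway_anova([1.0, 2.0, 3.0], ["a", "a", "b"])

    def test_length_mismatch_rejected(self):
        with pytest.raises(StatsError, match="equal length"):
            anova_from_summary([3, 3], [1.0, 2.0, 3.0], [1.0, 1.0])


class TestManova:
    def test_single_measure_reduces_to_anova(self):
        rng = np.random.default_rng(109)
        vals = rng.standard_normal(60)
        groups = np.repeat(list("abcd"), 15)
        uni = oneway_anova(vals, groups)
        multi = manova_wilks(vals[:, None], groups)
        assert multi.F_approx == pytest.approx(uni.F, abs=1e-9)
        lam_expected = 1.0 - uni.eta2  # SSw / (SSb + SSw)
        assert multi.wilks_lambda == pytest.approx(lam_expected, abs=1e-12)

    def test_two_group_two_measure_hotelling_equivalence(self):
        """Lambda from the cross-product matrices equals the closed-form
        Hotelling T^2 value 1 / (1 + T^2 / (N - 2))."""
        rng = np.random.default_rng(113)
        X = rng.standard_normal((30, 2))
        g = np.array(["A"] * 14 + ["B"] * 16)
        res = manova_wilks(X, g)
        a, b = X[g == "A"], X[g == "B"]
        na, nb = len(a), len(b)
        S = ((a - a.mean(0)).T @ (a - a.mean(0))
             + (b - b.mean(0)).T @ (b - b.mean(0))) / (na + nb - 2)
        d = a.mean(0) - b.mean(0)
        T2 = (na * nb) / (na + nb) * d @ np.linalg.solve(S, d)
        assert res.wilks_lambda == pytest.approx(
            1.0 / (1.0 + T2 / (na + nb - 2)), rel=1e-12)

    def test_matches_statsmodels(self):
        sm = pytest.importorskip("statsmodels.multivariate.manova")
        rng = np.random.default_rng(127)
        X = rng.standard_normal((80, 3))
        X += np.repeat(rng.standard_normal((4, 3)) * 0.4, 20, axis=0)
        g = np.repeat(list("abcd"), 20)
        res = manova_wilks(X, g)
        df = pd.DataFrame(X, columns=["m1", "m2", "m3"])
        df["g"] = g
        tbl = sm.MANOVA.from_formula(
            "m1 + m2 + m3 ~ g", data=df).mv_test().results["g"]["stat"]
        ref = tbl.loc["Wilks' lambda"]
        assert res.wilks_lambda == pytest.approx(ref["Value"], rel=1e-9)
        assert res.F_approx == pytest.approx(ref["F Value"], rel=1e-9)
        assert res.df1 == ref["Num DF"]
        assert res.df2 == pytest.approx(ref["Den DF"], rel=1e-9)
        assert res.p == pytest.approx(ref["Pr > F"], abs=1e-12)

    def test_design_df_reported_alongside_approx_df(self):
        rng = np.random.default_rng(131)
        X = rng.standard_normal((60, 3))
        res = manova_wilks(X, np.repeat(list("abcd"), 15))
        assert res.df_design == 3
        assert res.df1 == 9

    def test_collinear_measures_rejected(self):
        rng = np.random.default_rng(137)
        x = rng.standard_normal(40)
        X = np.column_stack([x, 2 * x, rng.standard_normal(40)])
        with pytest.raises(StatsError, match="singular"):
            manova_wilks(X, np.repeat(["a", "b"], 20))


class TestBenjaminiHochberg:
    @staticmethod
    def _oracle(p, q):
        """Check every k explicitly and reject all p <= p_(k*)."""
        p = np.asarray(p, float)
        m = len(p)
        s = np.sort(p)
        kstar = 0
        for k in range(1, m + 1):
            if s[k - 1] <= k / m * q:
                kstar = k
        if kstar == 0:
            return np.zeros(m, bool), 0.0
        return p <= s[kstar - 1], s[kstar - 1]

    def test_all_ones_reject_nothing(self):
        flags, crit = benjamini_hochberg([1.0, 1.0, 1.0])
        assert not flags.any() and crit == 0.0

    def test_three_value_example(self):
        flags, crit = benjamini_hochberg([0.001, 0.02, 0.9], q=0.05)
        exp_flags, exp_crit = self._oracle([0.001, 0.02, 0.9], 0.05)
        assert (flags == exp_flags).all()
        assert crit == exp_crit

    def test_matches_oracle_and_statsmodels(self):
        from statsmodels.stats.multitest import multipletests
        rng = np.random.default_rng(139)
        for _ in range(50):
            p = rng.uniform(size=rng.integers(1, 40)) ** 2
            flags, crit = benjamini_hochberg(p, q=0.05)
            oflags, ocrit = self._oracle(p, 0.05)
            assert (flags == oflags).all() and crit == ocrit
            ref = multipletests(p, alpha=0.05, method="fdr_bh")[0]
            assert (flags == ref).all()

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1,
                    max_size=40))
    def test_rejections_monotone_in_q(self, pvals):
        low, _ = benjamini_hochberg(pvals, q=0.05)
        high, _ = benjamini_hochberg(pvals, q=0.10)
        assert (high | ~low).all()  # rejections at 0.05 subset of at 0.10

    def test_invalid_p_rejected(self):
        with pytest.raises(StatsError):
            benjamini_hochberg([0.5, 1.5])


class TestEffectSizes:
    def test_identical_samples_give_zero_d(self):
        assert cohens_d_pairwise([1, 2, 3], [1, 2, 3]) == 0.0

    def test_one_pooled_sd_shift_gives_d_one(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        sd = a.std(ddof=1)
        assert cohens_d_pairwise(a + sd, a) == pytest.approx(1.0, abs=1e-9)

    def test_matches_direct_formula(self):
        rng = np.random.default_rng(149)
        a, b = rng.standard_normal(20), rng.standard_normal(31) + 0.5
        pooled = np.sqrt((19 * a.var(ddof=1) + 30 * b.var(ddof=1)) / 49)
        assert cohens_d_pairwise(a, b) == pytest.approx(
            (a.mean() - b.mean()) / pooled, rel=1e-12)

    def test_eta2_conversion_reproduces_published_d(self):
        """d = 2 sqrt(eta2/(1-eta2)) maps the summary-ANOVA eta2 onto the
        published d for the untransformed measures."""
        ns = [printed.GROUP_NS[g] for g in printed.GROUPS]
        for measure, (F_pub, d_pub) in [("coding", (13.04, 0.60)),
                                        ("similarities", (8.19, 0.47))]:
            stats_ = printed.MEASURE_STATS[measure]
            res = anova_from_summary(
                ns, [stats_[g][0] for g in printed.GROUPS],
                [stats_[g][1] for g in printed.GROUPS])
            assert eta2_to_d(res.eta2) == pytest.approx(d_pub, abs=0.01)

    def test_zero_pooled_sd_rejected(self):
        with pytest.raises(StatsError):
            cohens_d_pairwise([1.0, 1.0], [1.0, 1.0])


class TestPairwise:
    def test_full_battery_has_126_comparisons(self):
        cohort = generate_cohort(default_sim_config(seed=151))
        results, crit = pairwise_comparisons(cohort)
        assert len(results) == 126
        pairs = {r.pair for r in results}
        assert len(pairs) == 6
        assert 0.0 <= crit <= 1.0

    def test_identical_groups_nothing_significant(self, battery):
        rng = np.random.default_rng(157)
        from conftest import make_cohort
        groups = ["cADHD"] * 30 + ["Control"] * 30
        cohort = make_cohort(
            battery, groups,
            scores={m: rng.standard_normal(60)
                    for m in battery.measure_names})
        results, crit = pairwise_comparisons(cohort)
        assert not any(r.significant for r in results)

    def test_significance_set_is_bh_of_own_pvalues(self):
        cohort = generate_cohort(default_sim_config(seed=163))
        results, crit = pairwise_comparisons(cohort)
        p = np.array([r.p for r in results])
        oflags, ocrit = TestBenjaminiHochberg._oracle(p, 0.05)
        assert crit == ocrit
        assert all(r.significant == bool(f)
                   for r, f in zip(results, oflags))

    def test_d_sign_matches_mean_difference(self):
        cohort = generate_cohort(default_sim_config(seed=167))
        results, _ = pairwise_comparisons(cohort)
        for r in results:
            if r.mean_diff != 0:
                assert np.sign(r.d) == np.sign(r.mean_diff)

    def test_welch_vs_pooled_toggle(self):
        cohort = generate_cohort(default_sim_config(seed=173))
        welch, _ = pairwise_comparisons(cohort, measures=["coding"])
        pooled, _ = pairwise_comparisons(cohort, measures=["coding"],
                                         welch=False)
        assert any(abs(a.t - b.t) > 1e-9 for a, b in zip(welch, pooled))


class TestCorrelation:
    def test_perfect_linear(self):
        x = np.arange(10.0)
        assert pearson_correlation(x, 2 * x + 1).r == pytest.approx(1.0)
        assert pearson_correlation(x, -x).r == pytest.approx(-1.0)

    def test_matches_numpy_and_scipy(self):
        rng = np.random.default_rng(179)
        x, y = rng.standard_normal(200), rng.standard_normal(200)
        res = pearson_correlation(x, y)
        assert res.r == pytest.approx(np.corrcoef(x, y)[0, 1], abs=1e-12)
        ref = sps.pearsonr(x, y)
        assert res.p == pytest.approx(ref.pvalue, rel=1e-9)

    def test_pairwise_complete_deletion(self):
        x = np.array([1.0, 2.0, np.nan, 4.0, 5.0])
        y = np.array([2.0, 4.0, 6.0, np.nan, 10.0])
        res = pearson_correlation(x, y)
        assert res.n == 3
        assert res.r == pytest.approx(1.0)

    def test_zero_variance_rejected(self):
        with pytest.raises(StatsError):
            pearson_correlation([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
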