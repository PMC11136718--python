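"""Statistical primitives against closed-form and brute-force oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from cortexdiff import stats
from cortexdiff.errors import DegenerateDataError


class TestWelchT:
    def test_cohort_age_worked_example(self):
        """Welch t for age, 48 controls vs 176 patients, from summary stats."""
        res = stats.welch_t_from_stats(50.83, 7.04, 48, 54.24, 9.11, 176)
        assert res.statistic == pytest.approx(-2.78, abs=0.01)
        assert res.df == pytest.approx(94.4, abs=0.1)

    def test_identical_groups_give_zero(self):
        res = stats.welch_t_from_stats(5.0, 1.0, 10, 5.0, 2.0, 12)
        assert res.statistic == 0.0

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_defining_formulas(self, seed):
        rng = np.random.default_rng(seed)
        m1, m2 = rng.normal(size=2)
        s1, s2 = rng.uniform(0.5, 3, 2)
        n1, n2 = rng.integers(3, 50, 2)
        res = stats.welch_t_from_stats(m1, s1, n1, m2, s2, n2)
        v1, v2 = s1**2 / n1, s2**2 / n2
        t = (m1 - m2) / np.sqrt(v1 + v2)
        df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
        assert res.statistic == pytest.approx(t, rel=1e-10)
        assert res.df == pytest.approx(df, rel=1e-10)
        assert res.p_raw == pytest.approx(2 * sps.t.sf(abs(t), df), rel=1e-10)

    def test_sample_version_agrees_with_summary_version(self, rng):
        x = rng.normal(0, 1, 30)
        y = rng.normal(0.5, 2, 40)
        a = stats.welch_t(x, y)
        b = stats.welch_t_from_stats(
            x.mean(), x.std(ddof=1), 30, y.mean(), y.std(ddof=1), 40
        )
        assert a.statistic == pytest.approx(b.statistic, rel=1e-10)


class TestPooledT:
    def test_df_is_sum_minus_two(self):
        res = stats.pooled_t_from_stats(0.0, 0.95, 48, -0.62, 1.15, 176)
        assert res.df == 222

    def test_equal_means_give_zero(self):
        assert stats.pooled_t_from_stats(1.0, 1.0, 5, 1.0, 2.0, 7).statistic == 0.0

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_brute_force_formula(self, seed):
        rng = np.random.default_rng(seed)
        x, y = rng.normal(size=12), rng.normal(1, 1.5, 20)
        res = stats.pooled_t(x, y)
        sp2 = ((11) * x.var(ddof=1) + 19 * y.var(ddof=1)) / 30
        t = (x.mean() - y.mean()) / np.sqrt(sp2 * (1 / 12 + 1 / 20))
        assert res.statistic == pytest.approx(t, rel=1e-10)

    def test_levene_screen_picks_welch_under_unequal_variance(self, rng):
        x = rng.normal(0, 1, 200)
        y = rng.normal(0, 5, 200)
        assert stats.choose_t(x, y).test_name == "welch_t"
        z = rng.normal(0, 1, 200)
        assert stats.choose_t(x, z).test_name == "pooled_t"


class TestChiSquare:
    @pytest.mark.parametrize(
        "table, expected",
        [
            ([[27, 21], [118, 58]], 1.93),   # sex split, HC vs MS
            ([[26, 22], [73, 103]], 2.46),   # high education, HC vs MS
        ],
    )
    def test_cohort_worked_examples(self, table, expected):
        res = stats.pearson_chi_square(table)
        assert res.statistic == pytest.approx(expected, abs=0.01)
        assert res.df == 1

    def test_subtype_by_subgroup_example(self):
        table = [[65, 19, 11], [21, 11, 5], [25, 12, 7]]
        res = stats.pearson_chi_square(table)
        assert res.df == 4
        assert res.statistic == pytest.approx(2.72, abs=0.05)

    def test_table_proportional_to_margins_gives_zero(self):
        assert stats.pearson_chi_square([[10, 20], [30, 60]]).statistic == (
            pytest.approx(0.0, abs=1e-12)
        )

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_direct_summation_oracle(self, seed):
        rng = np.random.default_rng(seed)
        obs = rng.integers(5, 50, (3, 3)).astype(float)
        res = stats.pearson_chi_square(obs)
        row, col = obs.sum(1, keepdims=True), obs.sum(0, keepdims=True)
        exp = row @ col / obs.sum()
        assert res.statistic == pytest.approx(((obs - exp) ** 2 / exp).sum(), rel=1e-12)

    def test_zero_marginal_rejected(self):
        with pytest.raises(DegenerateDataError):
            stats.pearson_chi_square([[0, 0], [3, 4]])


class TestPairedT:
    def test_df_for_154_pairs(self, rng):
        a = rng.normal(1.08, 0.08, 154)
        b = a - rng.normal(0.02, 0.03, 154)
        assert stats.paired_t(a, b).df == 153

    def test_identical_pairs_give_zero(self, rng):
        a = rng.normal(size=10)
        res = stats.paired_t(a, a.copy())
        assert res.statistic == 0.0 and res.p_raw == 1.0

    def test_constant_nonzero_differences_degenerate(self):
        with pytest.raises(DegenerateDataError):
            stats.paired_t([1.0, 2.0, 3.0], [0.0, 1.0, 2.0])

    def test_reduces_to_one_sample_t_on_differences(self, rng):
        a, b = rng.normal(size=25), rng.normal(size=25)
        res = stats.paired_t(a, b)
        one = sps.ttest_1samp(a - b, 0.0)
        assert res.statistic == pytest.approx(one.statistic, rel=1e-12)
        assert res.p_raw == pytest.approx(one.pvalue, rel=1e-12)


class TestRankTests:
    def test_fully_separated_samples_give_zero_u(self):
        assert stats.mann_whitney_u([1, 2, 3], [10, 11, 12, 13]).statistic == 0.0

    def test_identical_samples_give_half_product(self):
        res = stats.mann_whitney_u([1, 2, 3], [1, 2, 3])
        assert res.statistic == pytest.approx(3 * 3 / 2)

    @pytest.mark.parametrize("seed", range(4))
    def test_u_equals_pair_count_oracle(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.integers(0, 6, 8).astype(float)
        y = rng.integers(0, 6, 11).astype(float)
        u = sum(
            1.0 if xi > yj else (0.5 if xi == yj else 0.0) for xi in x for yj in y
        )
        assert stats.mann_whitney_u(x, y).statistic == pytest.approx(u)

    def test_kruskal_wallis_matches_scipy_and_df(self, rng):
        g = [rng.normal(loc, 1, 20) for loc in (0, 0.5, 1)]
        res = stats.kruskal_wallis(*g)
        assert res.df == 2
        assert res.statistic == pytest.approx(sps.kruskal(*g).statistic, rel=1e-12)


class TestGlmGroupF:
    def _data(self, n=176, groups=("CP", "mildly_CI", "CI"), effect=0.0, seed=0):
        rng = np.random.default_rng(seed)
        g = pd.Series(rng.choice(groups, n))
        cov = pd.DataFrame(
            {
                "age": rng.normal(54, 9, n),
                "sex_female": rng.integers(0, 2, n),
                "educ_high": rng.integers(0, 2, n),
            }
        )
        shift = {gr: i * effect for i, gr in enumerate(groups)}
        y = pd.Series(g.map(shift).astype(float) + rng.normal(0, 1, n))
        return y, g, cov

    def test_residual_df_arithmetic(self):
        y, g, cov = self._data(n=176)
        res = stats.glm_group_f(y, g, cov)
        assert res.df == (2.0, 170.0)  # 176 - 1 - 2 - 3

    def test_zero_group_effect_in_noiseless_data(self):
        g = pd.Series(["a"] * 10 + ["b"] * 10)
        cov = pd.DataFrame({"age": np.arange(20, dtype=float)})
        y = 2.0 + 0.5 * cov["age"]  # no group dependence, no noise
        res = stats.glm_group_f(y, g, cov)
        assert res.statistic == pytest.approx(0.0, abs=1e-8)

    def test_matches_statsmodels_anova_f(self):
        import statsmodels.formula.api as smf
        from statsmodels.stats.anova import anova_lm

        y, g, cov = self._data(n=120, effect=0.4, seed=3)
        res = stats.glm_group_f(y, g, cov)
        frame = cov.copy()
        frame["y"], frame["g"] = y, g
        frame["age"] = frame["age"] - frame["age"].mean()
        fit = smf.ols("y ~ C(g) + age + sex_female + educ_high", frame).fit()
        tab = anova_lm(fit, typ=3)
        assert res.statistic == pytest.approx(tab.loc["C(g)", "F"], rel=1e-8)

    def test_effect_size_and_posthoc_reported(self):
        y, g, cov = self._data(effect=0.8, seed=1)
        res = stats.glm_group_f(y, g, cov)
        assert res.effect_name == "partial_eta2"
        assert 0 < res.effect_size < 1
        assert set(res.extra["posthoc"]) == {"CI_vs_CP", "mildly_CI_vs_CP"}
        ph = res.extra["posthoc"]["CI_vs_CP"]
        assert ph["ci_low"] < ph["mean_diff"] < ph["ci_high"]

    def test_singular_design_rejected(self):
        g = pd.Series(["a"] * 5 + ["b"] * 5)
        cov = pd.DataFrame({"c1": [1.0] * 10})  # collinear with intercept
        with pytest.raises(DegenerateDataError):
            stats.glm_group_f(pd.Series(np.arange(10.0)), g, cov)


class TestMultinomialLogistic:
    def test_two_by_two_cross_product_oracle(self, rng):
        """Binary predictor, two populated levels: OR = ad/bc exactly at MLE."""
        n = (40, 25, 15, 30)  # (y=CP,x=0) (CP,1) (CI,0) (CI,1)
        y = ["CP"] * (n[0] + n[1]) + ["CI"] * (n[2] + n[3])
        x = [0] * n[0] + [1] * n[1] + [0] * n[2] + [1] * n[3]
        fits = stats.multinomial_logistic(
            pd.Series(y), pd.Series(x, dtype=float), reference_level="CP"
        )
        or_oracle = (n[0] * n[3]) / (n[1] * n[2])
        assert fits["CI"].effect_size == pytest.approx(or_oracle, rel=1e-5)
        assert fits["CI"].ci_low < or_oracle < fits["CI"].ci_high

    def test_null_predictor_or_near_one(self):
        rng = np.random.default_rng(0)
        n = 4000
        y = pd.Series(rng.choice(["CP", "mildly_CI", "CI"], n))
        x = pd.Series(rng.normal(size=n))
        fits = stats.multinomial_logistic(y, x, reference_level="CP")
        for lvl in ("mildly_CI", "CI"):
            assert 0.85 < fits[lvl].effect_size < 1.18
            assert fits[lvl].ci_low < fits[lvl].effect_size < fits[lvl].ci_high

    def test_wald_ci_coverage_for_known_slope(self):
        """95% Wald CIs cover a true log-odds slope of 0.8 in >= 90% of reps."""
        rng = np.random.default_rng(7)
        hits = reps = 0
        for _ in range(100):
            n = 800
            x = rng.normal(size=n)
            logits = np.c_[np.zeros(n), -0.5 + 0.8 * x, -0.5 + 0.8 * x]
            p = np.exp(logits)
            p /= p.sum(1, keepdims=True)
            y = (rng.random((n, 1)) > p.cumsum(1)).sum(1)
            labels = pd.Series(np.array(["CP", "mildly_CI", "CI"])[y])
            try:
                fits = stats.multinomial_logistic(
                    labels, pd.Series(x), reference_level="CP"
                )
            except stats.ConvergenceError:
                continue
            reps += 1
            if fits["CI"].ci_low <= np.exp(0.8) <= fits["CI"].ci_high:
                hits += 1
        assert reps >= 90
        assert hits / reps >= 0.90


class TestCorrectionsAndTransforms:
    def test_bonferroni_monotone_and_capped(self):
        assert stats.bonferroni(0.01, 3) == pytest.approx(0.03)
        assert stats.bonferroni(0.6, 5) == 1.0
        assert stats.bonferroni(0.2, 1) == pytest.approx(0.2)

    def test_log1p_examples_and_roundtrip(self, rng):
        assert stats.log1p_transform(0.0) == 0.0
        assert stats.log1p_transform(np.e - 1) == pytest.approx(1.0)
        x = rng.random(100) * 50
        assert np.allclose(stats.log1p_inverse(stats.log1p_transform(x)), x, atol=1e-12)
        with pytest.raises(ValueError):
            stats.log1p_transform([-0.1])

    def test_normality_screen_calibration(self):
        rng = np.random.default_rng(3)
        normal_flags = sum(
            stats.normality_screen(rng.normal(size=500)).extra["normal"]
            for _ in range(200)
        )
        assert normal_flags >= 180  # >= 90% of clean normal samples pass
        nonnormal_flags = sum(
            not stats.normality_screen(rng.exponential(size=200)).extra["normal"]
            for _ in range(200)
        )
        assert nonnormal_flags >= 190  # >= 95% power against exponential

    def test_constant_vector_flagged_degenerate(self):
        res = stats.normality_screen([2.0] * 20)
        assert not res.extra["normal"] and res.extra["degenerate"]

    def test_percent_increase_conventions(self):
        ref, other = [2.0, 4.0, 6.0], [3.0, 6.0, 9.0]
        assert stats.percent_increase(ref, other, "median") == pytest.approx(50.0)
        lm = stats.percent_increase(ref, other, "log_mean")
        expected = 100 * (
            np.expm1(np.mean(np.log1p(other)) - np.mean(np.log1p(ref)))
        )
        assert lm == pytest.approx(expected)
        with pytest.raises(DegenerateDataError):
            stats.percent_increase([0.0, 0.0, 0.0], other, "median")


class TestBackwardRegression:
    def test_true_predictor_retained_noise_dropped(self):
        rng = np.random.default_rng(0)
        kept = 0
        for _ in range(30):
            n = 500
            X = pd.DataFrame(rng.normal(size=(n, 3)), columns=["true", "n1", "n2"])
            y = pd.Series(-0.5 * X["true"] + rng.normal(0, np.sqrt(1 - 0.25), n))
            model = stats.backward_regression(y, X)
            if model.retained == ["true"]:
                kept += 1
        assert kept >= 27  # 90% of reps

    def test_perfectly_linear_outcome(self, rng):
        X = pd.DataFrame({"x": rng.normal(size=50)})
        y = pd.Series(3.0 - 2.0 * X["x"])
        model = stats.linear_model(y, X)
        assert model.adj_r2 == pytest.approx(1.0)
        assert model.terms["x"].effect_size == pytest.approx(-1.0)

    def test_all_noise_candidates_usually_eliminated(self):
        rng = np.random.default_rng(1)
        empty = 0
        reps = 100
        for _ in range(reps):
            X = pd.DataFrame(rng.normal(size=(200, 3)), columns=list("abc"))
            y = pd.Series(rng.normal(size=200))
            if not stats.backward_regression(y, X).retained:
                empty += 1
        # roughly (1 - 0.05)^3 ~ 86% of null runs keep nothing
        assert 0.75 <= empty / reps <= 0.95

    def test_standardized_beta_matches_zscored_fit(self, rng):
        n = 300
        X = pd.DataFrame(rng.normal(size=(n, 2)), columns=["a", "b"])
        y = pd.Series(0.7 * X["a"] - 0.2 * X["b"] + rng.normal(size=n))
        model = stats.linear_model(y, X)
        import statsmodels.api as sm

        zx = (X - X.mean()) / X.std(ddof=1)
        zy = (y - y.mean()) / y.std(ddof=1)
        fit = sm.OLS(zy, sm.add_constant(zx)).fit()
        assert model.terms["a"].effect_size == pytest.approx(fit.params["a"], rel=1e-10)
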