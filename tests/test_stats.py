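import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sdohmpi.stats import (
    fit_logistic,
    oneway_anova_posthoc,
    spearman_matrix,
    table1_builder,
    tjur_r2,
    welch_t_test,
    yates_chi_square,
)


def _design_from_2x2(a, b, c, d):
    """Outcome/predictor vectors for a 2x2 table: exposed cases a, exposed
    non-cases b, unexposed cases c, unexposed non-cases d."""
    y = np.array([1] * a + [0] * b + [1] * c + [0] * d)
    x = np.array([1] * (a + b) + [0] * (c + d))
    return y, pd.DataFrame({"x": x})


class TestLogistic:
    def test_saturated_2x2_equals_cross_product_or(self):
        y, X = _design_from_2x2(10, 5, 5, 10)
        fit = fit_logistic(y, X)
        assert fit.odds_ratios["x"] == pytest.approx(4.0, rel=1e-6)
        assert fit.converged
        lo, hi = fit.ci95.loc["x"]
        assert lo < 4.0 < hi

    @given(st.tuples(*[st.integers(3, 40)] * 4))
    @settings(max_examples=40, deadline=None)
    def test_cross_product_property(self, cells):
        a, b, c, d = cells
        y, X = _design_from_2x2(a, b, c, d)
        fit = fit_logistic(y, X)
        assert fit.odds_ratios["x"] == pytest.approx(a * d / (b * c), rel=1e-5)

    def test_null_large_n(self):
        rng = np.random.default_rng(0)
        y = rng.integers(0, 2, size=5_000)
        X = pd.DataFrame({"noise": rng.standard_normal(5_000)})
        fit = fit_logistic(y, X)
        assert fit.odds_ratios["noise"] == pytest.approx(1.0, abs=0.1)
        assert abs(fit.tjur_r2) < 0.01

    def test_intercept_only_recovers_prevalence(self):
        y = np.array([1] * 30 + [0] * 70)
        fit = fit_logistic(y, pd.DataFrame(index=range(100)))
        assert fit.fitted.iloc[0] == pytest.approx(0.3, abs=1e-8)

    def test_perfect_separation_flagged_not_raised(self):
        y = np.array([1] * 20 + [0] * 20)
        X = pd.DataFrame({"x": y.astype(float)})
        fit = fit_logistic(y, X)
        assert not fit.converged
        assert fit.tjur_r2 == pytest.approx(1.0, abs=1e-3)

    def test_one_class_outcome_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            fit_logistic(np.ones(10), pd.DataFrame({"x": np.arange(10.0)}))


class TestTjur:
    def test_hand_fixture(self):
        assert tjur_r2([1, 1, 0, 0], [0.8, 0.6, 0.4, 0.2]) == pytest.approx(0.4)

    def test_constant_probability_zero(self):
        assert tjur_r2([1, 0, 1, 0], [0.5] * 4) == 0.0

    def test_perfect_fit_one(self):
        assert tjur_r2([1, 0, 1], [1.0, 0.0, 1.0]) == 1.0


class TestYatesChiSquare:
    def test_pinned_sex_by_cognitive_status(self):
        """Printed sex x MoCA-status counts reproduce p = 0.577 only under
        the continuity-corrected statistic."""
        res = yates_chi_square([[44, 163], [26, 79]])
        assert res.p_value == pytest.approx(0.577, abs=5e-4)
        assert res.df == 1
        uncorrected = yates_chi_square([[44, 163], [26, 79]], correction=False)
        assert abs(uncorrected.p_value - 0.577) > 0.05

    def test_hand_computed_value(self):
        # (20,10;10,20): chi2_yates = 60*(|20*20-10*10|-30)^2/(30*30*30*30)
        expected = 60 * (abs(400 - 100) - 30) ** 2 / 30**4
        res = yates_chi_square([[20, 10], [10, 20]])
        assert res.statistic == pytest.approx(expected, rel=1e-10)

    def test_identical_rows_p_one(self):
        res = yates_chi_square([[25, 75], [25, 75]])
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError, match="margin"):
            yates_chi_square([[0, 0], [5, 5]])


class TestWelch:
    def test_identical_groups(self):
        res = welch_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.p_value == pytest.approx(1.0)

    def test_separated_groups(self):
        res = welch_t_test([0, 0, 1, 1], [10, 10, 11, 11])
        assert res.p_value < 1e-6

    def test_formula_oracle(self, rng):
        x = rng.normal(0, 1, 30)
        y = rng.normal(0.5, 2, 40)
        res = welch_t_test(x, y)
        # direct evaluation of the Welch statistic and Satterthwaite df
        vx, vy = x.var(ddof=1) / len(x), y.var(ddof=1) / len(y)
        t = (x.mean() - y.mean()) / np.sqrt(vx + vy)
        df = (vx + vy) ** 2 / (vx**2 / (len(x) - 1) + vy**2 / (len(y) - 1))
        assert res.statistic == pytest.approx(t, abs=1e-12)
        assert res.df == pytest.approx(df, abs=1e-9)


class TestAnova:
    def test_identical_groups(self):
        values = np.tile([1.0, 2.0, 3.0], 3)
        groups = np.repeat(["a", "b", "c"], 3)
        omni, pairwise = oneway_anova_posthoc(values, groups)
        assert omni.statistic == pytest.approx(0.0, abs=1e-12)
        assert omni.p_value == pytest.approx(1.0)
        assert (pairwise["p_adjusted"].astype(float) > 0.9).all()

    def test_f_matches_hand_decomposition(self):
        values = np.array([1.0, 2.0, 3.0, 6.0, 7.0, 8.0, 11.0, 12.0, 13.0])
        groups = np.repeat(["a", "b", "c"], 3)
        omni, _ = oneway_anova_posthoc(values, groups)
        grand = values.mean()
        ss_between = 3 * sum((values[groups == g].mean() - grand) ** 2 for g in "abc")
        ss_within = sum(
            ((values[groups == g] - values[groups == g].mean()) ** 2).sum() for g in "abc"
        )
        f = (ss_between / 2) / (ss_within / 6)
        assert omni.statistic == pytest.approx(f, rel=1e-10)

    def test_bonferroni_is_m_times_raw(self, rng):
        values = np.concatenate([rng.normal(m, 1, 10) for m in (0, 0.5, 2)])
        groups = np.repeat(["a", "b", "c"], 10)
        _, pairwise = oneway_anova_posthoc(values, groups, method="bonferroni")
        row = pairwise[(pairwise.group1 == "a") & (pairwise.group2 == "b")].iloc[0]
        raw = welch_t_test(values[groups == "a"], values[groups == "b"]).p_value
        assert row["p_adjusted"] == pytest.approx(min(1.0, 3 * raw), rel=1e-10)

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            oneway_anova_posthoc([1.0, 2.0], ["a", "a"])


class TestSpearman:
    def test_identical_and_complementary_columns(self):
        df = pd.DataFrame({"a": [0, 1, 0, 1, 1, 0]})
        df["same"] = df["a"]
        df["flip"] = 1 - df["a"]
        rho = spearman_matrix(df)
        assert rho.loc["a", "same"] == pytest.approx(1.0)
        assert rho.loc["a", "flip"] == pytest.approx(-1.0)
        assert (np.diag(rho) == 1.0).all()

    def test_binary_rho_equals_phi(self, rng):
        a = rng.integers(0, 2, 300)
        b = (rng.random(300) < 0.3 + 0.4 * a).astype(int)
        rho = spearman_matrix(pd.DataFrame({"a": a, "b": b})).loc["a", "b"]
        # phi from the 2x2 table
        n11 = ((a == 1) & (b == 1)).sum()
        n10 = ((a == 1) & (b == 0)).sum()
        n01 = ((a == 0) & (b == 1)).sum()
        n00 = ((a == 0) & (b == 0)).sum()
        phi = (n11 * n00 - n10 * n01) / np.sqrt(
            (n11 + n10) * (n01 + n00) * (n11 + n01) * (n10 + n00)
        )
        assert rho == pytest.approx(phi, abs=1e-10)

    def test_constant_column_flagged_missing(self):
        df = pd.DataFrame({"a": [0, 1, 0, 1], "b": [1, 1, 1, 1]})
        rho = spearman_matrix(df)
        assert np.isnan(rho.loc["a", "b"])
        assert rho.loc["b", "b"] == 1.0


class TestTable1:
    def test_count_percent_formatting(self):
        cohort = pd.DataFrame(
            {
                "status": ["CN"] * 207 + ["PCI"] * 105,
                "sex": ["male"] * 44 + ["female"] * 163 + ["male"] * 26 + ["female"] * 79,
                "age": np.linspace(45, 92, 312),
            }
        )
        table = table1_builder(cohort, "status", ["sex"], ["age"])
        male = table[(table.variable == "sex") & (table.level == "male")].iloc[0]
        assert male["stratum_CN"] == "44 (21.3%)"
        assert male["stratum_PCI"] == "26 (24.8%)"
        sex_p = table[table.variable == "sex"].p_value.dropna().iloc[0]
        assert sex_p == pytest.approx(0.577, abs=5e-4)

    def test_continuous_row_matches_direct_computation(self, rng):
        cohort = pd.DataFrame(
            {"status": np.repeat(["a", "b"], 50), "age": rng.normal(65, 8, 100)}
        )
        table = table1_builder(cohort, "status", [], ["age"])
        mean_row = table[table.level == "mean_sd"].iloc[0]
        g = cohort.loc[cohort.status == "a", "age"]
        assert mean_row["stratum_a"] == f"{g.mean():.1f} ({g.std(ddof=1):.2f})"
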