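"""Inferential layer: logistic models, bivariate tests, ANOVA, overlap.

Logistic regressions of the binary cognitive outcomes on the deprivation
burden (plus covariates) are reported as odds ratios with Wald 95%
intervals and the Tjur discrimination coefficient (mean fitted probability
among cases minus non-cases).  Descriptive-table tests follow the cohort
table conventions: Welch t-test for continuous rows, continuity-corrected
(Yates) chi-square for categorical rows.  Indicator overlap is summarised
by the pairwise Spearman rank correlation (phi on binary columns).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from statsmodels.stats.multicomp import pairwise_tukeyhsd
from statsmodels.tools.sm_exceptions import PerfectSeparationWarning

__all__ = [
    "ModelFit",
    "BivariateTestResult",
    "fit_logistic",
    "tjur_r2",
    "yates_chi_square",
    "welch_t_test",
    "oneway_anova_posthoc",
    "spearman_matrix",
    "table1_builder",
]


@dataclass(frozen=True)
class ModelFit:
    """Logistic fit summarised on the odds-ratio scale."""

    terms: pd.Series  # coefficients, log-odds scale
    odds_ratios: pd.Series
    ci95: pd.DataFrame  # columns: low, high (exponentiated Wald)
    p_values: pd.Series
    tjur_r2: float
    n: int
    converged: bool
    fitted: pd.Series = field(repr=False, default=None)

    def tidy(self) -> pd.DataFrame:
        """Table-2-style layout: term, OR, CI bounds, p."""
        out = pd.DataFrame(
            {
                "term": self.terms.index,
                "coef": self.terms.values,
                "odds_ratio": self.odds_ratios.values,
                "ci_low": self.ci95["low"].values,
                "ci_high": self.ci95["high"].values,
                "p_value": self.p_values.values,
            }
        )
        out["n"] = self.n
        out["tjur_r2"] = self.tjur_r2
        return out


@dataclass(frozen=True)
class BivariateTestResult:
    statistic: float
    df: float
    p_value: float
    method: str


def tjur_r2(outcome, fitted_probabilities) -> float:
    """Tjur's coefficient of discrimination.

    Mean fitted probability among cases minus mean among non-cases.
    """
    y = np.asarray(outcome, dtype=float)
    p = np.asarray(fitted_probabilities, dtype=float)
    if not ((y == 1).any() and (y == 0).any()):
        raise ValueError("Tjur R2 needs both outcome classes")
    return float(p[y == 1].mean() - p[y == 0].mean())


def fit_logistic(outcome, predictors: pd.DataFrame) -> ModelFit:
    """Maximum-likelihood logistic regression with Wald intervals.

    ``predictors`` holds named numeric columns; an intercept is added.
    Perfect separation is flagged via ``converged=False`` (with the fit
    still returned) rather than raised.
    """
    y = pd.Series(np.asarray(outcome, dtype=float))
    X = pd.DataFrame(predictors).reset_index(drop=True).astype(float)
    y = y.reset_index(drop=True)
    if not ((y == 1).any() and (y == 0).any()):
        raise ValueError("outcome must contain both classes")
    if len(y) <= X.shape[1] + 1:
        raise ValueError("more terms than observations")
    Xc = sm.add_constant(X, has_constant="add")
    converged = True
    with warnings.catch_warnings():
        warnings.simplefilter("error", PerfectSeparationWarning)
        try:
            fit = sm.GLM(y, Xc, family=sm.families.Binomial()).fit(maxiter=200)
            converged = bool(fit.converged)
        except (PerfectSeparationWarning, Exception):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = sm.GLM(y, Xc, family=sm.families.Binomial()).fit(
                    maxiter=50, tol=1e-6
                )
            converged = False
    params = fit.params
    se = fit.bse
    # extreme SEs also signal (quasi-)separation
    if not np.all(np.isfinite(se)) or np.any(se > 1e3):
        converged = False
    z = sps.norm.ppf(0.975)
    with np.errstate(over="ignore"):  # separated fits: CI bound -> inf
        ci = pd.DataFrame(
            {"low": np.exp(params - z * se), "high": np.exp(params + z * se)},
            index=params.index,
        )
    pvals = pd.Series(2 * sps.norm.sf(np.abs(params / se)), index=params.index)
    fitted = pd.Series(np.asarray(fit.fittedvalues), index=Xc.index)
    return ModelFit(
        terms=params,
        odds_ratios=np.exp(params),
        ci95=ci,
        p_values=pvals,
        tjur_r2=tjur_r2(y, fitted),
        n=len(y),
        converged=converged,
        fitted=fitted,
    )


def yates_chi_square(table, correction: bool = True) -> BivariateTestResult:
    """Continuity-corrected chi-square on a 2x2 (or RxC) count table."""
    t = np.asarray(table, dtype=float)
    if (t < 0).any():
        raise ValueError("counts must be nonnegative")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise ValueError("zero margin in contingency table")
    res = sps.chi2_contingency(t, correction=correction)
    method = "yates_chi_square" if correction else "pearson_chi_square"
    return BivariateTestResult(
        statistic=float(res.statistic), df=float(res.dof),
        p_value=float(res.pvalue), method=method,
    )


def welch_t_test(x, y, pooled: bool = False) -> BivariateTestResult:
    """Two-sample t-test, Welch (Satterthwaite df) by default."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x, y = x[~np.isnan(x)], y[~np.isnan(y)]
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each group needs n >= 2")
    if np.std(x, ddof=1) == 0 and np.std(y, ddof=1) == 0:
        if np.mean(x) == np.mean(y):
            return BivariateTestResult(0.0, float(len(x) + len(y) - 2), 1.0, "t_test")
        raise ValueError("degenerate variance in both groups")
    res = sps.ttest_ind(x, y, equal_var=pooled)
    df = res.df if hasattr(res, "df") else len(x) + len(y) - 2
    return BivariateTestResult(
        statistic=float(res.statistic), df=float(df), p_value=float(res.pvalue),
        method="pooled_t_test" if pooled else "welch_t_test",
    )


def oneway_anova_posthoc(
    values, groups, method: str = "tukey", alpha: float = 0.05
) -> tuple[BivariateTestResult, pd.DataFrame]:
    """One-way ANOVA with adjusted pairwise post-hoc comparisons.

    ``method`` is ``"tukey"`` (Tukey HSD, default) or ``"bonferroni"``
    (Welch pairwise p-values multiplied by the number of comparisons).
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    levels = pd.unique(groups)
    if len(levels) < 2:
        raise ValueError("ANOVA needs at least 2 groups")
    samples = [values[groups == g] for g in levels]
    if any(len(s) < 2 for s in samples):
        raise ValueError("every group needs n >= 2")
    if all(np.std(s, ddof=1) == 0 for s in samples) and len({s.mean() for s in samples}) == 1:
        omnibus = BivariateTestResult(0.0, float(len(levels) - 1), 1.0, "oneway_anova")
    else:
        f = sps.f_oneway(*samples)
        omnibus = BivariateTestResult(
            statistic=float(f.statistic), df=float(len(levels) - 1),
            p_value=float(f.pvalue), method="oneway_anova",
        )
    if method == "tukey":
        hsd = pairwise_tukeyhsd(values, groups, alpha=alpha)
        pairwise = pd.DataFrame(
            hsd.summary().data[1:], columns=hsd.summary().data[0]
        )[["group1", "group2", "meandiff", "p-adj"]].rename(
            columns={"meandiff": "mean_diff", "p-adj": "p_adjusted"}
        )
    elif method == "bonferroni":
        rows = []
        m = len(levels) * (len(levels) - 1) // 2
        for i in range(len(levels)):
            for j in range(i + 1, len(levels)):
                r = welch_t_test(values[groups == levels[i]], values[groups == levels[j]])
                rows.append(
                    {
                        "group1": levels[i], "group2": levels[j],
                        "mean_diff": float(
                            values[groups == levels[j]].mean()
                            - values[groups == levels[i]].mean()
                        ),
                        "p_adjusted": min(1.0, m * r.p_value),
                    }
                )
        pairwise = pd.DataFrame(rows)
    else:
        raise ValueError(f"unknown post-hoc method {method!r}")
    return omnibus, pairwise


def spearman_matrix(matrix: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Spearman rank correlations between indicators.

    Mid-rank ties; on 0/1 columns Spearman's rho reduces to the phi
    coefficient.  Constant columns yield missing rho for their pairs.
    """
    df = matrix.values if not isinstance(matrix, pd.DataFrame) else matrix
    if df.shape[1] < 2:
        raise ValueError("need at least 2 indicators")
    arr = df.to_numpy(dtype=float)
    k = arr.shape[1]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rho = sps.spearmanr(arr).statistic
    if np.ndim(rho) == 0:  # k == 2 returns a scalar
        rho = np.array([[1.0, rho], [rho, 1.0]])
    const = arr.std(axis=0) == 0
    rho[const, :] = np.nan
    rho[:, const] = np.nan
    np.fill_diagonal(rho, 1.0)
    return pd.DataFrame(rho, index=df.columns, columns=df.columns)


def _fmt_count(k: int, n: int) -> str:
    return f"{k} ({100 * k / n:.1f}%)" if n else ""


def table1_builder(
    cohort: pd.DataFrame,
    label_column: str,
    categorical: list[str],
    continuous: list[str],
) -> pd.DataFrame:
    """Stratified descriptive table with per-row bivariate tests.

    One column per stratum of ``label_column``; categorical rows show
    ``count (percent)`` within the stratum and a Yates chi-square p-value,
    continuous rows show mean (SD) and median [min, max] with a Welch
    t-test p-value (first two strata).
    """
    strata = sorted(cohort[label_column].dropna().unique())
    rows = []
    for var in categorical:
        levels = sorted(cohort[var].dropna().unique())
        counts = {
            s: cohort.loc[cohort[label_column] == s, var].value_counts()
            for s in strata
        }
        n_strat = {s: int((cohort[label_column] == s).sum()) for s in strata}
        table = np.array(
            [[counts[s].get(lv, 0) for s in strata] for lv in levels], dtype=float
        )
        try:
            p = yates_chi_square(table).p_value if table.shape[0] > 1 else np.nan
        except ValueError:
            p = np.nan
        for i, lv in enumerate(levels):
            rows.append(
                {
                    "variable": var,
                    "level": str(lv),
                    **{
                        f"stratum_{s}": _fmt_count(int(table[i, j]), n_strat[s])
                        for j, s in enumerate(strata)
                    },
                    "p_value": p if i == 0 else np.nan,
                    "test": "yates_chi_square" if i == 0 else "",
                }
            )
    for var in continuous:
        groups = [
            cohort.loc[cohort[label_column] == s, var].dropna().to_numpy()
            for s in strata
        ]
        p = (
            welch_t_test(groups[0], groups[1]).p_value
            if len(groups) >= 2 and all(len(g) >= 2 for g in groups[:2])
            else np.nan
        )
        rows.append(
            {
                "variable": var,
                "level": "mean_sd",
                **{
                    f"stratum_{s}": (
                        f"{g.mean():.1f} ({g.std(ddof=1):.2f})" if len(g) > 1 else ""
                    )
                    for s, g in zip(strata, groups)
                },
                "p_value": p,
                "test": "welch_t_test",
            }
        )
        rows.append(
            {
                "variable": var,
                "level": "median_range",
                **{
                    f"stratum_{s}": (
                        f"{np.median(g):.1f} [{g.min():.1f}, {g.max():.1f}]"
                        if len(g) else ""
                    )
                    for s, g in zip(strata, groups)
                },
                "p_value": np.nan,
                "test": "",
            }
        )
    return pd.DataFrame(rows)
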