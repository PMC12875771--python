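"""Alkire-Foster dual-cutoff engine for the multidimensional deprivation index.

Given the participants x indicators 0/1 matrix g and indicator weights w
(total weight W), each participant's weighted deprivation score is
c_i = sum_j w_j g_ij.  The second cutoff d identifies participant i as
multidimensionally deprived ("poor") when c_i >= d (count form, EIW) or
c_i / W >= d (share form, ENW).  The three aggregate measures are

    H  = n_poor / n                      (headcount ratio)
    A  = mean over the poor of c_i / W   (average deprivation share)
    M0 = H * A                           (adjusted headcount ratio)

M0 is the composite index.  Indicator j's contribution to M0 uses the
censored headcount CH_j (fraction of the whole sample both poor and
deprived on j):  contribution_j = w_j CH_j / (W * M0); contributions sum
to one and roll up by factor and dimension.  M0 decomposes exactly over
population subgroups: M0 = sum_g (n_g / n) M0_g.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .indicators import DeprivationMatrix
from .registry import IndicatorRegistry

__all__ = [
    "WeightScheme",
    "AFConfig",
    "AFResult",
    "build_weight_scheme",
    "deprivation_scores",
    "identify_poor",
    "af_measures",
    "contributions",
    "m0_curve",
    "calibrate_cutoff",
    "subgroup_decompose",
    "relative_gap",
    "group_difference_test",
    "burden",
]


@dataclass(frozen=True)
class WeightScheme:
    """Per-indicator weights under EIW (equal indicator) or ENW (equal nested)."""

    scheme_name: str
    weights: pd.Series  # indexed by indicator name, positive
    cutoff_convention: str  # "count" (EIW) or "share" (ENW)

    def __post_init__(self) -> None:
        if self.scheme_name not in ("EIW", "ENW"):
            raise ValueError(f"unknown weight scheme {self.scheme_name!r}")
        if (self.weights <= 0).any():
            raise ValueError("weights must be positive")
        if self.cutoff_convention not in ("count", "share"):
            raise ValueError(f"unknown cutoff convention {self.cutoff_convention!r}")

    @property
    def total_weight(self) -> float:
        return float(self.weights.sum())


@dataclass(frozen=True)
class AFConfig:
    """Deprivation cutoff d plus the weighting scheme.

    Under the count convention d is a weighted-indicator count in
    (0, total_weight]; under the share convention d is a fraction of total
    weight in (0, 1].
    """

    d: float
    weight_scheme: WeightScheme

    def __post_init__(self) -> None:
        w = self.weight_scheme
        hi = w.total_weight if w.cutoff_convention == "count" else 1.0
        if not (0 < self.d <= hi):
            raise ValueError(f"cutoff d={self.d} outside (0, {hi}]")

    @property
    def d_share(self) -> float:
        """The cutoff expressed as a share of total weight."""
        if self.weight_scheme.cutoff_convention == "count":
            return self.d / self.weight_scheme.total_weight
        return self.d


@dataclass(frozen=True)
class AFResult:
    H: float
    A: float | None  # None when no one is poor
    M0: float
    n: int
    n_poor: int

    def as_dict(self) -> dict:
        return {"H": self.H, "A": self.A, "M0": self.M0, "n": self.n, "n_poor": self.n_poor}


def build_weight_scheme(registry: IndicatorRegistry, scheme_name: str) -> WeightScheme:
    """EIW: every indicator weighs 1.  ENW: each factor weighs 1, split
    equally over its member indicators (1/3 each in a 3-indicator factor)."""
    names = registry.indicator_names
    if scheme_name == "EIW":
        w = pd.Series(1.0, index=names)
        return WeightScheme("EIW", w, "count")
    if scheme_name == "ENW":
        vals = {}
        for factor in registry.factor_names:
            members = registry.indicators_in_factor(factor)
            for m in members:
                vals[m] = 1.0 / len(members)
        w = pd.Series(vals).reindex(names)
        return WeightScheme("ENW", w, "share")
    raise ValueError(f"unknown weight scheme {scheme_name!r}")


def _aligned_weights(matrix: DeprivationMatrix, scheme: WeightScheme) -> np.ndarray:
    if list(scheme.weights.index) != matrix.indicator_names:
        if set(scheme.weights.index) != set(matrix.indicator_names):
            raise ValueError("weight vector does not match matrix indicators")
        return scheme.weights.reindex(matrix.indicator_names).to_numpy()
    return scheme.weights.to_numpy()


def deprivation_scores(matrix: DeprivationMatrix, scheme: WeightScheme) -> pd.Series:
    """Weighted deprivation score c_i = sum_j w_j g_ij per participant."""
    w = _aligned_weights(matrix, scheme)
    c = matrix.values.to_numpy(dtype=float) @ w
    return pd.Series(c, index=matrix.participant_ids, name="c")


def identify_poor(scores: pd.Series, config: AFConfig) -> pd.Series:
    """Binary poor/non-poor identification: poor iff c_i >= d (inclusive)."""
    w = config.weight_scheme
    c = np.asarray(scores, dtype=float)
    if w.cutoff_convention == "count":
        poor = c >= config.d - 1e-12
    else:
        poor = c / w.total_weight >= config.d - 1e-12
    return pd.Series(poor.astype(int), index=scores.index, name="poor")


def af_measures(matrix: DeprivationMatrix, config: AFConfig) -> AFResult:
    """H, A and M0 for one population.

    Computes M0 both as H * A and as the censored-score mean
    sum_poor(c_i) / (n * W) and asserts they agree.
    """
    n = matrix.n
    if n == 0:
        raise ValueError("empty deprivation matrix")
    W = config.weight_scheme.total_weight
    c = deprivation_scores(matrix, config.weight_scheme)
    poor = identify_poor(c, config).to_numpy(dtype=bool)
    n_poor = int(poor.sum())
    H = n_poor / n
    if n_poor == 0:
        return AFResult(H=0.0, A=None, M0=0.0, n=n, n_poor=0)
    A = float(np.mean(c.to_numpy()[poor]) / W)
    M0 = H * A
    M0_direct = float(c.to_numpy()[poor].sum() / (n * W))
    if not math.isclose(M0, M0_direct, rel_tol=1e-12, abs_tol=1e-15):
        raise AssertionError("M0 identity H*A != censored mean")  # pragma: no cover
    return AFResult(H=H, A=A, M0=M0, n=n, n_poor=n_poor)


def contributions(
    matrix: DeprivationMatrix,
    config: AFConfig,
    registry: IndicatorRegistry | None = None,
    censored: bool = True,
) -> pd.DataFrame:
    """Per-indicator censored headcounts and contribution shares to M0.

    Returns a tidy frame with rows at the indicator, factor and dimension
    level (``level`` column); factor/dimension rows only when a registry is
    supplied.  ``censored=False`` uses raw (uncensored) headcounts in the
    numerator; shares then need not sum to one.
    """
    res = af_measures(matrix, config)
    if res.M0 == 0:
        raise ValueError("contributions undefined: M0 = 0 (no one is poor)")
    W = config.weight_scheme.total_weight
    w = _aligned_weights(matrix, config.weight_scheme)
    g = matrix.values.to_numpy(dtype=float)
    poor = identify_poor(deprivation_scores(matrix, config.weight_scheme), config)
    mask = poor.to_numpy(dtype=bool)

    g_eff = g * mask[:, None] if censored else g
    ch = g_eff.mean(axis=0)  # censored headcount per indicator
    share = w * ch / (W * res.M0)

    rows = [
        {
            "level": "indicator",
            "name": name,
            "censored_headcount": ch[j],
            "weight": w[j],
            "contribution": share[j],
        }
        for j, name in enumerate(matrix.indicator_names)
    ]
    out = pd.DataFrame(rows)
    if registry is not None:
        ind = out.set_index("name")
        for factor in registry.factor_names:
            members = [m for m in registry.indicators_in_factor(factor)
                       if m in ind.index]
            rows.append({
                "level": "factor",
                "name": factor,
                "censored_headcount": float("nan"),
                "weight": float(ind.loc[members, "weight"].sum()) if members else 0.0,
                "contribution": float(ind.loc[members, "contribution"].sum()),
            })
        fac = pd.DataFrame(rows)
        fac_ind = fac[fac.level == "factor"].set_index("name")
        for dim in registry.dimensions:
            members = [f.name for f in registry.factors if f.dimension == dim]
            rows.append({
                "level": "dimension",
                "name": dim,
                "censored_headcount": float("nan"),
                "weight": float(fac_ind.loc[members, "weight"].sum()),
                "contribution": float(fac_ind.loc[members, "contribution"].sum()),
            })
        out = pd.DataFrame(rows)
    return out


def m0_curve(
    matrix: DeprivationMatrix,
    scheme: WeightScheme,
    d_values: Sequence[float],
) -> pd.DataFrame:
    """AF measures at each cutoff d (robustness curve; H, M0 nonincreasing)."""
    if len(d_values) == 0:
        raise ValueError("d_values must be nonempty")
    rows = []
    for d in d_values:
        r = af_measures(matrix, AFConfig(d=d, weight_scheme=scheme))
        rows.append({"d": d, **r.as_dict()})
    return pd.DataFrame(rows)


def calibrate_cutoff(
    matrix: DeprivationMatrix,
    scheme: WeightScheme,
    target_prevalence: float,
    d_values: Sequence[float] | None = None,
) -> float:
    """The cutoff whose headcount ratio is nearest the target prevalence.

    Ties break toward the smaller d.  By default candidate cutoffs are the
    integers 1..total_weight (count convention) or their shares.
    """
    if not (0 < target_prevalence < 1):
        raise ValueError("target prevalence must be in (0, 1)")
    if d_values is None:
        top = int(math.floor(scheme.total_weight + 1e-9))
        if scheme.cutoff_convention == "count":
            d_values = list(range(1, top + 1))
        else:
            d_values = [k / scheme.total_weight for k in range(1, top + 1)]
    best_d, best_err = None, math.inf
    for d in d_values:
        r = af_measures(matrix, AFConfig(d=d, weight_scheme=scheme))
        err = abs(r.H - target_prevalence)
        if err < best_err - 1e-15:
            best_d, best_err = d, err
    return best_d


def subgroup_decompose(
    matrix: DeprivationMatrix,
    config: AFConfig,
    groups: pd.Series,
) -> pd.DataFrame:
    """Per-group AF measures with population shares.

    Asserts the AF decomposability identity
    M0_overall = sum_g (n_g / n) M0_g.  Groups absent from the matrix index
    are reported with n = 0 and missing measures.
    """
    groups = groups.reindex(matrix.participant_ids)
    if groups.isna().any():
        raise ValueError("group labels do not cover every participant")
    overall = af_measures(matrix, config)
    rows = []
    recomposed = 0.0
    for gname, idx in groups.groupby(groups, observed=False).groups.items():
        if len(idx) == 0:  # empty category: report with missing measures
            rows.append({
                "group": gname, "population_share": 0.0,
                "H": float("nan"), "A": None, "M0": float("nan"),
                "n": 0, "n_poor": 0,
            })
            continue
        sub = DeprivationMatrix(matrix.values.loc[idx])
        r = af_measures(sub, config)
        share = r.n / overall.n
        recomposed += share * r.M0
        rows.append({
            "group": gname, "population_share": share, **r.as_dict(),
        })
    if not math.isclose(recomposed, overall.M0, rel_tol=1e-10, abs_tol=1e-14):
        raise AssertionError("subgroup decomposition identity violated")  # pragma: no cover
    out = pd.DataFrame(rows)
    out.attrs["overall"] = overall
    return out


def relative_gap(a: AFResult, b: AFResult) -> float:
    """Percent difference in M0: 100 * (a.M0 - b.M0) / b.M0."""
    if b.M0 == 0:
        raise ValueError("reference group has M0 = 0; relative gap undefined")
    return 100.0 * (a.M0 - b.M0) / b.M0


def group_difference_test(
    matrix: DeprivationMatrix,
    config: AFConfig,
    labels: pd.Series,
    n_boot: int = 1000,
    seed: int = 0,
) -> dict:
    """Bootstrap test of the M0 difference between two groups.

    Participants are resampled with replacement *within* each group; the
    two-sided p-value is the percentile probability that the bootstrap
    difference crosses zero.  Returns the observed gap (percent, group a
    vs b where a, b follow sorted label order), the M0 difference, the
    p-value and a flag when either observed group has no poor members.
    """
    labels = labels.reindex(matrix.participant_ids)
    uniq = sorted(labels.dropna().unique())
    if len(uniq) != 2:
        raise ValueError("group_difference_test needs exactly 2 groups")
    rng = np.random.default_rng(seed)
    g = matrix.values.to_numpy(dtype=float)
    w = _aligned_weights(matrix, config.weight_scheme)
    W = config.weight_scheme.total_weight
    d_share = config.d_share

    def m0_of(rows: np.ndarray) -> float:
        c = rows @ w
        poor = c / W >= d_share - 1e-12
        return float(c[poor].sum() / (len(rows) * W)) if poor.any() else 0.0

    idx_a = np.flatnonzero((labels == uniq[0]).to_numpy())
    idx_b = np.flatnonzero((labels == uniq[1]).to_numpy())
    m0_a, m0_b = m0_of(g[idx_a]), m0_of(g[idx_b])
    observed = m0_a - m0_b
    flagged = m0_a == 0 or m0_b == 0

    diffs = np.empty(n_boot)
    for b in range(n_boot):
        ra = g[rng.choice(idx_a, size=len(idx_a), replace=True)]
        rb = g[rng.choice(idx_b, size=len(idx_b), replace=True)]
        diffs[b] = m0_of(ra) - m0_of(rb)
    p_low = np.mean(diffs <= 0)
    p_high = np.mean(diffs >= 0)
    p = min(1.0, 2.0 * min(p_low, p_high))
    gap = 100.0 * observed / m0_b if m0_b > 0 else float("nan")
    return {
        "group_a": uniq[0], "group_b": uniq[1],
        "m0_a": m0_a, "m0_b": m0_b,
        "difference": observed, "gap_percent": gap,
        "p_value": float(p), "n_boot": n_boot,
        "no_poor_flag": flagged,
    }


def burden(
    matrix: DeprivationMatrix,
    config: AFConfig,
    censored: bool = False,
) -> pd.Series:
    """Per-participant weighted deprivation share in [0, 1].

    Default (uncensored): burden_i = c_i / total_weight for everyone.
    ``censored=True`` zeroes the burden of the non-poor (the standard AF
    censored score c_i(k)).
    """
    c = deprivation_scores(matrix, config.weight_scheme)
    share = c / config.weight_scheme.total_weight
    if censored:
        poor = identify_poor(c, config)
        share = share * poor
    share.name = "burden"
    return share
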