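"""Operationalise raw cohort measurements into binary deprivation indicators.

Scale-based indicators use sample-referenced cutpoints: a *deficit* is a
score at or below the sample mean minus ``threshold_sd`` sample SDs (low
social cohesion, low reading skill), an *adverse exposure* is a score at or
above the mean plus ``threshold_sd`` SDs (disorder, stressors, neuroticism).
Both boundaries are inclusive.  Sample SDs use the n-1 denominator.

Composite rules cover material living standards, the polychoric-PCA asset
index, the 17-item / 9-component barriers-to-care scale and the optional
joint education rule.  ``build_deprivation_matrix`` applies the full
registry and yields the participants x indicators 0/1 matrix consumed by
the Alkire-Foster engine.  Participants with any missing source value are
dropped (complete-case) with a logged count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .polychoric import asset_index
from .registry import IndicatorRegistry, IndicatorRule

__all__ = [
    "DeprivationMatrix",
    "threshold_deficit",
    "threshold_adverse",
    "living_standards_rule",
    "education_rules",
    "barriers_components",
    "build_deprivation_matrix",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class DeprivationMatrix:
    """Participants x indicators binary matrix (1 = deprived)."""

    values: pd.DataFrame

    def __post_init__(self) -> None:
        arr = self.values.to_numpy()
        if arr.size and not np.isin(arr, (0, 1)).all():
            raise ValueError("deprivation matrix entries must be 0/1")

    @property
    def indicator_names(self) -> list[str]:
        return list(self.values.columns)

    @property
    def participant_ids(self) -> pd.Index:
        return self.values.index

    @property
    def n(self) -> int:
        return len(self.values)

    def to_csv(self, path) -> None:
        self.values.to_csv(path, index_label="participant_id")

    @classmethod
    def from_csv(cls, path) -> "DeprivationMatrix":
        return cls(pd.read_csv(path, index_col="participant_id"))


def _sample_cut(scores: np.ndarray, threshold_sd: float, name: str = "") -> tuple[float, float]:
    if len(scores) < 2:
        raise ValueError(f"indicator {name or '<scores>'}: need >= 2 scores to form a cutpoint")
    mean = float(np.mean(scores))
    sd = float(np.std(scores, ddof=1))
    if sd == 0:
        raise ValueError(f"indicator {name or '<scores>'}: degenerate scale (zero SD)")
    return mean, sd


def threshold_deficit(scores, threshold_sd: float = 1.0, name: str = "") -> np.ndarray:
    """Deprived iff score <= mean - threshold_sd * SD (inclusive)."""
    scores = np.asarray(scores, dtype=float)
    mean, sd = _sample_cut(scores[~np.isnan(scores)], threshold_sd, name)
    out = np.where(scores <= mean - threshold_sd * sd, 1.0, 0.0)
    out[np.isnan(scores)] = np.nan
    return out


def threshold_adverse(scores, threshold_sd: float = 1.0, name: str = "") -> np.ndarray:
    """Deprived iff score >= mean + threshold_sd * SD (inclusive)."""
    scores = np.asarray(scores, dtype=float)
    mean, sd = _sample_cut(scores[~np.isnan(scores)], threshold_sd, name)
    out = np.where(scores >= mean + threshold_sd * sd, 1.0, 0.0)
    out[np.isnan(scores)] = np.nan
    return out


def living_standards_rule(
    homeowner,
    persons_per_room,
    car_access,
    internet,
    all_conjunctive: bool = False,
) -> np.ndarray:
    """Material living-standards deprivation.

    Default reading: (not homeowner AND > 2 persons/room) OR no car access
    OR no internet.  The overcrowding clause binds to non-homeownership; car
    and internet are standalone disjuncts.  ``all_conjunctive`` requires all
    clauses jointly instead.
    """
    homeowner = np.asarray(homeowner, dtype=float)
    ppr = np.asarray(persons_per_room, dtype=float)
    car = np.asarray(car_access, dtype=float)
    net = np.asarray(internet, dtype=float)
    if np.nanmin(ppr) < 0:
        raise ValueError("persons_per_room must be nonnegative")
    crowd_rent = (homeowner == 0) & (ppr > 2.0)
    if all_conjunctive:
        deprived = crowd_rent & (car == 0) & (net == 0)
    else:
        deprived = crowd_rent | (car == 0) | (net == 0)
    return deprived.astype(float)


def education_rules(attended_college, reading_z) -> tuple[np.ndarray, np.ndarray]:
    """Two education indicators: years (no college) and reading (z <= -1).

    Returns ``(education_years, reading_skills)`` binary vectors.
    """
    college = np.asarray(attended_college, dtype=float)
    rz = np.asarray(reading_z, dtype=float)
    education_years = (college == 0).astype(float)
    reading_skills = (rz <= -1.0).astype(float)
    return education_years, reading_skills


def barriers_components(
    items: pd.DataFrame,
    component_map: dict[str, str],
    min_endorsed: int = 1,
) -> pd.DataFrame:
    """Collapse binary barrier-item endorsements into per-component indicators.

    A component is deprived when at least ``min_endorsed`` of its member
    items are endorsed.
    """
    unknown = set(items.columns) - set(component_map)
    if unknown:
        raise ValueError(f"items mapped to no component: {sorted(unknown)}")
    comps: dict[str, list[str]] = {}
    for item in items.columns:
        comps.setdefault(component_map[item], []).append(item)
    out = {
        comp: (items[cols].sum(axis=1) >= min_endorsed).astype(float)
        for comp, cols in comps.items()
    }
    return pd.DataFrame(out, index=items.index)[sorted(comps)]


def _apply_rule(rule: IndicatorRule, cohort: pd.DataFrame) -> pd.Series:
    cols = list(rule.source_columns)
    if rule.kind == "deficit_sd":
        vals = threshold_deficit(cohort[cols[0]], rule.threshold_sd, name=rule.name)
    elif rule.kind == "adverse_sd":
        vals = threshold_adverse(cohort[cols[0]], rule.threshold_sd, name=rule.name)
    elif rule.kind == "direct_binary":
        raw = np.asarray(cohort[cols[0]], dtype=float)
        vals = (raw == 0).astype(float) if rule.negate else (raw != 0).astype(float)
        vals[np.isnan(raw)] = np.nan
    elif rule.kind == "composite":
        ctype = rule.params.get("composite")
        if ctype == "living_standards":
            vals = living_standards_rule(
                cohort[cols[0]], cohort[cols[1]], cohort[cols[2]], cohort[cols[3]],
                all_conjunctive=bool(rule.params.get("all_conjunctive", False)),
            )
        elif ctype == "asset_index":
            _, deprived = asset_index(cohort[cols], threshold_sd=rule.threshold_sd)
            vals = deprived.to_numpy(dtype=float)
        elif ctype == "barriers":
            comp_map = {c: rule.name for c in cols}
            vals = barriers_components(
                cohort[cols], comp_map, min_endorsed=int(rule.params.get("min_endorsed", 1))
            )[rule.name].to_numpy()
        elif ctype == "education_joint":
            college = np.asarray(cohort[cols[0]], dtype=float)
            reading = np.asarray(cohort[cols[1]], dtype=float)
            reading_dep = threshold_deficit(reading, rule.threshold_sd, name=rule.name)
            vals = ((college == 0) & (reading_dep == 1)).astype(float)
        else:
            raise ValueError(f"indicator {rule.name!r}: unknown composite {ctype!r}")
    else:  # pragma: no cover - registry validates kinds
        raise ValueError(rule.kind)
    return pd.Series(np.asarray(vals, dtype=float), index=cohort.index, name=rule.name)


def build_deprivation_matrix(
    cohort: pd.DataFrame, registry: IndicatorRegistry
) -> DeprivationMatrix:
    """Apply every registry rule to the cohort table.

    Missing source columns raise a schema error listing all absences.
    Participants with any missing source value are dropped (complete-case)
    before cutpoints are formed; the drop count is logged.
    """
    needed = registry.source_columns()
    missing = [c for c in needed if c not in cohort.columns]
    if missing:
        raise KeyError(f"cohort is missing registry source columns: {missing}")

    complete = cohort[needed].notna().all(axis=1)
    n_drop = int((~complete).sum())
    if n_drop:
        log.info("complete-case filter dropped %d of %d participants", n_drop, len(cohort))
    analytic = cohort.loc[complete]

    if analytic.empty:
        empty = pd.DataFrame(
            {r.name: pd.Series(dtype=float) for r in registry.indicators}
        )
        return DeprivationMatrix(empty.astype(int))

    cols = {rule.name: _apply_rule(rule, analytic) for rule in registry.indicators}
    matrix = pd.DataFrame(cols, index=analytic.index)[registry.indicator_names]
    return DeprivationMatrix(matrix.astype(int))
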