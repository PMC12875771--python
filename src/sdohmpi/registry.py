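"""Declarative registry of deprivation indicators.

The composite index is organised as a three-level hierarchy taken from the
NIA Health Disparities Research Framework (HDRF): three *dimensions*
(environmental, sociocultural, behavioral), ten *factors* nested in the
dimensions, and 37 binary *indicators* nested in the factors.  Each
indicator carries a rule describing how it is derived from raw cohort
columns:

``deficit_sd``
    deprived iff the scale score falls at or below ``mean - threshold_sd * SD``
    of the analytic sample (e.g. low neighborhood cohesion, low extraversion).
``adverse_sd``
    deprived iff the score is at or above ``mean + threshold_sd * SD``
    (e.g. neighborhood disorder, neuroticism, chronic stressors).
``direct_binary``
    the source column is already a 0/1 exposure (e.g. current smoking);
    ``negate`` flips it so that absence of a good (no college attendance)
    marks deprivation.
``composite``
    multi-column rules: the living-standards material rule, the
    polychoric-PCA asset index, and the barriers-to-care components.

The registry is plain declarative data and serialises to/from YAML so that
alternative operationalisations (different thresholds, the conjunctive
education variant, per-component barrier thresholds) are configuration,
not code.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import yaml

__all__ = [
    "IndicatorRule",
    "Factor",
    "IndicatorRegistry",
    "default_registry",
    "BARRIER_COMPONENT_MAP",
]

KINDS = ("deficit_sd", "adverse_sd", "direct_binary", "composite")
DIMENSIONS = ("environmental", "sociocultural", "behavioral")

#: Item -> component map for the 17-item barriers-to-care scale.  The scale
#: spans nine components; eight are probed by two items and one by a single
#: item.  A component is deprived when at least ``min_endorsed`` of its items
#: are endorsed (default one).
BARRIER_COMPONENT_MAP: Mapping[str, str] = {
    "barrier_item_01": "bar_socioeconomic",
    "barrier_item_02": "bar_socioeconomic",
    "barrier_item_03": "bar_insurance",
    "barrier_item_04": "bar_insurance",
    "barrier_item_05": "bar_transport",
    "barrier_item_06": "bar_transport",
    "barrier_item_07": "bar_scheduling",
    "barrier_item_08": "bar_scheduling",
    "barrier_item_09": "bar_provider_attitudes",
    "barrier_item_10": "bar_provider_attitudes",
    "barrier_item_11": "bar_communication",
    "barrier_item_12": "bar_communication",
    "barrier_item_13": "bar_navigation",
    "barrier_item_14": "bar_navigation",
    "barrier_item_15": "bar_trust",
    "barrier_item_16": "bar_trust",
    "barrier_item_17": "bar_convenience",
}


@dataclass(frozen=True)
class IndicatorRule:
    """Rule deriving one binary deprivation indicator from cohort columns."""

    name: str
    kind: str
    factor: str
    source_columns: tuple[str, ...]
    threshold_sd: float = 1.0
    negate: bool = False
    params: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"indicator {self.name!r}: unknown kind {self.kind!r}")
        if not self.source_columns:
            raise ValueError(f"indicator {self.name!r}: no source columns")
        if self.threshold_sd <= 0:
            raise ValueError(f"indicator {self.name!r}: threshold_sd must be > 0")


@dataclass(frozen=True)
class Factor:
    name: str
    dimension: str

    def __post_init__(self) -> None:
        if self.dimension not in DIMENSIONS:
            raise ValueError(f"factor {self.name!r}: unknown dimension {self.dimension!r}")


@dataclass(frozen=True)
class IndicatorRegistry:
    """Ordered dimension -> factor -> indicator hierarchy with rules."""

    factors: tuple[Factor, ...]
    indicators: tuple[IndicatorRule, ...]
    dimensions: tuple[str, ...] = DIMENSIONS

    def __post_init__(self) -> None:
        factor_names = [f.name for f in self.factors]
        if len(set(factor_names)) != len(factor_names):
            raise ValueError("duplicate factor names")
        ind_names = [r.name for r in self.indicators]
        if len(set(ind_names)) != len(ind_names):
            raise ValueError("duplicate indicator names")
        known = set(factor_names)
        for rule in self.indicators:
            if rule.factor not in known:
                raise ValueError(
                    f"indicator {rule.name!r} references unknown factor {rule.factor!r}"
                )
        for f in self.factors:
            if f.dimension not in self.dimensions:
                raise ValueError(f"factor {f.name!r} has unlisted dimension")

    # -- lookups ---------------------------------------------------------

    @property
    def indicator_names(self) -> list[str]:
        return [r.name for r in self.indicators]

    @property
    def factor_names(self) -> list[str]:
        return [f.name for f in self.factors]

    def factor_of(self, indicator: str) -> str:
        for rule in self.indicators:
            if rule.name == indicator:
                return rule.factor
        raise KeyError(indicator)

    def dimension_of_factor(self, factor: str) -> str:
        for f in self.factors:
            if f.name == factor:
                return f.dimension
        raise KeyError(factor)

    def indicators_in_factor(self, factor: str) -> list[str]:
        return [r.name for r in self.indicators if r.factor == factor]

    def rule(self, indicator: str) -> IndicatorRule:
        for r in self.indicators:
            if r.name == indicator:
                return r
        raise KeyError(indicator)

    def source_columns(self) -> list[str]:
        """All raw cohort columns referenced by any rule, in first-use order."""
        seen: dict[str, None] = {}
        for rule in self.indicators:
            for col in rule.source_columns:
                seen.setdefault(col)
        return list(seen)

    def with_rule(self, rule: IndicatorRule) -> "IndicatorRegistry":
        """Return a registry with the named indicator's rule replaced."""
        new = tuple(rule if r.name == rule.name else r for r in self.indicators)
        if rule.name not in self.indicator_names:
            raise KeyError(rule.name)
        return replace(self, indicators=new)

    # -- serialisation ---------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "dimensions": list(self.dimensions),
            "factors": [{"name": f.name, "dimension": f.dimension} for f in self.factors],
            "indicators": [
                {
                    "name": r.name,
                    "kind": r.kind,
                    "factor": r.factor,
                    "source_columns": list(r.source_columns),
                    "threshold_sd": r.threshold_sd,
                    "negate": r.negate,
                    "params": dict(r.params),
                }
                for r in self.indicators
            ],
        }

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_dict(cls, data: Mapping) -> "IndicatorRegistry":
        factors = tuple(Factor(d["name"], d["dimension"]) for d in data["factors"])
        indicators = tuple(
            IndicatorRule(
                name=d["name"],
                kind=d["kind"],
                factor=d["factor"],
                source_columns=tuple(d["source_columns"]),
                threshold_sd=float(d.get("threshold_sd", 1.0)),
                negate=bool(d.get("negate", False)),
                params=dict(d.get("params", {})),
            )
            for d in data["indicators"]
        )
        dims = tuple(data.get("dimensions", DIMENSIONS))
        return cls(factors=factors, indicators=indicators, dimensions=dims)

    @classmethod
    def from_yaml(cls, path) -> "IndicatorRegistry":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def _scale(name: str, kind: str, factor: str, column: str) -> IndicatorRule:
    return IndicatorRule(name=name, kind=kind, factor=factor, source_columns=(column,))


def _binary(name: str, factor: str, column: str, negate: bool = False) -> IndicatorRule:
    return IndicatorRule(
        name=name, kind="direct_binary", factor=factor, source_columns=(column,), negate=negate
    )


def default_registry(
    n_asset_items: int = 5,
    conjunctive_education: bool = False,
    living_standards_all_conjunctive: bool = False,
) -> IndicatorRegistry:
    """The default 37-indicator / 10-factor / 3-dimension registry.

    Parameters
    ----------
    n_asset_items
        Number of ordinal asset-ownership items feeding the polychoric-PCA
        asset index.
    conjunctive_education
        If True, collapse education into a single joint indicator (no college
        attendance AND reading at or below -1 SD) instead of the default two
        separate indicators.  The two-indicator form matches how education
        and reading gaps are reported separately.
    living_standards_all_conjunctive
        If True, the material living-standards rule requires every clause
        jointly; the default attaches overcrowding to non-homeownership and
        treats no-car and no-internet as standalone disjuncts.
    """
    factors = (
        Factor("neighborhood", "environmental"),
        Factor("education", "environmental"),
        Factor("living_standards", "environmental"),
        Factor("healthcare_barriers", "environmental"),
        Factor("religiosity", "sociocultural"),
        Factor("social", "sociocultural"),
        Factor("psychological", "sociocultural"),
        Factor("coping", "behavioral"),
        Factor("discrimination", "behavioral"),
        Factor("health_behaviors", "behavioral"),
    )

    asset_cols = tuple(f"asset_item_{i + 1}" for i in range(n_asset_items))
    barrier_cols = tuple(sorted(BARRIER_COMPONENT_MAP))

    indicators: list[IndicatorRule] = [
        # environmental -- neighborhood
        _scale("social_cohesion", "deficit_sd", "neighborhood", "neighborhood_cohesion"),
        _scale("physical_disorder", "adverse_sd", "neighborhood", "neighborhood_disorder"),
    ]

    # environmental -- education
    if conjunctive_education:
        indicators.append(
            IndicatorRule(
                name="education_quality",
                kind="composite",
                factor="education",
                source_columns=("college_attended", "wrat_reading"),
                params={"composite": "education_joint"},
            )
        )
        # keep 37 by retaining reading as its own indicator alongside the joint
        indicators.append(
            _scale("reading_skills", "deficit_sd", "education", "wrat_reading")
        )
    else:
        indicators.append(_binary("education_years", "education", "college_attended", negate=True))
        indicators.append(_scale("reading_skills", "deficit_sd", "education", "wrat_reading"))

    indicators += [
        # environmental -- living standards
        _scale(
            "perceived_conditions", "deficit_sd", "living_standards", "perceived_conditions"
        ),
        IndicatorRule(
            name="material_living_standards",
            kind="composite",
            factor="living_standards",
            source_columns=("homeowner", "persons_per_room", "car_access", "internet"),
            params={
                "composite": "living_standards",
                "all_conjunctive": living_standards_all_conjunctive,
            },
        ),
        IndicatorRule(
            name="asset_index",
            kind="composite",
            factor="living_standards",
            source_columns=asset_cols,
            params={"composite": "asset_index"},
        ),
    ]

    # environmental -- healthcare barriers (9 components of a 17-item scale)
    components: dict[str, list[str]] = {}
    for item in barrier_cols:
        components.setdefault(BARRIER_COMPONENT_MAP[item], []).append(item)
    for comp in sorted(components):
        indicators.append(
            IndicatorRule(
                name=comp,
                kind="composite",
                factor="healthcare_barriers",
                source_columns=tuple(components[comp]),
                params={"composite": "barriers", "min_endorsed": 1},
            )
        )

    indicators += [
        # sociocultural -- religiosity (Duke Religion Index subscales)
        _scale("religiosity_organizational", "deficit_sd", "religiosity", "relig_organizational"),
        _scale("religiosity_private", "deficit_sd", "religiosity", "relig_private"),
        _scale("religiosity_intrinsic", "deficit_sd", "religiosity", "relig_intrinsic"),
        # sociocultural -- social hardship and chronic stressors
        _binary("hardship", "social", "hardship"),
        _scale("life_stressors", "adverse_sd", "social", "chronic_stressors"),
        # sociocultural -- psychological (Big Five + life satisfaction)
        _scale("extraversion", "deficit_sd", "psychological", "ipip_extraversion"),
        _scale("agreeableness", "deficit_sd", "psychological", "ipip_agreeableness"),
        _scale("openness", "deficit_sd", "psychological", "ipip_openness"),
        _scale("conscientiousness", "deficit_sd", "psychological", "ipip_conscientiousness"),
        _scale("neuroticism", "adverse_sd", "psychological", "ipip_neuroticism"),
        _scale("life_satisfaction", "deficit_sd", "psychological", "swls"),
        # behavioral -- coping (single-indicator factor)
        _scale("john_henryism", "adverse_sd", "coping", "john_henryism"),
        # behavioral -- discrimination
        _scale("vigilance", "adverse_sd", "discrimination", "heightened_vigilance"),
        _scale("everyday_discrimination", "adverse_sd", "discrimination", "everyday_discrimination"),
        # behavioral -- seven health-behavior risks
        _binary("current_smoking", "health_behaviors", "current_smoking"),
        _binary("alcohol_misuse", "health_behaviors", "alcohol_misuse"),
        _binary("drug_use", "health_behaviors", "drug_use"),
        _binary("physical_inactivity", "health_behaviors", "physical_inactivity"),
        _binary("food_insecurity", "health_behaviors", "food_insecurity"),
        _binary("poor_diet", "health_behaviors", "poor_diet"),
        _binary("short_sleep", "health_behaviors", "short_sleep"),
    ]

    registry = IndicatorRegistry(factors=factors, indicators=tuple(indicators))
    if not conjunctive_education and len(registry.indicators) != 37:
        raise AssertionError("default registry must define 37 indicators")
    return registry
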