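"""End-to-end orchestration: cohort -> indicators -> cognition -> index -> models.

``run_pipeline`` executes the full analysis on a loaded or simulated
cohort and writes tidy comma-separated artifacts: the deprivation matrix,
cognitive labels, AF measures overall and by subgroup, the M0-versus-d
robustness curves, radar-ready factor contribution tables, per-indicator
deprivation-gap tables, descriptive and regression tables, and a run
manifest recording the configuration, seed and package version.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .af import (
    AFConfig,
    af_measures,
    build_weight_scheme,
    burden,
    contributions,
    group_difference_test,
    m0_curve,
    subgroup_decompose,
)
from .cognition import attach_cognitive_labels
from .indicators import DeprivationMatrix, build_deprivation_matrix
from .registry import IndicatorRegistry, default_registry
from .simulate import SimConfig, generate_cohort
from .stats import fit_logistic, spearman_matrix, table1_builder, yates_chi_square

__all__ = ["RunConfig", "run_pipeline", "export_radar", "PipelineError"]

log = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage {stage!r}: {message}")


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one pipeline run.

    Exactly one of ``input_path`` (a cohort CSV) or ``sim_config``
    (simulate) must be set.
    """

    output_dir: str | Path
    input_path: str | Path | None = None
    sim_config: SimConfig | None = None
    registry_path: str | Path | None = None
    scheme: str = "EIW"
    d: float = 11.0
    d_sweep: tuple[float, ...] = tuple(range(1, 20))
    subgroup_columns: tuple[str, ...] = ("pci_status", "pcp_status", "sex", "age_group")
    n_boot: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        if (self.input_path is None) == (self.sim_config is None):
            raise ValueError("set exactly one of input_path or sim_config")


def export_radar(contrib_by_group: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Long-format (group, factor, contribution %) table for radar plots.

    Groups whose contributions are undefined (M0 = 0) are omitted with a
    warning.  Within each group, factor contributions sum to 100%.
    """
    rows = []
    for group, table in contrib_by_group.items():
        if table is None:
            log.warning("group %r omitted from radar export: M0 = 0", group)
            continue
        fac = table[table.level == "factor"]
        for _, r in fac.iterrows():
            rows.append(
                {
                    "group": group,
                    "factor": r["name"],
                    "contribution_percent": 100.0 * r["contribution"],
                }
            )
    return pd.DataFrame(rows, columns=["group", "factor", "contribution_percent"])


def _stage(name):
    def deco(fn):
        def wrapped(*a, **kw):
            try:
                log.info("stage %s", name)
                return fn(*a, **kw)
            except PipelineError:
                raise
            except Exception as exc:  # noqa: BLE001 - reported with stage name
                raise PipelineError(name, str(exc)) from exc

        return wrapped

    return deco


@_stage("cohort")
def _load_cohort(config: RunConfig, registry: IndicatorRegistry) -> pd.DataFrame:
    if config.sim_config is not None:
        cohort = generate_cohort(config.sim_config, registry)
        return cohort.table
    return pd.read_csv(config.input_path, index_col="participant_id")


@_stage("gap_table")
def _gap_table(
    matrix: DeprivationMatrix, labels: pd.Series, ref: str, cmp: str
) -> pd.DataFrame:
    """Per-indicator deprivation rates by group with gap and chi-square test."""
    rows = []
    lab = labels.reindex(matrix.participant_ids)
    for name in matrix.indicator_names:
        col = matrix.values[name]
        a = col[lab == cmp]
        b = col[lab == ref]
        gap = 100.0 * (a.mean() - b.mean())
        table = np.array(
            [[a.sum(), len(a) - a.sum()], [b.sum(), len(b) - b.sum()]], dtype=float
        )
        try:
            p = yates_chi_square(table).p_value
        except ValueError:
            p = np.nan
        rows.append(
            {
                "indicator": name,
                f"pct_deprived_{cmp}": 100.0 * a.mean(),
                f"pct_deprived_{ref}": 100.0 * b.mean(),
                "gap_percent": gap,
                "p_value": p,
            }
        )
    return pd.DataFrame(rows)


def _binary_labels(analytic: pd.DataFrame) -> pd.DataFrame:
    lab = pd.DataFrame(index=analytic.index)
    lab["pci_status"] = np.where(analytic["pci"] == 1, "PCI", "CN")
    lab["pcp_status"] = np.where(analytic["pcp"] == 1, "PCP", "CN")
    lab["sex"] = analytic["sex"]
    lab["age_group"] = np.where(analytic["age_65plus"] == 1, "65plus", "under65")
    return lab


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage and write artifacts under ``config.output_dir``.

    Returns a dict of the in-memory results keyed by artifact name.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    registry = (
        IndicatorRegistry.from_yaml(config.registry_path)
        if config.registry_path
        else default_registry()
    )

    cohort = _load_cohort(config, registry)

    try:
        analytic = attach_cognitive_labels(cohort)
    except Exception as exc:
        raise PipelineError("cognition", str(exc)) from exc

    try:
        matrix = build_deprivation_matrix(analytic, registry)
    except Exception as exc:
        raise PipelineError("indicators", str(exc)) from exc
    analytic = analytic.loc[matrix.participant_ids]

    scheme = build_weight_scheme(registry, config.scheme)
    d = config.d
    if scheme.cutoff_convention == "share" and d > 1:
        d = d / scheme.total_weight  # express a count-style cutoff as a share
    af_config = AFConfig(d=d, weight_scheme=scheme)

    labels = _binary_labels(analytic)

    try:
        overall = af_measures(matrix, af_config)
        subgroup_tables = {}
        for col in config.subgroup_columns:
            subgroup_tables[col] = subgroup_decompose(matrix, af_config, labels[col])
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("af_index", str(exc)) from exc

    curves = []
    d_values = list(config.d_sweep)
    if scheme.cutoff_convention == "share":
        d_values = [v / scheme.total_weight if v > 1 else v for v in d_values]
    curve_all = m0_curve(matrix, scheme, d_values)
    curve_all["group"] = "all"
    curves.append(curve_all)
    for col in config.subgroup_columns:
        for gname in labels[col].unique():
            sub = DeprivationMatrix(matrix.values[labels[col] == gname])
            c = m0_curve(sub, scheme, d_values)
            c["group"] = f"{col}={gname}"
            curves.append(c)
    curve_table = pd.concat(curves, ignore_index=True)

    contrib_by_group: dict[str, pd.DataFrame | None] = {}
    try:
        contrib_by_group["all"] = contributions(matrix, af_config, registry)
        for col in ("pci_status", "pcp_status"):
            if col not in config.subgroup_columns:
                continue
            for gname in labels[col].unique():
                sub = DeprivationMatrix(matrix.values[labels[col] == gname])
                try:
                    contrib_by_group[f"{col}={gname}"] = contributions(
                        sub, af_config, registry
                    )
                except ValueError:
                    contrib_by_group[f"{col}={gname}"] = None
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("contributions", str(exc)) from exc
    radar = export_radar(contrib_by_group)

    gap_pci = _gap_table(matrix, labels["pci_status"], "CN", "PCI")
    gap_pcp = _gap_table(matrix, labels["pcp_status"], "CN", "PCP")

    diff_tests = {}
    for col in ("pci_status", "pcp_status"):
        if col in config.subgroup_columns:
            diff_tests[col] = group_difference_test(
                matrix, af_config, labels[col],
                n_boot=config.n_boot, seed=config.seed,
            )

    table1 = table1_builder(
        analytic.join(labels[["pci_status", "age_group"]]),
        label_column="pci_status",
        categorical=["sex", "age_group", "marital_status"],
        continuous=["age"],
    )

    b = burden(matrix, af_config)
    models = {}
    try:
        for outcome in ("pci", "pcp"):
            y = analytic[outcome]
            models[f"{outcome}_unadjusted"] = fit_logistic(
                y, pd.DataFrame({"burden": b})
            )
            models[f"{outcome}_adjusted"] = fit_logistic(
                y,
                pd.DataFrame(
                    {
                        "burden": b,
                        "age_65plus": analytic["age_65plus"].astype(float),
                        "female": analytic["female"].astype(float),
                        "married_partnered": analytic["married_partnered"].astype(float),
                    }
                ),
            )
    except Exception as exc:
        raise PipelineError("association", str(exc)) from exc
    model_table = pd.concat(
        [m.tidy().assign(model=k) for k, m in models.items()], ignore_index=True
    )

    overlap = spearman_matrix(matrix.values)

    # -- write artifacts -------------------------------------------------
    matrix.to_csv(out / "deprivation_matrix.csv")
    analytic[["pci", "pcp", "pacc_score"]].to_csv(out / "cognitive_labels.csv")
    af_rows = [{"group": "all", "population_share": 1.0, **overall.as_dict()}]
    for col, t in subgroup_tables.items():
        for _, r in t.iterrows():
            af_rows.append({"group": f"{col}={r['group']}", **r.drop("group").to_dict()})
    pd.DataFrame(af_rows).to_csv(out / "af_measures.csv", index=False)
    curve_table.to_csv(out / "m0_curves.csv", index=False)
    radar.to_csv(out / "factor_contributions_radar.csv", index=False)
    gap_pci.to_csv(out / "deprivation_gaps_pci.csv", index=False)
    gap_pcp.to_csv(out / "deprivation_gaps_pcp.csv", index=False)
    table1.to_csv(out / "table1_descriptives.csv", index=False)
    model_table.to_csv(out / "logistic_models.csv", index=False)
    overlap.to_csv(out / "indicator_overlap_spearman.csv")
    pd.DataFrame(diff_tests).T.to_csv(out / "m0_group_difference_tests.csv")

    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "scheme": config.scheme,
        "d": config.d,
        "n_boot": config.n_boot,
        "n_participants": int(matrix.n),
        "simulated": config.sim_config is not None,
        "sim_seed": config.sim_config.seed if config.sim_config else None,
        "registry_indicators": len(registry.indicators),
        "subgroups": list(config.subgroup_columns),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))

    return {
        "matrix": matrix,
        "analytic": analytic,
        "overall": overall,
        "subgroups": subgroup_tables,
        "curves": curve_table,
        "contributions": contrib_by_group,
        "radar": radar,
        "gap_pci": gap_pci,
        "gap_pcp": gap_pcp,
        "difference_tests": diff_tests,
        "table1": table1,
        "models": models,
        "model_table": model_table,
        "overlap": overlap,
        "manifest": manifest,
    }
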