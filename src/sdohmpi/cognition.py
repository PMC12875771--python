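"""Binary cognitive outcomes: PCI from the MoCA, PCP from the PACC.

Possible cognitive impairment (PCI) is a Montreal Cognitive Assessment
total of 23 or below.  Poor cognitive performance (PCP) comes from the
preclinical Alzheimer's cognitive composite (PACC): z-score each component
test against the analytic sample, reverse-code the timed Trail Making
tests so that higher is always better, average the z-scores, and flag
scores at or below one sample SD under the sample mean.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "MOCA_CUTOFF",
    "classify_moca",
    "compute_pacc",
    "classify_pacc",
    "attach_cognitive_labels",
    "PACC_COMPONENTS",
]

MOCA_CUTOFF = 23

#: Default PACC component columns and their coding direction.  Free and
#: cued recall enter as one combined episodic-memory component; Trails A
#: and B are reverse-coded (longer time = worse performance).
PACC_COMPONENTS: dict[str, int] = {
    "recall_total": +1,
    "trails_a_seconds": -1,
    "trails_b_seconds": -1,
    "animal_naming": +1,
}


def classify_moca(moca_total) -> np.ndarray:
    """PCI indicator: 1 iff MoCA total <= 23 (inclusive).

    Accepts a scalar or vector of integer totals in 0-30.
    """
    arr = np.asarray(moca_total, dtype=float)
    valid = arr[~np.isnan(arr)]
    if valid.size and (valid.min() < 0 or valid.max() > 30):
        raise ValueError("MoCA totals must lie in 0-30")
    out = np.where(arr <= MOCA_CUTOFF, 1.0, 0.0)
    out[np.isnan(arr)] = np.nan
    return out if out.ndim else float(out)


def _zscore(x: np.ndarray, name: str) -> np.ndarray:
    mean = np.mean(x)
    sd = np.std(x, ddof=1)
    if sd == 0:
        raise ValueError(f"PACC component {name!r}: degenerate scale (zero SD)")
    return (x - mean) / sd


def compute_pacc(
    components: pd.DataFrame,
    directions: dict[str, int] | None = None,
) -> pd.Series:
    """PACC composite: mean of component z-scores, trails reverse-coded.

    ``components`` holds one column per component test for the whole
    analytic sample (z-scores are sample-referenced, n-1 SD).
    ``directions`` maps column -> +1/-1; -1 components are negated after
    z-scoring so that higher always means better.
    """
    if len(components) < 2:
        raise ValueError("PACC needs at least 2 participants to form z-scores")
    directions = dict(PACC_COMPONENTS) if directions is None else directions
    missing = set(directions) - set(components.columns)
    if missing:
        raise KeyError(f"PACC components absent from table: {sorted(missing)}")
    zs = []
    for col, sign in directions.items():
        z = _zscore(components[col].to_numpy(dtype=float), col)
        zs.append(sign * z)
    pacc = np.mean(np.column_stack(zs), axis=1)
    return pd.Series(pacc, index=components.index, name="pacc_score")


def classify_pacc(pacc_scores, threshold_sd: float = 1.0, strict: bool = False) -> np.ndarray:
    """PCP indicator: 1 iff PACC <= mean - threshold_sd * SD of the sample.

    ``strict`` switches the boundary to a strict "<".
    """
    scores = np.asarray(pacc_scores, dtype=float)
    if len(scores) < 2:
        raise ValueError("need >= 2 PACC scores")
    mean = float(np.mean(scores))
    sd = float(np.std(scores, ddof=1))
    if sd == 0:
        raise ValueError("degenerate PACC scores (zero SD)")
    cut = mean - threshold_sd * sd
    dep = scores < cut if strict else scores <= cut
    return dep.astype(float)


@dataclass(frozen=True)
class CognitiveLabels:
    pci: pd.Series
    pcp: pd.Series
    pacc_score: pd.Series


def attach_cognitive_labels(
    cohort: pd.DataFrame,
    moca_column: str = "moca_total",
    pacc_directions: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Append pci, pcp and pacc_score columns to a cohort table."""
    out = cohort.copy()
    out["pci"] = classify_moca(out[moca_column])
    pacc = compute_pacc(out, directions=pacc_directions)
    out["pacc_score"] = pacc
    out["pcp"] = classify_pacc(pacc.to_numpy())
    return out
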