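"""Polychoric correlation and the polychoric-PCA asset index.

An asset (wealth) index is built from ordinal ownership items by (1)
estimating the latent bivariate-normal correlation for every item pair
with the standard two-step maximum-likelihood estimator -- thresholds from
the marginal category frequencies via the inverse normal CDF, then the
correlation maximising the bivariate-normal cell likelihood -- (2)
eigendecomposing the polychoric correlation matrix, and (3) scoring
participants on the first eigenvector using normal-score category
quantifications (conditional means of a standard normal between the
estimated thresholds).  Deprivation on the asset index is a score at or
below one sample SD under the sample mean.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = ["polychoric_corr", "polychoric_matrix", "polychoric_pca_scores", "asset_index"]

log = logging.getLogger(__name__)

_EPS = 1e-10


def _thresholds(codes: np.ndarray, n_cat: int) -> np.ndarray:
    """Normal thresholds (length n_cat - 1) from marginal category frequencies."""
    counts = np.bincount(codes, minlength=n_cat).astype(float)
    cum = np.cumsum(counts)[:-1] / counts.sum()
    cum = np.clip(cum, _EPS, 1 - _EPS)
    return stats.norm.ppf(cum)


def _cell_probs(tau_x: np.ndarray, tau_y: np.ndarray, rho: float) -> np.ndarray:
    """Rectangle probabilities of a standard bivariate normal with corr rho."""
    ax = np.concatenate(([-np.inf], tau_x, [np.inf]))
    ay = np.concatenate(([-np.inf], tau_y, [np.inf]))
    biv = stats.multivariate_normal(mean=[0.0, 0.0], cov=[[1.0, rho], [rho, 1.0]])

    def cdf(x: float, y: float) -> float:
        if np.isinf(x) and x < 0 or np.isinf(y) and y < 0:
            return 0.0
        xx = 1e10 if np.isinf(x) else x
        yy = 1e10 if np.isinf(y) else y
        return float(biv.cdf([xx, yy]))

    nx, ny = len(ax) - 1, len(ay) - 1
    cdf_grid = np.array([[cdf(ax[i], ay[j]) for j in range(ny + 1)] for i in range(nx + 1)])
    probs = (
        cdf_grid[1:, 1:] - cdf_grid[:-1, 1:] - cdf_grid[1:, :-1] + cdf_grid[:-1, :-1]
    )
    return np.clip(probs, _EPS, None)


def polychoric_corr(x, y) -> float:
    """Two-step ML polychoric correlation between two ordinal variables.

    Parameters are integer category codes (any ordered values); pairs with
    missing entries (NaN) are dropped.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    if len(x) < 2:
        raise ValueError("polychoric correlation needs at least 2 complete pairs")

    cx = np.unique(x)
    cy = np.unique(y)
    if len(cx) < 2 or len(cy) < 2:
        raise ValueError("each item needs at least 2 observed categories")
    xi = np.searchsorted(cx, x)
    yi = np.searchsorted(cy, y)

    table = np.zeros((len(cx), len(cy)))
    np.add.at(table, (xi, yi), 1.0)

    tau_x = _thresholds(xi, len(cx))
    tau_y = _thresholds(yi, len(cy))

    def neg_loglik(rho: float) -> float:
        return -float(np.sum(table * np.log(_cell_probs(tau_x, tau_y, rho))))

    res = optimize.minimize_scalar(neg_loglik, bounds=(-0.999, 0.999), method="bounded")
    return float(res.x)


def polychoric_matrix(items: pd.DataFrame) -> pd.DataFrame:
    """Pairwise polychoric correlation matrix of ordinal items."""
    cols = list(items.columns)
    k = len(cols)
    mat = np.eye(k)
    for i in range(k):
        for j in range(i + 1, k):
            mat[i, j] = mat[j, i] = polychoric_corr(items.iloc[:, i], items.iloc[:, j])
    return pd.DataFrame(mat, index=cols, columns=cols)


def _repair_psd(corr: np.ndarray, floor: float = 1e-6) -> np.ndarray:
    vals, vecs = np.linalg.eigh(corr)
    if vals.min() >= floor:
        return corr
    log.warning(
        "polychoric correlation matrix not positive definite "
        "(min eigenvalue %.3g); clipping eigenvalues at %.1g", vals.min(), floor
    )
    warnings.warn("polychoric correlation matrix repaired by eigenvalue clipping")
    vals = np.clip(vals, floor, None)
    repaired = vecs @ np.diag(vals) @ vecs.T
    d = np.sqrt(np.diag(repaired))
    return repaired / np.outer(d, d)


def polychoric_pca_scores(items: pd.DataFrame) -> tuple[pd.Series, np.ndarray, np.ndarray]:
    """First-principal-component scores of the polychoric correlation matrix.

    Returns ``(scores, loadings, eigenvalues)``.  Each participant's score is
    the loading-weighted sum of normal-score quantifications of their item
    categories.  The component sign is fixed so that higher raw categories
    (more assets) give higher scores.
    """
    if items.shape[1] < 2:
        raise ValueError("asset index needs at least 2 items")
    corr = _repair_psd(polychoric_matrix(items).to_numpy())
    vals, vecs = np.linalg.eigh(corr)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    loadings = vecs[:, 0]

    quant = np.zeros(items.shape, dtype=float)
    for j, col in enumerate(items.columns):
        x = np.asarray(items[col], dtype=float)
        cats = np.unique(x[~np.isnan(x)])
        codes = np.searchsorted(cats, x)
        tau = np.concatenate(([-np.inf], _thresholds(codes[~np.isnan(x)], len(cats)), [np.inf]))
        # E[Z | tau_{c} < Z <= tau_{c+1}] for each observed category
        lo, hi = tau[codes], tau[codes + 1]
        mass = stats.norm.cdf(hi) - stats.norm.cdf(lo)
        quant[:, j] = (stats.norm.pdf(lo) - stats.norm.pdf(hi)) / np.clip(mass, _EPS, None)

    scores = quant @ loadings
    # orient: more assets -> higher score
    raw_total = items.sum(axis=1).to_numpy(dtype=float)
    if np.std(raw_total) > 0 and np.corrcoef(scores, raw_total)[0, 1] < 0:
        scores = -scores
        loadings = -loadings
    return pd.Series(scores, index=items.index, name="asset_score"), loadings, vals


def asset_index(items: pd.DataFrame, threshold_sd: float = 1.0) -> tuple[pd.Series, pd.Series]:
    """Asset-index scores and the binary asset deprivation indicator.

    Deprived iff score <= mean - threshold_sd * SD (sample statistics,
    n - 1 denominator).
    """
    scores, _, _ = polychoric_pca_scores(items)
    sd = scores.std(ddof=1)
    if sd == 0:
        raise ValueError("degenerate asset-index scores (zero variance)")
    cut = scores.mean() - threshold_sd * sd
    deprived = (scores <= cut).astype(int)
    deprived.name = "asset_deprived"
    return scores, deprived
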