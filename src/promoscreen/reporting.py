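"""Comparison artifacts: correlations, clustered heatmap matrices, PCA.

These are the descriptive outputs used to compare score sets: Pearson
correlation between matched score vectors (e.g. library vs validation
scores per tissue), hierarchically clustered log-rescaled score matrices
for heatmap display, and PCA projections of tissue/animal observations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

logger = logging.getLogger("promoscreen")


@dataclass(frozen=True)
class CorrelationResult:
    r: float  # NaN when undefined (zero variance or n < 3)
    n: int
    p_value: float
    pairing: str = ""


def pearson(x, y, pairing: str = "") -> CorrelationResult:
    """Product-moment correlation of two paired score vectors.

    Pairs with a masked value in either vector are dropped listwise.
    With fewer than 3 surviving pairs or zero variance in either vector
    the coefficient is undefined and reported as NaN.
    """
    x = pd.Series(np.asarray(x, dtype=float))
    y = pd.Series(np.asarray(y, dtype=float))
    if len(x) != len(y):
        raise ValueError(f"length mismatch: {len(x)} vs {len(y)}")
    ok = x.notna() & y.notna()
    x, y = x[ok], y[ok]
    n = int(ok.sum())
    if n < 3 or x.std() == 0 or y.std() == 0:
        logger.warning("pearson undefined (n=%d or zero variance)", n)
        return CorrelationResult(r=float("nan"), n=n, p_value=float("nan"), pairing=pairing)
    res = stats.pearsonr(x, y)
    return CorrelationResult(
        r=float(res.statistic), n=n, p_value=float(res.pvalue), pairing=pairing
    )


@dataclass
class ClusteredMatrix:
    """Log-rescaled, cluster-ordered score matrix for heatmap display."""

    values: pd.DataFrame  # transformed values in clustered order
    row_order: list
    col_order: list
    method: str
    metric: str
    clustered: bool
    note: str = ""


def _log_rescale(df: pd.DataFrame) -> pd.DataFrame:
    """Natural log with zero handling: ln(max(x, eps)), eps = half the
    smallest positive entry.  Monotone on positive values."""
    arr = df.to_numpy(dtype=float)
    pos = arr[np.isfinite(arr) & (arr > 0)]
    if pos.size == 0:
        raise ValueError("log transform needs at least one positive entry")
    eps = pos.min() / 2.0
    return pd.DataFrame(
        np.log(np.maximum(arr, eps)), index=df.index, columns=df.columns
    )


def _leaf_order(mat: np.ndarray, method: str, metric: str) -> np.ndarray:
    link = hierarchy.linkage(pdist(mat, metric=metric), method=method)
    return hierarchy.leaves_list(link)


def cluster_matrix(
    scores: pd.DataFrame,
    log_transform: bool = True,
    method: str = "complete",
    metric: str = "euclidean",
) -> ClusteredMatrix:
    """Agglomerative clustering of rows and columns of a score matrix.

    Distances are computed on the (optionally log-rescaled) values;
    scipy's linkage is deterministic, with equal-distance merges resolved
    by lowest cluster index.  An all-constant matrix cannot be clustered
    meaningfully: input order is retained with a notice.
    """
    df = scores.dropna(axis=0, how="all").dropna(axis=1, how="all")
    if df.shape[0] < 2 or df.shape[1] < 2:
        raise ValueError("need >= 2 rows and >= 2 columns after masking")
    vals = _log_rescale(df) if log_transform else df.astype(float)
    filled = vals.fillna(vals.mean().mean())  # distance computation only
    arr = filled.to_numpy()
    if np.allclose(arr, arr.flat[0]):
        logger.warning("all-constant matrix: clustering skipped, input order kept")
        return ClusteredMatrix(
            values=vals, row_order=list(df.index), col_order=list(df.columns),
            method=method, metric=metric, clustered=False,
            note="constant matrix; clustering skipped",
        )
    row_order = [df.index[i] for i in _leaf_order(arr, method, metric)]
    col_order = [df.columns[i] for i in _leaf_order(arr.T, method, metric)]
    return ClusteredMatrix(
        values=vals.loc[row_order, col_order],
        row_order=row_order,
        col_order=col_order,
        method=method,
        metric=metric,
        clustered=True,
    )


@dataclass
class PcaResult:
    coordinates: pd.DataFrame  # observations x components
    explained_variance_ratio: np.ndarray
    components: pd.DataFrame  # components x features (loadings)


def pca_project(matrix: pd.DataFrame, scale: bool = False) -> PcaResult:
    """PCA of observations x features score data.

    Columns are centered; variance scaling is off by default (matching
    the common default of R's prcomp) and available via ``scale``.  Each
    component is oriented so that its largest-magnitude loading is
    positive, making signs stable across runs and implementations.
    """
    df = matrix.dropna(axis=0, how="any")
    if df.shape[0] < 2 or df.shape[1] < 2:
        raise ValueError("need >= 2 complete observations and >= 2 features")
    x = df.to_numpy(dtype=float)
    x = x - x.mean(axis=0)
    if scale:
        sd = x.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        x = x / sd
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    if not np.any(s > 1e-12):
        raise ValueError("matrix has rank 0 after centering")
    # sign convention: largest-|loading| positive per component
    for k in range(vt.shape[0]):
        j = np.argmax(np.abs(vt[k]))
        if vt[k, j] < 0:
            vt[k] *= -1.0
            u[:, k] *= -1.0
    coords = u * s
    var = s**2
    evr = var / var.sum()
    comp_names = [f"PC{k + 1}" for k in range(len(s))]
    return PcaResult(
        coordinates=pd.DataFrame(coords, index=df.index, columns=comp_names),
        explained_variance_ratio=evr,
        components=pd.DataFrame(vt, index=comp_names, columns=df.columns),
    )
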