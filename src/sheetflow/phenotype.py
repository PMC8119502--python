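"""Multidimensional migration phenotypes and their clustering.

Replicates are paired: every cell line is measured on the same plate as its
control, so each (metric, line) entry of the phenotype matrix is a paired
t-statistic — the mean per-replicate difference from control divided by its
standard error.  Metrics and cell lines are then clustered hierarchically on
correlation distance (1 − sample correlation, average linkage, optimal leaf
ordering) and the leaf-ordered correlation matrix is segmented into
contiguous blocks by a greedy search scored with a Bayesian information
criterion (two-Gaussian model of within- versus between-block correlations).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import leaves_list, linkage, optimal_leaf_ordering
from scipy.spatial.distance import pdist

logger = logging.getLogger(__name__)

__all__ = [
    "paired_t_statistic",
    "build_phenotype_matrix",
    "ClusterTree",
    "cluster_tree",
    "block_split_bic",
    "bic_for_boundaries",
    "confidence_interval",
]

_VAR_FLOOR = 1e-6


class ZeroVarianceError(ValueError):
    pass


def paired_t_statistic(values_line: Sequence[float], values_control: Sequence[float]) -> float:
    """Mean paired difference over its standard error (sample SD, n−1).

    All-zero differences give t = 0; zero-variance differences with a
    nonzero mean are degenerate (t would be infinite) and raise.
    """
    a = np.asarray(values_line, dtype=float)
    b = np.asarray(values_control, dtype=float)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("need ≥ 2 paired values of equal length")
    d = a - b
    if np.all(d == 0):
        return 0.0
    sd = d.std(ddof=1)
    if sd == 0:
        raise ZeroVarianceError("paired differences have zero variance but nonzero mean")
    return float(d.mean() / (sd / np.sqrt(d.size)))


def build_phenotype_matrix(
    table: pd.DataFrame,
    control: str,
    reference: Optional[str] = None,
) -> pd.DataFrame:
    """Phenotype matrix (metrics × cell lines) of paired t-statistics.

    ``table`` is tidy with columns ``replicate, cell_line, metric, value``
    (technical replicates already averaged).  Each line is compared against
    ``control`` — or against ``reference`` if given (e.g. comparing a double
    mutant against each single mutant).  Replicates missing either member of
    a pair are dropped with a warning.
    """
    required = {"replicate", "cell_line", "metric", "value"}
    if not required.issubset(table.columns):
        raise ValueError(f"table needs columns {sorted(required)}")
    ref = reference if reference is not None else control
    if ref not in set(table["cell_line"]):
        raise ValueError(f"reference line {ref!r} not present in table")
    wide = table.pivot_table(index="replicate", columns=["cell_line", "metric"], values="value")
    lines = [l for l in wide.columns.get_level_values(0).unique() if l != ref]
    metrics = list(table["metric"].unique())
    out = pd.DataFrame(index=metrics, columns=lines, dtype=float)
    for line in lines:
        for metric in metrics:
            pair = wide[[(line, metric), (ref, metric)]].dropna()
            dropped = len(wide) - len(pair)
            if dropped:
                logger.warning(
                    "%s/%s: dropped %d replicate(s) without a matched %s measurement",
                    line, metric, dropped, ref,
                )
            out.loc[metric, line] = paired_t_statistic(
                pair[(line, metric)].to_numpy(), pair[(ref, metric)].to_numpy()
            )
    return out


@dataclass
class ClusterTree:
    """Average-linkage correlation-distance tree with optimal leaf order."""

    linkage_matrix: np.ndarray
    labels: list[str]
    leaf_order: list[str]
    axis: str


def cluster_tree(matrix: pd.DataFrame, axis: str = "metrics") -> ClusterTree:
    """Agglomerative tree over metrics (rows) or cell lines (columns).

    Correlation distance, 'average' linkage; leaves ordered to minimize the
    summed distance between adjacent leaves (exact optimal leaf ordering).
    Profiles with zero variance have undefined correlation and raise.
    """
    if axis == "metrics":
        X = matrix.to_numpy(dtype=float)
        labels = list(matrix.index)
    elif axis in ("lines", "cell_lines"):
        X = matrix.to_numpy(dtype=float).T
        labels = list(matrix.columns)
    else:
        raise ValueError("axis must be 'metrics' or 'lines'")
    if X.shape[0] < 2:
        raise ValueError("need at least two items to cluster")
    sd = X.std(axis=1)
    if np.any(sd == 0):
        bad = [labels[i] for i in np.flatnonzero(sd == 0)]
        raise ZeroVarianceError(f"zero-variance profile(s): {bad}")
    Z = linkage(X, method="average", metric="correlation")
    Z = optimal_leaf_ordering(Z, X, metric="correlation")
    order = leaves_list(Z)
    return ClusterTree(
        linkage_matrix=Z, labels=labels, leaf_order=[labels[i] for i in order], axis=axis
    )


def _gauss_loglik(x: np.ndarray) -> float:
    var = max(float(np.var(x)), _VAR_FLOOR)
    return float(-0.5 * len(x) * (np.log(2 * np.pi * var) + np.var(x) / var))


def bic_for_boundaries(corr: np.ndarray, boundaries: Sequence[int]) -> float:
    """BIC of a block-diagonal model of a leaf-ordered correlation matrix.

    ``boundaries`` are split positions (block b ends before index boundary).
    Off-diagonal entries are modeled as two Gaussian populations
    (within-block vs between-block).  Parameter count: 2 (mean, var) for a
    single population, else 4 plus one per boundary.
    """
    n = corr.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    vals = corr[iu, ju]
    if len(vals) == 0:
        return 0.0
    bounds = sorted(boundaries)
    lab = np.zeros(n, dtype=int)
    for b in bounds:
        lab[b:] += 1
    within = lab[iu] == lab[ju]
    if not bounds:
        ll = _gauss_loglik(vals)
        k = 2
    else:
        w, btw = vals[within], vals[~within]
        ll = (_gauss_loglik(w) if w.size else 0.0) + (_gauss_loglik(btw) if btw.size else 0.0)
        k = 4 + len(bounds)
    return k * np.log(len(vals)) - 2.0 * ll


def block_split_bic(corr: np.ndarray) -> np.ndarray:
    """Greedy block segmentation of a leaf-ordered correlation matrix.

    Starting from a single block, repeatedly add the one split boundary that
    most decreases the BIC; stop when no boundary improves it.  Returns
    contiguous integer block labels (all zeros for a single block).
    """
    corr = np.asarray(corr, dtype=float)
    n = corr.shape[0]
    if corr.ndim != 2 or corr.shape[0] != corr.shape[1]:
        raise ValueError("need a square matrix")
    if n < 2:
        return np.zeros(n, dtype=int)
    boundaries: list[int] = []
    best = bic_for_boundaries(corr, boundaries)
    while True:
        candidates = [b for b in range(1, n) if b not in boundaries]
        scored = [(bic_for_boundaries(corr, boundaries + [b]), b) for b in candidates]
        if not scored:
            break
        new_bic, new_b = min(scored)
        if new_bic >= best - 1e-12:
            break
        best = new_bic
        boundaries.append(new_b)
    lab = np.zeros(n, dtype=int)
    for b in sorted(boundaries):
        lab[b:] += 1
    return lab


def confidence_interval(
    values: Sequence[float], alpha: float = 0.05
) -> tuple[float, float, float]:
    """t-based CI on the mean: mean ± t_{1−α/2, n−1}·SD/√n (unadjusted)."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("need at least two values")
    m = x.mean()
    se = x.std(ddof=1) / np.sqrt(x.size)
    tcrit = stats.t.ppf(1 - alpha / 2, x.size - 1)
    return float(m), float(m - tcrit * se), float(m + tcrit * se)
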