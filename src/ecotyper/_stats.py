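"""Shared statistical primitives: BH adjustment, rank-sum tests, DBI."""

from __future__ import annotations

from itertools import combinations

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

#: below this total the Wilcoxon rank-sum p is computed by exact enumeration
EXACT_WILCOXON_MAX_GROUP = 8


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (monotone, capped at 1)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must be finite and in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def rank_sum_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided Wilcoxon rank-sum p.

    Groups of at most :data:`EXACT_WILCOXON_MAX_GROUP` each are handled by
    exact enumeration of all assignments of the pooled (possibly tied)
    values, counting assignments whose rank-sum deviates from its mean by
    at least the observed deviation. Larger groups use the normal
    approximation with tie correction and continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 == 0 or n2 == 0:
        raise ValueError("both groups must be non-empty")
    if n1 <= EXACT_WILCOXON_MAX_GROUP and n2 <= EXACT_WILCOXON_MAX_GROUP:
        pooled = np.concatenate([x, y])
        ranks = stats.rankdata(pooled)
        observed = ranks[:n1].sum()
        mean = n1 * (n1 + n2 + 1) / 2.0
        dev = abs(observed - mean)
        count = 0
        total = 0
        for combo in combinations(range(n1 + n2), n1):
            total += 1
            if abs(ranks[list(combo)].sum() - mean) >= dev - 1e-12:
                count += 1
        return count / total
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return float(res.pvalue)


def wilcoxon_marker_p(values: np.ndarray, in_group: np.ndarray) -> float:
    """Rank-sum p for one gene, group mask vs rest."""
    return rank_sum_p(values[in_group], values[~in_group])


def hypergeom_upper_tail(overlap: int, set_size: int, n_markers: int, universe: int) -> float:
    """P(X >= overlap) for X ~ Hypergeom(universe, set_size, n_markers)."""
    if overlap <= 0:
        return 1.0
    return float(stats.hypergeom.sf(overlap - 1, universe, set_size, n_markers))


def davies_bouldin(points: np.ndarray, labels: np.ndarray) -> float:
    """Davies-Bouldin index (lower is better); centroid-based, Euclidean."""
    from sklearn.metrics import davies_bouldin_score

    return float(davies_bouldin_score(points, labels))


def zscore_columns(matrix: np.ndarray, axis: int = 0, ddof: int = 0) -> np.ndarray:
    """Z-score along ``axis``; columns (or rows) with zero variance map to 0."""
    matrix = np.asarray(matrix, dtype=float)
    mean = matrix.mean(axis=axis, keepdims=True)
    sd = matrix.std(axis=axis, ddof=ddof, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (matrix - mean) / sd
    return np.where(sd == 0, 0.0, z)


def log_fold_change(x_in: np.ndarray, x_out: np.ndarray) -> float:
    """Natural-log fold change of (mean expm1 of normalized expression + 1).

    The dominant single-cell convention: undo the log1p, average on the
    linear scale, re-log with a pseudocount of 1.
    """
    return float(np.log((np.expm1(x_in).mean() + 1.0) / (np.expm1(x_out).mean() + 1.0)))
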