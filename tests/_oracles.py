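"""Independent brute-force oracles used to check the package's statistics.

Everything here is written from the textbook definitions — enumeration,
naive loops, closed forms — and deliberately shares no code with the
implementation it checks.
"""

from __future__ import annotations

from itertools import combinations
from math import comb

import numpy as np


def hypergeom_pmf(a: int, row1: int, col1: int, total: int) -> float:
    """P(top-left cell = a) for a 2x2 table with fixed margins."""
    return comb(col1, a) * comb(total - col1, row1 - a) / comb(total, row1)


def fisher_two_sided_enum(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by enumerating all tables with the observed margins."""
    row1, col1, total = a + b, a + c, a + b + c + d
    p_obs = hypergeom_pmf(a, row1, col1, total)
    lo, hi = max(0, row1 + col1 - total), min(row1, col1)
    p = 0.0
    for x in range(lo, hi + 1):
        px = hypergeom_pmf(x, row1, col1, total)
        if px <= p_obs * (1 + 1e-10):
            p += px
    return min(p, 1.0)


def bh_naive(p: np.ndarray) -> np.ndarray:
    """O(m^2) Benjamini-Hochberg: q_i = min over k with p_(k) >= p_i of m*p_(k)/k."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q_sorted = np.empty(m)
    for rank_pos in range(m):
        candidates = [m * p[order[k]] / (k + 1) for k in range(rank_pos, m)]
        q_sorted[rank_pos] = min(1.0, min(candidates))
    q = np.empty(m)
    q[order] = q_sorted
    return q


def davies_bouldin_definition(points: np.ndarray, labels: np.ndarray) -> float:
    """DBI straight from the definition: mean over clusters of max similarity."""
    points = np.asarray(points, dtype=float)
    labels = np.asarray(labels)
    clusters = np.unique(labels)
    centroids = {c: points[labels == c].mean(axis=0) for c in clusters}
    scatter = {
        c: np.mean(np.linalg.norm(points[labels == c] - centroids[c], axis=1))
        for c in clusters
    }
    total = 0.0
    for ci in clusters:
        worst = 0.0
        for cj in clusters:
            if ci == cj:
                continue
            dij = np.linalg.norm(centroids[ci] - centroids[cj])
            worst = max(worst, (scatter[ci] + scatter[cj]) / dij)
        total += worst
    return total / len(clusters)


def wilcoxon_exact_enum(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided rank-sum p by enumerating every group assignment of the pool."""
    from scipy.stats import rankdata

    x, y = np.asarray(x, float), np.asarray(y, float)
    n1 = len(x)
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    mean = n1 * (len(pooled) + 1) / 2.0
    dev = abs(ranks[:n1].sum() - mean)
    hits = total = 0
    for combo in combinations(range(len(pooled)), n1):
        total += 1
        if abs(ranks[list(combo)].sum() - mean) >= dev - 1e-12:
            hits += 1
    return hits / total


def hypergeom_tail_closed_form(overlap: int, set_size: int, n_markers: int,
                               universe: int) -> float:
    """P(X >= overlap) summed from the hypergeometric pmf."""
    hi = min(set_size, n_markers)
    total = 0.0
    for x in range(overlap, hi + 1):
        total += (comb(set_size, x) * comb(universe - set_size, n_markers - x)
                  / comb(universe, n_markers))
    return min(total, 1.0)
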