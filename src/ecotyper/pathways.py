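"""Marker genes, gene-set enrichment, per-cell set scoring, and marker pathways.

Marker detection is one-vs-rest Wilcoxon rank-sum per cluster with the
single-cell log-fold-change convention (natural log of mean expm1 + 1).
Set enrichment over a marker list is a one-sided hypergeometric upper tail
with BH adjustment. Per-cell pathway activity is a rank-based running-sum
statistic (see :func:`sample_set_score`), differential pathway activity a
moderated t with empirical-Bayes variance shrinkage, and the marker
pathway of a cluster is the top enriched-and-differential pathway that
contains one of the cluster's top-10 markers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import _stats
from .datatypes import ExpressionDataset, GeneSetCollection


# ---------------------------------------------------------------------------
# marker genes
# ---------------------------------------------------------------------------

def _tie_term(column: np.ndarray) -> float:
    _, counts = np.unique(column, return_counts=True)
    return float((counts**3 - counts).sum())


def _rank_sum_p_columns(X: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Two-sided rank-sum p per column, group ``mask`` vs rest.

    Exact enumeration when both groups are small (matching
    :func:`ecotyper._stats.rank_sum_p`), otherwise the tie-corrected normal
    approximation with continuity correction.
    """
    n1 = int(mask.sum())
    n2 = X.shape[0] - n1
    if n1 == 0 or n2 == 0:
        raise ValueError("both groups must be non-empty")
    if n1 <= _stats.EXACT_WILCOXON_MAX_GROUP and n2 <= _stats.EXACT_WILCOXON_MAX_GROUP:
        return np.array([_stats.rank_sum_p(col[mask], col[~mask]) for col in X.T])
    n = n1 + n2
    ranks = stats.rankdata(X, axis=0)
    r1 = ranks[mask].sum(axis=0)
    u = r1 - n1 * (n1 + 1) / 2.0
    mean = n1 * n2 / 2.0
    ties = np.array([_tie_term(col) for col in X.T])
    var = n1 * n2 / 12.0 * ((n + 1) - ties / (n * (n - 1)))
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (np.abs(u - mean) - 0.5) / np.sqrt(var)
    p = np.where(var > 0, 2.0 * stats.norm.sf(z), 1.0)
    return np.minimum(p, 1.0)


def find_markers(
    ds: ExpressionDataset,
    labels: np.ndarray | None = None,
    logfc_min: float | None = None,
    p_adj_max: float | None = None,
    min_pct: float | None = None,
    groups: list[str] | None = None,
) -> pd.DataFrame:
    """One-vs-rest Wilcoxon marker table per cluster.

    Returns one row per (cluster, gene) with ``logfc`` (natural-log fold
    change of mean expm1 + 1), ``pct_in``/``pct_out`` (detection fractions)
    and BH-adjusted p within each cluster. When thresholds are given they
    are applied as strict inequalities (``logfc > logfc_min``,
    ``p_adj < p_adj_max``, ``pct_in > min_pct``).
    """
    if labels is None:
        if ds.cell_label is None:
            raise ValueError("no labels given and dataset carries no cell_label")
        labels = ds.cell_label
    labels = np.asarray(labels).astype(str)
    X = ds.matrix
    frames = []
    clusters = np.unique(labels) if groups is None else [str(g) for g in groups]
    for cluster in clusters:
        mask = labels == cluster
        if not mask.any():
            raise ValueError(f"cluster {cluster!r} absent from labels")
        if mask.all():
            raise ValueError("a single cluster covers all cells; markers undefined")
        x_in, x_out = X[mask], X[~mask]
        logfc = np.log((np.expm1(x_in).mean(axis=0) + 1.0)
                       / (np.expm1(x_out).mean(axis=0) + 1.0))
        p = _rank_sum_p_columns(X, mask)
        frames.append(pd.DataFrame({
            "cluster": cluster,
            "gene": ds.gene_ids,
            "logfc": logfc,
            "pct_in": (x_in > 0).mean(axis=0),
            "pct_out": (x_out > 0).mean(axis=0),
            "p": p,
            "p_adj": _stats.bh_adjust(p),
        }))
    table = pd.concat(frames, ignore_index=True)
    if logfc_min is not None:
        table = table[table["logfc"] > logfc_min]
    if p_adj_max is not None:
        table = table[table["p_adj"] < p_adj_max]
    if min_pct is not None:
        table = table[table["pct_in"] > min_pct]
    return table.reset_index(drop=True)


# ---------------------------------------------------------------------------
# hypergeometric enrichment
# ---------------------------------------------------------------------------

def hypergeometric_enrichment(
    markers: list[str],
    collection: GeneSetCollection,
    universe: list[str],
) -> pd.DataFrame:
    """One-sided hypergeometric over-representation of each set in ``markers``.

    The ``enrichment_score`` column is -log10 of the BH q-value, the
    ranking statistic used downstream (the raw q is also emitted).
    """
    universe_set = set(universe)
    marker_set = set(markers) & universe_set
    n_universe, n_markers = len(universe_set), len(marker_set)
    rows = []
    for name, genes in collection.items():
        members = set(genes) & universe_set
        overlap = len(members & marker_set)
        p = _stats.hypergeom_upper_tail(overlap, len(members), n_markers, n_universe)
        rows.append({"set": name, "overlap": overlap, "set_size": len(members), "p": p})
    table = pd.DataFrame(rows)
    table["q"] = _stats.bh_adjust(table["p"].to_numpy())
    with np.errstate(divide="ignore"):
        table["enrichment_score"] = -np.log10(np.maximum(table["q"], 1e-300))
    return table


# ---------------------------------------------------------------------------
# per-cell rank-based set scoring
# ---------------------------------------------------------------------------

def sample_set_score(
    ds: ExpressionDataset | np.ndarray,
    genes: list[str],
    gene_ids: np.ndarray | None = None,
    weight_exponent: float = 0.25,
) -> np.ndarray:
    """Per-cell rank-based activity of one gene set.

    For a cell with ranks :math:`r_j` (1 = lowest expression, average
    ties) and weights :math:`w_j = r_j^{0.25}`, genes are walked in
    decreasing expression order and the score is

    .. math::

        \\frac{1}{G}\\sum_i \\Big[\\frac{S_{in}(i)}{m\\,W/G}
                               - \\frac{S_{all}(i)}{W}\\Big],

    the weighted in-set running mass normalized by its expectation under
    random gene placement, minus the weighted all-gene CDF (``m`` set
    genes, ``G`` genes, ``W`` total weight). The score depends only on
    within-cell ranks and its null expectation over random placements is
    exactly zero.
    """
    if isinstance(ds, ExpressionDataset):
        X, gene_ids = ds.matrix, ds.gene_ids
    else:
        X = np.asarray(ds, dtype=float)
        if gene_ids is None:
            raise ValueError("gene_ids required when passing a bare matrix")
    member = np.isin(np.asarray(gene_ids).astype(str), list(genes))
    m = int(member.sum())
    if m == 0:
        raise ValueError("gene set has no overlap with the matrix genes")
    n_cells, G = X.shape
    scores = np.empty(n_cells)
    for i in range(n_cells):
        ranks = stats.rankdata(X[i])
        order = np.argsort(-ranks, kind="stable")
        w = ranks[order] ** weight_exponent
        in_set = member[order]
        W = w.sum()
        s_all = np.cumsum(w)
        s_in = np.cumsum(w * in_set)
        scores[i] = float(np.sum(s_in / (m * W / G) - s_all / W)) / G
    return scores


def pathway_score_matrix(
    ds: ExpressionDataset, collection: GeneSetCollection, weight_exponent: float = 0.25
) -> pd.DataFrame:
    """Sets x cells matrix of :func:`sample_set_score` values."""
    data = {name: sample_set_score(ds, genes, weight_exponent=weight_exponent)
            for name, genes in collection.items()}
    return pd.DataFrame(data, index=ds.cell_ids).T


# ---------------------------------------------------------------------------
# differential pathways (moderated t)
# ---------------------------------------------------------------------------

def differential_pathways(
    scores: pd.DataFrame,
    labels: np.ndarray,
    logfc_min: float = 0.0,
    p_adj_max: float = 0.05,
    method: str = "moderated",
    prior_df: float = 4.0,
) -> pd.DataFrame:
    """Per-cluster one-vs-rest differential pathway activity.

    ``scores`` is sets x cells. ``method="moderated"`` shrinks per-set
    pooled variances toward their mean with ``prior_df`` pseudo-degrees of
    freedom (empirical-Bayes); ``method="welch"`` is a plain Welch t.
    Rows passing ``diff > logfc_min`` and ``p_adj < p_adj_max`` (strict)
    are returned.
    """
    labels = np.asarray(labels).astype(str)
    if scores.shape[1] != len(labels):
        raise ValueError("scores columns and labels disagree")
    X = scores.to_numpy(dtype=float)
    frames = []
    for cluster in np.unique(labels):
        mask = labels == cluster
        n1, n2 = int(mask.sum()), int((~mask).sum())
        if n1 < 2 or n2 < 2:
            continue
        a, b = X[:, mask], X[:, ~mask]
        diff = a.mean(axis=1) - b.mean(axis=1)
        if method == "welch":
            t, p = stats.ttest_ind(a, b, axis=1, equal_var=False)
            p = np.asarray(p)
        elif method == "moderated":
            df = n1 + n2 - 2
            s2 = ((a.var(axis=1, ddof=1) * (n1 - 1) + b.var(axis=1, ddof=1) * (n2 - 1)) / df)
            s2_0 = float(np.mean(s2)) if np.mean(s2) > 0 else 1e-12
            s2_post = (prior_df * s2_0 + df * s2) / (prior_df + df)
            se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
            with np.errstate(invalid="ignore", divide="ignore"):
                t = diff / se
            p = 2.0 * stats.t.sf(np.abs(t), df + prior_df)
        else:
            raise ValueError("method must be 'moderated' or 'welch'")
        frames.append(pd.DataFrame({
            "cluster": cluster, "set": scores.index, "diff": diff, "t": t,
            "p": p, "p_adj": _stats.bh_adjust(np.nan_to_num(p, nan=1.0)),
        }))
    table = pd.concat(frames, ignore_index=True)
    return table[(table["diff"] > logfc_min) & (table["p_adj"] < p_adj_max)].reset_index(drop=True)


# ---------------------------------------------------------------------------
# marker-pathway determination
# ---------------------------------------------------------------------------

@dataclass
class MarkerPathwayCall:
    cluster: str
    pathway: str
    enrichment_q: float
    enrichment_score: float
    marker_gene: str


def marker_pathway(
    cluster: str,
    enrichment: pd.DataFrame,
    differential: pd.DataFrame,
    markers: pd.DataFrame,
    collection: GeneSetCollection,
    top_n_markers: int = 10,
) -> MarkerPathwayCall | None:
    """Determine a cluster's marker pathway, or ``None`` when no call is possible.

    Candidates are the intersection of enriched and differential pathways
    for the cluster, ranked by enrichment score (-log10 q; ties break
    toward the smaller set, then lexicographically). The first candidate
    containing at least one of the cluster's top-10 markers by log-fold
    change wins; the call's marker gene is the max-logFC top marker inside
    that pathway.
    """
    cluster = str(cluster)
    diff_sets = set(differential.loc[differential["cluster"] == cluster, "set"])
    cand = enrichment[enrichment["set"].isin(diff_sets)].copy()
    if cand.empty:
        return None
    cl_markers = markers[markers["cluster"] == cluster].sort_values("logfc", ascending=False)
    top = list(cl_markers["gene"].head(top_n_markers))
    if not top:
        return None
    cand = cand.sort_values(
        by=["enrichment_score", "set_size", "set"], ascending=[False, True, True]
    )
    for _, row in cand.iterrows():
        members = set(collection[row["set"]])
        hits = [g for g in top if g in members]
        if hits:
            # top is already sorted by descending logfc
            return MarkerPathwayCall(
                cluster=cluster,
                pathway=row["set"],
                enrichment_q=float(row["q"]),
                enrichment_score=float(row["enrichment_score"]),
                marker_gene=hits[0],
            )
    return None


# ---------------------------------------------------------------------------
# polarization scores
# ---------------------------------------------------------------------------

def polarization_scores(
    ds: ExpressionDataset,
    labels: np.ndarray,
    axis1: tuple[str, list[str]],
    axis2: tuple[str, list[str]],
) -> pd.DataFrame:
    """Per-cluster mean scores on two opposing functional axes.

    ``axis1``/``axis2`` are (name, gene list) pairs — e.g. M1 vs M2, or
    angiogenic vs phagocytic. The result is butterfly-plot-ready: one row
    per cluster with the two mean set scores.
    """
    labels = np.asarray(labels).astype(str)
    name1, genes1 = axis1
    name2, genes2 = axis2
    s1 = sample_set_score(ds, genes1)
    s2 = sample_set_score(ds, genes2)
    rows = []
    for cluster in np.unique(labels):
        mask = labels == cluster
        rows.append({"cluster": cluster, name1: float(s1[mask].mean()),
                     name2: float(s2[mask].mean()), "n_cells": int(mask.sum())})
    return pd.DataFrame(rows)
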