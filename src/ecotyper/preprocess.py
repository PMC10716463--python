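"""QC filtering, normalization, two-run clustering, and annotation-method comparison.

The two-run clustering scheme reduces technical noise: a first coarse run
(top-2000 variable genes, 15 PCs, SNN graph, Leiden) yields the major cell
types; a second run re-clusters each coarse type at very high resolution
(default 50) into mini-clusters, and mini-clusters dominated by another
major type's marker panel are flagged as contaminants and excluded.
"""

from __future__ import annotations

import warnings
from dataclasses import replace

import numpy as np
import pandas as pd

from . import _stats
from .datatypes import (
    DROPLET,
    FULL_LENGTH,
    ClusterModel,
    ExpressionDataset,
    GeneSetCollection,
    MarkerPanel,
    QCThresholds,
)

CONTAMINANT_LABEL = "contaminant"


class AllCellsFilteredError(ValueError):
    pass


class AlreadyNormalizedError(ValueError):
    pass


def qc_filter(ds: ExpressionDataset, thr: QCThresholds | None = None) -> ExpressionDataset:
    """Remove droplet cells failing the UMI / detected-gene / mito-fraction gates.

    A cell is removed when it has fewer than ``thr.min_umi`` counts, fewer
    than ``thr.min_genes`` detected genes, or a mitochondrial fraction above
    ``thr.max_mito_fraction`` — strict inequalities, so ties at the
    thresholds are retained. Full-length TPM data bypasses the filter with
    a warning (those cells arrive quality-passed).
    """
    thr = thr or QCThresholds()
    if ds.platform == FULL_LENGTH:
        warnings.warn("full-length TPM data bypasses droplet QC", stacklevel=2)
        return ds
    if ds.normalized:
        raise ValueError("qc_filter expects raw counts, not normalized data")
    stats = ds.qc_stats()
    keep = (
        (stats["total_counts"].to_numpy() >= thr.min_umi)
        & (stats["n_genes_detected"].to_numpy() >= thr.min_genes)
        & (stats["mito_fraction"].to_numpy() <= thr.max_mito_fraction)
    )
    if not keep.any():
        raise AllCellsFilteredError("all cells filtered by QC thresholds")
    return ds.subset_cells(keep)


def normalize(ds: ExpressionDataset, droplet_target: float = 1e4) -> ExpressionDataset:
    """Library-size normalization.

    Droplet counts are scaled per cell to ``droplet_target`` total and
    ln(x+1)-transformed; full-length TPM is log2(x+1)-transformed. Calling
    this twice raises.
    """
    if ds.normalized:
        raise AlreadyNormalizedError("dataset is already normalized")
    if ds.platform == DROPLET:
        totals = ds.matrix.sum(axis=1, keepdims=True)
        totals[totals == 0] = 1.0
        matrix = np.log1p(ds.matrix / totals * droplet_target)
    else:
        matrix = np.log2(ds.matrix + 1.0)
    return replace(ds, matrix=matrix, normalized=True)


# ---------------------------------------------------------------------------
# graph clustering (scanpy-backed)
# ---------------------------------------------------------------------------

def leiden_cluster(
    matrix: np.ndarray,
    resolution: float,
    n_pcs: int = 15,
    n_neighbors: int = 20,
    n_top_genes: int | None = 2000,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """HVG -> PCA -> SNN graph -> Leiden. Returns (labels, PC embedding)."""
    import anndata as ad
    import scanpy as sc

    n_cells, n_genes = matrix.shape
    n_pcs = min(n_pcs, n_cells - 1, n_genes - 1)
    if n_pcs < 1:
        raise ValueError("fewer cells than principal components")
    adata = ad.AnnData(X=np.asarray(matrix, dtype=np.float64))
    if n_top_genes is not None and n_top_genes < n_genes:
        sc.pp.highly_variable_genes(adata, n_top_genes=n_top_genes)
        adata = adata[:, adata.var["highly_variable"]].copy()
    sc.pp.pca(adata, n_comps=n_pcs, svd_solver="arpack", random_state=seed)
    sc.pp.neighbors(adata, n_neighbors=min(n_neighbors, n_cells - 1), n_pcs=n_pcs,
                    random_state=seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", FutureWarning)
        sc.tl.leiden(adata, resolution=resolution, random_state=seed, key_added="leiden",
                     flavor="leidenalg")
    return adata.obs["leiden"].to_numpy().astype(str), adata.obsm["X_pca"].copy()


def _panel_scores(ds: ExpressionDataset, panel: MarkerPanel) -> pd.DataFrame:
    """Per-cell mean z-scored expression of each panel (missing genes skipped)."""
    present = set(ds.gene_ids)
    scores = {}
    for cell_type in panel.types():
        genes = [g for g in panel[cell_type] if g in present]
        if not genes:
            scores[cell_type] = np.zeros(ds.n_cells)
            continue
        sub = ds.subset_genes(genes).matrix
        scores[cell_type] = _stats.zscore_columns(sub, axis=0).mean(axis=1)
    return pd.DataFrame(scores, index=ds.cell_ids)


def two_run_cluster(
    ds: ExpressionDataset,
    resolution_first: float = 0.3,
    panel: MarkerPanel | None = None,
    resolution_mini: float = 50.0,
    contaminant_margin: float = 1.0,
    n_pcs: int = 15,
    n_neighbors: int = 20,
    n_top_genes: int = 2000,
    seed: int = 0,
) -> ClusterModel:
    """Coarse clustering followed by a mini-cluster contaminant purge.

    When a marker panel is supplied, each coarse cluster is assigned its
    major type (majority of the per-cell argmax panel score — robust even
    when one coarse cluster spans almost the whole dataset), then
    re-clustered at ``resolution_mini`` into mini-clusters. A mini-cluster
    whose mean panel score for some *other* major type exceeds its own
    type's score by more than ``contaminant_margin`` (z-score units; the
    margin absorbs the per-cell noise of small panels in tiny
    mini-clusters) is labeled ``"contaminant"`` in the returned model.
    """
    if not ds.normalized:
        raise ValueError("two_run_cluster expects normalized data")
    if ds.n_cells < n_pcs:
        raise ValueError(f"{ds.n_cells} cells is fewer than n_pcs={n_pcs}")
    labels, embedding = leiden_cluster(
        ds.matrix, resolution_first, n_pcs=n_pcs, n_neighbors=n_neighbors,
        n_top_genes=n_top_genes, seed=seed,
    )
    final = labels.astype(object).copy()
    if panel is not None:
        scores = _panel_scores(ds, panel)
        cell_argmax = scores.idxmax(axis=1).to_numpy()
        for cluster in np.unique(labels):
            rows = np.where(labels == cluster)[0]
            own_type = pd.Series(cell_argmax[rows]).mode().iloc[0]
            if len(rows) < 3:
                continue
            mini, _ = leiden_cluster(
                ds.matrix[rows], resolution_mini, n_pcs=n_pcs,
                n_neighbors=n_neighbors, n_top_genes=None, seed=seed,
            )
            for mini_id in np.unique(mini):
                members = rows[mini == mini_id]
                means = scores.iloc[members].mean(axis=0)
                if len(means) > 1 and (
                    means.drop(own_type).max() > means[own_type] + contaminant_margin
                ):
                    final[members] = CONTAMINANT_LABEL
    return ClusterModel(
        labels=final, embedding=embedding, resolution=resolution_first, n_pcs=n_pcs,
        n_neighbors=n_neighbors,
        params={"resolution_mini": resolution_mini, "purged": panel is not None, "seed": seed},
    )


def annotate_cluster_based(
    model: ClusterModel, panel: MarkerPanel, ds: ExpressionDataset
) -> np.ndarray:
    """Assign each cluster the type with the highest mean z-scored panel expression.

    Ties break toward the panel with larger coverage in the dataset, then
    lexicographically.
    """
    scores = _panel_scores(ds, panel)
    present = set(ds.gene_ids)
    coverage = {t: sum(g in present for g in panel[t]) for t in panel.types()}
    out = np.empty(ds.n_cells, dtype=object)
    for cluster in np.unique(model.labels):
        mask = model.labels == cluster
        if cluster == CONTAMINANT_LABEL:
            out[mask] = CONTAMINANT_LABEL
            continue
        means = scores.loc[mask].mean(axis=0)
        best = means.max()
        tied = sorted(
            [t for t in means.index if np.isclose(means[t], best, atol=1e-9)],
            key=lambda t: (-coverage[t], t),
        )
        out[mask] = tied[0]
    return out


def annotate_positive_selection(ds: ExpressionDataset, marker: str) -> np.ndarray:
    """Positive-expression annotation from a single marker gene.

    A cell is positive iff its marker expression is strictly above the
    dataset-wide mean of that marker. Returns a boolean mask.
    """
    values = ds.gene_vector(marker)
    return values > values.mean()


def compare_annotation_methods(
    ds: ExpressionDataset,
    panel: MarkerPanel,
    pathways: GeneSetCollection | None = None,
    resolution: float = 0.3,
    seed: int = 0,
) -> pd.DataFrame:
    """Compare cluster-based vs positive-selection annotation per cell type.

    For each method and type: number of cells annotated, mean expression of
    the panel markers in those cells, and their mean pathway enrichment
    score (the type's "mark pathway" from ``pathways`` when given, else the
    panel itself scored as a set).
    """
    from .pathways import sample_set_score

    model = two_run_cluster(ds, resolution_first=resolution, panel=None, seed=seed)
    cb_labels = annotate_cluster_based(model, panel, ds)
    present = set(ds.gene_ids)
    rows = []
    for cell_type in panel.types():
        genes = [g for g in panel[cell_type] if g in present]
        set_genes = (pathways[cell_type] if pathways is not None and cell_type in pathways
                     else genes)
        path_scores = sample_set_score(ds, set_genes) if set_genes else np.zeros(ds.n_cells)
        for method, mask in (
            ("cluster-based", cb_labels == cell_type),
            ("positive-selection", annotate_positive_selection(ds, genes[0])
             if genes else np.zeros(ds.n_cells, dtype=bool)),
        ):
            n = int(mask.sum())
            marker_mean = float(ds.subset_genes(genes).matrix[mask].mean()) if n and genes else np.nan
            rows.append(
                {"method": method, "cell_type": cell_type, "n_cells": n,
                 "mean_marker_expression": marker_mean,
                 "mean_pathway_score": float(np.mean(path_scores[mask])) if n else np.nan}
            )
    return pd.DataFrame(rows)
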