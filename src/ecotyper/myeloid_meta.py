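"""Cross-dataset informative genes, DBI-selected cluster number, similarity trees.

Informative-gene selection scores every gene by a one-way ANOVA F across
each dataset's own clusters, converts F to within-dataset percentile ranks
(largest F -> 1.0), takes the median rank across the datasets where the
gene is detected, drops ribosomal/cell-cycle/heat-shock families, and
keeps the top 2000 genes detected in more than half of the datasets.
Meta-clustering restricts the PCA to those genes and picks the Leiden
resolution minimizing the Davies-Bouldin index over a grid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch

from . import _stats
from .datatypes import ClusterModel, DBITrace, ExpressionDataset
from .synthio import CYCLE_GENES


def default_exclusion_lists(gene_ids: list[str]) -> dict[str, list[str]]:
    """Ribosomal / cell-cycle / heat-shock families present in a gene space."""
    genes = [str(g) for g in gene_ids]
    return {
        "ribosomal": [g for g in genes if g.startswith(("RPL", "RPS"))],
        "cell_cycle": [g for g in genes if g in set(CYCLE_GENES)],
        "heat_shock": [g for g in genes if g.startswith(("HSP", "DNAJ"))],
    }


@dataclass
class InformativeGeneRanking:
    table: pd.DataFrame                 # per gene: median_rank, n_detected, excluded
    informative: list[str]
    n_datasets: int
    rank_direction: str = "largest"
    excluded_families: dict[str, list[str]] = field(default_factory=dict)


def _anova_f(X: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Vectorized one-way ANOVA F per column; constant columns get F = 0."""
    labels = np.asarray(labels)
    groups = np.unique(labels)
    n = X.shape[0]
    grand = X.mean(axis=0)
    ss_between = np.zeros(X.shape[1])
    ss_within = np.zeros(X.shape[1])
    for g in groups:
        sub = X[labels == g]
        m = sub.mean(axis=0)
        ss_between += len(sub) * (m - grand) ** 2
        ss_within += ((sub - m) ** 2).sum(axis=0)
    df_b = len(groups) - 1
    df_w = n - len(groups)
    with np.errstate(invalid="ignore", divide="ignore"):
        f = (ss_between / df_b) / (ss_within / df_w)
    return np.nan_to_num(f, nan=0.0, posinf=np.finfo(float).max)


def rank_informative_genes(
    datasets: list[ExpressionDataset],
    cluster_labels: list[np.ndarray] | None = None,
    exclusion_lists: dict[str, list[str]] | None = None,
    top_n: int = 2000,
    rank_direction: str = "largest",
) -> InformativeGeneRanking:
    """Select cross-dataset informative genes by median ANOVA-F percentile rank.

    Each dataset must come pre-clustered (``cluster_labels`` or its
    ``cell_label``); datasets with a single cluster are skipped with a
    warning. A gene qualifies when detected in strictly more than half of
    the contributing datasets and outside the excluded families; the top
    ``top_n`` by median percentile rank are returned
    (``rank_direction="largest"`` keeps the most discriminating genes).
    """
    if rank_direction not in ("largest", "smallest"):
        raise ValueError("rank_direction must be 'largest' or 'smallest'")
    if cluster_labels is None:
        cluster_labels = [ds.cell_label for ds in datasets]
    per_ds_ranks: list[pd.Series] = []
    for ds, labels in zip(datasets, cluster_labels):
        if labels is None:
            raise ValueError(f"dataset {ds.name!r} is not pre-clustered")
        labels = np.asarray(labels).astype(str)
        if len(np.unique(labels)) < 2:
            warnings.warn(f"dataset {ds.name!r} has a single cluster; skipped",
                          stacklevel=2)
            continue
        detected = (ds.matrix > 0).any(axis=0)
        f = _anova_f(ds.matrix, labels)
        ranks = pd.Series(np.nan, index=ds.gene_ids.astype(str))
        det_genes = ds.gene_ids[detected].astype(str)
        # percentile rank among detected genes: largest F -> 1.0
        pct = pd.Series(f[detected], index=det_genes).rank(method="average") / detected.sum()
        ranks.loc[det_genes] = pct
        per_ds_ranks.append(ranks)
    if not per_ds_ranks:
        raise ValueError("no dataset with at least two clusters")
    rank_frame = pd.concat(per_ds_ranks, axis=1)
    n_datasets = len(per_ds_ranks)
    median_rank = rank_frame.median(axis=1, skipna=True)
    n_detected = rank_frame.notna().sum(axis=1)

    if exclusion_lists is None:
        exclusion_lists = default_exclusion_lists(list(rank_frame.index))
    excluded_genes = set().union(*exclusion_lists.values()) if exclusion_lists else set()

    table = pd.DataFrame({
        "median_rank": median_rank,
        "n_detected": n_detected,
        "excluded": median_rank.index.isin(excluded_genes),
    })
    quorum = n_datasets // 2  # detected in strictly more than half
    eligible = table[(~table["excluded"]) & (table["n_detected"] > quorum)]
    ascending = rank_direction == "smallest"
    informative = list(
        eligible.sort_values("median_rank", ascending=ascending, kind="stable")
        .head(top_n).index
    )
    return InformativeGeneRanking(
        table=table, informative=informative, n_datasets=n_datasets,
        rank_direction=rank_direction, excluded_families=exclusion_lists,
    )


def select_cluster_number(
    ds: ExpressionDataset,
    informative: list[str],
    resolutions: np.ndarray | None = None,
    n_pcs: int = 15,
    n_neighbors: int = 20,
    min_cluster_size: int = 5,
    seed: int = 0,
) -> tuple[DBITrace, ClusterModel]:
    """Cluster over a resolution grid and keep the DBI-minimizing solution.

    The PCA is restricted to the informative genes (all of them treated as
    HVGs); the Davies-Bouldin index is evaluated in PC space. Resolutions
    yielding a single cluster have undefined DBI and are recorded as NaN,
    as are solutions containing a cluster smaller than
    ``min_cluster_size``: the DBI rewards splitting off near-singleton
    shards (their scatter is ~0), so shard solutions must not be allowed
    to win the argmin.
    """
    import anndata as ad
    import scanpy as sc

    if resolutions is None:
        resolutions = np.round(np.arange(0.1, 2.0 + 1e-9, 0.1), 2)
    genes = [g for g in informative if g in set(ds.gene_ids)]
    if not genes:
        raise ValueError("no informative genes present in the dataset")
    sub = ds.subset_genes(genes)
    n_pcs = min(n_pcs, sub.n_cells - 1, len(genes) - 1)
    adata = ad.AnnData(X=sub.matrix.astype(np.float64))
    sc.pp.pca(adata, n_comps=n_pcs, svd_solver="arpack", random_state=seed)
    sc.pp.neighbors(adata, n_neighbors=min(n_neighbors, sub.n_cells - 1),
                    n_pcs=n_pcs, random_state=seed)
    pcs = adata.obsm["X_pca"]
    rows, labelings = [], {}
    for res in resolutions:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", FutureWarning)
            sc.tl.leiden(adata, resolution=float(res), random_state=seed,
                         key_added="leiden", flavor="leidenalg")
        labels = adata.obs["leiden"].to_numpy().astype(str)
        uniq, counts = np.unique(labels, return_counts=True)
        k = len(uniq)
        valid = k > 1 and counts.min() >= min_cluster_size
        dbi = _stats.davies_bouldin(pcs, labels) if valid else np.nan
        rows.append({"resolution": float(res), "n_clusters": k, "dbi": dbi})
        labelings[float(res)] = labels
    trace = pd.DataFrame(rows)
    if trace["dbi"].notna().sum() == 0:
        raise ValueError("DBI undefined at every resolution (single cluster everywhere)")
    best = trace.loc[trace["dbi"].idxmin()]
    model = ClusterModel(
        labels=labelings[float(best["resolution"])],
        embedding=pcs,
        resolution=float(best["resolution"]),
        n_pcs=n_pcs,
        n_neighbors=n_neighbors,
        params={"selection": "davies-bouldin", "seed": seed},
    )
    return DBITrace(table=trace, selected=float(best["resolution"])), model


# ---------------------------------------------------------------------------
# cross-tumor cluster similarity dendrogram
# ---------------------------------------------------------------------------

def cluster_mean_profiles(ds: ExpressionDataset, labels: np.ndarray) -> pd.DataFrame:
    """Z-score genes across cells, then average per cluster (genes x clusters)."""
    labels = np.asarray(labels).astype(str)
    z = _stats.zscore_columns(ds.matrix, axis=0)
    data = {cl: z[labels == cl].mean(axis=0) for cl in np.unique(labels)}
    return pd.DataFrame(data, index=ds.gene_ids.astype(str))


def cluster_similarity_dendrogram(
    profiles_by_type: dict[str, pd.DataFrame],
    linkage_method: str = "average",
) -> tuple[str, np.ndarray, list[str]]:
    """Hierarchical tree over cluster mean profiles from several tumor types.

    Only genes present in every input matrix are retained; the distance is
    1 - Pearson correlation, linkage is average (UPGMA) by default. Leaves
    are named ``"<tumor type>|<cluster>"``. Returns (newick, linkage
    matrix, leaf names).
    """
    from .io import linkage_to_newick

    if not profiles_by_type:
        raise ValueError("no cluster profiles given")
    shared: set[str] | None = None
    for frame in profiles_by_type.values():
        shared = set(frame.index) if shared is None else shared & set(frame.index)
    shared_genes = sorted(shared)
    if len(shared_genes) < 2:
        raise ValueError("fewer than 2 genes shared across all tumor types")
    columns, names = [], []
    for tumor_type in sorted(profiles_by_type):
        frame = profiles_by_type[tumor_type].loc[shared_genes]
        for cl in frame.columns:
            columns.append(frame[cl].to_numpy())
            names.append(f"{tumor_type}|{cl}")
    mat = np.column_stack(columns)
    corr = np.corrcoef(mat.T)
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
    from scipy.spatial.distance import squareform

    linkage = sch.linkage(squareform(dist, checks=False), method=linkage_method)
    return linkage_to_newick(linkage, names), linkage, names
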