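"""Cross-platform transfer of microglia vs macrophage labels.

Canonical MG/BMDM markers drop out on droplet platforms, so lineage labels
are learned where they are visible: full-length datasets are clustered and
labeled by marker-set score, a random forest (500 trees, sqrt-p features,
out-of-bag error) is trained on those labels, and applied to droplet cells.
Conserved DEGs — genes separating MG from BMDM in *every* source tumor
type — then support a restricted re-clustering of droplet data in
conserved-gene space.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _stats
from .datatypes import ClusterModel, ExpressionDataset
from .pathways import find_markers
from .preprocess import leiden_cluster

MG = "MG"
BMDM = "BMDM"
AMBIGUOUS = "ambiguous"


@dataclass
class LineageClassifier:
    """Trained MG/BMDM forest with its feature space and training provenance."""

    forest: object
    feature_genes: list[str]
    classes: list[str]
    oob_error: float
    source_datasets: list[str] = field(default_factory=list)
    marker_sets: dict = field(default_factory=dict)


@dataclass
class ConservedDEGSet:
    """Genes up in MG / up in BMDM in every source tumor type."""

    mg_up: list[str]
    bmdm_up: list[str]
    per_source: pd.DataFrame    # per (source, gene): direction, logfc, p_adj

    def __post_init__(self) -> None:
        if set(self.mg_up) & set(self.bmdm_up):
            raise ValueError("conserved up-sets must be disjoint")

    @property
    def genes(self) -> list[str]:
        return list(self.mg_up) + list(self.bmdm_up)


def _marker_set_scores(ds: ExpressionDataset, genes: list[str]) -> np.ndarray:
    present = [g for g in genes if g in set(ds.gene_ids)]
    if not present:
        return np.zeros(ds.n_cells)
    sub = ds.subset_genes(present).matrix
    return _stats.zscore_columns(sub, axis=0).mean(axis=1)


def label_reference(
    ds: ExpressionDataset,
    mg_markers: list[str],
    bmdm_markers: list[str],
    resolution: float = 0.3,
    seed: int = 0,
) -> np.ndarray:
    """Cluster a full-length dataset and call each cluster MG or BMDM.

    Clusters are assigned by the higher mean z-scored marker-set
    expression; exact ties are labeled ``"ambiguous"`` and excluded from
    classifier training downstream.
    """
    if not ds.normalized:
        raise ValueError("label_reference expects normalized data")
    labels, _ = leiden_cluster(ds.matrix, resolution, seed=seed)
    mg_score = _marker_set_scores(ds, mg_markers)
    bm_score = _marker_set_scores(ds, bmdm_markers)
    out = np.empty(ds.n_cells, dtype=object)
    for cluster in np.unique(labels):
        mask = labels == cluster
        mg_mean, bm_mean = mg_score[mask].mean(), bm_score[mask].mean()
        if mg_mean > bm_mean:
            out[mask] = MG
        elif bm_mean > mg_mean:
            out[mask] = BMDM
        else:
            out[mask] = AMBIGUOUS
    return out


def _features_scaled(ds: ExpressionDataset, feature_genes: list[str]) -> np.ndarray:
    """Per-dataset gene z-scores: puts both platforms on a comparable scale."""
    return _stats.zscore_columns(ds.subset_genes(feature_genes).matrix, axis=0)


def train_classifier(
    datasets: list[ExpressionDataset],
    labels: list[np.ndarray] | None = None,
    n_trees: int = 500,
    seed: int = 0,
) -> LineageClassifier:
    """Fit the 500-tree random forest on labeled full-length cells.

    Feature genes are the inner join of the training datasets' gene
    spaces, z-scored within each dataset so that the droplet and
    full-length scales are comparable at prediction time; cells labeled
    ``"ambiguous"`` are excluded. Out-of-bag error is recorded on the
    trained model.
    """
    from sklearn.ensemble import RandomForestClassifier

    if labels is None:
        labels = [ds.cell_label for ds in datasets]
        if any(lab is None for lab in labels):
            raise ValueError("datasets lack cell_label and no labels were given")
    shared = set(datasets[0].gene_ids)
    for ds in datasets[1:]:
        shared &= set(ds.gene_ids)
    feature_genes = sorted(shared)
    X_parts, y_parts = [], []
    for ds, lab in zip(datasets, labels):
        lab = np.asarray(lab).astype(str)
        keep = np.isin(lab, [MG, BMDM])
        X_parts.append(_features_scaled(ds, feature_genes)[keep])
        y_parts.append(lab[keep])
    X = np.vstack(X_parts)
    y = np.concatenate(y_parts)
    classes = sorted(set(y))
    if len(classes) < 2:
        raise ValueError(f"training data contains a single class: {classes}")
    forest = RandomForestClassifier(
        n_estimators=n_trees, max_features="sqrt", oob_score=True, random_state=seed,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        forest.fit(X, y)
    return LineageClassifier(
        forest=forest,
        feature_genes=feature_genes,
        classes=classes,
        oob_error=float(1.0 - forest.oob_score_),
        source_datasets=[ds.name for ds in datasets],
    )


def predict_lineage(clf: LineageClassifier, ds: ExpressionDataset) -> pd.DataFrame:
    """Predict MG/BMDM for every droplet cell.

    Feature genes missing from the target dataset raise a ``KeyError``
    naming them. Exact probability ties yield ``"ambiguous"``.
    """
    X = _features_scaled(ds, clf.feature_genes)  # KeyError names missing genes
    proba = clf.forest.predict_proba(X)
    classes = list(clf.forest.classes_)
    best = np.argmax(proba, axis=1)
    labels = np.asarray(classes, dtype=object)[best]
    sorted_p = np.sort(proba, axis=1)
    labels[sorted_p[:, -1] == sorted_p[:, -2]] = AMBIGUOUS
    out = pd.DataFrame(proba, columns=classes, index=ds.cell_ids)
    out["label"] = labels
    return out


def classifier_embedding(clf: LineageClassifier, ds: ExpressionDataset) -> np.ndarray:
    """Classical MDS (cmdscale) of the forest proximity matrix, 2-D.

    Proximity between two cells is the fraction of trees routing both to
    the same leaf; the embedding is the top-2 classical-scaling projection
    of 1 - proximity.
    """
    X = _features_scaled(ds, clf.feature_genes)
    leaves = clf.forest.apply(X)                       # cells x trees
    n = leaves.shape[0]
    prox = np.zeros((n, n))
    for t in range(leaves.shape[1]):
        same = leaves[:, t][:, None] == leaves[:, t][None, :]
        prox += same
    prox /= leaves.shape[1]
    d2 = (1.0 - prox) ** 2
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ d2 @ j
    vals, vecs = np.linalg.eigh(b)
    order = np.argsort(vals)[::-1][:2]
    return vecs[:, order] * np.sqrt(np.maximum(vals[order], 0.0))


def conserved_degs(
    datasets_by_type: dict[str, tuple[ExpressionDataset, np.ndarray]],
    logfc_min: float = 0.25,
    p_adj_max: float = 0.01,
) -> ConservedDEGSet:
    """Intersect MG-vs-BMDM DEGs across source tumor types.

    ``datasets_by_type`` maps tumor type -> (dataset, MG/BMDM labels). A
    gene is conserved when it passes ``logfc > logfc_min`` and
    ``p_adj < p_adj_max`` in the same direction in *every* tumor type.
    """
    if not datasets_by_type:
        raise ValueError("no source datasets")
    mg_sets, bm_sets, frames = [], [], []
    for source in sorted(datasets_by_type):
        ds, labels = datasets_by_type[source]
        labels = np.asarray(labels).astype(str)
        keep = np.isin(labels, [MG, BMDM])
        sub = ds.subset_cells(keep)
        table = find_markers(sub, labels[keep], logfc_min=logfc_min,
                             p_adj_max=p_adj_max)
        mg = set(table.loc[table["cluster"] == MG, "gene"])
        bm = set(table.loc[table["cluster"] == BMDM, "gene"])
        mg_sets.append(mg)
        bm_sets.append(bm)
        table = table.assign(source=source,
                             direction=np.where(table["cluster"] == MG, MG, BMDM))
        frames.append(table[["source", "gene", "direction", "logfc", "p_adj"]])
    mg_up = set.intersection(*mg_sets)
    bm_up = set.intersection(*bm_sets)
    # direction-consistency: a gene may not sit in both intersections
    both = mg_up & bm_up
    return ConservedDEGSet(
        mg_up=sorted(mg_up - both),
        bmdm_up=sorted(bm_up - both),
        per_source=pd.concat(frames, ignore_index=True),
    )


def recluster_on_conserved(
    ds: ExpressionDataset,
    conserved: ConservedDEGSet,
    clf: LineageClassifier,
    resolution: float = 0.2,
    seed: int = 0,
) -> tuple[ClusterModel, np.ndarray]:
    """Re-cluster droplet cells in conserved-DEG space and annotate by vote.

    The matrix is restricted to the conserved genes (all of them used as
    HVGs for the PCA), clustered at ``resolution``, and each cluster takes
    the majority classifier prediction of its cells.
    """
    genes = [g for g in conserved.genes if g in set(ds.gene_ids)]
    if not genes:
        raise ValueError("no conserved genes present in the target dataset")
    sub = ds.subset_genes(genes)
    n_pcs = min(15, len(genes) - 1, sub.n_cells - 1)
    labels, embedding = leiden_cluster(sub.matrix, resolution, n_pcs=n_pcs,
                                       n_top_genes=None, seed=seed)
    preds = predict_lineage(clf, ds)["label"].to_numpy()
    annotation = np.empty(ds.n_cells, dtype=object)
    for cluster in np.unique(labels):
        mask = labels == cluster
        votes = pd.Series(preds[mask])
        votes = votes[votes != AMBIGUOUS]
        annotation[mask] = votes.mode().iloc[0] if len(votes) else AMBIGUOUS
    model = ClusterModel(labels=labels, embedding=embedding, resolution=resolution,
                         n_pcs=n_pcs, params={"feature_space": "conserved-degs"})
    return model, annotation
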