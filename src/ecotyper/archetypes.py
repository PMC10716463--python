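"""Immune-stromal-tumor archetype discovery on bulk cohorts.

Samples are scored on a small panel of signatures — the 3-feature panel
(myeloid via ITGAM-anchored scFes, T cell via CD3, oligodendroglia via
MAG) or the 9-feature panel adding CD4, CD8, MG, BMDM and the two
immune-recruitment programs — then clustered by k-means in z-scored score
space with the cluster number chosen by the Davies-Bouldin index. Each
archetype receives a compact gene feature (<= 20 genes) used to project
external cohorts, and archetype membership is related to survival via
Kaplan-Meier / log-rank and univariate Cox models.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from ._stats import bh_adjust, davies_bouldin, zscore_columns
from .datatypes import (
    ArchetypeModel,
    BulkCohort,
    DBITrace,
    SignatureSet,
    SurvivalResult,
)
from .signatures import score_signature

UNASSIGNED = "unassigned"

#: default feature panels; the 9-feature composition is configurable
THREE_FEATURE_PANEL = ["Myeloid", "T", "Oligo"]
NINE_FEATURE_PANEL = THREE_FEATURE_PANEL + ["CD4_T", "CD8_T", "MG", "BMDM",
                                            "positive-IR", "negative-IR"]


def score_feature_matrix(
    cohort: BulkCohort, sigs: Sequence[SignatureSet | tuple[str, list[str]]]
) -> pd.DataFrame:
    """Samples x features signature-score matrix, columns z-scored."""
    columns = {}
    for sig in sigs:
        if isinstance(sig, SignatureSet):
            name, scores = sig.name, score_signature(cohort.expression, sig)
        else:
            name, genes = sig
            scores = score_signature(cohort.expression, genes)
        columns[name] = scores.to_numpy()
    frame = pd.DataFrame(columns, index=cohort.expression.columns)
    return pd.DataFrame(zscore_columns(frame.to_numpy(), axis=0),
                        index=frame.index, columns=frame.columns)


def discover_archetypes(
    scores: pd.DataFrame,
    k_range: Iterable[int] = range(2, 11),
    n_restarts: int = 20,
    seed: int = 0,
) -> ArchetypeModel:
    """K-means over a k grid; keep the Davies-Bouldin-minimizing solution."""
    from sklearn.cluster import KMeans

    k_range = sorted(set(int(k) for k in k_range))
    n = scores.shape[0]
    if min(k_range) < 2:
        raise ValueError("k grid must start at 2 (DBI is undefined for one cluster)")
    if max(k_range) > n - 1:
        raise ValueError(f"k grid exceeds n_samples - 1 = {n - 1}")
    X = scores.to_numpy(dtype=float)
    rows, fits = [], {}
    for k in k_range:
        km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
        labels = km.fit_predict(X)
        from scipy.spatial.distance import pdist

        if pdist(km.cluster_centers_).min() < 1e-8:
            warnings.warn(f"near-duplicate centroids at k={k}", stacklevel=2)
        rows.append({"resolution": float(k), "n_clusters": k,
                     "dbi": davies_bouldin(X, labels)})
        fits[k] = (labels, km.cluster_centers_)
    trace = pd.DataFrame(rows)
    best_k = int(trace.loc[trace["dbi"].idxmin(), "n_clusters"])
    labels, centers = fits[best_k]
    label_series = pd.Series([f"A{i}" for i in labels], index=scores.index, name="archetype")
    return ArchetypeModel(
        feature_names=list(scores.columns),
        scores=scores,
        labels=label_series,
        k=best_k,
        dbi_trace=DBITrace(table=trace, selected=float(best_k)),
        centroids=pd.DataFrame(centers, columns=scores.columns,
                               index=[f"A{i}" for i in range(best_k)]),
    )


# ---------------------------------------------------------------------------
# archetype gene features
# ---------------------------------------------------------------------------

def _pairwise_up_genes(cohort: BulkCohort, mask_a: np.ndarray, mask_b: np.ndarray,
                       p_max: float, logfc_min: float, top_n: int) -> pd.Index:
    from scipy import stats

    X = cohort.expression.to_numpy(dtype=float)
    a, b = X[:, mask_a], X[:, mask_b]
    logfc = a.mean(axis=1) - b.mean(axis=1)       # log2 scale in, log2 FC out
    with np.errstate(invalid="ignore", divide="ignore"):
        _, p = stats.ttest_ind(a, b, axis=1, equal_var=False)
    p = np.nan_to_num(np.asarray(p), nan=1.0)
    frame = pd.DataFrame({"logfc": logfc, "p": p}, index=cohort.expression.index)
    frame = frame[(frame["p"] < p_max) & (frame["logfc"] > logfc_min)]
    return frame.sort_values("logfc", ascending=False).head(top_n).index


def archetype_gene_features(
    cohort: BulkCohort,
    labels: pd.Series,
    p_max: float = 0.05,
    logfc_min: float = 1.0,
    top_n_by_logfc: int = 3000,
    max_genes: int = 20,
    detect_fraction: float = 0.8,
) -> dict[str, list[str]]:
    """Compact per-archetype gene features from pairwise bulk DEG intersections.

    For archetype A against each of the other k-1 archetypes: Welch t on
    log2 expression, keep genes with ``p < p_max`` and ``logfc > logfc_min``,
    top ``top_n_by_logfc`` by log-fold change. The k-1 lists are
    intersected; genes must be detected (expression > 0) in at least
    ``detect_fraction`` of A's samples, and when more than ``max_genes``
    remain the ``max_genes`` with the lowest within-A coefficient of
    variation (linear scale) are kept. An empty intersection produces an
    empty feature with a warning.
    """
    labels = labels.loc[cohort.expression.columns]
    archetypes = sorted(labels.unique())
    if len(archetypes) < 2:
        raise ValueError("need at least two archetypes for pairwise contrasts")
    features: dict[str, list[str]] = {}
    X = cohort.expression
    for arch in archetypes:
        mask_a = (labels == arch).to_numpy()
        gene_lists = []
        for other in archetypes:
            if other == arch:
                continue
            mask_b = (labels == other).to_numpy()
            gene_lists.append(set(_pairwise_up_genes(
                cohort, mask_a, mask_b, p_max, logfc_min, top_n_by_logfc)))
        initial = set.intersection(*gene_lists)
        if not initial:
            warnings.warn(f"archetype {arch!r}: empty gene-feature intersection; "
                          "kept with scores from the parent features", stacklevel=2)
            features[arch] = []
            continue
        sub = X.loc[sorted(initial)].iloc[:, mask_a]
        detected = (sub > 0).mean(axis=1) >= detect_fraction
        kept = sub[detected]
        if kept.shape[0] > max_genes:
            linear = np.exp2(kept.to_numpy()) - 1.0
            cv = linear.std(axis=1, ddof=1) / np.maximum(linear.mean(axis=1), 1e-12)
            order = pd.Series(cv, index=kept.index).sort_values(kind="stable")
            features[arch] = sorted(order.head(max_genes).index)
        else:
            features[arch] = sorted(kept.index)
    return features


def project_archetypes(
    external: BulkCohort,
    model: ArchetypeModel,
    margin_tau: float = 0.1,
) -> pd.Series:
    """Assign external samples to archetypes by gene-feature score argmax.

    Samples whose top-two archetype scores differ by less than
    ``margin_tau`` are labeled ``"unassigned"``.
    """
    if not model.gene_features:
        raise ValueError("model carries no archetype gene features")
    usable = {a: g for a, g in model.gene_features.items() if g}
    if len(usable) < 2:
        raise ValueError("need gene features for at least two archetypes")
    scores = pd.DataFrame(
        {arch: score_signature(external.expression, genes).to_numpy()
         for arch, genes in usable.items()},
        index=external.expression.columns,
    )
    arr = scores.to_numpy()
    order = np.argsort(arr, axis=1)
    top, second = arr[np.arange(len(arr)), order[:, -1]], arr[np.arange(len(arr)), order[:, -2]]
    labels = scores.columns.to_numpy(dtype=object)[order[:, -1]]
    labels[top - second < margin_tau] = UNASSIGNED
    return pd.Series(labels, index=scores.index, name="archetype")


# ---------------------------------------------------------------------------
# survival association
# ---------------------------------------------------------------------------

def survival_association(
    survival: pd.DataFrame,
    labels: pd.Series | None = None,
    scores: pd.DataFrame | None = None,
) -> SurvivalResult:
    """Kaplan-Meier / log-rank across groups and univariate Cox per score.

    ``survival`` needs ``time_months`` and ``event`` columns. With
    ``labels`` only, the Cox covariates are the group indicator dummies
    (first group as reference).
    """
    from lifelines import CoxPHFitter, KaplanMeierFitter
    from lifelines.statistics import multivariate_logrank_test

    t = survival["time_months"].to_numpy(dtype=float)
    ev = survival["event"].to_numpy(dtype=int)
    if ev.sum() == 0:
        raise ValueError("no events in the survival data")

    km_curves: dict[str, pd.DataFrame] = {}
    logrank_p = float("nan")
    if labels is not None:
        labels = labels.loc[survival.index]
        for group in sorted(labels.unique()):
            mask = (labels == group).to_numpy()
            kmf = KaplanMeierFitter()
            kmf.fit(t[mask], ev[mask], label=str(group))
            km_curves[str(group)] = kmf.survival_function_.rename(
                columns={str(group): "survival"})
        if labels.nunique() > 1:
            logrank_p = float(multivariate_logrank_test(t, labels.to_numpy(), ev).p_value)
    else:
        kmf = KaplanMeierFitter().fit(t, ev, label="all")
        km_curves["all"] = kmf.survival_function_.rename(columns={"all": "survival"})

    if scores is None and labels is not None and labels.nunique() > 1:
        scores = pd.get_dummies(labels, drop_first=True).astype(float)
    rows = []
    if scores is not None:
        scores = scores.loc[survival.index]
        for col in scores.columns:
            frame = pd.DataFrame({"time": t, "event": ev,
                                  "x": scores[col].to_numpy(dtype=float)})
            cph = CoxPHFitter()
            cph.fit(frame, duration_col="time", event_col="event")
            s = cph.summary.loc["x"]
            rows.append({"covariate": str(col), "hr": float(s["exp(coef)"]),
                         "ci_low": float(s["exp(coef) lower 95%"]),
                         "ci_high": float(s["exp(coef) upper 95%"]),
                         "p": float(s["p"])})
    cox = pd.DataFrame(rows, columns=["covariate", "hr", "ci_low", "ci_high", "p"])
    if len(cox):
        cox["q"] = bh_adjust(cox["p"].to_numpy())
    return SurvivalResult(km_curves=km_curves, logrank_p=logrank_p, cox=cox)
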