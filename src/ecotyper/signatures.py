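"""Single-cell-derived gene signatures (scFes) and immune-recruitment features.

An scFes is the gene feature of one cell type derived per dataset with
platform-specific marker thresholds and combined across datasets by a
stringency rule: plain intersection for common types and subpopulations, a
three-quarters quorum for cytotoxic CD8 cells, and a two-tumor-type rule
for conserved tumor features. Immune-recruitment (IR) features are
tumor-cell genes whose pseudobulk expression tracks immune content (the
CD45/PTPRC proxy) across samples, split into positively and negatively
correlated programs. Scoring is the mean of per-gene z-scored expression.
"""

from __future__ import annotations

import math
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import bh_adjust, zscore_columns
from .datatypes import DROPLET, ExpressionDataset, IRFeatures, SignatureSet
from .pathways import find_markers, sample_set_score

#: per-platform (p_adj_max, min_pct, logfc_min) marker thresholds.
#: "strict" applies to common major cell types, "loose" to subpopulations.
#: The strict full-length adjusted-p cut is configurable because the
#: printed value "10e-20" is ambiguous; the default reads it as 1e-20.
STRICT_P_FULL_LENGTH = 1e-20

PLATFORM_THRESHOLDS = {
    "strict": {
        "full-length-tpm": {"p_adj_max": STRICT_P_FULL_LENGTH, "min_pct": 0.3, "logfc_min": 1.0},
        DROPLET: {"p_adj_max": 1e-10, "min_pct": 0.1, "logfc_min": 0.25},
    },
    "loose": {
        "full-length-tpm": {"p_adj_max": 1e-10, "min_pct": 0.3, "logfc_min": 1.0},
        DROPLET: {"p_adj_max": 1e-10, "min_pct": 0.1, "logfc_min": 0.25},
    },
}

_RIGOR = {"common": "strict", "tumor-conserved": "strict",
          "subpopulation": "loose", "quorum-3/4": "loose"}


def _dataset_markers(ds: ExpressionDataset, cell_type: str, rigor: str,
                     thresholds: dict | None) -> set[str]:
    thr = (thresholds or PLATFORM_THRESHOLDS)[rigor][ds.platform]
    table = find_markers(ds, groups=[cell_type], **thr)
    return set(table["gene"])


def derive_scfes(
    datasets: list[ExpressionDataset],
    cell_type: str,
    stringency: str = "common",
    thresholds: dict | None = None,
) -> SignatureSet:
    """Derive one cell type's scFes across labeled datasets.

    Every dataset must carry the cell type in its ``cell_label`` (a
    missing type raises). Per-dataset markers use the platform threshold
    triple for the stringency's rigor class; genes are combined by the
    stringency rule:

    - ``common`` / ``subpopulation``: intersection over all datasets;
    - ``quorum-3/4``: genes passing in at least three quarters of the
      datasets (cytotoxic-CD8 rule);
    - ``tumor-conserved``: genes passing the common-type thresholds in at
      least two tumor types (in any dataset of the type).
    """
    if stringency not in SignatureSet.VALID_STRINGENCY:
        raise ValueError(f"unknown stringency {stringency!r}")
    rigor = _RIGOR[stringency]
    per_dataset: dict[str, set[str]] = {}
    for ds in datasets:
        if ds.cell_label is None or cell_type not in set(ds.cell_label):
            raise ValueError(f"cell type {cell_type!r} absent from dataset {ds.name!r}")
        per_dataset[ds.name] = _dataset_markers(ds, cell_type, rigor, thresholds)

    sets = list(per_dataset.values())
    if stringency in ("common", "subpopulation"):
        genes = set.intersection(*sets)
    elif stringency == "quorum-3/4":
        quorum = math.ceil(0.75 * len(sets))
        counts = pd.Series([g for s in sets for g in s]).value_counts()
        genes = set(counts[counts >= quorum].index)
    else:  # tumor-conserved
        by_type: dict[str, set[str]] = {}
        for ds in datasets:
            by_type.setdefault(ds.tumor_type, set()).update(per_dataset[ds.name])
        counts = pd.Series([g for s in by_type.values() for g in s]).value_counts()
        genes = set(counts[counts >= 2].index)
    if not genes:
        raise ValueError(f"no gene survives the {stringency!r} rule for {cell_type!r}")
    return SignatureSet(
        name=f"scFes:{cell_type}",
        cell_type=cell_type,
        genes=sorted(genes),
        stringency=stringency,
        provenance={
            "rule": stringency,
            "rigor": rigor,
            "thresholds": thresholds or PLATFORM_THRESHOLDS,
            "per_dataset_markers": {k: sorted(v) for k, v in per_dataset.items()},
            "dataset_platforms": {ds.name: ds.platform for ds in datasets},
            "dataset_tumor_types": {ds.name: ds.tumor_type for ds in datasets},
        },
    )


def verify_signature(sig: SignatureSet, datasets: list[ExpressionDataset]) -> bool:
    """Recompute an scFes from its source datasets and compare gene lists."""
    redo = derive_scfes(datasets, sig.cell_type, sig.stringency,
                        thresholds=sig.provenance.get("thresholds"))
    return redo.genes == sig.genes


# ---------------------------------------------------------------------------
# immune-recruitment features
# ---------------------------------------------------------------------------

def derive_ir_features(
    pseudobulk: pd.DataFrame,
    immune_content: pd.Series,
    rho_min: float = 0.5,
    q_max: float = 0.1,
) -> IRFeatures:
    """Split tumor-expressed genes into positive-IR and negative-IR programs.

    ``pseudobulk`` is tumor-cell expression, genes x samples;
    ``immune_content`` the per-sample CD45 proxy (mean normalized PTPRC or
    a planted immune fraction). Each gene's Spearman rho against immune
    content is tested; genes with ``rho > rho_min`` and BH ``q < q_max``
    form positive-IR, the mirror set negative-IR.
    """
    if pseudobulk.shape[1] < 8:
        raise ValueError("need at least 8 samples to derive IR features")
    immune = immune_content.loc[pseudobulk.columns].to_numpy(dtype=float)
    rhos, ps = [], []
    for _, row in pseudobulk.iterrows():
        rho, p = stats.spearmanr(row.to_numpy(dtype=float), immune)
        rhos.append(0.0 if np.isnan(rho) else float(rho))
        ps.append(1.0 if np.isnan(p) else float(p))
    table = pd.DataFrame({"rho": rhos, "p": ps}, index=pseudobulk.index)
    table["q"] = bh_adjust(table["p"].to_numpy())
    positive = list(table.index[(table["rho"] > rho_min) & (table["q"] < q_max)])
    negative = list(table.index[(table["rho"] < -rho_min) & (table["q"] < q_max)])
    return IRFeatures(positive=positive, negative=negative, correlations=table)


# ---------------------------------------------------------------------------
# signature scoring
# ---------------------------------------------------------------------------

def score_signature(
    data: pd.DataFrame | ExpressionDataset,
    sig: SignatureSet | list[str],
    method: str = "zscore",
) -> pd.Series:
    """Score a signature per sample (bulk frame, genes x samples) or per cell.

    ``method="zscore"`` (default) averages per-gene z-scores over the set
    members present; genes with zero variance contribute 0, and an
    all-degenerate set warns and returns zeros. ``method="rank"`` uses the
    rank-based set score for sensitivity analysis. The fraction of
    signature genes missing from the matrix is reported in
    ``result.attrs["missing_fraction"]``.
    """
    genes = sig.genes if isinstance(sig, SignatureSet) else list(sig)
    if isinstance(data, ExpressionDataset):
        matrix = data.matrix                      # cells x genes
        gene_ids = data.gene_ids.astype(str)
        index = pd.Index(data.cell_ids.astype(str))
    else:
        matrix = data.to_numpy(dtype=float).T     # samples x genes
        gene_ids = data.index.astype(str).to_numpy()
        index = data.columns
    present = [g for g in genes if g in set(gene_ids)]
    if not present:
        raise ValueError("signature has no overlap with the matrix genes")
    missing_fraction = 1.0 - len(present) / len(genes)
    col = {g: i for i, g in enumerate(gene_ids)}
    sub = matrix[:, [col[g] for g in present]]
    if method == "zscore":
        if np.all(sub.std(axis=0) == 0):
            warnings.warn("all signature genes are constant; scores are 0", stacklevel=2)
        values = zscore_columns(sub, axis=0).mean(axis=1)
    elif method == "rank":
        values = sample_set_score(matrix, present, gene_ids=gene_ids)
    else:
        raise ValueError("method must be 'zscore' or 'rank'")
    out = pd.Series(values, index=index, name=getattr(sig, "name", "signature"))
    out.attrs["missing_fraction"] = missing_fraction
    return out
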