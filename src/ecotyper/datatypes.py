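"""Core in-memory containers shared across the pipeline.

The containers are deliberately light: a single-cell dataset is a dense
cells × genes matrix with identifier and metadata vectors (convertible to
:class:`anndata.AnnData` for the scanpy-backed steps), a bulk cohort is a
genes × samples log2-scale frame with survival metadata, and gene sets are
named lists with GMT semantics.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

DROPLET = "droplet-count"
FULL_LENGTH = "full-length-tpm"
PLATFORMS = (DROPLET, FULL_LENGTH)

MITO_PREFIX = "MT-"


def _as_str_array(values, name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=object)
    if arr.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional")
    return arr.astype(str)


@dataclass
class ExpressionDataset:
    """One single-cell expression matrix with platform/tumor/donor metadata.

    Parameters
    ----------
    matrix
        Non-negative cells × genes matrix. Integer-valued for the
        ``droplet-count`` platform (UMI counts); non-negative reals for
        ``full-length-tpm`` (TPM, stored pre-log).
    gene_ids, cell_ids
        Unique identifiers for columns and rows.
    platform
        ``"droplet-count"`` (10x-style UMI counts) or ``"full-length-tpm"``
        (Smart-seq2-style TPM).
    donor
        Donor of origin per cell.
    cell_label
        Optional ground-truth or assigned cell-type label per cell.
    """

    matrix: np.ndarray
    gene_ids: np.ndarray
    cell_ids: np.ndarray
    platform: str
    tumor_type: str = "unknown"
    donor: np.ndarray | None = None
    cell_label: np.ndarray | None = None
    name: str = "dataset"
    normalized: bool = False

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2:
            raise ValueError("matrix must be 2-D (cells x genes)")
        self.gene_ids = _as_str_array(self.gene_ids, "gene_ids")
        self.cell_ids = _as_str_array(self.cell_ids, "cell_ids")
        n_cells, n_genes = self.matrix.shape
        if len(self.cell_ids) != n_cells:
            raise ValueError("cell_ids length does not match matrix rows")
        if len(self.gene_ids) != n_genes:
            raise ValueError("gene_ids length does not match matrix columns")
        if len(set(self.gene_ids)) != n_genes:
            raise ValueError("duplicate gene_ids")
        if len(set(self.cell_ids)) != n_cells:
            raise ValueError("duplicate cell_ids")
        if self.platform not in PLATFORMS:
            raise ValueError(f"platform must be one of {PLATFORMS}")
        if np.any(self.matrix < 0):
            raise ValueError("expression values must be non-negative")
        if self.platform == DROPLET and not self.normalized:
            if not np.allclose(self.matrix, np.round(self.matrix)):
                raise ValueError("droplet-count matrices must be integer-valued")
        if self.donor is None:
            self.donor = np.array(["donor0"] * n_cells, dtype=object)
        else:
            self.donor = _as_str_array(self.donor, "donor")
            if len(self.donor) != n_cells:
                raise ValueError("donor length does not match cell count")
        if self.cell_label is not None:
            self.cell_label = _as_str_array(self.cell_label, "cell_label")
            if len(self.cell_label) != n_cells:
                raise ValueError("cell_label length does not match cell count")

    # -- derived per-cell QC statistics -------------------------------------
    @property
    def n_cells(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_genes(self) -> int:
        return self.matrix.shape[1]

    def qc_stats(self) -> pd.DataFrame:
        """Per-cell total signal, detected-gene count and mitochondrial fraction."""
        total = self.matrix.sum(axis=1)
        detected = (self.matrix > 0).sum(axis=1)
        mito_mask = np.array([g.startswith(MITO_PREFIX) for g in self.gene_ids])
        with np.errstate(invalid="ignore", divide="ignore"):
            mito = np.where(total > 0, self.matrix[:, mito_mask].sum(axis=1) / np.maximum(total, 1e-300), 0.0)
        return pd.DataFrame(
            {"total_counts": total, "n_genes_detected": detected, "mito_fraction": mito},
            index=self.cell_ids,
        )

    # -- subsetting ---------------------------------------------------------
    def subset_cells(self, mask: np.ndarray) -> "ExpressionDataset":
        mask = np.asarray(mask)
        if mask.dtype == bool and mask.shape[0] != self.n_cells:
            raise ValueError("boolean mask length mismatch")
        return replace(
            self,
            matrix=self.matrix[mask],
            cell_ids=self.cell_ids[mask],
            donor=self.donor[mask],
            cell_label=None if self.cell_label is None else self.cell_label[mask],
        )

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionDataset":
        index = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in genes if g not in index]
        if missing:
            raise KeyError(f"genes not present in dataset: {missing[:5]}")
        cols = np.array([index[g] for g in genes])
        return replace(self, matrix=self.matrix[:, cols], gene_ids=np.asarray(list(genes), dtype=object))

    def gene_vector(self, gene: str) -> np.ndarray:
        idx = np.where(self.gene_ids == gene)[0]
        if idx.size == 0:
            raise KeyError(f"gene {gene!r} not present in dataset")
        return self.matrix[:, idx[0]]

    def copy(self) -> "ExpressionDataset":
        return replace(self, matrix=self.matrix.copy())

    def to_anndata(self):
        import anndata as ad

        obs = pd.DataFrame({"donor": self.donor}, index=self.cell_ids.astype(str))
        if self.cell_label is not None:
            obs["cell_label"] = self.cell_label
        adata = ad.AnnData(
            X=self.matrix.copy(),
            obs=obs,
            var=pd.DataFrame(index=self.gene_ids.astype(str)),
        )
        adata.uns["platform"] = self.platform
        adata.uns["tumor_type"] = self.tumor_type
        adata.uns["normalized"] = self.normalized
        return adata


@dataclass
class QCThresholds:
    """Droplet QC gates: minimum UMIs, minimum detected genes, maximum mito fraction.

    Cells with fewer than ``min_umi`` counts, fewer than ``min_genes``
    detected genes, or a mitochondrial fraction above ``max_mito_fraction``
    are removed; ties at the thresholds are retained.
    """

    min_umi: float = 2000
    min_genes: int = 200
    max_mito_fraction: float = 0.10

    def __post_init__(self) -> None:
        if self.min_umi <= 0 or self.min_genes <= 0 or self.max_mito_fraction <= 0:
            raise ValueError("QC thresholds must be positive")
        if self.max_mito_fraction > 1:
            raise ValueError("max_mito_fraction must be <= 1")


class GeneSetCollection:
    """Named gene lists with GMT semantics (name, description, members)."""

    def __init__(self, sets: Mapping[str, Sequence[str]] | None = None,
                 descriptions: Mapping[str, str] | None = None):
        self._sets: dict[str, list[str]] = {}
        self._desc: dict[str, str] = {}
        if sets:
            for name, genes in sets.items():
                self.add(name, genes, (descriptions or {}).get(name, ""))

    def add(self, name: str, genes: Sequence[str], description: str = "") -> None:
        genes = [str(g) for g in genes]
        if not genes:
            raise ValueError(f"gene set {name!r} is empty")
        if len(set(genes)) != len(genes):
            raise ValueError(f"gene set {name!r} contains duplicates")
        self._sets[name] = genes
        self._desc[name] = description

    def __getitem__(self, name: str) -> list[str]:
        return list(self._sets[name])

    def __contains__(self, name: str) -> bool:
        return name in self._sets

    def __iter__(self):
        return iter(self._sets)

    def __len__(self) -> int:
        return len(self._sets)

    def names(self) -> list[str]:
        return list(self._sets)

    def description(self, name: str) -> str:
        return self._desc[name]

    def items(self):
        return ((k, list(v)) for k, v in self._sets.items())

    def __eq__(self, other) -> bool:
        return isinstance(other, GeneSetCollection) and dict(self._sets) == dict(other._sets)


@dataclass
class MarkerPanel:
    """Cell type -> required marker genes (at least one per type)."""

    panels: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for cell_type, genes in self.panels.items():
            if not genes:
                raise ValueError(f"marker panel for {cell_type!r} is empty")

    def types(self) -> list[str]:
        return list(self.panels)

    def __getitem__(self, cell_type: str) -> list[str]:
        return list(self.panels[cell_type])


@dataclass
class ClusterModel:
    """Cluster labels with the PC embedding and graph parameters that produced them."""

    labels: np.ndarray
    embedding: np.ndarray
    resolution: float
    n_pcs: int = 15
    n_neighbors: int = 20
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=object).astype(str)
        self.embedding = np.asarray(self.embedding, dtype=float)
        if self.labels.shape[0] != self.embedding.shape[0]:
            raise ValueError("labels and embedding disagree on cell count")

    @property
    def n_clusters(self) -> int:
        return len(set(self.labels))


@dataclass
class DBITrace:
    """Davies-Bouldin index across a resolution (or k) grid, with the minimizer."""

    table: pd.DataFrame  # columns: resolution (or k), n_clusters, dbi
    selected: float      # the grid value at argmin DBI

    def best_k(self) -> int:
        row = self.table.loc[self.table["dbi"].idxmin()]
        return int(row["n_clusters"])


@dataclass
class SignatureSet:
    """A named gene signature with the provenance of its derivation.

    ``stringency`` records the combination rule used: ``common`` and
    ``subpopulation`` intersect per-dataset markers across all datasets
    (with strict vs loose per-platform thresholds), ``quorum-3/4`` keeps
    genes passing in at least three quarters of datasets, and
    ``tumor-conserved`` keeps genes passing common-type thresholds in at
    least two tumor types.
    """

    name: str
    cell_type: str
    genes: list[str]
    stringency: str = "common"
    provenance: dict = field(default_factory=dict)

    VALID_STRINGENCY = ("common", "subpopulation", "tumor-conserved", "quorum-3/4")

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"signature {self.name!r} is empty")
        if self.stringency not in self.VALID_STRINGENCY:
            raise ValueError(f"unknown stringency {self.stringency!r}")


@dataclass
class IRFeatures:
    """Tumor-cell gene programs correlated with immune content (CD45 proxy)."""

    positive: list[str]
    negative: list[str]
    correlations: pd.DataFrame  # per gene: rho, p, q

    def __post_init__(self) -> None:
        overlap = set(self.positive) & set(self.negative)
        if overlap:
            raise ValueError(f"positive-IR and negative-IR overlap: {sorted(overlap)[:5]}")
        for g in self.positive:
            if self.correlations.loc[g, "rho"] <= 0:
                raise ValueError(f"positive-IR gene {g} has non-positive correlation")
        for g in self.negative:
            if self.correlations.loc[g, "rho"] >= 0:
                raise ValueError(f"negative-IR gene {g} has non-negative correlation")


@dataclass
class BulkCohort:
    """Bulk cohort: genes × samples log2-scale expression plus survival metadata."""

    expression: pd.DataFrame              # genes x samples, log2 scale
    samples: pd.DataFrame                 # index sample_id; tumor_type, time_months, event

    def __post_init__(self) -> None:
        if not self.expression.columns.equals(self.samples.index):
            if set(self.expression.columns) != set(self.samples.index):
                raise ValueError("expression columns and sample metadata disagree")
            self.samples = self.samples.loc[self.expression.columns]
        if "time_months" in self.samples:
            t = self.samples["time_months"].to_numpy(dtype=float)
            if np.any(t <= 0):
                raise ValueError("survival_time must be positive")
        if "event" in self.samples:
            ev = self.samples["event"].to_numpy()
            if not np.isin(ev, [0, 1]).all():
                raise ValueError("event must be 0/1")

    @property
    def n_samples(self) -> int:
        return self.expression.shape[1]


@dataclass
class ArchetypeModel:
    """Bulk immune-stromal-tumor archetypes in signature-score space."""

    feature_names: list[str]
    scores: pd.DataFrame                  # samples x features (z-scored columns)
    labels: pd.Series                     # per sample archetype label
    k: int
    dbi_trace: DBITrace
    centroids: pd.DataFrame | None = None
    gene_features: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.k != self.labels.nunique():
            raise ValueError("k does not match number of distinct labels")


@dataclass
class SurvivalResult:
    """Kaplan-Meier curves with log-rank p and univariate Cox fits."""

    km_curves: dict[str, pd.DataFrame]
    logrank_p: float
    cox: pd.DataFrame                     # per covariate: hr, ci_low, ci_high, p

    def __post_init__(self) -> None:
        if "hr" in self.cox.columns and np.any(self.cox["hr"].to_numpy() <= 0):
            raise ValueError("hazard ratios must be positive")
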