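"""On-disk formats: MatrixMarket triplets with TSV sidecars, GMT, cohort TSVs, newick.

Single-cell matrices are exchanged as a directory holding ``matrix.mtx``
(MatrixMarket coordinate, 1-based, genes × cells as in the 10x convention),
``genes.tsv``, ``barcodes.tsv`` and a small ``meta.yaml`` with the
platform/tumor/donor/label columns. Gene sets use GMT (name, description,
members, tab-separated). Bulk cohorts are a genes × samples TSV plus a
``samples.tsv`` with ``sample_id``, ``tumor_type``, ``time_months``, ``event``.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
import yaml

from .datatypes import BulkCohort, ExpressionDataset, GeneSetCollection


# ---------------------------------------------------------------------------
# MTX triplet + sidecars
# ---------------------------------------------------------------------------

def write_expression_dir(ds: ExpressionDataset, path: str | os.PathLike) -> Path:
    """Write a dataset as matrix.mtx + genes.tsv + barcodes.tsv + meta.yaml."""
    out = Path(path)
    out.mkdir(parents=True, exist_ok=True)
    # genes x cells, matching the droplet-vendor convention
    mat = sp.coo_matrix(ds.matrix.T)
    scipy.io.mmwrite(str(out / "matrix.mtx"), mat)
    pd.Series(ds.gene_ids).to_csv(out / "genes.tsv", sep="\t", header=False, index=False)
    pd.Series(ds.cell_ids).to_csv(out / "barcodes.tsv", sep="\t", header=False, index=False)
    per_cell = pd.DataFrame({"cell_id": ds.cell_ids, "donor": ds.donor})
    if ds.cell_label is not None:
        per_cell["cell_label"] = ds.cell_label
    per_cell.to_csv(out / "cells.tsv", sep="\t", index=False)
    meta = {
        "name": ds.name,
        "platform": ds.platform,
        "tumor_type": ds.tumor_type,
        "normalized": bool(ds.normalized),
    }
    (out / "meta.yaml").write_text(yaml.safe_dump(meta))
    return out


def read_expression_dir(path: str | os.PathLike) -> ExpressionDataset:
    """Read a dataset written by :func:`write_expression_dir`."""
    p = Path(path)
    mtx = p / "matrix.mtx"
    if not mtx.exists():
        raise FileNotFoundError(f"no matrix.mtx under {p}")
    mat = scipy.io.mmread(str(mtx))
    genes = pd.read_csv(p / "genes.tsv", sep="\t", header=None)[0].astype(str).to_numpy()
    cells = pd.read_csv(p / "barcodes.tsv", sep="\t", header=None)[0].astype(str).to_numpy()
    dense = np.asarray(sp.coo_matrix(mat).todense()).T  # back to cells x genes
    if dense.shape != (len(cells), len(genes)):
        raise ValueError(
            f"matrix dimensions {dense.shape} do not match sidecars "
            f"({len(cells)} barcodes, {len(genes)} genes)"
        )
    meta = yaml.safe_load((p / "meta.yaml").read_text()) if (p / "meta.yaml").exists() else {}
    donor = None
    cell_label = None
    if (p / "cells.tsv").exists():
        per_cell = pd.read_csv(p / "cells.tsv", sep="\t", dtype=str).set_index("cell_id").loc[cells]
        donor = per_cell["donor"].to_numpy()
        if "cell_label" in per_cell:
            cell_label = per_cell["cell_label"].to_numpy()
    return ExpressionDataset(
        matrix=dense,
        gene_ids=genes,
        cell_ids=cells,
        platform=meta.get("platform", "droplet-count"),
        tumor_type=meta.get("tumor_type", "unknown"),
        donor=donor,
        cell_label=cell_label,
        name=meta.get("name", p.name),
        normalized=bool(meta.get("normalized", False)),
    )


# ---------------------------------------------------------------------------
# GMT
# ---------------------------------------------------------------------------

def write_gmt(collection: GeneSetCollection, path: str | os.PathLike) -> Path:
    out = Path(path)
    with out.open("w") as fh:
        for name, genes in collection.items():
            desc = collection.description(name) or "na"
            fh.write("\t".join([name, desc, *genes]) + "\n")
    return out


def read_gmt(path: str | os.PathLike) -> GeneSetCollection:
    coll = GeneSetCollection()
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"malformed GMT line {lineno}: expected >=3 tab-separated fields")
        name, desc, *genes = fields
        genes = [g for g in genes if g]
        coll.add(name, genes, "" if desc == "na" else desc)
    return coll


# ---------------------------------------------------------------------------
# Bulk cohort TSVs
# ---------------------------------------------------------------------------

def write_bulk_cohort(cohort: BulkCohort, expr_path: str | os.PathLike,
                      samples_path: str | os.PathLike) -> None:
    cohort.expression.to_csv(expr_path, sep="\t", index_label="gene")
    cohort.samples.to_csv(samples_path, sep="\t", index_label="sample_id")


def read_bulk_cohort(expr_path: str | os.PathLike,
                     samples_path: str | os.PathLike) -> BulkCohort:
    expr = pd.read_csv(expr_path, sep="\t", index_col="gene")
    samples = pd.read_csv(samples_path, sep="\t", index_col="sample_id")
    return BulkCohort(expression=expr, samples=samples)


# ---------------------------------------------------------------------------
# Newick
# ---------------------------------------------------------------------------

def linkage_to_newick(linkage: np.ndarray, leaf_names: list[str]) -> str:
    """Render a scipy linkage matrix as a newick string with branch lengths."""
    from skbio.tree import TreeNode

    tree = TreeNode.from_linkage_matrix(linkage, leaf_names)
    return str(tree).strip()


def write_newick(newick: str, path: str | os.PathLike) -> Path:
    out = Path(path)
    text = newick.strip()
    if not text.endswith(";"):
        text += ";"
    out.write_text(text + "\n")
    return out


def read_newick(path: str | os.PathLike):
    """Parse a newick file into a scikit-bio TreeNode."""
    from skbio.tree import TreeNode

    return TreeNode.read(str(path), format="newick")
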