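"""QC gates, normalization closed forms, two-run clustering and annotation."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import adjusted_rand_score

from ecotyper import preprocess, synthio
from ecotyper.datatypes import ExpressionDataset, MarkerPanel, QCThresholds

PANEL = MarkerPanel({"Myeloid": ["ITGAM", "LYZ", "AIF1", "CSF1R"],
                     "T": ["CD3D", "CD3E", "TRAC", "CD2"],
                     "Oligo": ["MBP", "MOG", "PLP1"]})


def _cell_with(total, n_genes, mito_frac, n_cols=600):
    """One synthetic droplet cell row with the requested QC statistics."""
    row = np.zeros(n_cols)
    mito = int(round(total * mito_frac))
    body = total - mito
    base, rem = divmod(body, n_genes - 1)
    row[1:n_genes] = base
    row[1] += rem
    row[0] = mito  # column 0 is the mitochondrial gene
    return row


def _dataset_from_rows(rows):
    genes = ["MT-1"] + [f"G{i}" for i in range(1, rows.shape[1])]
    return ExpressionDataset(matrix=rows, gene_ids=genes,
                             cell_ids=[f"c{i}" for i in range(rows.shape[0])],
                             platform="droplet-count")


class TestQCFilter:
    @pytest.mark.parametrize(
        "total,n_genes,mito,kept",
        [
            (1999, 500, 0.01, False),   # one count below the UMI gate
            (2000, 200, 0.10, True),    # exactly at every gate: retained
            (5000, 199, 0.01, False),   # one detected gene short
            (5000, 500, 0.101, False),  # just above the mito gate
            (5000, 500, 0.05, True),
        ],
    )
    def test_boundary_semantics(self, total, n_genes, mito, kept):
        ds = _dataset_from_rows(np.vstack([
            _cell_with(total, n_genes, mito),
            _cell_with(9000, 500, 0.02),  # companion cell so the result is non-empty
        ]))
        out = preprocess.qc_filter(ds, QCThresholds())
        assert ("c0" in out.cell_ids) == kept

    def test_planted_violations_counted_by_rule(self, programs_fragile):
        programs, fragile = programs_fragile
        cfg = synthio.SimulationConfig(
            datasets=[synthio.DatasetSpec("d", "droplet-count", "MB", 100,
                                          {"T": 0.5, "Myeloid": 0.5},
                                          qc_violations=10)],
            programs=programs, fragile_genes=fragile, seed=0,
        )
        ds = synthio.simulate_single_cell(cfg)[0]
        thr = QCThresholds()
        stats = ds.qc_stats()
        mask = ((stats["total_counts"] >= thr.min_umi)
                & (stats["n_genes_detected"] >= thr.min_genes)
                & (stats["mito_fraction"] <= thr.max_mito_fraction))
        out = preprocess.qc_filter(ds, thr)
        assert out.n_cells == int(mask.sum()) == 90

    @settings(max_examples=25, deadline=None)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_kept_count_equals_boolean_mask(self, seed):
        rng = np.random.default_rng(seed)
        rows = rng.poisson(rng.uniform(0.5, 30), size=(30, 400)).astype(float)
        ds = _dataset_from_rows(rows)
        thr = QCThresholds(min_umi=rng.integers(100, 5000),
                           min_genes=rng.integers(10, 300),
                           max_mito_fraction=float(rng.uniform(0.001, 0.2)))
        stats = ds.qc_stats()
        mask = ((stats["total_counts"] >= thr.min_umi)
                & (stats["n_genes_detected"] >= thr.min_genes)
                & (stats["mito_fraction"] <= thr.max_mito_fraction))
        if mask.sum() == 0:
            with pytest.raises(preprocess.AllCellsFilteredError):
                preprocess.qc_filter(ds, thr)
        else:
            assert preprocess.qc_filter(ds, thr).n_cells == int(mask.sum())

    def test_full_length_bypasses_with_warning(self):
        ds = ExpressionDataset(matrix=np.ones((3, 4)), gene_ids=list("abcd"),
                               cell_ids=list("xyz"), platform="full-length-tpm")
        with pytest.warns(UserWarning, match="bypass"):
            out = preprocess.qc_filter(ds)
        assert out.n_cells == 3


class TestNormalize:
    def test_droplet_closed_form(self):
        ds = _dataset_from_rows(np.array([[0.0, 10.0, 90.0] + [0.0] * 3,
                                          [0.0, 1.0, 1.0] + [0.0] * 3]))
        out = preprocess.normalize(ds)
        np.testing.assert_allclose(out.matrix[0, 1:3], [np.log(1001), np.log(9001)])
        assert out.matrix[0, 3] == 0.0

    def test_tpm_closed_form_and_zero_cell(self):
        ds = ExpressionDataset(matrix=np.array([[3.0, 0.0], [0.0, 0.0]]),
                               gene_ids=["a", "b"], cell_ids=["c1", "c2"],
                               platform="full-length-tpm")
        out = preprocess.normalize(ds)
        assert out.matrix[0, 0] == pytest.approx(2.0)  # log2(3+1)
        assert np.all(out.matrix[1] == 0.0)

    def test_double_normalization_raises(self):
        ds = _dataset_from_rows(np.ones((2, 5)))
        out = preprocess.normalize(ds)
        with pytest.raises(preprocess.AlreadyNormalizedError):
            preprocess.normalize(out)


class TestTwoRunCluster:
    def test_two_separated_types_perfectly_recovered(self, programs_fragile):
        programs, fragile = programs_fragile
        cfg = synthio.SimulationConfig(
            datasets=[synthio.DatasetSpec("d", "droplet-count", "MB", 300,
                                          {"T": 0.5, "Myeloid": 0.5})],
            programs=programs, fragile_genes=fragile, seed=0,
        )
        ds = preprocess.normalize(synthio.simulate_single_cell(cfg)[0])
        model = preprocess.two_run_cluster(ds, resolution_first=0.3, seed=0)
        assert model.n_clusters >= 2
        assert adjusted_rand_score(ds.cell_label, model.labels) == 1.0

    def test_single_type_low_resolution_one_cluster(self, programs_fragile):
        programs, fragile = programs_fragile
        cfg = synthio.SimulationConfig(
            datasets=[synthio.DatasetSpec("d", "droplet-count", "MB", 150,
                                          {"T": 1.0})],
            programs=programs, fragile_genes=fragile, seed=0,
        )
        ds = preprocess.normalize(synthio.simulate_single_cell(cfg)[0])
        model = preprocess.two_run_cluster(ds, resolution_first=0.01, seed=0)
        assert model.n_clusters == 1

    def test_planted_contaminants_purged(self, programs_fragile):
        programs, fragile = programs_fragile
        cfg = synthio.SimulationConfig(
            datasets=[synthio.DatasetSpec("d", "droplet-count", "MB", 400,
                                          {"Myeloid": 0.98, "T": 0.02})],
            programs=programs, fragile_genes=fragile, seed=0,
        )
        ds = preprocess.normalize(synthio.simulate_single_cell(cfg)[0])
        model = preprocess.two_run_cluster(ds, resolution_first=0.01,
                                           panel=PANEL, seed=0)
        t_cells = ds.cell_label == "T"
        flagged = model.labels == preprocess.CONTAMINANT_LABEL
        assert flagged[t_cells].mean() >= 0.8       # contaminants caught
        assert flagged[~t_cells].mean() <= 0.10     # bulk of the type kept

    def test_fewer_cells_than_pcs_rejected(self):
        ds = ExpressionDataset(matrix=np.ones((3, 50)), gene_ids=[f"g{i}" for i in range(50)],
                               cell_ids=list("abc"), platform="full-length-tpm",
                               normalized=True)
        with pytest.raises(ValueError):
            preprocess.two_run_cluster(ds, n_pcs=15, resolution_first=0.3)


class TestAnnotation:
    def test_constant_marker_yields_no_positives(self):
        ds = ExpressionDataset(matrix=np.full((10, 2), 3.0), gene_ids=["MBP", "x"],
                               cell_ids=[f"c{i}" for i in range(10)],
                               platform="full-length-tpm")
        assert preprocess.annotate_positive_selection(ds, "MBP").sum() == 0

    def test_bimodal_marker_recovers_high_mode(self, rng):
        high = rng.normal(8, 0.3, 30)
        low = rng.normal(1, 0.3, 70)
        values = np.concatenate([high, low])
        ds = ExpressionDataset(matrix=np.column_stack([values, rng.random(100)]),
                               gene_ids=["MBP", "x"],
                               cell_ids=[f"c{i}" for i in range(100)],
                               platform="full-length-tpm")
        positive = preprocess.annotate_positive_selection(ds, "MBP")
        assert positive[:30].all() and not positive[30:].any()

    def test_positive_set_invariant_to_common_rescale(self, rng):
        values = rng.lognormal(1, 1, 50)
        mat = np.column_stack([values, rng.random(50)])
        ds1 = ExpressionDataset(matrix=mat, gene_ids=["MBP", "x"],
                                cell_ids=[f"c{i}" for i in range(50)],
                                platform="full-length-tpm")
        ds2 = ExpressionDataset(matrix=mat * 7.5, gene_ids=["MBP", "x"],
                                cell_ids=[f"c{i}" for i in range(50)],
                                platform="full-length-tpm")
        np.testing.assert_array_equal(
            preprocess.annotate_positive_selection(ds1, "MBP"),
            preprocess.annotate_positive_selection(ds2, "MBP"),
        )

    def test_cluster_based_annotation_on_planted_types(self, tme_datasets):
        ds = tme_datasets[0]
        model = preprocess.two_run_cluster(ds, resolution_first=0.3, seed=0)
        labels = preprocess.annotate_cluster_based(model, PANEL, ds)
        assert (labels == ds.cell_label).mean() > 0.95

    def test_compare_annotation_methods_table(self, tme_datasets):
        table = preprocess.compare_annotation_methods(tme_datasets[0], PANEL, seed=0)
        assert set(table["method"]) == {"cluster-based", "positive-selection"}
        assert set(table["cell_type"]) == set(PANEL.types())
        assert {"n_cells", "mean_marker_expression", "mean_pathway_score"} <= set(table.columns)
        assert (table["n_cells"] > 0).all()
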