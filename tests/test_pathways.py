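"""Markers, enrichment, rank-based set scores and the marker-pathway rule."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ecotyper import pathways as pw
from ecotyper._stats import rank_sum_p
from ecotyper.datatypes import ExpressionDataset, GeneSetCollection
from tests._oracles import hypergeom_tail_closed_form, wilcoxon_exact_enum


def _dataset(matrix, genes=None, labels=None):
    matrix = np.asarray(matrix, dtype=float)
    genes = genes or [f"g{i}" for i in range(matrix.shape[1])]
    return ExpressionDataset(
        matrix=matrix, gene_ids=genes,
        cell_ids=[f"c{i}" for i in range(matrix.shape[0])],
        platform="full-length-tpm", normalized=True,
        cell_label=labels,
    )


class TestWilcoxon:
    @settings(max_examples=40, deadline=None)
    @given(st.integers(0, 2**31 - 1), st.integers(2, 8), st.integers(2, 8),
           st.booleans())
    def test_small_groups_match_exact_enumeration(self, seed, n1, n2, with_ties):
        rng = np.random.default_rng(seed)
        if with_ties:
            pool = rng.integers(0, 4, size=n1 + n2).astype(float)
        else:
            pool = rng.normal(size=n1 + n2)
        x, y = pool[:n1], pool[n1:]
        assert rank_sum_p(x, y) == pytest.approx(wilcoxon_exact_enum(x, y), abs=1e-12)

    def test_matches_scipy_exact_on_tie_free_data(self, rng):
        from scipy.stats import mannwhitneyu

        x, y = rng.normal(size=6), rng.normal(size=7)
        expected = mannwhitneyu(x, y, alternative="two-sided", method="exact").pvalue
        assert rank_sum_p(x, y) == pytest.approx(float(expected), abs=1e-12)


class TestFindMarkers:
    def test_exclusive_gene_is_a_marker_at_any_min_pct(self):
        rng = np.random.default_rng(0)
        mat = rng.lognormal(0, 0.2, size=(40, 5))
        mat[:20, 0] = 0.0            # gene 0 silent outside cluster A
        labels = np.array(["B"] * 20 + ["A"] * 20)
        table = pw.find_markers(_dataset(mat), labels)
        row = table[(table["cluster"] == "A") & (table["gene"] == "g0")].iloc[0]
        assert row["logfc"] > 0 and row["pct_out"] == 0.0 and row["pct_in"] == 1.0
        kept = pw.find_markers(_dataset(mat), labels, min_pct=0.99)
        assert "g0" in set(kept[kept["cluster"] == "A"]["gene"])

    def test_permuted_labels_yield_no_deep_significance(self, tme_datasets):
        ds = tme_datasets[0]
        rng = np.random.default_rng(7)
        hits = 0
        for _ in range(5):
            permuted = rng.permutation(ds.cell_label)
            table = pw.find_markers(ds, permuted, p_adj_max=1e-10)
            hits += len(table)
        assert hits == 0

    def test_planted_marker_passes_droplet_threshold_triple(self, tme_datasets):
        ds = tme_datasets[0]  # droplet platform
        table = pw.find_markers(ds, logfc_min=0.25, p_adj_max=1e-10, min_pct=0.1)
        t_markers = set(table[table["cluster"] == "T"]["gene"])
        assert "CD3D" in t_markers and "TRAC" in t_markers


class TestHypergeometricEnrichment:
    def test_markers_equal_universe_no_enrichment(self):
        universe = [f"g{i}" for i in range(50)]
        coll = GeneSetCollection({"s1": universe[:10], "s2": universe[20:30]})
        table = pw.hypergeometric_enrichment(universe, coll, universe)
        assert (table["p"] == 1.0).all()

    def test_perfect_overlap_matches_closed_form(self):
        universe = [f"g{i}" for i in range(1000)]
        markers = universe[:10]
        coll = GeneSetCollection({"hit": universe[:10], "other": universe[500:540]})
        table = pw.hypergeometric_enrichment(markers, coll, universe)
        p_hit = table.set_index("set").loc["hit", "p"]
        assert p_hit == pytest.approx(hypergeom_tail_closed_form(10, 10, 10, 1000),
                                      rel=1e-9)

    @settings(max_examples=30, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_tail_matches_pmf_sum_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n_universe = int(rng.integers(20, 60))
        universe = [f"g{i}" for i in range(n_universe)]
        set_genes = list(rng.choice(universe, int(rng.integers(3, 10)), replace=False))
        markers = list(rng.choice(universe, int(rng.integers(3, 15)), replace=False))
        coll = GeneSetCollection({"s": set_genes})
        table = pw.hypergeometric_enrichment(markers, coll, universe)
        overlap = len(set(set_genes) & set(markers))
        expected = hypergeom_tail_closed_form(overlap, len(set_genes),
                                              len(markers), n_universe)
        assert table["p"].iloc[0] == pytest.approx(expected, rel=1e-9)

    def test_disjoint_set_p_one(self):
        universe = [f"g{i}" for i in range(40)]
        coll = GeneSetCollection({"s": universe[30:]})
        table = pw.hypergeometric_enrichment(universe[:10], coll, universe)
        assert table["overlap"].iloc[0] == 0 and table["p"].iloc[0] == 1.0


class TestSampleSetScore:
    def test_set_at_top_ranks_is_the_maximum(self, rng):
        values = np.arange(1.0, 101.0)
        rng.shuffle(values)
        ds = _dataset(values[None, :])
        genes = list(ds.gene_ids)
        order = np.argsort(-values)
        top_set = [genes[i] for i in order[:10]]
        top_score = pw.sample_set_score(ds, top_set)[0]
        for _ in range(20):
            other = list(rng.choice(genes, 10, replace=False))
            if set(other) == set(top_set):
                continue
            assert pw.sample_set_score(ds, other)[0] < top_score

    def test_invariant_to_monotone_transform(self, rng):
        mat = rng.lognormal(0, 1, size=(5, 80))
        ds1, ds2 = _dataset(mat), _dataset(np.exp(mat))
        genes = [f"g{i}" for i in range(0, 80, 7)]
        np.testing.assert_allclose(pw.sample_set_score(ds1, genes),
                                   pw.sample_set_score(ds2, genes))

    def test_null_mean_near_zero_on_shuffled_data(self, tme_datasets):
        ds = tme_datasets[1]
        rng = np.random.default_rng(11)
        shuffled = rng.permuted(ds.matrix[:1000], axis=1)
        genes = list(rng.choice(ds.gene_ids, 20, replace=False))
        scores = pw.sample_set_score(shuffled, genes, gene_ids=ds.gene_ids)
        sem = scores.std(ddof=1) / np.sqrt(len(scores))
        assert abs(scores.mean()) < 3 * sem


class TestDifferentialAndMarkerPathway:
    def _score_frame(self, rng):
        labels = np.array(["A"] * 30 + ["B"] * 30)
        up = np.concatenate([rng.normal(1.0, 0.3, 30), rng.normal(0.0, 0.3, 30)])
        flat = rng.normal(0.0, 0.3, 60)
        scores = pd.DataFrame([up, flat], index=["up_in_A", "flat"],
                              columns=[f"c{i}" for i in range(60)])
        return scores, labels

    @pytest.mark.parametrize("method", ["moderated", "welch"])
    def test_differential_pathways_finds_planted_shift(self, rng, method):
        scores, labels = self._score_frame(rng)
        table = pw.differential_pathways(scores, labels, method=method)
        hits = set(table[table["cluster"] == "A"]["set"])
        assert hits == {"up_in_A"}

    def test_marker_pathway_single_candidate(self):
        coll = GeneSetCollection({"path1": ["m1", "m2", "x1"]})
        enrichment = pd.DataFrame({"set": ["path1"], "overlap": [2], "set_size": [3],
                                   "p": [1e-4], "q": [1e-4], "enrichment_score": [4.0]})
        differential = pd.DataFrame({"cluster": ["0"], "set": ["path1"], "diff": [1.0],
                                     "t": [5.0], "p": [1e-3], "p_adj": [1e-3]})
        markers = pd.DataFrame({"cluster": ["0", "0"], "gene": ["m1", "m2"],
                                "logfc": [2.0, 1.0], "pct_in": [0.9, 0.8],
                                "pct_out": [0.1, 0.1], "p": [1e-5, 1e-4],
                                "p_adj": [1e-4, 1e-3]})
        call = pw.marker_pathway("0", enrichment, differential, markers, coll)
        assert call.pathway == "path1" and call.marker_gene == "m1"

    def test_equal_score_tie_prefers_smaller_set(self):
        coll = GeneSetCollection({"big": [f"b{i}" for i in range(199)] + ["m1"],
                                  "small": [f"s{i}" for i in range(29)] + ["m1"]})
        enrichment = pd.DataFrame({
            "set": ["big", "small"], "overlap": [1, 1], "set_size": [200, 30],
            "p": [1e-3, 1e-3], "q": [1e-3, 1e-3], "enrichment_score": [3.0, 3.0]})
        differential = pd.DataFrame({"cluster": ["0", "0"], "set": ["big", "small"],
                                     "diff": [1, 1], "t": [4, 4],
                                     "p": [1e-3, 1e-3], "p_adj": [1e-3, 1e-3]})
        markers = pd.DataFrame({"cluster": ["0"], "gene": ["m1"], "logfc": [1.5],
                                "pct_in": [0.9], "pct_out": [0.1],
                                "p": [1e-6], "p_adj": [1e-5]})
        call = pw.marker_pathway("0", enrichment, differential, markers, coll)
        assert call.pathway == "small"

    def test_no_call_when_no_pathway_contains_top_markers(self):
        coll = GeneSetCollection({"path1": ["z1", "z2"]})
        enrichment = pd.DataFrame({"set": ["path1"], "overlap": [0], "set_size": [2],
                                   "p": [0.5], "q": [0.5], "enrichment_score": [0.3]})
        differential = pd.DataFrame({"cluster": ["0"], "set": ["path1"], "diff": [1],
                                     "t": [3], "p": [0.01], "p_adj": [0.01]})
        markers = pd.DataFrame({"cluster": ["0"], "gene": ["m1"], "logfc": [1.0],
                                "pct_in": [0.5], "pct_out": [0.1],
                                "p": [1e-4], "p_adj": [1e-3]})
        assert pw.marker_pathway("0", enrichment, differential, markers, coll) is None

    def test_polarization_table_shape(self, tme_datasets):
        ds = tme_datasets[0]
        table = pw.polarization_scores(
            ds, ds.cell_label,
            ("M1", ["CD3D", "CD3E"]), ("M2", ["ITGAM", "LYZ"]))
        assert set(table.columns) == {"cluster", "M1", "M2", "n_cells"}
        assert len(table) == len(set(ds.cell_label))
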