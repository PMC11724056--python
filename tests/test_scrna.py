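"""Single-cell stage: QC, normalization, clustering, markers, annotation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.metrics import adjusted_rand_score

from scarscreen import scrna
from scarscreen.io import CountMatrix, NormMatrix


def _matrix(values, genes=None, cells=None) -> CountMatrix:
    values = np.asarray(values)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    cells = cells or [f"c{j}" for j in range(values.shape[1])]
    return CountMatrix(genes, cells, values)


class TestQCFilter:
    def test_permissive_thresholds_are_identity(self):
        rng = np.random.default_rng(0)
        m = _matrix(rng.integers(0, 5, size=(20, 15)))
        out = scrna.qc_filter(m, min_genes=0, min_counts=0,
                              max_counts_quantile=1.0, min_cells_per_gene=0)
        np.testing.assert_array_equal(out.values, m.values)

    def test_zero_count_cell_removed_at_boundary(self):
        m = _matrix(np.array([[1, 0], [2, 0]]))
        out = scrna.qc_filter(m, min_genes=0, min_counts=1,
                              max_counts_quantile=1.0, min_cells_per_gene=0)
        assert out.obs_ids == ["c0"]

    def test_depth_quantile_removes_exactly_the_deepest_cell(self):
        rng = np.random.default_rng(1)
        depths = rng.permutation(np.arange(10, 110, 10))
        values = np.zeros((1, 10), dtype=int)
        values[0] = depths
        m = _matrix(values)
        out = scrna.qc_filter(m, min_genes=0, min_counts=0,
                              max_counts_quantile=0.9, min_cells_per_gene=0)
        removed = set(m.obs_ids) - set(out.obs_ids)
        deepest = m.obs_ids[int(np.argmax(depths))]
        assert removed == {deepest}

    def test_all_cells_removed_is_an_error(self):
        m = _matrix(np.array([[0, 0]]))
        with pytest.raises(ValueError, match="all cells"):
            scrna.qc_filter(m, min_genes=1, min_counts=1,
                            max_counts_quantile=1.0, min_cells_per_gene=0)


class TestNormalize:
    def test_zero_count_maps_to_zero(self):
        m = _matrix(np.array([[0, 5], [10, 0]]))
        norm = scrna.normalize_log_cpm(m)
        assert norm.values[0, 0] == 0.0
        assert norm.values[1, 1] == 0.0

    def test_two_equal_counts_match_closed_form(self):
        m = _matrix(np.array([[1], [1]]))
        norm = scrna.normalize_log_cpm(m)
        np.testing.assert_allclose(norm.values, np.log(1 + 5000.0), rtol=1e-12)

    def test_depth_invariance_within_observation(self):
        rng = np.random.default_rng(2)
        counts = rng.integers(1, 20, size=(30, 1))
        a = scrna.normalize_log_cpm(_matrix(counts))
        b = scrna.normalize_log_cpm(_matrix(counts * 2))
        np.testing.assert_allclose(a.values, b.values, rtol=1e-12)

    def test_monotone_in_count_within_observation(self):
        m = _matrix(np.array([[1], [5], [20]]))
        norm = scrna.normalize_log_cpm(m)
        assert norm.values[0, 0] < norm.values[1, 0] < norm.values[2, 0]


def _two_blob_norm(n_per=200, d=30, sep=6.0, seed=0):
    rng = np.random.default_rng(seed)
    a = rng.normal(0.0, 1.0, size=(n_per, d))
    b = rng.normal(0.0, 1.0, size=(n_per, d)) + sep / np.sqrt(d)
    X = np.vstack([a, b])
    order = rng.permutation(2 * n_per)
    X = X[order]
    labels_true = (order >= n_per).astype(int)
    norm = NormMatrix([f"g{i}" for i in range(d)],
                      [f"c{j}" for j in range(2 * n_per)],
                      np.abs(X.T))
    return norm, labels_true


class TestClustering:
    def test_two_planted_blobs_recovered_exactly(self):
        norm, truth = _two_blob_norm(sep=14.0, seed=3)
        labels = scrna.cluster_cells(norm, n_pcs=5, k_neighbors=10,
                                     resolution=0.5, seed=0)
        assert labels.max() + 1 == 2
        assert adjusted_rand_score(truth, labels) == 1.0

    def test_same_seed_reproduces_labels(self):
        norm, _ = _two_blob_norm(seed=4)
        a = scrna.cluster_cells(norm, n_pcs=5, k_neighbors=10, seed=7)
        b = scrna.cluster_cells(norm, n_pcs=5, k_neighbors=10, seed=7)
        np.testing.assert_array_equal(a, b)

    def test_partition_invariant_to_gene_order(self):
        norm, _ = _two_blob_norm(sep=14.0, seed=5)
        labels_a = scrna.cluster_cells(norm, n_pcs=5, k_neighbors=10, seed=1)
        rng = np.random.default_rng(0)
        perm = rng.permutation(norm.n_genes)
        shuffled = NormMatrix([norm.gene_ids[i] for i in perm], norm.obs_ids,
                              norm.values[perm])
        labels_b = scrna.cluster_cells(shuffled, n_pcs=5, k_neighbors=10, seed=1)
        assert adjusted_rand_score(labels_a, labels_b) == 1.0

    def test_too_few_cells_rejected(self):
        norm = NormMatrix(["g0"], ["c0", "c1"], np.ones((1, 2)))
        with pytest.raises(ValueError):
            scrna.cluster_cells(norm, n_pcs=1, k_neighbors=5)

    def test_single_tight_blob_is_one_subcluster(self):
        rng = np.random.default_rng(6)
        X = rng.normal(0, 0.05, size=(120, 10))
        norm = NormMatrix([f"g{i}" for i in range(10)],
                          [f"c{j}" for j in range(120)], np.abs(X.T))
        labels = np.zeros(120, dtype=int)
        subs = scrna.subcluster(norm, labels, 0, prefix="F", n_pcs=5,
                                k_neighbors=15, resolution=0.3, seed=0)
        assert subs.nunique() == 1
        assert set(subs) == {"F1"}


class TestMarkers:
    def test_constant_gene_is_never_a_marker(self):
        rng = np.random.default_rng(7)
        values = rng.normal(1, 0.1, size=(5, 60))
        values[0] = 2.0  # identical across clusters
        norm = NormMatrix([f"g{i}" for i in range(5)],
                          [f"c{j}" for j in range(60)], np.abs(values))
        labels = np.repeat([0, 1], 30)
        table = scrna.find_markers(norm, labels)
        assert not table[(table["gene"] == "g0") & table["is_marker"]].shape[0]

    def test_exact_wilcoxon_four_vs_four_enumeration(self):
        # (0,0,0,0) vs (5,5,5,5): only 2 of the C(8,4)=70 assignments are
        # as extreme as observed -> two-sided p = 2/70
        p = scrna.rank_sum_test(np.zeros(4), np.full(4, 5.0))
        assert p == pytest.approx(2.0 / 70.0, rel=1e-12)
        norm = NormMatrix(["g0"], [f"c{j}" for j in range(8)],
                          np.array([[0., 0., 0., 0., 5., 5., 5., 5.]]))
        table = scrna.find_markers(norm, np.repeat([0, 1], 4),
                                   q_max=0.5, lfc_min=0.0, pct_min=0.0)
        row = table[(table["gene"] == "g0") & (table["cluster"] == 1)].iloc[0]
        assert row["p"] == pytest.approx(2.0 / 70.0, rel=1e-12)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_bh_qvalues_monotone_and_bounded(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.uniform(size=40)
        q = scrna.benjamini_hochberg(p)
        assert np.all(q >= p - 1e-12)
        assert np.all(q <= 1.0)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)

    def test_small_cluster_skipped_with_warning(self):
        norm = NormMatrix(["g0"], [f"c{j}" for j in range(10)],
                          np.arange(10, dtype=float)[None, :])
        labels = np.array([0] * 8 + [1] * 2)
        with pytest.warns(UserWarning, match="skipped"):
            table = scrna.find_markers(norm, labels)
        assert set(table["cluster"]) == {0}


class TestAnnotation:
    def _norm(self):
        # cluster 0 dominated by Dcn, cluster 1 by Lyz2
        values = np.array([
            [5.0, 5.0, 0.1, 0.1],   # Dcn
            [0.1, 0.1, 5.0, 5.0],   # Lyz2
            [1.0, 1.0, 1.0, 1.0],   # bystander
        ])
        return NormMatrix(["Dcn", "Lyz2", "g2"], list("abcd"), values)

    def test_dcn_dominated_cluster_is_fibroblast(self):
        mapping = scrna.annotate_clusters(self._norm(), np.array([0, 0, 1, 1]),
                                          {"F": ["Dcn"], "M": ["Lyz2"]})
        assert mapping[0]["type"] == "F"
        assert mapping[1]["type"] == "M"
        assert not mapping[0]["tie"]

    def test_cluster_without_map_genes_unassigned(self):
        mapping = scrna.annotate_clusters(self._norm(), np.array([0, 0, 1, 1]),
                                          {"X": ["absent_gene"]})
        assert mapping[0]["type"] == "unassigned"

    def test_exact_tie_flagged_lexicographic(self):
        values = np.array([[1.0, 3.0], [1.0, 3.0]])
        norm = NormMatrix(["A", "B"], ["c0", "c1"], values)
        mapping = scrna.annotate_clusters(norm, np.array([0, 1]),
                                          {"beta": ["B"], "alpha": ["A"]})
        assert mapping[1]["type"] == "alpha"
        assert mapping[1]["tie"]


class TestTemporalProportions:
    def test_single_timepoint_subcluster_is_degenerate(self):
        table = scrna.temporal_proportions([3, 7, 14, 14], ["F1", "F1", "F1", "F2"])
        np.testing.assert_allclose(table.loc["F2"].to_numpy(), [0.0, 0.0, 1.0])

    def test_rows_sum_to_one(self):
        rng = np.random.default_rng(8)
        days = rng.choice([3, 7, 14], size=200)
        subs = rng.choice([f"F{i}" for i in range(1, 9)], size=200)
        table = scrna.temporal_proportions(days, subs)
        np.testing.assert_allclose(table.sum(axis=1).to_numpy(), 1.0, atol=1e-12)


class TestFibroblastSpecificity:
    def test_exclusive_gene_scores_one(self):
        values = np.array([[2.0, 2.0, 0.0, 0.0]])
        norm = NormMatrix(["g"], list("abcd"), values)
        score = scrna.fibroblast_specificity(norm, np.array(["F", "F", "M", "M"]), "g")
        assert score == pytest.approx(1.0, abs=1e-6)

    def test_uniform_gene_scores_one_over_k(self):
        labels = np.repeat([f"T{i}" for i in range(8)], 3)
        labels[:3] = "F"
        values = np.ones((1, 24))
        norm = NormMatrix(["g"], [f"c{j}" for j in range(24)], values)
        score = scrna.fibroblast_specificity(norm, labels, "g")
        assert score == pytest.approx(1.0 / 8.0, rel=1e-6)

    def test_absent_gene_raises(self):
        norm = NormMatrix(["g"], ["a", "b"], np.ones((1, 2)))
        with pytest.raises(KeyError):
            scrna.fibroblast_specificity(norm, np.array(["F", "M"]), "nope")
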