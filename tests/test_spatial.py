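"""Spot deconvolution (EM vs oracles) and region-level DEGs."""

import itertools

import numpy as np
import pandas as pd
import pytest

from scarscreen import spatial
from scarscreen.io import CountMatrix, SpotTable
from scarscreen.spatial import Reference


def _reference(K=3, G=20, seed=0) -> Reference:
    rng = np.random.default_rng(seed)
    profiles = rng.dirichlet(np.ones(G) * 0.8, size=K)
    return Reference([f"T{k}" for k in range(K)], [f"g{i}" for i in range(G)], profiles)


def _grid_search(y, reference, step=0.01):
    """Exhaustive simplex grid maximization of the same multinomial likelihood."""
    R = reference.profiles
    best, best_ll = None, -np.inf
    ticks = np.arange(0, 1 + step / 2, step)
    for w1, w2 in itertools.product(ticks, ticks):
        if w1 + w2 > 1 + 1e-12:
            continue
        w = np.array([w1, w2, 1.0 - w1 - w2])
        p = w @ R
        mask = y > 0
        ll = np.sum(y[mask] * np.log(np.maximum(p[mask], 1e-300)))
        if ll > best_ll:
            best, best_ll = w, ll
    return best


class TestBuildReference:
    def test_single_type_single_gene(self):
        m = CountMatrix(["g"], [f"c{i}" for i in range(12)],
                        np.full((1, 12), 7))
        ref = spatial.build_reference(m, np.array(["F"] * 12))
        np.testing.assert_allclose(ref.profiles, [[1.0]])

    def test_two_gene_arithmetic(self):
        values = np.array([[2, 2], [2, 2]]).repeat(5, axis=1)
        m = CountMatrix(["A", "B"], [f"c{i}" for i in range(10)], values)
        ref = spatial.build_reference(m, np.array(["F"] * 10))
        np.testing.assert_allclose(ref.profiles, [[0.5, 0.5]])

    def test_rows_on_simplex_and_zero_genes_dropped(self):
        rng = np.random.default_rng(1)
        values = rng.integers(0, 10, size=(30, 40))
        values[5] = 0
        m = CountMatrix([f"g{i}" for i in range(30)],
                        [f"c{j}" for j in range(40)], values)
        labels = np.repeat(["A", "B"], 20)
        ref = spatial.build_reference(m, labels)
        assert "g5" not in ref.gene_ids
        np.testing.assert_allclose(ref.profiles.sum(axis=1), 1.0, atol=1e-12)

    def test_small_type_rejected_by_name(self):
        m = CountMatrix(["g"], [f"c{i}" for i in range(12)], np.ones((1, 12), dtype=int))
        labels = np.array(["F"] * 11 + ["rare"])
        with pytest.raises(ValueError, match="rare"):
            spatial.build_reference(m, labels)


class TestDeconvolveSpot:
    def test_pure_spot_recovers_unit_weight(self):
        ref = _reference(seed=2)
        y = 1000.0 * ref.profiles[1]
        res = spatial.deconvolve_spot(y, ref, max_iter=5000, tol=1e-9)
        assert res["weights"][1] == pytest.approx(1.0, abs=1e-4)
        assert res["weights"].sum() == pytest.approx(1.0, abs=1e-9)

    def test_em_matches_grid_search_oracle(self):
        rng = np.random.default_rng(3)
        ref = _reference(seed=3)
        w_true = np.array([0.6, 0.3, 0.1])
        y = rng.multinomial(50_000, w_true @ ref.profiles).astype(float)
        res = spatial.deconvolve_spot(y, ref, max_iter=5000, tol=1e-9)
        w_grid = _grid_search(y, ref, step=0.01)
        assert np.max(np.abs(res["weights"] - w_grid)) <= 0.01

    def test_loglik_trace_nondecreasing(self):
        rng = np.random.default_rng(4)
        ref = _reference(seed=4)
        y = rng.multinomial(5000, np.full(20, 0.05)).astype(float)
        res = spatial.deconvolve_spot(y, ref, keep_trace=True)
        trace = np.array(res["trace"])
        assert np.all(np.diff(trace) >= -1e-8)

    def test_gene_permutation_leaves_weights_unchanged(self):
        rng = np.random.default_rng(5)
        ref = _reference(seed=5)
        y = rng.multinomial(10_000, np.array([0.5, 0.2, 0.3]) @ ref.profiles).astype(float)
        res_a = spatial.deconvolve_spot(y, ref)
        perm = rng.permutation(20)
        ref_p = Reference(ref.type_ids, [ref.gene_ids[i] for i in perm],
                          ref.profiles[:, perm] / ref.profiles[:, perm].sum(axis=1, keepdims=True))
        res_b = spatial.deconvolve_spot(y[perm], ref_p)
        np.testing.assert_allclose(res_a["weights"], res_b["weights"], atol=1e-9)

    def test_count_scaling_invariance(self):
        rng = np.random.default_rng(6)
        ref = _reference(seed=6)
        y = rng.multinomial(20_000, np.array([0.3, 0.3, 0.4]) @ ref.profiles).astype(float)
        a = spatial.deconvolve_spot(y, ref, tol=1e-9, max_iter=5000)["weights"]
        b = spatial.deconvolve_spot(7 * y, ref, tol=1e-9, max_iter=5000)["weights"]
        np.testing.assert_allclose(a, b, atol=1e-6)

    def test_zero_spot_skipped(self):
        ref = _reference(seed=7)
        res = spatial.deconvolve_spot(np.zeros(20), ref)
        assert res["skipped"]


class TestDeconvolveAll:
    def test_zero_spot_flagged_in_batch(self):
        ref = _reference(seed=8)
        rng = np.random.default_rng(8)
        Y = rng.multinomial(5000, np.full(20, 0.05), size=3).T
        Y[:, 1] = 0
        spots = CountMatrix(ref.gene_ids, ["s0", "s1", "s2"], Y)
        with pytest.warns(UserWarning, match="skipped"):
            res = spatial.deconvolve_all(spots, ref)
        assert res.skipped[1]
        assert np.isnan(res.weights[1]).all()
        assert np.isfinite(res.weights[0]).all()


class TestDominantType:
    def _result(self, weights):
        w = np.asarray(weights, dtype=float)
        n = w.shape[0]
        return spatial.DeconvResult([f"s{i}" for i in range(n)],
                                    [f"T{k}" for k in range(w.shape[1])],
                                    w, np.zeros(n), np.ones(n, dtype=int),
                                    np.ones(n, dtype=bool), np.zeros(n, dtype=bool))

    def test_exact_tie_flagged(self):
        table = spatial.dominant_type_map(self._result([[0.5, 0.5]]))
        assert bool(table["tie"].iloc[0])

    def test_pure_spot_margin_one(self):
        table = spatial.dominant_type_map(self._result([[1.0, 0.0]]))
        assert table["margin"].iloc[0] == pytest.approx(1.0)
        assert table["dominant_type"].iloc[0] == "T0"


class TestRegionDEG:
    def _spots(self, wound_vals, intact_vals):
        n_w, n_i = len(wound_vals), len(intact_vals)
        ids = [f"w{i}" for i in range(n_w)] + [f"i{j}" for j in range(n_i)]
        values = np.vstack([
            np.concatenate([wound_vals, intact_vals]),
            np.full(n_w + n_i, 50.0),  # constant depth companion gene
        ]).astype(int)
        spots = CountMatrix(["target", "flat"], ids, values)
        table = SpotTable(pd.DataFrame({
            "spot_id": ids,
            "x_um": np.arange(n_w + n_i, dtype=float),
            "y_um": 0.0,
            "in_tissue": True,
            "region": ["wound"] * n_w + ["intact"] * n_i}))
        return spots, table

    def test_exact_p_for_separated_five_vs_five(self):
        spots, table = self._spots([60, 70, 80, 90, 100], [1, 2, 3, 4, 5])
        deg = spatial.region_deg(spots, table, timepoint=7)
        row = deg[deg["gene"] == "target"].iloc[0]
        assert row["p"] == pytest.approx(2.0 / 252.0, rel=1e-12)
        assert row["log2fc"] > 0

    def test_uniform_gene_not_supported(self):
        rng = np.random.default_rng(9)
        vals = rng.poisson(50, size=20)
        spots, table = self._spots(vals[:10], vals[10:])
        deg = spatial.region_deg(spots, table, timepoint=7)
        assert not deg.loc[deg["gene"] == "flat", "supported"].iloc[0]

    def test_missing_region_rejected(self):
        spots, table = self._spots([60] * 5, [1] * 5)
        bad = SpotTable(table.frame.assign(region="wound"))
        with pytest.raises(ValueError, match="intact"):
            spatial.region_deg(spots, bad, timepoint=7)
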