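"""Generator contracts: determinism, simplex invariants, planted effect sizes,
decoy completeness, and the spot-lattice geometry."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from scarscreen import synthdata
from scarscreen.synthdata import ConfigError, SynthConfig
from conftest import small_synth_kwargs


class TestConfigValidation:
    def test_default_config_is_valid(self):
        SynthConfig().validate()

    @pytest.mark.parametrize("overrides", [
        {"nb_dispersion": -0.1},
        {"depth_mean_cells": 0},
        {"cells_per_spot_range": (0, 30)},
        {"cells_per_spot_range": (30, 20)},
        {"wound_radius_um": 5000.0},
        {"marker_log2fc": -1.0},
    ])
    def test_invalid_knobs_rejected(self, overrides):
        with pytest.raises(ConfigError):
            SynthConfig(**overrides).validate()

    def test_off_simplex_proportions_rejected(self):
        cfg = SynthConfig()
        cfg.major_types = dict(cfg.major_types)
        cfg.major_types["F"] = (0.5, 0.30, 0.35)
        with pytest.raises(ConfigError, match="sum"):
            cfg.validate()


class TestSingleCell:
    def test_seed_makes_outputs_byte_identical(self):
        cfg = SynthConfig(seed=5, **small_synth_kwargs())
        a_counts, a_meta, _ = synthdata.generate_single_cell(cfg)
        b_counts, b_meta, _ = synthdata.generate_single_cell(cfg)
        np.testing.assert_array_equal(a_counts.values, b_counts.values)
        pd.testing.assert_frame_equal(a_meta, b_meta)
        assert a_counts.obs_ids == b_counts.obs_ids

    def test_null_effect_config_has_flat_profiles(self):
        cfg = SynthConfig(seed=1, marker_log2fc=0.0, **small_synth_kwargs())
        _, _, truth = synthdata.generate_single_cell(cfg)
        profiles = truth.class_profiles.to_numpy()
        # every class shares the baseline: between-cluster fold-change is 1
        np.testing.assert_allclose(profiles.max(axis=0), profiles.min(axis=0),
                                   rtol=1e-12)

    def test_planted_subcluster_marker_fold_change(self):
        # fold-change fidelity at n >= 500 cells per side
        cfg = SynthConfig(seed=7, n_cells_per_timepoint=6000)
        counts, meta, truth = synthdata.generate_single_cell(cfg)
        gene = "mkF4_00"
        g = counts.gene_index(gene)
        in_f4 = (meta["subcluster"] == "F4").to_numpy()
        assert in_f4.sum() >= 500 and (~in_f4).sum() >= 500
        ratio = counts.values[g, in_f4].mean() / counts.values[g, ~in_f4].mean()
        expected = 2.0 ** cfg.marker_log2fc
        assert abs(ratio - expected) / expected < 0.25

    def test_timepoint_subcluster_frequencies_match_config(self, small_single_cell):
        _, meta, truth = small_single_cell
        cfg = truth.config
        fib = meta[meta["major_type"] == "F"]
        for ti, day in enumerate(cfg.timepoints):
            at_day = fib[fib["timepoint"] == day]
            freqs = at_day["subcluster"].value_counts(normalize=True)
            for sub, props in cfg.fibro_subclusters.items():
                observed = freqs.get(sub, 0.0)
                assert abs(observed - props[ti]) < 0.08  # multinomial error

    def test_truth_marker_sets_and_decoys_disjoint(self, small_single_cell):
        _, _, truth = small_single_cell
        all_decoys = set().union(*truth.decoy_genes.values())
        assert truth.true_scar_genes
        assert not truth.true_scar_genes & all_decoys
        # decoy completeness: one decoy per screen failure mode
        for mode in ("fails_ko_downregulation", "fails_fibroblast_marker",
                     "fails_fibroblast_specificity", "fails_spatial_support"):
            assert truth.decoy_genes[mode], mode

    def test_type_profiles_are_transcript_fractions(self, small_single_cell):
        _, _, truth = small_single_cell
        sums = truth.type_mean_profiles.sum(axis=1).to_numpy()
        np.testing.assert_allclose(sums, 1.0, atol=1e-9)


class TestBulk:
    def test_null_ko_effect_leaves_expectations_identical(self):
        cfg = SynthConfig(seed=3, ko_downregulation_log2fc=0.0, **small_synth_kwargs())
        _, _, truth = synthdata.generate_single_cell(cfg)
        counts, design = synthdata.generate_bulk(cfg, truth)
        V = counts.values / counts.values.sum(axis=0, keepdims=True)
        wt = V[:, (design.frame["genotype"] == "WT").to_numpy()].mean(axis=1)
        ko = V[:, (design.frame["genotype"] == "KO").to_numpy()].mean(axis=1)
        # same expectation for every gene; shifts bounded by NB sampling noise
        lfc = np.log2((ko + 1e-9) / (wt + 1e-9))
        assert np.abs(np.median(lfc)) < 0.05
        noise_sd = np.sqrt(2 * cfg.nb_dispersion / cfg.n_bulk_per_genotype) / np.log(2)
        expressed = counts.values.mean(axis=1) > 50
        assert np.abs(lfc[expressed]).max() < 4 * noise_sd

    def test_ko_scaling_of_flagged_genes(self):
        cfg = SynthConfig(seed=4, n_bulk_per_genotype=8, bulk_depth=1_000_000)
        _, _, truth = synthdata.generate_single_cell(cfg)
        counts, design = synthdata.generate_bulk(cfg, truth)
        wt_mask = (design.frame["genotype"] == "WT").to_numpy()
        expected = 2.0 ** cfg.ko_downregulation_log2fc
        ratios = []
        for gene in sorted(truth.true_scar_genes):
            g = counts.gene_index(gene)
            ratio = (counts.values[g, ~wt_mask].mean()
                     / counts.values[g, wt_mask].mean())
            ratios.append(ratio)
            # per-gene: within a factor of two of the planted scaling
            assert expected / 2 < ratio < expected * 2, gene
        # averaged over genes the NB noise cancels: within 25 %
        mean_ratio = np.exp(np.mean(np.log(ratios)))
        assert abs(mean_ratio - expected) / expected < 0.25

    def test_housekeeping_genes_unshifted(self):
        cfg = SynthConfig(seed=4, n_bulk_per_genotype=8, bulk_depth=1_000_000)
        _, _, truth = synthdata.generate_single_cell(cfg)
        counts, design = synthdata.generate_bulk(cfg, truth)
        wt_mask = (design.frame["genotype"] == "WT").to_numpy()
        flagged = truth.ko_genes
        hk = [g for g in counts.gene_ids if g.startswith("G")][:50]
        assert not set(hk) & flagged
        lfc = []
        for gene in hk:
            g = counts.gene_index(gene)
            lfc.append(np.log2(counts.values[g, ~wt_mask].mean()
                               / counts.values[g, wt_mask].mean()))
        assert np.abs(np.median(lfc)) < 0.1
        # NB sampling-error bound on a single gene's log-ratio of means
        noise_sd = np.sqrt(2 * cfg.nb_dispersion / cfg.n_bulk_per_genotype) / np.log(2)
        assert np.abs(lfc).max() < 4 * noise_sd

    def test_mismatched_truth_rejected(self, small_single_cell):
        _, _, truth = small_single_cell
        other = SynthConfig(seed=1)  # different gene universe size
        with pytest.raises(ConfigError, match="gene universe"):
            synthdata.generate_bulk(other, truth)


class TestVisium:
    def test_wound_spot_count_matches_geometric_enumeration(self):
        cfg = SynthConfig(seed=2, **small_synth_kwargs())
        _, _, truth = synthdata.generate_single_cell(cfg)
        _, table = synthdata.generate_visium(cfg, truth, timepoint=7)
        # independent enumeration of lattice points within the wound disk
        rows, cols = cfg.grid_shape
        xs = np.arange(cols) * cfg.spot_spacing_um
        ys = np.arange(rows) * cfg.spot_spacing_um
        cx, cy = xs.mean(), ys.mean()
        n_expected = sum(
            1 for x in xs for y in ys
            if np.hypot(x - cx, y - cy) <= cfg.wound_radius_um)
        assert (table.regions() == "wound").sum() == n_expected
        assert n_expected == synthdata.expected_wound_spot_count(cfg)

    def test_pure_composition_gives_unit_weight(self):
        kwargs = small_synth_kwargs()
        kwargs["region_composition"] = {
            r: {t: (1.0 if t == "EC" else 0.0) for t in synthdata.MAJOR_TYPES}
            for r in ("wound", "intact", "muscle")}
        cfg = SynthConfig(seed=6, **kwargs)
        _, _, truth = synthdata.generate_single_cell(cfg)
        synthdata.generate_visium(cfg, truth, timepoint=7)
        W = truth.spot_weights[7]
        np.testing.assert_allclose(W["EC"].to_numpy(), 1.0, atol=1e-12)

    def test_spot_weight_rows_on_simplex(self, small_single_cell):
        _, _, truth = small_single_cell
        synthdata.generate_visium(truth.config, truth, timepoint=7)
        sums = truth.spot_weights[7].sum(axis=1).to_numpy()
        np.testing.assert_allclose(sums, 1.0, atol=1e-9)

    def test_margin_to_center_gradients(self, small_single_cell):
        counts, _, truth = small_single_cell
        cfg = truth.config
        vis, table = synthdata.generate_visium(cfg, truth, timepoint=7)
        coords = table.coords()
        center = coords.mean(axis=0)
        r = np.hypot(*(coords - center).T)
        margin = (r >= 0.6 * cfg.wound_radius_um) & (r <= cfg.wound_radius_um)
        core = r < 0.4 * cfg.wound_radius_um
        lig = vis.values[vis.gene_index("Tgfb1")]
        rec = vis.values[vis.gene_index("Tgfbr1")]
        assert lig[margin].mean() > lig[core].mean()
        assert rec[core].mean() > rec[margin].mean()

    def test_planted_direction_unit_norm_inward(self, small_single_cell):
        _, _, truth = small_single_cell
        synthdata.generate_visium(truth.config, truth, timepoint=7)
        D = truth.planted_direction[7]
        valid = truth.direction_valid[7]
        norms = np.hypot(D[valid, 0], D[valid, 1])
        np.testing.assert_allclose(norms, 1.0, atol=1e-9)

    def test_oversized_wound_rejected(self):
        with pytest.raises(ConfigError, match="wound_radius"):
            SynthConfig(grid_shape=(10, 10), wound_radius_um=2000.0).validate()

    def test_visium_deterministic(self, small_single_cell):
        _, _, truth = small_single_cell
        a, _ = synthdata.generate_visium(truth.config, truth, timepoint=14)
        b, _ = synthdata.generate_visium(truth.config, truth, timepoint=14)
        np.testing.assert_array_equal(a.values, b.values)
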