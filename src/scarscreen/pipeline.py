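"""End-to-end orchestration: simulate -> cluster -> markers -> bulk DE ->
region DEGs -> deconvolve -> communicate -> screen.

The pipeline is a pure function of its configuration: every stochastic
stage takes an explicit seed derived from the top-level one, so a rerun
with the same config reproduces identical artifacts.  Stage outputs are
plain TSV/JSON files; the log records counts in/out and every threshold
used, keeping the screen arithmetic auditable.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, field_validator

from . import bulkde, commnet, scrna, screen, spatial, synthdata
from .io import (CountMatrix, LRDatabase, NormMatrix, write_mtx,
                 write_spot_positions)


class QCParams(BaseModel):
    model_config = ConfigDict(extra="forbid")
    min_genes: int = Field(50, ge=0)
    min_counts: int = Field(200, ge=0)
    max_counts_quantile: float = Field(1.0, gt=0, le=1)
    min_cells_per_gene: int = Field(3, ge=0)


class ClusterParams(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_pcs: int = 8
    k_neighbors: int = 15
    resolution: float = Field(0.3, gt=0)


class SubclusterParams(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_pcs: int = 10
    k_neighbors: int = 15
    resolution: float = Field(1.0, gt=0)


class MarkerParams(BaseModel):
    model_config = ConfigDict(extra="forbid")
    q_max: float = Field(0.05, gt=0, lt=1)
    lfc_min: float = Field(0.585, ge=0)
    pct_min: float = Field(0.25, ge=0, le=1)


class BulkParams(BaseModel):
    model_config = ConfigDict(extra="forbid")
    q_max: float = Field(0.05, gt=0, lt=1)
    lfc_max: float = Field(-1.0, lt=0)


class RegionParams(BaseModel):
    model_config = ConfigDict(extra="forbid")
    q_max: float = Field(0.05, gt=0, lt=1)


class DeconvParams(BaseModel):
    model_config = ConfigDict(extra="forbid")
    top_n_markers: int = Field(50, ge=1)
    max_iter: int = Field(500, ge=1)
    tol: float = Field(1e-6, gt=0)


class CommParams(BaseModel):
    model_config = ConfigDict(extra="forbid")
    hill_k: float = Field(0.5, gt=0)
    n_perm: int = Field(100, ge=20)
    ot_epsilon_factor: float = Field(0.05, gt=0)
    ot_cutoff_um: float = Field(500.0, gt=0)


class ScreenParams(BaseModel):
    model_config = ConfigDict(extra="forbid")
    tau: float = Field(0.7, ge=0, le=1)
    anchor_gene: str = "Col1a1"


class PipelineConfig(BaseModel):
    """Schema-versioned configuration for all stages; unknown keys rejected."""

    model_config = ConfigDict(extra="forbid")
    schema_version: int = 1
    seed: int = 0
    synth: dict = Field(default_factory=dict)
    qc: QCParams = Field(default_factory=QCParams)
    cluster: ClusterParams = Field(default_factory=ClusterParams)
    subcluster: SubclusterParams = Field(default_factory=SubclusterParams)
    markers: MarkerParams = Field(default_factory=MarkerParams)
    bulk: BulkParams = Field(default_factory=BulkParams)
    region: RegionParams = Field(default_factory=RegionParams)
    deconv: DeconvParams = Field(default_factory=DeconvParams)
    comm: CommParams = Field(default_factory=CommParams)
    screen: ScreenParams = Field(default_factory=ScreenParams)

    @field_validator("synth")
    @classmethod
    def _known_synth_keys(cls, v: dict) -> dict:
        allowed = {f.name for f in dataclasses.fields(synthdata.SynthConfig)}
        unknown = set(v) - allowed
        if unknown:
            raise ValueError(f"unknown synth keys {sorted(unknown)}")
        return v

    def synth_config(self) -> synthdata.SynthConfig:
        kwargs = dict(self.synth)
        kwargs.setdefault("seed", self.seed)
        return synthdata.SynthConfig(**kwargs)


@dataclasses.dataclass
class PipelineResult:
    """In-memory results of every stage plus the final screen report."""

    config: PipelineConfig
    truth: synthdata.SynthTruth
    counts: CountMatrix
    meta: pd.DataFrame
    norm: NormMatrix
    major_labels: np.ndarray            # per-cell recovered cluster ids
    annotation: dict                    # cluster id -> {"type", "tie"}
    major_types: np.ndarray             # per-cell annotated type names
    sub_labels: pd.Series               # fibroblast cells -> recovered F subcluster
    macro_sub_labels: pd.Series         # macrophage cells -> recovered M subcluster
    marker_table: pd.DataFrame          # major-level markers
    fibro_marker_table: pd.DataFrame    # within-fibroblast subcluster markers
    proportions: pd.DataFrame
    bulk_counts: CountMatrix
    bulk_design: synthdata.BulkDesign
    de_table: pd.DataFrame
    candidates: set
    visium: dict                        # day -> (CountMatrix, SpotTable)
    region_degs: dict                   # day -> DataFrame
    specificity: dict                   # gene -> score
    report: screen.ScreenReport
    log: list


def run_screen_stages(config: PipelineConfig) -> PipelineResult:
    """Run every stage needed by the intersection screen (no deconvolution
    or communication scoring; those are separate artifacts)."""
    log: list[str] = []
    scfg = config.synth_config()
    scfg.validate()

    counts, meta, truth = synthdata.generate_single_cell(scfg)
    log.append(f"simulate: {counts.n_genes} genes x {counts.n_obs} cells, seed={scfg.seed}")

    qc = config.qc
    counts = scrna.qc_filter(counts, min_genes=qc.min_genes, min_counts=qc.min_counts,
                             max_counts_quantile=qc.max_counts_quantile,
                             min_cells_per_gene=qc.min_cells_per_gene,
                             log=log.append)
    meta = meta[meta["cell_id"].isin(set(counts.obs_ids))].reset_index(drop=True)

    norm = scrna.normalize_log_cpm(counts)
    cl = config.cluster
    major_labels = scrna.cluster_cells(norm, n_pcs=cl.n_pcs, k_neighbors=cl.k_neighbors,
                                       resolution=cl.resolution, seed=config.seed)
    annotation = scrna.annotate_clusters(norm, major_labels, synthdata.NAMED_MAJOR_MARKERS)
    major_types = np.array([annotation[l]["type"] for l in major_labels])
    log.append(f"cluster: {major_labels.max() + 1} clusters -> "
               f"{sorted({v['type'] for v in annotation.values()})}")

    sub = config.subcluster
    fibro_clusters = [c for c, v in annotation.items() if v["type"] == "F"]
    if not fibro_clusters:
        raise RuntimeError("no cluster annotated as fibroblast")
    fibro_cluster = fibro_clusters[0]
    sub_labels = scrna.subcluster(norm, major_labels, fibro_cluster, prefix="F",
                                  n_pcs=sub.n_pcs, k_neighbors=sub.k_neighbors,
                                  resolution=sub.resolution, seed=config.seed)
    macro_clusters = [c for c, v in annotation.items() if v["type"] == "M"]
    macro_sub_labels = pd.Series(dtype=object)
    if macro_clusters:
        macro_sub_labels = scrna.subcluster(norm, major_labels, macro_clusters[0],
                                            prefix="M", n_pcs=sub.n_pcs,
                                            k_neighbors=sub.k_neighbors,
                                            resolution=sub.resolution, seed=config.seed)
    log.append(f"subcluster: F -> {sub_labels.nunique()}, M -> {macro_sub_labels.nunique()}")

    mk = config.markers
    marker_table = scrna.find_markers(norm, major_labels, q_max=mk.q_max,
                                      lfc_min=mk.lfc_min, pct_min=mk.pct_min)
    fibro_norm = norm.subset_obs(list(sub_labels.index))
    fibro_marker_table = scrna.find_markers(fibro_norm, sub_labels.to_numpy(),
                                            q_max=mk.q_max, lfc_min=mk.lfc_min,
                                            pct_min=mk.pct_min)
    log.append(f"markers: {int(marker_table['is_marker'].sum())} major, "
               f"{int(fibro_marker_table['is_marker'].sum())} fibro-subcluster calls")

    meta_idx = meta.set_index("cell_id")
    proportions = scrna.temporal_proportions(
        meta_idx.loc[sub_labels.index, "timepoint"], sub_labels)

    bulk_counts, bulk_design = synthdata.generate_bulk(scfg, truth)
    de_table, candidates = bulkde.run_bulk_de(bulk_counts, bulk_design,
                                              q_max=config.bulk.q_max,
                                              lfc_max=config.bulk.lfc_max)
    log.append(f"bulk DE: {len(candidates)} candidate inflammation-dependent genes "
               f"(q<{config.bulk.q_max}, lfc<={config.bulk.lfc_max})")

    visium, region_degs = {}, {}
    for day in scfg.timepoints:
        vis_counts, vis_table = synthdata.generate_visium(scfg, truth, timepoint=day)
        visium[day] = (vis_counts, vis_table)
        region_degs[day] = spatial.region_deg(vis_counts, vis_table, timepoint=day,
                                              q_max=config.region.q_max)
        log.append(f"region DEG day {day}: "
                   f"{int(region_degs[day]['supported'].sum())} wound-upregulated genes")

    _, union = screen.intersect_candidates(candidates, fibro_marker_table,
                                           sorted(sub_labels.unique()))
    specificity = {g: scrna.fibroblast_specificity(norm, major_types, g)
                   for g in union}
    report = screen.build_report(
        candidates, fibro_marker_table, sorted(sub_labels.unique()),
        specificity, region_degs, norm, sub_labels,
        anchor_gene=config.screen.anchor_gene, tau=config.screen.tau,
        thresholds={
            "bulk_q_max": config.bulk.q_max, "bulk_lfc_max": config.bulk.lfc_max,
            "marker_q_max": mk.q_max, "marker_lfc_min": mk.lfc_min,
            "marker_pct_min": mk.pct_min, "region_q_max": config.region.q_max,
            "seed": config.seed,
        })
    log.append(f"screen: stage counts {report.stage_counts()}")
    return PipelineResult(
        config=config, truth=truth, counts=counts, meta=meta, norm=norm,
        major_labels=major_labels, annotation=annotation, major_types=major_types,
        sub_labels=sub_labels, macro_sub_labels=macro_sub_labels,
        marker_table=marker_table, fibro_marker_table=fibro_marker_table,
        proportions=proportions, bulk_counts=bulk_counts, bulk_design=bulk_design,
        de_table=de_table, candidates=candidates, visium=visium,
        region_degs=region_degs, specificity=specificity, report=report, log=log)


def communication_labels(result: PipelineResult) -> pd.Series:
    """Per-cell labels for communication scoring: recovered subcluster for
    fibroblasts/macrophages, annotated major type otherwise."""
    labels = pd.Series(result.major_types, index=result.counts.obs_ids, dtype=object)
    labels.loc[result.sub_labels.index] = result.sub_labels
    if len(result.macro_sub_labels):
        labels.loc[result.macro_sub_labels.index] = result.macro_sub_labels
    return labels


def run_pipeline(config: PipelineConfig, outdir: str | Path,
                 lr_frame: pd.DataFrame | None = None,
                 write_inputs: bool = False) -> PipelineResult:
    """Full pipeline with artifacts on disk (adds deconvolution and
    communication to :func:`run_screen_stages`)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    result = run_screen_stages(config)
    log = result.log
    scfg = result.truth.config

    # deconvolution of the (first) timepoint grid against the scRNA reference
    reference = spatial.build_reference(result.counts, result.major_types)
    panel = spatial.select_deconvolution_genes(result.marker_table, reference,
                                               top_n=config.deconv.top_n_markers)
    day0 = scfg.timepoints[min(1, len(scfg.timepoints) - 1)]
    vis_counts, vis_table = result.visium[day0]
    deconv = spatial.deconvolve_all(vis_counts, reference, genes=panel,
                                    max_iter=config.deconv.max_iter,
                                    tol=config.deconv.tol)
    dominant = spatial.dominant_type_map(deconv)
    log.append(f"deconvolve day {day0}: {int((~deconv.skipped).sum())} spots, "
               f"{len(panel)} marker genes")

    # communication scoring on subcluster-resolved labels
    if lr_frame is None:
        lr_frame = synthdata.default_lr_frame()
    lrdb = LRDatabase(lr_frame.assign(missing_in_matrix=False))
    comm_cfg = commnet.CommConfig(hill_k=config.comm.hill_k, n_perm=config.comm.n_perm,
                                  seed=config.seed,
                                  ot_epsilon_factor=config.comm.ot_epsilon_factor,
                                  ot_cutoff_um=config.comm.ot_cutoff_um)
    comm = commnet.permutation_pvalues(result.norm, communication_labels(result),
                                       lrdb, comm_cfg)
    pathway = commnet.aggregate_pathway(comm)
    log.append(f"communication: {len(comm)} triples over {lrdb.n_pairs} pairs")

    # direction field for each planted pair on its wound grid
    fields = []
    vis_norm = scrna.normalize_log_cpm(vis_counts)
    for ligand, receptor, *_ in scfg.lr_pairs_planted:
        if ligand in vis_norm.gene_ids and receptor in vis_norm.gene_ids:
            fields.append(commnet.signaling_direction(
                vis_norm, vis_table, ligand, receptor, comm_cfg,
                pathway=f"{ligand}->{receptor}"))

    # ----- artifacts
    labels_tsv = pd.DataFrame({
        "cell_id": result.counts.obs_ids,
        "cluster": result.major_labels,
        "major": result.major_types,
    }).set_index("cell_id")
    labels_tsv["sub"] = result.sub_labels.reindex(labels_tsv.index)
    labels_tsv["sub"] = labels_tsv["sub"].fillna(
        result.macro_sub_labels.reindex(labels_tsv.index))
    labels_tsv.to_csv(outdir / "labels.tsv", sep="\t")
    result.marker_table.to_csv(outdir / "markers_major.tsv", sep="\t", index=False)
    result.fibro_marker_table.to_csv(outdir / "markers_fibro_sub.tsv", sep="\t", index=False)
    result.proportions.to_csv(outdir / "subcluster_proportions.tsv", sep="\t")
    result.de_table.to_csv(outdir / "bulk_de.tsv", sep="\t", index=False)
    (outdir / "candidates.txt").write_text("\n".join(sorted(result.candidates)) + "\n")
    for day, table in result.region_degs.items():
        table.to_csv(outdir / f"region_deg_day{day}.tsv", sep="\t", index=False)
    deconv.frame().to_csv(outdir / f"deconv_weights_day{day0}.tsv", sep="\t")
    dominant.to_csv(outdir / f"dominant_type_day{day0}.tsv", sep="\t", index=False)
    comm.to_csv(outdir / "communication.tsv", sep="\t", index=False)
    pathway.to_csv(outdir / "pathway_scores.tsv", sep="\t", index=False)
    for f in fields:
        f.frame().to_csv(outdir / f"direction_{f.pathway.replace('->', '_to_')}.tsv",
                         sep="\t", index=False)
    (outdir / "report.json").write_text(result.report.to_json() + "\n")
    if write_inputs:
        write_mtx(result.counts, outdir / "sc_counts")
        write_mtx(result.bulk_counts, outdir / "bulk_counts")
        for day, (vc, vt) in result.visium.items():
            write_mtx(vc, outdir / f"visium_day{day}")
            write_spot_positions(vt, outdir / f"tissue_positions_day{day}.csv")
    (outdir / "pipeline_log.json").write_text(json.dumps(log, indent=2) + "\n")
    return result
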