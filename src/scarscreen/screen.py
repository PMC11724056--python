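"""Cross-modality intersection screen for inflammation-related scarring genes.

The screen formalizes the multiomics triangulation as a chain of
filters with an explicit per-gene evidence trail:

1. candidates      — genes significantly DOWN in inflammation-deficient
                     bulk wounds (inflammation-dependent);
2. subcluster hits — candidates that are markers of >= 1 fibroblast
                     subcluster in the single-cell data;
3. fibro-specific  — hits whose expression is concentrated in the
                     fibroblast compartment (specificity >= tau);
4. spatially supported — survivors upregulated in annotated wound
                     regions at >= 1 timepoint;
5. final ranking   — survivors ordered by Pearson correlation of their
                     fibroblast-subcluster expression profile with the
                     collagen anchor gene (Col1a1), the scar-proximal
                     readout; highest correlation first.

Every stage output is nested inside the previous one, and the report
records thresholds and per-stage counts so the arithmetic is auditable.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import NormMatrix


def intersect_candidates(candidates: set, marker_table: pd.DataFrame,
                         subcluster_family) -> tuple[dict, dict]:
    """Stage 2: candidate genes that mark fibroblast subclusters.

    Returns ``(subcluster_hits, union_membership)`` where
    ``subcluster_hits[f]`` is the candidate/marker intersection for
    subcluster ``f`` and ``union_membership`` maps each union gene to
    the sorted list of subclusters it marks.
    """
    family = list(subcluster_family)
    if not candidates:
        warnings.warn("empty candidate set; screen stages will be empty")
    hits = {}
    for f in family:
        mk = set(marker_table.loc[(marker_table["cluster"] == f)
                                  & marker_table["is_marker"], "gene"])
        hits[f] = mk & set(candidates)
    union: dict[str, list] = {}
    for f in family:
        for g in hits[f]:
            union.setdefault(g, []).append(f)
    union = {g: sorted(fs) for g, fs in union.items()}
    return hits, union


def specificity_filter(union_membership: dict, specificity_scores: dict,
                       tau: float = 0.7) -> set:
    """Stage 3: keep genes whose fibroblast specificity reaches ``tau``."""
    missing = set(union_membership) - set(specificity_scores)
    if missing:
        raise KeyError(f"no specificity score for genes {sorted(missing)}")
    return {g for g in union_membership if specificity_scores[g] >= tau}


def spatial_support_filter(fibro_specific: set,
                           region_degs: dict) -> tuple[set, dict]:
    """Stage 4: keep genes wound-upregulated at >= 1 timepoint.

    ``region_degs`` maps timepoint -> region DEG table (with the
    ``supported`` column).  Returns the surviving set and per-timepoint
    membership mapping timepoint -> genes supported there.
    """
    if not region_degs:
        raise ValueError("need region DEG tables for >= 1 timepoint")
    membership = {}
    for day, table in region_degs.items():
        sup = set(table.loc[table["supported"], "gene"])
        membership[day] = fibro_specific & sup
    kept = set().union(*membership.values()) if membership else set()
    return kept, membership


def prioritize(survivors: set, norm: NormMatrix, sub_labels: pd.Series,
               anchor_gene: str = "Col1a1") -> pd.DataFrame:
    """Stage 5: rank survivors by anchor-correlated subcluster profile.

    The profile of a gene is its mean normalized expression across the
    fibroblast subclusters; ``anchor_correlation`` is the Pearson
    correlation with the anchor gene's profile.  Constant profiles have
    undefined correlation: flagged and ranked last.  Ties break
    lexicographically.
    """
    if anchor_gene not in norm.gene_ids:
        raise KeyError(f"anchor gene {anchor_gene!r} absent")
    subclusters = sorted(pd.unique(sub_labels))
    if len(subclusters) < 2:
        raise ValueError("need >= 2 fibroblast subclusters to build profiles")
    cells = list(sub_labels.index)
    sub_norm = norm.subset_obs(cells)
    labels = sub_labels.to_numpy()

    def profile(gene: str) -> np.ndarray:
        row = sub_norm.values[sub_norm.gene_index(gene)]
        return np.array([row[labels == s].mean() for s in subclusters])

    anchor = profile(anchor_gene)
    rows = []
    for gene in sorted(survivors):
        prof = profile(gene)
        if np.std(prof) < 1e-12 or np.std(anchor) < 1e-12:
            rows.append((gene, np.nan, True))
        else:
            rows.append((gene, float(np.corrcoef(prof, anchor)[0, 1]), False))
    table = pd.DataFrame(rows, columns=["gene", "anchor_correlation", "undefined"])
    table = table.sort_values(
        by=["undefined", "anchor_correlation", "gene"],
        ascending=[True, False, True], na_position="last").reset_index(drop=True)
    table["rank"] = np.arange(1, len(table) + 1)
    return table


@dataclass
class ScreenReport:
    """Staged gene sets of the screen with the thresholds that produced them."""

    candidate_set: set
    subcluster_hits: dict
    union_membership: dict
    fibro_specific: set
    spatial_supported: dict          # timepoint -> genes
    final_table: pd.DataFrame        # gene, anchor_correlation, rank, ...
    thresholds: dict = field(default_factory=dict)

    @property
    def final_genes(self) -> list:
        return list(self.final_table["gene"])

    def assert_nesting(self) -> None:
        union = set(self.union_membership)
        final = set(self.final_genes)
        spatial = set().union(*self.spatial_supported.values()) if self.spatial_supported else set()
        if not (final <= spatial <= self.fibro_specific <= union <= self.candidate_set):
            raise AssertionError("screen stage nesting violated")

    def stage_counts(self) -> dict:
        return {
            "candidates": len(self.candidate_set),
            "subcluster_union": len(self.union_membership),
            "fibro_specific": len(self.fibro_specific),
            "spatial_supported": len(set().union(*self.spatial_supported.values())
                                     if self.spatial_supported else set()),
            "final": len(self.final_genes),
        }

    def to_json(self) -> str:
        payload = {
            "thresholds": self.thresholds,
            "stage_counts": self.stage_counts(),
            "candidate_set": sorted(self.candidate_set),
            "subcluster_hits": {f: sorted(g) for f, g in sorted(self.subcluster_hits.items())},
            "union_membership": {g: list(m) for g, m in sorted(self.union_membership.items())},
            "fibro_specific": sorted(self.fibro_specific),
            "spatial_supported": {str(d): sorted(g)
                                  for d, g in sorted(self.spatial_supported.items())},
            "final_ranked": [
                {"gene": r.gene,
                 "anchor_correlation": None if pd.isna(r.anchor_correlation)
                 else round(float(r.anchor_correlation), 6),
                 "rank": int(r.rank),
                 "subclusters": self.union_membership.get(r.gene, []),
                 "spatial_timepoints": sorted(
                     str(d) for d, g in self.spatial_supported.items() if r.gene in g)}
                for r in self.final_table.itertuples()
            ],
        }
        return json.dumps(payload, indent=2, sort_keys=True)


def build_report(candidates: set, marker_table: pd.DataFrame, subcluster_family,
                 specificity_scores: dict, region_degs: dict,
                 norm: NormMatrix, sub_labels: pd.Series,
                 anchor_gene: str = "Col1a1", tau: float = 0.7,
                 thresholds: dict | None = None) -> ScreenReport:
    """Run stages 2-5 and assemble the audited report."""
    hits, union = intersect_candidates(candidates, marker_table, subcluster_family)
    specific = specificity_filter(union, specificity_scores, tau=tau)
    supported, membership = spatial_support_filter(specific, region_degs)
    final = prioritize(supported, norm, sub_labels, anchor_gene=anchor_gene)
    report = ScreenReport(
        candidate_set=set(candidates),
        subcluster_hits=hits,
        union_membership=union,
        fibro_specific=specific,
        spatial_supported=membership,
        final_table=final,
        thresholds=dict(thresholds or {}, tau=tau, anchor_gene=anchor_gene),
    )
    report.assert_nesting()
    return report
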