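"""Spatial stage: reference-based spot deconvolution and region DEGs.

Deconvolution models a spot's counts as a multinomial draw from a
convex mixture of cell-type reference profiles and maximizes the
likelihood over the probability simplex with EM — the transparent core
of reference-based decomposition of 55 um Visium spots pooling ~20-30
cells.  Region-level differential expression compares manually
annotated wound versus intact spots by Wilcoxon rank-sum on log-CPM
values, BH-corrected within each timepoint's family.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import CountMatrix, FormatError, NormMatrix, SpotTable
from .scrna import benjamini_hochberg, normalize_log_cpm, rank_sum_test


@dataclass
class Reference:
    """Cell-type x gene expected transcript-fraction profiles (rows sum to 1)."""

    type_ids: list[str]
    gene_ids: list[str]
    profiles: np.ndarray

    def __post_init__(self) -> None:
        self.profiles = np.asarray(self.profiles, dtype=float)
        if self.profiles.shape != (len(self.type_ids), len(self.gene_ids)):
            raise FormatError("reference dimensions inconsistent")
        if np.any(self.profiles < 0):
            raise FormatError("negative reference profile entry")
        sums = self.profiles.sum(axis=1)
        if np.any(np.abs(sums - 1.0) > 1e-9):
            raise FormatError("reference rows must sum to 1")

    def subset_genes(self, genes) -> "Reference":
        idx = [self.gene_ids.index(g) for g in genes]
        prof = self.profiles[:, idx]
        prof = prof / prof.sum(axis=1, keepdims=True)
        return Reference(self.type_ids, list(genes), prof)


def build_reference(counts: CountMatrix, major_labels, min_cells: int = 10) -> Reference:
    """Mean raw count per gene per annotated type, normalized to sum 1.

    Genes with zero total across all types are dropped from the
    reference's gene universe.
    """
    major_labels = np.asarray(major_labels)
    types = sorted(pd.unique(major_labels))
    profiles = []
    for t in types:
        mask = major_labels == t
        if mask.sum() < min_cells:
            raise ValueError(f"type {t!r} has {int(mask.sum())} cells; need >= {min_cells}")
        profiles.append(counts.values[:, mask].mean(axis=1))
    profiles = np.asarray(profiles, dtype=float)
    keep = profiles.sum(axis=0) > 0
    profiles = profiles[:, keep]
    profiles = profiles / profiles.sum(axis=1, keepdims=True)
    genes = [g for g, k in zip(counts.gene_ids, keep) if k]
    return Reference(types, genes, profiles)


def select_deconvolution_genes(marker_table: pd.DataFrame, reference: Reference,
                               top_n: int = 50) -> list[str]:
    """Union of each type's top-``top_n`` markers (by log2fc among significant),
    restricted to the reference gene universe — concentrates mixture signal."""
    genes: set = set()
    for _, grp in marker_table[marker_table["is_marker"]].groupby("cluster"):
        genes |= set(grp.nlargest(top_n, "log2fc")["gene"])
    ordered = [g for g in reference.gene_ids if g in genes]
    return ordered if ordered else list(reference.gene_ids)


def deconvolve_spot(y: np.ndarray, reference: Reference, max_iter: int = 500,
                    tol: float = 1e-6, keep_trace: bool = False):
    """Maximum-likelihood mixture weights for one spot via EM.

    Maximizes ``sum_g y_g log(sum_k w_k R_kg)`` over the simplex from a
    uniform start; the multiplicative EM update is
    ``w_k <- w_k * sum_g (y_g / p_g) R_kg / N``.  Returns a dict with
    weights, per-iteration log-likelihood trace (optional), iteration
    count and convergence flag.
    """
    y = np.asarray(y, dtype=float)
    R = reference.profiles
    K = R.shape[0]
    N = y.sum()
    if N <= 0:
        return {"weights": np.full(K, np.nan), "loglik": np.nan,
                "n_iter": 0, "converged": False, "skipped": True, "trace": []}
    w = np.full(K, 1.0 / K)
    trace = []
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        p = w @ R
        if keep_trace:
            trace.append(_mixture_loglik(y, p))
        w_new = w * ((y / np.maximum(p, 1e-300)) @ R.T) / N
        w_new = np.maximum(w_new, 0.0)
        w_new /= w_new.sum()
        delta = np.max(np.abs(w_new - w))
        w = w_new
        if delta < tol:
            converged = True
            break
    loglik = _mixture_loglik(y, w @ R)
    if keep_trace:
        trace.append(loglik)
    return {"weights": w, "loglik": loglik, "n_iter": n_iter,
            "converged": converged, "skipped": False, "trace": trace}


def _mixture_loglik(y: np.ndarray, p: np.ndarray) -> float:
    mask = y > 0
    return float(np.sum(y[mask] * np.log(np.maximum(p[mask], 1e-300))))


@dataclass
class DeconvResult:
    """Per-spot mixture weights on the simplex plus fit diagnostics."""

    spot_ids: list[str]
    type_ids: list[str]
    weights: np.ndarray          # spot x type; NaN rows for skipped spots
    loglik: np.ndarray
    n_iter: np.ndarray
    converged: np.ndarray
    skipped: np.ndarray

    def frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.weights, index=self.spot_ids, columns=self.type_ids)
        df.index.name = "spot_id"
        return df


def deconvolve_all(spots: CountMatrix, reference: Reference, genes=None,
                   max_iter: int = 500, tol: float = 1e-6) -> DeconvResult:
    """Deconvolve every spot against the reference.

    ``genes`` optionally restricts the fit to a marker panel (profiles
    are renormalized over the panel). Zero-count spots are skipped and
    flagged rather than failing the run.
    """
    if genes is not None:
        reference = reference.subset_genes(genes)
    shared = [g for g in reference.gene_ids if g in set(spots.gene_ids)]
    if not shared:
        raise ValueError("no genes shared between spots and reference")
    if shared != reference.gene_ids:
        reference = reference.subset_genes(shared)
    Y = spots.subset_genes(shared).values.T.astype(float)  # spot x gene

    K = len(reference.type_ids)
    n = Y.shape[0]
    weights = np.full((n, K), np.nan)
    loglik = np.full(n, np.nan)
    n_iter = np.zeros(n, dtype=int)
    converged = np.zeros(n, dtype=bool)
    skipped = np.zeros(n, dtype=bool)
    for s in range(n):
        res = deconvolve_spot(Y[s], reference, max_iter=max_iter, tol=tol)
        skipped[s] = res["skipped"]
        if not res["skipped"]:
            weights[s] = res["weights"]
            loglik[s] = res["loglik"]
            n_iter[s] = res["n_iter"]
            converged[s] = res["converged"]
    if skipped.any():
        warnings.warn(f"{int(skipped.sum())} zero-count spot(s) skipped")
    return DeconvResult(list(spots.obs_ids), list(reference.type_ids),
                        weights, loglik, n_iter, converged, skipped)


def dominant_type_map(deconv: DeconvResult, tie_tol: float = 1e-9) -> pd.DataFrame:
    """Per-spot argmax type plus the top1-minus-top2 margin; exact ties flagged."""
    rows = []
    for s, spot in enumerate(deconv.spot_ids):
        w = deconv.weights[s]
        if deconv.skipped[s] or not np.all(np.isfinite(w)):
            rows.append((spot, None, np.nan, False))
            continue
        order = np.argsort(w)[::-1]
        top1, top2 = w[order[0]], (w[order[1]] if len(w) > 1 else 0.0)
        tie = abs(top1 - top2) <= tie_tol
        rows.append((spot, deconv.type_ids[order[0]], top1 - top2, tie))
    return pd.DataFrame(rows, columns=["spot_id", "dominant_type", "margin", "tie"])


def region_deg(spots: CountMatrix, spot_table: SpotTable, timepoint,
               q_max: float = 0.05, min_spots: int = 5) -> pd.DataFrame:
    """Wound-vs-intact differential expression per gene at one timepoint.

    Wilcoxon rank-sum on log-CPM spot values; BH within this timepoint's
    family.  ``supported`` marks genes up in wound (q < q_max, lfc > 0).
    """
    regions = spot_table.regions()
    if list(spot_table.spot_ids) != list(spots.obs_ids):
        raise ValueError("spot table and matrix must cover the same spots in order")
    wound = regions == "wound"
    intact = regions == "intact"
    for name, mask in (("wound", wound), ("intact", intact)):
        if mask.sum() < min_spots:
            raise ValueError(f"region {name!r} has {int(mask.sum())} spots; need >= {min_spots}")
    norm = normalize_log_cpm(spots)
    Vw, Vi = norm.values[:, wound], norm.values[:, intact]
    mean_w, mean_i = Vw.mean(axis=1), Vi.mean(axis=1)
    lfc = np.log2(mean_w + 1e-9) - np.log2(mean_i + 1e-9)
    if Vw.shape[1] + Vi.shape[1] <= 16:
        p = np.array([rank_sum_test(Vw[g], Vi[g]) for g in range(norm.n_genes)])
    else:
        res = stats.mannwhitneyu(Vw, Vi, axis=1, alternative="two-sided",
                                 method="asymptotic")
        p = np.asarray(res.pvalue, dtype=float)
    q = benjamini_hochberg(p)
    return pd.DataFrame({
        "gene": norm.gene_ids, "timepoint": timepoint,
        "log2fc": lfc, "p": p, "q": q,
        "direction": np.where(lfc > 0, "up_in_wound", "down_in_wound"),
        "supported": (q < q_max) & (lfc > 0),
    })
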