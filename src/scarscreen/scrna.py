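"""Single-cell stage: QC, normalization, clustering, markers, annotation.

The clustering follows the standard scRNA-seq recipe — per-gene
standardization, PCA, a k-nearest-neighbor graph in PC space, and
seeded Louvain community detection — with the number of PCs acting as
the usual coarseness control: a small `n_pcs` captures the dominant
between-type axes for the top-level partition, while subclustering
re-runs the same recipe restricted to one cluster's cells, where the
within-type axes dominate the restricted PCA.
"""

from __future__ import annotations

import math
import warnings
from itertools import combinations

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

from .io import CountMatrix, NormMatrix


# ---------------------------------------------------------------------------
# QC and normalization


def qc_filter(counts: CountMatrix, min_genes: int = 200, min_counts: int = 500,
              max_counts_quantile: float = 1.0, min_cells_per_gene: int = 3,
              log=None) -> CountMatrix:
    """Remove low-quality cells and rarely detected genes.

    Cells need at least ``min_genes`` detected genes and ``min_counts``
    total counts, and must not exceed the ``max_counts_quantile`` depth
    quantile (doublet-like outliers). Genes detected in fewer than
    ``min_cells_per_gene`` surviving cells are dropped.
    """
    if min_genes < 0 or min_counts < 0 or min_cells_per_gene < 0:
        raise ValueError("QC thresholds must be nonnegative")
    if not (0 < max_counts_quantile <= 1):
        raise ValueError("max_counts_quantile must be in (0, 1]")
    depth = counts.values.sum(axis=0)
    n_detected = (counts.values > 0).sum(axis=0)
    keep = (n_detected >= min_genes) & (depth >= min_counts)
    if max_counts_quantile < 1.0:
        cap = np.quantile(depth, max_counts_quantile)
        keep &= depth <= cap
    if not keep.any():
        raise ValueError("QC removed all cells")
    out = counts.subset_obs(keep)
    gene_keep = (out.values > 0).sum(axis=1) >= min_cells_per_gene
    out = out.subset_genes(gene_keep)
    if log is not None:
        log(f"qc_filter: cells {counts.n_obs} -> {out.n_obs}, "
            f"genes {counts.n_genes} -> {out.n_genes}")
    return out


def normalize_log_cpm(counts: CountMatrix, scale: float = 1e4) -> NormMatrix:
    """log1p of counts-per-``scale`` (CP10K by default) per observation."""
    totals = counts.values.sum(axis=0).astype(float)
    safe = np.where(totals > 0, totals, 1.0)
    values = np.log1p(scale * counts.values / safe)
    return NormMatrix(counts.gene_ids, counts.obs_ids, values)


# ---------------------------------------------------------------------------
# clustering


def _embed(values: np.ndarray, n_pcs: int, seed: int) -> np.ndarray:
    """Standardize genes and project cells onto the top principal components."""
    X = values.T.astype(float)  # cells x genes
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    X = (X - mu) / sd
    n_pcs = min(n_pcs, min(X.shape) - 1)
    if n_pcs < 1:
        raise ValueError("not enough dimensions for PCA")
    return PCA(n_components=n_pcs, svd_solver="randomized",
               random_state=seed).fit_transform(X)


def _knn_graph(embedding: np.ndarray, k_neighbors: int) -> nx.Graph:
    nn = NearestNeighbors(n_neighbors=k_neighbors + 1).fit(embedding)
    _, idx = nn.kneighbors(embedding)
    graph = nx.Graph()
    graph.add_nodes_from(range(embedding.shape[0]))
    for i, neighbors in enumerate(idx):
        for j in neighbors[1:]:
            graph.add_edge(i, int(j))
    return graph


def cluster_cells(norm: NormMatrix, n_pcs: int = 8, k_neighbors: int = 15,
                  resolution: float = 0.3, seed: int = 0) -> np.ndarray:
    """Louvain clustering on the kNN graph of the PCA embedding.

    Returns integer labels ``0..K-1`` renamed by descending cluster size.
    """
    if norm.n_obs < k_neighbors + 1:
        raise ValueError(
            f"need more than k_neighbors={k_neighbors} cells, got {norm.n_obs}")
    if k_neighbors < 2:
        raise ValueError("k_neighbors must be >= 2")
    embedding = _embed(norm.values, n_pcs, seed)
    graph = _knn_graph(embedding, k_neighbors)
    communities = nx.community.louvain_communities(
        graph, resolution=resolution, seed=seed)
    communities = sorted(communities, key=lambda c: (-len(c), min(c)))
    labels = np.empty(norm.n_obs, dtype=int)
    for rank, members in enumerate(communities):
        labels[list(members)] = rank
    return labels


def subcluster(norm: NormMatrix, labels, target_label, prefix: str,
               n_pcs: int = 10, k_neighbors: int = 15,
               resolution: float = 1.0, seed: int = 0) -> pd.Series:
    """Re-cluster the cells of one cluster; returns sub-labels like ``F1..Fk``.

    Sub-labels are ordered by descending subcluster size, indexed from 1.
    """
    labels = np.asarray(labels)
    mask = labels == target_label
    if mask.sum() < 2 * k_neighbors:
        raise ValueError(
            f"cluster {target_label!r} has {int(mask.sum())} cells; "
            f"need >= {2 * k_neighbors} for subclustering")
    sub = norm.subset_obs(mask)
    sub_labels = cluster_cells(sub, n_pcs=n_pcs, k_neighbors=k_neighbors,
                               resolution=resolution, seed=seed)
    named = pd.Series([f"{prefix}{l + 1}" for l in sub_labels],
                      index=np.asarray(norm.obs_ids, dtype=object)[mask])
    return named


# ---------------------------------------------------------------------------
# marker detection


def _exact_rank_sum_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided exact Wilcoxon rank-sum p by full enumeration of assignments.

    Uses midranks for ties; the null distribution enumerates all
    ``C(n1+n2, n1)`` group assignments of the observed pooled values.
    """
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    n1 = len(x)
    obs = ranks[:n1].sum()
    center = n1 * (len(pooled) + 1) / 2.0
    obs_dev = abs(obs - center)
    total = 0
    extreme = 0
    for combo in combinations(range(len(pooled)), n1):
        total += 1
        dev = abs(ranks[list(combo)].sum() - center)
        if dev >= obs_dev - 1e-9:
            extreme += 1
    return extreme / total


def rank_sum_test(x: np.ndarray, y: np.ndarray, exact_max_n: int = 16) -> float:
    """Wilcoxon rank-sum p-value: exact enumeration for tiny groups,
    tie-corrected normal approximation otherwise."""
    if len(x) + len(y) <= exact_max_n:
        return _exact_rank_sum_p(np.asarray(x, float), np.asarray(y, float))
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return float(res.pvalue)


def benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    """BH-adjusted q-values (monotone, capped at 1)."""
    p = np.asarray(p, dtype=float)
    n = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(n)
    q[order] = np.minimum(ranked, 1.0)
    return q


def find_markers(norm: NormMatrix, labels, q_max: float = 0.05,
                 lfc_min: float = 0.585, pct_min: float = 0.25,
                 min_cluster_size: int = 3) -> pd.DataFrame:
    """One-vs-rest Wilcoxon marker detection on normalized values.

    Returns a tidy table (gene, cluster, log2fc, p, q, pct_in, pct_out,
    is_marker); BH correction is applied within each cluster's family.
    """
    labels = np.asarray(labels)
    clusters = pd.unique(labels)
    if len(clusters) < 2:
        raise ValueError("need at least 2 clusters for marker detection")
    V = norm.values
    rows = []
    for cl in clusters:
        mask = labels == cl
        n_in = int(mask.sum())
        if n_in < min_cluster_size:
            warnings.warn(f"cluster {cl!r} has {n_in} cells; skipped")
            continue
        Vin, Vout = V[:, mask], V[:, ~mask]
        mean_in, mean_out = Vin.mean(axis=1), Vout.mean(axis=1)
        lfc = np.log2(mean_in + 1e-9) - np.log2(mean_out + 1e-9)
        pct_in = (Vin > 0).mean(axis=1)
        pct_out = (Vout > 0).mean(axis=1)
        if Vin.shape[1] + Vout.shape[1] <= 16:
            p = np.array([rank_sum_test(Vin[g], Vout[g]) for g in range(V.shape[0])])
        else:
            res = stats.mannwhitneyu(Vin, Vout, axis=1, alternative="two-sided",
                                     method="asymptotic")
            p = np.asarray(res.pvalue, dtype=float)
        q = benjamini_hochberg(p)
        for g, gene in enumerate(norm.gene_ids):
            rows.append((gene, cl, lfc[g], p[g], q[g], pct_in[g], pct_out[g]))
    table = pd.DataFrame(rows, columns=["gene", "cluster", "log2fc", "p", "q",
                                        "pct_in", "pct_out"])
    table["is_marker"] = ((table["q"] < q_max) & (table["log2fc"] >= lfc_min)
                          & (table["pct_in"] >= pct_min))
    return table


def marker_sets(table: pd.DataFrame) -> dict:
    """Cluster -> set of marker genes from a :func:`find_markers` table."""
    out: dict = {}
    for cl, grp in table[table["is_marker"]].groupby("cluster"):
        out[cl] = set(grp["gene"])
    return out


# ---------------------------------------------------------------------------
# annotation, proportions, specificity


def annotate_clusters(norm: NormMatrix, labels, marker_map: dict) -> dict:
    """Assign each cluster the type whose markers have the highest mean z-score.

    ``marker_map`` maps type name -> marker gene list. Clusters where no
    map gene is expressed get ``"unassigned"``; exact ties resolve to the
    lexicographically first type and are flagged.
    """
    if not marker_map:
        raise ValueError("marker_map must be nonempty")
    labels = np.asarray(labels)
    V = norm.values
    mu = V.mean(axis=1, keepdims=True)
    sd = V.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    Z = (V - mu) / sd
    gidx = {g: i for i, g in enumerate(norm.gene_ids)}
    mapping = {}
    for cl in pd.unique(labels):
        mask = labels == cl
        best, best_score, tie = "unassigned", -np.inf, False
        any_expressed = False
        for type_name in sorted(marker_map):
            genes = [gidx[g] for g in marker_map[type_name] if g in gidx]
            if not genes:
                continue
            if V[genes][:, mask].sum() > 0:
                any_expressed = True
            score = Z[genes][:, mask].mean()
            if math.isclose(score, best_score, rel_tol=0, abs_tol=1e-12):
                tie = True
            elif score > best_score:
                best, best_score, tie = type_name, score, False
        if not any_expressed:
            best, tie = "unassigned", False
        mapping[cl] = {"type": best, "tie": tie}
    return mapping


def temporal_proportions(timepoints, sub_labels) -> pd.DataFrame:
    """Subcluster x timepoint fractions; each subcluster row sums to 1."""
    df = pd.DataFrame({"timepoint": np.asarray(timepoints),
                       "subcluster": np.asarray(sub_labels)})
    table = pd.crosstab(df["subcluster"], df["timepoint"])
    return table.div(table.sum(axis=1), axis=0)


def fibroblast_specificity(norm: NormMatrix, major_labels, gene: str,
                           fibro_label="F") -> float:
    """Share of the gene's per-type mean expression held by fibroblasts.

    ``score = mean(F) / sum over major clusters of per-cluster means``
    with a 1e-9 pseudocount; 1.0 means exclusively fibroblast.
    """
    major_labels = np.asarray(major_labels)
    if fibro_label not in set(major_labels):
        raise ValueError(f"no cluster labeled {fibro_label!r}")
    g = norm.gene_index(gene)
    expr = norm.values[g]
    means = {cl: expr[major_labels == cl].mean() for cl in pd.unique(major_labels)}
    total = sum(means.values()) + 1e-9
    return float((means[fibro_label] + 1e-9) / total)
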