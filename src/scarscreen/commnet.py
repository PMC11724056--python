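"""Cell-cell communication scores and spatial signaling direction fields.

Cluster-to-cluster ligand-receptor communication is scored with a Hill
saturation of the product of mean normalized ligand expression in the
sender and mean receptor expression in the receiver, with significance
from label-permutation nulls.  On spot lattices, the net direction of a
pathway is estimated by entropic-regularized balanced optimal transport
of ligand mass onto receptor mass (Sinkhorn, log-domain), with a hard
distance cutoff; each spot's sending vector is the transport-weighted
mean displacement to its receiver spots.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .io import LRDatabase, NormMatrix, SpotTable


@dataclass
class CommConfig:
    """Knobs for communication scoring and direction fields.

    hill_k: half-saturation constant of the Hill score (score = x/(Kh+x)).
    n_perm: label permutations for the null.
    ot_epsilon_factor: Sinkhorn regularization as a fraction of the
        median feasible cost (scale-invariant across grid spacings).
    ot_cutoff_um: ligand-receptor pairs farther apart are infeasible.
    """

    hill_k: float = 0.5
    n_perm: int = 100
    seed: int = 0
    ot_epsilon_factor: float = 0.05
    ot_cutoff_um: float = 500.0

    def validate(self) -> None:
        if self.hill_k <= 0 or self.ot_epsilon_factor <= 0 or self.ot_cutoff_um <= 0:
            raise ValueError("hill_k, ot_epsilon_factor and ot_cutoff_um must be positive")
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")


def _cluster_means(values: np.ndarray, labels: np.ndarray, clusters) -> np.ndarray:
    """gene x cluster mean matrix."""
    out = np.empty((values.shape[0], len(clusters)))
    for j, cl in enumerate(clusters):
        out[:, j] = values[:, labels == cl].mean(axis=1)
    return out


def _score_matrix(means: np.ndarray, lig_idx, rec_idx, hill_k: float) -> np.ndarray:
    """pair x sender x receiver Hill scores from a gene x cluster mean matrix."""
    L = means[lig_idx]       # pair x cluster
    R = means[rec_idx]
    x = L[:, :, None] * R[:, None, :]
    return x / (hill_k + x)


def communication_score(norm: NormMatrix, labels, lrdb: LRDatabase,
                        cfg: CommConfig | None = None) -> pd.DataFrame:
    """Hill-saturated communication score for every (sender, receiver, pair).

    ``x = mean(ligand | sender) * mean(receptor | receiver)`` on
    normalized expression; ``score = x / (Kh + x)`` lies in [0, 1) and
    is exactly 0 when either mean is 0.  Pairs with genes absent from
    the matrix are skipped with a flag.
    """
    cfg = cfg or CommConfig()
    cfg.validate()
    labels = np.asarray(labels)
    if len(labels) != norm.n_obs:
        raise ValueError("labels must cover all cells")
    if lrdb.n_pairs == 0:
        raise ValueError("empty LR database")
    clusters = sorted(pd.unique(labels))
    gidx = {g: i for i, g in enumerate(norm.gene_ids)}

    usable, skipped = [], []
    for pathway, ligand, receptor in lrdb.pairs():
        if ligand in gidx and receptor in gidx:
            usable.append((pathway, ligand, receptor))
        else:
            skipped.append((pathway, ligand, receptor))
    if skipped:
        warnings.warn(f"{len(skipped)} LR pair(s) skipped: gene absent from matrix")
    if not usable:
        raise ValueError("no LR pair has both genes in the matrix")

    means = _cluster_means(norm.values, labels, clusters)
    lig_idx = [gidx[l] for _, l, _ in usable]
    rec_idx = [gidx[r] for *_, r in usable]
    scores = _score_matrix(means, lig_idx, rec_idx, cfg.hill_k)

    rows = []
    for pi, (pathway, ligand, receptor) in enumerate(usable):
        for si, sender in enumerate(clusters):
            for ri, receiver in enumerate(clusters):
                rows.append((sender, receiver, ligand, receptor, pathway,
                             scores[pi, si, ri]))
    return pd.DataFrame(rows, columns=["sender", "receiver", "ligand",
                                       "receptor", "pathway", "score"])


def permutation_pvalues(norm: NormMatrix, labels, lrdb: LRDatabase,
                        cfg: CommConfig | None = None) -> pd.DataFrame:
    """Communication table with add-one permutation p-values.

    Cluster labels are permuted over cells ``n_perm`` times;
    ``p = (1 + #{perm score >= observed}) / (n_perm + 1)`` per triple.
    """
    cfg = cfg or CommConfig()
    cfg.validate()
    if cfg.n_perm < 20:
        raise ValueError("n_perm must be >= 20 for meaningful p-values")
    table = communication_score(norm, labels, lrdb, cfg)
    labels = np.asarray(labels)
    clusters = sorted(pd.unique(labels))
    gidx = {g: i for i, g in enumerate(norm.gene_ids)}
    usable = [(p, l, r) for p, l, r in lrdb.pairs() if l in gidx and r in gidx]
    lig_idx = [gidx[l] for _, l, _ in usable]
    rec_idx = [gidx[r] for *_, r in usable]

    observed = _score_matrix(_cluster_means(norm.values, labels, clusters),
                             lig_idx, rec_idx, cfg.hill_k)
    rng = np.random.default_rng(cfg.seed)
    exceed = np.zeros_like(observed)
    for _ in range(cfg.n_perm):
        perm = rng.permutation(labels)
        s = _score_matrix(_cluster_means(norm.values, perm, clusters),
                          lig_idx, rec_idx, cfg.hill_k)
        exceed += (s >= observed - 1e-12)
    pvals = (1.0 + exceed) / (cfg.n_perm + 1.0)

    lookup = {}
    for pi, (pathway, ligand, receptor) in enumerate(usable):
        for si, sender in enumerate(clusters):
            for ri, receiver in enumerate(clusters):
                lookup[(sender, receiver, ligand, receptor)] = pvals[pi, si, ri]
    table["p_perm"] = [lookup[k] for k in
                       zip(table["sender"], table["receiver"],
                           table["ligand"], table["receptor"])]
    table["n_perm"] = cfg.n_perm
    return table


def aggregate_pathway(comm: pd.DataFrame) -> pd.DataFrame:
    """Pathway-level sender x receiver score: probability union of pair scores.

    ``score_pathway = 1 - prod_pairs (1 - score_pair)`` — monotone in
    every pair score, and adding a zero-score pair is neutral.
    """
    grouped = comm.groupby(["pathway", "sender", "receiver"])["score"].apply(
        lambda s: 1.0 - np.prod(1.0 - s.to_numpy()))
    return grouped.reset_index().rename(columns={"score": "pathway_score"})


# ---------------------------------------------------------------------------
# optimal-transport direction field


def sinkhorn_log(a: np.ndarray, b: np.ndarray, cost: np.ndarray, epsilon: float,
                 feasible: np.ndarray, max_iter: int = 2000, tol: float = 1e-8):
    """Entropic balanced OT in the log domain with an infeasibility mask.

    Returns the transport plan T with row sums ``a`` and column sums
    ``b`` (within ``tol``); infeasible entries carry zero mass.
    """
    with np.errstate(divide="ignore"):
        logK = np.where(feasible, -cost / epsilon, -np.inf)
        log_a, log_b = np.log(a), np.log(b)
    f = np.zeros_like(a)
    g = np.zeros_like(b)
    for _ in range(max_iter):
        f_new = epsilon * (log_a - logsumexp((logK + g[None, :] / epsilon), axis=1))
        g_new = epsilon * (log_b - logsumexp((logK + f_new[:, None] / epsilon), axis=0))
        err = max(np.max(np.abs(f_new - f)), np.max(np.abs(g_new - g)))
        f, g = f_new, g_new
        if err < tol * epsilon:
            break
    T = np.exp(np.where(feasible,
                        (f[:, None] + g[None, :]) / epsilon + logK, -np.inf))
    return T


@dataclass
class VectorField:
    """Per-spot unit direction (u, v) with transported-mass magnitude."""

    spot_ids: list[str]
    u: np.ndarray
    v: np.ndarray
    magnitude: np.ndarray
    pathway: str = ""

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame({"spot_id": self.spot_ids, "u": self.u, "v": self.v,
                             "magnitude": self.magnitude, "pathway": self.pathway})


def signaling_direction(spot_norm: NormMatrix, spot_table: SpotTable,
                        ligand: str, receptor: str,
                        cfg: CommConfig | None = None,
                        pathway: str = "") -> VectorField:
    """Optimal-transport sending-direction field for one LR pair.

    Sender mass is proportional to linear-scale ligand expression
    (expm1 of the log-normalized value), receiver mass likewise for the
    receptor, each normalized to 1 over spots with signal;
    cost is Euclidean distance in micrometers with pairs beyond
    ``ot_cutoff_um`` infeasible; epsilon is ``ot_epsilon_factor`` times
    the median feasible cost.  The sending vector at spot s is the
    transport-weighted mean displacement toward its receiver spots,
    normalized to unit length; its magnitude is the mass sent.
    """
    cfg = cfg or CommConfig()
    cfg.validate()
    if list(spot_table.spot_ids) != list(spot_norm.obs_ids):
        raise ValueError("spot table and matrix must cover the same spots in order")
    coords = spot_table.coords()
    # masses live on the linear expression scale (undo the log1p) so that
    # spatial contrast between induced and baseline spots is preserved
    lig = np.expm1(spot_norm.values[spot_norm.gene_index(ligand)].astype(float))
    rec = np.expm1(spot_norm.values[spot_norm.gene_index(receptor)].astype(float))

    n = len(lig)
    u = np.zeros(n)
    v = np.zeros(n)
    mag = np.zeros(n)
    senders = np.flatnonzero(lig > 0)
    receivers = np.flatnonzero(rec > 0)
    if senders.size == 0 or receivers.size == 0:
        warnings.warn("no spots with both ligand and receptor signal; empty field")
        return VectorField(list(spot_norm.obs_ids), u, v, mag, pathway)

    dx = coords[receivers, 0][None, :] - coords[senders, 0][:, None]
    dy = coords[receivers, 1][None, :] - coords[senders, 1][:, None]
    cost = np.hypot(dx, dy)
    feasible = cost <= cfg.ot_cutoff_um
    # drop senders/receivers with no feasible partner (mass cannot move)
    s_ok = feasible.any(axis=1)
    r_ok = feasible.any(axis=0)
    if not s_ok.any() or not r_ok.any():
        warnings.warn("no feasible ligand-receptor spot pair within cutoff; empty field")
        return VectorField(list(spot_norm.obs_ids), u, v, mag, pathway)
    senders, receivers = senders[s_ok], receivers[r_ok]
    cost, feasible = cost[np.ix_(s_ok, r_ok)], feasible[np.ix_(s_ok, r_ok)]
    dx, dy = dx[np.ix_(s_ok, r_ok)], dy[np.ix_(s_ok, r_ok)]

    a = lig[senders] / lig[senders].sum()
    b = rec[receivers] / rec[receivers].sum()
    med = np.median(cost[feasible])
    epsilon = cfg.ot_epsilon_factor * max(med, 1e-9)
    T = sinkhorn_log(a, b, cost, epsilon, feasible)

    vx = (T * dx).sum(axis=1)
    vy = (T * dy).sum(axis=1)
    mass = T.sum(axis=1)
    norm_v = np.hypot(vx, vy)
    ok = norm_v > 1e-12
    u[senders[ok]] = vx[ok] / norm_v[ok]
    v[senders[ok]] = vy[ok] / norm_v[ok]
    mag[senders] = mass
    return VectorField(list(spot_norm.obs_ids), u, v, mag, pathway)
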