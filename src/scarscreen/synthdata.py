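"""Synthetic wound-healing multiomics generator with planted ground truth.

Emulates the statistical structure of a neonatal skin-wound time course:

* single-cell RNA-seq over Days 3/7/14 with eight major cell types
  (fibroblast F, macrophage M, neutrophil N, T cell TC, epithelial EpC,
  endothelial EC, pericyte P, mesenchymal MC), eight fibroblast
  subclusters F1-F8 (F4/F6/F8 appearing only from Day 7), and six
  macrophage subclusters M1-M6;
* bulk RNA-seq of wild-type versus inflammation-deficient (myeloid-less
  knockout) wounds, where a designated gene set is transcriptionally
  dependent on inflammation;
* a Visium-like spot lattice over a circular wound in intact skin, with
  20-30 cells pooled per spot and a planted ligand->receptor signaling
  geometry (e.g. Tgfb1 from wound-margin macrophages to Tgfbr1 on
  wound-center fibroblasts).

Counts are negative binomial with a single shared dispersion around
class-specific transcript-fraction profiles.  Planted effects are all
expressed as powers of ``2**marker_log2fc`` so that ``marker_log2fc = 0``
collapses every fold-change to 1 (a null generator).  The generator
records a :class:`SynthTruth` with everything downstream stages are
supposed to recover: cell labels, spot composition weights, region
labels, the true inflammation-dependent scarring genes, one decoy gene
per screen failure mode, and the planted signaling direction field.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import CountMatrix, SpotTable

MAJOR_TYPES = ("F", "M", "N", "TC", "EpC", "EC", "P", "MC")

#: canonical per-type marker symbols (murine skin wound constituents)
NAMED_MAJOR_MARKERS = {
    "F": ["Dcn", "Col3a1", "Pdgfra"],
    "M": ["Lyz2", "Cd68", "Adgre1"],
    "N": ["S100a9", "S100a8"],
    "TC": ["Cd3g", "Cd3e"],
    "EpC": ["Krt10", "Krt14"],
    "EC": ["Pecam1", "Cdh5"],
    "P": ["Rgs5", "Pdgfrb"],
    "MC": ["Bmp4"],
}

TRUE_SCAR_GENES = ("Itgbl1", "Clec3b", "Ccl11", "Lrrc17", "Pi16")
ANCHOR_GENE = "Col1a1"

# special planted genes: home majors, per-class boost exponents
# (multiples of marker_log2fc), whether restricted outside home majors,
# and whether flagged inflammation-dependent (downregulated in KO bulk).
# Boost keys are subcluster names, major names, or "F*"/"M*" for every
# subcluster of that major.
_SPECIALS: dict[str, dict] = {
    "Col1a1": dict(home=("F",), boosts={"F*": 0.4, "F4": 1.2, "F1": 0.8}, ko=False),
    "Acta2":  dict(home=("F",), boosts={"F4": 1.0}, ko=False),
    "Itgbl1": dict(home=("F",), boosts={"F4": 1.2, "F1": 0.8}, ko=True),
    "Clec3b": dict(home=("F",), boosts={"F1": 1.2, "F3": 1.2, "F7": 1.2}, ko=True),
    "Ccl11":  dict(home=("F",), boosts={"F1": 1.2, "F3": 1.2}, ko=True),
    "Lrrc17": dict(home=("F",), boosts={"F2": 1.2, "F6": 1.2, "F8": 1.2}, ko=True),
    "Pi16":   dict(home=("F",), boosts={"F3": 1.2, "F7": 1.2}, ko=True),
    # decoys: each fails exactly one screen criterion
    "Fbn1":   dict(home=("F",), boosts={"F2": 1.0, "F5": 1.0}, ko=False),   # fails KO-down
    "C4b":    dict(home=("F",), boosts={"F*": 0.8}, ko=True),               # fails subcluster marker
    "Ccl7":   dict(home=("F", "M"), boosts={"F1": 1.0, "F2": 1.0, "M*": 1.0}, ko=True),  # fails specificity
    "Saa3":   dict(home=("F",), boosts={"F2": 1.0, "F8": 1.0}, ko=True),    # fails spatial support
    # planted signaling axis
    "Tgfb1":  dict(home=("M",), boosts={"M1": 1.2}, ko=False),
    "Tgfbr1": dict(home=("F",), boosts={"F8": 1.2}, ko=False),
}

DECOY_GENES = {
    "fails_ko_downregulation": {"Fbn1"},
    "fails_fibroblast_marker": {"C4b"},
    "fails_fibroblast_specificity": {"Ccl7"},
    "fails_spatial_support": {"Saa3"},
}

#: named baseline genes used as null ligand-receptor pairs
_NULL_LR_GENES = ("Spp1", "Cd44", "Thbs1", "Cd47", "Osm", "Osmr", "Nampt", "Insr")

_DEFAULT_MAJOR_PROPS = {
    #        Day3  Day7  Day14
    "F":   (0.15, 0.30, 0.35),
    "M":   (0.25, 0.22, 0.15),
    "N":   (0.20, 0.06, 0.03),
    "TC":  (0.08, 0.07, 0.07),
    "EpC": (0.12, 0.13, 0.17),
    "EC":  (0.08, 0.09, 0.10),
    "P":   (0.06, 0.07, 0.07),
    "MC":  (0.06, 0.06, 0.06),
}

_DEFAULT_FIBRO_PROPS = {
    # F4/F6/F8 appear only from Day 7 (late, repair-phase subclusters)
    "F1": (0.25, 0.14, 0.12),
    "F2": (0.20, 0.12, 0.10),
    "F3": (0.20, 0.12, 0.10),
    "F4": (0.00, 0.14, 0.20),
    "F5": (0.20, 0.12, 0.10),
    "F6": (0.00, 0.12, 0.14),
    "F7": (0.15, 0.10, 0.08),
    "F8": (0.00, 0.14, 0.16),
}

_DEFAULT_MACRO_PROPS = {
    "M1": (0.30, 0.25, 0.20),
    "M2": (0.20, 0.20, 0.20),
    "M3": (0.15, 0.20, 0.20),
    "M4": (0.15, 0.15, 0.15),
    "M5": (0.10, 0.10, 0.15),
    "M6": (0.10, 0.10, 0.10),
}

#: region-conditioned major-type sampling probabilities for spots
_DEFAULT_REGION_COMPOSITION = {
    "wound":  {"F": 0.45, "M": 0.30, "N": 0.08, "TC": 0.04, "EpC": 0.04,
               "EC": 0.07, "P": 0.01, "MC": 0.01},
    "intact": {"F": 0.20, "M": 0.05, "N": 0.02, "TC": 0.05, "EpC": 0.35,
               "EC": 0.12, "P": 0.11, "MC": 0.10},
    "muscle": {"F": 0.10, "M": 0.05, "N": 0.00, "TC": 0.05, "EpC": 0.05,
               "EC": 0.20, "P": 0.35, "MC": 0.20},
}

_DEFAULT_LR_PLANTED = [("Tgfb1", "Tgfbr1", "M1", "F8", "margin_to_center")]


class ConfigError(ValueError):
    """Raised on an invalid generator configuration."""


@dataclass
class SynthConfig:
    """All knobs of the synthetic study, with wound-time-course defaults."""

    n_genes: int = 1000
    n_cells_per_timepoint: int = 3000
    timepoints: tuple[int, ...] = (3, 7, 14)
    major_types: dict = field(default_factory=lambda: dict(_DEFAULT_MAJOR_PROPS))
    fibro_subclusters: dict = field(default_factory=lambda: dict(_DEFAULT_FIBRO_PROPS))
    macro_subclusters: dict = field(default_factory=lambda: dict(_DEFAULT_MACRO_PROPS))
    n_markers_per_cluster: int = 30
    n_markers_per_subcluster: int = 8
    marker_log2fc: float = 2.5
    nb_dispersion: float = 0.1
    depth_mean_cells: int = 5000
    n_bulk_per_genotype: int = 4
    bulk_depth: int = 2_000_000
    ko_downregulation_log2fc: float = -2.0
    grid_shape: tuple[int, int] = (25, 25)
    spot_spacing_um: float = 100.0
    cells_per_spot_range: tuple[int, int] = (20, 30)
    spot_depth_per_cell: float = 200.0
    wound_radius_um: float = 600.0
    region_composition: dict = field(
        default_factory=lambda: {k: dict(v) for k, v in _DEFAULT_REGION_COMPOSITION.items()})
    lr_pairs_planted: list = field(default_factory=lambda: list(_DEFAULT_LR_PLANTED))
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes < 50:
            raise ConfigError("n_genes must be at least 50")
        if self.nb_dispersion < 0:
            raise ConfigError("nb_dispersion must be nonnegative")
        if self.depth_mean_cells <= 0 or self.bulk_depth <= 0 or self.spot_depth_per_cell <= 0:
            raise ConfigError("sequencing depths must be positive")
        if self.marker_log2fc < 0:
            raise ConfigError("marker_log2fc must be nonnegative")
        nt = len(self.timepoints)
        for name, props in [("major_types", self.major_types),
                            ("fibro_subclusters", self.fibro_subclusters),
                            ("macro_subclusters", self.macro_subclusters)]:
            if name != "major_types" and not props:
                continue
            for label, vec in props.items():
                if len(vec) != nt:
                    raise ConfigError(f"{name}[{label}] needs {nt} proportions")
                if any(p < 0 for p in vec):
                    raise ConfigError(f"{name}[{label}] has a negative proportion")
            for t in range(nt):
                total = sum(vec[t] for vec in props.values())
                if abs(total - 1.0) > 1e-9:
                    raise ConfigError(
                        f"{name} proportions at timepoint index {t} sum to {total}, not 1")
        lo, hi = self.cells_per_spot_range
        if not (1 <= lo <= hi <= 100):
            raise ConfigError("cells_per_spot_range must satisfy 1 <= low <= high <= 100")
        rows, cols = self.grid_shape
        half_extent = min(rows - 1, cols - 1) / 2.0 * self.spot_spacing_um
        if self.wound_radius_um > half_extent:
            raise ConfigError(
                f"wound_radius_um {self.wound_radius_um} exceeds grid half-extent {half_extent}")
        for region, comp in self.region_composition.items():
            unknown = set(comp) - set(self.major_types)
            if unknown:
                raise ConfigError(f"region {region} references unknown types {sorted(unknown)}")
            if abs(sum(comp.values()) - 1.0) > 1e-9:
                raise ConfigError(f"region {region} composition does not sum to 1")


@dataclass
class SynthTruth:
    """Planted ground truth shared by all downstream stage tests."""

    config: SynthConfig
    gene_ids: list[str]
    cell_labels: pd.DataFrame            # cell_id, major_type, subcluster, timepoint
    class_names: list[str]               # e.g. "F/F4", "M/M1", "N"
    class_profiles: pd.DataFrame         # class x gene relative rates (unnormalized)
    type_mean_profiles: pd.DataFrame     # major type x gene expected transcript fractions
    planted_markers_major: dict          # major type -> set of genes (rate-lfc >= 1)
    planted_markers_fibro_sub: dict      # F subcluster -> set of genes (within-F rate-lfc >= 1)
    true_scar_genes: set
    decoy_genes: dict
    ko_genes: set
    anchor_gene: str = ANCHOR_GENE
    # per-timepoint spatial truth, filled by generate_visium
    spot_weights: dict = field(default_factory=dict)        # day -> DataFrame spot x major type (transcript fractions)
    spot_cell_fractions: dict = field(default_factory=dict) # day -> DataFrame spot x major type (cell-count fractions)
    spot_regions: dict = field(default_factory=dict)        # day -> ndarray of region labels
    planted_direction: dict = field(default_factory=dict)   # day -> (n_spots, 2) unit vectors
    direction_valid: dict = field(default_factory=dict)     # day -> bool mask
    margin_mask: dict = field(default_factory=dict)         # day -> bool mask of wound-margin spots
    region_expected_lfc: dict = field(default_factory=dict) # day -> Series gene -> log2 wound/intact


# ---------------------------------------------------------------------------
# gene universe and class rate profiles


def _class_list(config: SynthConfig) -> list[tuple[str, str | None]]:
    classes: list[tuple[str, str | None]] = []
    for major in config.major_types:
        if major == "F" and config.fibro_subclusters:
            classes.extend(("F", s) for s in config.fibro_subclusters)
        elif major == "M" and config.macro_subclusters:
            classes.extend(("M", s) for s in config.macro_subclusters)
        else:
            classes.append((major, None))
    return classes


def _build_universe(config: SynthConfig, rng: np.random.Generator):
    """Assign gene symbols: named specials, per-cluster filler markers, baseline."""
    majors = list(config.major_types)
    specials = [g for g in _SPECIALS if set(_SPECIALS[g]["home"]) <= set(majors)]
    null_lr = list(_NULL_LR_GENES)

    marker_sets_major: dict[str, list[str]] = {}
    gene_ids: list[str] = specials + null_lr
    for major in majors:
        named = [g for g in NAMED_MAJOR_MARKERS.get(major, []) if g not in gene_ids]
        fillers = [f"mk{major}{i:02d}" for i in range(len(named), config.n_markers_per_cluster)]
        marker_sets_major[major] = named + fillers
        gene_ids.extend(named + fillers)

    marker_sets_sub: dict[str, list[str]] = {}
    for sub in list(config.fibro_subclusters) + list(config.macro_subclusters):
        if (sub.startswith("F") and "F" not in majors) or (sub.startswith("M") and "M" not in majors):
            continue
        fillers = [f"mk{sub}_{i:02d}" for i in range(config.n_markers_per_subcluster)]
        marker_sets_sub[sub] = fillers
        gene_ids.extend(fillers)

    if len(gene_ids) > config.n_genes:
        raise ConfigError(
            f"n_genes={config.n_genes} too small for {len(gene_ids)} planted genes")
    gene_ids = gene_ids + [f"G{i:04d}" for i in range(config.n_genes - len(gene_ids))]

    # heterogeneous per-gene baseline, shared across classes
    baseline = rng.lognormal(mean=0.0, sigma=0.6, size=config.n_genes)
    baseline[[gene_ids.index(g) for g in specials]] = 1.0
    return gene_ids, baseline, marker_sets_major, marker_sets_sub, specials


def _class_rate_profiles(config: SynthConfig, gene_ids, baseline,
                         marker_sets_major, marker_sets_sub, specials):
    """Relative expression rate per (class, gene); all effects scale with marker_log2fc."""
    classes = _class_list(config)
    class_names = [f"{m}/{s}" if s else m for m, s in classes]
    gidx = {g: i for i, g in enumerate(gene_ids)}
    boost = 2.0 ** config.marker_log2fc
    restrict = 2.0 ** (-2.5 * config.marker_log2fc)

    rates = np.tile(baseline, (len(classes), 1))
    for ci, (major, sub) in enumerate(classes):
        for g in marker_sets_major[major]:
            rates[ci, gidx[g]] *= boost
        if sub is not None and sub in marker_sets_sub:
            for g in marker_sets_sub[sub]:
                rates[ci, gidx[g]] *= boost

    for g in specials:
        info = _SPECIALS[g]
        j = gidx[g]
        for ci, (major, sub) in enumerate(classes):
            if major not in info["home"]:
                rates[ci, j] *= restrict
                continue
            mult = 1.0
            for key, expo in info["boosts"].items():
                hit = (key == sub) or (key == major) or (
                    key.endswith("*") and key[:-1] == major)
                if hit:
                    mult *= 2.0 ** (expo * config.marker_log2fc)
            rates[ci, j] *= mult
    return class_names, pd.DataFrame(rates, index=class_names, columns=gene_ids)


def _pooled_class_weights(config: SynthConfig) -> pd.Series:
    """Expected fraction of all cells (pooled over timepoints) per class."""
    classes = _class_list(config)
    nt = len(config.timepoints)
    w = {}
    for major, sub in classes:
        total = 0.0
        for t in range(nt):
            p = config.major_types[major][t]
            if sub is not None:
                subprops = (config.fibro_subclusters if major == "F"
                            else config.macro_subclusters)
                p *= subprops[sub][t]
            total += p
        name = f"{major}/{sub}" if sub else major
        w[name] = total / nt
    return pd.Series(w)


def _planted_marker_sets(config, class_profiles, class_weights):
    """Genes whose expected one-vs-rest rate log2FC is >= 1, per major and F subcluster."""
    classes = class_profiles.index
    weights = class_weights.reindex(classes).to_numpy()
    rates = class_profiles.to_numpy()
    majors = np.array([c.split("/")[0] for c in classes])

    planted_major: dict[str, set] = {}
    for major in config.major_types:
        inm = majors == major
        mean_in = np.average(rates[inm], axis=0, weights=weights[inm])
        mean_out = np.average(rates[~inm], axis=0, weights=weights[~inm])
        lfc = np.log2(mean_in + 1e-12) - np.log2(mean_out + 1e-12)
        planted_major[major] = {g for g, l in zip(class_profiles.columns, lfc) if l >= 1.0}

    planted_sub: dict[str, set] = {}
    if "F" in config.major_types and config.fibro_subclusters:
        f_classes = [c for c in classes if c.startswith("F/")]
        fw = class_weights.reindex(f_classes).to_numpy()
        fr = class_profiles.loc[f_classes].to_numpy()
        for si, sub in enumerate(s.split("/")[1] for s in f_classes):
            mask = np.arange(len(f_classes)) == si
            mean_in = fr[si]
            mean_out = np.average(fr[~mask], axis=0, weights=fw[~mask])
            lfc = np.log2(mean_in + 1e-12) - np.log2(mean_out + 1e-12)
            planted_sub[sub] = {g for g, l in zip(class_profiles.columns, lfc) if l >= 1.0}
    return planted_major, planted_sub


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative binomial via gamma-Poisson; dispersion 0 degenerates to Poisson."""
    mean = np.asarray(mean, dtype=float)
    if dispersion <= 0:
        return rng.poisson(mean)
    lam = rng.gamma(shape=1.0 / dispersion, scale=dispersion * mean)
    return rng.poisson(lam)


# ---------------------------------------------------------------------------
# generators


def generate_single_cell(config: SynthConfig):
    """Simulate the scRNA-seq modality; returns (CountMatrix, cell metadata, SynthTruth)."""
    config.validate()
    rng = np.random.default_rng([config.seed, 11])

    gene_ids, baseline, mk_major, mk_sub, specials = _build_universe(config, rng)
    class_names, class_profiles = _class_rate_profiles(
        config, gene_ids, baseline, mk_major, mk_sub, specials)
    class_weights = _pooled_class_weights(config)
    planted_major, planted_sub = _planted_marker_sets(config, class_profiles, class_weights)

    # per-class transcript fractions
    rates = class_profiles.to_numpy()
    fractions = rates / rates.sum(axis=1, keepdims=True)

    records = []
    count_blocks = []
    for ti, day in enumerate(config.timepoints):
        probs = []
        for name in class_names:
            major, _, sub = name.partition("/")
            p = config.major_types[major][ti]
            if sub:
                subprops = (config.fibro_subclusters if major == "F"
                            else config.macro_subclusters)
                p *= subprops[sub][ti]
            probs.append(p)
        probs = np.asarray(probs)
        probs = probs / probs.sum()
        assignment = rng.choice(len(class_names), size=config.n_cells_per_timepoint, p=probs)
        depths = rng.lognormal(mean=np.log(config.depth_mean_cells), sigma=0.25,
                               size=config.n_cells_per_timepoint)
        block = np.zeros((config.n_genes, config.n_cells_per_timepoint), dtype=np.int64)
        for ci in range(len(class_names)):
            cells = np.flatnonzero(assignment == ci)
            if cells.size == 0:
                continue
            mu = np.outer(fractions[ci], depths[cells])
            block[:, cells] = _nb_draw(rng, mu, config.nb_dispersion)
        count_blocks.append(block)
        for i, ci in enumerate(assignment):
            major, _, sub = class_names[ci].partition("/")
            records.append((f"c{day}d_{i:05d}", major, sub or None, day))

    counts = CountMatrix(gene_ids, [r[0] for r in records], np.hstack(count_blocks))
    meta = pd.DataFrame(records, columns=["cell_id", "major_type", "subcluster", "timepoint"])

    # expected transcript-fraction profile per major type (pooled subcluster mix)
    majors_of_class = np.array([c.split("/")[0] for c in class_names])
    type_rows = {}
    for major in config.major_types:
        inm = majors_of_class == major
        w = class_weights.reindex(np.array(class_names)[inm]).to_numpy()
        mean_rate = np.average(rates[inm], axis=0, weights=w)
        type_rows[major] = mean_rate / mean_rate.sum()
    type_mean_profiles = pd.DataFrame(type_rows, index=gene_ids).T

    truth = SynthTruth(
        config=config,
        gene_ids=gene_ids,
        cell_labels=meta.copy(),
        class_names=class_names,
        class_profiles=class_profiles,
        type_mean_profiles=type_mean_profiles,
        planted_markers_major=planted_major,
        planted_markers_fibro_sub=planted_sub,
        true_scar_genes=set(g for g in TRUE_SCAR_GENES if g in gene_ids),
        decoy_genes={k: set(v) & set(gene_ids) for k, v in DECOY_GENES.items()},
        ko_genes={g for g in specials if _SPECIALS[g]["ko"]},
    )
    return counts, meta, truth


@dataclass
class BulkDesign:
    """Sample sheet for the bulk modality."""

    frame: pd.DataFrame  # sample_id, genotype, library_size

    def __post_init__(self) -> None:
        if set(self.frame["genotype"]) - {"WT", "KO"}:
            raise ValueError("genotype must be WT or KO")
        counts = self.frame["genotype"].value_counts()
        if (counts < 2).any() or len(counts) < 2:
            raise ValueError("need >= 2 samples per genotype")
        if (self.frame["library_size"] <= 0).any():
            raise ValueError("library_size must be positive")


def generate_bulk(config: SynthConfig, truth: SynthTruth):
    """Simulate WT vs inflammation-deficient bulk wound RNA-seq.

    WT expectation is the Day-7 (granulation-phase) cell-type mixture of
    the truth profiles; the KO expectation is identical except that the
    inflammation-dependent genes are scaled by
    ``2**ko_downregulation_log2fc``.
    """
    config.validate()
    if truth.gene_ids != list(truth.class_profiles.columns) or len(truth.gene_ids) != config.n_genes:
        raise ConfigError("truth gene universe does not match config")
    rng = np.random.default_rng([config.seed, 23])

    ti = list(config.timepoints).index(7) if 7 in config.timepoints else 0
    rates = truth.class_profiles.to_numpy()
    weights = []
    for name in truth.class_names:
        major, _, sub = name.partition("/")
        p = config.major_types[major][ti]
        if sub:
            subprops = (config.fibro_subclusters if major == "F" else config.macro_subclusters)
            p *= subprops[sub][ti]
        weights.append(p)
    weights = np.asarray(weights)
    mixture = weights @ (rates / rates.sum(axis=1, keepdims=True))

    ko_mask = np.isin(truth.gene_ids, sorted(truth.ko_genes))
    mixture_ko = mixture.copy()
    mixture_ko[ko_mask] *= 2.0 ** config.ko_downregulation_log2fc

    n = config.n_bulk_per_genotype
    sample_ids, genotypes, cols = [], [], []
    for genotype, mix in (("WT", mixture), ("KO", mixture_ko)):
        frac = mix / mix.sum()
        for i in range(n):
            depth = config.bulk_depth * rng.lognormal(0.0, 0.15)
            cols.append(_nb_draw(rng, depth * frac, config.nb_dispersion))
            sample_ids.append(f"{genotype.lower()}_{i+1}")
            genotypes.append(genotype)
    values = np.column_stack(cols)
    counts = CountMatrix(truth.gene_ids, sample_ids, values)
    design = BulkDesign(pd.DataFrame({
        "sample_id": sample_ids,
        "genotype": genotypes,
        "library_size": values.sum(axis=0),
    }))
    return counts, design


def _grid_coordinates(config: SynthConfig):
    rows, cols = config.grid_shape
    rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    x = cc.ravel() * config.spot_spacing_um
    y = rr.ravel() * config.spot_spacing_um
    return rr.ravel(), cc.ravel(), x.astype(float), y.astype(float)


def expected_wound_spot_count(config: SynthConfig) -> int:
    """Lattice points within wound_radius_um of the grid center (geometry helper)."""
    _, _, x, y = _grid_coordinates(config)
    cx, cy = x.mean(), y.mean()
    r = np.hypot(x - cx, y - cy)
    return int(np.sum(r <= config.wound_radius_um))


def _lr_spatial_factor(geometry: str, role: str, r: np.ndarray, radius: float,
                       amplitude: float) -> np.ndarray:
    """Multiplicative spatial profile for a planted ligand or receptor gene.

    ``margin_to_center``: ligand peaks on the wound-margin annulus,
    receptor peaks at the wound center; ``center_to_margin`` swaps them.
    """
    # strong induction at the peak, suppression elsewhere: the planted
    # signaling genes are switched on only in their wound territory
    base = 0.05
    margin_peak = base + (amplitude - base) * np.exp(-((r - 0.85 * radius) / (0.3 * radius)) ** 2)
    center_peak = base + (amplitude - base) * np.exp(-(r / (0.5 * radius)) ** 2)
    at_margin = (role == "ligand") == (geometry == "margin_to_center")
    return margin_peak if at_margin else center_peak


def generate_visium(config: SynthConfig, truth: SynthTruth, timepoint: int | None = None):
    """Simulate a Visium-like spot lattice for one timepoint.

    Each spot pools 20-30 cells whose types follow region-conditioned
    probabilities (wound spots fibroblast/macrophage-rich); spot counts
    are sums of per-cell negative binomial draws. Realized major-type
    fractions, region labels, the planted signaling direction field, and
    analytically expected wound-vs-intact log2 fold-changes are recorded
    in the truth object.
    """
    config.validate()
    if truth.gene_ids != list(truth.class_profiles.columns):
        raise ConfigError("truth gene universe does not match config")
    day = timepoint if timepoint is not None else (7 if 7 in config.timepoints else config.timepoints[0])
    if day not in config.timepoints:
        raise ConfigError(f"timepoint {day} not in config.timepoints")
    ti = list(config.timepoints).index(day)
    rng = np.random.default_rng([config.seed, 37, int(day)])

    rows_idx, cols_idx, x, y = _grid_coordinates(config)
    cx, cy = x.mean(), y.mean()
    r = np.hypot(x - cx, y - cy)
    n_spots = x.size
    n_rows = config.grid_shape[0]

    regions = np.full(n_spots, "intact", dtype=object)
    regions[r <= config.wound_radius_um] = "wound"
    regions[(rows_idx >= n_rows - 2) & (r > config.wound_radius_um)] = "muscle"

    classes = truth.class_names
    majors_of_class = np.array([c.split("/")[0] for c in classes])
    rates = truth.class_profiles.to_numpy()
    fractions = rates / rates.sum(axis=1, keepdims=True)

    # per-region class sampling probabilities at this timepoint
    region_probs = {}
    for region, comp in config.region_composition.items():
        probs = []
        for name in classes:
            major, _, sub = name.partition("/")
            p = comp.get(major, 0.0)
            if sub:
                subprops = (config.fibro_subclusters if major == "F" else config.macro_subclusters)
                sp = np.array([subprops[s][ti] for s in subprops])
                if sp.sum() <= 0:
                    sp = np.ones_like(sp)
                sp = sp / sp.sum()
                p *= sp[list(subprops).index(sub)]
            probs.append(p)
        probs = np.asarray(probs)
        region_probs[region] = probs / probs.sum()

    # spatial multiplicative factors for planted LR genes
    gidx = {g: i for i, g in enumerate(truth.gene_ids)}
    amplitude = 2.0 ** config.marker_log2fc
    factors = np.ones((n_spots, len(truth.gene_ids)))
    for ligand, receptor, _, _, geometry in config.lr_pairs_planted:
        if ligand in gidx:
            factors[:, gidx[ligand]] *= _lr_spatial_factor(
                geometry, "ligand", r, config.wound_radius_um, amplitude)
        if receptor in gidx:
            factors[:, gidx[receptor]] *= _lr_spatial_factor(
                geometry, "receptor", r, config.wound_radius_um, amplitude)

    # expected per-region mean rates (before flattening), used both for the
    # spatial-decoy flattening factor and for the recorded expected DEG lfc
    def region_mean_rate(region: str) -> np.ndarray:
        return region_probs[region] @ fractions

    wound_rate = region_mean_rate("wound")
    intact_rate = region_mean_rate("intact")
    for decoy in truth.decoy_genes.get("fails_spatial_support", ()):
        j = gidx[decoy]
        # flatten the decoy in wound spots to just below its intact level
        factors[regions == "wound", j] *= 0.8 * intact_rate[j] / max(wound_rate[j], 1e-12)

    lo, hi = config.cells_per_spot_range
    n_cells = rng.integers(lo, hi + 1, size=n_spots)
    counts = np.zeros((len(truth.gene_ids), n_spots), dtype=np.int64)
    major_list = list(config.major_types)
    class_major_idx = np.array([major_list.index(m) for m in majors_of_class])
    # two flavors of realized composition: transcript fractions (the estimand
    # of expression-based deconvolution) and plain cell-count fractions
    weights = np.zeros((n_spots, len(major_list)))
    cell_fracs = np.zeros((n_spots, len(major_list)))
    for s in range(n_spots):
        cls = rng.choice(len(classes), size=n_cells[s], p=region_probs[regions[s]])
        depths = rng.lognormal(np.log(config.spot_depth_per_cell), 0.25, size=n_cells[s])
        # spot counts are the sum of per-cell NB draws: sum the per-cell
        # gamma intensities, then one Poisson draw on the total
        mu_cells = fractions[cls] * depths[:, None] * factors[s][None, :]
        if config.nb_dispersion > 0:
            lam = rng.gamma(1.0 / config.nb_dispersion,
                            config.nb_dispersion * mu_cells).sum(axis=0)
        else:
            lam = mu_cells.sum(axis=0)
        counts[:, s] = rng.poisson(lam)
        np.add.at(weights[s], class_major_idx[cls], depths)
        np.add.at(cell_fracs[s], class_major_idx[cls], 1.0)
    weights /= weights.sum(axis=1, keepdims=True)
    cell_fracs /= cell_fracs.sum(axis=1, keepdims=True)

    spot_ids = [f"d{day}_s{rr:02d}x{cc:02d}" for rr, cc in zip(rows_idx, cols_idx)]
    table = SpotTable(pd.DataFrame({
        "spot_id": spot_ids,
        "x_um": x, "y_um": y,
        "in_tissue": True,
        "region": regions,
    }))
    matrix = CountMatrix(truth.gene_ids, spot_ids, counts)

    # planted direction field: inward unit vectors on wound spots
    direction = np.zeros((n_spots, 2))
    valid = (regions == "wound") & (r > 1e-9)
    direction[valid, 0] = (cx - x[valid]) / r[valid]
    direction[valid, 1] = (cy - y[valid]) / r[valid]
    geometries = {g for *_, g in config.lr_pairs_planted}
    if geometries == {"center_to_margin"}:
        direction = -direction

    # analytically expected wound-vs-intact lfc (spatial factors averaged per region)
    wfac = factors[regions == "wound"].mean(axis=0)
    ifac = factors[regions == "intact"].mean(axis=0)
    expected_lfc = np.log2(wound_rate * wfac + 1e-12) - np.log2(intact_rate * ifac + 1e-12)

    truth.spot_weights[day] = pd.DataFrame(weights, index=spot_ids, columns=major_list)
    truth.spot_cell_fractions[day] = pd.DataFrame(cell_fracs, index=spot_ids,
                                                  columns=major_list)
    truth.spot_regions[day] = regions.copy()
    truth.planted_direction[day] = direction
    truth.direction_valid[day] = valid
    truth.margin_mask[day] = (regions == "wound") & (r >= 0.6 * config.wound_radius_um)
    truth.region_expected_lfc[day] = pd.Series(expected_lfc, index=truth.gene_ids)
    return matrix, table


def default_lr_frame() -> pd.DataFrame:
    """The packaged ligand-receptor pair table (planted axis + null pairs)."""
    rows = [
        ("TGFB", "Tgfb1", "Tgfbr1"),
        ("SPP1", "Spp1", "Cd44"),
        ("THBS", "Thbs1", "Cd47"),
        ("OSM", "Osm", "Osmr"),
        ("Visfatin", "Nampt", "Insr"),
    ]
    return pd.DataFrame(rows, columns=["pathway", "ligand", "receptor"])
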