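"""Readers and writers for the pipeline's on-disk formats.

Count matrices travel as MatrixMarket coordinate files with companion
gene / barcode TSVs (the 10x convention, genes x observations). Spot
geometry uses the Visium tissue-positions CSV dialect with physical
micrometer coordinates; ligand-receptor pairs come in as a three-column
TSV (pathway, ligand, receptor). All readers are strict: a malformed
file raises ``FormatError`` naming the offence rather than silently
coercing.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

REGION_VOCABULARY = ("wound", "intact", "muscle", "scab", "other")


class FormatError(ValueError):
    """Raised when an input file violates its documented dialect."""


@dataclass
class CountMatrix:
    """Genes x observations matrix of nonnegative integer counts.

    ``values`` is a dense int array (desk-scale data); observations are
    cells, Visium spots, or bulk samples depending on modality.
    """

    gene_ids: list[str]
    obs_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.gene_ids = list(self.gene_ids)
        self.obs_ids = list(self.obs_ids)
        if scipy.sparse.issparse(self.values):
            self.values = np.asarray(self.values.todense())
        self.values = np.asarray(self.values)
        if self.values.shape != (len(self.gene_ids), len(self.obs_ids)):
            raise FormatError(
                f"matrix shape {self.values.shape} inconsistent with "
                f"{len(self.gene_ids)} genes x {len(self.obs_ids)} observations"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise FormatError("duplicate gene identifiers")
        if len(set(self.obs_ids)) != len(self.obs_ids):
            raise FormatError("duplicate observation identifiers")
        if self.values.size:
            if np.any(self.values < 0):
                raise FormatError("negative count")
            if not np.issubdtype(self.values.dtype, np.integer):
                if not np.allclose(self.values, np.round(self.values)):
                    raise FormatError("non-integral count")
                self.values = np.round(self.values).astype(np.int64)
        else:
            self.values = self.values.astype(np.int64)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_obs(self) -> int:
        return len(self.obs_ids)

    def gene_index(self, gene: str) -> int:
        try:
            return self.gene_ids.index(gene)
        except ValueError:
            raise KeyError(f"gene {gene!r} absent from matrix") from None

    def subset_obs(self, mask_or_ids) -> "CountMatrix":
        idx = _resolve_index(mask_or_ids, self.obs_ids)
        return CountMatrix(self.gene_ids, [self.obs_ids[i] for i in idx],
                           self.values[:, idx])

    def subset_genes(self, mask_or_ids) -> "CountMatrix":
        idx = _resolve_index(mask_or_ids, self.gene_ids)
        return CountMatrix([self.gene_ids[i] for i in idx], self.obs_ids,
                           self.values[idx, :])


@dataclass
class NormMatrix:
    """Genes x observations real-valued normalized expression (log1p CP10K)."""

    gene_ids: list[str]
    obs_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.gene_ids = list(self.gene_ids)
        self.obs_ids = list(self.obs_ids)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.obs_ids)):
            raise FormatError("normalized matrix dimensions inconsistent")
        if self.values.size and not np.all(np.isfinite(self.values)):
            raise FormatError("non-finite normalized value")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_obs(self) -> int:
        return len(self.obs_ids)

    def gene_index(self, gene: str) -> int:
        try:
            return self.gene_ids.index(gene)
        except ValueError:
            raise KeyError(f"gene {gene!r} absent from matrix") from None

    def subset_obs(self, mask_or_ids) -> "NormMatrix":
        idx = _resolve_index(mask_or_ids, self.obs_ids)
        return NormMatrix(self.gene_ids, [self.obs_ids[i] for i in idx],
                          self.values[:, idx])


def _resolve_index(mask_or_ids, universe: list[str]) -> np.ndarray:
    arr = np.asarray(mask_or_ids)
    if arr.dtype == bool:
        if arr.shape != (len(universe),):
            raise FormatError("boolean mask length mismatch")
        return np.flatnonzero(arr)
    lookup = {name: i for i, name in enumerate(universe)}
    try:
        return np.array([lookup[x] for x in mask_or_ids], dtype=int)
    except KeyError as exc:
        raise KeyError(f"identifier {exc.args[0]!r} not found") from None


@dataclass
class SpotTable:
    """Per-spot geometry and annotation (Visium tissue-positions dialect)."""

    frame: pd.DataFrame  # columns: spot_id, x_um, y_um, in_tissue, region

    def __post_init__(self) -> None:
        required = {"spot_id", "x_um", "y_um", "in_tissue", "region"}
        missing = required - set(self.frame.columns)
        if missing:
            raise FormatError(f"spot table missing columns {sorted(missing)}")
        if self.frame["spot_id"].duplicated().any():
            dup = self.frame["spot_id"][self.frame["spot_id"].duplicated()].iloc[0]
            raise FormatError(f"duplicated spot id {dup!r}")
        coords = self.frame[["x_um", "y_um"]].to_numpy(dtype=float)
        if coords.size and not np.all(np.isfinite(coords)):
            raise FormatError("non-finite spot coordinate")
        bad = set(self.frame["region"]) - set(REGION_VOCABULARY)
        if bad:
            raise FormatError(f"unknown region labels {sorted(bad)}")
        self.frame = self.frame.reset_index(drop=True)

    @property
    def spot_ids(self) -> list[str]:
        return list(self.frame["spot_id"])

    def coords(self) -> np.ndarray:
        return self.frame[["x_um", "y_um"]].to_numpy(dtype=float)

    def regions(self) -> np.ndarray:
        return self.frame["region"].to_numpy()


@dataclass
class LRDatabase:
    """Deduplicated ligand-receptor pairs grouped into pathways."""

    frame: pd.DataFrame  # columns: pathway, ligand, receptor, missing_in_matrix

    @property
    def n_pairs(self) -> int:
        return len(self.frame)

    def pairs(self):
        return list(self.frame[["pathway", "ligand", "receptor"]].itertuples(index=False, name=None))


# ---------------------------------------------------------------------------
# MatrixMarket + TSV sidecars


def write_mtx(matrix: CountMatrix, prefix: str | Path) -> None:
    """Write ``<prefix>.mtx`` plus ``<prefix>.genes.tsv`` / ``<prefix>.barcodes.tsv``."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    sparse = scipy.sparse.coo_matrix(matrix.values)
    scipy.io.mmwrite(str(prefix) + ".mtx", sparse, field="integer")
    pd.Series(matrix.gene_ids).to_csv(str(prefix) + ".genes.tsv",
                                      sep="\t", index=False, header=False)
    pd.Series(matrix.obs_ids).to_csv(str(prefix) + ".barcodes.tsv",
                                     sep="\t", index=False, header=False)


def read_mtx(prefix: str | Path) -> CountMatrix:
    """Read a matrix written by :func:`write_mtx`; strict round-trip inverse."""
    prefix = Path(prefix)
    mtx_path = Path(str(prefix) + ".mtx")
    if not mtx_path.exists():
        raise FormatError(f"missing MatrixMarket file {mtx_path}")
    try:
        values = scipy.io.mmread(str(mtx_path))
    except Exception as exc:  # scipy raises ValueError on malformed headers
        raise FormatError(f"malformed MatrixMarket file {mtx_path}: {exc}") from exc
    values = np.asarray(scipy.sparse.coo_matrix(values).todense())
    if np.any(values < 0):
        raise FormatError(f"negative count in {mtx_path}")
    genes = pd.read_csv(str(prefix) + ".genes.tsv", sep="\t", header=None)[0].astype(str).tolist()
    obs = pd.read_csv(str(prefix) + ".barcodes.tsv", sep="\t", header=None)[0].astype(str).tolist()
    if values.shape != (len(genes), len(obs)):
        raise FormatError(
            f"dimension mismatch: matrix {values.shape} vs "
            f"{len(genes)} genes / {len(obs)} barcodes")
    return CountMatrix(genes, obs, values.astype(np.int64))


# ---------------------------------------------------------------------------
# Spot positions (tissue-positions CSV dialect)

_POSITION_COLUMNS = ["barcode", "in_tissue", "array_row", "array_col", "x_um", "y_um"]


def write_spot_positions(table: SpotTable, path: str | Path,
                         array_rows=None, array_cols=None) -> None:
    df = pd.DataFrame({
        "barcode": table.frame["spot_id"],
        "in_tissue": table.frame["in_tissue"].astype(int),
        "array_row": array_rows if array_rows is not None else 0,
        "array_col": array_cols if array_cols is not None else 0,
        "x_um": table.frame["x_um"],
        "y_um": table.frame["y_um"],
        "region": table.frame["region"],
    })
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)


def read_spot_positions(path: str | Path, in_tissue_only: bool = True) -> SpotTable:
    """Read a tissue-positions CSV; region defaults to ``other`` when absent."""
    df = pd.read_csv(path)
    missing = [c for c in _POSITION_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"spot positions file missing column(s) {missing}")
    if "region" not in df.columns:
        df["region"] = "other"
    if in_tissue_only:
        df = df[df["in_tissue"].astype(int) == 1]
    frame = pd.DataFrame({
        "spot_id": df["barcode"].astype(str),
        "x_um": df["x_um"].astype(float),
        "y_um": df["y_um"].astype(float),
        "in_tissue": df["in_tissue"].astype(int).astype(bool),
        "region": df["region"].astype(str),
    })
    return SpotTable(frame)


# ---------------------------------------------------------------------------
# Ligand-receptor table


def read_lr_table(path: str | Path, expression_universe=None) -> LRDatabase:
    """Read a pathway/ligand/receptor TSV.

    Pairs are deduplicated; pairs whose genes are missing from
    ``expression_universe`` (when given) are kept but flagged so the
    caller can decide, with a warning.
    """
    df = pd.read_csv(path, sep="\t")
    for col in ("pathway", "ligand", "receptor"):
        if col not in df.columns:
            raise FormatError(f"LR table missing column {col!r}")
    if len(df) == 0:
        raise FormatError("LR table is empty")
    if df["pathway"].isna().any() or (df["pathway"].astype(str).str.len() == 0).any():
        raise FormatError("LR table has empty pathway label")
    df = df.drop_duplicates(subset=["ligand", "receptor"], keep="first").reset_index(drop=True)
    if expression_universe is not None:
        universe = set(expression_universe)
        flag = ~(df["ligand"].isin(universe) & df["receptor"].isin(universe))
        if flag.any():
            warnings.warn(
                f"{int(flag.sum())} LR pair(s) reference genes absent from the "
                "expression matrix; kept with missing_in_matrix=True")
    else:
        flag = pd.Series(False, index=df.index)
    df = df.assign(missing_in_matrix=flag.to_numpy())
    return LRDatabase(df[["pathway", "ligand", "receptor", "missing_in_matrix"]])


def write_lr_table(db_or_frame, path: str | Path) -> None:
    frame = db_or_frame.frame if isinstance(db_or_frame, LRDatabase) else db_or_frame
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    frame[["pathway", "ligand", "receptor"]].to_csv(path, sep="\t", index=False)
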