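"""Readers and writers for the on-disk formats the pipeline touches.

Canonical table dialect is TSV with a header row, UTF-8, '.' decimal
separator.  Counts travel as MatrixMarket coordinate files plus one-entry-
per-line gene and spot index files; gene sets travel as GMT.  Coordinates
are stored in micrometres as reals; the grid pitch is metadata and is never
inferred from the coordinates.

Readers validate strictly and never silently drop rows: every rejection
raises (or, where the contract allows, logs) with the offending location.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse
import yaml

from .errors import ConfigError, FormatError, ValidationError

logger = logging.getLogger(__name__)

SPOT_TABLE_COLUMNS = ["spot_id", "x_um", "y_um", "donor", "roi", "group", "stage"]
STAGES = ("early", "middle", "late", "none")

WEIGHT_SUM_TOL = 1e-6


# ---------------------------------------------------------------------------
# Spot table


def validate_spot_table(df: pd.DataFrame) -> pd.DataFrame:
    """Check the per-spot table invariants and return the frame.

    Required columns: spot_id (unique), x_um/y_um (finite reals), donor,
    roi, group.  A missing ``stage`` column is filled with ``"none"``.
    """
    missing = [c for c in SPOT_TABLE_COLUMNS[:6] if c not in df.columns]
    if missing:
        raise ValidationError(f"spot table missing columns: {missing}")
    if df["spot_id"].duplicated().any():
        dupes = df.loc[df["spot_id"].duplicated(), "spot_id"].head(3).tolist()
        raise ValidationError(f"duplicate spot_id values, e.g. {dupes}")
    coords = df[["x_um", "y_um"]].to_numpy(dtype=float)
    if not np.isfinite(coords).all():
        bad = df.loc[~np.isfinite(coords).all(axis=1), "spot_id"].head(3).tolist()
        raise ValidationError(f"non-finite coordinates for spots {bad}")
    for col in ("donor", "roi", "group"):
        if df[col].isna().any() or (df[col].astype(str) == "").any():
            raise ValidationError(f"empty values in required column '{col}'")
    if "stage" not in df.columns:
        df = df.assign(stage="none")
    else:
        bad_stage = set(df["stage"].astype(str)) - set(STAGES)
        if bad_stage:
            raise ValidationError(f"unknown stage labels: {sorted(bad_stage)}")
    return df


def read_spot_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"spot_id": str, "donor": str, "roi": str})
    return validate_spot_table(df)


def write_spot_table(df: pd.DataFrame, path: str | Path) -> None:
    validate_spot_table(df)[SPOT_TABLE_COLUMNS].to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Cell-type weights


def validate_celltype_weights(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a spot x cell-type weight frame (index = spot_id).

    Weights must be nonnegative and sum to 1 per row within 1e-6; rows
    failing either check are rejected with the spot named in the message.
    """
    w = df.to_numpy(dtype=float)
    if (w < 0).any():
        bad = df.index[(w < 0).any(axis=1)][:3].tolist()
        raise ValidationError(f"negative cell-type weight for spots {bad}")
    sums = w.sum(axis=1)
    off = np.abs(sums - 1.0) > WEIGHT_SUM_TOL
    if off.any():
        bad = df.index[off][:3].tolist()
        raise ValidationError(
            f"cell-type weights do not sum to 1 (tol {WEIGHT_SUM_TOL}) for spots {bad}"
        )
    return df


def read_celltype_weights(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col="spot_id")
    df.index = df.index.astype(str)
    return validate_celltype_weights(df)


def write_celltype_weights(df: pd.DataFrame, path: str | Path) -> None:
    validate_celltype_weights(df)
    df.to_csv(path, sep="\t", index_label="spot_id")


# ---------------------------------------------------------------------------
# Gene sets (GMT)


@dataclass
class GeneSetCollection:
    """Ordered mapping from signature name to its member gene symbols."""

    sets: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if not genes:
                raise ValidationError(f"gene set '{name}' is empty")
            if len(set(genes)) != len(genes):
                raise ValidationError(f"gene set '{name}' has duplicate symbols")

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]

    def __contains__(self, name: str) -> bool:
        return name in self.sets

    def names(self) -> list[str]:
        return list(self.sets)

    def items(self):
        return self.sets.items()


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Parse a GMT file: ``name TAB description TAB gene...`` per line.

    Duplicate genes within one line are deduplicated (first occurrence
    kept) with a logged warning; a line with fewer than three fields is a
    parse error naming the line number.
    """
    sets: dict[str, list[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}: line {lineno}: expected name, description and "
                    f"at least one gene, got {len(fields)} fields"
                )
            name = fields[0]
            genes: list[str] = []
            seen: set[str] = set()
            for g in fields[2:]:
                if not g:
                    continue
                if g in seen:
                    logger.warning(
                        "%s: line %d: duplicate gene '%s' in set '%s' dropped",
                        path, lineno, g, name,
                    )
                    continue
                seen.add(g)
                genes.append(g)
            sets[name] = genes
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path: str | Path,
              descriptions: Mapping[str, str] | None = None) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name, genes in collection.items():
            desc = (descriptions or {}).get(name, "na")
            fh.write("\t".join([name, desc, *genes]) + "\n")


# ---------------------------------------------------------------------------
# Counts matrix (MatrixMarket + index files)


@dataclass
class CountsMatrix:
    """Genes x spots expression matrix with its two index vectors."""

    matrix: scipy.sparse.spmatrix | np.ndarray
    genes: list[str]
    spots: list[str]

    def __post_init__(self) -> None:
        n_genes, n_spots = self.matrix.shape
        if n_genes != len(self.genes):
            raise ValidationError(
                f"gene index length {len(self.genes)} != matrix rows {n_genes}"
            )
        if n_spots != len(self.spots):
            raise ValidationError(
                f"spot index length {len(self.spots)} != matrix columns {n_spots}"
            )
        mn = self.matrix.min() if self.matrix.size else 0
        if mn < 0:
            raise ValidationError("counts matrix has negative entries")

    @property
    def shape(self) -> tuple[int, int]:
        return self.matrix.shape

    def dense(self) -> np.ndarray:
        if scipy.sparse.issparse(self.matrix):
            return np.asarray(self.matrix.todense())
        return np.asarray(self.matrix)

    def subset_spots(self, spot_ids: Sequence[str]) -> "CountsMatrix":
        pos = {s: i for i, s in enumerate(self.spots)}
        idx = [pos[s] for s in spot_ids]
        m = self.matrix.tocsc()[:, idx] if scipy.sparse.issparse(self.matrix) \
            else self.matrix[:, idx]
        return CountsMatrix(m, list(self.genes), [self.spots[i] for i in idx])


def _read_index(path: str | Path) -> list[str]:
    with open(path, encoding="utf-8") as fh:
        return [line.rstrip("\n") for line in fh if line.strip()]


def read_counts_mtx(mtx_path: str | Path, genes_path: str | Path,
                    spots_path: str | Path) -> CountsMatrix:
    """Read a MatrixMarket coordinate counts file with its index files."""
    matrix = scipy.io.mmread(str(mtx_path))
    if scipy.sparse.issparse(matrix):
        matrix = matrix.tocsr()
    genes = _read_index(genes_path)
    spots = _read_index(spots_path)
    if matrix.shape != (len(genes), len(spots)):
        raise FormatError(
            f"{mtx_path}: header says {matrix.shape} but index files give "
            f"({len(genes)}, {len(spots)})"
        )
    return CountsMatrix(matrix, genes, spots)


def write_counts_mtx(counts: CountsMatrix, mtx_path: str | Path,
                     genes_path: str | Path, spots_path: str | Path) -> None:
    m = counts.matrix
    if not scipy.sparse.issparse(m):
        m = scipy.sparse.coo_matrix(m)
    scipy.io.mmwrite(str(mtx_path), m)
    Path(genes_path).write_text("\n".join(counts.genes) + "\n", encoding="utf-8")
    Path(spots_path).write_text("\n".join(counts.spots) + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# Stage labels and YAML config


def read_stage_labels(path: str | Path) -> pd.DataFrame:
    """Read a per-ROI stage table: columns roi, stage."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("roi", "stage"):
        if col not in df.columns:
            raise FormatError(f"{path}: stage table missing column '{col}'")
    bad = set(df["stage"]) - set(STAGES)
    if bad:
        raise ValidationError(f"{path}: unknown stage labels {sorted(bad)}")
    return df


def write_stage_labels(df: pd.DataFrame, path: str | Path) -> None:
    df[["roi", "stage"]].to_csv(path, sep="\t", index=False)


def read_config(path: str | Path) -> dict:
    with open(path, encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ConfigError(f"{path}: top-level YAML value must be a mapping")
    return cfg
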