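"""Readers and writers for the tab-separated pipeline tables.

Conventions: all tables are UTF-8 TSV with a header row; samples are rows
and features (MAGs, traits) are columns everywhere (a transpose flag handles
the other dialect).  Readers validate contracts and never silently coerce
negative or non-numeric values; writers are byte-deterministic.
"""

from __future__ import annotations

import logging
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from magfred.exceptions import ValidationError
from magfred.redundancy import RESULT_COLUMNS

logger = logging.getLogger(__name__)

LONG_HIT_COLUMNS = {"mag_id", "trait_id", "hit_count"}
MAG_META_COLUMNS = ["total_genes", "completeness", "contamination", "order", "fraction"]
FRACTIONS = {"PA", "FL"}
BAYS = {"Chesapeake", "Delaware"}
SEASONS = {"spring", "summer"}
SALINITY_CLASSES = {"low", "medium", "high"}
FLOAT_FORMAT = "%.12g"


def _read_tsv(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"no such file: {path}")
    try:
        frame = pd.read_csv(path, sep="\t", dtype=str)
    except pd.errors.EmptyDataError as exc:
        raise ValidationError(f"empty file: {path}") from exc
    except pd.errors.ParserError as exc:
        raise ValidationError(f"malformed TSV {path}: {exc}") from exc
    if frame.empty:
        raise ValidationError(f"no data rows in {path}")
    return frame


def _to_numeric(frame: pd.DataFrame, context: str) -> pd.DataFrame:
    try:
        return frame.astype(float)
    except ValueError as exc:
        raise ValidationError(f"non-numeric value in {context}: {exc}") from exc


def read_hit_table(path: str | Path) -> pd.DataFrame:
    """Read a MAG x trait annotation hit table (wide or long layout, auto-detected).

    Long layout has columns ``mag_id``, ``trait_id``, ``hit_count``; wide
    layout has a ``mag_id`` first column and one column per trait.  Missing
    cells become 0; negative counts are a validation error naming the
    offending (mag, trait).
    """
    frame = _read_tsv(path)
    cols = set(frame.columns)
    if LONG_HIT_COLUMNS <= cols:
        extra = cols - LONG_HIT_COLUMNS
        if extra:
            logger.warning("ignoring extra columns in %s: %s", path, sorted(extra))
        long = frame[["mag_id", "trait_id", "hit_count"]].copy()
        long["hit_count"] = _to_numeric(long[["hit_count"]], f"{path}")["hit_count"]
        dup = long.duplicated(["mag_id", "trait_id"])
        if dup.any():
            pair = long.loc[dup.idxmax(), ["mag_id", "trait_id"]].tolist()
            raise ValidationError(f"duplicated (mag_id, trait_id) pair {pair} in {path}")
        wide = long.pivot(index="mag_id", columns="trait_id", values="hit_count").fillna(0.0)
    else:
        first = frame.columns[0]
        wide = frame.set_index(first)
        if wide.index.duplicated().any():
            raise ValidationError(f"duplicated mag_id in {path}")
        wide = _to_numeric(wide, f"{path}").fillna(0.0)
    wide.index.name = "mag_id"
    wide.columns.name = "trait_id"
    neg = wide < 0
    if neg.any().any():
        mag = neg.any(axis=1).idxmax()
        trait = neg.loc[mag].idxmax()
        raise ValidationError(f"negative hit count at ({mag}, {trait}) in {path}")
    if not np.allclose(wide.to_numpy() % 1, 0):
        raise ValidationError(f"non-integer hit count in {path}")
    return wide.sort_index(axis=0).sort_index(axis=1)


def read_abundance_matrix(path: str | Path, transpose: bool = False) -> pd.DataFrame:
    """Read a sample x MAG abundance matrix (``transpose=True`` for MAG x sample)."""
    frame = _read_tsv(path)
    matrix = frame.set_index(frame.columns[0])
    matrix = _to_numeric(matrix, f"{path}")
    if transpose:
        matrix = matrix.T
    if matrix.index.duplicated().any():
        dup = matrix.index[matrix.index.duplicated()][0]
        raise ValidationError(f"duplicated sample id '{dup}' in {path}")
    if (matrix < 0).any().any():
        raise ValidationError(f"negative abundance in {path}")
    if matrix.isna().any().any():
        raise ValidationError(f"missing abundance value in {path}")
    matrix.index.name = "sample_id"
    matrix.columns.name = "mag_id"
    return matrix


def check_mag_consistency(abundance: pd.DataFrame, meta: pd.DataFrame) -> pd.DataFrame:
    """Warn about abundance MAGs missing from metadata; they are retained."""
    unknown = sorted(set(abundance.columns) - set(meta.index))
    if unknown:
        logger.warning("%d MAG(s) in abundance matrix without metadata (e.g. %s); retained",
                       len(unknown), unknown[:3])
    return abundance


def read_mag_metadata(path: str | Path) -> pd.DataFrame:
    """Read MAG metadata (total_genes, completeness, contamination, order, fraction)."""
    frame = _read_tsv(path)
    if "mag_id" not in frame.columns:
        raise ValidationError(f"'mag_id' column required in {path}")
    missing = [c for c in MAG_META_COLUMNS if c not in frame.columns]
    if missing:
        raise ValidationError(f"missing MAG metadata columns in {path}: {missing}")
    meta = frame.set_index("mag_id")
    if meta.index.duplicated().any():
        raise ValidationError(f"duplicated mag_id in {path}")
    for col in ("total_genes", "completeness", "contamination"):
        meta[col] = _to_numeric(meta[[col]], f"{path}:{col}")[col]
    meta["total_genes"] = meta["total_genes"].astype(int)
    if (meta["total_genes"] < 1).any():
        raise ValidationError(f"total_genes must be >= 1 in {path}")
    if ((meta["completeness"] <= 0) | (meta["completeness"] > 100)).any():
        raise ValidationError(f"completeness must be in (0, 100] in {path}")
    if ((meta["contamination"] < 0) | (meta["contamination"] >= 100)).any():
        raise ValidationError(f"contamination must be in [0, 100) in {path}")
    bad = set(meta["fraction"]) - FRACTIONS
    if bad:
        raise ValidationError(f"unknown size fraction(s) {sorted(bad)} in {path}")
    return meta


def read_sample_metadata(path: str | Path) -> pd.DataFrame:
    """Read sample metadata; categorical fields validated, covariates may be missing."""
    frame = _read_tsv(path)
    if "sample_id" not in frame.columns:
        raise ValidationError(f"'sample_id' column required in {path}")
    meta = frame.set_index("sample_id")
    if meta.index.duplicated().any():
        raise ValidationError(f"duplicated sample_id in {path}")
    for col, allowed in (("bay", BAYS), ("season", SEASONS),
                         ("salinity_class", SALINITY_CLASSES), ("fraction", FRACTIONS)):
        if col in meta.columns:
            bad = set(meta[col].dropna()) - allowed
            if bad:
                raise ValidationError(f"invalid {col} value(s) {sorted(bad)} in {path}")
    for col in meta.columns:
        if col not in ("bay", "season", "salinity_class", "fraction"):
            meta[col] = pd.to_numeric(meta[col], errors="coerce")
    return meta


def read_trait_table(path: str | Path) -> pd.DataFrame:
    """Read a MAG x trait table of non-negative floats."""
    frame = _read_tsv(path)
    table = _to_numeric(frame.set_index(frame.columns[0]), f"{path}")
    if (table < 0).any().any():
        raise ValidationError(f"negative trait value in {path}")
    table.index.name = "mag_id"
    table.columns.name = "trait_id"
    return table


def read_subsets(path: str | Path) -> dict[str, list[str]]:
    """Read trait-subset definitions (columns: subset_name, trait_id)."""
    frame = _read_tsv(path)
    for col in ("subset_name", "trait_id"):
        if col not in frame.columns:
            raise ValidationError(f"'{col}' column required in {path}")
    subsets: dict[str, list[str]] = {}
    for name, sub in frame.groupby("subset_name", sort=True):
        subsets[str(name)] = sub["trait_id"].astype(str).tolist()
    if not subsets:
        raise ValidationError(f"no subsets defined in {path}")
    return subsets


def default_subsets() -> dict[str, list[str]]:
    """Packaged illustrative trait-subset definitions (overridable via config)."""
    with resources.as_file(resources.files("magfred.data") / "trait_subsets.tsv") as p:
        return read_subsets(p)


def read_transcript_counts(path: str | Path) -> pd.DataFrame:
    """Read per-sample gene-level transcript counts.

    Columns: sample_id, gene_id, mag_id, trait_id, gene_length, read_count.
    """
    frame = _read_tsv(path)
    required = ["sample_id", "gene_id", "mag_id", "trait_id", "gene_length", "read_count"]
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise ValidationError(f"missing transcript columns in {path}: {missing}")
    counts = frame[required].copy()
    for col in ("gene_length", "read_count"):
        counts[col] = _to_numeric(counts[[col]], f"{path}:{col}")[col].astype(int)
    if (counts["gene_length"] < 1).any():
        raise ValidationError(f"gene_length must be >= 1 in {path}")
    if (counts["read_count"] < 0).any():
        raise ValidationError(f"negative read_count in {path}")
    if counts.duplicated(["sample_id", "gene_id"]).any():
        raise ValidationError(f"duplicated (sample_id, gene_id) in {path}")
    return counts


def filter_mags(meta: pd.DataFrame, min_completeness: float = 70.0,
                max_contamination: float = 5.0) -> pd.DataFrame:
    """Quality filter: completeness strictly above and contamination strictly below.

    Thresholds must lie in (0, 100); the number of removed MAGs is logged.
    """
    for name, value in (("min_completeness", min_completeness),
                        ("max_contamination", max_contamination)):
        if not 0 < value < 100:
            raise ValidationError(f"{name} must be in (0, 100), got {value}")
    keep = (meta["completeness"] > min_completeness) & (meta["contamination"] < max_contamination)
    removed = int((~keep).sum())
    if removed:
        logger.info("quality filter removed %d of %d MAGs", removed, len(meta))
    return meta[keep]


def write_fred_results(results: pd.DataFrame, path: str | Path) -> None:
    """Write FRed results as deterministic TSV (sorted by sample_id, subset_name)."""
    if results is None or len(results) == 0:
        raise ValidationError("refusing to write empty FRed results")
    missing = [c for c in RESULT_COLUMNS if c not in results.columns]
    if missing:
        raise ValidationError(f"results missing columns: {missing}")
    out = results[RESULT_COLUMNS].sort_values(
        ["sample_id", "subset_name"], kind="mergesort")
    out.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT,
               lineterminator="\n")


def read_fred_results(path: str | Path) -> pd.DataFrame:
    """Read a FRed results TSV written by :func:`write_fred_results`."""
    frame = _read_tsv(path)
    missing = [c for c in RESULT_COLUMNS if c not in frame.columns]
    if missing:
        raise ValidationError(f"missing FRed result columns in {path}: {missing}")
    for col in ("N",):
        frame[col] = _to_numeric(frame[[col]], f"{path}:{col}")[col].astype(int)
    for col in ("D", "Q", "U", "FRed"):
        frame[col] = pd.to_numeric(frame[col], errors="coerce")
    return frame.reset_index(drop=True)


def write_matrix(matrix: pd.DataFrame, path: str | Path) -> None:
    """Write any samples/MAG x features matrix as deterministic TSV."""
    matrix.to_csv(path, sep="\t", float_format=FLOAT_FORMAT, lineterminator="\n")
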