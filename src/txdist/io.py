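"""Tab-delimited readers/writers and validation for the pipeline's data objects.

Conventions used throughout the package:

* **Expression matrix** — :class:`pandas.DataFrame` of log2 intensities,
  rows indexed by gene (probe-set) identifier, columns by sample identifier.
  On disk: TSV whose first column holds gene IDs and whose header row holds
  sample IDs.
* **Sample metadata** — :class:`pandas.DataFrame` indexed by sample ID with
  columns ``group`` and ``batch``. On disk: TSV with columns
  ``sample``, ``group``, ``batch``.
* **Marker matrix** — binary (0/1) DataFrame, markers × lines, same TSV
  layout as the expression matrix.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "read_expression",
    "write_expression",
    "read_metadata",
    "write_metadata",
    "read_markers",
    "write_markers",
    "read_gene_list",
    "write_gene_list",
    "validate_expression",
    "validate_metadata",
    "check_samples_match",
]


def validate_expression(matrix: pd.DataFrame) -> pd.DataFrame:
    """Check the expression-matrix invariants: unique gene and sample IDs,
    no missing values."""
    if matrix.index.has_duplicates:
        dups = matrix.index[matrix.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate gene identifiers: {dups[:5]}")
    if matrix.columns.has_duplicates:
        dups = matrix.columns[matrix.columns.duplicated()].unique().tolist()
        raise ValueError(f"duplicate sample identifiers: {dups[:5]}")
    if matrix.isna().any().any():
        n = int(matrix.isna().sum().sum())
        raise ValueError(f"expression matrix contains {n} missing values")
    return matrix


def validate_metadata(metadata: pd.DataFrame) -> pd.DataFrame:
    """Check metadata invariants: unique samples, group and batch per sample."""
    for col in ("group", "batch"):
        if col not in metadata.columns:
            raise ValueError(f"sample metadata lacks required column {col!r}")
        if metadata[col].isna().any():
            bad = metadata.index[metadata[col].isna()].tolist()
            raise ValueError(f"samples without {col} label: {bad[:5]}")
    if metadata.index.has_duplicates:
        dups = metadata.index[metadata.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate sample identifiers in metadata: {dups[:5]}")
    return metadata


def check_samples_match(matrix: pd.DataFrame, metadata: pd.DataFrame) -> None:
    """Every matrix sample must carry exactly one metadata row."""
    missing = [s for s in matrix.columns if s not in metadata.index]
    if missing:
        raise ValueError(f"samples without metadata: {missing[:5]}")


def read_expression(path: str | Path) -> pd.DataFrame:
    matrix = pd.read_csv(path, sep="\t", index_col=0)
    matrix.index = matrix.index.astype(str)
    matrix.columns = matrix.columns.astype(str)
    return validate_expression(matrix.astype(float))


def write_expression(matrix: pd.DataFrame, path: str | Path) -> None:
    matrix.to_csv(path, sep="\t", index_label="gene")


def read_metadata(path: str | Path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", dtype=str)
    if "sample" not in meta.columns:
        raise ValueError("metadata TSV must have a 'sample' column")
    meta = meta.set_index("sample")
    return validate_metadata(meta)


def write_metadata(metadata: pd.DataFrame, path: str | Path) -> None:
    metadata.to_csv(path, sep="\t", index_label="sample")


def read_markers(path: str | Path) -> pd.DataFrame:
    markers = pd.read_csv(path, sep="\t", index_col=0)
    if not markers.isin([0, 1]).all().all():
        raise ValueError("marker matrix must be binary 0/1")
    return markers.astype(int)


def write_markers(markers: pd.DataFrame, path: str | Path) -> None:
    markers.to_csv(path, sep="\t", index_label="marker")


def read_gene_list(path: str | Path) -> list[str]:
    """One identifier per line; blank lines ignored."""
    lines = Path(path).read_text().splitlines()
    return [ln.strip() for ln in lines if ln.strip()]


def write_gene_list(genes: Iterable[str], path: str | Path) -> None:
    Path(path).write_text("".join(f"{g}\n" for g in genes))
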