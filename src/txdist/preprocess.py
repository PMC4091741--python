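"""Normalization, meta-data assembly, batch correction and probe exclusion.

The pipeline ingests already probe-summarized log2 matrices (RMA-style).
This module provides the steps between raw per-study matrices and the
joint *meta data* the distance analysis runs on: quantile normalization,
per-gene mean-shift batch correction, gene-intersection assembly of
multiple studies, and removal of designated probes (e.g. the transgene
probes before distance calculation).
"""

from __future__ import annotations

import logging
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .io import check_samples_match, validate_expression, validate_metadata

logger = logging.getLogger(__name__)

__all__ = [
    "quantile_normalize",
    "remove_batch_effect",
    "assemble_meta_data",
    "exclude_probes",
    "log2_transform",
]


def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Force every sample onto the common quantile profile.

    The target profile is, at each rank, the mean across samples of the
    rank-th order statistics. Tied values within a sample receive the mean
    of the target values their positions span, so ties stay tied.
    """
    validate_expression(matrix)
    if matrix.shape[1] < 2:
        raise ValueError("quantile normalization needs at least two samples")
    values = matrix.to_numpy(float)
    target = np.sort(values, axis=0).mean(axis=1)
    out = np.empty_like(values)
    for j in range(values.shape[1]):
        col = values[:, j]
        order = np.argsort(col, kind="stable")
        q = np.empty_like(col)
        q[order] = target
        # average target values across each tie group
        s = pd.Series(q)
        out[:, j] = s.groupby(col).transform("mean").to_numpy()
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def remove_batch_effect(matrix: pd.DataFrame, metadata: pd.DataFrame) -> pd.DataFrame:
    """Equalize per-gene batch means: ``x' = x - mean(batch) + grand mean``.

    Per-gene grand means are preserved exactly; the correction is
    idempotent and, with a single batch, the identity.
    """
    validate_expression(matrix)
    validate_metadata(metadata)
    check_samples_match(matrix, metadata)
    batches = metadata.loc[matrix.columns, "batch"]
    grand = matrix.mean(axis=1)
    batch_means = matrix.T.groupby(batches).transform("mean").T
    return matrix - batch_means + grand.to_numpy()[:, None]


def assemble_meta_data(
    studies: Sequence[tuple[pd.DataFrame, pd.DataFrame]],
    study_labels: Sequence[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Join several studies into one meta-data matrix.

    Genes are intersected (order follows the first study); sample IDs are
    prefixed with the study label to guarantee global uniqueness. Batch
    labels default to the study label; studies that already carry finer
    (non-constant) batch labels keep them, prefixed by the study label.
    """
    if not studies:
        raise ValueError("need at least one study")
    if study_labels is None:
        study_labels = [f"study{i + 1}" for i in range(len(studies))]
    if len(study_labels) != len(studies):
        raise ValueError("one label per study required")

    common = studies[0][0].index
    for matrix, _ in studies[1:]:
        common = common[common.isin(matrix.index)]
    if len(common) == 0:
        counts = ", ".join(
            f"{lab}: {len(m.index)} genes" for lab, (m, _) in zip(study_labels, studies)
        )
        raise ValueError(f"no genes shared by all studies ({counts})")

    matrices, metas = [], []
    for label, (matrix, meta) in zip(study_labels, studies):
        validate_expression(matrix)
        validate_metadata(meta)
        check_samples_match(matrix, meta)
        rename = {s: f"{label}:{s}" for s in matrix.columns}
        sub = matrix.loc[common].rename(columns=rename)
        meta = meta.loc[matrix.columns].rename(index=rename).copy()
        if meta["batch"].nunique() > 1:
            meta["batch"] = [f"{label}:{b}" for b in meta["batch"]]
        else:
            meta["batch"] = label
        matrices.append(sub)
        metas.append(meta)
    combined = pd.concat(matrices, axis=1)
    combined_meta = pd.concat(metas, axis=0)
    validate_expression(combined)
    return combined, combined_meta


def exclude_probes(matrix: pd.DataFrame, ids: Iterable[str]) -> pd.DataFrame:
    """Drop the listed probe rows; absent IDs are reported, not fatal."""
    ids = list(ids)
    present = [g for g in ids if g in matrix.index]
    missing = [g for g in ids if g not in matrix.index]
    if missing:
        logger.warning("exclusion list contains %d absent IDs: %s",
                       len(missing), missing[:5])
    return matrix.drop(index=present)


def log2_transform(matrix: pd.DataFrame, pseudocount: float = 0.0) -> pd.DataFrame:
    """log2-transform a linear-scale matrix (for inputs not already log2)."""
    shifted = matrix + pseudocount
    if (shifted <= 0).any().any():
        raise ValueError("non-positive values; supply a pseudocount")
    return np.log2(shifted)
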