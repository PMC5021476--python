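"""Expression preprocessing: prevalence filter, quantile normalization,
log2 transform, per-batch mean centering, and a PCA QC surface.

The canonical order is prevalence_filter -> quantile_normalize ->
log2_transform -> remove_batch_effect; :func:`preprocess_pipeline` enforces
it. An alternative log-then-normalize order is exposed through the
``order`` argument because sequencing pipelines differ on this point; the
default normalizes on the linear scale first.
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd

from mirlink.io_annotation import ExpressionMatrix, SampleAnnotation

logger = logging.getLogger(__name__)


def prevalence_filter(m: ExpressionMatrix, min_fraction: float = 0.5) -> ExpressionMatrix:
    """Keep features detected (value > 0) in at least half the samples.

    "At least half" means ``count(value > 0) >= ceil(n_samples *
    min_fraction)``; feature order is preserved.
    """
    if m.n_features == 0 or m.n_samples == 0:
        raise ValueError("empty expression matrix")
    if m.scale != "linear":
        raise ValueError("prevalence filter expects linear-scale values")
    threshold = math.ceil(m.n_samples * min_fraction)
    detected = (m.data.to_numpy() > 0).sum(axis=1)
    keep = detected >= threshold
    return ExpressionMatrix(m.data.loc[keep].copy(), m.scale)


def quantile_normalize(m: ExpressionMatrix) -> ExpressionMatrix:
    """Force every sample (column) onto the common mean quantile profile.

    After normalization each column's sorted values equal the across-column
    mean of sorted values. Ties within a column receive the mean of the
    reference values at their tied positions, so ties stay tied.
    """
    if m.scale != "linear":
        raise ValueError("quantile normalization expects linear-scale values")
    if m.n_samples < 2:
        logger.warning("quantile_normalize: fewer than 2 samples, returning input unchanged")
        return ExpressionMatrix(m.data.copy(), m.scale)
    x = m.data.to_numpy(dtype=float)
    ref = np.sort(x, axis=0).mean(axis=1)  # mean quantile profile, length n_features
    out = np.empty_like(x)
    for j in range(x.shape[1]):
        col = x[:, j]
        order = np.argsort(col, kind="stable")
        assigned = np.empty_like(ref)
        assigned[order] = ref
        # ties get the mean of the reference values at their tied positions
        if np.unique(col).size < col.size:
            assigned = pd.Series(assigned).groupby(col).transform("mean").to_numpy()
        out[:, j] = assigned
    return ExpressionMatrix(pd.DataFrame(out, index=m.data.index, columns=m.data.columns), m.scale)


def log2_transform(m: ExpressionMatrix, offset: float = 1.0) -> ExpressionMatrix:
    """log2(value + offset); the default pseudocount of 1 keeps zeros at 0."""
    if m.scale != "linear":
        raise ValueError("matrix is already log-scale")
    if offset < 0:
        raise ValueError("offset must be >= 0")
    x = m.data.to_numpy(dtype=float) + offset
    if (x <= 0).any():
        raise ValueError("value + offset <= 0; log2 undefined")
    out = np.log2(x)
    return ExpressionMatrix(
        pd.DataFrame(out, index=m.data.index, columns=m.data.columns), scale="log2"
    )


def remove_batch_effect(m: ExpressionMatrix, annot: SampleAnnotation) -> ExpressionMatrix:
    """Subtract, per feature, the mean of each batch from that batch's samples.

    Afterwards every (feature, batch) mean is zero, so the operation is
    idempotent. A single batch collapses to global per-feature centering.
    """
    if m.scale != "log2":
        raise ValueError("batch removal operates on log2-scale values")
    batches = annot.batches_for(m.sample_ids)
    x = m.data.to_numpy(dtype=float).copy()
    for batch in batches.unique():
        cols = np.flatnonzero((batches == batch).to_numpy())
        if cols.size == 0:
            continue
        x[:, cols] -= x[:, cols].mean(axis=1, keepdims=True)
    return ExpressionMatrix(
        pd.DataFrame(x, index=m.data.index, columns=m.data.columns), scale="log2"
    )


def pca_qc(m: ExpressionMatrix, annot: SampleAnnotation) -> pd.DataFrame:
    """Scores of the first two principal components per sample, for QC plots.

    Samples are observations, features variables; the feature-centered
    matrix is decomposed by SVD with no variance scaling. Sign convention:
    each component's largest-magnitude loading is made positive, so output
    is deterministic.

    Returns a DataFrame with columns sample_id, PC1, PC2, group, batch.
    """
    if m.scale != "log2":
        raise ValueError("PCA QC expects log2-scale values")
    if m.n_samples < 3:
        raise ValueError("PCA QC needs at least 3 samples")
    x = m.data.to_numpy(dtype=float).T  # samples x features
    x = x - x.mean(axis=0, keepdims=True)
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    scores = u[:, :2] * s[:2]
    for k in range(2):
        j = np.argmax(np.abs(vt[k]))
        if vt[k, j] < 0:
            scores[:, k] = -scores[:, k]
    groups = [annot.group_of(sid) for sid in m.sample_ids]
    batches = annot.batches_for(m.sample_ids).to_list()
    return pd.DataFrame(
        {
            "sample_id": m.sample_ids,
            "PC1": scores[:, 0],
            "PC2": scores[:, 1],
            "group": groups,
            "batch": batches,
        }
    )


def preprocess_pipeline(
    m: ExpressionMatrix,
    annot: SampleAnnotation,
    order: str = "normalize-then-log",
    log_offset: float = 1.0,
    min_fraction: float = 0.5,
) -> ExpressionMatrix:
    """Run the full preprocessing chain in its canonical order.

    ``order`` is "normalize-then-log" (default) or "log-then-normalize";
    the prevalence filter always runs first and batch centering last.
    """
    m = prevalence_filter(m, min_fraction=min_fraction)
    if order == "normalize-then-log":
        m = quantile_normalize(m)
        m = log2_transform(m, offset=log_offset)
    elif order == "log-then-normalize":
        m = log2_transform(m, offset=log_offset)
        # quantile normalization is scale-agnostic arithmetic; retag to reuse it
        tmp = ExpressionMatrix(m.data, scale="linear")
        tmp = quantile_normalize(tmp)
        m = ExpressionMatrix(tmp.data, scale="log2")
    else:
        raise ValueError(f"unknown preprocessing order: {order!r}")
    return remove_batch_effect(m, annot)
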