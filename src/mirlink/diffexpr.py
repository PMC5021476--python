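"""Differential expression between histotype groups.

The statistic stack is deliberately simple and robust: a median-based fold
change (MBFC) guards against outliers, a Welch two-sample t-test supplies
p-values, and Benjamini-Hochberg step-up adjustment controls the FDR. A
feature is called significant when FDR < 0.05 and its MBFC falls outside
the [0.8, 1.25] indifference band. Low-information features are removed
beforehand by a first-quartile variance filter.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from mirlink.io_annotation import ExpressionMatrix, SampleAnnotation

logger = logging.getLogger(__name__)

FDR_THRESHOLD = 0.05
MBFC_HI = 1.25
MBFC_LO = 0.8


@dataclass
class DiffExprRecord:
    feature_id: str
    mbfc: float  # linear-scale ratio of group medians, group1/group2
    t_stat: float
    p_value: float
    fdr: float
    significant: bool
    direction: str  # "up" or "down" in group1 relative to group2


def median_fold_change(x1: Sequence[float], x2: Sequence[float], eps: float = 1e-9) -> float:
    """Ratio of group medians, ``(median(x1)+eps) / (median(x2)+eps)``.

    Inputs must be linear-scale; the pseudocount guards zero medians.
    Using medians rather than means makes the fold change insensitive to a
    single extreme sample.
    """
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    if x1.size == 0 or x2.size == 0:
        raise ValueError("empty group in median_fold_change")
    return float((np.median(x1) + eps) / (np.median(x2) + eps))


def variance_filter(m: ExpressionMatrix, quantile: float = 0.25) -> ExpressionMatrix:
    """Drop features whose sample variance is not above the Q1 of variances.

    The quartile is computed over per-feature variances with the linear
    interpolation convention. Features with variance strictly greater than
    that quartile are kept; if all variances are equal, everything is kept
    (a strict cut would empty the matrix).
    """
    if m.n_features < 4:
        raise ValueError("variance filter needs at least 4 features")
    variances = m.data.to_numpy(dtype=float).var(axis=1, ddof=1)
    q1 = float(np.quantile(variances, quantile))
    keep = variances > q1
    if not keep.any():
        logger.warning("variance_filter: all variances equal, keeping all features")
        return ExpressionMatrix(m.data.copy(), m.scale)
    return ExpressionMatrix(m.data.loc[keep].copy(), m.scale)


def welch_t_test(x1: Sequence[float], x2: Sequence[float]) -> tuple[float, float]:
    """Two-sided Welch (unequal-variance) t-test.

    Returns (t, p) with p from the t distribution at Welch-Satterthwaite
    degrees of freedom. Degenerate zero-variance inputs: equal means give
    (0, 1); unequal means give (+/-inf, 0).
    """
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    if x1.size < 2 or x2.size < 2:
        raise ValueError("welch_t_test needs at least 2 values per group")
    m1, m2 = x1.mean(), x2.mean()
    v1, v2 = x1.var(ddof=1), x2.var(ddof=1)
    n1, n2 = x1.size, x2.size
    se2 = v1 / n1 + v2 / n2
    if se2 == 0.0:
        if m1 == m2:
            return 0.0, 1.0
        logger.warning("welch_t_test: zero variance in both groups with unequal means")
        return (np.inf if m1 > m2 else -np.inf), 0.0
    t = (m1 - m2) / np.sqrt(se2)
    df = se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(min(p, 1.0))


def bh_fdr(p_values: Sequence[float], m_total: int | None = None) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    ``m_total`` overrides the multiple-testing family size (must be at
    least ``len(p_values)``); by default the family is the input vector
    itself. Adjusted value i is ``min_{j>=i} p_(j) * m / j`` on the sorted
    scale, capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p) if m_total is None else int(m_total)
    if m < len(p):
        raise ValueError("m_total must be >= number of p-values")
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, len(p) + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty_like(adjusted)
    out[order] = adjusted
    return out


def _back_transform(x: np.ndarray) -> np.ndarray:
    """Map log2 values back to a linear (ratio) scale.

    Plain 2^x: since the exponential is monotone, median(2^x) = 2^median(x),
    so the MBFC of back-transformed values is exactly 2 to the difference of
    group medians on the log scale. This stays well defined for centered
    (batch-removed) data, where subtracting the log pseudocount would push
    medians to zero and destroy the ratio semantics of the 1.25/0.8 bounds.
    """
    return np.exp2(x)


def differential_table(
    m: ExpressionMatrix,
    annot: SampleAnnotation,
    group1: str,
    group2: str,
    fdr_threshold: float = FDR_THRESHOLD,
    mbfc_hi: float = MBFC_HI,
    mbfc_lo: float = MBFC_LO,
    m_total: int | None = None,
    apply_variance_filter: bool = True,
) -> list[DiffExprRecord]:
    """Per-feature differential-expression records for group1 vs group2.

    The variance filter runs first; for each surviving feature the MBFC is
    computed on back-transformed linear values (fold-change thresholds are
    ratios), the Welch t-test on the log2 values, and BH-FDR across the
    surviving features. Significant = FDR below threshold AND MBFC outside
    [mbfc_lo, mbfc_hi]. Output is sorted by FDR ascending (ties by p, then
    feature id).
    """
    s1 = annot.samples_in_group(group1)
    s2 = annot.samples_in_group(group2)
    s1 = [s for s in s1 if s in m.data.columns]
    s2 = [s for s in s2 if s in m.data.columns]
    if len(s1) < 2 or len(s2) < 2:
        raise ValueError("each group needs at least 2 samples in the matrix")
    if apply_variance_filter:
        m = variance_filter(m)
    x1 = m.data.loc[:, s1].to_numpy(dtype=float)
    x2 = m.data.loc[:, s2].to_numpy(dtype=float)
    if m.scale == "log2":
        lin1, lin2 = _back_transform(x1), _back_transform(x2)
    else:
        lin1, lin2 = x1, x2
    records: list[DiffExprRecord] = []
    pvals = np.empty(m.n_features)
    tstats = np.empty(m.n_features)
    mbfcs = np.empty(m.n_features)
    for i in range(m.n_features):
        tstats[i], pvals[i] = welch_t_test(x1[i], x2[i])
        mbfcs[i] = median_fold_change(lin1[i], lin2[i])
    fdrs = bh_fdr(pvals, m_total=m_total)
    for i, fid in enumerate(m.feature_ids):
        sig = bool(fdrs[i] < fdr_threshold and (mbfcs[i] > mbfc_hi or mbfcs[i] < mbfc_lo))
        records.append(
            DiffExprRecord(
                feature_id=fid,
                mbfc=float(mbfcs[i]),
                t_stat=float(tstats[i]),
                p_value=float(pvals[i]),
                fdr=float(fdrs[i]),
                significant=sig,
                direction="up" if mbfcs[i] >= 1.0 else "down",
            )
        )
    records.sort(key=lambda r: (r.fdr, r.p_value, r.feature_id))
    return records


def select_top_markers(records: Sequence[DiffExprRecord], k: int = 8) -> list[str]:
    """The k lowest-FDR significant features (a compact marker panel).

    Ties in FDR are broken by larger |log2(MBFC)| then feature id. Fewer
    than k significant features returns them all with a warning.
    """
    sig = [r for r in records if r.significant]
    if len(sig) < k:
        logger.warning("select_top_markers: only %d significant features (< k=%d)", len(sig), k)
    eps = 1e-300
    sig.sort(key=lambda r: (r.fdr, -abs(np.log2(max(r.mbfc, eps))), r.feature_id))
    return [r.feature_id for r in sig[:k]]


def records_to_frame(records: Sequence[DiffExprRecord]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in records])
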