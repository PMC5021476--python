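"""Group-wise all-pairs Spearman screen for inverse miRNA-mRNA correlation.

Every (miRNA isoform, gene) pair is correlated over one histotype group's
samples. At cohort scale this is tens of millions of pairs, so ranks are
computed once per feature and correlations come from chunked matrix
products over standardized ranks; the result is identical (to numerical
precision) to calling a pairwise Spearman per pair. P-values use the usual
t-approximation t = r * sqrt((n-2)/(1-r^2)) with n-2 degrees of freedom;
BH-FDR is applied per group over the full pair family, then records are
filtered to the best inverse correlations (r < -0.6 by default) and, for
final calling, to per-group strict thresholds that tighten as the group's
sample size grows.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Iterator, Sequence

import numpy as np
from scipy import stats
from scipy.stats import rankdata

from mirlink.io_annotation import ExpressionMatrix, SampleAnnotation

logger = logging.getLogger(__name__)

#: default screen threshold for "best inverse correlations"
SCREEN_THRESHOLD = -0.6

#: per-group strict thresholds; smaller groups demand stronger correlation
STRICT_THRESHOLDS = {"cPTC": -0.65, "fvPTC": -0.70, "tcPTC": -0.80}


@dataclass
class CorrelationRecord:
    mirna_id: str
    gene_id: str
    group: str
    r: float
    p_value: float
    fdr: float = float("nan")


def spearman(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Spearman rank correlation with average ranks for ties.

    Returns (r, p); p is two-sided from the t-approximation, exactly 0 at
    r = +/-1. A constant input vector makes r undefined: returns
    (nan, nan).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("length mismatch")
    if x.size < 4:
        raise ValueError("spearman needs at least 4 observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return float("nan"), float("nan")
    rx = rankdata(x, method="average")
    ry = rankdata(y, method="average")
    rx = (rx - rx.mean()) / rx.std()
    ry = (ry - ry.mean()) / ry.std()
    r = float(np.clip(np.mean(rx * ry), -1.0, 1.0))
    return r, _p_from_r(r, x.size)


def _p_from_r(r: float, n: int) -> float:
    if abs(r) >= 1.0:
        return 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    return float(2.0 * stats.t.sf(abs(t), n - 2))


def _standardized_ranks(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise average ranks, centered and scaled to unit norm.

    Returns (ranks, constant_mask); constant rows are zeroed and flagged.
    """
    n = values.shape[1]
    ranks = np.apply_along_axis(rankdata, 1, values)
    ranks -= ranks.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(ranks, axis=1)
    constant = norms == 0
    norms[constant] = 1.0
    ranks /= norms[:, None]
    ranks[constant] = 0.0
    return ranks, constant


def all_pairs_screen(
    mirna: ExpressionMatrix,
    mrna: ExpressionMatrix,
    annot: SampleAnnotation,
    group: str,
    chunk_size: int = 256,
) -> Iterator[CorrelationRecord]:
    """Stream Spearman records for every (miRNA, gene) pair in one group.

    Both matrices are restricted to the group's samples (which must agree
    between the two). Ranks are computed once per feature; correlations are
    dot products of standardized rank vectors, evaluated in chunks of
    ``chunk_size`` miRNA rows so peak memory is O(chunk_size x n_genes).
    Pairs involving a constant feature get r = nan and are excluded from
    the FDR family downstream. Traversal order (miRNA-major, gene order as
    in the matrix) is fixed, so output is deterministic.
    """
    samples = [s for s in annot.samples_in_group(group) if s in mirna.data.columns]
    if set(mirna.sample_ids) != set(mrna.sample_ids):
        raise ValueError("miRNA and mRNA matrices cover different sample sets")
    if len(samples) < 4:
        raise ValueError(f"group {group!r} has fewer than 4 samples")
    if chunk_size < 1:
        raise ValueError("chunk_size must be >= 1")
    xm = mirna.data.loc[:, samples].to_numpy(dtype=float)
    xg = mrna.data.loc[:, samples].to_numpy(dtype=float)
    n = len(samples)
    rm, const_m = _standardized_ranks(xm)
    rg, const_g = _standardized_ranks(xg)
    n_const = int(const_m.sum()) + int(const_g.sum())
    if n_const:
        logger.warning("all_pairs_screen: %d constant features yield NaN correlations", n_const)
    mirna_ids = mirna.feature_ids
    gene_ids = mrna.feature_ids
    for start in range(0, rm.shape[0], chunk_size):
        stop = min(start + chunk_size, rm.shape[0])
        block = np.clip(rm[start:stop] @ rg.T, -1.0, 1.0)  # (chunk, n_genes)
        with np.errstate(divide="ignore"):
            tstat = block * np.sqrt((n - 2) / (1.0 - block * block))
        pblock = 2.0 * stats.t.sf(np.abs(tstat), n - 2)
        pblock[np.abs(block) >= 1.0] = 0.0
        for bi, mi in enumerate(range(start, stop)):
            for gi in range(rg.shape[0]):
                if const_m[mi] or const_g[gi]:
                    yield CorrelationRecord(mirna_ids[mi], gene_ids[gi], group, float("nan"), float("nan"))
                else:
                    yield CorrelationRecord(
                        mirna_ids[mi], gene_ids[gi], group,
                        float(block[bi, gi]), float(pblock[bi, gi]),
                    )


def fdr_and_filter(
    records: Iterable[CorrelationRecord],
    threshold: float = SCREEN_THRESHOLD,
) -> list[CorrelationRecord]:
    """BH-adjust one group's pair family, keep r strictly below threshold.

    The FDR family is every non-NaN pair emitted for the group (NaN records
    from constant features are excluded from the family size and dropped).
    The returned list is sorted by r ascending, ties by (mirna_id, gene_id).
    """
    from mirlink.diffexpr import bh_fdr  # local import to avoid cycle at import time

    if threshold >= 0:
        raise ValueError("inverse-correlation screen needs a negative threshold")
    recs = [r for r in records if not np.isnan(r.r)]
    groups = {r.group for r in recs}
    if len(groups) > 1:
        raise ValueError(f"records from multiple groups: {sorted(groups)}")
    if recs:
        fdrs = bh_fdr([r.p_value for r in recs])
        for rec, q in zip(recs, fdrs):
            rec.fdr = float(q)
    kept = [r for r in recs if r.r < threshold]
    kept.sort(key=lambda r: (r.r, r.mirna_id, r.gene_id))
    return kept


def strict_threshold(
    records: Sequence[CorrelationRecord],
    group: str,
    thresholds: dict[str, float] | None = None,
) -> list[CorrelationRecord]:
    """Apply the per-group strict cut (r strictly below the group's bound)."""
    thresholds = STRICT_THRESHOLDS if thresholds is None else thresholds
    if group not in thresholds:
        raise ValueError(f"unknown group {group!r}; have thresholds for {sorted(thresholds)}")
    cut = thresholds[group]
    return [r for r in records if r.group == group and r.r < cut]
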