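"""Joining correlation and prediction evidence into final regulation calls.

The funnel mirrors the staged screen: (a) pairs with inverse correlation
below the screen threshold, (b) of those, pairs predicted by at least one
sequence predictor, (c) pairs predicted independently by both. Candidates
surviving the per-group strict correlation cut with both predictors are
then tested by the seed-weighted ranking stage; a final regulation call
requires all three confirmations. Stage counts are first-class outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from mirlink.correlation_screen import (
    SCREEN_THRESHOLD,
    STRICT_THRESHOLDS,
    CorrelationRecord,
    all_pairs_screen,
    fdr_and_filter,
    strict_threshold,
)
from mirlink.io_annotation import ExpressionMatrix, SampleAnnotation
from mirlink.preprocess import pca_qc, preprocess_pipeline
from mirlink.synthetic_data import SimulationConfig, simulate_expression, simulate_sequences
from mirlink.target_prediction import (
    MIN_MIRANDA_SCORE,
    MirnaSequence,
    PredictionRecord,
    TranscriptRegions,
    format_targetrank,
    predict_pair,
    targetrank_confirmed,
    targetrank_like,
)

logger = logging.getLogger(__name__)


@dataclass
class RegulationCandidate:
    """One (miRNA, gene) pair with all accumulated evidence (a report row)."""

    regulation_name: str
    group: str
    mirna_id: str
    gene_id: str
    r: float
    fdr: float
    predicted_targetscan: bool
    predicted_miranda: bool
    passed_strict: bool
    targetrank_confirmed: bool = False
    targetrank_rank: int | None = None
    targetrank_score: float = 0.0

    @property
    def n_predictors(self) -> int:
        return int(self.predicted_targetscan) + int(self.predicted_miranda)


@dataclass
class FunnelCounts:
    """Stage attrition counts for one group's screen."""

    group: str
    screened: int  # stage (a): pairs below the inverse-correlation screen threshold
    one_predictor: int  # stage (b): additionally predicted by >= 1 tool
    both_predictors: int  # stage (c): predicted by both tools
    strict: int = 0  # stage (c) pairs also below the group's strict threshold
    final: int = 0  # confirmed by the ranking stage as well
    # same counts with isoform ids collapsed to mature names, when a map is given
    screened_mature: int | None = None
    both_predictors_mature: int | None = None


def build_funnel(
    corr: Sequence[CorrelationRecord],
    preds: Mapping[tuple[str, str], PredictionRecord],
    group: str,
    strict_thresholds: dict[str, float] | None = None,
    mature_map: Mapping[str, str] | None = None,
) -> tuple[list[RegulationCandidate], FunnelCounts]:
    """Attach predictor verdicts to screened pairs and count the stages.

    ``corr`` is one group's screened (already FDR-annotated and
    threshold-filtered) records; ``preds`` maps (mirna_id, gene_id) to the
    pair's predictor verdicts (missing pairs count as predicted by
    neither). Candidates are named ``{GROUP}_{k}`` by r ascending, ties by
    (mirna_id, gene_id). When ``mature_map`` is given, counts collapsed to
    mature miRNA names are reported alongside the isoform-level counts.
    """
    bad = [c for c in corr if c.group != group]
    if bad:
        raise ValueError(f"correlation records from group {bad[0].group!r}, expected {group!r}")
    ordered = sorted(corr, key=lambda c: (c.r, c.mirna_id, c.gene_id))
    strict_ok = {c.mirna_id + "\t" + c.gene_id for c in strict_threshold(ordered, group, strict_thresholds)}
    candidates = []
    for k, c in enumerate(ordered, start=1):
        pred = preds.get((c.mirna_id, c.gene_id))
        candidates.append(
            RegulationCandidate(
                regulation_name=f"{group}_{k}",
                group=group,
                mirna_id=c.mirna_id,
                gene_id=c.gene_id,
                r=c.r,
                fdr=c.fdr,
                predicted_targetscan=bool(pred and pred.predicted_targetscan),
                predicted_miranda=bool(pred and pred.predicted_miranda),
                passed_strict=(c.mirna_id + "\t" + c.gene_id) in strict_ok,
            )
        )
    counts = FunnelCounts(
        group=group,
        screened=len(candidates),
        one_predictor=sum(1 for c in candidates if c.n_predictors >= 1),
        both_predictors=sum(1 for c in candidates if c.n_predictors == 2),
        strict=sum(1 for c in candidates if c.passed_strict and c.n_predictors == 2),
    )
    if mature_map is not None:
        def mat(c: RegulationCandidate) -> tuple[str, str]:
            return (mature_map.get(c.mirna_id, c.mirna_id), c.gene_id)

        counts.screened_mature = len({mat(c) for c in candidates})
        counts.both_predictors_mature = len({mat(c) for c in candidates if c.n_predictors == 2})
    return candidates, counts


def confirm_final(
    candidates: Sequence[RegulationCandidate],
    targetrank_records: Mapping[tuple[str, str], PredictionRecord],
    rank_max: int = 100,
    score_min: float = 0.25,
) -> list[RegulationCandidate]:
    """Final regulation calls: both predictors, strict cut, ranking confirmed.

    The ranking stage is consulted only for candidates that already pass
    the strict threshold with both predictors (the staged design keeps the
    expensive confirmation off everything else). Output is sorted by r
    ascending.
    """
    final = []
    for c in candidates:
        if not (c.passed_strict and c.n_predictors == 2):
            continue
        tr = targetrank_records.get((c.mirna_id, c.gene_id))
        if tr is not None:
            c.targetrank_rank = tr.targetrank_rank
            c.targetrank_score = tr.targetrank_score
            c.targetrank_confirmed = targetrank_confirmed(tr, rank_max, score_min)
        if c.targetrank_confirmed:
            final.append(c)
    final.sort(key=lambda c: (c.r, c.mirna_id, c.gene_id))
    return final


def candidates_to_frame(candidates: Sequence[RegulationCandidate]) -> pd.DataFrame:
    rows = []
    for c in candidates:
        row = asdict(c)
        row["n_predictors"] = c.n_predictors
        row["targetrank"] = format_targetrank(c, c.targetrank_confirmed)
        rows.append(row)
    cols = [
        "regulation_name", "group", "mirna_id", "gene_id", "r", "fdr",
        "predicted_targetscan", "predicted_miranda", "n_predictors",
        "passed_strict", "targetrank", "targetrank_rank", "targetrank_score",
    ]
    return pd.DataFrame(rows, columns=cols)


def screen_and_integrate(
    mirna: ExpressionMatrix,
    mrna: ExpressionMatrix,
    annot: SampleAnnotation,
    group: str,
    mirnas: Sequence[MirnaSequence],
    transcripts: Sequence[TranscriptRegions],
    screen_cut: float = SCREEN_THRESHOLD,
    strict_cuts: dict[str, float] | None = None,
    min_score: float = MIN_MIRANDA_SCORE,
    rank_max: int = 100,
    score_min: float = 0.25,
    chunk_size: int = 256,
    mature_map: Mapping[str, str] | None = None,
) -> tuple[list[RegulationCandidate], list[RegulationCandidate], FunnelCounts]:
    """One group's screen -> prediction -> funnel -> final confirmation.

    Matrices must already be preprocessed (log2 scale). Returns
    (candidates, final, funnel_counts). Sequence predictors run only on the
    pairs that survive the correlation screen; the ranking stage runs only
    for miRNAs with strict both-predictor candidates, over all transcripts.
    """
    strict_cuts = STRICT_THRESHOLDS if strict_cuts is None else strict_cuts
    mir_by_id = {m.mature_name: m for m in mirnas}
    tr_by_gene = {t.gene_id: t for t in transcripts}
    mature = (lambda i: mature_map.get(i, i)) if mature_map is not None else (lambda i: i)

    stream = all_pairs_screen(mirna, mrna, annot, group, chunk_size=chunk_size)
    screened = fdr_and_filter(stream, threshold=screen_cut)

    preds: dict[tuple[str, str], PredictionRecord] = {}
    for c in screened:
        key = (c.mirna_id, c.gene_id)
        if key in preds:
            continue
        mir = mir_by_id.get(mature(c.mirna_id))
        regions = tr_by_gene.get(c.gene_id)
        rec = PredictionRecord(c.mirna_id, c.gene_id)
        if mir is not None and regions is not None:
            ts, mr, _sites = predict_pair(mir, regions, min_score=min_score)
            rec.predicted_targetscan, rec.predicted_miranda = ts, mr
        preds[key] = rec

    candidates, counts = build_funnel(screened, preds, group, strict_cuts, mature_map)

    need_rank = {
        mature(c.mirna_id)
        for c in candidates
        if c.passed_strict and c.n_predictors == 2 and mature(c.mirna_id) in mir_by_id
    }
    targetrank: dict[tuple[str, str], PredictionRecord] = {}
    for mid in sorted(need_rank):
        for rec in targetrank_like(mir_by_id[mid], list(transcripts)):
            targetrank[(mid, rec.gene_id)] = rec
    tr_lookup = {
        (c.mirna_id, c.gene_id): targetrank[(mature(c.mirna_id), c.gene_id)]
        for c in candidates
        if (mature(c.mirna_id), c.gene_id) in targetrank
    }
    final = confirm_final(candidates, tr_lookup, rank_max, score_min)
    counts.final = len(final)
    for c in final:
        assert c.r < strict_cuts[group], "final record above the strict threshold"
    return candidates, final, counts


def run_pipeline(config: Mapping | str | Path, out_dir: str | Path | None = None) -> Path:
    """Execute the full discovery pipeline from a config mapping or YAML path.

    Config keys (all optional except the data source):

    * ``simulate``: SimulationConfig fields — generate a synthetic cohort; or
    * ``inputs``: paths ``mirna``, ``mrna``, ``annotations``, ``mirna_fasta``,
      ``regions_fasta`` for real data;
    * ``preprocess``: ``order``, ``log_offset``;
    * ``screen``: ``threshold``, ``strict_thresholds``, ``chunk_size``;
    * ``predict``: ``min_score``, ``rank_max``, ``score_min``;
    * ``groups``: which histotype groups to screen (default: all with >= 4
      samples);
    * ``out_dir``, ``seed``.

    Writes per-stage TSVs, PCA QC scatter plots (PNG + TSV), per-group
    candidate tables, the final regulation table, funnel counts as JSON,
    and a run log carrying the config hash. Reruns with the same config
    are byte-identical.
    """
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    config = dict(config)
    out = Path(out_dir or config.get("out_dir", "mirlink_out"))
    out.mkdir(parents=True, exist_ok=True)
    cfg_text = json.dumps(config, sort_keys=True, default=str)
    cfg_hash = hashlib.sha256(cfg_text.encode()).hexdigest()[:16]
    log_lines = [f"config_hash={cfg_hash}", f"seed={config.get('seed', 0)}"]

    stage = "ingest"
    try:
        if "simulate" in config:
            sim = dict(config["simulate"])
            sim.setdefault("seed", config.get("seed", 0))
            cfg = SimulationConfig(**sim)
            mirna, mrna, annot, truth = simulate_expression(cfg)
            mirnas, transcripts = simulate_sequences(
                truth, mirna.feature_ids, mrna.feature_ids, seed=cfg.seed + 1
            )
            truth.to_tsv(out / "ground_truth.tsv")
        elif "inputs" in config:
            from mirlink.io_annotation import read_gene_counts
            from mirlink.target_prediction import read_mirna_fasta, read_regions_fasta

            inputs = config["inputs"]
            mirna = ExpressionMatrix.from_tsv(inputs["mirna"])
            mrna = read_gene_counts(inputs["mrna"])
            annot = SampleAnnotation.from_tsv(inputs["annotations"])
            mirnas = read_mirna_fasta(inputs["mirna_fasta"])
            transcripts = read_regions_fasta(inputs["regions_fasta"])
            truth = None
        else:
            raise ValueError("config needs a 'simulate' or 'inputs' section")

        stage = "preprocess"
        pp = config.get("preprocess", {})
        mirna_pp = preprocess_pipeline(
            mirna, annot, order=pp.get("order", "normalize-then-log"),
            log_offset=pp.get("log_offset", 1.0),
        )
        mrna_pp = preprocess_pipeline(
            mrna, annot, order=pp.get("order", "normalize-then-log"),
            log_offset=pp.get("log_offset", 1.0),
        )
        mirna_pp.to_tsv(out / "mirna_preprocessed.tsv")
        mrna_pp.to_tsv(out / "mrna_preprocessed.tsv")
        _write_qc(mirna, mirna_pp, annot, out, "mirna")
        log_lines.append(
            f"preprocess: mirna {mirna.n_features}->{mirna_pp.n_features} features, "
            f"mrna {mrna.n_features}->{mrna_pp.n_features} features"
        )

        sc = config.get("screen", {})
        pr = config.get("predict", {})
        groups = config.get("groups")
        if groups is None:
            counts_by_group = annot.table["group"].value_counts()
            groups = [g for g, n in counts_by_group.items() if n >= 4 and g != "other"]
            groups.sort()
        all_candidates, all_final, funnels = [], [], []
        for group in groups:
            stage = f"screen:{group}"
            candidates, final, counts = screen_and_integrate(
                mirna_pp, mrna_pp, annot, group, mirnas, transcripts,
                screen_cut=sc.get("threshold", SCREEN_THRESHOLD),
                strict_cuts=sc.get("strict_thresholds"),
                min_score=pr.get("min_score", MIN_MIRANDA_SCORE),
                rank_max=pr.get("rank_max", 100),
                score_min=pr.get("score_min", 0.25),
                chunk_size=sc.get("chunk_size", 256),
            )
            candidates_to_frame(candidates).to_csv(
                out / f"candidates_{group}.tsv", sep="\t", index=False
            )
            all_candidates.extend(candidates)
            all_final.extend(final)
            funnels.append(counts)
            log_lines.append(
                f"{group}: screened={counts.screened} one_predictor={counts.one_predictor} "
                f"both={counts.both_predictors} strict={counts.strict} final={counts.final}"
            )
        stage = "integrate"
        candidates_to_frame(all_final).to_csv(out / "final_regulations.tsv", sep="\t", index=False)
        with open(out / "funnel.json", "w") as fh:
            json.dump([asdict(f) for f in funnels], fh, indent=2)
        (out / "run.log").write_text("\n".join(log_lines) + "\n")
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    return out


def _write_qc(
    raw: ExpressionMatrix,
    processed: ExpressionMatrix,
    annot: SampleAnnotation,
    out: Path,
    tag: str,
) -> None:
    """PCA QC before/after batch removal: TSV of scores plus a PNG scatter."""
    from mirlink.preprocess import log2_transform, prevalence_filter, quantile_normalize

    try:
        before = log2_transform(quantile_normalize(prevalence_filter(raw)))
        qc_before = pca_qc(before, annot)
        qc_after = pca_qc(processed, annot)
    except ValueError as exc:
        logger.warning("skipping PCA QC for %s: %s", tag, exc)
        return
    qc_before.to_csv(out / f"qc_{tag}_pca_before.tsv", sep="\t", index=False)
    qc_after.to_csv(out / f"qc_{tag}_pca_after.tsv", sep="\t", index=False)
    try:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, axes = plt.subplots(1, 2, figsize=(9, 4))
        for ax, qc, title in [(axes[0], qc_before, "before batch removal"),
                              (axes[1], qc_after, "after batch removal")]:
            for batch, sub in qc.groupby("batch"):
                ax.scatter(sub["PC1"], sub["PC2"], s=8, label=str(batch))
            ax.set_xlabel("PC1")
            ax.set_ylabel("PC2")
            ax.set_title(title)
        fig.tight_layout()
        fig.savefig(out / f"qc_{tag}_pca.png", dpi=100)
        plt.close(fig)
    except Exception as exc:  # plotting must never abort an analysis run
        logger.warning("QC plot failed for %s: %s", tag, exc)


def synthetic_benchmark(
    cfg: SimulationConfig | None = None,
    groups: Sequence[str] = ("cPTC",),
    screen_cut: float = SCREEN_THRESHOLD,
    strict_cuts: dict[str, float] | None = None,
) -> dict:
    """Recovery of implanted regulations by the full pipeline.

    Simulates a cohort, preprocesses it, runs the staged screen for the
    given groups, and scores the final calls against the implanted ground
    truth. Sensitivity = implanted pairs among the final calls / implanted
    pairs; false-discovery proportion = final pairs not implanted / final
    pairs (0 when nothing is called).
    """
    cfg = cfg or SimulationConfig()
    mirna, mrna, annot, truth = simulate_expression(cfg)
    mirnas, transcripts = simulate_sequences(truth, mirna.feature_ids, mrna.feature_ids, seed=cfg.seed + 1)
    mirna_pp = preprocess_pipeline(mirna, annot)
    mrna_pp = preprocess_pipeline(mrna, annot)
    final_pairs: set[tuple[str, str]] = set()
    funnels = []
    for group in groups:
        _cands, final, counts = screen_and_integrate(
            mirna_pp, mrna_pp, annot, group, mirnas, transcripts,
            screen_cut=screen_cut, strict_cuts=strict_cuts,
        )
        final_pairs |= {(c.mirna_id, c.gene_id) for c in final}
        funnels.append(counts)
    planted = truth.regulation_pairs
    tp = len(final_pairs & planted)
    sensitivity = tp / len(planted) if planted else float("nan")
    fdp = (len(final_pairs) - tp) / len(final_pairs) if final_pairs else 0.0
    return {
        "sensitivity": sensitivity,
        "fdp": fdp,
        "n_planted": len(planted),
        "n_final": len(final_pairs),
        "funnels": funnels,
    }
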