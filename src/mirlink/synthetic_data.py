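"""Synthetic cohorts with implanted miRNA->gene regulations.

The generator emulates the statistical structure of a grouped tumor
expression cohort as the screening pipeline sees it: histotype groups of
unequal size, per-batch additive offsets on the log scale, a mix of
prevalent and rarely detected features, differential features between the
first two groups, and a chosen number of implanted negative monotone
miRNA->gene couplings. Companion sequences plant a genuine canonical seed
site (an 8mer backed by full-length complementarity) in each regulated
gene's 3'UTR, so that every prediction stage can fire on true pairs.

Implanted couplings are bivariate-normal on the log scale with the Pearson
parameter chosen so the population Spearman correlation equals the target
strength (rho = 2 sin(pi * s / 6)); only rank structure matters to the
screen, so no attempt is made to match real count distributions.

All randomness flows from the single seed in :class:`SimulationConfig`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from mirlink.io_annotation import ExpressionMatrix, SampleAnnotation
from mirlink.target_prediction import MirnaSequence, TranscriptRegions, revcomp

RNA_BASES = np.array(list("ACGU"))


@dataclass
class SimulationConfig:
    """Knobs of the synthetic cohort.

    Defaults describe the benchmark panel used throughout the test suite:
    200 miRNAs x 1000 genes over histotype groups of 100/31/11 samples
    (cohort proportions scaled down from a 321/99/35 tumor series), 16
    sequencing batches, and 20 implanted regulations at Spearman strength
    0.85.
    """

    n_mirna: int = 200
    n_gene: int = 1000
    group_sizes: dict[str, int] = field(
        default_factory=lambda: {"cPTC": 100, "fvPTC": 31, "tcPTC": 11}
    )
    n_batches: int = 16
    n_regulations: int = 20
    regulation_strength: float = 0.85
    dropout_rate: float = 0.05
    rare_fraction: float = 0.2  # features detected too rarely to pass the prevalence filter
    de_fraction: float = 0.1
    de_effect: float = 2.0  # log2 shift planted between the first two groups
    batch_sd: float = 0.5  # sd of per-batch per-feature log2 offsets
    feature_sd: float = 1.0  # per-sample biological + technical log2 spread
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_mirna < 1 or self.n_gene < 1 or self.n_batches < 1:
            raise ValueError("counts must be >= 1")
        if not self.group_sizes or any(v < 1 for v in self.group_sizes.values()):
            raise ValueError("group sizes must be >= 1")
        if not 0 <= self.dropout_rate < 0.5:
            raise ValueError("dropout_rate must be in [0, 0.5)")
        if not 0 < self.regulation_strength < 1:
            raise ValueError("regulation_strength must be in (0, 1)")
        if self.n_regulations > self.n_mirna * self.n_gene:
            raise ValueError("more regulations than available pairs")


@dataclass(frozen=True)
class Regulation:
    mirna_id: str
    gene_id: str
    group: str
    planted_strength: float
    planted_site_types: tuple[str, ...] = ("8mer",)


@dataclass
class GroundTruth:
    """Ledger of what was implanted, for recovery scoring."""

    regulations: list[Regulation]
    de_features: list[tuple[str, str, str]]  # (feature_id, "group1|group2", "up"/"down")
    prebatch_mirna: pd.DataFrame | None = None  # log2 values before batch offsets
    prebatch_mrna: pd.DataFrame | None = None

    @property
    def regulation_pairs(self) -> set[tuple[str, str]]:
        return {(r.mirna_id, r.gene_id) for r in self.regulations}

    def to_tsv(self, path: str | Path) -> None:
        rows = [
            {
                "mirna_id": r.mirna_id,
                "gene_id": r.gene_id,
                "group": r.group,
                "planted_strength": r.planted_strength,
                "planted_site_types": ",".join(r.planted_site_types),
            }
            for r in self.regulations
        ]
        pd.DataFrame(rows, columns=["mirna_id", "gene_id", "group", "planted_strength", "planted_site_types"]).to_csv(
            path, sep="\t", index=False
        )


def _spearman_to_pearson(s: float) -> float:
    """Bivariate-normal Pearson rho giving population Spearman s."""
    return 2.0 * np.sin(np.pi * s / 6.0)


def simulate_expression(
    cfg: SimulationConfig,
) -> tuple[ExpressionMatrix, ExpressionMatrix, SampleAnnotation, GroundTruth]:
    """Generate linear-scale miRNA and mRNA matrices plus annotation and truth.

    Features are simulated on the log2 scale (baseline means uniform in
    [3, 9], spread ``feature_sd``), batch offsets added, then exponentiated
    to the linear scale; dropout zeros and rare features are injected on
    the linear scale so the prevalence filter has real work to do.
    Regulated genes follow a negative bivariate-normal coupling to their
    miRNA, calibrated so the population Spearman is -regulation_strength.
    """
    rng = np.random.default_rng(cfg.seed)
    groups = list(cfg.group_sizes)
    sample_ids, sample_groups = [], []
    for g in groups:
        for i in range(cfg.group_sizes[g]):
            sample_ids.append(f"{g}_s{i:03d}")
            sample_groups.append(g)
    n_samples = len(sample_ids)
    batches = rng.integers(0, cfg.n_batches, size=n_samples)
    annot = SampleAnnotation(
        pd.DataFrame(
            {
                "sample_id": sample_ids,
                "group": sample_groups,
                "batch": [f"batch{b:02d}" for b in batches],
            }
        )
    )

    mirna_ids = [f"syn-miR-{i:04d}" for i in range(cfg.n_mirna)]
    gene_ids = [f"GENE{j:04d}" for j in range(cfg.n_gene)]

    n_rare_m = int(round(cfg.rare_fraction * cfg.n_mirna))
    n_rare_g = int(round(cfg.rare_fraction * cfg.n_gene))
    rare_m = set(rng.choice(cfg.n_mirna, size=n_rare_m, replace=False).tolist())
    rare_g = set(rng.choice(cfg.n_gene, size=n_rare_g, replace=False).tolist())
    common_m = [i for i in range(cfg.n_mirna) if i not in rare_m]
    common_g = [j for j in range(cfg.n_gene) if j not in rare_g]
    if cfg.n_regulations > min(len(common_m), len(common_g)):
        raise ValueError("not enough prevalent features to host the requested regulations")

    reg_m = rng.choice(common_m, size=cfg.n_regulations, replace=False)
    reg_g = rng.choice(common_g, size=cfg.n_regulations, replace=False)
    detect_group = groups[0]
    regulations = [
        Regulation(mirna_ids[mi], gene_ids[gi], detect_group, cfg.regulation_strength)
        for mi, gi in zip(reg_m, reg_g)
    ]

    mu_m = rng.uniform(3.0, 9.0, size=cfg.n_mirna)
    mu_g = rng.uniform(3.0, 9.0, size=cfg.n_gene)
    zm = rng.standard_normal((cfg.n_mirna, n_samples))
    zg = rng.standard_normal((cfg.n_gene, n_samples))
    log_m = mu_m[:, None] + cfg.feature_sd * zm
    log_g = mu_g[:, None] + cfg.feature_sd * zg
    rho = _spearman_to_pearson(cfg.regulation_strength)
    for mi, gi in zip(reg_m, reg_g):
        coupled = -rho * zm[mi] + np.sqrt(1.0 - rho * rho) * zg[gi]
        log_g[gi] = mu_g[gi] + cfg.feature_sd * coupled

    # differential features between the first two groups
    de_features: list[tuple[str, str, str]] = []
    if len(groups) >= 2 and cfg.de_fraction > 0:
        g2_mask = np.array([g == groups[1] for g in sample_groups])
        pair = f"{groups[0]}|{groups[1]}"
        n_de_m = int(round(cfg.de_fraction * len(common_m)))
        n_de_g = int(round(cfg.de_fraction * len(common_g)))
        de_m = rng.choice(common_m, size=n_de_m, replace=False)
        de_g = rng.choice([j for j in common_g if j not in set(reg_g)], size=n_de_g, replace=False)
        for idx, (ids, log_x, chosen) in enumerate(
            [(mirna_ids, log_m, de_m), (gene_ids, log_g, de_g)]
        ):
            signs = rng.choice([-1.0, 1.0], size=len(chosen))
            for f, sgn in zip(chosen, signs):
                log_x[f, g2_mask] += sgn * cfg.de_effect
                # direction is of group1 relative to group2
                de_features.append((ids[f], pair, "down" if sgn > 0 else "up"))

    prebatch_m = pd.DataFrame(log_m.copy(), index=mirna_ids, columns=sample_ids)
    prebatch_g = pd.DataFrame(log_g.copy(), index=gene_ids, columns=sample_ids)

    offsets_m = rng.normal(0.0, cfg.batch_sd, size=(cfg.n_mirna, cfg.n_batches))
    offsets_g = rng.normal(0.0, cfg.batch_sd, size=(cfg.n_gene, cfg.n_batches))
    log_m = log_m + offsets_m[:, batches]
    log_g = log_g + offsets_g[:, batches]

    lin_m = np.exp2(log_m)
    lin_g = np.exp2(log_g)

    # rare features: detected in only ~30% of samples
    for idx_set, lin in [(rare_m, lin_m), (rare_g, lin_g)]:
        for f in idx_set:
            undetected = rng.random(n_samples) > 0.3
            lin[f, undetected] = 0.0
    # non-detection is abundance-driven in bulk sequencing: left-censor each
    # feature at its dropout_rate quantile rather than zeroing at random
    if cfg.dropout_rate > 0:
        for lin in (lin_m, lin_g):
            limits = np.quantile(lin, cfg.dropout_rate, axis=1, keepdims=True)
            lin[lin <= limits] = 0.0

    mirna = ExpressionMatrix(pd.DataFrame(lin_m, index=mirna_ids, columns=sample_ids), "linear")
    mrna = ExpressionMatrix(pd.DataFrame(lin_g, index=gene_ids, columns=sample_ids), "linear")
    truth = GroundTruth(regulations, de_features, prebatch_m, prebatch_g)
    return mirna, mrna, annot, truth


def simulate_sequences(
    truth: GroundTruth,
    mirna_ids: Sequence[str],
    gene_ids: Sequence[str],
    seed: int = 0,
    utr5_len: int = 200,
    cds_len: int = 600,
    utr3_len: int = 1000,
) -> tuple[list[MirnaSequence], list[TranscriptRegions]]:
    """Random mature miRNA and transcript-region sequences with planted sites.

    Mature sequences are 21-23 nt of random composition starting with U (the
    prevalent 5' base of real mature miRNAs; it also makes the planted
    full-complement site a genuine 8mer, since the base opposite position 1
    is then an A). Each regulated gene's 3'UTR receives one planted site:
    the full reverse complement of its miRNA, giving the seed detector an
    8mer and the duplex scorer perfect pairing. Non-regulated genes carry no
    planted sites; chance seed matches occur at the background k-mer rate.
    """
    rng = np.random.default_rng(seed)
    known_genes = set(gene_ids)
    for reg in truth.regulations:
        if reg.gene_id not in known_genes:
            raise ValueError(f"regulated gene {reg.gene_id} absent from gene_ids")
        if reg.mirna_id not in set(mirna_ids):
            raise ValueError(f"regulating miRNA {reg.mirna_id} absent from mirna_ids")

    def rand_rna(n: int) -> str:
        return "".join(RNA_BASES[rng.integers(0, 4, size=n)])

    mirnas = []
    for mid in mirna_ids:
        length = int(rng.integers(21, 24))
        mirnas.append(MirnaSequence(mid, "U" + rand_rna(length - 1)))
    mir_by_id = {m.mature_name: m for m in mirnas}

    regs_by_gene: dict[str, list[str]] = {}
    for reg in truth.regulations:
        regs_by_gene.setdefault(reg.gene_id, []).append(reg.mirna_id)

    transcripts = []
    for gid in gene_ids:
        utr3 = rand_rna(utr3_len)
        for mid in regs_by_gene.get(gid, []):
            site = revcomp(mir_by_id[mid].seq)  # ends in A: an 8mer with full 3' pairing
            pos = int(rng.integers(5, utr3_len - len(site) - 5))
            utr3 = utr3[:pos] + site + utr3[pos + len(site):]
        transcripts.append(
            TranscriptRegions(gid, utr5=rand_rna(utr5_len), cds=rand_rna(cds_len), utr3=utr3)
        )
    return mirnas, transcripts
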