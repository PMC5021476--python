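"""Sequence-based miRNA target prediction over transcript regions.

Three predictor stages are provided, each a documented simplification of
the decision logic of a widely used tool class:

* a canonical seed-site detector (site classes 8mer > 7mer-m8 > 7mer-A1 >
  6mer, defined by Watson-Crick complementarity to miRNA positions 2-8
  plus an adenosine opposite position 1);
* a local antiparallel duplex alignment scorer (Watson-Crick +5, G:U
  wobble +1, mismatch -3, affine gaps -8/-2, seed-position contributions
  doubled) evaluated around candidate sites;
* a seed-weighted per-gene ranking over 3'UTR sites with a rank/score
  confirmation rule.

Externally produced prediction tables can be imported instead of any
built-in stage via :func:`load_external_predictions`.

Numbering convention: position 1 is the miRNA 5' terminus; the seed is
positions 2-8. T and U are interchangeable on input and normalized to U.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

RNA_ALPHABET = set("ACGU")
_COMPLEMENT = {"A": "U", "U": "A", "G": "C", "C": "G"}

#: alignment scoring defaults
MATCH_WC = 5
MATCH_WOBBLE = 1
MISMATCH = -3
GAP_OPEN = -8
GAP_EXTEND = -2
SEED_START, SEED_END = 2, 8  # miRNA positions whose contributions are doubled
MIN_MIRANDA_SCORE = 140.0

#: seed-weighted ranking defaults
TARGETRANK_WEIGHTS = {"8mer": 1.0, "7mer-m8": 0.75, "7mer-A1": 0.5, "6mer": 0.25}
TARGETRANK_RANK_MAX = 100
TARGETRANK_SCORE_MIN = 0.25

SITE_TYPES = ("8mer", "7mer-m8", "7mer-A1", "6mer")  # most to least specific
REGIONS = ("utr5", "cds", "utr3")


def normalize_rna(seq: str) -> str:
    """Uppercase, map T->U, and validate the RNA alphabet."""
    s = seq.upper().replace("T", "U")
    bad = set(s) - RNA_ALPHABET
    if bad:
        raise ValueError(f"non-RNA characters: {sorted(bad)}")
    return s


def revcomp(seq: str) -> str:
    return "".join(_COMPLEMENT[b] for b in reversed(seq))


@dataclass(frozen=True)
class MirnaSequence:
    """A mature miRNA sequence, 5'->3'."""

    mature_name: str
    seq: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "seq", normalize_rna(self.seq))
        if not 18 <= len(self.seq) <= 26:
            raise ValueError(f"{self.mature_name}: mature length {len(self.seq)} outside 18-26")

    @property
    def seed(self) -> str:
        """Positions 2-8 (7 nt)."""
        return self.seq[1:8]


@dataclass(frozen=True)
class TranscriptRegions:
    """5'UTR / CDS / 3'UTR sequences of one gene; any region may be empty."""

    gene_id: str
    utr5: str = ""
    cds: str = ""
    utr3: str = ""

    def __post_init__(self) -> None:
        for region in REGIONS:
            object.__setattr__(self, region, normalize_rna(getattr(self, region)))

    def region_seq(self, region: str) -> str:
        if region not in REGIONS:
            raise ValueError(f"unknown region {region!r}")
        return getattr(self, region)


@dataclass
class SeedSite:
    """One canonical seed match; ``start`` is 1-based within its region."""

    gene_id: str
    region: str
    start: int
    site_type: str
    alignment_score: float | None = None


@dataclass
class PredictionRecord:
    mirna_id: str
    gene_id: str
    predicted_targetscan: bool = False
    predicted_miranda: bool = False
    targetrank_score: float = 0.0
    targetrank_rank: int | None = None


def find_seed_sites(mir: MirnaSequence, regions: TranscriptRegions) -> list[SeedSite]:
    """Scan each transcript region 5'->3' for canonical seed matches.

    Site definitions (mRNA sequence, 5'->3'):

    * 6mer     — reverse complement of miRNA positions 2-7
    * 7mer-m8  — reverse complement of positions 2-8
    * 7mer-A1  — 6mer followed by an A
    * 8mer     — 7mer-m8 followed by an A

    Each 6mer core occurrence is reported once, under the most specific
    class whose context it satisfies. ``start`` points at the site's
    5'-most matched nucleotide (the m8-pairing base for 7mer-m8/8mer).
    """
    if not mir.seq:
        raise ValueError("empty miRNA sequence")
    core = revcomp(mir.seq[1:7])  # positions 2-7
    m8 = _COMPLEMENT[mir.seq[7]]  # base pairing miRNA position 8
    sites: list[SeedSite] = []
    for region in REGIONS:
        seq = regions.region_seq(region)
        pos = seq.find(core)
        while pos != -1:
            has_m8 = pos > 0 and seq[pos - 1] == m8
            has_a1 = pos + len(core) < len(seq) and seq[pos + len(core)] == "A"
            if has_m8 and has_a1:
                site_type, start = "8mer", pos  # includes the m8 base
            elif has_m8:
                site_type, start = "7mer-m8", pos
            elif has_a1:
                site_type, start = "7mer-A1", pos + 1
            else:
                site_type, start = "6mer", pos + 1
            sites.append(SeedSite(regions.gene_id, region, start, site_type))
            pos = seq.find(core, pos + 1)
    return sites


def _pair_score(mb: str, tb: str) -> int:
    if _COMPLEMENT[mb] == tb:
        return MATCH_WC
    if {mb, tb} == {"G", "U"}:
        return MATCH_WOBBLE
    return MISMATCH


def miranda_like_score(mir: MirnaSequence, site_window: str) -> float:
    """Best local antiparallel duplex alignment score in a window.

    The miRNA (5'->3') is aligned against the reversed window so base i of
    the miRNA pairs antiparallel with the mRNA. Scoring: Watson-Crick +5,
    G:U wobble +1, mismatch -3, gap open -8, gap extend -2; substitution
    contributions at miRNA seed positions 2-8 are doubled. The score is the
    Smith-Waterman/Gotoh local maximum, hence invariant under extending the
    window with non-pairing flanks; it is never negative.
    """
    if len(site_window) < len(mir.seq):
        raise ValueError("window shorter than the miRNA")
    return duplex_align_score(mir.seq, site_window)


def duplex_align_score(mirna_seq: str, site_window: str) -> float:
    """String-level core of :func:`miranda_like_score` (any lengths)."""
    m = normalize_rna(mirna_seq)
    t = normalize_rna(site_window)[::-1]  # antiparallel: read target 3'->5'
    nm, nt = len(m), len(t)
    NEG = float("-inf")
    # Gotoh local alignment: H match/mismatch end, E gap in miRNA, F gap in target
    H = [[0.0] * (nt + 1) for _ in range(nm + 1)]
    E = [[NEG] * (nt + 1) for _ in range(nm + 1)]
    F = [[NEG] * (nt + 1) for _ in range(nm + 1)]
    best = 0.0
    for i in range(1, nm + 1):
        weight = 2 if SEED_START <= i <= SEED_END else 1
        for j in range(1, nt + 1):
            E[i][j] = max(H[i][j - 1] + GAP_OPEN, E[i][j - 1] + GAP_EXTEND)
            F[i][j] = max(H[i - 1][j] + GAP_OPEN, F[i - 1][j] + GAP_EXTEND)
            sub = weight * _pair_score(m[i - 1], t[j - 1])
            H[i][j] = max(0.0, H[i - 1][j - 1] + sub, E[i][j], F[i][j])
            if H[i][j] > best:
                best = H[i][j]
    return best


def _site_window(regions: TranscriptRegions, site: SeedSite, mir_len: int, flank: int = 10) -> str:
    """Window around a seed site wide enough for full-length duplex pairing.

    The miRNA 3' end pairs upstream (5' direction) of the seed match, so
    the window extends mostly upstream of the site.
    """
    seq = regions.region_seq(site.region)
    start0 = site.start - 1
    lo = max(0, start0 - (mir_len + flank))
    hi = min(len(seq), start0 + 8 + flank)
    return seq[lo:hi]


def predict_pair(
    mir: MirnaSequence,
    regions: TranscriptRegions,
    min_score: float = MIN_MIRANDA_SCORE,
) -> tuple[bool, bool, list[SeedSite]]:
    """Run the seed-class and duplex-alignment predictors on one pair.

    Returns (predicted_targetscan, predicted_miranda, sites). The seed-class
    predictor fires on any 8mer/7mer-m8/7mer-A1 site in any region; the
    alignment predictor fires when any site's surrounding window scores at
    least ``min_score``. Each site is annotated with its window score.
    """
    sites = find_seed_sites(mir, regions)
    ts = any(s.site_type in ("8mer", "7mer-m8", "7mer-A1") for s in sites)
    miranda = False
    for s in sites:
        window = _site_window(regions, s, len(mir.seq))
        if len(window) < len(mir.seq):  # site too close to a region edge for a full duplex
            s.alignment_score = 0.0
            continue
        s.alignment_score = miranda_like_score(mir, window)
        if s.alignment_score >= min_score:
            miranda = True
    return ts, miranda, sites


def targetrank_like(
    mir: MirnaSequence,
    all_regions: Sequence[TranscriptRegions],
    weights: dict[str, float] | None = None,
    rank_max: int = TARGETRANK_RANK_MAX,
    score_min: float = TARGETRANK_SCORE_MIN,
) -> list[PredictionRecord]:
    """Seed-weighted ranking of every gene for one miRNA.

    Per gene, the score sums site-class weights over 3'UTR sites (defaults
    8mer=1.0, 7mer-m8=0.75, 7mer-A1=0.5, 6mer=0.25). Genes are ranked by
    score descending (rank 1 best, ties by gene_id); a gene is confirmed —
    i.e. receives a rank — when score > 0. Downstream confirmation uses
    ``rank <= rank_max and score >= score_min`` via :func:`targetrank_confirmed`.
    """
    if not all_regions:
        raise ValueError("empty transcript list")
    weights = TARGETRANK_WEIGHTS if weights is None else weights
    records = []
    for regions in all_regions:
        utr3_sites = [s for s in find_seed_sites(mir, regions) if s.region == "utr3"]
        score = float(sum(weights[s.site_type] for s in utr3_sites))
        records.append(PredictionRecord(mir.mature_name, regions.gene_id, targetrank_score=score))
    ranked = sorted(records, key=lambda r: (-r.targetrank_score, r.gene_id))
    rank = 0
    for rec in ranked:
        if rec.targetrank_score > 0:
            rank += 1
            rec.targetrank_rank = rank
    return records


def targetrank_confirmed(
    rec: PredictionRecord,
    rank_max: int = TARGETRANK_RANK_MAX,
    score_min: float = TARGETRANK_SCORE_MIN,
) -> bool:
    return (
        rec.targetrank_rank is not None
        and rec.targetrank_rank <= rank_max
        and rec.targetrank_score >= score_min
    )


def format_targetrank(rec: PredictionRecord, confirmed: bool) -> str:
    """Serialize a confirmation verdict as ``YES (rank, score)`` or ``NO``."""
    if confirmed:
        return f"YES ({rec.targetrank_rank}, {rec.targetrank_score:.2f})"
    return "NO"


EXTERNAL_TOOLS = ("targetscan", "miranda", "targetrank")


def load_external_predictions(path: str | Path, tool_tag: str) -> list[PredictionRecord]:
    """Import a prediction table produced by an external tool run.

    The TSV needs columns ``mirna_id`` and ``gene_id``; a ``score`` column
    is used for the ranking stage. Duplicate pairs are deduplicated (first
    occurrence wins, logged). The caller substitutes these records for the
    built-in predictor named by ``tool_tag``.
    """
    if tool_tag not in EXTERNAL_TOOLS:
        raise ValueError(f"unknown tool tag {tool_tag!r}; expected one of {EXTERNAL_TOOLS}")
    df = pd.read_csv(path, sep="\t", dtype={"mirna_id": str, "gene_id": str})
    if df.empty:
        logger.warning("external prediction table %s is empty", path)
        return []
    if not {"mirna_id", "gene_id"}.issubset(df.columns):
        raise ValueError("external table needs columns mirna_id, gene_id")
    n0 = len(df)
    df = df.drop_duplicates(subset=["mirna_id", "gene_id"], keep="first")
    if len(df) < n0:
        logger.warning("deduplicated %d repeated pair rows in %s", n0 - len(df), path)
    out = []
    for _, row in df.iterrows():
        rec = PredictionRecord(str(row["mirna_id"]), str(row["gene_id"]))
        if tool_tag == "targetscan":
            rec.predicted_targetscan = True
        elif tool_tag == "miranda":
            rec.predicted_miranda = True
        else:
            rec.targetrank_score = float(row.get("score", 0.0))
            rec.targetrank_rank = int(row["rank"]) if "rank" in df.columns else None
        out.append(rec)
    return out


def read_mirna_fasta(path: str | Path) -> list[MirnaSequence]:
    """Read mature miRNA sequences from FASTA (id = first word of header)."""
    out = []
    for name, seq in _iter_fasta(path):
        out.append(MirnaSequence(name.split()[0], seq))
    return out


def read_regions_fasta(path: str | Path) -> list[TranscriptRegions]:
    """Read transcript regions from FASTA.

    Headers carry ``region=utr5|cds|utr3`` after the gene id, e.g.
    ``>GENE1 region=utr3``. Records of one gene are merged.
    """
    by_gene: dict[str, dict[str, str]] = {}
    order: list[str] = []
    for header, seq in _iter_fasta(path):
        parts = header.split()
        gene_id = parts[0]
        region = None
        for tok in parts[1:]:
            if tok.startswith("region="):
                region = tok.split("=", 1)[1]
        if region not in REGIONS:
            raise ValueError(f"FASTA record {gene_id!r} lacks a valid region= tag")
        if gene_id not in by_gene:
            by_gene[gene_id] = {}
            order.append(gene_id)
        by_gene[gene_id][region] = seq
    return [TranscriptRegions(g, **by_gene[g]) for g in order]


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for header, seq in records:
            fh.write(f">{header}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def _iter_fasta(path: str | Path):
    header = None
    chunks: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith(">"):
                if header is not None:
                    yield header, "".join(chunks)
                header = line[1:]
                chunks = []
            elif line:
                chunks.append(line)
    if header is not None:
        yield header, "".join(chunks)
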