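"""Core containers and file I/O: expression matrices, sample annotations,
and mapping of genomic isoform coordinates to mature miRNA names.

Isoform identifiers are canonical strings ``chrom:start-end:strand`` with
1-based inclusive coordinates, the same convention GFF3 uses. An isoform
absent from a sample's quantification file is treated as undetected and
stored as 0; downstream, "detected" means a strictly positive value.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

VALID_GROUPS = ("cPTC", "fvPTC", "tcPTC", "other")

_ISOFORM_RE = re.compile(r"^(?P<chrom>[^:]+):(?P<start>\d+)-(?P<end>\d+):(?P<strand>[+-])$")


class FormatError(ValueError):
    """Raised when an input file violates its expected format."""


@dataclass
class ExpressionMatrix:
    """Features x samples numeric grid with a value-scale tag.

    Parameters
    ----------
    data
        DataFrame indexed by feature id, columns are sample ids. Values are
        linear-scale abundances (RPM for miRNA isoforms, normalized counts
        for genes) until :func:`mirlink.preprocess.log2_transform` retags
        the matrix as ``log2``.
    scale
        Either ``"linear"`` or ``"log2"``.
    """

    data: pd.DataFrame
    scale: str = "linear"

    def __post_init__(self) -> None:
        if self.scale not in ("linear", "log2"):
            raise ValueError(f"scale must be 'linear' or 'log2', got {self.scale!r}")
        if self.data.index.has_duplicates:
            raise ValueError("duplicate feature ids")
        if self.data.columns.has_duplicates:
            raise ValueError("duplicate sample ids")
        if self.scale == "linear" and (self.data.to_numpy() < 0).any():
            raise ValueError("negative values in a linear-scale matrix")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def n_features(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def subset_samples(self, sample_ids: Sequence[str]) -> "ExpressionMatrix":
        missing = [s for s in sample_ids if s not in self.data.columns]
        if missing:
            raise KeyError(f"samples not in matrix: {missing[:5]}")
        return ExpressionMatrix(self.data.loc[:, list(sample_ids)].copy(), self.scale)

    def to_tsv(self, path: str | Path) -> None:
        """Write as TSV with a ``# scale=...`` header comment line."""
        path = Path(path)
        with open(path, "w") as fh:
            fh.write(f"# scale={self.scale}\n")
            self.data.to_csv(fh, sep="\t", index_label="feature_id", float_format="%.17g")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ExpressionMatrix":
        path = Path(path)
        scale = "linear"
        with open(path) as fh:
            first = fh.readline()
            if first.startswith("# scale="):
                scale = first.strip().split("=", 1)[1]
            else:
                fh.seek(0)
            df = pd.read_csv(fh, sep="\t", index_col="feature_id", float_precision="round_trip")
        df.index = df.index.astype(str)
        df.columns = df.columns.astype(str)
        return cls(df, scale)


@dataclass
class SampleAnnotation:
    """Per-sample histotype group and batch label.

    ``table`` has columns ``sample_id``, ``group``, ``batch``; one row per
    sample. Groups follow the papillary-thyroid-carcinoma histotype
    vocabulary (cPTC, fvPTC, tcPTC, other) but any subset may be present.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"sample_id", "group", "batch"}
        if not required.issubset(self.table.columns):
            raise ValueError(f"annotation table needs columns {sorted(required)}")
        if self.table["sample_id"].duplicated().any():
            dups = self.table.loc[self.table["sample_id"].duplicated(), "sample_id"]
            raise ValueError(f"duplicate sample ids in annotation: {list(dups)[:5]}")
        if self.table["group"].isna().any() or (self.table["group"] == "").any():
            raise ValueError("empty group label")
        if self.table["batch"].isna().any() or (self.table["batch"].astype(str) == "").any():
            raise ValueError("empty batch label")
        bad = set(self.table["group"]) - set(VALID_GROUPS)
        if bad:
            raise ValueError(f"unknown group labels: {sorted(bad)}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table["sample_id"])

    def group_of(self, sample_id: str) -> str:
        row = self.table.loc[self.table["sample_id"] == sample_id]
        if row.empty:
            raise KeyError(sample_id)
        return str(row["group"].iloc[0])

    def batch_of(self, sample_id: str) -> str:
        row = self.table.loc[self.table["sample_id"] == sample_id]
        if row.empty:
            raise KeyError(sample_id)
        return str(row["batch"].iloc[0])

    def samples_in_group(self, group: str) -> list[str]:
        return list(self.table.loc[self.table["group"] == group, "sample_id"])

    def batches_for(self, sample_ids: Sequence[str]) -> pd.Series:
        """Batch label per sample, ordered as ``sample_ids``."""
        lut = self.table.set_index("sample_id")["batch"]
        missing = [s for s in sample_ids if s not in lut.index]
        if missing:
            raise ValueError(f"samples without batch annotation: {missing[:5]}")
        return lut.loc[list(sample_ids)].astype(str)

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SampleAnnotation":
        df = pd.read_csv(path, sep="\t", dtype=str)
        return cls(df)


@dataclass(frozen=True)
class MirnaLocus:
    """A mature-miRNA genomic interval from a miRBase GFF3 record."""

    chrom: str
    start: int  # 1-based inclusive
    end: int
    strand: str
    mature_name: str | None = None

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"start > end in locus {self.chrom}:{self.start}-{self.end}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be + or -, got {self.strand!r}")

    @property
    def isoform_id(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}:{self.strand}"


def parse_isoform_id(isoform_id: str) -> tuple[str, int, int, str]:
    """Split ``chrom:start-end:strand`` into its parts.

    Raises :class:`FormatError` on malformed input.
    """
    m = _ISOFORM_RE.match(isoform_id)
    if not m:
        raise FormatError(f"malformed isoform coordinate: {isoform_id!r}")
    start, end = int(m["start"]), int(m["end"])
    if start > end:
        raise FormatError(f"start > end in isoform coordinate: {isoform_id!r}")
    return m["chrom"], start, end, m["strand"]


def read_isoform_quant(
    paths: Sequence[str | Path],
    annot: SampleAnnotation | None = None,
) -> ExpressionMatrix:
    """Read per-sample isoform quantification TSVs into one matrix.

    Each file holds one sample: two tab-separated columns, an isoform
    coordinate string and its reads-per-million value (a header row whose
    second field is non-numeric is skipped). The sample id is the file stem.
    The returned matrix is the union of isoforms across samples with 0 for
    isoforms not reported (undetected) in a sample.
    """
    if not paths:
        raise ValueError("no quantification files given")
    columns: dict[str, dict[str, float]] = {}
    for p in paths:
        p = Path(p)
        sample_id = p.stem
        if sample_id in columns:
            raise ValueError(f"duplicate sample id: {sample_id}")
        col: dict[str, float] = {}
        with open(p) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) < 2:
                    raise FormatError(f"{p}:{lineno}: expected 2 tab-separated columns")
                iso, val = parts[0], parts[1]
                try:
                    rpm = float(val)
                except ValueError:
                    if lineno == 1:  # header row
                        continue
                    raise FormatError(f"{p}:{lineno}: non-numeric value {val!r}")
                parse_isoform_id(iso)  # raises naming this line's coordinate
                if rpm < 0:
                    raise FormatError(f"{p}:{lineno}: negative RPM {rpm}")
                col[iso] = rpm
        columns[sample_id] = col
    all_isoforms = sorted({iso for col in columns.values() for iso in col})
    df = pd.DataFrame(
        {sid: [col.get(iso, 0.0) for iso in all_isoforms] for sid, col in columns.items()},
        index=pd.Index(all_isoforms, name="feature_id"),
    )
    if annot is not None:
        known = set(annot.sample_ids)
        unknown = [s for s in df.columns if s not in known]
        if unknown:
            raise ValueError(f"samples missing from annotation: {unknown[:5]}")
    return ExpressionMatrix(df, scale="linear")


def read_gene_counts(path: str | Path) -> ExpressionMatrix:
    """Read a gene-level normalized-count TSV (genes x samples)."""
    return ExpressionMatrix.from_tsv(path)


def parse_mirbase_gff3(path: str | Path) -> list[MirnaLocus]:
    """Parse a miRBase-style GFF3 into mature-miRNA loci.

    Only records with feature type ``miRNA`` (mature miRNAs; hairpin records
    are typed ``miRNA_primary_transcript``) are kept. Coordinates stay
    1-based inclusive as in GFF3. Records whose attribute column cannot be
    parsed are skipped with a warning.
    """
    path = Path(path)
    loci: list[MirnaLocus] = []
    with open(path) as fh:
        first_content: str | None = None
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                continue
            if first_content is None:
                first_content = line
            fields = line.split("\t")
            if len(fields) != 9:
                raise FormatError(f"{path}:{lineno}: not a GFF3 line (9 columns expected)")
            chrom, _src, ftype, start, end, _score, strand, _phase, attrs = fields
            if ftype != "miRNA":
                continue
            try:
                attr_map = dict(
                    kv.split("=", 1) for kv in attrs.split(";") if kv and "=" in kv
                )
                name = attr_map.get("Name")
                if name is None:
                    raise KeyError("Name")
                locus = MirnaLocus(chrom, int(start), int(end), strand, name)
            except (ValueError, KeyError) as exc:
                logger.warning("%s:%d: skipping unparseable miRNA record (%s)", path, lineno, exc)
                continue
            loci.append(locus)
    return loci


def write_mirbase_gff3(loci: Iterable[MirnaLocus], path: str | Path) -> None:
    """Write mature loci in the miRBase GFF3 dialect (round-trips with the parser)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for loc in loci:
            fh.write(
                f"{loc.chrom}\t.\tmiRNA\t{loc.start}\t{loc.end}\t.\t{loc.strand}\t.\t"
                f"ID={loc.mature_name};Name={loc.mature_name}\n"
            )


UNMAPPED = "unmapped"


def map_locus_to_mature(isoform_id: str, loci: Sequence[MirnaLocus]) -> str:
    """Map an isoform coordinate to the mature miRNA it overlaps most.

    Overlap is counted in bases on the same chromosome and strand; the
    mature name with the largest overlap wins, ties broken by
    lexicographically smallest name so the mapping is deterministic.
    Returns the sentinel ``"unmapped"`` when nothing overlaps.
    """
    chrom, start, end, strand = parse_isoform_id(isoform_id)
    best_name = None
    best_overlap = 0
    for loc in loci:
        if loc.chrom != chrom or loc.strand != strand or loc.mature_name is None:
            continue
        overlap = min(end, loc.end) - max(start, loc.start) + 1
        if overlap <= 0:
            continue
        if overlap > best_overlap or (overlap == best_overlap and best_name is not None and loc.mature_name < best_name):
            best_overlap = overlap
            best_name = loc.mature_name
    return best_name if best_name is not None else UNMAPPED


def annotate_isoforms(isoform_ids: Sequence[str], loci: Sequence[MirnaLocus]) -> dict[str, str]:
    """Vector form of :func:`map_locus_to_mature` over many isoforms."""
    return {iso: map_locus_to_mature(iso, loci) for iso in isoform_ids}
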