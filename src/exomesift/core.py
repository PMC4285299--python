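"""Shared domain types and coordinate conventions.

All genomic coordinates in the data model are 1-based and inclusive at both
ends (the VCF/HGVS convention).  BED input, which is 0-based half-open, is
converted on read and back on write.  Strand is carried on transcript models
for naming purposes only; it never affects filtering.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from intervaltree import IntervalTree

__all__ = [
    "GenomicInterval",
    "Zygosity",
    "ConsequenceClass",
    "AnnotatedVariant",
    "TranscriptModel",
    "RegionIndex",
    "interval_contains",
    "merge_intervals",
    "read_bed",
    "write_bed",
]


@dataclass(frozen=True)
class GenomicInterval:
    """A closed genomic interval: ``chrom:start-end``, 1-based inclusive."""

    chrom: str
    start: int
    end: int
    label: str = ""

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 1:
            raise ValueError(f"start must be >= 1, got {self.start}")
        if self.end < self.start:
            raise ValueError(
                f"end ({self.end}) must be >= start ({self.start})"
            )

    def __len__(self) -> int:
        return self.end - self.start + 1

    def contains(self, chrom: str, pos: int) -> bool:
        return self.chrom == chrom and self.start <= pos <= self.end


class Zygosity(enum.Enum):
    HETEROZYGOUS = "heterozygous"
    HOMOZYGOUS = "homozygous"
    HEMIZYGOUS = "hemizygous"
    UNKNOWN = "unknown"


class ConsequenceClass(enum.Enum):
    SYNONYMOUS = "synonymous"
    MISSENSE = "missense"
    NONSENSE = "nonsense"
    FRAMESHIFT = "frameshift"
    INFRAME_INDEL = "inframe_indel"
    SPLICE_REGION = "splice_region"
    INTRONIC = "intronic"
    UTR = "utr"
    INTERGENIC = "intergenic"


#: Consequence classes that alter the protein product (or plausibly splicing).
PROTEIN_ALTERING = frozenset(
    {
        ConsequenceClass.MISSENSE,
        ConsequenceClass.NONSENSE,
        ConsequenceClass.FRAMESHIFT,
        ConsequenceClass.INFRAME_INDEL,
        ConsequenceClass.SPLICE_REGION,
    }
)


@dataclass
class AnnotatedVariant:
    """One called variant joined to its functional annotation.

    This is the row unit of the filter cascade: the genomic call (chrom, pos,
    ref, alt, quality, depths, genotype) plus the transcript-level annotation
    (gene, HGVS names, consequence class, distance to the nearest exon
    boundary) and population/cohort context (dbSNP MAF, local observation
    count, curated pathogenicity score).

    ``splice_distance`` is signed: 0 inside an exon, negative upstream of the
    exon start, positive downstream of the exon end; ``None`` when unknown
    (e.g. intergenic).  ``maf`` and ``pathogenicity_score`` are ``None`` when
    missing — a missing MAF means a novel variant and must never be read as 0.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str = ""
    transcript: str = ""
    cnomen: str = ""
    pnomen: str = ""
    consequence: ConsequenceClass = ConsequenceClass.INTERGENIC
    splice_distance: Optional[int] = None
    zygosity: Zygosity = Zygosity.UNKNOWN
    quality: float = 0.0
    depth: int = 0
    alt_depth: int = 0
    maf: Optional[float] = None
    dbsnp_id: str = ""
    observation_count: int = 0
    pathogenicity_score: Optional[float] = None
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.alt_depth > self.depth:
            raise ValueError(
                f"alt_depth ({self.alt_depth}) exceeds depth ({self.depth})"
            )
        if self.maf is not None and not 0.0 <= self.maf <= 1.0:
            raise ValueError(f"maf out of [0, 1]: {self.maf}")

    @property
    def key(self) -> tuple[str, int, str, str]:
        """The (chrom, pos, ref, alt) identity used for table joins."""
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass
class TranscriptModel:
    """Exon/intron structure of one transcript, used to name indel events.

    Exons are stored in genomic order; exon *numbering* follows transcription
    order, so on the minus strand exon 1 is the genomically last exon.
    """

    gene: str
    transcript: str
    chrom: str
    strand: str
    exons: Sequence[GenomicInterval]
    cds_start: Optional[int] = None
    cds_end: Optional[int] = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        prev_end = 0
        for ex in self.exons:
            if ex.chrom != self.chrom:
                raise ValueError(
                    f"exon on {ex.chrom} but transcript on {self.chrom}"
                )
            if ex.start <= prev_end:
                raise ValueError("exons must be ordered and non-overlapping")
            prev_end = ex.end

    def exon_number(self, genomic_index: int) -> int:
        """Transcription-order exon number for the i-th exon in genomic order."""
        n = len(self.exons)
        return genomic_index + 1 if self.strand == "+" else n - genomic_index


def interval_contains(iv: GenomicInterval, chrom: str, pos: int) -> bool:
    """True iff ``chrom`` matches and ``iv.start <= pos <= iv.end``."""
    if pos < 1:
        raise ValueError(f"pos must be >= 1, got {pos}")
    return iv.contains(chrom, pos)


def merge_intervals(
    intervals: Iterable[GenomicInterval],
) -> list[GenomicInterval]:
    """Union a set of intervals into sorted, non-overlapping pieces.

    Touching intervals (end + 1 == next start) are merged: for coverage and
    target accounting, contiguous bases form one region.  Labels of merged
    inputs are joined with ``;`` (empty labels dropped).
    """
    ivs = sorted(intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))
    out: list[GenomicInterval] = []
    for iv in ivs:
        if out and out[-1].chrom == iv.chrom and iv.start <= out[-1].end + 1:
            last = out[-1]
            labels = [x for x in (last.label, iv.label) if x]
            # de-dup labels introduced by idempotent re-merging
            seen: list[str] = []
            for part in ";".join(labels).split(";"):
                if part and part not in seen:
                    seen.append(part)
            out[-1] = GenomicInterval(
                last.chrom, last.start, max(last.end, iv.end), ";".join(seen)
            )
        else:
            out.append(iv)
    return out


class RegionIndex:
    """Fast point-in-region lookup over a set of genomic intervals."""

    def __init__(self, intervals: Iterable[GenomicInterval]) -> None:
        self._trees: dict[str, IntervalTree] = {}
        self.intervals = list(intervals)
        for iv in self.intervals:
            # intervaltree is half-open; shift the inclusive end by one
            self._trees.setdefault(iv.chrom, IntervalTree()).addi(
                iv.start, iv.end + 1, iv
            )

    def __len__(self) -> int:
        return len(self.intervals)

    def contains(self, chrom: str, pos: int) -> bool:
        tree = self._trees.get(chrom)
        return bool(tree is not None and tree.overlaps(pos))

    def overlapping(self, chrom: str, start: int, end: int) -> list[GenomicInterval]:
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        hits = [h.data for h in tree.overlap(start, end + 1)]
        return sorted(hits, key=lambda iv: (iv.start, iv.end))


def read_bed(path) -> list[GenomicInterval]:
    """Read a BED3+ file into 1-based inclusive intervals.

    Column 4, when present, becomes the interval label.  Track/browser and
    comment lines are skipped.
    """
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(
                    f"{path}:{lineno}: BED line has fewer than 3 columns"
                )
            chrom, start0, end0 = parts[0], int(parts[1]), int(parts[2])
            label = parts[3] if len(parts) > 3 else ""
            out.append(GenomicInterval(chrom, start0 + 1, end0, label))
    return out


def write_bed(intervals: Iterable[GenomicInterval], path) -> None:
    """Write intervals as BED (0-based half-open), preserving labels."""
    with open(path, "w") as fh:
        for iv in intervals:
            cols = [iv.chrom, str(iv.start - 1), str(iv.end)]
            if iv.label:
                cols.append(iv.label)
            fh.write("\t".join(cols) + "\n")
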