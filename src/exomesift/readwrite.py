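"""Readers and writers for the tabular formats of the pipeline.

Covers single-sample VCF (via pysam), the annotated-variant TSV dialect,
gene-panel lists, curated-variant score lists, local observation-count
tables and the serialisable filtering-parameters audit file.

The annotated-variant dialect is a declared stand-in for the kind of table
a commercial annotation engine exports: tab-separated, one header row, the
missing-value sentinel is ``.`` throughout (VCF convention).  Columns beyond
the mandatory schema are carried through reads and writes as opaque extras.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

import pandas as pd
import pysam

from .core import (
    AnnotatedVariant,
    ConsequenceClass,
    GenomicInterval,
    Zygosity,
)

__all__ = [
    "FilterParameters",
    "CuratedVariantList",
    "SchemaError",
    "MANDATORY_COLUMNS",
    "DEFAULT_CONSEQUENCE_KEEP",
    "read_vcf",
    "read_annotated_table",
    "write_annotated_table",
    "read_gene_panel",
    "read_curated_list",
    "read_observation_counts",
    "annotate_with_curated_scores",
    "annotate_observation_counts",
    "save_parameters",
    "load_parameters",
]

MISSING = "."

MANDATORY_COLUMNS = [
    "chrom",
    "pos",
    "ref",
    "alt",
    "gene",
    "transcript",
    "cnomen",
    "pnomen",
    "consequence",
    "splice_distance",
    "zygosity",
    "quality",
    "depth",
    "alt_depth",
    "dbsnp_id",
    "maf",
    "observation_count",
    "pathogenicity_score",
]

#: Default classes kept by the consequence filter: exonic coding plus the
#: splice region.  UTR and deep-intronic variants are excluded by default.
DEFAULT_CONSEQUENCE_KEEP = frozenset(
    {
        ConsequenceClass.SYNONYMOUS,
        ConsequenceClass.MISSENSE,
        ConsequenceClass.NONSENSE,
        ConsequenceClass.FRAMESHIFT,
        ConsequenceClass.INFRAME_INDEL,
        ConsequenceClass.SPLICE_REGION,
    }
)

PARAMS_SCHEMA_VERSION = 1


class SchemaError(ValueError):
    """A table is missing mandatory columns or is internally inconsistent."""


@dataclass
class FilterParameters:
    """The complete, serialisable description of one filtering session.

    Saved parameter files double as the audit log of a diagnostic run:
    they are human-readable key=value text with a schema-version line, an
    ISO-8601 timestamp and, when attached to a run, the per-step variant
    counts of the cascade.

    Defaults: quality/depth thresholds of 0 (no-op, so the default cascade
    reports only the region → consequence → frequency → protein-altering →
    inheritance reductions), a 10 bp splice window, a dbSNP MAF cut-off of
    0.10 (variants with MAF ≥ 0.10 are excluded; missing MAF survives).
    """

    min_quality: float = 0.0
    min_depth: int = 0
    regions: Optional[list[GenomicInterval]] = None
    gene_panel: Optional[frozenset[str]] = None
    consequence_keep: frozenset = DEFAULT_CONSEQUENCE_KEEP
    splice_window_bp: int = 10
    max_maf: float = 0.10
    inheritance_mode: str = "none"
    min_pindel_supporting_reads: int = 10
    notes: str = ""

    _MODES = ("dominant", "recessive_consanguineous", "recessive_compound_het", "none")

    def __post_init__(self) -> None:
        if self.splice_window_bp < 0:
            raise ValueError("splice_window_bp must be >= 0")
        if not 0.0 <= self.max_maf <= 1.0:
            raise ValueError(f"max_maf out of [0, 1]: {self.max_maf}")
        if self.inheritance_mode not in self._MODES:
            raise ValueError(
                f"inheritance_mode must be one of {self._MODES}, "
                f"got {self.inheritance_mode!r}"
            )
        if self.gene_panel is not None:
            self.gene_panel = frozenset(g.upper() for g in self.gene_panel)
        self.consequence_keep = frozenset(self.consequence_keep)


@dataclass
class CuratedVariantList:
    """Mapping from (chrom, pos, ref, alt) to a curated pathogenicity score."""

    scores: dict[tuple[str, int, str, str], float] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.scores)


# ---------------------------------------------------------------------------
# VCF

_PLOIDY_2_HOM = 2


def _zygosity_from_gt(gt: Optional[tuple], allele_index: int) -> Zygosity:
    if gt is None:
        return Zygosity.UNKNOWN
    called = [a for a in gt if a is not None]
    if not called:
        return Zygosity.UNKNOWN
    copies = called.count(allele_index)
    if copies == 0:
        return Zygosity.UNKNOWN
    if len(called) == 1:
        return Zygosity.HEMIZYGOUS
    if copies == len(called):
        return Zygosity.HOMOZYGOUS
    return Zygosity.HETEROZYGOUS


def read_vcf(path) -> list[AnnotatedVariant]:
    """Read a single-sample VCF into bare :class:`AnnotatedVariant` rows.

    Annotation fields (gene, consequence, MAF, ...) are left unset; only the
    call itself is populated.  Multi-allelic records are split into one row
    per alternate allele.  Zygosity comes from the sample GT (0/1 →
    heterozygous, 1/1 → homozygous, haploid 1 → hemizygous, missing →
    unknown), depth from FORMAT DP (falling back to INFO DP, then to the sum
    of AD), alt-supporting depth from FORMAT AD when present.
    """
    out: list[AnnotatedVariant] = []
    try:
        vcf = pysam.VariantFile(str(path))
    except (OSError, ValueError) as exc:
        raise ValueError(f"cannot read VCF {path}: {exc}") from exc
    with vcf:
        samples = list(vcf.header.samples)
        for rec in vcf:
            sample = rec.samples[samples[0]] if samples else None
            gt = sample.get("GT") if sample is not None else None
            ad = sample.get("AD") if sample is not None else None
            dp = None
            if sample is not None and sample.get("DP") is not None:
                dp = sample["DP"]
            elif "DP" in rec.info:
                dp = rec.info["DP"]
            for i, alt in enumerate(rec.alts or ()):
                alt_depth = 0
                if ad is not None and len(ad) > i + 1 and ad[i + 1] is not None:
                    alt_depth = int(ad[i + 1])
                depth = int(dp) if dp is not None else 0
                if depth == 0 and ad is not None:
                    depth = int(sum(a for a in ad if a is not None))
                out.append(
                    AnnotatedVariant(
                        chrom=rec.chrom,
                        pos=rec.pos,
                        ref=rec.ref or "",
                        alt=str(alt),
                        quality=float(rec.qual) if rec.qual is not None else 0.0,
                        depth=depth,
                        alt_depth=min(alt_depth, depth),
                        zygosity=_zygosity_from_gt(gt, i + 1),
                        dbsnp_id=rec.id or "",
                    )
                )
    return out


# ---------------------------------------------------------------------------
# Annotated-variant TSV dialect


def _fmt(value) -> str:
    if value is None or value == "":
        return MISSING
    if isinstance(value, float):
        return repr(value)
    return str(value)


def write_annotated_table(variants: Iterable[AnnotatedVariant], path) -> None:
    variants = list(variants)
    extra_cols: list[str] = []
    for v in variants:
        for k in v.extras:
            if k not in extra_cols:
                extra_cols.append(k)
    cols = MANDATORY_COLUMNS + extra_cols
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for v in variants:
            row = [
                v.chrom,
                str(v.pos),
                v.ref,
                v.alt,
                _fmt(v.gene),
                _fmt(v.transcript),
                _fmt(v.cnomen),
                _fmt(v.pnomen),
                v.consequence.value,
                _fmt(v.splice_distance),
                v.zygosity.value,
                _fmt(v.quality),
                str(v.depth),
                str(v.alt_depth),
                _fmt(v.dbsnp_id),
                _fmt(v.maf),
                str(v.observation_count),
                _fmt(v.pathogenicity_score),
            ]
            row += [_fmt(v.extras.get(k)) for k in extra_cols]
            fh.write("\t".join(row) + "\n")


def _opt_float(s: str) -> Optional[float]:
    return None if s == MISSING else float(s)


def _opt_int(s: str) -> Optional[int]:
    return None if s == MISSING else int(s)


def read_annotated_table(path) -> list[AnnotatedVariant]:
    """Read the annotated-variant TSV dialect into typed rows.

    Raises :class:`SchemaError` naming every missing mandatory column.
    Missing MAF / score cells (``.``) become ``None``, never 0.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(
            f"{path}: missing mandatory columns: {', '.join(missing)}"
        )
    extra_cols = [c for c in df.columns if c not in MANDATORY_COLUMNS]
    out: list[AnnotatedVariant] = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        out.append(
            AnnotatedVariant(
                chrom=d["chrom"],
                pos=int(d["pos"]),
                ref=d["ref"],
                alt=d["alt"],
                gene="" if d["gene"] == MISSING else d["gene"],
                transcript="" if d["transcript"] == MISSING else d["transcript"],
                cnomen="" if d["cnomen"] == MISSING else d["cnomen"],
                pnomen="" if d["pnomen"] == MISSING else d["pnomen"],
                consequence=ConsequenceClass(d["consequence"]),
                splice_distance=_opt_int(d["splice_distance"]),
                zygosity=Zygosity(d["zygosity"]),
                quality=float(d["quality"]) if d["quality"] != MISSING else 0.0,
                depth=int(d["depth"]),
                alt_depth=int(d["alt_depth"]),
                dbsnp_id="" if d["dbsnp_id"] == MISSING else d["dbsnp_id"],
                maf=_opt_float(d["maf"]),
                observation_count=int(d["observation_count"]),
                pathogenicity_score=_opt_float(d["pathogenicity_score"]),
                extras={k: d[k] for k in extra_cols if d[k] != MISSING},
            )
        )
    return out


# ---------------------------------------------------------------------------
# Panels, curated scores, observation counts


def read_gene_panel(path) -> frozenset[str]:
    """One gene symbol per line; '#' comments allowed.  Upper-cased on read."""
    genes = set()
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                genes.add(line.upper())
    return frozenset(genes)


def _read_keyed_tsv(path, value_col: str) -> dict[tuple[str, int, str, str], float]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    needed = ["chrom", "pos", "ref", "alt", value_col]
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns: {', '.join(missing)}")
    out: dict[tuple[str, int, str, str], float] = {}
    for row in df.itertuples(index=False):
        d = row._asdict()
        key = (d["chrom"], int(d["pos"]), d["ref"], d["alt"])
        if key in out:
            raise SchemaError(
                f"{path}: duplicate key {key[0]}:{key[1]} {key[2]}>{key[3]}"
            )
        out[key] = float(d[value_col])
    return out


def read_curated_list(path) -> CuratedVariantList:
    """TSV keyed by chrom,pos,ref,alt with a pathogenicity ``score`` column."""
    return CuratedVariantList(_read_keyed_tsv(path, "score"))


def read_observation_counts(path) -> dict[tuple[str, int, str, str], int]:
    """TSV keyed by chrom,pos,ref,alt with a local-cohort ``count`` column.

    Duplicate keys raise :class:`SchemaError` — the source is ambiguous.
    """
    return {k: int(v) for k, v in _read_keyed_tsv(path, "count").items()}


def annotate_with_curated_scores(
    variants: Sequence[AnnotatedVariant], curated: CuratedVariantList
) -> list[AnnotatedVariant]:
    """Attach curated pathogenicity scores on exact (chrom,pos,ref,alt) match."""
    out = []
    for v in variants:
        score = curated.scores.get(v.key)
        out.append(v if score is None else replace(v, pathogenicity_score=score))
    return out


def annotate_observation_counts(
    variants: Sequence[AnnotatedVariant],
    counts: dict[tuple[str, int, str, str], int],
) -> list[AnnotatedVariant]:
    """Attach local-cohort observation counts; absent keys count as 0."""
    return [replace(v, observation_count=counts.get(v.key, 0)) for v in variants]


# ---------------------------------------------------------------------------
# Parameters file

_ENUM_BY_VALUE = {c.value: c for c in ConsequenceClass}


def _regions_to_text(regions: Optional[list[GenomicInterval]]) -> str:
    if not regions:
        return MISSING
    parts = []
    for iv in regions:
        s = f"{iv.chrom}:{iv.start}-{iv.end}"
        if iv.label:
            s += f"|{iv.label}"
        parts.append(s)
    return ";".join(parts)


def _regions_from_text(text: str) -> Optional[list[GenomicInterval]]:
    if text == MISSING or not text:
        return None
    out = []
    for part in text.split(";"):
        locus, _, label = part.partition("|")
        chrom, _, span = locus.partition(":")
        lo, _, hi = span.partition("-")
        out.append(GenomicInterval(chrom, int(lo), int(hi), label))
    return out


def save_parameters(
    params: FilterParameters,
    path,
    step_counts: Optional[list[tuple[str, int, int]]] = None,
    timestamp: Optional[str] = None,
) -> None:
    """Write a human-readable, diff-able audit file for one filter session.

    ``step_counts`` — (step name, variants in, variants out) triples from a
    cascade run — are recorded as comments so the file doubles as the log of
    the filtering procedure.  ``timestamp`` overrides the recorded ISO-8601
    save time (for reproducible output).
    """
    if timestamp is None:
        timestamp = _dt.datetime.now().isoformat(timespec="seconds")
    lines = [
        "# exomesift filtering parameters",
        f"schema_version={PARAMS_SCHEMA_VERSION}",
        f"saved_at={timestamp}",
        f"min_quality={params.min_quality!r}",
        f"min_depth={params.min_depth}",
        f"regions={_regions_to_text(params.regions)}",
        "gene_panel="
        + (MISSING if params.gene_panel is None else ",".join(sorted(params.gene_panel))),
        "consequence_keep="
        + ",".join(sorted(c.value for c in params.consequence_keep)),
        f"splice_window_bp={params.splice_window_bp}",
        f"max_maf={params.max_maf!r}",
        f"inheritance_mode={params.inheritance_mode}",
        f"min_pindel_supporting_reads={params.min_pindel_supporting_reads}",
        "notes=" + params.notes.replace("\n", " "),
    ]
    if step_counts:
        lines.append("# per-step variant counts")
        for name, n_in, n_out in step_counts:
            lines.append(f"# step {name}: {n_in} -> {n_out}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def load_parameters(path) -> FilterParameters:
    """Load a parameters file saved by :func:`save_parameters`.

    An unknown key or a schema-version mismatch raises ``ValueError`` naming
    the offending key/version — silent drift in a diagnostic audit file is
    worse than a hard failure.
    """
    kv: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected key=value")
            key, _, value = line.partition("=")
            kv[key] = value
    version = kv.pop("schema_version", None)
    if version != str(PARAMS_SCHEMA_VERSION):
        raise ValueError(
            f"{path}: schema_version {version!r} does not match "
            f"{PARAMS_SCHEMA_VERSION}"
        )
    kv.pop("saved_at", None)
    known = {
        "min_quality",
        "min_depth",
        "regions",
        "gene_panel",
        "consequence_keep",
        "splice_window_bp",
        "max_maf",
        "inheritance_mode",
        "min_pindel_supporting_reads",
        "notes",
    }
    unknown = set(kv) - known
    if unknown:
        raise ValueError(f"{path}: unknown key(s): {', '.join(sorted(unknown))}")
    panel = kv.get("gene_panel", MISSING)
    keep = frozenset(
        _ENUM_BY_VALUE[v] for v in kv["consequence_keep"].split(",") if v
    )
    return FilterParameters(
        min_quality=float(kv["min_quality"]),
        min_depth=int(kv["min_depth"]),
        regions=_regions_from_text(kv.get("regions", MISSING)),
        gene_panel=None if panel == MISSING else frozenset(panel.split(",")),
        consequence_keep=keep,
        splice_window_bp=int(kv["splice_window_bp"]),
        max_maf=float(kv["max_maf"]),
        inheritance_mode=kv["inheritance_mode"],
        min_pindel_supporting_reads=int(kv["min_pindel_supporting_reads"]),
        notes=kv.get("notes", ""),
    )
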