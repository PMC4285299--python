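"""The variant filter cascade.

An ordered sequence of predicate filters is applied to a list of annotated
variants, recording the in/out count at every step — the shape of the
per-patient reduction report a diagnostic lab signs off on.  Filters only
ever drop rows: no step may create or mutate a variant, so every step's
output is a subset of its input and counts are monotone non-increasing.

Inheritance-model logic uses unphased heuristics: under a recessive model
without known consanguinity, a gene with two or more distinct heterozygous
variants is flagged as *possibly* compound heterozygous (short-read data
cannot phase the pair), alongside any homozygous variant.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .core import (
    AnnotatedVariant,
    ConsequenceClass,
    GenomicInterval,
    PROTEIN_ALTERING,
    RegionIndex,
    Zygosity,
)
from .readwrite import FilterParameters, write_annotated_table

__all__ = [
    "CascadeReport",
    "filter_quality",
    "filter_regions",
    "filter_consequence",
    "filter_frequency",
    "filter_protein_altering",
    "filter_inheritance",
    "run_cascade",
    "DEFAULT_STEP_ORDER",
]

DEFAULT_STEP_ORDER = (
    "quality",
    "region",
    "consequence",
    "frequency",
    "protein_altering",
    "inheritance",
)


@dataclass
class CascadeStep:
    name: str
    description: str
    variants_in: int
    variants_out: int


@dataclass
class CascadeReport:
    """Per-step audit of one cascade run plus the surviving variants."""

    steps: list[CascadeStep] = field(default_factory=list)
    survivors: list[AnnotatedVariant] = field(default_factory=list)

    def counts(self) -> list[tuple[str, int, int]]:
        return [(s.name, s.variants_in, s.variants_out) for s in self.steps]

    def write(self, report_path, survivors_path=None) -> None:
        """Write the step table as TSV; optionally the surviving variants."""
        with open(report_path, "w") as fh:
            fh.write("step\tdescription\tvariants_in\tvariants_out\n")
            for s in self.steps:
                fh.write(
                    f"{s.name}\t{s.description}\t{s.variants_in}\t{s.variants_out}\n"
                )
        if survivors_path is not None:
            write_annotated_table(self.survivors, survivors_path)


def filter_quality(
    variants: Sequence[AnnotatedVariant], min_quality: float, min_depth: int
) -> list[AnnotatedVariant]:
    """Keep rows with quality >= min_quality and depth >= min_depth."""
    if min_quality < 0 or min_depth < 0:
        raise ValueError("quality/depth thresholds must be >= 0")
    return [
        v for v in variants if v.quality >= min_quality and v.depth >= min_depth
    ]


def filter_regions(
    variants: Sequence[AnnotatedVariant],
    regions: Optional[Iterable[GenomicInterval]] = None,
    gene_panel: Optional[Iterable[str]] = None,
) -> list[AnnotatedVariant]:
    """Keep rows inside a genomic region or with a gene symbol on the panel.

    Union semantics when both are given.  Gene matching is case-insensitive
    (panel lists are hand-curated).  Calling with neither regions nor panel
    is an error: it would silently drop every variant.
    """
    region_list = list(regions) if regions is not None else []
    panel = (
        {g.upper() for g in gene_panel} if gene_panel is not None else set()
    )
    if not region_list and not panel:
        raise ValueError(
            "filter_regions needs a non-empty region list and/or gene panel"
        )
    index = RegionIndex(region_list)
    return [
        v
        for v in variants
        if (panel and v.gene.upper() in panel) or index.contains(v.chrom, v.pos)
    ]


def filter_consequence(
    variants: Sequence[AnnotatedVariant],
    keep: Iterable[ConsequenceClass],
    splice_window_bp: int = 10,
) -> list[AnnotatedVariant]:
    """Keep rows whose class is in ``keep`` or that sit within the splice window.

    The splice window rescues rows of *any* class whose distance to the
    nearest exon boundary is at most ``splice_window_bp`` (boundary
    inclusive): an intronic variant 10 bp from the exon is a splice-site
    candidate even though its class says intronic.
    """
    if splice_window_bp < 0:
        raise ValueError("splice_window_bp must be >= 0")
    keep_set = frozenset(keep)
    return [
        v
        for v in variants
        if v.consequence in keep_set
        or (
            v.splice_distance is not None
            and abs(v.splice_distance) <= splice_window_bp
        )
    ]


def filter_frequency(
    variants: Sequence[AnnotatedVariant], max_maf: float
) -> list[AnnotatedVariant]:
    """Drop rows with a known dbSNP MAF >= max_maf; missing MAF is kept.

    Novel variants (no population frequency) are the diagnostic target and
    must survive this step.
    """
    if not 0.0 <= max_maf <= 1.0:
        raise ValueError(f"max_maf out of [0, 1]: {max_maf}")
    return [v for v in variants if v.maf is None or v.maf < max_maf]


def filter_protein_altering(
    variants: Sequence[AnnotatedVariant],
) -> list[AnnotatedVariant]:
    """Drop synonymous coding rows; keep everything else.

    Missense, nonsense, frameshift, in-frame indel and splice-region rows
    are kept; intronic/UTR rows not already removed upstream pass through
    unchanged.
    """
    return [
        v for v in variants if v.consequence is not ConsequenceClass.SYNONYMOUS
    ]


def filter_inheritance(
    variants: Sequence[AnnotatedVariant], mode: str
) -> list[AnnotatedVariant]:
    """Apply an inheritance-model zygosity filter.

    ``dominant`` keeps heterozygous rows only; ``recessive_consanguineous``
    homozygous (or hemizygous) rows only; ``recessive_compound_het`` keeps
    homozygous/hemizygous rows plus every heterozygous row in any gene
    carrying at least two distinct heterozygous variants (possible compound
    heterozygote — unphased); ``none`` is the identity.  Rows with unknown
    zygosity are dropped in every non-``none`` mode.
    """
    if mode == "none":
        return list(variants)
    if mode == "dominant":
        return [v for v in variants if v.zygosity is Zygosity.HETEROZYGOUS]
    hom = {Zygosity.HOMOZYGOUS, Zygosity.HEMIZYGOUS}
    if mode == "recessive_consanguineous":
        return [v for v in variants if v.zygosity in hom]
    if mode == "recessive_compound_het":
        het_keys_by_gene: dict[str, set] = {}
        for v in variants:
            if v.zygosity is Zygosity.HETEROZYGOUS and v.gene:
                het_keys_by_gene.setdefault(v.gene.upper(), set()).add(v.key)
        biallelic_genes = {
            g for g, keys in het_keys_by_gene.items() if len(keys) >= 2
        }
        return [
            v
            for v in variants
            if v.zygosity in hom
            or (
                v.zygosity is Zygosity.HETEROZYGOUS
                and v.gene.upper() in biallelic_genes
            )
        ]
    raise ValueError(f"unknown inheritance mode {mode!r}")


def _step_description(name: str, params: FilterParameters) -> str:
    if name == "quality":
        return (
            f"quality >= {params.min_quality} and depth >= {params.min_depth}"
        )
    if name == "region":
        parts = []
        if params.gene_panel:
            parts.append(f"{len(params.gene_panel)}-gene panel")
        if params.regions:
            parts.append(f"{len(params.regions)} regions")
        return "retain if in " + " or ".join(parts)
    if name == "consequence":
        return (
            "retain if exonic/splice ("
            + ",".join(sorted(c.value for c in params.consequence_keep))
            + f") or within {params.splice_window_bp} bp of an exon"
        )
    if name == "frequency":
        return f"exclude if dbSNP MAF >= {params.max_maf}"
    if name == "protein_altering":
        return "exclude synonymous variants"
    if name == "inheritance":
        return f"inheritance model: {params.inheritance_mode}"
    return name


def run_cascade(
    variants: Sequence[AnnotatedVariant],
    params: FilterParameters,
    step_order: Sequence[str] = DEFAULT_STEP_ORDER,
) -> CascadeReport:
    """Apply the configured filter steps in order, recording in/out counts.

    Steps with nothing configured are skipped rather than recorded as
    identity: the region step is skipped when neither regions nor a gene
    panel is set, and the inheritance step when the mode is ``none``.
    Counts are order-dependent, so the step order is part of the audit log.
    """
    report = CascadeReport()
    current = list(variants)
    for name in step_order:
        if name == "region" and not params.regions and not params.gene_panel:
            continue
        if name == "inheritance" and params.inheritance_mode == "none":
            continue
        n_in = len(current)
        try:
            if name == "quality":
                current = filter_quality(
                    current, params.min_quality, params.min_depth
                )
            elif name == "region":
                current = filter_regions(
                    current, params.regions, params.gene_panel
                )
            elif name == "consequence":
                current = filter_consequence(
                    current, params.consequence_keep, params.splice_window_bp
                )
            elif name == "frequency":
                current = filter_frequency(current, params.max_maf)
            elif name == "protein_altering":
                current = filter_protein_altering(current)
            elif name == "inheritance":
                current = filter_inheritance(current, params.inheritance_mode)
            else:
                raise ValueError(f"unknown cascade step {name!r}")
        except ValueError as exc:
            raise ValueError(f"cascade step {name!r}: {exc}") from exc
        report.steps.append(
            CascadeStep(name, _step_description(name, params), n_in, len(current))
        )
    report.survivors = current
    return report
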