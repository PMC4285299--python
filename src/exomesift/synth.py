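"""Synthetic inputs with known ground truth.

Every generator here fabricates one of the pipeline's input artefacts —
annotated variant cohorts, split-read read sets around a deletion,
SNP-array pedigree genotypes, Pindel-style event files, per-base depth
tracks — deterministically from a seed, together with a machine-readable
truth record.  Downstream parameter-recovery tests consume the truth
records; they never re-derive them.

The default cohort composition is calibrated to the per-patient filtering
trajectory of a whole-exome recessive-disease screen: ~33,143 variants in
total, of which on average 94 fall in an 18-gene panel, 66 of those are
exonic or within 10 bp of an exon, 15 survive a dbSNP MAF < 0.10 cut,
10 are non-synonymous, and 7 are homozygous or possibly compound
heterozygous.  Those printed means are converted to per-variant category
probabilities; the inheritance step is a property of gene-level grouping
rather than an independent per-variant draw, so only the first four ratios
are exact expectations.

Generated files use the exact dialects the readers define, so integration
tests exercise the real parsers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .core import AnnotatedVariant, ConsequenceClass, GenomicInterval, Zygosity
from .pindel import PindelEvent
from .roh import GenotypeTable
from .coverage import DepthTrack
from .splitread import ReadPair

__all__ = [
    "PCD_PANEL",
    "CohortSpec",
    "CohortTruth",
    "make_cohort",
    "DeletionTruth",
    "make_deletion_readset",
    "make_pedigree_genotypes",
    "make_pindel_events",
    "make_depth_track",
]

#: 18-gene recessive ciliopathy panel used as the default query set.
PCD_PANEL = (
    "DNAI1", "DNAI2", "DNAH5", "DNAH11", "DNAL1", "NME8",
    "LRRC6", "CCDC39", "CCDC40", "CCDC103", "CCDC114", "HEATR2",
    "HYDIN", "RSPH4A", "RSPH9", "DNAAF1", "DNAAF2", "DNAAF3",
)

# Table-shaped per-variant category probabilities (mean counts 33143 → 94
# → 66 → 15 → 10 along the default cascade)
_P_PANEL = 94 / 33143
_P_EXONIC_GIVEN_PANEL = 66 / 94
_P_COMMON_GIVEN_EXONIC = 51 / 66
_P_SYNONYMOUS_GIVEN_EXONIC = 5 / 15

_CODING_NONSYN = (
    (ConsequenceClass.MISSENSE, 0.76),
    (ConsequenceClass.NONSENSE, 0.06),
    (ConsequenceClass.FRAMESHIFT, 0.05),
    (ConsequenceClass.INFRAME_INDEL, 0.03),
    (ConsequenceClass.SPLICE_REGION, 0.10),
)


@dataclass
class CohortSpec:
    """Composition of one synthetic patient variant cohort.

    Fractions are per-variant category probabilities; defaults reproduce the
    mean filtering trajectory described in the module docstring.  ``seed``
    is mandatory: every cohort is reproducible.
    """

    seed: int
    n_total_variants: int = 33143
    panel_genes: Sequence[str] = PCD_PANEL
    fraction_in_panel: float = _P_PANEL
    fraction_exonic_splice: float = _P_EXONIC_GIVEN_PANEL
    fraction_common: float = _P_COMMON_GIVEN_EXONIC
    fraction_maf_missing_given_rare: float = 0.5
    fraction_synonymous: float = _P_SYNONYMOUS_GIVEN_EXONIC
    fraction_homozygous: float = 0.22
    inheritance_mode: str = "none"
    plant_causal: bool = False

    def __post_init__(self) -> None:
        for name in (
            "fraction_in_panel",
            "fraction_exonic_splice",
            "fraction_common",
            "fraction_maf_missing_given_rare",
            "fraction_synonymous",
            "fraction_homozygous",
        ):
            x = getattr(self, name)
            if not 0.0 <= x <= 1.0:
                raise ValueError(f"{name} out of [0, 1]: {x}")
        if self.n_total_variants < 0:
            raise ValueError("n_total_variants must be >= 0")


@dataclass
class CohortTruth:
    """Ground truth emitted beside a synthetic cohort."""

    causal_keys: list[tuple[str, int, str, str]]
    causal_gene: str
    expected_survivor_keys: set[tuple[str, int, str, str]]
    inheritance_mode: str


def _draw_consequence(rng: np.random.Generator, spec: CohortSpec) -> ConsequenceClass:
    if rng.random() < spec.fraction_synonymous:
        return ConsequenceClass.SYNONYMOUS
    classes, weights = zip(*_CODING_NONSYN)
    w = np.asarray(weights) / sum(weights)
    return classes[rng.choice(len(classes), p=w)]


def _draw_maf(rng: np.random.Generator, spec: CohortSpec) -> Optional[float]:
    if rng.random() < spec.fraction_common:
        return round(float(rng.uniform(0.10, 0.50)), 4)
    if rng.random() < spec.fraction_maf_missing_given_rare:
        return None
    return round(float(rng.uniform(0.0001, 0.0999)), 4)


def _make_variant(
    rng: np.random.Generator,
    spec: CohortSpec,
    used_pos: set,
) -> AnnotatedVariant:
    in_panel = rng.random() < spec.fraction_in_panel
    if in_panel:
        gene = spec.panel_genes[int(rng.integers(len(spec.panel_genes)))]
    else:
        gene = f"GENE{int(rng.integers(1, 15000)):05d}"
    chrom = f"chr{int(rng.integers(1, 23))}"
    while True:
        pos = int(rng.integers(1, 240_000_000))
        if (chrom, pos) not in used_pos:
            used_pos.add((chrom, pos))
            break
    bases = "ACGT"
    ref = bases[int(rng.integers(4))]
    alt = bases[(bases.index(ref) + 1 + int(rng.integers(3))) % 4]
    if in_panel and rng.random() < spec.fraction_exonic_splice:
        consequence = _draw_consequence(rng, spec)
        if consequence is ConsequenceClass.SPLICE_REGION:
            sd = int(rng.integers(1, 11)) * (1 if rng.random() < 0.5 else -1)
        else:
            sd = 0
    elif in_panel:
        consequence = ConsequenceClass.INTRONIC
        sd = int(rng.integers(11, 5000)) * (1 if rng.random() < 0.5 else -1)
    else:
        consequence = _draw_consequence(rng, spec)
        sd = 0
    maf = _draw_maf(rng, spec)
    zyg = (
        Zygosity.HOMOZYGOUS
        if rng.random() < spec.fraction_homozygous
        else Zygosity.HETEROZYGOUS
    )
    depth = int(rng.integers(20, 200))
    alt_depth = (
        depth
        if zyg is Zygosity.HOMOZYGOUS
        else int(np.clip(rng.binomial(depth, 0.5), 1, depth))
    )
    return AnnotatedVariant(
        chrom=chrom,
        pos=pos,
        ref=ref,
        alt=alt,
        gene=gene,
        transcript=f"NM_{int(rng.integers(1, 999999)):06d}.1",
        cnomen=f"c.{int(rng.integers(1, 9000))}{ref}>{alt}",
        pnomen="",
        consequence=consequence,
        splice_distance=sd,
        zygosity=zyg,
        quality=round(float(rng.uniform(100, 3000)), 2),
        depth=depth,
        alt_depth=alt_depth,
        maf=maf,
        dbsnp_id=f"rs{int(rng.integers(1, 10**8))}" if maf is not None else "",
        observation_count=int(rng.integers(0, 5)),
    )


def _plant_causal(
    rng: np.random.Generator, spec: CohortSpec, used_pos: set
) -> list[AnnotatedVariant]:
    gene = spec.panel_genes[int(rng.integers(len(spec.panel_genes)))]
    if spec.inheritance_mode == "dominant":
        zygs = [Zygosity.HETEROZYGOUS]
    elif spec.inheritance_mode == "recessive_consanguineous":
        zygs = [Zygosity.HOMOZYGOUS]
    elif spec.inheritance_mode == "recessive_compound_het":
        zygs = [Zygosity.HETEROZYGOUS, Zygosity.HETEROZYGOUS]
    else:
        raise ValueError(
            "plant_causal requires an inheritance mode other than 'none'"
        )
    chrom = f"chr{int(rng.integers(1, 23))}"
    out = []
    for zyg in zygs:
        while True:
            pos = int(rng.integers(1, 240_000_000))
            if (chrom, pos) not in used_pos:
                used_pos.add((chrom, pos))
                break
        depth = int(rng.integers(50, 200))
        out.append(
            AnnotatedVariant(
                chrom=chrom,
                pos=pos,
                ref="C",
                alt="T",
                gene=gene,
                transcript="NM_000001.1",
                cnomen=f"c.{int(rng.integers(1, 5000))}C>T",
                pnomen="p.Arg1*",
                consequence=ConsequenceClass.NONSENSE,
                splice_distance=0,
                zygosity=zyg,
                quality=round(float(rng.uniform(900, 3000)), 2),
                depth=depth,
                alt_depth=depth
                if zyg is Zygosity.HOMOZYGOUS
                else max(1, depth // 2),
                maf=None,
            )
        )
    return out


def _expected_survivors(
    variants: Sequence[AnnotatedVariant], spec: CohortSpec
) -> set:
    """Independent plain-loop prediction of the default cascade outcome."""
    panel = {g.upper() for g in spec.panel_genes}
    stage = [v for v in variants if v.gene.upper() in panel]
    stage = [
        v
        for v in stage
        if v.consequence.value
        in ("synonymous", "missense", "nonsense", "frameshift",
            "inframe_indel", "splice_region")
        or (v.splice_distance is not None and abs(v.splice_distance) <= 10)
    ]
    stage = [v for v in stage if v.maf is None or v.maf < 0.10]
    stage = [v for v in stage if v.consequence.value != "synonymous"]
    mode = spec.inheritance_mode
    if mode == "dominant":
        stage = [v for v in stage if v.zygosity is Zygosity.HETEROZYGOUS]
    elif mode == "recessive_consanguineous":
        stage = [v for v in stage if v.zygosity is Zygosity.HOMOZYGOUS]
    elif mode == "recessive_compound_het":
        per_gene: dict[str, int] = {}
        for v in stage:
            if v.zygosity is Zygosity.HETEROZYGOUS:
                per_gene[v.gene.upper()] = per_gene.get(v.gene.upper(), 0) + 1
        stage = [
            v
            for v in stage
            if v.zygosity is Zygosity.HOMOZYGOUS
            or (
                v.zygosity is Zygosity.HETEROZYGOUS
                and per_gene.get(v.gene.upper(), 0) >= 2
            )
        ]
    return {v.key for v in stage}


def make_cohort(spec: CohortSpec) -> tuple[list[AnnotatedVariant], CohortTruth]:
    """Fabricate one annotated cohort and its ground truth.

    Deterministic for a fixed spec (seed included).  When ``plant_causal``
    is set, causal variant(s) consistent with ``inheritance_mode`` are
    inserted at a random position in the row order; the truth lists their
    keys and the expected survivor set of the default cascade.
    """
    rng = np.random.default_rng(spec.seed)
    used_pos: set = set()
    variants = [
        _make_variant(rng, spec, used_pos)
        for _ in range(spec.n_total_variants)
    ]
    causal: list[AnnotatedVariant] = []
    if spec.plant_causal:
        causal = _plant_causal(rng, spec, used_pos)
        for cv in causal:
            variants.insert(int(rng.integers(len(variants) + 1)), cv)
    truth = CohortTruth(
        causal_keys=[cv.key for cv in causal],
        causal_gene=causal[0].gene if causal else "",
        expected_survivor_keys=_expected_survivors(variants, spec),
        inheritance_mode=spec.inheritance_mode,
    )
    return variants, truth


# ---------------------------------------------------------------------------
# Split-read read sets


@dataclass
class DeletionTruth:
    chrom: str
    del_start: int
    del_end: int
    length: int
    detectable: bool
    n_straddling_retained: int
    n_background: int


def make_deletion_readset(
    ref_length: int = 5000,
    del_length: int = 510,
    n_pairs: int = 10,
    read_length: int = 100,
    insert_mean: int = 300,
    capture_mask: Optional[Sequence[GenomicInterval]] = None,
    n_background_pairs: int = 0,
    seed: int = 0,
    chrom: str = "ref",
) -> tuple[dict[str, str], list[ReadPair], DeletionTruth]:
    """Error-free read pairs straddling one heterozygous deletion.

    Builds a random reference, deletes ``del_length`` bases from one
    haplotype, and samples ``n_pairs`` fragments whose unplaced mate crosses
    the junction with at least 20 bases on each side (anchors fall on either
    flank at random).  With a capture mask, pairs whose anchor lies outside
    the mask are discarded — uncaptured fragments are never sequenced — and
    the truth marks the deletion undetectable when no breakpoint flank
    intersects the mask.  ``n_background_pairs`` adds fragments from the
    unbroken haplotype.
    """
    if del_length < 1:
        raise ValueError("del_length must be >= 1")
    margin = insert_mean + read_length + 50
    if ref_length < del_length + 2 * margin:
        raise ValueError(
            f"ref_length {ref_length} too short for deletion {del_length} "
            f"with margin {margin}"
        )
    rng = np.random.default_rng(seed)
    ref = "".join(rng.choice(list("ACGT"), size=ref_length))
    del_start = int(rng.integers(margin, ref_length - del_length - margin))
    del_end = del_start + del_length - 1
    # truth breakpoints are left-normalised (VCF convention), which is what
    # the detector reports; the deleted haplotype string is identical
    while del_start > 1 and ref[del_start - 2] == ref[del_end - 1]:
        del_start -= 1
        del_end -= 1
    alt = ref[: del_start - 1] + ref[del_end:]
    j0 = del_start - 1  # 0-based alt index of first base after the junction
    L = read_length
    ins = insert_mean

    def in_mask(pos: int) -> bool:
        if capture_mask is None:
            return True
        return any(iv.contains(chrom, pos) for iv in capture_mask)

    # rejection-sample straddling fragments until n_pairs are *captured*:
    # a fragment is sequenced only when its mappable (anchoring) read falls
    # in the capture mask
    pairs: list[ReadPair] = []
    attempts = 0
    while len(pairs) < n_pairs and attempts < 50 * max(1, n_pairs):
        attempts += 1
        left_anchored = bool(rng.integers(2))
        if left_anchored:
            r2 = int(rng.integers(j0 - L + 20, j0 - 20 + 1))
            f = r2 + L - ins
            anchor_pos = f + 1
            anchor_seq = alt[f : f + L]
            unmapped = alt[r2 : r2 + L]
            strand = "+"
        else:
            a = int(rng.integers(j0 + ins - 2 * L + 20, j0 + ins - L - 20 + 1))
            anchor_pos = a + del_length + 1
            anchor_seq = alt[a : a + L]
            r2 = a + L - ins
            unmapped = alt[r2 : r2 + L]
            strand = "-"
        if not in_mask(anchor_pos):
            continue
        pairs.append(
            ReadPair(
                name=f"straddle_{len(pairs)}",
                anchor_chrom=chrom,
                anchor_pos=anchor_pos,
                anchor_strand=strand,
                anchor_seq=anchor_seq,
                unmapped_seq=unmapped,
            )
        )
    n_retained = len(pairs)
    for k in range(n_background_pairs):
        f = int(rng.integers(0, ref_length - ins))
        if not in_mask(f + 1):
            continue
        pairs.append(
            ReadPair(
                name=f"background_{k}",
                anchor_chrom=chrom,
                anchor_pos=f + 1,
                anchor_strand="+",
                anchor_seq=ref[f : f + L],
                unmapped_seq=ref[f + ins - L : f + ins],
            )
        )
    left_flank = GenomicInterval(chrom, max(1, del_start - ins), max(1, del_start - 1))
    right_flank = GenomicInterval(chrom, del_end + 1, del_end + ins)
    detectable = capture_mask is None or any(
        iv.chrom == chrom
        and iv.start <= flank.end
        and iv.end >= flank.start
        for iv in capture_mask
        for flank in (left_flank, right_flank)
    )
    truth = DeletionTruth(
        chrom=chrom,
        del_start=del_start,
        del_end=del_end,
        length=del_length,
        detectable=detectable,
        n_straddling_retained=n_retained,
        n_background=n_background_pairs,
    )
    return {chrom: ref}, pairs, truth


# ---------------------------------------------------------------------------
# Pedigree genotypes


def make_pedigree_genotypes(
    n_markers: int = 3000,
    tracts: Sequence[tuple[int, int]] = ((10_000_000, 15_000_000),),
    samples: Optional[dict[str, bool]] = None,
    het_error_rate: float = 0.002,
    missing_rate: float = 0.01,
    flank_het_markers: int = 3,
    chrom: str = "chr6",
    start_bp: int = 1_000_000,
    spacing_bp: int = 10_000,
    seed: int = 0,
) -> tuple[GenotypeTable, list[GenomicInterval]]:
    """SNP genotypes for a sibship with planted shared autozygous tracts.

    Markers are evenly spaced on one chromosome.  Inside every planted
    tract, all *affected* samples share one homozygous haplotype pattern
    (AA/BB per marker), perturbed to AB at ``het_error_rate`` (typical
    SNP-array discordance) and to no-call at ``missing_rate``.  Unaffected
    samples and all background positions draw independent
    Hardy-Weinberg-ish genotypes.

    Tract boundaries are made marker-identifiable: the ``flank_het_markers``
    markers immediately outside each tract end are forced heterozygous in
    affected samples — an idealisation of the het-dense background flanking
    a real identity-by-descent boundary.  The truth tract positions refer to
    the planted genomic interval; its outermost markers are its observable
    boundary.  ``samples`` maps name → affected; default is one affected
    proband and one unaffected sibling.
    """
    if samples is None:
        samples = {"proband": True, "sib1": False}
    rng = np.random.default_rng(seed)
    positions = [start_bp + i * spacing_bp for i in range(n_markers)]
    markers = [(f"snp{i:06d}", chrom, p) for i, p in enumerate(positions)]
    in_tract = [
        any(lo <= p <= hi for lo, hi in tracts) for p in positions
    ]
    in_flank = [False] * n_markers
    for lo, hi in tracts:
        below = [i for i, p in enumerate(positions) if p < lo]
        above = [i for i, p in enumerate(positions) if p > hi]
        for i in below[-flank_het_markers:]:
            in_flank[i] = True
        for i in above[:flank_het_markers]:
            in_flank[i] = True
    # one shared homozygous pattern per marker for tract carriers
    shared = rng.choice(["AA", "BB"], size=n_markers)
    genotypes: dict[str, list[str]] = {}
    for name, affected in samples.items():
        calls = []
        for i in range(n_markers):
            if affected and in_flank[i]:
                # boundary-defining markers stay informative
                calls.append("AB")
                continue
            if rng.random() < missing_rate:
                calls.append(".")
                continue
            if affected and in_tract[i]:
                if rng.random() < het_error_rate:
                    calls.append("AB")
                else:
                    calls.append(str(shared[i]))
            else:
                u = rng.random()
                calls.append("AA" if u < 0.32 else ("AB" if u < 0.68 else "BB"))
        genotypes[name] = calls
    truth = [GenomicInterval(chrom, lo, hi, "tract") for lo, hi in tracts]
    return GenotypeTable(markers, genotypes), truth


# ---------------------------------------------------------------------------
# Pindel-style events and depth tracks


def make_pindel_events(
    n_events: int = 100, seed: int = 0, chrom: str = "chr17"
) -> list[PindelEvent]:
    """Random well-formed events for parser fuzzing (deterministic)."""
    rng = np.random.default_rng(seed)
    events = []
    for i in range(n_events):
        etype = str(rng.choice(["D", "I", "TD"], p=[0.6, 0.3, 0.1]))
        bp_start = int(rng.integers(1_000, 50_000_000))
        if etype == "D":
            length = int(rng.integers(1, 600))
            bp_end = bp_start + length + 1
            nt = ""
        else:
            length = int(rng.integers(1, 30))
            bp_end = bp_start + 1
            nt = "".join(rng.choice(list("ACGT"), size=length)) if etype == "I" else ""
        supports = int(rng.integers(1, 500))
        unique = int(rng.integers(1, supports + 1))
        n_reads = int(rng.integers(0, 4))
        reads = [
            (
                "".join(rng.choice(list("ACGT"), size=30)),
                int(rng.integers(0, 40)),
                str(rng.choice(["+", "-"])),
            )
            for _ in range(n_reads)
        ]
        events.append(
            PindelEvent(
                index=i,
                event_type=etype,
                event_length=length,
                inserted_nt=nt,
                chrom=chrom,
                bp_start=bp_start,
                bp_end=bp_end,
                supporting_reads=supports,
                unique_supporting_reads=unique,
                sample_reads=reads,
                ref_line="".join(rng.choice(list("ACGT"), size=60)),
                extra=f"S1 {int(rng.integers(1, 99))}",
            )
        )
    return events


def make_depth_track(
    targets: Sequence[GenomicInterval],
    normal_depth: int = 100,
    low_depth: int = 10,
    low_labels: Sequence[str] = (),
    depth_jitter: int = 20,
    seed: int = 0,
) -> tuple[DepthTrack, list[str]]:
    """Per-base depths over capture targets with planted low-coverage ones.

    Targets whose label is in ``low_labels`` get depths centred on
    ``low_depth``; all others on ``normal_depth`` with +/- ``depth_jitter``
    uniform noise (floored at 0).  Truth is the list of planted low labels.
    """
    rng = np.random.default_rng(seed)
    records: dict[str, dict[int, int]] = {}
    for t in targets:
        centre = low_depth if t.label in low_labels else normal_depth
        for pos in range(t.start, t.end + 1):
            d = max(0, centre + int(rng.integers(-depth_jitter, depth_jitter + 1)))
            records.setdefault(t.chrom, {})[pos] = d
    return DepthTrack(records), list(low_labels)
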