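"""Runs of homozygosity and sibling-concordant autozygous candidate regions.

In consanguineous pedigrees a recessive disease gene lies, with high
probability, inside a chromosomal tract that is homozygous by descent in
every affected child.  This module finds such runs in SNP-array genotype
tables (abstract A/B allele coding, values AA/AB/BB with ``.`` for no-call),
intersects them across affected siblings requiring matching homozygous
alleles, removes regions where an unaffected sibling is homozygous-identical,
and restricts an annotated-variant list to the surviving candidate regions
with a homozygous + protein-altering + rare preset.

The run scan is a transparent sliding window: maximal stretches of markers
containing at most ``max_het`` heterozygous calls (tolerating genotyping
error), with no-calls neither breaking nor extending a run.  Thresholds
(``min_markers`` 50, ``min_length_bp`` 2 Mb, ``max_het`` 2) are declared
package defaults, all exposed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import pandas as pd

from .core import AnnotatedVariant, GenomicInterval, Zygosity
from .filters import filter_frequency, filter_protein_altering, filter_regions

__all__ = [
    "GenotypeTable",
    "HomozygosityRun",
    "read_genotype_table",
    "write_genotype_table",
    "find_runs",
    "concordant_regions",
    "restrict_variants_to_regions",
]

MISSING = "."
HOM_CALLS = ("AA", "BB")
VALID_CALLS = ("AA", "AB", "BB", MISSING)


@dataclass
class GenotypeTable:
    """Ordered SNP markers plus one genotype vector per sample."""

    markers: list[tuple[str, str, int]]  # (marker id, chrom, pos)
    genotypes: dict[str, list[str]]

    def __post_init__(self) -> None:
        prev: Optional[tuple[str, int]] = None
        for _mid, chrom, pos in self.markers:
            key = (chrom, pos)
            if prev is not None and key < prev:
                raise ValueError("markers must be sorted by (chrom, pos)")
            prev = key
        n = len(self.markers)
        for sample, calls in self.genotypes.items():
            if len(calls) != n:
                raise ValueError(
                    f"sample {sample}: {len(calls)} calls for {n} markers"
                )
            bad = set(calls) - set(VALID_CALLS)
            if bad:
                raise ValueError(f"sample {sample}: invalid calls {bad}")

    @property
    def samples(self) -> list[str]:
        return list(self.genotypes)

    def calls(self, sample: str) -> list[str]:
        if sample not in self.genotypes:
            raise KeyError(f"unknown sample {sample!r}")
        return self.genotypes[sample]


@dataclass
class HomozygosityRun:
    """A candidate autozygous interval for one or more samples."""

    chrom: str
    start: int
    end: int
    n_markers: int
    n_het_exceptions: int = 0
    samples: list[str] = field(default_factory=list)

    @property
    def length_bp(self) -> int:
        return self.end - self.start + 1

    def as_interval(self, label: str = "") -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end, label)


def read_genotype_table(path) -> GenotypeTable:
    """Genotype TSV: marker, chrom, pos, then one column per sample."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    needed = ["marker", "chrom", "pos"]
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns: {', '.join(missing)}")
    sample_cols = [c for c in df.columns if c not in needed]
    markers = [
        (r.marker, r.chrom, int(r.pos)) for r in df.itertuples(index=False)
    ]
    genotypes = {s: df[s].tolist() for s in sample_cols}
    return GenotypeTable(markers, genotypes)


def write_genotype_table(gt: GenotypeTable, path) -> None:
    samples = gt.samples
    with open(path, "w") as fh:
        fh.write("\t".join(["marker", "chrom", "pos"] + samples) + "\n")
        for i, (mid, chrom, pos) in enumerate(gt.markers):
            row = [mid, chrom, str(pos)]
            row += [gt.genotypes[s][i] for s in samples]
            fh.write("\t".join(row) + "\n")


def _maximal_windows(calls: Sequence[str], max_het: int) -> list[tuple[int, int, int]]:
    """Maximal index windows with <= max_het AB calls, trimmed to start and
    end on homozygous markers.  Returns (first_idx, last_idx, n_het)."""
    informative = [i for i, c in enumerate(calls) if c != MISSING]
    if not informative:
        return []
    is_het = [calls[i] == "AB" for i in informative]
    n = len(informative)
    windows: list[tuple[int, int]] = []
    left = 0
    het_count = 0
    prev_left = -1
    for right in range(n):
        het_count += is_het[right]
        while het_count > max_het:
            het_count -= is_het[left]
            left += 1
        at_end = right == n - 1
        # a window is maximal when the next extension would move `left`
        if at_end or (het_count + is_het[right + 1] > max_het):
            if left != prev_left or at_end:
                windows.append((left, right))
                prev_left = left
    out = []
    seen = set()
    for l, r in windows:
        # trim to homozygous end-points: het/missing edges carry no evidence
        while l <= r and is_het[l]:
            l += 1
        while r >= l and is_het[r]:
            r -= 1
        if l > r or (l, r) in seen:
            continue
        seen.add((l, r))
        n_het = sum(is_het[l : r + 1])
        out.append((informative[l], informative[r], n_het))
    return out


def find_runs(
    gt: GenotypeTable,
    sample: str,
    min_markers: int = 50,
    min_length_bp: int = 2_000_000,
    max_het: int = 2,
) -> list[HomozygosityRun]:
    """Maximal homozygous runs for one sample, per chromosome.

    A run may contain up to ``max_het`` heterozygous calls (genotyping
    error allowance) and any number of no-calls; it must span at least
    ``min_markers`` informative markers and ``min_length_bp`` bases.
    """
    if min_markers < 1 or min_length_bp < 1 or max_het < 0:
        raise ValueError("thresholds must be positive (max_het >= 0)")
    calls = gt.calls(sample)
    by_chrom: dict[str, list[int]] = {}
    for i, (_mid, chrom, _pos) in enumerate(gt.markers):
        by_chrom.setdefault(chrom, []).append(i)
    runs: list[HomozygosityRun] = []
    for chrom, idxs in by_chrom.items():
        sub = [calls[i] for i in idxs]
        windows = _maximal_windows(sub, max_het)
        # overlapping maximal windows describe one underlying tract seen
        # through different error-budget placements; merge them so each
        # tract is reported once (the merged span may then hold more than
        # max_het exceptions in total — max_het is a per-window allowance)
        merged: list[list[int]] = []
        for l, r, _n in sorted(windows):
            if merged and l <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], r)
            else:
                merged.append([l, r])
        for l, r in merged:
            gi_l, gi_r = idxs[l], idxs[r]
            start = gt.markers[gi_l][2]
            end = gt.markers[gi_r][2]
            span_calls = [calls[i] for i in range(gi_l, gi_r + 1)]
            n_markers = sum(1 for c in span_calls if c != MISSING)
            n_het = sum(1 for c in span_calls if c == "AB")
            if n_markers >= min_markers and end - start + 1 >= min_length_bp:
                runs.append(
                    HomozygosityRun(
                        chrom, start, end, n_markers, n_het, [sample]
                    )
                )
    return sorted(runs, key=lambda r: (r.chrom, r.start))


def _marker_indices_in(gt: GenotypeTable, chrom: str, start: int, end: int) -> list[int]:
    return [
        i
        for i, (_mid, c, p) in enumerate(gt.markers)
        if c == chrom and start <= p <= end
    ]


def _intersect_two(
    a: list[HomozygosityRun], b: list[HomozygosityRun]
) -> list[tuple[str, int, int]]:
    out = []
    for ra in a:
        for rb in b:
            if ra.chrom != rb.chrom:
                continue
            lo = max(ra.start, rb.start)
            hi = min(ra.end, rb.end)
            if lo <= hi:
                out.append((ra.chrom, lo, hi))
    return out


def concordant_regions(
    runs_by_sample: dict[str, list[HomozygosityRun]],
    affected: Iterable[str],
    unaffected: Iterable[str],
    gt: GenotypeTable,
    min_identity: float = 0.95,
) -> list[HomozygosityRun]:
    """Autozygous candidate regions shared by all affected siblings.

    The affected samples' runs are intersected; within each intersection the
    affected must carry identical homozygous alleles at >= ``min_identity``
    of the markers where all are homozygous-called.  A region is then
    discarded if any unaffected sibling is homozygous-identical to the
    affected across it (it cannot harbour the recessive allele).
    """
    affected = list(affected)
    unaffected = list(unaffected)
    if not affected:
        raise ValueError("at least one affected sample required")
    pieces = [(r.chrom, r.start, r.end) for r in runs_by_sample[affected[0]]]
    for s in affected[1:]:
        pieces = _intersect_two(
            [HomozygosityRun(c, a, b, 0) for c, a, b in pieces],
            runs_by_sample[s],
        )
    out: list[HomozygosityRun] = []
    for chrom, start, end in pieces:
        idxs = _marker_indices_in(gt, chrom, start, end)
        shared_hom = [
            i
            for i in idxs
            if all(gt.genotypes[s][i] in HOM_CALLS for s in affected)
        ]
        if not shared_hom:
            continue
        ident = sum(
            1
            for i in shared_hom
            if len({gt.genotypes[s][i] for s in affected}) == 1
        )
        if ident / len(shared_hom) < min_identity:
            continue
        excluded = False
        for u in unaffected:
            u_calls = [gt.genotypes[u][i] for i in shared_hom]
            informative = [
                (c, gt.genotypes[affected[0]][i])
                for c, i in zip(u_calls, shared_hom)
                if c != MISSING
            ]
            if not informative:
                continue
            hom_frac = sum(c in HOM_CALLS for c, _ in informative) / len(
                informative
            )
            same = [1 for c, a in informative if c in HOM_CALLS and c == a]
            ident_frac = len(same) / len(informative)
            if hom_frac >= min_identity and ident_frac >= min_identity:
                excluded = True
                break
        if excluded:
            continue
        n_markers = sum(
            1
            for i in idxs
            if any(gt.genotypes[s][i] != MISSING for s in affected)
        )
        out.append(
            HomozygosityRun(chrom, start, end, n_markers, 0, list(affected))
        )
    return sorted(out, key=lambda r: (r.chrom, r.start))


def restrict_variants_to_regions(
    variants: Sequence[AnnotatedVariant],
    regions: Sequence[GenomicInterval],
    max_maf: float = 0.10,
) -> list[AnnotatedVariant]:
    """Homozygous deleterious variants inside candidate autozygous regions.

    Composes the cascade's region filter with a homozygous-zygosity,
    protein-altering (synonymous excluded) and rare-frequency preset — the
    query used to extend a gene-panel search into autozygous candidate
    intervals.
    """
    kept = filter_regions(variants, regions=regions)
    kept = [
        v
        for v in kept
        if v.zygosity in (Zygosity.HOMOZYGOUS, Zygosity.HEMIZYGOUS)
    ]
    kept = filter_protein_altering(kept)
    kept = [
        v
        for v in kept
        if v.consequence.value not in ("intronic", "utr", "intergenic")
    ]
    return filter_frequency(kept, max_maf)
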