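"""Anchored split-read detection of deletions.

When a sequenced fragment straddles a deletion, the read crossing the
breakpoint cannot be placed by a gapless aligner, but its mate often maps
cleanly.  The mapped mate anchors a bounded genomic search window on the
side where the missing read must lie; the unplaced read is then
split-aligned inside that window: a prefix of the read is placed exactly,
the remaining suffix is placed exactly further downstream, and the skipped
reference bases between the two placements are the deleted segment, with
breakpoints at nucleotide resolution.

This is a desk-scale detector: alignment is exact-match (no mismatches),
which on error-free synthetic reads makes breakpoint exactness a testable
property rather than a statistical one.  Calls whose breakpoints can slide
inside a repeat are left-normalised (smallest start), matching the VCF
left-alignment convention.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from .core import GenomicInterval

__all__ = [
    "ReadPair",
    "DeletionCall",
    "SplitParams",
    "search_window",
    "split_align",
    "call_deletions",
]

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class ReadPair:
    """A read pair with one mapped (anchoring) mate and one unplaced mate.

    ``anchor_pos`` is the 1-based leftmost reference position of the mapped
    mate; ``anchor_strand`` its mapping strand.  The unplaced mate's
    sequence is held in ``unmapped_seq`` (orientation unknown — both the
    given sequence and its reverse complement are tried).
    """

    name: str
    anchor_chrom: str
    anchor_pos: int
    anchor_strand: str
    anchor_seq: str
    unmapped_seq: str

    def __post_init__(self) -> None:
        if self.anchor_pos < 1:
            raise ValueError("anchor_pos must be >= 1")
        if not self.anchor_seq or not self.unmapped_seq:
            raise ValueError("reads must be non-empty")
        if self.anchor_strand not in ("+", "-"):
            raise ValueError("anchor_strand must be '+' or '-'")


@dataclass(frozen=True)
class DeletionCall:
    """A deletion with exact breakpoints and its supporting read names."""

    chrom: str
    del_start: int  # first deleted base, 1-based
    del_end: int  # last deleted base, 1-based
    supporting_reads: int
    read_names: tuple[str, ...]

    @property
    def length(self) -> int:
        return self.del_end - self.del_start + 1


@dataclass(frozen=True)
class SplitParams:
    min_flank: int = 15
    min_supporting_reads: int = 1
    insert_mean: int = 300
    max_event: int = 1000

    def __post_init__(self) -> None:
        if self.min_flank < 1:
            raise ValueError("min_flank must be >= 1")
        if self.insert_mean <= 0:
            raise ValueError("insert_mean must be > 0")
        if self.max_event <= 0:
            raise ValueError("max_event must be > 0")


def search_window(
    anchor_pos: int,
    anchor_strand: str,
    insert_mean: int,
    max_event: int,
    read_length: int,
    chrom: str = "",
) -> GenomicInterval:
    """The genomic window in which the unplaced mate is sought.

    ``insert_mean`` is the expected outer fragment length.  For a ``+``
    anchor the mate is expected to start at ``anchor_pos + insert_mean −
    read_length``; the window spans from ``max_event`` before that point to
    ``insert_mean + max_event`` beyond it (a deletion pushes the mate's
    suffix placement downstream).  The ``-`` case mirrors it upstream.  The
    window size is the constant ``insert_mean + 2*max_event + read_length``
    before clipping at position 1.
    """
    if insert_mean <= 0 or max_event <= 0:
        raise ValueError("insert_mean and max_event must be > 0")
    if read_length < 1:
        raise ValueError("read_length must be >= 1")
    if anchor_strand == "+":
        expected = anchor_pos + insert_mean - read_length
        start = expected - max_event
        end = expected + insert_mean + max_event + read_length - 1
    elif anchor_strand == "-":
        expected = anchor_pos + read_length - insert_mean
        start = expected - insert_mean - max_event
        end = expected + max_event + read_length - 1
    else:
        raise ValueError("anchor_strand must be '+' or '-'")
    return GenomicInterval(chrom or "window", max(1, start), max(1, end))


def _occurrences(needle: str, haystack: str) -> list[int]:
    out = []
    i = haystack.find(needle)
    while i != -1:
        out.append(i)
        i = haystack.find(needle, i + 1)
    return out


@dataclass(frozen=True)
class SplitHit:
    """One split placement: window offsets of prefix and suffix, split index."""

    prefix_offset: int
    suffix_offset: int
    split_index: int

    @property
    def gap(self) -> int:
        return self.suffix_offset - (self.prefix_offset + self.split_index)


def split_align(
    read: str, window_seq: str, min_flank: int = 15
) -> Optional[SplitHit]:
    """Exact split alignment of a read inside a reference window.

    Looks for a split index ``s`` (``min_flank <= s <= L - min_flank``) such
    that ``read[:s]`` matches exactly at some window offset and ``read[s:]``
    matches exactly strictly downstream.  A contiguous full-length match is
    returned as a hit with gap 0.  Among valid splits the one with the most
    balanced flanks wins; remaining ties go to the smallest deletion start
    then the smallest gap.  Returns ``None`` when no exact placement exists
    (a normal outcome, not an error).
    """
    L = len(read)
    if len(window_seq) < L:
        raise ValueError("window shorter than read")
    contiguous = _occurrences(read, window_seq)
    if contiguous:
        # whole read is the prefix; suffix is empty and adjacent: gap 0
        return SplitHit(contiguous[0], contiguous[0] + L, L)
    if L < 2 * min_flank:
        return None
    best: Optional[tuple[tuple, SplitHit]] = None
    for s in range(min_flank, L - min_flank + 1):
        prefix_hits = _occurrences(read[:s], window_seq)
        if not prefix_hits:
            continue
        suffix_hits = _occurrences(read[s:], window_seq)
        if not suffix_hits:
            continue
        for p1 in prefix_hits:
            for p2 in suffix_hits:
                if p2 <= p1 + s:
                    continue
                hit = SplitHit(p1, p2, s)
                rank = (-min(s, L - s), p1 + s, hit.gap)
                if best is None or rank < best[0]:
                    best = (rank, hit)
    return best[1] if best else None


def _left_normalise(
    ref: str, del_start: int, del_end: int
) -> tuple[int, int]:
    # slide the deleted interval left while the base before it equals the
    # base at its end (1-based coordinates into ref)
    while del_start > 1 and ref[del_start - 2] == ref[del_end - 1]:
        del_start -= 1
        del_end -= 1
    return del_start, del_end


def call_deletions(
    pairs: Iterable[ReadPair],
    reference: dict[str, str] | str,
    params: SplitParams = SplitParams(),
    chrom: str = "ref",
) -> list[DeletionCall]:
    """Split-align every unplaced mate and cluster exact breakpoints.

    ``reference`` is either a mapping chrom → sequence or a single sequence
    (then ``chrom`` names it).  Identical (start, end) solutions across
    reads are clustered; clusters with at least ``min_supporting_reads``
    members become calls, sorted by position.  Reads that place contiguously
    (no gap) contribute no deletion evidence.
    """
    if isinstance(reference, str):
        reference = {chrom: reference}
    clusters: dict[tuple[str, int, int], list[str]] = {}
    for pair in pairs:
        ref = reference.get(pair.anchor_chrom)
        if ref is None:
            continue
        L = len(pair.unmapped_seq)
        win = search_window(
            pair.anchor_pos,
            pair.anchor_strand,
            params.insert_mean,
            params.max_event,
            L,
            pair.anchor_chrom,
        )
        lo = max(1, win.start)
        hi = min(len(ref), win.end)
        if hi - lo + 1 < L:
            continue
        window_seq = ref[lo - 1 : hi]
        hit = None
        for seq in (pair.unmapped_seq, revcomp(pair.unmapped_seq)):
            hit = split_align(seq, window_seq, params.min_flank)
            if hit is not None:
                break
        if hit is None or hit.gap == 0:
            continue
        del_start = lo + hit.prefix_offset + hit.split_index
        del_end = del_start + hit.gap - 1
        del_start, del_end = _left_normalise(ref, del_start, del_end)
        clusters.setdefault(
            (pair.anchor_chrom, del_start, del_end), []
        ).append(pair.name)
    calls = [
        DeletionCall(c, s, e, len(names), tuple(sorted(names)))
        for (c, s, e), names in clusters.items()
        if len(names) >= params.min_supporting_reads
    ]
    return sorted(calls, key=lambda c: (c.chrom, c.del_start, c.del_end))


def calls_to_pindel_events(
    calls: Sequence[DeletionCall], reference: dict[str, str] | str, chrom: str = "ref"
) -> list:
    """Convert deletion calls into Pindel-style deletion events so the
    event-block tooling can render and filter them (closing the loop)."""
    from .pindel import PindelEvent

    if isinstance(reference, str):
        reference = {chrom: reference}
    events = []
    for i, call in enumerate(calls):
        ref = reference[call.chrom]
        lo = max(1, call.del_start - 30)
        hi = min(len(ref), call.del_end + 30)
        events.append(
            PindelEvent(
                index=i,
                event_type="D",
                event_length=call.length,
                inserted_nt="",
                chrom=call.chrom,
                bp_start=call.del_start - 1,
                bp_end=call.del_end + 1,
                supporting_reads=call.supporting_reads,
                unique_supporting_reads=call.supporting_reads,
                sample_reads=[],
                ref_line=ref[lo - 1 : hi],
            )
        )
    return events
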