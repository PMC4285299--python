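"""Parsing, filtering and presentation of Pindel-style indel event blocks.

The split-read indel caller this module consumes exports events as textual
blocks per event type (deletions ``_D``, short insertions ``_SI``, large
insertions ``_LI``, tandem duplications ``_TD``), each block being a ``#``
separator line, a header of whitespace-separated fields keyed by the literal
tags ``NT``/``ChrID``/``BP``/``Supports``, a reference-context line, then
one line per supporting read placed at its alignment offset.  Field-order
drift between minor versions is absorbed by parsing keyed on the tags;
header fields beyond the modelled ones are preserved as opaque text and
written back verbatim, so parse → write → parse is stable.

Breakpoint convention: ``bp_start`` is the last reference base before the
event and ``bp_end`` the first reference base after it, both 1-based; a
deletion therefore removes ``bp_end - bp_start - 1`` bases.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .core import GenomicInterval, RegionIndex, TranscriptModel

__all__ = [
    "PindelEvent",
    "PindelParseError",
    "read_pindel_file",
    "read_pindel_dir",
    "write_pindel_file",
    "filter_events",
    "duplicate_groups",
    "name_event",
    "render_alignment",
]

SEPARATOR = "#" * 100

EVENT_TYPES = ("D", "I", "LI", "TD", "INV")

_FILE_SUFFIXES = ("_D", "_SI", "_LI", "_TD", "_INV")


class PindelParseError(ValueError):
    pass


@dataclass
class PindelEvent:
    """One reported structural event with its supporting evidence."""

    index: int
    event_type: str
    event_length: int
    inserted_nt: str
    chrom: str
    bp_start: int
    bp_end: int
    supporting_reads: int
    unique_supporting_reads: int
    sample_reads: list[tuple[str, int, str]] = field(default_factory=list)
    ref_line: str = ""
    extra: str = ""
    source_file: str = ""

    def __post_init__(self) -> None:
        if self.event_type not in EVENT_TYPES:
            raise ValueError(f"unknown event type {self.event_type!r}")
        if self.event_length < 1:
            raise ValueError("event_length must be >= 1")
        if self.bp_end <= self.bp_start:
            raise ValueError(
                f"bp_end ({self.bp_end}) must exceed bp_start ({self.bp_start})"
            )
        if self.event_type == "D":
            expected = self.bp_end - self.bp_start - 1
            if self.event_length != expected:
                raise ValueError(
                    f"deletion length {self.event_length} inconsistent with "
                    f"breakpoints {self.bp_start}/{self.bp_end} "
                    f"(expected {expected})"
                )
        if self.unique_supporting_reads > self.supporting_reads:
            raise ValueError("unique supports exceed total supports")

    @property
    def duplicate_key(self) -> tuple[str, str, int, int, str]:
        return (
            self.event_type,
            self.chrom,
            self.bp_start,
            self.bp_end,
            self.inserted_nt,
        )

    @property
    def deleted_span(self) -> Optional[tuple[int, int]]:
        """First and last deleted base for deletions, else None."""
        if self.event_type != "D":
            return None
        return (self.bp_start + 1, self.bp_end - 1)


def _parse_header(line: str, where: str) -> dict:
    tokens = line.split()
    if len(tokens) < 3:
        raise PindelParseError(f"{where}: truncated header line")
    try:
        out = {
            "index": int(tokens[0]),
            "event_type": tokens[1],
            "event_length": int(tokens[2]),
        }
    except ValueError as exc:
        raise PindelParseError(f"{where}: bad header prefix: {exc}") from exc
    consumed = {0, 1, 2}
    i = 3
    nt = ""
    while i < len(tokens):
        tag = tokens[i]
        try:
            if tag == "NT":
                nt = tokens[i + 2].strip('"')
                consumed |= {i, i + 1, i + 2}
                i += 3
            elif tag == "ChrID":
                out["chrom"] = tokens[i + 1]
                consumed |= {i, i + 1}
                i += 2
            elif tag == "BP":
                out["bp_start"] = int(tokens[i + 1])
                out["bp_end"] = int(tokens[i + 2])
                consumed |= {i, i + 1, i + 2}
                i += 3
            elif tag == "Supports":
                out["supporting_reads"] = int(tokens[i + 1])
                out["unique_supporting_reads"] = int(tokens[i + 2])
                consumed |= {i, i + 1, i + 2}
                i += 3
            else:
                i += 1
        except (IndexError, ValueError) as exc:
            raise PindelParseError(
                f"{where}: malformed {tag} field: {exc}"
            ) from exc
    out["inserted_nt"] = nt
    missing = {"chrom", "bp_start", "supporting_reads"} - set(out)
    if missing:
        raise PindelParseError(
            f"{where}: header missing tag(s) for {', '.join(sorted(missing))}"
        )
    out["extra"] = " ".join(
        tokens[j] for j in range(len(tokens)) if j not in consumed
    )
    return out


def _parse_read_line(line: str) -> tuple[str, int, str]:
    offset = len(line) - len(line.lstrip(" "))
    body = line.strip()
    seq, _, strand = body.partition("\t")
    return (seq, offset, strand or "+")


def read_pindel_file(path) -> list[PindelEvent]:
    """Parse one event-block file into events (order preserved)."""
    events: list[PindelEvent] = []
    with open(path) as fh:
        lines = fh.read().split("\n")
    i = 0
    fname = os.path.basename(str(path))
    while i < len(lines):
        line = lines[i]
        if not line.strip():
            i += 1
            continue
        if not line.startswith("####"):
            raise PindelParseError(
                f"{path}:{i + 1}: expected block separator, got {line[:40]!r}"
            )
        if i + 1 >= len(lines) or not lines[i + 1].strip():
            raise PindelParseError(f"{path}:{i + 2}: missing block header")
        header = _parse_header(lines[i + 1], f"{path}:{i + 2}")
        ref_line = lines[i + 2] if i + 2 < len(lines) else ""
        i += 3
        reads: list[tuple[str, int, str]] = []
        while i < len(lines) and lines[i] and not lines[i].startswith("####"):
            reads.append(_parse_read_line(lines[i]))
            i += 1
        events.append(
            PindelEvent(
                sample_reads=reads,
                ref_line=ref_line,
                source_file=fname,
                **header,
            )
        )
    return events


def read_pindel_dir(path) -> list[PindelEvent]:
    """Parse every recognised event file (``*_D``, ``*_SI``, ``*_LI``,
    ``*_TD``, ``*_INV``) in a directory.  An empty directory yields an empty
    list; a malformed block raises with file and line."""
    events: list[PindelEvent] = []
    for fname in sorted(os.listdir(path)):
        if fname.endswith(_FILE_SUFFIXES):
            events.extend(read_pindel_file(os.path.join(path, fname)))
    return events


def write_pindel_file(events: Iterable[PindelEvent], path) -> None:
    """Write events back in the block format read_pindel_file accepts."""
    with open(path, "w") as fh:
        for ev in events:
            fh.write(SEPARATOR + "\n")
            header = (
                f"{ev.index}\t{ev.event_type} {ev.event_length}\t"
                f'NT {len(ev.inserted_nt)} "{ev.inserted_nt}"\t'
                f"ChrID {ev.chrom}\tBP {ev.bp_start}\t{ev.bp_end}\t"
                f"Supports {ev.supporting_reads}\t{ev.unique_supporting_reads}"
            )
            if ev.extra:
                header += "\t" + ev.extra
            fh.write(header + "\n")
            fh.write(ev.ref_line + "\n")
            for seq, offset, strand in ev.sample_reads:
                fh.write(" " * offset + seq + "\t" + strand + "\n")


def filter_events(
    events: Sequence[PindelEvent],
    min_supporting_reads: int = 0,
    regions: Optional[Iterable[GenomicInterval]] = None,
    require_both_ends: bool = False,
) -> list[PindelEvent]:
    """Keep events with enough read support that touch the target regions.

    An event overlaps the targets when *either* breakpoint falls inside one
    (large deletions are captured as long as one end is in the pull-down
    region); ``require_both_ends`` switches to the stricter rule.
    """
    if min_supporting_reads < 0:
        raise ValueError("min_supporting_reads must be >= 0")
    index = RegionIndex(regions) if regions is not None else None
    out = []
    for ev in events:
        if ev.supporting_reads < min_supporting_reads:
            continue
        if index is not None:
            s_in = index.contains(ev.chrom, ev.bp_start)
            e_in = index.contains(ev.chrom, ev.bp_end)
            hit = (s_in and e_in) if require_both_ends else (s_in or e_in)
            if not hit:
                continue
        out.append(ev)
    return out


def duplicate_groups(
    events: Sequence[PindelEvent],
) -> dict[tuple, list[PindelEvent]]:
    """Group events by (type, chrom, breakpoints, inserted sequence).

    Identical events reported in multiple source files are kept, not
    dropped; groups with more than one member mark the duplicates.
    """
    groups: dict[tuple, list[PindelEvent]] = {}
    for ev in events:
        groups.setdefault(ev.duplicate_key, []).append(ev)
    return groups


_TYPE_WORD = {
    "D": "deletion",
    "I": "insertion",
    "LI": "large insertion",
    "TD": "tandem duplication",
    "INV": "inversion",
}


def _intron_number(tm: TranscriptModel, genomic_gap_index: int) -> int:
    # the intron between genomic exons i and i+1 follows, in transcription
    # order, the smaller-numbered of the two flanking exons
    return min(
        tm.exon_number(genomic_gap_index), tm.exon_number(genomic_gap_index + 1)
    )


def _locate(tm: TranscriptModel, pos: int) -> str:
    if pos < tm.exons[0].start or pos > tm.exons[-1].end:
        return f"outside {tm.gene}"
    for i, ex in enumerate(tm.exons):
        if ex.start <= pos <= ex.end:
            return f"exon {tm.exon_number(i)}"
        if pos < ex.start:
            return f"intron {_intron_number(tm, i - 1)}"
    return f"outside {tm.gene}"


def name_event(event: PindelEvent, tm: TranscriptModel) -> str:
    """Describe an event relative to a transcript's exon/intron structure.

    e.g. ``510 bp deletion removing exon 22 and flanking intronic sequence``.
    """
    if event.chrom != tm.chrom:
        raise ValueError(
            f"event on {event.chrom} but transcript {tm.transcript} "
            f"on {tm.chrom}"
        )
    word = _TYPE_WORD[event.event_type]
    if event.event_type != "D":
        where = _locate(tm, event.bp_start)
        return (
            f"{event.event_length} bp {word} in {tm.gene} ({where}), "
            f"between positions {event.bp_start} and {event.bp_end}"
        )
    span_start, span_end = event.deleted_span
    hit = [
        (i, ex)
        for i, ex in enumerate(tm.exons)
        if ex.start <= span_end and ex.end >= span_start
    ]
    if hit:
        numbers = sorted(tm.exon_number(i) for i, _ in hit)
        if len(numbers) == 1:
            exon_txt = f"exon {numbers[0]}"
        else:
            exon_txt = f"exons {numbers[0]}–{numbers[-1]}"
        partial = any(
            span_start > ex.start or span_end < ex.end for _, ex in hit
        )
        flanking = span_start < min(ex.start for _, ex in hit) or span_end > max(
            ex.end for _, ex in hit
        )
        desc = f"{event.event_length} bp {word} removing {exon_txt}"
        if flanking:
            desc += " and flanking intronic sequence"
        elif partial:
            desc += " (partial)"
        return desc + f" of {tm.gene}"
    where = _locate(tm, span_start)
    return f"{event.event_length} bp {word} within {where} of {tm.gene}"


def render_alignment(
    event: PindelEvent, window_start: int, ref_seq: str
) -> str:
    """Fixed-width text view of supporting reads against the reference.

    The first line is the reference window, the second marks the event span
    (``-`` under deleted bases, ``^`` at an insertion point), then one line
    per supporting read placed at its offset, with gap characters spanning a
    deletion.  Reads extending past the window are clipped and marked with
    ``<``/``>``.  Every emitted line has the same width.

    Read placement offsets are interpreted as 1-based reference positions of
    the first read base.
    """
    width = len(ref_seq)
    window_end = window_start + width - 1
    if not (window_start <= event.bp_start and event.bp_end <= window_end):
        raise ValueError("reference window must cover both breakpoints")
    lines = [ref_seq]
    marker = [" "] * width
    if event.event_type == "D":
        for p in range(event.bp_start + 1, event.bp_end):
            marker[p - window_start] = "-"
    else:
        marker[event.bp_start - window_start] = "^"
    lines.append("".join(marker))
    for seq, offset, _strand in event.sample_reads:
        buf = [" "] * width
        pos = offset  # 1-based reference position of next base
        clipped_left = clipped_right = False
        for ch in seq:
            if event.event_type == "D" and pos == event.bp_start + 1:
                for p in range(event.bp_start + 1, event.bp_end):
                    if window_start <= p <= window_end:
                        buf[p - window_start] = "-"
                pos = event.bp_end
            if pos < window_start:
                clipped_left = True
            elif pos > window_end:
                clipped_right = True
            else:
                buf[pos - window_start] = ch
            pos += 1
        if clipped_left:
            buf[0] = "<"
        if clipped_right:
            buf[-1] = ">"
        lines.append("".join(buf))
    return "\n".join(lines)
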