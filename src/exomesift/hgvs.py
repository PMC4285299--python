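"""Parsing and sizing of cDNA-level HGVS indel descriptions.

Supports the indel subset of HGVS ``c.`` nomenclature: deletions,
duplications, insertions and deletion–insertions, with intron-offset
positions such as ``c.207+1`` or ``c.1668-19``.  Substitutions, inversions
and UTR-anchored (``*``) positions are deliberately out of scope — they are
handled by the VCF path upstream — and raise :class:`HgvsParseError`.

The affected-reference-base count for a range assumes the range is
genomically contiguous, i.e. offsets are measured from the two anchors of a
single exon/intron junction (``c.197_207+20del`` spans the end of an exon
and 20 bases of the adjoining intron).  A range that provably crosses an
entire intron (start offset > 0 and end offset < 0) cannot be sized without
the transcript sequence and is rejected rather than silently mis-sized.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from functools import total_ordering
from typing import Optional

__all__ = [
    "CPosition",
    "HgvsIndel",
    "HgvsParseError",
    "parse_cdna",
    "affected_bases",
    "classify",
]


class HgvsParseError(ValueError):
    """Raised for HGVS text outside the supported indel grammar."""


@total_ordering
@dataclass(frozen=True)
class CPosition:
    """A cDNA coordinate: integer anchor plus signed intron offset.

    ``c.100`` → anchor 100, offset 0; ``c.100+5`` → (100, +5);
    ``c.100-5`` → (100, -5).  Anchor 0 does not exist in HGVS.
    """

    anchor: int
    offset: int = 0

    def __post_init__(self) -> None:
        if self.anchor == 0:
            raise ValueError("cDNA anchor 0 does not exist")

    def __str__(self) -> str:
        if self.offset == 0:
            return str(self.anchor)
        return f"{self.anchor}{self.offset:+d}"

    def _key(self) -> tuple[int, int]:
        return (self.anchor, self.offset)

    def __lt__(self, other: "CPosition") -> bool:
        return self._key() < other._key()


@dataclass(frozen=True)
class HgvsIndel:
    """A parsed cDNA indel: kind, coordinate range, inserted sequence."""

    start: CPosition
    end: CPosition
    kind: str  # del | dup | ins | delins
    inserted_seq: str = ""
    raw: str = ""

    def __post_init__(self) -> None:
        if self.kind not in ("del", "dup", "ins", "delins"):
            raise ValueError(f"unknown indel kind {self.kind!r}")
        if self.end < self.start:
            raise ValueError(f"range end before start in {self.raw!r}")
        has_seq = bool(self.inserted_seq)
        needs_seq = self.kind in ("ins", "delins")
        if has_seq != needs_seq:
            raise ValueError(
                f"inserted sequence {'required' if needs_seq else 'not allowed'}"
                f" for kind {self.kind!r}"
            )

    def format(self) -> str:
        """Canonical HGVS text; ``parse_cdna(v.format())`` is a fixed point."""
        if self.start == self.end:
            span = str(self.start)
        else:
            span = f"{self.start}_{self.end}"
        return f"c.{span}{self.kind}{self.inserted_seq}"

    @property
    def inserted_length(self) -> int:
        return len(self.inserted_seq)


_POS = r"(-?\d+)([+-]\d+)?"
_PATTERN = re.compile(
    rf"^c\.{_POS}(?:_{_POS})?(delins|del|dup|ins)([ACGTNacgtn]*)$"
)


def _cpos(anchor: str, offset: Optional[str]) -> CPosition:
    return CPosition(int(anchor), int(offset) if offset else 0)


def parse_cdna(text: str) -> HgvsIndel:
    """Parse a cDNA HGVS indel description.

    >>> v = parse_cdna("c.197_207+20del")
    >>> (v.start.anchor, v.end.anchor, v.end.offset, v.kind)
    (197, 207, 20, 'del')
    """
    text = text.strip()
    if "*" in text:
        raise HgvsParseError(
            f"UTR-anchored (*) positions are not supported: {text!r}"
        )
    m = _PATTERN.match(text)
    if m is None:
        tail = re.search(r"(>|inv|con|=)", text)
        token = tail.group(1) if tail else text
        raise HgvsParseError(f"unsupported HGVS syntax near {token!r}: {text!r}")
    a1, o1, a2, o2, kind, seq = m.groups()
    start = _cpos(a1, o1)
    end = _cpos(a2, o2) if a2 is not None else start
    if end < start:
        raise HgvsParseError(f"range end before start: {text!r}")
    if kind in ("ins", "delins") and not seq:
        raise HgvsParseError(f"{kind} requires an inserted sequence: {text!r}")
    if kind in ("del", "dup") and seq:
        raise HgvsParseError(
            f"trailing sequence after {kind} is not supported: {text!r}"
        )
    if kind == "ins" and (a2 is None or not _adjacent(start, end)):
        raise HgvsParseError(
            f"ins requires two adjacent flanking positions: {text!r}"
        )
    return HgvsIndel(start, end, kind, seq.upper(), raw=text)


def _adjacent(a: CPosition, b: CPosition) -> bool:
    if a.anchor == b.anchor:
        return b.offset - a.offset == 1
    return b.anchor - a.anchor == 1 and a.offset == 0 and b.offset == 0


def affected_bases(v: HgvsIndel) -> int:
    """Number of reference bases affected by the event.

    For del/dup/delins this is the coordinate span
    ``(end.anchor - start.anchor) + (end.offset - start.offset) + 1``,
    valid because supported ranges are genomically contiguous.  A pure
    insertion affects 0 reference bases (its inserted length is reported
    separately by :attr:`HgvsIndel.inserted_length`).
    """
    if v.kind == "ins":
        return 0
    if v.start.offset > 0 and v.end.offset < 0:
        raise HgvsParseError(
            f"range {v.raw!r} crosses a full intron; its reference span "
            "cannot be computed from cDNA coordinates alone"
        )
    span = (v.end.anchor - v.start.anchor) + (v.end.offset - v.start.offset) + 1
    if span < 1:
        raise HgvsParseError(f"inconsistent range in {v.raw!r}: span {span}")
    return span


def classify(v: HgvsIndel) -> str:
    """Insertion/deletion class label: del→``D``, dup/ins→``I``, delins→``D/I``."""
    return {"del": "D", "dup": "I", "ins": "I", "delins": "D/I"}[v.kind]
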