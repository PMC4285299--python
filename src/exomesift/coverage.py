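"""Per-target coverage acceptance reporting.

Diagnostic targeted sequencing needs two things from a coverage report: a
coherent list of the regions where coverage was too low to genotype, and a
defined per-target sensitivity statement.  Given a per-base depth track and
the capture targets, this module computes per-target minimum and mean depth
and the fraction of bases at or above each acceptance threshold, then flags
the targets failing a required threshold/fraction pair.

A base absent from the depth track has depth 0 — gaps are never
interpolated.  Accounting is exact integer arithmetic: the per-target depth
sums conserve the track's total depth mass restricted to the targets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from .core import GenomicInterval

__all__ = [
    "DepthTrack",
    "TargetCoverage",
    "read_depth_track",
    "write_depth_track",
    "coverage_by_target",
    "failing_targets",
]


@dataclass
class DepthTrack:
    """Sparse per-base depth: chrom → {pos: depth}.  Missing pos = depth 0."""

    depths: dict[str, dict[int, int]] = field(default_factory=dict)

    def depth_at(self, chrom: str, pos: int) -> int:
        return self.depths.get(chrom, {}).get(pos, 0)

    def has_chrom(self, chrom: str) -> bool:
        return chrom in self.depths

    @classmethod
    def from_records(
        cls, records: Iterable[tuple[str, int, int]]
    ) -> "DepthTrack":
        depths: dict[str, dict[int, int]] = {}
        last: dict[str, int] = {}
        for chrom, pos, depth in records:
            if depth < 0:
                raise ValueError(f"negative depth at {chrom}:{pos}")
            if pos <= last.get(chrom, 0):
                raise ValueError(
                    f"positions must strictly increase within {chrom} "
                    f"(saw {pos} after {last[chrom]})"
                )
            last[chrom] = pos
            depths.setdefault(chrom, {})[pos] = depth
        return cls(depths)


def read_depth_track(path) -> DepthTrack:
    """Three-column depth TSV (chrom, pos, depth), 1-based positions."""
    df = pd.read_csv(
        path, sep="\t", names=["chrom", "pos", "depth"], dtype=str, comment="#"
    )
    if len(df) and df.iloc[0]["pos"] == "pos":  # tolerate a header row
        df = df.iloc[1:]
    return DepthTrack.from_records(
        (r.chrom, int(r.pos), int(r.depth)) for r in df.itertuples(index=False)
    )


def write_depth_track(track: DepthTrack, path) -> None:
    with open(path, "w") as fh:
        for chrom in track.depths:
            for pos in sorted(track.depths[chrom]):
                fh.write(f"{chrom}\t{pos}\t{track.depths[chrom][pos]}\n")


@dataclass
class TargetCoverage:
    """Coverage statistics for one capture target."""

    target: GenomicInterval
    min_depth: int
    depth_sum: int  # exact integer depth mass over the target
    fraction_at_or_above: dict[int, float]
    chrom_missing: bool = False  # target chrom absent from the track

    @property
    def n_bases(self) -> int:
        return len(self.target)

    @property
    def mean_depth(self) -> float:
        return self.depth_sum / self.n_bases


def coverage_by_target(
    track: DepthTrack,
    targets: Sequence[GenomicInterval],
    thresholds: Sequence[int],
) -> list[TargetCoverage]:
    """Per-target min/mean depth and fraction of bases at/above each threshold.

    A target on a chromosome absent from the track gets fractions 0 and is
    flagged (``chrom_missing``) so a missing-data problem is not read as a
    clean coverage failure.
    """
    if not thresholds:
        raise ValueError("at least one threshold required")
    out = []
    for target in targets:
        chrom_depths = track.depths.get(target.chrom, {})
        depths = [
            chrom_depths.get(pos, 0)
            for pos in range(target.start, target.end + 1)
        ]
        fractions = {
            t: sum(1 for d in depths if d >= t) / len(depths)
            for t in thresholds
        }
        out.append(
            TargetCoverage(
                target=target,
                min_depth=min(depths),
                depth_sum=sum(depths),
                fraction_at_or_above=fractions,
                chrom_missing=not track.has_chrom(target.chrom),
            )
        )
    return out


def failing_targets(
    coverages: Sequence[TargetCoverage],
    threshold: int,
    required_fraction: float = 1.0,
) -> list[TargetCoverage]:
    """Targets whose at-or-above fraction misses the requirement.

    The default requirement is every base at or above the threshold (a
    single under-covered base fails the target's genotype acceptance);
    relax ``required_fraction`` for sensitivity-style reporting.  Sorted
    worst-first (lowest fraction, then lowest minimum depth).
    """
    if threshold not in (coverages[0].fraction_at_or_above if coverages else {threshold: 0}):
        raise ValueError(
            f"threshold {threshold} was not computed by coverage_by_target"
        )
    failing = [
        c
        for c in coverages
        if c.fraction_at_or_above[threshold] < required_fraction
    ]
    return sorted(
        failing,
        key=lambda c: (c.fraction_at_or_above[threshold], c.min_depth),
    )


def write_coverage_report(
    coverages: Sequence[TargetCoverage], path
) -> None:
    thresholds = sorted(coverages[0].fraction_at_or_above) if coverages else []
    cols = ["chrom", "start", "end", "label", "min_depth", "mean_depth"]
    cols += [f"frac_ge_{t}" for t in thresholds]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for c in coverages:
            row = [
                c.target.chrom,
                str(c.target.start),
                str(c.target.end),
                c.target.label or ".",
                str(c.min_depth),
                f"{c.mean_depth:.2f}",
            ]
            row += [f"{c.fraction_at_or_above[t]:.4f}" for t in thresholds]
            fh.write("\t".join(row) + "\n")
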