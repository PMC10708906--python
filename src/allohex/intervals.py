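"""Genomic coordinate primitives.

All coordinates in this package are 0-based half-open (BED convention).
Any 1-based external dialect is converted at the I/O boundary and nowhere
else.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

STRAND_VALUES = {"+", "-", "."}
ORIENTATIONS = {"same", "inverted"}


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open span on a named chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("interval needs a chromosome name")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in STRAND_VALUES:
            raise ValueError(f"strand must be one of {STRAND_VALUES}, got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def overlap_length(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.chrom}:{self.start}-{self.end}"


@dataclass(frozen=True)
class Anchor:
    """One aligned region between a query and a target genome."""

    query: GenomicInterval
    target: GenomicInterval
    orientation: str = "same"
    identity: float = 1.0

    def __post_init__(self) -> None:
        if self.orientation not in ORIENTATIONS:
            raise ValueError(f"orientation must be one of {ORIENTATIONS}")
        if not (0.0 <= self.identity <= 1.0):
            raise ValueError("identity must lie in [0, 1]")
        # GenomicInterval guarantees positive length on both sides.


def merge_intervals(intervals: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    """Union of intervals: merged, sorted, per chromosome.

    Strand is dropped (the union is strandless).
    """
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    out: list[GenomicInterval] = []
    for chrom in sorted(by_chrom):
        ivs = sorted(by_chrom[chrom], key=lambda x: (x.start, x.end))
        cur_start, cur_end = ivs[0].start, ivs[0].end
        for iv in ivs[1:]:
            if iv.start <= cur_end:
                cur_end = max(cur_end, iv.end)
            else:
                out.append(GenomicInterval(chrom, cur_start, cur_end))
                cur_start, cur_end = iv.start, iv.end
        out.append(GenomicInterval(chrom, cur_start, cur_end))
    return out


def covered_length(intervals: Sequence[GenomicInterval], iv: GenomicInterval) -> int:
    """Number of bases of ``iv`` covered by the union of ``intervals``."""
    merged = merge_intervals([x for x in intervals if x.chrom == iv.chrom])
    return sum(iv.overlap_length(m) for m in merged)


def hull(intervals: Sequence[GenomicInterval]) -> GenomicInterval:
    """Smallest interval containing all inputs (must share a chromosome)."""
    if not intervals:
        raise ValueError("hull of empty interval list")
    chroms = {iv.chrom for iv in intervals}
    if len(chroms) != 1:
        raise ValueError(f"hull spans multiple chromosomes: {sorted(chroms)}")
    return GenomicInterval(
        intervals[0].chrom,
        min(iv.start for iv in intervals),
        max(iv.end for iv in intervals),
    )
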