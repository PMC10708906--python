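"""Syntenic collinearity blocks and coordinate liftover.

Alignment anchors between two genomes are chained into collinearity
blocks by linking anchors whose gaps are below a distance cutoff
(default 20 kb). The resulting blocks gate homeologous-exchange calls
(an outlier depth region must fall in synteny) and provide the
coordinate transform between the two genomes.

Chaining semantics: two anchors are *linkable* when they share the
(query chrom, target chrom) pair and orientation and the gap between
their hulls is below ``link_gap`` on the query side and (by default)
also on the target side. Blocks are the connected components of this
relation, i.e. its transitive closure, not merely consecutive joins.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .intervals import Anchor, GenomicInterval, covered_length, hull

log = logging.getLogger("allohex.synteny")


@dataclass
class SyntenyBlock:
    anchors: list[Anchor]
    query_span: GenomicInterval
    target_span: GenomicInterval
    orientation: str

    @property
    def n_anchors(self) -> int:
        return len(self.anchors)


def _gap(a_start: int, a_end: int, b_start: int, b_end: int) -> int:
    """Distance between two spans on one axis; 0 when they touch/overlap."""
    return max(b_start - a_end, a_start - b_end, 0)


def anchors_linkable(a: Anchor, b: Anchor, link_gap: int, gap_sides: str = "both") -> bool:
    if (
        a.query.chrom != b.query.chrom
        or a.target.chrom != b.target.chrom
        or a.orientation != b.orientation
    ):
        return False
    q_ok = _gap(a.query.start, a.query.end, b.query.start, b.query.end) < link_gap
    if gap_sides == "query":
        return q_ok
    t_ok = _gap(a.target.start, a.target.end, b.target.start, b.target.end) < link_gap
    return q_ok and t_ok


def _merge_query_overlaps(anchors: list[Anchor]) -> list[Anchor]:
    """Merge anchors overlapping on the query within one chromosome pair.

    Aligners emit overlapping local hits; chaining assumes a tiling, so
    overlapping anchors are collapsed to their hulls with a
    length-weighted identity.
    """
    merged: list[Anchor] = []
    group: list[Anchor] = []

    def flush() -> None:
        if not group:
            return
        if len(group) == 1:
            merged.append(group[0])
        else:
            qh = hull([a.query for a in group])
            th = hull([a.target for a in group])
            w = np.array([a.query.length for a in group], dtype=float)
            ident = float(np.average([a.identity for a in group], weights=w))
            merged.append(Anchor(qh, th, group[0].orientation, ident))
        group.clear()

    for a in sorted(anchors, key=lambda x: (x.query.start, x.query.end)):
        if group and a.query.start < group[-1].query.end:
            group.append(a)
        else:
            flush()
            group.append(a)
    flush()
    return merged


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[rj] = ri


def link_anchors(
    anchors: list[Anchor], link_gap: int = 20_000, gap_sides: str = "both"
) -> list[SyntenyBlock]:
    """Chain anchors into maximal syntenic collinearity blocks.

    Every anchor ends up in exactly one block; blocks are the connected
    components of the pairwise linkable relation. Output is sorted by
    (query chrom, query start).
    """
    if link_gap <= 0:
        raise ValueError("link_gap must be positive")
    by_pair: dict[tuple[str, str, str], list[Anchor]] = {}
    for a in anchors:
        by_pair.setdefault((a.query.chrom, a.target.chrom, a.orientation), []).append(a)

    blocks: list[SyntenyBlock] = []
    for (_, _, orientation), group in by_pair.items():
        group = _merge_query_overlaps(group)
        group.sort(key=lambda a: (a.query.start, a.query.end))
        n = len(group)
        uf = _UnionFind(n)
        # Sorted by query start: once the query gap alone exceeds the cutoff
        # for anchor j, it does for all later anchors too.
        for i in range(n):
            for j in range(i + 1, n):
                if group[j].query.start - group[i].query.end >= link_gap:
                    break
                if anchors_linkable(group[i], group[j], link_gap, gap_sides):
                    uf.union(i, j)
        components: dict[int, list[Anchor]] = {}
        for i, a in enumerate(group):
            components.setdefault(uf.find(i), []).append(a)
        for members in components.values():
            members.sort(key=lambda a: (a.query.start, a.query.end))
            blocks.append(
                SyntenyBlock(
                    anchors=members,
                    query_span=hull([a.query for a in members]),
                    target_span=hull([a.target for a in members]),
                    orientation=orientation,
                )
            )
    blocks.sort(key=lambda b: (b.query_span.chrom, b.query_span.start))
    log.info("link_anchors: %d anchors -> %d blocks (gap=%d)", len(anchors), len(blocks), link_gap)
    return blocks


@dataclass
class LiftResult:
    """Outcome of lifting one interval through a chain."""

    mapped: list[GenomicInterval]
    uncovered: list[GenomicInterval]
    ambiguous: bool = False


@dataclass
class LiftoverChain:
    """Indexed synteny blocks supporting interval queries and liftover.

    Within a block the map is piecewise linear through the anchor
    endpoints; gaps between anchors are interpolated linearly (sub-anchor
    precision is immaterial at the >= 60 kb scale the caller operates on).
    An interval covered by blocks on two different chromosome pairs is
    mapped through both and flagged ambiguous rather than silently
    resolved.
    """

    blocks: list[SyntenyBlock]
    _by_qchrom: dict[str, list[SyntenyBlock]] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._by_qchrom = {}
        for b in self.blocks:
            self._by_qchrom.setdefault(b.query_span.chrom, []).append(b)
        for chrom, bl in self._by_qchrom.items():
            bl.sort(key=lambda b: b.query_span.start)

    @classmethod
    def from_anchors(
        cls, anchors: list[Anchor], link_gap: int = 20_000, gap_sides: str = "both"
    ) -> "LiftoverChain":
        return cls(link_anchors(anchors, link_gap, gap_sides))

    def has_query_chrom(self, chrom: str) -> bool:
        return chrom in self._by_qchrom

    def invert(self) -> "LiftoverChain":
        """Chain with query and target swapped (for lifting the other way)."""
        inv_blocks = []
        for b in self.blocks:
            inv_anchors = [
                Anchor(a.target, a.query, a.orientation, a.identity) for a in b.anchors
            ]
            inv_anchors.sort(key=lambda a: (a.query.start, a.query.end))
            inv_blocks.append(
                SyntenyBlock(inv_anchors, b.target_span, b.query_span, b.orientation)
            )
        return LiftoverChain(inv_blocks)

    def _block_map(self, block: SyntenyBlock, q0: int, q1: int) -> GenomicInterval:
        """Map [q0, q1) (inside the block's query span) to target coordinates."""
        qs: list[float] = []
        ts: list[float] = []
        if block.orientation == "same":
            for a in block.anchors:
                qs.extend([a.query.start, a.query.end])
                ts.extend([a.target.start, a.target.end])
        else:
            for a in block.anchors:
                qs.extend([a.query.start, a.query.end])
                ts.extend([a.target.end, a.target.start])
        # Deduplicate query nodes while keeping the map monotone in q.
        q_arr = np.array(qs, dtype=float)
        t_arr = np.array(ts, dtype=float)
        order = np.argsort(q_arr, kind="stable")
        q_arr, t_arr = q_arr[order], t_arr[order]
        t0 = float(np.interp(q0, q_arr, t_arr))
        t1 = float(np.interp(q1, q_arr, t_arr))
        lo, hi = (t0, t1) if t0 <= t1 else (t1, t0)
        start, end = int(round(lo)), int(round(hi))
        if end <= start:
            end = start + 1
        return GenomicInterval(block.target_span.chrom, start, end)

    def lift(self, iv: GenomicInterval) -> LiftResult:
        blocks = self._by_qchrom.get(iv.chrom)
        if not blocks:
            log.warning("lift: chromosome %s absent from chain", iv.chrom)
            return LiftResult([], [iv])
        mapped: list[GenomicInterval] = []
        covered: list[GenomicInterval] = []
        pairs_hit: set[tuple[str, str]] = set()
        for b in blocks:
            q0 = max(iv.start, b.query_span.start)
            q1 = min(iv.end, b.query_span.end)
            if q0 >= q1:
                continue
            mapped.append(self._block_map(b, q0, q1))
            covered.append(GenomicInterval(iv.chrom, q0, q1))
            pairs_hit.add((b.query_span.chrom, b.target_span.chrom))
        uncovered = _subtract(iv, covered)
        ambiguous = len(pairs_hit) > 1
        if uncovered:
            log.warning(
                "lift: %d bp of %s not covered by any block",
                sum(u.length for u in uncovered), iv,
            )
        return LiftResult(mapped, uncovered, ambiguous)


def _subtract(iv: GenomicInterval, covers: list[GenomicInterval]) -> list[GenomicInterval]:
    """Portions of iv not covered by the (same-chromosome) cover intervals."""
    segments = sorted(
        (c.start, c.end) for c in covers if c.chrom == iv.chrom
    )
    out: list[GenomicInterval] = []
    pos = iv.start
    for s, e in segments:
        if s > pos:
            out.append(GenomicInterval(iv.chrom, pos, min(s, iv.end)))
        pos = max(pos, e)
        if pos >= iv.end:
            break
    if pos < iv.end:
        out.append(GenomicInterval(iv.chrom, pos, iv.end))
    return out


def lift_interval(chain: LiftoverChain, iv: GenomicInterval) -> list[GenomicInterval]:
    """Target-genome intervals for the block-covered portions of ``iv``."""
    return chain.lift(iv).mapped


def overlap_fraction(blocks: list[SyntenyBlock], iv: GenomicInterval) -> float:
    """Fraction of iv's bases covered by the union of block query spans."""
    spans = [b.query_span for b in blocks]
    return covered_length(spans, iv) / iv.length
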