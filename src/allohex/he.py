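"""Depth-window homeologous-exchange (HE) detection.

The detector works on per-sample read depth against a *concatenated
progenitor reference* (both parental genomes in one index, so reads from
each subgenome map to their own parent). In a balanced allotetraploid
every 10 kb window sits near the chromosome average depth; an "HE with
replacement" event deletes one subgenome's segment and duplicates its
homeolog, producing a ~0x run on the lost side and a ~2x run on the
gained side. The caller classifies windows against the chromosome mean,
merges same-mark runs, filters by span and progenitor synteny, and pairs
reciprocal deletion/duplication signatures through the synteny chain.

Mapping the allotetraploid to a *diverged* progenitor reference
depresses depth genome-wide and patchily (mismapping grows with
read-to-reference divergence), producing spurious deletion blocks;
``compare_references`` quantifies that artifact between two candidate
references.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .intervals import Anchor, GenomicInterval, covered_length, hull
from .io import WindowDepthRecord
from .synteny import LiftoverChain, SyntenyBlock, overlap_fraction

log = logging.getLogger("allohex.he")

MARK_DUP = "DUP"
MARK_DEL = "DEL"
MARK_NORMAL = "NORMAL"
MARK_HIGH = "HIGH"
MARK_PARTIAL = "PARTIAL"


@dataclass(frozen=True)
class WindowMark:
    window: GenomicInterval
    mark: str
    ratio: float
    sample_id: str = ""


@dataclass
class OutlierBlock:
    span: GenomicInterval
    mark: str  # DUP or DEL
    n_windows: int
    sample_id: str
    synteny_covered: float = float("nan")


@dataclass
class HECall:
    kind: str  # "replacement" or "reciprocal"
    lost_region: GenomicInterval
    gained_region: GenomicInterval
    direction: str  # e.g. "S_replaced_by_D"
    samples_supporting: list[str] = field(default_factory=list)
    overlap_bp: int = 0


# ---------------------------------------------------------------------------
# Window classification
# ---------------------------------------------------------------------------

def chromosome_mean_depth(
    records: Sequence[WindowDepthRecord], trimmed_fraction: float = 0.0
) -> float:
    """Mean depth over the full (non-partial) windows of one chromosome.

    All records must belong to one sample and chromosome. An optional
    two-sided trim guards the mean against extreme windows on short
    chromosomes; the default is the plain mean.
    """
    full = [r.mean_depth for r in records if not r.partial]
    if not full:
        raise ValueError("no full windows: cannot compute chromosome mean depth")
    if trimmed_fraction > 0:
        from scipy.stats import trim_mean

        return float(trim_mean(full, trimmed_fraction))
    return float(np.mean(full))


def classify_windows(
    records: Sequence[WindowDepthRecord],
    chrom_mean: float,
    dup_range: tuple[float, float] = (1.5, 5.0),
    del_range: tuple[float, float] = (0.0, 0.5),
) -> list[WindowMark]:
    """Mark each window by its depth ratio to the chromosome mean.

    DUP and DEL ranges are closed intervals; ratios above the DUP range
    are HIGH (repeat-like, never merged into HE blocks); partial windows
    are marked PARTIAL regardless of depth.
    """
    if chrom_mean <= 0:
        raise ValueError(f"chromosome mean depth must be positive, got {chrom_mean}")
    dup_low, dup_high = dup_range
    del_low, del_high = del_range
    marks = []
    for r in records:
        ratio = r.mean_depth / chrom_mean
        if r.partial:
            mark = MARK_PARTIAL
        elif del_low <= ratio <= del_high:
            mark = MARK_DEL
        elif dup_low <= ratio <= dup_high:
            mark = MARK_DUP
        elif ratio > dup_high:
            mark = MARK_HIGH
        else:
            mark = MARK_NORMAL
        marks.append(WindowMark(r.window, mark, ratio, r.sample_id))
    return marks


def merge_marked_windows(marks: Sequence[WindowMark]) -> list[OutlierBlock]:
    """Link adjacent same-mark DUP/DEL windows into maximal outlier blocks.

    NORMAL, HIGH and PARTIAL windows break runs. Windows are adjacent
    when one ends where the next starts on the same chromosome.
    """
    blocks: list[OutlierBlock] = []
    run: list[WindowMark] = []

    def flush() -> None:
        if run:
            blocks.append(
                OutlierBlock(
                    span=hull([m.window for m in run]),
                    mark=run[0].mark,
                    n_windows=len(run),
                    sample_id=run[0].sample_id,
                )
            )
            run.clear()

    ordered = sorted(marks, key=lambda m: (m.sample_id, m.window.chrom, m.window.start))
    for m in ordered:
        if m.mark not in (MARK_DUP, MARK_DEL):
            flush()
            continue
        if run and (
            m.mark != run[-1].mark
            or m.sample_id != run[-1].sample_id
            or m.window.chrom != run[-1].window.chrom
            or m.window.start != run[-1].window.end
        ):
            flush()
        run.append(m)
    flush()
    return blocks


def filter_he_candidates(
    blocks: Sequence[OutlierBlock],
    synteny: Sequence[SyntenyBlock],
    min_span: int = 60_000,
    min_windows: int = 6,
    min_synteny_frac: float = 0.5,
) -> list[OutlierBlock]:
    """Keep blocks long enough and inside progenitor synteny.

    A block survives when span >= min_span, run length >= min_windows and
    at least ``min_synteny_frac`` of its bases lie in syntenic
    collinearity blocks between the two progenitor genomes. Kept blocks
    are annotated with their synteny coverage.
    """
    kept = []
    synteny = list(synteny)
    # An outlier block may live on either genome of the synteny map; its
    # chromosome matches the query spans of one orientation and the target
    # spans of the other, so coverage is taken over both span sets.
    span_pool = [s.query_span for s in synteny] + [s.target_span for s in synteny]
    for b in blocks:
        if b.span.length < min_span or b.n_windows < min_windows:
            continue
        frac = covered_length(span_pool, b.span) / b.span.length
        if frac < min_synteny_frac:
            continue
        kept.append(
            OutlierBlock(b.span, b.mark, b.n_windows, b.sample_id, synteny_covered=frac)
        )
    log.info(
        "filter_he_candidates: %d/%d blocks kept (min_span=%d, min_windows=%d, "
        "min_synteny_frac=%.2f)", len(kept), len(blocks), min_span, min_windows,
        min_synteny_frac,
    )
    return kept


def call_outlier_blocks(
    records: Sequence[WindowDepthRecord],
    synteny: Sequence[SyntenyBlock],
    config: PipelineConfig | None = None,
) -> list[OutlierBlock]:
    """Classify, merge and filter: the per-sample block-calling pipeline."""
    cfg = config or PipelineConfig()
    by_sample_chrom: dict[tuple[str, str], list[WindowDepthRecord]] = {}
    for r in records:
        by_sample_chrom.setdefault((r.sample_id, r.window.chrom), []).append(r)
    blocks: list[OutlierBlock] = []
    for (sample, chrom), recs in sorted(by_sample_chrom.items()):
        recs.sort(key=lambda r: r.window.start)
        mean = chromosome_mean_depth(recs, cfg.trimmed_mean_fraction)
        marks = classify_windows(
            recs, mean, (cfg.dup_low, cfg.dup_high), (cfg.del_low, cfg.del_high)
        )
        blocks.extend(merge_marked_windows(marks))
    filtered = filter_he_candidates(
        blocks, synteny, cfg.min_span, cfg.min_windows, cfg.min_synteny_frac
    )
    return filtered


# ---------------------------------------------------------------------------
# Replacement pairing
# ---------------------------------------------------------------------------

def _lift_hull(chain: LiftoverChain, iv: GenomicInterval) -> GenomicInterval | None:
    mapped = chain.lift(iv).mapped
    if not mapped:
        return None
    chroms = {m.chrom for m in mapped}
    if len(chroms) > 1:
        # ambiguous across chromosomes: keep the largest mapped mass
        best = max(chroms, key=lambda c: sum(m.length for m in mapped if m.chrom == c))
        mapped = [m for m in mapped if m.chrom == best]
    return hull(mapped)


def pair_replacement_events(
    dup_blocks: Sequence[OutlierBlock],
    del_blocks: Sequence[OutlierBlock],
    synteny: LiftoverChain,
    subgenome_of: Mapping[str, str] | Callable[[str], str],
    reciprocal_overlap_frac: float = 0.5,
) -> tuple[list[HECall], list[OutlierBlock]]:
    """Pair DEL blocks with synteny-matched DUP blocks into replacement calls.

    The DEL span is lifted through the synteny chain onto the homeologous
    genome; a DUP block qualifies when the lifted span and the DUP span
    overlap reciprocally by at least ``reciprocal_overlap_frac`` of each.
    Within one sample each block joins at most one call; assignment is
    greedy by overlap size with deterministic leftmost tie-breaking.
    Returns (calls, unpaired blocks).

    ``subgenome_of`` labels a chromosome with its subgenome/progenitor
    ("D" or "S"); the call direction reads "<lost>_replaced_by_<donor>".
    The synteny chain must map DEL-side (query) coordinates onto DUP-side
    (target) coordinates; blocks from both subgenomes can be passed, the
    chain and its inverse are tried as needed.
    """
    label = subgenome_of if callable(subgenome_of) else subgenome_of.__getitem__
    inverse = synteny.invert()
    candidates = []  # (overlap, del_idx, dup_idx, lifted_hull)
    for i, dl in enumerate(del_blocks):
        side = synteny if synteny.has_query_chrom(dl.span.chrom) else inverse
        lifted = _lift_hull(side, dl.span)
        if lifted is None:
            continue
        for j, dp in enumerate(dup_blocks):
            if dl.sample_id != dp.sample_id:
                continue
            ov = lifted.overlap_length(dp.span)
            if ov >= reciprocal_overlap_frac * lifted.length and ov >= (
                reciprocal_overlap_frac * dp.span.length
            ):
                candidates.append((ov, i, j, lifted))
    candidates.sort(
        key=lambda c: (-c[0], del_blocks[c[1]].span.start, dup_blocks[c[2]].span.start)
    )
    used_del: set[int] = set()
    used_dup: set[int] = set()
    calls: list[HECall] = []
    for ov, i, j, lifted in candidates:
        if i in used_del or j in used_dup:
            continue
        used_del.add(i)
        used_dup.add(j)
        dl, dp = del_blocks[i], dup_blocks[j]
        lost_sub = label(dl.span.chrom)
        donor_sub = label(dp.span.chrom)
        calls.append(
            HECall(
                kind="replacement",
                lost_region=dl.span,
                gained_region=dp.span,
                direction=f"{lost_sub}_replaced_by_{donor_sub}",
                samples_supporting=[dl.sample_id],
                overlap_bp=ov,
            )
        )
    unpaired = [b for k, b in enumerate(del_blocks) if k not in used_del]
    unpaired += [b for k, b in enumerate(dup_blocks) if k not in used_dup]
    calls.sort(key=lambda c: (c.lost_region.chrom, c.lost_region.start))
    log.info(
        "pair_replacement_events: %d calls, %d unpaired blocks", len(calls), len(unpaired)
    )
    return calls, unpaired


# ---------------------------------------------------------------------------
# Reciprocal swaps from assembly anchors
# ---------------------------------------------------------------------------

def detect_reciprocal_swaps(
    anchors: Sequence[Anchor],
    query_subgenome: Mapping[str, str],
    target_genome: Mapping[str, str],
    min_span: int = 60_000,
) -> list[HECall]:
    """Detect syntenic swapped segments from allotetraploid-vs-progenitor anchors.

    A maximal run of anchors on one allotetraploid chromosome whose
    targets lie in the *other* progenitor genome, spanning at least
    ``min_span`` and flanked on both sides by same-subgenome anchors, is
    a reciprocal-swap candidate. Candidates on the two homeologous
    chromosomes whose swapped targets mirror each other are reported as
    one call; an unmirrored candidate is still reported on its own.
    """
    for a in anchors:
        if a.query.chrom not in query_subgenome:
            raise ValueError(f"unlabeled query chromosome {a.query.chrom!r}")
        if a.target.chrom not in target_genome:
            raise ValueError(f"unlabeled target chromosome {a.target.chrom!r}")

    by_qchrom: dict[str, list[Anchor]] = {}
    for a in anchors:
        by_qchrom.setdefault(a.query.chrom, []).append(a)

    candidates: list[tuple[HECall, GenomicInterval | None]] = []
    for qchrom, group in sorted(by_qchrom.items()):
        group.sort(key=lambda a: a.query.start)
        own = query_subgenome[qchrom]
        flags = [target_genome[a.target.chrom] != own for a in group]
        i = 0
        while i < len(group):
            if not flags[i]:
                i += 1
                continue
            j = i
            while j + 1 < len(group) and flags[j + 1]:
                j += 1
            run = group[i : j + 1]
            flanked = i > 0 and j < len(group) - 1
            span = hull([a.query for a in run])
            if flanked and span.length >= min_span:
                foreign = hull([a.target for a in run])
                donor = target_genome[run[0].target.chrom]
                # The stretch of this subgenome's own progenitor that was
                # swapped out: the gap between the flanking anchors' targets.
                left, right = group[i - 1].target, group[j + 1].target
                home = None
                if left.chrom == right.chrom and left.end < right.start:
                    home = GenomicInterval(left.chrom, left.end, right.start)
                candidates.append(
                    (
                        HECall(
                            kind="reciprocal",
                            lost_region=span,       # segment of the query chromosome
                            gained_region=foreign,  # its foreign-genome origin
                            direction=f"{own}_carries_{donor}_segment",
                        ),
                        home,
                    )
                )
            i = j + 1

    # Mirror-pair candidates: in a true swap, the foreign origin carried by
    # one side coincides with the region the other side swapped out of its
    # own progenitor genome (and vice versa).
    paired: set[int] = set()
    calls: list[HECall] = []
    for i, (c, c_home) in enumerate(candidates):
        if i in paired:
            continue
        mirror = None
        for j in range(i + 1, len(candidates)):
            if j in paired:
                continue
            d, d_home = candidates[j]
            fwd = d_home is not None and c.gained_region.overlaps(d_home)
            rev = c_home is not None and d.gained_region.overlaps(c_home)
            if fwd and rev:
                mirror = j
                break
        if mirror is not None:
            paired.add(mirror)
            d, _ = candidates[mirror]
            calls.append(
                HECall(
                    kind="reciprocal",
                    lost_region=c.lost_region,
                    gained_region=d.lost_region,
                    direction="reciprocal_swap",
                )
            )
        else:
            calls.append(c)
    log.info("detect_reciprocal_swaps: %d calls from %d anchors", len(calls), len(anchors))
    return calls


# ---------------------------------------------------------------------------
# Multi-sample consolidation and reference comparison
# ---------------------------------------------------------------------------

def consolidate_calls(calls: Sequence[HECall], overlap_frac: float = 0.5) -> list[HECall]:
    """Merge per-sample calls of the same event across samples.

    Calls of identical kind and direction whose lost regions overlap
    reciprocally by at least ``overlap_frac`` are one event; its span is
    the hull and its support the sorted union of sample lists.
    """
    groups: list[list[HECall]] = []
    for c in sorted(calls, key=lambda c: (c.kind, c.direction, c.lost_region.chrom, c.lost_region.start)):
        placed = False
        for g in groups:
            rep = g[0]
            if rep.kind != c.kind or rep.direction != c.direction:
                continue
            ov = rep.lost_region.overlap_length(c.lost_region)
            if (
                ov >= overlap_frac * rep.lost_region.length
                and ov >= overlap_frac * c.lost_region.length
            ):
                g.append(c)
                placed = True
                break
        if not placed:
            groups.append([c])
    out = []
    for g in groups:
        samples = sorted({s for c in g for s in c.samples_supporting})
        out.append(
            HECall(
                kind=g[0].kind,
                lost_region=hull([c.lost_region for c in g]),
                gained_region=hull([c.gained_region for c in g]),
                direction=g[0].direction,
                samples_supporting=samples,
                overlap_bp=max(c.overlap_bp for c in g),
            )
        )
    out.sort(key=lambda c: (c.lost_region.chrom, c.lost_region.start))
    return out


def compare_references(
    depth_by_ref: Mapping[str, Sequence[WindowDepthRecord]],
    synteny_by_ref: Mapping[str, Sequence[SyntenyBlock]],
    config: PipelineConfig | None = None,
) -> pd.DataFrame:
    """Count filtered DUP/DEL blocks per sample against each candidate reference.

    ``depth_by_ref`` maps a reference label to that reference's depth
    records for the *same* samples. Returns a table with one row per
    (sample, reference) and per-sample count differences for each
    reference pair, sorted by sample. Differing sample sets between
    references are an error.
    """
    cfg = config or PipelineConfig()
    labels = sorted(depth_by_ref)
    sample_sets = {
        lab: {r.sample_id for r in depth_by_ref[lab]} for lab in labels
    }
    reference_samples = sample_sets[labels[0]]
    for lab in labels[1:]:
        if sample_sets[lab] != reference_samples:
            raise ValueError(
                "sample sets differ between references: "
                f"{lab} has {sorted(sample_sets[lab] ^ reference_samples)} mismatched"
            )
    rows = []
    for lab in labels:
        blocks = call_outlier_blocks(depth_by_ref[lab], list(synteny_by_ref[lab]), cfg)
        counts: dict[str, dict[str, int]] = {
            s: {MARK_DUP: 0, MARK_DEL: 0} for s in reference_samples
        }
        for b in blocks:
            counts[b.sample_id][b.mark] += 1
        for sample in sorted(reference_samples):
            rows.append(
                {
                    "sample_id": sample,
                    "reference": lab,
                    "n_dup_blocks": counts[sample][MARK_DUP],
                    "n_del_blocks": counts[sample][MARK_DEL],
                    "n_outlier_blocks": counts[sample][MARK_DUP] + counts[sample][MARK_DEL],
                }
            )
    df = pd.DataFrame(rows).sort_values(["sample_id", "reference"]).reset_index(drop=True)
    if len(labels) == 2:
        a, b = labels
        wide = df.pivot(index="sample_id", columns="reference", values="n_outlier_blocks")
        diff = (wide[a] - wide[b]).rename("diff_" + a + "_minus_" + b)
        df = df.merge(diff.reset_index(), on="sample_id")
    log.info("compare_references: %d references, %d samples", len(labels), len(reference_samples))
    return df
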