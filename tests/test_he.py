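"""The depth-window HE caller: classification, merging, filtering, pairing."""

import itertools

import numpy as np
import pytest

from allohex.config import PipelineConfig
from allohex.he import (
    MARK_DEL,
    MARK_DUP,
    MARK_HIGH,
    MARK_NORMAL,
    MARK_PARTIAL,
    OutlierBlock,
    call_outlier_blocks,
    chromosome_mean_depth,
    classify_windows,
    compare_references,
    consolidate_calls,
    detect_reciprocal_swaps,
    filter_he_candidates,
    merge_marked_windows,
    pair_replacement_events,
)
from allohex.intervals import Anchor, GenomicInterval
from allohex.io import WindowDepthRecord
from allohex.simulate import (
    HEEvent,
    SimConfig,
    matched_reference,
    simulate_allotetraploid,
    simulate_depth,
    simulate_progenitors,
)
from allohex.synteny import LiftoverChain, link_anchors


def _rec(chrom, start, depth, sample="s1", partial=False, w=10_000):
    return WindowDepthRecord(
        GenomicInterval(chrom, start, start + (3_000 if partial else w)),
        sample, depth, partial=partial,
    )


class TestChromosomeMean:
    def test_plain_mean(self):
        assert chromosome_mean_depth([_rec("c1", 0, 20), _rec("c1", 10_000, 40)]) == 30

    def test_partial_windows_excluded(self):
        recs = [_rec("c1", 0, 30), _rec("c1", 10_000, 30), _rec("c1", 20_000, 90, partial=True)]
        assert chromosome_mean_depth(recs) == 30

    def test_all_partial_is_error(self):
        with pytest.raises(ValueError):
            chromosome_mean_depth([_rec("c1", 0, 30, partial=True)])


class TestClassifyWindows:
    @pytest.mark.parametrize(
        "depth,expected",
        [
            (50, MARK_DUP),      # ratio 1.67
            (10, MARK_DEL),      # ratio 0.33
            (200, MARK_HIGH),    # ratio 6.67, repeat-like, excluded from HE
            (30, MARK_NORMAL),
            (45, MARK_DUP),      # exactly 1.5x: closed interval
            (15, MARK_DEL),      # exactly 0.5x: closed interval
            (150, MARK_DUP),     # exactly 5x: still DUP
            (0, MARK_DEL),
        ],
    )
    def test_threshold_application(self, depth, expected):
        marks = classify_windows([_rec("c1", 0, depth)], chrom_mean=30.0)
        assert marks[0].mark == expected

    def test_partial_never_dup_or_del(self):
        marks = classify_windows([_rec("c1", 0, 90, partial=True)], 30.0)
        assert marks[0].mark == MARK_PARTIAL

    def test_nonpositive_mean_is_error(self):
        with pytest.raises(ValueError):
            classify_windows([_rec("c1", 0, 30)], 0.0)

    def test_every_full_window_gets_exactly_one_mark(self, rng):
        recs = [_rec("c1", i * 10_000, float(d)) for i, d in enumerate(rng.integers(0, 200, 50))]
        marks = classify_windows(recs, 30.0)
        assert len(marks) == len(recs)
        assert all(
            m.mark in {MARK_DUP, MARK_DEL, MARK_NORMAL, MARK_HIGH} for m in marks
        )


class TestMergeMarkedWindows:
    def _marks(self, depths, mean=30.0):
        recs = [_rec("c1", i * 10_000, d) for i, d in enumerate(depths)]
        return classify_windows(recs, mean)

    def test_runs_become_blocks(self):
        blocks = merge_marked_windows(self._marks([60, 60, 10]))
        assert [(b.mark, b.span.start, b.span.end, b.n_windows) for b in blocks] == [
            (MARK_DUP, 0, 20_000, 2), (MARK_DEL, 20_000, 30_000, 1)
        ]

    def test_normal_breaks_runs(self):
        blocks = merge_marked_windows(self._marks([60, 30, 60]))
        assert [b.n_windows for b in blocks] == [1, 1]
        assert all(b.mark == MARK_DUP for b in blocks)

    def test_all_normal_no_blocks(self):
        assert merge_marked_windows(self._marks([30, 30, 30])) == []

    def test_window_conservation(self, rng):
        """Block window counts must sum to the DUP/DEL-marked window count."""
        depths = rng.choice([0.0, 10.0, 30.0, 60.0, 200.0], size=200)
        marks = self._marks(list(depths))
        n_outlier = sum(1 for m in marks if m.mark in {MARK_DUP, MARK_DEL})
        blocks = merge_marked_windows(marks)
        assert sum(b.n_windows for b in blocks) == n_outlier


class TestFilterCandidates:
    def _synteny(self):
        return link_anchors(
            [Anchor(GenomicInterval("c1", 0, 1_000_000), GenomicInterval("h1", 0, 1_000_000))]
        )

    def _block(self, start, n, mark=MARK_DUP):
        return OutlierBlock(
            GenomicInterval("c1", start, start + n * 10_000), mark, n, "s1"
        )

    def test_five_window_block_rejected(self):
        assert filter_he_candidates([self._block(0, 5)], self._synteny()) == []

    def test_six_window_block_kept_at_boundary(self):
        kept = filter_he_candidates([self._block(0, 6)], self._synteny())
        assert len(kept) == 1 and kept[0].synteny_covered == 1.0

    def test_outside_synteny_rejected(self):
        blocks = [
            OutlierBlock(GenomicInterval("c2", 0, 80_000), MARK_DUP, 8, "s1")
        ]
        assert filter_he_candidates(blocks, self._synteny()) == []


class TestReplacementPairing:
    def _chain(self):
        return LiftoverChain.from_anchors(
            [Anchor(GenomicInterval("S1", 0, 1_000_000), GenomicInterval("D1", 0, 1_000_000))]
        )

    def test_reciprocal_overlap_forms_call(self):
        dels = [OutlierBlock(GenomicInterval("S1", 100_000, 200_000), MARK_DEL, 10, "s1")]
        dups = [OutlierBlock(GenomicInterval("D1", 95_000, 205_000), MARK_DUP, 11, "s1")]
        calls, unpaired = pair_replacement_events(
            dups, dels, self._chain(), lambda c: c[0]
        )
        assert len(calls) == 1 and not unpaired
        assert calls[0].direction == "S_replaced_by_D"
        assert calls[0].lost_region.chrom == "S1"
        assert calls[0].gained_region.chrom == "D1"

    def test_unpartnered_del_reported(self):
        dels = [OutlierBlock(GenomicInterval("S1", 100_000, 200_000), MARK_DEL, 10, "s1")]
        calls, unpaired = pair_replacement_events([], dels, self._chain(), lambda c: c[0])
        assert calls == [] and unpaired == dels

    def test_samples_never_mix(self):
        dels = [OutlierBlock(GenomicInterval("S1", 100_000, 200_000), MARK_DEL, 10, "s1")]
        dups = [OutlierBlock(GenomicInterval("D1", 100_000, 200_000), MARK_DUP, 10, "s2")]
        calls, unpaired = pair_replacement_events(dups, dels, self._chain(), lambda c: c[0])
        assert calls == [] and len(unpaired) == 2

    def test_greedy_matches_brute_force_on_small_instances(self):
        """On <= 3-block instances the greedy assignment must reach the
        matching an exhaustive search finds (maximal total overlap)."""
        chain = self._chain()

        def greedy_total(dels, dups):
            calls, _ = pair_replacement_events(dups, dels, chain, lambda c: c[0])
            return sum(c.overlap_bp for c in calls), len(calls)

        def brute_total(dels, dups):
            best = (0, 0)
            k = min(len(dels), len(dups))
            for size in range(k, 0, -1):
                for del_sub in itertools.permutations(range(len(dels)), size):
                    for dup_sub in itertools.combinations(range(len(dups)), size):
                        total, count = 0, 0
                        for di, pi in zip(del_sub, dup_sub):
                            dl, dp = dels[di], dups[pi]
                            lifted = chain.lift(dl.span).mapped[0]
                            ov = lifted.overlap_length(dp.span)
                            if ov >= 0.5 * lifted.length and ov >= 0.5 * dp.span.length:
                                total += ov
                                count += 1
                        best = max(best, (total, count))
            return best

        # two DELs competing for one DUP
        dels = [
            OutlierBlock(GenomicInterval("S1", 100_000, 200_000), MARK_DEL, 10, "s1"),
            OutlierBlock(GenomicInterval("S1", 130_000, 210_000), MARK_DEL, 8, "s1"),
        ]
        dups = [OutlierBlock(GenomicInterval("D1", 100_000, 200_000), MARK_DUP, 10, "s1")]
        calls, unpaired = pair_replacement_events(dups, dels, self._chain(), lambda c: c[0])
        assert len(calls) == 1
        assert calls[0].lost_region.start == 100_000  # higher-overlap DEL wins
        assert greedy_total(dels, dups) == brute_total(dels, dups)

        # three blocks with partially conflicting overlaps
        dels3 = dels + [OutlierBlock(GenomicInterval("S1", 400_000, 480_000), MARK_DEL, 8, "s1")]
        dups3 = dups + [OutlierBlock(GenomicInterval("D1", 390_000, 480_000), MARK_DUP, 9, "s1")]
        assert greedy_total(dels3, dups3) == brute_total(dels3, dups3)


class TestReciprocalSwaps:
    def _setup(self, events):
        cfg = SimConfig(seed=42, he_events=events)
        allo = simulate_allotetraploid(simulate_progenitors(cfg), cfg)
        return allo

    def test_planted_swap_recovered_exactly(self):
        allo = self._setup([HEEvent("reciprocal", "D", 1, 500_000, 100_000)])
        calls = detect_reciprocal_swaps(
            allo.assembly_anchors, allo.query_subgenome, allo.target_genome
        )
        assert len(calls) == 1
        c = calls[0]
        assert c.kind == "reciprocal" and c.direction == "reciprocal_swap"
        spans = {(r.chrom, r.start, r.end) for r in (c.lost_region, c.gained_region)}
        assert spans == {("BhD1", 500_000, 600_000), ("BhS1", 500_000, 600_000)}

    def test_unmodified_assembly_yields_nothing(self):
        allo = self._setup([])
        assert detect_reciprocal_swaps(
            allo.assembly_anchors, allo.query_subgenome, allo.target_genome
        ) == []

    def test_short_swap_below_span_ignored(self):
        allo = self._setup([HEEvent("reciprocal", "D", 1, 500_000, 20_000)])
        assert detect_reciprocal_swaps(
            allo.assembly_anchors, allo.query_subgenome, allo.target_genome,
            min_span=60_000,
        ) == []

    def test_unlabeled_chromosome_is_error(self):
        allo = self._setup([])
        with pytest.raises(ValueError, match="unlabeled"):
            detect_reciprocal_swaps(allo.assembly_anchors, {}, allo.target_genome)


class TestConsolidation:
    def test_shared_events_merge_across_samples(self):
        from allohex.he import HECall

        calls = [
            HECall("replacement", GenomicInterval("S1", 100_000, 200_000),
                   GenomicInterval("D1", 100_000, 200_000), "S_replaced_by_D", ["s1"]),
            HECall("replacement", GenomicInterval("S1", 110_000, 200_000),
                   GenomicInterval("D1", 110_000, 200_000), "S_replaced_by_D", ["s2"]),
            HECall("replacement", GenomicInterval("S1", 700_000, 800_000),
                   GenomicInterval("D1", 700_000, 800_000), "S_replaced_by_D", ["s1"]),
        ]
        merged = consolidate_calls(calls)
        assert len(merged) == 2
        assert merged[0].samples_supporting == ["s1", "s2"]


class TestCompareReferences:
    def test_identical_references_give_equal_counts(self, planted_config, progenitor_chain):
        depth = simulate_depth(planted_config, matched_reference())
        report = compare_references(
            {"refA": depth, "refB": depth},
            {"refA": progenitor_chain.blocks, "refB": progenitor_chain.blocks},
        )
        wide = report.pivot(index="sample_id", columns="reference", values="n_outlier_blocks")
        assert (wide["refA"] == wide["refB"]).all()

    def test_differing_sample_sets_rejected(self, planted_config, progenitor_chain):
        depth = simulate_depth(planted_config, matched_reference())
        other = simulate_depth(planted_config, matched_reference(), sample_id="other")
        with pytest.raises(ValueError, match="sample sets differ"):
            compare_references(
                {"refA": depth, "refB": other},
                {"refA": progenitor_chain.blocks, "refB": progenitor_chain.blocks},
            )

    def test_no_events_noise_free_matched_reference_zero_blocks(self, progenitor_chain):
        cfg = SimConfig(seed=99)
        depth = simulate_depth(cfg, matched_reference())
        blocks = call_outlier_blocks(depth, progenitor_chain.blocks)
        assert blocks == []


def test_determinism_identical_inputs_identical_calls(planted_config, progenitor_chain):
    def run():
        depth = simulate_depth(planted_config, matched_reference())
        blocks = call_outlier_blocks(depth, progenitor_chain.blocks)
        dups = [b for b in blocks if b.mark == MARK_DUP]
        dels = [b for b in blocks if b.mark == MARK_DEL]
        calls, _ = pair_replacement_events(
            dups, dels, progenitor_chain, lambda c: c[0]
        )
        return [
            (c.kind, c.direction, str(c.lost_region), str(c.gained_region)) for c in calls
        ]

    assert run() == run()
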