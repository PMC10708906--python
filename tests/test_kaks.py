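"""Nei-Gojobori Ka/Ks against enumeration oracles, zero-Ks tests, dating."""

import math
import warnings
from itertools import permutations, product

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from allohex.kaks import (
    STOP_CODONS,
    _STANDARD_TABLE,
    CodonAlignment,
    QuadChain,
    SaturationError,
    closeness_test,
    divergence_time,
    exact_binomial_two_sided,
    kaks_table,
    ks_peak,
    ng86_kaks,
    synonymous_site_fraction,
    zero_ks_counts,
)

SENSE_CODONS = sorted(c for c in _STANDARD_TABLE if c not in STOP_CODONS)


# ---------------------------------------------------------------------------
# Independent oracles
# ---------------------------------------------------------------------------

def oracle_pathway_counts(ca: str, cb: str) -> tuple[float, float]:
    """Brute-force pathway enumerator, written directly from the rule:
    walk every ordering of the differing positions, classify each step by
    translating with the standard code (stop steps nonsynonymous)."""
    diffs = [i for i in range(3) if ca[i] != cb[i]]
    if not diffs:
        return 0.0, 0.0
    sd = nd = 0.0
    orders = list(permutations(diffs))
    for order in orders:
        cur = ca
        for pos in order:
            nxt = cur[:pos] + cb[pos] + cur[pos + 1 :]
            syn = (
                cur not in STOP_CODONS
                and nxt not in STOP_CODONS
                and _STANDARD_TABLE[cur] == _STANDARD_TABLE[nxt]
            )
            if syn:
                sd += 1
            else:
                nd += 1
            cur = nxt
    return sd / len(orders), nd / len(orders)


def oracle_site_fraction(codon: str) -> float:
    s = 0.0
    for pos, base in product(range(3), "ACGT"):
        if base == codon[pos]:
            continue
        mut = codon[:pos] + base + codon[pos + 1 :]
        if mut not in STOP_CODONS and _STANDARD_TABLE[mut] == _STANDARD_TABLE[codon]:
            s += 1 / 3
    return s


# ---------------------------------------------------------------------------
# NG86 estimator
# ---------------------------------------------------------------------------

class TestNG86:
    def test_identical_sequences(self):
        aln = CodonAlignment("a", "b", "ATGAAATTT", "ATGAAATTT")
        r = ng86_kaks(aln)
        assert r.Ka == 0.0 and r.Ks == 0.0 and r.Sd == 0.0 and r.Nd == 0.0

    def test_worked_single_synonymous_difference(self):
        """TTT->TTC in a 4-codon frame: S = 10/3, pS = 0.3, Ks = -0.75 ln 0.6."""
        r = ng86_kaks(CodonAlignment("a", "b", "TTTGGGGGGGGG", "TTCGGGGGGGGG"))
        assert r.S_sites == pytest.approx(10 / 3)
        assert r.Sd == 1.0 and r.Nd == 0.0
        assert r.Ks == pytest.approx(-0.75 * math.log(0.6))
        assert r.Ks == pytest.approx(0.3831, abs=1e-4)
        assert r.Ka == 0.0

    def test_lysine_third_position_synonymous(self):
        # AAA->AAG (Lys->Lys) is purely synonymous; the frame carries
        # enough glycine codons for the synonymous proportion to stay
        # below the Jukes-Cantor limit.
        r = ng86_kaks(CodonAlignment("a", "b", "GGGGGGAAA", "GGGGGGAAG"))
        assert r.Sd == 1.0 and r.Nd == 0.0
        assert r.Ka == 0.0 and r.Ks > 0

    def test_two_codon_toy_saturates(self):
        # at 2 codons the single synonymous difference exceeds the JC
        # limit (pS = 3 with only 1/3 synonymous site per sequence)
        with pytest.raises(SaturationError):
            ng86_kaks(CodonAlignment("a", "b", "ATGAAA", "ATGAAG"))

    def test_site_counts_match_enumeration_oracle(self):
        for codon in SENSE_CODONS:
            assert synonymous_site_fraction(codon) == pytest.approx(
                oracle_site_fraction(codon)
            ), codon

    def test_pathway_counts_match_oracle_for_all_le2_position_pairs(self):
        """Exhaustive check over every sense-codon pair differing at <= 2
        positions (the spec of the pathway-averaging rule)."""
        from allohex.kaks import codon_pair_differences

        n_checked = 0
        for ca in SENSE_CODONS:
            for cb in SENSE_CODONS:
                ndiff = sum(a != b for a, b in zip(ca, cb))
                if ndiff > 2:
                    continue
                assert codon_pair_differences(ca, cb) == pytest.approx(
                    oracle_pathway_counts(ca, cb)
                ), (ca, cb)
                n_checked += 1
        assert n_checked > 1_000

    def test_site_conservation(self, rng):
        for _ in range(10):
            n = int(rng.integers(5, 40))
            seq = "".join(SENSE_CODONS[i] for i in rng.integers(0, len(SENSE_CODONS), n))
            r = ng86_kaks(CodonAlignment("a", "b", seq, seq))
            assert r.S_sites + r.N_sites == pytest.approx(3 * n)

    def test_symmetry_under_sequence_swap(self, rng):
        for _ in range(20):
            n = int(rng.integers(5, 30))
            sa = "".join(SENSE_CODONS[i] for i in rng.integers(0, len(SENSE_CODONS), n))
            sb = "".join(SENSE_CODONS[i] for i in rng.integers(0, len(SENSE_CODONS), n))
            try:
                r1 = ng86_kaks(CodonAlignment("a", "b", sa, sb))
                r2 = ng86_kaks(CodonAlignment("b", "a", sb, sa))
            except SaturationError:
                continue
            for f in ("S_sites", "N_sites", "Sd", "Nd", "Ka", "Ks"):
                assert getattr(r1, f) == pytest.approx(getattr(r2, f))

    def test_agrees_with_independent_reference_implementation(self, rng):
        """Cross-check against Biopython's NG86 on random pairs.

        Pairs are restricted to codon substitutions whose mutational
        pathways avoid stop codons: there the two implementations share
        one convention (they differ only in how a stop-to-stop step is
        classified, which this package counts as nonsynonymous).
        """
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            from Bio.codonalign.codonseq import CodonSeq, cal_dn_ds

        def pathway_stop_free(ca, cb):
            diffs = [i for i in range(3) if ca[i] != cb[i]]
            for order in permutations(diffs):
                cur = ca
                for pos in order:
                    cur = cur[:pos] + cb[pos] + cur[pos + 1 :]
                    if cur in STOP_CODONS:
                        return False
            return True

        for _ in range(10):
            n = 60
            codons = [SENSE_CODONS[i] for i in rng.integers(0, len(SENSE_CODONS), n)]
            derived = list(codons)
            for idx in rng.choice(n, size=8, replace=False):
                for _attempt in range(50):
                    alt = SENSE_CODONS[int(rng.integers(0, len(SENSE_CODONS)))]
                    if pathway_stop_free(codons[int(idx)], alt):
                        derived[int(idx)] = alt
                        break
            sa, sb = "".join(codons), "".join(derived)
            ours = ng86_kaks(CodonAlignment("a", "b", sa, sb))
            dn, ds = cal_dn_ds(CodonSeq(sa), CodonSeq(sb), method="NG86")
            assert ours.Ka == pytest.approx(dn, abs=1e-9)
            assert ours.Ks == pytest.approx(ds, abs=1e-9)

    def test_internal_stop_rejected(self):
        with pytest.raises(ValueError, match="stop"):
            ng86_kaks(CodonAlignment("a", "b", "ATGTAA", "ATGTAA"))

    def test_gap_columns_dropped_codonwise(self):
        aln = CodonAlignment.from_aligned(
            "a", "b", "ATGGGGGGG---AAA", "ATGGGGGGGCCCAAG"
        )
        assert aln.n_codons == 4
        r = ng86_kaks(aln)
        assert r.Sd == 1.0 and r.Nd == 0.0


@given(st.integers(0, 2**31 - 1))
@settings(max_examples=25, deadline=None, derandomize=True)
def test_ng86_symmetry_property(seed):
    """Swapping the sequences leaves every NG86 field unchanged."""
    r = np.random.default_rng(seed)
    n = 12
    codons = [SENSE_CODONS[i] for i in r.integers(0, len(SENSE_CODONS), n)]
    other = list(codons)
    for idx in r.choice(n, size=2, replace=False):
        other[idx] = SENSE_CODONS[int(r.integers(0, len(SENSE_CODONS)))]
    sa, sb = "".join(codons), "".join(other)
    r1 = ng86_kaks(CodonAlignment("a", "b", sa, sb))
    r2 = ng86_kaks(CodonAlignment("b", "a", sb, sa))
    assert (r1.Sd, r1.Nd, r1.Ks, r1.Ka) == (r2.Sd, r2.Nd, r2.Ks, r2.Ka)
    assert r1.S_sites + r1.N_sites == pytest.approx(3 * n)


# ---------------------------------------------------------------------------
# Zero-Ks counting and the closeness test
# ---------------------------------------------------------------------------

def _chain(ks_map):
    genes = {g: f"{g}_gene" for pair in ks_map for g in pair}
    return QuadChain(genes, {frozenset(k): v for k, v in ks_map.items()})


class TestZeroKsCounts:
    def test_counts_exact_zeros_only(self):
        chains = [
            _chain({("A", "B"): 0.0}),
            _chain({("A", "B"): 0.0}),
            _chain({("A", "B"): 0.01}),
        ]
        out = zero_ks_counts(chains, [("A", "B")])
        assert out.loc[0, "n_zero_ks"] == 2

    def test_missing_counted_separately(self):
        chains = [_chain({("A", "B"): None}) for _ in range(4)]
        out = zero_ks_counts(chains, [("A", "B")])
        assert out.loc[0, "n_zero_ks"] == 0 and out.loc[0, "n_missing"] == 4

    def test_unknown_genome_is_error(self):
        with pytest.raises(ValueError, match="absent"):
            zero_ks_counts([_chain({("A", "B"): 0.0})], [("A", "Z")])

    def test_invariant_under_chain_permutation(self, rng):
        chains = [
            _chain({("A", "B"): float(v)}) for v in rng.choice([0.0, 0.01], size=50)
        ]
        out1 = zero_ks_counts(chains, [("A", "B")])
        perm = [chains[i] for i in rng.permutation(len(chains))]
        out2 = zero_ks_counts(perm, [("A", "B")])
        assert out1.equals(out2)

    def test_binomial_recovery_on_seeded_simulation(self, rng):
        p_zero, n = 0.6, 500
        zeros = rng.random(n) < p_zero
        chains = [_chain({("A", "B"): 0.0 if z else 0.02}) for z in zeros]
        out = zero_ks_counts(chains, [("A", "B")])
        se = math.sqrt(n * p_zero * (1 - p_zero))
        assert abs(out.loc[0, "n_zero_ks"] - n * p_zero) < 4 * se


class TestClosenessTest:
    def test_worked_discordant_counts(self):
        """n10 = 30, n01 = 10: two-sided exact binomial ~ 0.0022, matching
        an explicit comb-sum oracle."""
        chains = (
            [_chain({("F", "A"): 0.0, ("F", "B"): 0.5}) for _ in range(30)]
            + [_chain({("F", "A"): 0.5, ("F", "B"): 0.0}) for _ in range(10)]
        )
        rep = closeness_test(chains, "F", "A", "B")
        assert (rep.n10, rep.n01) == (30, 10)
        oracle = 2 * sum(math.comb(40, k) for k in range(11)) / 2**40
        assert rep.p_value == pytest.approx(oracle)
        assert rep.p_value == pytest.approx(0.0022, abs=3e-4)
        assert rep.direction == "A"

    def test_balanced_discordance_p_is_one(self):
        chains = (
            [_chain({("F", "A"): 0.0, ("F", "B"): 0.5}) for _ in range(5)]
            + [_chain({("F", "A"): 0.5, ("F", "B"): 0.0}) for _ in range(5)]
        )
        rep = closeness_test(chains, "F", "A", "B")
        assert rep.p_value == 1.0 and rep.direction == "tie"

    def test_no_discordance(self):
        chains = [_chain({("F", "A"): 0.0, ("F", "B"): 0.0}) for _ in range(5)]
        rep = closeness_test(chains, "F", "A", "B")
        assert rep.direction == "no discordance" and rep.p_value == 1.0

    def test_two_sided_doubling_capped_at_one(self):
        assert exact_binomial_two_sided(5, 10) <= 1.0
        assert exact_binomial_two_sided(0, 0) == 1.0


# ---------------------------------------------------------------------------
# Ks peak and dating
# ---------------------------------------------------------------------------

class TestKsPeak:
    def test_degenerate_distribution(self):
        assert ks_peak([0.0035] * 40) == 0.0035

    def test_seeded_normal_sample_recovers_mode(self, rng):
        vals = np.abs(rng.normal(0.0035, 0.0005, size=1_000))
        assert ks_peak(vals) == pytest.approx(0.0035, abs=0.0003)

    def test_bimodal_picks_heavier_mode(self, rng):
        vals = np.concatenate([
            np.abs(rng.normal(0.003, 0.0004, size=800)),
            np.abs(rng.normal(0.03, 0.004, size=200)),
        ])
        assert ks_peak(vals) == pytest.approx(0.003, abs=0.001)

    def test_too_few_values_is_error(self):
        with pytest.raises(ValueError, match="at least"):
            ks_peak([0.001] * 10)


class TestDating:
    @pytest.mark.parametrize(
        "ks,expected_ma", [(0.0035, 0.27), (0.0031, 0.24), (0.0, 0.0)]
    )
    def test_published_rate_and_peaks(self, ks, expected_ma):
        res = divergence_time(ks, 6.5e-9)
        assert res.time_years == pytest.approx(ks / (2 * 6.5e-9))
        assert round(res.time_ma, 2) == expected_ma

    def test_invalid_rate(self):
        with pytest.raises(ValueError):
            divergence_time(0.01, 0.0)

    def test_saturated_pairs_flagged_in_table(self):
        # maximally diverged synonymous third positions: force saturation
        sat = CodonAlignment("a", "b", "GGT" * 40, "GGC" * 40)
        tab = kaks_table([sat])
        # pS = 40 / S with S ~ 40 -> saturated
        assert bool(tab.loc[0, "saturated"]) is True
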