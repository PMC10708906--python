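"""Codon-level Ka/Ks, zero-Ks closeness testing, and Ks-peak dating.

The substitution-rate estimator is the Nei–Gojobori (1986) counting
method: per-codon synonymous site fractions averaged over the two
sequences, pathway-averaged difference counts for codons differing at
more than one position (all minimal pathways weighted equally; steps
through or into stop codons count as nonsynonymous), and a
Jukes–Cantor multiple-hit correction applied separately to the
synonymous and nonsynonymous proportions. In the near-zero Ks regime
this counting estimator and codon-model estimators agree closely, and
the "Ks = 0" class (no synonymous differences at all) is
estimator-independent.

Divergence dating uses T = Ks_peak / (2 r) with the Ks distribution
peak located by Gaussian kernel density estimation.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from functools import lru_cache
from itertools import permutations
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger("allohex.kaks")

BASES = "ACGT"

_STANDARD_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}

STOP_CODONS = {c for c, aa in _STANDARD_TABLE.items() if aa == "*"}


class SaturationError(ValueError):
    """Raised when a substitution proportion reaches the Jukes–Cantor limit."""


@dataclass
class CodonAlignment:
    """A gap-free aligned CDS pair (columns with gaps/N removed codon-wise)."""

    gene_a: str
    gene_b: str
    seq_a: str
    seq_b: str

    def __post_init__(self) -> None:
        if len(self.seq_a) != len(self.seq_b):
            raise ValueError("aligned sequences must have equal length")
        if len(self.seq_a) % 3 != 0:
            raise ValueError("aligned length must be divisible by 3")

    @classmethod
    def from_aligned(cls, gene_a: str, gene_b: str, seq_a: str, seq_b: str) -> "CodonAlignment":
        """Build from aligned CDS, removing codon columns with gaps or N."""
        sa, sb = seq_a.upper(), seq_b.upper()
        if len(sa) != len(sb) or len(sa) % 3 != 0:
            raise ValueError("aligned CDS must be equal length and a codon multiple")
        keep_a, keep_b = [], []
        n_dropped = 0
        for i in range(0, len(sa), 3):
            ca, cb = sa[i : i + 3], sb[i : i + 3]
            if set(ca + cb) <= set(BASES):
                keep_a.append(ca)
                keep_b.append(cb)
            else:
                n_dropped += 1
        if n_dropped:
            log.info(
                "%s/%s: dropped %d codon columns containing gaps or ambiguity",
                gene_a, gene_b, n_dropped,
            )
        return cls(gene_a, gene_b, "".join(keep_a), "".join(keep_b))

    @property
    def n_codons(self) -> int:
        return len(self.seq_a) // 3

    def codons(self) -> Iterable[tuple[str, str]]:
        for i in range(0, len(self.seq_a), 3):
            yield self.seq_a[i : i + 3], self.seq_b[i : i + 3]


@dataclass
class KaKsResult:
    gene_a: str
    gene_b: str
    S_sites: float
    N_sites: float
    Sd: float
    Nd: float
    Ka: float
    Ks: float

    @property
    def omega(self) -> float:
        """Ka/Ks; NaN when Ks = 0."""
        return self.Ka / self.Ks if self.Ks > 0 else float("nan")


@lru_cache(maxsize=None)
def synonymous_site_fraction(codon: str) -> float:
    """Number of synonymous sites in a codon (0..3).

    Each position contributes the fraction of its three possible
    single-nucleotide changes that preserve the amino acid; changes into
    stop codons count as nonsynonymous.
    """
    if codon in STOP_CODONS:
        raise ValueError(f"stop codon {codon} has no site decomposition")
    aa = _STANDARD_TABLE[codon]
    s = 0.0
    for pos in range(3):
        for base in BASES:
            if base == codon[pos]:
                continue
            mutant = codon[:pos] + base + codon[pos + 1 :]
            if mutant not in STOP_CODONS and _STANDARD_TABLE[mutant] == aa:
                s += 1.0 / 3.0
    return s


def _step_is_synonymous(c1: str, c2: str) -> bool:
    if c1 in STOP_CODONS or c2 in STOP_CODONS:
        return False
    return _STANDARD_TABLE[c1] == _STANDARD_TABLE[c2]


@lru_cache(maxsize=None)
def codon_pair_differences(codon_a: str, codon_b: str) -> tuple[float, float]:
    """(Sd, Nd) for one codon pair, averaged over all minimal pathways.

    Pathways change one differing position at a time; each of the k!
    orderings gets equal weight. A step whose source or destination is a
    stop codon, or that changes the amino acid, is nonsynonymous.
    """
    diff_pos = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diff_pos:
        return 0.0, 0.0
    sd_total = nd_total = 0.0
    paths = list(permutations(diff_pos))
    for order in paths:
        cur = codon_a
        for pos in order:
            nxt = cur[:pos] + codon_b[pos] + cur[pos + 1 :]
            if _step_is_synonymous(cur, nxt):
                sd_total += 1.0
            else:
                nd_total += 1.0
            cur = nxt
    k = len(paths)
    return sd_total / k, nd_total / k


def jukes_cantor(p: float) -> float:
    """JC69 distance d = -(3/4) ln(1 - (4/3) p); requires p < 3/4."""
    if p < 0:
        raise ValueError("proportion must be non-negative")
    if p >= 0.75:
        raise SaturationError(f"proportion {p:.4f} at or beyond the JC limit 3/4")
    if p == 0:
        return 0.0
    return -0.75 * math.log(1.0 - (4.0 / 3.0) * p)


def ng86_kaks(aln: CodonAlignment) -> KaKsResult:
    """Nei–Gojobori (1986) Ka/Ks for one gap-free codon alignment.

    Symmetric in the two sequences. Raises SaturationError when either
    substitution proportion reaches 3/4 (such pairs are excluded from
    dating).
    """
    if aln.n_codons == 0:
        raise ValueError("empty alignment")
    s_a = s_b = 0.0
    sd = nd = 0.0
    for ca, cb in aln.codons():
        if ca in STOP_CODONS or cb in STOP_CODONS:
            raise ValueError(
                f"internal stop codon in {aln.gene_a}/{aln.gene_b}: {ca}/{cb}"
            )
        s_a += synonymous_site_fraction(ca)
        s_b += synonymous_site_fraction(cb)
        d_s, d_n = codon_pair_differences(ca, cb)
        sd += d_s
        nd += d_n
    n_sites_total = 3.0 * aln.n_codons
    S = (s_a + s_b) / 2.0
    N = n_sites_total - S
    ps = sd / S if S > 0 else 0.0
    pn = nd / N if N > 0 else 0.0
    ks = jukes_cantor(ps)
    ka = jukes_cantor(pn)
    return KaKsResult(aln.gene_a, aln.gene_b, S, N, sd, nd, ka, ks)


# ---------------------------------------------------------------------------
# Zero-Ks closeness testing over quadruple gene chains
# ---------------------------------------------------------------------------

@dataclass
class QuadChain:
    """One ortho-homeologous gene chain: one gene per genome.

    ``ks`` maps an unordered genome pair (frozenset) to the pair's Ks, or
    None when the comparison is missing for this chain.
    """

    genes: dict[str, str]  # genome -> gene id
    ks: dict[frozenset, float | None]

    def ks_for(self, genome_a: str, genome_b: str) -> float | None:
        return self.ks.get(frozenset((genome_a, genome_b)))


def zero_ks_counts(
    chains: Sequence[QuadChain], comparisons: Sequence[tuple[str, str]]
) -> pd.DataFrame:
    """Count, per genome pair, the chains with no synonymous substitutions.

    "Zero Ks" means an exact zero (Sd = 0), not a small value. Chains
    whose comparison is missing are excluded from the zero count and
    tallied separately.
    """
    genomes_present: set[str] = set()
    for c in chains:
        genomes_present.update(c.genes)
    rows = []
    for a, b in comparisons:
        for g in (a, b):
            if g not in genomes_present:
                raise ValueError(f"genome {g!r} absent from chains")
        n_zero = n_missing = 0
        for c in chains:
            v = c.ks_for(a, b)
            if v is None:
                n_missing += 1
            elif v == 0.0:
                n_zero += 1
        rows.append(
            {
                "genome_a": a,
                "genome_b": b,
                "n_zero_ks": n_zero,
                "n_missing": n_missing,
                "n_chains": len(chains),
            }
        )
    return pd.DataFrame(rows)


def exact_binomial_two_sided(k_small: int, n: int) -> float:
    """Two-sided exact binomial p at p0 = 1/2: double the smaller tail, cap at 1."""
    if n == 0:
        return 1.0
    tail = stats.binom.cdf(k_small, n, 0.5)
    return float(min(1.0, 2.0 * tail))


@dataclass
class ClosenessReport:
    focal: str
    candidate_a: str
    candidate_b: str
    n10: int  # zero-Ks with a only
    n01: int  # zero-Ks with b only
    p_value: float
    direction: str  # which candidate the focal genome is closer to


def closeness_test(
    chains: Sequence[QuadChain], focal: str, candidate_a: str, candidate_b: str
) -> ClosenessReport:
    """Discordant-chain (McNemar-style) test of which candidate is closer.

    Chains zero-Ks with exactly one candidate are informative; under the
    null both directions are equally likely, so the discordant counts are
    compared with a two-sided exact binomial at p = 1/2.
    """
    n10 = n01 = 0
    for c in chains:
        ka = c.ks_for(focal, candidate_a)
        kb = c.ks_for(focal, candidate_b)
        if ka is None or kb is None:
            continue
        za, zb = ka == 0.0, kb == 0.0
        if za and not zb:
            n10 += 1
        elif zb and not za:
            n01 += 1
    n = n10 + n01
    if n == 0:
        return ClosenessReport(
            focal, candidate_a, candidate_b, 0, 0, 1.0, "no discordance"
        )
    p = exact_binomial_two_sided(min(n10, n01), n)
    if n10 > n01:
        direction = candidate_a
    elif n01 > n10:
        direction = candidate_b
    else:
        direction = "tie"
    return ClosenessReport(focal, candidate_a, candidate_b, n10, n01, p, direction)


# ---------------------------------------------------------------------------
# Ks-peak estimation and dating
# ---------------------------------------------------------------------------

def ks_peak(
    ks_values: Sequence[float],
    bandwidth_rule: str | float = "silverman",
    grid_points: int = 512,
    min_values: int = 30,
) -> float:
    """Mode of the non-zero Ks distribution by Gaussian KDE.

    The argmax is taken on a regular grid of ``grid_points`` spanning
    [0, max(ks) * 1.1]. Degenerate (all-equal) samples return that value
    exactly.
    """
    values = np.asarray(ks_values, dtype=float)
    if values.size < min_values:
        raise ValueError(
            f"need at least {min_values} non-zero Ks values, got {values.size}"
        )
    if np.ptp(values) == 0:
        return float(values[0])
    kde = stats.gaussian_kde(values, bw_method=bandwidth_rule)
    grid = np.linspace(0.0, values.max() * 1.1, max(grid_points, 512))
    density = kde(grid)
    peak = float(grid[int(np.argmax(density))])
    log.info("ks_peak: %d values, peak %.5f", values.size, peak)
    return peak


@dataclass
class DatingResult:
    ks_peak: float
    rate: float
    time_years: float

    @property
    def time_ma(self) -> float:
        return self.time_years / 1e6

    def summary(self) -> str:
        return (
            f"Ks_peak = {self.ks_peak:.4f}, r = {self.rate:.3g}/site/year -> "
            f"T = {self.time_years:,.0f} years ({self.time_ma:.2f} Ma)"
        )


def divergence_time(ks_peak_value: float, rate: float = 6.5e-9) -> DatingResult:
    """Date a split with T = Ks / (2 r)."""
    if rate <= 0:
        raise ValueError("rate must be positive")
    if ks_peak_value < 0:
        raise ValueError("Ks peak must be non-negative")
    t = ks_peak_value / (2.0 * rate)
    return DatingResult(ks_peak_value, rate, t)


def kaks_table(alignments: Sequence[CodonAlignment]) -> pd.DataFrame:
    """Ka/Ks for a list of alignments as a tidy table; saturated pairs flagged."""
    rows = []
    for aln in alignments:
        try:
            r = ng86_kaks(aln)
            rows.append(
                {
                    "gene_a": r.gene_a, "gene_b": r.gene_b,
                    "S_sites": r.S_sites, "N_sites": r.N_sites,
                    "Sd": r.Sd, "Nd": r.Nd, "Ka": r.Ka, "Ks": r.Ks,
                    "saturated": False,
                }
            )
        except SaturationError:
            rows.append(
                {
                    "gene_a": aln.gene_a, "gene_b": aln.gene_b,
                    "S_sites": np.nan, "N_sites": np.nan,
                    "Sd": np.nan, "Nd": np.nan, "Ka": np.nan, "Ks": np.nan,
                    "saturated": True,
                }
            )
    return pd.DataFrame(rows)
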