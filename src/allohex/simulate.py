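"""Synthetic data generator with a ground-truth ledger.

Every input the pipeline consumes can be generated here from a seeded
configuration: two diverged progenitor genomes and their exact anchor
map, an allotetraploid assembly with planted homeologous-exchange
events, per-window depth profiles whose mean scales with copy number
and decays with read-to-reference divergence, codon-aligned gene pairs
with controlled synonymous divergence, and replicated TPM matrices with
planted subgenome bias, condition effects and a planted negative
TE-density/expression correlation.

Truth is recorded before any noise is applied and never mutated
afterwards; with noise disabled every downstream detector recovers the
planted truth exactly.

Conventions: progenitor chromosomes are named ``D1..Dn`` and ``S1..Sn``;
homeologous chromosomes share an index and (being simulated without
indels) share coordinates. The allotetraploid subgenome chromosomes are
``BhD1..`` and ``BhS1..``. The depth model for a window of local
copy number c against a reference with local per-site divergence d is

    E[depth] = coverage * (c / 2) * exp(-k * d)

with ``k`` a mismapping coefficient (default 20, so d = 0.05 pushes a
normal window to ~0.37x, below the 0.5x deletion threshold). This is a
deliberately minimal one-parameter monotone model of the
reference-mismatch artifact.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .intervals import Anchor, GenomicInterval
from .io import ExpressionMatrix, SampleMeta, WindowDepthRecord
from .kaks import (
    BASES,
    STOP_CODONS,
    _STANDARD_TABLE,
    CodonAlignment,
    synonymous_site_fraction,
)

log = logging.getLogger("allohex.simulate")

# Fixed stage tags keep each simulate_* stream independent of call order.
_STAGE_GENOME = 11
_STAGE_DEPTH = 12
_STAGE_CODON = 13
_STAGE_EXPR = 14
_STAGE_REF = 15


@dataclass(frozen=True)
class HEEvent:
    """A planted homeologous-exchange event.

    ``replacement``: the lost subgenome's segment is overwritten by a
    copy of its homeolog (donor copy number 4, lost segment 0).
    ``reciprocal``: the homeologous segments are exchanged (copy numbers
    unchanged, so depth stays flat).
    """

    kind: str  # "replacement" | "reciprocal"
    lost_subgenome: str  # "D" | "S"
    chrom_index: int  # 1-based homeologous chromosome index
    start: int
    span: int

    def __post_init__(self) -> None:
        if self.kind not in {"replacement", "reciprocal"}:
            raise ValueError(f"unknown HE kind {self.kind!r}")
        if self.lost_subgenome not in {"D", "S"}:
            raise ValueError("lost_subgenome must be 'D' or 'S'")
        if self.start < 0 or self.span <= 0:
            raise ValueError("event start/span must be non-negative/positive")

    @property
    def lost_chrom(self) -> str:
        return f"{self.lost_subgenome}{self.chrom_index}"

    @property
    def donor_chrom(self) -> str:
        other = "S" if self.lost_subgenome == "D" else "D"
        return f"{other}{self.chrom_index}"

    @property
    def end(self) -> int:
        return self.start + self.span


@dataclass
class SimConfig:
    """Seeded configuration for the whole synthetic study.

    Defaults emulate the study's conditions: 10 kb depth windows at ~30x
    coverage, a handful of >= 60 kb replacement events, three biological
    replicates over leaf/root tissue under well-watered/drought
    conditions, a near-zero synonymous divergence between subgenome and
    progenitor, and a weak negative TE-density/expression correlation.
    """

    seed: int
    n_chromosomes: int = 2
    chrom_length: int = 2_000_000
    window_size: int = 10_000
    progenitor_divergence: float = 0.10
    he_events: list[HEEvent] = field(default_factory=list)
    coverage: float = 30.0
    depth_noise: str = "none"  # none | poisson | negbin
    negbin_theta: float = 10.0
    read_length: int = 150
    mismap_k: float = 20.0
    n_divergent_patches: int = 10
    patch_span: int = 100_000
    ks_targets: list[float] = field(default_factory=lambda: [0.0035])
    ks_n_pairs: int = 1_000
    ks_n_codons: int = 2_000
    n_gene_pairs: int = 2_000
    bias_fraction: float = 0.1
    bias_fold: float = 4.0
    flip_fraction: float = 0.05
    expression_sigma: float = 0.2
    n_replicates: int = 3
    tissues: tuple[str, ...] = ("leaf", "root")
    conditions: tuple[str, ...] = ("well-watered", "drought")
    induced_fraction: float = 0.05
    induction_fold: float = 4.0
    te_effect: float = 0.1
    te_expression_rho: float = -0.3
    epsilon: float = 0.1

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if not (0 <= self.progenitor_divergence < 0.75):
            raise ValueError("progenitor divergence must lie in [0, 0.75) (saturation)")
        if self.chrom_length % self.window_size != 0:
            raise ValueError("chrom_length must be a multiple of window_size")
        for ev in self.he_events:
            if ev.start % self.window_size or ev.span % self.window_size:
                raise ValueError(
                    "HE event coordinates must be multiples of the window size"
                )
            if ev.end > self.chrom_length:
                raise ValueError("HE event extends past the chromosome")
            if ev.chrom_index > self.n_chromosomes:
                raise ValueError("HE event chromosome index out of range")
        for frac in (self.bias_fraction, self.flip_fraction, self.induced_fraction):
            if not (0 <= frac <= 1):
                raise ValueError("fractions must lie in [0, 1]")
        if self.depth_noise not in {"none", "poisson", "negbin"}:
            raise ValueError("depth_noise must be none, poisson or negbin")
        _check_events_disjoint(self.he_events)

    def rng(self, stage: int) -> np.random.Generator:
        return np.random.default_rng([self.seed, stage])


def _check_events_disjoint(events: Sequence[HEEvent]) -> None:
    # Replacement events occupy both homeologous chromosomes; treat each
    # event as claiming [start, end) on its chromosome *index*.
    by_index: dict[int, list[tuple[int, int]]] = {}
    for ev in events:
        by_index.setdefault(ev.chrom_index, []).append((ev.start, ev.end))
    for idx, spans in by_index.items():
        spans.sort()
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            if s2 < e1:
                raise ValueError(
                    f"overlapping HE events on homeologous chromosome {idx}"
                )


# ---------------------------------------------------------------------------
# Truth ledger
# ---------------------------------------------------------------------------

@dataclass
class SimTruth:
    """Ground truth, written before noise and never mutated afterwards."""

    he_events: list[dict] = field(default_factory=list)
    reference_divergence: dict = field(default_factory=dict)
    pair_truth: list[dict] = field(default_factory=list)
    ks_truth: list[dict] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "SimTruth":
        return cls(**json.loads(Path(path).read_text()))


# ---------------------------------------------------------------------------
# Progenitor genomes
# ---------------------------------------------------------------------------

@dataclass
class Progenitors:
    sequences_d: dict[str, str]
    sequences_s: dict[str, str]
    anchors: list[Anchor]  # query: D chromosomes, target: S chromosomes
    genes: dict[str, list[GenomicInterval]]  # subgenome -> gene models


_BASE_ARR = np.frombuffer(b"ACGT", dtype="S1")


def _random_sequence(rng: np.random.Generator, length: int) -> np.ndarray:
    return _BASE_ARR[rng.integers(0, 4, size=length)]


def _mutate(rng: np.random.Generator, seq: np.ndarray, rate: float) -> np.ndarray:
    """Substitute each site independently with probability ``rate``."""
    out = seq.copy()
    n_mut = rng.binomial(len(seq), rate)
    if n_mut == 0:
        return out
    sites = rng.choice(len(seq), size=n_mut, replace=False)
    # new base drawn from the three alternatives
    shift = rng.integers(1, 4, size=n_mut)
    idx = np.searchsorted(_BASE_ARR, out[sites])  # ACGT sorted already
    out[sites] = _BASE_ARR[(idx + shift) % 4]
    return out


def simulate_progenitors(config: SimConfig) -> Progenitors:
    """Two progenitor genomes descended from a common ancestor.

    Each lineage is mutated at half the configured divergence under a
    uniform substitution model, so homologous sites differ at close to
    ``progenitor_divergence``. Anchors are exact (the simulation knows
    true homology) and tiled with sub-20 kb gaps so chaining yields one
    collinearity block per homeologous chromosome pair. Gene models sit
    on a regular grid.
    """
    rng = config.rng(_STAGE_GENOME)
    d_half = config.progenitor_divergence / 2.0
    seqs_d: dict[str, str] = {}
    seqs_s: dict[str, str] = {}
    anchors: list[Anchor] = []
    genes: dict[str, list[GenomicInterval]] = {"D": [], "S": []}
    anchor_len, anchor_step = 90_000, 100_000
    gene_len, gene_step = 2_000, 20_000
    for i in range(1, config.n_chromosomes + 1):
        ancestor = _random_sequence(rng, config.chrom_length)
        d_seq = _mutate(rng, ancestor, d_half)
        s_seq = _mutate(rng, ancestor, d_half)
        seqs_d[f"D{i}"] = d_seq.tobytes().decode()
        seqs_s[f"S{i}"] = s_seq.tobytes().decode()
        identity = 1.0 - config.progenitor_divergence
        pos = 0
        while pos < config.chrom_length:
            end = min(pos + anchor_len, config.chrom_length)
            anchors.append(
                Anchor(
                    GenomicInterval(f"D{i}", pos, end),
                    GenomicInterval(f"S{i}", pos, end),
                    orientation="same",
                    identity=max(0.0, identity),
                )
            )
            pos += anchor_step
        for sub in ("D", "S"):
            for g0 in range(0, config.chrom_length - gene_len, gene_step):
                genes[sub].append(GenomicInterval(f"{sub}{i}", g0, g0 + gene_len))
    log.info(
        "simulate_progenitors: %d chromosomes x %d bp, divergence %.3f, %d anchors",
        config.n_chromosomes, config.chrom_length, config.progenitor_divergence,
        len(anchors),
    )
    return Progenitors(seqs_d, seqs_s, anchors, genes)


# ---------------------------------------------------------------------------
# Allotetraploid assembly with planted HE events
# ---------------------------------------------------------------------------

@dataclass
class Allotetraploid:
    sequences: dict[str, str]  # BhD*/BhS* chromosomes
    assembly_anchors: list[Anchor]  # allotetraploid vs concatenated progenitors
    query_subgenome: dict[str, str]  # BhD1 -> "D", ...
    target_genome: dict[str, str]  # D1 -> "D", S1 -> "S", ...
    truth: SimTruth


def simulate_allotetraploid(
    progenitors: Progenitors, config: SimConfig, truth: SimTruth | None = None
) -> Allotetraploid:
    """Concatenate the progenitors into an allotetraploid and plant HE events.

    Replacement events overwrite the lost subgenome's segment with the
    homeologous copy; reciprocal events exchange the two segments.
    Assembly anchors record, per <= 50 kb tile, which progenitor each
    stretch of the assembly truly derives from; the truth ledger records
    exact breakpoints.
    """
    truth = truth or SimTruth()
    # origin[chrom] = list of (start, end, source_genome) segments
    origin: dict[str, list[tuple[int, int, str]]] = {}
    seqs: dict[str, str] = {}
    for name, seq in progenitors.sequences_d.items():
        seqs["Bh" + name] = seq
        origin["Bh" + name] = [(0, len(seq), "D")]
    for name, seq in progenitors.sequences_s.items():
        seqs["Bh" + name] = seq
        origin["Bh" + name] = [(0, len(seq), "S")]

    def splice(chrom: str, start: int, end: int, segment: str, source: str) -> None:
        seqs[chrom] = seqs[chrom][:start] + segment + seqs[chrom][end:]
        new = []
        for s, e, src in origin[chrom]:
            if e <= start or s >= end:
                new.append((s, e, src))
                continue
            if s < start:
                new.append((s, start, src))
            if e > end:
                new.append((end, e, src))
        new.append((start, end, source))
        new.sort()
        origin[chrom] = new

    for ev in config.he_events:
        lost = "Bh" + ev.lost_chrom
        donor = "Bh" + ev.donor_chrom
        donor_genome = "S" if ev.lost_subgenome == "D" else "D"
        donor_seg = seqs[donor][ev.start : ev.end]
        if ev.kind == "replacement":
            splice(lost, ev.start, ev.end, donor_seg, donor_genome)
        else:  # reciprocal: exchange the two homeologous segments
            lost_seg = seqs[lost][ev.start : ev.end]
            splice(lost, ev.start, ev.end, donor_seg, donor_genome)
            splice(donor, ev.start, ev.end, lost_seg, ev.lost_subgenome)
        truth.he_events.append(
            {
                "kind": ev.kind,
                "lost_subgenome": ev.lost_subgenome,
                "lost_chrom": ev.lost_chrom,
                "donor_chrom": ev.donor_chrom,
                "start": ev.start,
                "end": ev.end,
                "span": ev.span,
            }
        )

    # Assembly anchors: per constant-origin segment, tiled to <= 50 kb.
    anchors: list[Anchor] = []
    tile = 50_000
    for chrom, segments in origin.items():
        idx = chrom[3:]  # chromosome index string
        for s, e, src in segments:
            pos = s
            while pos < e:
                end = min(pos + tile, e)
                anchors.append(
                    Anchor(
                        GenomicInterval(chrom, pos, end),
                        GenomicInterval(f"{src}{idx}", pos, end),
                        orientation="same",
                        identity=1.0,
                    )
                )
                pos = end
    query_subgenome = {c: ("D" if c.startswith("BhD") else "S") for c in seqs}
    target_genome = {}
    for name in progenitors.sequences_d:
        target_genome[name] = "D"
    for name in progenitors.sequences_s:
        target_genome[name] = "S"
    log.info(
        "simulate_allotetraploid: %d planted events, %d assembly anchors",
        len(config.he_events), len(anchors),
    )
    return Allotetraploid(seqs, anchors, query_subgenome, target_genome, truth)


# ---------------------------------------------------------------------------
# Depth profiles
# ---------------------------------------------------------------------------

@dataclass
class ReferenceModel:
    """A candidate concatenated progenitor reference for read mapping.

    ``divergence_patches`` are window-aligned regions where reads
    diverge from the reference by ``d`` substitutions/site (0 elsewhere
    plus ``baseline``); mismapping depresses expected depth by
    exp(-k d).
    """

    label: str
    baseline_divergence: float = 0.0
    divergence_patches: list[tuple[str, int, int, float]] = field(default_factory=list)

    def local_divergence(self, chrom: str, start: int, end: int) -> float:
        d = self.baseline_divergence
        for pchrom, ps, pe, pd_ in self.divergence_patches:
            if pchrom == chrom and start < pe and ps < end:
                d = max(d, pd_)
        return d


def matched_reference(label: str = "ref_matched") -> ReferenceModel:
    return ReferenceModel(label=label)


def diverged_reference(
    config: SimConfig, d: float, label: str | None = None
) -> ReferenceModel:
    """A reference with ``n_divergent_patches`` window-aligned patches at divergence d."""
    if d == 0:
        return ReferenceModel(label=label or "ref_d0")
    rng = config.rng(_STAGE_REF)
    windows_per_chrom = config.chrom_length // config.window_size
    patch_windows = max(1, config.patch_span // config.window_size)
    chroms = [
        f"{sub}{i}" for sub in ("D", "S") for i in range(1, config.n_chromosomes + 1)
    ]
    patches = []
    for _ in range(config.n_divergent_patches):
        chrom = chroms[int(rng.integers(0, len(chroms)))]
        w0 = int(rng.integers(0, max(1, windows_per_chrom - patch_windows)))
        start = w0 * config.window_size
        end = start + patch_windows * config.window_size
        patches.append((chrom, start, end, d))
    return ReferenceModel(label=label or f"ref_d{d:g}", divergence_patches=patches)


def copy_number(config: SimConfig, chrom: str, start: int, end: int) -> int:
    """Haploid-equivalent copy number of a progenitor-reference window.

    Normal windows carry 2 copies; a replacement event zeroes the lost
    homeolog and doubles the donor to 4. Reciprocal events leave copy
    number unchanged.
    """
    for ev in config.he_events:
        if ev.kind != "replacement":
            continue
        if not (start < ev.end and ev.start < end):
            continue
        if chrom == ev.lost_chrom:
            return 0
        if chrom == ev.donor_chrom:
            return 4
    return 2


def simulate_depth(
    config: SimConfig,
    reference: ReferenceModel,
    sample_id: str = "sim1",
    replicate_seed: int | None = None,
) -> list[WindowDepthRecord]:
    """Per-window mean depth of one sample against one candidate reference.

    Expected depth is coverage * (copy/2) * exp(-k d); noise (if any) is
    applied at the read level: the window's read count is Poisson (or
    gamma-Poisson for ``negbin``) around the expectation.
    ``replicate_seed`` separates the noise streams of replicate samples.
    """
    if config.coverage <= 0:
        raise ValueError("coverage must be positive")
    rng = np.random.default_rng(
        [config.seed, _STAGE_DEPTH, 0 if replicate_seed is None else replicate_seed]
    )
    reads_per_window = config.window_size / config.read_length
    records: list[WindowDepthRecord] = []
    chroms = [
        f"{sub}{i}" for sub in ("D", "S") for i in range(1, config.n_chromosomes + 1)
    ]
    for chrom in chroms:
        for start in range(0, config.chrom_length, config.window_size):
            end = start + config.window_size
            c = copy_number(config, chrom, start, end)
            d = reference.local_divergence(chrom, start, end)
            expected = config.coverage * (c / 2.0) * np.exp(-config.mismap_k * d)
            if config.depth_noise == "none":
                depth = expected
            else:
                lam = expected * reads_per_window
                if config.depth_noise == "negbin" and lam > 0:
                    lam = rng.gamma(config.negbin_theta, lam / config.negbin_theta)
                n_reads = rng.poisson(lam) if lam > 0 else 0
                depth = n_reads / reads_per_window
            records.append(
                WindowDepthRecord(GenomicInterval(chrom, start, end), sample_id, float(depth))
            )
    return records


# ---------------------------------------------------------------------------
# Codon pairs with controlled Ks
# ---------------------------------------------------------------------------

_SENSE_CODONS = sorted(c for c in _STANDARD_TABLE if c not in STOP_CODONS)


from functools import lru_cache


@lru_cache(maxsize=None)
def _synonymous_options(codon: str) -> tuple[tuple[int, str], ...]:
    """All (position, alternative base) synonymous single-nt changes."""
    aa = _STANDARD_TABLE[codon]
    opts = []
    for pos in range(3):
        for base in BASES:
            if base == codon[pos]:
                continue
            mutant = codon[:pos] + base + codon[pos + 1 :]
            if mutant not in STOP_CODONS and _STANDARD_TABLE[mutant] == aa:
                opts.append((pos, base))
    return tuple(opts)


def simulate_codon_pair(
    rng: np.random.Generator, n_codons: int, ks_target: float, pair_id: int = 0
) -> CodonAlignment:
    """One aligned CDS pair whose synonymous divergence centres on ks_target.

    Substitution events are Poisson with mean ks_target * S_sites and
    each event applies one synonymous single-nucleotide change drawn
    uniformly from the current synonymous opportunities; nonsynonymous
    sites are untouched.
    """
    if ks_target < 0 or ks_target > 2.0:
        raise ValueError("ks_target must lie in [0, 2] (beyond is saturated)")
    codons = [
        _SENSE_CODONS[i] for i in rng.integers(0, len(_SENSE_CODONS), size=n_codons)
    ]
    s_sites = sum(synonymous_site_fraction(c) for c in codons)
    derived = list(codons)
    n_events = rng.poisson(ks_target * s_sites)
    # codon choice weighted by its current synonymous opportunities;
    # weights maintained incrementally as codons mutate
    weights = np.array([len(_synonymous_options(c)) for c in derived], dtype=float)
    for _ in range(n_events):
        total = weights.sum()
        if total == 0:
            break
        idx = int(rng.choice(len(derived), p=weights / total))
        opts = _synonymous_options(derived[idx])
        pos, base = opts[int(rng.integers(0, len(opts)))]
        c = derived[idx]
        derived[idx] = c[:pos] + base + c[pos + 1 :]
        weights[idx] = len(_synonymous_options(derived[idx]))
    return CodonAlignment(
        f"pair{pair_id}_a", f"pair{pair_id}_b", "".join(codons), "".join(derived)
    )


def simulate_codon_pairs(
    config: SimConfig, truth: SimTruth | None = None
) -> tuple[list[CodonAlignment], SimTruth]:
    """ks_n_pairs alignments per configured Ks target, with truth."""
    truth = truth or SimTruth()
    rng = config.rng(_STAGE_CODON)
    alignments: list[CodonAlignment] = []
    pair_id = 0
    for target in config.ks_targets:
        for _ in range(config.ks_n_pairs):
            aln = simulate_codon_pair(rng, config.ks_n_codons, target, pair_id)
            alignments.append(aln)
            truth.ks_truth.append(
                {"gene_a": aln.gene_a, "gene_b": aln.gene_b, "ks_true": target}
            )
            pair_id += 1
    log.info("simulate_codon_pairs: %d pairs, targets %s", len(alignments), config.ks_targets)
    return alignments, truth


# ---------------------------------------------------------------------------
# Expression matrices with planted bias
# ---------------------------------------------------------------------------

@dataclass
class ExpressionSim:
    pairs: pd.DataFrame  # bhd_gene, bhs_gene
    matrix: ExpressionMatrix
    te_density: dict[str, float]  # gene -> flanking TE density
    gene_intervals: dict[str, GenomicInterval]
    te_intervals: list[GenomicInterval]
    truth: SimTruth


def simulate_expression(
    config: SimConfig, truth: SimTruth | None = None
) -> ExpressionSim:
    """Replicated TPM matrices with planted bias, flips, induction and TE effects.

    Per gene, log TPM is Normal(mu_pair + bias + condition terms, sigma^2)
    with i.i.d. replicates. A ``bias_fraction`` of pairs receives
    +-log(bias_fold) on one homeolog; ``flip_fraction`` of those reverse
    direction under the stress condition; ``induced_fraction`` of pairs
    are induced ``induction_fold``-fold on both homeologs under stress.
    TE densities follow a Gaussian copula against realized mean log
    expression (planted correlation ``te_expression_rho``) plus a
    ``te_effect`` shift on submissive genes; genes sit on a 10 kb grid on
    one virtual chromosome per subgenome and the emitted TE intervals
    reproduce each gene's flanking density exactly.
    """
    truth = truth or SimTruth()
    rng = config.rng(_STAGE_EXPR)
    n = config.n_gene_pairs
    stress = config.conditions[1] if len(config.conditions) > 1 else None

    bhd_genes = [f"BhD_g{i:05d}" for i in range(n)]
    bhs_genes = [f"BhS_g{i:05d}" for i in range(n)]
    mu_pair = rng.normal(np.log(20.0), 1.0, size=n)
    biased = rng.random(n) < config.bias_fraction
    # +1 -> BhS dominant, -1 -> BhD dominant, 0 -> unbiased
    direction = np.where(biased, rng.choice([-1, 1], size=n), 0)
    flips = biased & (rng.random(n) < config.flip_fraction)
    induced = rng.random(n) < config.induced_fraction
    log_fold = np.log(config.bias_fold)
    log_induction = np.log(config.induction_fold)

    samples: list[SampleMeta] = []
    for tissue in config.tissues:
        for condition in config.conditions:
            for rep in range(1, config.n_replicates + 1):
                samples.append(
                    SampleMeta(f"{tissue}_{condition}_r{rep}", tissue, condition, rep)
                )

    values = np.empty((2 * n, len(samples)))
    gene_ids = bhd_genes + bhs_genes
    for j, sm in enumerate(samples):
        dir_here = np.where(
            flips & (sm.condition == stress), -direction, direction
        )
        cond_term = np.where(induced & (sm.condition == stress), log_induction, 0.0)
        noise_d = rng.normal(0.0, config.expression_sigma, size=n)
        noise_s = rng.normal(0.0, config.expression_sigma, size=n)
        log_bhd = mu_pair + np.where(dir_here < 0, log_fold, 0.0) + cond_term + noise_d
        log_bhs = mu_pair + np.where(dir_here > 0, log_fold, 0.0) + cond_term + noise_s
        values[:n, j] = np.exp(log_bhd)
        values[n:, j] = np.exp(log_bhs)

    matrix = ExpressionMatrix(
        pd.DataFrame(values, index=gene_ids, columns=[s.sample_id for s in samples]),
        samples,
    )

    # TE densities: Gaussian copula against realized mean log2(TPM + eps).
    mean_log = np.log2(values.mean(axis=1) + config.epsilon)
    x = (mean_log - mean_log.mean()) / mean_log.std()
    w = rng.normal(size=2 * n)
    rho = config.te_expression_rho
    z = rho * x + np.sqrt(max(0.0, 1.0 - rho**2)) * w
    from scipy.stats import norm

    density = norm.cdf(z)
    # Dom/Sub shift: submissive genes gain te_effect (clipped to [0, 1]).
    submissive_bhd = direction > 0  # BhS dominant -> BhD submissive
    submissive_bhs = direction < 0
    density[:n][submissive_bhd] = np.clip(density[:n][submissive_bhd] + config.te_effect, 0, 1)
    density[n:][submissive_bhs] = np.clip(density[n:][submissive_bhs] + config.te_effect, 0, 1)

    # Gene grid on one virtual chromosome per subgenome; TE intervals
    # reproduce each gene's flank-window density exactly (one TE run at
    # the window start).
    gene_len, gene_step, flank = 2_000, 10_000, 2_000
    gene_intervals: dict[str, GenomicInterval] = {}
    te_intervals: list[GenomicInterval] = []
    te_density: dict[str, float] = {}
    window_len = gene_len + 2 * flank
    for k, gid in enumerate(gene_ids):
        chrom = "BhD_genes" if k < n else "BhS_genes"
        g0 = flank + (k % n) * gene_step
        gene_intervals[gid] = GenomicInterval(chrom, g0, g0 + gene_len)
        te_len = int(round(density[k] * window_len))
        te_density[gid] = te_len / window_len
        if te_len > 0:
            te_intervals.append(GenomicInterval(chrom, g0 - flank, g0 - flank + te_len))

    dir_label = {1: "BhS", -1: "BhD", 0: "none"}
    for i in range(n):
        truth.pair_truth.append(
            {
                "bhd_gene": bhd_genes[i],
                "bhs_gene": bhs_genes[i],
                "bias_direction": dir_label[int(direction[i])],
                "flips_under_stress": bool(flips[i]),
                "induced_under_stress": bool(induced[i]),
                "mu_log_tpm": float(mu_pair[i]),
                "te_density_bhd": float(te_density[bhd_genes[i]]),
                "te_density_bhs": float(te_density[bhs_genes[i]]),
            }
        )
    pairs = pd.DataFrame({"bhd_gene": bhd_genes, "bhs_gene": bhs_genes})
    log.info(
        "simulate_expression: %d pairs, %d samples, %d biased (%d flip under stress)",
        n, len(samples), int(biased.sum()), int(flips.sum()),
    )
    return ExpressionSim(pairs, matrix, te_density, gene_intervals, te_intervals, truth)
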