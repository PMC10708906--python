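# Methods

This note records the models implemented in `allohex`, the parameter
choices that matter, and the deliberate simplifications of the
synthetic-data generator — so a reader can judge what the passing test
suite does and does not establish about real data.

## Coordinates and formats

All coordinates are 0-based half-open (BED convention) everywhere in
memory; 1-based external dialects would be converted at the I/O
boundary and nowhere else. Depth is consumed as precomputed per-window
mean-depth TSVs (`chrom, start, end, sample_id, mean_depth`); computing
depth from BAM is outside the tested surface, which keeps the pipeline
alignment-tool-agnostic. Configuration is a flat YAML/JSON mapping
validated against the `PipelineConfig` schema; unknown keys are errors
because a silently ignored typo in a depth threshold would invalidate
every homeologous-exchange (HE) call downstream. Every stage logs its
parameters and record counts at INFO.

## Synteny chaining and liftover

Anchors (local alignments between two genomes) are chained into
syntenic collinearity blocks: anchors sharing a chromosome pair and
orientation are linked when the gap between their hulls is `< link_gap`
(default 20,000 bp). Blocks are the **connected components** of this
pairwise relation — verified in tests against a brute-force transitive
closure — not merely consecutive joins. Two open choices:

- *Which side's gap counts?* The 20 kb rule does not name a genome;
  the default requires the gap on **both** query and target
  (`gap_sides: both`), the conservative reading that keeps blocks
  collinear; `query` is available in config.
- *Overlapping anchors* on the query (aligners emit these) are merged
  to their hulls with length-weighted identity before chaining, since
  chaining assumes a tiling.

Liftover interpolates linearly through anchor endpoints and across
inter-anchor gaps; at the ≥ 60 kb scale of HE calls sub-anchor
precision is immaterial. Portions of an interval outside any block are
dropped and reported; an interval covered by blocks on two chromosome
pairs is mapped through both and flagged ambiguous rather than
silently resolved.

## Depth-window HE calling

Per sample and chromosome, the mean depth of full (non-partial) 10 kb
windows defines the chromosome average; each window's ratio to that
average is classified:

- deletion (DEL): ratio in [0, 0.5] (closed);
- duplication (DUP): ratio in [1.5, 5.0] (closed);
- HIGH: ratio > 5 — repeat-like windows, never merged into HE blocks,
  which avoids transposon-driven artifacts;
- partial windows are never DUP/DEL.

Adjacent same-mark windows merge into outlier blocks; a block is an HE
candidate when span ≥ 60,000 bp **and** run length ≥ 6 windows **and**
at least half its bases (default `min_synteny_frac = 0.5`) lie in
progenitor syntenic collinearity blocks. Two readings were open:

- "span of six windows (60 kb)" is implemented as *both* thresholds,
  each configurable, which honours the explicit 60 kb figure;
- synteny containment is a coverage fraction rather than strict
  containment because block hulls include anchor gaps; strict
  containment (1.0) is available in config.

*Replacement pairing.* A DEL block lifted through the synteny chain
onto the homeologous genome pairs with a DUP block when they overlap
reciprocally by ≥ 0.5 of each. Assignment is greedy by overlap with
leftmost tie-breaking; instances are tiny (a handful of events per
genome) and the greedy choice is oracle-checked against exhaustive
matching in tests. Direction reads `<lost>_replaced_by_<donor>`.
Calls sharing ≥ 50% reciprocal overlap across samples consolidate into
one event with a supporting-sample list.

*Reciprocal swaps* are detected from assembly-vs-progenitor anchors: a
≥ 60 kb run of anchors on one subgenome's chromosome whose targets lie
in the other progenitor, flanked by same-subgenome anchors, is a
candidate; candidates mirror-pair when each one's foreign origin
coincides with the stretch the other swapped out of its own progenitor
(inferred from the flanking anchors' targets).

*Reference comparison.* The same samples' depth against two candidate
references is run through the identical caller; the report carries
per-sample DUP/DEL block counts and their difference. Mapping against
a diverged reference loses reads to mismatches, so deletion-range
windows appear where the genome is fine — the central false-positive
mode this comparison exposes.

## Ka/Ks (Nei–Gojobori 1986) and dating

The counting estimator is implemented from first principles:

- per-codon synonymous site fractions (each position contributes the
  fraction of its three single-nucleotide changes that preserve the
  amino acid), averaged over the two sequences; S + N = 3 × codons;
- difference counts pathway-averaged for codons differing at 2–3
  positions, all minimal pathways weighted equally;
- **stop-codon convention:** a change into a stop codon is a
  nonsynonymous site, and any pathway step whose source or destination
  is a stop counts nonsynonymous (including stop→stop);
- Jukes–Cantor correction `d = −(3/4)·ln(1 − (4/3)p)` applied
  separately to pS and pN; p ≥ 3/4 raises a saturation error and the
  pair is excluded from dating;
- alignment columns containing a gap or N are removed codon-wise.

The estimator is symmetric in its two sequences and is cross-checked
in tests against both an exhaustive pathway enumerator (all codon
pairs differing at ≤ 2 positions) and an independent reference
implementation on pairs whose pathways avoid stop codons. A
codon-model (YN00-class) estimator is deliberately out of scope: in
the near-zero Ks regime this package targets, counting and model
estimators agree closely, and the "Ks = 0" class — defined here as
**exactly zero synonymous differences** (Sd = 0), never a float
threshold — is estimator-independent.

*Zero-Ks closeness test.* Over gene chains with one gene per genome,
chains that are zero-Ks with exactly one of two candidate progenitors
are discordant; under the null both directions are equally likely, so
`n10` vs `n01` is referred to an exact binomial at p = ½. The two-sided
p-value doubles the smaller tail and caps at 1 — a simple, reproducible
convention, documented because the original analysis does not name its
procedure. No discordance reports p = 1.

*Ks-peak dating.* The mode of the non-zero Ks values is located by a
Gaussian KDE (Silverman bandwidth, configurable; argmax on a ≥ 512-point
grid over [0, 1.1·max]); `T = Ks_peak / (2r)` with
`r = 6.5 × 10⁻⁹` substitutions/site/year converts it to a split time.
At least 30 non-zero values are required. A known numerical property:
when every pair has the *same* true Ks near zero (as in the recovery
simulations, where ~5 synonymous events per 2,000-codon pair are
expected), the estimate distribution is discrete and right-skewed, and
its KDE mode sits slightly below its mean (≈ floor(λ)/S vs λ/S), so
peak estimates carry a small (~10%) downward tendency that mode-based
dating at near-zero divergence cannot avoid.

## Homeolog expression bias

Pairs whose two genes are both below 1 TPM in **every** sample are
filtered (removing only doubly-silent pairs keeps the biologically
interesting one-homeolog-silenced class; the stricter either-gene rule
is a config option). Within a (tissue, condition) group, replicate TPMs
are averaged per gene (arithmetic mean, the fold-change convention for
TPM) and the pair is dominant when one mean **strictly** exceeds twice
the other. Zeros are resolved without pseudocounts (0 vs 0 → neutral;
x > 0 vs 0 → dominant); the pseudocount ε = 0.1 enters only the
reported `log2((BhS+ε)/(BhD+ε))`. This keeps the stated 2-fold rule
undistorted while making behaviour at zeros reproducible. The
classification is scale-invariant and label-antisymmetric (both are
property-tested).

Cross-group summaries count pairs biased in every group and, of those,
pairs with one direction throughout ("consistent"); converse dominance
between two groups counts opposite-direction pairs, with the
percentage denominator being pairs biased in at least one of the two
groups — a documented stand-in, since the original denominators are
not printed.

Small-sample testing uses exact null distributions: rank-sum
(Mann–Whitney) for per-gene induction with the exact null when both
groups have ≤ 8 tie-free replicates (a 3-replicate design makes
asymptotic p-values meaningless), and the paired Wilcoxon signed-rank
for TE-density contrasts with the exact null at ≤ 25 tie-free pairs;
otherwise tie-corrected normal approximations. TE density is the
covered fraction of the gene body ± 2 kb flanks (2 kb is a standard
promoter/flank scale; "near" is not defined by the source analysis and
the flank is configurable). The genome-wide TE–expression association
is the Pearson correlation between log2(TPM + ε) and density.

## The synthetic-data generator

The generator defines the study conditions; its defaults are fixed:
2 chromosomes per subgenome × 2 Mb, 10 kb windows, 30× coverage,
3 replicates over leaf/root × well-watered/drought, 10% of pairs biased
4-fold with 5% of those flipping direction under drought, log-noise
σ = 0.2, true Ks targets at 0.0035 over 1,000 pairs × 2,000 codons,
TE–expression correlation −0.30 and a +0.1 density shift on submissive
genes. Truth is written before noise and never mutated.

- *Genomes*: one ancestor per chromosome, each lineage mutated
  independently at d/2 under a uniform substitution model (no indels,
  no base-composition structure — depth ratios and Sd counts do not
  need them). Anchors are exact because the simulation knows homology;
  genes sit on a regular grid. Homeologous chromosomes therefore share
  coordinates, which keeps liftover exact and tests sharp.
- *Depth*: expected depth = coverage × (copy/2) × exp(−k·d), with
  copy ∈ {0, 2, 4} from planted replacement events and d the local
  read-to-reference divergence. The one-parameter exponential is the
  simplest monotone mismapping model; k = 20 by default, so d = 0.05
  depresses a normal window to ~0.37× — into deletion-call territory —
  which is the artifact regime being studied, not an inference about
  any real aligner. Noise is Poisson (or gamma-Poisson) at the read
  level (150 bp reads).
- *Codon pairs*: substitution events are Poisson with mean
  Ks_target × S_sites; each event applies one synonymous change drawn
  from the current synonymous opportunities. Nonsynonymous sites are
  untouched, so Ka = 0 by construction.
- *Expression*: log-TPM is Normal(μ_pair + bias + condition, σ²) with
  i.i.d. replicates; TE densities follow a Gaussian copula against
  realized mean log expression. Genes live on a virtual per-subgenome
  coordinate grid, decoupled from the genome simulation; emitted TE
  intervals reproduce each gene's flank density exactly.

What passing tests therefore show: the detectors recover *their own
generating model* exactly without noise and within stated tolerances
with noise. What they do not show: robustness to indels, unequal gene
spacing, GC/mappability structure, replicate correlation, or
misspecified homeology — none of which the generator emulates.

## Problem sizes and runtime

The test suite and the acceptance script run the full synthetic study
at 2 × 2 × 2 Mb genomes (800 depth windows/sample), 20 depth
replicates per divergence level, 1,000–2,000 codon pairs and 1,500–2,000
expression pairs — sizes chosen so every planted effect is resolvable
with comfortable statistical margin while the whole suite completes in
seconds.
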