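"""Homeolog expression bias (HEB) analysis.

For each homeolog pair (one gene on each subgenome, BhD and BhS) and
each case-study group (tissue x condition), replicate TPMs are averaged
per gene and the pair is called BhS-dominant when the BhS mean exceeds
twice the BhD mean (strictly), BhD-dominant symmetrically, and neutral
otherwise. Pairs with TPM < 1 in every sample for both genes are
filtered out first. Downstream summaries cover the log2(BhS/BhD)
distribution per group, cross-group consistency and converse dominance,
drought induction per gene, and the association between flanking
transposable-element density and expression bias.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .intervals import GenomicInterval, covered_length, merge_intervals

log = logging.getLogger("allohex.heb")

CALL_BHS = "BhS_dominant"
CALL_BHD = "BhD_dominant"
CALL_NEUTRAL = "neutral"
CALL_FILTERED = "filtered"


# ---------------------------------------------------------------------------
# Filtering and classification
# ---------------------------------------------------------------------------

def filter_low_expression(
    pairs: pd.DataFrame,
    expression: pd.DataFrame,
    threshold: float = 1.0,
    mode: str = "both",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Remove pairs expressed below ``threshold`` TPM in every sample.

    ``mode='both'`` (default) removes a pair only when *both* genes fail
    in every sample, which keeps pairs where one homeolog is silenced —
    biologically the interesting case. ``mode='either'`` removes the pair
    when either gene fails everywhere. Returns (retained, filtered).
    """
    if mode not in {"both", "either"}:
        raise ValueError("mode must be 'both' or 'either'")
    fails = {}
    for col in ("bhd_gene", "bhs_gene"):
        tpm = expression.loc[pairs[col].to_numpy()]
        fails[col] = (tpm < threshold).all(axis=1).to_numpy()
    if mode == "both":
        drop = fails["bhd_gene"] & fails["bhs_gene"]
    else:
        drop = fails["bhd_gene"] | fails["bhs_gene"]
    retained = pairs.loc[~drop].reset_index(drop=True)
    filtered = pairs.loc[drop].reset_index(drop=True)
    log.info(
        "filter_low_expression: %d retained, %d filtered (threshold=%g, mode=%s)",
        len(retained), len(filtered), threshold, mode,
    )
    return retained, filtered


def classify_bias(
    mean_bhd: float, mean_bhs: float, fold: float = 2.0, epsilon: float = 0.1
) -> tuple[str, float]:
    """Call one pair in one group from its replicate-mean TPMs.

    The fold rule is strict (> fold, not >=) and applied to the raw
    means; exactly ``fold``-fold pairs are neutral. Zeros are handled
    without the pseudocount: 0 vs 0 is neutral, x > 0 vs 0 is dominant.
    The pseudocount enters only the reported log2 ratio.
    Returns (call, log2_ratio) with log2_ratio = log2((bhs+eps)/(bhd+eps)).
    """
    if mean_bhd < 0 or mean_bhs < 0:
        raise ValueError("TPM means must be non-negative")
    log2_ratio = float(np.log2((mean_bhs + epsilon) / (mean_bhd + epsilon)))
    if mean_bhd == 0 and mean_bhs == 0:
        return CALL_NEUTRAL, log2_ratio
    if mean_bhd == 0:
        return CALL_BHS, log2_ratio
    if mean_bhs == 0:
        return CALL_BHD, log2_ratio
    if mean_bhs > fold * mean_bhd:
        return CALL_BHS, log2_ratio
    if mean_bhd > fold * mean_bhs:
        return CALL_BHD, log2_ratio
    return CALL_NEUTRAL, log2_ratio


def classify_group(
    pairs: pd.DataFrame,
    expression: pd.DataFrame,
    group_samples: list[str],
    fold: float = 2.0,
    epsilon: float = 0.1,
) -> pd.DataFrame:
    """Bias calls for every retained pair in one (tissue, condition) group."""
    if not group_samples:
        raise ValueError("group has no samples")
    sub = expression[group_samples]
    mean_bhd = sub.loc[pairs["bhd_gene"].to_numpy()].mean(axis=1).to_numpy()
    mean_bhs = sub.loc[pairs["bhs_gene"].to_numpy()].mean(axis=1).to_numpy()
    calls, ratios = [], []
    for d, s in zip(mean_bhd, mean_bhs):
        call, ratio = classify_bias(float(d), float(s), fold, epsilon)
        calls.append(call)
        ratios.append(ratio)
    return pd.DataFrame(
        {
            "bhd_gene": pairs["bhd_gene"].to_numpy(),
            "bhs_gene": pairs["bhs_gene"].to_numpy(),
            "mean_bhd": mean_bhd,
            "mean_bhs": mean_bhs,
            "log2_ratio": ratios,
            "call": calls,
        }
    )


def bias_distribution(calls: pd.DataFrame) -> dict:
    """Histogram-style summary of one group's calls."""
    if calls.empty:
        raise ValueError("no calls in group")
    counts = calls["call"].value_counts().to_dict()
    n = len(calls)
    return {
        "n_pairs": n,
        "median_log2_ratio": float(calls["log2_ratio"].median()),
        "mean_log2_ratio": float(calls["log2_ratio"].mean()),
        "counts": {
            c: int(counts.get(c, 0)) for c in (CALL_BHS, CALL_BHD, CALL_NEUTRAL)
        },
        "percent": {
            c: 100.0 * counts.get(c, 0) / n for c in (CALL_BHS, CALL_BHD, CALL_NEUTRAL)
        },
    }


# ---------------------------------------------------------------------------
# Cross-group summaries
# ---------------------------------------------------------------------------

@dataclass
class ConsistencyReport:
    n_pairs: int
    n_biased_all_groups: int
    n_consistent: int
    per_group_counts: dict
    pairwise_overlap: dict  # (group_a, group_b) -> n biased in both


def _check_same_universe(calls_by_group: dict[str, pd.DataFrame]) -> pd.Index:
    universes = {
        g: tuple(zip(df["bhd_gene"], df["bhs_gene"])) for g, df in calls_by_group.items()
    }
    first = None
    for g, u in universes.items():
        if first is None:
            first = u
        elif u != first:
            raise ValueError(f"group {g!r} has a different pair universe")
    return pd.Index(first)


def consistency_across_groups(calls_by_group: dict[str, pd.DataFrame]) -> ConsistencyReport:
    """Pairs biased in every group, and those with one direction throughout."""
    if len(calls_by_group) < 2:
        raise ValueError("need at least two groups")
    _check_same_universe(calls_by_group)
    groups = list(calls_by_group)
    call_matrix = pd.DataFrame(
        {g: calls_by_group[g]["call"].to_numpy() for g in groups}
    )
    biased = call_matrix.isin([CALL_BHS, CALL_BHD])
    biased_all = biased.all(axis=1)
    consistent = biased_all & (call_matrix.nunique(axis=1) == 1)
    pairwise = {}
    for i, a in enumerate(groups):
        for b in groups[i + 1 :]:
            pairwise[(a, b)] = int((biased[a] & biased[b]).sum())
    per_group = {
        g: calls_by_group[g]["call"].value_counts().to_dict() for g in groups
    }
    return ConsistencyReport(
        n_pairs=len(call_matrix),
        n_biased_all_groups=int(biased_all.sum()),
        n_consistent=int(consistent.sum()),
        per_group_counts=per_group,
        pairwise_overlap=pairwise,
    )


def consistent_pair_mask(calls_by_group: dict[str, pd.DataFrame]) -> np.ndarray:
    """Boolean mask over the pair universe: biased with one direction in all groups."""
    _check_same_universe(calls_by_group)
    call_matrix = pd.DataFrame(
        {g: df["call"].to_numpy() for g, df in calls_by_group.items()}
    )
    biased = call_matrix.isin([CALL_BHS, CALL_BHD]).all(axis=1)
    return (biased & (call_matrix.nunique(axis=1) == 1)).to_numpy()


def converse_dominance(
    calls_a: pd.DataFrame, calls_b: pd.DataFrame
) -> tuple[int, float, pd.DataFrame]:
    """Pairs dominant in opposite directions between two groups.

    Returns (count, percentage, pair table). The percentage denominator
    is the number of pairs biased in at least one of the two groups.
    """
    if len(calls_a) != len(calls_b):
        raise ValueError("groups have different pair universes")
    a, b = calls_a["call"].to_numpy(), calls_b["call"].to_numpy()
    converse = ((a == CALL_BHS) & (b == CALL_BHD)) | ((a == CALL_BHD) & (b == CALL_BHS))
    biased_any = np.isin(a, [CALL_BHS, CALL_BHD]) | np.isin(b, [CALL_BHS, CALL_BHD])
    denom = int(biased_any.sum())
    count = int(converse.sum())
    pct = 100.0 * count / denom if denom else 0.0
    table = calls_a.loc[converse, ["bhd_gene", "bhs_gene"]].reset_index(drop=True)
    return count, pct, table


# ---------------------------------------------------------------------------
# Per-gene induction testing
# ---------------------------------------------------------------------------

def induction_test(
    tpm_control: np.ndarray | list[float],
    tpm_treatment: np.ndarray | list[float],
    alternative: str = "two-sided",
) -> dict:
    """Rank-sum test of one gene's per-replicate TPM between two conditions.

    Uses the exact null distribution when both groups have <= 8
    replicates and there are no ties (the three-replicate design makes
    asymptotic p-values meaningless); otherwise the tie-corrected normal
    approximation. Reports direction and fold change of the means.
    """
    x = np.asarray(tpm_control, dtype=float)
    y = np.asarray(tpm_treatment, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("need at least two replicates per group")
    has_ties = len(np.unique(np.concatenate([x, y]))) < x.size + y.size
    method = "exact" if (x.size <= 8 and y.size <= 8 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(y, x, alternative=alternative, method=method)
    mean_c, mean_t = float(np.mean(x)), float(np.mean(y))
    direction = "induced" if mean_t > mean_c else ("repressed" if mean_t < mean_c else "unchanged")
    fold = mean_t / mean_c if mean_c > 0 else float("inf")
    return {
        "statistic": float(res.statistic),
        "p_value": float(res.pvalue),
        "direction": direction,
        "fold_change": fold,
        "method": method,
    }


# ---------------------------------------------------------------------------
# TE density and its association with bias
# ---------------------------------------------------------------------------

def te_flank_density(
    gene_interval: GenomicInterval,
    te_intervals: list[GenomicInterval],
    flank: int = 2_000,
    chrom_length: int | None = None,
) -> float:
    """Fraction of the gene body plus ``flank`` bp each side covered by TEs."""
    start = max(0, gene_interval.start - flank)
    end = gene_interval.end + flank
    if chrom_length is not None:
        end = min(end, chrom_length)
    window = GenomicInterval(gene_interval.chrom, start, end)
    on_chrom = [t for t in te_intervals if t.chrom == gene_interval.chrom]
    if not on_chrom:
        log.warning("te_flank_density: no TEs on chromosome %s", gene_interval.chrom)
        return 0.0
    return covered_length(on_chrom, window) / window.length


def _paired_wilcoxon(x: np.ndarray, y: np.ndarray) -> float:
    """Paired signed-rank p-value; exact null for small n without ties/zeros."""
    diffs = x - y
    if np.all(diffs == 0):
        return 1.0
    nonzero = diffs[diffs != 0]
    has_ties = len(np.unique(np.abs(nonzero))) < nonzero.size
    method = "exact" if (nonzero.size <= 25 and not has_ties) else "approx"
    res = stats.wilcoxon(x, y, method=method)
    return float(res.pvalue)


def te_bias_association(
    stable_pairs: pd.DataFrame,
    all_log_expression: np.ndarray | None = None,
    all_te_density: np.ndarray | None = None,
    min_pairs: int = 10,
) -> dict:
    """TE-density tests over stably biased pairs, plus a genome-wide correlation.

    ``stable_pairs`` needs columns te_density_bhd, te_density_bhs and
    call (the stable direction). Reports:
      (i)  paired Wilcoxon of TE density grouped by subgenome (BhD vs BhS),
      (ii) paired Wilcoxon grouped by bias class (dominant vs submissive),
      (iii) Pearson r between log expression and TE density across all
            genes, when the genome-wide vectors are supplied.
    """
    if len(stable_pairs) < min_pairs:
        raise ValueError(f"need at least {min_pairs} stable pairs, got {len(stable_pairs)}")
    d = stable_pairs["te_density_bhd"].to_numpy(dtype=float)
    s = stable_pairs["te_density_bhs"].to_numpy(dtype=float)
    call = stable_pairs["call"].to_numpy()
    if not set(call) <= {CALL_BHS, CALL_BHD}:
        raise ValueError("stable pairs must carry a dominant-direction call")
    dom = np.where(call == CALL_BHD, d, s)
    sub = np.where(call == CALL_BHD, s, d)
    report = {
        "subgenome_p": _paired_wilcoxon(d, s),
        "dom_sub_p": _paired_wilcoxon(dom, sub),
        "mean_density_bhd": float(d.mean()),
        "mean_density_bhs": float(s.mean()),
        "mean_density_dominant": float(dom.mean()),
        "mean_density_submissive": float(sub.mean()),
    }
    if all_log_expression is not None and all_te_density is not None:
        r, p = stats.pearsonr(
            np.asarray(all_log_expression, dtype=float),
            np.asarray(all_te_density, dtype=float),
        )
        report["pearson_r"] = float(r)
        report["pearson_p"] = float(p)
    return report


# ---------------------------------------------------------------------------
# Whole-dataset convenience driver
# ---------------------------------------------------------------------------

def run_heb_analysis(
    pairs: pd.DataFrame,
    expression: pd.DataFrame,
    groups: dict[str, list[str]],
    threshold: float = 1.0,
    fold: float = 2.0,
    epsilon: float = 0.1,
    low_expr_mode: str = "both",
) -> tuple[dict[str, pd.DataFrame], ConsistencyReport]:
    """Filter once, classify every group, and report cross-group consistency."""
    retained, _ = filter_low_expression(pairs, expression, threshold, low_expr_mode)
    calls_by_group = {
        g: classify_group(retained, expression, samples, fold, epsilon)
        for g, samples in groups.items()
    }
    report = consistency_across_groups(calls_by_group)
    return calls_by_group, report
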