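"""Flat key-value pipeline configuration with schema validation.

Unknown keys are hard errors: a silent typo in a depth threshold would
invalidate every homeologous-exchange call downstream, so the config
loader refuses anything it does not recognise.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, fields
from pathlib import Path

import yaml

log = logging.getLogger("allohex.config")


@dataclass
class PipelineConfig:
    """Tunable thresholds of the analysis pipeline.

    Depth-window HE calling:
      window_size       non-overlapping depth window (bp)
      dup_low/dup_high  depth-ratio range called duplication (closed interval)
      del_low/del_high  depth-ratio range called deletion (closed interval)
      min_span          minimum outlier-block span (bp) to call an HE candidate
      min_windows       minimum run length in windows
      min_synteny_frac  fraction of a block that must lie in progenitor synteny
      reciprocal_overlap_frac  reciprocal overlap required to pair DEL with DUP
      consolidation_overlap    reciprocal overlap merging calls across samples
      trimmed_mean_fraction    optional two-sided trim on the chromosome mean

    Synteny chaining:
      link_gap      maximum gap between chained anchors (bp)
      gap_sides     'both' requires the gap rule on query and target,
                    'query' on the query side only

    Expression bias:
      tpm_threshold  pairs with every sample below this for both genes drop out
      fold           dominance requires mean TPM > fold x the homeolog's mean
      epsilon        pseudocount used inside log2 ratios only
      te_flank       flank (bp) on each side of the gene body for TE density
      low_expr_mode  'both' drops a pair only when both genes fail the filter,
                    'either' when either gene fails

    Dating:
      rate          divergence rate r (substitutions/site/year) in T = Ks/2r
      min_ks_values minimum number of non-zero Ks values for peak estimation
      min_codons    minimum alignment length (codons) for dating use
    """

    window_size: int = 10_000
    dup_low: float = 1.5
    dup_high: float = 5.0
    del_low: float = 0.0
    del_high: float = 0.5
    min_span: int = 60_000
    min_windows: int = 6
    min_synteny_frac: float = 0.5
    reciprocal_overlap_frac: float = 0.5
    consolidation_overlap: float = 0.5
    trimmed_mean_fraction: float = 0.0
    link_gap: int = 20_000
    gap_sides: str = "both"
    tpm_threshold: float = 1.0
    fold: float = 2.0
    epsilon: float = 0.1
    te_flank: int = 2_000
    low_expr_mode: str = "both"
    rate: float = 6.5e-9
    min_ks_values: int = 30
    min_codons: int = 30

    def __post_init__(self) -> None:
        if self.window_size <= 0:
            raise ValueError("window_size must be positive")
        if not (0 <= self.del_low <= self.del_high < self.dup_low <= self.dup_high):
            raise ValueError(
                "depth thresholds must satisfy 0 <= del_low <= del_high < "
                "dup_low <= dup_high"
            )
        if self.gap_sides not in {"both", "query"}:
            raise ValueError("gap_sides must be 'both' or 'query'")
        if self.low_expr_mode not in {"both", "either"}:
            raise ValueError("low_expr_mode must be 'both' or 'either'")
        if self.link_gap <= 0:
            raise ValueError("link_gap must be positive")
        if not (0 <= self.min_synteny_frac <= 1):
            raise ValueError("min_synteny_frac must lie in [0, 1]")
        if not (0 < self.reciprocal_overlap_frac <= 1):
            raise ValueError("reciprocal_overlap_frac must lie in (0, 1]")
        if self.rate <= 0:
            raise ValueError("rate must be positive")


_FIELD_TYPES = {f.name: f.type for f in fields(PipelineConfig)}


def load_config(path: str | Path) -> PipelineConfig:
    """Load a YAML or JSON config; unknown keys are errors."""
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ValueError(f"config {path} must be a flat key-value mapping")
    unknown = set(data) - set(_FIELD_TYPES)
    if unknown:
        raise ValueError(f"unknown config keys in {path}: {sorted(unknown)}")
    cfg = PipelineConfig(**data)
    log.info("load_config: %s -> %s", path, cfg)
    return cfg
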