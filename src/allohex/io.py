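"""Readers and writers for the on-disk formats shared by every stage.

Formats handled here: FASTA (sequences), BED3 (intervals), TSV depth
tables (``chrom  start  end  sample_id  mean_depth``), anchor tables (a
PAF-compatible subset), expression matrices (gene_id plus one column per
sample) and sample metadata. Every reader validates against the domain
invariants and converts to the package's internal 0-based half-open
coordinates at this boundary.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import IO, Iterable, Sequence

import pandas as pd
from Bio import SeqIO

from .intervals import Anchor, GenomicInterval

log = logging.getLogger("allohex.io")

VALID_BASES = set("ACGTN")


def _open_text(path: str | Path, mode: str = "rt") -> IO[str]:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into ``{name: uppercase sequence}``.

    Duplicate record names and empty sequences are hard errors; any
    character outside {A, C, G, T, N} (after upper-casing) is rejected.
    """
    sequences: dict[str, str] = {}
    with _open_text(path) as handle:
        for record in SeqIO.parse(handle, "fasta"):
            if record.id in sequences:
                raise ValueError(f"duplicate sequence name {record.id!r} in {path}")
            seq = str(record.seq).upper()
            if not seq:
                raise ValueError(f"empty sequence for {record.id!r} in {path}")
            bad = set(seq) - VALID_BASES
            if bad:
                raise ValueError(
                    f"sequence {record.id!r} contains invalid characters {sorted(bad)}"
                )
            sequences[record.id] = seq
    log.info("read_fasta: %d sequences from %s", len(sequences), path)
    return sequences


def write_fasta(sequences: dict[str, str], path: str | Path, width: int = 80) -> None:
    with _open_text(path, "wt") as handle:
        for name, seq in sequences.items():
            handle.write(f">{name}\n")
            for i in range(0, len(seq), width):
                handle.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# BED intervals
# ---------------------------------------------------------------------------

def read_intervals(path: str | Path, format: str = "BED") -> list[GenomicInterval]:
    """Read intervals from a BED3(+) file, preserving input order."""
    if format != "BED":
        raise ValueError(f"unsupported interval format {format!r}")
    intervals: list[GenomicInterval] = []
    with _open_text(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected >= 3 BED columns")
            chrom, start_s, end_s = fields[0], fields[1], fields[2]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
            if start >= end:
                raise ValueError(
                    f"{path}:{lineno}: invalid interval {chrom}:{start}-{end} "
                    "(start must be < end)"
                )
            strand = fields[5] if len(fields) >= 6 and fields[5] in "+-" else "."
            intervals.append(GenomicInterval(chrom, start, end, strand))
    log.info("read_intervals: %d intervals from %s", len(intervals), path)
    return intervals


def write_intervals(intervals: Iterable[GenomicInterval], path: str | Path) -> None:
    with _open_text(path, "wt") as handle:
        for iv in intervals:
            handle.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


# ---------------------------------------------------------------------------
# Depth tables
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class WindowDepthRecord:
    """Mean mapping depth of one window of the non-overlapping tiling."""

    window: GenomicInterval
    sample_id: str
    mean_depth: float
    partial: bool = False

    def __post_init__(self) -> None:
        if self.mean_depth < 0:
            raise ValueError(f"negative depth {self.mean_depth} in {self.window}")


DEPTH_COLUMNS = ["chrom", "start", "end", "sample_id", "mean_depth"]


def read_depth_table(path: str | Path, window_size: int = 10_000) -> list[WindowDepthRecord]:
    """Read a per-window depth TSV.

    Windows must tile each (sample, chromosome) without overlap; all full
    windows have ``end - start == window_size``. A single trailing shorter
    window per chromosome is accepted and flagged ``partial``.
    """
    df = pd.read_csv(path, sep="\t")
    missing = set(DEPTH_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"depth table {path} missing columns {sorted(missing)}")
    if (df["mean_depth"] < 0).any():
        bad = df[df["mean_depth"] < 0].iloc[0]
        raise ValueError(
            f"negative depth {bad['mean_depth']} at {bad['chrom']}:{bad['start']}"
        )
    records: list[WindowDepthRecord] = []
    for (sample, chrom), group in df.groupby(["sample_id", "chrom"], sort=False):
        group = group.sort_values("start")
        prev_end = None
        starts = group["start"].to_numpy()
        ends = group["end"].to_numpy()
        for start, end in zip(starts, ends):
            if prev_end is not None and start < prev_end:
                raise ValueError(
                    f"overlapping windows on {sample}/{chrom} at {start} (< {prev_end})"
                )
            prev_end = end
        last_start = starts[-1]
        for _, row in group.iterrows():
            span = row["end"] - row["start"]
            partial = span != window_size
            if partial and row["start"] != last_start:
                raise ValueError(
                    f"non-trailing partial window {chrom}:{row['start']}-{row['end']} "
                    f"for sample {sample}"
                )
            records.append(
                WindowDepthRecord(
                    GenomicInterval(chrom, int(row["start"]), int(row["end"])),
                    str(sample),
                    float(row["mean_depth"]),
                    partial=partial,
                )
            )
    log.info("read_depth_table: %d windows from %s", len(records), path)
    return records


def write_depth_table(records: Iterable[WindowDepthRecord], path: str | Path) -> None:
    rows = [
        (r.window.chrom, r.window.start, r.window.end, r.sample_id, r.mean_depth)
        for r in records
    ]
    pd.DataFrame(rows, columns=DEPTH_COLUMNS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Anchors (PAF-compatible subset)
# ---------------------------------------------------------------------------

ANCHOR_COLUMNS = [
    "qchrom", "qstart", "qend", "tchrom", "tstart", "tend", "orientation", "identity",
]


def read_anchors(path: str | Path) -> list[Anchor]:
    df = pd.read_csv(path, sep="\t")
    missing = set(ANCHOR_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"anchor table {path} missing columns {sorted(missing)}")
    anchors = [
        Anchor(
            GenomicInterval(row.qchrom, int(row.qstart), int(row.qend)),
            GenomicInterval(row.tchrom, int(row.tstart), int(row.tend)),
            orientation=row.orientation,
            identity=float(row.identity),
        )
        for row in df.itertuples()
    ]
    log.info("read_anchors: %d anchors from %s", len(anchors), path)
    return anchors


def write_anchors(anchors: Iterable[Anchor], path: str | Path) -> None:
    rows = [
        (
            a.query.chrom, a.query.start, a.query.end,
            a.target.chrom, a.target.start, a.target.end,
            a.orientation, a.identity,
        )
        for a in anchors
    ]
    pd.DataFrame(rows, columns=ANCHOR_COLUMNS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Expression matrices and sample metadata
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SampleMeta:
    sample_id: str
    tissue: str
    condition: str
    replicate: int

    def __post_init__(self) -> None:
        if self.replicate < 1:
            raise ValueError("replicate index must be >= 1")

    @property
    def group(self) -> tuple[str, str]:
        return (self.tissue, self.condition)


@dataclass
class ExpressionMatrix:
    """TPM matrix (genes x samples) with per-sample metadata."""

    values: pd.DataFrame  # index: gene ids, columns: sample ids
    samples: list[SampleMeta]

    def __post_init__(self) -> None:
        ids = [s.sample_id for s in self.samples]
        if sorted(ids) != sorted(self.values.columns):
            raise ValueError("expression columns do not match sample metadata ids")
        triples = [(s.tissue, s.condition, s.replicate) for s in self.samples]
        if len(set(triples)) != len(triples):
            raise ValueError("duplicate (tissue, condition, replicate) in metadata")
        if (self.values.to_numpy() < 0).any():
            raise ValueError("negative TPM values in expression matrix")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    def samples_in_group(self, tissue: str, condition: str) -> list[str]:
        return [
            s.sample_id
            for s in self.samples
            if s.tissue == tissue and s.condition == condition
        ]

    @property
    def groups(self) -> list[tuple[str, str]]:
        seen: list[tuple[str, str]] = []
        for s in self.samples:
            if s.group not in seen:
                seen.append(s.group)
        return seen


def read_expression(expr_path: str | Path, meta_path: str | Path) -> ExpressionMatrix:
    values = pd.read_csv(expr_path, sep="\t", index_col="gene_id")
    meta_df = pd.read_csv(meta_path, sep="\t")
    required = {"sample_id", "tissue", "condition", "replicate"}
    missing = required - set(meta_df.columns)
    if missing:
        raise ValueError(f"metadata {meta_path} missing columns {sorted(missing)}")
    samples = [
        SampleMeta(str(r.sample_id), str(r.tissue), str(r.condition), int(r.replicate))
        for r in meta_df.itertuples()
    ]
    matrix = ExpressionMatrix(values, samples)
    log.info(
        "read_expression: %d genes x %d samples from %s",
        len(matrix.genes), len(samples), expr_path,
    )
    return matrix


def write_expression(matrix: ExpressionMatrix, expr_path: str | Path, meta_path: str | Path) -> None:
    matrix.values.to_csv(expr_path, sep="\t", index_label="gene_id")
    pd.DataFrame(
        [(s.sample_id, s.tissue, s.condition, s.replicate) for s in matrix.samples],
        columns=["sample_id", "tissue", "condition", "replicate"],
    ).to_csv(meta_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Pair tables
# ---------------------------------------------------------------------------

def read_pairs(path: str | Path) -> pd.DataFrame:
    """Read a homeolog pair table; requires bhd_gene and bhs_gene columns."""
    df = pd.read_csv(path, sep="\t")
    missing = {"bhd_gene", "bhs_gene"} - set(df.columns)
    if missing:
        raise ValueError(f"pair table {path} missing columns {sorted(missing)}")
    return df


def write_pairs(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)
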