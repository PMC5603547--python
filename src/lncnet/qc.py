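"""Read-accounting and assembly QC summaries.

Aggregates a per-sample read-accounting table (raw, quality-cleaned and
mapped read counts) into the totals and mapping-ratio summaries typically
reported for a bulk RNA-seq experiment, and computes standard de novo
assembly statistics (N50, mean, median contig length) from contig lengths.

Percentages are rounded half-up to one decimal to match how such tables are
conventionally printed; the mean mapping ratio is the unweighted mean of the
per-sample one-decimal ratios, not the pooled ratio of totals.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MappingRecord",
    "MappingSummary",
    "AssemblyStats",
    "summarize_mapping",
    "assembly_stats",
    "n50",
    "read_mapping_table",
    "fasta_lengths",
]


def _round1(x: float) -> float:
    """Round half-up to one decimal (Python's round() is half-even)."""
    return float(Decimal(repr(float(x))).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class MappingRecord:
    """Per-sample read accounting: raw -> quality-cleaned -> mapped."""

    sample_id: str
    group: str
    time_h: float
    raw_reads: int
    clean_reads: int
    mapped_reads: int

    def __post_init__(self) -> None:
        if not (0 <= self.mapped_reads <= self.clean_reads <= self.raw_reads):
            raise ValueError(
                f"{self.sample_id}: require 0 <= mapped <= clean <= raw, got "
                f"({self.raw_reads}, {self.clean_reads}, {self.mapped_reads})"
            )


@dataclass(frozen=True)
class MappingSummary:
    total_raw: int
    total_clean: int
    total_mapped: int
    pct_clean: float
    per_sample_ratio: tuple[float, ...]
    mean_ratio: float
    min_raw_millions: float
    max_raw_millions: float

    def to_dict(self) -> dict:
        d = asdict(self)
        d["per_sample_ratio"] = list(self.per_sample_ratio)
        return d


@dataclass(frozen=True)
class AssemblyStats:
    n_contigs: int
    max_len: int
    min_len: int
    mean_len: int
    median_len: float
    n50: int

    def to_dict(self) -> dict:
        return asdict(self)


def summarize_mapping(records: Sequence[MappingRecord]) -> MappingSummary:
    """Aggregate per-sample read accounting.

    Per-sample mapping ratio is 100*mapped/clean rounded half-up to one
    decimal; ``mean_ratio`` averages those rounded ratios (again to one
    decimal).  ``pct_clean`` is 100*sum(clean)/sum(raw) to one decimal.
    """
    if len(records) == 0:
        raise ValueError("summarize_mapping requires at least one record")
    raw = np.array([r.raw_reads for r in records], dtype=np.int64)
    clean = np.array([r.clean_reads for r in records], dtype=np.int64)
    mapped = np.array([r.mapped_reads for r in records], dtype=np.int64)
    if np.any(clean == 0):
        raise ValueError("clean_reads must be positive to form a mapping ratio")
    ratios = tuple(_round1(100.0 * m / c) for m, c in zip(mapped, clean))
    return MappingSummary(
        total_raw=int(raw.sum()),
        total_clean=int(clean.sum()),
        total_mapped=int(mapped.sum()),
        pct_clean=_round1(100.0 * clean.sum() / raw.sum()),
        per_sample_ratio=ratios,
        mean_ratio=_round1(float(np.mean(ratios))),
        min_raw_millions=_round1(raw.min() / 1e6),
        max_raw_millions=_round1(raw.max() / 1e6),
    )


def n50(lengths: Iterable[int]) -> int:
    """Largest length L such that contigs >= L cover at least half the
    total assembly length (descending cumulative sum crossing total/2)."""
    arr = np.sort(np.asarray(list(lengths), dtype=np.int64))[::-1]
    if arr.size == 0:
        raise ValueError("n50 of an empty length set is undefined")
    if np.any(arr <= 0):
        raise ValueError("contig lengths must be positive")
    csum = np.cumsum(arr)
    idx = int(np.searchsorted(csum, csum[-1] / 2.0, side="left"))
    return int(arr[idx])


def assembly_stats(lengths: Iterable[int]) -> AssemblyStats:
    """Contig-count, length extremes, rounded mean, median and N50."""
    arr = np.asarray(list(lengths), dtype=np.int64)
    if arr.size == 0:
        raise ValueError("assembly_stats requires at least one contig")
    if np.any(arr <= 0):
        raise ValueError("contig lengths must be positive")
    return AssemblyStats(
        n_contigs=int(arr.size),
        max_len=int(arr.max()),
        min_len=int(arr.min()),
        mean_len=int(Decimal(repr(float(arr.mean()))).quantize(Decimal("1"), rounding=ROUND_HALF_UP)),
        median_len=float(np.median(arr)),
        n50=n50(arr),
    )


def read_mapping_table(path: str | Path) -> list[MappingRecord]:
    """Read a TSV with columns sample, group, time_h, raw_reads,
    clean_reads, mapped_reads (extra columns ignored)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"sample", "group", "time_h", "raw_reads", "clean_reads", "mapped_reads"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"mapping table missing columns: {sorted(missing)}")
    return [
        MappingRecord(
            sample_id=str(row["sample"]),
            group=str(row["group"]),
            time_h=float(row["time_h"]),
            raw_reads=int(row["raw_reads"]),
            clean_reads=int(row["clean_reads"]),
            mapped_reads=int(row["mapped_reads"]),
        )
        for _, row in df.iterrows()
    ]


def fasta_lengths(path: str | Path) -> list[int]:
    """Sequence lengths from a FASTA file."""
    from Bio import SeqIO

    return [len(rec.seq) for rec in SeqIO.parse(str(path), "fasta")]
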