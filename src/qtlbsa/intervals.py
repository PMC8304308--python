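"""Interval algebra over QTL calls from multiple mapping experiments.

QTL intervals from independent experiments (a genome-wide bulked-segregant
scan, seasonal linkage-mapping runs, published studies) are carried as
physical coordinates in megabases, as they are conventionally printed.  The
consensus locus supported by all experiments is their intersection; genes
falling inside the consensus region are the input to candidate filtering.

Coordinates are 1-based inclusive at both endpoints, matching the printed
convention; full floating-point precision is kept internally and rounding
happens only at output time.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

__all__ = [
    "GenomicInterval",
    "GeneFeature",
    "intersect",
    "width",
    "genes_in_region",
]


@dataclass(frozen=True)
class GenomicInterval:
    """A physical QTL interval on one chromosome, in Mb.

    Endpoints are 1-based inclusive, e.g. the consensus flowering-time locus
    chr1:21.65-23.03 Mb spans ``width == 1.38`` Mb.
    """

    chrom: str
    start_mb: float
    end_mb: float
    label: str = ""

    def __post_init__(self) -> None:
        if self.end_mb < self.start_mb:
            raise ValueError(
                f"interval {self.label or self.chrom}: end {self.end_mb} < start {self.start_mb}"
            )

    @property
    def width(self) -> float:
        return self.end_mb - self.start_mb

    @property
    def start_bp(self) -> int:
        return int(round(self.start_mb * 1e6))

    @property
    def end_bp(self) -> int:
        return int(round(self.end_mb * 1e6))

    def __str__(self) -> str:  # printed at 2 decimals, the field convention
        lab = f"{self.label} " if self.label else ""
        return f"{lab}{self.chrom}:{self.start_mb:.2f}-{self.end_mb:.2f} Mb"


@dataclass(frozen=True)
class GeneFeature:
    """A gene model span in base pairs (1-based inclusive)."""

    gene_id: str
    chrom: str
    start_bp: int
    end_bp: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.end_bp < self.start_bp:
            raise ValueError(f"gene {self.gene_id}: end < start")
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be '+' or '-'")


def width(interval: GenomicInterval) -> float:
    """Physical span of ``interval`` in Mb (end minus start)."""
    return interval.width


def intersect(intervals: Sequence[GenomicInterval]) -> Optional[GenomicInterval]:
    """Common overlap of a set of intervals, or ``None`` when empty.

    The result is nonempty only when every interval lies on the same
    chromosome and ``max(starts) <= min(ends)``; it is then
    ``[max(starts), min(ends)]``.  Order-invariant over the input list.
    """
    if not intervals:
        raise ValueError("intersect requires at least one interval")
    chroms = {iv.chrom for iv in intervals}
    if len(chroms) > 1:
        return None
    start = max(iv.start_mb for iv in intervals)
    end = min(iv.end_mb for iv in intervals)
    if start > end:
        return None
    label = "+".join(sorted({iv.label for iv in intervals if iv.label}))
    return GenomicInterval(intervals[0].chrom, start, end, label=label)


def genes_in_region(
    features: Iterable[GeneFeature], region: GenomicInterval
) -> list[GeneFeature]:
    """Genes whose span overlaps ``region`` (any overlap, inclusive endpoints).

    A gene straddling a region boundary is included; containment is not
    required.  Features on other chromosomes are ignored; if none of the
    features share the region's chromosome a warning is emitted and the
    result is empty.  Output is sorted by start coordinate.
    """
    features = list(features)
    same_chrom = [f for f in features if f.chrom == region.chrom]
    if features and not same_chrom:
        warnings.warn(
            f"no gene features on chromosome {region.chrom!r}; "
            "check the chromosome naming of the feature set",
            stacklevel=2,
        )
        return []
    lo, hi = region.start_bp, region.end_bp
    hits = [f for f in same_chrom if f.start_bp <= hi and f.end_bp >= lo]
    return sorted(hits, key=lambda f: (f.start_bp, f.end_bp, f.gene_id))
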