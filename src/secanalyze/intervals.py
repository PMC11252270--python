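"""Genomic interval model and interval algebra.

All coordinates are 0-based, half-open ``[start, end)`` — the BED
convention. GFF3 input (1-based, inclusive) is converted at the parsing
boundary in :mod:`secanalyze.io`. Strand is carried on intervals but
deliberately ignored by merging and overlap tests: H3K27Ac enrichment
domains are unstranded.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

__all__ = [
    "GenomicInterval",
    "Peak",
    "GeneAnnotation",
    "merge_within",
    "overlaps",
    "overlap_length",
]

_STRANDS = ("+", "-", ".")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open genomic region ``chrom:[start, end)``."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be a non-empty string")
        if self.start < 0:
            raise ValueError(f"start must be >= 0 (got {self.start})")
        if self.end <= self.start:
            raise ValueError(
                f"end must be > start (got [{self.start}, {self.end}))"
            )
        if self.strand not in _STRANDS:
            raise ValueError(f"strand must be one of {_STRANDS} (got {self.strand!r})")

    @property
    def width(self) -> int:
        return self.end - self.start

    def __str__(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"


@dataclass(frozen=True)
class Peak:
    """A called peak: an interval plus narrowPeak-style metadata.

    ``summit_offset`` is the summit position relative to ``interval.start``
    (narrowPeak column 10), or ``None`` when the caller reported none.
    Peak records are consumed, never produced, by this package.
    """

    interval: GenomicInterval
    name: str = "."
    score: float = 0.0
    summit_offset: int | None = None

    def __post_init__(self) -> None:
        if self.summit_offset is not None and not (
            0 <= self.summit_offset < self.interval.width
        ):
            raise ValueError(
                f"summit_offset {self.summit_offset} outside "
                f"[0, {self.interval.width}) for peak {self.name!r}"
            )


@dataclass(frozen=True)
class GeneAnnotation:
    """A gene reduced to its TSS, plus a transcriptional-activity flag.

    The TSS is a width-1 interval; ``active`` marks transcriptionally
    active genes, the only ones eligible for super-enhancer assignment.
    """

    gene_id: str
    gene_name: str
    tss: GenomicInterval
    active: bool = True

    def __post_init__(self) -> None:
        if self.tss.width != 1:
            raise ValueError(
                f"tss must be a width-1 interval (gene {self.gene_id!r})"
            )


def merge_within(
    intervals: Iterable[GenomicInterval], max_gap: int
) -> list[GenomicInterval]:
    """Stitch intervals whose genomic gap is at most ``max_gap``.

    The gap between two sorted intervals is ``next.start - prev.end``; the
    stitch condition is inclusive (``gap <= max_gap``), so ``max_gap=0``
    reduces to the classic overlapping/book-ended interval merge. Output is
    sorted by ``(chrom, start)``, strand is dropped (merged regions are
    unstranded), and the operation is idempotent and order-independent.
    """
    if max_gap < 0:
        raise ValueError("max_gap must be >= 0")
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    out: list[GenomicInterval] = []
    for chrom in sorted(by_chrom):
        ivs = sorted(by_chrom[chrom], key=lambda iv: (iv.start, iv.end))
        cur_start, cur_end = ivs[0].start, ivs[0].end
        for iv in ivs[1:]:
            if iv.start - cur_end <= max_gap:
                cur_end = max(cur_end, iv.end)
            else:
                out.append(GenomicInterval(chrom, cur_start, cur_end))
                cur_start, cur_end = iv.start, iv.end
        out.append(GenomicInterval(chrom, cur_start, cur_end))
    return out


def overlap_length(a: GenomicInterval, b: GenomicInterval) -> int:
    """Number of shared base pairs (0 if different chromosomes)."""
    if a.chrom != b.chrom:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


def overlaps(a: GenomicInterval, b: GenomicInterval, min_bp: int = 1) -> bool:
    """True iff ``a`` and ``b`` share at least ``min_bp`` base pairs.

    Half-open adjacency ([0,10) vs [10,20)) does not count as overlap.
    """
    if min_bp < 1:
        raise ValueError("min_bp must be >= 1")
    return overlap_length(a, b) >= min_bp
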