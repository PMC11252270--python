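"""Factor occupancy, condition-dependent peak loss and target nomination.

Three set-level analyses sit on top of the interval layer: which genes a
factor (ARID1A, BRD4, PU.1, ...) occupies by TSS proximity; which binding
sites present in a reference condition vanish in an alternative condition
(e.g. after a knockout); and the intersection of SE-associated genes,
factor-occupied genes and differentially expressed genes that nominates
candidate direct targets.
"""
from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .intervals import GeneAnnotation, Peak

__all__ = [
    "NominationResult",
    "annotate_peaks_to_genes",
    "dependent_peaks",
    "nominate_targets",
]


def annotate_peaks_to_genes(
    peaks: Sequence[Peak],
    genes: Sequence[GeneAnnotation],
    window: int = 50000,
) -> tuple[str, ...]:
    """Genes with any peak overlapping ``[tss - window, tss + window)``.

    Any overlap of the peak with the TSS window counts (symmetric with the
    SE gene-assignment rule); the result is a deduplicated, sorted tuple of
    gene ids.
    """
    if window <= 0:
        raise ValueError("window must be strictly positive")
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom in {p.interval.chrom for p in peaks}:
        rows = sorted(
            (p.interval.start, p.interval.end)
            for p in peaks
            if p.interval.chrom == chrom
        )
        starts = np.array([r[0] for r in rows], dtype=np.int64)
        # prefix max of peak ends, aligned to start-sorted order: a peak
        # overlaps the window iff start < win_end and end > win_start
        pref_ends = np.maximum.accumulate(np.array([r[1] for r in rows], dtype=np.int64))
        by_chrom[chrom] = (starts, pref_ends)
    occupied: set[str] = set()
    for g in genes:
        chrom = g.tss.chrom
        if chrom not in by_chrom:
            continue
        starts, pref_ends = by_chrom[chrom]
        win_start = g.tss.start - window
        win_end = g.tss.start + window
        k = int(np.searchsorted(starts, win_end, side="left")) - 1
        if k >= 0 and pref_ends[k] > win_start:
            occupied.add(g.gene_id)
    return tuple(sorted(occupied))


def dependent_peaks(
    peaks_ref: Sequence[Peak],
    peaks_alt: Sequence[Peak],
    min_overlap: int = 1,
) -> list[Peak]:
    """Reference peaks with no alternative-condition peak overlapping them.

    A reference peak is "dependent" (lost) when no peak in ``peaks_alt``
    overlaps it by at least ``min_overlap`` bp. ``dependent_peaks(X, X)``
    is empty; ``dependent_peaks(X, [])`` is ``X``.
    """
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    alt_by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom in {p.interval.chrom for p in peaks_alt}:
        rows = [
            (p.interval.start, p.interval.end)
            for p in peaks_alt
            if p.interval.chrom == chrom
        ]
        alt_by_chrom[chrom] = (
            np.array([r[0] for r in rows], dtype=np.int64),
            np.array([r[1] for r in rows], dtype=np.int64),
        )
    lost: list[Peak] = []
    for p in peaks_ref:
        iv = p.interval
        if iv.chrom not in alt_by_chrom:
            lost.append(p)
            continue
        alt_s, alt_e = alt_by_chrom[iv.chrom]
        ov = np.minimum(alt_e, iv.end) - np.maximum(alt_s, iv.start)
        if not np.any(ov >= min_overlap):
            lost.append(p)
    return lost


@dataclass(frozen=True)
class NominationResult:
    """Set-intersection summary nominating candidate direct targets.

    ``nominated`` is the triple intersection of SE-associated genes,
    factor-occupied genes and differentially expressed genes of the
    requested direction. Cardinalities of all parent sets and pairwise
    intersections are reported alongside.
    """

    se_genes: frozenset[str]
    occupied_genes: frozenset[str]
    deg_genes: frozenset[str]
    direction: str
    nominated: tuple[str, ...]

    @property
    def cardinalities(self) -> dict[str, int]:
        se, occ, deg = self.se_genes, self.occupied_genes, self.deg_genes
        return {
            "se_genes": len(se),
            "occupied_genes": len(occ),
            "deg_genes": len(deg),
            "se_and_occupied": len(se & occ),
            "se_and_deg": len(se & deg),
            "occupied_and_deg": len(occ & deg),
            "triple": len(se & occ & deg),
        }

    def to_json(self, path=None, indent: int = 2) -> str:
        payload = {
            "direction": self.direction,
            "cardinalities": self.cardinalities,
            "nominated": list(self.nominated),
            "members": {
                "se_genes": sorted(self.se_genes),
                "occupied_genes": sorted(self.occupied_genes),
                "deg_genes": sorted(self.deg_genes),
            },
        }
        text = json.dumps(payload, indent=indent, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text


def _deg_gene_set(deg, direction: str) -> set[str]:
    if direction not in ("up", "down", "any"):
        raise ValueError("direction must be one of 'up', 'down', 'any'")
    genes: set[str] = set()
    if isinstance(deg, Mapping):
        for gid, d in deg.items():
            if direction == "any" or d == direction:
                genes.add(gid)
        return genes
    for item in deg:
        if isinstance(item, str):
            genes.add(item)
            continue
        # MarkerResult-like: honor the passes flag and direction label
        if getattr(item, "passes", True) and (
            direction == "any" or item.direction == direction
        ):
            genes.add(item.gene_id)
    return genes


def nominate_targets(
    se_genes: Iterable[str],
    occupied_genes: Iterable[str],
    deg,
    direction: str = "any",
    restrict_to: Iterable[str] | None = None,
) -> NominationResult:
    """Intersect SE-associated, occupied and differential gene sets.

    ``deg`` may be a collection of MarkerResult records (their ``passes``
    flag and ``direction`` labels are honored), a mapping gene -> direction,
    or a plain iterable of gene ids (used as-is when ``direction='any'``).
    ``restrict_to`` optionally filters the DEG set to a curated gene list
    (e.g. a lineage-differentiation gene set) before intersecting. The
    operation is pure set algebra: idempotent and order-independent.
    """
    se = frozenset(se_genes)
    occ = frozenset(occupied_genes)
    degset = _deg_gene_set(deg, direction)
    if restrict_to is not None:
        degset &= set(restrict_to)
    degf = frozenset(degset)
    if se and occ and degf and not (se & occ or se & degf or occ & degf):
        warnings.warn(
            "gene namespaces of the three sets do not overlap at all; "
            "empty nomination",
            stacklevel=2,
        )
    nominated = tuple(sorted(se & occ & degf))
    return NominationResult(
        se_genes=se,
        occupied_genes=occ,
        deg_genes=degf,
        direction=direction,
        nominated=nominated,
    )
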