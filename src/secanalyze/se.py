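"""Super-enhancer identification from H3K27Ac peak calls and coverage.

The chain mirrors the ROSE-style recipe: H3K27Ac peaks fully contained
within a +/-2.5 kb promoter flank are discarded; surviving peaks within
12.5 kb of one another are stitched into candidate enhancers; each stitched
region is quantified as background-subtracted ChIP occupancy in reads per
million (rpm); enhancers are ranked by increasing signal and the cutoff is
placed at the geometrically defined inflection of the hockey-stick curve
(the discrete point where a slope-1 tangent touches after min-max scaling
of both axes); enhancers above the cutoff are super-enhancers (SEs).
Transcriptionally active genes whose TSS lies within 50 kb of an SE are
assigned to it.
"""
from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .coverage import CoverageTrack
from .intervals import GeneAnnotation, GenomicInterval, Peak, merge_within

__all__ = [
    "SEConfig",
    "StitchedEnhancer",
    "SECallResult",
    "SEGeneAssignment",
    "SEPipelineResult",
    "exclude_promoter_regions",
    "quantify_region_signal",
    "rank_signal_cutoff",
    "call_superenhancers",
    "assign_genes_to_ses",
    "run_se_pipeline",
]

_DEGENERATE_TOL = 1e-12


@dataclass(frozen=True)
class SEConfig:
    """Window parameters of the SE chain (base pairs).

    promoter_flank: half-width of the promoter exclusion zone around a TSS.
    stitch_gap: maximum gap between enhancers merged into one region.
    assign_window: distance from an SE edge within which an active TSS is
    assigned to it.
    """

    promoter_flank: int = 2500
    stitch_gap: int = 12500
    assign_window: int = 50000

    def __post_init__(self) -> None:
        for name in ("promoter_flank", "stitch_gap", "assign_window"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")


@dataclass(frozen=True)
class StitchedEnhancer:
    """A stitched enhancer region with its quantified, ranked signal."""

    region: GenomicInterval
    constituent_count: int = 1
    signal_rpm: float = 0.0
    rank: int = 0  # 1-based, ascending signal; 0 until ranked
    is_super: bool = False

    def __post_init__(self) -> None:
        if self.signal_rpm < 0:
            raise ValueError("signal_rpm must be >= 0 (floored at quantification)")
        if self.constituent_count < 1:
            raise ValueError("constituent_count must be >= 1")


@dataclass(frozen=True)
class SECallResult:
    """Ranked enhancers plus the inflection cutoff separating SEs.

    ``degenerate`` flags landscapes without a usable inflection (all
    signals identical, or a curve indistinguishable from the diagonal);
    such landscapes yield zero SEs.
    """

    enhancers: tuple[StitchedEnhancer, ...]
    cutoff_rank: int
    cutoff_signal_rpm: float
    degenerate: bool = False

    @property
    def n_enhancers(self) -> int:
        return len(self.enhancers)

    @property
    def n_super(self) -> int:
        return sum(e.is_super for e in self.enhancers)

    @property
    def superenhancers(self) -> tuple[StitchedEnhancer, ...]:
        return tuple(e for e in self.enhancers if e.is_super)


@dataclass(frozen=True)
class SEGeneAssignment:
    """Per-SE assigned active genes and the flattened unique gene list."""

    per_se: dict[str, tuple[str, ...]]
    genes: tuple[str, ...]


@dataclass(frozen=True)
class SEPipelineResult:
    call: SECallResult
    assignment: SEGeneAssignment
    stitched: tuple[GenomicInterval, ...]
    n_input_peaks: int
    n_promoter_excluded: int


def exclude_promoter_regions(
    peaks: Sequence[Peak], genes: Sequence[GeneAnnotation], flank: int
) -> list[Peak]:
    """Drop peaks fully contained within ``[tss - flank, tss + flank)``.

    Partially overlapping peaks are retained intact: the active-enhancer
    definition only removes regions contained within the promoter flank of
    some gene. With an empty gene set the input is returned unchanged with
    a warning.
    """
    if flank <= 0:
        raise ValueError("flank must be strictly positive")
    genes = list(genes)
    if not genes:
        warnings.warn("empty gene set: no promoter regions to exclude", stacklevel=2)
        return list(peaks)
    windows: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom in {g.tss.chrom for g in genes}:
        ws = sorted(
            (max(0, g.tss.start - flank), g.tss.start + flank)
            for g in genes
            if g.tss.chrom == chrom
        )
        starts = np.array([w[0] for w in ws], dtype=np.int64)
        # prefix max of window ends: containment needs some window with
        # start <= peak.start and end >= peak.end
        ends = np.maximum.accumulate(np.array([w[1] for w in ws], dtype=np.int64))
        windows[chrom] = (starts, ends)
    kept: list[Peak] = []
    for p in peaks:
        iv = p.interval
        if iv.chrom in windows:
            starts, pref_ends = windows[iv.chrom]
            k = int(np.searchsorted(starts, iv.start, side="right")) - 1
            if k >= 0 and pref_ends[k] >= iv.end:
                continue
        kept.append(p)
    return kept


def quantify_region_signal(
    regions: Sequence[GenomicInterval],
    chip: CoverageTrack,
    input_track: CoverageTrack,
) -> np.ndarray:
    """Background-subtracted ChIP occupancy per region, in rpm.

    signal = max(0, sum_bp chip_rpm - sum_bp input_rpm); the floor is
    applied per region, after subtraction. Regions on chromosomes absent
    from both tracks score 0 with a warning.
    """
    signals = np.empty(len(regions), dtype=float)
    warned: set[str] = set()
    for i, r in enumerate(regions):
        if not chip.has_chrom(r.chrom) and not input_track.has_chrom(r.chrom):
            if r.chrom not in warned:
                warnings.warn(
                    f"chromosome {r.chrom!r} absent from both coverage tracks; signal 0",
                    stacklevel=2,
                )
                warned.add(r.chrom)
            signals[i] = 0.0
            continue
        signals[i] = max(
            0.0,
            chip.rpm(r.chrom, r.start, r.end) - input_track.rpm(r.chrom, r.start, r.end),
        )
    return signals


def rank_signal_cutoff(signals: np.ndarray) -> tuple[int, bool]:
    """Locate the hockey-stick inflection on ascending-sorted signals.

    Ranks are scaled to x in [0, 1] and signals to y in [0, 1] (min-max);
    the cutoff is the point maximizing ``x - y`` — the discrete point where
    a line of slope 1 is tangent to the convex rank curve. Ties break
    toward the larger rank (the conservative choice: fewer SEs). Returns
    ``(cutoff_rank, degenerate)`` with a 1-based cutoff rank; enhancers
    ranked strictly above it are super-enhancers.
    """
    s = np.asarray(signals, dtype=float)
    n = len(s)
    if n < 3:
        raise ValueError("need at least 3 enhancers to place a cutoff")
    if not np.all(np.isfinite(s)) or np.any(s < 0):
        raise ValueError("signals must be finite and >= 0")
    if np.any(np.diff(s) < 0):
        raise ValueError("signals must be sorted ascending")
    lo, hi = s[0], s[-1]
    if hi == lo:
        return n, True
    x = np.arange(n, dtype=float) / (n - 1)
    y = (s - lo) / (hi - lo)
    d = x - y
    best = float(np.max(d))
    if best <= _DEGENERATE_TOL:
        return n, True
    idx = n - 1 - int(np.argmax(d[::-1]))  # last argmax: ties to larger rank
    return idx + 1, False


def call_superenhancers(enhancers: Sequence[StitchedEnhancer]) -> SECallResult:
    """Rank enhancers by ascending signal and call SEs above the inflection.

    Ordering is deterministic and independent of input order: ties in
    signal are broken by genomic position. Min-max scaling makes the call
    invariant to multiplying all signals by a positive constant.
    """
    enh = list(enhancers)
    order = sorted(
        range(len(enh)),
        key=lambda i: (
            enh[i].signal_rpm,
            enh[i].region.chrom,
            enh[i].region.start,
            enh[i].region.end,
        ),
    )
    signals = np.array([enh[i].signal_rpm for i in order], dtype=float)
    cutoff_rank, degenerate = rank_signal_cutoff(signals)
    ranked = tuple(
        replace(enh[j], rank=r, is_super=(not degenerate and r > cutoff_rank))
        for r, j in enumerate(order, start=1)
    )
    return SECallResult(
        enhancers=ranked,
        cutoff_rank=cutoff_rank,
        cutoff_signal_rpm=float(signals[cutoff_rank - 1]),
        degenerate=degenerate,
    )


def assign_genes_to_ses(
    ses: Sequence[StitchedEnhancer],
    genes: Sequence[GeneAnnotation],
    window: int,
) -> SEGeneAssignment:
    """Assign active-gene TSSs within ``window`` bp of SE edges.

    A gene is assigned to an SE iff it is transcriptionally active and its
    TSS lies within ``[se.start - window, se.end + window)``. The flattened
    list is deduplicated by gene_id and sorted.
    """
    if window <= 0:
        raise ValueError("window must be strictly positive")
    active = [g for g in genes if g.active]
    per_se: dict[str, tuple[str, ...]] = {}
    flat: set[str] = set()
    for se in ses:
        r = se.region
        lo, hi = r.start - window, r.end + window
        hits = sorted(
            g.gene_id
            for g in active
            if g.tss.chrom == r.chrom and lo <= g.tss.start < hi
        )
        per_se[str(r)] = tuple(hits)
        flat.update(hits)
    return SEGeneAssignment(per_se=per_se, genes=tuple(sorted(flat)))


def _count_constituents(
    stitched: Sequence[GenomicInterval], peaks: Sequence[Peak]
) -> list[int]:
    counts = [0] * len(stitched)
    by_chrom: dict[str, list[tuple[int, int, int]]] = {}
    for i, r in enumerate(stitched):
        by_chrom.setdefault(r.chrom, []).append((r.start, r.end, i))
    index: dict[str, tuple[np.ndarray, np.ndarray, list[int]]] = {}
    for chrom, rows in by_chrom.items():
        rows.sort()
        index[chrom] = (
            np.array([r[0] for r in rows], dtype=np.int64),
            np.array([r[1] for r in rows], dtype=np.int64),
            [r[2] for r in rows],
        )
    for p in peaks:
        iv = p.interval
        if iv.chrom not in index:
            continue
        starts, ends, idx = index[iv.chrom]
        # stitched regions are disjoint: the only candidate container is the
        # rightmost region starting at or before the peak
        k = int(np.searchsorted(starts, iv.start, side="right")) - 1
        if k >= 0 and ends[k] >= iv.end:
            counts[idx[k]] += 1
    return [max(1, c) for c in counts]


def run_se_pipeline(
    peaks: Sequence[Peak],
    genes: Sequence[GeneAnnotation],
    chip: CoverageTrack,
    input_track: CoverageTrack,
    config: SEConfig = SEConfig(),
    out_dir: str | os.PathLike | None = None,
) -> SEPipelineResult:
    """Exclude promoters, stitch, quantify, call SEs and assign genes.

    The composition is deterministic; rerunning on identical inputs yields
    byte-identical outputs. With fewer than 3 stitched regions no cutoff
    can be placed: everything is reported as typical with the degenerate
    flag set (an empty peak list yields an empty result without error).
    """
    retained = exclude_promoter_regions(peaks, genes, config.promoter_flank)
    stitched = merge_within((p.interval for p in retained), config.stitch_gap)
    signals = quantify_region_signal(stitched, chip, input_track) if stitched else np.array([])
    counts = _count_constituents(stitched, retained)
    enh = [
        StitchedEnhancer(region=r, constituent_count=c, signal_rpm=float(s))
        for r, c, s in zip(stitched, counts, signals)
    ]
    if len(enh) >= 3:
        call = call_superenhancers(enh)
    else:
        order = sorted(range(len(enh)), key=lambda i: enh[i].signal_rpm)
        ranked = tuple(replace(enh[j], rank=r) for r, j in enumerate(order, start=1))
        call = SECallResult(
            enhancers=ranked,
            cutoff_rank=len(enh),
            cutoff_signal_rpm=float(ranked[-1].signal_rpm) if ranked else 0.0,
            degenerate=True,
        )
    assignment = assign_genes_to_ses(call.superenhancers, genes, config.assign_window)
    result = SEPipelineResult(
        call=call,
        assignment=assignment,
        stitched=tuple(stitched),
        n_input_peaks=len(peaks),
        n_promoter_excluded=len(peaks) - len(retained),
    )
    if out_dir is not None:
        write_se_outputs(result, out_dir)
    return result


def write_se_outputs(result: SEPipelineResult, out_dir: str | os.PathLike) -> None:
    """Emit stitched.bed, superenhancers.bed, ranked_signal.tsv,
    se_genes.tsv and the hockey-stick plot into ``out_dir``."""
    from .io import write_bed

    os.makedirs(out_dir, exist_ok=True)
    call = result.call
    ranked = sorted(call.enhancers, key=lambda e: e.rank)
    write_bed(
        [
            Peak(e.region, name=f"enh_{e.rank:05d}", score=round(e.signal_rpm, 4))
            for e in ranked
        ],
        os.path.join(out_dir, "stitched.bed"),
    )
    write_bed(
        [
            Peak(e.region, name=f"SE_{e.rank:05d}", score=round(e.signal_rpm, 4))
            for e in ranked
            if e.is_super
        ],
        os.path.join(out_dir, "superenhancers.bed"),
    )
    with open(os.path.join(out_dir, "ranked_signal.tsv"), "w") as fh:
        fh.write("rank\tchrom\tstart\tend\tconstituents\tsignal_rpm\tis_super\n")
        for e in ranked:
            fh.write(
                f"{e.rank}\t{e.region.chrom}\t{e.region.start}\t{e.region.end}\t"
                f"{e.constituent_count}\t{e.signal_rpm:.6g}\t{int(e.is_super)}\n"
            )
    with open(os.path.join(out_dir, "se_genes.tsv"), "w") as fh:
        fh.write("gene_id\n")
        for gid in result.assignment.genes:
            fh.write(f"{gid}\n")
    with open(os.path.join(out_dir, "se_gene_map.tsv"), "w") as fh:
        fh.write("se_region\tgene_id\n")
        for region, gids in sorted(result.assignment.per_se.items()):
            for gid in gids:
                fh.write(f"{region}\t{gid}\n")
    _plot_hockey_stick(call, os.path.join(out_dir, "hockey_stick.png"))


def _plot_hockey_stick(call: SECallResult, path: str) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ranked = sorted(call.enhancers, key=lambda e: e.rank)
    ranks = [e.rank for e in ranked]
    sig = [e.signal_rpm for e in ranked]
    fig, ax = plt.subplots(figsize=(5, 4))
    colors = ["#d62728" if e.is_super else "#7f7f7f" for e in ranked]
    ax.scatter(ranks, sig, s=6, c=colors)
    if not call.degenerate:
        ax.axvline(call.cutoff_rank, ls="--", lw=0.8, color="k")
    ax.set_xlabel("enhancer rank (ascending signal)")
    ax.set_ylabel("background-subtracted H3K27Ac signal (rpm)")
    n_super = call.n_super
    ax.set_title(f"{call.n_enhancers} enhancers, {n_super} super-enhancers")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
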