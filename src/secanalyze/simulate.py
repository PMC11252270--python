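"""Synthetic inputs with planted ground truth for every pipeline stage.

The generator emulates, at desk scale, the data landscape of an
osteoclastogenesis regulatory study on one synthetic chromosome:

* a hockey-stick H3K27Ac enhancer landscape — a few dozen planted
  super-enhancer (SE) loci, each a cluster of 3-8 constituent peaks with
  Poisson coverage far above the 400-odd single-peak typical enhancers,
  over a flat Poisson input track;
* active/inactive TSS annotations, with each planted SE locus given a
  designated active target gene within the assignment window;
* factor-occupancy peak sets, including a reference/knockout pair with a
  known subset of peaks lost in the knockout;
* negative-binomial scRNA-seq counts over clusters and conditions with
  planted cluster markers and condition DEGs;
* 3C-qPCR quantities log-normally scattered around known interaction
  frequencies anchored to a short-range ligation control.

Everything is bit-reproducible given (parameters, seed), and every planted
entity is locatable by id in the emitted files via the
:class:`GroundTruthManifest`.
"""
from __future__ import annotations

import json
import os
from dataclasses import asdict, dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import sparse

from .coverage import CoverageTrack
from .intervals import GeneAnnotation, GenomicInterval, Peak
from .markers import CountMatrix

__all__ = [
    "PlantedLocus",
    "PlantedMarker",
    "PlantedDEG",
    "GroundTruthManifest",
    "EnhancerLandscape",
    "simulate_annotation",
    "simulate_enhancer_landscape",
    "simulate_occupancy_peaks",
    "simulate_dependent_peaks",
    "simulate_counts",
    "simulate_3c",
    "simulate_ocfate",
]


@dataclass(frozen=True)
class PlantedLocus:
    """A planted enhancer entity: its stitched extent and target gene."""

    locus_id: str
    start: int
    end: int
    gene_id: str | None = None


@dataclass(frozen=True)
class PlantedMarker:
    """A gene planted as a cluster marker with a known true fold."""

    gene_id: str
    cluster: str
    fold: float
    base_mean: float | None = None


@dataclass(frozen=True)
class PlantedDEG:
    """A gene planted as differentially expressed in one condition."""

    gene_id: str
    cluster: str
    direction: str  # 'up' or 'down' in `condition` relative to the other
    fold: float
    condition: str
    base_mean: float | None = None


@dataclass
class GroundTruthManifest:
    """Everything the tests need to check recovery against the truth."""

    seed: int
    chrom: str
    planted_se_loci: list[PlantedLocus] = field(default_factory=list)
    planted_typical_enhancers: list[PlantedLocus] = field(default_factory=list)
    planted_dependent_peaks: list[str] = field(default_factory=list)
    planted_markers: list[PlantedMarker] = field(default_factory=list)
    planted_condition_degs: list[PlantedDEG] = field(default_factory=list)
    three_c_true_if: dict = field(default_factory=dict)
    occupied_gene_ids: list[str] = field(default_factory=list)
    oc_gene_set: list[str] = field(default_factory=list)
    expected_nominated: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    def save(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def load(cls, path: str | os.PathLike) -> "GroundTruthManifest":
        with open(path) as fh:
            d = json.load(fh)
        d["planted_se_loci"] = [PlantedLocus(**x) for x in d["planted_se_loci"]]
        d["planted_typical_enhancers"] = [
            PlantedLocus(**x) for x in d["planted_typical_enhancers"]
        ]
        d["planted_markers"] = [PlantedMarker(**x) for x in d["planted_markers"]]
        d["planted_condition_degs"] = [
            PlantedDEG(**x) for x in d["planted_condition_degs"]
        ]
        return cls(**d)


def simulate_annotation(
    n_genes: int,
    genome_length: int = 10_000_000,
    active_fraction: float = 0.7,
    chrom: str = "chrS",
    seed: int = 1,
    min_spacing: int = 1000,
) -> list[GeneAnnotation]:
    """Uniformly placed collision-free TSSs with Bernoulli active flags."""
    if n_genes < 10:
        raise ValueError("need at least 10 genes")
    rng = np.random.default_rng(seed)
    n_slots = genome_length // min_spacing
    if n_genes > n_slots // 2:
        raise ValueError(
            f"genome of {genome_length} bp too small to space {n_genes} genes "
            f"at {min_spacing} bp"
        )
    slots = np.sort(rng.choice(n_slots, size=n_genes, replace=False))
    tss = slots * min_spacing + rng.integers(0, min_spacing, size=n_genes)
    active = rng.random(n_genes) < active_fraction
    strands = rng.choice(["+", "-"], size=n_genes)
    return [
        GeneAnnotation(
            gene_id=f"G{i:04d}",
            gene_name=f"G{i:04d}",
            tss=GenomicInterval(chrom, int(t), int(t) + 1, str(s)),
            active=bool(a),
        )
        for i, (t, a, s) in enumerate(zip(tss, active, strands), start=1)
    ]


def _layout(widths: np.ndarray, genome_length: int, min_sep: int, margin: int, rng) -> np.ndarray:
    """Sequential left-to-right placement with >= min_sep between entities."""
    n = len(widths)
    base = int(widths.sum()) + (n - 1) * min_sep + 2 * margin
    slack = genome_length - base
    if slack < 0:
        raise ValueError(
            f"genome of {genome_length} bp too small for {n} entities "
            f"(need {base} bp)"
        )
    extra = rng.multinomial(slack, np.full(n + 1, 1.0 / (n + 1)))
    starts = np.empty(n, dtype=np.int64)
    pos = margin + int(extra[0])
    for i, w in enumerate(widths):
        starts[i] = pos
        pos += int(w) + min_sep + int(extra[i + 1])
    return starts


@dataclass
class EnhancerLandscape:
    """All emitted pieces of one synthetic enhancer landscape."""

    peaks: list[Peak]
    chip: CoverageTrack
    input_track: CoverageTrack
    genes: list[GeneAnnotation]
    se_loci: list[PlantedLocus]
    typical: list[PlantedLocus]
    chrom: str

    def save(self, out_dir: str | os.PathLike) -> dict[str, str]:
        """Write narrowPeak, bedGraphs and GFF3; return the path map."""
        from .io import write_gene_annotation, write_narrowpeak

        os.makedirs(out_dir, exist_ok=True)
        paths = {
            "peaks": os.path.join(out_dir, "h3k27ac.narrowPeak"),
            "chip": os.path.join(out_dir, "h3k27ac_treat.bedGraph"),
            "input": os.path.join(out_dir, "input.bedGraph"),
            "genes": os.path.join(out_dir, "genes.gff3"),
        }
        write_narrowpeak(self.peaks, paths["peaks"])
        self.chip.to_bedgraph(paths["chip"])
        self.input_track.to_bedgraph(paths["input"])
        write_gene_annotation(self.genes, paths["genes"])
        return paths


def simulate_enhancer_landscape(
    n_se: int = 20,
    n_typical: int = 400,
    signal_ratio: float = 20.0,
    typical_depth: float = 2.0,
    background_depth: float = 0.25,
    n_genes: int = 300,
    active_fraction: float = 0.7,
    n_promoter_decoys: int = 30,
    genome_length: int = 10_000_000,
    chrom: str = "chrS",
    bin_size: int = 50,
    stitch_gap: int = 12500,
    promoter_flank: int = 2500,
    seed: int = 1,
) -> EnhancerLandscape:
    """Plant a hockey-stick enhancer landscape with known SE loci.

    SE loci are clusters of 3-8 constituent peaks with intra-locus gaps
    well below ``stitch_gap`` (each locus stitches into exactly one
    region); typical enhancers are single peaks. Constituent coverage is
    Poisson with per-bp mean ``signal_ratio * typical_depth`` over a flat
    Poisson input of mean ``background_depth``. Entities are separated by
    more than ``stitch_gap`` so planted counts survive stitching, and every
    SE locus gets a designated active gene with its TSS 3-40 kb past the
    locus edge. Promoter-decoy peaks are placed fully inside some
    non-target promoter flanks to exercise the exclusion step.
    """
    if signal_ratio < 1:
        raise ValueError("signal_ratio must be >= 1")
    rng = np.random.default_rng(seed)

    # --- constituent geometry and genome layout -------------------------
    se_geoms = []
    for _ in range(n_se):
        k = int(rng.integers(3, 9))
        widths = rng.integers(800, 2001, size=k)
        gaps = rng.integers(500, min(8000, stitch_gap) + 1, size=k - 1)
        se_geoms.append((widths, gaps))
    typ_widths = rng.integers(600, 1501, size=n_typical)

    entities: list[tuple[str, int, int]] = [  # (kind, index, footprint)
        ("se", i, int(w.sum() + g.sum())) for i, (w, g) in enumerate(se_geoms)
    ] + [("typ", i, int(w)) for i, w in enumerate(typ_widths)]
    order = rng.permutation(len(entities))
    entities = [entities[i] for i in order]
    footprints = np.array([e[2] for e in entities], dtype=np.int64)
    min_sep = stitch_gap + 2000
    margin = 60_000
    starts = _layout(footprints, genome_length, min_sep, margin, rng)

    peaks: list[Peak] = []
    se_extents: dict[int, tuple[int, int]] = {}
    typical: list[PlantedLocus] = []
    gap_after: dict[int, int] = {}  # se index -> free bp after the locus
    for j, ((kind, i, fp), s0) in enumerate(zip(entities, starts)):
        end_of_entity = int(s0) + fp
        next_start = int(starts[j + 1]) if j + 1 < len(starts) else genome_length - margin
        if kind == "typ":
            iv = GenomicInterval(chrom, int(s0), end_of_entity)
            peaks.append(Peak(iv, name=f"TYP{i:03d}", score=typical_depth))
            typical.append(PlantedLocus(f"TYP{i:03d}", iv.start, iv.end))
        else:
            widths, gaps = se_geoms[i]
            pos = int(s0)
            for c, w in enumerate(widths):
                iv = GenomicInterval(chrom, pos, pos + int(w))
                peaks.append(
                    Peak(iv, name=f"SE{i:02d}_c{c}", score=signal_ratio * typical_depth)
                )
                pos += int(w)
                if c < len(gaps):
                    pos += int(gaps[c])
            se_extents[i] = (int(s0), end_of_entity)
            gap_after[i] = next_start - end_of_entity

    # --- genes: SE targets first, then background TSSs ------------------
    gene_rows: list[tuple[int, str, bool, int | None]] = []  # (tss, strand, active, se_idx)
    for i in sorted(se_extents):
        lo_ext, hi_ext = se_extents[i]
        free = gap_after[i]
        hi_off = min(40_000, free - 3000)
        off = int(rng.integers(3000, hi_off + 1))
        gene_rows.append((hi_ext + off, str(rng.choice(["+", "-"])), True, i))

    forbidden: list[tuple[int, int]] = []
    pad = promoter_flank + 1000
    for (kind, i, fp), s0 in zip(entities, starts):
        forbidden.append((int(s0) - pad, int(s0) + fp + pad))
    for t, _, _, _ in gene_rows:
        forbidden.append((t - promoter_flank - 500, t + promoter_flank + 500))
    forbidden.sort()
    fstarts = np.array([f[0] for f in forbidden], dtype=np.int64)
    fends = np.maximum.accumulate(np.array([f[1] for f in forbidden], dtype=np.int64))

    taken = sorted(t for t, _, _, _ in gene_rows)
    n_other = n_genes - len(gene_rows)
    if n_other < 0:
        raise ValueError("n_genes smaller than the number of SE loci")
    placed = 0
    attempts = 0
    while placed < n_other:
        attempts += 1
        if attempts > 200 * n_other:
            raise ValueError("genome too crowded to place background genes")
        t = int(rng.integers(margin, genome_length - margin))
        k = int(np.searchsorted(fstarts, t, side="right")) - 1
        if k >= 0 and fends[k] > t:
            continue
        j = int(np.searchsorted(taken, t))
        if (j > 0 and t - taken[j - 1] < 500) or (
            j < len(taken) and taken[j] - t < 500
        ):
            continue
        taken.insert(j, t)
        gene_rows.append(
            (t, str(rng.choice(["+", "-"])), bool(rng.random() < active_fraction), None)
        )
        placed += 1

    gene_rows.sort(key=lambda r: r[0])
    genes: list[GeneAnnotation] = []
    se_gene: dict[int, str] = {}
    for num, (t, strand, active, se_idx) in enumerate(gene_rows, start=1):
        gid = f"G{num:04d}"
        genes.append(
            GeneAnnotation(gid, gid, GenomicInterval(chrom, t, t + 1, strand), active)
        )
        if se_idx is not None:
            se_gene[se_idx] = gid

    se_loci = [
        PlantedLocus(f"SE{i:02d}", se_extents[i][0], se_extents[i][1], se_gene[i])
        for i in sorted(se_extents)
    ]

    # --- promoter-decoy peaks (always excluded downstream) ---------------
    other_gene_tss = [t for t, _, _, se_idx in gene_rows if se_idx is None]
    n_decoys = min(n_promoter_decoys, len(other_gene_tss))
    decoy_tss = rng.choice(other_gene_tss, size=n_decoys, replace=False)
    decoys: list[Peak] = []
    for di, t in enumerate(sorted(int(x) for x in decoy_tss)):
        w = int(rng.integers(300, 801))
        o = int(rng.integers(-promoter_flank, promoter_flank - w + 1))
        iv = GenomicInterval(chrom, max(0, t + o), max(0, t + o) + w)
        decoys.append(Peak(iv, name=f"PROM{di:03d}", score=typical_depth))

    all_peaks = sorted(
        peaks + decoys, key=lambda p: (p.interval.start, p.interval.end)
    )

    # --- Poisson coverage aggregated to fixed-size bins ------------------
    n_bins = genome_length // bin_size
    lam = np.full(n_bins, background_depth, dtype=float)
    for p in all_peaks:
        b0 = p.interval.start // bin_size
        b1 = -(-p.interval.end // bin_size)
        lam[b0:b1] += p.score  # score carries the planted per-bp depth
    chip_vals = rng.poisson(lam).astype(float)
    input_vals = rng.poisson(background_depth, size=n_bins).astype(float)
    bin_starts = np.arange(n_bins, dtype=np.int64) * bin_size
    bin_ends = bin_starts + bin_size
    chip = CoverageTrack(
        {chrom: (bin_starts, bin_ends, chip_vals)},
        total_mapped_reads=float(chip_vals.sum()),
    )
    input_track = CoverageTrack(
        {chrom: (bin_starts, bin_ends, input_vals)},
        total_mapped_reads=float(max(1.0, input_vals.sum())),
    )
    return EnhancerLandscape(
        peaks=all_peaks,
        chip=chip,
        input_track=input_track,
        genes=genes,
        se_loci=se_loci,
        typical=typical,
        chrom=chrom,
    )


def simulate_occupancy_peaks(
    genes: Sequence[GeneAnnotation],
    occupied_gene_ids: Sequence[str],
    window: int = 50000,
    peak_width: int = 500,
    n_background: int = 20,
    genome_length: int = 10_000_000,
    chrom: str = "chrS",
    seed: int = 1,
    factor: str = "ARID1A",
) -> list[Peak]:
    """One peak inside the TSS window of each designated occupied gene.

    Background peaks are placed clear of every TSS window so they annotate
    to no gene. Neighboring genes closer than ``window`` to a planted peak
    will also score as occupied — as with real occupancy data.
    """
    rng = np.random.default_rng(seed)
    by_id = {g.gene_id: g for g in genes}
    peaks: list[Peak] = []
    for gid in occupied_gene_ids:
        g = by_id[gid]
        center = g.tss.start + int(rng.integers(-(window - 2000), window - 2000))
        start = max(0, center - peak_width // 2)
        peaks.append(
            Peak(
                GenomicInterval(chrom, start, start + peak_width),
                name=f"{factor}_{gid}",
                score=10.0,
            )
        )
    tss_sorted = np.sort(np.array([g.tss.start for g in genes], dtype=np.int64))
    placed = 0
    attempts = 0
    while placed < n_background:
        attempts += 1
        if attempts > 200 * max(1, n_background):
            break
        s = int(rng.integers(0, genome_length - peak_width))
        j = int(np.searchsorted(tss_sorted, s))
        near = []
        if j > 0:
            near.append(abs(s - int(tss_sorted[j - 1])))
        if j < len(tss_sorted):
            near.append(abs(int(tss_sorted[j]) - s))
        if near and min(near) < window + peak_width + 1000:
            continue
        peaks.append(
            Peak(
                GenomicInterval(chrom, s, s + peak_width),
                name=f"{factor}_bg{placed:03d}",
                score=5.0,
            )
        )
        placed += 1
    peaks.sort(key=lambda p: (p.interval.start, p.interval.end))
    return peaks


def simulate_dependent_peaks(
    n_ref: int = 200,
    n_lost: int = 40,
    n_gained: int = 20,
    genome_length: int = 10_000_000,
    chrom: str = "chrS",
    seed: int = 1,
    factor: str = "BRD4",
) -> tuple[list[Peak], list[Peak], list[str]]:
    """A reference peak set and an altered set missing ``n_lost`` peaks.

    Retained peaks are jittered by up to 150 bp (still overlapping their
    reference peak); gained peaks avoid every reference peak so they can
    never rescue a planted loss. Returns (ref, alt, lost peak names).
    """
    if not 0 <= n_lost <= n_ref:
        raise ValueError("n_lost must be within [0, n_ref]")
    rng = np.random.default_rng(seed)
    widths = rng.integers(300, 1201, size=n_ref)
    starts = _layout(widths, genome_length, min_sep=1000, margin=10_000, rng=rng)
    ref = [
        Peak(
            GenomicInterval(chrom, int(s), int(s + w)),
            name=f"{factor}_{i:03d}",
            score=8.0,
        )
        for i, (s, w) in enumerate(zip(starts, widths))
    ]
    lost_idx = set(int(i) for i in rng.choice(n_ref, size=n_lost, replace=False))
    alt: list[Peak] = []
    for i, p in enumerate(ref):
        if i in lost_idx:
            continue
        shift = int(rng.integers(-150, 151))
        iv = p.interval
        s = max(0, iv.start + shift)
        alt.append(
            Peak(GenomicInterval(chrom, s, s + iv.width), name=f"{factor}ko_{i:03d}", score=8.0)
        )
    ref_starts = np.array([p.interval.start for p in ref], dtype=np.int64)
    ref_ends = np.array([p.interval.end for p in ref], dtype=np.int64)
    placed = 0
    attempts = 0
    while placed < n_gained:
        attempts += 1
        if attempts > 200 * max(1, n_gained):
            break
        w = int(rng.integers(300, 1201))
        s = int(rng.integers(0, genome_length - w))
        ov = np.minimum(ref_ends, s + w) - np.maximum(ref_starts, s)
        if np.any(ov > -500):  # keep a 500 bp moat around reference peaks
            continue
        alt.append(
            Peak(GenomicInterval(chrom, s, s + w), name=f"{factor}ko_gain{placed:03d}", score=8.0)
        )
        placed += 1
    alt.sort(key=lambda p: (p.interval.start, p.interval.end))
    lost_names = [ref[i].name for i in sorted(lost_idx)]
    return ref, alt, lost_names


def simulate_counts(
    gene_ids: Sequence[str],
    cells_per_cluster: dict,
    dispersion: float = 0.5,
    markers: Sequence[PlantedMarker] = (),
    degs: Sequence[PlantedDEG] = (),
    base_log_mean: float = -1.0,
    base_log_sigma: float = 1.0,
    seed: int = 1,
) -> CountMatrix:
    """Negative-binomial counts with planted markers and condition DEGs.

    ``cells_per_cluster`` maps cluster -> cell count (single condition
    "WT") or cluster -> {condition: cell count}. Per-gene base means are
    log-normal; a planted marker multiplies its gene's mean in the target
    cluster by ``fold``; a planted DEG multiplies (direction 'up') or
    divides ('down') the mean in (cluster, condition) cells. Planted genes
    may override their base mean so the effect is detectable at the planted
    fold. NB variance is mu + dispersion * mu^2.
    """
    if dispersion <= 0:
        raise ValueError("dispersion must be positive")
    if len(cells_per_cluster) < 2:
        raise ValueError("need at least 2 clusters")
    rng = np.random.default_rng(seed)
    gene_ids = list(gene_ids)
    gene_index = {g: i for i, g in enumerate(gene_ids)}
    G = len(gene_ids)

    cell_ids: list[str] = []
    clusters: list[str] = []
    conditions: list[str] = []
    for cluster in sorted(cells_per_cluster):
        spec = cells_per_cluster[cluster]
        if isinstance(spec, int):
            spec = {"WT": spec}
        for cond in sorted(spec):
            for i in range(spec[cond]):
                cell_ids.append(f"{cluster}.{cond}.{i:04d}")
                clusters.append(cluster)
                conditions.append(cond)
    n_cells = len(cell_ids)
    clusters_arr = np.array(clusters)
    conditions_arr = np.array(conditions)

    base = rng.lognormal(base_log_mean, base_log_sigma, size=G)
    for planted in list(markers) + list(degs):
        if planted.base_mean is not None:
            base[gene_index[planted.gene_id]] = planted.base_mean
    mu = np.tile(base[:, None], (1, n_cells))
    for m in markers:
        mu[gene_index[m.gene_id], clusters_arr == m.cluster] *= m.fold
    for d in degs:
        mask = (clusters_arr == d.cluster) & (conditions_arr == d.condition)
        if d.direction == "up":
            mu[gene_index[d.gene_id], mask] *= d.fold
        elif d.direction == "down":
            mu[gene_index[d.gene_id], mask] /= d.fold
        else:
            raise ValueError(f"direction must be 'up' or 'down', got {d.direction!r}")

    r = 1.0 / dispersion
    p = r / (r + mu)
    counts = rng.negative_binomial(r, p)
    return CountMatrix(
        sparse.csr_matrix(counts), gene_ids, cell_ids, clusters, conditions
    )


def simulate_3c(
    true_if: dict,
    distances_kb: dict,
    control_fragment: str = "SR",
    cv: float = 0.1,
    n_replicates: int = 4,
    control_quantity: float = 1000.0,
    seed: int = 1,
) -> pd.DataFrame:
    """qPCR quantities log-normally scattered around true interaction
    frequencies.

    ``true_if`` maps condition -> {fragment -> IF percent}; the control
    fragment must carry a true IF of exactly 100 in every condition.
    Multiplicative log-normal noise has coefficient of variation ``cv``
    (``cv=0`` is the exact noise-free limit; negative raises).
    """
    if cv < 0:
        raise ValueError("cv must be >= 0")
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    for cond, frags in true_if.items():
        if frags.get(control_fragment) != 100:
            raise ValueError(
                f"control fragment {control_fragment!r} must have true IF 100 "
                f"in condition {cond!r}"
            )
    rng = np.random.default_rng(seed)
    sigma = float(np.sqrt(np.log1p(cv**2)))
    rows = []
    for cond in sorted(true_if):
        for rep in range(1, n_replicates + 1):
            for frag in sorted(true_if[cond]):
                q = control_quantity * true_if[cond][frag] / 100.0
                if sigma > 0:
                    q *= float(rng.lognormal(-sigma**2 / 2, sigma))
                rows.append(
                    {
                        "fragment_id": frag,
                        "distance_kb": float(distances_kb[frag]),
                        "condition": cond,
                        "replicate": rep,
                        "quantity": q,
                    }
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# the "ocfate" preset: one coherent synthetic study
# ---------------------------------------------------------------------------

_3C_DISTANCES = {"SR": 2.0, "F1": 5.0, "E2": 10.0, "E3": 21.0, "F4": 30.0, "F5": 45.0}
_3C_TRUE_IF = {
    "WT_0h": {"SR": 100, "F1": 40.0, "E2": 20.0, "E3": 15.0, "F4": 8.0, "F5": 5.0},
    "WT_RANKL": {"SR": 100, "F1": 45.0, "E2": 60.0, "E3": 45.0, "F4": 9.0, "F5": 5.0},
    "KO_RANKL": {"SR": 100, "F1": 42.0, "E2": 22.0, "E3": 16.0, "F4": 8.0, "F5": 5.0},
}


def simulate_ocfate(
    out_dir: str | os.PathLike,
    seed: int = 1,
    n_se: int = 20,
    n_typical: int = 400,
    signal_ratio: float = 20.0,
    n_genes: int = 300,
    assign_window: int = 50000,
) -> tuple[GroundTruthManifest, dict[str, str]]:
    """Generate the full coherent synthetic study into ``out_dir``.

    Emits the enhancer landscape, an ARID1A-style occupancy peak set, a
    reference/knockout BRD4-style peak pair with planted losses, an
    scRNA-seq count matrix with planted markers and condition DEGs, a
    3C-qPCR table and a lineage gene-set file, plus ``manifest.json``. The
    designated nominated target is, by construction, the only gene that is
    SE-associated, occupied and down-regulated within the lineage gene set:
    down-DEG decoys are drawn only from genes farther than
    ``assign_window`` + 5 kb from every planted SE locus.
    """
    out_dir = os.fspath(out_dir)
    os.makedirs(out_dir, exist_ok=True)
    master = np.random.default_rng(seed)
    sub = master.integers(0, 2**31 - 1, size=6)

    land = simulate_enhancer_landscape(
        n_se=n_se,
        n_typical=n_typical,
        signal_ratio=signal_ratio,
        n_genes=n_genes,
        seed=int(sub[0]),
    )
    paths = land.save(out_dir)

    rng = np.random.default_rng(int(sub[1]))
    se_target_genes = [l.gene_id for l in land.se_loci]
    other_genes = [g.gene_id for g in land.genes if g.gene_id not in se_target_genes]
    occupied = sorted(
        se_target_genes[: max(1, len(se_target_genes) // 2)]
        + [str(x) for x in rng.choice(other_genes, size=50, replace=False)]
    )
    arid1a = simulate_occupancy_peaks(
        land.genes, occupied, window=assign_window, seed=int(sub[1]), chrom=land.chrom
    )
    from .io import write_narrowpeak

    paths["arid1a"] = os.path.join(out_dir, "arid1a.narrowPeak")
    write_narrowpeak(arid1a, paths["arid1a"])

    ref, alt, lost = simulate_dependent_peaks(seed=int(sub[2]), chrom=land.chrom)
    paths["brd4_ref"] = os.path.join(out_dir, "brd4_wt.narrowPeak")
    paths["brd4_alt"] = os.path.join(out_dir, "brd4_ko.narrowPeak")
    write_narrowpeak(ref, paths["brd4_ref"])
    write_narrowpeak(alt, paths["brd4_alt"])

    # genes geometrically clear of every SE locus: safe DEG decoys
    clearance = assign_window + 5000
    far_genes = [
        g.gene_id
        for g in land.genes
        if all(
            g.tss.start < l.start - clearance or g.tss.start >= l.end + clearance
            for l in land.se_loci
        )
    ]
    target = [g for g in se_target_genes if g in set(occupied)][0]
    rng2 = np.random.default_rng(int(sub[3]))
    decoy_pool = [g for g in far_genes if g != target]
    picked = [str(x) for x in rng2.choice(decoy_pool, size=30, replace=False)]
    up_decoys, down_decoys, marker_genes = picked[:10], picked[10:20], picked[20:30]

    # base means chosen so planted up and down effects shift per-cell
    # library size by equal and opposite amounts (up: +m(f-1) per gene,
    # down with base m*f: -m(f-1)), avoiding composition-bias DEGs
    deg_cluster, deg_condition = "cycOC", "KO"
    degs = [
        PlantedDEG(target, deg_cluster, "down", 4.0, deg_condition, base_mean=8.0)
    ]
    degs += [
        PlantedDEG(g, deg_cluster, "up", 3.0, deg_condition, base_mean=2.0)
        for g in up_decoys
    ]
    degs += [
        PlantedDEG(g, deg_cluster, "down", 3.0, deg_condition, base_mean=6.0)
        for g in down_decoys
    ]
    markers = [
        PlantedMarker(g, "preOC", 4.0, base_mean=2.0) for g in marker_genes
    ]
    matrix = simulate_counts(
        [g.gene_id for g in land.genes],
        cells_per_cluster={
            "mono": {"WT": 150, "KO": 150},
            "cycOC": {"WT": 150, "KO": 150},
            "preOC": {"WT": 100, "KO": 100},
        },
        markers=markers,
        degs=degs,
        seed=int(sub[4]),
    )
    paths["counts_mtx"] = os.path.join(out_dir, "counts.mtx")
    paths["counts_genes"] = os.path.join(out_dir, "genes.tsv")
    paths["counts_cells"] = os.path.join(out_dir, "cells.tsv")
    matrix.save(paths["counts_mtx"], paths["counts_genes"], paths["counts_cells"])

    table = simulate_3c(_3C_TRUE_IF, _3C_DISTANCES, cv=0.1, n_replicates=4, seed=int(sub[5]))
    paths["three_c"] = os.path.join(out_dir, "three_c.tsv")
    table.to_csv(paths["three_c"], sep="\t", index=False)

    oc_gene_set = sorted(
        {target}
        | set(up_decoys)
        | set(str(x) for x in rng2.choice(decoy_pool, size=10, replace=False))
    )
    paths["oc_gene_set"] = os.path.join(out_dir, "oc_genes.txt")
    with open(paths["oc_gene_set"], "w") as fh:
        for g in oc_gene_set:
            fh.write(g + "\n")

    manifest = GroundTruthManifest(
        seed=seed,
        chrom=land.chrom,
        planted_se_loci=land.se_loci,
        planted_typical_enhancers=land.typical,
        planted_dependent_peaks=lost,
        planted_markers=markers,
        planted_condition_degs=degs,
        three_c_true_if=_3C_TRUE_IF,
        occupied_gene_ids=occupied,
        oc_gene_set=oc_gene_set,
        expected_nominated=[target],
    )
    paths["manifest"] = os.path.join(out_dir, "manifest.json")
    manifest.save(paths["manifest"])
    return manifest, paths
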