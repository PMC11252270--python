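"""Super-enhancer chain: promoter exclusion, quantification, inflection
cutoff and gene assignment."""
import filecmp

import numpy as np
import pytest

from secanalyze.coverage import CoverageTrack
from secanalyze.intervals import GeneAnnotation, GenomicInterval, Peak
from secanalyze.se import (
    SEConfig,
    StitchedEnhancer,
    assign_genes_to_ses,
    call_superenhancers,
    exclude_promoter_regions,
    quantify_region_signal,
    rank_signal_cutoff,
    run_se_pipeline,
)


def gene(gid, tss, active=True, chrom="chrS"):
    return GeneAnnotation(gid, gid, GenomicInterval(chrom, tss, tss + 1), active)


def peak(start, end, chrom="chrS", name="."):
    return Peak(GenomicInterval(chrom, start, end), name=name)


def flat_track(value, length=1_000_000, total=1e6, chrom="chrS"):
    return CoverageTrack(
        {chrom: (np.array([0]), np.array([length]), np.array([float(value)]))}, total
    )


class TestPromoterExclusion:
    def test_contained_peak_excluded_partial_retained(self):
        genes = [gene("g", 10200)]
        contained = peak(10000, 10400)
        partial = peak(7000, 13000)
        out = exclude_promoter_regions([contained, partial], genes, 2500)
        assert out == [partial]

    def test_empty_gene_set_warns_and_passes_through(self):
        peaks = [peak(0, 100)]
        with pytest.warns(UserWarning, match="empty gene set"):
            assert exclude_promoter_regions(peaks, [], 2500) == peaks

    def test_matches_quadratic_oracle(self):
        rng = np.random.default_rng(17)
        for _ in range(10):
            peaks = [
                peak(int(s), int(s) + int(w))
                for s, w in zip(
                    rng.integers(0, 200_000, 50), rng.integers(100, 8000, 50)
                )
            ]
            genes = [gene(f"g{i}", int(t)) for i, t in enumerate(rng.integers(0, 200_000, 50))]
            flank = 2500
            expected = [
                p
                for p in peaks
                if not any(
                    max(0, g.tss.start - flank) <= p.interval.start
                    and p.interval.end <= g.tss.start + flank
                    for g in genes
                )
            ]
            assert exclude_promoter_regions(peaks, genes, flank) == expected


class TestQuantification:
    def test_closed_form(self):
        chip = flat_track(2.0)
        region = GenomicInterval("chrS", 0, 100)
        sig = quantify_region_signal([region], chip, flat_track(0, total=1e6))
        assert sig[0] == pytest.approx(200.0)

    def test_floor_at_zero(self):
        chip = flat_track(1.0)
        bg = flat_track(5.0)
        sig = quantify_region_signal([GenomicInterval("chrS", 0, 100)], chip, bg)
        assert sig[0] == 0.0

    def test_absent_chromosome_warns_zero(self):
        chip = flat_track(2.0)
        with pytest.warns(UserWarning, match="absent"):
            sig = quantify_region_signal(
                [GenomicInterval("chrZ", 0, 100)], chip, flat_track(0.1)
            )
        assert sig[0] == 0.0

    def test_matches_per_base_brute_force(self):
        rng = np.random.default_rng(23)
        for _ in range(5):
            # random piecewise tracks over a 10 kb toy chromosome
            bounds = np.sort(rng.choice(np.arange(1, 10_000), size=30, replace=False))
            starts = np.concatenate([[0], bounds])
            ends = np.concatenate([bounds, [10_000]])
            cvals = rng.integers(0, 6, size=len(starts)).astype(float)
            ivals = rng.integers(0, 3, size=len(starts)).astype(float)
            chip = CoverageTrack({"chrS": (starts, ends, cvals)}, 5e5)
            bg = CoverageTrack({"chrS": (starts, ends, ivals)}, 3e5)
            chip_bp = np.repeat(cvals, ends - starts)
            bg_bp = np.repeat(ivals, ends - starts)
            regions = []
            for _ in range(20):
                a, b = sorted(rng.integers(0, 10_000, size=2))
                if a < b:
                    regions.append(GenomicInterval("chrS", int(a), int(b)))
            got = quantify_region_signal(regions, chip, bg)
            for r, g in zip(regions, got):
                expected = max(
                    0.0,
                    chip_bp[r.start : r.end].sum() / 5e5 * 1e6
                    - bg_bp[r.start : r.end].sum() / 3e5 * 1e6,
                )
                assert g == pytest.approx(expected, abs=1e-9)


def enhancers_from_signals(signals, chrom="chrS"):
    return [
        StitchedEnhancer(
            region=GenomicInterval(chrom, 1000 * i, 1000 * i + 500),
            signal_rpm=float(s),
        )
        for i, s in enumerate(signals)
    ]


def tangent_scan_oracle(sorted_signals):
    """Independent O(n^2) scan: the cutoff is the largest-rank point whose
    slope-1 line (in min-max scaled coordinates) supports the curve from
    below."""
    s = np.asarray(sorted_signals, dtype=float)
    n = len(s)
    lo, hi = s[0], s[-1]
    if hi == lo:
        return n, True
    x = np.arange(n) / (n - 1)
    y = (s - lo) / (hi - lo)
    candidates = [
        i
        for i in range(n)
        if all(y[j] - x[j] >= y[i] - x[i] - 1e-12 for j in range(n))
    ]
    cutoff = max(candidates) + 1
    degenerate = max(x - y) <= 1e-12
    return (n, True) if degenerate else (cutoff, False)


class TestInflectionCutoff:
    def test_single_outlier_is_the_only_super(self):
        result = call_superenhancers(enhancers_from_signals([1, 1, 1, 1, 100]))
        flags = [e.is_super for e in sorted(result.enhancers, key=lambda e: e.rank)]
        assert flags == [False, False, False, False, True]
        assert result.cutoff_rank == 4

    def test_linear_curve_is_degenerate(self):
        result = call_superenhancers(enhancers_from_signals([1, 2, 3, 4, 5]))
        assert result.degenerate
        assert result.n_super == 0

    def test_identical_signals_degenerate(self):
        result = call_superenhancers(enhancers_from_signals([3, 3, 3, 3]))
        assert result.degenerate
        assert result.n_super == 0

    def test_too_few_enhancers_rejected(self):
        with pytest.raises(ValueError, match="at least 3"):
            rank_signal_cutoff(np.array([1.0, 2.0]))

    def test_scale_invariance(self):
        rng = np.random.default_rng(9)
        signals = np.concatenate([rng.exponential(1, 95), rng.exponential(1, 5) + 50])
        base = call_superenhancers(enhancers_from_signals(signals))
        scaled = call_superenhancers(enhancers_from_signals(signals * 37.5))
        assert scaled.cutoff_rank == base.cutoff_rank
        assert [e.is_super for e in scaled.enhancers] == [
            e.is_super for e in base.enhancers
        ]

    def test_ranks_are_permutation_and_flag_matches_cutoff(self):
        rng = np.random.default_rng(11)
        result = call_superenhancers(enhancers_from_signals(rng.exponential(1, 40)))
        ranks = sorted(e.rank for e in result.enhancers)
        assert ranks == list(range(1, 41))
        for e in result.enhancers:
            assert e.is_super == (not result.degenerate and e.rank > result.cutoff_rank)

    def test_matches_tangent_scan_oracle(self):
        rng = np.random.default_rng(31)
        for n in range(3, 51):
            for _ in range(3):
                s = np.sort(
                    np.concatenate(
                        [rng.exponential(1, n - max(1, n // 10)),
                         rng.exponential(1, max(1, n // 10)) + 20]
                    )
                )
                assert rank_signal_cutoff(s) == tangent_scan_oracle(s)

    def test_adding_a_minimum_rarely_disturbs_calls(self):
        # discrete-geometry edge: prepending one below-minimum enhancer
        # should almost never remove an existing SE call
        rng = np.random.default_rng(13)
        violations = 0
        for _ in range(100):
            signals = np.concatenate(
                [rng.exponential(1, 190), rng.exponential(1, 10) + 30]
            )
            before = call_superenhancers(enhancers_from_signals(signals))
            ses_before = {str(e.region) for e in before.superenhancers}
            extended = np.concatenate([signals, [signals.min() / 2]])
            after = call_superenhancers(enhancers_from_signals(extended))
            ses_after = {str(e.region) for e in after.superenhancers}
            if not ses_before <= ses_after:
                violations += 1
        assert violations < 1


class TestGeneAssignment:
    def make_se(self, start, end):
        return StitchedEnhancer(
            region=GenomicInterval("chrS", start, end), signal_rpm=10.0, is_super=True
        )

    def test_window_measured_from_edges(self):
        se = self.make_se(100_000, 120_000)
        a = assign_genes_to_ses([se], [gene("near", 160_000)], 50_000)
        assert a.genes == ("near",)
        b = assign_genes_to_ses([se], [gene("far", 170_001)], 50_000)
        assert b.genes == ()

    def test_inactive_genes_never_assigned(self):
        se = self.make_se(100_000, 120_000)
        a = assign_genes_to_ses([se], [gene("off", 100_500, active=False)], 50_000)
        assert a.genes == ()

    def test_flattened_list_deduplicated_sorted(self):
        ses = [self.make_se(0, 1000), self.make_se(5000, 6000)]
        genes = [gene("b", 2000), gene("a", 3000)]
        a = assign_genes_to_ses(ses, genes, 50_000)
        assert a.genes == ("a", "b")
        assert set(a.per_se) == {"chrS:0-1000", "chrS:5000-6000"}


class TestPipeline:
    def test_empty_peak_set_is_handled(self):
        result = run_se_pipeline(
            [], [gene("g", 1000)], flat_track(1.0), flat_track(0.5)
        )
        assert result.call.n_enhancers == 0
        assert result.call.n_super == 0
        assert result.assignment.genes == ()

    def test_rerun_outputs_byte_identical(self, tmp_path, landscape):
        for d in ("a", "b"):
            run_se_pipeline(
                landscape.peaks,
                landscape.genes,
                landscape.chip,
                landscape.input_track,
                SEConfig(),
                out_dir=tmp_path / d,
            )
        for name in ("stitched.bed", "superenhancers.bed", "ranked_signal.tsv", "se_genes.tsv"):
            assert filecmp.cmp(tmp_path / "a" / name, tmp_path / "b" / name, shallow=False)

    def test_signal_additivity_over_partition(self):
        # with zero input, the signal of a union equals the sum over a
        # partition of it
        chip = flat_track(2.0)
        bg = flat_track(0, total=1e6)
        whole = GenomicInterval("chrS", 0, 3000)
        parts = [
            GenomicInterval("chrS", 0, 1000),
            GenomicInterval("chrS", 1000, 2500),
            GenomicInterval("chrS", 2500, 3000),
        ]
        total = quantify_region_signal([whole], chip, bg)[0]
        assert sum(quantify_region_signal(parts, chip, bg)) == pytest.approx(total)


def test_config_validation():
    with pytest.raises(ValueError):
        SEConfig(promoter_flank=0)
    with pytest.raises(ValueError):
        SEConfig(stitch_gap=-1)
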