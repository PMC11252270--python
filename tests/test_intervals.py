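"""Interval model, merging/stitching algebra and format round-trips."""
import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from secanalyze import io as sio
from secanalyze.intervals import (
    GeneAnnotation,
    GenomicInterval,
    Peak,
    merge_within,
    overlap_length,
    overlaps,
)


@pytest.mark.parametrize(
    "kwargs",
    [
        dict(chrom="", start=0, end=10),
        dict(chrom="chr1", start=-1, end=10),
        dict(chrom="chr1", start=10, end=10),
        dict(chrom="chr1", start=10, end=5),
        dict(chrom="chr1", start=0, end=10, strand="x"),
    ],
)
def test_interval_validation(kwargs):
    with pytest.raises(ValueError):
        GenomicInterval(**kwargs)


def test_peak_summit_bounds():
    iv = GenomicInterval("chr1", 100, 200)
    assert Peak(iv, summit_offset=0).summit_offset == 0
    assert Peak(iv, summit_offset=99).summit_offset == 99
    with pytest.raises(ValueError):
        Peak(iv, summit_offset=100)


def test_gene_annotation_requires_width_one_tss():
    with pytest.raises(ValueError):
        GeneAnnotation("g", "g", GenomicInterval("chr1", 0, 2))


class TestMergeWithin:
    def test_gap_threshold_is_inclusive(self):
        ivs = [GenomicInterval("chr1", 0, 100), GenomicInterval("chr1", 150, 200)]
        assert merge_within(ivs, 50) == [GenomicInterval("chr1", 0, 200)]
        ivs2 = [GenomicInterval("chr1", 0, 100), GenomicInterval("chr1", 151, 200)]
        assert len(merge_within(ivs2, 50)) == 2

    def test_chromosomes_never_merge(self):
        ivs = [GenomicInterval("chr1", 0, 100), GenomicInterval("chr2", 0, 100)]
        assert len(merge_within(ivs, 10**9)) == 2

    def test_negative_gap_rejected(self):
        with pytest.raises(ValueError):
            merge_within([GenomicInterval("chr1", 0, 1)], -1)


def _random_intervals(rng, n, span=100_000):
    starts = rng.integers(0, span, size=n)
    widths = rng.integers(1, 2000, size=n)
    return [GenomicInterval("chrS", int(s), int(s + w)) for s, w in zip(starts, widths)]


def brute_force_stitch(intervals, max_gap):
    """Transitive-closure oracle: connected components of the gap graph."""
    from scipy.sparse import csr_matrix
    from scipy.sparse.csgraph import connected_components

    n = len(intervals)
    s = np.array([iv.start for iv in intervals])
    e = np.array([iv.end for iv in intervals])
    adj = (s[:, None] <= e[None, :] + max_gap) & (s[None, :] <= e[:, None] + max_gap)
    _, labels = connected_components(csr_matrix(adj), directed=False)
    out = []
    for lab in np.unique(labels):
        sel = labels == lab
        out.append(GenomicInterval("chrS", int(s[sel].min()), int(e[sel].max())))
    return sorted(out, key=lambda iv: iv.start)


@pytest.mark.parametrize("max_gap", [0, 100, 5000])
def test_merge_matches_transitive_closure(max_gap):
    rng = np.random.default_rng(42)
    for _ in range(20):
        ivs = _random_intervals(rng, int(rng.integers(2, 80)))
        assert merge_within(ivs, max_gap) == brute_force_stitch(ivs, max_gap)


@given(
    st.lists(
        st.tuples(st.integers(0, 50_000), st.integers(1, 3000)), min_size=1, max_size=40
    ),
    st.integers(0, 10_000),
    st.randoms(),
)
def test_merge_idempotent_and_order_independent(pairs, max_gap, rnd):
    ivs = [GenomicInterval("chrS", s, s + w) for s, w in pairs]
    merged = merge_within(ivs, max_gap)
    # idempotent
    assert merge_within(merged, max_gap) == merged
    # permutation-invariant
    shuffled = list(ivs)
    rnd.shuffle(shuffled)
    assert merge_within(shuffled, max_gap) == merged
    # output gaps strictly exceed max_gap
    for a, b in zip(merged, merged[1:]):
        assert b.start - a.end > max_gap
    # union preserved: every input interval is contained in some output
    for iv in ivs:
        assert any(m.start <= iv.start and iv.end <= m.end for m in merged)


class TestOverlaps:
    def test_basic_and_adjacency(self):
        a = GenomicInterval("chr1", 0, 10)
        assert overlaps(a, GenomicInterval("chr1", 9, 20))
        assert not overlaps(a, GenomicInterval("chr1", 10, 20))
        assert not overlaps(a, GenomicInterval("chr2", 0, 10))

    def test_min_bp(self):
        a = GenomicInterval("chr1", 0, 10)
        b = GenomicInterval("chr1", 5, 20)
        assert overlap_length(a, b) == 5
        assert overlaps(a, b, min_bp=5)
        assert not overlaps(a, b, min_bp=6)
        with pytest.raises(ValueError):
            overlaps(a, b, min_bp=0)


class TestReaders:
    def test_bed_field_mapping_and_sorting(self, tmp_path):
        path = tmp_path / "x.bed"
        path.write_text("chr2\t5\t50\tp3\t1\nchr1\t100\t200\tp1\t5\nchr1\t10\t20\tp2\t2\n")
        peaks = sio.read_intervals(path, "bed")
        assert [p.name for p in peaks] == ["p2", "p1", "p3"]
        assert peaks[1].interval == GenomicInterval("chr1", 100, 200)
        assert peaks[1].score == 5

    def test_gff3_one_based_conversion(self, tmp_path):
        path = tmp_path / "x.gff3"
        path.write_text("##gff-version 3\nchr1\tsrc\tregion\t101\t200\t.\t+\t.\tID=r1\n")
        (peak,) = sio.read_intervals(path, "gff3")
        assert (peak.interval.start, peak.interval.end) == (100, 200)

    def test_parse_error_names_line(self, tmp_path):
        path = tmp_path / "bad.bed"
        path.write_text("chr1\t0\t10\nchr1\tnope\t20\n")
        with pytest.raises(sio.ParseError, match=r"bad\.bed:2"):
            sio.read_intervals(path, "bed")

    def test_inverted_coordinates_rejected(self, tmp_path):
        path = tmp_path / "bad.gff3"
        path.write_text("chr1\tsrc\tregion\t201\t200\t.\t+\t.\tID=r1\n")
        with pytest.raises(sio.ParseError, match="end <= start"):
            sio.read_intervals(path, "gff3")

    @pytest.mark.parametrize("fmt,writer", [("bed", sio.write_bed), ("narrowPeak", sio.write_narrowpeak)])
    def test_round_trip_coordinates_exact(self, tmp_path, fmt, writer):
        rng = np.random.default_rng(3)
        peaks = [
            Peak(iv, name=f"p{i}", score=float(i), summit_offset=(i % iv.width) if fmt == "narrowPeak" else None)
            for i, iv in enumerate(_random_intervals(rng, 30))
        ]
        peaks.sort(key=lambda p: (p.interval.chrom, p.interval.start, p.interval.end, p.name))
        path = tmp_path / f"x.{fmt}"
        writer(peaks, path)
        back = sio.read_intervals(path, fmt)
        assert [(p.interval, p.name, p.score) for p in back] == [
            (p.interval, p.name, p.score) for p in peaks
        ]
        if fmt == "narrowPeak":
            assert [p.summit_offset for p in back] == [p.summit_offset for p in peaks]
        # write-read-write is byte stable
        path2 = tmp_path / f"y.{fmt}"
        writer(back, path2)
        assert path.read_bytes() == path2.read_bytes()


class TestGeneAnnotationIO:
    def test_round_trip_with_flags_and_strand(self, tmp_path):
        genes = [
            GeneAnnotation("g1", "Alpha", GenomicInterval("chrS", 100, 101, "+"), True),
            GeneAnnotation("g2", "Beta", GenomicInterval("chrS", 500, 501, "-"), False),
        ]
        path = tmp_path / "g.gff3"
        sio.write_gene_annotation(genes, path)
        back = sio.read_gene_annotation(path)
        assert back == genes

    def test_minus_strand_tss_is_feature_end(self, tmp_path):
        path = tmp_path / "g.gff3"
        path.write_text("chr1\tsrc\tgene\t101\t300\t.\t-\t.\tID=g1\n")
        (g,) = sio.read_gene_annotation(path)
        assert g.tss.start == 299  # 0-based position of the 1-based end

    def test_duplicate_gene_id_rejected(self, tmp_path):
        path = tmp_path / "g.gff3"
        path.write_text(
            "chr1\tsrc\tgene\t101\t101\t.\t+\t.\tID=g1\n"
            "chr1\tsrc\tgene\t201\t201\t.\t+\t.\tID=g1\n"
        )
        with pytest.raises(sio.ParseError, match="duplicate"):
            sio.read_gene_annotation(path)
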