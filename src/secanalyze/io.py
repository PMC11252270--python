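"""Readers and writers for the flat-text formats the pipeline touches.

Dialects: BED (3-6 columns), narrowPeak (10 columns) and GFF3. All are TSV
with LF line endings; ``#`` comments, GFF3 pragmas and ``track``/``browser``
lines are tolerated on input. GFF3 coordinates (1-based inclusive) are
converted to the internal 0-based half-open convention at this boundary.
Chromosome names are matched as exact strings — no "chr" aliasing.
"""
from __future__ import annotations

import os
from typing import Iterable, Sequence

from .intervals import GeneAnnotation, GenomicInterval, Peak

__all__ = [
    "ParseError",
    "read_intervals",
    "write_bed",
    "write_narrowpeak",
    "read_gene_annotation",
    "write_gene_annotation",
]

_FORMATS = ("bed", "narrowPeak", "gff3")


class ParseError(ValueError):
    """A malformed line in a genomics text file, located by line number."""

    def __init__(self, path: str | os.PathLike, lineno: int, message: str):
        self.path = os.fspath(path)
        self.lineno = lineno
        super().__init__(f"{self.path}:{lineno}: {message}")


def _is_skippable(line: str) -> bool:
    s = line.strip()
    return not s or s.startswith(("#", "track", "browser"))


def _parse_int(field: str, what: str, path, lineno) -> int:
    try:
        return int(field)
    except ValueError:
        raise ParseError(path, lineno, f"non-integer {what}: {field!r}") from None


def _parse_float(field: str, what: str, path, lineno) -> float:
    if field == ".":
        return 0.0
    try:
        return float(field)
    except ValueError:
        raise ParseError(path, lineno, f"non-numeric {what}: {field!r}") from None


def _build_interval(chrom, start, end, strand, path, lineno) -> GenomicInterval:
    if not chrom:
        raise ParseError(path, lineno, "empty chromosome name")
    if end <= start:
        raise ParseError(path, lineno, f"end <= start after conversion ([{start}, {end}))")
    if start < 0:
        raise ParseError(path, lineno, f"negative start: {start}")
    return GenomicInterval(chrom, start, end, strand)


def _parse_bed_line(fields, path, lineno) -> Peak:
    if len(fields) < 3:
        raise ParseError(path, lineno, f"BED needs >= 3 columns, got {len(fields)}")
    start = _parse_int(fields[1], "start", path, lineno)
    end = _parse_int(fields[2], "end", path, lineno)
    name = fields[3] if len(fields) > 3 and fields[3] else "."
    score = _parse_float(fields[4], "score", path, lineno) if len(fields) > 4 else 0.0
    strand = fields[5] if len(fields) > 5 and fields[5] in ("+", "-") else "."
    iv = _build_interval(fields[0], start, end, strand, path, lineno)
    return Peak(iv, name=name, score=score)


def _parse_narrowpeak_line(fields, path, lineno) -> Peak:
    if len(fields) != 10:
        raise ParseError(path, lineno, f"narrowPeak needs 10 columns, got {len(fields)}")
    start = _parse_int(fields[1], "start", path, lineno)
    end = _parse_int(fields[2], "end", path, lineno)
    strand = fields[5] if fields[5] in ("+", "-") else "."
    iv = _build_interval(fields[0], start, end, strand, path, lineno)
    signal = _parse_float(fields[6], "signalValue", path, lineno)
    summit = _parse_int(fields[9], "summit offset", path, lineno)
    if summit == -1:
        summit_offset = None
    elif 0 <= summit < iv.width:
        summit_offset = summit
    else:
        raise ParseError(path, lineno, f"summit offset {summit} outside peak of width {iv.width}")
    return Peak(iv, name=fields[3] or ".", score=signal, summit_offset=summit_offset)


def _parse_gff3_attributes(field: str) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for item in field.split(";"):
        item = item.strip()
        if not item or "=" not in item:
            continue
        key, value = item.split("=", 1)
        attrs[key.strip()] = value.strip()
    return attrs


def _parse_gff3_line(fields, path, lineno) -> tuple[Peak, str, dict[str, str]]:
    if len(fields) != 9:
        raise ParseError(path, lineno, f"GFF3 needs 9 columns, got {len(fields)}")
    start1 = _parse_int(fields[3], "start", path, lineno)
    end1 = _parse_int(fields[4], "end", path, lineno)
    # 1-based inclusive -> 0-based half-open
    start, end = start1 - 1, end1
    strand = fields[6] if fields[6] in ("+", "-") else "."
    iv = _build_interval(fields[0], start, end, strand, path, lineno)
    attrs = _parse_gff3_attributes(fields[8])
    name = attrs.get("ID") or attrs.get("Name") or fields[2]
    score = _parse_float(fields[5], "score", path, lineno)
    return Peak(iv, name=name, score=score), fields[2], attrs


def read_intervals(path: str | os.PathLike, format: str) -> list[Peak]:
    """Read peak records from a BED, narrowPeak or GFF3 file.

    Coordinates are normalized to 0-based half-open regardless of the input
    dialect, and records come back sorted by ``(chrom, start, end)``.
    """
    if format not in _FORMATS:
        raise ValueError(f"format must be one of {_FORMATS}, got {format!r}")
    peaks: list[Peak] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if _is_skippable(line):
                continue
            fields = line.rstrip("\n").split("\t")
            if format == "bed":
                peaks.append(_parse_bed_line(fields, path, lineno))
            elif format == "narrowPeak":
                peaks.append(_parse_narrowpeak_line(fields, path, lineno))
            else:
                peaks.append(_parse_gff3_line(fields, path, lineno)[0])
    peaks.sort(key=lambda p: (p.interval.chrom, p.interval.start, p.interval.end, p.name))
    return peaks


def _fmt_score(score: float) -> str:
    if float(score) == int(score):
        return str(int(score))
    return repr(float(score))


def write_bed(peaks: Iterable[Peak], path: str | os.PathLike) -> None:
    """Write peaks as 6-column BED (chrom, start, end, name, score, strand)."""
    with open(path, "w") as fh:
        for p in peaks:
            iv = p.interval
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{p.name}\t"
                f"{_fmt_score(p.score)}\t{iv.strand}\n"
            )


def write_narrowpeak(peaks: Iterable[Peak], path: str | os.PathLike) -> None:
    """Write peaks as 10-column narrowPeak; score is stored in signalValue."""
    with open(path, "w") as fh:
        for p in peaks:
            iv = p.interval
            summit = -1 if p.summit_offset is None else p.summit_offset
            display = max(0, min(1000, int(round(p.score))))
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{p.name}\t{display}\t"
                f"{iv.strand}\t{_fmt_score(p.score)}\t-1\t-1\t{summit}\n"
            )


_TRUE = {"1", "true", "yes"}
_FALSE = {"0", "false", "no"}


def read_gene_annotation(path: str | os.PathLike) -> list[GeneAnnotation]:
    """Read ``gene`` features from GFF3 into TSS-anchored annotations.

    The TSS is the 5' end of the feature (start for ``+``/unstranded, end
    for ``-``). An ``active`` attribute (1/0, true/false) sets the
    transcriptional-activity flag; absent means active.
    """
    genes: list[GeneAnnotation] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if _is_skippable(line):
                continue
            fields = line.rstrip("\n").split("\t")
            peak, ftype, attrs = _parse_gff3_line(fields, path, lineno)
            if ftype.lower() != "gene":
                continue
            gene_id = attrs.get("ID") or attrs.get("gene_id")
            if not gene_id:
                raise ParseError(path, lineno, "gene feature without ID attribute")
            if gene_id in seen:
                raise ParseError(path, lineno, f"duplicate gene_id {gene_id!r}")
            seen.add(gene_id)
            iv = peak.interval
            tss_pos = iv.end - 1 if iv.strand == "-" else iv.start
            active_raw = attrs.get("active", "1").lower()
            if active_raw in _TRUE:
                active = True
            elif active_raw in _FALSE:
                active = False
            else:
                raise ParseError(path, lineno, f"unparseable active flag {active_raw!r}")
            genes.append(
                GeneAnnotation(
                    gene_id=gene_id,
                    gene_name=attrs.get("Name", gene_id),
                    tss=GenomicInterval(iv.chrom, tss_pos, tss_pos + 1, iv.strand),
                    active=active,
                )
            )
    genes.sort(key=lambda g: (g.tss.chrom, g.tss.start, g.gene_id))
    return genes


def write_gene_annotation(
    genes: Sequence[GeneAnnotation], path: str | os.PathLike
) -> None:
    """Write TSS-anchored gene annotations as minimal GFF3 gene features."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            tss = g.tss
            fh.write(
                f"{tss.chrom}\tsecanalyze\tgene\t{tss.start + 1}\t{tss.start + 1}\t.\t"
                f"{tss.strand}\t.\tID={g.gene_id};Name={g.gene_name};"
                f"active={1 if g.active else 0}\n"
            )
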