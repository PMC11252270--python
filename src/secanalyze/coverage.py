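"""Library-size-aware read-depth tracks backed by bedGraph step functions."""
from __future__ import annotations

import os
import warnings

import numpy as np

from .io import ParseError, _is_skippable

__all__ = ["CoverageTrack"]


class CoverageTrack:
    """Per-chromosome step function of read depth (reads per base pair).

    ``steps`` maps chromosome name to ``(starts, ends, values)`` arrays of
    sorted, non-overlapping 0-based half-open steps; base pairs outside any
    step have depth 0. ``total_mapped_reads`` is the library size used for
    reads-per-million (rpm) scaling.
    """

    def __init__(self, steps: dict, total_mapped_reads: float):
        self.steps: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        for chrom, (s, e, v) in steps.items():
            s = np.asarray(s, dtype=np.int64)
            e = np.asarray(e, dtype=np.int64)
            v = np.asarray(v, dtype=float)
            if not (len(s) == len(e) == len(v)):
                raise ValueError(f"step arrays for {chrom!r} differ in length")
            if np.any(e <= s):
                raise ValueError(f"empty or inverted step on {chrom!r}")
            if np.any(s[1:] < e[:-1]):
                raise ValueError(f"overlapping steps on {chrom!r}")
            if np.any(v < 0):
                raise ValueError(f"negative depth on {chrom!r}")
            self.steps[chrom] = (s, e, v)
        if not total_mapped_reads > 0:
            raise ValueError("total_mapped_reads must be positive")
        self.total_mapped_reads = float(total_mapped_reads)

    @classmethod
    def from_bedgraph(
        cls,
        path: str | os.PathLike,
        total_mapped_reads: float | None = None,
        read_length: float = 50.0,
    ) -> "CoverageTrack":
        """Load a fixed 4-column bedGraph.

        When the library size is not given it is estimated as total covered
        bases divided by ``read_length`` — adequate for tracks whose reads
        each span about one bin, as the synthetic generator emits.
        """
        per_chrom: dict[str, list[tuple[int, int, float]]] = {}
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                if _is_skippable(line):
                    continue
                fields = line.rstrip("\n").split("\t")
                if len(fields) != 4:
                    raise ParseError(path, lineno, f"bedGraph needs 4 columns, got {len(fields)}")
                try:
                    start, end = int(fields[1]), int(fields[2])
                    value = float(fields[3])
                except ValueError:
                    raise ParseError(path, lineno, f"unparseable bedGraph fields {fields[1:]!r}") from None
                if end <= start:
                    raise ParseError(path, lineno, f"end <= start ([{start}, {end}))")
                if value < 0:
                    raise ParseError(path, lineno, f"negative coverage {value}")
                per_chrom.setdefault(fields[0], []).append((start, end, value))
        steps = {}
        for chrom, rows in per_chrom.items():
            rows.sort()
            arr = np.asarray(rows, dtype=float)
            steps[chrom] = (arr[:, 0].astype(np.int64), arr[:, 1].astype(np.int64), arr[:, 2])
        if total_mapped_reads is None:
            covered = sum(float(np.sum(v * (e - s))) for s, e, v in steps.values())
            total_mapped_reads = covered / read_length
            if not total_mapped_reads > 0:
                raise ValueError(f"track {os.fspath(path)!r} has no coverage; cannot infer library size")
        return cls(steps, total_mapped_reads)

    def to_bedgraph(self, path: str | os.PathLike) -> None:
        """Write the track, run-length merging adjacent equal-valued steps."""
        with open(path, "w") as fh:
            for chrom in sorted(self.steps):
                s, e, v = self.steps[chrom]
                cur_s, cur_e, cur_v = int(s[0]), int(e[0]), v[0]
                for i in range(1, len(s)):
                    if s[i] == cur_e and v[i] == cur_v:
                        cur_e = int(e[i])
                    else:
                        fh.write(f"{chrom}\t{cur_s}\t{cur_e}\t{cur_v:g}\n")
                        cur_s, cur_e, cur_v = int(s[i]), int(e[i]), v[i]
                fh.write(f"{chrom}\t{cur_s}\t{cur_e}\t{cur_v:g}\n")

    def has_chrom(self, chrom: str) -> bool:
        return chrom in self.steps

    def region_sum(self, chrom: str, start: int, end: int) -> float:
        """Sum of per-bp depth over ``[start, end)``; uncovered bp count 0."""
        if chrom not in self.steps:
            return 0.0
        s, e, v = self.steps[chrom]
        i0 = int(np.searchsorted(e, start, side="right"))
        i1 = int(np.searchsorted(s, end, side="left"))
        if i0 >= i1:
            return 0.0
        ov = np.minimum(e[i0:i1], end) - np.maximum(s[i0:i1], start)
        return float(np.sum(v[i0:i1] * ov))

    def rpm(self, chrom: str, start: int, end: int) -> float:
        """Region depth sum scaled to reads per million mapped reads."""
        return self.region_sum(chrom, start, end) / self.total_mapped_reads * 1e6
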