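"""Genomic intervals, genome layout, and BED/bedGraph input/output.

All coordinates are 0-based half-open (BED convention). Signal lives on a
fixed grid of ``bin_size`` bp bins per chromosome; a partial terminal bin is
dropped so every track has a fixed, predictable shape.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "GenomicInterval",
    "GenomeLayout",
    "IntervalIndex",
    "BedParseError",
    "read_bed",
    "read_bedgraph",
    "write_predictions_bed",
    "min_distance",
]


class BedParseError(ValueError):
    """Raised for malformed BED/bedGraph records; carries the line number."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A located region on a chromosome, 0-based half-open.

    Parameters
    ----------
    chrom : str
        Chromosome name; non-empty.
    start, end : int
        0 <= start < end, in base pairs.
    name : str, optional
        Free-text label (peak id, validity flag, ...).
    score : float, optional
        Real-valued score (prediction score, peak strength, ...).
    """

    chrom: str
    start: int
    end: int
    name: str | None = field(default=None, compare=False)
    score: float | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"require 0 <= start < end, got [{self.start}, {self.end})"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


@dataclass(frozen=True)
class GenomeLayout:
    """Ordered chromosome sizes plus the fixed signal bin width.

    The last partial bin of each chromosome is dropped: chromosome ``c``
    contributes exactly ``floor(length(c) / bin_size)`` bins.
    """

    chroms: tuple[tuple[str, int], ...]
    bin_size: int = 100

    def __post_init__(self) -> None:
        if self.bin_size <= 0:
            raise ValueError("bin_size must be positive")
        seen = set()
        for chrom, length in self.chroms:
            if not chrom or length <= 0:
                raise ValueError(f"bad chromosome entry ({chrom!r}, {length})")
            if chrom in seen:
                raise ValueError(f"duplicate chromosome {chrom!r}")
            seen.add(chrom)

    @property
    def chrom_names(self) -> tuple[str, ...]:
        return tuple(c for c, _ in self.chroms)

    def length_of(self, chrom: str) -> int:
        for c, length in self.chroms:
            if c == chrom:
                return length
        raise KeyError(f"chromosome {chrom!r} not in layout")

    def n_bins(self, chrom: str) -> int:
        return self.length_of(chrom) // self.bin_size

    def bin_index(self, chrom: str, position: int) -> int:
        """Index of the bin containing ``position``; errors past the grid."""
        idx = position // self.bin_size
        if not (0 <= idx < self.n_bins(chrom)):
            raise ValueError(
                f"position {chrom}:{position} falls outside the binned grid"
            )
        return idx

    def bin_interval(self, chrom: str, bin_idx: int) -> GenomicInterval:
        start = bin_idx * self.bin_size
        return GenomicInterval(chrom, start, start + self.bin_size)


def min_distance(a: GenomicInterval, b: GenomicInterval) -> float:
    """Edge-to-edge distance in bp; 0 when overlapping, +inf across chromosomes."""
    if a.chrom != b.chrom:
        return math.inf
    if a.start < b.end and b.start < a.end:
        return 0.0
    return float(max(a.start, b.start) - min(a.end, b.end))


class IntervalIndex:
    """Sorted per-chromosome index answering nearest edge-to-edge distances.

    Handles overlapping reference intervals via a running maximum of interval
    ends in start order, so queries are O(log n) and exact.
    """

    def __init__(self, intervals: Iterable[GenomicInterval]) -> None:
        by_chrom: dict[str, list[GenomicInterval]] = {}
        self._n = 0
        for iv in intervals:
            by_chrom.setdefault(iv.chrom, []).append(iv)
            self._n += 1
        self._starts: dict[str, np.ndarray] = {}
        self._cummax_end: dict[str, np.ndarray] = {}
        for chrom, ivs in by_chrom.items():
            ivs.sort(key=lambda iv: (iv.start, iv.end))
            starts = np.array([iv.start for iv in ivs], dtype=np.int64)
            ends = np.array([iv.end for iv in ivs], dtype=np.int64)
            self._starts[chrom] = starts
            self._cummax_end[chrom] = np.maximum.accumulate(ends)

    def __len__(self) -> int:
        return self._n

    def nearest_distance(self, query: GenomicInterval) -> float:
        """Distance from ``query`` to the nearest indexed interval."""
        starts = self._starts.get(query.chrom)
        if starts is None:
            return math.inf
        cm_end = self._cummax_end[query.chrom]
        # first indexed interval starting at or after the query end
        i = int(np.searchsorted(starts, query.end, side="left"))
        best = math.inf
        if i < len(starts):
            best = float(starts[i] - query.end)
        if i > 0:
            # any interval before i overlaps iff its (cummax) end > query.start
            left_end = int(cm_end[i - 1])
            if left_end > query.start:
                return 0.0
            best = min(best, float(query.start - left_end))
        return best

    def nearest_distances(self, queries: Sequence[GenomicInterval]) -> np.ndarray:
        return np.array([self.nearest_distance(q) for q in queries], dtype=float)


def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read a 3-6 column BED file into intervals, in file order.

    Lines starting with ``#``, ``track`` or ``browser`` are skipped. Raises
    :class:`BedParseError` naming the offending line for malformed records.
    """
    intervals: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise BedParseError(
                    f"{path}:{lineno}: expected >=3 tab-separated columns"
                )
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise BedParseError(
                    f"{path}:{lineno}: non-integer coordinates"
                ) from exc
            name = fields[3] if len(fields) > 3 and fields[3] != "." else None
            score: float | None = None
            if len(fields) > 4 and fields[4] != ".":
                try:
                    score = float(fields[4])
                except ValueError as exc:
                    raise BedParseError(
                        f"{path}:{lineno}: non-numeric score"
                    ) from exc
            try:
                intervals.append(GenomicInterval(chrom, start, end, name, score))
            except ValueError as exc:
                raise BedParseError(f"{path}:{lineno}: {exc}") from exc
    return intervals


def read_bedgraph(path: str | Path, layout: GenomeLayout, mark: str):
    """Resample a bedGraph coverage file onto the layout's fixed bins.

    Each bin's value is the length-weighted mean of the records overlapping
    it, with uncovered stretches contributing zero — so a record covering
    half a bin at value 8 yields a bin value of 4. Records must lie within
    the layout and must not overlap each other.

    Returns a :class:`~dresnap.features.BinnedSignalTrack`.
    """
    from .features import BinnedSignalTrack  # local import: avoid cycle

    bs = layout.bin_size
    data = {c: np.zeros(layout.n_bins(c)) for c in layout.chrom_names}
    prev_end: dict[str, int] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise BedParseError(
                    f"{path}:{lineno}: expected 4 bedGraph columns"
                )
            chrom = fields[0]
            try:
                start, end, value = int(fields[1]), int(fields[2]), float(fields[3])
            except ValueError as exc:
                raise BedParseError(f"{path}:{lineno}: bad record") from exc
            if chrom not in data:
                raise BedParseError(
                    f"{path}:{lineno}: chromosome {chrom!r} not in layout"
                )
            if start < 0 or end > layout.length_of(chrom) or start >= end:
                raise BedParseError(
                    f"{path}:{lineno}: record [{start}, {end}) outside layout"
                )
            if start < prev_end.get(chrom, 0):
                raise BedParseError(
                    f"{path}:{lineno}: overlapping/unsorted records on {chrom}"
                )
            prev_end[chrom] = end
            vec = data[chrom]
            n = len(vec)
            b0, b1 = start // bs, (end - 1) // bs
            for b in range(b0, min(b1, n - 1) + 1):
                overlap = min(end, (b + 1) * bs) - max(start, b * bs)
                vec[b] += value * overlap / bs
    return BinnedSignalTrack(mark=mark, layout=layout, data=data)


def write_predictions_bed(
    predictions: Sequence[tuple[GenomicInterval, float, bool]],
    path: str | Path,
) -> None:
    """Write scored predictions as BED6: validity in the name field, score in column 5."""
    with open(path, "w") as fh:
        for interval, score, validated in predictions:
            if not math.isfinite(score):
                raise ValueError(f"non-finite score for {interval}")
            label = "validated" if validated else "invalid"
            fh.write(
                f"{interval.chrom}\t{interval.start}\t{interval.end}"
                f"\t{label}\t{score:g}\t.\n"
            )
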