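"""Snapshot feature extraction from binned histone-modification signal.

A classifier example is the signal in a fixed window around one genomic
location: ten 100 bp bins on each side of the anchor bin boundary, for each
mark in the panel. Stacking the per-mark rows gives a (n_marks, 20) matrix —
a "snapshot" of local chromatin state — which flattens row-major to the
480-dimensional vector the flat-input models consume.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .intervals import GenomeLayout, GenomicInterval

__all__ = [
    "DEFAULT_MARK_PANEL",
    "MarkPanel",
    "BinnedSignalTrack",
    "HistoneSnapshot",
    "EdgeError",
    "rpkm",
    "average_replicates",
    "window_bins",
    "extract_snapshot",
    "flatten",
]

# Canonical panel of 24 histone modifications, in fixed order. The classifiers
# are order-sensitive (row i is always the same mark), so this order is part
# of the model contract.
DEFAULT_MARK_PANEL: tuple[str, ...] = (
    "H2AK5ac", "H2BK120ac", "H2BK12ac", "H2BK15ac", "H2BK20ac", "H2BK5ac",
    "H3K14ac", "H3K18ac", "H3K23ac", "H3K27ac", "H3K27me3", "H3K36me3",
    "H3K4ac", "H3K4me1", "H3K4me2", "H3K4me3", "H3K56ac", "H3K79me1",
    "H3K79me2", "H3K9ac", "H3K9me3", "H4K20me1", "H4K5ac", "H4K91ac",
)


class EdgeError(ValueError):
    """A feature window would extend past a chromosome edge."""


@dataclass(frozen=True)
class MarkPanel:
    """Ordered, unique set of mark names defining snapshot row order."""

    marks: tuple[str, ...] = DEFAULT_MARK_PANEL

    def __post_init__(self) -> None:
        if len(set(self.marks)) != len(self.marks):
            raise ValueError("panel marks must be unique")
        if not self.marks:
            raise ValueError("panel must be non-empty")

    def __len__(self) -> int:
        return len(self.marks)

    def __iter__(self):
        return iter(self.marks)


@dataclass
class BinnedSignalTrack:
    """Per-chromosome vectors of binned RPKM values for one mark."""

    mark: str
    layout: GenomeLayout
    data: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        for chrom, vec in self.data.items():
            expected = self.layout.n_bins(chrom)
            if len(vec) != expected:
                raise ValueError(
                    f"{self.mark}/{chrom}: {len(vec)} bins, layout says {expected}"
                )
            if not np.all(np.isfinite(vec)) or np.any(vec < 0):
                raise ValueError(f"{self.mark}/{chrom}: RPKM must be finite and >= 0")


@dataclass(frozen=True)
class HistoneSnapshot:
    """(n_marks, n_bins) matrix of RPKM around one location.

    Rows follow the panel's canonical mark order; columns are bins in genomic
    order. Permuting rows is a different snapshot.
    """

    values: np.ndarray
    anchor: GenomicInterval
    marks: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.values.ndim != 2 or self.values.shape[0] != len(self.marks):
            raise ValueError(
                f"snapshot shape {self.values.shape} inconsistent with "
                f"{len(self.marks)} marks"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


def rpkm(read_count: int, bin_length: int, total_mapped_reads: int) -> float:
    """Reads per kilobase of bin per million mapped reads.

    ``read_count / ((bin_length/1000) * (total_mapped_reads/1e6))``
    """
    if bin_length <= 0:
        raise ValueError("bin_length must be positive")
    if total_mapped_reads <= 0:
        raise ValueError("total_mapped_reads must be positive")
    if read_count < 0:
        raise ValueError("read_count must be non-negative")
    return read_count / ((bin_length / 1000.0) * (total_mapped_reads / 1e6))


def average_replicates(tracks: Sequence[BinnedSignalTrack]) -> BinnedSignalTrack:
    """Element-wise mean of replicate tracks for one mark."""
    if not tracks:
        raise ValueError("need at least one replicate track")
    first = tracks[0]
    for t in tracks[1:]:
        if t.mark != first.mark:
            raise ValueError(f"mark mismatch: {t.mark!r} vs {first.mark!r}")
        if t.layout != first.layout:
            raise ValueError("replicate layouts differ")
    data = {
        chrom: np.mean([t.data[chrom] for t in tracks], axis=0)
        for chrom in first.data
    }
    return BinnedSignalTrack(mark=first.mark, layout=first.layout, data=data)


def window_bins(
    location: GenomicInterval,
    layout: GenomeLayout | None = None,
    flank: int = 1000,
    bin_size: int = 100,
    n_bins_chrom: int | None = None,
) -> np.ndarray:
    """Bin indices of the feature window around an anchor bin.

    The window spans ``flank/bin_size`` bins to the left of the anchor bin's
    start plus the same count starting at the anchor bin — 20 consecutive
    indices at the defaults (flank 1000 bp, bins 100 bp). Raises
    :class:`EdgeError` when the window would leave the chromosome, in which
    case callers skip the location.
    """
    if layout is not None:
        bin_size = layout.bin_size
        n_bins_chrom = layout.n_bins(location.chrom)
    if flank % bin_size != 0:
        raise ValueError("flank must be divisible by bin_size")
    if location.start % bin_size != 0:
        raise ValueError(
            f"anchor {location.chrom}:{location.start} not on a bin boundary"
        )
    half = flank // bin_size
    anchor_bin = location.start // bin_size
    lo, hi = anchor_bin - half, anchor_bin + half
    if lo < 0 or (n_bins_chrom is not None and hi > n_bins_chrom):
        raise EdgeError(
            f"window around {location.chrom}:{location.start} exceeds chromosome"
        )
    return np.arange(lo, hi)


def extract_snapshot(
    tracks: Mapping[str, BinnedSignalTrack],
    location: GenomicInterval,
    panel: MarkPanel | None = None,
    flank: int = 1000,
) -> HistoneSnapshot:
    """Stack per-mark window signal into a (|panel|, 2*flank/bin) snapshot."""
    panel = panel or MarkPanel()
    missing = [m for m in panel if m not in tracks]
    if missing:
        raise KeyError(f"panel marks missing from tracks: {missing}")
    any_track = tracks[panel.marks[0]]
    idx = window_bins(location, layout=any_track.layout, flank=flank)
    rows = np.stack(
        [tracks[m].data[location.chrom][idx] for m in panel], axis=0
    )
    return HistoneSnapshot(values=rows, anchor=location, marks=tuple(panel.marks))


def flatten(snapshot: HistoneSnapshot) -> np.ndarray:
    """Row-major flattening to the models' feature vector (480 at defaults)."""
    return snapshot.values.reshape(-1)
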