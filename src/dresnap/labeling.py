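"""Positive, negative, and true-positive-marker set construction.

Positives are the union of p300 peaks, stem-cell transcription-factor
binding sites (NANOG/OCT4/SOX2) and DNase I hypersensitivity sites that lie
at least 1 kb from every annotated transcription start site; TSS bins plus
random genomic bins far from open chromatin serve as negatives. Each peak is
anchored to the 100 bp bin containing its midpoint.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np

from .intervals import GenomeLayout, GenomicInterval, IntervalIndex, min_distance

__all__ = [
    "MarkerSet",
    "LabeledLocation",
    "min_distance",
    "distal_filter",
    "build_positive_set",
    "build_negative_set",
    "build_marker_set",
    "anchor_bin",
]

Source = Literal["p300", "tfbs", "dhs", "tss", "random_distal"]
POSITIVE_SOURCES: tuple[Source, ...] = ("p300", "tfbs", "dhs")


@dataclass(frozen=True)
class LabeledLocation:
    """One anchored bin with its class label and provenance."""

    location: GenomicInterval
    label: int
    source: Source

    def __post_init__(self) -> None:
        expected = 1 if self.source in POSITIVE_SOURCES else 0
        if self.label != expected:
            raise ValueError(f"label {self.label} inconsistent with source {self.source}")


@dataclass(frozen=True)
class MarkerSet:
    """True positive markers (TPMs) and the TSS list used for invalidation.

    ``tpm`` is the distal-filtered union of p300/TFBS/DHS peaks: the ground
    truth that validates predictions. The TSS list is kept in full because a
    prediction on a TSS is known-wrong regardless of marker distance.
    """

    tpm: tuple[GenomicInterval, ...]
    tss: tuple[GenomicInterval, ...]
    sources: tuple[Source, ...] = field(default=(), compare=False)


def distal_filter(
    candidates: Iterable[GenomicInterval],
    tss: Sequence[GenomicInterval],
    min_dist: int = 1000,
) -> list[GenomicInterval]:
    """Keep candidates >= ``min_dist`` bp (inclusive) from every TSS; order preserved."""
    index = IntervalIndex(tss)
    return [c for c in candidates if index.nearest_distance(c) >= min_dist]


def anchor_bin(interval: GenomicInterval, bin_size: int = 100) -> GenomicInterval:
    """The bin containing the interval's midpoint (midpoint floored to the grid)."""
    start = (interval.midpoint // bin_size) * bin_size
    return GenomicInterval(interval.chrom, start, start + bin_size)


def build_positive_set(
    p300: Sequence[GenomicInterval],
    tfbs: Sequence[GenomicInterval],
    dhs: Sequence[GenomicInterval],
    tss: Sequence[GenomicInterval],
    min_dist: int = 1000,
    bin_size: int = 100,
) -> list[LabeledLocation]:
    """Distal-filtered peak union, anchored to midpoint bins, deduplicated.

    When two peaks land on the same bin the source tag follows the fixed
    precedence p300 > tfbs > dhs.
    """
    out: list[LabeledLocation] = []
    seen: set[tuple[str, int]] = set()
    for source, peaks in (("p300", p300), ("tfbs", tfbs), ("dhs", dhs)):
        for peak in distal_filter(peaks, tss, min_dist):
            loc = anchor_bin(peak, bin_size)
            key = (loc.chrom, loc.start)
            if key in seen:
                continue
            seen.add(key)
            out.append(LabeledLocation(location=loc, label=1, source=source))
    return out


def build_negative_set(
    layout: GenomeLayout,
    positives: Sequence[LabeledLocation],
    tss: Sequence[GenomicInterval],
    dhs: Sequence[GenomicInterval],
    n_required: int,
    dhs_exclusion: int = 2500,
    seed: int = 0,
) -> list[LabeledLocation]:
    """TSS bins plus ``n_required`` random genome bins distal to open chromatin.

    Random bins are drawn uniformly without replacement from the bins that
    are >= ``dhs_exclusion`` bp from every DHS and are neither positive nor
    TSS bins; the draw is reproducible under ``seed``. Raises when fewer
    eligible bins exist than requested, reporting the shortfall.
    """
    bs = layout.bin_size
    occupied: set[tuple[str, int]] = {
        (p.location.chrom, p.location.start) for p in positives
    }
    out: list[LabeledLocation] = []
    for t in tss:
        loc = anchor_bin(t, bs)
        key = (loc.chrom, loc.start)
        if key in occupied:
            continue
        occupied.add(key)
        out.append(LabeledLocation(location=loc, label=0, source="tss"))

    if n_required == 0:
        return out

    dhs_index = IntervalIndex(dhs)
    eligible: list[tuple[str, int]] = []
    for chrom in layout.chrom_names:
        n = layout.n_bins(chrom)
        starts = np.arange(n, dtype=np.int64) * bs
        # bin [s, s+bs) is eligible iff no DHS comes within dhs_exclusion
        dists = np.array(
            [
                dhs_index.nearest_distance(GenomicInterval(chrom, int(s), int(s) + bs))
                for s in starts
            ]
        )
        keep = dists >= dhs_exclusion
        for s in starts[keep]:
            key = (chrom, int(s))
            if key not in occupied:
                eligible.append(key)
    if len(eligible) < n_required:
        raise ValueError(
            f"only {len(eligible)} eligible bins for {n_required} random "
            f"negatives (short by {n_required - len(eligible)})"
        )
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(eligible), size=n_required, replace=False)
    for i in sorted(int(c) for c in chosen):
        chrom, start = eligible[i]
        out.append(
            LabeledLocation(
                location=GenomicInterval(chrom, start, start + bs),
                label=0,
                source="random_distal",
            )
        )
    return out


def build_marker_set(
    p300: Sequence[GenomicInterval],
    tfbs: Sequence[GenomicInterval],
    dhs: Sequence[GenomicInterval],
    tss: Sequence[GenomicInterval],
    min_dist: int = 1000,
) -> MarkerSet:
    """Distal-filtered peak union as TPMs, with the full TSS list retained."""
    tpm: list[GenomicInterval] = []
    sources: list[Source] = []
    seen: set[tuple[str, int, int]] = set()
    for source, peaks in (("p300", p300), ("tfbs", tfbs), ("dhs", dhs)):
        for peak in distal_filter(peaks, tss, min_dist):
            key = (peak.chrom, peak.start, peak.end)
            if key in seen:
                continue
            seen.add(key)
            tpm.append(peak)
            sources.append(source)
    return MarkerSet(tpm=tuple(tpm), tss=tuple(tss), sources=tuple(sources))
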