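"""Synthetic genomes with planted regulatory signal for end-to-end testing.

The generator emulates the statistical structure the pipeline assumes: 24
per-mark binned signal tracks over a small multi-chromosome genome, with
additive unimodal enrichment bumps on an acetylation-flavoured mark subset
at planted DRE sites and on a trimethylation-flavoured subset at planted
TSS sites (so the classes are separable, but not on any single mark), a
non-negative noise background, roughly 8% of example locations with no
signal at all, and roughly 22% positive-class prevalence before balancing.
Planted DREs always respect the >= 1 kb distal-to-TSS rule. Everything is
deterministic under the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .features import (
    DEFAULT_MARK_PANEL,
    BinnedSignalTrack,
    EdgeError,
    HistoneSnapshot,
    MarkPanel,
    extract_snapshot,
)
from .intervals import GenomeLayout, GenomicInterval
from .labeling import (
    LabeledLocation,
    MarkerSet,
    build_marker_set,
    build_negative_set,
    build_positive_set,
)
from .preprocessing import LabeledExample, mark_gray

__all__ = [
    "SyntheticConfig",
    "SyntheticTruth",
    "generate",
    "generate_dataset",
    "make_snapshot_examples",
    "make_xor_examples",
]

# Mark-panel indices carrying the planted class signal. DREs light up
# acetylation marks, TSSs trimethylation marks; only the fact that the
# subsets differ matters to the tests.
DRE_MARK_IDX: tuple[int, ...] = (5, 6, 9, 12, 19, 22)   # H2BK5ac, H3K14ac, H3K27ac, H3K4ac, H3K9ac, H4K5ac
TSS_MARK_IDX: tuple[int, ...] = (10, 11, 15, 20)        # H3K27me3, H3K36me3, H3K4me3, H3K9me3


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for one synthetic genome.

    Defaults yield ~5,000 example locations at 22% positive prevalence with
    8% zero-signal examples: 1,100 planted DREs, 900 TSSs and 3,000 random
    distal negatives on a 2 x 5 Mb genome of 100 bp bins.
    """

    n_chroms: int = 2
    chrom_length: int = 5_000_000
    bin_size: int = 100
    n_marks: int = 24
    n_dre: int = 1100
    n_tss: int = 900
    positive_frac: float = 0.22
    zero_frac: float = 0.08
    amplitude: float = 5.0
    bump_halfwidth: int = 3          # bins on each side of the bump peak
    bump_sigma: float = 1.5          # bins
    noise_scale: float = 1.0
    shift_max: int = 0               # bump-centre jitter in bins (augmentation)
    min_tss_dist: int = 1000
    dhs_exclusion: int = 2500
    flank: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.zero_frac <= 1 and 0 < self.positive_frac <= 1):
            raise ValueError("fractions must lie in [0, 1]")
        if min(self.n_chroms, self.chrom_length, self.n_dre, self.n_tss) <= 0:
            raise ValueError("counts and lengths must be positive")

    @property
    def n_random_neg(self) -> int:
        total = round(self.n_dre / self.positive_frac)
        return max(total - self.n_dre - self.n_tss, 0)

    @property
    def layout(self) -> GenomeLayout:
        return GenomeLayout(
            chroms=tuple(
                (f"chr{i + 1}", self.chrom_length) for i in range(self.n_chroms)
            ),
            bin_size=self.bin_size,
        )

    @property
    def panel(self) -> MarkPanel:
        return MarkPanel(DEFAULT_MARK_PANEL[: self.n_marks])


@dataclass
class SyntheticTruth:
    """Ground truth of one generated genome: planted sites and zeroed windows."""

    dre_sites: list[GenomicInterval]
    tss_sites: list[GenomicInterval]
    negatives: list[LabeledLocation]
    zeroed: set[tuple[str, int]]
    layout: GenomeLayout


def _bump_kernel(halfwidth: int, sigma: float) -> np.ndarray:
    """Discrete Gaussian bump over +/- halfwidth bins, peak normalised to 1."""
    offs = np.arange(-halfwidth, halfwidth + 1)
    k = np.exp(-0.5 * (offs / sigma) ** 2)
    return k / k.max()


def _place_sites(config: SyntheticConfig, rng: np.random.Generator):
    """Pick DRE and TSS bins: uniform, interior, DREs >= 1 kb from every TSS."""
    margin = config.flank // config.bin_size + config.bump_halfwidth + 1
    candidates: list[tuple[str, int]] = []
    layout = config.layout
    for chrom in layout.chrom_names:
        n = layout.n_bins(chrom)
        for b in range(margin, n - margin):
            candidates.append((chrom, b))
    rng.shuffle(candidates)
    needed = config.n_dre + config.n_tss
    if needed > len(candidates):
        raise ValueError("genome too small to pack the requested sites")

    sep_bins = config.min_tss_dist // config.bin_size + 1
    dre_bins = candidates[: config.n_dre]
    dre_by_chrom = {
        chrom: np.sort(np.array([b for c, b in dre_bins if c == chrom]))
        for chrom in layout.chrom_names
    }
    tss_bins: list[tuple[str, int]] = []
    for chrom, b in candidates[config.n_dre:]:
        if len(tss_bins) == config.n_tss:
            break
        arr = dre_by_chrom[chrom]
        i = int(np.searchsorted(arr, b))
        near = min(
            abs(int(arr[j]) - b) for j in (i - 1, i) if 0 <= j < len(arr)
        ) if len(arr) else sep_bins
        if near >= sep_bins:
            tss_bins.append((chrom, b))
    if len(tss_bins) < config.n_tss:
        raise ValueError("could not place all TSS sites distal to planted DREs")
    return dre_bins, tss_bins


def generate(config: SyntheticConfig) -> tuple[dict[str, BinnedSignalTrack], SyntheticTruth]:
    """Build per-mark signal tracks plus the planted ground truth.

    DRE windows carry bumps on the acetylation subset, TSS windows on the
    trimethylation subset; random distal negatives are drawn through the
    labeling module's negative sampler; a ``zero_frac`` Bernoulli subset of
    all example windows is zeroed across every mark.
    """
    rng = np.random.default_rng(config.seed)
    layout = config.layout
    bs = config.bin_size

    dre_bins, tss_bins = _place_sites(config, rng)
    to_iv = lambda c, b: GenomicInterval(c, b * bs, (b + 1) * bs)
    dre_sites = [to_iv(c, b) for c, b in dre_bins]
    tss_sites = [to_iv(c, b) for c, b in tss_bins]

    positives = build_positive_set(
        p300=dre_sites, tfbs=[], dhs=[], tss=tss_sites,
        min_dist=config.min_tss_dist, bin_size=bs,
    )
    negatives = build_negative_set(
        layout, positives, tss=tss_sites, dhs=dre_sites,
        n_required=config.n_random_neg, dhs_exclusion=config.dhs_exclusion,
        seed=int(rng.integers(2**31)),
    )

    # per-chromosome signal matrices: background noise plus planted bumps
    kernel = _bump_kernel(config.bump_halfwidth, config.bump_sigma)
    hw = config.bump_halfwidth
    signal: dict[str, np.ndarray] = {}
    for chrom in layout.chrom_names:
        n = layout.n_bins(chrom)
        signal[chrom] = np.clip(
            rng.normal(0.0, config.noise_scale, size=(config.n_marks, n)), 0, None
        )

    def plant(bins: list[tuple[str, int]], mark_idx: Sequence[int]) -> None:
        for chrom, b in bins:
            shift = int(rng.integers(-config.shift_max, config.shift_max + 1)) \
                if config.shift_max else 0
            c = b + shift
            for m in mark_idx:
                signal[chrom][m, c - hw : c + hw + 1] += config.amplitude * kernel

    plant(dre_bins, [i for i in DRE_MARK_IDX if i < config.n_marks])
    plant(tss_bins, [i for i in TSS_MARK_IDX if i < config.n_marks])

    # zero out the full feature window of a zero_frac subset of examples
    all_locations = (
        [p.location for p in positives] + [n.location for n in negatives]
    )
    half = config.flank // bs
    zero_mask = rng.random(len(all_locations)) < config.zero_frac
    zeroed: set[tuple[str, int]] = set()
    for loc, z in zip(all_locations, zero_mask):
        if z:
            b = loc.start // bs
            signal[loc.chrom][:, b - half : b + half] = 0.0
            zeroed.add((loc.chrom, loc.start))

    panel = config.panel
    tracks = {
        mark: BinnedSignalTrack(
            mark=mark, layout=layout,
            data={c: signal[c][i] for c in layout.chrom_names},
        )
        for i, mark in enumerate(panel)
    }
    truth = SyntheticTruth(
        dre_sites=dre_sites, tss_sites=tss_sites, negatives=negatives,
        zeroed=zeroed, layout=layout,
    )
    return tracks, truth


def generate_dataset(
    config: SyntheticConfig,
) -> tuple[list[LabeledExample], MarkerSet, SyntheticTruth]:
    """Run the feature and labeling pipeline over a generated genome.

    Returns the raw labeled examples (before zero-filtering and balancing),
    the marker set built from the planted peaks, and the ground truth.
    """
    tracks, truth = generate(config)
    markers = build_marker_set(
        p300=truth.dre_sites, tfbs=[], dhs=[], tss=truth.tss_sites,
        min_dist=config.min_tss_dist,
    )
    positives = build_positive_set(
        p300=truth.dre_sites, tfbs=[], dhs=[], tss=truth.tss_sites,
        min_dist=config.min_tss_dist, bin_size=config.bin_size,
    )
    examples: list[LabeledExample] = []
    for lab in positives + truth.negatives:
        try:
            snap = extract_snapshot(tracks, lab.location, config.panel, config.flank)
        except EdgeError:
            continue
        examples.append(
            LabeledExample(
                snapshot=snap, label=lab.label, location=lab.location,
                source=lab.source,
            )
        )
    return mark_gray(examples, markers), markers, truth


def _synthetic_snapshot(
    rng: np.random.Generator,
    mark_idx: Sequence[int],
    n_marks: int,
    n_bins: int,
    amplitude: float,
    noise_scale: float,
    center: int,
    kernel: np.ndarray,
    halfwidth: int,
) -> np.ndarray:
    mat = np.clip(rng.normal(0.0, noise_scale, size=(n_marks, n_bins)), 0, None)
    lo, hi = center - halfwidth, center + halfwidth + 1
    klo, khi = max(0, -lo), len(kernel) - max(0, hi - n_bins)
    for m in mark_idx:
        mat[m, max(lo, 0) : min(hi, n_bins)] += amplitude * kernel[klo:khi]
    return mat


def make_snapshot_examples(
    n_pos: int,
    n_neg: int,
    shift: int = 0,
    config: SyntheticConfig | None = None,
    seed: int = 0,
) -> list[LabeledExample]:
    """Track-free snapshot sampler matching the generator's signal model.

    Positives carry the DRE-mark bump centred at column ``10 + shift``;
    negatives are pure background. Used for model-property probes (shift
    invariance, score gaps) where genome placement is irrelevant.
    """
    config = config or SyntheticConfig()
    rng = np.random.default_rng(seed)
    kernel = _bump_kernel(config.bump_halfwidth, config.bump_sigma)
    n_bins = 2 * (config.flank // config.bin_size)
    center = n_bins // 2 + shift
    out: list[LabeledExample] = []
    for i in range(n_pos + n_neg):
        positive = i < n_pos
        mat = _synthetic_snapshot(
            rng,
            [j for j in DRE_MARK_IDX if j < config.n_marks] if positive else [],
            config.n_marks, n_bins, config.amplitude, config.noise_scale,
            center, kernel, config.bump_halfwidth,
        )
        loc = GenomicInterval("chrSim", (i + 100) * 10_000, (i + 100) * 10_000 + 100)
        snap = HistoneSnapshot(values=mat, anchor=loc, marks=tuple(config.panel.marks))
        out.append(LabeledExample(snapshot=snap, label=int(positive), location=loc))
    return out


def make_xor_examples(
    n: int,
    config: SyntheticConfig | None = None,
    seed: int = 0,
) -> list[LabeledExample]:
    """Examples whose class is the XOR of two mark-group bumps.

    Each example independently carries the acetylation-group bump with
    probability 1/2 and the trimethylation-group bump with probability 1/2;
    the label is 1 iff exactly one group is present. No linear function of
    the features separates the classes, while kernel and convolutional
    models can.
    """
    config = config or SyntheticConfig()
    rng = np.random.default_rng(seed)
    kernel = _bump_kernel(config.bump_halfwidth, config.bump_sigma)
    n_bins = 2 * (config.flank // config.bin_size)
    center = n_bins // 2
    group_a = [j for j in DRE_MARK_IDX if j < config.n_marks]
    group_b = [j for j in TSS_MARK_IDX if j < config.n_marks]
    out: list[LabeledExample] = []
    for i in range(n):
        has_a, has_b = rng.random() < 0.5, rng.random() < 0.5
        marks: list[int] = (group_a if has_a else []) + (group_b if has_b else [])
        mat = _synthetic_snapshot(
            rng, marks, config.n_marks, n_bins, config.amplitude,
            config.noise_scale, center, kernel, config.bump_halfwidth,
        )
        loc = GenomicInterval("chrXor", (i + 100) * 10_000, (i + 100) * 10_000 + 100)
        snap = HistoneSnapshot(values=mat, anchor=loc, marks=tuple(config.panel.marks))
        out.append(
            LabeledExample(snapshot=snap, label=int(has_a != has_b), location=loc)
        )
    return out
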