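"""Validation-Rate (VR) evaluation and model ranking.

Conventional precision/recall cannot be computed for regulatory-element
prediction because the genome's true positive set is incompletely mapped.
VR instead asks, of a fixed number of top-scoring predictions, how many lie
within 2.5 kb of a true positive marker (TPM: a distal p300/TFBS/DHS site).
Such a prediction is "validated" — it is either a known regulatory site or
open chromatin plausibly regulatory; anything else is a TSS or unknown and
counts as invalid. Controlling the prediction count makes the rate
comparable across models; the headline figure averages VR over the five
train/test pairs of the split protocol.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .intervals import GenomicInterval, IntervalIndex
from .labeling import MarkerSet
from .models.suite import PredictionScoreSet

__all__ = [
    "ValidatedPrediction",
    "VRCurve",
    "VRResult",
    "ComparisonResult",
    "validate",
    "top_n",
    "vr_at_n",
    "vr_curve",
    "aggregate_pairs",
    "compare_models",
    "PAPER_PREDICTION_TARGET",
]

# 100,000 genome-wide predictions x 30% test share / 5 disjoint test subsets
PAPER_PREDICTION_TARGET = 6000


@dataclass(frozen=True)
class ValidatedPrediction:
    location: GenomicInterval
    score: float
    validated: bool
    nearest_tpm_distance: float


@dataclass(frozen=True)
class VRCurve:
    """(n_predictions, VR) points with strictly increasing n."""

    n_predictions: tuple[int, ...]
    vr: tuple[float, ...]

    def __post_init__(self) -> None:
        if any(b <= a for a, b in zip(self.n_predictions, self.n_predictions[1:])):
            raise ValueError("n_predictions must be strictly increasing")


@dataclass(frozen=True)
class VRResult:
    """Per-pair VRs with their mean and sample standard deviation."""

    per_pair: tuple[float, ...]
    mean: float
    std: float
    n_predictions: int


@dataclass(frozen=True)
class ComparisonResult:
    """Outcome of a one-tailed t-test between two models' per-pair VRs."""

    t_statistic: float | None
    p_value: float | None
    paired: bool
    degenerate: bool = False
    note: str = ""

    @property
    def significant(self) -> bool:
        return self.p_value is not None and self.p_value < 0.05


def validate(
    predictions: PredictionScoreSet,
    markers: MarkerSet,
    radius: int = 2500,
) -> list[ValidatedPrediction]:
    """Mark each prediction validated iff within ``radius`` bp of a TPM.

    Distances are edge-to-edge and the boundary is inclusive: exactly
    2,500 bp away still validates. A prediction overlapping a TSS is always
    invalid — it is known not to be a distal element — regardless of marker
    distance.
    """
    if not markers.tpm:
        raise ValueError("marker set has no TPMs")
    tpm_index = IntervalIndex(markers.tpm)
    tss_index = IntervalIndex(markers.tss)
    out = []
    for loc, score in zip(predictions.locations, predictions.scores):
        d = tpm_index.nearest_distance(loc)
        on_tss = len(markers.tss) > 0 and tss_index.nearest_distance(loc) == 0
        out.append(
            ValidatedPrediction(
                location=loc,
                score=float(score),
                validated=bool(d <= radius and not on_tss),
                nearest_tpm_distance=d,
            )
        )
    return out


def top_n(predictions: PredictionScoreSet, n: int) -> PredictionScoreSet:
    """The n highest-scoring predictions; ties break by (chrom, start) ascending."""
    if n > len(predictions):
        raise ValueError(f"requested top {n} of {len(predictions)} predictions")
    order = sorted(
        range(len(predictions)),
        key=lambda i: (
            -predictions.scores[i],
            predictions.locations[i].chrom,
            predictions.locations[i].start,
        ),
    )[:n]
    return PredictionScoreSet(
        locations=[predictions.locations[i] for i in order],
        scores=predictions.scores[order],
    )


def vr_at_n(
    predictions: PredictionScoreSet,
    markers: MarkerSet,
    n: int,
    radius: int = 2500,
) -> float:
    """Fraction of the top-n predictions that validate."""
    if n <= 0:
        raise ValueError("n must be positive")
    validated = validate(top_n(predictions, n), markers, radius)
    return sum(v.validated for v in validated) / n


def vr_curve(
    predictions: PredictionScoreSet,
    markers: MarkerSet,
    n_grid: Sequence[int],
    radius: int = 2500,
) -> VRCurve:
    """VR at each prediction count of an ascending grid."""
    if list(n_grid) != sorted(set(n_grid)):
        raise ValueError("n_grid must be sorted ascending without duplicates")
    return VRCurve(
        n_predictions=tuple(int(n) for n in n_grid),
        vr=tuple(vr_at_n(predictions, markers, n, radius) for n in n_grid),
    )


def aggregate_pairs(per_pair_vr: Sequence[float], n_predictions: int = 0) -> VRResult:
    """Mean and sample standard deviation (ddof=1) over the train/test pairs."""
    vals = [float(v) for v in per_pair_vr]
    if len(vals) < 2:
        raise ValueError("need at least two per-pair values to aggregate")
    return VRResult(
        per_pair=tuple(vals),
        mean=float(np.mean(vals)),
        std=float(np.std(vals, ddof=1)),
        n_predictions=n_predictions,
    )


def compare_models(
    a: Sequence[float],
    b: Sequence[float],
    paired: bool,
) -> ComparisonResult:
    """One-tailed t-test of H1: mean(a) > mean(b).

    Models trained on the same group of training sets are compared with a
    paired test on the per-pair differences; models trained on different
    groups use the unpaired (Welch) form. Zero-variance paired differences
    make the statistic undefined, reported as a degenerate case rather than
    a number.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if paired:
        if len(a) != len(b):
            raise ValueError("paired comparison requires equal lengths")
        diffs = a - b
        if np.allclose(diffs.std(ddof=1) if len(diffs) > 1 else 0.0, 0.0):
            return ComparisonResult(
                t_statistic=None, p_value=None, paired=True, degenerate=True,
                note="zero-variance paired differences; t undefined",
            )
        t, p = stats.ttest_rel(a, b, alternative="greater")
    else:
        if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
            return ComparisonResult(
                t_statistic=None, p_value=None, paired=False, degenerate=True,
                note="both samples have zero variance; t undefined",
            )
        t, p = stats.ttest_ind(a, b, equal_var=False, alternative="greater")
    return ComparisonResult(t_statistic=float(t), p_value=float(p), paired=paired)


def brute_force_validate(
    predictions: PredictionScoreSet,
    markers: MarkerSet,
    radius: int = 2500,
) -> list[ValidatedPrediction]:
    """O(P x T) all-pairs reference for :func:`validate` (testing oracle)."""
    from .intervals import min_distance

    if not markers.tpm:
        raise ValueError("marker set has no TPMs")
    out = []
    for loc, score in zip(predictions.locations, predictions.scores):
        d = min(min_distance(loc, t) for t in markers.tpm)
        on_tss = any(min_distance(loc, t) == 0 for t in markers.tss)
        out.append(
            ValidatedPrediction(
                location=loc, score=float(score),
                validated=bool(d <= radius and not on_tss),
                nearest_tpm_distance=d,
            )
        )
    return out
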