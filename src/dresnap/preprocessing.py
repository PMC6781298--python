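"""Dataset refinement and the five-pair train/test split protocol.

Raw labeled examples are cleaned in three steps before training: locations
with no histone signal at all (an all-zero snapshot) are dropped, the class
imbalance (~22% positives) is removed by subsampling negatives, and the
result is split 70/30 into a training pool and a test pool. The test pool is
partitioned into five non-overlapping test sets, each paired with one of
five (possibly overlapping) training sets drawn from the pool, so the final
validation rate can be reported as a mean and spread over five runs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .features import HistoneSnapshot
from .intervals import GenomicInterval, IntervalIndex
from .labeling import MarkerSet

__all__ = [
    "LabeledExample",
    "SplitSet",
    "filter_zero_signal",
    "balance_classes",
    "make_split_set",
    "mark_gray",
    "apply_gray_labels",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class LabeledExample:
    """One training/testing unit: a snapshot, its label, and its location.

    ``gray`` flags locations within the validation radius of a true positive
    marker that are not markers themselves; with gray inclusion on, these are
    relabeled positive in training sets (they would count as validated).
    """

    snapshot: HistoneSnapshot
    label: int
    location: GenomicInterval
    gray: bool = False
    source: str | None = None

    def __post_init__(self) -> None:
        if self.label not in (0, 1):
            raise ValueError("label must be 0 or 1")


@dataclass
class SplitSet:
    """Five overlapping training sets paired with five disjoint test sets."""

    train_sets: list[list[LabeledExample]]
    test_sets: list[list[LabeledExample]]
    train_frac: float
    seed: int

    def __post_init__(self) -> None:
        if len(self.train_sets) != len(self.test_sets):
            raise ValueError("train/test pairing must be one-to-one")
        self.assert_no_leakage()

    @property
    def n_pairs(self) -> int:
        return len(self.train_sets)

    def pairs(self):
        return zip(self.train_sets, self.test_sets)

    def assert_no_leakage(self) -> None:
        """Test sets are pairwise disjoint and share no location with training sets."""
        test_keys: list[set] = [
            {(e.location.chrom, e.location.start) for e in ts} for ts in self.test_sets
        ]
        for i in range(len(test_keys)):
            for j in range(i + 1, len(test_keys)):
                if test_keys[i] & test_keys[j]:
                    raise AssertionError(f"test sets {i} and {j} overlap")
        all_test = set().union(*test_keys) if test_keys else set()
        for i, tr in enumerate(self.train_sets):
            train_keys = {(e.location.chrom, e.location.start) for e in tr}
            if train_keys & all_test:
                raise AssertionError(f"training set {i} leaks into the test pool")


def filter_zero_signal(examples: Sequence[LabeledExample]) -> list[LabeledExample]:
    """Drop examples whose snapshot is exactly all zeros (no signal to learn from)."""
    return [e for e in examples if np.any(e.snapshot.values != 0)]


def balance_classes(
    examples: Sequence[LabeledExample], seed: int = 0
) -> list[LabeledExample]:
    """Equalize class counts by subsampling negatives, keeping all positives.

    Input order is preserved. If negatives are already the minority the set
    is returned unchanged (with a warning): upsampling is never done.
    """
    positives = [e for e in examples if e.label == 1]
    negatives = [e for e in examples if e.label == 0]
    if not positives:
        raise ValueError("cannot balance a set with no positive examples")
    if len(negatives) <= len(positives):
        if len(negatives) < len(positives):
            logger.warning(
                "negatives (%d) fewer than positives (%d); nothing to subsample",
                len(negatives), len(positives),
            )
        return list(examples)
    rng = np.random.default_rng(seed)
    keep_idx = set(
        int(i) for i in rng.choice(len(negatives), size=len(positives), replace=False)
    )
    kept_neg = {id(negatives[i]) for i in keep_idx}
    return [e for e in examples if e.label == 1 or id(e) in kept_neg]


def make_split_set(
    examples: Sequence[LabeledExample],
    train_frac: float = 0.7,
    n_pairs: int = 5,
    train_size: int | None = None,
    seed: int = 0,
) -> SplitSet:
    """Shuffle, split 70/30, partition the test pool, and draw training sets.

    The training pool is the first ``train_frac`` of the shuffled examples;
    the remainder is partitioned into ``n_pairs`` equal disjoint test sets
    (a remainder of fewer than ``n_pairs`` examples is dropped). Each
    training set is an independent draw of ``train_size`` examples without
    replacement from the pool — sets may overlap each other but never touch
    the test pool. ``train_size=None`` uses the whole pool for every set.
    """
    n = len(examples)
    n_train_pool = int(round(train_frac * n))
    if train_size is not None and train_size > n_train_pool:
        raise ValueError(
            f"train_size {train_size} exceeds training pool of {n_train_pool}"
        )
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    shuffled = [examples[int(i)] for i in order]
    pool = shuffled[:n_train_pool]
    test_pool = shuffled[n_train_pool:]
    per_test = len(test_pool) // n_pairs
    if per_test == 0:
        raise ValueError("test pool too small to partition")
    test_sets = [
        test_pool[i * per_test : (i + 1) * per_test] for i in range(n_pairs)
    ]
    train_sets = []
    for _ in range(n_pairs):
        if train_size is None:
            train_sets.append(list(pool))
        else:
            idx = rng.choice(len(pool), size=train_size, replace=False)
            train_sets.append([pool[int(i)] for i in idx])
    return SplitSet(
        train_sets=train_sets, test_sets=test_sets, train_frac=train_frac, seed=seed
    )


def mark_gray(
    examples: Sequence[LabeledExample],
    markers: MarkerSet,
    radius: int = 2500,
) -> list[LabeledExample]:
    """Flag examples within ``radius`` of a TPM that are not TPM bins themselves.

    A marker location is a positive, not gray; everything else close enough
    to a marker to validate is gray and may be folded into the training
    positives downstream.
    """
    index = IntervalIndex(markers.tpm)
    tpm_bins = {(anchor.chrom, anchor.start) for anchor in _tpm_anchor_bins(markers)}
    out = []
    for e in examples:
        d = index.nearest_distance(e.location)
        is_tpm_bin = (e.location.chrom, e.location.start) in tpm_bins
        out.append(replace(e, gray=bool(d <= radius and not is_tpm_bin)))
    return out


def _tpm_anchor_bins(markers: MarkerSet, bin_size: int = 100):
    from .labeling import anchor_bin

    return [anchor_bin(t, bin_size) for t in markers.tpm]


def apply_gray_labels(train_set: Sequence[LabeledExample]) -> list[LabeledExample]:
    """Relabel gray examples as positives (training-set use only)."""
    return [replace(e, label=1) if e.gray else e for e in train_set]
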