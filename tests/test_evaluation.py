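"""Validation-rate metric, VR curves, aggregation, and model ranking tests."""

import numpy as np
import pytest
from scipy import stats

from dresnap.evaluation import (
    PAPER_PREDICTION_TARGET,
    aggregate_pairs,
    brute_force_validate,
    compare_models,
    top_n,
    validate,
    vr_at_n,
    vr_curve,
)
from dresnap.intervals import GenomicInterval
from dresnap.labeling import MarkerSet
from dresnap.models import PredictionScoreSet


def iv(start, end=None, chrom="chr1"):
    return GenomicInterval(chrom, start, end if end is not None else start + 100)


def scoreset(starts, scores, chrom="chr1"):
    return PredictionScoreSet(
        locations=[iv(s, chrom=chrom) for s in starts],
        scores=np.asarray(scores, dtype=float),
    )


MARKERS = MarkerSet(tpm=(iv(50_000),), tss=(iv(90_000),))


class TestValidate:
    @pytest.mark.parametrize(
        "start,expected",
        [
            (47_500, True),    # gap 2,400 -> validated
            (47_399, False),   # gap 2,501 -> invalid
            (47_400, True),    # gap exactly 2,500 -> inclusive boundary
            (50_000, True),    # on the marker
        ],
    )
    def test_radius_boundary(self, start, expected):
        [v] = validate(scoreset([start], [1.0]), MARKERS)
        assert v.validated is expected

    def test_tss_override_beats_distance(self):
        markers = MarkerSet(tpm=(iv(50_000),), tss=(iv(50_200),))
        [v] = validate(scoreset([50_200], [1.0]), markers)
        assert not v.validated and v.nearest_tpm_distance <= 2500

    def test_empty_marker_set_rejected(self):
        with pytest.raises(ValueError):
            validate(scoreset([0], [1.0]), MarkerSet(tpm=(), tss=()))

    def test_monotone_in_radius(self):
        rng = np.random.default_rng(3)
        preds = scoreset(rng.integers(0, 200_000, 50), rng.random(50))
        small = validate(preds, MARKERS, radius=1000)
        large = validate(preds, MARKERS, radius=5000)
        for s, l in zip(small, large):
            assert l.validated or not s.validated


class TestTopN:
    def test_highest_scores_selected(self):
        top = top_n(scoreset([0, 1000, 2000], [0.9, 0.5, 0.7]), 2)
        assert sorted(top.scores) == [0.7, 0.9]

    def test_ties_break_genomically(self):
        top = top_n(scoreset([3000, 1000, 2000], [0.5, 0.5, 0.5]), 2)
        assert [l.start for l in top.locations] == [1000, 2000]

    def test_full_n_is_identity_set(self):
        ps = scoreset([0, 1000], [0.1, 0.2])
        top = top_n(ps, 2)
        assert set(l.start for l in top.locations) == {0, 1000}

    def test_n_too_large_rejected(self):
        with pytest.raises(ValueError):
            top_n(scoreset([0], [1.0]), 2)


class TestVrAtN:
    def test_all_validated(self):
        preds = scoreset([50_000 + i * 100 for i in range(6)], np.arange(6))
        assert vr_at_n(preds, MARKERS, 6) == 1.0

    def test_half_validated(self):
        starts = [50_000, 50_100, 50_200, 200_000, 210_000, 220_000]
        preds = scoreset(starts, np.ones(6))
        assert vr_at_n(preds, MARKERS, 6) == 0.5

    def test_invariant_under_monotone_score_transform(self):
        rng = np.random.default_rng(8)
        preds = scoreset(rng.integers(0, 300_000, 100), rng.random(100))
        transformed = PredictionScoreSet(
            locations=preds.locations, scores=np.exp(3 * preds.scores)
        )
        for n in (1, 10, 50, 100):
            assert vr_at_n(preds, MARKERS, n) == vr_at_n(transformed, MARKERS, n)

    def test_agrees_with_brute_force_oracle(self):
        rng = np.random.default_rng(21)
        for _ in range(25):
            tpm = tuple(iv(int(s)) for s in rng.integers(0, 500_000, 8))
            tss = tuple(iv(int(s)) for s in rng.integers(0, 500_000, 3))
            markers = MarkerSet(tpm=tpm, tss=tss)
            preds = scoreset(rng.integers(0, 500_000, 40), rng.random(40))
            fast = validate(preds, markers)
            slow = brute_force_validate(preds, markers)
            assert [v.validated for v in fast] == [v.validated for v in slow]
            np.testing.assert_array_equal(
                [v.nearest_tpm_distance for v in fast],
                [v.nearest_tpm_distance for v in slow],
            )


class TestVrCurve:
    def test_perfect_scorer_starts_at_one(self):
        starts = [50_000, 50_100, 200_000, 210_000]
        preds = scoreset(starts, [4, 3, 2, 1])
        curve = vr_curve(preds, MARKERS, [1, 2, 4])
        assert curve.vr[0] == 1.0 and curve.vr[1] == 1.0
        assert curve.vr[2] == 0.5

    def test_single_point_equals_vr_at_n(self):
        preds = scoreset([50_000, 200_000], [1.0, 0.5])
        curve = vr_curve(preds, MARKERS, [2])
        assert curve.vr == (vr_at_n(preds, MARKERS, 2),)

    def test_unsorted_grid_rejected(self):
        preds = scoreset([50_000, 200_000], [1.0, 0.5])
        with pytest.raises(ValueError):
            vr_curve(preds, MARKERS, [2, 1])

    def test_random_scorer_tracks_background_rate(self):
        """With random scores, VR at any n hovers near the validated fraction."""
        rng = np.random.default_rng(17)
        starts = rng.integers(0, 400_000, 400)
        preds = scoreset(starts, rng.random(400))
        background = sum(
            v.validated for v in validate(preds, MARKERS)
        ) / len(starts)
        vr = vr_at_n(preds, MARKERS, 200)
        se = np.sqrt(background * (1 - background) / 200)
        assert abs(vr - background) < 4 * se + 1e-12


class TestAggregatePairs:
    def test_constant_pairs(self):
        res = aggregate_pairs([1, 1, 1, 1, 1])
        assert res.mean == 1.0 and res.std == 0.0

    def test_two_value_closed_form(self):
        res = aggregate_pairs([0.9, 1.0])
        assert res.mean == pytest.approx(0.95)
        assert res.std == pytest.approx(0.07071067811865478)

    def test_matches_streaming_recomputation(self):
        rng = np.random.default_rng(2)
        vals = rng.random(5)
        res = aggregate_pairs(vals)
        # independent streaming mean/variance (Welford)
        mean, m2 = 0.0, 0.0
        for k, v in enumerate(vals, start=1):
            d = v - mean
            mean += d / k
            m2 += d * (v - mean)
        assert res.mean == pytest.approx(mean)
        assert res.std == pytest.approx(np.sqrt(m2 / (len(vals) - 1)))

    def test_single_value_rejected(self):
        with pytest.raises(ValueError):
            aggregate_pairs([1.0])


class TestCompareModels:
    def test_paired_matches_textbook_formula(self):
        a = [0.97, 0.98, 0.96, 0.99, 0.97]
        b = [0.95, 0.96, 0.95, 0.96, 0.94]
        res = compare_models(a, b, paired=True)
        d = np.array(a) - np.array(b)
        t = d.mean() / (d.std(ddof=1) / np.sqrt(len(d)))
        p = stats.t.sf(t, df=len(d) - 1)
        assert res.t_statistic == pytest.approx(t, abs=1e-10)
        assert res.p_value == pytest.approx(p, abs=1e-10)

    def test_identical_paired_samples_degenerate(self):
        res = compare_models([1, 2, 3], [1, 2, 3], paired=True)
        assert res.degenerate and res.p_value is None

    def test_unpaired_welch_form(self):
        a, b = [0.9, 0.95, 0.92], [0.80, 0.82, 0.81, 0.79]
        res = compare_models(a, b, paired=False)
        t, p = stats.ttest_ind(a, b, equal_var=False, alternative="greater")
        assert res.t_statistic == pytest.approx(float(t), abs=1e-12)
        assert res.p_value == pytest.approx(float(p), abs=1e-12)

    def test_dominant_model_detected_significant(self):
        rng = np.random.default_rng(11)
        wins = 0
        for _ in range(40):
            a = 0.95 + 0.01 * rng.standard_normal(5)
            b = 0.85 + 0.01 * rng.standard_normal(5)
            if compare_models(a, b, paired=True).significant:
                wins += 1
        assert wins >= 38  # p < 0.05 in >= 95% of clearly separated draws

    def test_paired_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            compare_models([1, 2], [1, 2, 3], paired=True)


def test_paper_prediction_target_arithmetic():
    """100k genome-wide predictions x 30% test share / 5 subsets = 6,000."""
    assert PAPER_PREDICTION_TARGET == round(100_000 * 0.3 / 5)
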