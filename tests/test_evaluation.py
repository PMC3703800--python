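import numpy as np
import pytest
from scipy.stats import rankdata

from fundusbench.evaluation import (
    ROCCurve,
    ScoredSet,
    SingleClassError,
    auc,
    eer,
    eer_point,
    pixel_roc,
    roc_from_scores,
    sample_scores,
    summarize,
    wer,
    wer_point,
)


def exhaustive_roc_counts(scores, abnormal):
    """Independent oracle: explicit loop over every unique threshold."""
    scores = list(map(float, scores))
    abnormal = list(map(bool, abnormal))
    rows = []
    thresholds = [float("inf")] + sorted(set(scores), reverse=True)
    for t in thresholds:
        tp = fp = tn = fn = 0
        for s, a in zip(scores, abnormal):
            predicted = s >= t
            if predicted and a:
                tp += 1
            elif predicted and not a:
                fp += 1
            elif not predicted and a:
                fn += 1
            else:
                tn += 1
        rows.append((t, tp, fp, tn, fn))
    return rows


def random_scored_set(rng, n_max=50):
    n = int(rng.integers(2, n_max + 1))
    # duplicated score values are common in practice; force some ties
    scores = np.round(rng.normal(size=n), 1)
    abnormal = rng.random(n) < 0.5
    if not abnormal.any():
        abnormal[0] = True
    if abnormal.all():
        abnormal[-1] = False
    return ScoredSet(scores=scores, abnormal=abnormal)


class TestRocFromScores:
    def test_counts_match_exhaustive_oracle(self, rng):
        for _ in range(50):
            s = random_scored_set(rng)
            curve = roc_from_scores(s)
            expected = exhaustive_roc_counts(s.scores, s.abnormal)
            got = list(zip(curve.thresholds, curve.tp, curve.fp, curve.tn, curve.fn))
            assert got == [tuple(map(float, r)) for r in expected]

    def test_separable_scores(self):
        curve = roc_from_scores(
            ScoredSet(scores=[0.9, 0.8, 0.3, 0.1], abnormal=[True, True, False, False])
        )
        assert any((f == 0.0 and s == 1.0) for f, s in curve.points)
        assert eer(curve) == 0.0

    def test_interleaved_scores_vertices_and_eer(self):
        curve = roc_from_scores(
            ScoredSet(
                scores=[0.9, 0.4, 0.6, 0.1],
                abnormal=["abnormal", "abnormal", "normal", "normal"],
            )
        )
        pts = {tuple(p) for p in curve.points}
        assert {(0.0, 0.5), (0.5, 0.5), (0.5, 1.0)} <= pts
        assert eer(curve) == pytest.approx(0.5)

    def test_all_equal_scores_degenerate_curve(self):
        curve = roc_from_scores(ScoredSet(scores=[1.0, 1.0], abnormal=[True, False]))
        assert [tuple(p) for p in curve.points] == [(0.0, 0.0), (1.0, 1.0)]
        assert eer(curve) == pytest.approx(0.5)

    def test_single_class_rejected(self):
        with pytest.raises(SingleClassError, match="both populations"):
            roc_from_scores(ScoredSet(scores=[1.0, 2.0], abnormal=[True, True]))


class TestSampleScores:
    @pytest.mark.parametrize(
        "n, step, expected_len",
        [(10, 2, 5), (10, 1, 10), (10, 3, 3), (5, 7, 0), (0, 3, 0)],
    )
    def test_lengths(self, n, step, expected_len):
        sampled = sample_scores(np.arange(n, dtype=float), step)
        assert len(sampled) == expected_len

    def test_identity_and_positions(self):
        ladder = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        np.testing.assert_array_equal(sample_scores(ladder, 1), ladder)
        np.testing.assert_array_equal(sample_scores(ladder, 2), [2.0, 4.0, 6.0])

    def test_requires_ascending_unique(self):
        with pytest.raises(ValueError):
            sample_scores([3.0, 1.0, 2.0], 1)


class TestPixelRoc:
    def test_separable_single_image(self):
        lmap = np.array([[0.9, 0.8], [0.2, 0.1]])
        mask = np.array([[1, 1], [0, 0]], dtype=bool)
        curve = pixel_roc([lmap], [mask])
        assert eer(curve) == 0.0
        assert auc(curve) == pytest.approx(1.0)

    def test_normal_images_only_affect_specificity(self, rng):
        maps = [rng.random((6, 6)) for _ in range(3)]
        masks = [rng.random((6, 6)) < 0.3 for _ in range(3)]
        masks[0][0, 0] = True
        base = pixel_roc(maps, masks)
        with_normal = pixel_roc(
            maps + [np.zeros((6, 6))], masks + [np.zeros((6, 6), bool)]
        )
        # same positives: at every shared threshold SN is unchanged and the
        # low-scoring normal image can only improve specificity
        base_at = {t: (s, p) for t, s, p in zip(base.thresholds, base.sn, base.sp)}
        for t, sn_new, sp_new in zip(with_normal.thresholds, with_normal.sn, with_normal.sp):
            if t in base_at:
                sn_old, sp_old = base_at[t]
                assert sn_new == pytest.approx(sn_old)
                assert sp_new >= sp_old - 1e-12

    def test_matches_image_level_pooling_oracle(self, rng):
        maps = [rng.integers(0, 5, size=(4, 4)) / 4.0 for _ in range(3)]
        masks = [rng.random((4, 4)) < 0.4 for _ in range(3)]
        masks[0][1, 1] = True
        curve = pixel_roc(maps, masks, sampling_step=1)
        pooled = ScoredSet(
            scores=np.concatenate([m.ravel() for m in maps]),
            abnormal=np.concatenate([m.ravel() for m in masks]),
        )
        expected = roc_from_scores(pooled)
        np.testing.assert_array_equal(curve.tp, expected.tp)
        np.testing.assert_array_equal(curve.fp, expected.fp)

    def test_no_positive_pixels_rejected(self):
        with pytest.raises(SingleClassError):
            pixel_roc([np.ones((2, 2))], [np.zeros((2, 2), bool)])


class TestOperatingMeasures:
    def test_eer_on_diagonal_curve(self):
        curve = roc_from_scores(ScoredSet(scores=[1.0, 1.0], abnormal=[True, False]))
        assert eer(curve) == pytest.approx(0.5)

    def test_eer_symmetric_under_label_swap_and_negation(self, rng):
        for _ in range(20):
            s = random_scored_set(rng)
            direct = eer(roc_from_scores(s))
            flipped = eer(
                roc_from_scores(ScoredSet(scores=-s.scores, abnormal=~s.abnormal))
            )
            assert direct == pytest.approx(flipped, abs=1e-9)

    def test_eer_crossing_satisfies_sn_equals_sp(self, rng):
        for _ in range(20):
            fpr, sn = eer_point(roc_from_scores(random_scored_set(rng)))
            assert sn == pytest.approx(1.0 - fpr, abs=1e-12)

    def test_adding_correctly_ranked_abnormal_never_raises_eer(self, rng):
        for _ in range(20):
            s = random_scored_set(rng, n_max=20)
            before = eer(roc_from_scores(s))
            extended = ScoredSet(
                scores=np.append(s.scores, s.scores.max() + 1.0),
                abnormal=np.append(s.abnormal, True),
            )
            assert eer(roc_from_scores(extended)) <= before + 1e-12

    @pytest.mark.parametrize(
        "fpr, fnr, ratio, expected",
        [(0.2, 0.4, 1.0, 0.3), (0.2, 0.4, 3.0, 0.35), (0.5, 0.5, 1.0, 0.5)],
    )
    def test_wer_point_arithmetic(self, fpr, fnr, ratio, expected):
        assert wer_point(fpr, fnr, ratio) == pytest.approx(expected)

    def test_wer_curve_minimum_bounded_by_vertices(self, rng):
        s = random_scored_set(rng)
        curve = roc_from_scores(s)
        for ratio in (0.5, 1.0, 3.0):
            value = wer(curve, ratio)
            vertex_values = [
                wer_point(f, 1.0 - sn_, ratio) for f, sn_ in zip(curve.fpr, curve.sn)
            ]
            assert value == pytest.approx(min(vertex_values))

    def test_wer_requires_positive_cost_ratio(self):
        curve = roc_from_scores(ScoredSet(scores=[1.0, 0.0], abnormal=[True, False]))
        with pytest.raises(ValueError):
            wer(curve, 0.0)

    def test_auc_endpoints(self):
        separable = roc_from_scores(
            ScoredSet(scores=[2.0, 1.0], abnormal=[True, False])
        )
        diagonal = roc_from_scores(ScoredSet(scores=[1.0, 1.0], abnormal=[True, False]))
        assert auc(separable) == pytest.approx(1.0)
        assert auc(diagonal) == pytest.approx(0.5)

    def test_auc_equals_rank_statistic_with_tie_half_credit(self, rng):
        for _ in range(20):
            s = random_scored_set(rng)
            pos = s.scores[s.abnormal]
            neg = s.scores[~s.abnormal]
            ranks = rankdata(np.concatenate([pos, neg]))
            u = ranks[: len(pos)].sum() - len(pos) * (len(pos) + 1) / 2
            expected = u / (len(pos) * len(neg))
            assert auc(roc_from_scores(s)) == pytest.approx(expected, abs=1e-12)

    def test_summarize_collects_measures(self, rng):
        s = random_scored_set(rng)
        summary = summarize(roc_from_scores(s), cost_ratios=(1.0, 2.0))
        assert 0.0 <= summary.eer <= 1.0
        assert 0.0 <= summary.auc <= 1.0
        assert set(summary.wer) == {1.0, 2.0}
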