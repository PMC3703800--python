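import math

import numpy as np
import pytest

from fundusbench.fusion import (
    FusionDataset,
    average_experts,
    default_tau_grid,
    fuse_at,
    mutual_agreement_perf,
    optimize_tau,
    original_fusion,
    threshold_mask,
)
from fundusbench.rasterize import ConfidenceImage

from conftest import random_fusion_dataset


def ci(values, expert="e0", image="img00"):
    return ConfidenceImage(
        image_id=image, lesion_type="hard_exudates", expert_id=expert,
        values=np.asarray(values, dtype=float),
    )


def stack_dataset(stacks, lesion="hard_exudates"):
    stacks = tuple(np.asarray(s, dtype=float) for s in stacks)
    return FusionDataset(
        lesion_type=lesion,
        image_ids=tuple(f"img{i:02d}" for i in range(len(stacks))),
        expert_ids=tuple(f"e{i}" for i in range(stacks[0].shape[0])),
        stacks=stacks,
    )


# ---------------------------------------------------------------------------
# independent brute-force oracle: explicit loops, no shared library code

def brute_force_perf(stacks, tau):
    n_experts = len(stacks[0])
    n_images = len(stacks)
    labels = []
    for i in range(n_images):
        h = len(stacks[i][0])
        w = len(stacks[i][0][0])
        abnormal = False
        for r in range(h):
            for c in range(w):
                total = 0.0
                for n in range(n_experts):
                    total += stacks[i][n][r][c]
                if total / n_experts >= tau:
                    abnormal = True
        labels.append(abnormal)
    if all(labels) or not any(labels):
        return None
    eers = []
    for n in range(n_experts):
        scores = []
        for i in range(n_images):
            flat = sorted((v for row in stacks[i][n] for v in row), reverse=True)
            k = max(1, math.ceil(0.01 * len(flat)))
            scores.append(sum(flat[:k]))
        eers.append(brute_force_eer(scores, labels))
    return sum(eers) / n_experts


def brute_force_eer(scores, labels):
    points = [(0.0, 0.0)]
    n_pos = sum(labels)
    n_neg = len(labels) - n_pos
    for t in sorted(set(scores), reverse=True):
        tp = sum(1 for s, l in zip(scores, labels) if l and s >= t)
        fp = sum(1 for s, l in zip(scores, labels) if not l and s >= t)
        points.append((fp / n_neg, tp / n_pos))
    if points[-1] != (1.0, 1.0):
        points.append((1.0, 1.0))
    for (x1, y1), (x2, y2) in zip(points, points[1:]):
        f1 = y1 - (1.0 - x1)
        f2 = y2 - (1.0 - x2)
        if f1 == 0.0:
            return x1
        if f1 < 0.0 <= f2:
            t = f1 / (f1 - f2)
            return x1 + t * (x2 - x1)
    return points[-1][0]


class TestAveraging:
    def test_binary_votes(self):
        imgs = [ci([[v]], expert=f"e{i}") for i, v in enumerate([1.0, 1.0, 1.0, 0.0])]
        assert average_experts(imgs).values[0, 0] == pytest.approx(0.75)

    def test_identical_images_average_to_themselves(self, rng):
        values = rng.choice([0.0, 1 / 3, 2 / 3, 1.0], size=(5, 5))
        imgs = [ci(values, expert=f"e{i}") for i in range(4)]
        np.testing.assert_allclose(average_experts(imgs).values, values)

    def test_mixed_confidences(self):
        imgs = [ci([[1 / 3]], "e0"), ci([[1.0]], "e1")]
        assert average_experts(imgs).values[0, 0] == pytest.approx(2 / 3)

    def test_size_mismatch_names_image(self):
        with pytest.raises(ValueError, match="img00"):
            average_experts([ci(np.zeros((4, 4))), ci(np.zeros((5, 4)), "e1")])

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            average_experts([])


class TestThresholdMask:
    def test_three_of_four_binary_experts_survive_075(self):
        counts = np.array([[0, 1, 2], [3, 4, 0]], dtype=float)
        avg = counts / 4.0
        mask = threshold_mask(avg, 0.75)
        np.testing.assert_array_equal(mask, counts >= 3)

    def test_union_and_intersection_limits(self, rng):
        supports = rng.random((4, 8, 8)) < 0.3
        avg = supports.astype(float).mean(axis=0)
        union = threshold_mask(avg, 0.25)  # smallest attainable positive average
        np.testing.assert_array_equal(union, supports.any(axis=0))
        intersection = threshold_mask(avg, 1.0)
        np.testing.assert_array_equal(intersection, supports.all(axis=0))

    @pytest.mark.parametrize("tau", [0.0, -0.1, 1.0001])
    def test_tau_outside_unit_interval_rejected(self, tau):
        with pytest.raises(ValueError):
            threshold_mask(np.zeros((2, 2)), tau)

    def test_mask_monotone_in_tau(self, rng):
        for _ in range(20):
            ds = random_fusion_dataset(rng)
            avgs = ds.averages()
            taus = sorted(rng.uniform(0.01, 1.0, size=4))
            for avg in avgs:
                previous = None
                for tau in taus:
                    mask = threshold_mask(avg, tau)
                    if previous is not None:
                        assert not (mask & ~previous).any()  # mask shrinks
                    previous = mask


class TestMutualAgreement:
    def test_perfect_agreement_scores_zero(self):
        lesion = np.zeros((8, 8))
        lesion[2:5, 2:5] = 1.0
        blank = np.zeros((8, 8))
        stacks = [np.stack([lesion] * 3), np.stack([blank] * 3),
                  np.stack([lesion] * 3), np.stack([blank] * 3)]
        assert mutual_agreement_perf(stack_dataset(stacks), 1.0) == 0.0

    def test_single_expert_reduces_to_own_eer(self, rng):
        ds = random_fusion_dataset(rng, n_experts=1, n_images=6)
        tau = 0.5
        perf = mutual_agreement_perf(ds, tau)
        if not math.isnan(perf):
            assert perf == pytest.approx(brute_force_perf([s.tolist() for s in ds.stacks], tau))

    def test_degenerate_tau_returns_nan(self):
        blank = np.zeros((4, 4))
        ds = stack_dataset([np.stack([blank]), np.stack([blank])])
        assert math.isnan(mutual_agreement_perf(ds, 0.5))

    def test_matches_brute_force_on_random_datasets(self, rng):
        for _ in range(15):
            ds = random_fusion_dataset(rng)
            for tau in default_tau_grid(ds):
                expected = brute_force_perf([s.tolist() for s in ds.stacks], tau)
                got = mutual_agreement_perf(ds, tau)
                if expected is None:
                    assert math.isnan(got)
                else:
                    assert got == pytest.approx(expected, abs=1e-12)

    def test_invariant_under_expert_relabeling(self, rng):
        for _ in range(10):
            ds = random_fusion_dataset(rng, n_experts=3)
            perm = rng.permutation(3)
            permuted = FusionDataset(
                lesion_type=ds.lesion_type,
                image_ids=ds.image_ids,
                expert_ids=tuple(ds.expert_ids[p] for p in perm),
                stacks=tuple(s[perm] for s in ds.stacks),
            )
            for tau in (0.25, 0.5, 1.0):
                a = mutual_agreement_perf(ds, tau)
                b = mutual_agreement_perf(permuted, tau)
                assert (math.isnan(a) and math.isnan(b)) or a == pytest.approx(b)


class TestOptimizeTau:
    def test_identical_experts_tie_over_all_admissible(self):
        lesion = np.zeros((8, 8))
        lesion[1:4, 1:4] = 1.0
        blank = np.zeros((8, 8))
        stacks = [np.stack([lesion] * 2), np.stack([blank] * 2), np.stack([lesion] * 2)]
        result = optimize_tau(stack_dataset(stacks))
        admissible = [t for t, p in zip(result.tau_grid, result.perf_per_tau)
                      if not math.isnan(p)]
        assert result.best_perf == 0.0
        assert list(result.equally_performing) == admissible
        assert result.tau_hat == result.tau_max

    def test_single_candidate_grid(self):
        lesion = np.zeros((4, 4))
        lesion[0, 0] = 1.0
        blank = np.zeros((4, 4))
        ds = stack_dataset([np.stack([lesion]), np.stack([blank])])
        result = optimize_tau(ds, grid=[0.5])
        assert result.tau_hat == 0.5

    def test_all_degenerate_grid_rejected(self):
        blank = np.zeros((4, 4))
        ds = stack_dataset([np.stack([blank]), np.stack([blank])])
        with pytest.raises(ValueError, match="no admissible"):
            optimize_tau(ds)

    def test_invalid_grid_rejected(self, rng):
        ds = random_fusion_dataset(rng)
        with pytest.raises(ValueError):
            optimize_tau(ds, grid=[0.0, 0.5])

    def test_search_is_deterministic(self, rng):
        ds = random_fusion_dataset(rng)
        try:
            a = optimize_tau(ds)
            b = optimize_tau(ds)
        except ValueError:
            return
        assert a.tau_hat == b.tau_hat
        assert a.perf_per_tau == b.perf_per_tau


class TestOriginalFusion:
    def test_binary_vote_thresholding(self):
        votes = np.zeros((4, 1, 3))  # 4 experts, pixel columns voted by 2, 3, 4
        votes[:2, 0, 0] = 1.0
        votes[:3, 0, 1] = 1.0
        votes[:, 0, 2] = 1.0
        blank = np.zeros((4, 1, 3))
        fused = original_fusion(stack_dataset([votes, blank]))
        assert fused.tau == 0.75
        mask = fused.masks[0]
        assert not mask[0, 0]  # 2 of 4 -> 0.5 < 0.75 excluded
        assert mask[0, 1]  # 3 of 4 -> 0.75 >= 0.75 included
        assert mask[0, 2]  # unanimous included
        assert fused.image_labels["img00"] == "abnormal"
        assert fused.image_labels["img01"] == "normal"
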