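"""Objective terms: closed forms, oracle equivalence, analytic gradients."""

import numpy as np
import pytest

from cdmenet.density import DensityMap, LevelTargets
from cdmenet.losses import (
    LossWeights,
    compose_losses,
    cosine_similarity,
    cross_entropy_loss,
    density_difference_loss,
    mse_density_loss,
)
from conftest import outputs_from


def _targets(maps, validity=None, source="ground_truth"):
    maps = np.asarray(maps, dtype=float)
    if validity is None:
        validity = np.ones(maps.shape[1:])
    return LevelTargets(maps, np.asarray(validity, dtype=float), 8, source)


class TestCrossEntropy:
    def test_hand_case_single_pixel(self):
        # k=2, target (1, 0), both predictions 0.5: -(log .5 + log .5)/2
        out = outputs_from([[[0.5]], [[0.5]]])
        lt = _targets([[[1.0]], [[0.0]]])
        assert cross_entropy_loss(out, lt) == pytest.approx(0.6931, abs=1e-4)
        # pixel-sum and pixel-mean normalisations agree on one valid pixel
        assert cross_entropy_loss(out, lt, normalize_pixels=True) == pytest.approx(
            0.6931, abs=1e-4
        )

    def test_confident_correct_predictions_cost_nothing(self):
        probs = np.array([[[1.0, 0.0]], [[0.0, 1.0]]])
        lt = _targets(probs.copy())
        assert cross_entropy_loss(outputs_from(probs), lt) <= 1e-6

    def test_invalid_pixels_contribute_nothing(self):
        rng = np.random.default_rng(0)
        maps = np.zeros((2, 3, 3))
        maps[0, 0, 0] = 1.0
        validity = np.ones((3, 3))
        validity[1:, :] = 0.0
        lt = _targets(maps, validity)
        probs = rng.uniform(0.1, 0.9, (2, 3, 3))
        flipped = probs.copy()
        flipped[:, 1:, :] = rng.uniform(0.1, 0.9, (2, 2, 3))
        a = cross_entropy_loss(outputs_from(probs), lt)
        b = cross_entropy_loss(outputs_from(flipped), lt)
        assert a == pytest.approx(b, rel=1e-12)

    def test_no_valid_pixels_returns_zero(self):
        lt = _targets(np.zeros((2, 2, 2)), np.zeros((2, 2)))
        loss, grad = cross_entropy_loss(
            outputs_from(np.full((2, 2, 2), 0.5)), lt, with_grad=True
        )
        assert loss == 0.0
        assert np.all(grad == 0)

    def test_monotone_decrease_toward_target(self):
        rng = np.random.default_rng(1)
        target = (rng.uniform(size=(3, 4, 4)) < 0.3).astype(float)
        target *= target.sum(axis=0, keepdims=True) <= 1  # keep exclusive
        lt = _targets(target)
        start = rng.uniform(0.2, 0.8, (3, 4, 4))
        losses = [
            cross_entropy_loss(outputs_from(start + a * (target - start)), lt)
            for a in np.linspace(0, 0.95, 12)
        ]
        assert all(b <= a + 1e-12 for a, b in zip(losses, losses[1:]))

    def test_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(2)
        probs = rng.uniform(0.1, 0.9, (2, 3, 3))
        maps = np.zeros((2, 3, 3))
        maps[1, 2, 2] = 1.0
        validity = (rng.uniform(size=(3, 3)) < 0.8).astype(float)
        lt = _targets(maps, validity)
        _, grad = cross_entropy_loss(outputs_from(probs), lt, with_grad=True)
        eps = 1e-7
        for idx in [(0, 0, 0), (1, 2, 2), (0, 1, 1)]:
            p1, p2 = probs.copy(), probs.copy()
            p1[idx] += eps
            p2[idx] -= eps
            fd = (
                cross_entropy_loss(outputs_from(p1), lt)
                - cross_entropy_loss(outputs_from(p2), lt)
            ) / (2 * eps)
            assert grad[idx] == pytest.approx(fd, rel=1e-5, abs=1e-10)


class TestCosineSimilarity:
    @pytest.mark.parametrize(
        "f1, f2, expected",
        [
            ([3.0, 4.0], [3.0, 4.0], 1.0),
            ([1.0, 0.0], [0.0, 1.0], 0.0),
            ([1.0, 0.0], [1.0, 1.0], 1.0 / np.sqrt(2)),
            ([0.0, 0.0], [1.0, 1.0], 0.0),  # epsilon-dominated
        ],
    )
    def test_closed_forms(self, f1, f2, expected):
        assert cosine_similarity(f1, f2) == pytest.approx(expected, abs=1e-6)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            cosine_similarity([1.0], [1.0, 2.0])


def _dd_oracle(probs, targets, epsilon=1e-8):
    """Brute-force triple loop over levels and columns."""
    k, _, w = probs.shape
    l_max = 0.0
    for i in range(k):
        for col in range(w):
            l_max += cosine_similarity(probs[i, :, col], targets[i, :, col], epsilon)
    l_max *= -1.0 / k
    l_min = 0.0
    for i in range(k):
        for j in range(k):
            if j == i:
                continue
            for col in range(w):
                l_min += cosine_similarity(probs[i, :, col], targets[j, :, col], epsilon)
    l_min /= k * (k - 1)
    return l_max + l_min


class TestDensityDifferenceLoss:
    def test_disjoint_one_hot_closed_form(self):
        """Perfect predictions of disjoint one-hot targets: the two matched
        nonzero columns each score cosine 1, averaged over k=2 levels the
        pulling term is -1; no cross-level column pair overlaps, so the
        pushing term is 0."""
        t1 = np.array([[1.0, 0.0], [1.0, 0.0]])
        t2 = np.array([[0.0, 1.0], [0.0, 1.0]])
        lt = _targets(np.stack([t1, t2]))
        loss = density_difference_loss(outputs_from(np.stack([t1, t2])), lt)
        assert loss == pytest.approx(-1.0, abs=1e-6)
        assert loss == pytest.approx(_dd_oracle(np.stack([t1, t2]), lt.maps), abs=1e-9)

    def test_swapped_predictions_are_penalized(self):
        t1 = np.array([[1.0, 0.0], [1.0, 0.0]])
        t2 = np.array([[0.0, 1.0], [0.0, 1.0]])
        lt = _targets(np.stack([t1, t2]))
        matched = density_difference_loss(outputs_from(np.stack([t1, t2])), lt)
        swapped = density_difference_loss(outputs_from(np.stack([t2, t1])), lt)
        assert swapped > matched

    def test_identity_assignment_is_best_permutation(self):
        from itertools import permutations

        rng = np.random.default_rng(3)
        targets = np.zeros((3, 4, 4))
        for col in range(4):  # disjoint one-hot columns
            lvl = rng.integers(3)
            targets[lvl, rng.integers(4), col] = 1.0
        lt = _targets(targets)
        losses = {
            perm: density_difference_loss(outputs_from(targets[list(perm)]), lt)
            for perm in permutations(range(3))
        }
        assert min(losses, key=losses.get) == (0, 1, 2)

    def test_all_zero_maps_give_zero_loss(self):
        lt = _targets(np.zeros((2, 3, 3)))
        assert density_difference_loss(outputs_from(np.zeros((2, 3, 3))), lt) == 0.0

    def test_matches_brute_force_on_random_cases(self):
        rng = np.random.default_rng(4)
        for _ in range(150):
            k = int(rng.integers(2, 4))
            probs = rng.uniform(0, 1, (k, 4, 4))
            maps = np.zeros((k, 4, 4))
            pick = rng.integers(0, k + 1, size=(4, 4))  # k means background
            for lvl in range(k):
                maps[lvl][pick == lvl] = 1.0
            validity = (rng.uniform(size=(4, 4)) < 0.9).astype(float)
            lt = _targets(maps * validity, validity, source="pseudo_label")
            got = density_difference_loss(outputs_from(probs), lt)
            want = _dd_oracle(probs, maps * validity)
            assert got == pytest.approx(want, rel=1e-9, abs=1e-12)

    def test_rows_extraction_is_transposed_columns(self):
        rng = np.random.default_rng(5)
        probs = rng.uniform(0, 1, (2, 3, 5))
        maps = (rng.uniform(size=(2, 3, 5)) < 0.4).astype(float)
        maps[1] *= 1 - maps[0]
        lt = _targets(maps)
        lt_t = _targets(maps.transpose(0, 2, 1))
        a = density_difference_loss(outputs_from(probs), lt, extract="rows")
        b = density_difference_loss(outputs_from(probs.transpose(0, 2, 1)), lt_t)
        assert a == pytest.approx(b, rel=1e-12)

    def test_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(6)
        probs = rng.uniform(0.05, 0.95, (3, 3, 3))
        maps = np.zeros((3, 3, 3))
        maps[0, 0, 0] = maps[1, 1, 1] = maps[2, 2, 2] = 1.0
        lt = _targets(maps)
        _, grad = density_difference_loss(outputs_from(probs), lt, with_grad=True)
        eps = 1e-7
        for idx in [(0, 0, 0), (1, 2, 1), (2, 1, 2)]:
            p1, p2 = probs.copy(), probs.copy()
            p1[idx] += eps
            p2[idx] -= eps
            fd = (
                density_difference_loss(outputs_from(p1), lt)
                - density_difference_loss(outputs_from(p2), lt)
            ) / (2 * eps)
            assert grad[idx] == pytest.approx(fd, rel=1e-5, abs=1e-10)

    def test_single_level_rejected(self):
        lt = _targets(np.zeros((1, 2, 2)))
        with pytest.raises(ValueError, match="k >= 2"):
            density_difference_loss(outputs_from(np.zeros((1, 2, 2))), lt)


class TestMseDensityLoss:
    def test_hand_case(self):
        a = DensityMap(np.array([[1.0, 2.0]]), 8)
        b = DensityMap(np.zeros((1, 2)), 8)
        assert mse_density_loss(a, b) == 5.0

    def test_symmetry_and_zero(self):
        rng = np.random.default_rng(7)
        a = DensityMap(rng.uniform(0, 2, (4, 4)), 8)
        b = DensityMap(rng.uniform(0, 2, (4, 4)), 8)
        assert mse_density_loss(a, b) == mse_density_loss(b, a)
        assert mse_density_loss(a, a) == 0.0

    def test_shape_or_resolution_mismatch_rejected(self):
        a = DensityMap(np.zeros((2, 2)), 8)
        with pytest.raises(ValueError):
            mse_density_loss(a, DensityMap(np.zeros((2, 3)), 8))
        with pytest.raises(ValueError):
            mse_density_loss(a, DensityMap(np.zeros((2, 2)), 1))


class TestComposeLosses:
    def test_labeled_composition_hand_case(self):
        bd = compose_losses(ce=1.0, dd=-1.0, mse=2.0, image_is_labeled=True)
        assert bd.labeled_total == pytest.approx(2 + 0.01 * 1 + 1 * (-1))
        assert bd.total == bd.labeled_total
        assert bd.unlabeled_total == 0.0

    def test_unlabeled_has_no_density_term(self):
        bd = compose_losses(ce=0.5, dd=0.2, image_is_labeled=False)
        assert bd.mse == 0.0
        assert bd.unlabeled_total == pytest.approx(0.01 * 0.5 + 0.2)

    def test_unlabeled_with_density_target_is_contract_violation(self):
        with pytest.raises(ValueError, match="unlabeled"):
            compose_losses(ce=0.0, dd=0.0, mse=1.0, image_is_labeled=False)

    def test_linearity_in_each_component(self):
        w = LossWeights(lambda1=0.5, lambda2=2.0, lambda3=0.25, lambda4=3.0)
        base = compose_losses(ce=1.0, dd=1.0, mse=1.0, weights=w, image_is_labeled=True)
        bumped = compose_losses(ce=2.0, dd=1.0, mse=1.0, weights=w, image_is_labeled=True)
        assert bumped.labeled_total - base.labeled_total == pytest.approx(0.5)
        u1 = compose_losses(ce=0.0, dd=1.0, weights=w, image_is_labeled=False)
        u2 = compose_losses(ce=0.0, dd=3.0, weights=w, image_is_labeled=False)
        assert u2.unlabeled_total - u1.unlabeled_total == pytest.approx(6.0)

    def test_weights_validate(self):
        with pytest.raises(ValueError):
            LossWeights(lambda1=-0.1)
        with pytest.raises(ValueError):
            LossWeights(epsilon=0.0)
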