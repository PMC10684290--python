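"""Density-map construction, thresholds and level targets."""

import numpy as np
import pytest
from scipy.ndimage import gaussian_filter

from cdmenet.density import (
    DensityMap,
    PointSet,
    ThresholdSet,
    compute_thresholds,
    downsample_sum,
    make_density_map,
    make_level_targets,
)


class TestPointSet:
    def test_rejects_out_of_bounds_points(self):
        with pytest.raises(ValueError, match="outside"):
            PointSet("p", 64, 64, [[64.0, 10.0]])
        with pytest.raises(ValueError, match="outside"):
            PointSet("p", 64, 64, [[10.0, -0.1]])

    def test_count(self):
        assert PointSet("p", 64, 64, [[1, 2], [3, 4]]).count() == 2
        assert PointSet("p", 64, 64, np.empty((0, 2))).count() == 0


class TestMakeDensityMap:
    def test_empty_pointset_gives_zero_map(self):
        d = make_density_map(PointSet("e", 64, 64, np.empty((0, 2))), sigma=5.0)
        assert d.values.shape == (64, 64)
        assert d.sum() == 0.0

    def test_interior_point_has_unit_mass(self):
        d = make_density_map(PointSet("c", 256, 256, [[128.0, 128.0]]), sigma=15.0)
        assert abs(d.sum() - 1.0) < 1e-3
        assert d.values.min() >= 0.0

    def test_matches_gaussian_filter_oracle_for_integer_point(self):
        # independent route: blur a unit impulse with scipy's Gaussian filter
        h = w = 96
        impulse = np.zeros((h, w))
        impulse[40, 50] = 1.0
        oracle = gaussian_filter(impulse, sigma=5.0, truncate=4.0, mode="constant")
        d = make_density_map(PointSet("i", w, h, [[50.0, 40.0]]), sigma=5.0)
        assert np.allclose(d.values, oracle, atol=1e-6)

    def test_border_truncation_reduces_mass(self):
        d = make_density_map(PointSet("b", 64, 64, [[0.0, 0.0]]), sigma=5.0)
        assert d.sum() < 0.5  # about three quarters of the bump falls outside

    def test_sum_conservation_for_interior_points(self):
        # points at least 4 sigma from every border keep ~all their mass
        rng = np.random.default_rng(7)
        sigma, margin = 5.0, 20
        for _ in range(10):
            n = int(rng.integers(1, 40))
            pts = rng.uniform(margin, 96 - margin, size=(n, 2))
            d = make_density_map(PointSet("s", 96, 96, pts), sigma=sigma)
            assert abs(d.sum() - n) <= 0.01 * n

    def test_invalid_sigma_rejected(self):
        ps = PointSet("p", 32, 32, [[4, 4]])
        with pytest.raises(ValueError, match="sigma"):
            make_density_map(ps, sigma=0.0)


class TestDownsampleSum:
    def test_factor_one_is_identity(self):
        d = DensityMap(np.arange(16.0).reshape(4, 4))
        out = downsample_sum(d, 1)
        assert np.array_equal(out.values, d.values)

    def test_block_sums(self):
        out = downsample_sum(DensityMap(np.ones((4, 4))), 2)
        assert out.values.shape == (2, 2)
        assert np.array_equal(out.values, np.full((2, 2), 4.0))
        assert out.resolution_divisor == 2

    def test_sum_preserved_exactly(self):
        rng = np.random.default_rng(0)
        v = rng.uniform(0, 3, size=(40, 64))
        for factor in (2, 4, 8):
            out = downsample_sum(DensityMap(v), factor)
            assert out.sum() == pytest.approx(v.sum(), abs=1e-12)

    def test_non_divisible_dimensions_rejected(self):
        with pytest.raises(ValueError, match="divisible"):
            downsample_sum(DensityMap(np.ones((6, 6))), 4)


class TestComputeThresholds:
    def test_explicit_index_rule(self):
        # ascending nonzero values [0.1, 0.2, 0.3, 0.4]; threshold at S is the
        # 1-based index ceil(S*T) clamped to [1, T]
        d = DensityMap(np.array([[0.1, 0.2], [0.3, 0.4]]))
        th = compute_thresholds([d], [0.0, 0.5, 1.0])
        assert th.thresholds == (0.1, 0.2, 0.4)
        assert th.n_levels == 2

    def test_default_positions_span_min_to_max(self):
        rng = np.random.default_rng(3)
        d = DensityMap(rng.uniform(0, 1, (16, 16)))
        th = compute_thresholds([d])
        assert th.n_levels == 3
        assert th.thresholds[0] == pytest.approx(d.values[d.values > 0].min())
        assert th.thresholds[-1] == pytest.approx(d.values.max())

    def test_constant_values_collapse(self):
        d = DensityMap(np.full((4, 4), 0.7))
        th = compute_thresholds([d])
        assert all(t == 0.7 for t in th.thresholds)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(5)
        vals = rng.uniform(0, 2, size=60)
        a = DensityMap(vals[:36].reshape(6, 6))
        b = DensityMap(vals[36:].reshape(4, 6))
        shuffled = rng.permutation(vals)
        c = DensityMap(shuffled[:24].reshape(4, 6))
        d = DensityMap(shuffled[24:].reshape(6, 6))
        assert (
            compute_thresholds([a, b]).thresholds
            == compute_thresholds([b, a]).thresholds
            == compute_thresholds([c, d]).thresholds
        )

    def test_all_zero_maps_rejected(self):
        with pytest.raises(ValueError, match="nonzero"):
            compute_thresholds([DensityMap(np.zeros((4, 4)))])


def _level_targets_oracle(values, thresholds):
    """Independent per-pixel loop applying the interval rule."""
    k = len(thresholds) - 1
    maps = np.zeros((k,) + values.shape)
    for i in range(values.shape[0]):
        for j in range(values.shape[1]):
            v = values[i, j]
            for lvl in range(k):
                lower = 0.0 if lvl == 0 else thresholds[lvl]
                upper = thresholds[lvl + 1]
                if lower < v <= upper:
                    maps[lvl, i, j] = 1.0
    return maps


class TestMakeLevelTargets:
    def test_matches_per_pixel_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(30):
            values = rng.uniform(0, 1, size=(16, 16))
            values[rng.uniform(size=(16, 16)) < 0.3] = 0.0
            q = np.sort(rng.uniform(0, 1, size=4))
            th = compute_thresholds([DensityMap(values)], [0.0, q[1], q[2], 1.0])
            lt = make_level_targets(DensityMap(values, 8), th)
            assert np.array_equal(lt.maps, _level_targets_oracle(values, th.thresholds))
            assert np.all(lt.validity == 1)
            assert lt.source == "ground_truth"

    def test_interval_rule_example(self):
        # thresholds (0.2, 0.3, 0.4): level 1 covers (0, 0.3], level 2 (0.3, 0.4]
        th = ThresholdSet((0.0, 0.5, 1.0), (0.2, 0.3, 0.4))
        lt = make_level_targets(DensityMap(np.array([[0.25]]), 8), th)
        assert lt.maps[:, 0, 0].tolist() == [1.0, 0.0]
        oracle = _level_targets_oracle(np.array([[0.25]]), th.thresholds)
        assert np.array_equal(lt.maps, oracle)

    def test_all_zero_map_has_no_levels(self):
        th = ThresholdSet((0.0, 0.5, 1.0), (0.1, 0.2, 0.3))
        lt = make_level_targets(DensityMap(np.zeros((4, 4)), 8), th)
        assert lt.maps.sum() == 0

    def test_levels_are_mutually_exclusive(self):
        rng = np.random.default_rng(2)
        values = rng.uniform(0, 2, (12, 12))
        th = compute_thresholds([DensityMap(values)])
        lt = make_level_targets(DensityMap(values, 8), th)
        assert (lt.maps.sum(axis=0) <= 1).all()

    def test_raising_density_never_lowers_level(self):
        th = ThresholdSet((0.0, 0.4, 0.8, 1.0), (0.1, 0.3, 0.6, 1.0))

        def level_index(v):
            lt = make_level_targets(DensityMap(np.array([[v]]), 8), th)
            hits = np.flatnonzero(lt.maps[:, 0, 0])
            return int(hits[0]) if len(hits) else -1

        grid = np.linspace(0.0, 1.0, 101)
        indices = [level_index(v) for v in grid if level_index(v) >= 0]
        assert indices == sorted(indices)


class TestThresholdSet:
    def test_needs_two_levels(self):
        with pytest.raises(ValueError, match="2 levels"):
            ThresholdSet((0.0, 1.0), (0.1, 0.2))

    def test_rejects_decreasing_thresholds(self):
        with pytest.raises(ValueError, match="non-decreasing"):
            ThresholdSet((0.0, 0.5, 1.0), (0.3, 0.2, 0.4))
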