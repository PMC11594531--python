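"""Tests for direction angles, radial burden and dispersion σ."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tumevo.spatial import (
    DispersionConfig,
    angle_distribution,
    angle_uniformity_test,
    clone_position,
    direction_angle,
    dispersion_sigma,
    dispersion_table,
    expected_packed_distance,
    ks_statistic,
    radial_mutation_burden,
    reconstruct_parent_map,
    true_parent_map,
    tumour_centre,
)

from conftest import make_table


class TestGeometryPrimitives:
    def test_centre_is_sample_centroid(self):
        t = make_table([[0, 0], [2, 0], [1, 3]], [[0.5, 0.5, 0.5]])
        np.testing.assert_allclose(tumour_centre(t), [1.0, 1.0])

    def test_clone_position_weighted_centroid(self):
        t = make_table([[0, 0], [2, 0]], [[0.5, 0.5]])
        np.testing.assert_allclose(clone_position(1, t), [1.0, 0.0])
        t2 = make_table([[0, 0], [2, 0]], [[0.75, 0.25]])
        np.testing.assert_allclose(clone_position(1, t2), [0.5, 0.0])

    def test_single_carrier_clone_sits_on_its_sample(self):
        t = make_table([[3, 4], [9, 9]], [[0.4, 0.0]])
        np.testing.assert_allclose(clone_position(1, t), [3.0, 4.0])

    @pytest.mark.parametrize("child,expected", [
        ((2.0, 0.0), 0.0),      # radially outward
        ((0.5, 0.0), 180.0),    # back towards the centre
        ((1.0, 1.0), 90.0),     # perpendicular, counter-clockwise
        ((1.0, -1.0), -90.0),   # perpendicular, clockwise
    ])
    def test_direction_angle_examples(self, child, expected):
        ang = direction_angle((0, 0), (1, 0), child)
        assert ang == pytest.approx(expected)

    def test_degenerate_vectors_raise(self):
        with pytest.raises(ValueError):
            direction_angle((0, 0), (0, 0), (1, 0))
        with pytest.raises(ValueError):
            direction_angle((0, 0), (1, 0), (1, 0))

    def test_3d_angle_is_unsigned(self):
        a = direction_angle((0, 0, 0), (1, 0, 0), (1, 1, 0))
        b = direction_angle((0, 0, 0), (1, 0, 0), (1, -1, 0))
        assert a == pytest.approx(90.0) and b == pytest.approx(90.0)


class TestParentMaps:
    def test_containment_recovers_nested_clones(self):
        # m1 everywhere, m2 in a sub-region, m3 inside m2's region
        F = np.array([
            [0.9, 0.9, 0.9, 0.9],
            [0.0, 0.6, 0.6, 0.0],
            [0.0, 0.3, 0.0, 0.0],
        ])
        t = make_table([[0, 0], [1, 0], [2, 0], [3, 0]], F)
        pm = reconstruct_parent_map(t)
        assert pm == {1: -1, 2: 1, 3: 2}

    def test_true_parent_map_chains_multi_gains(self):
        from tumevo.simulate import GenotypeTree

        tree = GenotypeTree()
        g1 = tree.add_node(0, 2, 1.0, 2)   # gains mutations 0,1
        tree.add_node(g1, 1, 2.0, 3)       # gains mutation 2
        pm = true_parent_map(tree)
        assert pm[0] == -1 and pm[1] == 0 and pm[2] == 1


class TestAngleDistribution:
    def _nested_table(self):
        F = np.array([
            [0.8, 0.8, 0.8, 0.8, 0.8],
            [0.0, 0.0, 0.7, 0.7, 0.0],
            [0.0, 0.0, 0.0, 0.4, 0.0],
        ])
        pos = [[0, 0], [1, 0], [2, 0], [3, 0], [4, 0]]
        return make_table(pos, F)

    def test_weights_sum_to_one_per_clone(self):
        t = self._nested_table()
        pm = reconstruct_parent_map(t)
        for mode in ("centroid", "pairwise"):
            ad = angle_distribution(t, pm, mode=mode)
            sums = ad.groupby("mutation_id")["weight"].sum()
            np.testing.assert_allclose(sums, 1.0)

    def test_invariant_under_rigid_motions(self):
        t = self._nested_table()
        pm = reconstruct_parent_map(t)
        ad0 = angle_distribution(t, pm, mode="pairwise")
        theta = np.radians(37.0)
        R = np.array([[np.cos(theta), -np.sin(theta)],
                      [np.sin(theta), np.cos(theta)]])
        pos2 = t.positions() @ R.T + np.array([5.0, -3.0])
        t2 = make_table(pos2, np.array([
            [0.8, 0.8, 0.8, 0.8, 0.8],
            [0.0, 0.0, 0.7, 0.7, 0.0],
            [0.0, 0.0, 0.0, 0.4, 0.0],
        ]))
        ad2 = angle_distribution(t2, reconstruct_parent_map(t2), mode="pairwise")
        # compare on the circle: ±180° are the same direction
        for f in (np.cos, np.sin):
            np.testing.assert_allclose(f(np.radians(ad0["theta"])),
                                       f(np.radians(ad2["theta"])), atol=1e-6)
        np.testing.assert_allclose(ad0["weight"], ad2["weight"], atol=1e-12)

    def test_uniform_angles_pass_and_peaked_fail(self):
        rng = np.random.default_rng(0)
        flat = rng.uniform(-180, 180, 300)
        _, _, p_flat = angle_uniformity_test(flat)
        assert p_flat > 0.01
        peaked = rng.normal(0, 30, 300)
        _, _, p_peak = angle_uniformity_test(peaked)
        assert p_peak < 1e-6

    def test_3d_null_is_sin_weighted(self):
        rng = np.random.default_rng(1)
        iso = np.degrees(np.arccos(rng.uniform(-1, 1, 400)))
        _, _, p = angle_uniformity_test(iso, dim=3)
        assert p > 0.01
        flat3d = rng.uniform(0, 180, 400)
        _, _, p2 = angle_uniformity_test(flat3d, dim=3)
        assert p2 < 1e-4

    def test_group_clustering_shrinks_effective_n(self):
        th = np.repeat([10.0, 50.0, -120.0], 100)
        w = np.full(300, 1 / 100)
        groups = np.repeat([1, 2, 3], 100)
        _, n_eff, _ = angle_uniformity_test(th, w, groups=groups)
        assert n_eff == pytest.approx(3.0)


class TestRadialBurden:
    def test_equal_burden_gives_zero_correlation(self):
        F = np.tile([0.5], (1, 9)).reshape(1, 9)
        pos = [[x, y] for x in range(3) for y in range(3)]
        t = make_table(pos, F)
        per, binned, rho = radial_mutation_burden(t)
        assert np.isnan(rho.statistic) or abs(rho.statistic) < 1e-9

    def test_surface_like_gradient_is_detected(self):
        pos = [[float(x), 0.0] for x in range(-5, 6)]
        F = np.zeros((4, 11))
        for i in range(4):
            F[i, np.abs(np.arange(11) - 5) > i] = 0.5
        t = make_table(pos, F)
        per, binned, rho = radial_mutation_burden(t)
        assert rho.statistic > 0.8


class TestPackedDistance:
    def test_disc_and_ball_constants_match_monte_carlo(self):
        rng = np.random.default_rng(12345)
        # disc: rejection-sample uniform points, mean pairwise distance
        pts = rng.uniform(-1, 1, size=(200_000, 2))
        pts = pts[(pts**2).sum(axis=1) <= 1][:40_000]
        a, b = pts[: 20_000], pts[20_000: 40_000]
        mc_disc = np.linalg.norm(a - b, axis=1).mean()
        assert 128 / (45 * math.pi) == pytest.approx(mc_disc, rel=5e-3)
        pts = rng.uniform(-1, 1, size=(400_000, 3))
        pts = pts[(pts**2).sum(axis=1) <= 1][:40_000]
        a, b = pts[: 20_000], pts[20_000: 40_000]
        mc_ball = np.linalg.norm(a - b, axis=1).mean()
        assert 36 / 35 == pytest.approx(mc_ball, rel=5e-3)

    def test_scaling_with_clone_size(self):
        # disc of measure n*a has radius sqrt(n a / pi)
        val = expected_packed_distance(100, math.sqrt(3) / 2, 2)
        R = math.sqrt(100 * math.sqrt(3) / 2 / math.pi)
        assert val == pytest.approx(128 / (45 * math.pi) * R)

    def test_single_cell_has_zero_extent(self):
        assert expected_packed_distance(1, 1.0, 2) == 0.0
        assert expected_packed_distance(0.5, 1.0, 3) == 0.0


class TestDispersion:
    def test_two_samples_at_packed_distance_give_sigma_one(self):
        cfg = DispersionConfig(coverage_fraction=1.0)
        n_clone = 200  # 100 carriers in each of two samples
        D = expected_packed_distance(n_clone, cfg.cross_section(2), 2)
        t = make_table([[0, 0], [D, 0]], [[1.0, 1.0]], cell_counts=[100, 100])
        rec = dispersion_sigma(1, t, cfg)
        assert rec["sigma"] == pytest.approx(1.0)
        assert rec["estimated_clone_cells"] == pytest.approx(200)

    def test_fewer_than_two_carriers_is_undefined(self):
        t = make_table([[0, 0], [1, 0]], [[0.5, 0.0]])
        with pytest.raises(ValueError):
            dispersion_sigma(1, t)
        assert len(dispersion_table(t)) == 0

    def test_scale_invariance(self):
        # doubling lengths and quadrupling the cell cross-section leaves
        # sigma unchanged
        F = [[0.8, 0.6, 0.4]]
        t1 = make_table([[0, 0], [3, 0], [0, 4]], F)
        t2 = make_table([[0, 0], [6, 0], [0, 8]], F)
        s1 = dispersion_sigma(1, t1, DispersionConfig(cell_diameter=1.0))
        s2 = dispersion_sigma(1, t2, DispersionConfig(cell_diameter=2.0))
        assert s1["sigma"] == pytest.approx(s2["sigma"])

    def test_scattered_exceeds_contiguous_of_equal_mass(self):
        pos = [[float(x), float(y)] for x in range(6) for y in range(6)]
        tight = np.zeros(36)
        tight[[0, 1, 6, 7]] = 0.5   # adjacent block
        spread = np.zeros(36)
        spread[[0, 5, 30, 35]] = 0.5  # corners
        t = make_table(pos, np.vstack([tight, spread]))
        st = dispersion_sigma(1, t)
        ss = dispersion_sigma(2, t)
        assert ss["sigma"] > st["sigma"]


class TestKS:
    def test_identical_samples_give_zero(self):
        x = np.arange(10.0)
        assert ks_statistic(x, x) == 0.0

    def test_disjoint_two_by_two(self):
        assert ks_statistic([0.0, 1.0], [5.0, 6.0]) == pytest.approx(1.0)

    @given(st.integers(10, 60), st.integers(10, 60), st.integers(0, 10_000))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_matches_brute_force_ecdf(self, n1, n2, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(size=n1)
        b = rng.normal(1.0, 1.5, size=n2)
        grid = np.concatenate([a, b])
        ecdf_a = (a[None, :] <= grid[:, None]).mean(axis=1)
        ecdf_b = (b[None, :] <= grid[:, None]).mean(axis=1)
        D = np.abs(ecdf_a - ecdf_b).max()
        expected = math.sqrt(n1 * n2 / (n1 + n2)) * D
        assert ks_statistic(a, b) == pytest.approx(expected)
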