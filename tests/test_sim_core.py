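"""Unit and property tests for the off-lattice growth simulator."""

import math

import numpy as np
import pytest
from scipy import stats

from tumevo.simulate import (
    SimParams,
    Simulation,
    ball_measure,
    birth_rate,
    close_packed_density,
    divide_cell,
    draw_mutation_count,
    local_density,
    push_apart,
    simulate,
    simulate_surviving,
)


class TestBirthRate:
    def test_linear_decrease(self):
        p = SimParams(b0=1.0, rho_c=2.0)
        assert birth_rate(0.0, p) == 1.0
        assert birth_rate(2.0, p) == 0.0
        assert birth_rate(1.0, p) == pytest.approx(0.5)
        assert birth_rate(5.0, p) == 0.0  # clipped below at zero

    def test_infinite_rho_c_gives_constant_rate(self):
        p = SimParams(b0=0.7, rho_c=math.inf)
        for rho in [0.0, 0.9, 123.0]:
            assert birth_rate(rho, p) == 0.7

    def test_negative_density_rejected(self):
        with pytest.raises(ValueError):
            birth_rate(-0.1, SimParams())


class TestDensity:
    def test_isolated_cell_has_zero_density(self):
        sim = Simulation.from_positions([[0.0, 0.0]], SimParams(dimension=2))
        pop = sim.snapshot()
        assert local_density(pop.cell_ids[0], pop) == 0.0

    def test_six_touching_neighbours(self):
        # hexagonal shell at distance 1, window radius 1.5 -> 6 / (pi 1.5^2)
        ang = np.arange(6) * np.pi / 3
        pts = [[0.0, 0.0]] + [[np.cos(a), np.sin(a)] for a in ang]
        sim = Simulation.from_positions(pts, SimParams(dimension=2))
        pop = sim.snapshot()
        assert local_density(pop.cell_ids[0], pop) == pytest.approx(
            6 / (np.pi * 1.5**2))

    def test_close_packed_density_matches_hex_shell(self):
        # with window 1.5 x contact distance only the 6 nearest count
        assert close_packed_density(2, 1.0, 1.5) == pytest.approx(
            6 / (np.pi * 1.5**2))
        # FCC: 12 at distance 1 plus 6 at sqrt(2)
        assert close_packed_density(3, 1.0, 1.5) == pytest.approx(
            18 / ball_measure(1.5, 3))

    def test_dense_packing_below_close_packed(self):
        pop = simulate(SimParams(dimension=2, b0=1, d=0, n_max=600, seed=2))
        rho_c = close_packed_density(2, 1.0, 1.5)
        centre_cell = pop.cell_ids[np.argmin(np.linalg.norm(pop.positions, axis=1))]
        rho = local_density(int(centre_cell), pop)
        assert 0.5 * rho_c < rho <= rho_c * 1.01


class TestMutationDraws:
    def test_zero_rate_never_mutates(self):
        rng = np.random.default_rng(0)
        assert all(draw_mutation_count(0.0, rng) == 0 for _ in range(100))

    def test_poisson_distribution_gof(self):
        rng = np.random.default_rng(42)
        mu = 0.3
        draws = np.array([draw_mutation_count(mu, rng) for _ in range(10_000)])
        se = math.sqrt(mu / draws.size)
        assert abs(draws.mean() - mu) < 3 * se
        # chi-square GOF against the Poisson pmf, tail-merged
        kmax = 4
        obs = np.bincount(np.minimum(draws, kmax), minlength=kmax + 1)
        pmf = stats.poisson.pmf(np.arange(kmax), mu)
        exp = np.append(pmf, 1 - pmf.sum()) * draws.size
        chi2 = ((obs - exp) ** 2 / exp).sum()
        assert stats.chi2.sf(chi2, kmax) > 0.01
        assert math.exp(-0.3) == pytest.approx((draws == 0).mean(), abs=0.02)


class TestDivisionAndPushing:
    def test_division_without_mutation_extends_population_only(self):
        sim = Simulation.from_positions([[0.0, 0.0]], SimParams(dimension=2, mu=0.0))
        n_nodes = len(sim.tree)
        divide_cell(sim, 0)
        pop = sim.snapshot()
        assert pop.size == 2
        assert len(pop.tree) == n_nodes  # no new genotypes

    def test_daughter_placed_at_contact_distance(self):
        sim = Simulation.from_positions([[0.0, 0.0]], SimParams(dimension=2))
        d = divide_cell(sim, 0)
        dist = np.linalg.norm(sim.pos[d] - sim.pos[0])
        assert dist == pytest.approx(1.0)  # 2 x cell_radius, no pushes

    def test_division_inside_packed_cluster_resolves_overlaps(self):
        pop = simulate(SimParams(dimension=2, b0=1, d=0, n_max=300, seed=7))
        sim = Simulation.from_positions(pop.positions, SimParams(dimension=2, seed=1))
        centre = int(np.argmin(np.linalg.norm(pop.positions, axis=1)))
        divide_cell(sim, centre)
        final = sim.snapshot()
        dists = np.linalg.norm(
            final.positions[:, None] - final.positions[None, :], axis=-1)
        np.fill_diagonal(dists, np.inf)
        assert dists.min() >= 1.0 - 1e-6

    def test_push_separates_overlapping_pair(self):
        p = SimParams(dimension=2)
        out = push_apart([[0.0, 0.0], [0.9, 0.0]], 0, p)
        dist = np.linalg.norm(out[1] - out[0])
        assert dist == pytest.approx(1.0 + p.margin)

    def test_no_overlap_is_identity(self):
        pts = [[0.0, 0.0], [3.0, 0.0], [0.0, 3.0]]
        out = push_apart(pts, 0, SimParams(dimension=2))
        np.testing.assert_allclose(out, pts)

    @pytest.mark.parametrize("seed", range(5))
    def test_middle_insertion_displaces_outer_cells_outward(self, seed):
        p = SimParams(dimension=2, seed=seed)
        pts = [[-0.95, 0.0], [0.0, 0.0], [0.95, 0.0]]
        out = push_apart(pts, 1, p)
        assert out[0][0] < -0.95 or out[2][0] > 0.95
        d01 = np.linalg.norm(out[1] - out[0])
        d12 = np.linalg.norm(out[2] - out[1])
        assert min(d01, d12) >= 1.0 - 1e-9


class TestSimulate:
    def test_pure_birth_no_mutation(self):
        pop = simulate(SimParams(dimension=2, b0=1, d=0, mu=0, n_max=10, seed=1))
        assert pop.size == 10
        assert len(pop.tree) == 1
        assert pop.tree.live_count[0] == 10

    def test_determinism(self):
        p = SimParams(dimension=2, b0=1, d=0.3, mu=0.2, n_max=400, seed=99)
        a, b = simulate(p), simulate(p)
        np.testing.assert_array_equal(a.positions, b.positions)
        assert a.tree.parent == b.tree.parent
        assert a.time == b.time

    def test_bookkeeping_identity(self):
        pop = simulate(SimParams(dimension=2, b0=1, d=0.5, mu=0.3, n_max=300, seed=5))
        assert pop.size == 1 + pop.births - pop.deaths
        assert sum(pop.tree.live_count) == pop.size

    def test_extinction_flagged(self):
        pop = simulate(SimParams(dimension=2, b0=1, d=10.0, n_max=100, seed=0))
        assert pop.extinct and pop.size == 0

    def test_surviving_wrapper_reaches_target(self):
        pop = simulate_surviving(SimParams(dimension=2, b0=1, d=0.8, n_max=50, seed=1))
        assert pop.size == 50 and not pop.extinct

    def test_exponential_growth_rate_matches_b0(self):
        # pooled log-linear fit of N(t) over 20 replicates, d=0, rho_c=inf
        rates = []
        for seed in range(20):
            pop = simulate(SimParams(dimension=2, b0=1.0, d=0.0, mu=0.0,
                                     n_max=400, seed=seed))
            t, n = pop.history[:, 0], pop.history[:, 1]
            keep = n >= 10
            slope = np.polyfit(t[keep], np.log(n[keep]), 1)[0]
            rates.append(slope)
        assert np.mean(rates) == pytest.approx(1.0, rel=0.10)

    def test_3d_geometry_stays_overlap_free(self):
        pop = simulate(SimParams(dimension=3, b0=1, d=0.2, mu=0.1, n_max=400,
                                 seed=3), validate_geometry=False)
        d = np.linalg.norm(pop.positions[:, None] - pop.positions[None, :], axis=-1)
        np.fill_diagonal(d, np.inf)
        assert d.min() >= 1.0 - 1e-6

    def test_surface_mode_divides_at_the_rim(self):
        # d=0 isolates the density response: with death, gap-refilling
        # divisions in the bulk dilute the rim signal
        p = SimParams(dimension=2, b0=1, d=0.0, mu=0.0, n_max=1200,
                      seed=8).surface_growth()
        sim = Simulation(p)
        div_rel_radius = []
        while 0 < sim.n_alive < p.n_max:
            kind = sim.step()
            if kind == "division" and sim.n_alive > 400:
                slots = sim.alive_list[: sim.n_alive]
                radii = np.linalg.norm(sim.pos[slots], axis=1)
                div_rel_radius.append(
                    np.linalg.norm(sim.pos[sim.last_division]) / radii.max())
        assert np.mean(div_rel_radius) > 0.7

    def test_volume_mode_divisions_are_location_independent(self):
        p = SimParams(dimension=2, b0=1, d=0.0, mu=0.0, n_max=3000, seed=21)
        sim = Simulation(p)
        n_div = {}
        while 0 < sim.n_alive < p.n_max:
            sim.step()
            if sim.n_alive > 500:
                n_div[sim.last_division_mother] = \
                    n_div.get(sim.last_division_mother, 0) + 1
        slots = sim.alive_list[: sim.n_alive]
        radii = np.linalg.norm(sim.pos[slots], axis=1)
        counts = np.array([n_div.get(int(s), 0) for s in slots])
        rho = stats.spearmanr(radii, counts).statistic
        assert abs(rho) < 0.1


class TestParamValidation:
    @pytest.mark.parametrize("kwargs", [
        {"b0": 0.0}, {"d": -0.1}, {"mu": -1.0}, {"rho_c": 0.0},
        {"n_max": 0}, {"dimension": 4},
    ])
    def test_invalid_params_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SimParams(**kwargs)

    def test_unknown_cell_division_rejected(self):
        sim = Simulation.from_positions([[0.0, 0.0]], SimParams(dimension=2))
        with pytest.raises(ValueError):
            divide_cell(sim, 57)
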