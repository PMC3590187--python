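"""Unit and property tests for placement, sectors, orientation and networks."""

import numpy as np
import pytest
from scipy import stats as sps

from crabsync.config import ConfigError, GridConfig
from crabsync.spatial import (
    Population,
    build_network,
    in_sector,
    network_statistics,
    orient_preferential,
    orient_random,
    place_individuals,
)


def make_population(positions, L=30, L_c=10, R=3.0, theta=60.0, rho=None):
    positions = np.asarray(positions, dtype=int)
    rho = rho if rho is not None else max(len(positions) / (L * L), 1e-6)
    grid = GridConfig(L=L, L_c=L_c, rho=rho)
    return Population(grid=grid, positions=positions, R=R, theta=theta)


class TestPlacement:
    def test_population_size_rounds_rho_l_squared(self, rng):
        pop = place_individuals(GridConfig(L=30, L_c=10, rho=0.4), rng)
        assert pop.n == 360
        assert len(np.unique(pop.positions[:, 0] * 30 + pop.positions[:, 1])) == 360

    def test_full_occupancy(self, rng):
        pop = place_individuals(GridConfig(L=30, L_c=10, rho=1.0), rng)
        assert pop.n == 900

    def test_same_seed_same_positions(self):
        a = place_individuals(GridConfig(), np.random.default_rng(5))
        b = place_individuals(GridConfig(), np.random.default_rng(5))
        assert np.array_equal(a.positions, b.positions)

    def test_empty_population_rejected(self):
        with pytest.raises(ConfigError, match="empty population"):
            GridConfig(L=1, L_c=1, rho=0.4)


class TestInSector:
    def test_boundary_distance_inclusive(self):
        assert in_sector((0, 0), 0.0, (3, 0), R=3.0, theta=60.0)
        assert not in_sector((0, 0), 0.0, (4, 0), R=3.0, theta=60.0)

    def test_angular_boundary_inclusive(self):
        # target at bearing 30 deg, sector centred on 0 with half-angle 30
        assert in_sector((0, 0), 0.0, (1, 1), R=3.0, theta=60.0) is False
        assert in_sector((0, 0), 15.0, (1, 1), R=3.0, theta=60.0)

    def test_global_attention_ignores_angle(self):
        for phi in (0.0, 90.0, 271.5):
            assert in_sector((0, 0), phi, (-2, -1), R=3.0, theta=360.0)

    def test_self_rejected(self):
        with pytest.raises(ValueError, match="own neighbor"):
            in_sector((2, 2), 0.0, (2, 2), R=3.0, theta=60.0)


class TestOrientation:
    def test_random_orientation_uniform(self):
        pop = make_population([[i % 30, i // 30] for i in range(300)])
        pops = []
        for seed in range(34):
            orient_random(pop, np.random.default_rng(seed))
            pops.append(pop.phi.copy())
        draws = np.concatenate(pops)  # > 1e4 draws
        assert sps.kstest(draws / 360.0, "uniform").pvalue > 0.01

    def test_preferential_connects_lone_neighbor(self, rng):
        pop = make_population([[10, 10], [12, 12]])
        orient_preferential(pop, rng)
        net = build_network(pop)
        assert net.n_edges == 2 and set(net.out_degree) == {1}

    def test_symmetric_tie_broken_evenly(self):
        # two singleton alternatives on opposite sides, never coverable together
        pop = make_population([[15, 15], [12, 15], [18, 15]])
        chose_left = 0
        trials = 400
        for seed in range(trials):
            orient_preferential(pop, np.random.default_rng(seed))
            net = build_network(pop)
            targets = net.dst[net.src == 0]
            assert len(targets) == 1
            chose_left += targets[0] == 1
        assert abs(chose_left / trials - 0.5) < 0.07

    def test_no_neighbor_gets_random_orientation(self, rng):
        pop = make_population([[2, 2], [20, 20]])
        orient_preferential(pop, rng)
        net = build_network(pop)
        assert net.n_edges == 0

    def test_similarity_tie_rule_prefers_matching_displacement(self):
        pop = make_population([[15, 15], [12, 15], [18, 15]])
        x = np.array([0.8, 0.1, 0.79])
        for seed in range(10):
            orient_preferential(
                pop, np.random.default_rng(seed), tie_rule="similarity", displacements=x
            )
            net = build_network(pop)
            assert list(net.dst[net.src == 0]) == [2]  # closest displacement wins

    def test_theta_360_models_equivalent(self, rng):
        grid = GridConfig(L=15, L_c=5, rho=0.4)
        pos = place_individuals(grid, np.random.default_rng(3), theta=360.0).positions
        p1 = Population(grid=grid, positions=pos, R=3.0, theta=360.0)
        p2 = Population(grid=grid, positions=pos.copy(), R=3.0, theta=360.0)
        orient_random(p1, np.random.default_rng(7))
        orient_preferential(p2, np.random.default_rng(11))
        n1, n2 = build_network(p1), build_network(p2)
        assert np.array_equal(
            np.sort(n1.src * p1.n + n1.dst), np.sort(n2.src * p2.n + n2.dst)
        )


class TestNetwork:
    def test_mutual_pair_is_bidirectional(self, rng):
        pop = make_population([[10, 10], [12, 10]])
        pop.phi = np.array([0.0, 180.0])  # facing each other
        net = build_network(pop)
        assert net.n_edges == 2 and net.reciprocal.all()
        stats = network_statistics(net, pop, central_only=False)
        assert stats.reciprocal_per_participant == 1.0
        assert stats.component_sizes == (2,)

    def test_m2_everyone_in_reach_is_covered(self, rng):
        grid = GridConfig(L=20, L_c=10, rho=0.3)
        pop = place_individuals(grid, rng)
        orient_preferential(pop, rng)
        net = build_network(pop)
        p = pop.positions.astype(float)
        d = np.hypot(*(p[None] - p[:, None]).transpose(2, 0, 1))
        np.fill_diagonal(d, np.inf)
        has_reach = (d <= pop.R).any(axis=1)
        assert np.all(net.out_degree[has_reach] >= 1)

    def test_m2_edge_count_dominates_m1(self):
        """M2 maximises each out-degree, so it never has fewer edges than M1."""
        for seed in range(5):
            grid = GridConfig(L=20, L_c=10, rho=0.35)
            pos = place_individuals(grid, np.random.default_rng(seed)).positions
            p1 = Population(grid=grid, positions=pos, R=3.0, theta=60.0)
            p2 = Population(grid=grid, positions=pos.copy(), R=3.0, theta=60.0)
            orient_random(p1, np.random.default_rng(seed + 100))
            orient_preferential(p2, np.random.default_rng(seed + 200))
            assert build_network(p2).n_edges >= build_network(p1).n_edges

    def test_isolated_individual_has_no_edges(self, rng):
        pop = make_population([[1, 1], [25, 25], [26, 25]])
        orient_random(pop, rng)
        net = build_network(pop)
        assert net.out_degree[0] == 0
        assert not np.any(net.dst == 0)

    def test_literal_boundary_rule_silences_edge_individuals(self, rng):
        pop = make_population([[0, 0], [2, 0], [15, 15], [17, 15]])
        pop.phi = np.array([0.0, 180.0, 0.0, 180.0])
        clipped = build_network(pop, boundary_rule="clip")
        literal = build_network(pop, boundary_rule="literal")
        assert clipped.out_degree[0] == 1  # sees its neighbour under clipping
        assert literal.out_degree[0] == 0  # sector leaves grid -> uncoupled
        assert literal.out_degree[2] == 1  # interior pair unaffected


class TestStatistics:
    def test_no_leaders_at_full_density_global_attention(self, rng):
        grid = GridConfig(L=10, L_c=4, rho=1.0)
        pop = place_individuals(grid, rng, theta=360.0)
        orient_random(pop, rng)
        stats = network_statistics(build_network(pop), pop, central_only=False)
        assert stats.n_leaders == 0

    def test_m2_has_no_leader_per_follower(self, rng):
        for rho in (0.1, 0.3, 0.6):
            grid = GridConfig(L=20, L_c=10, rho=rho)
            pop = place_individuals(grid, rng)
            orient_preferential(pop, rng)
            stats = network_statistics(build_network(pop), pop, central_only=False)
            if stats.leaders_per_follower is not None:
                assert stats.leaders_per_follower == 0.0

    def test_zero_followers_reported_as_undefined(self, rng):
        pop = make_population([[1, 1], [25, 25]])
        orient_random(pop, rng)
        stats = network_statistics(build_network(pop), pop, central_only=False)
        assert stats.leaders_per_follower is None
        assert stats.n_followers == 0

    def test_upstream_counts_follow_chain(self):
        # chain: 0 watches 1, 1 watches 2 (leader); plus direct leader 3 for 0
        pop = make_population([[10, 10], [12, 10], [14, 10], [10, 12]], theta=90.0)
        pop.phi = np.array([45.0, 0.0, 270.0, 90.0])
        net = build_network(pop)
        assert net.out_degree[2] == 0 and net.out_degree[3] == 0
        stats = network_statistics(net, pop, central_only=False, include_upstream=True)
        # follower 0 reaches leaders 2 (via 1) and 3 (direct); follower 1 reaches 2
        assert stats.upstream_leaders_per_follower == pytest.approx(1.5)
        assert stats.leaders_per_follower == pytest.approx(1.0)
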