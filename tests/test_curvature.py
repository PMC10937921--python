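import itertools

import networkx as nx
import numpy as np
import pytest

from dyncurv._mincostflow import GraphArcs
from dyncurv.curvature import (
    CurvatureField,
    DiffusionOperator,
    build_laplacian,
    curvature_sweep,
    default_tau_grid,
    diffuse,
    edge_curvature,
    find_tau_crit,
    integral_curvature,
    truncate_support,
    wasserstein1,
)

from conftest import make_network, uniform_network


# ---------------------------------------------------------------- oracles


def w1_path_graph_oracle(p, q, edge_costs):
    """Closed-form W1 on a path graph: sum over edges of |CDF difference|."""
    cum = np.cumsum(p - q)[:-1]
    return float(np.sum(np.abs(cum) * np.asarray(edge_costs)))


def w1_integer_flow_oracle(p, q, cost, mass_scale=10**12, cost_scale=10**10):
    """Exact transportation solve with integer arithmetic via network simplex.

    Masses and costs are scaled to integers (largest-remainder rounding keeps
    the totals equal), so networkx's integral min-cost flow is exact; the
    result is exact for the rounded problem and within ~1e-10 of the real one.
    """

    def to_int(x):
        scaled = x * mass_scale
        base = np.floor(scaled).astype(object)
        short = int(round(mass_scale - sum(base)))
        order = np.argsort(-(scaled - np.floor(scaled)))
        for k in range(short):
            base[order[k]] += 1
        return base

    pi, qi = to_int(np.asarray(p, float)), to_int(np.asarray(q, float))
    g = nx.DiGraph()
    n = len(p)
    for i in range(n):
        g.add_node(("s", i), demand=-int(pi[i]))
        g.add_node(("t", i), demand=int(qi[i]))
    for i in range(n):
        for j in range(n):
            g.add_edge(("s", i), ("t", j), weight=int(round(cost[i, j] * cost_scale)))
    flow_cost, _ = nx.network_simplex(g)
    return flow_cost / (mass_scale * cost_scale)


# ---------------------------------------------------------------- laplacian


class TestLaplacian:
    def test_two_vertex_edge_any_weight(self):
        for rho in (0.9, 0.0, -0.5):
            net = make_network({("A", "B"): rho})
            L = build_laplacian(net).L
            assert np.allclose(L, [[1.0, -1.0], [-1.0, 1.0]])

    def test_rows_sum_to_zero(self, clique_bridge_network):
        L = build_laplacian(clique_bridge_network).L
        assert np.allclose(L.sum(axis=1), 0.0, atol=1e-10)
        off = L - np.diag(np.diag(L))
        assert (off <= 1e-12).all()

    def test_equal_weight_cycle_is_half_adjacency(self):
        net = uniform_network([("A", "B"), ("B", "C"), ("C", "D"), ("A", "D")], rho=0.5)
        lap = build_laplacian(net)
        adj = nx.to_numpy_array(net.graph, nodelist=net.nodes, weight=None)
        assert np.allclose(lap.L, np.eye(4) - adj / 2.0)


class TestDiffusion:
    def test_tau_zero_is_identity(self, clique_bridge_network):
        lap = build_laplacian(clique_bridge_network)
        assert np.allclose(diffuse(lap, 0.0), np.eye(clique_bridge_network.n_nodes))

    def test_negative_tau_rejected(self, clique_bridge_network):
        lap = build_laplacian(clique_bridge_network)
        with pytest.raises(ValueError, match="nonnegative"):
            diffuse(lap, -0.1)

    def test_rows_stay_probability_vectors_across_grid(self, clique_bridge_network):
        op = DiffusionOperator(build_laplacian(clique_bridge_network))
        for tau in default_tau_grid():
            D = op.at(tau)
            assert np.abs(D.sum(axis=1) - 1.0).max() < 1e-8
            assert D.min() >= 0.0

    def test_large_tau_reaches_weighted_degree_stationary(self, clique_bridge_network):
        lap = build_laplacian(clique_bridge_network)
        D = diffuse(lap, 100.0)
        pi = lap.K / lap.K.sum()
        assert np.abs(D - pi[None, :]).max() < 1e-6

    def test_semigroup_property(self, clique_bridge_network):
        op = DiffusionOperator(build_laplacian(clique_bridge_network))
        for t1, t2 in [(0.05, 0.3), (0.5, 1.5), (2.0, 7.0)]:
            assert np.abs(op.at(t1) @ op.at(t2) - op.at(t1 + t2)).max() < 1e-8


# ---------------------------------------------------------------- wasserstein


class TestWasserstein:
    def test_identical_distributions_cost_zero(self):
        p = np.array([0.25, 0.25, 0.5])
        d = np.array([[0, 1, 2], [1, 0, 1], [2, 1, 0]], float)
        assert wasserstein1(p, p, d) == pytest.approx(0.0, abs=1e-12)

    def test_two_deltas_cost_their_distance(self):
        p = np.array([1.0, 0.0])
        q = np.array([0.0, 1.0])
        d = np.array([[0.0, 1.7], [1.7, 0.0]])
        assert wasserstein1(p, q, d) == pytest.approx(1.7, abs=1e-12)

    def test_mass_mismatch_rejected(self):
        d = np.zeros((2, 2))
        with pytest.raises(ValueError, match="mass mismatch"):
            wasserstein1(np.array([0.6, 0.6]), np.array([0.5, 0.5]), d)

    def test_exact_lp_matches_path_cdf_oracle(self):
        rng = np.random.default_rng(4)
        costs = [0.7, 1.3, 0.5]
        d = np.zeros((4, 4))
        for i in range(4):
            for j in range(4):
                d[i, j] = sum(costs[min(i, j) : max(i, j)])
        for _ in range(20):
            p = rng.dirichlet(np.ones(4))
            q = rng.dirichlet(np.ones(4))
            assert wasserstein1(p, q, d) == pytest.approx(
                w1_path_graph_oracle(p, q, costs), abs=1e-10
            )

    def test_exact_lp_matches_integer_flow_oracle(self):
        rng = np.random.default_rng(5)
        for n in (3, 5, 8):
            g = nx.gnp_random_graph(n, 0.6, seed=int(rng.integers(1e6)))
            g = g.subgraph(max(nx.connected_components(g), key=len)).copy()
            nodes = sorted(g.nodes())
            for u, v in g.edges():
                g[u][v]["cost"] = float(rng.uniform(0.5, 2.5))
            from dyncurv.network import all_pairs_shortest_paths

            d = all_pairs_shortest_paths(g, nodes)
            m = len(nodes)
            p = rng.dirichlet(np.ones(m))
            q = rng.dirichlet(np.ones(m))
            assert wasserstein1(p, q, d) == pytest.approx(
                w1_integer_flow_oracle(p, q, d), abs=1e-9
            )

    def test_sinkhorn_close_to_exact(self):
        rng = np.random.default_rng(6)
        d = np.abs(np.subtract.outer(np.arange(5.0), np.arange(5.0))) * 0.8
        for _ in range(10):
            p = rng.dirichlet(np.ones(5))
            q = rng.dirichlet(np.ones(5))
            exact = wasserstein1(p, q, d, method="exact_lp")
            approx = wasserstein1(p, q, d, method="sinkhorn")
            if exact > 1e-6:
                assert abs(approx - exact) / exact < 0.01

    def test_symmetry_and_triangle_inequality(self):
        rng = np.random.default_rng(7)
        d = np.array([[0, 1, 2, 1.5], [1, 0, 1, 2], [2, 1, 0, 1], [1.5, 2, 1, 0]], float)
        dists = [rng.dirichlet(np.ones(4)) for _ in range(3)]
        w = {}
        for i, j in itertools.combinations(range(3), 2):
            w[i, j] = wasserstein1(dists[i], dists[j], d)
            assert w[i, j] == pytest.approx(
                wasserstein1(dists[j], dists[i], d), abs=1e-9
            )
        assert w[0, 2] <= w[0, 1] + w[1, 2] + 1e-9

    def test_flow_backend_equals_exact_lp_random_graphs(self):
        rng = np.random.default_rng(8)
        from dyncurv.network import all_pairs_shortest_paths

        for trial in range(15):
            n = int(rng.integers(4, 9))
            g = nx.gnp_random_graph(n, 0.5, seed=int(rng.integers(1e6)))
            g = g.subgraph(max(nx.connected_components(g), key=len)).copy()
            if g.number_of_edges() == 0:
                continue
            nodes = sorted(g.nodes())
            for u, v in g.edges():
                g[u][v]["cost"] = float(rng.uniform(0.3, 3.0))
            d = all_pairs_shortest_paths(g, nodes)
            arcs = GraphArcs(g, nodes)
            m = len(nodes)
            p = rng.dirichlet(np.ones(m))
            q = rng.dirichlet(np.ones(m))
            assert arcs.wasserstein1(p, q) == pytest.approx(
                wasserstein1(p, q, d), abs=1e-8
            )

    def test_support_truncation_drops_smallest_mass(self):
        p = np.array([0.5, 0.49995, 3e-5, 2e-5])
        out = truncate_support(p, delta=1e-4)
        assert out[3] == 0.0 and out[2] == 0.0
        assert out.sum() == pytest.approx(1.0)


# ---------------------------------------------------------------- curvature


class TestEdgeCurvature:
    def test_zero_at_tau_zero_when_edges_are_geodesic(self, clique_bridge_network):
        # uniform costs: every direct edge is a shortest path
        lap = build_laplacian(clique_bridge_network)
        D = diffuse(lap, 0.0)
        kappa = edge_curvature(clique_bridge_network, D)
        assert np.abs(kappa.to_numpy()).max() < 1e-12

    def test_one_when_fully_diffused(self, clique_bridge_network):
        lap = build_laplacian(clique_bridge_network)
        D = diffuse(lap, 100.0)
        kappa = edge_curvature(clique_bridge_network, D)
        assert np.abs(kappa.to_numpy() - 1.0).max() < 0.01

    def test_bridge_curvature_below_clique_curvature(self, clique_bridge_network):
        lap = build_laplacian(clique_bridge_network)
        D = diffuse(lap, 1.0)
        kappa = edge_curvature(clique_bridge_network, D)
        bridge = kappa[("C", "D")]
        within = [kappa[e] for e in [("A", "B"), ("B", "C"), ("D", "E"), ("E", "F")]]
        assert bridge < min(within)

    def test_flow_sweep_matches_untruncated_lp_pointwise(self, clique_bridge_network):
        taus = np.array([0.05, 0.5, 2.0])
        field = curvature_sweep(clique_bridge_network, taus, method="flow")
        op = DiffusionOperator(build_laplacian(clique_bridge_network))
        for t, tau in enumerate(taus):
            ref = edge_curvature(
                clique_bridge_network, op.at(tau), method="exact_lp", support_delta=0.0
            )
            assert np.abs(field.kappa[:, t] - ref.loc[field.edges].to_numpy()).max() < 1e-8

    def test_sweep_single_point_consistent(self, clique_bridge_network):
        field = curvature_sweep(clique_bridge_network, np.array([0.7]))
        direct = edge_curvature(
            clique_bridge_network,
            DiffusionOperator(build_laplacian(clique_bridge_network)).at(0.7),
        )
        assert np.allclose(field.kappa[:, 0], direct.loc[field.edges].to_numpy())

    def test_trajectories_rise_from_zero_to_one(self, clique_bridge_network):
        field = curvature_sweep(clique_bridge_network, default_tau_grid(21))
        assert np.abs(field.kappa[:, 0]).max() < 0.05
        assert np.abs(field.kappa[:, -1] - 1.0).max() < 0.01


def _uniform_field(values_per_tau, n_edges=200):
    taus = default_tau_grid(len(values_per_tau))
    kappa = np.tile(np.asarray(values_per_tau), (n_edges, 1))
    edges = [(f"g{i}", f"h{i}") for i in range(n_edges)]
    return CurvatureField(edges=edges, tau_grid=taus, kappa=kappa)


class TestCriticalScale:
    def test_immediate_crossing_gives_first_grid_point(self):
        field = _uniform_field([0.8] * 101)
        tau, idx = find_tau_crit(field)
        assert idx == 0 and tau == pytest.approx(0.01)

    def test_never_reached_raises(self):
        field = _uniform_field([0.5] * 101)
        with pytest.raises(ValueError, match="extend"):
            find_tau_crit(field)

    def test_crossing_between_grid_points_returns_next_index(self):
        vals = [0.7] * 41 + [0.76] * 60
        field = _uniform_field(vals)
        _, idx = find_tau_crit(field)
        assert idx == 41

    def test_percentile_uses_linear_interpolation(self):
        # 100 edges, one at 0.9 and the rest at 0.5: P99 = 0.5 + 0.01-quantile gap
        taus = default_tau_grid(1)
        kappa = np.full((100, 1), 0.5)
        kappa[0, 0] = 0.9
        field = CurvatureField(
            edges=[(f"a{i}", f"b{i}") for i in range(100)], tau_grid=taus, kappa=kappa
        )
        expected = np.percentile(kappa[:, 0], 99)
        if expected >= 0.75:
            find_tau_crit(field)
        else:
            with pytest.raises(ValueError):
                find_tau_crit(field)


class TestIntegralCurvature:
    def test_constant_trajectory_rectangle(self):
        field = _uniform_field([0.4] * 101, n_edges=3)
        _, idx = 10.0, 100
        vals = integral_curvature(field, idx)
        tau_crit = field.tau_grid[idx]
        # the prepended (0, 0) point shaves half the first panel
        assert np.allclose(vals, 0.4 * tau_crit, rtol=1e-3)

    def test_linear_trajectory_triangle(self):
        taus = np.linspace(0.0, 2.0, 5)[1:]  # grid 0.5 .. 2.0
        kappa = np.tile(taus / 2.0, (2, 1))
        field = CurvatureField(edges=[("a", "b"), ("c", "d")], tau_grid=taus, kappa=kappa)
        vals = integral_curvature(field, 3)
        assert np.allclose(vals, 2.0 / 2.0 * 2.0 / 2.0)  # (tau_crit * max_kappa) / 2

    def test_hand_trapezoid_sum(self):
        taus = np.array([0.1, 0.2, 0.4, 0.8, 1.6])
        kappa = np.array([[0.1, 0.3, 0.2, 0.5, 0.6]])
        field = CurvatureField(edges=[("a", "b")], tau_grid=taus, kappa=kappa)
        # panels: 0.005 + 0.02 + 0.05 + 0.14 + 0.44
        assert integral_curvature(field, 4).iloc[0] == pytest.approx(0.655)

    def test_normalization_flag_divides_by_tau_crit(self):
        field = _uniform_field([0.4] * 11, n_edges=2)
        raw = integral_curvature(field, 10)
        norm = integral_curvature(field, 10, normalize=True)
        assert np.allclose(norm, raw / field.tau_grid[10])

    def test_beyond_computed_prefix_rejected(self):
        field = _uniform_field([0.4] * 5, n_edges=2)
        with pytest.raises(ValueError, match="beyond"):
            integral_curvature(field, 7)
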