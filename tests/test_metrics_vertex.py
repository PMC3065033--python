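"""Vertex centralities and network entropy."""

import itertools
import math

import numpy as np
import pytest

from neurosync import (
    ComputationError,
    WeightedNetwork,
    betweenness,
    closeness,
    compute_vertex_metrics,
    degree_strength,
    efficiency,
    eigenvector_centrality,
    gen_random_network,
    hubbell_centrality,
    network_entropy,
    subgraph_centrality,
)
from neurosync.network import edge_lengths


class TestDegreeStrength:
    def test_star_hub_degree_and_normalization(self, star11):
        assert degree_strength(star11, 0) == 10.0
        assert degree_strength(star11, 0, normalized=True) == 1.0

    def test_greyscale_strength_sums_incident_weights(self):
        W = np.array([[0, 0.5, 0.3], [0.5, 0, 0], [0.3, 0, 0]])
        net = WeightedNetwork(W)
        assert degree_strength(net, 0) == pytest.approx(0.8)

    def test_directed_two_cycle_in_out(self):
        W = np.array([[0, 1.0], [1.0, 0]])
        net = WeightedNetwork(W, directed=True, mode="binary")
        assert degree_strength(net, 0, "in") == 1.0
        assert degree_strength(net, 0, "out") == 1.0


class TestCloseness:
    def test_complete_graph_all_one(self):
        W = np.ones((5, 5)) - np.eye(5)
        assert np.allclose(closeness(WeightedNetwork(W, mode="binary")), 1.0)

    def test_disconnected_graph_undefined(self):
        W = np.zeros((3, 3))
        W[0, 1] = W[1, 0] = 1.0
        c = closeness(WeightedNetwork(W, mode="binary"))
        assert np.all(np.isnan(c))

    def test_path_graph_hand_values(self, path3):
        c = closeness(path3)
        assert c[1] == pytest.approx(1.0)
        assert c[0] == pytest.approx(2 / 3)


class TestEfficiency:
    def test_complete_graph_is_one(self):
        W = np.ones((4, 4)) - np.eye(4)
        assert np.allclose(efficiency(WeightedNetwork(W, mode="binary")), 1.0)

    def test_isolated_vertex_zero(self):
        W = np.zeros((3, 3))
        W[0, 1] = W[1, 0] = 1.0
        assert efficiency(WeightedNetwork(W, mode="binary"), 2) == 0.0

    def test_path_end_vertex(self, path3):
        assert efficiency(path3, 0) == pytest.approx(0.75)


def brute_force_geodesics(net, fn):
    """All simple paths per ordered pair: (min length, all minimal paths)."""
    L = edge_lengths(net, fn)
    n = net.n_vertices
    out = {}
    for s in range(n):
        for t in range(n):
            if s == t:
                continue
            best, paths = np.inf, []
            stack = [(s, 0.0, (s,))]
            while stack:
                u, dist, path = stack.pop()
                if u == t:
                    if not np.isfinite(best) or dist < best - 1e-9 * max(best, 1.0):
                        best, paths = dist, [path]
                    elif abs(dist - best) <= 1e-9 * max(best, 1.0):
                        paths.append(path)
                    continue
                for v in range(n):
                    if v in path or not np.isfinite(L[u, v]):
                        continue
                    stack.append((v, dist + L[u, v], path + (v,)))
            out[(s, t)] = (best, paths)
    return out


def brute_force_betweenness(net, fn):
    geo = brute_force_geodesics(net, fn)
    n = net.n_vertices
    scores = np.zeros(n)
    for (s, t), (best, paths) in geo.items():
        if not np.isfinite(best):
            continue
        for v in range(n):
            if v in (s, t):
                continue
            through = sum(1 for p in paths if v in p)
            scores[v] += through / len(paths)
    return scores / ((n - 1) * (n - 2))


def brute_force_efficiency(net, fn):
    geo = brute_force_geodesics(net, fn)
    n = net.n_vertices
    scores = np.zeros(n)
    for (s, t), (best, _) in geo.items():
        if np.isfinite(best):
            scores[s] += 1.0 / best
    return scores / (n - 1)


class TestBetweenness:
    def test_path_centre_is_one_ends_zero(self, path3):
        assert np.allclose(betweenness(path3), [0.0, 1.0, 0.0])

    def test_complete_graph_all_zero(self):
        W = np.ones((5, 5)) - np.eye(5)
        assert np.allclose(betweenness(WeightedNetwork(W, mode="binary")), 0.0)

    def test_tied_geodesics_split_evenly(self):
        # 4-cycle: two equal-length paths between opposite corners
        W = np.zeros((4, 4))
        for i, j in [(0, 1), (1, 2), (2, 3), (3, 0)]:
            W[i, j] = W[j, i] = 1.0
        b = betweenness(WeightedNetwork(W, mode="binary"))
        # each vertex lies on 1 of the 2 geodesics of the opposite pair,
        # counted in both directions: (1/2 + 1/2) / (3 * 2)
        assert np.allclose(b, 1 / 6)

    @pytest.mark.parametrize("kind", ["inverse", "log2"])
    def test_matches_brute_force_enumeration(self, small_nets, kind):
        for net in small_nets:
            got = betweenness(net, fn=kind)
            expected = brute_force_betweenness(net, kind)
            assert np.allclose(got, expected, atol=1e-10)

    def test_efficiency_matches_brute_force(self, small_nets):
        for net in small_nets:
            assert np.allclose(
                efficiency(net), brute_force_efficiency(net, "inverse"), atol=1e-12
            )


class TestEigenvectorCentrality:
    def test_triangle_inf_norm_all_one(self, triangle):
        assert np.allclose(eigenvector_centrality(triangle, np.inf), 1.0)

    def test_triangle_two_norm(self, triangle):
        assert np.allclose(eigenvector_centrality(triangle, 2), 1 / np.sqrt(3))

    def test_satisfies_eigen_equation(self):
        for seed in range(5):
            net = gen_random_network(9, 0.5, seed=seed)
            if net.n_edges == 0:
                continue
            c = eigenvector_centrality(net, 2)
            W = net.weights
            lam = float(np.max(np.abs(np.linalg.eigvals(W))))
            resid = np.linalg.norm(W.T @ c - lam * c) / np.linalg.norm(c)
            assert resid < 1e-10

    def test_scale_invariant_in_weights(self):
        net = gen_random_network(8, 0.6, seed=3)
        scaled = WeightedNetwork(net.weights * 0.41)
        assert np.allclose(
            eigenvector_centrality(net), eigenvector_centrality(scaled), atol=1e-10
        )


class TestHubbell:
    def test_edgeless_network_returns_exogenous(self):
        net = WeightedNetwork(np.zeros((4, 4)))
        assert np.allclose(hubbell_centrality(net, 0.3), 1.0)

    def test_alpha_zero_returns_exogenous(self, triangle):
        e = np.array([1.0, 2.0, 3.0])
        assert np.allclose(hubbell_centrality(triangle, 0.0, e), e)

    def test_two_cycle_hand_solution(self):
        # c = 1 + 0.5 c per vertex => c = 2
        W = np.array([[0, 1.0], [1.0, 0]])
        net = WeightedNetwork(W, mode="binary")
        assert np.allclose(hubbell_centrality(net, 0.5), 2.0)

    def test_alpha_restriction_enforced(self, triangle):
        with pytest.raises(Exception, match="alpha"):
            hubbell_centrality(triangle, 0.6)  # lambda_1 = 2 => |alpha| < 0.5

    def test_solution_is_fixed_point_of_iteration(self):
        for seed in range(5):
            net = gen_random_network(7, 0.5, seed=seed)
            c = hubbell_centrality(net)
            W = net.weights
            lam = float(np.max(np.abs(np.linalg.eigvals(W)))) or 1.0
            alpha = 0.5 / lam
            e = np.ones(7)
            x = np.zeros(7)
            for _ in range(600):
                x = alpha * W.T @ x + e
            assert np.allclose(x, c, atol=1e-8)


class TestSubgraphCentrality:
    def test_isolated_vertex_is_one(self):
        W = np.zeros((3, 3))
        W[0, 1] = W[1, 0] = 1.0
        assert subgraph_centrality(WeightedNetwork(W, mode="binary"))[2] == pytest.approx(1.0)

    def test_single_edge_closed_form_cosh(self):
        W = np.array([[0, 1.0], [1.0, 0]])
        c = subgraph_centrality(WeightedNetwork(W, mode="binary"))
        assert np.allclose(c, np.cosh(1.0))

    def test_triangle_spectral_closed_form(self, triangle):
        expected = (np.exp(2) + 2 * np.exp(-1)) / 3
        assert np.allclose(subgraph_centrality(triangle), expected)

    def test_matches_truncated_walk_series(self):
        for seed in range(5):
            net = gen_random_network(7, 0.5, seed=seed)
            A = net.weights
            series = np.zeros(7)
            power = np.eye(7)
            for k in range(26):
                series += np.diag(power) / math.factorial(k)
                power = power @ A
            assert np.allclose(subgraph_centrality(net), series, atol=1e-9)


class TestNetworkEntropy:
    def test_deterministic_cycle_zero_entropy(self):
        W = np.array([[0, 1.0], [1.0, 0]])
        net = WeightedNetwork(W, directed=True, mode="binary")
        assert network_entropy(net).entropy == pytest.approx(0.0)

    def test_uniform_triangle_one_bit(self, triangle):
        ent = network_entropy(triangle, log_base=2)
        assert ent.entropy == pytest.approx(1.0)
        assert np.allclose(ent.stationary, 1 / 3)
        assert np.allclose(ent.vertex_entropy, 1.0)

    def test_stationary_distribution_residual(self):
        for seed in range(10):
            net = gen_random_network(8, 0.7, seed=seed)
            try:
                ent = network_entropy(net)
            except ComputationError:
                continue
            P = net.weights / net.weights.sum(axis=1, keepdims=True)
            assert np.linalg.norm(ent.stationary @ P - ent.stationary) < 1e-12
            assert ent.stationary.sum() == pytest.approx(1.0, abs=1e-12)

    def test_three_vertex_chains_bounded_by_one_bit(self):
        """No-self-loop 3-vertex chains have at most 2 exits per state, so the
        entropy rate is at most 1 bit, attained by the uniform triangle."""
        rng = np.random.default_rng(0)
        for _ in range(50):
            W = rng.uniform(0.05, 1.0, (3, 3))
            np.fill_diagonal(W, 0.0)
            net = WeightedNetwork(W, directed=True)
            ent = network_entropy(net)
            assert ent.entropy <= 1.0 + 1e-12

    def test_dangling_vertex_rejected(self):
        W = np.zeros((3, 3))
        W[0, 1] = W[1, 0] = 1.0
        net = WeightedNetwork(W, mode="binary")
        with pytest.raises(ComputationError, match="out-strength"):
            network_entropy(net)

    def test_reducible_support_rejected(self):
        W = np.array([[0, 1.0, 0], [0, 0, 1.0], [0, 1.0, 0]])
        net = WeightedNetwork(W, directed=True, mode="binary")
        with pytest.raises(ComputationError, match="strongly connected"):
            network_entropy(net)


class TestVertexMetricTable:
    def test_table_has_all_requested_columns(self, triangle):
        df = compute_vertex_metrics(triangle)
        for col in (
            "degree",
            "closeness",
            "efficiency",
            "betweenness",
            "eigenvector",
            "hubbell",
            "subgraph",
            "entropy_rate_contribution",
        ):
            assert col in df.columns
        assert list(df.index) == list(triangle.labels)

    def test_failed_metric_reported_as_nan_not_crash(self):
        W = np.zeros((3, 3))
        W[0, 1] = W[1, 0] = 1.0  # vertex 2 isolated: entropy undefined
        net = WeightedNetwork(W, mode="binary")
        df = compute_vertex_metrics(net, ("degree", "entropy"))
        assert df["degree"].tolist() == [1.0, 1.0, 0.0]
        assert df["entropy_rate_contribution"].isna().all()
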