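"""Centrality/clustering descriptors against hand values and brute force."""

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import phasegraph as pg

from bruteforce_oracles import (
    brute_betweenness,
    brute_closeness_wf,
    brute_clustering,
    brute_degree_centrality,
)
from conftest import graph_to_adj


def series(table):
    return table.values.to_numpy()


class TestHandValues:
    def test_degree_complete_graph(self):
        np.testing.assert_allclose(series(pg.degree_centrality(nx.complete_graph(4))),
                                   1.0)

    def test_degree_path(self, path3):
        values = pg.degree_centrality(path3).values
        assert values[1] == 1.0
        assert values[0] == values[2] == 0.5

    def test_closeness_path(self, path3):
        # centre: (2/2)*(2/2) = 1; ends: (2/2)*(2/3)
        values = pg.closeness_centrality(path3).values
        assert values[1] == pytest.approx(1.0)
        assert values[0] == pytest.approx(2.0 / 3.0)

    def test_closeness_two_disjoint_edges(self):
        graph = nx.Graph([(0, 1), (2, 3)])
        np.testing.assert_allclose(series(pg.closeness_centrality(graph)), 1 / 3)

    def test_closeness_isolated_node_zero(self):
        graph = nx.Graph([(0, 1)])
        graph.add_node(2)
        assert pg.closeness_centrality(graph).values[2] == 0.0

    def test_closeness_connected_reduces_to_classical(self):
        graph = nx.erdos_renyi_graph(15, 0.4, seed=2)
        assert nx.is_connected(graph)
        values = pg.closeness_centrality(graph).values
        n = graph.number_of_nodes()
        for v in graph.nodes:
            total = sum(nx.shortest_path_length(graph, v).values())
            assert values[v] == pytest.approx((n - 1) / total)

    def test_betweenness_star(self):
        star = nx.star_graph(3)  # centre 0, leaves 1-3
        values = pg.betweenness_centrality(star).values
        assert values[0] == pytest.approx(3.0)
        assert values[1] == values[2] == values[3] == 0.0

    def test_betweenness_path4(self):
        values = pg.betweenness_centrality(nx.path_graph(4)).values
        assert values[1] == pytest.approx(2.0)

    def test_betweenness_cycle4_tie_split(self):
        np.testing.assert_allclose(
            series(pg.betweenness_centrality(nx.cycle_graph(4))), 0.5)

    def test_betweenness_normalized(self):
        star = nx.star_graph(3)
        values = pg.betweenness_centrality(star, normalized=True).values
        assert values[0] == pytest.approx(1.0)  # 3 / (3*2/2)

    def test_clustering_triangle_conventions(self):
        k3 = nx.complete_graph(3)
        np.testing.assert_allclose(
            series(pg.clustering_coefficient(k3, "half")), 0.5)
        np.testing.assert_allclose(
            series(pg.clustering_coefficient(k3, "standard")), 1.0)

    def test_clustering_star_zero(self):
        star = nx.star_graph(4)
        for conv in ("half", "standard"):
            np.testing.assert_allclose(
                series(pg.clustering_coefficient(star, conv)), 0.0)

    def test_clustering_k4_standard(self):
        np.testing.assert_allclose(
            series(pg.clustering_coefficient(nx.complete_graph(4), "standard")), 1.0)

    def test_small_graph_rejected(self):
        with pytest.raises(pg.ConfigurationError):
            pg.degree_centrality(nx.empty_graph(1))


class TestBruteForceEquivalence:
    """The networkx-backed descriptors match independent brute-force oracles."""

    @settings(max_examples=40, deadline=None)
    @given(seed=st.integers(0, 10_000), n=st.integers(4, 30),
           p=st.floats(0.05, 0.6))
    def test_all_metrics_match(self, seed, n, p):
        graph = nx.gnp_random_graph(n, p, seed=seed)
        adj = graph_to_adj(graph)
        np.testing.assert_allclose(series(pg.degree_centrality(graph)),
                                   brute_degree_centrality(adj), atol=1e-12)
        np.testing.assert_allclose(series(pg.closeness_centrality(graph)),
                                   brute_closeness_wf(adj), atol=1e-12)
        np.testing.assert_allclose(series(pg.betweenness_centrality(graph)),
                                   brute_betweenness(adj), atol=1e-9)
        for conv in ("half", "standard"):
            np.testing.assert_allclose(
                series(pg.clustering_coefficient(graph, conv)),
                brute_clustering(adj, conv), atol=1e-12)

    @settings(max_examples=20, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_intra_component_edge_never_decreases_closeness(self, seed):
        # note: closeness monotonicity only holds for edges *within* a
        # component — an edge merging two components can flood a node with
        # distant vertices and lower its Wasserman-Faust score
        rng = np.random.default_rng(seed)
        graph = nx.gnp_random_graph(12, 0.25, seed=int(rng.integers(1 << 30)))
        candidates = [
            (u, v) for u, v in nx.non_edges(graph)
            if nx.has_path(graph, u, v)
        ]
        if not candidates:
            return
        before = pg.closeness_centrality(graph).values
        graph.add_edge(*candidates[rng.integers(len(candidates))])
        after = pg.closeness_centrality(graph).values
        assert np.all(after.to_numpy() >= before.to_numpy() - 1e-12)

    @settings(max_examples=20, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_degree_and_closeness_in_unit_interval(self, seed):
        graph = nx.gnp_random_graph(15, 0.3, seed=seed)
        for table in (pg.degree_centrality(graph), pg.closeness_centrality(graph)):
            values = table.values.to_numpy()
            assert np.all((values >= 0) & (values <= 1))


class TestStatistics:
    def test_distribution_constant_values(self):
        table = pg.NodeMetricTable("m", {i: 0.4 for i in range(10)})
        dist = pg.metric_distribution(table, bins=20)
        assert dist.probability.max() == pytest.approx(1.0)
        assert (dist.probability > 0).sum() == 1
        assert dist.mean == pytest.approx(0.4)

    def test_distribution_pooled_mean(self):
        t1 = pg.NodeMetricTable("m", {0: 0.0, 1: 1.0})
        t2 = pg.NodeMetricTable("m", {0: 1.0, 1: 1.0})
        dist = pg.metric_distribution([t1, t2])
        assert dist.mean == pytest.approx(0.75)
        assert dist.probability.sum() == pytest.approx(1.0)

    def test_distribution_bimodal_masses(self):
        table = pg.NodeMetricTable("m", dict(enumerate([0.1] * 50 + [0.9] * 50)))
        dist = pg.metric_distribution(table, bins=10)
        occupied = dist.probability[dist.probability > 0]
        np.testing.assert_allclose(occupied, [0.5, 0.5])

    def test_running_average_identity_cases(self):
        const = np.full(30, 2.5)
        np.testing.assert_allclose(pg.running_average(const, 5), const)
        ramp = np.arange(30, dtype=float)
        np.testing.assert_allclose(pg.running_average(ramp, 5)[2:-2], ramp[2:-2])
        np.testing.assert_allclose(pg.running_average(ramp, 1), ramp)

    def test_running_average_window_validation(self):
        with pytest.raises(pg.ConfigurationError):
            pg.running_average(np.arange(10.0), 4)  # even
        with pytest.raises(pg.ConfigurationError):
            pg.running_average(np.arange(10.0), 11)  # longer than series

    def test_minmax_normalize(self):
        np.testing.assert_allclose(pg.minmax_normalize([2, 4, 6]), [0, 0.5, 1])
        x = np.array([0.0, 0.25, 1.0])
        np.testing.assert_allclose(pg.minmax_normalize(x), x)
        np.testing.assert_allclose(pg.minmax_normalize(-x),
                                   1 - pg.minmax_normalize(x))
        with pytest.raises(pg.ConfigurationError):
            pg.minmax_normalize([3.0, 3.0, 3.0])

    def test_metric_correlation(self):
        x = np.linspace(0, 1, 50)
        assert pg.metric_correlation(x, x) == pytest.approx(1.0)
        assert pg.metric_correlation(x, -x) == pytest.approx(-1.0)
        rng = np.random.default_rng(0)
        a, b = rng.normal(size=1000), rng.normal(size=1000)
        assert abs(pg.metric_correlation(a, b)) < 0.1
        with pytest.raises(pg.ConfigurationError):
            pg.metric_correlation(np.ones(10), np.arange(10.0))
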