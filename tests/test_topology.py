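import math
import random

import networkx as nx
import pytest

from ppinet import (
    DegenerateInputError,
    betweenness_centrality,
    closeness_centrality,
    compute_node_metrics,
    degree_centrality,
    eigenvector_centrality,
    global_metrics,
    local_clustering,
    top_k,
)

from oracles import (
    brute_betweenness,
    brute_closeness,
    brute_clustering,
    dense_eigenvector,
    net_from_edges,
    random_connected_graph,
)


def cycle(n):
    return net_from_edges([(f"N{i}", f"N{(i + 1) % n}") for i in range(n)])


def complete(n):
    names = [f"N{i}" for i in range(n)]
    return net_from_edges(
        [(u, v) for i, u in enumerate(names) for v in names[i + 1 :]]
    )


class TestDegreeCentrality:
    def test_star_center_and_leaves(self, star4):
        dc = degree_centrality(star4)
        assert dc["HUB"] == 1.0
        assert dc["L1"] == 1 / 3

    def test_triangle_all_one(self, triangle):
        assert set(degree_centrality(triangle).values()) == {1.0}

    def test_path_closed_form(self, path4):
        dc = degree_centrality(path4)
        assert dc["A"] == 1 / 3
        assert dc["B"] == 2 / 3

    def test_single_node_is_degenerate(self):
        from ppinet import Network

        net = Network(edges={}, seed_flags={"A": False})
        with pytest.raises(DegenerateInputError):
            degree_centrality(net)


class TestBetweenness:
    def test_path3_midpoint(self):
        net = net_from_edges([("A", "B"), ("B", "C")])
        bc = betweenness_centrality(net)
        assert bc == {"A": 0.0, "B": 1.0, "C": 0.0}

    def test_path4_inner_node(self, path4):
        assert betweenness_centrality(path4)["B"] == 2 / 3

    def test_degree_one_node_in_connected_graph_is_zero(self, star4):
        bc = betweenness_centrality(star4)
        assert bc["L1"] == 0.0
        assert bc["HUB"] == 1.0

    def test_two_node_graph_all_zero(self):
        net = net_from_edges([("A", "B")])
        assert betweenness_centrality(net) == {"A": 0.0, "B": 0.0}


class TestCloseness:
    def test_path3(self):
        net = net_from_edges([("A", "B"), ("B", "C")])
        cc = closeness_centrality(net)
        assert cc["B"] == 1.0
        assert cc["A"] == 2 / 3

    def test_complete4_all_one(self):
        assert set(closeness_centrality(complete(4)).values()) == {1.0}

    def test_disconnected_component_scaling(self):
        net = net_from_edges([("A", "B"), ("C", "D")])
        cc = closeness_centrality(net)
        assert all(v == pytest.approx(1 / 3, abs=1e-15) for v in cc.values())

    def test_isolated_node_zero(self):
        from ppinet import Network

        net = Network(
            edges={("A", "B"): 1.0}, seed_flags={"A": False, "B": False, "C": False}
        )
        assert closeness_centrality(net)["C"] == 0.0


class TestEigenvector:
    def test_four_cycle_uniform(self):
        ec = eigenvector_centrality(cycle(4))
        for v in ec.values():
            assert v == pytest.approx(0.5, abs=1e-6)

    def test_triangle_uniform(self, triangle):
        ec = eigenvector_centrality(triangle)
        for v in ec.values():
            assert v == pytest.approx(1 / math.sqrt(3), abs=1e-6)

    def test_path3_dominant_eigenvector(self):
        net = net_from_edges([("A", "B"), ("B", "C")])
        ec = eigenvector_centrality(net)
        assert ec["B"] == pytest.approx(math.sqrt(0.5), abs=1e-6)
        assert ec["A"] == pytest.approx(0.5, abs=1e-6)
        assert ec["C"] == pytest.approx(0.5, abs=1e-6)

    def test_norm_is_one(self, two_cliques_bridge):
        ec = eigenvector_centrality(two_cliques_bridge)
        assert math.sqrt(sum(v * v for v in ec.values())) == pytest.approx(
            1.0, abs=1e-6
        )

    def test_edgeless_graph_is_degenerate(self):
        from ppinet import Network

        net = Network(edges={}, seed_flags={"A": False, "B": False})
        with pytest.raises(DegenerateInputError):
            eigenvector_centrality(net)

    def test_relabel_invariance(self):
        rng = random.Random(5)
        pairs = random_connected_graph(rng, 7)
        net = net_from_edges(pairs)
        mapping = {f"N{i}": f"Z{9 - i}" for i in range(7)}
        relabeled = net_from_edges([(mapping[u], mapping[v]) for u, v in pairs])
        ec = eigenvector_centrality(net, tol=1e-10)
        ec2 = eigenvector_centrality(relabeled, tol=1e-10)
        for u in net.nodes:
            assert ec[u] == pytest.approx(ec2[mapping[u]], abs=1e-6)


class TestClustering:
    def test_triangle_all_one(self, triangle):
        assert set(local_clustering(triangle).values()) == {1.0}

    def test_star_all_zero(self, star4):
        assert set(local_clustering(star4).values()) == {0.0}

    def test_k4_minus_edge(self):
        # complete 4-graph minus the (N0, N1) edge
        net = net_from_edges(
            [("N0", "N2"), ("N0", "N3"), ("N1", "N2"), ("N1", "N3"), ("N2", "N3")]
        )
        cl = local_clustering(net)
        assert cl["N2"] == pytest.approx(2 / 3)  # degree 3
        assert cl["N0"] == 1.0  # degree 2


class TestGlobalMetrics:
    def test_path4_closed_form(self, path4):
        gm = global_metrics(path4)
        assert gm.density == 0.5
        assert gm.diameter_lcc == 3
        assert gm.avg_shortest_path_lcc == pytest.approx(10 / 6)

    def test_complete5(self):
        gm = global_metrics(complete(5))
        assert gm.density == 1.0
        assert gm.diameter_lcc == 1
        assert gm.avg_shortest_path_lcc == 1.0

    def test_disconnected_path_metrics_on_lcc_density_on_all(self):
        net = net_from_edges(
            [("A", "B"), ("B", "C"), ("C", "D"), ("D", "E"), ("X", "Y")]
        )
        gm = global_metrics(net)
        assert gm.n_nodes == 7
        assert gm.density == pytest.approx(2 * 5 / (7 * 6))
        assert gm.diameter_lcc == 4
        assert gm.avg_shortest_path_lcc == pytest.approx(2.0)

    def test_singleton_lcc_reports_undefined(self):
        from ppinet import Network

        net = Network(edges={}, seed_flags={"A": False, "B": False})
        gm = global_metrics(net)
        assert gm.diameter_lcc is None
        assert gm.avg_shortest_path_lcc is None


class TestTopK:
    def test_tie_broken_lexicographically(self):
        ranked = top_k({"A": 0.3, "B": 0.7, "C": 0.3}, 2)
        assert ranked == [("B", 0.7), ("A", 0.3)]

    def test_k_larger_than_node_count(self):
        assert len(top_k({"A": 0.1, "B": 0.2}, 10)) == 2

    def test_first_element_attains_maximum(self):
        metrics = {f"N{i}": (i * 7 % 5) / 5 for i in range(10)}
        assert top_k(metrics, 1)[0][1] == max(metrics.values())


class TestVertexTransitivity:
    @pytest.mark.parametrize("make", [cycle, complete], ids=["cycle", "complete"])
    @pytest.mark.parametrize("n", [4, 5, 6])
    def test_all_centralities_constant(self, make, n):
        net = make(n)
        for fn in (degree_centrality, betweenness_centrality, closeness_centrality):
            vals = list(fn(net).values())
            assert max(vals) - min(vals) < 1e-12
        ev = list(eigenvector_centrality(net).values())
        assert max(ev) - min(ev) < 1e-6


class TestOracleEquivalence:
    """Cross-checks against brute-force oracles and the reference library."""

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_and_networkx(self, seed):
        rng = random.Random(1000 + seed)
        n = rng.randint(4, 8)
        pairs = random_connected_graph(rng, n)
        net = net_from_edges(pairs)
        nodes = sorted(net.nodes)

        bc = betweenness_centrality(net)
        oracle_bc = brute_betweenness(pairs, set(nodes))
        g = nx.Graph(pairs)
        nx_bc = nx.betweenness_centrality(g)
        for u in nodes:
            assert bc[u] == pytest.approx(oracle_bc[u], abs=1e-12)
            assert bc[u] == pytest.approx(nx_bc[u], abs=1e-10)

        cc = closeness_centrality(net)
        oracle_cc = brute_closeness(pairs, set(nodes))
        nx_cc = nx.closeness_centrality(g)
        for u in nodes:
            assert cc[u] == pytest.approx(oracle_cc[u], abs=1e-12)
            assert cc[u] == pytest.approx(nx_cc[u], abs=1e-10)

        cl = local_clustering(net)
        oracle_cl = brute_clustering(pairs, set(nodes))
        nx_cl = nx.clustering(g)
        for u in nodes:
            assert cl[u] == pytest.approx(oracle_cl[u], abs=1e-12)
            assert cl[u] == pytest.approx(nx_cl[u], abs=1e-10)

        ec = eigenvector_centrality(net, tol=1e-10)
        oracle_ec = dense_eigenvector(pairs, set(nodes))
        for u in nodes:
            assert ec[u] == pytest.approx(oracle_ec[u], abs=1e-6)

    def test_adding_edge_never_decreases_degree_centrality(self):
        rng = random.Random(7)
        pairs = random_connected_graph(rng, 6)
        net = net_from_edges(pairs)
        missing = [
            (u, v)
            for i, u in enumerate(sorted(net.nodes))
            for v in sorted(net.nodes)[i + 1 :]
            if (u, v) not in net.edges
        ]
        if not missing:
            pytest.skip("graph already complete")
        grown = net_from_edges(pairs + [missing[0]])
        before, after = degree_centrality(net), degree_centrality(grown)
        assert all(after[u] >= before[u] for u in net.nodes)
        assert global_metrics(grown).density > global_metrics(net).density


def test_compute_node_metrics_is_consistent(two_cliques_bridge):
    metrics = compute_node_metrics(two_cliques_bridge)
    dc = degree_centrality(two_cliques_bridge)
    assert all(metrics[u].degree_centrality == dc[u] for u in two_cliques_bridge.nodes)
    for m in metrics.values():
        for value in (m.degree_centrality, m.betweenness, m.closeness,
                      m.eigenvector, m.clustering):
            assert 0.0 <= value <= 1.0
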