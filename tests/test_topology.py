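import math

import networkx as nx
import numpy as np
import pytest

from hubtrace.netio import Network
from hubtrace.topology import (
    ConvergenceError,
    bin_measure_by_degree,
    betweenness_centrality,
    closeness_centrality,
    clustering_by_degree,
    degree_distribution,
    eigenvector_centrality,
    local_clustering,
    neighborhood_connectivity,
)
import oracles
from conftest import adj_of, net_from, random_net


class TestDegreeDistribution:
    def test_triangle(self, triangle):
        assert degree_distribution(triangle).as_dict() == {2: 1.0}

    def test_star(self, star5):
        assert degree_distribution(star5).as_dict() == {1: 0.8, 4: 0.2}

    def test_path(self, path3):
        d = degree_distribution(path3).as_dict()
        assert d[1] == pytest.approx(2 / 3) and d[2] == pytest.approx(1 / 3)

    def test_includes_isolated_nodes(self):
        net = net_from([("A", "B")], nodes=["A", "B", "Z"])
        assert degree_distribution(net).as_dict()[0] == pytest.approx(1 / 3)

    def test_sums_to_one(self):
        for seed in range(5):
            prof = degree_distribution(random_net(40, 0.1, seed))
            assert prof.vals.sum() == pytest.approx(1.0, abs=1e-12)


class TestClustering:
    def test_k4_all_one(self, k4):
        assert clustering_by_degree(k4).as_dict() == {3: 1.0}

    def test_star_center_zero_leaves_excluded(self, star5):
        assert clustering_by_degree(star5).as_dict() == {4: 0.0}

    def test_paw_vertex(self, paw):
        # A has neighbours {B, C, D}, one edge among them: c = 2/(3*2)
        assert local_clustering(paw)["A"] == pytest.approx(1 / 3)

    def test_matches_brute_force_triangle_counting(self):
        for seed in range(10):
            net = random_net(25, 0.2, seed)
            expect = oracles.brute_clustering(adj_of(net))
            got = local_clustering(net)
            for n in net.nodes:
                assert got[n] == pytest.approx(expect[n], abs=1e-12)


class TestNeighborhoodConnectivity:
    def test_k4(self, k4):
        assert neighborhood_connectivity(k4).as_dict() == {3: 3.0}

    def test_star(self, star5):
        assert neighborhood_connectivity(star5).as_dict() == {1: 4.0, 4: 1.0}

    def test_path4_hand_enumeration(self, path4):
        prof = neighborhood_connectivity(path4).as_dict()
        assert prof[1] == pytest.approx(2.0)
        assert prof[2] == pytest.approx(1.5)

    def test_isolated_nodes_excluded(self):
        net = net_from([("A", "B")], nodes=["A", "B", "Z"])
        assert 0 not in neighborhood_connectivity(net).as_dict()


class TestCloseness:
    def test_k4_all_one(self, k4):
        cc = closeness_centrality(k4)
        assert all(cc[n] == pytest.approx(1.0) for n in k4.nodes)

    def test_path3(self, path3):
        cc = closeness_centrality(path3)
        assert cc["B"] == pytest.approx(1.0)
        assert cc["A"] == pytest.approx(2 / 3)

    def test_per_component_no_infinities(self):
        net = net_from([("A", "B"), ("X", "Y")])
        cc = closeness_centrality(net)
        assert all(cc[n] == pytest.approx(1.0) for n in net.nodes)

    def test_isolated_node_scores_zero(self):
        net = net_from([("A", "B")], nodes=["A", "B", "Z"])
        assert closeness_centrality(net)["Z"] == 0.0


class TestEigenvector:
    def test_k4_symmetric(self, k4):
        ce = eigenvector_centrality(k4)
        assert all(ce[n] == pytest.approx(0.5, abs=1e-8) for n in k4.nodes)

    def test_star_center_leaf_ratio_two(self, star5):
        ce = eigenvector_centrality(star5)
        assert ce["C"] / ce["W"] == pytest.approx(2.0, abs=1e-6)

    def test_single_edge(self):
        net = net_from([("A", "B")])
        ce = eigenvector_centrality(net)
        assert ce["A"] == pytest.approx(1 / math.sqrt(2), abs=1e-8)

    def test_outside_largest_component_is_zero(self):
        net = net_from([("A", "B"), ("B", "C"), ("X", "Y")])
        ce = eigenvector_centrality(net)
        assert ce["X"] == 0.0 and ce["Y"] == 0.0

    def test_nonconvergence_raises_with_iteration_count(self, path4):
        with pytest.raises(ConvergenceError) as exc:
            eigenvector_centrality(path4, tol=1e-16, max_iter=2)
        assert exc.value.max_iter == 2

    def test_requires_an_edge(self):
        with pytest.raises(ValueError):
            eigenvector_centrality(net_from([], nodes=["A"]))

    def test_matches_dense_eigendecomposition(self):
        for seed in range(6):
            net = random_net(40, 0.12, seed)
            expect = oracles.dense_principal_eigenvector(adj_of(net))
            got = eigenvector_centrality(net, tol=1e-12, max_iter=5000)
            for n in net.nodes:
                assert got[n] == pytest.approx(expect[n], abs=1e-8)


class TestBetweenness:
    def test_path3_raw(self, path3):
        cb = betweenness_centrality(path3, normalized=False)
        assert cb["B"] == pytest.approx(1.0)
        assert cb["A"] == 0.0

    def test_k4_all_zero(self, k4):
        cb = betweenness_centrality(k4, normalized=False)
        assert all(v == 0.0 for v in cb.values.values())

    def test_star_center_raw_is_pair_count(self, star5):
        cb = betweenness_centrality(star5, normalized=False)
        assert cb["C"] == pytest.approx(6.0)  # C(4,2) pairs

    def test_star_center_normalized_is_one(self, star5):
        assert betweenness_centrality(star5)["C"] == pytest.approx(1.0)

    def test_normalization_uses_component_size(self):
        net = net_from([("A", "B"), ("B", "C"), ("X", "Y"), ("Y", "Z")])
        cb = betweenness_centrality(net, normalized=True)
        assert cb["B"] == pytest.approx(1.0) and cb["Y"] == pytest.approx(1.0)

    def test_matches_brute_force_enumeration(self):
        for seed in range(10):
            net = random_net(22, 0.18, seed)
            expect = oracles.brute_betweenness(adj_of(net), normalized=False)
            got = betweenness_centrality(net, normalized=False)
            for n in net.nodes:
                assert got[n] == pytest.approx(expect[n], abs=1e-9)


class TestBinning:
    def test_star_betweenness_by_degree(self, star5):
        prof = bin_measure_by_degree(
            star5, betweenness_centrality(star5, normalized=False))
        assert prof.as_dict() == {1: 0.0, 4: 6.0}

    def test_k4_closeness(self, k4):
        prof = bin_measure_by_degree(k4, closeness_centrality(k4))
        assert prof.as_dict() == {3: 1.0}

    def test_constant_measure_gives_constant_profile(self, paw):
        from hubtrace.topology import NodeMeasure
        m = NodeMeasure("const", {n: 2.5 for n in paw.nodes})
        prof = bin_measure_by_degree(paw, m)
        assert all(v == 2.5 for v in prof.vals)


class TestInvariants:
    @pytest.mark.parametrize("seed", range(5))
    def test_degree_sum_is_twice_edges(self, seed):
        net = random_net(30, 0.15, seed)
        assert sum(net.degree().values()) == 2 * net.n_edges

    @pytest.mark.parametrize("seed", range(4))
    def test_measures_invariant_under_relabeling(self, seed):
        net = random_net(18, 0.2, seed)
        mapping = {n: f"x{n}" for n in net.nodes}
        relab = Network(graph=nx.relabel_nodes(net.graph, mapping))
        for fn in (closeness_centrality,
                   lambda g: betweenness_centrality(g, normalized=False),
                   local_clustering):
            a, b = fn(net), fn(relab)
            for n in net.nodes:
                assert a[n] == pytest.approx(b[mapping[n]], abs=1e-9)
        pa = degree_distribution(net).as_dict()
        pb = degree_distribution(relab).as_dict()
        assert pa == pb
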