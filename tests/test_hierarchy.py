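import itertools

import networkx as nx
import pytest

from hubtrace.hierarchy import (
    decompose,
    key_regulators,
    louvain_partition,
    modularity_by_level,
    motif_localized_hubs,
    pkr_profile,
)
from hubtrace.netio import Network, induced_subgraph
from hubtrace.synthetic import HierarchyShape, planted_hub_hierarchy
import oracles
from conftest import adj_of, net_from, random_net


def ring_of_cliques(n_cliques=8, k=5):
    g = nx.ring_of_cliques(n_cliques, k)
    return Network(graph=nx.relabel_nodes(g, {v: f"n{v:02d}" for v in g}))


class TestLouvain:
    def test_two_disjoint_triangles_q_half(self, two_triangles):
        parts, q = louvain_partition(two_triangles, rng_seed=1)
        assert sorted(map(sorted, parts)) == [list("ABC"), list("XYZ")]
        assert q == pytest.approx(0.5)
        assert q == pytest.approx(oracles.max_modularity(adj_of(two_triangles)))

    def test_single_triangle_no_split(self, triangle):
        parts, q = louvain_partition(triangle, rng_seed=1)
        assert len(parts) == 1
        assert q == pytest.approx(0.0)

    @pytest.mark.parametrize("seed", range(10))
    def test_ring_of_cliques_recovered(self, seed):
        net = ring_of_cliques(8, 5)
        parts, _ = louvain_partition(net, rng_seed=seed)
        sizes = sorted(len(p) for p in parts)
        assert sizes == [5] * 8

    def test_edgeless_graph_is_error(self):
        with pytest.raises(ValueError):
            louvain_partition(net_from([], nodes=["A", "B"]))

    @pytest.mark.parametrize("seed", range(12))
    def test_close_to_exact_maximum_on_tiny_graphs(self, seed):
        net = random_net(8, 0.35, seed)
        if net.n_edges == 0:
            return
        _, q = louvain_partition(net, rng_seed=seed)
        assert q >= oracles.max_modularity(adj_of(net)) - 0.02

    def test_deterministic_given_seed(self, two_triangles):
        a = louvain_partition(two_triangles, rng_seed=3)
        b = louvain_partition(two_triangles, rng_seed=3)
        assert a == b


@pytest.fixture(scope="module")
def planted():
    net, truth = planted_hub_hierarchy(rng_seed=0)
    tree = decompose(net, hub_threshold=truth.hub_degree_floor, rng_seed=0)
    return net, truth, tree


class TestDecompose:
    def test_planted_hub_triangle_is_deepest_motif_leaf(self, planted):
        net, truth, tree = planted
        deepest = tree.max_motif_level
        assert deepest is not None
        for hub in truth.planted_hub_ids:
            trace = tree.traces[hub]
            leaf = tree.community(trace.path[-1])
            assert leaf.is_motif
            assert leaf.members == frozenset(truth.planted_hub_ids)

    def test_single_clique_gives_depth_zero_no_motifs(self):
        net = net_from(itertools.combinations([f"n{i}" for i in range(6)], 2))
        tree = decompose(net, hub_threshold=1, rng_seed=0)
        assert tree.root.is_leaf
        assert tree.max_motif_level is None

    def test_children_partition_parents(self, planted):
        _, _, tree = planted
        for comm in tree.root.walk():
            if comm.children:
                union = set()
                total = 0
                for ch in comm.children:
                    assert not (union & ch.members)
                    union |= ch.members
                    total += len(ch.members)
                assert union == set(comm.members)
                assert total == len(comm.members)

    def test_trace_paths_are_parent_child_chains(self, planted):
        _, _, tree = planted
        for trace in tree.traces.values():
            assert trace.path[0] == tree.root.id
            for a, b in zip(trace.path, trace.path[1:]):
                parent = tree.community(a)
                assert any(ch.id == b for ch in parent.children)

    def test_intra_community_degree_never_increases(self, planted):
        _, _, tree = planted
        for trace in tree.traces.values():
            xs = [x for _, x in trace.x_by_level]
            assert all(b <= a for a, b in zip(xs, xs[1:]))

    def test_path_of_three_nodes_is_leaf_but_not_motif(self):
        # two weakly joined squares plus a dangling 2-edge path
        edges = [("A", "B"), ("B", "C"), ("C", "D"), ("D", "A"),
                 ("E", "F"), ("F", "G"), ("G", "H"), ("H", "E"),
                 ("A", "E"), ("D", "P1"), ("P1", "P2"), ("P2", "P3")]
        net = net_from(edges)
        tree = decompose(net, hub_threshold=1, rng_seed=0, full=True)
        for comm in tree.root.walk():
            if comm.members == frozenset({"P1", "P2", "P3"}):
                assert not comm.is_motif

    def test_hub_quantile_mode(self, planted):
        net, truth, _ = planted
        tree = decompose(net, hub_quantile=0.02, rng_seed=0)
        assert tree.hub_threshold >= 1
        assert truth.planted_hub_ids <= set(tree.traces)

    def test_json_export_round_trips_class(self, planted, tmp_path):
        import json
        _, _, tree = planted
        payload = json.loads(tree.to_json(tmp_path / "tree.json"))
        assert payload["max_level"] == tree.max_level
        assert payload["tree"]["level"] == 0

    def test_traces_tsv_export(self, planted, tmp_path):
        from hubtrace.hierarchy import traces_to_tsv
        _, _, tree = planted
        out = tmp_path / "traces.tsv"
        traces_to_tsv(tree, out)
        lines = out.read_text().strip().splitlines()
        n_rows = sum(len(t.path) for t in tree.traces.values())
        assert len(lines) == n_rows + 1
        assert lines[0].split("\t")[0] == "gene"


class TestKeyRegulators:
    def test_single_motif_level_equals_motif_localized(self, planted):
        _, truth, tree = planted
        assert motif_localized_hubs(tree) == key_regulators(tree)
        assert key_regulators(tree) == truth.planted_hub_ids

    def test_no_motifs_is_error(self):
        net = net_from(itertools.combinations([f"n{i}" for i in range(6)], 2))
        tree = decompose(net, hub_threshold=1, rng_seed=0)
        assert motif_localized_hubs(tree) == set()
        with pytest.raises(ValueError, match="no key regulators"):
            key_regulators(tree)

    def test_two_tier_planting_returns_only_deepest_triple(self):
        """Triangles planted at two depths: the deeper triple wins.

        Louvain is a heuristic, so the planting is recovered in most but
        not all seeds; require 8 of 10.
        """
        shape = HierarchyShape(motif_depths=(2, 4))
        ok = 0
        for seed in range(10):
            try:
                net, truth = planted_hub_hierarchy(shape, rng_seed=seed)
            except ValueError:
                continue
            tree = decompose(net, hub_threshold=truth.hub_degree_floor,
                             rng_seed=seed)
            try:
                krs = key_regulators(tree)
            except ValueError:
                continue
            ok += krs == truth.deepest_motif_hubs
        assert ok >= 8


class TestPkrProfile:
    def test_root_level_is_degree_over_edges(self, planted):
        net, truth, tree = planted
        hub = sorted(truth.planted_hub_ids)[0]
        prof = pkr_profile(tree, hub)
        level0, p0 = prof[0]
        assert level0 == 0
        assert p0 == pytest.approx(net.degree()[hub] / net.n_edges)

    def test_motif_level_is_two_thirds(self, planted):
        _, truth, tree = planted
        for hub in truth.planted_hub_ids:
            assert pkr_profile(tree, hub)[-1][1] == pytest.approx(2 / 3)

    def test_profile_values_in_unit_interval(self, planted):
        _, truth, tree = planted
        for hub in truth.planted_hub_ids:
            for _, p in pkr_profile(tree, hub):
                assert 0 < p <= 1

    def test_untracked_gene_is_error(self, planted):
        _, _, tree = planted
        with pytest.raises(KeyError):
            pkr_profile(tree, "B00_00")


class TestModularityByLevel:
    def test_depth_one_tree_single_entry(self, two_triangles):
        tree = decompose(two_triangles, hub_threshold=2, rng_seed=1)
        levels = modularity_by_level(tree)
        assert len(levels) == 1
        assert levels[0][0] == 0
        assert levels[0][1] == pytest.approx(0.5)

    def test_root_split_beats_deepest_split(self):
        """Splitting the whole modular network is worth more modularity
        than splitting the small deep communities (criterion of the
        shrinking-Q trend; exact monotonicity is not promised by a
        greedy heuristic)."""
        ok = 0
        for seed in range(10):
            net, truth = planted_hub_hierarchy(rng_seed=seed)
            tree = decompose(net, hub_threshold=truth.hub_degree_floor,
                             rng_seed=seed)
            levels = modularity_by_level(tree)
            if len(levels) >= 2 and levels[0][1] > levels[-1][1]:
                ok += 1
        assert ok >= 8
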