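import itertools
import random

import pytest

from hubtrace.netio import (
    AnnotationSchemaError,
    EdgeListParseError,
    Network,
    induced_subgraph,
    read_annotations,
    read_edge_list,
    read_edge_list_with_isolates,
    remove_nodes,
    write_annotations,
    write_edge_list,
)
from conftest import net_from, random_net


def write_lines(tmp_path, lines, name="net.tsv"):
    p = tmp_path / name
    p.write_text("\n".join(lines) + "\n")
    return p


class TestReadEdgeList:
    def test_dedup_and_self_loops_dropped(self, tmp_path):
        p = write_lines(tmp_path, ["A\tB", "B\tA", "A\tA"])
        net = read_edge_list(p)
        assert net.nodes == {"A", "B"}
        assert net.n_edges == 1

    def test_two_edges(self, tmp_path):
        p = write_lines(tmp_path, ["A\tB", "B\tC"])
        net = read_edge_list(p)
        assert (net.n_nodes, net.n_edges) == (3, 2)

    def test_unique_edge_list_shape_contract(self, tmp_path):
        """n unique pairs over m names -> m nodes, n edges (the shape
        contract of a pre-cleaned database export)."""
        rng = random.Random(7)
        names = [f"G{i:03d}" for i in range(150)]
        pairs = rng.sample(list(itertools.combinations(names, 2)), 2000)
        used = sorted({n for p in pairs for n in p})
        p = write_lines(tmp_path, [f"{a}\t{b}" for a, b in pairs])
        net = read_edge_list(p)
        assert net.n_edges == 2000
        assert net.nodes == set(used)

    def test_malformed_line_names_line_number(self, tmp_path):
        p = write_lines(tmp_path, ["A\tB", "LONELY"])
        with pytest.raises(EdgeListParseError, match=r":2:"):
            read_edge_list(p)

    def test_empty_file_is_error(self, tmp_path):
        p = write_lines(tmp_path, ["# only a comment"])
        with pytest.raises(ValueError, match="no edges"):
            read_edge_list(p)

    def test_whitespace_dialect_and_comments(self, tmp_path):
        p = write_lines(tmp_path, ["# header", "A B", "B  C"])
        net = read_edge_list(p, delimiter=None)
        assert (net.n_nodes, net.n_edges) == (3, 2)

    def test_sif_read_only(self, tmp_path):
        p = write_lines(tmp_path, ["A\tpp\tB", "B\tpp\tC"], name="net.sif")
        net = read_edge_list(p)
        assert net.edges == {frozenset("AB"), frozenset("BC")}

    def test_third_weight_column_ignored(self, tmp_path):
        p = write_lines(tmp_path, ["A\tB\t0.9"])
        assert read_edge_list(p).n_edges == 1

    def test_node_order_in_file_does_not_matter(self, tmp_path):
        p1 = write_lines(tmp_path, ["A\tB", "C\tD"], "a.tsv")
        p2 = write_lines(tmp_path, ["C\tD", "A\tB"], "b.tsv")
        n1, n2 = read_edge_list(p1), read_edge_list(p2)
        assert n1.nodes == n2.nodes and n1.edges == n2.edges


class TestAnnotations:
    def test_flags_parsed(self, tmp_path):
        p = write_lines(tmp_path, ["node\tdrug_associated", "APP\ttrue", "FYN\tfalse"])
        ann = read_annotations(p)
        assert ann.is_drug_associated("APP") is True
        assert ann.is_drug_associated("FYN") is False

    def test_absent_node_is_unannotated_not_false(self, tmp_path):
        p = write_lines(tmp_path, ["node\tdrug_associated", "APP\t1"])
        assert read_annotations(p).is_drug_associated("MAPT") is None

    def test_empty_table(self, tmp_path):
        p = write_lines(tmp_path, ["node\tdrug_associated"])
        assert len(read_annotations(p)) == 0

    def test_flag_count(self, tmp_path):
        rows = [f"G{i}\t{'1' if i < 45 else '0'}" for i in range(80)]
        p = write_lines(tmp_path, ["node\tdrug_associated", *rows])
        assert len(read_annotations(p).drug_genes) == 45

    def test_missing_column_is_schema_error(self, tmp_path):
        p = write_lines(tmp_path, ["gene\tflag", "APP\t1"])
        with pytest.raises(AnnotationSchemaError):
            read_annotations(p)

    def test_extra_columns_preserved(self, tmp_path):
        p = write_lines(tmp_path,
                        ["node\tdrug_associated\tsource", "APP\ttrue\tdb1"])
        ann = read_annotations(p)
        assert ann.records["APP"]["extra"]["source"] == "db1"

    def test_round_trip(self, tmp_path):
        p = write_lines(tmp_path, ["node\tdrug_associated", "A\ttrue", "B\tfalse"])
        ann = read_annotations(p)
        out = tmp_path / "out.tsv"
        write_annotations(ann, out)
        again = read_annotations(out)
        assert again.drug_genes == ann.drug_genes


class TestSubgraphPrimitives:
    def test_induced_k4_triple_is_triangle(self, k4):
        sub = induced_subgraph(k4, {"A", "B", "C"})
        assert (sub.n_nodes, sub.n_edges) == (3, 3)

    def test_induced_identity(self, paw):
        sub = induced_subgraph(paw, paw.nodes)
        assert sub.nodes == paw.nodes and sub.edges == paw.edges

    def test_induced_endpoints_only(self, path3):
        sub = induced_subgraph(path3, {"A", "C"})
        assert (sub.n_nodes, sub.n_edges) == (2, 0)

    def test_induced_rejects_empty_and_foreign(self, k4):
        with pytest.raises(ValueError):
            induced_subgraph(k4, set())
        with pytest.raises(ValueError, match="ZZ"):
            induced_subgraph(k4, {"A", "ZZ"})

    def test_remove_star_center_isolates_leaves(self, star5):
        out = remove_nodes(star5, {"C"})
        assert out.n_nodes == 4 and out.n_edges == 0
        assert all(d == 0 for _, d in out.graph.degree())

    def test_remove_nothing_is_identity(self, k4):
        out = remove_nodes(k4, set())
        assert out.nodes == k4.nodes and out.edges == k4.edges

    def test_remove_from_triangle_leaves_edge(self, triangle):
        out = remove_nodes(triangle, {"A"})
        assert out.edges == {frozenset("BC")}

    def test_remove_all_nodes_is_error(self, triangle):
        with pytest.raises(ValueError, match="empty result"):
            remove_nodes(triangle, triangle.nodes)

    def test_input_unchanged(self, k4):
        remove_nodes(k4, {"A"})
        assert k4.n_nodes == 4 and k4.n_edges == 6

    @pytest.mark.parametrize("seed", range(8))
    def test_induced_edge_count_matches_brute_force(self, seed):
        rng = random.Random(seed)
        net = random_net(30, 0.2, seed)
        members = set(rng.sample(sorted(net.nodes), 12))
        sub = induced_subgraph(net, members)
        brute = sum(1 for e in net.edges if e <= members)
        assert sub.n_edges == brute

    @pytest.mark.parametrize("seed", range(8))
    def test_removal_conserves_edges(self, seed):
        rng = random.Random(seed)
        net = random_net(25, 0.15, seed)
        victims = set(rng.sample(sorted(net.nodes), 6))
        out = remove_nodes(net, victims)
        incident = sum(1 for e in net.edges if e & victims)
        assert net.n_edges - out.n_edges == incident


class TestRoundTrip:
    @pytest.mark.parametrize("seed", range(5))
    def test_write_read_identical(self, tmp_path, seed):
        net = random_net(20, 0.1, seed)  # sparse: isolated nodes likely
        p = tmp_path / "rt.tsv"
        write_edge_list(net, p)
        back = read_edge_list_with_isolates(p)
        assert back.nodes == net.nodes
        assert back.edges == net.edges

    def test_self_loop_rejected_at_construction(self):
        import networkx as nx
        g = nx.Graph([("A", "A")])
        with pytest.raises(ValueError, match="self-loop"):
            Network(graph=g)
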