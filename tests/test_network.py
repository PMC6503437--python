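import networkx as nx
import numpy as np
import pytest

from genesurrounder import (
    GeneNetwork,
    NetworkError,
    build_union_graph,
    geodesic_distances,
    largest_connected_component,
    read_edge_list,
)
from oracles import floyd_warshall, union_by_pairwise_merge


class TestUnionGraph:
    def test_overlapping_pathways_merge_to_set_union(self):
        net = build_union_graph([[("A", "B"), ("B", "C")], [("B", "C"), ("C", "D")]])
        assert net.nodes == {"A", "B", "C", "D"}
        assert {frozenset(e) for e in net.graph.edges} == {
            frozenset(p) for p in [("A", "B"), ("B", "C"), ("C", "D")]
        }

    def test_self_loops_are_dropped(self):
        net = build_union_graph([[("A", "A"), ("A", "B")]])
        assert net.n_edges == 1 and net.nodes == {"A", "B"}

    def test_empty_input_is_an_error(self):
        with pytest.raises(NetworkError, match="no edges"):
            build_union_graph([[]])

    def test_malformed_edge_names_offending_record(self):
        with pytest.raises(NetworkError, match="A.*B.*C"):
            build_union_graph([[("A", "B", "C")]])

    def test_random_pathways_match_pairwise_merge_oracle(self, rng):
        pathways = []
        for _ in range(10):
            genes = [f"n{k}" for k in rng.choice(20, size=5, replace=False)]
            pathways.append(
                [tuple(rng.choice(genes, size=2, replace=False)) for _ in range(6)]
            )
        pathways = [[e for e in p if e[0] != e[1]] for p in pathways]
        net = build_union_graph(pathways)
        nodes, edges = union_by_pairwise_merge(pathways)
        assert net.nodes == nodes
        assert {frozenset(e) for e in net.graph.edges} == edges

    def test_union_edge_count_bounded_by_sum_with_equality_iff_disjoint(self):
        disjoint = [[("A", "B")], [("C", "D")]]
        overlapping = [[("A", "B")], [("A", "B"), ("B", "C")]]
        assert build_union_graph(disjoint).n_edges == 2
        assert build_union_graph(overlapping).n_edges == 2 < 3


class TestLargestComponent:
    def test_keeps_the_bigger_component(self):
        g = nx.Graph()
        nx.add_path(g, ["a", "b", "c", "d", "e"])
        nx.add_path(g, ["x", "y", "z"])
        lcc = largest_connected_component(GeneNetwork(g))
        assert lcc.nodes == {"a", "b", "c", "d", "e"}

    def test_connected_graph_is_unchanged(self, path_net):
        lcc = largest_connected_component(path_net)
        assert lcc.nodes == path_net.nodes and lcc.n_edges == path_net.n_edges

    def test_size_tie_broken_toward_alphabetically_first_node(self):
        g = nx.Graph([("m", "n"), ("a", "z")])
        lcc = largest_connected_component(GeneNetwork(g))
        assert lcc.nodes == {"a", "z"}

    def test_assayed_mask_restricted_to_kept_component(self):
        g = nx.Graph([("a", "b"), ("c", "d"), ("d", "e")])
        net = GeneNetwork(g, assayed=frozenset({"a", "d"}))
        lcc = largest_connected_component(net)
        assert lcc.assayed == {"d"}


class TestDistances:
    def test_path_graph_end_to_end(self, path_net):
        oracle = geodesic_distances(path_net)
        assert oracle.distance("A", "D") == 3
        assert oracle.diameter == 3

    def test_complete_graph_all_distance_one(self):
        net = GeneNetwork(nx.complete_graph(["a", "b", "c", "d"]))
        oracle = geodesic_distances(net)
        assert oracle.diameter == 1
        assert all(
            oracle.distance(i, j) == 1 for i in net.nodes for j in net.nodes if i != j
        )

    def test_disconnected_graph_is_rejected(self):
        net = GeneNetwork(nx.Graph([("a", "b"), ("c", "d")]))
        with pytest.raises(NetworkError, match="disconnected"):
            geodesic_distances(net)

    def test_random_graphs_match_floyd_warshall(self, rng):
        for trial in range(5):
            g = nx.gnp_random_graph(30, 0.12, seed=int(rng.integers(1 << 30)))
            g = g.subgraph(max(nx.connected_components(g), key=len)).copy()
            g = nx.relabel_nodes(g, {n: f"v{n}" for n in g.nodes})
            net = GeneNetwork(g)
            oracle = geodesic_distances(net)
            fw = floyd_warshall(oracle.nodes, list(g.edges))
            mine = np.array(
                [[oracle.distance(i, j) for j in oracle.nodes] for i in oracle.nodes]
            )
            assert np.array_equal(mine, fw.astype(int))


class TestNeighborhood:
    def test_radius_one_on_a_path(self, path_net):
        oracle = geodesic_distances(path_net)
        assert oracle.neighborhood("B", 1) == {"A", "C"}

    def test_saturates_to_everything_else_at_diameter(self, path_net):
        oracle = geodesic_distances(path_net)
        assert oracle.neighborhood("A", oracle.diameter) == {"B", "C", "D"}

    def test_center_gene_is_excluded(self, path_net):
        oracle = geodesic_distances(path_net)
        for r in range(1, oracle.diameter + 1):
            assert "B" not in oracle.neighborhood("B", r)

    def test_radius_out_of_range_is_an_error(self, path_net):
        oracle = geodesic_distances(path_net)
        with pytest.raises(NetworkError):
            oracle.neighborhood("A", 0)
        with pytest.raises(NetworkError):
            oracle.neighborhood("A", oracle.diameter + 1)

    def test_nested_and_nondecreasing_in_radius_on_random_graphs(self, rng):
        for _ in range(3):
            g = nx.connected_watts_strogatz_graph(
                30, 4, 0.2, seed=int(rng.integers(1 << 30))
            )
            net = GeneNetwork(nx.relabel_nodes(g, {n: f"v{n}" for n in g.nodes}))
            oracle = geodesic_distances(net)
            center = sorted(net.nodes)[0]
            prev: set = set()
            for r in range(1, oracle.diameter + 1):
                cur = oracle.neighborhood(center, r)
                direct = {
                    j
                    for j in net.nodes
                    if j != center and oracle.distance(center, j) <= r
                }
                assert cur == direct
                assert prev <= cur
                prev = cur
            assert len(prev) == net.n_nodes - 1

    def test_assayed_only_restriction(self, path_net):
        net = path_net.with_assayed({"A", "D"})
        oracle = geodesic_distances(net)
        assert oracle.neighborhood("B", 2, assayed_only=True) == {"A", "D"}


class TestEdgeListIO:
    def test_two_column_and_sif_roundtrip(self, tmp_path):
        p2 = tmp_path / "net.tsv"
        p2.write_text("# comment\nA\tB\nB\tC\n")
        net = read_edge_list(p2)
        assert net.nodes == {"A", "B", "C"} and net.n_edges == 2

        psif = tmp_path / "net.sif"
        psif.write_text("A\tpp\tB\nB\tpp\tC\tD\n")
        sif = read_edge_list(psif)
        assert sif.nodes == {"A", "B", "C", "D"} and sif.n_edges == 3

    def test_unparseable_line_reports_location(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("A\tB\nlonely\n")
        with pytest.raises(NetworkError, match="2"):
            read_edge_list(p)
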