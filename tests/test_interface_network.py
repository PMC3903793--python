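import itertools

import networkx as nx
import pytest

from piface.interface_network import (
    ClusterSet,
    InterfaceNetwork,
    build_network,
    cluster_interfaces,
    clustering_coefficient,
    edge_betweenness,
    girvan_newman_divide,
    group_nodes,
    param_tag,
    select_representative,
)
from piface.structural_align import SimilarityTable
from piface.synthetic_fixtures import PlantedGraphSpec, planted_partition_graph


def net_from_edges(edges, nodes=()):
    g = nx.Graph()
    g.add_nodes_from(nodes)
    for u, v, *w in edges:
        g.add_edge(u, v, weight=w[0] if w else 1.0)
    for n in g.nodes:
        g.nodes[n]["members"] = (n,)
    return InterfaceNetwork(graph=g)


# ---------------------------------------------------------------------------
# independent oracles

def cc_oracle(g: nx.Graph) -> float:
    """Mean local clustering coefficient by explicit triple enumeration."""
    if g.number_of_nodes() == 0:
        raise ValueError
    total = 0.0
    for i in g.nodes:
        nbrs = list(g.neighbors(i))
        k = len(nbrs)
        if k < 2:
            continue
        closed = sum(1 for a, b in itertools.combinations(nbrs, 2) if g.has_edge(a, b))
        total += 2.0 * closed / (k * (k - 1))
    return total / g.number_of_nodes()


def betweenness_oracle(g: nx.Graph) -> dict:
    """Edge betweenness by explicit enumeration of all shortest paths."""
    def all_shortest_paths(src, dst):
        # BFS layering, then recursive path expansion
        dist = {src: 0}
        preds = {src: []}
        frontier = [src]
        while frontier:
            nxt = []
            for u in frontier:
                for v in g.neighbors(u):
                    if v not in dist:
                        dist[v] = dist[u] + 1
                        preds[v] = [u]
                        nxt.append(v)
                    elif dist[v] == dist[u] + 1:
                        preds[v].append(u)
            frontier = nxt
        if dst not in dist:
            return []
        paths = []

        def walk(node, acc):
            if node == src:
                paths.append([src] + acc[::-1])
                return
            for p in preds[node]:
                walk(p, acc + [node])

        walk(dst, [])
        return [p for p in paths]

    eb = {tuple(sorted(e)): 0.0 for e in g.edges}
    for src, dst in itertools.combinations(sorted(g.nodes), 2):
        paths = all_shortest_paths(src, dst)
        if not paths:
            continue
        for p in paths:
            for u, v in zip(p, p[1:]):
                eb[tuple(sorted((u, v)))] += 1.0 / len(paths)
    return eb


# ---------------------------------------------------------------------------

class TestBuildNetwork:
    def table(self):
        t = SimilarityTable()
        t.add("A", "B", 10, 1.0, 0.80)
        t.add("B", "C", 10, 1.0, 0.70)
        for n in "DE":
            t.add_node(n)
        return t

    def test_threshold_semantics(self):
        net = build_network(self.table(), edge_threshold=0.75)
        assert net.graph.has_edge("A", "B")
        assert net.graph["A"]["B"]["weight"] == pytest.approx(0.80)
        assert not net.graph.has_edge("B", "C")

    def test_isolated_nodes_kept(self):
        net = build_network(self.table(), edge_threshold=0.75)
        assert set(net.graph.nodes) == {"A", "B", "C", "D", "E"}
        assert net.graph.degree["D"] == 0

    def test_empty_table_all_isolated(self):
        t = SimilarityTable()
        for n in "ABCDE":
            t.add_node(n)
        net = build_network(t)
        assert net.graph.number_of_nodes() == 5
        assert net.graph.number_of_edges() == 0

    def test_planted_two_blocks_two_components(self):
        net, labels = planted_partition_graph(PlantedGraphSpec(
            block_sizes=(5, 5), p_in=1.0, p_out=0.0, seed=1))
        comps = net.connected_components()
        assert len(comps) == 2
        assert {frozenset(c.graph.nodes) for c in comps} == {
            frozenset(n for n, b in labels.items() if b == 0),
            frozenset(n for n, b in labels.items() if b == 1),
        }


class TestClusteringCoefficient:
    def test_triangle_is_one(self):
        assert clustering_coefficient(net_from_edges([("a", "b"), ("b", "c"), ("a", "c")])) == 1.0

    def test_path_is_zero(self):
        assert clustering_coefficient(net_from_edges([("a", "b"), ("b", "c")])) == 0.0

    def test_four_node_example(self):
        net = net_from_edges([("A", "B"), ("B", "C"), ("C", "D"), ("A", "C")])
        assert clustering_coefficient(net) == pytest.approx(cc_oracle(net.graph))

    def test_empty_graph_error(self):
        with pytest.raises(ValueError):
            clustering_coefficient(InterfaceNetwork())

    def test_matches_oracle_on_all_graphs_up_to_5_nodes(self):
        for n in range(1, 6):
            possible = list(itertools.combinations(range(n), 2))
            for bits in range(2 ** len(possible)):
                g = nx.Graph()
                g.add_nodes_from(range(n))
                g.add_edges_from(e for i, e in enumerate(possible) if bits >> i & 1)
                assert clustering_coefficient(InterfaceNetwork(graph=g)) == pytest.approx(cc_oracle(g))


class TestEdgeBetweenness:
    def test_bridge_has_maximal_value(self):
        g = nx.disjoint_union(nx.complete_graph(5), nx.complete_graph(5))
        g.add_edge(0, 5)
        eb = edge_betweenness(InterfaceNetwork(graph=g))
        bridge = eb[(0, 5)]
        assert all(v < bridge for e, v in eb.items() if e != (0, 5))

    def test_clique_edges_equal(self):
        eb = edge_betweenness(InterfaceNetwork(graph=nx.complete_graph(5)))
        assert len(set(round(v, 9) for v in eb.values())) == 1

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_matches_bruteforce_on_random_graphs(self, seed):
        g = nx.gnp_random_graph(12, 0.3, seed=seed)
        eb = edge_betweenness(InterfaceNetwork(graph=g))
        oracle = betweenness_oracle(g)
        assert set(eb) == set(oracle)
        for e in oracle:
            assert eb[e] == pytest.approx(oracle[e])


class TestGirvanNewmanDivide:
    def two_cliques_bridged(self, n1=6, n2=6):
        g = nx.disjoint_union(nx.complete_graph(n1), nx.complete_graph(n2))
        g.add_edge(0, n1)
        for node in g.nodes:
            g.nodes[node]["members"] = (node,)
        nx.set_edge_attributes(g, 1.0, "weight")
        return InterfaceNetwork(graph=g)

    def test_recovers_two_cliques(self):
        net = self.two_cliques_bridged()
        parts = girvan_newman_divide(net, cc_stop=1.0)
        assert sorted(sorted(p.graph.nodes) for p in parts) == [
            list(range(6)), list(range(6, 12))]

    def test_first_removal_is_the_bridge(self):
        net = self.two_cliques_bridged()
        eb = edge_betweenness(net)
        assert max(eb, key=eb.get) == (0, 6)

    def test_single_clique_returned_whole(self):
        g = nx.complete_graph(5)
        for n in g.nodes:
            g.nodes[n]["members"] = (n,)
        parts = girvan_newman_divide(InterfaceNetwork(graph=g), cc_stop=1.0)
        assert len(parts) == 1
        assert set(parts[0].graph.nodes) == set(range(5))

    def test_cc_stop_zero_returns_components_whole(self):
        g = nx.path_graph(10)  # cc = 0 everywhere; >= 0 stops immediately
        for n in g.nodes:
            g.nodes[n]["members"] = (n,)
        parts = girvan_newman_divide(InterfaceNetwork(graph=g), cc_stop=0.0)
        assert len(parts) == 1

    def test_small_split_product_not_divided(self):
        # star(4 nodes, cc 0) -- bridge -- path(6 nodes, cc 0):
        # after the bridge is cut the 4-node side is < 5 and must stay whole,
        # while the 6-node side keeps dividing.
        g = nx.Graph()
        g.add_edges_from([("s0", "s1"), ("s0", "s2"), ("s0", "s3")])
        g.add_edges_from([(f"p{i}", f"p{i+1}") for i in range(5)])
        g.add_edge("s0", "p0")
        for n in g.nodes:
            g.nodes[n]["members"] = (n,)
        parts = girvan_newman_divide(InterfaceNetwork(graph=g), cc_stop=1.0)
        part_sets = [set(p.graph.nodes) for p in parts]
        assert {"s0", "s1", "s2", "s3"} in part_sets
        assert all(not s < {"s0", "s1", "s2", "s3"} for s in part_sets)  # never subdivided
        assert sum(1 for s in part_sets if s <= {f"p{i}" for i in range(6)}) > 1


class TestGroupNodes:
    def test_pair_merges_with_max_weight_to_neighbour(self):
        net = net_from_edges([("G", "H", 0.9), ("G", "X", 0.5), ("H", "X", 0.7)])
        grouped = group_nodes(net, sim_threshold=0.8, merge_mode="max")
        assert grouped.graph.number_of_nodes() == 2
        supernode = next(n for n in grouped.graph.nodes if n != "X")
        assert set(grouped.members(supernode)) == {"G", "H"}
        assert grouped.graph[supernode]["X"]["weight"] == pytest.approx(0.7)

    def test_min_mode(self):
        net = net_from_edges([("G", "H", 0.9), ("G", "X", 0.5), ("H", "X", 0.7)])
        grouped = group_nodes(net, 0.8, merge_mode="min")
        supernode = next(n for n in grouped.graph.nodes if n != "X")
        assert grouped.graph[supernode]["X"]["weight"] == pytest.approx(0.5)

    def test_no_edge_above_threshold_unchanged(self):
        net = net_from_edges([("a", "b", 0.5), ("b", "c", 0.7)])
        grouped = group_nodes(net, 0.8)
        assert set(grouped.graph.nodes) == {"a", "b", "c"}
        assert grouped.graph.number_of_edges() == 2

    def test_chain_merge_order(self):
        net = net_from_edges([("a", "b", 0.95), ("b", "c", 0.85)])
        grouped = group_nodes(net, 0.8, merge_mode="max")
        assert grouped.graph.number_of_nodes() == 1
        assert set(grouped.members(next(iter(grouped.graph.nodes)))) == {"a", "b", "c"}

    def test_membership_conserved(self):
        net, _ = planted_partition_graph(PlantedGraphSpec(
            block_sizes=(6, 6), p_in=0.9, p_out=0.2, w_out=(0.3, 0.5), seed=5))
        grouped = group_nodes(net, 0.85)
        assert sorted(grouped.all_members()) == sorted(net.graph.nodes)

    def test_threshold_inclusive(self):
        net = net_from_edges([("a", "b", 0.8)])
        grouped = group_nodes(net, 0.8)
        assert grouped.graph.number_of_nodes() == 1


class TestClusterInterfaces:
    def test_three_mutually_similar(self):
        net = net_from_edges([("a", "b", 0.9), ("b", "c", 0.9), ("a", "c", 0.9)])
        cs = cluster_interfaces(net, cc_stop=1.0)
        assert cs.clusters == [frozenset({"a", "b", "c"})]

    def test_planted_four_communities_recovered(self):
        net, labels = planted_partition_graph(PlantedGraphSpec(
            block_sizes=(6, 6, 6, 6), p_in=1.0, p_out=0.0, seed=3))
        # add a couple of weak cross links so the graph is not trivially split
        names = sorted(labels)
        net.graph.add_edge(names[0], names[6], weight=0.76)
        net.graph.add_edge(names[12], names[18], weight=0.76)
        cs = cluster_interfaces(net, cc_stop=1.0)
        expected = {frozenset(n for n in labels if labels[n] == b) for b in range(4)}
        assert set(cs.clusters) == expected

    def test_partition_property(self):
        net, labels = planted_partition_graph(PlantedGraphSpec(
            block_sizes=(7, 5, 8), p_in=0.8, p_out=0.15, w_out=(0.75, 0.8), seed=11))
        cs = cluster_interfaces(net, cc_stop=1.0)
        all_members = [m for c in cs.clusters for m in c]
        assert sorted(all_members) == sorted(labels)

    def test_param_tag(self):
        assert param_tag(1.0, 5, "max") == "100_5_max"
        assert param_tag(0.6, 5, "max") == "60_5_max"
        assert param_tag(0.95, 1, "min") == "95_1_min"

    def test_deterministic(self):
        net, _ = planted_partition_graph(PlantedGraphSpec(
            block_sizes=(6, 6), p_in=0.9, p_out=0.1, seed=2))
        cs1 = cluster_interfaces(net, cc_stop=1.0)
        cs2 = cluster_interfaces(net, cc_stop=1.0)
        assert cs1.clusters == cs2.clusters


class TestSelectRepresentative:
    def table(self):
        t = SimilarityTable()
        t.add("a", "b", 1, 0.1, 0.9)
        t.add("b", "c", 1, 0.1, 0.9)
        t.add("a", "c", 1, 0.1, 0.5)
        return t

    def test_singleton(self):
        assert select_representative({"x"}, SimilarityTable()) == "x"

    def test_central_node_wins(self):
        # b has mean 0.9; a and c have mean 0.7
        assert select_representative({"a", "b", "c"}, self.table()) == "b"

    def test_tie_broken_by_name(self):
        t = SimilarityTable()
        for x, y in itertools.combinations("abc", 2):
            t.add(x, y, 1, 0.1, 0.9)
        assert select_representative({"a", "b", "c"}, t) == "a"

    def test_empty_cluster_error(self):
        with pytest.raises(ValueError):
            select_representative(set(), SimilarityTable())


def test_cluster_set_tsv_round_trip(tmp_path):
    cs = ClusterSet(clusters=[frozenset({"a", "b"}), frozenset({"c"})],
                    representative={0: "a", 1: "c"})
    path = tmp_path / "clusters.tsv"
    cs.to_tsv(path)
    back = ClusterSet.from_tsv(path)
    assert back.clusters == cs.clusters
    assert back.representative == cs.representative
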