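"""Interface-similarity network and staged community finding.

Clustering follows a two-phase scheme: five node-grouping stages at
ascending similarity thresholds (0.80 ... 1.00), each followed by
edge-betweenness division of the grouped networks, then a final division
pass on the expanded (ungrouped) networks. Division removes the
highest-betweenness edge repeatedly, recursing into split components
until a component's mean local clustering coefficient reaches the stop
criterion or a split product holds fewer than ``min_size`` interfaces.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx

from piface.structural_align import SimilarityTable

logger = logging.getLogger(__name__)

DEFAULT_EDGE_THRESHOLD = 0.75
DEFAULT_GROUPING_STEPS = (0.80, 0.85, 0.90, 0.95, 1.00)
DEFAULT_MIN_CLUSTER_SIZE = 5


@dataclass
class InterfaceNetwork:
    """Weighted graph of interfaces; nodes may be supernodes with members."""

    graph: nx.Graph = field(default_factory=nx.Graph)

    def copy(self) -> "InterfaceNetwork":
        return InterfaceNetwork(graph=self.graph.copy())

    @property
    def nodes(self):
        return self.graph.nodes

    @property
    def edges(self):
        return self.graph.edges

    def members(self, node) -> tuple:
        return self.graph.nodes[node].get("members", (node,))

    def all_members(self) -> list:
        out = []
        for n in self.graph.nodes:
            out.extend(self.members(n))
        return out

    def n_interfaces(self) -> int:
        return sum(len(self.members(n)) for n in self.graph.nodes)

    def subnetwork(self, nodes) -> "InterfaceNetwork":
        return InterfaceNetwork(graph=self.graph.subgraph(nodes).copy())

    def connected_components(self) -> list["InterfaceNetwork"]:
        comps = sorted(nx.connected_components(self.graph), key=lambda c: sorted(c)[0])
        return [self.subnetwork(c) for c in comps]

    def to_graphml(self, path) -> None:
        g = self.graph.copy()
        for n in g.nodes:
            if "members" in g.nodes[n]:
                g.nodes[n]["members"] = ",".join(map(str, g.nodes[n]["members"]))
        nx.write_graphml(g, path)


@dataclass
class ClusterSet:
    """Final partition of interfaces plus representatives and parameters."""

    clusters: list[frozenset]
    representative: dict[int, str] = field(default_factory=dict)
    params: tuple = ()

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    def labels(self) -> dict[str, int]:
        return {m: ci for ci, cluster in enumerate(self.clusters) for m in cluster}

    def to_tsv(self, path) -> None:
        lines = ["cluster_id\trepresentative\tmembers\n"]
        for ci, cluster in enumerate(self.clusters):
            rep = self.representative.get(ci, "")
            lines.append(f"{ci}\t{rep}\t{','.join(sorted(cluster))}\n")
        from pathlib import Path
        Path(path).write_text("".join(lines))

    @classmethod
    def from_tsv(cls, path) -> "ClusterSet":
        from pathlib import Path
        clusters, reps = [], {}
        for line in Path(path).read_text().splitlines()[1:]:
            if not line.strip():
                continue
            ci, rep, members = line.split("\t")
            clusters.append(frozenset(members.split(",")))
            reps[int(ci)] = rep
        return cls(clusters=clusters, representative=reps)


def param_tag(cc_stop: float, step_percent: int, merge_mode: str) -> str:
    """Parameter-cell tag, e.g. cc_stop=1.0, 5% step, max mode -> "100_5_max"."""
    return f"{int(round(cc_stop * 100))}_{step_percent}_{merge_mode}"


def build_network(
    sim_table: SimilarityTable,
    edge_threshold: float = DEFAULT_EDGE_THRESHOLD,
) -> InterfaceNetwork:
    """Node per interface; edge where similarity >= ``edge_threshold``."""
    g = nx.Graph()
    for n in sorted(sim_table.nodes):
        g.add_node(n, members=(n,))
    for a, b, _, _, s in sim_table.pairs():
        if a != b and s >= edge_threshold:
            g.add_edge(a, b, weight=s)
    return InterfaceNetwork(graph=g)


def clustering_coefficient(net: InterfaceNetwork) -> float:
    """Mean local clustering coefficient; degree-<2 nodes contribute 0."""
    g = net.graph
    if g.number_of_nodes() == 0:
        raise ValueError("empty network")
    cc = nx.clustering(g)  # unweighted local coefficients
    return sum(cc.values()) / g.number_of_nodes()


def edge_betweenness(net: InterfaceNetwork) -> dict[tuple, float]:
    """Exact (Brandes) edge betweenness on the unweighted graph."""
    raw = nx.edge_betweenness_centrality(net.graph, normalized=False)
    return {(min(u, v), max(u, v)): val for (u, v), val in raw.items()}


def _highest_betweenness_edge(net: InterfaceNetwork) -> tuple:
    eb = edge_betweenness(net)
    # max value; ties broken lexicographically on (min endpoint, max endpoint)
    return min(eb, key=lambda e: (-eb[e], e))


def girvan_newman_divide(
    net: InterfaceNetwork,
    cc_stop: float,
    min_size: int = DEFAULT_MIN_CLUSTER_SIZE,
) -> list[InterfaceNetwork]:
    """Edge-betweenness division with the two stopping criteria.

    A component stops dividing when its clustering coefficient reaches
    ``cc_stop`` (>= convention, so cc_stop=0 returns components whole
    and cc_stop=1 stops exactly on locally complete graphs), or when it
    carries fewer than ``min_size`` interfaces — the algorithm only
    tries to divide networks above the minimum size, which prevents
    small components from falling apart into singletons (supernode
    members are counted, not nodes).
    """
    out: list[InterfaceNetwork] = []
    stack = list(reversed(net.connected_components()))
    while stack:
        comp = stack.pop()
        n_nodes = comp.graph.number_of_nodes()
        if n_nodes <= 1 or comp.graph.number_of_edges() == 0:
            out.append(comp)
            continue
        if comp.n_interfaces() < min_size:
            out.append(comp)
            continue
        if clustering_coefficient(comp) >= cc_stop:
            out.append(comp)
            continue
        # remove highest-betweenness edges until the component splits
        work = comp.copy()
        while nx.is_connected(work.graph) and work.graph.number_of_edges() > 0:
            u, v = _highest_betweenness_edge(work)
            work.graph.remove_edge(u, v)
        pieces = work.connected_components()
        for piece in reversed(pieces):
            stack.append(piece)
    return out


def group_nodes(
    net: InterfaceNetwork,
    sim_threshold: float,
    merge_mode: str = "max",
) -> InterfaceNetwork:
    """Condense nodes joined by edges of weight >= ``sim_threshold``.

    Merging is greedy from the current highest-weight edge; the merged
    supernode inherits each neighbour with the max (or min) of the
    existing edge weights to that neighbour. Member lists concatenate
    (kept sorted for determinism).
    """
    if merge_mode not in ("max", "min"):
        raise ValueError(f"merge_mode must be 'max' or 'min', got {merge_mode!r}")
    g = net.graph.copy()
    for n in g.nodes:
        g.nodes[n].setdefault("members", (n,))
    pick = max if merge_mode == "max" else min
    while True:
        candidates = [(d["weight"], (min(u, v), max(u, v)))
                      for u, v, d in g.edges(data=True) if d["weight"] >= sim_threshold]
        if not candidates:
            break
        _, (u, v) = min(candidates, key=lambda c: (-c[0], c[1]))
        merged_members = tuple(sorted(g.nodes[u]["members"] + g.nodes[v]["members"]))
        for nbr in list(g.neighbors(v)):
            if nbr == u:
                continue
            w_v = g[v][nbr]["weight"]
            if g.has_edge(u, nbr):
                g[u][nbr]["weight"] = pick(g[u][nbr]["weight"], w_v)
            else:
                g.add_edge(u, nbr, weight=w_v)
        g.remove_node(v)
        g.nodes[u]["members"] = merged_members
    return InterfaceNetwork(graph=g)


def cluster_interfaces(
    net: InterfaceNetwork,
    cc_stop: float = 1.0,
    grouping_steps: tuple[float, ...] = DEFAULT_GROUPING_STEPS,
    merge_mode: str = "max",
    min_size: int = DEFAULT_MIN_CLUSTER_SIZE,
    sim_table: SimilarityTable | None = None,
) -> ClusterSet:
    """Staged grouping + division, then a final ungrouped division pass.

    Returns a partition of every interface in ``net``. When
    ``sim_table`` is provided, cluster representatives (members with
    maximal mean similarity to the rest of their cluster) are selected.
    """
    original = net.graph
    networks = [net.copy()]
    for step in grouping_steps:
        next_networks: list[InterfaceNetwork] = []
        for sub in networks:
            grouped = group_nodes(sub, step, merge_mode)
            next_networks.extend(girvan_newman_divide(grouped, cc_stop, min_size))
        networks = next_networks

    # expand supernodes: induced subgraphs of the original network
    clusters: list[frozenset] = []
    for sub in networks:
        members = sub.all_members()
        expanded = InterfaceNetwork(graph=original.subgraph(members).copy())
        for n in expanded.graph.nodes:
            expanded.graph.nodes[n]["members"] = (n,)
        for piece in girvan_newman_divide(expanded, cc_stop, min_size):
            clusters.append(frozenset(piece.graph.nodes))
    clusters.sort(key=lambda c: sorted(c)[0])

    result = ClusterSet(clusters=clusters, params=(cc_stop, grouping_steps, merge_mode, min_size))
    if sim_table is not None:
        for ci, cluster in enumerate(clusters):
            result.representative[ci] = select_representative(cluster, sim_table)
    return result


def select_representative(cluster, sim_table: SimilarityTable) -> str:
    """Member with maximal mean similarity to the others; ties by name."""
    members = sorted(cluster)
    if not members:
        raise ValueError("empty cluster")
    if len(members) == 1:
        return members[0]
    best = None
    for m in members:
        mean_sim = sum(sim_table.get(m, o, 0.0) for o in members if o != m) / (len(members) - 1)
        key = (-mean_sim, m)
        if best is None or key < best[0]:
            best = (key, m)
    return best[1]
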