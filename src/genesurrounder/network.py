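"""Interaction-network model: pathway union graphs, geodesic distances, neighborhoods.

The analysis operates on a single *global* undirected gene network obtained by
taking the graph union of individual pathway edge sets and keeping the largest
connected component (LCC).  Edges are untyped and undirected.  Nodes that are
on the network but not assayed in the expression data ("conduits") stay in the
graph and contribute to geodesic distances, but are never scored.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
from scipy.sparse.csgraph import shortest_path


class NetworkError(ValueError):
    """Raised for malformed or structurally invalid network input."""


@dataclass(frozen=True)
class GeneNetwork:
    """Undirected gene interaction graph plus the subset of assayed genes.

    Parameters
    ----------
    graph
        ``networkx.Graph`` over gene-identifier strings.  Self loops are
        forbidden; parallel edges cannot occur in a simple Graph.
    assayed
        Genes that are both on the network and measured in the expression
        data.  Must be a subset of the node set.
    """

    graph: nx.Graph
    assayed: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        loops = list(nx.selfloop_edges(self.graph))
        if loops:
            raise NetworkError(f"self-loops are not allowed: {loops[:3]}")
        extra = set(self.assayed) - set(self.graph.nodes)
        if extra:
            raise NetworkError(
                f"assayed genes not on the network: {sorted(extra)[:5]}"
            )
        object.__setattr__(self, "assayed", frozenset(self.assayed))

    @property
    def nodes(self) -> frozenset:
        return frozenset(self.graph.nodes)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def degree(self, gene: str) -> int:
        return self.graph.degree[gene]

    def is_connected(self) -> bool:
        return self.n_nodes > 0 and nx.is_connected(self.graph)

    def with_assayed(self, genes: Iterable[str]) -> "GeneNetwork":
        """Return a copy whose assayed mask is ``genes ∩ nodes``."""
        return GeneNetwork(self.graph, frozenset(genes) & self.nodes)


def build_union_graph(
    pathway_edge_lists: Iterable[Iterable[Sequence[str]]],
) -> GeneNetwork:
    """Merge pathway edge sets into one global network (graph union).

    Every link that occurs in at least one pathway becomes an edge of the
    global graph; duplicates collapse and self-loops are dropped.

    Raises
    ------
    NetworkError
        If no edges remain, or an edge record does not name exactly two
        endpoints (the offending record is included in the message).
    """
    g = nx.Graph()
    for pathway in pathway_edge_lists:
        for record in pathway:
            record = tuple(record)
            if len(record) != 2:
                raise NetworkError(f"malformed edge record: {record!r}")
            a, b = record
            if a == b:  # self-loop: drop
                continue
            g.add_edge(str(a), str(b))
    if g.number_of_edges() == 0:
        raise NetworkError("no edges")
    return GeneNetwork(g)


def read_edge_list(path) -> GeneNetwork:
    """Read a network from tab/whitespace-delimited text.

    Two columns per line are taken as an edge (``A<TAB>B``); three or more
    columns are parsed as SIF (``A<TAB>relation<TAB>B [C ...]``, relation
    ignored).  Lines starting with ``#`` and blank lines are skipped.
    """
    edges = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) == 2:
                edges.append((parts[0], parts[1]))
            elif len(parts) >= 3:
                edges.extend((parts[0], t) for t in parts[2:])
            else:
                raise NetworkError(
                    f"{path}:{lineno}: cannot parse edge line {line!r}"
                )
    return build_union_graph([edges])


def largest_connected_component(net: GeneNetwork) -> GeneNetwork:
    """Reduce to the largest connected component.

    Ties in component size are broken toward the component containing the
    lexicographically smallest node id, for determinism.
    """
    if net.n_nodes == 0:
        raise NetworkError("empty network")
    components = sorted(
        nx.connected_components(net.graph), key=lambda c: (-len(c), min(c))
    )
    keep = components[0]
    sub = net.graph.subgraph(keep).copy()
    return GeneNetwork(sub, frozenset(net.assayed) & keep)


class DistanceOracle:
    """All-pairs geodesic (hop-count) distances on a connected network.

    Distances satisfy ``d_ii = 0``, symmetry and the triangle inequality;
    ``diameter`` is the largest pairwise distance.
    """

    def __init__(self, net: GeneNetwork):
        if not net.is_connected():
            raise NetworkError(
                "network is disconnected; apply largest_connected_component first"
            )
        self.net = net
        self.nodes: list[str] = sorted(net.graph.nodes)
        self._index = {g: k for k, g in enumerate(self.nodes)}
        adj = nx.to_scipy_sparse_array(net.graph, nodelist=self.nodes, format="csr")
        dist = shortest_path(adj, method="D", directed=False, unweighted=True)
        self._d = dist.astype(np.int32)
        self.diameter: int = int(self._d.max())

    def distance(self, i: str, j: str) -> int:
        return int(self._d[self._index[i], self._index[j]])

    def distances_from(self, i: str) -> np.ndarray:
        """Distances from ``i`` to every node, aligned with ``self.nodes``."""
        return self._d[self._index[i]]

    def neighborhood(
        self, i: str, r: int, assayed_only: bool = False
    ) -> set[str]:
        """Genes ``j`` with ``0 < d_ij <= r`` (the center is excluded).

        With ``assayed_only`` the result is restricted to the assayed mask.
        """
        if not (1 <= r <= self.diameter):
            raise NetworkError(
                f"radius {r} out of range 1..{self.diameter}"
            )
        d = self.distances_from(i)
        sel = (d > 0) & (d <= r)
        nb = {self.nodes[k] for k in np.flatnonzero(sel)}
        if assayed_only:
            nb &= set(self.net.assayed)
        return nb


def geodesic_distances(net: GeneNetwork) -> DistanceOracle:
    """Build the all-pairs distance oracle for a connected network."""
    return DistanceOracle(net)
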