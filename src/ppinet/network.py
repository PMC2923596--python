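"""Undirected simple-graph container used throughout the package.

A protein-protein interaction network is represented microscopically by a
symmetric adjacency matrix c with c_ij = c_ji in {0, 1} and c_ii = 0.  The
:class:`InteractionNetwork` container enforces exactly that: string node
identifiers, unordered edges over distinct nodes, no parallel edges.  Isolated
nodes are first-class citizens because p(0) is a legitimate degree bin.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import networkx as nx
import numpy as np

__all__ = ["InteractionNetwork"]


@dataclass(frozen=True)
class InteractionNetwork:
    """An undirected simple graph over string node identifiers.

    Parameters
    ----------
    node_ids:
        Unique node identifiers, in a fixed (insertion) order.
    edges:
        Unordered pairs ``(i, j)`` of *node indices* with ``i < j``; each pair
        occurs at most once and never pairs a node with itself.
    """

    node_ids: tuple[str, ...]
    edges: frozenset[tuple[int, int]]
    _index: dict[str, int] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if len(self.node_ids) == 0:
            raise ValueError("a network needs at least one node")
        index = {name: i for i, name in enumerate(self.node_ids)}
        if len(index) != len(self.node_ids):
            raise ValueError("duplicate node identifiers")
        n = len(self.node_ids)
        for i, j in self.edges:
            if not (0 <= i < j < n):
                raise ValueError(f"edge ({i}, {j}) is not a sorted pair of distinct node indices")
        object.__setattr__(self, "_index", index)

    # -- constructors ------------------------------------------------------

    @classmethod
    def from_pairs(
        cls,
        pairs: Iterable[tuple[str, str]],
        extra_nodes: Iterable[str] = (),
    ) -> "InteractionNetwork":
        """Build a network from (possibly redundant) identifier pairs.

        Self-pairs are dropped and duplicates (in either orientation)
        collapse to a single edge, mirroring the symmetrisation of raw
        interaction records.
        """
        order: dict[str, None] = {}
        raw: list[tuple[str, str]] = []
        for a, b in pairs:
            order.setdefault(a)
            order.setdefault(b)
            raw.append((a, b))
        for name in extra_nodes:
            order.setdefault(name)
        nodes = tuple(order)
        index = {name: i for i, name in enumerate(nodes)}
        edges = set()
        for a, b in raw:
            i, j = index[a], index[b]
            if i == j:
                continue
            edges.add((min(i, j), max(i, j)))
        return cls(nodes, frozenset(edges))

    @classmethod
    def from_networkx(cls, graph: nx.Graph) -> "InteractionNetwork":
        nodes = tuple(str(v) for v in graph.nodes())
        index = {name: i for i, name in enumerate(nodes)}
        edges = set()
        for a, b in graph.edges():
            i, j = index[str(a)], index[str(b)]
            if i != j:
                edges.add((min(i, j), max(i, j)))
        return cls(nodes, frozenset(edges))

    # -- basic queries -----------------------------------------------------

    @property
    def N(self) -> int:
        return len(self.node_ids)

    @property
    def E(self) -> int:
        return len(self.edges)

    def degree_sequence(self) -> np.ndarray:
        """Degree of every node, in node order."""
        deg = np.zeros(self.N, dtype=np.int64)
        for i, j in self.edges:
            deg[i] += 1
            deg[j] += 1
        return deg

    @property
    def mean_degree(self) -> float:
        return 2.0 * self.E / self.N

    def edge_array(self) -> np.ndarray:
        """Edges as an (E, 2) int64 array of node indices (sorted rows)."""
        if self.E == 0:
            return np.empty((0, 2), dtype=np.int64)
        return np.array(sorted(self.edges), dtype=np.int64)

    def edge_names(self) -> Iterator[tuple[str, str]]:
        for i, j in sorted(self.edges):
            yield self.node_ids[i], self.node_ids[j]

    def has_edge(self, a: str, b: str) -> bool:
        i, j = self._index[a], self._index[b]
        return (min(i, j), max(i, j)) in self.edges

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.node_ids)
        g.add_edges_from((self.node_ids[i], self.node_ids[j]) for i, j in self.edges)
        return g

    # -- derived networks --------------------------------------------------

    def with_edges(self, edges: Iterable[tuple[int, int]]) -> "InteractionNetwork":
        """Same node set, different edge set (indices)."""
        norm = frozenset((min(i, j), max(i, j)) for i, j in edges if i != j)
        return InteractionNetwork(self.node_ids, norm)

    def induced_subgraph(self, keep: Sequence[int]) -> "InteractionNetwork":
        """Subgraph induced by the node *indices* in ``keep`` (order kept).

        Nodes isolated by the removal stay in the network: they move
        probability mass to the degree-zero bin, which is part of the
        honest characterisation of a sub-sampled network.
        """
        keep = list(dict.fromkeys(int(k) for k in keep))
        remap = {old: new for new, old in enumerate(keep)}
        nodes = tuple(self.node_ids[i] for i in keep)
        edges = frozenset(
            (min(remap[i], remap[j]), max(remap[i], remap[j]))
            for i, j in self.edges
            if i in remap and j in remap
        )
        return InteractionNetwork(nodes, edges)

    def relabelled(self, order: Sequence[str]) -> "InteractionNetwork":
        """Reorder nodes; the graph itself (node set + edge set) is unchanged."""
        if set(order) != set(self.node_ids) or len(order) != self.N:
            raise ValueError("order must be a permutation of the node identifiers")
        remap = {self._index[name]: pos for pos, name in enumerate(order)}
        edges = frozenset(
            (min(remap[i], remap[j]), max(remap[i], remap[j])) for i, j in self.edges
        )
        return InteractionNetwork(tuple(order), edges)

    def same_node_set(self, other: "InteractionNetwork") -> bool:
        return set(self.node_ids) == set(other.node_ids)

    def edge_name_set(self) -> frozenset[frozenset[str]]:
        return frozenset(frozenset((a, b)) for a, b in self.edge_names())
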