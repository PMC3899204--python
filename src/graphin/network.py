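"""Undirected simple interaction networks over gene identifiers.

The package's graph container is a thin wrapper around :class:`networkx.Graph`
that enforces the invariants the counting machinery relies on (no self-loops,
no parallel edges, string-identified nodes) and exposes fast set-based
adjacency lookups.
"""

from __future__ import annotations

import logging
from typing import Iterable, Iterator

import networkx as nx

logger = logging.getLogger(__name__)


class UnknownGeneError(KeyError):
    """Raised when an operation refers to a gene absent from the network."""

    def __init__(self, gene: str):
        super().__init__(gene)
        self.gene = gene

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"gene {self.gene!r} is not a node of the network"


class InteractionNetwork:
    """An undirected, unweighted simple graph of gene/protein interactions.

    Parameters
    ----------
    edges:
        Iterable of 2-tuples of gene identifiers. Self-loops and duplicate
        edges are dropped (with a logged count), mirroring how raw
        protein-protein interaction downloads are typically cleaned.
    nodes:
        Optional extra nodes to include even if isolated.
    """

    def __init__(self, edges: Iterable[tuple[str, str]] = (),
                 nodes: Iterable[str] = ()):
        g = nx.Graph()
        n_self = 0
        n_dup = 0
        for u, v in edges:
            u, v = str(u), str(v)
            if u == v:
                n_self += 1
                continue
            if g.has_edge(u, v):
                n_dup += 1
                continue
            g.add_edge(u, v)
        g.add_nodes_from(str(n) for n in nodes)
        if n_self or n_dup:
            logger.warning("dropped %d self-loop(s) and %d duplicate edge(s)",
                           n_self, n_dup)
        self._g = g
        self._adj: dict[str, frozenset[str]] = {
            n: frozenset(g.neighbors(n)) for n in g.nodes
        }
        # memo for pairwise interaction vectors, keyed (source, target)
        self._pair_cache: dict[tuple[str, str], object] = {}

    # -- basic accessors -------------------------------------------------
    @classmethod
    def from_networkx(cls, g: nx.Graph) -> "InteractionNetwork":
        return cls(g.edges(), g.nodes())

    def to_networkx(self) -> nx.Graph:
        return self._g.copy()

    @property
    def graph(self) -> nx.Graph:
        return self._g

    @property
    def nodes(self) -> frozenset[str]:
        return frozenset(self._g.nodes)

    @property
    def edges(self) -> frozenset[frozenset[str]]:
        return frozenset(frozenset(e) for e in self._g.edges)

    def __contains__(self, gene: str) -> bool:
        return gene in self._g

    def __len__(self) -> int:
        return self._g.number_of_nodes()

    def __iter__(self) -> Iterator[str]:
        return iter(self._g.nodes)

    def number_of_edges(self) -> int:
        return self._g.number_of_edges()

    def degree(self, gene: str) -> int:
        self._require(gene)
        return len(self._adj[gene])

    def neighbors(self, gene: str) -> frozenset[str]:
        self._require(gene)
        return self._adj[gene]

    def a(self, i: str, j: str) -> int:
        """Adjacency-matrix entry: 1 iff the edge ``{i, j}`` exists."""
        self._require(i)
        self._require(j)
        return 1 if j in self._adj[i] else 0

    def _require(self, gene: str) -> None:
        if gene not in self._g:
            raise UnknownGeneError(gene)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, InteractionNetwork):
            return NotImplemented
        return self.nodes == other.nodes and self.edges == other.edges

    def __hash__(self):  # mutable cache inside; identity hash is fine
        return id(self)

    def __repr__(self) -> str:
        return (f"InteractionNetwork(n_nodes={len(self)}, "
                f"n_edges={self.number_of_edges()})")
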