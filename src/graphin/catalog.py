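"""Graphlet, orbit and interaction-isomer catalogs.

Graphlets are the connected, pairwise non-isomorphic graphs on 2-4 vertices.
There are nine of them (G0-G8) carrying 15 automorphism orbits (0-14), in the
conventional order: G0 the edge; G1 the 3-path; G2 the triangle; G3 the
4-path; G4 the 3-star; G5 the 4-cycle; G6 the paw (triangle plus pendant);
G7 the diamond (K4 minus an edge); G8 the complete graph K4.

A *graphlet-interaction isomer* is a graphlet together with an ordered pair
of marked vertices, considered up to automorphisms of the graphlet. Marking
an ordered pair makes the relation directional: the 3-path with the source
at its middle is a different isomer from the 3-path with the target at its
middle. Enumeration yields exactly 28 isomers I1-I28; reversing the marked
pair is an involution ``sym`` on {1..28}.

Canonical order
---------------
The catalog orders isomers by graphlet index first and, within a graphlet,
by (target orbit, source orbit, marked-pair adjacency — adjacent first).
This anchors the five small-graphlet isomers:

=====  ========  =====================================================
index  graphlet  marked pair
=====  ========  =====================================================
I1     G0        the edge itself
I2     G1        source and target at the two ends of the 3-path
I3     G1        source at the middle, target at an end
I4     G1        source at an end, target at the middle
I5     G2        any ordered pair of triangle vertices
=====  ========  =====================================================

so that, for an adjacent pair (i, j), I3 counts the third nodes attached to
i only and I4 those attached to j only, and ``sym`` swaps I3 with I4.

Everything here is enumerated from first principles at import cost (a few
milliseconds); nothing is hard-coded beyond the ordering convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from itertools import combinations, permutations
from typing import Sequence

__all__ = [
    "Graphlet",
    "Isomer",
    "GraphletCatalog",
    "IsomerCatalog",
    "build_catalogs",
    "N_ISOMERS",
    "N_ORBITS",
    "N_GRAPHLETS",
]

N_GRAPHLETS = 9
N_ORBITS = 15
N_ISOMERS = 28

# fixed bit layout for edge masks of graphs on 0..s-1
_PAIRS: dict[int, list[tuple[int, int]]] = {
    s: list(combinations(range(s), 2)) for s in (2, 3, 4)
}
_PAIR_BIT: dict[int, dict[frozenset[int], int]] = {
    s: {frozenset(pq): b for b, pq in enumerate(ps)} for s, ps in _PAIRS.items()
}


def _mask(edges, s: int) -> int:
    m = 0
    bit = _PAIR_BIT[s]
    for e in edges:
        m |= 1 << bit[frozenset(e)]
    return m


def _relabel_mask(edges, s: int, mapping: dict[int, int]) -> int:
    return _mask(((mapping[u], mapping[v]) for u, v in edges), s)


def graph_certificate(edges, s: int) -> int:
    """Canonical form of an unlabeled graph on ``s`` vertices."""
    edges = list(edges)
    return min(
        _relabel_mask(edges, s, dict(zip(range(s), perm)))
        for perm in permutations(range(s))
    )


def marked_pair_certificate(edges, s: int, u: int, v: int) -> int:
    """Canonical form of a graph with an ordered marked pair (u -> 0, v -> 1)."""
    edges = list(edges)
    others = [w for w in range(s) if w not in (u, v)]
    best = None
    for perm in permutations(range(2, s)):
        mapping = {u: 0, v: 1, **dict(zip(others, perm))}
        m = _relabel_mask(edges, s, mapping)
        if best is None or m < best:
            best = m
    return best


def marked_node_certificate(edges, s: int, u: int) -> int:
    """Canonical form of a graph with one marked vertex (u -> 0)."""
    edges = list(edges)
    others = [w for w in range(s) if w != u]
    best = None
    for perm in permutations(range(1, s)):
        mapping = {u: 0, **dict(zip(others, perm))}
        m = _relabel_mask(edges, s, mapping)
        if best is None or m < best:
            best = m
    return best


@dataclass(frozen=True)
class Graphlet:
    """One of the nine connected graphs on 2-4 vertices."""

    index: int                      # 0..8, i.e. G0..G8
    n: int                          # vertex count
    edges: tuple[tuple[int, int], ...]
    orbit_of: tuple[int, ...]       # vertex -> global orbit label (0..14)

    @property
    def degrees(self) -> tuple[int, ...]:
        deg = [0] * self.n
        for u, v in self.edges:
            deg[u] += 1
            deg[v] += 1
        return tuple(deg)

    @property
    def name(self) -> str:
        return f"G{self.index}"


@dataclass(frozen=True)
class Isomer:
    """A graphlet with an ordered marked vertex pair, up to automorphism."""

    index: int                      # 1..28, i.e. I1..I28
    graphlet: int                   # G index 0..8
    n: int                          # vertex count of the graphlet
    source_orbit: int               # global orbit of the source mark
    target_orbit: int               # global orbit of the target mark
    adjacent: bool                  # are the marked vertices adjacent?
    source_degree: int
    target_degree: int
    certificate: int = field(repr=False)
    rep: tuple[tuple[tuple[int, int], ...], int, int] = field(repr=False)

    @property
    def name(self) -> str:
        return f"I{self.index}"


class GraphletCatalog:
    """The nine 2-4-node graphlets and their 15 automorphism orbits."""

    def __init__(self, graphlets: Sequence[Graphlet]):
        self.graphlets: tuple[Graphlet, ...] = tuple(graphlets)
        self.n_orbits = 1 + max(o for g in graphlets for o in g.orbit_of)
        # single-marked certificate -> global orbit label
        self._orbit_by_cert: dict[tuple[int, int], int] = {}
        for g in self.graphlets:
            for u in range(g.n):
                cert = marked_node_certificate(g.edges, g.n, u)
                self._orbit_by_cert[(g.n, cert)] = g.orbit_of[u]

    def __len__(self) -> int:
        return len(self.graphlets)

    def __iter__(self):
        return iter(self.graphlets)

    def __getitem__(self, i: int) -> Graphlet:
        return self.graphlets[i]

    def orbit_of_occurrence(self, n: int, cert: int) -> int | None:
        """Global orbit for a marked occurrence given its certificate."""
        return self._orbit_by_cert.get((n, cert))


class IsomerCatalog:
    """The 28 graphlet-interaction isomers and their reversal involution."""

    def __init__(self, isomers: Sequence[Isomer], sym: Sequence[int],
                 graphlet_catalog: GraphletCatalog):
        self.isomers: tuple[Isomer, ...] = tuple(isomers)
        #: sym[k-1] = index (1-based) of the isomer obtained by reversing I_k
        self.sym: tuple[int, ...] = tuple(sym)
        self.graphlets = graphlet_catalog
        self._by_cert: dict[tuple[int, int], int] = {
            (iso.n, iso.certificate): iso.index for iso in self.isomers
        }

    def __len__(self) -> int:
        return len(self.isomers)

    def __iter__(self):
        return iter(self.isomers)

    def __getitem__(self, k: int) -> Isomer:
        """1-based lookup: catalog[3] is I3."""
        if not 1 <= k <= len(self.isomers):
            raise IndexError(f"isomer index {k} outside 1..{len(self.isomers)}")
        return self.isomers[k - 1]

    def classify(self, n: int, cert: int) -> int | None:
        """Isomer index (1-based) for a marked occurrence, or None if the
        configuration is not a connected graphlet."""
        return self._by_cert.get((n, cert))

    def reverse_index(self, k: int) -> int:
        return self.sym[k - 1]

    def small_indices(self, max_nodes: int = 3) -> list[int]:
        """1-based indices of isomers from graphlets with <= ``max_nodes``."""
        return [iso.index for iso in self.isomers if iso.n <= max_nodes]

    def to_table(self) -> "list[dict]":
        """Rows describing the catalog, suitable for TSV serialization."""
        return [
            {
                "isomer": iso.name,
                "graphlet": f"G{iso.graphlet}",
                "nodes": iso.n,
                "source_orbit": iso.source_orbit,
                "target_orbit": iso.target_orbit,
                "marked_pair_adjacent": int(iso.adjacent),
                "sym_partner": f"I{self.sym[iso.index - 1]}",
            }
            for iso in self.isomers
        ]


def _connected(edges, s: int) -> bool:
    if s == 1:
        return True
    adj = {u: set() for u in range(s)}
    for u, v in edges:
        adj[u].add(v)
        adj[v].add(u)
    seen = {0}
    stack = [0]
    while stack:
        u = stack.pop()
        for w in adj[u]:
            if w not in seen:
                seen.add(w)
                stack.append(w)
    return len(seen) == s


def _automorphisms(edges, s: int):
    mask = _mask(edges, s)
    edges = list(edges)
    return [
        perm for perm in permutations(range(s))
        if _relabel_mask(edges, s, dict(zip(range(s), perm))) == mask
    ]


def _enumerate_graphlets() -> list[Graphlet]:
    reps: list[tuple[int, tuple[tuple[int, int], ...]]] = []
    seen: set[tuple[int, int]] = set()
    for s in (2, 3, 4):
        all_pairs = _PAIRS[s]
        for r in range(s - 1, len(all_pairs) + 1):
            for edges in combinations(all_pairs, r):
                if not _connected(edges, s):
                    continue
                cert = graph_certificate(edges, s)
                if (s, cert) in seen:
                    continue
                seen.add((s, cert))
                reps.append((s, edges))

    def sort_key(item):
        s, edges = item
        deg = [0] * s
        for u, v in edges:
            deg[u] += 1
            deg[v] += 1
        return (s, len(edges), tuple(sorted(deg, reverse=True)))

    reps.sort(key=sort_key)

    graphlets: list[Graphlet] = []
    next_orbit = 0
    for gi, (s, edges) in enumerate(reps):
        autos = _automorphisms(edges, s)
        # vertex orbits under the automorphism group
        orbit_sets: list[set[int]] = []
        assigned: set[int] = set()
        for u in range(s):
            if u in assigned:
                continue
            orb = {perm[u] for perm in autos}
            orbit_sets.append(orb)
            assigned |= orb
        deg = [0] * s
        for u, v in edges:
            deg[u] += 1
            deg[v] += 1
        # within a graphlet, orbits get ascending labels by vertex degree;
        # on 2-4 nodes distinct orbits never share a degree
        orbit_sets.sort(key=lambda orb: deg[next(iter(orb))])
        degs_of_orbits = [deg[next(iter(orb))] for orb in orbit_sets]
        assert len(set(degs_of_orbits)) == len(orbit_sets)
        orbit_of = [0] * s
        for orb in orbit_sets:
            for u in orb:
                orbit_of[u] = next_orbit
            next_orbit += 1
        graphlets.append(
            Graphlet(index=gi, n=s, edges=tuple(edges),
                     orbit_of=tuple(orbit_of))
        )
    return graphlets


def _enumerate_isomers(gcat: GraphletCatalog) -> IsomerCatalog:
    entries: list[Isomer] = []
    per_graphlet: list[list[Isomer]] = []
    for g in gcat:
        classes: dict[int, tuple[int, int]] = {}
        adj = {frozenset(e) for e in g.edges}
        deg = g.degrees
        for u, v in permutations(range(g.n), 2):
            cert = marked_pair_certificate(g.edges, g.n, u, v)
            classes.setdefault(cert, (u, v))
        rows = []
        for cert, (u, v) in classes.items():
            rows.append(Isomer(
                index=0,  # assigned after global sorting
                graphlet=g.index,
                n=g.n,
                source_orbit=g.orbit_of[u],
                target_orbit=g.orbit_of[v],
                adjacent=frozenset((u, v)) in adj,
                source_degree=deg[u],
                target_degree=deg[v],
                certificate=cert,
                rep=(g.edges, u, v),
            ))
        keys = [(r.target_orbit, r.source_orbit, 0 if r.adjacent else 1)
                for r in rows]
        assert len(set(keys)) == len(rows), "ambiguous within-graphlet order"
        rows = [r for _, r in sorted(zip(keys, rows), key=lambda t: t[0])]
        per_graphlet.append(rows)

    k = 1
    for rows in per_graphlet:
        for r in rows:
            entries.append(Isomer(**{**r.__dict__, "index": k}))
            k += 1

    by_cert = {(iso.n, iso.certificate): iso.index for iso in entries}
    sym: list[int] = []
    for iso in entries:
        edges, u, v = iso.rep
        rev = marked_pair_certificate(edges, iso.n, v, u)
        sym.append(by_cert[(iso.n, rev)])
    assert all(sym[sym[k - 1] - 1] == k for k in range(1, len(entries) + 1))
    return IsomerCatalog(entries, sym, gcat)


@lru_cache(maxsize=1)
def build_catalogs() -> tuple[GraphletCatalog, IsomerCatalog]:
    """Enumerate the graphlet and interaction-isomer catalogs.

    Returns the pair ``(GraphletCatalog, IsomerCatalog)``; the result is
    cached, so repeated calls are free and share the lookup tables.
    """
    gcat = GraphletCatalog(_enumerate_graphlets())
    icat = _enumerate_isomers(gcat)
    assert len(gcat) == N_GRAPHLETS
    assert gcat.n_orbits == N_ORBITS
    assert len(icat) == N_ISOMERS
    return gcat, icat
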