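"""Counting graphlet signatures and pairwise graphlet-interaction vectors.

All counting uses the induced-subgraph convention: an occurrence of a
graphlet on a vertex subset requires the induced subgraph on that subset to
equal the graphlet — absent edges are forbidden, not ignored. Three routes
are provided:

``oracle_count``
    Exhaustive enumeration of every 2/3/4-vertex subset containing the
    marked pair. Exact but exponential in spirit; it refuses networks with
    more than 15 nodes and exists to validate the other two routes.

``count_interaction``
    The definitional traversal: one loop over third nodes ``l`` for 3-node
    isomers and one over unordered pairs ``{l, m}`` for 4-node isomers,
    classifying each configuration by its adjacency pattern. O(n^2) per
    gene pair.

``count_interaction_fast``
    The production path. 3-node counts come from closed-form neighbor-set
    arithmetic (common-neighbor intersections and set differences, the
    adjacency-row inner products of the method); 4-node counts restrict the
    ``l``/``m`` candidates to the relevant neighborhoods, which is
    O(sum-of-squared-degrees)-ish on sparse graphs. Results are exactly
    equal to ``count_interaction``.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np

from .catalog import (
    IsomerCatalog,
    GraphletCatalog,
    N_ISOMERS,
    build_catalogs,
    marked_node_certificate,
    marked_pair_certificate,
)
from .network import InteractionNetwork, UnknownGeneError

__all__ = [
    "InteractionVector",
    "GraphletSignature",
    "count_interaction",
    "count_interaction_fast",
    "oracle_count",
    "pair_counts",
    "signature",
    "symmetry_check",
]

_ORACLE_MAX_NODES = 15


@dataclass(frozen=True)
class InteractionVector:
    """The 28 isomer counts N_ij(I_1..I_28) for an ordered gene pair."""

    source: str
    target: str
    counts: np.ndarray  # shape (28,), non-negative ints

    def __post_init__(self):
        c = np.asarray(self.counts, dtype=np.int64)
        object.__setattr__(self, "counts", c)
        assert c.shape == (N_ISOMERS,)

    def __getitem__(self, k: int) -> int:
        """1-based access: vec[2] is the I2 count."""
        return int(self.counts[k - 1])

    def restrict(self, indices) -> np.ndarray:
        """Counts for a subset of 1-based isomer indices, in that order."""
        return self.counts[[k - 1 for k in indices]]


@dataclass(frozen=True)
class GraphletSignature:
    """Per-orbit occurrence counts (the graphlet degree vector) of one gene."""

    gene: str
    orbit_counts: np.ndarray  # shape (15,)

    def __post_init__(self):
        c = np.asarray(self.orbit_counts, dtype=np.int64)
        object.__setattr__(self, "orbit_counts", c)

    def __getitem__(self, orbit: int) -> int:
        return int(self.orbit_counts[orbit])


def _check_pair(net: InteractionNetwork, i: str, j: str) -> None:
    if i not in net:
        raise UnknownGeneError(i)
    if j not in net:
        raise UnknownGeneError(j)
    if i == j:
        raise ValueError(f"ordered pair requires two distinct genes, got {i!r} twice")


def _subset_cert(net: InteractionNetwork, ordered: tuple[str, ...]) -> int:
    """Marked-pair certificate of the induced subgraph on ``ordered`` nodes,
    with ordered[0] as source and ordered[1] as target."""
    s = len(ordered)
    idx = {g: p for p, g in enumerate(ordered)}
    edges = [
        (idx[u], idx[v])
        for u, v in combinations(ordered, 2)
        if net.a(u, v)
    ]
    return marked_pair_certificate(edges, s, 0, 1)


def oracle_count(net: InteractionNetwork, i: str, j: str,
                 catalog: IsomerCatalog | None = None) -> InteractionVector:
    """Brute-force isomer counts via exhaustive subset enumeration.

    Test oracle only: refuses networks with more than 15 nodes.
    """
    _check_pair(net, i, j)
    if len(net) > _ORACLE_MAX_NODES:
        raise ValueError(
            f"oracle_count is a test oracle; network has {len(net)} > "
            f"{_ORACLE_MAX_NODES} nodes"
        )
    catalog = catalog if catalog is not None else build_catalogs()[1]
    counts = np.zeros(N_ISOMERS, dtype=np.int64)
    others = sorted(net.nodes - {i, j})
    for extra in range(0, 3):
        for combo in combinations(others, extra):
            cert = _subset_cert(net, (i, j) + combo)
            k = catalog.classify(2 + extra, cert)
            if k is not None:
                counts[k - 1] += 1
    return InteractionVector(i, j, counts)


def count_interaction(net: InteractionNetwork, i: str, j: str,
                      catalog: IsomerCatalog | None = None) -> InteractionVector:
    """Isomer counts by the definitional traversal over third/fourth nodes."""
    _check_pair(net, i, j)
    catalog = catalog if catalog is not None else build_catalogs()[1]
    counts = np.zeros(N_ISOMERS, dtype=np.int64)
    cert2 = marked_pair_certificate([(0, 1)] if net.a(i, j) else [], 2, 0, 1)
    k = catalog.classify(2, cert2)
    if k is not None:
        counts[k - 1] += 1
    others = [g for g in net.nodes if g not in (i, j)]
    for l in others:
        k = catalog.classify(3, _subset_cert(net, (i, j, l)))
        if k is not None:
            counts[k - 1] += 1
    for l, m in combinations(others, 2):
        k = catalog.classify(4, _subset_cert(net, (i, j, l, m)))
        if k is not None:
            counts[k - 1] += 1
    return InteractionVector(i, j, counts)


def _three_node_index_map(catalog: IsomerCatalog) -> dict[str, int]:
    """Map structural roles of the 3-node isomers to 1-based indices."""
    roles: dict[str, int] = {}
    for iso in catalog:
        if iso.n != 3:
            continue
        if not iso.adjacent:
            roles["ends"] = iso.index            # path, both marks at ends
        elif iso.source_degree == 2 and iso.target_degree == 2:
            roles["triangle"] = iso.index
        elif iso.source_degree == 2:
            roles["source_middle"] = iso.index   # third node hangs off source
        else:
            roles["target_middle"] = iso.index   # third node hangs off target
    assert len(roles) == 4
    return roles


def _four_node_table(catalog: IsomerCatalog) -> np.ndarray:
    """64-entry lookup: adjacency bitmask of (i,j,l,m) -> isomer index or 0.

    Bit layout: 0:ij 1:il 2:im 3:jl 4:jm 5:lm. The marked-pair certificate
    canonicalizes over the unordered {l, m}, so either ordering of the two
    extra nodes maps to the same isomer.
    """
    cached = getattr(catalog, "_four_table", None)
    if cached is not None:
        return cached
    bit_edges = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]
    table = np.zeros(64, dtype=np.int64)
    for mask in range(64):
        edges = [bit_edges[b] for b in range(6) if mask >> b & 1]
        k = catalog.classify(4, marked_pair_certificate(edges, 4, 0, 1))
        table[mask] = k if k is not None else 0
    catalog._four_table = table
    return table


def count_interaction_fast(net: InteractionNetwork, i: str, j: str,
                           catalog: IsomerCatalog | None = None) -> InteractionVector:
    """Isomer counts via neighbor-set arithmetic and neighborhood-restricted
    enumeration; exactly equal to :func:`count_interaction`."""
    _check_pair(net, i, j)
    catalog = catalog if catalog is not None else build_catalogs()[1]
    counts = np.zeros(N_ISOMERS, dtype=np.int64)
    ni = net.neighbors(i)
    nj = net.neighbors(j)
    aij = 1 if j in ni else 0

    cert2 = marked_pair_certificate([(0, 1)] if aij else [], 2, 0, 1)
    k2 = catalog.classify(2, cert2)
    if k2 is not None:
        counts[k2 - 1] += 1

    # 3-node isomers in closed form from adjacency rows
    roles = _three_node_index_map(catalog)
    common = (ni & nj) - {i, j}
    if aij:
        counts[roles["triangle"] - 1] = len(common)
        counts[roles["source_middle"] - 1] = len(ni - nj - {j})
        counts[roles["target_middle"] - 1] = len(nj - ni - {i})
    else:
        counts[roles["ends"] - 1] = len(common)

    # 4-node isomers: {l, m} with the induced subgraph connected requires at
    # least one of l, m adjacent to {i, j}; the other is then in the joint
    # neighborhood of {i, j, l}. Classification is a precomputed bitmask
    # lookup over the six adjacency entries.
    table = _four_node_table(catalog)
    frontier = sorted((ni | nj) - {i, j})
    order = {g: p for p, g in enumerate(frontier)}
    for l in frontier:
        nl = net.neighbors(l)
        base = aij | (1 << 1 if l in ni else 0) | (1 << 3 if l in nj else 0)
        pos_l = order[l]
        for m in (ni | nj | nl) - {i, j, l}:
            pos_m = order.get(m)
            if pos_m is not None and pos_m <= pos_l:
                continue  # unordered pair already visited
            mask = (base
                    | (1 << 2 if m in ni else 0)
                    | (1 << 4 if m in nj else 0)
                    | (1 << 5 if m in nl else 0))
            k = table[mask]
            if k:
                counts[k - 1] += 1
    return InteractionVector(i, j, counts)


def pair_counts(net: InteractionNetwork, i: str, j: str,
                catalog: IsomerCatalog | None = None) -> InteractionVector:
    """Memoized fast counts for an ordered pair.

    The reverse direction is derived through the ``sym`` involution instead
    of being recounted, and both directions share one cache entry on the
    network instance.
    """
    catalog = catalog if catalog is not None else build_catalogs()[1]
    cache = net._pair_cache
    hit = cache.get((i, j))
    if hit is not None:
        return hit
    rev = cache.get((j, i))
    if rev is not None:
        vec = reverse_vector(rev, catalog)
    else:
        vec = count_interaction_fast(net, i, j, catalog)
    cache[(i, j)] = vec
    return vec


def reverse_vector(vec: InteractionVector,
                   catalog: IsomerCatalog) -> InteractionVector:
    """The vector for the reversed ordered pair, via the sym involution."""
    rc = np.empty_like(vec.counts)
    for k in range(1, N_ISOMERS + 1):
        rc[catalog.sym[k - 1] - 1] = vec.counts[k - 1]
    return InteractionVector(vec.target, vec.source, rc)


def symmetry_check(v_ij: InteractionVector, v_ji: InteractionVector,
                   catalog: IsomerCatalog | None = None) -> bool:
    """True iff N_ij(I_k) == N_ji(I_sym(k)) for every isomer k."""
    catalog = catalog if catalog is not None else build_catalogs()[1]
    return all(
        v_ij[k] == v_ji[catalog.sym[k - 1]]
        for k in range(1, N_ISOMERS + 1)
    )


def _connected_subsets_through(net: InteractionNetwork, i: str,
                               max_size: int = 4):
    """All vertex subsets of size 2..max_size containing ``i`` whose induced
    subgraph is connected, by frontier expansion."""
    seen: set[frozenset[str]] = set()
    out: list[frozenset[str]] = []

    def grow(current: frozenset[str]):
        if len(current) >= 2:
            if current in seen:
                return
            seen.add(current)
            out.append(current)
        if len(current) == max_size:
            return
        frontier = set()
        for u in current:
            frontier |= net.neighbors(u)
        for w in frontier - current:
            grow(current | {w})

    grow(frozenset({i}))
    return out


def signature(net: InteractionNetwork, i: str,
              catalog: GraphletCatalog | None = None) -> GraphletSignature:
    """Graphlet signature (15 orbit counts) of gene ``i``.

    ``orbit_counts[o]`` is the number of induced graphlet occurrences in
    which ``i`` occupies automorphism orbit ``o``; orbit 0 equals the degree.
    """
    if i not in net:
        raise UnknownGeneError(i)
    catalog = catalog if catalog is not None else build_catalogs()[0]
    counts = np.zeros(catalog.n_orbits, dtype=np.int64)
    for subset in _connected_subsets_through(net, i):
        ordered = (i,) + tuple(sorted(subset - {i}))
        s = len(ordered)
        idx = {g: p for p, g in enumerate(ordered)}
        edges = [(idx[u], idx[v]) for u, v in combinations(ordered, 2)
                 if net.a(u, v)]
        cert = marked_node_certificate(edges, s, 0)
        orbit = catalog.orbit_of_occurrence(s, cert)
        if orbit is not None:
            counts[orbit] += 1
    return GraphletSignature(i, counts)
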