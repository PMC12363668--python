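"""Isomorph-free generation of small connected graphs, canonical codes,
random fixtures, and graph edit distance.

The exhaustive analyses ("all connected undirected graphs on N vertices")
need exactly one representative per isomorphism class.  Representatives are
generated by vertex augmentation: every connected graph on ``n`` vertices
arises from a connected graph on ``n - 1`` vertices (delete any
non-cut-vertex) by adding one vertex attached to a non-empty neighbour set,
so extending each representative by every non-empty attachment subset and
de-duplicating by canonical code is exhaustive and isomorph-free.

Canonical codes use igraph's BLISS canonical labelling; the test suite
cross-checks them against brute-force permutation search at small N.
"""

from __future__ import annotations

from typing import Iterator

import igraph as ig
import numpy as np

from .errors import CapacityError, InvalidParameterError, UnsupportedInputError
from .graph import Graph

__all__ = [
    "canonical_code",
    "enumerate_connected_graphs",
    "random_connected_graph",
    "graph_edit_distance",
]

CANONICAL_MAX_N = 10
ENUMERATION_MAX_N = 8
EDIT_DISTANCE_MAX_N = 8

#: connected-graph class counts for N = 1..8 (OEIS A001349)
CONNECTED_GRAPH_COUNTS = (1, 1, 2, 6, 21, 112, 853, 11117)


def _require_simple_undirected(g: Graph, op: str) -> None:
    if not g.is_undirected():
        raise UnsupportedInputError(f"{op} supports undirected graphs only")
    if g.has_self_loops():
        raise UnsupportedInputError(f"{op} does not support self-loops")


def _canon_edges(n: int, pairs: list[tuple[int, int]]) -> bytes:
    """Canonical byte code from an unordered edge list via BLISS."""
    G = ig.Graph(n, pairs)
    perm = G.canonical_permutation()
    H = G.permute_vertices(perm)
    edges = sorted((min(e.tuple), max(e.tuple)) for e in H.es)
    return bytes([n]) + b"".join(bytes((u, v)) for u, v in edges)


def canonical_code(g: Graph) -> bytes:
    """A byte string shared by two graphs iff they are isomorphic.

    Permutation-invariant by construction (canonical relabelling);
    undirected simple graphs with ``N <= 10`` only.
    """
    _require_simple_undirected(g, "canonical_code")
    if g.n_vertices > CANONICAL_MAX_N:
        raise CapacityError(f"canonical codes supported up to N={CANONICAL_MAX_N}")
    return _canon_edges(g.n_vertices, [tuple(e) for e in g.undirected_edges()])


def enumerate_connected_graphs(N: int) -> Iterator[Graph]:
    """Yield one representative per isomorphism class of connected
    undirected simple graphs on ``N`` vertices, in canonical-code order.

    Generation is by canonical augmentation from the (N-1)-vertex classes;
    ``N <= 8`` (11,117 classes at N = 8).
    """
    if N < 1:
        raise InvalidParameterError(f"need N >= 1, got {N}")
    if N > ENUMERATION_MAX_N:
        raise CapacityError(f"enumeration supported up to N={ENUMERATION_MAX_N}")
    level: list[list[tuple[int, int]]] = [[]]  # K1 as an edge list on 1 vertex
    for n in range(2, N + 1):
        seen: dict[bytes, list[tuple[int, int]]] = {}
        new_v = n - 1
        for parent in level:
            for subset in range(1, 1 << (n - 1)):
                child = list(parent)
                for u in range(n - 1):
                    if subset >> u & 1:
                        child.append((u, new_v))
                code = _canon_edges(n, child)
                if code not in seen:
                    seen[code] = child
        level = [seen[code] for code in sorted(seen)]
    if N == 1:
        yield Graph(1, [])
        return
    for edges in level:
        yield Graph(N, edges, undirected=True)


def random_connected_graph(N: int, edge_probability: float, rng: np.random.Generator) -> Graph:
    """Erdős–Rényi ``G(N, p)`` resampled until connected.

    A test-fixture generator, not an object of study; fails after 10^4
    unsuccessful draws.
    """
    if N < 2:
        raise InvalidParameterError(f"need N >= 2, got {N}")
    if not 0 < edge_probability <= 1:
        raise InvalidParameterError(f"edge probability must be in (0, 1], got {edge_probability}")
    pairs = [(u, v) for u in range(N) for v in range(u + 1, N)]
    for _ in range(10_000):
        mask = rng.random(len(pairs)) < edge_probability
        g = Graph(N, [p for p, m in zip(pairs, mask) if m], undirected=True)
        if g.is_strongly_connected():
            return g
    raise InvalidParameterError(
        f"no connected draw in 10^4 attempts at N={N}, p={edge_probability}"
    )


def graph_edit_distance(g: Graph, h: Graph) -> int:
    """Minimum edge edits turning ``g`` into a graph isomorphic to ``h``.

    For equal-order graphs this is the minimum, over vertex bijections, of
    the symmetric difference of the edge sets; computed by brute force over
    permutations (``N <= 8``).  Unequal orders (vertex edits) are out of
    scope.
    """
    _require_simple_undirected(g, "graph_edit_distance")
    _require_simple_undirected(h, "graph_edit_distance")
    if g.n_vertices != h.n_vertices:
        raise UnsupportedInputError("edit distance requires graphs of equal order")
    n = g.n_vertices
    if n > EDIT_DISTANCE_MAX_N:
        raise CapacityError(f"edit distance supported up to N={EDIT_DISTANCE_MAX_N}")
    eg = g.undirected_edges()
    # adjacency bitmasks of h for fast overlap counting
    adj_h = [0] * n
    for u, v in h.undirected_edges():
        adj_h[u] |= 1 << v
        adj_h[v] |= 1 << u
    ne_g, ne_h = len(eg), len(h.undirected_edges())
    from itertools import permutations

    best_overlap = 0
    for perm in permutations(range(n)):
        overlap = 0
        for u, v in eg:
            if adj_h[perm[u]] >> perm[v] & 1:
                overlap += 1
        if overlap > best_overlap:
            best_overlap = overlap
            if overlap == min(ne_g, ne_h):
                break
    return ne_g + ne_h - 2 * best_overlap
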