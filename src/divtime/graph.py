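"""Population-structure graphs.

A population of ``N`` individuals occupies the vertices ``0 .. N-1`` of a
directed graph; an edge ``(u, v)`` means the offspring of the individual at
``u`` may replace the individual at ``v``.  Undirected (bidirectional)
structures are stored as symmetric edge sets: an undirected edge contributes
both ordered pairs.  Self-loops are permitted and count once in both the
out-degree and the in-degree, so the complete graph *with* self-loops has
``deg+(u) = N`` for every vertex — the well-mixed population.

Only strongly connected graphs are meaningful population structures for the
dynamics in :mod:`divtime.dynamics`; constructors in :mod:`divtime.families`
always produce strongly connected graphs, but :class:`Graph` itself does not
enforce the property so that intermediate objects (e.g. during enumeration)
can be built freely.
"""

from __future__ import annotations

import math
from typing import Iterable, Tuple

import networkx as nx

from .errors import InvalidParameterError, UnsupportedInputError

__all__ = ["Graph", "degree_entropy"]

Edge = Tuple[int, int]


class Graph:
    """An unweighted directed graph on vertices ``0 .. n_vertices - 1``.

    Parameters
    ----------
    n_vertices:
        Number of vertices ``N >= 1``.
    edges:
        Iterable of ordered pairs ``(u, v)``.  Duplicates collapse (the edge
        set is a set, not a multiset).  An undirected edge must be supplied
        as both ``(u, v)`` and ``(v, u)`` (or use ``undirected=True``).
    undirected:
        If true, every supplied pair is mirrored.
    """

    __slots__ = ("_n", "_edges", "_out", "_in", "_strong")

    def __init__(self, n_vertices: int, edges: Iterable[Edge], *, undirected: bool = False):
        n = int(n_vertices)
        if n < 1:
            raise InvalidParameterError(f"graph needs at least one vertex, got {n_vertices}")
        es: set[Edge] = set()
        for u, v in edges:
            u, v = int(u), int(v)
            if not (0 <= u < n and 0 <= v < n):
                raise InvalidParameterError(f"edge ({u}, {v}) out of range for N={n}")
            es.add((u, v))
            if undirected:
                es.add((v, u))
        self._n = n
        self._edges = frozenset(es)
        out: list[list[int]] = [[] for _ in range(n)]
        inn: list[list[int]] = [[] for _ in range(n)]
        for u, v in es:
            out[u].append(v)
            inn[v].append(u)
        self._out = tuple(tuple(sorted(a)) for a in out)
        self._in = tuple(tuple(sorted(a)) for a in inn)
        self._strong: bool | None = None

    # -- basic queries -----------------------------------------------------

    @property
    def n_vertices(self) -> int:
        return self._n

    @property
    def edges(self) -> frozenset[Edge]:
        """The set of ordered pairs."""
        return self._edges

    def out_neighbors(self, u: int) -> tuple[int, ...]:
        return self._out[u]

    def in_neighbors(self, v: int) -> tuple[int, ...]:
        return self._in[v]

    def out_degree(self, u: int) -> int:
        return len(self._out[u])

    def in_degree(self, v: int) -> int:
        return len(self._in[v])

    def degree(self, u: int) -> int:
        """Number of neighbours of ``u`` in an undirected graph."""
        if not self.is_undirected():
            raise UnsupportedInputError("degree() is defined for undirected graphs only")
        return len(self._out[u])

    def has_self_loops(self) -> bool:
        return any((u, u) in self._edges for u in range(self._n))

    def is_undirected(self) -> bool:
        """True iff the edge set is symmetric."""
        return all((v, u) in self._edges for (u, v) in self._edges)

    def is_regular(self) -> bool:
        """True iff undirected and every vertex has the same degree."""
        if not self.is_undirected():
            return False
        degs = {len(a) for a in self._out}
        return len(degs) == 1

    def is_strongly_connected(self) -> bool:
        if self._strong is None:
            self._strong = nx.is_strongly_connected(self.to_networkx(directed=True))
        return self._strong

    def undirected_edges(self) -> frozenset[Edge]:
        """The edge set as unordered pairs ``(min, max)``; undirected graphs only."""
        if not self.is_undirected():
            raise UnsupportedInputError("undirected_edges() requires a symmetric edge set")
        return frozenset((min(u, v), max(u, v)) for (u, v) in self._edges)

    # -- conversions -------------------------------------------------------

    def to_networkx(self, *, directed: bool = True):
        """Export as a :class:`networkx.DiGraph` (or ``Graph`` for symmetric sets)."""
        if directed:
            G = nx.DiGraph()
            G.add_nodes_from(range(self._n))
            G.add_edges_from(self._edges)
            return G
        if not self.is_undirected():
            raise UnsupportedInputError("cannot export a directed edge set as undirected")
        G = nx.Graph()
        G.add_nodes_from(range(self._n))
        G.add_edges_from(self.undirected_edges())
        return G

    @classmethod
    def from_networkx(cls, G) -> "Graph":
        """Build from a networkx (di)graph whose nodes are ``0 .. N-1``."""
        n = G.number_of_nodes()
        if set(G.nodes) != set(range(n)):
            raise InvalidParameterError("networkx nodes must be 0..N-1")
        undirected = not G.is_directed()
        return cls(n, G.edges(), undirected=undirected)

    # -- dunder ------------------------------------------------------------

    def __eq__(self, other) -> bool:
        if not isinstance(other, Graph):
            return NotImplemented
        return self._n == other._n and self._edges == other._edges

    def __hash__(self) -> int:
        return hash((self._n, self._edges))

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        kind = "undirected" if self.is_undirected() else "directed"
        return f"Graph(N={self._n}, |E|={len(self._edges)} ordered pairs, {kind})"


def degree_entropy(g: Graph) -> float:
    """Normalized degree entropy of an undirected graph.

    Shannon entropy of the degree-proportional distribution
    ``p(u) = deg(u) / sum_v deg(v)`` divided by ``log N``.  Equals 1 exactly
    when the degree distribution is uniform (regular graphs) and approaches
    its minimum on the star, the least regular connected graph.

    Raises
    ------
    UnsupportedInputError
        If the graph is directed.
    InvalidParameterError
        If ``N < 2`` or the graph has no edges.
    """
    if not g.is_undirected():
        raise UnsupportedInputError("degree entropy is defined for undirected graphs")
    n = g.n_vertices
    if n < 2:
        raise InvalidParameterError("degree entropy requires N >= 2")
    degs = [g.degree(u) for u in range(n)]
    total = sum(degs)
    if total == 0:
        raise InvalidParameterError("degree entropy requires at least one edge")
    h = 0.0
    for d in degs:
        if d > 0:
            p = d / total
            h -= p * math.log(p)
    return h / math.log(n)
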