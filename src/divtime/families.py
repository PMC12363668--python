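"""Canonical graph-family constructors.

Each family is indexed by its size and produces a strongly connected graph
with a documented, deterministic vertex layout (0-based throughout):

========================  =====================================================
family                    layout
========================  =====================================================
complete (with loops)     all ordered pairs, including ``(u, u)``
complete (no loops)       all ordered pairs with ``u != v``
cycle                     vertex ``i`` adjacent to ``(i ± 1) mod N``
path                      chain ``0 - 1 - ... - N-1``
star                      centre ``0``; leaves ``1 .. N-1``
double star               centres ``0`` and ``1`` (adjacent); the first centre
                          carries the extra leaf when ``N`` is odd
barbell                   clique A ``0..n-1``, path ``n..2n-1``, clique B
                          ``2n..3n-1``; the path endpoints attach to clique
                          vertices ``0`` and ``2n`` respectively
contracting star          centre ``0``; blade ``j`` occupies
                          ``1 + j*m .. (j+1)*m`` innermost-first
========================  =====================================================
"""

from __future__ import annotations

from .errors import InvalidParameterError
from .graph import Graph

__all__ = [
    "make_complete",
    "make_cycle",
    "make_path",
    "make_star",
    "make_double_star",
    "make_barbell",
    "make_contracting_star",
    "FAMILIES",
]


def make_complete(N: int, self_loops: bool = True) -> Graph:
    """Complete graph on ``N`` vertices.

    With ``self_loops`` the edge set is the full Cartesian product (the
    well-mixed population, ``deg+ = N``); without, all ordered pairs
    ``u != v`` (``deg+ = N - 1``).
    """
    if N < 1:
        raise InvalidParameterError(f"complete graph needs N >= 1, got {N}")
    if not self_loops and N < 2:
        raise InvalidParameterError("complete graph without loops needs N >= 2")
    edges = [(u, v) for u in range(N) for v in range(N) if self_loops or u != v]
    return Graph(N, edges)


def make_cycle(N: int) -> Graph:
    """Undirected cycle: each vertex adjacent to its two ring neighbours."""
    if N < 3:
        raise InvalidParameterError(f"cycle needs N >= 3, got {N}")
    return Graph(N, [(i, (i + 1) % N) for i in range(N)], undirected=True)


def make_path(N: int) -> Graph:
    """Undirected path ``0 - 1 - ... - N-1``."""
    if N < 2:
        raise InvalidParameterError(f"path needs N >= 2, got {N}")
    return Graph(N, [(i, i + 1) for i in range(N - 1)], undirected=True)


def make_star(N: int) -> Graph:
    """Undirected star: centre ``0`` adjacent to the ``n = N - 1`` leaves."""
    if N < 2:
        raise InvalidParameterError(f"star needs N >= 2, got {N}")
    return Graph(N, [(0, i) for i in range(1, N)], undirected=True)


def make_double_star(N: int) -> Graph:
    """Two stars joined at their centres (vertices ``0`` and ``1``).

    The ``N - 2`` leaves split as evenly as possible; for odd ``N`` the sizes
    differ by one, with the extra leaf on centre ``0``.
    """
    if N < 4:
        raise InvalidParameterError(f"double star needs N >= 4, got {N}")
    n_left = (N - 2 + 1) // 2  # ceil
    edges = [(0, 1)]
    edges += [(0, i) for i in range(2, 2 + n_left)]
    edges += [(1, i) for i in range(2 + n_left, N)]
    return Graph(N, edges, undirected=True)


def make_barbell(n: int) -> Graph:
    """Two ``n``-cliques joined by an ``n``-vertex path, ``N = 3n`` total.

    Each path endpoint attaches bidirectionally to exactly one clique vertex,
    so path endpoints have degree 2 and each clique's attachment vertex has
    degree ``n`` (``n - 1`` clique neighbours plus the path).
    """
    if n < 2:
        raise InvalidParameterError(f"barbell needs clique size n >= 2, got {n}")
    edges = []
    # cliques: 0..n-1 and 2n..3n-1
    for base in (0, 2 * n):
        for i in range(n):
            for j in range(i + 1, n):
                edges.append((base + i, base + j))
    # path: n..2n-1
    edges += [(i, i + 1) for i in range(n, 2 * n - 1)]
    # attachments
    edges.append((0, n))
    edges.append((2 * n - 1, 2 * n))
    return Graph(3 * n, edges, undirected=True)


def make_contracting_star(N: int, b: int) -> Graph:
    """Directed contracting star: ``b`` blades of ``m = (N-1)/b`` vertices.

    Each blade is a bidirectional path ordered innermost-first; on top of the
    path, every blade vertex sends a directed "contracting" edge to every
    blade vertex closer to the centre.  The innermost vertex of each blade is
    connected to centre ``0`` bidirectionally.  Contracting edges stay inside
    a blade; the centre receives none beyond the innermost links.
    """
    if N < 3:
        raise InvalidParameterError(f"contracting star needs N >= 3, got {N}")
    if b < 1 or (N - 1) % b != 0:
        raise InvalidParameterError(f"blade count b={b} must divide N-1={N - 1}")
    m = (N - 1) // b
    edges: list[tuple[int, int]] = []
    for j in range(b):
        blade = [1 + j * m + i for i in range(m)]  # innermost first
        edges += [(0, blade[0]), (blade[0], 0)]
        for i in range(m - 1):
            edges += [(blade[i], blade[i + 1]), (blade[i + 1], blade[i])]
        for hi in range(m):
            for lo in range(hi - 1):  # strictly-inward extras beyond the path
                edges.append((blade[hi], blade[lo]))
    return Graph(N, edges)


#: name -> constructor taking the family's size parameter (N, or n for
#: barbell); used by the CLI and the analysis drivers.
FAMILIES = {
    "complete": lambda N: make_complete(N, self_loops=True),
    "complete_no_loops": lambda N: make_complete(N, self_loops=False),
    "cycle": make_cycle,
    "path": make_path,
    "star": make_star,
    "double_star": make_double_star,
    "barbell": make_barbell,
    "contracting_path": lambda N: make_contracting_star(N, 2),
    "contracting_star": lambda N: make_contracting_star(N, 3),
}
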