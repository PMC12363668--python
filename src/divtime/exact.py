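"""Exact expected absorption times and fixation probabilities.

The neutral multi-type process on a graph ``G`` is an absorbing Markov
chain.  Three exact routes are provided, in increasing order of reach:

* :func:`absorption_time_full` — the labelled chain over all ``N^N`` type
  vectors ``x``; expected absorption times solve ``tau_x = 0`` on
  homogeneous states and ``tau_x = 1 + sum_x' p(x -> x') tau_x'`` otherwise.
  Feasible only for ``N <= 5``; kept as the ground-truth oracle.
* :func:`absorption_time_lumped` — because all types share one fitness and
  never mutate, the chain is lumpable: only the *set partition* of vertices
  by shared type matters, not which label sits where.  The reduced chain has
  ``Bell(N)`` states (4140 at ``N = 8``); a replacement event ``u -> v``
  moves vertex ``v`` into the block of ``u``.  States are encoded as
  restricted-growth strings and the sparse linear system is solved directly.
  An exact-rational mode (``Fraction`` arithmetic, ``N <= 6``) gives
  bit-exact reference values.
* Closed forms for the canonical families: the well-mixed population
  (:func:`complete_time`), the cycle (:func:`cycle_time`), and the star
  conjecture (:func:`star_time_conjecture`).

Closed forms are evaluated in exact rational arithmetic.  For the complete
graph with self-loops and abundance vector ``lambda = (l1 >= ... >= lk)``,
with ``b_h = sum_i max(l_i - h, 0)`` (the "histogram boxes above height h"),
the two equivalent expressions

    T = N^2 - N - sum_i sum_{l=1..l_i-1} (N + l_i - 2l) * l / (N - l)
    T = N * (N - sum_{h=0..N-1} b_h / (N - h))

are both evaluated and asserted equal on every call.  From maximal diversity
they reduce to ``N(N-1)``; without self-loops the maximal-diversity time is
``(N-1)^2``.  For the cycle (types stay contiguous), the time from abundance
vector ``lambda`` is ``(N+1)N(N-1)/6 - sum_h b_h h``.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from fractions import Fraction
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .errors import CapacityError, InvalidParameterError, StructuralError
from .graph import Graph

__all__ = [
    "ExactResult",
    "b_profile",
    "complete_time",
    "cycle_time",
    "star_time_conjecture",
    "harmonic_number",
    "partition_state_count",
    "restricted_growth_strings",
    "canonical_partition",
    "absorption_time_full",
    "absorption_time_lumped",
    "lumped_absorption_times",
    "fixation_probability_two_type",
]

FULL_CHAIN_MAX_N = 5
LUMPED_MAX_N = 12
RATIONAL_MAX_N = 6
FIXATION_MAX_N = 14


@dataclass(frozen=True)
class ExactResult:
    """An exactly computed expected absorption time."""

    expected_time: float
    method: str  # "full" | "lumped" | "closed_form"
    state_count: int
    rule: Optional[str] = None
    fraction: Optional[Fraction] = None
    conjecture: bool = False

    def __float__(self) -> float:
        return self.expected_time


# ---------------------------------------------------------------------------
# abundance vectors and closed forms
# ---------------------------------------------------------------------------


def _check_abundances(lam: Sequence[int]) -> tuple[int, ...]:
    lam = tuple(int(v) for v in lam)
    if not lam:
        raise InvalidParameterError("abundance vector must be non-empty")
    if any(v <= 0 for v in lam):
        raise InvalidParameterError(f"abundances must be positive, got {lam}")
    return tuple(sorted(lam, reverse=True))


def b_profile(lam: Sequence[int], h: int) -> int:
    """Number of histogram boxes of the partition ``lam`` above height ``h``:
    ``sum_i max(lam_i - h, 0)``; ``b_0`` equals the population size."""
    if h < 0:
        raise InvalidParameterError(f"height must be non-negative, got {h}")
    return sum(max(int(v) - h, 0) for v in lam)


def complete_time(lam: Sequence[int], self_loops: bool = True) -> ExactResult:
    """Expected absorption time on the complete graph from abundances ``lam``.

    With self-loops the double-sum and histogram forms are both evaluated
    and cross-asserted.  Without self-loops only the maximal-diversity start
    is covered (time ``(N-1)^2``); other starts raise.
    """
    lam = _check_abundances(lam)
    N = sum(lam)
    if not self_loops:
        if lam != tuple([1] * N):
            raise InvalidParameterError(
                "complete graph without self-loops: closed form covers only "
                "the maximal-diversity start"
            )
        val = Fraction((N - 1) ** 2)
        return ExactResult(float(val), "closed_form", N, fraction=val)
    # double-sum form
    t_sum = Fraction(N * N - N)
    for li in lam:
        for ell in range(1, li):
            t_sum -= Fraction((N + li - 2 * ell) * ell, N - ell)
    # histogram form
    s = Fraction(0)
    for h in range(N):
        s += Fraction(b_profile(lam, h), N - h)
    t_hist = N * (N - s)
    if t_sum != t_hist:
        raise AssertionError(
            f"internal inconsistency: double-sum form {t_sum} != histogram form {t_hist}"
        )
    return ExactResult(float(t_sum), "closed_form", N, fraction=t_sum)


def cycle_time(lam: Sequence[int]) -> ExactResult:
    """Expected absorption time on the cycle from contiguous clusters with
    abundances ``lam``: ``(N+1)N(N-1)/6 - sum_h b_h h``.

    Contiguity of same-type clusters is the caller's responsibility; it
    holds automatically on any trajectory started from maximal diversity.
    """
    lam = _check_abundances(lam)
    N = sum(lam)
    val = Fraction((N + 1) * N * (N - 1), 6)
    for h in range(1, N):
        val -= b_profile(lam, h) * h
    return ExactResult(float(val), "closed_form", N, fraction=val)


def harmonic_number(n: int) -> Fraction:
    """``H_n = 1 + 1/2 + ... + 1/n`` as an exact rational."""
    if n < 0:
        raise InvalidParameterError(f"harmonic number needs n >= 0, got {n}")
    return sum((Fraction(1, j) for j in range(1, n + 1)), Fraction(0))


def star_time_conjecture(n: int) -> ExactResult:
    """Conjectured exact bd absorption time of the star with ``n`` leaves
    (``N = n + 1`` vertices) from maximal diversity: ``n^3 - n^2 + n H_n``.

    The result is flagged ``conjecture=True``; it is a checkable oracle, not
    ground truth — the lumped solver verifies it for small ``n``.
    """
    if n < 1:
        raise InvalidParameterError(f"star needs n >= 1 leaves, got {n}")
    val = Fraction(n**3 - n**2) + n * harmonic_number(n)
    return ExactResult(float(val), "closed_form", n + 1, rule="bd", fraction=val, conjecture=True)


# ---------------------------------------------------------------------------
# set-partition states
# ---------------------------------------------------------------------------


def restricted_growth_strings(n: int) -> list[tuple[int, ...]]:
    """All set partitions of ``{0..n-1}`` as restricted-growth strings,
    in lexicographic order.  ``a[0] = 0`` and ``a[i] <= max(a[:i]) + 1``."""
    if n < 1:
        raise InvalidParameterError(f"need n >= 1, got {n}")
    out: list[tuple[int, ...]] = []
    a = [0] * n

    def rec(i: int, mx: int) -> None:
        if i == n:
            out.append(tuple(a))
            return
        for j in range(mx + 2):
            a[i] = j
            rec(i + 1, max(mx, j))

    rec(1, 0)
    return out


def canonical_partition(assignment: Iterable[int]) -> tuple[int, ...]:
    """Relabel a block-assignment vector into its restricted-growth string."""
    relabel: dict[int, int] = {}
    out = []
    for v in assignment:
        if v not in relabel:
            relabel[v] = len(relabel)
        out.append(relabel[v])
    return tuple(out)


def partition_state_count(N: int) -> int:
    """The Bell number ``B_N`` — the number of set partitions of ``N``
    vertices, i.e. the state count of the lumped chain."""
    if N < 1:
        raise InvalidParameterError(f"need N >= 1, got {N}")
    # Bell triangle: after k extensions the leading entry is B_k
    row = [1]
    for _ in range(N):
        nxt = [row[-1]]
        for v in row:
            nxt.append(nxt[-1] + v)
        row = nxt
    return row[0]


# ---------------------------------------------------------------------------
# replacement events
# ---------------------------------------------------------------------------


def _events(g: Graph, rule: str, exact: bool) -> list[tuple[int, int, object]]:
    """Ordered replacement events ``(u, v, prob)``: offspring of ``u``
    replaces ``v``.  bd: ``1/(N deg+(u))``; db: ``1/(N deg-(v))``."""
    if rule not in ("bd", "db"):
        raise InvalidParameterError(f"update rule must be 'bd' or 'db', got {rule!r}")
    N = g.n_vertices
    ev: list[tuple[int, int, object]] = []
    if rule == "bd":
        for u in range(N):
            nbrs = g.out_neighbors(u)
            if not nbrs:
                raise StructuralError(f"vertex {u} has no out-neighbours")
            p = Fraction(1, N * len(nbrs)) if exact else 1.0 / (N * len(nbrs))
            ev.extend((u, v, p) for v in nbrs)
    else:
        for v in range(N):
            nbrs = g.in_neighbors(v)
            if not nbrs:
                raise StructuralError(f"vertex {v} has no in-neighbours")
            p = Fraction(1, N * len(nbrs)) if exact else 1.0 / (N * len(nbrs))
            ev.extend((u, v, p) for u in nbrs)
    return ev


# ---------------------------------------------------------------------------
# full labelled chain (oracle, N <= 5)
# ---------------------------------------------------------------------------


def absorption_time_full(g: Graph, rule: str, x0: Sequence[int]) -> ExactResult:
    """Expected absorption time from type vector ``x0`` on the full labelled
    chain over all ``N^N`` states.  Oracle-scale only (``N <= 5``)."""
    N = g.n_vertices
    if N > FULL_CHAIN_MAX_N:
        raise CapacityError(
            f"full chain has N^N = {N}^{N} states; use absorption_time_lumped for N > "
            f"{FULL_CHAIN_MAX_N}"
        )
    x0 = tuple(int(v) for v in x0)
    if len(x0) != N or any(not 0 <= v < N for v in x0):
        raise InvalidParameterError("x0 must be a length-N vector of labels in 0..N-1")
    n_states = N**N
    # itertools.product order makes x[0] the most significant mixed-radix digit
    states = list(itertools.product(range(N), repeat=N))
    transient = [i for i, x in enumerate(states) if len(set(x)) > 1]
    if not transient:
        return ExactResult(0.0, "full", n_states, rule=rule)
    events = _events(g, rule, exact=False)
    tmap = {s: i for i, s in enumerate(transient)}
    rows, cols, vals = [], [], []
    rhs = np.ones(len(transient))
    for si, ti in tmap.items():
        x = states[si]
        acc: dict[int, float] = {}
        for u, v, p in events:
            xv = list(x)
            xv[v] = x[u]
            j = 0
            for val in xv:
                j = j * N + val
            acc[j] = acc.get(j, 0.0) + p
        for j, p in acc.items():
            if j in tmap:
                rows.append(ti)
                cols.append(tmap[j])
                vals.append(-p)
        rows.append(ti)
        cols.append(ti)
        vals.append(1.0)
    A = sp.csr_matrix(
        sp.coo_matrix((vals, (rows, cols)), shape=(len(transient), len(transient)))
    )
    tau = spla.spsolve(A, rhs)
    # state index in product order: x[0] most significant
    start = 0
    for v in x0:
        start = start * N + v
    t = 0.0 if start not in tmap else float(tau[tmap[start]])
    return ExactResult(t, "full", n_states, rule=rule)


# ---------------------------------------------------------------------------
# lumped partition chain
# ---------------------------------------------------------------------------


def _lumped_transitions(g: Graph, rule: str, exact: bool):
    N = g.n_vertices
    states = restricted_growth_strings(N)
    index = {s: i for i, s in enumerate(states)}
    trans: list[Optional[dict[int, object]]] = [None] * len(states)
    if N == 1:  # sole state is absorbing; no events needed
        return states, index, trans
    events = _events(g, rule, exact)
    for i, s in enumerate(states):
        if max(s) == 0:  # single block: absorbing
            continue
        acc: dict[int, object] = {}
        for u, v, p in events:
            if s[u] == s[v]:
                j = i
            else:
                new = list(s)
                new[v] = s[u]
                j = index[canonical_partition(new)]
            acc[j] = acc.get(j, 0) + p
        trans[i] = acc
    return states, index, trans


def lumped_absorption_times(g: Graph, rule: str, exact: bool = False):
    """Solve the partition-lumped chain for *all* starting partitions.

    Returns ``(states, times)`` where ``states`` is the lexicographic list
    of restricted-growth strings and ``times`` the matching expected
    absorption times (floats, or ``Fraction`` in exact mode).
    """
    N = g.n_vertices
    if N > LUMPED_MAX_N:
        raise CapacityError(
            f"lumped chain has Bell({N}) states; supported up to N={LUMPED_MAX_N}"
        )
    if exact and N > RATIONAL_MAX_N:
        raise CapacityError(f"exact-rational mode supported up to N={RATIONAL_MAX_N}")
    if not g.is_strongly_connected():
        raise StructuralError("absorption times require a strongly connected graph")
    states, index, trans = _lumped_transitions(g, rule, exact)
    transient = [i for i, t in enumerate(trans) if t is not None]
    tmap = {i: k for k, i in enumerate(transient)}
    if exact:
        tau_t = _solve_rational(transient, tmap, trans)
        times: list = [Fraction(0)] * len(states)
        for i, k in tmap.items():
            times[i] = tau_t[k]
        return states, times
    rows, cols, vals = [], [], []
    for i in transient:
        k = tmap[i]
        rows.append(k)
        cols.append(k)
        vals.append(1.0)
        for j, p in trans[i].items():
            if j in tmap:
                rows.append(k)
                cols.append(tmap[j])
                vals.append(-float(p))
    A = sp.csr_matrix(
        sp.coo_matrix((vals, (rows, cols)), shape=(len(transient), len(transient)))
    )
    A.sum_duplicates()
    try:
        tau_t = spla.spsolve(A, np.ones(len(transient)))
    except RuntimeError as exc:  # pragma: no cover - defensive
        raise StructuralError(f"singular lumped system: {exc}") from exc
    times_f = np.zeros(len(states))
    for i, k in tmap.items():
        times_f[i] = tau_t[k]
    return states, times_f


def _solve_rational(transient, tmap, trans):
    """Dense Gaussian elimination over Fractions for (I - Q) tau = 1."""
    m = len(transient)
    A = [[Fraction(0)] * m for _ in range(m)]
    b = [Fraction(1)] * m
    for i in transient:
        k = tmap[i]
        A[k][k] += 1
        for j, p in trans[i].items():
            if j in tmap:
                A[k][tmap[j]] -= p
    for col in range(m):
        piv = next((r for r in range(col, m) if A[r][col] != 0), None)
        if piv is None:
            raise StructuralError("singular lumped system in rational mode")
        A[col], A[piv] = A[piv], A[col]
        b[col], b[piv] = b[piv], b[col]
        inv = A[col][col]
        for r in range(col + 1, m):
            f = A[r][col]
            if f == 0:
                continue
            f /= inv
            row_c, row_r = A[col], A[r]
            for c in range(col, m):
                if row_c[c] != 0:
                    row_r[c] -= f * row_c[c]
            b[r] -= f * b[col]
    tau = [Fraction(0)] * m
    for r in range(m - 1, -1, -1):
        s = b[r]
        row = A[r]
        for c in range(r + 1, m):
            if row[c] != 0:
                s -= row[c] * tau[c]
        tau[r] = s / row[r]
    return tau


def _as_partition(N: int, omega) -> tuple[int, ...]:
    """Accept a restricted-growth string, assignment vector, or block list."""
    if omega is None:
        return tuple(range(N))  # maximal diversity: all-singleton partition
    omega = list(omega)
    if omega and not isinstance(omega[0], (int, np.integer)):
        assign = [-1] * N
        for b, block in enumerate(omega):
            for v in block:
                v = int(v)
                if not 0 <= v < N or assign[v] != -1:
                    raise InvalidParameterError("blocks must disjointly cover 0..N-1")
                assign[v] = b
        if any(a == -1 for a in assign):
            raise InvalidParameterError("blocks must cover every vertex")
        omega = assign
    if len(omega) != N:
        raise InvalidParameterError(f"partition length {len(omega)} != N={N}")
    return canonical_partition(int(v) for v in omega)


def absorption_time_lumped(
    g: Graph,
    rule: str,
    omega0=None,
    exact: bool = False,
) -> ExactResult:
    """Expected absorption time from partition ``omega0`` (default: all
    singletons, i.e. maximal diversity) on the lumped ``Bell(N)``-state chain.

    ``omega0`` may be an assignment vector, a restricted-growth string, or an
    iterable of blocks.  ``exact=True`` switches to rational arithmetic
    (``N <= 6``).
    """
    N = g.n_vertices
    start = _as_partition(N, omega0)
    states, times = lumped_absorption_times(g, rule, exact=exact)
    index = {s: i for i, s in enumerate(states)}
    t = times[index[start]]
    if exact:
        return ExactResult(float(t), "lumped", len(states), rule=rule, fraction=t)
    return ExactResult(float(t), "lumped", len(states), rule=rule)


# ---------------------------------------------------------------------------
# two-type fixation probabilities
# ---------------------------------------------------------------------------


def fixation_probability_two_type(g: Graph, rule: str, focal_set: Iterable[int]) -> float:
    """Probability that the type occupying ``focal_set`` takes over.

    Solves the first-step system on the ``2^N``-state chain whose states are
    the vertex subsets occupied by the focal type (the complement carries a
    single rival type).
    """
    N = g.n_vertices
    if N > FIXATION_MAX_N:
        raise CapacityError(f"subset chain has 2^{N} states; supported up to N={FIXATION_MAX_N}")
    if not g.is_strongly_connected():
        raise StructuralError("fixation probabilities require a strongly connected graph")
    focal = 0
    for v in focal_set:
        v = int(v)
        if not 0 <= v < N:
            raise InvalidParameterError(f"focal vertex {v} out of range")
        focal |= 1 << v
    full = (1 << N) - 1
    if focal == full:
        return 1.0
    if focal == 0:
        return 0.0
    events = _events(g, rule, exact=False)
    transient = [s for s in range(1, full) ]
    tmap = {s: k for k, s in enumerate(transient)}
    rows, cols, vals = [], [], []
    rhs = np.zeros(len(transient))
    for s in transient:
        k = tmap[s]
        rows.append(k)
        cols.append(k)
        vals.append(1.0)
        for u, v, p in events:
            if s >> u & 1:
                s2 = s | (1 << v)
            else:
                s2 = s & ~(1 << v)
            if s2 == full:
                rhs[k] += p
            elif s2 != 0:
                rows.append(k)
                cols.append(tmap[s2])
                vals.append(-p)
    A = sp.csr_matrix(sp.coo_matrix((vals, (rows, cols)), shape=(len(transient),) * 2))
    A.sum_duplicates()
    phi = spla.spsolve(A, rhs)
    return float(phi[tmap[focal]])
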