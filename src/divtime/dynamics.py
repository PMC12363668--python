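"""Stochastic simulation of neutral bd and db updating on graphs.

One *step* is a single birth–death event:

* **bd** — a birth vertex ``u`` is drawn uniformly from the population, then
  a death vertex ``v`` uniformly from the out-neighbours of ``u``; each
  ordered event ``(u, v)`` has probability ``1/N * 1/deg+(u)``.
* **db** — a death vertex ``v`` is drawn uniformly, then a birth vertex
  ``u`` uniformly from the in-neighbours of ``v``; probability
  ``1/N * 1/deg-(v)``.

In either case the type at ``v`` is overwritten by the type at ``u``.  Steps
that change nothing (the offspring lands on its own type, or a self-loop
replaces a vertex by itself) still consume one unit of time; the closed-form
absorption times in :mod:`divtime.exact` count time the same way.

The population starts, by default, at *maximal diversity* — a distinct type
on every vertex — and the simulation runs until the population is
homogeneous (absorption).  Types are labelled ``0 .. N-1`` to match the
0-based vertex indexing.

:func:`step` is the plain-Python reference transition used for kernel
audits; the replicated estimators run a numba-compiled loop with identical
event probabilities.  Per-replicate randomness comes from counter-based
Philox substreams derived deterministically from ``(seed, replicate)``, so
runs are reproducible and embarrassingly parallel.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np

from . import _kernels
from .errors import InvalidParameterError, StructuralError
from .graph import Graph

__all__ = [
    "UpdateRule",
    "SingleRun",
    "SimulationResult",
    "maximal_diversity",
    "step",
    "simulate_to_absorption",
    "estimate_absorption_time",
    "characteristic_curve",
]

UpdateRule = Literal["bd", "db"]
_RULES = ("bd", "db")


def _check_rule(rule: str) -> None:
    if rule not in _RULES:
        raise InvalidParameterError(f"update rule must be 'bd' or 'db', got {rule!r}")


def maximal_diversity(N: int) -> np.ndarray:
    """The initial configuration with a distinct type on every vertex."""
    return np.arange(N, dtype=np.int64)


def _validate_config(g: Graph, x) -> np.ndarray:
    x = np.asarray(x, dtype=np.int64)
    if x.shape != (g.n_vertices,):
        raise InvalidParameterError(
            f"configuration length {x.shape} does not match N={g.n_vertices}"
        )
    return x


def _csr(g: Graph, rule: UpdateRule) -> tuple[np.ndarray, np.ndarray]:
    """Neighbour arrays for the first-picked vertex: out for bd, in for db."""
    n = g.n_vertices
    rows = [g.out_neighbors(u) if rule == "bd" else g.in_neighbors(u) for u in range(n)]
    for u, r in enumerate(rows):
        if not r:
            kind = "out" if rule == "bd" else "in"
            raise StructuralError(
                f"vertex {u} has no {kind}-neighbours; graph is not strongly connected"
            )
    indptr = np.zeros(n + 1, dtype=np.int64)
    for u, r in enumerate(rows):
        indptr[u + 1] = indptr[u] + len(r)
    indices = np.concatenate([np.asarray(r, dtype=np.int64) for r in rows])
    return indptr, indices


def _substream(seed: int, replicate: int) -> np.random.Generator:
    ss = np.random.SeedSequence(entropy=int(seed), spawn_key=(int(replicate),))
    return np.random.Generator(np.random.Philox(ss))


def step(g: Graph, x, rule: UpdateRule, rng: np.random.Generator) -> np.ndarray:
    """One birth–death event; returns the new configuration (input untouched)."""
    _check_rule(rule)
    x = _validate_config(g, x).copy()
    n = g.n_vertices
    first = int(rng.integers(0, n))
    if rule == "bd":
        nbrs = g.out_neighbors(first)
        if not nbrs:
            raise StructuralError(f"vertex {first} has no out-neighbours")
        u, v = first, nbrs[int(rng.integers(0, len(nbrs)))]
    else:
        nbrs = g.in_neighbors(first)
        if not nbrs:
            raise StructuralError(f"vertex {first} has no in-neighbours")
        u, v = nbrs[int(rng.integers(0, len(nbrs)))], first
    x[v] = x[u]
    return x


@dataclass(frozen=True)
class SingleRun:
    """One trajectory run to absorption (or to the step cap)."""

    absorption_time: int
    winner: int
    censored: bool = False


@dataclass
class SimulationResult:
    """Replicated absorption-time estimate."""

    graph_n: int
    rule: str
    seed: int
    times: np.ndarray
    winners: np.ndarray
    censored: np.ndarray
    mean: float = field(init=False)
    sem: float = field(init=False)

    def __post_init__(self) -> None:
        self.mean = float(np.mean(self.times))
        self.sem = (
            float(np.std(self.times, ddof=1) / np.sqrt(len(self.times)))
            if len(self.times) > 1
            else 0.0
        )

    @property
    def n_replicates(self) -> int:
        return len(self.times)


def _normalise_types(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Map arbitrary labels to 0..k-1; returns (normalised, original labels)."""
    labels, norm = np.unique(x, return_inverse=True)
    return norm.astype(np.int64), labels


def _run_one(
    x0: np.ndarray,
    indptr: np.ndarray,
    indices: np.ndarray,
    copy_from_second: bool,
    gen: np.random.Generator,
    max_steps: Optional[int],
) -> SingleRun:
    norm, labels = _normalise_types(x0)
    counts = np.bincount(norm, minlength=len(x0)).astype(np.int64)
    n_distinct = int(len(labels))
    budget = np.int64(max_steps) if max_steps is not None else np.int64(2**62)
    steps, n_distinct = _kernels.advance(
        norm, counts, n_distinct, indptr, indices, copy_from_second, budget, gen
    )
    censored = n_distinct > 1
    winner = int(labels[norm[0]]) if not censored else -1
    return SingleRun(int(steps), winner, censored)


def simulate_to_absorption(
    g: Graph,
    x0,
    rule: UpdateRule,
    rng: np.random.Generator,
    max_steps: Optional[int] = None,
) -> SingleRun:
    """Iterate events until the population is homogeneous.

    Returns the exact step count and the winning type label.  If
    ``max_steps`` is reached first the run is flagged ``censored`` (and the
    reported time is a lower bound); nothing is silently truncated.
    """
    _check_rule(rule)
    x0 = _validate_config(g, x0)
    indptr, indices = _csr(g, rule)
    return _run_one(x0, indptr, indices, rule == "db", rng, max_steps)


def estimate_absorption_time(
    g: Graph,
    rule: UpdateRule,
    reps: int,
    seed: int,
    init=None,
    max_steps: Optional[int] = None,
) -> SimulationResult:
    """Monte-Carlo estimate of the expected absorption time.

    Replicate ``r`` uses a Philox substream derived from ``(seed, r)``; the
    default initial configuration is maximal diversity.
    """
    _check_rule(rule)
    if reps < 1:
        raise InvalidParameterError(f"reps must be >= 1, got {reps}")
    x0 = maximal_diversity(g.n_vertices) if init is None else _validate_config(g, init)
    indptr, indices = _csr(g, rule)
    copy_from_second = rule == "db"
    times = np.empty(reps, dtype=np.int64)
    winners = np.empty(reps, dtype=np.int64)
    censored = np.zeros(reps, dtype=bool)
    for r in range(reps):
        run = _run_one(x0, indptr, indices, copy_from_second, _substream(seed, r), max_steps)
        times[r] = run.absorption_time
        winners[r] = run.winner
        censored[r] = run.censored
    return SimulationResult(g.n_vertices, rule, int(seed), times, winners, censored)


def characteristic_curve(
    g: Graph,
    rule: UpdateRule,
    reps: int,
    time_points: Sequence[int],
    seed: int,
    init=None,
) -> list[tuple[int, float]]:
    """Mean diversity (distinct-type count) at each requested time.

    ``time_points`` must be non-negative and strictly increasing.  After a
    replicate absorbs, its diversity stays frozen at 1 for all later times.
    """
    _check_rule(rule)
    if reps < 1:
        raise InvalidParameterError(f"reps must be >= 1, got {reps}")
    tps = [int(t) for t in time_points]
    if any(t < 0 for t in tps) or any(b <= a for a, b in zip(tps, tps[1:])):
        raise InvalidParameterError("time points must be non-negative and strictly increasing")
    x0 = maximal_diversity(g.n_vertices) if init is None else _validate_config(g, init)
    indptr, indices = _csr(g, rule)
    copy_from_second = rule == "db"
    acc = np.zeros(len(tps), dtype=np.float64)
    for r in range(reps):
        gen = _substream(seed, r)
        norm, labels = _normalise_types(x0)
        counts = np.bincount(norm, minlength=len(x0)).astype(np.int64)
        n_distinct = int(len(labels))
        now = 0
        for i, t in enumerate(tps):
            if n_distinct > 1 and t > now:
                used, n_distinct = _kernels.advance(
                    norm,
                    counts,
                    n_distinct,
                    indptr,
                    indices,
                    copy_from_second,
                    np.int64(t - now),
                    gen,
                )
                now += int(used)
            acc[i] += n_distinct
    return [(t, float(a / reps)) for t, a in zip(tps, acc)]
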