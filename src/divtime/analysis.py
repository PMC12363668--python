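"""Comparative experiment drivers.

These reproduce, at desk scale, the headline comparative analyses: exhaustive
bd-vs-db absorption-time sweeps over all small connected graphs, Pareto
fronts of (bd, db) times, degree-entropy relations, log-log scaling slopes
for the graph families, and the path-vs-contracting-path comparison.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .dynamics import estimate_absorption_time
from .enumeration import enumerate_connected_graphs
from .errors import InvalidParameterError
from .exact import absorption_time_lumped
from .families import FAMILIES
from .graph import Graph, degree_entropy
from .io import write_graph6

__all__ = [
    "GraphRecord",
    "sweep_exact",
    "pareto_front",
    "scaling_slope",
    "contracting_comparison",
    "find_edge_addition_anomaly",
    "records_to_dataframe",
]


@dataclass(frozen=True)
class GraphRecord:
    """Per-graph summary emitted by the exact sweeps."""

    graph_id: str
    n_vertices: int
    bd_time: Optional[float]
    db_time: Optional[float]
    degree_entropy: Optional[float]
    ratio: Optional[float]  # db_time / bd_time
    method: str = "lumped"


def sweep_exact(N: int, rules: Sequence[str] = ("bd", "db")) -> list[GraphRecord]:
    """Exact lumped absorption times from maximal diversity for every
    connected undirected graph on ``N`` vertices (one per isomorphism
    class), identified by graph6 string."""
    records = []
    for g in enumerate_connected_graphs(N):
        times = {}
        for rule in rules:
            times[rule] = absorption_time_lumped(g, rule).expected_time
        bd, db = times.get("bd"), times.get("db")
        ent = degree_entropy(g) if N >= 2 else None
        ratio = (db / bd) if (bd and db is not None) else None
        records.append(GraphRecord(write_graph6(g), N, bd, db, ent, ratio))
    return records


def pareto_front(records: Sequence[GraphRecord]) -> list[GraphRecord]:
    """Records not dominated in (bd_time, db_time): no other record is at
    least as slow in both rules and strictly slower in one.  Returned in
    increasing bd_time order."""
    if not records:
        raise InvalidParameterError("pareto_front needs at least one record")
    groups: dict[float, list[GraphRecord]] = {}
    for r in records:
        if r.bd_time is None or r.db_time is None:
            raise InvalidParameterError("pareto_front needs both bd and db times")
        groups.setdefault(r.bd_time, []).append(r)
    front: list[GraphRecord] = []
    best_db = -np.inf
    for bd in sorted(groups, reverse=True):
        top = max(r.db_time for r in groups[bd])
        if top > best_db:
            front.extend(r for r in groups[bd] if r.db_time == top)
            best_db = top
    return sorted(front, key=lambda r: (r.bd_time, r.graph_id))


def scaling_slope(
    family: Union[str, Callable[[int], Graph]],
    rule: str,
    sizes: Sequence[int],
    mode: str = "exact",
    reps: int = 100,
    seed: int = 0,
) -> float:
    """Least-squares slope of log T against log N across a graph family.

    ``mode='exact'`` uses the lumped solver; ``'simulated'`` uses
    Monte-Carlo means with ``reps`` replicates per size.  ``sizes`` are the
    family's size parameters (clique size for the barbell); the regression
    abscissa is always the actual vertex count.
    """
    if len(sizes) < 3:
        raise InvalidParameterError("need at least 3 sizes for a slope")
    if mode not in ("exact", "simulated"):
        raise InvalidParameterError(f"mode must be 'exact' or 'simulated', got {mode!r}")
    ctor = FAMILIES[family] if isinstance(family, str) else family
    ns, ts = [], []
    for s in sizes:
        g = ctor(int(s))
        if mode == "exact":
            t = absorption_time_lumped(g, rule).expected_time
        else:
            t = estimate_absorption_time(g, rule, reps=reps, seed=seed).mean
        ns.append(g.n_vertices)
        ts.append(t)
    ts = np.asarray(ts, dtype=float)
    if np.any(ts <= 0) or np.allclose(ts, ts[0]):
        raise InvalidParameterError("degenerate times: slope undefined")
    return float(np.polyfit(np.log(ns), np.log(ts), 1)[0])


def contracting_comparison(
    N: int,
    b: int = 3,
    reps: int = 100,
    seed: int = 0,
    max_steps: Optional[int] = None,
) -> pd.DataFrame:
    """Simulated mean absorption times for the undirected path, the
    contracting path (b=2), and the contracting star (given ``b``) at the
    same size and seeds.  Families whose divisibility constraint fails at
    this ``N`` are skipped; censored replicates are counted, not hidden."""
    rows = []
    jobs = [("path", FAMILIES["path"])]
    if (N - 1) % 2 == 0:
        jobs.append(("contracting_path", FAMILIES["contracting_path"]))
    if b != 2 and (N - 1) % b == 0:
        from .families import make_contracting_star

        jobs.append(("contracting_star", lambda n: make_contracting_star(n, b)))
    for name, ctor in jobs:
        g = ctor(N)
        res = estimate_absorption_time(g, "bd", reps=reps, seed=seed, max_steps=max_steps)
        rows.append(
            {
                "family": name,
                "N": N,
                "reps": reps,
                "mean_time": res.mean,
                "sem": res.sem,
                "n_censored": int(res.censored.sum()),
            }
        )
    return pd.DataFrame(rows)


def find_edge_addition_anomaly(rule: str = "bd", N: int = 4):
    """Search labelled connected graphs on ``N`` vertices for a chain
    ``G ⊂ G' ⊂ G''`` (one edge added each time) whose absorption time rises
    and then falls — adding an edge can slow *or* speed homogenisation.

    Returns ``(G, G', G'', (t, t', t''))`` for the first chain found, or
    ``None``.
    """
    from itertools import combinations

    pairs = list(combinations(range(N), 2))
    cache: dict[frozenset, float] = {}

    def time_of(edge_set: frozenset) -> Optional[float]:
        if edge_set in cache:
            return cache[edge_set]
        g = Graph(N, list(edge_set), undirected=True)
        t = (
            absorption_time_lumped(g, rule).expected_time
            if g.is_strongly_connected()
            else None
        )
        cache[edge_set] = t
        return t

    for k in range(N - 1, len(pairs) - 1):
        for base in combinations(pairs, k):
            e0 = frozenset(base)
            t0 = time_of(e0)
            if t0 is None:
                continue
            rest = [p for p in pairs if p not in e0]
            for e_add in rest:
                e1 = e0 | {e_add}
                t1 = time_of(e1)
                if t1 is None or t1 <= t0:
                    continue
                for f_add in rest:
                    if f_add == e_add:
                        continue
                    e2 = e1 | {f_add}
                    t2 = time_of(e2)
                    if t2 is not None and t2 < t1:
                        return (
                            Graph(N, list(e0), undirected=True),
                            Graph(N, list(e1), undirected=True),
                            Graph(N, list(e2), undirected=True),
                            (t0, t1, t2),
                        )
    return None


def records_to_dataframe(records: Sequence[GraphRecord]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in records])
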