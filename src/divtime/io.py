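"""Reading and writing graphs: graph6 strings and TSV edge lists.

graph6 (the standard headerless dialect, upper-triangle column-major bits in
63-offset printable bytes) covers undirected simple graphs only; encoding and
decoding are delegated to networkx.  Directed graphs and graphs with
self-loops use the TSV edge-list format::

    # optional comment lines
    # n=9
    directed=true
    0\t1
    1\t0
    ...

The first non-comment line declares directedness; an ``# n=<N>`` comment
preserves the vertex count (isolated trailing vertices would otherwise be
lost).  Round-tripping either format is the identity on valid input.
"""

from __future__ import annotations

import io as _io
from typing import IO, Iterable, Union

import networkx as nx

from .errors import FormatError
from .graph import Graph

__all__ = [
    "read_graph6",
    "write_graph6",
    "read_graph6_file",
    "write_graph6_file",
    "read_edge_list",
    "write_edge_list",
]


def write_graph6(g: Graph) -> str:
    """Encode an undirected simple graph as a graph6 string (no header)."""
    if not g.is_undirected():
        raise FormatError("graph6 cannot represent directed graphs")
    if g.has_self_loops():
        raise FormatError("graph6 cannot represent self-loops")
    data = nx.to_graph6_bytes(g.to_networkx(directed=False), header=False)
    return data.decode("ascii").strip()


def read_graph6(text: Union[str, bytes]) -> Graph:
    """Decode a single graph6 string."""
    if isinstance(text, str):
        text = text.encode("ascii")
    text = text.strip()
    try:
        G = nx.from_graph6_bytes(text)
    except (nx.NetworkXError, ValueError, IndexError) as exc:
        raise FormatError(f"malformed graph6 input: {exc}") from exc
    return Graph.from_networkx(G)


def write_graph6_file(graphs: Iterable[Graph], stream: Union[str, IO[str]]) -> None:
    """Write one graph6 string per line."""
    close = False
    if isinstance(stream, str):
        stream, close = open(stream, "w"), True
    try:
        for g in graphs:
            stream.write(write_graph6(g) + "\n")
    finally:
        if close:
            stream.close()


def read_graph6_file(stream: Union[str, IO[str]]) -> list[Graph]:
    """Read a file with one graph6 string per line (blank lines skipped)."""
    close = False
    if isinstance(stream, str):
        stream, close = open(stream), True
    try:
        return [read_graph6(line) for line in stream if line.strip()]
    finally:
        if close:
            stream.close()


def write_edge_list(g: Graph, stream: Union[str, IO[str]]) -> None:
    """Write a TSV edge list with a directedness header.

    Undirected graphs emit each unordered edge once; directed graphs emit
    every ordered pair.
    """
    close = False
    if isinstance(stream, str):
        stream, close = open(stream, "w"), True
    try:
        undirected = g.is_undirected()
        stream.write(f"# n={g.n_vertices}\n")
        stream.write(f"directed={'false' if undirected else 'true'}\n")
        edges = g.undirected_edges() if undirected else g.edges
        for u, v in sorted(edges):
            stream.write(f"{u}\t{v}\n")
    finally:
        if close:
            stream.close()


def read_edge_list(stream: Union[str, IO[str]]) -> Graph:
    """Parse the TSV edge-list format written by :func:`write_edge_list`."""
    close = False
    if isinstance(stream, str):
        stream, close = open(stream), True
    try:
        n_declared: int | None = None
        directed: bool | None = None
        edges: list[tuple[int, int]] = []
        for raw in stream:
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if body.startswith("n="):
                    try:
                        n_declared = int(body[2:])
                    except ValueError as exc:
                        raise FormatError(f"bad vertex-count comment: {line!r}") from exc
                continue
            if directed is None:
                if line == "directed=true":
                    directed = True
                elif line == "directed=false":
                    directed = False
                else:
                    raise FormatError(
                        "first non-comment line must be 'directed=true' or "
                        f"'directed=false', got {line!r}"
                    )
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise FormatError(f"expected 'u<TAB>v', got {line!r}")
            try:
                u, v = int(parts[0]), int(parts[1])
            except ValueError as exc:
                raise FormatError(f"non-integer vertex in {line!r}") from exc
            if u < 0 or v < 0:
                raise FormatError(f"negative vertex index in {line!r}")
            edges.append((u, v))
        if directed is None:
            raise FormatError("missing 'directed=...' header line")
        n = n_declared if n_declared is not None else (max((max(e) for e in edges), default=-1) + 1)
        if n < 1:
            raise FormatError("edge list declares no vertices")
        try:
            return Graph(n, edges, undirected=not directed)
        except Exception as exc:
            raise FormatError(str(exc)) from exc
    finally:
        if close:
            stream.close()


def load_graph(path: str) -> Graph:
    """Load a graph from a path, dispatching on suffix (.g6/.graph6 vs .tsv)."""
    if path.endswith((".g6", ".graph6")):
        with open(path) as fh:
            return read_graph6(fh.read())
    return read_edge_list(path)
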