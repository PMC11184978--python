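"""Undirected simple graphs: loading, validation, components, degree statistics.

Node labels are arbitrary strings kept in first-appearance order and mapped
internally to contiguous 0-based indices; all matrix-valued results are
aligned with that order.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence, TextIO

import networkx as nx
import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "Graph",
    "DegreeStats",
    "GraphFormatError",
    "read_edge_list",
    "read_adjacency_matrix",
    "write_edge_list",
    "giant_connected_component",
    "degree_stats",
]


class GraphFormatError(ValueError):
    """Raised when an edge-list or adjacency-matrix source is malformed."""


class Graph:
    """A simple undirected graph.

    Parameters
    ----------
    nodes:
        Node labels in the order they should be indexed. Labels are
        coerced to ``str`` and must be unique.
    edges:
        Iterable of index pairs ``(i, j)`` with ``i != j``. Duplicates
        collapse silently (the edge set is a set); self-loops are an error
        here — the lenient readers drop them before construction.
    """

    __slots__ = ("nodes", "edges", "_index")

    def __init__(self, nodes: Iterable, edges: Iterable[tuple[int, int]]):
        self.nodes: tuple[str, ...] = tuple(str(u) for u in nodes)
        if len(set(self.nodes)) != len(self.nodes):
            raise ValueError("duplicate node labels")
        if not self.nodes:
            raise ValueError("a graph needs at least one node")
        self._index = {u: i for i, u in enumerate(self.nodes)}
        n = len(self.nodes)
        es: set[tuple[int, int]] = set()
        for i, j in edges:
            i, j = int(i), int(j)
            if not (0 <= i < n and 0 <= j < n):
                raise ValueError(f"edge ({i}, {j}) references a missing node")
            if i == j:
                raise ValueError(f"self-loop on node index {i}")
            es.add((i, j) if i < j else (j, i))
        self.edges: frozenset[tuple[int, int]] = frozenset(es)

    # -- basic accessors -------------------------------------------------

    @property
    def n(self) -> int:
        """Number of nodes N."""
        return len(self.nodes)

    @property
    def w(self) -> int:
        """Number of edges W."""
        return len(self.edges)

    def index(self, label) -> int:
        """0-based index of a node label."""
        return self._index[str(label)]

    def degrees(self) -> np.ndarray:
        d = np.zeros(self.n, dtype=np.int64)
        for i, j in self.edges:
            d[i] += 1
            d[j] += 1
        return d

    def adjacency(self, dtype=np.int64) -> np.ndarray:
        """Dense symmetric 0/1 adjacency matrix with zero diagonal."""
        a = np.zeros((self.n, self.n), dtype=dtype)
        for i, j in self.edges:
            a[i, j] = 1
            a[j, i] = 1
        return a

    def neighbor_lists(self) -> list[list[int]]:
        adj: list[list[int]] = [[] for _ in range(self.n)]
        for i, j in self.edges:
            adj[i].append(j)
            adj[j].append(i)
        return adj

    # -- conversions -----------------------------------------------------

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from((self.nodes[i], self.nodes[j]) for i, j in self.edges)
        return g

    @classmethod
    def from_networkx(cls, g: nx.Graph) -> "Graph":
        nodes = list(g.nodes())
        index = {u: i for i, u in enumerate(nodes)}
        return cls(nodes, ((index[u], index[v]) for u, v in g.edges() if u != v))

    def subgraph(self, indices: Sequence[int]) -> "Graph":
        """Induced subgraph on ``indices``, preserving relative node order."""
        keep = sorted(set(int(i) for i in indices))
        remap = {old: new for new, old in enumerate(keep)}
        labels = [self.nodes[i] for i in keep]
        edges = [
            (remap[i], remap[j]) for i, j in self.edges if i in remap and j in remap
        ]
        return Graph(labels, edges)

    # -- dunder ----------------------------------------------------------

    def __eq__(self, other) -> bool:
        if not isinstance(other, Graph):
            return NotImplemented
        return self.nodes == other.nodes and self.edges == other.edges

    def __hash__(self) -> int:
        return hash((self.nodes, self.edges))

    def __repr__(self) -> str:
        return f"Graph(n={self.n}, w={self.w})"


@dataclass(frozen=True)
class DegreeStats:
    """Elementary degree statistics of a graph.

    ``edge_density`` is p_edge = <k>/(N-1), the fraction of possible edges
    present; ``degree_distribution`` maps each observed degree d to its
    empirical probability P(d), summing to 1.
    """

    degrees: np.ndarray
    mean_degree: float
    edge_density: float
    degree_distribution: dict[int, float]


def _as_stream(source) -> TextIO:
    if hasattr(source, "read"):
        return source
    return open(source, "r", encoding="utf-8")


def read_edge_list(source, delimiter: str | None = None) -> Graph:
    """Read a two-column edge list into a :class:`Graph`.

    Lines starting with ``#`` or ``%`` and blank lines are ignored. The
    delimiter is auto-detected from the first data line (comma if present,
    otherwise any whitespace) unless given. Duplicate edges and self-loops
    are dropped with a logged count, since public edge lists commonly
    contain them. Node order is first-appearance order.
    """
    stream = _as_stream(source)
    close = stream is not source
    try:
        order: list[str] = []
        index: dict[str, int] = {}
        edges: set[tuple[int, int]] = set()
        loops = dupes = 0
        for lineno, raw in enumerate(stream, start=1):
            line = raw.strip()
            if not line or line[0] in "#%":
                continue
            if delimiter is None:
                delimiter = "," if "," in line else None
                tokens = line.split(delimiter)
                if delimiter is None:
                    delimiter = " "  # lock in whitespace splitting
                    tokens = line.split()
            else:
                tokens = line.split() if delimiter == " " else line.split(delimiter)
            tokens = [t.strip() for t in tokens if t.strip()]
            if len(tokens) != 2:
                raise GraphFormatError(
                    f"line {lineno}: expected 2 node tokens, got {len(tokens)}: {line!r}"
                )
            pair = []
            for tok in tokens:
                if tok not in index:
                    index[tok] = len(order)
                    order.append(tok)
                pair.append(index[tok])
            i, j = pair
            if i == j:
                loops += 1
                continue
            key = (i, j) if i < j else (j, i)
            if key in edges:
                dupes += 1
            else:
                edges.add(key)
        if not order:
            raise GraphFormatError("empty input: no edges or nodes found")
        if loops or dupes:
            logger.warning(
                "dropped %d self-loop(s) and %d duplicate edge(s)", loops, dupes
            )
        return Graph(order, edges)
    finally:
        if close:
            stream.close()


def read_adjacency_matrix(source, delimiter: str | None = None) -> Graph:
    """Read a dense 0/1 adjacency matrix from delimited numeric text.

    The matrix must be square, symmetric, with a zero diagonal. Nodes are
    labelled by their 0-based row index.
    """
    stream = _as_stream(source)
    close = stream is not source
    try:
        text = stream.read()
    finally:
        if close:
            stream.close()
    if not text.strip():
        raise GraphFormatError("empty input")
    if delimiter is None and "," in text:
        delimiter = ","
    try:
        a = np.loadtxt(io.StringIO(text), delimiter=delimiter, ndmin=2)
    except ValueError as exc:
        raise GraphFormatError(f"could not parse adjacency matrix: {exc}") from exc
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise GraphFormatError(f"adjacency matrix must be square, got shape {a.shape}")
    if not np.isin(a, (0, 1)).all():
        raise GraphFormatError("adjacency entries must be 0 or 1")
    if not np.array_equal(a, a.T):
        raise GraphFormatError("adjacency matrix must be symmetric")
    if np.trace(a) != 0:
        logger.warning("dropped %d self-loop(s) from adjacency diagonal",
                       int(np.trace(a)))
        np.fill_diagonal(a, 0)
    n = a.shape[0]
    ii, jj = np.nonzero(np.triu(a, k=1))
    return Graph([str(i) for i in range(n)], zip(ii.tolist(), jj.tolist()))


def write_edge_list(g: Graph, sink, header: str | None = None) -> None:
    """Write sorted ``u v`` lines; an optional header is emitted as comments."""
    stream = sink if hasattr(sink, "write") else open(sink, "w", encoding="utf-8")
    close = stream is not sink
    try:
        if header:
            for line in header.splitlines():
                stream.write(f"# {line}\n")
        for i, j in sorted(g.edges):
            stream.write(f"{g.nodes[i]} {g.nodes[j]}\n")
    finally:
        if close:
            stream.close()


def connected_components(g: Graph) -> list[list[int]]:
    """Connected components as lists of node indices, each sorted ascending."""
    adj = g.neighbor_lists()
    seen = [False] * g.n
    comps: list[list[int]] = []
    for start in range(g.n):
        if seen[start]:
            continue
        stack = [start]
        seen[start] = True
        comp = []
        while stack:
            v = stack.pop()
            comp.append(v)
            for w in adj[v]:
                if not seen[w]:
                    seen[w] = True
                    stack.append(w)
        comps.append(sorted(comp))
    return comps


def is_connected(g: Graph) -> bool:
    return len(connected_components(g)) == 1


def giant_connected_component(g: Graph) -> Graph:
    """Induced subgraph on the largest connected component.

    Ties are broken by the smallest minimum node index. A connected input
    is returned as an identical graph (the operation is idempotent).
    """
    comps = connected_components(g)
    best = max(comps, key=lambda c: (len(c), -c[0]))
    if len(best) == g.n:
        return g
    return g.subgraph(best)


def degree_stats(g: Graph) -> DegreeStats:
    """Degrees, mean degree <k>, edge density p_edge, and the empirical P(d).

    Requires N >= 2, since p_edge = <k>/(N-1) is undefined for a single node.
    """
    if g.n < 2:
        raise ValueError("degree statistics require at least 2 nodes")
    d = g.degrees()
    mean_k = float(d.mean())
    values, counts = np.unique(d, return_counts=True)
    dist = {int(v): float(c) / g.n for v, c in zip(values, counts)}
    return DegreeStats(
        degrees=d,
        mean_degree=mean_k,
        edge_density=mean_k / (g.n - 1),
        degree_distribution=dist,
    )
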