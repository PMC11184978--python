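"""All-pairs geodesic counting and the path-hesitation metrics.

The number of shortest paths between a node pair — its *path hesitation
amount* (PHA), h_ij — measures routing-choice diversity. Aggregating over
pairs gives a per-node *path hesitation degree* (PHD)

    d~_i = (1/(N-1)) * sum_{j != i} h_ij,

and a network-level *path hesitation index* (PHI)

    Phi(G) = sum_i sum_{j != i} h_ij / (N (N-1)) >= 1,

which equals 1 exactly when every node pair has a unique geodesic (trees,
stars, complete graphs).

Two independent implementations are provided: a matrix-power algorithm
(:func:`pha_matrix_fast`) that accumulates counts from successive powers of
the adjacency matrix, masking already-resolved pairs with a Hadamard
product, and a per-source BFS (:func:`pha_matrix_oracle`) counting
predecessors along the shortest-path DAG. Both return exact integers: the
fast path runs in int64 and promotes to arbitrary-precision Python integers
before any entry could overflow.
"""

from __future__ import annotations

from collections import Counter, deque
from dataclasses import dataclass

import numpy as np

from .graph import Graph

__all__ = [
    "PathHesitationResult",
    "PHADistribution",
    "DisconnectedGraphError",
    "pha_matrix_fast",
    "pha_matrix_oracle",
    "phd_vector",
    "phi_index",
    "pha_distribution",
    "phi_from_pair_counts",
]


class DisconnectedGraphError(ValueError):
    """The graph is disconnected; path metrics need one component."""


@dataclass(frozen=True)
class PathHesitationResult:
    """Shortest-path counts and lengths for all node pairs.

    ``H`` is the N x N path hesitation matrix of geodesic counts h_ij
    (symmetric, zero diagonal, exact integers); ``L`` is the matching
    matrix of geodesic lengths l_ij. Rows and columns follow ``nodes``.
    """

    H: np.ndarray
    L: np.ndarray
    nodes: tuple[str, ...]

    @property
    def n(self) -> int:
        return len(self.nodes)

    @property
    def phd(self) -> np.ndarray:
        return phd_vector(self)

    @property
    def phi(self) -> float:
        return phi_index(self)


@dataclass(frozen=True)
class PHADistribution:
    """Empirical distribution of a positive-integer pair statistic.

    Built from PHA values (one count per unordered node pair) but equally
    usable for any discrete positive support. ``probability[h]`` is
    ``pair_counts[h]`` divided by the total number of pairs.
    """

    support: np.ndarray
    probability: dict[int, float]
    pair_counts: dict[int, int]
    max_value: int

    @classmethod
    def from_counts(cls, counts: dict[int, int]) -> "PHADistribution":
        total = sum(counts.values())
        if total == 0:
            raise ValueError("empty distribution")
        support = np.array(sorted(counts), dtype=np.int64)
        prob = {int(h): counts[h] / total for h in support}
        return cls(
            support=support,
            probability=prob,
            pair_counts={int(h): int(counts[h]) for h in support},
            max_value=int(support[-1]),
        )


# Promote to Python-int arithmetic before a matmul could exceed int64:
# each product entry is bounded by N * max(Ak), so guard at 2^62 / N.
_INT64_GUARD = 2**62


def _next_power(ak: np.ndarray, a: np.ndarray) -> np.ndarray:
    if ak.dtype == object:
        return ak @ a.astype(object)
    if int(ak.max()) > _INT64_GUARD // ak.shape[0]:
        return ak.astype(object) @ a.astype(object)
    return ak @ a


def pha_matrix_fast(g: Graph, max_diameter: int | None = None) -> PathHesitationResult:
    """Count all-pairs shortest paths by accumulating adjacency powers.

    At step k the entry (A^k)_ij counts walks of length k from i to j; for
    the *first* k at which it is non-zero, walks cannot revisit a node, so
    the entry is exactly the geodesic count h_ij and l_ij = k. The mask T
    (1 where h_ij is still 0, off-diagonal only) freezes resolved pairs:
    H += T o A^k, L gets k on newly resolved entries, and the loop ends
    when every off-diagonal pair is resolved. Complexity is
    O(diameter * N^3).

    The diagonal is masked permanently (h_ii = 0 by definition, even though
    A^k develops non-zero diagonal entries). Raises
    :class:`DisconnectedGraphError` if unresolved pairs remain once k
    exceeds N-1, the longest possible geodesic.
    """
    n = g.n
    if n < 2:
        raise ValueError("path hesitation requires at least 2 nodes")
    a = g.adjacency(np.int64)
    h = np.zeros((n, n), dtype=np.int64)
    length = np.zeros((n, n), dtype=np.int64)
    offdiag = ~np.eye(n, dtype=bool)
    limit = max_diameter if max_diameter is not None else n - 1
    ak = a.copy()
    k = 1
    while True:
        unresolved = offdiag & (h == 0)
        if not unresolved.any():
            break
        if k > limit:
            raise DisconnectedGraphError(
                "graph is disconnected (or max_diameter too small); "
                "extract the giant connected component first"
            )
        newly = unresolved & (ak != 0)
        if ak.dtype == object and h.dtype != object:
            h = h.astype(object)
        h[newly] = ak[newly]
        length[newly] = k
        k += 1
        if (offdiag & (h == 0)).any():
            ak = _next_power(ak, a)
    return PathHesitationResult(H=h, L=length, nodes=g.nodes)


def pha_matrix_oracle(g: Graph) -> PathHesitationResult:
    """Independent geodesic counter: one BFS per source.

    Accumulates sigma counts along the shortest-path DAG (each node's count
    is the sum over its predecessors), in exact Python integers. Output
    contract is identical to :func:`pha_matrix_fast`.
    """
    n = g.n
    if n < 2:
        raise ValueError("path hesitation requires at least 2 nodes")
    adj = g.neighbor_lists()
    h_rows: list[list[int]] = []
    l_rows: list[list[int]] = []
    for s in range(n):
        dist = [-1] * n
        sigma = [0] * n
        dist[s] = 0
        sigma[s] = 1
        queue = deque([s])
        while queue:
            v = queue.popleft()
            for w in adj[v]:
                if dist[w] < 0:
                    dist[w] = dist[v] + 1
                    queue.append(w)
                if dist[w] == dist[v] + 1:
                    sigma[w] += sigma[v]
        if min(dist) < 0:
            raise DisconnectedGraphError(
                "graph is disconnected; extract the giant connected component first"
            )
        sigma[s] = 0
        h_rows.append(sigma)
        l_rows.append(dist)
    h = np.array(h_rows)  # int64, or object if counts exceed 2^63
    length = np.array(l_rows, dtype=np.int64)
    return PathHesitationResult(H=h, L=length, nodes=g.nodes)


def phd_vector(result: PathHesitationResult) -> np.ndarray:
    """Per-node mean PHA over the other N-1 nodes, as float64."""
    n = result.n
    return result.H.sum(axis=1).astype(np.float64) / (n - 1)


def phi_index(result: PathHesitationResult) -> float:
    """Network mean PHA over ordered pairs; >= 1 for connected graphs."""
    n = result.n
    return float(result.H.sum()) / (n * (n - 1))


def phi_from_pair_counts(pair_counts: dict[int, int], n: int) -> float:
    """PHI from a multiset of unordered-pair PHA values.

    Each unordered pair contributes twice to the ordered-pair sum, so
    Phi = 2 * sum_h h * count(h) / (N (N-1)). The pair counts must cover
    all N(N-1)/2 pairs.
    """
    total_pairs = sum(pair_counts.values())
    expected = n * (n - 1) // 2
    if total_pairs != expected:
        raise ValueError(
            f"pair counts cover {total_pairs} pairs but N={n} has {expected}"
        )
    return 2.0 * sum(h * c for h, c in pair_counts.items()) / (n * (n - 1))


def pha_distribution(result: PathHesitationResult) -> PHADistribution:
    """Empirical P(h) over unordered node pairs (each pair counted once)."""
    n = result.n
    iu = np.triu_indices(n, k=1)
    counts = Counter(int(v) for v in result.H[iu])
    return PHADistribution.from_counts(counts)
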