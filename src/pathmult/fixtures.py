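"""Deterministic toy topologies used throughout the tests and docs.

Each fixture regenerates bit-identically. ``fig1_union`` is the 6-node,
8-edge graph formed by the union of four length-3 geodesics between v1 and
v6 (via v2/v4 then v3/v5) — the canonical worked example of a node pair
with path hesitation amount 4.
"""

from __future__ import annotations

import networkx as nx

from .graph import Graph

__all__ = ["make_fixture", "FIXTURE_NAMES"]


def _tree(n: int = 10, seed: int = 0) -> Graph:
    return Graph.from_networkx(nx.random_labeled_tree(n, seed=seed))


def _star(n: int = 10) -> Graph:
    # node 0 is the hub
    return Graph(range(n), ((0, i) for i in range(1, n)))


def _complete(n: int = 10) -> Graph:
    return Graph(range(n), ((i, j) for i in range(n) for j in range(i + 1, n)))


def _ring(n: int = 10, half_k: int = 2) -> Graph:
    # each node linked to half_k nearest neighbours per side
    return Graph.from_networkx(nx.circulant_graph(n, list(range(1, half_k + 1))))


def _grid(rows: int = 4, cols: int = 4) -> Graph:
    g = nx.grid_2d_graph(rows, cols)  # 4-neighbour lattice, open boundary
    return Graph.from_networkx(nx.relabel_nodes(g, {t: f"{t[0]},{t[1]}" for t in g}))


def _hypercube(dim: int = 3) -> Graph:
    g = nx.hypercube_graph(dim)
    return Graph.from_networkx(
        nx.relabel_nodes(g, {t: "".join(map(str, t)) for t in g})
    )


def _fig1_union() -> Graph:
    labels = ["v1", "v2", "v3", "v4", "v5", "v6"]
    pairs = [
        ("v1", "v2"),
        ("v2", "v3"),
        ("v3", "v6"),
        ("v2", "v5"),
        ("v5", "v6"),
        ("v1", "v4"),
        ("v4", "v3"),
        ("v4", "v5"),
    ]
    index = {u: i for i, u in enumerate(labels)}
    return Graph(labels, ((index[u], index[v]) for u, v in pairs))


_BUILDERS = {
    "tree": _tree,
    "star": _star,
    "complete": _complete,
    "ring": _ring,
    "grid": _grid,
    "hypercube": _hypercube,
    "fig1_union": _fig1_union,
}

FIXTURE_NAMES = tuple(sorted(_BUILDERS))


def make_fixture(name: str, **params) -> Graph:
    """Build a named toy topology.

    Known names: tree(n, seed), star(n), complete(n), ring(n, half_k),
    grid(rows, cols), hypercube(dim), fig1_union().
    """
    try:
        builder = _BUILDERS[name]
    except KeyError:
        raise ValueError(
            f"unknown fixture {name!r}; available: {', '.join(FIXTURE_NAMES)}"
        ) from None
    return builder(**params)
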