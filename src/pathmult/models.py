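"""Random-graph reference models: ER, NW, BA, and clustered BA (CBA).

These are the standard null models against which path-multiplicity levels
of a target network are judged: Erdős–Rényi random graphs, Newman–Watts
small-world graphs (ring lattice plus random shortcuts — shortcuts are
*added*, no edges are rewired away), Barabási–Albert preferential
attachment, and a clustered BA variant with a triad-formation step that
raises the clustering coefficient while keeping the scale-free degree
distribution.

:func:`matched_reference` picks model parameters so the expected edge count
matches a target graph's, reproducing the size-and-density-matched
comparison design.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .graph import Graph, giant_connected_component, is_connected

__all__ = ["ModelConfig", "generate", "matched_reference", "MODELS"]

MODELS = ("er", "nw", "ba", "cba")


@dataclass(frozen=True)
class ModelConfig:
    """Parameters for one model draw.

    model:   one of "er", "nw", "ba", "cba"
    n:       node count
    p:       ER edge probability
    p_tilde: NW shortcut probability per lattice edge
    k_ring:  NW base-ring neighbour count (even, split across both sides)
    m0:      BA/CBA seed-clique size
    m:       BA/CBA edges attached per arriving node
    ms:      CBA triad-formation edges per preferentially attached target
    seed:    RNG seed; identical configs reproduce identical edge sets
    """

    model: str
    n: int
    p: float | None = None
    p_tilde: float | None = None
    k_ring: int | None = None
    m0: int | None = None
    m: int | None = None
    ms: int | None = None
    seed: int = 0

    def validate(self) -> None:
        if self.model not in MODELS:
            raise ValueError(f"unknown model {self.model!r}; choose from {MODELS}")
        if self.n < 2:
            raise ValueError("n must be at least 2")
        if self.model == "er":
            if self.p is None or not 0 <= self.p <= 1:
                raise ValueError("ER requires edge probability p in [0, 1]")
        elif self.model == "nw":
            if self.p_tilde is None or not 0 <= self.p_tilde <= 1:
                raise ValueError("NW requires shortcut probability p_tilde in [0, 1]")
            if self.k_ring is None or self.k_ring < 2 or self.k_ring % 2:
                raise ValueError("NW requires an even base-ring degree k_ring >= 2")
            if self.k_ring >= self.n:
                raise ValueError("k_ring must be smaller than n")
        else:
            m0 = self.m0 if self.m0 is not None else self.m
            if self.m is None or m0 is None or not 1 <= self.m <= m0 < self.n:
                raise ValueError("BA/CBA require 1 <= m <= m0 < n")
            if self.model == "cba":
                if self.ms is None or not 0 <= self.ms <= self.m:
                    raise ValueError("CBA requires 0 <= ms <= m")


def _ba_cba(n: int, m0: int, m: int, ms: int, rng: np.random.Generator) -> Graph:
    """Growth with preferential attachment from an m0-clique seed.

    Each arriving node attaches m edges to distinct existing nodes sampled
    proportionally to current degree (without replacement). With ms > 0,
    each attachment triggers triad formation: ms extra edges from the new
    node to random neighbours of the attached target — or to all eligible
    neighbours when fewer than ms remain.
    """
    adj: list[set[int]] = [set() for _ in range(n)]
    repeated: list[int] = []  # degree-weighted sampling pool

    def add_edge(u: int, v: int) -> None:
        adj[u].add(v)
        adj[v].add(u)
        repeated.append(u)
        repeated.append(v)

    for i in range(m0):
        for j in range(i + 1, m0):
            add_edge(i, j)

    for v in range(m0, n):
        targets: set[int] = set()
        while len(targets) < m:
            u = repeated[int(rng.integers(len(repeated)))]
            if u != v:
                targets.add(u)
        for u in targets:
            add_edge(v, u)
        if ms:
            for u in list(targets):
                eligible = [w for w in adj[u] if w != v and w not in adj[v]]
                if len(eligible) > ms:
                    idx = rng.choice(len(eligible), size=ms, replace=False)
                    chosen = [eligible[int(i)] for i in idx]
                else:
                    chosen = eligible  # saturation: connect to all that remain
                for w in chosen:
                    add_edge(v, w)

    edges = [(u, v) for u in range(n) for v in adj[u] if u < v]
    return Graph(range(n), edges)


def generate(config: ModelConfig) -> Graph:
    """Draw one graph from the configured model.

    All outputs are simple undirected graphs on exactly ``n`` nodes;
    identical configs (including seed) yield identical edge sets.
    """
    config.validate()
    n, seed = config.n, config.seed
    if config.model == "er":
        g = nx.gnp_random_graph(n, config.p, seed=seed)
        return Graph.from_networkx(g)
    if config.model == "nw":
        g = nx.newman_watts_strogatz_graph(n, config.k_ring, config.p_tilde, seed=seed)
        return Graph.from_networkx(g)
    rng = np.random.default_rng(seed)
    m0 = config.m0 if config.m0 is not None else config.m
    ms = config.ms if config.model == "cba" else 0
    return _ba_cba(n, m0, config.m, ms or 0, rng)


def _draw_connected(make_config, seed: int, retries: int = 100) -> Graph:
    """Redraw a stochastic model until connected, else fall back to the GCC.

    Child seeds derive deterministically from ``seed`` so matched references
    are reproducible.
    """
    rng = np.random.default_rng(seed)
    child_seeds = rng.integers(2**31, size=retries)
    g = None
    for s in child_seeds:
        g = generate(make_config(int(s)))
        if is_connected(g):
            return g
    return giant_connected_component(g)


def matched_reference(
    target: Graph, model: str, seed: int, ms: int = 1
) -> Graph:
    """A model graph with the target's size and (as near as possible) density.

    ER: p set to the target's edge density. BA: m = round(W/N). CBA: m
    chosen so that the expected m*(1+ms) edges per arriving node match W/N.
    NW: k_ring = 2*floor(W/N) ring edges plus shortcuts with probability
    set so the expected total equals W. Disconnected draws are retried up
    to 100 times before falling back to the giant component, so the path
    hesitation index is always defined on the result.
    """
    if model not in MODELS:
        raise ValueError(f"unknown model {model!r}; choose from {MODELS}")
    n, w = target.n, target.w
    if n < 10:
        raise ValueError("matched references need a target with at least 10 nodes")
    if not is_connected(target):
        raise ValueError("target must be connected; extract its giant component")
    p_edge = 2.0 * w / (n * (n - 1))

    if model == "er":
        return _draw_connected(
            lambda s: ModelConfig(model="er", n=n, p=p_edge, seed=s), seed
        )
    if model == "nw":
        k_ring = 2 * (w // n)
        if k_ring < 2:
            closest = 2.0 / (n - 1)
            raise ValueError(
                f"target density {p_edge:.4g} unreachable by NW: the sparsest "
                f"ring (k_ring=2) already has density {closest:.4g}"
            )
        ring_edges = n * k_ring // 2
        p_tilde = min(1.0, (w - ring_edges) / ring_edges)
        return _draw_connected(
            lambda s: ModelConfig(
                model="nw", n=n, k_ring=k_ring, p_tilde=p_tilde, seed=s
            ),
            seed,
        )
    if model == "ba":
        m = max(1, round(w / n))
        return generate(ModelConfig(model="ba", n=n, m=m, m0=m, seed=seed))
    # cba: each arriving node adds about m*(1+ms) edges
    m = max(1, round(w / (n * (1 + ms))))
    return generate(
        ModelConfig(model="cba", n=n, m=m, m0=m, ms=min(ms, m), seed=seed)
    )
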