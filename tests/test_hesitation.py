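"""Geodesic counting: closed forms, worked example, and oracle equivalence."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pathmult import (
    DisconnectedGraphError,
    Graph,
    make_fixture,
    pha_distribution,
    pha_matrix_fast,
    pha_matrix_oracle,
    phd_vector,
    phi_from_pair_counts,
    phi_index,
)

from conftest import random_connected_graph


@pytest.mark.parametrize("algo", [pha_matrix_fast, pha_matrix_oracle])
class TestClosedForms:
    def test_complete_graph_all_single_geodesics(self, algo):
        g = make_fixture("complete", n=4)
        res = algo(g)
        off = ~np.eye(4, dtype=bool)
        assert np.all(res.H[off] == 1) and np.all(res.L[off] == 1)
        assert phi_index(res) == 1.0

    def test_even_cycle_antipodal_two_arcs(self, algo):
        g = make_fixture("ring", n=6, half_k=1)
        res = algo(g)
        i, j = g.index("0"), g.index("3")
        assert res.L[i, j] == 3 and res.H[i, j] == 2

    @pytest.mark.parametrize("rows,cols", [(4, 4), (3, 5), (2, 7)])
    def test_grid_corner_binomial(self, algo, rows, cols):
        # corner-to-corner geodesics = lattice paths: C((a-1)+(b-1), a-1)
        g = make_fixture("grid", rows=rows, cols=cols)
        res = algo(g)
        i, j = g.index("0,0"), g.index(f"{rows-1},{cols-1}")
        assert res.L[i, j] == (rows - 1) + (cols - 1)
        assert res.H[i, j] == math.comb(rows + cols - 2, rows - 1)

    @pytest.mark.parametrize("dim", [3, 4])
    def test_hypercube_antipodal_factorial(self, algo, dim):
        g = make_fixture("hypercube", dim=dim)
        res = algo(g)
        i, j = g.index("0" * dim), g.index("1" * dim)
        assert res.H[i, j] == math.factorial(dim)

    def test_trees_have_unique_geodesics(self, algo):
        for g in (make_fixture("tree", n=12, seed=3), make_fixture("star", n=6),
                  Graph(range(5), [(0, 1), (1, 2), (2, 3), (3, 4)])):
            res = algo(g)
            off = ~np.eye(g.n, dtype=bool)
            assert np.all(res.H[off] == 1)
            assert phi_index(res) == 1.0

    def test_disconnected_graph_rejected(self, algo):
        g = Graph(range(4), [(0, 1), (2, 3)])
        with pytest.raises(DisconnectedGraphError, match="giant"):
            algo(g)

    def test_single_node_rejected(self, algo):
        with pytest.raises(ValueError):
            algo(Graph(["a"], []))


class TestWorkedExample:
    """The 6-node union of four length-3 geodesics between v1 and v6."""

    def test_pair_count_and_length(self, fig1_union):
        res = pha_matrix_fast(fig1_union)
        i, j = fig1_union.index("v1"), fig1_union.index("v6")
        assert res.H[i, j] == 4 and res.L[i, j] == 3

    def test_phd_of_v1(self, fig1_union):
        res = pha_matrix_fast(fig1_union)
        # row of v1: h to v2..v6 is (1, 2, 1, 2, 4) -> mean 2
        assert phd_vector(res)[fig1_union.index("v1")] == pytest.approx(2.0)

    def test_phi(self, fig1_union):
        res = pha_matrix_fast(fig1_union)
        assert phi_index(res) == pytest.approx(52 / 30)

    def test_pair_count_multiset(self, fig1_union):
        dist = pha_distribution(pha_matrix_fast(fig1_union))
        assert dist.pair_counts == {1: 8, 2: 4, 3: 2, 4: 1}
        assert dist.max_value == 4
        assert sum(dist.probability.values()) == pytest.approx(1.0)


class TestPhiFromPairCounts:
    def test_seven_node_example(self):
        phi = phi_from_pair_counts({1: 14, 2: 4, 3: 2, 4: 1}, n=7)
        assert round(phi, 4) == 1.5238

    def test_incomplete_pair_cover_rejected(self):
        with pytest.raises(ValueError, match="pairs"):
            phi_from_pair_counts({1: 5}, n=7)


@given(st.integers(0, 10_000))
@settings(max_examples=40, derandomize=True, deadline=None)
def test_fast_equals_oracle(seed):
    """Matrix-power and BFS implementations agree exactly on H and L."""
    g = random_connected_graph(np.random.default_rng(seed), n_max=40)
    fast, oracle = pha_matrix_fast(g), pha_matrix_oracle(g)
    assert np.array_equal(fast.H, oracle.H)
    assert np.array_equal(fast.L, oracle.L)


@given(st.integers(0, 10_000))
@settings(max_examples=20, derandomize=True, deadline=None)
def test_walk_geodesic_identity(seed):
    """h_ij equals the (i,j) entry of A^l_ij: distance-length walks are geodesics."""
    g = random_connected_graph(np.random.default_rng(seed), n_max=25)
    res = pha_matrix_fast(g)
    a = g.adjacency(np.int64)
    powers = {1: a}
    for k in range(2, int(res.L.max()) + 1):
        powers[k] = powers[k - 1] @ a
    for i in range(g.n):
        for j in range(i + 1, g.n):
            assert res.H[i, j] == powers[int(res.L[i, j])][i, j]


@given(st.integers(0, 10_000))
@settings(max_examples=30, derandomize=True, deadline=None)
def test_phi_floor_and_symmetry(seed):
    """Phi >= 1 on every connected graph; H and L symmetric, zero diagonal."""
    g = random_connected_graph(np.random.default_rng(seed), n_max=30)
    res = pha_matrix_fast(g)
    assert phi_index(res) >= 1.0
    assert np.array_equal(res.H, res.H.T) and np.array_equal(res.L, res.L.T)
    assert np.all(np.diag(res.H) == 0) and np.all(np.diag(res.L) == 0)
    off = ~np.eye(g.n, dtype=bool)
    assert np.all(res.H[off] >= 1) and np.all(res.L[off] >= 1)


def test_lengths_match_bfs_distances(rng):
    import networkx as nx

    g = random_connected_graph(rng, n_max=40)
    res = pha_matrix_fast(g)
    dist = dict(nx.all_pairs_shortest_path_length(g.to_networkx()))
    for i, u in enumerate(g.nodes):
        for j, v in enumerate(g.nodes):
            assert res.L[i, j] == dist[u][v]


def test_exact_arithmetic_beyond_int64():
    """Intermediate walk counts past int64 promote to exact Python integers."""
    n_clique, n_tail = 12, 22
    edges = [(i, j) for i in range(n_clique) for j in range(i + 1, n_clique)]
    prev = 0
    for t in range(n_tail):
        edges.append((prev, n_clique + t))
        prev = n_clique + t
    g = Graph(range(n_clique + n_tail), edges)
    fast, oracle = pha_matrix_fast(g), pha_matrix_oracle(g)
    assert fast.H.dtype == object  # promotion actually happened
    assert np.array_equal(fast.H, oracle.H)
    assert np.array_equal(fast.L, oracle.L)


def test_max_diameter_cutoff_raises():
    g = Graph(range(5), [(0, 1), (1, 2), (2, 3), (3, 4)])
    with pytest.raises(DisconnectedGraphError):
        pha_matrix_fast(g, max_diameter=2)
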