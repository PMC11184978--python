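# pathmult

Shortest-path **multiplicity** analysis for undirected networks.

Most path-based network analysis asks *how long* the shortest path between
two nodes is. `pathmult` asks *how many* shortest paths there are. The
number of geodesics between a node pair — its **path hesitation amount**
(PHA), h_ij — measures routing-choice diversity: a pair with many equally
short routes forces a choice, a pair with one route does not. The package
is aimed at network scientists studying brain connectomes, infrastructure,
social and web graphs, who want to quantify this diversity and compare it
against classical metrics and random-graph null models.

## The quantities

For a simple connected undirected graph G(V, E) with N = |V| nodes,
adjacency matrix A and geodesic counts h_ij (h_ii = 0):

- **PHA** h_ij — number of shortest paths between v_i and v_j; the N×N
  matrix H is the path hesitation matrix.
- **PHD** (per node): d̃_i = (1/(N−1)) Σ_{j≠i} h_ij.
- **PHI** (per network): Φ(G) = Σ_i Σ_{j≠i} h_ij / (N(N−1)) ≥ 1, with
  Φ = 1 exactly when every pair has a unique geodesic (trees, stars,
  complete graphs).

H and L (geodesic lengths) are computed by a matrix-power scheme: the
first power k at which (A^k)_ij ≠ 0 gives l_ij = k and h_ij = (A^k)_ij,
so accumulating H += T ⊙ A^k with a mask T over still-unresolved pairs
resolves all pairs in O(diameter · N³) with exact integer arithmetic. An
independent per-source BFS oracle verifies every count in the tests.

The empirical distribution P(h) over node pairs (and P(d) over degrees) is
fitted with a power law p(x) = a·x^(−α) by nonlinear least squares over
the full support, with goodness of fit R² = 1 − SS_res/SS_tot. Matched
Erdős–Rényi, Newman–Watts, Barabási–Albert and clustered-BA reference
graphs with the same size and density provide null baselines for Φ.

## Worked example

The bundled `fig1_union` fixture is a 6-node, 8-edge graph formed by the
union of four length-3 geodesics between v1 and v6
(v1–v2–v3–v6, v1–v2–v5–v6, v1–v4–v3–v6, v1–v4–v5–v6):

```sh
$ pha fixture fig1_union -o fig1.edges
wrote fig1.edges: N=6 W=8
$ pha compute fig1.edges
# pathmult 0.1.0 | pha compute | input=fig1.edges giant=False oracle=False N=6 W=8
N=6 W=8 phi=1.7333 max_pha=4
$ pha report fig1.edges
N       mean_degree     p_edge  assortativity   clustering      avg_path_length phi
6       2.66667         0.533333        -0.333333       0       1.53333 1.73333
```

Φ = 1.7333 means the average node pair in this small graph has about 1.7
shortest paths; the most hesitant pair (v1, v6) has 4. The same numbers
from Python:

```python
from pathmult import make_fixture, pha_matrix_fast

g = make_fixture("fig1_union")
res = pha_matrix_fast(g)
i, j = g.index("v1"), g.index("v6")
res.H[i, j], res.L[i, j], round(res.phi, 4)   # (4, 3, 1.7333)
```

Other subcommands: `pha generate` / `pha match` for model networks,
`pha fit` for power-law fits of a distribution table, `pha compare` for a
Φ-vs-matched-models table.

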