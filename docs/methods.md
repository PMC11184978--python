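# Methods

## Model and definitions

`pathmult` operates on simple undirected graphs G(V, E): no self-loops, no
multi-edges, no weights or directions. All path metrics are defined on a
connected graph; disconnected inputs must first be reduced to their giant
connected component (`giant_connected_component`), mirroring standard
practice for empirical networks. For a pair (v_i, v_j), h_ij counts the
distinct geodesics (shortest paths) between them and l_ij their common
length. Aggregation is by plain averaging: PHD d̃_i averages row i of H
over the other N−1 nodes; PHI Φ(G) averages over all ordered pairs.
Φ(G) ≥ 1 always, with equality exactly when geodesics are unique
everywhere — trees, stars and complete graphs sit on the floor.

## The matrix-power counting algorithm

(A^k)_ij counts walks of length k between i and j. For the *smallest* k
with (A^k)_ij ≠ 0, no walk can revisit a node (a revisit would imply a
shorter i–j walk), so that entry is exactly the geodesic count. The
algorithm therefore iterates k = 1, 2, …, keeping a mask T of off-diagonal
pairs whose h is still zero, and accumulates H += T ⊙ A^k, L += k·1(T ⊙
A^k ≠ 0), terminating when no off-diagonal zero remains. Cost is
O(diameter · N³) via the incremental update A^k = A^(k−1)·A, against
O(N⁴) for per-pair path enumeration.

Numerical choices:

- **Diagonal masking.** A^k develops non-zero diagonal entries (closed
  walks); since h_ii = 0 by definition, the mask excludes the diagonal
  permanently rather than letting it fill.
- **Exact integers.** Geodesic counts are combinatorial and overflow is a
  correctness bug, not a warning. The fast path runs in int64 and promotes
  both A^k and H to Python-integer (object-dtype) arrays before any matmul
  could exceed int64 range (guard: max entry > 2^62 / N). The BFS oracle
  uses Python integers throughout. A dedicated test forces the promotion
  and checks exact agreement between the two implementations.
- **Termination bound.** A geodesic has length ≤ N−1; if unresolved pairs
  remain past k = N−1 the graph is disconnected and a
  `DisconnectedGraphError` directs the caller to the giant component.
- **Presentation.** d̃_i and Φ are exact integer sums divided once at the
  end; they are reported as float64 and rounded to 4 decimals only for
  display.

The independent oracle (`pha_matrix_oracle`) is a per-source BFS that
accumulates each node's geodesic count as the sum over its shortest-path
predecessors — the same sigma recurrence used in Brandes' betweenness
algorithm. The two implementations share no code beyond the graph type.

## Power-law fitting

The model p(x) = a·x^(−α) is fitted to the (support, probability) pairs of
an empirical distribution by nonlinear least squares in **linear
probability space** over the **full observed range** — no binning, no tail
truncation, no x_min selection (Clauset-style maximum likelihood is a
non-goal). R² = 1 − SS_res/SS_tot is computed on the same linear-space
values used for fitting. The default emulates common curve-fitting
toolbox behaviour; a `log_space=True` flag minimises log-residuals
instead. The degree distribution P(d) and the PHA distribution P(h) go
through the identical code path; only the input differs (exponents are
conventionally called λ_d and λ_h).

- Initialisation: α from the log–log regression slope, a from the first
  support point — deterministic and close enough for these unimodal
  problems.
- Convergence: residual-norm tolerance 1e−10, at most 10,000 evaluations;
  non-convergence raises with the last iterate.
- Degenerate inputs: fewer than 3 support points is under-determined and
  an error; a constant distribution is fitted exactly by α ≈ 0 (R² is
  reported as 1 for the residual-free constant fit, where the usual
  SS_tot-based formula is undefined).
- Estimator sensitivity: linear-space least squares weights the largest
  probabilities — i.e. the smallest support values — most heavily, so
  noise on the first support point moves α noticeably. Parameter-recovery
  tests use ~10% multiplicative (lognormal σ = 0.1) noise, the order of
  sampling error on empirical probabilities at the problem sizes used;
  recovery within 10% of the generating exponent should not be expected
  under much heavier noise with this estimator.

## Reference models

Four null models, all returning simple undirected graphs and reproducible
from a seed:

- **ER** — G(n, p), each pair independent with probability p.
- **NW** — Newman–Watts small world: ring lattice (each node tied to
  k_ring/2 neighbours per side, k_ring even) plus shortcut edges added
  with probability p̃ per lattice edge. Shortcuts are *added*, never
  rewired away — the literature sometimes labels p̃ a "rewiring
  probability", but the construction cited is shortcut addition, which is
  what is implemented.
- **BA** — growth with preferential attachment: seed clique on m0 nodes,
  each arriving node attaches m edges to distinct nodes sampled
  proportionally to degree without replacement. The seed topology is a
  design choice (a clique is the conventional default).
- **CBA** — BA plus triad formation: after each preferential attachment to
  a target u, ms extra edges join the new node to random neighbours of u,
  saturating to all eligible neighbours when fewer than ms remain. The
  extra triangles raise the clustering coefficient while preserving the
  scale-free degree distribution.

`matched_reference` matches a target's size exactly and its edge count in
expectation: ER takes p = p_edge of the target; NW takes k_ring =
2⌊W/N⌋ and p̃ = (W − ring)/ring so the expected total equals W (densities
below the sparsest ring are unreachable and raise); BA takes
m = round(W/N); CBA accounts for its ≈ m(1+ms) edges per arriving node and
takes m = round(W/(N(1+ms))) with ms = 1 by default. Disconnected ER/NW
draws are retried up to 100 times (child seeds derived deterministically
from the given seed) before falling back to the giant component, so Φ is
always defined on the result.

## Classical metrics

Per-network rows report N, ⟨k⟩, p_edge, assortativity r, clustering C,
mean geodesic length L_avg (reused from the L matrix) and Φ. Where the
convention was genuinely open, the defaults are: **Pearson** correlation
for the Φ-vs-metric table (Spearman via `method=`), and **mean local
clustering** for C (global transitivity via `clustering="global"`) —
both choices match common scatter-plot annotation practice.
Assortativity is undefined on degree-regular graphs and reported as nan;
a constant metric column likewise yields nan correlation rather than an
exception. Betweenness is accumulated directly from H and L — the pair
dependency of v for (s, t) is h_sv·h_vt/h_st when l_sv + l_vt = l_st —
normalised by (N−1)(N−2)/2, so the centrality table is consistent by
construction with the geodesic counts it sits next to; tests verify
agreement with Brandes accumulation.

## Synthetic data: what it does and does not show

All inputs are generated programmatically: deterministic toy topologies
(trees, stars, complete graphs, rings, open-boundary 4-neighbour grids,
hypercubes, and the 6-node geodesic-union worked example) with known
closed forms — corner-to-corner grid counts C((a−1)+(b−1), a−1), antipodal
hypercube counts n!, antipodal even-cycle counts 2 — plus the four random
models above. These exercise every operation and pin the arithmetic
exactly, and the model comparison reproduces the *direction* of the
empirical finding at desk scale (matched ER/NW references show lower Φ
than a clustered scale-free target; problem size N = 500, 20 seeds per
model). What passing tests do **not** show: the magnitudes seen in real
networks — PHI in the tens, maximum PHA in the thousands, and strong
power-law P(h) fits are properties of empirical corpora that no generator
here emulates, and real-data claims are outside what this synthetic suite
can certify.

## Known limitations

- Unweighted, undirected, single-component graphs only.
- Dense N×N matrices: memory is O(N²) and time O(diameter·N³), intended
  for desk-scale networks (up to a few thousand nodes), not web-scale
  graphs.
- The power-law fitter is a descriptive least-squares tool; it makes no
  claim of statistical model selection against alternatives.
- Geodesics are counted, never enumerated.
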