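"""Classical network metrics alongside the path hesitation index.

Global metrics follow the conventions used when annotating network
scatter plots: assortativity r is the Pearson degree–degree correlation
over edge endpoints, C is the mean local clustering coefficient (global
transitivity available via a flag), and L_avg is the mean geodesic length
over unordered pairs, reused from the path-hesitation computation.

Node centralities put PHD next to degree centrality and geodesic
betweenness. Betweenness here is accumulated directly from the geodesic
count matrix H and length matrix L — the pair-dependency of node v for a
pair (s, t) is H[s,v]*H[v,t]/H[s,t] whenever v lies on a geodesic
(L[s,v]+L[v,t] = L[s,t]) — so it is consistent by construction with the
counts the rest of the package reports. It agrees with Brandes-style
accumulation; the test suite checks that.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd

from .graph import Graph, is_connected
from .hesitation import PathHesitationResult, pha_matrix_fast, phd_vector, phi_index

__all__ = [
    "global_metrics",
    "node_centralities",
    "betweenness_from_counts",
    "top_k_overlap",
    "metric_correlations",
    "GLOBAL_METRIC_COLUMNS",
]

GLOBAL_METRIC_COLUMNS = (
    "N",
    "mean_degree",
    "p_edge",
    "assortativity",
    "clustering",
    "avg_path_length",
    "phi",
)


def global_metrics(
    g: Graph,
    ph: PathHesitationResult | None = None,
    clustering: str = "local",
) -> dict[str, float]:
    """One row of per-network metrics: N, <k>, p_edge, r, C, L_avg, Phi.

    ``clustering`` selects "local" (mean local clustering coefficient,
    default) or "global" (transitivity). Assortativity is reported as nan
    for degree-regular graphs, where the correlation is undefined.
    """
    if not is_connected(g):
        raise ValueError("global metrics require a connected graph")
    if ph is None:
        ph = pha_matrix_fast(g)
    if clustering not in ("local", "global"):
        raise ValueError("clustering must be 'local' or 'global'")
    gx = g.to_networkx()
    c = nx.average_clustering(gx) if clustering == "local" else nx.transitivity(gx)
    degs = g.degrees()
    if np.ptp(degs) == 0:
        r = float("nan")  # zero degree variance: correlation undefined
    else:
        with np.errstate(invalid="ignore", divide="ignore"):
            r = float(nx.degree_assortativity_coefficient(gx))
    n = g.n
    offdiag = ~np.eye(n, dtype=bool)
    l_avg = float(ph.L[offdiag].mean())
    mean_k = float(degs.mean())
    return {
        "N": float(n),
        "mean_degree": mean_k,
        "p_edge": mean_k / (n - 1),
        "assortativity": r,
        "clustering": float(c),
        "avg_path_length": l_avg,
        "phi": phi_index(ph),
    }


def betweenness_from_counts(H: np.ndarray, L: np.ndarray) -> np.ndarray:
    """Normalized geodesic betweenness from count and length matrices.

    B(v) = sum over unordered pairs {s,t} not containing v of
    sigma_st(v)/sigma_st, with sigma_st(v) = H[s,v]*H[v,t] when
    L[s,v] + L[v,t] = L[s,t], normalized by (N-1)(N-2)/2.
    """
    n = H.shape[0]
    hf = H.astype(np.float64)
    denom = np.where(hf > 0, hf, 1.0)
    b = np.zeros(n)
    for v in range(n):
        on_geodesic = (L[:, v, None] + L[None, v, :]) == L
        contrib = np.outer(hf[:, v], hf[v, :]) / denom
        contrib = np.where(on_geodesic, contrib, 0.0)
        contrib[v, :] = 0.0
        contrib[:, v] = 0.0
        np.fill_diagonal(contrib, 0.0)
        b[v] = contrib.sum() / 2.0  # each unordered pair appears twice
    norm = (n - 1) * (n - 2) / 2.0
    return b / norm if norm > 0 else b


def node_centralities(
    g: Graph, ph: PathHesitationResult | None = None
) -> pd.DataFrame:
    """Per-node table: degree centrality d_i/(N-1), betweenness, PHD.

    Rows are indexed by node label in graph order.
    """
    if ph is None:
        ph = pha_matrix_fast(g)
    n = g.n
    return pd.DataFrame(
        {
            "degree_centrality": g.degrees() / (n - 1),
            "betweenness": betweenness_from_counts(ph.H, ph.L),
            "phd": phd_vector(ph),
        },
        index=pd.Index(g.nodes, name="node"),
    )


def top_k_overlap(
    table: pd.DataFrame, metric_a: str, metric_b: str, k: int
) -> float:
    """Fraction of shared nodes among the top-k of two centrality columns.

    Ties are broken deterministically by node position in the table.
    """
    for name in (metric_a, metric_b):
        if name not in table.columns:
            raise KeyError(
                f"unknown metric {name!r}; available: {list(table.columns)}"
            )
    n = len(table)
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}]")

    def top_k(name: str) -> set[int]:
        values = table[name].to_numpy(dtype=np.float64)
        order = np.lexsort((np.arange(n), -values))
        return set(order[:k].tolist())

    return len(top_k(metric_a) & top_k(metric_b)) / k


def metric_correlations(
    reports: Iterable[Mapping[str, float]] | pd.DataFrame,
    method: str = "pearson",
) -> pd.Series:
    """Correlation of Phi against each global metric across networks.

    ``method`` is "pearson" (default) or "spearman". A constant column
    yields nan (undefined correlation), never an exception. Requires at
    least 3 networks.
    """
    if method not in ("pearson", "spearman"):
        raise ValueError("method must be 'pearson' or 'spearman'")
    df = reports if isinstance(reports, pd.DataFrame) else pd.DataFrame(list(reports))
    if len(df) < 3:
        raise ValueError("need at least 3 networks to correlate")
    if "phi" not in df.columns:
        raise ValueError("reports must contain a 'phi' column")
    out = {}
    for col in df.columns:
        if col == "phi":
            continue
        with np.errstate(invalid="ignore", divide="ignore"):
            out[col] = df["phi"].corr(df[col], method=method)
    return pd.Series(out, name=f"corr_phi_{method}")
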