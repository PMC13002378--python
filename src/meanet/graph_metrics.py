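"""Statistical metrics and centrality measures on binary functional graphs.

Conventions for the (common) multi-component case: the characteristic path
length averages over *connected* ordered pairs only (the excluded fraction is
reported); closeness — the unnormalized reciprocal of the total hop
distance — and eccentricity are computed within each node's
connected component; eigenvector centrality is the leading (Perron)
eigenvector of the full adjacency matrix, max-normalized, which concentrates
on the dominant component.  Betweenness is unnormalized with endpoints
excluded, each unordered pair counted once.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.sparse import csr_array
from scipy.sparse.csgraph import connected_components, shortest_path

from .spike_io import _check_square_symmetric


@dataclass
class Graph:
    """Binary symmetric graph with optional aligned weights."""

    A: np.ndarray
    node_ids: list[str] = field(default_factory=list)
    W: np.ndarray | None = None

    def __post_init__(self) -> None:
        A = _check_square_symmetric(self.A)
        if np.any((A != 0) & (A != 1)):
            raise ValueError("adjacency must be binary")
        if np.any(np.diag(A) != 0):
            raise ValueError("adjacency must have zero diagonal")
        self.A = A.astype(int)
        if not self.node_ids:
            self.node_ids = [str(i) for i in range(A.shape[0])]
        if self.W is not None:
            W = _check_square_symmetric(self.W)
            if np.any((W != 0) != (self.A != 0)):
                raise ValueError("weights must be nonzero exactly where A = 1")
            self.W = W

    @classmethod
    def from_connectivity(cls, conn, sign: str = "pos") -> "Graph":
        if sign == "pos":
            return cls(A=conn.A_pos.copy(), node_ids=list(conn.unit_ids),
                       W=conn.W_pos.copy())
        return cls(A=conn.A_neg.copy(), node_ids=list(conn.unit_ids),
                   W=conn.W_neg.copy())

    @property
    def n(self) -> int:
        return int(self.A.shape[0])

    @property
    def m(self) -> int:
        return int(self.A.sum() // 2)

    def to_networkx(self) -> nx.Graph:
        G = nx.from_numpy_array(self.A)
        return nx.relabel_nodes(G, dict(enumerate(self.node_ids)))


def _distances(A: np.ndarray) -> np.ndarray:
    """All-pairs hop distances (inf across components)."""
    if A.shape[0] == 0:
        return np.zeros((0, 0))
    return shortest_path(csr_array(A), method="D", unweighted=True, directed=False)


def leading_eigenvector(M: np.ndarray) -> tuple[float, np.ndarray]:
    """Largest eigenvalue and its nonnegative (Perron) eigenvector."""
    if M.shape[0] == 0:
        return 0.0, np.zeros(0)
    w, V = np.linalg.eigh(M)
    lam = float(w[-1])
    v = V[:, -1]
    if v.sum() < 0:
        v = -v
    return lam, np.abs(v)


def node_metrics(G: Graph) -> pd.DataFrame:
    """Per-node degree, clustering, betweenness, closeness, eigenvector
    centrality and eccentricity.

    Degree counts incident edges; clustering is the triangle ratio with
    ``CC_i = 0`` for degree < 2; betweenness counts, over unordered pairs
    (s, t) excluding the node itself, the fraction of shortest s-t paths
    through the node, unnormalized; closeness is ``1 / sum(d)`` over the
    node's component (0 for isolated nodes); eigenvector centrality is the
    Perron vector of A scaled so its maximum is 1; eccentricity is the hop
    count to the farthest node in the component.
    """
    n = G.n
    if n == 0:
        return pd.DataFrame(columns=["degree", "clustering", "betweenness",
                                     "closeness", "eigenvector", "eccentricity"])
    H = G.to_networkx()
    degree = G.A.sum(axis=1)
    cc_map = nx.clustering(H)
    clustering = np.array([cc_map[u] for u in G.node_ids], float)
    bc_map = nx.betweenness_centrality(H, normalized=False)
    betweenness = np.array([bc_map[u] for u in G.node_ids], float)
    D = _distances(G.A)
    closeness = np.zeros(n)
    eccentricity = np.zeros(n)
    for i in range(n):
        finite = np.isfinite(D[i]) & (np.arange(n) != i)
        total = D[i, finite].sum()
        closeness[i] = 1.0 / total if total > 0 else 0.0
        eccentricity[i] = D[i, finite].max() if finite.any() else 0.0
    _lam, v = leading_eigenvector(G.A.astype(float))
    eig = v / v.max() if v.size and v.max() > 0 else np.zeros(n)
    return pd.DataFrame({"degree": degree.astype(int), "clustering": clustering,
                         "betweenness": betweenness, "closeness": closeness,
                         "eigenvector": eig, "eccentricity": eccentricity},
                        index=G.node_ids)


def degree_distribution(degrees: np.ndarray) -> dict:
    """Histogram, cumulative distribution and the 1-6 / >=7 degree bands.

    Band values are the mean number of nodes per degree value inside the band
    (the scale on which degree-distribution frequencies are reported).
    """
    degrees = np.asarray(degrees, int)
    max_deg = int(degrees.max()) if degrees.size else 0
    hist = np.bincount(degrees, minlength=max_deg + 1)
    cumulative = np.cumsum(hist[::-1])[::-1]  # nodes with degree >= d
    low = hist[1:7].sum() if max_deg >= 1 else 0
    high = hist[7:].sum() if max_deg >= 7 else 0
    n_high_vals = max(max_deg - 6, 1)
    return {"histogram": hist.tolist(),
            "cumulative": cumulative.tolist(),
            "count_1_6": int(low),
            "count_ge7": int(high),
            "mean_freq_1_6": float(low / 6.0),
            "mean_freq_ge7": float(high / n_high_vals),
            "max_degree": max_deg}


def network_metrics(G: Graph) -> dict:
    """Network-level summary: average degree, density, components,
    characteristic path length (connected pairs only), average clustering and
    the degree distribution."""
    n = G.n
    if n == 0:
        return {"n": 0, "m": 0, "average_degree": 0.0, "density": 0.0,
                "components": 0, "path_length": None, "fraction_pairs_excluded": 0.0,
                "clustering": 0.0, "degree_distribution": degree_distribution(np.array([]))}
    m = G.m
    degrees = G.A.sum(axis=1)
    K = float(degrees.mean())
    density = 2.0 * m / (n * (n - 1)) if n > 1 else 0.0
    n_comp, _ = connected_components(csr_array(G.A), directed=False)
    D = _distances(G.A)
    off = ~np.eye(n, dtype=bool)
    finite = np.isfinite(D) & off
    n_pairs = int(off.sum())
    if finite.any():
        path_length = float(D[finite].mean())
        excluded = 1.0 - finite.sum() / n_pairs
    else:
        path_length = None
        excluded = 1.0
    H = G.to_networkx()
    cc_map = nx.clustering(H)
    cc_bar = float(np.mean([cc_map[u] for u in G.node_ids]))
    return {"n": n, "m": m, "average_degree": K, "density": float(density),
            "components": int(n_comp), "path_length": path_length,
            "fraction_pairs_excluded": float(excluded),
            "clustering": cc_bar,
            "degree_distribution": degree_distribution(degrees)}
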