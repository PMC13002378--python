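import numpy as np
import pytest

from conftest import complete, cycle, path, star, triangle_with_pendant
from meanet.graph_metrics import Graph, network_metrics, node_metrics


def brute_force(A):
    """Independent oracle: Floyd-Warshall distances, matrix-power shortest-path
    counts, and direct enumeration of clustering/betweenness/closeness."""
    n = A.shape[0]
    D = np.where(A > 0, 1.0, np.inf)
    np.fill_diagonal(D, 0.0)
    for k in range(n):
        D = np.minimum(D, D[:, k, None] + D[None, k, :])
    max_d = int(D[np.isfinite(D)].max()) if n else 0
    powers = [np.eye(n)]
    for _ in range(max_d):
        powers.append(powers[-1] @ A)
    sigma = np.zeros((n, n))
    for s in range(n):
        for t in range(n):
            if s != t and np.isfinite(D[s, t]):
                sigma[s, t] = powers[int(D[s, t])][s, t]
    betweenness = np.zeros(n)
    for i in range(n):
        for s in range(n):
            for t in range(s + 1, n):
                if i in (s, t) or not np.isfinite(D[s, t]):
                    continue
                if D[s, i] + D[i, t] == D[s, t]:
                    betweenness[i] += sigma[s, i] * sigma[i, t] / sigma[s, t]
    degree = A.sum(axis=1)
    clustering = np.zeros(n)
    for i in range(n):
        nb = np.where(A[i] > 0)[0]
        k = len(nb)
        if k >= 2:
            links = sum(A[u, v] for a, u in enumerate(nb) for v in nb[a + 1:])
            clustering[i] = 2.0 * links / (k * (k - 1))
    closeness = np.zeros(n)
    eccentricity = np.zeros(n)
    for i in range(n):
        finite = [D[i, j] for j in range(n) if j != i and np.isfinite(D[i, j])]
        closeness[i] = 1.0 / sum(finite) if finite else 0.0
        eccentricity[i] = max(finite) if finite else 0.0
    off = ~np.eye(n, dtype=bool)
    finite_pairs = np.isfinite(D) & off
    ell = float(D[finite_pairs].mean()) if finite_pairs.any() else None
    return {"degree": degree, "clustering": clustering,
            "betweenness": betweenness, "closeness": closeness,
            "eccentricity": eccentricity, "path_length": ell}


def power_iteration_eigvec(A, iters=5000):
    # shift by n*I so the leading eigenvalue dominates in modulus even for
    # bipartite graphs (eigenvector unchanged)
    n = A.shape[0]
    M = A + n * np.eye(n)
    v = np.full(n, 1.0 / np.sqrt(n))
    for _ in range(iters):
        w = M @ v
        norm = np.linalg.norm(w)
        if norm == 0:
            return np.zeros(n)
        v = w / norm
    return v / v.max() if v.max() > 0 else v


class TestHandValues:
    def test_star_centralities(self):
        G = Graph(A=star(4))
        nm = node_metrics(G)
        assert nm["betweenness"].iloc[0] == 6.0
        assert (nm["betweenness"].iloc[1:] == 0.0).all()
        assert nm["closeness"].iloc[0] == pytest.approx(1 / 4)
        assert nm["closeness"].iloc[1] == pytest.approx(1 / 7)
        assert nm["eigenvector"].iloc[0] / nm["eigenvector"].iloc[1] == \
            pytest.approx(2.0)

    def test_triangle_with_pendant(self):
        nm = node_metrics(Graph(A=triangle_with_pendant()))
        assert nm["clustering"].iloc[2] == pytest.approx(1 / 3)
        assert nm["clustering"].iloc[3] == 0.0
        assert nm["eccentricity"].iloc[3] == 2.0

    def test_complete_k4(self):
        nm = node_metrics(Graph(A=complete(4)))
        assert (nm["degree"] == 3).all()
        assert (nm["clustering"] == 1.0).all()
        assert (nm["betweenness"] == 0.0).all()
        assert (nm["eccentricity"] == 1.0).all()

    def test_path_p4_network(self):
        net = network_metrics(Graph(A=path(4)))
        assert net["average_degree"] == pytest.approx(1.5)
        assert net["density"] == pytest.approx(0.5)
        assert net["components"] == 1
        assert net["path_length"] == pytest.approx(10 / 6)

    def test_cycle_c4_network(self):
        net = network_metrics(Graph(A=cycle(4)))
        assert net["path_length"] == pytest.approx(4 / 3)
        assert net["clustering"] == 0.0

    def test_empty_graph(self):
        net = network_metrics(Graph(A=np.zeros((5, 5), int)))
        assert net["average_degree"] == 0.0
        assert net["density"] == 0.0
        assert net["components"] == 5
        assert net["path_length"] is None


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", range(12))
    def test_random_graphs_match_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 13))
        p = rng.uniform(0.15, 0.7)
        A = (rng.random((n, n)) < p).astype(int)
        A = np.triu(A, 1)
        A = A + A.T
        G = Graph(A=A)
        nm = node_metrics(G)
        oracle = brute_force(A)
        for col in ("degree", "clustering", "betweenness", "closeness",
                    "eccentricity"):
            np.testing.assert_allclose(nm[col].to_numpy(), oracle[col],
                                       atol=1e-9, err_msg=col)
        net = network_metrics(G)
        if oracle["path_length"] is None:
            assert net["path_length"] is None
        else:
            assert net["path_length"] == pytest.approx(oracle["path_length"])
        w = np.linalg.eigvalsh(A.astype(float))
        if A.sum() > 0 and w[-1] - w[-2] > 1e-8:  # unique leading eigenpair
            np.testing.assert_allclose(nm["eigenvector"].to_numpy(),
                                       power_iteration_eigvec(A.astype(float)),
                                       atol=1e-6)


class TestInvariants:
    def test_handshake(self):
        rng = np.random.default_rng(1)
        A = (rng.random((20, 20)) < 0.2).astype(int)
        A = np.triu(A, 1)
        A = A + A.T
        G = Graph(A=A)
        nm = node_metrics(G)
        assert nm["degree"].sum() == 2 * G.m

    def test_density_of_complete_graph_is_one(self):
        assert network_metrics(Graph(A=complete(7)))["density"] == 1.0

    def test_adding_edge_never_decreases_degree_metrics(self):
        rng = np.random.default_rng(2)
        A = (rng.random((10, 10)) < 0.3).astype(int)
        A = np.triu(A, 1)
        A = A + A.T
        zeros = np.argwhere(np.triu(A == 0, 1))
        i, j = zeros[0]
        B = A.copy()
        B[i, j] = B[j, i] = 1
        na, nb = network_metrics(Graph(A=A)), network_metrics(Graph(A=B))
        assert nb["average_degree"] >= na["average_degree"]
        assert nb["density"] >= na["density"]

    def test_nonbinary_adjacency_rejected(self):
        with pytest.raises(ValueError, match="binary"):
            Graph(A=np.array([[0, 2.0], [2.0, 0]]))

    def test_degree_bands(self):
        from meanet.graph_metrics import degree_distribution
        out = degree_distribution(np.array([1, 2, 3, 6, 7, 9, 0]))
        assert out["count_1_6"] == 4
        assert out["count_ge7"] == 2
        assert out["mean_freq_1_6"] == pytest.approx(4 / 6)
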