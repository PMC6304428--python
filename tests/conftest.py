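import networkx as nx
import numpy as np
import pytest

from fracnet.network import BinaryNetwork


def adj(edges, n):
    """Adjacency matrix from an edge list."""
    a = np.zeros((n, n), dtype=np.int8)
    for i, j in edges:
        a[i, j] = a[j, i] = 1
    return a


@pytest.fixture(scope="session")
def atlas_graphs():
    """All connected-or-not simple graphs on 2..7 nodes, one per
    isomorphism class (the networkx graph atlas)."""
    graphs = []
    for g in nx.graph_atlas_g():
        n = g.number_of_nodes()
        if n < 2:
            continue
        graphs.append(nx.to_numpy_array(g, dtype=np.int8))
    return graphs


@pytest.fixture
def path4():
    return adj([(0, 1), (1, 2), (2, 3)], 4)


@pytest.fixture
def star6():
    """Hub node 0 with 5 leaves."""
    return adj([(0, i) for i in range(1, 6)], 6)


@pytest.fixture
def k5():
    a = np.ones((5, 5), dtype=np.int8)
    np.fill_diagonal(a, 0)
    return a


@pytest.fixture
def ring_lattice():
    """97-node ring lattice, each node linked to its 6 nearest neighbours."""
    return BinaryNetwork.from_networkx(nx.watts_strogatz_graph(97, 6, 0, seed=0))


# ---------------------------------------------------------------------------
# independent brute-force oracles (matrix powers / enumeration), used to
# cross-check the implementation on small graphs


def oracle_distances(a: np.ndarray) -> np.ndarray:
    """Shortest-path lengths from matrix-power reachability."""
    n = a.shape[0]
    d = np.full((n, n), np.inf)
    np.fill_diagonal(d, 0)
    power = np.eye(n, dtype=np.int64)
    for k in range(1, n):
        power = power @ a.astype(np.int64)
        newly = (power > 0) & np.isinf(d)
        d[newly] = k
    return d


def oracle_path_counts(a: np.ndarray, d: np.ndarray) -> np.ndarray:
    """Number of geodesics per pair: walks of minimal length are paths."""
    n = a.shape[0]
    rho = np.zeros((n, n), dtype=np.int64)
    power = np.eye(n, dtype=np.int64)
    for k in range(1, n):
        power = power @ a.astype(np.int64)
        at_k = d == k
        rho[at_k] = power[at_k]
    return rho


def oracle_betweenness(a: np.ndarray) -> np.ndarray:
    """Betweenness by explicit geodesic counting over ordered pairs,
    normalized by (n-1)(n-2)."""
    n = a.shape[0]
    d = oracle_distances(a)
    rho = oracle_path_counts(a, d)
    b = np.zeros(n)
    for i in range(n):
        for h in range(n):
            for j in range(n):
                if len({i, h, j}) < 3 or not np.isfinite(d[h, j]):
                    continue
                if d[h, i] + d[i, j] == d[h, j]:
                    b[i] += rho[h, i] * rho[i, j] / rho[h, j]
    return b / ((n - 1) * (n - 2))


def oracle_triangles(a: np.ndarray) -> np.ndarray:
    """Per-node triangle count by neighbour-pair enumeration."""
    n = a.shape[0]
    t = np.zeros(n)
    for i in range(n):
        nbrs = np.nonzero(a[i])[0]
        t[i] = sum(
            a[u, v] for ii, u in enumerate(nbrs) for v in nbrs[ii + 1:]
        )
    return t


def oracle_global_efficiency(a: np.ndarray) -> float:
    d = oracle_distances(a)
    n = a.shape[0]
    total = 0.0
    for i in range(n):
        for j in range(n):
            if i != j and np.isfinite(d[i, j]):
                total += 1.0 / d[i, j]
    return total / (n * (n - 1))
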