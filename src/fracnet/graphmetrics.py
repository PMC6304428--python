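"""Graph quantities for binary undirected networks.

Degree, density, components, unweighted shortest paths, triangles and
clustering, betweenness centrality, global efficiency, and the
characteristic path length under three conventions for handling
disconnected node pairs:

``harmonic``
    reciprocal of the mean inverse distance (Newman's harmonic mean),
    finite whenever at least one pair is connected; equals
    ``1 / E_glob``.
``finite_mean``
    arithmetic mean of the finite distances over connected ordered pairs.
``lcs_mean``
    ``finite_mean`` restricted to the largest connected component.

Also provides Maslov-Sneppen degree-preserving rewiring and ensemble
baselines against it, the null model used to judge small-world structure.
"""

from __future__ import annotations

import warnings

import networkx as nx
import numpy as np
from scipy.sparse import csgraph
from scipy.sparse import csr_matrix

from .network import BinaryNetwork

__all__ = [
    "possible_links",
    "degrees",
    "density",
    "largest_component",
    "shortest_paths",
    "triangles",
    "clustering",
    "global_efficiency",
    "char_path_length",
    "betweenness",
    "small_world_estimable",
    "maslov_sneppen",
    "random_network_baseline",
    "global_metrics",
    "nodal_metrics",
]

LP_CONVENTIONS = ("harmonic", "finite_mean", "lcs_mean")


def _adj(net) -> np.ndarray:
    if isinstance(net, BinaryNetwork):
        return net.adjacency
    return np.asarray(net)


def possible_links(n: int) -> int:
    """Maximum link count of an n-node simple graph: n(n-1)/2."""
    return n * (n - 1) // 2


def degrees(net) -> tuple[np.ndarray, float]:
    """Per-node degree (adjacency row sums) and the network mean degree."""
    a = _adj(net)
    k = a.sum(axis=1).astype(float)
    return k, float(k.mean())


def density(net) -> float:
    """Percentage of possible links present: 100 * l / (n(n-1)/2)."""
    a = _adj(net)
    n = a.shape[0]
    if n < 2:
        raise ValueError("density needs at least 2 nodes")
    return float(100.0 * (a.sum() / 2) / possible_links(n))


def largest_component(net) -> tuple[int, np.ndarray]:
    """Size of the largest connected component and its node mask.

    An isolated node is a component of size 1, so LCS >= 1 even for the
    empty graph.  Ties go to the lowest component id (deterministic).
    """
    a = _adj(net)
    n_comp, labels = csgraph.connected_components(csr_matrix(a), directed=False)
    sizes = np.bincount(labels, minlength=n_comp)
    best = int(np.argmax(sizes))
    return int(sizes[best]), labels == best


def shortest_paths(net) -> np.ndarray:
    """All-pairs unweighted shortest-path lengths; inf across components."""
    a = _adj(net)
    return csgraph.shortest_path(csr_matrix(a), method="D", unweighted=True)


def triangles(net) -> np.ndarray:
    """Triangle count per node: half the closed 2-walks through it."""
    a = _adj(net).astype(np.int64)
    return np.diag(a @ a @ a) / 2.0


def clustering(net) -> tuple[float, np.ndarray]:
    """Network clustering coefficient C_p and per-node c_i.

    ``c_i = 2 t_i / (k_i (k_i - 1))``, defined as 0 for nodes of degree
    below 2; C_p is the mean over all n nodes.
    """
    a = _adj(net)
    k, _ = degrees(a)
    t = triangles(a)
    c = np.zeros_like(k)
    ok = k >= 2
    c[ok] = 2.0 * t[ok] / (k[ok] * (k[ok] - 1.0))
    return float(c.mean()), c


def global_efficiency(net) -> float:
    """Mean inverse shortest-path length over ordered pairs (1/inf = 0)."""
    a = _adj(net)
    n = a.shape[0]
    if n < 2:
        raise ValueError("global efficiency needs at least 2 nodes")
    d = shortest_paths(a)
    with np.errstate(divide="ignore"):
        inv = 1.0 / d
    inv[~np.isfinite(inv)] = 0.0
    np.fill_diagonal(inv, 0.0)
    return float(inv.sum() / (n * (n - 1)))


def char_path_length(net, convention: str = "harmonic") -> float:
    """Characteristic path length L_p under a disconnection convention."""
    if convention not in LP_CONVENTIONS:
        raise ValueError(f"convention must be one of {LP_CONVENTIONS}")
    a = _adj(net)
    if convention == "harmonic":
        e = global_efficiency(a)
        if e == 0:
            raise ValueError("L_p undefined: no connected pair")
        return 1.0 / e
    if convention == "lcs_mean":
        _, mask = largest_component(a)
        a = a[np.ix_(mask.nonzero()[0], mask.nonzero()[0])]
        if a.shape[0] < 2:
            raise ValueError("L_p undefined: largest component is a single node")
    d = shortest_paths(a)
    off = ~np.eye(d.shape[0], dtype=bool)
    finite = np.isfinite(d) & off
    if not finite.any():
        raise ValueError("L_p undefined: no connected pair")
    return float(d[finite].mean())


def betweenness(net) -> np.ndarray:
    """Betweenness centrality per node, normalized by (n-1)(n-2).

    The fraction of shortest paths between ordered pairs (h, j), with
    h, j distinct from i, that pass through i; disconnected pairs
    contribute 0.  Range [0, 1]; the hub of a star scores exactly 1.
    """
    net = net if isinstance(net, BinaryNetwork) else BinaryNetwork(_adj(net))
    if net.n_nodes < 3:
        raise ValueError("betweenness needs at least 3 nodes")
    b = nx.betweenness_centrality(net.to_networkx(), normalized=True)
    return np.asarray([b[name] for name in net.node_names])


def small_world_estimable(net) -> bool:
    """True iff mean degree exceeds ln(n) (e.g. ln 97 = 4.574).

    Below this, the sparse graph fragments and small-world indices are
    not meaningfully estimable.
    """
    a = _adj(net)
    _, k_mean = degrees(a)
    return bool(k_mean > np.log(a.shape[0]))


def maslov_sneppen(
    net: BinaryNetwork,
    n_swaps_per_edge: int = 10,
    seed=None,
) -> BinaryNetwork:
    """Degree-preserving randomization by repeated double-edge swaps.

    Picks two links (a-b, c-d) at random and rewires them to (a-d, c-b),
    rejecting swaps that would create self-loops or duplicate links.
    Targets ``n_swaps_per_edge`` successful swaps per link with an
    attempt cap of 100x that; rigid graphs with no feasible swap (e.g. a
    complete graph or a star) are returned unchanged with a warning.
    """
    a = _adj(net).copy()
    edges = np.column_stack(np.nonzero(np.triu(a, k=1)))
    m = len(edges)
    if m < 2:
        raise ValueError("rewiring needs at least 2 links")
    rng = np.random.default_rng(seed)
    target = n_swaps_per_edge * m
    max_attempts = 100 * target
    done = attempts = 0
    while done < target and attempts < max_attempts:
        attempts += 1
        e1, e2 = rng.integers(0, m, size=2)
        if e1 == e2:
            continue
        x, y = edges[e1]
        u, v = edges[e2]
        if rng.random() < 0.5:
            u, v = v, u
        # proposed: x-u, y-v
        if len({x, y, u, v}) < 4:
            continue
        if a[x, u] or a[y, v]:
            continue
        a[x, y] = a[y, x] = 0
        a[u, v] = a[v, u] = 0
        a[x, u] = a[u, x] = 1
        a[y, v] = a[v, y] = 1
        edges[e1] = (x, u)
        edges[e2] = (y, v)
        done += 1
    if done == 0:
        warnings.warn(
            "no feasible degree-preserving swap found; returning input unchanged",
            stacklevel=2,
        )
    names = net.node_names if isinstance(net, BinaryNetwork) else None
    return BinaryNetwork(a, list(names) if names else [])


def random_network_baseline(
    net: BinaryNetwork,
    n_random: int = 100,
    seed=None,
    lp_convention: str = "harmonic",
    n_swaps_per_edge: int = 10,
) -> dict[str, dict[str, float]]:
    """Mean and sd of L_p, C_p, E_glob over a rewired ensemble.

    Each ensemble member is an independent Maslov-Sneppen randomization
    of the input, so it shares the exact degree sequence; the spread of
    its metrics is the null band against which the empirical network's
    segregation/integration is judged.
    """
    if n_random < 2:
        raise ValueError("need n_random >= 2 for an ensemble sd")
    rng = np.random.default_rng(seed)
    lp, cp, eg = [], [], []
    for _ in range(n_random):
        r = maslov_sneppen(net, n_swaps_per_edge=n_swaps_per_edge, seed=rng)
        try:
            lp.append(char_path_length(r, lp_convention))
        except ValueError:
            lp.append(np.nan)
        cp.append(clustering(r)[0])
        eg.append(global_efficiency(r))
    out = {}
    for name, vals in (("L_p", lp), ("C_p", cp), ("E_glob", eg)):
        v = np.asarray(vals, dtype=float)
        out[name] = {
            "mean": float(np.nanmean(v)),
            "sd": float(np.nanstd(v, ddof=1)),
        }
    return out


def global_metrics(net, lp_convention: str = "harmonic") -> dict[str, float]:
    """The study's global summary: LCS, mean degree, density %, L_p, C_p, E_glob.

    L_p is NaN (not an error) for networks with no connected pair, so
    threshold sweeps can record empty networks.
    """
    a = _adj(net)
    lcs, _ = largest_component(a)
    _, k_mean = degrees(a)
    try:
        lp = char_path_length(a, lp_convention)
    except ValueError:
        lp = float("nan")
    return {
        "LCS": float(lcs),
        "mean_degree": k_mean,
        "density_pct": density(a),
        "L_p": lp,
        "C_p": clustering(a)[0],
        "E_glob": global_efficiency(a),
        "small_world_estimable": float(small_world_estimable(a)),
    }


def nodal_metrics(net: BinaryNetwork) -> "pd.DataFrame":
    """Per-node degree, triangles, clustering and betweenness as a table."""
    import pandas as pd

    k, _ = degrees(net)
    t = triangles(net)
    _, c = clustering(net)
    b = betweenness(net)
    return pd.DataFrame(
        {"degree": k, "triangles": t, "clustering": c, "betweenness": b},
        index=net.node_names,
    )
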