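"""Binary undirected network container and on-disk formats.

The whole pipeline converges on one graph object: an unweighted,
undirected adjacency matrix over named brain regions, with ``a_ij = 1``
when the inter-regional correlation survived thresholding.  All graph
metrics and attack simulations consume this container.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

__all__ = ["BinaryNetwork", "load_network", "save_network"]


@dataclass
class BinaryNetwork:
    """Undirected, unweighted graph over named nodes.

    Parameters
    ----------
    adjacency
        ``(n, n)`` symmetric 0/1 matrix with a zero diagonal.
    node_names
        Region name per node; defaults to ``"n000" .. "n{n-1}"``.
    """

    adjacency: np.ndarray
    node_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        a = np.asarray(self.adjacency)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ValueError(f"adjacency must be square, got shape {a.shape}")
        if not np.isin(a, (0, 1)).all():
            raise ValueError("adjacency entries must be 0 or 1")
        a = a.astype(np.int8)
        if not np.array_equal(a, a.T):
            raise ValueError("adjacency must be symmetric")
        if np.any(np.diag(a) != 0):
            raise ValueError("adjacency diagonal must be zero (no self-links)")
        self.adjacency = a
        if not self.node_names:
            self.node_names = [f"n{i:03d}" for i in range(a.shape[0])]
        if len(self.node_names) != a.shape[0]:
            raise ValueError("node_names length must match adjacency size")

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_links(self) -> int:
        return int(self.adjacency.sum()) // 2

    def subnetwork(self, keep: np.ndarray) -> "BinaryNetwork":
        """Induced subgraph on the node indices in ``keep`` (order kept)."""
        keep = np.asarray(keep)
        sub = self.adjacency[np.ix_(keep, keep)]
        return BinaryNetwork(sub, [self.node_names[i] for i in keep])

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.node_names)
        i, j = np.nonzero(np.triu(self.adjacency, k=1))
        g.add_edges_from(
            (self.node_names[a], self.node_names[b]) for a, b in zip(i, j)
        )
        return g

    @classmethod
    def from_networkx(cls, g: nx.Graph) -> "BinaryNetwork":
        names = [str(v) for v in g.nodes()]
        a = nx.to_numpy_array(g, dtype=np.int8)
        np.fill_diagonal(a, 0)
        a = (a != 0).astype(np.int8)
        return cls(a, names)


def save_network(net: BinaryNetwork, path: str | Path, fmt: str | None = None) -> None:
    """Write a network as adjacency CSV, edge-list TSV, or GraphML.

    ``fmt`` defaults from the file suffix: ``.csv`` adjacency matrix with
    node names as header/index, ``.tsv`` two-column edge list, ``.graphml``
    via networkx.
    """
    path = Path(path)
    fmt = fmt or path.suffix.lstrip(".")
    if fmt == "csv":
        pd.DataFrame(
            net.adjacency, index=net.node_names, columns=net.node_names
        ).to_csv(path)
    elif fmt == "tsv":
        i, j = np.nonzero(np.triu(net.adjacency, k=1))
        pd.DataFrame(
            {
                "node_i": [net.node_names[a] for a in i],
                "node_j": [net.node_names[b] for b in j],
            }
        ).to_csv(path, sep="\t", index=False)
    elif fmt == "graphml":
        nx.write_graphml(net.to_networkx(), path)
    else:
        raise ValueError(f"unknown network format: {fmt!r}")


def load_network(path: str | Path, fmt: str | None = None) -> BinaryNetwork:
    """Read a network written by :func:`save_network`.

    Edge-list TSV loses isolated nodes by construction; adjacency CSV and
    GraphML round-trip exactly.
    """
    path = Path(path)
    fmt = fmt or path.suffix.lstrip(".")
    if fmt == "csv":
        df = pd.read_csv(path, index_col=0)
        return BinaryNetwork(df.to_numpy(), [str(c) for c in df.columns])
    if fmt == "tsv":
        df = pd.read_csv(path, sep="\t")
        g = nx.Graph()
        g.add_edges_from(zip(df["node_i"].astype(str), df["node_j"].astype(str)))
        return BinaryNetwork.from_networkx(g)
    if fmt == "graphml":
        return BinaryNetwork.from_networkx(nx.read_graphml(path))
    raise ValueError(f"unknown network format: {fmt!r}")
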