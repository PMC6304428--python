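"""Network resilience under random failure and targeted attack.

Nodes are deleted one at a time (with their incident links); after each
deletion the global efficiency and the largest-component size of the
induced subgraph on the remaining nodes are recomputed and expressed
relative to the intact network.  Targeted attacks delete in descending
betweenness order (ties broken by higher degree, then node index);
random attacks average the curves over many shuffled deletion orders.
A network whose relative largest-component curve collapses early under
targeted attack depends on few high-betweenness hubs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import graphmetrics as gm
from .network import BinaryNetwork

__all__ = ["AttackCurve", "attack", "compare_resilience"]


@dataclass
class AttackCurve:
    """Efficiency and largest-component decay along a node-removal sequence.

    All three arrays have length n+1 (before any removal through full
    destruction); ``efficiency_ratio`` and ``relative_lcs`` are
    normalized by the intact network's values, so both start at 1 and
    ``relative_lcs`` ends at 0.
    """

    removed_fraction: np.ndarray
    efficiency_ratio: np.ndarray
    relative_lcs: np.ndarray
    strategy: str
    n_realizations: int | None = None
    seed: int | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "strategy": self.strategy,
                "step": np.arange(len(self.removed_fraction)),
                "removed_fraction": self.removed_fraction,
                "efficiency_ratio": self.efficiency_ratio,
                "relative_lcs": self.relative_lcs,
            }
        )


def _curve_for_order(adj: np.ndarray, order: np.ndarray, e0: float, lcs0: int):
    n = adj.shape[0]
    eff = np.empty(n + 1)
    lcs = np.empty(n + 1)
    eff[0], lcs[0] = 1.0, 1.0
    remaining = list(range(n))
    for step, victim in enumerate(order, start=1):
        remaining.remove(int(victim))
        if len(remaining) >= 2:
            sub = adj[np.ix_(remaining, remaining)]
            eff[step] = gm.global_efficiency(sub) / e0
            lcs[step] = gm.largest_component(sub)[0] / lcs0
        elif len(remaining) == 1:
            eff[step] = 0.0
            lcs[step] = 1.0 / lcs0
        else:
            eff[step] = 0.0
            lcs[step] = 0.0
    return eff, lcs


def _targeted_order(adj: np.ndarray, rank_mode: str) -> np.ndarray:
    n = adj.shape[0]
    if rank_mode == "static":
        b = gm.betweenness(adj)
        k = adj.sum(axis=1)
        # descending betweenness; ties by higher degree, then node index
        return np.lexsort((np.arange(n), -k, -b))
    order = []
    remaining = list(range(n))
    a = adj
    while remaining:
        if len(remaining) >= 3:
            b = gm.betweenness(a)
        else:
            b = np.zeros(len(remaining))
        k = a.sum(axis=1)
        local = np.lexsort((np.arange(len(remaining)), -k, -b))[0]
        order.append(remaining.pop(int(local)))
        a = np.delete(np.delete(a, local, axis=0), local, axis=1)
    return np.asarray(order)


def attack(
    net: BinaryNetwork,
    strategy: str = "targeted",
    n_realizations: int = 100,
    seed=None,
    rank_mode: str = "static",
) -> AttackCurve:
    """Simulate node-removal attacks and return the decay curve.

    ``strategy='targeted'`` removes in descending betweenness order
    (``rank_mode='static'`` ranks once on the intact network;
    ``'dynamic'`` re-ranks after every removal).  ``strategy='random'``
    averages the curves of ``n_realizations`` uniformly shuffled orders.
    """
    adj = net.adjacency
    n = net.n_nodes
    if n < 2:
        raise ValueError("attack needs at least 2 nodes")
    e0 = gm.global_efficiency(adj)
    if e0 == 0:
        raise ValueError("initial global efficiency is 0; ratios undefined")
    lcs0 = gm.largest_component(adj)[0]
    frac = np.arange(n + 1) / n

    if strategy == "targeted":
        if rank_mode not in ("static", "dynamic"):
            raise ValueError("rank_mode must be 'static' or 'dynamic'")
        order = _targeted_order(adj, rank_mode)
        eff, lcs = _curve_for_order(adj, order, e0, lcs0)
        return AttackCurve(frac, eff, lcs, "targeted")
    if strategy == "random":
        if n_realizations < 1:
            raise ValueError("n_realizations must be >= 1")
        rng = np.random.default_rng(seed)
        eff_sum = np.zeros(n + 1)
        lcs_sum = np.zeros(n + 1)
        for _ in range(n_realizations):
            eff, lcs = _curve_for_order(adj, rng.permutation(n), e0, lcs0)
            eff_sum += eff
            lcs_sum += lcs
        return AttackCurve(
            frac,
            eff_sum / n_realizations,
            lcs_sum / n_realizations,
            "random",
            n_realizations=n_realizations,
            seed=seed,
        )
    raise ValueError("strategy must be 'targeted' or 'random'")


def compare_resilience(curve_a: AttackCurve, curve_b: AttackCurve) -> dict:
    """Per-step differences (A minus B) and where the LCS gap peaks.

    Both curves must share the removal grid.  The reported
    ``max_gap_fraction`` is the removed fraction at which the
    relative-LCS difference is largest (earliest step on ties).
    """
    if len(curve_a.removed_fraction) != len(curve_b.removed_fraction) or not np.allclose(
        curve_a.removed_fraction, curve_b.removed_fraction
    ):
        raise ValueError("attack curves must share the same removal grid")
    d_eff = curve_a.efficiency_ratio - curve_b.efficiency_ratio
    d_lcs = curve_a.relative_lcs - curve_b.relative_lcs
    # earliest step within float tolerance of the maximum gap
    gap_idx = int(np.argmax(d_lcs >= d_lcs.max() - 1e-9))
    return {
        "removed_fraction": curve_a.removed_fraction,
        "efficiency_ratio_diff": d_eff,
        "relative_lcs_diff": d_lcs,
        "max_lcs_gap": float(d_lcs[gap_idx]),
        "max_gap_fraction": float(curve_a.removed_fraction[gap_idx]),
    }
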