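"""Group-level inference on structural covariance networks.

One network per group means no subject-level variance to feed a
conventional test, so group differences in network metrics are judged
by permutation: subjects are reshuffled between groups (group sizes
preserved), both networks are rebuilt per shuffle — covariate
residualization included, so the null respects the full pipeline — and
the observed metric difference is compared with the 95th percentile of
its permutation distribution (a one-tailed 5% criterion in the
hypothesized direction).

The same machinery drives threshold sweeps over a grid of significance
levels and per-node betweenness comparisons.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from . import graphmetrics as gm
from .covnet import (
    CohortTable,
    ThresholdRule,
    pearson_rp,
    residualize_values,
    threshold_mask,
)
from .network import BinaryNetwork

__all__ = [
    "SweepResult",
    "PermutationResult",
    "build_network",
    "sweep",
    "permutation_test",
    "nodal_betweenness_decrease",
    "bh_fdr",
    "GLOBAL_METRICS",
]

DEFAULT_SWEEP_GRID = (0.05, 0.04, 0.03, 0.02, 0.01, 0.005, 0.001)

#: named global metrics usable in permutation tests (adjacency -> float)
GLOBAL_METRICS: dict[str, Callable[[np.ndarray], float]] = {
    "global_efficiency": gm.global_efficiency,
    "char_path_length": lambda a: gm.char_path_length(a, "harmonic"),
    "clustering": lambda a: gm.clustering(a)[0],
    "largest_component": lambda a: float(gm.largest_component(a)[0]),
    "density": gm.density,
    "mean_degree": lambda a: gm.degrees(a)[1],
}

#: default tested direction for observed = metric(A) - metric(B), with A
#: the control-like group: integration/segregation metrics are expected
#: higher in A, path length lower
DEFAULT_DIRECTION = {
    "global_efficiency": "greater",
    "clustering": "greater",
    "largest_component": "greater",
    "density": "greater",
    "mean_degree": "greater",
    "char_path_length": "less",
}


@dataclass
class SweepResult:
    """Global metrics for both groups across a threshold grid."""

    thresholds: list[float]
    rule_mode: str
    table: pd.DataFrame  # tidy: group, alpha, metric, value


@dataclass
class PermutationResult:
    """Observed metric difference against its permutation null."""

    metric: str
    observed_diff: float
    null_diffs: np.ndarray
    critical_value: float
    significant: bool
    direction: str
    n_perm: int
    p_value: float


# ---------------------------------------------------------------------------
# fast array core

def _cov_matrix(covariates: pd.DataFrame) -> np.ndarray:
    cols = []
    for c in ("age", "sex"):
        x = covariates[c].to_numpy(dtype=float)
        if np.ptp(x) > 0:
            cols.append(x)
    return np.column_stack(cols) if cols else np.empty((len(covariates), 0))


def _network_mask(
    values: np.ndarray,
    covs: np.ndarray,
    rule: ThresholdRule,
    residualize_first: bool,
) -> np.ndarray:
    if residualize_first:
        values = residualize_values(values, covs)
    r, p = pearson_rp(values)
    return threshold_mask(r, p, rule)


def build_network(
    table: CohortTable, rule: ThresholdRule | None = None
) -> BinaryNetwork:
    """Residualize -> correlate -> threshold, in one call."""
    rule = rule or ThresholdRule()
    mask = _network_mask(
        table.values.to_numpy(dtype=float),
        _cov_matrix(table.covariates),
        rule,
        residualize_first=True,
    )
    return BinaryNetwork(mask.astype(np.int8), table.region_names)


# ---------------------------------------------------------------------------
# threshold sweep

def sweep(
    group_a: CohortTable,
    group_b: CohortTable,
    thresholds: Sequence[float] = DEFAULT_SWEEP_GRID,
    rule_mode: str = "p_value",
    lp_convention: str = "harmonic",
) -> SweepResult:
    """Global metrics for each group at each significance threshold.

    An empty network at a tight threshold is recorded with L_p = NaN
    rather than dropped, so both groups share the full grid.
    """
    if group_a.region_names != group_b.region_names:
        raise ValueError("groups must share the same region set and order")
    if any(not 0 < a <= 1 for a in thresholds):
        raise ValueError("thresholds must lie in (0, 1]")
    rows = []
    for name, table in (("A", group_a), ("B", group_b)):
        for alpha in thresholds:
            net = build_network(table, ThresholdRule(mode=rule_mode, alpha=alpha))
            for metric, value in gm.global_metrics(net, lp_convention).items():
                rows.append(
                    {"group": name, "alpha": alpha, "metric": metric, "value": value}
                )
    return SweepResult(list(thresholds), rule_mode, pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# permutation tests

def _pooled(group_a: CohortTable, group_b: CohortTable):
    if group_a.region_names != group_b.region_names:
        raise ValueError("groups must share the same region set and order")
    values = np.concatenate(
        [group_a.values.to_numpy(float), group_b.values.to_numpy(float)], axis=1
    )
    covs = np.concatenate(
        [_cov_matrix(group_a.covariates), _cov_matrix(group_b.covariates)], axis=0
    )
    return values, covs, group_a.n_subjects, group_b.n_subjects


def _resolve_metric(metric) -> tuple[str, Callable[[np.ndarray], float]]:
    if callable(metric):
        return getattr(metric, "__name__", "custom"), metric
    if metric not in GLOBAL_METRICS:
        raise ValueError(f"unknown metric {metric!r}; choose from {sorted(GLOBAL_METRICS)}")
    return metric, GLOBAL_METRICS[metric]


def permutation_test(
    group_a: CohortTable,
    group_b: CohortTable,
    metric="global_efficiency",
    rule: ThresholdRule | None = None,
    n_perm: int = 1000,
    seed=None,
    direction: str | None = None,
    residualize_mode: str = "per_permutation",
    max_undefined_frac: float = 0.05,
) -> PermutationResult:
    """One-tailed permutation test of a global-metric group difference.

    The observed statistic is metric(network A) - metric(network B).
    Under the null, subjects are randomly reassigned between the groups
    (sizes preserved) and both networks rebuilt; with
    ``residualize_mode='per_permutation'`` (default) age/sex removal is
    repeated inside every shuffle, with ``'once'`` it is done up front on
    the pooled data.  Significance: observed beyond the 95th (direction
    'greater') or 5th ('less') percentile of the null differences.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    if residualize_mode not in ("per_permutation", "once"):
        raise ValueError("residualize_mode must be 'per_permutation' or 'once'")
    rule = rule or ThresholdRule()
    name, metric_fn = _resolve_metric(metric)
    direction = direction or DEFAULT_DIRECTION.get(name, "greater")
    if direction not in ("greater", "less"):
        raise ValueError("direction must be 'greater' or 'less'")

    values, covs, n_a, n_b = _pooled(group_a, group_b)
    per_perm = residualize_mode == "per_permutation"
    if not per_perm:
        values = residualize_values(values, covs)

    def diff(idx: np.ndarray) -> float:
        out = []
        for sel in (idx[:n_a], idx[n_a:]):
            mask = _network_mask(
                values[:, sel], covs[sel], rule, residualize_first=per_perm
            )
            try:
                out.append(metric_fn(mask.astype(np.int8)))
            except ValueError:
                out.append(np.nan)
        return out[0] - out[1]

    observed = diff(np.arange(n_a + n_b))
    if np.isnan(observed):
        raise ValueError(f"metric {name!r} undefined on the observed networks")

    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for i in range(n_perm):
        null[i] = diff(rng.permutation(n_a + n_b))
    n_bad = int(np.isnan(null).sum())
    if n_bad > max_undefined_frac * n_perm:
        raise ValueError(
            f"metric {name!r} undefined in {n_bad}/{n_perm} permutations; "
            "loosen the threshold rule or choose a disconnection-robust metric"
        )
    finite_null = null[~np.isnan(null)]

    if direction == "greater":
        critical = float(np.percentile(finite_null, 95))
        significant = observed > critical
        p = float((1 + np.sum(finite_null >= observed)) / (len(finite_null) + 1))
    else:
        critical = float(np.percentile(finite_null, 5))
        significant = observed < critical
        p = float((1 + np.sum(finite_null <= observed)) / (len(finite_null) + 1))

    return PermutationResult(
        metric=name,
        observed_diff=float(observed),
        null_diffs=null,
        critical_value=critical,
        significant=bool(significant),
        direction=direction,
        n_perm=n_perm,
        p_value=p,
    )


def nodal_betweenness_decrease(
    group_a: CohortTable,
    group_b: CohortTable,
    rule: ThresholdRule | None = None,
    n_perm: int = 1000,
    top_k: int = 5,
    p_cut: float = 0.001,
    seed=None,
    residualize_mode: str = "per_permutation",
) -> pd.DataFrame:
    """Regions with the largest significant betweenness decrease in group B.

    Per region, the observed decrease is betweenness(A) - betweenness(B);
    its permutation p-value is the fraction of label shuffles producing a
    decrease at least as large, with the +1 correction (smallest
    attainable p is 1/(n_perm+1), so p < 0.001 needs n_perm >= 1000).
    Returns up to ``top_k`` regions with p < p_cut, sorted by decrease.
    """
    rule = rule or ThresholdRule()
    values, covs, n_a, n_b = _pooled(group_a, group_b)
    per_perm = residualize_mode == "per_permutation"
    if not per_perm:
        values = residualize_values(values, covs)
    regions = group_a.region_names

    def btw_diff(idx: np.ndarray) -> np.ndarray:
        out = []
        for sel in (idx[:n_a], idx[n_a:]):
            mask = _network_mask(
                values[:, sel], covs[sel], rule, residualize_first=per_perm
            )
            out.append(gm.betweenness(mask.astype(np.int8)))
        return out[0] - out[1]

    observed = btw_diff(np.arange(n_a + n_b))
    rng = np.random.default_rng(seed)
    count_ge = np.zeros(len(regions))
    for _ in range(n_perm):
        count_ge += btw_diff(rng.permutation(n_a + n_b)) >= observed
    pvals = (1.0 + count_ge) / (n_perm + 1.0)

    df = pd.DataFrame(
        {"decrease": observed, "p_value": pvals}, index=pd.Index(regions, name="region")
    )
    sig = df[df["p_value"] < p_cut].sort_values("decrease", ascending=False)
    if len(sig) < top_k:
        warnings.warn(
            f"only {len(sig)} regions significant at p < {p_cut} (requested {top_k})",
            stacklevel=2,
        )
    return sig.head(top_k)


def bh_fdr(pvals, q: float = 0.05) -> tuple[float, np.ndarray]:
    """Benjamini-Hochberg step-up: cutoff and retained mask.

    Sorts the m p-values, finds the largest k with p_(k) <= k q / m, and
    retains every p-value at or below p_(k).  Returns (0.0, empty mask)
    when nothing is retained.
    """
    p = np.asarray(pvals, dtype=float)
    if not 0 < q < 1:
        raise ValueError("q must be in (0, 1)")
    if p.size == 0:
        return 0.0, np.zeros(0, dtype=bool)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    m = p.size
    ok = ranked <= (np.arange(1, m + 1) * q / m)
    if not ok.any():
        return 0.0, np.zeros(m, dtype=bool)
    cutoff = float(ranked[np.nonzero(ok)[0][-1]])
    return cutoff, p <= cutoff
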