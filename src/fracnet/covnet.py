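"""Group-level structural covariance networks from regional FD tables.

One network per group: age and sex are regressed out of each region's
FD values across subjects, every region pair is correlated (Pearson,
two-tailed p from the t transform with n-2 df), and the correlation
matrix is binarized.  Only positive coefficients can become links; the
significance gate is configurable (raw p, Benjamini-Hochberg FDR, or
the p<=0.05-then-top-20%-of-coefficients rule).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .network import BinaryNetwork

__all__ = [
    "CohortTable",
    "CorrelationResult",
    "ThresholdRule",
    "load_cohort",
    "save_cohort",
    "residualize",
    "correlate",
    "describe_coefficients",
    "threshold",
]


@dataclass
class CohortTable:
    """Regions x subjects matrix of 3D-FD values plus per-subject covariates.

    ``values``: DataFrame, one row per region, one column per subject.
    ``covariates``: DataFrame indexed by subject with ``age`` (years) and
    ``sex`` (0/1) columns, in the same subject order as the value columns.
    """

    values: pd.DataFrame
    covariates: pd.DataFrame

    def __post_init__(self) -> None:
        if self.values.shape[1] < 3:
            raise ValueError("need at least 3 subjects")
        if self.values.isna().any().any():
            raise ValueError("missing FD values; filter regions first")
        if list(self.values.columns) != list(self.covariates.index):
            raise ValueError("covariates must be indexed by the subject columns")
        for col in ("age", "sex"):
            if col not in self.covariates.columns:
                raise ValueError(f"covariates missing {col!r}")

    @property
    def region_names(self) -> list[str]:
        return [str(r) for r in self.values.index]

    @property
    def n_subjects(self) -> int:
        return self.values.shape[1]

    @property
    def n_regions(self) -> int:
        return self.values.shape[0]


@dataclass
class CorrelationResult:
    """Symmetric Pearson r and two-tailed p matrices for one group."""

    r: np.ndarray
    p: np.ndarray
    n_subjects: int
    region_names: list[str] = field(default_factory=list)
    degenerate_regions: list[str] = field(default_factory=list)

    @property
    def n_regions(self) -> int:
        return self.r.shape[0]


@dataclass
class ThresholdRule:
    """How a correlation matrix becomes a binary network.

    mode
        ``p_value``: link iff r > 0 and p <= alpha.
        ``fdr``: link iff r > 0 and p survives Benjamini-Hochberg at
        level alpha over the upper-triangle p-values.
        ``p05_top_density``: among pairs with r > 0 and p <= alpha, keep
        the ``density_target`` fraction of all possible links with the
        largest r.
    """

    mode: str = "p_value"
    alpha: float = 0.05
    density_target: float = 0.20

    def __post_init__(self) -> None:
        if self.mode not in ("p_value", "fdr", "p05_top_density"):
            raise ValueError(f"unknown threshold mode {self.mode!r}")
        if not 0 < self.alpha <= 1:
            raise ValueError("alpha must be in (0, 1]")
        if not 0 < self.density_target <= 1:
            raise ValueError("density_target must be in (0, 1]")


# ---------------------------------------------------------------------------
# array-level core (shared with the permutation machinery, which rebuilds
# thousands of networks and cannot afford container overhead)

def residualize_values(values: np.ndarray, covariates: np.ndarray) -> np.ndarray:
    """OLS residuals of each region (row) on [intercept | covariates]."""
    n_subj = values.shape[1]
    x = np.column_stack([np.ones(n_subj), covariates])
    beta, *_ = np.linalg.lstsq(x, values.T, rcond=None)
    return values - (x @ beta).T


def pearson_rp(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Pearson r across subjects for every region pair, with two-tailed p.

    Zero-variance regions yield NaN rows/columns (flagged upstream).
    """
    n = values.shape[1]
    sd = values.std(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (values - values.mean(axis=1, keepdims=True)) / sd[:, None]
        r = (z @ z.T) / n
    np.clip(r, -1.0, 1.0, out=r)
    np.fill_diagonal(r, 1.0)
    r[sd == 0, :] = np.nan
    r[:, sd == 0] = np.nan
    with np.errstate(invalid="ignore", divide="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r**2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p[np.isinf(t)] = 0.0
    p[np.isnan(r)] = np.nan
    np.fill_diagonal(p, 0.0)
    return r, p


def threshold_mask(r: np.ndarray, p: np.ndarray, rule: ThresholdRule) -> np.ndarray:
    """Symmetric boolean link mask for a correlation matrix under a rule."""
    n = r.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    r_u, p_u = r[iu, ju], p[iu, ju]
    valid = ~np.isnan(r_u)
    positive = valid & (r_u > 0)

    if rule.mode == "p_value":
        keep = positive & (p_u <= rule.alpha)
    elif rule.mode == "fdr":
        keep = np.zeros_like(positive)
        if valid.any():
            reject, *_ = multipletests(
                p_u[valid], alpha=rule.alpha, method="fdr_bh"
            )
            keep[valid] = reject
        keep &= positive
    else:  # p05_top_density
        survivors = positive & (p_u <= rule.alpha)
        n_pairs = n * (n - 1) // 2
        k = int(np.floor(rule.density_target * n_pairs))
        keep = np.zeros_like(survivors)
        if k > 0 and survivors.any():
            cand = np.nonzero(survivors)[0]
            # descending r; ties broken by (i, j) lexicographic pair
            order = np.lexsort((ju[cand], iu[cand], -r_u[cand]))
            keep[cand[order[:k]]] = True

    mask = np.zeros((n, n), dtype=bool)
    mask[iu[keep], ju[keep]] = True
    return mask | mask.T


# ---------------------------------------------------------------------------
# public operations on containers

def residualize(table: CohortTable) -> CohortTable:
    """Remove age and sex effects from every region by linear regression.

    Each region's values are replaced by the residuals of an OLS fit on
    [intercept, age, sex].  A covariate that is constant across subjects
    (rank-deficient design) is dropped with a warning.
    """
    cov_cols = []
    for col in ("age", "sex"):
        x = table.covariates[col].to_numpy(dtype=float)
        if np.ptp(x) == 0:
            warnings.warn(
                f"covariate {col!r} is constant across subjects; dropped",
                stacklevel=2,
            )
        else:
            cov_cols.append(x)
    covs = (
        np.column_stack(cov_cols)
        if cov_cols
        else np.empty((table.n_subjects, 0))
    )
    resid = residualize_values(table.values.to_numpy(dtype=float), covs)
    out = pd.DataFrame(resid, index=table.values.index, columns=table.values.columns)
    return CohortTable(out, table.covariates)


def correlate(table: CohortTable) -> CorrelationResult:
    """Inter-regional Pearson correlation matrix with two-tailed p-values."""
    vals = table.values.to_numpy(dtype=float)
    r, p = pearson_rp(vals)
    degenerate = [
        table.region_names[i]
        for i in np.nonzero(vals.std(axis=1) == 0)[0]
    ]
    if degenerate:
        warnings.warn(
            f"zero-variance regions (no links possible): {degenerate}",
            stacklevel=2,
        )
    return CorrelationResult(
        r=r,
        p=p,
        n_subjects=table.n_subjects,
        region_names=table.region_names,
        degenerate_regions=degenerate,
    )


def describe_coefficients(res: CorrelationResult) -> dict[str, float]:
    """Mean, skewness and (non-excess) kurtosis of the off-diagonal r's.

    Kurtosis is reported on the Pearson convention, so a normal
    distribution scores 3.  Degenerate inputs (constant coefficients or
    fewer than 4 of them) raise.
    """
    n = res.n_regions
    if n < 2:
        raise ValueError("need at least 2 regions")
    iu, ju = np.triu_indices(n, k=1)
    coeffs = res.r[iu, ju]
    coeffs = coeffs[~np.isnan(coeffs)]
    if coeffs.size < 4:
        raise ValueError("kurtosis undefined for fewer than 4 coefficients")
    if np.ptp(coeffs) == 0:
        raise ValueError("skewness/kurtosis undefined: all coefficients equal")
    return {
        "mean": float(coeffs.mean()),
        "skewness": float(stats.skew(coeffs)),
        "kurtosis": float(stats.kurtosis(coeffs, fisher=False)),
    }


def threshold(res: CorrelationResult, rule: ThresholdRule | None = None) -> BinaryNetwork:
    """Binarize a correlation matrix into an unweighted network.

    Negative and diagonal entries never become links; the remaining
    positive coefficients pass through the rule's significance gate.
    An empty result is a valid network (warned, not an error).
    """
    rule = rule or ThresholdRule()
    mask = threshold_mask(res.r, res.p, rule)
    if not mask.any():
        warnings.warn("no links survive thresholding; network is empty", stacklevel=2)
    return BinaryNetwork(mask.astype(np.int8), list(res.region_names))


# ---------------------------------------------------------------------------
# on-disk format: cohort CSV (first column region, one column per subject)
# plus covariates CSV (subject, age, sex)

def save_cohort(table: CohortTable, values_path: str | Path, covariates_path: str | Path) -> None:
    table.values.to_csv(values_path, index_label="region")
    table.covariates.to_csv(covariates_path, index_label="subject")


def load_cohort(values_path: str | Path, covariates_path: str | Path) -> CohortTable:
    values = pd.read_csv(values_path, index_col=0)
    cov = pd.read_csv(covariates_path, index_col=0)
    cov.index = cov.index.astype(str)
    values.columns = values.columns.astype(str)
    return CohortTable(values, cov.loc[list(values.columns)])
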