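"""Group-level inference on network metrics.

The study design: case-vs-control differences in each metric are tested
with an ordinary least-squares model ``y ~ intercept + group + age + sex``
(group coded case=1, sex coded M=1), reporting the t statistic and
two-sided p of the group coefficient, Bonferroni-corrected within the
natural families (8 global metrics; 90 nodes per nodal metric).
Associations with blind duration within cases use partial correlation
after residualizing on age and sex.  Demographics are compared with a
pooled-variance two-sample t test (age) and a Pearson chi-square without
continuity correction (sex).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io import CohortDataset, Phenotype

__all__ = [
    "GroupComparisonResult",
    "PartialCorrelationResult",
    "SingularDesignError",
    "fit_group_model",
    "bonferroni_correct",
    "partial_correlation",
    "two_sample_t",
    "chi_square_2x2",
    "describe",
    "run_nodal_comparison",
]


class SingularDesignError(ValueError):
    """The design matrix is rank deficient (collinear covariates)."""


@dataclass
class GroupComparisonResult:
    metric: str
    t: float
    p: float
    n: int
    p_threshold: float | None = None
    significant: bool | None = None
    family_size: int | None = None


@dataclass
class PartialCorrelationResult:
    metric: str
    r: float
    df: int
    p: float


def design_matrix(phenotypes: Sequence[Phenotype]) -> np.ndarray:
    """Columns: intercept, group (case=1), age, sex (M=1)."""
    return np.column_stack(
        [
            np.ones(len(phenotypes)),
            [1.0 if p.is_case else 0.0 for p in phenotypes],
            [p.age for p in phenotypes],
            [1.0 if p.sex == "M" else 0.0 for p in phenotypes],
        ]
    )


def _ols_group_t(X: np.ndarray, Y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """t and two-sided p of the group coefficient for each column of Y.

    Closed-form OLS shared across response columns (identical design), so
    per-node comparisons over 90 nodes cost a single factorization.
    """
    n, k = X.shape
    if n <= k:
        raise SingularDesignError(f"need more than {k} subjects, got {n}")
    if np.linalg.matrix_rank(X) < k:
        raise SingularDesignError("design matrix is rank deficient")
    xtx_inv = np.linalg.inv(X.T @ X)
    beta = xtx_inv @ X.T @ Y  # (k, m)
    resid = Y - X @ beta
    dof = n - k
    sigma2 = (resid**2).sum(axis=0) / dof
    se = np.sqrt(sigma2 * xtx_inv[1, 1])
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, beta[1] / np.where(se > 0, se, 1.0), 0.0)
    p = 2 * sps.t.sf(np.abs(t), dof)
    return t, p


def fit_group_model(
    y: Sequence[float] | np.ndarray,
    phenotypes: Sequence[Phenotype],
    metric: str = "metric",
) -> GroupComparisonResult:
    """Covariate-adjusted group comparison of one per-subject metric.

    OLS of ``y`` on [intercept, group, age, sex]; the reported t and
    two-sided p are those of the group coefficient (positive t means
    cases higher).
    """
    y = np.asarray(y, dtype=float)
    groups = {p.group for p in phenotypes}
    if groups != {"case", "control"}:
        raise ValueError("both groups must be present")
    X = design_matrix(phenotypes)
    t, p = _ols_group_t(X, y[:, None])
    return GroupComparisonResult(metric=metric, t=float(t[0]), p=float(p[0]), n=len(y))


def bonferroni_correct(
    results: Sequence[GroupComparisonResult],
    alpha: float = 0.05,
    family_size: int | None = None,
) -> list[GroupComparisonResult]:
    """Annotate results with the Bonferroni threshold alpha/family_size.

    ``family_size`` defaults to the number of results; significance is
    ``p < alpha / family_size``.
    """
    m = family_size if family_size is not None else len(results)
    if m < 1:
        raise ValueError("family_size must be >= 1")
    thr = alpha / m
    return [
        replace(r, p_threshold=thr, significant=bool(r.p < thr), family_size=m)
        for r in results
    ]


def _residualize(v: np.ndarray, Z: np.ndarray) -> np.ndarray:
    beta, *_ = np.linalg.lstsq(Z, v, rcond=None)
    return v - Z @ beta


def partial_correlation(
    x: Sequence[float] | np.ndarray,
    y: Sequence[float] | np.ndarray,
    covariates: np.ndarray | None = None,
    metric: str = "metric",
) -> PartialCorrelationResult:
    """Pearson correlation of x and y after removing linear covariate effects.

    ``covariates`` is an (n, k) column matrix (an intercept is always
    included); df = n - 2 - k and the two-sided p comes from
    t = r * sqrt(df / (1 - r^2)).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if covariates is None:
        Z = np.ones((n, 1))
        k = 0
    else:
        covariates = np.atleast_2d(np.asarray(covariates, dtype=float))
        if covariates.shape[0] != n:
            covariates = covariates.T
        Z = np.column_stack([np.ones(n), covariates])
        k = covariates.shape[1]
    if n <= k + 2:
        raise ValueError(f"need n > {k + 2} observations, got {n}")
    rx = _residualize(x, Z)
    ry = _residualize(y, Z)
    sx = np.sqrt((rx**2).sum())
    sy = np.sqrt((ry**2).sum())
    if sx == 0 or sy == 0:
        raise ValueError("zero residual variance: correlation undefined")
    r = float(np.clip((rx * ry).sum() / (sx * sy), -1.0, 1.0))
    df = n - 2 - k
    if abs(r) == 1.0:
        p = 0.0
    else:
        t = r * np.sqrt(df / (1 - r**2))
        p = float(2 * sps.t.sf(abs(t), df))
    return PartialCorrelationResult(metric=metric, r=r, df=df, p=p)


def two_sample_t(
    a: Sequence[float] | tuple[float, float, int],
    b: Sequence[float] | tuple[float, float, int],
) -> tuple[float, float]:
    """Pooled-variance two-sample t test, two-sided.

    Each sample is either raw values or a ``(mean, sd, n)`` summary (so the
    demographics printed as mean ± sd can be re-tested directly).
    """

    def is_summary(v) -> bool:
        return isinstance(v, tuple) and len(v) == 3

    if is_summary(a) or is_summary(b):
        ma, sa, na = a if is_summary(a) else (np.mean(a), np.std(a, ddof=1), len(a))
        mb, sb, nb = b if is_summary(b) else (np.mean(b), np.std(b, ddof=1), len(b))
        res = sps.ttest_ind_from_stats(ma, sa, na, mb, sb, nb, equal_var=True)
    else:
        a = np.asarray(a, dtype=float)
        b = np.asarray(b, dtype=float)
        if len(a) < 2 or len(b) < 2:
            raise ValueError("each sample needs n >= 2")
        if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0 and a.mean() == b.mean():
            return 0.0, 1.0
        res = sps.ttest_ind(a, b, equal_var=True)
    t = float(res.statistic)
    p = float(res.pvalue)
    if not np.isfinite(t):
        raise ValueError("zero pooled variance: t undefined")
    return t, p


def chi_square_2x2(table: Sequence[Sequence[int]]) -> tuple[float, float]:
    """Pearson chi-square on a 2x2 count table, df=1, no continuity correction."""
    tab = np.asarray(table)
    if tab.shape != (2, 2) or (tab < 0).any():
        raise ValueError("table must be 2x2 nonnegative counts")
    if (tab.sum(axis=0) == 0).any() or (tab.sum(axis=1) == 0).any():
        raise ValueError("zero margin: chi-square undefined")
    res = sps.chi2_contingency(tab, correction=False)
    return float(res.statistic), float(res.pvalue)


def describe(values: Sequence[float]) -> tuple[float, float]:
    """Arithmetic mean and sample standard deviation (n-1 denominator)."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("empty input")
    sd = float(np.std(v, ddof=1)) if v.size >= 2 else float("nan")
    return float(v.mean()), sd


def run_nodal_comparison(
    cohort: CohortDataset,
    nodal_values: np.ndarray,
    metric: str,
    alpha: float = 0.05,
    family_size: int | None = None,
) -> pd.DataFrame:
    """Per-node covariate-adjusted group comparison with Bonferroni correction.

    ``nodal_values`` is (subjects x nodes) in cohort subject order; NaNs
    (e.g. undefined path length at isolated nodes) exclude that subject
    for that node only, with the exclusion count reported.  Returns one
    row per node with its functional-system annotation.
    """
    Y = np.asarray(nodal_values, dtype=float)
    n_sub, n_nodes = Y.shape
    if n_sub != len(cohort.phenotypes):
        raise ValueError("nodal_values rows must match cohort subjects")
    if n_nodes != cohort.atlas.n_nodes:
        raise ValueError("nodal_values columns must match atlas nodes")
    fam = family_size if family_size is not None else n_nodes
    X = design_matrix(cohort.phenotypes)
    nan_mask = np.isnan(Y)
    t = np.full(n_nodes, np.nan)
    p = np.full(n_nodes, np.nan)
    n_used = np.full(n_nodes, n_sub)

    clean_cols = np.flatnonzero(~nan_mask.any(axis=0))
    if clean_cols.size:
        t[clean_cols], p[clean_cols] = _ols_group_t(X, Y[:, clean_cols])
    for j in np.flatnonzero(nan_mask.any(axis=0)):
        keep = ~nan_mask[:, j]
        n_used[j] = int(keep.sum())
        phe = [ph for ph, k in zip(cohort.phenotypes, keep) if k]
        if len({q.group for q in phe}) < 2 or keep.sum() <= X.shape[1]:
            continue  # node untestable; left NaN with count reported
        tj, pj = _ols_group_t(X[keep], Y[keep, j][:, None])
        t[j], p[j] = tj[0], pj[0]

    thr = alpha / fam
    return pd.DataFrame(
        {
            "node": np.arange(n_nodes),
            "abbreviation": cohort.atlas.abbreviations,
            "system": [e.system for e in cohort.atlas],
            "metric": metric,
            "t": t,
            "p": p,
            "p_threshold": thr,
            "significant": p < thr,
            "n_used": n_used,
            "n_excluded": n_sub - n_used,
        }
    )
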