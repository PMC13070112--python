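"""Inferential layer: outlier rules, transforms, correlations, hierarchical
regression with R-squared-change tests, group comparisons, multiplicity
adjustment and a-priori power.

Conventions
-----------
* Sample (n-1) SD throughout; excess-kurtosis convention for ``describe``.
* Univariate outliers: |z| >= 3.29 with mean/SD computed before exclusion,
  removed as pairwise deletions (only the offending variable's value).
* Standardized betas: outcome and predictors z-scored on the analysis
  sample; binary covariates are 0/1-coded and then standardized.
* Power: noncentral F with noncentrality lambda = f2 * N by default; the
  lambda = f2 * (df2 + df1 + 1) convention is exposed as an option.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "OutlierReport",
    "RegressionResult",
    "GroupCompareResult",
    "PowerSpec",
    "univariate_outliers",
    "mahalanobis_outliers",
    "log_lesion_transform",
    "partial_correlation",
    "pearson_correlation",
    "hierarchical_regression",
    "group_compare",
    "bonferroni_adjust",
    "power_min_n",
    "power_at_n",
    "describe",
]


@dataclass
class OutlierReport:
    variable: str
    rule: str  # "univariate_z" | "mahalanobis"
    threshold: float
    flagged_ids: list
    statistics: np.ndarray  # |z| or D^2 per observation

    @property
    def n_flagged(self) -> int:
        return len(self.flagged_ids)


def univariate_outliers(
    values,
    threshold_sd: float = 3.29,
    *,
    center: float | None = None,
    scale: float | None = None,
    name: str = "",
) -> OutlierReport:
    """Flag values at least ``threshold_sd`` sample SDs from the mean.

    Mean and SD are computed from all non-missing values (before any
    exclusion); ``center``/``scale`` may override them when the rule is
    applied against published summary statistics. Zero-variance input
    yields no flags and a warning.
    """
    x = pd.Series(values, dtype=float)
    obs = x.dropna()
    if obs.size < 3 and (center is None or scale is None):
        raise ValueError("need at least 3 values to estimate mean and SD")
    mean = obs.mean() if center is None else center
    sd = obs.std(ddof=1) if scale is None else scale
    if sd == 0:
        warnings.warn("zero SD: no univariate outliers can be flagged")
        z = pd.Series(np.zeros(x.size), index=x.index)
    else:
        z = (x - mean).abs() / sd
    flagged = list(x.index[z >= threshold_sd])
    return OutlierReport(
        variable=name, rule="univariate_z", threshold=threshold_sd,
        flagged_ids=flagged, statistics=z.to_numpy(),
    )


def mahalanobis_outliers(
    matrix, p_threshold: float = 0.001, name: str = ""
) -> OutlierReport:
    """Flag multivariate outliers by squared Mahalanobis distance.

    ``D^2`` is referred to the chi-square(df = n variables) upper quantile
    at ``p_threshold``. Complete rows only; a singular covariance raises.
    """
    X = pd.DataFrame(matrix).dropna()
    n, p = X.shape
    if n <= p + 1:
        raise ValueError("need more rows than variables + 1")
    Z = X.to_numpy() - X.to_numpy().mean(axis=0)
    cov = np.cov(Z, rowvar=False, ddof=1)
    cov = np.atleast_2d(cov)
    sign, logdet = np.linalg.slogdet(cov)
    if sign <= 0 or logdet < -50 * p:
        raise ValueError("singular covariance matrix")
    d2 = np.einsum("ij,jk,ik->i", Z, np.linalg.inv(cov), Z)
    cutoff = sps.chi2.ppf(1.0 - p_threshold, df=p)
    flagged = list(X.index[d2 > cutoff])
    return OutlierReport(
        variable=name, rule="mahalanobis", threshold=p_threshold,
        flagged_ids=flagged, statistics=d2,
    )


def log_lesion_transform(volumes_ml) -> tuple[pd.Series, dict]:
    """Natural log of lesion volumes plus before/after shape diagnostics."""
    x = pd.Series(volumes_ml, dtype=float)
    obs = x.dropna()
    if (obs <= 0).any():
        raise ValueError("lesion volumes must be > 0 for log transform")
    logged = np.log(x)
    report = {
        "skewness_before": float(sps.skew(obs, bias=False)),
        "kurtosis_before": float(sps.kurtosis(obs, bias=False)),
        "skewness_after": float(sps.skew(np.log(obs), bias=False)),
        "kurtosis_after": float(sps.kurtosis(np.log(obs), bias=False)),
    }
    return logged, report


def _complete(*arrays) -> list[np.ndarray]:
    cols = [np.asarray(a, dtype=float) for a in arrays]
    mask = np.ones(cols[0].shape[0], dtype=bool)
    for c in cols:
        mask &= np.all(np.isfinite(np.atleast_2d(c.T).T), axis=1)
    return [c[mask] for c in cols]


def pearson_correlation(x, y) -> tuple[float, float]:
    """Zero-order Pearson r and two-sided p on complete pairs."""
    x, y = _complete(x, y)
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)


def partial_correlation(x, y, covariates) -> tuple[float, float]:
    """Pearson correlation of x and y after removing shared covariates.

    Both variables are residualized on the covariates (with intercept) by
    least squares; the residual correlation is tested on
    ``df = n - 2 - k`` with ``t = r sqrt(df / (1 - r^2))``.
    """
    Z = np.asarray(
        covariates.to_numpy() if hasattr(covariates, "to_numpy") else covariates,
        dtype=float,
    )
    if Z.ndim == 1:
        Z = Z.reshape(-1, 1)
    x, y, Z = _complete(x, y, Z)
    n, k = Z.shape
    if x.size < k + 3:
        raise ValueError("need at least covariates + 3 complete cases")
    D = np.column_stack([np.ones(n), Z])
    rx = x - D @ np.linalg.lstsq(D, x, rcond=None)[0]
    ry = y - D @ np.linalg.lstsq(D, y, rcond=None)[0]
    denom = np.sqrt((rx @ rx) * (ry @ ry))
    if denom == 0:
        raise ValueError("degenerate residuals: zero variance after adjustment")
    r = float(np.clip((rx @ ry) / denom, -1.0, 1.0))
    df = n - 2 - k
    if r**2 >= 1.0:
        return r, 0.0
    t = r * np.sqrt(df / (1.0 - r**2))
    return r, float(2.0 * sps.t.sf(abs(t), df))


@dataclass
class RegressionResult:
    """One block of a hierarchical OLS on standardized variables."""

    predictors: list
    beta: pd.Series
    t: pd.Series
    partial_r: pd.Series
    p: pd.Series
    r_squared: float
    adj_r_squared: float
    f_statistic: float
    f_p_value: float
    n: int
    # nested comparison against the previous block (NaN for the first)
    delta_r_squared: float = float("nan")
    f_change: float = float("nan")
    df_change: tuple = ()
    p_change: float = float("nan")


class RankDeficientError(ValueError):
    pass


def _standardize(col: pd.Series) -> pd.Series:
    sd = col.std(ddof=1)
    if sd == 0 or not np.isfinite(sd):
        raise ValueError(f"zero-variance variable {col.name!r}")
    return (col - col.mean()) / sd


def hierarchical_regression(
    data: pd.DataFrame, outcome: str, blocks: list[list[str]]
) -> list[RegressionResult]:
    """Cumulative-block OLS with standardized coefficients and ΔR² F-tests.

    ``blocks`` are ordered predictor sets; block j is fit with the union
    of blocks 1..j. All variables (outcome included; binary covariates
    0/1-coded beforehand) are z-standardized on the common complete-case
    sample, so coefficients are standardized betas and the single-predictor
    beta equals Pearson's r. Partial r is recovered from the t statistic.
    """
    cum: list[list[str]] = []
    seen: list[str] = []
    for block in blocks:
        seen = seen + [p for p in block if p not in seen]
        cum.append(list(seen))
    cols = [outcome] + cum[-1]
    frame = data[cols].apply(pd.to_numeric).dropna()
    n = frame.shape[0]
    if n <= len(cum[-1]) + 1:
        raise ValueError("too few complete cases for the full model")
    Z = frame.apply(_standardize)
    y = Z[outcome].to_numpy()

    results: list[RegressionResult] = []
    prev_r2, prev_k = 0.0, 0
    for preds in cum:
        X = np.column_stack([np.ones(n)] + [Z[p].to_numpy() for p in preds])
        rank = np.linalg.matrix_rank(X)
        if rank < X.shape[1]:
            raise RankDeficientError(
                f"collinear predictor set {preds}: rank {rank} < {X.shape[1]}"
            )
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        rss = float(resid @ resid)
        tss = float(((y - y.mean()) ** 2).sum())
        k = len(preds)
        df_resid = n - k - 1
        r2 = 1.0 - rss / tss
        sigma2 = rss / df_resid
        XtX_inv = np.linalg.inv(X.T @ X)
        se = np.sqrt(sigma2 * np.diag(XtX_inv))[1:]
        b = beta[1:]
        t = b / se
        p = 2.0 * sps.t.sf(np.abs(t), df_resid)
        pr = t / np.sqrt(t**2 + df_resid)
        f = (r2 / k) / ((1.0 - r2) / df_resid)
        f_p = float(sps.f.sf(f, k, df_resid))
        res = RegressionResult(
            predictors=list(preds),
            beta=pd.Series(b, index=preds),
            t=pd.Series(t, index=preds),
            partial_r=pd.Series(pr, index=preds),
            p=pd.Series(p, index=preds),
            r_squared=r2,
            adj_r_squared=1.0 - (1.0 - r2) * (n - 1) / df_resid,
            f_statistic=float(f),
            f_p_value=f_p,
            n=n,
        )
        if results:
            q = k - prev_k
            dr2 = r2 - prev_r2
            f_ch = (dr2 / q) / ((1.0 - r2) / df_resid)
            res.delta_r_squared = dr2
            res.f_change = float(f_ch)
            res.df_change = (q, df_resid)
            res.p_change = float(sps.f.sf(f_ch, q, df_resid))
        results.append(res)
        prev_r2, prev_k = r2, k
    return results


@dataclass
class GroupCompareResult:
    statistic: float
    p_value: float
    df: float | tuple
    kind: str


def group_compare(
    values, groups, covariates=None, kind: str = "auto"
) -> GroupCompareResult:
    """Two-group t-test, ANCOVA, or chi-square association test.

    ``kind='t'`` is a pooled-variance two-sample t-test (the reported-df
    style); ``'welch'`` drops the pooling; ``'ancova'`` tests the group
    effect in a linear model with covariates; ``'chi2'`` is a Pearson
    chi-square without continuity correction on the values-by-groups
    table. ``'auto'`` picks ANCOVA when covariates are given, chi-square
    for non-numeric values, else the pooled t.
    """
    values = pd.Series(values)
    groups = pd.Series(groups)
    if kind == "auto":
        if covariates is not None:
            kind = "ancova"
        elif not pd.api.types.is_numeric_dtype(values):
            kind = "chi2"
        else:
            kind = "t"

    if kind == "chi2":
        table = pd.crosstab(values, groups)
        if table.shape[0] < 2 or table.shape[1] < 2:
            raise ValueError("chi-square needs at least a 2x2 table")
        chi2, p, dof, _ = sps.chi2_contingency(table.to_numpy(), correction=False)
        return GroupCompareResult(float(chi2), float(p), dof, "chi2")

    mask = values.notna() & groups.notna()
    levels = pd.unique(groups[mask])
    if len(levels) != 2:
        raise ValueError(f"need exactly 2 groups, got {len(levels)}")
    a = values[mask & (groups == levels[0])].to_numpy(dtype=float)
    b = values[mask & (groups == levels[1])].to_numpy(dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("empty group")

    if kind in ("t", "welch"):
        t, p = sps.ttest_ind(a, b, equal_var=(kind == "t"))
        df = a.size + b.size - 2 if kind == "t" else float("nan")
        return GroupCompareResult(float(t), float(p), df, kind)

    if kind == "ancova":
        if covariates is None:
            raise ValueError("ancova requires covariates")
        C = pd.DataFrame(covariates).loc[mask.index[mask]]
        g = (groups[mask] == levels[0]).astype(float).to_numpy()
        y = values[mask].to_numpy(dtype=float)
        keep = np.all(np.isfinite(C.to_numpy(dtype=float)), axis=1) & np.isfinite(y)
        y, g, C = y[keep], g[keep], C.to_numpy(dtype=float)[keep]
        n = y.size
        X0 = np.column_stack([np.ones(n), C])
        X1 = np.column_stack([X0, g])
        rss0 = float(np.sum((y - X0 @ np.linalg.lstsq(X0, y, rcond=None)[0]) ** 2))
        rss1 = float(np.sum((y - X1 @ np.linalg.lstsq(X1, y, rcond=None)[0]) ** 2))
        df2 = n - X1.shape[1]
        f = (rss0 - rss1) / (rss1 / df2)
        return GroupCompareResult(float(f), float(sps.f.sf(f, 1, df2)), (1, df2), "ancova")

    raise ValueError(f"unknown kind {kind!r}")


def bonferroni_adjust(p_values, family_size: int | None = None) -> np.ndarray:
    """min(1, p * m); m defaults to the number of p-values supplied."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size if family_size is None else int(family_size)
    return np.minimum(1.0, p * m)


@dataclass(frozen=True)
class PowerSpec:
    """A-priori power target for an R-squared-change F test."""

    f2: float = 0.15
    alpha: float = 0.05
    power_target: float = 0.80
    n_tested_predictors: int = 1
    n_covariates: int = 1

    def __post_init__(self) -> None:
        if self.f2 <= 0:
            raise ValueError("f2 must be > 0")
        if not (0 < self.alpha < 1 and 0 < self.power_target < 1):
            raise ValueError("alpha and power_target must lie in (0, 1)")


def power_at_n(spec: PowerSpec, n: int, lambda_convention: str = "n") -> float:
    """Exact noncentral-F power of the ΔR² test at total sample size n."""
    df1 = spec.n_tested_predictors
    df2 = n - spec.n_tested_predictors - spec.n_covariates - 1
    if df2 < 1:
        return 0.0
    if lambda_convention == "n":
        lam = spec.f2 * n
    elif lambda_convention == "df":
        lam = spec.f2 * (df2 + df1 + 1)
    else:
        raise ValueError("lambda_convention must be 'n' or 'df'")
    crit = sps.f.ppf(1.0 - spec.alpha, df1, df2)
    return float(sps.ncf.sf(crit, df1, df2, lam))


def power_min_n(
    spec: PowerSpec, lambda_convention: str = "n", max_n: int = 100_000
) -> int:
    """Smallest total N whose ΔR² F-test power reaches the target."""
    n = spec.n_tested_predictors + spec.n_covariates + 2
    while n <= max_n:
        if power_at_n(spec, n, lambda_convention) >= spec.power_target:
            return n
        n += 1
    raise ValueError(f"power target unreachable below N={max_n}")


def describe(values) -> dict:
    """Sample mean, SD, skewness, excess kurtosis, and range."""
    x = pd.Series(values, dtype=float).dropna().to_numpy()
    out = {
        "n": int(x.size),
        "mean": float(np.mean(x)),
        "sd": float(np.std(x, ddof=1)) if x.size > 1 else float("nan"),
        "min": float(np.min(x)),
        "max": float(np.max(x)),
        "skewness": float(sps.skew(x, bias=False)) if x.size >= 3 else float("nan"),
        "kurtosis": float(sps.kurtosis(x, bias=False)) if x.size >= 4 else float("nan"),
    }
    return out
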