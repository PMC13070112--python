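"""Analysis variables: striatal z-composite, PCA factor score, cognition.

All z-standardization uses the sample (n-1) standard deviation and complete
cases; missing values stay missing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "PcaResult",
    "zscore",
    "dat_composite",
    "pca_from_correlation",
    "maob_pca_score",
    "speed_score",
    "domain_and_general_scores",
]


@dataclass
class PcaResult:
    """Principal components of a correlation matrix plus factor scores."""

    eigenvalues: np.ndarray  # descending
    loadings: np.ndarray  # columns = components
    variance_fractions: np.ndarray
    scores: pd.Series | None = None  # first-component factor scores, unit SD
    variables: tuple = ()


def zscore(values) -> pd.Series:
    """(x - mean) / sample SD over complete cases; NaN propagates."""
    x = pd.Series(values, dtype=float)
    obs = x.dropna()
    if obs.size < 2:
        raise ValueError("zscore needs at least 2 non-missing values")
    sd = obs.std(ddof=1)
    if sd == 0 or not np.isfinite(sd):
        raise ValueError("zscore undefined for zero-variance input")
    return (x - obs.mean()) / sd


def dat_composite(caudate_bp, putamen_bp) -> pd.Series:
    """Z-score of the per-subject mean of caudate and putamen BP_ND.

    The regional values are averaged raw (available regions only) and the
    average is then standardized; a subject missing both regions stays
    missing.
    """
    pair = pd.concat(
        [pd.Series(caudate_bp, dtype=float), pd.Series(putamen_bp, dtype=float)],
        axis=1,
    )
    return zscore(pair.mean(axis=1, skipna=True))


def pca_from_correlation(corr: np.ndarray) -> PcaResult:
    """Eigendecomposition of a correlation matrix, components descending.

    The first loading vector is oriented so its mean is positive.
    """
    corr = np.asarray(corr, dtype=float)
    if not np.all(np.isfinite(corr)):
        raise ValueError("correlation matrix contains non-finite values")
    w, V = np.linalg.eigh(corr)
    order = np.argsort(w)[::-1]
    w, V = w[order], V[:, order]
    for j in range(V.shape[1]):
        if V[:, j].mean() < 0:
            V[:, j] = -V[:, j]
    return PcaResult(
        eigenvalues=w,
        loadings=V,
        variance_fractions=w / w.sum(),
    )


def maob_pca_score(ki_table: pd.DataFrame) -> PcaResult:
    """First-component factor score of regional Ki_ref values.

    PCA of the Pearson correlation matrix over complete rows; factor
    scores are the standardized variables projected on the first
    eigenvector, rescaled to unit sample SD, with sign fixed so the mean
    loading is positive. Rows with any missing region get a missing score.
    """
    ki_table = pd.DataFrame(ki_table)
    complete = ki_table.dropna()
    if complete.shape[0] < 3:
        raise ValueError("PCA needs at least 3 complete rows")
    sds = complete.std(ddof=1)
    if (sds == 0).any():
        bad = list(sds.index[sds == 0])
        raise ValueError(f"constant column(s) {bad}: correlation undefined")
    res = pca_from_correlation(complete.corr().to_numpy())
    Z = (ki_table - complete.mean()) / sds
    raw = Z.to_numpy() @ res.loadings[:, 0]
    raw_obs = raw[np.isfinite(raw)]
    res.scores = pd.Series(
        (raw - raw_obs.mean()) / np.std(raw_obs, ddof=1), index=ki_table.index
    )
    res.variables = tuple(ki_table.columns)
    return res


def speed_score(n_correct, total_rt_ms):
    """Correct responses per minute: n_correct / total_rt_ms * 60000."""
    n_correct = np.asarray(n_correct, dtype=float)
    total_rt_ms = np.asarray(total_rt_ms, dtype=float)
    if np.any(total_rt_ms[np.isfinite(total_rt_ms)] <= 0):
        raise ValueError("total_rt_ms must be positive")
    if np.any(n_correct[np.isfinite(n_correct)] < 0):
        raise ValueError("n_correct must be >= 0")
    out = n_correct / total_rt_ms * 60_000.0
    return float(out) if out.ndim == 0 else out


def domain_and_general_scores(
    test_z: pd.DataFrame,
    domain_map: dict[str, str],
    require_all_domains: bool = True,
) -> pd.DataFrame:
    """Domain z-means and the general-cognition composite.

    Each domain score is the mean of that domain's available test
    z-scores; a subject with no tests in a domain gets a missing domain
    score. General cognition is the mean of the domain scores — by
    default only for subjects with all domains present (matching the
    effective-n drop of incomplete batteries); with
    ``require_all_domains=False`` it averages the available domains.
    """
    test_z = pd.DataFrame(test_z)
    unmapped = [c for c in test_z.columns if c not in domain_map]
    if unmapped:
        raise KeyError(f"tests without a domain mapping: {unmapped}")
    out = pd.DataFrame(index=test_z.index)
    domains = sorted(set(domain_map[c] for c in test_z.columns))
    for domain in domains:
        cols = [c for c in test_z.columns if domain_map[c] == domain]
        out[domain] = test_z[cols].mean(axis=1, skipna=True)
    if require_all_domains:
        out["general_cognition"] = out[domains].mean(axis=1, skipna=False)
    else:
        out["general_cognition"] = out[domains].mean(axis=1, skipna=True)
    return out
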