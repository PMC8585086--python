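"""Reliability and sampling-adequacy statistics used during index development.

All statistics are computed on complete cases for the variables involved;
pairwise-complete handling is deliberately not offered anywhere.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "CorrelationSummary",
    "cronbach_alpha",
    "kmo",
    "rm_correlation",
    "spearman_ci",
]


@dataclass(frozen=True)
class CorrelationSummary:
    """A correlation estimate with a Fisher-z 95% confidence interval."""

    estimate: float
    ci_low: float
    ci_high: float
    n: int
    method: str
    p_value: float

    def __post_init__(self) -> None:
        if not (-1.0 - 1e-12 <= self.estimate <= 1.0 + 1e-12):
            raise ValueError("correlation outside [-1, 1]")
        if not (self.ci_low - 1e-12 <= self.estimate <= self.ci_high + 1e-12):
            raise ValueError("estimate outside its confidence interval")


def _fisher_ci(r: float, effective_n: float, level: float = 0.95) -> tuple[float, float]:
    # effective_n plays the role of n in the classical sd = 1/sqrt(n-3).
    if effective_n <= 3 or abs(r) >= 1.0:
        return (-1.0, 1.0) if abs(r) < 1.0 else (r, r)
    z = np.arctanh(r)
    half = stats.norm.ppf(0.5 + level / 2) / np.sqrt(effective_n - 3)
    return float(np.tanh(z - half)), float(np.tanh(z + half))


def cronbach_alpha(items: np.ndarray) -> float:
    """Internal-consistency alpha for an observations x items matrix.

    alpha = k/(k-1) * (1 - sum of item variances / variance of the item sum),
    with unbiased (n-1) variances.  Requires >= 2 items, >= 2 complete
    observations and a nonzero total-score variance.
    """
    x = np.asarray(items, float)
    if x.ndim != 2 or x.shape[1] < 2 or x.shape[0] < 2:
        raise ValueError("need at least 2 observations and 2 items")
    if np.isnan(x).any():
        raise ValueError("complete observations required (no missing values)")
    k = x.shape[1]
    total_var = x.sum(axis=1).var(ddof=1)
    if total_var <= 0:
        raise ValueError("zero total-score variance")
    return float(k / (k - 1) * (1 - x.var(axis=0, ddof=1).sum() / total_var))


def kmo(R: np.ndarray) -> tuple[float, np.ndarray]:
    """Kaiser-Meyer-Olkin measure of sampling adequacy.

    Returns the overall MSA and the per-item MSA vector.  Partial
    correlations come from the anti-image (inverse correlation) matrix:
    partial_ij = -S_ij / sqrt(S_ii S_jj) with S = R^-1.  The measure is the
    share of squared off-diagonal correlation not attributable to partial
    correlation; it is undefined for a diagonal correlation matrix.
    """
    R = np.asarray(R, float)
    p = R.shape[0]
    if R.ndim != 2 or R.shape[1] != p or p < 3:
        raise ValueError("need a square correlation matrix with p >= 3")
    if not np.allclose(R, R.T, atol=1e-10) or not np.allclose(np.diag(R), 1.0, atol=1e-8):
        raise ValueError("not a correlation matrix (symmetric, unit diagonal)")
    try:
        S = np.linalg.inv(R)
    except np.linalg.LinAlgError as e:
        raise ValueError("singular correlation matrix") from e
    d = 1.0 / np.sqrt(np.diag(S))
    partial = -S * np.outer(d, d)
    off = ~np.eye(p, dtype=bool)
    r2 = R[off] ** 2
    q2 = partial[off] ** 2
    if r2.sum() + q2.sum() <= 1e-12:
        raise ValueError("KMO undefined: all off-diagonal correlations are zero")
    overall = float(r2.sum() / (r2.sum() + q2.sum()))
    r2_i = (R**2 * off).sum(axis=1)
    q2_i = (partial**2 * off).sum(axis=1)
    return overall, r2_i / (r2_i + q2_i)


def rm_correlation(x: np.ndarray, y: np.ndarray, subjects: np.ndarray) -> CorrelationSummary:
    """Common within-subject correlation of two repeated measures.

    Subject means are removed from both variables (the ANCOVA formulation
    with subject dummies) and the correlation of the centered residuals is
    computed with df = N - n_subjects - 1.  Subjects contributing fewer than
    two paired visits carry no within-subject information and are dropped.
    The CI uses the Fisher transform with an effective sample size of
    df + 2.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    subjects = np.asarray(subjects)
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y, subjects = x[keep], y[keep], subjects[keep]
    uniq, counts = np.unique(subjects, return_counts=True)
    valid = set(uniq[counts >= 2])
    mask = np.array([s in valid for s in subjects])
    if mask.sum() == 0 or len(valid) < 2:
        raise ValueError("need >= 2 subjects with >= 2 paired visits each")
    x, y, subjects = x[mask], y[mask], subjects[mask]
    n, k = len(x), len(valid)
    xc = x - _group_means(x, subjects)
    yc = y - _group_means(y, subjects)
    denom = np.sqrt((xc**2).sum() * (yc**2).sum())
    if denom <= 0:
        raise ValueError("no within-subject variance")
    r = float((xc * yc).sum() / denom)
    df = n - k - 1
    if df <= 0:
        raise ValueError("nonpositive degrees of freedom")
    t = r * np.sqrt(df / max(1e-300, 1 - r**2)) if abs(r) < 1 else np.inf
    p = float(2 * stats.t.sf(abs(t), df))
    lo, hi = _fisher_ci(r, df + 2)
    return CorrelationSummary(r, lo, hi, n, "repeated-measures", p)


def _group_means(v: np.ndarray, groups: np.ndarray) -> np.ndarray:
    uniq, inv = np.unique(groups, return_inverse=True)
    sums = np.bincount(inv, weights=v)
    counts = np.bincount(inv)
    return (sums / counts)[inv]


def spearman_ci(x: np.ndarray, y: np.ndarray) -> CorrelationSummary:
    """Spearman rho (average ranks for ties) with a Fisher-z 95% CI."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    n = len(x)
    if n < 4:
        raise ValueError("need n >= 4 complete pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant vector")
    rho, p = stats.spearmanr(x, y)
    lo, hi = _fisher_ci(float(rho), n)
    return CorrelationSummary(float(rho), lo, hi, n, "spearman", float(p))
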