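"""Exploratory factor analysis machinery and confirmatory fit indices.

Extraction uses principal-axis factoring (iterated communalities on the
reduced correlation matrix); oblique rotation uses promax (varimax
pre-rotation followed by an oblique Procrustes fit to a power-4 target),
which yields a pattern matrix ``loadings`` and an inter-factor correlation
matrix ``phi``.  Factor-count selection offers Horn's parallel analysis and
the Very Simple Structure criterion.  The confirmatory side fits a
single-level correlated-factors model by maximum likelihood and reports the
chi-square statistic, RMSEA with a 90% CI, and CFI.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy import optimize, stats

from .instruments import ItemSubset

__all__ = [
    "FactorModel",
    "FitIndices",
    "principal_axis",
    "varimax",
    "promax",
    "parallel_analysis",
    "vss_criterion",
    "prune_items",
    "cfa_fit",
]


@dataclass
class FactorModel:
    """An oblique factor solution: pattern loadings, factor correlations.

    ``communalities`` are diag(L Phi L') and ``uniquenesses`` their
    complement; both are invariant to the (oblique) rotation.
    """

    item_ids: tuple[str, ...]
    loadings: np.ndarray          # items x factors pattern matrix
    phi: np.ndarray               # factor correlation matrix, unit diagonal
    factor_labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.loadings = np.asarray(self.loadings, float)
        self.phi = np.asarray(self.phi, float)
        p, k = self.loadings.shape
        if len(self.item_ids) != p:
            raise ValueError("item_ids length does not match loadings")
        if self.phi.shape != (k, k):
            raise ValueError("phi shape does not match factor count")
        if not np.allclose(self.phi, self.phi.T, atol=1e-8):
            raise ValueError("phi must be symmetric")
        if not np.allclose(np.diag(self.phi), 1.0, atol=1e-6):
            raise ValueError("phi must have unit diagonal")
        if np.linalg.eigvalsh(self.phi).min() <= 0:
            raise ValueError("phi must be positive definite")
        if not self.factor_labels:
            self.factor_labels = tuple(f"F{i+1}" for i in range(k))

    @property
    def n_factors(self) -> int:
        return self.loadings.shape[1]

    @property
    def communalities(self) -> np.ndarray:
        return np.einsum("ij,jk,ik->i", self.loadings, self.phi, self.loadings)

    @property
    def uniquenesses(self) -> np.ndarray:
        return 1.0 - self.communalities

    @property
    def structure(self) -> np.ndarray:
        """Structure matrix (item-factor correlations) = pattern @ phi."""
        return self.loadings @ self.phi

    def to_dict(self) -> dict:
        return {
            "item_ids": list(self.item_ids),
            "loadings": self.loadings.tolist(),
            "phi": self.phi.tolist(),
            "factor_labels": list(self.factor_labels),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "FactorModel":
        return cls(
            tuple(d["item_ids"]),
            np.array(d["loadings"], float),
            np.array(d["phi"], float),
            tuple(d["factor_labels"]),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "FactorModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


def _check_corr(R: np.ndarray) -> np.ndarray:
    R = np.asarray(R, float)
    if R.ndim != 2 or R.shape[0] != R.shape[1]:
        raise ValueError("correlation matrix must be square")
    if not np.allclose(R, R.T, atol=1e-8) or not np.allclose(np.diag(R), 1.0, atol=1e-6):
        raise ValueError("need a symmetric matrix with unit diagonal")
    return R


def principal_axis(
    R: np.ndarray,
    k: int,
    max_iter: int = 1000,
    tol: float = 1e-6,
    strict: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Principal-axis factoring with iterated communalities.

    Starts from squared multiple correlations, repeatedly eigendecomposes
    the reduced correlation matrix (communalities on the diagonal) and keeps
    the top-``k`` components until the communalities stabilise.  Returns the
    unrotated loading matrix and the communalities.  A Heywood communality
    is clipped to 0.995 with a warning; non-convergence raises with the last
    change attached.
    """
    R = _check_corr(R)
    p = R.shape[0]
    if not (1 <= k < p):
        raise ValueError(f"need 1 <= k < p, got k={k}, p={p}")
    try:
        smc = 1.0 - 1.0 / np.diag(np.linalg.inv(R))
    except np.linalg.LinAlgError:
        smc = np.abs(R - np.eye(p)).max(axis=1) ** 2
    h2 = np.clip(smc, 0.0, 0.995)
    delta = np.inf
    for it in range(max_iter):
        Rr = R.copy()
        np.fill_diagonal(Rr, h2)
        w, V = np.linalg.eigh(Rr)
        idx = np.argsort(w)[::-1][:k]
        L = V[:, idx] * np.sqrt(np.clip(w[idx], 0.0, None))
        new_h2 = (L**2).sum(axis=1)
        if (new_h2 >= 1.0).any():
            warnings.warn("Heywood case: communality >= 1 clipped to 0.995")
            new_h2 = np.clip(new_h2, None, 0.995)
        delta = np.abs(new_h2 - h2).max()
        # plain fixed-point iteration can cycle at high k; relax after a while
        step = 1.0 if it < 50 else 0.5
        h2 = h2 + step * (new_h2 - h2)
        if delta < tol:
            break
    else:
        if strict:
            raise RuntimeError(
                f"principal-axis iteration did not converge (last delta {delta:.2e})"
            )
        warnings.warn(f"principal-axis iteration stopped at delta {delta:.2e}")
    if h2.max() < 1e-3:
        warnings.warn("degenerate solution: all communalities near zero")
    # deterministic orientation: make each column's dominant sign positive
    sign = np.sign(L.sum(axis=0))
    sign[sign == 0] = 1.0
    return L * sign, h2


def varimax(A: np.ndarray, normalize: bool = True, eps: float = 1e-5, max_iter: int = 1000) -> tuple[np.ndarray, np.ndarray]:
    """Orthogonal varimax rotation (Kaiser-normalized by default)."""
    A = np.asarray(A, float)
    p, k = A.shape
    if k < 2:
        return A.copy(), np.eye(k)
    x = A.copy()
    if normalize:
        sc = np.sqrt((x**2).sum(axis=1))
        sc[sc == 0] = 1.0
        x = x / sc[:, None]
    T = np.eye(k)
    d = 0.0
    for _ in range(max_iter):
        z = x @ T
        B = x.T @ (z**3 - z * ((z**2).sum(axis=0) / p))
        U, s, Vt = np.linalg.svd(B)
        T = U @ Vt
        d_old, d = d, s.sum()
        if d < d_old * (1 + eps):
            break
    z = x @ T
    if normalize:
        z = z * sc[:, None]
    return z, T


def promax(A: np.ndarray, power: int = 4) -> tuple[np.ndarray, np.ndarray]:
    """Oblique promax rotation of an unrotated loading matrix.

    Varimax pre-rotation, an element-wise ``|x|^power * sign(x)`` simple
    structure target, then an oblique least-squares fit to that target with
    columns scaled so the implied factor correlation matrix has unit
    diagonal.  Returns (pattern, phi).
    """
    A = np.asarray(A, float)
    if A.shape[1] < 2:
        raise ValueError("promax needs at least 2 factors")
    X, _ = varimax(A)
    Q = X * np.abs(X) ** (power - 1)
    U, *_ = np.linalg.lstsq(X, Q, rcond=None)
    try:
        d = np.diag(np.linalg.inv(U.T @ U))
    except np.linalg.LinAlgError as e:
        raise ValueError("singular promax target regression") from e
    U = U @ np.diag(np.sqrt(d))
    pattern = X @ U
    Uinv = np.linalg.inv(U)
    phi = Uinv @ Uinv.T
    # symmetrize and pin the diagonal against round-off
    phi = (phi + phi.T) / 2
    np.fill_diagonal(phi, 1.0)
    # orientation: dominant sign of each pattern column positive
    s = np.sign(pattern.sum(axis=0))
    s[s == 0] = 1.0
    pattern = pattern * s
    phi = phi * np.outer(s, s)
    np.fill_diagonal(phi, 1.0)
    return pattern, phi


def parallel_analysis(
    n: int,
    p: int,
    observed_eigenvalues: Sequence[float],
    reps: int = 100,
    seed: int | np.random.Generator = 0,
    quantile: float | None = None,
) -> int:
    """Horn's parallel analysis: retained factor count.

    Simulates ``reps`` standard-normal n x p datasets, takes the mean (or a
    quantile) of each ordered eigenvalue of their correlation matrices, and
    counts how many leading observed eigenvalues exceed that reference.
    """
    if reps < 50:
        raise ValueError("need reps >= 50 for a stable reference")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    obs = np.sort(np.asarray(observed_eigenvalues, float))[::-1]
    sims = np.empty((reps, p))
    for r in range(reps):
        X = rng.standard_normal((n, p))
        ev = np.linalg.eigvalsh(np.corrcoef(X, rowvar=False))
        sims[r] = np.sort(ev)[::-1]
    ref = sims.mean(axis=0) if quantile is None else np.quantile(sims, quantile, axis=0)
    count = 0
    for o, m in zip(obs, ref):
        if o > m:
            count += 1
        else:
            break
    return count


def vss_criterion(R: np.ndarray, max_factors: int, complexity: int = 1) -> tuple[np.ndarray, int]:
    """Very Simple Structure curve over factor counts.

    For each k the fitted pattern is simplified to its ``complexity``
    largest |loadings| per item (the rest zeroed); the criterion is one
    minus the squared off-diagonal residual of the simplified model
    relative to the squared off-diagonal of R.  Returns the curve (index 0
    = one factor) and the argmax factor count.  With correlated factors the
    complexity-1 curve is known to favour fewer factors; the complexity-2
    curve is the usual companion diagnostic for oblique structures.
    """
    R = _check_corr(R)
    if max_factors < 1:
        raise ValueError("max_factors must be >= 1")
    if complexity < 1:
        raise ValueError("complexity must be >= 1")
    off = ~np.eye(R.shape[0], dtype=bool)
    denom = (R[off] ** 2).sum()
    curve = np.empty(max_factors)
    for k in range(1, max_factors + 1):
        # factor-count scan only: a looser communality tolerance suffices,
        # and a high-k scan is allowed to stop at the iteration cap
        L, _ = principal_axis(R, k, tol=1e-3, strict=(k == 1))
        if k == 1:
            pat, phi = L, np.eye(1)
        else:
            pat, phi = promax(L)
        simple = np.zeros_like(pat)
        keep = np.argsort(np.abs(pat), axis=1)[:, -min(complexity, k):]
        rows = np.arange(pat.shape[0])[:, None]
        simple[rows, keep] = pat[rows, keep]
        resid = R - simple @ phi @ simple.T
        curve[k - 1] = 1.0 - (resid[off] ** 2).sum() / denom
    curve = np.clip(curve, 0.0, 1.0)
    return curve, int(np.argmax(curve) + 1)


def prune_items(
    model: FactorModel,
    threshold: float = 0.3,
    redundancy_r: float = 0.8,
    R: np.ndarray | None = None,
) -> tuple[ItemSubset, bool]:
    """Drop items that load below ``threshold`` on every factor.

    A loading exactly at the threshold is retained (the removal rule is
    strictly "below").  When the observed correlation matrix ``R`` is
    supplied, pairs of retained items dominated by the same factor whose
    residual correlation exceeds ``redundancy_r`` are treated as redundant
    and the lower-loading member is dropped.  Returns the retained subset
    (dropped items tagged ``low-loading``) and a flag signalling that the
    factor model must be refit.
    """
    pat = model.loadings
    maxload = np.abs(pat).max(axis=1)
    drop = set(np.where(maxload < threshold)[0])
    if R is not None:
        R = _check_corr(R)
        resid = R - model.loadings @ model.phi @ model.loadings.T
        dominant = np.argmax(np.abs(pat), axis=1)
        p = len(model.item_ids)
        for i in range(p):
            for j in range(i + 1, p):
                if i in drop or j in drop:
                    continue
                if dominant[i] == dominant[j] and abs(resid[i, j]) > redundancy_r:
                    drop.add(i if maxload[i] < maxload[j] else j)
    keep = [i for i in range(len(model.item_ids)) if i not in drop]
    for f in range(model.n_factors):
        if not any(abs(pat[i, f]) >= threshold for i in keep):
            raise ValueError(f"pruning would leave factor {f + 1} with no salient item")
    prov = {
        model.item_ids[i]: ("retained" if i not in drop else "low-loading")
        for i in range(len(model.item_ids))
    }
    subset = ItemSubset(tuple(model.item_ids[i] for i in keep), prov)
    return subset, bool(drop)


@dataclass(frozen=True)
class FitIndices:
    """Maximum-likelihood fit summary for a confirmatory model."""

    chi2: float
    df: int
    rmsea: float
    rmsea_ci: tuple[float, float]
    cfi: float
    n: int

    def __post_init__(self) -> None:
        if self.rmsea < 0 or not (0 <= self.cfi <= 1):
            raise ValueError("invalid fit indices")
        lo, hi = self.rmsea_ci
        if not (lo - 1e-9 <= self.rmsea <= hi + 1e-9):
            raise ValueError("RMSEA outside its confidence interval")


def _rmsea_ci(chi2: float, df: int, n: int, level: float = 0.90) -> tuple[float, float]:
    # invert the noncentral chi-square cdf in the noncentrality parameter
    lo_p, hi_p = 0.5 + level / 2, 0.5 - level / 2

    def bound(target: float) -> float:
        if stats.ncx2.cdf(chi2, df, 1e-10) < target:
            return 0.0
        f = lambda nc: stats.ncx2.cdf(chi2, df, nc) - target
        hi = 1.0
        while f(hi) > 0:
            hi *= 2
            if hi > 1e7:
                return np.nan
        return optimize.brentq(f, 1e-12, hi)

    nc_lo, nc_hi = bound(lo_p), bound(hi_p)
    scale = df * (n - 1)
    return float(np.sqrt(max(nc_lo, 0.0) / scale)), float(np.sqrt(max(nc_hi, 0.0) / scale))


def cfa_fit(
    S: np.ndarray,
    pattern: Mapping[int, Sequence[int]] | Sequence[Sequence[int]],
    n: int,
) -> tuple[FitIndices, dict]:
    """Fit a correlated-factors confirmatory model by maximum likelihood.

    ``pattern`` lists, per factor, the indices of the items loading on it;
    the first listed item anchors the factor scale (loading fixed to 1).
    Minimizes the ML discrepancy F = ln|Sigma| - ln|S| + tr(S Sigma^-1) - p
    over free loadings, the factor covariance matrix and the uniquenesses,
    with chi2 = (n - 1) F at the optimum.  RMSEA's 90% CI inverts the
    noncentral chi-square cdf; CFI uses the independence baseline.
    """
    S = np.asarray(S, float)
    p = S.shape[0]
    if np.linalg.eigvalsh(S).min() <= 0:
        raise ValueError("sample covariance matrix is not positive definite")
    factors = list(pattern.values()) if isinstance(pattern, Mapping) else [list(f) for f in pattern]
    k = len(factors)
    if k != 2:
        raise ValueError("this confirmatory fit supports exactly 2 correlated factors")
    # free-loading bookkeeping: (item, factor) pairs, markers excluded
    free: list[tuple[int, int]] = []
    Lam0 = np.zeros((p, k))
    for f, items in enumerate(factors):
        if not items:
            raise ValueError("empty factor in pattern")
        Lam0[items[0], f] = 1.0
        free.extend((i, f) for i in items[1:])
    nfree = len(free) + 3 + p
    df = p * (p + 1) // 2 - nfree
    if df <= 0:
        raise ValueError("model is not identified (nonpositive degrees of freedom)")

    logdetS = np.linalg.slogdet(S)[1]

    def unpack(theta):
        Lam = Lam0.copy()
        for t, (i, f) in zip(theta[: len(free)], free):
            Lam[i, f] = t
        v1, v2 = np.exp(theta[len(free)]), np.exp(theta[len(free) + 1])
        rho = np.tanh(theta[len(free) + 2])
        Phi = np.array([[v1, rho * np.sqrt(v1 * v2)], [rho * np.sqrt(v1 * v2), v2]])
        Psi = np.exp(theta[len(free) + 3 :])
        return Lam, Phi, Psi, rho

    def fgrad(theta):
        Lam, Phi, Psi, rho = unpack(theta)
        Sigma = Lam @ Phi @ Lam.T + np.diag(Psi)
        try:
            c = np.linalg.cholesky(Sigma)
        except np.linalg.LinAlgError:
            return 1e10, np.zeros_like(theta)
        Sinv = np.linalg.inv(Sigma)
        F = 2 * np.log(np.diag(c)).sum() - logdetS + np.trace(S @ Sinv) - p
        G = Sinv - Sinv @ S @ Sinv
        gL = 2 * G @ Lam @ Phi
        gPhi = Lam.T @ G @ Lam
        grad = np.empty_like(theta)
        for idx, (i, f) in enumerate(free):
            grad[idx] = gL[i, f]
        v1, v2 = Phi[0, 0], Phi[1, 1]
        grad[len(free)] = gPhi[0, 0] * v1 + gPhi[0, 1] * Phi[0, 1]
        grad[len(free) + 1] = gPhi[1, 1] * v2 + gPhi[0, 1] * Phi[0, 1]
        grad[len(free) + 2] = 2 * gPhi[0, 1] * np.sqrt(v1 * v2) * (1 - rho**2)
        grad[len(free) + 3 :] = np.diag(G) * Psi
        return F, grad

    theta0 = np.concatenate([
        np.full(len(free), 0.8),
        [np.log(0.3), np.log(0.3), np.arctanh(0.4)],
        np.log(0.5 * np.diag(S)),
    ])
    res = optimize.minimize(fgrad, theta0, jac=True, method="L-BFGS-B",
                            options={"maxiter": 2000, "ftol": 1e-12, "gtol": 1e-8})
    if not res.success and np.linalg.norm(res.jac) > 1e-3:
        raise RuntimeError(
            f"CFA optimizer failed: {res.message} (gradient norm {np.linalg.norm(res.jac):.2e})"
        )
    Lam, Phi, Psi, _ = unpack(res.x)
    F = max(float(res.fun), 0.0)
    chi2 = (n - 1) * F
    rmsea = float(np.sqrt(max(chi2 - df, 0.0) / (df * (n - 1))))
    ci = _rmsea_ci(chi2, df, n)
    # independence baseline: diagonal covariance
    Fb = float(np.log(np.diag(S)).sum() - logdetS)
    chi2_b = (n - 1) * Fb
    df_b = p * (p - 1) // 2
    denom = max(chi2_b - df_b, chi2 - df, 0.0)
    cfi = 1.0 if denom == 0 else 1.0 - max(chi2 - df, 0.0) / denom
    fit = FitIndices(chi2, df, rmsea, ci, float(np.clip(cfi, 0.0, 1.0)), n)
    estimates = {"loadings": Lam, "phi": Phi, "uniquenesses": Psi, "discrepancy": F}
    return fit, estimates
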