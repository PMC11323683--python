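"""Θ-IPOD: iterative mean-shift outlier detection for linear regression.

The mean-shift model is y = Xβ + γ + ε with ε ~ N(0, σ²I); a nonzero γ_i
marks observation i as an outlier.  For a threshold rule Θ and level λ the
penalized objective

    f_P(β, γ) = ½‖y − Xβ − γ‖² + Σ_i P_Θ(γ_i; λ_i),   λ_i = λ√(1 − h_i),

is minimized by iterating γ ← Θ(Hγ + (I − H)y; λ_i) where H = X(XᵀX)⁻¹Xᵀ is
the hat matrix and h_i its diagonal (leverage).  λ is tuned over a
decreasing grid by a modified BIC,

    BIC*(λ) = m·log(RSS/m) + k·(log m + 1),   m = n − p, k = DF(λ) + 1,

with RSS = ‖(I − H)(y − γ̂)‖² and DF(λ) the number of flagged observations.

Two γ vectors live on a fit: the thresholding fixed point (``gamma_iterate``,
shrunk under the soft rule) and the support-restricted least-squares refit
(``gamma_hat``, one free parameter per flagged observation).  BIC* and the
reported β̂ use the refit; for the hard rule the two coincide.  Because
BIC* is unbounded below as the flagged set approaches saturation, selection
is restricted to fits flagging at most half the sample (the usual 50%
breakdown bound) and exact-interpolation fits (RSS ≈ 0) are excluded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import scipy.linalg

from .thresholding import apply_threshold, get_rule, induced_penalty

__all__ = [
    "RegressionProblem",
    "HatDecomposition",
    "IPODFit",
    "hat_matrix",
    "ipod_fit",
    "refit_gamma",
    "bic_star",
    "lambda_max",
    "ipod_select",
    "DEGENERATE_BIC",
]

#: Sentinel returned by :func:`bic_star` for saturated (RSS ≈ 0) fits.
DEGENERATE_BIC = -np.inf

#: Leverage above this is treated as exact (h_i = 1): the per-coordinate
#: threshold λ_i = λ√(1−h_i) would vanish and always flag, so such
#: coordinates are excluded from thresholding and reported in diagnostics.
_LEVERAGE_ONE = 1.0 - 1e-10


@dataclass
class RegressionProblem:
    """A design matrix X (n×p, full column rank, n > p) and response y (n)."""

    X: np.ndarray
    y: np.ndarray

    def __post_init__(self):
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        self.y = np.asarray(self.y, dtype=float).ravel()
        n, p = self.X.shape
        if self.y.shape[0] != n:
            raise ValueError(f"X has {n} rows but y has {self.y.shape[0]} entries")
        if n <= p:
            raise ValueError(f"need n > p, got n={n}, p={p}")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]


@dataclass
class HatDecomposition:
    """Hat matrix H = X(XᵀX)⁻¹Xᵀ held through an orthonormal basis Q of col(X).

    ``H @ v`` is evaluated as ``Q @ (Q.T @ v)``; the dense H is materialized
    only on demand.  H is symmetric and idempotent with trace p, and the
    leverage values satisfy 0 ≤ h_i ≤ 1.
    """

    Q: np.ndarray          # n×p orthonormal basis of the column space of X
    h: np.ndarray          # leverage: diagonal of H
    m: int                 # residual degrees of freedom n − p
    excluded: np.ndarray   # indices with h_i numerically equal to 1

    @property
    def n(self) -> int:
        return self.Q.shape[0]

    @property
    def p(self) -> int:
        return self.Q.shape[1]

    @property
    def H(self) -> np.ndarray:
        return self.Q @ self.Q.T

    def project(self, v: np.ndarray) -> np.ndarray:
        """Apply H to a vector."""
        return self.Q @ (self.Q.T @ v)

    def resid_project(self, v: np.ndarray) -> np.ndarray:
        """Apply I − H to a vector."""
        return v - self.project(v)


def hat_matrix(X: np.ndarray) -> HatDecomposition:
    """Orthogonal-factorization hat matrix; rejects rank-deficient designs.

    Raises
    ------
    ValueError
        If X is not of full column rank; the message names the columns that
        are linearly dependent on the others (from a pivoted QR).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n, p = X.shape
    if n <= p:
        raise ValueError(f"need n > p, got n={n}, p={p}")
    q, r, piv = scipy.linalg.qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = max(n, p) * np.finfo(float).eps * (diag[0] if diag.size else 0.0)
    rank = int(np.sum(diag > tol))
    if rank < p:
        bad = sorted(piv[rank:].tolist())
        raise ValueError(
            f"design matrix is rank deficient (rank {rank} < p={p}); "
            f"columns {bad} are linearly dependent on the others"
        )
    h = np.einsum("ij,ij->i", q, q)
    h = np.clip(h, 0.0, 1.0)
    excluded = np.flatnonzero(h >= _LEVERAGE_ONE)
    return HatDecomposition(Q=q, h=h, m=n - p, excluded=excluded)


@dataclass
class IPODFit:
    """A converged Θ-IPOD fit at one threshold level λ."""

    beta_hat: np.ndarray        # LS coefficients on (X, y − gamma_hat)
    gamma_hat: np.ndarray       # support-restricted LS refit of the shifts
    gamma_iterate: np.ndarray   # fixed point of the thresholding iteration
    lam: float
    outlier_idx: np.ndarray     # {i : gamma_hat_i ≠ 0}
    n_iter: int
    converged: bool
    objective: float            # penalized objective at the fixed point
    bic_star: float
    rss: float
    rule: str
    excluded_leverage: np.ndarray = field(default_factory=lambda: np.empty(0, int))
    objective_path: Optional[np.ndarray] = None
    # populated by ipod_select:
    lambda_grid: Optional[np.ndarray] = None
    bic_path: Optional[np.ndarray] = None
    df_path: Optional[np.ndarray] = None

    @property
    def n_outliers(self) -> int:
        return int(self.outlier_idx.size)


def _objective(dec, y, gamma, lam_vec, rule):
    resid = dec.resid_project(y - gamma)
    finite = np.isfinite(lam_vec)
    pen = induced_penalty(gamma[finite], lam_vec[finite], rule)
    return 0.5 * float(resid @ resid) + float(np.sum(pen))


def _lambda_vec(dec, lam):
    lam_vec = lam * np.sqrt(np.clip(1.0 - dec.h, 0.0, None))
    # excluded coordinates are never thresholded (γ pinned to zero there)
    lam_vec[dec.excluded] = np.inf
    return lam_vec


def _iterate(dec, y, lam_vec, rule, gamma, tol, max_iter, track_objective=False):
    """Run γ ← Θ(Hγ + (I−H)y; λ_i) to a fixed point or a detected 2-cycle."""
    finite = np.isfinite(lam_vec)
    obj_path = [] if track_objective else None
    converged = False
    prev = None
    it = 0
    for it in range(1, max_iter + 1):
        working = y + dec.project(gamma - y)  # Hγ + (I − H)y
        new = np.zeros_like(gamma)
        new[finite] = apply_threshold(working[finite], lam_vec[finite], rule)
        if obj_path is not None:
            obj_path.append(_objective(dec, y, new, lam_vec, rule))
        if np.max(np.abs(new - gamma), initial=0.0) < tol:
            gamma = new
            converged = True
            break
        if prev is not None and np.max(np.abs(new - prev)) < tol:
            # 2-cycle (hard rule): keep the lower-objective member
            f_new = _objective(dec, y, new, lam_vec, rule)
            f_cur = _objective(dec, y, gamma, lam_vec, rule)
            gamma = new if f_new <= f_cur else gamma
            converged = True
            break
        prev = gamma
        gamma = new
    path = np.asarray(obj_path) if obj_path is not None else None
    return gamma, it, converged, path


def ipod_fit(
    prob: RegressionProblem,
    lam: float,
    rule="soft",
    gamma_init: Optional[np.ndarray] = None,
    tol: float = 1e-8,
    max_iter: int = 500,
    dec: Optional[HatDecomposition] = None,
    track_objective: bool = False,
) -> IPODFit:
    """Run the γ-update iteration at a fixed threshold level λ.

    Non-convergence within ``max_iter`` is flagged on the fit (not raised)
    and the last iterate is returned.
    """
    rule = get_rule(rule)
    if lam < 0:
        raise ValueError(f"lam must be nonnegative, got {lam}")
    if dec is None:
        dec = hat_matrix(prob.X)
    y = prob.y
    if gamma_init is None:
        gamma = np.zeros(prob.n)
    else:
        gamma = np.asarray(gamma_init, dtype=float).copy()
        if gamma.shape != (prob.n,):
            raise ValueError(f"gamma_init must have length {prob.n}")
    gamma[dec.excluded] = 0.0
    lam_vec = _lambda_vec(dec, lam)
    gamma, it, converged, obj_path = _iterate(
        dec, y, lam_vec, rule, gamma, tol, max_iter, track_objective
    )
    support = np.flatnonzero(gamma != 0.0)
    if support.size <= prob.n - prob.p:
        beta, gamma_refit, rss = refit_gamma(prob, support)
    else:
        # saturated support: no refit possible; report the iterate itself
        gamma_refit = gamma.copy()
        beta, _, _, _ = np.linalg.lstsq(prob.X, y - gamma, rcond=None)
        resid = dec.resid_project(y - gamma)
        rss = float(resid @ resid)
    return IPODFit(
        beta_hat=beta,
        gamma_hat=gamma_refit,
        gamma_iterate=gamma,
        lam=float(lam),
        outlier_idx=support,
        n_iter=it,
        converged=converged,
        objective=_objective(dec, y, gamma, lam_vec, rule),
        bic_star=bic_star(dec, y, gamma),
        rss=rss,
        rule=rule.name,
        excluded_leverage=dec.excluded.copy(),
        objective_path=obj_path,
    )


def refit_gamma(prob: RegressionProblem, support: np.ndarray):
    """Least-squares refit with one free mean-shift per flagged observation.

    Equivalent to OLS on the unflagged rows: β̂ minimizes
    ‖y_{∉S} − X_{∉S}β‖² and γ̂_i = y_i − x_iᵀβ̂ for i ∈ S (zero elsewhere).
    Returns (beta, gamma, rss).
    """
    support = np.asarray(support, dtype=int)
    keep = np.ones(prob.n, dtype=bool)
    keep[support] = False
    Xk, yk = prob.X[keep], prob.y[keep]
    if Xk.shape[0] < prob.p:
        raise ValueError(
            f"support of size {support.size} leaves fewer rows than parameters"
        )
    beta, _, _, _ = np.linalg.lstsq(Xk, yk, rcond=None)
    resid = yk - Xk @ beta
    gamma = np.zeros(prob.n)
    gamma[support] = prob.y[support] - prob.X[support] @ beta
    return beta, gamma, float(resid @ resid)


def bic_star(dec: HatDecomposition, y: np.ndarray, gamma_hat: np.ndarray) -> float:
    """Modified BIC: m·log(RSS/m) + k(log m + 1) with k = DF + 1.

    RSS = ‖(I − H)(y − γ̂)‖².  A saturated fit (RSS ≈ 0) returns the −∞
    sentinel with a warning; such λ are excluded from selection.
    """
    y = np.asarray(y, dtype=float).ravel()
    gamma_hat = np.asarray(gamma_hat, dtype=float).ravel()
    m = dec.m
    if m <= 0:
        raise ValueError("need m = n − p > 0")
    resid = dec.resid_project(y - gamma_hat)
    rss = float(resid @ resid)
    base = dec.resid_project(y)
    scale = max(1.0, float(base @ base))
    if rss <= 1e-12 * scale:
        warnings.warn(
            "degenerate fit: RSS is numerically zero after shift removal; "
            "BIC* is undefined and this lambda is excluded from selection",
            RuntimeWarning,
            stacklevel=2,
        )
        return DEGENERATE_BIC
    df = int(np.count_nonzero(gamma_hat))
    k = df + 1
    return m * np.log(rss / m) + k * (np.log(m) + 1.0)


def max_admissible_outliers(n: int, p: int, frac: float = 0.5) -> int:
    """Largest flagged-set size BIC* can compare meaningfully.

    Two bounds: the usual breakdown bound ``frac``·n, and the point where
    the expected log-RSS gain from deleting a *clean* observation
    (≈ 2m/(residual dof) on the m·log(RSS/m) scale) starts to exceed the
    per-flag penalty (log m + 1), beyond which BIC* always prefers more
    deletions and selection degenerates.
    """
    m = n - p
    consistency = int(np.floor(m - 2.0 * m / (np.log(m) + 1.0) - 1)) if m > 1 else 0
    return max(0, min(int(np.floor(frac * n)), consistency))


def lambda_max(dec: HatDecomposition, y: np.ndarray) -> float:
    """Top of the λ grid: ‖(I − H)y / √diag(I − H)‖_∞ over usable coordinates."""
    resid = dec.resid_project(y)
    denom = np.sqrt(np.clip(1.0 - dec.h, 0.0, None))
    ok = denom > 1e-8
    if not np.any(ok):
        raise ValueError("all observations have unit leverage")
    return float(np.max(np.abs(resid[ok]) / denom[ok]))


def ipod_select(
    prob: RegressionProblem,
    rule="soft",
    n_lambda: int = 100,
    tol: float = 1e-8,
    max_iter: int = 500,
    dec: Optional[HatDecomposition] = None,
    max_outlier_frac: float = 0.5,
) -> IPODFit:
    """Tune λ by BIC* over a decreasing grid with warm starts.

    The grid has ``n_lambda`` linearly spaced points from λ_max =
    ‖(I−H)y/√diag(I−H)‖_∞ down to 0, traversed in decreasing order; each fit
    warm-starts from the previous (larger-λ) fixed point.  BIC* is evaluated
    at the penalized estimate γ̂(λ) itself; the winning support is then
    refitted by support-restricted least squares (one free shift per flagged
    observation) for the reported γ̂ and β̂.  The fit minimizing BIC* is
    returned, ties broken toward larger λ (fewer outliers).  Fits flagging
    more than :func:`max_admissible_outliers` observations and degenerate
    (RSS ≈ 0) fits are excluded from the comparison.
    """
    if n_lambda < 2:
        raise ValueError("n_lambda must be at least 2")
    rule = get_rule(rule)
    if dec is None:
        dec = hat_matrix(prob.X)
    y = prob.y
    # start a hair above λ_max so the first fit is robustly the null fit
    # (at exactly λ_max the boundary coordinate can tip over by rounding)
    grid = np.linspace(lambda_max(dec, y) * (1.0 + 1e-8), 0.0, n_lambda)
    max_df = max_admissible_outliers(prob.n, prob.p, max_outlier_frac)

    best = None  # (bic, lam, gamma, n_iter, converged, objective)
    gamma = np.zeros(prob.n)
    bics = np.full(n_lambda, np.nan)
    dfs = np.zeros(n_lambda, dtype=int)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        for j, lam in enumerate(grid):
            lam_vec = _lambda_vec(dec, lam)
            gamma, it, converged, _ = _iterate(
                dec, y, lam_vec, rule, gamma, tol, max_iter
            )
            support = np.flatnonzero(gamma != 0.0)
            dfs[j] = support.size
            if support.size > max_df:
                continue  # past the admissibility bound; keep warm start only
            bic = bic_star(dec, y, gamma)
            bics[j] = bic
            if np.isfinite(bic) and (best is None or bic < best[0]):
                best = (
                    bic,
                    float(lam),
                    gamma.copy(),
                    it,
                    converged,
                    _objective(dec, y, gamma, lam_vec, rule),
                )
    if best is None:
        # every grid point was inadmissible or degenerate; report the null fit
        warnings.warn(
            "no admissible fit on the lambda grid; returning the no-outlier fit",
            RuntimeWarning,
            stacklevel=2,
        )
        lam0 = float(grid[0])
        best = (
            bic_star(dec, y, np.zeros(prob.n)),
            lam0,
            np.zeros(prob.n),
            1,
            True,
            _objective(dec, y, np.zeros(prob.n), _lambda_vec(dec, lam0), rule),
        )
    bic, lam, gamma, it, converged, obj = best
    support = np.flatnonzero(gamma != 0.0)
    beta, gamma_refit, rss = refit_gamma(prob, support)
    fit = IPODFit(
        beta_hat=beta,
        gamma_hat=gamma_refit,
        gamma_iterate=gamma,
        lam=lam,
        outlier_idx=support,
        n_iter=it,
        converged=converged,
        objective=obj,
        bic_star=bic,
        rss=rss,
        rule=rule.name,
        excluded_leverage=dec.excluded.copy(),
    )
    fit.lambda_grid = grid
    fit.bic_path = bics
    fit.df_path = dfs
    return fit
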