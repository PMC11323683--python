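"""Spatial error model (SEM) machinery.

The SEM is y = Xβ + ξ with spatially autocorrelated disturbances
ξ = μWξ + ε, ε ~ N(0, σ²I), where W is a (usually row-standardized) spatial
weight matrix and μ the spatial autoregressive parameter.  Writing
B(μ) = I − μW, the error covariance is σ²(BᵀB)⁻¹ and left-multiplying the
model by B whitens it back to an independent-error regression (the GLS
transform).

Estimation of (μ, β, σ) is provided two ways:

* :func:`sem_mle` — Gaussian maximum likelihood with β and σ² profiled out
  and μ found by bounded scalar optimization over its admissible interval;
* :func:`romle_fit` — robustified-likelihood Fisher scoring in which the
  standardized residual r = B(y − Xβ)/σ̂ enters the score equations through
  a bounded influence function ψ, limiting the pull of gross outliers:

      s_β = Xᵀ Bᵀ ψ(r) / σ̂ = 0,
      s_μ = −K·tr(B⁻¹W) + ψ(r)ᵀ W B⁻¹ ψ(r) = 0,   K = ∫ψ²(r)f(r)dr,

  with f the standard-normal reference density and the information terms
  evaluated by Gauss–Hermite quadrature.  σ̂ is refreshed each sweep by the
  normalized median absolute deviation of the whitened residuals.

Any factor S with SᵀS = Ω⁻¹ = BᵀB whitens the disturbances; the scoring
iteration uses S = B itself (O(n²) per sweep), while the symmetric inverse
square root Ω^{-1/2} is available from :func:`omega_inv_sqrt`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Dict, Optional, Tuple

import numpy as np
import scipy.linalg
import scipy.optimize

__all__ = [
    "SpatialWeights",
    "SEMEstimate",
    "row_standardize",
    "weights_from_array",
    "transform_matrix",
    "gls_transform",
    "omega_inv_sqrt",
    "admissible_interval",
    "sem_mle",
    "psi",
    "psi_deriv_moment",
    "psi_squared_moment",
    "PSI_FUNCTIONS",
    "romle_fit",
]


# ---------------------------------------------------------------------------
# Spatial weights


@dataclass
class SpatialWeights:
    """An n×n nonnegative weight matrix with zero diagonal.

    ``source`` records provenance (a file path or "generated").  Eigenvalues
    are computed lazily and cached; for a matrix row-standardized from a
    symmetric kernel they come from a symmetric eigenproblem.
    """

    W: np.ndarray
    row_standardized: bool = False
    source: str = "generated"
    isolated: np.ndarray = field(default_factory=lambda: np.empty(0, int))
    _eigvals: Optional[np.ndarray] = field(default=None, repr=False, compare=False)
    _sym_seed: Optional[np.ndarray] = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        self.W = np.atleast_2d(np.asarray(self.W, dtype=float))
        n, m = self.W.shape
        if n != m:
            raise ValueError(f"weight matrix must be square, got {n}×{m}")
        if np.any(self.W < 0):
            raise ValueError("weight matrix entries must be nonnegative")
        if np.any(np.abs(np.diag(self.W)) > 0):
            raise ValueError("weight matrix must have a zero diagonal")
        if self.row_standardized:
            sums = self.W.sum(axis=1)
            nz = sums > 0
            if np.any(np.abs(sums[nz] - 1.0) > 1e-10):
                raise ValueError("rows marked standardized must sum to 1")

    @property
    def n(self) -> int:
        return self.W.shape[0]

    def eigenvalues(self) -> np.ndarray:
        """Real eigenvalues of W (cached)."""
        if self._eigvals is None:
            if self._sym_seed is not None:
                # W = D⁻¹S with S symmetric is similar to D^{-1/2}SD^{-1/2}
                s = self._sym_seed
                d = s.sum(axis=1)
                d_isqrt = np.where(d > 0, 1.0 / np.sqrt(np.where(d > 0, d, 1.0)), 0.0)
                m = s * d_isqrt[:, None] * d_isqrt[None, :]
                self._eigvals = np.sort(scipy.linalg.eigvalsh(m))
            else:
                ev = np.linalg.eigvals(self.W)
                if np.max(np.abs(ev.imag), initial=0.0) > 1e-8 * max(
                    1.0, np.max(np.abs(ev.real))
                ):
                    warnings.warn(
                        "weight matrix has notably complex eigenvalues; "
                        "using real parts for the admissible interval",
                        RuntimeWarning,
                        stacklevel=2,
                    )
                self._eigvals = np.sort(ev.real)
        return self._eigvals


def weights_from_array(W, row_standardize_flag: bool = True, source: str = "generated"):
    """Build :class:`SpatialWeights` from a dense array, optionally row-standardizing."""
    w = SpatialWeights(W=np.asarray(W, dtype=float), source=source)
    return row_standardize(w) if row_standardize_flag else w


def row_standardize(w) -> SpatialWeights:
    """Divide each nonzero row by its sum; zero rows stay zero and are reported.

    Accepts a dense array or a :class:`SpatialWeights`.
    """
    if not isinstance(w, SpatialWeights):
        w = SpatialWeights(W=np.asarray(w, dtype=float))
    sums = w.W.sum(axis=1)
    isolated = np.flatnonzero(sums == 0)
    if isolated.size:
        warnings.warn(
            f"{isolated.size} isolated unit(s) (zero weight rows): "
            f"{isolated.tolist()}",
            RuntimeWarning,
            stacklevel=2,
        )
    denom = np.where(sums > 0, sums, 1.0)
    ws = w.W / denom[:, None]
    out = SpatialWeights(
        W=ws, row_standardized=True, source=w.source, isolated=isolated
    )
    if np.allclose(w.W, w.W.T):
        out._sym_seed = w.W
    return out


def admissible_interval(w: SpatialWeights) -> Tuple[float, float]:
    """Interval of μ keeping I − μW invertible with 1 − μλ_i(W) > 0.

    (1/λ_min, 1/λ_max) from the extreme real eigenvalues, intersected with
    (−1, 1) when W is row-standardized.
    """
    ev = w.eigenvalues()
    lo, hi = -np.inf, np.inf
    if ev.size and ev[0] < -1e-12:
        lo = 1.0 / ev[0]
    if ev.size and ev[-1] > 1e-12:
        hi = 1.0 / ev[-1]
    if w.row_standardized:
        lo, hi = max(lo, -1.0), min(hi, 1.0)
    if not np.isfinite(lo):
        lo = -1.0
    if not np.isfinite(hi):
        hi = 1.0
    return lo, hi


def transform_matrix(w: SpatialWeights, mu: float) -> np.ndarray:
    """B(μ) = I − μW, checked for invertibility."""
    n = w.n
    B = np.eye(n) - mu * w.W
    ev = w.eigenvalues()
    if ev.size and np.min(np.abs(1.0 - mu * ev)) < 1e-10:
        raise ValueError(
            f"I - mu*W is singular at mu={mu}: 1/mu equals an eigenvalue of W"
        )
    return B


def gls_transform(X, y, w: SpatialWeights, mu: float):
    """Whitening transform of the SEM: (X̃, ỹ) = ((I−μW)X, (I−μW)y)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    B = transform_matrix(w, mu)
    return B @ X, B @ y


def omega_inv_sqrt(w: SpatialWeights, mu: float) -> np.ndarray:
    """Symmetric inverse square root of Ω = (I−μW)⁻¹(I−μWᵀ)⁻¹.

    Ω⁻¹ = BᵀB is symmetric positive definite for admissible μ; the returned
    S satisfies S·Ω·S = I with S = Sᵀ ≻ 0.
    """
    B = transform_matrix(w, mu)
    M = B.T @ B
    vals, vecs = scipy.linalg.eigh(M)
    if vals[0] <= 0:
        raise ValueError(f"Omega inverse is not positive definite at mu={mu}")
    return (vecs * np.sqrt(vals)) @ vecs.T


# ---------------------------------------------------------------------------
# Influence functions


@dataclass(frozen=True)
class PsiFunction:
    """A bounded, odd, continuous influence function with its tuning constant."""

    name: str
    c: float
    fn: Callable = field(repr=False)

    def __call__(self, r):
        return self.fn(np.asarray(r, dtype=float), self.c)


def _psi_cauchy(r, c):
    return r / (1.0 + (r / c) ** 2)


def _psi_welsch(r, c):
    return r * np.exp(-((r / c) ** 2))


def _psi_insha(r, c):
    return r * (1.0 + (r / c) ** 4) ** -2


def _psi_logistic(r, c):
    return c * np.tanh(r / c)


def _psi_identity(r, c):
    return r


#: Tuning constants follow the conventional ~95%-efficiency choices for each
#: family (identity = no downweighting, reduces scoring to likelihood scoring).
PSI_FUNCTIONS: Dict[str, PsiFunction] = {
    "cauchy": PsiFunction("cauchy", 2.385, _psi_cauchy),
    "welsch": PsiFunction("welsch", 2.985, _psi_welsch),
    "insha": PsiFunction("insha", 4.0, _psi_insha),
    "logistic": PsiFunction("logistic", 1.205, _psi_logistic),
    "none": PsiFunction("none", np.inf, _psi_identity),
}


def _get_psi(kind) -> PsiFunction:
    if isinstance(kind, PsiFunction):
        return kind
    try:
        return PSI_FUNCTIONS[kind]
    except KeyError:
        raise ValueError(
            f"unknown psi function {kind!r}; available: {sorted(PSI_FUNCTIONS)}"
        ) from None


def psi(r, kind):
    """Evaluate the named influence function at r (vectorized)."""
    out = _get_psi(kind)(r)
    return out if np.ndim(out) else float(out)


_GH_NODES, _GH_WEIGHTS = np.polynomial.hermite.hermgauss(80)


def _normal_expect(fn) -> float:
    # E[fn(Z)], Z ~ N(0,1), by Gauss–Hermite quadrature
    z = np.sqrt(2.0) * _GH_NODES
    return float(np.sum(_GH_WEIGHTS * fn(z)) / np.sqrt(np.pi))


def psi_squared_moment(kind) -> float:
    """K = E[ψ²(Z)] under the standard-normal reference density."""
    p = _get_psi(kind)
    return _normal_expect(lambda z: p(z) ** 2)


def psi_deriv_moment(kind) -> float:
    """E[ψ′(Z)] under the standard normal, via Stein's identity E[Zψ(Z)]."""
    p = _get_psi(kind)
    return _normal_expect(lambda z: z * p(z))


# ---------------------------------------------------------------------------
# Estimates


@dataclass
class SEMEstimate:
    """(μ̂, β̂, σ̂) for a spatial error model."""

    mu_hat: float
    beta_hat: Optional[np.ndarray]
    sigma_hat: Optional[float]
    method: str                 # "mle" | "romle" | "fixed"
    psi_kind: str = "none"
    converged: bool = True
    n_iter: int = 0
    loglik: Optional[float] = None

    def __post_init__(self):
        self.mu_hat = float(self.mu_hat)


# ---------------------------------------------------------------------------
# Gaussian maximum likelihood


def _profile_negloglik(mu, w, X, y, ev):
    n = len(y)
    B = np.eye(n) - mu * w.W
    Xt, yt = B @ X, B @ y
    beta, _, _, _ = np.linalg.lstsq(Xt, yt, rcond=None)
    resid = yt - Xt @ beta
    rss = float(resid @ resid)
    one_minus = 1.0 - mu * ev
    if np.any(one_minus <= 0):
        return np.inf
    logdet = float(np.sum(np.log(one_minus)))
    return 0.5 * n * np.log(max(rss, 1e-300) / n) - logdet


def sem_mle(X, y, w: SpatialWeights, bounds: Optional[Tuple[float, float]] = None):
    """Gaussian SEM maximum likelihood via the profiled (concentrated) likelihood.

    β and σ² are profiled out analytically for each μ; μ is located by a
    bounded scalar search on the admissible interval.  A boundary hit is
    reported with ``converged=False`` and μ̂ at the boundary.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if n <= p:
        raise ValueError(f"need n > p, got n={n}, p={p}")
    ev = w.eigenvalues()
    if bounds is None:
        lo, hi = admissible_interval(w)
    else:
        lo, hi = bounds
    margin = 1e-6 * (hi - lo)
    lo, hi = lo + margin, hi - margin
    res = scipy.optimize.minimize_scalar(
        _profile_negloglik,
        bounds=(lo, hi),
        args=(w, X, y, ev),
        method="bounded",
        options={"xatol": 1e-7},
    )
    mu = float(res.x)
    boundary = min(mu - lo, hi - mu) < 1e-4 * (hi - lo)
    B = np.eye(n) - mu * w.W
    Xt, yt = B @ X, B @ y
    beta, _, _, _ = np.linalg.lstsq(Xt, yt, rcond=None)
    resid = yt - Xt @ beta
    sigma2 = float(resid @ resid) / n
    one_minus = 1.0 - mu * ev
    ll = (
        -0.5 * n * (np.log(2 * np.pi * sigma2) + 1.0)
        + float(np.sum(np.log(one_minus)))
    )
    return SEMEstimate(
        mu_hat=mu,
        beta_hat=beta,
        sigma_hat=float(np.sqrt(sigma2)),
        method="mle",
        psi_kind="none",
        converged=bool(res.success) and not boundary,
        n_iter=int(res.nfev),
        loglik=ll,
    )


# ---------------------------------------------------------------------------
# Robustified-likelihood (RoMLE) scoring


_MAD_NORM = 1.4826022185056018  # 1/Φ⁻¹(3/4): normal-consistent MAD factor


def _robust_scale(resid) -> float:
    med = np.median(resid)
    return _MAD_NORM * float(np.median(np.abs(resid - med)))


def _coarse_profile_mu(X, y, w, ev, lo, hi, n_grid=21) -> float:
    grid = np.linspace(lo, hi, n_grid)
    vals = [_profile_negloglik(m, w, X, y, ev) for m in grid]
    return float(grid[int(np.argmin(vals))])


def romle_fit(
    X,
    y,
    w: SpatialWeights,
    psi_kind="cauchy",
    init: str = "ols",
    tol: float = 1e-6,
    max_sweeps: int = 60,
) -> SEMEstimate:
    """Robustified maximum-likelihood scoring for the SEM.

    Alternates a Fisher-scoring step for β, a residual/scale refresh, and a
    Fisher-scoring step for μ until both updates fall below ``tol``.  If the
    step norm grows for 5 consecutive sweeps the routine falls back to the
    Gaussian MLE with ``converged=False``.

    ``init='ols'`` starts β at OLS and μ at a coarse profile-likelihood grid
    point; a method-of-moments start is an extension hook.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if n <= p:
        raise ValueError(f"need n > p, got n={n}, p={p}")
    if init not in ("ols", "gmm"):
        raise ValueError(f"init must be 'ols' or 'gmm', got {init!r}")
    if init == "gmm":
        raise NotImplementedError("moment-based initialization is an extension hook")
    pfun = _get_psi(psi_kind)
    identity_psi = pfun.name == "none"
    K = psi_squared_moment(pfun)
    D1 = psi_deriv_moment(pfun)

    ev = w.eigenvalues()
    lo, hi = admissible_interval(w)
    margin = 1e-4 * (hi - lo)
    lo_i, hi_i = lo + margin, hi - margin

    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    mu = _coarse_profile_mu(X, y, w, ev, lo_i, hi_i)
    mu = float(np.clip(mu, lo_i, hi_i))

    e = y - X @ beta
    Be = e - mu * (w.W @ e)
    sigma = float(np.sqrt(np.mean(Be**2))) if identity_psi else _robust_scale(Be)
    sigma = max(sigma, 1e-12)

    converged = False
    grow = 0
    last_step = np.inf
    it = 0
    for it in range(1, max_sweeps + 1):
        Xt = X - mu * (w.W @ X)
        e = y - X @ beta
        Be = e - mu * (w.W @ e)
        r = Be / sigma
        psir = pfun(r)
        # β scoring: s_β = X̃ᵀψ(r)/σ̂,  I(β) = E[ψ′]·X̃ᵀX̃/σ̂²
        s_beta = Xt.T @ psir / sigma
        info_b = D1 * (Xt.T @ Xt) / sigma**2
        try:
            d_beta = np.linalg.solve(info_b, s_beta)
        except np.linalg.LinAlgError:
            d_beta, _, _, _ = np.linalg.lstsq(info_b, s_beta, rcond=None)
        beta = beta + d_beta

        # residual + scale refresh at the new β
        e = y - X @ beta
        Be = e - mu * (w.W @ e)
        sigma = float(np.sqrt(np.mean(Be**2))) if identity_psi else _robust_scale(Be)
        sigma = max(sigma, 1e-12)
        r = Be / sigma
        psir = pfun(r)

        # μ scoring: s_μ = −K·tr(B⁻¹W) + ψ(r)ᵀWB⁻¹ψ(r)
        B = np.eye(n) - mu * w.W
        one_minus = 1.0 - mu * ev
        tr_G = float(np.sum(ev / one_minus))
        g = scipy.linalg.solve(B, psir)
        s_mu = -K * tr_G + float(psir @ (w.W @ g))
        # information: K(tr(G²) + tr(GᵀG)), G = WB⁻¹
        G = scipy.linalg.solve(B.T, w.W.T).T
        tr_G2 = float(np.sum(ev**2 / one_minus**2))
        info_mu = K * (tr_G2 + float(np.sum(G * G)))
        d_mu = s_mu / info_mu if info_mu > 0 else 0.0
        new_mu = mu + d_mu
        if not (lo_i < new_mu < hi_i):
            new_mu = float(np.clip(mu + 0.5 * d_mu, lo_i, hi_i))
        d_mu = new_mu - mu
        mu = new_mu

        step = max(float(np.max(np.abs(d_beta), initial=0.0)), abs(d_mu))
        if step < tol:
            converged = True
            break
        grow = grow + 1 if step > last_step else 0
        last_step = step
        if grow >= 5:
            mle = sem_mle(X, y, w)
            mle.converged = False
            mle.psi_kind = pfun.name
            return mle

    return SEMEstimate(
        mu_hat=float(mu),
        beta_hat=beta,
        sigma_hat=float(sigma),
        method="romle",
        psi_kind=pfun.name,
        converged=converged,
        n_iter=it,
    )
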