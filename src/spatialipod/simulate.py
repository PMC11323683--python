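"""Benchmark data generator for the contaminated spatial error model.

A scenario draws y = Xβ + γ + ξ with ξ = μWξ + ε, ε ~ N(0, σ²I):

* design: X = UΣ^{1/2} with U_ij ~ U(−5, 5) iid and Σ the p×p
  equicorrelation matrix (1 on the diagonal, ρ off);
* leverage contamination (optional): the first O rows of X are overwritten
  with the constant vector L·[1, …, 1];
* outliers: γ_i = shift for the first O observations, 0 elsewhere, so the
  ground-truth outlier set is always {0, …, O−1};
* spatial weights: sites sit on a chain with the geometric decay kernel
  w_ij = r^{|i−j|} (i ≠ j), row-standardized by default;
* errors: ξ = (I − μW)⁻¹ε, solved exactly.

Defaults follow the benchmark conditions: n = 500, μ = 0.7, σ² = 0.2,
ρ = 0.5, r = 0.5, shift 8, β = 1_p, p ∈ {15, 50}, O ∈ {10, 20, 50},
L ∈ {none, 15, 20}.  All randomness flows from the scenario seed through a
single ``numpy`` Generator (design drawn first, then ε), so identical seeds
give bit-identical datasets.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import NamedTuple, Optional

import numpy as np
import scipy.linalg

from .sem import SpatialWeights, row_standardize

__all__ = ["Scenario", "make_weights", "make_design", "make_dataset", "Dataset"]


@dataclass(frozen=True)
class Scenario:
    """One cell of the simulation grid."""

    n: int = 500
    p: int = 15
    n_outliers: int = 50          # O: contaminated observations
    leverage: Optional[float] = None  # L: leverage value, or None
    mu: float = 0.7               # spatial autoregressive parameter
    sigma2: float = 0.2           # innovation variance
    rho: float = 0.5              # design equicorrelation
    r_decay: float = 0.5          # weight kernel decay
    shift: float = 8.0            # mean-shift magnitude at outliers
    seed: int = 0
    row_standardize_w: bool = True

    def __post_init__(self):
        if not self.n > self.p:
            raise ValueError(f"need n > p, got n={self.n}, p={self.p}")
        if not 0 <= self.n_outliers < self.n:
            raise ValueError(f"need 0 <= O < n, got O={self.n_outliers}")
        if self.p > 1 and self.rho <= -1.0 / (self.p - 1):
            raise ValueError(
                f"equicorrelation rho={self.rho} is not positive definite for p={self.p}"
            )
        if not 0 < self.r_decay < 1:
            raise ValueError(f"need 0 < r_decay < 1, got {self.r_decay}")
        if self.sigma2 < 0:
            raise ValueError("sigma2 must be nonnegative")

    def with_seed(self, seed: int) -> "Scenario":
        return replace(self, seed=int(seed))


class Dataset(NamedTuple):
    X: np.ndarray
    y: np.ndarray
    w: SpatialWeights
    truth: np.ndarray        # indices of the planted outliers
    beta_true: np.ndarray
    xi: np.ndarray           # the realized spatial error term


def make_weights(n: int, r_decay: float = 0.5, standardize: bool = True) -> SpatialWeights:
    """Chain-graph decay weights w_ij = r^{|i−j|}, zero diagonal.

    Row-standardized by default; pass ``standardize=False`` for the raw
    kernel (sensitivity checks).
    """
    if n < 2:
        raise ValueError(f"need at least 2 units, got n={n}")
    if not 0 < r_decay < 1:
        raise ValueError(f"need 0 < r_decay < 1, got {r_decay}")
    col = r_decay ** np.arange(n, dtype=float)
    W = scipy.linalg.toeplitz(col)
    np.fill_diagonal(W, 0.0)
    w = SpatialWeights(W=W, source="generated")
    return row_standardize(w) if standardize else w


def _equicorr_sqrt(p: int, rho: float) -> np.ndarray:
    """Symmetric square root of the equicorrelation matrix (1−ρ)I + ρJ."""
    if p == 1:
        return np.ones((1, 1))
    if rho <= -1.0 / (p - 1):
        raise ValueError(f"equicorrelation rho={rho} not positive definite for p={p}")
    a = np.sqrt(1.0 - rho)               # eigenvalue on 1⊥
    b = np.sqrt(1.0 - rho + p * rho)     # eigenvalue along 1
    return a * np.eye(p) + (b - a) / p * np.ones((p, p))


def make_design(
    p: int,
    rho: float,
    leverage: Optional[float],
    n_outliers: int,
    rng: np.random.Generator,
    n: int = 500,
) -> np.ndarray:
    """Correlated uniform design X = UΣ^{1/2}, with optional leverage rows.

    When ``leverage`` is not None the first ``n_outliers`` rows of X are
    replaced by the constant vector leverage·[1, …, 1].
    """
    U = rng.uniform(-5.0, 5.0, size=(n, p))
    X = U @ _equicorr_sqrt(p, rho)
    if leverage is not None:
        X[:n_outliers, :] = float(leverage)
    return X


def make_dataset(sc: Scenario, w: Optional[SpatialWeights] = None) -> Dataset:
    """Draw one replicate of the scenario.

    ``w`` may be passed in to reuse a prebuilt (and eigen-cached) weight
    matrix across replicates; it must match the scenario's n/r_decay.
    """
    if w is None:
        w = make_weights(sc.n, sc.r_decay, standardize=sc.row_standardize_w)
    elif w.n != sc.n:
        raise ValueError(f"weights are {w.n}×{w.n} but scenario has n={sc.n}")
    rng = np.random.default_rng(np.random.SeedSequence(sc.seed))
    X = make_design(sc.p, sc.rho, sc.leverage, sc.n_outliers, rng, n=sc.n)
    beta = np.ones(sc.p)
    gamma = np.zeros(sc.n)
    gamma[: sc.n_outliers] = sc.shift
    eps = rng.normal(0.0, np.sqrt(sc.sigma2), size=sc.n)
    B = np.eye(sc.n) - sc.mu * w.W
    xi = scipy.linalg.solve(B, eps)
    y = X @ beta + gamma + xi
    return Dataset(
        X=X,
        y=y,
        w=w,
        truth=np.arange(sc.n_outliers),
        beta_true=beta,
        xi=xi,
    )
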