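"""Threshold (shrinkage) rules and their induced penalties.

A threshold rule Θ(·; λ) is an odd, monotone, unbounded shrinkage operator:
for every λ ≥ 0,

* Θ(−t; λ) = −Θ(t; λ),
* Θ(t; λ) ≤ Θ(t′; λ) for 0 ≤ t ≤ t′,
* 0 ≤ Θ(t; λ) ≤ t for t ≥ 0,
* Θ(t; λ) → ∞ as t → ∞.

Each rule determines a minimum-curvature penalty through the inverse-integral
construction

    Θ⁻¹(u; λ) = sup{t : Θ(t; λ) ≤ u},
    s(u; λ)   = Θ⁻¹(u; λ) − u,
    P_Θ(θ; λ) = ∫₀^{|θ|} s(u; λ) du,

whose penalized least-squares stationary condition reproduces Θ.  The soft
rule induces the lasso penalty λ|θ|; the hard rule induces the capped
quadratic λ|θ| − θ²/2 for |θ| < λ and λ²/2 beyond.  Penalties are stored in
closed form; quadrature of the construction is used only as a test oracle.

The boundary |x| = λ belongs to the zero branch for both rules.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Dict

import numpy as np

__all__ = [
    "ThresholdRule",
    "RULES",
    "get_rule",
    "register_rule",
    "theta_soft",
    "theta_hard",
    "induced_penalty",
    "apply_threshold",
]


def _check_lam(lam) -> np.ndarray:
    lam = np.asarray(lam, dtype=float)
    if np.any(lam < 0):
        raise ValueError(f"threshold level lambda must be nonnegative, got {lam}")
    return lam


def theta_soft(x, lam):
    """Soft threshold: 0 if |x| ≤ λ, else x − sgn(x)·λ.  Vectorized."""
    lam = _check_lam(lam)
    x = np.asarray(x, dtype=float)
    out = np.where(np.abs(x) <= lam, 0.0, x - np.sign(x) * lam)
    return out if out.ndim else float(out)


def theta_hard(x, lam):
    """Hard threshold: 0 if |x| ≤ λ, else x unchanged.  Vectorized."""
    lam = _check_lam(lam)
    x = np.asarray(x, dtype=float)
    out = np.where(np.abs(x) <= lam, 0.0, x)
    return out if out.ndim else float(out)


def _penalty_soft(theta, lam):
    # P(θ; λ) = λ|θ|
    lam = _check_lam(lam)
    theta = np.asarray(theta, dtype=float)
    out = lam * np.abs(theta)
    return out if out.ndim else float(out)


def _penalty_hard(theta, lam):
    # P(θ; λ) = λ|θ| − θ²/2 on |θ| < λ, λ²/2 beyond
    lam = _check_lam(lam)
    theta = np.asarray(theta, dtype=float)
    a = np.abs(theta)
    out = np.where(a < lam, lam * a - 0.5 * a**2, 0.5 * lam**2)
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class ThresholdRule:
    """A named shrinkage rule Θ(·; λ) together with its induced penalty P_Θ."""

    name: str
    theta: Callable = field(repr=False)
    penalty: Callable = field(repr=False)

    def __call__(self, x, lam):
        return self.theta(x, lam)


#: Registry of available rules; additional rules satisfying the shrinkage
#: axioms may be registered without touching the solver.
RULES: Dict[str, ThresholdRule] = {}


def register_rule(rule: ThresholdRule) -> ThresholdRule:
    RULES[rule.name] = rule
    return rule


register_rule(ThresholdRule("soft", theta_soft, _penalty_soft))
register_rule(ThresholdRule("hard", theta_hard, _penalty_hard))


def get_rule(rule) -> ThresholdRule:
    """Resolve a rule name (or pass through a ThresholdRule instance)."""
    if isinstance(rule, ThresholdRule):
        return rule
    try:
        return RULES[rule]
    except KeyError:
        raise ValueError(
            f"unknown threshold rule {rule!r}; available: {sorted(RULES)}"
        ) from None


def induced_penalty(theta, lam, rule) -> float:
    """Evaluate the induced penalty P_Θ(θ; λ) of ``rule`` in closed form."""
    return get_rule(rule).penalty(theta, lam)


def apply_threshold(v, lams, rule):
    """Apply Θ coordinate-wise with a per-coordinate threshold vector.

    Parameters
    ----------
    v : array of working residuals.
    lams : array of the same length; ``lams[i]`` thresholds ``v[i]``.
    rule : rule name or :class:`ThresholdRule`.
    """
    v = np.asarray(v, dtype=float)
    lams = np.asarray(lams, dtype=float)
    if v.shape != lams.shape:
        raise ValueError(
            f"v and lams must have equal length, got {v.shape} vs {lams.shape}"
        )
    return get_rule(rule).theta(v, lams)
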