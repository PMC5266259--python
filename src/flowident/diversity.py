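"""Hill diversity of order one with instrument-error propagation.

The Hill number D1 = exp(-sum p_i ln p_i) (the exponential of Shannon
entropy) is the effective number of equally abundant populations of a
composition; it ranges from 1 (a single population) to S (the even
community).

Flow-cytometric cell counts carry a relative instrumental error eps_I
(<= 5% for typical instruments). Since a relative abundance is a ratio of
two independently measured counts, its variance is

    sigma_p^2 = 2 eps_I^2 p^2,

and first-order (delta-method) propagation through D1 gives

    sigma_D1^2 = D1^2 sum_i (ln p_i + 1)^2 sigma_pi^2.

For S = 2 with p2 = 1 - p1 this reduces to the closed form

    sigma_D1^2 = 2 eps_I^2 D1^2 [p1^2 (ln p1 + 1)^2 + (1-p1)^2 (ln(1-p1) + 1)^2].

Confidence intervals assume approximate normality of D1: 68% -> z = 1.0,
95% -> z = 1.96. The approximation degrades as any p_i -> 0 or 1, where D1
is pinned at a boundary and the linearization loses validity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "DiversityEstimate",
    "d1_with_ci",
    "hill_d1",
    "var_d1",
    "var_d1_binary",
    "var_p",
]

DEFAULT_EPSILON_I = 0.05


def _check_composition(p) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("composition must be a non-empty 1-D vector")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("relative abundances must lie in [0, 1]")
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValueError(f"composition must sum to 1, got {p.sum()!r}")
    return p


def hill_d1(p) -> float:
    """exp(Shannon entropy); zero abundances contribute 0 (0 ln 0 := 0)."""
    p = _check_composition(p)
    nz = p[p > 0]
    return float(np.exp(-np.sum(nz * np.log(nz))))


def var_p(p, epsilon_i: float = DEFAULT_EPSILON_I):
    """Variance of a relative abundance: 2 eps_I^2 p^2 (ratio of two counts)."""
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p must lie in [0, 1]")
    if epsilon_i < 0:
        raise ValueError("epsilon_i must be >= 0")
    out = 2.0 * epsilon_i**2 * p**2
    return float(out) if out.ndim == 0 else out


def var_d1(p, epsilon_i: float = DEFAULT_EPSILON_I) -> float:
    """Delta-method variance of D1 for any richness S.

    Terms with p_i = 0 are skipped: p^2 (ln p + 1)^2 -> 0 as p -> 0. A term
    also vanishes at p_i = 1/e, where ln p_i + 1 = 0.
    """
    p = _check_composition(p)
    d1 = hill_d1(p)
    nz = p[p > 0]
    return float(d1**2 * np.sum((np.log(nz) + 1.0) ** 2 * var_p(nz, epsilon_i)))


def var_d1_binary(p1: float, epsilon_i: float = DEFAULT_EPSILON_I) -> float:
    """Closed form of var_d1 for S = 2, written in terms of p1 alone."""
    p1 = float(p1)
    if not (0.0 <= p1 <= 1.0):
        raise ValueError("p1 must lie in [0, 1]")
    p2 = 1.0 - p1
    d1 = hill_d1(np.array([p1, p2]))
    term1 = p1**2 * (np.log(p1) + 1.0) ** 2 if p1 > 0 else 0.0
    term2 = p2**2 * (np.log(p2) + 1.0) ** 2 if p2 > 0 else 0.0
    return float(2.0 * epsilon_i**2 * d1**2 * (term1 + term2))


@dataclass
class DiversityEstimate:
    """D1 with propagated variance and Gaussian confidence intervals."""

    d1: float
    var_d1: float
    ci68: tuple
    ci95: tuple
    epsilon_i: float


def d1_with_ci(p, epsilon_i: float = DEFAULT_EPSILON_I) -> DiversityEstimate:
    """D1 plus 68%- and 95%-CIs (z = 1.0 and 1.96), both centered on D1."""
    p = _check_composition(p)
    d1 = hill_d1(p)
    var = var_d1(p, epsilon_i)
    sd = float(np.sqrt(var))
    return DiversityEstimate(
        d1=d1,
        var_d1=var,
        ci68=(d1 - sd, d1 + sd),
        ci95=(d1 - 1.96 * sd, d1 + 1.96 * sd),
        epsilon_i=float(epsilon_i),
    )
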