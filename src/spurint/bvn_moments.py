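"""Quadrant probabilities and truncated conditional means of a standard
bivariate normal dichotomized at a common cut point.

Dichotomizing a standard bivariate normal pair (X1, X2) with correlation
``rho`` at a common threshold ``c`` partitions the plane into four
quadrants, indexed ``(i, j) = (1(X1 > c), 1(X2 > c))``.  This module
provides the orthant probabilities F_ij of landing in each quadrant and
the conditional expectations E(X1 | quadrant ij), both in closed form
(via the Mehler-identity result for the upper quadrant plus the
marginalization identities that recover the other three) and by adaptive
2-D quadrature, which also serves unequal cut points.

All quantities are on the standard-normal scale; conditional means of X2
follow from symmetry: E(X2 | quadrant ij) = E(X1 | quadrant ji).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import integrate
from scipy.stats import multivariate_normal, norm

__all__ = [
    "UNDERFLOW_GUARD",
    "BivariateSpec",
    "QuadrantProbabilities",
    "QuadrantMeans",
    "DegenerateCorrelationError",
    "QuadrantUnderflowError",
    "bvn_cdf",
    "quadrant_probabilities",
    "upper_quadrant_mean",
    "quadrant_means",
    "quadrant_means_numeric",
]

#: Quadrant probabilities below this are treated as numerical underflow:
#: conditional means divide by F_ij, so values this small yield noise.
UNDERFLOW_GUARD = 1e-12

#: Effectively-infinite integration bound on the standard-normal scale.
_INF = 9.0


class DegenerateCorrelationError(ValueError):
    """Raised when |rho| >= 1 (the dichotomized pair is degenerate)."""


class QuadrantUnderflowError(FloatingPointError):
    """Raised when a quadrant probability underflows below the guard."""


@dataclass(frozen=True)
class BivariateSpec:
    """Standard bivariate normal with correlation ``rho``, cut at ``c``.

    Both exposures share the cut point (the analytically tractable case);
    unequal cuts are available through :func:`quadrant_means_numeric`.
    """

    rho: float
    c: float

    def __post_init__(self) -> None:
        if not abs(self.rho) < 1.0:
            raise DegenerateCorrelationError(
                f"|rho| must be < 1, got rho={self.rho} (rho = +/-1 is degenerate)"
            )
        if not math.isfinite(self.c):
            raise ValueError(f"cut point must be finite, got c={self.c}")


@dataclass(frozen=True)
class QuadrantProbabilities:
    """Orthant probabilities F_ij, (i, j) = (1(X1 > c1), 1(X2 > c2))."""

    F00: float
    F01: float
    F10: float
    F11: float

    def as_array(self) -> np.ndarray:
        return np.array([self.F00, self.F01, self.F10, self.F11])


@dataclass(frozen=True)
class QuadrantMeans:
    """Conditional means E(X1 | quadrant ij), same indexing as F_ij."""

    E00: float
    E01: float
    E10: float
    E11: float

    def as_array(self) -> np.ndarray:
        return np.array([self.E00, self.E01, self.E10, self.E11])


def bvn_cdf(h: float, k: float, rho: float) -> float:
    """P(X1 <= h, X2 <= k) for a standard bivariate normal."""
    return float(
        multivariate_normal.cdf(
            [h, k], mean=[0.0, 0.0], cov=[[1.0, rho], [rho, 1.0]]
        )
    )


def _orthant_quad(rho: float, a: float, b: float) -> float:
    """P(X1 <= a, X2 <= b) by a 1-D reduction, relatively accurate even
    for tiny orthant masses (the integrand is positive)."""
    s = math.sqrt(1.0 - rho * rho)
    val, _ = integrate.quad(
        lambda x: norm.pdf(x) * norm.cdf((b - rho * x) / s),
        -np.inf,
        a,
        epsabs=1e-16,
        epsrel=1e-12,
        limit=200,
    )
    return val


def _orthants(rho: float, c1: float, c2: float) -> QuadrantProbabilities:
    F00 = bvn_cdf(c1, c2, rho)
    F01 = norm.cdf(c1) - F00
    F10 = norm.cdf(c2) - F00
    F11 = 1.0 - norm.cdf(c1) - norm.cdf(c2) + F00
    # the library CDF is absolutely (not relatively) accurate; refine any
    # near-underflow orthant with the positive-integrand reduction
    if F00 < 1e-8:
        F00 = _orthant_quad(rho, c1, c2)
    if F01 < 1e-8:
        F01 = _orthant_quad(-rho, c1, -c2)
    if F10 < 1e-8:
        F10 = _orthant_quad(-rho, -c1, c2)
    if F11 < 1e-8:
        F11 = _orthant_quad(rho, -c1, -c2)
    probs = QuadrantProbabilities(F00, F01, F10, F11)
    if np.any(probs.as_array() < UNDERFLOW_GUARD):
        raise QuadrantUnderflowError(
            f"quadrant probability below {UNDERFLOW_GUARD:g} at "
            f"rho={rho}, cuts=({c1}, {c2}): {probs}"
        )
    return probs


def quadrant_probabilities(spec: BivariateSpec) -> QuadrantProbabilities:
    """Orthant probabilities of the four quadrants at the common cut.

    With equal cuts F01 = F10 by symmetry, and the four probabilities sum
    to one exactly up to the accuracy of the bivariate-normal CDF.
    """
    return _orthants(spec.rho, spec.c, spec.c)


def upper_quadrant_mean(spec: BivariateSpec) -> float:
    """E(X1 | X1 > c, X2 > c), the upper-quadrant truncated mean.

    Closed form (a Mehler-identity consequence):

        F11 * E(X1 | X1>c, X2>c) = phi(c) * [1 - Phi((c - rho*c)/sqrt(1-rho^2))] * (1 + rho)
    """
    F11 = quadrant_probabilities(spec).F11
    return _upper_quadrant_numerator(spec.rho, spec.c) / F11


def _upper_quadrant_numerator(rho: float, c: float) -> float:
    a = (c - rho * c) / math.sqrt(1.0 - rho * rho)
    return norm.pdf(c) * (1.0 - norm.cdf(a)) * (1.0 + rho)


def quadrant_means(spec: BivariateSpec) -> QuadrantMeans:
    """Closed-form conditional means of X1 in all four quadrants.

    The upper quadrant comes from :func:`upper_quadrant_mean`; the others
    follow from the marginalization identities

        F10*E10 = phi(c) - F11*E11          (marginalizing over X2 > c vs <= c)
        F01*E01 = rho*phi(c) - F11*E11
        F00*E00 = E(X1) - F11*E11 - F01*E01 - F10*E10,   E(X1) = 0.

    The last identity simplifies to the cancellation-free product
    F00*E00 = -phi(c)*Phi(a)*(1+rho), a = (c - rho*c)/sqrt(1-rho^2),
    which stays relatively accurate when F00 is tiny.
    """
    probs = quadrant_probabilities(spec)
    phi_c = norm.pdf(spec.c)
    a = (spec.c - spec.rho * spec.c) / math.sqrt(1.0 - spec.rho**2)
    n11 = _upper_quadrant_numerator(spec.rho, spec.c)
    n10 = phi_c - n11
    n01 = spec.rho * phi_c - n11
    n00 = -phi_c * norm.cdf(a) * (1.0 + spec.rho)
    return QuadrantMeans(
        E00=n00 / probs.F00,
        E01=n01 / probs.F01,
        E10=n10 / probs.F10,
        E11=n11 / probs.F11,
    )


def quadrant_means_numeric(
    rho: float, c1: float, c2: float, *, epsabs: float = 1e-10
) -> tuple[QuadrantProbabilities, QuadrantMeans]:
    """Quadrant probabilities and conditional means of X1 by 2-D quadrature.

    Independent of the closed forms: integrates the bivariate-normal
    density (and x1 times it) over each quadrant with adaptive quadrature.
    Also handles unequal cut points, which the closed forms do not cover.

    Raises
    ------
    DegenerateCorrelationError
        If ``|rho| >= 1``.
    RuntimeError
        If the quadrature error estimate exceeds 100x ``epsabs``.
    """
    if not abs(rho) < 1.0:
        raise DegenerateCorrelationError(f"|rho| must be < 1, got {rho}")

    det = 1.0 - rho * rho
    norm_const = 1.0 / (2.0 * math.pi * math.sqrt(det))

    def density(x2: float, x1: float) -> float:
        q = (x1 * x1 - 2.0 * rho * x1 * x2 + x2 * x2) / det
        return norm_const * math.exp(-0.5 * q)

    def x1_density(x2: float, x1: float) -> float:
        return x1 * density(x2, x1)

    # (i, j) -> x1 limits, x2 limits
    quadrants = {
        (0, 0): ((-_INF, c1), (-_INF, c2)),
        (0, 1): ((-_INF, c1), (c2, _INF)),
        (1, 0): ((c1, _INF), (-_INF, c2)),
        (1, 1): ((c1, _INF), (c2, _INF)),
    }
    probs: dict[tuple[int, int], float] = {}
    means: dict[tuple[int, int], float] = {}
    for ij, ((x1_lo, x1_hi), (x2_lo, x2_hi)) in quadrants.items():
        p, perr = integrate.dblquad(
            density, x1_lo, x1_hi, x2_lo, x2_hi, epsabs=epsabs
        )
        m, merr = integrate.dblquad(
            x1_density, x1_lo, x1_hi, x2_lo, x2_hi, epsabs=epsabs
        )
        if max(perr, merr) > 100.0 * epsabs:
            raise RuntimeError(
                f"quadrature did not converge on quadrant {ij}: "
                f"achieved error {max(perr, merr):.2e} > {100.0 * epsabs:.2e}"
            )
        if p < UNDERFLOW_GUARD:
            raise QuadrantUnderflowError(
                f"quadrant {ij} probability {p:g} below guard"
            )
        probs[ij] = p
        means[ij] = m / p

    return (
        QuadrantProbabilities(
            F00=probs[0, 0], F01=probs[0, 1], F10=probs[1, 0], F11=probs[1, 1]
        ),
        QuadrantMeans(
            E00=means[0, 0], E01=means[0, 1], E10=means[1, 0], E11=means[1, 1]
        ),
    )
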