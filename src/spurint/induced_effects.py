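"""Induced coefficients of the saturated model in two dichotomized exposures.

The data-generating model is linear with no interaction,

    Y = beta0 + beta1*X1 + beta2*X2 + eps,   (X1, X2) standard bivariate
    normal with correlation rho,

but the analyst fits a saturated model in the 0/1 indicators
X~1 = 1(X1 > c), X~2 = 1(X2 > c) and their product.  Because the fitted
model is saturated, its coefficients are exact contrasts of the four cell
means mu_ij = E(Y | X~1=i, X~2=j):

    bt0 = mu00, bt1 = mu10 - mu00, bt2 = mu01 - mu00,
    bt3 = mu11 - mu01 - mu10 + mu00,

and bt3 — the induced interaction — is generally nonzero even though the
true model has none.  It vanishes only at the median cut (c = 0), under
independence (rho = 0), or when beta1 = -beta2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.stats import norm

from .bvn_moments import (
    BivariateSpec,
    quadrant_means,
    quadrant_probabilities,
)

__all__ = [
    "TrueModel",
    "CellMeans",
    "InducedCoefficients",
    "ZeroInteractionRoots",
    "cell_means",
    "induced_coefficients",
    "interaction_contrast_eq11",
    "interaction_ratio",
    "main_effect_curve",
    "zero_interaction_roots",
    "theory_grid",
]


@dataclass(frozen=True)
class TrueModel:
    """Linear no-interaction model Y = beta0 + beta1*X1 + beta2*X2 + eps.

    ``sigma2`` is the residual variance; it does not enter any expectation
    here but is carried for the simulation engine.
    """

    beta0: float = 0.0
    beta1: float = 1.0
    beta2: float = 1.0
    sigma2: float = 0.0

    def __post_init__(self) -> None:
        if self.sigma2 < 0:
            raise ValueError(f"sigma2 must be >= 0, got {self.sigma2}")


@dataclass(frozen=True)
class CellMeans:
    """E(Y | X~1 = i, X~2 = j) over the four dichotomized cells."""

    mu00: float
    mu01: float
    mu10: float
    mu11: float


@dataclass(frozen=True)
class InducedCoefficients:
    """Coefficients of the saturated fit in 0/1-coded indicators."""

    bt0: float
    bt1: float
    bt2: float
    bt3: float

    @classmethod
    def from_cell_means(cls, mu: CellMeans) -> "InducedCoefficients":
        return cls(
            bt0=mu.mu00,
            bt1=mu.mu10 - mu.mu00,
            bt2=mu.mu01 - mu.mu00,
            bt3=mu.mu11 - mu.mu01 - mu.mu10 + mu.mu00,
        )

    def as_array(self) -> np.ndarray:
        return np.array([self.bt0, self.bt1, self.bt2, self.bt3])


def cell_means(model: TrueModel, spec: BivariateSpec) -> CellMeans:
    """Cell means of Y given the pair of dichotomized indicators.

    mu_ij = beta0 + beta1*E(X1|quadrant ij) + beta2*E(X2|quadrant ij),
    with E(X2|quadrant ij) = E(X1|quadrant ji) by the symmetry of the
    equal-cut bivariate normal.
    """
    E = quadrant_means(spec)
    b0, b1, b2 = model.beta0, model.beta1, model.beta2
    return CellMeans(
        mu00=b0 + b1 * E.E00 + b2 * E.E00,
        mu01=b0 + b1 * E.E01 + b2 * E.E10,
        mu10=b0 + b1 * E.E10 + b2 * E.E01,
        mu11=b0 + b1 * E.E11 + b2 * E.E11,
    )


def induced_coefficients(
    model: TrueModel, spec: BivariateSpec
) -> InducedCoefficients:
    """The four saturated-model coefficients; ``bt3`` is the induced interaction."""
    return InducedCoefficients.from_cell_means(cell_means(model, spec))


def interaction_contrast_eq11(model: TrueModel, spec: BivariateSpec) -> float:
    """The induced interaction via the explicit orthant-probability bracket.

    Writes bt3 = (beta1+beta2)(1+rho)*phi(c) * [ (1-Phi(a))/F11
    - Phi(a)/F00 - (2*Phi(a)-1)/F01 ] with a = (c - rho*c)/sqrt(1-rho^2);
    an algebraically equivalent route to the cell-mean contrast, exposed
    for cross-validation and root-finding.
    """
    F = quadrant_probabilities(spec)
    rho, c = spec.rho, spec.c
    a = (c - rho * c) / math.sqrt(1.0 - rho * rho)
    Phi_a = norm.cdf(a)
    bracket = (
        (1.0 - Phi_a) / F.F11 - Phi_a / F.F00 - (2.0 * Phi_a - 1.0) / F.F01
    )
    return (
        (model.beta1 + model.beta2) * (1.0 + rho) * norm.pdf(c) * bracket
    )


def interaction_ratio(model: TrueModel, spec: BivariateSpec) -> float:
    """|bt3 / bt2|: size of the induced interaction relative to a main effect.

    With beta1 = beta2 the ratio to bt1 is identical by symmetry.
    """
    coef = induced_coefficients(model, spec)
    if abs(coef.bt2) < 1e-12:
        raise ZeroDivisionError(
            f"main effect bt2 = {coef.bt2:g} is degenerate; ratio undefined"
        )
    return abs(coef.bt3 / coef.bt2)


def main_effect_curve(
    model: TrueModel, rho: float, c_grid: np.ndarray
) -> np.ndarray:
    """bt2 as a function of the cut point, at fixed correlation."""
    return np.array(
        [
            induced_coefficients(model, BivariateSpec(rho=rho, c=float(c))).bt2
            for c in np.asarray(c_grid, dtype=float)
        ]
    )


@dataclass(frozen=True)
class ZeroInteractionRoots:
    """Roots of bt3(c) in a cut-point range, at fixed correlation.

    ``identically_zero`` flags the degenerate regimes (rho = 0 or
    beta1 = -beta2) where bt3 vanishes for every cut point, in which case
    ``roots`` is empty rather than listing the whole grid.
    """

    roots: tuple[float, ...]
    identically_zero: bool


def zero_interaction_roots(
    model: TrueModel,
    rho: float,
    c_range: tuple[float, float] = (-2.0, 2.0),
    *,
    n_grid: int = 400,
    xtol: float = 1e-8,
) -> ZeroInteractionRoots:
    """All sign-change roots of the induced interaction bt3(c).

    Scans ``n_grid`` points for sign changes, then polishes each bracket
    with Brent's method.  For normal marginals with rho != 0 and
    beta1 != -beta2 the unique root in any range containing it is c = 0.
    """
    lo, hi = map(float, c_range)
    if not (math.isfinite(lo) and math.isfinite(hi) and lo < hi):
        raise ValueError(f"invalid c_range {c_range}")

    def f(c: float) -> float:
        return interaction_contrast_eq11(model, BivariateSpec(rho=rho, c=c))

    grid = np.linspace(lo, hi, n_grid)
    values = np.array([f(c) for c in grid])
    if np.max(np.abs(values)) < 1e-10:
        return ZeroInteractionRoots(roots=(), identically_zero=True)

    roots: list[float] = []
    for cl, cr, vl, vr in zip(grid[:-1], grid[1:], values[:-1], values[1:]):
        if vl == 0.0:
            roots.append(float(cl))
        elif vl * vr < 0.0:
            roots.append(float(optimize.brentq(f, cl, cr, xtol=xtol)))
    if values[-1] == 0.0:
        roots.append(float(grid[-1]))
    return ZeroInteractionRoots(roots=tuple(roots), identically_zero=False)


def theory_grid(
    model: TrueModel,
    rhos: "list[float]",
    c_grid: np.ndarray,
) -> pd.DataFrame:
    """Induced coefficients and |bt3/bt2| over a (rho, c) grid.

    One row per grid point with columns
    (rho, c, bt0, bt1, bt2, bt3, ratio_bt3_bt2); the numeric form of the
    interaction-ratio and main-effect curves.
    """
    rows = []
    for rho in rhos:
        for c in np.asarray(c_grid, dtype=float):
            coef = induced_coefficients(model, BivariateSpec(rho=rho, c=float(c)))
            ratio = (
                abs(coef.bt3 / coef.bt2) if abs(coef.bt2) >= 1e-12 else np.nan
            )
            rows.append(
                {
                    "rho": rho,
                    "c": float(c),
                    "bt0": coef.bt0,
                    "bt1": coef.bt1,
                    "bt2": coef.bt2,
                    "bt3": coef.bt3,
                    "ratio_bt3_bt2": ratio,
                }
            )
    return pd.DataFrame(rows)
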