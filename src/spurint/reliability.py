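"""Point-biserial reliability of dichotomized exposures.

Dichotomization is an extreme form of measurement error: the indicator
1(X > c) is a noisy surrogate for the continuous X, and its reliability
is the point-biserial correlation corr(X, 1(X > c)).  For a normal X this
is h / sqrt(p*q), with h the normal ordinate at the cut and p, q the
probability masses above and below it (the formula is symmetric in p, q).

When the reliability of X~1 differs between the strata of the other
dichotomized variable X~2, the measurement error is differential, which
is what produces the induced interaction — and the stratum with the
poorer reliability determines its sign.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

__all__ = [
    "ReliabilityReport",
    "point_biserial_normal",
    "empirical_point_biserial",
    "stratified_reliability",
]


@dataclass(frozen=True)
class ReliabilityReport:
    """Point-biserial reliability of X~1, overall and within X~2 strata.

    ``by_stratum`` holds the correlations within X~2 = 0 and X~2 = 1,
    in that order.
    """

    overall: float
    by_stratum: tuple[float, float]
    cut: float


def point_biserial_normal(c: float) -> float:
    """Closed-form corr(X, 1(X > c)) for standard-normal X.

    Equals phi(c) / sqrt(Phi(c) * (1 - Phi(c))); maximal at the median
    cut c = 0, where it is 2*phi(0) = sqrt(2/pi).
    """
    p = norm.sf(c)
    q = norm.cdf(c)
    return float(norm.pdf(c) / np.sqrt(p * q))


def empirical_point_biserial(x: np.ndarray, cut: float) -> float:
    """Sample Pearson correlation between x and the indicator 1(x > cut).

    Raises
    ------
    ValueError
        If fewer than two observations, x is constant, or either category
        is empty (the correlation is undefined).
    """
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValueError(f"need at least 2 observations, got {x.size}")
    ind = (x > cut).astype(float)
    if ind.min() == ind.max():
        raise ValueError(f"degenerate sample: all values on one side of cut={cut}")
    if np.ptp(x) == 0.0:
        raise ValueError("degenerate sample: x is constant")
    return float(np.corrcoef(x, ind)[0, 1])


def stratified_reliability(
    x1: np.ndarray,
    x2: np.ndarray,
    cut1: float,
    cut2: float,
) -> ReliabilityReport:
    """Reliability of X~1 overall and within the two strata of X~2.

    The stratified correlations are always the empirical estimator, even
    for normal samples: within a stratum of X~2 the distribution of X1 is
    no longer normal, so the marginal closed form does not apply.

    Raises
    ------
    ValueError
        If the paired samples differ in length or any of the four
        stratum-by-category cells is empty.
    """
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    if x1.shape != x2.shape:
        raise ValueError(f"paired samples required, got {x1.shape} vs {x2.shape}")

    overall = empirical_point_biserial(x1, cut1)
    strata = []
    for level, mask in ((0, x2 <= cut2), (1, x2 > cut2)):
        sub = x1[mask]
        if sub.size == 0 or not (np.any(sub > cut1) and np.any(sub <= cut1)):
            raise ValueError(
                f"degenerate stratum X~2={level}: empty reliability cell"
            )
        strata.append(empirical_point_biserial(sub, cut1))
    return ReliabilityReport(
        overall=overall, by_stratum=(strata[0], strata[1]), cut=cut1
    )
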