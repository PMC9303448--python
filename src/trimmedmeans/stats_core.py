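"""Normal and truncated-normal moment analytics.

Everything in the bias calculus for trimmed-means estimation of a two-arm
trial reduces to moments of a standard normal restricted to a quantile
window ``(u, v)``: the window ``(p, 1)`` is the retained fraction after
trimming the lowest ``p`` of an arm, ``(0, c)`` is a region affected by
dropout, and so on.  All public operations here are parameterized on the
probability scale; conversion to outcome units happens only through
:class:`NormalArm`, which keeps the two arms interchangeable.

The central quantity is the dimensionless factor

    Q(u, v) = [phi(Phi^-1(v)) - phi(Phi^-1(u))] / (v - u),

with ``phi`` the standard-normal density and ``Phi^-1`` its quantile
function, under the convention ``phi(Phi^-1(0)) = phi(Phi^-1(1)) = 0``
(the limiting value).  The mean of a normal with location ``mu`` and scale
``sigma`` truncated to the quantile window ``(u, v)`` is then
``mu - sigma * Q(u, v)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy.stats import norm

__all__ = [
    "NormalArm",
    "QuantileInterval",
    "q_factor",
    "truncated_mean",
    "truncated_sd",
    "half_normal_sd_factor",
    "HALF_NORMAL_SD_RATIO",
    "tail_density",
]

#: Numerical tolerance for probability-interval checks.
INTERVAL_TOL = 1e-12

#: Ratio between the SD of the upper (or lower) half of a normal
#: distribution and the full-sample SD: sqrt(1 - 2/pi) ~= 0.60281.
HALF_NORMAL_SD_RATIO = math.sqrt(1.0 - 2.0 / math.pi)


@dataclass(frozen=True)
class NormalArm:
    """Normal outcome model for one trial arm.

    Parameters
    ----------
    mu : float
        Population mean of the arm's outcome, in outcome units.
    sigma : float
        Population SD of the arm's outcome, in outcome units.  Must be
        strictly positive.
    """

    mu: float
    sigma: float

    def __post_init__(self) -> None:
        if not self.sigma > 0:
            raise ValueError(f"sigma must be > 0, got {self.sigma}")


@dataclass(frozen=True)
class QuantileInterval:
    """A probability window ``(u, v)`` of a distribution, ``0 <= u < v <= 1``.

    ``mass`` is the probability content ``v - u`` of the window.
    """

    u: float
    v: float

    def __post_init__(self) -> None:
        if self.u < -INTERVAL_TOL or self.v > 1.0 + INTERVAL_TOL:
            raise ValueError(f"interval ({self.u}, {self.v}) not within [0, 1]")
        if self.v - self.u <= INTERVAL_TOL:
            raise ValueError(
                f"degenerate quantile interval ({self.u}, {self.v}): "
                "the window contains no probability mass"
            )

    @property
    def mass(self) -> float:
        return self.v - self.u

    def reflected(self) -> "QuantileInterval":
        """The window mirrored about the median: ``(1 - v, 1 - u)``."""
        return QuantileInterval(1.0 - self.v, 1.0 - self.u)


def tail_density(q: float) -> float:
    """``phi(Phi^-1(q))`` with the limit value 0 at ``q`` in {0, 1}."""
    if q <= 0.0 or q >= 1.0:
        return 0.0
    return float(norm.pdf(norm.ppf(q)))


def _quantile_times_density(q: float) -> float:
    """``Phi^-1(q) * phi(Phi^-1(q))``, with limit value 0 at q in {0, 1}."""
    if q <= 0.0 or q >= 1.0:
        return 0.0
    z = norm.ppf(q)
    return float(z * norm.pdf(z))


def q_factor(interval: QuantileInterval) -> float:
    """Dimensionless truncation factor ``Q(u, v)``.

    Antisymmetric under reflection of the window about the median:
    ``Q(1 - v, 1 - u) = -Q(u, v)``.  ``Q(0, 1) = 0`` (no truncation) and
    ``Q(0.5, 1) = -sqrt(2/pi)`` (upper half).
    """
    return (tail_density(interval.v) - tail_density(interval.u)) / interval.mass


def truncated_mean(arm: NormalArm, interval: QuantileInterval) -> float:
    """Mean of the arm's outcome restricted to the quantile window.

    For the full window ``(0, 1)`` this is ``mu``; for ``(p, 1)`` it is the
    population trimmed mean after removing the lowest fraction ``p``; for
    ``(0.5, 1)`` it equals ``mu + sigma * sqrt(2/pi)``.
    """
    return arm.mu - arm.sigma * q_factor(interval)


def truncated_sd(arm: NormalArm, interval: QuantileInterval) -> float:
    """SD of the arm's outcome restricted to the quantile window.

    Uses the standard truncated-normal second moment
    ``E[Z^2 | window] = 1 + (z_u phi(z_u) - z_v phi(z_v)) / (v - u)``.
    """
    second = 1.0 + (
        _quantile_times_density(interval.u) - _quantile_times_density(interval.v)
    ) / interval.mass
    var = second - q_factor(interval) ** 2
    # guard tiny negative round-off for very narrow windows
    return arm.sigma * math.sqrt(max(var, 0.0))


def half_normal_sd_factor() -> tuple[float, float]:
    """Ratio linking a half-normal fraction SD to the full-sample SD.

    Returns ``(r, 1/r)`` with ``r = sqrt(1 - 2/pi)``: the SD of the upper
    (or lower) half of a normal with SD ``sigma`` is ``r * sigma``, so a
    full-sample SD can be extrapolated from a 50%-trimmed fraction SD by
    multiplying with ``1/r = sqrt(pi/(pi - 2))``.
    """
    return HALF_NORMAL_SD_RATIO, 1.0 / HALF_NORMAL_SD_RATIO
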