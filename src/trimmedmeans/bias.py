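"""Closed-form bias calculus for CCA and trimmed-means estimators.

All formulae assume normally distributed outcomes within each arm and a
*homogeneous* dropout mechanism: within a quantile region of spread ``c``
measured from the trimmed tail, every value is equally likely to be
missing (``c = 1`` is MCAR); ``p_d`` is the arm's marginal dropout
proportion, ``p`` the trimming fraction.

Two assumptions drive the decomposition of the total TM bias:

* *location shift*: the arm outcome distributions differ only by a mean
  shift (equal SDs).  Violation biases the TM effect by
  ``(sigma_1 - sigma_0) * phi(Phi^-1(p)) / (1 - p)`` for lower-tail
  trimming (``(sigma_1 - sigma_0) * sqrt(2/pi)`` at ``p = 0.5``).
* *strong MNAR*: all dropout falls inside the trimmed-away fraction
  (``c <= p``).  When dropout spreads beyond the trimmed fraction
  (``c > p``), the retained fraction silently extends below the intended
  quantile, from ``p`` down to a shift quantile ``b``, and the affected
  arm's trimmed mean is overestimated.

Sign convention: every bias is reported on the ``beta_hat - beta`` scale
of the fitted treatment-effect regression.  For lower-tail trimming, a
strong-MNAR violation in the comparator arm pushes the estimate up
(overestimating the effect) and a violation in the treatment arm pushes
it down; both flip under higher-tail trimming.  Direction handling is
centralized in :func:`combine_biases`; the per-arm magnitude functions
are direction agnostic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .stats_core import (
    NormalArm,
    QuantileInterval,
    q_factor,
    tail_density,
    truncated_sd,
)

__all__ = [
    "ArmDropout",
    "DropoutScenario",
    "BiasDecomposition",
    "MaxBiasBounds",
    "location_shift_bias",
    "strong_mnar_shift",
    "strong_mnar_bias",
    "cca_bias",
    "cca_max_bias",
    "tm_max_bias",
    "combine_biases",
    "bias_adjusted_estimate",
    "infer_full_sd",
]


@dataclass(frozen=True)
class ArmDropout:
    """Homogeneous dropout scenario for one arm.

    ``dropout_proportion`` (``p_d``) of the arm is missing, spread
    homogeneously over the fraction ``spread_bound`` (``c``) of the
    outcome distribution adjacent to the trimmed tail; the implied
    within-region missingness rate is ``p_d / c``.
    """

    dropout_proportion: float
    spread_bound: float = 1.0
    direction: str = "lower"

    def __post_init__(self) -> None:
        if not 0.0 <= self.dropout_proportion < 1.0:
            raise ValueError(f"dropout proportion must be in [0, 1), got {self.dropout_proportion}")
        if not 0.0 < self.spread_bound <= 1.0:
            raise ValueError(f"spread bound must be in (0, 1], got {self.spread_bound}")
        if self.dropout_proportion > self.spread_bound + 1e-12:
            raise ValueError(
                f"dropout proportion {self.dropout_proportion} exceeds the spread "
                f"bound {self.spread_bound}: the region cannot hold that much dropout"
            )
        if self.direction not in ("lower", "higher"):
            raise ValueError(f"direction must be 'lower' or 'higher', got {self.direction!r}")

    @property
    def is_mcar(self) -> bool:
        return self.spread_bound >= 1.0


@dataclass(frozen=True)
class DropoutScenario:
    """Per-arm homogeneous dropout scenario for a two-arm trial."""

    comparator: ArmDropout
    treatment: ArmDropout

    def arm(self, j: int) -> ArmDropout:
        return self.comparator if j == 0 else self.treatment


@dataclass(frozen=True)
class BiasDecomposition:
    """Additive decomposition of the total TM estimator bias.

    ``b_total = b_ls + b_sm_arm0 + b_sm_arm1`` (all signed on the
    ``beta_hat - beta`` scale); ``bias_adjusted_estimate`` is
    ``tm_estimate - b_total`` and ``estimate_bounds`` the ordered pair
    bracketing the effect between the raw and bias-adjusted TM estimates.
    """

    b_ls: float
    b_sm_arm0: float
    b_sm_arm1: float
    tm_estimate: float

    @property
    def b_total(self) -> float:
        return self.b_ls + self.b_sm_arm0 + self.b_sm_arm1

    @property
    def bias_adjusted_estimate(self) -> float:
        return self.tm_estimate - self.b_total

    @property
    def estimate_bounds(self) -> tuple[float, float]:
        lo, hi = sorted((self.tm_estimate, self.bias_adjusted_estimate))
        return lo, hi

    def to_dict(self) -> dict:
        return {
            "b_ls": self.b_ls,
            "b_sm_arm0": self.b_sm_arm0,
            "b_sm_arm1": self.b_sm_arm1,
            "b_total": self.b_total,
            "tm_estimate": self.tm_estimate,
            "bias_adjusted_estimate": self.bias_adjusted_estimate,
            "estimate_bounds": list(self.estimate_bounds),
        }


@dataclass(frozen=True)
class MaxBiasBounds:
    """Worst-case bias bounds under adversarial (threshold) dropout.

    ``cca_max`` is the Copas-Jackson bound on the CCA bias magnitude;
    ``tm_sm_max`` the maximal strong-MNAR bias of the affected arm's
    trimmed mean (signed: opposite-tail dropout underestimates it);
    ``tm_total_max`` adds the location-shift term.  ``threshold`` is the
    selection threshold of the attaining step-function mechanism, as an
    offset from the affected arm's mean, and ``selection_probability``
    the overall probability ``1 - p_d`` of being observed.
    """

    cca_max: float
    tm_sm_max: float
    tm_total_max: float
    threshold: float
    selection_probability: float

    def to_dict(self) -> dict:
        return {
            "cca_max": self.cca_max,
            "tm_sm_max": self.tm_sm_max,
            "tm_total_max": self.tm_total_max,
            "threshold": self.threshold,
            "selection_probability": self.selection_probability,
        }


# ---------------------------------------------------------------------------
# location shift
# ---------------------------------------------------------------------------

def location_shift_bias(
    sigma1: float, sigma0: float, p: float = 0.5, direction: str = "lower"
) -> float:
    """TM bias from unequal arm SDs: ``(sigma1 - sigma0) phi(Phi^-1(p)) / (1-p)``.

    Zero iff the SDs are equal; reduces to ``(sigma1 - sigma0) sqrt(2/pi)``
    at ``p = 0.5``.  The sign flips for higher-tail trimming.
    """
    if not (sigma1 > 0 and sigma0 > 0):
        raise ValueError("arm SDs must be positive")
    if not 0.0 < p < 1.0:
        raise ValueError(f"trimming fraction must be in (0, 1), got {p}")
    bias = (sigma1 - sigma0) * tail_density(p) / (1.0 - p)
    return bias if direction == "lower" else -bias


# ---------------------------------------------------------------------------
# strong MNAR under homogeneous dropout
# ---------------------------------------------------------------------------

def strong_mnar_shift(p: float, c: float, pd: float) -> float:
    """Quantile ``b`` down to which the retained fraction silently extends.

    Homogeneous dropout of total mass ``pd`` over the region ``(0, c)``
    thins the observed distribution there by ``1 - pd/c``; taking the top
    ``1 - p`` of the missing-padded sample therefore reaches down to the
    quantile ``b`` solving ``(c - b)(1 - pd/c) = c - p``, i.e.
    ``b = c - c (c - p) / (c - pd)``.  When the dropout region lies
    inside the trimmed fraction (``c <= p``) there is no shift: ``b = p``.
    """
    if not 0.0 < p < 1.0:
        raise ValueError(f"trimming fraction must be in (0, 1), got {p}")
    if not 0.0 < c <= 1.0:
        raise ValueError(f"spread bound must be in (0, 1], got {c}")
    if pd > p + 1e-12:
        raise ValueError(
            f"dropout proportion {pd} exceeds the trimming fraction {p}; "
            "the trimming fraction is infeasible for this arm"
        )
    if pd < 0:
        raise ValueError(f"dropout proportion must be >= 0, got {pd}")
    if c <= p + 1e-12:
        return p
    return c - c * (c - p) / (c - pd)


def strong_mnar_bias(sigma: float, p: float, c: float, pd: float) -> float:
    """Magnitude of the strong-MNAR bias of one arm's trimmed mean.

    For an arm with SD ``sigma``, trimming fraction ``p`` and homogeneous
    dropout ``(c, pd)``:

        B = -[(c - p)/(1 - p)] * sigma * (Q(p, c) - Q(b, c)),

    with ``b`` from :func:`strong_mnar_shift`.  Zero when ``c <= p``
    (assumption satisfied); maximal over homogeneous mechanisms at
    ``c = 1`` (MCAR).  The value is the overestimation of the affected
    arm's trimmed mean, always >= 0 here; signs on the treatment-effect
    scale are applied by :func:`combine_biases`.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    b = strong_mnar_shift(p, c, pd)
    if c <= p + 1e-12 or pd == 0:
        return 0.0
    q_pc = q_factor(QuantileInterval(p, c))
    q_bc = q_factor(QuantileInterval(b, c))
    return -((c - p) / (1.0 - p)) * sigma * (q_pc - q_bc)


# ---------------------------------------------------------------------------
# CCA bias and its maximum
# ---------------------------------------------------------------------------

def cca_bias(sigma: float, c: float, pd: float, direction: str = "lower") -> float:
    """CCA bias from homogeneous dropout in one arm, on the effect scale
    for dropout in the comparator arm (``mu - mu_complete``).

    The observed-case distribution is the mixture of the thinned region
    ``(0, c)`` (mass ``c - pd``) and the intact region ``(c, 1)`` (mass
    ``1 - c``), normalized by ``1 - pd``.  Zero when ``pd = 0`` or when
    dropout is spread over the whole distribution (``c = 1``, MCAR);
    lower-value dropout overestimates the arm mean (negative value here),
    mirrored for higher-value dropout.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    if not 0.0 < c <= 1.0:
        raise ValueError(f"spread bound must be in (0, 1], got {c}")
    if pd > c + 1e-12:
        raise ValueError(f"dropout proportion {pd} exceeds the spread bound {c}")
    if pd <= 0 or c >= 1.0:
        return 0.0
    mean_low = -tail_density(c) / c  # standard-normal mean of (0, c)
    mean_high = tail_density(c) / (1.0 - c)  # standard-normal mean of (c, 1)
    mean_complete = ((c - pd) * mean_low + (1.0 - c) * mean_high) / (1.0 - pd)
    bias = -sigma * mean_complete
    return bias if direction == "lower" else -bias


def cca_max_bias(sigma: float, pd: float) -> float:
    """Copas-Jackson bound on the CCA bias magnitude for one arm:
    ``sigma * phi(Phi^-1(pd)) / (1 - pd)``.

    Attained by fully directional (threshold-selection) dropout of the
    ``pd`` most extreme values; equals ``|cca_bias(sigma, c=pd, pd)|``.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    if not 0.0 <= pd < 1.0:
        raise ValueError(f"dropout proportion must be in [0, 1), got {pd}")
    return sigma * tail_density(pd) / (1.0 - pd)


# ---------------------------------------------------------------------------
# maximum TM bias
# ---------------------------------------------------------------------------

def tm_max_bias(
    sigma0: float, sigma1: float, p: float, pd: float
) -> MaxBiasBounds:
    """Worst-case TM bias bounds under opposite-tail (adversarial) dropout.

    For lower-tail trimming the worst case is dropout of the ``pd``
    *highest* comparator values (a threshold selection model with
    selection probability ``p_s = 1 - pd``).  The strong-MNAR component,
    on the affected arm's trimmed-mean scale, is

        -sigma0/(1-p) * [phi(Phi^-1(p_s)) - phi(Phi^-1(p_s - (1-p)))
                         + phi(Phi^-1(1-p))],

    which is 0 at ``pd = 0``; the total adds the location-shift term
    ``(sigma1 - sigma0) phi(Phi^-1(p)) / (1 - p)``.
    """
    if not (sigma0 > 0 and sigma1 > 0):
        raise ValueError("arm SDs must be positive")
    if not 0.0 < p < 1.0:
        raise ValueError(f"trimming fraction must be in (0, 1), got {p}")
    if not 0.0 <= pd < 1.0:
        raise ValueError(f"dropout proportion must be in [0, 1), got {pd}")
    ps = 1.0 - pd
    if ps - (1.0 - p) < -1e-12:
        raise ValueError(
            f"infeasible quantile argument: selection probability {ps} is smaller "
            f"than the retained fraction {1 - p}; not enough observed values remain "
            "to fill the retained fraction"
        )
    lower = max(ps - (1.0 - p), 0.0)
    sm_max = -sigma0 / (1.0 - p) * (
        tail_density(ps) - tail_density(lower) + tail_density(1.0 - p)
    )
    total = sm_max + (sigma1 - sigma0) * tail_density(p) / (1.0 - p)
    from scipy.stats import norm

    threshold = sigma0 * float(norm.ppf(ps)) if 0.0 < ps < 1.0 else math.inf
    return MaxBiasBounds(
        cca_max=cca_max_bias(sigma0, pd) if pd > 0 else 0.0,
        tm_sm_max=sm_max,
        tm_total_max=total,
        threshold=threshold,
        selection_probability=ps,
    )


# ---------------------------------------------------------------------------
# composition
# ---------------------------------------------------------------------------

def combine_biases(
    tm_estimate: float,
    sigma0: float,
    sigma1: float,
    scenario: DropoutScenario,
    p: float,
    direction: str = "lower",
) -> BiasDecomposition:
    """Signed bias decomposition for a two-arm scenario.

    Each arm's strong-MNAR magnitude is signed on the treatment-effect
    scale: for lower-tail trimming, a comparator-arm violation pushes the
    estimate up and a treatment-arm violation pushes it down (flipped for
    higher-tail trimming).  Requires every arm scenario to share the
    trimming direction.
    """
    for j in (0, 1):
        if scenario.arm(j).direction != direction:
            raise ValueError(
                f"arm {j} dropout direction {scenario.arm(j).direction!r} is "
                f"inconsistent with the trimming direction {direction!r}"
            )
    sign = 1.0 if direction == "lower" else -1.0
    sm0 = strong_mnar_bias(
        sigma0, p, scenario.comparator.spread_bound, scenario.comparator.dropout_proportion
    )
    sm1 = strong_mnar_bias(
        sigma1, p, scenario.treatment.spread_bound, scenario.treatment.dropout_proportion
    )
    return BiasDecomposition(
        b_ls=location_shift_bias(sigma1, sigma0, p, direction),
        b_sm_arm0=sign * sm0,
        b_sm_arm1=-sign * sm1,
        tm_estimate=tm_estimate,
    )


def bias_adjusted_estimate(tm_estimate: float, b_total: float) -> float:
    """Bias-adjusted TM estimate: ``tm_estimate - b_total``."""
    return tm_estimate - b_total


# ---------------------------------------------------------------------------
# full-sample SD inference
# ---------------------------------------------------------------------------

def infer_full_sd(observed_sd: float, c: float, pd: float) -> float:
    """Full-sample SD implied by the observed (post-dropout) SD.

    Under homogeneous dropout ``(c, pd)`` the observed-case distribution
    is a thinned normal, which is a pure scale family in ``sigma``; hence
    ``sigma = observed_sd / g(c, pd)`` with ``g`` the SD of the thinned
    *standard* normal, computed from truncated-normal moments.  MCAR
    (``c = 1``) returns ``observed_sd`` unchanged; the inversion is exact
    and monotone in ``observed_sd``.  The tail side does not matter by
    symmetry.
    """
    if observed_sd <= 0:
        raise ValueError("observed SD must be positive")
    if not 0.0 < c <= 1.0:
        raise ValueError(f"spread bound must be in (0, 1], got {c}")
    if pd > c + 1e-12:
        raise ValueError(f"dropout proportion {pd} exceeds the spread bound {c}")
    if pd <= 0 or c >= 1.0:
        return observed_sd
    z = NormalArm(0.0, 1.0)
    low = QuantileInterval(0.0, c)
    high = QuantileInterval(c, 1.0)
    w_low = (c - pd) / (1.0 - pd)
    w_high = (1.0 - c) / (1.0 - pd)
    m_low = -q_factor(low)
    m_high = -q_factor(high)
    s2_low = truncated_sd(z, low) ** 2
    s2_high = truncated_sd(z, high) ** 2
    mean = w_low * m_low + w_high * m_high
    second = w_low * (s2_low + m_low**2) + w_high * (s2_high + m_high**2)
    g = math.sqrt(second - mean**2)
    return observed_sd / g
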