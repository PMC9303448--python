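"""Synthetic two-arm trial generator with MNAR/MAR/MCAR dropout.

Emulates the study conditions of a parallel-group trial with a single
continuous outcome: per-arm normal (or shifted-lognormal) outcomes with a
mean difference ``beta``, an optional standard-normal covariate ``U``
acting additively on the outcome, and outcome/covariate missingness
mechanisms:

* ``restricted_homogeneous`` — exactly ``round(pd * n)`` outcomes deleted
  uniformly from the region below (above) the arm's empirical
  ``c``-quantile; ``c = 1`` is MCAR;
* ``logit_covariate`` — per-row Bernoulli missingness with probability
  ``expit(intercept + coefficient * U + arm_offset)``;
* ``threshold_worst_case`` — exactly the ``round(pd * n)`` most extreme
  values in a stated tail deleted (the step-function selection model
  attaining the analytic maximum-bias bounds).

Exact-count (rather than Bernoulli) deletion is used for the restricted
and threshold mechanisms to reduce Monte-Carlo variance; region
membership is decided on the *true* pre-deletion outcomes within arm.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .dataset import TrialDataset

__all__ = [
    "TrialDesign",
    "RestrictedHomogeneousDropout",
    "McarDropout",
    "LogitDropout",
    "ThresholdDropout",
    "LogitCovariateMissingness",
    "generate_trial",
    "apply_dropout",
    "apply_covariate_missingness",
]


@dataclass(frozen=True)
class TrialDesign:
    """Two-arm trial design.

    ``arm_sigmas`` are total outcome SDs per arm; with a covariate effect
    ``gamma`` the residual SD is ``sqrt(sigma_j^2 - gamma^2)`` so the
    total SD stays at ``sigma_j``.  For the lognormal family the outcome
    is a shifted lognormal whose outcome-scale SD equals ``sigma_j``,
    with the effect ``beta`` still entering on the outcome scale.
    """

    n_per_arm: int = 500
    effect: float = 0.5
    arm_sigmas: tuple[float, float] = (1.0, 1.0)
    outcome_family: str = "normal"
    covariate_effect: float = 0.0
    baseline_mean: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_per_arm < 2:
            raise ValueError("need at least 2 participants per arm")
        if self.outcome_family not in ("normal", "lognormal"):
            raise ValueError(f"unknown outcome family {self.outcome_family!r}")
        for s in self.arm_sigmas:
            if self.residual_variance(s) < 0:
                raise ValueError(
                    f"covariate effect {self.covariate_effect} exceeds the arm SD {s}: "
                    "residual variance would be negative"
                )

    def residual_variance(self, sigma: float) -> float:
        return sigma**2 - self.covariate_effect**2


def _lognormal_shape(sd: float) -> float:
    """Log-scale SD ``a`` with ``SD(exp(a Z)) = sd`` for standard normal Z."""
    # (e^{a^2} - 1) e^{a^2} = sd^2  =>  e^{a^2} = (1 + sqrt(1 + 4 sd^2)) / 2
    e = (1.0 + math.sqrt(1.0 + 4.0 * sd**2)) / 2.0
    return math.sqrt(math.log(e))


def generate_trial(design: TrialDesign, seed: int | None = None) -> TrialDataset:
    """Generate a complete (no missingness) trial dataset.

    Outcomes are ``y = mu_j + gamma * U + eps`` for the normal family;
    for the lognormal family the standardized linear score is pushed
    through a lognormal transform calibrated so the arm's outcome-scale
    SD equals ``sigma_j`` and then mean-centred, preserving the stated
    arm-mean difference.  Fully reproducible from the seed.
    """
    rng = np.random.default_rng(design.seed if seed is None else seed)
    n = design.n_per_arm
    frames = []
    has_u = design.covariate_effect != 0.0
    for j, sigma in enumerate(design.arm_sigmas):
        mu = design.baseline_mean + design.effect * j
        u = rng.standard_normal(n) if has_u else np.zeros(n)
        resid_sd = math.sqrt(design.residual_variance(sigma))
        eps = rng.normal(0.0, resid_sd, n) if resid_sd > 0 else np.zeros(n)
        linear = design.covariate_effect * u + eps
        if design.outcome_family == "normal":
            y = mu + linear
        else:
            a = _lognormal_shape(sigma)
            z = linear / sigma  # standardized linear score
            raw = np.exp(a * z)
            y = mu + raw - math.exp(a**2 / 2.0)
        cols = {"arm": np.full(n, j), "y": y}
        if has_u:
            cols["u"] = u
        frames.append(pd.DataFrame(cols))
    frame = pd.concat(frames, ignore_index=True)
    return TrialDataset(frame)


# ---------------------------------------------------------------------------
# missingness mechanisms
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RestrictedHomogeneousDropout:
    """Exact-count homogeneous dropout restricted to one tail region."""

    arm: int
    p_d: float
    c: float = 1.0
    direction: str = "lower"
    kind: str = field(default="restricted_homogeneous", init=False)

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_d < 1.0:
            raise ValueError(f"dropout proportion must be in [0, 1), got {self.p_d}")
        if not 0.0 < self.c <= 1.0:
            raise ValueError(f"spread bound must be in (0, 1], got {self.c}")
        if self.p_d > self.c + 1e-12:
            raise ValueError(f"dropout proportion {self.p_d} exceeds spread bound {self.c}")
        if self.direction not in ("lower", "higher"):
            raise ValueError(f"direction must be 'lower' or 'higher', got {self.direction!r}")


def McarDropout(arm: int, p_d: float) -> RestrictedHomogeneousDropout:
    """MCAR dropout: homogeneous over the whole distribution (``c = 1``)."""
    return RestrictedHomogeneousDropout(arm=arm, p_d=p_d, c=1.0)


@dataclass(frozen=True)
class LogitDropout:
    """Bernoulli missingness with probability expit(intercept + coef*U + offset[arm])."""

    intercept: float
    coefficient: float = 0.0
    arm_offsets: tuple[float, float] = (0.0, 0.0)
    kind: str = field(default="logit_covariate", init=False)


@dataclass(frozen=True)
class ThresholdDropout:
    """Delete exactly the ``round(p_d * n)`` most extreme values in one tail."""

    arm: int
    p_d: float
    tail: str = "higher"
    kind: str = field(default="threshold_worst_case", init=False)

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_d < 1.0:
            raise ValueError(f"dropout proportion must be in [0, 1), got {self.p_d}")
        if self.tail not in ("lower", "higher"):
            raise ValueError(f"tail must be 'lower' or 'higher', got {self.tail!r}")


@dataclass(frozen=True)
class LogitCovariateMissingness:
    """Bernoulli missingness in the covariate: expit(intercept + arm_coef*arm + u_coef*U)."""

    intercept: float
    arm_coefficient: float = 0.0
    kind: str = field(default="logit_covariate_missingness", init=False)


Mechanism = RestrictedHomogeneousDropout | LogitDropout | ThresholdDropout


def apply_dropout(
    data: TrialDataset,
    mech: Mechanism | Sequence[Mechanism],
    seed: int | None = None,
) -> TrialDataset:
    """Apply one or more outcome-missingness mechanisms (sequentially)."""
    if isinstance(mech, (list, tuple)):
        ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
        out = data
        for m, child in zip(mech, ss.spawn(len(mech))):
            out = _apply_one(out, m, np.random.default_rng(child))
        return out
    return _apply_one(data, mech, np.random.default_rng(seed))


def _apply_one(data: TrialDataset, mech, rng: np.random.Generator) -> TrialDataset:
    frame = data.frame.copy()
    y = frame["y"].to_numpy(float)
    arm = frame["arm"].to_numpy()

    if mech.kind == "restricted_homogeneous":
        pos = np.flatnonzero(arm == mech.arm)
        if np.isnan(y[pos]).any():
            raise ValueError(
                "exact-count mechanisms need the arm's true outcomes: apply them "
                "before any Bernoulli mechanism"
            )
        n = pos.size
        k_miss = int(round(mech.p_d * n))
        if k_miss == 0:
            return TrialDataset(frame)
        k_region = int(round(mech.c * n))
        order = np.argsort(y[pos], kind="stable")
        region = order[:k_region] if mech.direction == "lower" else order[-k_region:]
        if k_miss > region.size:
            raise ValueError(
                f"cannot delete {k_miss} outcomes from a region of size {region.size}"
            )
        chosen = rng.choice(region, size=k_miss, replace=False)
        frame.iloc[pos[chosen], frame.columns.get_loc("y")] = np.nan
        return TrialDataset(frame)

    if mech.kind == "threshold_worst_case":
        pos = np.flatnonzero(arm == mech.arm)
        if np.isnan(y[pos]).any():
            raise ValueError(
                "exact-count mechanisms need the arm's true outcomes: apply them "
                "before any Bernoulli mechanism"
            )
        n = pos.size
        k_miss = int(round(mech.p_d * n))
        if k_miss == 0:
            return TrialDataset(frame)
        order = np.argsort(y[pos], kind="stable")
        chosen = order[:k_miss] if mech.tail == "lower" else order[-k_miss:]
        frame.iloc[pos[chosen], frame.columns.get_loc("y")] = np.nan
        return TrialDataset(frame)

    if mech.kind == "logit_covariate":
        u = frame["u"].to_numpy(float) if "u" in frame.columns else np.zeros(len(frame))
        lin = mech.intercept + mech.coefficient * u
        lin = lin + np.asarray(mech.arm_offsets)[arm]
        miss = rng.random(len(frame)) < expit(lin)
        frame.loc[miss, "y"] = np.nan
        return TrialDataset(frame)

    raise ValueError(f"unknown outcome-dropout mechanism kind {mech.kind!r}")


def apply_covariate_missingness(
    data: TrialDataset,
    mech: LogitCovariateMissingness | None,
    seed: int | None = None,
    covariate: str = "u",
) -> TrialDataset:
    """Apply Bernoulli (logit) missingness to a covariate column."""
    if mech is None:
        return data
    if covariate not in data.frame.columns:
        raise ValueError(f"dataset has no covariate column {covariate!r}")
    rng = np.random.default_rng(seed)
    frame = data.frame.copy()
    arm = frame["arm"].to_numpy()
    lin = mech.intercept + mech.arm_coefficient * arm
    miss = rng.random(len(frame)) < expit(lin)
    frame.loc[miss, covariate] = np.nan
    return TrialDataset(frame)
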