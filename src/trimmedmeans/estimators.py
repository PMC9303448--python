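"""Treatment-effect estimators for trials with MNAR outcome dropout.

Implements worst-value trimming and three effect estimators over a
two-arm :class:`~trimmedmeans.dataset.TrialDataset`:

* complete case analysis (CCA): OLS of outcome on arm (plus optional
  covariates) among participants with observed data;
* the trimmed-means (TM) estimator: missing outcomes are ranked as the
  most extreme values on the trimmed side, an equal fraction ``p`` is
  trimmed away from the same tail of both arms, and the effect is the OLS
  arm coefficient over the retained rows;
* an adjusted TM estimator that relaxes the equal-SD (location shift)
  assumption under 50% trimming by treating each retained fraction as a
  half normal and rescaling one arm's trimmed mean to the other arm's
  full-sample SD.

Inference for the trimming-based estimators is permutation based: arm
labels are permuted (missingness travelling with its participant), the
full trim-and-fit pipeline is re-run per permutation, and a two-sided
interval is formed by shifting the observed estimate by the quantiles of
the permutation null distribution.

The primary API is the scikit-learn style estimator classes
(:class:`CompleteCaseEffect`, :class:`TrimmedMeansEffect`,
:class:`AdjustedTrimmedMeansEffect`); the module-level functions
(:func:`cca_fit`, :func:`tm_fit`, :func:`adjusted_tm_fit`) are thin
wrappers over them returning plain result records.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.base import BaseEstimator

from .dataset import EstimateResult, TrialDataset, TrimSpec

__all__ = [
    "trim",
    "cca_fit",
    "tm_fit",
    "adjusted_tm_fit",
    "permutation_ci",
    "impute_covariate",
    "tm_fit_imputed",
    "CompleteCaseEffect",
    "TrimmedMeansEffect",
    "AdjustedTrimmedMeansEffect",
]

_HALF_TO_FULL_SD = math.sqrt(math.pi / (math.pi - 2.0))
_HALF_NORMAL_MEAN = math.sqrt(2.0 / math.pi)


# ---------------------------------------------------------------------------
# trimming
# ---------------------------------------------------------------------------

def trim(data: TrialDataset, spec: TrimSpec) -> TrialDataset:
    """Worst-value trimming of both arms.

    Within each arm, missing outcomes are ranked as a block at the trimmed
    extreme (their exact value is immaterial), observed outcomes are
    ordered, and exactly ``ceil(n_j * (1 - p))`` rows are retained from
    the untrimmed tail; ties and the missing block keep stable input
    order.  ``direction='higher'`` mirrors the procedure on the upper
    tail.  Returns the retained rows in their original order.
    """
    trimmed, _, _ = _trim_detail(data, spec)
    return trimmed


def _trim_detail(
    data: TrialDataset, spec: TrimSpec
) -> tuple[TrialDataset, float, list[str]]:
    p = spec.resolve(data)
    arm_col = data.frame["arm"].to_numpy()
    y_col = data.frame["y"].to_numpy()
    keep_positions: list[np.ndarray] = []
    warnings: list[str] = []
    for j in (0, 1):
        pos = np.flatnonzero(arm_col == j)
        n = pos.size
        n_keep = TrimSpec.retained_count(n, p)
        if n_keep < 1:
            raise ValueError(f"arm {j} is left empty after trimming with p={p}")
        y = y_col[pos]
        if spec.direction == "lower":
            key = np.where(np.isnan(y), -np.inf, y)
            order = np.argsort(key, kind="stable")
            kept = order[n - n_keep:]
        else:
            key = np.where(np.isnan(y), np.inf, y)
            order = np.argsort(key, kind="stable")
            kept = order[:n_keep]
        kept_y = y[kept]
        n_missing_kept = int(np.isnan(kept_y).sum())
        if n_missing_kept == n_keep:
            raise ValueError(f"arm {j} has no observed outcomes after trimming")
        if n_missing_kept:
            warnings.append(
                f"arm {j}: {n_missing_kept} missing outcomes remain in the retained "
                "fraction (in-sample strong MNAR violation); they are excluded from "
                "estimation"
            )
        keep_positions.append(pos[np.sort(kept)])
    all_pos = np.sort(np.concatenate(keep_positions))
    trimmed = TrialDataset(data.frame.iloc[all_pos].copy())
    return trimmed, p, warnings


# ---------------------------------------------------------------------------
# OLS backend
# ---------------------------------------------------------------------------

def _complete_rows(frame: pd.DataFrame, covariates: Sequence[str]) -> pd.DataFrame:
    cols = ["y", *covariates]
    return frame[frame[cols].notna().all(axis=1)]


def _ols_effect(
    frame: pd.DataFrame, covariates: Sequence[str], ci_level: float
) -> tuple[float, float, tuple[float, float]]:
    """OLS of outcome on arm (+ covariates); returns (effect, se, t-CI)."""
    for c in covariates:
        if c not in frame.columns:
            raise ValueError(f"unknown covariate column {c!r}")
    X = sm.add_constant(frame[["arm", *covariates]].to_numpy(float), has_constant="add")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design matrix is rank deficient (collinear covariates)")
    fit = sm.OLS(frame["y"].to_numpy(float), X).fit()
    alpha = 1.0 - ci_level
    ci = fit.conf_int(alpha=alpha)[1]
    return float(fit.params[1]), float(fit.bse[1]), (float(ci[0]), float(ci[1]))


def _mean_difference(frame: pd.DataFrame) -> float:
    y = frame["y"].to_numpy(float)
    arm = frame["arm"].to_numpy()
    return float(y[arm == 1].mean() - y[arm == 0].mean())


# ---------------------------------------------------------------------------
# core fits (used by the estimator classes and permutation engine)
# ---------------------------------------------------------------------------

def _cca_core(
    data: TrialDataset,
    covariates: Sequence[str],
    ci_level: float,
    minimal: bool = False,
) -> EstimateResult:
    complete = _complete_rows(data.frame, covariates)
    for j in (0, 1):
        if int((complete["arm"] == j).sum()) < 2:
            raise ValueError(f"arm {j} has fewer than 2 complete cases")
    if minimal and not covariates:
        return EstimateResult("CCA", _mean_difference(complete), n_obs=len(complete))
    est, se, ci = _ols_effect(complete, covariates, ci_level)
    return EstimateResult(
        "CCA", est, se=se, ci=ci, ci_level=ci_level, n_obs=len(complete)
    )


def _tm_core(
    data: TrialDataset,
    spec: TrimSpec,
    covariates: Sequence[str],
    ci_level: float,
    minimal: bool = False,
    dropna_covariates: bool = False,
) -> EstimateResult:
    trimmed, p, warnings = _trim_detail(data, spec)
    frame = trimmed.frame[trimmed.frame["y"].notna()]
    if covariates and frame[list(covariates)].isna().any().any():
        if dropna_covariates:
            frame = _complete_rows(frame, list(covariates))
        else:
            raise ValueError(
                "covariate values are missing in the retained fraction; impute them "
                "first (see impute_covariate / tm_fit_imputed)"
            )
    retained = {j: int((trimmed.frame["arm"] == j).sum()) for j in (0, 1)}
    if minimal and not covariates:
        return EstimateResult(
            "TM", _mean_difference(frame), retained_per_arm=retained, p_used=p,
            n_obs=len(frame), warnings=warnings,
        )
    est, se, ci = _ols_effect(frame, covariates, ci_level)
    return EstimateResult(
        "TM", est, se=se, ci=ci, ci_level=ci_level, retained_per_arm=retained,
        p_used=p, n_obs=len(frame), warnings=warnings,
    )


def _adjusted_core(
    data: TrialDataset, spec: TrimSpec, rescale_arm: int
) -> EstimateResult:
    if spec.mode != "fixed" or abs(spec.fraction - 0.5) > 1e-9:
        raise ValueError(
            "the adjusted TM estimator is defined for fixed 50% trimming only "
            f"(got mode={spec.mode!r}, p={spec.fraction})"
        )
    if rescale_arm not in (0, 1):
        raise ValueError(f"rescale_arm must be 0 or 1, got {rescale_arm}")
    if spec.direction == "higher":
        flipped = TrialDataset(data.frame.assign(y=-data.frame["y"]))
        res = _adjusted_core(flipped, TrimSpec(0.5, "lower", "fixed"), rescale_arm)
        res.estimate = -res.estimate
        return res

    trimmed, p, warnings = _trim_detail(data, spec)
    obs = trimmed.frame[trimmed.frame["y"].notna()]
    retained_values = {
        j: obs.loc[obs["arm"] == j, "y"].to_numpy(float) for j in (0, 1)
    }
    for j in (0, 1):
        if retained_values[j].size < 2:
            raise ValueError(f"arm {j} retains fewer than 2 observed outcomes")
    other = 1 - rescale_arm

    # Rescaled arm: mirror the retained (half-normal) fraction about the
    # trimming threshold to recover an artificial full normal.
    rg = retained_values[rescale_arm]
    threshold = rg.min()
    sd_art = math.sqrt(float(np.mean((rg - threshold) ** 2)))
    if sd_art <= 0:
        raise ValueError("zero trimmed-fraction SD in the rescaled arm")

    # Other arm: full-sample SD, observed directly when the arm has no
    # dropout, otherwise extrapolated from its half-normal fraction SD.
    arm_other = data.arm_frame(other)["y"]
    if not arm_other.isna().any():
        sd_other = float(arm_other.std(ddof=1))
    else:
        sd_other = float(np.std(retained_values[other], ddof=1)) * _HALF_TO_FULL_SD
    if sd_other <= 0:
        raise ValueError("zero trimmed-fraction SD in the reference arm")

    mu_adj = threshold + (rg.mean() - threshold) * sd_other / sd_art
    if rescale_arm == 0:
        estimate = float(retained_values[1].mean() - mu_adj)
    else:
        estimate = float(mu_adj - retained_values[0].mean())
    retained = {j: retained_values[j].size for j in (0, 1)}
    return EstimateResult(
        f"TM-adjusted-{rescale_arm}", estimate, retained_per_arm=retained,
        p_used=p, n_obs=len(obs), warnings=warnings,
    )


# ---------------------------------------------------------------------------
# permutation inference
# ---------------------------------------------------------------------------

def permutation_ci(
    data: TrialDataset,
    spec: TrimSpec,
    n_perm: int = 1000,
    seed: int | None = None,
    level: float = 0.95,
    method: str = "tm",
    rescale_arm: int = 0,
    covariates: Sequence[str] | None = None,
) -> tuple[float, tuple[float, float]]:
    """Permutation SE and confidence interval for a trimming estimator.

    Arm labels are permuted with missingness travelling with its
    participant; the full trim + fit pipeline is re-run per permutation.
    The interval is the basic (reflection) construction
    ``[b - q_{(1+level)/2}, b - q_{(1-level)/2}]`` with ``q`` the
    quantiles of the permutation-null estimates; the SE is the SD of the
    null distribution.  Identical seed gives identical output.
    """
    if n_perm < 100:
        raise ValueError(f"n_perm must be at least 100, got {n_perm}")
    covariates = list(covariates or [])

    def fit_one(ds: TrialDataset) -> float:
        if method == "tm":
            return _tm_core(ds, spec, covariates, level, minimal=True).estimate
        if method == "tm_adjusted":
            return _adjusted_core(ds, spec, rescale_arm).estimate
        raise ValueError(f"unknown permutation method {method!r}")

    observed = fit_one(data)
    rng = np.random.default_rng(seed)
    arm = data.frame["arm"].to_numpy()
    null = np.empty(n_perm)
    for k in range(n_perm):
        permuted = TrialDataset(data.frame.assign(arm=rng.permutation(arm)))
        null[k] = fit_one(permuted)
    if np.ptp(null) < 1e-14:
        raise ValueError("degenerate permutation distribution: all estimates identical")
    alpha = 1.0 - level
    q_lo, q_hi = np.quantile(null, [alpha / 2.0, 1.0 - alpha / 2.0])
    se = float(np.std(null, ddof=1))
    return se, (float(observed - q_hi), float(observed - q_lo))


# ---------------------------------------------------------------------------
# covariate imputation (after trimming)
# ---------------------------------------------------------------------------

def impute_covariate(
    data: TrialDataset,
    covariate: str,
    predictors: Sequence[str] = ("arm", "y"),
    n_imputations: int = 5,
    seed: int | None = None,
) -> list[TrialDataset]:
    """Normal-linear stochastic-regression imputation of one covariate.

    Intended for use after trimming, when the retained outcomes are fully
    observed.  Each imputation draws the residual variance and regression
    coefficients from their posterior (normal-inverse-chi-square under a
    flat prior) and then the missing covariate values from the fitted
    conditional normal.  Returns ``n_imputations`` completed datasets
    (or ``[data]`` unchanged if the covariate is fully observed).
    """
    if covariate not in data.frame.columns:
        raise ValueError(f"unknown covariate column {covariate!r}")
    missing = data.frame[covariate].isna()
    if not missing.any():
        return [data]
    for j in (0, 1):
        if data.frame.loc[(data.frame["arm"] == j) & ~missing, covariate].empty:
            raise ValueError(f"arm {j} has no observed values of {covariate!r}")
    frame = data.frame
    X_all = sm.add_constant(frame[list(predictors)].to_numpy(float), has_constant="add")
    if np.isnan(X_all).any():
        raise ValueError("imputation predictors contain missing values")
    obs = ~missing.to_numpy()
    X, z = X_all[obs], frame.loc[~missing, covariate].to_numpy(float)
    n, k = X.shape
    if n <= k:
        raise ValueError("too few observed covariate values to fit the imputation model")
    beta_hat, _, rank, _ = np.linalg.lstsq(X, z, rcond=None)
    if rank < k:
        raise ValueError("imputation model design matrix is rank deficient")
    resid = z - X @ beta_hat
    df = n - k
    sse = float(resid @ resid)
    xtx_inv = np.linalg.inv(X.T @ X)
    chol = np.linalg.cholesky(xtx_inv)
    rng = np.random.default_rng(seed)
    X_mis = X_all[~obs]
    out = []
    for _ in range(n_imputations):
        sigma2 = sse / rng.chisquare(df)
        beta = beta_hat + math.sqrt(sigma2) * chol @ rng.standard_normal(k)
        draws = X_mis @ beta + rng.normal(0.0, math.sqrt(sigma2), X_mis.shape[0])
        completed = frame.copy()
        completed.loc[missing, covariate] = draws
        out.append(TrialDataset(completed))
    return out


def tm_fit_imputed(
    data: TrialDataset,
    spec: TrimSpec,
    covariate: str,
    covariates: Sequence[str] | None = None,
    predictors: Sequence[str] = ("arm", "y"),
    n_imputations: int = 5,
    seed: int | None = None,
    ci_level: float = 0.95,
) -> EstimateResult:
    """TM fit with post-trimming multiple imputation of one covariate.

    Trims first, imputes the covariate within the retained fraction, fits
    the TM regression per completed dataset, and pools with Rubin's rules
    (point estimate = mean of per-imputation estimates).
    """
    covariates = list(covariates) if covariates is not None else [covariate]
    trimmed, p, warnings = _trim_detail(data, spec)
    observed = TrialDataset(trimmed.frame[trimmed.frame["y"].notna()].copy())
    completed = impute_covariate(
        observed, covariate, predictors=predictors,
        n_imputations=n_imputations, seed=seed,
    )
    ests, ses = [], []
    for ds in completed:
        est, se, _ = _ols_effect(ds.frame, covariates, ci_level)
        ests.append(est)
        ses.append(se)
    m = len(ests)
    point = float(np.mean(ests))
    within = float(np.mean(np.square(ses)))
    between = float(np.var(ests, ddof=1)) if m > 1 else 0.0
    total_var = within + (1.0 + 1.0 / m) * between
    se = math.sqrt(total_var)
    z = stats.norm.ppf(0.5 + ci_level / 2.0)
    retained = {j: int((trimmed.frame["arm"] == j).sum()) for j in (0, 1)}
    return EstimateResult(
        "TM-imputed", point, se=se, ci=(point - z * se, point + z * se),
        ci_level=ci_level, retained_per_arm=retained, p_used=p,
        n_obs=len(observed.frame), warnings=warnings,
    )


# ---------------------------------------------------------------------------
# scikit-learn style estimator classes
# ---------------------------------------------------------------------------

def _as_dataset(X, y=None) -> TrialDataset:
    if isinstance(X, TrialDataset):
        if y is not None:
            raise ValueError("pass either a TrialDataset or (X, y), not both")
        return X
    if isinstance(X, pd.DataFrame):
        if "arm" not in X.columns:
            raise ValueError("X must contain an 'arm' column")
        frame = X.copy()
    else:
        X = np.asarray(X, float)
        if X.ndim != 2:
            raise ValueError("X must be 2-dimensional")
        cols = ["arm"] + [f"x{i}" for i in range(1, X.shape[1])]
        frame = pd.DataFrame(X, columns=cols)
    if y is None:
        raise ValueError("y (outcome, NaN = missing) is required")
    frame = frame.assign(y=np.asarray(y, float))
    return TrialDataset(frame)


class _TrialEffectBase(BaseEstimator):
    """Shared fit plumbing for the trial-effect estimators."""

    def fit(self, X, y=None):
        """Fit on a :class:`TrialDataset`, or on ``(X, y)`` with ``X`` a
        DataFrame containing an ``arm`` column (plus covariates) and ``y``
        the outcome with NaN marking missing values."""
        data = _as_dataset(X, y)
        result = self._fit_dataset(data)
        self.result_ = result
        self.effect_ = result.estimate
        self.se_ = result.se
        self.ci_ = result.ci
        self.p_used_ = result.p_used
        self.retained_per_arm_ = result.retained_per_arm
        self.n_obs_ = result.n_obs
        self.warnings_ = list(result.warnings)
        return self

    def _fit_dataset(self, data: TrialDataset) -> EstimateResult:  # pragma: no cover
        raise NotImplementedError


class CompleteCaseEffect(_TrialEffectBase):
    """Complete case analysis: OLS treatment effect among observed rows.

    With no covariates the effect equals the difference of observed-case
    arm means exactly.
    """

    def __init__(self, covariates=None, ci_level=0.95):
        self.covariates = covariates
        self.ci_level = ci_level

    def _fit_dataset(self, data: TrialDataset) -> EstimateResult:
        return _cca_core(data, list(self.covariates or []), self.ci_level)


class TrimmedMeansEffect(_TrialEffectBase):
    """Trimmed-means treatment effect under worst-value dropout.

    Parameters
    ----------
    trim_fraction : float
        Fraction ``p`` trimmed away from each arm (ignored when
        ``adaptive`` is true).
    direction : {'lower', 'higher'}
        Tail trimmed away; 'lower' assumes worst-value (low) dropout.
    adaptive : bool
        Set ``p`` to the largest observed per-arm dropout proportion.
    n_permutations : int
        Permutations for the permutation CI; 0 uses the model-based OLS
        interval from the trimmed regression instead.
    """

    def __init__(
        self,
        trim_fraction=0.5,
        direction="lower",
        adaptive=False,
        covariates=None,
        dropna_covariates=False,
        n_permutations=0,
        ci_level=0.95,
        random_state=None,
    ):
        self.trim_fraction = trim_fraction
        self.direction = direction
        self.adaptive = adaptive
        self.covariates = covariates
        self.dropna_covariates = dropna_covariates
        self.n_permutations = n_permutations
        self.ci_level = ci_level
        self.random_state = random_state

    def _spec(self) -> TrimSpec:
        mode = "adaptive" if self.adaptive else "fixed"
        return TrimSpec(self.trim_fraction, self.direction, mode)

    def _fit_dataset(self, data: TrialDataset) -> EstimateResult:
        spec = self._spec()
        covs = list(self.covariates or [])
        result = _tm_core(
            data, spec, covs, self.ci_level, dropna_covariates=self.dropna_covariates
        )
        if self.n_permutations:
            se, ci = permutation_ci(
                data, spec, n_perm=self.n_permutations, seed=self.random_state,
                level=self.ci_level, method="tm", covariates=covs,
            )
            result.se, result.ci, result.ci_level = se, ci, self.ci_level
        return result


class AdjustedTrimmedMeansEffect(_TrialEffectBase):
    """Variance-rescaled TM estimator (50% trimming only).

    Relaxes the location shift assumption: the retained fraction of
    ``rescale_arm`` is treated as a half normal, mirrored about the
    trimming threshold, and rescaled to the other arm's full-sample SD
    before taking the difference of trimmed means.
    """

    def __init__(
        self,
        rescale_arm=0,
        direction="lower",
        n_permutations=0,
        ci_level=0.95,
        random_state=None,
    ):
        self.rescale_arm = rescale_arm
        self.direction = direction
        self.n_permutations = n_permutations
        self.ci_level = ci_level
        self.random_state = random_state

    def _fit_dataset(self, data: TrialDataset) -> EstimateResult:
        spec = TrimSpec(0.5, self.direction, "fixed")
        result = _adjusted_core(data, spec, self.rescale_arm)
        if self.n_permutations:
            se, ci = permutation_ci(
                data, spec, n_perm=self.n_permutations, seed=self.random_state,
                level=self.ci_level, method="tm_adjusted",
                rescale_arm=self.rescale_arm,
            )
            result.se, result.ci, result.ci_level = se, ci, self.ci_level
        return result


# ---------------------------------------------------------------------------
# functional wrappers
# ---------------------------------------------------------------------------

def cca_fit(
    data: TrialDataset,
    covariates: Sequence[str] | None = None,
    ci_level: float = 0.95,
) -> EstimateResult:
    """Complete case analysis of ``data``; see :class:`CompleteCaseEffect`."""
    return CompleteCaseEffect(covariates=covariates, ci_level=ci_level).fit(data).result_


def tm_fit(
    data: TrialDataset,
    spec: TrimSpec,
    covariates: Sequence[str] | None = None,
    n_permutations: int = 0,
    ci_level: float = 0.95,
    random_state: int | None = None,
) -> EstimateResult:
    """Trimmed-means fit of ``data``; see :class:`TrimmedMeansEffect`."""
    est = TrimmedMeansEffect(
        trim_fraction=spec.fraction, direction=spec.direction,
        adaptive=spec.mode == "adaptive", covariates=covariates,
        n_permutations=n_permutations, ci_level=ci_level, random_state=random_state,
    )
    return est.fit(data).result_


def adjusted_tm_fit(
    data: TrialDataset,
    spec: TrimSpec,
    rescale_arm: int = 0,
    n_permutations: int = 0,
    ci_level: float = 0.95,
    random_state: int | None = None,
) -> EstimateResult:
    """Adjusted TM fit of ``data``; see :class:`AdjustedTrimmedMeansEffect`.

    ``spec`` must request fixed 50% trimming.
    """
    if spec.mode != "fixed" or abs(spec.fraction - 0.5) > 1e-9:
        raise ValueError("the adjusted TM estimator requires fixed p = 0.5")
    est = AdjustedTrimmedMeansEffect(
        rescale_arm=rescale_arm, direction=spec.direction,
        n_permutations=n_permutations, ci_level=ci_level, random_state=random_state,
    )
    return est.fit(data).result_
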