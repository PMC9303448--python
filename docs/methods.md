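# Methods

This note records the statistical model the package implements, the
estimator definitions as actually computed on data, the simulator's
scope, and the numerical and design choices that were genuinely open.

## Model and estimands

A two-arm randomized trial with a single continuous outcome measured
once. Outcomes in arm `j ∈ {0, 1}` are modelled as normal with mean
`μ_j` and SD `σ_j` (a shifted-lognormal family is available in the
simulator for robustness checks). The estimand is the population mean
difference `β = μ₁ − μ₀`. Missingness is univariable: only the outcome
(and optionally one covariate) can be missing.

The trimmed-means (TM) estimand with trimming fraction `p` under
lower-value trimming is `β_t = μ_t1 − μ_t0` with
`μ_tj = E[Y | R = j, Y > F_j⁻¹(p)]`. Under the location shift assumption
(equal arm SDs, or more generally identically shaped arm distributions)
`β_t = β`; under the strong MNAR assumption (all dropout confined to the
trimmed-away fraction) the sample TM estimator is unbiased for `β_t`.

All probability-scale quantities (trimming fraction `p`, dropout
proportion `p_d`, dropout spread `c`, shift quantile `b`) live on the
quantile scale of the affected arm's outcome distribution, measured from
the trimmed tail; conversion to outcome units happens only through the
`NormalArm(mu, sigma)` container. Direction handling ("lower" vs
"higher" trimming) is centralized: estimators negate outcomes and
delegate to the lower-tail code path, and the bias composition applies a
single global sign flip, so no formula is duplicated per direction.

## Estimators as computed on data

**Trimming.** Within each arm, missing outcomes form a block at the
trimmed extreme (stable input order within the block — their numeric
value is never materialized), observed outcomes are ordered stably, and
exactly `⌈n_j(1 − p)⌉` rows are retained. Fixed `p` below the largest
observed per-arm dropout proportion is an error naming the violating
arm; adaptive mode sets `p` to that proportion exactly (no rounding to a
grid). If missing rows survive trimming (possible only in hand-crafted
edge cases, since `p ≥ p_min` is enforced), they are excluded from the
regression and a warning is attached to the result.

**CCA and TM fits.** OLS of outcome on arm (plus optional covariates)
via statsmodels, over complete cases (CCA) or the retained fraction
(TM). With no covariates the OLS arm coefficient equals the difference
of (trimmed) arm means to round-off; the fast path in the study harness
computes the mean difference directly. Covariates missing inside the
retained fraction raise an error pointing at the imputation helper,
unless complete-case deletion is explicitly requested
(`dropna_covariates`).

**Adjusted TM estimator (p = 0.5 only).** For the rescaled arm `g`, the
retained fraction is treated as the upper half of a normal distribution:
it is mirrored about the trimming threshold (estimated as the smallest
retained value `m̂`), giving an artificial full normal with centre `m̂`
and SD `σ̂_art = √(mean((y − m̂)²))`. The adjusted trimmed mean is
`μ̂_at,g = m̂ + (μ̂_t,g − m̂)·σ̂_o/σ̂_art`, where `σ̂_o` is the *other*
arm's full-sample SD — the ordinary sample SD when that arm has no
dropout, otherwise the half-normal extrapolation
`σ̂_o = SD(retained)·√(π/(π−2))`. The effect estimate substitutes
`μ̂_at,g` for arm `g`'s trimmed mean. Two estimator variants were
considered for the rescaled arm (moment-based centring
`μ̂ = μ̂_t − σ̂·√(2/π)` versus threshold mirroring); the moment version
makes the two rescaling choices (`g = 0` and `g = 1`) algebraically
identical and cannot reproduce the distinct behaviour of the two
variants under strong-MNAR violation, so threshold mirroring was
adopted for the rescaled arm and the moment extrapolation for the other
arm's SD; the package's simulation harness validates both columns. The
adjustment is deliberately restricted to 50% trimming — the half-normal
geometry underlying both steps holds only there — and is strongly
reliant on normality, unlike the plain TM estimator.

**Permutation inference.** The cited permutation approach for TM
intervals does not fix a construction, so the package uses the basic
(reflection) interval: arm labels are permuted (missingness travels with
its row), the full trim-and-fit pipeline is re-run per permutation, and
the interval is `[β̂ − q_{(1+γ)/2}, β̂ − q_{(1−γ)/2}]` with `q` the
permutation-null quantiles; the SE is the null SD. Defaults: 1000
permutations, 95% level; identical seeds give identical intervals. With
adaptive trimming the trimming fraction is re-resolved inside every
permutation.

**Covariate imputation.** A single partially missing covariate can be
multiply imputed *after trimming* (when retained outcomes are fully
observed) by normal-linear stochastic regression with proper posterior
draws (residual variance from a scaled inverse-chi-square, coefficients
from their conditional normal). Point estimates pool as the mean across
imputations; variances by Rubin's rules. This is a deliberately simple
imputation model for a single covariate, not a general MI engine.

## Bias calculus

Implemented formulae, all for normal outcomes and validated against
Monte-Carlo oracles in the test suite:

* location-shift bias `(σ₁ − σ₀)·φ(Φ⁻¹(p))/(1 − p)`;
* homogeneous-dropout shift `b = c − c(c − p)/(c − p_d)` for `c > p`
  (no shift when the spread lies inside the trimmed fraction), and the
  per-arm strong-MNAR bias `−[(c − p)/(1 − p)]·σ·(Q(p,c) − Q(b,c))`,
  reported as the (non-negative) overestimation of the affected arm's
  trimmed mean;
* CCA bias from the thinned-mixture mean
  `μ_c = [(c − p_d)·μ_{(0,c)} + (1 − c)·μ_{(c,1)}]/(1 − p_d)`;
* the Copas–Jackson CCA bound `σ·φ(Φ⁻¹(p_d))/(1 − p_d)`, attained by
  threshold selection and equal to the homogeneous bias at `c = p_d`;
* the worst-case TM strong-MNAR bias under opposite-tail dropout,
  `−σ₀/(1 − p)·[φ(Φ⁻¹(p_s)) − φ(Φ⁻¹(p_s − (1 − p))) + φ(Φ⁻¹(1 − p))]`
  with `p_s = 1 − p_d`. Its sign is on the *affected arm's trimmed-mean*
  scale (the trimmed mean is underestimated); the treatment-effect-scale
  sign is applied in the composition step.

Composition signs (lower trimming): a comparator-arm violation pushes
the effect estimate up, a treatment-arm violation pushes it down; both
flip under higher trimming. The bias-adjusted estimate is
`β̂_tBA = β̂_t − B̂_t`, and `{β̂_t, β̂_tBA}` (ordered) are reported as
bounds on the effect under the stated scenario.

**Full-sample SD inference.** The sensitivity workflow needs full-sample
SDs, but only post-dropout SDs are observed. Under a homogeneous
scenario the observed-case distribution is a thinned normal — a pure
scale family — so the inversion is exact:
`σ = s_obs / g(c, p_d)` with `g` the SD of the thinned standard normal
computed from truncated-normal moments. MCAR (`c = 1`) leaves the SD
unchanged. No root-finding is required.

## Simulator

The generator emulates: two arms of equal size; normal outcomes
`y = μ_j + γU + ε` with `U ~ N(0,1)` and residual SD chosen so the total
arm SD equals `σ_j`; or a shifted-lognormal outcome whose outcome-scale
SD equals `σ_j` with the effect still additive on the outcome scale
(log-scale shape solved from `(e^{a²} − 1)e^{a²} = σ²`). Dropout
mechanisms: exact-count homogeneous deletion within a tail region
(hypergeometric-style rather than Bernoulli, to remove binomial noise
from the dropout count — matching designs stated as "20% dropout"),
MCAR as its `c = 1` special case, threshold (step-selection) deletion of
the most extreme values, and Bernoulli logit missingness driven by `U`
and arm. Region membership uses the true pre-deletion empirical
quantiles within arm, so exact-count mechanisms must be applied before
Bernoulli ones. Covariate missingness is Bernoulli logit in arm.

Defaults chosen where the study conditions left them open: the logit
outcome-dropout mechanism uses `expit(−1.80 + U)` (realized dropout
≈ 18% in an intact arm and ≈ 36% when combined with confined 20%
comparator dropout, via the positive correlation between `U` and `Y`);
covariate missingness uses `expit(−1.1 + 0.5·arm)` (≈ 25%/35% by arm,
≈ 30% overall); post-trim imputation uses 5 imputations with predictors
`(arm, y)`. Seeding is hierarchical (`numpy` `SeedSequence` spawning per
scenario, replicate and randomness source), so every study is bit
reproducible from one root seed.

What the simulator does *not* emulate — and hence what passing tests do
not establish about real data: longitudinal dropout processes and
intermediate outcome measurements, more than two arms, skewed outcomes
beyond the single lognormal family, covariate-outcome confounding beyond
one additive standard-normal covariate, and missingness in more than one
covariate. Real-data analyses (such as the depression-trial style
workflow in `sensitivity_report`) additionally face non-normality, for
which the bias formulae claim only direction and relative magnitude, not
exact size.

## Problem sizes and numerical choices

* Study harness defaults: S = 1000 replicates of n = 500 per arm; the
  acceptance script uses exactly these; test-suite studies run reduced
  replicate counts (150–1000) with statistical tolerances of three
  Monte-Carlo standard errors (plus the half-width of 2-dp printed
  reference values where those are the comparison target).
* Monte-Carlo oracles in tests use 4×10⁵–10⁶ draws with 3-MC-SE bands.
* Probability-interval checks use a 1e−12 tolerance; `φ(Φ⁻¹(x))` and
  `x·φ(Φ⁻¹(x))` are defined as their limit value 0 at `x ∈ {0, 1}`.
* The ceiling rule `⌈n(1 − p)⌉` is evaluated with a 1e−9 guard against
  floating-point representation of `n(1 − p)`.
* Ties at the trim boundary break by stable input order, making output
  deterministic.
* Degenerate inputs (single-arm data, an arm with all outcomes missing,
  trimming an arm to emptiness, zero trimmed-fraction SD, collinear
  covariates) raise errors rather than returning NaN.

## Known limitations

* Bias formulae are exact only for normal outcomes; for skewed data they
  indicate direction and relative size.
* The adjusted estimator exists only for fixed 50% trimming and degrades
  under strong-MNAR violation faster than the plain TM estimator —
  rescale the arm for which the strong MNAR assumption is most credible.
* Covariate-dependent (non-homogeneous) dropout has no closed-form bias
  here; the homogeneous formula with an enlarged spread serves as an
  upper bound.
* Outcome imputation (as opposed to covariate imputation) is out of
  scope, as are binary and time-to-event outcomes.
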