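# trimmedmeans

Sensitivity analysis for randomized trials whose continuous outcome is
**missing not at random (MNAR)** — for example when the patients who drop
out are precisely those doing worst. In that situation complete case
analysis (CCA) and multiple imputation are biased, because both assume
the missing outcomes look like the observed ones (given covariates).

This package implements the **trimmed means (TM) estimator** and its bias
calculus for two-arm trials: estimation, closed-form bias formulae under
assumption violations, worst-case bias bounds, a variance-rescaled
adjusted estimator, permutation confidence intervals, an MNAR dropout
simulator, and a study harness. It is aimed at trial statisticians who
want a transparent MNAR sensitivity analysis with a single, bounded
sensitivity parameter (the trimming fraction) instead of a full selection
or pattern-mixture model.

## The estimator

Let `y_ij` be the outcome of patient `i` in arm `j` (0 = comparator,
1 = treatment), with true effect `β = μ₁ − μ₀`. Under *worst-value*
(lower-tail) dropout:

1. within each arm, rank missing outcomes below the worst observed value;
2. trim away the same fraction `p` from the lower end of both arms, keeping
   `⌈n_j(1 − p)⌉` patients per arm (`p` must be at least the largest
   observed per-arm dropout proportion; *adaptive* trimming sets `p` equal
   to it);
3. estimate `β̂_t` by OLS of outcome on arm over the retained rows
   (with no covariates this is the difference of trimmed means).

`β̂_t` is unbiased for `β` under two assumptions:

* **strong MNAR** — all missing outcomes lie in the trimmed-away fraction;
* **location shift** — the arm outcome distributions differ only by a mean
  shift (equal SDs under normality).

For normal outcomes the package quantifies what happens when either
assumption fails:

* location-shift bias `B_LS = (σ₁ − σ₀)·φ(Φ⁻¹(p))/(1 − p)`
  (`(σ₁ − σ₀)·√(2/π)` at `p = 0.5`);
* strong-MNAR bias under homogeneous dropout of total mass `p_d` spread
  over the fraction `c` of the distribution: the retained fraction
  silently extends down to the quantile `b = c − c(c − p)/(c − p_d)` and
  the affected arm's trimmed mean is biased by
  `−[(c − p)/(1 − p)]·σ·(Q(p,c) − Q(b,c))`, where
  `Q(u,v) = [φ(Φ⁻¹(v)) − φ(Φ⁻¹(u))]/(v − u)`;
* CCA bias under the same mechanism, and the Copas–Jackson worst-case
  bound `|B_C^max| = σ·φ(Φ⁻¹(p_d))/(1 − p_d)`;
* worst-case TM bias under opposite-tail (threshold-selection) dropout;
* a total-bias decomposition `B_t = B_LS + B_SM0 + B_SM1` with the
  bias-adjusted estimate `β̂_t − B̂_t` bracketing the plausible effect.

The **adjusted TM estimator** (50% trimming only) relaxes the location
shift assumption: the retained fraction of one arm is treated as a half
normal, mirrored about the trimming threshold, and rescaled to the other
arm's full-sample SD (observed when that arm has no dropout, otherwise
extrapolated as `SD_trimmed·√(π/(π−2))`).

## Worked example

Simulate a trial with true effect 0.5, unequal arm SDs (σ₀ = 1.5,
σ₁ = 1), and 20% comparator dropout confined to the lowest 20% of the
outcome distribution, then fit the three estimators:

```bash
trimmed-means simulate --n-per-arm 500 --effect 0.5 --sigma0 1.5 --sigma1 1 \
    --mechanism restricted --dropout-proportion 0.2 --spread 0.2 \
    --seed 12 --out trial.csv
trimmed-means fit trial.csv --method cca
trimmed-means fit trial.csv --method tm --trim-fraction 0.5 --n-perm 1000 --seed 1
trimmed-means fit trial.csv --method tm-adj0
```

Output (abridged):

```
method: CCA
estimate: -0.0353494
---
method: TM
estimate: 0.120679
se: 0.0869509
ci (95%): [-0.0511633, 0.292839]
p_used: 0.5
retained_per_arm: arm 0: 250, arm 1: 250
---
method: TM-adjusted-0
estimate: 0.447126
```

CCA (−0.04) is badly biased: the worst comparator outcomes are missing,
so the comparator's observed mean is too high. The plain TM estimate
(0.12) removes that bias but pays the location-shift penalty
`(1 − 1.5)√(2/π) ≈ −0.40` because the arm SDs differ. The adjusted
estimator (0.45) rescales the comparator's trimmed fraction to the
treatment arm's SD and recovers the true effect 0.5 to within sampling
error. The same objects are available in Python as scikit-learn style
estimators:

```python
from trimmedmeans import TrimmedMeansEffect, read_trial_csv
est = TrimmedMeansEffect(trim_fraction=0.5, n_permutations=1000, random_state=1)
est.fit(read_trial_csv("trial.csv"))
est.effect_, est.se_, est.ci_
```

A quick screening bound for a real trial — observed SD 13.2 and 47.1%
dropout, on a depression-score scale:

```
$ trimmed-means maxbias --sigma 13.2 --dropout 0.471
max CCA bias: +/- 9.928
```

i.e. outcome-dependent dropout alone could move the complete-case
treatment effect by about 10 score units in either direction, motivating
the more precise scenario-based TM analysis
(`trimmed-means bias scenario.yaml`, `trimmedmeans.sensitivity_report`).

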