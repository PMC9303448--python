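"""Trimming rule, CCA/TM/adjusted estimators, permutation inference, imputation."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.base import clone

from trimmedmeans import (
    CompleteCaseEffect,
    McarDropout,
    RestrictedHomogeneousDropout,
    TrialDataset,
    TrialDesign,
    TrimmedMeansEffect,
    TrimSpec,
    adjusted_tm_fit,
    apply_dropout,
    cca_fit,
    generate_trial,
    impute_covariate,
    permutation_ci,
    tm_fit,
    tm_fit_imputed,
    trim,
)
from conftest import dataset_from_arms

LOWER_HALF = TrimSpec(0.5, "lower", "fixed")


def arm_values(data: TrialDataset, j: int) -> list:
    return sorted(data.arm_frame(j)["y"].dropna().tolist())


class TestTrim:
    def test_missing_ranked_lowest_with_ceiling_rule(self, toy_dataset):
        out = trim(toy_dataset, TrimSpec(0.4, "lower", "fixed"))
        assert arm_values(out, 0) == [2, 3, 4]
        assert arm_values(out, 1) == [4, 5, 6]

    def test_half_trim_no_missing(self):
        data = dataset_from_arms([1, 2, 3, 4], [1, 2, 3, 4])
        out = trim(data, LOWER_HALF)
        assert arm_values(out, 0) == [3, 4]

    def test_adaptive_trim_uses_observed_dropout(self):
        data = generate_trial(TrialDesign(n_per_arm=500, effect=0.5), seed=0)
        data = apply_dropout(data, McarDropout(0, 0.2), seed=1)
        spec = TrimSpec(mode="adaptive")
        res = tm_fit(data, spec)
        assert res.p_used == pytest.approx(0.2)
        assert res.retained_per_arm == {0: 400, 1: 400}

    def test_higher_direction_mirrors_lower(self, toy_dataset):
        hi = trim(toy_dataset, TrimSpec(0.4, "higher", "fixed"))
        flipped = TrialDataset(toy_dataset.frame.assign(y=-toy_dataset.frame["y"]))
        lo = trim(flipped, TrimSpec(0.4, "lower", "fixed"))
        assert arm_values(hi, 0) == sorted(-v for v in arm_values(lo, 0))

    def test_infeasible_fixed_fraction_raises(self, toy_dataset):
        with pytest.raises(ValueError, match="p_min"):
            trim(toy_dataset, TrimSpec(0.1, "lower", "fixed"))


class TestCompleteCase:
    def test_mean_difference_exact(self):
        data = dataset_from_arms([1, 3, np.nan], [4, 6])
        assert cca_fit(data).estimate == pytest.approx(3.0, abs=1e-12)

    def test_collinear_covariates_rejected(self):
        rng = np.random.default_rng(0)
        y = rng.normal(size=40)
        data = dataset_from_arms(y[:20], y[20:], cov0=np.ones(20), cov1=np.ones(20))
        with pytest.raises(ValueError, match="collinear|rank"):
            cca_fit(data, covariates=["u"])

    def test_empty_complete_arm_rejected(self):
        data = dataset_from_arms([np.nan, np.nan, 1.0], [1, 2, 3])
        with pytest.raises(ValueError, match="complete cases"):
            cca_fit(data)


class TestTrimmedMeans:
    def test_difference_of_trimmed_means(self):
        data = dataset_from_arms([1, 2, 3, 4], [2, 3, 4, 5])
        assert tm_fit(data, LOWER_HALF).estimate == pytest.approx(1.0, abs=1e-10)

    def test_ols_equals_mean_difference(self):
        rng = np.random.default_rng(3)
        data = dataset_from_arms(rng.normal(0, 1, 51), rng.normal(1, 2, 47))
        res = tm_fit(data, TrimSpec(0.3, "lower", "fixed"))
        trimmed = trim(data, TrimSpec(0.3, "lower", "fixed"))
        by_hand = np.mean(arm_values(trimmed, 1)) - np.mean(arm_values(trimmed, 0))
        assert res.estimate == pytest.approx(by_hand, abs=1e-10)

    def test_missing_covariate_directs_to_imputation(self):
        rng = np.random.default_rng(4)
        u0 = rng.normal(size=20)
        u0[3] = np.nan
        data = dataset_from_arms(rng.normal(0, 1, 20), rng.normal(1, 1, 20), cov0=u0,
                                 cov1=rng.normal(size=20))
        with pytest.raises(ValueError, match="impute"):
            tm_fit(data, TrimSpec(0.1, "lower", "fixed"), covariates=["u"])

    @given(st.floats(-50, 50), st.floats(0.1, 10))
    @settings(max_examples=25, deadline=None)
    def test_shift_and_scale_equivariance(self, shift, scale):
        rng = np.random.default_rng(12)
        y0, y1 = rng.normal(0, 1, 30), rng.normal(0.7, 1, 30)
        y0[:5] = np.nan
        base = tm_fit(dataset_from_arms(y0, y1), LOWER_HALF).estimate
        moved = tm_fit(dataset_from_arms(y0 * scale + shift, y1 * scale + shift), LOWER_HALF).estimate
        assert moved == pytest.approx(base * scale, rel=1e-9, abs=1e-9)

    def test_direction_mirror(self):
        rng = np.random.default_rng(5)
        y0, y1 = rng.normal(0, 1, 41), rng.normal(1, 1, 37)
        data = dataset_from_arms(y0, y1)
        flipped = dataset_from_arms(-y0, -y1)
        hi = tm_fit(data, TrimSpec(0.3, "higher", "fixed")).estimate
        lo = tm_fit(flipped, TrimSpec(0.3, "lower", "fixed")).estimate
        assert hi == pytest.approx(-lo, abs=1e-10)


class TestAdjustedTrimmedMeans:
    def test_equals_tm_at_population_level_when_sds_equal(self):
        data = generate_trial(TrialDesign(n_per_arm=20_000, effect=0.5), seed=8)
        at0 = adjusted_tm_fit(data, LOWER_HALF, rescale_arm=0).estimate
        tm = tm_fit(data, LOWER_HALF).estimate
        assert at0 == pytest.approx(tm, abs=0.05)

    def test_recovers_effect_under_unequal_sds(self):
        # location shift violated, strong MNAR satisfied: the adjusted
        # estimator is unbiased while the plain TM estimator is not
        design = TrialDesign(n_per_arm=2000, effect=0.5, arm_sigmas=(1.5, 1.0))
        ests = []
        for s in range(40):
            data = generate_trial(design, seed=100 + s)
            data = apply_dropout(data, RestrictedHomogeneousDropout(0, 0.2, 0.2), seed=s)
            ests.append(adjusted_tm_fit(data, LOWER_HALF, rescale_arm=0).estimate)
        assert np.mean(ests) == pytest.approx(0.5, abs=3 * np.std(ests) / math.sqrt(40))

    def test_requires_half_trimming(self, toy_dataset):
        with pytest.raises(ValueError, match="0.5"):
            adjusted_tm_fit(toy_dataset, TrimSpec(0.4, "lower", "fixed"), rescale_arm=0)

    def test_direction_mirror(self):
        rng = np.random.default_rng(6)
        y0, y1 = rng.normal(0, 1.5, 60), rng.normal(1, 1, 60)
        data = dataset_from_arms(y0, y1)
        flipped = dataset_from_arms(-y0, -y1)
        hi = adjusted_tm_fit(data, TrimSpec(0.5, "higher", "fixed"), 0).estimate
        lo = adjusted_tm_fit(flipped, LOWER_HALF, 0).estimate
        assert hi == pytest.approx(-lo, abs=1e-10)


class TestPermutationCI:
    def _data(self, seed=0):
        data = generate_trial(TrialDesign(n_per_arm=100, effect=0.5), seed=seed)
        return apply_dropout(data, RestrictedHomogeneousDropout(0, 0.2, 0.2), seed=seed + 1)

    def test_deterministic_given_seed(self):
        data = self._data()
        a = permutation_ci(data, LOWER_HALF, n_perm=150, seed=42)
        b = permutation_ci(data, LOWER_HALF, n_perm=150, seed=42)
        assert a == b

    def test_interval_brackets_estimate(self):
        data = self._data(3)
        res = tm_fit(data, LOWER_HALF, n_permutations=200, random_state=1)
        lo, hi = res.ci
        assert lo <= res.estimate <= hi

    def test_null_coverage(self):
        # beta = 0, no dropout: the 90% interval should cover 0 about 90%
        # of the time over repeated trials
        cover = 0
        reps = 120
        for s in range(reps):
            data = generate_trial(TrialDesign(n_per_arm=60, effect=0.0), seed=s)
            _, (lo, hi) = permutation_ci(data, LOWER_HALF, n_perm=200, seed=s, level=0.9)
            cover += lo <= 0.0 <= hi
        assert 0.81 <= cover / reps <= 0.99

    def test_se_tracks_monte_carlo_sd(self):
        # permutation SE should be on the scale of the replicate-to-replicate
        # SD of the TM estimate for the same design
        ests = []
        for s in range(80):
            data = self._data(200 + s)
            ests.append(tm_fit(data, LOWER_HALF).estimate)
        mc_sd = np.std(ests, ddof=1)
        se, _ = permutation_ci(self._data(999), LOWER_HALF, n_perm=400, seed=0)
        assert 0.6 * mc_sd < se < 1.6 * mc_sd

    def test_too_few_permutations_rejected(self, toy_dataset):
        with pytest.raises(ValueError, match="100"):
            permutation_ci(toy_dataset, TrimSpec(0.2, "lower", "fixed"), n_perm=10)


class TestImputation:
    def _covariate_trial(self, seed):
        design = TrialDesign(n_per_arm=500, effect=1.0, arm_sigmas=(2.0, 2.0),
                             covariate_effect=1.0)
        data = generate_trial(design, seed=seed)
        data = apply_dropout(data, RestrictedHomogeneousDropout(0, 0.2, 0.2), seed=seed + 1)
        frame = data.frame.copy()
        rng = np.random.default_rng(seed + 2)
        miss = rng.random(len(frame)) < 0.3
        frame.loc[miss, "u"] = np.nan
        return TrialDataset(frame)

    def test_fully_observed_returned_unchanged(self, toy_dataset):
        data = dataset_from_arms([1, 2, 3], [4, 5, 6], cov0=[1, 1, 2], cov1=[2, 1, 1])
        out = impute_covariate(data, "u")
        assert len(out) == 1 and out[0].equals(data)

    def test_reproducible_given_seed(self):
        data = trim(self._covariate_trial(7), LOWER_HALF)
        a = impute_covariate(data, "u", n_imputations=3, seed=5)
        b = impute_covariate(data, "u", n_imputations=3, seed=5)
        assert all(x.equals(y) for x, y in zip(a, b))
        assert not data.frame["u"].notna().all()  # something was imputed
        assert a[0].frame["u"].notna().all()

    def test_pooled_tm_estimate_unbiased(self):
        ests = []
        for s in range(30):
            data = self._covariate_trial(1000 + 10 * s)
            res = tm_fit_imputed(data, LOWER_HALF, "u", n_imputations=5, seed=s)
            ests.append(res.estimate)
        se = np.std(ests, ddof=1) / math.sqrt(len(ests))
        assert np.mean(ests) == pytest.approx(1.0, abs=3 * se)


class TestSklearnApi:
    def test_fit_with_dataframe_and_outcome(self):
        rng = np.random.default_rng(1)
        data = generate_trial(TrialDesign(n_per_arm=50, effect=1.0), seed=2)
        X = data.frame[["arm"]]
        y = data.frame["y"].to_numpy()
        est = TrimmedMeansEffect(trim_fraction=0.2).fit(X, y)
        assert math.isfinite(est.effect_)
        assert est.retained_per_arm_ == {0: 40, 1: 40}

    def test_get_set_params_and_clone(self):
        est = TrimmedMeansEffect(trim_fraction=0.3, direction="higher", n_permutations=0)
        params = est.get_params()
        assert params["trim_fraction"] == 0.3
        twin = clone(est).set_params(trim_fraction=0.5)
        assert twin.get_params()["trim_fraction"] == 0.5
        assert est.get_params()["trim_fraction"] == 0.3

    def test_estimator_classes_agree_with_wrappers(self, toy_dataset):
        spec = TrimSpec(0.4, "lower", "fixed")
        a = TrimmedMeansEffect(trim_fraction=0.4).fit(toy_dataset).effect_
        b = tm_fit(toy_dataset, spec).estimate
        assert a == b
        c = CompleteCaseEffect().fit(toy_dataset).effect_
        assert c == cca_fit(toy_dataset).estimate
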