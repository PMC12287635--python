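"""Random-intercept LMM fitter and the repeated-subsample inference.

The fitter is cross-checked against statsmodels MixedLM (an independent
general-purpose implementation) and against closed-form identities.
"""

import numpy as np
import pandas as pd
import pytest

from caniact import SimulationConfig, simulate_activity, simulate_cohort
from caniact.design import ModelSpec, build_design
from caniact.lmm import (
    LmmError,
    aggregate_intervals,
    check_multicollinearity,
    estimate_marginal_means,
    fit_lmm,
    grouped_kfold_consistency,
    resampled_inference,
    select_interactions,
)
from caniact.simulate import full_generating_spec, make_analysis_table


@pytest.fixture(scope="module")
def cohort_table(small_cohort):
    return small_cohort[3]


SMALL_SPEC = ModelSpec(
    fixed_effects=("age_inv_sq", "age", "breed_size", "sex", "day_type"),
    interactions=(("breed_size", "age"),),
)


class TestFitterAgainstMixedLM:
    def test_matches_statsmodels_reml(self, cohort_table):
        import statsmodels.formula.api as smf

        sub = cohort_table[cohort_table["dog_id"] < "D00060"].copy()
        fit = fit_lmm(sub, SMALL_SPEC)
        sub["log_am"] = np.log(sub["active_minutes"])
        formula = (
            "log_am ~ age_inv_sq + age"
            " + C(breed_size, Treatment('medium_large'))"
            " + C(sex, Treatment('male')) + C(day_type, Treatment('weekday'))"
            " + C(breed_size, Treatment('medium_large')):age"
        )
        sm_fit = smf.mixedlm(formula, sub, groups=sub["dog_id"]).fit(reml=True)
        assert fit.var_residual == pytest.approx(float(sm_fit.scale), rel=1e-4)
        assert fit.var_random == pytest.approx(
            float(sm_fit.cov_re.iloc[0, 0]), rel=1e-3, abs=1e-6
        )
        # term-by-term agreement of estimates and standard errors
        sm_terms = {
            "intercept": "Intercept",
            "age_inv_sq": "age_inv_sq",
            "age": "age",
            "sex[female]": "C(sex, Treatment('male'))[T.female]",
            "day_type[weekend]": "C(day_type, Treatment('weekday'))[T.weekend]",
            "breed_size[toy]": "C(breed_size, Treatment('medium_large'))[T.toy]",
            "breed_size[toy]:age": "C(breed_size, Treatment('medium_large'))[T.toy]:age",
        }
        for mine, theirs in sm_terms.items():
            c = fit.coefficients[mine]
            assert c.estimate == pytest.approx(float(sm_fit.params[theirs]), abs=1e-4)
            assert c.se == pytest.approx(float(sm_fit.bse[theirs]), rel=1e-2)

    def test_balanced_within_dog_contrast_equals_mean_difference(self):
        # condition varies within dog, perfectly balanced: the fixed effect
        # equals the raw difference of log-means for any variance ratio
        rng = np.random.default_rng(8)
        n_dogs, reps = 40, 6
        dog = np.repeat([f"d{i}" for i in range(n_dogs)], 2 * reps)
        cond = np.tile(["a", "b"] * reps, n_dogs)
        u = np.repeat(rng.normal(0, 0.6, n_dogs), 2 * reps)
        y = np.exp(
            3.0 + 0.25 * (cond == "b") + u + rng.normal(0, 0.3, len(dog))
        )
        data = pd.DataFrame({"dog_id": dog, "cond": cond, "active_minutes": y})
        spec = ModelSpec(fixed_effects=("cond",), reference_levels={"cond": "a"})
        fit = fit_lmm(data, spec)
        logs = np.log(y)
        expected = logs[cond == "b"].mean() - logs[cond == "a"].mean()
        assert fit.coefficients["cond[b]"].estimate == pytest.approx(expected, abs=1e-9)

    def test_variance_ratio_recovery(self):
        cfg = SimulationConfig(
            n_dogs=400, records_per_dog_mean=20, records_per_dog_dispersion=None,
            anomaly_prob=0.0, tau2=0.2, sigma2=0.2, seed=33,
        )
        dogs, truth = simulate_cohort(cfg)
        table = make_analysis_table(dogs, simulate_activity(dogs, truth, cfg))
        fit = fit_lmm(table, full_generating_spec())
        share = fit.var_random / (fit.var_random + fit.var_residual)
        assert share == pytest.approx(0.5, abs=0.05)

    def test_noise_free_limit_recovers_generating_coefficients(self):
        cfg = SimulationConfig(
            n_dogs=80, records_per_dog_mean=20, records_per_dog_dispersion=None,
            tau2=0.0, sigma2=1e-8, anomaly_prob=0.0, seed=9,
        )
        dogs, truth = simulate_cohort(cfg)
        table = make_analysis_table(dogs, simulate_activity(dogs, truth, cfg))
        fit = fit_lmm(table, full_generating_spec())
        for nm, c in fit.coefficients.items():
            assert c.estimate == pytest.approx(truth.coefficients.get(nm, 0.0), abs=1e-3)
        assert fit.var_random < 1e-6  # no between-dog variance left

    def test_ci_brackets_estimate(self, cohort_table):
        fit = fit_lmm(cohort_table, SMALL_SPEC)
        for c in fit.coefficients.values():
            assert c.ci_low <= c.estimate <= c.ci_high

    def test_too_few_groups_raises(self):
        data = pd.DataFrame(
            {"dog_id": ["a"] * 10, "x": np.arange(10.0), "active_minutes": np.ones(10) * 30}
        )
        with pytest.raises(LmmError):
            fit_lmm(data, ModelSpec(fixed_effects=("x",)))


class TestMulticollinearity:
    def test_perfect_continuous_correlation_flagged(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(500)
        data = pd.DataFrame({"x": x, "y": x})
        rep = check_multicollinearity(data, ["x", "y"])
        assert rep.matrix.loc["x", "y"] == pytest.approx(1.0)
        assert ("x", "y", pytest.approx(1.0)) in rep.flagged

    def test_perfect_categorical_association_is_cramers_v_one(self):
        data = pd.DataFrame(
            {"a": ["u"] * 50 + ["v"] * 50, "b": ["p"] * 50 + ["q"] * 50}
        )
        rep = check_multicollinearity(data, ["a", "b"])
        assert rep.matrix.loc["a", "b"] == pytest.approx(1.0)

    def test_independent_predictors_not_flagged(self):
        rng = np.random.default_rng(1)
        data = pd.DataFrame(
            {
                "x": rng.standard_normal(5000),
                "y": rng.standard_normal(5000),
                "g": rng.choice(["a", "b", "c"], 5000),
            }
        )
        rep = check_multicollinearity(data, ["x", "y", "g"])
        assert rep.flagged == []

    def test_constant_column_degenerate_not_error(self):
        data = pd.DataFrame({"x": np.ones(100), "y": np.arange(100.0)})
        rep = check_multicollinearity(data, ["x", "y"])
        assert rep.degenerate == ["x"]
        assert np.isnan(rep.matrix.loc["x", "y"])


class TestInteractionSelection:
    def test_empty_candidate_list_is_identity(self, cohort_table):
        base = ModelSpec(fixed_effects=("age_inv_sq", "age", "breed_size"))
        assert select_interactions(cohort_table, base, []) == base

    def test_absent_main_effect_rejected(self, cohort_table):
        base = ModelSpec(fixed_effects=("age",))
        with pytest.raises(ValueError, match="main effect"):
            select_interactions(cohort_table, base, [("breed_size", "age")])


class TestResampledInference:
    def test_single_repetition_equals_single_fit(self, cohort_table):
        agg = resampled_inference(cohort_table, SMALL_SPEC, K=10**6, R=1, seed=5)
        fit = fit_lmm(cohort_table, SMALL_SPEC)
        for nm, c in fit.coefficients.items():
            assert agg.terms[nm].estimate == pytest.approx(c.estimate, abs=1e-10)
            assert agg.terms[nm].p in (0.0, 1.0)

    def test_forced_interval_aggregation(self):
        # three repetitions with CIs (-1,1), (0.5,2), (1,3): one contains 0
        agg = aggregate_intervals(
            np.array([0.0, 1.2, 2.0]),
            np.array([-1.0, 0.5, 1.0]),
            np.array([1.0, 2.0, 3.0]),
        )
        assert agg.p == pytest.approx(1 / 3)
        assert agg.estimate == pytest.approx(np.mean([0.0, 1.2, 2.0]))

    def test_reproducible_from_seed(self, cohort_table):
        a = resampled_inference(cohort_table, SMALL_SPEC, K=10, R=5, seed=3)
        b = resampled_inference(cohort_table, SMALL_SPEC, K=10, R=5, seed=3)
        assert a.terms == b.terms

    def test_aggregate_within_min_max_of_repetitions(self, cohort_table):
        agg = resampled_inference(cohort_table, SMALL_SPEC, K=15, R=20, seed=1)
        reps = agg.per_repetition
        for nm, c in agg.terms.items():
            assert reps[nm].min() - 1e-12 <= c.estimate <= reps[nm].max() + 1e-12

    def test_invalid_sizes_rejected(self, cohort_table):
        with pytest.raises(ValueError):
            resampled_inference(cohort_table, SMALL_SPEC, K=0, R=1)


class TestMarginalMeans:
    def test_two_level_factor_ratio_is_exp_coefficient(self, cohort_table):
        fit = fit_lmm(cohort_table, SMALL_SPEC)
        mm = estimate_marginal_means(
            fit, cohort_table, "day_type", ["weekday", "weekend"], SMALL_SPEC
        )
        ratio = mm.table["prediction"].iloc[1] / mm.table["prediction"].iloc[0]
        assert ratio == pytest.approx(
            np.exp(fit.coefficients["day_type[weekend]"].estimate), rel=1e-12
        )

    def test_log_prediction_equals_linear_predictor(self, cohort_table):
        # round-trip identity with bias correction off
        fit = fit_lmm(cohort_table, SMALL_SPEC)
        mm = estimate_marginal_means(
            fit, cohort_table, "sex", ["male"], SMALL_SPEC
        )
        c = fit.coefficients
        lp = (
            c["intercept"].estimate
            + c["age_inv_sq"].estimate * cohort_table["age_inv_sq"].mean()
            + c["age"].estimate * cohort_table["age"].mean()
        )
        assert np.log(mm.table["prediction"].iloc[0]) == pytest.approx(lp, abs=1e-10)

    def test_bias_correction_multiplies_by_half_variance_exp(self, cohort_table):
        fit = fit_lmm(cohort_table, SMALL_SPEC)
        raw = estimate_marginal_means(fit, cohort_table, "sex", ["male"], SMALL_SPEC)
        corr = estimate_marginal_means(
            fit, cohort_table, "sex", ["male"], SMALL_SPEC, bias_correction=True
        )
        factor = corr.table["prediction"].iloc[0] / raw.table["prediction"].iloc[0]
        assert factor == pytest.approx(
            np.exp(0.5 * (fit.var_random + fit.var_residual)), rel=1e-12
        )

    def test_age_grid_updates_inverse_square_term(self, cohort_table):
        fit = fit_lmm(cohort_table, SMALL_SPEC)
        mm = estimate_marginal_means(
            fit, cohort_table, "age", [2.0, 10.0], SMALL_SPEC
        )
        # the age^-2 coefficient is large and positive: young >> old
        assert mm.table["prediction"].iloc[0] > mm.table["prediction"].iloc[1]

    def test_unknown_grid_level_rejected(self, cohort_table):
        fit = fit_lmm(cohort_table, SMALL_SPEC)
        with pytest.raises(ValueError, match="absent"):
            estimate_marginal_means(
                fit, cohort_table, "sex", ["hermaphrodite"], SMALL_SPEC
            )


class TestGroupedKFold:
    def test_folds_partition_dogs(self, cohort_table):
        res = grouped_kfold_consistency(cohort_table, SMALL_SPEC, k=3, seed=0)
        assert len(res.per_fold) == 3
        assert np.isfinite(res.sd["r2"])

    def test_single_fold_degenerate(self, cohort_table):
        res = grouped_kfold_consistency(cohort_table, SMALL_SPEC, k=1, seed=0)
        assert res.degenerate and res.sd.isna().all()

    def test_more_folds_than_dogs_rejected(self, cohort_table):
        with pytest.raises(ValueError, match="fewer dogs"):
            grouped_kfold_consistency(cohort_table, SMALL_SPEC, k=10**6)
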