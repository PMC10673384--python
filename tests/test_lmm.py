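"""Mixed-model engine tests: OLS limits, closed-form variance components,
ICC and R2 arithmetic, model comparison, Wald CI calibration."""

import numpy as np
import pandas as pd
import pytest

from metamediate import (
    COVARIATES_FULL,
    COVARIATES_REDUCED,
    LMMFit,
    ModelSpec,
    SimConfig,
    compare_fits,
    fit_lmm,
    generate_cohort,
    icc,
    r2_nakagawa,
)
from metamediate.lmm import RankDeficientError, prepare

from conftest import single_level_cohort


def balanced_layout(g, m, var_between, var_within, seed):
    rng = np.random.default_rng(seed)
    u = rng.normal(0, np.sqrt(var_between), g)
    y = (u[:, None] + rng.normal(0, np.sqrt(var_within), (g, m))).ravel()
    return pd.DataFrame(
        {
            "family_id": np.repeat(np.arange(g), m),
            "individual_id": np.repeat(np.arange(g), m),
            "visit_index": 2,
            "age": 55.0,
            "sex": "M",
            "race": "white",
            "education": 0,
            "cesd": 0.0,
            "alcohol_weekly": 0.0,
            "bmi_category": "normal",
            "smoking": "never",
            "smoking_code": 0,
            "y": y,
        }
    )


def make_fit(var_fixed, family, individual, slope, residual, mean_age_c2=1.0):
    """Assemble an LMMFit with hand-set variance structure."""
    return LMMFit(
        spec=ModelSpec(outcome="y"),
        params=pd.DataFrame(
            {"beta": [0.0], "se": [1.0], "ci_low": [-2.0], "ci_high": [2.0], "p": [1.0]},
            index=["Intercept"],
        ),
        variance_components={
            "family": family, "individual": individual,
            "age_slope": slope, "residual": residual,
        },
        loglike=0.0, n_obs=10, n_individuals=5, n_families=5,
        converged=True, method="reml", cov_mode="independent",
        var_fixed=var_fixed, mean_age_c2=mean_age_c2, n_params=3,
    )


class TestFitLMM:
    def test_ols_limit_matches_lstsq(self):
        df = single_level_cohort(300, seed=1)
        spec = ModelSpec(
            outcome="PACC3", exposure_coding="numeric", covariates=("age", "cesd"),
            family_intercept=False, individual_intercept=False, age_slope=False,
        )
        fit = fit_lmm(df, spec)
        d = prepare(df)
        X = np.column_stack(
            [np.ones(len(d)), d["smoking_code"], d["age_c"], d["cesd"]]
        )
        beta = np.linalg.lstsq(X, d["PACC3"], rcond=None)[0]
        got = fit.params["beta"].to_numpy()
        assert np.abs(np.sort(got) - np.sort(beta)).max() < 1e-8
        assert fit.method == "ols"

    def test_balanced_variance_components_match_anova(self):
        g, m = 60, 5
        df = balanced_layout(g, m, 2.0, 1.0, seed=3)
        spec = ModelSpec(
            outcome="y", include_exposure=False, covariates=(),
            family_intercept=False, individual_intercept=True, age_slope=False,
        )
        fit = fit_lmm(df, spec, polish=True)
        y = df["y"].to_numpy().reshape(g, m)
        ybar_g, ybar = y.mean(axis=1), y.mean()
        msb = m * ((ybar_g - ybar) ** 2).sum() / (g - 1)
        msw = ((y - ybar_g[:, None]) ** 2).sum() / (g * (m - 1))
        assert abs(fit.variance_components["individual"] - (msb - msw) / m) < 1e-6
        assert abs(fit.variance_components["residual"] - msw) < 1e-6

    def test_one_observation_per_individual_approaches_ols(self):
        df = single_level_cohort(250, seed=5)
        spec_mm = ModelSpec(
            outcome="PACC3", exposure_coding="numeric", covariates=("age",),
            family_intercept=False, individual_intercept=True, age_slope=False,
        )
        spec_ols = ModelSpec(
            outcome="PACC3", exposure_coding="numeric", covariates=("age",),
            family_intercept=False, individual_intercept=False, age_slope=False,
        )
        fit_mm = fit_lmm(df, spec_mm, polish=True)
        fit_ols = fit_lmm(df, spec_ols)
        np.testing.assert_allclose(
            fit_mm.params["beta"], fit_ols.params["beta"], atol=1e-6
        )

    def test_simulated_betas_within_3_se(self):
        cfg = SimConfig(n_families=550, n_metabolites=0,
                        direct_effect=-0.2, seed=17)
        cohort, truth = generate_cohort(cfg)
        fit = fit_lmm(cohort, ModelSpec(outcome="PACC3", exposure_coding="numeric"))
        eff = cfg.covariate_effects
        for term, true_val in [
            ("smoking_code", truth.de["PACC3"]),
            ("C(sex, Treatment('M'))[T.F]", eff["female"]),
            ("education", eff["college"]),
            ("practice", cfg.practice_effect),
            ("age_c", cfg.age_coefs[0]),
        ]:
            assert abs(fit.beta(term) - true_val) < 3 * fit.se(term), term

    def test_scale_equivariance(self):
        df = single_level_cohort(200, seed=7)
        k = 3.7
        df2 = df.assign(PACC3=df["PACC3"] * k)
        spec = ModelSpec(
            outcome="PACC3", exposure_coding="numeric", covariates=("age", "cesd"),
            family_intercept=False, individual_intercept=False, age_slope=False,
        )
        f1, f2 = fit_lmm(df, spec), fit_lmm(df2, spec)
        np.testing.assert_allclose(f2.params["beta"], k * f1.params["beta"], rtol=1e-8)
        np.testing.assert_allclose(f2.params["se"], k * f1.params["se"], rtol=1e-8)
        np.testing.assert_allclose(f2.params["p"], f1.params["p"], atol=1e-8)

    def test_scale_equivariance_mixed(self):
        g, m = 40, 4
        df = balanced_layout(g, m, 1.5, 1.0, seed=9)
        spec = ModelSpec(
            outcome="y", include_exposure=False, covariates=(),
            family_intercept=False, individual_intercept=True, age_slope=False,
        )
        k = 2.5
        f1 = fit_lmm(df, spec, polish=True)
        f2 = fit_lmm(df.assign(y=df["y"] * k), spec, polish=True)
        np.testing.assert_allclose(f2.params["beta"], k * f1.params["beta"], rtol=1e-6)
        np.testing.assert_allclose(f2.params["se"], k * f1.params["se"], rtol=1e-5)

    def test_rank_deficient_names_terms(self):
        df = single_level_cohort(100, seed=11)
        df["cesd"] = 0.0  # constant -> collinear with the intercept
        spec = ModelSpec(
            outcome="PACC3", exposure_coding="numeric", covariates=("cesd",),
            family_intercept=False, individual_intercept=False, age_slope=False,
        )
        with pytest.raises(RankDeficientError, match="cesd"):
            fit_lmm(df, spec)

    def test_nonconvergence_is_flagged(self):
        # near-degenerate: two observations, maximal structure
        cfg = SimConfig(n_families=25, n_metabolites=0, seed=3)
        cohort, _ = generate_cohort(cfg)
        fit = fit_lmm(cohort, ModelSpec(outcome="PACC3", exposure_coding="numeric"))
        assert isinstance(fit.converged, bool)  # status always explicit


class TestICC:
    def test_arithmetic(self):
        fit = make_fit(0.0, family=2.0, individual=1.0, slope=0.5, residual=1.0)
        assert icc(fit) == pytest.approx(0.75)

    def test_zero_random(self):
        fit = make_fit(1.0, 0.0, 0.0, 0.0, 1.0)
        assert icc(fit) == 0.0

    def test_simulated_near_generative_value(self):
        cfg = SimConfig(n_families=600, n_metabolites=0, seed=23)
        cohort, _ = generate_cohort(cfg)
        fit = fit_lmm(cohort, ModelSpec(outcome="PACC3", exposure_coding="numeric"))
        vc = cfg.variance_components
        truth_icc = (vc["family"] + vc["individual"]) / (
            vc["family"] + vc["individual"] + vc["residual"]
        )
        assert abs(fit.icc - truth_icc) < 0.07


class TestR2:
    def test_hand_set_variances(self):
        fit = make_fit(3.0, family=1.0, individual=0.0, slope=0.0, residual=1.0)
        assert r2_nakagawa(fit) == pytest.approx((0.6, 0.8))

    def test_zero_fixed_variance(self):
        fit = make_fit(0.0, family=1.0, individual=0.0, slope=0.0, residual=1.0)
        marginal, conditional = r2_nakagawa(fit)
        assert marginal == 0.0
        assert conditional == pytest.approx(0.5)

    def test_perfect_fixed_fit_limit(self):
        fit = make_fit(2.0, 0.0, 0.0, 0.0, 0.0)
        assert r2_nakagawa(fit) == (1.0, 1.0)

    def test_marginal_not_above_conditional_on_simulation(self):
        cfg = SimConfig(n_families=150, n_metabolites=0, seed=29)
        cohort, _ = generate_cohort(cfg)
        fit = fit_lmm(cohort, ModelSpec(outcome="IMM", exposure_coding="numeric"))
        marginal, conditional = fit.r2
        assert 0.0 <= marginal <= conditional <= 1.0

    def test_verified_against_direct_variance_decomposition(self):
        # generative check: with known components, the population R2s are
        # var(fixed)/(var(fixed)+vc_total) and (var(fixed)+vc)/(...)
        cfg = SimConfig(n_families=600, n_metabolites=0, seed=31)
        cohort, truth = generate_cohort(cfg)
        fit = fit_lmm(cohort, ModelSpec(outcome="PACC3", exposure_coding="numeric"))
        d = prepare(cohort)
        eff = cfg.covariate_effects
        predictor = (
            eff["female"] * (d["sex"] == "F")
            + eff["white"] * (d["race"] == "white")
            + eff["college"] * d["education"]
            + eff["cesd"] * d["cesd"]
            + eff["alcohol"] * d["alcohol_weekly"]
            + eff["bmi_underweight"] * (d["bmi_category"] == "underweight")
            + eff["bmi_overweight"] * (d["bmi_category"] == "overweight")
            + eff["bmi_obese"] * (d["bmi_category"] == "obese")
            + cfg.age_coefs[0] * d["age_c"]
            + cfg.age_coefs[1] * d["age_c"] ** 2
            + cfg.practice_effect * d["practice"]
            + truth.de["PACC3"] * d["smoking_code"]
        )
        vc = cfg.variance_components
        vf = float(np.var(predictor))
        vr = vc["family"] + vc["individual"] + vc["age_slope"] * float(
            np.mean(d["age_c"] ** 2)
        )
        expect_marg = vf / (vf + vr + vc["residual"])
        expect_cond = (vf + vr) / (vf + vr + vc["residual"])
        marginal, conditional = fit.r2
        assert abs(marginal - expect_marg) < 0.05
        assert abs(conditional - expect_cond) < 0.05


class TestCompareFits:
    def test_identical_models_tie_to_reduced(self):
        df = single_level_cohort(150, seed=13)
        spec = ModelSpec(
            outcome="PACC3", exposure_coding="numeric", covariates=("age",),
            family_intercept=False, individual_intercept=False, age_slope=False,
        )
        fit = fit_lmm(df, spec)
        sel = compare_fits(fit, fit)
        assert sel["choice"] == "reduced"

    def test_differing_observation_sets_rejected(self):
        df = single_level_cohort(150, seed=13)
        spec = ModelSpec(
            outcome="PACC3", exposure_coding="numeric", covariates=("age",),
            family_intercept=False, individual_intercept=False, age_slope=False,
        )
        f1 = fit_lmm(df, spec)
        f2 = fit_lmm(df.iloc[:100], spec)
        with pytest.raises(ValueError, match="observation"):
            compare_fits(f1, f2)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_strong_confounder_selects_full(self, seed):
        # cesd has a strong planted effect: the model including it should win
        df = single_level_cohort(400, seed=seed)
        df["PACC3"] = df["PACC3"] + 1.5 * df["cesd"]
        reduced = ModelSpec(
            outcome="PACC3", exposure_coding="numeric", covariates=("age",),
            family_intercept=False, individual_intercept=False, age_slope=False,
        )
        full = ModelSpec(
            outcome="PACC3", exposure_coding="numeric", covariates=("age", "cesd"),
            family_intercept=False, individual_intercept=False, age_slope=False,
        )
        sel = compare_fits(fit_lmm(df, reduced), fit_lmm(df, full))
        assert sel["choice"] == "full"

    def test_pure_noise_extras_prefer_reduced_in_majority(self):
        # AIC admits an irrelevant covariate with probability ~P(chi2_1 > 2),
        # so the property is a majority over replicates, not every replicate
        choices = []
        for seed in range(9):
            rng = np.random.default_rng(seed)
            df = single_level_cohort(1000, seed=seed)
            df["cesd"] = rng.normal(0, 1, len(df))  # independent noise covariate
            reduced = ModelSpec(
                outcome="PACC3", exposure_coding="numeric", covariates=("age",),
                family_intercept=False, individual_intercept=False, age_slope=False,
            )
            full = ModelSpec(
                outcome="PACC3", exposure_coding="numeric", covariates=("age", "cesd"),
                family_intercept=False, individual_intercept=False, age_slope=False,
            )
            sel = compare_fits(fit_lmm(df, reduced), fit_lmm(df, full))
            choices.append(sel["choice"])
        assert choices.count("reduced") > len(choices) / 2


class TestWaldCalibration:
    def test_ci_coverage_for_exposure_coefficient(self):
        # scaled-down replicate study: 95% Wald CIs for the numeric smoking
        # coefficient should cover the truth at ~95%
        n_reps, covered = 200, 0
        for rep in range(n_reps):
            cfg = SimConfig(
                n_families=70,
                n_visits={2: 0.5, 3: 0.5},
                n_metabolites=0,
                direct_effect=-0.15,
                seed=40_000 + rep,
            )
            cohort, truth = generate_cohort(cfg)
            spec = ModelSpec(
                outcome="PACC3", exposure_coding="numeric",
                covariates=COVARIATES_REDUCED,
            )
            fit = fit_lmm(cohort, spec)
            lo = fit.params.loc["smoking_code", "ci_low"]
            hi = fit.params.loc["smoking_code", "ci_high"]
            covered += lo <= truth.de["PACC3"] <= hi
        assert abs(covered / n_reps - 0.95) <= 0.04
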