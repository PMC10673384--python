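# Methods

## Scientific setting

`metamediate` implements a four-step screening workflow for asking whether
small-molecule metabolites lie on the biological pathway between a
behavioral exposure (smoking status) and a longitudinal outcome (cognitive
composite scores), in a cohort where individuals are nested within
sibships and observed over repeated visits. The design mirrors the classic
product-of-coefficients mediation analysis, scaled up to an untargeted
metabolomics panel with false-discovery-rate gating between steps:

1. **Total effect.** Mixed models of each cognitive composite on smoking
   plus covariates establish the exposure–outcome association (path *c*)
   and select between a reduced and a fully-adjusted covariate set.
2. **Exposure → metabolite.** One mixed model per metabolite (metabolite
   as outcome, numeric smoking as predictor) estimates path *a*;
   Benjamini–Hochberg FDR across the metabolites of one fluid gates the
   survivors.
3. **Metabolite → outcome.** For each survivor, the outcome is regressed
   on smoking plus the metabolite; the metabolite coefficient is path
   *b*, FDR-gated within (fluid, outcome).
4. **Decomposition.** For each finalist, the indirect effect IE = a·b and
   the direct effect DE = c′ (the smoking coefficient with the mediator in
   the model) are reported with a Monte-Carlo confidence interval for the
   product and a mediation classification.

## Models

All association models are Gaussian linear mixed models fitted by REML
(statsmodels `MixedLM`):

    y_ijk = Xβ + u_fam(i) + u_ind(ij) + s_ind(ij) · age_c + ε_ijk

with random intercepts for family *i* and individual *j* (individuals
nested in families) and a random age slope per individual. Fixed effects:
smoking; sex; race; education; practice term (visit − 2, baseline being
the second visit); linear and quadratic centered age; and, in the full
specification, depressive-symptom score (CES-D), BMI category (reference
normal) and weekly alcohol. Age is centered to the realized analysis-
sample mean before squaring. Models for CSF metabolites drop the family
intercept (few related CSF donors).

Implementation notes:

- The nested individual intercept and the individual age slope enter as
  variance components using within-family slot coding, which keeps the
  component design at (max sibship size) columns rather than one per
  individual. Variance components are mutually independent, so the
  slope–intercept covariance is fixed at zero; each fit records this as
  `cov_mode = "independent"`.
- Coefficient tests are Wald z-tests; 95% CIs use ±1.96·SE. No
  small-sample degrees-of-freedom correction is applied (the cohorts this
  targets have hundreds of families).
- With all random terms disabled the same surface fits OLS, which is the
  engine's degenerate limit and the basis of its exactness tests.
- Optimization is L-BFGS with a conjugate-gradient fallback; `polish=True`
  adds a derivative-free (Powell) refinement from the first-stage optimum
  and is used where variance components are compared with closed forms at
  tight tolerance.
- Reduced-vs-full selection uses AIC from maximum-likelihood refits (REML
  likelihoods are not comparable across fixed structures); ties go to the
  reduced model.

**Exposure coding.** Step-1 models use categorical smoking
(never/former/current, reference never), exposing separate former- and
current-smoker coefficients. Steps 2–4 code smoking numerically
(never = 0, former = 1, current = 2) so each mediation path is a single
coefficient. Both codings are switchable per `ModelSpec`.

**Reported summaries.** ICC = (family + individual intercept variance) /
(those + residual); the age-slope variance is excluded. Marginal and
conditional R² follow the fixed-vs-total variance decomposition, with the
random-slope contribution entering as σ²_slope · mean(age_c²).

## Mediation decomposition

IE = a·b and DE = c′ come from separate models, so the Monte-Carlo CI
draws a* ~ N(â, SE_a²) and b* ~ N(b̂, SE_b²) independently (cross-path
covariance taken as zero, the standard assumption when the paths come
from different fits) and takes empirical α/2 and 1−α/2 quantiles of a*·b*;
default 100 000 draws, seeded and reproducible. The
distribution-of-product reference is implemented as a numerical
integration of the product-of-normals CDF and serves as the oracle in the
test suite rather than a second production code path.

On single-level nested least-squares fits with a shared covariate set the
identity c = a·b + c′ holds exactly; with mixed models a small additivity
gap remains and is recorded on every result (`additivity_gap`).

Proportion mediated is reported under two denominators — IE/(IE + DE)
(primary) and IE/c — because both conventions are in common use and they
differ whenever the model-implied total effect a·b + c′ differs from the
separately estimated c. It is undefined when IE and DE have opposite
signs (inconsistent mediation / suppression) or the denominator vanishes,
and exactly 0 when IE = 0 with DE ≠ 0.

Classification: **none** if the IE interval spans 0; **inconsistent** if
it excludes 0 and IE, DE disagree in sign; **complete** if it excludes 0
and the direct effect is not significant (p ≥ 0.05); **partial**
otherwise.

## Quality control

The QC cascade runs in fixed order: (1) drop metabolites with missingness
strictly above 50%; (2) drop samples with missingness strictly above 40%;
(3) drop metabolites whose observed values have interquartile range 0
(metabolites with fewer than two observed values are removed and flagged
as degenerate); (4) log10-transform. Threshold comparisons are strict, so
a metabolite at exactly the threshold is retained. The IQR uses linear
interpolation between order statistics; only IQR = 0 versus > 0 matters,
which is insensitive to the quantile rule for the constant-column case.
The accounting identities (final = initial − removals) hold exactly and
are asserted on every run. Zero-IQR status can change when a
high-missingness sample is dropped, which is why the cascade order is
fixed and tested; for the same reason exact idempotence of the cascade is
a property of data whose missing fractions sit clear of the thresholds,
not of arbitrary inputs.

Residual missingness after QC is handled per-model by complete-case
analysis; a half-minimum imputation mode exists as a sensitivity option.
Metabolite values enter models as unstandardized log10 abundances; a
z-score option is provided.

Samples collected off-visit are matched to the nearest study visit by
age, ties breaking toward the earlier visit.

## Synthetic cohort generator

The generator emulates a midlife longitudinal cohort: sibships of 1–3
individuals (mean ≈ 1.26, i.e. ≈ 1000 families per ≈ 1266 individuals),
1–6 visits per individual averaging ≈ 3.7 at ≈ 2-year spacing, baseline
age ~ N(58.5, 6.47²) truncated to [40.7, 75.0], 70.4% female, 94.8%
white, 61.4% college-educated, smoking distributed 56.2/37.0/6.8% over
never/former/current, BMI categories 0.6/27.8/35.5/36.1%, and CES-D and
weekly alcohol drawn from gamma distributions matched to mean/SD
(7.13/7.16 and 4.25/6.74) since both are right-skewed. Smoking is
time-constant by default; an optional mode lets current smokers quit
between visits (status never increases).

Outcomes are generated from exactly the mixed model the engine fits:
fixed covariate effects (defaults on the scale of the cohort's published
full-model coefficients), a per-unit-smoking direct effect c′, linear
(−0.047/yr) and quadratic (−0.001/yr²) centered-age terms, a practice
effect (+0.10/visit), planted metabolite terms, and family/individual/
age-slope/residual variances (0.08/0.25/0.0004/0.09, giving ICC ≈ 0.79).
Latent log10 metabolite abundances are μ_j + a_j·smoking + individual +
sample noise (SD 0.5 and 0.2); emitted abundances are 10^latent, hence
strictly positive and log-normal. Mediator terms enter the outcome
centered on μ_j so the planted b_j is the exact generative slope of the
log10 abundance. Cohort and metabolome come from one seeded generator,
so they can be produced jointly or separately and remain consistent;
identical configurations are byte-identical.

Ground truth records per-metabolite a_j, b_j, IE = a_j·b_j, the direct
effect, and a role label (mediator, suppressor, null_a, null_b, noise);
the suppressor sign constraint sign(a·b) ≠ sign(DE) is asserted at
construction. Planted b_j applies to every generated composite, so the
truth is outcome-invariant.

What the generator does **not** emulate: raw mass spectra or ion counts,
batch/drift structure, informative missingness beyond the optional
low-abundance mode, metabolite–metabolite correlation beyond the shared
exposure, dropout correlated with outcomes, or dementia conversion.
Passing tests therefore demonstrate correctness of the statistical
machinery under a faithful generative model of the *design*, not
robustness to assay artifacts of real metabolomics data.

## FDR families

Step 2 adjusts across all metabolites of one fluid; Step 3 adjusts across
the Step-2 survivors within one (fluid, outcome). Plasma and CSF
p-values are never pooled into one family. The family structure, FDR
level, exposure coding and seeds are recorded in the run metadata of
every pipeline run. The survivor sets narrow monotonically by
construction: Step 3 only sees Step-2 survivors, Step 4 only Step-3
survivors, and an empty survivor set terminates the run cleanly with an
explanatory report.

## Numerical choices and degenerate inputs

- BH adjustment is delegated to `statsmodels.stats.multitest` and checked
  against an exhaustive step-up oracle over all short p-vectors.
- Rank-deficient fixed designs raise an error naming the collinear
  columns (QR with pivoting). Categorical covariates with a single
  observed level in an analysis subset are dropped from the design (a
  constant term); a missing reference level falls back to default
  contrast coding.
- Metabolite models with fewer than 50 complete-case rows (configurable)
  are skipped and reported, never silently dropped.
- Non-convergence of a mixed-model fit is always carried as an explicit
  flag on the fit object.
- Monte-Carlo CIs with both SEs zero collapse to the point product.
- Percentages in descriptive tables round half-to-even at one decimal;
  tallies are exact integers.

## Problem sizes used in the checks

The automated checks run at reduced but statistically adequate sizes,
chosen once: CI coverage uses 500 single-level datasets of n = 1000 with
5000 Monte-Carlo draws per interval; path recovery uses 20 multilevel
cohorts of ≈ 2000 observations; suppressor classification 15 cohorts of
≈ 1000 observations; the null false-discovery check 200 replicates of a
10-metabolite null screen; QC accounting runs at the full study-sized
matrices (412 × 372 and 1275 × 2500). Single-level replicate checks use
the OLS limit of the engine, which is exact for those designs and keeps
the Monte-Carlo replicate counts high where they matter.

## Known limitations

- No counterfactual (natural direct/indirect effect) estimators,
  exposure–mediator interaction, multiple-mediator joint models, or
  sensitivity analysis for sequential ignorability.
- Wald z inference only; no Satterthwaite/Kenward–Roger corrections.
- No batch correction or normalization to internal standards.
- The slope–intercept covariance of the random structure is not
  estimated (fixed at zero by the variance-components formulation).
- Cohort-specific coefficient values from any particular study are not
  reproduction targets; the package validates against planted ground
  truth and closed-form oracles instead.
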