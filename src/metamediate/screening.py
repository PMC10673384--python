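"""Association screening: the first three steps of the mediation cascade.

Step 1 tests the total exposure -> outcome effect and selects between the
reduced and fully-adjusted covariate sets by ML-based AIC. Step 2 fits one
mixed model per metabolite (metabolite as outcome, numeric smoking as
predictor) and gates on Benjamini-Hochberg FDR within fluid. Step 3
regresses the cognitive outcome on smoking plus each Step-2 survivor and
gates the metabolite coefficient on FDR within (fluid, outcome). The
candidate sets only ever narrow: no metabolite reaches Step 3 without
passing Step 2.

FDR families are recorded in the run metadata: Step 2 adjusts across
metabolites within one fluid; Step 3 across candidates within one fluid
and outcome; plasma and CSF p-values are never pooled.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .lmm import LMMFit, ModelSpec, compare_fits, fit_lmm, prepare
from .qc import match_matrix_to_cohort
from .synthetic_data import MetaboliteMatrix

DEFAULT_FDR_LEVEL = 0.05
DEFAULT_MIN_OBS = 50


@dataclass
class AssociationResult:
    """One screening association: the exposure or metabolite coefficient
    from a single mixed model, with its BH-FDR q-value."""

    metabolite: str
    fluid: str
    outcome: str
    beta: float
    se: float
    ci_low: float
    ci_high: float
    p: float
    q: float = np.nan
    passed: bool = False
    n_obs: int = 0

    def as_dict(self) -> dict:
        return dict(
            metabolite=self.metabolite,
            fluid=self.fluid,
            outcome=self.outcome,
            beta=self.beta,
            se=self.se,
            ci_low=self.ci_low,
            ci_high=self.ci_high,
            p=self.p,
            q=self.q,
            passed=self.passed,
            n_obs=self.n_obs,
        )


def results_frame(results) -> pd.DataFrame:
    return pd.DataFrame([r.as_dict() for r in results])


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (step-up), original order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _attach_fdr(results, fdr_level: float) -> None:
    if not results:
        return
    q = bh_fdr([r.p for r in results])
    for r, qi in zip(results, q):
        r.q = float(qi)
        r.passed = bool(qi < fdr_level)


@dataclass
class Step1Result:
    fit_reduced: LMMFit
    fit_full: LMMFit
    selection: dict

    @property
    def chosen_spec(self) -> ModelSpec:
        return self.selection["chosen_spec"]

    @property
    def chosen_fit(self) -> LMMFit:
        return self.selection["chosen_fit"]

    def smoking_coefficients(self) -> pd.DataFrame:
        fit = self.chosen_fit
        return fit.params.loc[fit.spec.exposure_terms()]


def step1_total_effect(
    cohort: pd.DataFrame,
    outcome: str,
    reduced_spec: ModelSpec | None = None,
    full_spec: ModelSpec | None = None,
) -> Step1Result:
    """Exposure -> outcome total-effect models; choose reduced vs full.

    Both specs are fitted to the rows complete for the full covariate
    set, so the AIC comparison sees identical observations.
    """
    from .lmm import COVARIATES_FULL, COVARIATES_REDUCED

    reduced_spec = reduced_spec or ModelSpec(outcome=outcome, covariates=COVARIATES_REDUCED)
    full_spec = full_spec or ModelSpec(outcome=outcome, covariates=COVARIATES_FULL)
    data = prepare(cohort)
    fit_reduced = fit_lmm(data, reduced_spec)
    fit_full = fit_lmm(data, full_spec)
    selection = compare_fits(fit_reduced, fit_full)
    return Step1Result(fit_reduced, fit_full, selection)


def merge_metabolites(
    cohort: pd.DataFrame, matrix: MetaboliteMatrix
) -> pd.DataFrame:
    """Join QC'd metabolite values onto cohort visits.

    Samples are matched to visits by nearest age (ties to the earlier
    visit); the result is one row per matched (individual, visit) with
    metabolite columns appended.
    """
    if not matrix.log_scale:
        raise ValueError("matrix must be QC'd (log scale) before screening")
    meta = match_matrix_to_cohort(matrix, cohort)
    wide = matrix.data.copy()
    wide["individual_id"] = meta["individual_id"]
    wide["visit_index"] = meta["visit_index"]
    # one sample per (individual, visit): keep the first on duplicates
    wide = wide.drop_duplicates(subset=["individual_id", "visit_index"], keep="first")
    return cohort.merge(wide, on=["individual_id", "visit_index"], how="inner")


def step2_metabolite_screen(
    cohort: pd.DataFrame,
    matrix: MetaboliteMatrix,
    spec_template: ModelSpec | None = None,
    fdr_level: float = DEFAULT_FDR_LEVEL,
    min_obs: int = DEFAULT_MIN_OBS,
    standardize: bool = False,
) -> tuple[list, list]:
    """Per-metabolite exposure -> metabolite mixed models, FDR within fluid.

    Returns (results, skipped) where skipped lists metabolites with fewer
    than ``min_obs`` complete-case rows.
    """
    fluid = str(matrix.meta["fluid"].iloc[0]) if matrix.n_samples else "plasma"
    if spec_template is None:
        spec_template = ModelSpec(
            outcome="_met",
            exposure_coding="numeric",
            family_intercept=(fluid != "csf"),
        )
    merged = prepare(merge_metabolites(cohort, matrix))
    results, skipped = [], []
    for met in matrix.data.columns:
        sub = merged.dropna(subset=[met]).copy()
        if len(sub) < min_obs:
            skipped.append(met)
            continue
        sub["_met"] = (
            (sub[met] - sub[met].mean()) / sub[met].std(ddof=1) if standardize else sub[met]
        )
        fit = fit_lmm(sub, replace(spec_template, outcome="_met"))
        row = fit.params.loc["smoking_code"]
        results.append(
            AssociationResult(
                metabolite=met,
                fluid=fluid,
                outcome="metabolite",
                beta=float(row["beta"]),
                se=float(row["se"]),
                ci_low=float(row["ci_low"]),
                ci_high=float(row["ci_high"]),
                p=float(row["p"]),
                n_obs=fit.n_obs,
            )
        )
    _attach_fdr(results, fdr_level)
    return results, skipped


def step3_outcome_screen(
    cohort: pd.DataFrame,
    matrix: MetaboliteMatrix,
    candidates,
    outcome: str,
    spec_template: ModelSpec | None = None,
    fdr_level: float = DEFAULT_FDR_LEVEL,
    min_obs: int = DEFAULT_MIN_OBS,
    standardize: bool = False,
) -> tuple[list, list]:
    """Metabolite -> outcome models adjusted for exposure, FDR across the
    Step-2 survivors for this (fluid, outcome)."""
    candidates = list(candidates)
    unknown = set(candidates) - set(matrix.data.columns)
    if unknown:
        raise ValueError(f"candidate metabolites absent from matrix: {sorted(unknown)}")
    fluid = str(matrix.meta["fluid"].iloc[0]) if matrix.n_samples else "plasma"
    if spec_template is None:
        spec_template = ModelSpec(
            outcome=outcome,
            exposure_coding="numeric",
            family_intercept=(fluid != "csf"),
        )
    merged = prepare(merge_metabolites(cohort, matrix))
    results, skipped = [], []
    for met in candidates:
        sub = merged.dropna(subset=[met]).copy()
        if len(sub) < min_obs:
            skipped.append(met)
            continue
        sub["_met"] = (
            (sub[met] - sub[met].mean()) / sub[met].std(ddof=1) if standardize else sub[met]
        )
        fit = fit_lmm(sub, replace(spec_template, outcome=outcome, metabolite="_met"))
        row = fit.params.loc["_met"]
        results.append(
            AssociationResult(
                metabolite=met,
                fluid=fluid,
                outcome=outcome,
                beta=float(row["beta"]),
                se=float(row["se"]),
                ci_low=float(row["ci_low"]),
                ci_high=float(row["ci_high"]),
                p=float(row["p"]),
                n_obs=fit.n_obs,
            )
        )
    _attach_fdr(results, fdr_level)
    return results, skipped
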