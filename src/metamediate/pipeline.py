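"""End-to-end orchestration: data in, QC, Steps 1-4, reports out.

The stage order mirrors the screening cascade: QC -> total-effect model
selection (Step 1) -> exposure-metabolite screen (Step 2) -> metabolite-
outcome screen on Step-2 survivors (Step 3) -> mediation decomposition on
Step-3 survivors (Step 4). Survivor sets only narrow; an empty survivor
set ends the run cleanly with an explanatory report rather than an error.
Every stage's tables and decisions are serialized to the output directory
so each number in the final report traces to an artifact.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import mediation as med
from . import qc as qc_mod
from . import screening as scr
from .lmm import ModelSpec, serialize_fit
from .synthetic_data import (
    OUTCOMES,
    MetaboliteMatrix,
    SimConfig,
    generate_study,
    read_cohort,
)

logger = logging.getLogger("metamediate")

CATEGORICAL_VARS = ("sex", "race", "education", "smoking", "bmi_category")
CONTINUOUS_VARS = ("age", "cesd", "alcohol_weekly") + OUTCOMES

REQUIRED_COHORT_COLUMNS = (
    "family_id",
    "individual_id",
    "visit_index",
    "age",
    "sex",
    "race",
    "education",
    "cesd",
    "bmi_category",
    "alcohol_weekly",
    "smoking",
) + OUTCOMES


class SchemaError(ValueError):
    """Input table does not match the expected schema."""


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    Exactly one of ``simulate`` (with ``sim``) or ``phenotype_path`` (with
    at least one matrix path) must be active.
    """

    simulate: bool = False
    sim: SimConfig | None = None
    phenotype_path: str | None = None
    plasma_path: str | None = None
    plasma_meta_path: str | None = None
    csf_path: str | None = None
    csf_meta_path: str | None = None
    qc: qc_mod.QCConfig = field(default_factory=qc_mod.QCConfig)
    outcomes: tuple = OUTCOMES
    fdr_level: float = 0.05
    min_obs: int = 50
    max_visit: int = 6
    baseline_visit: int = 2
    standardize_metabolites: bool = False
    mc_reps: int = med.DEFAULT_MC_REPS
    alpha: float = 0.05
    seed: int = 0
    outdir: str = "metamediate_run"

    def __post_init__(self) -> None:
        if not 0 < self.fdr_level < 1:
            raise ValueError("fdr_level must be in (0, 1)")
        has_inputs = self.phenotype_path is not None
        if self.simulate == has_inputs:
            raise ValueError("exactly one of simulate or input paths must be active")
        if self.simulate and self.sim is None:
            self.sim = SimConfig()


def _round1(x: float) -> float:
    # banker's rounding to one decimal, as used for printed percentages
    return float(np.round(x, 1))


def descriptive_report(cohort: pd.DataFrame, baseline_visit: int = 2) -> pd.DataFrame:
    """Baseline descriptives: counts/percentages for categorical variables,
    mean/SD/median/min/max for continuous ones; one row per statistic."""
    base = cohort[cohort["visit_index"] == baseline_visit]
    rows = []
    n = len(base)
    rows.append({"variable": "n_individuals", "level": "", "value": float(n)})
    for var in CATEGORICAL_VARS:
        counts = base[var].value_counts(sort=False)
        for level, count in counts.items():
            rows.append(
                {
                    "variable": var,
                    "level": str(level),
                    "value": int(count),
                    "percent": _round1(100.0 * count / n) if n else np.nan,
                }
            )
    for var in CONTINUOUS_VARS:
        s = base[var].astype(float)
        for stat, val in (
            ("mean", s.mean()),
            ("sd", s.std(ddof=1)),
            ("median", s.median()),
            ("min", s.min()),
            ("max", s.max()),
        ):
            rows.append({"variable": var, "level": stat, "value": float(val)})
    return pd.DataFrame(rows)


def _check_schema(cohort: pd.DataFrame) -> None:
    missing = [c for c in REQUIRED_COHORT_COLUMNS if c not in cohort.columns]
    if missing:
        raise SchemaError(f"phenotype table is missing columns: {missing}")


def _load_inputs(config: RunConfig):
    matrices = {}
    if config.simulate:
        cohort, plasma, truth = generate_study(config.sim, fluid="plasma")
        matrices["plasma"] = plasma
        return cohort, matrices, truth
    cohort = read_cohort(config.phenotype_path)
    _check_schema(cohort)
    if config.plasma_path:
        matrices["plasma"] = MetaboliteMatrix.from_csv(
            config.plasma_path, config.plasma_meta_path
        )
    if config.csf_path:
        matrices["csf"] = MetaboliteMatrix.from_csv(config.csf_path, config.csf_meta_path)
    if not matrices:
        raise SchemaError("at least one metabolite matrix is required")
    return cohort, matrices, None


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full workflow; returns the artifact bundle and writes
    every stage's outputs under ``config.outdir``."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_path = outdir / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    artifacts: dict = {"outdir": str(outdir), "terminated_at": None}
    try:
        cohort, matrices, truth = _load_inputs(config)
        n_dropped = int((cohort["visit_index"] > config.max_visit).sum())
        if n_dropped:
            logger.info("dropping %d rows beyond visit %d", n_dropped, config.max_visit)
            cohort = cohort[cohort["visit_index"] <= config.max_visit]
        artifacts["cohort"] = cohort
        if truth is not None:
            truth.to_json(outdir / "truth.json")
        logger.info(
            "cohort: %d rows, %d individuals, seed %s",
            len(cohort),
            cohort["individual_id"].nunique(),
            config.seed,
        )

        descriptives = descriptive_report(cohort, config.baseline_visit)
        descriptives.to_csv(outdir / "descriptives.tsv", sep="\t", index=False)
        artifacts["descriptives"] = descriptives

        qcd = {}
        for fluid, matrix in matrices.items():
            clean, report = qc_mod.run_qc(matrix, config.qc)
            report.to_json(outdir / f"qc_report_{fluid}.json")
            clean.to_csv(
                outdir / f"matrix_{fluid}_qc.tsv", outdir / f"matrix_{fluid}_meta.tsv"
            )
            qcd[fluid] = clean
            artifacts[f"qc_report_{fluid}"] = report
            logger.info("QC %s: %s", fluid, report.summary().replace("\n", " | "))
        artifacts["qc_matrices"] = qcd

        # Step 1: total-effect model choice per outcome
        step1 = {}
        for outcome in config.outcomes:
            res = scr.step1_total_effect(cohort, outcome)
            step1[outcome] = res
            payload = {
                "selection": {
                    "choice": res.selection["choice"],
                    "aic_reduced": res.selection["aic_reduced"],
                    "aic_full": res.selection["aic_full"],
                },
                "reduced": serialize_fit(res.fit_reduced),
                "full": serialize_fit(res.fit_full),
            }
            with open(outdir / f"step1_{outcome}.json", "w") as fh:
                json.dump(payload, fh, indent=2)
            logger.info(
                "step1 %s: chose %s model", outcome, res.selection["choice"]
            )
        artifacts["step1"] = step1
        # Steps 2-4 reuse the covariate set chosen for the first outcome
        chosen_covs = step1[config.outcomes[0]].chosen_spec.covariates

        metadata = {
            "fdr_level": config.fdr_level,
            "fdr_families": {
                "step2": "within fluid across metabolites",
                "step3": "within (fluid, outcome) across step-2 survivors",
            },
            "exposure_coding": {"step1": "categorical", "steps2-4": "numeric (0/1/2)"},
            "chosen_covariates": list(chosen_covs),
            "mc_reps": config.mc_reps,
            "seed": config.seed,
            "min_obs": config.min_obs,
        }

        step2, step3, step4 = {}, {}, {}
        for fluid, matrix in qcd.items():
            spec2 = ModelSpec(
                outcome="_met",
                exposure_coding="numeric",
                covariates=chosen_covs,
                family_intercept=(fluid != "csf"),
            )
            results2, skipped2 = scr.step2_metabolite_screen(
                cohort,
                matrix,
                spec_template=spec2,
                fdr_level=config.fdr_level,
                min_obs=config.min_obs,
                standardize=config.standardize_metabolites,
            )
            scr.results_frame(results2).to_csv(
                outdir / f"step2_{fluid}.tsv", sep="\t", index=False
            )
            step2[fluid] = results2
            metadata[f"step2_{fluid}_skipped"] = skipped2
            survivors = [r.metabolite for r in results2 if r.passed]
            logger.info(
                "step2 %s: %d/%d passed FDR (%d skipped)",
                fluid,
                len(survivors),
                len(results2),
                len(skipped2),
            )
            if not survivors:
                artifacts["terminated_at"] = f"step2:{fluid}"
                continue

            for outcome in config.outcomes:
                spec3 = ModelSpec(
                    outcome=outcome,
                    exposure_coding="numeric",
                    covariates=chosen_covs,
                    family_intercept=(fluid != "csf"),
                )
                results3, skipped3 = scr.step3_outcome_screen(
                    cohort,
                    matrix,
                    survivors,
                    outcome,
                    spec_template=spec3,
                    fdr_level=config.fdr_level,
                    min_obs=config.min_obs,
                    standardize=config.standardize_metabolites,
                )
                scr.results_frame(results3).to_csv(
                    outdir / f"step3_{fluid}_{outcome}.tsv", sep="\t", index=False
                )
                step3[(fluid, outcome)] = results3
                finalists = [r.metabolite for r in results3 if r.passed]
                logger.info(
                    "step3 %s/%s: %d/%d passed FDR",
                    fluid,
                    outcome,
                    len(finalists),
                    len(results3),
                )
                if not finalists:
                    continue

                merged = scr.merge_metabolites(cohort, matrix)
                med_results = []
                for rank, metab in enumerate(finalists):
                    result = med.mediate(
                        merged,
                        metab,
                        outcome,
                        spec_template=ModelSpec(
                            outcome=outcome,
                            exposure_coding="numeric",
                            covariates=chosen_covs,
                            family_intercept=(fluid != "csf"),
                        ),
                        reps=config.mc_reps,
                        alpha=config.alpha,
                        seed=config.seed + rank,
                    )
                    med_results.append(result)
                step4[(fluid, outcome)] = med_results
                med.write_results(
                    med_results,
                    outdir / f"mediation_{fluid}_{outcome}.tsv",
                    outdir / f"mediation_{fluid}_{outcome}.json",
                )
                with open(outdir / f"paths_{fluid}_{outcome}.txt", "w") as fh:
                    fh.write("\n\n".join(r.path_diagram() for r in med_results))

        artifacts.update(step2=step2, step3=step3, step4=step4, metadata=metadata)
        if not any(
            r.passed for results in step3.values() for r in results
        ) and artifacts["terminated_at"] is None and step3:
            artifacts["terminated_at"] = "step3"
        with open(outdir / "run_metadata.json", "w") as fh:
            json.dump(metadata, fh, indent=2)
        if artifacts["terminated_at"]:
            with open(outdir / "termination.txt", "w") as fh:
                fh.write(
                    f"run ended at {artifacts['terminated_at']}: no metabolites "
                    "survived FDR gating; downstream stages were not run.\n"
                )
            logger.info("terminated at %s", artifacts["terminated_at"])
        return artifacts
    finally:
        logger.removeHandler(handler)
        handler.close()
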