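"""Product-method mediation decomposition with Monte-Carlo intervals.

The exposure -> outcome total effect c is decomposed into an indirect
effect IE = a*b carried by a metabolite (a: exposure -> metabolite slope;
b: metabolite -> outcome slope adjusted for exposure) and a direct effect
DE = c' (the exposure coefficient with the mediator in the model). On
single-level nested least-squares fits with a shared covariate set the
identity c = a*b + c' is exact; with mixed models a small additivity gap
remains and is recorded.

The 95% CI for a*b comes from the Monte-Carlo method: draw
a* ~ N(a, se_a^2) and b* ~ N(b, se_b^2) independently (the two paths come
from separate models, so the cross-path covariance is taken as zero) and
take empirical quantiles of a*b*. Proportion mediated is reported under
two denominators, IE/(IE+DE) (primary) and IE/c; it is undefined when IE
and DE disagree in sign (inconsistent mediation / suppression).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .lmm import LMMFit, ModelSpec, fit_lmm, prepare

DEFAULT_MC_REPS = 100_000


@dataclass
class MediationResult:
    """Path estimates and decomposition for one metabolite-outcome pair."""

    metabolite: str
    outcome: str
    a: float
    se_a: float
    b: float
    se_b: float
    c: float
    se_c: float
    c_prime: float
    se_c_prime: float
    de_p: float = np.nan
    ie_ci: tuple | None = None
    proportion_mediated: float | None = None
    proportion_mediated_total: float | None = None
    proportion_tag: str = ""
    classification: str = ""
    mc_reps: int = 0
    seed: int | None = None

    @property
    def ie(self) -> float:
        return self.a * self.b

    @property
    def de(self) -> float:
        return self.c_prime

    @property
    def additivity_gap(self) -> float:
        return abs(self.c - (self.ie + self.c_prime))

    def as_dict(self) -> dict:
        d = dict(
            metabolite=self.metabolite,
            outcome=self.outcome,
            a=self.a,
            se_a=self.se_a,
            b=self.b,
            se_b=self.se_b,
            c=self.c,
            se_c=self.se_c,
            c_prime=self.c_prime,
            se_c_prime=self.se_c_prime,
            de_p=self.de_p,
            ie=self.ie,
            de=self.de,
            additivity_gap=self.additivity_gap,
            ie_ci_low=self.ie_ci[0] if self.ie_ci else None,
            ie_ci_high=self.ie_ci[1] if self.ie_ci else None,
            proportion_mediated=self.proportion_mediated,
            proportion_mediated_total=self.proportion_mediated_total,
            proportion_tag=self.proportion_tag,
            classification=self.classification,
            mc_reps=self.mc_reps,
            seed=self.seed,
        )
        return d

    def path_diagram(self) -> str:
        """Plain-text path diagram: total effect, a/b paths, IE with CI,
        direct effect and the mediated proportions."""
        ci = (
            f"[{self.ie_ci[0]:.4g}, {self.ie_ci[1]:.4g}]" if self.ie_ci else "(no CI)"
        )
        prop = (
            f"{100 * self.proportion_mediated:.1f}% of IE+DE, "
            f"{100 * self.proportion_mediated_total:.1f}% of c"
            if self.proportion_mediated is not None
            and self.proportion_mediated_total is not None
            else f"undefined ({self.proportion_tag})"
        )
        return (
            f"{self.outcome} <- smoking, mediated by {self.metabolite}\n"
            f"  total effect      c  = {self.c:+.4f} (SE {self.se_c:.4f})\n"
            f"  smoking -> met    a  = {self.a:+.4f} (SE {self.se_a:.4f})\n"
            f"  met -> outcome    b  = {self.b:+.4f} (SE {self.se_b:.4f})\n"
            f"  indirect effect   IE = a*b = {self.ie:+.4f}, 95% CI {ci}\n"
            f"  direct effect     c' = {self.c_prime:+.4f} (SE {self.se_c_prime:.4f}, "
            f"p = {self.de_p:.3g})\n"
            f"  proportion mediated: {prop}\n"
            f"  classification: {self.classification}"
        )


def product_method(
    fit_a: LMMFit,
    fit_outcome: LMMFit,
    fit_total: LMMFit,
    exposure_term: str = "smoking_code",
    metabolite_term: str = "_met",
    metabolite: str = "",
) -> MediationResult:
    """Extract the a, b, c, c' paths from three fitted models.

    ``fit_a``: metabolite ~ exposure (+ covariates); ``fit_outcome``:
    outcome ~ exposure + metabolite (+ covariates); ``fit_total``:
    outcome ~ exposure (+ covariates). A missing coefficient raises a
    KeyError naming it.
    """
    a, se_a = fit_a.beta(exposure_term), fit_a.se(exposure_term)
    b, se_b = fit_outcome.beta(metabolite_term), fit_outcome.se(metabolite_term)
    c, se_c = fit_total.beta(exposure_term), fit_total.se(exposure_term)
    cp, se_cp = fit_outcome.beta(exposure_term), fit_outcome.se(exposure_term)
    result = MediationResult(
        metabolite=metabolite or (fit_a.spec.outcome if fit_a.spec.outcome != "_met" else ""),
        outcome=fit_total.spec.outcome,
        a=a,
        se_a=se_a,
        b=b,
        se_b=se_b,
        c=c,
        se_c=se_c,
        c_prime=cp,
        se_c_prime=se_cp,
        de_p=fit_outcome.pvalue(exposure_term),
    )
    prim, total, tag = proportion_mediated(result.ie, result.de, result.c)
    result.proportion_mediated = prim
    result.proportion_mediated_total = total
    result.proportion_tag = tag
    return result


def monte_carlo_ci(
    a: float,
    se_a: float,
    b: float,
    se_b: float,
    reps: int = DEFAULT_MC_REPS,
    alpha: float = 0.05,
    seed: int | np.random.Generator = 0,
) -> tuple:
    """Monte-Carlo confidence interval for the product a*b.

    Empirical (alpha/2, 1-alpha/2) quantiles of a* b* with
    a* ~ N(a, se_a^2), b* ~ N(b, se_b^2) drawn independently.
    Deterministic given the seed.
    """
    if se_a < 0 or se_b < 0:
        raise ValueError("standard errors must be nonnegative")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if reps < 1:
        raise ValueError("reps must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    prod = rng.normal(a, se_a, reps) * rng.normal(b, se_b, reps)
    low, high = np.quantile(prod, [alpha / 2.0, 1.0 - alpha / 2.0])
    return (float(low), float(high))


def proportion_mediated(ie: float, de: float, c: float | None = None):
    """Mediated proportions of the exposure -> outcome effect.

    Returns ``(primary, total, tag)`` where primary = IE/(IE+DE) and
    total = IE/c (None if c is not supplied or zero). Undefined (None,
    None, reason) when IE and DE have opposite signs or the denominator
    vanishes; exactly zero when IE = 0 and DE != 0.
    """
    if ie == 0.0 and de != 0.0:
        return 0.0, (0.0 if c else None), "zero indirect effect"
    if ie + de == 0.0:
        return None, None, "zero denominator"
    if np.sign(ie) != np.sign(de):
        return None, None, "inconsistent (IE and DE have different signs)"
    primary = ie / (ie + de)
    total = ie / c if c not in (None, 0.0) else None
    return primary, total, "consistent"


def classify_mediation(result: MediationResult, de_p: float | None = None, ie_ci=None) -> str:
    """Classify the mediation pattern from the IE interval and the direct
    effect: none (CI spans 0), inconsistent (CI excludes 0, signs of IE
    and DE differ), complete (CI excludes 0, DE not significant), else
    partial."""
    ci = ie_ci if ie_ci is not None else result.ie_ci
    if ci is None:
        raise ValueError("confidence interval not attached")
    p = de_p if de_p is not None else result.de_p
    low, high = ci
    if low <= 0.0 <= high:
        return "none"
    if result.de != 0.0 and np.sign(result.ie) != np.sign(result.de):
        return "inconsistent"
    if p >= 0.05:
        return "complete"
    return "partial"


def attach_ci_and_classify(
    result: MediationResult,
    reps: int = DEFAULT_MC_REPS,
    alpha: float = 0.05,
    seed: int = 0,
) -> MediationResult:
    result.ie_ci = monte_carlo_ci(
        result.a, result.se_a, result.b, result.se_b, reps=reps, alpha=alpha, seed=seed
    )
    result.mc_reps = reps
    result.seed = seed
    result.classification = classify_mediation(result)
    return result


def mediate(
    data: pd.DataFrame,
    metabolite: str,
    outcome: str,
    spec_template: ModelSpec | None = None,
    reps: int = DEFAULT_MC_REPS,
    alpha: float = 0.05,
    seed: int = 0,
) -> MediationResult:
    """Full Step-4 decomposition for one metabolite-outcome pair.

    ``data`` is a merged cohort-metabolite table; the three models (a
    path, outcome model, total-effect model) are fitted on the
    complete-case rows for the metabolite, all with numeric exposure
    coding, then the decomposition, Monte-Carlo CI and classification
    are attached.
    """
    if spec_template is None:
        spec_template = ModelSpec(outcome=outcome, exposure_coding="numeric")
    spec_template = replace(spec_template, exposure_coding="numeric", metabolite=None)
    sub = prepare(data).dropna(subset=[metabolite]).copy()
    sub["_met"] = sub[metabolite]
    fit_a = fit_lmm(sub, replace(spec_template, outcome="_met"))
    fit_out = fit_lmm(sub, replace(spec_template, outcome=outcome, metabolite="_met"))
    fit_tot = fit_lmm(sub, replace(spec_template, outcome=outcome))
    result = product_method(fit_a, fit_out, fit_tot, metabolite=metabolite)
    return attach_ci_and_classify(result, reps=reps, alpha=alpha, seed=seed)


def write_results(results, tsv_path, json_path=None) -> None:
    frame = pd.DataFrame([r.as_dict() for r in results])
    frame.to_csv(tsv_path, sep="\t", index=False)
    if json_path is not None:
        with open(json_path, "w") as fh:
            json.dump([r.as_dict() for r in results], fh, indent=2, default=float)
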