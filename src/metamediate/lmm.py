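"""Linear mixed models for the clustered longitudinal cohort.

Models have the form

    y ~ exposure + sex + race + education + practice + age_c + age_c^2
        [+ CES-D + BMI + alcohol] [+ metabolite]
        + (1 | family) + (1 | individual) + (age_c | individual) + eps

with individuals nested within families. Fitting is by REML through
statsmodels MixedLM; the nested individual intercept and the individual
age slope enter as variance components (one variance each, slope and
intercept independent — the covariance mode is recorded on the fit).
Models with CSF metabolites drop the family intercept, since very few CSF
donors are related. Wald z statistics give coefficient SEs, confidence
intervals and p-values. With all random structure disabled the same
surface fits ordinary least squares.

The nested individual intercept uses within-family slot coding (each
individual's index within its sibship), which keeps the variance-component
design at ``max sibship size`` columns instead of one per individual.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.linalg
import statsmodels.formula.api as smf

COVARIATES_REDUCED = ("sex", "race", "education", "practice", "age", "age2")
COVARIATES_FULL = COVARIATES_REDUCED + ("cesd", "bmi", "alcohol")

_TERM_FORMULAS = {
    "sex": "C(sex, Treatment('M'))",
    "race": "C(race, Treatment('other'))",
    "education": "education",
    "practice": "practice",
    "age": "age_c",
    "age2": "age_c2",
    "cesd": "cesd",
    "bmi": "C(bmi_category, Treatment('normal'))",
    "alcohol": "alcohol_weekly",
}


class RankDeficientError(ValueError):
    """Fixed-effects design is collinear; names the offending columns."""


@dataclass(frozen=True)
class ModelSpec:
    """Specification of one mixed model.

    ``covariates`` is a tuple of term names drawn from
    ``COVARIATES_FULL``; ``exposure_coding`` selects categorical smoking
    (separate former/current coefficients, reference = never) or the
    numeric 0/1/2 coding used on the mediation path diagram. A
    ``metabolite`` column name adds the mediator term. Random structure
    toggles: family intercept, individual intercept, individual age
    slope.
    """

    outcome: str
    exposure_coding: str = "categorical"
    include_exposure: bool = True
    covariates: Sequence[str] = COVARIATES_FULL
    metabolite: str | None = None
    family_intercept: bool = True
    individual_intercept: bool = True
    age_slope: bool = True

    def __post_init__(self) -> None:
        if self.exposure_coding not in ("categorical", "numeric"):
            raise ValueError("exposure_coding must be 'categorical' or 'numeric'")
        unknown = set(self.covariates) - set(COVARIATES_FULL)
        if unknown:
            raise ValueError(f"unknown covariate terms: {sorted(unknown)}")

    @property
    def has_random(self) -> bool:
        return self.family_intercept or self.individual_intercept or self.age_slope

    def fixed_formula(self, data: pd.DataFrame | None = None) -> str:
        def categorical(col: str, ref: str) -> str | None:
            # degrade gracefully on subsets missing levels: a single observed
            # level is a constant (dropped); a missing reference level falls
            # back to patsy's default coding
            if data is None:
                return f"C({col}, Treatment('{ref}'))"
            levels = data[col].dropna().unique()
            if len(levels) < 2:
                return None
            if ref not in set(map(str, levels)):
                return f"C({col})"
            return f"C({col}, Treatment('{ref}'))"

        cat_refs = {"sex": "M", "race": "other", "bmi": "normal"}
        cat_cols = {"sex": "sex", "race": "race", "bmi": "bmi_category"}
        terms = []
        if self.include_exposure:
            if self.exposure_coding == "categorical":
                terms.append(categorical("smoking", "never"))
            else:
                terms.append("smoking_code")
        for t in self.covariates:
            if t in cat_refs:
                terms.append(categorical(cat_cols[t], cat_refs[t]))
            else:
                terms.append(_TERM_FORMULAS[t])
        if self.metabolite is not None:
            terms.append(self.metabolite)
        terms = [t for t in terms if t is not None]
        rhs = " + ".join(terms) if terms else "1"
        return f"{self.outcome} ~ {rhs}"

    def exposure_terms(self) -> list:
        if self.exposure_coding == "numeric":
            return ["smoking_code"]
        return [
            "C(smoking, Treatment('never'))[T.former]",
            "C(smoking, Treatment('never'))[T.current]",
        ]


@dataclass
class LMMFit:
    """A fitted model: coefficient table, variance components, summaries."""

    spec: ModelSpec
    params: pd.DataFrame  # beta, se, ci_low, ci_high, p per term
    variance_components: dict
    loglike: float
    n_obs: int
    n_individuals: int
    n_families: int
    converged: bool
    method: str  # "reml", "ml" or "ols"
    cov_mode: str  # slope-intercept covariance handling
    var_fixed: float
    mean_age_c2: float
    n_params: int
    _data: pd.DataFrame | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        for name, v in self.variance_components.items():
            if v < -1e-10:
                raise ValueError(f"negative variance component {name}: {v}")

    def beta(self, term: str) -> float:
        if term not in self.params.index:
            raise KeyError(
                f"coefficient {term!r} absent from fit of {self.spec.outcome!r}; "
                f"available: {list(self.params.index)}"
            )
        return float(self.params.loc[term, "beta"])

    def se(self, term: str) -> float:
        if term not in self.params.index:
            raise KeyError(f"coefficient {term!r} absent from fit")
        return float(self.params.loc[term, "se"])

    def pvalue(self, term: str) -> float:
        return float(self.params.loc[term, "p"])

    @property
    def icc(self) -> float:
        return icc(self)

    @property
    def r2(self) -> tuple:
        return r2_nakagawa(self)

    @property
    def aic(self) -> float:
        if self.method == "reml":
            raise ValueError("AIC requires a maximum-likelihood fit (method='ml' or 'ols')")
        return -2.0 * self.loglike + 2.0 * self.n_params

    def to_frame(self) -> pd.DataFrame:
        return self.params.copy()


def prepare(data: pd.DataFrame, outcome: str | None = None) -> pd.DataFrame:
    """Add the derived model columns: centered age (to the realized sample
    mean), its square, the practice term (visit - 2), and the within-family
    individual slot used by the nested variance component."""
    df = data.copy()
    df["age_c"] = df["age"] - df["age"].mean()
    df["age_c2"] = df["age_c"] ** 2
    if "visit_index" in df:
        df["practice"] = df["visit_index"] - 2
    elif "practice" not in df:
        df["practice"] = 0
    if "smoking_code" not in df and "smoking" in df:
        codes = pd.Categorical(
            df["smoking"], categories=["never", "former", "current"]
        ).codes
        df["smoking_code"] = codes
    # plain strings so the design matrix only carries observed levels
    for col in ("smoking", "bmi_category", "sex", "race"):
        if col in df:
            df[col] = df[col].astype(str)
    if "family_id" in df:
        # within-family slot index per individual (any bijection works)
        pairs = df[["family_id", "individual_id"]].drop_duplicates()
        pairs = pairs.assign(ind_slot=pairs.groupby("family_id").cumcount())
        df = df.merge(pairs, on=["family_id", "individual_id"], how="left")
    else:
        df["ind_slot"] = 0
    return df


def _check_rank(exog: pd.DataFrame) -> None:
    x = np.asarray(exog, dtype=float)
    rank = np.linalg.matrix_rank(x)
    if rank < x.shape[1]:
        _, _, piv = scipy.linalg.qr(x, mode="economic", pivoting=True)
        bad = sorted(exog.columns[i] for i in piv[rank:])
        raise RankDeficientError(f"collinear fixed-effect terms: {bad}")


def fit_lmm(
    data: pd.DataFrame, spec: ModelSpec, reml: bool = True, polish: bool = False
) -> LMMFit:
    """Fit ``spec`` to ``data`` (REML by default; ML for model comparison).

    ``data`` is a long cohort table (possibly merged with metabolite
    values); derived columns are added by :func:`prepare` if absent. With
    all random structure disabled this reduces to OLS on the same design.
    ``polish=True`` adds a derivative-free refinement pass from the
    first-stage optimum for high-precision variance components.
    """
    if "age_c" not in data or "ind_slot" not in data:
        data = prepare(data)
    needed = [spec.outcome, "age_c"]
    if spec.metabolite:
        needed.append(spec.metabolite)
    data = data.dropna(subset=[c for c in needed if c in data.columns])
    if data["individual_id"].nunique() < 2:
        raise ValueError("need at least 2 individuals to fit")

    formula = spec.fixed_formula(data)
    n_ind = data["individual_id"].nunique()
    n_fam = data["family_id"].nunique() if "family_id" in data else n_ind

    if not spec.has_random:
        model = smf.ols(formula, data=data)
        _check_rank(pd.DataFrame(model.exog, columns=model.exog_names))
        res = model.fit()
        ci = res.conf_int()
        params = pd.DataFrame(
            {
                "beta": res.params,
                "se": res.bse,
                "ci_low": ci[0],
                "ci_high": ci[1],
                "p": res.pvalues,
            }
        )
        vc = {"family": 0.0, "individual": 0.0, "age_slope": 0.0, "residual": float(res.scale)}
        fitted_fixed = np.asarray(res.fittedvalues)
        return LMMFit(
            spec=spec,
            params=params,
            variance_components=vc,
            loglike=float(res.llf),
            n_obs=int(res.nobs),
            n_individuals=n_ind,
            n_families=n_fam,
            converged=True,
            method="ols",
            cov_mode="none",
            var_fixed=float(np.var(fitted_fixed)),
            mean_age_c2=float(np.mean(data["age_c"] ** 2)),
            n_params=len(res.params) + 1,
            _data=data,
        )

    # random structure: groups = coarsest active level; the group random
    # intercept comes from re_formula, finer levels enter as variance
    # components (slot coding keeps the vc design narrow)
    vc_formula = {}
    slope_in_re = False
    if spec.family_intercept:
        groups = "family_id"
        re_formula = "1"
        if spec.individual_intercept:
            vc_formula["individual"] = "0 + C(ind_slot)"
        if spec.age_slope:
            vc_formula["age_slope"] = "0 + C(ind_slot):age_c"
    else:
        groups = "individual_id"
        if spec.individual_intercept:
            re_formula = "1"
            if spec.age_slope:
                vc_formula["age_slope"] = "0 + age_c"
        else:
            re_formula = "0 + age_c"  # slope-only model
            slope_in_re = True

    model = smf.mixedlm(
        formula,
        data=data,
        groups=data[groups],
        re_formula=re_formula,
        vc_formula=vc_formula or None,
    )
    _check_rank(pd.DataFrame(model.exog, columns=model.exog_names))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit(reml=reml, method=["lbfgs", "cg"], maxiter=200)
        if polish:
            res = model.fit(
                reml=reml, method="powell", maxiter=5000, start_params=res.params_object
            )
    converged = bool(res.converged)

    k_fe = model.k_fe
    fe = res.params.iloc[:k_fe]
    bse = res.bse.iloc[:k_fe]
    z975 = 1.959963984540054
    params = pd.DataFrame(
        {
            "beta": fe,
            "se": bse,
            "ci_low": fe - z975 * bse,
            "ci_high": fe + z975 * bse,
            "p": res.pvalues.iloc[:k_fe],
        }
    )

    vc = {"family": 0.0, "individual": 0.0, "age_slope": 0.0, "residual": float(res.scale)}
    group_var = max(float(np.asarray(res.cov_re)[0, 0]), 0.0)
    if slope_in_re:
        vc["age_slope"] = group_var
    elif spec.family_intercept:
        vc["family"] = group_var
    else:
        vc["individual"] = group_var
    if vc_formula:
        for name, value in zip(model.exog_vc.names, np.atleast_1d(res.vcomp)):
            key = "individual" if name == "individual" else "age_slope"
            vc[key] = max(float(value), 0.0)

    fitted_fixed = model.exog @ fe.to_numpy()
    n_vc = len(vc_formula) + 1  # + the group-level random term
    return LMMFit(
        spec=spec,
        params=params,
        variance_components=vc,
        loglike=float(res.llf),
        n_obs=int(model.nobs),
        n_individuals=n_ind,
        n_families=n_fam,
        converged=converged,
        method="reml" if reml else "ml",
        cov_mode="independent",
        var_fixed=float(np.var(fitted_fixed)),
        mean_age_c2=float(np.mean(data["age_c"] ** 2)),
        n_params=k_fe + n_vc + 1,
        _data=data,
    )


def icc(fit: LMMFit) -> float:
    """Intraclass correlation: the share of outcome variance attributable
    to the random intercepts (family + individual); the age-slope variance
    is excluded."""
    vc = fit.variance_components
    intercepts = vc["family"] + vc["individual"]
    denom = intercepts + vc["residual"]
    if denom == 0:
        return 0.0
    val = intercepts / denom
    if not 0.0 <= val <= 1.0:
        raise ValueError(f"ICC out of [0, 1]: {val}")
    return val


def r2_nakagawa(fit: LMMFit, data=None, spec=None) -> tuple:
    """Marginal and conditional R² for a mixed model.

    Marginal R² is the variance explained by fixed effects alone;
    conditional R² adds the random-effect variances. The random age
    slope contributes its variance scaled by the mean squared centered
    age. Returns ``(marginal, conditional)``.
    """
    vc = fit.variance_components
    var_random = (
        vc["family"] + vc["individual"] + vc["age_slope"] * fit.mean_age_c2
    )
    total = fit.var_fixed + var_random + vc["residual"]
    if total == 0:
        return (1.0, 1.0)
    marginal = fit.var_fixed / total
    conditional = (fit.var_fixed + var_random) / total
    if marginal > conditional + 1e-12:
        raise ValueError("marginal R^2 exceeded conditional R^2")
    return (marginal, conditional)


def compare_fits(fit_reduced: LMMFit, fit_full: LMMFit) -> dict:
    """Select between nested fixed-effect structures by ML-based AIC.

    REML likelihoods are not comparable across fixed structures, so REML
    fits are refit by maximum likelihood before comparison. Ties select
    the reduced model (parsimony). Returns the choice and both criterion
    values.
    """
    if fit_reduced.spec.outcome != fit_full.spec.outcome:
        raise ValueError("fits compare different outcomes")
    if fit_reduced.n_obs != fit_full.n_obs:
        raise ValueError(
            f"fits use different observation sets "
            f"({fit_reduced.n_obs} vs {fit_full.n_obs} rows)"
        )

    def _ml_aic(fit: LMMFit) -> float:
        if fit.method != "reml":
            return fit.aic
        refit = fit_lmm(fit._data, fit.spec, reml=False)
        return refit.aic

    aic_reduced, aic_full = _ml_aic(fit_reduced), _ml_aic(fit_full)
    choice = "full" if aic_full < aic_reduced - 1e-9 else "reduced"
    return {
        "choice": choice,
        "aic_reduced": aic_reduced,
        "aic_full": aic_full,
        "chosen_fit": fit_full if choice == "full" else fit_reduced,
        "chosen_spec": (fit_full if choice == "full" else fit_reduced).spec,
    }


def serialize_fit(fit: LMMFit) -> dict:
    marginal, conditional = fit.r2
    return {
        "outcome": fit.spec.outcome,
        "coefficients": {
            term: {
                "beta": float(row["beta"]),
                "se": float(row["se"]),
                "ci_low": float(row["ci_low"]),
                "ci_high": float(row["ci_high"]),
                "p": float(row["p"]),
            }
            for term, row in fit.params.iterrows()
        },
        "variance_components": {k: float(v) for k, v in fit.variance_components.items()},
        "icc": fit.icc,
        "r2_marginal": marginal,
        "r2_conditional": conditional,
        "n_observations": fit.n_obs,
        "n_individuals": fit.n_individuals,
        "n_families": fit.n_families,
        "converged": fit.converged,
        "method": fit.method,
        "slope_intercept_covariance": fit.cov_mode,
    }
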