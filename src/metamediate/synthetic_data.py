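"""Synthetic multilevel cohort and metabolome generator.

Emulates a longitudinal aging cohort in which individuals are nested within
sibships (families), attend 1-6 roughly biennial study visits, and carry a
three-level smoking exposure (never/former/current). Cognitive outcomes are
generated from a linear mixed model with family and individual random
intercepts, an individual random age slope, fixed covariate effects, a
practice effect, linear and quadratic age terms, and optional metabolite
mediator terms. Metabolite abundances are log-normal with planted
exposure effects, so the ground-truth mediation structure (a and b paths,
indirect and direct effects, suppressors) is known exactly and every
downstream screening stage is testable without restricted cohort data.

Smoking enters the generative model numerically as never=0, former=1,
current=2.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

OUTCOMES = ("PACC3", "IMM", "DEL", "EXE")

SMOKING_LEVELS = ("never", "former", "current")
SMOKING_CODE = {"never": 0, "former": 1, "current": 2}

BMI_LEVELS = ("underweight", "normal", "overweight", "obese")

#: Baseline covariate distributions (cohort Table-1-style defaults):
#: age ~ N(58.5, 6.47^2) truncated to [40.7, 75.0]; 70.4% female; 94.8%
#: white; 61.4% with a college degree; CES-D and weekly alcohol are
#: right-skewed and drawn from gammas matched to mean/SD.
DEFAULT_COVARIATE_PARAMS: dict = {
    "age_mean": 58.5,
    "age_sd": 6.47,
    "age_range": (40.7, 75.0),
    "p_female": 0.704,
    "p_white": 0.948,
    "p_college": 0.614,
    "cesd_mean": 7.13,
    "cesd_sd": 7.16,
    "cesd_max": 60.0,
    "alcohol_mean": 4.25,
    "alcohol_sd": 6.74,
    "alcohol_max": 52.5,
    "bmi_probs": (0.006, 0.278, 0.355, 0.361),
}

#: Fixed effects of the covariates on every cognitive composite
#: (full-model scale; reference categories: male, non-white, no degree,
#: normal BMI, never smoker).
DEFAULT_COVARIATE_EFFECTS: dict = {
    "intercept": -1.0,
    "female": 0.50,
    "white": 0.40,
    "college": 0.37,
    "cesd": -0.005,
    "bmi_underweight": -0.20,
    "bmi_overweight": 0.005,
    "bmi_obese": 0.03,
    "alcohol": 0.005,
}

#: Sibship-size distribution averaging ~1.26 individuals per family
#: (about 1007 families per 1266 individuals).
DEFAULT_FAMILY_SIZES: dict = {1: 0.78, 2: 0.18, 3: 0.04}

#: Visit-count distribution over 1..6 averaging ~3.7 visits.
DEFAULT_VISIT_COUNTS: dict = {1: 0.06, 2: 0.12, 3: 0.22, 4: 0.33, 5: 0.17, 6: 0.10}

#: Variance components giving an intraclass correlation of ~0.78.
DEFAULT_VARIANCE_COMPONENTS: dict = {
    "family": 0.08,
    "individual": 0.25,
    "age_slope": 0.0004,
    "residual": 0.09,
}


class ConfigurationError(ValueError):
    """Raised when a simulation configuration field is invalid."""


@dataclass(frozen=True)
class MediatorSpec:
    """A planted mediator: metabolite ``index`` with exposure->metabolite
    slope ``a`` (per unit numeric smoking, on the log10-abundance scale)
    and metabolite->outcome slope ``b`` (outcome units per log10 unit)."""

    index: int
    a: float
    b: float


@dataclass
class SimConfig:
    """Configuration of the synthetic study.

    Attributes
    ----------
    n_families : int
        Number of sibships.
    individuals_per_family : mapping size -> probability.
    n_visits : int or mapping count -> probability (counts within 1..6).
    visit_spacing_years : mean gap between consecutive visits.
    smoking_probs : probabilities of (never, former, current).
    covariate_params : distribution parameters for baseline covariates.
    covariate_effects : fixed effects of covariates on the composites.
    n_metabolites : number of metabolites in the generated matrix.
    mediator_spec : planted (index, a, b) triples; indices are distinct.
    direct_effect : direct (c') effect of numeric smoking on each
        composite, either a scalar applied to all four or a per-outcome
        mapping.
    variance_components : family/individual/age_slope/residual variances.
    practice_effect : per-visit fixed increment to the composites.
    age_coefs : (linear, quadratic) fixed age effects; age is centered to
        the realized sample mean before squaring.
    metabolite_noise : individual- and sample-level SDs of the latent
        log10 abundances.
    missingness_spec : metabolite index -> missing fraction (completely at
        random by default).
    missing_low_abundance : if True, missingness preferentially removes
        low-abundance measurements instead of being random (stress mode
        for QC).
    smoking_transitions : if True, current smokers may quit between
        visits (never->former transitions are not generated); default is
        a time-constant exposure.
    seed : integer seed; identical configs produce identical tables.
    """

    n_families: int = 1007
    individuals_per_family: Mapping[int, float] = field(
        default_factory=lambda: dict(DEFAULT_FAMILY_SIZES)
    )
    n_visits: int | Mapping[int, float] = field(
        default_factory=lambda: dict(DEFAULT_VISIT_COUNTS)
    )
    visit_spacing_years: float = 2.0
    smoking_probs: Sequence[float] = (0.562, 0.370, 0.068)
    covariate_params: Mapping[str, object] = field(
        default_factory=lambda: dict(DEFAULT_COVARIATE_PARAMS)
    )
    covariate_effects: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_COVARIATE_EFFECTS)
    )
    n_metabolites: int = 50
    mediator_spec: Sequence[MediatorSpec | tuple] = ()
    direct_effect: float | Mapping[str, float] = -0.08
    variance_components: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_VARIANCE_COMPONENTS)
    )
    practice_effect: float = 0.10
    age_coefs: tuple = (-0.047, -0.001)
    metabolite_noise: Mapping[str, float] = field(
        default_factory=lambda: {"individual": 0.5, "sample": 0.2}
    )
    metabolite_baseline_mean: float = 5.0
    metabolite_baseline_sd: float = 1.0
    missingness_spec: Mapping[int, float] = field(default_factory=dict)
    missing_low_abundance: bool = False
    smoking_transitions: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        self.mediator_spec = tuple(
            m if isinstance(m, MediatorSpec) else MediatorSpec(*m)
            for m in self.mediator_spec
        )
        self.validate()

    def validate(self) -> None:
        if self.n_families < 1:
            raise ConfigurationError("n_families must be >= 1")
        if abs(sum(self.smoking_probs) - 1.0) > 1e-8 or len(self.smoking_probs) != 3:
            raise ConfigurationError("smoking_probs must be 3 probabilities summing to 1")
        if any(p < 0 for p in self.smoking_probs):
            raise ConfigurationError("smoking_probs must be nonnegative")
        for name, v in self.variance_components.items():
            if v < 0:
                raise ConfigurationError(f"variance_components[{name!r}] must be >= 0")
        if isinstance(self.n_visits, Mapping):
            if abs(sum(self.n_visits.values()) - 1.0) > 1e-8:
                raise ConfigurationError("n_visits probabilities must sum to 1")
            if any(k < 1 for k in self.n_visits):
                raise ConfigurationError("n_visits counts must be >= 1")
        elif self.n_visits < 1:
            raise ConfigurationError("n_visits must be >= 1")
        if abs(sum(self.individuals_per_family.values()) - 1.0) > 1e-8:
            raise ConfigurationError("individuals_per_family probabilities must sum to 1")
        if self.n_metabolites < 0:
            raise ConfigurationError("n_metabolites must be >= 0")
        idx = [m.index for m in self.mediator_spec]
        if len(set(idx)) != len(idx):
            raise ConfigurationError("mediator_spec indices must be distinct")
        if any(i < 0 or i >= self.n_metabolites for i in idx):
            raise ConfigurationError("mediator_spec index out of range of n_metabolites")
        for i, frac in self.missingness_spec.items():
            if not 0 <= frac <= 1:
                raise ConfigurationError(f"missingness_spec[{i}] must be in [0, 1]")
        if self.visit_spacing_years <= 0:
            raise ConfigurationError("visit_spacing_years must be positive")

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimConfig":
        d = dict(d)
        if "mediator_spec" in d:
            d["mediator_spec"] = [
                MediatorSpec(**m) if isinstance(m, Mapping) else MediatorSpec(*m)
                for m in d["mediator_spec"]
            ]
        for key in ("individuals_per_family", "n_visits", "missingness_spec"):
            if key in d and isinstance(d[key], Mapping):
                d[key] = {int(k): v for k, v in d[key].items()}
        return cls(**d)

    @classmethod
    def from_file(cls, path) -> "SimConfig":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass
class TruthRecord:
    """Ground truth of the planted mediation structure.

    ``a``, ``b`` and ``ie`` (= a*b) are per-metabolite arrays; ``de`` is
    the direct effect per outcome; ``roles`` labels each metabolite as
    mediator / suppressor / null_a / null_b / noise. A suppressor has
    sign(a*b) opposite to sign(de); this is asserted at construction.
    """

    a: np.ndarray
    b: np.ndarray
    de: Mapping[str, float]
    roles: list

    def __post_init__(self) -> None:
        self.a = np.asarray(self.a, dtype=float)
        self.b = np.asarray(self.b, dtype=float)
        for j, role in enumerate(self.roles):
            if role == "suppressor":
                for out, de in self.de.items():
                    if de != 0 and np.sign(self.a[j] * self.b[j]) == np.sign(de):
                        raise ValueError(
                            f"metabolite {j} labelled suppressor but sign(a*b) == "
                            f"sign(direct effect) for outcome {out}"
                        )
            if role == "null_a" and self.a[j] != 0:
                raise ValueError(f"null_a metabolite {j} has a != 0")
            if role == "null_b" and self.b[j] != 0:
                raise ValueError(f"null_b metabolite {j} has b != 0")

    @property
    def ie(self) -> np.ndarray:
        return self.a * self.b

    def to_json(self, path) -> None:
        payload = {
            "a": self.a.tolist(),
            "b": self.b.tolist(),
            "ie": self.ie.tolist(),
            "de": dict(self.de),
            "roles": list(self.roles),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


@dataclass
class MetaboliteMatrix:
    """Sample x metabolite abundance matrix with sample metadata.

    ``data`` holds strictly positive abundances (NaN = missing) indexed by
    sample_id; ``meta`` maps each sample_id to (individual_id, age,
    fluid). After QC the values are log10 abundances and ``log_scale``
    is True.
    """

    data: pd.DataFrame
    meta: pd.DataFrame
    log_scale: bool = False

    def __post_init__(self) -> None:
        if not self.data.index.equals(self.meta.index):
            raise ValueError("data and meta must share the same sample index")
        dup = self.meta.index.duplicated()
        if dup.any():
            raise ValueError(f"duplicate sample ids: {list(self.meta.index[dup])}")

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_metabolites(self) -> int:
        return self.data.shape[1]

    def copy(self) -> "MetaboliteMatrix":
        return MetaboliteMatrix(self.data.copy(), self.meta.copy(), self.log_scale)

    def to_csv(self, data_path, meta_path) -> None:
        self.data.to_csv(data_path, sep="\t")
        self.meta.to_csv(meta_path, sep="\t")

    @classmethod
    def from_csv(cls, data_path, meta_path, log_scale: bool = False) -> "MetaboliteMatrix":
        data = pd.read_csv(data_path, sep="\t", index_col=0)
        meta = pd.read_csv(meta_path, sep="\t", index_col=0)
        return cls(data, meta.loc[data.index], log_scale)


def _truncated_normal(rng, mean, sd, low, high, size):
    out = np.empty(size)
    remaining = np.arange(size)
    while remaining.size:
        draw = rng.normal(mean, sd, remaining.size)
        ok = (draw >= low) & (draw <= high)
        out[remaining[ok]] = draw[ok]
        remaining = remaining[~ok]
    return out


def _gamma_from_moments(rng, mean, sd, upper, size):
    # right-skewed nonnegative draws matched to the target mean/SD
    shape = (mean / sd) ** 2
    scale = sd**2 / mean
    return np.clip(rng.gamma(shape, scale, size), 0.0, upper)


def _draw_counts(rng, spec, size):
    if isinstance(spec, Mapping):
        keys = np.array(sorted(spec))
        probs = np.array([spec[k] for k in keys], dtype=float)
        return rng.choice(keys, size=size, p=probs / probs.sum())
    return np.full(size, int(spec))


def _build_truth(config: SimConfig) -> TruthRecord:
    a = np.zeros(config.n_metabolites)
    b = np.zeros(config.n_metabolites)
    if isinstance(config.direct_effect, Mapping):
        de = {o: float(config.direct_effect.get(o, 0.0)) for o in OUTCOMES}
    else:
        de = {o: float(config.direct_effect) for o in OUTCOMES}
    roles = ["noise"] * config.n_metabolites
    de_sign = np.sign(next(iter(de.values())) if de else 0.0)
    for m in config.mediator_spec:
        a[m.index], b[m.index] = m.a, m.b
        if m.a == 0.0 and m.b == 0.0:
            roles[m.index] = "noise"
        elif m.a == 0.0:
            roles[m.index] = "null_a"
        elif m.b == 0.0:
            roles[m.index] = "null_b"
        elif de_sign != 0 and np.sign(m.a * m.b) != de_sign:
            roles[m.index] = "suppressor"
        else:
            roles[m.index] = "mediator"
    return TruthRecord(a=a, b=b, de=de, roles=roles)


def _spawn(config: SimConfig):
    """Independent child streams for the cohort and metabolome stages so the
    two public generators can be called separately yet stay mutually
    consistent (the joint-generation contract)."""
    root = np.random.SeedSequence(config.seed)
    cohort_ss, metab_ss, miss_ss = root.spawn(3)
    return (
        np.random.default_rng(cohort_ss),
        np.random.default_rng(metab_ss),
        np.random.default_rng(miss_ss),
    )


def _generate_structure(config: SimConfig, rng) -> pd.DataFrame:
    """Family/individual/visit skeleton with covariates and smoking."""
    cp = config.covariate_params
    fam_sizes = _draw_counts(rng, config.individuals_per_family, config.n_families)
    family_id = np.repeat(np.arange(config.n_families), fam_sizes)
    n_ind = family_id.size
    individual_id = np.arange(n_ind)

    n_visits = _draw_counts(rng, config.n_visits, n_ind)
    age0 = _truncated_normal(
        rng, cp["age_mean"], cp["age_sd"], cp["age_range"][0], cp["age_range"][1], n_ind
    )
    female = rng.random(n_ind) < cp["p_female"]
    white = rng.random(n_ind) < cp["p_white"]
    college = rng.random(n_ind) < cp["p_college"]
    smoking0 = rng.choice(3, size=n_ind, p=np.asarray(config.smoking_probs))

    rows = []
    for i in range(n_ind):
        # strictly increasing ages: positive jittered biennial gaps
        gaps = np.maximum(
            rng.normal(config.visit_spacing_years, 0.2, n_visits[i] - 1), 0.1
        )
        ages = age0[i] + np.concatenate([[0.0], np.cumsum(gaps)])
        smoke = smoking0[i]
        for v in range(n_visits[i]):
            if config.smoking_transitions and v > 0 and smoke == 2:
                if rng.random() < 0.05:  # current smokers may quit
                    smoke = 1
            rows.append(
                (
                    family_id[i],
                    i,
                    v + 2,  # baseline is visit 2
                    ages[v],
                    female[i],
                    white[i],
                    college[i],
                    smoke,
                )
            )
    df = pd.DataFrame(
        rows,
        columns=[
            "family_id",
            "individual_id",
            "visit_index",
            "age",
            "female",
            "white",
            "college",
            "smoking_code",
        ],
    )
    n_rows = len(df)
    df["sex"] = np.where(df["female"], "F", "M")
    df["race"] = np.where(df["white"], "white", "other")
    df["education"] = df["college"].astype(int)
    df["smoking"] = pd.Categorical.from_codes(
        df["smoking_code"], categories=list(SMOKING_LEVELS)
    )
    # visit-level covariates
    df["cesd"] = _gamma_from_moments(
        rng, cp["cesd_mean"], cp["cesd_sd"], cp["cesd_max"], n_rows
    )
    df["alcohol_weekly"] = _gamma_from_moments(
        rng, cp["alcohol_mean"], cp["alcohol_sd"], cp["alcohol_max"], n_rows
    )
    bmi_codes = rng.choice(4, size=n_rows, p=np.asarray(cp["bmi_probs"]))
    df["bmi_category"] = pd.Categorical.from_codes(bmi_codes, categories=list(BMI_LEVELS))
    return df.drop(columns=["female", "white", "college"])


def _latent_metabolome(config: SimConfig, cohort: pd.DataFrame, rng):
    """Latent log10 abundances per cohort row (sample = individual-visit).

    L_j = mu_j + a_j * smoking_code + individual noise + sample noise.
    """
    n_rows = len(cohort)
    p = config.n_metabolites
    mu = rng.normal(config.metabolite_baseline_mean, config.metabolite_baseline_sd, p)
    truth = _build_truth(config)
    ind = cohort["individual_id"].to_numpy()
    n_ind = int(ind.max()) + 1 if n_rows else 0
    ind_noise = rng.normal(0.0, config.metabolite_noise["individual"], (n_ind, p))
    samp_noise = rng.normal(0.0, config.metabolite_noise["sample"], (n_rows, p))
    smoking = cohort["smoking_code"].to_numpy(dtype=float)
    latent = mu[None, :] + smoking[:, None] * truth.a[None, :]
    latent += ind_noise[ind, :] + samp_noise
    return latent, mu, truth


def generate_cohort(config: SimConfig) -> tuple[pd.DataFrame, TruthRecord]:
    """Generate the long-format cohort table and the planted truth.

    Each composite is fixed linear predictor + planted mediator terms +
    family intercept + individual intercept + individual age slope * age
    + residual. Deterministic given ``config.seed``; re-running with the
    same config yields an identical table.
    """
    cohort_rng, metab_rng, _ = _spawn(config)
    df = _generate_structure(config, cohort_rng)
    latent, mu, truth = _latent_metabolome(config, df, metab_rng)

    eff = config.covariate_effects
    vc = config.variance_components
    age_c = df["age"] - df["age"].mean()
    lin, quad = config.age_coefs
    fixed = (
        eff["intercept"]
        + eff["female"] * (df["sex"] == "F")
        + eff["white"] * (df["race"] == "white")
        + eff["college"] * df["education"]
        + eff["cesd"] * df["cesd"]
        + eff["alcohol"] * df["alcohol_weekly"]
        + eff["bmi_underweight"] * (df["bmi_category"] == "underweight")
        + eff["bmi_overweight"] * (df["bmi_category"] == "overweight")
        + eff["bmi_obese"] * (df["bmi_category"] == "obese")
        + lin * age_c
        + quad * age_c**2
        + config.practice_effect * (df["visit_index"] - 2)
    ).to_numpy()

    mediated = (latent - mu[None, :]) @ truth.b  # centered so intercept is stable
    fam = df["family_id"].to_numpy()
    ind = df["individual_id"].to_numpy()
    n_fam, n_ind = int(fam.max()) + 1, int(ind.max()) + 1
    smoking = df["smoking_code"].to_numpy(dtype=float)

    for outcome in OUTCOMES:
        u_fam = cohort_rng.normal(0.0, np.sqrt(vc["family"]), n_fam)
        u_ind = cohort_rng.normal(0.0, np.sqrt(vc["individual"]), n_ind)
        s_ind = cohort_rng.normal(0.0, np.sqrt(vc["age_slope"]), n_ind)
        eps = cohort_rng.normal(0.0, np.sqrt(vc["residual"]), len(df))
        df[outcome] = (
            fixed
            + truth.de[outcome] * smoking
            + mediated
            + u_fam[fam]
            + u_ind[ind]
            + s_ind[ind] * age_c.to_numpy()
            + eps
        )
    return df, truth


def generate_metabolome(
    cohort: pd.DataFrame,
    truth: TruthRecord,
    config: SimConfig,
    fluid: str = "plasma",
) -> MetaboliteMatrix:
    """Emit the abundance matrix consistent with a generated cohort.

    Abundances are 10**latent (strictly positive, log-normal scale);
    missing entries are inserted per ``config.missingness_spec``, either
    completely at random or preferentially at low abundance.
    """
    if any(m.index >= config.n_metabolites for m in config.mediator_spec):
        raise ConfigurationError("mediator index out of range")
    _, metab_rng, miss_rng = _spawn(config)
    latent, _, _ = _latent_metabolome(config, cohort, metab_rng)
    abund = 10.0**latent
    sample_id = [
        f"S{ind}_{visit}"
        for ind, visit in zip(cohort["individual_id"], cohort["visit_index"])
    ]
    data = pd.DataFrame(
        abund,
        index=pd.Index(sample_id, name="sample_id"),
        columns=[f"met_{j}" for j in range(config.n_metabolites)],
    )
    for j, frac in config.missingness_spec.items():
        n_missing = int(round(frac * len(data)))
        if n_missing == 0:
            continue
        col = data.columns[j]
        if config.missing_low_abundance:
            rows = np.argsort(data[col].to_numpy())[:n_missing]
        else:
            rows = miss_rng.choice(len(data), size=n_missing, replace=False)
        data.iloc[rows, j] = np.nan
    meta = pd.DataFrame(
        {
            "individual_id": cohort["individual_id"].to_numpy(),
            "age": cohort["age"].to_numpy(),
            "fluid": fluid,
        },
        index=data.index,
    )
    return MetaboliteMatrix(data, meta, log_scale=False)


def generate_study(
    config: SimConfig, fluid: str = "plasma"
) -> tuple[pd.DataFrame, MetaboliteMatrix, TruthRecord]:
    """Cohort, metabolome, and truth from one config in one call."""
    cohort, truth = generate_cohort(config)
    matrix = generate_metabolome(cohort, truth, config, fluid=fluid)
    return cohort, matrix, truth


def compute_composite(raw_scores, lower_is_better=None) -> np.ndarray:
    """Combine raw test scores into a composite.

    Each test (row) is standardized to mean 0 / SD 1 (sample SD), flipped
    in sign where lower raw scores indicate better performance, then
    averaged over tests per subject (column).

    Parameters
    ----------
    raw_scores : (n_tests, n_subjects) array or DataFrame.
    lower_is_better : boolean flags per test; default all False.
    """
    scores = np.asarray(raw_scores, dtype=float)
    if scores.ndim != 2 or scores.shape[0] < 1:
        raise ValueError("raw_scores must be a test x subject matrix with >= 1 test")
    n_tests = scores.shape[0]
    if lower_is_better is None:
        lower_is_better = np.zeros(n_tests, dtype=bool)
    lower_is_better = np.asarray(lower_is_better, dtype=bool)
    if lower_is_better.shape != (n_tests,):
        raise ValueError("lower_is_better must have one flag per test")
    sd = scores.std(axis=1, ddof=1)
    names = (
        list(raw_scores.index) if isinstance(raw_scores, pd.DataFrame) else list(range(n_tests))
    )
    for t in np.nonzero(sd == 0)[0]:
        raise ValueError(f"test {names[t]!r} has zero standard deviation")
    z = (scores - scores.mean(axis=1, keepdims=True)) / sd[:, None]
    z[lower_is_better] *= -1.0
    return z.mean(axis=0)


def write_cohort(cohort: pd.DataFrame, path) -> None:
    cohort.to_csv(path, sep="\t", index=False)


def read_cohort(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if "smoking" in df:
        df["smoking"] = pd.Categorical(df["smoking"], categories=list(SMOKING_LEVELS))
        if "smoking_code" not in df:
            df["smoking_code"] = df["smoking"].cat.codes
    if "bmi_category" in df:
        df["bmi_category"] = pd.Categorical(df["bmi_category"], categories=list(BMI_LEVELS))
    return df
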