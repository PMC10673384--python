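"""Metabolomics quality control.

The QC cascade applied to each fluid's abundance matrix, in fixed order:

1. drop metabolites with missingness strictly above a threshold (default 50%),
2. drop samples with missingness strictly above a threshold (default 40%),
3. drop metabolites whose observed values have interquartile range 0,
4. log10-transform the surviving abundances.

Threshold comparisons are strict (a metabolite at exactly the threshold is
retained). The IQR uses linear interpolation between order statistics; only
IQR == 0 versus > 0 matters for the filter, which is insensitive to the
quantile rule for constant columns. Remaining missing values are left
missing and handled downstream by complete-case analysis (an optional
half-minimum imputation mode is provided as a sensitivity analysis).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .synthetic_data import MetaboliteMatrix


@dataclass
class QCConfig:
    metabolite_missingness_threshold: float = 0.50
    sample_missingness_threshold: float = 0.40
    transform: str = "log10"
    impute_half_minimum: bool = False

    def __post_init__(self) -> None:
        for name in ("metabolite_missingness_threshold", "sample_missingness_threshold"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must be in (0, 1]")
        if self.transform != "log10":
            raise ValueError("transform must be 'log10'")


@dataclass
class QCReport:
    """Accounting of removals; the identities
    final_metabolites = initial - removed_missing - removed_zero_iqr and
    final_samples = initial_samples - removed_samples hold exactly."""

    initial_metabolites: int
    initial_samples: int
    removed_missing_metabolites: list = field(default_factory=list)
    removed_samples: list = field(default_factory=list)
    removed_zero_iqr_metabolites: list = field(default_factory=list)
    degenerate_metabolites: list = field(default_factory=list)

    @property
    def final_metabolites(self) -> int:
        return (
            self.initial_metabolites
            - len(self.removed_missing_metabolites)
            - len(self.removed_zero_iqr_metabolites)
        )

    @property
    def final_samples(self) -> int:
        return self.initial_samples - len(self.removed_samples)

    def to_dict(self) -> dict:
        return {
            "initial_metabolites": self.initial_metabolites,
            "initial_samples": self.initial_samples,
            "removed_missing_metabolites": list(self.removed_missing_metabolites),
            "n_removed_missing_metabolites": len(self.removed_missing_metabolites),
            "removed_samples": list(self.removed_samples),
            "n_removed_samples": len(self.removed_samples),
            "removed_zero_iqr_metabolites": list(self.removed_zero_iqr_metabolites),
            "n_removed_zero_iqr_metabolites": len(self.removed_zero_iqr_metabolites),
            "degenerate_metabolites": list(self.degenerate_metabolites),
            "final_metabolites": self.final_metabolites,
            "final_samples": self.final_samples,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    def summary(self) -> str:
        d = self.to_dict()
        return (
            f"QC: {d['initial_metabolites']} metabolites x {d['initial_samples']} samples\n"
            f"  removed for missingness: {d['n_removed_missing_metabolites']} metabolites, "
            f"{d['n_removed_samples']} samples\n"
            f"  removed for zero IQR:    {d['n_removed_zero_iqr_metabolites']} metabolites\n"
            f"  final: {d['final_metabolites']} metabolites x {d['final_samples']} samples"
        )


def filter_metabolites_by_missingness(
    matrix: MetaboliteMatrix, threshold: float = 0.50
) -> tuple[MetaboliteMatrix, list]:
    """Remove metabolites whose missing fraction strictly exceeds ``threshold``."""
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    if matrix.n_samples == 0:
        return matrix.copy(), []
    frac = matrix.data.isna().mean(axis=0)
    removed = list(frac.index[frac > threshold])
    return (
        MetaboliteMatrix(matrix.data.drop(columns=removed), matrix.meta.copy(), matrix.log_scale),
        removed,
    )


def filter_samples_by_missingness(
    matrix: MetaboliteMatrix, threshold: float = 0.40
) -> tuple[MetaboliteMatrix, list]:
    """Remove samples whose missing fraction strictly exceeds ``threshold``."""
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    if matrix.n_metabolites == 0:
        return matrix.copy(), []
    frac = matrix.data.isna().mean(axis=1)
    removed = list(frac.index[frac > threshold])
    kept = matrix.data.drop(index=removed)
    return (
        MetaboliteMatrix(kept, matrix.meta.loc[kept.index].copy(), matrix.log_scale),
        removed,
    )


def filter_zero_iqr(matrix: MetaboliteMatrix) -> tuple[MetaboliteMatrix, list, list]:
    """Remove metabolites whose observed values have IQR == 0.

    Metabolites with fewer than two observed values cannot show variation;
    they are removed and reported separately as degenerate.
    """
    removed, degenerate = [], []
    for col in matrix.data.columns:
        obs = matrix.data[col].dropna().to_numpy()
        if obs.size < 2:
            removed.append(col)
            degenerate.append(col)
        elif np.subtract(*np.percentile(obs, [75, 25])) == 0:
            removed.append(col)
    return (
        MetaboliteMatrix(matrix.data.drop(columns=removed), matrix.meta.copy(), matrix.log_scale),
        removed,
        degenerate,
    )


def log10_transform(matrix: MetaboliteMatrix) -> MetaboliteMatrix:
    """Elementwise log10 of the observed abundances; missing stays missing."""
    bad = matrix.data.le(0)
    if bad.any().any():
        col = bad.any(axis=0).idxmax()
        row = bad[col].idxmax()
        raise ValueError(
            f"non-positive abundance for metabolite {col!r} in sample {row!r}; "
            "cannot log10-transform"
        )
    return MetaboliteMatrix(np.log10(matrix.data), matrix.meta.copy(), log_scale=True)


def run_qc(
    matrix: MetaboliteMatrix, config: QCConfig | None = None
) -> tuple[MetaboliteMatrix, QCReport]:
    """Apply the full cascade: metabolite missingness -> sample missingness
    -> zero IQR -> log10."""
    config = config or QCConfig()
    report = QCReport(matrix.n_metabolites, matrix.n_samples)
    m, report.removed_missing_metabolites = filter_metabolites_by_missingness(
        matrix, config.metabolite_missingness_threshold
    )
    m, report.removed_samples = filter_samples_by_missingness(
        m, config.sample_missingness_threshold
    )
    m, iqr_removed, report.degenerate_metabolites = filter_zero_iqr(m)
    report.removed_zero_iqr_metabolites = iqr_removed
    if not m.log_scale:
        m = log10_transform(m)
    if config.impute_half_minimum:
        m = MetaboliteMatrix(
            m.data.fillna(m.data.min(axis=0) - np.log10(2.0)), m.meta, m.log_scale
        )
    return m, report


def match_samples_to_visits(
    sample_ages: pd.Series | dict, visit_ages: pd.Series | dict
) -> dict:
    """Map each sample to the visit whose age is nearest the sample's age.

    Both arguments are keyed collections: sample id -> (individual, age)
    may be passed as a DataFrame-backed Series of ages grouped by
    individual; here we take the simple per-individual form — for one
    individual, ``sample_ages`` maps sample id -> age and ``visit_ages``
    maps visit index -> age. Ties break toward the earlier visit.
    """
    visit_items = sorted(dict(visit_ages).items())
    if not visit_items:
        raise ValueError("individual has samples but no visits")
    mapping = {}
    for sid, age in dict(sample_ages).items():
        best = min(visit_items, key=lambda kv: (abs(age - kv[1]), kv[0]))
        mapping[sid] = best[0]
    return mapping


def match_matrix_to_cohort(
    matrix: MetaboliteMatrix, cohort: pd.DataFrame
) -> pd.DataFrame:
    """Attach a visit_index to every sample by nearest-age matching.

    Returns a copy of ``matrix.meta`` with a ``visit_index`` column. Raises
    if a sampled individual has no cohort visits.
    """
    out = matrix.meta.copy()
    missing = sorted(
        set(out["individual_id"]) - set(cohort["individual_id"].unique())
    )
    if missing:
        raise ValueError(f"individuals with samples but no visits: {missing}")
    visits = cohort[["individual_id", "visit_index", "age"]].rename(
        columns={"age": "visit_age"}
    )
    merged = (
        out.reset_index()
        .merge(visits, on="individual_id", how="left")
        .assign(dist=lambda d: (d["age"] - d["visit_age"]).abs())
        .sort_values(["dist", "visit_index"], kind="stable")  # tie -> earlier
    )
    best = merged.drop_duplicates(subset=matrix.meta.index.name or "index").set_index(
        matrix.meta.index.name or "index"
    )
    out["visit_index"] = best.loc[out.index, "visit_index"].astype(int)
    return out
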