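import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from metamediate import MediatorSpec, MetaboliteMatrix, SimConfig, generate_study

settings.register_profile("suite", derandomize=True, deadline=None, max_examples=25)
settings.load_profile("suite")


def make_matrix(values, sample_ids=None, metabolite_ids=None, log_scale=False,
                individual_ids=None, ages=None, fluid="plasma"):
    """Small abundance matrix from a 2D array (NaN = missing)."""
    values = np.asarray(values, dtype=float)
    n, p = values.shape
    sample_ids = sample_ids or [f"s{i}" for i in range(n)]
    metabolite_ids = metabolite_ids or [f"m{j}" for j in range(p)]
    data = pd.DataFrame(values, index=pd.Index(sample_ids, name="sample_id"),
                        columns=metabolite_ids)
    meta = pd.DataFrame(
        {
            "individual_id": individual_ids if individual_ids is not None else range(n),
            "age": ages if ages is not None else np.linspace(50, 60, n),
            "fluid": fluid,
        },
        index=data.index,
    )
    return MetaboliteMatrix(data, meta, log_scale=log_scale)


def single_level_cohort(n, seed=0, a=0.4, b=0.5, c_prime=-0.3, noise_m=1.0,
                        noise_y=1.0, outcome="PACC3"):
    """One-visit-per-individual dataset with a single planted mediator,
    suitable for ordinary least-squares mediation fits."""
    rng = np.random.default_rng(seed)
    x = rng.choice(3, n, p=[0.562, 0.370, 0.068]).astype(float)
    cov = rng.normal(0.0, 1.0, n)
    m = 5.0 + a * x + 0.3 * cov + rng.normal(0.0, noise_m, n)
    y = 1.0 + c_prime * x + b * m + 0.2 * cov + rng.normal(0.0, noise_y, n)
    df = pd.DataFrame(
        {
            "family_id": np.arange(n),
            "individual_id": np.arange(n),
            "visit_index": 2,
            "age": 50.0 + rng.normal(0.0, 5.0, n),
            "sex": "M",
            "race": "white",
            "education": 0,
            "cesd": cov,
            "alcohol_weekly": 0.0,
            "bmi_category": "normal",
            "smoking": pd.Categorical.from_codes(
                x.astype(int), ["never", "former", "current"]
            ),
            "smoking_code": x,
            "met": m,
            outcome: y,
        }
    )
    return df


@pytest.fixture(scope="session")
def planted_study():
    """Small multilevel study with one mediator, one suppressor, one null_a,
    one null_b metabolite among noise."""
    cfg = SimConfig(
        n_families=250,
        n_metabolites=12,
        mediator_spec=[
            MediatorSpec(0, 0.4, -0.35),   # consistent mediator (IE < 0, DE < 0)
            MediatorSpec(1, 0.5, 0.45),    # suppressor (IE > 0, DE < 0)
            MediatorSpec(2, 0.0, 0.5),     # null_a
            MediatorSpec(3, 0.5, 0.0),     # null_b
        ],
        direct_effect=-0.15,
        seed=20260930,
    )
    return cfg, generate_study(cfg)
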