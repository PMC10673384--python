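# metamediate

Mediation screening of exposure–outcome relationships through untargeted
metabolomics in multilevel longitudinal cohorts.

## What this is for

Epidemiological cohorts often show that a behavioral exposure (here:
smoking status) is associated with a longitudinal outcome (here:
cognitive composite scores), without saying anything about mechanism.
If the exposure shifts circulating metabolites, and those metabolites in
turn track the outcome, the metabolites are candidate links on the
biological pathway. `metamediate` implements that question as a tested,
reusable pipeline for biostatisticians and molecular-epidemiology groups:
untargeted metabolomics QC, mixed-model association screening with
false-discovery-rate gating, and product-method mediation decomposition
with Monte-Carlo confidence intervals — plus a synthetic cohort generator
with known planted mediation structure, so the whole workflow is testable
end to end without access to restricted cohort data.

## The method

For exposure X, metabolite M, outcome Y and covariates Z, with random
intercepts for family and individual and a random age slope per
individual:

- **Step 1** — total effect: `Y ~ X + Z + (1|fam) + (1 + age|ind)`; the
  exposure coefficient is *c*. A reduced and a fully-adjusted covariate
  set compete by ML-based AIC; the winner is used downstream.
- **Step 2** — exposure → metabolite: `M_j ~ X + Z + …` per metabolite;
  the exposure coefficient is *a_j*. Benjamini–Hochberg FDR across the
  metabolites of a fluid (q < 0.05) gates survivors.
- **Step 3** — metabolite → outcome: `Y ~ X + M_j + Z + …` for each
  survivor; the metabolite coefficient is *b_j*, FDR-gated within
  (fluid, outcome).
- **Step 4** — decomposition: indirect effect IE = a_j·b_j, direct
  effect DE = c′ (the exposure coefficient from the Step-3 model), a
  Monte-Carlo 95% CI for the product (draws a* ~ N(â, SE²_a),
  b* ~ N(b̂, SE²_b) independently), the proportion mediated
  IE/(IE + DE) (with IE/c reported alongside), and a classification:
  none / partial / complete / inconsistent (suppression, when IE and DE
  have opposite signs).

Smoking is categorical (never/former/current) in Step 1 and numeric
(0/1/2) on the mediation paths. QC removes metabolites with > 50%
missingness, samples with > 40% missingness, zero-IQR metabolites, and
log10-transforms the rest. See `docs/methods.md` for the full model and
every numerical choice.

## Worked example

Simulate a cohort of ~250 sibships (~950 visit records) with 40 plasma
metabolites, one of which is a planted mediator (a = 0.5, b = −0.4,
direct effect −0.2 per unit smoking), then run the full pipeline:

```python
from metamediate import MediatorSpec, RunConfig, SimConfig, run_pipeline

sim = SimConfig(
    n_families=250,
    n_metabolites=40,
    mediator_spec=[MediatorSpec(0, 0.5, -0.4)],
    direct_effect=-0.2,
    seed=11,
)
config = RunConfig(simulate=True, sim=sim, outcomes=("PACC3",),
                   mc_reps=100_000, seed=11, outdir="demo_run")
artifacts = run_pipeline(config)
print(artifacts["step4"][("plasma", "PACC3")][0].path_diagram())
```

which prints:

```
step2: 1/40 metabolites passed FDR
step3: 1/1 candidates passed FDR

PACC3 <- smoking, mediated by met_0
  total effect      c  = -0.4283 (SE 0.0603)
  smoking -> met    a  = +0.4811 (SE 0.0457)
  met -> outcome    b  = -0.4066 (SE 0.0421)
  indirect effect   IE = a*b = -0.1956, 95% CI [-0.2523, -0.1443]
  direct effect     c' = -0.2287 (SE 0.0591, p = 0.00011)
  proportion mediated: 46.1% of IE+DE, 45.7% of c
  classification: partial
```

Reading it: only the planted mediator survived the two FDR gates among
40 metabolites. Its estimated paths (a ≈ 0.48, b ≈ −0.41) bracket the
planted values; the indirect effect −0.196 (CI excluding 0) accounts for
about 46% of the smoking–cognition effect, the direct path stays
significant, so the mediation is *partial*. Every stage's tables, model
choices, QC report, FDR metadata, ground truth and a run log land in
`demo_run/`.

The same workflow is available from the shell:

```sh
metamediate simulate --seed 11 --outdir study/
metamediate qc --matrix study/metabolites.tsv --meta study/metabolites_meta.tsv
metamediate run-all --config run_config.yaml
```

with subcommands `simulate`, `qc`, `screen`, `mediate`, `run-all` (exit
codes: 0 ok, 2 config error, 3 schema error, 4 stage failure).

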