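# gestval

External validation tooling for **geriatric end-of-life mortality
screens in the emergency department**.

Older adults with high short-term mortality risk are candidates for
serious-illness conversations and palliative care referral, but ED
clinicians need a way to find them. Two screening approaches compete in
practice:

* a **logistic risk model** (the Geriatric End-of-Life Screening Tool,
  GEST) that estimates each encounter's 6-month mortality probability
  from age, CBC labs, vitals, utilization and diagnosis history; and
* a binary **serious-illness screen** that flags any encounter with a
  life-limiting ICD-10 diagnosis (stroke/TIA, liver disease, cancer,
  heart disease, lung disease, ... ) in the past year, or age ≥ 80.

`gestval` implements the full external-validation analysis that
compares them, as a reusable, tested library:

* **`gestval.simulate`** — a seeded synthetic ED cohort generator
  (encounters, long-format vitals and labs, dated diagnoses, prior
  admissions, death dates with administrative right-censoring), so the
  whole analysis runs end to end with no data access.
* **`gestval.features`** — covariate extraction with the
  first-4-hours vitals window and 1-year admission lookback.
* **`gestval.model`** — declarative scoring: per-covariate imputation
  value, standardization mean/SD and coefficient live in a YAML file;
  `p = logistic(β₀ + Σ βᵢ zᵢ)` with `zᵢ = (xᵢ − x̄ᵢ)/sᵢ`.
* **`gestval.serious_illness`** — the binary screen with a
  configurable ICD-10 prefix catalog and optional age-80 criterion.
* **`gestval.metrics`** — AUROC with DeLong variance and 95% CIs
  (overall, by subgroup, by year) and observed-vs-predicted calibration.
* **`gestval.update`** — intercept-only recalibration and full
  logistic refit on a temporal train/validation split.
* **`gestval.screening`** — sens/spec/PPV/NPV/LR± at risk cutoffs,
  decision-curve net benefit `NB(p_t) = TP/n − (FP/n)·p_t/(1−p_t)`, and
  the serious-illness × risk-band misclassification cross-tab.
* **`gestval.survival`** — Kaplan-Meier curves on first encounters by
  risk stratum with administrative censoring.
* **`gestval.pipeline` / `gestval` CLI** — one-call orchestration and
  thin subcommands (`simulate`, `extract`, `score`, `validate`,
  `update`, `screen`, `dca`, `survival`, `crosstab`, `report`,
  `run-all`).

The published model's coefficients live in a supplement that is not
redistributed here; the shipped spec
(`gestval/data/gest_model_synthetic.yaml`) is a clearly-labelled
synthetic stand-in with the same covariates. Point `--model-spec` (or
`RunConfig.model_spec_path`) at a transcription to score with the real
model.

## Worked example

```python
from gestval import CohortConfig, RunConfig, run_pipeline

bundle = run_pipeline(RunConfig(simulate=CohortConfig(n_patients=2000, seed=42), seed=42))
m = bundle.manifest
print(f"6-month mortality: {100 * m['prevalence']:.1f}%")
print(f"serious illness:   {100 * m['serious_illness_fraction']:.1f}%")
print(f"overall AUROC:     {m['overall_auroc']:.3f}")
print(f"discordant screens:{100 * m['discordant_share']:.1f}%")
```

prints

```
6-month mortality: 12.2%
serious illness:   59.1%
overall AUROC:     0.770
discordant screens:26.8%
```

Here 12.2% of the 3 764 simulated encounters end in death within 183
days; the risk model ranks a random decedent above a random survivor
77% of the time; and for 26.8% of encounters the two screens disagree
(serious-illness-positive but model-low-risk, or the reverse) — the
population where the choice of screen changes who gets approached.
The `examples/` directory holds one short script per capability
(simulation, scoring and validation, model updating, screening and
decision curves, survival, full pipeline), each printing the numbers it
computes and what they mean.

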