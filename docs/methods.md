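# Methods

`gestval` evaluates two ED screening strategies for 6-month mortality in
adults 65 and older — a logistic risk model applied from a declarative
specification, and a binary serious-illness diagnosis screen — and
compares them with the standard external-validation toolkit:
discrimination, calibration, model updating, threshold test
characteristics, decision-curve net benefit, and Kaplan-Meier survival.
This note records the models, the defaults and why, the numerical
choices, and what the synthetic data can and cannot show.

## The risk model

Scoring is specification-driven. A model specification carries, per
covariate, an imputation value (raw units, used when the covariate is
absent), a standardization mean and SD from the derivation cohort, a
log-odds coefficient per standardized unit, and a flag saying whether
the covariate is standardized at all (binary covariates commonly are
not). Prediction is

    z_i = (x_i − x̄_i) / s_i        (x_i ← imputation value when absent)
    η   = β₀ + Σ β_i z_i
    p   = 1 / (1 + exp(−η))

Probabilities are never clipped or rounded internally; rounding is a
display concern. Specifications round-trip bit-exactly through YAML, so
updated models are plain files.

The shipped specification is a **synthetic stand-in**: it has the
published screening tool's 17 covariates with clinically signed,
plausible per-SD coefficients (anaemia, azotaemia, anisocytosis,
tachycardia, hypotension, oxygen use, utilization and cancer history
increase risk), because the published imputation/standardization/
coefficient values appear only in a supplement not redistributed here.
Every analysis accepts a user-supplied specification file instead.

Outpatient cardiovascular medication use is modelled as unavailable in
the validation setting (as it was in the motivating study): the default
missingness rate for it is 1.0, so it is always imputed with the
specification's derivation-median value.

## Feature extraction

* **Vitals**: only observations within the first 240 minutes of arrival
  count (configurable). Mean over heart-rate observations, minimum over
  systolic pressures, and supplemental oxygen true iff any in-window
  oxygen-device observation is not room air. No in-window observation →
  absent.
* **Labs**: the earliest resulted value per analyte in the encounter;
  offset ties resolve to the lower row index (logged). Rationale:
  screening-at-presentation uses the first available result; no rule was
  published, so the earliest result is pinned for reproducibility.
* **Admissions**: count in `[arrival − 365 d, arrival)`, closed on the
  left — an admission exactly one year prior counts, a same-day
  admission does not.
* **Diagnosis-history covariates**: ICD-10 prefix match against a
  configurable catalog; history flags use any code dated strictly before
  arrival (full history by default — the published 1-year lookback
  applies to the serious-illness screen, not the model covariates — with
  an optional lookback limit); the syncope/CVA flag uses only codes
  attached to the index encounter.
* "Reticulocyte distribution width" in the covariate list is treated as
  red cell distribution width (RDW), the standard CBC analyte.

Extraction is pure: identical tables give identical feature vectors.

## The serious-illness screen

An encounter is flagged when any code of any catalog category appears in
`[arrival − 365 d, arrival]` (index-day codes count; the boundary was
unstated and is fixed closed for determinism), or when age ≥ 80 and the
age criterion is enabled (the default, matching the screen's published
form; disabling it reproduces the "without age criteria" sensitivity
analysis). The shipped catalog lists the thirteen standard
claims-based serious-illness categories at ICD-10 prefix level; exact
institutional code lists can be supplied as YAML.

## Discrimination and calibration

AUROC uses midranks (case/control ties credit ½); its variance is the
DeLong structural-component estimator over case and control placement
values, and the 95% CI is the normal approximation truncated to [0, 1].
Subgroup and per-year AUROCs reuse the same estimator; strata missing a
class are reported as skipped rather than failing the run. Calibration
groups encounters by score decile (10 groups by default; the published
grouping was unspecified) or by fixed probability edges, reporting mean
predicted risk, observed event rate and count per group; empty fixed
bins are retained with count 0 and undefined rates.

## Model updating

On a temporal split (2017-2018 update / 2019-2021 validate by default):

* **Recalibration** is intercept-only: with the full linear predictor
  as an offset (slope fixed at 1), the MLE shift δ is
  calibration-in-the-large, and the new intercept is β₀ + δ. An
  intercept+slope variant exists behind a flag, off by default, since
  the published update names only the intercept.
* **Refit** re-estimates all coefficients by logistic maximum
  likelihood (IRLS, convergence tolerance 1e-8, 100 iterations max) on
  the specification's standardized covariates. Separation is detected
  (diverging coefficient plus the fitter's separation diagnostic) and
  reported naming the covariate; the pipeline records a skipped refit
  rather than aborting when sparse training data separates on a rare
  flag.

Both updates emit ordinary specification files. Intercept shifts are
monotone, so recalibration provably never changes AUROC — this is
asserted in the tests.

## Screening characteristics, net benefit, cross-tab

Thresholding is strict (`score > cutoff`, reading "risk > 5%"
literally). Sens, spec, PPV, NPV, LR± and fraction positive are
computed from the 2×2 counts; undefined ratios are reported as NaN,
never fabricated. Proportion CIs use the Wilson score interval and LR
CIs the log method (the published table named no CI method; the method
used is recorded in the output). Net benefit at threshold probability
p_t is `TP/n − (FP/n)·p_t/(1−p_t)`; the model strategy reclassifies at
each p_t, the binary screen keeps its fixed classification, and
treat-all/treat-none are the reference strategies. The default grid is
0.01–0.50 in steps of 0.01. The misclassification cross-tab bins
encounters by serious-illness status × risk band (<10%, 10–30%, >30%)
with per-cell counts, shares and observed mortality; the discordant
share is serious-illness-with-low-risk plus no-serious-illness-with-
high-risk.

## Survival

Kaplan-Meier estimation runs on first encounters only (earliest arrival
per patient, timestamp ties broken by encounter id) with administrative
right-censoring at a fixed calendar date (2022-12-31 by default). Time
is day-granular; at tied times deaths are processed before censorings
(the standard convention); the horizon is 183 days ≈ 6 months, both
configurable. The product-limit computation is delegated to
`lifelines`; the test suite checks it against an independent
brute-force risk-set oracle, and with complete follow-up `1 − S(183)`
equals the binary 6-month mortality rate exactly, tying the survival
module to the rest of the analysis.

## The synthetic cohort generator

The generator emulates the statistical structure the analysis assumes,
not any real population:

* **Ages** truncated normal on [65, 105], mean 77, SD 8 (the published
  cohort's moments). Labs and vitals use normal/lognormal families with
  plausible adult ranges; flags are Bernoulli; admissions Poisson.
* **Dependence** comes from a single patient-level latent severity
  factor with per-covariate loadings (sign = clinical direction) —
  enough structure for discrimination/calibration testing without a
  full copula. Serious-illness categories load on the same factor with
  a logit-normal marginal correction that keeps per-category prevalence
  near its configured base rate.
* **Outcomes**: the true model is evaluated on each patient's anchor
  covariates, the intercept is bisected (bounds ±30) until the mean
  predicted probability equals the target prevalence (13.8% by
  default), and death is a Bernoulli draw. Deaths within 6 months get a
  date uniform on (1, 183] days after first arrival; 15% of survivors
  die later (uniform on (183, 548]), so administrative censoring is
  exercised; deaths after the censor date are unknown to the outcomes
  table.
* **Repeat visits**: geometric visit counts (mean 2), exponential
  inter-visit gaps (mean 45 d), visits truncated at the study end and
  before death; continuous covariates redraw around the patient anchor
  (SD = 0.25 × the covariate's own scale), with the first visit equal
  to the anchor.
* **Raw tables** are emitted so that extraction reproduces the
  generated truth: in-window vital observations are constructed to have
  exactly the true mean/minimum (plus out-of-window decoys that would
  change the answer if the window were ignored), labs carry the true
  value at the earliest offset, diagnosis codes are dated inside the
  relevant lookbacks, and codes for serious-illness categories are
  chosen not to collide with the model's own diagnosis prefixes.
* **Missingness** blanks each covariate independently at its configured
  rate (defaults: 5% labs, 2% vitals, 100% outpatient medications —
  placeholders, since the study's per-covariate rates were published
  only in a supplement) and drops the corresponding long-table rows so
  extraction and truth stay consistent.

Everything is driven by one `numpy` generator seed: identical configs
produce byte-identical tables.

What passing tests on this generator do **not** show: real EHR data have
informative missingness, measurement error correlated with acuity,
miscoded and delayed diagnoses, COVID-era mortality shifts, and
serious-illness categories whose prevalences co-occur in ways a single
severity factor cannot capture. Results on synthetic cohorts validate
the *arithmetic and statistical machinery*, not the clinical performance
of any screen.

## Problem sizes and numerical choices

Simulation-based checks use sizes chosen to make their Monte-Carlo error
small relative to the tolerance they assert: DeLong CI coverage uses
1000 cohorts of n = 2000 (binormal scores, true AUROC Φ(1/√2) ≈ 0.76);
parameter recovery uses 20 000 single-visit encounters (3-SE criterion);
calibration concentration uses 50 000 draws (±0.02); the end-to-end
pipeline examples use 2000–4000 patients. Intercept bisection runs 200
halvings of [−30, 30]; logistic fits converge at 1e-8; AUROC/KM oracle
comparisons assert agreement to 1e-12.

## Known limitations

* The shipped model specification is synthetic; absolute risks and
  AUROCs computed with it characterize the pipeline, not the published
  tool.
* The serious-illness catalog is prefix-level; institutional code lists
  are more specific in both directions.
* The generator's severity factor induces exchangeable dependence only;
  no within-patient time trends beyond the visit-redraw noise.
* Net-benefit CIs are not computed (none were published); the decision
  curves are point estimates.
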