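"""Generate a synthetic geriatric ED cohort and look at its structure.

The generator emulates the statistical shape of an institutional ED
extract: ages >= 65, ~13.8% 6-month mortality, repeat visits, linked
vitals/labs/diagnoses/admissions tables, and death dates that allow
administrative right-censoring.
"""

from gestval import CohortConfig, generate_cohort, six_month_mortality

cohort = generate_cohort(CohortConfig(n_patients=2000, seed=42))

labels = six_month_mortality(cohort.encounters, cohort.outcomes)
print(f"patients:            {cohort.manifest['n_patients']}")
print(f"encounters:          {cohort.manifest['n_encounters']}")
print(f"6-month mortality:   {labels.mean():.3f}  (target {cohort.manifest['target_prevalence']})")
print(f"tuned intercept:     {cohort.manifest['tuned_intercept']:.3f}")
print(f"mean age:            {cohort.features_true['age'].mean():.1f}")
print(f"vitals rows:         {len(cohort.vitals)}")
print(f"diagnosis codes:     {len(cohort.diagnoses)}")

# The mortality rate sits near the configured target because the outcome
# model's intercept is bisected against the cohort's own risk scores.
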