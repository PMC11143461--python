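"""Score encounters with the declarative risk model and validate it.

Feature extraction applies the first-4-hours vitals window and 1-year
admission lookback; scoring imputes missing covariates with the spec's
derivation-cohort values, standardizes, and applies the logistic model.
Discrimination is the DeLong AUROC; calibration compares predicted and
observed risk by decile.
"""

from gestval import CohortConfig, generate_cohort, six_month_mortality
from gestval.features import extract_features
from gestval.metrics import auroc_delong, calibration_bins
from gestval.model import default_model_spec, score_frame

cohort = generate_cohort(CohortConfig(n_patients=2000, seed=42))
features = extract_features(
    cohort.encounters, cohort.vitals, cohort.labs, cohort.diagnoses, cohort.admissions
)
scores = score_frame(features.drop(columns=["encounter_id"]), default_model_spec())
labels = six_month_mortality(cohort.encounters, cohort.outcomes)

disc = auroc_delong(scores["probability"], labels)
print(f"AUROC {disc.auroc:.3f} (95% CI {disc.ci95[0]:.3f}-{disc.ci95[1]:.3f}), "
      f"{disc.n_cases} deaths / {disc.n_controls} survivors")

cal = calibration_bins(scores["probability"], labels)
print("\nrisk decile   predicted   observed    n")
for _, row in cal.bins.iterrows():
    print(f"{int(row['bin']):>10}   {row['predicted_mean']:.3f}       "
          f"{row['observed_rate']:.3f}      {int(row['count'])}")

# An AUROC near 0.8 means a randomly chosen decedent outranks a randomly
# chosen survivor ~4 times in 5; close predicted/observed columns mean
# the probabilities themselves are trustworthy, not just their ranking.
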