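# SYNTHETIC stand-in risk model specification.
#
# Same covariate set as the published geriatric end-of-life screening
# logistic model, but the imputation values, standardization moments and
# coefficients here are plausible synthetic values (clinically signed,
# per-SD log-odds), NOT the published ones, which are not redistributed.
# Replace this file with a transcription to score with the real model.
name: gest-synthetic-standin
intercept: -2.6
covariates:
  - {name: age, imputation_value: 77.0, standardization_mean: 77.0, standardization_sd: 8.0, coefficient: 0.45}
  - {name: hemoglobin, imputation_value: 12.5, standardization_mean: 12.5, standardization_sd: 2.0, coefficient: -0.25}
  - {name: hematocrit, imputation_value: 37.5, standardization_mean: 37.5, standardization_sd: 5.5, coefficient: -0.05}
  - {name: blood_urea_nitrogen, imputation_value: 20.0, standardization_mean: 22.0, standardization_sd: 12.0, coefficient: 0.35}
  - {name: red_cell_distribution_width, imputation_value: 14.3, standardization_mean: 14.5, standardization_sd: 2.0, coefficient: 0.4}
  - {name: lymphocyte_count, imputation_value: 1.5, standardization_mean: 1.6, standardization_sd: 0.9, coefficient: -0.2}
  - {name: mean_corpuscular_volume, imputation_value: 90.0, standardization_mean: 90.0, standardization_sd: 6.0, coefficient: 0.1}
  - {name: mean_heart_rate, imputation_value: 84.0, standardization_mean: 85.0, standardization_sd: 15.0, coefficient: 0.3}
  - {name: min_systolic_bp, imputation_value: 126.0, standardization_mean: 125.0, standardization_sd: 22.0, coefficient: -0.3}
  - {name: supplemental_oxygen, imputation_value: 0.0, standardization_mean: 0.0, standardization_sd: 1.0, coefficient: 0.5, standardize: false}
  - {name: admissions_past_year, imputation_value: 0.0, standardization_mean: 0.7, standardization_sd: 1.2, coefficient: 0.35}
  - {name: dx_secondary_cancer, imputation_value: 0.0, standardization_mean: 0.0, standardization_sd: 1.0, coefficient: 1.0, standardize: false}
  - {name: dx_cognitive_disorder, imputation_value: 0.0, standardization_mean: 0.0, standardization_sd: 1.0, coefficient: 0.4, standardize: false}
  - {name: dx_lung_cancer, imputation_value: 0.0, standardization_mean: 0.0, standardization_sd: 1.0, coefficient: 0.8, standardize: false}
  - {name: dx_pancreatic_cancer, imputation_value: 0.0, standardization_mean: 0.0, standardization_sd: 1.0, coefficient: 1.2, standardize: false}
  - {name: ed_dx_syncope_or_cva, imputation_value: 0.0, standardization_mean: 0.0, standardization_sd: 1.0, coefficient: 0.2, standardize: false}
  - {name: outpatient_cv_meds, imputation_value: 1.0, standardization_mean: 0.0, standardization_sd: 1.0, coefficient: 0.15, standardize: false}
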