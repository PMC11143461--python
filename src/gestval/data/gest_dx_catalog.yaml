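# ICD-10 prefix catalog for the risk model's diagnosis-history covariates.
# History flags use any code dated before the index arrival (configurable
# lookback); the syncope/CVA flag uses codes attached to the index ED
# encounter itself.
dx_secondary_cancer: ["C77", "C78", "C79"]
dx_cognitive_disorder: ["F01", "F02", "F03", "F05", "G30", "R41.0"]
dx_lung_cancer: ["C34"]
dx_pancreatic_cancer: ["C25"]
ed_dx_syncope_or_cva: ["R55", "I60", "I61", "I62", "I63", "G45"]
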