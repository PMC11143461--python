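# Serious-illness ICD-10 category catalog, at code-prefix level.
#
# Categories follow the widely used claims-based serious-illness
# definitions (stroke/TIA, liver disease, hip fracture, cancer, heart
# disease, lung disease, neurodegenerative disease, diabetes with
# peripheral vascular disease, coronary artery disease, chronic kidney
# disease, HIV/AIDS, kidney failure, dementia).  Prefixes are coarse
# family-level stand-ins; supply your own catalog file to use an exact
# institutional code list.
stroke_tia: ["I60", "I61", "I62", "I63", "G45"]
liver_disease: ["K70", "K72", "K74", "K76.6", "I85"]
hip_fracture: ["S72.0", "S72.1", "S72.2"]
cancer: ["C77", "C78", "C79", "C25", "C34", "C91", "C92", "C93", "C94", "C95", "C96"]
heart_disease: ["I50", "I42", "I43"]
lung_disease: ["J44", "J43", "J47", "J84", "J96.1"]
neurodegenerative_disease: ["G12", "G10", "G35"]
diabetes_pvd: ["E10.5", "E11.5", "E13.5"]
coronary_artery_disease: ["I25"]
chronic_kidney_disease: ["N18.3", "N18.4", "N18.5"]
hiv_aids: ["B20", "B21", "B22", "B24"]
kidney_failure: ["N18.6", "N17", "Z99.2"]
dementia: ["F01", "F02", "F03", "G30", "G31.1"]
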