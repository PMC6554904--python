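# Canonical comorbidity category registry.
#
# charlson: the 17 disease categories of the Charlson Comorbidity Index with
#   the original 1987 weights (range 1-6) and the Quan 2011 12-item update
#   (five categories re-weighted to 0; weights in {0,1,2,4,6}).
# elixhauser: the 31 diagnostic categories of the Elixhauser Method (no
#   weights: the categories enter regression models as separate indicators).
# hierarchy: severity rules applied before index computation - when the severe
#   category is flagged the milder one is cleared.  Edit or empty per study.
charlson:
  - {id: myocardial_infarction,   name: "Myocardial infarction",            weight_original: 1, weight_quan: 0}
  - {id: congestive_heart_failure, name: "Congestive heart failure",        weight_original: 1, weight_quan: 2}
  - {id: peripheral_vascular,     name: "Peripheral vascular disease",      weight_original: 1, weight_quan: 0}
  - {id: cerebrovascular,         name: "Cerebrovascular disease",          weight_original: 1, weight_quan: 0}
  - {id: dementia,                name: "Dementia",                         weight_original: 1, weight_quan: 2}
  - {id: chronic_pulmonary,       name: "Chronic pulmonary disease",        weight_original: 1, weight_quan: 1}
  - {id: rheumatic,               name: "Rheumatic disease",                weight_original: 1, weight_quan: 1}
  - {id: peptic_ulcer,            name: "Peptic ulcer disease",             weight_original: 1, weight_quan: 0}
  - {id: liver_mild,              name: "Mild liver disease",               weight_original: 1, weight_quan: 2}
  - {id: diabetes_uncomplicated,  name: "Diabetes without complications",   weight_original: 1, weight_quan: 0}
  - {id: diabetes_complicated,    name: "Diabetes with complications",      weight_original: 2, weight_quan: 1}
  - {id: hemiplegia_paraplegia,   name: "Hemiplegia or paraplegia",         weight_original: 2, weight_quan: 2}
  - {id: renal,                   name: "Renal disease",                    weight_original: 2, weight_quan: 1}
  - {id: malignancy,              name: "Any malignancy incl. leukaemia and lymphoma", weight_original: 2, weight_quan: 2}
  - {id: liver_moderate_severe,   name: "Moderate or severe liver disease", weight_original: 3, weight_quan: 4}
  - {id: metastatic_solid_tumour, name: "Metastatic solid tumour",          weight_original: 6, weight_quan: 6}
  - {id: aids_hiv,                name: "AIDS/HIV",                         weight_original: 6, weight_quan: 4}
elixhauser:
  - {id: congestive_heart_failure, name: "Congestive heart failure"}
  - {id: cardiac_arrhythmias,     name: "Cardiac arrhythmias"}
  - {id: valvular_disease,        name: "Valvular disease"}
  - {id: pulmonary_circulation,   name: "Pulmonary circulation disorders"}
  - {id: peripheral_vascular,     name: "Peripheral vascular disorders"}
  - {id: hypertension_uncomplicated, name: "Hypertension, uncomplicated"}
  - {id: hypertension_complicated, name: "Hypertension, complicated"}
  - {id: paralysis,               name: "Paralysis"}
  - {id: other_neurological,      name: "Other neurological disorders"}
  - {id: chronic_pulmonary,       name: "Chronic pulmonary disease"}
  - {id: diabetes_uncomplicated,  name: "Diabetes, uncomplicated"}
  - {id: diabetes_complicated,    name: "Diabetes, complicated"}
  - {id: hypothyroidism,          name: "Hypothyroidism"}
  - {id: renal_failure,           name: "Renal failure"}
  - {id: liver_disease,           name: "Liver disease"}
  - {id: peptic_ulcer,            name: "Peptic ulcer disease excluding bleeding"}
  - {id: aids_hiv,                name: "AIDS/HIV"}
  - {id: lymphoma,                name: "Lymphoma"}
  - {id: metastatic_cancer,       name: "Metastatic cancer"}
  - {id: solid_tumour,            name: "Solid tumour without metastasis"}
  - {id: rheumatoid_arthritis,    name: "Rheumatoid arthritis / collagen vascular diseases"}
  - {id: coagulopathy,            name: "Coagulopathy"}
  - {id: obesity,                 name: "Obesity"}
  - {id: weight_loss,             name: "Weight loss"}
  - {id: fluid_electrolyte,       name: "Fluid and electrolyte disorders"}
  - {id: blood_loss_anaemia,      name: "Blood loss anaemia"}
  - {id: deficiency_anaemia,      name: "Deficiency anaemia"}
  - {id: alcohol_abuse,           name: "Alcohol abuse"}
  - {id: drug_abuse,              name: "Drug abuse"}
  - {id: psychoses,               name: "Psychoses"}
  - {id: depression,              name: "Depression"}
hierarchy:
  charlson:
    - {severe: diabetes_complicated,    superseded: diabetes_uncomplicated}
    - {severe: liver_moderate_severe,   superseded: liver_mild}
    - {severe: metastatic_solid_tumour, superseded: malignancy}
  elixhauser:
    - {severe: hypertension_complicated, superseded: hypertension_uncomplicated}
    - {severe: metastatic_cancer,        superseded: solid_tumour}
    - {severe: diabetes_complicated,     superseded: diabetes_uncomplicated}
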