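# Original Charlson comorbidity condition groups and integer weights.
# Hierarchies: when both members are present only the higher-weighted counts.
weights:
  myocardial_infarction: 1
  congestive_heart_failure: 1
  peripheral_vascular_disease: 1
  cerebrovascular_disease: 1
  dementia: 1
  chronic_pulmonary_disease: 1
  connective_tissue_disease: 1
  peptic_ulcer_disease: 1
  mild_liver_disease: 1
  diabetes: 1
  hemiplegia: 2
  moderate_severe_renal_disease: 2
  diabetes_with_complications: 2
  any_malignancy: 2
  leukemia: 2
  lymphoma: 2
  moderate_severe_liver_disease: 3
  metastatic_solid_tumor: 6
  aids: 6
hierarchies:
  - [diabetes, diabetes_with_complications]
  - [mild_liver_disease, moderate_severe_liver_disease]
  - [any_malignancy, metastatic_solid_tumor]
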