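{
 "_note": "Charlson condition weights. 'charlson_original' from Charlson et al. 1987; 'quan_updated' from Quan et al., Am J Epidemiol 2011;173:676-82.",
 "hierarchy": [
  [
   "metastatic_solid_tumor",
   "any_malignancy"
  ],
  [
   "moderate_severe_liver_disease",
   "mild_liver_disease"
  ],
  [
   "diabetes_with_complication",
   "diabetes_without_complication"
  ]
 ],
 "tables": {
  "charlson_original": {
   "myocardial_infarction": 1,
   "congestive_heart_failure": 1,
   "peripheral_vascular_disease": 1,
   "cerebrovascular_disease": 1,
   "dementia": 1,
   "chronic_pulmonary_disease": 1,
   "rheumatic_disease": 1,
   "peptic_ulcer_disease": 1,
   "mild_liver_disease": 1,
   "diabetes_without_complication": 1,
   "diabetes_with_complication": 2,
   "hemiplegia_paraplegia": 2,
   "renal_disease": 2,
   "any_malignancy": 2,
   "moderate_severe_liver_disease": 3,
   "metastatic_solid_tumor": 6,
   "aids_hiv": 6
  },
  "quan_updated": {
   "myocardial_infarction": 0,
   "congestive_heart_failure": 2,
   "peripheral_vascular_disease": 0,
   "cerebrovascular_disease": 0,
   "dementia": 2,
   "chronic_pulmonary_disease": 1,
   "rheumatic_disease": 1,
   "peptic_ulcer_disease": 0,
   "mild_liver_disease": 2,
   "diabetes_without_complication": 0,
   "diabetes_with_complication": 1,
   "hemiplegia_paraplegia": 2,
   "renal_disease": 1,
   "any_malignancy": 2,
   "moderate_severe_liver_disease": 4,
   "metastatic_solid_tumor": 6,
   "aids_hiv": 4
  }
 }
}
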