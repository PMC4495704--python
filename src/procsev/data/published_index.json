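{
 "_note": "Integer points of the published procedure-based inpatient severity index (19 admission-day procedures; derivation cohort of 270 054 Japanese acute-care admissions, 2012-2013). Points are transcribed, not recomputed, from the published regression table.",
 "reference_coefficient": 0.091,
 "points": {
  "invasive_arterial_pressure_measurement": -3,
  "blood_tests_excluding_coagulation": -3,
  "radiography": -2,
  "urinalyses_excluding_chemistry": -2,
  "temporary_urinary_catheterization": -1,
  "endocrinology_tests": -1,
  "bacterial_microscopy_or_culture": -1,
  "bacterial_drug_susceptibility_tests": 1,
  "urine_chemistry_tests": 1,
  "heart_rate_respiration_monitoring": 2,
  "peripheral_intravenous_infusion": 2,
  "computed_tomography_scan": 3,
  "pulse_oximetry": 3,
  "gastric_drainage_tube_insertion": 4,
  "urinary_catheter_insertion": 5,
  "central_venous_catheter_insertion": 5,
  "catecholamines_or_vasopressin": 8,
  "sputum_suction": 12,
  "intratracheal_intubation": 23
 }
}
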