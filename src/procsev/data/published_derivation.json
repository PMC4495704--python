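{
 "_note": "Summary data of the published derivation cohort of the procedure-based inpatient severity index (Japanese acute-care administrative claims, FY2012): admission-day procedure usage counts by outcome, the five collinearity group policies, the regression coefficients, and study-population marginals. Used as screening/consolidation fixtures and as defaults for the synthetic cohort generator.",
 "surviving_n": 244416,
 "deceased_n": 25638,
 "procedures": [
  {
   "name": "blood_chemistry_tests",
   "surviving_with": 213046,
   "deceased_with": 22949,
   "group": "blood"
  },
  {
   "name": "hematology_tests",
   "surviving_with": 210402,
   "deceased_with": 22704,
   "group": "blood"
  },
  {
   "name": "plasma_protein_immunology_tests",
   "surviving_with": 198064,
   "deceased_with": 21896,
   "group": "blood"
  },
  {
   "name": "radiography",
   "surviving_with": 190981,
   "deceased_with": 20922,
   "group": null
  },
  {
   "name": "electrocardiogram",
   "surviving_with": 169490,
   "deceased_with": 17869,
   "group": null
  },
  {
   "name": "peripheral_intravenous_infusion",
   "surviving_with": 159043,
   "deceased_with": 18581,
   "group": null
  },
  {
   "name": "coagulation_tests",
   "surviving_with": 145418,
   "deceased_with": 15937,
   "group": null
  },
  {
   "name": "computed_tomography_scan",
   "surviving_with": 123559,
   "deceased_with": 15938,
   "group": null
  },
  {
   "name": "infectious_disease_immunology_tests",
   "surviving_with": 123481,
   "deceased_with": 12622,
   "group": null
  },
  {
   "name": "hepatitis_virus_tests",
   "surviving_with": 96552,
   "deceased_with": 9681,
   "group": null
  },
  {
   "name": "heart_rate_respiration_monitoring",
   "surviving_with": 91457,
   "deceased_with": 12770,
   "group": null
  },
  {
   "name": "pulse_oximetry",
   "surviving_with": 85254,
   "deceased_with": 13128,
   "group": "oxygen"
  },
  {
   "name": "oxygen_administration",
   "surviving_with": 74526,
   "deceased_with": 13961,
   "group": "oxygen"
  },
  {
   "name": "urine_tests_general",
   "surviving_with": 78225,
   "deceased_with": 9046,
   "group": "urine"
  },
  {
   "name": "endocrinology_tests",
   "surviving_with": 69282,
   "deceased_with": 8222,
   "group": null
  },
  {
   "name": "bacterial_culture",
   "surviving_with": 61069,
   "deceased_with": 8852,
   "group": "bacteriology"
  },
  {
   "name": "urine_microscopy",
   "surviving_with": 52891,
   "deceased_with": 6211,
   "group": "urine"
  },
  {
   "name": "immunohematology_tests",
   "surviving_with": 53197,
   "deceased_with": 5486,
   "group": null
  },
  {
   "name": "bacterial_microscopy",
   "surviving_with": 49180,
   "deceased_with": 7127,
   "group": "bacteriology"
  },
  {
   "name": "urinary_catheter_insertion",
   "surviving_with": 43933,
   "deceased_with": 9534,
   "group": null
  },
  {
   "name": "ultrasound_imaging",
   "surviving_with": 46118,
   "deceased_with": 4830,
   "group": null
  },
  {
   "name": "magnetic_resonance_imaging",
   "surviving_with": 45489,
   "deceased_with": 2615,
   "group": null
  },
  {
   "name": "acid_fast_bacilli_culture",
   "surviving_with": 20879,
   "deceased_with": 2727,
   "group": null
  },
  {
   "name": "bacterial_drug_susceptibility_tests",
   "surviving_with": 17667,
   "deceased_with": 3267,
   "group": null
  },
  {
   "name": "sputum_suction",
   "surviving_with": 13061,
   "deceased_with": 5680,
   "group": null
  },
  {
   "name": "catecholamines_or_vasopressin",
   "surviving_with": 12371,
   "deceased_with": 3143,
   "group": null
  },
  {
   "name": "red_blood_cell_transfusion",
   "surviving_with": 12268,
   "deceased_with": 1324,
   "group": null
  },
  {
   "name": "nucleic_acid_amplification_tests",
   "surviving_with": 9102,
   "deceased_with": 1178,
   "group": null
  },
  {
   "name": "tumor_markers",
   "surviving_with": 8018,
   "deceased_with": 667,
   "group": null
  },
  {
   "name": "invasive_arterial_pressure_measurement",
   "surviving_with": 5649,
   "deceased_with": 1130,
   "group": null
  },
  {
   "name": "autoantibody_tests",
   "surviving_with": 5740,
   "deceased_with": 488,
   "group": null
  },
  {
   "name": "urine_chemistry_tests",
   "surviving_with": 5130,
   "deceased_with": 654,
   "group": null
  },
  {
   "name": "gastric_drainage_tube_insertion",
   "surviving_with": 3993,
   "deceased_with": 1559,
   "group": null
  },
  {
   "name": "central_venous_catheter_insertion",
   "surviving_with": 2997,
   "deceased_with": 1346,
   "group": "central_venous"
  },
  {
   "name": "intratracheal_intubation",
   "surviving_with": 2252,
   "deceased_with": 1963,
   "group": null
  },
  {
   "name": "stool_tests",
   "surviving_with": 3377,
   "deceased_with": 311,
   "group": null
  },
  {
   "name": "central_venous_infusion",
   "surviving_with": 2467,
   "deceased_with": 1163,
   "group": "central_venous"
  },
  {
   "name": "temporary_urinary_catheterization",
   "surviving_with": 2465,
   "deceased_with": 352,
   "group": null
  }
 ],
 "groups": [
  {
   "members": [
    "blood_chemistry_tests",
    "hematology_tests",
    "plasma_protein_immunology_tests"
   ],
   "policy": "combine_any_of",
   "arg": "blood_tests_excluding_coagulation"
  },
  {
   "members": [
    "urine_tests_general",
    "urine_microscopy"
   ],
   "policy": "combine_any_of",
   "arg": "urinalyses_excluding_chemistry"
  },
  {
   "members": [
    "bacterial_microscopy",
    "bacterial_culture"
   ],
   "policy": "combine_any_of",
   "arg": "bacterial_microscopy_or_culture"
  },
  {
   "members": [
    "central_venous_infusion",
    "central_venous_catheter_insertion"
   ],
   "policy": "keep_named_first",
   "arg": "central_venous_catheter_insertion"
  },
  {
   "members": [
    "oxygen_administration",
    "pulse_oximetry"
   ],
   "policy": "keep_named_first",
   "arg": "pulse_oximetry"
  }
 ],
 "model_terms": {
  "diagnosis": {
   "acute_myocardial_infarction": 0.0,
   "congestive_heart_failure": -0.1,
   "acute_cerebrovascular_disease": -0.11,
   "gastrointestinal_hemorrhage": -0.51,
   "pneumonia": 0.04,
   "septicemia": 0.73
  },
  "sex_female": -0.12,
  "age_category": {
   "<60": 0.0,
   "60-69": 0.35,
   "70-79": 0.68,
   "80-89": 1.14,
   ">=90": 1.6
  },
  "cci_category": {
   "0": 0.0,
   "1": 0.03,
   "2": 0.182,
   ">=3": 0.72
  },
  "procedures": {
   "invasive_arterial_pressure_measurement": -0.3,
   "blood_tests_excluding_coagulation": -0.26,
   "radiography": -0.2,
   "urinalyses_excluding_chemistry": -0.18,
   "temporary_urinary_catheterization": -0.18,
   "endocrinology_tests": -0.06,
   "bacterial_microscopy_or_culture": -0.05,
   "acid_fast_bacilli_culture": -0.04,
   "coagulation_tests": -0.03,
   "nucleic_acid_amplification_tests": 0.01,
   "bacterial_drug_susceptibility_tests": 0.06,
   "urine_chemistry_tests": 0.1,
   "heart_rate_respiration_monitoring": 0.18,
   "peripheral_intravenous_infusion": 0.18,
   "computed_tomography_scan": 0.25,
   "pulse_oximetry": 0.29,
   "gastric_drainage_tube_insertion": 0.32,
   "urinary_catheter_insertion": 0.47,
   "central_venous_catheter_insertion": 0.49,
   "catecholamines_or_vasopressin": 0.7,
   "sputum_suction": 1.11,
   "intratracheal_intubation": 2.05
  }
 },
 "marginals": {
  "n_total": 539385,
  "diagnosis": {
   "acute_myocardial_infarction": 20597,
   "congestive_heart_failure": 113897,
   "acute_cerebrovascular_disease": 180054,
   "gastrointestinal_hemorrhage": 69502,
   "pneumonia": 136773,
   "septicemia": 18562
  },
  "male": 310130,
  "age_category": {
   "<60": 74788,
   "60-69": 94068,
   "70-79": 146977,
   "80-89": 169929,
   ">=90": 53623
  },
  "cci_category": {
   "0": 323635,
   "1": 68322,
   "2": 105529,
   ">=3": 41899
  },
  "death_rate": 0.095
 }
}
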