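"""Compute the Charlson comorbidity index from present-on-admission ICD-10
codes, with the bundled Quan condition map and both weight tables."""
from procsev import cci_score, load_weights, map_conditions

patients = {
    "uncomplicated diabetic": ["E11.9"],
    "heart failure + COPD": ["I50.9", "J44.1"],
    "metastatic lung cancer": ["C34.1", "C78.0"],
    "no comorbidity codes": [],
}

quan = load_weights("quan_updated")
orig = load_weights("charlson_original")

for label, codes in patients.items():
    conditions = map_conditions(codes)
    s_quan, cat = cci_score(conditions, quan)
    s_orig, _ = cci_score(conditions, orig)
    print(f"{label:26s} codes={codes!r:24s} conditions={sorted(conditions)}")
    print(f"{'':26s} CCI (Quan-updated) = {s_quan} (category {cat}); "
          f"original weights = {s_orig}")

print("\nHierarchy note: metastatic disease supersedes 'any malignancy', "
      "so the\nlung-cancer patient scores the metastatic weight alone, not "
      "the sum.")
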