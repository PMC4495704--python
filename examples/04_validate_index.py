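"""Validate the published index on a held-out synthetic cohort.

Fits the four standard mortality models, compares their c-statistics,
computes the IDI of adding the index to the demographic model, the omega
variance-ratio of the index's contribution, and the calibration tables.
"""
import warnings

from procsev import (FeatureCatalog, add_severity_index, consolidated_catalog,
                     default_config, generate, feature_frame, published_index,
                     run_validation)
from procsev.published import published_groups

cfg = default_config(n=40_000)
cohort = generate(cfg, seed=4)
catalog = consolidated_catalog(
    FeatureCatalog.identity([p.name for p in cfg.procedures]),
    published_groups())
with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    frame = feature_frame(cohort, catalog)
    scored = add_severity_index(frame, published_index())
    report = run_validation(scored, n_boot=50, seed=0,
                            subgroup_columns=("ambulance",))

print(f"n = {report.n}, death rate = {report.death_rate:.3f}")
for label in ("model1", "model2", "model3", "model4"):
    m = report.models[label]
    lo, hi = m["ci95"]
    print(f"  {label}: c = {m['c']:.3f} (95% CI {lo:.3f}-{hi:.3f})")
idi = report.idi
print(f"  IDI (model 4 vs 3) = {idi['estimate']:.4f} "
      f"(95% CI {idi['ci95'][0]:.4f}-{idi['ci95'][1]:.4f})")
om = report.omega
print(f"  omega = {om['estimate']:.2f} "
      f"(95% CI {om['ci95'][0]:.2f}-{om['ci95'][1]:.2f})")
print("  per-diagnosis c-statistics:")
for name, s in report.subgroups.items():
    if name.startswith("diagnosis="):
        print(f"    {name.split('=')[1]:32s} c = {s['c']:.3f} "
              f"(n={s['n']}, mortality {s['mortality']:.3f})")

print("\nmodel 3 uses demographics + CCI only; adding the index (model 4) "
      "raises\nthe c-statistic and yields a positive IDI. omega ~ 1 means "
      "the index\ncontributes about as much log-odds variance as all other "
      "covariates combined.")
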