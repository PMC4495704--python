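"""Derive a point table end to end on a synthetic cohort.

Generates admissions under the published study conditions (marginals,
procedure prevalences, co-occurrence blocks, true coefficients), then runs
the three derivation stages: prevalence/chi-square screening, phi-based
consolidation, and the logistic fit with Sullivan point assignment.
"""
import warnings

from procsev import (FeatureCatalog, RunConfig, default_config, derive,
                     feature_frame, generate, index_range)
from procsev.published import published_groups

cfg = default_config(n=60_000)  # modest size so the example runs in seconds
cohort = generate(cfg, seed=2)
names = [p.name for p in cfg.procedures]
frame = feature_frame(cohort, FeatureCatalog.identity(names))
print(f"generated {len(frame)} admissions, "
      f"death rate {frame['death'].mean():.3f}")

with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    result = derive(frame, names,
                    RunConfig(group_policies=published_groups()))

retained = sum(r.retained for r in result.screening)
print(f"screening retained {retained} of {len(result.screening)} procedures")
print(f"consolidation left {len(result.candidate_variables)} candidates "
      f"({len(result.groups)} correlated groups)")
print(f"reference coefficient "
      f"{result.point_table.reference_coefficient:.4f}")
lo, hi = index_range(result.point_table)
print(f"derived point table ({len(result.point_table)} procedures, "
      f"range [{lo}, {hi}]):")
for name, pts in sorted(result.point_table.points.items(),
                        key=lambda kv: kv[1]):
    print(f"  {pts:+3d}  {name}")

print("\nWith the published coefficients as ground truth, the derived "
      "points track\nbeta/0.091 up to sampling noise in the fitted betas "
      "and the CCI anchor.")
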