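# Methods

## The index and its derivation

The severity index summarises admission-day procedure usage as a single
integer. Its derivation has three stages, each with explicit, configurable
thresholds (defaults in parentheses):

1. **Screening.** For every procedure with prevalence ≥ `prevalence_threshold`
   (0.01) in the derivation cohort, a Pearson χ² test (1 df, *no* continuity
   correction) against in-hospital death is computed from the 2×2 table.
   Procedures are retained when P < `screen_p_threshold` (0.1) *and* the
   usage rate is higher among the deceased. The uncorrected Pearson variant
   is pinned down by the bundled published screening counts: it is the only
   common variant whose P values match the printed non-significant rows
   (0.244, 0.909, 0.313, 0.175, 0.027) to three decimals. Ties in the usage
   rates count as "no direction" and are not retained. No multiplicity
   adjustment is applied at this stage, by design.

2. **Consolidation.** Retained procedures with pairwise φ > `phi_threshold`
   (0.6, strict) are linked; *connected components* of this graph form the
   correlation groups. Components rather than cliques: the published
   description speaks of "groups" without defining transitivity, and
   components are deterministic and order-independent. Whether a group's
   members are performed simultaneously (combine as an any-of indicator) or
   consecutively (keep the one performed first) is clinical knowledge, so it
   is configuration; the five published group policies ship as defaults, and
   unconfigured groups fall back to combine-any-of with a warning. φ is
   thresholded as signed φ, not |φ|: co-occurring procedures correlate
   positively, and the published description gives no sign convention.

3. **Regression and points.** A maximum-likelihood logistic model of death
   on diagnosis, sex, age band and CCI category (dummy-coded; references
   AMI, male, <60, CCI=0) plus the consolidated procedure indicators.
   Newton iterations, relative convergence 1e-8, at most 100 iterations;
   rank-deficient designs and non-convergence raise errors naming the
   aliased terms / iteration diagnostics. Wald tests drive both
   significance gates (conventional for regression-table output; the
   likelihood-ratio alternative is not implemented). Points follow the
   Sullivan rule: `round(β_j / β_ref)` for each procedure significant at
   `significance_level` (0.05), with exact halves rounded away from zero
   (symmetric for negative points; published derivations never hit an exact
   tie). The anchor β_ref is β(CCI=1) when that level is significantly
   harmful, else β(CCI=2)/2; if neither level is significant the package
   raises rather than guess — no further fallback is defined anywhere.

Scoring is additive over performed procedures; indicator names missing from
a feature vector count as "not performed" with a warning. The attainable
range is the sum of negative points to the sum of positive points
(−13…69 for the bundled published table).

## Charlson comorbidity index

Present-on-admission ICD-10 codes are mapped to the 17 Charlson conditions
by uppercase, dot-insensitive prefix matching (the Quan coding algorithm,
transcribed into `data/charlson_icd10_quan.json`). Three hierarchy rules
suppress the milder partner (metastatic > any malignancy, moderate/severe >
mild liver disease, complicated > uncomplicated diabetes) before weights are
summed. Two weight tables ship: the original 1987 weights and the
Quan-updated weights; the default is Quan-updated, matching the weight
reference the original index derivation cites. A precomputed per-admission
CCI column is accepted as an alternative input, bypassing code mapping
entirely. Categories are 0 / 1 / 2 / ≥3.

## Validation metrics

* **c-statistic** — concordant pairs plus half-ties over events ×
  non-events, computed via midranks; 95 % CI by the DeLong
  structural-component variance (the original publication does not name its
  CI method; DeLong is the reproducible standard).
* **IDI** — difference in discrimination slope between two models; its CI
  uses the usual normal approximation with per-outcome-class standard
  errors of the mean probability difference.
* **ω** — Var(index contribution) / Var(other covariates' contribution)
  across patients, in the full model; CI by seeded nonparametric bootstrap
  over patients with a per-replicate refit (percentile method, default
  B = 200). The analytic variance of the source publication for ω is not
  restated there, hence the bootstrap.
* **Hosmer–Lemeshow table** — patients ranked by predicted risk, cut into
  g = 10 near-equal groups; ties at boundaries stay together in the
  lower-risk group (deterministic). Expected counts are sums of predicted
  probabilities and conserve their total exactly.
* **Per-index-value calibration** — one bin per distinct index value;
  sparse values are merged with adjacent values, sweeping inward from both
  extremes (plus a safety pass for interior gaps), until every bin holds at
  least 1 % of patients. Observed-rate CIs use the Wald binomial
  approximation, adequate at the ≥1 % bin sizes the rule guarantees.

Model battery: model 1 = index (continuous); model 2 = index + diagnosis +
age + sex; model 3 = diagnosis + age + sex + CCI; model 4 = all. IDI
compares 4 vs 3; ω is computed in model 4; subgroup c-statistics refit
model 4 per stratum and an index+age+sex+CCI model per diagnosis. Subgroups
with a single outcome class are skipped with a warning.

## Synthetic cohort generator

The generator draws admissions with (i) demographics sampled independently
from the published study-population marginals (six diagnoses, sex, five age
bands, four CCI categories — emitted both as ICD-10 codes consistent with
the default weight table and as a precomputed score), (ii) 38 admission-day
procedure indicators at the published prevalences, and (iii) death from a
logistic model whose coefficients default to the published regression table
(22 consolidated candidate variables), with the intercept calibrated by
root-finding so the realised death rate matches 9.5 %.

Two structural choices make the generator exercise the pipeline the way
real claims data would:

* **Co-occurrence blocks.** Members of each of the five published groups
  share a latent binary cause (member = latent ∧ Bernoulli thinning, with
  the latent's prevalence set just above the largest member's, coupling
  0.995). This pushes within-block φ to ~0.7–0.9 — above the 0.6 grouping
  threshold — while cross-block φ stays below ~0.1.
* **Acuity loading.** Each procedure's logit loads on an observed acuity
  score `z = 0.4·(age band index − mean) + 0.3·(CCI category index − mean)`.
  Sicker patients receive more procedures, so routine tests whose
  *conditional* effect on death is protective (negative β) remain
  *marginally* associated with death — the confounding pattern that lets
  the positive-direction screening rule retain them, as it did in the
  original data. Loadings are set per procedure as
  `(published marginal log-OR − β) / K` with K = 0.42, the induced marginal
  log-OR per unit loading measured once by simulation with zero-effect
  probe procedures under the default death model. Because z is a function
  of covariates that are all in the regression model, the model remains
  correctly specified and the fit is consistent for the true β.
  Per-procedure intercepts are calibrated by root-finding of the exact
  expectation over the discrete z distribution, so empirical prevalences
  match their targets to binomial accuracy.

What the generator does **not** emulate: hospital-level clustering,
length-of-stay dynamics, seasonal effects, within-procedure heterogeneity
(number/type of tested items), dependence of the strata labels (ambulance,
referral, hospital type) on severity, and any direct dependence of
procedures on the diagnosis. Passing tests therefore show that the
pipeline's statistics behave correctly under a faithful-but-idealised data
generating process; they do not certify performance on real claims data.

### Reference-coefficient variability (a known, deliberate behaviour)

The Sullivan anchor is an *estimated* quantity. With the published truth
(β(CCI=1)=0.03, β(CCI=2)=0.182) at n = 200 000, β̂(CCI=2)/2 carries ~10 %
relative sampling error that scales every point ratio coherently, and
CCI=1 itself crosses the 0.05 significance gate at a sizeable fraction of
seeds (switching the anchor to ~0.03–0.05 and inflating all points).
Likewise the smallest candidate coefficients (|β| ≈ 0.04–0.10) sit on the
significance boundary, so their table membership varies by seed. This is
faithful behaviour of the published rule, not an implementation artefact;
consequently exact point-for-point reproduction of the published table from
a finite synthetic cohort is not statistically guaranteed, and the
end-to-end checks that report agreement counts should be read with that in
mind. Derivations on real data at larger n (or with a fixed, externally
supplied reference) do not share the gate-flip issue.

## Problem sizes used by the shipped checks

The test suite shares one seeded cohort of 200 000 admissions for the
distributional checks and runs one end-to-end derivation/validation at
400 000 admissions (200 000 per half); the acceptance script repeats that
end-to-end run at the same sizes with the caller's seed and uses B = 100
bootstrap replicates for the ω interval. Examples use 40 000–60 000
admissions so they complete in seconds.

## Numerical and degenerate-input conventions

Day offsets are 0-based (admission day = 0); age bands close on the left
([60,70) → "60–69"). Exclusion reasons are disjoint with precedence
under-18 > ICU > life support. χ² and φ are undefined on tables with an
empty margin and raise; constant screening features are marked
not-retained with a diagnostic instead. The cohort split is shuffle-then-
cut (sizes within one of n·fraction); a Bernoulli per-admission split is
available by flag. All randomness flows through explicit seeds; identical
configurations reproduce byte-identical outputs.
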