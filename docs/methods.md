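# Methods

## The measure

The continuous mental-health score combines two constructs. Subjective
well-being is built from life satisfaction (Cantril ladder, 0–10), a single
positive-affect item, and two negative-affect items; psychopathology from a
four-item internalized-symptoms subscale (0–16) and a seven-behavior overt
risk-taking scale (0–14, each behavior coded None = 0 / Infrequent = 1 /
Frequent = 2). Every 5-level Likert or frequency item is coded 0–4 after
orientation — the only coding consistent with the instruments' declared
ranges (four items, range 0–16) — and a scale score is the plain sum of its
oriented item codes.

Scoring then proceeds in stages: each subscale is T-standardized
(mean 50, SD 10); `SWB = T(LS) + T(PA) − T(NA)` and `PTH = T(INT) + T(EXT)`
are each re-standardized; the final score is the standardized difference
`T(T(SWB) − T(PTH))`. Because the last step is itself a T-standardization,
the score has unweighted mean 50 and SD 10 over the scoring sample by
construction (to ~1e-12; enforced in tests at 1e-9).

Numerical conventions, fixed for bit-for-bit reproducibility:

* standardization moments are **unweighted** over students with
  non-missing inputs at that stage; survey weights enter only in
  descriptive and validation analyses. (A survey-weighted mean of a score
  standardized unweighted is close to, but not exactly, 50 — consistent
  with how such scores are reported in practice.)
* sample SD uses the n−1 denominator;
* missing items are never imputed: a scale score is missing if any
  constituent item is missing, and each standardization stage simply drops
  missing inputs. A stage with fewer than two observed inputs yields
  missing T-scores with a logged warning; a *constant* observed input is a
  hard error (no silent all-50 column);
* every stage's (mean, SD) pair is saved as a calibration (JSON) so new
  data can be scored against a frozen reference sample.

The four-group categorization is a quadrant rule on `(T(SWB), T(PTH))`
with configurable cutoffs; ties count as "high" on both axes. The default
(50, 50) is a neutral placeholder: published group prevalences depend on
instrument-specific cutoffs defined outside this package, so prevalence
claims require explicitly configured thresholds.

## Validity analysis

* **Complete cases.** Analyses of covariate effects drop students missing
  any analysis variable, and the attrition report compares included vs
  excluded students on age (Welch t), sex, affluence, and self-rated
  health (chi-square).
* **Quartile binning.** Continuous covariates are cut at the weighted
  25/50/75th percentiles (inverse-CDF weighted quantiles: smallest value
  whose cumulative weight fraction reaches the target). Ties at a cut
  fall in the lower-score bin, so bins on discrete scales are
  "approximate" and may be unequal; labels run High/Q2/Q3/Low with High =
  most supportive.
* **Weighted descriptives.** Weighted SD and skewness normalize by the
  weight total (population-moment definitions, no small-sample
  correction); skewness is `g1 = m3 / m2^{3/2}`.
* **Cohen's d** uses the *unweighted* pooled SD, `sqrt((s₁² + s₂²)/2)`,
  applied to the raw weighted group means/SDs — not model-adjusted means.
  This is a deliberate, discriminating choice: it reproduces the published
  validation table's d values exactly at two decimals (45 of 47 printed
  cells; one further cell is consistent up to rounding of its printed
  inputs, and one printed cell is internally inconsistent with its printed
  summaries under any pooling form), whereas the classical n-weighted
  pooled SD does not (e.g. 1.67 vs the printed 1.63 for family support).
  Positive d means the comparison group scores lower than the reference.
* **Clustered comparisons.** `outcome ~ C(group) + C(age_band) + C(sex)`
  with a random school intercept, fit by REML (statsmodels MixedLM).
  Adjusters equal to the tested covariate are dropped (the sex contrast is
  age-adjusted only, and vice versa). Age enters as the reporting bands
  ≤11/12/13/14/≥15. Trend tests refit with the ordered groups coded
  1..k as a numeric term. MixedLM does not accept analytic weights, so the
  adjusted p-values are unweighted while every descriptive quantity is
  survey-weighted; with weights independent of the outcome (as in the
  generator) the two estimands coincide. A singular or failed fit reports
  ICC 0 with a note instead of raising. No multiple-testing adjustment is
  applied (per-contrast p-values are reported as-is).
* **ICC** is `σ²_school / (σ²_school + σ²_residual)` from the
  random-intercept components; the headline ICC comes from the null model.
* **Power.** The minimal detectable difference uses the two-sample normal
  approximation `(z_{1−α/2} + z_{power}) · sd · sqrt(1/n₁ + 1/n₂)`.

## Synthetic cohorts

The generator emulates the study conditions the measure was developed
under: 400 schools × ~50 students (n = 20,000), a school-level variance
fraction of 0.038 on the measured score, scale reliabilities implied by the
instruments' published alphas (0.75–0.92, converted to mean inter-item
correlations by inverting Spearman–Brown), survey weights assigned by
grade-within-region strata (lognormal, CV 0.3, mean exactly 1, independent
of mental health), covariate prevalences and effect-size targets matching
the published validation table (d from 0.30 for sex to 1.63 for family
support), and item-level missingness completely at random at 0.4% per
response — chosen so that roughly 85% of students have complete analysis
data, as in the source study.

Structure: latent well-being W and psychopathology P are unit-variance
factors with correlation −0.5 by default (the two constructs are related
but distinct; a moderate negative association populates all four quadrants
of the categorical classification). Each factor splits into school and
student components with the *same* correlation structure at both levels,
so every linear combination of (W, P) — including the measured score —
has the same school-variance fraction. Items load on W or P with loading
`sqrt(r̄)` and are discretized at equal-probability normal cuts.

Two calibrations make the emitted cohort meet its targets on the scale the
analysis actually sees rather than on the error-free latents:

1. **ICC inflation.** Item noise and discretization attenuate the measured
   score's school fraction to `f · R²`, where R² (~0.88 at default
   reliabilities) is the share of measured-score variance explained by
   (W, P). The generator estimates R² by regression on an internal pilot
   draw (n = 6,000, its own seed stream) and sets the latent fraction to
   `icc_school / R²`.
2. **Effect-size calibration.** Covariate groups are slices of a latent
   `C = ρ·Ẑ + sqrt(1−ρ²)·ε`, where Ẑ is the realized measured score of
   the cohort being generated. Truncated-normal slice moments give a
   closed-form ρ for any target d and group prevalences
   (`rho_for_target_d`), but the measured score's thin tails and the
   tie-afflicted quartile bins of discrete scale scores leave that
   analytic value a few percent short. The generator therefore fixes all
   noise draws and root-finds ρ on the realized d in the generated sample
   itself (Brent's method, xtol 1e-4), so the round-trip recovery of d
   through score-then-validate is limited only by the analysis-side
   sampling noise (complete-case restriction and weighting), about ±0.05
   at n = 20,000.

Multi-item covariate scales (family/peer/student/teacher support,
prosocial) are emitted as items from a scale factor correlated with Ẑ, so
the analysis must rebuild and re-bin them, exercising the whole pipeline.
Self-rated health is emitted as four labels (Excellent/Good/Fair/Poor,
with Fair+Poor calibrated jointly because the analysis collapses them).

An optional skew mode (`CohortConfig.with_skew(1.6)`) tilts the item-cut
probabilities geometrically — well-being items toward their ceiling,
symptom items toward their floor — which reproduces the left skew of real
adolescent mental-health scores (realized skewness ≈ −0.7 vs the symmetric
default's ≈ 0). The d calibration is still applied on the realized sample,
so targets hold under skew as well.

What the generator does **not** emulate: multistage survey sampling and
informative nonresponse (weights and missingness are independent of the
outcome), correlations *between* covariate blocks beyond what they share
through the latent score (real affluence and support are directly
correlated), item-level residual correlations, and school-by-covariate
interactions. Passing recovery tests therefore show the pipeline is
correct under a faithful-but-idealized data-generating process, not that
the measure is unbiased under real survey complexities.

## Problem sizes and test design

Recovery checks run at the study's own scale (20,000 students / 400
schools), where ICC is recoverable to ±0.01 and d to ±0.1; type-I
calibration uses 1,000 replicates of 500 students in 20 schools (rejection
rate 0.05 ± 0.015); smaller fixtures (≤ 8,000 students) cover everything
that does not need that precision. Property tests (orientation reversal,
affine invariance, permutation invariance, monotonicity, partition of the
four groups) are seeded/derandomized.

## Known limitations

* The mixed model is unweighted (backend limitation, documented above);
  descriptives and effect sizes are weighted.
* Group-prevalence replication for the four-category classification is out
  of scope: the external cutoffs are not part of this package.
* The SWB and PTH components are equally weighted by design; differential
  weighting (e.g. favoring SWB) is deliberately not implemented.
* `cronbach_alpha` requires complete item data; scores with missing items
  are excluded upstream by the no-imputation rule.
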