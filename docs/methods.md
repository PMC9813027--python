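# Methods

## Data model and scales

The analysis unit is the breast; breasts come in pairs within patients, and
the patient is the clustering unit for case-level inference. Truth is
three-valued (malignant / biopsy-proven benign / normal-negative after
one-year follow-up); for ROC and specificity the positive class is
malignant and *both* other classes are negatives — benign lesions are not
dropped, they are hard negatives.

Two rating scales per reading mode:

* **POM-completed scale.** The elicitation protocol collects a 0–100
  probability of malignancy only for BI-RADS ≥ 3. For an ROC over all
  breasts, BI-RADS 1 and 2 are mapped to −2 and −1: below every legal POM
  (0 is a legal value, distinct from "absent") while preserving the 1 < 2
  ordering. Empirical ROC analysis is invariant to any strictly increasing
  re-encoding, so only the ordering is a commitment. A variant collapsing
  1 and 2 to a single rank is available (`distinguish_birads12=False`)
  because the elicitation protocol leaves that choice open.
* **Forced BI-RADS scale.** The ordinal 1–5 score itself, giving at most
  four interior operating points.

Positivity for sensitivity/specificity is BI-RADS ≥ 4. Counts are pooled
over readers (reader-averaging coincides with pooling in a complete fully
crossed design, but pooled counts are the declared reference). Finding-type
strata are lesion strata: soft-tissue = {mass, mass with calcifications,
focal asymmetry}, calcification = {calcification}; their specificity
denominators are the benign lesions of the stratum only, since finding
type is a lesion attribute and normal-negative breasts have none.
Architectural distortions are reported descriptively and belong to neither
group.

## Empirical ROC and AUC

Operating points sweep the distinct score thresholds ("positive if
score ≥ t"); the AUC is the trapezoidal area, identical to the
tie-corrected Mann–Whitney pair statistic. Ties get half credit,
deterministically — never broken at random. Single-class inputs raise; the
bootstrap layer treats them as degenerate resamples. The ROC plumbing uses
`sklearn.metrics.roc_curve`; the test suite verifies the trapezoid against
an independent brute-force pair-counting oracle, and the midrank formula
used on the bootstrap fast path against both.

## Two-way bootstrap inference

The reader-averaged statistic (AUC, or a stratum sensitivity/specificity)
is compared between two modes under a random-reader random-case view:

1. **Case resampling** draws patients with replacement; a drawn patient
   contributes both breasts with all their ratings. This preserves the
   within-patient correlation that motivates clustering at the patient
   level. (Breast-level resampling is available behind
   `cluster_key="breast"` for sensitivity analysis.) Resampling is not
   stratified by truth class; a resample on which the statistic is
   undefined (e.g. single-class) is redrawn from the same substream, with
   the count reported as `n_degenerate_skipped`.
2. **Reader resampling** draws reader identities with replacement, nested
   within each case resample: 1000 case × 100 reader resamples = 100,000
   paired differences by default.
3. The statistic is computed for both modes on the *same* resampled cases
   and readers, so the contrast is fully paired.

**Reader-component correction.** The case bootstrap regenerates each
reader's case-level noise, so the between-reader spread of per-reader
differences within a case resample is part noise, part genuine
reader-by-modality heterogeneity. Naive reader draws re-add the whole
spread and over-disperse the bootstrap distribution — measured on this
package's null simulations, bootstrap SD ≈ 0.021 against a true sampling
SD ≈ 0.013, collapsing the type-I error to ≈ 0.005 at nominal 0.05. The
default scheme therefore estimates the genuine heterogeneity component as

    sigma2_reader = max(0, s2_obs − (v̄ − c̄))

where `s2_obs` is the observed between-reader variance of the full-data
per-reader differences and `v̄ − c̄` (mean variance minus mean covariance of
per-reader differences across case resamples) is its case-noise
expectation; reader-draw deviations are rescaled to contribute exactly
`sigma2_reader / R`. This is a components-of-variance bootstrap in spirit,
while keeping percentile inference and the nested 1000 × 100 structure.
Monte-Carlo calibration under the generator: type-I ≈ 0.03–0.06 and 95% CI
coverage ≈ 0.95–0.98. The uncorrected scheme remains available
(`reader_correction="naive"`) and is strictly conservative.

**Quantiles and P values.** The CI is nearest-rank percentile: with B
sorted differences the q-quantile is the ⌈qB⌉-th order statistic. The
two-sided P value is `p = 2·min((#{d ≤ 0}+1)/(B+1), (#{d ≥ 0}+1)/(B+1))`,
capped at 1; the +1 correction keeps p > 0 at finite B. Determinism: one
master seed, one spawned substream per case-resample iteration plus one for
the reader-draw matrix, so results are independent of execution order.

Closed-form MRMC variance decompositions (Obuchowski–Rockette, DBM ANOVA)
and multiplicity adjustment across contrasts are out of scope; inference is
at an unadjusted 0.05.

## Synthetic-study generator

The generator exists so every pipeline stage is testable against known
truth; its parameters are conventions, not estimates of any real study's
raw data (which were never released).

**Latent model.** `x = μ(class, mode) + r_j + c_k + rc_jk + ε`, with
reader effect `r_j ~ N(0, 0.0225)`, case effect `c_k` with variance 0.6
and within-patient correlation ρ = 0.3, interaction `rc_jk ~ N(0, 0.2)`,
and unit residual (the residual fixes the scale). Reader, case and
interaction effects are shared across all four modes, so mode contrasts
are paired through the latent structure; only the residual and the mode
shift differ between modes. Normal-negative breasts sit at 0; benign
lesions at +0.3 (biopsy-proven benign cases drew real suspicion; the value
is a knob, chosen as a modest fraction of the malignant shift); malignant
breasts at a per-mode μ. Optional `(mode, finding-type)` increments let
tests build scenarios such as "synthesized mammography better on
soft-tissue, worse on calcifications" without claiming real effect sizes.

**Scales.** BI-RADS is the latent score cut at (0.5, 1.3, 2.1, 3.2); the
third cutpoint is placed so the DM arm operates near 94% specificity at
BI-RADS ≥ 4, a plausible diagnostic-setting operating point. POM (emitted
only for BI-RADS ≥ 3) is `round(100·logistic((x − 3.0)/1.2))` — a rounded
monotone map, hence rank-consistent with the latent score within reader ×
mode. No additive jitter is applied: jitter would break exactly the
rank-consistency invariant the generator guarantees, and integer rounding
already provides bounded quantization.

**Calibration.** Per-mode μ is chosen so the *population AUC of the
emitted POM-completed score* equals the configured target (defaults
0.871 / 0.902 / 0.895 / 0.909 for DM / AICAD_SM / DM_DBT / AICAD_SM_DBT).
Because BI-RADS 1–2 collapse to two tied ranks, that AUC is below the
latent-scale binormal value by ≈ 0.01 at these operating points; ignoring
the censoring would bias every downstream recovery check. The censored
mixture AUC is computed by Gauss–Legendre integration over the
continuous-vs-censored pair probabilities, mixing normal and benign
negatives, with Gauss–Hermite averaging over the reader effect, and
inverted by Brent's method; the closed form `μ = √(2v)·Φ⁻¹(AUC)` applies
when nothing is censored and no benign shift is present, and is exposed as
the no-censoring path of `calibrate_mu`. Residual quantization of POM to
101 levels contributes < 0.001 and is neglected. Monte-Carlo check: mean
recovered reader-averaged AUC difference 0.0295–0.032 over 100 replicate
studies against a population value of 0.031.

**Composition.** 194 patients × 2 breasts; 84/83/221 truth classes;
finding-type margins (malignant/benign) mass 49/34, mass + calcification
15/1, focal asymmetry 2/3, distortion 4/6, calcification 14/39; 206
non-dense breasts assigned at the patient level (both breasts alike, one
split patient if the margin is odd). All margins are exact in every
dataset, not in expectation. Scaled designs apportion the margins by
largest remainder (`SimConfig.with_composition`). Malignant histology
labels follow the design's distribution; lesion sizes are log-normal
within type-specific clips (malignant masses center on ~19 mm). Unilateral
patients are unsupported: two breasts per patient keeps the cluster
bootstrap exact.

**What the generator does not emulate.** Reading-order and wash-out
effects; within-session correlation beyond the shared latent effects (the
2D and +DBT scores of a session share case/reader/interaction effects plus
a mode shift — nothing more); reader-specific skill differences in
discriminability (the reader effect shifts a reader's operating points,
not their population AUC); images, localization, and morphology
descriptors. Passing tests therefore demonstrate the pipeline's
correctness and calibration under this structure, not the behavior of any
particular clinical dataset.

## Numerical and reporting conventions

* Full precision internally; rounding half-up once at serialization
  (3 dp AUCs, 1 dp percentages), implemented via `decimal` on the shortest
  float repr so printed-table arithmetic is reproducible.
* Mean rows are re-verified against their per-reader cells before a table
  is emitted.
* Degenerate-resample counts, seeds and resample sizes are carried in
  every analysis artifact.
* Test and acceptance problem sizes: Monte-Carlo calibration runs use 100–
  200 replicate studies at 200 × 50 bootstrap resamples — small enough to
  iterate on, large enough that binomial error on a 5% rate is ~1.5–3
  percentage points; single-study analyses use the full 1000 × 100.

## Known limitations

* The per-lesion mean BI-RADS table reports lesion size and per-mode means
  only; calcification morphology/distribution descriptors are not part of
  the truth schema.
* The noise-corrected reader component relies on the estimated covariance
  of per-reader differences across case resamples; with very few case
  resamples (≪ 100) the correction itself is noisy.
* The percentile CI is first-order; no BCa acceleration.
* Specificity conventions for lesion strata (benign lesions only) are a
  declared choice — other partitions of the negatives are defensible and
  would shift stratum specificities.
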