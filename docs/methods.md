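# Methods

This note records the statistical procedure the package implements, the
assumptions behind it, the synthetic data model used to exercise it,
and the numerical choices that were genuinely open.

## Data model

A cohort is a subjects × markers matrix of non-negative immunoassay
concentrations with three kinds of awkward cell: missing (no usable
well), below the marker's limit of detection (LOD), and observed.
Replicate wells per subject are reduced to the arithmetic mean of
non-missing replicates per marker *before* any LOD comparison; the
reduction is the simplest symmetric one and can be disabled
(`average_replicates`).  Subjects carry group (control / pancreatic /
ovarian / bladder), AJCC stage I or II for cases (with optional
sub-stage such as IA and a histology tag such as serous), age and sex.
Controls never carry a stage; validation enforces this and the matrix
dimensions.

## Preprocessing

* **Prevalence filter.** A marker is retained iff its fraction of
  missing-or-below-LOD values, pooled over cases and controls, is
  strictly below `marker_missing_max_frac` (default 0.5).  Pooling is
  the simplest reading of "fraction of values"; values exactly at the
  LOD count as observed (strict inequality for "below").  The filter is
  monotone in the threshold.
* **Left-censored imputation.** Every missing or below-LOD cell becomes
  the marker's LOD, flagged `imputed_lod` in a provenance mask.  This
  is the single-value substitution convention of the immunoassay
  field; it is idempotent and biases low quantiles upward, which is
  conservative for a classifier anchored at high specificity.
* **log2 transform** on all marker values (LOD > 0 makes it finite
  everywhere).  Age is appended untransformed — it is already on an
  interpretable linear scale and is not a concentration.

## Classifier and selection

* **Logistic regression, unpenalized**, fitted by IRLS (Newton) with
  convergence when the score (gradient) has max absolute entry below
  1e-8, at most 100 iterations.  No penalty: shrinkage would distort
  the standardized coefficients that drive both elimination and the
  reported importance.  Near-separable training sets are routine when
  thresholds target 99% specificity, so separation is not an error:
  linear predictors are capped at ±30 and the fit flagged
  `converged=False` (detected by a vanishing score with every training
  point fitted to within 1e-6 of its label, or by predictors at the
  cap).  Constant features are dropped with a warning and given zero
  coefficient.
* **Importance** of feature j in one fit is |β_j · sd_j| with sd_j the
  training standard deviation (the "standardized coefficient"
  convention); across fits, the mean of these, rescaled so the maximum
  is 100.  The rescaling is purely presentational.
* **RFE with repeated CV.** Each of `rfe_reps` (default 100)
  repetitions draws a stratified K-fold partition (K = 5), stratified
  by cancer type so every fold sees every stratum.  Per held-out fold:
  fit the full model on the other folds, remove the weakest marker by
  standardized coefficient, refit, repeat to one marker (true stepwise
  elimination — the ranking is recomputed after every removal), and
  score every panel size on the held-out fold by partial AUC.  Age is
  present in every model and exempt from elimination, since it is a
  forced covariate rather than a candidate marker.  The selected size
  maximises the mean held-out pAUC over all reps × folds (ties to the
  smaller panel); the named panel is the top `size` markers under mean
  elimination-order rank (1 = last survivor), ties alphabetical — the
  same convention caret uses to name variables at the optimal subset
  size.  Within a given fold the candidate sets are nested by
  construction.  Fits along the elimination path are warm-started from
  the parent model, which is what makes 100 × 5 × ~35-step paths cheap.

## ROC machinery

* ROC curves come from the empirical score distribution with tied
  scores collapsed into single steps; AUC is the trapezoidal area and
  equals the tie-corrected Mann–Whitney probability.
* **Partial AUC** over a specificity band [s_lo, s_hi] is the raw
  (unnormalized) trapezoidal area of TPR over FPR ∈ [1−s_hi, 1−s_lo],
  with linear interpolation at the band edges.  Maximum = band width
  (0.25 for the default [0.75, 1.00] band); the chance diagonal gives
  0.25²/2 = 0.03125.  No McClish normalization: selection by argmax is
  invariant to that affine rescaling, so only the printed scale would
  change.
* **Threshold at target specificity**: the smallest threshold t such
  that the fraction of controls with score > t is at most 1 − target.
  Positive call ⇔ score strictly above t (ties negative); with n
  controls the rule permits ⌊n(1−target)⌋ control positives, so 61
  controls at target 0.99 permit none and t is the maximum control
  score.  A small epsilon guards the floor against binary-fraction
  rounding (e.g. 10 × (1 − 0.9)).
* **Wilson two-sided intervals** for all proportions (via statsmodels).
* **AUC intervals** by bias-corrected percentile bootstrap, B = 2000:
  cases and controls resampled separately (preserving counts — this
  avoids degenerate single-class replicates), z₀ = Φ⁻¹(fraction of
  bootstrap AUCs below the observed AUC), interval at percentiles
  Φ(2z₀ ± z).  No acceleration term (BC, not BCa).  The replicate AUCs
  are computed as a bilinear form of multinomial resample counts
  against the pairwise win/tie matrix, which is exactly equivalent in
  law to resampling indices and O(B·n²) vectorised.  A degenerate
  bootstrap distribution collapses to a point interval with a warning.

## Resampled evaluation

`resamples` (default 100) independent splits assign, within each
cancer-type stratum, round(n_s · 2/3) subjects to training (184
controls → 123 train / 61 test; total train 215 of 323).  Per split:
fit on train, score the held-out third, calibrate the threshold on the
held-out controls.  Each subject's held-out probabilities are averaged
on the probability scale (the natural reading of an "average fit" per
subject), the per-split thresholds are averaged into τ̄, and the final
call is mean score > τ̄.  A subject never held out (possible only at
very small `resamples`) triggers a redraw of the whole split sequence
from a fresh substream; if coverage still fails the subject is excluded
with a warning.  Performance is tabulated for the full cohort and every
sub-cohort (per cancer, per stage, stage within cancer, sub-stage,
histology), sensitivity over cases and specificity over controls with
Wilson intervals, plus the AUC of mean scores with its BC bootstrap
interval and the averaged ROC across splits on a common FPR grid.

One consequence of averaging both scores and thresholds: the
top-scoring control can end marginally above τ̄ even when every
per-split threshold separates the classes perfectly, because its mean
score tracks the split maxima while τ̄ averages over all splits.
Final-call specificity of n−1/n on controls is therefore the expected
outcome in strongly separated settings, not a defect.

## Synthetic cohorts

The generator emulates the structure the pipeline assumes, not real
concentrations:

* Marker vectors are `2**z` with `z` multivariate normal on the log2
  scale — the pipeline's log2 transform is variance-stabilising by
  construction.  Base log2 means spread over [2, 12] (units pg/mL),
  sd 1.5, equicorrelated blocks of 7 markers at ρ = 0.3 (assay-panel
  style correlation; real inter-marker correlation magnitudes are not
  constrained by the study description, so the block defaults are this
  package's choice).
* Each cancer shifts an overlapping subset of informative markers
  (default 7 per cancer, stride 3, union 13 of 42) by a decaying
  per-marker profile.  Effect scales default to pancreatic 5.5,
  ovarian 3.0, bladder 1.8 log2 units, calibrated once so the pooled
  classifier operates in the regime EV-protein MCED panels report
  (overall AUC ≈ 0.95, sensitivity ≈ 0.7 near 99% specificity,
  pancreatic strongest, bladder weakest).  The top pancreatic shift
  (~2⁸·⁸) corresponds to the orders-of-magnitude CA19-9-like
  elevations seen in pancreatic cancer.
* Per-marker LODs sit at a chosen quantile of the control distribution
  (default 0.15, i.e. ~15% of control values censored); the
  study-shaped preset places 8 uninformative markers at quantile 0.65
  so the prevalence filter drops exactly those 8 (34 of 42 retained).
  Values below the LOD are emitted as drawn — censoring is the
  preprocessing stage's job.
* 2% of cells missing completely at random; ages normal around medians
  60 (cases) and 57 (controls), sd 8, clipped to the observed ranges;
  stage composition fixed to the study-shaped counts (pancreatic
  22 I / 25 II; ovarian 39 I of which 26 IA, 5 II, 22 serous; bladder
  27 I / 21 II).
* The generator is a pure function of its spec including the seed;
  every Monte Carlo layer (RFE repetitions, resamples, bootstrap)
  spawns independent substreams from one root seed, so results do not
  depend on execution order.

What passing tests on these cohorts do **not** show: robustness to
non-lognormal tails, assay batch effects, informative missingness,
age–marker interactions, or distribution shift between cases and
controls beyond mean shifts — none of which the generator models.  On
synthetic data the RFE size curve is also notably flat at the top
(uninformative extra markers cost little held-out pAUC at n = 323), so
the selected panel often lands near the full retained set rather than
at 13; the informative markers still dominate the elimination-order
ranking.

## Problem sizes used in the checked examples

The test suite and the acceptance script exercise the pipeline at the
cohort's own scale (323 subjects, 42 markers) for structure and
end-to-end runs, with Monte Carlo layers sized for stable verdicts at
desk scale: 500 simulated datasets (B = 2000) for bootstrap coverage,
20 seeds at 20 RFE repetitions for planted-marker recovery, 50 seeds at
20 resamples for the null-specificity property.  These sizes are the
package's own verification choices; all default pipeline parameters
(100 repetitions, 100 resamples, B = 2000, K = 5) remain the operating
configuration.

## Known limitations

* LOD substitution is the field's convention but is known to bias
  downstream estimates relative to censored-likelihood approaches.
* The per-stratum rounding rule reproduces the 123/61 control split
  exactly; other cohort compositions may round a subject differently
  than an alternative largest-remainder rule would.
* Standardized-coefficient importance inherits the instability of
  unpenalized logistic coefficients under strong collinearity; the
  averaging across 100 resample fits is what makes it usable.
* The pipeline detects cancer presence only; tissue-of-origin
  prediction is out of scope.
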