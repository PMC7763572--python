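# Methods

This note documents the models, the synthetic-data generator, the numerical
choices and the known limitations of `salimet`. It states no empirical result
beyond what the test suite and `scripts/acceptance.py` compute.

## Study design and data model

The design has three groups of saliva ¹H-NMR samples: periodontitis patients
at baseline (B), the same patients after non-surgical therapy (AT; paired
with B by subject), and independent healthy individuals (HI). The canonical
sizes are 12 B/AT pairs and 11 HI samples. Two feature representations are
supported: a bucket matrix (integrated 0.02-ppm spectral intervals) and a
metabolite table (integrated assignment windows, 31 metabolites).

## Preprocessing

* **Calibration.** The ppm axis is rigidly shifted so the intensity argmax
  within ±0.2 ppm of 0 (the TMSP reference) maps exactly to 0.00 ppm. Ties on
  the argmax are broken toward the point nearest the reference, making the
  operation deterministic and idempotent.
* **Bucketing.** Half-open intervals `[low, low + 0.02)` tile the range
  0–10 ppm from its low end (500 candidate buckets). Any bucket whose
  interval intersects an exclusion region — by default the residual-water
  band 4.3–6.5 ppm — is dropped entirely rather than truncated, avoiding
  partial-bucket area artifacts; the default layout retains 390 buckets.
  Bucket values are trapezoidal integrals on the native (possibly irregular)
  grid with linear interpolation at interval ends, so with no exclusions the
  bucket sum equals the total spectrum integral to rounding error.
* **Normalization.** Each sample row is scaled to unit total area (dilution
  removal) as the last step before pattern recognition. No mean-centering or
  variance scaling happens in preprocessing; centering belongs to the model
  fits.
* **Baseline.** An optional windowed running-minimum subtraction stands in
  for instrument-side baseline correction; the default is to do nothing,
  since rendered synthetic spectra are baseline-free.

## Latent-variable models

All fits are deterministic: NIPALS with a 1e-10 weight-convergence tolerance,
at most 500 iterations per component (non-convergence is an error), X- and
Y-deflation per component, and a sign convention that makes the
largest-magnitude element of each weight vector positive, so scores are
reproducible bit for bit. Only column mean-centering is applied inside fits;
unit-variance scaling exists as an option (`scale=True`) but is off by
default because the source workflow states none. Class encodings: one
+1/−1 column for two classes (sign decision rule, boundary ties to the first
class of `class_order`), a dummy matrix with class-of-maximum otherwise.

* **Multilevel PLS.** The paired contrast is isolated by the within-subject
  split `x_s − x̄_subject(s)`; for a complete B/AT pair the two within rows
  are ±d/2 where d is the paired difference. PLS is fitted on the within
  matrix only; the between-subject part is retained for diagnostics. A new
  subject's within part is computed from its own pair, so prediction never
  borrows training-set subject means. Default: 2 predictive components.
* **OPLS-DA.** Each orthogonal component takes the X-loading of a
  provisional PLS component and removes its projection onto the span of
  X′Y; its scores are therefore exactly uncorrelated with every encoding
  column. X is deflated and the predictive PLS model is fitted on the
  filtered matrix; with zero orthogonal components the model coincides with
  plain PLS-DA. Default: 2 predictive + 1 orthogonal component — the
  three-group score plot is two predictive dimensions, with the orthogonal
  dimension available as a third axis. Multi-class mechanics (dummy Y,
  class-of-maximum) are this package's definition, as is the within-part
  construction of the multilevel model.

## Validation

* **Monte Carlo CV.** Default 100 runs. Units are subjects (never samples)
  whenever pairing exists, so B/AT pairs move between train and test as a
  block; units are stratified by their class composition and ⌈⅓ × units⌉
  per stratum are held out each run. Per-run substreams are derived from the
  master seed by counter, so results are independent of execution order.
  The headline accuracy is pooled (trace of the accumulated confusion matrix
  over total held-out predictions); with equal test sizes it equals the mean
  of per-run accuracies.
* **Permutation test.** The statistic defaults to the pooled CV accuracy.
  The null preserves the design: for paired models each subject's B/AT
  labels are independently swapped with probability ½; otherwise group
  labels are shuffled across samples. p = (b+1)/(N+1) with ties counted in
  b, so p is never 0 and its floor at N = 100 is 1/101 ≈ 0.0099. N = 100 by
  default.

## Univariate statistics

Kruskal–Wallis (B/AT/HI), Wilcoxon signed-rank (B vs AT, zero differences
dropped), and Mann–Whitney U (HI vs AT), all two-sided, all on mid-ranks
with tie-corrected variances. Exact p-values are computed by dynamic
programming over the rank-sum distributions when the data are tie-free and
small (signed-rank n ≤ 25; U with n₁n₂ ≤ 400) — the study's n of 11–12
always qualifies when ties are absent; otherwise a normal approximation
without continuity correction is used (the two differ by < 0.02 near the
cutoffs). BH-FDR is applied separately within each test family with m = the
number of metabolites, mirroring the three separate FDR columns of the
published table. Note that the BH step-up map is monotone and dominating but
*not* idempotent as a map on p-vectors; constant vectors are fixed points.
Clinical covariates use paired and Welch t-tests.

## Synthetic-data generator

The generator emulates the study's sampling structure, not its spectra:

* Group means and SDs per metabolite come from the packaged published table
  (31 metabolites, arbitrary relative-concentration units — the source does
  not state units).
* **Pairing.** For subject i, the B and AT values share a latent subject
  effect: z_B = √ρ·z_i + √(1−ρ)·e_B (and likewise AT), giving within-pair
  correlation ρ on the latent scale. ρ is not estimable from published
  summaries; the default 0.8 reflects the strong subject-level component
  typical of repeated saliva sampling, with the sensible range 0.5–0.95
  exposed in `SimulationConfig`.
* **Effect multiplier κ** scales each group mean's deviation from the
  metabolite's grand mean: m_g(κ) = m̄ + κ(m_g − m̄). κ = 1 reproduces the
  published moments; κ = 2 is the strong-signal regime used to validate the
  discrimination machinery against the published accuracy regime.
* **Non-negativity.** Concentrations are censored at zero
  (`truncated_normal`, the default) — censoring rather than rejection keeps
  the correlation construction exact; the induced moment bias is negligible
  when SD ≪ mean and grows for the handful of published rows with SD ≥ mean.
  A moment-matched lognormal (`lognormal_matched`, correlation applied on
  the log scale) is available where strict positivity and right skew are
  preferred.
* **Null generator.** For type-I-error harnesses all three group means are
  replaced by the grand mean *and* the group SDs by their pooled mean, so
  the three groups are exchangeable — without pooling the SDs, B/AT label
  swaps would not be distribution-preserving and permutation p-values would
  not be guaranteed valid.
* **Spectrum rendering.** Each metabolite gets one Lorentzian singlet from a
  packaged illustrative peak library (typical ¹H shifts, spaced ≥ 0.05 ppm,
  all outside the water band; no claim about true multiplet structure), with
  amplitude proportional to concentration; a TMSP peak is added at 0.00 ppm;
  one global per-sample shift ~ N(0, jitter) and white noise complete the
  model. The grid spans −0.7 to 10.2 ppm so the binned range stays covered
  after calibration undoes the jitter. A Lorentzian of FWHM w and amplitude
  h has area hπw/2, which is what window integration recovers.

What the generator does **not** emulate: J-coupling multiplets, peak overlap
between metabolites, pH-dependent shift drift, baseline/phase artifacts, and
any between-metabolite correlation beyond the shared subject effect.
Passing tests therefore demonstrate the correctness and calibration of the
statistical machinery under the study's design and printed moments — not
performance on real saliva spectra.

## Problem sizes used in the checked examples

The test suite and acceptance script run at the study's scale (12 pairs +
11 healthy, 31 metabolites; 100 CV runs; 100 permutations). Property tests
that need large-sample limits use up to 2000 pairs for moment recovery and
100 replicate datasets for type-I-error calibration; the permutation
super-uniformity harness uses reduced inner loops (6 CV runs, 19
permutations per replicate), which leaves the add-one estimator's validity
untouched. The acceptance script reports CV accuracies averaged over three
replicate datasets, and regenerates data until the permutation target's
stated precondition (observed statistic topping all permutations) holds,
since that quantity is defined conditionally on the event.

## Known limitations

* The multilevel decomposition requires complete pairs; subjects with a
  single sample are an error, not silently dropped.
* OPLS orthogonal components are estimated from provisional PLS loadings
  (Trygg–Wold style); purely Y-orthogonal variation that is uncorrelated
  with the predictive scores leaves no trace in the loadings and thus cannot
  (and need not) be removed.
* Exact rank-test enumeration switches to the normal approximation in the
  presence of ties — including ties at zero created by censoring — so
  heavily censored metabolites are tested approximately.
* The bucket route assumes spectra cover 0–10 ppm after calibration; spectra
  acquired over narrower windows need a custom `ppm_range`.
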