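# Methods

This note documents the models, default parameters and design choices in
`specvar`, and what the synthetic-data checks do and do not establish.

## Measurement model and calculated reflectance

Each sample is measured with five scans in each of four leaf-clip
conditions (WR, WRL, BR, BRL) on a 350–2500 nm, 1 nm grid. The first scan
of every condition is dropped: opening and closing the clip perturbs the
first reading, and the generator reproduces this as a +0.005 absolute
first-scan bias so the drop is observable in tests.

Condition means use scans 2–5 (or three scans when one was removed as an
outlier). The scan-to-scan dispersion STD_c is the sample (n−1) standard
deviation; the population convention differs only by a factor √(N−1)/√N
and is available by passing precomputed summaries.

Calculated reflectance combines the four means,

CR = (WR·BRL − BR·WRL)/(WR − BR),

which is algebraically exact under a single-pass transmission model
(leaf reflectance R, transmittance T, background B: signal = R + T²B).
Higher-order inter-reflections between leaf and background are neglected;
under that forward model the estimator is background-invariant, and the
end-to-end identity (noiseless generator → screen → CR = true R to 1e-12)
is asserted in the acceptance suite. The white–black denominator is
guarded at 1e-6; real references differ by more than 0.5, so a failing
guard indicates an instrument or labelling fault, not a numerical edge.

Absolute uncertainty propagates the four standard errors STD_c/√N through
CR to first order, treating conditions as independent (shared lamp drift
between conditions is ignored). The propagation is verified against a
10⁵-draw Monte-Carlo oracle to within 3% in the small-noise regime; at
larger noise the first-order expansion degrades as expected. Relative
uncertainty RU = AU/CR is masked (NaN) where |CR| < 1e-4 rather than
reported as a huge ratio. CR is never clipped or smoothed; implausible
values survive to the QC layer, which is where judgements belong.

Analysis is restricted to 400–2500 nm (2101 points); the 350–399 nm region
of this detector class has poor signal-to-noise. No smoothing is applied
anywhere.

## Outlier screen

Three automated steps replace what is often done by eye, so every removal
is reproducible and logged:

1. **Shape check.** The red-edge contrast index
   (v(800) − v(670))/(v(800) + v(670)) exceeds 0.3 for vegetation (deep
   chlorophyll absorption at 670 nm, NIR plateau at 800 nm) and is near 0
   for flat references. A leaf-like bare-reference scan, or a
   reference-like leaf scan, is flagged.
2. **Local Outlier Factor** per measurement condition within each
   experiment, Euclidean distance on the full spectral vector
   (scikit-learn's implementation of the classic definition; a brute-force
   direct-definition oracle checks it exactly on small sets). Genotype is
   deliberately ignored in the grouping so unusual-but-genuine genotype
   spectra are judged against their local density, not a global centroid.
   Default neighbour count k = 3: after the first-scan drop each sample
   contributes four replicate scans per condition, so k = 3 makes a scan's
   neighbourhood its own replicate cluster and measures density at the
   replicate scale. Larger k (e.g. 10) spans other samples, whose
   biological spread dwarfs replicate noise, and flags clean edge-of-
   distribution samples. Flag threshold 1.5 (scores near 1 are inliers);
   both are configurable.
3. **Post-reflectance check.** After CR is computed, a sample is flagged
   when CR leaves [−0.02, 1.05] at any analysis wavelength, or deviates
   more than 6 robust standard deviations (1.4826·MAD) from the
   per-wavelength median of its experiment × genotype-group peers (groups
   under 3 samples skip the robust rule). The 1.4826 consistency constant
   makes the unit an estimate of σ under normality; with the raw MAD the
   effective threshold would be ≈4σ, which small groups' noisy MAD
   estimates turn into a few-percent false-flag rate on clean data. An
   explicit manual exclusion list is honoured verbatim and logged, for the
   cases where a human judgement must be recorded.

Removal policy per sample and condition: no flagged scans → keep; exactly
one → drop that scan (three retained scans remain valid); two or more in
any condition, or any whole-sample flag, → drop the sample. Samples
measured at several times are distinct samples, so a flag at one
measurement time never removes the other times.

Measured on the generator at 10% contamination (condition swaps, 10×
spectral spikes, +0.3 global shifts): recall 1.0, false-flag rate ≈ 1–2%.
Global shifts are caught by the post-reflectance robust rule — their scans
form a tight cluster of their own, invisible to replicate-scale LOF —
which is the intended division of labour between steps 2 and 3.

## Descriptive statistics

**CV spectra.** sd/mean per wavelength within a group (sample sd), masked
where the group mean is ≤ 0. For unequal group sizes, the larger group is
subsampled to the smaller group's size, by default without replacement
(the draw is a downscaling, not a classical bootstrap; with-replacement is
available), 100 times with a seeded generator; the pointwise min/mean/max
envelope is reported. A percentile envelope is available but the min/max
range is the default, matching how such envelopes are usually plotted.

**PCA.** Covariance PCA (mean-centered, unscaled) via SVD. Reflectance
shares units across wavelengths, and correlation scaling would inflate the
noisy water bands. Explained variance is reported against the total over
all components; the contribution of wavelength w to component k is
100·loading(w,k)²/Σ_w loading(w,k)². Component signs are fixed
deterministically (largest-magnitude loading positive). The four
wavelengths contributing most to the first four PCs (ties to the shorter
wavelength, duplicates replaced by runners-up) seed model selection.

A note on "brightness": when samples differ mainly by a wavelength-
constant additive offset, PC1 contributions are near-uniform across
wavelengths. A *multiplicative* brightness factor instead yields loadings
proportional to the mean spectrum and strongly non-uniform contributions
(ratio ≈ (R_NIR/R_VIS)²). The generator provides both mechanisms; the
near-uniform PC1 pattern is asserted for the additive case.

## Per-wavelength models

All factors are treatment-coded categoricals; reference levels default to
the scientifically natural baseline (reference genotype, morning window,
first batch, one leaf) so the intercept is the baseline condition's
reflectance. Rank deficiency is reported with the aliased terms named.

- **ANOVA**: vectorized one-way decomposition; η² = SSB/SST with a
  one-sided noncentral-F confidence interval (lower bound from inverting
  the noncentral-F CDF at the 95% quantile, upper bound fixed at 1 — the
  usual one-sided effect-size convention).
- **OLS**: vectorized normal-equations solve across wavelengths; Wald-t
  CIs, omnibus F, R²/adjusted R², and AIC in the Gaussian-likelihood
  convention that counts σ² as a parameter (comparable to R's `AIC` on
  `lm` fits; constant offsets cancel in comparisons).
- **Mixed models**: random-intercept REML via statsmodels MixedLM, checked
  against a brute-force profiled-REML oracle. Marginal R² =
  var_fixed/(var_fixed + var_random + var_residual); conditional R² adds
  var_random to the numerator; var_fixed is the variance of the
  fixed-effect linear predictor. Wald-t df uses the residual approximation
  n_obs − n_fixed − n_groups + 1. A variance estimated at the zero
  boundary is reported with a flag, never fatal — per-wavelength batch
  fitting must not halt on one degenerate wavelength.
- **Tukey post-hoc**: all pairwise contrasts of a factor's model-based
  means, p from the studentized-range distribution at the model's residual
  df; with two levels it reduces exactly to the unadjusted t-test.
- **BY adjustment**: Benjamini–Yekutieli step-up implemented from the
  definition (min(1, min_{j'≥j} p_(j')·m·c(m)/j') with c(m) = Σ 1/i),
  applied across the 2101 analysis wavelengths of one test series; each
  post-hoc contrast is its own family. BY dominates BH elementwise and
  controls FDR under the strong spectral dependence between wavelengths.
- **Model selection**: forward stepwise from the main-effects model toward
  the all-interactions model, adding the interaction that improves AIC by
  more than 2 at the majority of the four probe wavelengths; with two or
  fewer main effects the two models are compared directly. The ΔAIC < −2
  acceptance threshold is the conventional "substantial support" cut.
- **Regions**: maximal runs of consecutive wavelengths with adjusted
  p < α, reported as closed nm intervals.

## Synthetic-data generator

The generator emulates the three-experiment structure (glasshouse and two
field settings) at the raw-scan level. Per sample, the true reflectance is
a smooth leaf template (VIS baseline 0.05 with a green peak at 550 nm,
logistic red edge at 715 nm, NIR plateau 0.48, multiplicative water dips
at 1450/1940 nm, SWIR decline; transmittance = 0.85·R, keeping R + T ≤ 1)
plus additive genotype-group effect spectra, a plant-level intercept
(sd 0.008, shared across measurement times), batch effects (sd 0.003),
fixed diurnal offsets (noon +0.004, pm −0.003), a leaf-number effect
(+0.005), a residual sample offset (sd 0.008), smooth pigment and
water-band jitter (sd 0.004/0.006, Gaussian shapes at 550 and 1450/1940
nm), and an optional multiplicative brightness factor (sd 0.03). The
jitter components matter: with flat offsets alone, sample variation is
rank-2 and exhibits degenerate "pinch-point" wavelengths where the group
MAD collapses — an artefact real leaf data does not show.

Measured signals follow the forward model (WR = B_w = 0.98, BR = B_b =
0.03, WRL = R + T²B_w, BRL = R + T²B_b), with five scans per condition,
first-scan bias +0.005, additive scan noise sd 5·10⁻⁴ and multiplicative
scan noise sd 10⁻³ — the regime of a well-operated leaf clip, chosen so
within-group CVs land at roughly 5–20% in the VIS and a few percent in
the NIR, and median RU stays below 1% (measured ≈0.08%). Effects are
additive on R so the per-wavelength linear models are correctly specified.

All randomness flows from one seed through counter-keyed per-sample
streams (plant- and batch-level draws come from a separate structure
stream), so any subset of samples is reproducible independently of
generation order. Labelled contaminants of three kinds target the three
screen steps: condition swaps (a leaf scan recorded as a reference),
10× spikes over a random 200 nm window, and +0.3 global shifts.

What passing these checks does *not* show: the generator has flat
(wavelength-constant) random effects plus a handful of smooth components,
no detector-splice artefacts, no wavelength-dependent noise floor, no
temporal drift within a measurement day, and additive (not physiological)
genotype effects. Results on real data depend on those unmodelled features;
the checks establish the correctness of the algebra and the statistical
calibration of the inference chain, not field performance.

## Acceptance measurements

`scripts/acceptance.py` recomputes, from scratch at the given seed:
background invariance (max |CR − R|, noiseless, 12 samples × full grid),
AU vs. 10⁵-draw Monte-Carlo (three measurement regimes), the worked BY
example, LOF vs. direct definition (six random sets up to 12 points), PCA
vs. eigen-decomposition, the removal-policy truth table, the mean
false-discovery proportion over 100 null experiments (8+8 samples, 2101
wavelengths), median Jaccard overlap of the detected region with an
injected 450–550 nm effect over 50 experiments (20+20 samples),
mixed-model variance recovery over 200 replicates (50 plants × 3 times,
variances 0.04/0.01), screen recall and false-flag rate at 10%
contamination (4 × 30 samples), and the median relative uncertainty under
default noise. These problem sizes keep the whole script under a minute
on one CPU while leaving each estimate stable across seeds.

## Known limitations

- The mixed-model Wald df is an approximation; Satterthwaite or
  Kenward-Roger corrections are not implemented.
- Uncertainty propagation ignores covariance between conditions (shared
  lamp or temperature drift).
- The screen's surrogate rules are principled formalizations of visual
  checks; they are not claimed to reproduce any particular historical
  removal list beyond an explicitly supplied manual exclusion list.
- No radiometric calibration, splice correction or proprietary instrument
  file parsing; input is plain tabular reflectance factors.
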