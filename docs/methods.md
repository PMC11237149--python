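# Methods

## The problem and the model

Blood plasma and saliva are overwhelmingly water, so their near-infrared
absorbance in the 1300–1600 nm window (the first overtone of the water OH
stretch, peaking near 1450 nm) is dominated by the water matrix.
Aquaphotomics treats that water spectrum as a holistic biomarker: a
systemic perturbation such as inflammatory bowel disease (IBD — Crohn's
disease, CD, or ulcerative colitis, UC) redistributes water among its
molecular species (free water, solvation shells, 1–4 hydrogen-bonded
clusters), and the redistribution shows up as coordinated absorbance
shifts inside twelve characteristic sub-bands, the water matrix
coordinates C1–C12 (WAMACs).

The diagnostic pipeline is classical chemometrics:

1. **Pretreatment** — standard normal variate (SNV), multiplicative
   scatter correction (MSC), Savitzky–Golay smoothing/derivatives,
   normalization, detrending, two-point linear baseline correction, and
   absorbance↔transmittance conversion, composable in any order.
2. **PCA** — mean-centered SVD; the smallest number of components whose
   cumulative explained variance reaches 99% is retained; Hotelling
   T² in score space screens outliers.
3. **Classification** — Gaussian discriminants on the retained scores
   (LDA with pooled covariance, QDA with per-class covariances) and a
   soft-margin SVM (one-vs-one for three classes), healthy vs IBD or
   healthy/CD/UC.
4. **Validation** — leave-one-subject-out cross-validation and an
   external 75/25 subject-level split; metrics are sensitivity
   `100·TP/(TP+FN)`, specificity `100·TN/(TN+FP)`, and a rate-weighted
   total accuracy `100·(TN·TN/(TN+FP) + TP·TP/(TP+FN))/n`.  The
   rate-weighted form never exceeds plain accuracy `100·(TP+TN)/n`
   (equality exactly when each of the TP and TN terms is individually
   lossless); both are reported.
5. **Aquagram** — after scatter correction (MSC against the dataset mean
   by default, SNV selectable), each WAMAC wavelength is z-scored over
   all spectra, `A′λ = (Aλ − µλ)/σλ`, and a class's band value is the
   mean of `A′λ` over its spectra and the band's wavelengths.  The radar
   chart of the twelve band values per class is the aquagram; the sign
   pattern across bands is the water spectral pattern (WASP).

## The synthetic cohort generator

No patient spectra are available, so every downstream stage is exercised
on seeded synthetic cohorts that emulate the statistical structure the
analysis assumes:

* **Spectral shape.** One broad Gaussian at 1450 nm (σ = 45 nm, amplitude
  1 AU) — the dominant water first-overtone peak — plus one narrower
  Gaussian per WAMAC band, centered at the band midpoint with σ = half
  the band width and amplitude 0.06 AU.  Band shapes are a modeling
  convenience: the band tables give ranges, not line shapes.
* **Cohort structure.** 13 subjects (3 healthy, 2 CD, 8 UC) × 3 replicate
  spectra = 39 spectra per cohort, on the 1280–1630 nm grid at 0.5 nm.
* **Class signal.** Each class carries a map of fractional band-amplitude
  shifts (default magnitude 5%).  The plasma preset lowers C1–C4 and C8
  and raises C11–C12 in disease (CD additionally shifts C1–C8 down and
  C9–C12 up); the saliva preset mirrors it (C1–C8 up, C9–C12 down in
  disease, CD raising the C6 hydration band).  The `null` preset zeroes
  every effect and is the type-I-error control.
* **Nuisance structure.** Per subject: the class effect is jittered
  (sd = 10% of the effect) and a small class-independent band
  perturbation (sd 0.2%) gives each subject an identity — this creates
  the subject > replicate variance hierarchy that makes replicate-leakage
  tests meaningful.  Per replicate: multiplicative scatter
  (slope ~ 1 + N(0, 0.02)), additive scatter (N(0, 0.005) AU) — exactly
  the artifacts SNV/MSC remove — and spectrally smooth instrument noise:
  white noise convolved with a 5 nm Gaussian kernel and rescaled to a
  per-point sd of 2.5×10⁻⁴ AU (a slow-scanning spectrophotometer's noise
  is correlated in wavelength, not independent per point; iid noise would
  spread PCA variance over ~all components, unlike real spectra, where a
  handful of components carry ~100%).  The band effect : noise ratio at
  band centers is ~12:1, comfortably in the strongly separated regime,
  and the jitter fraction is small enough that subject-level class
  margins (~10 sd) keep leave-one-subject-out recovery at 100% rather
  than leaving boundary-adjacent subjects to chance; the `null` preset
  realizes the opposite regime.

What the generator does **not** emulate: temperature-dependent water band
shifts, solute absorbance outside the water bands, wavelength-dependent
detector noise, physiological covariates, or any real-data effect sizes
(the literature gives directions, not magnitudes).  Passing tests
therefore demonstrate that the pipeline recovers a class structure of the
assumed form without leakage — not that real plasma spectra separate this
way.

## Numerical choices

* **Wavelength selection** is closed-interval on both ends; the single
  shared band boundary (1482 nm, ending C10 and starting C11) is assigned
  to the lower band so membership is unique.
* **Savitzky–Golay "12 points"**: symmetric windows must be odd, so an
  even request is widened by one (12 → 13 = 12 neighbors + center);
  polynomial order defaults to 2; derivatives are scaled by step⁻ᵈ (per
  nm) so results are grid-independent; edges use polynomial extrapolation
  from the first/last full window.
* **Normalization** defaults to the unit (L2) vector; min–max and area
  variants are selectable.
* **PCA signs** are fixed by making each loading's largest-magnitude
  entry positive; explained variance covers the full decomposition.
* **Covariance ridge**: near-singular pooled or per-class covariances get
  `1e-8 · trace/dim` added to the diagonal (a 3-subject class in a
  high-dimensional score space makes this necessary); a covariance that
  stays singular raises an error naming the dimensionality.
* **LDA/QDA priors** are empirical class frequencies (3 vs 10 subjects is
  not balanced, and pretending otherwise hides the imbalance); uniform
  priors are selectable.  Discriminant ties resolve to the first class in
  sorted name order.
* **SVM**: scores are standardized with training-set statistics before
  the dual problem is solved — soft margins are scale-sensitive and raw
  PC scores sit orders of magnitude below the unit margin, which would
  saturate every dual coefficient at C and collapse predictions to the
  majority class.  The dual QP is solved directly (SLSQP with box and
  equality constraints; cohort-scale problems have ≤ ~40 samples).
  Defaults: linear kernel, C = 1; RBF with γ = 1/(d·var) selectable.
  Multiclass is one-vs-one majority vote, ties broken by summed decision
  values.  Calibration R²/RMSEC regress predicted numeric class codes
  (healthy = 0, IBD = 1; or healthy = 0, UC = 1, CD = 2) on true codes.
* **Replicate aggregation**: a held-out subject's three replicate
  predictions are reduced by majority vote; ties break toward the
  disease class (screening favors sensitivity).  This is configurable.
* **75/25 split**: per class, `round(0.75 · n_subjects)` subjects go to
  calibration, clamped so each side keeps at least one subject; all
  replicates travel with their subject.
* **Leakage control**: pretreatment statistics (the MSC reference), the
  PCA basis and the classifier are fitted on training spectra only, in
  every fold and in the external split.  A canary test verifies that
  perturbing test spectra changes no fitted parameter.
* **Missing metrics** (empty denominator) are reported as NA, never 0.

## Design choices where the design was open

* Whether replicates should be modeled individually or averaged is left
  to the caller: leave-one-out supports both `subject` (default —
  clinically honest) and `spectrum` units.  A regression test shows why
  the default matters: with zero class signal but strong subject
  identity, spectrum-level LOO inflates accuracy by >20 points while
  subject-level LOO stays at chance.
* The rate-weighted total accuracy is reported exactly as defined even
  though it is not the conventional accuracy; the conventional value sits
  beside it in every report row.
* Aquagram band values aggregate within-band wavelengths by the mean
  (all band wavelengths carry information; the mean is the convention
  used for the dataset reference elsewhere in the pipeline).
* Aquagram µλ/σλ pool all spectra of the dataset, not per class.

## Known limitations

* **Raw-data grid cells are scatter-limited.**  With realistic scatter,
  the variance of uncorrected spectra is dominated by the two scatter
  directions; the ≥99%-variance rule then retains only those PCs and the
  class signal never reaches the classifier, so raw cells sit at the
  majority-class rate.  This is structural — it is the reason scatter
  correction exists — and disappears under SNV/MSC, where all models
  reach 100% on the strong-separation presets.
* **Null cohorts sit slightly below the majority rate.**  On effect-free
  cohorts the 99% rule keeps ~30 noise PCs, LDA overfits them, and
  held-out predictions approximate prior-matched guessing (expected
  agreement p² + (1−p)² ≈ 0.645 for a 10:3 split) rather than
  constant-majority prediction (0.769).  The null guard therefore tests
  for the absence of optimism (accuracy not significantly *above*
  chance), which is the failure mode leakage would produce.
* The SVM solver targets cohort-scale problems (tens of samples); it is
  not tuned for large n.
* Problem sizes throughout (13 subjects × 3 replicates, 50-seed null
  sweeps) match the study design the generator emulates; they are the
  package's native scale, not a benchmark configuration.
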