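# Methods

## Overview

The package fuses two vibrational spectroscopies of articular cartilage at
the lowest level of abstraction — concatenation of preprocessed intensity
vectors — and treats the fused vector as a single fingerprint for
classification and biomarker mining. Everything operates at the *patient*
level: the ~30 replicate spectra per patient per modality are preprocessed
individually, averaged, and each patient contributes exactly one Raman
vector (1011 points), one NIR-SWIR vector (512 points) and one fused
vector (1523 points).

## Synthetic cohort model

Raw spectra are simulated as Gaussian bands on a smooth background with
additive noise:

    I(ν) = Σ_b A_b exp(−(ν − c_b)² / 2w_b²) + B(ν) + ε(ν),
    A_b  = a_b · (1 + δ_b · E · 1[class = OA]) · u_{p,b}

* `a_b` — base amplitude (arbitrary units; only relative class effects are
  meaningful, since no absolute intensity scale exists for tissue bands),
* `δ_b` — fractional OA effect of band *b*; `E` — global effect size
  (default 1),
* `u_{p,b}` — patient-level log-normal multiplier, drawn once per patient
  per band (σ = `patient_sd`, default 0.05), modelling between-patient
  biochemical heterogeneity; replicates within a patient share it,
* `B(ν)` — per-spectrum random background: a degree-3 polynomial
  (fluorescence/Mie-like) for Raman, an offset-plus-slope scattering trend
  for NIR-SWIR, scaled by `baseline_scale` (default 1.5),
* `ε` — i.i.d. Gaussian noise, `noise_sd` = 0.02.

Band widths reflect the instruments: ~8–16 cm⁻¹ (Raman, ~1 cm⁻¹
resolution) and 120–170 cm⁻¹ (NIR-SWIR overtone bands). Planted OA
directions follow the cartilage literature: matrix bands decrease in OA
(sGAG 1063 cm⁻¹ −20%, amide III 1250 cm⁻¹ −12%, GAG CH wag 1338 cm⁻¹
−15%, amide I 1616 cm⁻¹ −18%, N-H/PG 6500 cm⁻¹ −22%, ECM C-H 4385 cm⁻¹
−12%, C-H 8755 cm⁻¹ −8%) while water bands increase (5345 cm⁻¹ +30%,
7120 cm⁻¹ +15%). Magnitudes are set for late-stage (grade 3–4) OA tissue
so that every planted band is individually separable at the patient level
(≥ 2.4 patient-SDs at E = 1); the water-combination band carries the
largest effect because tissue hydration is among the strongest OA markers.
Band amplitudes are deliberately *not* dominated by any single band:
vector normalization divides a dominant band's own class effect out of the
fingerprint (closure), so a physically dominant water band would paradoxically
hide its own change.

Cohort defaults mirror the study design: 14 Control + 13 OA patients,
3 samples × 10 spectra each, per modality. All randomness flows from a
single integer seed; identical configurations are bit-reproducible.

What the generator does **not** emulate: spatial correlation across the
joint surface, instrument line-shape asymmetries, cosmic rays, wavelength
calibration drift, detector nonlinearity, grade heterogeneity within a
class, or correlated (non-white) noise. Passing tests therefore show the
pipeline recovers known planted structure under idealized conditions —
not that it would achieve the same figures on real tissue.

## Preprocessing chains

Raman: iterative 5th-order polynomial baseline correction → 6-level Haar
wavelet de-noising → rubber-band baseline correction → vector
normalization. NIR-SWIR: first derivative (with respect to wavenumber) →
Savitzky-Golay smoothing (order 2, 9 points) → rubber-band → 6-level Haar
de-noising → vector normalization. Each chain emits a trace with per-step
parameters and checksums.

Numerical choices, where the operator names leave freedom:

* **Polynomial baseline** uses the modified-polyfit iteration: fit, clip
  the working signal to min(signal, fit), refit, until the working signal
  changes < 10⁻⁶ in relative L2 (max 100 iterations). A single
  least-squares fit would subtract peak mass. The fit itself is one
  projection onto a QR-orthonormalized polynomial basis on a [−1, 1]
  scaled axis, so iteration cost is negligible and conditioning is safe.
* **Wavelet shrinkage**: symmetric extension, soft thresholding of all
  detail levels at the universal threshold σ̂√(2 ln n) with σ̂ estimated
  from the median absolute deviation of the finest detail coefficients
  (Gaussian consistency factor 0.6745). A zero threshold (noise-free
  input) leaves coefficients untouched.
* **Rubber band** subtracts the lower convex hull of (ν, I), computed by a
  monotone-chain scan; the endpoints are exactly zero and sampled points
  never fall below the hull, so the output is non-negative up to rounding.
* **Derivative**: central differences against the wavenumber axis (not
  the array index), so descending axes keep a consistent sign; a constant
  input maps to exact zeros (rounding residue is clamped), which makes the
  downstream normalization fail loudly on degenerate input rather than
  amplify noise.
* Derivative and smoothing are separate stages (not a combined SG
  derivative), in the order listed.
* Axes are never resampled; each modality keeps its native grid, and both
  segments are stored high→low wavenumber in the fused vector.

Patient averaging happens after per-spectrum preprocessing, and the mean
is re-normalized to unit length so both modalities enter the fingerprint
at compatible magnitude. The fused 1523-vector is the plain concatenation
of the two unit-norm segments (norm √2); no further rescaling is applied,
and the segment map records the index ranges and native axes so any
fingerprint index is invertibly mapped to (modality, wavenumber).

## Classification

**PCA-LDA.** Column-mean centering, PCA truncation to 20, 10 or 5
components (keeping the variable count below the 27 samples), then a
Fisher discriminant on the scores with pooled within-class covariance
(n − 2 denominator). Prediction assigns the nearer class mean along the
discriminant; exact ties go to Control, the negative class. A singular
pooled covariance receives a ridge of 10⁻⁸·trace/k, recorded on the model.
Quality parameters are computed by resubstitution on all 27 fingerprints
(the 20-PC setting should be read as a positive control — it overfits, as
the null-data tests demonstrate). Mahalanobis separation is summarized as
the absolute difference of class-wise means (and medians) of the
discriminant coordinate expressed in pooled-SD units; on that scale the
mean summary equals the Mahalanobis distance between the class centroids.

**SVM.** RBF kernel; for every outer CV split (stratified seeded 3-fold,
or leave-one-out, whose splits carry no randomness) the parameters c and
γ are chosen by an inner stratified 3-fold grid search on the training
portion only, so the test subset is never seen during training. Ties in
inner accuracy resolve to the smallest c, then the smallest γ. The
default grid spans c ∈ 2⁻⁵…2¹⁵ and γ ∈ 2⁻¹⁵…2³ in steps of 2² (the
classic coarse grid); simulation-heavy tests and the acceptance script use
a 3 × 4 sub-grid spanning the same decades to keep nested LOO tractable on
one CPU. Test predictions are accumulated over all splits into one
confusion matrix before quality parameters are computed ("accumulated
hits"); k-fold partitions can be repeated and accumulated with
`repeats > 1`.

Leave-one-out SVM on exchangeable-label (null) cohorts tends to land
*below* 50% accuracy (the well-known anti-learning bias of LOO on
label-balanced noise); the null tests therefore check the binomial band
around chance rather than a lower bound only.

## Feature extraction and corroboration

Six scorers produce a per-index score track and a ranked top list
(20 entries; 7 for forward selection):

1. **LDA loadings** — the 3 PCs with the largest |LD weight| contribute
   their loading-magnitude peaks, merged rank-interleaved.
2. **Cluster vectors** — each class centroid is back-projected through
   those top discriminant PCs into fingerprint space (rank-k
   reconstruction); the class-difference vector is ranked.
3. **DBMS** — mean(OA) − mean(Control), sign retained.
4. **Student t** (pooled variance) and
5. **Mann-Whitney U** (exact null distribution when both classes ≤ 15 and
   tie-free, tie-corrected normal approximation otherwise) — scored as
   −log₁₀ p, only peaks with p < 0.01 enter the top list.
6. **Feature forward selection** — 100 random stratified 90/10 splits;
   greedy accrual of the feature that most improves held-out accuracy of
   a pooled-covariance linear discriminant (ties by held-out Mahalanobis
   margin, then lowest index), capped at 10 features; the selection
   histogram is ranked.

Top lists rank *local maxima* of the score magnitude, thinned to one peak
per 5 points, rather than raw indices — otherwise a single strong band's
contiguous neighbours fill an entire top-20 list. Corroboration pools all
top indices per modality segment (regions never straddle the Raman/NIR
junction, and the two junction-flanking indices — pure concatenation
artifacts — are excluded), merges indices within a 5-point window
(≈ 5 cm⁻¹ Raman, ≈ 70 cm⁻¹ NIR-SWIR, matching the width of typical
reported biomarker intervals), counts distinct contributing tests per
region, and reports regions with ≥ 3 hits, annotated from the packaged
band-assignment table. NIR-SWIR regions — which live in derivative space —
can additionally be attributed to a zero-order band position: the nearest
first-derivative extremum corroborates the lobe, and the nearest local
minimum of the second derivative within ±3 grid points of the region
center supplies the band-center wavenumber ("unresolved" if absent).

A caveat the null-cohort simulations make explicit: the loadings, cluster
-vector and DBMS scorers are three views of the same class-mean-difference
vector, so they corroborate each other on chance features and ≥ 3-hit
regions do occur on label-exchangeable data (≈ 7–8 per default null
cohort). Regions supported by the p-gated tests (t/U) are the
inferentially controlled ones; hit composition is reported per region so
users can weigh this.

## Problem sizes and determinism

Simulation-based tests use the full study-scale cohort (27 patients ×
30 spectra × 2 modalities) over 20 seeds per property; operator oracles
use 50–1024-point vectors. The acceptance script runs one full cohort.
Every stochastic component (generator, k-fold partitions, inner grid-search
folds, forward-selection splits) is driven by explicit integer seeds, and
leave-one-out results are exactly reproducible by construction.

## Known limitations

* Synthetic spectra are idealized (see above); headline accuracies on the
  default cohort (≈ 100%) characterize the planted effect sizes, not
  clinical performance.
* The Mahalanobis separation summary is one specific reading of
  "difference between mean and median distance"; other readings exist.
* The forward-selection histogram is data-driven: on a fixed dataset it
  concentrates on that dataset's best chance features rather than
  flattening, which is intrinsic to any selection rule that maximizes
  held-out performance.
* 3-fold SVM rates depend on the fold seed; accumulated counts from a
  single partition are reported unless `repeats` is raised.
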