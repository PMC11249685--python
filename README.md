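# spectromics

Low-level data fusion of Raman scattering and NIR-SWIR absorption spectra
of articular cartilage for osteoarthritis (OA) classification, with
corroborated spectral-biomarker mining.

Osteoarthritic degeneration changes the biochemistry of cartilage — loss
of sulphated glycosaminoglycans (sGAG) and proteoglycans, disruption of
the collagen matrix, rising water content. Raman spectroscopy (fingerprint
region, 614–1722 cm⁻¹) and NIR-SWIR absorption spectroscopy
(11127–3993 cm⁻¹, O-H/C-H/N-H overtones and combinations) probe these
changes through different physics and therefore carry complementary
information. This package implements the *spectromics* approach: each
patient's preprocessed, averaged Raman and NIR-SWIR spectra are
concatenated into one fused fingerprint

```
x = [ x_Raman (1011 points, 1722 → 614 cm⁻¹) | x_NIR-SWIR (512 points, 11127 → 3993 cm⁻¹) ]
```

which is classified by PCA-LDA (mean-centred PCA truncation to 20/10/5
components, Fisher discriminant with pooled within-class covariance,
Mahalanobis separation diagnostics) and by a Gaussian-kernel SVM with
nested grid search under 3-fold and leave-one-out cross-validation.
Classification quality is reported as accumulated-hit confusion counts and

```
ACC  = (TP+TN)/(TP+FP+TN+FN) · 100        SENS = TP/(TP+FN) · 100
SPEC = TN/(TN+FP) · 100                   F    = 2·SENS·SPEC/(SENS+SPEC)
```

with OA the positive class. Six feature scorers (PCA-LDA loadings, cluster
vectors, differences between mean spectra, per-wavenumber Student t and
Mann-Whitney U tests, feature forward selection) rank fingerprint indices;
regions where at least three scorers' top features agree are reported as
candidate biomarkers, translated back to modality and wavenumber, and
annotated from a packaged cartilage band table.

Because no patient spectra are publicly deposited, the package ships a
first-class synthetic-cohort generator that emulates the study design
(14 Control and 13 OA patients, 3 samples × 10 spectra per patient per
modality) with Gaussian tissue bands, planted OA effects at the known
biomarker positions, fluorescence/scattering backgrounds, patient-level
random effects and shot noise — so the whole pipeline is testable end to
end with known ground truth.

## Worked example

```python
import spectromics as sp
from spectromics.pipeline import patient_fingerprints

cohort = sp.generate_cohort(sp.CohortConfig(seed=7))   # 810 + 810 spectra
X, y, patients, fused = patient_fingerprints(cohort)   # preprocess + fuse
print(fused[0].values.size)                            # 1523

results = sp.PCALDA(X["Concatenated"], y).fit(n_pcs=5)
print(results.summary())
```

prints

```
1523
PCA-LDA results
==================================================
samples: 27   features: 1523   PCs retained: 5
cumulative explained variance: 92.5%
discriminant ridge: 0
--------------------------------------------------
    accuracy  sensitivity  specificity      f_score
       100.0        100.0        100.0        100.0
--------------------------------------------------
Mahalanobis separation (mean)  : 8.9551
Mahalanobis separation (median): 8.7400
```

i.e. on the default synthetic cohort the planted class differences are
strong enough for a 5-component PCA-LDA model to separate the 27 patient
fingerprints completely, with the two class centroids about 9 pooled
standard deviations apart along the discriminant. Cross-validated SVM
classification and biomarker mining work the same way:

```python
cv = sp.SpectromicsSVM(X["Concatenated"], y,
                       sp.SvmConfig(cv_scheme="loo")).cross_validate()
scores = sp.extract_all_features(X["Concatenated"], y, results, seed=7)
regions = sp.corroborate(scores, fused[0].segment_map)
for r in regions[:3]:
    print(r.modality, f"{r.wavenumber_high:.0f}-{r.wavenumber_low:.0f}",
          r.hit_count, r.assignment)
```

```
Raman 1067-1045 6 SO3- symmetric stretch (sGAG)
NIRSWIR 6729-6324 6 N-H stretch 1st overtone (PG)
NIRSWIR 4342-4216 5 C-H bend 2nd overtone (ECM)
```

The same pipeline is available from the shell:

```sh
spectromics run --seed 7 --out-dir results/
spectromics simulate --out-dir cohort/ --seed 7
spectromics classify --fingerprints fp.csv --labels labels.csv --model svm --cv loo
```

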