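# algaespec

Hyperspectral discrimination of intertidal seaweed from field
reflectance spectra.

Monitoring nearshore macroalgal resources by remote sensing starts from
ground truth: can the dominant intertidal species be told apart from their
reflectance curves alone, across the wet/moderate/dry states they cycle
through between tides?  `algaespec` implements the complete analysis chain
for that question, for six dominant species of a rocky intertidal system —
*Ulva pertusa* (Chlorophyta), *Sargassum thunbergii* and *S. fusiforme*
(Ochrophyta), and *Chondrus ocellatus*, *Chondria crassiaulis* and
*Grateloupia filicina* (Rhodophyta):

1. **Preprocessing** (`algaespec.spectra`) — read/write labeled spectral
   libraries (long or wide CSV), trim to the reliable 400–900 nm window,
   average replicate reads, resample to the 1-nm grid.
2. **Derivative spectroscopy** (`algaespec.features`) — the first-derivative
   spectrum D(λ) = R(λ+1) − R(λ) and 14 standard variables: green-peak
   amplitude/location (R_g, L_g; max reflectance in 510–560 nm), red-valley
   amplitude/location (R_r, L_r; min in 640–680 nm), red- and blue-edge
   derivative maxima (V_re, L_re in 680–760 nm; V_be, L_be in 490–530 nm),
   edge areas A_re, A_be (derivative sums), and the vegetation indices
   RVI(x,y) = x/y and NDVI(x,y) = (x−y)/(x+y) for the pairs (R_g, R_r) and
   (A_re, A_be).
3. **Screening** (`algaespec.screening`) — one-way ANOVA and Tukey HSD per
   variable; variables ranked by the number of significant class pairs
   ("stars", p ≤ 0.05), then backward elimination along the ranking selects
   the subset maximizing classifier accuracy.
4. **Classification** (`algaespec.classify`) — soft-margin RBF-SVM with
   exhaustive (g, c) grid search under stratified 4-fold cross-validation,
   and an SVM + XGBoost soft-vote fusion; statsmodels-style
   `SeaweedClassifier(...).fit() → ClassificationResults` with `summary()`.
5. **Evaluation** (`algaespec.evaluate`) — confusion matrix, overall
   accuracy (100·trace/total), one-vs-rest ROC with micro and macro
   averaging, and per-class PC1 explained variance.
6. **Synthetic data** (`algaespec.simulate`) — because the original field
   spectra are not deposited, a generator builds reference curves through
   the published band-wise reflectance anchors (shape-preserving PCHIP
   interpolation) and perturbs them with dryness gains, amplitude gain,
   wavelength jitter and smoothed noise.  See `docs/methods.md`.

## Worked example

```python
import numpy as np
from algaespec import (AnchorTable, TEMPLATE_ANCHORS, build_reference_curve,
                       extract_features)

grid = np.arange(400.0, 901.0)
ulva = build_reference_curve(AnchorTable("Ulva", TEMPLATE_ANCHORS["Ulva"]), grid)
fv = extract_features(ulva)
print(fv.L_g, fv.R_g)          # 554.0 25.27
print(fv.L_r, fv.R_r)          # 669.0 5.78
print(round(fv.NDVI_RgRr, 5))  # 0.6277
print(round(fv.RVI_RgRr, 4))   # 4.372
```

The green seaweed's chlorophyll reflection peak sits at 554 nm (25.27%
reflectance), the chlorophyll absorption valley at 669 nm (5.78%), and the
normalized green-peak/red-valley contrast NDVI(R_g, R_r) ≈ 0.628 — the
single most discriminative of the 14 variables.

A full seeded pipeline run:

```bash
algaespec run --seed 1 --outdir out/
# -> spectra.csv, features.csv, screening.json, model.json, report.json
```

or stage by stage via `algaespec generate / extract / screen / train /
evaluate` (see `--help` on each).

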