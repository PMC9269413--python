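# Methods

## The measurement model

The package operates on hemispherical reflectance spectra of seaweed
thalli as produced by a handheld field spectroradiometer (visible/NIR,
1-nm sampling), already whiteboard-calibrated upstream: input is
reflectance in percent (0–100), not radiance.  A curve lying entirely in
(0, 1] is rejected as a unit error unless the reader is told the input is
fractional (`fractional=True` multiplies by 100), because every
downstream threshold and anchor value is on the percent scale.

Preprocessing follows standard practice for this instrument class: the UV
end below 400 nm is noise-dominated and the region above 900 nm is
corrupted by water-vapour absorption, so spectra are trimmed to the
**closed** interval [400, 900] nm (both endpoints kept — the unreliable
regions are strictly *before* 400 and *after* 900), replicate reads are
pointwise-averaged, and curves are linearly resampled to the integer-nm
grid (501 points).  Resampling is exact on data already on the grid and
never extrapolates.

## The 14 spectral variables

The first-derivative spectrum is the forward difference
D(λ) = (R(λ+1) − R(λ)) / 1 nm, assigned to the left wavelength.  This is
the simplest convention consistent with reading edge "areas" as plain sums
of derivative values, and it gives the exact telescoping identity
Σ_{λ=a}^{b} D(λ) = R(b+1) − R(a), which the tests exploit as an algebraic
oracle.

Window definitions: green peak = reflectance **max** in [510, 560] nm;
red valley = reflectance **min** in [640, 680] nm; red edge = derivative
max in [680, 760] nm; blue edge = derivative max in [490, 530] nm; edge
areas are derivative sums over the same windows.  One tabulation in the
source literature prints the red-valley amplitude as a "maximum", but the
narrated worked value for *Ulva pertusa* (minimum 5.78% at 669 nm) and the
name "red valley" make clear it is the chlorophyll absorption minimum;
this package computes the minimum.  Window-extremum ties break toward the
smallest wavelength, deterministically.  Indices with zero denominators
(possible only on degenerate flat curves) yield NaN and the sample is
excluded from fits using that column, with a logged count.

## Variable screening

Each variable is scored across classes by one-way ANOVA followed by Tukey
HSD on all class pairs; the star count is the number of pairs with
p ≤ 0.05.  Six species give 15 pairs, so counts range 0–15 (reports also
state the pair count explicitly; published tabulations that top out at 14
may reflect a different comparison layout, which cannot be resolved from
the available material).  Ranking is by descending star count with ties
broken by a fixed reference ordering (`SIGNIFICANCE_ORDER`, the published
significance order) so results are reproducible and comparable.

Backward elimination is standardized to strict one-at-a-time removal of
the lowest-ranked remaining variable, evaluating a classifier accuracy
after each removal, down to a single variable; the selected subset
maximizes accuracy with ties resolved toward the larger subset (a
constant evaluator therefore keeps all 14).  The nested chain visits the
published subsets, and replaying the published per-subset accuracies
through the procedure selects the published 8-variable optimum
(NDVI(R_g,R_r), RVI(R_g,R_r), V_re, A_be, R_g, L_re, L_g, L_r) at 74.99%.
Degenerate inputs: zero overall variance reports (F, p) = (0, 1) with a
flag; zero pooled within-group variance counts distinct-mean pairs as
significant, flagged.

## Classification

Features are z-scored with statistics from the training data only (the
scaler lives inside the fitted pipeline, so no public interface can refit
it on test data).  The SVM is a soft-margin RBF classifier with kernel
width g (gamma) and penalty c, tuned by exhaustive grid search maximizing
mean stratified 4-fold CV accuracy.  The default coarse grid spans
0.05–10.0 in steps of 0.25 for both parameters (1600 points); a fine grid
(step 0.05) is available when the extra resolution is worth the 25×
cost — the published optima all lie on a 0.05 lattice, but the original
grid is not documented, so optima are always searched, never hard-coded.
Grid ties prefer the smallest c, then the smallest g.  Other kernel knobs
(degree, coef0) are irrelevant to an RBF kernel and are not exposed.

The fusion model soft-votes the tuned SVM (probability outputs) with a
gradient-boosted tree classifier at fixed, untuned defaults (300 trees,
depth 3, learning rate 0.1): ensemble probability is the unweighted mean
of the two members' class probabilities and the label is its argmax.
Soft voting is used because with only two voters a hard majority cannot
break disagreements.  Predicted labels are always the argmax of the
probability matrix (ties to the smallest class index), keeping prediction
and ROC scoring consistent; note that Platt-calibrated SVM probabilities
can be poorly ordered on tiny degenerate training sets (e.g. classes of
identical duplicated points), which is an SVM-calibration property, not a
voting defect — the boosted member restores sane ordering in the fusion.

Splits are stratified 3:1 (train fraction 0.75) by default, reproducible
from a seed; per-class train sizes are within 1 of 0.75 × class count
(382 samples → 286/96).

## Evaluation

Multiclass accuracy is 100·trace/total of the confusion matrix, the
multiclass form of (TP+TN)/(TP+FP+TN+FN).  ROC analysis is one-vs-rest
per class; the micro average pools all (sample, class) indicator/score
pairs into one binary problem, and the macro average interpolates each
class's TPR on the pooled FPR grid and averages curves.  AUCs use the
trapezoid rule.  A class absent from the truth labels has an undefined
one-vs-rest curve and is excluded from the per-class set and macro
average with a warning.

The per-class PC1 representation column-centers one class's
samples × wavelengths matrix and takes the first SVD axis, sign-fixed to
non-negative mean so curves are comparable across runs; the explained
variance percentage (first eigenvalue over total) measures how
one-dimensional the within-class variation is.  ("Loading" is sometimes
used loosely for this quantity; what is computed and reported here is
explained variance.)

## The synthetic-data generator

The original field spectra are not publicly deposited, so the package
ships a generator whose defaults emulate the documented study conditions:
382 labeled samples (64 per species, 63 for the two *Sargassum*), split
as evenly as possible over three dryness states.

Per-class reference curves interpolate published band-wise reflectance
anchors with shape-preserving piecewise-cubic Hermite interpolation
(PCHIP): the curve passes through each anchor exactly, is monotone
between adjacent anchors (no overshoot), and therefore has local extrema
only at anchors.  Three phylum templates carry the printed values — e.g.
the green template peaks at 25.27% at 554 nm with its minimum 5.78% at
669 nm and a NIR plateau near 80%; the brown template's three visible
maxima at 570/596/643 nm with 3.74% at 596 nm and a 35% plateau; the red
template's 12.55% minimum at 536 nm, maxima at 648/678 nm and an 85–86%
plateau.  Dip/shoulder values not printed anywhere (the brown 570/583/620/
700-nm values, the red 663-nm saddle and 700-nm shoulder) are design
choices that realize the narrated shapes without contradicting any
printed number.  Species within a phylum share the template but shift the
green-band extremum anchor by {0, −14, −9} nm (red species) and scale
visible-band amplitude by {1.00, 0.95, 1.05} (red) / {1.00, 1.07}
(brown), mirroring published within-phylum location spreads: species are
separable but hard, phyla trivially separable — reproducing the ordering
of the published species-level (≈75%) vs phylum-level (≈94%) accuracies.

Per-sample perturbations, in order: dryness gain {wet 0.90, moderate
1.00, dry 1.10} (multiplicative; the literature does not quantify how
drying alters these spectra, so this is an explicit stand-in), amplitude
gain ~ Normal(1, 0.08) truncated to [0.7, 1.3] (thallus
thickness/geometry; the dominant variance component, which is what drives
per-species PC1 explained variance above 90%), integer wavelength shift
~ Uniform{−2, …, 2} nm (pigment jitter; flat extension at the span
edges), additive Gaussian noise (sd 0.4% before smoothing) smoothed with
a 5-nm Gaussian kernel (correlated sensor noise), and clipping to
[0, 100]%.  Everything is reproducible from a single integer seed.

What the generator does **not** emulate: radiative transfer or pigment
chemistry, canopy/water-column effects, layer-thickness saturation,
instrument-specific noise spectra, or any real within-species covariance
beyond the gain/shift/noise model.  Passing tests on synthetic data
therefore demonstrate that the *pipeline* is correct and that the
published *procedure* behaves as described under controlled class
structure — not that the published accuracies on the real field data are
reproduced.  The headline field-data accuracies are not reproducible
without the undeposited data, and no test claims them.

## Pipeline orchestration

`run_full_pipeline` derives per-stage seeds as
SHA-256(master_seed:stage) mod 2³¹, so adding a stage never perturbs
earlier stages' randomness.  The train/test split happens *before*
variable screening; ranking and elimination see only the training split
(the subset evaluator is 4-fold CV accuracy of an RBF-SVM over a small
4×4 grid on the training data — cheap enough to run 14 times), and the
test split is evaluated exactly once, at the end.  By default the final
classifier uses the fixed 8-variable optimal subset; `feature_subset:
"screened"` switches to the run's own elimination choice.  `report.json`
is bit-identical across re-runs of the same configuration (timings live
only in the manifest; the output directory is not part of the report).

## Problem sizes and numerical choices

Default analyses use 382 samples on the 501-point grid with the coarse
1600-point (g, c) grid and 4-fold CV — a desk-scale configuration chosen
so a full seeded benchmark (ten replicates) completes in minutes on one
CPU.  Tolerances: anchor pass-through and telescoping identities are
exact to 1e−9; probability rows must sum to 1 within 1e−6; PCA explained
variance matches a dense eigendecomposition to 1e−8.  Known limitations:
the dryness model is multiplicative only; Tukey star counts assume
balanced-ish groups (scipy's studentized-range implementation); SVC
probability calibration adds a seed-dependence to probabilities (pinned
by the model seed); and the CLI `evaluate` command relies on a joblib
sidecar written by `train` for the fitted estimator, since the JSON model
description alone cannot reconstruct support vectors.
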