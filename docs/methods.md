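# Methods

`tuberhsi` classifies potato tubers by industrial processing aptitude —
*cooking* versus *frying as crisps* — from near-infrared (900–1700 nm)
line-scan hyperspectral images of fresh-cut slices. This note documents
the models and procedures, the parameters that matter, what the
synthetic data emulate, and the design choices made where the design was
genuinely open.

## Reflectance calibration and band trimming

Raw camera counts `I(x, λ)` are converted to relative reflectance per
spatial column `x` and band `λ` against white- and dark-reference scans:

    R(x, λ) = (I(x, λ) − I_D(x, λ)) / (I_W(x, λ) − I_D(x, λ))

References may be recorded as scan-line stacks; they are averaged over
the scan direction before use, the standard correction for push-broom
systems whose gain pattern varies only across the slit. A degenerate
reference (|I_W − I_D| ≤ 1e-6 in count units) raises an error naming the
offending column and band rather than silently producing NaN.
Reflectance may optionally be clipped to [0, 2]; the pipeline leaves
clipping off because out-of-range excursions are rare and informative.

The instrument grid holds 256 bands from 900 to 1700 nm (≈3.14 nm
spacing). The first 30 bands are noisy at the detector edge and are
trimmed by default, leaving 226 bands from ≈994 nm.

## Segmentation

The slice rests on a dark plate, so a scalar projection (mean
reflectance over retained bands) separates tissue from background:
Otsu's threshold on a 256-bin histogram, then morphological closing
(disc radius 2 px), hole filling, and retention of the single largest
8-connected component (minimum 50 px). The published workflow's
superpixel/local-contrast pre-stage is a separate algorithm with its own
literature; mean-band projection followed by the same Otsu + morphology
binarization is used here instead and reaches Jaccard ≥ 0.95 against
ground truth on the synthetic slices, which is sufficient for the
downstream chemometrics. Structuring-element sizes are stated defaults,
configurable; no published values exist for them.

## Spectral pre-processing

Six operators compose into '+'-joined chains (e.g. `SM+SNV+MC`); the ten
chains compared in the reference experiments are `None`, `MC`,
`SM+SNV+MC`, `SM+MSC+MC`, `1D+MC`, `2D+MC`, `1D+SNV+MC`, `1D+MSC+MC`,
`2D+SNV+MC`, `2D+MSC+MC`.

* **SM** — Savitzky–Golay smoothing, 15-point window, 2nd-order
  polynomial. Edges use polynomial-fit extrapolation within the terminal
  window so no bands are lost and the filter is exact on polynomials of
  degree ≤ 2 everywhere.
* **SNV** — per-spectrum centering and scaling to unit standard
  deviation. The *sample* standard deviation (n−1) is used; either
  convention is defensible, this one is stated so results reproduce.
* **MSC** — each spectrum is regressed on a reference spectrum
  (`s = a + b·ref`) and corrected to `(s − a)/b`. The reference is the
  mean of the calibration spectra (per-pixel models use the mean over
  all calibration pixels); the choice is not prescribed anywhere
  authoritative and the calibration mean is the common default.
* **1D / 2D** — Savitzky–Golay derivatives, 15-point window, 2nd-order
  polynomial, reported per nm (divided by spacing^order). The derivative
  filters are treated as self-contained (no separate smoothing pass):
  a Savitzky–Golay derivative already embeds least-squares smoothing.
* **MC** — subtraction of the calibration-set mean spectrum.

MSC and MC are stateful: fitted on calibration data only and re-applied
frozen to test data, including inside every cross-validation fold.

## PLS-DA

Classes are dummy-coded as a two-column 0/1 matrix and regressed on the
spectra by PLS2. Latent variables are extracted with **SIMPLS**
(de Jong 1993), the default of the commercial toolbox ecosystem this
workflow mirrors; a NIPALS implementation is retained as an internal
cross-check oracle. For a two-class dummy response the centered Y has
rank 1, so SIMPLS and NIPALS span the same subspace and agree on
continuous responses to numerical precision — the test suite asserts
this, and also that the full-rank model reproduces a direct
least-squares solve.

The decision rule is the argmax of the predicted class responses
(equivalent to a 0.5 threshold on their difference); ties resolve to the
first class and are logged. A probabilistic (Bayes-threshold) decision
rule found in some toolboxes is deliberately not replicated — the argmax
rule is simpler, deterministic, and symmetric in the class coding.

**Cross-validation** uses venetian blinds: fold(i) = ⌊i/width⌋ mod
n_splits over sample order, with 10 splits and width 1 by default. For
pixel-wise models the folds are over pixels, replicating the reference
design; a grouped-by-tuber split would be statistically stricter but is
not the emulated protocol.

**Latent-variable count** is the smallest value minimizing the
unweighted mean of the calibration and cross-validation class errors
(the combination weighting is not prescribed; the unweighted mean is the
natural default). Both error curves are returned for audit.

**Metrics.** With TP/TN/FP/FN from the binary confusion matrix:
accuracy% = 100(TP+TN)/n, sensitivity = TP/(TP+FN), specificity =
TN/(TN+FP), class error = 1 − (sensitivity+specificity)/2. The cooking
class is the positive class. Tables are written with mirrored class rows
("C"/"FC") since in the binary case the second row's sensitivity is the
first row's specificity and the class error is shared. Presentation
rounding is 3 decimals for errors and 2 for accuracies (round-half-even);
raw values are retained in results objects.

## Forward iPLS

The 226-band spectrum is divided into contiguous equal-width intervals
(width 1 or 5 in the reference experiments). A remainder shorter
interval keeps full coverage when the band count is not a multiple —
dropping the tail bands would silently exclude the 1700 nm end of the
water-absorption shoulder. Greedy forward selection adds, at each step,
the interval minimizing RMSECV of the continuous PLS response; the LV
count of every candidate model is re-optimized (capped at 10) with the
same rule as above. "Automatic number of intervals" is interpreted as a
stopping rule: selection ends when the best candidate improves RMSECV by
less than a relative tolerance of 1e-3, or at a configured maximum.

## Synthetic data

No public dataset exists for this workflow, so the generator emulates
the acquisition end to end; every stage of the pipeline runs against it
with no downloads. What it reproduces:

* 320-column line-scan cubes, 256 bands on 900–1700 nm, variable rows
  (default 120); elliptical slice (default semi-axes 36×42 px ≈ 4.8k
  foreground pixels, matching the per-slice pixel counts of the
  emulated design) on a dark plate (background reflectance 0.03).
* A smooth reflectance baseline (0.50 at 900 nm to 0.42 at 1700 nm)
  minus Gaussian absorption valleys at 1015/1200/1450 nm (depths
  0.05/0.07/0.25, σ 20/35/45 nm): C–H stretch, the weak water
  combination band, and the first water overtone. Foreground
  reflectance lands mostly in [0, 0.6].
* A central pith (radius fraction 0.28) with reduced brightness
  (factor 0.80), a deepened water valley (+0.05 at 1450 nm, the
  pith's higher water / lower starch content), and an *attenuated*
  class signal (60 % loss), which is what makes false-positive pixels
  concentrate in the pith.
* The class effect: frying-class tubers get a +0.02 reflectance offset
  over 1200–1400 nm (flat-top window, 20 nm cosine ramps). Cultivar-
  and tuber-level jitter (sd 0.003 each) and a per-tuber flat baseline
  shift (sd 0.01) make tubers exchangeable rather than identical; the
  jitter scale is calibrated so that the headline mean-spectra
  experiment is recoverable (external accuracy ≥ 90 %) while a
  zero-offset control stays at chance.
* Per-pixel multiplicative/additive scatter (sd 0.04 / 0.008), sensor
  noise (sd 0.01 per pixel per band), column stripes (sd 0.003), and a
  3 px rim taper into the background (ground-truth mask = pixels that
  are majority foreground).
* White reference = 99 % tile under a smooth lamp spectrum and column
  gain at ~3000 counts; dark = 96-count sensor offset. The raw cube is
  synthesized by inverting the calibration equation, so calibration
  recovers the constructed reflectance exactly at zero noise.
* Ten named cultivars with dry-matter, starch and reducing-sugar
  chemistry in the cooking (DM 17–19 %) and crisping (DM 20–23.2 %,
  RS < 0.2 %) windows; the chemistry table's %RS column satisfies the
  DNSA-assay calibration `%RS = (absorbance − 0.00385) × 1.07893`
  exactly. Sub-selections of cultivars are class-interleaved so small
  simulated datasets remain binary problems.

What it does **not** emulate: radiative transfer (the spectral shapes
are phenomenological, not physical), spatial texture within tissues,
specular highlights, cultivar-specific spectral signatures beyond the
class offset, or chemistry–spectrum coupling (the chemistry table and
the cubes are statistically independent given the class). Passing tests
therefore demonstrate that the *pipeline* recovers structure it is
pointed at under realistic noise — not that real tubers are separable.

The spatial-resolution metadata of the emulated instrument (0.56
mm/pixel at 9 mm/s and 100 Hz) is internally inconsistent as printed
and is treated as descriptive metadata only.

## Study designs and problem sizes

* **Mean-spectra design**: 10 cultivars × 8 tubers = 80 cubes; one mean
  spectrum per tuber; stratified 75/25 split (60 calibration / 20
  validation); venetian blinds 10×1.
* **Pixel-wise design**: 3 tubers per cultivar (30 cubes, ≈143k
  foreground pixels); per cultivar 2 calibration + 1 validation tubers
  (≈100k / 43k pixels); folds over pixels. Classification maps are
  rendered for the 10 validation tubers with TP dark green, TN dark
  blue, FP light green, FN yellow.
* The iPLS recovery check uses an 80 × 226 matrix with the class signal
  confined to five known bands, against an exhaustive single-interval
  RMSECV oracle.

## Numerical choices and degenerate inputs

* Division guard 1e-6 on reference contrast; flat-spectrum guard 1e-12
  for SNV; |slope| guard 1e-12 for MSC — all raise typed errors naming
  the offending rows/positions.
* SIMPLS stops early when the residual covariance is numerically
  exhausted (singular value ≤ 1e-12); LV truncations beyond the found
  rank repeat the last component, and requested LV counts are capped at
  min(n−1, bands).
* Cross-validation folds whose training portion holds a single class
  are skipped with a warning and excluded from aggregation.
* Argmax ties in the decision rule go to the first class (logged).
* ENVI wavelengths are written as shortest round-tripping float
  representations so the uniform-grid invariant survives I/O.
* Coordinates are 0-based, row-major, origin top-left, throughout.

## Known limitations

* The published real-data accuracies cannot be reproduced here because
  the tuber dataset is unpublished; the synthetic recovery experiments
  characterize the pipeline, not the biology.
* Pixel-wise venetian blinds over pixels leak tuber identity between
  folds (as in the emulated protocol); the library exposes the split
  machinery to build grouped alternatives but does not default to them.
* MSC on derivative spectra can be ill-conditioned for near-flat rows;
  the slope guard raises rather than repairs.
* Only binary classification is supported; multiclass PLS-DA is out of
  scope.
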