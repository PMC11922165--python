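# Methods

## Pipeline model and assumptions

The pipeline treats an RGB endoscope as a colorimetric instrument that can
be mapped onto a reference spectrometer through three fitted objects: a
polynomial color correction, a PCA spectral basis, and a regression
transform from tristimulus values to basis scores. The underlying
assumptions are:

* the camera's deviation from ideal sRGB colorimetry (nonlinear response,
  color crosstalk, dark current) is smooth enough to be absorbed by a
  third-order polynomial in XYZ. The 20-term expansion contains every
  monomial of (X, Y, Z) up to degree 3; the dark current, being
  signal-independent, is realized as a constant-1 regressor whose
  per-channel weight is estimated inside the correction matrix;
* reflectance spectra of natural and mucosal surfaces are low-dimensional:
  a basis of 6–12 principal components fitted to 24 checker patches
  represents them to well under 1% residual variance;
* the mapping from corrected XYZ to basis scores is adequately captured by
  the 7-term color expansion (X, Y, Z, XY, XZ, YZ, XYZ).

All XYZ values are kept on the 0–100 scale (a perfect reflector under the
adopted normalization has Y = 100); Lab conversions use the same scale for
white points. Chromatic adaptation defaults to the identity diagonal —
capture and source white points are assumed to coincide unless the caller
supplies ratios — because no principled default exists without measured
white points.

## An information-theoretic limit of the reconstruction

A camera delivers three numbers per pixel, so the reconstructed spectrum
is, exactly, a fixed smooth function of (X, Y, Z). Two consequences are
worth stating explicitly.

First, with mean-centered PCA the scores of any spectrum family are an
*affine* function of XYZ (`scores = B⁻¹(XYZ − XYZ_of_mean)`), but the
7-term color expansion contains no constant term, so the score regression
cannot be exact after centering — there is always a residual floor. Exact
end-to-end closure (reconstruction RMSE at machine precision) is possible
only for spectra confined to a rank-3 *linear* (through-origin) family
with the basis fitted uncentered; the synthetic module provides such a
generator (`make_low_rank_checker_spectra`) precisely for closure testing.
Centering remains the default for ordinary use because variance-explained
fractions are otherwise ill-defined; the uncentered option is exposed.

Second, on realistic 24-patch checkers the score matrix spans more than
three dimensions, so the transform can only capture the component of the
scores that is predictable from three tristimulus degrees of freedom.
Training reconstruction RMSE on the smooth synthetic checker plateaus
near 0.07 reflectance units from k ≈ 6 onward: the bottleneck is
metamerism, not basis size. Reconstruction error is therefore
non-increasing in k but not driven to zero by it.

## Parameters

| parameter | default | meaning |
|---|---|---|
| k (basis size) | 12 | principal components kept; 6 offered as a compact preset (the two conventional choices for checker-derived bases — both are tested) |
| RGB→XYZ matrix | standard sRGB/D65 | a published variant with a perturbed first row (0.4104, duplicated 0.3576) is selectable as `"published"`; it is not a valid sRGB matrix and breaks white-point consistency, so it is not the default |
| integration limits | 380–780 nm | full-grid integration keeps spectrum→XYZ consistent with the 380–780 nm reconstruction output; a 400–700 nm option exists for pipelines that integrate the narrower range |
| pseudoinverse cutoff | 1e-10 (relative) | 24 patches against 20 regressors is nearly square; the cutoff guards conditioning without biasing well-posed fits |
| Lab threshold | (6/29)³, offset 4/29 | the standard cube-root/linear split (≈ 0.008856 and 0.137931) |
| train/validation split | none for calibration | 24 patches match the single-target procedure; calibration reports are in-sample by design |

CIEDE2000 is implemented per the public standard (chroma-dependent
weighting, hue rotation term) and verified against 34 published test pairs
and an independent implementation to 1e-9.

## Band configurations and rendering

Seven named configurations are frozen, white-light first; endpoints are
inclusive on the 1 nm grid. The fifth configuration uses 540–590 nm for
its green component (the variant with 540–780 is available as
`cfg5_alt_540_780`, since the originating description states both). Rendering
normalizes luminance against the FULL illuminant, so narrow bands render
dim and tinted — their true relative brightness. The display mode instead
rescales the whole image so its brightest XYZ component reaches full
scale; normalizing against the masked illuminant was rejected because the
luminance curve ȳ is nearly zero around 405–415 nm, making that
normalization divergent exactly in the band of interest.

## Classification harness

Metrics are computed from confusion counts with bleeding as the positive
class; zero-denominator metrics are returned as undefined (`None`), never
as silent zeros. The published seven-row metric table reconciles with its
stated group totals (121/145) only if those are predicted-class totals —
precision 95/121, recall 95/114, specificity 126/152 for the white-light
row — and the harness adopts that reading. Comparisons against printed
values allow one unit in the last printed digit, because one printed value
(specificity 113/165 → printed 0.684) is truncated rather than rounded
and two are printed at two decimals.

Splits are patient-level (no patient spans train and test) and stratified
by the patient's majority label, so both splits see both classes whenever
a class has more than one patient. Two reference classifiers ship with the
harness: a band-energy logistic baseline (per-channel mean, SD and
10th/90th percentiles, standardized), and a compact convolutional
reference — a bank of seeded random 3×3×3 filters with ReLU, 2×2 average
pooling and a standardized logistic head — which stands in for large
transfer-learned networks at desk scale while honoring the same
deterministic fit/predict contract. Any classifier with that contract can
be plugged in.

## Synthetic-data generator

The generator emulates, from explicit seeds only:

* **checker spectra** — 18 chromatic patches as Gaussian mixtures passed
  through a gentle logistic squash (smooth, strictly inside [0, 1]) plus
  6 exactly flat neutral grays (0.90 … 0.03);
* **camera** — spectral integration to XYZ, a 3×3 mixing matrix
  (default: exact inverse of the sRGB matrix, i.e. a colorimetrically
  ideal device), per-channel polynomial distortion up to cubic, dark
  offset, optional additive Gaussian noise, sRGB gamma encoding;
* **tissue frames** — a mucosa-like baseline (dim blue rising into red)
  multiplied by hemoglobin-style absorption bands: a strong Soret-like
  band at 415 nm (width 28 nm) and Q-like bands at 540/577 nm whose
  depths sit near one ninth of the Soret depth, mirroring hemoglobin's
  extinction ratio. Bleeding tissue receives the deep defaults
  (0.90/0.25/0.20), non-bleeding the shallow ones (0.25/0.05/0.04).
  Absorption depth is modulated by a smooth spatial texture field;
  per-frame brightness jitter (±25%) emulates exposure variation; a
  per-frame red-shoulder "scatter" jitter (±25% above ~620 nm) emulates
  the class-independent structural variability that deep-penetrating red
  light reflects. Under these defaults the class-mean reflectance gap per
  nanometre is largest inside 405–415 nm.

The illuminants are an equal-energy spectrum and a white-LED endoscope
lamp model (blue pump at 450 nm, σ = 20 nm, broad phosphor lobe at
560 nm). The color-matching functions are a smooth multi-lobe Gaussian
analytic approximation of the CIE 1931 2° observer (equal-energy
chromaticity within 3×10⁻⁴ of 1/3), packaged as CSV.

What the generator does **not** emulate: radiative-transfer tissue optics,
specular highlights, vignetting, motion blur, debris, compression
artifacts, and inter-patient anatomical variability. Passing tests on
these fixtures therefore demonstrate that the pipeline's mathematics is
correct and that its band-selection logic recovers a spectrally planted
signal; they do not demonstrate clinical-grade performance on real
capsule-endoscopy frames.

## Problem sizes and determinism

Experiments run at desk scale by choice: 24-patch calibrations, 32×32 or
16×16 tissue frames, 24 frames per class, five seeded replicates for the
band-ranking comparison (seeds also regenerate rigs, so each replicate is
a fresh camera, checker and cohort). All randomness flows from explicit
`numpy` generators; two runs with the same seed produce bit-identical
cubes, metrics files and predictions.

## Known limitations

* The reconstruction carries at most three degrees of freedom per pixel;
  spectra outside the checker-spanned manifold are represented by their
  closest in-model proxy (metamerism floor above).
* The correction matrix inverts the camera's distortion only within the
  gamut sampled by the checker; extreme colors extrapolate.
* The analytic color-matching functions deviate pointwise by a few percent
  from the tabulated observer; all quantities are internally consistent,
  but absolute XYZ values differ slightly from ones computed with
  tabulated data.
* With white LED illumination the lamp emits little power below ~430 nm,
  so the 405–415 nm band of a reconstructed cube is an extrapolation
  informed mostly by the blue channel — informative, but the noisiest part
  of the reconstruction, which is why sensor noise degrades the blue-band
  classifier before the others.
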