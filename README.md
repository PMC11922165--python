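# specband

Spectral reconstruction through band selection for white-light endoscopy.

Capsule endoscopes record ordinary RGB (white-light) frames, yet much of
what distinguishes bleeding from non-bleeding mucosa is spectral: hemoglobin
absorbs strongly near 415 nm (the Soret band) and moderately near
540/577 nm (the Q bands). `specband` calibrates an RGB endoscope against a
24-patch color checker, reconstructs a 401-band visible-light reflectance
cube (380–780 nm at 1 nm) for every pixel, re-renders images restricted to
chosen wavelength bands — simulating narrow-band imaging in software — and
evaluates bleeding / non-bleeding classification per band configuration.
It is aimed at researchers in biomedical image analysis who want a fully
reproducible, self-contained desk-scale version of this pipeline: every
input it needs (checker spectra, camera, tissue frames) can be synthesized.

## Model

Calibration relates the camera to a reference spectrometer through the
CIE 1931 XYZ space:

* sRGB frames are linearized (gamma removal) and mapped to tristimulus
  values, `XYZ_camera = M_A · T · f(RGB) × 100`;
* measured patch reflectances `R(λ)` are integrated against the illuminant
  `S(λ)` and the color-matching functions, `X = k ∫ S R x̄ dλ` with
  `k = 100 / ∫ S ȳ dλ`, giving `XYZ_spectrum`;
* a 3×20 correction matrix `C = XYZ_spectrum · pinv(V)` regresses the
  spectrometer values on a 20-term cubic expansion `V` of `XYZ_camera`
  (all monomials of X, Y, Z up to third order plus a constant absorbing
  the dark current), yielding `XYZ_corrected = C · V`;
* PCA of the 24 patch spectra gives an orthonormal basis `E` (k×401,
  k = 12 by default, 6 as a compact preset) with scores
  `αᵀ = Rᵀ · pinv(E)`; a k×7 transform `M = α · pinv(V_color)` regresses
  the scores on the 7-term color expansion
  `V_color = (X, Y, Z, XY, XZ, YZ, XYZ)`;
* per pixel, the reconstructed spectrum is
  `S(λ) = mean(λ) + Eᵀ · M · V_color(XYZ_corrected)`.

Band selection masks the cube to named wavelength sets (seven
configurations: white light; 540–780; 470–500 ∪ 540–780; 470–500;
405–415 ∪ 470–500 ∪ 540–590; 405–415; 405–415 ∪ 535–545 nm) and renders
the masked spectra back to sRGB. Calibration quality is reported as XYZ
RMSE and CIEDE2000 between corrected and spectrometer values; classifiers
are scored by accuracy, precision, recall, specificity and F1 from
confusion counts, with bleeding as the positive class.

## Worked example

Python, using the synthetic rig (a distorted camera fitted and corrected):

```python
from specband.experiments import calibration_quality_experiment, published_metric_table

q = calibration_quality_experiment(seed=1)
print(f"dE00 uncorrected {q.mean_delta_e_uncorrected:.3f} -> corrected {q.mean_delta_e_corrected:.4f}")
print(f"12-component basis explains {100 * q.pca12_variance_fraction:.2f}% of checker variance")

wli = published_metric_table()["wli"]
print(f"white-light row: accuracy {wli.accuracy:.3f}, precision {wli.precision:.3f}")
```

prints

```
dE00 uncorrected 3.886 -> corrected 0.0982
12-component basis explains 100.00% of checker variance
white-light row: accuracy 0.831, precision 0.785
```

i.e. the polynomial correction removes ~97% of the camera's perceptual
color error on the checker, the checker spectra are numerically
low-dimensional, and the white-light evaluation metrics follow from the
confusion counts (221 of 266 frames correct).

The same pipeline from the shell:

```
$ specband simulate --seed 7 --out demo
wrote calibration target and 48 frames to demo
$ specband calibrate --target demo --out demo/calibration.json
calibrated: mean XYZ RMSE 0.03478, mean dE00 0.07337
$ specband evaluate --manifest demo/manifest.csv --calibration demo/calibration.json --config cfg6 --seed 7
configuration,accuracy,precision,recall,specificity,f1,tp,fp,tn,fn
cfg6_405_415,1.0,1.0,1.0,1.0,1.0,8,0,8,0
```

Here the 405–415 nm configuration classifies the 16 held-out synthetic
frames perfectly; the calibration recovered the simulated camera to a mean
color error of ΔE00 ≈ 0.07 (well below a just-noticeable difference).

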