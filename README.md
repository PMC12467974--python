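# endospec

Hyperspectral reconstruction and narrow-band imaging (NBI) emulation for
white-light endoscopy images.

Standard endoscopes — and in particular wireless capsule endoscopes — record
only broadband RGB. Hardware enhancements such as Olympus NBI, which
illuminate the mucosa at the 415 nm and 540 nm hemoglobin absorption peaks to
bring out vasculature, are not available on capsule systems. `endospec`
provides the software alternative: it calibrates a camera against a 24-patch
color checker, reconstructs a per-pixel reflectance spectrum from each sRGB
frame, and renders narrow-band views from the reconstructed hyperspectral
cube. It is aimed at researchers building spectrally enhanced computer-aided
diagnosis pipelines on ordinary endoscopy footage.

## Method

The chain has four calibrated stages:

1. **Device linearization.** 8-bit sRGB is decoded with the IEC 61966-2-1
   transfer function and mapped to CIE XYZ through the standard sRGB/D65
   primary matrix (XYZ on the 0–100 scale).

2. **Variable-matrix correction.** Camera XYZ is expanded in the fixed
   20-term monomial basis `[1, X, Y, Z, X², …, XYZ]` (third order — the cap
   guards against overcorrection; the constant term absorbs dark current) and
   mapped onto spectrometer-reference XYZ by least squares,

       C = XYZ_ref · pinv(V),        XYZ_corr = C · V,

   where the columns of `V` are the expanded patch features. Reference XYZ
   comes from tristimulus integration of the patch reflectances,
   `X = k ∫ S(λ) R(λ) x̄(λ) dλ` over 400–700 nm, with
   `k = 100 / ∫ S(λ) ȳ(λ) dλ`.

3. **PCA spectral basis.** The 24 checker reflectances are reduced to six
   principal components (covering > 99.6 % of their variance), and a second
   least-squares map `M = Score · pinv(V_color)` takes corrected-XYZ features
   to PC scores. A pixel's reflectance is `mean + score · loadings`, clipped
   to [0, 1] — turning an RGB image into a 39-band reflectance cube on the
   400–780 nm grid.

4. **Narrow-band rendering.** A band model (Gaussian bands at 415/540 nm,
   FWHM 30 nm, plus auxiliary 600/700/780 nm bands feeding the red channel)
   integrates each pixel spectrum per band; the 415 nm response drives
   display B and G, the 540 nm group drives R. Band weights are calibrated
   against reference patch colors by fast simulated annealing with the
   Cauchy–Lorentz visiting distribution
   `f(x; x₀, γ) = 1/(πγ(1 + ((x−x₀)/γ)²))` under a mean-CIEDE2000 objective
   and the fast cooling schedule `T_k = T₀/(1+k)`.

Everything is testable offline: a synthetic-camera module generates checker
captures with configurable spectral sensitivities, sRGB gamma, dark current,
Gaussian noise and a planted polynomial color distortion, alongside the
noiseless "spectrometer" ground truth.

## Worked example

```python
from endospec import colorchecker_reference, fit_spectral_basis
from endospec.evaluation import round_trip_report, calibration_gain_report

basis = fit_spectral_basis(colorchecker_reference(), n_pc=6)
print(f"6-PC explained variance: {basis.explained_variance_ratio.sum():.4f}")

rt = round_trip_report()          # noiseless camera, full chain, 24 patches
print(f"mean spectral RMSE : {rt['mean_rmse']:.4f}")
print(f"max  spectral RMSE : {rt['max_rmse']:.4f}")
print(f"black-patch RMSE   : {rt['black_rmse']:.4f}")
print(f"mean dE00 (colors) : {rt['mean_de2000']:.3f}")

gain = calibration_gain_report(noise_sigma=0.01, seed=7)
print(f"dE00 before/after  : {gain['mean_de2000_pre']:.2f} -> {gain['mean_de2000_post']:.3f}")
```

prints

```
6-PC explained variance: 0.9992
mean spectral RMSE : 0.0204
max  spectral RMSE : 0.0688
black-patch RMSE   : 0.0146
mean dE00 (colors) : 0.572
dE00 before/after  : 10.87 -> 0.505
```

Six components carry 99.9 % of the checker set's spectral variance; the
noiseless round trip (capture → correct → reconstruct) reproduces every patch
spectrum to RMSE < 0.07 (black, the easiest patch, to 0.015) and the colors
of the reconstructed spectra to about half a just-noticeable difference
(ΔE00 ≈ 0.57). On the deliberately miscalibrated camera — planted
second-order color distortion plus σ = 0.01 sensor noise — fitting the
third-order correction pulls the mean color error from 10.9 down to 0.5.

A `endospec` console script exposes the same pipeline from the shell:
`endospec fixtures make`, `endospec calibrate`, `endospec convert --mode
hsi|nbi`, `endospec evaluate`, `endospec manifest summarize`.

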