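# Methods

This note documents the models implemented in `endospec`, the defaults and
why they were chosen, what the synthetic fixtures do and do not emulate, and
the numerical conventions the tests rely on.

## Spectral representation

Reflectance spectra live on a uniform 400–780 nm grid at 10 nm (39 bands).
Storage extends to 780 nm so the auxiliary near-infrared narrow bands
(600/700/780 nm) remain representable, but all tristimulus integration is
restricted to a 400–700 nm window, where the CIE 1931 2° observer carries
essentially all of its weight. Integrals use the trapezoid rule; the
integrands (illuminant × reflectance × observer) are smooth at 10 nm, and
grid-step invariance is covered by tests. The normalization
`k = 100 / ∫ S ȳ dλ` is recomputed per illuminant, so a perfect reflector has
Y = 100 exactly under any light source.

The observer is the CIE 1931 2° standard observer at 10 nm and the default
illuminant is D65, both bundled as CSV tables; with this tabulation and
window the computed D65 white point agrees with the canonical
(95.047, 100, 108.883) to within 0.5 units. Both are configurable — the
light source of a particular endoscope can be substituted by loading another
table onto the grid.

## Camera correction

Decoded camera colors are corrected with a linear map over a polynomial
feature expansion of (X, Y, Z). The monomial set is fixed and ordered —
`[1, X, Y, Z, X², Y², Z², XY, XZ, YZ, X³, Y³, Z³, X²Y, X²Z, XY², Y²Z, XZ²,
YZ², XYZ]` (20 terms at order 3) — so serialized models are unambiguous. The
constant term's learned coefficient acts as the dark-current offset; the
expansion is capped at third order because higher orders overfit 24 training
patches badly. The solve is `C = ref · pinv(V)` with an SVD pseudoinverse at
relative cutoff 1e-10; rank deficiency (e.g. all-identical patches) is
recorded in the fit report rather than raised.

Correction operates in XYZ, after sRGB decoding and the primary matrix, not
on raw RGB: the correction model is defined over tristimulus quantities, and
out-of-gamut (negative) values are deliberately carried through unclipped so
the regression is not biased; clipping happens only at 8-bit display
encoding.

With 24 patches and 20 terms the fit is close to interpolation, so training
residuals are small while leave-one-patch-out error is necessarily larger
(about an order of magnitude above training error on the noiseless synthetic
camera, yet still far below the uncorrected error). This is the expected
bias/variance trade at chart scale and the reason the order cap exists;
calibrating from patch-region means of a photographed chart (see below)
keeps the effective noise per patch low.

## Spectral basis and reconstruction

The checker reflectances are decomposed by mean-centered PCA (SVD); six
components are kept by default. Loadings are orthonormal with explained
variance nonincreasing; signs are fixed so each loading's largest-magnitude
entry is positive, making fits bit-reproducible. The transformation matrix
`M = Score · pinv(V_color)` is fit on the same 20-term expansion of the
*corrected* XYZ — the chain defines the feature map once and reuses it for
both regressions, which keeps the two solves dimensionally consistent. Reconstruction is `mean + (M·v) · loadings`, clipped to [0, 1].

Reported reconstruction error is the mean over patches of each patch's
per-band RMSE; the pooled global RMSE over all bands and patches is computed
alongside (the two differ little on the checker set and the summary
convention matters only in edge cases).

## Synthetic fixtures

The generator exists so the whole chain can be exercised with no external
data; its defaults define the package's operating point.

* **Checker table.** A synthetic analog of the classic 24-patch chart: six
  near-flat neutral greys at the classic luminous-reflectance levels
  (0.90 … 0.031) and eighteen smooth chromatic curves (monotone cubic
  interpolation through eight control points per patch) mimicking each
  classic patch's qualitative spectral shape. It is *not* a measurement of a
  physical chart; it reproduces the structural properties that matter here —
  smoothness, [0, 1] range, a grey axis, and a spectral set whose six
  principal components carry > 99.6 % of the variance.
* **Camera.** Gaussian-shaped RGB sensitivities peaking at 610/550/460 nm
  with 70 nm FWHM — deliberately different from the CIE observer so the
  polynomial correction has genuine work to do (the uncorrected color error
  of this camera is ≈ 14 ΔE00). Channel responses are treated as pseudo-XYZ,
  normalized by the green-channel integral, passed through the optional
  distortion, dark offset (constant, ≤ 0.05) and additive Gaussian noise,
  and encoded to sRGB. Encoding is sign-preserving for float captures so
  that noiseless captures are exactly invertible; the 8-bit mosaic clips and
  quantizes like a real file. A colorimetric variant (`SyntheticCamera.ideal`)
  uses the observer itself as sensitivities and decodes back to the
  spectrometer XYZ to 1e-9, pinning the geometry of the capture model.
* **Planted distortion.** A fixed second-order polynomial in the three
  responses (channel gains 0.75–0.85, crosstalk, mild quadratic terms),
  shipped as a CSV fixture — not regenerated per run — chosen so an
  uncorrected capture of the checker sits above 10 ΔE00 mean.
* **Calibration-gain experiment.** The distorted camera with σ = 0.01 noise
  (fixture seed 7) photographs the 4×6 mosaic at 16 px patches; each patch
  region is decoded to linear RGB and averaged before conversion to XYZ,
  which is how a chart photograph is reduced for calibration in practice.
  The correction then brings the mean color error from ≈ 10.9 to ≈ 0.5.

What the fixtures do *not* emulate: endoscope optics, specular highlights,
vignetting, spatially varying illumination, mucosal scene statistics, or the
spectral response of any real sensor. Passing tests therefore demonstrate
that the calibration chain is implemented correctly and behaves as designed
under controlled conditions — not that a particular physical endoscope would
reach the same error levels.

## Narrow-band model

Bands are Gaussian: 415 nm and 540 nm at 30 nm FWHM (the hemoglobin
absorption peaks; only centers are dictated by the physics, the width is a
design default), plus auxiliary bands at 600/700/780 nm at 20 nm FWHM that
feed the red display channel to mimic the brown cast real systems show. The
display mapping (415 → B and G, 540-group → R) follows the Olympus
convention and is configurable. Per-band pixel response is the
ȳ-weighted in-band average of the reflectance, normalized so a perfect
reflector reads 1.0 per band; channels are weighted band sums, clipped, then
sRGB-encoded. Before clipping the renderer is exactly linear in the cube.

Weight calibration minimizes the mean CIEDE2000 between rendered and
reference patch colors with fast simulated annealing: per-coordinate Cauchy
steps `x + γ_k tan(π(u−½))` (inverse-CDF sampling of the visiting
distribution), scale `γ_k = γ·T_k/T₀`, cooling `T_k = T₀/(1+k)`, Metropolis
acceptance, reflection at the [0, 1] bounds (reflection rather than clamping
so proposals are not piled onto the box edges), and best-ever bookkeeping.
Defaults: γ = 0.1 per weight, T₀ = 1, 5000 iterations, seed 42. The
optimizer is derivative-free because the clipped renderer is only piecewise
smooth. Per-band weights (five parameters) rather than a per-wavelength
spectrum keep the problem identifiable from 24 patches.

## Quality metrics

Spectral RMSE is the per-band root-mean-square difference. SSIM uses the
standard Gaussian-window convention (11×11, σ = 1.5, K1 = 0.01, K2 = 0.03,
dynamic range 255; color images averaged over per-channel scores) via
scikit-image. PSNR is `10·log10(255²/MSE)` with identical images capped at
100 dB instead of returning infinity. Histogram entropy is Shannon entropy
of the 256-bin histogram in bits (color reduced by BT.601 luma); the
pairwise comparison is reported both in bits and as a percentage of the
8-bit maximum — the percentage convention is flagged experimental, as it is
not a standardized unit.

## Problem sizes

All validation experiments run at chart scale: 24 patches, 4×6 mosaics at
16 px per patch, 39 bands, annealing budgets of a few thousand iterations.
These sizes make every harness rerun from scratch in seconds while leaving
the statistics (noise averaging over 256 px patches, 1e5-sample
distributional checks) well resolved.

## Known limitations

* The correction and basis are global; spatially varying illumination or
  vignetting would need per-region calibration, which is out of scope.
* Reconstruction is a six-dimensional linear model: metameric failures of a
  three-channel camera cannot be resolved, and spectra far outside the span
  of the training chart (narrow emission features, fluorescence) will not be
  recovered.
* Comparisons against real narrow-band hardware require proprietary
  reference images of the same scenes and are not part of the test surface;
  the NBI calibration is validated against planted synthetic references
  only.
* 8-bit inputs quantize dark patches coarsely; 16-bit input is accepted but
  downscaled with a warning rather than used at full precision.
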