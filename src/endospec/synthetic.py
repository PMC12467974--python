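"""Synthetic fixtures: checker reflectances and a parametric camera model.

Everything the calibration chain needs can be generated here without external
data: a bundled 24-patch reflectance table shaped like the classic Macbeth /
X-Rite chart, a camera with smooth RGB spectral sensitivities, sRGB-style
encoding, dark current, Gaussian shot noise and an optional planted polynomial
color distortion, plus the noiseless "spectrometer" side of each capture.

The bundled checker table is a synthetic analog of the published chart: six
near-flat neutral greys at the classic reflectance levels and eighteen smooth
chromatic curves mimicking each patch's qualitative spectral shape.  It is
not a measurement of a physical chart.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .calibration import FeatureExpansion, expand_features
from .colorimetry import (
    ColorMatchingFunctions,
    Illuminant,
    ReflectanceSpectrum,
    RGB_TO_XYZ_100,
    SpectralGrid,
    XYZ_100_TO_RGB,
    _data_table,
    _resample,
    _srgb_decode_signed,
    _srgb_encode_signed,
    load_cmfs,
    load_d65,
    spectrum_to_xyz,
)
from .spectral_basis import HyperspectralCube

__all__ = [
    "SyntheticCamera",
    "colorchecker_reference",
    "planted_distortion",
    "simulate_capture",
    "decode_capture_xyz",
    "make_checker_mosaic",
    "NEUTRAL_NAMES",
    "BLACK_PATCH",
]

NEUTRAL_NAMES = (
    "white_9_5", "neutral_8", "neutral_6_5", "neutral_5", "neutral_3_5", "black_2",
)
BLACK_PATCH = "black_2"


def colorchecker_reference(grid: SpectralGrid | None = None) -> list[ReflectanceSpectrum]:
    """The bundled 24-patch checker analog, resampled to *grid*.

    Patch order follows the classic chart layout (rows of six): natural
    colors, miscellaneous chromatic, primaries/secondaries, neutral series
    from white to black.
    """
    grid = grid or SpectralGrid.default()
    t = _data_table("colorchecker_synthetic_10nm.csv")
    wl = t["wavelength_nm"].to_numpy(float)
    out = []
    for name in t.columns[1:]:
        vals = np.clip(_resample(wl, t[name].to_numpy(float), grid), 0.0, 1.0)
        out.append(ReflectanceSpectrum(grid, vals, name=name))
    assert len(out) == 24
    return out


def planted_distortion() -> np.ndarray:
    """Fixed second-order color distortion coefficients, shape (3, 10).

    Rows map the order-2 monomial expansion of the camera's normalized
    channel responses to distorted responses; the coefficients are a bundled
    fixture (gain loss, channel crosstalk, mild quadratic terms) strong
    enough that an uncorrected capture of the checker shows a mean CIEDE2000
    error above ten.
    """
    t = _data_table("planted_distortion_order2.csv")
    return np.stack([t[c].to_numpy(float) for c in ("coef_x", "coef_y", "coef_z")])


@dataclass
class SyntheticCamera:
    """Parametric RGB camera with known spectral sensitivities.

    The three sensitivities act like a private set of color matching
    functions: channel responses are ``integral(S * R * sens_i)`` normalized
    so the green channel of a perfect reflector reads 1.0.  Responses pass
    through the optional planted polynomial distortion, gain a dark-current
    offset and Gaussian noise, and are encoded to sRGB through the standard
    XYZ -> linear RGB matrix (responses are treated as pseudo-XYZ on the 0-1
    scale).  Out-of-gamut values are encoded sign-preservingly so that
    float captures remain exactly invertible.
    """

    grid: SpectralGrid
    sensitivities: np.ndarray                 # (3, n_bands), >= 0
    dark_offset: np.ndarray = field(default_factory=lambda: np.zeros(3))
    noise_sigma: float = 0.0
    distortion: np.ndarray | None = None      # (3, 10) order-2 coefficients
    seed: int = 0

    def __post_init__(self) -> None:
        s = np.asarray(self.sensitivities, float)
        if s.shape != (3, self.grid.n_bands):
            raise ValueError("sensitivities must be (3, n_bands)")
        if np.any(s < 0):
            raise ValueError("sensitivities must be nonnegative")
        self.sensitivities = s
        self.dark_offset = np.asarray(self.dark_offset, float).reshape(3)
        if np.any(self.dark_offset < 0) or np.any(self.dark_offset > 0.05):
            raise ValueError("dark offset must lie in [0, 0.05]")
        if self.distortion is not None:
            d = np.asarray(self.distortion, float)
            if d.shape != (3, 10):
                raise ValueError("distortion must be (3, 10) order-2 coefficients")
            self.distortion = d

    @classmethod
    def default(
        cls,
        grid: SpectralGrid | None = None,
        noise_sigma: float = 0.0,
        dark_offset: float = 0.0,
        distorted: bool = False,
        seed: int = 0,
    ) -> "SyntheticCamera":
        """Gaussian-shaped RGB sensitivities (peaks 610/550/460 nm, FWHM 70 nm).

        Deliberately distinct from the CIE observer so the polynomial
        correction has genuine work to do.
        """
        grid = grid or SpectralGrid.default()
        wl = grid.wavelengths
        sigma = 70.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))
        peaks = (610.0, 550.0, 460.0)  # response channels ordered like (X, Y, Z)
        sens = np.stack([np.exp(-0.5 * ((wl - p) / sigma) ** 2) for p in peaks])
        return cls(
            grid,
            sens,
            dark_offset=np.full(3, dark_offset),
            noise_sigma=noise_sigma,
            distortion=planted_distortion() if distorted else None,
            seed=seed,
        )

    @classmethod
    def ideal(
        cls, grid: SpectralGrid | None = None, cmf: ColorMatchingFunctions | None = None
    ) -> "SyntheticCamera":
        """Colorimetric camera whose sensitivities equal the CIE observer.

        Its captures decode back to the spectrometer XYZ exactly (no dark
        current, noise or distortion).
        """
        grid = grid or SpectralGrid.default()
        cmf = cmf or load_cmfs(grid)
        return cls(grid, np.stack([cmf.xbar, cmf.ybar, cmf.zbar]))

    def linear_responses(
        self, spectra: np.ndarray, illuminant: Illuminant, rng: np.random.Generator
    ) -> np.ndarray:
        """Noisy, distorted linear channel responses for reflectance rows."""
        grid = self.grid
        if illuminant.grid != grid:
            raise ValueError("illuminant grid does not match the camera grid")
        m = grid.window_mask()
        wl = grid.wavelengths[m]
        S = illuminant.power[m]
        R = np.atleast_2d(spectra)[:, m]
        raw = np.stack(
            [np.trapezoid(S * R * self.sensitivities[i][m], wl, axis=-1) for i in range(3)],
            axis=-1,
        )
        norm = np.trapezoid(S * self.sensitivities[1][m], wl)
        resp = raw / norm
        if self.distortion is not None:
            V = expand_features(resp, FeatureExpansion(2))  # (n, 10)
            resp = V @ self.distortion.T
        resp = resp + self.dark_offset
        if self.noise_sigma > 0:
            resp = resp + rng.normal(0.0, self.noise_sigma, resp.shape)
        return resp


def simulate_capture(
    scene_spectra: list[ReflectanceSpectrum] | np.ndarray,
    camera: SyntheticCamera,
    illuminant: Illuminant | None = None,
    cmf: ColorMatchingFunctions | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Capture reflectance spectra with the synthetic camera.

    Returns ``(srgb, true_xyz)``: float sRGB triplets (rows, unquantized,
    sign-preserving outside [0, 1]) and the paired noiseless spectrometer-side
    XYZ computed by direct tristimulus integration.  Reproducible given the
    camera seed.
    """
    grid = camera.grid
    illuminant = illuminant or load_d65(grid)
    cmf = cmf or load_cmfs(grid)
    if isinstance(scene_spectra, (list, tuple)):
        for s in scene_spectra:
            if s.grid != grid:
                raise ValueError("scene spectra are not on the camera grid")
        spectra = np.stack([s.values for s in scene_spectra])
    else:
        spectra = np.atleast_2d(np.asarray(scene_spectra, float))
        if spectra.shape[1] != grid.n_bands:
            raise ValueError("scene spectra are not on the camera grid")
    rng = np.random.default_rng(camera.seed)
    resp = camera.linear_responses(spectra, illuminant, rng)
    # responses are pseudo-XYZ on the 0-1 scale; map through the standard matrix
    lin_rgb = resp @ (XYZ_100_TO_RGB * 100.0).T
    srgb = _srgb_encode_signed(lin_rgb)
    true_xyz = spectrum_to_xyz(spectra, illuminant, cmf)
    return srgb, np.atleast_2d(true_xyz)


def decode_capture_xyz(srgb: np.ndarray) -> np.ndarray:
    """Camera-side XYZ as the pipeline sees it: decode and apply the matrix."""
    lin = _srgb_decode_signed(np.asarray(srgb, float))
    return lin @ RGB_TO_XYZ_100.T


def make_checker_mosaic(
    camera: SyntheticCamera,
    patch_px: int = 16,
    illuminant: Illuminant | None = None,
) -> tuple[np.ndarray, HyperspectralCube]:
    """Render a 4 x 6 checker mosaic plus its ground-truth reflectance cube.

    The image is 8-bit sRGB with per-pixel noise; the cube holds the true
    patch reflectances.
    """
    if patch_px < 1:
        raise ValueError("patch_px must be >= 1")
    grid = camera.grid
    illuminant = illuminant or load_d65(grid)
    patches = colorchecker_reference(grid)
    spectra = np.stack([p.values for p in patches])  # (24, B)

    n_pix = patch_px * patch_px
    rng = np.random.default_rng(camera.seed)
    rows = []
    for _ in range(n_pix):
        rows.append(camera.linear_responses(spectra, illuminant, rng))
    resp = np.stack(rows, axis=1)  # (24, n_pix, 3)
    lin_rgb = resp @ (XYZ_100_TO_RGB * 100.0).T
    srgb = np.clip(_srgb_encode_signed(lin_rgb), 0.0, 1.0)
    img8 = np.round(srgb * 255.0).astype(np.uint8)

    h, w = 4 * patch_px, 6 * patch_px
    image = np.zeros((h, w, 3), np.uint8)
    cube = np.zeros((h, w, grid.n_bands))
    for idx in range(24):
        r, c = divmod(idx, 6)
        block = img8[idx].reshape(patch_px, patch_px, 3)
        image[r * patch_px:(r + 1) * patch_px, c * patch_px:(c + 1) * patch_px] = block
        cube[r * patch_px:(r + 1) * patch_px, c * patch_px:(c + 1) * patch_px] = spectra[idx]
    return image, HyperspectralCube(grid, cube)
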