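"""Core color science for spectral endoscopy emulation.

This module holds the device-independent half of the pipeline: the sRGB
transfer function, the linear-RGB <-> CIE XYZ primary matrix, spectral
integration of reflectance against an illuminant and the CIE 1931 standard
observer, CIELAB conversion, and the CIEDE2000 color difference.

Conventions
-----------
* Wavelengths are nanometres on a uniform ascending grid (default
  400-780 nm in 10 nm steps).  Tristimulus integration is restricted to a
  400-700 nm window; the bands above 700 nm exist so that near-infrared
  narrow-band channels remain representable.
* XYZ lives on the 0-100 scale: the normalization constant
  ``k = 100 / integral(S * ybar)`` forces Y = 100 for a perfect reflector
  under any illuminant.
* Out-of-gamut (negative) linear RGB / XYZ values are carried through
  unclipped; clipping happens only at final 8-bit display encoding.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SpectralGrid",
    "ReflectanceSpectrum",
    "Illuminant",
    "ColorMatchingFunctions",
    "srgb_to_linear_rgb",
    "linear_rgb_to_srgb",
    "linear_rgb_to_xyz",
    "xyz_to_linear_rgb",
    "spectrum_to_xyz",
    "white_point",
    "xyz_to_lab",
    "lab_to_xyz",
    "ciede2000",
    "load_cmfs",
    "load_d65",
    "D65_WHITE",
    "RGB_TO_XYZ_100",
    "XYZ_100_TO_RGB",
]


class GridMismatchError(ValueError):
    """Raised when two spectral quantities do not share a wavelength grid."""


# ---------------------------------------------------------------------------
# spectral containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SpectralGrid:
    """Uniform ascending wavelength grid with an integration window.

    Parameters
    ----------
    wavelengths
        Strictly increasing, uniformly spaced wavelengths in nm.
    integration_window
        ``(lo, hi)`` in nm; both endpoints must lie on the grid.  Tristimulus
        integrals run over this window only.
    """

    wavelengths: np.ndarray
    integration_window: tuple[float, float] = (400.0, 700.0)

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=float)
        if wl.ndim != 1 or wl.size < 2:
            raise ValueError("grid needs at least two wavelengths")
        steps = np.diff(wl)
        if np.any(steps <= 0):
            raise ValueError("wavelengths must be strictly increasing")
        if not np.allclose(steps, steps[0], rtol=0, atol=1e-9):
            raise ValueError("wavelengths must be uniformly spaced")
        lo, hi = self.integration_window
        if not (np.isclose(wl, lo).any() and np.isclose(wl, hi).any()):
            raise ValueError("integration window endpoints must lie on the grid")
        object.__setattr__(self, "wavelengths", wl)

    @classmethod
    def default(cls) -> "SpectralGrid":
        return cls(np.arange(400.0, 781.0, 10.0))

    @property
    def step(self) -> float:
        return float(self.wavelengths[1] - self.wavelengths[0])

    @property
    def n_bands(self) -> int:
        return int(self.wavelengths.size)

    def window_mask(self) -> np.ndarray:
        lo, hi = self.integration_window
        return (self.wavelengths >= lo - 1e-9) & (self.wavelengths <= hi + 1e-9)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SpectralGrid):
            return NotImplemented
        return (
            self.wavelengths.shape == other.wavelengths.shape
            and np.allclose(self.wavelengths, other.wavelengths)
            and self.integration_window == other.integration_window
        )

    def __hash__(self) -> int:  # frozen dataclass with array field
        return hash((self.wavelengths.tobytes(), self.integration_window))


def _check_grid(a: SpectralGrid, b: SpectralGrid) -> None:
    if a != b:
        raise GridMismatchError("spectral quantities are on different grids")


@dataclass
class ReflectanceSpectrum:
    """Per-wavelength reflectance in [0, 1] on a shared grid."""

    grid: SpectralGrid
    values: np.ndarray
    name: str = ""

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (self.grid.n_bands,):
            raise ValueError("reflectance length must match the grid")
        if not np.all(np.isfinite(v)):
            raise ValueError("reflectance must be finite")
        self.values = v

    def clipped(self) -> "ReflectanceSpectrum":
        return ReflectanceSpectrum(self.grid, np.clip(self.values, 0.0, 1.0), self.name)


@dataclass
class Illuminant:
    """Relative spectral power distribution S(lambda) >= 0."""

    grid: SpectralGrid
    power: np.ndarray
    name: str = ""

    def __post_init__(self) -> None:
        p = np.asarray(self.power, dtype=float)
        if p.shape != (self.grid.n_bands,):
            raise ValueError("power length must match the grid")
        if np.any(p < 0) or not np.all(np.isfinite(p)):
            raise ValueError("power must be finite and nonnegative")
        self.power = p

    def k(self, cmf: "ColorMatchingFunctions") -> float:
        """Normalization 100 / integral(S * ybar) over the integration window."""
        _check_grid(self.grid, cmf.grid)
        m = self.grid.window_mask()
        denom = np.trapezoid(self.power[m] * cmf.ybar[m], self.grid.wavelengths[m])
        if denom <= 0:
            raise ValueError("ybar weighted power integrates to zero over the window")
        return 100.0 / denom


@dataclass
class ColorMatchingFunctions:
    """CIE 1931 2-degree standard-observer weights on the working grid."""

    grid: SpectralGrid
    xbar: np.ndarray
    ybar: np.ndarray
    zbar: np.ndarray

    def __post_init__(self) -> None:
        for attr in ("xbar", "ybar", "zbar"):
            v = np.asarray(getattr(self, attr), dtype=float)
            if v.shape != (self.grid.n_bands,):
                raise ValueError(f"{attr} length must match the grid")
            if np.any(v < 0):
                raise ValueError(f"{attr} must be nonnegative")
            setattr(self, attr, v)


def _data_table(name: str) -> pd.DataFrame:
    ref = importlib.resources.files("endospec.data").joinpath(name)
    with ref.open("r") as fh:
        return pd.read_csv(fh)


def _resample(wl_src: np.ndarray, v: np.ndarray, grid: SpectralGrid) -> np.ndarray:
    return np.interp(grid.wavelengths, wl_src, v, left=0.0, right=0.0)


def load_cmfs(grid: SpectralGrid | None = None) -> ColorMatchingFunctions:
    """Bundled CIE 1931 2-degree observer, 10 nm tabulation, resampled to *grid*."""
    grid = grid or SpectralGrid.default()
    t = _data_table("cie1931_2deg_10nm.csv")
    wl = t["wavelength_nm"].to_numpy(float)
    return ColorMatchingFunctions(
        grid,
        _resample(wl, t["xbar"].to_numpy(float), grid),
        _resample(wl, t["ybar"].to_numpy(float), grid),
        _resample(wl, t["zbar"].to_numpy(float), grid),
    )


def load_d65(grid: SpectralGrid | None = None) -> Illuminant:
    """Bundled CIE D65 relative spectral power, resampled to *grid*."""
    grid = grid or SpectralGrid.default()
    t = _data_table("illuminant_d65_10nm.csv")
    wl = t["wavelength_nm"].to_numpy(float)
    return Illuminant(grid, _resample(wl, t["power"].to_numpy(float), grid), name="D65")


# ---------------------------------------------------------------------------
# sRGB transfer function and primary matrix
# ---------------------------------------------------------------------------

def srgb_to_linear_rgb(values: np.ndarray | float) -> np.ndarray | float:
    """Decode sRGB-encoded values in [0, 1] to linear light (IEC 61966-2-1)."""
    v = np.asarray(values, dtype=float)
    if np.any(v < 0) or np.any(v > 1) or not np.all(np.isfinite(v)):
        raise ValueError("sRGB components must lie in [0, 1]")
    out = np.where(v <= 0.04045, v / 12.92, ((v + 0.055) / 1.055) ** 2.4)
    return out if out.ndim else float(out)


def linear_rgb_to_srgb(values: np.ndarray | float) -> np.ndarray | float:
    """Encode linear-light values in [0, 1] to sRGB."""
    v = np.asarray(values, dtype=float)
    if np.any(v < 0) or np.any(v > 1) or not np.all(np.isfinite(v)):
        raise ValueError("linear components must lie in [0, 1]")
    out = np.where(v <= 0.0031308, 12.92 * v, 1.055 * v ** (1.0 / 2.4) - 0.055)
    return out if out.ndim else float(out)


def _srgb_encode_signed(v: np.ndarray) -> np.ndarray:
    """Sign-preserving sRGB encode; keeps out-of-gamut values invertible."""
    return np.sign(v) * np.where(
        np.abs(v) <= 0.0031308, 12.92 * np.abs(v), 1.055 * np.abs(v) ** (1 / 2.4) - 0.055
    )


def _srgb_decode_signed(v: np.ndarray) -> np.ndarray:
    return np.sign(v) * np.where(
        np.abs(v) <= 0.04045, np.abs(v) / 12.92, ((np.abs(v) + 0.055) / 1.055) ** 2.4
    )


# IEC 61966-2-1 sRGB primaries / D65, scaled to the 0-100 XYZ range
RGB_TO_XYZ_100 = 100.0 * np.array(
    [
        [0.4124564, 0.3575761, 0.1804375],
        [0.2126729, 0.7151522, 0.0721750],
        [0.0193339, 0.1191920, 0.9503041],
    ]
)
XYZ_100_TO_RGB = np.linalg.inv(RGB_TO_XYZ_100)
D65_WHITE = RGB_TO_XYZ_100 @ np.ones(3)


def linear_rgb_to_xyz(rgb: np.ndarray) -> np.ndarray:
    """Linear RGB (rows or single triplet) to XYZ on the 0-100 scale.

    Negative outputs from out-of-gamut inputs are returned unclipped.
    """
    rgb = np.asarray(rgb, dtype=float)
    if not np.all(np.isfinite(rgb)):
        raise ValueError("non-finite RGB input")
    return rgb @ RGB_TO_XYZ_100.T


def xyz_to_linear_rgb(xyz: np.ndarray) -> np.ndarray:
    xyz = np.asarray(xyz, dtype=float)
    if not np.all(np.isfinite(xyz)):
        raise ValueError("non-finite XYZ input")
    return xyz @ XYZ_100_TO_RGB.T


# ---------------------------------------------------------------------------
# spectral integration
# ---------------------------------------------------------------------------

def spectrum_to_xyz(
    reflectance: ReflectanceSpectrum | np.ndarray,
    illuminant: Illuminant,
    cmf: ColorMatchingFunctions,
) -> np.ndarray:
    """Integrate reflectance against illuminant and observer to XYZ (0-100).

    ``X = k * integral(S * R * xbar)`` etc., with ``k = 100 / integral(S * ybar)``,
    trapezoid quadrature over the grid's integration window.  Accepts a single
    spectrum or an ``(n, n_bands)`` array of reflectance rows.
    """
    if isinstance(reflectance, ReflectanceSpectrum):
        _check_grid(reflectance.grid, illuminant.grid)
        values = reflectance.values
    else:
        values = np.asarray(reflectance, dtype=float)
        if values.shape[-1] != illuminant.grid.n_bands:
            raise GridMismatchError("reflectance rows do not match the grid")
    _check_grid(illuminant.grid, cmf.grid)
    grid = illuminant.grid
    m = grid.window_mask()
    wl = grid.wavelengths[m]
    k = illuminant.k(cmf)
    S = illuminant.power[m]
    R = np.atleast_2d(values)[:, m]
    xyz = np.stack(
        [
            k * np.trapezoid(S * R * cmf.xbar[m], wl, axis=-1),
            k * np.trapezoid(S * R * cmf.ybar[m], wl, axis=-1),
            k * np.trapezoid(S * R * cmf.zbar[m], wl, axis=-1),
        ],
        axis=-1,
    )
    return xyz[0] if np.asarray(values).ndim == 1 else xyz


def white_point(illuminant: Illuminant, cmf: ColorMatchingFunctions) -> np.ndarray:
    """XYZ of the perfect reflector under *illuminant* (Y = 100 by construction)."""
    ones = np.ones(illuminant.grid.n_bands)
    return spectrum_to_xyz(ones, illuminant, cmf)


# ---------------------------------------------------------------------------
# CIELAB and CIEDE2000
# ---------------------------------------------------------------------------

_DELTA = 6.0 / 29.0


def xyz_to_lab(xyz: np.ndarray, white: np.ndarray) -> np.ndarray:
    """CIE 1976 L*a*b* relative to *white* (which must have positive components)."""
    xyz = np.asarray(xyz, dtype=float)
    white = np.asarray(white, dtype=float)
    if np.any(white <= 0):
        raise ValueError("white point components must be positive")
    t = xyz / white

    def f(t):
        return np.where(t > _DELTA**3, np.cbrt(t), t / (3 * _DELTA**2) + 4.0 / 29.0)

    fx, fy, fz = f(t[..., 0]), f(t[..., 1]), f(t[..., 2])
    return np.stack([116.0 * fy - 16.0, 500.0 * (fx - fy), 200.0 * (fy - fz)], axis=-1)


def lab_to_xyz(lab: np.ndarray, white: np.ndarray) -> np.ndarray:
    lab = np.asarray(lab, dtype=float)
    white = np.asarray(white, dtype=float)
    if np.any(white <= 0):
        raise ValueError("white point components must be positive")
    fy = (lab[..., 0] + 16.0) / 116.0
    fx = fy + lab[..., 1] / 500.0
    fz = fy - lab[..., 2] / 200.0

    def finv(f):
        return np.where(f > _DELTA, f**3, 3 * _DELTA**2 * (f - 4.0 / 29.0))

    return np.stack([finv(fx), finv(fy), finv(fz)], axis=-1) * white


def ciede2000(lab1: np.ndarray, lab2: np.ndarray) -> np.ndarray | float:
    """CIEDE2000 color difference with kL = kC = kH = 1.

    Vectorized over leading axes; symmetric in its arguments.
    """
    lab1 = np.asarray(lab1, dtype=float)
    lab2 = np.asarray(lab2, dtype=float)
    L1, a1, b1 = lab1[..., 0], lab1[..., 1], lab1[..., 2]
    L2, a2, b2 = lab2[..., 0], lab2[..., 1], lab2[..., 2]

    C1 = np.hypot(a1, b1)
    C2 = np.hypot(a2, b2)
    Cbar = 0.5 * (C1 + C2)
    G = 0.5 * (1.0 - np.sqrt(Cbar**7 / (Cbar**7 + 25.0**7)))
    a1p, a2p = (1.0 + G) * a1, (1.0 + G) * a2
    C1p, C2p = np.hypot(a1p, b1), np.hypot(a2p, b2)
    h1p = np.degrees(np.arctan2(b1, a1p)) % 360.0
    h2p = np.degrees(np.arctan2(b2, a2p)) % 360.0
    h1p = np.where(C1p == 0, 0.0, h1p)
    h2p = np.where(C2p == 0, 0.0, h2p)

    dLp = L2 - L1
    dCp = C2p - C1p
    dh = h2p - h1p
    dh = np.where(dh > 180.0, dh - 360.0, dh)
    dh = np.where(dh < -180.0, dh + 360.0, dh)
    dh = np.where(C1p * C2p == 0, 0.0, dh)
    dHp = 2.0 * np.sqrt(C1p * C2p) * np.sin(np.radians(dh) / 2.0)

    Lbp = 0.5 * (L1 + L2)
    Cbp = 0.5 * (C1p + C2p)
    hsum = h1p + h2p
    hdiff = np.abs(h1p - h2p)
    hbp = np.where(
        C1p * C2p == 0,
        hsum,
        np.where(
            hdiff <= 180.0,
            0.5 * hsum,
            np.where(hsum < 360.0, 0.5 * (hsum + 360.0), 0.5 * (hsum - 360.0)),
        ),
    )

    T = (
        1.0
        - 0.17 * np.cos(np.radians(hbp - 30.0))
        + 0.24 * np.cos(np.radians(2.0 * hbp))
        + 0.32 * np.cos(np.radians(3.0 * hbp + 6.0))
        - 0.20 * np.cos(np.radians(4.0 * hbp - 63.0))
    )
    dtheta = 30.0 * np.exp(-(((hbp - 275.0) / 25.0) ** 2))
    RC = 2.0 * np.sqrt(Cbp**7 / (Cbp**7 + 25.0**7))
    SL = 1.0 + 0.015 * (Lbp - 50.0) ** 2 / np.sqrt(20.0 + (Lbp - 50.0) ** 2)
    SC = 1.0 + 0.045 * Cbp
    SH = 1.0 + 0.015 * Cbp * T
    RT = -np.sin(np.radians(2.0 * dtheta)) * RC

    dE = np.sqrt(
        (dLp / SL) ** 2
        + (dCp / SC) ** 2
        + (dHp / SH) ** 2
        + RT * (dCp / SC) * (dHp / SH)
    )
    return float(dE) if dE.ndim == 0 else dE
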