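"""Spectrum- and image-fidelity metrics.

Spectral RMSE scores the reconstruction chain against ground-truth
reflectance; SSIM, PSNR and histogram entropy compare rendered images.  SSIM
uses the standard 11x11 Gaussian window (sigma 1.5, K1 = 0.01, K2 = 0.03,
dynamic range 255); PSNR of identical images is capped at 100 dB rather than
returned as infinity.  The entropy comparison is reported both in bits and as
a percentage of the 8-bit maximum (the latter flagged experimental, since the
percentage convention is not standardized).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from skimage.metrics import structural_similarity

from .colorimetry import GridMismatchError, ReflectanceSpectrum

__all__ = [
    "QualityReport",
    "spectral_rmse",
    "ssim",
    "psnr",
    "shannon_entropy",
    "entropy_difference",
]

PSNR_CAP_DB = 100.0


def spectral_rmse(a: ReflectanceSpectrum | np.ndarray, b: ReflectanceSpectrum | np.ndarray) -> float:
    """Root-mean-square difference between two spectra on one grid."""
    if isinstance(a, ReflectanceSpectrum) and isinstance(b, ReflectanceSpectrum):
        if a.grid != b.grid:
            raise GridMismatchError("spectra are on different grids")
        va, vb = a.values, b.values
    else:
        va = a.values if isinstance(a, ReflectanceSpectrum) else np.asarray(a, float)
        vb = b.values if isinstance(b, ReflectanceSpectrum) else np.asarray(b, float)
        if va.shape != vb.shape:
            raise GridMismatchError("spectra have different lengths")
    return float(np.sqrt(np.mean((va - vb) ** 2)))


def _as_float_image(a: np.ndarray) -> np.ndarray:
    a = np.asarray(a)
    return a.astype(float)


def ssim(a: np.ndarray, b: np.ndarray) -> float:
    """Mean structural similarity with the Gaussian-window convention.

    Color images are scored per channel and averaged.
    """
    a, b = np.asarray(a), np.asarray(b)
    if a.shape != b.shape:
        raise ValueError("images must have the same shape")
    if a.shape[0] < 11 or a.shape[1] < 11:
        raise ValueError("images must be at least 11 x 11")
    kwargs = dict(
        win_size=11,
        gaussian_weights=True,
        sigma=1.5,
        use_sample_covariance=False,
        K1=0.01,
        K2=0.03,
        data_range=255,
    )
    if a.ndim == 3:
        vals = [
            structural_similarity(_as_float_image(a[..., c]), _as_float_image(b[..., c]), **kwargs)
            for c in range(a.shape[2])
        ]
        return float(np.mean(vals))
    return float(structural_similarity(_as_float_image(a), _as_float_image(b), **kwargs))


def psnr(a: np.ndarray, b: np.ndarray) -> float:
    """Peak signal-to-noise ratio in dB for 8-bit dynamic range.

    Identical images return the documented 100 dB cap.
    """
    a, b = np.asarray(a), np.asarray(b)
    if a.shape != b.shape:
        raise ValueError("images must have the same shape")
    mse = np.mean((_as_float_image(a) - _as_float_image(b)) ** 2)
    if mse == 0:
        return PSNR_CAP_DB
    return min(float(10.0 * np.log10(255.0**2 / mse)), PSNR_CAP_DB)


def _to_gray(a: np.ndarray) -> np.ndarray:
    """ITU-R BT.601 luma for color inputs, rounded back to 8-bit levels."""
    a = np.asarray(a)
    if a.ndim == 3:
        luma = 0.299 * a[..., 0] + 0.587 * a[..., 1] + 0.114 * a[..., 2]
        return np.clip(np.round(luma), 0, 255).astype(np.uint8)
    return a


def shannon_entropy(a: np.ndarray) -> float:
    """Shannon entropy (bits) of the 256-bin normalized histogram."""
    a = _to_gray(a)
    if a.size == 0:
        raise ValueError("empty image")
    hist = np.bincount(a.astype(np.uint8).ravel(), minlength=256).astype(float)
    p = hist / hist.sum()
    nz = p[p > 0]
    return float(-(nz * np.log2(nz)).sum())


def entropy_difference(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """|H(a) - H(b)| in bits and as a percentage of the 8-bit maximum.

    The percentage convention is experimental (not a standardized unit).
    """
    d = abs(shannon_entropy(a) - shannon_entropy(b))
    return d, d / 8.0 * 100.0


@dataclass
class QualityReport:
    """Bundle of fidelity metrics for a reconstruction or rendering run."""

    per_patch_rmse: list[float] = field(default_factory=list)
    mean_rmse: float = float("nan")
    max_rmse: float = float("nan")
    mean_de2000: float = float("nan")
    ssim: float = float("nan")
    psnr_db: float = float("nan")
    entropy_bits_a: float = float("nan")
    entropy_bits_b: float = float("nan")
    entropy_diff_bits: float = float("nan")
    entropy_diff_percent: float = float("nan")

    @classmethod
    def from_spectra(
        cls,
        reconstructed: np.ndarray,
        reference: np.ndarray,
        mean_de2000: float = float("nan"),
    ) -> "QualityReport":
        rec = np.atleast_2d(reconstructed)
        ref = np.atleast_2d(reference)
        per = [spectral_rmse(x, y) for x, y in zip(rec, ref)]
        return cls(
            per_patch_rmse=per,
            mean_rmse=float(np.mean(per)),
            max_rmse=float(np.max(per)),
            mean_de2000=mean_de2000,
        )

    def with_images(self, a: np.ndarray, b: np.ndarray) -> "QualityReport":
        self.ssim = ssim(a, b)
        self.psnr_db = psnr(a, b)
        self.entropy_bits_a = shannon_entropy(a)
        self.entropy_bits_b = shannon_entropy(b)
        self.entropy_diff_bits, self.entropy_diff_percent = entropy_difference(a, b)
        return self

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)

    def to_csv(self, path) -> None:
        import pandas as pd

        d = self.to_dict()
        per = d.pop("per_patch_rmse")
        rows = [{"metric": k, "value": v} for k, v in d.items()]
        rows += [{"metric": f"rmse_patch_{i}", "value": v} for i, v in enumerate(per)]
        pd.DataFrame(rows).to_csv(path, index=False)
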