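"""PCA spectral basis and XYZ-to-spectrum reconstruction.

The 24 checker reflectances span a low-dimensional subspace: a mean-centered
PCA keeps six principal components, and a transformation matrix

    M = Score @ pinv(V_color)

maps polynomial features of corrected XYZ to PC scores.  A pixel's reflectance
is then ``mean + scores @ loadings``, which turns an RGB image into a
hyperspectral reflectance cube one pixel at a time (vectorized in practice).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .calibration import CorrectionModel, FeatureExpansion, apply_correction, expand_features
from .colorimetry import (
    ReflectanceSpectrum,
    SpectralGrid,
    linear_rgb_to_xyz,
    srgb_to_linear_rgb,
)

__all__ = [
    "SpectralBasis",
    "TransformationModel",
    "HyperspectralCube",
    "fit_spectral_basis",
    "fit_transformation_matrix",
    "reconstruct_reflectance",
    "rgb_image_to_cube",
]


@dataclass
class SpectralBasis:
    """Mean spectrum plus orthonormal PC loadings with explained variance."""

    grid: SpectralGrid
    mean_spectrum: np.ndarray            # (n_bands,)
    loadings: np.ndarray                 # (n_pc, n_bands), rows orthonormal
    explained_variance_ratio: np.ndarray  # (n_pc,), nonincreasing
    training_scores: np.ndarray          # (n_train, n_pc)

    @property
    def n_pc(self) -> int:
        return self.loadings.shape[0]

    def project(self, spectra: np.ndarray) -> np.ndarray:
        return (np.atleast_2d(spectra) - self.mean_spectrum) @ self.loadings.T

    def to_dict(self) -> dict:
        return {
            "wavelengths": self.grid.wavelengths.tolist(),
            "integration_window": list(self.grid.integration_window),
            "mean_spectrum": self.mean_spectrum.tolist(),
            "loadings": self.loadings.tolist(),
            "explained_variance_ratio": self.explained_variance_ratio.tolist(),
            "training_scores": self.training_scores.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SpectralBasis":
        grid = SpectralGrid(np.array(d["wavelengths"]), tuple(d["integration_window"]))
        return cls(
            grid,
            np.array(d["mean_spectrum"]),
            np.array(d["loadings"]),
            np.array(d["explained_variance_ratio"]),
            np.array(d["training_scores"]),
        )


def fit_spectral_basis(
    spectra: list[ReflectanceSpectrum] | np.ndarray,
    n_pc: int = 6,
    grid: SpectralGrid | None = None,
) -> SpectralBasis:
    """Mean-centered PCA of reflectance spectra via SVD.

    Signs are fixed so each loading's largest-magnitude entry is positive,
    making the decomposition deterministic.
    """
    if isinstance(spectra, (list, tuple)):
        grid = spectra[0].grid
        for s in spectra[1:]:
            if s.grid != grid:
                raise ValueError("all spectra must share one grid")
        X = np.stack([s.values for s in spectra])
    else:
        X = np.atleast_2d(np.asarray(spectra, float))
        grid = grid or SpectralGrid.default()
    n, b = X.shape
    if not (1 <= n_pc <= min(n - 1, b)):
        raise ValueError("n_pc must be between 1 and min(n_samples - 1, n_bands)")

    mean = X.mean(axis=0)
    Xc = X - mean
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    # deterministic sign: largest |entry| of each loading is positive
    flip = np.sign(Vt[np.arange(Vt.shape[0]), np.argmax(np.abs(Vt), axis=1)])
    flip[flip == 0] = 1.0
    Vt = Vt * flip[:, None]
    U = U * flip[None, :]

    ev = s**2
    ratio = ev / ev.sum() if ev.sum() > 0 else np.zeros_like(ev)
    scores = U[:, :n_pc] * s[:n_pc]
    return SpectralBasis(grid, mean, Vt[:n_pc], ratio[:n_pc], scores)


@dataclass
class TransformationModel:
    """Maps expanded corrected-XYZ features to PC scores (M = Score @ pinv(V))."""

    basis: SpectralBasis
    expansion: FeatureExpansion
    M: np.ndarray  # (n_pc, n_terms)
    score_rmse: float = 0.0

    def __post_init__(self) -> None:
        M = np.asarray(self.M, float)
        if M.shape != (self.basis.n_pc, self.expansion.n_terms):
            raise ValueError("M must be n_pc x n_terms")
        if not np.all(np.isfinite(M)):
            raise ValueError("M contains non-finite entries")
        self.M = M

    def to_dict(self) -> dict:
        return {
            "basis": self.basis.to_dict(),
            "order": self.expansion.order,
            "M": self.M.tolist(),
            "score_rmse": self.score_rmse,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TransformationModel":
        return cls(
            SpectralBasis.from_dict(d["basis"]),
            FeatureExpansion(d["order"]),
            np.array(d["M"]),
            d.get("score_rmse", 0.0),
        )


def fit_transformation_matrix(
    basis: SpectralBasis,
    corrected_xyz: np.ndarray,
    expansion: FeatureExpansion | None = None,
) -> TransformationModel:
    """Least-squares fit of M on the basis's training scores.

    ``corrected_xyz`` must pair 1:1 with the spectra the basis was fit on.
    """
    expansion = expansion or FeatureExpansion(3)
    xyz = np.atleast_2d(np.asarray(corrected_xyz, float))
    scores = basis.training_scores
    if xyz.shape[0] != scores.shape[0]:
        raise ValueError("corrected XYZ rows must pair with the training spectra")
    V = expand_features(xyz, expansion).T          # (n_terms, n)
    M = scores.T @ np.linalg.pinv(V, rcond=1e-10)  # (n_pc, n_terms)
    resid = (M @ V).T - scores
    return TransformationModel(basis, expansion, M, float(np.sqrt(np.mean(resid**2))))


def reconstruct_reflectance(
    model: TransformationModel, xyz: np.ndarray, clip: bool = True
) -> np.ndarray:
    """Reconstruct reflectance rows from corrected XYZ rows.

    ``spectrum = mean + (M @ features) @ loadings``, clipped to [0, 1] unless
    ``clip=False`` (useful for error analysis of in-span targets).
    """
    xyz = np.asarray(xyz, float)
    if not np.all(np.isfinite(xyz)):
        raise ValueError("non-finite XYZ input")
    single = xyz.ndim == 1
    V = expand_features(np.atleast_2d(xyz), model.expansion)
    scores = V @ model.M.T
    spectra = model.basis.mean_spectrum + scores @ model.basis.loadings
    if clip:
        spectra = np.clip(spectra, 0.0, 1.0)
    return spectra[0] if single else spectra


@dataclass
class HyperspectralCube:
    """Reconstructed reflectance image: (height, width, n_bands) in [0, 1]."""

    grid: SpectralGrid
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        if v.ndim != 3 or v.shape[2] != self.grid.n_bands:
            raise ValueError("cube must be (H, W, n_bands) matching the grid")
        if v.shape[0] == 0 or v.shape[1] == 0:
            raise ValueError("cube must have nonzero spatial size")
        self.values = v

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    def flat(self) -> np.ndarray:
        return self.values.reshape(-1, self.grid.n_bands)


def rgb_image_to_cube(
    image: np.ndarray,
    correction: CorrectionModel,
    model: TransformationModel,
) -> HyperspectralCube:
    """Full per-pixel chain: sRGB decode -> XYZ -> correction -> reconstruction.

    ``image`` is an (H, W, 3) 8-bit or [0, 1] float sRGB raster.  The
    vectorized implementation is contractually identical to a per-pixel loop.
    """
    img = np.asarray(image)
    if img.ndim != 3 or img.shape[2] != 3 or img.shape[0] == 0 or img.shape[1] == 0:
        raise ValueError("image must be a nonempty (H, W, 3) raster")
    if img.dtype == np.uint8:
        srgb = img.astype(float) / 255.0
    else:
        srgb = img.astype(float)
    h, w, _ = srgb.shape
    flat = srgb.reshape(-1, 3)
    xyz = linear_rgb_to_xyz(srgb_to_linear_rgb(flat))
    xyz = apply_correction(correction, xyz)
    spectra = reconstruct_reflectance(model, xyz)
    return HyperspectralCube(model.basis.grid, spectra.reshape(h, w, -1))
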