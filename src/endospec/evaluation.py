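"""Built-in validation experiments for the reconstruction chain.

Two harnesses exercise the whole pipeline on the bundled synthetic checker:

* :func:`round_trip_report` — noiseless captures of the 24 patches are
  calibrated and reconstructed, yielding per-patch spectral RMSE and the
  color error between reconstructed and true spectra.
* :func:`calibration_gain_report` — a camera carrying the planted
  second-order color distortion plus Gaussian noise photographs the checker
  mosaic; the correction is fitted on patch-region means (the standard way a
  chart photograph is reduced for calibration) and the report records the
  mean CIEDE2000 before and after correction.
"""

from __future__ import annotations

import numpy as np

from . import colorimetry as cm
from .calibration import apply_correction, fit_correction_model
from .colorimetry import _srgb_decode_signed
from .spectral_basis import fit_spectral_basis, fit_transformation_matrix, reconstruct_reflectance
from .synthetic import (
    BLACK_PATCH,
    SyntheticCamera,
    colorchecker_reference,
    decode_capture_xyz,
    make_checker_mosaic,
    simulate_capture,
)

__all__ = ["round_trip_report", "calibration_gain_report", "fit_pipeline_from_patches"]


def _context(grid=None):
    grid = grid or cm.SpectralGrid.default()
    cmf = cm.load_cmfs(grid)
    d65 = cm.load_d65(grid)
    return grid, cmf, d65, cm.white_point(d65, cmf)


def fit_pipeline_from_patches(camera_xyz, reference_xyz, reference_spectra, n_pc=6):
    """Fit correction + basis + transformation matrix from paired patch data."""
    corr = fit_correction_model(camera_xyz, reference_xyz)
    corrected = apply_correction(corr, camera_xyz)
    basis = fit_spectral_basis(reference_spectra, n_pc)
    tm = fit_transformation_matrix(basis, corrected)
    return corr, tm


def round_trip_report(grid=None, n_pc: int = 6) -> dict:
    """Noiseless synthetic-camera round trip over the 24 checker patches.

    Calibrates the third-order correction and the PCA transformation on the
    patches themselves, reconstructs each patch spectrum from its camera
    color, and reports spectral RMSE (full storage grid) plus the CIEDE2000
    between colors of reconstructed and true spectra under D65.
    """
    grid, cmf, d65, white = _context(grid)
    patches = colorchecker_reference(grid)
    spectra = np.stack([p.values for p in patches])
    names = [p.name for p in patches]

    camera = SyntheticCamera.default(grid)
    srgb, true_xyz = simulate_capture(patches, camera, d65, cmf)
    cam_xyz = decode_capture_xyz(srgb)

    corr, tm = fit_pipeline_from_patches(cam_xyz, true_xyz, patches, n_pc)
    corrected = apply_correction(corr, cam_xyz)
    rec = reconstruct_reflectance(tm, corrected)

    per_patch = np.sqrt(np.mean((rec - spectra) ** 2, axis=1))
    rec_xyz = cm.spectrum_to_xyz(rec, d65, cmf)
    de = cm.ciede2000(cm.xyz_to_lab(rec_xyz, white), cm.xyz_to_lab(true_xyz, white))
    return {
        "patch_names": names,
        "per_patch_rmse": per_patch,
        "mean_rmse": float(per_patch.mean()),
        "max_rmse": float(per_patch.max()),
        "black_rmse": float(per_patch[names.index(BLACK_PATCH)]),
        "global_rmse": float(np.sqrt(np.mean((rec - spectra) ** 2))),
        "per_patch_de2000": np.asarray(de),
        "mean_de2000": float(np.mean(de)),
        "reconstructed": rec,
        "reference": spectra,
        "explained_variance_6pc": float(tm.basis.explained_variance_ratio.sum()),
    }


def calibration_gain_report(
    noise_sigma: float = 0.01,
    seed: int = 7,
    patch_px: int = 16,
    grid=None,
) -> dict:
    """Calibration gain on the planted-distortion camera.

    The distorted, noisy camera photographs the 4x6 checker mosaic; each
    patch region is decoded to linear RGB and averaged before conversion to
    camera XYZ, then the third-order correction is fitted against the
    noiseless spectrometer reference.  Returns the mean CIEDE2000 before and
    after correction.
    """
    grid, cmf, d65, white = _context(grid)
    patches = colorchecker_reference(grid)
    spectra = np.stack([p.values for p in patches])

    camera = SyntheticCamera.default(grid, noise_sigma=noise_sigma, distorted=True, seed=seed)
    image, _ = make_checker_mosaic(camera, patch_px=patch_px, illuminant=d65)
    true_xyz = cm.spectrum_to_xyz(spectra, d65, cmf)

    lin = _srgb_decode_signed(image.astype(float) / 255.0)
    cam_xyz = np.empty((24, 3))
    for idx in range(24):
        r, c = divmod(idx, 6)
        block = lin[r * patch_px:(r + 1) * patch_px, c * patch_px:(c + 1) * patch_px]
        cam_xyz[idx] = block.reshape(-1, 3).mean(axis=0) @ cm.RGB_TO_XYZ_100.T

    corr = fit_correction_model(cam_xyz, true_xyz, white=white)
    return {
        "mean_de2000_pre": corr.fit_report["mean_de2000_pre"],
        "mean_de2000_post": corr.fit_report["mean_de2000_post"],
        "model": corr,
    }
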