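"""Variable-matrix camera calibration.

A camera's XYZ estimates (from decoded sRGB through the fixed primary matrix)
are mapped onto spectrometer-reference XYZ with a learned linear map ``C`` over
a third-order polynomial feature expansion of (X, Y, Z):

    C = XYZ_ref @ pinv(V),        XYZ_corrected = C @ V

where the columns of ``V`` are expanded feature vectors, one per patch.  The
expansion carries a constant term whose learned coefficient plays the role of
the sensor's dark-current offset, and is capped at third order to avoid
overcorrection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .colorimetry import D65_WHITE, ciede2000, xyz_to_lab

__all__ = [
    "FeatureExpansion",
    "CorrectionModel",
    "expand_features",
    "fit_correction_model",
    "apply_correction",
]

# exponents of (X, Y, Z) for the fixed order-3 monomial basis:
# [1, X, Y, Z, X2, Y2, Z2, XY, XZ, YZ, X3, Y3, Z3, X2Y, X2Z, XY2, Y2Z, XZ2, YZ2, XYZ]
_EXPONENTS = [
    (0, 0, 0),
    (1, 0, 0), (0, 1, 0), (0, 0, 1),
    (2, 0, 0), (0, 2, 0), (0, 0, 2),
    (1, 1, 0), (1, 0, 1), (0, 1, 1),
    (3, 0, 0), (0, 3, 0), (0, 0, 3),
    (2, 1, 0), (2, 0, 1), (1, 2, 0), (0, 2, 1), (1, 0, 2), (0, 1, 2),
    (1, 1, 1),
]
_ORDER_COUNTS = {1: 4, 2: 10, 3: 20}


@dataclass(frozen=True)
class FeatureExpansion:
    """Polynomial monomial basis in (X, Y, Z) up to ``order`` (max 3)."""

    order: int = 3

    def __post_init__(self) -> None:
        if self.order not in _ORDER_COUNTS:
            raise ValueError("expansion order must be 1, 2 or 3")

    @property
    def exponents(self) -> list[tuple[int, int, int]]:
        return _EXPONENTS[: _ORDER_COUNTS[self.order]]

    @property
    def n_terms(self) -> int:
        return _ORDER_COUNTS[self.order]

    @property
    def term_names(self) -> list[str]:
        def nm(e):
            if e == (0, 0, 0):
                return "1"
            return "".join(
                f"{s}" * p if p == 1 else (f"{s}^{p}" if p else "")
                for s, p in zip("XYZ", e)
            )
        return [nm(e) for e in self.exponents]


def expand_features(xyz: np.ndarray, expansion: FeatureExpansion) -> np.ndarray:
    """Evaluate the monomial basis; rows in, rows of length ``n_terms`` out."""
    xyz = np.asarray(xyz, dtype=float)
    if not np.all(np.isfinite(xyz)):
        raise ValueError("non-finite XYZ input")
    single = xyz.ndim == 1
    pts = np.atleast_2d(xyz)
    cols = [
        pts[:, 0] ** px * pts[:, 1] ** py * pts[:, 2] ** pz
        for px, py, pz in expansion.exponents
    ]
    V = np.stack(cols, axis=1)
    return V[0] if single else V


@dataclass
class CorrectionModel:
    """Fitted polynomial correction from camera XYZ to reference XYZ."""

    expansion: FeatureExpansion
    C: np.ndarray  # (3, n_terms)
    fit_report: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        C = np.asarray(self.C, dtype=float)
        if C.shape != (3, self.expansion.n_terms):
            raise ValueError("C must be 3 x n_terms")
        if not np.all(np.isfinite(C)):
            raise ValueError("C contains non-finite entries")
        self.C = C

    def to_dict(self) -> dict:
        return {
            "order": self.expansion.order,
            "terms": self.expansion.term_names,
            "C": self.C.tolist(),
            "fit_report": self.fit_report,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CorrectionModel":
        return cls(FeatureExpansion(d["order"]), np.array(d["C"]), d.get("fit_report", {}))


def _mean_de(xyz_a: np.ndarray, xyz_b: np.ndarray, white: np.ndarray) -> np.ndarray:
    return ciede2000(xyz_to_lab(xyz_a, white), xyz_to_lab(xyz_b, white))


def fit_correction_model(
    camera_xyz: np.ndarray,
    reference_xyz: np.ndarray,
    expansion: FeatureExpansion | None = None,
    white: np.ndarray | None = None,
) -> CorrectionModel:
    """Least-squares fit of the variable matrix C on paired patch colors.

    Parameters
    ----------
    camera_xyz, reference_xyz
        ``(n, 3)`` paired camera-side and spectrometer-side tristimulus rows;
        the 24-patch checker is the canonical input.
    expansion
        Feature basis (default third order, 20 terms).
    white
        White point for the Lab conversions in the fit report (default D65).
    """
    expansion = expansion or FeatureExpansion(3)
    white = D65_WHITE if white is None else np.asarray(white, float)
    cam = np.atleast_2d(np.asarray(camera_xyz, float))
    ref = np.atleast_2d(np.asarray(reference_xyz, float))
    if cam.shape != ref.shape or cam.shape[1] != 3:
        raise ValueError("camera and reference XYZ must be paired (n, 3) arrays")
    n = cam.shape[0]
    if n < 4:
        raise ValueError("at least 4 paired samples are required")

    V = expand_features(cam, expansion).T  # (n_terms, n)
    rank = np.linalg.matrix_rank(V, tol=1e-10 * np.linalg.norm(V, 2))
    C = ref.T @ np.linalg.pinv(V, rcond=1e-10)

    corrected = (C @ V).T
    resid = corrected - ref
    per_patch_rmse = np.sqrt(np.mean(resid**2, axis=1))
    report = {
        "n_samples": int(n),
        "rank": int(rank),
        "rank_deficient": bool(rank < min(V.shape)),
        "rmse_xyz": float(np.sqrt(np.mean(resid**2))),
        "per_patch_rmse_xyz": per_patch_rmse.tolist(),
        "de2000_pre": np.asarray(_mean_de(cam, ref, white)).tolist(),
        "de2000_post": np.asarray(_mean_de(corrected, ref, white)).tolist(),
        "mean_de2000_pre": float(np.mean(_mean_de(cam, ref, white))),
        "mean_de2000_post": float(np.mean(_mean_de(corrected, ref, white))),
    }
    return CorrectionModel(expansion, C, report)


def apply_correction(model: CorrectionModel, xyz: np.ndarray) -> np.ndarray:
    """Apply the fitted variable matrix: corrected = C @ expanded(xyz)."""
    xyz = np.asarray(xyz, dtype=float)
    if not np.all(np.isfinite(xyz)):
        raise ValueError("non-finite XYZ input")
    V = expand_features(xyz, model.expansion)
    return V @ model.C.T
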