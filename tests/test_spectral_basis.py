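"""PCA spectral basis, transformation matrix and cube reconstruction."""

import numpy as np
import pytest

from endospec import colorimetry as cm
from endospec.calibration import FeatureExpansion, expand_features, fit_correction_model
from endospec.spectral_basis import (
    HyperspectralCube,
    fit_spectral_basis,
    fit_transformation_matrix,
    reconstruct_reflectance,
    rgb_image_to_cube,
)
from endospec.synthetic import SyntheticCamera, decode_capture_xyz, simulate_capture


class TestFitBasis:
    def test_exact_low_rank_recovery(self, grid, rng):
        # spectra spanning a rank-3 affine space: 3 PCs explain everything
        base = rng.random((3, grid.n_bands)) * 0.3
        coef = rng.random((12, 3))
        X = 0.2 + coef @ base
        basis = fit_spectral_basis(X, 3, grid)
        assert basis.explained_variance_ratio.sum() == pytest.approx(1.0, abs=1e-10)

    def test_checker_six_components_cover_variance(self, checker):
        basis = fit_spectral_basis(checker, 6)
        assert basis.explained_variance_ratio.sum() >= 0.9964

    def test_matches_covariance_eigensolver(self, checker_array, grid):
        """Brute-force eigendecomposition of the covariance matrix as oracle."""
        basis = fit_spectral_basis(checker_array, 6, grid)
        Xc = checker_array - checker_array.mean(0)
        C = Xc.T @ Xc
        w, V = np.linalg.eigh(C)
        order = np.argsort(w)[::-1]
        w, V = w[order], V[:, order]
        # reconstruction error of the 6-dim projection must agree to 1e-8
        P_svd = basis.loadings.T @ basis.loadings
        P_eig = V[:, :6] @ V[:, :6].T
        err_svd = np.linalg.norm(Xc - Xc @ P_svd)
        err_eig = np.linalg.norm(Xc - Xc @ P_eig)
        assert err_svd == pytest.approx(err_eig, abs=1e-8)
        assert np.allclose(basis.explained_variance_ratio, (w / w.sum())[:6], atol=1e-10)

    def test_orthonormal_and_ordered(self, checker):
        basis = fit_spectral_basis(checker, 6)
        G = basis.loadings @ basis.loadings.T
        assert np.max(np.abs(G - np.eye(6))) < 1e-8
        assert np.all(np.diff(basis.explained_variance_ratio) <= 1e-12)
        assert basis.explained_variance_ratio.sum() <= 1.0 + 1e-12

    def test_deterministic_signs(self, checker_array, grid):
        b1 = fit_spectral_basis(checker_array, 6, grid)
        b2 = fit_spectral_basis(checker_array, 6, grid)
        assert np.array_equal(b1.loadings, b2.loadings)
        for row in b1.loadings:
            assert row[np.argmax(np.abs(row))] > 0

    def test_excessive_components_rejected(self, checker_array, grid):
        with pytest.raises(ValueError):
            fit_spectral_basis(checker_array, 24, grid)


class TestTransformationMatrix:
    def test_identity_embedding_recovered(self, grid, rng):
        """Features equal to scores (order-1 alignment) give an exact solve."""
        X = 0.3 + 0.1 * rng.standard_normal((10, grid.n_bands))
        basis = fit_spectral_basis(np.clip(X, 0, 1), 3, grid)
        scores = basis.training_scores
        # craft XYZ whose order-1 features [1, X, Y, Z] linearly embed the scores
        xyz = scores.copy()
        tm = fit_transformation_matrix(basis, xyz, FeatureExpansion(1))
        V = expand_features(xyz, FeatureExpansion(1))
        assert np.max(np.abs(V @ tm.M.T - scores)) < 1e-8

    def test_matches_normal_equations(self, checker_array, grid, d65, cmf, rng):
        basis = fit_spectral_basis(checker_array, 6, grid)
        xyz = cm.spectrum_to_xyz(checker_array, d65, cmf) + rng.normal(0, 0.5, (24, 3))
        tm = fit_transformation_matrix(basis, xyz)
        V = expand_features(xyz, tm.expansion)
        M_ref, *_ = np.linalg.lstsq(V, basis.training_scores, rcond=None)
        assert np.max(np.abs(V @ tm.M.T - V @ M_ref)) < 1e-8

    def test_pairing_mismatch_rejected(self, checker_array, grid):
        basis = fit_spectral_basis(checker_array, 6, grid)
        with pytest.raises(ValueError):
            fit_transformation_matrix(basis, np.ones((10, 3)))


class TestReconstruction:
    @pytest.fixture(scope="class")
    def chain(self, checker, checker_array, grid, d65, cmf):
        camera = SyntheticCamera.default(grid)
        srgb, true_xyz = simulate_capture(checker, camera, d65, cmf)
        cam_xyz = decode_capture_xyz(srgb)
        corr = fit_correction_model(cam_xyz, true_xyz)
        from endospec.calibration import apply_correction

        corrected = apply_correction(corr, cam_xyz)
        basis = fit_spectral_basis(checker, 6)
        tm = fit_transformation_matrix(basis, corrected)
        return corr, tm, corrected, true_xyz

    def test_in_span_target_recovered_exactly(self, grid, rng):
        """A spectrum in the basis span whose features are exactly consistent
        with the fitted map round-trips through the closed linear loop."""
        X = np.clip(0.3 + 0.1 * rng.standard_normal((12, grid.n_bands)), 0, 1)
        basis = fit_spectral_basis(X, 3, grid)
        # features linearly embed the scores exactly -> the order-1 solve is exact
        xyz = basis.training_scores
        tm = fit_transformation_matrix(basis, xyz, FeatureExpansion(1))
        for i in (0, 5, 11):
            target = basis.mean_spectrum + basis.training_scores[i] @ basis.loadings
            rec = reconstruct_reflectance(tm, xyz[i], clip=False)
            assert np.sqrt(np.mean((rec - target) ** 2)) < 1e-8

    def test_training_patch_within_residual(self, chain, checker_array):
        _, tm, corrected, _ = chain
        rec = reconstruct_reflectance(tm, corrected)
        rmse = np.sqrt(np.mean((rec - checker_array) ** 2, axis=1))
        assert rmse.mean() < 0.06

    def test_clipping_never_hurts(self, chain, checker_array):
        _, tm, corrected, _ = chain
        raw = reconstruct_reflectance(tm, corrected, clip=False)
        clipped = np.clip(raw, 0, 1)
        rmse_raw = np.sqrt(np.mean((raw - checker_array) ** 2, axis=1))
        rmse_clip = np.sqrt(np.mean((clipped - checker_array) ** 2, axis=1))
        assert np.all(rmse_clip <= rmse_raw + 1e-12)

    def test_non_finite_rejected(self, chain):
        _, tm, _, _ = chain
        with pytest.raises(ValueError):
            reconstruct_reflectance(tm, np.array([np.inf, 0, 0]))


class TestImageToCube:
    @pytest.fixture(scope="class")
    def models(self, checker, grid, d65, cmf):
        camera = SyntheticCamera.default(grid)
        srgb, true_xyz = simulate_capture(checker, camera, d65, cmf)
        cam_xyz = decode_capture_xyz(srgb)
        corr = fit_correction_model(cam_xyz, true_xyz)
        from endospec.calibration import apply_correction

        basis = fit_spectral_basis(checker, 6)
        tm = fit_transformation_matrix(basis, apply_correction(corr, cam_xyz))
        return corr, tm

    def test_single_pixel_composition(self, models, rng):
        corr, tm = models
        px = rng.integers(0, 256, (1, 1, 3), dtype=np.uint8)
        cube = rgb_image_to_cube(px, corr, tm)
        from endospec.calibration import apply_correction

        xyz = cm.linear_rgb_to_xyz(cm.srgb_to_linear_rgb(px.reshape(3) / 255.0))
        expect = reconstruct_reflectance(tm, apply_correction(corr, xyz))
        assert np.allclose(cube.values[0, 0], expect, atol=1e-12)

    def test_uniform_image_uniform_spectra(self, models):
        corr, tm = models
        img = np.full((5, 7, 3), 128, dtype=np.uint8)
        cube = rgb_image_to_cube(img, corr, tm)
        assert np.max(np.ptp(cube.flat(), axis=0)) == 0.0

    def test_vectorized_equals_pixel_loop(self, models, rng):
        corr, tm = models
        img = rng.integers(0, 256, (8, 8, 3), dtype=np.uint8)
        cube = rgb_image_to_cube(img, corr, tm)
        from endospec.calibration import apply_correction

        for i, j in [(0, 0), (3, 5), (7, 7), (2, 1)]:
            xyz = cm.linear_rgb_to_xyz(cm.srgb_to_linear_rgb(img[i, j] / 255.0))
            expect = reconstruct_reflectance(tm, apply_correction(corr, xyz))
            assert np.max(np.abs(cube.values[i, j] - expect)) < 1e-10

    def test_invalid_inputs_rejected(self, models, grid):
        corr, tm = models
        with pytest.raises(ValueError):
            rgb_image_to_cube(np.zeros((0, 4, 3)), corr, tm)
        with pytest.raises(ValueError):
            rgb_image_to_cube(np.zeros((4, 4)), corr, tm)
        with pytest.raises(ValueError):
            HyperspectralCube(grid, np.zeros((2, 2, grid.n_bands + 1)))
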