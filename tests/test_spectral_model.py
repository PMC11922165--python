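"""Spectrum integration, PCA basis, transform regression, reconstruction."""

import warnings

import numpy as np
import pytest

from specband import datasets
from specband.camera_calibration import color_expansion_matrix
from specband.spectral_model import (
    SpectralTransform,
    fit_spectral_basis,
    fit_spectral_transform,
    reconstruct_spectra_array,
    reconstruct_spectrum,
    rgb_image_to_cube,
    spectra_to_xyz_array,
    spectrum_to_xyz,
)

class TestSpectrumToXyz:
    def test_perfect_reflector_has_y_100(self, illum_e, illum_led):
        for ill in (illum_e, illum_led):
            xyz = spectrum_to_xyz(np.ones(401), ill)
            assert xyz.y == pytest.approx(100.0, abs=1e-9)
            assert xyz.provenance == "spectrum"

    def test_zero_reflector_is_black(self, illum_e):
        assert np.allclose(spectrum_to_xyz(np.zeros(401), illum_e).as_array(), 0.0)

    def test_linear_in_reflectance(self, illum_led):
        full = spectrum_to_xyz(np.ones(401), illum_led).as_array()
        half = spectrum_to_xyz(np.full(401, 0.5), illum_led).as_array()
        assert np.allclose(half, 0.5 * full, atol=1e-12)

    def test_zero_illuminant_rejected(self):
        with pytest.raises(ValueError, match="illuminant"):
            spectrum_to_xyz(np.ones(401), np.zeros(401))

    def test_restricted_integration_limits(self, illum_e):
        narrow = spectrum_to_xyz(np.ones(401), illum_e, limits=(400.0, 700.0))
        # normalization makes the perfect reflector Y = 100 in any range
        assert narrow.y == pytest.approx(100.0, abs=1e-9)
        chromatic = np.linspace(0.1, 0.9, 401)
        a = spectrum_to_xyz(chromatic, illum_e).as_array()
        b = spectrum_to_xyz(chromatic, illum_e, limits=(400.0, 700.0)).as_array()
        assert not np.allclose(a, b)


class TestFitSpectralBasis:
    def test_matches_brute_force_eigendecomposition(self, checker_spectra):
        basis, _ = fit_spectral_basis(checker_spectra, k=12)
        centered = checker_spectra - checker_spectra.mean(axis=0)
        cov = centered.T @ centered
        evals = np.sort(np.linalg.eigvalsh(cov))[::-1]
        fractions = evals[:12] / evals.sum()
        assert np.allclose(basis.variance_ratio, fractions, atol=1e-8)

    def test_rows_orthonormal_and_variance_sorted(self, checker_spectra):
        basis, _ = fit_spectral_basis(checker_spectra, k=6)
        gram = basis.components @ basis.components.T
        assert np.allclose(gram, np.eye(6), atol=1e-8)
        assert np.all(np.diff(basis.variance_ratio) <= 1e-12)
        assert basis.variance_ratio.sum() <= 1.0 + 1e-9

    def test_rank_one_construction(self):
        mean = np.linspace(0.2, 0.8, 401)
        mode = np.sin(np.linspace(0.0, np.pi, 401))
        amps = np.linspace(-0.1, 0.1, 24)
        spectra = mean[None, :] + amps[:, None] * mode[None, :]
        basis, _ = fit_spectral_basis(spectra, k=1)
        assert basis.variance_ratio[0] >= 0.999

    def test_degenerate_identical_spectra_truncate_to_empty(self):
        spectra = np.tile(np.linspace(0.1, 0.9, 401), (24, 1))
        with pytest.warns(UserWarning, match="truncating"):
            basis, scores = fit_spectral_basis(spectra, k=3)
        assert basis.k == 0
        assert basis.variance_ratio.size == 0
        assert scores.shape == (0, 24)

    def test_scores_follow_pinv_projection(self, checker_spectra):
        basis, scores = fit_spectral_basis(checker_spectra, k=5)
        centered = checker_spectra - basis.mean_spectrum
        expected = (centered @ np.linalg.pinv(basis.components)).T
        assert np.allclose(scores, expected, atol=1e-10)

    def test_invalid_k_rejected(self, checker_spectra):
        with pytest.raises(ValueError):
            fit_spectral_basis(checker_spectra, k=0)
        with pytest.raises(ValueError):
            fit_spectral_basis(checker_spectra, k=25)


class TestFitSpectralTransform:
    def test_recovers_forward_constructed_map(self):
        rng = np.random.default_rng(0)
        xyz = rng.uniform(5.0, 95.0, (24, 3))
        b = rng.normal(size=(4, 7))
        scores = b @ color_expansion_matrix(xyz)
        m = fit_spectral_transform(scores, xyz)
        assert np.allclose(
            m.matrix @ color_expansion_matrix(xyz), scores, atol=1e-6
        )

    def test_zero_scores_give_zero_transform(self):
        rng = np.random.default_rng(1)
        xyz = rng.uniform(5.0, 95.0, (24, 3))
        m = fit_spectral_transform(np.zeros((3, 24)), xyz)
        assert np.allclose(m.matrix, 0.0)

    def test_single_patch_minimum_norm_solution(self):
        xyz = np.array([[50.0, 50.0, 50.0]])
        scores = np.array([[2.0]])
        m = fit_spectral_transform(scores, xyz)
        v = color_expansion_matrix(xyz)
        assert np.allclose(m.matrix @ v, scores, atol=1e-9)

    def test_misaligned_counts_rejected(self):
        with pytest.raises(ValueError):
            fit_spectral_transform(np.zeros((3, 24)), np.zeros((23, 3)))


class TestReconstruction:
    def test_training_patches_round_trip_exactly(self, low_rank_rig):
        target, artifacts = low_rank_rig
        recon = reconstruct_spectra_array(
            artifacts.corrected_xyz, artifacts.basis, artifacts.transform
        )
        rmse = np.sqrt(np.mean((recon - target.spectra) ** 2, axis=1))
        assert rmse.max() < 1e-6

    def test_render_consistency_closure(self, low_rank_rig, illum_e):
        target, artifacts = low_rank_rig
        recon = reconstruct_spectra_array(
            artifacts.corrected_xyz, artifacts.basis, artifacts.transform
        )
        xyz = spectra_to_xyz_array(recon, illum_e)
        assert np.abs(xyz - artifacts.spectrum_xyz).max() < 1e-4

    def test_zero_xyz_with_zero_mean_gives_zero_spectrum(self, low_rank_rig):
        _, artifacts = low_rank_rig
        s = reconstruct_spectrum((0.0, 0.0, 0.0), artifacts.basis, artifacts.transform)
        # uncentered basis: mean term is zero, V_color has no constant term
        assert np.allclose(s, 0.0, atol=1e-12)

    def test_neutral_patch_reconstructs_flat(self, distorted_rig):
        target, artifacts, _ = distorted_rig
        # the last six checker patches are flat neutrals
        recon = reconstruct_spectra_array(
            artifacts.corrected_xyz[-6:], artifacts.basis, artifacts.transform
        )
        # compare flatness to the basis' own best representation of flat
        for r, level in zip(recon, target.spectra[-6:, 0]):
            proj = artifacts.basis.mean_spectrum + artifacts.basis.components.T @ (
                artifacts.basis.components @ (np.full(401, level) - artifacts.basis.mean_spectrum)
            )
            representable_ripple = proj.max() - proj.min()
            assert (r.max() - r.min()) < representable_ripple + 0.12

    def test_monotone_refinement_in_k(self, distorted_rig, illum_e):
        from specband.pipeline import calibrate_rig

        target, _, _ = distorted_rig
        rmses = []
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for k in (1, 2, 3, 6, 12):
                art = calibrate_rig(target, illum_e, k=k)
                rmses.append(art.training_reconstruction_rmse(target))
        assert all(b <= a + 1e-9 for a, b in zip(rmses, rmses[1:]))

    def test_clipping_is_optional_and_recorded(self, low_rank_rig):
        _, artifacts = low_rank_rig
        s = reconstruct_spectrum(
            (500.0, 500.0, 500.0), artifacts.basis, artifacts.transform, clip=True
        )
        assert s.min() >= 0.0 and s.max() <= 1.0


class TestRgbImageToCube:
    def test_training_color_pixel_matches_patch_spectrum(self, low_rank_rig):
        target, artifacts = low_rank_rig
        pixel = np.round(target.rgb[4] * 255.0).astype(np.uint8).reshape(1, 1, 3)
        # quantization to 8 bits limits agreement; compare against the
        # unquantized float capture for the exact statement
        cube = rgb_image_to_cube(
            target.rgb[4].reshape(1, 1, 3),
            artifacts.correction,
            artifacts.basis,
            artifacts.transform,
        )
        assert np.sqrt(np.mean((cube.data[0, 0] - target.spectra[4]) ** 2)) < 1e-6
        cube8 = rgb_image_to_cube(
            pixel, artifacts.correction, artifacts.basis, artifacts.transform
        )
        assert np.sqrt(np.mean((cube8.data[0, 0] - target.spectra[4]) ** 2)) < 0.02

    def test_constant_image_gives_identical_pixels(self, low_rank_rig):
        _, artifacts = low_rank_rig
        image = np.full((5, 7, 3), 130, dtype=np.uint8)
        cube = rgb_image_to_cube(
            image, artifacts.correction, artifacts.basis, artifacts.transform
        )
        assert np.allclose(cube.data, cube.data[0, 0])

    def test_shape_contract_and_determinism(self, low_rank_rig):
        _, artifacts = low_rank_rig
        rng = np.random.default_rng(0)
        image = rng.integers(0, 256, (16, 16, 3), dtype=np.uint8)
        c1 = rgb_image_to_cube(
            image, artifacts.correction, artifacts.basis, artifacts.transform
        )
        c2 = rgb_image_to_cube(
            image, artifacts.correction, artifacts.basis, artifacts.transform
        )
        assert c1.shape == (16, 16, 401)
        assert np.array_equal(c1.data, c2.data)
        assert c1.metadata["correction_sha"] == c2.metadata["correction_sha"]

    def test_non_rgb_input_rejected(self, low_rank_rig):
        _, artifacts = low_rank_rig
        with pytest.raises(ValueError, match="RGB"):
            rgb_image_to_cube(
                np.zeros((4, 4)), artifacts.correction, artifacts.basis, artifacts.transform
            )


def test_transform_shape_contract():
    with pytest.raises(ValueError):
        SpectralTransform(np.zeros((3, 6)))
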