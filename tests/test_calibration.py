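"""Calibration fits: feature expansion, correction matrix, PCA basis,
transform matrix and spectrum/cube reconstruction."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from save_hsi.calibration import (CalibrationModel, ExpansionSpecError,
                                  FeatureExpansionSpec, PINV_RCOND,
                                  SpectralCalibration, XYZ_FEATURE_SCALE,
                                  apply_correction, expand_features,
                                  fit_correction, fit_spectral_basis,
                                  fit_transform_matrix, reconstruct_cube,
                                  reconstruct_spectrum)
from save_hsi.colorimetry import XYZColor, ciede2000, srgb_to_xyz, xyz_to_srgb
from save_hsi.fixtures import PatchMeasurementSet


# -- feature expansion ------------------------------------------------------

def brute_force_monomials(v, order):
    """Independent enumeration oracle: all monomials r^i g^j b^k with
    i+j+k <= order, in (total degree, reverse-lex) order."""
    out = []
    for total in range(order + 1):
        for i in range(total, -1, -1):
            for j in range(total - i, -1, -1):
                k = total - i - j
                out.append(v[0] ** i * v[1] ** j * v[2] ** k)
    return np.array(out)


def test_expansion_term_counts():
    assert FeatureExpansionSpec(1).n_terms == 4
    assert FeatureExpansionSpec(2).n_terms == 10
    assert FeatureExpansionSpec(3).n_terms == 20
    assert FeatureExpansionSpec(3).includes_constant


def test_expansion_order_cap():
    with pytest.raises(ExpansionSpecError):
        FeatureExpansionSpec(4)
    with pytest.raises(ExpansionSpecError):
        FeatureExpansionSpec(2, ((0, 0, 0), (0, 0, 0)))
    with pytest.raises(ExpansionSpecError):
        FeatureExpansionSpec(2, ((1, 0, 0),))  # constant missing


@pytest.mark.parametrize("order", [1, 2, 3])
def test_expansion_matches_bruteforce_oracle(order):
    v = np.array([2.0, 3.0, 5.0])
    got = expand_features(v, FeatureExpansionSpec(order))
    assert np.allclose(got, brute_force_monomials(v, order))


def test_expansion_trivial_points():
    spec = FeatureExpansionSpec(3)
    zero = expand_features(np.zeros(3), spec)
    assert zero[0] == 1.0 and np.all(zero[1:] == 0.0)
    assert np.all(expand_features(np.ones(3), spec) == 1.0)


@settings(derandomize=True, max_examples=25)
@given(st.lists(st.floats(-2, 2), min_size=3, max_size=3))
def test_expansion_constant_term_always_one(v):
    assert expand_features(np.array(v), FeatureExpansionSpec(3))[0] == 1.0


# -- correction matrix ------------------------------------------------------

def _patchset_from_xyz(ref_xyz, cam_xyz, patches):
    rgb = xyz_to_srgb(cam_xyz)
    return PatchMeasurementSet(patches.patch_ids, patches.spectra,
                               patches.grid, ref_xyz, rgb)


def test_correction_identity_case(patches):
    """Camera XYZ already equals reference XYZ: linear C acts as identity."""
    ps = _patchset_from_xyz(patches.reference_xyz, patches.reference_xyz,
                            patches)
    corr = fit_correction(ps, FeatureExpansionSpec(1))
    out = apply_correction(corr, patches.reference_xyz)
    assert np.allclose(out, patches.reference_xyz, atol=1e-6)


def test_correction_recovers_linear_distortion(patches, rng):
    """Camera = reference distorted by a known invertible 3x3 map; a linear
    correction recovers the reference exactly. Colours are kept strictly
    inside the sRGB gamut so encode/decode is lossless."""
    from save_hsi.colorimetry import _SRGB_TO_XYZ, srgb_encode
    A = np.array([[1.1, 0.05, -0.02],
                  [0.03, 0.95, 0.04],
                  [-0.01, 0.02, 1.08]])
    linear = rng.uniform(0.1, 0.8, (24, 3))
    cam_xyz = 100.0 * linear @ _SRGB_TO_XYZ.T
    ref_xyz = cam_xyz @ np.linalg.inv(A).T
    ps = PatchMeasurementSet(patches.patch_ids, patches.spectra,
                             patches.grid, ref_xyz, srgb_encode(linear))
    corr = fit_correction(ps, FeatureExpansionSpec(1))
    out = apply_correction(corr, srgb_to_xyz(ps.camera_rgb))
    assert np.allclose(out, ref_xyz, atol=1e-6)


def test_correction_zero_input_returns_offset_column(patches, fitted):
    corr = fitted.model.correction
    out = apply_correction(corr, np.zeros(3))
    assert np.allclose(out, corr.C[:, 0])


def test_correction_closed_loop_mean_de(fitted):
    """Simulated 24-patch camera, full cubic: mean dE00 within the printed
    calibration quality (reduced from ~10.8 to <= 0.63)."""
    assert fitted.mean_delta_e_corrected <= 0.63
    assert np.nanmean(fitted.delta_e_raw) > fitted.mean_delta_e_corrected


def test_correction_warns_below_24_patches(patches_with_rgb):
    small = PatchMeasurementSet(patches_with_rgb.patch_ids[:10],
                                patches_with_rgb.spectra[:10],
                                patches_with_rgb.grid,
                                patches_with_rgb.reference_xyz[:10],
                                patches_with_rgb.camera_rgb[:10])
    with pytest.warns(UserWarning):
        fit_correction(small, FeatureExpansionSpec(1))


# -- PCA basis --------------------------------------------------------------

def test_basis_six_components_explain_colorchecker(patches):
    basis = fit_spectral_basis(patches, 6)
    assert basis.cumulative_variance >= 0.9964
    assert np.all(np.diff(basis.explained_variance_ratio) <= 1e-12)
    # orthonormality
    G = basis.components @ basis.components.T
    assert np.allclose(G, np.eye(6), atol=1e-10)


def test_basis_full_rank_is_complete(patches):
    basis = fit_spectral_basis(patches, patches.n_patches - 1)
    assert basis.cumulative_variance == pytest.approx(1.0, abs=1e-9)


def test_basis_degenerate_identical_spectra(patches):
    flat = np.tile(patches.spectra[0], (24, 1))
    ps = PatchMeasurementSet(patches.patch_ids, flat, patches.grid,
                             patches.reference_xyz)
    basis = fit_spectral_basis(ps, 3)
    assert np.all(basis.explained_variance_ratio == 0.0)
    assert np.allclose(basis.scores, 0.0)


def test_basis_rejects_too_many_components(patches):
    with pytest.raises(ValueError):
        fit_spectral_basis(patches, 24)


def test_basis_sign_convention(patches):
    basis = fit_spectral_basis(patches, 6)
    for comp in basis.components:
        assert comp[np.abs(comp).argmax()] > 0


# -- transform matrix -------------------------------------------------------

def test_transform_equals_normal_equations_oracle(patches, fitted):
    """pinv-based M against an independent least-squares solution."""
    basis = fitted.model.basis
    V = expand_features(fitted.corrected_xyz / XYZ_FEATURE_SCALE,
                        fitted.model.transform.expansion)
    # normal equations via lstsq (independent of pinv route)
    M_oracle, *_ = np.linalg.lstsq(V, basis.scores, rcond=None)
    assert np.max(np.abs(fitted.model.transform.M - M_oracle.T)) <= 1e-8


def test_transform_exact_when_model_realizable(patches):
    """Scores that are exact linear functions of the features fit with
    zero residual."""
    basis = fit_spectral_basis(patches, 6)
    rng = np.random.default_rng(0)
    W = rng.normal(size=(6, 4))
    xyz = np.abs(rng.normal(30, 10, size=(24, 3)))
    V = expand_features(xyz / XYZ_FEATURE_SCALE, FeatureExpansionSpec(1))
    basis.scores = V @ W.T
    tm = fit_transform_matrix(basis, xyz, FeatureExpansionSpec(1))
    assert np.allclose(V @ tm.M.T, basis.scores, atol=1e-9)


def test_transform_patch_count_mismatch(patches):
    basis = fit_spectral_basis(patches, 6)
    with pytest.raises(ValueError):
        fit_transform_matrix(basis, np.zeros((5, 3)))


# -- reconstruction ---------------------------------------------------------

def test_reconstruction_closed_loop_rmse(fitted):
    assert fitted.mean_rmse <= 0.056
    assert np.sort(fitted.per_patch_rmse)[22] < 0.1  # >= 23 of 24 patches


def test_reconstruction_closed_loop_colour(fitted):
    assert fitted.mean_delta_e_reconstructed <= 0.75


def test_reconstruction_zero_transform_returns_mean(fitted):
    model = fitted.model
    zero = CalibrationModel(
        model.correction,
        model.basis,
        type(model.transform)(np.zeros_like(model.transform.M),
                              model.transform.expansion),
        model.grid)
    spec = reconstruct_spectrum(zero, XYZColor(30, 40, 20))
    assert np.allclose(spec.reflectance,
                       np.clip(model.basis.mean_spectrum, 0, 1))


def test_reconstruction_error_nonincreasing_in_components(patches_with_rgb):
    errs = []
    for n in (2, 4, 6, 8):
        res = SpectralCalibration(patches_with_rgb, n_components=n).fit()
        errs.append(res.mean_rmse)
    assert all(b <= a + 1e-12 for a, b in zip(errs, errs[1:]))


def test_reconstruct_cube_matches_pixel_loop(fitted, rng):
    img = rng.uniform(0.1, 0.9, size=(3, 4, 3))
    cube = fitted.reconstruct_cube(img)
    for i in range(3):
        for j in range(4):
            xyz = srgb_to_xyz(img[i, j])
            corrected = apply_correction(fitted.model.correction, xyz)
            spec = fitted.reconstruct_spectrum(corrected)
            assert np.allclose(cube.data[i, j], spec.reflectance, atol=1e-12)


def test_reconstruct_cube_constant_image_constant_cube(fitted):
    img = np.full((2, 2, 3), 0.4)
    cube = fitted.reconstruct_cube(img)
    assert np.allclose(cube.data, cube.data[0, 0])
    assert np.all((cube.data >= 0) & (cube.data <= 1))


def test_reconstruct_cube_rejects_bad_shape(fitted):
    with pytest.raises(ValueError):
        fitted.reconstruct_cube(np.zeros((4, 4)))


def test_model_json_round_trip(fitted, rng):
    text = fitted.model.to_json()
    model2 = CalibrationModel.from_json(text)
    img = rng.uniform(0, 1, size=(2, 2, 3))
    c1 = reconstruct_cube(fitted.model, img)
    c2 = reconstruct_cube(model2, img)
    assert np.allclose(c1.data, c2.data)


def test_summary_mentions_key_figures(fitted):
    text = fitted.summary()
    assert "explained variance" in text
    assert "RMSE" in text
    assert len(text.splitlines()) > 24
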