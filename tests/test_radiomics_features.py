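"""Radiomics feature bank vs brute-force oracles and hand computations."""

import numpy as np
import pytest

import oracles
from mipradiomics.errors import ContractError
from mipradiomics.imaging_io import BinaryMask, MaskRole, MIPImage
from mipradiomics.radiomics_features import (
    FIRST_ORDER_NAMES,
    GLCM_NAMES,
    GLDM_NAMES,
    GLRLM_NAMES,
    GLSZM_NAMES,
    SHAPE2D_NAMES,
    FeatureVector,
    GrayLevelImage,
    RadiomicsConfig,
    discretize,
    extract_feature_vector,
    feature_names,
    first_order_features,
    glcm_features,
    gldm_features,
    gldm_matrix,
    glrlm_features,
    glszm_features,
    shape2d_features,
    wavelet_decompose,
)


def _random_gl(rng, n_levels=4, shape=(8, 8), mask_p=0.7):
    mask = rng.random(shape) < mask_p
    if not mask.any():
        mask[0, 0] = True
    levels = np.where(mask, rng.integers(1, n_levels + 1, shape), 0).astype(np.int64)
    # renumber so max level is realized
    return GrayLevelImage(levels=levels, n_levels=int(levels.max()), bin_width=1.0)


class TestDiscretize:
    def test_worked_example(self):
        img = np.array([[0.0, 24.9], [25.0, 75.0]])
        gl = discretize(img, np.ones((2, 2), bool), 25.0)
        np.testing.assert_array_equal(gl.levels, [[1, 1], [2, 4]])
        assert gl.n_levels == 4

    def test_constant_roi_single_level(self):
        gl = discretize(np.full((3, 3), 9.0), np.ones((3, 3), bool), 25.0)
        assert gl.n_levels == 1 and np.all(gl.levels == 1)

    def test_matches_brute_force_binning(self, rng):
        img = rng.random((10, 10)) * 130
        mask = rng.random((10, 10)) > 0.3
        mask[0, 0] = True
        gl = discretize(img, mask, 25.0)
        lo = img[mask].min()
        for (r, c) in np.argwhere(mask):
            assert gl.levels[r, c] == int(np.floor((img[r, c] - lo) / 25.0)) + 1
        assert np.all(gl.levels[~mask] == 0)

    def test_empty_mask_rejected(self):
        with pytest.raises(ContractError):
            discretize(np.ones((3, 3)), np.zeros((3, 3), bool), 25.0)


class TestFirstOrder:
    def test_tiny_roi_arithmetic(self):
        img = np.array([[1.0, 2.0, 3.0]])
        f = first_order_features(img, np.ones((1, 3), bool))
        assert f["Mean"] == pytest.approx(2.0)
        assert f["Variance"] == pytest.approx(2.0 / 3.0)
        assert f["Range"] == pytest.approx(2.0)

    def test_constant_roi_degenerate_conventions(self):
        f = first_order_features(np.full((4, 4), 5.0), np.ones((4, 4), bool))
        assert f["Variance"] == 0.0
        assert f["Skewness"] == 0.0
        assert f["Kurtosis"] == 0.0

    def test_all_19_match_direct_formula_oracle(self, rng):
        for _ in range(10):
            img = rng.random((9, 9)) * 200
            mask = rng.random((9, 9)) > 0.4
            mask[4, 4] = True
            ours = first_order_features(img, mask)
            ref = oracles.first_order_by_loops(img[mask])
            assert set(ours) == set(FIRST_ORDER_NAMES)
            for name in FIRST_ORDER_NAMES:
                assert ours[name] == pytest.approx(ref[name], rel=1e-9, abs=1e-12), name


class TestShape2D:
    def test_single_pixel_surface_uses_spacing(self):
        mask = np.zeros((5, 5), bool)
        mask[2, 2] = True
        f = shape2d_features(mask, pixel_spacing=(0.5, 0.8))
        assert f["PixelSurface"] == pytest.approx(0.4)

    def test_disc_sphericity_near_one(self):
        yy, xx = np.mgrid[:50, :50]
        disc = (yy - 25) ** 2 + (xx - 25) ** 2 <= 20**2
        f = shape2d_features(disc)
        assert 0.95 <= f["Sphericity"] <= 1.0
        assert f["MaximumDiameter"] == pytest.approx(40, rel=0.05)

    def test_square_elongation_is_one(self):
        mask = np.zeros((20, 20), bool)
        mask[5:15, 5:15] = True
        f = shape2d_features(mask)
        assert f["Elongation"] == pytest.approx(1.0)
        assert f["MajorAxisLength"] == pytest.approx(f["MinorAxisLength"])

    def test_mesh_surface_accounts_for_holes(self):
        ring = np.zeros((30, 30), bool)
        ring[5:25, 5:25] = True
        solid_area = shape2d_features(ring)["MeshSurface"]
        ring[12:18, 12:18] = False
        hole_area = shape2d_features(ring)["MeshSurface"]
        assert hole_area < solid_area

    def test_returns_the_10_named_features(self, rng):
        mask = rng.random((12, 12)) > 0.5
        mask[6, 6] = True
        assert set(shape2d_features(mask)) == set(SHAPE2D_NAMES)


class TestGLCM:
    def test_constant_roi(self):
        gl = discretize(np.full((4, 4), 3.0), np.ones((4, 4), bool), 25.0)
        f = glcm_features(gl)
        assert f["Contrast"] == 0.0
        assert f["Correlation"] == 1.0
        assert f["JointEnergy"] == pytest.approx(1.0)

    def test_checkerboard_horizontal_matrix(self):
        from mipradiomics.radiomics_features import _glcm_matrix

        levels = np.array([[1, 2], [2, 1]], dtype=np.int64)
        counts = _glcm_matrix(levels, 2, (0, 1))
        assert counts[0, 0] == 0 and counts[1, 1] == 0  # zero diagonal mass
        assert counts.sum() == 4  # 2 horizontal pairs, symmetric
        f = oracles._glcm_single_by_loops((counts / counts.sum()).tolist(), 2)
        assert f["Contrast"] == pytest.approx(1.0)

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(20):
            gl = _random_gl(rng)
            ours = glcm_features(gl)
            ref = oracles.glcm_features_by_loops(gl.levels)
            for name in GLCM_NAMES:
                assert ours[name] == pytest.approx(ref[name], rel=1e-9, abs=1e-12), name


class TestGLRLMAndGLSZM:
    def test_constant_roi_normalized_nonuniformity(self):
        gl = discretize(np.full((4, 4), 3.0), np.ones((4, 4), bool), 25.0)
        assert glrlm_features(gl)["GrayLevelNonUniformityNormalized"] == pytest.approx(1.0)
        assert glszm_features(gl)["GrayLevelNonUniformityNormalized"] == pytest.approx(1.0)

    def test_glrlm_matches_brute_force_oracle(self, rng):
        for _ in range(20):
            gl = _random_gl(rng)
            ours = glrlm_features(gl)
            ref = oracles.glrlm_features_by_loops(gl.levels, GLRLM_NAMES)
            for name in GLRLM_NAMES:
                assert ours[name] == pytest.approx(ref[name], rel=1e-9, abs=1e-12), name

    def test_glszm_matches_brute_force_oracle(self, rng):
        for _ in range(20):
            gl = _random_gl(rng)
            ours = glszm_features(gl)
            ref = oracles.glszm_features_by_loops(gl.levels, GLSZM_NAMES)
            for name in GLSZM_NAMES:
                assert ours[name] == pytest.approx(ref[name], rel=1e-9, abs=1e-12), name


class TestGLDM:
    def test_uniform_3x3_dependence_histogram(self):
        gl = discretize(np.full((3, 3), 2.0), np.ones((3, 3), bool), 25.0)
        m = gldm_matrix(gl)
        # corners have 3 neighbors, edges 5, center 8; one gray level
        assert m.counts.shape == (1, 9)
        assert m.counts[0, 3] == 4 and m.counts[0, 5] == 4 and m.counts[0, 8] == 1
        f = gldm_features(m)
        assert f["LargeDependenceEmphasis"] == pytest.approx(200.0 / 9.0)

    def test_single_pixel_roi(self):
        mask = np.zeros((5, 5), bool)
        mask[2, 2] = True
        gl = discretize(np.ones((5, 5)), mask, 25.0)
        m = gldm_matrix(gl)
        assert m.counts.shape == (1, 1)
        assert m.counts[0, 0] == 1

    def test_single_gray_level_emphases(self):
        gl = discretize(np.full((4, 4), 7.0), np.ones((4, 4), bool), 25.0)
        f = gldm_features(gldm_matrix(gl))
        assert f["LowGrayLevelEmphasis"] == pytest.approx(1.0)
        assert f["HighGrayLevelEmphasis"] == pytest.approx(1.0)
        assert f["GrayLevelVariance"] == 0.0

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(20):
            gl = _random_gl(rng)
            ours = gldm_features(gldm_matrix(gl))
            ref = oracles.gldm_features_by_loops(gl.levels, GLDM_NAMES)
            for name in GLDM_NAMES:
                assert ours[name] == pytest.approx(ref[name], rel=1e-9, abs=1e-12), name

    def test_one_based_dependence_alternative(self, rng):
        gl = _random_gl(rng)
        ours = gldm_features(gldm_matrix(gl, base=1))
        ref = oracles.gldm_features_by_loops(gl.levels, GLDM_NAMES, base=1)
        for name in GLDM_NAMES:
            assert ours[name] == pytest.approx(ref[name], rel=1e-9, abs=1e-12), name

    def test_count_conservation(self, rng):
        gl = _random_gl(rng)
        m = gldm_matrix(gl)
        assert m.counts.sum() == gl.mask.sum()


class TestWavelet:
    def test_constant_image_has_no_detail_content(self):
        bands = wavelet_decompose(np.full((16, 16), 11.0))
        assert np.ptp(bands["LL"]) < 1e-9
        for b in ("LH", "HL", "HH"):
            assert np.abs(bands[b]).max() < 1e-9

    def test_stripes_concentrate_energy_in_one_detail_band(self):
        img = np.zeros((32, 32))
        img[::2, :] = 100.0  # horizontal stripes: variation along rows
        bands = wavelet_decompose(img)
        energies = sorted(float(np.sum(bands[b] ** 2)) for b in ("LH", "HL", "HH"))
        assert energies[-1] > 10 * max(energies[0], 1e-12)
        assert energies[-1] > 10 * energies[1]

    def test_subband_shapes_match_input(self, rng):
        for shape in ((15, 22), (16, 16), (33, 47)):
            bands = wavelet_decompose(rng.random(shape))
            assert all(b.shape == shape for b in bands.values())

    def test_too_small_image_rejected(self):
        with pytest.raises(ContractError):
            wavelet_decompose(np.ones((4, 12)))


class TestExtractFeatureVector:
    def test_counts_and_determinism(self, small_phantom):
        mip = small_phantom.image
        fv_t = extract_feature_vector(mip, small_phantom.tumor_mask_gt, "tumor")
        fv_v = extract_feature_vector(mip, small_phantom.vessel_mask_gt, "vessel")
        assert len(fv_t) == 455
        assert len(fv_v) == 99
        fv_t2 = extract_feature_vector(mip, small_phantom.tumor_mask_gt, "tumor")
        np.testing.assert_array_equal(fv_t.values, fv_t2.values)

    def test_name_schema_partitions(self):
        names = feature_names("tumor")
        assert len(names) == 455
        assert sum(n.startswith("wavelet-") for n in names) == 356
        original_texture = [
            n for n in names
            if n.startswith("original_") and n.split("_")[1] in ("glcm", "glrlm", "glszm", "gldm")
        ]
        assert len(original_texture) == 70
        assert len(feature_names("vessel")) == 99

    def test_texture_features_shift_invariant(self, small_phantom):
        mip = small_phantom.image
        mask = small_phantom.tumor_mask_gt
        a = extract_feature_vector(mip, mask, "vessel").as_dict()
        shifted = MIPImage(mip.pixels + 100.0, mip.pixel_spacing)
        b = extract_feature_vector(shifted, mask, "vessel").as_dict()
        texture = [n for n in a if n.split("_")[1] in ("glcm", "glrlm", "glszm", "gldm")]
        for name in texture:
            assert a[name] == pytest.approx(b[name], rel=1e-9), name

    def test_empty_mask_rejected(self, small_phantom):
        empty = BinaryMask(np.zeros(small_phantom.image.shape, bool), role=MaskRole.TUMOR)
        with pytest.raises(ContractError):
            extract_feature_vector(small_phantom.image, empty, "tumor")

    def test_feature_vector_rejects_nonfinite(self):
        with pytest.raises(ContractError):
            FeatureVector(names=("a", "b"), values=np.array([1.0, np.nan]))
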