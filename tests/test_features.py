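from __future__ import annotations

import numpy as np
import pytest

from radpipe import FeatureConfig, extract_feature_vector, generate_phantom_pair
from radpipe.features import (
    N_FEATURES_PER_MODALITY,
    N_FEATURES_TOTAL,
    base_features,
    discretize,
    extract_modality_features,
    feature_names,
    glcm_features,
    glszm_features,
    texture_family_features,
)
from radpipe.features.texture import _glcm_matrix
from radpipe.segmentation import VolumePair


def _disc_from_levels(levels):
    """Wrap a pre-discretized level array for the texture functions."""
    from radpipe.features.discretize import DiscretizedVolume
    levels = np.asarray(levels, dtype=np.int64)
    return DiscretizedVolume(levels=levels, n_levels=int(levels.max()),
                             mapping=(0.0, 1.0))


class TestDiscretize:
    def test_three_values_two_bins(self):
        vol = np.array([0.0, 0.5, 1.0]).reshape(3, 1, 1)
        mask = np.ones_like(vol, bool)
        d = discretize(vol, mask, n_bins=2)
        np.testing.assert_array_equal(d.levels.ravel(), [1, 2, 2])

    def test_constant_region_all_level_one(self):
        vol = np.full((3, 3, 2), 5.0)
        d = discretize(vol, np.ones_like(vol, bool), n_bins=16)
        assert set(d.levels.ravel()) == {1}

    def test_affine_invariance(self, rng):
        vol = rng.normal(size=(6, 6, 3))
        mask = rng.uniform(size=vol.shape) > 0.3
        d1 = discretize(vol, mask, 32)
        d2 = discretize(2.5 * vol + 17.0, mask, 32)
        np.testing.assert_array_equal(d1.levels, d2.levels)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            discretize(np.ones((2, 2, 2)), np.zeros((2, 2, 2), bool), 8)


class TestGLCMWorkedExamples:
    def test_1d_toy_cluster_shade(self):
        # [1,1,1,2], distance 1, one direction, symmetric:
        # p(1,1)=2/3, p(1,2)=p(2,1)=1/6, marginal means 7/6,
        # shade = sum (i+j-7/3)^3 p = 2/27
        d = _disc_from_levels(np.array([1, 1, 1, 2]).reshape(4, 1, 1))
        f = glcm_features(d, offsets=[(1, 0, 0)])
        assert f["ClusterShade"] == pytest.approx(2.0 / 27.0, rel=1e-12)

    def test_constant_image_degenerate(self):
        d = _disc_from_levels(np.ones((3, 3, 3), int))
        f = glcm_features(d)
        assert f["ClusterShade"] == 0.0
        assert f["ClusterProminence"] == 0.0
        assert f["MaximumProbability"] == 1.0

    def test_matrix_normalizes_to_one(self, rng):
        lv = rng.integers(1, 6, size=(5, 5, 3))
        c = _glcm_matrix(lv, (1, 0, 0), 5)
        p = c / c.sum()
        assert p.sum() == pytest.approx(1.0, abs=1e-12)

    def test_symmetric_tables_have_zero_shade(self):
        # tables symmetric about their marginal mean
        from radpipe.features.texture import _glcm_features_single
        uniform = np.full((4, 4), 1 / 16)
        assert _glcm_features_single(uniform)["ClusterShade"] == pytest.approx(0, abs=1e-12)
        two = np.array([[0.0, 0.5], [0.5, 0.0]])
        assert _glcm_features_single(two)["ClusterShade"] == pytest.approx(0, abs=1e-12)

    def test_no_valid_pairs_raises(self):
        lv = np.zeros((3, 3, 3), int)
        lv[1, 1, 1] = 1   # single voxel: no co-occurring pair anywhere
        with pytest.raises(ValueError):
            glcm_features(_disc_from_levels(lv))


class TestGLSZMWorkedExamples:
    def test_2x2_three_zones(self):
        # zones {1: size 2}, {2: size 1}, {3: size 1}; GLN = 3/3 = 1
        d = _disc_from_levels(np.array([[1, 1], [2, 3]]).reshape(2, 2, 1))
        f = glszm_features(d)
        assert f["GrayLevelNonUniformity"] == pytest.approx(1.0)

    def test_1d_alternating(self):
        # [1,2,1,2]: four singleton zones, two per level; GLN = 8/4 = 2
        d = _disc_from_levels(np.array([1, 2, 1, 2]).reshape(4, 1, 1))
        f = glszm_features(d)
        assert f["GrayLevelNonUniformity"] == pytest.approx(2.0)

    def test_constant_single_zone(self):
        d = _disc_from_levels(np.ones((4, 4, 2), int))
        f = glszm_features(d)
        assert f["GrayLevelNonUniformity"] == pytest.approx(1.0)
        assert f["ZonePercentage"] == pytest.approx(1.0 / 32.0)


class TestTextureFamilies:
    def test_constant_region_glrlm_degenerate(self):
        d = _disc_from_levels(np.ones((4, 1, 1), int))
        f = texture_family_features(d, "GLRLM")   # no division error
        assert np.isfinite(list(f.values())).all()
        # along the line axis the whole region is one run: GLN = 1^2 / 1
        from radpipe.features.texture import _glrlm_matrix
        mat = _glrlm_matrix(d.levels, (1, 0, 0), 1)
        assert mat.sum() == 1 and mat[0, 3] == 1

    def test_unknown_family_rejected(self):
        d = _disc_from_levels(np.ones((4, 1, 1), int))
        with pytest.raises(ValueError):
            texture_family_features(d, "GLXX")

    def test_memory_layout_irrelevant(self, rng):
        lv = rng.integers(1, 5, size=(6, 5, 4))
        a = texture_family_features(_disc_from_levels(lv), "GLDM")
        b = texture_family_features(_disc_from_levels(np.asfortranarray(lv)), "GLDM")
        assert a == b


class TestBaseFeatures:
    def test_constant_values_degenerate_moments(self):
        mask = np.ones((3, 3, 3), bool)
        f = base_features(np.full(27, 4.2), mask, (1, 1, 1))
        assert f["firstorder_Variance"] == 0.0
        assert f["firstorder_Skewness"] == 0.0
        assert f["firstorder_Kurtosis"] == 0.0

    def test_single_voxel_volume(self):
        mask = np.zeros((3, 3, 3), bool)
        mask[1, 1, 1] = True
        f = base_features(np.array([7.0]), mask, (1, 1, 1))
        assert f["shape_VoxelVolume"] == pytest.approx(1.0)

    def test_sphere_sphericity_near_analytic(self):
        # voxelized sphere, radius 8, isotropic 1 mm: analytic sphericity 1
        r = 8.0
        idx = np.indices((20, 20, 20)) - 9.5
        mask = (idx ** 2).sum(axis=0) <= r ** 2
        f = base_features(np.ones(mask.sum()), mask, (1, 1, 1))
        assert f["shape_Sphericity"] == pytest.approx(1.0, rel=0.05)
        analytic_volume = 4 / 3 * np.pi * r ** 3
        assert f["shape_MeshVolume"] == pytest.approx(analytic_volume, rel=0.05)

    def test_count_is_32(self):
        mask = np.ones((4, 4, 2), bool)
        f = base_features(np.arange(32.0), mask, (1, 1, 1))
        assert len(f) == 32


class TestFeatureVector:
    def test_length_214_and_107_per_modality(self, small_spec):
        pair, mask, _ = generate_phantom_pair(small_spec, 0, seed=1)
        per_mod = extract_modality_features(pair.volume_t1c, mask.mask, pair.spacing)
        assert len(per_mod) == N_FEATURES_PER_MODALITY == 107
        vec = extract_feature_vector(pair, mask, mask)
        assert len(vec) == N_FEATURES_TOTAL == 214
        assert list(vec.index) == feature_names()
        assert np.isfinite(vec.to_numpy()).all()

    def test_identical_modalities_symmetric(self, small_spec):
        pair, mask, _ = generate_phantom_pair(small_spec, 0, seed=2)
        same = VolumePair(pair.volume_t1c, pair.volume_t1c.copy(), pair.spacing,
                          pair.affine_t1c, pair.affine_t1c.copy())
        vec = extract_feature_vector(same, mask, mask)
        t1 = vec.filter(like="T1_").to_numpy()
        t2 = vec.filter(like="T2_").to_numpy()
        np.testing.assert_array_equal(t1, t2)

    def test_repeatability_bit_identical(self, small_spec):
        pair, mask, _ = generate_phantom_pair(small_spec, 1, seed=3)
        v1 = extract_feature_vector(pair, mask, mask)
        v2 = extract_feature_vector(pair, mask, mask)
        assert (v1 == v2).all()

    def test_texture_and_shape_invariant_to_intensity_rescale(self, small_spec):
        # fixed-bin-count discretization makes all 150 texture values and the
        # 28 shape values invariant; raw first-order statistics are not
        pair, mask, _ = generate_phantom_pair(small_spec, 1, seed=4)
        scaled = VolumePair(3.0 * pair.volume_t1c + 50.0, 0.5 * pair.volume_t2 + 7.0,
                            pair.spacing, pair.affine_t1c, pair.affine_t2)
        v1 = extract_feature_vector(pair, mask, mask)
        v2 = extract_feature_vector(scaled, mask, mask)
        invariant = [n for n in feature_names()
                     if n.split("_", 1)[1].startswith(("glcm", "glrlm", "glszm",
                                                       "ngtdm", "gldm", "shape"))]
        assert len(invariant) == 178
        np.testing.assert_allclose(v1[invariant], v2[invariant], rtol=1e-12)

    def test_2d_mode_runs(self, small_spec):
        pair, mask, _ = generate_phantom_pair(small_spec, 0, seed=5)
        vec = extract_feature_vector(pair, mask, mask, FeatureConfig(mode="2d"))
        assert len(vec) == 214 and np.isfinite(vec.to_numpy()).all()
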