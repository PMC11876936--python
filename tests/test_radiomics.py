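"""Radiomics features against brute-force enumeration oracles."""

import numpy as np
import pytest

from lesionfuse import radiomics as rad
from lesionfuse.phantoms import PhantomParams, generate_study

import oracles


def _random_case(seed, n_levels=4, max_side=6):
    rng = np.random.default_rng(seed)
    levels, mask = oracles.random_roi(rng, max_side=max_side, n_levels=n_levels)
    droi = rad.DiscretizedROI(levels=levels, mask=mask, n_levels=n_levels)
    return droi, levels, mask


class TestDiscretize:
    def test_binning_matches_direct_enumeration(self, rng):
        vol = rng.random((5, 5, 4))
        mask = rng.random((5, 5, 4)) < 0.7
        mask.flat[0] = True
        droi = rad.discretize_roi(vol, mask, n_levels=4)
        vals = vol[mask]
        width = (vals.max() - vals.min()) / 4
        expect = np.minimum(np.floor((vals - vals.min()) / width).astype(int) + 1, 4)
        np.testing.assert_array_equal(droi.levels[mask], expect)
        assert droi.levels[~mask].max() == 0
        assert droi.levels[mask].min() == 1 and droi.levels[mask].max() == 4

    def test_constant_roi_all_level_one(self):
        vol = np.full((3, 3, 3), 7.0)
        mask = np.ones((3, 3, 3), bool)
        with pytest.warns(RuntimeWarning):
            droi = rad.discretize_roi(vol, mask, 8)
        assert set(droi.levels[mask]) == {1}

    def test_extremes_map_to_first_and_last_level(self, rng):
        vol = rng.normal(size=(6, 6, 6))
        mask = np.ones(vol.shape, bool)
        droi = rad.discretize_roi(vol, mask, 5)
        assert droi.levels[np.unravel_index(vol.argmin(), vol.shape)] == 1
        assert droi.levels[np.unravel_index(vol.argmax(), vol.shape)] == 5


class TestFirstOrder:
    def test_tiny_roi_closed_forms(self):
        f = rad.firstorder_features(np.array([1.0, 2.0, 3.0, 4.0]))
        assert f["range"] == 3.0
        assert f["mean"] == 2.5

    def test_constant_roi_degenerate(self):
        f = rad.firstorder_features(np.full(10, 3.3))
        assert f["range"] == 0.0
        assert f["entropy"] == 0.0
        assert f["skewness"] == 0.0

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_formula_oracle(self, seed):
        x = np.random.default_rng(seed).normal(5, 2, size=50)
        ours = rad.firstorder_features(x)
        ref = oracles.brute_firstorder(x)
        for key in ref:
            assert ours[key] == pytest.approx(ref[key], abs=1e-9), key


class TestShape:
    def test_cube_volume_and_area(self):
        mask = np.zeros((8, 8, 8), bool)
        mask[2:6, 2:6, 2:6] = True
        f = rad.shape_features(mask)
        assert f["volume"] == 64.0
        assert f["surface_area"] == 6 * 16.0

    def test_rod_more_elongated_than_cube(self):
        rod = np.zeros((10, 3, 3), bool)
        rod[1:9, 1, 1] = True
        cube = np.zeros((4, 4, 4), bool)
        cube[1:3, 1:3, 1:3] = True
        assert rad.shape_features(rod)["elongation"] > \
            rad.shape_features(cube)["elongation"]

    def test_single_voxel_degenerate_axes(self):
        mask = np.zeros((3, 3, 3), bool)
        mask[1, 1, 1] = True
        f = rad.shape_features(mask)
        assert f["elongation"] == pytest.approx(1.0)
        assert f["flatness"] == pytest.approx(1.0)
        assert f["max_diameter3d"] == 0.0

    @pytest.mark.parametrize("seed", range(5))
    def test_diameter_and_area_match_pairwise_oracle(self, seed):
        rng = np.random.default_rng(seed)
        mask = rng.random((6, 6, 6)) < 0.4
        mask.flat[0] = True
        f = rad.shape_features(mask, spacing=(1.0, 0.5, 2.0))
        assert f["max_diameter3d"] == pytest.approx(
            oracles.brute_max_diameter(mask, (1.0, 0.5, 2.0)), abs=1e-9)
        assert f["surface_area"] == pytest.approx(
            oracles.brute_surface_area(mask, (1.0, 0.5, 2.0)), abs=1e-9)


class TestGLCM:
    def test_alternating_strip_contrast_one(self):
        # 1-D strip 1,2,1,2: every co-occurring pair differs by one level
        levels = np.array([[[1, 2, 1, 2]]])
        mask = np.ones(levels.shape, bool)
        droi = rad.DiscretizedROI(levels=levels, mask=mask, n_levels=2)
        f = rad.glcm_features(droi)
        assert f["contrast"] == pytest.approx(1.0)

    def test_constant_roi(self):
        droi = rad.DiscretizedROI(levels=np.ones((3, 3, 3), np.int64),
                                  mask=np.ones((3, 3, 3), bool), n_levels=2)
        f = rad.glcm_features(droi)
        assert f["contrast"] == 0.0
        assert f["idm"] == pytest.approx(1.0)

    def test_isolated_voxels_raise(self):
        levels = np.zeros((5, 5, 5), np.int64)
        mask = np.zeros((5, 5, 5), bool)
        levels[0, 0, 0] = 1
        mask[0, 0, 0] = True
        levels[4, 4, 4] = 2
        mask[4, 4, 4] = True
        droi = rad.DiscretizedROI(levels=levels, mask=mask, n_levels=2)
        with pytest.raises(rad.FeatureUndefinedError):
            rad.glcm_features(droi)

    @pytest.mark.parametrize("seed", range(10))
    def test_matrix_matches_pair_enumeration(self, seed):
        droi, levels, mask = _random_case(seed, n_levels=3, max_side=5)
        ours = rad.glcm_matrix(droi)
        ref = oracles.brute_glcm(levels, mask, 3)
        np.testing.assert_allclose(ours, ref, atol=1e-12)


class TestGLDM:
    def test_constant_cube_dependence_counts(self):
        # 3x3x3 constant ROI, alpha=0: centre has 26 dependents, faces 17,
        # edges 11, corners 7 — verified by direct neighbour counting
        droi = rad.DiscretizedROI(levels=np.ones((3, 3, 3), np.int64),
                                  mask=np.ones((3, 3, 3), bool), n_levels=1)
        m = rad.gldm_matrix(droi, alpha=0)
        ref = oracles.brute_gldm(np.ones((3, 3, 3), np.int64),
                                 np.ones((3, 3, 3), bool), 1, 0)
        np.testing.assert_array_equal(m, ref)
        assert m[0, 26] == 1  # centre voxel
        assert m.sum() == 27

    def test_single_voxel_dependence_zero(self):
        mask = np.zeros((3, 3, 3), bool)
        levels = np.zeros((3, 3, 3), np.int64)
        mask[1, 1, 1] = True
        levels[1, 1, 1] = 1
        droi = rad.DiscretizedROI(levels=levels, mask=mask, n_levels=1)
        m = rad.gldm_matrix(droi, 0)
        assert m[0, 0] == 1 and m.sum() == 1

    @pytest.mark.parametrize("seed", range(10))
    @pytest.mark.parametrize("alpha", [0, 1])
    def test_matrix_matches_neighbour_enumeration(self, seed, alpha):
        droi, levels, mask = _random_case(seed, n_levels=3, max_side=4)
        np.testing.assert_array_equal(rad.gldm_matrix(droi, alpha),
                                      oracles.brute_gldm(levels, mask, 3, alpha))


class TestGLSZM:
    def test_constant_cube_single_zone(self):
        droi = rad.DiscretizedROI(levels=np.ones((2, 2, 2), np.int64),
                                  mask=np.ones((2, 2, 2), bool), n_levels=1)
        assert rad.glszm_zones(droi) == [(1, 8)]

    def test_two_disjoint_singleton_zones(self):
        levels = np.zeros((5, 5, 5), np.int64)
        mask = np.zeros((5, 5, 5), bool)
        levels[0, 0, 0], mask[0, 0, 0] = 1, True
        levels[4, 4, 4], mask[4, 4, 4] = 2, True
        droi = rad.DiscretizedROI(levels=levels, mask=mask, n_levels=2)
        assert sorted(rad.glszm_zones(droi)) == [(1, 1), (2, 1)]

    @pytest.mark.parametrize("seed", range(10))
    def test_zones_match_flood_fill_oracle(self, seed):
        droi, levels, mask = _random_case(seed, n_levels=3, max_side=5)
        assert sorted(rad.glszm_zones(droi)) == \
            sorted(oracles.brute_glszm_zones(levels, mask))


class TestNGTDM:
    def test_constant_roi_degenerate_conventions(self):
        droi = rad.DiscretizedROI(levels=np.ones((3, 3, 3), np.int64),
                                  mask=np.ones((3, 3, 3), bool), n_levels=2)
        f = rad.ngtdm_features(droi)
        assert f["contrast"] == 0.0
        assert f["coarseness"] == rad.COARSENESS_CONSTANT

    def test_plane_with_hot_centre_hand_enumeration(self):
        # 3x3 single-slice plane, centre level 2 amid level 1:
        # centre: |2 - 1| = 1; each edge/corner neighbourhood includes the
        # centre, so s_1 = sum over 8 voxels of |1 - mean(neighbours)|
        levels = np.ones((1, 3, 3), np.int64)
        levels[0, 1, 1] = 2
        mask = np.ones((1, 3, 3), bool)
        droi = rad.DiscretizedROI(levels=levels, mask=mask, n_levels=2)
        n, s, nvc = rad.ngtdm_table(droi)
        # corners: 3 neighbours (1,1,2) -> mean 4/3
        # edges: 5 neighbours (1,1,1,1,2) -> mean 6/5
        expect_s1 = 4 * abs(1 - 4 / 3) + 4 * abs(1 - 6 / 5)
        assert nvc == 9
        assert n[0] == 8 and n[1] == 1
        assert s[0] == pytest.approx(expect_s1, abs=1e-12)
        assert s[1] == pytest.approx(1.0, abs=1e-12)

    def test_isolated_voxel_raises(self):
        mask = np.zeros((3, 3, 3), bool)
        levels = np.zeros((3, 3, 3), np.int64)
        mask[0, 0, 0], levels[0, 0, 0] = True, 1
        droi = rad.DiscretizedROI(levels=levels, mask=mask, n_levels=1)
        with pytest.raises(rad.FeatureUndefinedError):
            rad.ngtdm_features(droi)

    @pytest.mark.parametrize("seed", range(10))
    def test_features_match_per_voxel_oracle(self, seed):
        droi, levels, mask = _random_case(seed, n_levels=3, max_side=5)
        try:
            ours = rad.ngtdm_features(droi)
        except rad.FeatureUndefinedError:
            pytest.skip("ROI with no neighbourhood")
        ref = oracles.brute_ngtdm_features(levels, mask, 3)
        for key in ref:
            assert ours[key] == pytest.approx(ref[key], abs=1e-9), key


class TestFeatureVector:
    def test_fixed_schema_and_determinism(self, small_cohort):
        v1 = rad.extract_feature_vector(small_cohort[0])
        v2 = rad.extract_feature_vector(small_cohort[0])
        assert tuple(v1.values) == rad.FEATURE_NAMES
        assert len(v1.to_array()) == len(rad.FEATURE_NAMES)
        np.testing.assert_array_equal(v1.to_array(), v2.to_array())
        assert np.all(np.isfinite(v1.to_array()))

    def test_translation_invariance(self):
        params = PhantomParams(grid_shape=(16, 32, 32), noise_sd=0.0,
                               intensity_scale_jitter=(1.0, 1.0),
                               n_lesions_range=(1, 1))
        study = generate_study(params, 1, rng=3)
        v0 = rad.extract_feature_vector(study).to_array()
        shifted = type(study)(volume=np.roll(study.volume, 3, axis=3),
                              mask=np.roll(study.mask, 3, axis=2),
                              label=study.label, study_id="shifted")
        v1 = rad.extract_feature_vector(shifted).to_array()
        np.testing.assert_allclose(v0, v1, atol=1e-9)

    def test_intensity_shift_invariance_of_texture(self, small_cohort):
        study = small_cohort[0]
        cfg = rad.RadiomicsConfig()
        droi_a = rad.discretize_roi(study.volume[0], study.mask, cfg.n_levels)
        droi_b = rad.discretize_roi(study.volume[0] + 100.0, study.mask,
                                    cfg.n_levels)
        fa, fb = rad.glcm_features(droi_a), rad.glcm_features(droi_b)
        for key in fa:
            assert fa[key] == pytest.approx(fb[key], abs=1e-12)

    def test_rotation_invariance_of_direction_averaged_glcm(self, rng):
        droi, levels, mask = _random_case(99, n_levels=3, max_side=5)
        rot = rad.DiscretizedROI(levels=np.rot90(levels, axes=(1, 2)).copy(),
                                 mask=np.rot90(mask, axes=(1, 2)).copy(),
                                 n_levels=3)
        fa, fb = rad.glcm_features(droi), rad.glcm_features(rot)
        for key in fa:
            assert fa[key] == pytest.approx(fb[key], abs=1e-12)


class TestStandardizer:
    def test_fold_statistics_and_constant_columns(self, rng):
        train = rng.normal(size=(20, 5))
        train[:, 2] = 4.0
        std = rad.FeatureStandardizer().fit(train)
        out = std.transform(train)
        np.testing.assert_allclose(out.mean(axis=0), 0.0, atol=1e-12)
        assert np.all(out[:, 2] == 0.0)
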