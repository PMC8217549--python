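"""Feature extraction: discretisation, per-class oracles, counting identities."""

import numpy as np
import pytest

from asradiomics import ImageVolume, QuantisationConfig, RoiMask
from asradiomics.features import (
    ANGLES,
    CLASS_SIZES,
    DiscretisedRoi,
    discretise,
    extract_feature_vector,
    feature_names,
    first_order_features,
    glcm_features,
    glcm_matrices,
    gldm_features,
    gldm_matrix,
    glrlm_features,
    glrlm_matrices,
    glszm_features,
    glszm_matrix,
    ngtdm_features,
    shape_features_3d,
)

from conftest import random_roi, sphere_mask, random_volume


def _vol_mask(values, spacing=(1, 1, 1)):
    arr = np.asarray(values, dtype=float)
    return ImageVolume(arr, spacing), RoiMask(np.ones(arr.shape, bool), spacing)


class TestDiscretise:
    def test_uniform_0_255_with_8_bins(self):
        vals = np.arange(256, dtype=float).reshape(4, 8, 8)
        vol, mask = _vol_mask(vals)
        roi = discretise(vol, mask, QuantisationConfig(8))
        lv = roi.levels[roi.mask]
        # each bin spans 32 units, monotone in intensity
        assert np.array_equal(np.sort(np.unique(lv)), np.arange(1, 9))
        order = np.argsort(vals.ravel())
        assert np.all(np.diff(lv.ravel()[order]) >= 0)
        assert np.bincount(lv)[1:].tolist() == [32] * 8

    def test_constant_roi_all_level_one_and_degenerate(self):
        vol, mask = _vol_mask(np.full((3, 3, 3), 7.0))
        roi = discretise(vol, mask, QuantisationConfig(16))
        assert roi.degenerate
        assert np.all(roi.levels[roi.mask] == 1)

    def test_known_values_match_edge_formula(self):
        vals = np.array([0.0, 1.0, 2.5, 3.9, 4.0, 5.5, 7.9, 8.0, 9.9, 10.0])
        vol = ImageVolume(vals.reshape(1, 2, 5), (1, 1, 1))
        mask = RoiMask(np.ones((1, 2, 5), bool), (1, 1, 1))
        roi = discretise(vol, mask, QuantisationConfig(4))
        width = 10.0 / 4
        expected = np.minimum(np.floor(vals / width).astype(int) + 1, 4)
        assert np.array_equal(roi.levels.ravel(), expected)

    def test_intensity_shift_leaves_levels_unchanged(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(100, 15, (4, 4, 4))
        vol, mask = _vol_mask(vals)
        vol2 = ImageVolume(vals + 123.4, (1, 1, 1))
        r1 = discretise(vol, mask, QuantisationConfig(16))
        r2 = discretise(vol2, mask, QuantisationConfig(16))
        assert np.array_equal(r1.levels, r2.levels)


class TestFirstOrder:
    def test_constant_roi(self):
        vol, mask = _vol_mask(np.full((3, 3, 3), 5.0))
        roi = discretise(vol, mask, QuantisationConfig(8))
        f = first_order_features(np.full(27, 5.0), roi)
        assert f["firstorder_Mean"] == 5.0
        assert f["firstorder_Variance"] == 0.0
        assert f["firstorder_Energy"] == 27 * 25.0
        assert f["firstorder_Uniformity"] == 1.0
        assert f["firstorder_Entropy"] == 0.0
        assert np.isnan(f["firstorder_Skewness"])

    def test_two_voxel_roi(self):
        vol = ImageVolume(np.array([[[0.0, 2.0]]]), (1, 1, 1))
        mask = RoiMask(np.ones((1, 1, 2), bool), (1, 1, 1))
        roi = discretise(vol, mask, QuantisationConfig(2))
        f = first_order_features(np.array([0.0, 2.0]), roi)
        assert f["firstorder_Mean"] == 1.0
        assert f["firstorder_Range"] == 2.0
        assert f["firstorder_RootMeanSquared"] == pytest.approx(np.sqrt(2))

    def test_random_values_match_brute_force(self):
        rng = np.random.default_rng(1)
        x = rng.normal(10, 4, 20)
        vol = ImageVolume(x.reshape(1, 4, 5), (1, 1, 2))
        mask = RoiMask(np.ones((1, 4, 5), bool), (1, 1, 2))
        roi = discretise(vol, mask, QuantisationConfig(8))
        f = first_order_features(x, roi, voxel_volume=2.0)
        n = x.size
        dev = x - x.mean()
        hist = np.bincount(roi.levels.ravel())[1:]
        p = hist[hist > 0] / n
        robust = x[(x >= np.percentile(x, 10)) & (x <= np.percentile(x, 90))]
        expected = {
            "firstorder_Energy": np.sum(x**2),
            "firstorder_TotalEnergy": 2.0 * np.sum(x**2),
            "firstorder_Entropy": -np.sum(p * np.log2(p)),
            "firstorder_Minimum": x.min(),
            "firstorder_10Percentile": np.percentile(x, 10),
            "firstorder_90Percentile": np.percentile(x, 90),
            "firstorder_Maximum": x.max(),
            "firstorder_Mean": x.mean(),
            "firstorder_Median": np.median(x),
            "firstorder_InterquartileRange": np.percentile(x, 75) - np.percentile(x, 25),
            "firstorder_Range": np.ptp(x),
            "firstorder_MeanAbsoluteDeviation": np.mean(np.abs(dev)),
            "firstorder_RobustMeanAbsoluteDeviation": np.mean(np.abs(robust - robust.mean())),
            "firstorder_RootMeanSquared": np.sqrt(np.mean(x**2)),
            "firstorder_Skewness": np.mean(dev**3) / np.mean(dev**2) ** 1.5,
            "firstorder_Kurtosis": np.mean(dev**4) / np.mean(dev**2) ** 2,
            "firstorder_Variance": np.mean(dev**2),
            "firstorder_Uniformity": np.sum(p**2),
        }
        assert set(f) == set(expected)
        for k, v in expected.items():
            assert f[k] == pytest.approx(v, rel=1e-12), k

    def test_mean_variance_invariant_under_shuffle(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=24)
        vol = ImageVolume(x.reshape(2, 3, 4), (1, 1, 1))
        mask = RoiMask(np.ones((2, 3, 4), bool), (1, 1, 1))
        roi = discretise(vol, mask, QuantisationConfig(4))
        f1 = first_order_features(x, roi)
        f2 = first_order_features(rng.permutation(x), roi)
        assert f1["firstorder_Mean"] == pytest.approx(f2["firstorder_Mean"])
        assert f1["firstorder_Variance"] == pytest.approx(f2["firstorder_Variance"])


class TestShape:
    def test_cube_geometry(self):
        m = np.zeros((14, 14, 14), bool)
        m[2:12, 2:12, 2:12] = True
        f = shape_features_3d(RoiMask(m, (1, 1, 1)))
        assert f["shape_VoxelVolume"] == 1000.0
        assert f["shape_MeshVolume"] == pytest.approx(1000, rel=0.05)
        assert f["shape_SurfaceArea"] == pytest.approx(600, rel=0.10)

    def test_digitised_sphere_sphericity(self):
        f = shape_features_3d(sphere_mask(8, shape=(22, 22, 22)))
        assert f["shape_Sphericity"] >= 0.95
        # analytic cross-check: mesh area/volume near the true sphere's
        assert f["shape_MeshVolume"] == pytest.approx(4 / 3 * np.pi * 512, rel=0.05)
        assert f["shape_SurfaceArea"] == pytest.approx(4 * np.pi * 64, rel=0.07)

    def test_shape_identical_across_bin_counts(self, one_lesion):
        from asradiomics import BIN_COUNTS

        vecs = [
            extract_feature_vector(one_lesion.volumes["T2W"], one_lesion.mask,
                                   QuantisationConfig(nb))
            for nb in BIN_COUNTS
        ]
        shape_keys = [k for k in vecs[0] if k.startswith("shape_")]
        assert len(shape_keys) == 14
        for k in shape_keys:
            assert len({v[k] for v in vecs}) == 1

    def test_anisotropic_spacing_scales_volume(self):
        m = np.zeros((10, 10, 10), bool)
        m[3:7, 3:7, 3:7] = True
        f1 = shape_features_3d(RoiMask(m, (1, 1, 1)))
        f2 = shape_features_3d(RoiMask(m, (1, 1, 3)))
        assert f2["shape_VoxelVolume"] == pytest.approx(3 * f1["shape_VoxelVolume"])

    def test_tiny_mask_mesh_features_nan(self):
        m = np.zeros((6, 6, 6), bool)
        m[2, 2, 2:4] = True
        f = shape_features_3d(RoiMask(m, (1, 1, 1)))
        assert np.isnan(f["shape_MeshVolume"])
        assert f["shape_VoxelVolume"] == 2.0


class TestGLCM:
    def test_two_by_two_matches_pair_enumeration(self):
        lv = np.array([[[1], [1]], [[2], [2]]], dtype=np.int32)
        roi = DiscretisedRoi(lv, lv > 0, 2)
        mats = glcm_matrices(roi)
        vox = {idx: lv[idx] for idx in np.ndindex(lv.shape)}
        for a, (dx, dy, dz) in enumerate(ANGLES):
            P = np.zeros((2, 2))
            for (i, j, k), g1 in vox.items():
                nb = (i + dx, j + dy, k + dz)
                if nb in vox:
                    P[g1 - 1, vox[nb] - 1] += 1
                    P[vox[nb] - 1, g1 - 1] += 1
            if P.sum():
                P /= P.sum()
            np.testing.assert_allclose(mats[a], P)

    def test_checkerboard_concentrates_off_diagonal(self):
        idx = np.indices((4, 4, 4)).sum(axis=0)
        lv = (idx % 2 + 1).astype(np.int32)
        roi = DiscretisedRoi(lv, np.ones(lv.shape, bool), 2)
        f = glcm_features(roi)
        # face-adjacent pairs always differ -> high contrast, energy off-diagonal
        mats = glcm_matrices(roi)
        face_dirs = [i for i, d in enumerate(ANGLES) if sum(map(abs, d)) == 1]
        for i in face_dirs:
            assert mats[i][0, 0] == 0 and mats[i][1, 1] == 0
        assert f["glcm_Contrast"] > 0.5

    def test_matrices_symmetric_and_normalised(self):
        rng = np.random.default_rng(3)
        for _ in range(25):
            roi = random_roi(rng)
            for P in glcm_matrices(roi):
                if P.sum() == 0:
                    continue
                assert P.sum() == pytest.approx(1.0)
                np.testing.assert_allclose(P, P.T)

    def test_constant_roi_conventions(self):
        lv = np.ones((3, 3, 3), dtype=np.int32)
        f = glcm_features(DiscretisedRoi(lv, lv > 0, 8, degenerate=True))
        assert f["glcm_Correlation"] == 1.0
        assert f["glcm_Imc1"] == 0.0
        assert f["glcm_MCC"] == 1.0


class TestGLRLM:
    def test_row_of_four_matches_hand_enumeration(self):
        lv = np.array([[[1, 1, 2, 2]]], dtype=np.int32)
        roi = DiscretisedRoi(lv, lv > 0, 2)
        mats = glrlm_matrices(roi)
        for a, d in enumerate(ANGLES):
            P = mats[a]
            total = (P * np.arange(1, P.shape[1] + 1)).sum()
            assert total == 4  # every voxel in exactly one run
            if d == (0, 0, 1):  # along the row: runs (1,len2),(2,len2)
                assert P[0, 1] == 1 and P[1, 1] == 1 and P.sum() == 2

    def test_constant_roi_single_full_run_along_each_line(self):
        lv = np.ones((1, 1, 5), dtype=np.int32)
        roi = DiscretisedRoi(lv, lv > 0, 1)
        along = glrlm_matrices(roi)[ANGLES.index((0, 0, 1))]
        assert along[0, 4] == 1 and along.sum() == 1


try:
    from hypothesis import given, settings, strategies as st
    from hypothesis.extra.numpy import arrays

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        levels=arrays(np.int32, (4, 4, 4), elements=st.integers(1, 4)),
        mask_bits=arrays(np.bool_, (4, 4, 4)),
    )
    def test_counting_identities_hold_for_arbitrary_rois(levels, mask_bits):
        """Zones, dependences and runs partition any ROI's voxels."""
        mask = mask_bits.copy()
        if not mask.any():
            mask[0, 0, 0] = True
        roi = DiscretisedRoi(np.where(mask, levels, 0).astype(np.int32), mask, 4)
        n = roi.voxel_count
        Z = glszm_matrix(roi)
        assert (Z * np.arange(1, Z.shape[1] + 1)).sum() == n
        assert gldm_matrix(roi).sum() == n
        for M in glrlm_matrices(roi):
            assert (M * np.arange(1, M.shape[1] + 1)).sum() == n
except ImportError:  # pragma: no cover - hypothesis is an optional test dep
    pass


class TestMatrixIdentities:
    """Voxel-counting identities on random small ROIs (>=100 instances)."""

    def test_counting_identities_random_rois(self):
        rng = np.random.default_rng(12)
        for i in range(110):
            roi = random_roi(rng, n_levels=int(rng.integers(2, 6)))
            n = roi.voxel_count
            P = glszm_matrix(roi)
            sizes = np.arange(1, P.shape[1] + 1)
            assert (P * sizes).sum() == n  # zones partition the ROI
            D = gldm_matrix(roi)
            assert D.sum() == n  # one dependence entry per voxel
            for M in glrlm_matrices(roi):
                lengths = np.arange(1, M.shape[1] + 1)
                assert (M * lengths).sum() == n  # runs partition per direction

    def test_constant_roi_degenerate_texture(self):
        lv = np.ones((3, 3, 3), dtype=np.int32)
        roi = DiscretisedRoi(lv, lv > 0, 8, degenerate=True)
        P = glszm_matrix(roi)
        assert P.shape[0] == 1 and P[0, 26] == 1  # one zone of 27 voxels
        assert ngtdm_features(roi)["ngtdm_Busyness"] == 0.0
        D = gldm_matrix(roi)
        assert D.shape[0] == 1 and D.sum() == 27  # single grey-level row


class TestFullVector:
    def test_vector_has_107_features_in_class_sizes(self, one_lesion):
        vec = extract_feature_vector(
            one_lesion.volumes["T2W"], one_lesion.mask, QuantisationConfig(32)
        )
        feats = {k: v for k, v in vec.items()
                 if k not in ("sequence", "mask_version", "n_bins")}
        assert len(feats) == 107
        for cls, size in CLASS_SIZES.items():
            assert sum(k.startswith(cls + "_") for k in feats) == size
        assert all(np.isfinite(v) for v in feats.values())

    def test_feature_names_stable_and_complete(self):
        names = feature_names()
        assert len(names) == len(set(names)) == 107

    def test_extraction_deterministic(self, one_lesion):
        v1 = extract_feature_vector(one_lesion.volumes["ADC"], one_lesion.mask,
                                    QuantisationConfig(16))
        v2 = extract_feature_vector(one_lesion.volumes["ADC"], one_lesion.mask,
                                    QuantisationConfig(16))
        assert v1 == v2

    def test_intensity_shift_invariance_of_texture_classes(self, one_lesion):
        vol = one_lesion.volumes["T2W"]
        shifted = ImageVolume(vol.data + 500.0, vol.spacing, vol.sequence)
        v1 = extract_feature_vector(vol, one_lesion.mask, QuantisationConfig(64))
        v2 = extract_feature_vector(shifted, one_lesion.mask, QuantisationConfig(64))
        for k in v1:
            if k.split("_")[0] in ("glcm", "glrlm", "glszm", "gldm", "ngtdm"):
                assert v1[k] == pytest.approx(v2[k], rel=1e-9), k

    def test_provenance_fields(self, one_lesion):
        vec = extract_feature_vector(one_lesion.volumes["T2W"], one_lesion.mask,
                                     QuantisationConfig(8))
        assert vec["sequence"] == "T2W"
        assert vec["mask_version"] == "original"
        assert vec["n_bins"] == 8
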