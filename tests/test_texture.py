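"""Feature-math oracles: hand computations, brute-force matrix enumeration,
and the constant-shift invariance of the whole derived-image bank."""

import numpy as np
import pytest

from dpetfusion import texture as T
from dpetfusion.filters import image_bank, default_image_names


class TestFirstOrder:
    def test_hand_listed_region(self):
        # 3x3x3 region, hand-enumerable values 1..27
        vals = np.arange(1.0, 28.0)
        f = T.firstorder_features(vals, voxel_volume=2.0)
        assert f["Mean"] == pytest.approx(14.0)
        assert f["Minimum"] == 1.0 and f["Maximum"] == 27.0
        assert f["Median"] == 14.0
        assert f["Range"] == 26.0
        assert f["Energy"] == pytest.approx(sum(v * v for v in vals))
        assert f["TotalEnergy"] == pytest.approx(2.0 * f["Energy"])
        assert f["RootMeanSquared"] == pytest.approx(np.sqrt((vals**2).mean()))
        assert f["Variance"] == pytest.approx(vals.var())

    def test_constant_region_limits(self):
        f = T.firstorder_features(np.full(50, 3.3))
        assert f["Entropy"] == 0.0
        assert f["Uniformity"] == 1.0
        assert f["Variance"] == pytest.approx(0.0, abs=1e-24)
        assert f["Skewness"] == 0.0

    def test_count_is_18_plus_optional_std(self):
        vals = np.arange(10.0)
        assert len(T.firstorder_features(vals)) == 18
        assert len(T.firstorder_features(vals, with_std=True)) == 19


class TestMatrices:
    def test_glcm_constant_region_contrast_zero(self):
        disc, n = T.discretize(np.full((4, 4, 4), 5.0), np.ones((4, 4, 4), bool), 32)
        f = T.glcm_features(T.glcm_matrix(disc, n))
        assert f["Contrast"] == 0.0
        assert f["JointEntropy"] == 0.0
        assert f["MaximumProbability"] == 1.0

    def test_glrlm_matches_explicit_run_enumeration(self):
        # independent oracle: walk every line in every direction, collect runs
        rng = np.random.default_rng(5)
        disc = rng.integers(0, 3, size=(4, 5, 3)).astype(np.int32)

        def oracle(disc, n_levels):
            runs = {}
            shape = disc.shape
            for d in T.unique_directions(3):
                starts = [
                    (z, y, x)
                    for z in range(shape[0])
                    for y in range(shape[1])
                    for x in range(shape[2])
                ]
                seen = set()
                for p in starts:
                    prev = (p[0] - d[0], p[1] - d[1], p[2] - d[2])
                    in_prev = all(0 <= c < s for c, s in zip(prev, shape))
                    v = disc[p]
                    if v == 0:
                        continue
                    if in_prev and disc[prev] == v:
                        continue  # not a run start
                    length = 0
                    q = p
                    while all(0 <= c < s for c, s in zip(q, shape)) and disc[q] == v:
                        length += 1
                        q = (q[0] + d[0], q[1] + d[1], q[2] + d[2])
                    runs[(d, p)] = (v, length)
            mat = np.zeros((n_levels, max(l for _, l in runs.values())))
            for v, l in runs.values():
                mat[v - 1, l - 1] += 1
            return mat

        got = T.glrlm_matrix(disc, 2)
        want = oracle(disc, 2)
        np.testing.assert_array_equal(got, want)

    def test_glszm_counts_connected_zones(self):
        disc = np.zeros((3, 3, 1), dtype=np.int32)
        disc[0, 0, 0] = 1
        disc[2, 2, 0] = 1  # two separate single-voxel zones of level 1
        disc[0, 2, 0] = 2
        disc[1, 1, 0] = 2  # diagonal touch: one zone of size 2 (26-connectivity)
        mat = T.glszm_matrix(disc, 2)
        assert mat[0, 0] == 2  # level 1: two zones of size 1
        assert mat[1, 1] == 1  # level 2: one zone of size 2

    def test_gldm_dependence_counts(self):
        disc = np.ones((1, 1, 3), dtype=np.int32)  # row of three equal voxels
        mat = T.gldm_matrix(disc, 1, alpha=0)
        # ends have 1 dependent neighbour, center has 2
        assert mat[0, 1] == 2 and mat[0, 2] == 1

    def test_texture_vector_has_93_features(self, rng):
        img = rng.normal(size=(6, 6, 6))
        mask = np.ones((6, 6, 6), bool)
        assert len(T.texture_feature_vector(img, mask)) == 93


class TestShiftInvariance:
    def test_full_bank_invariant_to_constant_shift(self, rng):
        """Bin-count discretization + shift-equivariant bank => identical features."""
        img = rng.normal(size=(14, 14, 14)) * 3 + 20
        mask = np.zeros((14, 14, 14), bool)
        mask[3:11, 3:11, 3:11] = True
        for name_set in [default_image_names()]:
            bank_a = image_bank(img, (1, 1, 1), name_set)
            bank_b = image_bank(img + 37.5, (1, 1, 1), name_set)
            for name in name_set:
                fa = T.texture_feature_vector(bank_a[name], mask)
                fb = T.texture_feature_vector(bank_b[name], mask)
                texture_keys = [k for k in fa if not k.startswith("firstorder")]
                for k in texture_keys:
                    assert fa[k] == pytest.approx(fb[k], rel=1e-8, abs=1e-10), (name, k)


class TestShape:
    def test_sphere_shape_descriptors(self):
        zz, yy, xx = np.indices((21, 21, 21), dtype=float)
        r = np.sqrt((zz - 10) ** 2 + (yy - 10) ** 2 + (xx - 10) ** 2)
        mask = r <= 8
        f = T.shape3d_features(mask, (1.0, 1.0, 1.0))
        assert f["Sphericity"] == pytest.approx(1.0, abs=0.08)
        assert f["Maximum3DDiameter"] == pytest.approx(16.0, rel=0.1)
        assert f["Elongation"] == pytest.approx(1.0, abs=0.05)
        assert f["Flatness"] == pytest.approx(1.0, abs=0.05)
        assert f["VoxelVolume"] == int(mask.sum())
        assert len(f) == 14

    def test_anisotropic_spacing_scales_volume(self):
        mask = np.zeros((4, 4, 4), bool)
        mask[1:3, 1:3, 1:3] = True
        f = T.shape3d_features(mask, (2.0, 1.0, 1.0))
        assert f["VoxelVolume"] == pytest.approx(8 * 2.0)

    def test_square_shape2d(self):
        mask = np.zeros((6, 6), bool)
        mask[1:5, 1:5] = True
        f = T.shape2d_features(mask)
        assert f["PixelSurface"] == 16.0
        assert f["Extent"] == 1.0
        assert f["Solidity"] == 1.0
        assert f["Elongation"] == pytest.approx(1.0)
        assert f["MaximumDiameter"] == pytest.approx(3 * np.sqrt(2))
        assert len(f) == 10


def test_discretize_respects_bin_count(rng):
    img = rng.normal(size=(8, 8, 8))
    mask = np.ones((8, 8, 8), bool)
    disc, n = T.discretize(img, mask, 16)
    assert n == 16
    assert disc.min() == 1 and disc.max() == 16

def test_discretize_levels_monotone_in_intensity(rng):
    img = rng.random(size=(6, 6, 6)) + 0.5
    mask = np.ones((6, 6, 6), bool)
    order = np.argsort(img[mask])
    for transform in (lambda x: x, np.log):
        disc, _ = T.discretize(transform(img), mask, 8)
        levels = disc[mask][order].astype(int)
        assert (np.diff(levels) >= 0).all()
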