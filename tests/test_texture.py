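import numpy as np
import pytest
from skimage.feature import graycomatrix

from cottonvit import (glcm, quantize, seed_texture_matrix, texture_column_names,
                       texture_features)
from cottonvit.calibration import PlateCube


def _brute_glcm(q, levels, offset, symmetric, mask=None):
    """Independent double-loop co-occurrence tally."""
    H, W = q.shape
    dr, dc = offset
    counts = np.zeros((levels, levels))
    for r in range(H):
        for c in range(W):
            r2, c2 = r + dr, c + dc
            if not (0 <= r2 < H and 0 <= c2 < W):
                continue
            if mask is not None and not (mask[r, c] and mask[r2, c2]):
                continue
            counts[q[r, c], q[r2, c2]] += 1
    if symmetric:
        counts = counts + counts.T
    return counts / counts.sum()


def _brute_features(p):
    L = p.shape[0]
    contrast = corr_num = 0.0
    mu_i = sum(i * p[i, j] for i in range(L) for j in range(L))
    mu_j = sum(j * p[i, j] for i in range(L) for j in range(L))
    var_i = sum((i - mu_i) ** 2 * p[i, j] for i in range(L) for j in range(L))
    var_j = sum((j - mu_j) ** 2 * p[i, j] for i in range(L) for j in range(L))
    energy = entropy = 0.0
    for i in range(L):
        for j in range(L):
            contrast += (i - j) ** 2 * p[i, j]
            corr_num += (i - mu_i) * (j - mu_j) * p[i, j]
            energy += p[i, j] ** 2
            if p[i, j] > 0:
                entropy -= p[i, j] * np.log2(p[i, j])
    return contrast, corr_num / np.sqrt(var_i * var_j), energy, entropy


class TestGLCM:
    def test_two_by_two_hand_count(self):
        # two horizontal pairs: (0,0) and (1,1)
        img = np.array([[0, 0], [1, 1]])
        p = glcm(img, levels=2, distance=1, angle=0, symmetric=False)
        np.testing.assert_allclose(p, [[0.5, 0.0], [0.0, 0.5]])

    def test_two_by_two_features(self):
        img = np.array([[0, 0], [1, 1]])
        f = texture_features(glcm(img, levels=2, angle=0, symmetric=False))
        assert f.contrast == pytest.approx(0.0)
        assert f.energy == pytest.approx(0.5)
        assert f.entropy == pytest.approx(1.0)  # one bit: two equal cells

    def test_constant_patch(self):
        p = glcm(np.full((4, 4), 3.7), levels=8)
        assert p[0, 0] == pytest.approx(1.0)
        with pytest.warns(RuntimeWarning, match="correlation"):
            f = texture_features(p)
        assert (f.contrast, f.energy, f.entropy) == (0.0, 1.0, 0.0)
        assert f.correlation == 0.0

    @pytest.mark.parametrize("angle,offset", [(0, (0, 1)), (45, (-1, 1)),
                                              (90, (-1, 0)), (135, (-1, -1))])
    def test_matches_double_loop_oracle(self, rng, angle, offset):
        patch = rng.normal(size=(9, 7))
        for symmetric in (False, True):
            p = glcm(patch, levels=6, angle=angle, symmetric=symmetric)
            q = quantize(patch, 6)
            np.testing.assert_allclose(p, _brute_glcm(q, 6, offset, symmetric))

    def test_masked_pairs_dropped(self, rng):
        patch = rng.normal(size=(8, 8))
        mask = rng.random((8, 8)) > 0.3
        p = glcm(patch, levels=5, mask=mask)
        q = quantize(patch, 5, mask)
        np.testing.assert_allclose(p, _brute_glcm(q, 5, (0, 1), True, mask))

    def test_matches_skimage_on_integer_patch(self, rng):
        q = rng.integers(0, 8, size=(10, 10)).astype(np.uint8)
        p = glcm(q, levels=8, distance=1, angle=0, symmetric=True)
        sk = graycomatrix(q, [1], [0], levels=8, symmetric=True, normed=True)
        np.testing.assert_allclose(p, sk[:, :, 0, 0])

    def test_normalization(self, rng):
        for _ in range(5):
            p = glcm(rng.normal(size=(6, 6)), levels=4)
            assert p.sum() == pytest.approx(1.0, abs=1e-12)

    def test_features_match_brute_force(self, rng):
        p = glcm(rng.normal(size=(12, 10)), levels=8)
        f = texture_features(p)
        contrast, corr, energy, entropy = _brute_features(p)
        assert f.contrast == pytest.approx(contrast)
        assert f.correlation == pytest.approx(corr)
        assert f.energy == pytest.approx(energy)
        assert f.entropy == pytest.approx(entropy)

    def test_gray_offset_invariance(self, rng):
        patch = rng.normal(size=(8, 8))
        f1 = texture_features(glcm(patch, levels=8))
        f2 = texture_features(glcm(patch + 100.0, levels=8))
        np.testing.assert_allclose(f1.as_array(), f2.as_array(), atol=1e-12)

    def test_feature_ranges(self, rng):
        for _ in range(10):
            f = texture_features(glcm(rng.normal(size=(7, 7)), levels=5))
            assert 0 < f.energy <= 1
            assert f.entropy >= 0
            assert f.contrast >= 0
            assert -1 <= f.correlation <= 1

    def test_too_small_patch(self):
        with pytest.raises(ValueError):
            glcm(np.array([[1.0]]), levels=2)


@pytest.fixture(scope="module")
def cube_mask():
    rng = np.random.default_rng(0)
    S = rng.random((20, 20, 12))
    cube = PlateCube(S=S, wavelengths=400.0 + 10.0 * np.arange(12))
    mask = np.zeros((20, 20), dtype=np.uint8)
    mask[2:8, 2:9] = 1
    mask[12:18, 11:18] = 2
    return cube, mask


class TestSeedTextureMatrix:
    def test_four_features_per_band(self, cube_mask):
        cube, mask = cube_mask
        T = seed_texture_matrix(cube, mask, np.arange(10))
        assert T.shape == (2, 40)

    def test_band_permutation_permutes_blocks(self, cube_mask):
        cube, mask = cube_mask
        bands = np.array([0, 3, 7])
        T = seed_texture_matrix(cube, mask, bands)
        Tp = seed_texture_matrix(cube, mask, bands[::-1])
        np.testing.assert_array_equal(Tp, np.hstack([T[:, 8:12], T[:, 4:8], T[:, 0:4]]))

    def test_column_names(self, cube_mask):
        cube, _ = cube_mask
        names = texture_column_names(cube.wavelengths, [0, 2])
        assert names[0] == "400nm_contrast"
        assert names[-1] == "420nm_entropy"
        assert len(names) == 8

    def test_degenerate_seed_named(self, cube_mask):
        cube, _ = cube_mask
        mask = np.zeros((20, 20), dtype=np.uint8)
        mask[0, :5] = 1  # 1-pixel-tall bounding box
        with pytest.raises(ValueError, match="seed 1"):
            seed_texture_matrix(cube, mask, [0])

    def test_bad_band_index(self, cube_mask):
        cube, mask = cube_mask
        with pytest.raises(IndexError):
            seed_texture_matrix(cube, mask, [99])
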