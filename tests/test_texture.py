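import numpy as np
import pytest

from radsig.texture import (
    DIRECTIONS_3D,
    GLCM_NAMES,
    GLRLM_NAMES,
    glcm,
    glcm_features,
    glrlm,
    glrlm_features,
    quantize,
)
from tests.reference import (
    ref_glcm,
    ref_glcm_features,
    ref_glrlm,
    ref_glrlm_features,
    ref_quantize,
)


def _line_roi(levels_1d):
    """Embed a 1D level sequence as a 1x1xN quantized grid (0 = outside)."""
    return np.asarray(levels_1d, dtype=np.int32).reshape(1, 1, -1)


class TestQuantize:
    def test_exact_levels(self):
        vals = np.array([1.0, 2.0, 3.0, 4.0]).reshape(1, 1, 4)
        mask = np.ones_like(vals, dtype=bool)
        levels, q = quantize(vals, mask, n_levels=4)
        np.testing.assert_array_equal(levels.ravel(), [1, 2, 3, 4])
        assert q.n_levels == 4

    def test_max_maps_to_top_level(self):
        rng = np.random.default_rng(0)
        vals = rng.random((6, 6, 6))
        mask = np.ones_like(vals, dtype=bool)
        levels, _ = quantize(vals, mask, n_levels=32)
        assert levels[np.unravel_index(vals.argmax(), vals.shape)] == 32
        assert levels.min() >= 1 and levels.max() <= 32

    @pytest.mark.parametrize("ng", [2, 7, 32])
    def test_level_histogram_counts_roi(self, ng):
        rng = np.random.default_rng(1)
        vals = rng.normal(size=(8, 8, 8))
        mask = rng.random((8, 8, 8)) < 0.5
        levels, _ = quantize(vals, mask, n_levels=ng)
        assert (levels > 0).sum() == mask.sum()
        np.testing.assert_array_equal(levels, ref_quantize(vals, mask, ng))

    def test_constant_roi_rejected(self):
        vals = np.full((4, 4, 4), 2.0)
        with pytest.raises(ValueError, match="constant region"):
            quantize(vals, np.ones_like(vals, dtype=bool), 8)


class TestGLCM:
    def test_single_gray_level(self):
        levels = np.ones((3, 3, 3), dtype=np.int32)
        P = glcm(levels, n_levels=4)
        assert P[0, 0] == pytest.approx(1.0)
        assert P.sum() == pytest.approx(1.0)

    def test_alternating_line_hand_count(self):
        # axial direction only: pairs (1,2)x3 symmetrized -> p(1,2)=p(2,1)=0.5
        levels = _line_roi([1, 2, 1, 2])
        P = glcm(levels, n_levels=2, directions=((0, 0, 1),))
        assert P[0, 1] == pytest.approx(0.5)
        assert P[1, 0] == pytest.approx(0.5)
        assert P[0, 0] == 0.0 and P[1, 1] == 0.0

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_normalized_and_symmetric(self, seed):
        rng = np.random.default_rng(seed)
        vals = rng.normal(size=(7, 7, 7))
        mask = rng.random((7, 7, 7)) < 0.6
        mask[3, 3, 3] = True
        levels, _ = quantize(vals, mask, 8)
        P = glcm(levels, 8)
        assert P.sum() == pytest.approx(1.0, abs=1e-12)
        np.testing.assert_allclose(P, P.T, atol=1e-12)

    def test_matches_brute_force(self):
        rng = np.random.default_rng(3)
        vals = rng.normal(size=(6, 6, 6))
        mask = rng.random((6, 6, 6)) < 0.7
        levels, _ = quantize(vals, mask, 5)
        np.testing.assert_allclose(glcm(levels, 5), ref_glcm(levels, 5), atol=1e-12)

    def test_isolated_voxel_has_no_pairs(self):
        levels = np.zeros((5, 5, 5), dtype=np.int32)
        levels[2, 2, 2] = 1
        with pytest.raises(ValueError, match="no co-occurrences"):
            glcm(levels, 2)


class TestGLCMFeatures:
    def test_degenerate_single_cell(self):
        P = np.zeros((4, 4))
        P[0, 0] = 1.0
        f = glcm_features(P)
        assert f["Energy"] == 1.0
        assert f["Entropy"] == 0.0
        assert f["Contrast"] == 0.0
        assert f["Maximum Probability"] == 1.0
        assert f["Cluster Tendency"] == 0.0
        assert f["Correlation"] == 0.0  # zero marginal variance convention

    def test_uniform_matrix(self):
        P = np.full((4, 4), 1.0 / 16.0)
        f = glcm_features(P)
        assert f["Entropy"] == pytest.approx(4.0)
        assert f["Energy"] == pytest.approx(1.0 / 16.0)

    def test_two_level_hand_computation(self):
        P = np.array([[0.0, 0.5], [0.5, 0.0]])
        f = glcm_features(P)
        assert f["Contrast"] == pytest.approx(1.0)
        assert f["Correlation"] == pytest.approx(-1.0)
        assert f["Dissimilarity"] == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", [0, 1])
    def test_all_22_match_reference(self, seed):
        rng = np.random.default_rng(seed)
        C = rng.random((6, 6))
        P = (C + C.T) / (C + C.T).sum()
        ours = glcm_features(P)
        ref = ref_glcm_features(P)
        assert set(ours) == set(GLCM_NAMES)
        for name in GLCM_NAMES:
            assert ours[name] == pytest.approx(ref[name], rel=1e-9), name


class TestGLRLM:
    def test_constant_line_single_run(self):
        levels = _line_roi([3, 3, 3, 3])
        R = glrlm(levels, n_levels=4, directions=((0, 0, 1),))
        assert R[2, 3] == 1.0
        assert R.sum() == 1.0

    def test_two_runs_hand_count(self):
        levels = _line_roi([1, 1, 2, 2])
        R = glrlm(levels, n_levels=2, directions=((0, 0, 1),))
        assert R[0, 1] == 1.0 and R[1, 1] == 1.0
        assert R.sum() == 2.0

    @pytest.mark.parametrize("d", DIRECTIONS_3D)
    def test_run_cover_conservation_per_direction(self, d):
        rng = np.random.default_rng(11)
        vals = rng.normal(size=(6, 7, 8))
        mask = rng.random((6, 7, 8)) < 0.6
        mask[0, 0, 0] = True
        levels, _ = quantize(vals, mask, 4)
        R = glrlm(levels, 4, directions=(d,))
        lengths = np.arange(1, R.shape[1] + 1)
        assert (R * lengths).sum() == mask.sum()

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        vals = rng.normal(size=(6, 6, 6))
        mask = rng.random((6, 6, 6)) < 0.7
        mask[3, 3, 3] = True
        levels, _ = quantize(vals, mask, 4)
        np.testing.assert_array_equal(glrlm(levels, 4), ref_glrlm(levels, 4))


class TestGLRLMFeatures:
    def test_all_runs_length_one(self):
        R = np.zeros((3, 4))
        R[0, 0] = 5.0
        R[2, 0] = 5.0
        f = glrlm_features(R, n_voxels=10, n_directions=1)
        assert f["Short Run Emphasis"] == 1.0
        assert f["Long Run Emphasis"] == 1.0
        assert f["Run Percentage"] == 1.0

    def test_single_long_run(self):
        R = np.zeros((2, 4))
        R[0, 3] = 1.0  # one run of level 1, length 4
        f = glrlm_features(R, n_voxels=4, n_directions=1)
        assert f["Short Run Emphasis"] == pytest.approx(1.0 / 16.0)
        assert f["Long Run Emphasis"] == pytest.approx(16.0)
        assert f["Low Gray Level Run Emphasis"] == pytest.approx(1.0)

    def test_sre_lre_bounds(self):
        rng = np.random.default_rng(2)
        R = rng.integers(0, 5, size=(6, 9)).astype(float)
        R[0, 0] += 1
        f = glrlm_features(R, n_voxels=int((R * np.arange(1, 10)).sum()))
        assert f["Short Run Emphasis"] <= 1.0
        assert f["Long Run Emphasis"] >= 1.0

    def test_all_11_match_reference(self):
        rng = np.random.default_rng(4)
        vals = rng.normal(size=(7, 7, 7))
        mask = rng.random((7, 7, 7)) < 0.5
        mask[3, 3, 3] = True
        levels, _ = quantize(vals, mask, 5)
        R = glrlm(levels, 5)
        n_vox = int(mask.sum())
        ours = glrlm_features(R, n_vox)
        ref = ref_glrlm_features(R, n_vox)
        assert set(ours) == set(GLRLM_NAMES)
        for name in GLRLM_NAMES:
            assert ours[name] == pytest.approx(ref[name], rel=1e-9), name
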