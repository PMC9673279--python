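"""GLCM/GLRLM construction and feature formulas against brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tmjoa.texture import (
    DIRECTIONS_13,
    GLCM_FEATURES,
    GLRLM_FEATURES,
    TextureParams,
    build_glcm,
    build_glrlm,
    glcm_features,
    glrlm_features,
    quantize,
    texture_vector,
)
from oracles import (
    glcm_features_oracle,
    glcm_oracle,
    glrlm_features_oracle,
    glrlm_oracle,
)


class TestQuantize:
    @pytest.mark.parametrize(
        "value,expected_bin",
        [(-1000, 1), (2500, 10), (3000, 10), (-2000, 1), (-651, 1), (-649, 2)],
    )
    def test_range_endpoints_and_clipping(self, value, expected_bin):
        assert quantize(np.full((1, 1, 1), float(value)))[0, 0, 0] == expected_bin

    def test_uniform_ramp_fills_bins_evenly(self):
        # 1000 values evenly spaced over the range -> 100 per bin.
        vals = np.linspace(-1000, 2500, 1000, endpoint=False).reshape(10, 10, 10)
        binned = quantize(vals)
        occupancy = np.bincount(binned.ravel(), minlength=11)[1:]
        assert np.all(np.abs(occupancy - 100) <= 1)


class TestGLCM:
    def test_constant_block_concentrates_diagonal(self):
        binned = np.full((4, 4, 4), 7)
        m = build_glcm(binned)
        assert m.p[6, 6] == 1.0
        assert m.counts.sum() == m.counts[6, 6]

    def test_two_voxel_enumeration(self):
        binned = np.array([1, 2]).reshape(2, 1, 1)
        m = build_glcm(binned, TextureParams(neighborhood_radius=1))
        expected = np.zeros((10, 10), dtype=np.int64)
        expected[0, 1] = expected[1, 0] = 1
        assert np.array_equal(m.counts, expected)
        assert m.p[0, 1] == 0.5 and m.p[1, 0] == 0.5

    @pytest.mark.parametrize("radius", [1, 2, 4])
    def test_matches_brute_force_on_random_blocks(self, rng, radius):
        for _ in range(25):
            binned = rng.integers(1, 11, size=(3, 3, 3))
            params = TextureParams(neighborhood_radius=radius)
            ours = build_glcm(binned, params).counts
            assert np.array_equal(ours, glcm_oracle(binned, radius, 10))

    def test_symmetry_and_normalization(self, rng):
        binned = rng.integers(1, 11, size=(5, 5, 5))
        m = build_glcm(binned)
        assert np.array_equal(m.counts, m.counts.T)
        assert np.isclose(m.p.sum(), 1.0)

    def test_empty_block_rejected(self):
        with pytest.raises(ValueError):
            build_glcm(np.empty((0, 0, 0), dtype=int))


class TestGLCMFeatures:
    def test_constant_block_limit_values(self):
        feats = glcm_features(build_glcm(np.full((3, 3, 3), 5)))
        assert feats["Energy"] == 1.0
        assert feats["Entropy"] == 0.0
        assert feats["Inertia"] == 0.0
        assert feats["InverseDifferenceMoment"] == 1.0
        assert feats["degenerate"] is True
        assert feats["Correlation"] == 0.0
        assert feats["HaralickCorrelation"] == 0.0

    def test_uniform_distribution_values(self):
        from tmjoa.texture import CooccurrenceMatrix

        m = CooccurrenceMatrix(counts=np.ones((10, 10), dtype=np.int64), radius=1)
        feats = glcm_features(m)
        assert np.isclose(feats["Energy"], 0.01)
        assert np.isclose(feats["Entropy"], np.log2(100))

    def test_all_features_match_literal_formula_oracle(self, rng):
        for _ in range(50):
            binned = rng.integers(1, 11, size=(3, 3, 3))
            m = build_glcm(binned, TextureParams(neighborhood_radius=1))
            ours = glcm_features(m)
            expected = glcm_features_oracle(m.p)
            for name in GLCM_FEATURES:
                assert ours[name] == pytest.approx(expected[name], abs=1e-10), name


class TestGLRLM:
    def test_constant_cube_axis_runs(self):
        binned = np.full((4, 4, 4), 3)
        axes = ((1, 0, 0), (0, 1, 0), (0, 0, 1))
        m = build_glrlm(binned, directions=axes)
        # every axis line is one run of length 4: 16 lines x 3 directions
        assert m.counts[2, 3] == 48
        assert m.n_runs == 48

    def test_alternating_pattern_all_runs_length_one(self):
        line = np.tile([1, 2], 8).reshape(16, 1, 1)
        m = build_glrlm(line, directions=((1, 0, 0),))
        assert m.counts[:, 1:].sum() == 0
        assert m.n_runs == 16

    def test_matches_brute_force_on_random_blocks(self, rng):
        for _ in range(25):
            binned = rng.integers(1, 11, size=(3, 3, 3))
            ours = build_glrlm(binned).counts
            expected = glrlm_oracle(binned, DIRECTIONS_13, 10, ours.shape[1])
            assert np.array_equal(ours, expected)

    def test_voxel_accounting_invariant(self, rng):
        binned = rng.integers(1, 11, size=(6, 5, 4))
        m = build_glrlm(binned)
        lengths = np.arange(1, m.counts.shape[1] + 1)
        assert (m.counts * lengths).sum() == m.n_voxels * m.n_directions


class TestGLRLMFeatures:
    def test_all_unit_runs_extremes(self):
        line = np.tile([1, 2], 8).reshape(16, 1, 1)
        feats = glrlm_features(build_glrlm(line, directions=((1, 0, 0),)))
        assert feats["ShortRunEmphasis"] == 1.0
        assert feats["LongRunEmphasis"] == 1.0

    def test_single_cell_matrix_values(self):
        binned = np.full((4, 1, 1), 10)
        feats = glrlm_features(build_glrlm(binned, directions=((1, 0, 0),)))
        assert feats["HighGreyLevelRunEmphasis"] == 100.0
        assert feats["ShortRunEmphasis"] == pytest.approx(1 / 16)

    def test_all_features_match_literal_formula_oracle(self, rng):
        for _ in range(50):
            binned = rng.integers(1, 11, size=(3, 3, 3))
            m = build_glrlm(binned)
            ours = glrlm_features(m)
            expected = glrlm_features_oracle(m.counts)
            for name in GLRLM_FEATURES:
                assert ours[name] == pytest.approx(expected[name], abs=1e-10), name


class TestInvariants:
    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 2**32 - 1))
    def test_sre_le_one_le_lre(self, seed):
        rng = np.random.default_rng(seed)
        binned = rng.integers(1, 4, size=(4, 4, 4))
        feats = glrlm_features(build_glrlm(binned))
        assert feats["ShortRunEmphasis"] <= 1.0 + 1e-12 <= feats["LongRunEmphasis"] + 2e-12

    def test_bin_preserving_intensity_transform_leaves_features_fixed(self, rng):
        block = rng.uniform(-1000, 2500, size=(6, 6, 6))
        binned = quantize(block)
        # Snap every voxel to its bin centre: same bins, different intensities.
        centres = -1000 + (binned - 0.5) * 350.0
        v1 = texture_vector(block)
        v2 = texture_vector(centres)
        for name, val in v1.items():
            assert val == pytest.approx(v2[name], rel=1e-12), name

    def test_texture_vector_has_18_features(self, rng):
        v = texture_vector(rng.uniform(-1000, 2500, size=(5, 5, 5)))
        assert len(v) == 18
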