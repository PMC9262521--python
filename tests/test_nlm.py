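"""Non-local means core: oracle equivalence, weight laws, limit behaviour."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from echodenoise import FULL, GrayImage, NLMParams, compute_weights, nlm_denoise, patch_distance
from oracles import (
    brute_nlm,
    brute_patch_distance,
    brute_weights,
    brute_window_mean,
)


class TestPatchDistance:
    def test_constant_image_zero(self):
        img = GrayImage(np.full((6, 6), 0.4))
        assert patch_distance(img, (2, 2), (4, 1), patch_radius=1, eta=0.5) == 0.0

    def test_same_pixel_zero(self, random_image):
        assert patch_distance(random_image, (3, 3), (3, 3), patch_radius=2, eta=1.0) == 0.0

    def test_symmetry(self, random_image):
        a = patch_distance(random_image, (1, 2), (6, 5), patch_radius=2, eta=1.0)
        b = patch_distance(random_image, (6, 5), (1, 2), patch_radius=2, eta=1.0)
        assert a == pytest.approx(b, abs=1e-15)
        assert a >= 0.0

    def test_matches_double_loop_oracle(self, rng):
        img = rng.uniform(0, 1, (5, 5))
        gi = GrayImage(img)
        for x, y in [((0, 0), (4, 4)), ((2, 2), (1, 3)), ((0, 4), (3, 0))]:
            expected = brute_patch_distance(img, x, y, r=1, eta=0.5)
            got = patch_distance(gi, x, y, patch_radius=1, eta=0.5)
            assert got == pytest.approx(expected, abs=1e-12)

    def test_out_of_bounds_rejected(self, random_image):
        with pytest.raises(ValueError):
            patch_distance(random_image, (0, 0), (9, 0), patch_radius=1)

    def test_bad_eta_rejected(self, random_image):
        with pytest.raises(ValueError):
            patch_distance(random_image, (0, 0), (1, 1), patch_radius=1, eta=0.0)


class TestComputeWeights:
    def test_constant_image_uniform(self):
        img = GrayImage(np.full((7, 7), 0.6))
        wf = compute_weights(img, (3, 3), NLMParams(1, 2, alpha=0.3, eta=0.5))
        assert len(wf.weights) == 25
        np.testing.assert_allclose(wf.weights, 1 / 25, atol=1e-14)

    def test_alpha_to_zero_concentrates_on_center(self, rng):
        img = GrayImage(rng.uniform(0, 1, (7, 7)))
        wf = compute_weights(img, (3, 3), NLMParams(1, 2, alpha=1e-8, eta=0.5))
        center = np.flatnonzero((wf.coords[:, 0] == 3) & (wf.coords[:, 1] == 3))[0]
        assert wf.weights[center] == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("mode", ["as_printed", "max_neighbor"])
    def test_matches_brute_force(self, rng, mode):
        img = rng.uniform(0, 1, (7, 7))
        gi = GrayImage(img)
        params = NLMParams(1, 2, alpha=0.3, eta=0.5, self_weight_mode=mode)
        for x in [(0, 0), (3, 3), (6, 2)]:
            coords, expected = brute_weights(img, x, 1, 2, 0.3, 0.5, mode)
            wf = compute_weights(gi, x, params)
            assert [tuple(c) for c in wf.coords] == coords
            np.testing.assert_allclose(wf.weights, expected, atol=1e-12)

    def test_weights_sum_to_one_everywhere(self, phantom32):
        params = NLMParams(patch_radius=2, search_radius=4, alpha=0.2)
        for x0 in range(0, 32, 5):
            for x1 in range(0, 32, 5):
                wf = compute_weights(phantom32, (x0, x1), params)
                assert abs(wf.weights.sum() - 1.0) < 1e-12


class TestDenoise:
    def test_constant_image_fixed_point(self):
        img = GrayImage(np.full((10, 10), 0.3))
        out = nlm_denoise(img, NLMParams(1, 3, alpha=0.5))
        np.testing.assert_array_equal(out.values, img.values)

    @pytest.mark.parametrize("mode", ["as_printed", "max_neighbor"])
    @pytest.mark.parametrize("shape", [(5, 5), (9, 9), (6, 9)])
    def test_windowed_matches_brute_force(self, rng, shape, mode):
        img = rng.uniform(0, 1, shape)
        expected = brute_nlm(img, 1, 2, 0.3, 0.5, mode)
        got = nlm_denoise(
            GrayImage(img), NLMParams(1, 2, alpha=0.3, eta=0.5, self_weight_mode=mode)
        )
        np.testing.assert_allclose(got.values, expected, atol=1e-10)

    @pytest.mark.parametrize("mode", ["as_printed", "max_neighbor"])
    def test_full_matches_brute_force(self, rng, mode):
        img = rng.uniform(0, 1, (8, 7))
        expected = brute_nlm(img, 1, "full", 0.3, 0.5, mode)
        got = nlm_denoise(
            GrayImage(img), NLMParams(1, FULL, alpha=0.3, eta=0.5, self_weight_mode=mode)
        )
        np.testing.assert_allclose(got.values, expected, atol=1e-10)

    def test_window_saturation_equals_full(self, rng):
        img = GrayImage(rng.uniform(0, 1, (12, 10)))
        windowed = nlm_denoise(img, NLMParams(1, 12, alpha=0.3, eta=0.5))
        full = nlm_denoise(img, NLMParams(1, FULL, alpha=0.3, eta=0.5))
        np.testing.assert_array_equal(windowed.values, full.values)

    def test_alpha_small_limit_identity(self, rng):
        img = GrayImage(rng.uniform(0, 1, (10, 10)))
        out = nlm_denoise(img, NLMParams(1, 3, alpha=1e-6, eta=0.5))
        assert np.abs(out.values - img.values).max() < 1e-6

    def test_alpha_large_limit_window_mean(self, rng):
        img = rng.uniform(0, 1, (10, 10))
        out = nlm_denoise(GrayImage(img), NLMParams(1, 3, alpha=1e6, eta=0.5))
        for x in [(0, 0), (5, 4), (9, 9)]:
            assert out.values[x] == pytest.approx(brute_window_mean(img, x, 3), abs=1e-6)

    def test_default_alpha_estimated_from_noise(self, rng):
        # noisy image: the automatic alpha should smooth, not pass through
        img = GrayImage(np.clip(0.5 + 0.1 * rng.standard_normal((32, 32)), 0, 1))
        out = nlm_denoise(img, NLMParams(patch_radius=2, search_radius=5))
        assert out.values.std() < img.values.std()

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            NLMParams(patch_radius=-1)
        with pytest.raises(ValueError):
            NLMParams(patch_radius=3, search_radius=1)
        with pytest.raises(ValueError):
            NLMParams(alpha=0.0)
        with pytest.raises(ValueError):
            NLMParams(self_weight_mode="median")


class TestProperties:
    @settings(max_examples=15, deadline=None, derandomize=True)
    @given(
        hnp.arrays(
            np.float64,
            st.tuples(st.integers(3, 8), st.integers(3, 8)),
            elements=st.floats(0.0, 1.0, allow_nan=False),
        )
    )
    def test_output_is_convex_combination(self, arr):
        img = GrayImage(arr)
        out = nlm_denoise(img, NLMParams(1, 2, alpha=0.4, eta=0.5))
        assert out.values.min() >= arr.min() - 1e-12
        assert out.values.max() <= arr.max() + 1e-12

    @settings(max_examples=10, deadline=None, derandomize=True)
    @given(
        hnp.arrays(
            np.float64,
            st.tuples(st.integers(4, 7), st.integers(4, 7)),
            elements=st.floats(0.0, 1.0, allow_nan=False),
        )
    )
    def test_transpose_equivariance(self, arr):
        params = NLMParams(1, 2, alpha=0.4, eta=0.5)
        direct = nlm_denoise(GrayImage(arr), params).values
        transposed = nlm_denoise(GrayImage(arr.T.copy()), params).values.T
        np.testing.assert_allclose(direct, transposed, atol=1e-12)
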