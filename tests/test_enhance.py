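"""Core enhancement math: windowed statistics, gain laws, decomposition,
staged application. Oracles are brute-force double loops and direct kernel
evaluation; identities are exact by construction."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from sonoenhance.enhance import (
    GainScheme,
    Stage,
    StagePlan,
    WindowSpec,
    default_plan,
    enhance_local,
    enhance_unsharp,
    gain_field,
    gaussian_decompose,
    local_mean_variance,
    run_stages,
)

from conftest import brute_local_stats, gaussian_kernel_1d

THREE_BY_THREE = np.arange(1.0, 10.0).reshape(3, 3)

small_images = hnp.arrays(
    np.float64,
    st.tuples(st.integers(3, 16), st.integers(3, 16)),
    elements=st.floats(0, 1, width=32, allow_nan=False),
)


class TestLocalStats:
    def test_constant_image(self):
        img = np.full((12, 15), 0.5)
        stats = local_mean_variance(img, WindowSpec(2))
        np.testing.assert_allclose(stats.mean, 0.5, atol=1e-12)
        np.testing.assert_allclose(stats.variance, 0.0, atol=1e-12)

    def test_center_pixel_by_hand(self):
        stats = local_mean_variance(THREE_BY_THREE, WindowSpec(1))
        assert stats.mean[1, 1] == pytest.approx(5.0, abs=1e-12)
        assert stats.variance[1, 1] == pytest.approx(60.0 / 9.0, abs=1e-12)

    def test_corner_pixel_matches_padded_oracle(self):
        mean, var = brute_local_stats(THREE_BY_THREE, 1)
        stats = local_mean_variance(THREE_BY_THREE, WindowSpec(1))
        assert stats.mean[0, 0] == pytest.approx(mean[0, 0], abs=1e-10)
        assert stats.variance[0, 0] == pytest.approx(var[0, 0], abs=1e-10)

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(img=small_images)
    def test_matches_brute_force_oracle(self, img):
        n = 1
        mean, var = brute_local_stats(img, n)
        stats = local_mean_variance(img, WindowSpec(n))
        np.testing.assert_allclose(stats.mean, mean, atol=1e-10)
        np.testing.assert_allclose(stats.variance, var, atol=1e-10)

    def test_window_larger_than_image_rejected(self):
        with pytest.raises(ValueError):
            local_mean_variance(np.zeros((5, 5)), WindowSpec(3))

    def test_variance_never_negative(self, rng):
        img = rng.random((30, 30)) * 1e-8  # cancellation-prone scale
        stats = local_mean_variance(img, WindowSpec(3))
        assert (stats.variance >= 0).all()


class TestGainField:
    def test_flat_image_hits_cap(self):
        stats = local_mean_variance(np.full((9, 9), 0.4), WindowSpec(2))
        gain = gain_field(stats, GainScheme(mode="adaptive", D=0.5, g_max=5.0))
        np.testing.assert_array_equal(gain, 5.0)

    def test_constant_unit_gain(self):
        stats = local_mean_variance(np.zeros((7, 7)), WindowSpec(1))
        gain = gain_field(stats, GainScheme(mode="constant", C=1.0))
        np.testing.assert_array_equal(gain, 1.0)

    def test_adaptive_unit_gain_at_center_sigma(self):
        img = np.zeros((3, 3))
        img[1, 1] = 0.9
        stats = local_mean_variance(img, WindowSpec(1))
        sigma_center = np.sqrt(stats.variance[1, 1])
        gain = gain_field(stats, GainScheme(mode="adaptive", D=sigma_center, g_max=10.0))
        assert gain[1, 1] == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize(
        "bad",
        [
            dict(mode="constant", C=0.5),
            dict(mode="adaptive", D=0.0),
            dict(mode="constant", g_max=0.5),
            dict(mode="adaptive", D=1.0, epsilon=0.0),
            dict(mode="mystery"),
        ],
    )
    def test_invalid_schemes_rejected(self, bad):
        with pytest.raises(ValueError):
            GainScheme(**bad)


class TestEnhanceLocal:
    def test_unit_gain_is_exact_identity(self, rng):
        img = rng.random((20, 20))
        out = enhance_local(img, WindowSpec(2), GainScheme(mode="constant", C=1.0))
        assert np.array_equal(out, img)

    def test_hand_computed_center_and_clip(self):
        img = np.zeros((3, 3))
        img[1, 1] = 0.9
        scheme = GainScheme(mode="constant", C=2.0)
        pre = enhance_local(img, WindowSpec(1), scheme, clip=False)
        assert pre[1, 1] == pytest.approx(0.1 + 2 * (0.9 - 0.1), abs=1e-12)
        clipped = enhance_local(img, WindowSpec(1), scheme)
        assert clipped[1, 1] == 1.0

    def test_deviation_monotone_in_gain(self, rng):
        img = rng.random((16, 16))
        window = WindowSpec(2)
        m = local_mean_variance(img, window).mean
        prev = None
        for C in (1.0, 1.5, 2.0, 4.0):
            out = enhance_local(img, window, GainScheme(mode="constant", C=C), clip=False)
            dev = np.abs(out - m)
            if prev is not None:
                assert (dev >= prev - 1e-12).all()
            prev = dev


class TestGaussianDecompose:
    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(img=small_images, sigma=st.floats(0.5, 3.0))
    def test_reconstruction_identity(self, img, sigma):
        low, high = gaussian_decompose(img, sigma)
        np.testing.assert_allclose(low + high, img, atol=1e-12)

    def test_constant_image_has_zero_high_band(self):
        low, high = gaussian_decompose(np.full((10, 10), 0.8), 2.0)
        np.testing.assert_allclose(high, 0.0, atol=1e-12)

    def test_impulse_low_band_is_kernel(self):
        img = np.zeros((33, 33))
        img[16, 16] = 1.0
        low, _ = gaussian_decompose(img, 1.0)
        k = gaussian_kernel_1d(1.0)
        r = len(k) // 2
        expected = np.zeros_like(img)
        expected[16 - r : 16 + r + 1, 16 - r : 16 + r + 1] = np.outer(k, k)
        np.testing.assert_allclose(low, expected, atol=1e-12)

    def test_nonpositive_sigma_rejected(self):
        with pytest.raises(ValueError):
            gaussian_decompose(np.zeros((5, 5)), 0.0)


class TestEnhanceUnsharp:
    def test_unit_gain_is_exact_identity(self, rng):
        img = rng.random((18, 18))
        out = enhance_unsharp(img, 1.5, GainScheme(mode="constant", C=1.0))
        assert np.array_equal(out, img)

    def test_constant_image_fixed_point(self):
        img = np.full((12, 12), 0.6)
        out = enhance_unsharp(img, 2.0, GainScheme(mode="adaptive", D=0.3))
        np.testing.assert_allclose(out, img, atol=1e-12)

    def test_impulse_linear_combination_oracle(self):
        img = np.zeros((33, 33))
        img[16, 16] = 0.5
        low, high = gaussian_decompose(img, 1.0)
        out = enhance_unsharp(img, 1.0, GainScheme(mode="constant", C=2.0), clip=False)
        np.testing.assert_allclose(out, low + 2.0 * high, atol=1e-12)


class TestStagePlans:
    def test_all_identity_plan_is_identity(self, rng):
        img = rng.random((24, 24))
        plan = StagePlan(
            (
                Stage("local_stats", GainScheme(mode="constant", C=1.0)),
                Stage("gaussian_unsharp", GainScheme(mode="constant", C=1.0), sigma=2.0),
            )
        )
        out, snaps = run_stages(img, plan)
        assert np.array_equal(out, img)
        assert len(snaps) == 2

    def test_single_stage_plan_equals_direct_call(self, rng):
        img = rng.random((20, 20))
        stage = Stage("local_stats", GainScheme(mode="adaptive", D=0.05), WindowSpec(2))
        out, _ = run_stages(img, StagePlan((stage,)))
        np.testing.assert_array_equal(out, stage.apply(img))

    def test_empty_plan_rejected(self):
        with pytest.raises(ValueError):
            StagePlan(())

    def test_default_plan_shape(self):
        plan = default_plan()
        assert [s.operator for s in plan.stages] == ["local_stats", "gaussian_unsharp"]


@settings(deadline=None, max_examples=30, derandomize=True)
@given(img=small_images, d=st.floats(1e-3, 10.0), g_max=st.floats(1.0, 8.0))
def test_gain_never_exceeds_cap(img, d, g_max):
    stats = local_mean_variance(img, WindowSpec(1))
    gain = gain_field(stats, GainScheme(mode="adaptive", D=d, g_max=g_max))
    assert np.isfinite(gain).all()
    assert (gain > 0).all() and (gain <= g_max + 1e-12).all()
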