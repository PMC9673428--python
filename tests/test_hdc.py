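"""Dilated convolution primitive and HDC schedule validation."""

import itertools
import math

import numpy as np
import pytest

from scunet.hdc import (FilterKernel, HDCSchedule, HDCGroup,
                        ScheduleInvalidError, dilated_conv2d,
                        validate_schedule, ABLATION_SCHEDULE)


def brute_force_dilated_conv(image, kernel, rate, padding):
    """Direct double-loop evaluation of (F *_l k)(p) = sum F(s) k(t), s+l*t=p."""
    k = kernel.shape[0]
    r = k // 2
    h, w = image.shape
    padded = np.zeros((h + 2 * padding, w + 2 * padding))
    padded[padding:padding + h, padding:padding + w] = image
    hp, wp = padded.shape
    oh, ow = hp - rate * (k - 1), wp - rate * (k - 1)
    out = np.zeros((oh, ow))
    for y in range(oh):
        for x in range(ow):
            acc = 0.0
            for ty in range(-r, r + 1):
                for tx in range(-r, r + 1):
                    acc += (padded[y + rate * (ty + r), x + rate * (tx + r)]
                            * kernel[ty + r, tx + r])
            out[y, x] = acc
    return out


class TestDilatedConv:
    def test_delta_kernel_is_identity(self):
        img = np.arange(36.0).reshape(6, 6)
        delta = np.zeros((3, 3))
        delta[1, 1] = 1.0
        out = dilated_conv2d(img, delta, rate=1, padding=1)
        np.testing.assert_allclose(out, img)

    def test_zero_input_gives_zero_output(self):
        out = dilated_conv2d(np.zeros((8, 8)), np.ones((3, 3)), rate=3, padding=3)
        assert np.all(out == 0)

    def test_rate2_center_value_matches_offset_sum(self):
        """Centre output of a rate-2 conv samples offsets {-2, 0, 2}^2."""
        img = np.arange(1.0, 26.0).reshape(5, 5)
        out = dilated_conv2d(img, np.ones((3, 3)), rate=2, padding=2)
        expected_center = sum(img[2 + dy, 2 + dx]
                              for dy in (-2, 0, 2) for dx in (-2, 0, 2))
        assert out.shape == (5, 5)
        assert out[2, 2] == pytest.approx(expected_center)

    @pytest.mark.parametrize("rate", [1, 2, 3])
    def test_matches_double_loop_oracle(self, rate):
        rng = np.random.default_rng(42 + rate)
        for _ in range(34):  # ~100 cases over the three rates
            h, w = rng.integers(2 * rate + 1, 9, size=2)
            img = rng.standard_normal((h, w))
            kernel = rng.standard_normal((3, 3))
            pad = rate
            got = dilated_conv2d(img, kernel, rate=rate, padding=pad)
            want = brute_force_dilated_conv(img, kernel, rate, pad)
            np.testing.assert_allclose(got, want, atol=1e-5)

    def test_filter_kernel_validation(self):
        with pytest.raises(ValueError):
            FilterKernel(radius=1, weights=np.ones((5, 5)))
        with pytest.raises(ValueError):
            FilterKernel(radius=1, weights=np.full((3, 3), np.nan))
        fk = FilterKernel(radius=1, weights=np.eye(3))
        out = dilated_conv2d(np.ones((5, 5)), fk, rate=1, padding=1)
        assert out.shape == (5, 5)

    def test_invalid_arguments(self):
        img = np.ones((5, 5))
        with pytest.raises(ValueError):
            dilated_conv2d(img, np.ones((3, 3)), rate=0, padding=1)
        with pytest.raises(ValueError):
            dilated_conv2d(img, np.ones((3, 3)), rate=4, padding=0)

    def test_channelwise_application(self):
        img = np.stack([np.ones((6, 6)), 2 * np.ones((6, 6))])
        out = dilated_conv2d(img, np.ones((3, 3)) / 9.0, rate=1, padding=1)
        assert out.shape == (2, 6, 6)
        np.testing.assert_allclose(out[1, 2:4, 2:4], 2.0)


def coverage_offsets(rates, kernel_size=3):
    """All 1-D offsets reachable by stacking dilated kernels of these rates."""
    half = (kernel_size - 1) // 2
    taps = range(-half, half + 1)
    cover = {0}
    for r in rates:
        cover = {c + r * t for c in cover for t in taps}
    return sorted(cover)


class TestScheduleValidation:
    def test_default_rates_are_valid(self):
        report = validate_schedule(HDCSchedule(kernel_size=3, rates=(1, 2, 3)))
        assert report.m_values[2] == 3          # M_n = r_n
        assert report.m_values[1] == 2          # max[3-4, 3-2(3-2), 2]
        assert report.gcd_of_rates == 1
        assert report.valid

    def test_common_factor_rates_invalid(self):
        report = validate_schedule(HDCSchedule(kernel_size=3, rates=(2, 4, 8)))
        assert report.gcd_of_rates == 2
        assert not report.valid
        assert any("gcd" in r for r in report.reasons)

    def test_large_top_rate_invalid_by_m2(self):
        report = validate_schedule(HDCSchedule(kernel_size=3, rates=(1, 2, 9)))
        assert report.m_values[2] == 9          # M_n = r_n
        assert report.m_values[1] == 5          # M_2 = max[9-4, 9-14, 2] = 5
        assert not report.valid
        assert any("M_2" in r for r in report.reasons)

    def test_ablation_preset_is_valid(self):
        assert ABLATION_SCHEDULE.rates == (2, 3, 4)
        assert ABLATION_SCHEDULE.paddings == (2, 3, 4)
        assert validate_schedule(ABLATION_SCHEDULE).valid

    def test_single_rate_rejected(self):
        with pytest.raises(ValueError):
            validate_schedule(HDCSchedule(kernel_size=3, rates=(2,)))

    def test_mn_equals_last_rate_property(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            rates = tuple(int(r) for r in rng.integers(1, 10, size=3))
            report = validate_schedule(HDCSchedule(rates=rates))
            assert report.m_values[-1] == rates[-1]

    def test_exhaustive_triples_against_coverage_oracle(self):
        """M_2 upper-bounds the largest hole left by stacking layers 2..n,
        exhaustively over rate triples with entries <= 6; valid schedules
        starting at rate 1 leave no hole at all."""
        for rates in itertools.product(range(1, 7), repeat=3):
            report = validate_schedule(HDCSchedule(kernel_size=3, rates=rates))
            assert report.gcd_of_rates == math.gcd(*rates)
            tail_gap = int(np.diff(coverage_offsets(rates[1:])).max())
            assert tail_gap <= report.m_values[1], rates
            if report.valid and rates[0] == 1:
                full_gap = int(np.diff(coverage_offsets(rates)).max())
                assert full_gap == 1, rates


class TestHDCGroup:
    def test_output_channels_and_size_preserved(self):
        rng = np.random.default_rng(0)
        group = HDCGroup(1, 8, rng=rng)
        out = group(np.random.default_rng(1).random((1, 1, 32, 32),
                                                    dtype=np.float32))
        assert out.data.shape == (1, 8, 32, 32)

    def test_relu_nonnegative_output(self):
        group = HDCGroup(2, 4, rng=np.random.default_rng(3))
        out = group(np.random.default_rng(4).standard_normal((2, 2, 16, 16)))
        assert out.data.min() >= 0

    def test_deterministic_given_seed(self):
        x = np.random.default_rng(5).random((1, 1, 16, 16), dtype=np.float32)
        a = HDCGroup(1, 4, rng=np.random.default_rng(7))(x).data
        b = HDCGroup(1, 4, rng=np.random.default_rng(7))(x).data
        np.testing.assert_array_equal(a, b)

    def test_invalid_schedule_rejected_unless_overridden(self):
        bad = HDCSchedule(kernel_size=3, rates=(2, 4, 8))
        with pytest.raises(ScheduleInvalidError):
            HDCGroup(1, 4, bad, rng=np.random.default_rng(0))
        group = HDCGroup(1, 4, bad, rng=np.random.default_rng(0),
                         override_invalid=True)
        out = group(np.ones((1, 1, 32, 32), dtype=np.float32))
        assert out.data.shape == (1, 4, 32, 32)

    @pytest.mark.parametrize("size", [16, 32, 48])
    def test_spatial_preservation_across_sizes(self, size):
        group = HDCGroup(1, 3, rng=np.random.default_rng(1))
        out = group(np.ones((1, 1, size, size), dtype=np.float32))
        assert out.data.shape[2:] == (size, size)
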