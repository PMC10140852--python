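"""Unit, oracle and property tests for the monitoring algorithm."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from decellmon.fixtures import ideal_trace_percent
from decellmon.monitor import (
    ROI,
    FormatError,
    Frame,
    ProcessTrace,
    StoppingRule,
    mean_intensity,
    normalize_time_to_flow,
    replay_stop_rule,
    run_monitor,
    should_stop,
    smooth_trace,
    to_grayscale,
    to_percent,
)
from decellmon.phantom import DilutionModel, PhantomScene, simulate_discoloration_run

from conftest import trace_from_smoothed, uniform_frame


class TestToGrayscale:
    def test_single_channel_passthrough(self):
        frame = uniform_frame(77)
        assert to_grayscale(frame) is frame

    def test_rgb_reduces_to_green_channel(self):
        pixels = np.zeros((4, 4, 3), dtype=np.uint8)
        pixels[..., 0], pixels[..., 1], pixels[..., 2] = 10, 200, 30
        gray = to_grayscale(Frame(pixels=pixels, timestamp_min=0.0))
        assert gray.n_channels == 1
        assert np.all(gray.pixels == 200)

    def test_equal_channels_match_any_channel(self):
        rng = np.random.default_rng(0)
        one = rng.integers(0, 256, (6, 5), dtype=np.uint8)
        rgb = np.stack([one] * 3, axis=-1)
        gray = to_grayscale(Frame(pixels=rgb, timestamp_min=0.0))
        assert np.array_equal(gray.pixels, one)

    def test_unsupported_channel_count_rejected(self):
        with pytest.raises(FormatError):
            Frame(pixels=np.zeros((4, 4, 2), dtype=np.uint8), timestamp_min=0.0)


class TestMeanIntensity:
    @pytest.mark.parametrize("values,expected", [
        (np.full((2, 2), 100, dtype=np.uint8), 100.0),
        (np.array([[0, 255], [255, 0]], dtype=np.uint8), 127.5),
        (np.arange(16, dtype=np.uint8).reshape(4, 4), 7.5),
    ])
    def test_exact_means(self, values, expected):
        frame = Frame(pixels=values, timestamp_min=0.0)
        roi = ROI(0, 0, values.shape[1], values.shape[0])
        assert mean_intensity(frame, roi) == expected

    def test_agrees_with_double_loop_brute_force(self):
        rng = np.random.default_rng(11)
        for _ in range(30):
            h, w = rng.integers(2, 9, 2)
            pixels = rng.integers(0, 256, (h, w), dtype=np.uint8)
            x0, y0 = rng.integers(0, w), rng.integers(0, h)
            x1 = rng.integers(x0 + 1, w + 1)
            y1 = rng.integers(y0 + 1, h + 1)
            roi = ROI(int(x0), int(y0), int(x1), int(y1))
            total = count = 0
            for y in range(y0, y1):
                for x in range(x0, x1):
                    total += int(pixels[y, x])
                    count += 1
            frame = Frame(pixels=pixels, timestamp_min=0.0)
            assert mean_intensity(frame, roi) == total / count

    def test_roi_outside_frame_rejected(self):
        frame = uniform_frame(10, shape=(4, 4))
        with pytest.raises(ValueError):
            mean_intensity(frame, ROI(0, 0, 5, 4))

    def test_offset_outside_roi_never_changes_mean(self):
        pixels = np.full((8, 8), 100, dtype=np.uint8)
        roi = ROI(2, 2, 6, 6)
        base = mean_intensity(Frame(pixels=pixels, timestamp_min=0.0), roi)
        shifted = pixels.copy()
        shifted[0, :] = 255  # outside the ROI
        shifted[:, 7] = 0
        assert mean_intensity(Frame(pixels=shifted, timestamp_min=0.0), roi) == base


class TestToPercent:
    @pytest.mark.parametrize("value,expected", [(255, 100.0), (0, 0.0), (127.5, 50.0)])
    def test_scaling(self, value, expected):
        assert to_percent(value) == expected

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            to_percent(256.0)


class TestSmoothTrace:
    def test_constant_sequence_unchanged(self):
        out = smooth_trace(np.full(30, 42.0), sigma=2.0)
        np.testing.assert_allclose(out, 42.0, rtol=1e-12)

    def test_impulse_center_equals_kernel_center_weight(self):
        # Independent oracle: normalized truncated Gaussian weights.
        sigma = 2.0
        r = int(4.0 * sigma + 0.5)
        j = np.arange(-r, r + 1)
        weights = np.exp(-(j ** 2) / (2 * sigma ** 2))
        weights /= weights.sum()
        raw = np.zeros(101)
        raw[50] = 1.0
        out = smooth_trace(raw, sigma)
        assert out[50] == pytest.approx(weights[r], rel=1e-10)
        np.testing.assert_allclose(out[50 - r : 50 + r + 1], weights, rtol=1e-10)

    @settings(derandomize=True, max_examples=40)
    @given(st.lists(st.floats(0.0, 100.0), min_size=1, max_size=60),
           st.floats(0.3, 5.0))
    def test_length_preserved_and_mean_bounded(self, values, sigma):
        out = smooth_trace(values, sigma)
        assert len(out) == len(values)
        assert out.min() >= min(values) - 1e-9
        assert out.max() <= max(values) + 1e-9


class TestShouldStop:
    def test_too_few_samples_never_stops(self):
        trace = trace_from_smoothed([50.0] * 9)
        assert not should_stop(trace, StoppingRule()).stop

    def test_identical_window_stops(self):
        trace = trace_from_smoothed([50.0] * 10)
        decision = should_stop(trace, StoppingRule())
        assert decision.stop and decision.window_range == 0.0

    def test_ten_percent_step_does_not_stop(self):
        trace = trace_from_smoothed([50.0] * 9 + [55.0])
        assert not should_stop(trace, StoppingRule()).stop

    def test_hand_checked_plateau_window(self):
        window = [100.0, 99.0, 98.5, 98.0, 98.0, 97.9, 97.9, 97.8, 97.8, 97.8]
        decision = should_stop(trace_from_smoothed(window), StoppingRule())
        # range 2.2, mean 98.27, bound 2.9481
        assert decision.window_range == pytest.approx(2.2)
        assert decision.threshold == pytest.approx(2.9481)
        assert decision.stop

    def test_agrees_with_brute_force_on_random_traces(self):
        rng = np.random.default_rng(5)
        rule = StoppingRule(window_n=6, k_percent=4.0)
        for _ in range(300):
            n = int(rng.integers(1, 25))
            vals = rng.uniform(1.0, 100.0, n)
            trace = trace_from_smoothed(vals)
            got = should_stop(trace, rule).stop
            if n < rule.window_n:
                expected = False
            else:
                window = list(vals[-rule.window_n:])
                expected = (max(window) - min(window)) <= (
                    rule.k_percent / 100.0 * (sum(window) / len(window)))
            assert got == expected


class TestRunMonitor:
    def test_constant_frames_stop_at_window_boundary(self):
        rule = StoppingRule(window_n=10, k_percent=3.0)
        frames = [uniform_frame(128, t=float(i)) for i in range(30)]
        roi = ROI(0, 0, 8, 8)
        trace, stop = run_monitor(iter(frames), roi, rule)
        assert stop == float(rule.window_n - 1)
        assert len(trace) == rule.window_n

    def test_too_few_frames_returns_none(self):
        frames = [uniform_frame(128, t=float(i)) for i in range(5)]
        trace, stop = run_monitor(iter(frames), ROI(0, 0, 8, 8), StoppingRule())
        assert stop is None and len(trace) == 5

    def test_strictly_changing_trace_above_band_never_stops(self):
        # Each step changes by 20% of the level: window relative range stays
        # far above k = 3%, so the monotone-safety property forbids a stop.
        rule = StoppingRule()
        values = [int(round(5 * 1.2 ** i)) for i in range(22)]
        frames = [uniform_frame(min(v, 255), t=float(i)) for i, v in enumerate(values)]
        _, stop = run_monitor(iter(frames), ROI(0, 0, 8, 8), rule)
        assert stop is None

    def test_replay_matches_streaming_monitor(self):
        rng = np.random.default_rng(21)
        rule = StoppingRule(window_n=5, k_percent=8.0, smoothing_sigma=1.5)
        for _ in range(50):
            n = int(rng.integers(5, 80))
            raw255 = rng.integers(40, 230, n)
            frames = [uniform_frame(int(v), t=float(i)) for i, v in enumerate(raw255)]
            _, stop_stream = run_monitor(iter(frames), ROI(0, 0, 8, 8), rule)
            stop_replay = replay_stop_rule(
                np.arange(n, dtype=float), raw255 / 255.0 * 100.0, rule)
            assert stop_stream == stop_replay

    def test_end_to_end_stop_matches_gompertz_oracle(self):
        """Across a 20-set parameter sweep, the stop time recovered from
        rendered noise-free frames matches the stop computed analytically on
        the Gompertz closed form, within one frame interval."""
        rule = StoppingRule()
        roi = ROI(10, 8, 22, 16)  # inscribed in the ellipse below
        for interval, tau_factor, epsl in itertools.product(
            (2.0, 5.0), (2.0, 3.5, 5.0, 6.5, 7.5), (2.0, 2.5)
        ):
            tau = tau_factor * interval
            scene = PhantomScene(
                width_px=32, height_px=24, center_x=16.0, center_y=12.0,
                semi_axis_x=10.0, semi_axis_y=8.0, backlight_intensity=250,
                background_intensity=30, pixel_noise_sd=0.0, seed=0)
            model = DilutionModel(
                reservoir_volume_mL=tau * 50.0 / 60.0, flow_rate_mL_per_h=50.0,
                initial_concentration=1.0, optical_depth_coeff=epsl)
            n = int(tau / interval * 12) + 40
            frames, _ = simulate_discoloration_run(scene, model, interval, n)
            _, stop = run_monitor(iter(frames), roi, rule)
            times, ideal = ideal_trace_percent(model, interval, n, 250)
            oracle = replay_stop_rule(times, ideal, rule)
            assert stop is not None and oracle is not None
            assert abs(stop - oracle) <= interval


class TestNormalizeTimeToFlow:
    @pytest.mark.parametrize("t,q,expected", [
        (60.0, 50.0, 50.0),
        (120.0, 25.0, 50.0),
        (340.0, 50.0, 340.0 * 50.0 / 60.0),
    ])
    def test_delivered_volume(self, t, q, expected):
        assert normalize_time_to_flow(t, q) == pytest.approx(expected)

    def test_nonpositive_inputs_rejected(self):
        with pytest.raises(ValueError):
            normalize_time_to_flow(0.0, 50.0)
        with pytest.raises(ValueError):
            normalize_time_to_flow(10.0, -1.0)
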