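import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from emdassist import signals
from emdassist.errors import (
    GeometryError,
    InputError,
    NormalizationError,
    OnsetOrderingError,
)
from .reference_filters import reference_envelope

RATE = 2000.0


class TestThreshold:
    @pytest.mark.parametrize(
        "peak,expected_rest_max,expected_threshold",
        [(10.0, 100.0, 101.0), (2.0, 4.0, 4.04)],
    )
    def test_one_percent_rule(self, peak, expected_rest_max, expected_threshold):
        rest = np.array([0.1, -peak, 0.3, peak / 2])
        res = signals.compute_threshold(rest)
        assert res.rest_max == pytest.approx(expected_rest_max)
        assert res.threshold == pytest.approx(expected_threshold)

    def test_all_zero_rest_uses_epsilon_floor(self):
        res = signals.compute_threshold(np.zeros(100))
        assert res.rest_max == 0.0
        assert res.threshold == np.finfo(float).eps

    def test_empty_rest_rejected(self):
        with pytest.raises(InputError):
            signals.compute_threshold(np.array([]))


class TestDetectOnset:
    def test_subthreshold_never_fires(self):
        assert signals.detect_onset(np.full(500, 0.5), threshold=1.0, search_start=0) is None

    def test_step_crossing_found_at_first_sample(self):
        x = np.zeros(500)
        x[200:] = 2.0  # squared = 4 > 1
        assert signals.detect_onset(x, threshold=1.0, search_start=0) == 200

    def test_crossings_before_search_start_ignored(self):
        x = np.zeros(500)
        x[100] = 5.0
        x[300] = 5.0
        assert signals.detect_onset(x, threshold=1.0, search_start=150) == 300

    @given(st.integers(min_value=0, max_value=99), st.integers(min_value=0, max_value=99))
    def test_matches_naive_scan(self, seed, start):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=100)
        thr = float(rng.uniform(0.1, 4.0))
        naive = next((i for i in range(start, 100) if x[i] ** 2 > thr), None)
        assert signals.detect_onset(x, thr, start) == naive


class TestEnvelope:
    def test_zero_in_zero_out(self):
        assert np.allclose(signals.emg_envelope(np.zeros(1000), RATE), 0.0)

    def test_dc_removed_by_highpass(self):
        env = signals.emg_envelope(np.full(4000, 3.0), RATE)
        assert np.max(np.abs(env[1000:3000])) < 1e-6

    def test_scaling_linearity(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=3000)
        assert np.allclose(
            signals.emg_envelope(2.5 * x, RATE), 2.5 * signals.emg_envelope(x, RATE)
        )

    def test_matches_transfer_function_oracle(self):
        """Interior samples agree with an independently derived filter to 1e-9."""
        rng = np.random.default_rng(2024)
        x = rng.normal(size=8000) * (1.0 + 0.5 * np.sin(np.arange(8000) / 300.0))
        env = signals.emg_envelope(x, RATE)
        ref = reference_envelope(x, RATE)
        # compare away from the edges: the 10 Hz low-pass startup transient
        # decays below 1e-9 only after ~1.75 s at this rate
        sl = slice(3500, 4500)
        scale = np.abs(ref[sl]).max()
        assert np.max(np.abs(env[sl] - ref[sl])) < 1e-9 * scale

    def test_short_series_rejected(self):
        with pytest.raises(InputError):
            signals.emg_envelope(np.ones(10), RATE)

    def test_low_rate_rejected(self):
        with pytest.raises(InputError):
            signals.emg_envelope(np.ones(1000), rate=30.0)


class TestPeakActivation:
    def test_monotone_envelope_peaks_at_window_end(self):
        env = np.linspace(0, 1, 2000)
        last = 100 + int(round(0.2 * RATE))
        assert signals.peak_activation(env, 100, RATE) == pytest.approx(env[last])

    def test_interior_peak_found(self):
        env = np.zeros(2000)
        env[300] = 5.0  # 100 ms after onset at 2000 Hz
        assert signals.peak_activation(env, 100, RATE) == pytest.approx(5.0)

    def test_window_truncated_at_series_end(self):
        env = np.linspace(0, 1, 500)
        assert signals.peak_activation(env, 450, RATE) == pytest.approx(env[-1])

    def test_onset_outside_series_rejected(self):
        with pytest.raises(InputError):
            signals.peak_activation(np.zeros(100), 100, RATE)


class TestNormalization:
    def test_control_self_normalizes_to_100(self):
        peaks = np.array([1.0, 2.0, 3.0])
        assert np.mean(signals.normalize_peaks(peaks, peaks)) == pytest.approx(100.0)

    def test_level_maps_to_percent(self):
        control = np.array([2.0, 2.0])
        assert signals.normalize_peaks([2.0], control)[0] == pytest.approx(100.0)
        assert signals.normalize_peaks([2.0 * 1.6897], control)[0] == pytest.approx(168.97)

    def test_bad_reference_rejected(self):
        with pytest.raises(NormalizationError):
            signals.normalize_peaks([1.0], np.zeros(3))
        with pytest.raises(NormalizationError):
            signals.normalize_peaks([1.0], np.array([]))


class TestAngularVelocity:
    def test_stationary_markers_give_zero(self):
        wrist = np.tile([0.25, 0.0], (200, 1))
        elbow = np.zeros((200, 2))
        assert np.allclose(signals.angular_velocity(wrist, elbow, 200.0), 0.0)

    def test_uniform_rotation_recovered_exactly_at_interior(self):
        omega, rate, n = 3.0, 200.0, 400
        theta = omega * np.arange(n) / rate
        wrist = 0.25 * np.column_stack([np.cos(theta), np.sin(theta)])
        est = signals.angular_velocity(wrist, np.zeros((n, 2)), rate)
        assert np.allclose(est[1:-1], omega, rtol=1e-10)

    def test_coincident_markers_rejected(self):
        xy = np.ones((50, 2))
        with pytest.raises(GeometryError):
            signals.angular_velocity(xy, xy, 200.0)


class TestReactionTime:
    def test_known_duration(self):
        assert signals.reaction_time(0, 360, RATE) == pytest.approx(180.0)

    def test_single_sample(self):
        assert signals.reaction_time(100, 101, RATE) == pytest.approx(0.5)

    def test_onset_before_cue_rejected(self):
        with pytest.raises(OnsetOrderingError):
            signals.reaction_time(100, 100, RATE)
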