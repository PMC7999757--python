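"""Resampling, gravity/body separation and windowing."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from mobiward import FilterSpec, SensorTrace, ValidationError
from mobiward.preprocessing import (
    label_windows,
    resample,
    segment,
    split_acceleration,
    window_count,
)
from mobiward.types import ActivityLabel, LabelInterval

START = pd.Timestamp("2020-06-15 09:00:00")


def _trace(samples, rate=100.0, site="arm", start=START):
    return SensorTrace(site=site, sample_rate_hz=rate, start_time=start, samples=samples)


def _sine_trace(freq, rate, duration_s, axis=0, amp=1.0):
    t = np.arange(int(duration_s * rate)) / rate
    s = np.zeros((t.size, 3))
    s[:, axis] = amp * np.sin(2 * np.pi * freq * t)
    return _trace(s, rate=rate), t


class TestResample:
    def test_identity_at_target_rate(self):
        trace = _trace(np.random.default_rng(0).normal(size=(500, 3)))
        out = resample(trace, 100.0)
        np.testing.assert_array_equal(out.samples, trace.samples)

    def test_constant_signal_preserved(self):
        trace = _trace(np.tile([1.0, 0.0, 0.0], (600, 1)), rate=60.0)
        out = resample(trace, 100.0)
        assert out.sample_rate_hz == 100.0
        np.testing.assert_allclose(out.samples, np.tile([1.0, 0.0, 0.0], (out.n_samples, 1)))
        assert abs(out.duration_s - trace.duration_s) <= 1.0 / 60.0

    def test_sinusoid_interpolation_error_small(self):
        """60 Hz 1 Hz-sine resampled to 100 Hz tracks the analytic waveform."""
        trace, _ = _sine_trace(1.0, 60.0, 10.0)
        out = resample(trace, 100.0)
        t_new = np.arange(out.n_samples) / 100.0
        np.testing.assert_allclose(out.samples[:, 0], np.sin(2 * np.pi * t_new), atol=0.01)

    def test_heavy_upsampling_refused(self):
        trace = _trace(np.zeros((100, 3)) + [0, 0, 1], rate=20.0)
        with pytest.raises(ValidationError, match="upsample"):
            resample(trace, 90.0)


class TestSplitAcceleration:
    def test_dc_rejected(self):
        """Pure gravity leaves near-zero dynamic output away from the edges."""
        trace = _trace(np.tile([0.0, 0.0, 1.0], (1000, 1)))
        _, dyn = split_acceleration(trace)
        core = dyn.samples[100:-100]
        assert np.sqrt(np.mean(core**2, axis=0)).max() < 1e-3

    @pytest.mark.parametrize(
        "freq,amp_tol",
        [(5.0, 0.05), (0.1, None)],  # passband within 5%; deep stopband
    )
    def test_amplitude_matches_frequency_response(self, freq, amp_tol):
        """Sinusoid amplitude after filtering matches |H(f)| of the design."""
        spec = FilterSpec()
        trace, t = _sine_trace(freq, 100.0, 40.0)
        _, dyn = split_acceleration(trace, spec)
        core = dyn.samples[500:-500, 0]
        # amplitude via RMS of a sinusoid
        amp = np.sqrt(2.0) * np.sqrt(np.mean(core**2))
        expected = spec.response_magnitude(freq, 100.0)
        if amp_tol is not None:
            assert amp == pytest.approx(expected, rel=amp_tol)
            assert amp == pytest.approx(1.0, rel=0.05)
        else:
            assert amp < 0.05
            assert expected < 0.05

    def test_linearity(self):
        rng = np.random.default_rng(7)
        x = rng.normal(size=(1200, 3))
        t1 = _trace(x)
        t2 = _trace(2.5 * x)
        _, d1 = split_acceleration(t1)
        _, d2 = split_acceleration(t2)
        np.testing.assert_allclose(d2.samples, 2.5 * d1.samples, atol=1e-9)

    def test_short_trace_rejected(self):
        trace = _trace(np.zeros((200, 3)) + [0, 0, 1])
        with pytest.raises(ValidationError, match="transient"):
            split_acceleration(trace)

    def test_total_returned_unchanged(self):
        trace = _trace(np.random.default_rng(1).normal(size=(1000, 3)))
        total, _ = split_acceleration(trace)
        assert total is trace


class TestSegment:
    def _pair(self, n, rate=100.0):
        rng = np.random.default_rng(0)
        arm = _trace(rng.normal(size=(n, 3)), rate=rate, site="arm")
        leg = _trace(rng.normal(size=(n, 3)), rate=rate, site="leg")
        return arm, leg

    @pytest.mark.parametrize("overlap,expected", [(0.0, 4), (0.5, 7)])
    def test_window_counts(self, overlap, expected):
        arm, leg = self._pair(1024)
        assert len(segment(arm, leg, overlap_fraction=overlap)) == expected

    def test_too_short_yields_empty(self, caplog):
        arm, leg = self._pair(255)
        with caplog.at_level("WARNING"):
            assert segment(arm, leg) == []
        assert "shorter than one" in caplog.text

    def test_no_overlap_tiles_a_prefix(self):
        """With overlap 0 window indices reconstruct a prefix, no reuse."""
        arm, leg = self._pair(1000)
        windows = segment(arm, leg, overlap_fraction=0.0)
        recon = np.vstack([w.arm_total for w in windows])
        np.testing.assert_array_equal(recon, arm.samples[: len(windows) * 256])

    def test_all_windows_have_256_samples(self):
        arm, leg = self._pair(2000)
        for w in segment(arm, leg, overlap_fraction=0.5):
            assert w.arm_total.shape == (256, 3)
            assert w.leg_total.shape == (256, 3)

    def test_rate_mismatch_rejected(self):
        arm, _ = self._pair(512)
        leg = _trace(np.zeros((512, 3)) + [0, 0, 1], rate=60.0, site="leg")
        with pytest.raises(ValidationError, match="sample rate"):
            segment(arm, leg)

    def test_alignment_uses_latest_common_start(self):
        rng = np.random.default_rng(3)
        arm = _trace(rng.normal(size=(600, 3)), site="arm", start=START)
        leg = _trace(
            rng.normal(size=(600, 3)), site="leg", start=START + pd.Timedelta(seconds=1)
        )
        windows = segment(arm, leg)
        assert windows[0].start_time == START + pd.Timedelta(seconds=1)
        np.testing.assert_array_equal(windows[0].leg_total, leg.samples[:256])
        np.testing.assert_array_equal(windows[0].arm_total, arm.samples[100:356])

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(
        n=st.integers(min_value=256, max_value=4000),
        overlap=st.sampled_from([0.0, 0.25, 0.5, 0.75]),
    )
    def test_count_formula_matches_enumeration(self, n, overlap):
        """floor((N - w)/step) + 1 equals brute-force enumeration."""
        step = int(round(256 * (1 - overlap)))
        brute = sum(1 for s in range(0, n, step) if s + 256 <= n and s % step == 0)
        assert window_count(n, 256, overlap) == brute


class TestLabelWindows:
    def _session_windows(self, n_samples=3000, overlap=0.5):
        rng = np.random.default_rng(0)
        arm = _trace(rng.normal(size=(n_samples, 3)), site="arm")
        leg = _trace(rng.normal(size=(n_samples, 3)), site="leg")
        return segment(arm, leg, overlap_fraction=overlap)

    def test_fully_covered_window_labelled(self):
        windows = self._session_windows(512, overlap=0.0)
        iv = LabelInterval(START, START + pd.Timedelta(seconds=6), ActivityLabel(1))
        labelled = label_windows(windows, [iv])
        assert len(labelled) == 2
        assert all(w.label.code == 1 for w in labelled)

    def test_straddling_window_excluded(self):
        """A 60%/40% straddle fails the full-coverage rule."""
        windows = self._session_windows(256, overlap=0.0)
        mid = START + pd.Timedelta(seconds=0.6 * 2.56)
        ivs = [
            LabelInterval(START, mid, ActivityLabel(1)),
            LabelInterval(mid, START + pd.Timedelta(seconds=10), ActivityLabel(2)),
        ]
        assert label_windows(windows, ivs) == []
        assert len(label_windows(windows, ivs, min_coverage=0.5)) == 1

    def test_thirty_second_interval_window_count(self):
        """A 30 s labelled block yields 22 fully covered windows (enumeration)."""
        windows = self._session_windows(3000, overlap=0.5)
        iv = LabelInterval(START, START + pd.Timedelta(seconds=30), ActivityLabel(4))
        labelled = label_windows(windows, [iv])
        # enumeration: starts at k*128 samples with k*128 + 256 <= 3000
        expected = sum(1 for k in range(100) if k * 128 + 256 <= 3000)
        assert expected == 22
        assert len(labelled) == expected
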