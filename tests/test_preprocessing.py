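import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lumbargait.io import AccelRecording, DataError
from lumbargait.preprocessing import (ParameterError, butterworth_filter,
                                      cwt_gaus1, frequency_to_scale,
                                      integrate, scale_to_frequency,
                                      tilt_correct)

FS = 100.0


def _sine(f, fs=FS, dur=10.0, phase=0.0):
    t = np.arange(0, dur, 1 / fs)
    return t, np.sin(2 * np.pi * f * t + phase)


class TestButterworth:
    def test_dc_rejected_by_bandpass(self):
        x = np.full(2000, 3.3)
        y = butterworth_filter(x, FS, "bandpass", (0.25, 7.5))
        assert np.max(np.abs(y[200:-200])) < 1e-6 * 3.3

    def test_passband_amplitude_preserved(self):
        _, x = _sine(2.0)
        y = butterworth_filter(x, FS, "lowpass", 20.0)
        assert np.max(np.abs(y[200:-200])) == pytest.approx(1.0, rel=0.01)

    def test_zero_phase_at_passband_frequency(self):
        _, x = _sine(2.0)
        y = butterworth_filter(x, FS, "bandpass", (0.25, 7.5))
        xc = np.correlate(y[100:-100], x[100:-100], mode="full")
        lag = np.argmax(xc) - (len(x) - 201)
        assert lag == 0

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_time_reversal_symmetry(self, seed):
        """Zero-phase filtering commutes with time reversal away from the
        bout edges (the 0.25 Hz band edge leaves a long but decaying
        transient, so the band-pass check uses a wide margin)."""
        x = np.random.default_rng(seed).normal(size=6000)
        y = butterworth_filter(x, FS, "lowpass", 20.0)
        y_rev = butterworth_filter(x[::-1], FS, "lowpass", 20.0)[::-1]
        assert np.allclose(y[100:-100], y_rev[100:-100], atol=1e-9)
        y = butterworth_filter(x, FS, "bandpass", (0.25, 7.5))
        y_rev = butterworth_filter(x[::-1], FS, "bandpass", (0.25, 7.5))[::-1]
        assert np.allclose(y[2500:-2500], y_rev[2500:-2500], atol=1e-6)

    def test_cutoff_at_nyquist_rejected(self):
        with pytest.raises(ParameterError):
            butterworth_filter(np.zeros(1000), FS, "lowpass", 50.0)

    def test_short_signal_rejected(self):
        with pytest.raises(DataError):
            butterworth_filter(np.zeros(10), FS, "lowpass", 20.0)


class TestIntegrate:
    def test_constant_closed_form(self):
        # cumulative trapezoid of a constant: (n-1)/fs at the last sample
        y = integrate(np.ones(11), 10.0)
        assert y[0] == 0.0
        assert y[-1] == pytest.approx(1.0)
        assert y.size == 11

    def test_zero_maps_to_zero(self):
        assert np.all(integrate(np.zeros(50), 100.0) == 0.0)

    def test_sine_over_integer_periods_closes(self):
        t, x = _sine(1.0, fs=100, dur=5.0)
        x = np.sin(2 * np.pi * t)  # exactly integer periods on [0, 5)
        y = integrate(x, 100.0)
        assert abs(y[-1]) < 1e-3


class TestCwt:
    def test_linearity(self):
        x = np.random.default_rng(3).normal(size=1000)
        c1 = cwt_gaus1(x, 8.0)
        assert c1.shape == x.shape
        assert np.all(cwt_gaus1(np.zeros(500), 8.0) == 0.0)
        assert np.allclose(cwt_gaus1(2 * x, 8.0), 2 * c1)

    def test_matched_frequency_response_dominates(self):
        # scale tuned to 2 Hz responds more to 2 Hz than to 0.3 Hz
        scale = frequency_to_scale(2.0, FS)
        _, on = _sine(2.0)
        _, off = _sine(0.3)
        rms = lambda v: np.sqrt(np.mean(v[100:-100] ** 2))
        assert rms(cwt_gaus1(on, scale)) > 3 * rms(cwt_gaus1(off, scale))

    def test_translation_covariance(self):
        rng = np.random.default_rng(4)
        n, k, scale = 1200, 37, 6.0
        x = rng.normal(size=n)
        c = cwt_gaus1(x, scale)
        c_shift = cwt_gaus1(np.concatenate([np.zeros(k), x]), scale)
        m = int(5 * scale) + 1       # full wavelet support
        assert np.allclose(c[m:n - m], c_shift[m + k:n - m + k], atol=1e-9)

    def test_scale_below_one_rejected(self):
        with pytest.raises(ParameterError):
            cwt_gaus1(np.zeros(100), 0.5)


class TestFrequencyScale:
    def test_reference_point(self):
        # the fixed point of the convention: 1.25 Hz at 50 Hz is scale 8
        assert frequency_to_scale(1.25, 50.0) == 8.0

    def test_direct_evaluation(self):
        assert frequency_to_scale(2.0, 100.0) == 10.0

    def test_proportional_in_fs(self):
        for f in (0.7, 1.3, 2.9):
            assert (frequency_to_scale(f, 200.0)
                    == pytest.approx(2 * frequency_to_scale(f, 100.0), abs=0.2))

    @given(st.floats(min_value=0.5, max_value=20.0))
    @settings(deadline=None, max_examples=50)
    def test_round_trip_within_rounding(self, f):
        fs = 128.0
        s = frequency_to_scale(f, fs)
        assert scale_to_frequency(s, fs) == pytest.approx(f, rel=0.05)

    def test_out_of_range_rejected(self):
        with pytest.raises(ParameterError):
            frequency_to_scale(60.0, 100.0)
        with pytest.raises(ParameterError):
            frequency_to_scale(0.0, 100.0)


class TestTiltCorrect:
    @staticmethod
    def _recording(a, fs=100.0):
        t = np.arange(a.shape[0]) / fs
        return AccelRecording(t=t, a=a, fs=fs)

    def test_aligned_recording_unchanged(self):
        rng = np.random.default_rng(5)
        a = rng.normal(0, 0.2, size=(500, 3))
        a[:, 2] -= a[:, 2].mean() + 9.81      # exact -g mean
        a[:, 0] -= a[:, 0].mean()
        a[:, 1] -= a[:, 1].mean()
        rec = self._recording(a)
        out = tilt_correct(rec, (2, 1))
        assert np.allclose(out.a, rec.a, atol=1e-12)

    @pytest.mark.parametrize("axis", [0, 1])
    def test_five_degree_tilt_recovered(self, axis):
        rng = np.random.default_rng(6)
        body = rng.normal(0, 0.3, size=(2000, 3))
        body -= body.mean(axis=0)
        body[:, 2] -= 9.81
        ang = np.deg2rad(5.0)
        rot = np.eye(3)
        i, j = axis, 2
        rot[i, i] = rot[j, j] = np.cos(ang)
        rot[i, j] = np.sin(ang)
        rot[j, i] = -np.sin(ang)
        rec = self._recording(body @ rot.T)
        out = tilt_correct(rec, (2, 1))
        assert out.a[:, 2].mean() == pytest.approx(-9.81, rel=0.005)

    def test_joint_tilt_zeroes_horizontal_means(self):
        rng = np.random.default_rng(7)
        body = rng.normal(0, 0.3, size=(2000, 3))
        body -= body.mean(axis=0)
        body[:, 2] -= 9.81
        r1 = np.array([[np.cos(0.0873), 0, np.sin(0.0873)], [0, 1, 0],
                       [-np.sin(0.0873), 0, np.cos(0.0873)]])
        r2 = np.array([[1, 0, 0], [0, np.cos(0.0873), np.sin(0.0873)],
                       [0, -np.sin(0.0873), np.cos(0.0873)]])
        rec = self._recording(body @ (r2 @ r1).T)
        out = tilt_correct(rec, (2, 1))
        assert abs(out.a[:, 0].mean()) < 0.05 * 9.81
        assert abs(out.a[:, 1].mean()) < 0.05 * 9.81
        # proper rotation: energy preserved
        assert np.sum(out.a ** 2) == pytest.approx(np.sum(rec.a ** 2), rel=1e-9)

    def test_missing_gravity_dominance_rejected(self):
        a = np.random.default_rng(8).normal(0, 1.0, size=(500, 3))
        rec = self._recording(a)
        with pytest.raises(DataError):
            tilt_correct(rec, (2, 1))
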