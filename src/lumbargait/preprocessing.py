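"""Shared signal operators.

Butterworth filtering (always zero-phase), small-angle tilt correction,
cumulative-trapezoid integration, and the single-scale Gaussian
first-derivative CWT together with its frequency <-> scale convention.

Sign convention: the Gaussian first-derivative wavelet (pywt ``gaus1``) has
normalized central frequency 0.2, so ``scale = 0.2 * fs / f_target`` — at
50 Hz a 1.25 Hz target gives scale 8.  The raw pywt coefficient series is
(up to scale-dependent gain) the *negative* smoothed derivative of the
input; callers that want "smoothed derivative" polarity negate it.
"""

from __future__ import annotations

import numpy as np
import pywt
from scipy import signal as sps
from scipy.integrate import cumulative_trapezoid

from .io import AccelRecording, DataError

#: normalized central frequency of the gaus1 wavelet (per-sample units)
GAUS1_CENTER_FREQ = 0.2


class ParameterError(ValueError):
    pass


def butterworth_filter(x, fs, kind, cutoffs, order: int = 4):
    """Zero-phase Butterworth filter (forward-backward, SOS).

    ``order`` refers to the one-pass design; the effective order after the
    forward-backward application is doubled, with zero phase lag so that
    event timing downstream is unbiased.
    """
    x = np.asarray(x, dtype=float)
    cut = np.atleast_1d(np.asarray(cutoffs, dtype=float))
    if np.any(cut <= 0) or np.any(cut >= fs / 2):
        raise ParameterError(
            f"cutoffs {cutoffs} must lie strictly inside (0, {fs / 2}) Hz")
    if kind == "bandpass":
        sos = sps.butter(order, cut, btype="bandpass", fs=fs, output="sos")
    elif kind == "lowpass":
        sos = sps.butter(order, cut[0], btype="lowpass", fs=fs, output="sos")
    elif kind == "highpass":
        sos = sps.butter(order, cut[0], btype="highpass", fs=fs, output="sos")
    else:
        raise ParameterError(f"unknown filter kind {kind!r}")
    padlen = 3 * (2 * order + 1)
    if x.shape[-1] <= padlen:
        raise DataError(f"signal too short to filter ({x.shape[-1]} samples)")
    return sps.sosfiltfilt(sos, x, axis=-1)


def tilt_correct(rec: AccelRecording, vertical: tuple[int, int]) -> AccelRecording:
    """Tilt correction from the per-channel mean accelerations.

    Rotates the triaxial signal so the time-averaged gravity vector lies
    along the signed vertical axis.  The rotation is the minimal (Rodrigues)
    rotation taking the mean acceleration direction onto the vertical axis,
    which coincides with the classical pair of small-angle rotations about
    the horizontal axes for the small tilts it is meant to repair.  Being a
    proper rotation it preserves the per-sample signal energy exactly.
    """
    v_idx, v_sign = vertical
    m = rec.a.mean(axis=0)
    if abs(m[v_idx]) < 0.5 * 9.81:
        raise DataError(
            "gravity does not dominate the vertical channel "
            f"(|mean| = {abs(m[v_idx]):.2f} m/s^2); bout not upright?")

    u = m / np.linalg.norm(m)
    target = np.zeros(3)
    target[v_idx] = -v_sign          # sensor reads -g along signed vertical
    c = float(np.dot(u, target))
    if c > 1.0 - 1e-15:
        rot = np.eye(3)
    else:
        axis = np.cross(u, target)
        s = np.linalg.norm(axis)
        axis = axis / s
        k = np.array([[0, -axis[2], axis[1]],
                      [axis[2], 0, -axis[0]],
                      [-axis[1], axis[0], 0]])
        rot = np.eye(3) + s * k + (1 - c) * (k @ k)
    a = rec.a @ rot.T
    out = AccelRecording(t=rec.t, a=a, fs=rec.fs,
                         meta={**rec.meta, "tilt_corrected": True})
    e0 = float(np.sum(rec.a ** 2))
    e1 = float(np.sum(a ** 2))
    assert abs(e1 - e0) <= 1e-6 * max(e0, 1.0), "tilt correction lost energy"
    return out


def integrate(x, fs):
    """Cumulative trapezoid with initial value 0; same length as input."""
    x = np.asarray(x, dtype=float)
    if x.shape[-1] < 2:
        raise DataError("need at least 2 samples to integrate")
    return cumulative_trapezoid(x, dx=1.0 / fs, initial=0.0)


def cwt_gaus1(x, scale):
    """Single-scale CWT with the Gaussian first-derivative wavelet.

    Edges are handled by symmetric extension of ``2 * scale`` samples,
    cropped after the transform.  The output has the length of the input
    and is linear in it.  Polarity follows pywt: coefficients are the
    negative smoothed derivative of the input.
    """
    x = np.asarray(x, dtype=float)
    if scale < 1:
        raise ParameterError(f"scale must be >= 1, got {scale}")
    pad = int(np.ceil(2 * scale))
    pad = min(pad, x.shape[-1] - 1)
    xp = np.pad(x, pad, mode="symmetric")
    coef, _ = pywt.cwt(xp, [float(scale)], "gaus1")
    c = coef[0]
    return c[pad:c.shape[-1] - pad] if pad else c


def frequency_to_scale(f_target, fs):
    """Scale of the gaus1 wavelet whose center frequency is ``f_target``.

    ``scale = 0.2 * fs / f_target``, rounded to the nearest 0.1 (continuous
    scales are allowed); 1.25 Hz at 50 Hz gives scale 8.
    """
    if not 0 < f_target < fs / 2:
        raise ParameterError(
            f"target frequency {f_target} Hz outside (0, {fs / 2}) Hz")
    return round(GAUS1_CENTER_FREQ * fs / f_target, 1)


def scale_to_frequency(scale, fs):
    """Inverse of :func:`frequency_to_scale` (within its 0.1 rounding)."""
    if scale <= 0:
        raise ParameterError(f"scale must be positive, got {scale}")
    return GAUS1_CENTER_FREQ * fs / scale


def edge_margin_s(scale, fs):
    """Time margin near bout edges inside which CWT peaks are discarded."""
    return 2.0 * scale / fs
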