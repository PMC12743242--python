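"""Bout profiling: axis identification and mean step frequency.

The a-priori mean step time of the bout drives every dynamic parameter
downstream: the QC thresholds, the contact-detector wavelet scales and the
minimum peak distances.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .io import AccelRecording, DataError
from .preprocessing import butterworth_filter, cwt_gaus1, frequency_to_scale


class NoGaitError(ValueError):
    """No periodic step pattern found in the analysed band."""


class AmbiguousOrientationError(ValueError):
    pass


@dataclass
class BoutProfile:
    """Identified axes and the bout's a-priori step timing."""

    vertical: tuple[int, int]          # (channel index, sign)
    ap: tuple[int, int]
    t_step_mean: float                 # s
    f_step_mean: float                 # Hz, exactly 1/t_step_mean
    window_lags: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.vertical[0] == self.ap[0]:
            raise ValueError("vertical and AP axes must differ")
        if not 0.5 <= self.f_step_mean <= 5.0:
            raise NoGaitError(
                f"mean step frequency {self.f_step_mean:.2f} Hz outside "
                "[0.5, 5.0] Hz")


def identify_vertical_axis(rec: AccelRecording) -> tuple[int, int]:
    """Channel with the largest absolute mean acceleration (gravity).

    The sign makes the signed channel's mean negative: the sensor measures
    -g at rest in the internal convention.
    """
    m = rec.a.mean(axis=0)
    order = np.argsort(np.abs(m))[::-1]
    if abs(m[order[1]]) > 0.99 * abs(m[order[0]]):
        raise AmbiguousOrientationError(
            f"two channels share the gravity load (means {m}); "
            "sensor orientation ambiguous")
    idx = int(order[0])
    sign = -1 if m[idx] > 0 else 1
    return idx, sign


def identify_ap_axis(rec: AccelRecording, vertical: tuple[int, int],
                     fs: float | None = None,
                     bandpass=(0.25, 7.5), order: int = 4) -> tuple[int, int]:
    """Non-vertical channel most cross-correlated with the vertical one.

    Channels are band-passed to the walking band first.  The sign is
    flipped when the peak correlation is negative, so the AP trace has the
    forward-positive morphology the contact detectors expect.
    """
    fs = fs or rec.fs
    v_idx, v_sign = vertical
    bp = butterworth_filter(rec.a.T, fs, "bandpass", bandpass, order)
    v = v_sign * bp[v_idx]
    v = v - v.mean()
    sv = np.sqrt(np.mean(v ** 2))
    best = None
    for c in range(3):
        if c == v_idx:
            continue
        x = bp[c] - bp[c].mean()
        sx = np.sqrt(np.mean(x ** 2))
        if sv == 0 or sx == 0:
            corr_peak = 0.0
        else:
            xc = sps.correlate(x, v, mode="full", method="fft")
            xc /= (sv * sx * v.size)
            corr_peak = xc[np.argmax(np.abs(xc))]
        if best is None or abs(corr_peak) > abs(best[1]):
            best = (c, corr_peak)
    c_idx, corr = best
    if abs(corr) < 0.1:
        warnings.warn(
            f"weak vertical/AP coupling (|r| = {abs(corr):.2f}); "
            "bout may not contain gait", stacklevel=2)
    return c_idx, (1 if corr >= 0 else -1)


def _lower_median(values: np.ndarray) -> float:
    """Median returning an observed value (lower midpoint on even counts)."""
    v = np.sort(np.asarray(values, dtype=float))
    k = v.size
    return float(v[(k - 1) // 2])


def estimate_mean_step_time(ap, fs, band=(0.5, 5.0), n_scales: int = 10,
                            scale_spacing: str = "linear",
                            power_mode: str = "signed",
                            window_s: float = 5.0, overlap: float = 0.5,
                            min_lag_s: float = 0.2, max_lag_s: float = 2.0,
                            peak_prominence: float = 0.1):
    """Mean step time from the windowed autocovariance of the CWT power.

    The band-passed AP signal is transformed at ``n_scales`` scales whose
    target frequencies span ``band``; the per-sample sum of coefficients
    (signed by default) forms a "CWT power" signal.  Per 5-s window (50%
    overlap) the biased autocovariance is computed and its first local
    maximum beyond ``min_lag_s`` taken as that window's step time; the
    median over windows is the bout estimate.

    Returns ``(t_step_mean, f_step_mean, window_lags)``.
    """
    ap = np.asarray(ap, dtype=float)
    if scale_spacing == "linear":
        freqs = np.linspace(band[0], band[1], n_scales)
    elif scale_spacing == "log":
        freqs = np.geomspace(band[0], band[1], n_scales)
    else:
        raise ValueError(f"unknown scale spacing {scale_spacing!r}")
    coefs = np.stack([cwt_gaus1(ap, frequency_to_scale(f, fs)) for f in freqs])
    if power_mode == "abs":
        power = np.sum(np.abs(coefs), axis=0)
    elif power_mode == "signed":
        power = np.sum(coefs, axis=0)
    elif power_mode == "square":
        power = np.sum(coefs ** 2, axis=0)
    else:
        raise ValueError(f"unknown CWT power mode {power_mode!r}")

    n = power.size
    win = int(round(window_s * fs))
    if n < win:
        starts = [0]
        win = n
    else:
        hop = max(1, int(round(win * (1.0 - overlap))))
        starts = list(range(0, n - win + 1, hop))

    min_lag = int(round(min_lag_s * fs))
    max_lag = min(int(round(max_lag_s * fs)), win - 2)
    lags = []
    for s0 in starts:
        x = power[s0:s0 + win]
        x = x - x.mean()
        acov = sps.correlate(x, x, mode="full", method="fft")[x.size - 1:]
        acov /= x.size          # biased normalization
        if acov[0] <= 0:
            continue
        seg = acov[:max_lag + 1]
        pk, _ = sps.find_peaks(seg, prominence=peak_prominence * acov[0])
        # a step-periodicity peak must be a *positive* autocovariance;
        # harmonic ripples below zero are not self-similarity evidence
        pk = pk[(pk >= min_lag) & (seg[pk] > 0)]
        if pk.size:
            lags.append(pk[0] / fs)   # first (smallest-lag) peak
    if not lags:
        raise NoGaitError(
            "no autocovariance peak in the physiologic lag range "
            f"[{min_lag_s}, {max_lag_s}] s — no gait detected")
    t_step = _lower_median(np.array(lags))
    return t_step, 1.0 / t_step, lags


def build_profile(rec: AccelRecording, cfg=None) -> BoutProfile:
    """Identify axes and estimate the bout's mean step time."""
    from .io import RunConfig

    cfg = cfg or RunConfig()
    rec.require_processable()
    vertical = identify_vertical_axis(rec)
    ap_axis = identify_ap_axis(rec, vertical, rec.fs,
                               cfg.bandpass_hz, cfg.bandpass_order)
    ap = ap_axis[1] * rec.a[:, ap_axis[0]]
    ap_bp = butterworth_filter(ap, rec.fs, "bandpass",
                               cfg.bandpass_hz, cfg.bandpass_order)
    t_step, f_step, lags = estimate_mean_step_time(
        ap_bp, rec.fs, band=cfg.step_freq_band,
        n_scales=cfg.step_freq_n_scales,
        scale_spacing=cfg.step_freq_scale_spacing,
        power_mode=cfg.cwt_power_mode,
        window_s=cfg.acov_window_s, overlap=cfg.acov_overlap,
        min_lag_s=cfg.acov_min_lag_s, max_lag_s=cfg.acov_max_lag_s,
        peak_prominence=cfg.acov_peak_prominence)
    return BoutProfile(vertical=vertical, ap=ap_axis,
                       t_step_mean=t_step, f_step_mean=f_step,
                       window_lags=lags)
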