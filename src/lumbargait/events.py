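"""Initial- and final-contact detection from the lumbar signal.

Two detectors are provided:

* the current AP-signal method with dynamic wavelet scales: FC events are
  peaks of the CWT of the AP velocity, IC events come from a backward
  search on the smoothed AP jerk (midpoint of the latest positive-to-
  negative zero crossing and its preceding local minimum);
* the legacy vertical-signal "m" method (50 Hz, fixed scale) kept as a
  comparator.

All thresholds are expressed in units of the coefficient-series SD
(sigma_Wn), which makes detection amplitude-invariant.  The pywt gaus1
coefficient series is the *negative* smoothed derivative of its input, so
the FC stage negates it (peaks = forward-acceleration maxima) while the IC
stage uses it as-is (it already carries the sign the midpoint rule needs).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .preprocessing import (butterworth_filter, cwt_gaus1, frequency_to_scale,
                            integrate)


class InsufficientEventsError(ValueError):
    pass


class CalibrationError(ValueError):
    pass


@dataclass
class ScaleRelation:
    """Affine maps from mean step frequency to wavelet centre frequency.

    ``f_cwt = a * f_step + b`` with one (a, b) pair for IC and one for FC
    detection.  The packaged defaults were fitted by
    :func:`calibrate_scale_relation` on the bundled simulator (see
    docs/methods.md); they can be overridden from the run configuration.
    """

    ic: tuple[float, float] = (2.01, 8.09)
    fc: tuple[float, float] = (10.07, -10.67)
    provenance: str = "default"

    #: lower clamp keeping f_cwt positive over the whole step-frequency band
    F_CWT_FLOOR = 0.5

    def f_cwt_ic(self, f_step: float) -> float:
        return max(self.ic[0] * f_step + self.ic[1], self.F_CWT_FLOOR)

    def f_cwt_fc(self, f_step: float) -> float:
        return max(self.fc[0] * f_step + self.fc[1], self.F_CWT_FLOOR)


@dataclass
class ContactEvents:
    """Ordered IC and FC times (seconds from bout start)."""

    ic: np.ndarray
    fc: np.ndarray
    detector: str = "v3"
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.ic = np.asarray(self.ic, dtype=float)
        self.fc = np.asarray(self.fc, dtype=float)
        for name, arr in (("ic", self.ic), ("fc", self.fc)):
            if arr.size > 1 and np.any(np.diff(arr) <= 0):
                raise ValueError(f"{name} times must be strictly increasing")


def _sigma_peaks(w, fs, prominence_factor, min_dist_s, edge_margin_s):
    """Peaks of a coefficient series with sigma_Wn-relative prominence."""
    sigma = float(np.std(w))
    if sigma == 0:
        return np.array([], dtype=int), sigma
    dist = max(1, int(round(min_dist_s * fs)))
    idx, _ = sps.find_peaks(w, prominence=prominence_factor * sigma,
                            distance=dist)
    margin = int(round(edge_margin_s * fs))
    idx = idx[(idx >= margin) & (idx < w.size - margin)]
    return idx, sigma


def detect_fc_v3(ap, fs, t_step_mean, rel: ScaleRelation | None = None,
                 prominence_factor: float = 0.6, d_frac: float = 0.5):
    """FC events: peaks of the CWT of the AP velocity.

    ``ap`` must already be low-pass filtered (20 Hz).  The CWT scale is set
    from the bout's mean step frequency through the FC scale relation.
    Returns FC times in seconds.
    """
    rel = rel or ScaleRelation()
    f_cwt = rel.f_cwt_fc(1.0 / t_step_mean)
    scale = frequency_to_scale(f_cwt, fs)
    vel = integrate(ap, fs)
    w = -cwt_gaus1(vel, scale)           # peaks = forward-accel maxima
    idx, sigma = _sigma_peaks(w, fs, prominence_factor,
                              d_frac * t_step_mean, 2 * scale / fs)
    if idx.size < 2:
        raise InsufficientEventsError(
            f"only {idx.size} FC candidate(s) found in bout")
    return idx / fs


def _pos_neg_crossings(w, fs):
    """Sub-sample times of positive-to-negative zero crossings."""
    i = np.where((w[:-1] > 0) & (w[1:] <= 0))[0]
    frac = w[i] / (w[i] - w[i + 1])
    return (i + frac) / fs


def detect_ic_v3(ap, fs, t_step_mean, rel: ScaleRelation | None = None,
                 fc=None, prominence_factor: float = 0.6,
                 d_frac: float = 0.5):
    """IC events by backward search from each FC on the smoothed AP jerk.

    For every FC, the latest positive-to-negative zero crossing of the
    coefficient series before the FC (bounded by the previous FC) is
    paired with the latest local minimum preceding that crossing; the IC
    is the midpoint of the two times.  FCs with no valid pair yield no IC.
    """
    rel = rel or ScaleRelation()
    fc = np.asarray(fc, dtype=float)
    if fc.size == 0:
        raise InsufficientEventsError("no FC events to pair ICs with")
    f_cwt = rel.f_cwt_ic(1.0 / t_step_mean)
    scale = frequency_to_scale(f_cwt, fs)
    w = cwt_gaus1(ap, scale)             # pywt sign: the IC complex polarity
    min_idx, sigma = _sigma_peaks(-w, fs, prominence_factor,
                                  d_frac * t_step_mean, 2 * scale / fs)
    if sigma == 0:
        raise InsufficientEventsError("flat coefficient series")
    t_min = min_idx / fs
    t_cross = _pos_neg_crossings(w, fs)

    ics = []
    for k, t_fc in enumerate(fc):
        lo = fc[k - 1] if k > 0 else 0.0
        cand_cross = t_cross[(t_cross > lo) & (t_cross < t_fc)]
        if cand_cross.size == 0:
            continue
        tc = cand_cross[-1]
        cand_min = t_min[(t_min > lo) & (t_min < tc)]
        if cand_min.size == 0:
            continue
        ics.append(0.5 * (tc + cand_min[-1]))
    if not ics:
        raise InsufficientEventsError("no FC could be paired with an IC")
    return np.unique(np.asarray(ics))


def downsample(x, fs, fs_out):
    """Polyphase antialiased resampling to ``fs_out`` (used by the legacy
    detector, which runs at 50 Hz)."""
    from fractions import Fraction

    if fs == fs_out:
        return np.asarray(x, dtype=float), fs
    frac = Fraction(fs_out / fs).limit_denominator(1000)
    y = sps.resample_poly(np.asarray(x, dtype=float), frac.numerator,
                          frac.denominator)
    return y, fs * frac.numerator / frac.denominator


def detect_events_v2(vert, fs, scale: float = 8.0,
                     height_factor: float = 0.5, v2_fs: float = 50.0):
    """Legacy "m" method on the vertical signal.

    The vertical acceleration is down-sampled to 50 Hz, mean-removed and
    integrated; the CWT of the result is the smoothed vertical acceleration
    whose peaks (height > 0.5 SD) are IC estimates; a second CWT pass gives
    the smoothed jerk whose peaks are FC estimates.  Default scale 8
    corresponds to 1.25 Hz at 50 Hz.
    """
    vert = np.asarray(vert, dtype=float)
    x, fs_d = downsample(vert, fs, v2_fs)
    x = x - x.mean()
    vel = integrate(x, fs_d)
    w1 = -cwt_gaus1(vel, scale)          # smoothed vertical acceleration
    margin = int(round(2 * scale))
    sd1 = np.std(w1)
    if sd1 == 0:
        return np.array([]), np.array([])
    ic_idx, _ = sps.find_peaks(w1, height=height_factor * sd1)
    ic_idx = ic_idx[(ic_idx >= margin) & (ic_idx < w1.size - margin)]

    w2 = -cwt_gaus1(w1, scale)           # smoothed vertical jerk
    sd2 = np.std(w2)
    fc_idx, _ = sps.find_peaks(w2, height=height_factor * sd2)
    fc_idx = fc_idx[(fc_idx >= margin) & (fc_idx < w2.size - margin)]
    return ic_idx / fs_d, fc_idx / fs_d


def calibrate_scale_relation(bouts, grid, lam: float = 1.0,
                             window: float = 0.3,
                             prominence_factor: float = 0.6,
                             d_frac: float = 0.5) -> ScaleRelation:
    """Fit the step-frequency -> wavelet-frequency relations on labelled data.

    ``bouts`` is a sequence of ``(recording, (ic_ref, fc_ref))`` tuples.
    For each bout and candidate wavelet frequency the detector is run and
    scored with ``cost = (1 - F1) + lam * RMSE`` against the reference
    events; the per-bout optimum frequencies are regressed (least squares)
    on the bout's mean step frequency.
    """
    from .bout import build_profile
    from .evaluate import match_events

    grid = np.asarray(grid, dtype=float)
    if len(bouts) < 3:
        raise CalibrationError("need at least 3 labelled bouts")

    rows = []       # (f_step, f_opt_fc, f_opt_ic)
    diagnostics = []
    for rec, (ic_ref, fc_ref) in bouts:
        profile = build_profile(rec)
        ap = profile.ap[1] * rec.a[:, profile.ap[0]]
        ap20 = butterworth_filter(ap, rec.fs, "lowpass", 20.0)
        region = (2.0, rec.duration - 2.0)

        def cost_of(f_cwt, kind, fc_base=None):
            rel = ScaleRelation(ic=(0.0, f_cwt), fc=(0.0, f_cwt),
                                provenance="sweep")
            try:
                if kind == "fc":
                    det = detect_fc_v3(ap20, rec.fs, profile.t_step_mean,
                                       rel, prominence_factor, d_frac)
                    ref = fc_ref
                else:
                    det = detect_ic_v3(ap20, rec.fs, profile.t_step_mean,
                                       rel, fc_base, prominence_factor,
                                       d_frac)
                    ref = ic_ref
            except (InsufficientEventsError, ValueError):
                return np.inf, None
            rep = match_events(det, ref, window=window, region=region)
            if rep.f1 is None or rep.tp == 0:
                return np.inf, det
            rmse = float(np.sqrt(np.mean(rep.errors ** 2)))
            return (1.0 - rep.f1) + lam * rmse, det

        costs_fc = [cost_of(f, "fc")[0] for f in grid]
        f_fc = grid[int(np.argmin(costs_fc))]
        _, fc_det = cost_of(f_fc, "fc")
        costs_ic = [cost_of(f, "ic", fc_det)[0] for f in grid]
        f_ic = grid[int(np.argmin(costs_ic))]
        rows.append((profile.f_step_mean, f_fc, f_ic))
        diagnostics.append({"f_step": profile.f_step_mean,
                            "f_opt_fc": float(f_fc), "f_opt_ic": float(f_ic),
                            "cost_fc": float(np.min(costs_fc)),
                            "cost_ic": float(np.min(costs_ic))})

    rows = np.asarray(rows)
    if np.ptp(rows[:, 0]) < 1e-9:
        raise CalibrationError(
            "all bouts share one step frequency; affine fit degenerate")
    A = np.column_stack([rows[:, 0], np.ones(rows.shape[0])])
    a_fc, b_fc = np.linalg.lstsq(A, rows[:, 1], rcond=None)[0]
    a_ic, b_ic = np.linalg.lstsq(A, rows[:, 2], rcond=None)[0]
    rel = ScaleRelation(ic=(float(a_ic), float(b_ic)),
                        fc=(float(a_fc), float(b_fc)),
                        provenance="calibrated")
    rel.diagnostics = diagnostics
    return rel
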