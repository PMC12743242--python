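"""Inverted-pendulum spatial model.

Step length from the CoM vertical excursion via the chord of a circular
arc.  Model 1 treats the whole step as one inverted pendulum of leg length
l_leg = 0.53 * height:

    S = 2 * sqrt(2 * l_leg * dh - dh^2)

Model 2 splits the step into a normal pendulum of effective length l2
during initial double support and an inverted pendulum of length l_leg
during single support, summing the two chords.  The extra unknown l2 is
closed with the empirical length-/time-ratio relation

    l2 = C * l_leg * (t_bip / t_sup),   C = 1.1

evaluated with the bout-median phase durations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .preprocessing import integrate

#: fraction of the pendulum length a height excursion is clamped to when a
#: noisy bout produces a geometrically impossible value
_CLAMP_FRAC = 0.95


class InvalidGeometryError(ValueError):
    pass


@dataclass
class PendulumParams:
    """Per-bout lengths of the two-phase pendulum construction."""

    l_leg: float
    l_2: float
    c: float = 1.1
    t_bip_med: float | None = None
    t_sup_med: float | None = None


@dataclass
class StepSpatial:
    """Spatial decomposition of one step."""

    delta_h: float        # total CoM height change over the step, m
    delta_bip: float      # during initial double support
    delta_sup: float      # during single support
    s_bip: float
    s_sup: float
    s_step: float


def com_height_change(vert, fs, window):
    """CoM vertical position trace and total height change over a window.

    The window mean (gravity plus slow drift) is removed from the vertical
    acceleration, which is double-integrated by the cumulative trapezoid
    rule; the position trace is linearly detrended over the window and
    ``delta_h`` is its max - min.  Returns ``(t, trace, delta_h)`` with
    ``t`` in the bout's time frame.

    The detrend line is the chord through the window's endpoint samples
    rather than a least-squares fit: gait steps are near-periodic, so the
    CoM height at consecutive ICs is equal and the endpoint chord is
    exactly the unknown drift line, while a least-squares fit is tilted by
    the asymmetric within-step waveform and inflates the per-phase height
    changes.  (The doubly integrated trace is smooth, so endpoint samples
    are not noise-critical.)
    """
    vert = np.asarray(vert, dtype=float)
    i0 = int(round(window[0] * fs))
    i1 = int(round(window[1] * fs)) + 1
    i0 = max(i0, 0)
    i1 = min(i1, vert.size)
    if i1 - i0 < 3:
        raise ValueError(f"window {window} shorter than 3 samples")
    x = vert[i0:i1] - vert[i0:i1].mean()
    pos = integrate(integrate(x, fs), fs)
    t = np.arange(i0, i1) / fs
    pos = pos - (pos[0] + (pos[-1] - pos[0])
                 * (t - t[0]) / (t[-1] - t[0]))
    return t, pos, float(pos.max() - pos.min())


def _chord(length: float, dh: float) -> float:
    return 2.0 * np.sqrt(max(2.0 * length * dh - dh * dh, 0.0))


def step_length_model1(l_leg: float, delta_h: float) -> float:
    """Single inverted-pendulum chord from the total height change."""
    if delta_h < 0:
        raise InvalidGeometryError(f"negative height change {delta_h}")
    if delta_h > l_leg:
        raise InvalidGeometryError(
            f"height change {delta_h:.3f} m exceeds leg length {l_leg:.3f} m")
    return _chord(l_leg, delta_h)


def l2_from_time_ratio(l_leg: float, t_bip_med: float, t_sup_med: float,
                       c: float = 1.1) -> float:
    """Effective double-support pendulum length from the phase-time ratio."""
    if t_sup_med <= 0:
        raise InvalidGeometryError(
            f"non-positive single-support time {t_sup_med}")
    return c * l_leg * (t_bip_med / t_sup_med)


def _clamped(dh: float, length: float, what: str) -> float:
    if dh > length:
        warnings.warn(
            f"{what} height change {dh:.3f} m exceeds pendulum length "
            f"{length:.3f} m; clamped", stacklevel=3)
        return _CLAMP_FRAC * length
    return dh


def step_length_model2(l_leg: float, l_2: float, delta_bip: float,
                       delta_sup: float) -> StepSpatial:
    """Two-phase pendulum step length.

    Normal-pendulum chord of length ``l_2`` over the double-support height
    change plus inverted-pendulum chord of ``l_leg`` over the single-
    support height change.  Out-of-domain height changes are clamped to
    0.95 of the pendulum length with a warning.
    """
    if delta_bip < 0 or delta_sup < 0:
        raise InvalidGeometryError("height changes must be nonnegative")
    delta_sup = _clamped(delta_sup, l_leg, "single-support")
    delta_bip = _clamped(delta_bip, l_2, "double-support") if l_2 > 0 else 0.0
    s_sup = _chord(l_leg, delta_sup)
    s_bip = _chord(l_2, delta_bip)
    return StepSpatial(delta_h=delta_bip + delta_sup, delta_bip=delta_bip,
                       delta_sup=delta_sup, s_bip=s_bip, s_sup=s_sup,
                       s_step=s_bip + s_sup)


def fill_spatial(strides, vert, fs, l_leg: float, model: int = 2,
                 c: float = 1.1) -> PendulumParams:
    """Fill the spatial fields of assembled steps in place.

    For each step with a following IC, the vertical position trace over
    [IC, IC_next] provides the total height change; the double-support
    portion [IC, FC_opp] and single-support portion [FC_opp, IC_next] of
    the same trace provide the per-phase changes.  Stride length is the
    sum of two consecutive step lengths and gait speed is stride length
    over stride time (within continuity runs only).
    """
    bips = [s.t_bip for s in strides if s.t_sup is not None]
    sups = [s.t_sup for s in strides if s.t_sup is not None]
    l_2 = 0.0
    tb_med = ts_med = None
    if model == 2 and sups:
        tb_med = float(np.median(bips))
        ts_med = float(np.median(sups))
        l_2 = l2_from_time_ratio(l_leg, tb_med, ts_med, c)

    for s in strides:
        if s.ic_next is None:
            continue
        try:
            t, pos, dh = com_height_change(vert, fs, (s.ic, s.ic_next))
        except ValueError:
            continue
        sl_b = pos[t <= s.fc_opp]
        sl_s = pos[t >= s.fc_opp]
        d_bip = float(sl_b.max() - sl_b.min()) if sl_b.size >= 2 else 0.0
        d_sup = float(sl_s.max() - sl_s.min()) if sl_s.size >= 2 else 0.0
        s.delta_h = dh
        s.delta_h_bip = d_bip
        s.delta_h_sup = d_sup
        try:
            if model == 1:
                s.step_length = step_length_model1(l_leg, dh)
            else:
                s.step_length = step_length_model2(l_leg, l_2, d_bip,
                                                   d_sup).s_step
        except InvalidGeometryError as e:
            warnings.warn(f"step at {s.ic:.2f} s discarded: {e}",
                          stacklevel=2)
            s.step_length = None

    for s, s_next in zip(strides, strides[1:]):
        if (s.stride_time is not None and s.step_length is not None
                and s_next.step_length is not None):
            s.stride_length = s.step_length + s_next.step_length
            s.gait_speed = s.stride_length / s.stride_time
    return PendulumParams(l_leg=l_leg, l_2=l_2, c=c,
                          t_bip_med=tb_med, t_sup_med=ts_med)
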