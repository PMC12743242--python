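"""Synthetic lumbar-acceleration walking bouts with exact ground truth.

The generator is kinematic: it prescribes a two-phase pendulum trajectory of
the centre of mass (CoM) — a normal-pendulum arc of effective length ``l2``
during initial double support and an inverted-pendulum arc of leg length
during single support, C1-continuous at the phase boundaries — and emits the
second derivatives as accelerations.  Ground truth (IC/FC times, phase
durations, per-phase CoM excursions, step lengths) is therefore exact by
construction.

The AP channel carries, on top of the arc kinematics, two shaped transients
per step: a one-cycle sinusoidal jerk complex centred so that the smoothed
AP jerk has its positive-to-negative zero crossing and its preceding local
minimum symmetrically around the true IC (the IC midpoint rule lands on the
true IC in the noiseless case), and a Gaussian forward-push bump whose
centre is the true FC (the smoothed AP-velocity-derivative peak lands on the
true FC).  This placement is the generator's testability contract.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize
from scipy.ndimage import gaussian_filter1d

from .io import AccelRecording, G_STANDARD

#: IC jerk-complex half-offset as a fraction of step time: the zero crossing
#: sits at +D_IC_FRAC*T and the preceding minimum at -D_IC_FRAC*T around IC
D_IC_FRAC = 0.08
#: width (SD) of the Gaussian FC forward-push bump, fraction of step time
FC_SIGMA_FRAC = 0.07
#: zero-phase Gaussian band-limiting kernel SD (s) applied to all channels
_SMOOTH_SIGMA_S = 0.010
#: internal synthesis oversampling factor (band-limit before decimating)
_OVERSAMPLE = 8


class SpecError(ValueError):
    pass


@dataclass
class WalkerSpec:
    """Parameters of one simulated steady-walking bout."""

    f_step: float = 1.7            # step frequency, Hz
    duty: float = 0.30             # t_bip / t_step, initial double support
    leg_length: float = 0.90       # m (0.53 x a 1.70 m stature)
    step_length: float = 0.65      # m
    com_amplitude: float | None = None  # total CoM excursion (m); None ->
                                        # closed with l2 = C*l_leg*tb/ts
    duration_s: float = 30.0
    fs: float = 128.0
    tilt_deg: tuple[float, float] = (0.0, 0.0)   # about (ML, AP) axes
    noise_sd: float = 0.0          # additive white noise, m/s^2
    seed: int = 0
    axis_order: tuple[str, str, str] = ("vertical", "ap", "ml")
    ap_ic_amp: float = 1.8         # IC complex acceleration amplitude, m/s^2
    ap_fc_amp: float = 2.0         # FC bump acceleration amplitude, m/s^2
    length_ratio_c: float = 1.1    # C in l2 = C*l_leg*(t_bip/t_sup)

    def __post_init__(self) -> None:
        if not 0.5 <= self.f_step <= 5.0:
            raise SpecError(f"f_step {self.f_step} outside [0.5, 5.0] Hz")
        if not 0.0 < self.duty < 0.5:
            raise SpecError(f"duty {self.duty} outside (0, 0.5)")
        if self.noise_sd < 0:
            raise SpecError("noise SD must be >= 0")
        if self.step_length >= 2 * self.leg_length:
            raise SpecError("step length exceeds pendulum geometry (2*l_leg)")
        if sorted(self.axis_order) != ["ap", "ml", "vertical"]:
            raise SpecError(f"bad axis_order {self.axis_order}")

    @property
    def t_step(self) -> float:
        return 1.0 / self.f_step

    @property
    def t_bip(self) -> float:
        return self.duty / self.f_step

    @property
    def t_sup(self) -> float:
        return (1.0 - self.duty) / self.f_step


@dataclass
class GroundTruth:
    """Exact event times and per-step quantities of a simulated bout."""

    ic: np.ndarray                 # IC times, s
    fc: np.ndarray                 # FC times, s
    t_bip: float
    t_sup: float
    t_step_mean: float
    delta_bip: float               # CoM drop during double support, m
    delta_sup: float               # CoM rise during single support, m
    step_length: float
    s_bip: float
    s_sup: float
    l2: float                      # effective double-support pendulum length
    theta_sup: float = 0.0         # arc half-angles (rad), provenance
    phi_bip: float = 0.0
    com_height: np.ndarray | None = None   # planted CoM height trace, m

    @property
    def delta_h(self) -> float:
        return self.delta_bip + self.delta_sup


def _solve_geometry(spec: WalkerSpec) -> tuple[float, float, float]:
    """Solve the two-phase arc geometry: half-angles and l2.

    Constraints: chord lengths sum to the step length; the vertical CoM
    velocity is continuous at the phase boundaries (C1).  When
    ``com_amplitude`` is given it becomes a third constraint and l2 is free;
    otherwise l2 is closed with the empirical length-/time-ratio relation
    l2 = C * l_leg * (t_bip / t_sup).
    """
    L, S = spec.leg_length, spec.step_length
    tb, ts = spec.t_bip, spec.t_sup

    if spec.com_amplitude is None:
        l2 = spec.length_ratio_c * L * tb / ts

        def eqs(v):
            th, ph = v
            return [
                2 * L * np.sin(th) + 2 * l2 * np.sin(ph) - S,
                L * th * np.sin(th) / ts - l2 * ph * np.sin(ph) / tb,
            ]

        th0 = np.arcsin(min(0.95, S / (2 * (L + l2))))
        sol, info, ier, msg = optimize.fsolve(
            eqs, [th0, th0], full_output=True)
        if ier != 1:
            raise SpecError(f"geometry solve failed: {msg}")
        th, ph = np.abs(sol)
    else:
        A = spec.com_amplitude
        if A >= spec.leg_length:
            raise SpecError("CoM amplitude exceeds leg length")

        def eqs(v):
            th, ph, l2v = v
            return [
                2 * L * np.sin(th) + 2 * l2v * np.sin(ph) - S,
                L * th * np.sin(th) / ts - l2v * ph * np.sin(ph) / tb,
                L * (1 - np.cos(th)) + l2v * (1 - np.cos(ph)) - A,
            ]

        l2g = spec.length_ratio_c * L * tb / ts
        th0 = np.arcsin(min(0.95, S / (2 * (L + l2g))))
        sol, info, ier, msg = optimize.fsolve(
            eqs, [th0, th0, l2g], full_output=True)
        if ier != 1:
            raise SpecError(f"geometry solve failed: {msg}")
        th, ph, l2 = abs(sol[0]), abs(sol[1]), abs(sol[2])
    if th >= np.pi / 2 or ph >= np.pi / 2:
        raise SpecError("geometry infeasible: arc half-angle >= 90 deg")
    return float(th), float(ph), float(l2)


def _phase_signals(spec: WalkerSpec, tau: np.ndarray,
                   th: float, ph: float, l2: float):
    """Piecewise arc height, vertical accel and AP arc accel vs step phase."""
    L = spec.leg_length
    tb, ts = spec.t_bip, spec.t_sup
    wb, ws = 2 * ph / tb, 2 * th / ts

    in_bip = tau < tb
    phi = -ph + wb * tau                     # double support angle
    theta = -th + ws * (tau - tb)            # single support angle

    # heights, offset so the two pieces join continuously
    h_b = -l2 * np.cos(phi) + l2 * np.cos(ph) + L * np.cos(th)
    h_s = L * np.cos(theta)
    h = np.where(in_bip, h_b, h_s)

    hdd = np.where(in_bip, l2 * wb ** 2 * np.cos(phi),
                   -L * ws ** 2 * np.cos(theta))
    ap_arc = np.where(in_bip, -l2 * wb ** 2 * np.sin(phi),
                      -L * ws ** 2 * np.sin(theta))
    return h, hdd, ap_arc


def _ic_complex(spec: WalkerSpec, dt: np.ndarray) -> np.ndarray:
    """AP acceleration transient around each IC (dt = time since nearest IC).

    The waveform is -amp * cos(w * (dt - d)) with w = 3*pi/(4*d), windowed
    over two cosine cycles whose endpoints fall on cosine zeros (phase
    [-7*pi/2, pi/2], i.e. dt in [-11d/3, 5d/3]) so the acceleration is
    continuous.  Its jerk is a sine whose smoothed, sign-flipped version —
    the IC-detection CWT coefficient series — has its latest local minimum
    at dt = -d and its latest positive-to-negative zero crossing at
    dt = +d: the midpoint rule lands on the true IC.
    """
    d = D_IC_FRAC * spec.t_step
    w = 3 * np.pi / (4 * d)
    out = np.zeros_like(dt)
    m = (dt >= -11 * d / 3) & (dt <= 5 * d / 3)
    out[m] = -spec.ap_ic_amp * np.cos(w * (dt[m] - d))
    return out


def simulate_bout(spec: WalkerSpec) -> tuple[AccelRecording, GroundTruth]:
    """Generate one steady-walking bout with exact ground truth."""
    th, ph, l2 = _solve_geometry(spec)
    T = spec.t_step
    n = int(round(spec.duration_s * spec.fs)) + 1

    # synthesize on an oversampled grid, band-limit the phase-boundary
    # acceleration steps with a zero-phase Gaussian (~10 ms impact smear),
    # then decimate back to fs: the emitted samples are those of a smooth
    # band-limited signal, so trapezoid double integration downstream is
    # consistent with the planted trajectory.  The same kernel is applied
    # to the planted height trace, preserving feature locations exactly.
    ovs = _OVERSAMPLE
    fs_hi = spec.fs * ovs
    t_hi = np.arange((n - 1) * ovs + 1) / fs_hi
    t0 = 0.5 * spec.t_sup            # first IC; leaves a partial lead-in step
    tau = np.mod(t_hi - t0, T)
    h, hdd, ap_arc = _phase_signals(spec, tau, th, ph, l2)

    # signed time to nearest IC / nearest FC
    dt_ic = np.mod(t_hi - t0 + T / 2, T) - T / 2
    dt_fc = np.mod(t_hi - t0 - spec.t_bip + T / 2, T) - T / 2
    sig_fc = FC_SIGMA_FRAC * T
    ap = (ap_arc + _ic_complex(spec, dt_ic)
          + spec.ap_fc_amp * np.exp(-dt_fc ** 2 / (2 * sig_fc ** 2)))

    sig_k = _SMOOTH_SIGMA_S * fs_hi
    hdd = gaussian_filter1d(hdd, sig_k, mode="nearest")[::ovs]
    ap = gaussian_filter1d(ap, sig_k, mode="nearest")[::ovs]
    h = gaussian_filter1d(h, sig_k, mode="nearest")[::ovs]
    t = t_hi[::ovs]

    vert = hdd - hdd.mean() - G_STANDARD   # sensor reads -g at rest
    rng = np.random.default_rng(spec.seed)
    ml = np.zeros_like(t)

    body = np.column_stack([vert, ap, ml])          # (vertical, ap, ml)
    if any(spec.tilt_deg):
        a_ml, a_ap = np.deg2rad(spec.tilt_deg)
        # tilt about ML mixes vertical/AP; tilt about AP mixes vertical/ML
        c, s = np.cos(a_ml), np.sin(a_ml)
        r_ml = np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
        c, s = np.cos(a_ap), np.sin(a_ap)
        r_ap = np.array([[c, 0.0, -s], [0.0, 1.0, 0.0], [s, 0.0, c]])
        body = body @ (r_ap @ r_ml).T
    if spec.noise_sd > 0:
        body = body + rng.normal(0.0, spec.noise_sd, size=body.shape)

    a = np.empty_like(body)
    a[:, spec.axis_order.index("vertical")] = body[:, 0]
    a[:, spec.axis_order.index("ap")] = body[:, 1]
    a[:, spec.axis_order.index("ml")] = body[:, 2]

    ic = t0 + T * np.arange(int(np.floor((spec.duration_s - t0) / T)) + 1)
    ic = ic[ic <= t[-1]]
    fc = ic + spec.t_bip
    fc = fc[fc <= t[-1]]

    rec = AccelRecording(
        t=t, a=a, fs=spec.fs,
        meta={"source": "lumbargait.simulate", "seed": spec.seed,
              "axis_order": list(spec.axis_order)})
    gt = GroundTruth(
        ic=ic, fc=fc, t_bip=spec.t_bip, t_sup=spec.t_sup, t_step_mean=T,
        delta_bip=l2 * (1 - np.cos(ph)), delta_sup=spec.leg_length * (1 - np.cos(th)),
        step_length=spec.step_length,
        s_bip=2 * l2 * np.sin(ph), s_sup=2 * spec.leg_length * np.sin(th),
        l2=l2, theta_sup=th, phi_bip=ph, com_height=h)
    return rec, gt


def default_grid(duration_s: float = 30.0, seed: int = 0) -> list[WalkerSpec]:
    """The 12-fixture design: 3 cadences x (no/moderate noise) x (0/5 deg).

    Step length and duty factor co-vary with cadence the way they do in
    healthy self-paced walking (slow walks take shorter steps with longer
    double support).  "Moderate" noise is 10 dB SNR relative to the
    dynamic (gravity-free) acceleration of the noiseless bout.
    """
    specs = []
    k = 0
    for f in (1.2, 1.7, 2.2):
        step_len = 0.5 + 0.25 * (f - 1.2)
        duty = 0.38 - 0.05 * f
        for noisy in (False, True):
            for tilt in (0.0, 5.0):
                spec = WalkerSpec(
                    f_step=f, duty=round(duty, 3), step_length=round(step_len, 3),
                    duration_s=duration_s, tilt_deg=(tilt, 0.0),
                    noise_sd=0.0, seed=seed + k)
                if noisy:
                    spec.noise_sd = round(_snr_noise_sd(spec, snr_db=10.0), 4)
                specs.append(spec)
                k += 1
    return specs


def _snr_noise_sd(spec: WalkerSpec, snr_db: float) -> float:
    """Noise SD giving the requested SNR on the AP channel.

    The AP trace is the detection signal, so the signal-to-noise ratio is
    referenced to its dynamic (mean-removed) RMS; 10 dB is far above the
    noise floor of any wearable-grade accelerometer and serves as a
    stress condition.
    """
    clean = WalkerSpec(**{**spec.__dict__, "noise_sd": 0.0, "tilt_deg": (0.0, 0.0)})
    rec, _ = simulate_bout(clean)
    ap = rec.a[:, clean.axis_order.index("ap")]
    rms = float(np.sqrt(np.mean((ap - ap.mean()) ** 2)))
    return rms / 10 ** (snr_db / 20.0)


def make_test_suite(grid: list[WalkerSpec] | None = None, out_dir=None):
    """Simulate a grid of bouts; optionally write CSV fixtures + manifest."""
    grid = grid if grid is not None else default_grid()
    if not grid:
        raise SpecError("empty fixture grid")
    fixtures = []
    for i, spec in enumerate(grid):
        rec, gt = simulate_bout(spec)
        fixtures.append({"name": f"fixture_{i:02d}", "spec": spec,
                         "recording": rec, "ground_truth": gt})
    if out_dir is not None:
        import json
        from pathlib import Path

        import pandas as pd

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        manifest = []
        for fx in fixtures:
            rec, gt, spec = fx["recording"], fx["ground_truth"], fx["spec"]
            base = out / fx["name"]
            pd.DataFrame({
                "time": rec.t, "ax": rec.a[:, 0], "ay": rec.a[:, 1],
                "az": rec.a[:, 2]}).to_csv(
                    f"{base}_accel.csv", index=False, float_format="%.9f")
            rows = [(x, "IC") for x in gt.ic] + [(x, "FC") for x in gt.fc]
            rows.sort()
            pd.DataFrame(rows, columns=["time", "event"]).to_csv(
                f"{base}_events.csv", index=False, float_format="%.9f")
            manifest.append({
                "name": fx["name"], "f_step": spec.f_step, "duty": spec.duty,
                "step_length": spec.step_length, "noise_sd": spec.noise_sd,
                "tilt_deg": list(spec.tilt_deg), "seed": spec.seed,
                "n_ic": int(gt.ic.size), "n_fc": int(gt.fc.size),
                "delta_bip": gt.delta_bip, "delta_sup": gt.delta_sup,
                "l2": gt.l2})
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return fixtures
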