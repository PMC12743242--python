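"""Reading, writing and run configuration.

Raw recordings are delimited text files with a time column and three
acceleration columns.  Internally everything is held in SI units (m/s^2,
seconds from bout start) on a uniform sampling grid.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

#: standard gravity, used for g -> m/s^2 conversion
G_STANDARD = 9.80665

#: maximum timestamp jitter (s) tolerated before resampling kicks in
_JITTER_TOL = 1e-4


class FormatError(ValueError):
    """Input file does not have the expected columns/layout."""


class DataError(ValueError):
    """Input data violate a precondition (non-monotone time, too short...)."""


@dataclass
class AccelRecording:
    """Uniformly sampled tri-axial acceleration for one walking bout.

    Attributes
    ----------
    t : ndarray
        Time in seconds from bout start, strictly increasing, uniform grid.
    a : ndarray, shape (n, 3)
        Acceleration in m/s^2.  Gravity is present in the raw signal.
    fs : float
        Sampling rate in Hz.
    meta : dict
        Free-form provenance (source file, original units, axis order).
    """

    t: np.ndarray
    a: np.ndarray
    fs: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.a = np.asarray(self.a, dtype=float)
        if self.fs <= 0:
            raise DataError(f"sampling rate must be positive, got {self.fs}")
        if self.a.ndim != 2 or self.a.shape[1] != 3:
            raise FormatError(f"expected (n, 3) acceleration, got {self.a.shape}")
        if self.a.shape[0] != self.t.shape[0]:
            raise FormatError("time and acceleration lengths differ")
        if self.t.shape[0] < 2:
            raise DataError("recording needs at least 2 samples")
        dt = np.diff(self.t)
        if np.any(dt <= 0):
            raise DataError("time must be strictly increasing")
        if abs(np.median(dt) - 1.0 / self.fs) > 1e-6:
            raise DataError("time grid inconsistent with stated sampling rate")

    @property
    def n(self) -> int:
        return self.t.shape[0]

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0])

    def require_processable(self) -> None:
        """Entry-point check: at least 2 s of data."""
        if self.n < 2 * self.fs:
            raise DataError(
                f"recording too short: {self.n} samples < {2 * self.fs:.0f} "
                "(2 s) required for processing"
            )


@dataclass
class RunConfig:
    """Every tunable parameter of the pipeline, with paper-stated defaults.

    Serializable to/from a single YAML file; the effective configuration of a
    run is echoed into the output metadata sidecar.
    """

    # --- input handling -------------------------------------------------
    units: str = "m/s2"              # "m/s2" | "g"
    time_col: str = "time"
    accel_cols: tuple[str, str, str] = ("ax", "ay", "az")
    height_m: float = 1.70           # participant height; l_leg = 0.53 * height
    detector: str = "v3"             # "v3" | "v2"

    # --- preprocessing --------------------------------------------------
    bandpass_hz: tuple[float, float] = (0.25, 7.5)   # axis/step-freq stage
    bandpass_order: int = 4
    lowpass_hz: float = 20.0                          # contact-detection stage
    lowpass_order: int = 4

    # --- mean step frequency estimation ---------------------------------
    step_freq_band: tuple[float, float] = (0.5, 5.0)
    step_freq_n_scales: int = 10
    step_freq_scale_spacing: str = "linear"           # "linear" | "log"
    cwt_power_mode: str = "signed"                    # "signed" | "abs" | "square"
    acov_window_s: float = 5.0
    acov_overlap: float = 0.5
    acov_min_lag_s: float = 0.2
    acov_max_lag_s: float = 2.0
    acov_peak_prominence: float = 0.1                 # fraction of lag-0 value

    # --- contact detection (v3) -----------------------------------------
    prominence_factor: float = 0.6                    # x sigma_Wn
    d_frac: float = 0.5                               # min peak distance x t_step
    # affine step-frequency -> wavelet-frequency relations, f_cwt = a*f + b;
    # defaults calibrated on the packaged simulator (see docs/methods.md)
    ic_relation: tuple[float, float] = (2.01, 8.09)
    fc_relation: tuple[float, float] = (10.07, -10.67)

    # --- contact detection (v2 comparator) ------------------------------
    v2_fs: float = 50.0
    v2_scale: float = 8.0                             # 1.25 Hz at 50 Hz
    v2_height_factor: float = 0.5                     # x signal SD

    # --- step QC ---------------------------------------------------------
    qc_mode: str = "dynamic"                          # "dynamic" | "static"
    static_t_max_stride: float = 2.25
    static_c_loading: float = 0.2

    # --- spatial model ---------------------------------------------------
    pendulum_model: int = 2                           # 1 | 2
    length_ratio_c: float = 1.1                       # C in l2 = C*l_leg*tb/ts
    leg_length_factor: float = 0.53

    # --- evaluation -------------------------------------------------------
    match_window_s: float = 0.3                       # total window (+/- 0.15)

    def __post_init__(self) -> None:
        if self.units not in ("m/s2", "g"):
            raise ValueError(f"units must be 'm/s2' or 'g', got {self.units!r}")
        if self.detector not in ("v3", "v2"):
            raise ValueError(f"detector must be 'v3' or 'v2', got {self.detector!r}")
        self.accel_cols = tuple(self.accel_cols)
        self.bandpass_hz = tuple(self.bandpass_hz)
        self.step_freq_band = tuple(self.step_freq_band)
        self.ic_relation = tuple(self.ic_relation)
        self.fc_relation = tuple(self.fc_relation)

    @property
    def leg_length(self) -> float:
        return self.leg_length_factor * self.height_m

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        return d

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def read_recording(path, cfg: RunConfig | None = None) -> AccelRecording:
    """Read a delimited-text recording and normalize it.

    Units are converted to m/s^2, time is rebased to start at 0, and
    irregular timestamps (jitter > 0.1 ms) are repaired by linear
    interpolation onto the nominal uniform grid.
    """
    cfg = cfg or RunConfig()
    path = Path(path)
    df = pd.read_csv(path, sep=None, engine="python")
    missing = [c for c in (cfg.time_col, *cfg.accel_cols) if c not in df.columns]
    if missing:
        raise FormatError(f"missing columns {missing} in {path.name}; "
                          f"found {list(df.columns)}")
    t = df[cfg.time_col].to_numpy(dtype=float)
    a = df[list(cfg.accel_cols)].to_numpy(dtype=float)
    if t.size < 2:
        raise DataError("fewer than 2 samples")
    if np.any(np.diff(t) < 0):
        raise DataError("time column is non-monotone")
    t = t - t[0]
    if cfg.units == "g":
        a = a * G_STANDARD

    dt = np.diff(t)
    dt_nom = float(np.median(dt))
    if dt_nom <= 0:
        raise DataError("degenerate time grid (zero median step)")
    fs = 1.0 / dt_nom
    if t[-1] < 2.0:
        raise DataError(f"recording too short: {t[-1]:.3f} s < 2 s")

    jitter = np.max(np.abs(dt - dt_nom))
    if jitter > _JITTER_TOL:
        # repair onto uniform grid of the same duration; duplicated stamps
        # are collapsed before interpolating
        tu, idx = np.unique(t, return_index=True)
        n_out = int(round(t[-1] / dt_nom)) + 1
        t_new = np.arange(n_out) * dt_nom
        a = np.column_stack(
            [np.interp(t_new, tu, a[idx, j]) for j in range(3)]
        )
        t = t_new

    meta = {"source": str(path), "original_units": cfg.units,
            "columns": list(cfg.accel_cols)}
    return AccelRecording(t=t, a=a, fs=fs, meta=meta)


#: columns of the stride table, in output order
STRIDE_COLUMNS = [
    "ic", "fc_opp", "fc_same", "step_time", "stride_time", "stance",
    "t_bip", "t_sup", "delta_h", "step_length", "stride_length",
    "gait_speed", "cadence",
]


def write_stride_table(strides, path) -> None:
    """Write one row per QC-passed step; empty input writes just the header."""
    rows = []
    for s in strides:
        rows.append({c: getattr(s, c, None) for c in STRIDE_COLUMNS})
    df = pd.DataFrame(rows, columns=STRIDE_COLUMNS)
    df.to_csv(path, index=False, float_format="%.12g")


def read_stride_table(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_events(ic, fc, path) -> None:
    """Two-column CSV of event times and types, ordered in time."""
    rows = [(t, "IC") for t in ic] + [(t, "FC") for t in fc]
    rows.sort()
    pd.DataFrame(rows, columns=["time", "event"]).to_csv(
        path, index=False, float_format="%.9f")


def read_events(path) -> tuple[np.ndarray, np.ndarray]:
    df = pd.read_csv(path)
    ic = df.loc[df["event"] == "IC", "time"].to_numpy(dtype=float)
    fc = df.loc[df["event"] == "FC", "time"].to_numpy(dtype=float)
    return np.sort(ic), np.sort(fc)


def write_run_metadata(path, cfg: RunConfig, extra: dict | None = None) -> None:
    """JSON sidecar echoing the effective configuration of a run."""
    from . import __version__

    payload = {"software": "lumbargait", "version": __version__,
               "config": cfg.to_dict()}
    if extra:
        payload.update(extra)
    Path(path).write_text(json.dumps(payload, indent=2, default=float))
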