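"""Scoring detected events and metrics against a reference.

Event matching is one-to-one within a total window of 0.3 s (0.15 s each
side), solved as an optimal assignment (maximum matched count, then minimum
total absolute error).  Agreement between paired measurement methods is
summarised with ICC(2,1): single-measure, two-way random effects, absolute
agreement.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

_BIG = 1e9


@dataclass
class EvalReport:
    """Event-matching outcome.

    Signed errors follow the detected-minus-reference convention (positive
    means late detection).  Ratio metrics with zero denominators are
    ``None`` (undefined), not 0.
    """

    tp: int
    fp: int
    fn: int
    errors: np.ndarray = field(default_factory=lambda: np.array([]))
    window: float = 0.3

    @property
    def sensitivity(self):
        d = self.tp + self.fn
        return self.tp / d if d else None

    @property
    def precision(self):
        d = self.tp + self.fp
        return self.tp / d if d else None

    @property
    def f1(self):
        s, p = self.sensitivity, self.precision
        if s is None or p is None or (s + p) == 0:
            return None
        return 2 * p * s / (p + s)

    @property
    def mae(self):
        return float(np.mean(np.abs(self.errors))) if self.errors.size else None


def _in_region(times, region):
    if region is None:
        return np.ones(times.size, dtype=bool)
    region = np.atleast_2d(np.asarray(region, dtype=float))
    mask = np.zeros(times.size, dtype=bool)
    for lo, hi in region:
        mask |= (times >= lo) & (times <= hi)
    return mask


def match_events(detected, reference, window: float = 0.3,
                 region=None) -> EvalReport:
    """One-to-one matching of detected to reference event times.

    ``window`` is the total matching window (events match within
    +/- window/2).  ``region`` is an optional interval (or list of
    intervals); detected events outside it are ignored rather than counted
    as false positives, and reference events outside it are excluded — the
    reference only exists inside its measurement area.
    """
    detected = np.sort(np.asarray(detected, dtype=float))
    reference = np.sort(np.asarray(reference, dtype=float))
    detected = detected[_in_region(detected, region)]
    reference = reference[_in_region(reference, region)]
    half = window / 2.0

    if detected.size == 0 or reference.size == 0:
        return EvalReport(tp=0, fp=int(detected.size),
                          fn=int(reference.size), window=window)

    diff = np.abs(reference[:, None] - detected[None, :])
    cost = np.where(diff <= half, diff, _BIG)
    ri, di = linear_sum_assignment(cost)
    ok = cost[ri, di] <= half
    ri, di = ri[ok], di[ok]
    errors = detected[di] - reference[ri]
    tp = int(ri.size)
    return EvalReport(tp=tp, fp=int(detected.size - tp),
                      fn=int(reference.size - tp),
                      errors=errors, window=window)


@dataclass
class ICCResult:
    icc: float
    ci_low: float
    ci_high: float


def icc_2_1(data) -> ICCResult:
    """ICC(2,1): two-way random effects, absolute agreement, single measure.

    ``data`` is a subjects x raters matrix with no missing cells.  The
    confidence interval is the standard F-distribution one.
    """
    import pingouin as pg

    data = np.asarray(data, dtype=float)
    if data.ndim != 2 or data.shape[0] < 2 or data.shape[1] < 2:
        raise ValueError("need a (>=2 subjects) x (>=2 raters) matrix")
    if np.any(~np.isfinite(data)):
        raise ValueError("missing/non-finite cells are not supported")
    n, k = data.shape
    if np.allclose(data.var(axis=1, ddof=0).sum() + data.mean(1).var(), 0):
        warnings.warn("degenerate data (zero variance)", stacklevel=2)
    if np.ptp(data.mean(axis=1)) == 0:
        warnings.warn("zero between-subject variance; ICC degenerate",
                      stacklevel=2)

    long = pd.DataFrame({
        "subject": np.repeat(np.arange(n), k),
        "rater": np.tile(np.arange(k), n),
        "score": data.ravel(),
    })
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = pg.intraclass_corr(long, targets="subject", raters="rater",
                                 ratings="score")
    # single-measure absolute agreement: labelled ICC2 or ICC(A,1)
    # depending on the pingouin version
    row = res.loc[res["Type"].isin(["ICC2", "ICC(A,1)"])].iloc[0]
    ci_col = "CI95%" if "CI95%" in res.columns else "CI95"
    lo, hi = row[ci_col]
    return ICCResult(icc=float(row["ICC"]), ci_low=float(lo),
                     ci_high=float(hi))
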