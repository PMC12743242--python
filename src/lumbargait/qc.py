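"""Step assembly and physiological quality control.

Steps are groups of one IC and two FCs (opposite then same side).  Three
QC rules bound the loading (initial double support) time, the stance time
and the stride time.  The limits derive from two parameters — the maximum
stride time and a loading factor — which are either the legacy static
values (2.25 s, 0.2) or dynamic functions of the bout's mean step time:

    t_max_stride = 2 * t_step_mean + 1        (at least 2 SDs above the
                                               expected mean stride time)
    C_loading    = 0.17 * t_step_mean + 0.05
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


class ParameterError(ValueError):
    pass


@dataclass(frozen=True)
class QCThresholds:
    t_max_stride: float            # s
    c_loading: float               # dimensionless

    @property
    def max_loading(self) -> float:
        """Rule 1 limit: loading time < C_loading * t_max_stride."""
        return self.c_loading * self.t_max_stride

    @property
    def max_stance(self) -> float:
        """Rule 2 limit: stance < t_max_stride / 2 + max loading."""
        return self.t_max_stride / 2.0 + self.max_loading


def dynamic_thresholds(t_step_mean: float) -> QCThresholds:
    """Cadence-adaptive thresholds from the bout's mean step time."""
    if not 0.2 <= t_step_mean <= 2.0:
        raise ParameterError(
            f"mean step time {t_step_mean} s outside [0.2, 2.0] s")
    return QCThresholds(t_max_stride=2.0 * t_step_mean + 1.0,
                        c_loading=0.17 * t_step_mean + 0.05)


def static_thresholds(t_max_stride: float = 2.25,
                      c_loading: float = 0.2) -> QCThresholds:
    """Legacy fixed thresholds (adult defaults)."""
    return QCThresholds(t_max_stride=t_max_stride, c_loading=c_loading)


@dataclass
class StrideRecord:
    """One QC-passed step with its phase decomposition.

    Temporal fields are set at assembly; spatial fields (``delta_h``,
    ``step_length``...) are filled by the spatial model.  ``ic_next``,
    ``t_step`` and ``t_sup`` are ``None`` for the terminal step of a
    continuity run; ``stride_time`` additionally needs the following step.
    """

    ic: float
    fc_opp: float
    fc_same: float
    ic_next: float | None = None
    stride_time: float | None = None
    # spatial (filled later)
    delta_h: float | None = None
    delta_h_bip: float | None = None
    delta_h_sup: float | None = None
    step_length: float | None = None
    stride_length: float | None = None
    gait_speed: float | None = None
    cadence: float | None = None

    @property
    def t_bip(self) -> float:
        """Initial double support: IC to opposite-side FC."""
        return self.fc_opp - self.ic

    @property
    def stance(self) -> float:
        """IC to same-side FC."""
        return self.fc_same - self.ic

    @property
    def t_step(self) -> float | None:
        return None if self.ic_next is None else self.ic_next - self.ic

    #: alias used in tabular output
    @property
    def step_time(self) -> float | None:
        return self.t_step

    @property
    def t_sup(self) -> float | None:
        """Single support: step time minus initial double support."""
        return None if self.t_step is None else self.t_step - self.t_bip


def assemble_strides(events, thr: QCThresholds,
                     return_rejections: bool = False):
    """Group IC/FC events into QC-passed steps and chain them into strides.

    Greedy left-to-right grouping: each IC takes the first two following
    FCs as opposite- and same-side contacts.  When two ICs would share a
    first FC the later IC wins (the earlier one would imply an implausibly
    long loading phase).  Continuity requires one step's same-side FC to be
    the next step's opposite-side FC; breaks partition the bout into runs,
    and stride time (two consecutive step times) is only defined within a
    run and only kept when it passes rule 3 (stride time < t_max_stride).
    """
    ic = np.asarray(events.ic, dtype=float)
    fc = np.asarray(events.fc, dtype=float)
    rejected = []
    steps: list[StrideRecord] = []

    for k, t_ic in enumerate(ic):
        later = fc[fc > t_ic]
        if later.size < 2:
            rejected.append((t_ic, "fewer than 2 FCs after IC"))
            continue
        fc_opp, fc_same = later[0], later[1]
        if k + 1 < ic.size and ic[k + 1] < fc_opp:
            rejected.append((t_ic, "superseded by later IC before first FC"))
            continue
        cand = StrideRecord(ic=t_ic, fc_opp=fc_opp, fc_same=fc_same)
        if not cand.t_bip < thr.max_loading:
            rejected.append((t_ic, f"loading {cand.t_bip:.3f} s >= "
                             f"{thr.max_loading:.3f} s"))
            continue
        if not cand.stance < thr.max_stance:
            rejected.append((t_ic, f"stance {cand.stance:.3f} s >= "
                             f"{thr.max_stance:.3f} s"))
            continue
        steps.append(cand)

    # continuity chaining: fc_same of one step == fc_opp of the next
    for s, s_next in zip(steps, steps[1:]):
        if s.fc_same == s_next.fc_opp:
            s.ic_next = s_next.ic

    # stride time across unbroken consecutive pairs, rule 3
    for s, s_next in zip(steps, steps[1:]):
        if s.ic_next is not None and s_next.ic_next is not None:
            stride = s.t_step + s_next.t_step
            if stride < thr.t_max_stride:
                s.stride_time = stride
            else:
                rejected.append((s.ic, f"stride {stride:.3f} s >= "
                                 f"{thr.t_max_stride:.3f} s"))
    if return_rejections:
        return steps, rejected
    return steps
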