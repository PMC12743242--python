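"""End-to-end processing of one walking bout."""

from __future__ import annotations

from dataclasses import dataclass

from . import bout as bout_mod
from . import metrics as metrics_mod
from . import qc as qc_mod
from . import spatial as spatial_mod
from .events import ContactEvents, ScaleRelation, detect_events_v2, detect_fc_v3, detect_ic_v3
from .io import AccelRecording, RunConfig
from .preprocessing import butterworth_filter, tilt_correct


@dataclass
class GaitResult:
    profile: bout_mod.BoutProfile
    events: ContactEvents
    strides: list
    table: metrics_mod.GaitMetricsTable
    pendulum: spatial_mod.PendulumParams
    config: RunConfig


def process_recording(rec: AccelRecording, cfg: RunConfig | None = None) -> GaitResult:
    """Run the full pipeline on one bout.

    Stages: axis identification and mean-step-frequency estimation; tilt
    correction; contact-event detection (current AP-signal detector or the
    legacy vertical-signal comparator); step assembly under the QC
    thresholds (dynamic or static per config); pendulum spatial model;
    metric tabulation.
    """
    cfg = cfg or RunConfig()
    rec.require_processable()
    profile = bout_mod.build_profile(rec, cfg)
    rec_c = tilt_correct(rec, profile.vertical)
    v_idx, v_sign = profile.vertical
    a_idx, a_sign = profile.ap
    vert = v_sign * rec_c.a[:, v_idx]
    ap = a_sign * rec_c.a[:, a_idx]

    if cfg.detector == "v3":
        rel = ScaleRelation(ic=cfg.ic_relation, fc=cfg.fc_relation)
        ap20 = butterworth_filter(ap, rec.fs, "lowpass", cfg.lowpass_hz,
                                  cfg.lowpass_order)
        fc = detect_fc_v3(ap20, rec.fs, profile.t_step_mean, rel,
                          cfg.prominence_factor, cfg.d_frac)
        ic = detect_ic_v3(ap20, rec.fs, profile.t_step_mean, rel, fc,
                          cfg.prominence_factor, cfg.d_frac)
        events = ContactEvents(ic=ic, fc=fc, detector="v3",
                               provenance={
                                   "f_cwt_ic": rel.f_cwt_ic(profile.f_step_mean),
                                   "f_cwt_fc": rel.f_cwt_fc(profile.f_step_mean)})
        thr = (qc_mod.dynamic_thresholds(profile.t_step_mean)
               if cfg.qc_mode == "dynamic"
               else qc_mod.static_thresholds(cfg.static_t_max_stride,
                                             cfg.static_c_loading))
        model = cfg.pendulum_model
    else:
        ic, fc = detect_events_v2(vert, rec.fs, cfg.v2_scale,
                                  cfg.v2_height_factor, cfg.v2_fs)
        events = ContactEvents(ic=ic, fc=fc, detector="v2",
                               provenance={"scale": cfg.v2_scale})
        thr = qc_mod.static_thresholds(cfg.static_t_max_stride,
                                       cfg.static_c_loading)
        model = 1

    strides, rejected = qc_mod.assemble_strides(events, thr,
                                                return_rejections=True)
    pend = spatial_mod.fill_spatial(strides, vert, rec.fs, cfg.leg_length,
                                    model=model, c=cfg.length_ratio_c)
    table = metrics_mod.compute_metrics(strides, n_rejected=len(rejected))
    return GaitResult(profile=profile, events=events, strides=strides,
                      table=table, pendulum=pend, config=cfg)
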