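import numpy as np
import pytest

from lumbargait.bout import build_profile
from lumbargait.evaluate import match_events
from lumbargait.events import (ContactEvents, InsufficientEventsError,
                               ScaleRelation, calibrate_scale_relation,
                               detect_events_v2, detect_fc_v3, detect_ic_v3)
from lumbargait.preprocessing import butterworth_filter
from lumbargait.simulate import WalkerSpec, simulate_bout

REGION_MARGIN = 2.0


def _prep(rec):
    prof = build_profile(rec)
    ap = prof.ap[1] * rec.a[:, prof.ap[0]]
    ap20 = butterworth_filter(ap, rec.fs, "lowpass", 20.0)
    return prof, ap20


class TestDetectV3:
    def test_zero_signal_has_no_events(self):
        with pytest.raises(InsufficientEventsError):
            detect_fc_v3(np.zeros(4000), 128.0, 0.6)

    def test_noiseless_fc_recovery(self, walker):
        spec, rec, gt = walker
        prof, ap20 = _prep(rec)
        fc = detect_fc_v3(ap20, rec.fs, prof.t_step_mean)
        region = (REGION_MARGIN, rec.duration - REGION_MARGIN)
        rep = match_events(fc, gt.fc, region=region)
        assert rep.fn <= 1 and rep.fp <= 1
        assert np.median(np.abs(rep.errors)) < 0.03

    def test_noiseless_ic_recovery_and_ordering(self, walker):
        spec, rec, gt = walker
        prof, ap20 = _prep(rec)
        fc = detect_fc_v3(ap20, rec.fs, prof.t_step_mean)
        ic = detect_ic_v3(ap20, rec.fs, prof.t_step_mean, fc=fc)
        region = (REGION_MARGIN, rec.duration - REGION_MARGIN)
        rep = match_events(ic, gt.ic, region=region)
        assert np.median(np.abs(rep.errors)) < 0.03
        # every IC produced by backward search precedes its generating FC
        for t_ic in ic:
            assert np.any(fc > t_ic)

    def test_slow_walker_ic_yield(self):
        """Flat-peak regime: the midpoint rule must still pair nearly all
        FCs at slow cadence."""
        spec = WalkerSpec(f_step=1.2, duty=0.32, step_length=0.5, seed=9)
        rec, gt = simulate_bout(spec)
        prof, ap20 = _prep(rec)
        fc = detect_fc_v3(ap20, rec.fs, prof.t_step_mean)
        ic = detect_ic_v3(ap20, rec.fs, prof.t_step_mean, fc=fc)
        assert ic.size >= 0.9 * fc.size

    def test_amplitude_invariance(self, walker):
        _, rec, _ = walker
        prof, ap20 = _prep(rec)
        fc1 = detect_fc_v3(ap20, rec.fs, prof.t_step_mean)
        fc2 = detect_fc_v3(5.5 * ap20, rec.fs, prof.t_step_mean)
        assert np.array_equal(fc1, fc2)
        ic1 = detect_ic_v3(ap20, rec.fs, prof.t_step_mean, fc=fc1)
        ic2 = detect_ic_v3(5.5 * ap20, rec.fs, prof.t_step_mean, fc=fc2)
        assert np.array_equal(ic1, ic2)

    def test_translation_covariance(self, walker):
        _, rec, _ = walker
        prof, ap20 = _prep(rec)
        k = 2.0
        shifted = np.concatenate([np.zeros(int(k * rec.fs)), ap20])
        fc0 = detect_fc_v3(ap20, rec.fs, prof.t_step_mean)
        fc1 = detect_fc_v3(shifted, rec.fs, prof.t_step_mean)
        interior = fc0[(fc0 > 1.0) & (fc0 < fc0.max() - 1.0)]
        for t in interior:
            assert np.min(np.abs(fc1 - k - t)) < 1e-6

    def test_determinism(self, walker):
        _, rec, _ = walker
        prof, ap20 = _prep(rec)
        a = detect_fc_v3(ap20, rec.fs, prof.t_step_mean)
        b = detect_fc_v3(ap20.copy(), rec.fs, prof.t_step_mean)
        assert np.array_equal(a, b)


class TestDetectV2:
    def test_zero_signal_empty(self):
        ic, fc = detect_events_v2(np.zeros(4000) - 9.81, 128.0)
        assert ic.size == 0 and fc.size == 0

    def test_sinusoid_event_spacing_matches_period(self):
        t = np.arange(0, 30, 1 / 50.0)
        vert = np.sin(2 * np.pi * 1.25 * t) - 9.81
        ic, fc = detect_events_v2(vert, 50.0, scale=8.0)
        spacing = np.median(np.diff(ic))
        assert spacing == pytest.approx(0.8, abs=0.05)

    def test_v2_ic_lags_behind_truth_more_than_v3(self, walker):
        spec, rec, gt = walker
        prof, ap20 = _prep(rec)
        fc3 = detect_fc_v3(ap20, rec.fs, prof.t_step_mean)
        ic3 = detect_ic_v3(ap20, rec.fs, prof.t_step_mean, fc=fc3)
        v_sign = prof.vertical[1]
        vert = v_sign * rec.a[:, prof.vertical[0]]
        ic2, _ = detect_events_v2(vert, rec.fs)
        region = (REGION_MARGIN, rec.duration - REGION_MARGIN)
        r3 = match_events(ic3, gt.ic, region=region)
        r2 = match_events(ic2, gt.ic, region=region)
        assert r2.mae > r3.mae
        # the legacy landmark sits inside double support: late on average
        assert np.mean(r2.errors) > 0


class TestContactEvents:
    def test_times_must_increase(self):
        with pytest.raises(ValueError):
            ContactEvents(ic=[1.0, 0.5], fc=[2.0, 3.0])


@pytest.fixture(scope="module")
def labelled_bouts():
    bouts = []
    for i, f in enumerate((1.2, 1.7, 2.2)):
        spec = WalkerSpec(f_step=f, duty=round(0.38 - 0.05 * f, 3),
                          step_length=round(0.5 + 0.25 * (f - 1.2), 3),
                          duration_s=20.0, seed=20 + i)
        rec, gt = simulate_bout(spec)
        bouts.append((rec, (gt.ic, gt.fc)))
    return bouts


class TestCalibration:
    def test_recovered_relation_detects_well(self, labelled_bouts):
        grid = np.arange(2.0, 13.0, 1.0)
        rel = calibrate_scale_relation(labelled_bouts, grid, lam=1.0)
        assert rel.provenance == "calibrated"
        for rec, (ic_ref, fc_ref) in labelled_bouts:
            prof, ap20 = _prep(rec)
            fc = detect_fc_v3(ap20, rec.fs, prof.t_step_mean, rel)
            rep = match_events(fc, fc_ref,
                               region=(REGION_MARGIN,
                                       rec.duration - REGION_MARGIN))
            assert rep.f1 >= 0.95

    def test_too_few_bouts_rejected(self, labelled_bouts):
        from lumbargait.events import CalibrationError

        with pytest.raises(CalibrationError):
            calibrate_scale_relation(labelled_bouts[:2], np.array([3.0, 4.0]))

    def test_relation_clamped_positive(self):
        rel = ScaleRelation(ic=(1.0, -2.0), fc=(1.0, -2.0))
        assert rel.f_cwt_ic(0.5) > 0
        assert rel.f_cwt_fc(5.0) > 0
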