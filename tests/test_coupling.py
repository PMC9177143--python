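import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.special import i0, i1

from swcouple.coupling import (
    coupling_bookkeeping,
    match_spindles_to_sw,
    subject_coupling_summary,
    sw_phase_at,
    sw_time_at_phase,
)
from swcouple.spindle_detect import SpindleEvent
from swcouple.sw_detect import SlowWaveEvent

FS = 200.0


def make_sw(t0=10.0, d=(0.2, 0.25, 0.2, 0.25), switcher="slow", event_id=0):
    return SlowWaveEvent(
        channel="F3", t_start=t0, t_neg_peak=t0 + d[0],
        t_mid_cross=t0 + d[0] + d[1], t_pos_peak=t0 + d[0] + d[1] + d[2],
        t_end=t0 + sum(d), neg_amp=-45.0, pos_amp=45.0, switcher=switcher,
        event_id=event_id,
    )


def make_spindle(onset, event_id=0):
    return SpindleEvent("F3", onset=onset, offset=onset + 1.0, peak_env=10.0,
                        threshold_used=5.0, event_id=event_id)


class TestSwPhaseAt:
    def test_landmark_phases_exact(self):
        sw = make_sw()
        landmarks = (sw.t_start, sw.t_neg_peak, sw.t_mid_cross, sw.t_pos_peak,
                     sw.t_end)
        phases = (0.0, math.pi / 2, math.pi, 1.5 * math.pi, 2 * math.pi)
        for t, expected in zip(landmarks, phases):
            assert sw_phase_at(sw, t) == expected

    def test_linear_interpolation_within_quarter(self):
        sw = make_sw()
        midpoint = (sw.t_start + sw.t_neg_peak) / 2
        assert sw_phase_at(sw, midpoint) == pytest.approx(math.pi / 4)

    def test_outside_wave_errors(self):
        sw = make_sw()
        with pytest.raises(ValueError):
            sw_phase_at(sw, sw.t_start - 0.01)
        with pytest.raises(ValueError):
            sw_phase_at(sw, sw.t_end + 0.01)

    @settings(deadline=None, max_examples=100)
    @given(st.floats(0.0, 1.0), st.floats(0.0, 1.0))
    def test_monotone_in_time(self, u, v):
        sw = make_sw()
        t1 = sw.t_start + u * (sw.t_end - sw.t_start)
        t2 = sw.t_start + v * (sw.t_end - sw.t_start)
        if t1 > t2:
            t1, t2 = t2, t1
        assert sw_phase_at(sw, t1) <= sw_phase_at(sw, t2)

    @settings(deadline=None, max_examples=100)
    @given(st.floats(0.0, 2 * math.pi))
    def test_inversion_round_trip(self, phase):
        sw = make_sw()
        t = sw_time_at_phase(sw, phase)
        assert sw_phase_at(sw, t) == pytest.approx(phase, abs=1e-9)


class TestMatchSpindles:
    def test_onset_at_positive_peak_has_phase_three_half_pi(self):
        sw = make_sw()
        events = match_spindles_to_sw([make_spindle(sw.t_pos_peak)], [sw])
        assert len(events) == 1
        assert events[0].phase == pytest.approx(1.5 * math.pi)
        assert events[0].cos_phase == pytest.approx(0.0, abs=1e-12)
        assert events[0].switcher == "slow"

    def test_spindle_after_sw_unmatched(self):
        sw = make_sw()
        assert match_spindles_to_sw([make_spindle(sw.t_end + 1.0)], [sw]) == []

    def test_each_spindle_matches_at_most_one_sw(self):
        sws = [make_sw(t0=10.0, event_id=0), make_sw(t0=12.0, event_id=1)]
        spindles = [make_spindle(10.3, 0), make_spindle(12.3, 1),
                    make_spindle(50.0, 2)]
        events = match_spindles_to_sw(spindles, sws)
        assert len(events) == 2
        assert {ev.sw_id for ev in events} == {0, 1}

    def test_degenerate_sw_excluded(self):
        sw = make_sw()
        sw.t_neg_peak = sw.t_start  # coincident landmarks
        assert match_spindles_to_sw([make_spindle(sw.t_mid_cross)], [sw]) == []

    def test_cos_phase_consistency(self):
        sw = make_sw()
        for onset in np.linspace(sw.t_start, sw.t_end, 17):
            events = match_spindles_to_sw([make_spindle(float(onset))], [sw])
            ev = events[0]
            assert ev.cos_phase == pytest.approx(math.cos(ev.phase), abs=1e-12)
            assert -1.0 <= ev.cos_phase <= 1.0


class TestSubjectSummary:
    def test_symmetric_phases_average_to_zero(self):
        sw = make_sw(switcher="slow")
        events = match_spindles_to_sw(
            [make_spindle(sw_time_at_phase(sw, math.pi / 2), 0),
             make_spindle(sw_time_at_phase(sw, 1.5 * math.pi), 1)], [sw])
        out = subject_coupling_summary(events, {"slow": 1, "fast": 0}, 2, "s1")
        assert out.mean_cos_phase["slow"] == pytest.approx(0.0, abs=1e-12)
        assert math.isnan(out.mean_cos_phase["fast"])

    def test_all_events_at_phase_zero(self):
        sw = make_sw(switcher="slow")
        events = match_spindles_to_sw([make_spindle(sw.t_start)], [sw])
        out = subject_coupling_summary(events, {"slow": 1, "fast": 0}, 1, "s1")
        assert out.mean_cos_phase["slow"] == pytest.approx(1.0)

    def test_von_mises_mean_cosine_matches_closed_form(self):
        rng = np.random.default_rng(9)
        mu, kappa, n = 1.25 * math.pi, 4.0, 4000
        sws = [make_sw(t0=10.0 + 3 * k, switcher="slow", event_id=k)
               for k in range(n)]
        spindles = [
            make_spindle(sw_time_at_phase(
                sw, float(np.mod(rng.vonmises(mu, kappa), 2 * math.pi))), k)
            for k, sw in enumerate(sws)
        ]
        events = match_spindles_to_sw(spindles, sws)
        out = subject_coupling_summary(events, {"slow": n, "fast": 0}, n, "s1")
        expected = math.cos(mu) * i1(kappa) / i0(kappa)
        assert out.mean_cos_phase["slow"] == pytest.approx(expected, abs=0.02)

    def test_count_conservation_and_rates(self):
        slow = make_sw(t0=10.0, switcher="slow", event_id=0)
        fast = make_sw(t0=20.0, switcher="fast", event_id=1)
        events = match_spindles_to_sw(
            [make_spindle(10.4, 0), make_spindle(20.4, 1), make_spindle(99.0, 2)],
            [slow, fast])
        out = subject_coupling_summary(events, {"slow": 1, "fast": 1}, 3, "s1")
        assert out.n_coupled["slow"] + out.n_coupled["fast"] == len(events) == 2
        assert out.coupling_rate_sw["slow"] == 1.0
        assert out.coupling_rate_spindle["slow"] == pytest.approx(1 / 3)


class TestBookkeeping:
    def test_study_scale_counts(self):
        out = coupling_bookkeeping(
            n_sw_slow=341_836, n_sw_fast=78_235,
            n_coupled_slow=75_910, n_coupled_fast=26_912,
            n_spindles=563_928)
        assert out["pct_slow_sw_with_spindle"] == 22
        assert out["pct_fast_sw_with_spindle"] == 34
        assert out["n_coupled_total"] == 102_822
        assert out["pct_spindles_coupled"] == 18
        assert out["pct_spindles_on_slow"] == 13
        assert out["pct_spindles_on_fast"] == 5

    def test_rejects_non_positive_counts(self):
        with pytest.raises(ValueError):
            coupling_bookkeeping(0, 1, 0, 0, 1)

    def test_injection_rate_reproduced_on_synthetic_data(self, ten_minute_recording):
        # ~57% of slow SWs in the fixture carry a spindle by construction
        rec, _, truth, segments = ten_minute_recording
        from swcouple.spindle_detect import detect_spindles
        from swcouple.sw_detect import detect_slow_waves, fir_bandpass

        x = rec.channel("F3")
        sws = detect_slow_waves(fir_bandpass(x, FS, 0.3, 4.0), FS, sex="female",
                                segments=segments, channel="F3")
        spindles = detect_spindles(x, FS, segments=segments, channel="F3")
        events = match_spindles_to_sw(spindles, sws)
        n_injected = sum(1 for d in truth.spindle_onsets if d["sw_index"] is not None)
        # binomial slack around the injected coupling count
        assert abs(len(events) - n_injected) <= 6
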