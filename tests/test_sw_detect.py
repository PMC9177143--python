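import numpy as np
import pytest

from swcouple import synthetic

from swcouple.sw_detect import (
    DetectionCriteria,
    SlowWaveEvent,
    classify_switchers,
    detect_slow_waves,
    fir_bandpass,
    fit_switcher_model,
    gaussian_intersection,
    sw_density,
    transition_frequency,
)

FS = 200.0


def make_event(dt_transition, t0=10.0, **kw):
    """A symmetric SW whose neg-to-pos peak interval is dt_transition."""
    half = dt_transition / 2
    defaults = dict(
        channel="F3", t_start=t0, t_neg_peak=t0 + 0.2, t_mid_cross=t0 + 0.2 + half,
        t_pos_peak=t0 + 0.2 + dt_transition, t_end=t0 + 0.4 + dt_transition,
        neg_amp=-45.0, pos_amp=45.0,
    )
    defaults.update(kw)
    return SlowWaveEvent(**defaults)


class TestFirBandpass:
    def setup_method(self):
        self.t = np.arange(0, 120, 1 / FS)

    def gain_db(self, freq, band):
        x = np.sin(2 * np.pi * freq * self.t)
        y = fir_bandpass(x, FS, *band)
        sl = slice(5000, -5000)
        return 20 * np.log10(np.std(y[sl]) / np.std(x[sl]))

    def test_passband_identity(self):
        assert abs(self.gain_db(1.0, (0.3, 4.0))) < 0.45  # within 5% amplitude

    def test_stopband_attenuation(self):
        assert self.gain_db(20.0, (0.3, 4.0)) < -20.0

    def test_dc_rejected(self):
        y = fir_bandpass(np.ones(24000), FS, 0.3, 4.0)
        assert np.abs(y[8000:16000]).max() < 1e-3

    @pytest.mark.parametrize("edge", [10.0, 16.0])
    def test_spindle_band_minus_3db_at_edges(self, edge):
        assert self.gain_db(edge, (10.0, 16.0)) == pytest.approx(-3.0, abs=0.6)

    def test_band_outside_nyquist_errors(self):
        with pytest.raises(ValueError):
            fir_bandpass(np.zeros(100), FS, 10.0, 120.0)


class TestDetectSlowWaves:
    def synth_signal(self, recipe):
        wave, lm = synthetic.synth_slow_wave(recipe, FS, closing_dip=(-8.0, 0.35))
        sig = np.zeros(int(20 * FS))
        i0 = int(recipe.t_place * FS)
        sig[i0:i0 + len(wave)] += wave
        return sig, lm

    def test_criterion_wave_detected_with_exact_landmarks(self):
        recipe = synthetic.SWRecipe(t_place=5.0, neg_amp=-45.0, pos_amp=45.0,
                                    seg_durations=(0.2, 0.2, 0.2, 0.2))
        sig, lm = self.synth_signal(recipe)
        events = detect_slow_waves(sig, FS, sex="female", channel="F3")
        assert len(events) == 1
        ev = events[0]
        for name in ("t_start", "t_neg_peak", "t_mid_cross", "t_pos_peak", "t_end"):
            assert abs(getattr(ev, name) - (5.0 + lm[name])) <= 1.0 / FS

    @pytest.mark.parametrize(
        "recipe_kw, sex",
        [
            # p2p 65 < 70 required for women
            (dict(neg_amp=-38.0, pos_amp=27.0), "female"),
            # negative peak -30 shallower than the -37 bound
            (dict(neg_amp=-30.0, pos_amp=60.0), "female"),
            # negative half-wave 100 ms, below the 125 ms floor
            (dict(seg_durations=(0.05, 0.05, 0.3, 0.3)), "female"),
            # positive half-wave 1.3 s, above the 1000 ms cap
            (dict(seg_durations=(0.3, 0.3, 0.65, 0.65)), "female"),
        ],
    )
    def test_sub_criterion_waves_rejected(self, recipe_kw, sex):
        kw = dict(t_place=5.0, neg_amp=-45.0, pos_amp=45.0,
                  seg_durations=(0.2, 0.2, 0.2, 0.2))
        kw.update(recipe_kw)
        sig, _ = self.synth_signal(synthetic.SWRecipe(**kw))
        assert detect_slow_waves(sig, FS, sex=sex) == []

    def test_male_criteria_accept_smaller_waves(self):
        # p2p 65, neg -38: fails the female thresholds, passes the male ones
        sig, _ = self.synth_signal(
            synthetic.SWRecipe(t_place=5.0, neg_amp=-38.0, pos_amp=27.0,
                               seg_durations=(0.2, 0.2, 0.2, 0.2)))
        assert len(detect_slow_waves(sig, FS, sex="male")) == 1
        assert detect_slow_waves(sig, FS, sex="female") == []

    def test_sub_criterion_amplitude_margin_never_detected(self):
        crit = DetectionCriteria.for_sex("female")
        p2p = 0.95 * crit.p2p_min
        sig, _ = self.synth_signal(
            synthetic.SWRecipe(t_place=5.0, neg_amp=-p2p / 2, pos_amp=p2p / 2,
                               seg_durations=(0.2, 0.2, 0.2, 0.2)))
        assert detect_slow_waves(sig, FS, sex="female") == []

    def test_empty_segments_give_empty_list(self):
        sig = np.zeros(6000)
        assert detect_slow_waves(sig, FS, segments=[]) == []

    def test_events_sorted_and_non_overlapping(self, ten_minute_recording):
        rec, _, _, segments = ten_minute_recording
        filtered = fir_bandpass(rec.channel("F3"), FS, 0.3, 4.0)
        events = detect_slow_waves(filtered, FS, sex="female",
                                   segments=segments, channel="F3")
        assert len(events) > 30
        for a, b in zip(events, events[1:]):
            assert a.t_end <= b.t_start + 1e-9
        for ev in events:
            assert (ev.t_start < ev.t_neg_peak < ev.t_mid_cross
                    < ev.t_pos_peak < ev.t_end)


class TestTransitionFrequency:
    def test_hand_computed_values(self):
        assert transition_frequency(make_event(0.45)) == pytest.approx(1.111, abs=1e-3)
        assert transition_frequency(make_event(0.25)) == pytest.approx(2.0)

    def test_symmetric_slow_switcher_duration_matches_cohort_mean(self):
        # a symmetric SW of total duration 0.906 s has transition freq ~1.1 Hz
        ev = make_event(0.453, t_start=10.0, t_neg_peak=10.2265,
                        t_mid_cross=10.4530, t_pos_peak=10.6795, t_end=10.906)
        assert ev.duration == pytest.approx(0.906)
        assert transition_frequency(ev) == pytest.approx(1.10, abs=0.01)

    def test_degenerate_interval_errors(self):
        ev = make_event(0.45)
        ev.t_pos_peak = ev.t_neg_peak - 0.1
        with pytest.raises(ValueError):
            transition_frequency(ev)

    def test_landmark_order_validated_at_construction(self):
        with pytest.raises(ValueError, match="order"):
            SlowWaveEvent(channel="F3", t_start=1.0, t_neg_peak=0.5,
                          t_mid_cross=1.2, t_pos_peak=1.4, t_end=1.6,
                          neg_amp=-40.0, pos_amp=40.0)


class TestSwitcherModel:
    def test_threshold_matches_analytic_intersection(self):
        rng = np.random.default_rng(3)
        draws = np.concatenate([rng.normal(1.1, 0.05, 2500),
                                rng.normal(2.0, 0.1, 2500)])
        model = fit_switcher_model(draws, seed=0)
        analytic = gaussian_intersection(1.1, 0.05, 0.5, 2.0, 0.1, 0.5)
        assert abs(model.threshold - analytic) <= 0.05
        assert model.means[0] < model.threshold < model.means[1]

    def test_convergence_at_large_n(self):
        rng = np.random.default_rng(4)
        draws = np.concatenate([rng.normal(1.1, 0.05, 10000),
                                rng.normal(2.0, 0.1, 10000)])
        model = fit_switcher_model(draws, seed=0)
        analytic = gaussian_intersection(1.1, 0.05, 0.5, 2.0, 0.1, 0.5)
        assert abs(model.threshold - analytic) <= 0.02

    def test_cohort_like_weights(self):
        rng = np.random.default_rng(5)
        draws = np.concatenate([rng.normal(1.1, 0.05, 3500),
                                rng.normal(2.0, 0.1, 1500)])
        model = fit_switcher_model(draws, seed=0)
        assert 1.1 < model.threshold < 2.0
        assert model.weights[0] == pytest.approx(0.7, abs=0.03)

    def test_too_few_values_error_advises_pooling(self):
        with pytest.raises(ValueError, match="pool"):
            fit_switcher_model(np.linspace(0.9, 2.2, 30))

    def test_one_sided_values_error(self):
        with pytest.raises(ValueError, match="split"):
            fit_switcher_model(np.full(100, 1.0) + np.linspace(0, 0.05, 100))

    def test_classification_threshold_and_tie_break(self):
        model = fit_switcher_model(
            np.concatenate([np.random.default_rng(0).normal(1.1, 0.05, 200),
                            np.random.default_rng(1).normal(2.0, 0.1, 200)]),
            seed=0)
        dt_at_threshold = 1.0 / (2.0 * model.threshold)
        events = [make_event(0.455), make_event(0.25), make_event(dt_at_threshold)]
        labelled = classify_switchers(events, model)
        assert [ev.switcher for ev in labelled] == ["slow", "fast", "fast"]
        again = classify_switchers(labelled, model)
        assert [ev.switcher for ev in again] == [ev.switcher for ev in labelled]

    def test_counts_conserved_under_classification(self):
        rng = np.random.default_rng(6)
        model = fit_switcher_model(np.concatenate([rng.normal(1.1, 0.05, 500),
                                                   rng.normal(2.0, 0.1, 500)]), seed=0)
        events = [make_event(float(dt), t0=10.0 + 3 * k)
                  for k, dt in enumerate(rng.uniform(0.2, 0.5, 50))]
        labelled = classify_switchers(events, model)
        n_slow = sum(ev.switcher == "slow" for ev in labelled)
        n_fast = sum(ev.switcher == "fast" for ev in labelled)
        assert n_slow + n_fast == len(events)


class TestSwDensity:
    def test_single_channel_rate(self):
        events = [make_event(0.45, t0=10.0 + 5 * k) for k in range(70)]
        assert sw_density(events, 10.0)["total"] == pytest.approx(7.0)

    def test_no_events(self):
        assert sw_density([], 10.0)["total"] == 0.0

    def test_per_type_rates(self):
        slow = [make_event(0.45, t0=10 + 3 * k, switcher="slow") for k in range(10)]
        fast = [make_event(0.25, t0=200 + 3 * k, switcher="fast") for k in range(5)]
        out = sw_density(slow + fast, 5.0)
        assert out == {"total": 3.0, "slow": 2.0, "fast": 1.0}

    def test_zero_minutes_errors(self):
        with pytest.raises(ValueError):
            sw_density([], 0.0)
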