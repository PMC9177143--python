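import numpy as np
import pytest

from swcouple import io_staging, synthetic
from swcouple.coupling import sw_phase_at

from swcouple.sw_detect import detect_slow_waves, fir_bandpass

FS = 200.0


class TestSynthSlowWave:
    def test_symmetric_slow_switcher_geometry(self):
        recipe = synthetic.SWRecipe(t_place=0.0, neg_amp=-45.0, pos_amp=45.0,
                                    seg_durations=(0.225, 0.225, 0.225, 0.225))
        assert recipe.transition_freq == pytest.approx(1.0 / 0.9, abs=1e-9)
        wave, lm = synthetic.synth_slow_wave(recipe, FS)
        assert lm["t_neg_peak"] == 0.225
        assert lm["t_end"] == 0.9
        i_neg = int(0.225 * FS)
        assert wave[i_neg] == pytest.approx(-45.0, abs=0.2)
        assert wave.min() >= -45.0 - 1e-9
        assert wave.max() <= 45.0 + 1e-9

    def test_fast_switcher_transition_frequency(self):
        recipe = synthetic.SWRecipe(t_place=0.0,
                                    seg_durations=(0.21, 0.125, 0.125, 0.21))
        assert recipe.transition_freq == pytest.approx(2.0)

    def test_bad_amplitudes_rejected(self):
        with pytest.raises(ValueError):
            synthetic.synth_slow_wave(
                synthetic.SWRecipe(t_place=0.0, neg_amp=0.0, pos_amp=45.0), FS)
        with pytest.raises(ValueError):
            synthetic.synth_slow_wave(
                synthetic.SWRecipe(t_place=0.0, neg_amp=45.0, pos_amp=-45.0), FS)

    def test_continuity(self):
        recipe = synthetic.SWRecipe(t_place=0.0)
        wave, _ = synthetic.synth_slow_wave(recipe, 1000.0)
        assert np.abs(np.diff(wave)).max() < 1.0  # no jumps at segment joins


class TestGenerateRecording:
    def test_same_seed_bit_identical(self):
        rng1 = np.random.default_rng(0)
        recipes = synthetic.random_sw_recipes(10, 120.0, rng1)
        a, _, _ = synthetic.generate_recording(recipes, [], 120.0, seed=5,
                                               channels=("F3",))
        b, _, _ = synthetic.generate_recording(recipes, [], 120.0, seed=5,
                                               channels=("F3",))
        assert np.array_equal(a.data, b.data)

    def test_overlapping_sws_rejected(self):
        r1 = synthetic.SWRecipe(t_place=10.0)
        r2 = synthetic.SWRecipe(t_place=10.3)
        with pytest.raises(ValueError, match="overlap"):
            synthetic.generate_recording([r1, r2], [], 60.0, seed=0,
                                         channels=("F3",))

    def test_sw_outside_nrem_rejected(self):
        hyp = ["W", "N2"]
        with pytest.raises(ValueError, match="N2/N3"):
            synthetic.generate_recording([synthetic.SWRecipe(t_place=5.0)], [],
                                         60.0, seed=0, hypnogram_spec=hyp,
                                         channels=("F3",))

    def test_infeasible_spindle_placement_errors(self):
        sw = synthetic.SWRecipe(t_place=58.5)
        spindle = synthetic.SpindleRecipe(sw_index=0, phase=1.9 * np.pi,
                                          duration=2.0)
        with pytest.raises(ValueError, match="fit"):
            synthetic.generate_recording([sw], [spindle], 60.0, seed=0,
                                         channels=("F3",))

    def test_phase_targeted_onset_inverts_phase_map(self):
        rng = np.random.default_rng(1)
        recipes = synthetic.random_sw_recipes(20, 300.0, rng)
        phases = rng.uniform(0.1 * np.pi, 1.9 * np.pi, 20)
        spindles = [synthetic.SpindleRecipe(sw_index=k, phase=float(ph))
                    for k, ph in enumerate(phases)]
        _, _, truth = synthetic.generate_recording(recipes, spindles, 300.0,
                                                   seed=2, channels=("F3",))
        for d, requested in zip(truth.spindle_onsets, phases):
            sw = truth.sw_events[d["sw_index"]]
            realised = sw_phase_at(sw, d["onset"])
            # one sample maps to at most fs * max phase slope
            slope = 2 * np.pi / min(np.diff(
                [sw.t_start, sw.t_neg_peak, sw.t_mid_cross, sw.t_pos_peak,
                 sw.t_end])) / 4
            assert abs(realised - requested) <= slope / FS + 1e-9


class TestRoundTripRecovery:
    def test_noise_free_landmarks_within_one_sample(self, noise_free_recording):
        rec, _, truth, segments = noise_free_recording
        events = detect_slow_waves(rec.channel("F3"), FS, sex="female",
                                   segments=segments, channel="F3")
        assert len(events) == len(truth.sw_events)
        det_starts = np.array([ev.t_start for ev in events])
        for true_ev in truth.sw_events:
            ev = events[int(np.argmin(np.abs(det_starts - true_ev.t_start)))]
            for name in ("t_start", "t_neg_peak", "t_mid_cross", "t_pos_peak",
                         "t_end"):
                assert abs(getattr(ev, name) - getattr(true_ev, name)) <= 1.0 / FS
            assert ev.transition_freq == pytest.approx(
                true_ev.transition_freq, rel=0.02)

    def test_noise_only_recording_yields_almost_no_events(self):
        rec, hyp, _ = synthetic.generate_recording(
            [], [], 600.0, seed=9, noise={"rms": 15.0}, channels=("F3",))
        segments = io_staging.select_analysis_segments(hyp, [], FS)
        filtered = fir_bandpass(rec.channel("F3"), FS, 0.3, 4.0)
        sws = detect_slow_waves(filtered, FS, sex="female", segments=segments)
        assert len(sws) <= 1
        # spindle detection finds percentile-threshold noise runs by design;
        # the false-positive audit belongs to the SW amplitude criteria

    def test_generators_pure_functions_of_seed(self):
        t = synthetic.CohortTruth(seed=123)
        a = synthetic.generate_cohort(t)
        b = synthetic.generate_cohort(synthetic.CohortTruth(seed=123))
        assert a.equals(b)


class TestCohortTable:
    def test_schema_and_ranges(self, default_cohort):
        truth, cohort = default_cohort
        assert len(cohort) == truth.n_subjects
        assert cohort.rm_followup.notna().sum() == truth.n_followup
        assert cohort.age.between(50, 70).all()
        assert (cohort.centiloid > 0).all()
        assert set(cohort.sex) == {"female", "male"}
        decline = (cohort.rm_baseline - cohort.rm_followup) / cohort.rm_baseline
        followed = cohort.memory_decline.notna()
        np.testing.assert_allclose(cohort.memory_decline[followed],
                                   decline[followed])

    def test_long_table_two_rows_per_subject(self, default_cohort):
        _, cohort = default_cohort
        long = synthetic.cohort_long_table(cohort)
        assert len(long) == 2 * len(cohort)
        assert set(long.switcher) == {"slow", "fast"}

    def test_invalid_truth_rejected(self):
        with pytest.raises(ValueError):
            synthetic.CohortTruth(n_subjects=5)
        with pytest.raises(ValueError):
            synthetic.CohortTruth(noise_sd=-1.0)
        with pytest.raises(ValueError):
            synthetic.CohortTruth(n_subjects=20, n_followup=30)


def test_subject_recording_densities_and_coupling():
    rec, hyp, truth = synthetic.generate_subject_recording(seed=77, minutes=6)
    minutes = 6.0
    per_channel_sw = sum(1 for ev in truth.sw_events if ev.channel == "F3")
    per_channel_sp = sum(1 for d in truth.spindle_onsets if d["channel"] == "F3")
    assert per_channel_sw == pytest.approx(7.0 * minutes, abs=1)
    assert per_channel_sp == pytest.approx(8.3 * minutes, rel=0.15)
    coupled = [d for d in truth.spindle_onsets
               if d["channel"] == "F3" and d["sw_index"] is not None]
    assert len(coupled) > 0
    for d in coupled:
        sw = truth.sw_events[d["sw_index"]]
        assert sw.t_start <= d["onset"] <= sw.t_end
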