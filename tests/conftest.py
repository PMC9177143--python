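import logging

import numpy as np
import pytest

from swcouple import io_staging, synthetic

logging.getLogger("swcouple").setLevel(logging.ERROR)

FS = 200.0


@pytest.fixture(scope="session")
def ten_minute_recording():
    """10-min, 200 Hz recording with SWs and spindles at study-like densities.

    70 slow waves (slow/fast mix) and 83 spindles per channel on F3; spindles
    are a mix of SW-coupled (phase 1.25*pi) and free bursts. Ground truth is
    exact by construction.
    """
    rng = np.random.default_rng(11)
    duration = 600.0
    sw = synthetic.random_sw_recipes(70, duration, rng, channel="F3")
    spindles = []
    slow_ix = [i for i, r in enumerate(sw) if r.transition_freq < 1.2]
    coupled = rng.choice(slow_ix, size=min(40, len(slow_ix)), replace=False)
    for i in coupled:
        spindles.append(synthetic.SpindleRecipe(
            sw_index=int(i), phase=1.25 * np.pi, channel="F3", amplitude=30.0,
            duration=float(np.clip(rng.normal(1.0, 0.2), 0.6, 2.0))))
    busy = [(r.t_place - 1.5, r.t_place + r.duration + 1.5) for r in sw]
    times = []
    while len(times) < 83 - len(coupled):
        t = float(rng.uniform(5, duration - 5))
        if any(a < t < b for a, b in busy):
            continue
        if any(abs(t - u) < 3.0 for u in times):
            continue
        times.append(t)
    for t in times:
        spindles.append(synthetic.SpindleRecipe(
            t_onset=t, channel="F3", amplitude=30.0,
            duration=float(np.clip(rng.normal(1.0, 0.2), 0.6, 2.0))))
    rec, hyp, truth = synthetic.generate_recording(
        sw, spindles, duration, fs=FS, noise={"rms": 10.0}, seed=12,
        channels=("F3",))
    segments = io_staging.select_analysis_segments(hyp, [], FS)
    return rec, hyp, truth, segments


@pytest.fixture(scope="session")
def noise_free_recording():
    """Same geometry, zero background noise: landmark ground truth is exact."""
    rng = np.random.default_rng(21)
    duration = 600.0
    sw = synthetic.random_sw_recipes(60, duration, rng, channel="F3")
    rec, hyp, truth = synthetic.generate_recording(
        sw, [], duration, fs=FS, noise={"rms": 0.0}, seed=22, channels=("F3",))
    segments = io_staging.select_analysis_segments(hyp, [], FS)
    return rec, hyp, truth, segments


@pytest.fixture(scope="session")
def default_cohort():
    truth = synthetic.CohortTruth(seed=7)
    return truth, synthetic.generate_cohort(truth)
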