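"""Ground-truthed synthetic sleep EEG and cohorts.

No public raw data accompany the kind of overnight EEG/PET study this package
targets, so every pipeline stage is exercised on synthetic recordings whose
ground truth is exact by construction:

* slow waves are piecewise half-cosine segments through the five landmarks,
  so landmark times, amplitudes and transition frequencies are known exactly;
* spindles are Tukey-windowed 10-16 Hz bursts placed either at absolute times
  or at a requested phase of a reference SW (by inverting the five-landmark
  phase map);
* the background is seeded 1/f^alpha (pink) noise;
* cohort tables carry a prescribed linear association between the cosine of
  the coupling phase and a lognormal amyloid burden, plus a memory-decline
  slope on that cosine.

All generators are pure functions of their seed.

Default condition parameters mirror the late-midlife cohort the pipeline is
built for: 200 Hz frontal EEG, slow/fast switcher transition-frequency modes
near 1.1 and 2.0 Hz with roughly 0.81/0.19 prevalence, SW durations near
0.906 s (slow) and 0.671 s (fast), ~100 µV peak-to-peak amplitudes, N = 100
subjects (66 with follow-up), ages 50-70, 68% women.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .coupling import sw_time_at_phase
from .io_staging import EEGRecording, Hypnogram
from .sw_detect import SlowWaveEvent

DEFAULT_FS = 200.0
FRONTAL = ("F3", "Fz", "F4")

#: geometry of the two switcher classes: (transition-frequency mean/sd,
#: total-duration mean, amplitude p2p mean) per Table-style cohort values
SWITCHER_GEOMETRY = {
    "slow": {"tf_mean": 1.1, "tf_sd": 0.05, "duration": 0.906, "p2p": 104.5},
    "fast": {"tf_mean": 2.0, "tf_sd": 0.10, "duration": 0.671, "p2p": 94.0},
}
SLOW_FRACTION = 0.81  # 341,836 of 420,071 detected SWs


@dataclass
class SWRecipe:
    """Geometry and placement of one synthetic slow wave.

    ``seg_durations`` are the four landmark-to-landmark durations in seconds
    (start->neg peak, neg->mid cross, mid->pos peak, pos->end). The implied
    transition frequency is 1 / (2 * (neg->mid + mid->pos)).
    """

    t_place: float
    neg_amp: float = -50.0
    pos_amp: float = 52.0
    seg_durations: tuple[float, float, float, float] = (0.225, 0.225, 0.225, 0.225)
    channel: str = "F3"

    @property
    def transition_freq(self) -> float:
        return 1.0 / (2.0 * (self.seg_durations[1] + self.seg_durations[2]))

    @property
    def duration(self) -> float:
        return float(sum(self.seg_durations))


@dataclass
class SpindleRecipe:
    """One synthetic spindle burst, placed absolutely or at a SW phase."""

    carrier: float = 13.0
    duration: float = 1.0
    amplitude: float = 25.0
    channel: str = "F3"
    t_onset: float | None = None
    sw_index: int | None = None
    phase: float | None = None
    taper: float = 0.2  # Tukey taper fraction of the envelope


@dataclass
class GroundTruth:
    """Everything needed to score any detector exactly."""

    sw_events: list[SlowWaveEvent] = field(default_factory=list)
    spindle_onsets: list[dict] = field(default_factory=list)
    noise: dict = field(default_factory=dict)
    seed: int = 0

    def to_frames(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        sw = pd.DataFrame([{**asdict(ev)} for ev in self.sw_events])
        sp = pd.DataFrame(self.spindle_onsets)
        return sw, sp


@dataclass
class CohortTruth:
    """Design of a synthetic cohort: effect sizes, noise, covariates, seed.

    Slopes are on the cosine of the coupling phase per Centiloid unit
    (``slope_slow``/``slope_fast``) and on relative memory decline per unit
    cosine (``decline_slope``).
    """

    n_subjects: int = 100
    n_followup: int = 66
    seed: int = 0
    slope_slow: float = -0.010
    slope_fast: float = 0.0
    intercept_slow: float = -0.5
    intercept_fast: float = -0.15
    subject_sd: float = 0.10
    noise_sd: float = 0.15
    decline_slope: float = 0.4
    decline_mean: float = 0.08
    decline_sd: float = 0.28
    age_range: tuple[float, float] = (50.0, 70.0)
    age_mean: float = 59.4
    age_sd: float = 5.3
    female_fraction: float = 0.68
    tst_mean: float = 392.8
    tst_sd: float = 45.9
    education_mean: float = 15.2
    education_sd: float = 3.0
    centiloid_log_mean: float = 2.3
    centiloid_log_sd: float = 0.5

    def __post_init__(self) -> None:
        if self.n_subjects < 10:
            raise ValueError("need at least 10 subjects")
        if self.n_followup > self.n_subjects:
            raise ValueError("n_followup cannot exceed n_subjects")
        for name in ("subject_sd", "noise_sd", "decline_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


# ---------------------------------------------------------------------------
# waveform primitives


def synth_slow_wave(
    recipe: SWRecipe, fs: float, closing_dip: tuple[float, float] | None = None
) -> tuple[np.ndarray, dict[str, float]]:
    """Sample one SW waveform and return its landmark times (relative, s).

    The wave is four quarter-cosine segments through (0, neg_amp, 0, pos_amp,
    0): flat at the peaks but with non-zero slope at the zero crossings, as in
    real slow waves — a flat crossing would make detected crossing times
    purely noise-determined. ``closing_dip`` = (amp, dur) optionally appends a
    small sub-criterion biphasic wiggle after the end landmark so the terminal
    down-going zero crossing exists even in noise-free signals.
    """
    if recipe.neg_amp >= 0 or recipe.pos_amp <= 0:
        raise ValueError("need neg_amp < 0 < pos_amp")
    if any(d <= 0 for d in recipe.seg_durations):
        raise ValueError("segment durations must be positive")
    if fs < 100:
        raise ValueError("fs must be at least 100 Hz")
    d1, d2, d3, d4 = recipe.seg_durations
    bounds = np.cumsum([0.0, d1, d2, d3, d4])
    total = bounds[-1] + (closing_dip[1] if closing_dip else 0.0)
    n = int(np.ceil(total * fs))
    t = np.arange(n) / fs
    y = np.zeros(n)

    def zero_to_peak(u, amp):
        return amp * np.sin(0.5 * np.pi * u)

    def peak_to_zero(u, amp):
        return amp * np.cos(0.5 * np.pi * u)

    segments = (
        (zero_to_peak, recipe.neg_amp),
        (peak_to_zero, recipe.neg_amp),
        (zero_to_peak, recipe.pos_amp),
        (peak_to_zero, recipe.pos_amp),
    )
    for k, (shape, amp) in enumerate(segments):
        sel = (t >= bounds[k]) & (t < bounds[k + 1])
        u = (t[sel] - bounds[k]) / (bounds[k + 1] - bounds[k])
        y[sel] = shape(u, amp)
    if closing_dip:
        # biphasic sub-criterion wiggle: ends on a positive lobe so trailing
        # silence keeps positive sign and the terminal down-crossing is exact
        amp, dur = closing_dip
        sel = t >= bounds[-1]
        u = np.clip((t[sel] - bounds[-1]) / dur, 0, 1)
        y[sel] = amp * np.sin(2 * np.pi * u)

    landmarks = {
        "t_start": 0.0,
        "t_neg_peak": float(bounds[1]),
        "t_mid_cross": float(bounds[2]),
        "t_pos_peak": float(bounds[3]),
        "t_end": float(bounds[4]),
    }
    return y, landmarks


def synth_spindle(recipe: SpindleRecipe, fs: float) -> np.ndarray:
    """Tukey-windowed sinusoidal burst of the recipe's carrier and duration."""
    from scipy.signal.windows import tukey

    n = int(round(recipe.duration * fs))
    t = np.arange(n) / fs
    env = tukey(n, alpha=2 * recipe.taper)
    return recipe.amplitude * env * np.sin(2 * np.pi * recipe.carrier * t)


def pink_noise(n: int, rng: np.random.Generator, alpha: float = 1.0,
               rms: float = 15.0, fs: float = DEFAULT_FS) -> np.ndarray:
    """Seeded 1/f^alpha noise scaled to the requested broadband RMS (µV)."""
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    spectrum = np.zeros(len(freqs), dtype=complex)
    shape = np.zeros(len(freqs))
    shape[1:] = freqs[1:] ** (-alpha / 2.0)
    re = rng.standard_normal(len(freqs))
    im = rng.standard_normal(len(freqs))
    spectrum = shape * (re + 1j * im)
    x = np.fft.irfft(spectrum, n=n)
    if rms == 0.0:
        return np.zeros(n)
    x *= rms / np.sqrt(np.mean(x**2))
    return x


# ---------------------------------------------------------------------------
# recipe helpers


def sw_recipe_for_class(
    switcher: str, t_place: float, rng: np.random.Generator, channel: str = "F3"
) -> SWRecipe:
    """Draw one SW recipe whose geometry matches a switcher class."""
    geom = SWITCHER_GEOMETRY[switcher]
    tf = float(rng.normal(geom["tf_mean"], geom["tf_sd"]))
    tf = float(np.clip(tf, geom["tf_mean"] - 2.5 * geom["tf_sd"],
                       geom["tf_mean"] + 2.5 * geom["tf_sd"]))
    transition = 1.0 / (2.0 * tf)
    outer = max(geom["duration"] - transition, 0.26)
    p2p = float(rng.normal(geom["p2p"], 5.0))
    neg = -p2p * 0.5 - float(rng.uniform(0, 3))
    return SWRecipe(
        t_place=t_place,
        neg_amp=neg,
        pos_amp=p2p + neg,
        seg_durations=(outer / 2, transition / 2, transition / 2, outer / 2),
        channel=channel,
    )


def random_sw_recipes(
    n: int,
    duration_s: float,
    rng: np.random.Generator,
    slow_fraction: float = SLOW_FRACTION,
    channel: str = "F3",
    margin: float = 1.5,
    spacing: float = 0.6,
) -> list[SWRecipe]:
    """Non-overlapping SW recipes spread over a recording of ``duration_s``."""
    max_len = 1.6  # longest synthetic SW incl. closing dip
    slot = max_len + spacing
    n_slots = int((duration_s - 2 * margin) / slot)
    if n > n_slots:
        raise ValueError(f"cannot place {n} SWs in {duration_s:.0f} s")
    chosen = rng.choice(n_slots, size=n, replace=False)
    chosen.sort()
    recipes = []
    for k in chosen:
        t = margin + k * slot + float(rng.uniform(0, spacing / 2))
        kind = "slow" if rng.random() < slow_fraction else "fast"
        recipes.append(sw_recipe_for_class(kind, t, rng, channel=channel))
    return recipes


# ---------------------------------------------------------------------------
# recording generation


def generate_recording(
    sw_recipes: list[SWRecipe],
    spindle_recipes: list[SpindleRecipe],
    duration: float,
    fs: float = DEFAULT_FS,
    noise: dict | None = None,
    hypnogram_spec: list[str] | None = None,
    seed: int = 0,
    channels: tuple[str, ...] = FRONTAL,
    closing_dip: tuple[float, float] = (-8.0, 0.35),
) -> tuple[EEGRecording, Hypnogram, GroundTruth]:
    """Build a multichannel recording with injected SWs and spindles.

    Phase-targeted spindles (``sw_index`` + ``phase``) are placed by inverting
    the five-landmark phase map of the referenced ground-truth SW. Injected
    SWs must not overlap on a channel and must fall inside N2/N3 epochs of the
    hypnogram. The same seed reproduces the recording bit for bit.
    """
    noise = {"alpha": 1.0, "rms": 15.0} | (noise or {})
    n = int(round(duration * fs))
    if hypnogram_spec is None:
        hypnogram_spec = ["N2"] * int(np.ceil(duration / 30.0))
    hyp = Hypnogram(stages=list(hypnogram_spec))
    nrem_epochs = [i for i, s in enumerate(hyp.stages) if s in ("N2", "N3")]

    rng = np.random.default_rng(seed)
    data = np.vstack([pink_noise(n, rng, noise["alpha"], noise["rms"], fs)
                      for _ in channels])
    ch_index = {c: i for i, c in enumerate(channels)}
    truth = GroundTruth(noise=dict(noise), seed=seed)

    # inject slow waves
    occupied: dict[str, list[tuple[float, float]]] = {c: [] for c in channels}
    for k, recipe in enumerate(sw_recipes):
        if recipe.channel not in ch_index:
            raise ValueError(f"recipe channel {recipe.channel!r} not in {channels}")
        t0, t1 = recipe.t_place, recipe.t_place + recipe.duration
        epoch = int(t0 // 30.0)
        if epoch not in nrem_epochs or int(t1 // 30.0) not in nrem_epochs:
            raise ValueError(f"SW at {t0:.1f}s falls outside N2/N3 epochs")
        for a, b in occupied[recipe.channel]:
            if t0 < b and t1 > a:
                raise ValueError(f"injected SWs overlap on {recipe.channel} near {t0:.1f}s")
        occupied[recipe.channel].append((t0, t1 + closing_dip[1]))
        wave, lm = synth_slow_wave(recipe, fs, closing_dip=closing_dip)
        i0 = int(round(t0 * fs))
        if i0 + len(wave) > n:
            raise ValueError(f"SW at {t0:.1f}s runs past the recording end")
        data[ch_index[recipe.channel], i0:i0 + len(wave)] += wave
        truth.sw_events.append(
            SlowWaveEvent(
                channel=recipe.channel,
                t_start=t0 + lm["t_start"],
                t_neg_peak=t0 + lm["t_neg_peak"],
                t_mid_cross=t0 + lm["t_mid_cross"],
                t_pos_peak=t0 + lm["t_pos_peak"],
                t_end=t0 + lm["t_end"],
                neg_amp=recipe.neg_amp,
                pos_amp=recipe.pos_amp,
                switcher="slow" if recipe.transition_freq < 1.2 else "fast",
                event_id=k,
            )
        )

    # inject spindles
    for recipe in spindle_recipes:
        if recipe.t_onset is not None:
            onset = recipe.t_onset
            ref = None
        elif recipe.sw_index is not None and recipe.phase is not None:
            ref = truth.sw_events[recipe.sw_index]
            onset = sw_time_at_phase(ref, recipe.phase)
        else:
            raise ValueError("spindle recipe needs t_onset or (sw_index, phase)")
        i0 = int(round(onset * fs))
        burst = synth_spindle(recipe, fs)
        if i0 < 0 or i0 + len(burst) > n:
            raise ValueError(f"spindle at {onset:.2f}s does not fit the recording")
        data[ch_index[recipe.channel], i0:i0 + len(burst)] += burst
        truth.spindle_onsets.append(
            {
                "channel": recipe.channel,
                "onset": onset,
                "offset": onset + recipe.duration,
                "carrier": recipe.carrier,
                "amplitude": recipe.amplitude,
                "sw_index": recipe.sw_index,
                "phase": recipe.phase,
            }
        )

    rec = EEGRecording(list(channels), fs, data,
                       reference_note=f"synthetic (seed {seed})")
    return rec, hyp, truth


def generate_subject_recording(
    seed: int,
    minutes: float = 10.0,
    fs: float = DEFAULT_FS,
    channels: tuple[str, ...] = FRONTAL,
    sw_per_min: float = 7.0,
    spindle_per_min: float = 8.3,
    couple_prob: dict[str, float] | None = None,
    phase_mu: dict[str, float] | None = None,
    phase_kappa: dict[str, float] | None = None,
    slow_fraction: float = SLOW_FRACTION,
    noise_rms: float = 10.0,
    spindle_amp: float = 25.0,
) -> tuple[EEGRecording, Hypnogram, GroundTruth]:
    """One subject's night in miniature: coupled events on every frontal channel.

    SWs are placed at the requested density with the cohort's slow/fast mix;
    a type-dependent fraction carries a spindle whose onset phase is drawn von
    Mises (concentrated late in the depolarisation for slow switchers, more
    dispersed for fast ones); free spindles fill up the spindle density. The
    same events are injected on all channels, as frontal derivations see the
    same frontal generators.
    """
    couple_prob = couple_prob or {"slow": 0.22, "fast": 0.34}
    phase_mu = phase_mu or {"slow": 1.25 * math.pi, "fast": 1.1 * math.pi}
    phase_kappa = phase_kappa or {"slow": 4.0, "fast": 1.0}
    rng = np.random.default_rng(seed)
    duration = minutes * 60.0

    base = random_sw_recipes(int(round(sw_per_min * minutes)), duration, rng,
                             slow_fraction=slow_fraction, channel=channels[0])
    sw_recipes = []
    for ch in channels:
        for r in base:
            sw_recipes.append(SWRecipe(r.t_place, r.neg_amp, r.pos_amp,
                                       r.seg_durations, channel=ch))

    spindle_recipes: list[SpindleRecipe] = []
    n_per_ch = len(base)
    coupled_ix: list[tuple[int, float]] = []
    for i, r in enumerate(base):
        kind = "slow" if r.transition_freq < 1.2 else "fast"
        if rng.random() < couple_prob[kind]:
            phase = float(np.mod(rng.vonmises(phase_mu[kind], phase_kappa[kind]),
                                 2 * math.pi))
            # keep the onset inside the SW frame with room for detection jitter
            phase = float(np.clip(phase, 0.08 * math.pi, 1.92 * math.pi))
            coupled_ix.append((i, phase))
    n_free = max(int(round(spindle_per_min * minutes)) - len(coupled_ix), 0)
    busy = [(r.t_place - 1.5, r.t_place + r.duration + 1.5) for r in base]
    free_times: list[float] = []
    guard = 0
    while len(free_times) < n_free and guard < 20000:
        guard += 1
        t = float(rng.uniform(5.0, duration - 5.0))
        if any(a < t < b for a, b in busy):
            continue
        if any(abs(t - u) < 3.0 for u in free_times):
            continue
        free_times.append(t)
    for c, ch in enumerate(channels):
        for i, phase in coupled_ix:
            spindle_recipes.append(SpindleRecipe(
                channel=ch, amplitude=spindle_amp,
                duration=float(np.clip(rng.normal(1.0, 0.2), 0.6, 2.0)),
                carrier=float(rng.uniform(12.0, 14.5)),
                sw_index=c * n_per_ch + i, phase=phase))
        for t in free_times:
            spindle_recipes.append(SpindleRecipe(
                channel=ch, amplitude=spindle_amp,
                duration=float(np.clip(rng.normal(1.0, 0.2), 0.6, 2.0)),
                carrier=float(rng.uniform(12.0, 14.5)), t_onset=t))

    return generate_recording(
        sw_recipes, spindle_recipes, duration, fs=fs,
        noise={"rms": noise_rms}, seed=int(rng.integers(2**31)),
        channels=channels,
    )


# ---------------------------------------------------------------------------
# cohort generation


def generate_cohort(truth: CohortTruth) -> pd.DataFrame:
    """Simulate a cohort table with the prescribed association structure.

    Per subject: demographics and TST from the stated distributions, a
    lognormal Centiloid burden, per-SW-type mean cos coupling phase generated
    as intercept + slope * Centiloid + subject intercept + noise, SW-type
    durations and densities from the class geometry, and baseline/follow-up
    recognition-memory scores in which relative decline carries the prescribed
    slope on the slow-switcher cosine. Deterministic given ``truth.seed``.
    """
    rng = np.random.default_rng(truth.seed)
    n = truth.n_subjects
    age = np.clip(rng.normal(truth.age_mean, truth.age_sd, n), *truth.age_range)
    sex = np.where(rng.random(n) < truth.female_fraction, "female", "male")
    tst = np.clip(rng.normal(truth.tst_mean, truth.tst_sd, n), 229.0, 500.0)
    education = np.clip(rng.normal(truth.education_mean, truth.education_sd, n), 9, 25)
    centiloid = rng.lognormal(truth.centiloid_log_mean, truth.centiloid_log_sd, n)

    subject_effect = rng.normal(0.0, truth.subject_sd, n)
    # deliberately not truncated at ±1: with default parameters ~2% of
    # subjects overshoot marginally, and truncating would attenuate the
    # injected slope that estimator-validity checks rely on
    cos_slow = (truth.intercept_slow + truth.slope_slow * centiloid
                + subject_effect + rng.normal(0, truth.noise_sd, n))
    cos_fast = (truth.intercept_fast + truth.slope_fast * centiloid
                + subject_effect + rng.normal(0, truth.noise_sd, n))

    dur_slow = rng.normal(SWITCHER_GEOMETRY["slow"]["duration"], 0.046, n)
    dur_fast = rng.normal(SWITCHER_GEOMETRY["fast"]["duration"], 0.046, n)
    dens_slow = np.clip(rng.normal(4.9, 3.1, n), 0.6, 15.9)
    dens_fast = np.clip(rng.normal(2.1, 1.6, n), 0.1, 8.8)
    dens_spindle = np.clip(rng.normal(8.3, 1.1, n), 5.7, 10.7)

    rm_baseline = np.clip(rng.normal(0.6, 0.15, n), 0.1, 0.95)
    centered_cos = cos_slow - float(np.mean(cos_slow))
    decline = (truth.decline_mean + truth.decline_slope * centered_cos
               + rng.normal(0, truth.decline_sd, n))
    rm_followup = rm_baseline * (1.0 - decline)
    followed = np.zeros(n, bool)
    followed[rng.choice(n, size=truth.n_followup, replace=False)] = True

    frame = pd.DataFrame(
        {
            "subject_id": [f"S{i:03d}" for i in range(n)],
            "age": age,
            "sex": sex,
            "education": education,
            "tst": tst,
            "centiloid": centiloid,
            "cos_phase_slow": cos_slow,
            "cos_phase_fast": cos_fast,
            "sw_duration_slow": dur_slow,
            "sw_duration_fast": dur_fast,
            "sw_density_slow": dens_slow,
            "sw_density_fast": dens_fast,
            "spindle_density": dens_spindle,
            "rm_baseline": rm_baseline,
            "rm_followup": np.where(followed, rm_followup, np.nan),
        }
    )
    frame["memory_decline"] = np.where(
        followed, (frame.rm_baseline - frame.rm_followup) / frame.rm_baseline, np.nan
    )
    return frame


def cohort_long_table(frame: pd.DataFrame) -> pd.DataFrame:
    """Reshape a cohort table to one row per subject x switcher type."""
    rows = []
    for _, r in frame.iterrows():
        for sw_type in ("slow", "fast"):
            rows.append(
                {
                    "subject_id": r.subject_id,
                    "switcher": sw_type,
                    "cos_phase": r[f"cos_phase_{sw_type}"],
                    "sw_duration": r[f"sw_duration_{sw_type}"],
                    "centiloid": r.centiloid,
                    "age": r.age,
                    "sex": r.sex,
                    "tst": r.tst,
                }
            )
    return pd.DataFrame(rows)
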