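"""Slow-wave detection and slow/fast switcher classification.

A slow wave (SW) is a high-amplitude NREM deflection consisting of a negative
(down-state, hyperpolarised) half-wave followed by a positive (up-state,
depolarised) half-wave between consecutive zero crossings of the 0.3-4 Hz
filtered signal. Detection uses sex-adapted amplitude criteria with duration
gates on both half-waves.

Each SW carries a *transition frequency*, the frequency of the half-cycle
spanning its down-to-up transition: 1 / (2 * (t_pos_peak - t_neg_peak)).
Pooled transition frequencies form a two-component mixture; the intersection
of the two fitted Gaussian densities (around 1.2 Hz in ageing cohorts) splits
SWs into slow and fast "switchers".
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import signal as sps
from sklearn.mixture import GaussianMixture

from .io_staging import SampleInterval, SegmentSelection

SW_BAND = (0.3, 4.0)

#: sex-adapted amplitude criteria: peak-to-peak minimum and negative-peak bound
SEX_CRITERIA = {
    "female": {"p2p_min": 70.0, "neg_amp_max": -37.0},
    "male": {"p2p_min": 60.5, "neg_amp_max": -32.0},
}


@dataclass(frozen=True)
class DetectionCriteria:
    """Amplitude and duration gates for SW candidates.

    ``neg_dur_range`` bounds the negative deflection (start to mid-crossing),
    ``pos_dur_max`` the positive deflection (mid-crossing to end), in seconds.
    """

    p2p_min: float
    neg_amp_max: float
    neg_dur_range: tuple[float, float] = (0.125, 1.5)
    pos_dur_max: float = 1.0

    def __post_init__(self) -> None:
        if self.p2p_min <= 0:
            raise ValueError("p2p_min must be positive")
        if self.neg_amp_max >= 0:
            raise ValueError("neg_amp_max must be negative")

    @classmethod
    def for_sex(cls, sex: str) -> "DetectionCriteria":
        try:
            amp = SEX_CRITERIA[sex]
        except KeyError:
            raise ValueError(f"sex must be one of {sorted(SEX_CRITERIA)}, got {sex!r}") from None
        return cls(**amp)


@dataclass
class SlowWaveEvent:
    """One detected slow wave with its five time landmarks (seconds)."""

    channel: str
    t_start: float
    t_neg_peak: float
    t_mid_cross: float
    t_pos_peak: float
    t_end: float
    neg_amp: float
    pos_amp: float
    switcher: str = "unassigned"
    event_id: int = -1

    def __post_init__(self) -> None:
        order = (self.t_start, self.t_neg_peak, self.t_mid_cross,
                 self.t_pos_peak, self.t_end)
        if not all(a < b for a, b in zip(order, order[1:])):
            raise ValueError(f"landmarks out of order: {order}")
        if self.neg_amp > 0 or self.pos_amp < 0:
            raise ValueError("neg_amp must be <= 0 and pos_amp >= 0")

    @property
    def p2p(self) -> float:
        return self.pos_amp - self.neg_amp

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start

    @property
    def frequency(self) -> float:
        """Overall SW frequency, 1/duration."""
        return 1.0 / self.duration

    @property
    def transition_freq(self) -> float:
        return transition_frequency(self)


@dataclass
class SwitcherModel:
    """Two-Gaussian mixture over transition frequencies with its split point."""

    means: tuple[float, float]
    sds: tuple[float, float]
    weights: tuple[float, float]
    threshold: float
    n: int = 0
    converged: bool = True


# ---------------------------------------------------------------------------
# filtering


def fir_bandpass(x: np.ndarray, fs: float, low: float, high: float,
                 transition: float | None = None) -> np.ndarray:
    """Zero-phase band-pass with a linear-phase FIR filter.

    An odd-length Hamming-window FIR is applied by symmetric convolution, which
    exactly compensates the group delay. Cutoffs are nudged outward so the
    -3 dB points fall at the nominal band edges. Output has the input's length.
    """
    x = np.asarray(x, dtype=float)
    if not (0 < low < high < fs / 2):
        raise ValueError(f"band ({low}, {high}) must lie inside (0, {fs / 2})")
    if transition is None:
        transition = max(min(low / 2.0, 2.0), 0.2)
    numtaps = int(np.ceil(3.3 * fs / transition))
    numtaps += 1 - numtaps % 2
    # Hamming FIR is -6 dB at the designed cutoff; shifting by ~0.13 of the
    # transition width puts -3 dB at the nominal edge instead.
    shift = 0.126 * transition
    lo = max(low - shift, transition * 0.05)
    hi = min(high + shift, fs / 2 * 0.999)
    taps = sps.firwin(numtaps, [lo, hi], pass_zero=False, fs=fs, window="hamming")
    if len(x) < numtaps:
        pad = numtaps - len(x)
        xp = np.pad(x, (pad, pad), mode="reflect")
        return sps.fftconvolve(xp, taps, mode="same")[pad:pad + len(x)]
    return sps.fftconvolve(x, taps, mode="same")


# ---------------------------------------------------------------------------
# detection


def _crossing_time(x: np.ndarray, i: int, fs: float) -> float:
    """Linear-interpolated time of the zero crossing between samples i, i+1."""
    x0, x1 = x[i], x[i + 1]
    frac = 0.0 if x1 == x0 else x0 / (x0 - x1)
    return (i + frac) / fs


def detect_slow_waves(
    filtered: np.ndarray,
    fs: float,
    sex: str = "female",
    segments: SegmentSelection | list[SampleInterval] | None = None,
    criteria: DetectionCriteria | None = None,
    channel: str = "",
) -> list[SlowWaveEvent]:
    """Detect slow waves on an already 0.3-4 Hz filtered signal.

    Candidates are negative-then-positive half-wave pairs delimited by zero
    crossings (start = down-going crossing, mid = up-going crossing, end = next
    down-going crossing), evaluated within each contiguous run of analysis
    segments. A candidate is kept iff peak-to-peak amplitude, negative-peak
    amplitude and both half-wave durations pass the (sex-specific) criteria.
    The input must already be band-filtered; detection on raw EEG is outside
    this function's contract.
    """
    if criteria is None:
        criteria = DetectionCriteria.for_sex(sex)
    filtered = np.asarray(filtered, dtype=float)

    if segments is None:
        runs = [SampleInterval(0, len(filtered))]
    elif isinstance(segments, SegmentSelection):
        runs = segments.contiguous_runs()
    else:
        runs = SegmentSelection(intervals=list(segments)).contiguous_runs()

    events: list[SlowWaveEvent] = []
    for run in runs:
        x = filtered[run.start:run.end]
        if len(x) < 3:
            continue
        events.extend(
            _detect_in_run(x, fs, run.start / fs, criteria, channel)
        )
    for k, ev in enumerate(events):
        ev.event_id = k
    return events


def _detect_in_run(x, fs, t_offset, criteria, channel):
    # exact zeros adopt the preceding sample's sign (leading zeros: positive)
    sign = np.sign(x)
    if sign[0] == 0:
        sign[0] = 1.0
    nz = np.where(sign != 0, np.arange(sign.size), 0)
    np.maximum.accumulate(nz, out=nz)
    sign = sign[nz]

    down = np.flatnonzero((sign[:-1] > 0) & (sign[1:] < 0))
    up = np.flatnonzero((sign[:-1] < 0) & (sign[1:] > 0))

    events = []
    for d0, d1 in zip(down, down[1:]):
        ups = up[(up > d0) & (up < d1)]
        if len(ups) != 1:
            continue
        u = ups[0]
        t_start = t_offset + _crossing_time(x, d0, fs)
        t_mid = t_offset + _crossing_time(x, u, fs)
        t_end = t_offset + _crossing_time(x, d1, fs)

        neg_seg = slice(d0 + 1, u + 1)
        pos_seg = slice(u + 1, d1 + 1)
        i_neg = d0 + 1 + int(np.argmin(x[neg_seg]))
        i_pos = u + 1 + int(np.argmax(x[pos_seg]))
        neg_amp = float(x[i_neg])
        pos_amp = float(x[i_pos])

        neg_dur = t_mid - t_start
        pos_dur = t_end - t_mid
        if not (criteria.neg_dur_range[0] <= neg_dur <= criteria.neg_dur_range[1]):
            continue
        if pos_dur > criteria.pos_dur_max:
            continue
        if neg_amp > criteria.neg_amp_max:
            continue
        if pos_amp - neg_amp < criteria.p2p_min:
            continue
        if neg_amp > 0 or pos_amp < 0:
            continue
        events.append(
            SlowWaveEvent(
                channel=channel,
                t_start=t_start,
                t_neg_peak=t_offset + i_neg / fs,
                t_mid_cross=t_mid,
                t_pos_peak=t_offset + i_pos / fs,
                t_end=t_end,
                neg_amp=neg_amp,
                pos_amp=pos_amp,
            )
        )
    return events


def transition_frequency(sw: SlowWaveEvent) -> float:
    """Down-to-up transition frequency: 1 / (2 * (t_pos_peak - t_neg_peak)).

    The negative-to-positive peak interval is half a cycle of the underlying
    oscillation, so its frequency is the reciprocal of twice its duration.
    """
    dt = sw.t_pos_peak - sw.t_neg_peak
    if dt <= 0:
        raise ValueError(f"non-positive transition duration {dt}")
    return 1.0 / (2.0 * dt)


# ---------------------------------------------------------------------------
# switcher classification


def gaussian_intersection(m1, s1, w1, m2, s2, w2) -> float:
    """Root of w1*N(m1, s1) = w2*N(m2, s2) strictly between the two means."""
    if m1 > m2:
        m1, s1, w1, m2, s2, w2 = m2, s2, w2, m1, s1, w1
    a = 0.5 / s1**2 - 0.5 / s2**2
    b = m2 / s2**2 - m1 / s1**2
    c = m1**2 / (2 * s1**2) - m2**2 / (2 * s2**2) - np.log((w1 * s2) / (w2 * s1))
    if abs(a) < 1e-12:
        roots = [-c / b] if b != 0 else []
    else:
        disc = b**2 - 4 * a * c
        if disc < 0:
            roots = []
        else:
            sq = np.sqrt(disc)
            roots = [(-b - sq) / (2 * a), (-b + sq) / (2 * a)]
    between = [r for r in roots if m1 < r < m2]
    if not between:
        raise ValueError(
            f"no density intersection strictly between means {m1:.3f} and {m2:.3f}"
        )
    return float(between[0] if len(between) == 1 else min(between, key=lambda r: abs(r - (m1 + m2) / 2)))


def fit_switcher_model(
    transition_freqs: np.ndarray,
    seed: int = 0,
    init_split: float = 1.2,
    tol: float = 1e-8,
    max_iter: int = 500,
) -> SwitcherModel:
    """Fit a two-Gaussian mixture to pooled transition frequencies by EM.

    EM is initialised from the values below/above ``init_split`` (1.2 Hz); the
    classification threshold is the intersection of the two fitted component
    densities lying strictly between the means. Deterministic given ``seed``.
    """
    x = np.asarray(transition_freqs, dtype=float).ravel()
    if len(x) < 50:
        raise ValueError(
            f"need >= 50 transition frequencies to fit the mixture, got {len(x)}; "
            "pool across subjects"
        )
    lo, hi = x[x < init_split], x[x >= init_split]
    if len(lo) < 2 or len(hi) < 2:
        raise ValueError(
            f"values do not span both sides of the {init_split} Hz initial split"
        )
    means_init = np.array([[lo.mean()], [hi.mean()]])
    weights_init = np.array([len(lo), len(hi)], dtype=float) / len(x)
    prec_init = 1.0 / np.maximum(
        np.array([lo.var(), hi.var()]), 1e-6
    ).reshape(2, 1, 1)

    gm = GaussianMixture(
        n_components=2,
        covariance_type="full",
        tol=tol,
        max_iter=max_iter,
        means_init=means_init,
        weights_init=weights_init,
        precisions_init=prec_init,
        random_state=seed,
        n_init=1,
    ).fit(x.reshape(-1, 1))

    means = gm.means_.ravel()
    sds = np.sqrt(gm.covariances_.ravel())
    weights = gm.weights_.ravel()
    order = np.argsort(means)
    means, sds, weights = means[order], sds[order], weights[order]
    if sds.min() < 1e-4:
        raise ValueError(f"degenerate EM fit: component sd {sds.min():.2e} collapsed")
    threshold = gaussian_intersection(
        means[0], sds[0], weights[0], means[1], sds[1], weights[1]
    )
    return SwitcherModel(
        means=tuple(means), sds=tuple(sds), weights=tuple(weights),
        threshold=threshold, n=len(x), converged=bool(gm.converged_),
    )


def classify_switchers(
    events: list[SlowWaveEvent], model: SwitcherModel
) -> list[SlowWaveEvent]:
    """Label each SW slow/fast by its transition frequency vs the threshold.

    A wave exactly at the threshold is labelled fast (the rule is
    ``slow iff transition_freq < threshold``); idempotent.
    """
    return [
        replace(ev, switcher="slow" if ev.transition_freq < model.threshold else "fast")
        for ev in events
    ]


def sw_density(
    events: list[SlowWaveEvent],
    n2n3_minutes: float,
    channels: list[str] | None = None,
) -> dict[str, float]:
    """SW counts per minute of N2/N3 sleep, overall and per switcher type.

    Densities are computed per channel then averaged across ``channels``
    (default: the channels present in ``events``, or a single implicit channel
    when there are none).
    """
    if n2n3_minutes <= 0:
        raise ValueError("n2n3_minutes must be positive")
    if channels is None:
        channels = sorted({ev.channel for ev in events}) or [""]
    out = {}
    for label, pred in (
        ("total", lambda ev: True),
        ("slow", lambda ev: ev.switcher == "slow"),
        ("fast", lambda ev: ev.switcher == "fast"),
    ):
        per_ch = [
            sum(1 for ev in events if ev.channel == ch and pred(ev)) / n2n3_minutes
            for ch in channels
        ]
        out[label] = float(np.mean(per_ch))
    return out


def events_to_frame(events: list[SlowWaveEvent]):
    """Tabulate SW events (BED-like TSV layout)."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "channel": ev.channel,
                "start_s": ev.t_start,
                "neg_peak_s": ev.t_neg_peak,
                "mid_cross_s": ev.t_mid_cross,
                "pos_peak_s": ev.t_pos_peak,
                "end_s": ev.t_end,
                "neg_amp": ev.neg_amp,
                "pos_amp": ev.pos_amp,
                "transition_freq": ev.transition_freq,
                "switcher": ev.switcher,
            }
            for ev in events
        ]
    )
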