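"""Sleep-spindle detection by Hilbert-envelope percentile thresholding.

The raw channel is band-passed 10-16 Hz, the modulus of its analytic signal is
smoothed with a short centred moving average, and a per-channel threshold is
set at the 75th percentile of the envelope over artifact-free N2/N3 samples.
Maximal supra-threshold runs lasting 0.5-3 s become spindles; the onset
("ignition") is the first supra-threshold sample of the run.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import hilbert

from .io_staging import SampleInterval, SegmentSelection
from .sw_detect import fir_bandpass

SPINDLE_BAND = (10.0, 16.0)
DEFAULT_SMOOTH_WIN = 0.1
DEFAULT_PERCENTILE = 75.0
DURATION_RANGE = (0.5, 3.0)

#: onset ("ignition") refinement: fraction of the run's envelope excursion
#: above threshold under which the latest local envelope minimum before the
#: peak is taken as the onset (0 disables the refinement)
IGNITION_LEVEL_FRACTION = 0.1


@dataclass
class SpindleEvent:
    """One detected spindle (times in seconds from recording start)."""

    channel: str
    onset: float
    offset: float
    peak_env: float
    threshold_used: float
    event_id: int = -1

    @property
    def duration(self) -> float:
        return self.offset - self.onset


def spindle_envelope(signal: np.ndarray, fs: float,
                     smooth_win: float = DEFAULT_SMOOTH_WIN) -> np.ndarray:
    """Smoothed amplitude envelope of an already 10-16 Hz filtered signal.

    The envelope is the modulus of the analytic signal, smoothed by a centred
    moving average of width ``smooth_win`` seconds (default 0.1 s: longer
    than one 13 Hz cycle, short enough to keep onset smear well under the
    minimum spindle duration).
    """
    signal = np.asarray(signal, dtype=float)
    win = int(round(smooth_win * fs))
    if win < 2:
        raise ValueError(f"smooth_win {smooth_win}s is under 2 samples at {fs} Hz")
    env = np.abs(hilbert(signal))
    kernel = np.ones(win) / win
    # reflect-pad so the average stays centred at the edges
    padded = np.pad(env, win, mode="reflect")
    return np.convolve(padded, kernel, mode="same")[win:-win]


def detect_spindles(
    signal: np.ndarray,
    fs: float,
    segments: SegmentSelection | list[SampleInterval] | None = None,
    percentile: float = DEFAULT_PERCENTILE,
    smooth_win: float = DEFAULT_SMOOTH_WIN,
    duration_range: tuple[float, float] = DURATION_RANGE,
    channel: str = "",
) -> list[SpindleEvent]:
    """Detect spindles on a raw channel within the analysis segments.

    The percentile threshold is computed per channel over all selected,
    non-flagged samples of this recording. Supra-threshold runs shorter than
    0.5 s or longer than 3 s are discarded (long runs are not truncated), as
    are runs cut by the edge of a contiguous segment run.

    The onset ("ignition") is the first supra-threshold sample of the run,
    refined to the latest local envelope minimum preceding the run's peak
    when such a minimum lies within the lowest tenth of the run's excursion
    above threshold: background exceedances hovering just above a percentile
    threshold otherwise drag the onset backwards into noise that precedes the
    burst proper.
    """
    signal = np.asarray(signal, dtype=float)
    if segments is None:
        selection = SegmentSelection(intervals=[SampleInterval(0, len(signal))])
    elif isinstance(segments, SegmentSelection):
        selection = segments
    else:
        selection = SegmentSelection(intervals=list(segments))
    if not selection.intervals:
        return []

    filtered = fir_bandpass(signal, fs, *SPINDLE_BAND)
    env = spindle_envelope(filtered, fs, smooth_win)

    clean = selection.sample_indices(include_flagged=False)
    if clean.size == 0:
        return []
    threshold = float(np.percentile(env[clean], percentile))

    min_len = int(np.ceil(duration_range[0] * fs))
    max_len = int(np.floor(duration_range[1] * fs))
    events: list[SpindleEvent] = []
    for run in selection.contiguous_runs():
        above = env[run.start:run.end] > threshold
        for a, b in _runs_of_true(above):
            if a == 0 or b == len(above):  # cut by the segment edge
                continue
            if not (min_len <= b - a <= max_len):
                continue
            seg = env[run.start + a:run.start + b]
            j = _refine_ignition(seg, threshold)
            onset = (run.start + a + j) / fs
            offset = (run.start + b) / fs
            if offset - onset < duration_range[0]:
                continue
            events.append(
                SpindleEvent(
                    channel=channel,
                    onset=onset,
                    offset=offset,
                    peak_env=float(seg.max()),
                    threshold_used=threshold,
                )
            )
    for k, ev in enumerate(events):
        ev.event_id = k
    return events


def _refine_ignition(seg: np.ndarray, threshold: float,
                     frac: float = IGNITION_LEVEL_FRACTION) -> int:
    """Offset (samples) of the run's ignition point past the first crossing."""
    m = int(np.argmax(seg))
    if frac <= 0 or m < 2:
        return 0
    level = threshold + frac * (seg[m] - threshold)
    interior = np.flatnonzero(
        (seg[1:m] <= seg[:m - 1]) & (seg[1:m] <= seg[2:m + 1]) & (seg[1:m] <= level)
    ) + 1
    return int(interior[-1]) if interior.size else 0


def _runs_of_true(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, stop) index pairs of maximal True runs."""
    if not mask.any():
        return []
    padded = np.concatenate(([False], mask, [False]))
    diff = np.diff(padded.astype(int))
    starts = np.flatnonzero(diff == 1)
    stops = np.flatnonzero(diff == -1)
    return list(zip(starts, stops))


def spindle_density(
    events: list[SpindleEvent],
    n2n3_minutes: float,
    channels: list[str] | None = None,
) -> float:
    """Spindles per minute of N2/N3, averaged across channels."""
    if n2n3_minutes <= 0:
        raise ValueError("n2n3_minutes must be positive")
    if channels is None:
        channels = sorted({ev.channel for ev in events}) or [""]
    per_ch = [
        sum(1 for ev in events if ev.channel == ch) / n2n3_minutes for ch in channels
    ]
    return float(np.mean(per_ch))


def events_to_frame(events: list[SpindleEvent]):
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "channel": ev.channel,
                "onset_s": ev.onset,
                "offset_s": ev.offset,
                "duration_s": ev.duration,
                "peak_env": ev.peak_env,
                "threshold": ev.threshold_used,
            }
            for ev in events
        ]
    )
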