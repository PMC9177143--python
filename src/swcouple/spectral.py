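"""Overnight delta-band power summaries (slow-wave energy and band ratio).

Slow-wave energy (SWE) is the band power cumulated (summed) over artifact-free
N2/N3 30-s epochs of the night. The summary also reports the ratio of the
cumulated 0.5-1 Hz power to the cumulated 1-4 Hz power, a classical index of
the slower portion of slow-wave activity. Band powers use a Hann-tapered
periodogram per epoch, integrated over half-open bands [lo, hi).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import periodogram

from .io_staging import EEGRecording, SampleInterval, SegmentSelection

BANDS = {"slow": (0.5, 1.0), "fast": (1.0, 4.0), "delta": (0.5, 4.0)}
FRONTAL_CHANNELS = ("F3", "Fz", "F4")


@dataclass
class BandPowerSummary:
    """Cumulated band powers (µV²·epochs) across analysis epochs."""

    power: dict[str, float]
    ratio_slow_fast: float
    n_epochs: int


def epoch_band_power(signal: np.ndarray, fs: float,
                     band: tuple[float, float]) -> float:
    """Integrated Hann-periodogram power of one epoch within [lo, hi) Hz (µV²)."""
    signal = np.asarray(signal, dtype=float)
    lo, hi = band
    if hi <= lo:
        raise ValueError(f"empty band {band}")
    resolution = fs / len(signal)
    if hi - lo < resolution:
        raise ValueError(
            f"band {band} narrower than the {resolution:.3f} Hz resolution of a "
            f"{len(signal) / fs:.1f} s epoch"
        )
    freqs, psd = periodogram(signal, fs=fs, window="hann", detrend="constant")
    df = freqs[1] - freqs[0]
    sel = (freqs >= lo) & (freqs < hi)
    return float(np.sum(psd[sel]) * df)


def overnight_summary(
    recording: EEGRecording,
    segments: SegmentSelection | list[SampleInterval],
    channels: tuple[str, ...] | None = None,
) -> BandPowerSummary:
    """Cumulated band powers over analysis epochs, averaged over frontal channels.

    Epochs containing flagged (short-artifact) samples are dropped from the
    power summary. Per band, per-epoch powers are summed across epochs and the
    per-channel sums averaged; the ratio is cumulated(0.5-1) / cumulated(1-4).
    """
    if isinstance(segments, SegmentSelection):
        selection = segments
    else:
        selection = SegmentSelection(intervals=list(segments))
    if channels is None:
        present = [c.lower() for c in recording.channel_labels]
        channels = tuple(c for c in FRONTAL_CHANNELS if c.lower() in present) \
            or tuple(recording.channel_labels)

    epochs = [
        iv for iv in selection.intervals
        if not any(f.start < iv.end and f.end > iv.start for f in selection.flagged)
    ]
    if not epochs:
        raise ValueError("no unflagged analysis epochs for the power summary")

    sums = {name: [] for name in BANDS}
    for ch in channels:
        x = recording.channel(ch)
        per_band = {name: 0.0 for name in BANDS}
        for iv in epochs:
            seg = x[iv.start:iv.end]
            for name, band in BANDS.items():
                per_band[name] += epoch_band_power(seg, recording.fs, band)
        for name in BANDS:
            sums[name].append(per_band[name])

    power = {name: float(np.mean(vals)) for name, vals in sums.items()}
    if power["fast"] <= 0:
        raise ValueError("zero 1-4 Hz power: band ratio undefined")
    return BandPowerSummary(
        power=power,
        ratio_slow_fast=power["slow"] / power["fast"],
        n_epochs=len(epochs),
    )
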