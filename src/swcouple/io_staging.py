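"""Reading EEG recordings, hypnograms and event masks; selecting analysis segments.

All detections in this package run on artifact-free N2/N3 sleep. This module
owns the bookkeeping that gets us there: 30-s hypnogram epochs staged N2 or N3
are selected, any epoch overlapping an artifact or arousal event longer than
5 s is dropped entirely, and shorter events flag their own samples so that
percentile thresholds and band powers are not contaminated while the waves
themselves remain contiguous for event detection.

Conventions: sample indexing is 0-based, intervals are half-open
``[start, end)``; event times are seconds from recording start and converted
to samples only at the edge.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

STAGES = ("W", "N1", "N2", "N3", "R")
NREM_ANALYSIS_STAGES = ("N2", "N3")

#: events strictly longer than this (seconds) exclude every epoch they touch
MASK_EXCLUSION_SECONDS = 5.0

MASTOID_LABELS = ("M1", "M2", "A1", "A2")


@dataclass
class EEGRecording:
    """Multichannel scalp EEG in microvolts.

    ``data`` has shape (n_channels, n_samples); channels are addressed by
    label, case-insensitively.
    """

    channel_labels: list[str]
    fs: float
    data: np.ndarray
    reference_note: str = ""

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if self.data.shape[0] != len(self.channel_labels):
            raise ValueError(
                f"{len(self.channel_labels)} labels but {self.data.shape[0]} channels"
            )

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Recording duration in seconds."""
        return self.n_samples / self.fs

    def channel(self, label: str) -> np.ndarray:
        """Return one channel by label (case-insensitive)."""
        lowered = [c.lower() for c in self.channel_labels]
        try:
            idx = lowered.index(label.lower())
        except ValueError:
            raise KeyError(
                f"channel {label!r} not in recording (has {self.channel_labels})"
            ) from None
        return self.data[idx]


@dataclass
class Hypnogram:
    """Sleep-stage labels in fixed-length scoring epochs (30 s by default)."""

    stages: list[str]
    epoch_length: float = 30.0
    start_offset: float = 0.0

    def __post_init__(self) -> None:
        bad = sorted(set(self.stages) - set(STAGES))
        if bad:
            raise ValueError(f"unknown stage labels {bad}; allowed: {STAGES}")

    @property
    def n_epochs(self) -> int:
        return len(self.stages)

    def epoch_bounds(self, i: int) -> tuple[float, float]:
        """(start, end) of epoch ``i`` in seconds from recording start."""
        t0 = self.start_offset + i * self.epoch_length
        return t0, t0 + self.epoch_length


@dataclass(frozen=True)
class MaskEvent:
    """An artifact or arousal interval to be excluded from analysis."""

    onset: float
    duration: float
    kind: str = "artifact"

    def __post_init__(self) -> None:
        if self.duration < 0:
            raise ValueError(f"negative mask duration {self.duration}")

    @property
    def offset(self) -> float:
        return self.onset + self.duration


@dataclass(frozen=True, order=True)
class SampleInterval:
    """Half-open, 0-based sample interval ``[start, end)``."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"bad interval [{self.start}, {self.end})")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class SegmentSelection:
    """Artifact-free N2/N3 analysis segments plus flagged-sample bookkeeping.

    ``intervals`` are the retained 30-s epochs as sample intervals; ``flagged``
    are sub-intervals within them covered by short (≤ 5 s) mask events, to be
    excluded from percentile and power computations but not from event
    detection.
    """

    intervals: list[SampleInterval] = field(default_factory=list)
    flagged: list[SampleInterval] = field(default_factory=list)

    def total_samples(self) -> int:
        return sum(len(iv) for iv in self.intervals)

    def minutes(self, fs: float) -> float:
        """Total selected time in minutes."""
        return self.total_samples() / fs / 60.0

    def sample_indices(self, include_flagged: bool = True) -> np.ndarray:
        """All selected sample indices, optionally with flagged samples removed."""
        if not self.intervals:
            return np.array([], dtype=np.intp)
        idx = np.concatenate([np.arange(iv.start, iv.end) for iv in self.intervals])
        if not include_flagged and self.flagged:
            bad = np.concatenate([np.arange(iv.start, iv.end) for iv in self.flagged])
            idx = np.setdiff1d(idx, bad, assume_unique=False)
        return idx

    def contiguous_runs(self) -> list[SampleInterval]:
        """Merge adjacent selected intervals into maximal contiguous runs."""
        runs: list[SampleInterval] = []
        for iv in sorted(self.intervals):
            if runs and iv.start == runs[-1].end:
                runs[-1] = SampleInterval(runs[-1].start, iv.end)
            else:
                runs.append(iv)
        return runs


# ---------------------------------------------------------------------------
# readers


def read_recording(path: str | Path, wanted_channels: list[str]) -> EEGRecording:
    """Read an EEG recording from EDF or the package's plain TSV format.

    TSV format: one column per channel, a header row of labels, and a first
    comment line ``# fs=<Hz>``. Channel matching is case-insensitive. A
    requested channel missing from the file raises ``KeyError`` naming it.

    If both mastoid channels (M1/M2 or A1/A2) are present the requested
    channels are re-referenced to the mastoid mean; otherwise signals are used
    as stored.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() == ".edf":
        labels, fs, data = _read_edf(path)
    elif path.suffix.lower() in (".tsv", ".txt", ".csv"):
        labels, fs, data = _read_plain(path)
    else:
        raise ValueError(f"unreadable recording format: {path.suffix!r}")

    lowered = {lab.lower(): i for i, lab in enumerate(labels)}
    rows = []
    for ch in wanted_channels:
        if ch.lower() not in lowered:
            raise KeyError(f"channel {ch!r} not found in {path.name} (has {labels})")
        rows.append(data[lowered[ch.lower()]])
    out = np.vstack(rows)

    mastoids = [lowered[m.lower()] for m in MASTOID_LABELS if m.lower() in lowered]
    if len(mastoids) >= 2:
        ref = data[mastoids[:2]].mean(axis=0)
        out = out - ref
        note = "re-referenced to mastoid mean at load"
    else:
        note = "used as stored (no mastoid pair present)"
        logger.info("no mastoid pair in %s; signals used as stored", path.name)
    return EEGRecording(list(wanted_channels), fs, out, reference_note=note)


def _read_edf(path: Path) -> tuple[list[str], float, np.ndarray]:
    import mne

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    data = raw.get_data() * 1e6  # mne loads EEG in volts
    return list(raw.ch_names), float(raw.info["sfreq"]), data


def _read_plain(path: Path) -> tuple[list[str], float, np.ndarray]:
    with open(path) as fh:
        first = fh.readline().strip()
    if not first.startswith("#") or "fs=" not in first:
        raise ValueError(f"{path.name}: plain recordings need a '# fs=<Hz>' first line")
    fs = float(first.split("fs=")[1].split()[0])
    frame = pd.read_csv(path, sep="\t", comment="#")
    return list(frame.columns), fs, frame.to_numpy().T


def read_hypnogram(path: str | Path, epoch_length: float = 30.0) -> Hypnogram:
    """Read a two-column (epoch index, stage label) TSV hypnogram."""
    frame = pd.read_csv(path, sep="\t", comment="#", header=None,
                        names=["epoch", "stage"])
    frame = frame.sort_values("epoch")
    return Hypnogram(stages=[str(s) for s in frame["stage"]], epoch_length=epoch_length)


def read_masks(path: str | Path) -> list[MaskEvent]:
    """Read mask events from a TSV with columns onset_s, duration_s, kind."""
    frame = pd.read_csv(path, sep="\t", comment="#")
    return [
        MaskEvent(float(r.onset_s), float(r.duration_s), str(r.kind))
        for r in frame.itertuples()
    ]


def write_hypnogram(path: str | Path, hypnogram: Hypnogram) -> None:
    with open(path, "w") as fh:
        for i, stage in enumerate(hypnogram.stages):
            fh.write(f"{i}\t{stage}\n")


def write_masks(path: str | Path, masks: list[MaskEvent]) -> None:
    with open(path, "w") as fh:
        fh.write("onset_s\tduration_s\tkind\n")
        for m in masks:
            fh.write(f"{m.onset}\t{m.duration}\t{m.kind}\n")


# ---------------------------------------------------------------------------
# segment selection and macrostructure


def select_analysis_segments(
    hypnogram: Hypnogram,
    masks: list[MaskEvent],
    fs: float,
    exclusion_seconds: float = MASK_EXCLUSION_SECONDS,
) -> SegmentSelection:
    """Select N2/N3 epochs free of long artifacts/arousals.

    An epoch staged N2 or N3 is retained unless it overlaps a mask event of
    duration strictly greater than ``exclusion_seconds`` (default 5 s). Mask
    events of at most that duration do not exclude an epoch; their samples
    within retained epochs are returned as ``flagged``.
    """
    long_masks = [m for m in masks if m.duration > exclusion_seconds]
    short_masks = [m for m in masks if 0 < m.duration <= exclusion_seconds]

    selection = SegmentSelection()
    for i, stage in enumerate(hypnogram.stages):
        if stage not in NREM_ANALYSIS_STAGES:
            continue
        t0, t1 = hypnogram.epoch_bounds(i)
        if any(m.onset < t1 and m.offset > t0 for m in long_masks):
            continue
        s0, s1 = int(round(t0 * fs)), int(round(t1 * fs))
        selection.intervals.append(SampleInterval(s0, s1))
        for m in short_masks:
            lo = max(t0, m.onset)
            hi = min(t1, m.offset)
            if hi > lo:
                f0, f1 = int(np.floor(lo * fs)), int(np.ceil(hi * fs))
                selection.flagged.append(SampleInterval(max(f0, s0), min(f1, s1)))

    if not selection.intervals:
        logger.warning("no artifact-free N2/N3 epochs selected")
    return selection


def macro_summary(hypnogram: Hypnogram) -> dict[str, float]:
    """Total sleep time (minutes) and each stage's share of TST (percent).

    TST is the summed duration of all non-wake epochs. Raises ``ValueError``
    on an all-wake hypnogram, where stage percentages are undefined.
    """
    minutes_per_epoch = hypnogram.epoch_length / 60.0
    counts = {s: hypnogram.stages.count(s) for s in STAGES}
    tst_epochs = sum(n for s, n in counts.items() if s != "W")
    if tst_epochs == 0:
        raise ValueError("all-wake hypnogram: TST is zero, stage percentages undefined")
    out: dict[str, float] = {"tst_minutes": tst_epochs * minutes_per_epoch}
    for s in STAGES:
        if s != "W":
            out[f"pct_{s}"] = 100.0 * counts[s] / tst_epochs
    return out
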