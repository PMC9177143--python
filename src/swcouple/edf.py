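"""Minimal European Data Format (EDF) writer.

Writes continuous multichannel signals as 16-bit EDF with one-second data
records, enough for round-tripping synthetic recordings through standard EDF
readers. Physical units are microvolts; per-channel physical min/max are taken
from the data, so quantisation error is (max - min) / 65535.
"""

from __future__ import annotations


from datetime import datetime
from pathlib import Path

import numpy as np

_DIG_MIN, _DIG_MAX = -32768, 32767


def _field(value: str, width: int) -> bytes:
    s = str(value)[:width]
    return s.ljust(width).encode("ascii")


def write_edf(
    path: str | Path,
    data: np.ndarray,
    fs: float,
    channel_labels: list[str],
    physical_dim: str = "uV",
    patient_id: str = "X X X X",
    recording_id: str = "Startdate X X X X",
) -> None:
    """Write ``data`` (n_channels, n_samples) in µV to an EDF file.

    ``fs`` must be a whole number of samples per second; the signal is padded
    with its final value to a whole number of one-second records.
    """
    data = np.atleast_2d(np.asarray(data, dtype=float))
    n_ch, n_samp = data.shape
    if n_ch != len(channel_labels):
        raise ValueError("one label per channel required")
    spr = int(round(fs))
    if abs(spr - fs) > 1e-9 or spr <= 0:
        raise ValueError(f"EDF writer needs an integer sampling rate, got {fs}")
    n_rec = int(np.ceil(n_samp / spr))
    padded = np.empty((n_ch, n_rec * spr))
    padded[:, :n_samp] = data
    padded[:, n_samp:] = data[:, -1:]

    pmin = padded.min(axis=1)
    pmax = padded.max(axis=1)
    # avoid a zero physical span on flat channels
    flat = pmax - pmin < 1e-6
    pmax[flat] += 1.0
    pmin[flat] -= 1.0

    scale = (_DIG_MAX - _DIG_MIN) / (pmax - pmin)
    digital = np.round((padded - pmin[:, None]) * scale[:, None] + _DIG_MIN)
    digital = np.clip(digital, _DIG_MIN, _DIG_MAX).astype("<i2")

    now = datetime(2000, 1, 1)
    header = b"".join(
        [
            _field("0", 8),
            _field(patient_id, 80),
            _field(recording_id, 80),
            _field(now.strftime("%d.%m.%y"), 8),
            _field(now.strftime("%H.%M.%S"), 8),
            _field(str(256 * (1 + n_ch)), 8),
            _field("", 44),
            _field(str(n_rec), 8),
            _field("1", 8),
            _field(str(n_ch), 4),
        ]
    )
    sig = b"".join(
        [
            b"".join(_field(lab, 16) for lab in channel_labels),
            b"".join(_field("", 80) for _ in range(n_ch)),
            b"".join(_field(physical_dim, 8) for _ in range(n_ch)),
            b"".join(_field(f"{v:.7g}"[:8], 8) for v in pmin),
            b"".join(_field(f"{v:.7g}"[:8], 8) for v in pmax),
            b"".join(_field(str(_DIG_MIN), 8) for _ in range(n_ch)),
            b"".join(_field(str(_DIG_MAX), 8) for _ in range(n_ch)),
            b"".join(_field("", 80) for _ in range(n_ch)),
            b"".join(_field(str(spr), 8) for _ in range(n_ch)),
            b"".join(_field("", 32) for _ in range(n_ch)),
        ]
    )
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(sig)
        for r in range(n_rec):
            block = digital[:, r * spr : (r + 1) * spr]
            fh.write(block.tobytes())


def quantisation_step(data: np.ndarray) -> np.ndarray:
    """Per-channel physical resolution of the 16-bit encoding of ``data``."""
    data = np.atleast_2d(np.asarray(data, dtype=float))
    span = data.max(axis=1) - data.min(axis=1)
    span = np.where(span < 1e-6, 2.0, span)
    return span / (_DIG_MAX - _DIG_MIN)
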