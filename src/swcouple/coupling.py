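"""Spindle/slow-wave coincidence and phase-of-coupling assignment.

A coincidence is a spindle whose onset ("ignition") falls inside a SW's time
frame. The onset is then assigned a phase on the SW by the five-landmark
convention: SW start (zero crossing) = 0, maximal hyperpolarisation = pi/2,
mid zero crossing = pi, maximal depolarisation = 3pi/2, SW end = 2pi, with
linear interpolation in time within each quarter. Downstream statistics use
the cosine of that phase, which linearises the circular variable.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .spindle_detect import SpindleEvent
from .sw_detect import SlowWaveEvent

logger = logging.getLogger(__name__)

LANDMARK_PHASES = (0.0, math.pi / 2, math.pi, 3 * math.pi / 2, 2 * math.pi)


@dataclass
class CouplingEvent:
    """One spindle-onset-to-SW match with its phase on the SW."""

    spindle_id: int
    sw_id: int
    channel: str
    phase: float
    switcher: str

    @property
    def cos_phase(self) -> float:
        return math.cos(self.phase)


@dataclass
class SubjectCouplingSummary:
    """Per-subject coupling metrics per switcher type, averaged over channels."""

    subject_id: str
    n_coupled: dict[str, int]
    mean_cos_phase: dict[str, float]  # NaN where a type has no events
    coupling_rate_sw: dict[str, float]
    coupling_rate_spindle: dict[str, float]


def _landmarks(sw: SlowWaveEvent) -> tuple[float, ...]:
    return (sw.t_start, sw.t_neg_peak, sw.t_mid_cross, sw.t_pos_peak, sw.t_end)


def sw_phase_at(sw: SlowWaveEvent, t: float) -> float:
    """Phase of the SW at time ``t``, piecewise linear between the landmarks.

    Exactly {0, pi/2, pi, 3pi/2, 2pi} at the five landmarks and monotone
    non-decreasing in ``t``. Raises for ``t`` outside [t_start, t_end].
    """
    times = _landmarks(sw)
    if not (times[0] <= t <= times[-1]):
        raise ValueError(f"t={t} outside SW [{times[0]}, {times[-1]}]")
    if any(b <= a for a, b in zip(times, times[1:])):
        raise ValueError("degenerate SW with coincident landmarks")
    return float(np.interp(t, times, LANDMARK_PHASES))


def sw_time_at_phase(sw: SlowWaveEvent, phase: float) -> float:
    """Inverse of :func:`sw_phase_at`: the time at which the SW reaches ``phase``."""
    if not (0.0 <= phase <= 2 * math.pi):
        raise ValueError(f"phase {phase} outside [0, 2pi]")
    return float(np.interp(phase, LANDMARK_PHASES, _landmarks(sw)))


def match_spindles_to_sw(
    spindles: list[SpindleEvent], sws: list[SlowWaveEvent]
) -> list[CouplingEvent]:
    """Emit one CouplingEvent per spindle whose onset lies within some SW.

    Both lists must come from the same channel; SWs on a channel never overlap,
    so each spindle matches at most one SW. SWs with coincident landmarks are
    excluded from phase assignment.
    """
    events: list[CouplingEvent] = []
    usable = [
        sw for sw in sws
        if all(b > a for a, b in zip(_landmarks(sw), _landmarks(sw)[1:]))
    ]
    starts = np.array([sw.t_start for sw in usable])
    ends = np.array([sw.t_end for sw in usable])
    for sp in spindles:
        if len(usable) == 0:
            break
        hits = np.flatnonzero((starts <= sp.onset) & (sp.onset <= ends))
        if hits.size == 0:
            continue
        sw = usable[hits[0]]
        events.append(
            CouplingEvent(
                spindle_id=sp.event_id,
                sw_id=sw.event_id,
                channel=sp.channel,
                phase=sw_phase_at(sw, sp.onset),
                switcher=sw.switcher,
            )
        )
    return events


def subject_coupling_summary(
    events: list[CouplingEvent],
    sw_counts: dict[str, int],
    spindle_count: int,
    subject_id: str = "",
    channels: list[str] | None = None,
) -> SubjectCouplingSummary:
    """Summarise coupling per switcher type for one subject.

    The mean cosine of the coupling phase is computed per channel then
    averaged over channels (F3/Fz/F4 in the standard pipeline); coupling rates
    are the fraction of SWs of that type carrying a spindle and the fraction
    of all spindles coupled to that type.
    """
    if channels is None:
        channels = sorted({ev.channel for ev in events}) or [""]
    n_coupled: dict[str, int] = {}
    mean_cos: dict[str, float] = {}
    rate_sw: dict[str, float] = {}
    rate_spindle: dict[str, float] = {}
    for sw_type in ("slow", "fast"):
        typed = [ev for ev in events if ev.switcher == sw_type]
        n_coupled[sw_type] = len(typed)
        per_ch = []
        for ch in channels:
            cos_vals = [ev.cos_phase for ev in typed if ev.channel == ch]
            if cos_vals:
                per_ch.append(float(np.mean(cos_vals)))
        if per_ch:
            mean_cos[sw_type] = float(np.mean(per_ch))
        else:
            mean_cos[sw_type] = float("nan")
            logger.info("subject %s: no %s-switcher coupling events", subject_id, sw_type)
        n_sw = sw_counts.get(sw_type, 0)
        rate_sw[sw_type] = len(typed) / n_sw if n_sw else float("nan")
        rate_spindle[sw_type] = len(typed) / spindle_count if spindle_count else float("nan")
    return SubjectCouplingSummary(
        subject_id=subject_id,
        n_coupled=n_coupled,
        mean_cos_phase=mean_cos,
        coupling_rate_sw=rate_sw,
        coupling_rate_spindle=rate_spindle,
    )


def coupling_bookkeeping(
    n_sw_slow: int,
    n_sw_fast: int,
    n_coupled_slow: int,
    n_coupled_fast: int,
    n_spindles: int,
) -> dict[str, float]:
    """Corpus-level coincidence rates from raw detection counts.

    Returns the percentage of each SW type carrying a spindle, the total
    number of coupled spindles, and the percentages of all spindles coupled to
    any/slow/fast SWs, each rounded to whole percent as conventionally
    reported.
    """
    for name, n in (("n_sw_slow", n_sw_slow), ("n_sw_fast", n_sw_fast),
                    ("n_spindles", n_spindles)):
        if n <= 0:
            raise ValueError(f"{name} must be positive")
    coupled_total = n_coupled_slow + n_coupled_fast
    return {
        "pct_slow_sw_with_spindle": round(100.0 * n_coupled_slow / n_sw_slow),
        "pct_fast_sw_with_spindle": round(100.0 * n_coupled_fast / n_sw_fast),
        "n_coupled_total": coupled_total,
        "pct_spindles_coupled": round(100.0 * coupled_total / n_spindles),
        "pct_spindles_on_slow": round(100.0 * n_coupled_slow / n_spindles),
        "pct_spindles_on_fast": round(100.0 * n_coupled_fast / n_spindles),
    }


def events_to_frame(events: list[CouplingEvent], subject_id: str = "") -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "subject": subject_id,
                "channel": ev.channel,
                "spindle_id": ev.spindle_id,
                "sw_id": ev.sw_id,
                "switcher": ev.switcher,
                "phase_rad": ev.phase,
                "cos_phase": ev.cos_phase,
            }
            for ev in events
        ]
    )
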