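"""Per-subject and cohort orchestration.

``run_subject`` chains segment selection, SW detection, spindle detection,
coupling and the spectral summary for one recording and returns a metrics row
plus the event tables. ``run_cohort`` pools transition frequencies across
subjects, fits the switcher mixture, classifies and couples every subject's
events, and runs the cohort statistics (primary amyloid model, post-hoc
slopes, outlier diagnostics, circular tests, memory-change model).

All default parameters in :class:`PipelineConfig` are the detection settings
the pipeline is specified with (0.3-4 Hz SW band, sex-adapted amplitude
criteria, 10-16 Hz spindle band at the 75th envelope percentile, 0.5-3 s
duration gate, 30-s epochs, 5-s artifact-exclusion rule).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import circstats, cohort_stats, coupling, io_staging, spectral
from . import spindle_detect, sw_detect
from .io_staging import EEGRecording, Hypnogram, MaskEvent

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All tunable parameters, defaulting to the specified detection settings."""

    channels: tuple[str, ...] = ("F3", "Fz", "F4")
    epoch_length: float = 30.0
    mask_exclusion_s: float = 5.0
    sw_band: tuple[float, float] = (0.3, 4.0)
    p2p_min_female: float = 70.0
    neg_amp_max_female: float = -37.0
    p2p_min_male: float = 60.5
    neg_amp_max_male: float = -32.0
    neg_dur_range: tuple[float, float] = (0.125, 1.5)
    pos_dur_max: float = 1.0
    spindle_band: tuple[float, float] = (10.0, 16.0)
    spindle_percentile: float = 75.0
    spindle_duration_range: tuple[float, float] = (0.5, 3.0)
    spindle_smooth_win: float = 0.1
    switcher_scope: str = "pooled"  # or "per-subject"
    switcher_init_split: float = 1.2
    df_method: str = "satterthwaite"
    seed: int = 0

    def criteria(self, sex: str) -> sw_detect.DetectionCriteria:
        if sex == "female":
            amp = (self.p2p_min_female, self.neg_amp_max_female)
        elif sex == "male":
            amp = (self.p2p_min_male, self.neg_amp_max_male)
        else:
            raise ValueError(f"sex must be female or male, got {sex!r}")
        return sw_detect.DetectionCriteria(
            p2p_min=amp[0], neg_amp_max=amp[1],
            neg_dur_range=tuple(self.neg_dur_range),
            pos_dur_max=self.pos_dur_max,
        )

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        kwargs = dict(d)
        for key in ("channels", "sw_band", "neg_dur_range", "spindle_band",
                    "spindle_duration_range"):
            if key in kwargs:
                kwargs[key] = tuple(kwargs[key])
        return cls(**kwargs)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump({k: list(v) if isinstance(v, tuple) else v
                            for k, v in self.to_dict().items()}, fh)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass
class SubjectResult:
    """Everything run_subject produces for one recording."""

    subject_id: str
    sex: str
    sw_events: list
    spindle_events: list
    segments: io_staging.SegmentSelection
    n2n3_minutes: float
    band_power: spectral.BandPowerSummary | None
    coupling_events: list = field(default_factory=list)
    metrics: dict = field(default_factory=dict)


def run_subject(
    config: PipelineConfig,
    recording: EEGRecording,
    hypnogram: Hypnogram,
    masks: list[MaskEvent],
    sex: str,
    subject_id: str = "",
    switcher_model: sw_detect.SwitcherModel | None = None,
) -> SubjectResult:
    """Detect events for one subject; classify/couple if a model is given.

    Stage errors are re-raised with the stage name for context.
    """
    def stage(name, fn):
        try:
            return fn()
        except Exception as exc:
            raise RuntimeError(f"subject {subject_id or '?'}: {name} failed: {exc}") from exc

    segments = stage("segment selection", lambda: io_staging.select_analysis_segments(
        hypnogram, masks, recording.fs, config.mask_exclusion_s))
    if not segments.intervals:
        raise RuntimeError(f"subject {subject_id or '?'}: segment selection "
                           "yielded no artifact-free N2/N3 epochs")
    minutes = segments.minutes(recording.fs)

    criteria = config.criteria(sex)
    sw_events: list = []
    spindle_events: list = []
    for ch in config.channels:
        raw = stage("channel access", lambda ch=ch: recording.channel(ch))
        filtered = stage("SW filtering", lambda raw=raw: sw_detect.fir_bandpass(
            raw, recording.fs, *config.sw_band))
        sw_events.extend(stage("SW detection", lambda f=filtered, ch=ch:
                               sw_detect.detect_slow_waves(
                                   f, recording.fs, sex=sex, segments=segments,
                                   criteria=criteria, channel=ch)))
        spindle_events.extend(stage("spindle detection", lambda raw=raw, ch=ch:
                                    spindle_detect.detect_spindles(
                                        raw, recording.fs, segments=segments,
                                        percentile=config.spindle_percentile,
                                        smooth_win=config.spindle_smooth_win,
                                        duration_range=config.spindle_duration_range,
                                        channel=ch)))
    for k, ev in enumerate(sw_events):
        ev.event_id = k
    for k, ev in enumerate(spindle_events):
        ev.event_id = k
    logger.info("subject %s: %d SWs, %d spindles in %.1f min N2/N3",
                subject_id, len(sw_events), len(spindle_events), minutes)

    band = stage("spectral summary", lambda: spectral.overnight_summary(
        recording, segments, channels=config.channels))

    result = SubjectResult(
        subject_id=subject_id, sex=sex, sw_events=sw_events,
        spindle_events=spindle_events, segments=segments,
        n2n3_minutes=minutes, band_power=band,
    )
    result.metrics = {
        "subject_id": subject_id,
        "sex": sex,
        "n2n3_minutes": minutes,
        "n_sw": len(sw_events),
        "n_spindles": len(spindle_events),
        "spindle_density": spindle_detect.spindle_density(
            spindle_events, minutes, channels=list(config.channels)),
        "swe_delta": band.power["delta"],
        "power_ratio_slow_fast": band.ratio_slow_fast,
    }
    if switcher_model is not None:
        finalize_subject(config, result, switcher_model)
    return result


def finalize_subject(config: PipelineConfig, result: SubjectResult,
                     model: sw_detect.SwitcherModel) -> None:
    """Classify SWs, couple spindles and fill the per-subject metrics row."""
    result.sw_events = sw_detect.classify_switchers(result.sw_events, model)
    result.coupling_events = []
    for ch in config.channels:
        result.coupling_events.extend(
            coupling.match_spindles_to_sw(
                [s for s in result.spindle_events if s.channel == ch],
                [w for w in result.sw_events if w.channel == ch],
            )
        )
    counts = {
        t: sum(1 for ev in result.sw_events if ev.switcher == t)
        for t in ("slow", "fast")
    }
    summary = coupling.subject_coupling_summary(
        result.coupling_events, counts, len(result.spindle_events),
        subject_id=result.subject_id, channels=list(config.channels),
    )
    dens = sw_detect.sw_density(result.sw_events, result.n2n3_minutes,
                                channels=list(config.channels))
    durations = {
        t: float(np.mean([ev.duration for ev in result.sw_events
                          if ev.switcher == t] or [np.nan]))
        for t in ("slow", "fast")
    }
    result.metrics.update({
        "sw_density_total": dens["total"],
        "sw_density_slow": dens["slow"],
        "sw_density_fast": dens["fast"],
        "cos_phase_slow": summary.mean_cos_phase["slow"],
        "cos_phase_fast": summary.mean_cos_phase["fast"],
        "sw_duration_slow": durations["slow"],
        "sw_duration_fast": durations["fast"],
        "n_coupled_slow": summary.n_coupled["slow"],
        "n_coupled_fast": summary.n_coupled["fast"],
    })


def run_cohort(
    config: PipelineConfig,
    subject_results: list[SubjectResult],
    covariates: pd.DataFrame,
    out_dir: str | Path | None = None,
) -> dict:
    """Pool, classify and couple all subjects, then run the cohort statistics.

    ``covariates`` must carry subject_id, age, sex, tst, centiloid (and
    optionally education, rm_baseline, rm_followup for the memory model).
    Returns a JSON-serialisable report; writes it (plus the metrics table)
    under ``out_dir`` when given.
    """
    if len(subject_results) < 10:
        raise ValueError("cohort analysis needs at least 10 subjects")
    required = {"subject_id", "age", "sex", "tst", "centiloid"}
    missing = required - set(covariates.columns)
    if missing:
        raise KeyError(f"covariates table lacks columns {sorted(missing)}")

    pooled = np.concatenate([
        [ev.transition_freq for ev in res.sw_events] for res in subject_results
    ])
    model = sw_detect.fit_switcher_model(
        pooled, seed=config.seed, init_split=config.switcher_init_split)
    for res in subject_results:
        finalize_subject(config, res, model)

    metrics = pd.DataFrame([res.metrics for res in subject_results])
    table = metrics.merge(
        covariates.drop(columns=[c for c in ("sex",) if c in covariates.columns
                                 and c in metrics.columns]),
        on="subject_id", how="inner",
    )

    long_rows = []
    for _, r in table.iterrows():
        for sw_type in ("slow", "fast"):
            long_rows.append({
                "subject_id": r.subject_id, "switcher": sw_type,
                "cos_phase": r[f"cos_phase_{sw_type}"],
                "sw_duration": r[f"sw_duration_{sw_type}"],
                "centiloid": r.centiloid, "age": r.age, "sex": r.sex,
                "tst": r.tst,
            })
    long_table = pd.DataFrame(long_rows)

    primary = cohort_stats.fit_primary_model(long_table)
    posthoc = cohort_stats.posthoc_slopes(primary)
    cooks = cohort_stats.cooks_check(primary)

    phases = {
        t: np.array([ev.phase for res in subject_results
                     for ev in res.coupling_events if ev.switcher == t])
        for t in ("slow", "fast")
    }
    circ: dict[str, dict] = {}
    if min(len(v) for v in phases.values()) >= 2:
        two = circstats.watson_u2(phases["slow"], phases["fast"],
                                  seed=config.seed)
        circ["slow_vs_fast"] = {"u2": two.u2, "p": two.p, "method": two.method}
        for t in ("slow", "fast"):
            uni = circstats.uniformity_by_reference(
                phases[t], n_reps=5, seed=config.seed)
            circ[f"uniformity_{t}"] = {"u2": uni.u2, "median_p": uni.median_p}

    report = {
        "n_subjects": len(subject_results),
        "switcher_model": {
            "means": list(model.means), "sds": list(model.sds),
            "weights": list(model.weights), "threshold": model.threshold,
            "n": model.n,
        },
        "primary_model": _fit_to_dict(primary),
        "posthoc_slopes": posthoc.to_dict(orient="records"),
        "max_cooks_distance": float(cooks.cooks_distance.max()),
        "circular": circ,
    }

    if {"rm_baseline", "rm_followup"}.issubset(table.columns):
        follow = table.dropna(subset=["rm_baseline", "rm_followup"]).copy()
        if len(follow) >= 10 and "education" in follow.columns:
            t, df, p = cohort_stats.paired_change_test(
                follow.rm_baseline.to_numpy(), follow.rm_followup.to_numpy())
            follow["memory_decline"] = [
                cohort_stats.memory_decline(b, f)
                for b, f in zip(follow.rm_baseline, follow.rm_followup)
            ]
            mem = cohort_stats.fit_model(
                follow, dependent="memory_decline",
                fixed=["cos_phase_slow", "age", "sex", "education"],
            )
            report["memory"] = {
                "paired_t": {"t": t, "df": df, "p": p},
                "decline_model": _fit_to_dict(mem),
            }

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        table.to_csv(out_dir / "metrics.tsv", sep="\t", index=False)
        with open(out_dir / "report.json", "w") as fh:
            json.dump(report, fh, indent=2,
                      default=lambda o: o.item() if isinstance(o, np.generic) else str(o))
    return report


def _fit_to_dict(fit: cohort_stats.MixedModelFit) -> dict:
    return {
        "dependent": fit.dependent,
        "effects": {
            name: dataclasses.asdict(eff) for name, eff in fit.effects.items()
        },
        "coefficients": fit.coefficients,
        "random_intercept_var": fit.random_intercept_var,
        "residual_var": fit.residual_var,
        "meta": fit.meta,
    }
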