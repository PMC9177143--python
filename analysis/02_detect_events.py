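"""Detect slow waves and spindles on the simulated night and score recovery.

Reads results/sim/ written by 01_simulate_night.py, runs the segment
selection, SW and spindle detectors on F3, writes the detected event tables,
and reports sensitivity/precision against the ground truth (SWs matched at
the down-state peak, spindles at onset, both within 100 ms).
"""

from pathlib import Path

import numpy as np
import pandas as pd

from swcouple import io_staging, spindle_detect, sw_detect

BASE = Path(__file__).resolve().parent.parent / "results"
SIM = BASE / "sim"


def match_rate(detected, truth, tol=0.1):
    detected, truth = np.asarray(detected), np.asarray(truth)
    sens = np.mean([np.any(np.abs(detected - t) < tol) for t in truth])
    prec = np.mean([np.any(np.abs(truth - d) < tol) for d in detected])
    return sens, prec


def main() -> None:
    rec = io_staging.read_recording(SIM / "recording.edf", ["F3", "Fz", "F4"])
    hyp = io_staging.read_hypnogram(SIM / "hypnogram.tsv")
    segments = io_staging.select_analysis_segments(hyp, [], rec.fs)
    minutes = segments.minutes(rec.fs)

    filtered = sw_detect.fir_bandpass(rec.channel("F3"), rec.fs, 0.3, 4.0)
    sws = sw_detect.detect_slow_waves(filtered, rec.fs, sex="female",
                                      segments=segments, channel="F3")
    spindles = spindle_detect.detect_spindles(rec.channel("F3"), rec.fs,
                                              segments=segments, channel="F3")
    sw_detect.events_to_frame(sws).to_csv(BASE / "detected_sw.tsv", sep="\t",
                                          index=False)
    spindle_detect.events_to_frame(spindles).to_csv(
        BASE / "detected_spindles.tsv", sep="\t", index=False)

    truth_sw = pd.read_csv(SIM / "truth_sw.tsv", sep="\t")
    truth_sw = truth_sw[truth_sw.channel == "F3"]
    truth_sp = pd.read_csv(SIM / "truth_spindles.tsv", sep="\t")
    truth_sp = truth_sp[truth_sp.channel == "F3"]

    sw_sens, sw_prec = match_rate([e.t_neg_peak for e in sws],
                                  truth_sw.t_neg_peak)
    sp_sens, sp_prec = match_rate([e.onset for e in spindles], truth_sp.onset)

    print(f"N2/N3 analysed: {minutes:.1f} min")
    print(f"SWs: {len(sws)} detected / {len(truth_sw)} injected "
          f"-> sensitivity {sw_sens:.3f}, precision {sw_prec:.3f} "
          f"(density {len(sws) / minutes:.1f}/min)")
    print(f"spindles: {len(spindles)} detected / {len(truth_sp)} injected "
          f"-> sensitivity {sp_sens:.3f}, precision {sp_prec:.3f} "
          f"(density {len(spindles) / minutes:.1f}/min)")


if __name__ == "__main__":
    main()
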