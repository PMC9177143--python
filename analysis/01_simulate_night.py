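"""Simulate one subject's miniature night of frontal sleep EEG.

Writes a 10-minute, 200 Hz, three-channel (F3/Fz/F4) recording as EDF with
its hypnogram and exact ground-truth event tables under results/sim/. The
recording carries slow waves at 7/min (81% slow switchers), spindles at
8.3/min, type-dependent spindle-SW coupling, and 1/f background noise.
"""

import sys
from pathlib import Path

from swcouple import edf, io_staging
from swcouple.synthetic import generate_subject_recording

OUT = Path(__file__).resolve().parent.parent / "results" / "sim"
SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 2024


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    rec, hyp, truth = generate_subject_recording(seed=SEED, minutes=10.0)
    edf.write_edf(OUT / "recording.edf", rec.data, rec.fs, rec.channel_labels)
    io_staging.write_hypnogram(OUT / "hypnogram.tsv", hyp)
    sw_frame, spindle_frame = truth.to_frames()
    sw_frame.to_csv(OUT / "truth_sw.tsv", sep="\t", index=False)
    spindle_frame.to_csv(OUT / "truth_spindles.tsv", sep="\t", index=False)

    n_sw = sum(1 for ev in truth.sw_events if ev.channel == "F3")
    n_slow = sum(1 for ev in truth.sw_events
                 if ev.channel == "F3" and ev.switcher == "slow")
    n_sp = sum(1 for d in truth.spindle_onsets if d["channel"] == "F3")
    n_coupled = sum(1 for d in truth.spindle_onsets
                    if d["channel"] == "F3" and d["sw_index"] is not None)
    print(f"wrote {OUT}/recording.edf (seed {SEED})")
    print(f"per channel: {n_sw} SWs ({n_slow} slow switchers), "
          f"{n_sp} spindles of which {n_coupled} SW-coupled")


if __name__ == "__main__":
    main()
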