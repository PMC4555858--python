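"""Build the playback stimulus set: natural series and size-cue-modified calls.

From a jitter-free 'average male' base call (1.7 Hz, 14 pulses, Q25 643 Hz)
the seven modified-signal configurations are constructed: pulse rates of
1 / 1.7 / 3 Hz, pulse counts of 7 / 21, and Q25 shifted to 536 / 804 Hz.
Each is rendered as a two-repetition series at 116 dB peak re 20 uPa at 1 m
(three repetitions and three distinct calls for the natural series).  Every
target is re-measured from the built signal before it is accepted.  WAV
renderings go to scratch/ (they are bulky); the measured table is the
deliverable.
"""

import json
from pathlib import Path

import numpy as np

from rivalcall import acoustics, io, playback, synth

SEED = 53
SAMPLE_RATE = 48000.0

ROOT = Path(__file__).resolve().parent.parent
RESULTS = ROOT / "results"
WAV_DIR = ROOT / "scratch" / "stimuli"


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    WAV_DIR.mkdir(parents=True, exist_ok=True)
    base_sig = synth.CallSignature(
        male_id="BASE", pulse_rate=1.7, n_pulses=14,
        centroid_target=1700.0, q25_target=643.0, jitter=0.0,
    )
    base = synth.simulate_call(base_sig, sample_rate=SAMPLE_RATE, seed=SEED)

    rows = []
    for spec in playback.seven_signal_configurations():
        if spec.kind == "mod_pulse_rate":
            call = playback.modify_pulse_rate(base, spec.target_pulse_rate)
            name = f"rate_{spec.target_pulse_rate:g}hz"
        elif spec.kind == "mod_pulse_count":
            call = playback.modify_pulse_count(base, spec.target_n_pulses)
            name = f"count_{spec.target_n_pulses}"
        else:
            call = playback.shift_q25(base, spec.target_q25)
            name = f"q25_{spec.target_q25:g}hz"
        series = playback.build_series([call], spec)
        f = acoustics.extract_features(call)
        rows.append(
            {
                "name": name,
                "kind": spec.kind,
                "repetitions": spec.repetitions,
                "gap_s": spec.gap,
                "measured_pulse_rate_hz": round(f.pulse_rate, 4),
                "measured_n_pulses": f.n_pulses,
                "measured_q25_hz": round(f.q25, 2),
                "rendered_level_db_peak": round(acoustics.peak_level(series), 3),
            }
        )
        io.write_wav(series, WAV_DIR / f"{name}.wav")
        print(
            f"{name:12s} rate {f.pulse_rate:5.2f} Hz, {f.n_pulses:2d} pulses, "
            f"Q25 {f.q25:6.1f} Hz, level {acoustics.peak_level(series):6.2f} dB"
        )
    with open(RESULTS / "stimuli.json", "w") as fh:
        json.dump(rows, fh, indent=2)
    print(f"{len(rows)} stimulus configurations; wrote {RESULTS / 'stimuli.json'}, "
          f"WAVs under {WAV_DIR}")


if __name__ == "__main__":
    main()
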