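#!/usr/bin/env python
"""Generate a demonstration recording session.

Simulates 2 h of the pressure-coupled sleep model with one REM-off
unit, synthesises EEG/EMG at 500 Hz, and writes everything (with ground
truth) under results/session/.
"""

import json
from pathlib import Path

import numpy as np

from remgate import io, synthgen
from remgate.params import GeneratorParams

OUT = Path("results/session")
SEED = 1
FS = 500.0


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    params = GeneratorParams(seed=SEED)
    hyp, truth = synthgen.simulate_hypnogram(params, 2 * 3600, seed=SEED)
    eeg, emg = synthgen.synthesize_eeg_emg(hyp, FS, params, seed=SEED + 1)
    spikes = synthgen.simulate_unit(hyp, params, seed=SEED + 2, truth=truth)

    io.write_hypnogram(hyp, OUT / "hypnogram.tsv")
    io.write_signal(eeg, FS, OUT / "eeg.bin", "eeg")
    io.write_signal(emg, FS, OUT / "emg.bin", "emg")
    io.write_spikes(spikes, OUT / "spikes.csv")
    io.write_ground_truth(truth, OUT / "truth.json")

    summary = {
        "seed": SEED,
        "n_epochs": hyp.n_epochs,
        "state_fractions": {s: float(np.mean(hyp.labels == s))
                            for s in "WNR"},
        "n_spikes": spikes.n_spikes,
        "final_pressure": float(truth.pressure[-1]),
    }
    (OUT / "summary.json").write_text(json.dumps(summary, indent=1))
    print("session written to", OUT)
    for k, v in summary.items():
        print(f"  {k}: {v}")


if __name__ == "__main__":
    main()
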