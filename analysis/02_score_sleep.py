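#!/usr/bin/env python
"""Score the demo session from its EEG/EMG and compare to ground truth.

Reads results/session/ (run 01_simulate_session.py first), applies the
threshold scoring rules, and reports epoch-wise agreement with the
generator's hypnogram plus the session thresholds.
"""

import json
from pathlib import Path

import numpy as np

from remgate import io, staging

SESSION = Path("results/session")
OUT = Path("results/scoring")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    eeg, fs = io.read_signal(SESSION / "eeg.bin")
    emg, _ = io.read_signal(SESSION / "emg.bin")
    truth = io.read_hypnogram(SESSION / "hypnogram.tsv")

    scored, thr, feats = staging.score(eeg, emg, fs)
    io.write_hypnogram(scored, OUT / "hypnogram_scored.tsv")

    agreement = float(np.mean(scored.labels == truth.labels))
    per_state = {s: float(np.mean(scored.labels[truth.labels == s] == s))
                 for s in "WNR"}
    report = {
        "agreement": agreement,
        "per_state_recall": per_state,
        "delta_threshold": thr.delta_threshold,
        "emg_cut": thr.emg_cut,
        "ratio_cut": thr.ratio_cut,
    }
    (OUT / "report.json").write_text(json.dumps(report, indent=1))
    print(f"epoch-wise agreement with ground truth: {agreement:.1%}")
    for s, r in per_state.items():
        print(f"  recall {s}: {r:.1%}")


if __name__ == "__main__":
    main()
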