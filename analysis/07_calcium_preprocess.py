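#!/usr/bin/env python
"""Calcium-movie preprocessing and state analysis of ΔF/F.

Simulates an 8 min miniscope movie (3 ROIs, shared neuropil, bleaching,
integer jitter) whose transient rates follow a REM-off profile on a
fixed hypnogram; runs motion correction, neuropil subtraction (cf
estimated from the vessel regions), ΔF/F, and classifies each ROI from
its state-resolved activity.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from remgate import imaging, synthgen
from remgate.hypnogram import Hypnogram
from remgate.params import GeneratorParams
from remgate.units import RateSeries, classify_unit, state_rates

OUT = Path("results/calcium")
SEED = 90
RATES = {"W": 0.25, "N": 0.2, "R": 0.01}  # transient rates, Hz


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    pattern = [("W", 24), ("N", 80), ("R", 32), ("N", 40), ("W", 16)]
    labels = np.concatenate([[s] * n for s, n in pattern])
    hyp = Hypnogram(labels)
    params = GeneratorParams(seed=SEED)
    rng = np.random.default_rng(SEED)
    events = []
    for _ in range(3):
        ev = []
        for e_idx, lab in enumerate(hyp.labels):
            for _ in range(rng.poisson(RATES[lab] * hyp.epoch_s)):
                ev.append(e_idx * hyp.epoch_s + rng.uniform(0, hyp.epoch_s))
        events.append(np.sort(ev))
    sess = synthgen.simulate_calcium(params, duration_s=hyp.duration_s,
                                     seed=SEED, event_times=events)

    shifts, corrected, flagged = imaging.motion_correct(
        sess.movie.astype(float), max_shift=5)
    exact = float(np.mean((shifts == sess.truth.shifts).all(axis=1)))
    cf, cf_src = imaging.estimate_cf(
        imaging.roi_trace(corrected, sess.bv_polygon),
        imaging.roi_trace(corrected, sess.near_polygon),
        imaging.roi_trace(corrected, sess.offlens_polygon))

    rows = []
    for i, poly in enumerate(sess.rois):
        tr_ = imaging.process_roi(
            corrected, poly, params.frame_hz, cf=cf,
            exclude=[p for j, p in enumerate(sess.rois) if j != i])
        per_epoch = tr_.dff.reshape(hyp.n_epochs, -1).mean(axis=1)
        lab = classify_unit(state_rates(RateSeries(per_epoch), hyp))
        rows.append({"roi": i, "category": lab.category,
                     "baseline_slope_per_s": tr_.baseline_slope,
                     "mean_dff": float(tr_.dff.mean())})
    df = pd.DataFrame(rows)
    df.to_csv(OUT / "roi_results.csv", index=False)
    report = {"shift_recovery_exact_fraction": exact,
              "cf_estimated": cf, "cf_source": cf_src,
              "cf_true": params.neuropil_gain,
              "categories": df.category.tolist()}
    (OUT / "report.json").write_text(json.dumps(report, indent=1))
    print(f"shifts recovered exactly on {exact:.0%} of frames")
    print(f"cf estimated {cf:.3f} (true {params.neuropil_gain})")
    print("ROI categories:", ", ".join(df.category))


if __name__ == "__main__":
    main()
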