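"""Plain-text interchange formats for sessions.

Hypnograms travel as TSV (epoch_index, t_start_s, label, laser_flag),
laser schedules and ground truth as JSON, spikes as a one-column CSV of
seconds, signals as float32 flat binary with a JSON sidecar, ROI
polygons as JSON vertex lists, movies as multi-page TIFF, and run
configuration as YAML.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .hypnogram import STATES, Hypnogram, LaserSchedule, SpikeTrain


def write_hypnogram(hyp: Hypnogram, path) -> None:
    df = pd.DataFrame({
        "epoch_index": np.arange(hyp.n_epochs),
        "t_start_s": hyp.times(),
        "label": hyp.labels,
        "laser_flag": (hyp.laser.astype(int) if hyp.laser is not None
                       else np.zeros(hyp.n_epochs, dtype=int)),
    })
    df.to_csv(path, sep="\t", index=False)


def read_hypnogram(path) -> Hypnogram:
    df = pd.read_csv(path, sep="\t")
    labels = df["label"].to_numpy(dtype="<U1")
    bad = ~np.isin(labels, STATES)
    if bad.any():
        line = int(np.flatnonzero(bad)[0]) + 2  # 1-based + header
        raise ValueError(f"unknown label {labels[bad][0]!r} at line {line}")
    idx = df["epoch_index"].to_numpy()
    if not np.array_equal(idx, np.arange(len(df))):
        raise ValueError("non-contiguous epochs")
    t = df["t_start_s"].to_numpy(dtype=float)
    epoch_s = float(t[1] - t[0]) if len(t) > 1 else 2.5
    laser = df["laser_flag"].to_numpy(dtype=bool) \
        if "laser_flag" in df else None
    return Hypnogram(labels, epoch_s, laser=laser)


def write_laser_schedule(sched: LaserSchedule, path) -> None:
    obj = {"onsets_s": sched.onsets_s.tolist(),
           "durations_s": sched.durations_s.tolist(),
           "pulse_hz": sched.pulse_hz, "mode": sched.mode}
    Path(path).write_text(json.dumps(obj, indent=1))


def read_laser_schedule(path) -> LaserSchedule:
    obj = json.loads(Path(path).read_text())
    return LaserSchedule(np.array(obj["onsets_s"]),
                         np.array(obj["durations_s"]),
                         pulse_hz=obj.get("pulse_hz", 20.0),
                         mode=obj.get("mode", "open"))


def write_spikes(spikes: SpikeTrain, path) -> None:
    pd.DataFrame({"t_s": spikes.times}).to_csv(path, index=False)


def read_spikes(path, t_end: float | None = None) -> SpikeTrain:
    t = pd.read_csv(path)["t_s"].to_numpy(dtype=float)
    end = t_end if t_end is not None else (t[-1] if t.size else 0.0)
    return SpikeTrain(t, t_end=end)


def write_signal(x: np.ndarray, fs: float, path, channel: str = "eeg") -> None:
    """Float32 flat binary plus a JSON sidecar with fs and channels."""
    path = Path(path)
    np.asarray(x, dtype=np.float32).tofile(path)
    sidecar = {"fs": fs, "channels": [channel], "dtype": "float32",
               "n_samples": int(np.asarray(x).size)}
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(sidecar, indent=1))


def read_signal(path) -> tuple[np.ndarray, float]:
    path = Path(path)
    sidecar = json.loads(
        path.with_suffix(path.suffix + ".json").read_text())
    x = np.fromfile(path, dtype=np.float32)
    if x.size != sidecar["n_samples"]:
        raise ValueError("signal length does not match sidecar")
    return x.astype(float), float(sidecar["fs"])


def write_rois(rois: list, path) -> None:
    Path(path).write_text(json.dumps(
        [np.asarray(p).tolist() for p in rois], indent=1))


def read_rois(path) -> list:
    return [np.array(p, dtype=float)
            for p in json.loads(Path(path).read_text())]


def write_movie(movie: np.ndarray, path) -> None:
    import tifffile

    tifffile.imwrite(path, np.asarray(movie, dtype=np.float32),
                     photometric="minisblack")


def read_movie(path) -> np.ndarray:
    import tifffile

    return np.asarray(tifffile.imread(path), dtype=float)


def write_ground_truth(truth, path) -> None:
    obj = {}
    if truth.pressure is not None:
        obj["pressure"] = np.asarray(truth.pressure).tolist()
    if truth.unit_gain is not None:
        obj["unit_gain"] = np.asarray(truth.unit_gain).tolist()
    if truth.shifts is not None:
        obj["shifts"] = np.asarray(truth.shifts).tolist()
    Path(path).write_text(json.dumps(obj))
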