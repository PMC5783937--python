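"""EEG/EMG sleep scoring.

Brain states are scored on 2.5 s epochs from spectral features: the EEG
power spectrum is computed in 5 s Hann-tapered windows stepped by 2.5 s;
delta power is the summed power in [1, 4) Hz, theta in [6, 12) Hz and
EMG power in [20, 300) Hz.  A delta threshold splits the (typically
bimodal) delta distribution; an epoch is NREM if delta exceeds the
threshold with low EMG, REM if delta is below threshold with a high
theta/delta ratio and low EMG, and wake otherwise.  "Low EMG" and "high
ratio" mean below / above the session mean plus one standard deviation.

A causal online REM detector (used for closed-loop stimulation) is
included: it classifies epochs as they arrive against pre-computed
thresholds and gates the laser at each detected REM onset.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal import get_window

from .hypnogram import Hypnogram

DELTA_BAND = (1.0, 4.0)
THETA_BAND = (6.0, 12.0)
EMG_BAND = (20.0, 300.0)


class DegenerateDeltaWarning(UserWarning):
    """Raised when the delta-power distribution has no usable bimodality."""


@dataclass
class Spectrogram:
    """Power spectra on the epoch grid: one spectrum per 2.5 s step."""

    power: np.ndarray   # (n_epochs, n_freqs), PSD, >= 0
    freqs: np.ndarray   # bin centers, Hz
    times: np.ndarray   # window start per epoch, s
    fs: float
    window_s: float = 5.0
    step_s: float = 2.5

    @property
    def df(self) -> float:
        return float(self.freqs[1] - self.freqs[0])


@dataclass
class FeatureSeries:
    """Per-epoch scoring features."""

    delta: np.ndarray
    theta: np.ndarray
    emg: np.ndarray

    @property
    def ratio(self) -> np.ndarray:
        """Theta/delta ratio; NaN where delta is zero."""
        with np.errstate(divide="ignore", invalid="ignore"):
            r = np.where(self.delta > 0, self.theta / self.delta, np.nan)
        return r

    @property
    def n_epochs(self) -> int:
        return self.delta.size


@dataclass
class StagingThresholds:
    """Session-wide thresholds entering the state rules."""

    delta_threshold: float
    emg_mean: float
    emg_sd: float
    ratio_mean: float
    ratio_sd: float
    degenerate_delta: bool = False

    @property
    def emg_cut(self) -> float:
        return self.emg_mean + self.emg_sd

    @property
    def ratio_cut(self) -> float:
        return self.ratio_mean + self.ratio_sd


def spectrogram(x: np.ndarray, fs: float, window_s: float = 5.0,
                step_s: float = 2.5) -> Spectrogram:
    """Sliding-window periodogram aligned to the epoch grid.

    Windows of ``window_s`` start at every epoch boundary (``step_s``
    apart).  The final epochs, whose full window would run past the end
    of the signal, reuse the last complete window so that the output has
    exactly one spectrum per epoch of the recording.
    """
    x = np.asarray(x, dtype=float)
    if fs <= 0:
        raise ValueError("fs must be positive")
    nper = int(round(window_s * fs))
    step = int(round(step_s * fs))
    if x.size < nper:
        raise ValueError("signal shorter than one analysis window")
    n_epochs = x.size // step
    win = get_window("hann", nper)
    scale = 1.0 / (fs * (win ** 2).sum())
    starts = np.arange(0, x.size - nper + 1, step)
    frames = np.lib.stride_tricks.sliding_window_view(x, nper)[::step]
    spec = np.abs(np.fft.rfft(frames * win, axis=1)) ** 2 * scale
    spec[:, 1:-1] *= 2.0  # one-sided PSD
    if spec.shape[0] < n_epochs:  # pad tail epochs with last full window
        pad = np.repeat(spec[-1:], n_epochs - spec.shape[0], axis=0)
        spec = np.vstack([spec, pad])
    freqs = np.fft.rfftfreq(nper, 1.0 / fs)
    times = np.arange(n_epochs) * step_s
    return Spectrogram(power=spec, freqs=freqs, times=times, fs=fs,
                       window_s=window_s, step_s=step_s)


def band_power(spec: Spectrogram, lo: float, hi: float) -> np.ndarray:
    """Summed power over the half-open frequency band [lo, hi).

    The half-open convention makes band power exactly additive over a
    partition of bands.
    """
    if not (0 <= lo < hi <= spec.fs / 2):
        raise ValueError("band must satisfy 0 <= lo < hi <= fs/2")
    sel = (spec.freqs >= lo) & (spec.freqs < hi)
    if not sel.any():
        raise ValueError(f"band [{lo}, {hi}) contains no frequency bins")
    return spec.power[:, sel].sum(axis=1) * spec.df


def normalize_spectrogram(spec: Spectrogram) -> Spectrogram:
    """Divide each frequency row by its temporal mean (row means -> 1)."""
    means = spec.power.mean(axis=0)
    bad = np.flatnonzero(means <= 0)
    if bad.size:
        raise ValueError(
            f"frequency {spec.freqs[bad[0]]:g} Hz has non-positive mean power"
        )
    return Spectrogram(power=spec.power / means, freqs=spec.freqs,
                       times=spec.times, fs=spec.fs,
                       window_s=spec.window_s, step_s=spec.step_s)


def compute_features(eeg: np.ndarray, emg: np.ndarray,
                     fs: float) -> FeatureSeries:
    """Delta/theta/EMG band powers per epoch from raw signals."""
    es = spectrogram(eeg, fs)
    ms = spectrogram(emg, fs)
    emg_hi = min(EMG_BAND[1], fs / 2)
    return FeatureSeries(
        delta=band_power(es, *DELTA_BAND),
        theta=band_power(es, *THETA_BAND),
        emg=band_power(ms, EMG_BAND[0], emg_hi),
    )


def estimate_delta_threshold(delta: np.ndarray) -> float:
    """Threshold separating the bimodal delta-power distribution.

    Otsu's intra-class-variance-minimising split, computed on log delta
    power (band powers are approximately log-normal within state), then
    mapped back to the linear domain.  On a degenerate (constant)
    distribution a :class:`DegenerateDeltaWarning` is issued and the
    variance-minimising split of whatever spread exists is returned.
    """
    delta = np.asarray(delta, dtype=float)
    if delta.size < 100:
        raise ValueError("need at least 100 epochs to estimate the threshold")
    if np.any(delta <= 0):
        raise ValueError("delta power must be positive")
    logd = np.log(delta)
    if np.ptp(logd) < 1e-12:
        warnings.warn("delta-power distribution is degenerate (constant)",
                      DegenerateDeltaWarning, stacklevel=2)
        return float(delta[0])
    from skimage.filters import threshold_otsu

    thr_log = threshold_otsu(logd, nbins=512)
    return float(np.exp(thr_log))


def compute_thresholds(features: FeatureSeries) -> StagingThresholds:
    """Session-wide thresholds: Otsu delta split plus mean/SD of EMG power
    and of the theta/delta ratio (ratio stats over defined epochs only)."""
    degenerate = False
    with warnings.catch_warnings(record=True) as rec:
        warnings.simplefilter("always", DegenerateDeltaWarning)
        thr = estimate_delta_threshold(features.delta)
        degenerate = any(issubclass(w.category, DegenerateDeltaWarning)
                         for w in rec)
    ratio = features.ratio
    ratio_ok = ratio[np.isfinite(ratio)]
    return StagingThresholds(
        delta_threshold=thr,
        emg_mean=float(features.emg.mean()),
        emg_sd=float(features.emg.std()),
        ratio_mean=float(ratio_ok.mean()) if ratio_ok.size else 0.0,
        ratio_sd=float(ratio_ok.std()) if ratio_ok.size else 0.0,
        degenerate_delta=degenerate,
    )


def _classify_one(delta: float, ratio: float, emg: float,
                  thr: StagingThresholds) -> str:
    emg_low = emg < thr.emg_cut
    if delta > thr.delta_threshold and emg_low:
        return "N"
    # NaN ratio (delta == 0) fails the ratio criterion
    if (delta < thr.delta_threshold and np.isfinite(ratio)
            and ratio > thr.ratio_cut and emg_low):
        return "R"
    return "W"


def classify_epochs(features: FeatureSeries,
                    thr: StagingThresholds) -> Hypnogram:
    """Apply the threshold state rules to every epoch.

    NREM and REM conditions sit on opposite sides of the delta threshold,
    so the two rules are mutually exclusive; everything else is wake.
    """
    delta, ratio, emg = features.delta, features.ratio, features.emg
    emg_low = emg < thr.emg_cut
    is_n = (delta > thr.delta_threshold) & emg_low
    is_r = ((delta < thr.delta_threshold) & np.isfinite(ratio)
            & (ratio > thr.ratio_cut) & emg_low)
    labels = np.full(features.n_epochs, "W", dtype="<U1")
    labels[is_n] = "N"
    labels[is_r] = "R"
    return Hypnogram(labels)


def score(eeg: np.ndarray, emg: np.ndarray, fs: float
          ) -> tuple[Hypnogram, StagingThresholds, FeatureSeries]:
    """End-to-end scoring: features -> thresholds -> hypnogram."""
    feats = compute_features(eeg, emg, fs)
    thr = compute_thresholds(feats)
    return classify_epochs(feats, thr), thr, feats


def closed_loop_detector(features: FeatureSeries, thr: StagingThresholds,
                         gate_p: float = 0.5,
                         seed: int | None = None) -> list[tuple[int, int]]:
    """Causal online REM detection with probabilistic laser gating.

    Epochs are classified one at a time, in order, using only the
    pre-computed thresholds (no future data).  At the first epoch of
    each detected REM episode the laser switches on with probability
    ``gate_p`` and stays on until the first subsequent non-REM epoch.

    Returns a list of (on_epoch, off_epoch) half-open laser intervals.
    """
    rng = np.random.default_rng(seed)
    events: list[tuple[int, int]] = []
    in_rem = False
    laser_on = False
    onset = -1
    for i in range(features.n_epochs):
        state = _classify_one(features.delta[i], features.ratio[i],
                              features.emg[i], thr)
        if state == "R" and not in_rem:
            in_rem = True
            if rng.random() < gate_p:
                laser_on = True
                onset = i
        elif state != "R" and in_rem:
            in_rem = False
            if laser_on:
                events.append((onset, i))
                laser_on = False
    if laser_on:
        events.append((onset, features.n_epochs))
    return events
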