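"""Synthetic sleep sessions with the statistical structure the analyses assume.

Every downstream stage of the pipeline (staging, transition statistics,
unit analyses, tagging, prediction, calcium preprocessing) is exercised
against sessions produced here, for which the ground truth — hypnogram,
REM-pressure trajectory, unit gain, calcium events and motion shifts —
is known exactly.

The hypnogram generator is an epoch-level (2.5 s) semi-Markov chain whose
NREM->REM hazard is coupled to a homeostatic REM pressure; see
:mod:`remgate.params` for the model.  Laser protocols modify the chain
through hazard multipliers only, so null experiments (all multipliers 1)
and effect experiments share one code path.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps
from scipy import ndimage

from .hypnogram import Hypnogram, LaserSchedule, SpikeTrain
from .params import GeneratorParams

__all__ = [
    "GroundTruth",
    "simulate_hypnogram",
    "simulate_open_loop",
    "simulate_closed_loop",
    "synthesize_eeg_emg",
    "simulate_unit",
    "simulate_calcium",
    "simulate_tagged_unit",
    "CalciumSession",
]


@dataclass
class GroundTruth:
    """Everything the generator knows that the analyses must recover."""

    hypnogram: Hypnogram | None = None
    pressure: np.ndarray | None = None       # per epoch, at epoch start
    unit_gain: np.ndarray | None = None      # per epoch slow gain g(t)
    unit_rate: np.ndarray | None = None      # per epoch Poisson rate (Hz)
    ca_event_times: list | None = None       # per ROI, seconds
    ca_clean_traces: np.ndarray | None = None  # (n_rois, n_frames)
    shifts: np.ndarray | None = None         # (n_frames, 2) int px (dy, dx)


# ---------------------------------------------------------------------------
# hypnogram chain
# ---------------------------------------------------------------------------

def _step_hazards(state: str, pressure: float, params: GeneratorParams,
                  laser_on: bool) -> list[tuple[str, float]]:
    """Per-epoch exit hazards from `state`, laser multipliers applied."""
    m = params.laser_mult if laser_on else None

    def mult(key: str) -> float:
        return m[key] if (m is not None and key in m) else 1.0

    if state == "W":
        out = [("N", params.h_w2n * mult("WN"))]
    elif state == "N":
        out = [("W", params.h_n2w * mult("NW")),
               ("R", params.n2r_hazard(pressure) * mult("NR"))]
    else:  # R
        out = [("W", params.h_r2w * mult("RW")),
               ("N", params.h_r2n * mult("RN"))]
    return [(s, min(max(h, 0.0), 1.0)) for s, h in out]


def _run_chain(params: GeneratorParams, n_epochs: int, rng: np.random.Generator,
               laser_mask: np.ndarray | None = None,
               closed_loop: bool = False,
               initial_state: str = "W") -> tuple[np.ndarray, np.ndarray,
                                                  np.ndarray, list]:
    """Simulate the state chain epoch by epoch.

    Returns (labels, pressure, laser, closed_loop_trials) where
    closed_loop_trials is a list of (onset_epoch, offset_epoch) pairs.
    """
    labels = np.empty(n_epochs, dtype="<U1")
    pressure = np.empty(n_epochs, dtype=float)
    laser = np.zeros(n_epochs, dtype=bool)
    trials: list[tuple[int, int]] = []

    state = initial_state
    p = params.initial_pressure
    cl_on = False
    cl_onset = -1
    dt = params.epoch_s

    for i in range(n_epochs):
        if closed_loop:
            if state == "R" and not cl_on and (i == 0 or labels[i - 1] != "R"):
                # fresh REM onset: gate the laser
                if rng.random() < params.closed_gate_p:
                    cl_on = True
                    cl_onset = i
            if cl_on and state != "R":
                trials.append((cl_onset, i))
                cl_on = False
            on = cl_on
        else:
            on = bool(laser_mask[i]) if laser_mask is not None else False

        labels[i] = state
        pressure[i] = p
        laser[i] = on

        # pressure update over this epoch
        if state == "N":
            p += params.rem_pressure_gain * dt
        elif state == "R":
            p = max(0.0, p - params.rem_dissipation * dt)

        # draw next state
        hazards = _step_hazards(state, p, params, on)
        total = sum(h for _, h in hazards)
        if total > 1.0:  # defensive; defaults never reach this
            hazards = [(s, h / total) for s, h in hazards]
            total = 1.0
        u = rng.random()
        acc = 0.0
        for s, h in hazards:
            acc += h
            if u < acc:
                state = s
                break

    if closed_loop and cl_on:
        trials.append((cl_onset, n_epochs))
    return labels, pressure, laser, trials


def simulate_hypnogram(params: GeneratorParams, duration_s: float,
                       seed: int | None = None) -> tuple[Hypnogram, GroundTruth]:
    """Simulate a laser-free session of `duration_s` seconds.

    The returned ground truth carries the latent REM-pressure trajectory
    (value at each epoch start), piecewise linear with slope
    ``+rem_pressure_gain`` in NREM, ``-rem_dissipation`` in REM (floored
    at 0), and 0 in wake.
    """
    params.validate()
    n_epochs = int(round(duration_s / params.epoch_s))
    if n_epochs < 10:
        raise ValueError("duration_s must cover at least 10 epochs")
    rng = np.random.default_rng(params.seed if seed is None else seed)
    labels, pressure, _, _ = _run_chain(params, n_epochs, rng)
    hyp = Hypnogram(labels, params.epoch_s)
    return hyp, GroundTruth(hypnogram=hyp, pressure=pressure)


def simulate_open_loop(params: GeneratorParams, duration_s: float,
                       seed: int | None = None
                       ) -> tuple[LaserSchedule, Hypnogram, GroundTruth]:
    """Open-loop stimulation session: 300 s pulse trains at 20 Hz with
    inter-trial intervals drawn uniformly from 15-25 min; during each
    trial the chain's hazards are multiplied by the laser-effect factors.
    """
    params.validate()
    if duration_s <= params.iti_min_s:
        # still valid, but at most the initial ITI fits; may yield 0 trials
        pass
    rng = np.random.default_rng(params.seed if seed is None else seed)
    onsets = []
    t = rng.uniform(params.iti_min_s, params.iti_max_s)
    while t + params.laser_dur_s <= duration_s:
        onsets.append(t)
        t += params.laser_dur_s + rng.uniform(params.iti_min_s,
                                              params.iti_max_s)
    sched = LaserSchedule(np.array(onsets), np.full(len(onsets),
                                                    params.laser_dur_s),
                          pulse_hz=params.laser_hz, mode="open")
    n_epochs = int(round(duration_s / params.epoch_s))
    mask = sched.mask(n_epochs, params.epoch_s)
    labels, pressure, laser, _ = _run_chain(params, n_epochs, rng,
                                            laser_mask=mask)
    hyp = Hypnogram(labels, params.epoch_s, laser=laser)
    return sched, hyp, GroundTruth(hypnogram=hyp, pressure=pressure)


def simulate_closed_loop(params: GeneratorParams, duration_s: float,
                         seed: int | None = None
                         ) -> tuple[LaserSchedule, Hypnogram, GroundTruth]:
    """Closed-loop REM gating: each REM onset triggers the laser with
    probability ``closed_gate_p``; the laser stays on until the episode
    ends, with the R->W hazard multiplied while on.
    """
    params.validate()
    if params.laser_mult.get("RW", 1.0) < 1.0:
        raise ValueError("closed-loop protocol expects an R->W multiplier >= 1")
    rng = np.random.default_rng(params.seed if seed is None else seed)
    n_epochs = int(round(duration_s / params.epoch_s))
    labels, pressure, laser, trials = _run_chain(params, n_epochs, rng,
                                                 closed_loop=True)
    eps = params.epoch_s
    onsets = np.array([a * eps for a, _ in trials])
    durs = np.array([(b - a) * eps for a, b in trials])
    sched = LaserSchedule(onsets, durs, pulse_hz=params.laser_hz,
                          mode="closed")
    hyp = Hypnogram(labels, eps, laser=laser)
    return sched, hyp, GroundTruth(hypnogram=hyp, pressure=pressure)


# ---------------------------------------------------------------------------
# EEG / EMG
# ---------------------------------------------------------------------------

def _bandpass(x: np.ndarray, lo: float, hi: float, fs: float) -> np.ndarray:
    sos = sps.butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, x)


def synthesize_eeg_emg(hyp: Hypnogram, fs: float, params: GeneratorParams,
                       seed: int | None = None) -> tuple[np.ndarray, np.ndarray]:
    """State-conditioned EEG and EMG for a hypnogram.

    The EEG is a mixture of a delta (1-4 Hz), theta (6-12 Hz) and
    broadband component whose amplitudes follow the per-state mixing
    table; the EMG is band-limited (20-300 Hz) noise with per-state
    amplitude and erratic bursts during wake.  Per-state gains are
    crossfaded over ``crossfade_s`` so the signals are continuous at
    epoch boundaries.
    """
    if fs < 100:
        raise ValueError("fs must be at least 100 Hz")
    spe = fs * hyp.epoch_s
    if abs(spe - round(spe)) > 1e-9:
        raise ValueError("fs * epoch_s must be an integer number of samples")
    spe = int(round(spe))
    n = spe * hyp.n_epochs
    rng = np.random.default_rng(params.seed if seed is None else seed)

    white_eeg = rng.standard_normal(n)
    delta_c = _bandpass(white_eeg, 1.0, 4.0, fs)
    theta_c = _bandpass(white_eeg, 6.0, 12.0, fs)
    broad_c = rng.standard_normal(n)
    emg_hi = min(300.0, 0.45 * fs)
    emg_c = _bandpass(rng.standard_normal(n), 20.0, emg_hi, fs)

    def per_sample(gains_per_epoch: np.ndarray) -> np.ndarray:
        g = np.repeat(gains_per_epoch, spe)
        w = max(1, int(round(params.crossfade_s * fs)))
        return ndimage.uniform_filter1d(g, size=w, mode="nearest")

    mix = params.eeg_mix
    g_delta = per_sample(np.array([mix[s]["delta"] for s in hyp.labels]))
    g_theta = per_sample(np.array([mix[s]["theta"] for s in hyp.labels]))
    g_broad = per_sample(np.array([mix[s]["broad"] for s in hyp.labels]))
    eeg = (g_delta * delta_c + g_theta * theta_c + g_broad * broad_c
           + params.eeg_noise_amp * rng.standard_normal(n))

    amp = np.array([params.emg_amp[s] for s in hyp.labels])
    burst = np.where(hyp.labels == "W",
                     rng.uniform(0.5, 2.0, hyp.n_epochs), 1.0)
    g_emg = per_sample(amp * burst)
    emg = g_emg * emg_c + params.emg_noise_amp * rng.standard_normal(n)
    return eeg, emg


# ---------------------------------------------------------------------------
# single units
# ---------------------------------------------------------------------------

def unit_gain_trajectory(hyp: Hypnogram, params: GeneratorParams) -> np.ndarray:
    """Slow multiplicative gain g(t) of the simulated unit, per epoch.

    g starts at 1, decays by ``unit_drift_per_min`` per minute spent in
    NREM (floored at ``unit_gain_floor``), is frozen during wake and REM,
    and at each REM offset jumps up by ``unit_reset_per_s`` x REM episode
    duration, capped at the starting value 1.
    """
    n = hyp.n_epochs
    g = np.empty(n, dtype=float)
    val = 1.0
    dt = hyp.epoch_s
    labels = hyp.labels
    i = 0
    while i < n:
        if labels[i] == "R":
            j = i
            while j < n and labels[j] == "R":
                g[j] = val
                j += 1
            rem_dur = (j - i) * dt
            if j < n:  # REM offset inside the recording: reset
                val = min(1.0, val + params.unit_reset_per_s * rem_dur)
            i = j
        else:
            g[i] = val
            if labels[i] == "N":
                val = max(params.unit_gain_floor,
                          val - params.unit_drift_per_min * dt / 60.0)
            i += 1
    return g


def simulate_unit(hyp: Hypnogram, params: GeneratorParams,
                  seed: int | None = None,
                  truth: GroundTruth | None = None) -> SpikeTrain:
    """Inhomogeneous Poisson spike train with state-dependent base rate
    modulated by the slow gain from :func:`unit_gain_trajectory`."""
    if any(r < 0 for r in params.unit_rates.values()):
        raise ValueError("unit rates must be non-negative")
    rng = np.random.default_rng(params.seed if seed is None else seed)
    g = unit_gain_trajectory(hyp, params)
    base = np.array([params.unit_rates[s] for s in hyp.labels])
    rate = base * g
    dt = hyp.epoch_s
    counts = rng.poisson(rate * dt)
    times = []
    t0 = hyp.times()
    for i, c in enumerate(counts):
        if c:
            times.append(t0[i] + rng.uniform(0, dt, c))
    all_t = np.sort(np.concatenate(times)) if times else np.array([])
    if truth is not None:
        truth.unit_gain = g
        truth.unit_rate = rate
    return SpikeTrain(all_t, t_end=hyp.duration_s)


# ---------------------------------------------------------------------------
# optogenetic tagging sessions
# ---------------------------------------------------------------------------

def simulate_tagged_unit(kind: str, seed: int, n_trains: int = 40,
                         base_rate_hz: float = 8.0,
                         latency_s: float = 0.003,
                         reliability: float = 0.8,
                         jitter_s: float = 0.0005):
    """Synthetic tagging session for one unit.

    Trains of laser pulses are delivered every 60 s, alternating a 15 Hz
    1 s train and a 30 Hz 0.5 s train.  ``kind`` selects the unit model:

    * ``"responder"`` — baseline Poisson firing plus, after each pulse, a
      spike at ``latency_s`` (+/- jitter) with probability ``reliability``;
    * ``"inhibited"`` — firing silenced during trains;
    * ``"null"`` — homogeneous Poisson, ignores the laser.

    Returns ``(spikes, pulses, trains)`` where ``trains`` is an array of
    (onset_s, duration_s, pulse_hz) rows.
    """
    if kind not in ("responder", "inhibited", "null"):
        raise ValueError(f"unknown unit kind {kind!r}")
    rng = np.random.default_rng(seed)
    trains = []
    pulses = []
    t = 30.0
    for k in range(n_trains):
        hz, dur = (15.0, 1.0) if k % 2 == 0 else (30.0, 0.5)
        trains.append((t, dur, hz))
        pulses.append(t + np.arange(int(round(hz * dur))) / hz)
        t += 60.0
    t_end = t + 30.0
    pulses = np.concatenate(pulses)
    trains = np.array(trains)

    # baseline Poisson train over the whole session
    n_exp = rng.poisson(base_rate_hz * t_end)
    spk = np.sort(rng.uniform(0, t_end, n_exp))

    if kind == "inhibited":
        keep = np.ones(spk.size, dtype=bool)
        for onset, dur, _ in trains:
            keep &= ~((spk >= onset) & (spk < onset + dur))
        spk = spk[keep]
    elif kind == "responder":
        evoked = []
        for p in pulses:
            if rng.random() < reliability:
                evoked.append(p + latency_s + rng.normal(0, jitter_s))
        spk = np.sort(np.concatenate([spk, np.array(evoked)]))
    return SpikeTrain(np.clip(spk, 0, t_end), t_end=t_end), pulses, trains


# ---------------------------------------------------------------------------
# calcium movies
# ---------------------------------------------------------------------------

@dataclass
class CalciumSession:
    """A small synthetic miniscope movie plus its ground truth."""

    movie: np.ndarray                 # (n_frames, H, W) float32, >= 0
    rois: list                        # list of (k, 2) polygon vertices (x, y)
    frame_hz: float
    truth: GroundTruth
    bv_polygon: np.ndarray | None = None       # blood-vessel region
    near_polygon: np.ndarray | None = None     # near-vessel, no-ROI region
    offlens_polygon: np.ndarray | None = None  # off-lens region
    neuropil_trace: np.ndarray | None = None


def _disk_polygon(cx: float, cy: float, r: float, k: int = 16) -> np.ndarray:
    ang = np.linspace(0, 2 * np.pi, k, endpoint=False)
    return np.column_stack([cx + r * np.cos(ang), cy + r * np.sin(ang)])


def _rect_polygon(x0, y0, x1, y1) -> np.ndarray:
    return np.array([[x0, y0], [x1, y0], [x1, y1], [x0, y1]], dtype=float)


def ca_kernel(frame_hz: float, rise_s: float, decay_s: float) -> np.ndarray:
    """Difference-of-exponentials calcium transient, peak-normalised."""
    t = np.arange(0, 6 * decay_s, 1.0 / frame_hz)
    k = (1 - np.exp(-t / rise_s)) * np.exp(-t / decay_s)
    return k / k.max()


def simulate_calcium(params: GeneratorParams, duration_s: float = 120.0,
                     seed: int | None = None, n_rois: int = 3,
                     frame_shape: tuple[int, int] = (64, 64),
                     event_times: list | None = None) -> CalciumSession:
    """Synthetic movie: disk-shaped sources with spike-driven transients,
    one shared neuropil background (appearing inside ROIs scaled by
    ``neuropil_gain``), linear photobleaching, integer frame jitter and
    Gaussian noise.  All ground truth is recorded.
    """
    if params.frame_hz <= 0:
        raise ValueError("frame rate must be positive")
    if n_rois < 1 and event_times is None:
        raise ValueError("at least one ROI is required")
    rng = np.random.default_rng(params.seed if seed is None else seed)
    H, W = frame_shape
    n_frames = int(round(duration_s * params.frame_hz))
    tf = np.arange(n_frames) / params.frame_hz

    # ROI geometry: sources on the left 2/3; vessel/near/off regions right
    radius = 4.0
    margin = 10
    centers = []
    n_rois = n_rois if event_times is None else len(event_times)
    for i in range(n_rois):
        cx = margin + (i % 3) * 14
        cy = margin + (i // 3) * 14
        centers.append((cx, cy))
    rois = [_disk_polygon(cx, cy, radius) for cx, cy in centers]
    for poly in rois:
        if (poly < 0).any() or (poly[:, 0] > W - 1).any() or (poly[:, 1] > H - 1).any():
            raise ValueError("ROI polygon extends outside the frame")

    from skimage.draw import polygon as _sk_polygon

    def rasterize(poly: np.ndarray) -> np.ndarray:
        rr, cc = _sk_polygon(poly[:, 1], poly[:, 0], shape=(H, W))
        m = np.zeros((H, W), dtype=bool)
        m[rr, cc] = True
        return m

    roi_masks = [rasterize(p) for p in rois]

    bv_poly = _rect_polygon(W - 18, 6, W - 12, 26)
    near_poly = _rect_polygon(W - 10, 6, W - 4, 26)
    off_poly = _rect_polygon(W - 10, H - 14, W - 4, H - 4)
    bv_mask, near_mask, off_mask = (rasterize(p) for p in
                                    (bv_poly, near_poly, off_poly))

    # transient traces
    kern = ca_kernel(params.frame_hz, params.ca_rise_s, params.ca_decay_s)
    clean = np.zeros((n_rois, n_frames))
    events = []
    for i in range(n_rois):
        if event_times is not None:
            ev = np.asarray(event_times[i], dtype=float)
        else:
            n_ev = rng.poisson(params.ca_event_hz * duration_s)
            ev = np.sort(rng.uniform(0, duration_s, n_ev))
        events.append(ev)
        impulses = np.zeros(n_frames)
        idx = np.clip((ev * params.frame_hz).astype(int), 0, n_frames - 1)
        for j, a in zip(idx, rng.uniform(0.6, 1.4, idx.size)):
            impulses[j] += a
        clean[i] = np.convolve(impulses, kern)[:n_frames]

    # shared neuropil background: slow positive fluctuation
    npil = ndimage.gaussian_filter1d(rng.standard_normal(n_frames), 20)
    npil = 0.25 + 0.12 * (npil - npil.min()) / max(np.ptp(npil), 1e-12)

    dark = 0.05      # sensor offset, unaffected by bleaching
    cell_base = 0.6  # resting fluorescence of a source
    movie = np.zeros((n_frames, H, W), dtype=float)
    field = np.zeros((H, W))
    # neuropil spatial weight: 1 on-lens, gain inside ROIs/vessel, 0 off-lens
    np_weight = np.ones((H, W))
    for m in roi_masks:
        np_weight[m] = params.neuropil_gain
    np_weight[bv_mask] = params.neuropil_gain
    np_weight[off_mask] = 0.0

    bleach = 1.0 - params.bleach_per_min * tf / 60.0
    src = np.zeros((n_frames, H, W))
    for i, m in enumerate(roi_masks):
        src[:, m] += (cell_base + clean[i])[:, None]
    src[:, off_mask] = 0.0
    src[:, bv_mask] = 0.0  # vessel blocks in-focus light
    fluor = src + np_weight[None, :, :] * npil[:, None, None]
    movie = dark + bleach[:, None, None] * fluor

    # integer jitter, recorded, applied with wrap-around
    if params.jitter_px > 0:
        shifts = rng.integers(-params.jitter_px, params.jitter_px + 1,
                              size=(n_frames, 2))
    else:
        shifts = np.zeros((n_frames, 2), dtype=int)
    for f in range(n_frames):
        if shifts[f, 0] or shifts[f, 1]:
            movie[f] = np.roll(movie[f], (shifts[f, 0], shifts[f, 1]),
                               axis=(0, 1))
    if params.ca_noise_sd > 0:
        movie = movie + rng.normal(0, params.ca_noise_sd, movie.shape)
    movie = np.clip(movie, 0, None).astype(np.float32)

    truth = GroundTruth(ca_event_times=events, ca_clean_traces=clean,
                        shifts=shifts.astype(int))
    return CalciumSession(movie=movie, rois=rois, frame_hz=params.frame_hz,
                          truth=truth, bv_polygon=bv_poly,
                          near_polygon=near_poly, offlens_polygon=off_poly,
                          neuropil_trace=npil)
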