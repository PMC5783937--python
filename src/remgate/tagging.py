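"""Optogenetic tagging: classifying units by their laser-pulse responses.

Units recorded with an optrode are classified as identified (direct,
opsin-driven responders), laser-inhibited, or laser-unmodulated:

1. a response test asks whether spike patterns in 30 ms windows after
   single laser pulses differ from spontaneous spike patterns — here a
   permutation test on the Jensen-Shannon divergence between the evoked
   and spontaneous first-spike-latency histograms (a contract-equivalent
   stand-in for the SALT family of latency tests);
2. the modulation sign compares per-train firing during the 30 Hz pulse
   train with the preceding 0.5 s window (two-sided Wilcoxon signed-rank);
3. excited units pass the identification gates only with median
   first-spike latency < 10 ms and reliability > 0.4.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sstats

from .hypnogram import SpikeTrain

RESPONSE_WINDOW_S = 0.030
LATENCY_GATE_S = 0.010
LATENCY_MAX_MS = 10.0
RELIABILITY_MIN = 0.4


@dataclass
class TagResult:
    p_response: float
    sign: int                    # +1 excited, -1 inhibited, 0 unmodulated
    latency_ms: float            # NaN when no evoked spikes
    reliability: float
    category: str                # identified | inhibited | unmodulated | excluded
    untestable: bool = False


def _first_spike_bins(spikes: np.ndarray, window_starts: np.ndarray,
                      window_s: float, n_bins: int) -> np.ndarray:
    """Histogram-bin index of the first spike in each window.

    Bin ``n_bins`` is the no-spike bucket.  Windows are half-open
    (t0, t0 + window_s].
    """
    out = np.full(window_starts.size, n_bins, dtype=int)
    for i, t0 in enumerate(window_starts):
        j = np.searchsorted(spikes, t0, side="right")
        if j < spikes.size and spikes[j] - t0 <= window_s:
            out[i] = min(int((spikes[j] - t0) / window_s * n_bins),
                         n_bins - 1)
    return out


def _jsd(p: np.ndarray, q: np.ndarray) -> float:
    """Jensen-Shannon divergence of two count vectors."""
    p = p / p.sum()
    q = q / q.sum()
    m = 0.5 * (p + q)

    def kl(a, b):
        sel = a > 0
        return float(np.sum(a[sel] * np.log2(a[sel] / b[sel])))

    return 0.5 * kl(p, m) + 0.5 * kl(q, m)


def default_baseline_windows(trains: np.ndarray, n_windows: int,
                             window_s: float = RESPONSE_WINDOW_S,
                             lead_s: float = 10.0,
                             guard_s: float = 1.0) -> np.ndarray:
    """Spontaneous window start times tiled in the quiet period before
    each train onset (from ``lead_s`` to ``guard_s`` before onset)."""
    starts = []
    for onset in np.atleast_1d(trains[:, 0] if trains.ndim == 2 else trains):
        t = onset - lead_s
        while t + window_s < onset - guard_s:
            starts.append(t)
            t += window_s
    starts = np.array(starts)
    if starts.size > n_windows:
        idx = np.linspace(0, starts.size - 1, n_windows).astype(int)
        starts = starts[idx]
    return starts


def pulse_response_test(spikes: SpikeTrain, pulses: np.ndarray,
                        baseline_starts: np.ndarray,
                        window_s: float = RESPONSE_WINDOW_S,
                        n_perm: int = 500, n_bins: int = 10,
                        seed: int | None = None) -> float:
    """Permutation p-value for laser-pulse modulation.

    The observed statistic is the Jensen-Shannon divergence between the
    first-spike-latency histograms (``n_bins`` latency bins plus a
    no-spike bucket) of evoked windows (one per pulse) and of equally
    sized spontaneous windows.  The null is generated by shuffling the
    evoked/spontaneous labels over the pooled windows.
    """
    pulses = np.asarray(pulses, dtype=float)
    baseline_starts = np.asarray(baseline_starts, dtype=float)
    if pulses.size < 50:
        raise ValueError(f"need >= 50 pulses, got {pulses.size}")
    if baseline_starts.size < 50:
        raise ValueError(
            f"need >= 50 baseline windows, got {baseline_starts.size}")
    if spikes.n_spikes == 0:
        return 1.0
    rng = np.random.default_rng(seed)
    ev = _first_spike_bins(spikes.times, pulses, window_s, n_bins)
    sp = _first_spike_bins(spikes.times, baseline_starts, window_s, n_bins)
    pooled = np.concatenate([ev, sp])
    n_ev = ev.size

    def stat(labels_ev: np.ndarray) -> float:
        h_ev = np.bincount(labels_ev, minlength=n_bins + 1).astype(float)
        h_sp = (np.bincount(pooled, minlength=n_bins + 1) - h_ev).astype(float)
        return _jsd(h_ev, h_sp)

    obs = stat(ev)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(pooled)
        if stat(perm[:n_ev]) >= obs:
            count += 1
    return (count + 1) / (n_perm + 1)


def modulation_sign(spikes: SpikeTrain, trains: np.ndarray,
                    alpha: float = 0.05,
                    pre_s: float = 0.5) -> int:
    """Sign of laser modulation from the 30 Hz trains.

    Per train, the firing rate during the train is paired with the rate
    in the 0.5 s window preceding it; a two-sided Wilcoxon signed-rank
    test decides significance and the median difference the sign
    (0 when not significant).
    """
    trains = np.atleast_2d(np.asarray(trains, dtype=float))
    hf = trains[trains[:, 2] >= 25.0] if trains.shape[1] >= 3 else trains
    if hf.shape[0] < 10:
        raise ValueError(f"need >= 10 trains, got {hf.shape[0]}")
    t = spikes.times
    during = np.array([np.sum((t >= on) & (t < on + dur)) / dur
                       for on, dur, *_ in hf])
    before = np.array([np.sum((t >= on - pre_s) & (t < on)) / pre_s
                       for on, dur, *_ in hf])
    d = during - before
    if np.all(d == 0):
        return 0
    p = sstats.wilcoxon(during, before).pvalue
    if p >= alpha:
        return 0
    return int(np.sign(np.median(d))) or int(np.sign(d.mean()))


def latency_reliability(spikes: SpikeTrain, pulses: np.ndarray,
                        gate_s: float = LATENCY_GATE_S
                        ) -> tuple[float, float]:
    """Median first-spike latency (ms) and reliability over pulses.

    Latency is the median across pulses of the first spike within the
    10 ms gate after pulse onset; reliability is the fraction of pulses
    with at least one spike in the gate.  With no evoked spikes at all
    the latency is NaN and reliability 0.
    """
    pulses = np.asarray(pulses, dtype=float)
    if pulses.size < 50:
        raise ValueError(f"need >= 50 pulses, got {pulses.size}")
    t = spikes.times
    lat = []
    hits = 0
    for p in pulses:
        j = np.searchsorted(t, p, side="right")
        if j < t.size and t[j] - p <= gate_s:
            lat.append(t[j] - p)
            hits += 1
    reliability = hits / pulses.size
    latency_ms = float(np.median(lat) * 1000) if lat else float("nan")
    return latency_ms, reliability


def categorize(p_response: float, sign: int, latency_ms: float,
               reliability: float, alpha: float = 0.05) -> str:
    """Decision tree over the tagging sub-results.

    significant + excited + latency < 10 ms + reliability > 0.4 ->
    identified; significant + excited failing a gate -> excluded
    (reported separately); significant + inhibited -> inhibited;
    not significant -> unmodulated.
    """
    if p_response >= alpha or sign == 0:
        return "unmodulated"
    if sign < 0:
        return "inhibited"
    if (np.isfinite(latency_ms) and latency_ms < LATENCY_MAX_MS
            and reliability > RELIABILITY_MIN):
        return "identified"
    return "excluded"


def tag_unit(spikes: SpikeTrain, pulses: np.ndarray, trains: np.ndarray,
             n_perm: int = 500, seed: int | None = None,
             alpha: float = 0.05) -> TagResult:
    """Full tagging pipeline for one unit."""
    if spikes.n_spikes == 0:
        return TagResult(p_response=1.0, sign=0, latency_ms=float("nan"),
                         reliability=0.0, category="unmodulated",
                         untestable=True)
    baseline = default_baseline_windows(trains, n_windows=len(pulses))
    p = pulse_response_test(spikes, pulses, baseline, n_perm=n_perm,
                            seed=seed)
    sign = modulation_sign(spikes, trains, alpha=alpha)
    latency_ms, reliability = latency_reliability(spikes, pulses)
    cat = categorize(p, sign, latency_ms, reliability, alpha=alpha)
    return TagResult(p_response=p, sign=sign, latency_ms=latency_ms,
                     reliability=reliability, category=cat)
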