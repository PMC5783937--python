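"""Single-unit firing-rate analyses on the hypnogram grid.

Spike trains are binned at 2.5 s (aligned with the state annotation),
smoothed with a causal exponential kernel (time constant 7.5 s) and
optionally z-scored over the whole recording.  On these rate series the
module implements: per-state rate comparisons and the REM-off / REM-on
classification (rank-sum tests, Bonferroni-corrected), transition-
triggered averages, time-normalised episode profiles, the inter-REM
quintile analysis, the pre/post-REM NREM comparison and the REM-
pressure correlation suite.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sstats

from .hypnogram import Hypnogram, SpikeTrain
from .transitions import Episode

TAU_S = 7.5


# ---------------------------------------------------------------------------
# rate series
# ---------------------------------------------------------------------------

@dataclass
class RateSeries:
    """Per-epoch firing rate aligned 1:1 with a hypnogram."""

    values: np.ndarray
    epoch_s: float = 2.5
    tau_s: float = TAU_S
    zscored: bool = False

    @property
    def n_epochs(self) -> int:
        return self.values.size


def _causal_exp_smooth(x: np.ndarray, tau_epochs: float) -> np.ndarray:
    """Causal exponential smoothing that conserves total mass exactly.

    The kernel k_j ∝ exp(-j/tau) has unit mass; near the end of the
    series, where part of a sample's kernel would extend past the
    recording, each source sample's kernel is renormalised to the mass
    that actually fits, so sum(out) == sum(x) to machine precision.
    """
    n = x.size
    K = min(n, int(np.ceil(10 * tau_epochs)) + 1)
    k = np.exp(-np.arange(K) / tau_epochs)
    k /= k.sum()
    csum = np.cumsum(k)
    # mass of the kernel that fits for a source at position j
    fit = csum[np.minimum(n - 1 - np.arange(n), K - 1)]
    out = np.convolve(x / fit, k)[:n]
    return out


def rate_series(spikes: SpikeTrain, hyp: Hypnogram, tau_s: float = TAU_S,
                zscore: bool = False) -> RateSeries:
    """Binned (2.5 s), exponentially smoothed firing rate in Hz.

    The kernel is causal (one-sided) and mass-conserving, so the mean of
    the smoothed series equals the mean of the raw binned rate.  With
    ``zscore=True`` the smoothed series is standardised over the full
    recording (mean 0, SD 1).
    """
    edges = np.arange(hyp.n_epochs + 1) * hyp.epoch_s
    counts, _ = np.histogram(spikes.times, bins=edges)
    raw = counts / hyp.epoch_s
    sm = _causal_exp_smooth(raw.astype(float), tau_s / hyp.epoch_s)
    if zscore:
        sd = sm.std()
        if sd == 0:
            raise ValueError("cannot z-score a constant rate series")
        sm = (sm - sm.mean()) / sd
    return RateSeries(values=sm, epoch_s=hyp.epoch_s, tau_s=tau_s,
                      zscored=zscore)


# ---------------------------------------------------------------------------
# state rates and unit classification
# ---------------------------------------------------------------------------

def state_rates(rs: RateSeries, hyp: Hypnogram) -> dict:
    """Mean rate and raw per-epoch samples for each state present."""
    out = {}
    for s in ("W", "N", "R"):
        samples = rs.values[hyp.labels == s]
        out[s] = {"mean": float(samples.mean()) if samples.size else np.nan,
                  "samples": samples}
    return out


@dataclass
class UnitLabel:
    category: str                  # "REM-off" | "REM-on" | "other"
    p_r_vs_n: float | None = None  # Bonferroni-corrected
    p_r_vs_w: float | None = None
    untestable: bool = False


def classify_unit(rates: dict, alpha: float = 0.05) -> UnitLabel:
    """REM-off / REM-on / other from per-epoch rate distributions.

    Two-sided Wilcoxon rank-sum tests of REM vs NREM and REM vs wake,
    Bonferroni-corrected for the two comparisons.  REM-off: both
    corrected p < alpha with the REM mean lower in both; REM-on is the
    mirror image; anything else is "other".
    """
    r = rates["R"]["samples"]
    n = rates["N"]["samples"]
    w = rates["W"]["samples"]
    if min(r.size, n.size, w.size) < 2:
        return UnitLabel("other", untestable=True)
    p_rn = min(1.0, 2 * sstats.ranksums(r, n).pvalue)
    p_rw = min(1.0, 2 * sstats.ranksums(r, w).pvalue)
    sig = p_rn < alpha and p_rw < alpha
    r_mean = rates["R"]["mean"]
    if sig and r_mean < rates["N"]["mean"] and r_mean < rates["W"]["mean"]:
        cat = "REM-off"
    elif sig and r_mean > rates["N"]["mean"] and r_mean > rates["W"]["mean"]:
        cat = "REM-on"
    else:
        cat = "other"
    return UnitLabel(cat, p_r_vs_n=p_rn, p_r_vs_w=p_rw)


# ---------------------------------------------------------------------------
# transition-triggered averages and episode compression
# ---------------------------------------------------------------------------

def transition_triggered(rs: RateSeries, eps: list[Episode],
                         from_state: str, to_state: str,
                         window_s: float = 60.0
                         ) -> tuple[np.ndarray, np.ndarray, np.ndarray, int]:
    """Mean +/- SEM rate around `from_state` -> `to_state` transitions.

    Traces are aligned at the first epoch of the `to_state` episode;
    samples outside the two flanking episodes are masked out, so only
    time spent in the pre- and post-transition states contributes.
    Returns (times, mean, sem, n_transitions); empty (n=0) when no
    transition qualifies.
    """
    half = int(round(window_s / rs.epoch_s))
    times = (np.arange(-half, half) + 0.5) * rs.epoch_s
    stack = []
    for i in range(len(eps) - 1):
        if eps[i].state != from_state or eps[i + 1].state != to_state:
            continue
        t0 = eps[i + 1].start
        row = np.full(2 * half, np.nan)
        a = max(eps[i].start, t0 - half)
        b = min(eps[i + 1].end, t0 + half)
        row[(a - t0) + half:(b - t0) + half] = rs.values[a:b]
        stack.append(row)
    if not stack:
        return times, np.full(times.size, np.nan), \
            np.full(times.size, np.nan), 0
    arr = np.array(stack)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(arr, axis=0)
        cnt = np.sum(np.isfinite(arr), axis=0)
        sem = np.nanstd(arr, axis=0) / np.sqrt(np.maximum(cnt, 1))
    return times, mean, sem, arr.shape[0]


def compress_episode(rs: RateSeries, start: int, end: int,
                     n_bins: int) -> np.ndarray:
    """Piecewise-mean resampling of epochs [start, end) into `n_bins`
    equal normalised-time bins.

    The series is treated as piecewise constant over epochs; each bin's
    value is the exact average of the series over its sub-interval
    (fractional epochs weighted by coverage), so the profile mean equals
    the interval mean exactly.
    """
    if end <= start:
        raise ValueError("empty interval")
    seg = rs.values[start:end].astype(float)
    L = seg.size
    # integral of the piecewise-constant series from 0 to t (epoch units)
    csum = np.concatenate([[0.0], np.cumsum(seg)])

    def integral(t: float) -> float:
        i = int(np.floor(t))
        if i >= L:
            return csum[L]
        return csum[i] + seg[i] * (t - i)

    edges = np.linspace(0, L, n_bins + 1)
    out = np.empty(n_bins)
    for j in range(n_bins):
        out[j] = (integral(edges[j + 1]) - integral(edges[j])) \
            / (edges[j + 1] - edges[j])
    return out


# ---------------------------------------------------------------------------
# regression / paired-comparison helpers
# ---------------------------------------------------------------------------

@dataclass
class Regression:
    """Least-squares fit y ~ x with the field's standard report."""

    r: float
    t: float
    df: int
    p: float
    slope: float
    intercept: float


def regression(x: np.ndarray, y: np.ndarray) -> Regression:
    """Simple linear regression reporting (R, T, df, P)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need at least 3 paired points")
    res = sstats.linregress(x, y)
    df = x.size - 2
    t = res.slope / res.stderr if res.stderr > 0 else np.inf
    return Regression(r=float(res.rvalue), t=float(t), df=df,
                      p=float(res.pvalue), slope=float(res.slope),
                      intercept=float(res.intercept))


@dataclass
class PairedComparison:
    test: str        # "paired-t" or "signed-rank"
    statistic: float
    p: float
    n: int
    mean_diff: float


def paired_compare(a: np.ndarray, b: np.ndarray,
                   normality_alpha: float = 0.05) -> PairedComparison:
    """Two-sided paired comparison of a vs b.

    Uses the paired t-test when a Shapiro-Wilk check on the differences
    does not reject normality, otherwise the Wilcoxon signed-rank test;
    the choice is recorded in the result.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    d = a - b
    if d.size < 3:
        raise ValueError("need at least 3 pairs")
    if np.allclose(d, d[0]):
        normal = True
    else:
        normal = sstats.shapiro(d).pvalue >= normality_alpha
    if normal:
        res = sstats.ttest_rel(a, b)
        return PairedComparison("paired-t", float(res.statistic),
                                float(res.pvalue), d.size, float(d.mean()))
    res = sstats.wilcoxon(a, b)
    return PairedComparison("signed-rank", float(res.statistic),
                            float(res.pvalue), d.size, float(d.mean()))


# ---------------------------------------------------------------------------
# inter-REM analyses
# ---------------------------------------------------------------------------

def inter_rem_intervals(eps: list[Episode]) -> list[tuple[int, int]]:
    """Epoch spans (offset of one REM episode, onset of the next),
    wake included."""
    rem = [e for e in eps if e.state == "R"]
    return [(rem[i].end, rem[i + 1].start) for i in range(len(rem) - 1)
            if rem[i + 1].start > rem[i].end]


@dataclass
class InterRemResult:
    nrem_quintile_means: np.ndarray      # (5,) across intervals
    wake_quintile_means: np.ndarray
    nrem_regression: Regression | None
    wake_regression: Regression | None
    first_last_nrem: PairedComparison | None
    first_last_wake: PairedComparison | None
    n_intervals: int
    skipped: int = 0


def inter_rem_analysis(rs: RateSeries, hyp: Hypnogram, eps: list[Episode],
                       n_bins: int = 5) -> InterRemResult:
    """Quintile analysis of firing within inter-REM intervals.

    Each interval (REM offset -> next REM onset) is divided into
    ``n_bins`` equal bins; epochs are assigned to bins individually, and
    NREM / wake rates are averaged within each bin.  Rates are regressed
    on bin index (R, T, df, P); the first and last NREM (and wake)
    episodes of each interval are compared pairwise.
    """
    spans = inter_rem_intervals(eps)
    nrem_binned, wake_binned = [], []
    first_last_n, first_last_w = [], []
    skipped = 0
    for a, b in spans:
        labels = hyp.labels[a:b]
        if not (labels == "N").any():
            skipped += 1
            continue
        idx = np.arange(b - a)
        bins = np.minimum((idx * n_bins) // (b - a), n_bins - 1)
        vals = rs.values[a:b]
        nrow = np.full(n_bins, np.nan)
        wrow = np.full(n_bins, np.nan)
        for j in range(n_bins):
            nm = (bins == j) & (labels == "N")
            wm = (bins == j) & (labels == "W")
            if nm.any():
                nrow[j] = vals[nm].mean()
            if wm.any():
                wrow[j] = vals[wm].mean()
        nrem_binned.append(nrow)
        wake_binned.append(wrow)
        # first / last episode means within the interval
        sub_eps = [e for e in eps if e.start >= a and e.end <= b]
        for state, store in (("N", first_last_n), ("W", first_last_w)):
            se = [e for e in sub_eps if e.state == state]
            if len(se) >= 2:
                store.append((rs.values[se[0].start:se[0].end].mean(),
                              rs.values[se[-1].start:se[-1].end].mean()))

    def _agg(binned):
        if not binned:
            return np.full(n_bins, np.nan), None
        arr = np.array(binned)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            means = np.nanmean(arr, axis=0)
        xs, ys = [], []
        for row in arr:
            for j, v in enumerate(row):
                if np.isfinite(v):
                    xs.append(j + 1)
                    ys.append(v)
        reg = regression(np.array(xs), np.array(ys)) if len(xs) >= 3 else None
        return means, reg

    n_means, n_reg = _agg(nrem_binned)
    w_means, w_reg = _agg(wake_binned)

    def _fl(pairs):
        if len(pairs) < 3:
            return None
        arr = np.array(pairs)
        return paired_compare(arr[:, 0], arr[:, 1])

    return InterRemResult(nrem_quintile_means=n_means,
                          wake_quintile_means=w_means,
                          nrem_regression=n_reg, wake_regression=w_reg,
                          first_last_nrem=_fl(first_last_n),
                          first_last_wake=_fl(first_last_w),
                          n_intervals=len(nrem_binned), skipped=skipped)


@dataclass
class PrePostResult:
    pre: np.ndarray
    post: np.ndarray
    comparison: PairedComparison | None
    n_sequences: int


def _flanking_nrem_pairs(eps: list[Episode], middle: str) -> list[tuple]:
    """(pre-NREM, post-NREM) episode pairs flanking a `middle`-state
    passage; for middle='R' intervening wake after the REM is allowed,
    for middle='W' the passage must be wake only (the REM-free control)."""
    pairs = []
    i = 0
    while i < len(eps):
        if eps[i].state != "N":
            i += 1
            continue
        j = i + 1
        seen_mid = False
        ok = True
        while j < len(eps) and eps[j].state != "N":
            if eps[j].state == middle:
                seen_mid = True
            elif middle == "W" and eps[j].state == "R":
                ok = False
            elif middle == "R" and eps[j].state == "W" and not seen_mid:
                ok = False  # wake before the REM episode: not N->R->...
            j += 1
        if j < len(eps) and seen_mid and ok:
            pairs.append((eps[i], eps[j]))
        i = j if j > i else i + 1
    return pairs


def pre_post_rem(rs: RateSeries, eps: list[Episode],
                 middle: str = "R") -> PrePostResult:
    """Paired NR_pre vs NR_post comparison across qualifying sequences.

    With ``middle='R'`` sequences are NREM -> REM (-> wake) -> NREM;
    with ``middle='W'`` the REM-free NREM -> wake -> NREM control.  The
    unit's mean rate in the flanking NREM episodes is compared with a
    paired two-sided test.
    """
    pairs = _flanking_nrem_pairs(eps, middle)
    pre = np.array([rs.values[a.start:a.end].mean() for a, _ in pairs])
    post = np.array([rs.values[b.start:b.end].mean() for _, b in pairs])
    comp = paired_compare(pre, post) if len(pairs) >= 3 else None
    return PrePostResult(pre=pre, post=post, comparison=comp,
                         n_sequences=len(pairs))


@dataclass
class HomeostasisResult:
    dur_vs_interval: Regression
    dur_vs_rate: Regression | None
    rate_vs_interval: Regression | None
    split_interval: "object"            # rank-sum result, short vs long
    split_rate: "object | None"
    n_episodes: int


def homeostasis_correlations(eps: list[Episode],
                             rs: RateSeries | None = None,
                             split_s: float = 90.0) -> HomeostasisResult:
    """REM-pressure correlation suite.

    For every REM episode with a defined subsequent inter-REM interval:
    (i) REM duration vs interval duration; with a rate series also
    (ii) REM duration vs mean rate over the interval and (iii) interval
    mean rate vs interval duration — each reported as (R, T, df, P).
    Interval distributions (and post-REM rates) after short (<= 90 s)
    and long (> 90 s) REM episodes are compared with two-sided rank-sum
    tests.
    """
    rem = [e for e in eps if e.state == "R"]
    rows = []
    for i in range(len(rem) - 1):
        a, b = rem[i].end, rem[i + 1].start
        if b <= a:
            continue
        dur = rem[i].duration_s
        interval = (b - a) * rem[i].epoch_s
        rate = rs.values[a:b].mean() if rs is not None else np.nan
        rows.append((dur, interval, rate))
    if len(rows) < 3:
        raise ValueError("need at least 3 REM episodes with subsequent "
                         "intervals")
    arr = np.array(rows)
    dur, interval, rate = arr[:, 0], arr[:, 1], arr[:, 2]
    reg_i = regression(dur, interval)
    reg_ii = regression(dur, rate) if rs is not None else None
    reg_iii = regression(rate, interval) if rs is not None else None
    short = dur <= split_s
    if short.any() and (~short).any():
        split_interval = sstats.ranksums(interval[short], interval[~short])
        split_rate = (sstats.ranksums(rate[short], rate[~short])
                      if rs is not None else None)
    else:
        split_interval = None
        split_rate = None
    return HomeostasisResult(dur_vs_interval=reg_i, dur_vs_rate=reg_ii,
                             rate_vs_interval=reg_iii,
                             split_interval=split_interval,
                             split_rate=split_rate, n_episodes=len(rows))


# ---------------------------------------------------------------------------
# printed count fractions
# ---------------------------------------------------------------------------

def proportion(k: int, n: int, ci_level: float = 0.95,
               digits: int | None = None) -> tuple[float, tuple[float, float]]:
    """Percentage k/n with an exact (Clopper-Pearson) binomial CI.

    Returns (percentage, (lo, hi)); with ``digits`` the percentage is
    rounded to that many decimals (0 = nearest integer).
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if not 0 <= k <= n:
        raise ValueError("k must lie in [0, n]")
    pct = 100.0 * k / n
    ci = sstats.binomtest(k, n).proportion_ci(confidence_level=ci_level,
                                              method="exact")
    if digits is not None:
        pct = round(pct, digits)
        if digits == 0:
            pct = float(int(pct))
    return pct, (100 * ci.low, 100 * ci.high)
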