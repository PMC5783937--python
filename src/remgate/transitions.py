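"""Laser-aligned brain-state statistics and the trial-resampling bootstrap.

Trials are hypnogram windows aligned to laser onset (time 0).  Time is
discretised into 20 s bins (8 epochs); the transition probability from
state X to Y at bin i is P_i(Y|X) = m/n where n counts trials in X at
bin i-1 and m the subset of those in Y at bin i.  Baseline probabilities
average all bins outside the laser period and the 2 min that follow it.

Confidence intervals and p-values come from a per-mouse trial-resampling
bootstrap: each iteration redraws, for every mouse, that mouse's number
of trials with replacement, and recomputes the statistic across mice.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sstats

from .hypnogram import Hypnogram, LaserSchedule, laser_overlap_mask

STATES = ("W", "N", "R")
STATE_IDX = {s: i for i, s in enumerate(STATES)}

EPOCHS_PER_BIN = 8          # 20 s bins on the 2.5 s grid
BIN_S = 20.0


@dataclass
class Episode:
    """A maximal run of one state; epochs [start, end)."""

    state: str
    start: int
    end: int
    epoch_s: float = 2.5
    laser_overlap: bool = False

    @property
    def duration_s(self) -> float:
        return (self.end - self.start) * self.epoch_s

    @property
    def start_s(self) -> float:
        return self.start * self.epoch_s

    @property
    def end_s(self) -> float:
        return self.end * self.epoch_s


def episodes(hyp: Hypnogram,
             laser: LaserSchedule | None = None) -> list[Episode]:
    """Maximal same-state runs, in order, tiling the hypnogram exactly.

    ``laser_overlap`` is true iff the episode interval intersects any
    laser trial (taken from `laser` if given, else from the hypnogram's
    own laser mask).
    """
    labels = hyp.labels
    change = np.flatnonzero(labels[1:] != labels[:-1]) + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [labels.size]])
    out = [Episode(str(labels[a]), int(a), int(b), hyp.epoch_s)
           for a, b in zip(starts, ends)]
    if laser is not None:
        ov = laser_overlap_mask(np.array([e.start_s for e in out]),
                                np.array([e.end_s for e in out]), laser)
        for e, o in zip(out, ov):
            e.laser_overlap = bool(o)
    elif hyp.laser is not None:
        for e in out:
            e.laser_overlap = bool(hyp.laser[e.start:e.end].any())
    return out


# ---------------------------------------------------------------------------
# trial alignment and the transition table
# ---------------------------------------------------------------------------

def extract_trials(hyp: Hypnogram, schedule: LaserSchedule,
                   pre_s: float = 240.0, post_s: float = 240.0
                   ) -> np.ndarray:
    """Laser-aligned label windows, one row per trial.

    Each row spans [-pre_s, laser_dur + post_s) around a laser onset;
    trials whose window exits the recording are dropped.  Returns an
    (n_trials, n_epochs_window) array of state labels.
    """
    eps = hyp.epoch_s
    pre = int(round(pre_s / eps))
    post = int(round(post_s / eps))
    rows = []
    for onset, dur in zip(schedule.onsets_s, schedule.durations_s):
        i0 = int(round(onset / eps))
        a, b = i0 - pre, i0 + int(round(dur / eps)) + post
        if a >= 0 and b <= hyp.n_epochs:
            rows.append(hyp.labels[a:b])
    return np.array(rows) if rows else np.empty((0, pre + post), dtype="<U1")


def bin_labels(trial: np.ndarray, epochs_per_bin: int = EPOCHS_PER_BIN
               ) -> np.ndarray:
    """Collapse an epoch-label row to 20 s bins by majority vote.

    Ties are broken in favour of the state whose last occurrence within
    the bin is later (the state the animal is heading into).
    """
    n_bins = trial.size // epochs_per_bin
    out = np.empty(n_bins, dtype="<U1")
    for i in range(n_bins):
        chunk = trial[i * epochs_per_bin:(i + 1) * epochs_per_bin]
        best, best_count, best_last = "", -1, -1
        for s in STATES:
            hits = np.flatnonzero(chunk == s)
            if hits.size > best_count or (hits.size == best_count
                                          and hits.size
                                          and hits[-1] > best_last):
                if hits.size:
                    best, best_count, best_last = s, hits.size, hits[-1]
        out[i] = best
    return out


@dataclass
class TransitionTable:
    """Per-bin conditional transition probabilities with counts.

    ``n[i, x]`` counts trials in state x throughout bin i-1;
    ``m[i, x, y]`` the subset of those in state y at bin i;
    ``prob = m / n`` (NaN where n = 0).  ``bin_times`` gives each bin's
    start relative to laser onset at time 0.
    """

    m: np.ndarray            # (n_bins, 3, 3)
    n: np.ndarray            # (n_bins, 3)
    bin_times: np.ndarray    # (n_bins,) seconds
    bin_s: float = BIN_S

    @property
    def prob(self) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(self.n[:, :, None] > 0,
                            self.m / self.n[:, :, None], np.nan)

    def pair(self, x: str, y: str) -> np.ndarray:
        """P_i(Y|X) over bins for one ordered state pair."""
        return self.prob[:, STATE_IDX[x], STATE_IDX[y]]

    def averaged(self, k: int = 3) -> tuple[np.ndarray, np.ndarray]:
        """Display aggregation: probabilities averaged over k consecutive
        bins (NaN-aware).  Returns (times, (n_groups, 3, 3) array)."""
        p = self.prob
        n_groups = p.shape[0] // k
        times = self.bin_times[: n_groups * k : k]
        out = np.full((n_groups, 3, 3), np.nan)
        for g in range(n_groups):
            with np.errstate(invalid="ignore"):
                out[g] = np.nanmean(p[g * k:(g + 1) * k], axis=0)
        return times, out


def transition_probability(trials: np.ndarray, onset_epoch: int,
                           epochs_per_bin: int = EPOCHS_PER_BIN
                           ) -> TransitionTable:
    """Build the transition table from laser-aligned trials.

    ``onset_epoch`` is the index of the first laser-on epoch within each
    trial row; bins are laid out so that a bin boundary falls exactly at
    laser onset (time 0).
    """
    trials = np.asarray(trials)
    if trials.ndim != 2:
        raise ValueError("trials must be a 2-D array of labels")
    if trials.size and len({trials.shape[1]}) != 1:
        raise ValueError("trials must share one window extent")
    if onset_epoch % epochs_per_bin:
        # keep laser onset on a bin edge by trimming leading epochs
        cut = onset_epoch % epochs_per_bin
        trials = trials[:, cut:]
        onset_epoch -= cut
    n_bins = trials.shape[1] // epochs_per_bin
    binned = np.array([bin_labels(t, epochs_per_bin) for t in trials])
    m = np.zeros((n_bins, 3, 3), dtype=int)
    n = np.zeros((n_bins, 3), dtype=int)
    for i in range(1, n_bins):
        for x_i, x in enumerate(STATES):
            in_x = binned[:, i - 1] == x
            n[i, x_i] = in_x.sum()
            for y_i, y in enumerate(STATES):
                m[i, x_i, y_i] = (in_x & (binned[:, i] == y)).sum()
    onset_bin = onset_epoch // epochs_per_bin
    bin_times = (np.arange(n_bins) - onset_bin) * BIN_S
    return TransitionTable(m=m, n=n, bin_times=bin_times)


def baseline_probability(table: TransitionTable, laser_dur_s: float,
                         post_exclusion_s: float = 120.0) -> np.ndarray:
    """Mean per-pair probability over bins outside the laser period and
    the 2 min that follow it (per-trial, trial-aligned coordinates).

    Bin 0 of the table has no predecessor and never contributes.
    Returns a (3, 3) array; raises if every bin is excluded.
    """
    t = table.bin_times
    excluded = (t >= 0) & (t < laser_dur_s + post_exclusion_s)
    keep = ~excluded
    keep[0] = False
    if not keep.any():
        raise ValueError("all bins fall inside the exclusion zone")
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return np.nanmean(table.prob[keep], axis=0)


def cumulative_transition(eps: list[Episode], from_state: str, to_state: str,
                          horizon_s: float = 120.0,
                          laser_overlap: bool | None = None,
                          epoch_s: float = 2.5
                          ) -> tuple[np.ndarray, np.ndarray, int]:
    """Fraction of `from_state` episodes that have ended in `to_state`
    within t seconds of episode initiation, for t in (0, horizon_s].

    Episodes are optionally conditioned on laser overlap.  The final
    episode of a recording has no successor and is skipped.  Returns
    (times, curve, n_episodes); the curve is monotone non-decreasing.
    """
    t_grid = np.arange(epoch_s, horizon_s + epoch_s / 2, epoch_s)
    qual = []
    for i, e in enumerate(eps[:-1]):
        if e.state != from_state:
            continue
        if laser_overlap is not None and e.laser_overlap != laser_overlap:
            continue
        qual.append((e.duration_s, eps[i + 1].state))
    if not qual:
        return t_grid, np.full(t_grid.size, np.nan), 0
    durs = np.array([d for d, _ in qual])
    nxt = np.array([s for _, s in qual])
    curve = np.array([np.mean((durs <= t) & (nxt == to_state))
                      for t in t_grid])
    return t_grid, curve, len(qual)


# ---------------------------------------------------------------------------
# per-mouse trial-resampling bootstrap
# ---------------------------------------------------------------------------

@dataclass
class BootstrapResult:
    estimate: float
    ci_low: float
    ci_high: float
    p_value: float
    n_iter: int
    trials_per_mouse: dict = field(default_factory=dict)
    n_redrawn: int = 0
    samples: np.ndarray | None = None


def bootstrap(statistic, data_by_mouse: dict, n_iter: int = 10000,
              seed: int | None = None, ci_level: float = 0.95,
              difference=None) -> BootstrapResult:
    """Per-mouse trial-resampling bootstrap.

    ``data_by_mouse`` maps mouse id -> sequence of per-trial data.  Each
    iteration draws, for every mouse, that mouse's own number of trials
    with replacement, and evaluates ``statistic(resampled_dict)`` (a
    scalar).  The CI is the percentile interval of the resampled
    statistics.  If ``difference`` is given (a second callable producing
    the laser-minus-baseline difference on a resample), the two-sided
    p-value is computed from the difference distribution as
    ``2 * min(Pr(d <= 0), Pr(d >= 0))``, floored at ``1/n_iter``;
    otherwise the statistic's own distribution is used.

    A resample on which the statistic is undefined (raises or returns
    NaN) is redrawn; the redraw count is reported.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    rng = np.random.default_rng(seed)
    mice = list(data_by_mouse)
    trials = {m: list(data_by_mouse[m]) for m in mice}
    counts = {m: len(trials[m]) for m in mice}
    if any(c == 0 for c in counts.values()):
        raise ValueError("every mouse needs at least one trial")

    est = float(statistic(data_by_mouse))
    stat_samples = np.empty(n_iter)
    diff_samples = np.empty(n_iter) if difference is not None else None
    redrawn = 0
    for it in range(n_iter):
        for _attempt in range(100):
            res = {m: [trials[m][j] for j in
                       rng.integers(0, counts[m], counts[m])]
                   for m in mice}
            try:
                v = float(statistic(res))
            except (ValueError, ZeroDivisionError, FloatingPointError):
                v = np.nan
            if np.isfinite(v):
                break
            redrawn += 1
        else:
            raise RuntimeError("statistic undefined on 100 consecutive "
                               "resamples")
        stat_samples[it] = v
        if diff_samples is not None:
            diff_samples[it] = float(difference(res))

    alpha = 1.0 - ci_level
    lo, hi = np.percentile(stat_samples, [100 * alpha / 2,
                                          100 * (1 - alpha / 2)])
    d = diff_samples if diff_samples is not None else stat_samples
    p = 2.0 * min(np.mean(d <= 0), np.mean(d >= 0))
    p = min(1.0, max(p, 1.0 / n_iter))
    return BootstrapResult(estimate=est, ci_low=float(lo), ci_high=float(hi),
                           p_value=float(p), n_iter=n_iter,
                           trials_per_mouse=counts, n_redrawn=redrawn,
                           samples=stat_samples)


# ---------------------------------------------------------------------------
# state percentages and episode-overlap statistics
# ---------------------------------------------------------------------------

def state_fraction_by_bin(trials: np.ndarray, state: str,
                          epochs_per_bin: int = EPOCHS_PER_BIN) -> np.ndarray:
    """Per-bin fraction of epochs spent in `state`, per trial.

    Returns (n_trials, n_bins); multiplied by 100 these are the
    brain-state percentages plotted around laser onset.
    """
    n_bins = trials.shape[1] // epochs_per_bin
    cut = trials[:, : n_bins * epochs_per_bin]
    r = cut.reshape(trials.shape[0], n_bins, epochs_per_bin)
    return (r == state).mean(axis=2)


def laser_state_percentages(trials_by_mouse: dict, onset_epoch: int,
                            n_iter: int = 1000, seed: int | None = None
                            ) -> dict:
    """Percentage of W/N/R per 20 s bin around laser onset, averaged
    across mice, with per-mouse trial-resampling bootstrap CIs.

    Returns a dict state -> (mean curve, lo curve, hi curve); the three
    mean curves sum to 100 at every bin.
    """
    rng = np.random.default_rng(seed)
    out = {}
    for s in STATES:
        frac = {m: list(state_fraction_by_bin(t, s))
                for m, t in trials_by_mouse.items()}

        def stat(d):
            return 100.0 * np.mean(
                [np.mean(np.array(v), axis=0) for v in d.values()], axis=0)

        mean_curve = stat(frac)
        boots = np.empty((n_iter, mean_curve.size))
        for it in range(n_iter):
            res = {m: [v[j] for j in rng.integers(0, len(v), len(v))]
                   for m, v in frac.items()}
            boots[it] = stat(res)
        lo, hi = np.percentile(boots, [2.5, 97.5], axis=0)
        out[s] = (mean_curve, lo, hi)
    return out


@dataclass
class OverlapStats:
    """Per-mouse episode statistics split by laser overlap."""

    per_mouse: "object"            # tidy DataFrame
    rem_duration_p: float | None
    nrem_duration_p: float | None
    nrem_to_rem_p: float | None
    excluded_mice: list = field(default_factory=list)


def episode_overlap_stats(episodes_by_mouse: dict) -> OverlapStats:
    """Mean REM/NREM episode durations and the percentage of NREM
    episodes followed by REM, split by laser overlap, compared across
    mice with two-sided Wilcoxon signed-rank tests.

    Edge-truncated episodes (first/last of a recording) are excluded
    from duration statistics.  Mice lacking episodes in one overlap
    condition are dropped from the corresponding pairing.
    """
    import pandas as pd

    rows = []
    for mouse, eps in episodes_by_mouse.items():
        interior = eps[1:-1]
        for overlap in (False, True):
            rem_d = [e.duration_s for e in interior
                     if e.state == "R" and e.laser_overlap == overlap]
            nrem_d = [e.duration_s for e in interior
                      if e.state == "N" and e.laser_overlap == overlap]
            n2r = [eps[i + 1].state == "R"
                   for i, e in enumerate(eps[:-1])
                   if e.state == "N" and e.laser_overlap == overlap]
            rows.append({
                "mouse": mouse, "laser_overlap": overlap,
                "rem_dur_mean": np.mean(rem_d) if rem_d else np.nan,
                "nrem_dur_mean": np.mean(nrem_d) if nrem_d else np.nan,
                "pct_nrem_to_rem": 100 * np.mean(n2r) if n2r else np.nan,
                "n_rem": len(rem_d), "n_nrem": len(nrem_d),
            })
    df = pd.DataFrame(rows)

    def paired_p(col):
        wide = df.pivot(index="mouse", columns="laser_overlap",
                        values=col).dropna()
        if len(wide) < 2 or (wide[True] == wide[False]).all():
            return None, list(df["mouse"].unique()[:0])
        stat = sstats.wilcoxon(wide[False], wide[True])
        return float(stat.pvalue), []

    rem_p, _ = paired_p("rem_dur_mean")
    nrem_p, _ = paired_p("nrem_dur_mean")
    n2r_p, _ = paired_p("pct_nrem_to_rem")
    all_mice = set(df["mouse"])
    have_overlap = set(df.loc[df["laser_overlap"]
                              & df["n_nrem"].gt(0), "mouse"])
    return OverlapStats(per_mouse=df, rem_duration_p=rem_p,
                        nrem_duration_p=nrem_p, nrem_to_rem_p=n2r_p,
                        excluded_mice=sorted(all_mice - have_overlap))
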