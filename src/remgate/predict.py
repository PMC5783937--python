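"""Single-neuron prediction of the upcoming NREM->REM vs NREM->wake
transition.

For every NREM episode ending in REM or wake, the unit's NREM firing
rate in each 10 s bin from 60 s to 0 s before the transition is a
feature.  NREM->wake events are subsampled to match the NREM->REM count
(balanced classes, chance = 0.5).  A Fisher linear discriminant,
w = S_w^{-1} (mu_1 - mu_2) with the decision threshold at the projected
class-mean midpoint, is trained on the pooled pre-transition bins and
evaluated separately at each bin in a 10-fold cross-validation repeated
100 times; the repetition distribution provides the CI and the p-value
against chance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .hypnogram import Hypnogram
from .transitions import Episode
from .units import RateSeries

N_BINS = 6
BIN_EPOCHS = 4          # 10 s bins on the 2.5 s grid


@dataclass
class PredictionDataset:
    """Balanced transition events with pre-transition NREM features.

    ``X[e, b]`` is the mean NREM rate of event e in 10 s bin b, ordered
    from -60 s (b=0) to 0 s (b=5) before the transition; NaN marks bins
    whose epochs fall outside the NREM episode.  ``y`` is True for
    NREM->REM events.
    """

    X: np.ndarray
    y: np.ndarray
    unit_id: str = ""

    @property
    def n_events(self) -> int:
        return self.y.size


def build_dataset(rs: RateSeries, eps: list[Episode],
                  seed: int | None = None,
                  unit_id: str = "") -> PredictionDataset:
    """Collect and balance NREM->REM / NREM->wake transition events.

    All NREM->REM events are kept; an equal number of NREM->wake events
    is drawn without replacement.  Events whose 60 s pre-window exits
    the NREM episode keep only the bins that lie inside it (others are
    NaN); events with no usable bin are dropped before balancing.
    """
    rem_events, wake_events = [], []
    for i in range(len(eps) - 1):
        if eps[i].state != "N":
            continue
        nxt = eps[i + 1].state
        if nxt not in ("R", "W"):
            continue
        t_end = eps[i].end
        row = np.full(N_BINS, np.nan)
        for b in range(N_BINS):
            b0 = t_end - (N_BINS - b) * BIN_EPOCHS
            b1 = b0 + BIN_EPOCHS
            a = max(b0, eps[i].start)
            if b1 > a:
                row[b] = rs.values[a:b1].mean()
        if not np.isfinite(row).any():
            continue
        (rem_events if nxt == "R" else wake_events).append(row)
    if len(rem_events) < 2 or len(wake_events) < 2:
        raise ValueError("need at least 2 transitions of each type")
    rng = np.random.default_rng(seed)
    k = min(len(rem_events), len(wake_events))
    rem_idx = rng.choice(len(rem_events), k, replace=False) \
        if len(rem_events) > k else np.arange(k)
    wake_idx = rng.choice(len(wake_events), k, replace=False) \
        if len(wake_events) > k else np.arange(k)
    X = np.vstack([np.array(rem_events)[rem_idx],
                   np.array(wake_events)[wake_idx]])
    y = np.concatenate([np.ones(k, bool), np.zeros(k, bool)])
    return PredictionDataset(X=X, y=y, unit_id=unit_id)


@dataclass
class Discriminant:
    """Fisher linear discriminant in explicit form."""

    w: np.ndarray
    threshold: float
    mu1: np.ndarray          # class True
    mu0: np.ndarray
    ridge_used: bool = False

    def decision(self, X: np.ndarray) -> np.ndarray:
        return np.atleast_2d(X) @ self.w - self.threshold

    def predict(self, X: np.ndarray) -> np.ndarray:
        """True where the projection falls on the mu1 side."""
        return self.decision(X) > 0


def fit_fisher(X: np.ndarray, y: np.ndarray) -> Discriminant:
    """w = S_w^{-1} (mu_1 - mu_0); threshold at the projected midpoint.

    S_w is the pooled within-class scatter; when singular, a ridge
    eps * trace(S_w)/dim is added (flagged in the result).  In one
    dimension this reduces to the sign of the mean difference with a
    midpoint threshold.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=bool)
    if not y.any() or y.all():
        raise ValueError("both classes must be present")
    X1, X0 = X[y], X[~y]
    mu1, mu0 = X1.mean(axis=0), X0.mean(axis=0)
    d = X.shape[1]
    Sw = ((X1 - mu1).T @ (X1 - mu1)) + ((X0 - mu0).T @ (X0 - mu0))
    ridge = False
    try:
        w = np.linalg.solve(Sw, mu1 - mu0)
        if not np.all(np.isfinite(w)):
            raise np.linalg.LinAlgError
    except np.linalg.LinAlgError:
        eps = 1e-8 * max(np.trace(Sw), 1.0) / d
        w = np.linalg.solve(Sw + eps * np.eye(d), mu1 - mu0)
        ridge = True
    thr = float(w @ (mu1 + mu0) / 2)
    return Discriminant(w=w, threshold=thr, mu1=mu1, mu0=mu0,
                        ridge_used=ridge)


@dataclass
class CrossvalResult:
    accuracy: np.ndarray         # (N_BINS,) mean over repetitions
    ci_low: np.ndarray
    ci_high: np.ndarray
    p_vs_chance: np.ndarray
    rep_accuracy: np.ndarray     # (reps, N_BINS)
    folds: int
    reps: int
    n_resplit: int = 0


def _fold_split(n: int, folds: int, rng: np.random.Generator) -> list:
    idx = rng.permutation(n)
    return [idx[f::folds] for f in range(folds)]


def crossval_accuracy(ds: PredictionDataset, folds: int = 10,
                      reps: int = 100, seed: int | None = None,
                      pooled_bins: bool = True) -> CrossvalResult:
    """Repeated k-fold cross-validated accuracy per pre-transition bin.

    In the default pooled mode every (event, bin) scalar of the training
    events is a training sample for a one-dimensional discriminant,
    which is then evaluated separately at each 10 s bin on the held-out
    events (NaN bins are excluded from that bin's evaluation, never
    imputed).  With ``pooled_bins=False`` a 6-dimensional discriminant
    is trained on complete events instead.

    Accuracy, percentile CI and the two-sided p-value against chance
    (0.5) come from the distribution over ``reps`` repetitions.
    """
    if ds.n_events < folds:
        raise ValueError("need at least `folds` events")
    rng = np.random.default_rng(seed)
    rep_acc = np.full((reps, N_BINS), np.nan)
    n_resplit = 0
    for rep in range(reps):
        for _attempt in range(100):
            fold_idx = _fold_split(ds.n_events, folds, rng)
            ok = all(len(set(ds.y[np.concatenate(
                [fold_idx[g] for g in range(folds) if g != f])])) == 2
                for f in range(folds))
            if ok:
                break
            n_resplit += 1
        else:
            raise RuntimeError("could not build folds containing both "
                               "classes")
        correct = np.zeros(N_BINS)
        total = np.zeros(N_BINS)
        for f in range(folds):
            test = fold_idx[f]
            train = np.concatenate([fold_idx[g] for g in range(folds)
                                    if g != f])
            Xtr, ytr = ds.X[train], ds.y[train]
            if pooled_bins:
                flat = Xtr.ravel()
                lab = np.repeat(ytr, N_BINS)
                fin = np.isfinite(flat)
                disc = fit_fisher(flat[fin, None], lab[fin])
            else:
                full = np.isfinite(Xtr).all(axis=1)
                disc = fit_fisher(Xtr[full], ytr[full])
            for b in range(N_BINS):
                vals = ds.X[test, b]
                fin = np.isfinite(vals)
                if not fin.any():
                    continue
                if pooled_bins:
                    pred = disc.predict(vals[fin, None]).ravel()
                else:
                    Xt = ds.X[test][fin]
                    good = np.isfinite(Xt).all(axis=1)
                    if not good.any():
                        continue
                    pred = disc.predict(Xt[good]).ravel()
                    fin = np.flatnonzero(fin)[good]
                    correct[b] += (pred == ds.y[test][fin]).sum()
                    total[b] += pred.size
                    continue
                correct[b] += (pred == ds.y[test][fin]).sum()
                total[b] += pred.size
        with np.errstate(invalid="ignore"):
            rep_acc[rep] = np.where(total > 0, correct / total, np.nan)
    mean = np.nanmean(rep_acc, axis=0)
    lo, hi = np.nanpercentile(rep_acc, [2.5, 97.5], axis=0)
    p = np.empty(N_BINS)
    for b in range(N_BINS):
        col = rep_acc[:, b]
        col = col[np.isfinite(col)]
        if col.size == 0:
            p[b] = np.nan
            continue
        p[b] = 2.0 * min(np.mean(col <= 0.5), np.mean(col >= 0.5))
        p[b] = min(1.0, max(p[b], 1.0 / reps))
    return CrossvalResult(accuracy=mean, ci_low=lo, ci_high=hi,
                          p_vs_chance=p, rep_accuracy=rep_acc,
                          folds=folds, reps=reps, n_resplit=n_resplit)
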