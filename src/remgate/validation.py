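"""Simulation-based calibration experiments.

These experiments measure the statistical properties the pipeline
promises — above all the empirical coverage of the per-mouse
trial-resampling bootstrap CI — on synthetic data whose ground truth is
known exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .transitions import STATES, bootstrap


def fixed_hazard_matrix(params) -> np.ndarray:
    """Per-epoch transition matrix of the pressure-decoupled (fixed
    hazard) Markov generator, rows/cols ordered W, N, R."""
    w2n, n2w = params.h_w2n, params.h_n2w
    n2r = params.h_n2r_fixed
    r2w, r2n = params.h_r2w, params.h_r2n
    return np.array([
        [1 - w2n, w2n, 0.0],
        [n2w, 1 - n2w - n2r, n2r],
        [r2w, r2n, 1 - r2w - r2n],
    ])


def stationary_distribution(P: np.ndarray) -> np.ndarray:
    """Stationary distribution of a row-stochastic matrix."""
    vals, vecs = np.linalg.eig(P.T)
    k = int(np.argmin(np.abs(vals - 1.0)))
    pi = np.real(vecs[:, k])
    pi = np.abs(pi)
    return pi / pi.sum()


def simulate_markov_trials(P: np.ndarray, n_trials: int, n_epochs: int,
                           rng: np.random.Generator) -> np.ndarray:
    """(n_trials, n_epochs) state-index array; initial states drawn from
    the stationary distribution (the chain is in steady state)."""
    pi = stationary_distribution(P)
    cum = np.cumsum(P, axis=1)
    states = np.empty((n_trials, n_epochs), dtype=int)
    states[:, 0] = rng.choice(3, size=n_trials, p=pi)
    u = rng.random((n_trials, n_epochs - 1))
    for t in range(1, n_epochs):
        c = cum[states[:, t - 1]]
        states[:, t] = (u[:, t - 1, None] >= c).sum(axis=1)
    return states


@dataclass
class CoverageResult:
    coverage_pct: float
    true_pct: float
    n_datasets: int
    n_mice: int
    n_trials: int
    n_epochs: int
    n_iter: int


def nrem_ci_coverage(params, n_datasets: int = 200, n_mice: int = 8,
                     n_trials: int = 20, n_epochs: int = 48,
                     n_iter: int = 1000, seed: int = 1) -> CoverageResult:
    """Empirical coverage of the 95% trial-resampling bootstrap CI.

    Datasets of ``n_mice`` x ``n_trials`` laser-aligned trial windows
    (``n_epochs`` epochs each) are drawn from the fixed-hazard Markov
    generator; for each dataset the percentile bootstrap CI of the mean
    NREM percentage (resampling trials within mouse) is computed and
    scored against the generator's true stationary NREM percentage.
    """
    P = fixed_hazard_matrix(params)
    true_pct = 100.0 * stationary_distribution(P)[STATES.index("N")]
    ss = np.random.SeedSequence(seed)
    covered = 0
    for child in ss.spawn(n_datasets):
        rng = np.random.default_rng(child)
        data = {}
        for m in range(n_mice):
            st = simulate_markov_trials(P, n_trials, n_epochs, rng)
            # per-trial NREM percentage within the window
            data[f"m{m}"] = list(100.0 * (st == 1).mean(axis=1))

        def stat(d):
            return float(np.mean([np.mean(v) for v in d.values()]))

        boot_seed = int(rng.integers(0, 2**31 - 1))
        res = bootstrap(stat, data, n_iter=n_iter, seed=boot_seed)
        if res.ci_low <= true_pct <= res.ci_high:
            covered += 1
    return CoverageResult(coverage_pct=100.0 * covered / n_datasets,
                          true_pct=float(true_pct), n_datasets=n_datasets,
                          n_mice=n_mice, n_trials=n_trials,
                          n_epochs=n_epochs, n_iter=n_iter)
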