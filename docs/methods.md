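# Methods

This note documents the models and numerical choices behind `remgate`:
what the synthetic generator emulates, how each analysis stage is
defined, and where the design was genuinely open.

## The hypnogram model

Brain states W (wake), N (NREM) and R (REM) evolve on the 2.5 s epoch
grid — the native resolution of the scoring and of every downstream
analysis — as a semi-Markov chain with per-epoch exit hazards:

| transition | default hazard / epoch |
|---|---|
| W→N | 0.05 |
| N→W | 0.012 |
| N→R | pressure-dependent, ≤ 0.08 |
| R→W | 0.03 |
| R→N | 0.002 |

A latent REM pressure `p` accumulates at `a = 0.007` units/s during
NREM, dissipates at `b = 0.14` units/s during REM (floored at 0), and
is frozen during wake, so the trajectory is piecewise linear and
assertable against ground truth. The NREM→REM hazard is a logistic in
`p` (midpoint 6, scale 0.8) shifted and rescaled so that `h(0) = 0`
exactly and `h(∞) =` 0.08/epoch. The anchoring keeps the trivial limit
honest — zero pressure means zero REM entry — while the steep midpoint
gives the post-REM refractory period the homeostatic literature
describes. These constants were fixed once so that 24 h simulations
reproduce the light-phase regime the analyses assume: REM episodes of
roughly 60–90 s recurring every 10–15 min (about 12 min on average over
seeds), REM occupying ~8–11% of time. Setting `pressure_coupled=False`
replaces the coupled hazard with a constant (`h_n2r_fixed = 0.01`),
yielding an exactly Markov generator used for calibration experiments.

Because dissipation is proportional to REM duration and pressure is
rarely driven all the way to zero, longer REM episodes leave less
residual pressure and are followed by longer inter-REM intervals — the
duration–interval coupling is positive by construction whenever
`b > 0`, and vanishes when `b = 0`.

## EEG/EMG synthesis and scoring

The synthetic EEG mixes a delta-band (1–4 Hz), theta-band (6–12 Hz) and
broadband component with per-state amplitudes (NREM delta-dominated,
REM theta-dominated, wake broadband); the EMG is 20–300 Hz noise with
per-state amplitude and erratic per-epoch bursts during wake. Gains
are crossfaded over 0.5 s so signals are continuous at epoch
boundaries and 5 s scoring windows see no edge artifacts. A
state-independent noise floor sets the SNR; scoring accuracy is
monotone in it. The generator does **not** attempt biophysical
realism: no 1/f background, no spindles or theta phase structure, no
movement artifacts. Passing recovery tests therefore shows the scoring
logic is correct, not that it would reach the same accuracy on real
recordings.

Scoring follows the threshold rules exactly: spectra from 5 s Hann
windows stepped by 2.5 s (the final epochs reuse the last complete
window so the feature series aligns 1:1 with the epoch grid); band
powers summed over half-open ranges `[lo, hi)`, which makes band
additivity exact; NREM iff delta above the delta threshold with EMG
below mean+1 SD; REM iff delta below threshold, theta/delta above
mean+1 SD and EMG low; wake otherwise. Epochs with zero delta power
have an undefined ratio and fail the REM criterion. The delta
threshold is Otsu's intra-class-variance-minimising split computed on
log delta power — the within-state distributions are approximately
log-normal, and the log-domain split is scale-equivariant; whether the
original procedure used log or linear power is unstated, so this
choice is flagged. EMG and ratio statistics are computed over the full
session (the only scope the rules state). A degenerate (unimodal)
delta distribution raises a warning flag and returns the
variance-minimising split anyway. Manual curation is reduced to an
edit API (`Hypnogram.set_labels`); no GUI.

The closed-loop detector classifies epochs strictly causally against
pre-computed thresholds (in practice calibrated on an initial segment
of the session, e.g. the first 20 min) and gates the laser at each
fresh REM onset with probability 0.5, holding it until the first
non-REM epoch.

## Laser protocols and transition statistics

Open-loop trials are 300 s pulse trains (20 Hz) with inter-trial
intervals uniform on 15–25 min; closed-loop stimulation gates each
detected REM onset at 50%. Both protocols act on the chain only
through hazard multipliers (defaults: NREM→REM ×0.1, NREM→W ×0.5,
R→W ×2, W→N ×2 — the directions of the optogenetic effect; magnitudes
are free defaults, since no quantitative generative effect sizes are
available, and are documented, not fitted). With all multipliers at 1
the laser-on process is identical in distribution to baseline, which
is the null the bootstrap calibration uses.

Trials are aligned with laser onset at time 0 and discretised into
20 s bins (8 epochs). A bin's state is the majority label of its
epochs, ties broken toward the state whose last occurrence is later;
the rules are silent on sub-bin mixtures, and majority is the least
surprising reduction. `P_i(Y|X) = m/n` with `n` the trials in X at bin
i−1 and `m` those in Y at bin i; bins with `n = 0` are undefined
(NaN), and a 3-consecutive-bin average is provided for display.
Baselines average all defined bins outside the laser period and the
2 min after it, in trial-aligned coordinates. Episodes truncated by
the recording edges are excluded from duration statistics (censoring).

The bootstrap resamples, per iteration, each mouse's own trial count
with replacement (M = 10,000 by default, reducible; percentile CI).
Two-sided p-values are `2·min(Pr(d≤0), Pr(d≥0))` on the
laser-minus-baseline difference distribution, floored at 1/M.
Resamples on which a statistic is undefined are redrawn and counted.
Simulation calibration (the acceptance experiment) puts the empirical
coverage of the 95% CI at ~95% over 200 ground-truth datasets.

## Unit analyses

Spike trains are binned at 2.5 s and smoothed with a causal
exponential kernel, τ = 7.5 s. The kernel is normalised per source
sample to the mass that fits before the end of the recording, so
smoothing conserves the total spike count exactly (the mean-rate
identity holds to 1e-9). Sidedness of the kernel is unstated in the
procedure this follows; causal is chosen for online interpretability
and flagged. Z-scoring, when requested, is applied after smoothing
over the full recording.

REM-off/REM-on classification uses two-sided Wilcoxon rank-sum tests
of per-epoch rates, R vs N and R vs W, Bonferroni-corrected ×2 (only
those two comparisons define the labels); REM-off requires both
corrected p < 0.05 with the REM mean lowest, REM-on the mirror.
Transition-triggered averages align at the transition epoch and mask
samples outside the two flanking episodes; the window extent is
configurable (default 60 s each way — the original extent is not
stated numerically). Episode compression integrates the
piecewise-constant rate over n equal normalised-time bins, so the
profile mean equals the interval mean exactly.

The inter-REM interval runs from a REM offset to the next REM onset,
wake included. Quintile analysis assigns epochs to five equal bins
individually, averages NREM (or wake) rates per bin and interval, and
regresses rate on bin index; regressions report (R, T, df, P) from
ordinary least squares. Paired comparisons (first-vs-last episode,
NR_pre vs NR_post) use the paired t-test when a Shapiro–Wilk check on
the differences does not reject normality, otherwise the signed-rank
test, with the choice recorded. The NREM→wake→NREM control uses the
identical machinery with REM excluded from the passage. Note a
generator-specific caveat: because the drift acts during every NREM
episode, the REM-free control shows a drift-driven *decrease* (post <
pre) even though only the REM reset produces the *increase* the
homeostasis analyses look for; with drift and reset off, both tests
are calibrated at the α level (verified over 100 seeded sessions).

The simulated unit's slow gain starts at 1, loses 0.05 per minute of
NREM (floored at 0.2), freezes during wake and REM, and jumps at each
REM offset by 0.005 × REM duration (s), capped at 1. Defaults were
chosen so the gain is roughly stationary over the ~12 min inter-REM
cycle.

## Tagging

The pulse-response test is a permutation test on the Jensen–Shannon
divergence between first-spike-latency histograms (ten 3 ms bins plus
a no-spike bucket) of evoked 30 ms windows and equally many
spontaneous windows tiled before each train; labels are shuffled over
the pooled windows and the p-value is `(k+1)/(n_perm+1)`. This is a
contract-equivalent stand-in for the SALT family of latency tests,
whose exact internals are external to the procedure reimplemented
here; its type-I rate is calibrated on null Poisson units. Modulation
sign pairs per-train rates during the 30 Hz trains against the
preceding 0.5 s (two-sided signed-rank). Latency is the median across
pulses of the first spike within a 10 ms gate — median rather than
mean, which is robust to the occasional coincident spontaneous spike —
and reliability is the fraction of pulses with a spike in that same
gate (the gate doubles as the reliability window; only the thresholds
are stated). Categories: significant+excited passing both gates →
identified; failing a gate → excluded (reported separately);
significant+inhibited → inhibited; otherwise unmodulated.

## Transition prediction

For every NREM episode ending in REM or wake, features are the unit's
mean NREM rate in each 10 s bin from −60 s to 0 s; bins whose epochs
leave the episode are missing and are excluded from that bin's
evaluation, never imputed. All NREM→REM events are kept and NREM→wake
events subsampled without replacement to match, so chance is exactly
0.5. The discriminant is computed explicitly
(`w = S_w⁻¹(μ₁−μ₂)`, threshold at the projected class-mean midpoint;
ridge `1e-8·tr(S_w)/d` only if `S_w` is singular, flagged). The
default reading trains a single one-dimensional discriminant on the
pooled (event, bin) scalars and evaluates it per bin — the
interpretation most consistent with predicting from a single neuron's
momentary rate; the 6-dimensional per-event alternative is available
via `pooled_bins=False`. Accuracy, CIs and p-values against chance
come from 10-fold cross-validation repeated 100 times with fresh
random splits (folds lacking a class in training are redrawn).
Chance-level behaviour under label shuffling is asserted *averaged
over shuffles*: any single shuffle of a finite event set retains
residual label–feature overlap and can sit a few points off 0.5.

## Calcium preprocessing

Motion correction high-passes each frame (frame minus a Gaussian
low-pass, σ = 10 px in downsampled coordinates — the spatial scale is
otherwise unspecified), picks the highest-variance block of the mean
high-pass projection as reference, and finds the integer shift (±8 px
default) maximising the correlation of the reference region with each
frame. The template is rebuilt from corrected frames and registration
repeated to a fixed point (a handful of passes): the first-pass
template is motion-blurred and can bias isolated frames by one pixel.
Shifts are integer-only by design; subpixel refinement is out of
scope. ROI traces average the rasterised polygon's pixels per frame.
The neuropil ring sits at the stated 20 μm offset from the ROI
perimeter (converted to pixels via the session's pixel size; the
synthetic movies use 5 px), is 4 px wide — the ring's width is not
specified, only its distance — and excludes all ROI polygons.
`cf = (F_bv − F_off)/(F_near − F_off)` from the vessel, near-vessel
and off-lens region means, with the population default 0.55 when no
vessel region exists (provenance recorded). ΔF/F uses a straight-line
baseline fitted to the frames at or below the session's 20th
percentile of the *corrected* trace (corrected vs raw is unstated;
corrected chosen), erroring if the fitted baseline is non-positive
anywhere. The synthetic movie shares a single neuropil field whose
weight is 1 on-lens, `cf` inside ROIs and the vessel, and 0 off-lens —
the simplest structure under which the cf formula identifies the
contamination factor.

## Problem sizes and reproducibility

Default test and analysis sizes are chosen for a desk-scale run: 2 h
sessions for single-unit checks, 24 h for homeostasis statistics,
100-seed batches for power/false-positive calibration, 200 datasets ×
1000 bootstrap iterations for CI coverage, and movies of 64×64 px at
10 Hz for a few minutes. All randomness flows through seeded
`numpy.random.Generator` instances; identical seeds give bit-identical
outputs, and the pipeline runner stamps every report with the manifest
hash and seed.

## Known limitations

* The generator's laser effect magnitudes, EEG mixing amplitudes and
  unit gain dynamics are plausible defaults, not fitted to data;
  analyses validated on them demonstrate correctness of the
  statistical machinery, not field performance.
* Epoch-level simulation cannot produce sub-epoch latencies (e.g. the
  closed-loop detector's latency floor is one epoch).
* Band-power additivity and other "exact" identities hold to float
  summation order (asserted at 1e-12 relative tolerance).
* Spike sorting, cross-day unit matching, behavioural video scoring
  and anatomical analyses are out of scope.
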