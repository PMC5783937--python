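"""Generator-level checks: hazard arithmetic, pressure dynamics,
protocol mechanics and reproducibility."""

import itertools

import numpy as np
import pytest

from remgate import staging, synthgen, transitions as tr
from remgate.params import GeneratorParams


def rem_spans(labels):
    spans, pos = [], 0
    for s, grp in itertools.groupby(labels):
        n = len(list(grp))
        if s == "R":
            spans.append((pos, pos + n))
        pos += n
    return spans


class TestHypnogram:
    def test_no_pressure_no_rem(self):
        p = GeneratorParams(rem_pressure_gain=0.0, initial_pressure=0.0)
        hyp, _ = synthgen.simulate_hypnogram(p, 4 * 3600, seed=1)
        assert not (hyp.labels == "R").any()

    def test_mean_inter_rem_interval_10_to_15_min(self):
        hyp, _ = synthgen.simulate_hypnogram(GeneratorParams(), 24 * 3600,
                                             seed=11)
        spans = rem_spans(hyp.labels)
        iv = [(spans[i + 1][0] - spans[i][1]) * 2.5 / 60
              for i in range(len(spans) - 1)]
        assert 10.0 <= np.mean(iv) <= 15.0

    def test_fixed_hazard_empirical_matrix(self):
        """With pressure coupling off the chain is Markov; empirical
        one-step transition counts must match the specified matrix
        (brute-force counting oracle, 3 binomial SEs)."""
        p = GeneratorParams(pressure_coupled=False)
        hyp, _ = synthgen.simulate_hypnogram(p, 1e5 * 2.5, seed=3)
        from remgate.validation import fixed_hazard_matrix

        P = fixed_hazard_matrix(p)
        lab = hyp.labels
        states = "WNR"
        for i, x in enumerate(states):
            src = lab[:-1] == x
            n = src.sum()
            for j, y in enumerate(states):
                m = (src & (lab[1:] == y)).sum()
                se = np.sqrt(P[i, j] * (1 - P[i, j]) / n)
                assert abs(m / n - P[i, j]) <= 3 * se + 1e-12, (x, y)

    def test_pressure_piecewise_linear(self, session_2h, params):
        """Pressure slope is +a in NREM, -b (floored at 0) in REM and 0
        in wake, epoch by epoch."""
        hyp, pressure = session_2h["hyp"], session_2h["truth"].pressure
        dt = hyp.epoch_s
        d = np.diff(pressure)
        lab = hyp.labels[:-1]
        assert np.allclose(d[lab == "N"], params.rem_pressure_gain * dt)
        assert np.allclose(d[lab == "W"], 0.0)
        exp_r = np.maximum(0.0, pressure[:-1][lab == "R"]
                           - params.rem_dissipation * dt) \
            - pressure[:-1][lab == "R"]
        assert np.allclose(d[lab == "R"], exp_r)

    def test_pressure_non_negative(self, session_24h):
        assert (session_24h["truth"].pressure >= 0).all()

    def test_seed_reproducibility(self, params):
        a, ta = synthgen.simulate_hypnogram(params, 1800, seed=9)
        b, tb = synthgen.simulate_hypnogram(params, 1800, seed=9)
        assert np.array_equal(a.labels, b.labels)
        assert np.array_equal(ta.pressure, tb.pressure)
        e1, m1 = synthgen.synthesize_eeg_emg(a, 250.0, params, seed=4)
        e2, m2 = synthgen.synthesize_eeg_emg(b, 250.0, params, seed=4)
        assert np.array_equal(e1, e2) and np.array_equal(m1, m2)

    def test_nonfinite_param_rejected(self):
        with pytest.raises(ValueError, match="h_n2w"):
            GeneratorParams(h_n2w=float("nan"))
        with pytest.raises(ValueError, match="hazard"):
            GeneratorParams(h_w2n=1.5)

    def test_duration_too_short(self, params):
        with pytest.raises(ValueError):
            synthgen.simulate_hypnogram(params, 10, seed=0)


class TestEEG:
    def test_zero_amplitudes_zero_signals(self, params):
        import dataclasses

        zero_mix = {s: {k: 0.0 for k in "delta theta broad".split()}
                    for s in "WNR"}
        p = dataclasses.replace(params, eeg_mix=zero_mix,
                                emg_amp={s: 0.0 for s in "WNR"},
                                eeg_noise_amp=0.0, emg_noise_amp=0.0)
        hyp, _ = synthgen.simulate_hypnogram(p, 300, seed=1)
        eeg, emg = synthgen.synthesize_eeg_emg(hyp, 200.0, p, seed=1)
        assert np.allclose(eeg, 0) and np.allclose(emg, 0)

    def test_state_band_power_design(self, scored_session):
        """NREM carries more delta than REM; wake more EMG power than
        either sleep state (computed through staging.band_power)."""
        hyp = scored_session["hyp"]
        fs = scored_session["fs"]
        es = staging.spectrogram(scored_session["eeg"], fs)
        ms = staging.spectrogram(scored_session["emg"], fs)
        delta = staging.band_power(es, 1, 4)
        emgp = staging.band_power(ms, 20, min(300, fs / 2))
        lab = hyp.labels
        assert delta[lab == "N"].mean() > delta[lab == "R"].mean()
        assert emgp[lab == "W"].mean() > emgp[lab == "N"].mean()
        assert emgp[lab == "W"].mean() > emgp[lab == "R"].mean()

    def test_low_fs_rejected(self, params):
        hyp, _ = synthgen.simulate_hypnogram(params, 300, seed=1)
        with pytest.raises(ValueError):
            synthgen.synthesize_eeg_emg(hyp, 50.0, params, seed=1)


class TestUnit:
    def test_zero_rates_empty_train(self, params):
        import dataclasses

        p = dataclasses.replace(params,
                                unit_rates={s: 0.0 for s in "WNR"})
        hyp, _ = synthgen.simulate_hypnogram(p, 1800, seed=1)
        spk = synthgen.simulate_unit(hyp, p, seed=2)
        assert spk.n_spikes == 0

    def test_stationary_state_rates(self):
        """With drift and reset off, per-state empirical rates match the
        configured base rates within 3 Poisson SEs (counting oracle)."""
        p = GeneratorParams(unit_drift_per_min=0.0, unit_reset_per_s=0.0)
        hyp, _ = synthgen.simulate_hypnogram(p, 6 * 3600, seed=21)
        spk = synthgen.simulate_unit(hyp, p, seed=22)
        for s, rate in p.unit_rates.items():
            mask = hyp.labels == s
            T = mask.sum() * hyp.epoch_s
            t = spk.times
            count = 0
            for i in np.flatnonzero(mask):
                t0 = i * hyp.epoch_s
                count += np.sum((t >= t0) & (t < t0 + hyp.epoch_s))
            se = np.sqrt(rate / T) if rate > 0 else 0.1
            assert abs(count / T - rate) <= 3 * se + 1e-9, s

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            GeneratorParams(unit_rates={"W": 8.0, "N": -1.0, "R": 1.0})

    def test_gain_dynamics(self, params):
        """The slow gain decays only during NREM, freezes in wake, and
        jumps at REM offsets in proportion to the episode duration."""
        from tests.conftest import make_hypnogram

        hyp = make_hypnogram([("W", 10), ("N", 48), ("R", 24), ("W", 10)])
        g = synthgen.unit_gain_trajectory(hyp, params)
        dt = hyp.epoch_s
        assert np.allclose(g[:10], 1.0)                      # frozen in W
        drop = params.unit_drift_per_min * dt / 60.0
        assert np.allclose(np.diff(g[10:58]), -drop)         # NREM decay
        assert np.allclose(np.diff(g[58:82]), 0.0)           # flat in R
        jump = min(1.0, g[81] + params.unit_reset_per_s * 24 * dt)
        assert g[82] == pytest.approx(jump)                  # reset at offset


class TestLaserProtocols:
    def test_short_session_at_most_one_trial(self, params):
        sched, hyp, _ = synthgen.simulate_open_loop(params, 600, seed=1)
        assert sched.n_trials <= 1

    def test_open_loop_schedule_shape(self, params):
        sched, hyp, _ = synthgen.simulate_open_loop(params, 3 * 3600, seed=2)
        assert np.all(sched.durations_s == params.laser_dur_s)
        gaps = np.diff(sched.onsets_s) - params.laser_dur_s
        assert np.all(gaps >= params.iti_min_s - 1e-9)
        assert np.all(gaps <= params.iti_max_s + 1e-9)
        assert hyp.laser is not None and hyp.laser.sum() > 0

    def test_suppressive_laser_reduces_n_to_r(self, params):
        """Default multipliers suppress the NREM->REM transition during
        the laser relative to baseline."""
        probs_laser, probs_base = [], []
        for seed in (31, 32, 33):
            sched, hyp, _ = synthgen.simulate_open_loop(params, 6 * 3600,
                                                        seed=seed)
            trials = tr.extract_trials(hyp, sched)
            if not trials.size:
                continue
            table = tr.transition_probability(trials, onset_epoch=96)
            base = tr.baseline_probability(table, params.laser_dur_s)
            in_laser = (table.bin_times >= 0) & \
                (table.bin_times < params.laser_dur_s)
            probs_laser.append(np.nanmean(table.pair("N", "R")[in_laser]))
            probs_base.append(base[1, 2])
        assert np.nanmean(probs_laser) < np.nanmean(probs_base)

    def test_closed_loop_gate_zero_empty(self, params):
        import dataclasses

        p = dataclasses.replace(params, closed_gate_p=0.0)
        sched, _, _ = synthgen.simulate_closed_loop(p, 2 * 3600, seed=1)
        assert sched.n_trials == 0

    def test_closed_loop_gating_fraction_half(self, params):
        """Across many REM episodes the stimulated fraction is 0.5
        within 3 binomial SEs."""
        n_stim = n_rem = 0
        for seed in (41, 42):
            sched, hyp, _ = synthgen.simulate_closed_loop(params, 24 * 3600,
                                                          seed=seed)
            spans = rem_spans(hyp.labels)
            n_rem += len(spans)
            n_stim += sched.n_trials
        assert n_rem >= 200
        se = np.sqrt(0.25 / n_rem)
        assert abs(n_stim / n_rem - 0.5) <= 3 * se

    def test_closed_loop_shortens_rem(self, params):
        """R->W multiplier > 1 makes laser-on REM episodes shorter."""
        on, off = [], []
        for seed in (43, 44):
            sched, hyp, _ = synthgen.simulate_closed_loop(params, 12 * 3600,
                                                          seed=seed)
            eps = tr.episodes(hyp, sched)
            on += [e.duration_s for e in eps[1:-1]
                   if e.state == "R" and e.laser_overlap]
            off += [e.duration_s for e in eps[1:-1]
                    if e.state == "R" and not e.laser_overlap]
        assert np.mean(on) < np.mean(off)

    def test_closed_loop_requires_shortening_multiplier(self, params):
        import dataclasses

        p = dataclasses.replace(params, laser_mult={"RW": 0.5})
        with pytest.raises(ValueError):
            synthgen.simulate_closed_loop(p, 3600, seed=1)


class TestNullLaser:
    def test_null_multipliers_leave_transitions_unchanged(self, params):
        """With all multipliers at 1, laser-bin transition probabilities
        differ from baseline only by sampling error (|z| < 3)."""
        import dataclasses

        p = dataclasses.replace(params,
                                laser_mult={k: 1.0 for k in
                                            ("NR", "NW", "RW", "WN")})
        tables = []
        for seed in (51, 52, 53, 54):
            sched, hyp, _ = synthgen.simulate_open_loop(p, 6 * 3600,
                                                        seed=seed)
            trials = tr.extract_trials(hyp, sched)
            if trials.size:
                tables.append(tr.transition_probability(trials,
                                                        onset_epoch=96))
        m = np.sum([t.m for t in tables], axis=0)
        n = np.sum([t.n for t in tables], axis=0)
        bt = tables[0].bin_times
        in_laser = (bt >= 0) & (bt < p.laser_dur_s)
        for xi in range(3):
            n_las = n[in_laser, xi].sum()
            n_base = n[~in_laser][1:, xi].sum()
            if min(n_las, n_base) < 30:
                continue
            for yi in range(3):
                p_las = m[in_laser, xi, yi].sum() / n_las
                p_base = m[~in_laser][1:, xi, yi].sum() / n_base
                pool = (m[in_laser, xi, yi].sum()
                        + m[~in_laser][1:, xi, yi].sum()) / (n_las + n_base)
                if pool in (0.0, 1.0):
                    continue
                se = np.sqrt(pool * (1 - pool) * (1 / n_las + 1 / n_base))
                assert abs(p_las - p_base) / se < 3.5, (xi, yi)
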