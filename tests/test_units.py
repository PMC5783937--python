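"""Firing-rate analyses: kernel mass conservation, state comparisons,
episode compression, and the inter-REM homeostasis suite."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from remgate import transitions as tr, units
from remgate.hypnogram import Hypnogram, SpikeTrain
from remgate.units import (RateSeries, classify_unit, compress_episode,
                           homeostasis_correlations, inter_rem_analysis,
                           pre_post_rem, proportion, rate_series, regression,
                           state_rates, transition_triggered)
from tests.conftest import make_hypnogram


def const_hyp(n, state="N"):
    return Hypnogram(np.full(n, state, dtype="<U1"))


class TestRateSeries:
    def test_empty_train_zero_series(self):
        hyp = const_hyp(100)
        rs = rate_series(SpikeTrain(np.array([]), t_end=250.0), hyp)
        assert np.allclose(rs.values, 0.0)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_smoothing_conserves_mean(self, seed):
        """The causal kernel has unit mass, so smoothing preserves the
        mean rate exactly (random trains)."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(20, 400))
        hyp = const_hyp(n)
        t = np.sort(rng.uniform(0, n * 2.5, rng.integers(0, 800)))
        rs = rate_series(SpikeTrain(t, t_end=n * 2.5), hyp)
        raw = np.histogram(t, bins=np.arange(n + 1) * 2.5)[0] / 2.5
        assert rs.values.mean() == pytest.approx(raw.mean(), abs=1e-9)

    def test_homogeneous_poisson_mean(self):
        """A 5 Hz Poisson unit over 2 h averages 5 Hz within 3 SEs."""
        rng = np.random.default_rng(30)
        T = 7200.0
        t = np.sort(rng.uniform(0, T, rng.poisson(5.0 * T)))
        hyp = const_hyp(int(T / 2.5))
        rs = rate_series(SpikeTrain(t, t_end=T), hyp)
        se = np.sqrt(5.0 / T)
        assert abs(rs.values.mean() - 5.0) <= 3 * se

    def test_zscore_identity(self, session_2h):
        rs = session_2h["rs"]
        assert rs.values.mean() == pytest.approx(0.0, abs=1e-9)
        assert rs.values.std() == pytest.approx(1.0, abs=1e-9)

    def test_unsorted_spikes_sorted_with_warning(self):
        hyp = const_hyp(40)
        with pytest.warns(UserWarning, match="unsorted"):
            spk = SpikeTrain(np.array([5.0, 1.0, 3.0]), t_end=100.0)
        assert np.all(np.diff(spk.times) >= 0)


class TestStateRates:
    def test_constant_series_equal_means(self):
        hyp = make_hypnogram([("W", 10), ("N", 10), ("R", 10)])
        rs = RateSeries(np.full(30, 2.0))
        sr = state_rates(rs, hyp)
        assert sr["W"]["mean"] == sr["N"]["mean"] == sr["R"]["mean"] == 2.0

    def test_matches_masking_oracle(self, session_2h):
        """State means equal an independent boolean-mask average."""
        rs, hyp = session_2h["rs"], session_2h["hyp"]
        sr = state_rates(rs, hyp)
        for s in "WNR":
            oracle = rs.values[np.array([c == s for c in hyp.labels])]
            assert sr[s]["mean"] == oracle.mean()

    def test_rem_off_unit_profile(self, session_2h):
        sr = state_rates(session_2h["rs"], session_2h["hyp"])
        assert sr["R"]["mean"] < sr["N"]["mean"]
        assert sr["R"]["mean"] < sr["W"]["mean"]


class TestClassifyUnit:
    def _rates(self, r, n, w):
        return {"R": {"mean": float(np.mean(r)), "samples": np.asarray(r)},
                "N": {"mean": float(np.mean(n)), "samples": np.asarray(n)},
                "W": {"mean": float(np.mean(w)), "samples": np.asarray(w)}}

    def test_identical_distributions_other(self):
        rng = np.random.default_rng(31)
        x = rng.normal(0, 1, 300)
        lab = classify_unit(self._rates(x, x.copy(), x.copy()))
        assert lab.category == "other"

    def test_generator_rem_off_detected(self, session_2h):
        lab = classify_unit(state_rates(session_2h["rs"],
                                        session_2h["hyp"]))
        assert lab.category == "REM-off"
        assert lab.p_r_vs_n < 0.05 and lab.p_r_vs_w < 0.05

    def test_swapping_r_and_n_flips_label(self, session_2h):
        sr = state_rates(session_2h["rs"], session_2h["hyp"])
        r, n, w = sr["R"]["samples"], sr["N"]["samples"], sr["W"]["samples"]
        # make the "wake" reference sit between the swapped R and N
        mid = np.concatenate([r, n])
        flipped = classify_unit(self._rates(np.concatenate([n, w]), r, mid))
        assert flipped.category == "REM-on"

    def test_missing_state_untestable(self):
        lab = classify_unit(self._rates([1.0], [1, 2, 3], [1, 2, 3]))
        assert lab.category == "other" and lab.untestable


class TestTransitionTriggered:
    def test_constant_series_flat(self):
        hyp = make_hypnogram([("N", 30), ("R", 30)])
        rs = RateSeries(np.full(60, 1.5))
        t, mean, sem, n = transition_triggered(rs, tr.episodes(hyp),
                                               "N", "R", window_s=30)
        assert n == 1
        assert np.allclose(mean[np.isfinite(mean)], 1.5)

    def test_step_recovered_at_lag_zero(self):
        hyp = make_hypnogram([("N", 40), ("R", 40)])
        vals = np.concatenate([np.ones(40), np.zeros(40)])
        rs = RateSeries(vals)
        t, mean, _, _ = transition_triggered(rs, tr.episodes(hyp),
                                             "N", "R", window_s=25)
        assert np.allclose(mean[t < 0], 1.0)
        assert np.allclose(mean[t > 0], 0.0)

    def test_matches_stack_and_mean_oracle(self, session_2h):
        rs, eps = session_2h["rs"], session_2h["eps"]
        t, mean, _, n = transition_triggered(rs, eps, "N", "R",
                                             window_s=60)
        if n == 0:
            pytest.skip("no N->R transitions in fixture")
        half = 24
        rows = []
        for i in range(len(eps) - 1):
            if eps[i].state == "N" and eps[i + 1].state == "R":
                t0 = eps[i + 1].start
                row = np.full(48, np.nan)
                a = max(eps[i].start, t0 - half)
                b = min(eps[i + 1].end, t0 + half)
                row[a - t0 + half:b - t0 + half] = rs.values[a:b]
                rows.append(row)
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            oracle = np.nanmean(np.array(rows), axis=0)
        assert np.array_equal(mean[np.isfinite(mean)],
                              oracle[np.isfinite(oracle)])


class TestCompressEpisode:
    def test_constant_profile(self):
        rs = RateSeries(np.full(17, 3.0))
        assert np.allclose(compress_episode(rs, 0, 17, 5), 3.0)

    def test_linear_ramp_stays_linear(self):
        n = 100
        rs = RateSeries(np.arange(n, dtype=float))
        prof = compress_episode(rs, 0, n, 10)
        d = np.diff(prof)
        assert np.allclose(d, d[0], atol=1e-9)

    def test_mass_preserved(self):
        rng = np.random.default_rng(32)
        vals = rng.random(37)
        rs = RateSeries(vals)
        prof = compress_episode(rs, 5, 30, 7)
        assert prof.mean() == pytest.approx(vals[5:30].mean(), abs=1e-9)

    def test_idempotent_on_matching_length(self):
        vals = np.full(8, 2.5)
        rs = RateSeries(vals)
        assert np.allclose(compress_episode(rs, 0, 8, 8), vals)

    def test_empty_interval_rejected(self):
        with pytest.raises(ValueError):
            compress_episode(RateSeries(np.ones(10)), 4, 4, 3)


class TestRegression:
    def test_matches_closed_form_oracle(self):
        """(R, T, df, P) agree with the closed-form least-squares
        formulas to 1e-9 on a fixed 10-point table."""
        x = np.array([1, 2, 3, 4, 5, 1, 2, 3, 4, 5], dtype=float)
        y = np.array([2.1, 1.8, 1.1, 0.9, 0.4, 2.3, 1.7, 1.4, 0.8, 0.6])
        reg = regression(x, y)
        n = x.size
        sxx = np.sum((x - x.mean()) ** 2)
        sxy = np.sum((x - x.mean()) * (y - y.mean()))
        syy = np.sum((y - y.mean()) ** 2)
        slope = sxy / sxx
        r = sxy / np.sqrt(sxx * syy)
        df = n - 2
        t_stat = r * np.sqrt(df / (1 - r ** 2))
        from scipy.stats import t as tdist

        p = 2 * tdist.sf(abs(t_stat), df)
        assert reg.slope == pytest.approx(slope, abs=1e-9)
        assert reg.r == pytest.approx(r, abs=1e-9)
        assert reg.t == pytest.approx(t_stat, abs=1e-9)
        assert reg.df == df
        assert reg.p == pytest.approx(p, abs=1e-9)


class TestInterRem:
    def test_sign_recovery_with_drift(self, session_24h):
        """NREM drift on: negative quintile slope with P < 0.05; wake
        trend much weaker."""
        res = inter_rem_analysis(session_24h["rs"], session_24h["hyp"],
                                 session_24h["eps"])
        assert res.nrem_regression.slope < 0
        assert res.nrem_regression.p < 0.05
        assert abs(res.wake_regression.r) < abs(res.nrem_regression.r)

    def test_first_last_nrem_decrease(self, session_24h):
        res = inter_rem_analysis(session_24h["rs"], session_24h["hyp"],
                                 session_24h["eps"])
        assert res.first_last_nrem is not None
        assert res.first_last_nrem.mean_diff > 0  # first > last

    def test_interval_without_nrem_skipped(self):
        hyp = make_hypnogram([("R", 4), ("W", 8), ("R", 4), ("N", 8),
                              ("R", 4)])
        rs = RateSeries(np.ones(hyp.n_epochs))
        res = inter_rem_analysis(rs, hyp, tr.episodes(hyp))
        assert res.skipped == 1
        assert res.n_intervals == 1


class TestPrePostRem:
    def test_toy_sequence_enumeration(self):
        """Hand-enumerated episode list: one NREM->REM->wake->NREM
        sequence and one NREM->wake->NREM control."""
        hyp = make_hypnogram([("N", 4), ("R", 4), ("W", 4), ("N", 4),
                              ("W", 4), ("N", 4), ("R", 4), ("W", 4)])
        vals = np.arange(hyp.n_epochs, dtype=float)
        rs = RateSeries(vals)
        eps = tr.episodes(hyp)
        res_r = pre_post_rem(rs, eps, middle="R")
        assert res_r.n_sequences == 1
        assert res_r.pre[0] == vals[0:4].mean()
        assert res_r.post[0] == vals[12:16].mean()
        res_w = pre_post_rem(rs, eps, middle="W")
        assert res_w.n_sequences == 1
        assert res_w.pre[0] == vals[12:16].mean()
        assert res_w.post[0] == vals[20:24].mean()

    def test_reset_recovery(self, session_24h):
        """With the post-REM reset on, NR_post exceeds NR_pre."""
        res = pre_post_rem(session_24h["rs"], session_24h["eps"])
        assert res.n_sequences >= 10
        assert res.comparison.mean_diff < 0  # pre - post < 0
        assert res.comparison.p < 0.05


class TestHomeostasis:
    def test_positive_correlations_with_dissipation(self, session_24h):
        res = homeostasis_correlations(session_24h["eps"],
                                       session_24h["rs"])
        assert res.dur_vs_interval.r > 0
        assert res.dur_vs_rate.r > 0
        assert res.rate_vs_interval.r > 0

    def test_duration_split_distributions_differ(self, session_24h):
        res = homeostasis_correlations(session_24h["eps"],
                                       session_24h["rs"])
        assert res.split_interval is not None

    def test_too_few_episodes_rejected(self):
        hyp = make_hypnogram([("N", 8), ("R", 4), ("N", 8)])
        with pytest.raises(ValueError):
            homeostasis_correlations(tr.episodes(hyp))


class TestProportion:
    @pytest.mark.parametrize("k,n,expected", [
        (317, 782, 41.0), (11, 19, 58.0), (0, 50, 0.0),
        (33, 96, 34.0), (83, 148, 56.0), (4, 19, 21.0),
    ])
    def test_rounded_percentages(self, k, n, expected):
        pct, (lo, hi) = proportion(k, n, digits=0)
        assert pct == expected
        assert lo <= 100 * k / n <= hi

    def test_zero_n_rejected(self):
        with pytest.raises(ValueError):
            proportion(1, 0)
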