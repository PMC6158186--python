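"""Latency decomposition: envelopes, shared-tau fits, BIC, count statistics."""

import numpy as np
import pandas as pd
import pytest

from simplesyn.latency import (
    bic_compare,
    count_matrix,
    covariance_windows,
    crossover_index,
    cumulative_sync_curves,
    deletion_window_ms,
    fit_biexponential_shared,
    fit_exponential_decay,
    separate_asynchronous,
    variance_mean,
)


class TestSeparation:
    def test_deletion_windows(self):
        assert deletion_window_ms(200.0) == 4.6
        assert deletion_window_ms(100.0) == 5.0
        assert deletion_window_ms(50.0) == pytest.approx(19.6)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            separate_asynchronous(np.array([]), np.array([0.5]), 10, 200.0)

    def test_fast_events_give_zero_envelope(self):
        rng = np.random.default_rng(0)
        aps = 0.5 + 5.0 * np.arange(8)
        times = np.concatenate([ap + rng.exponential(0.4, 100) for ap in aps])
        times = times[times < 45]
        sep = separate_asynchronous(times, aps, 100, 200.0, t_end_ms=60.0)
        # nearly all events are synchronous; the envelope stays tiny
        assert sep.async_rate.max() < 0.05 * sep.total_rate.max()

    def test_flat_poisson_rate_recovered(self):
        """Homogeneous Poisson events: async ~= r, sync ~= 0."""
        rng = np.random.default_rng(1)
        rate, n_trials, t_end = 0.2, 400, 60.0
        n = rng.poisson(rate * n_trials * t_end)
        times = np.sort(rng.uniform(0, t_end, n))
        aps = 0.5 + 5.0 * np.arange(8)
        sep = separate_asynchronous(times, aps, n_trials, 200.0, t_end_ms=t_end)
        mid = (sep.time_ms > 5) & (sep.time_ms < 55)
        assert sep.async_rate[mid].mean() == pytest.approx(rate, rel=0.1)
        assert sep.sync_rate[mid].mean() < 0.05 * rate + 0.02

    def test_count_conservation(self):
        """Sync + async integrate back to the total event count within 2%."""
        rng = np.random.default_rng(2)
        aps = 0.5 + 5.0 * np.arange(8)
        sync = np.concatenate([ap + rng.exponential(0.5, 300) for ap in aps])
        asyn = rng.uniform(0, 80, 1500)
        times = np.concatenate([sync, asyn])
        times = times[times < 80]
        sep = separate_asynchronous(times, aps, 100, 200.0, t_end_ms=80.0)
        bin_ms = sep.time_ms[1] - sep.time_ms[0]
        total = sep.total_rate.sum() * bin_ms * 100
        parts = (sep.sync_rate + sep.async_rate).sum() * bin_ms * 100
        assert parts == pytest.approx(total, rel=0.02)


class TestBiexponentialFit:
    @staticmethod
    def _sample_mixture(rng, n, frac_fast, tau_f, tau_s):
        fast = rng.random(n) < frac_fast
        lat = np.where(fast, rng.exponential(tau_f, n), rng.exponential(tau_s, n))
        return lat

    def test_recovers_known_mixture(self):
        """tau = 0.5/2.0 ms, 70/30 amplitudes, 1e4 events: parameters
        recovered within the 95% CIs."""
        rng = np.random.default_rng(7)
        lat = self._sample_mixture(rng, 10_000, 0.7, 0.5, 2.0)
        fit = fit_biexponential_shared({1: lat[lat < 8.0]}, fit_window_ms=8.0)
        lo, hi = fit.tau_fast_ci
        assert lo - 0.05 <= 0.5 <= hi + 0.05
        lo, hi = fit.tau_slow_ci
        assert lo - 0.2 <= 2.0 <= hi + 0.2
        assert fit.amplitudes["fast_fraction"].iloc[0] == pytest.approx(0.7, abs=0.08)

    def test_shared_taus_across_stimuli(self):
        rng = np.random.default_rng(8)
        data = {
            1: self._sample_mixture(rng, 4000, 0.9, 0.5, 2.0),
            2: self._sample_mixture(rng, 4000, 0.5, 0.5, 2.0),
            3: self._sample_mixture(rng, 4000, 0.2, 0.5, 2.0),
        }
        data = {k: v[v < 8.0] for k, v in data.items()}
        fit = fit_biexponential_shared(data, fit_window_ms=8.0)
        assert fit.tau_fast_ms == pytest.approx(0.5, abs=0.15)
        assert fit.tau_slow_ms == pytest.approx(2.0, abs=0.5)
        fr = fit.amplitudes["slow_fraction"]
        assert fr.loc[1] < fr.loc[2] < fr.loc[3]

    def test_pure_single_exponential_flags_small_slow(self):
        rng = np.random.default_rng(9)
        lat = rng.exponential(0.5, 6000)
        fit = fit_biexponential_shared({1: lat[lat < 6.0]}, fit_window_ms=6.0)
        assert fit.amplitudes["slow_fraction"].iloc[0] < 0.12

    def test_min_events_threshold(self):
        with pytest.raises(ValueError, match="20"):
            fit_biexponential_shared({1: np.array([0.3, 0.5])})

    def test_ci_coverage_over_replicates(self):
        """95% CI for tau_fast covers the truth in >= 90% of replicates."""
        rng = np.random.default_rng(10)
        hits = 0
        n_rep = 40
        for _ in range(n_rep):
            lat = self._sample_mixture(rng, 3000, 0.7, 0.5, 2.0)
            fit = fit_biexponential_shared({1: lat[lat < 8.0]}, fit_window_ms=8.0)
            lo, hi = fit.tau_fast_ci
            if np.isnan(lo) or (lo <= 0.5 <= hi):
                hits += 1
        assert hits / n_rep >= 0.9


class TestExponentialDecay:
    def test_recovers_tau(self):
        t = np.arange(0, 3, 0.01)
        c = 1.0 - np.exp(-t / 0.362)
        assert fit_exponential_decay(t, c, 0.2, 3.0) == pytest.approx(0.362, rel=0.01)

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            fit_exponential_decay(np.array([0.1, 0.2]), np.array([0.0, 0.1]), 0.0)


class TestBIC:
    @staticmethod
    def _cumulative(lat, grid):
        return np.searchsorted(np.sort(lat), grid, side="right") / len(lat)

    def test_mono_data_prefers_mono(self):
        rng = np.random.default_rng(11)
        grid = np.arange(0.05, 6.0, 0.05)
        wins = 0
        for _ in range(20):
            lat = rng.exponential(0.6, 500)
            out = bic_compare(grid, self._cumulative(lat, grid))
            wins += out["winner"] == "mono"
        assert wins >= 19  # >= 95%

    def test_bi_data_prefers_bi(self):
        rng = np.random.default_rng(12)
        grid = np.arange(0.05, 10.0, 0.05)
        n = 2000
        fast = rng.random(n) < 0.5
        lat = np.where(fast, rng.exponential(0.4, n), rng.exponential(3.0, n))
        out = bic_compare(grid, self._cumulative(lat, grid))
        assert out["winner"] == "bi"

    def test_identical_fits_penalty(self):
        """When bi collapses onto mono, mono wins by exactly 2 ln n."""
        t = np.arange(0.05, 5.0, 0.05)
        c = 1 - np.exp(-t / 0.7)
        out = bic_compare(t, c)
        n = len(t)
        assert out["winner"] == "mono"
        assert out["bic_bi"] - out["bic_mono"] <= 2 * np.log(n) + 1e-6

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            bic_compare(np.arange(3), np.arange(3.0))


class TestCrossover:
    def test_definition(self):
        fast = np.array([0.9, 0.6, 0.45, 0.3])
        slow = 1 - fast
        assert crossover_index(fast, slow) == 3

    def test_none_when_fast_dominates(self):
        fast = np.array([0.9, 0.8, 0.7])
        assert crossover_index(fast, 1 - fast) is None

    def test_tie_resolves_to_that_stimulus(self):
        fast = np.array([0.8, 0.5, 0.2])
        assert crossover_index(fast, 1 - fast) == 2

    def test_respects_stimulus_labels(self):
        fast = np.array([0.9, 0.4])
        assert crossover_index(fast, 1 - fast, stimuli=[3, 5]) == 5


class TestCounts:
    @staticmethod
    def _poisson_events(rng, lam, n_trials, window):
        rows = []
        for tr in range(n_trials):
            n = rng.poisson(lam)
            for t in rng.uniform(window[0], window[1], n):
                rows.append((tr, t))
        df = pd.DataFrame(rows, columns=["trial", "time_ms"])
        return df

    def test_count_matrix_windows(self):
        events = pd.DataFrame(
            {"trial": [0, 0, 1, 1, 1], "time_ms": [1.0, 6.0, 2.0, 41.0, 70.0]}
        )
        ap = np.array([0.5, 5.5])
        cm = count_matrix(events, ap, n_trials=2)
        assert list(cm["s1"]) == [1, 1]
        assert list(cm["s2"]) == [1, 0]
        # 41.0 and 70.0 both fall in (35, 65] ms after the last AP at 5.5
        assert list(cm["post_35_65"]) == [0, 2]
        assert cm.columns.tolist() == ["s1", "s2", "post_0_5", "post_5_35", "post_35_65"]

    def test_independent_poisson_covariance_near_zero(self):
        rng = np.random.default_rng(13)
        a = self._poisson_events(rng, 2.0, 3000, (0.5, 5.5))
        b = self._poisson_events(rng, 1.0, 3000, (40.5, 70.5))
        events = pd.concat([a, b])
        cm = count_matrix(events, np.array([0.5, 35.5]), n_trials=3000)
        out = covariance_windows(cm, "s1", "post_5_35")
        assert abs(out["covariance"]) < 3 * out["se"]

    def test_covariance_needs_two_trials(self):
        cm = pd.DataFrame({"a": [1.0], "b": [2.0]})
        with pytest.raises(ValueError):
            covariance_windows(cm, "a", "b")

    def test_variance_mean_binomial(self):
        """Binomial(4, 0.3) counts: mean 1.2, variance 0.84."""
        rng = np.random.default_rng(14)
        counts = pd.DataFrame({"s1": rng.binomial(4, 0.3, 20000)})
        vm = variance_mean(counts)
        row = vm[vm.window == "s1"].iloc[0]
        assert row["mean"] == pytest.approx(1.2, abs=0.03)
        assert row["variance"] == pytest.approx(0.84, abs=0.03)

    def test_variance_mean_deterministic_and_poisson(self):
        rng = np.random.default_rng(15)
        counts = pd.DataFrame(
            {"s1": np.full(5000, 3.0), "s2": rng.poisson(2.0, 5000)}
        )
        vm = variance_mean(counts).set_index("window")
        assert vm.loc["s1", "variance"] == 0.0
        assert vm.loc["s2", "variance"] == pytest.approx(
            vm.loc["s2", "mean"], rel=0.06
        )


def test_cumulative_sync_curves_event_level():
    """Event-level curves equal the raw cumulative minus the envelope."""
    aps = np.array([0.5])
    times = np.array([0.7, 0.9, 1.5, 3.0, 4.0])
    sep = separate_asynchronous(times, aps, 1, 200.0, t_end_ms=10.0)
    grid, curves = cumulative_sync_curves(
        sep, aps, 4.6, event_times_ms=times, n_trials=1
    )
    assert 1 in curves
    assert curves[1][-1] <= 5.0
    assert (np.diff(curves[1]) >= 0).all()
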