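"""Spiking statistics: rates, kernel smoothing, LvR, correlations, spectra."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mam import spike_stats as ss
from mam.simulator import SpikeData
from mam.spike_stats import RateSeries


def _spikes(trains: dict, duration: float, sizes=None, recorded=None) -> SpikeData:
    sizes = sizes or {k: max(len(set(v[0])), 1) for k, v in trains.items()}
    recorded = recorded or sizes
    return SpikeData(
        trains={k: (np.asarray(i, dtype=np.int64), np.asarray(t, float)) for k, (i, t) in trains.items()},
        sizes=sizes,
        recorded=recorded,
        duration=duration,
        h=0.1,
        seed=0,
    )


class TestRateHistogram:
    def test_periodic_train_mean_rate(self):
        t = np.arange(5.0, 10_000.0, 10.0)
        sd = _spikes({"A-23E": (np.zeros(t.size), t)}, 10_000.0)
        series = ss.rate_histogram(sd, "A-23E")
        assert series.values.mean() == pytest.approx(100.0, rel=1e-6)

    def test_empty_scope_gives_zero_series(self):
        sd = _spikes({"A-23E": ([], [])}, 1000.0)
        series = ss.rate_histogram(sd, "A-23E")
        assert series.values.shape == (1000,)
        assert np.all(series.values == 0)

    def test_time_average_equals_total_count(self, multiarea_run):
        """Direct count oracle: mean of the series equals spikes / (N T)."""
        label = multiarea_run.populations[3]
        series = ss.rate_histogram(multiarea_run, label)
        n_spk = multiarea_run.trains[label][1].size
        n = multiarea_run.recorded[label]
        expect = n_spk / n / (multiarea_run.duration / 1000.0)
        assert series.values.mean() == pytest.approx(expect, rel=1e-12)

    def test_area_scope_aggregates_populations(self, multiarea_run, multiarea_spec):
        area = multiarea_spec.grid.areas[0]
        series = ss.rate_histogram(multiarea_run, area)
        labels = [l for l in multiarea_run.populations if l.startswith(area + "-")]
        total = sum(multiarea_run.trains[l][1].size for l in labels)
        n = sum(multiarea_run.recorded[l] for l in labels)
        assert series.values.mean() == pytest.approx(total / n / 10.0, rel=1e-12)


class TestOptimalKernel:
    def test_mass_conserved_for_burst(self):
        x = np.zeros(4000)
        x[2000] = 1000.0
        out = ss.optimal_kernel_rate(RateSeries(x, "burst"))
        assert out.values.sum() == pytest.approx(x.sum(), rel=1e-3)

    def test_manual_bandwidth_matches_naive_convolution(self):
        rng = np.random.default_rng(0)
        x = rng.poisson(5.0, 3000).astype(float)
        out = ss.optimal_kernel_rate(RateSeries(x, "x"), bandwidth=4.0)
        support = np.arange(-20, 21, dtype=float)
        kern = np.exp(-0.5 * (support / 4.0) ** 2)
        kern /= kern.sum()
        naive = np.zeros_like(x)
        for k, w in zip(support.astype(int), kern):
            lo, hi = max(0, -k), min(x.size, x.size - k)
            naive[lo + k : hi + k] += w * x[lo:hi]
        interior = slice(30, -30)
        assert np.allclose(out.values[interior], naive[interior], atol=1e-10)

    def test_bandwidth_grows_at_lower_rate(self):
        """Fewer spikes force a wider MISE-optimal kernel."""
        rng = np.random.default_rng(1)
        dense = rng.poisson(50.0 / 1000.0 * 20, 60_000).astype(float)
        sparse = rng.poisson(1.0 / 1000.0 * 20, 60_000).astype(float)
        bw_dense = ss.optimal_kernel_rate(RateSeries(dense, "d")).kernel_sd
        bw_sparse = ss.optimal_kernel_rate(RateSeries(sparse, "s")).kernel_sd
        assert bw_sparse > bw_dense

    def test_all_zero_series_unchanged(self):
        out = ss.optimal_kernel_rate(RateSeries(np.zeros(100), "z"))
        assert np.all(out.values == 0)


class TestLvR:
    def test_periodic_train_is_zero(self):
        assert ss.lvr(np.arange(0.0, 1000.0, 10.0), 0.0) == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_value(self):
        # ISIs (10, 10, 30) at R = 0: 3/2 * [0 + (1 - 4*10*30/40^2)] = 0.375
        assert ss.lvr(np.array([0.0, 10.0, 20.0, 50.0]), 0.0) == pytest.approx(0.375)

    def test_poisson_expectation_is_one(self):
        rng = np.random.default_rng(2)
        vals = np.array(
            [ss.lvr(np.cumsum(rng.exponential(100.0, 100)), 0.0) for _ in range(2000)]
        )
        se = vals.std(ddof=1) / np.sqrt(vals.size)
        assert abs(vals.mean() - 1.0) < 3 * se

    def test_undefined_below_three_spikes(self):
        assert np.isnan(ss.lvr(np.array([1.0, 2.0]), 0.0))

    @given(st.floats(0.1, 50.0), st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_scale_invariance_at_zero_refractoriness(self, scale, seed):
        rng = np.random.default_rng(seed)
        t = np.cumsum(rng.exponential(10.0, 50))
        a, b = ss.lvr(t, 0.0), ss.lvr(t * scale, 0.0)
        assert a == pytest.approx(b, rel=1e-12)


class TestPairwiseCorrelation:
    def test_identical_trains_give_one(self):
        t = np.sort(np.random.default_rng(0).uniform(0, 5000.0, 300))
        sd = _spikes(
            {"A-23E": (np.concatenate([np.zeros(300), np.ones(300)]), np.concatenate([t, t]))},
            5000.0,
            sizes={"A-23E": 2},
        )
        assert ss.pairwise_correlation(sd, "A-23E") == pytest.approx(1.0)

    def test_antiphase_pair_is_negative(self):
        t0 = np.arange(0.0, 5000.0, 2.0)
        t1 = t0 + 1.0
        sd = _spikes(
            {"A-23E": (np.concatenate([np.zeros(t0.size), np.ones(t1.size)]),
                       np.concatenate([t0, t1]))},
            5000.0,
            sizes={"A-23E": 2},
        )
        assert ss.pairwise_correlation(sd, "A-23E") < 0

    def test_independent_poisson_near_zero(self):
        rng = np.random.default_rng(3)
        n, T = 40, 100_000.0
        idx, times = [], []
        for i in range(n):
            t = np.cumsum(rng.exponential(100.0, 1500))
            t = t[t < T]
            idx.append(np.full(t.size, i))
            times.append(t)
        sd = _spikes(
            {"A-23E": (np.concatenate(idx), np.concatenate(times))}, T, sizes={"A-23E": n}
        )
        c = ss.pairwise_correlation(sd, "A-23E", n_sample=40, seed=1)
        # null SE of a single Pearson coefficient ~ 1/sqrt(T_bins); pairs are
        # correlated through shared neurons, so stay conservative
        assert abs(c) < 3.0 / np.sqrt(T)

    def test_matrix_symmetric_unit_diagonal(self, multiarea_run):
        c = ss.correlation_matrix(multiarea_run, multiarea_run.populations[1],
                                  n_sample=30, seed=0)
        assert np.allclose(c, c.T, equal_nan=True)
        assert np.allclose(np.diag(c), 1.0)

    def test_undefined_below_two_neurons(self):
        sd = _spikes({"A-23E": ([0], [1.0])}, 100.0)
        assert np.isnan(ss.pairwise_correlation(sd, "A-23E"))


class TestWelch:
    def test_sinusoid_peak_location(self):
        t = np.arange(30_000) / 1000.0
        x = 5.0 + np.sin(2 * np.pi * 10.0 * t)
        f, p = ss.welch_psd(RateSeries(np.clip(x, 0, None), "x"))
        grid = f[1:]  # skip DC
        peak = grid[np.argmax(p[1:])]
        df = f[1] - f[0]
        assert abs(peak - 10.0) <= df

    def test_white_noise_flat_spectrum(self):
        rng = np.random.default_rng(4)
        reps = []
        for k in range(30):
            x = rng.standard_normal(20_000)
            f, p = ss.welch_psd(x)
            b1 = p[(f >= 1) & (f <= 100)].mean()
            b2 = p[(f >= 200) & (f <= 300)].mean()
            reps.append(b1 / b2)
        reps = np.array(reps)
        se = reps.std(ddof=1) / np.sqrt(reps.size)
        assert abs(reps.mean() - 1.0) < 3 * se

    def test_parseval_within_window_tolerance(self):
        rng = np.random.default_rng(5)
        x = rng.standard_normal(50_000)
        f, p = ss.welch_psd(x - x.mean())
        df = f[1] - f[0]
        # one-sided PSD: integral approximates the variance
        assert np.sum(p) * df == pytest.approx(x.var(), rel=0.05)

    def test_short_series_fallback_warns(self):
        with pytest.warns(UserWarning, match="shorter than one Welch segment"):
            f, p = ss.welch_psd(np.ones(500))
        assert f.size > 0


class TestFluctuationPhases:
    def test_constant_series_all_low(self):
        out = ss.classify_fluctuation_phases(RateSeries(np.full(35_000, 7.0), "x"), 1e-12)
        assert out.labels == ["low", "low", "low"]  # trailing 5 s discarded

    def test_large_slow_modulation_all_high(self):
        t = np.arange(30_000) / 1000.0
        x = 50.0 + 40.0 * np.sin(2 * np.pi * 1.0 * t)
        out = ss.classify_fluctuation_phases(RateSeries(x, "x"), 1e-6)
        assert out.labels == ["high", "high", "high"]

    def test_constructed_mixture_flips_at_midpoint(self):
        t = np.arange(40_000) / 1000.0
        x = np.full(40_000, 20.0)
        x[:20_000] += 15.0 * np.sin(2 * np.pi * 2.0 * t[:20_000])
        out = ss.classify_fluctuation_phases(RateSeries(x, "x"), 1.0)
        assert out.labels == ["high", "high", "low", "low"]

    def test_interval_count_partition(self, multiarea_run):
        series = ss.rate_histogram(multiarea_run)
        out = ss.classify_fluctuation_phases(series, 1e3)
        assert len(out.labels) == int(multiarea_run.duration / 1000.0) // 10


class TestRateDistribution:
    def test_all_silent_empty(self):
        sd = _spikes({"A-23E": ([], [])}, 1000.0, sizes={"A-23E": 5}, recorded={"A-23E": 5})
        assert ss.rate_distribution(sd).size == 0

    def test_threshold_excludes_slow_neurons(self):
        # neuron 0 at 1 spike/s, neuron 1 at 0.1 spikes/s over 10 s
        trains = {"A-23E": ([0] * 10 + [1], list(np.arange(10) * 1000.0 + 5) + [500.0])}
        sd = _spikes(trains, 10_000.0, sizes={"A-23E": 2}, recorded={"A-23E": 2})
        rates = ss.rate_distribution(sd, min_rate=0.56)
        assert rates.size == 1 and rates[0] == pytest.approx(1.0)

    def test_largest_remainder_apportionment(self):
        sizes = np.array([80, 20, 37, 3])
        counts = ss.largest_remainder_apportionment(sizes, 140)
        assert counts.sum() == 140
        # oracle: floors plus largest remainders
        quota = 140 * sizes / sizes.sum()
        floors = np.floor(quota).astype(int)
        rem_order = np.argsort(-(quota - floors), kind="stable")
        expect = floors.copy()
        expect[rem_order[: 140 - floors.sum()]] += 1
        assert np.array_equal(counts, expect)

    def test_proportional_subsample_counts(self, multiarea_run):
        rates = ss.rate_distribution(multiarea_run, min_rate=0.0, target_count=140, seed=0)
        assert rates.size <= 140
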