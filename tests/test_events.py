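import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import ipsckit as ik
from ipsckit.events import _rise_time_ms

from conftest import make_clean_trace


class TestWeightedTau:
    @pytest.mark.parametrize(
        "If, tf, Is, ts, expected",
        [
            (5.0, 3.0, 0.0, 12.0, 3.0),      # slow component absent
            (2.0, 7.0, 3.0, 7.0, 7.0),       # equal taus collapse to tau
            (2.0, 3.0, 1.0, 9.0, 5.0),       # (6 + 9) / 3
        ],
    )
    def test_hand_computed_values(self, If, tf, Is, ts, expected):
        assert ik.weighted_tau(If, tf, Is, ts) == pytest.approx(expected)

    def test_zero_total_amplitude_rejected(self):
        with pytest.raises(ValueError):
            ik.weighted_tau(0.0, 3.0, 0.0, 9.0)

    @settings(derandomize=True, max_examples=200)
    @given(
        If=st.floats(0.0, 100.0),
        Is=st.floats(0.0, 100.0),
        tf=st.floats(0.1, 50.0),
        ratio=st.floats(1.0, 30.0),
    )
    def test_always_between_component_taus(self, If, Is, tf, ratio):
        if If + Is <= 1e-6:  # numerically degenerate weights
            return
        ts = tf * ratio
        tw = ik.weighted_tau(If, tf, Is, ts)
        assert tf - 1e-9 <= tw <= ts + 1e-9


class TestRiseTime:
    def test_linear_ramp(self):
        """A 1 ms linear ramp has a 0.8 ms 10-90% rise."""
        fs = 100_000.0
        n = int(0.001 * fs)
        y = np.r_[np.zeros(10), np.linspace(0, 30, n + 1), np.full(50, 30.0)]
        rise = _rise_time_ms(y, 10, 10 + n, 0.0, fs)
        assert rise == pytest.approx(0.8, rel=0.01)

    def test_exponential_activation_closed_form(self):
        """10-90% rise of a tau-exponential equals tau * ln 9."""
        fs = 100_000.0
        tau_s = 0.0005
        t = np.arange(int(0.02 * fs)) / fs
        y = np.r_[np.zeros(100), 30 * (1 - np.exp(-t / tau_s))]
        rise = _rise_time_ms(y, 100, y.size - 1, 0.0, fs)
        assert rise == pytest.approx(np.log(9) * 0.5, rel=1e-3)

    def test_step_hits_resolution_floor(self):
        fs = 10_000.0
        y = np.r_[np.zeros(100), np.full(100, 30.0)]
        rise = _rise_time_ms(y, 99, 150, 0.0, fs)
        assert rise <= 1e3 / fs  # at most one inter-sample interval


class TestBiexpFit:
    def test_single_exponential_self_consistency(self):
        t = np.arange(0, 60, 0.1)
        fit = ik.fit_biexponential(30 * np.exp(-t / 5.0), t)
        assert fit.converged
        assert fit.tau_weighted_ms == pytest.approx(5.0, rel=0.01)

    def test_two_component_recovery_noiseless(self):
        t = np.arange(0, 80, 0.1)
        y = 20 * np.exp(-t / 3.0) + 10 * np.exp(-t / 12.0)
        fit = ik.fit_biexponential(y, t)
        assert fit.converged
        assert fit.I_fast_pA == pytest.approx(20.0, rel=0.01)
        assert fit.I_slow_pA == pytest.approx(10.0, rel=0.01)
        assert fit.tau_fast_ms == pytest.approx(3.0, rel=0.01)
        assert fit.tau_slow_ms == pytest.approx(12.0, rel=0.01)

    def test_all_zero_segment_not_converged(self):
        t = np.arange(0, 50, 0.1)
        fit = ik.fit_biexponential(np.zeros_like(t), t)
        assert not fit.converged

    def test_tau_ordering_and_weighted_bound_on_noisy_fit(self):
        rng = np.random.default_rng(0)
        t = np.arange(0, 80, 0.1)
        y = 20 * np.exp(-t / 4.0) + 10 * np.exp(-t / 15.0) + rng.normal(0, 0.5, t.size)
        fit = ik.fit_biexponential(y, t)
        assert fit.tau_fast_ms <= fit.tau_slow_ms
        assert fit.tau_fast_ms - 1e-9 <= fit.tau_weighted_ms <= fit.tau_slow_ms + 1e-9


class TestDetection:
    def test_flat_trace_yields_empty_table(self):
        table = ik.detect_events(ik.Trace(np.zeros(10_000), 10_000.0), threshold_pA=5.0)
        assert len(table) == 0

    def test_noiseless_events_detected_exactly(self):
        trace, true_peaks, amps = make_clean_trace(np.linspace(10, 40, 10))
        table = ik.detect_events(trace, threshold_pA=5.0)
        df = table.to_dataframe()
        assert len(df) == 10
        dt_samples = (df["peak_time_s"].to_numpy() - true_peaks) * trace.sampling_hz
        assert np.all(np.abs(dt_samples) <= 1.0)
        np.testing.assert_allclose(df["amplitude_pA"], amps, atol=0.1)

    def test_snr5_sensitivity_and_fdr(self, snr5_trace):
        trace, gt = snr5_trace
        table = ik.detect_events(trace)
        _, sens, fdr = ik.match_events(
            gt.event_times_s, table.to_dataframe()["peak_time_s"].to_numpy())
        assert sens >= 0.95
        assert fdr <= 0.05

    def test_translation_invariance(self):
        """Shifting a trace by k samples shifts every event by exactly k."""
        trace, _, _ = make_clean_trace([20.0, 30.0, 25.0])
        k = 137
        shifted = ik.Trace(np.r_[np.zeros(k), trace.samples[:-k]], trace.sampling_hz)
        t1 = ik.detect_events(trace, threshold_pA=5.0).to_dataframe()
        t2 = ik.detect_events(shifted, threshold_pA=5.0).to_dataframe()
        np.testing.assert_allclose(
            t2["peak_time_s"].to_numpy() - t1["peak_time_s"].to_numpy(),
            k / trace.sampling_hz, atol=1e-12)

    def test_low_threshold_warns(self):
        rng = np.random.default_rng(0)
        trace = ik.Trace(rng.normal(0, 6, 50_000), 10_000.0)
        with pytest.warns(UserWarning, match="noise SD"):
            ik.detect_events(trace, threshold_pA=3.0)

    def test_overlapping_pair_is_merged_and_flagged(self):
        trace, _, _ = make_clean_trace([30.0], pad_s=0.3)
        # add a second event 8 ms after the first (on its decay)
        fs = trace.sampling_hz
        unit = ik.event_waveform(0.5, 5.0, 15.0, 0.7, 1.0, fs)
        i0 = int(0.308 * fs)
        samples = trace.samples.copy()
        samples[i0 : i0 + unit.size] += 25.0 * unit[: samples.size - i0]
        table = ik.detect_events(ik.Trace(samples, fs), threshold_pA=5.0)
        assert any(e.overlap_flag for e in table.events)


class TestSummaries:
    def test_frequency_is_count_over_window(self):
        events = [ik.Event(t, 20.0, 1.0, 0.0, False, int(t * 1e4), 0)
                  for t in np.linspace(1, 599, 1200)]
        table = ik.EventTable(events=events, sampling_hz=10_000.0)
        s = ik.summarize_cell(table, window=(0.0, 600.0))
        assert s.frequency_hz == pytest.approx(2.0)
        assert s.n_events == 1200

    def test_empty_window_zero_frequency(self):
        table = ik.EventTable(events=[], sampling_hz=10_000.0)
        s = ik.summarize_cell(table, window=(0.0, 10.0))
        assert s.frequency_hz == 0.0 and s.n_events == 0
        assert np.isnan(s.mean_amplitude_pA)

    def test_default_window_is_final_two_thirds(self):
        events = [ik.Event(t, 20.0, 1.0, 0.0, False, int(t * 1e4), 0)
                  for t in [1.0, 2.0, 10.0, 11.0, 12.0]]
        table = ik.EventTable(events=events, sampling_hz=10_000.0)
        s = ik.summarize_cell(table, trace_duration_s=15.0)
        assert s.analysis_window_s == (5.0, 15.0)
        assert s.n_events == 3


class TestPooledHistogram:
    def test_counts_conserve_sample_size(self):
        rng = np.random.default_rng(0)
        pools = [rng.normal(30, 5, 4000), rng.normal(28, 5, 4000)]
        counts, edges, kde, sample = ik.pooled_histogram(pools, seed=1)
        assert counts.sum() == 5000
        assert np.all(np.diff(edges) == pytest.approx(3.0))
        assert kde is not None

    def test_identical_amplitudes_single_bin(self):
        with pytest.warns(UserWarning, match="pool"):
            counts, _, kde, _ = ik.pooled_histogram([np.full(100, 21.0)], seed=0)
        assert (counts > 0).sum() == 1
        assert kde is None

    def test_two_point_pool_proportions_within_binomial_bounds(self):
        rng = np.random.default_rng(2)
        pool = np.where(rng.random(20_000) < 0.7, 10.0, 40.0)
        counts, edges, _, sample = ik.pooled_histogram([pool], seed=3)
        frac10 = (sample == 10.0).mean()
        se = np.sqrt(0.7 * 0.3 / 5000)
        assert abs(frac10 - 0.7) < 4 * se


class TestInterEventIntervals:
    def test_simple_differences(self):
        events = [ik.Event(t, 20.0, 1.0, 0.0, False, int(t * 1e4), 0)
                  for t in [1.0, 2.0, 3.0]]
        table = ik.EventTable(events=events, sampling_hz=10_000.0)
        intervals, (x, cdf) = ik.inter_event_intervals(table)
        np.testing.assert_allclose(intervals, [1.0, 1.0])
        assert cdf[-1] == 1.0

    def test_single_event_empty(self):
        table = ik.EventTable(
            events=[ik.Event(1.0, 20.0, 1.0, 0.0, False, 10_000, 0)],
            sampling_hz=10_000.0)
        intervals, _ = ik.inter_event_intervals(table)
        assert intervals.size == 0

    def test_poisson_intervals_exponential(self):
        """Inter-event intervals of a Poisson train pass a KS test vs Exp."""
        cfg = ik.SimConfig(seed=9, duration_s=400.0, event_rate_hz=2.0,
                           noise_sd_pA=0.0)
        _, gt = ik.simulate_trace(cfg)
        intervals = np.diff(gt.event_times_s)
        _, p = stats.kstest(intervals, "expon", args=(0, intervals.mean()))
        assert p > 0.01
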