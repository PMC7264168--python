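import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import ipsckit as ik


def train_times_s(freq_hz, n_pulses=5, recovery_s=0.5):
    t = np.arange(n_pulses) / freq_hz
    return np.r_[t, t[-1] + recovery_s]


class TestTMPredict:
    def test_fast_recovery_limit_all_ones(self):
        params = ik.TMParams(A_pA=50.0, U=0.6, tau_rec_ms=1e-6)
        pred = ik.tm_predict(params, np.arange(5) * 50.0)
        np.testing.assert_allclose(pred, 1.0, atol=1e-9)

    def test_second_response_closed_form_20hz(self):
        """R2 = 1 - U e^(-dt/tau_rec) for the depression-only recurrence."""
        params = ik.TMParams(A_pA=1.0, U=0.5, tau_rec_ms=500.0)
        pred = ik.tm_predict(params, np.arange(5) * 50.0)
        assert pred[1] == pytest.approx(1 - 0.5 * np.exp(-0.1), rel=1e-12)

    def test_infinite_interval_full_recovery(self):
        params = ik.TMParams(A_pA=1.0, U=0.5, tau_rec_ms=300.0)
        pred = ik.tm_predict(params, np.arange(5) * 1e7)
        np.testing.assert_allclose(pred, 1.0, atol=1e-9)

    @settings(derandomize=True, max_examples=100)
    @given(U=st.floats(0.01, 1.0), tau_rec=st.floats(10.0, 5000.0),
           freq=st.sampled_from([5.0, 20.0, 50.0, 100.0]))
    def test_depression_only_train_non_increasing(self, U, tau_rec, freq):
        params = ik.TMParams(A_pA=1.0, U=U, tau_rec_ms=tau_rec)
        pred = ik.tm_predict(params, np.arange(8) / freq * 1e3)
        assert np.all(np.diff(pred) <= 1e-12)

    def test_state_variables_bounded(self):
        params = ik.TMParams(A_pA=1.0, U=0.3, tau_rec_ms=400.0, tau_facil_ms=200.0)
        t = np.arange(10) * 20.0
        # recompute states as tm_predict does and check bounds
        u, R = params.U, 1.0
        for dt in np.diff(t):
            assert params.U - 1e-12 <= u <= 1.0 + 1e-12
            assert 0.0 < R <= 1.0
            u_next = params.U + u * (1 - params.U) * np.exp(-dt / params.tau_facil_ms)
            R = 1 - (1 - R * (1 - u)) * np.exp(-dt / params.tau_rec_ms)
            u = u_next

    def test_facilitation_raises_second_response(self):
        base = ik.TMParams(A_pA=1.0, U=0.2, tau_rec_ms=500.0)
        fac = ik.TMParams(A_pA=1.0, U=0.2, tau_rec_ms=500.0, tau_facil_ms=300.0)
        t = np.arange(5) * 20.0
        assert ik.tm_predict(fac, t)[1] > ik.tm_predict(base, t)[1]


class TestAverageSweeps:
    def test_identical_sweeps_mean_equals_each(self):
        params = ik.TMParams(A_pA=80.0, U=0.5, tau_rec_ms=500.0)
        ss, gt = ik.simulate_tm_sweeps(params, 20.0, trial_cv=0.0,
                                       failure_rate=0.0, seed=0, noise_sd_pA=0.0)
        mean_amps, stats_d = ik.average_sweeps(ss)
        sa = stats_d["sweep_amplitudes"]
        np.testing.assert_allclose(sa, np.broadcast_to(sa[0], sa.shape), rtol=1e-9)
        np.testing.assert_allclose(mean_amps, sa[0], rtol=1e-9)

    def test_keep_all_policy_halves_mean_with_half_failures(self):
        fs = 50_000.0
        pulse_times = np.array([0.05, 0.10])
        unit = ik.event_waveform(0.5, 5.0, 15.0, 0.7, 1.0, fs)
        n = int(0.2 * fs)
        sweeps = np.zeros((20, n))
        rng = np.random.default_rng(0)
        sweeps += rng.normal(0, 0.1, sweeps.shape)
        for s in range(20):
            for j, t_p in enumerate(pulse_times):
                amp = 50.0
                if j == 1 and s % 2 == 0:
                    amp = 0.0  # failure on pulse 2 in half the sweeps
                i0 = int(t_p * fs)
                sweeps[s, i0 : i0 + unit.size] += amp * unit[: n - i0]
        ss = ik.SweepSet(sweeps, fs, pulse_times, 20.0)
        mean_amps, _ = ik.average_sweeps(ss, failure_policy="keep_all")
        assert mean_amps[1] == pytest.approx(mean_amps[0] / 2, rel=0.05)

    def test_exclude_policy_drops_failure_sweeps(self):
        """With unambiguous failures (large responses, low noise) the policy
        keeps exactly the failure-free sweeps."""
        params = ik.TMParams(A_pA=80.0, U=0.5, tau_rec_ms=500.0)
        ss, gt = ik.simulate_tm_sweeps(params, 20.0, n_sweeps=30, trial_cv=0.1,
                                       failure_rate=0.15, seed=1, noise_sd_pA=0.5)
        mean_amps, stats_d = ik.average_sweeps(ss, failure_policy="exclude_sweep")
        expected_kept = (~ss.failure_flags.any(axis=1)).sum()
        assert stats_d["n_sweeps_used"] == expected_kept

    def test_generated_sweeps_match_tm_prediction_within_3se(self):
        params = ik.TMParams(A_pA=100.0, U=0.5, tau_rec_ms=500.0)
        ss, _ = ik.simulate_tm_sweeps(params, 20.0, n_sweeps=25, trial_cv=0.2,
                                      failure_rate=0.0, seed=2)
        mean_amps, stats_d = ik.average_sweeps(ss)
        pred = ik.tm_predict(params, ss.pulse_times_s * 1e3, normalized=False)
        se = stats_d["sweep_amplitudes"].std(axis=0, ddof=1) / np.sqrt(
            stats_d["n_sweeps_used"])
        assert np.all(np.abs(mean_amps - pred) < 3 * se + 0.02 * pred)

    def test_no_usable_sweeps_is_error(self):
        params = ik.TMParams(A_pA=80.0, U=0.5, tau_rec_ms=500.0)
        ss, _ = ik.simulate_tm_sweeps(params, 20.0, failure_rate=1.0,
                                      trial_cv=0.0, seed=0)
        with pytest.raises(ValueError):
            ik.average_sweeps(ss, failure_policy="exclude_sweep")


class TestNormalizeTrain:
    def test_equal_responses_all_ones(self):
        times = train_times_s(20.0)
        tr = ik.normalize_train(np.full(6, 40.0), 20.0, times, n_train_pulses=5)
        np.testing.assert_allclose(tr.normalized, 1.0)
        assert tr.recovery_ratio == pytest.approx(1.0)

    def test_depressing_train_ratio_shape(self):
        """Ratios of a depressing 20 Hz train normalized to the first pulse."""
        amps = np.array([10.0, 7.2, 5.8, 5.3, 4.9])
        tr = ik.normalize_train(amps, 20.0, train_times_s(20.0)[:5],
                                n_train_pulses=5)
        np.testing.assert_allclose(tr.normalized, [1.0, 0.72, 0.58, 0.53, 0.49])

    def test_renormalization_idempotent(self):
        params = ik.TMParams(A_pA=80.0, U=0.5, tau_rec_ms=500.0)
        times = train_times_s(50.0)
        pred = ik.tm_predict(params, times * 1e3, normalized=False)
        tr1 = ik.normalize_train(pred, 50.0, times, n_train_pulses=5)
        tr2 = ik.normalize_train(np.r_[tr1.normalized, tr1.recovery_ratio],
                                 50.0, times, n_train_pulses=5)
        np.testing.assert_allclose(tr2.normalized, tr1.normalized, rtol=1e-12)

    def test_zero_first_pulse_rejected(self):
        with pytest.raises(ValueError, match="first response"):
            ik.normalize_train(np.array([0.0, 1.0]), 20.0, np.array([0.0, 0.05]))


class TestFitTM:
    @staticmethod
    def _noiseless_trains(params, freqs=(5.0, 20.0, 50.0, 100.0)):
        trains = []
        for f in freqs:
            times = train_times_s(f)
            amps = ik.tm_predict(params, times * 1e3, normalized=False)
            trains.append(ik.normalize_train(amps, f, times, n_train_pulses=5))
        return trains

    def test_noiseless_recovery_within_2pct(self):
        true = ik.TMParams(A_pA=100.0, U=0.4, tau_rec_ms=300.0)
        fit = ik.fit_tm(self._noiseless_trains(true))
        assert fit.params.U == pytest.approx(0.4, rel=0.02)
        assert fit.params.tau_rec_ms == pytest.approx(300.0, rel=0.02)
        assert fit.params.A_pA == pytest.approx(100.0, rel=0.02)

    def test_flat_trains_flagged_non_identifiable(self):
        trains = []
        for f in (20.0, 50.0):
            times = train_times_s(f)
            trains.append(ik.normalize_train(np.full(6, 30.0), f, times,
                                             n_train_pulses=5))
        fit = ik.fit_tm(trains)
        assert not fit.identifiable

    def test_single_train_warns(self):
        true = ik.TMParams(A_pA=100.0, U=0.4, tau_rec_ms=300.0)
        with pytest.warns(UserWarning, match="single"):
            ik.fit_tm(self._noiseless_trains(true, freqs=(20.0,)))

    def test_round_trip_recovery_noisy_sweeps(self):
        """simulate -> average -> normalize -> fit recovers U and tau_rec."""
        true = ik.TMParams(A_pA=100.0, U=0.5, tau_rec_ms=500.0)
        errU, errT = [], []
        for seed in range(5):
            trains = []
            for k, f in enumerate((5.0, 20.0, 50.0, 100.0)):
                ss, _ = ik.simulate_tm_sweeps(true, f, n_sweeps=25, trial_cv=0.2,
                                              failure_rate=0.0, seed=seed * 10 + k)
                trains.append(ik.analyze_sweepset(ss))
            fit = ik.fit_tm(trains)
            errU.append(abs(fit.params.U - 0.5) / 0.5)
            errT.append(abs(fit.params.tau_rec_ms - 500.0) / 500.0)
        assert np.median(errU) <= 0.10
        assert np.median(errT) <= 0.20
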