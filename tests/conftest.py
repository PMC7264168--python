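import numpy as np
import pytest

import ipsckit as ik
from ipsckit.synth import waveform_peak_time_ms

DEFAULT_KIN = dict(rise_tau_ms=0.5, tau_fast_ms=5.0, tau_slow_ms=15.0, frac_fast=0.7)


def make_clean_trace(amps, spacing_s=0.5, fs=10_000.0, kin=DEFAULT_KIN, pad_s=0.3):
    """Noiseless trace with events of known amplitudes at regular spacing.

    Returns (Trace, true_peak_times, amps).
    """
    amps = np.asarray(amps, dtype=float)
    n = int((pad_s * 2 + spacing_s * len(amps)) * fs)
    samples = np.zeros(n)
    unit = ik.event_waveform(amp_pA=1.0, sampling_hz=fs, **kin)
    onsets = pad_s + np.arange(len(amps)) * spacing_s
    for t0, a in zip(onsets, amps):
        i0 = int(round(t0 * fs))
        seg = min(unit.size, n - i0)
        samples[i0 : i0 + seg] += a * unit[:seg]
    t_pk = waveform_peak_time_ms(**kin) / 1e3
    return ik.Trace(samples, fs), onsets + t_pk, amps


@pytest.fixture(scope="session")
def snr5_trace():
    """One noisy trace at SNR 5 (amp 30 pA, noise 6 pA) with ground truth."""
    cfg = ik.SimConfig(seed=11, duration_s=100.0, event_rate_hz=1.68,
                       amp_mean_pA=30.0, amp_sd_pA=5.0, noise_sd_pA=6.0)
    return ik.simulate_trace(cfg)


@pytest.fixture(scope="session")
def channel_ensemble():
    """400 binomial gating events, N=20 channels, i=2 pA, low noise."""
    model = ik.ChannelModel(n_channels=20, unit_current_pA=2.0,
                            popen_peak=1.0, popen_decay_tau_ms=10.0)
    return model, ik.simulate_channel_events(model, 400, seed=3, noise_sd_pA=0.5)
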