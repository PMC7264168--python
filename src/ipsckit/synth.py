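"""Seeded synthetic-data generators for every input of the analysis chain.

The generators emulate the study conditions of whole-cell voltage-clamp IPSC
recordings: Poisson-timed events of 20-40 pA riding on Gaussian baseline
noise at 10 kHz, trial-to-trial binomial channel gating for noise analysis,
5-pulse depressing trains at 5/20/50/100 Hz (sampled at 50 kHz) with a
recovery pulse 500 ms after the last, and grouped lognormal immunoblot band
intensities with lane-total covariates.  Every generator is deterministic
given its seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .io_formats import RecordingConditions, SweepSet, Trace
from .psnsn import EventMatrix
from .stp import TMParams, tm_predict

AMPLITUDE_FLOOR_PA = 5.0  # lower bound of the quantal analysis range


@dataclass
class SimConfig:
    """Continuous-trace simulation settings.

    Defaults reflect typical prepubescent mPFC recordings: ~1.7 Hz event
    rate, ~30 pA mean amplitude, biexponential decay with a weighted tau
    near 8 ms, 10 kHz sampling.
    """

    seed: int = 0
    duration_s: float = 60.0
    sampling_hz: float = 10_000.0
    event_rate_hz: float = 1.7
    amp_mean_pA: float = 30.0
    amp_sd_pA: float = 6.0
    tau_fast_ms: float = 5.0
    tau_slow_ms: float = 15.0
    frac_fast: float = 0.7
    rise_tau_ms: float = 0.5
    noise_sd_pA: float = 2.0

    def __post_init__(self) -> None:
        if self.duration_s <= 0 or self.sampling_hz <= 0:
            raise ValueError("duration and sampling rate must be positive")
        if self.event_rate_hz < 0 or self.amp_sd_pA < 0 or self.noise_sd_pA < 0:
            raise ValueError("rates and SDs must be non-negative")
        if min(self.tau_fast_ms, self.tau_slow_ms) <= 0 or self.rise_tau_ms < 0:
            raise ValueError("decay taus must be positive, rise tau non-negative")
        if not 0 <= self.frac_fast <= 1:
            raise ValueError("frac_fast must be in [0, 1]")


@dataclass
class ChannelModel:
    """Ground-truth gating model for the noise-analysis generator."""

    n_channels: int = 20
    unit_current_pA: float = 2.0
    popen_peak: float = 1.0
    popen_decay_tau_ms: float = 10.0

    def __post_init__(self) -> None:
        if self.n_channels < 1:
            raise ValueError("n_channels must be >= 1")
        if not 0 < self.popen_peak <= 1:
            raise ValueError("popen_peak must be in (0, 1]")
        if self.unit_current_pA <= 0 or self.popen_decay_tau_ms <= 0:
            raise ValueError("unit current and decay tau must be positive")


@dataclass
class GroundTruth:
    """What the generator actually produced, for oracle comparisons."""

    event_times_s: np.ndarray = field(default_factory=lambda: np.array([]))
    event_amps_pA: np.ndarray = field(default_factory=lambda: np.array([]))
    channel_model: ChannelModel | None = None
    tm_params: TMParams | None = None
    sweep_amps_pA: np.ndarray | None = None
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.event_times_s = np.asarray(self.event_times_s, dtype=float)
        self.event_amps_pA = np.asarray(self.event_amps_pA, dtype=float)
        if self.event_times_s.size != self.event_amps_pA.size:
            raise ValueError("event times and amplitudes must have equal length")
        if np.any(np.diff(self.event_times_s) <= 0):
            raise ValueError("event times must be strictly increasing")


def _waveform_shape(t_ms: np.ndarray, rise_tau_ms: float, tau_fast_ms: float,
                    tau_slow_ms: float, frac_fast: float) -> np.ndarray:
    decay = frac_fast * np.exp(-t_ms / tau_fast_ms) + (1 - frac_fast) * np.exp(-t_ms / tau_slow_ms)
    if rise_tau_ms <= 0:
        return decay
    return (1 - np.exp(-t_ms / rise_tau_ms)) * decay


def waveform_peak_time_ms(rise_tau_ms: float, tau_fast_ms: float,
                          tau_slow_ms: float, frac_fast: float) -> float:
    """Time of the continuous waveform maximum, found numerically."""
    if rise_tau_ms <= 0:
        return 0.0
    res = minimize_scalar(
        lambda t: -_waveform_shape(np.asarray(t), rise_tau_ms, tau_fast_ms,
                                   tau_slow_ms, frac_fast),
        bounds=(0.0, 10 * tau_slow_ms + 5 * rise_tau_ms),
        method="bounded",
        options={"xatol": 1e-9},
    )
    return float(res.x)


def event_waveform(
    rise_tau_ms: float,
    tau_fast_ms: float,
    tau_slow_ms: float,
    frac_fast: float,
    amp_pA: float,
    sampling_hz: float,
    duration_ms: float | None = None,
) -> np.ndarray:
    """Sampled synaptic event: exponential activation times biexponential decay.

    The rise is modeled as (1 - exp(-t/rise_tau)) multiplying the decay sum
    and the waveform is renormalized so the continuous peak equals
    ``amp_pA`` (the sampled peak matches within one sample's interpolation
    error).  ``amp_pA = 0`` yields an all-zero waveform.
    """
    if min(tau_fast_ms, tau_slow_ms) <= 0 or rise_tau_ms < 0:
        raise ValueError("decay taus must be positive, rise tau non-negative")
    if tau_fast_ms > tau_slow_ms:
        raise ValueError("tau_fast must not exceed tau_slow")
    if not 0 <= frac_fast <= 1:
        raise ValueError("frac_fast must be in [0, 1]")
    if amp_pA < 0:
        raise ValueError("amplitude must be non-negative")
    if duration_ms is None:
        duration_ms = 10 * tau_slow_ms + 5 * max(rise_tau_ms, 0.1)
    n = max(2, int(round(duration_ms / 1e3 * sampling_hz)))
    t_ms = np.arange(n) / sampling_hz * 1e3
    shape = _waveform_shape(t_ms, rise_tau_ms, tau_fast_ms, tau_slow_ms, frac_fast)
    t_pk = waveform_peak_time_ms(rise_tau_ms, tau_fast_ms, tau_slow_ms, frac_fast)
    g_max = float(_waveform_shape(np.asarray(t_pk), rise_tau_ms, tau_fast_ms,
                                  tau_slow_ms, frac_fast))
    if g_max <= 0:
        return np.zeros(n)
    return amp_pA / g_max * shape


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float, n: int,
                      lower: float = AMPLITUDE_FLOOR_PA) -> np.ndarray:
    """Gaussian draws resampled above the quantal-analysis amplitude floor."""
    if sd == 0:
        if mean < lower:
            raise ValueError("degenerate amplitude distribution below the floor")
        return np.full(n, mean)
    out = rng.normal(mean, sd, n)
    bad = out < lower
    while bad.any():
        out[bad] = rng.normal(mean, sd, int(bad.sum()))
        bad = out < lower
    return out


def simulate_trace(config: SimConfig) -> tuple[Trace, GroundTruth]:
    """Continuous trace: Poisson-timed biexponential events on Gaussian noise.

    Ground-truth times refer to event *peaks* (matching what a detector
    reports); amplitudes are Gaussian truncated at the 5 pA analysis floor.
    """
    rng = np.random.default_rng(config.seed)
    n = int(round(config.duration_s * config.sampling_hz))
    trace = rng.normal(0.0, config.noise_sd_pA, n) if config.noise_sd_pA > 0 else np.zeros(n)

    warn: list[str] = []
    expected = config.event_rate_hz * config.duration_s
    if 0 < expected < 1:
        warn.append("expected event count below 1")

    if config.event_rate_hz == 0:
        gt = GroundTruth(warnings=warn)
        return Trace(trace, config.sampling_hz), gt

    n_events = rng.poisson(expected)
    onsets = np.sort(rng.uniform(0, config.duration_s, n_events))
    # enforce strictly increasing times (duplicate draws are measure-zero but possible)
    onsets = np.unique(onsets)
    amps = _truncated_normal(rng, config.amp_mean_pA, config.amp_sd_pA, onsets.size)

    unit = event_waveform(config.rise_tau_ms, config.tau_fast_ms, config.tau_slow_ms,
                          config.frac_fast, 1.0, config.sampling_hz)
    t_pk_s = waveform_peak_time_ms(config.rise_tau_ms, config.tau_fast_ms,
                                   config.tau_slow_ms, config.frac_fast) / 1e3
    for t0, a in zip(onsets, amps):
        i0 = int(round(t0 * config.sampling_hz))
        seg = min(unit.size, n - i0)
        if seg > 0:
            trace[i0 : i0 + seg] += a * unit[:seg]
    gt = GroundTruth(event_times_s=onsets + t_pk_s, event_amps_pA=amps, warnings=warn)
    return Trace(trace, config.sampling_hz), gt


def simulate_channel_events(
    model: ChannelModel,
    n_events: int,
    window_ms: float = 50.0,
    sampling_hz: float = 10_000.0,
    noise_sd_pA: float = 0.5,
    seed: int = 0,
    pre_ms: float = 2.0,
) -> EventMatrix:
    """Peak-aligned ensemble of stochastic channel-gating events.

    Per event, the number of channels open at the peak is binomial
    Bin(N, popen_peak); during the decay each peak-open channel remains open
    at each sample with probability exp(-t / popen_decay_tau), so the
    marginal open probability is popen_peak * exp(-t / tau) and the
    across-event variance at any decay time obeys the binomial
    mean-variance identity.  Rows are events; the peak is at a fixed column
    after ``pre_ms`` of baseline.
    """
    if n_events < 1:
        raise ValueError("n_events must be >= 1")
    if not 50 <= n_events <= 500:
        warnings.warn(
            f"n_events={n_events} outside the conventional 50-500 selection range",
            stacklevel=2,
        )
    if window_ms < 5 * model.popen_decay_tau_ms:
        warnings.warn(
            "window shorter than 5x the open-probability decay tau; "
            "a truncated decay biases downstream fits",
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    pre = int(round(pre_ms / 1e3 * sampling_hz))
    post = int(round(window_ms / 1e3 * sampling_hz))
    t_ms = np.arange(post) / sampling_hz * 1e3
    survival = np.exp(-t_ms / model.popen_decay_tau_ms)

    x0 = rng.binomial(model.n_channels, model.popen_peak, n_events)
    open_counts = rng.binomial(x0[:, None], survival[None, :])
    open_counts[:, 0] = x0  # the peak column is exactly the peak count
    current = open_counts.astype(float) * model.unit_current_pA
    matrix = np.zeros((n_events, pre + post))
    matrix[:, pre:] = current
    if noise_sd_pA > 0:
        matrix += rng.normal(0.0, noise_sd_pA, matrix.shape)
    return EventMatrix(matrix=matrix, peak_col=pre, sampling_hz=sampling_hz)


DEFAULT_TRAIN_FREQS_HZ = (5.0, 20.0, 50.0, 100.0)

_SWEEP_KINETICS = dict(rise_tau_ms=0.5, tau_fast_ms=5.0, tau_slow_ms=15.0, frac_fast=0.7)


def simulate_tm_sweeps(
    params: TMParams,
    freq_hz: float,
    n_pulses: int = 5,
    recovery_ms: float = 500.0,
    n_sweeps: int = 25,
    trial_cv: float = 0.2,
    failure_rate: float = 0.0,
    seed: int = 0,
    sampling_hz: float = 50_000.0,
    noise_sd_pA: float = 2.0,
    kinetics: dict | None = None,
) -> tuple[SweepSet, GroundTruth]:
    """Render depressing-train sweeps from deterministic TM amplitudes.

    Each per-sweep, per-pulse amplitude is the TM prediction multiplied by
    lognormal trial noise of coefficient of variation ``trial_cv`` (exactly
    the prediction when 0), independently zeroed with probability
    ``failure_rate``; responses are rendered as synaptic waveforms at the
    pulse times on Gaussian baseline noise.  The recovery pulse follows the
    last train pulse by ``recovery_ms``.
    """
    if trial_cv < 0 or not 0 <= failure_rate <= 1:
        raise ValueError("trial_cv must be >= 0 and failure_rate in [0, 1]")
    rng = np.random.default_rng(seed)
    kin = dict(_SWEEP_KINETICS)
    if kinetics:
        kin.update(kinetics)

    t0 = 0.05  # pre-train baseline segment, s
    pulse_times = t0 + np.arange(n_pulses) / freq_hz
    pulse_times = np.r_[pulse_times, pulse_times[-1] + recovery_ms / 1e3]
    mean_amps = tm_predict(params, pulse_times * 1e3, normalized=False)

    if trial_cv > 0:
        sigma = np.sqrt(np.log1p(trial_cv**2))
        factors = rng.lognormal(-sigma**2 / 2, sigma, (n_sweeps, pulse_times.size))
    else:
        factors = np.ones((n_sweeps, pulse_times.size))
    failures = rng.random((n_sweeps, pulse_times.size)) < failure_rate
    amps = mean_amps[None, :] * factors
    amps[failures] = 0.0

    unit = event_waveform(kin["rise_tau_ms"], kin["tau_fast_ms"], kin["tau_slow_ms"],
                          kin["frac_fast"], 1.0, sampling_hz)
    n_samples = int(round((pulse_times[-1] + 0.1) * sampling_hz))
    sweeps = (
        rng.normal(0.0, noise_sd_pA, (n_sweeps, n_samples))
        if noise_sd_pA > 0
        else np.zeros((n_sweeps, n_samples))
    )
    for j, t_p in enumerate(pulse_times):
        i0 = int(round(t_p * sampling_hz))
        seg = min(unit.size, n_samples - i0)
        sweeps[:, i0 : i0 + seg] += amps[:, j : j + 1] * unit[:seg]

    sweepset = SweepSet(
        sweeps=sweeps,
        sampling_hz=sampling_hz,
        pulse_times_s=pulse_times,
        freq_hz=freq_hz,
        failure_flags=failures,
    )
    gt = GroundTruth(tm_params=params, sweep_amps_pA=amps)
    return sweepset, gt


def simulate_blot_table(
    group_means: dict[str, float] | None = None,
    cv: float = 0.25,
    n_per_group: int = 8,
    seed: int = 0,
    lane_total_mean: float = 100.0,
    lane_cv: float = 0.2,
) -> pd.DataFrame:
    """Grouped lognormal band intensities with lane-total covariates.

    Each lane total is lognormal around ``lane_total_mean``; the band
    intensity is ``group_mean * lane_total`` times unit-mean lognormal noise
    of coefficient of variation ``cv``, so the lane-corrected ratio has the
    group mean as its expectation (exactly, when ``cv = 0``).  Default group
    structure: eight WT and eight KO samples.
    """
    if group_means is None:
        group_means = {"WT": 1.0, "KO": 0.8}
    if any(m <= 0 for m in group_means.values()):
        raise ValueError("group means must be positive")
    if cv < 0 or lane_cv < 0:
        raise ValueError("coefficients of variation must be non-negative")
    rng = np.random.default_rng(seed)

    def lognormal_mean1(c: float, size: int) -> np.ndarray:
        if c == 0:
            return np.ones(size)
        s = np.sqrt(np.log1p(c**2))
        return rng.lognormal(-s**2 / 2, s, size)

    rows = []
    for group, mean in group_means.items():
        lanes = lane_total_mean * lognormal_mean1(lane_cv, n_per_group)
        bands = mean * lanes * lognormal_mean1(cv, n_per_group)
        for j, (b, l) in enumerate(zip(bands, lanes)):
            rows.append(
                {"sample_id": f"{group}{j + 1}", "group": group,
                 "band_intensity": b, "lane_total": l}
            )
    return pd.DataFrame(rows)


def simulate_quantal_amplitudes(
    n: int,
    n_components: int,
    q_pA: float,
    sigma_pA: float,
    offset_pA: float | None = None,
    weights: np.ndarray | None = None,
    seed: int = 0,
) -> np.ndarray:
    """Amplitudes from an equidistant Gaussian mixture (quantal ground truth)."""
    if offset_pA is None:
        offset_pA = q_pA
    rng = np.random.default_rng(seed)
    if weights is None:
        weights = np.full(n_components, 1.0 / n_components)
    weights = np.asarray(weights, dtype=float)
    weights = weights / weights.sum()
    comps = rng.choice(n_components, size=n, p=weights)
    means = offset_pA + comps * q_pA
    return rng.normal(means, sigma_pA)
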