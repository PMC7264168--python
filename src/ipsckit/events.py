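"""IPSC event detection, kinetics, and per-cell summaries.

Detection is a classical open mini-event detector: a moving-median baseline
(50 ms) is subtracted, the signal is box-smoothed (0.5 ms), threshold
crossings mark candidate events, the peak is the local maximum, and the onset
is the last sub-10% sample before the peak.  Amplitudes are refined by
regressing each event window against the peak-aligned mean waveform, which
removes the positive noise-selection bias of a raw peak-minus-baseline
measurement.

Decay kinetics use the biexponential model

    f(t) = I_fast exp(-t / tau_fast) + I_slow exp(-t / tau_slow)

summarised by the amplitude-weighted time constant

    tau_w = (tau_fast I_fast + tau_slow I_slow) / (I_fast + I_slow).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter1d
from scipy.optimize import least_squares
from scipy.stats import gaussian_kde

from .io_formats import Trace


@dataclass
class BiexpFit:
    I_fast_pA: float
    I_slow_pA: float
    tau_fast_ms: float
    tau_slow_ms: float
    tau_weighted_ms: float
    rss: float
    converged: bool
    r_squared: float = np.nan


@dataclass
class Event:
    peak_time_s: float
    amplitude_pA: float
    rise_time_ms: float  # NaN when the 10% crossing was not found
    baseline_pA: float
    overlap_flag: bool
    peak_index: int
    onset_index: int
    decay_fit: BiexpFit | None = None


@dataclass
class EventTable:
    """Ordered detected events plus a snapshot of the detection settings."""

    events: list[Event]
    sampling_hz: float
    settings: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        times = [e.peak_time_s for e in self.events]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("event peak times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.events)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "peak_time_s": [e.peak_time_s for e in self.events],
                "amplitude_pA": [e.amplitude_pA for e in self.events],
                "rise_ms": [e.rise_time_ms for e in self.events],
                "tau_w_ms": [
                    e.decay_fit.tau_weighted_ms if e.decay_fit is not None else np.nan
                    for e in self.events
                ],
                "overlap_flag": [e.overlap_flag for e in self.events],
            }
        )


@dataclass
class CellSummary:
    frequency_hz: float
    mean_amplitude_pA: float
    mean_rise_ms: float
    mean_tau_weighted_ms: float
    n_events: int
    analysis_window_s: tuple[float, float]


def weighted_tau(I_fast: float, tau_fast: float, I_slow: float, tau_slow: float) -> float:
    """Amplitude-weighted mean decay time constant."""
    total = I_fast + I_slow
    if total <= 0:
        raise ValueError("I_fast + I_slow must be positive")
    return (tau_fast * I_fast + tau_slow * I_slow) / total


def _baseline_subtract(trace: Trace, baseline_median_ms: float) -> np.ndarray:
    win = max(3, int(round(baseline_median_ms / 1e3 * trace.sampling_hz)) | 1)
    baseline = (
        pd.Series(trace.samples).rolling(win, center=True, min_periods=1).median().to_numpy()
    )
    return trace.samples - baseline


def _candidate_peaks(ys: np.ndarray, threshold: float, prominence: float):
    from scipy.signal import find_peaks

    peaks, _ = find_peaks(ys, height=threshold, prominence=prominence)
    return peaks


def _hysteresis_merge(ys: np.ndarray, peaks: np.ndarray, rearm: float):
    """Merge peaks not separated by a dip below the re-arm level.

    A later peak on the un-recovered decay of an earlier one is the same
    event (or an unresolvable overlap): the taller peak is kept and the
    event is overlap-flagged.
    """
    merged: list[int] = []
    overlap: list[bool] = []
    for p in peaks:
        if merged and ys[merged[-1] : p + 1].min() > rearm:
            if ys[p] > ys[merged[-1]]:
                merged[-1] = int(p)
            overlap[-1] = True
        else:
            merged.append(int(p))
            overlap.append(False)
    return np.array(merged, dtype=int), np.array(overlap, dtype=bool)


def _rise_anchor(ys: np.ndarray, peak: int, fs: float, frac: float = 0.5) -> int | None:
    """Last sample below ``frac`` of the peak on the rising phase.

    The mid-rise crossing sits on the steepest part of the waveform, so its
    position jitters far less under noise than the peak sample does; it is
    the alignment anchor for amplitude regression.
    """
    level = frac * ys[peak]
    lo = max(0, peak - int(round(0.01 * fs)))
    below = np.flatnonzero(ys[lo:peak] <= level)
    return lo + int(below[-1]) if below.size else None


def _refine_amplitudes(y: np.ndarray, ys: np.ndarray, peaks: np.ndarray,
                       overlap: np.ndarray, fs: float,
                       pre_ms: float = 3.0, post_ms: float = 40.0) -> np.ndarray:
    """Template-regression amplitudes resistant to noise-selection bias.

    The detected peak sample sits wherever smoothed noise pushed the argmax,
    so reading the current there overestimates amplitudes.  Instead, events
    are aligned on their mid-rise crossing, averaged into a mean waveform
    (non-overlapping events only), and each event window is regressed
    against the unit-peak template; the regression coefficient is the
    amplitude.  Events without a usable anchor or window fall back to the
    raw peak value.
    """
    pre = int(round(pre_ms / 1e3 * fs))
    post = int(round(post_ms / 1e3 * fs))
    guard = int(round(1.5e-3 * fs))  # keep the rise out of the per-row baseline
    n_base = max(2, pre - guard)
    amps = np.array([y[p] for p in peaks], dtype=float)
    refined = np.zeros(peaks.size, dtype=bool)
    anchors = np.full(peaks.size, -1, dtype=int)
    for k, p in enumerate(peaks):
        a = _rise_anchor(ys, p, fs)
        if a is not None and a - pre >= 0 and a + post < y.size:
            anchors[k] = a
    usable = anchors >= 0
    clean = usable & ~overlap
    if clean.sum() < 5:
        clean = usable
    if clean.sum() < 5:
        return amps, refined

    def row(a: int) -> np.ndarray:
        seg = y[a - pre : a + post]
        return seg - np.median(seg[:n_base])

    template = np.mean([row(a) for a in anchors[clean]], axis=0)
    t_peak = template.max()
    if t_peak <= 0:
        return amps, refined
    template = template / t_peak
    denom = float(template @ template)
    for k in np.flatnonzero(usable):
        amps[k] = float(row(anchors[k]) @ template) / denom
        refined[k] = True
    return amps, refined


def detect_events(
    trace: Trace,
    threshold_pA: float = 15.0,
    min_interval_ms: float = 5.0,
    baseline_window_ms: float = 10.0,
    smooth_ms: float = 0.5,
    baseline_median_ms: float = 200.0,
    decay_clear_frac: float = 0.2,
    rearm_frac: float = 0.4,
    prominence_pA: float | None = None,
    refine_amplitudes: bool = True,
) -> EventTable:
    """Detect threshold-crossing events on a baseline-subtracted trace.

    Candidate peaks must exceed the threshold with a prominence of at least
    ``prominence_pA`` (default: the threshold itself), which suppresses
    noise re-crossings on event decays.  Peaks not separated by a dip below
    ``rearm_frac * threshold`` — or closer than ``min_interval_ms`` — are
    merged (tallest kept) and overlap-flagged; an event is also
    overlap-flagged when the signal does not fall below
    ``decay_clear_frac`` of its peak before the next event, which excludes
    it from decay fitting and noise analysis while keeping it for frequency
    and amplitude statistics.
    """
    if threshold_pA <= 0:
        raise ValueError("threshold_pA must be positive")
    fs = trace.sampling_hz
    y = _baseline_subtract(trace, baseline_median_ms)
    k = max(1, int(round(smooth_ms / 1e3 * fs)))
    ys = uniform_filter1d(y, size=k)
    noise_sd = 1.4826 * np.median(np.abs(ys - np.median(ys)))
    if threshold_pA < 2 * noise_sd:
        warnings.warn(
            f"threshold {threshold_pA:.3g} pA is below 2x noise SD "
            f"({noise_sd:.3g} pA); expect a high false-positive rate",
            stacklevel=2,
        )
    settings = dict(
        threshold_pA=threshold_pA, min_interval_ms=min_interval_ms,
        baseline_window_ms=baseline_window_ms, smooth_ms=smooth_ms,
        baseline_median_ms=baseline_median_ms, decay_clear_frac=decay_clear_frac,
        rearm_frac=rearm_frac,
    )
    if prominence_pA is None:
        prominence_pA = threshold_pA
    peaks = _candidate_peaks(ys, threshold_pA, prominence_pA)
    if peaks.size == 0:
        return EventTable(events=[], sampling_hz=fs, settings=settings)
    peaks, overlap_arr = _hysteresis_merge(ys, peaks, rearm_frac * threshold_pA)

    # additionally merge peaks closer than min_interval
    min_gap = max(1, int(round(min_interval_ms / 1e3 * fs)))
    merged: list[int] = []
    overlap: list[bool] = []
    for p, ov in zip(peaks, overlap_arr):
        if merged and p - merged[-1] < min_gap:
            if ys[p] > ys[merged[-1]]:
                merged[-1] = int(p)
            overlap[-1] = True
        else:
            merged.append(int(p))
            overlap.append(bool(ov))
    peaks = np.array(merged)
    overlap_arr = np.array(overlap)

    # decay interrupted by the next event's onset -> overlap flag
    for j in range(len(peaks) - 1):
        seg = ys[peaks[j] : peaks[j + 1]]
        if not np.any(seg < decay_clear_frac * ys[peaks[j]]):
            overlap_arr[j] = True

    if refine_amplitudes:
        amps, refined = _refine_amplitudes(y, ys, peaks, overlap_arr, fs)
    else:
        amps = np.array([y[p] for p in peaks])
        refined = np.zeros(peaks.size, dtype=bool)

    bw = max(1, int(round(baseline_window_ms / 1e3 * fs)))
    events = []
    for p, a, ov, rf in zip(peaks, amps, overlap_arr, refined):
        onset = _find_onset(ys, p, frac=0.10, max_back=int(round(0.05 * fs)))
        base = float(np.median(y[max(0, onset - bw) : onset])) if onset > 0 else 0.0
        rise = _rise_time_ms(y, onset, p, base, fs)
        events.append(
            Event(
                peak_time_s=trace.t0_s + p / fs,
                amplitude_pA=float(a if rf else a - base),
                rise_time_ms=rise,
                baseline_pA=base,
                overlap_flag=bool(ov),
                peak_index=int(p),
                onset_index=int(onset),
            )
        )
    return EventTable(events=events, sampling_hz=fs, settings=settings)


def _find_onset(ys: np.ndarray, peak: int, frac: float, max_back: int) -> int:
    """Last sample below ``frac`` of the peak value before the peak."""
    level = frac * ys[peak]
    lo = max(0, peak - max_back)
    below = np.flatnonzero(ys[lo:peak] <= level)
    return lo + int(below[-1]) if below.size else lo


def _rise_time_ms(y: np.ndarray, onset: int, peak: int, base: float, fs: float) -> float:
    """10-90% rise time by linear interpolation of first upward crossings."""
    amp = y[peak] - base
    if amp <= 0 or peak <= onset:
        return np.nan
    seg = y[onset : peak + 1] - base
    t10 = _first_crossing(seg, 0.10 * amp)
    t90 = _first_crossing(seg, 0.90 * amp)
    if t10 is None or t90 is None or t90 <= t10:
        return np.nan
    return (t90 - t10) / fs * 1e3


def _first_crossing(seg: np.ndarray, level: float) -> float | None:
    above = seg >= level
    if not above.any():
        return None
    j = int(np.argmax(above))
    if j == 0:
        return 0.0
    y0, y1 = seg[j - 1], seg[j]
    return j - 1 + (level - y0) / (y1 - y0) if y1 != y0 else float(j)


def rise_time_10_90(trace: Trace, event: Event) -> float:
    """Recompute the 10-90% rise time of a detected event from its trace."""
    if event.amplitude_pA <= 0:
        raise ValueError("event amplitude must be positive")
    y = trace.samples
    return _rise_time_ms(y, event.onset_index, event.peak_index, event.baseline_pA,
                         trace.sampling_hz)


_TAU_RATIOS = (2.0, 5.0, 10.0, 20.0)


def fit_biexponential(decay_segment: np.ndarray, t_grid_ms: np.ndarray) -> BiexpFit:
    """Multi-start nonlinear least squares of the biexponential decay.

    ``decay_segment`` starts at the event peak; ``t_grid_ms`` is relative to
    the peak.  Four initializations span fast/slow tau ratios 1:2 to 1:20;
    the best residual sum of squares wins, ties broken by the smaller
    tau_slow.  Degenerate input returns ``converged=False``.
    """
    y = np.asarray(decay_segment, dtype=float)
    t = np.asarray(t_grid_ms, dtype=float)
    if y.size != t.size or y.size < 5:
        raise ValueError("decay segment and time grid must match and have >= 5 points")
    a0 = y[0]
    if not np.isfinite(a0) or a0 <= 0 or np.max(np.abs(y)) == 0:
        return BiexpFit(0.0, 0.0, np.nan, np.nan, np.nan, np.nan, converged=False)

    # crude overall tau from the 1/e crossing
    below = np.flatnonzero(y < a0 / np.e)
    tau_est = t[below[0]] if below.size else t[-1] / 2
    tau_est = max(tau_est, t[1] - t[0])

    def model(p):
        If, Is, tf, ts = p
        return If * np.exp(-t / tf) + Is * np.exp(-t / ts)

    def resid(p):
        return model(p) - y

    best = None
    best_ts = np.inf
    for r in _TAU_RATIOS:
        tf0 = tau_est / np.sqrt(r)
        ts0 = tf0 * r
        x0 = [a0 / 2, a0 / 2, tf0, ts0]
        try:
            sol = least_squares(
                resid, x0,
                bounds=([0, 0, 1e-3, 1e-3], [np.inf, np.inf, 1e4, 1e4]),
                method="trf",
            )
        except ValueError:
            continue
        if best is None or sol.cost < best.cost - 1e-12 or (
            abs(sol.cost - best.cost) <= 1e-12 and max(sol.x[2], sol.x[3]) < best_ts
        ):
            best = sol
            best_ts = max(sol.x[2], sol.x[3])
    if best is None:
        return BiexpFit(0.0, 0.0, np.nan, np.nan, np.nan, np.nan, converged=False)
    If, Is, tf, ts = best.x
    if tf > ts:  # order components fast <= slow
        If, Is, tf, ts = Is, If, ts, tf
    rss = float(2 * best.cost)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1 - rss / ss_tot if ss_tot > 0 else np.nan
    try:
        tau_w = weighted_tau(If, tf, Is, ts)
    except ValueError:
        return BiexpFit(If, Is, tf, ts, np.nan, rss, converged=False, r_squared=r2)
    converged = bool(best.success) and np.isfinite(tau_w)
    return BiexpFit(
        I_fast_pA=float(If), I_slow_pA=float(Is),
        tau_fast_ms=float(tf), tau_slow_ms=float(ts),
        tau_weighted_ms=float(tau_w), rss=rss,
        converged=converged, r_squared=float(r2),
    )


def fit_event_decays(
    trace: Trace,
    table: EventTable,
    n_sample: int = 400,
    seed: int | None = None,
    post_ms: float = 50.0,
    r2_min: float = 0.5,
) -> int:
    """Fit biexponential decays on a seeded random subset of clean events.

    Mirrors the practice of fitting ~400 randomly selected events and keeping
    those whose fit quality passes; here fits with ``converged`` and
    R^2 >= ``r2_min`` are attached to their events.  Returns the number of
    accepted fits.
    """
    fs = trace.sampling_hz
    post = int(round(post_ms / 1e3 * fs))
    eligible = [
        e for e in table.events
        if not e.overlap_flag and e.peak_index + post < trace.samples.size
        and e.amplitude_pA > 0
    ]
    rng = np.random.default_rng(seed)
    if len(eligible) > n_sample:
        sel = rng.choice(len(eligible), size=n_sample, replace=False)
        eligible = [eligible[i] for i in sorted(sel)]
    t_ms = np.arange(post) / fs * 1e3
    n_kept = 0
    for e in eligible:
        seg = trace.samples[e.peak_index : e.peak_index + post] - e.baseline_pA
        fit = fit_biexponential(seg, t_ms)
        if fit.converged and (np.isnan(fit.r_squared) or fit.r_squared >= r2_min):
            e.decay_fit = fit
            n_kept += 1
    return n_kept


def summarize_cell(
    table: EventTable,
    window: tuple[float, float] | None = None,
    trace_duration_s: float | None = None,
) -> CellSummary:
    """Frequency and mean kinetics over an analysis window.

    The default window is the final two thirds of the record, emulating the
    practice of analyzing the last 10 of 15 recorded minutes.
    """
    if window is None:
        if trace_duration_s is None:
            if not table.events:
                raise ValueError("need a window or trace duration for an empty table")
            trace_duration_s = table.events[-1].peak_time_s
        window = (trace_duration_s / 3.0, trace_duration_s)
    t0, t1 = window
    if t1 <= t0:
        raise ValueError("window end must exceed window start")
    sel = [e for e in table.events if t0 <= e.peak_time_s < t1]
    n = len(sel)
    freq = n / (t1 - t0)
    if n == 0:
        return CellSummary(0.0, np.nan, np.nan, np.nan, 0, (t0, t1))
    amps = np.array([e.amplitude_pA for e in sel])
    rises = np.array([e.rise_time_ms for e in sel])
    taus = np.array([
        e.decay_fit.tau_weighted_ms for e in sel if e.decay_fit is not None
    ])
    return CellSummary(
        frequency_hz=freq,
        mean_amplitude_pA=float(amps.mean()),
        mean_rise_ms=float(np.nanmean(rises)) if np.any(np.isfinite(rises)) else np.nan,
        mean_tau_weighted_ms=float(taus.mean()) if taus.size else np.nan,
        n_events=n,
        analysis_window_s=(t0, t1),
    )


def pooled_histogram(
    amplitude_pools: list[np.ndarray],
    bin_pA: float = 3.0,
    n_sample: int = 5000,
    seed: int | None = None,
):
    """General amplitude histogram from a seeded random subsample of a pool.

    Amplitudes from all tables are pooled; ``n_sample`` events are drawn
    uniformly without replacement (all of them, with a warning, if the pool
    is smaller); counts are binned at ``bin_pA`` increments and a Gaussian
    kernel density estimate (Silverman bandwidth) is returned alongside.
    """
    pool = np.concatenate([np.asarray(a, dtype=float) for a in amplitude_pools])
    rng = np.random.default_rng(seed)
    if pool.size < n_sample:
        warnings.warn(
            f"pool has {pool.size} events < requested {n_sample}; using all",
            stacklevel=2,
        )
        sample = pool
    else:
        sample = rng.choice(pool, size=n_sample, replace=False)
    lo = np.floor(sample.min() / bin_pA) * bin_pA
    hi = np.ceil(sample.max() / bin_pA) * bin_pA
    if hi <= lo:
        hi = lo + bin_pA
    edges = np.arange(lo, hi + bin_pA / 2, bin_pA)
    counts, edges = np.histogram(sample, bins=edges)
    kde = gaussian_kde(sample, bw_method="silverman") if np.ptp(sample) > 0 else None
    return counts, edges, kde, sample


def inter_event_intervals(table: EventTable):
    """Successive peak-time differences and their empirical CDF.

    Returns ``(intervals, (x, cdf))``; both empty with fewer than two events.
    """
    times = np.array([e.peak_time_s for e in table.events])
    if times.size < 2:
        return np.array([]), (np.array([]), np.array([]))
    intervals = np.diff(times)
    x = np.sort(intervals)
    cdf = np.arange(1, x.size + 1) / x.size
    return intervals, (x, cdf)


def match_events(
    true_times_s: np.ndarray,
    detected_times_s: np.ndarray,
    tol_s: float = 0.005,
):
    """Greedy one-to-one matching of detected to ground-truth event times.

    Returns ``(n_matched, sensitivity, false_discovery_rate)``.
    """
    true_times = np.sort(np.asarray(true_times_s, dtype=float))
    det = np.sort(np.asarray(detected_times_s, dtype=float))
    i = j = matched = 0
    while i < true_times.size and j < det.size:
        dt = det[j] - true_times[i]
        if abs(dt) <= tol_s:
            matched += 1
            i += 1
            j += 1
        elif dt < 0:
            j += 1
        else:
            i += 1
    sens = matched / true_times.size if true_times.size else np.nan
    fdr = (det.size - matched) / det.size if det.size else np.nan
    return matched, sens, fdr
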