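"""Peak-scaled non-stationary noise analysis (PSnSN) of synaptic event decays.

From an ensemble of peak-aligned events, the mean waveform is scaled to each
event's peak and subtracted, leaving a residual matrix whose across-event
variance during the decay, plotted against the mean amplitude I, follows

    sigma^2(I) = i * I - I^2 / N + sigma_b^2

where i is the single-channel current, N the number of receptors open at the
peak, and sigma_b^2 the baseline variance.  Fitting this parabola yields i and
N; dividing i by the chloride driving force (from the Nernst potential of the
recording solutions) gives the unitary conductance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import lsq_linear

from .io_formats import RecordingConditions, Trace

GAS_CONSTANT = 8.314462618  # J / (mol K)
FARADAY = 96485.33212  # C / mol


@dataclass
class EventMatrix:
    """Peak-aligned event ensemble (rows: events, columns: samples, pA)."""

    matrix: np.ndarray
    peak_col: int
    sampling_hz: float
    mean_waveform: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.matrix = np.atleast_2d(np.asarray(self.matrix, dtype=float))
        if not 0 <= self.peak_col < self.matrix.shape[1]:
            raise ValueError("peak_col outside matrix columns")
        self.mean_waveform = self.matrix.mean(axis=0)

    @property
    def n_events(self) -> int:
        return self.matrix.shape[0]


@dataclass
class PSnSNResult:
    """Fitted single-channel parameters from the variance-amplitude parabola."""

    i_pA: float
    N_receptors: float
    sigma_b2_pA2: float
    fit_rss: float
    n_bins_used: int
    converged: bool
    conductance_pS: float | None = None


def build_event_matrix(
    trace: Trace,
    events_df,
    pre_ms: float = 10.0,
    post_ms: float = 50.0,
    min_events: int = 50,
    max_events: int = 500,
    override: bool = False,
    rise_guard_ms: float = 3.0,
) -> EventMatrix:
    """Cut peak-aligned windows around non-overlapping detected events.

    Events flagged as overlapping during their decay are excluded (their
    count is reported in a warning); between ``min_events`` and
    ``max_events`` eligible events are required unless ``override``.
    Each row is locally baseline-subtracted: the median of its pre-peak
    segment, excluding the final ``rise_guard_ms`` that may contain the
    event's rising phase.
    """
    fs = trace.sampling_hz
    pre = int(round(pre_ms / 1e3 * fs))
    post = int(round(post_ms / 1e3 * fs))
    n_base = max(1, pre - int(round(rise_guard_ms / 1e3 * fs)))
    peaks = np.asarray(events_df["peak_time_s"], dtype=float)
    overlap = np.asarray(events_df["overlap_flag"], dtype=bool)
    n_dropped = int(overlap.sum())
    if n_dropped:
        warnings.warn(f"excluded {n_dropped} overlap-flagged events", stacklevel=2)
    idx = np.round((peaks[~overlap] - trace.t0_s) * fs).astype(int)
    idx = idx[(idx - pre >= 0) & (idx + post < trace.samples.size)]
    if idx.size < min_events and not override:
        raise ValueError(
            f"only {idx.size} eligible events; need >= {min_events} (use override to force)"
        )
    if idx.size > max_events:
        idx = idx[:max_events]
    rows = np.stack([trace.samples[i - pre : i + post] for i in idx])
    base = np.median(rows[:, :n_base], axis=1) if pre > 0 else np.zeros(rows.shape[0])
    rows = rows - base[:, None]
    return EventMatrix(matrix=rows, peak_col=pre, sampling_hz=fs)


def peak_scaled_residuals(em: EventMatrix) -> np.ndarray:
    """Scale the mean waveform to each event's peak and subtract.

    Residuals at the peak column are exactly zero by construction.  Rows with
    non-positive peak amplitude are excluded (returned matrix may have fewer
    rows; a warning reports the count).
    """
    mean = em.mean_waveform
    m_peak = mean[em.peak_col]
    if m_peak <= 0:
        raise ValueError("mean waveform peak must be positive")
    row_peaks = em.matrix[:, em.peak_col]
    ok = row_peaks > 0
    if not np.all(ok):
        warnings.warn(f"excluded {int((~ok).sum())} rows with non-positive peak",
                      stacklevel=2)
    rows = em.matrix[ok]
    scale = rows[:, em.peak_col] / m_peak
    return rows - scale[:, None] * mean[None, :]


def decay_range(em: EventMatrix, end_frac: float = 0.05) -> slice:
    """Decay phase: from the peak to where the mean falls below ``end_frac`` of it."""
    mean = em.mean_waveform
    peak = mean[em.peak_col]
    below = np.flatnonzero(mean[em.peak_col :] < end_frac * peak)
    end = em.peak_col + (below[0] if below.size else mean.size - em.peak_col)
    return slice(em.peak_col, end)


def variance_vs_amplitude(
    em: EventMatrix,
    residuals: np.ndarray,
    n_bins: int = 25,
    end_frac: float = 0.05,
) -> np.ndarray:
    """Bin the mean decay amplitude and average the residual variance per bin.

    The mean waveform's decay amplitude range is partitioned into ``n_bins``
    equal-width bins; time points are assigned by their mean amplitude, the
    across-event residual variance at each time point is averaged within the
    bin.  Returns an array of (I_mean_pA, variance_pA2) rows for non-empty
    bins, ordered by amplitude.
    """
    span = decay_range(em, end_frac)
    mean_dec = em.mean_waveform[span]
    var_t = residuals[:, span].var(axis=0, ddof=1)
    lo, hi = mean_dec.min(), mean_dec.max()
    if hi <= lo:
        raise ValueError("mean waveform has no decay amplitude range")
    edges = np.linspace(lo, hi, n_bins + 1)
    which = np.clip(np.digitize(mean_dec, edges) - 1, 0, n_bins - 1)
    pairs = []
    for b in range(n_bins):
        sel = which == b
        if sel.any():
            pairs.append((mean_dec[sel].mean(), var_t[sel].mean()))
    return np.array(sorted(pairs))


def fit_variance_parabola(pairs: np.ndarray, min_points: int = 8) -> PSnSNResult:
    """Constrained least squares of sigma^2 = i*I - I^2/N + sigma_b^2.

    Linear in (i, 1/N, sigma_b^2); solved with bounds i > 0, 1/N > 0,
    sigma_b^2 >= 0.  A convex best fit (no saturation information) or too few
    points yields ``converged=False``.
    """
    pairs = np.asarray(pairs, dtype=float)
    if pairs.ndim != 2 or pairs.shape[1] != 2 or pairs.shape[0] < min_points:
        return PSnSNResult(np.nan, np.nan, np.nan, np.nan, 0, converged=False)
    I, v = pairs[:, 0], pairs[:, 1]
    design = np.column_stack([I, -(I**2), np.ones_like(I)])
    # curvature must be concave AND resolvable above the residual noise
    free, res_free, *_ = np.linalg.lstsq(design, v, rcond=None)
    dof = I.size - 3
    rss_free = float(res_free[0]) if res_free.size else float(
        np.sum((design @ free - v) ** 2))
    try:
        cov = np.linalg.inv(design.T @ design) * rss_free / max(dof, 1)
        curv_se = float(np.sqrt(max(cov[1, 1], 0.0)))
    except np.linalg.LinAlgError:
        curv_se = np.inf
    # ... and contribute non-negligibly to the fitted relation
    curv_span = free[1] * (I.max() ** 2 - I.min() ** 2)
    curvature_ok = (
        free[1] > 0
        and free[1] > 2 * curv_se
        and curv_span > 1e-3 * float(np.mean(np.abs(v)))
    )
    sol = lsq_linear(design, v, bounds=([1e-12, 1e-12, 0.0], np.inf))
    i_hat, invN, sb2 = sol.x
    rss = float(np.sum((design @ sol.x - v) ** 2))
    converged = bool(sol.success) and curvature_ok and i_hat > 1e-9 and invN > 1e-9
    return PSnSNResult(
        i_pA=float(i_hat),
        N_receptors=float(1.0 / invN) if invN > 0 else np.nan,
        sigma_b2_pA2=float(sb2),
        fit_rss=rss,
        n_bins_used=pairs.shape[0],
        converged=converged,
    )


def chloride_reversal_mV(cond: RecordingConditions) -> float:
    """Nernst potential for Cl- (z = -1): E = -(RT/F) ln([Cl]_out / [Cl]_in)."""
    T = cond.temperature_C + 273.15
    rt_f_mV = GAS_CONSTANT * T / FARADAY * 1e3
    return -rt_f_mV * np.log(cond.cl_out_mM / cond.cl_in_mM)


def unitary_conductance(i_pA: float, cond: RecordingConditions) -> float:
    """Single-channel conductance in pS from current and chloride driving force."""
    e_cl = chloride_reversal_mV(cond)
    driving = abs(cond.v_hold_mV - e_cl)
    if driving == 0:
        raise ValueError("zero driving force: holding potential equals E_Cl")
    return i_pA / driving * 1e3  # pA/mV = nS -> pS


def run_psnsn(
    em: EventMatrix,
    n_bins: int = 25,
    conditions: RecordingConditions | None = None,
) -> PSnSNResult:
    """Full chain: peak-scaled residuals -> variance-amplitude -> parabola fit."""
    residuals = peak_scaled_residuals(em)
    pairs = variance_vs_amplitude(em, residuals, n_bins=n_bins)
    result = fit_variance_parabola(pairs)
    if result.converged and conditions is not None:
        result.conductance_pS = unitary_conductance(result.i_pA, conditions)
    return result
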