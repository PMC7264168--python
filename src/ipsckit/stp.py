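"""Short-term plasticity train analysis and Tsodyks-Markram model fitting.

A depressing synapse driven by a pulse train is summarised by its per-pulse
mean amplitudes normalized to the first response, plus the ratio of a delayed
recovery pulse.  The phenomenological Tsodyks-Markram (TM) model describes
those trains with four parameters: absolute efficacy A (pA), utilization of
resources U (a release-probability analogue), a resource recovery time
constant tau_rec (ms), and an optional facilitation time constant tau_facil
(ms; 0 disables facilitation).  The per-pulse recurrences are

    u_1 = U,  R_1 = 1
    u_{n+1} = U + u_n (1 - U) exp(-dt_n / tau_facil)     (= U when tau_facil = 0)
    R_{n+1} = 1 - [1 - R_n (1 - u_n)] exp(-dt_n / tau_rec)
    response_n = A * u_n * R_n

With tau_facil = 0 and U in (0, 1] the normalized responses of a
constant-frequency train are non-increasing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .io_formats import SweepSet


@dataclass
class TMParams:
    """Tsodyks-Markram synapse parameters."""

    A_pA: float = 1.0
    U: float = 0.5
    tau_rec_ms: float = 500.0
    tau_facil_ms: float = 0.0

    def __post_init__(self) -> None:
        if self.A_pA <= 0:
            raise ValueError("A_pA must be positive")
        if not 0 < self.U <= 1:
            raise ValueError("U must be in (0, 1]")
        if self.tau_rec_ms <= 0:
            raise ValueError("tau_rec_ms must be positive")
        if self.tau_facil_ms < 0:
            raise ValueError("tau_facil_ms must be non-negative")


@dataclass
class STPTrain:
    """Normalized train summary for one stimulation frequency."""

    freq_hz: float
    pulse_amplitudes_pA: np.ndarray
    normalized: np.ndarray
    recovery_ratio: float | None
    n_sweeps_used: int
    failure_counts: np.ndarray
    pulse_times_s: np.ndarray

    def __post_init__(self) -> None:
        self.pulse_amplitudes_pA = np.asarray(self.pulse_amplitudes_pA, dtype=float)
        self.normalized = np.asarray(self.normalized, dtype=float)
        self.failure_counts = np.asarray(self.failure_counts, dtype=int)
        self.pulse_times_s = np.asarray(self.pulse_times_s, dtype=float)


@dataclass
class TMFit:
    """Result of fitting the TM model to one or more trains."""

    params: TMParams
    rss: float
    stderr: dict = field(default_factory=dict)
    identifiable: bool = True
    n_points: int = 0


def tm_predict(
    params: TMParams,
    pulse_times_ms: np.ndarray,
    normalized: bool = True,
) -> np.ndarray:
    """Deterministic TM response amplitudes at the given pulse times (ms)."""
    t = np.asarray(pulse_times_ms, dtype=float)
    if t.ndim != 1 or t.size == 0:
        raise ValueError("pulse_times_ms must be a non-empty 1-d sequence")
    if np.any(np.diff(t) <= 0):
        raise ValueError("pulse times must be strictly increasing")
    u = np.empty(t.size)
    R = np.empty(t.size)
    u[0] = params.U
    R[0] = 1.0
    for n in range(t.size - 1):
        dt = t[n + 1] - t[n]
        if params.tau_facil_ms > 0:
            u[n + 1] = params.U + u[n] * (1 - params.U) * np.exp(-dt / params.tau_facil_ms)
        else:
            u[n + 1] = params.U
        R[n + 1] = 1 - (1 - R[n] * (1 - u[n])) * np.exp(-dt / params.tau_rec_ms)
    resp = params.A_pA * u * R
    if normalized:
        return resp / resp[0]
    return resp


def average_sweeps(
    sweepset: SweepSet,
    failure_policy: str = "exclude_sweep",
    window_ms: float = 20.0,
    baseline_ms: float = 2.0,
    failure_k: float = 4.0,
    smooth_ms: float = 0.5,
):
    """Measure per-pulse amplitudes on each sweep and average across sweeps.

    Sweeps are box-smoothed (``smooth_ms``) before measurement so that the
    peak statistic is not dominated by the maximum of raw sampling noise.
    Each pulse is measured as the baseline-subtracted maximum in the window
    from the pulse time to ``min(inter-pulse interval, window_ms)``; the
    baseline is the median over ``baseline_ms`` immediately before the pulse.
    A pulse is a failure when its response is below ``failure_k`` times the
    smoothed pre-train baseline SD.  Policy ``exclude_sweep`` drops sweeps
    containing any failure (evoked-train convention); ``keep_all`` averages
    failures as zeros (unitary-pair convention).

    Returns ``(mean_amplitudes, stats)`` where stats carries per-pulse failure
    counts, number of sweeps used and the per-sweep amplitude matrix.
    """
    if failure_policy not in ("exclude_sweep", "keep_all"):
        raise ValueError("failure_policy must be 'exclude_sweep' or 'keep_all'")
    from scipy.ndimage import uniform_filter1d

    fs = sweepset.sampling_hz
    pulses = sweepset.pulse_times_s
    n_sweeps, n_samples = sweepset.sweeps.shape
    n_pulses = pulses.size
    k = max(1, int(round(smooth_ms / 1e3 * fs)))
    smoothed = uniform_filter1d(sweepset.sweeps, size=k, axis=1)

    # per-pulse measurement windows (half-open, in samples)
    ipis = np.diff(pulses)
    win_s = np.empty(n_pulses)
    win_s[:-1] = np.minimum(ipis, window_ms / 1e3)
    win_s[-1] = window_ms / 1e3
    amps = np.empty((n_sweeps, n_pulses))
    pre_len = max(1, int(round(baseline_ms / 1e3 * fs)))
    for j, (t_p, w) in enumerate(zip(pulses, win_s)):
        i0 = int(round(t_p * fs))
        i1 = min(n_samples, i0 + max(2, int(round(w * fs))))
        base = np.median(smoothed[:, max(0, i0 - pre_len):i0], axis=1)
        amps[:, j] = smoothed[:, i0:i1].max(axis=1) - base

    # noise floor from the smoothed pre-train segment of each sweep
    i_first = int(round(pulses[0] * fs))
    pre = smoothed[:, : max(2, i_first)]
    noise_sd = pre.std(axis=1, ddof=1)
    failures = amps < failure_k * noise_sd[:, None]

    if failure_policy == "exclude_sweep":
        keep = ~failures.any(axis=1)
        if keep.sum() == 0:
            raise ValueError("no usable sweeps after failure exclusion")
        used = amps[keep]
        mean_amps = used.mean(axis=0)
        n_used = int(keep.sum())
    else:
        used = np.where(failures, 0.0, amps)
        mean_amps = used.mean(axis=0)
        n_used = n_sweeps
    if n_used < 5:
        raise ValueError(f"only {n_used} usable sweeps (need >= 5)")
    if n_used < 10:
        warnings.warn(f"only {n_used} usable sweeps", stacklevel=2)
    stats = {
        "failure_counts": failures.sum(axis=0),
        "n_sweeps_used": n_used,
        "sweep_amplitudes": used,
    }
    return mean_amps, stats


def normalize_train(
    mean_amplitudes: np.ndarray,
    freq_hz: float,
    pulse_times_s: np.ndarray,
    n_train_pulses: int | None = None,
    failure_counts: np.ndarray | None = None,
    n_sweeps_used: int = 0,
    noise_floor_pA: float = 0.0,
) -> STPTrain:
    """Normalize a mean train to its first response.

    The final pulse is treated as the recovery pulse when the pulse count
    exceeds ``n_train_pulses`` (default: all but the last pulse form the
    train).
    """
    amps = np.asarray(mean_amplitudes, dtype=float)
    times = np.asarray(pulse_times_s, dtype=float)
    if amps[0] <= max(noise_floor_pA, 0.0):
        raise ValueError("first response at or below noise floor; cannot normalize")
    if n_train_pulses is None:
        n_train_pulses = amps.size - 1 if amps.size > 1 else amps.size
    ratios = amps[:n_train_pulses] / amps[0]
    recovery = float(amps[n_train_pulses] / amps[0]) if amps.size > n_train_pulses else None
    if failure_counts is None:
        failure_counts = np.zeros(amps.size, dtype=int)
    return STPTrain(
        freq_hz=freq_hz,
        pulse_amplitudes_pA=amps,
        normalized=ratios,
        recovery_ratio=recovery,
        n_sweeps_used=n_sweeps_used,
        failure_counts=failure_counts,
        pulse_times_s=times,
    )


def _train_residuals(theta, trains, with_facil):
    U = theta[0]
    tau_rec = theta[1]
    tau_facil = theta[2] if with_facil else 0.0
    try:
        params = TMParams(A_pA=1.0, U=U, tau_rec_ms=tau_rec, tau_facil_ms=tau_facil)
    except ValueError:
        return np.full(sum(t.normalized.size + (t.recovery_ratio is not None) for t in trains), 1e3)
    res = []
    for tr in trains:
        pred = tm_predict(params, tr.pulse_times_s * 1e3)
        n = tr.normalized.size
        res.append(pred[:n] - tr.normalized)
        if tr.recovery_ratio is not None and tr.pulse_times_s.size > n:
            res.append(np.atleast_1d(pred[n] - tr.recovery_ratio))
    return np.concatenate(res)


def fit_tm(trains: list[STPTrain], mode: str = "depression_only") -> TMFit:
    """Jointly fit the TM model to normalized trains across frequencies.

    Frequencies are weighted equally.  A is recovered from the un-normalized
    first-pulse amplitudes (mean over trains) as ``A = amp_1 / U``.  With a
    single train and a free facilitation constant the fit is flagged as
    potentially non-identifiable.
    """
    if mode not in ("depression_only", "with_facilitation"):
        raise ValueError("mode must be 'depression_only' or 'with_facilitation'")
    with_facil = mode == "with_facilitation"
    if len(trains) < 2:
        warnings.warn("fitting a single frequency; parameters may be poorly identified",
                      stacklevel=2)
    lo = [1e-3, 1.0] + ([1.0] if with_facil else [])
    hi = [1.0, 1e4] + ([1e4] if with_facil else [])
    best = None
    for U0 in (0.2, 0.5, 0.8):
        for tr0 in (100.0, 500.0, 1500.0):
            x0 = [U0, tr0] + ([100.0] if with_facil else [])
            sol = least_squares(_train_residuals, x0, args=(trains, with_facil),
                                bounds=(lo, hi), method="trf")
            if best is None or sol.cost < best.cost:
                best = sol
    rss = float(2 * best.cost)
    U_hat, tau_rec_hat = best.x[0], best.x[1]
    tau_facil_hat = best.x[2] if with_facil else 0.0

    amp1 = np.mean([tr.pulse_amplitudes_pA[0] for tr in trains])
    A_hat = float(amp1 / U_hat) if amp1 > 0 else 1.0
    params = TMParams(A_pA=A_hat, U=float(U_hat), tau_rec_ms=float(tau_rec_hat),
                      tau_facil_ms=float(tau_facil_hat))

    n_points = best.fun.size
    identifiable = True
    # flat trains carry no information about the recovery constant
    depth = 1.0 - min(float(tr.normalized.min()) for tr in trains)
    if depth < 0.05:
        identifiable = False
    # boundary solutions are also unidentified
    if tau_rec_hat <= lo[1] * 1.01 or tau_rec_hat >= hi[1] * 0.99 or U_hat <= lo[0] * 2:
        identifiable = False
    stderr: dict = {}
    dof = n_points - best.x.size
    if dof > 0 and identifiable:
        try:
            jtj = best.jac.T @ best.jac
            cov = np.linalg.inv(jtj) * rss / dof
            names = ["U", "tau_rec_ms"] + (["tau_facil_ms"] if with_facil else [])
            stderr = {k: float(np.sqrt(max(cov[i, i], 0.0)))
                      for i, k in enumerate(names)}
        except np.linalg.LinAlgError:
            identifiable = False
    return TMFit(params=params, rss=rss, stderr=stderr,
                 identifiable=identifiable, n_points=n_points)


def analyze_sweepset(
    sweepset: SweepSet,
    failure_policy: str = "exclude_sweep",
    n_train_pulses: int | None = None,
    **kwargs,
) -> STPTrain:
    """Convenience chain: average sweeps, then normalize to the first pulse."""
    mean_amps, stats = average_sweeps(sweepset, failure_policy=failure_policy, **kwargs)
    return normalize_train(
        mean_amps,
        freq_hz=sweepset.freq_hz,
        pulse_times_s=sweepset.pulse_times_s,
        n_train_pulses=n_train_pulses,
        failure_counts=stats["failure_counts"],
        n_sweeps_used=stats["n_sweeps_used"],
    )
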