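"""Readers and writers for current traces, sweep sets, event tables and blot tables.

Conventions
-----------
* Currents are stored amplitude-positive in picoamperes: inhibitory events,
  although inward (negative) at the amplifier, are represented with positive
  peaks.  Raw-file polarity is declared in the file header (``sign``) and
  applied on read.
* Times are in seconds with t = 0 at the start of the record; sweep sets use
  sweep-relative time.  All analysis windows are half-open ``[start, end)``.
* CSV files are comma-separated with '.' decimals; metadata lives in
  '#'-prefixed ``key=value`` header lines.  The binary container is a single
  HDF5 file with a ``samples`` (or ``sweeps``) dataset and scalar attributes.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd


class FormatError(ValueError):
    """Raised for malformed or unsupported on-disk data."""


_TRACE_FORMATS = ("csv", "container")
_SWEEP_FORMATS = ("container",)


@dataclass
class RecordingConditions:
    """Ionic and holding conditions needed for driving-force arithmetic.

    Defaults correspond to a high-chloride internal solution (70 mM Cl-)
    against standard ACSF (125 NaCl + 3 KCl + 2x2 CaCl2 = 132 mM Cl-),
    recorded at 32 degC and a -70 mV holding potential.
    """

    v_hold_mV: float = -70.0
    temperature_C: float = 32.0
    cl_in_mM: float = 70.0
    cl_out_mM: float = 132.0

    def __post_init__(self) -> None:
        if self.cl_in_mM <= 0 or self.cl_out_mM <= 0:
            raise ValueError("chloride concentrations must be positive")


@dataclass
class Trace:
    """Uniformly sampled current record in pA (amplitude-positive)."""

    samples: np.ndarray
    sampling_hz: float
    t0_s: float = 0.0
    conditions: RecordingConditions = field(default_factory=RecordingConditions)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.sampling_hz <= 0:
            raise ValueError("sampling_hz must be positive")
        if self.samples.ndim != 1:
            raise ValueError("trace samples must be one-dimensional")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("trace samples must be finite")

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.sampling_hz

    def times(self) -> np.ndarray:
        return self.t0_s + np.arange(self.samples.size) / self.sampling_hz


@dataclass
class SweepSet:
    """Repeated stimulus-locked sweeps for one train frequency.

    ``pulse_times_s`` lists the train pulses followed by the recovery pulse;
    ``failure_flags`` (optional, n_sweeps x n_pulses) marks pulses with no
    release, as known from a generator or flagged by analysis.
    """

    sweeps: np.ndarray
    sampling_hz: float
    pulse_times_s: np.ndarray
    freq_hz: float
    failure_flags: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.sweeps = np.atleast_2d(np.asarray(self.sweeps, dtype=float))
        self.pulse_times_s = np.asarray(self.pulse_times_s, dtype=float)
        if self.sampling_hz <= 0:
            raise ValueError("sampling_hz must be positive")
        if np.any(np.diff(self.pulse_times_s) <= 0):
            raise ValueError("pulse times must be strictly increasing")
        if self.failure_flags is not None:
            self.failure_flags = np.atleast_2d(np.asarray(self.failure_flags, dtype=bool))
            if self.failure_flags.shape[0] != self.sweeps.shape[0]:
                raise ValueError("failure_flags rows must match number of sweeps")
            if self.failure_flags.shape[1] != self.pulse_times_s.size:
                raise ValueError("failure_flags columns must match number of pulses")

    @property
    def n_sweeps(self) -> int:
        return self.sweeps.shape[0]


BLOT_COLUMNS = ["sample_id", "group", "band_intensity", "lane_total"]


def _validate_blot(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in BLOT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"blot table missing columns: {missing}")
    if (df["band_intensity"] <= 0).any() or (df["lane_total"] <= 0).any():
        raise FormatError("blot intensities must be positive")
    return df


# ---------------------------------------------------------------------------
# traces
# ---------------------------------------------------------------------------

def _infer_format(path: str | Path, supported: tuple[str, ...]) -> str:
    suffix = Path(path).suffix.lower()
    fmt = {".csv": "csv", ".h5": "container", ".hdf5": "container"}.get(suffix)
    if fmt is None or fmt not in supported:
        raise FormatError(
            f"cannot infer a supported format from {path!s}; supported: {supported}"
        )
    return fmt


def _conditions_to_dict(cond: RecordingConditions) -> dict:
    return dataclasses.asdict(cond)


def _parse_header(path: Path) -> tuple[dict, int]:
    meta: dict[str, str] = {}
    n_header = 0
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            n_header += 1
            body = line[1:].strip()
            if "=" in body:
                key, val = body.split("=", 1)
                meta[key.strip()] = val.strip()
    return meta, n_header


def read_trace(path: str | Path, format: str | None = None) -> Trace:
    """Read a current trace from CSV or the HDF5 container.

    The header must declare ``sampling_hz``; a declared ``sign`` is applied so
    that events come out amplitude-positive.  A ``time_s`` column, if present,
    must be uniformly spaced.
    """
    path = Path(path)
    fmt = format or _infer_format(path, _TRACE_FORMATS)
    if fmt == "container":
        with h5py.File(path, "r") as f:
            cond = RecordingConditions(
                v_hold_mV=float(f.attrs.get("v_hold_mV", -70.0)),
                temperature_C=float(f.attrs.get("temperature_C", 32.0)),
                cl_in_mM=float(f.attrs.get("cl_in_mM", 70.0)),
                cl_out_mM=float(f.attrs.get("cl_out_mM", 132.0)),
            )
            return Trace(
                samples=f["samples"][()],
                sampling_hz=float(f.attrs["sampling_hz"]),
                t0_s=float(f.attrs.get("t0_s", 0.0)),
                conditions=cond,
            )
    if fmt != "csv":
        raise FormatError(f"unknown trace format {fmt!r}; supported: {_TRACE_FORMATS}")

    meta, n_header = _parse_header(path)
    if "sampling_hz" not in meta:
        raise FormatError(f"{path}: header does not declare sampling_hz")
    sampling_hz = float(meta["sampling_hz"])
    sign = float(meta.get("sign", 1.0))
    df = pd.read_csv(path, skiprows=n_header)
    if "time_s" in df.columns:
        dt = np.diff(df["time_s"].to_numpy())
        if dt.size and (np.ptp(dt) > 1e-6 * np.median(dt) + 1e-12):
            raise FormatError(f"{path}: time_s column is not uniformly spaced")
    col = "current_pA" if "current_pA" in df.columns else df.columns[-1]
    cond_kwargs = {
        k: float(meta[k])
        for k in ("v_hold_mV", "temperature_C", "cl_in_mM", "cl_out_mM")
        if k in meta
    }
    return Trace(
        samples=sign * df[col].to_numpy(dtype=float),
        sampling_hz=sampling_hz,
        t0_s=float(meta.get("t0_s", 0.0)),
        conditions=RecordingConditions(**cond_kwargs),
    )


def write_trace(trace: Trace, path: str | Path, format: str | None = None) -> Path:
    """Write a trace to CSV (>= 6 significant digits) or the HDF5 container."""
    path = Path(path)
    fmt = format or _infer_format(path, _TRACE_FORMATS)
    if fmt == "container":
        with h5py.File(path, "w") as f:
            f.attrs["kind"] = "trace"
            f.attrs["sampling_hz"] = trace.sampling_hz
            f.attrs["t0_s"] = trace.t0_s
            for key, val in _conditions_to_dict(trace.conditions).items():
                f.attrs[key] = val
            f.create_dataset("samples", data=trace.samples, track_times=False)
        return path
    if fmt != "csv":
        raise FormatError(f"unknown trace format {fmt!r}; supported: {_TRACE_FORMATS}")
    with open(path, "w") as fh:
        fh.write("# ipsckit_trace\n")
        fh.write(f"# sampling_hz={trace.sampling_hz:.10g}\n")
        fh.write(f"# t0_s={trace.t0_s:.10g}\n")
        fh.write("# units=pA\n# sign=1\n")
        for key, val in _conditions_to_dict(trace.conditions).items():
            fh.write(f"# {key}={val:.10g}\n")
        fh.write("current_pA\n")
        np.savetxt(fh, trace.samples, fmt="%.8g")
    return path


# ---------------------------------------------------------------------------
# sweep sets
# ---------------------------------------------------------------------------

def write_sweepset(sweepset: SweepSet, path: str | Path) -> Path:
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.attrs["kind"] = "sweepset"
        f.attrs["sampling_hz"] = sweepset.sampling_hz
        f.attrs["freq_hz"] = sweepset.freq_hz
        f.create_dataset("sweeps", data=sweepset.sweeps, track_times=False)
        f.create_dataset("pulse_times_s", data=sweepset.pulse_times_s, track_times=False)
        if sweepset.failure_flags is not None:
            f.create_dataset("failure_flags", data=sweepset.failure_flags, track_times=False)
    return path


def read_sweepset(path: str | Path) -> SweepSet:
    with h5py.File(path, "r") as f:
        flags = f["failure_flags"][()] if "failure_flags" in f else None
        return SweepSet(
            sweeps=f["sweeps"][()],
            sampling_hz=float(f.attrs["sampling_hz"]),
            pulse_times_s=f["pulse_times_s"][()],
            freq_hz=float(f.attrs["freq_hz"]),
            failure_flags=flags,
        )


# ---------------------------------------------------------------------------
# event tables and blot tables
# ---------------------------------------------------------------------------

EVENT_COLUMNS = ["peak_time_s", "amplitude_pA", "rise_ms", "tau_w_ms", "overlap_flag"]


def write_events(events_df: pd.DataFrame, path: str | Path) -> Path:
    """Write a detected-event table as TSV (header-only when empty)."""
    path = Path(path)
    out = events_df.reindex(columns=EVENT_COLUMNS)
    out.to_csv(path, sep="\t", index=False)
    return path


def read_events(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in EVENT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"event table missing columns: {missing}")
    return df


def write_blot_table(df: pd.DataFrame, path: str | Path) -> Path:
    _validate_blot(df)
    path = Path(path)
    df.to_csv(path, sep="\t", index=False)
    return path


def read_blot_table(path: str | Path) -> pd.DataFrame:
    return _validate_blot(pd.read_csv(path, sep="\t"))
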