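"""End-to-end pipeline orchestration from a single JSON config.

A run config names a master seed, an output directory and an ordered list of
stages (synth, detect, summarize, quantal, psnsn, stp, blot).  Per-stage
seeds are derived from the master seed by a stated splitting rule
(CRC-32 of ``"<seed>:<stage>"``, reduced modulo 2^31), so each stage is
reproducible independently of stage order.  A failing stage halts the run,
leaving a partial manifest; every output file and the config hash are
recorded in the manifest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, blot, events, io_formats, psnsn, quantal, stp, synth

KNOWN_STAGES = ("synth", "detect", "summarize", "quantal", "psnsn", "stp", "blot")

SYNTH_PRESETS = {
    # miniature IPSCs: TTX-like rate ~1 Hz
    "mini": dict(event_rate_hz=1.0, amp_mean_pA=29.0, amp_sd_pA=5.0),
    # spontaneous IPSCs: ~1.7 Hz, slightly larger events
    "spont": dict(event_rate_hz=1.7, amp_mean_pA=30.0, amp_sd_pA=6.0),
}


class ConfigError(ValueError):
    """Raised when a run config violates the schema."""


@dataclass
class RunManifest:
    config: dict
    config_hash: str
    version: str
    master_seed: int
    stages: list[dict] = field(default_factory=list)

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True))
        return path


def stage_seed(master_seed: int, stage_name: str) -> int:
    """Derived per-stage seed: CRC-32 of "<seed>:<stage>" modulo 2^31."""
    return zlib.crc32(f"{master_seed}:{stage_name}".encode()) % (2**31)


def validate_config(config: dict) -> dict:
    if not isinstance(config, dict):
        raise ConfigError("config must be a JSON object")
    for key in ("seed", "outdir", "stages"):
        if key not in config:
            raise ConfigError(f"config missing required field '{key}'")
    if not isinstance(config["seed"], int):
        raise ConfigError("field 'seed' must be an integer")
    if not isinstance(config["stages"], list) or not config["stages"]:
        raise ConfigError("field 'stages' must be a non-empty list")
    for i, st in enumerate(config["stages"]):
        if not isinstance(st, dict) or "name" not in st:
            raise ConfigError(f"stages[{i}] must be an object with a 'name' field")
        if st["name"] not in KNOWN_STAGES:
            raise ConfigError(
                f"stages[{i}].name {st['name']!r} unknown; known stages: {KNOWN_STAGES}"
            )
    return config


def _config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, separators=(",", ":")).encode()
    ).hexdigest()


def _run_synth(st, seed, outdir, ctx):
    preset = st.get("preset", "mini")
    if preset not in SYNTH_PRESETS:
        raise ConfigError(f"unknown synth preset {preset!r}; known: {tuple(SYNTH_PRESETS)}")
    kwargs = dict(SYNTH_PRESETS[preset])
    kwargs.update(st.get("overrides", {}))
    cfg = synth.SimConfig(seed=seed, **kwargs)
    trace, gt = synth.simulate_trace(cfg)
    trace_path = io_formats.write_trace(trace, outdir / "trace.h5")
    gt_path = outdir / "ground_truth.tsv"
    pd.DataFrame(
        {"event_times_s": gt.event_times_s, "event_amps_pA": gt.event_amps_pA}
    ).to_csv(gt_path, sep="\t", index=False)
    params_path = outdir / "sim_params.json"
    params_path.write_text(json.dumps(dataclasses.asdict(cfg), indent=2, sort_keys=True))
    ctx["trace"] = trace
    return [trace_path, gt_path, params_path]


def _run_detect(st, seed, outdir, ctx):
    if "trace" not in ctx:
        raise ConfigError("detect stage requires a prior synth stage")
    table = events.detect_events(
        ctx["trace"],
        threshold_pA=st.get("threshold_pA", 12.0),
        min_interval_ms=st.get("min_interval_ms", 5.0),
    )
    events.fit_event_decays(ctx["trace"], table, seed=seed)
    path = io_formats.write_events(table.to_dataframe(), outdir / "events.tsv")
    ctx["events"] = table
    return [path]


def _run_summarize(st, seed, outdir, ctx):
    if "events" not in ctx:
        raise ConfigError("summarize stage requires a prior detect stage")
    summary = events.summarize_cell(
        ctx["events"], trace_duration_s=ctx["trace"].duration_s
    )
    path = outdir / "summary.json"
    path.write_text(json.dumps(dataclasses.asdict(summary), indent=2, sort_keys=True))
    return [path]


def _run_quantal(st, seed, outdir, ctx):
    if "events" not in ctx:
        raise ConfigError("quantal stage requires a prior detect stage")
    amps = ctx["events"].to_dataframe()["amplitude_pA"].to_numpy()
    hist = quantal.bin_amplitudes(
        amps, lo=st.get("lo", 5.0), hi=st.get("hi", 150.0), width=st.get("bin", 2.0)
    )
    best_k, fits = quantal.select_component_count(hist, k_max=st.get("kmax", 10))
    payload = {
        "best_k": best_k,
        "fits": {
            str(k): {
                "q_pA": f.quantal_size_pA,
                "offset_pA": f.offset_pA,
                "criterion": f.criterion_value,
                "rss": f.rss,
            }
            for k, f in fits.items()
        },
    }
    path = outdir / "quantal.json"
    path.write_text(json.dumps(payload, indent=2, sort_keys=True))
    return [path]


def _run_psnsn(st, seed, outdir, ctx):
    if "events" not in ctx:
        raise ConfigError("psnsn stage requires a prior detect stage")
    em = psnsn.build_event_matrix(
        ctx["trace"],
        ctx["events"].to_dataframe(),
        min_events=st.get("min_events", 50),
        max_events=st.get("max_events", 500),
    )
    result = psnsn.run_psnsn(em, n_bins=st.get("bins", 25),
                             conditions=ctx["trace"].conditions)
    path = outdir / "psnsn.json"
    path.write_text(json.dumps(dataclasses.asdict(result), indent=2, sort_keys=True))
    return [path]


def _run_stp(st, seed, outdir, ctx):
    params = stp.TMParams(
        A_pA=st.get("A_pA", 100.0),
        U=st.get("U", 0.5),
        tau_rec_ms=st.get("tau_rec_ms", 500.0),
        tau_facil_ms=st.get("tau_facil_ms", 0.0),
    )
    freqs = st.get("freqs_hz", list(synth.DEFAULT_TRAIN_FREQS_HZ))
    trains = []
    paths = []
    for k, f_hz in enumerate(freqs):
        sweepset, _ = synth.simulate_tm_sweeps(
            params, f_hz,
            n_sweeps=st.get("n_sweeps", 25),
            trial_cv=st.get("trial_cv", 0.2),
            failure_rate=st.get("failure_rate", 0.0),
            seed=seed + k,
        )
        paths.append(io_formats.write_sweepset(sweepset, outdir / f"sweeps_{int(f_hz)}hz.h5"))
        trains.append(stp.analyze_sweepset(sweepset, failure_policy=st.get("policy", "exclude_sweep")))
    fit = stp.fit_tm(trains, mode=st.get("mode", "depression_only"))
    payload = {
        "true_params": dataclasses.asdict(params),
        "fitted_params": dataclasses.asdict(fit.params),
        "rss": fit.rss,
        "identifiable": fit.identifiable,
        "trains": [
            {"freq_hz": tr.freq_hz, "normalized": tr.normalized.tolist(),
             "recovery_ratio": tr.recovery_ratio}
            for tr in trains
        ],
    }
    path = outdir / "stp.json"
    path.write_text(json.dumps(payload, indent=2, sort_keys=True))
    return paths + [path]


def _run_blot(st, seed, outdir, ctx):
    if "path" in st:
        table = io_formats.read_blot_table(st["path"])
    else:
        table = synth.simulate_blot_table(
            group_means=st.get("group_means"),
            cv=st.get("cv", 0.25),
            n_per_group=st.get("n_per_group", 8),
            seed=seed,
        )
    nb = blot.normalize_blot(table, exclude=st.get("exclude", True))
    path = outdir / "blot_normalized.tsv"
    nb.table.to_csv(path, sep="\t", index=False)
    return [path]


_STAGE_RUNNERS = {
    "synth": _run_synth,
    "detect": _run_detect,
    "summarize": _run_summarize,
    "quantal": _run_quantal,
    "psnsn": _run_psnsn,
    "stp": _run_stp,
    "blot": _run_blot,
}


def run_pipeline(config: dict | str | Path, base_dir: str | Path | None = None) -> RunManifest:
    """Execute the configured stages in order, writing a manifest.

    ``config`` may be a dict or a path to a JSON file.  Raises the failing
    stage's error after writing the partial manifest.
    """
    if not isinstance(config, dict):
        config = json.loads(Path(config).read_text())
    validate_config(config)
    outdir = Path(base_dir or ".") / config["outdir"]
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        config=config,
        config_hash=_config_hash(config),
        version=__version__,
        master_seed=config["seed"],
    )
    ctx: dict = {}
    try:
        for st in config["stages"]:
            name = st["name"]
            seed = stage_seed(config["seed"], name)
            record = {"name": name, "seed": seed, "status": "running", "outputs": []}
            manifest.stages.append(record)
            outputs = _STAGE_RUNNERS[name](st, seed, outdir, ctx)
            record["outputs"] = [str(p) for p in outputs]
            record["status"] = "ok"
    except Exception as exc:
        manifest.stages[-1]["status"] = f"failed: {exc}"
        manifest.to_json(outdir / "manifest.json")
        raise
    manifest.to_json(outdir / "manifest.json")
    return manifest
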