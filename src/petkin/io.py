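"""Trace and config I/O plus the end-to-end recovery experiment driver.

Traces are stored as delimited text with a ``time_s,fluorescence_au`` header
(comma or tab, auto-detected) and an optional JSON metadata sidecar next to
the file. Run configurations are YAML or JSON. Reports are JSON plus a tidy
per-seed CSV; timestamps are deliberately excluded so identical configs give
byte-identical reports.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .exceptions import ConfigurationError, InputError, PetkinError
from .fitting import analyze_two_windows, fit_single_turnover, select_model_order
from .presets import (
    binding_acquisition,
    default_quenching_model,
    long_pair_acquisitions,
    preset_library,
    turnover_acquisition,
)
from .simulate import (
    AcquisitionSpec,
    FlatTurnoverModel,
    Trace,
    generate_binding_trace,
    generate_long_trace_pair,
    generate_single_turnover_trace,
)

__all__ = ["read_trace", "write_trace", "RunConfig", "load_run_config", "run_recovery_experiment"]

logger = logging.getLogger("petkin")


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def read_trace(path) -> Trace:
    """Read a two-column trace file; delimiter auto-detected, header required."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep=None, engine="python", comment="#")
    except Exception as exc:  # parse-level failure
        raise InputError(f"{path}: cannot parse trace file ({exc})") from exc
    required = {"time_s", "fluorescence_au"}
    if not required.issubset(df.columns):
        raise InputError(
            f"{path}: header must contain columns {sorted(required)}, got {list(df.columns)}"
        )
    for col in ("time_s", "fluorescence_au"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            line = int(bad.idxmax()) + 2  # +1 header, +1 one-based
            raise InputError(f"{path}: non-numeric value in column {col!r} at line {line}")
        if coerced.isna().any():
            line = int(coerced.isna().idxmax()) + 2
            raise InputError(f"{path}: missing value in column {col!r} at line {line}")
        df[col] = coerced
    t = df["time_s"].to_numpy()
    if t.size >= 2 and np.any(np.diff(t) <= 0):
        i = int(np.argmax(np.diff(t) <= 0))
        raise InputError(f"{path}: times not strictly increasing at line {i + 3}")
    metadata = {}
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        metadata = json.loads(sidecar.read_text())
    return Trace(t, df["fluorescence_au"].to_numpy(), metadata)


def write_trace(trace: Trace, path, sidecar: bool = True) -> Path:
    """Write a trace as CSV (full double precision) plus a JSON metadata sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame({"time_s": trace.times, "fluorescence_au": trace.fluorescence})
    df.to_csv(path, index=False, float_format="%.17g")
    if sidecar:
        _sidecar_path(path).write_text(trace.to_json_metadata())
    return path


@dataclass
class RunConfig:
    """Configuration of a simulate-fit-summarize recovery experiment.

    ``kind`` is one of ``turnover``, ``binding`` or ``two_window``; seeds
    drive every source of randomness.
    """

    kind: str
    presets: Sequence[str]
    seeds: Sequence[int]
    probe: str = "lid"
    slow_family: str | None = None
    outdir: str | None = None
    acquisition: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in ("turnover", "binding", "two_window"):
            raise ConfigurationError(f"unknown experiment kind {self.kind!r}")
        if not self.seeds:
            raise ConfigurationError("seed list must not be empty")
        if not self.presets:
            raise ConfigurationError("preset list must not be empty")


def load_run_config(path) -> RunConfig:
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    try:
        return RunConfig(**data)
    except TypeError as exc:
        raise ConfigurationError(f"{path}: bad run config ({exc})") from exc


def _with_overrides(acq: AcquisitionSpec, overrides: Mapping[str, float]) -> AcquisitionSpec:
    if not overrides:
        return acq
    from dataclasses import replace

    return replace(acq, **overrides)


def _run_one(config: RunConfig, preset_name: str, seed: int) -> dict:
    record = preset_library(preset_name)
    qm = default_quenching_model()
    if config.kind == "turnover":
        acq = _with_overrides(turnover_acquisition(record, seed), config.acquisition)
        trace = generate_single_turnover_trace(record.turnover_model, acq)
        fit = fit_single_turnover(trace)
        truth = (
            record.turnover_model.k2
            if not isinstance(record.turnover_model, FlatTurnoverModel)
            else None
        )
        return {
            "k2": fit.k2,
            "Fmax": fit.Fmax,
            "k2_true": truth,
            "flags": list(fit.flags),
        }
    if config.kind == "binding":
        acq = _with_overrides(binding_acquisition(record, seed), config.acquisition)
        trace = generate_binding_trace(record.scheme, config.probe, acq, qm)
        fit = select_model_order(trace)
        return {
            "weighted_rate": fit.weighted_rate,
            "total_amplitude": fit.total_amplitude,
            "n_phases": fit.n_phases,
            "runs_test_p": fit.runs_test_p,
        }
    # two_window
    if record.long_scheme is None:
        raise ConfigurationError(f"preset {preset_name!r} has no long-trace scheme")
    acq_s, acq_l = long_pair_acquisitions(seed)
    acq_s = _with_overrides(acq_s, config.acquisition)
    short, long = generate_long_trace_pair(record.long_scheme, "sbdb_ib", acq_s, acq_l, qm)
    family = config.slow_family or record.slow_family or "biexp"
    summary = analyze_two_windows(short, long, family)
    return {
        "amplitude_ratio": summary.amplitude_ratio,
        "rate_separation": summary.rate_separation,
        "slow_family": summary.slow_family,
        "flags": list(summary.flags),
    }


def run_recovery_experiment(config: RunConfig) -> dict:
    """Simulate -> fit -> summarize for every (preset, seed); aggregate mean/SD.

    Per-seed failures are recorded and the run continues. The report is fully
    reproducible from the config and seeds (no timestamps in the payload).
    """
    per_seed: list[dict] = []
    for preset_name in config.presets:
        for seed in config.seeds:
            rec: dict = {"preset": preset_name, "seed": int(seed)}
            logger.info("recover kind=%s preset=%s seed=%d", config.kind, preset_name, seed)
            try:
                rec.update(_run_one(config, preset_name, seed))
            except PetkinError as exc:
                rec["error"] = f"{type(exc).__name__}: {exc}"
                logger.warning("stage failed preset=%s seed=%d: %s", preset_name, seed, exc)
            per_seed.append(rec)

    summary: dict[str, dict] = {}
    df = pd.DataFrame(per_seed)
    for preset_name, group in df.groupby("preset", sort=False):
        stats: dict[str, dict | int] = {}
        numeric = group.select_dtypes(include=[np.number]).drop(columns=["seed"], errors="ignore")
        for col in numeric.columns:
            vals = numeric[col].dropna()
            if vals.empty:
                continue
            stats[col] = {
                "mean": float(vals.mean()),
                "sd": float(vals.std(ddof=1)) if len(vals) > 1 else 0.0,
                "n": int(len(vals)),
            }
        stats["n_failed"] = int(group.get("error", pd.Series(dtype=object)).notna().sum())
        summary[preset_name] = stats

    report = {"config": asdict(config), "per_seed": per_seed, "summary": summary}
    if config.outdir:
        outdir = Path(config.outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True, default=str))
        df.to_csv(outdir / "report.csv", index=False)
    return report
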