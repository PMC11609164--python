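"""Configuration loading, trace serialization and run manifests.

Experiment configs are TOML with sections [device1], [device2] (a preset
name plus overrides, or inline constants), [neuron], [protocol],
[integrator], [noise] and [analysis].  Physical quantities must carry unit
suffixes ("120 uV", "11 ms", "3 Hz", "4.3 kohm") and are normalized on
load, so the ambiguity between micro-, milli- and model volts never
reaches the solver.

Traces are written as CSV with a JSON sidecar manifest recording the seed,
the resolved configuration, software version and decimation — enough to
re-run a noise-free experiment bit-identically.
"""

from __future__ import annotations

import datetime as _dt
import json
import tomllib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import units
from .device import IVTrace, MemristorParams, SwitchingNoise, get_preset
from .neuron import IntegratorConfig, NeuronParams, NeuronState, SimulationTrace
from .stimulus import StimulusProtocol, build_protocol

__all__ = [
    "ExperimentConfig",
    "ConfigError",
    "load_config",
    "experiment_names",
    "load_experiment",
    "write_trace",
    "read_trace",
    "write_iv_trace",
    "read_iv_trace",
    "run_manifest",
]

_TRACE_COLUMNS = ["time", "u", "theta", "x1", "x2", "w_ex", "i1", "i2"]


class ConfigError(ValueError):
    """A config file is missing, malformed or violates an invariant."""


@dataclass
class ExperimentConfig:
    neuron: NeuronParams
    protocol: StimulusProtocol | None
    integrator: IntegratorConfig
    noise: SwitchingNoise
    analysis: dict = field(default_factory=dict)
    seed: int = 0
    raw: dict = field(default_factory=dict)


_DEVICE_VOLT_KEYS = ("V_set", "V_reset")
_DEVICE_OHM_KEYS = ("sigma", "d")
_DEVICE_PLAIN_KEYS = ("B", "b", "E_b", "A_rate", "E_m", "delta", "S_el",
                      "gamma", "p", "polarity", "field_convention", "name")


def _device_from_section(sec: dict, label: str) -> MemristorParams:
    sec = dict(sec)
    preset = sec.pop("preset", None)
    kw: dict = {}
    for key in list(sec):
        if key in _DEVICE_VOLT_KEYS:
            kw[key] = units.parse_voltage(sec.pop(key))
        elif key in _DEVICE_OHM_KEYS:
            kw[key] = units.parse_resistance(sec.pop(key))
        elif key in _DEVICE_PLAIN_KEYS:
            kw[key] = sec.pop(key)
    if sec:
        raise ConfigError(f"[{label}] unknown keys: {sorted(sec)}")
    try:
        if preset is not None:
            return get_preset(preset, **kw)
        return MemristorParams(**kw)
    except (KeyError, ValueError) as exc:
        raise ConfigError(f"[{label}] {exc}") from exc


def _parse_config(doc: dict) -> ExperimentConfig:
    doc = dict(doc)
    d1 = _device_from_section(doc.pop("device1", {"preset": "Ta"}), "device1")
    d2 = _device_from_section(doc.pop("device2", {"preset": "Ru"}), "device2")
    nsec = dict(doc.pop("neuron", {}))
    try:
        neuron = NeuronParams(
            alpha=float(nsec.pop("alpha", 0.78)),
            beta=float(nsec.pop("beta", 1.86)),
            epsilon=float(nsec.pop("epsilon", 0.009)),
            eta=float(nsec.pop("eta", 0.1)),
            literal_eq7=bool(nsec.pop("literal_eq7", False)),
            device1=d1, device2=d2)
    except ValueError as exc:
        raise ConfigError(f"[neuron] {exc}") from exc
    if nsec:
        raise ConfigError(f"[neuron] unknown keys: {sorted(nsec)}")

    protocol = None
    if "protocol" in doc:
        try:
            protocol = build_protocol(doc.pop("protocol"))
        except ValueError as exc:
            raise ConfigError(f"[protocol] {exc}") from exc

    isec = dict(doc.pop("integrator", {}))
    seed = int(doc.pop("seed", isec.pop("seed", 0)))
    init = isec.pop("initial_state", None)
    try:
        state = NeuronState(*[float(v) for v in init]) if init else NeuronState()
        integ = IntegratorConfig(
            step=float(isec.pop("step", 0.02)),
            duration=units.parse_time(isec.pop("duration", 1000.0)),
            err_check=float(isec.pop("err_check", 1e-10)),
            record_every=int(isec.pop("record_every", 1)),
            audit=bool(isec.pop("audit", False)),
            seed=seed, initial_state=state)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"[integrator] {exc}") from exc
    if isec:
        raise ConfigError(f"[integrator] unknown keys: {sorted(isec)}")

    xsec = dict(doc.pop("noise", {}))
    try:
        noise = SwitchingNoise(enabled=bool(xsec.pop("enabled", False)),
                               rel_std=float(xsec.pop("rel_std", 0.05)),
                               seed=int(xsec.pop("seed", seed)))
    except ValueError as exc:
        raise ConfigError(f"[noise] {exc}") from exc
    if xsec:
        raise ConfigError(f"[noise] unknown keys: {sorted(xsec)}")

    analysis = dict(doc.pop("analysis", {}))
    if doc:
        raise ConfigError(f"unknown top-level sections: {sorted(doc)}")
    return ExperimentConfig(neuron=neuron, protocol=protocol, integrator=integ,
                            noise=noise, analysis=analysis, seed=seed)


def load_config(path) -> ExperimentConfig:
    """Load and validate an experiment config file."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    with path.open("rb") as fh:
        try:
            doc = tomllib.load(fh)
        except tomllib.TOMLDecodeError as exc:
            raise ConfigError(f"{path}: {exc}") from exc
    cfg = _parse_config(doc)
    cfg.raw = doc
    return cfg


def experiment_names() -> list[str]:
    """Names of the shipped experiment configs."""
    from importlib import resources
    base = resources.files("memfhn").joinpath("data/experiments")
    return sorted(p.name[:-5] for p in base.iterdir() if p.name.endswith(".toml"))


def load_experiment(name: str) -> ExperimentConfig:
    """Load a shipped experiment config by name (see experiment_names())."""
    from importlib import resources
    ref = resources.files("memfhn").joinpath(f"data/experiments/{name}.toml")
    try:
        data = ref.read_bytes()
    except FileNotFoundError:
        raise ConfigError(f"unknown experiment {name!r}; have {experiment_names()}")
    cfg = _parse_config(tomllib.loads(data.decode()))
    cfg.raw = tomllib.loads(data.decode())
    return cfg


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def run_manifest(seed: int, config: dict | None = None, **extra) -> dict:
    from . import __version__
    return {"software": "memfhn", "version": __version__,
            "created": _dt.datetime.now(_dt.timezone.utc).isoformat(),
            "seed": seed, "config": config or {}, **extra}


def write_trace(trace: SimulationTrace, path, config: dict | None = None,
                decimate: int = 1) -> Path:
    """Write a simulation trace as CSV plus a JSON sidecar manifest.

    ``decimate = k`` keeps every k-th row (noted in the manifest).  The
    matching reader round-trips all series losslessly.
    """
    path = Path(path)
    df = pd.DataFrame({"time": trace.time, "u": trace.u, "theta": trace.theta,
                       "x1": trace.x1, "x2": trace.x2, "w_ex": trace.w_ex,
                       "i1": trace.i1, "i2": trace.i2})
    if decimate > 1:
        df = df.iloc[::decimate]
    df.to_csv(path, index=False, float_format="%.17g")
    manifest = run_manifest(trace.seed, config, step=trace.step,
                            decimation=trace.decimation * decimate,
                            n_rows=len(df), columns=_TRACE_COLUMNS)
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(manifest, indent=1))
    return path


def read_trace(path) -> SimulationTrace:
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    missing = set(_TRACE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    side = path.with_suffix(path.suffix + ".json")
    meta = json.loads(side.read_text()) if side.exists() else {}
    arrays = {c: df[c].to_numpy(dtype=float) for c in _TRACE_COLUMNS}
    return SimulationTrace(time=arrays["time"], u=arrays["u"], theta=arrays["theta"],
                           x1=arrays["x1"], x2=arrays["x2"], w_ex=arrays["w_ex"],
                           i1=arrays["i1"], i2=arrays["i2"],
                           step=float(meta.get("step", 0.02)),
                           seed=int(meta.get("seed", 0)),
                           decimation=int(meta.get("decimation", 1)), meta=meta)


def write_iv_trace(trace: IVTrace, path, config: dict | None = None,
                   seed: int = 0) -> Path:
    """Two-column CSV (voltage_V, current_A) plus JSON sweep metadata."""
    path = Path(path)
    pd.DataFrame({"voltage_V": trace.voltage, "current_A": trace.current}
                 ).to_csv(path, index=False, float_format="%.17g")
    manifest = run_manifest(seed, config, sweep_rate=trace.sweep_rate,
                            compliance=trace.compliance, n_rows=len(trace.voltage))
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(manifest, indent=1))
    return path


def read_iv_trace(path) -> IVTrace:
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    for col in ("voltage_V", "current_A"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col}")
    side = path.with_suffix(path.suffix + ".json")
    meta = json.loads(side.read_text()) if side.exists() else {}
    return IVTrace(voltage=df["voltage_V"].to_numpy(float),
                   current=df["current_A"].to_numpy(float),
                   sweep_rate=float(meta.get("sweep_rate", 7.25e-3)),
                   compliance=float(meta.get("compliance", 1e-3)))
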