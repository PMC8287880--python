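"""Configuration loading/validation, CSV serialization and run manifests.

Configurations are flat YAML or JSON (YAML is a superset, so one loader
handles both).  Recognised blocks: ``parameters`` (keys v0, v, K, n,
k_deg, k_B, k_D, k_C), ``variant`` (kind, magnitude), ``protocol``
(either segments/duration or a step/memory shorthand), ``experiment``
(name + keyword settings), plus top-level ``seed``, ``output_dir`` and
``log_level``.  Unknown keys are rejected with an error naming the key.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Dict, Optional

import numpy as np
import pandas as pd
import yaml

from .params import CircuitParameters, VariantSpec
from .protocols import StressProtocol, memory_protocol, step_protocol

__all__ = ["RunConfig", "ConfigError", "load_config", "save_config",
           "write_manifest", "TRACE_CSV_SCHEMA"]

TRACE_CSV_SCHEMA = "sigvsim-trace-v1"  # cell_id, time_min, sigv, rsiv, complex, L

_TOP_KEYS = {"parameters", "variant", "protocol", "experiment", "seed",
             "output_dir", "log_level"}
_PROTOCOL_KEYS = {"segments", "duration", "kind", "t_on", "t_off", "gap",
                  "L_level", "post_duration"}
_EXPERIMENT_NAMES = {"simulate", "dose_response", "copy_number", "memory",
                     "feedback", "leak_scan", "hill_check", "robustness",
                     "generate", "analyze"}


class ConfigError(ValueError):
    """Raised for malformed configuration files."""


@dataclass
class RunConfig:
    """Validated run configuration with defaults filled in."""

    parameters: CircuitParameters = field(default_factory=CircuitParameters)
    variant: VariantSpec = field(default_factory=VariantSpec)
    protocol: Optional[StressProtocol] = None
    experiment: str = "simulate"
    experiment_options: Dict[str, Any] = field(default_factory=dict)
    seed: int = 0
    output_dir: str = "."
    log_level: str = "INFO"

    def as_dict(self) -> dict:
        d: Dict[str, Any] = {
            "parameters": self.parameters.as_dict(),
            "variant": self.variant.as_dict(),
            "experiment": {"name": self.experiment, **self.experiment_options},
            "seed": self.seed,
            "output_dir": self.output_dir,
            "log_level": self.log_level,
        }
        if self.protocol is not None:
            d["protocol"] = self.protocol.as_dict()
        return d


def _parse_protocol(block: dict) -> StressProtocol:
    unknown = set(block) - _PROTOCOL_KEYS
    if unknown:
        raise ConfigError(f"unknown protocol key(s): {sorted(unknown)}")
    kind = block.get("kind")
    try:
        if "segments" in block:
            return StressProtocol.from_dict(block)
        if kind == "step" or (kind is None and "t_on" in block):
            duration = block.get("duration",
                                 block["t_on"] + block.get("post_duration", 1000.0))
            return step_protocol(block["t_on"], block.get("L_level", 1.0), duration)
        if kind == "memory":
            return memory_protocol(block.get("t_on", 0.0), block["t_off"],
                                   block["gap"], block.get("L_level", 1.0),
                                   block.get("post_duration", 1000.0))
    except KeyError as e:
        raise ConfigError(f"protocol block is missing key {e.args[0]!r}") from e
    except ValueError as e:
        raise ConfigError(f"invalid protocol: {e}") from e
    raise ConfigError(f"cannot interpret protocol block {block!r}")


def parse_config(raw: dict) -> RunConfig:
    if not isinstance(raw, dict):
        raise ConfigError("configuration root must be a mapping")
    unknown = set(raw) - _TOP_KEYS
    if unknown:
        raise ConfigError(f"unknown configuration key(s): {sorted(unknown)}")
    try:
        parameters = CircuitParameters.from_dict(raw.get("parameters", {}))
    except ValueError as e:
        raise ConfigError(f"invalid parameters block: {e}") from e
    try:
        variant = VariantSpec.from_dict(raw.get("variant", {"kind": "wild_type"}))
    except (TypeError, ValueError) as e:
        raise ConfigError(f"invalid variant block: {e}") from e
    protocol = _parse_protocol(raw["protocol"]) if "protocol" in raw else None
    exp_block = dict(raw.get("experiment", {"name": "simulate"}))
    name = exp_block.pop("name", "simulate")
    if name not in _EXPERIMENT_NAMES:
        raise ConfigError(f"unknown experiment {name!r}; expected one of "
                          f"{sorted(_EXPERIMENT_NAMES)}")
    seed = raw.get("seed", 0)
    if not isinstance(seed, int):
        raise ConfigError(f"seed must be an integer, got {seed!r}")
    return RunConfig(parameters=parameters, variant=variant, protocol=protocol,
                     experiment=name, experiment_options=exp_block, seed=seed,
                     output_dir=str(raw.get("output_dir", ".")),
                     log_level=str(raw.get("log_level", "INFO")))


def load_config(path) -> RunConfig:
    """Load and validate a YAML/JSON run configuration."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"configuration file not found: {path}")
    with open(path) as fh:
        try:
            raw = yaml.safe_load(fh) or {}
        except yaml.YAMLError as e:
            raise ConfigError(f"cannot parse {path}: {e}") from e
    return parse_config(raw)


def save_config(config: RunConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.as_dict(), fh, sort_keys=True)


def write_manifest(out_dir, config: RunConfig, artifacts: Dict[str, str]) -> Path:
    """JSON run manifest: config (and its hash), seed, package and schema
    versions, and the artifact paths written by the run."""
    from . import __version__

    out_dir = Path(out_dir)
    payload = config.as_dict()
    blob = json.dumps(payload, sort_keys=True).encode()
    manifest = {
        "config": payload,
        "config_sha256": hashlib.sha256(blob).hexdigest(),
        "seed": config.seed,
        "sigvsim_version": __version__,
        "trace_csv_schema": TRACE_CSV_SCHEMA,
        "artifacts": artifacts,
    }
    path = out_dir / "manifest.json"
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return path


def traces_to_csv(traces, path) -> None:
    """Write mother-machine-style traces to the tidy trace CSV schema."""
    rows = []
    for tr in traces:
        n = len(tr.times)
        div = set(tr.division_frames.tolist()) if tr.division_frames is not None else set()
        for i in range(n):
            rows.append({
                "cell_id": tr.cell_id, "frame": i, "time_min": tr.times[i],
                "yfp": tr.fluorescence[i],
                "length_um": tr.length[i] if tr.length is not None else np.nan,
                "width_um": tr.width[i] if tr.width is not None else np.nan,
                "division": int(i in div),
                "stress_time": tr.stress_time,
            })
    pd.DataFrame(rows).to_csv(path, index=False)


def traces_from_csv(path):
    """Read traces written by :func:`traces_to_csv`."""
    from .traces import CellTrace

    df = pd.read_csv(path)
    traces = []
    for cid, g in df.groupby("cell_id"):
        g = g.sort_values("frame")
        div = g.index[g["division"] == 1]
        traces.append(CellTrace(
            cell_id=int(cid), times=g["time_min"].to_numpy(),
            fluorescence=g["yfp"].to_numpy(),
            stress_time=float(g["stress_time"].iloc[0]),
            length=g["length_um"].to_numpy() if g["length_um"].notna().all() else None,
            width=g["width_um"].to_numpy() if g["width_um"].notna().all() else None,
            division_frames=np.nonzero(g["division"].to_numpy() == 1)[0],
        ))
    return traces
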