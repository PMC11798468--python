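"""Run configuration: YAML file -> validated per-module config objects.

A run config is a nested mapping with optional blocks ``io``, ``rule``,
``features``, ``ensemble``, ``evaluation``, ``simulation`` plus a global
``seed`` and ``out_dir``.  Every block is validated against its module's
dataclass before any work starts; the effective (defaults-merged) config is
written alongside the outputs so a run can be reproduced from its manifest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .eiod_rules import EiodRuleConfig
from .ensemble import BaseClassifierSpec
from .errors import ConfigError
from .features import FeatureConfig
from .synthetic import SimConfig


@dataclass
class RunConfig:
    seed: int = 0
    out_dir: str = "."
    rule: EiodRuleConfig = field(default_factory=EiodRuleConfig)
    features: FeatureConfig = field(default_factory=FeatureConfig)
    spec: BaseClassifierSpec = field(default_factory=BaseClassifierSpec)
    ensemble: dict = field(default_factory=lambda: {"L": 11, "max_rounds": None, "method": "adaboost"})
    simulation: SimConfig = field(default_factory=SimConfig)
    io: dict = field(default_factory=lambda: {"schema": "raw"})


def _build(cls, block: dict, name: str):
    fields = {f.name for f in dataclasses.fields(cls)}
    unknown = set(block) - fields
    if unknown:
        raise ConfigError(f"config block {name!r}: unknown keys {sorted(unknown)}")
    # tuples serialised as lists in YAML
    kwargs = {}
    for f in dataclasses.fields(cls):
        if f.name in block:
            v = block[f.name]
            kwargs[f.name] = tuple(v) if isinstance(v, list) else v
    return cls(**kwargs)


def load_config(path: str | Path | None, overrides: dict | None = None) -> RunConfig:
    """Load YAML config (all blocks optional) and apply flag overrides."""
    data: dict = {}
    if path is not None:
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigError(f"{path}: config root must be a mapping")
    for key, value in (overrides or {}).items():
        if value is not None:
            data[key] = value

    known = {"seed", "out_dir", "rule", "features", "classifier", "ensemble",
             "simulation", "io", "evaluation"}
    unknown = set(data) - known
    if unknown:
        raise ConfigError(f"unknown config blocks {sorted(unknown)}")

    sim_block = dict(data.get("simulation", {}))
    if "rule" in sim_block:
        sim_block["rule"] = _build(EiodRuleConfig, sim_block["rule"], "simulation.rule")
    cls_block = dict(data.get("classifier", {}))
    if "hyperparameters" in cls_block and cls_block["hyperparameters"] is None:
        cls_block["hyperparameters"] = {}
    return RunConfig(
        seed=int(data.get("seed", 0)),
        out_dir=str(data.get("out_dir", ".")),
        rule=_build(EiodRuleConfig, data.get("rule", {}), "rule"),
        features=_build(FeatureConfig, data.get("features", {}), "features"),
        spec=_build(BaseClassifierSpec, cls_block, "classifier"),
        ensemble={**{"L": 11, "max_rounds": None, "method": "adaboost"},
                  **dict(data.get("ensemble", {}))},
        simulation=_build(SimConfig, sim_block, "simulation"),
        io={**{"schema": "raw"}, **dict(data.get("io", {}))},
    )


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if hasattr(obj, "item"):  # numpy scalar
        return obj.item()
    return obj


def file_checksum(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(out_dir: str | Path, cfg: RunConfig, command: str,
                   inputs: list[str | Path] = ()) -> Path:
    """Versioned run manifest: effective config, its hash, seed, input checksums."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    effective = _jsonable(cfg)
    blob = json.dumps(effective, sort_keys=True).encode()
    manifest = {
        "command": command,
        "package_version": __version__,
        "seed": cfg.seed,
        "config": effective,
        "config_sha256": hashlib.sha256(blob).hexdigest(),
        "inputs": {str(p): file_checksum(p) for p in inputs},
    }
    path = out_dir / f"manifest-{command}.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return path
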