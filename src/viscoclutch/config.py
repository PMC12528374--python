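"""YAML run configuration and provenance manifests.

A run config is a nested mapping with optional blocks ``substrate``,
``clutch``, ``motors``, ``genotype``, ``sim``, ``grid`` and
``relaxometry``; omitted blocks fall back to package defaults.  Every
run echoes its resolved config, root seed and package version into a
manifest in the output directory so results are reproducible from the
output alone.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .engine import ClutchParams, Genotype, MotorParams, SimConfig
from .substrate import SLSParams
from .synthetic import GridSpec, make_default_grid

__all__ = ["RunConfig", "load_config", "write_manifest", "ConfigError"]


class ConfigError(ValueError):
    """Invalid or missing configuration, reported with its key path."""


@dataclass
class RunConfig:
    """Resolved parameter blocks for one workbench invocation."""

    substrate: SLSParams = field(default_factory=lambda: SLSParams(0.1, 0.25, 0.1))
    clutch: ClutchParams = field(default_factory=ClutchParams)
    motors: MotorParams = field(default_factory=MotorParams)
    genotype: Genotype = field(default_factory=Genotype.control)
    sim: SimConfig = field(default_factory=SimConfig)
    grid: GridSpec = field(default_factory=make_default_grid)
    ed_method: str = "amplitude"
    raw: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "substrate": self.substrate.to_dict(),
            "clutch": self.clutch.to_dict(),
            "motors": self.motors.to_dict(),
            "genotype": self.genotype.to_dict(),
            "sim": self.sim.to_dict(),
            "grid": self.grid.to_dict(),
            "relaxometry": {"ed_method": self.ed_method},
        }


def _build(section: str, cls, data, default):
    if data is None:
        return default
    if not isinstance(data, dict):
        raise ConfigError(f"{section}: expected a mapping, got {type(data).__name__}")
    try:
        return cls.from_dict(data)
    except (KeyError, TypeError, ValueError) as exc:
        raise ConfigError(f"{section}: {exc}") from exc


def load_config(path: str | Path | None) -> RunConfig:
    """Load a YAML config file; a missing path gives all defaults."""
    if path is None:
        return RunConfig(raw={})
    path = Path(path)
    try:
        data = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ConfigError(f"{path}: not valid YAML ({exc})") from exc
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    known = {"substrate", "clutch", "motors", "genotype", "sim", "grid", "relaxometry"}
    for key in data:
        if key not in known:
            raise ConfigError(f"{key}: unknown config block (expected one of {sorted(known)})")
    cfg = RunConfig(
        substrate=_build("substrate", SLSParams, data.get("substrate"), RunConfig().substrate),
        clutch=_build("clutch", ClutchParams, data.get("clutch"), ClutchParams()),
        motors=_build("motors", MotorParams, data.get("motors"), MotorParams()),
        genotype=_build("genotype", Genotype, data.get("genotype"), Genotype.control()),
        sim=_build("sim", SimConfig, data.get("sim"), SimConfig()),
        grid=_build("grid", GridSpec, data.get("grid"), make_default_grid()),
        raw=data,
    )
    relax = data.get("relaxometry") or {}
    if not isinstance(relax, dict):
        raise ConfigError("relaxometry: expected a mapping")
    cfg.ed_method = relax.get("ed_method", "amplitude")
    if cfg.ed_method not in ("amplitude", "area"):
        raise ConfigError(f"relaxometry.ed_method: unknown method {cfg.ed_method!r}")
    return cfg


def write_manifest(outdir: Path, config: RunConfig, seed: int, extra: dict | None = None) -> Path:
    """Write the provenance manifest (resolved config, seed, version, hash)."""
    from . import __version__

    resolved = config.to_dict()
    payload = json.dumps(resolved, sort_keys=True).encode()
    manifest = {
        "package": "viscoclutch",
        "version": __version__,
        "root_seed": seed,
        "config": resolved,
        "config_sha256": hashlib.sha256(payload).hexdigest(),
    }
    if extra:
        manifest.update(extra)
    out = Path(outdir) / "manifest.json"
    out.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return out
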