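"""Structured run configuration.

One YAML file describes a whole run — method, ladder, integrator,
schedule, toy system, and flags — so that every simulation is fully
reconstructible from (config, seed).  Unknown keys are rejected rather
than ignored: a typo in a threshold should fail loudly, not silently
run a different experiment.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, replace
from typing import Optional

import yaml

from .ladder import LadderSpec, build_ladder
from .tempering import TemperingSchedule
from .toysim import IntegratorConfig, ToySystem

__all__ = ["RunConfig", "parse_config", "write_config", "ConfigError"]


class ConfigError(ValueError):
    """Invalid or unrecognized configuration content."""


_LADDER_DEFAULTS = {
    "t_min": None,  # required
    "t_max": None,  # required
    "t_ref": None,  # required
    "n_rungs": 10,
    "n_below_ref": None,
    "kb": 1.0,
}
_INTEGRATOR_DEFAULTS = {"timestep": 0.01, "friction": 1.0, "seed": 0}
_SCHEDULE_DEFAULTS = {
    "exchange_interval": 200,
    "n_segments": 1000,
    "weight_update": "averaged",
    "weight_refresh_interval": 100,
    "burn_in_fraction": 0.10,
    "start_rung": None,
}
_SYSTEM_DEFAULTS = {
    "d_solute": 1,
    "d_solvent": 0,
    "potential_kind": "harmonic",
    "k_solute": 1.0,
    "k_solvent": 1.0,
    "barrier": 0.0,
    "well_separation": 2.0,
    "coupling": 0.0,
    "k_restraint": 0.0,
}
_FLAG_DEFAULTS = {"omega_exclusion": False, "monitor_variant": "radical"}


@dataclass(frozen=True)
class RunConfig:
    """Validated, fully defaulted run configuration."""

    method: str
    ladder: dict
    integrator: dict
    schedule: dict
    system: dict
    flags: dict

    def build_ladder(self) -> LadderSpec:
        lp = self.ladder
        return build_ladder(
            lp["t_min"], lp["t_max"], lp["t_ref"], lp["n_rungs"],
            n_below_ref=lp["n_below_ref"], kb=lp["kb"],
        )

    def build_system(self) -> ToySystem:
        return ToySystem(**self.system)

    def build_integrator(self, seed: Optional[int] = None) -> IntegratorConfig:
        ip = dict(self.integrator)
        if seed is not None:
            ip["seed"] = seed
        return IntegratorConfig(t_ref=self.ladder["t_ref"], **ip)

    def build_schedule(self) -> TemperingSchedule:
        sp = self.schedule
        return TemperingSchedule(
            method=self.method,
            exchange_interval=sp["exchange_interval"],
            n_segments=sp["n_segments"],
            weight_update=sp["weight_update"],
            weight_refresh_interval=sp["weight_refresh_interval"],
            burn_in_fraction=sp["burn_in_fraction"],
            start_rung=sp["start_rung"],
            monitor_variant=self.flags["monitor_variant"],
        )

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "ladder": dict(self.ladder),
            "integrator": dict(self.integrator),
            "schedule": dict(self.schedule),
            "system": dict(self.system),
            "flags": dict(self.flags),
        }


def _merge_block(name: str, defaults: dict, given: dict) -> dict:
    out = dict(defaults)
    for key, value in given.items():
        if key not in defaults:
            raise ConfigError(f"unrecognized option: {name}.{key}")
        out[key] = value
    missing = [k for k, v in out.items() if v is None and defaults[k] is None and k in ("t_min", "t_max", "t_ref")]
    if missing:
        raise ConfigError(f"missing required option: {name}.{missing[0]}")
    return out


def from_dict(raw: dict) -> RunConfig:
    """Validate a raw mapping into a RunConfig (defaults filled)."""
    if not isinstance(raw, dict):
        raise ConfigError("config must be a mapping")
    known_top = {"method", "ladder", "integrator", "schedule", "system", "flags"}
    for key in raw:
        if key not in known_top:
            raise ConfigError(f"unrecognized option: {key}")
    method = raw.get("method", "sst2")
    if method not in ("st", "sst1", "sst2"):
        raise ConfigError(f"method: unsupported method {method!r}")
    ladder = _merge_block("ladder", _LADDER_DEFAULTS, raw.get("ladder", {}))
    integrator = _merge_block("integrator", _INTEGRATOR_DEFAULTS, raw.get("integrator", {}))
    schedule = _merge_block("schedule", _SCHEDULE_DEFAULTS, raw.get("schedule", {}))
    system = _merge_block("system", _SYSTEM_DEFAULTS, raw.get("system", {}))
    flags = _merge_block("flags", _FLAG_DEFAULTS, raw.get("flags", {}))

    if not ladder["t_min"] <= ladder["t_ref"]:
        raise ConfigError("t_ref: must satisfy t_min <= t_ref")
    if not ladder["t_ref"] <= ladder["t_max"]:
        raise ConfigError("t_ref: must satisfy t_ref <= t_max")
    if schedule["burn_in_fraction"] is not None and not (
        0 <= schedule["burn_in_fraction"] < 1
    ):
        raise ConfigError("burn_in_fraction: must be in [0, 1)")
    if flags["monitor_variant"] not in ("radical", "printed"):
        raise ConfigError("monitor_variant: must be 'radical' or 'printed'")
    return RunConfig(
        method=method,
        ladder=ladder,
        integrator=integrator,
        schedule=schedule,
        system=system,
        flags=flags,
    )


def parse_config(path) -> RunConfig:
    """Parse and validate a YAML run configuration."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return from_dict(raw or {})


def write_config(cfg: RunConfig, path) -> None:
    """Serialize a RunConfig so that parse(write(cfg)) == cfg."""
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=True)
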