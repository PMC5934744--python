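"""Run configuration: YAML files mapping onto the parameter dataclasses.

A config file holds optional ``spiking``, ``cck``, ``secretion`` and
``plasma`` sections whose keys override the published defaults, plus
run-level settings (``seed``, ``dt``, ``duration``, ``burn_in``,
``decay_mode``, ``outdir``).  Unknown keys and out-of-range values raise
a named validation error.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Optional, Union

import yaml

from .params import (CCKParams, PlasmaParams, SecretionParams, SpikingParams,
                     param_fields)

__all__ = ["RunConfig", "ConfigError", "load_config"]


class ConfigError(ValueError):
    """Invalid configuration (unknown key, wrong type, bad value)."""


_RUN_KEYS = {"seed", "dt", "duration", "burn_in", "decay_mode", "outdir"}
_SECTIONS = {
    "spiking": SpikingParams,
    "cck": CCKParams,
    "secretion": SecretionParams,
    "plasma": PlasmaParams,
}


@dataclass
class RunConfig:
    """Effective configuration: parameter sets plus run settings."""

    spiking: SpikingParams = field(default_factory=SpikingParams)
    cck: CCKParams = field(default_factory=CCKParams)
    secretion: SecretionParams = field(default_factory=SecretionParams)
    plasma: PlasmaParams = field(default_factory=PlasmaParams)
    seed: int = 0
    dt: float = 0.001
    duration: float = 1000.0
    burn_in: float = 0.0
    decay_mode: str = "euler"
    outdir: str = "."

    def as_dict(self) -> dict:
        return {
            "spiking": vars(self.spiking).copy(),
            "cck": vars(self.cck).copy(),
            "secretion": vars(self.secretion).copy(),
            "plasma": vars(self.plasma).copy(),
            "seed": self.seed,
            "dt": self.dt,
            "duration": self.duration,
            "burn_in": self.burn_in,
            "decay_mode": self.decay_mode,
            "outdir": self.outdir,
        }


def _build_section(name: str, cls: type, overrides: dict) -> Any:
    allowed = set(param_fields(cls))
    for key in overrides:
        if key not in allowed:
            raise ConfigError(f"unknown key {name}.{key!r}; "
                              f"allowed: {sorted(allowed)}")
    try:
        return cls(**overrides)
    except (TypeError, ValueError) as err:
        raise ConfigError(f"invalid value in section {name!r}: {err}") from err


def load_config(path: Union[str, Path, None] = None,
                overrides: Optional[dict] = None) -> RunConfig:
    """Load a YAML config file (or pure overrides) onto the defaults.

    An empty or missing file yields all published defaults.
    """
    data: dict = {}
    if path is not None:
        text = Path(path).read_text()
        loaded = yaml.safe_load(text)
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ConfigError("config file must contain a mapping")
        data.update(loaded)
    if overrides:
        for k, v in overrides.items():
            if isinstance(v, dict) and isinstance(data.get(k), dict):
                data[k].update(v)
            else:
                data[k] = v

    unknown = set(data) - _RUN_KEYS - set(_SECTIONS)
    if unknown:
        raise ConfigError(f"unknown top-level key(s): {sorted(unknown)}")

    kwargs: dict[str, Any] = {}
    for name, cls in _SECTIONS.items():
        section = data.get(name, {})
        if not isinstance(section, dict):
            raise ConfigError(f"section {name!r} must be a mapping")
        kwargs[name] = _build_section(name, cls, section)
    for key in _RUN_KEYS:
        if key in data:
            kwargs[key] = data[key]
    cfg = RunConfig(**kwargs)
    if cfg.dt <= 0:
        raise ConfigError("dt must be > 0")
    if cfg.decay_mode not in ("euler", "exact"):
        raise ConfigError("decay_mode must be 'euler' or 'exact'")
    return cfg
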