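"""Run configuration: a single YAML mapping with one section per stage.

Unknown keys are rejected by name so a typo in a config file cannot silently
fall back to a default.  All randomness in a run flows from the single
``seed`` through named per-stage substreams.
"""

from __future__ import annotations

import dataclasses
import zlib
from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np
import yaml

from .bcm import SlidingParams
from .device import DeviceParams
from .network import NetworkConfig

__all__ = ["RunConfig", "load_config", "save_config", "substream"]


@dataclass(frozen=True)
class ProtocolConfig:
    """Sweep settings for the timing protocols."""

    g0_levels: tuple[float, ...] = (0.5, 3.0, 7.0)
    dt_min: float = 0.002
    dt_max: float = 0.120
    dt_step: float = 0.002
    relax_after: float = 60.0

    @property
    def dt_grid(self) -> np.ndarray:
        n = int(round((self.dt_max - self.dt_min) / self.dt_step)) + 1
        return self.dt_min + self.dt_step * np.arange(n)


@dataclass(frozen=True)
class RunConfig:
    """Top-level configuration: device, protocols, bcm, network sections."""

    device: DeviceParams = field(default_factory=DeviceParams)
    protocols: ProtocolConfig = field(default_factory=ProtocolConfig)
    bcm: SlidingParams = field(default_factory=SlidingParams)
    network: NetworkConfig = field(default_factory=NetworkConfig)
    seed: int = 0
    out_dir: str = "results"
    verbosity: int = 1


_SECTIONS = {
    "device": DeviceParams,
    "protocols": ProtocolConfig,
    "bcm": SlidingParams,
    "network": NetworkConfig,
}
_SCALARS = ("seed", "out_dir", "verbosity")


def _build_section(cls, data: dict, section: str):
    known = {f.name for f in fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(
            f"unknown key(s) {sorted(unknown)} in config section '{section}'"
        )
    coerced = {}
    for f in fields(cls):
        if f.name in data:
            value = data[f.name]
            coerced[f.name] = tuple(value) if isinstance(value, list) else value
    return cls(**coerced)


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML run configuration; missing keys take defaults."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError("config file must contain a mapping at top level")
    unknown = set(raw) - set(_SECTIONS) - set(_SCALARS)
    if unknown:
        raise ValueError(f"unknown top-level config key(s): {sorted(unknown)}")
    kwargs = {}
    for name, cls in _SECTIONS.items():
        section = raw.get(name, {}) or {}
        if not isinstance(section, dict):
            raise ValueError(f"config section '{name}' must be a mapping")
        kwargs[name] = _build_section(cls, section, name)
    for name in _SCALARS:
        if name in raw:
            kwargs[name] = raw[name]
    return RunConfig(**kwargs)


def save_config(config: RunConfig, path: str | Path) -> None:
    """Write a configuration back to YAML (round-trips through load_config)."""
    out: dict = {}
    for name, cls in _SECTIONS.items():
        section = dataclasses.asdict(getattr(config, name))
        out[name] = {
            k: (list(v) if isinstance(v, tuple) else v) for k, v in section.items()
        }
    for name in _SCALARS:
        out[name] = getattr(config, name)
    Path(path).write_text(yaml.safe_dump(out, sort_keys=False))


def substream(seed: int, stage: str) -> np.random.Generator:
    """Named child generator of the global seed for one pipeline stage."""
    key = zlib.crc32(stage.encode()) % (2**31)
    ss = np.random.SeedSequence(seed, spawn_key=(key,))
    return np.random.default_rng(ss)
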