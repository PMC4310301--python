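"""Run configuration: defaults, YAML loading and validation.

The defaults are the model's canonical simulation constants; any override is
validated against the hard parameter bounds and logged by the CLI as a
deviation.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import yaml

from .learning import SCHEMES

__all__ = ["RunConfig", "load_config"]

_SCENARIOS = ("single", "double")


@dataclass
class RunConfig:
    """Everything a reproducible run needs (scenario, scheme, constants)."""

    scenario: str = "single"
    scheme: str = "full"
    seed: int | None = None
    dt_ms: float = 1.0
    t_ph_s: float = 500.0  # phase duration, single scenario
    duration_s: float = 500.0  # total duration, double scenario
    nu_in: float = 10.0
    nu_high: float = 30.0
    nu_low: float = 5.0
    eta_bar: float = 0.1
    gamma: float = 2.0
    gamma_high: float = 1.0  # single-scenario high phases
    gamma_low: float = 2.0  # single-scenario low phases
    update_scale: float = 5.0
    coupling: float | None = None  # None: pooled default 0.28/N
    facilitation_first: bool = True
    record_every_s: float = 1.0
    record_raster: bool = False

    def __post_init__(self) -> None:
        if self.scenario not in _SCENARIOS:
            raise ValueError(f"scenario must be one of {_SCENARIOS}")
        if self.scheme not in SCHEMES:
            raise ValueError(f"unknown scheme {self.scheme!r}; valid: {sorted(SCHEMES)}")
        if self.dt_ms <= 0:
            raise ValueError("dt_ms must be positive")
        for name in ("nu_in", "nu_high", "nu_low", "eta_bar", "update_scale"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.coupling is not None and self.coupling <= 0:
            raise ValueError("coupling must be positive")
        if self.t_ph_s < 0 or self.duration_s < 0:
            raise ValueError("durations must be non-negative")

    def overrides(self) -> dict:
        """Fields that differ from the canonical defaults."""
        ref = RunConfig()
        return {
            f.name: getattr(self, f.name)
            for f in dataclasses.fields(self)
            if getattr(self, f.name) != getattr(ref, f.name)
        }

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def load_config(path) -> RunConfig:
    """Parse a YAML config file; unknown keys are rejected.

    An empty file yields all canonical defaults.
    """
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError("config file must contain a mapping")
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**data)
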