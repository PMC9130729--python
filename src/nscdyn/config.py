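"""Run configuration: a fully serializable description of a simulation run.

A run is reproducible from its echoed configuration alone — rates, cohort
size, horizon, schedule, death model, replicate count and master seed all
live in one flat document (YAML on disk, JSON accepted).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .core import RateSet
from .ssa import DeathModel, TrainingSchedule

__all__ = ["RunConfig", "load_config", "ConfigError"]


class ConfigError(ValueError):
    """Configuration file violates the schema; message names the key path."""


@dataclass
class RunConfig:
    rates: RateSet = field(default_factory=RateSet)
    p0: int = 1000
    horizon: float = 30.0
    schedule: TrainingSchedule | None = None
    death: DeathModel | None = None
    replicates: int = 20
    master_seed: int = 0
    output_dir: str = "results"

    def __post_init__(self) -> None:
        if self.p0 <= 0:
            raise ConfigError(f"p0: must be positive, got {self.p0}")
        if self.horizon <= 0:
            raise ConfigError(f"horizon: must be positive, got {self.horizon}")
        if self.replicates < 1:
            raise ConfigError(f"replicates: must be >= 1, got {self.replicates}")

    def to_dict(self) -> dict:
        return {
            "rates": self.rates.to_dict(),
            "p0": self.p0,
            "horizon": self.horizon,
            "schedule": self.schedule.to_dict() if self.schedule else None,
            "death": self.death.to_dict() if self.death else None,
            "replicates": self.replicates,
            "master_seed": self.master_seed,
            "output_dir": self.output_dir,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        try:
            rates = RateSet.from_dict(d.get("rates", RateSet().to_dict()))
        except KeyError as e:
            raise ConfigError(f"rates: {e.args[0]}") from e
        try:
            schedule = (
                TrainingSchedule.from_dict(d["schedule"]) if d.get("schedule") else None
            )
        except (KeyError, ValueError) as e:
            raise ConfigError(f"schedule: {e}") from e
        try:
            death = DeathModel.from_dict(d["death"]) if d.get("death") else None
        except ValueError as e:
            raise ConfigError(f"death: {e}") from e
        return cls(
            rates=rates,
            p0=int(d.get("p0", 1000)),
            horizon=float(d.get("horizon", 30.0)),
            schedule=schedule,
            death=death,
            replicates=int(d.get("replicates", 20)),
            master_seed=int(d.get("master_seed", 0)),
            output_dir=str(d.get("output_dir", "results")),
        )

    def save(self, path: str | Path) -> None:
        path = Path(path)
        payload = self.to_dict()
        if path.suffix == ".json":
            path.write_text(json.dumps(payload, indent=2))
        else:
            path.write_text(yaml.safe_dump(payload, sort_keys=False))


def load_config(path: str | Path) -> RunConfig:
    """Parse a YAML/JSON run configuration; parse -> serialize -> parse is identity."""
    data = yaml.safe_load(Path(path).read_text())
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: expected a mapping at the top level")
    return RunConfig.from_dict(data)
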