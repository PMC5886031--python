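"""Run configuration: a serializable description of a full simulated session.

A persisted :class:`RunConfig` plus its master seed fully determine every
output file (distribution JSONs, trajectory CSVs, session logs, summaries).
Unknown keys are rejected so a typo cannot silently fall back to a default.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Literal

from pydantic import BaseModel, ConfigDict, Field

from .experiments import ExperimentConfig
from .observers import (
    DirectionGapObserver,
    DmaxObserver,
    GuessingObserver,
    SpeedGapObserver,
)
from .rdk import StimulusSpec

__all__ = ["StimulusConfig", "ObserverConfig", "RunConfig", "load_config", "save_config"]


class StimulusConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    n_dots: int = Field(default=226, gt=0)
    aperture_diameter: float = Field(default=12.0, gt=0)
    dot_diameter: float = Field(default=0.1, gt=0)
    dot_luminance: float = Field(default=0.05, ge=0)
    background_luminance: float = Field(default=25.0, ge=0)
    update_rate: float = Field(default=18.75, gt=0)
    n_updates: int = Field(default=10, gt=0)
    isi_ms: float = Field(default=500.0, ge=0)
    monitor_refresh: float = Field(default=75.0, gt=0)

    def to_spec(self) -> StimulusSpec:
        return StimulusSpec(**self.model_dump())


class ObserverConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    name: Literal["guess", "oracle", "noisy-speed", "direction", "dmax"] = "guess"
    params: dict[str, float] = Field(default_factory=dict)

    def build(self):
        p = self.params
        if self.name == "guess":
            return GuessingObserver()
        if self.name == "oracle":
            return SpeedGapObserver(noise_fraction=0.0)
        if self.name == "noisy-speed":
            return SpeedGapObserver(**p) if p else SpeedGapObserver()
        if self.name == "direction":
            return DirectionGapObserver(**p) if p else DirectionGapObserver()
        return DmaxObserver(**p) if p else DmaxObserver()


class RunConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    experiment: int = Field(ge=1, le=4)
    variant: Literal["mean", "bandwidth"] = "mean"  # experiment 2 only
    speed_range: Literal["slow", "fast"] = "slow"  # experiment 3 only
    notch_widths: list[float] | None = None
    mean_distances: list[float] | None = None
    bandwidths: list[float] | None = None
    gap_widths: list[float] | None = None
    speeds: list[float] | None = None
    mean_distance: float = 6.0
    grid_interval: float | None = None
    trials_per_condition: int = Field(default=280, gt=0)
    seed: int = 0
    stimulus: StimulusConfig = Field(default_factory=StimulusConfig)
    observer: ObserverConfig = Field(default_factory=ObserverConfig)
    out_dir: str | None = None

    def conditions(self):
        kwargs: dict = {"experiment": self.experiment}
        if self.experiment == 1 and self.notch_widths:
            kwargs["notch_widths"] = tuple(self.notch_widths)
        if self.experiment == 2:
            kwargs["variant"] = self.variant
            if self.mean_distances:
                kwargs["mean_distances"] = tuple(self.mean_distances)
            if self.bandwidths:
                kwargs["bandwidths"] = tuple(self.bandwidths)
        if self.experiment == 3:
            kwargs["speed_range"] = self.speed_range
            kwargs["mean_distance"] = self.mean_distance
            if self.notch_widths:
                kwargs["notch_widths"] = tuple(self.notch_widths)
        if self.experiment == 4:
            if self.gap_widths:
                kwargs["gap_widths"] = tuple(self.gap_widths)
            if self.speeds:
                kwargs["speeds"] = tuple(self.speeds)
        if self.grid_interval:
            kwargs["interval"] = self.grid_interval
        return ExperimentConfig(**kwargs).conditions()

    def config_hash(self) -> str:
        canonical = json.dumps(self.model_dump(), sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()[:16]


def load_config(path) -> RunConfig:
    """Load and validate a JSON run configuration."""
    with open(path) as fh:
        data = json.load(fh)
    return RunConfig.model_validate(data)


def save_config(config: RunConfig, path) -> None:
    Path(path).write_text(json.dumps(config.model_dump(), indent=1))
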