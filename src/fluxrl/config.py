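"""Run configuration schema and presets.

A :class:`RunConfig` fully determines a run (environment, grid,
uncertainty level, objective, training and evaluation settings, master
seed), is validated before any computation, and is written back next to
the outputs so every artifact is regenerable from the resolved config
plus the seed alone.

Two shipped presets mirror the reference training setups of the case
studies: ``fatty_acid_paper`` (terminal-titer objective, 25 x 1 h
inputs, 350 epochs x 500 episodes at learning rate 0.0075) and
``lactate_paper`` (golden-batch tracking, 11 inputs over 9.5 h, 500
epochs x 500 episodes at 0.001).
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path
from typing import Literal, Optional

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, model_validator

from . import benchmark as bm
from .episodes import ControlGrid, RandomizationSpec
from .kinetics import KineticModel, get_model
from .objectives import ObjectiveSpec
from .training import TrainingConfig

__all__ = ["RunConfig", "ConfigError", "load_config", "load_preset", "PRESETS"]

PRESETS = ("fatty_acid_paper", "lactate_paper")


class ConfigError(ValueError):
    """Invalid run configuration."""


class GridSection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    t_end: float
    n_intervals: int
    t0: float = 0.0


class ObjectiveSection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    kind: Literal["terminal_titer", "reference_tracking"] = "terminal_titer"
    # bang-bang switch step of the golden-batch construction; None = optimize
    switch_step: Optional[int] = None
    tracked_state: str = "E"


class TrainingSection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    learning_rate: float
    epochs: int
    episodes_per_epoch: int
    patience: int = 50
    eps_mach: float = 1e-8
    optimizer: str = "adam"


class EvaluationSection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_episodes: int = 500
    deterministic_actions: bool = False


class PolicySection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    constant_input: Optional[float] = None
    checkpoint: Optional[str] = None


class RunConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    environment: Literal["fatty_acid", "lactate"]
    grid: GridSection
    level: float = 0.0
    objective: ObjectiveSection = ObjectiveSection()
    training: Optional[TrainingSection] = None
    evaluation: EvaluationSection = EvaluationSection()
    policy: PolicySection = PolicySection()
    seed: int = 0
    outdir: Optional[str] = None

    @model_validator(mode="after")
    def _check(self) -> "RunConfig":
        if self.level < 0:
            raise ValueError("uncertainty level must be non-negative")
        return self

    # -- builders -----------------------------------------------------------

    def build_model(self) -> KineticModel:
        return get_model(self.environment)

    def build_grid(self) -> ControlGrid:
        return ControlGrid(
            t_end=self.grid.t_end, n_intervals=self.grid.n_intervals, t0=self.grid.t0
        )

    def build_spec(self) -> RandomizationSpec:
        return RandomizationSpec(self.level)

    def build_objective(self, model: KineticModel, grid: ControlGrid) -> ObjectiveSpec:
        if self.objective.kind == "terminal_titer":
            return ObjectiveSpec("terminal_titer")
        ref, _sw = bm.build_golden_batch_reference(
            model, grid, self.objective.switch_step, self.objective.tracked_state
        )
        return ObjectiveSpec(
            "reference_tracking", reference=ref, tracked_state=self.objective.tracked_state
        )

    def build_training(self) -> TrainingConfig:
        if self.training is None:
            raise ConfigError("this command needs a 'training' config section")
        t = self.training
        return TrainingConfig(
            learning_rate=t.learning_rate,
            epochs=t.epochs,
            episodes_per_epoch=t.episodes_per_epoch,
            patience=t.patience,
            eps_mach=t.eps_mach,
            seed=self.seed,
            optimizer=t.optimizer,
        )

    def dump_yaml(self, path: Path) -> None:
        path.write_text(yaml.safe_dump(self.model_dump(), sort_keys=False))


def load_preset(name: str) -> dict:
    if name not in PRESETS:
        raise ConfigError(f"unknown preset {name!r}; available: {PRESETS}")
    ref = resources.files("fluxrl.data").joinpath(f"preset_{name}.yaml")
    with ref.open("r") as fh:
        return yaml.safe_load(fh)


def load_config(
    path: str | Path | None = None,
    preset: str | None = None,
    overrides: dict | None = None,
) -> RunConfig:
    """Assemble a validated RunConfig from a preset and/or YAML file plus overrides."""
    doc: dict = {}
    if preset is not None:
        doc.update(load_preset(preset))
    if path is not None:
        loaded = yaml.safe_load(Path(path).read_text())
        if not isinstance(loaded, dict):
            raise ConfigError(f"config file {path} does not hold a mapping")
        doc.update(loaded)
    # dotted override keys (e.g. "training.epochs") patch nested sections
    for key, value in (overrides or {}).items():
        if value is None:
            continue
        parts = key.split(".")
        section = doc
        for part in parts[:-1]:
            section = section.setdefault(part, {})
        section[parts[-1]] = value
    if not doc:
        raise ConfigError("no configuration given: pass --config and/or --preset")
    try:
        return RunConfig(**doc)
    except Exception as exc:  # pydantic ValidationError and friends
        raise ConfigError(str(exc)) from exc
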