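"""Run configuration: every tunable of the pipeline in one serializable block.

A :class:`RunConfig` bundles the task constants, the simulated agent's exit
policy, the neural- and photometry-generator parameters, and the detector
settings, and round-trips losslessly through YAML so a whole benchmark run is
reproducible from a single file plus a seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .photometry import PhotometryTrace  # noqa: F401  (re-export convenience)
from .step_detection import StepDetectionConfig
from .synthetic_data import ExitPolicy, PhotometryGenParams
from .task_model import TaskConfig

__all__ = ["RunConfig", "load_config", "save_config", "default_config"]


@dataclass(frozen=True)
class PopulationParams:
    """Synthetic neural population layout."""

    n_units: int = 16
    fraction_on_off: float = 0.25
    rate_low: float = 5.0
    rate_high: float = 20.0
    delay_min: float = 0.05
    delay_max: float = 0.95
    delay_jitter_sd: float = 0.05
    participation: float = 0.9


@dataclass(frozen=True)
class RunConfig:
    """Everything a benchmark run needs besides the seed itself."""

    task: TaskConfig = field(default_factory=TaskConfig)
    policy: ExitPolicy = field(default_factory=ExitPolicy)
    population: PopulationParams = field(default_factory=PopulationParams)
    photometry: PhotometryGenParams = field(default_factory=PhotometryGenParams)
    steps: StepDetectionConfig = field(default_factory=StepDetectionConfig)
    n_sessions: int = 20
    min_step_units: int = 6
    svm_bin: float = 0.01
    svm_leave_window: float = 5.0
    hazard_bin: float = 0.25
    seed: int = 1


def default_config() -> RunConfig:
    return RunConfig()


_SECTIONS = {
    "task": TaskConfig,
    "policy": ExitPolicy,
    "population": PopulationParams,
    "photometry": PhotometryGenParams,
    "steps": StepDetectionConfig,
}


def save_config(config: RunConfig, path) -> None:
    data = dataclasses.asdict(config)
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


def load_config(path) -> RunConfig:
    data = yaml.safe_load(Path(path).read_text()) or {}
    kwargs = {}
    for key, cls in _SECTIONS.items():
        if key in data:
            kwargs[key] = cls(**data.pop(key))
    kwargs.update(data)
    return RunConfig(**kwargs)
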