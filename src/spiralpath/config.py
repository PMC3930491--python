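"""Run configuration: schema-validated YAML/JSON settings for the full
pipeline, with the simulation defaults baked in.

A fully-defaulted (even empty) config file reproduces the default
experiments.  Unknown keys are rejected with field-path diagnostics.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from .camera import CameraModel
from .mstd import LESION_POOLS, ModelParams, TemplateBankConfig
from .mt import PoolingParams
from .stimulus import TargetSpec

__all__ = ["RunConfig", "ConfigError", "load_config", "save_config", "config_hash"]


class ConfigError(ValueError):
    """Invalid or malformed run configuration."""


class _Section(BaseModel):
    model_config = ConfigDict(extra="forbid", frozen=True)


class CameraConfig(_Section):
    focal_length: float = 1.0
    fov_h: float = 110.0
    fov_v: float = 94.0
    frame_rate: float = 20.0

    def build(self) -> CameraModel:
        return CameraModel(**self.model_dump())


class SceneConfig(_Section):
    kind: str = "ground_plane"
    n_dots: int = Field(default=200, ge=1)
    depth_near: float = 1.4
    depth_far: float = 25.0
    eye_height: float = 1.6


class TrajectoryConfig(_Section):
    frames: int = Field(default=60, ge=1)
    radii: tuple[float, ...] = (12.0, 16.0, 20.0)
    direction: int = 1
    # Path rotation rate in deg/s; the default traverses well under a
    # quarter circle in a 60-frame trial.
    omega_deg: float = 26.7
    on_path_distance: float = 12.0
    lateral_offset_deg: float = 15.0

    def target_spec(self) -> TargetSpec:
        return TargetSpec(self.on_path_distance, self.lateral_offset_deg)


class PoolingConfig(_Section):
    kernel_sigma: float = 3.0
    kernel_radius: float = 9.0

    def build(self) -> PoolingParams:
        return PoolingParams(**self.model_dump())


class BankConfig(_Section):
    n_pattern: int = Field(default=23, ge=1)
    n_x: int = Field(default=25, ge=1)
    n_y: int = Field(default=20, ge=1)
    span_factor: float = 1.5

    def build(self) -> TemplateBankConfig:
        return TemplateBankConfig(**self.model_dump())


class ModelConfig(_Section):
    A: float = 1.0
    D: float = 3.25
    U: float = 1.0
    W: float = 2.5
    gamma: float = 0.01
    beta: float = 0.07
    sigma_d: float = 12.0
    gain: float = 1.0
    dt: float = 0.005
    lesions: tuple[str, ...] = ()

    def build(self) -> ModelParams:
        for name in self.lesions:
            if name not in LESION_POOLS:
                raise ConfigError(f"model.lesions: unknown pool {name!r}")
        return ModelParams(**self.model_dump())


class ExperimentConfig(_Section):
    reps: int = Field(default=20, ge=1)
    rotation_rates_deg: tuple[float, ...] = (-5.0, -4.0, -3.0, -2.0, -1.0, 0.0,
                                             1.0, 2.0, 3.0, 4.0, 5.0)
    sled_rates_deg: tuple[float, ...] = (2.0, 4.0, 8.0, 16.0, 32.0, 64.0)
    dot_counts: tuple[int, ...] = (25, 50, 100, 200, 400)


class RunConfig(_Section):
    camera: CameraConfig = CameraConfig()
    scene: SceneConfig = SceneConfig()
    trajectory: TrajectoryConfig = TrajectoryConfig()
    pooling: PoolingConfig = PoolingConfig()
    bank: BankConfig = BankConfig()
    model: ModelConfig = ModelConfig()
    experiment: ExperimentConfig = ExperimentConfig()
    seed: int = 0
    out_dir: str = "results"
    log_level: str = "INFO"


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML or JSON run configuration.

    An empty file yields the full defaults; unknown keys raise
    :class:`ConfigError` with the offending field path.
    """
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(p)
    text = p.read_text()
    data = yaml.safe_load(text) if text.strip() else {}
    if data is None:
        data = {}
    try:
        return RunConfig.model_validate(data)
    except ValidationError as exc:
        locs = "; ".join(
            ".".join(str(x) for x in err["loc"]) + ": " + err["msg"]
            for err in exc.errors()
        )
        raise ConfigError(f"invalid config {p}: {locs}") from exc


def save_config(config: RunConfig, path: str | Path) -> None:
    p = Path(path)
    data = json.loads(config.model_dump_json())
    if p.suffix in (".yaml", ".yml"):
        p.write_text(yaml.safe_dump(data, sort_keys=False))
    else:
        p.write_text(json.dumps(data, indent=2))


def config_hash(config: RunConfig) -> str:
    """Stable short hash of the full configuration (for run logging)."""
    return hashlib.sha256(config.model_dump_json().encode()).hexdigest()[:12]
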