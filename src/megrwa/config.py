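"""Validated run configuration (YAML-backed pydantic models).

Defaults mirror the emulated study parameters: 1-80 Hz band-pass with a
50 Hz notch, 400 Hz resampling, epochs -0.5 to 1 s, searchlight k = 10
sensors / r = 10 samples, 100,000 permutations, alpha = 0.05 one-tailed,
50-ms display bins.
"""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, Field, model_validator


class StimulusConfig(BaseModel):
    n_categories: int = Field(6, ge=1)
    n_per_category: int = Field(5, ge=1)
    image_size: int = Field(128, ge=32)
    jitter: float = Field(0.15, ge=0.0)
    collinear: bool = True


class ModelConfig(BaseModel):
    gist_scales: int = Field(4, ge=1)
    gist_orientations: int = Field(8, ge=1)
    gist_grid: int = Field(4, ge=1)
    gist_normalize: str = "zscore"
    gist_prefilter: bool = True
    shape_radius_weight: float = Field(1.0, ge=0.0)
    shape_branch_penalty: float = Field(0.05, ge=0.0)


class SimulationConfig(BaseModel):
    n_subjects: int = Field(8, ge=2)
    n_sensors: int = Field(30, ge=2)
    n_trials_per_stimulus: int = Field(24, ge=1)
    noise_sd: float = Field(1.0, ge=0.0)
    sfreq: float = Field(400.0, gt=0)
    epoch_window: tuple[float, float] = (-0.5, 1.0)
    plant_weights: tuple[float, float, float] = (0.5, 0.3, 0.2)
    plant_window: tuple[float, float] = (0.1, 0.15)
    plant_n_sensors: int = Field(10, ge=1)

    @model_validator(mode="after")
    def _windows(self):
        if self.epoch_window[1] <= self.epoch_window[0]:
            raise ValueError("epoch window must have positive length")
        if not (
            self.epoch_window[0] <= self.plant_window[0] < self.plant_window[1] <= self.epoch_window[1]
        ):
            raise ValueError("plant window must lie inside the epoch window")
        return self


class SearchlightConfig(BaseModel):
    k: int = Field(10, ge=1)
    r: int = Field(10, ge=0)
    adjacency_neighbors: int = Field(4, ge=1)


class RWAConfig(BaseModel):
    orthogonalization: str = "johnson"
    rank_transform: bool = False
    baseline: str = "null_mean"  # or "none"
    n_null: int = Field(100, ge=20)

    @model_validator(mode="after")
    def _check(self):
        if self.orthogonalization not in ("johnson", "pca"):
            raise ValueError("orthogonalization must be 'johnson' or 'pca'")
        if self.baseline not in ("null_mean", "none"):
            raise ValueError("baseline must be 'null_mean' or 'none'")
        return self


class StatsConfig(BaseModel):
    n_permutations: int = Field(100_000, ge=2)
    alpha: float = Field(0.05, gt=0, lt=1)
    tfce_E: float = 0.5
    tfce_H: float = 2.0
    tfce_steps: int = Field(100, ge=2)
    bin_ms: float = Field(50.0, gt=0)


class RunConfig(BaseModel):
    """Full configuration of an end-to-end run."""

    seed: int = 0
    stimuli: StimulusConfig = StimulusConfig()
    models: ModelConfig = ModelConfig()
    simulation: SimulationConfig = SimulationConfig()
    searchlight: SearchlightConfig = SearchlightConfig()
    rwa: RWAConfig = RWAConfig()
    stats: StatsConfig = StatsConfig()

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.model_validate(yaml.safe_load(Path(path).read_text()) or {})

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.model_dump(mode="json")))
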