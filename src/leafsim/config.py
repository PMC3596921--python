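"""Pipeline configuration: one JSON document drives the whole run."""
from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

from pydantic import BaseModel, Field, model_validator


class OutlineSource(BaseModel):
    """Either a key-point file or a synthetic outline recipe."""

    file: Optional[Path] = None
    recipe: Optional[dict] = None

    @model_validator(mode="after")
    def _one_of(self):
        if (self.file is None) == (self.recipe is None):
            raise ValueError("outline needs exactly one of 'file' or 'recipe'")
        return self


class MaskSource(BaseModel):
    """Either a grayscale image file or a synthetic mask recipe."""

    file: Optional[Path] = None
    recipe: Optional[dict] = None

    @model_validator(mode="after")
    def _one_of(self):
        if (self.file is None) == (self.recipe is None):
            raise ValueError("mask needs exactly one of 'file' or 'recipe'")
        return self


class MeshingBlock(BaseModel):
    n_boundary: int = Field(64, ge=4)
    iterations: int = Field(160, ge=0)
    target_edge: Optional[float] = Field(None, gt=0)


class DeformationBlock(BaseModel):
    dt: float = Field(0.005, gt=0)
    tau_c: float = Field(0.1, ge=0)
    stiffness: float = Field(50.0, gt=0)
    damping: float = Field(0.1, ge=0)
    gravity: float = Field(1.0, ge=0)  # magnitude of the downward field force
    n_constraint_passes: int = Field(3, ge=1)
    n_steps: int = Field(200, ge=0)
    snapshot_every: int = Field(50, ge=1)
    petiole: Optional[tuple[float, float]] = None
    anchor_radius: float = Field(0.0, ge=0)


class ScheduleEpoch(BaseModel):
    temperature: float = Field(..., ge=0, le=1)
    humidness: float = Field(..., ge=0, le=1)
    duration: float = Field(..., gt=0)


class SeasonsBlock(BaseModel):
    spec_file: Optional[Path] = None
    n_states: int = Field(4, ge=2)  # used when spec_file is absent
    schedule: list[ScheduleEpoch] = Field(default_factory=list)
    population: int = Field(1000, ge=1)


class PipelineConfig(BaseModel):
    """Everything a full contour -> mesh -> deform -> season run needs."""

    outline: OutlineSource
    mask: MaskSource
    meshing: MeshingBlock = Field(default_factory=MeshingBlock)
    deformation: DeformationBlock = Field(default_factory=DeformationBlock)
    seasons: SeasonsBlock = Field(default_factory=SeasonsBlock)
    seed: int = 0
    output_dir: Path = Path("leafsim_out")

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.model_validate(json.load(fh))
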