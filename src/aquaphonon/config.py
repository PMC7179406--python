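"""Run configuration: a validated YAML-loadable bundle of every tunable.

Unknown keys are rejected so that typos in a config file fail loudly.
"""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .constants import AMU, CELL_LENGTH_M, M1_H2_U, M2_O_U, PhysicalConstants


class RunConfig(BaseModel):
    """All knobs of the pipeline with their defaults."""

    model_config = ConfigDict(extra="forbid")

    # constants
    constants_mode: str = Field("paper", pattern="^(paper|exact)$")
    # masses in atomic mass units
    m1_u: float = Field(M1_H2_U, gt=0)
    m2_u: float = Field(M2_O_U, gt=0)
    cell_length_m: float = Field(CELL_LENGTH_M, gt=0)
    # spectral peak picking / assignment
    min_prominence: float = Field(0.02, gt=0, lt=1)
    smoothing_window: int = Field(1, ge=1)
    intermolecular_window_cm1: tuple[float, float] = (50.0, 400.0)
    oh_stretch_window_cm1: tuple[float, float] = (2800.0, 3800.0)
    # NEGF
    eta_scale: float = Field(1e-8, gt=0)  # eta = eta_scale * omega_p^2
    interface_spring: str = Field("device", pattern="^(device|reservoir|mean)$")
    # quadrature
    quad_rtol: float = Field(1e-8, gt=0)
    quad_atol: float = Field(1e-15, gt=0)
    omega_margin: float = Field(0.05, ge=0)
    # misc
    seed: int = 0

    @model_validator(mode="after")
    def _check_windows(self) -> "RunConfig":
        for w in (self.intermolecular_window_cm1, self.oh_stretch_window_cm1):
            if not w[0] < w[1]:
                raise ValueError(f"window {w} must be (low, high) with low < high")
        if self.smoothing_window % 2 == 0:
            raise ValueError("smoothing_window must be odd")
        return self

    def constants(self) -> PhysicalConstants:
        return (
            PhysicalConstants.paper()
            if self.constants_mode == "paper"
            else PhysicalConstants.codata()
        )

    @property
    def M1_kg(self) -> float:
        return self.m1_u * AMU

    @property
    def M2_kg(self) -> float:
        return self.m2_u * AMU

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)
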