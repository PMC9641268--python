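"""Schema-validated run configuration (JSON-compatible, unknown keys rejected).

A single structured file drives both simulation and reconstruction; every
default is explicit in the resolved echo so a run can be reproduced from
its own output.
"""

from __future__ import annotations

import json
import math
from pathlib import Path

from pydantic import BaseModel, ConfigDict, Field, field_validator

from .diffusion import MediumPair, OpticalProperties
from .phantom import AcquisitionConfig, CameraModel, PhantomSpec, TargetSpec

__all__ = ["RunConfig", "load_config"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class OpticalPropertiesConfig(_Strict):
    mu_a: float = Field(gt=0, description="absorption coefficient, mm^-1")
    mu_s_prime: float = Field(gt=0, description="reduced scattering coefficient, mm^-1")
    n_rel: float = Field(default=1.33, ge=1.0)

    def build(self) -> OpticalProperties:
        return OpticalProperties(mu_a=self.mu_a, mu_s_prime=self.mu_s_prime, n_rel=self.n_rel)


class MediumConfig(_Strict):
    ex: OpticalPropertiesConfig = OpticalPropertiesConfig(mu_a=0.004, mu_s_prime=0.8)
    em: OpticalPropertiesConfig = OpticalPropertiesConfig(mu_a=0.006, mu_s_prime=0.76)

    def build(self) -> MediumPair:
        return MediumPair(ex=self.ex.build(), em=self.em.build())


class TargetConfig(_Strict):
    center: tuple[float, float]
    width: float = 10.0
    height: float = 10.0
    z_top: float = Field(default=2.0, ge=0)
    thickness: float = Field(default=0.0, ge=0)
    concentration: float = Field(default=1.0, gt=0)
    shape: str = "rect"

    def build(self) -> TargetSpec:
        return TargetSpec(**self.model_dump())


class PhantomConfig(_Strict):
    targets: list[TargetConfig] = Field(default_factory=list)
    epsilon: float = 1.0
    eta: float = 1.0
    background: float = Field(default=0.0, ge=0)

    def build(self, medium: MediumPair) -> PhantomSpec:
        return PhantomSpec(
            targets=tuple(t.build() for t in self.targets),
            medium=medium,
            epsilon=self.epsilon,
            eta=self.eta,
            background=self.background,
        )


class AcquisitionSettings(_Strict):
    f_min: float = Field(default=0.0, ge=0)
    f_max: float = Field(default=0.15, gt=0)
    n_frequencies: int = Field(default=31, ge=2)
    phases: list[float] = Field(
        default_factory=lambda: [0.0, 2.0 * math.pi / 3.0, 4.0 * math.pi / 3.0]
    )
    field_of_view: tuple[float, float] = (100.0, 100.0)
    grid: tuple[int, int] = (256, 256)
    S0: float = 1.0
    frequency_scale: float = 1.0

    def build(self) -> AcquisitionConfig:
        import numpy as np

        return AcquisitionConfig(
            frequencies=tuple(np.linspace(self.f_min, self.f_max, self.n_frequencies)),
            phases=tuple(self.phases),
            field_of_view=self.field_of_view,
            grid=self.grid,
            S0=self.S0,
            frequency_scale=self.frequency_scale,
        )


class CameraConfig(_Strict):
    bit_depth: int = 12
    full_scale: int = 4095
    target_peak: float = 4000.0
    shot_noise: bool = True
    read_noise_sd: float = Field(default=2.0, ge=0)
    quantize: bool = True

    def build(self) -> CameraModel:
        return CameraModel(**self.model_dump())


class AnalysisConfig(_Strict):
    sigma_min: float = Field(default=0.01, gt=0)
    sigma_max: float = Field(default=5.0, gt=0)
    sigma_step: float = Field(default=0.01, gt=0)
    true_area_mm2: float = Field(default=100.0, gt=0)
    segmentation: bool = True
    convention: str = "consistent"
    taper_fraction: float = Field(default=0.1, ge=0, le=0.5)
    calibrate_frequencies: bool = True

    @field_validator("convention")
    @classmethod
    def _known_convention(cls, v: str) -> str:
        if v not in ("consistent", "literal"):
            raise ValueError(f"unknown demodulation convention {v!r}")
        return v

    def sigma_grid(self):
        import numpy as np

        return np.round(
            np.arange(self.sigma_min, self.sigma_max + 1e-12, self.sigma_step), 10
        )


class RunConfig(_Strict):
    """Everything one run needs: geometry, camera, medium, phantom, analysis."""

    acquisition: AcquisitionSettings = AcquisitionSettings()
    camera: CameraConfig = CameraConfig()
    medium: MediumConfig = MediumConfig()
    phantom: PhantomConfig = PhantomConfig()
    analysis: AnalysisConfig = AnalysisConfig()
    seed: int = 0

    def resolved_json(self) -> str:
        return json.dumps(self.model_dump(), indent=1, sort_keys=True)


def load_config(path: str | Path) -> RunConfig:
    """Parse and validate a JSON run configuration file."""
    return RunConfig.model_validate(json.loads(Path(path).read_text()))
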