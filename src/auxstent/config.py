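"""Validated run configuration (YAML-backed, schema-checked)."""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid", frozen=True)


class DesignConfig(_Strict):
    """Micro design grid, CSRBF layout and initial hole pattern."""

    nx: int = Field(40, ge=4, description="design-grid elements per cell side")
    support_cells: float = Field(3.0, gt=1.0)
    smoothing_cells: float = Field(2.0, gt=0.0)
    alpha_bound: float = Field(1e3, gt=0.0)
    holes_nx: int = Field(4, ge=0)
    holes_ny: int = Field(4, ge=0)
    hole_radius: float = Field(0.06, ge=0.0, lt=0.5)


class MaterialConfig(_Strict):
    E: float = Field(1.0, gt=0.0)
    nu: float = Field(0.3, gt=-1.0, lt=0.5)
    ersatz: float = Field(1e-4, gt=0.0, le=1e-3)


class FlowConfig(_Strict):
    mu: float = Field(1.0, gt=0.0)
    rho: float = Field(1.0, gt=0.0)
    inlet_speed: float = Field(1.0, gt=0.0)
    k_solid: float = Field(1e-5, gt=0.0, le=1e-4)
    stab_const: float = Field(0.02, gt=0.0)
    resolution: int = Field(8, ge=4, description="flow elements per unit length")
    inlet_length: float = Field(1.0, gt=0.0)
    outlet_length: float = Field(1.0, gt=0.0)
    stent_thickness: float = Field(0.25, gt=0.0)
    top_thickness: float = Field(0.25, gt=0.0)


class MacroConfig(_Strict):
    nx: int = Field(20, ge=1)
    ny: int = Field(20, ge=1)
    stretch: float = Field(1.0)


class WeightsConfig(_Strict):
    w1: float = Field(0.35, ge=0.0, description="auxetic objective weight")
    w2: float = Field(0.35, ge=0.0, description="MFP objective weight")
    w3: float = Field(0.30, ge=0.0, description="macro compliance weight")

    @model_validator(mode="after")
    def _positive_sum(self):
        if self.w1 + self.w2 + self.w3 <= 0:
            raise ValueError("weights must have positive sum")
        return self


class OptimizationConfig(_Strict):
    volume_max: float = Field(0.30, gt=0.0, le=1.0)
    max_iter: int = Field(150, ge=1)
    tol: float = Field(1e-3, gt=0.0)
    tol_window: int = Field(5, ge=1)
    volume_gain_p: float = Field(
        40.0, gt=0.0, description="proportional gain of the volume controller"
    )
    volume_gain_i: float = Field(
        5.0, gt=0.0, description="integral (multiplier) gain of the volume controller"
    )
    step_cells: float = Field(1.0, gt=0.0, description="max interface motion per iteration, in design cells")
    max_halvings: int = Field(8, ge=0)
    constraint_force_cap: float = Field(
        50.0, gt=0.0, description="cap on the normalized volume-constraint force (prevents multiplier windup)"
    )
    volume_step_cap: float = Field(
        0.04, gt=0.0, description="max volume-fraction change per iteration"
    )
    normalize_values: bool = True
    use_adjoint_mfp: bool = Field(
        True, description="use the adjoint-corrected MFP gradient instead of the frozen-velocity form"
    )
    checkpoint_every: int = Field(0, ge=0)


class Config(_Strict):
    """Top-level run configuration with validated defaults."""

    design: DesignConfig = DesignConfig()
    material: MaterialConfig = MaterialConfig()
    flow: FlowConfig = FlowConfig()
    macro: MacroConfig = MacroConfig()
    weights: WeightsConfig = WeightsConfig()
    optimization: OptimizationConfig = OptimizationConfig()
    seed: int = 0

    def dump(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.model_dump(), sort_keys=True))


def load_config(path: str | Path) -> Config:
    """Load and validate a YAML configuration; unknown keys are rejected."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    return Config.model_validate(raw)
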