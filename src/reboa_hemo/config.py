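"""Scenario and study configuration (YAML-backed, schema-validated).

The four simulated physiologic phases carry the study's boundary targets:

===========  ===========  ========  ==================
phase        CO (L/min)   HR (bpm)  supra P (mmHg)
===========  ===========  ========  ==================
baseline     6.5          114       93/62
hemorrhage   4.8          192       74/42
f_reboa      6.0          240       147/103
p_reboa      4.5          180       144/86
===========  ===========  ========  ==================

Clinical units at this surface; SI internally.  The balloon mode is tied
to the phase (full occlusion for ``f_reboa``, partial for ``p_reboa``,
none otherwise) and validated accordingly.
"""

from __future__ import annotations

import hashlib
import json
import yaml
from pydantic import BaseModel, Field, model_validator

from .geometry import AortaParams, BalloonMode, BalloonSpec
from .rheology import FluidProperties
from .solver import SolverSettings
from .waveforms import HemodynamicTargets, Phase, WaveformShape

__all__ = ["ScenarioConfig", "StudyConfig", "PHASE_DEFAULTS",
           "default_scenario", "load_scenario", "load_study"]

PHASE_DEFAULTS = {
    "baseline": dict(co_l_min=6.5, hr_bpm=114.0, systolic_mmhg=93.0,
                     diastolic_mmhg=62.0),
    "hemorrhage": dict(co_l_min=4.8, hr_bpm=192.0, systolic_mmhg=74.0,
                       diastolic_mmhg=42.0),
    "f_reboa": dict(co_l_min=6.0, hr_bpm=240.0, systolic_mmhg=147.0,
                    diastolic_mmhg=103.0),
    "p_reboa": dict(co_l_min=4.5, hr_bpm=180.0, systolic_mmhg=144.0,
                    diastolic_mmhg=86.0),
}

_PHASE_MODE = {"baseline": "none", "hemorrhage": "none",
               "f_reboa": "full", "p_reboa": "partial"}


class TargetsConfig(BaseModel):
    co_l_min: float = Field(ge=0)
    hr_bpm: float = Field(gt=0)
    map_mmhg: float | None = None
    systolic_mmhg: float | None = None
    diastolic_mmhg: float | None = None


class AortaConfig(BaseModel):
    ascending_diameter: float = AortaParams.ascending_diameter
    descending_diameter: float = AortaParams.descending_diameter
    arch_radius: float = AortaParams.arch_radius
    branch_diameters: tuple[float, float] = AortaParams.branch_diameters
    branch_positions: tuple[float, float] = AortaParams.branch_positions
    segment_lengths: tuple[float, float] = AortaParams.segment_lengths


class BalloonConfig(BaseModel):
    length: float = 0.105
    max_diameter: float = 0.0138
    center_station: float = 0.0825
    mode: str = "none"
    shape: str = "capsule"


class FluidConfig(BaseModel):
    density: float = 1060.0
    mu_inf: float = 0.0035
    mu_zero: float = 0.056
    lam: float = 3.313
    power_index: float = 0.368
    newtonian_override: float | None = None


class ShapeConfig(BaseModel):
    systolic_fraction: float = 0.35
    reverse_fraction: float = 0.10
    reverse_amplitude: float = 0.08
    decay_const: float = 3.0


class NumericsConfig(BaseModel):
    grid_spacing: float = 0.85e-3
    cfl: float = 0.4
    eta: float = 1e-8
    max_cycles: int = 8
    periodicity_tol: float = 1e-2
    n_snapshots: int = 40
    poisson: str = "direct"


class ScenarioConfig(BaseModel):
    phase: str
    targets: TargetsConfig | None = None
    aorta: AortaConfig = AortaConfig()
    balloon: BalloonConfig | None = None
    fluid: FluidConfig = FluidConfig()
    shape: ShapeConfig = ShapeConfig()
    numerics: NumericsConfig = NumericsConfig()
    # initial distal-outlet level relative to the supra-aortic waveform
    # (the calibration loop's starting point).  Default: slightly below the
    # supra level for an open aorta; during high-grade partial occlusion
    # the distal arterial pressure collapses to roughly a third of the
    # proximal MAP, hence the large default drop for p_reboa.
    distal_offset_mmhg: float | None = None
    seed: int = 0

    @model_validator(mode="after")
    def _fill_and_check(self):
        if self.phase not in PHASE_DEFAULTS:
            raise ValueError(f"unknown phase {self.phase!r}")
        if self.targets is None:
            self.targets = TargetsConfig(**PHASE_DEFAULTS[self.phase])
        required = _PHASE_MODE[self.phase]
        if self.balloon is None:
            self.balloon = BalloonConfig(mode=required)
        elif self.balloon.mode != required:
            raise ValueError(
                f"phase {self.phase!r} requires balloon mode {required!r}, "
                f"got {self.balloon.mode!r}")
        if self.distal_offset_mmhg is None:
            self.distal_offset_mmhg = -70.0 if self.phase == "p_reboa" else -2.0
        return self

    # -- bridges to the library objects -----------------------------------
    def aorta_params(self) -> AortaParams:
        return AortaParams(**self.aorta.model_dump())

    def balloon_spec(self) -> BalloonSpec:
        d = self.balloon.model_dump()
        d["mode"] = BalloonMode(d["mode"])
        return BalloonSpec(**d)

    def fluid_props(self) -> FluidProperties:
        return FluidProperties(**self.fluid.model_dump())

    def hemo_targets(self) -> HemodynamicTargets:
        return HemodynamicTargets(phase=Phase(self.phase),
                                  **self.targets.model_dump())

    def wave_shape(self) -> WaveformShape:
        return WaveformShape(**self.shape.model_dump())

    def solver_settings(self, **overrides) -> SolverSettings:
        base = dict(cfl=self.numerics.cfl, eta=self.numerics.eta,
                    max_cycles=self.numerics.max_cycles,
                    periodicity_tol=self.numerics.periodicity_tol,
                    n_snapshots=self.numerics.n_snapshots,
                    poisson=self.numerics.poisson)
        base.update(overrides)
        return SolverSettings(**base)

    def config_hash(self) -> str:
        blob = json.dumps(self.model_dump(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


class CohortConfig(BaseModel):
    group: str = "f_reboa"
    n_animals: int | None = None
    seed: int = 42
    n_cycles: int = 10
    beat_noise_cv: float = 0.03
    pressure_noise_mmhg: float = 1.0
    flow_noise_l_min: float = 0.05
    distal_fraction: float = 1.0


class StudyConfig(BaseModel):
    scenarios: dict[str, ScenarioConfig] | None = None
    cohort: CohortConfig = CohortConfig()
    calibrate: bool = True
    calibration_tol: float = 0.05
    seed: int = 0

    @model_validator(mode="after")
    def _fill(self):
        if self.scenarios is None:
            self.scenarios = {ph: ScenarioConfig(phase=ph) for ph in PHASE_DEFAULTS}
        for ph, sc in self.scenarios.items():
            if sc.phase != ph:
                raise ValueError(f"study key {ph!r} maps to scenario phase {sc.phase!r}")
        return self


def default_scenario(phase: str, **overrides) -> ScenarioConfig:
    return ScenarioConfig(phase=phase, **overrides)


def load_scenario(path) -> ScenarioConfig:
    with open(path) as fh:
        return ScenarioConfig(**yaml.safe_load(fh))


def load_study(path) -> StudyConfig:
    with open(path) as fh:
        return StudyConfig(**yaml.safe_load(fh))
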