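"""End-to-end validation computations.

Each function reconstructs one headline check of the model from scratch —
geometry occlusion ratio, rheology limits, boundary-condition calibration
against a synthetic reference, solver residuals, cohort statistics — and
returns plain numbers.  They are used by both the test suite and the
acceptance script.
"""

from __future__ import annotations

import warnings

import numpy as np

from .config import default_scenario
from .geometry import AortaParams, BalloonMode, BalloonSpec, build_aorta, \
    occlusion_fraction
from .pipeline import calibrate_scenario, run_scenario
from .rheology import FluidProperties, apparent_viscosity
from .solver import residual_report
from .synthetic import CohortSpec, draw_cohort, render_traces

__all__ = [
    "occlusion_fraction_default", "viscosity_zero_shear",
    "viscosity_infinite_shear", "baseline_calibration_max_error",
    "baseline_residual_max", "cohort_mean_map",
]


def occlusion_fraction_default(spacing: float = 0.25e-3):
    """Occlusion-of-diameter (%) of the stock balloon in the default
    p-REBOA geometry, measured on the discretized mask at the mid-plane."""
    spec = BalloonSpec(mode=BalloonMode.partial)
    geom = build_aorta(AortaParams(), spacing, balloon=spec)
    return occlusion_fraction(geom, spec), geom.nx * geom.ny


def viscosity_zero_shear(props: FluidProperties | None = None) -> float:
    return apparent_viscosity(0.0, props or FluidProperties())


def viscosity_infinite_shear(props: FluidProperties | None = None,
                             rate: float = 1e9) -> float:
    return apparent_viscosity(rate, props or FluidProperties())


def baseline_calibration_max_error(cohort_seed: int = 42, n_cycles: int = 10,
                                   tol: float = 0.05):
    """Calibrate the coarse-grid baseline against a synthetic reference.

    Returns (max relative error in %, iteration history): the larger of
    the two relative errors — cycle-mean descending-aorta flow and
    cycle-mean subclavian pressure — between the calibrated simulation
    and the reference recording.
    """
    spec = CohortSpec(group="f_reboa", phases=("baseline",), n_animals=1,
                      seed=cohort_seed)
    reference = render_traces(draw_cohort(spec), spec=spec,
                              n_cycles=n_cycles)[0]
    cfg = default_scenario("baseline")
    _, history, _ = calibrate_scenario(cfg, reference, tol=tol)
    last = history[-1]
    return 100.0 * max(last["rel_err_flow"], last["rel_err_pressure"]), history


def baseline_residual_max(max_cycles: int | None = None):
    """Max normalized residual of the final baseline cycle (coarse grid)."""
    cfg = default_scenario("baseline")
    if max_cycles is not None:
        cfg.numerics.max_cycles = max_cycles
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = run_scenario(cfg)
    return residual_report(res.run.records[-1]), res


def cohort_mean_map(n_animals: int = 10000, seed: int = 1,
                    group: str = "f_reboa", phase: str = "baseline") -> float:
    """Sample mean MAP (mmHg) of a synthetic cohort draw."""
    spec = CohortSpec(group=group, phases=(phase,), n_animals=n_animals,
                      seed=seed)
    draws = draw_cohort(spec)
    return float(np.mean([d.map_mmhg for d in draws]))
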