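"""Synthesis of pulsatile boundary-condition waveforms from clinical targets.

The in vivo waveform shapes exist only as recordings; here they are emulated
by a small parametric family:

* inlet flow — a half-sine systolic ejection over a systolic fraction ``s``
  of the cycle, an optional brief reverse-flow notch at valve closure, and
  zero diastolic flow.  The waveform is rescaled after shaping so its cycle
  mean equals the cardiac output exactly.
* outlet pressure — a half-cosine systolic rise to the systolic pressure
  followed by an exponential diastolic decay, periodic by construction,
  with exact systolic/diastolic extrema.

When only a mean arterial pressure (MAP) is available, systolic/diastolic
values are derived from the standard identity MAP = dia + PP/3 with pulse
pressure PP = MAP/2, and the waveform is then shifted so its time mean is
exactly the MAP.

``calibrate_distal_pressure`` reproduces the experimental practice of
iteratively prescribing the thoracic (distal) pressure outlet until the
simulated cycle-mean descending-aorta flow and subclavian pressure match a
reference recording.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from .units import M3S_PER_LMIN, PA_PER_MMHG, bpm_to_period_s

__all__ = [
    "Phase",
    "HemodynamicTargets",
    "WaveformShape",
    "Waveform",
    "make_inlet_flow",
    "make_outlet_pressure",
    "couple_supra_outlets",
    "calibrate_distal_pressure",
    "CalibrationError",
]


class Phase(str, Enum):
    baseline = "baseline"
    hemorrhage = "hemorrhage"
    f_reboa = "f_reboa"
    p_reboa = "p_reboa"


@dataclass(frozen=True)
class HemodynamicTargets:
    """Clinical targets for one physiologic phase (clinical units)."""

    co_l_min: float
    hr_bpm: float
    map_mmhg: float | None = None
    systolic_mmhg: float | None = None
    diastolic_mmhg: float | None = None
    phase: Phase = Phase.baseline

    def __post_init__(self):
        if self.co_l_min < 0:
            raise ValueError("cardiac output must be non-negative")
        if self.hr_bpm <= 0:
            raise ValueError("heart rate must be positive")
        s, d, m = self.systolic_mmhg, self.diastolic_mmhg, self.map_mmhg
        if s is not None and d is not None and d > s:
            raise ValueError("diastolic pressure exceeds systolic")
        if s is not None and d is not None and m is not None and not (d <= m <= s):
            raise ValueError("require systolic >= MAP >= diastolic")


@dataclass(frozen=True)
class WaveformShape:
    """Tunable shape parameters of the parametric waveform family."""

    systolic_fraction: float = 0.35   # fraction of the cycle spent ejecting
    reverse_fraction: float = 0.10    # width of the reverse-flow notch
    reverse_amplitude: float = 0.08   # notch depth relative to systolic peak
    decay_const: float = 3.0          # diastolic pressure decay (1/cycle)
    n_samples: int = 257              # samples per cycle incl. repeated endpoint

    def __post_init__(self):
        if not (0 < self.systolic_fraction < 1):
            raise ValueError("systolic fraction must lie in (0, 1)")
        if self.reverse_fraction < 0 or self.systolic_fraction + self.reverse_fraction >= 1:
            raise ValueError("reverse notch must fit inside the cycle")
        if self.reverse_amplitude < 0:
            raise ValueError("reverse amplitude must be non-negative")
        if self.decay_const <= 0:
            raise ValueError("decay constant must be positive")
        if self.n_samples < 16:
            raise ValueError("need at least 16 samples per cycle")


@dataclass
class Waveform:
    """One periodic cycle of a flow (m3/s) or pressure (Pa) trace.

    Samples cover [0, T] with the first value repeated at t = T.
    """

    period: float
    times: np.ndarray
    values: np.ndarray
    kind: str  # "flow" | "pressure"
    shape_params: WaveformShape = field(default_factory=WaveformShape)

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape or self.times.ndim != 1:
            raise ValueError("times and values must be matching 1-D arrays")
        if abs(self.times[-1] - self.period) > 1e-9 * self.period or self.times[0] != 0:
            raise ValueError("samples must span exactly one period")
        if abs(self.values[0] - self.values[-1]) > 1e-9 * (1 + abs(self.values[0])):
            raise ValueError("waveform must be periodic (first == last value)")

    def __call__(self, t):
        tau = np.mod(t, self.period)
        return np.interp(tau, self.times, self.values)

    def mean(self) -> float:
        return float(np.trapezoid(self.values, self.times) / self.period)

    def shifted(self, offset: float) -> "Waveform":
        return Waveform(self.period, self.times.copy(), self.values + offset,
                        self.kind, self.shape_params)

    def to_csv(self, path) -> None:
        import pandas as pd

        pd.DataFrame({"time_s": self.times, "value_SI": self.values}).to_csv(
            path, index=False)


def make_inlet_flow(targets: HemodynamicTargets,
                    shape: WaveformShape | None = None) -> Waveform:
    """Pulsatile ascending-aorta inflow with cycle mean exactly CO."""
    shape = shape or WaveformShape()
    period = bpm_to_period_s(targets.hr_bpm)
    tau = np.linspace(0.0, 1.0, shape.n_samples)
    s, rf, ra = shape.systolic_fraction, shape.reverse_fraction, shape.reverse_amplitude
    g = np.zeros_like(tau)
    sys_mask = tau < s
    g[sys_mask] = np.sin(np.pi * tau[sys_mask] / s)
    if rf > 0 and ra > 0:
        rev = (tau >= s) & (tau < s + rf)
        g[rev] = -ra * np.sin(np.pi * (tau[rev] - s) / rf)
    g[-1] = g[0]
    co_si = targets.co_l_min * M3S_PER_LMIN
    if co_si == 0.0:
        values = np.zeros_like(g)
    else:
        mean_g = np.trapezoid(g, tau)
        if mean_g <= 0:
            raise ValueError("waveform shape has non-positive mean; reduce reverse notch")
        values = g * (co_si / mean_g)
    return Waveform(period, tau * period, values, "flow", shape)


def make_outlet_pressure(targets: HemodynamicTargets,
                         shape: WaveformShape | None = None) -> Waveform:
    """Periodic outlet pressure with exact systolic max and diastolic min.

    With explicit systolic/diastolic targets those extrema are honored
    exactly; with only a MAP the waveform's time mean is pinned to the MAP.
    """
    shape = shape or WaveformShape()
    period = bpm_to_period_s(targets.hr_bpm)
    sys_p, dia_p = targets.systolic_mmhg, targets.diastolic_mmhg
    from_map = sys_p is None or dia_p is None
    if from_map:
        if targets.map_mmhg is None:
            raise ValueError("need systolic/diastolic pressures or a MAP")
        pp = 0.5 * targets.map_mmhg
        dia_p = targets.map_mmhg - pp / 3.0
        sys_p = dia_p + pp
    if dia_p > sys_p:
        raise ValueError("diastolic pressure exceeds systolic")

    tau = np.linspace(0.0, 1.0, shape.n_samples)
    sp, k = shape.systolic_fraction, shape.decay_const
    b0 = np.exp(-k * (1.0 - sp))
    base = np.where(
        tau <= sp,
        b0 + (1.0 - b0) * 0.5 * (1.0 - np.cos(np.pi * tau / np.maximum(sp, 1e-12))),
        np.exp(-k * (tau - sp)),
    )
    base[-1] = base[0]
    # normalize on the sampled grid so the extrema are met exactly
    norm = (base - base.min()) / (base.max() - base.min())
    values_mmhg = dia_p + (sys_p - dia_p) * norm
    if from_map:
        mean_now = np.trapezoid(values_mmhg, tau)
        values_mmhg = values_mmhg + (targets.map_mmhg - mean_now)
    return Waveform(period, tau * period, values_mmhg * PA_PER_MMHG, "pressure", shape)


def couple_supra_outlets(p: Waveform) -> tuple[Waveform, Waveform]:
    """Prescribe the same pressure at both supra-aortic outlets."""
    if p.kind != "pressure":
        raise ValueError("supra-aortic outlets take a pressure waveform")
    mk = lambda: Waveform(p.period, p.times.copy(), p.values.copy(), p.kind, p.shape_params)
    return mk(), mk()


class CalibrationError(RuntimeError):
    """Distal-outlet calibration failed; ``history`` holds the iterations."""

    def __init__(self, message, history=None):
        super().__init__(message)
        self.history = history or []


def calibrate_distal_pressure(scenario, reference, solver_handle, tol: float = 0.05,
                              max_iter: int = 12, damping: float = 0.8,
                              max_step_mmhg: float = 20.0):
    """Iteratively prescribe the thoracic pressure outlet to match a reference.

    Parameters
    ----------
    scenario
        Object with ``targets`` (HemodynamicTargets) and waveform ``shape``
        attributes; only the hemodynamic targets are consulted here.
    reference
        A synthetic recording; its cycle-mean descending-aorta flow (L/min)
        and subclavian pressure (mmHg) are the calibration targets.
    solver_handle
        Callable ``(distal_pressure_waveform) -> (q_mean_l_min, p_mean_mmhg)``
        returning the simulated cycle means at the flow-probe and
        subclavian-probe stations.
    tol
        Maximum tolerated relative error on either matched quantity.

    Returns
    -------
    (waveform, history) — the calibrated distal pressure waveform and the
    list of iteration records.

    The control variable is the mean level of the distal waveform only
    (shape held fixed).  Raising the distal mean pressure lowers the mean
    distal outflow, so the map is monotone; because each solver evaluation
    carries cycle-to-cycle noise, the update is a damped, step-capped
    linear regression over the whole iteration history rather than a
    two-point secant.
    """
    from .synthetic import reference_means

    ref = reference_means(reference)
    q_ref = ref["descending_flow_l_min"]["mean"]
    p_ref = ref["subclavian_pressure_mmhg"]["mean"]
    targets = scenario.targets
    shape = getattr(scenario, "shape", None) or WaveformShape()
    if q_ref > targets.co_l_min * (1.0 + tol):
        raise CalibrationError(
            f"reference mean flow {q_ref:.2f} L/min exceeds inlet CO "
            f"{targets.co_l_min:.2f} L/min; unreachable by mass conservation")

    base = make_outlet_pressure(targets, shape)
    history: list[dict] = []
    deltas: list[float] = []
    flows: list[float] = []
    delta = 0.0
    for it in range(max_iter):
        wf = base.shifted(delta * PA_PER_MMHG)
        q_sim, p_sim = solver_handle(wf)
        err_q = abs(q_sim - q_ref) / max(abs(q_ref), 1e-9)
        err_p = abs(p_sim - p_ref) / max(abs(p_ref), 1e-9)
        history.append({"iteration": it, "delta_mmhg": delta,
                        "q_sim_l_min": q_sim, "p_sim_mmhg": p_sim,
                        "rel_err_flow": err_q, "rel_err_pressure": err_p})
        if max(err_q, err_p) <= tol:
            return wf, history
        deltas.append(delta)
        flows.append(q_sim)
        # the flow response is monotone in the control but each evaluation
        # carries cycle-to-cycle noise: regress over the whole history
        # instead of a two-point secant
        d = np.asarray(deltas)
        q = np.asarray(flows)
        if len(d) >= 2 and np.ptp(d) > 1e-9:
            slope = float(np.sum((d - d.mean()) * (q - q.mean()))
                          / np.sum((d - d.mean()) ** 2))
            if slope < -1e-6:  # raising the level must lower the outflow
                target = deltas[-1] + (q_ref - q[-1]) / slope
                step = damping * (target - delta)
            else:
                step = 2.0 if q_sim > q_ref else -2.0
        else:
            step = 2.0 if q_sim > q_ref else -2.0
        step = float(np.clip(step, -max_step_mmhg, max_step_mmhg))
        delta = delta + step
    raise CalibrationError(
        f"calibration did not reach {tol:.0%} in {max_iter} iterations",
        history=history)
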