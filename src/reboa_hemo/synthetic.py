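"""Synthetic porcine hemodynamic recordings.

Stand-ins for the continuous pressure/flow instrumentation of a porcine
hemorrhage/REBOA study: per-animal cardiac output (CO), heart rate (HR)
and mean arterial pressure (MAP) are drawn from the group statistics of
the two experimental arms (full occlusion, n = 4; partial occlusion,
n = 6) across the three phases (baseline T0, end of hemorrhage T30,
occlusion T60), and periodic pressure/flow traces are rendered from the
parametric waveform family with beat-to-beat period jitter and additive
measurement noise.

The rendered descending-aorta flow trace is expressed as inlet-equivalent
flow (its noise-free cycle mean equals the animal's CO), mirroring the
experimental practice of scaling the distal flow waveform to the
Swan-Ganz cardiac output; ``distal_fraction`` rescales it when a true
distal fraction is wanted.  CO, HR and MAP are drawn independently (the
group tables report no covariances), from normal distributions truncated
at physiologic floors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .waveforms import (HemodynamicTargets, Phase, WaveformShape,
                        make_inlet_flow, make_outlet_pressure)
from .units import m3s_to_lmin, pa_to_mmhg

__all__ = [
    "GROUP_STATS", "CohortSpec", "AnimalDraw", "SyntheticRecording",
    "draw_cohort", "render_traces", "reference_means",
]

# group means +/- SD per phase: CO (L/min), HR (bpm), MAP (mmHg)
GROUP_STATS = {
    "f_reboa": {
        "baseline":   {"co": (6.9, 0.9), "hr": (126, 22), "map": (83, 7)},
        "hemorrhage": {"co": (4.7, 0.7), "hr": (176, 7), "map": (63, 7)},
        "occlusion":  {"co": (6.9, 0.9), "hr": (207, 17), "map": (136, 17)},
    },
    "p_reboa": {
        "baseline":   {"co": (6.1, 1.2), "hr": (128, 22), "map": (82, 5)},
        "hemorrhage": {"co": (3.8, 0.8), "hr": (177, 23), "map": (55, 7)},
        "occlusion":  {"co": (4.6, 1.4), "hr": (171, 33), "map": (114, 9)},
    },
}

GROUP_SIZES = {"f_reboa": 4, "p_reboa": 6}

# physiologic floors for the truncated draws
_FLOORS = {"co": 0.5, "hr": 40.0, "map": 20.0}


@dataclass(frozen=True)
class CohortSpec:
    """Which group/phases to draw, with noise and reproducibility knobs."""

    group: str = "f_reboa"                  # "f_reboa" | "p_reboa"
    phases: tuple[str, ...] = ("baseline", "hemorrhage", "occlusion")
    n_animals: int | None = None            # default: the group's actual size
    seed: int = 0
    beat_noise_cv: float = 0.03             # beat-to-beat period jitter
    pressure_noise_mmhg: float = 1.0        # additive measurement noise
    flow_noise_l_min: float = 0.05
    distal_fraction: float = 1.0            # flow trace scale relative to CO
    stats: dict = field(default_factory=lambda: GROUP_STATS)

    def __post_init__(self):
        if self.group not in self.stats:
            raise ValueError(f"unknown group {self.group!r}")
        for ph in self.phases:
            if ph not in self.stats[self.group]:
                raise ValueError(f"unknown phase {ph!r}")
        if self.n_animals is not None and self.n_animals < 1:
            raise ValueError("need at least one animal")
        if self.beat_noise_cv < 0 or self.pressure_noise_mmhg < 0 \
                or self.flow_noise_l_min < 0:
            raise ValueError("noise parameters must be non-negative")

    @property
    def size(self) -> int:
        return self.n_animals if self.n_animals is not None \
            else GROUP_SIZES[self.group]


@dataclass(frozen=True)
class AnimalDraw:
    animal_id: int
    group: str
    phase: str
    co_l_min: float
    hr_bpm: float
    map_mmhg: float


@dataclass
class SyntheticRecording:
    """Rendered traces for one animal in one phase.

    ``time_s`` is shared by the three traces; pressures in mmHg, flow in
    L/min (inlet-equivalent, see module docstring).
    """

    animal_id: int
    group: str
    phase: str
    draw: AnimalDraw
    time_s: np.ndarray
    subclavian_pressure_mmhg: np.ndarray
    femoral_pressure_mmhg: np.ndarray
    descending_flow_l_min: np.ndarray
    n_cycles: int
    seed: int
    cycle_edges_s: np.ndarray | None = None  # true beat boundaries

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({
            "time_s": self.time_s,
            "subclavian_pressure_mmhg": self.subclavian_pressure_mmhg,
            "femoral_pressure_mmhg": self.femoral_pressure_mmhg,
            "descending_flow_l_min": self.descending_flow_l_min,
        })


def _draw_truncated(rng, mean, sd, floor, size):
    vals = rng.normal(mean, sd, size)
    for _ in range(100):
        bad = vals <= floor
        if not bad.any():
            break
        vals[bad] = rng.normal(mean, sd, bad.sum())
    return np.maximum(vals, floor)


def draw_cohort(spec: CohortSpec) -> list[AnimalDraw]:
    """Per-animal CO/HR/MAP draws for every phase of a cohort specification.

    Reproducible under a fixed seed; draws are independent across animals
    and variables.
    """
    rng = np.random.default_rng(spec.seed)
    stats = spec.stats[spec.group]
    n = spec.size
    out = []
    for phase in spec.phases:
        st = stats[phase]
        co = _draw_truncated(rng, *st["co"], _FLOORS["co"], n)
        hr = _draw_truncated(rng, *st["hr"], _FLOORS["hr"], n)
        mp = _draw_truncated(rng, *st["map"], _FLOORS["map"], n)
        for a in range(n):
            out.append(AnimalDraw(animal_id=a, group=spec.group, phase=phase,
                                  co_l_min=float(co[a]), hr_bpm=float(hr[a]),
                                  map_mmhg=float(mp[a])))
    return out


def render_traces(draws, shape: WaveformShape | None = None,
                  spec: CohortSpec | None = None, n_cycles: int = 10,
                  seed: int | None = None, sample_rate_hz: float = 250.0,
                  ) -> list[SyntheticRecording]:
    """Render periodic pressure/flow traces for each animal draw.

    Beat-to-beat jitter rescales each cycle's period by ``1 + cv * eps``;
    measurement noise is additive white Gaussian.  In the occlusion phase
    of the full-occlusion group, the distal flow probe reads (noise
    around) zero.  Bit-reproducible for a fixed seed.
    """
    if n_cycles < 2:
        raise ValueError("need at least two cycles")
    spec = spec or CohortSpec()
    shape = shape or WaveformShape()
    rng = np.random.default_rng(spec.seed + 1 if seed is None else seed)
    out = []
    for d in draws:
        targets = HemodynamicTargets(co_l_min=d.co_l_min, hr_bpm=d.hr_bpm,
                                     map_mmhg=d.map_mmhg,
                                     phase=Phase.baseline)
        q_wf = make_inlet_flow(targets, shape)
        p_wf = make_outlet_pressure(targets, shape)
        occluded = d.phase == "occlusion" and d.group == "f_reboa"
        # femoral (distal) pressure: near-arterial at open aorta, low
        # distal to an occlusion
        fem_scale = 0.35 if d.phase == "occlusion" else 0.96
        T = q_wf.period
        eps = rng.normal(0.0, 1.0, n_cycles)
        periods = T * (1.0 + spec.beat_noise_cv * eps)
        periods = np.maximum(periods, 0.2 * T)
        t_edges = np.concatenate([[0.0], np.cumsum(periods)])
        t = np.arange(0.0, t_edges[-1], 1.0 / sample_rate_hz)
        cyc = np.searchsorted(t_edges, t, side="right") - 1
        cyc = np.clip(cyc, 0, n_cycles - 1)
        tau = (t - t_edges[cyc]) / periods[cyc] * T  # phase-warped time
        q = m3s_to_lmin(q_wf(tau)) * spec.distal_fraction
        if occluded:
            q = np.zeros_like(q)
        elif q.mean() != 0.0:
            # discrete sampling slightly biases the mean; pin it to the
            # drawn target so the noise-free trace reproduces CO exactly
            q *= (d.co_l_min * spec.distal_fraction) / q.mean()
        base = pa_to_mmhg(p_wf(tau))
        base += d.map_mmhg - base.mean()
        p_sub = base
        p_fem = base * fem_scale
        if spec.flow_noise_l_min > 0:
            q = q + rng.normal(0.0, spec.flow_noise_l_min, q.shape)
        if spec.pressure_noise_mmhg > 0:
            p_sub = p_sub + rng.normal(0.0, spec.pressure_noise_mmhg, p_sub.shape)
            p_fem = p_fem + rng.normal(0.0, spec.pressure_noise_mmhg, p_fem.shape)
        out.append(SyntheticRecording(
            animal_id=d.animal_id, group=d.group, phase=d.phase, draw=d,
            time_s=t, subclavian_pressure_mmhg=p_sub,
            femoral_pressure_mmhg=p_fem, descending_flow_l_min=q,
            n_cycles=n_cycles, seed=spec.seed if seed is None else seed,
            cycle_edges_s=t_edges))
    return out


def reference_means(rec: SyntheticRecording) -> dict:
    """Cycle-averaged targets with jackknife-over-cycles standard errors.

    Blocks follow the true beat boundaries when the recording carries
    them (equal time blocks otherwise); the jackknife SE quantifies the
    beat-to-beat variability of the mean.
    """
    n = rec.n_cycles
    if n < 2:
        raise ValueError("need at least two complete cycles")
    if rec.cycle_edges_s is not None:
        cyc = np.clip(np.searchsorted(rec.cycle_edges_s, rec.time_s,
                                      side="right") - 1, 0, n - 1)
    else:
        cyc = None
    out = {}
    for key, trace in (("subclavian_pressure_mmhg", rec.subclavian_pressure_mmhg),
                       ("femoral_pressure_mmhg", rec.femoral_pressure_mmhg),
                       ("descending_flow_l_min", rec.descending_flow_l_min)):
        if cyc is None:
            blocks = np.array_split(trace, n)
        else:
            blocks = [trace[cyc == k] for k in range(n) if np.any(cyc == k)]
        bm = np.array([b.mean() for b in blocks])
        mean = float(bm.mean())
        jk = np.array([np.delete(bm, i).mean() for i in range(n)])
        se = float(np.sqrt((n - 1) / n * np.sum((jk - jk.mean()) ** 2)))
        out[key] = {"mean": mean, "se": se}
    return out
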