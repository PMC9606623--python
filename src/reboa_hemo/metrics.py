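"""Wall shear metrics and cycle summaries.

Wall shear rate is the magnitude of the tangential-velocity gradient along
the inward wall normal, evaluated one-sidedly (second order) from the
velocity at one and two grid spacings inside the lumen; wall shear stress
is the apparent viscosity at the wall shear rate times the signed
gradient, the sign following the consistent tangent orientation of each
wall contour.  In this planar setting the wall shear stress "vector"
reduces to a signed tangential scalar, so the time-averaged magnitudes

    TAWSS = (1/T) int_0^T |wss| dt,      TAWSR = (1/T) int_0^T |wsr| dt,

and the oscillatory shear index

    OSI = 1/2 (1 - |int_0^T wss dt| / int_0^T |wss| dt)

are evaluated exactly as in the 3D definitions.  OSI is 0 for
unidirectional shear, 1/2 for fully reversing zero-mean shear, and is
defined as 0 (flagged) where the shear vanishes identically over the
cycle.  Regional aggregation is the arc-length-weighted mean over the
wall samples of each region.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import AorticGeometry, WALL_REGIONS
from .rheology import FluidProperties, apparent_viscosity
from .units import pa_to_mmhg, m3s_to_lmin

__all__ = [
    "WallMetricSeries", "CycleSummary", "wall_shear_series",
    "tawss", "tawsr", "osi", "extract_sys_dia", "summarize_scenario",
    "percent_change",
]


@dataclass
class WallMetricSeries:
    """Signed wall shear stress/rate at wall samples over one cycle.

    ``wss``/``wsr`` have shape (n_samples, n_times); ``times`` spans one
    period with the wrap-around instant repeated at the end.
    """

    x: np.ndarray
    y: np.ndarray
    region: np.ndarray
    times: np.ndarray
    wss: np.ndarray
    wsr: np.ndarray
    flagged: np.ndarray       # samples without adjacent fluid (kept, flagged)
    period: float

    def _check(self):
        dt = np.diff(self.times)
        if len(dt) < 2 or np.ptp(dt) > 1e-9 * self.period:
            raise ValueError("wall series requires uniform time samples")
        if abs((self.times[-1] - self.times[0]) - self.period) > 1e-6 * self.period:
            raise ValueError("wall series must span exactly one period")


def _bilinear_at(f, ii, jj):
    i0 = np.clip(np.floor(ii).astype(int), 0, f.shape[0] - 2)
    j0 = np.clip(np.floor(jj).astype(int), 0, f.shape[1] - 2)
    fx = np.clip(ii - i0, 0.0, 1.0)
    fy = np.clip(jj - j0, 0.0, 1.0)
    return ((1 - fx) * (1 - fy) * f[i0, j0] + fx * (1 - fy) * f[i0 + 1, j0]
            + (1 - fx) * fy * f[i0, j0 + 1] + fx * fy * f[i0 + 1, j0 + 1])


def wall_shear_series(snapshots: dict, geom: AorticGeometry,
                      props: FluidProperties) -> WallMetricSeries:
    """Evaluate signed wall shear stress/rate from stored cycle snapshots.

    Requires at least 20 stored instants per cycle.  For each wall sample,
    tangential velocity is interpolated at one and two spacings along the
    inward normal; the one-sided second-order derivative at the wall
    (no-slip: zero velocity) is ``(4 u1 - u2) / (2 h)``.
    """
    ws = geom.wall_samples
    if ws is None:
        raise ValueError("geometry carries no wall samples")
    times = np.asarray(snapshots["times"], dtype=float)
    if len(times) < 20:
        raise ValueError(f"need >= 20 instants per cycle, got {len(times)}")
    h = geom.spacing
    n_s = len(ws["x"])
    n_t = len(times)
    wss = np.empty((n_s, n_t))
    wsr = np.empty((n_s, n_t))

    p1x = ws["x"] + ws["normal_x"] * h
    p1y = ws["y"] + ws["normal_y"] * h
    p2x = ws["x"] + ws["normal_x"] * 2 * h
    p2y = ws["y"] + ws["normal_y"] * 2 * h
    ox, oy = geom.origin

    def interp_uv(u, v, px, py):
        # cell-centered velocity field, bilinear at arbitrary points
        uc = 0.5 * (u[:-1, :] + u[1:, :])
        vc = 0.5 * (v[:, :-1] + v[:, 1:])
        ii = (px - ox) / h - 0.5
        jj = (py - oy) / h - 0.5
        return _bilinear_at(uc, ii, jj), _bilinear_at(vc, ii, jj)

    # flag samples whose interior probe points leave the lumen (e.g. the
    # sealed mid-plane of a full occlusion, or port corners)
    ii2 = (p2x - ox) / h - 0.5
    jj2 = (p2y - oy) / h - 0.5
    in_lumen = _bilinear_at(geom.fluid.astype(float), ii2, jj2) > 0.5
    flagged = ~in_lumen

    tx, ty = ws["tangent_x"], ws["tangent_y"]
    for k in range(n_t):
        u, v = snapshots["u"][k], snapshots["v"][k]
        u1, v1 = interp_uv(u, v, p1x, p1y)
        u2, v2 = interp_uv(u, v, p2x, p2y)
        ut1 = u1 * tx + v1 * ty
        ut2 = u2 * tx + v2 * ty
        dudn = (4.0 * ut1 - ut2) / (2.0 * h)
        rate = np.abs(dudn)
        mu_w = apparent_viscosity(rate, props)
        wss[:, k] = mu_w * dudn
        wsr[:, k] = rate

    # close the cycle: repeat the first instant at t0 + T
    period = times[-1] - times[0] + (times[1] - times[0])
    times_c = np.concatenate([times - times[0], [period]])
    wss = np.concatenate([wss, wss[:, :1]], axis=1)
    wsr = np.concatenate([wsr, wsr[:, :1]], axis=1)
    return WallMetricSeries(
        x=ws["x"], y=ws["y"], region=ws["region"], times=times_c,
        wss=wss, wsr=wsr, flagged=flagged, period=period)


def tawss(series: WallMetricSeries) -> np.ndarray:
    """Time-averaged |WSS| (Pa) per wall sample, trapezoidal in time."""
    series._check()
    return np.trapezoid(np.abs(series.wss), series.times, axis=-1) / series.period


def tawsr(series: WallMetricSeries) -> np.ndarray:
    """Time-averaged |WSR| (1/s) per wall sample."""
    series._check()
    return np.trapezoid(np.abs(series.wsr), series.times, axis=-1) / series.period


def osi(series: WallMetricSeries, zero_tol: float = 1e-12):
    """Oscillatory shear index per wall sample, in [0, 1/2].

    Returns ``(osi, zero_flag)``: where the shear magnitude integral
    vanishes the index is defined as 0 and flagged.
    """
    series._check()
    num = np.abs(np.trapezoid(series.wss, series.times, axis=-1))
    den = np.trapezoid(np.abs(series.wss), series.times, axis=-1)
    zero = den <= zero_tol
    out = np.zeros_like(den)
    out[~zero] = 0.5 * (1.0 - num[~zero] / den[~zero])
    return out, zero


def extract_sys_dia(trace, times=None) -> tuple[float, float, float]:
    """(systolic, diastolic, mean) of a pressure trace over one cycle.

    Values are returned in the units of the trace; the mean is the time
    average (trapezoidal when ``times`` are supplied).
    """
    trace = np.asarray(trace, dtype=float)
    if trace.size == 0:
        raise ValueError("empty pressure trace")
    if times is not None:
        times = np.asarray(times, dtype=float)
        mean = float(np.trapezoid(trace, times) / (times[-1] - times[0]))
    else:
        mean = float(trace.mean())
    return float(trace.max()), float(trace.min()), mean


@dataclass
class CycleSummary:
    """Per-region wall shear indices and per-probe hemodynamics (clinical units)."""

    phase: str
    region_tawss: dict = field(default_factory=dict)   # Pa
    region_tawsr: dict = field(default_factory=dict)   # 1/s
    region_osi: dict = field(default_factory=dict)     # [0, 0.5]
    probe_pressure: dict = field(default_factory=dict)  # (sys, dia, mean) mmHg
    probe_velocity: dict = field(default_factory=dict)  # (peak, mean) m/s
    station_flow: dict = field(default_factory=dict)    # mean L/min
    outlet_flow: dict = field(default_factory=dict)     # mean L/min
    peak_tawss: float = 0.0
    not_applicable: list = field(default_factory=list)

    def to_dict(self):
        return {
            "phase": self.phase,
            "region_tawss_pa": self.region_tawss,
            "region_tawsr_per_s": self.region_tawsr,
            "region_osi": self.region_osi,
            "probe_pressure_mmhg": {k: dict(zip(("systolic", "diastolic", "mean"), v))
                                    for k, v in self.probe_pressure.items()},
            "probe_velocity_m_s": {k: dict(zip(("peak", "mean"), v))
                                   for k, v in self.probe_velocity.items()},
            "station_flow_l_min": self.station_flow,
            "outlet_flow_l_min": self.outlet_flow,
            "peak_tawss_pa": self.peak_tawss,
            "not_applicable": self.not_applicable,
        }


def summarize_scenario(run_result, phase: str = "baseline") -> CycleSummary:
    """Aggregate a completed periodic run into a :class:`CycleSummary`.

    Wall indices are arc-length-weighted (samples are equispaced in arc
    length, so a simple mean over each region's unflagged samples);
    regions without valid samples are marked not-applicable.
    """
    series = wall_shear_series(run_result.snapshots, run_result.geom,
                               run_result.props)
    ta_s = tawss(series)
    ta_r = tawsr(series)
    oi, _ = osi(series)
    summary = CycleSummary(phase=phase)
    ok = ~series.flagged
    for region in WALL_REGIONS:
        sel = (series.region == region) & ok
        if not np.any(sel):
            summary.not_applicable.append(region)
            continue
        summary.region_tawss[region] = float(ta_s[sel].mean())
        summary.region_tawsr[region] = float(ta_r[sel].mean())
        summary.region_osi[region] = float(oi[sel].mean())
    summary.peak_tawss = float(ta_s[ok].max()) if np.any(ok) else 0.0

    rec = run_result.records[-1]
    for st, trace in rec.probe_pressure.items():
        s, d, m = extract_sys_dia(pa_to_mmhg(trace), rec.phase_times)
        summary.probe_pressure[st] = (s, d, m)
    for st, trace in rec.probe_velocity.items():
        summary.probe_velocity[st] = (float(trace.max()), float(trace.mean()))
    for st, trace in rec.flux.items():
        summary.station_flow[st] = float(m3s_to_lmin(trace.mean()))
    for st, trace in rec.outlet_flux.items():
        summary.outlet_flow[st] = float(m3s_to_lmin(trace.mean()))
    return summary


def percent_change(a: float, b: float) -> float:
    """100 (a - b) / b — the change of ``a`` relative to reference ``b``."""
    if b == 0:
        return float("nan")
    return 100.0 * (a - b) / b
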