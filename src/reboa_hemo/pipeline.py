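"""Scenario and study drivers: geometry -> waveforms -> solve -> metrics.

``run_scenario`` executes one physiologic phase end to end and writes a
run directory (probe/wall CSV, summary JSON, snapshots, manifest).
``run_study`` runs all four phases on a shared geometry family (only the
balloon changes), optionally calibrating each open-aorta phase against a
synthetic reference recording, and emits phase-comparison and calibration
reports.  All outputs are deterministic functions of (config, seed).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import ScenarioConfig, StudyConfig
from .geometry import build_aorta
from .metrics import (CycleSummary, percent_change, summarize_scenario,
                      wall_shear_series)
from .solver import FlowSolver, RunResult, run_cycles
from .synthetic import CohortSpec, draw_cohort, render_traces
from .units import PA_PER_MMHG, m3s_to_lmin, pa_to_mmhg
from .waveforms import (CalibrationError, calibrate_distal_pressure,
                        couple_supra_outlets, make_inlet_flow,
                        make_outlet_pressure)
from .vtk_io import cell_centered_velocity, write_structured_vtk

__all__ = ["ScenarioResult", "StudyResult", "build_geometry", "build_bc",
           "run_scenario", "run_study", "export_vtk", "scenario_convergence_study"]


@dataclass
class ScenarioResult:
    config: ScenarioConfig
    run: RunResult
    summary: CycleSummary
    manifest: dict
    calibration: list | None = None
    run_dir: Path | None = None


@dataclass
class StudyResult:
    scenarios: dict
    comparison: pd.DataFrame
    calibration_report: pd.DataFrame
    run_dir: Path | None = None


def build_geometry(config: ScenarioConfig):
    return build_aorta(config.aorta_params(), config.numerics.grid_spacing,
                       balloon=config.balloon_spec())


def build_bc(config: ScenarioConfig, geom, distal_waveform=None) -> dict:
    """Boundary waveform set for a scenario.

    The supra-aortic outlets share one pressure waveform built from the
    phase targets; the distal outlet starts from the same waveform shifted
    by ``distal_offset_mmhg`` unless a calibrated waveform is supplied.
    """
    targets = config.hemo_targets()
    shape = config.wave_shape()
    qin = make_inlet_flow(targets, shape)
    pout = make_outlet_pressure(targets, shape)
    p1, p2 = couple_supra_outlets(pout)
    bc = {"inlet": qin, "supra_1": p1, "supra_2": p2}
    port_names = {p.name for p in geom.ports}
    if "distal" in port_names:
        bc["distal"] = (distal_waveform if distal_waveform is not None
                        else pout.shifted(config.distal_offset_mmhg * PA_PER_MMHG))
    return bc


class ScenarioSolverHandle:
    """Reusable solver for the distal-pressure calibration loop.

    Keeps the flow state and the factorized pressure operator across
    iterations; each call swaps the distal waveform, advances a few
    cycles, and returns the simulated cycle means of descending-aorta
    flow (L/min) and subclavian probe pressure (mmHg).
    """

    def __init__(self, geom, props, bc, settings, init_cycles=3, warm_cycles=2):
        self.geom, self.props, self.bc = geom, props, dict(bc)
        self.settings = settings
        self.solver = FlowSolver(geom, props, self.bc, settings)
        self.init_cycles = init_cycles
        self.warm_cycles = warm_cycles
        self.calls = 0
        self.last_result = None

    def __call__(self, distal_waveform):
        self.bc["distal"] = distal_waveform
        n = self.init_cycles if self.calls == 0 else self.warm_cycles
        self.calls += 1
        settings = self.settings.__class__(
            **{**self.settings.__dict__, "max_cycles": n, "periodicity_tol": 0.0})
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = run_cycles(self.geom, self.props, self.bc, settings,
                             solver=self.solver)
        self.last_result = res
        # average over this call's cycles: single-cycle means carry
        # cycle-to-cycle noise on the not-exactly-periodic coarse grid
        recs = res.records[-2:] if len(res.records) > 1 else res.records
        q = float(np.mean([m3s_to_lmin(r.flux["descending_proximal"].mean())
                           for r in recs]))
        p = float(np.mean([pa_to_mmhg(r.probe_pressure["subclavian"].mean())
                           for r in recs]))
        return q, p


@dataclass
class _CalibScenarioView:
    targets: object
    shape: object


def calibrate_scenario(config: ScenarioConfig, reference, geom=None,
                       tol: float = 0.05, **handle_kwargs):
    """Calibrate the distal outlet of one scenario against a reference.

    The scenario targets are taken from the reference draw (CO/HR/MAP of
    the synthetic animal), as in the experimental practice of matching
    the model to the instrumented subject.  Returns (calibrated waveform,
    iteration history, handle).
    """
    from .waveforms import HemodynamicTargets, Phase

    d = reference.draw
    targets = HemodynamicTargets(co_l_min=d.co_l_min, hr_bpm=d.hr_bpm,
                                 map_mmhg=d.map_mmhg, phase=Phase(config.phase))
    shape = config.wave_shape()
    geom = geom if geom is not None else build_geometry(config)
    qin = make_inlet_flow(targets, shape)
    pout = make_outlet_pressure(targets, shape)
    p1, p2 = couple_supra_outlets(pout)
    bc = {"inlet": qin, "supra_1": p1, "supra_2": p2,
          "distal": pout.shifted(config.distal_offset_mmhg * PA_PER_MMHG)}
    handle = ScenarioSolverHandle(geom, config.fluid_props(), bc,
                                  config.solver_settings(), **handle_kwargs)
    view = _CalibScenarioView(targets=targets, shape=shape)
    wf, history = calibrate_distal_pressure(view, reference, handle, tol=tol)
    return wf, history, handle


def run_scenario(config: ScenarioConfig, out_dir=None,
                 distal_waveform=None) -> ScenarioResult:
    """Execute one scenario; optionally persist a run directory."""
    geom = build_geometry(config)
    props = config.fluid_props()
    bc = build_bc(config, geom, distal_waveform)
    settings = config.solver_settings()
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        run = run_cycles(geom, props, bc, settings)
    summary = summarize_scenario(run, phase=config.phase)
    rec = run.records[-1]
    manifest = {
        "package_version": __version__,
        "config": config.model_dump(),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "grid": {"nx": geom.nx, "ny": geom.ny, "spacing_m": geom.spacing},
        "cycles_run": len(run.records),
        "dt_history": [r.dt for r in run.records],
        "periodicity": [r.periodicity for r in run.records],
        "periodic": run.periodic,
        "max_residual": max(float(r.poisson_residuals.max())
                            for r in run.records),
        "u_max_m_s": rec.u_max,
        "warnings": [str(w.message) for w in caught],
    }
    result = ScenarioResult(config=config, run=run, summary=summary,
                            manifest=manifest)
    if out_dir is not None:
        result.run_dir = _write_run_dir(Path(out_dir), result)
    return result


def _write_run_dir(out_dir: Path, result: ScenarioResult) -> Path:
    out_dir.mkdir(parents=True, exist_ok=True)
    rec = result.run.records[-1]
    probes = pd.DataFrame({"phase_time_s": rec.phase_times})
    for st in rec.probe_pressure:
        probes[f"p_{st}_mmhg"] = pa_to_mmhg(rec.probe_pressure[st])
        probes[f"v_{st}_m_s"] = rec.probe_velocity[st]
        probes[f"q_{st}_l_min"] = m3s_to_lmin(rec.flux[st])
    probes.to_csv(out_dir / "probes.csv", index=False)

    series = wall_shear_series(result.run.snapshots, result.run.geom,
                               result.run.props)
    n_s, n_t = series.wss.shape
    wall = pd.DataFrame({
        "sample": np.repeat(np.arange(n_s), n_t),
        "time_s": np.tile(series.times, n_s),
        "x_m": np.repeat(series.x, n_t),
        "y_m": np.repeat(series.y, n_t),
        "region": np.repeat(series.region.astype(str), n_t),
        "wss_pa": series.wss.ravel(),
        "wsr_per_s": series.wsr.ravel(),
    })
    wall.to_csv(out_dir / "wall_series.csv", index=False)

    with open(out_dir / "summary.json", "w") as fh:
        json.dump(result.summary.to_dict(), fh, indent=1)
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(result.manifest, fh, indent=1, default=str)

    snaps = result.run.snapshots
    np.savez_compressed(
        out_dir / "snapshots.npz", times=snaps["times"],
        u=np.array(snaps["u"]), v=np.array(snaps["v"]),
        p=np.array(snaps["p"]), mu=np.array(snaps["mu"]),
        chi=result.run.geom.chi, spacing=result.run.geom.spacing,
        origin=np.array(result.run.geom.origin))
    return out_dir


def run_study(study: StudyConfig, out_dir=None) -> StudyResult:
    """Run all four phases on a shared geometry family and compare them.

    With ``study.calibrate`` the open-aorta phases (baseline, hemorrhage,
    p_reboa) are first calibrated against synthetic reference recordings
    of the configured cohort group; the full-occlusion phase has no
    distal outlet to calibrate and is checked against its prescribed
    supra-aortic pressure only.
    """
    phase_to_table = {"baseline": "baseline", "hemorrhage": "hemorrhage",
                      "f_reboa": "occlusion", "p_reboa": "occlusion"}
    cohort = study.cohort
    spec = CohortSpec(group=cohort.group, n_animals=1, seed=cohort.seed,
                      beat_noise_cv=cohort.beat_noise_cv,
                      pressure_noise_mmhg=cohort.pressure_noise_mmhg,
                      flow_noise_l_min=cohort.flow_noise_l_min,
                      distal_fraction=cohort.distal_fraction)
    draws = {d.phase: d for d in draw_cohort(spec)}
    recs = {r.phase: r for r in render_traces(list(draws.values()), spec=spec,
                                              n_cycles=cohort.n_cycles)}

    scenarios = {}
    calib_rows = []
    for phase, cfg in study.scenarios.items():
        distal_wf = None
        calib_hist = None
        if study.calibrate and phase != "f_reboa":
            ref = recs[phase_to_table[phase]]
            try:
                distal_wf, calib_hist, _ = calibrate_scenario(
                    cfg, ref, tol=study.calibration_tol)
                last = calib_hist[-1]
                calib_rows.append({
                    "phase": phase, "converged": True,
                    "iterations": len(calib_hist),
                    "rel_err_flow": last["rel_err_flow"],
                    "rel_err_pressure": last["rel_err_pressure"]})
            except CalibrationError as err:
                calib_rows.append({"phase": phase, "converged": False,
                                   "iterations": len(err.history),
                                   "rel_err_flow": np.nan,
                                   "rel_err_pressure": np.nan})
        res = run_scenario(cfg, distal_waveform=distal_wf,
                           out_dir=None if out_dir is None
                           else Path(out_dir) / phase)
        res.calibration = calib_hist
        scenarios[phase] = res
        if phase == "f_reboa" and study.calibrate:
            # no distal outlet: report the supra-pressure match only
            rec = res.run.records[-1]
            p_sim = pa_to_mmhg(rec.probe_pressure["subclavian"].mean())
            p_ref = recs["occlusion"].subclavian_pressure_mmhg.mean()
            calib_rows.append({
                "phase": phase, "converged": True, "iterations": 0,
                "rel_err_flow": np.nan,
                "rel_err_pressure": abs(p_sim - p_ref) / p_ref})

    comparison = _comparison_table(scenarios)
    calib_df = pd.DataFrame(calib_rows)
    result = StudyResult(scenarios=scenarios, comparison=comparison,
                         calibration_report=calib_df,
                         run_dir=None if out_dir is None else Path(out_dir))
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        comparison.to_csv(out / "comparison.csv", index=False)
        calib_df.to_csv(out / "calibration_report.csv", index=False)
    return result


def _comparison_table(scenarios: dict) -> pd.DataFrame:
    rows = []
    base = scenarios.get("baseline")
    for phase, res in scenarios.items():
        s = res.summary
        row = {"phase": phase}
        for region, val in s.region_tawss.items():
            row[f"tawss_{region}_pa"] = val
        for region, val in s.region_osi.items():
            row[f"osi_{region}"] = val
        for st, (sys_p, dia_p, mean_p) in s.probe_pressure.items():
            row[f"p_mean_{st}_mmhg"] = mean_p
        for st, q in s.station_flow.items():
            row[f"q_{st}_l_min"] = q
        rows.append(row)
    df = pd.DataFrame(rows)
    if base is not None:
        ref = df[df.phase == "baseline"].iloc[0]
        for col in df.columns:
            if col == "phase":
                continue
            df[f"pct_vs_baseline_{col}"] = [
                percent_change(v, ref[col]) for v in df[col]]
    return df


def export_vtk(run_dir, instants="all", out_dir=None):
    """Write VTK snapshot files from a stored run directory.

    ``instants``: "all", an index, or a time in seconds (nearest stored
    instant).  Raises with the list of stored instants when the request
    cannot be matched.
    """
    run_dir = Path(run_dir)
    snap_path = run_dir / "snapshots.npz"
    if not snap_path.exists():
        raise FileNotFoundError(
            f"no snapshots stored in {run_dir}; available instants: []")
    data = np.load(snap_path)
    times = data["times"]
    if instants == "all":
        sel = list(range(len(times)))
    else:
        try:
            t_req = float(instants)
        except (TypeError, ValueError):
            raise ValueError(f"bad instant selector {instants!r}; "
                             f"available: {times.tolist()}")
        sel = [int(np.argmin(np.abs(times - t_req)))]
    out_dir = Path(out_dir) if out_dir is not None else run_dir

    class _GeomShim:
        spacing = float(data["spacing"])
        origin = tuple(data["origin"])
        nx, ny = data["p"].shape[1:]

    written = []
    for k in sel:
        u, v = data["u"][k], data["v"][k]
        uc, vc = cell_centered_velocity(u, v)
        fields = {"u": uc, "v": vc, "speed": np.hypot(uc, vc),
                  "p": data["p"][k], "mu": data["mu"][k],
                  "mask": data["chi"]}
        path = out_dir / f"snapshot_t{times[k]:.4f}.vtk"
        write_structured_vtk(path, _GeomShim, fields)
        written.append(path)
    return written


def scenario_convergence_study(config: ScenarioConfig, spacings,
                               max_cycles: int = 3):
    """Grid-convergence table for a scenario (see solver module)."""
    from .solver import grid_convergence_study

    def runner(h):
        cfg = config.model_copy(deep=True)
        cfg.numerics.grid_spacing = h
        cfg.numerics.max_cycles = max_cycles
        res = run_scenario(cfg)
        rec = res.run.records[-1]
        out = {"p_mean_ascending_mmhg":
               pa_to_mmhg(rec.probe_pressure["ascending"].mean()),
               "q_distal_l_min": m3s_to_lmin(rec.flux["descending_distal"].mean()),
               "peak_tawss_pa": res.summary.peak_tawss}
        return out

    return grid_convergence_study(runner, spacings)
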