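import numpy as np
import pytest

from reboa_hemo.geometry import build_channel
from reboa_hemo.rheology import FluidProperties
from reboa_hemo.solver import (FlowSolver, SolverSettings, StabilityError,
                               grid_convergence_study, residual_report,
                               run_cycles, run_until_steady)


class ConstWaveform:
    """Constant boundary value with the waveform interface."""

    def __init__(self, value, period=0.2):
        self.period = period
        self.values = np.array([value])

    def __call__(self, t):
        return self.values[0]


def poiseuille_channel(h_cells=16, height=0.01, length=0.02, u_mean=0.02,
                       align=True):
    geom = build_channel(length, height, height / h_cells, align_walls=align)
    props = FluidProperties(newtonian_override=0.056)
    bc = {"inlet": ConstWaveform(u_mean * height),  # depth = 1 m
          "right": ConstWaveform(0.0)}
    return geom, props, bc


def womersley_u(y, t, *, G, omega, nu, a, rho):
    """Analytic pulsatile channel profile (independent oracle)."""
    beta = np.sqrt(1j * omega / nu)
    prof = (G / (1j * rho * omega)) * (1 - np.cosh(beta * (y - a))
                                       / np.cosh(beta * a))
    return np.real(prof * np.exp(1j * omega * t))


class TestStep:
    def test_equilibrium_stays_at_rest(self):
        geom = build_channel(0.02, 0.01, 1e-3, left="pressure",
                             right="pressure")
        props = FluidProperties(newtonian_override=0.0035)
        bc = {"left": ConstWaveform(40.0), "right": ConstWaveform(40.0)}
        # equal outlet pressures, no inflow: zero velocity is a fixed point
        sol = FlowSolver(geom, props, bc, SolverSettings())
        for _ in range(50):
            sol.step(2e-4)
        assert np.abs(sol.state.u).max() < 1e-10
        assert np.abs(sol.state.v).max() < 1e-10

    def test_compiled_kernels_match_numpy_reference(self):
        geom, props, bc = poiseuille_channel()
        rng = np.random.default_rng(11)
        states = []
        for compiled in (True, False):
            sol = FlowSolver(geom, props, bc,
                             SolverSettings(compiled=compiled))
            r = np.random.default_rng(3)
            sol.state.u += 0.01 * r.standard_normal(sol.state.u.shape)
            sol.state.v += 0.01 * r.standard_normal(sol.state.v.shape)
            for _ in range(5):
                sol.step(1e-4)
            states.append((sol.state.u.copy(), sol.state.v.copy(),
                           sol.state.p.copy()))
        for a, b in zip(*states):
            np.testing.assert_allclose(a, b, rtol=1e-10, atol=1e-13)

    def test_cfl_violation_raises(self):
        geom, props, bc = poiseuille_channel()
        sol = FlowSolver(geom, props, bc, SolverSettings())
        sol.state.u += 1.0
        with pytest.raises(StabilityError):
            sol.step(1.0)


class TestPoiseuille:
    @pytest.fixture(scope="class")
    def steady(self):
        geom, props, bc = poiseuille_channel()
        sol = run_until_steady(geom, props, bc, t_max=3.0, tol=1e-8)
        return geom, sol

    def test_centerline_is_three_halves_mean(self, steady):
        geom, sol = steady
        u = sol.state.u[int(geom.nx * 0.75), :]
        assert u.max() == pytest.approx(1.5 * 0.02, rel=0.01)

    def test_parabolic_profile(self, steady):
        geom, sol = steady
        y = geom.cell_y()
        m = (y > 0) & (y < 0.01)
        exact = 6 * 0.02 * y[m] * (0.01 - y[m]) / 0.01 ** 2
        u = sol.state.u[int(geom.nx * 0.75), m]
        assert np.linalg.norm(u - exact) / np.linalg.norm(exact) < 0.01

    def test_flux_conserved_along_channel(self, steady):
        geom, sol = steady
        h = geom.spacing
        fluxes = [(sol.state.u[i, :] * h).sum()
                  for i in range(1, geom.nx, 7)]
        assert np.ptp(fluxes) / abs(np.mean(fluxes)) < 1e-8

    def test_divergence_free_after_projection(self, steady):
        geom, sol = steady
        umax = np.abs(sol.state.u).max()
        assert sol.last_divergence * geom.spacing / umax < 1e-8


class TestResiduals:
    def test_converged_run_below_criterion(self):
        geom, props, bc = poiseuille_channel()
        sol = run_until_steady(geom, props, bc, t_max=2.0, tol=1e-7)
        res = run_cycles(geom, props, bc,
                         SolverSettings(max_cycles=1, periodicity_tol=0.0),
                         solver=sol)
        assert residual_report(res.records[-1]) < 1e-3

    def test_zero_flow_residual_is_machine_level(self):
        geom = build_channel(0.02, 0.01, 1e-3, left="pressure",
                             right="pressure")
        props = FluidProperties(newtonian_override=0.0035)
        bc = {"left": ConstWaveform(0.0), "right": ConstWaveform(0.0)}
        res = run_cycles(geom, props, bc,
                         SolverSettings(max_cycles=1, periodicity_tol=0.0))
        assert residual_report(res.records[-1]) < 1e-10

    def test_single_jacobi_sweep_fails_criterion(self):
        # negative control: a deliberately crippled pressure solve
        geom, props, bc = poiseuille_channel()
        sol = FlowSolver(geom, props, bc,
                         SolverSettings(poisson="jacobi", jacobi_sweeps=1))
        for _ in range(20):
            sol.step(1e-4)
        assert sol.last_poisson_residual > 1e-3


class TestWomersley:
    def test_profile_matches_analytic_series(self):
        H, a = 0.01, 0.005
        alpha = 5.0
        props = FluidProperties(newtonian_override=0.0035)
        nu = props.newtonian_override / props.density
        omega = (alpha / a) ** 2 * nu
        T = 2 * np.pi / omega
        G = 350.0  # Pa/m pressure-gradient amplitude
        L = 0.005
        geom = build_channel(L, H, H / 64, left="pressure", right="pressure")

        class OscP:
            period = T
            values = np.array([G * L])

            def __call__(self, t):
                return G * L * np.cos(omega * t)

        sol = FlowSolver(geom, props, {"left": OscP(), "right": ConstWaveform(0.0, T)},
                         SolverSettings())
        y = geom.cell_y()
        kw = dict(G=G, omega=omega, nu=nu, a=a, rho=props.density)
        # start on the analytic solution; compare over the second period
        for i in range(geom.nx + 1):
            sol.state.u[i, :] = womersley_u(np.clip(y, 0, H), 0.0, **kw)
        sol.state.u[:, y <= 0] = 0.0
        sol.state.u[:, y >= H] = 0.0
        dt = min(sol.suggest_dt(T), 0.4 * geom.spacing / 0.3)
        n = int(round(T / dt))
        dt = T / n
        peak = np.abs((G / (1j * props.density * omega))
                      * (1 - 1 / np.cosh(np.sqrt(1j * omega / nu) * a)))
        m = (y > 0) & (y < H)
        i_mid = geom.nx // 2
        worst = 0.0
        for cyc in range(2):
            for k in range(n):
                sol.step(dt)
                if cyc == 1 and k % (n // 12) == 0:
                    exact = womersley_u(y[m], sol.state.time, **kw)
                    err = np.linalg.norm(sol.state.u[i_mid, m] - exact) \
                        / (peak * np.sqrt(m.sum()))
                    worst = max(worst, err)
        assert worst < 0.03


class TestStokesLinearity:
    def test_doubling_inflow_doubles_solution(self):
        geom, props, bc = poiseuille_channel(u_mean=0.01)
        settings = SolverSettings(stokes=True)
        sol1 = run_until_steady(geom, props, bc, settings, t_max=2.0, tol=1e-8)
        bc2 = dict(bc, inlet=ConstWaveform(2 * 0.01 * 0.01))
        sol2 = run_until_steady(geom, props, bc2, settings, t_max=2.0, tol=1e-8)
        m = np.abs(sol1.state.u) > 1e-6
        assert np.allclose(sol2.state.u[m] / sol1.state.u[m], 2.0, rtol=1e-3)
        dp1 = sol1.state.p.max() - sol1.state.p.min()
        dp2 = sol2.state.p.max() - sol2.state.p.min()
        assert dp2 / dp1 == pytest.approx(2.0, rel=1e-2)


class TestGridConvergence:
    def test_error_decreases_under_refinement(self):
        # walls off the cell centers: wall representation dominates, so the
        # scheme is first-to-second order in the spacing
        def runner(h):
            geom = build_channel(0.02, 0.01, h, align_walls=False)
            props = FluidProperties(newtonian_override=0.056)
            bc = {"inlet": ConstWaveform(0.02 * 0.01), "right": ConstWaveform(0.0)}
            sol = run_until_steady(geom, props, bc, t_max=3.0, tol=1e-8)
            u = sol.state.u[int(geom.nx * 0.75), :]
            return {"centerline_error": abs(u.max() - 1.5 * 0.02)}

        df = grid_convergence_study(runner, [0.01 / 8, 0.01 / 16, 0.01 / 32])
        errs = df["centerline_error"].to_numpy()
        assert errs[1] < errs[0] and errs[2] < errs[1]
        assert errs[0] / errs[1] > 1.3  # at least first-order

    def test_identical_spacing_gives_zero_difference(self):
        df = grid_convergence_study(lambda h: {"x": 1.23}, [1e-3, 1e-3])
        assert df["rel_diff_x"].iloc[1] == 0.0

    def test_requires_two_spacings(self):
        with pytest.raises(ValueError):
            grid_convergence_study(lambda h: {}, [1e-3])


class TestAortaRun:
    def test_mass_conserved_over_cycle(self, phase_runs):
        rec = phase_runs["baseline"].run.records[-1]
        q_in = 6.5 / 60000.0
        q_out = sum(t.mean() for t in rec.outlet_flux.values())
        assert abs(q_in - q_out) / q_in < 0.01

    def test_full_occlusion_zeroes_distal_flow(self, phase_runs):
        rec = phase_runs["f_reboa"].run.records[-1]
        q_in = 6.0 / 60000.0
        assert np.abs(rec.flux["descending_distal"]).max() < 1e-3 * q_in
        assert "distal" not in rec.outlet_flux

    def test_partial_occlusion_passes_flow(self, phase_runs):
        rec = phase_runs["p_reboa"].run.records[-1]
        assert rec.flux["descending_distal"].mean() > 0

    def test_periodicity_metric_tracked_and_decreasing_trend(self, phase_runs):
        recs = phase_runs["baseline"].run.records
        pers = [r.periodicity for r in recs if r.periodicity is not None]
        assert len(pers) >= 1 and all(p >= 0 for p in pers)

    def test_balloon_raises_proximal_pressure_under_hemorrhage_targets(
            self, phase_runs):
        import warnings

        from reboa_hemo.config import default_scenario
        from reboa_hemo.geometry import BalloonMode, BalloonSpec, build_aorta
        from reboa_hemo.pipeline import build_bc

        cfg = default_scenario("hemorrhage")
        geom = build_aorta(cfg.aorta_params(), cfg.numerics.grid_spacing,
                           balloon=BalloonSpec(mode=BalloonMode.full))
        bc = build_bc(cfg, geom)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = run_cycles(geom, cfg.fluid_props(), bc,
                             cfg.solver_settings(max_cycles=3))
        p_with = res.records[-1].probe_pressure["ascending"].mean()
        p_without = phase_runs["hemorrhage"].run.records[-1] \
            .probe_pressure["ascending"].mean()
        assert p_with > p_without
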