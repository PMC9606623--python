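"""Incompressible variable-viscosity Navier-Stokes on the masked geometry.

Discretization
--------------
* uniform staggered (MAC) grid: u on x-faces, v on y-faces, p at cell
  centers; walls and balloon represented by Brinkman volume penalization
  with an implicit drag ``-(chi/eta) u`` (``eta`` = 1e-8 s, so penalized
  cells are driven to rest within a single step);
* explicit second-order upwind-biased advection (first order in the two
  cells nearest a boundary), explicit variable-viscosity stress divergence
  ``div(mu (grad u + grad u^T))`` with the apparent viscosity lagged one
  step (Picard linearization of the shear-thinning law);
* first-order pressure projection.  The pressure Poisson operator lives on
  the binary fluid mask with solid faces closed, so wall-normal mass flux
  is identically zero; outlet faces carry Dirichlet pressure from the
  boundary waveforms (ghost value ``2 p_out - p``), inlet and wall faces
  are homogeneous Neumann.  The operator is factorized once (sparse LU)
  and reused every step, which makes runs bit-reproducible.
* inlet faces carry a parabolic profile rescaled each step so the
  discrete face-integrated flux equals the prescribed Q_in(t) exactly;
  outlets use zero-gradient velocity extrapolation, whose edge-replicated
  upwind ghosts double as the backflow treatment during the inflow part
  of the cycle (relevant at the high heart rates of the occlusion
  phases).

Cardiac cycles are advanced until the probe-pressure traces of consecutive
cycles agree in relative L2 below a periodicity threshold, mirroring the
usual cycle-to-cycle convergence practice for pulsatile hemodynamics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.linalg import splu

from .geometry import AorticGeometry
from .rheology import FluidProperties, apparent_viscosity

__all__ = [
    "SolverSettings", "FlowState", "CycleRecord", "RunResult", "FlowSolver",
    "run_cycles", "run_until_steady", "residual_report",
    "grid_convergence_study", "StabilityError", "LinearSolverError",
]


class StabilityError(RuntimeError):
    """Advective CFL violated for the chosen time step."""


class LinearSolverError(RuntimeError):
    """Pressure Poisson solve failed to reach its tolerance."""


@dataclass(frozen=True)
class SolverSettings:
    cfl: float = 0.4
    diff_safety: float = 0.25
    eta: float = 1e-8              # penalization time scale (s)
    poisson: str = "direct"        # "direct" | "jacobi" (diagnostic)
    jacobi_sweeps: int = 200
    max_cycles: int = 8
    periodicity_tol: float = 1e-2
    n_snapshots: int = 40
    n_phase_samples: int = 200     # uniform-phase resampling of probe traces
    stokes: bool = False           # drop the advection term (linearity checks)
    dt: float | None = None        # override automatic step selection
    velocity_headroom: float = 1.3 # CFL margin over the running velocity estimate
    compiled: bool = True          # numba kernels (numpy reference path if False)


@dataclass
class FlowState:
    u: np.ndarray
    v: np.ndarray
    p: np.ndarray
    mu: np.ndarray
    gamma_dot: np.ndarray
    time: float = 0.0


@dataclass
class CycleRecord:
    cycle_index: int
    phase_times: np.ndarray                 # uniform samples over one period
    probe_pressure: dict = field(default_factory=dict)   # station -> Pa trace
    probe_velocity: dict = field(default_factory=dict)   # station -> m/s trace
    flux: dict = field(default_factory=dict)             # station -> m3/s trace
    outlet_flux: dict = field(default_factory=dict)      # port -> m3/s trace
    poisson_residuals: np.ndarray | None = None
    continuity_residuals: np.ndarray | None = None
    u_max: float = 0.0
    dt: float = 0.0
    h: float = 0.0
    periodicity: float | None = None


@dataclass
class RunResult:
    records: list
    snapshots: dict          # times, u, v, p, mu (final stored cycle)
    state: FlowState
    periodic: bool
    geom: AorticGeometry
    props: FluidProperties
    settings: SolverSettings


# ---------------------------------------------------------------------------


def _upwind_deriv(f, vel, axis, h):
    """Upwind-biased derivative of f at its own points, 2nd order interior."""
    fp = np.concatenate([f.take([0, 0], axis=axis), f,
                         f.take([-1, -1], axis=axis)], axis=axis)

    def sl(off):
        idx = [slice(None)] * f.ndim
        idx[axis] = slice(2 + off, 2 + off + f.shape[axis])
        return fp[tuple(idx)]

    d_back = (3 * sl(0) - 4 * sl(-1) + sl(-2)) / (2 * h)
    d_fwd = (-3 * sl(0) + 4 * sl(1) - sl(2)) / (2 * h)
    return np.where(vel > 0, d_back, d_fwd)


class FlowSolver:
    """Advances one geometry/BC configuration; see module docstring."""

    def __init__(self, geom: AorticGeometry, props: FluidProperties,
                 bc: dict, settings: SolverSettings | None = None):
        self.geom = geom
        self.props = props
        self.bc = bc
        self.settings = settings or SolverSettings()
        self.h = geom.spacing
        self.nx, self.ny = geom.nx, geom.ny
        self._build_masks()
        self._assemble_poisson()
        self.state = self.zero_state()
        self.last_poisson_residual = 0.0
        self.last_divergence = 0.0

    # -- setup ------------------------------------------------------------
    def _build_masks(self):
        nx, ny, h = self.nx, self.ny, self.h
        # drag only on solid-centered cells (chi >= 1/2): the smoothing
        # band on the fluid side must stay drag-free or the stiff
        # penalization would effectively narrow every passage by a cell
        chi = np.where(self.geom.chi >= 0.5, self.geom.chi, 0.0)
        F = self.geom.fluid
        chi_u = np.ones((nx + 1, ny))
        chi_u[1:-1, :] = 0.5 * (chi[:-1, :] + chi[1:, :])
        chi_v = np.ones((nx, ny + 1))
        chi_v[:, 1:-1] = 0.5 * (chi[:, :-1] + chi[:, 1:])
        open_u = np.zeros((nx + 1, ny), dtype=bool)
        open_u[1:-1, :] = F[:-1, :] & F[1:, :]
        open_v = np.zeros((nx, ny + 1), dtype=bool)
        open_v[:, 1:-1] = F[:, :-1] & F[:, 1:]

        self.inlet_faces = []    # (component, fixed_idx, along_idx, shape, sign)
        self.outlet_faces = {}   # port name -> (component, fixed_idx, along_idx, sign)
        for port in self.geom.ports:
            idx = port.indices
            if port.kind == "inlet":
                xi = (port.coords - port.coords.mean())
                halfw = (port.coords.max() - port.coords.min()) / 2 + h / 2
                shape = np.maximum(1.0 - (xi / halfw) ** 2, 0.0)
                ent = self._edge_faces(port.edge, idx)
                self.inlet_faces.append((*ent, shape))
                comp, fixed, along, sign = ent
                if comp == "v":
                    open_v[along, fixed] = False   # prescribed, not projected
                    chi_v[along, fixed] = 0.0
                else:
                    open_u[fixed, along] = False
                    chi_u[fixed, along] = 0.0
            else:
                ent = self._edge_faces(port.edge, idx)
                self.outlet_faces[port.name] = ent
                comp, fixed, along, sign = ent
                if comp == "v":
                    chi_v[along, fixed] = 0.0
                else:
                    chi_u[fixed, along] = 0.0
        self.chi_u, self.chi_v = chi_u, chi_v
        self.open_u, self.open_v = open_u, open_v
        self.F = F

    def _edge_faces(self, edge, idx):
        """(component, fixed index, along indices, outward sign) of edge faces."""
        if edge == "bottom":
            return ("v", 0, idx, -1)
        if edge == "top":
            return ("v", self.ny, idx, +1)
        if edge == "left":
            return ("u", 0, idx, -1)
        if edge == "right":
            return ("u", self.nx, idx, +1)
        raise ValueError(edge)

    def _assemble_poisson(self):
        nx, ny, h = self.nx, self.ny, self.h
        F = self.F
        idx = -np.ones((nx, ny), dtype=int)
        cells = np.argwhere(F)
        idx[F] = np.arange(len(cells))
        rows, cols, vals = [], [], []
        diag = np.zeros(len(cells))
        inv_h2 = 1.0 / h ** 2

        def couple(ci, cj, ni, nj):
            a, b = idx[ci, cj], idx[ni, nj]
            rows.append(a); cols.append(b); vals.append(inv_h2)
            diag[a] -= inv_h2

        for i, j in cells:
            if i > 0 and F[i - 1, j]:
                couple(i, j, i - 1, j)
            if i < nx - 1 and F[i + 1, j]:
                couple(i, j, i + 1, j)
            if j > 0 and F[i, j - 1]:
                couple(i, j, i, j - 1)
            if j < ny - 1 and F[i, j + 1]:
                couple(i, j, i, j + 1)

        # Dirichlet outlet faces: ghost cell p_ghost = 2 p_bc - p
        self._dirichlet_cells = {}
        for name, (comp, fixed, along, sign) in self.outlet_faces.items():
            cell_list = []
            for a in along:
                ci, cj = (a, 0 if fixed == 0 else ny - 1) if comp == "v" else \
                         (0 if fixed == 0 else nx - 1, a)
                if not F[ci, cj]:
                    continue
                k = idx[ci, cj]
                diag[k] -= 2.0 * inv_h2
                cell_list.append(k)
            self._dirichlet_cells[name] = np.array(cell_list, dtype=int)

        n = len(cells)
        rows.extend(range(n)); cols.extend(range(n)); vals.extend(diag)
        A = csr_matrix((vals, (rows, cols)), shape=(n, n))
        self._A = A
        self._cell_index = idx
        self._cells = cells
        self._inv_h2 = inv_h2
        if self.settings.poisson == "direct":
            self._lu = splu(A.tocsc())
        else:
            self._Adiag = A.diagonal()

    # -- state helpers ----------------------------------------------------
    def zero_state(self) -> FlowState:
        nx, ny = self.nx, self.ny
        mu0 = self.props.newtonian_override or self.props.mu_zero
        return FlowState(
            u=np.zeros((nx + 1, ny)), v=np.zeros((nx, ny + 1)),
            p=np.zeros((nx, ny)), mu=np.full((nx, ny), mu0),
            gamma_dot=np.zeros((nx, ny)), time=0.0)

    def _bc_value(self, name, t):
        wf = self.bc.get(name)
        if wf is None:
            return 0.0
        return float(wf(t)) if callable(wf) else float(wf)

    def apply_inlet(self, u, v, t):
        for comp, fixed, along, sign, shape in self.inlet_faces:
            q = self._bc_value("inlet", t) / self.geom.depth  # m2/s
            denom = shape.sum() * self.h
            prof = shape * (q / denom) if denom > 0 else shape * 0.0
            if comp == "v":
                v[along, fixed] = -sign * prof
            else:
                u[fixed, along] = -sign * prof

    # -- kernels ----------------------------------------------------------
    def shear_fields(self, u, v):
        h = self.h
        dudx = (u[1:, :] - u[:-1, :]) / h
        dvdy = (v[:, 1:] - v[:, :-1]) / h
        # off-diagonal terms at nodes, averaged back to centers
        dudy_n = np.zeros((self.nx + 1, self.ny + 1))
        dudy_n[:, 1:-1] = (u[:, 1:] - u[:, :-1]) / h
        dvdx_n = np.zeros((self.nx + 1, self.ny + 1))
        dvdx_n[1:-1, :] = (v[1:, :] - v[:-1, :]) / h
        cross_n = dudy_n + dvdx_n
        cross_c = 0.25 * (cross_n[:-1, :-1] + cross_n[1:, :-1]
                          + cross_n[:-1, 1:] + cross_n[1:, 1:])
        gamma = np.sqrt(2 * dudx ** 2 + 2 * dvdy ** 2 + cross_c ** 2)
        return gamma

    def diffusion(self, u, v, mu):
        h = self.h
        nx, ny = self.nx, self.ny
        mp = np.pad(mu, 1, mode="edge")
        mu_n = 0.25 * (mp[:-1, :-1] + mp[1:, :-1] + mp[:-1, 1:] + mp[1:, 1:])

        sxx = 2.0 * mu * (u[1:, :] - u[:-1, :]) / h
        syy = 2.0 * mu * (v[:, 1:] - v[:, :-1]) / h
        dudy_n = np.zeros((nx + 1, ny + 1))
        dudy_n[:, 1:-1] = (u[:, 1:] - u[:, :-1]) / h
        dvdx_n = np.zeros((nx + 1, ny + 1))
        dvdx_n[1:-1, :] = (v[1:, :] - v[:-1, :]) / h
        sxy = mu_n * (dudy_n + dvdx_n)

        du = np.zeros_like(u)
        du[1:-1, :] = (sxx[1:, :] - sxx[:-1, :]) / h \
            + (sxy[1:-1, 1:] - sxy[1:-1, :-1]) / h
        dv = np.zeros_like(v)
        dv[:, 1:-1] = (syy[:, 1:] - syy[:, :-1]) / h \
            + (sxy[1:, 1:-1] - sxy[:-1, 1:-1]) / h
        return du, dv

    def advection(self, u, v, t):
        h = self.h
        u_a, v_a = u, v
        # outlet faces keep their projected values; zero-gradient ghosts in
        # the upwind stencils act as the backflow treatment during inflow
        # v interpolated to u points and vice versa
        vpad = np.pad(v_a, ((1, 1), (0, 0)), mode="edge")
        v_at_u = 0.25 * (vpad[:-1, :-1] + vpad[1:, :-1]
                         + vpad[:-1, 1:] + vpad[1:, 1:])
        upad = np.pad(u_a, ((0, 0), (1, 1)), mode="edge")
        u_at_v = 0.25 * (upad[:-1, :-1] + upad[1:, :-1]
                         + upad[:-1, 1:] + upad[1:, 1:])
        au = u_a * _upwind_deriv(u_a, u_a, 0, h) \
            + v_at_u * _upwind_deriv(u_a, v_at_u, 1, h)
        av = u_at_v * _upwind_deriv(v_a, u_at_v, 0, h) \
            + v_a * _upwind_deriv(v_a, v_a, 1, h)
        return au, av

    def divergence(self, u, v):
        return (u[1:, :] - u[:-1, :] + v[:, 1:] - v[:, :-1]) / self.h

    def _solve_poisson(self, rhs_cells, t):
        b = rhs_cells.copy()
        bc_vals = {}
        for name, cells in self._dirichlet_cells.items():
            pb = self._bc_value(name, t)
            bc_vals[name] = pb
            b[cells] -= 2.0 * self._inv_h2 * pb
        if self.settings.poisson == "direct":
            p = self._lu.solve(b)
        else:
            p = self.state.p[self.F].copy()
            d = self._Adiag
            for _ in range(self.settings.jacobi_sweeps):
                p = p + (b - self._A @ p) / d
        nb = np.linalg.norm(b)
        res = np.linalg.norm(self._A @ p - b) / nb if nb > 0 else 0.0
        self.last_poisson_residual = float(res)
        return p, bc_vals

    # -- time stepping ----------------------------------------------------
    def step(self, dt: float):
        st = self.state
        h, rho = self.h, self.props.density
        t_new = st.time + dt

        umax = max(np.abs(st.u).max(), np.abs(st.v).max())
        if umax * dt / h > 1.0:
            raise StabilityError(
                f"advective CFL {umax * dt / h:.2f} > 1 at dt = {dt:.3e} s")

        if self.settings.compiled:
            from ._kernels import predictor_kernel, shear_kernel
            gamma = shear_kernel(st.u, st.v, h)
            mu = apparent_viscosity(gamma, self.props)
            us, vs = predictor_kernel(
                st.u, st.v, mu, rho, dt, h, self.chi_u, self.chi_v,
                self.settings.eta, self.settings.stokes)
        else:
            gamma = self.shear_fields(st.u, st.v)
            mu = apparent_viscosity(gamma, self.props)
            du, dv = self.diffusion(st.u, st.v, mu)
            if self.settings.stokes:
                au = av = 0.0
            else:
                au, av = self.advection(st.u, st.v, st.time)
            us = st.u + dt * (-au + du / rho)
            vs = st.v + dt * (-av + dv / rho)
            us /= (1.0 + dt * self.chi_u / self.settings.eta)
            vs /= (1.0 + dt * self.chi_v / self.settings.eta)

        # boundary faces: prescribed inlet, zero-gradient outlets, closed walls
        us[~self.open_u] = 0.0
        vs[~self.open_v] = 0.0
        for name, (comp, fixed, along, sign) in self.outlet_faces.items():
            if comp == "v":
                inner = 1 if fixed == 0 else self.ny - 1
                vs[along, fixed] = vs[along, inner]
            else:
                inner = 1 if fixed == 0 else self.nx - 1
                us[fixed, along] = us[inner, along]
        self.apply_inlet(us, vs, t_new)

        div = self.divergence(us, vs)
        rhs = (rho / dt) * div[self.F]
        p_cells, bc_vals = self._solve_poisson(rhs, t_new)
        p = np.zeros((self.nx, self.ny))
        p[self.F] = p_cells

        # projection on open interior faces
        gpx = (p[1:, :] - p[:-1, :]) / h
        us[1:-1, :] -= dt / rho * gpx * self.open_u[1:-1, :]
        gpy = (p[:, 1:] - p[:, :-1]) / h
        vs[:, 1:-1] -= dt / rho * gpy * self.open_v[:, 1:-1]
        # outlet boundary faces: gradient against the Dirichlet ghost
        for name, (comp, fixed, along, sign) in self.outlet_faces.items():
            pb = bc_vals[name]
            if comp == "v":
                cj = 0 if fixed == 0 else self.ny - 1
                g = sign * (2.0 * pb - 2.0 * p[along, cj]) / h
                keep = self.F[along, cj]
                vs[along, fixed] = np.where(
                    keep, vs[along, fixed] - dt / rho * g, 0.0)
            else:
                ci = 0 if fixed == 0 else self.nx - 1
                g = sign * (2.0 * pb - 2.0 * p[ci, along]) / h
                keep = self.F[ci, along]
                us[fixed, along] = np.where(
                    keep, us[fixed, along] - dt / rho * g, 0.0)

        div_post = self.divergence(us, vs)[self.F]
        self.last_divergence = float(np.abs(div_post).max()) if len(div_post) else 0.0

        st.u, st.v, st.p = us, vs, p
        st.mu, st.gamma_dot = mu, gamma
        st.time = t_new
        return st

    # -- sampling ---------------------------------------------------------
    def probe_values(self):
        st = self.state
        out_p, out_v, out_q = {}, {}, {}
        for name, spec in self.geom.stations.items():
            i, j = spec["probe"]
            out_p[name] = st.p[i, j]
            uc = 0.5 * (st.u[i, j] + st.u[i + 1, j])
            vc = 0.5 * (st.v[i, j] + st.v[i, j + 1])
            out_v[name] = float(np.hypot(uc, vc))
            axis, fidx, cols, qsign = spec["flux"]
            if axis == "y":
                out_q[name] = float(qsign * st.v[cols, fidx].sum()
                                    * self.h * self.geom.depth)
            else:
                out_q[name] = float(qsign * st.u[fidx, cols].sum()
                                    * self.h * self.geom.depth)
        return out_p, out_v, out_q

    def outlet_fluxes(self):
        st = self.state
        out = {}
        for name, (comp, fixed, along, sign) in self.outlet_faces.items():
            if comp == "v":
                out[name] = float(sign * st.v[along, fixed].sum()
                                  * self.h * self.geom.depth)
            else:
                out[name] = float(sign * st.u[fixed, along].sum()
                                  * self.h * self.geom.depth)
        return out

    def inlet_flux(self, t):
        return self._bc_value("inlet", t)

    def suggest_dt(self, period: float) -> float:
        s = self.settings
        if s.dt is not None:
            return s.dt
        mu_max = self.props.newtonian_override or self.props.mu_zero
        dt_diff = s.diff_safety * self.h ** 2 * self.props.density / (4.0 * mu_max)
        u_now = max(np.abs(self.state.u).max(), np.abs(self.state.v).max())
        wf = self.bc.get("inlet")
        u_in = 0.0
        if wf is not None and hasattr(wf, "values"):
            qpk = float(np.abs(wf.values).max()) / self.geom.depth
            for ent in self.inlet_faces:
                shape = ent[4]
                width = len(shape) * self.h
                u_in = max(u_in, 1.6 * qpk / width)
            # jets where the whole stroke squeezes through the outlets
            w_out = sum(len(ent[2]) for ent in self.outlet_faces.values()) * self.h
            if w_out > 0:
                u_in = max(u_in, 1.6 * qpk / w_out)
        u_est = max(u_now, u_in, 1e-3) * s.velocity_headroom
        dt_cfl = s.cfl * self.h / u_est
        dt = min(dt_diff, dt_cfl)
        n = max(int(np.ceil(period / dt)), 8)
        return period / n


# ---------------------------------------------------------------------------


def run_cycles(geom: AorticGeometry, props: FluidProperties, bc: dict,
               settings: SolverSettings | None = None,
               solver: FlowSolver | None = None) -> RunResult:
    """Advance whole cardiac cycles until cycle-to-cycle periodicity.

    Periodicity is the relative L2 difference of the probe pressure traces
    between consecutive cycles (threshold ``settings.periodicity_tol``).
    Non-periodic termination is flagged on the result, never silent.
    Field snapshots of the last simulated cycle are retained at
    ``settings.n_snapshots`` uniformly spaced instants.
    """
    settings = settings or SolverSettings()
    sol = solver or FlowSolver(geom, props, bc, settings)
    period = None
    for wf in bc.values():
        if wf is not None and hasattr(wf, "period"):
            period = wf.period
            break
    if period is None:
        raise ValueError("boundary conditions carry no waveform period")

    records = []
    prev_traces = None
    snapshots = None
    periodic = False
    station_names = list(geom.stations)
    phase = np.linspace(0.0, period, settings.n_phase_samples, endpoint=False)

    for cyc in range(settings.max_cycles):
        dt = sol.suggest_dt(period)
        start = (sol.state.u.copy(), sol.state.v.copy(), sol.state.p.copy(),
                 sol.state.time)
        for attempt in range(4):
            try:
                rec, snaps = _advance_one_cycle(
                    sol, geom, settings, period, dt, cyc, station_names, phase)
                break
            except StabilityError:
                if attempt == 3:
                    raise
                sol.state.u, sol.state.v, sol.state.p = (
                    start[0].copy(), start[1].copy(), start[2].copy())
                sol.state.time = start[3]
                dt /= 1.5
        cur = np.concatenate([rec.probe_pressure[s] for s in station_names])
        if prev_traces is not None:
            denom = max(np.linalg.norm(cur), 1e-30)
            rec.periodicity = float(np.linalg.norm(cur - prev_traces) / denom)
        prev_traces = cur
        records.append(rec)
        snapshots = snaps
        if rec.periodicity is not None and rec.periodicity < settings.periodicity_tol:
            periodic = True
            break

    if not periodic:
        import warnings
        warnings.warn(
            f"cycle-to-cycle periodicity {records[-1].periodicity} not below "
            f"{settings.periodicity_tol} after {len(records)} cycles", stacklevel=2)
    snapshots["times"] = np.asarray(snapshots["times"])
    return RunResult(records=records, snapshots=snapshots, state=sol.state,
                     periodic=periodic, geom=geom, props=props, settings=settings)


def _advance_one_cycle(sol, geom, settings, period, dt, cyc, station_names, phase):
    nsteps = int(round(period / dt))
    dt = period / nsteps
    t0 = sol.state.time
    tp = np.empty(nsteps)
    traces_p = {s: np.empty(nsteps) for s in station_names}
    traces_v = {s: np.empty(nsteps) for s in station_names}
    traces_q = {s: np.empty(nsteps) for s in station_names}
    traces_out = {s: np.empty(nsteps) for s in sol.outlet_faces}
    res_pois = np.empty(nsteps)
    res_cont = np.empty(nsteps)
    snap_every = max(nsteps // settings.n_snapshots, 1)
    snaps = dict(times=[], u=[], v=[], p=[], mu=[])
    umax = 0.0
    for k in range(nsteps):
        sol.step(dt)
        tp[k] = sol.state.time - t0
        pv, vv, qv = sol.probe_values()
        for s in station_names:
            traces_p[s][k] = pv[s]
            traces_v[s][k] = vv[s]
            traces_q[s][k] = qv[s]
        for s, val in sol.outlet_fluxes().items():
            traces_out[s][k] = val
        res_pois[k] = sol.last_poisson_residual
        res_cont[k] = sol.last_divergence
        umax = max(umax, float(np.abs(sol.state.u).max()),
                   float(np.abs(sol.state.v).max()))
        if k % snap_every == 0 and len(snaps["times"]) < settings.n_snapshots:
            snaps["times"].append(sol.state.time)
            for key, arr in (("u", sol.state.u), ("v", sol.state.v),
                             ("p", sol.state.p), ("mu", sol.state.mu)):
                snaps[key].append(arr.copy())

    rec = CycleRecord(
        cycle_index=cyc, phase_times=phase,
        probe_pressure={s: np.interp(phase, tp, traces_p[s]) for s in station_names},
        probe_velocity={s: np.interp(phase, tp, traces_v[s]) for s in station_names},
        flux={s: np.interp(phase, tp, traces_q[s]) for s in station_names},
        outlet_flux={s: np.interp(phase, tp, traces_out[s]) for s in traces_out},
        poisson_residuals=res_pois, continuity_residuals=res_cont,
        u_max=umax, dt=dt, h=sol.h)
    return rec, snaps


def run_until_steady(geom, props, bc, settings=None, t_max=10.0,
                     tol=1e-6, check_every=50):
    """Step a constant-BC problem to steady state (for analytic benchmarks).

    Convergence criterion: relative change of the velocity field per unit
    time below ``tol`` / s.
    """
    settings = settings or SolverSettings()
    sol = FlowSolver(geom, props, bc, settings)
    dt = sol.suggest_dt(period=1.0)
    u_prev = None
    while sol.state.time < t_max:
        for _ in range(check_every):
            sol.step(dt)
        scale = max(np.abs(sol.state.u).max(), 1e-12)
        if u_prev is not None:
            rate = np.abs(sol.state.u - u_prev).max() / (scale * dt * check_every)
            if rate < tol:
                return sol
        u_prev = sol.state.u.copy()
        dt = min(sol.suggest_dt(period=1.0), dt)
    return sol


def residual_report(record: CycleRecord) -> float:
    """Max normalized residual (momentum-closure and continuity) over a cycle.

    The momentum residual is the relative residual of the pressure Poisson
    solve (the linear closure of the momentum update); the continuity
    residual is the post-projection divergence normalized by U_max / h.
    """
    if record.poisson_residuals is None or len(record.poisson_residuals) == 0:
        raise ValueError("empty cycle record")
    u_ref = max(record.u_max, 1e-12)
    # divergence carries 1/s; normalize by the cell-crossing rate U_ref / h
    cont_norm = record.continuity_residuals.max() * record.h / u_ref
    return float(max(record.poisson_residuals.max(), cont_norm))


def grid_convergence_study(runner, spacings):
    """Key outputs vs. grid spacing with successive relative differences.

    ``runner`` maps a spacing (m) to a dict of scalar outputs (e.g.
    cycle-mean probe pressures/flows, peak wall shear).  Returns a pandas
    DataFrame with one row per spacing plus ``rel_diff_<key>`` columns
    comparing consecutive rows.
    """
    import pandas as pd

    if len(spacings) < 2:
        raise ValueError("need at least two spacings")
    rows = []
    for h in spacings:
        out = dict(runner(h))
        out["spacing"] = h
        rows.append(out)
    df = pd.DataFrame(rows)
    keys = [k for k in rows[0] if k != "spacing"]
    for k in keys:
        vals = df[k].to_numpy(dtype=float)
        rel = np.full(len(vals), np.nan)
        denom = np.where(np.abs(vals[:-1]) > 0, np.abs(vals[:-1]), np.nan)
        rel[1:] = np.abs(np.diff(vals)) / denom
        df[f"rel_diff_{k}"] = rel
    return df
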