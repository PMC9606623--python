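# Methods

## Scope and idealization

The package models the acute hemodynamics of hemorrhage and aortic
balloon occlusion in a **planar (2D) idealization** of the porcine
aorta.  A subject-specific 3D geometry requires imaging data that cannot
ship with a software package; the planar analogue preserves every
mechanism the analysis interrogates — pulsatile inertia, the flow split
between supra-aortic branches and the descending aorta, the occlusion
jet and its wall shear, recirculation and shear oscillation — at desk
scale.  Quantities that depend on 3D secondary flows (absolute OSI
levels, circumferential shear distribution) are **not** quantitatively
comparable to 3D or in vivo values; the package's quantitative claims
are restricted to boundary-condition synthesis, calibration closure,
rheology, occlusion geometry, conservation and convergence behavior,
plus directional comparisons between phases.

Geometry defaults (all overridable in the scenario config):

| parameter | default | note |
|---|---|---|
| ascending lumen diameter | 2.0 cm | plausible porcine aortic root scale |
| descending lumen diameter | 1.4323 cm | back-computed so the stock balloon occludes 96.35% of diameter |
| arch centerline radius | 2.5 cm | |
| branch diameters | 0.8 / 0.7 cm | brachiocephalic, left subclavian |
| balloon | 10.5 cm x 1.38 cm | stock ER-REBOA dimensions |
| balloon center station | 8.25 cm below arch center | proximal shoulder ~3 cm distal to the subclavian takeoff (Zone 1) |

The lumen is the zero super-level set of an analytic level function
(exact on the vessel walls), rasterized on a uniform Cartesian grid.
The one-cell smoothed solid fraction is exported for inspection and wall
sampling; a geometry build refuses grids that resolve the narrowest
branch with fewer than 8 cells.

**Under-resolved partial-occlusion gap.**  The 96.35% occlusion leaves a
0.26 mm annular gap per side — below any affordable solver grid.  The
rasterization is topology-preserving: when the boolean mask would close
a side of the gap, the one cell nearest that side's gap centerline stays
fluid.  A coarse grid therefore *overestimates* the leak cross-section
(one cell instead of 0.26 mm per side); the representation converges to
the true gap as spacing shrinks, and no quantitative acceptance result
depends on the trans-balloon flow magnitude.

## Fluid and rheology

Blood: incompressible, homogeneous, shear-thinning Carreau fluid
(rho = 1060 kg/m^3, mu_inf = 0.0035 Pa s, mu_0 = 0.056 Pa s,
lambda = 3.313 s, n = 0.368).  The scalar shear rate is the standard
generalized-Newtonian invariant sqrt(2 D:D); lambda carries seconds so
lambda*gdot is dimensionless.  The law is the Carreau form (a fixed
Yasuda exponent of 2); `newtonian_override` freezes the viscosity for
analytic validation.  Note the law itself leaves
mu(1e9 /s) - mu_inf = 5e-8 Pa s, so "infinite-shear" checks use an
absolute tolerance.

## Flow solver

Staggered (MAC) uniform grid; Brinkman volume penalization with an
implicit drag -(chi/eta) u, eta = 1e-8 s.  Drag acts only on
solid-centered cells (chi >= 1/2): applying the stiff drag inside the
fluid half of the smoothed interface band would effectively narrow every
vessel by about one cell and seal under-resolved gaps.  The pressure
Poisson operator lives on the binary fluid mask with solid faces closed,
so wall-normal mass flux is identically zero and global mass
conservation is limited only by the linear solve (direct sparse LU,
factorized once per geometry; runs are bit-reproducible).

Time integration: explicit second-order upwind-biased advection (first
order in the two cells nearest a boundary), explicit variable-viscosity
stress divergence with the viscosity lagged one step (Picard), implicit
penalization, first-order pressure projection.  The step is chosen per
cycle from an advective CFL of 0.4 against a running velocity estimate
(with headroom) and the explicit diffusive limit; a mid-cycle CFL
violation restarts the cycle with a smaller step and is an error after
four attempts.

Boundary conditions: the inlet carries a parabolic profile rescaled
every step so the discrete flux equals Q_in(t) exactly; outlets are
pressure-Dirichlet at the boundary faces (ghost value 2 p_out - p) with
zero-gradient velocity extrapolation; during outlet inflow the upwind
ghosts are zero-gradient, which proved a sufficient backflow treatment
at the high heart rates of the occlusion phases.  Walls are rigid and
no-slip.

Cycles are advanced until the relative L2 difference of consecutive
cycles' probe-pressure traces falls below 1e-2, up to 8 cycles.  On the
default coarse grid the metric typically plateaus at 1-5% — the planar
junction flows shed vortices and are not exactly periodic — in which
case the result is returned flagged (`periodic=False`) with a warning,
never silently.

`residual_report` returns the maximum over the final cycle of (a) the
relative residual of the pressure-Poisson solve (the linear closure of
the momentum update) and (b) the post-projection divergence normalized
by U_max/h.  With the direct solver both sit near machine precision; a
deliberately crippled iterative solve (one Jacobi sweep) fails the 1e-3
criterion, which the tests use as a negative control.

## Boundary-condition synthesis and calibration

Waveform family: inlet flow is a half-sine systolic ejection over a
systolic fraction (default 0.35) with an optional reverse-flow notch,
rescaled so the cycle mean equals CO exactly; outlet pressure is a
half-cosine rise to the systolic value with an exponential diastolic
decay (decay constant 3 per cycle), periodic by construction with exact
extrema.  When only a MAP is given, pulse pressure defaults to MAP/2
with diastolic = MAP - PP/3, and the waveform is shifted to pin the time
mean to the MAP exactly.  The two supra-aortic outlets share one
waveform.

The distal (thoracic) outlet is calibrated: its mean level is the only
control.  Because each evaluation of the coarse-grid plant carries
cycle-to-cycle noise of a few percent, the level is updated by a damped,
step-capped linear regression of simulated flow on control level over
the whole iteration history (each iteration also averages its flow and
pressure means over two cycles), until both the cycle-mean
descending-aorta flow and the subclavian probe pressure match the
reference within 5%.  A reference mean flow above the inlet CO (beyond tolerance) is
rejected up front as unreachable.  In the planar geometry the wide,
short branch channels take most of the stroke at equal outlet pressures,
so matching a distal flow near CO drives the calibrated distal level
tens of mmHg below the supra waveform — the 2D counterpart of tuning a
single outlet to reproduce measured flows.  The p-REBOA scenario's
default (uncalibrated) distal level sits 70 mmHg below the supra
waveform, reflecting the collapse of distal arterial pressure to roughly
a third of proximal MAP during high-grade occlusion.

## Wall shear metrics

Wall samples are resampled at one grid spacing along the zero-level-set
contours, with inward normals from the level-function gradient.  The
signed wall shear rate is the one-sided second-order normal derivative
of the tangential velocity at the wall, (4 u_1 - u_2)/(2h) from probes
one and two spacings inside the lumen (first-to-second order accurate at
penalized boundaries); wall shear stress multiplies by the apparent
viscosity at that rate.  TAWSS/TAWSR are trapezoidal time averages of
the magnitudes over one period; OSI = (1/2)(1 - |int wss| / int |wss|),
defined as 0 (flagged) where the shear vanishes identically.  In 2D the
wall shear "vector" is a signed tangential scalar, making these exactly
the standard 3D definitions.  Regional values are arc-length-weighted
means; the `balloon` region comprises the balloon surface *and* the
vessel wall within the balloon's axial extent, where the residual-gap
jet acts.  Samples whose interior probes leave the lumen (the sealed
mid-plane of a full occlusion, port corners) are flagged, not dropped.

## Synthetic recordings

The cohort generator draws per-animal CO/HR/MAP from the study arms'
per-phase means and SDs (independently — no covariances are reported),
truncated at physiologic floors (CO > 0.5 L/min, HR > 40 bpm,
MAP > 20 mmHg), and renders subclavian/femoral pressure and
descending-aorta flow traces from the waveform family with beat-period
jitter (CV 3%) and additive measurement noise (1 mmHg, 0.05 L/min) at
250 Hz.  The flow trace is expressed as inlet-equivalent flow (noise-free
mean = CO), mirroring the experimental practice of scaling the distal
flow waveform to the Swan-Ganz cardiac output.  What the generator does
*not* emulate: reflex physiology, hemorrhage volume kinetics, waveform
shape details beyond the two-parameter family, or correlated
hemodynamic variables — so passing calibration tests demonstrates
closure of the loop against data with the study's first- and
second-moment structure, not fidelity to real waveform morphology.

## Scenario defaults and problem sizes

Simulated phases use CO/HR of 6.5 L/min at 114 bpm (baseline),
4.8 at 192 (hemorrhage), 6.0 at 240 (f-REBOA), 4.5 at 180 (p-REBOA),
with supra-aortic pressures 93/62, 74/42, 147/103 and 144/86 mmHg.  The
cohort generator instead carries the group tables (e.g. f-REBOA arm
baseline CO 6.9 +/- 0.9 L/min, MAP 83 +/- 7 mmHg), whose occlusion-phase
CO differs from the simulated f-REBOA value; both sets are kept, as
configuration defaults and generator defaults respectively.

The default solver grid spacing is 0.85 mm (the coarsest spacing that
resolves the 7 mm subclavian with 8 cells), giving an 88 x 248 grid and
2-4 thousand time steps per cardiac cycle; a scenario cycle runs in tens
of seconds on one core.  Validation cases use channels of 16-64 cells
across.  The out-of-plane depth used to convert 2D fluxes to L/min is
pi/4 times the ascending diameter, which makes the mean inlet velocity
match its 3D counterpart at equal CO.

## Known limitations

* Absolute pressures, velocities and shear levels carry 2D junction and
  recirculation artifacts; only cycle means at calibrated stations and
  cross-phase orderings are interpreted.
* The baseline planar flow is already strongly oscillatory (regional
  OSI ~0.2-0.4), and the sealed distal cavity of a full occlusion admits
  no net flux and settles into a slow unidirectional recirculation, so
  the elevation of proximal OSI by full occlusion seen in 3D does not
  reproduce in this idealization (its acceptance check is accordingly
  red, with the analysis above).
* Rigid walls (no FSI), laminar model at transitional Reynolds numbers,
  no distal arterial branches below the balloon, no oxygen transport or
  autoregulation.
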