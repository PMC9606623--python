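"""Idealized porcine aortic geometry with a parametric REBOA balloon.

The vessel tree is a planar (2D) idealization of the porcine aorta: a
vertical ascending segment, a semicircular arch carrying two supra-aortic
branch channels (brachiocephalic trunk and left subclavian artery), and a
vertical descending thoracic segment.  The domain has one inlet (ascending
aorta, bottom edge), two supra-aortic pressure outlets (top edge) and one
distal thoracic outlet (bottom edge) — the same topology as the
reconstructed 3D geometry this idealizes.

The lumen is described by a level function (positive inside the lumen,
exact zero set on the vessel walls) sampled on a uniform Cartesian grid.
A REBOA balloon (capsule or ellipse) can be subtracted from the lumen in
``partial`` mode, or combined with a full-width occlusion wall at its
mid-plane in ``full`` mode, in which case the distal outlet label is
removed and the distal lumen becomes a closed cavity.

The default descending lumen diameter (1.4323 cm) is back-computed so the
stock 10.5 cm x 1.38 cm balloon occludes 96.35% of the local diameter.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np
from scipy import ndimage

__all__ = [
    "AortaParams",
    "BalloonSpec",
    "BalloonMode",
    "AorticGeometry",
    "Port",
    "build_aorta",
    "build_channel",
    "insert_balloon",
    "occlusion_fraction",
    "ResolutionError",
    "GeometryError",
]

WALL_REGIONS = ("ascending", "arch", "supra_1", "supra_2",
                "descending_proximal", "balloon", "descending_distal")


class ResolutionError(ValueError):
    """Grid spacing too coarse for the narrowest lumen passage."""


class GeometryError(ValueError):
    """Invalid geometric parameters."""


class BalloonMode(str, Enum):
    none = "none"
    full = "full"
    partial = "partial"


@dataclass(frozen=True)
class AortaParams:
    """Idealized aorta dimensions (m).

    ``branch_positions`` are arc-length coordinates along the arch outer
    wall, measured from the ascending side.  ``segment_lengths`` are the
    lengths of the ascending and descending vertical segments (inlet and
    distal outlet both sit on the bottom domain edge).
    """

    ascending_diameter: float = 0.020
    descending_diameter: float = 0.0138 / 0.9635  # stock balloon -> 96.35% of diameter
    arch_radius: float = 0.025
    branch_diameters: tuple[float, float] = (0.008, 0.007)
    branch_positions: tuple[float, float] = (0.0336, 0.0611)
    segment_lengths: tuple[float, float] = (0.16, 0.16)
    branch_clearance: float = 0.015  # branch channel run above the arch apex

    def __post_init__(self):
        dims = (self.ascending_diameter, self.descending_diameter, self.arch_radius,
                *self.branch_diameters, *self.branch_positions, *self.segment_lengths,
                self.branch_clearance)
        if any(d <= 0 for d in dims):
            raise GeometryError("all lengths must be positive")
        arc_total = np.pi * self.outer_wall_radius
        for s in self.branch_positions:
            if not (0 < s < arc_total):
                raise GeometryError(
                    f"branch position {s:.4f} m outside arch outer wall (0, {arc_total:.4f})")

    @property
    def outer_wall_radius(self) -> float:
        return self.arch_radius + self.ascending_diameter / 2.0

    @property
    def branch_angles(self) -> tuple[float, ...]:
        """Branch takeoff angles (rad) from the ascending side of the arch."""
        return tuple(s / self.outer_wall_radius for s in self.branch_positions)


@dataclass(frozen=True)
class BalloonSpec:
    """REBOA balloon: stock ER-REBOA dimensions by default.

    ``center_station`` is the distance of the balloon center below the arch
    center height, along the descending centerline (Zone 1 placement: the
    proximal shoulder sits ~3 cm distal to the left subclavian takeoff).
    """

    length: float = 0.105
    max_diameter: float = 0.0138
    center_station: float = 0.0825
    mode: BalloonMode = BalloonMode.none
    shape: str = "capsule"  # "capsule" | "ellipse"

    def __post_init__(self):
        if self.length <= 0 or self.max_diameter <= 0:
            raise GeometryError("balloon length and diameter must be positive")
        if self.shape not in ("capsule", "ellipse"):
            raise GeometryError(f"unknown balloon shape {self.shape!r}")


@dataclass(frozen=True)
class Port:
    """One opening of the lumen onto the domain boundary."""

    name: str
    kind: str            # "inlet" | "pressure"
    edge: str            # "bottom" | "top" | "left" | "right"
    indices: np.ndarray  # along-edge cell indices
    coords: np.ndarray   # face-center coordinate along the edge (m)


@dataclass
class AorticGeometry:
    """Discretized vascular domain on a uniform Cartesian grid.

    ``sdf`` is the level function (m, positive in the lumen, zero on walls,
    balloon subtracted), ``lumen_sdf`` the same without the balloon, and
    ``chi`` the solid fraction used by the penalization solver (edge
    smoothed over one cell).  ``fluid`` is the binary lumen mask used for
    connectivity and the pressure solve.  Arrays are indexed ``[i, j]``
    with cell centers at ``origin + (index + 0.5) * spacing``.
    """

    params: AortaParams | None
    balloon: BalloonSpec
    spacing: float
    nx: int
    ny: int
    origin: tuple[float, float]
    depth: float                       # out-of-plane depth for flux reporting
    sdf: np.ndarray
    lumen_sdf: np.ndarray
    balloon_sdf: np.ndarray | None
    chi: np.ndarray
    fluid: np.ndarray
    ports: list[Port]
    stations: dict = field(default_factory=dict)
    wall_samples: dict | None = None
    meta: dict = field(default_factory=dict)

    # -- coordinates -------------------------------------------------------
    def cell_x(self):
        return self.origin[0] + (np.arange(self.nx) + 0.5) * self.spacing

    def cell_y(self):
        return self.origin[1] + (np.arange(self.ny) + 0.5) * self.spacing

    def port(self, name: str) -> Port:
        for p in self.ports:
            if p.name == name:
                return p
        raise KeyError(name)

    @property
    def lumen_area(self) -> float:
        return float(np.count_nonzero(self.fluid)) * self.spacing ** 2

    # -- measurements ------------------------------------------------------
    def _row_widths(self, f: np.ndarray, y: float) -> list[tuple[float, float]]:
        """Sub-cell intervals where field ``f`` > 0 along the row nearest y."""
        j = int(np.clip(round((y - self.origin[1]) / self.spacing - 0.5), 0, self.ny - 1))
        row = f[:, j]
        x = self.cell_x()
        intervals = []
        inside = row > 0
        idx = np.flatnonzero(np.diff(inside.astype(int)))
        crossings = []
        for i in idx:
            f0, f1 = row[i], row[i + 1]
            crossings.append(x[i] + (0.0 - f0) / (f1 - f0) * self.spacing)
        if inside[0]:
            crossings.insert(0, x[0])
        if inside[-1]:
            crossings.append(x[-1])
        for a, b in zip(crossings[::2], crossings[1::2]):
            intervals.append((a, b))
        return intervals

    def local_lumen_diameter(self, y: float) -> float:
        """Lumen diameter (m) measured from the discretized level function,
        at height ``y``, ignoring the balloon."""
        intervals = self._row_widths(self.lumen_sdf, y)
        if not intervals:
            raise GeometryError(f"no lumen at y = {y:.4f} m")
        # descending segment = rightmost interval at this height
        a, b = intervals[-1]
        return b - a

    def connectivity_ok(self) -> bool:
        """True when a fluid path connects the inlet to the distal port."""
        labels, _ = ndimage.label(self.fluid)
        inlet = self.port("inlet")
        linlet = set(labels[inlet.indices, 0]) - {0}
        try:
            distal = self.port("distal")
            ldistal = set(labels[distal.indices, 0]) - {0}
        except KeyError:
            # full mode: the distal cavity exists but carries no port
            jb = int(round((self.meta["y_balloon"] - 0.06 - self.origin[1])
                           / self.spacing - 0.5))
            jb = int(np.clip(jb, 0, self.ny - 1))
            in_desc = self.cell_x() > self.meta["x_c"]
            cav = np.flatnonzero(self.fluid[:, jb] & in_desc)
            ldistal = set(labels[cav, jb]) - {0}
        return bool(linlet & ldistal)


# ---------------------------------------------------------------------------
# level functions
# ---------------------------------------------------------------------------

def _lumen_level(params: AortaParams, x, y, layout):
    """Level function of the balloon-free lumen (positive inside)."""
    x_asc, x_c, x_desc, y_c = (layout[k] for k in ("x_asc", "x_c", "x_desc", "y_c"))
    da, dd, R = params.ascending_diameter, params.descending_diameter, params.arch_radius

    f_asc = np.minimum(da / 2 - np.abs(x - x_asc), y_c - y)
    f_desc = np.minimum(dd / 2 - np.abs(x - x_desc), y_c - y)

    r = np.hypot(x - x_c, y - y_c)
    theta = np.arctan2(np.maximum(y - y_c, 0.0), x - x_c)  # 0 at descending, pi ascending
    phi = np.pi - theta                                     # 0 at ascending side
    w = da / 2 + (dd / 2 - da / 2) * (phi / np.pi)
    f_arch = np.minimum(w - np.abs(r - R), y - y_c)

    f = np.maximum(np.maximum(f_asc, f_desc), f_arch)
    for d_k, phi_k in zip(params.branch_diameters, params.branch_angles):
        x_b = x_c - R * np.cos(phi_k)
        y_start = y_c + np.sqrt(np.maximum(R ** 2 - (x - x_c) ** 2, 0.0))
        f_branch = np.minimum(d_k / 2 - np.abs(x - x_b), y - y_start)
        f = np.maximum(f, f_branch)
    return f


def _balloon_level(spec: BalloonSpec, x, y, layout):
    """Level function of the balloon body (positive inside the balloon)."""
    x_desc = layout["x_desc"]
    y_b = layout["y_c"] - spec.center_station
    if spec.shape == "capsule":
        hl = max(spec.length / 2 - spec.max_diameter / 2, 0.0)
        dy = np.maximum(np.abs(y - y_b) - hl, 0.0)
        return spec.max_diameter / 2 - np.hypot(x - x_desc, dy)
    a, b = spec.max_diameter / 2, spec.length / 2
    q = np.sqrt(((x - x_desc) / a) ** 2 + ((y - y_b) / b) ** 2)
    return (1.0 - q) * min(a, b)


# ---------------------------------------------------------------------------
# builders
# ---------------------------------------------------------------------------

def _layout(params: AortaParams, h: float) -> dict:
    margin = max(2.5 * h, 0.002)
    x_asc = margin + params.ascending_diameter / 2
    x_c = x_asc + params.arch_radius
    x_desc = x_c + params.arch_radius
    y_c = max(params.segment_lengths)
    r_out = params.outer_wall_radius
    Lx = x_c + r_out + margin
    Ly = y_c + r_out + params.branch_clearance
    return dict(margin=margin, x_asc=x_asc, x_c=x_c, x_desc=x_desc, y_c=y_c,
                r_out=r_out, Lx=Lx, Ly=Ly)


def build_aorta(params: AortaParams | None = None, grid_spacing: float = 0.5e-3,
                balloon: BalloonSpec | None = None,
                depth: float | None = None) -> AorticGeometry:
    """Discretize the idealized aorta (optionally with a balloon inserted).

    Raises :class:`ResolutionError` if the narrowest lumen passage spans
    fewer than 8 cells, and :class:`GeometryError` for invalid parameters.
    """
    params = params or AortaParams()
    balloon = balloon or BalloonSpec()
    h = float(grid_spacing)
    if h <= 0:
        raise GeometryError("grid spacing must be positive")
    narrowest = min(params.ascending_diameter, params.descending_diameter,
                    *params.branch_diameters)
    if narrowest / h < 8.0:
        raise ResolutionError(
            f"spacing {h * 1e3:.2f} mm gives {narrowest / h:.1f} cells across the "
            f"narrowest lumen ({narrowest * 1e3:.1f} mm); need >= 8")

    lay = _layout(params, h)
    nx, ny = int(np.ceil(lay["Lx"] / h)), int(np.ceil(lay["Ly"] / h))
    origin = (0.0, 0.0)
    x = origin[0] + (np.arange(nx) + 0.5) * h
    y = origin[1] + (np.arange(ny) + 0.5) * h
    X, Y = np.meshgrid(x, y, indexing="ij")

    lumen = _lumen_level(params, X, Y, lay)
    y_b = lay["y_c"] - balloon.center_station
    bal = None
    sdf = lumen.copy()
    if balloon.mode != BalloonMode.none:
        _validate_balloon(params, balloon, lay, h)
        bal = _balloon_level(balloon, X, Y, lay)
        solid_extra = bal.copy()
        if balloon.mode == BalloonMode.full:
            hs = max(1.5 * h, 0.0015)
            slab = np.minimum(hs - np.abs(Y - y_b),
                              (params.descending_diameter / 2 + 2 * h)
                              - np.abs(X - lay["x_desc"]))
            solid_extra = np.maximum(solid_extra, slab)
        sdf = np.minimum(lumen, -solid_extra)

    fluid = sdf > 0.0
    chi = np.clip(0.5 - sdf / h, 0.0, 1.0)

    if balloon.mode == BalloonMode.partial:
        _preserve_gap(fluid, chi, params, balloon, lay, x, y, h)

    ports = _make_ports(params, balloon, lay, fluid, x, y, h)
    geom = AorticGeometry(
        params=params, balloon=balloon, spacing=h, nx=nx, ny=ny, origin=origin,
        depth=depth if depth is not None else np.pi * params.ascending_diameter / 4,
        sdf=sdf, lumen_sdf=lumen, balloon_sdf=bal, chi=chi, fluid=fluid,
        ports=ports, meta=dict(lay, y_balloon=y_b))
    geom.stations = _make_stations(geom)
    geom.wall_samples = sample_walls(geom)
    return geom


def _validate_balloon(params, balloon, lay, h):
    y_c = lay["y_c"]
    cs, L = balloon.center_station, balloon.length
    if L + 4 * h > y_c:
        raise GeometryError("balloon longer than the descending segment")
    if cs - L / 2 < 2 * h or cs + L / 2 > y_c - 2 * h:
        raise GeometryError("balloon does not fit inside the descending segment")
    if balloon.mode == BalloonMode.partial and \
            balloon.max_diameter >= params.descending_diameter:
        raise GeometryError("partial-mode balloon must be narrower than the lumen")


def _preserve_gap(fluid, chi, params, balloon, lay, x, y, h):
    """Keep the annular gap topologically open when it is under-resolved.

    The physical gap beside a high-degree partial occlusion (0.26 mm per
    side for the stock balloon) can be narrower than one grid cell.  For
    each row crossed by the balloon, if the boolean mask closed a side of
    the gap, the cell nearest the gap centerline on that side is kept
    fluid.  Coarse grids therefore overestimate the leak cross-section;
    the rasterization converges to the true gap as spacing shrinks.
    """
    x_desc, y_c = lay["x_desc"], lay["y_c"]
    y_b = y_c - balloon.center_station
    wall_l = x_desc - params.descending_diameter / 2
    wall_r = x_desc + params.descending_diameter / 2
    # fixed carve column per side (first cell center inside each wall) so the
    # preserved gap is vertically 4-connected along the whole balloon
    i_left = int(np.searchsorted(x, wall_l))
    i_right = int(np.searchsorted(x, wall_r)) - 1
    hl = max(balloon.length / 2 - balloon.max_diameter / 2, 0.0)
    for j in np.flatnonzero(np.abs(y - y_b) <= balloon.length / 2):
        dy = max(abs(y[j] - y_b) - hl, 0.0)
        if balloon.shape == "capsule":
            arg = (balloon.max_diameter / 2) ** 2 - dy ** 2
            if arg <= 0:
                continue
            wb = float(np.sqrt(arg))
        else:
            frac = 1 - (2 * (y[j] - y_b) / balloon.length) ** 2
            if frac <= 0:
                continue
            wb = balloon.max_diameter / 2 * float(np.sqrt(frac))
        for i_carve, lo, hi in ((i_left, wall_l, x_desc - wb),
                                (i_right, x_desc + wb, wall_r)):
            cells = np.flatnonzero((x > lo) & (x < hi))
            if len(cells) == 0 or not fluid[cells, j].any():
                fluid[i_carve, j] = True
                chi[i_carve, j] = 0.0


def _make_ports(params, balloon, lay, fluid, x, y, h):
    ports = []
    x_asc, x_desc, x_c = lay["x_asc"], lay["x_desc"], lay["x_c"]
    bottom = np.flatnonzero(fluid[:, 0])
    inlet = bottom[np.abs(x[bottom] - x_asc) < params.ascending_diameter]
    if len(inlet) == 0:
        raise GeometryError("inlet does not reach the domain boundary")
    ports.append(Port("inlet", "inlet", "bottom", inlet, x[inlet]))
    if balloon.mode != BalloonMode.full:
        distal = bottom[np.abs(x[bottom] - x_desc) < params.descending_diameter]
        if len(distal) == 0:
            raise GeometryError("distal outlet does not reach the domain boundary")
        ports.append(Port("distal", "pressure", "bottom", distal, x[distal]))
    top = np.flatnonzero(fluid[:, -1])
    R = params.arch_radius
    for k, phi_k in enumerate(params.branch_angles):
        x_b = x_c - R * np.cos(phi_k)
        sel = top[np.abs(x[top] - x_b) < params.branch_diameters[k]]
        if len(sel) == 0:
            raise GeometryError(f"supra-aortic outlet {k + 1} does not reach the boundary")
        ports.append(Port(f"supra_{k + 1}", "pressure", "top", sel, x[sel]))
    return ports


def _make_stations(geom: AorticGeometry) -> dict:
    """Probe cells and flux cross-sections at named anatomical stations."""
    lay, params, h = geom.meta, geom.params, geom.spacing
    x, y = geom.cell_x(), geom.cell_y()
    y_c, x_c, x_asc, x_desc = lay["y_c"], lay["x_c"], lay["x_asc"], lay["x_desc"]
    y_b = lay["y_balloon"]
    R = params.arch_radius
    L = geom.balloon.length

    def nearest_fluid_cell(px, py):
        i0 = int(np.clip(round(px / h - 0.5), 0, geom.nx - 1))
        j0 = int(np.clip(round(py / h - 0.5), 0, geom.ny - 1))
        if geom.fluid[i0, j0]:
            return i0, j0
        fi, fj = np.nonzero(geom.fluid)
        k = np.argmin((fi - i0) ** 2 + (fj - j0) ** 2)
        return int(fi[k]), int(fj[k])

    def hline(py, xc, half_w, sign=1):
        # sign = +1 when physiologic flow direction is +y at this station
        j = int(np.clip(round(py / h), 1, geom.ny - 1))  # v-face row index
        cols = np.flatnonzero(np.abs(x - xc) <= half_w + h)
        return ("y", j, cols, sign)

    phi2 = params.branch_angles[1]
    x_b2 = x_c - R * np.cos(phi2)
    phi1 = params.branch_angles[0]
    x_b1 = x_c - R * np.cos(phi1)
    y_top = geom.origin[1] + geom.ny * h
    stations = {
        "ascending": dict(probe=nearest_fluid_cell(x_asc, 0.4 * y_c),
                          flux=hline(0.4 * y_c, x_asc, params.ascending_diameter / 2)),
        "supra_1": dict(probe=nearest_fluid_cell(x_b1, y_top - 0.4 * params.branch_clearance),
                        flux=hline(y_top - 0.4 * params.branch_clearance, x_b1,
                                   params.branch_diameters[0] / 2)),
        "subclavian": dict(probe=nearest_fluid_cell(x_b2, y_top - 0.4 * params.branch_clearance),
                           flux=hline(y_top - 0.4 * params.branch_clearance, x_b2,
                                      params.branch_diameters[1] / 2)),
        "descending_proximal": dict(
            probe=nearest_fluid_cell(x_desc, min(y_b + L / 2 + 0.01, y_c - 0.01)),
            flux=hline(min(y_b + L / 2 + 0.01, y_c - 0.01), x_desc,
                       params.descending_diameter / 2, sign=-1)),
        "descending_distal": dict(
            probe=nearest_fluid_cell(x_desc, max(y_b - L / 2 - 0.01, 0.005)),
            flux=hline(max(y_b - L / 2 - 0.01, 0.005), x_desc,
                       params.descending_diameter / 2, sign=-1)),
    }
    return stations


def insert_balloon(geom: AorticGeometry, spec: BalloonSpec) -> AorticGeometry:
    """Insert (or replace) the balloon, returning a new geometry.

    ``mode = none`` returns the balloon-free geometry; ``full`` closes the
    lumen at the balloon mid-plane (no inlet-to-distal fluid path remains
    and the distal outlet label is removed); ``partial`` leaves an open
    two-sided gap.
    """
    return build_aorta(geom.params, geom.spacing, balloon=spec, depth=geom.depth)


def occlusion_fraction(geom: AorticGeometry, spec: BalloonSpec | None = None) -> float:
    """Percent of the local lumen diameter occluded at the balloon mid-plane.

    Measured on the discretized geometry: the local lumen diameter comes
    from the zero crossings of the balloon-free level function along the
    mid-plane row (sub-cell linear interpolation).  Returns 100 for full
    occlusion; raises for ``mode = none``.
    """
    spec = spec or geom.balloon
    if spec.mode == BalloonMode.none:
        raise GeometryError("occlusion fraction undefined without a balloon")
    if spec.mode == BalloonMode.full:
        return 100.0
    y_b = geom.meta["y_c"] - spec.center_station
    lumen_d = geom.local_lumen_diameter(y_b)
    return 100.0 * spec.max_diameter / lumen_d


# ---------------------------------------------------------------------------
# wall sampling
# ---------------------------------------------------------------------------

def sample_walls(geom: AorticGeometry, spacing_cells: float = 1.0) -> dict:
    """Ordered wall sample points with unit normals, tangents and regions.

    Walls are the zero level set of ``sdf``; samples are resampled at
    ``spacing_cells`` grid spacings of arc length along each contour.
    Inward normals follow the gradient of the level function; tangents
    follow the contour orientation.
    """
    from skimage import measure

    h = geom.spacing
    contours = measure.find_contours(geom.sdf, 0.0)
    gx, gy = np.gradient(geom.sdf, h)
    xs, ys, nxs, nys, txs, tys, arcs, cids = [], [], [], [], [], [], [], []
    for cid, c in enumerate(contours):
        pts = (c + 0.5) * h  # index -> physical coordinates
        seg = np.diff(pts, axis=0)
        ds = np.hypot(seg[:, 0], seg[:, 1])
        s = np.concatenate([[0.0], np.cumsum(ds)])
        if s[-1] < 2 * h:
            continue
        n_samp = max(int(s[-1] / (spacing_cells * h)), 2)
        si = np.linspace(0, s[-1], n_samp)
        px = np.interp(si, s, pts[:, 0])
        py = np.interp(si, s, pts[:, 1])
        # tangent from contour ordering
        tx = np.gradient(px, si, edge_order=1)
        ty = np.gradient(py, si, edge_order=1)
        tn = np.hypot(tx, ty)
        tn[tn == 0] = 1.0
        tx, ty = tx / tn, ty / tn
        # inward normal from the level-function gradient
        ii = np.clip(px / h - 0.5, 0, geom.nx - 1.001)
        jj = np.clip(py / h - 0.5, 0, geom.ny - 1.001)
        nxv = _bilinear(gx, ii, jj)
        nyv = _bilinear(gy, ii, jj)
        nn = np.hypot(nxv, nyv)
        nn[nn == 0] = 1.0
        nxv, nyv = nxv / nn, nyv / nn
        xs.append(px); ys.append(py)
        nxs.append(nxv); nys.append(nyv)
        txs.append(tx); tys.append(ty)
        arcs.append(si); cids.append(np.full(n_samp, cid))
    out = dict(
        x=np.concatenate(xs), y=np.concatenate(ys),
        normal_x=np.concatenate(nxs), normal_y=np.concatenate(nys),
        tangent_x=np.concatenate(txs), tangent_y=np.concatenate(tys),
        arc=np.concatenate(arcs), contour=np.concatenate(cids))
    if geom.params is None:  # validation channel: no anatomical regions
        out["region"] = np.full(len(out["x"]), "wall", dtype=object)
    else:
        out["region"] = _classify_regions(geom, out["x"], out["y"])
    return out


def _bilinear(f, ii, jj):
    i0 = np.floor(ii).astype(int)
    j0 = np.floor(jj).astype(int)
    i1 = np.minimum(i0 + 1, f.shape[0] - 1)
    j1 = np.minimum(j0 + 1, f.shape[1] - 1)
    fx, fy = ii - i0, jj - j0
    return ((1 - fx) * (1 - fy) * f[i0, j0] + fx * (1 - fy) * f[i1, j0]
            + (1 - fx) * fy * f[i0, j1] + fx * fy * f[i1, j1])


def _classify_regions(geom: AorticGeometry, x, y):
    lay, params, h = geom.meta, geom.params, geom.spacing
    y_c, x_c, x_desc = lay["y_c"], lay["x_c"], lay["x_desc"]
    y_b = lay["y_balloon"]
    R = params.arch_radius
    region = np.empty(len(x), dtype=object)
    near_balloon = np.zeros(len(x), dtype=bool)
    if geom.balloon.mode != BalloonMode.none and geom.balloon_sdf is not None:
        ii = np.clip(x / h - 0.5, 0, geom.nx - 1.001)
        jj = np.clip(y / h - 0.5, 0, geom.ny - 1.001)
        bval = _bilinear(geom.balloon_sdf, ii, jj)
        near_balloon = bval > -2.0 * h
        # the vessel wall alongside the balloon belongs to the occlusion
        # region: that is where the residual-gap jet rubs the endothelium
        near_balloon |= ((np.abs(y - y_b) <= geom.balloon.length / 2 + h)
                         & (np.abs(x - x_desc)
                            < params.descending_diameter / 2 + 2 * h)
                         & (y <= y_c))
        if geom.balloon.mode == BalloonMode.full:
            hs = max(1.5 * h, 0.0015)
            near_balloon |= ((np.abs(y - y_b) < hs + 2 * h)
                             & (np.abs(x - x_desc) < params.descending_diameter / 2 + 2 * h))
    upper = y > y_c
    branch = np.full(len(x), -1)
    for k, phi_k in enumerate(params.branch_angles):
        x_bk = x_c - R * np.cos(phi_k)
        sel = upper & (np.abs(x - x_bk) <= params.branch_diameters[k] / 2 + 1.5 * h) \
            & (y > y_c + np.sqrt(max(R ** 2 - (x_bk - x_c) ** 2, 0.0)) - 1.5 * h)
        branch[sel] = k
    region[upper & (branch == 0)] = "supra_1"
    region[upper & (branch == 1)] = "supra_2"
    region[upper & (branch < 0)] = "arch"
    lower = ~upper
    region[lower & (x < x_c)] = "ascending"
    region[lower & (x >= x_c) & (y >= y_b)] = "descending_proximal"
    region[lower & (x >= x_c) & (y < y_b)] = "descending_distal"
    region[near_balloon] = "balloon"
    return region


# ---------------------------------------------------------------------------
# straight-channel validation geometry
# ---------------------------------------------------------------------------

def build_channel(length: float, height: float, grid_spacing: float,
                  left: str = "inlet", right: str = "pressure",
                  align_walls: bool = True, depth: float = 1.0) -> AorticGeometry:
    """Straight horizontal channel for analytic solver validation.

    With ``align_walls`` the grid is offset half a cell so the channel
    walls y = 0 and y = height fall exactly on cell-center rows, making
    the penalized no-slip condition land on the analytic wall location
    (Poiseuille/Womersley comparisons are then second-order clean).
    ``left``/``right`` choose the port type: "inlet" (prescribed flow),
    "pressure" (Dirichlet pressure), or "wall".
    """
    h = float(grid_spacing)
    if align_walls:
        ny = int(round(height / h)) + 1
        y0 = -h / 2  # cell-center rows land exactly on y = 0 and y = height
    else:
        ny = int(round(height / h)) + 2
        y0 = -1.3 * h  # walls land between cell centers
    nx = int(round(length / h))
    x0 = 0.0
    x = x0 + (np.arange(nx) + 0.5) * h
    y = y0 + (np.arange(ny) + 0.5) * h
    X, Y = np.meshgrid(x, y, indexing="ij")
    sdf = np.minimum(Y, height - Y)
    fluid = sdf > 0
    chi = np.clip(0.5 - sdf / h, 0.0, 1.0)
    ports = []
    rows = np.flatnonzero(fluid[0, :])
    for name, kind, edge, col in (("left", left, "left", 0), ("right", right, "right", nx - 1)):
        if kind == "wall":
            continue
        rr = np.flatnonzero(fluid[col, :])
        pname = "inlet" if kind == "inlet" else name
        ports.append(Port(pname, kind, edge, rr, y[rr]))
    geom = AorticGeometry(
        params=None, balloon=BalloonSpec(mode=BalloonMode.none), spacing=h,
        nx=nx, ny=ny, origin=(x0, y0), depth=depth, sdf=sdf, lumen_sdf=sdf,
        balloon_sdf=None, chi=chi, fluid=fluid, ports=ports,
        meta=dict(height=height, length=length, y_balloon=0.0, y_c=height))
    mid_i = nx // 2
    mid_j = int(np.argmin(np.abs(y - height / 2)))
    geom.stations = {
        "mid": dict(probe=(mid_i, mid_j), flux=("x", mid_i, rows, 1)),
    }
    geom.wall_samples = None
    return geom
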