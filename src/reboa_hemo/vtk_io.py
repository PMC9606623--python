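"""Minimal legacy-ASCII VTK writer for uniform-grid field snapshots.

Writes STRUCTURED_POINTS datasets with cell data, readable by ParaView
and VisIt.  Velocity components are averaged from the staggered faces to
cell centers before writing.
"""

from __future__ import annotations

import numpy as np

__all__ = ["write_structured_vtk"]


def write_structured_vtk(path, geom, fields: dict, title: str = "reboa-hemo") -> None:
    """Write cell-centered scalar ``fields`` (name -> (nx, ny) array).

    The 2D grid is written as a one-cell-thick 3D structured-points
    dataset with the geometry's grid spacing and origin.
    """
    nx, ny, h = geom.nx, geom.ny, geom.spacing
    ox, oy = geom.origin
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\n")
        fh.write(f"{title}\n")
        fh.write("ASCII\n")
        fh.write("DATASET STRUCTURED_POINTS\n")
        fh.write(f"DIMENSIONS {nx + 1} {ny + 1} 2\n")
        fh.write(f"ORIGIN {ox:.9g} {oy:.9g} 0\n")
        fh.write(f"SPACING {h:.9g} {h:.9g} {h:.9g}\n")
        fh.write(f"CELL_DATA {nx * ny}\n")
        for name, arr in fields.items():
            arr = np.asarray(arr)
            if arr.shape != (nx, ny):
                raise ValueError(f"field {name!r} has shape {arr.shape}, "
                                 f"expected {(nx, ny)}")
            fh.write(f"SCALARS {name} float 1\nLOOKUP_TABLE default\n")
            # VTK cell ordering: x fastest, then y
            np.savetxt(fh, arr.T.reshape(ny, nx), fmt="%.6e")


def cell_centered_velocity(u, v):
    """Average staggered face velocities to cell centers."""
    uc = 0.5 * (u[:-1, :] + u[1:, :])
    vc = 0.5 * (v[:, :-1] + v[:, 1:])
    return uc, vc
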