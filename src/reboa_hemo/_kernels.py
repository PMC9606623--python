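"""Compiled inner loops of the flow solver.

These reproduce, loop-for-loop, the vectorized numpy reference
implementations in :mod:`reboa_hemo.solver` (``FlowSolver.shear_fields``,
``.advection``, ``.diffusion`` plus the penalized predictor); a unit test
asserts bitwise-level agreement between the two paths.  Upwind stencils
clamp indices at the array edges, which matches the edge-replicated
padding of the reference path.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["shear_kernel", "predictor_kernel"]


@njit(cache=True)
def shear_kernel(u, v, h):
    nx = v.shape[0]
    ny = u.shape[1]
    gamma = np.empty((nx, ny))
    for i in range(nx):
        for j in range(ny):
            dudx = (u[i + 1, j] - u[i, j]) / h
            dvdy = (v[i, j + 1] - v[i, j]) / h
            cross = 0.0
            for a in (i, i + 1):
                for b in (j, j + 1):
                    dudy_n = (u[a, b] - u[a, b - 1]) / h if 1 <= b <= ny - 1 else 0.0
                    dvdx_n = (v[a, b] - v[a - 1, b]) / h if 1 <= a <= nx - 1 else 0.0
                    cross += dudy_n + dvdx_n
            cross *= 0.25
            gamma[i, j] = np.sqrt(2.0 * dudx ** 2 + 2.0 * dvdy ** 2 + cross ** 2)
    return gamma


@njit(cache=True, inline="always")
def _upwind(fm2, fm1, f0, fp1, fp2, vel, h):
    if vel > 0.0:
        return (3.0 * f0 - 4.0 * fm1 + fm2) / (2.0 * h)
    return (-3.0 * f0 + 4.0 * fp1 - fp2) / (2.0 * h)


@njit(cache=True)
def predictor_kernel(u, v, mu, rho, dt, h, chi_u, chi_v, eta, stokes):
    """One explicit predictor: advection + viscous stress + penalization."""
    nx = v.shape[0]
    ny = u.shape[1]
    us = np.zeros_like(u)
    vs = np.zeros_like(v)

    for i in range(1, nx):
        for j in range(ny):
            uu = u[i, j]
            vv = 0.25 * (v[i - 1, j] + v[i - 1, j + 1] + v[i, j] + v[i, j + 1])
            adv = 0.0
            if not stokes:
                im1 = i - 1
                im2 = max(i - 2, 0)
                ip1 = min(i + 1, nx)
                ip2 = min(i + 2, nx)
                dudx = _upwind(u[im2, j], u[im1, j], uu, u[ip1, j], u[ip2, j], uu, h)
                jm1 = max(j - 1, 0)
                jm2 = max(j - 2, 0)
                jp1 = min(j + 1, ny - 1)
                jp2 = min(j + 2, ny - 1)
                dudy = _upwind(u[i, jm2], u[i, jm1], uu, u[i, jp1], u[i, jp2], vv, h)
                adv = uu * dudx + vv * dudy
            # d/dx [2 mu du/dx]
            sxx_r = 2.0 * mu[i, j] * (u[i + 1, j] - u[i, j]) / h
            sxx_l = 2.0 * mu[i - 1, j] * (u[i, j] - u[i - 1, j]) / h
            diff = (sxx_r - sxx_l) / h
            # d/dy [mu (du/dy + dv/dx)] via the two adjacent nodes
            sxy = np.empty(2)
            for k in range(2):
                jn = j + k
                ci0 = max(i - 1, 0)
                ci1 = min(i, nx - 1)
                cj0 = max(jn - 1, 0)
                cj1 = min(jn, ny - 1)
                mu_n = 0.25 * (mu[ci0, cj0] + mu[ci1, cj0] + mu[ci0, cj1] + mu[ci1, cj1])
                dudy_n = (u[i, jn] - u[i, jn - 1]) / h if 1 <= jn <= ny - 1 else 0.0
                dvdx_n = (v[i, jn] - v[i - 1, jn]) / h
                sxy[k] = mu_n * (dudy_n + dvdx_n)
            diff += (sxy[1] - sxy[0]) / h
            val = uu + dt * (-adv + diff / rho)
            us[i, j] = val / (1.0 + dt * chi_u[i, j] / eta)

    for i in range(nx):
        for j in range(1, ny):
            vv = v[i, j]
            uu = 0.25 * (u[i, j - 1] + u[i + 1, j - 1] + u[i, j] + u[i + 1, j])
            adv = 0.0
            if not stokes:
                im1 = max(i - 1, 0)
                im2 = max(i - 2, 0)
                ip1 = min(i + 1, nx - 1)
                ip2 = min(i + 2, nx - 1)
                dvdx = _upwind(v[im2, j], v[im1, j], vv, v[ip1, j], v[ip2, j], uu, h)
                jm1 = j - 1
                jm2 = max(j - 2, 0)
                jp1 = min(j + 1, ny)
                jp2 = min(j + 2, ny)
                dvdy = _upwind(v[i, jm2], v[i, jm1], vv, v[i, jp1], v[i, jp2], vv, h)
                adv = uu * dvdx + vv * dvdy
            syy_t = 2.0 * mu[i, j] * (v[i, j + 1] - v[i, j]) / h
            syy_b = 2.0 * mu[i, j - 1] * (v[i, j] - v[i, j - 1]) / h
            diff = (syy_t - syy_b) / h
            sxy = np.empty(2)
            for k in range(2):
                inode = i + k
                ci0 = max(inode - 1, 0)
                ci1 = min(inode, nx - 1)
                cj0 = max(j - 1, 0)
                cj1 = min(j, ny - 1)
                mu_n = 0.25 * (mu[ci0, cj0] + mu[ci1, cj0] + mu[ci0, cj1] + mu[ci1, cj1])
                dudy_n = (u[inode, j] - u[inode, j - 1]) / h
                dvdx_n = (v[inode, j] - v[inode - 1, j]) / h if 1 <= inode <= nx - 1 else 0.0
                sxy[k] = mu_n * (dudy_n + dvdx_n)
            diff += (sxy[1] - sxy[0]) / h
            val = vv + dt * (-adv + diff / rho)
            vs[i, j] = val / (1.0 + dt * chi_v[i, j] / eta)

    return us, vs
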