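"""Shear-thinning blood rheology.

Blood is modeled as an incompressible generalized-Newtonian fluid whose
apparent viscosity follows the Carreau law

    mu(gdot) = mu_inf + (mu_0 - mu_inf) * [1 + (lambda*gdot)^2]^((n-1)/2)

interpolating between the zero-shear plateau ``mu_0`` (rouleaux-dominated,
0.056 Pa.s for porcine/human blood) and the infinite-shear plateau
``mu_inf`` (0.0035 Pa.s).  ``lambda`` is a relaxation time in seconds and
``n`` the power-law index.  The shear-rate magnitude used as the scalar
argument is the standard generalized-Newtonian invariant
``gdot = sqrt(2 D:D)`` of the strain-rate tensor ``D``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["FluidProperties", "apparent_viscosity", "shear_rate_magnitude"]


@dataclass(frozen=True)
class FluidProperties:
    """Blood density and Carreau viscosity parameters.

    ``newtonian_override``, when set, replaces the shear-thinning law with
    a constant viscosity; used for analytic validation (Poiseuille,
    Womersley) where closed forms assume a Newtonian fluid.
    """

    density: float = 1060.0       # kg/m^3
    mu_inf: float = 0.0035        # Pa.s, infinite-shear viscosity
    mu_zero: float = 0.056        # Pa.s, zero-shear viscosity
    lam: float = 3.313            # s, relaxation time
    power_index: float = 0.368    # dimensionless
    newtonian_override: float | None = None  # Pa.s

    def __post_init__(self):
        if self.density <= 0:
            raise ValueError("density must be positive")
        if not (0 < self.mu_inf <= self.mu_zero):
            raise ValueError("require 0 < mu_inf <= mu_zero")
        if self.lam < 0:
            raise ValueError("lambda must be non-negative")
        if not (0 < self.power_index <= 1):
            raise ValueError("power index must lie in (0, 1]")
        if self.newtonian_override is not None and self.newtonian_override <= 0:
            raise ValueError("newtonian_override must be positive")


def apparent_viscosity(shear_rate, props: FluidProperties):
    """Apparent viscosity (Pa.s) at scalar shear rate(s) ``shear_rate`` (1/s).

    Vectorizes over arrays; raises ``ValueError`` for negative rates.
    """
    gdot = np.asarray(shear_rate, dtype=float)
    if np.any(gdot < 0):
        raise ValueError("shear rate must be non-negative")
    if props.newtonian_override is not None:
        mu = np.full_like(gdot, props.newtonian_override)
    else:
        expo = (props.power_index - 1.0) / 2.0
        mu = props.mu_inf + (props.mu_zero - props.mu_inf) * (
            1.0 + (props.lam * gdot) ** 2
        ) ** expo
    if np.isscalar(shear_rate) or np.ndim(shear_rate) == 0:
        return float(mu)
    return mu


def shear_rate_magnitude(velocity_gradient):
    """Shear-rate invariant ``sqrt(2 D:D)`` from a 2x2 velocity-gradient field.

    ``velocity_gradient`` has shape ``(..., 2, 2)`` with entry ``[..., i, j]``
    holding du_i/dx_j.  A rigid-body rotation (antisymmetric gradient)
    yields zero; simple shear du/dy = k yields |k|.
    """
    grad = np.asarray(velocity_gradient, dtype=float)
    if grad.shape[-2:] != (2, 2):
        raise ValueError("velocity gradient must have trailing shape (2, 2)")
    if not np.all(np.isfinite(grad)):
        raise ValueError("velocity gradient must be finite")
    d = 0.5 * (grad + np.swapaxes(grad, -1, -2))
    return np.sqrt(2.0 * np.sum(d * d, axis=(-2, -1)))
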