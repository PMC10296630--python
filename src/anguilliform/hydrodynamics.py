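"""Resistive (Taylor) fluid forces on body segments.

The fluid load on a slender segment is computed locally from the segment's
velocity relative to still water, decomposed into the link's normal and
tangential directions -- no wake memory, no added mass.  Per unit length:

    W_n = -c_quad * rho_f * a * |v_n| * v_n  -  c_visc * sqrt(rho_f * a * mu_f * |v_n|) * v_n
    W_t = -c_tang * sqrt(rho_f * a * mu_f * |v_n|) * v_t

with ``a`` the local half-axis setting the wetted width, ``rho_f`` and
``mu_f`` the fluid density and viscosity.  The first term is pressure drag,
quadratic in the normal speed; the square-root terms are the boundary-layer
(skin-friction) corrections of Taylor's resistive theory for a cylinder in
oblique flow, in which the tangential shear is controlled by the *normal*
Reynolds number.  Default prefactors ``c_quad = 1``, ``c_visc = sqrt(8)``,
``c_tang = 2.72``; all three are exposed so alternative typesettings of the
resistive law can be matched exactly.

Both components oppose the corresponding velocity, so the fluid can only
extract energy from body motion (``W_n v_n + W_t v_t <= 0`` pointwise).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["FluidParams", "taylor_force"]

SQRT8 = float(np.sqrt(8.0))


@dataclass(frozen=True)
class FluidParams:
    """Fluid density [kg/m^3], dynamic viscosity [Pa s], on/off flag, prefactors."""

    rho: float = 1000.0
    mu: float = 1.0e-3
    enabled: bool = True
    c_quad: float = 1.0
    c_visc: float = SQRT8
    c_tang: float = 2.72

    def __post_init__(self):
        if self.enabled and (self.rho <= 0 or self.mu <= 0):
            raise ValueError("enabled fluid requires rho > 0 and mu > 0")


def taylor_force(v_n, v_t, a, fluid: FluidParams):
    """Normal and tangential resistive force per unit length ``(W_n, W_t)`` [N/m].

    ``v_n``/``v_t`` are the local normal/tangential velocity components of the
    segment through the fluid, ``a`` the local half-axis [m].  Returns zeros
    when the fluid is disabled.
    """
    v_n = np.asarray(v_n, dtype=float)
    v_t = np.asarray(v_t, dtype=float)
    a = np.asarray(a, dtype=float)
    if np.any(a < 0):
        raise ValueError("half-axis must be non-negative")
    if not fluid.enabled:
        return np.zeros_like(v_n), np.zeros_like(v_t)
    absvn = np.abs(v_n)
    visc = np.sqrt(fluid.rho * a * fluid.mu * absvn)
    W_n = -fluid.c_quad * fluid.rho * a * absvn * v_n - fluid.c_visc * visc * v_n
    W_t = -fluid.c_tang * visc * v_t
    return W_n, W_t
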