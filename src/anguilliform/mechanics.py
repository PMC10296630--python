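"""Viscoelastic joint mechanics of the serial-parallel chain.

Each joint couples two neighbouring links through a pair of
spring-dashpot-muscle legs anchored to myoseptal arms of half-width ``w``
projecting from the link midlines.  With ``psi = phi_{i+1} - phi_i`` the
inter-link angle and ``h`` the link length, elementary trigonometry on the
anchor chords gives the relative extensions of the two legs

    Delta_R = cos(psi/2) - 1 - (2 w / h) sin(psi/2)
    Delta_L = cos(psi/2) - 1 + (2 w / h) sin(psi/2)

and the moment arms of the leg tensions about the joint

    L_R = w cos(psi/2) + (h/2) sin(psi/2)
    L_L = w cos(psi/2) - (h/2) sin(psi/2)

The total leg tension is active muscle force plus passive viscoelasticity,
``G = f + k Delta + gamma dDelta/dt``, and the net joint torque is the exact
expression ``M = G_R L_R - G_L L_L``.  A positive ``Delta`` means the leg is
stretched and the spring pulls back (contractile).

Sign convention: ``psi > 0`` shortens the leg labelled R (``Delta_R < 0``),
i.e. the body is concave toward the R side; activating the R muscle alone
produces ``M > 0`` and drives ``psi`` further positive.  Swapping the two
sides and ``psi -> -psi`` flips the sign of ``M`` exactly (mirror symmetry).

Per-joint coefficients scale with the local elliptic cross-section,
``k = a b k_bar`` and ``gamma = a b gamma_bar``, where the fiber stiffness
relates to the Young's modulus of the body by ``E = 2 k_bar / pi``.  This is
precisely the scaling for which the linearized joint reproduces the continuum
bending stiffness of an elliptic beam: the small-angle passive torque is
``-2 k w^2 psi / h`` and with ``w = b/2`` the effective flexural rigidity is
``2 k w^2 = (2 k_bar / pi) * (pi a b^3 / 4) = E I`` with ``I = pi a b^3 / 4``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "MaterialParams",
    "scale_coefficients",
    "relative_extensions",
    "extension_rates",
    "moment_arms",
    "side_forces",
    "joint_torque",
    "joint_torque_small_angle",
]


@dataclass(frozen=True)
class MaterialParams:
    """Passive material parameters of the body.

    ``E`` [Pa] and the fiber stiffness ``k_bar`` [N/m^2] are tied by
    ``E = 2 k_bar / pi``; the body viscosity ``mu_body`` [Pa s] maps to the
    fiber damping by the same geometric factor, ``gamma_bar = pi mu_body / 2``
    (the body gives no independent damping calibration).
    """

    E: float
    mu_body: float

    def __post_init__(self):
        if self.E < 0 or self.mu_body < 0:
            raise ValueError("material parameters must be non-negative")

    @property
    def k_bar(self) -> float:
        return np.pi * self.E / 2.0

    @property
    def gamma_bar(self) -> float:
        return np.pi * self.mu_body / 2.0

    @classmethod
    def from_fiber(cls, k_bar: float, gamma_bar: float) -> "MaterialParams":
        return cls(E=2.0 * k_bar / np.pi, mu_body=2.0 * gamma_bar / np.pi)


def scale_coefficients(a, b, k_bar: float, gamma_bar: float):
    """Per-joint spring and dashpot coefficients ``(k, gamma) = (a b k_bar, a b gamma_bar)``."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if np.any(a < 0) or np.any(b < 0) or k_bar < 0 or gamma_bar < 0:
        raise ValueError("half-axes and fiber coefficients must be non-negative")
    return a * b * k_bar, a * b * gamma_bar


def relative_extensions(psi, w, h):
    """Relative extensions ``(Delta_R, Delta_L)`` of the two legs.

    Dimensionless (chord length change over rest length ``h``).  Mirror
    symmetric: ``Delta_L(psi) = Delta_R(-psi)``.
    """
    if np.any(np.asarray(h) <= 0):
        raise ValueError("segment length h must be positive")
    if np.any(np.asarray(w) < 0):
        raise ValueError("moment arm w must be non-negative")
    psi = np.asarray(psi, dtype=float)
    c, s = np.cos(psi / 2.0), np.sin(psi / 2.0)
    r = 2.0 * np.asarray(w, dtype=float) / np.asarray(h, dtype=float)
    return c - 1.0 - r * s, c - 1.0 + r * s


def extension_rates(psi, psi_dot, w, h):
    """Time derivatives ``(dDelta_R/dt, dDelta_L/dt)`` at angular rate ``psi_dot``."""
    psi = np.asarray(psi, dtype=float)
    c, s = np.cos(psi / 2.0), np.sin(psi / 2.0)
    r = 2.0 * np.asarray(w, dtype=float) / np.asarray(h, dtype=float)
    dR = (-s / 2.0 - r * c / 2.0) * psi_dot
    dL = (-s / 2.0 + r * c / 2.0) * psi_dot
    return dR, dL


def moment_arms(psi, w, h):
    """Moment arms ``(L_R, L_L)`` of the leg tensions about the joint [m]."""
    psi = np.asarray(psi, dtype=float)
    c, s = np.cos(psi / 2.0), np.sin(psi / 2.0)
    w = np.asarray(w, dtype=float)
    h2 = np.asarray(h, dtype=float) / 2.0
    return w * c + h2 * s, w * c - h2 * s


def side_forces(f_active, delta, delta_dot, k, gamma):
    """Total leg tension ``G = f_active + k Delta + gamma dDelta/dt`` [N]."""
    if np.any(np.asarray(k) < 0) or np.any(np.asarray(gamma) < 0):
        raise ValueError("viscoelastic coefficients must be non-negative")
    return np.asarray(f_active) + np.asarray(k) * delta + np.asarray(gamma) * delta_dot


def joint_torque(fL, fR, psi, psi_dot, k, gamma, w, h):
    """Exact net joint torque ``M = G_R L_R - G_L L_L`` [N m].

    ``fL``/``fR`` are the active muscle tensions on the two sides.  Vanishes
    for a straight, resting joint with balanced activation; antisymmetric
    under ``(fL, fR, psi, psi_dot) -> (fR, fL, -psi, -psi_dot)``.
    """
    dR, dL = relative_extensions(psi, w, h)
    dRd, dLd = extension_rates(psi, psi_dot, w, h)
    GR = side_forces(fR, dR, dRd, k, gamma)
    GL = side_forces(fL, dL, dLd, k, gamma)
    LR, LL = moment_arms(psi, w, h)
    return GR * LR - GL * LL


def joint_torque_small_angle(fL, fR, psi, psi_dot, k, gamma, w, h):
    """Leading-order expansion of :func:`joint_torque` in ``psi``.

    ``M ~ (fR - fL) w + (fR + fL) h psi / 4 - 2 k w^2 psi / h
    - 2 gamma w^2 psi_dot / h``.  Test oracle only; the exact form is the
    production path.
    """
    return (
        (np.asarray(fR) - np.asarray(fL)) * w
        + (np.asarray(fR) + np.asarray(fL)) * h * psi / 4.0
        - 2.0 * k * w * w * psi / h
        - 2.0 * gamma * w * w * psi_dot / h
    )
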