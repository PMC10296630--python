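"""Discretized body geometry of an anguilliform swimmer.

The body is an elongated, laterally flexible trunk whose cross-sections are
approximated as ellipses with major (dorso-ventral) half-axis ``a(x)`` and
minor (lateral) half-axis ``b(x)``, ``x`` being arc position from the nose.
The trunk is cut into ``N`` equal segments of length ``h = L/N``; each segment
is one rigid link of the serial-parallel chain, and neighbouring links are
coupled at pivots by the viscoelastic / muscular machinery in
:mod:`anguilliform.mechanics` and :mod:`anguilliform.muscle`.

Profiles
--------
The lateral half-width is a single parabola peaking at ``0.51 L``::

    b(x) = 0.08 L [1 - ((x - 0.51 L) / (0.51 L))**2]

The dorso-ventral half-height is a three-piece profile: an elliptic nose for
``x < 0.04 L``, a shallow parabola over the trunk, and a linear taper
``(L - x)/5`` over the last 5% of the body::

    a(x) = sqrt(0.08 L x - x**2)                     0     <= x < 0.04 L
           0.04 L - 0.03 L ((x - 0.04 L)/(0.91 L))^2 0.04 L <= x <= 0.95 L
           (L - x) / 5                               0.95 L <  x <= L

The three branches are exactly continuous at both breakpoints (the nose
branch reaches ``0.04 L`` at ``x = 0.04 L``; the trunk branch falls to
``0.01 L`` at ``x = 0.95 L``, matching the taper).  The profile is pluggable:
:func:`discretize` accepts any callables with the same signature.

Muscle moment arms are anchored at half the local half-width, ``w = b/2``,
modelling the myosepta to which the fibers attach.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

__all__ = [
    "BodyGeometry",
    "minor_axis_profile",
    "major_axis_profile",
    "discretize",
]


def _check_domain(x: np.ndarray, L: float) -> None:
    if L <= 0:
        raise ValueError(f"body length must be positive, got L={L}")
    if np.any(x < -1e-12 * L) or np.any(x > L * (1 + 1e-12)):
        raise ValueError(f"arc position outside [0, L={L}]")


def minor_axis_profile(x, L: float):
    """Lateral half-width ``b(x)`` of the body (minor half-axis), in meters.

    A parabola with vertex ``0.08 L`` at ``x = 0.51 L`` and zero at the nose.
    Raises ``ValueError`` outside ``[0, L]``.
    """
    x = np.asarray(x, dtype=float)
    _check_domain(x, L)
    u = (x - 0.51 * L) / (0.51 * L)
    return (0.08 * L * (1.0 - u * u))[()] if x.ndim == 0 else 0.08 * L * (1.0 - u * u)


def major_axis_profile(x, L: float):
    """Dorso-ventral half-height ``a(x)`` of the body (major half-axis), [m].

    Three-piece profile with breakpoints at ``0.04 L`` and ``0.95 L``; the
    branches join continuously (see module docstring).  Raises ``ValueError``
    outside ``[0, L]``.
    """
    x = np.asarray(x, dtype=float)
    _check_domain(x, L)
    xs = np.atleast_1d(x)
    out = np.empty_like(xs)

    head = xs < 0.04 * L
    mid = (xs >= 0.04 * L) & (xs <= 0.95 * L)
    tail = xs > 0.95 * L

    # clip guards roundoff at x ~ 0 where 0.08*L*x - x^2 can be -eps
    out[head] = np.sqrt(np.clip(0.08 * L * xs[head] - xs[head] ** 2, 0.0, None))
    u = (xs[mid] - 0.04 * L) / (0.91 * L)
    out[mid] = 0.04 * L - 0.03 * L * u * u
    out[tail] = (L - xs[tail]) / 5.0
    return out[0] if x.ndim == 0 else out.reshape(x.shape)


@dataclass(frozen=True)
class BodyGeometry:
    """Discretized elliptic body.

    Cross-section values are carried both at segment midpoints (used for
    hydrodynamic widths, per-link masses and inertias) and at pivot stations
    (used for lumped pivot masses and the viscoelastic/muscle coefficients of
    the joints, which live at pivots).

    Attributes
    ----------
    L, N, h : body length [m], segment count, segment length ``L/N`` [m].
    x_mid, x_pivot : station arrays, shapes ``(N,)`` and ``(N+1,)``.
    a_mid, b_mid, w_mid : half-axes and muscle arm ``w = b/2`` at midpoints.
    a_pivot, b_pivot, w_pivot : the same at pivot stations.
    m_pivot : lumped masses at pivots ``rho*pi*a*b*h`` [kg], shape ``(N+1,)``.
    m_link, J_link : per-link slice mass and slab inertia ``m h^2/12``.
    head_fraction, n_passive : passive head length fraction and the number of
        head segments that carry no muscle.
    """

    L: float
    N: int
    h: float
    rho: float
    head_fraction: float
    n_passive: int
    x_mid: np.ndarray = field(repr=False)
    x_pivot: np.ndarray = field(repr=False)
    a_mid: np.ndarray = field(repr=False)
    b_mid: np.ndarray = field(repr=False)
    w_mid: np.ndarray = field(repr=False)
    a_pivot: np.ndarray = field(repr=False)
    b_pivot: np.ndarray = field(repr=False)
    w_pivot: np.ndarray = field(repr=False)
    m_pivot: np.ndarray = field(repr=False)
    m_link: np.ndarray = field(repr=False)
    J_link: np.ndarray = field(repr=False)

    @property
    def total_mass(self) -> float:
        return float(self.m_pivot.sum())

    @property
    def active_joints(self) -> np.ndarray:
        """Indices of interior pivots (1..N-1) that carry muscle."""
        joints = np.arange(1, self.N)
        return joints[joints >= max(self.n_passive, 1)]

    def passive_mask(self) -> np.ndarray:
        """Boolean per-segment mask, True for muscle-less head segments."""
        mask = np.zeros(self.N, dtype=bool)
        mask[: self.n_passive] = True
        return mask

    def to_csv(self, path_or_buf=None):
        """Dump one row per segment: x_m, a_m, b_m, w_m, mass_kg, inertia_kgm2."""
        import pandas as pd

        df = pd.DataFrame(
            {
                "x_m": self.x_mid,
                "a_m": self.a_mid,
                "b_m": self.b_mid,
                "w_m": self.w_mid,
                "mass_kg": self.m_link,
                "inertia_kgm2": self.J_link,
            }
        )
        if path_or_buf is None:
            buf = io.StringIO()
            df.to_csv(buf, index=False)
            return buf.getvalue()
        df.to_csv(path_or_buf, index=False)
        return None


def discretize(
    L: float,
    N: int,
    rho: float,
    head_fraction: float = 0.1,
    major_profile: Callable | None = None,
    minor_profile: Callable | None = None,
    volumetric: bool = True,
) -> BodyGeometry:
    """Cut the body into ``N`` equal segments and lump masses and inertias.

    Segment midpoints sit at ``x_i = (i - 1/2) h``; pivots at ``i h``.
    Masses are elliptic slices ``m = rho * pi * a * b * h`` (volumetric; the
    planar model is two-dimensional with constant height, but the density is
    given per unit volume, so the elliptic slice is the dimensionally
    consistent choice).  ``volumetric=False`` drops the factor ``pi*a`` and
    uses per-unit-height slab masses ``rho * 2b * h`` instead.

    The first ``ceil(head_fraction * N)`` segments are flagged passive: the
    head carries no activation muscle.
    """
    if N < 4:
        raise ValueError(f"need at least 4 segments, got N={N}")
    if L <= 0 or rho < 0:
        raise ValueError("L must be > 0 and rho >= 0")
    if not 0 <= head_fraction < 1:
        raise ValueError(f"head_fraction must be in [0, 1), got {head_fraction}")

    a_of = major_profile or major_axis_profile
    b_of = minor_profile or minor_axis_profile

    h = L / N
    x_mid = (np.arange(N) + 0.5) * h
    x_pivot = np.arange(N + 1) * h

    a_mid = np.asarray(a_of(x_mid, L), dtype=float)
    b_mid = np.asarray(b_of(x_mid, L), dtype=float)
    a_piv = np.asarray(a_of(x_pivot, L), dtype=float)
    b_piv = np.asarray(b_of(x_pivot, L), dtype=float)

    if volumetric:
        m_piv = rho * np.pi * a_piv * b_piv * h
        m_link = rho * np.pi * a_mid * b_mid * h
    else:
        m_piv = rho * 2.0 * b_piv * h
        m_link = rho * 2.0 * b_mid * h
    J_link = m_link * h * h / 12.0

    return BodyGeometry(
        L=L,
        N=N,
        h=h,
        rho=rho,
        head_fraction=head_fraction,
        n_passive=int(np.ceil(head_fraction * N)),
        x_mid=x_mid,
        x_pivot=x_pivot,
        a_mid=a_mid,
        b_mid=b_mid,
        w_mid=b_mid / 2.0,
        a_pivot=a_piv,
        b_pivot=b_piv,
        w_pivot=b_piv / 2.0,
        m_pivot=m_piv,
        m_link=m_link,
        J_link=J_link,
    )
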