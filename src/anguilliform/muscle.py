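"""Calcium-kinetics muscle activation and the traveling drive wave.

Activation model
----------------
Following stimulation, force development in a myotome is governed by calcium
release, binding and reuptake.  We use a two-state first-order kinetic
cascade per muscle: free calcium fraction ``c`` and activation ``chi`` (the
fraction of force-generating sites switched on),

    dc/dt   = k1 * s(t) * (1 - c) - k2 * c
    dchi/dt = k3 * c * (1 - chi)  - k4 * chi

with ``s(t)`` the neural stimulation (0/1 burst with short tanh edges).
Both states live in [0, 1] by construction.  During a burst, ``c`` rises
toward ``k1/(k1+k2)`` and ``chi`` toward a plateau; after the burst both
relax to zero.  The rate constants set a twitch-like rise over a few hundred
milliseconds, so at high stimulation frequency a burst ends before the
plateau is reached and the per-cycle peak activation drops -- the kinetics
saturate with frequency.

Drive wave
----------
Myotomes are stimulated sequentially from just behind the head toward the
tail, alternating sides: the burst onset at arc position ``x`` lags the first
active station by ``(x - x0) / (wave_length * L * f)`` and the two sides of
one station are half a period apart.  The passive head (no muscle) never
activates.

The active force density is linear in activation and in the actuation
amplitude, ``f = chi * D`` (the force per unit muscle cross-section is
``chi * D * stress_scale``; the chain assembly multiplies by the local
cross-section area ``a*b``).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.integrate import solve_ivp

from .geometry import BodyGeometry

__all__ = [
    "CalciumKinetics",
    "MuscleDrive",
    "stimulus",
    "calcium_activation",
    "activation_wave",
    "muscle_force",
]


@dataclass(frozen=True)
class CalciumKinetics:
    """Rate constants [1/s] of the two-state activation cascade.

    Defaults give a twitch with time-to-near-plateau ~0.2 s and relaxation
    ~0.15 s, reproducing the qualitative single-myotome shape (fast rise,
    plateau under sustained stimulation, slower decay); per-cycle peak
    activation is then frequency-saturating: bursts at tail-beat frequencies
    around 5 Hz end before the plateau is reached.
    """

    k1: float = 20.0
    k2: float = 10.0
    k3: float = 15.0
    k4: float = 8.0

    def __post_init__(self):
        if min(self.k1, self.k2, self.k3, self.k4) <= 0:
            raise ValueError("calcium rate constants must be positive")


@dataclass(frozen=True)
class MuscleDrive:
    """Traveling, side-alternating activation wave specification.

    Parameters
    ----------
    D : dimensionless actuation amplitude (fraction of the maximal muscle
        stress recruited at full activation), biological range 0.01-0.2.
    f : tail-beat / stimulation frequency [Hz].
    kinetics : calcium rate constants.
    duty : fraction of the period each side is stimulated (default 0.5:
        the two sides tile the period).
    wave_length : activation-wave wavelength as a fraction of body length
        (default 1.0, one full wave on the body -- the canonical
        anguilliform drive).
    phase_offset : stimulation-to-curvature phase delay [rad], shifts all
        onsets by ``phase_offset / (2 pi f)``.
    stress_scale : maximal muscle stress [Pa] at ``chi = D = 1``; fixed
        calibration constant of the force-assembly layer.
    edge : tanh edge width of the stimulus bursts [s].
    """

    D: float
    f: float
    kinetics: CalciumKinetics = CalciumKinetics()
    duty: float = 0.5
    wave_length: float = 1.0
    phase_offset: float = 0.0
    stress_scale: float = 0.6e6
    edge: float = 0.010

    def __post_init__(self):
        if self.D < 0:
            raise ValueError("actuation amplitude D must be non-negative")
        if self.f <= 0:
            raise ValueError("tail-beat frequency must be positive")
        if not 0 < self.duty <= 1:
            raise ValueError("duty must be in (0, 1]")
        if self.wave_length <= 0:
            raise ValueError("wave_length must be positive")

    def with_(self, **kw) -> "MuscleDrive":
        return replace(self, **kw)

    def onset_phases(self, geometry: BodyGeometry) -> np.ndarray:
        """Burst onset phase [cycles] per active joint, head-to-tail wave."""
        joints = geometry.active_joints
        x = geometry.x_pivot[joints]
        return (x - x[0]) / (self.wave_length * geometry.L) + self.phase_offset / (
            2.0 * np.pi
        )


def stimulus(t, f: float, onset_phase: float, duty: float, edge_phase: float):
    """Periodic stimulation burst in [0, 1] with smooth tanh edges.

    ``t`` may be an array; ``onset_phase`` is in cycles, ``edge_phase`` is the
    tanh edge width in cycles.  The burst occupies phase ``[0, duty)`` of each
    cycle (relative to ``onset_phase``); neighbouring-period images keep the
    waveform smooth and periodic across the wrap.
    """
    theta = np.mod(np.asarray(t, dtype=float) * f - onset_phase, 1.0)
    e = max(edge_phase, 1e-12)
    s = np.zeros_like(theta)
    for k in (-1.0, 0.0, 1.0):
        u = theta - k
        s = s + 0.5 * (np.tanh(u / e) - np.tanh((u - duty) / e))
    return np.clip(s, 0.0, 1.0)


def _burst(t, on: float, off: float, edge: float):
    """Single (non-periodic) stimulation burst on [on, off]."""
    t = np.asarray(t, dtype=float)
    e = max(edge, 1e-12)
    return 0.5 * (np.tanh((t - on) / e) - np.tanh((t - off) / e))


def calcium_activation(
    t,
    stim_on: float,
    stim_off: float,
    kinetics: CalciumKinetics = CalciumKinetics(),
    edge: float = 0.010,
    rtol: float = 1e-8,
    atol: float = 1e-10,
):
    """Activation ``chi(t)`` of one myotome for a single stimulation burst.

    Zero before ``stim_on``, rises toward a plateau during the burst, decays
    toward zero after ``stim_off``.  ``t`` may be a scalar or an array.
    """
    if stim_on >= stim_off:
        raise ValueError("stim_on must precede stim_off")
    k = kinetics
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    t_end = float(t_arr.max())
    out = np.zeros_like(t_arr)
    if t_end > stim_on:
        def rhs(tt, y):
            s = _burst(tt, stim_on, stim_off, edge)
            c, chi = y
            return [k.k1 * s * (1 - c) - k.k2 * c, k.k3 * c * (1 - chi) - k.k4 * chi]

        sol = solve_ivp(
            rhs,
            (stim_on - 10 * edge, t_end),
            [0.0, 0.0],
            method="LSODA",
            rtol=rtol,
            atol=atol,
            dense_output=True,
            max_step=max((stim_off - stim_on) / 20.0, 1e-4),
        )
        late = t_arr > stim_on - 10 * edge
        out[late] = np.clip(sol.sol(t_arr[late])[1], 0.0, 1.0)
    return out[0] if np.ndim(t) == 0 else out.reshape(np.shape(t))


def activation_wave(
    geometry: BodyGeometry,
    drive: MuscleDrive,
    t,
    rtol: float = 1e-8,
    atol: float = 1e-10,
):
    """Per-segment left/right activations ``(chiL, chiR)`` at time(s) ``t``.

    Integrates the kinetics cascade from rest at ``t = 0`` under the periodic
    traveling stimulus.  Segments inherit the activation of the joint at
    their tailward pivot; passive head segments (and the tail-most segment,
    whose tail pivot is the free end) return zero.

    Returns arrays of shape ``(N,)`` for scalar ``t`` or ``(N, len(t))``.
    """
    k = drive.kinetics
    joints = geometry.active_joints
    phases = drive.onset_phases(geometry)
    nj = len(joints)
    edge_phase = drive.edge * drive.f
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    t_end = float(t_arr.max())

    def rhs(tt, y):
        c = y[: 2 * nj]
        chi = y[2 * nj :]
        sL = stimulus(tt, drive.f, phases, drive.duty, edge_phase)
        sR = stimulus(tt, drive.f, phases + 0.5, drive.duty, edge_phase)
        s = np.concatenate([sL, sR])
        return np.concatenate(
            [k.k1 * s * (1 - c) - k.k2 * c, k.k3 * c * (1 - chi) - k.k4 * chi]
        )

    chiL = np.zeros((geometry.N, t_arr.size))
    chiR = np.zeros((geometry.N, t_arr.size))
    if t_end > 0 and nj:
        sol = solve_ivp(
            rhs,
            (0.0, t_end),
            np.zeros(4 * nj),
            method="LSODA",
            rtol=rtol,
            atol=atol,
            dense_output=True,
            max_step=0.05 / drive.f,
        )
        pos = np.where(t_arr > 0)[0]
        y = sol.sol(t_arr[pos])
        chi = np.clip(y[2 * nj :], 0.0, 1.0)
        # the joint at pivot j drives the segment tailward of it (index j)
        chiL[np.ix_(joints, pos)] = chi[:nj]
        chiR[np.ix_(joints, pos)] = chi[nj:]
    if np.ndim(t) == 0:
        return chiL[:, 0], chiR[:, 0]
    return chiL, chiR


def muscle_force(chi, D):
    """Active force density ``f = chi * D`` (linear in both arguments)."""
    chi = np.asarray(chi, dtype=float)
    if np.any(chi < -1e-12) or np.any(chi > 1 + 1e-12):
        raise ValueError("activation must lie in [0, 1]")
    if np.any(np.asarray(D) < 0):
        raise ValueError("actuation amplitude D must be non-negative")
    return chi * D
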