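"""Coupled body-muscle dynamics of the swimming chain.

Formulation
-----------
The chain of ``N`` rigid links is described by generalized coordinates
``q = (X, Y, phi_1 .. phi_N)``: the nose position and the absolute angle of
every link.  Lumped masses ``m_k`` sit at the ``N+1`` pivots
``p_0 = (X, Y)``, ``p_k = p_{k-1} + h (cos phi_k, sin phi_k)``; each link
additionally carries a slab inertia about its midpoint.  Writing the kinetic
energy of the point masses and applying Lagrange's equations eliminates the
inter-link constraint forces analytically; with the cumulative tail masses
``T_p = sum_{k >= p} m_k`` and ``mu_j = h T_j`` the equations of motion are

    m_tot Xdd - sum_j mu_j sin(phi_j) phidd_j = Q_X + sum_j mu_j cos(phi_j) phid_j^2
    m_tot Ydd + sum_j mu_j cos(phi_j) phidd_j = Q_Y + sum_j mu_j sin(phi_j) phid_j^2
    mu_i (-sin phi_i Xdd + cos phi_i Ydd)
        + sum_j [h^2 T_max(i,j) cos(phi_i - phi_j) + delta_ij J_i] phidd_j
        = Q_phi_i - h^2 sum_j T_max(i,j) sin(phi_i - phi_j) phid_j^2

a dense symmetric linear system of size ``N + 2`` solved at every step.
The head and tail are free: no external force or moment acts there beyond
the fluid load, so boundary conditions are automatic in this formulation.

Generalized forces collect (i) the exact viscoelastic + muscular joint
torques (equal and opposite on the two links at each interior pivot) and
(ii) the Taylor resistive fluid force, evaluated at each link midpoint from
its instantaneous normal/tangential velocity and applied there.

Muscle kinetics (two first-order states per side per interior joint) are
integrated alongside the mechanics; the full state is

    [X, Y, phi (N), Xd, Yd, phid (N), cL, chiL, cR, chiR (each N-1)].

The passive joints of the head region carry no stimulation; their kinetic
states stay identically zero.

Integration uses a stiff adaptive solver (BDF by default, LSODA as an
option): at tissue-like viscosity the distal joints are strongly overdamped
(decay rates of order 1e5 1/s), far too stiff for an explicit pair at the
1 ms output stride, which is kept as the fixed sampling grid of the
results.  The right-hand side is compiled
with numba.  The whole pipeline is deterministic: no random numbers enter
anywhere.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit
from scipy.integrate import solve_ivp

from .config import SimulationConfig
from .geometry import BodyGeometry

__all__ = ["ChainState", "SimulationResult", "derivatives", "simulate"]


# ---------------------------------------------------------------------------
# numba kernel
# ---------------------------------------------------------------------------


@njit(cache=True)
def _smooth_box(theta, duty, eps):
    """Periodic unit burst on phase [0, duty) with tanh edges of width eps."""
    s = 0.0
    for k in (-1.0, 0.0, 1.0):
        u = theta - k
        s += 0.5 * (np.tanh(u / eps) - np.tanh((u - duty) / eps))
    if s < 0.0:
        s = 0.0
    elif s > 1.0:
        s = 1.0
    return s


@njit(cache=True)
def _rhs(
    t,
    y,
    N,
    h,
    tailmass,  # (N+1,) T_p = sum_{k>=p} m_k
    Js,  # (N,) link slab inertias
    kj,  # (N-1,) joint spring coefficients
    gj,  # (N-1,) joint damping coefficients
    wj,  # (N-1,) joint moment arms
    famp,  # (N-1,) active force amplitude chi -> force [N]; 0 for passive joints
    onset,  # (N-1,) stimulus onset phase [cycles]
    active,  # (N-1,) 0/1 mask
    f,
    duty,
    edge_phase,
    km1,
    km2,
    km3,
    km4,
    fluid_on,
    rho_f,
    mu_f,
    c_quad,
    c_visc,
    c_tang,
    a_mid,  # (N,) hydrodynamic half-axis at link midpoints
):
    nq = N + 2
    phi = y[2 : 2 + N]
    Xd = y[2 + N]
    Yd = y[3 + N]
    phid = y[4 + N : 4 + 2 * N]
    nm = N - 1
    mb = 4 + 2 * N
    cL = y[mb : mb + nm]
    chiL = y[mb + nm : mb + 2 * nm]
    cR = y[mb + 2 * nm : mb + 3 * nm]
    chiR = y[mb + 3 * nm : mb + 4 * nm]

    dy = np.zeros_like(y)

    cphi = np.cos(phi)
    sphi = np.sin(phi)

    # --- muscle kinetics and active forces ---------------------------------
    fL = np.zeros(nm)
    fR = np.zeros(nm)
    for j in range(nm):
        if active[j] > 0.5:
            thL = (t * f - onset[j]) % 1.0
            thR = (thL - 0.5) % 1.0
            sL = _smooth_box(thL, duty, edge_phase)
            sR = _smooth_box(thR, duty, edge_phase)
            dy[mb + j] = km1 * sL * (1.0 - cL[j]) - km2 * cL[j]
            dy[mb + nm + j] = km3 * cL[j] * (1.0 - chiL[j]) - km4 * chiL[j]
            dy[mb + 2 * nm + j] = km1 * sR * (1.0 - cR[j]) - km2 * cR[j]
            dy[mb + 3 * nm + j] = km3 * cR[j] * (1.0 - chiR[j]) - km4 * chiR[j]
            fL[j] = chiL[j] * famp[j]
            fR[j] = chiR[j] * famp[j]

    # --- joint torques (exact serial-parallel mechanics) -------------------
    Qphi = np.zeros(N)
    for j in range(nm):
        psi = phi[j + 1] - phi[j]
        psid = phid[j + 1] - phid[j]
        c2 = np.cos(0.5 * psi)
        s2 = np.sin(0.5 * psi)
        r = 2.0 * wj[j] / h
        dR = c2 - 1.0 - r * s2
        dL = c2 - 1.0 + r * s2
        dRd = (-0.5 * s2 - 0.5 * r * c2) * psid
        dLd = (-0.5 * s2 + 0.5 * r * c2) * psid
        GR = fR[j] + kj[j] * dR + gj[j] * dRd
        GL = fL[j] + kj[j] * dL + gj[j] * dLd
        LR = wj[j] * c2 + 0.5 * h * s2
        LL = wj[j] * c2 - 0.5 * h * s2
        M = GR * LR - GL * LL
        Qphi[j + 1] += M
        Qphi[j] -= M

    # --- fluid forces at link midpoints ------------------------------------
    QX = 0.0
    QY = 0.0
    Fx = np.zeros(N)
    Fy = np.zeros(N)
    if fluid_on > 0.5:
        # prefix velocity sums: contribution of phid_j for j < i
        px = Xd
        py = Yd
        for i in range(N):
            vx = px + 0.5 * h * phid[i] * (-sphi[i])
            vy = py + 0.5 * h * phid[i] * cphi[i]
            tx, ty = cphi[i], sphi[i]
            nx, ny = -sphi[i], cphi[i]
            vn = vx * nx + vy * ny
            vt = vx * tx + vy * ty
            absvn = abs(vn)
            visc = np.sqrt(rho_f * a_mid[i] * mu_f * absvn)
            Wn = -c_quad * rho_f * a_mid[i] * absvn * vn - c_visc * visc * vn
            Wt = -c_tang * visc * vt
            Fx[i] = h * (Wn * nx + Wt * tx)
            Fy[i] = h * (Wn * ny + Wt * ty)
            QX += Fx[i]
            QY += Fy[i]
            px += h * phid[i] * (-sphi[i])
            py += h * phid[i] * cphi[i]
        # suffix force sums: link i's force works on phi_j for j < i (full arm)
        sfx = 0.0
        sfy = 0.0
        for j in range(N - 1, -1, -1):
            Qphi[j] += h * (-sphi[j]) * (sfx + 0.5 * Fx[j]) + h * cphi[j] * (
                sfy + 0.5 * Fy[j]
            )
            sfx += Fx[j]
            sfy += Fy[j]

    # --- assemble and solve the (N+2) linear system ------------------------
    mu = h * tailmass[1:]  # (N,) mu for link j (1-based) = h * T_j
    m_tot = tailmass[0]
    A = np.zeros((nq, nq))
    b = np.zeros(nq)
    A[0, 0] = m_tot
    A[1, 1] = m_tot
    b[0] = QX
    b[1] = QY
    for j in range(N):
        A[0, 2 + j] = -mu[j] * sphi[j]
        A[2 + j, 0] = A[0, 2 + j]
        A[1, 2 + j] = mu[j] * cphi[j]
        A[2 + j, 1] = A[1, 2 + j]
        b[0] += mu[j] * cphi[j] * phid[j] * phid[j]
        b[1] += mu[j] * sphi[j] * phid[j] * phid[j]
    h2 = h * h
    for i in range(N):
        bi = Qphi[i]
        for j in range(N):
            mx = i if i > j else j
            Tm = tailmass[mx + 1]
            cij = cphi[i] * cphi[j] + sphi[i] * sphi[j]
            sij = sphi[i] * cphi[j] - cphi[i] * sphi[j]
            A[2 + i, 2 + j] = h2 * Tm * cij
            bi -= h2 * Tm * sij * phid[j] * phid[j]
        A[2 + i, 2 + i] += Js[i]
        b[2 + i] = bi
    acc = np.linalg.solve(A, b)

    dy[0] = Xd
    dy[1] = Yd
    dy[2 : 2 + N] = phid
    dy[2 + N : 4 + 2 * N] = acc
    return dy


# ---------------------------------------------------------------------------
# python-facing containers and drivers
# ---------------------------------------------------------------------------


@dataclass
class ChainState:
    """Chain configuration at one instant, in generalized coordinates."""

    head: np.ndarray  # (2,) nose position [m]
    phi: np.ndarray  # (N,) absolute link angles [rad]
    head_vel: np.ndarray  # (2,)
    phi_dot: np.ndarray  # (N,)
    muscle: np.ndarray  # (4*(N-1),) kinetic states (cL, chiL, cR, chiR blocks)

    @property
    def N(self) -> int:
        return len(self.phi)

    @classmethod
    def rest(cls, N: int) -> "ChainState":
        """Straight chain along +x, at rest, muscles quiescent."""
        return cls(
            head=np.zeros(2),
            phi=np.zeros(N),
            head_vel=np.zeros(2),
            phi_dot=np.zeros(N),
            muscle=np.zeros(4 * (N - 1)),
        )

    def to_vector(self) -> np.ndarray:
        return np.concatenate(
            [self.head, self.phi, self.head_vel, self.phi_dot, self.muscle]
        )

    @classmethod
    def from_vector(cls, y: np.ndarray, N: int) -> "ChainState":
        return cls(
            head=y[0:2].copy(),
            phi=y[2 : 2 + N].copy(),
            head_vel=y[2 + N : 4 + N].copy(),
            phi_dot=y[4 + N : 4 + 2 * N].copy(),
            muscle=y[4 + 2 * N :].copy(),
        )

    def pivots(self, h: float) -> np.ndarray:
        """Pivot positions (N+1, 2); consecutive pivots are exactly h apart."""
        p = np.empty((self.N + 1, 2))
        p[0] = self.head
        steps = h * np.stack([np.cos(self.phi), np.sin(self.phi)], axis=1)
        p[1:] = self.head + np.cumsum(steps, axis=0)
        return p


def _kernel_args(cfg: SimulationConfig, geom: BodyGeometry):
    mats = cfg.materials
    drv = cfg.drive
    fl = cfg.fluid
    N = geom.N
    tailmass = np.cumsum(geom.m_pivot[::-1])[::-1].copy()
    a_p = geom.a_pivot[1:N]
    b_p = geom.b_pivot[1:N]
    kj = a_p * b_p * mats.k_bar
    gj = a_p * b_p * mats.gamma_bar
    wj = geom.w_pivot[1:N]
    active = np.zeros(N - 1)
    joints = geom.active_joints
    active[joints - 1] = 1.0
    famp = np.zeros(N - 1)
    famp[joints - 1] = drv.D * drv.stress_scale * a_p[joints - 1] * b_p[joints - 1]
    onset = np.zeros(N - 1)
    onset[joints - 1] = drv.onset_phases(geom)
    k = drv.kinetics
    return (
        N,
        geom.h,
        tailmass,
        geom.J_link,
        kj,
        gj,
        wj,
        famp,
        onset,
        active,
        drv.f,
        drv.duty,
        max(drv.edge * drv.f, 1e-9),
        k.k1,
        k.k2,
        k.k3,
        k.k4,
        1.0 if fl.enabled else 0.0,
        fl.rho,
        fl.mu,
        fl.c_quad,
        fl.c_visc,
        fl.c_tang,
        geom.a_mid,
    )


def derivatives(state: ChainState, t: float, config: SimulationConfig) -> np.ndarray:
    """State rate of the full coupled system (momentum balance per unit with
    constraint forces eliminated; free head/tail boundaries).

    Raises ``FloatingPointError`` on a non-finite state.
    """
    y = state.to_vector()
    if not np.all(np.isfinite(y)):
        raise FloatingPointError("non-finite chain state passed to derivatives()")
    geom = config.geometry()
    return _rhs(t, y, *_kernel_args(config, geom))


@dataclass
class SimulationResult:
    """Uniformly sampled time series of a swimming run.

    ``x``/``y`` are pivot coordinates, shape (frames, N+1); the midline arc
    length is exactly L at every frame (rigid links).  ``v_com`` is the
    center-of-mass velocity (frames, 2).  ``torque`` holds net joint torques
    (frames, N-1) and ``chiL``/``chiR`` the activation traces.
    """

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    v_com: np.ndarray
    torque: np.ndarray
    chiL: np.ndarray
    chiR: np.ndarray
    config: SimulationConfig
    quasi_steady: bool
    n_periods: int
    period_speeds: np.ndarray  # period-averaged COM speed [m/s] per period
    message: str = ""

    @property
    def L(self) -> float:
        return self.config.L

    @property
    def f(self) -> float:
        return self.config.drive.f

    def frames_per_period(self) -> int:
        return int(round(1.0 / (self.f * self.config.solver.dt_out)))

    def save(self, outdir) -> None:
        """Persist as CSV (midline frames) + JSON scalars with provenance."""
        import json
        from pathlib import Path

        import pandas as pd

        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        stations = [f"s{i}" for i in range(self.x.shape[1])]
        pd.DataFrame(self.x, columns=stations).assign(t=self.t).to_csv(
            out / "midline_x.csv", index=False
        )
        pd.DataFrame(self.y, columns=stations).assign(t=self.t).to_csv(
            out / "midline_y.csv", index=False
        )
        pd.DataFrame(
            {"t": self.t, "vx": self.v_com[:, 0], "vy": self.v_com[:, 1]}
        ).to_csv(out / "com_velocity.csv", index=False)
        scalars = {
            "config_hash": self.config.hash(),
            "rtol": self.config.solver.rtol,
            "atol": self.config.solver.atol,
            "quasi_steady": bool(self.quasi_steady),
            "n_periods": int(self.n_periods),
            "period_speeds_m_per_s": [float(v) for v in self.period_speeds],
            "message": self.message,
        }
        (out / "run.json").write_text(json.dumps(scalars, indent=2))


def _recompute_outputs(ys, cfg: SimulationConfig, geom: BodyGeometry):
    """Vectorized post-processing of raw state frames -> result arrays."""
    from . import mechanics

    N = geom.N
    h = geom.h
    phi = ys[:, 2 : 2 + N]
    phid = ys[:, 4 + N : 4 + 2 * N]
    cph, sph = np.cos(phi), np.sin(phi)
    x = np.concatenate(
        [ys[:, 0:1], ys[:, 0:1] + np.cumsum(h * cph, axis=1)], axis=1
    )
    y = np.concatenate(
        [ys[:, 1:2], ys[:, 1:2] + np.cumsum(h * sph, axis=1)], axis=1
    )
    tailmass = np.cumsum(geom.m_pivot[::-1])[::-1]
    mu = h * tailmass[1:]
    m_tot = tailmass[0]
    v_com = np.stack(
        [
            ys[:, 2 + N] + (phid * (-sph) * mu).sum(axis=1) / m_tot,
            ys[:, 3 + N] + (phid * cph * mu).sum(axis=1) / m_tot,
        ],
        axis=1,
    )
    nm = N - 1
    mb = 4 + 2 * N
    chiL = ys[:, mb + nm : mb + 2 * nm]
    chiR = ys[:, mb + 3 * nm : mb + 4 * nm]
    a_p, b_p = geom.a_pivot[1:N], geom.b_pivot[1:N]
    kj = a_p * b_p * cfg.materials.k_bar
    gj = a_p * b_p * cfg.materials.gamma_bar
    wj = geom.w_pivot[1:N]
    famp = np.zeros(nm)
    joints = geom.active_joints
    famp[joints - 1] = (
        cfg.drive.D * cfg.drive.stress_scale * a_p[joints - 1] * b_p[joints - 1]
    )
    psi = np.diff(phi, axis=1)
    psid = np.diff(phid, axis=1)
    torque = mechanics.joint_torque(
        chiL * famp, chiR * famp, psi, psid, kj, gj, wj, h
    )
    return x, y, v_com, torque, chiL, chiR


def simulate(config: SimulationConfig, progress: bool = False) -> SimulationResult:
    """Integrate from rest until quasi-steady swimming (or the period cap).

    The run starts from a straight chain at rest and is integrated period by
    period; after each tail-beat period the period-averaged center-of-mass
    speed (net displacement over one period divided by the period) is
    compared with the previous period's.  The run stops when the relative
    change falls below ``solver.steady_tol`` (minimum ``min_periods``), or is
    flagged non-quasi-steady at ``max_periods``.  Fully deterministic.
    """
    geom = config.geometry()
    args = _kernel_args(config, geom)
    opts = config.solver
    T = 1.0 / config.drive.f
    n_frames = max(int(round(T / opts.dt_out)), 8)

    y0 = ChainState.rest(geom.N).to_vector()
    frames = [y0[None, :]]
    times = [np.array([0.0])]
    period_speeds = []
    quasi = False
    msg = ""

    def rhs(t, y):
        return _rhs(t, y, *args)

    method = opts.method
    t0 = 0.0
    for p in range(opts.max_periods):
        com_start = _com_of(y0, geom)
        t_eval = t0 + np.linspace(0.0, T, n_frames + 1)[1:]
        sol = solve_ivp(
            rhs,
            (t0, t0 + T),
            y0,
            method=method,
            rtol=opts.rtol,
            atol=opts.atol,
            t_eval=t_eval,
            max_step=0.05 * T,
        )
        if not sol.success or not np.all(np.isfinite(sol.y)):
            msg = f"integration failed in period {p + 1}: {sol.message}"
            break
        frames.append(sol.y.T)
        times.append(sol.t)
        y0 = sol.y[:, -1].copy()
        t0 += T
        # net COM displacement over the period -> period-averaged speed
        com_end = _com_of(y0, geom)
        u = float(np.hypot(*(com_end - com_start)) / T)
        period_speeds.append(u)
        if progress:
            print(f"  period {p + 1}: U = {u / config.L:.4f} BL/s")
        if p + 1 >= opts.min_periods:
            u_prev = period_speeds[-2]
            floor = opts.speed_floor_bl * config.L
            if abs(u - u_prev) <= opts.steady_tol * max(u, floor) or (
                u < floor and u_prev < floor
            ):
                quasi = True
                break
    else:
        msg = msg or "quasi-steady criterion not met within max_periods"

    ys = np.vstack(frames)
    ts = np.concatenate(times)
    x, y, v_com, torque, chiL, chiR = _recompute_outputs(ys, config, geom)
    return SimulationResult(
        t=ts,
        x=x,
        y=y,
        v_com=v_com,
        torque=torque,
        chiL=chiL,
        chiR=chiR,
        config=config,
        quasi_steady=quasi,
        n_periods=len(period_speeds),
        period_speeds=np.asarray(period_speeds),
        message=msg,
    )


def _com_of(y: np.ndarray, geom: BodyGeometry) -> np.ndarray:
    st = ChainState.from_vector(np.asarray(y, dtype=float), geom.N)
    p = st.pivots(geom.h)
    return (geom.m_pivot[:, None] * p).sum(axis=0) / geom.m_pivot.sum()
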