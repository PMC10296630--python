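import numpy as np
import pytest
from scipy.integrate import solve_ivp

from anguilliform import FluidParams, SolverOptions, baseline_config, simulate
from anguilliform.mechanics import joint_torque
from anguilliform.solver import ChainState, derivatives


def passive_cfg(N=4, fluid=False):
    cfg = baseline_config(N=N)
    return cfg.with_(
        drive=cfg.drive.with_(D=0.0),
        fluid=FluidParams(enabled=fluid),
    )


def fd_lagrangian_acceleration(state, cfg, eps_v=0.5, eps_q=1e-6):
    """Independent oracle: accelerations from a finite-difference Lagrangian.

    Kinetic energy is evaluated from elementary chain kinematics (pivot
    velocities by the chain rule on the cumulative link vectors) and every
    derivative entering Lagrange's equations is taken numerically -- the
    analytic mass-matrix assembly of the production path is never used.
    Velocity differences are exact for any step since T is quadratic in the
    rates.  Fluid off, activation off.
    """
    geom = cfg.geometry()
    h = geom.h
    N = geom.N

    def kinetic(q, qd):
        phi, phid = q[2:], qd[2:]
        steps = h * phid[:, None] * np.stack([-np.sin(phi), np.cos(phi)], axis=1)
        pdot = np.zeros((N + 1, 2))
        pdot[0] = qd[:2]
        pdot[1:] = qd[:2] + np.cumsum(steps, axis=0)
        T = 0.5 * np.sum(geom.m_pivot[:, None] * pdot**2)
        T += 0.5 * np.sum(geom.J_link * phid**2)
        return T

    q = np.concatenate([state.head, state.phi])
    qd = np.concatenate([state.head_vel, state.phi_dot])
    n = len(q)
    eye = np.eye(n)

    M = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            ei, ej = eye[i] * eps_v, eye[j] * eps_v
            M[i, j] = (
                kinetic(q, qd + ei + ej)
                - kinetic(q, qd + ei - ej)
                - kinetic(q, qd - ei + ej)
                + kinetic(q, qd - ei - ej)
            ) / (4 * eps_v * eps_v)

    def momentum(qq, qqd):
        p = np.zeros(n)
        for i in range(n):
            ei = eye[i] * eps_v
            p[i] = (kinetic(qq, qqd + ei) - kinetic(qq, qqd - ei)) / (2 * eps_v)
        return p

    dTdq = np.zeros(n)
    dpdq_qd = np.zeros(n)
    for i in range(n):
        ei = eye[i] * eps_q
        dTdq[i] = (kinetic(q + ei, qd) - kinetic(q - ei, qd)) / (2 * eps_q)
        dpdq_qd += (momentum(q + ei, qd) - momentum(q - ei, qd)) / (2 * eps_q) * qd[i]

    # generalized forces: passive joint torques only
    geomN = geom.N
    Q = np.zeros(n)
    kj = geom.a_pivot[1:geomN] * geom.b_pivot[1:geomN] * cfg.materials.k_bar
    gj = geom.a_pivot[1:geomN] * geom.b_pivot[1:geomN] * cfg.materials.gamma_bar
    wj = geom.w_pivot[1:geomN]
    for j in range(geomN - 1):
        psi = state.phi[j + 1] - state.phi[j]
        psid = state.phi_dot[j + 1] - state.phi_dot[j]
        Mj = joint_torque(0.0, 0.0, psi, psid, kj[j], gj[j], wj[j], h)
        Q[2 + j + 1] += Mj
        Q[2 + j] -= Mj

    return np.linalg.solve(M, Q + dTdq - dpdq_qd)


class TestDerivatives:
    def test_equilibrium_has_zero_rate(self):
        # straight chain at rest with zero actuation: no mechanical motion
        # (the stimulated but force-free calcium states may still cycle)
        cfg = passive_cfg(N=6)
        rate = derivatives(ChainState.rest(6), 0.0, cfg)
        assert np.allclose(rate[: 4 + 2 * 6], 0.0, atol=1e-14)

    def test_matches_fd_lagrangian_oracle(self):
        """Newton-Euler balance vs brute-force numeric Lagrangian on 4 links."""
        cfg = passive_cfg(N=4)
        rng = np.random.default_rng(7)
        st = ChainState.rest(4)
        st.phi = 0.2 * rng.standard_normal(4)
        st.phi_dot = 0.5 * rng.standard_normal(4)
        st.head_vel = 0.05 * rng.standard_normal(2)
        rate = derivatives(st, 0.0, cfg)
        acc = rate[6:12]  # [Xdd, Ydd, phidd x4]
        acc_oracle = fd_lagrangian_acceleration(st, cfg)
        assert np.allclose(acc, acc_oracle, rtol=2e-4, atol=1e-7)

    def test_nonfinite_state_raises(self):
        cfg = passive_cfg()
        st = ChainState.rest(4)
        st.phi[0] = np.nan
        with pytest.raises(FloatingPointError):
            derivatives(st, 0.0, cfg)


def _integrate(cfg, state, t_end, n_out=200):
    y0 = state.to_vector()
    sol = solve_ivp(
        lambda t, y: derivatives(ChainState.from_vector(y, cfg.N), t, cfg),
        (0, t_end),
        y0,
        method="BDF",
        rtol=1e-8,
        atol=1e-11,
        t_eval=np.linspace(0, t_end, n_out),
    )
    assert sol.success
    return sol


def _momenta(y, geom):
    st = ChainState.from_vector(y, geom.N)
    p = st.pivots(geom.h)
    # pivot velocities via the chain jacobian
    e1 = np.stack([-np.sin(st.phi), np.cos(st.phi)], axis=1)
    pdot = np.zeros_like(p)
    pdot[0] = st.head_vel
    pdot[1:] = st.head_vel + np.cumsum(
        geom.h * st.phi_dot[:, None] * e1, axis=0
    )
    P = (geom.m_pivot[:, None] * pdot).sum(axis=0)
    Lz = np.sum(geom.m_pivot * (p[:, 0] * pdot[:, 1] - p[:, 1] * pdot[:, 0]))
    Lz += np.sum(geom.J_link * st.phi_dot)
    return P, Lz


class TestConservation:
    def test_momentum_conserved_without_fluid_or_activation(self):
        cfg = passive_cfg(N=6).with_(materials=cfg_mats())
        geom = cfg.geometry()
        st = ChainState.rest(6)
        st.phi = np.array([0.1, -0.2, 0.15, 0.0, -0.1, 0.2])
        st.phi_dot = np.array([0.5, -0.3, 0.2, 0.4, -0.5, 0.1])
        st.head_vel = np.array([0.02, -0.01])
        sol = _integrate(cfg, st, 0.5)
        P0, L0 = _momenta(sol.y[:, 0], geom)
        # drift bounded by the integration tolerance, tiny vs |P| ~ 6e-4
        for k in (len(sol.t) // 2, -1):
            P, Lz = _momenta(sol.y[:, k], geom)
            assert np.abs(P - P0).max() < 1e-8
            assert Lz == pytest.approx(L0, abs=1e-8)

    def test_passive_energy_decays_to_straight(self):
        """A bent chain released from rest relaxes; mechanical energy never grows."""
        cfg = passive_cfg(N=6)
        geom = cfg.geometry()
        st = ChainState.rest(6)
        st.phi = np.array([0.0, 0.3, -0.3, 0.3, -0.3, 0.0])
        sol = _integrate(cfg, st, 2.0)
        energies = []
        from anguilliform.mechanics import relative_extensions

        kj = geom.a_pivot[1:6] * geom.b_pivot[1:6] * cfg.materials.k_bar
        wj = geom.w_pivot[1:6]
        for k in range(len(sol.t)):
            stk = ChainState.from_vector(sol.y[:, k], 6)
            _, T = 0.0, 0.0
            P, _ = _momenta(sol.y[:, k], geom)
            # kinetic energy
            e1 = np.stack([-np.sin(stk.phi), np.cos(stk.phi)], axis=1)
            pdot = np.zeros((7, 2))
            pdot[0] = stk.head_vel
            pdot[1:] = stk.head_vel + np.cumsum(geom.h * stk.phi_dot[:, None] * e1, axis=0)
            T = 0.5 * np.sum(geom.m_pivot[:, None] * pdot**2) + 0.5 * np.sum(
                geom.J_link * stk.phi_dot**2
            )
            psi = np.diff(stk.phi)
            dR, dL = relative_extensions(psi, wj, geom.h)
            V = 0.5 * np.sum(kj * geom.h * (dR**2 + dL**2))
            energies.append(T + V)
        energies = np.array(energies)
        assert np.all(np.diff(energies) <= 1e-9 * energies[0])
        # and the chain ends nearly straight
        final = ChainState.from_vector(sol.y[:, -1], 6)
        assert np.max(np.abs(np.diff(final.phi))) < 1e-3


def cfg_mats():
    from anguilliform.mechanics import MaterialParams

    return MaterialParams(E=0.01e6, mu_body=50.0)


class TestSimulate:
    def test_zero_activation_means_no_propulsion(self):
        cfg = passive_cfg(N=6, fluid=True).with_(
            solver=SolverOptions(min_periods=2, max_periods=2)
        )
        res = simulate(cfg)
        assert np.hypot(*(res.v_com.mean(axis=0))) < 1e-10

    def test_midline_arc_length_is_L(self, small_result):
        dx = np.diff(small_result.x, axis=1)
        dy = np.diff(small_result.y, axis=1)
        arc = np.sqrt(dx**2 + dy**2).sum(axis=1)
        assert np.allclose(arc, small_result.L, rtol=1e-12)

    def test_uniform_output_grid(self, small_result):
        dt = np.diff(small_result.t)
        assert np.allclose(dt, small_result.config.solver.dt_out, atol=1e-9)

    def test_deterministic_rerun(self, small_cfg, small_result):
        res2 = simulate(small_cfg)
        assert np.array_equal(res2.v_com, small_result.v_com)
        assert np.array_equal(res2.y, small_result.y)

    def test_mirrored_drive_mirrors_trajectory(self, small_cfg, small_result):
        """Swapping left/right stimulation reflects the path about the x axis."""
        cfg2 = small_cfg.with_(
            drive=small_cfg.drive.with_(phase_offset=np.pi)
        )
        res2 = simulate(cfg2)
        n = min(len(res2.t), len(small_result.t))
        # mirrored to within the integration tolerance (body scale 0.2 m)
        assert np.allclose(res2.y[:n], -small_result.y[:n], atol=1e-5)
        assert np.allclose(res2.x[:n], small_result.x[:n], atol=1e-5)

    def test_tolerance_robustness(self, small_cfg, small_result):
        """Tightening integrator tolerances leaves the mean speed unchanged."""
        tight = small_cfg.with_(
            solver=SolverOptions(
                min_periods=3, max_periods=4, rtol=5e-7, atol=5e-10
            )
        )
        res2 = simulate(tight)
        u1 = small_result.period_speeds[-1]
        u2 = res2.period_speeds[-1]
        assert abs(u1 - u2) / u2 < 0.005

    def test_fluid_damps_head_oscillation(self, small_cfg):
        """Without fluid forces the head swings wider: the resistive load
        is pure dissipation and most effective on the thin, fast head."""
        from anguilliform.metrics import midline_field

        on = simulate(small_cfg)
        off = simulate(small_cfg.with_(fluid=FluidParams(enabled=False)))

        def envelope(res):
            f = midline_field(res, n_periods=2)
            return np.max(np.abs(f.y - f.y.mean(axis=1, keepdims=True)), axis=1)

        e_on, e_off = envelope(on), envelope(off)
        assert e_off[0] > e_on[0]
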