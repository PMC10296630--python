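import numpy as np
import pytest

from anguilliform import MaterialParams, SolverOptions, baseline_config, simulate


@pytest.fixture(scope="session")
def small_cfg():
    """A light configuration for solver-level tests: short body, few links."""
    cfg = baseline_config(N=10)
    return cfg.with_(
        drive=cfg.drive.with_(D=0.1),
        solver=SolverOptions(min_periods=3, max_periods=4),
    )


@pytest.fixture(scope="session")
def small_result(small_cfg):
    return simulate(small_cfg)


@pytest.fixture(scope="session")
def baseline_result():
    """The full reference run (Table-1 defaults, calibrated actuation)."""
    return simulate(baseline_config())


def traveling_wave_field(
    M=24, Nt=128, f=1.0, lam=0.2, L=0.2, A=0.01, periods=2, reverse=False, standing=0.0
):
    """Synthetic midline: A sin(2 pi (x/lam -/+ f t)) + standing * sin(kx)cos(wt)."""
    from anguilliform.cod import MidlineField

    x = np.linspace(0.0, L, M, endpoint=False)
    t = np.arange(Nt) * (periods / f / Nt)
    k = 2 * np.pi / lam
    om = 2 * np.pi * f
    sign = 1.0 if reverse else -1.0
    y = A * np.sin(k * x[:, None] + sign * om * t[None, :])
    if standing:
        y = y + standing * A * np.sin(k * x[:, None]) * np.cos(om * t[None, :])
    return MidlineField(stations=x, times=t, y=y)
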