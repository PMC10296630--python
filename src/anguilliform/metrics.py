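"""Swimming performance metrics: speed, body-wave speed, efficiency.

* **Mean asymptotic speed (MAS)** -- the magnitude of the center-of-mass
  velocity averaged over the final whole tail-beat periods of a quasi-steady
  run, in body lengths per second.  Averaging the velocity *vector* over
  whole periods cancels the lateral recoil oscillation exactly.
* **Body-wave speed V** -- phase speed of the rostro-caudal lateral
  displacement wave, in BL/s.  Primary estimator: slope of the dominant
  COD-mode phase along arc position (the same decomposition used for the
  traveling index); cross-check: lagged cross-correlation between two trunk
  stations.  Positive V means head-to-tail propagation.
* **Efficiency** -- from elongated-body theory, ``eta = (1 + U/V) / 2``:
  the slip ratio U/V of an undulatory swimmer sets how much of the wave
  momentum is converted to forward motion; eta -> 1 as U -> V.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict

import numpy as np

from .cod import MidlineField, decompose, traveling_index
from .solver import SimulationResult

__all__ = [
    "GaitMetrics",
    "mean_asymptotic_speed",
    "wave_speed",
    "efficiency",
    "midline_field",
    "evaluate",
    "lateral_oscillation_frequency",
]


@dataclass
class GaitMetrics:
    """Scalar gait summary; speeds in BL/s, tail amplitude in BL."""

    U_bls: float
    V_bls: float
    eta: float
    f_hz: float
    tail_amp_bl: float
    traveling_index: float
    quasi_steady: bool

    def to_dict(self) -> dict:
        d = asdict(self)
        d["quasi_steady"] = bool(d["quasi_steady"])
        return d


def _final_window(result: SimulationResult, n_periods: int) -> slice:
    fpp = result.frames_per_period()
    n = min(n_periods, result.n_periods)
    if n < 1:
        raise ValueError("result contains no complete period")
    return slice(len(result.t) - n * fpp, len(result.t))


def mean_asymptotic_speed(
    result: SimulationResult, f: float | None = None, n_periods: int = 3
) -> float:
    """Period-averaged forward COM speed over the final whole periods [BL/s].

    Warns (and still computes) if the run never met the quasi-steady
    criterion.
    """
    if not result.quasi_steady:
        warnings.warn("run is not quasi-steady; MAS may be unreliable")
    win = _final_window(result, n_periods)
    v = result.v_com[win].mean(axis=0)
    return float(np.hypot(*v) / result.L)


def swim_direction(result: SimulationResult, n_periods: int = 3) -> np.ndarray:
    """Unit vector of net COM travel over the final periods."""
    win = _final_window(result, n_periods)
    v = result.v_com[win].mean(axis=0)
    nv = np.hypot(*v)
    return v / nv if nv > 0 else np.array([-1.0, 0.0])


def midline_field(
    result: SimulationResult,
    n_periods: int = 2,
    station_range: tuple[float, float] = (0.0, 1.0),
) -> MidlineField:
    """Lateral midline displacement in the COM frame over the final periods.

    Lateral means perpendicular to the mean swimming direction; each station
    is de-meaned by the COD machinery downstream.  ``station_range`` selects
    arc positions as fractions of L.
    """
    win = _final_window(result, n_periods)
    d = swim_direction(result, n_periods)
    n_hat = np.array([-d[1], d[0]])
    geom = result.config.geometry()
    m = geom.m_pivot
    com_x = (result.x[win] * m).sum(axis=1) / m.sum()
    com_y = (result.y[win] * m).sum(axis=1) / m.sum()
    lat = (result.x[win] - com_x[:, None]) * n_hat[0] + (
        result.y[win] - com_y[:, None]
    ) * n_hat[1]
    s = geom.x_pivot / geom.L
    sel = (s >= station_range[0] - 1e-12) & (s <= station_range[1] + 1e-12)
    return MidlineField(
        stations=geom.x_pivot[sel], times=result.t[win], y=lat[:, sel].T
    )


def wave_speed(
    result_or_field,
    f: float | None = None,
    L: float | None = None,
    fit_range: tuple[float, float] = (0.25, 0.95),
    xcorr_stations: tuple[float, float] = (0.4, 0.8),
    return_both: bool = False,
):
    """Phase speed of the lateral displacement wave along the trunk [BL/s].

    Primary estimator: straight-line fit of the unwrapped dominant-COD-mode
    phase against arc position over ``fit_range`` (fractions of L); speed is
    ``2 pi f / |slope|``, signed positive for head-to-tail propagation.
    Cross-check: peak-lag cross-correlation between the stations nearest
    ``xcorr_stations``.  With ``return_both`` the pair ``(V_cod, V_xcorr)``
    is returned; otherwise the primary estimate.

    Accepts a :class:`SimulationResult` (f and L inferred) or a
    :class:`MidlineField` (pass ``f`` and ``L``).  Warns when the motion is
    standing-dominated (traveling index < 0.05), where the phase is
    ill-defined.
    """
    if isinstance(result_or_field, SimulationResult):
        field = midline_field(result_or_field)
        f = result_or_field.f
        L = result_or_field.L
    else:
        field = result_or_field
        if f is None or L is None:
            raise ValueError("pass f and L together with a MidlineField")

    res = decompose(field)
    w1 = res.dominant
    if res.traveling_index < 0.05:
        warnings.warn("standing-dominated motion: wave phase is ill-defined")

    s = field.stations / L
    sel = (s >= fit_range[0] - 1e-9) & (s <= fit_range[1] + 1e-9)
    if sel.sum() < 3:
        sel = np.ones_like(s, dtype=bool)
    phase = np.unwrap(np.angle(w1[sel]))
    slope = np.polyfit(field.stations[sel], phase, 1)[0]  # rad / m
    # Determine the time sense of the analytic signal: the modal coordinate
    # a1(t) = w1^H z rotates as exp(+i omega t) for hilbert()'s convention.
    # y ~ Re[w1(x) e^{i omega t}]; crest x(t) satisfies arg w1 + omega t = const,
    # so dx/dt = -omega / slope: head-to-tail (positive) speed for slope < 0.
    if slope == 0:
        raise ValueError("degenerate spatial phase: cannot estimate wave speed")
    V_cod = float(-2.0 * np.pi * f / slope / L)

    # cross-correlation cross-check between two trunk stations.  The record
    # is (quasi-)periodic, so the correlation peaks once per period; the peak
    # nearest the primary estimate's implied lag resolves that ambiguity.
    i1 = int(np.argmin(np.abs(s - xcorr_stations[0])))
    i2 = int(np.argmin(np.abs(s - xcorr_stations[1])))
    y1 = field.y[i1] - field.y[i1].mean()
    y2 = field.y[i2] - field.y[i2].mean()
    c = np.correlate(y2, y1, mode="full")
    dt = float(field.times[1] - field.times[0])
    lags = (np.arange(c.size) - (len(y1) - 1)) * dt
    dx = float(field.stations[i2] - field.stations[i1])
    expect = dx / (V_cod * L)
    window = (lags >= expect - 0.45 / f) & (lags <= expect + 0.45 / f)
    if not window.any():
        window = np.abs(lags) <= 0.5 / f
    lag = float(lags[window][np.argmax(c[window])])
    V_x = float(dx / lag / L) if lag != 0 else np.inf

    return (V_cod, V_x) if return_both else V_cod


def efficiency(U: float, V: float) -> float:
    """Elongated-body-theory efficiency ``eta = (1 + U/V) / 2``; requires V > 0."""
    if V <= 0:
        raise ValueError("wave speed V must be positive")
    return 0.5 * (1.0 + U / V)


def tail_amplitude(result: SimulationResult, n_periods: int = 2) -> float:
    """Peak lateral excursion of the tail tip in the COM frame [BL]."""
    field = midline_field(result, n_periods)
    ytail = field.y[-1] - field.y[-1].mean()
    return float(np.max(np.abs(ytail)) / result.L)


def lateral_oscillation_frequency(result: SimulationResult, n_periods: int = 4) -> float:
    """Dominant frequency [Hz] of the lateral COM velocity (recoil oscillation)."""
    win = _final_window(result, min(n_periods, result.n_periods))
    d = swim_direction(result)
    n_hat = np.array([-d[1], d[0]])
    vlat = result.v_com[win] @ n_hat
    vlat = vlat - vlat.mean()
    dt = float(result.t[1] - result.t[0])
    spec = np.abs(np.fft.rfft(vlat))
    freqs = np.fft.rfftfreq(len(vlat), dt)
    return float(freqs[np.argmax(spec[1:]) + 1])


def evaluate(result: SimulationResult, cod_periods: int = 2) -> GaitMetrics:
    """Full scalar gait summary of a run."""
    U = mean_asymptotic_speed(result)
    V = wave_speed(result)
    field = midline_field(result, n_periods=cod_periods)
    xi = decompose(field).traveling_index
    return GaitMetrics(
        U_bls=U,
        V_bls=V,
        eta=efficiency(U, V) if V > 0 else np.nan,
        f_hz=result.f,
        tail_amp_bl=tail_amplitude(result),
        traveling_index=xi,
        quasi_steady=result.quasi_steady,
    )
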