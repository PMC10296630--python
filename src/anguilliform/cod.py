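"""Complex orthogonal decomposition (COD) of midline motions.

A midline motion sampled at ``M`` stations over ``Nt`` instants is lifted to
complex analytic signals ``z_m(t) = y_m(t) + i H[y_m](t)`` (``H`` the Hilbert
transform), collected into ``Z`` (M x Nt), and eigen-decomposed through the
complex covariance ``R = Z Z^H / Nt``.  The dominant eigenvector ``w_1`` is a
complex spatial mode whose real and imaginary parts span the plane of the
motion: for a pure traveling wave they are independent (equal in norm,
orthogonal), for a pure standing wave they are collinear.  The traveling
index

    xi = 1 / cond([Re w_1, Im w_1]) = sigma_min / sigma_max

(reciprocal spectral condition number of the M x 2 matrix) is therefore 1
for pure traveling and 0 for pure standing motion.

The dominant motion splits into pure traveling + pure standing parts through
the singular-value geometry of ``B = [Re w_1, Im w_1] = U S V^T``: the
circular component ``U diag(s2, s2) V^T`` (equal singular values) is the
traveling part and the rank-one remainder ``U diag(s1 - s2, 0) V^T`` the
standing part; the two reconstructed fields sum to the mode's motion.

Stations are de-meaned before the transform, which makes the index invariant
to rigid lateral offsets.  Input should cover whole periods on a uniform
time grid (the FFT-based Hilbert transform is exact for periodic records).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal import hilbert

__all__ = [
    "MidlineField",
    "CODResult",
    "analytic_signal",
    "decompose",
    "traveling_index",
    "split_standing_traveling",
]


@dataclass(frozen=True)
class MidlineField:
    """Lateral displacement y(x_m, t_n): stations (M,), times (Nt,), y (M, Nt)."""

    stations: np.ndarray
    times: np.ndarray
    y: np.ndarray

    def __post_init__(self):
        y = np.asarray(self.y, dtype=float)
        if y.ndim != 2 or y.shape != (len(self.stations), len(self.times)):
            raise ValueError("y must have shape (M stations, Nt times)")
        if len(self.stations) < 3 or len(self.times) < 4:
            raise ValueError("need at least 3 stations and 4 time samples")
        dt = np.diff(self.times)
        if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-12):
            raise ValueError("time sampling must be uniform")

    @classmethod
    def from_csv(cls, path) -> "MidlineField":
        """Read a stations-by-times table: first column station, header times."""
        import pandas as pd

        df = pd.read_csv(path, index_col=0)
        return cls(
            stations=df.index.to_numpy(dtype=float),
            times=df.columns.to_numpy(dtype=float),
            y=df.to_numpy(dtype=float),
        )

    def to_csv(self, path) -> None:
        import pandas as pd

        pd.DataFrame(self.y, index=self.stations, columns=self.times).to_csv(path)


@dataclass
class CODResult:
    """Modes (M, r) column-orthonormal, eigenvalues (r,) descending, and the
    dominant mode's traveling index and standing/traveling split."""

    modes: np.ndarray
    eigenvalues: np.ndarray
    traveling_index: float
    mode_coords: np.ndarray  # (r, Nt) complex modal coordinates
    field: MidlineField

    @property
    def dominant(self) -> np.ndarray:
        return self.modes[:, 0]

    @property
    def energy_fractions(self) -> np.ndarray:
        return self.eigenvalues / self.eigenvalues.sum()

    def to_json_dict(self) -> dict:
        return {
            "eigenvalues": [float(v) for v in self.eigenvalues],
            "energy_fractions": [float(v) for v in self.energy_fractions],
            "traveling_index": float(self.traveling_index),
        }


def analytic_signal(y: np.ndarray) -> np.ndarray:
    """Complex analytic signal per station: real part the (de-meaned) input,
    imaginary part its Hilbert transform; one-sided spectrum.

    ``y`` is (M, Nt) or (Nt,).  A constant (zero after de-meaning) series
    yields a zero analytic signal and a warning.
    """
    y = np.asarray(y, dtype=float)
    yd = y - y.mean(axis=-1, keepdims=True)
    if np.any(np.ptp(yd, axis=-1) == 0):
        warnings.warn("constant time series: analytic signal is identically zero")
    return hilbert(yd, axis=-1)


def decompose(field: MidlineField) -> CODResult:
    """Eigen-decomposition of the complex covariance ``Z Z^H / Nt``.

    Modes are sorted by descending eigenvalue; numerically rank-deficient
    directions (eigenvalues below ``1e-12`` of the total) are dropped.  The
    eigenvalues sum to the mean signal energy of ``Z``.
    """
    Z = analytic_signal(field.y)
    Nt = Z.shape[1]
    R = Z @ Z.conj().T / Nt
    lam, W = np.linalg.eigh(R)
    order = np.argsort(lam)[::-1]
    lam = np.clip(lam[order], 0.0, None)
    W = W[:, order]
    total = lam.sum()
    keep = lam > max(total, 1e-300) * 1e-12
    keep[0] = True
    lam, W = lam[keep], W[:, keep]
    coords = W.conj().T @ Z
    return CODResult(
        modes=W,
        eigenvalues=lam,
        traveling_index=traveling_index(W[:, 0]) if total > 0 else 0.0,
        mode_coords=coords,
        field=field,
    )


def traveling_index(w1: np.ndarray) -> float:
    """Reciprocal 2-norm condition number of ``[Re w1, Im w1]`` in [0, 1]."""
    w1 = np.asarray(w1)
    if not np.any(np.abs(w1) > 0):
        raise ValueError("traveling index undefined for a zero mode")
    B = np.stack([w1.real, w1.imag], axis=1)
    s = np.linalg.svd(B, compute_uv=False)
    return float(s[1] / s[0]) if s[0] > 0 else 0.0


def split_standing_traveling(w1: np.ndarray, field: MidlineField):
    """Split the dominant-mode motion into pure standing + pure traveling parts.

    Returns ``(standing, traveling)``, each a dict with keys ``mode`` (complex
    station vector) and ``y`` (reconstructed real field, M x Nt).  The two
    reconstructed fields sum to the dominant mode's own motion
    ``Re(w1 a1(t)^T)`` with ``a1 = w1^H Z``.
    """
    w1 = np.asarray(w1, dtype=complex)
    Z = analytic_signal(field.y)
    a1 = w1.conj() @ Z  # (Nt,) modal coordinate
    B = np.stack([w1.real, w1.imag], axis=1)
    U, s, Vt = np.linalg.svd(B, full_matrices=False)
    B_trav = U @ np.diag([s[1], s[1]]) @ Vt
    B_stand = U @ np.diag([s[0] - s[1], 0.0]) @ Vt
    w_trav = B_trav[:, 0] + 1j * B_trav[:, 1]
    w_stand = B_stand[:, 0] + 1j * B_stand[:, 1]
    standing = {"mode": w_stand, "y": np.real(np.outer(w_stand, a1))}
    traveling = {"mode": w_trav, "y": np.real(np.outer(w_trav, a1))}
    return standing, traveling
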