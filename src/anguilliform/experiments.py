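"""Config-driven parameter sweeps over stiffness, actuation and frequency.

Grids over Young's modulus E, actuation amplitude D and tail-beat frequency
f map to fully resolved simulation configurations; each cell yields one
:class:`~anguilliform.metrics.GaitMetrics` plus the traveling index.  Cell
results are cached on disk by config hash, so interrupted sweeps resume and
re-runs are free.  Everything is deterministic -- one replicate per cell.

"Variable stiffness" is realized as an outer maximization over the E grid
for each (D, f) cell: the comparison is between the best achievable
performance when the body may pick its stiffness and the performance at one
fixed stiffness (no within-run stiffness controller is modelled).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import SimulationConfig, baseline_config
from .mechanics import MaterialParams
from .metrics import evaluate
from .solver import simulate

__all__ = ["SweepSpec", "run_sweep", "run_cell", "compare_fixed_vs_variable", "variable_stiffness_E_grid"]

log = logging.getLogger(__name__)

#: default logarithmic E grid for variable-stiffness mode: 10 kPa .. 1 MPa
def variable_stiffness_E_grid(n: int = 13) -> np.ndarray:
    return np.logspace(np.log10(0.01e6), np.log10(1.0e6), n)


@dataclass(frozen=True)
class SweepSpec:
    """Grids (each in SI units: E [Pa], D [-], f [Hz]) and a base config."""

    E: tuple
    D: tuple
    f: tuple
    base: SimulationConfig = field(default_factory=baseline_config)
    cache_dir: str | None = None

    def __post_init__(self):
        if not (len(self.E) and len(self.D) and len(self.f)):
            raise ValueError("sweep grids must be non-empty")

    def cell_config(self, E: float, D: float, f: float) -> SimulationConfig:
        return self.base.with_(
            materials=MaterialParams(E=float(E), mu_body=self.base.materials.mu_body),
            drive=self.base.drive.with_(D=float(D), f=float(f)),
        )


def run_cell(cfg: SimulationConfig, cache_dir=None) -> dict:
    """One fully resolved simulation -> metric dict, cached by config hash."""
    if cache_dir is not None:
        cache = Path(cache_dir) / f"{cfg.hash()}.json"
        if cache.exists():
            return json.loads(cache.read_text())
    result = simulate(cfg)
    m = evaluate(result).to_dict()
    m["config_hash"] = cfg.hash()
    if cache_dir is not None:
        Path(cache_dir).mkdir(parents=True, exist_ok=True)
        cache.write_text(json.dumps(m))
    return m


def run_sweep(spec: SweepSpec) -> pd.DataFrame:
    """Tidy table: one row per (E, D, f) cell with the gait metrics.

    Individual cell failures are recorded (``error`` column) and the sweep
    continues.
    """
    rows = []
    for E in spec.E:
        for D in spec.D:
            for f in spec.f:
                row = {"E_pa": float(E), "D": float(D), "f_hz": float(f)}
                try:
                    row.update(run_cell(spec.cell_config(E, D, f), spec.cache_dir))
                except Exception as exc:  # noqa: BLE001 - sweep must continue
                    log.warning("cell (E=%g, D=%g, f=%g) failed: %s", E, D, f, exc)
                    row["error"] = str(exc)
                rows.append(row)
    return pd.DataFrame(rows)


def compare_fixed_vs_variable(
    fixed_E: float,
    E_grid,
    D_grid,
    f_grid,
    base: SimulationConfig | None = None,
    cache_dir=None,
) -> pd.DataFrame:
    """Per-(D, f) speed/efficiency increments of variable over fixed stiffness.

    For each cell the variable-stiffness value is the best over ``E_grid``
    (which is augmented with ``fixed_E`` so increments are never negative);
    the increment columns are best-over-E minus the fixed-E value.
    """
    base = base or baseline_config()
    E_all = sorted(set(float(E) for E in E_grid) | {float(fixed_E)})
    spec = SweepSpec(E=tuple(E_all), D=tuple(D_grid), f=tuple(f_grid), base=base, cache_dir=cache_dir)
    table = run_sweep(spec)
    ok = table[~table.get("error", pd.Series(index=table.index, dtype=object)).notna()] if "error" in table else table
    rows = []
    for D in D_grid:
        for f in f_grid:
            cell = ok[(ok.D == float(D)) & (ok.f_hz == float(f))]
            fixed = cell[cell.E_pa == float(fixed_E)]
            if not len(cell) or not len(fixed):
                continue
            best_idx = cell.U_bls.idxmax()
            rows.append(
                {
                    "D": float(D),
                    "f_hz": float(f),
                    "U_fixed_bls": float(fixed.U_bls.iloc[0]),
                    "U_best_bls": float(cell.U_bls.max()),
                    "E_best_pa": float(cell.loc[best_idx, "E_pa"]),
                    "dU_bls": float(cell.U_bls.max() - fixed.U_bls.iloc[0]),
                    "eta_fixed": float(fixed.eta.iloc[0]),
                    "eta_best": float(cell.eta.max()),
                    "deta": float(cell.eta.max() - fixed.eta.iloc[0]),
                }
            )
    return pd.DataFrame(rows)
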