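"""Simulation configuration: one dataclass mirroring the model's parameter table.

The defaults are the reference swimmer: a 20 cm body cut into 40 segments,
neutrally buoyant in water (both densities 1000 kg/m^3), Young's modulus
0.1 MPa, body viscosity 3 kPa s, driven at 1 Hz by a one-body-length
activation wave.  The baseline actuation amplitude ``D`` and the muscle
stress scale are the package's documented calibration (see docs/methods.md).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import yaml

from .geometry import BodyGeometry, discretize
from .hydrodynamics import FluidParams
from .mechanics import MaterialParams
from .muscle import CalciumKinetics, MuscleDrive

__all__ = ["SolverOptions", "SimulationConfig", "baseline_config"]

#: calibrated baseline actuation amplitude (dimensionless, in the biological
#: 0.01-0.2 range) used when none is specified; see docs/methods.md.
BASELINE_D = 0.2


@dataclass(frozen=True)
class SolverOptions:
    """Integrator settings: stiff adaptive solver, 1 ms output grid."""

    method: str = "BDF"
    rtol: float = 1.0e-6
    atol: float = 1.0e-9
    dt_out: float = 1.0e-3
    min_periods: int = 10
    max_periods: int = 30
    steady_tol: float = 0.005  # relative change of period-averaged speed
    speed_floor_bl: float = 1.0e-4  # [BL/s] below which the fish counts as at rest


@dataclass(frozen=True)
class SimulationConfig:
    L: float = 0.20
    N: int = 40
    rho: float = 1000.0
    head_fraction: float = 0.1
    volumetric: bool = True
    materials: MaterialParams = field(default_factory=lambda: MaterialParams(E=0.1e6, mu_body=3.0e3))
    drive: MuscleDrive = field(default_factory=lambda: MuscleDrive(D=BASELINE_D, f=1.0))
    fluid: FluidParams = field(default_factory=FluidParams)
    solver: SolverOptions = field(default_factory=SolverOptions)

    def geometry(self) -> BodyGeometry:
        return discretize(
            self.L, self.N, self.rho, self.head_fraction, volumetric=self.volumetric
        )

    def with_(self, **kw) -> "SimulationConfig":
        return replace(self, **kw)

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        if "materials" in d and isinstance(d["materials"], dict):
            d["materials"] = MaterialParams(**d["materials"])
        if "drive" in d and isinstance(d["drive"], dict):
            dd = dict(d["drive"])
            if isinstance(dd.get("kinetics"), dict):
                dd["kinetics"] = CalciumKinetics(**dd["kinetics"])
            d["drive"] = MuscleDrive(**dd)
        if "fluid" in d and isinstance(d["fluid"], dict):
            d["fluid"] = FluidParams(**d["fluid"])
        if "solver" in d and isinstance(d["solver"], dict):
            d["solver"] = SolverOptions(**d["solver"])
        return cls(**d)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def hash(self) -> str:
        """Stable content hash of the fully resolved configuration."""
        blob = json.dumps(self.to_dict(), sort_keys=True, default=float)
        return hashlib.sha1(blob.encode()).hexdigest()[:16]


def baseline_config(**overrides) -> SimulationConfig:
    """The reference configuration (see module docstring), with overrides."""
    cfg = SimulationConfig()
    return cfg.with_(**overrides) if overrides else cfg
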