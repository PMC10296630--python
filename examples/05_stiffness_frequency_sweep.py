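"""Sweep tail-beat frequency at fixed body stiffness.

At a soft body (E = 0.006 MPa) and small actuation (D = 0.03) the forward
speed rises with tail-beat frequency to an optimum and then falls: beyond
the optimum the viscoelastic body cannot follow the drive and the wave
amplitude collapses.  A coarse three-point sweep keeps this example quick
(~2 min); widen the grids for the full picture.
"""

from anguilliform import SolverOptions, baseline_config
from anguilliform.experiments import SweepSpec, run_sweep

base = baseline_config().with_(
    solver=SolverOptions(min_periods=8, max_periods=12)
)
spec = SweepSpec(E=(0.006e6,), D=(0.03,), f=(0.5, 1.0, 2.0), base=base)
table = run_sweep(spec)

print(table[["E_pa", "D", "f_hz", "U_bls", "eta", "traveling_index"]].to_string(index=False))
best = table.loc[table.U_bls.idxmax()]
print(f"\npeak speed {best.U_bls:.3f} BL/s at f = {best.f_hz} Hz "
      "(rises from 0.5 Hz, falls by 2 Hz)")
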