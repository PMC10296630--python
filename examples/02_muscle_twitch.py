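"""Calcium-kinetics activation: one twitch and the traveling wave.

Prints the activation time course of a single 0.36 s stimulation burst
(rise toward a plateau while stimulated, relaxation after) and the
frequency saturation of the periodic drive: at high tail-beat frequency a
burst ends before the plateau is reached, so the per-cycle peak activation
drops.
"""

import numpy as np

from anguilliform import CalciumKinetics, MuscleDrive, discretize
from anguilliform.muscle import activation_wave, calcium_activation

k = CalciumKinetics()
print(f"rate constants: k1={k.k1}, k2={k.k2}, k3={k.k3}, k4={k.k4} 1/s")

t = np.linspace(0.0, 1.2, 13)
chi = calcium_activation(t, stim_on=0.2, stim_off=0.56, kinetics=k)
print("\nsingle 0.36 s burst (stimulated 0.2-0.56 s):")
for ti, ci in zip(t, chi):
    bar = "#" * int(40 * ci)
    print(f"  t={ti:4.1f} s  chi={ci:5.3f}  {bar}")

geom = discretize(0.2, 40, 1000.0)
print("\nper-cycle peak activation vs drive frequency (segment at mid-body):")
for f in (1.0, 2.0, 3.0, 5.0):
    drive = MuscleDrive(D=0.1, f=f)
    ts = np.linspace(4.0 / f, 5.0 / f, 150)  # one cycle after transients
    chiL, _ = activation_wave(geom, drive, ts)
    print(f"  f = {f:3.1f} Hz -> peak chi = {chiL[20].max():.3f}")
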