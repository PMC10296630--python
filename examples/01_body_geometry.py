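"""Discretize the eel-like body and inspect its geometry.

Builds the default 20 cm body at 40 segments and prints the section
profiles, masses and muscle arms.  The printed total mass is the volume
integral of the elliptic sections times the (neutral-buoyancy) density —
a ~20 cm eel weighs a few tens of grams.
"""

import numpy as np

from anguilliform import discretize

geom = discretize(L=0.20, N=40, rho=1000.0, head_fraction=0.1)

print(f"segments: {geom.N}, segment length h = {geom.h * 1000:.1f} mm")
print(f"passive head segments (no muscle): {geom.n_passive}")
print(f"total body mass: {geom.total_mass * 1000:.1f} g")
mid = geom.N // 2
print(
    f"mid-body section: a = {geom.a_mid[mid] * 1000:.1f} mm, "
    f"b = {geom.b_mid[mid] * 1000:.1f} mm, muscle arm w = {geom.w_mid[mid] * 1000:.2f} mm"
)
print(f"peak half-width b_max = {geom.b_mid.max() * 1000:.1f} mm "
      f"at x = {geom.x_mid[np.argmax(geom.b_mid)] / geom.L:.2f} L")

print("\nper-segment table (head):")
print(geom.to_csv().splitlines()[0])
for line in geom.to_csv().splitlines()[1:5]:
    print(line)
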