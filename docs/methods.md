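# Methods

## The model

The swimmer is a planar chain of `N` rigid links (default 40) discretizing a
20 cm eel-like body.  Cross-sections are ellipses: the dorso-ventral
half-height `a(x)` follows a three-piece profile — an elliptic nose
`sqrt(0.08 L x − x²)` for `x < 0.04 L`, a shallow trunk parabola
`0.04 L − 0.03 L ((x − 0.04 L)/(0.91 L))²`, and a linear taper `(L − x)/5`
over the last 5% — and the lateral half-width `b(x)` is the single parabola
`0.08 L [1 − ((x − 0.51 L)/(0.51 L))²]`.  The three `a` branches are exactly
continuous at both breakpoints, which is the constraint that fixes the nose
branch; the profile functions are pluggable if a different body is wanted.
Segment masses are elliptic slices `ρ π a b h` (the density is volumetric,
so this is the dimensionally consistent choice for the planar model; a
per-unit-height 2-D mass is available behind a flag) and are lumped at the
pivots, with a slab inertia `m h²/12` per link.

Neighbouring links are coupled by serial–parallel units: a revolute joint
plus a pair of muscle–spring–dashpot legs anchored to myoseptal arms of
half-width `w = b/2`.  With inter-link angle `ψ`, the leg extensions and
moment arms follow from the chord geometry,

    Δ_R,L = cos(ψ/2) − 1 ∓ (2w/h) sin(ψ/2),
    L_R,L = w cos(ψ/2) ± (h/2) sin(ψ/2),

the leg tensions are `G = f_active + k Δ + γ dΔ/dt`, and the joint torque is
the exact `M = G_R L_R − G_L L_L` (the small-angle expansion is kept only as
a test oracle).  Per-joint coefficients scale with the cross-section,
`k = a b k̄`, `γ = a b γ̄`, and the fiber stiffness maps to a Young's modulus
through `E = 2 k̄/π`.  This scaling is exactly the one for which the
linearized joint reproduces the bending stiffness of a continuum elliptic
beam: the passive torque is `−2 k w² ψ/h` and `2 k w² = E · (π a b³/4) = EI`.
The damping is mapped the same way, `γ̄ = π μ/2` from the body viscosity `μ`
(no independent damping calibration exists for this model; this choice makes
`μ` the loss modulus of the equivalent Voigt rod).  Sign convention: `ψ > 0`
shortens the R-labelled leg; mirror symmetry is enforced by tests, so the
label choice only reflects trajectories.

Muscle activation follows two-state calcium kinetics per side per joint,

    dc/dt = k1 s(t) (1 − c) − k2 c,      dχ/dt = k3 c (1 − χ) − k4 χ,

driven by a periodic stimulus `s(t)` (duty 0.5 per side, sides antiphase)
whose onset travels head-to-tail at `wave_length · L · f` (default one body
length per period — the canonical anguilliform drive).  The head (first 10%
of the body) has no muscle.  Rate constants default to
`(k1..k4) = (20, 10, 15, 8) s⁻¹`, chosen once to give a twitch-like rise to
plateau in ~0.2 s and relaxation in ~0.15 s; with these, per-cycle peak
activation is non-increasing in stimulation frequency and bursts at ~5 Hz
end before the plateau is reached.  Stimulus edges are smoothed with a 10 ms
tanh ramp — neural bursts are not discontinuous, and a C¹ drive is kinder to
the stiff integrator.  Active force is `f = χ D σ₀ a b`: `D ∈ [0.01, 0.2]`
is the dimensionless recruited fraction of the maximal muscle stress and
`σ₀` a single global stress scale (see Calibration).

Fluid loading is Taylor's resistive law per unit length, evaluated at each
link midpoint from the local normal/tangential velocity:

    W_n = −ρ_f a |v_n| v_n − √(8 ρ_f a μ_f |v_n|) v_n,
    W_τ = −2.72 √(ρ_f a μ_f |v_n|) v_τ.

Quadratic pressure drag plus boundary-layer corrections in which the
tangential shear is controlled by the normal Reynolds number; all three
prefactors are config-exposed.  There is no added mass and no wake memory.
The law is purely dissipative pointwise (`W_n v_n + W_τ v_τ ≤ 0`), which is
property-tested.

## Solver

Generalized coordinates `(X, Y, φ_1..φ_N)` (nose position + absolute link
angles) eliminate the inter-link constraint forces analytically; a dense
symmetric `(N+2)` mass matrix built from cumulative tail masses is solved at
every right-hand-side call (numba-compiled).  Head and tail are force- and
moment-free automatically.  The muscle kinetics (4 first-order states per
interior joint) are integrated alongside the mechanics.  At tissue-like
viscosity the distal joints are overdamped with decay rates ~1e5 s⁻¹, so a
stiff integrator is required: BDF by default (LSODA available), relative
tolerance 1e-6, absolute 1e-9, output on a fixed 1 ms grid.  Runs start from
a straight chain at rest and integrate period by period until the
period-averaged center-of-mass speed (net displacement per period over the
period) changes by less than 0.5% between consecutive periods, with at least
10 and at most 30 periods; a run that never settles is returned flagged, not
raised.  Everything is deterministic — no random numbers are drawn anywhere
in the pipeline.

Solver checks: the accelerations match an independent finite-difference
Lagrangian on small chains; with fluid and actuation off, linear and angular
momentum are conserved to integration tolerance and the passive mechanical
energy of a released bent chain decays monotonically to the straight state;
mirrored stimulation mirrors the trajectory; tightening tolerances moves the
mean speed by < 0.5%.

## Metrics

* Mean asymptotic speed (MAS): magnitude of the COM velocity vector averaged
  over the final 3 whole periods, in BL/s (vector averaging cancels the
  lateral recoil exactly).
* Wave speed `V`: slope of the unwrapped dominant-COD-mode phase against arc
  position over 0.25–0.95 L (primary), cross-checked by the peak-lag
  cross-correlation between the stations nearest 0.4 L and 0.8 L.  For slow
  waves the 0.4 L separation exceeds half a period of lag, so the
  cross-check resolves the periodic ambiguity toward the primary estimate's
  implied lag.  Whether the reference value for this quantity is a
  displacement- or curvature-wave speed is not stated in its source; the
  displacement wave is used here and stated as such.
* Efficiency: `η = (1 + U/V)/2` from large-amplitude elongated-body theory.
* Traveling index `ξ`: midline lateral displacements in the COM frame,
  de-meaned per station over whole periods (making `ξ` invariant to rigid
  offsets — whether the source de-means is unstated), Hilbert-transformed to
  analytic signals; `ξ = σ_min/σ_max` of `[Re w₁, Im w₁]` of the dominant
  complex-covariance eigenvector.  The spectral-norm condition number is the
  only convention mapping pure traveling → 1 and pure standing → 0.  The
  standing/traveling split takes the circular (equal-singular-value) part of
  the dominant mode as traveling and the rank-one remainder as standing,
  validated by round-trip and known-composition tests.

## Calibration (fixed once, then frozen)

Two constants are not derivable from the printed model and are calibrated
once, documented here:

* `σ₀ = 0.6 MPa` — the muscle stress scale.  Anchored to the reported peak
  speed at the explicit-amplitude cell (E = 0.006 MPa, D = 0.03, f = 1 Hz):
  the model's speed there saturates near 0.27 BL/s around σ₀ ≈ 0.6–0.9 MPa
  and degrades beyond (head flailing and growing standing-wave content), so
  the low end of the saturating plateau is used.  Effective stress of this
  magnitude is plausible when the whole elliptic section stands in for the
  muscle cross-section.
* Baseline `D = 0.2` — the reference-run amplitude, unspecified in the
  source.  Within the biological range the closest approach to the reported
  0.60 BL/s is at the upper end (U ≈ 0.22 BL/s); it also reproduces the
  reported traveling index closely (0.706 vs 0.672).

## What the simulations do and do not reproduce

Reproduced: the qualitative gait phenomenology — a rostro-caudal wave
emerges from the traveling drive; speed rises with frequency to an optimum
and falls beyond it (at E = 0.006 MPa, D = 0.03 the optimum is at 1 Hz, as
reported); the amplitude envelope is U-shaped with the minimum near
0.2–0.5 L; the traveling index sits in the reported 0.4–0.7 band, and at the
baseline is within 5% of the reported 0.672; fluid forces damp the head
oscillation.

Not reproduced quantitatively: absolute swimming speeds.  The model's slip
ratio U/V saturates near 0.3, against ~0.57 reported.  A kinematic check
(prescribing ideal traveling-wave midlines and balancing the same Taylor
force law) shows slip 0.5–0.65 requires near-uniform large amplitude along
the whole body and nearly pure traveling motion; the chain's emergent
U-shaped envelope cannot deliver it.  Reported high-frequency speeds
(≥ 1.2 BL/s at 2.5–3 Hz with small D) would require an underdamped body,
incompatible with a 3 kPa·s body viscosity under the `γ̄ = π μ/2` mapping.
Likewise, mean speeds at N = 40 and N = 100 differ by ~10%, not < 0.1%:
the discrete serial–parallel mechanism has genuinely h-dependent terms (the
co-contraction geometric stiffening `(f_L + f_R) h ψ/4` and the tail end of
the actuated region), both runs being fully time-converged.  The tail-side
fluid on/off amplitude contrast is also not robust in this implementation
(only the head contrast is).  These gaps are stated rather than tuned away;
the property suite (conservation laws, dissipation, symmetries, COD
identities) passes unconditionally.

## Problem sizes

Default runs use N = 40 segments and 10–30 tail-beat periods to reach the
quasi-steady state; the refinement check uses N = 100.  Frequency sweeps
cover 0.5–5 Hz in 0.5 Hz steps; the stiffness grid is 13 points,
logarithmic over 10 kPa–1 MPa.  Unit and property tests run on 4–20-link
chains over a few periods.
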