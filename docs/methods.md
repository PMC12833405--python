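# Methods

This note documents the model behind `ukawear`: what is simulated, the
parameter defaults and why, the numerical choices, and what the synthetic
setup can and cannot say about real joints.

## Scope and fidelity trade-off

The package re-creates, at desk scale, an adaptive polyethylene-wear
simulation of a medial unicompartmental knee replacement and its
whole-joint extension. The central fidelity trade-off is the replacement of
continuum finite-element contact by an **elastic-foundation (Winkler)
layer**: each tibial surface node is an independent spring of modulus
`k = E(1−ν) / [(1+ν)(1−2ν)t]`. This is the standard surrogate for thin
conformal polymer and cartilage layers. It reproduces contact pressure and
area scales well (a bonded layer under a conforming indenter deforms almost
columnarly) but carries no long-range surface coupling, no sub-surface
stress field, and no creep.

Out of scope by design: bone geometry and implantation, continuum ligaments
(replaced by lumped neutral-zone restraints), continuum meniscus (folded
into the lateral foundation layer), cross-shear- or pressure-dependent wear
factors, creep and thermal effects.

## Geometry

All surfaces are analytic biaxial circular-arc height fields on regular
lattices (x anterior, z medial, height proximal; mm). Defaults:

| quantity | value | basis |
|---|---|---|
| femoral footprint | 45 × 20 mm (AP × ML) | measured component class |
| femoral radii (sag/cor) | 28 / 22 mm | representative, not manufacturer CAD |
| insert footprint | 41 × 26 mm | measured component class |
| insert dish radii | 45 / 30 mm | low-conformity fixed-bearing design |
| insert thickness | 8 mm | component class |
| lateral cartilage dish radii | 32 / 24 mm | meniscus-integrated compartments are nearly conforming |
| lateral layer thickness | 3 mm cartilage + 3 mm meniscus equivalent | lumped-layer choice |

The femoral condyle is rotationally symmetric about the flexion axis in the
sagittal plane, so flexion leaves the contact geometry invariant and enters
only through sliding (arc length `R_s Δθ`). Heights are analytic, so
refining the lattice never changes values at shared nodes, and trapezoid
nodal-area weights integrate the footprint exactly.

Because the insert dish is everywhere at least as open as the condyle
(non-negative clearance), the apex-aligned gap field is non-negative with
an exact zero at the dish bottom; contact is a per-node 1-D gap test.

## Gait cycle and restraints

Only the two stance axial-force peaks are pinned to published values
(2600 N at 13 % cycle, 2433.5 N at 45 %); the baseline is 168 N. The axial
curve is a baseline plus two periodic von-Mises bumps whose amplitudes are
solved exactly for the configured peaks. Flexion, AP force and IE torque
are periodic cubic splines through ISO-14243-like anchors. Two anchor
choices matter and are deliberate:

* **AP force** is anterior-dominant in stance (peak +265 N). The tibia
  translates anteriorly ~4–5 mm against its neutral-zone restraint, so the
  femoral contact migrates posteriorly on the insert — giving the
  central–posterior wear patch location reported for this implant class.
* **IE torque** peaks at 2.5 N·m internal, chosen so that with the default
  restraints (0.6 N·m/deg beyond a ±3° neutral zone, Coulomb friction
  μ = 0.04) the solved tibial rotation stays near the ISO
  displacement-control envelope (−2…+5.7°). An early development value of
  5.7 N·m produced ±11° rotations — outside any ISO regime — and was
  replaced on kinematic-envelope grounds.

AP displacement and IE rotation are solved sample-by-sample by a
stick–slip quasi-static balance (applied load vs. restraint vs. Coulomb
traction bound `μ∫p dA`, `μ∫p r dA`), marched over two cycles so the
friction hysteresis settles. Residuals are held below 0.01 N / 0.001 N·m.
With nonzero neutral zones an infinitely stiff restraint pins the tibia at
the zone edge, not at zero; the stiff-limit invariant is therefore checked
with zero-width zones.

## Load sharing

In the whole-joint scenario the axial force acts at a femoral load point
5 mm medial of the joint center, and the femur is free in axial translation
and varus–valgus (VV) rotation. The split follows from a 2-DOF equilibrium:
total foundation force equals the applied load (rel. tol. 1e-4) and the VV
moment of both pressure fields about the load point vanishes (tol.
0.01 N·m). A damped finite-difference Newton solves the pair; because the
residuals are piecewise linear in the unknowns, a stalled Newton falls back
to an always-convergent nested bisection (outer on tilt via the moment,
inner on approach via the force — both monotone maps).

A consequence worth stating plainly: in this ligament-free two-pad statics
the medial fraction equals a ratio of center-of-pressure lever arms about
the load point. The default split at the 2600 N peak is ≈ 0.65 medial.
Progressive insert wear tilts the femur varus-ward, but the equilibrium
fraction itself moves only at the 1e-4 level with a discretization-dependent
sign — the strong wear-driven drop in medial load share seen in whole-knee
FE models arises from the structures (ligaments, continuum cartilage and
meniscus compliance) that this model deliberately lumps away. The package
therefore demonstrates the lateral-stress *increase* (below) but not a
large medial-share migration; tests assert what the model actually does.

Lateral cartilage stress is summarized by the confined-compression von
Mises surrogate `σ_vM = p (1−2ν)/(1−ν)` under each node (0.095 p at
ν = 0.475). FE peak von Mises values arise partly from edge gradients this
surrogate cannot see, so cartilage-stress conclusions are trend-based; at
the defaults the initial peak is ≈ 3.6 MPa and rises monotonically with
wear (+0.25 % over 5 MC).

## Wear model

Archard's law per node and time increment: `H = Kw σ S` with
`Kw = 3.3 × 10⁻⁷ mm³/(N·m)` (unit contract: MPa × m → mm). One
representative cycle (100 samples) is evaluated per analysis step; nodal
depth increments use the pressure at the increment start and the sliding
magnitude across the increment (flexion arc + AP translation + IE lever,
composed vectorially; femoral-relative-to-insert convention; unidirectional
— no cross-shear). The per-cycle field times 0.5 million cycles recedes the
insert surface along its current normal (vertical drop = recession divided
by the normal's vertical component). Volume accounting is the exact prism
volume (vertical drop × plan nodal area — identical to recession × true
surface area); mass is 0.93 mg/mm³ × volume, exactly, by construction.
Within-step sub-iteration was prototyped (0.125 MC updates): the 5 MC mass
changes by 0.01 % and no trend changes, so the single update per 0.5 MC
step is retained. Halving the step size (20 × 0.25 MC) is part of the test
suite with a 5 % mass tolerance; the observed difference is ≈ 0.01 %.
Wear never exceeds ~0.26 mm here, far from the 8 mm thickness guard that
halts a simulation on wear-through.

## Reported metrics and numerical choices

* **Contact solve tolerances:** load balance 0.1 % (practically ~1e-9 via
  Brent), joint moment 0.01 N·m.
* **Default lattice: 1 node/mm** — the element size at which the reference
  FE class reports convergence; the refinement check (peak pressure change
  < 5 % on doubling) passes at ~1 %.
* **Peak contact stress** is reported two ways. The nodal maximum of the
  foundation pressure is exact for smooth surfaces but becomes a
  noise-amplifying sup-estimator once the worn trough carries node-scale
  relief: on the default run it falls 63 → 34 MPa and then plateaus with
  ±1 % wiggle while the load-peak patches ride the trough walls.
  `element_stress_MPa` averages the bilinear pressure field over 1-mm
  patches (the reference element scale) and is the package's headline
  stress metric; it decreases monotonically (60.4 → 32.0 MPa over 5 MC)
  at the default discretization. At finer grids the late-schedule plateau
  wiggles within 1 % for either metric.
* **Determinism:** there is no randomness anywhere on the default path;
  identical configurations produce bit-identical outputs. `random_seed` is
  reserved plumbing.

## What the synthetic setup does and does not show

The generator emulates the *conditions* of a standardized wear test on an
idealized implant: exact load peaks, smooth periodic kinematics, perfectly
rigid femoral metal, homogeneous layers. It does not emulate subject
anatomy, ligament tension, meniscus extrusion, cartilage biphasics,
cross-shear softening of polyethylene, or creep. Passing tests therefore
demonstrate internal mechanical consistency (equilibrium, conservation,
unit contracts, trend directions) and plausibility against published FE
magnitudes — not patient-level predictions. Absolute wear masses here
(40.2 / 21.7 mg over 5 MC for the isolated vs whole-joint scenario) sit
below published FE values (48.1 / 38.2 mg) mainly because the idealized
articulation concentrates less sliding per cycle and the lateral
compartment, being highly conforming, takes a third of the load; the
ordering and all trend directions match.

## Known limitations

* Two-pad rigid-femur statics pins the load split to lever-arm geometry;
  wear-driven medial-share migration is essentially absent (see above).
* The Winkler layer at ν = 0.475 amplifies cartilage stiffness ninefold
  relative to E/t; an effective confined modulus can be substituted via the
  foundation config if softer lateral response is wanted.
* Late in the schedule the worn trough's walls concentrate nodal pressure;
  single-node maxima should not be over-interpreted (use the element
  stress).
* One representative cycle per step assumes perfect cycle-to-cycle
  repeatability; variability in gait is not modeled.
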