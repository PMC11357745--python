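# Methods

## The model

A bamboo culm is idealized as a vertical cantilever of length
L = 10 m, clamped at the ground, with a hollow circular cross-section
that tapers from root to tip and a wall whose elastic moduli are
radially graded.  The package compares two wall materials on identical
geometry and loads:

* **graded** — each modulus follows `A·exp(k·r)` with `r` the radial
  coordinate in millimetres (axial Young's modulus `1.23·e^{0.08 r}` GPa,
  transverse `0.56·e^{0.016 r}`, axial shear `0.5·e^{0.05 r}`,
  transverse shear `0.46·e^{0.03 r}`; Poisson ratios 0.36 / 0.19);
* **homogeneous** — the cross-section averages of the same profiles
  (10.9, 0.85, 1.9, 1.02 GPa).

### Geometry and calibration

The source data print no radii, so the wall is *calibrated*: the second
moment of area follows the cubic taper law

    I(x) = I0 · [1 + (n − 1) x / L]³,   x from the free end,

with taper constant n = 2 and a constant wall-thickness-to-radius ratio
c = 0.18 (so outer radius and thickness scale as I^{1/4}), and the outer
radius at a reference station is found by root-finding so that the
area-weighted average of the graded axial modulus over the wall annulus
equals the homogeneous value of 10.9 GPa.  The default reference
station is the **clamped root**, because culm mechanical
characterization conventionally uses basal internode specimens; this
puts the mid-wall radius near 27 mm (root outer radius ≈ 29.8 mm, tip
≈ 17.7 mm, tip wall ≈ 3.2 mm).  Only the axial Young's modulus can be
matched exactly by a single annulus; the residual mismatch of the other
three moduli (≈ 2–3 % here) is reported, not enforced.

Two modelling choices are genuinely open and are config knobs with the
following defaults: the radial datum of `r` is the **section axis**
(the alternative inner-surface datum calibrates to a 43 mm wall and a
0.24 m outer radius, which is not a culm), and `r` is in millimetres
(any other unit makes the calibration leave the physical range).

### Loads

Wind speed follows the boundary-layer power law `v = v0 (x/x0)^{1/14}`
with v0 = 16 m/s at x0 = 10 m, evaluated at the *undeformed* height of
each material station, and is converted to drag per unit length on the
local culm diameter by `q = ½ ρ C_d d v²` with ρ = 1.2 kg/m³ and
C_d = 1.2 (circular cylinder, subcritical).  Wind acts in a fixed
horizontal direction.  On the deformed culm each load element is split
into a component normal to the local axis (`∝ cos θ`, bending-effective)
and a tangential component (`∝ sin θ`, discarded for bending): a culm
that aligns with the wind sheds effective load.  This "normal"
resolution is the default; the exact dead-load moment ("full") is kept
for classical benchmarks.  The graded-vs-homogeneous comparison uses
wind alone; a 100 N horizontal tip load is retained as a solver
validation case.  Superposing the two was examined and rejected: it
drives both beams into deep alignment where their tip deflections
saturate and the comparison degenerates.

### Solvers

Both solvers iterate the moment field to self-consistency on the
deformed shape (the bending moment uses deformed lever arms), with
under-relaxation 0.5 (adaptively reduced if the tip deflection
oscillates), a relative tolerance of 1e-6 on the tip deflection, at most
200 outer iterations, and 401 stations by default.

* **Pseudo-linear equivalent system** (primary): the nonlinear Cartesian
  equation `y''/(1+y'²)^{3/2} = M/(EI)` is integrated as a *linear* beam
  `y'' = Me′/(E0 I0)` whose equivalent moment diagram
  `Me′ = M (1+y'²)^{3/2}/(f g)` absorbs the curvature correction and the
  stiffness modifiers `f(x) = E_eff(x)/E0`, `g(x) = I(x)/I0` (reference
  values at the free end).  Double integration uses composite Simpson
  with clamped-end constants; the tip shortening Δ is updated each
  iteration from arc-length conservation and under-relaxed.
* **Arc-length shooting** (independent cross-check): direct integration
  of `dθ/ds = M/(EI)`, `dx/ds = cos θ`, `dy/ds = sin θ` from the root.

The taper bracket takes the running material arc length as its argument
in both solvers, which is what makes 0.5 % cross-solver agreement
attainable at large deflection; the linearized `(L − Δ)` stretched
mapping of the deformed coordinate is available as
`taper_mapping="stretched"` for comparison.  Rotations at or beyond π/2
(fold-over) are outside the model and raise a regime error.  Under the
default study conditions the culm reaches tip rotations of ≈ 28°
(homogeneous) to ≈ 34° (graded), tip deflections of 3.15 and 3.63 m,
and both solvers agree to ~3·10⁻⁶ relative.

The section-effective bending modulus is `E_eff = π∫E(r) r³ dr / I`
(Gauss–Legendre, 64 nodes, machine-precision for exponentials), sampled
at 256 stations and linearly interpolated.

### Stress recovery

Axial stress is first-order beam stress on the wall traverse at the
extreme-fibre azimuth, `σ_xx(x, r) = E(r) κ(x) r`, with the
modulus-weighted neutral axis on the section axis by radial symmetry;
it reduces to `M z / I` exactly for a homogeneous wall, and satisfies
`∫σ dA = 0` and `∫σ z dA = M` over the full annulus (to quadrature
accuracy).  Transverse shear is recovered on the same traverse with a
modulus-weighted Jourawski (shear-flow) construction treating the wall
as a graded strip: `τ(z) = V·Q_E(z)/(D·b)` with
`Q_E(z) = ∫_z^outer E (z′ − z_n) dz′`, `z_n` the modulus-weighted
neutral surface of the strip, `D` its modulus-weighted inertia, and the
effective width `b = A/t` chosen so the strip carries the section shear
resultant `V` exactly.  τ vanishes at both free wall surfaces, peaks at
mid-wall for a homogeneous material (classical `1.5 V/A` parabola) and
shifts outward for the graded wall (to ≈ 0.54 of the wall here).
Stations are reported as x/L from the clamped root.  Through-wall
traverses ("at x = 0") are evaluated at the root, where moment and
shear are largest.

### Crack-transformation threshold

Measured toughness data are not reprinted in the source, so toughness
enters as parameterized through-wall profiles.  The shipped default is
an exponential pair with the inner surface 5× tougher than the outer
(the only printed anchor) and through-thickness toughness 5× the
interlaminar one everywhere; outer-surface anchors are 1.75 and
0.35 MPa·√m, at the scale of woody-grass fracture measurements.  The
critical far-field stress for a surface crack of depth a is
`σ_c = K/(Y √(π a))` with Y = 1.12 (edge crack) and K the toughness of
the propagation mode at the crack's wall surface; the default crack is
a 1 mm inner-surface crack transforming into the interlaminar plane.
The threshold wind speed bisects on v0 (to 0.1 m/s) until the maximum
surface stress over all stations reaches σ_c; fold-over during a probe
is treated as exceeding any finite critical stress (curvature diverges
there), and an unreachable toughness censors the result at v_max.
Under the defaults the inner-crack threshold is ≈ 17.5 m/s for the
homogeneous culm and ≈ 22.3 m/s for the graded one — the graded culm
survives stronger wind whenever the inner surface is the tougher one,
which is the ordering the analysis asserts (the absolute published
threshold values depend on unpublished toughness curves and are not
reproduced).

## Synthetic scenario suite

The perturbed suite multiplies every profile amplitude and rate by
seeded log-normal factors (default CV 0.1, which keeps moduli positive
and spans the culm-to-culm variability reported for bamboo), optionally
jitters taper constant and thickness ratio, re-calibrates each variant
and re-homogenizes its twin, so every pair satisfies the averaging
identity by construction.  What the generator does *not* emulate:
along-length property variation independent of the radial law, nodes
and diaphragms, moisture gradients, measurement noise correlated across
moduli.  Passing suite statistics therefore demonstrate robustness of
the *orderings* to parameter uncertainty, not fidelity to any
particular culm.

## What the comparison does and does not reproduce

With the calibrated geometry the graded culm deflects ≈ 15 % more than
its homogenized twin under the reference wind (the published solid-model
value is 12.5 %), and the delamination ordering reproduces.  Two
published observations do **not** emerge from a first-order beam model
on the cubic taper law, and the package reports its own computed values
rather than forcing them:

* an *interior* outer-surface stress peak (x/L ≈ 0.8): for
  `σ = M/S` with `S ∝ (1+(n−1)u)^{9/4}`, the moment's logarithmic
  derivative exceeds the section modulus's at every station for any
  physical load case and regime tried, so the peak sits at the root;
* a ≈ 75 % inner-surface stress reduction: the calibrated annulus pins
  the mid-wall radius near 27 mm, capping the across-wall modulus
  contrast at `e^{0.08·5.3} ≈ 1.5`, which caps the inner-surface
  reduction near 26 %.

Both would require the unpublished three-dimensional geometry (much
thicker walls relative to radius, or a far stronger taper) used for the
original solid-element computations.

## Numerical choices and limitations

* Trapezoid cumulative integrals for moment/rotation fields; composite
  Simpson for the pseudo-linear double integration; halving the station
  spacing changes the tip deflection by < 0.1 %.
* Ties in `argmax` resolve to the first (root-most) station; the
  crack-path decision breaks ties toward the through path.
* Degenerate inputs (zero load, zero toughness, vanishing crack, empty
  annulus) return exact limits or raise typed errors.
* No dynamics, no self-weight beam-column coupling, no node/diaphragm
  mechanics, no Brazier ovalization, no moisture or viscoelastic
  effects, no post-fold continuation.
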