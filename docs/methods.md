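# Methods

## Physical model and assumptions

The package computes the quasi-static electric field around a focal
ablation electrode delivering high-voltage pulses in monopolar mode.
Over the microsecond pulse plateau the problem is electro-quasistatic:
displacement currents and the cell-membrane charging transient are
neglected, so the potential obeys ∇·(σ∇φ) = 0 with E = −∇φ and J = σE.
The catheter is perpendicular to the tissue, which makes the scene
axisymmetric: all geometry lives in the (r, z) half-plane and the weak
form carries the 2πr revolution weight. z = 0 is the undisturbed
endocardial surface with +z pointing into the wall; the tissue conforms
to the inserted electrode (no gap, no tenting).

Electroporation is represented purely through conductivity: once pores
form, current can cross cell membranes, which raises the bulk σ of
cell-rich tissue from its low-frequency value σ0 to a post-poration
value σ1. The transition is a smooth sigmoid of the local field
magnitude (center 58 kV/m, slope 3 kV/m, prefactor 10). Only viable
myocardium has σ1 > σ0 (0.4 → 0.6 S/m); scar (0.85 S/m), fat
(0.08 S/m), blood (0.6 S/m) and the connective tissue beyond the wall
(0.115 S/m) are treated as field-independent, so the sigmoid reduces to
a constant for them. An alternative fat conductivity of 0.015 S/m
appears in parts of the literature; `TissueProperties.with_fat(0.015)`
selects it for sensitivity runs, but 0.08 S/m — the value with direct
in-vivo provenance — is the default. No thermal effects, no anisotropy,
no frequency dispersion, and a single lethal threshold (1000 V/cm)
applied to the field map regardless of tissue type.

## Geometry and the synthetic scar

Models A and B are fully determined by the macroscopic parameters
(7-mm wall, 2-mm epicardial band of fat or connective tissue, 7-Fr
3.5-mm electrode inserted 0.5 mm). The scar models C–F stand in for a
histology-derived tissue distribution that is not publicly
reproducible, so the generator is parametric and its defaults are the
package's declared study conditions:

* scar: fibrotic disc, radius 10 mm, spanning depths 1–6 mm (a 1-mm
  viable subendocardial rim remains, consistent with a non-transmural
  healed infarct);
* model D fat: one dominant slab between 2.6 and 4.59 mm depth with a
  7-mm radial extent and a rounded rim (a stadium cross-section, so the
  rim has no corner singularity), plus 6 seeded elliptical blobs with
  0.3–1.0 mm semi-axes placed by rejection sampling inside the scar,
  clear of the slab and of each other — the "patchy" deposits;
* model E channel: a 2-mm-wide column of viable myocardium on the axis
  through the scar; model F: the subendocardial rim under the electrode
  replaced by fibrosis.

The slab's radial extent is chosen so the deposit spans the lesion
footprint; this is the geometric condition for the depth-clamping
mechanism (see below) to operate, as it does in the histology-based
arrangement the stand-in emulates. The slab depth interval is the
declared default; everything else about the deposit (blob count, sizes,
positions) only perturbs the local field pattern. With a fixed seed the
generator is bit-reproducible.

The electrode tip is a flat-ended cylinder with a 0.1-mm corner fillet.
An unfilleted corner carries a field singularity that would make the
1000 V/cm isoline mesh-dependent near the electrode; the fillet radius
is a `GeometrySpec` knob. Domain extents (40 mm radius, 20 mm blood
above, 20 mm connective below) are far-field enough that doubling them
changes lesion depth by ≈ 0.2%.

## Discretization and solvers

The mesh is a tensor-product triangulation: graded 1D point sets in r
and z (near-electrode target size 0.05 mm, geometric growth ≈ 1.2×,
far-field 3 mm), with grid lines snapped onto every horizontal/vertical
material interface so elements never straddle the stratified
boundaries; curved boundaries (fillet, blobs, slab rim) are resolved at
the local grid size by centroid labeling. Piecewise-linear triangles
with the axisymmetric 2πr̄ element weight; electrode and shaft elements
are excluded from the conductive domain, their surface nodes becoming
the Dirichlet electrode set and a natural (insulated) boundary
respectively. With ~17k nodes a nonlinear solve takes a couple of
seconds on one CPU.

The σ(|E|) nonlinearity is resolved by damped Picard iteration
(damping 0.5, relative-σ tolerance 1e-4, per-element σ from the
element-mean |E| of the previous iterate). The contrast is modest
(0.4 → 0.6 S/m) and the sigmoid smooth, so the fixed point converges in
~10 iterations from σ0 and in 3–5 when warm-started. Delivered current
is computed with the volume-consistent flux — the assembled stiffness
operator applied to the solution, summed over electrode Dirichlet
nodes — which matches the ground-side flux to machine precision by
discrete conservation. The voltage delivering a target current is found
by secant iteration on the monotone, nearly linear I–V characteristic
(relative tolerance 1e-3, typically 3 voltage solves).

## Lesion metrics

|E| is resampled onto a 0.025-mm cell-centered grid of the tissue
half-plane. Because the normal field component genuinely jumps at
conductivity interfaces (σ₁E_n,1 = σ₂E_n,2), each tissue is resampled
one-sidedly from its own elements, falling back to the two-sided nodal
average where the one-sided stencil is incomplete; without this the
averaged field smears the jump and biases the isoline by half a mesh
cell at clamped boundaries. Marching squares extracts the 1000 V/cm
contour. Only the superlevel component connected to the electrode tip
is the lesion proper; detached pockets (e.g. inside the epicardial fat
band, where the field rebounds above threshold) are counted as
satellites and excluded from depth/width. Depth is reported from z = 0
even where the isoline crosses non-myocardial tissue; surface width is
measured in the tissue at z = 0⁺ with sub-cell interpolation. A
refinement of the resampling grid to 0.0125 mm moves depth and width by
< 1%.

`clamped_to_fat` flags lesions whose deepest isoline point sits on the
lower boundary of a fat region (within one resampling cell). The
mechanism: fat takes a disproportionate share of the potential drop, so
|E| inside the deposit far exceeds the threshold down to its deep face,
while the screened tissue below stays subthreshold — the isoline
coincides with the fat boundary and is insensitive to the delivered
current (19–25 A move the model-D depth by < 0.005 mm).

The hot/cold-point classifier samples each discrete fat inclusion's
boundary at a 0.15-mm exterior offset and compares |E| against a
reference: the median |E| over the shell of points at the same distance
from the electrode tip. The matched-distance shell removes the radial
decay of the source field, leaving the inclusion's perturbation (in a
uniform applied field it reduces to the unperturbed field). Samples
below 0.5× the reference with the boundary normal within 30° of the
local current direction are cold points (current entry/exit); samples
above 1.25× on laterally oriented boundary (> 60°) are hot points.
For a poorly conducting sphere in a uniform field this reproduces the
classical solution: cold poles, hot equator, interior field
3σ_m/(2σ_m+σ_f)·E0.

## What the generator does and does not emulate

The synthetic wall models reproduce the *arrangements* of tissue that
drive field redistribution — layered fat, embedded scar, discrete
deposits, channels — under idealized conditions: sharp interfaces,
isotropic homogeneous-per-tissue conductivity, perfectly perpendicular
rigid contact, a static field abstraction of the pulse train. Passing
tests therefore demonstrate the electrical mechanism (field
concentration in fat, clamping at deposit boundaries, cold/hot points),
not clinical lesion sizes: real scars have graded interfaces and
irregular morphology, real catheters tilt and deform tissue, and the
lethal threshold itself depends on waveform and pulse count. The
homogeneous models A/B carry the quantitative weight; the scar models
are qualitative by construction.

## Numerical choices and edge cases

* Reference problem sizes: near-electrode mesh 0.05 mm (halving it
  moves model-A depth by < 0.1%), resampling 0.025 mm, domain 40 mm.
* Linear solves via sparse LU; single-threaded and deterministic, so
  a fixed config + seed reproduces results byte-identically.
* A threshold above the global field maximum yields an empty lesion
  (zeros), not an error. Meshing rejects h_fine ≥ h_coarse; the solver
  aborts with a diagnostic on a missing ground boundary, a non-monotone
  I–V pair, or Picard stall.
* σ0 = σ1 tissues short-circuit the sigmoid exactly, and an all-linear
  configuration solves in one Picard iteration (used by the linearity
  tests).
* The blob sampler raises after 400 rejected placements rather than
  silently dropping blobs.

## Known limitations

Axisymmetry cannot represent laterally offset deposits or oblique
catheters; the stand-in scar is a disc, not a segmented infarct; fat
blobs revolve into tori around the axis, so a "blob" models an annular
deposit rather than an isolated pocket — acceptable for the boundary
physics it probes, which is local. Thermal side effects and conductivity
anisotropy are out of scope by design.
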