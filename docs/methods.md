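# Methods

`bonefem` simulates quasi-static axial compression of a rat femoral
cortical-bone diaphysis segment to fracture, using continuum damage
mechanics (CDM) on a voxel-based hexahedral finite-element mesh. Its
purpose is to compare two *strain judging criteria* — the minimum
principal strain and the von Mises equivalent strain — as drivers of
element damage and failure, and to extract the structural fracture
parameters (fracture load, fracture displacement/time, apparent
stiffness, crack orientation) that distinguish them.

Units project-wide: mm, N, MPa, dimensionless strain.

## Constitutive model

Cortical bone is a transversely isotropic linear elastic solid; the stiff
axis follows the osteons and coincides with the shaft (loading) axis.
The engineering constants default to nanoindentation values for rat
femoral cortical bone:

| constant | default | meaning |
|----------|---------|---------|
| `E_L`    | 13 498 MPa | longitudinal (osteon-axis) Young's modulus |
| `E_T`    | 11 025 MPa | transverse Young's modulus |
| `nu_LT`  | 0.3     | longitudinal–transverse Poisson ratio |
| `nu_TT`  | = `nu_LT` | in-plane transverse Poisson ratio |
| `G_LT`   | = `E_L`/(2(1+`nu_LT`)) | longitudinal shear modulus |

Only `E_L`, `E_T` and one Poisson ratio are measured quantities; `nu_TT`
and `G_LT` are not available for this tissue and are filled with the
isotropy-consistent defaults above. Both are configurable
(`material.nu_TT`, `material.G_LT`). The assembled 6×6 stiffness is
checked for positive definiteness at construction (thermodynamic
admissibility).

Damage is the scalar CDM kind: a single variable `D` per element degrades
the whole stiffness tensor, `σ = (1−D) C ε`. `D` follows an exponential
softening law of the criterion strain κ,

    D = 0                      κ ≤ ε_f
    D = 1 − exp(1 − κ/ε_f)     κ > ε_f,   capped at D_max,

with `ε_f = 0.043` (compressive failure strain of the tissue) and
`D_max = 0.9`. An element *fails* — permanently loses load-bearing
capacity — when its modulus has dropped to 10 % of the original, i.e.
exactly when `D` reaches the 0.9 cap; the residual fraction and the cap
are tied (`residual_fraction = 1 − D_max`) and enforced at construction.
The threshold comparison is strict: κ = ε_f gives D = 0, and D is
continuous across initiation.

κ is a **history variable**: the running maximum over the whole loading
(and iteration) history of the chosen criterion strain. The softening law
alone is instantaneous; driving it with the historical maximum makes
damage irreversible, which is physically required and consistent with the
monotone loading. This is a design choice — the alternative
(instantaneous strain) would allow healing on elastic unloading during
load redistribution.

The two criterion strains:

- **minimum principal** — magnitude of the most-negative eigenvalue of
  the strain tensor; purely tensile states drive no damage (the loading
  is compressive; lateral tensile strains are small and deliberately
  ignored, as a scalar compressive-damage model);
- **equivalent** — von Mises form `ε_eq = sqrt(2/3 · e:e)` of the total
  strain deviator `e`. No specific equivalent-strain formula is standard
  across FE codes; the von Mises form is the conventional choice that
  incorporates longitudinal, transverse and shear strain components
  together, which is the distinction the comparison is about. The Mazars
  tensile-equivalent form was rejected because the load case is
  compressive.

Both scalars are objective (rotation-invariant), verified by property
test.

The point update (`material_update`) is a UMAT-style contract: strain in;
stress, new state and a 6×6 matrix out. The solver uses the **secant**
matrix `(1−D) C`. The full algorithmic tangent, including the rank-one
softening term `−(C ε) ⊗ ∂D/∂ε`, is implemented and verified against
finite differences (`consistent_tangent`) but is not used by the default
solution scheme: with the staggered scheme below the secant suffices for
equilibrium and is far more robust for quasi-brittle softening.

## Geometry and meshing

No segmented micro-CT data ship with the package, so the synthetic
generator stands in for scan + segmentation. It produces a hollow,
roughly tubular shell voxelized on a cubic lattice:

- outer diameter 3.5 mm, wall 0.5 mm — plausible rat femoral
  mid-diaphysis values, chosen so that 80 μm voxels give an element count
  of the same order (tens of thousands) as segmented-femur meshes at that
  resolution; **these are stand-ins and fully configurable**;
- height 5.0 mm — the physical specimen preparation;
- medullary-cavity eccentricity (fraction of wall thickness) and smooth
  wall-surface noise built from low-order Fourier harmonics around the
  circumference modulated by low-order modes along the shaft. A real
  diaphysis is neither axisymmetric nor prismatic; without such
  irregularity the specimen has no physical place to localize failure.
  The run-configuration defaults are eccentricity 0.15 and noise SD
  0.03 mm; the generator's own defaults are zero for analytic
  verification.

The generator rejects voxel sizes coarser than half the wall thickness
(the wall would not be resolved) and keeps only the largest 26-connected
component (isolated voxels would make the stiffness singular).
Segmented masks can be imported from MetaImage/NRRD files instead
(isotropic spacing required; largest component kept, discards logged).

Meshing is one 8-node hexahedron per occupied voxel. Corner nodes are
merged exactly by integer lattice index — no floating-point tolerance is
involved, so conformity is exact by construction and the summed element
volume equals `count · h³` identically. Node sets `top_surface` /
`bottom_surface` collect the nodes on the extreme lattice planes along
the loading axis.

The default *test-scale* voxel size is 0.25 mm (≈1.5 k elements for the
default specimen), keeping a full two-criterion fracture study around a
minute on one CPU; the physical-scale 80 μm (≈46 k elements) is a
configuration change only.

## Finite elements and boundary conditions

Trilinear hexahedra with full 2×2×2 Gauss integration, small-strain
small-displacement kinematics (the full protocol reaches 10 % nominal
strain; the linear-kinematics idealization is accepted as part of the
implicit CDM framework). Every element of a voxel mesh is the same cube
with the same base stiffness, so the global matrix is assembled from one
reference element matrix scaled by the per-element factor `(1−D)` (or the
failed-element floor). Strain/damage are evaluated at one point per
element (the centroid), matching element-level failure semantics: one
`D`, one failed flag per element.

The physical test compresses the specimen between rigid platens — the
lower one frictionless, the upper one with penalty friction (μ = 0.2).
True frictional contact is out of scope; the platens are replaced by
nodal constraints:

- bottom: axial displacement fixed, lateral free (frictionless);
- top, default **stick**: axial displacement prescribed, lateral fixed —
  a conservative stand-in for the frictional platen that transmits shear
  into the specimen;
- top, **frictionless** option for analytic verification (uniform
  uniaxial stress; reaction = `E_L·A_net·Δ/h` to machine precision).
  With two frictionless platens the in-plane rigid-body modes are pinned
  at two bottom nodes chosen so the pins are force-free under any
  uniform-strain field.

This stick/frictionless bracketing is the largest deliberate deviation
from the physical contact condition and is recorded in every run summary.

Linear solves use a sparse direct factorization (SuperLU, symmetric
mode). Because the staggered iteration re-solves the same system with
slowly drifting element factors, the last factorization is kept and
reused: unchanged factors are solved directly; drifted factors are solved
by conjugate gradients preconditioned with the cached factorization
(rtol 1e-13), refactorizing when CG does not converge within 30
iterations. Every solution is checked a posteriori: equilibrium residual
≤ 1e-8 × the reaction scale, and top/bottom reactions balance.

## Progressive-failure driver

Displacement-controlled ramp: 0.5 mm total compression in 100 equal
increments (0.5 %/increment of the 5 mm height). Each increment runs a
staggered (operator-split) fixed-point iteration: solve with frozen
damage → recover centroid strains → update κ (running max) and D →
repeat until the largest per-element ΔD ≤ 1e-3 (cap 25 iterations; a
capped increment is accepted with a warning recorded in the result, never
silently). D is non-decreasing within the iteration and across
increments by construction.

Failed elements are not deleted: their stiffness factor is floored at
1e-4 (configurable), keeping the system non-singular while removing
load-bearing capacity — an approximation of element deletion. Peak
(fracture) load changes by less than 1 % across floors 1e-3–1e-5
(verified by test).

When one increment flips more than 5 % of all elements to failed, the
increment is bisected (recursively, up to depth 6) so that brutal
softening is traversed in smaller steps.

Termination, whichever comes first: (a) full displacement; (b) reaction
drops 20 % below its running peak (with at least one failed element); (c)
percolation — the failed elements, viewed on the voxel grid, disconnect
the intact top layer from the intact bottom layer (face connectivity), a
precise stand-in for "failed elements accumulated to a certain degree".
Both (b) and (c) are config-exposed and the summary records which fired.

The staggered secant scheme was chosen over a Newton scheme with the
consistent tangent because quasi-brittle softening makes the tangent
indefinite at localization; the fixed-point iteration is unconditionally
stable at desk scale. Its accuracy is controlled by the stagger
tolerance, for which self-convergence is first order: tightening 1e-4 →
1e-5 changes the final reaction by ~1e-6 relative.

## Post-processing

- **Fracture load** := peak reaction of the load–displacement curve (the
  standard reading for a quasi-brittle curve, which has no yield
  plateau); fracture displacement is the displacement at the peak.
- **Fracture time** = fracture displacement ÷ (1 mm/min), in seconds —
  the quasi-static machine rate of the physical protocol.
- **Apparent stiffness** = least-squares slope of the curve restricted to
  the rising branch with reactions in [0.1, 0.4] × peak. The window is
  perturbation-stable (< 2 % change for [0.15, 0.45]) and the rising
  branch restriction keeps post-peak points from contaminating the fit.
- **Crack orientation**: centroids of the largest face-connected cluster
  of failed elements are fitted with a plane (principal-axis analysis;
  the plane normal is the smallest-spread direction). The angle between
  that normal and the loading axis classifies the crack: ≤ 15°
  transverse, otherwise oblique. The 15° boundary is a package choice —
  the underlying distinction ("perpendicular to the load" vs "at an
  angle") is qualitative.

`mesh_sensitivity_study` repeats the full fracture run across element
sizes with identical material/loading; `compare_criteria` runs both
criteria on the same mesh and reports both summaries, their load and
displacement ratios, crack classes, and the maximum relative reaction
difference across the shared damage-free increments (the elastic branches
must coincide because the moduli are identical — observed agreement is
exact, since the runs share the mesh and solver path).

## What the synthetic specimen does and does not show

Passing structural tests on the synthetic tube demonstrates the *model
mechanics*: criterion-dependent fracture ordering, elastic-branch
coincidence, mesh-size sensitivity direction, localization and crack
classification. The synthetic geometry does not reproduce real cortical
microstructure (porosity, osteonal texture, endosteal/periosteal
roughness beyond smooth harmonics), real specimen-to-specimen variance,
or the true frictional platen contact; absolute fracture loads are
therefore not comparable to any particular physical specimen, only their
ordering and orders of magnitude are meaningful.

Observed structural behavior at the default test scale (0.25 mm voxels,
stick top, seed 0): the equivalent-strain run fails later (0.25 vs
0.19 mm) and at a higher load (~15 % higher) than the minimum-principal
run, with identical pre-damage curves — the expected criterion ordering.
The equivalent-criterion crack is a flat transverse ring (plane-fit angle
0.7°). The minimum-principal failed band is visibly stepped/inclined —
it winds across five voxel layers around the circumference — but most of
its elements lie in one flat ring, so the plane fit reports 12.5°, which
the 15° boundary still classifies as transverse. At this resolution the
two criteria are separated by the fitted angle (12.5° vs 0.7°) but not
by the two-class label; resolving a cleanly oblique minimum-principal
band most likely needs finer voxels (sub-wall-thickness localization)
than the desk-scale default.

## Numerical choices and degenerate inputs

- Strict threshold comparison (`κ ≤ ε_f → D = 0`); damage-onset reads in
  tests treat `D ≤ 1e-12` as zero (the exponential evaluates to ~7e-16
  one ulp above the threshold).
- Failed flag uses `D ≥ D_max − 1e-12` to absorb cap rounding.
- Node merging is integer-exact; no geometric tolerance anywhere in
  meshing.
- Empty masks, anisotropic spacings, unresolved walls, inverted elements
  and singular systems all raise informative errors rather than
  producing degenerate results.
- Reruns of the same configuration and seed produce byte-identical
  curve/summary artifacts (no timestamps in outputs).

## Known limitations

Scalar isotropic damage (no anisotropic degradation or
tension–compression asymmetry); no contact mechanics, geometric
nonlinearity, or rate dependence; mesh-dependent softening is inherent
to local CDM and is a *finding* of the sensitivity study, not corrected
by nonlocal regularization; crack paths are element-resolution limited
(stair-stepped on the voxel lattice).
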