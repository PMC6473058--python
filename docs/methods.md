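# Methods

## Physical model

The head is treated as an Ohmic volume conductor: at tDCS frequencies
(DC to a few Hz) capacitive and inductive effects are negligible, so the
potential obeys the quasistatic current-flow equation

    div( sigma grad Phi ) = 0        in the head volume,
    sigma dPhi/dn = j_e              under electrode patches,
    sigma dPhi/dn = 0                elsewhere on the scalp,

with isotropic conductivity sigma per tissue.  The electric field is
E = -grad Phi (V/m), and all region summaries are computed from it.
Compatibility of the pure-Neumann problem requires the electrode currents to
sum to zero; the potential is determined up to a constant, fixed by a
zero-mean gauge over the scalp-surface nodes.

Tissue conductivities (S/m): scalp 0.465, skull 0.010, CSF 1.654, gray
matter 0.276, white matter 0.126 — the standard isotropic literature values
for tDCS modeling.  Anisotropy is a known limitation of this class of model
and is not implemented.

## Phantom geometry

Because the package is imaging-free, all inputs are synthesized:

* **Head**: five concentric shells with outer radii 92 / 86 / 81 / 79 / 67 mm
  (scalp, skull, CSF, gray, white).  The radii are arbitrary but
  anatomically ordered; only the ordering and the conductivity contrast
  matter for the phenomena the pipeline studies.  Meshes are built from
  concentric golden-angle point layers (every shell interface is a layer;
  intermediate layers at the target edge length) tetrahedralized by Delaunay
  triangulation; elements are labeled by the innermost shell containing
  their centroid.  A quality gate enforces positive element volumes, one
  connected component, and no empty tissue label.  A resolution coarser than
  4x the thinnest shell thickness is rejected (elements would bridge the
  shell).  Coordinates are RAS millimetres, origin at the sphere center.
* **Parcellation**: a pseudo-cerebellum occupying a spherical-cap sector
  around the posterior-inferior direction (0,-1,-1)/sqrt(2), radii 0.55-1.0
  of the brain radius, cap half-angle 50 degrees.  It is tiled into 28
  regions: 10 polar-angle bands per hemisphere (named X, IX, VIIIb, VIIIa,
  VIIb, Crus II, Crus I, VI, V, I-IV from the cap axis outward, mirroring
  the inferior-to-superior lobule order) and 8 vermis bands on the midline
  strip (the central 35% of each band's mediolateral extent).  The rest of
  the gray/white compartment is the pooled non-cerebellar brain mask.
  Voxel grids are 1 mm isotropic by default, voxel ownership by center.
* **Electrode catalogs**: golden-angle point sets restricted to the
  allowed scalp band (below the vertex slot, above a neck line at
  z = -0.6 R; below-inion positions are standard in cerebellar montages),
  plus a vertex reference.  Discs default to 1 cm diameter, the size used
  for lead-field construction; 5x5 cm pads are realized as equal-area
  geodesic discs (radius 28.2 mm), since a true rectangle on a sphere is
  ill-defined and equal area preserves the injected current density.

What the phantom does *not* emulate: cortical folding, CSF geometry around a
real cerebellum, tissue boundary irregularity, and inter-subject anatomical
variability.  Tests passing on the phantom therefore validate the numerics
and the method logic (solver correctness, superposition, optimizer
behavior), not the field magnitudes a specific human head would produce.

## Analytic oracle

For concentric shells with point-current injection on the outer surface the
potential has a per-shell Legendre expansion; the coefficients solve a small
linear system per harmonic degree (interface continuity of Phi and of
sigma dPhi/dr, regularity at the origin, Neumann matching at the surface).
The per-shell basis is normalized by the shell radii to keep the systems
well conditioned at high degree.  The n = 0 mode is excluded, fixing the
zero-mean-over-spheres gauge.  Truncation defaults to 100 terms with a
convergence check *at the observation radii* (last-degree relative RMS
contribution; the check matters because the series does not converge on the
surface itself, where the point electrode is singular).  For the homogeneous
sphere the series is cross-checked against the closed form
I/(4 pi sigma R) [2R/d - 2 + ln(2R / (R - r cos(gamma) + d))].

The oracle models point electrodes; FEM patch solutions are compared against
it only at interior points at least one electrode diameter away from the
scalp, where the patch and point near-fields have merged.

## FEM discretization and solver

First-order tetrahedral elements with the standard stiffness assembly
(conductivity-weighted shape-function-gradient products); E is constant per
element.  Electrodes are pure Neumann patches: each electrode's current is
distributed over the boundary facets whose centroids fall inside its
equal-area geodesic disc, proportionally to facet area, then to facet nodes
(exact for linear shape functions); when the disc is below the surface-mesh
resolution the nearest facet takes the full current.  No contact-impedance
layer or sponge volume is modeled — a deliberate simplification that leaves
the interior field (the quantity every downstream stage consumes) intact.

The singular SPD system is solved, by default for desk-scale meshes, via a
sparse LU factorization of the Lagrange-augmented system [[K, c],[c', 0]]
(c = 1/n), which fixes the mean potential without pinning a node.  The
factorization is cached and reused across load vectors, so a lead-field
assembly costs one factorization plus one triangular solve per electrode,
and linearity closures (superposition, reciprocity, current scaling) hold to
machine precision.  A deflated Jacobi-preconditioned conjugate-gradient path
(relative tolerance 1e-8, 10,000 iteration cap) is provided for meshes too
large to factorize and is cross-checked against the direct path in the
suite.  After either path the potential is shifted to zero mean over the
scalp nodes.

Verification: on the homogeneous sphere with antipodal 1 cm discs at
+-1 mA, interior potentials agree with the series oracle to ~3% relative L2
at the default 8 mm edge length, decreasing monotonically under refinement
(12 -> 9 -> 6 mm in the suite).  The remaining error is dominated by the
polyhedral approximation of the spherical surface.

## Region statistics

Element fields are rasterized by assigning to each voxel center the field of
the containing element (containment via barycentric coordinates against
nearest-centroid candidates; exact for first-order elements, no
interpolation).  Voxel centers outside the mesh are masked invalid,
distinguishable from a zero field.  The voxel-to-element map depends only on
(mesh, grid) and is cached, which is what makes the many-solve lead-field
loop cheap.  Region summaries are unweighted voxel means of Ex, Ey, Ez and
of the per-voxel magnitude Enorm; mean-of-magnitudes was chosen (rather
than magnitude-of-mean) because field-strength tables are magnitude
summaries, and it makes the Jensen inequality mean(Enorm) >= |mean(E)|
testable per region.  Voxel-uniform weighting is a fixed convention;
element-volume weighting would be the alternative.

## Lead field and optimizer

The lead field is assembled by simulating each non-reference electrode at
+1 mA against the vertex reference at -1 mA and storing the 29-region means
per direction: three matrices (29 x N-1) in (V/m)/mA, serialized in one
HDF5 container with provenance (mesh hash, conductivity table, grid).  The
reference has no column; any zero-sum current vector's field follows by
superposition, and predictions are invariant to the choice of reference
(asserted in the suite).

The montage-design program is convex:

    minimize ||W (LF x - b)||^2
    s.t.     sum(x) = 0,   sum|x| <= cap (default 4 mA),
             optional per-electrode |x_i| <= cap_i.

Stage 1 solves the equality-constrained least squares exactly on an
orthonormal basis of the zero-sum subspace; if the L1 budget is slack that
solution is the global optimum.  Otherwise the L1 ball is handled by the
exact variable split x = p - q (p, q >= 0, sum(p+q) <= cap) and the smooth
QP is solved with SLSQP, warm-started from the scaled stage-1 solution.
The result is then projected exactly onto the constraint set (mean
subtraction restores sum(x) = 0; radial scaling restores the L1 budget), so
reported solutions satisfy the safety constraints to machine precision with
negligible objective change.  A brute-force grid search on a 3-electrode
problem pins the solver to 1e-4 in objective in the suite.

Per-direction optimization is the default (montages are tabulated per field
direction); a stacked multi-direction variant (`stacked=True`) joins the X,
Y, Z rows in one objective.  The stacked variant is the one that steers the
field-*magnitude* hotspot: a single-direction objective leaves the other two
components unpenalized.  The desired magnitude has no principled default —
achieved field scales linearly with current, so users scale post hoc; the
examples use 0.05-0.1 V/m, a typical tDCS brain-field scale.  Region
weights default to 1 everywhere (`spillover_weight` adjusts off-target
rows; 0 removes them).  Optional sparsification (dropping electrodes below
1% of the cap and re-solving) is off by default since the program imposes
no cardinality constraint.

## Statistics

The observation unit is one voxel inside a lobule mask; the response is that
voxel's field value (Ex, Ey, Ez, or Enorm).  `anova_eta` fits a
fixed-effects linear model (sum-to-zero coding) with all main effects and
pairwise interactions and reports classical eta-squared, SS_term / SS_total.
Type III sums of squares are the default because lobule voxel counts are
inherently unbalanced; the type is switchable and recorded in the result.
The decomposition sum(SS) + SS_residual = SS_total is exact for Type I
always and for Type III on balanced designs; the result object carries the
additivity gap as a diagnostic, and the suite asserts exactness on balanced
fixtures.  Post-hoc comparisons test all k(k-1)/2 level pairs at
alpha / m with the fitted model's residual mean square (or a one-way pooled
variance when no fit is supplied), reporting Bonferroni-adjusted confidence
intervals and significance flags.

## Problem sizes and determinism

Default study conditions used by the test suite and the acceptance script:
five-shell phantom at 8 mm edge length (~10k nodes, ~58k tetrahedra), 2 mm
raster grids for region means (1 mm is the library default and is exercised
in the consistency tests), an 8-electrode quasi-uniform catalog for the
constraint and closure checks, and a 48-electrode catalog for the targeting
study (dense candidate sets are what make current steering work; the
8-electrode set is too sparse to cover the posterior-inferior scalp).  All
random elements (mesh layer rotations, test vectors) are seeded;
parcellation and catalogs are deterministic functions of their parameters,
and identical seeds reproduce artifacts byte-for-byte.

## Known limitations

* Isotropic conductivity only; no anisotropy tensor support.
* Spherical phantom geometry; no real-anatomy import beyond the Gmsh/NIfTI
  adapters.
* Pure-Neumann electrode model (no contact impedance), appropriate for
  field-distribution questions but not for electrode-voltage predictions.
* Per-lobule field magnitudes on the phantom are not comparable to
  subject-specific values; only relative patterns and method properties
  transfer.
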