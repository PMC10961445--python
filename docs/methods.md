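# Methods

## Volume-conductor model and SPFD discretization

The head is modelled as a piecewise-homogeneous, isotropic, purely
resistive volume conductor in the quasi-static (DC) regime: the scalar
potential obeys ∇·(σ∇φ) = 0 with Neumann boundaries except at the
electrodes, where current is injected. On a regular voxel grid the
scalar-potential finite-difference (SPFD) method assigns the unknown φ to
the (nx+1)(ny+1)(nz+1) voxel corner nodes and a conductance to every
lattice edge. For cubic voxels of side h, a voxel of conductivity σ
contributes σ·h/4 to each of its four edges parallel to a given axis, so
the edge conductance is the mean conductivity of the (up to four) voxels
sharing the edge — exterior voxels count as zero — times h. Kirchhoff's
current law at every node yields a sparse, symmetric operator with zero
row sums over interior nodes; this edge rule is verified in the tests
against an independent dense assembly that loops over voxels and edges
explicitly.

Electrode patches are node sets on the staircase scalp surface: surface
nodes under a square geodesic footprint, thinned to one node per
tangent-plane grid cell so the areal injection density is uniform despite
the staircase (without thinning, patch node counts would be inflated by
the L1 norm of the surface normal, between 1 and √3 depending on patch
orientation). Montage current is divided equally over the patch nodes,
positive at the anode, negative at the cathode.

The gauge is fixed by pinning one scalp node (the bottom-pole node, chosen
away from all electrode patches) to zero; potentials are gauge-dependent,
fields are not, so tests assert fields only.

### Solver

The normative contract is the relative residual ‖Aφ − b‖/‖b‖ < 10⁻⁶;
the algorithm behind it is a configuration choice (`backend`):

- `direct` — sparse LU of the reduced operator, cached on the system, so a
  bank of many injections costs one factorization plus cheap triangular
  solves;
- `cg` — Jacobi-preconditioned conjugate gradients, run to a residual two
  orders below the contract;
- `auto` (default) — LU below 20 000 active unknowns, CG above. The
  crossover is an amortization trade-off: at 48³ one CG solve takes
  ~0.4 s while the LU factorization alone takes ~30 s.

Non-convergence raises with the achieved residual rather than returning a
silently bad field.

### Field computation and outlier capping

Each Cartesian field component per voxel is minus the mean of the four
parallel corner-edge potential differences divided by the node distance;
the field is zero outside the conductor. Staircase electrodes produce a
small number of spuriously large near-electrode values, so magnitudes
above the 99.9th percentile of in-conductor magnitudes are rescaled to
that percentile, preserving direction. The threshold is the *lower order
statistic* at the percentile (an observed magnitude, not an interpolated
one): with interpolation, re-capping a capped field would lower the
threshold slightly each time because a tie block forms at the cap, whereas
the order-statistic convention makes capping exactly idempotent.

### Numerical verification

- A homogeneous slab with area-weighted uniform face injection has the
  exact discrete solution |E| = I/(Aσ); the solver reproduces it to
  machine precision (the 1% acceptance margin is slack). Stacked slabs
  reproduce the flux-continuity ratio E₂/E₁ = σ₁/σ₂ exactly.
- Because slab solutions are discretely exact at any resolution, grid
  convergence is instead demonstrated on the real problem class: a
  patch-electrode sphere solve at h = 2 and 1 mm against an h = 0.5 mm
  reference shows the O(h²) error of the central field decreasing
  monotonically.
- Discrete current conservation, anode/cathode reciprocity and linearity
  in the injected current are asserted directly.

## Phantom

A concentric five-layer sphere (skin, skull, CSF, gray matter, white
matter) stands in for a segmented head, with two deep gray nuclei embedded
in the white matter: the *target* (radius 4 mm, right-anterior) and a
*decoy* (radius 5 mm, left-posterior). The deep region is their union; the
decoy provides the non-target deep tissue that the designed field sets to
zero. The radii differ deliberately so the deep-region surface has no
point symmetry — with equal radii, registering a subject surface to the
template would be ambiguous under point reflection.

Tissue conductivities (S/m) follow measured values: gray matter 0.2,
white matter 0.14 (70% of gray), CSF 1.8, skin 0.1, compact bone 0.008,
deep gray nuclei 0.2. An alternative "text" variant (skin 0.08, blood
0.2) is selectable. The default grid is 48³ at 1 mm. One millimetre
(rather than the 0.5 mm of high-resolution anatomical models) keeps a full
19-electrode lead-field bank under a minute on one CPU; resolution is a
config knob and all spatial quantities are resolution-independent by
construction.

The 19 electrodes sit at idealized spherical 10–20 positions (outer-ring
electrodes on the upper-hemisphere equator, F3/F4/P3/P4 at great-circle
midpoints of their neighbours). The physical 3 cm sponge footprint is
scaled by (phantom outer radius / 92 mm) so each patch covers the same
solid angle as the device on an adult head; patches are additionally
clipped to their spherical Voronoi cell, which guarantees disjointness for
any configured size.

### Subject ensembles

`perturb_config` jitters layer radii by ±5%, every tissue conductivity by
±10%, and the target centre by up to 2 voxels, then restores the
invariants (strictly decreasing radii with a minimum gap, nucleus inside
the white matter). These magnitudes are a plausible stand-in for
inter-subject anatomical and conductivity variability; what the ensemble
does *not* emulate is real anatomy — gyrification, tissue-boundary
irregularity, electrode–anatomy covariation. Passing group tests therefore
show the pipeline's statistics and registration machinery are correct, not
that any particular montage transfers to human cohorts.

## Lead fields and datasets

With electrode 0 as reference, the bank stores k − 1 solved fields; any
montage field is the difference of two bank entries (verified in tests
against direct two-electrode solves to ~10⁻¹⁵ relative, bounded in the
suite at twice the solver tolerance). Montage base current is 1 mA — the
"original" current that the weight bound multiplies; it is a config knob
since only the product w·I_base is physical.

Dataset rows are ordered x, y, z per element, elements in C-scan order of
the region mask (volume mode) or mesh-vertex order (surface mode), and
every montage column is outlier-capped before extraction. Surface
sampling: marching-cubes isosurface of the binary region mask at level
0.5; each vertex is moved 1 mm along its inward normal (both normal signs
are tested against the mask; if the region is thinner than the depth the
point snaps to the nearest in-mask voxel centre and is flagged). Fields at
sampling points are trilinearly interpolated from voxel centres. The
"depth" is a single inset surface, not a shell band; `depth_mm` is
exposed.

## Optimization

`E_designed` holds the unit vector e₀ on target elements and zero on the
rest of the deep region; e₀ defaults to the +y (anterior) axis of the
phantom — the "horizontal" direction is anatomy-dependent and configurable.
The box-constrained least-squares problem (|w_m| ≤ 2) is solved with
SciPy's bounded least squares (BVLS, with a trust-region fallback), which
is deterministic; optimality is checked via the KKT conditions (projected
gradient ≈ 0 on inactive bounds) and validated in tests against
exhaustive grid search on small instances.

RMSE is computed on the optimizer's own dataset rows (surface rows in
surface mode), *before* normalization, with the 3N-component denominator.
The exhaustive subset search evaluates every C(n,k) subset, breaks ties
lexicographically, and applies the 4 mA safety cap per electrode *after*
normalizing to the 0.4 V/m target level; an optional total-current
interpretation of the cap is selectable. Normalization always averages
|E| over the volumetric target voxels (even in surface mode), using the
superposed capped montage fields, and is exactly idempotent. Because the
normalization scale multiplies the weights, the effective per-montage
current can exceed 2× base after scaling; raw and scaled weights are both
reported.

Infeasibility is reported, not hidden: if no subset passes the cap, the
minimum-RMSE result is returned with `feasible=False`.

## Group analysis

The template is the unperturbed base phantom's deep-region surface.
Registration is affine ICP: nearest-template-vertex correspondences and a
least-squares affine refit per iteration, run from two deterministic
initializations — centroid translation only, and centroid plus
principal-axes alignment with a fixed sign convention — keeping the
lower-residual fit. (For near-spherical surfaces the principal axes are
noise-driven; the centroid start avoids the local minima a wrong axis
alignment can cause.) The mean squared residual is non-increasing across
iterations.

Per-subject strengths are normalized by the subject's maximum over the
deep surface, projected to the template by nearest neighbour, and
summarized by vertexwise mean and relative SD (population SD / mean;
vertices with zero mean are reported as undefined, not infinite). The
group montage is the subset most subjects selected (ties lexicographic);
mean current ratios average over *all* subjects, re-solving the weights on
the group subset for subjects whose individual optimum differed.

## Problem sizes and tolerances

Default test and acceptance sizes: 48³ (1 mm) for the single-subject
pipeline, 32³ phantoms for oracle suites and the 10-subject group
ensemble, chosen so the whole suite runs in a few minutes on one CPU.
Solver contract 10⁻⁶ (CG run to 10⁻⁸); weight-bound feasibility asserted
to 10⁻⁹; normalization exact to 10⁻⁶ relative; ICP synthetic-transform
recovery to 10⁻³ (on an asymmetric surface — a sphere would make affine
registration ill-posed under rotation).

## Known limitations

- Spherical phantoms only; no anatomical segmentation, cortical surface
  reconstruction, or dura/eye/blood detail beyond optional extra shells.
- Isotropic DC conductivities; no tensors, no frequency dependence.
- Exhaustive subset search scales as C(19,k); practical for small k (or
  the 6-electrode toys used in tests), by design — no heuristic search.
- Surface-mode economy on desk-scale phantoms is modest (the
  surface/volume element ratio falls as O(h): measured 1.11 → 0.57 → 0.28
  for h = 1 → 0.5 → 0.25 mm on the default geometry); the order-of-
  magnitude savings appear at anatomical head sizes and resolutions.
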