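# Methods

This note records the models, conventions and design choices behind the
package, in the order the pipeline runs.

## Conventions

Axis 0 is mediolateral, axis 1 dorsoventral (dorsal = increasing index),
axis 2 anteroposterior.  Voxel indices are 0-based; physical coordinates
are `index × voxel_size` with the origin at the corner of voxel (0,0,0)
and voxel centers at `(index + 0.5) × voxel_size`.  Volumes carry µm,
meshes mm; the FE system is mm–N–MPa, so displacements come out in mm and
strains dimensionless.  "Expansion of *n* voxels" means *n* iterations of
unit dilation with the full 3×3×3 structuring element; "contact" is
26-connectivity; suture-bridging checks use face (6-) adjacency.

## Phantoms

The synthetic calvaria is a hemispherical shell of outer radius *R* and
thickness *t*, partitioned into wedge plates by planes containing the
mediolateral axis; a gap of width *g* is cut symmetrically about each
plane, so gap widths are analytically exact.  With `cavity=True` a basal
disk seals the cavity from below, separated from the shell by the same
gap (a basal suture ring).  Two constraint patches are carved from the
most anterior and most posterior-ventral solid voxels, mirroring
incisor-against-tube contact and basioccipital fixation without anatomy.
Defaults (R = 2 mm, t = 0.2 mm, g = 50 µm, 4 plates, 25 µm voxels)
match the scale of a neonatal mouse skull imaged at ~10–25 µm.  The
construction is deterministic; the seed field exists for provenance and
for downstream noise injection.

Loaded/unloaded surface pairs are marching-cubes surfaces (Gaussian
pre-smoothing, 2 voxels by default, so they are curved rather than
staircase) with per-vertex bone labels; the loaded set is the exact image
of the unloaded set under stored per-bone rigid motions, giving perfect
vertex correspondence for registration ground truth.

Two auxiliary fixtures exist because the dome is a poor test bench for
specific questions: `suture_slab` (a planar bone–suture–bone sandwich
with exactly known width) for strain recovery, and `calibration_rig`
(three clamped slender beam pairs, spans 24/12/6 mm at 100 µm voxels,
joined by 0.2 mm sutures) for modulus sweeps.  The rig exists because a
dome with fat, very soft sutures is mechanically insensitive to the bone
modulus — suture compliance dominates — whereas slender plates put bone
bending in series with the suture, and staggering three spans keeps the
objective steep (log-slope ≥ ~0.1 somewhere on every decade) across the
whole 10–7000 MPa sweep range.

## Suture synthesis

Recipe order: dilate bones (default 5) → record contacts (dilation-tie
voxels, which are assigned to neither claimant, plus face-adjacent
cross-label voxels) → dilate contacts (default 5) restricted to original
background → smooth → grow 1 → smooth → restore bones.  The smoothing
counts 9/1/9 are interpreted as kernel *sizes* (window side 9, radius 4):
with a window of side 19 every counting rule that lets air vote deletes a
suture confined to a gap thinner than half the window, which would
destroy the very sutures the recipe exists to build in a shell only ~8
voxels thick.

Smoothing itself is a neighbourhood vote with three modes.  The default
for synthesis is the *solid* vote: a background/suture voxel becomes (or
stays) suture when suture∪bone occupies a strict majority of the window
and the window contains at least one suture voxel.  Counting bone as
occupied is what lets an in-gap suture — which air would out-vote —
survive, while the suture-presence guard stops the label from creeping
along bone surfaces far from any joint.  A plain strict-majority mode
(the textbook label smoother; a flat half-space is a fixed point, a
protruding voxel is removed) and a Gaussian-reblur-threshold mode are
selectable.  Window sums replicate edges so flatness is preserved at the
volume boundary.  Throughout, additions claim background only and bones
are never modified.

The suture is additionally clipped to the Euclidean envelope
`dist(bone) ≤ bone_expand + 1`: the recipe's contract is that the suture
follows the shell, and without the clip the expansion steps leak into
the cranial cavity wherever gap planes pass near it (fatal at coarse
phantom scales).  Finally, suture components face-adjacent to fewer than
two bones are dropped.

Individual sutures in a model with a single suture label are told apart
by their two nearest bone labels (per-voxel distance transforms), giving
bone-pair regions such as "(1, 2)" = the joint between plates 1 and 2.

## Endocast and covers

The solid mask is closed with a Euclidean ball (two distance transforms,
so any radius is cheap); interior components of the complement under
face connectivity are cavity candidates, and flood fill that escapes to
the volume boundary is the "not closable" failure.  Discretization makes
the closable hole size approximately, not exactly, 2× the closing
radius (about one voxel of margin).  Covers are exterior background
voxels face-adjacent to the endocast — one shell, which provably blocks
every face-connected path inside — and take suture material downstream.
`endocast_sealed` re-checks the seal by an independent exterior flood.

## Meshing

Tetrahedral meshes are structured Kuhn (Freudenthal) subdivisions: six
positively oriented tets per voxel with a translation-invariant diagonal
pattern, hence conforming across region interfaces by construction,
exactly volume-conserving per region, and deterministic.  `max_edge_mm`
is honoured by integer subvoxel refinement (the longest edge is the cube
diagonal √3·h).  Per-region *adaptive* sizing is intentionally absent:
with no constrained Delaunay mesher available the finest requested size
simply sets the global pitch.  Surface meshes come from per-region
marching cubes at the 0.5 iso-level with optional Gaussian pre-smoothing
(σ = extent/2) and vertex-clustering decimation (regions never merge);
surfaces of different regions are extracted independently and are not
vertex-conforming — volume meshing does not go through them.

## Elastic FE

Linear (constant-strain) tetrahedra, isotropic Hooke materials per region
role, one Poisson ratio (0.3).  Material fallbacks: constraint patches →
bone, covers → suture, endocast → brain.  The calibrated material set is
brain 3 Pa (a deliberate near-void that keeps the mesh conforming while
discounting the brain), suture 30 kPa, bone swept 10–7000 MPa with
20 MPa as the calibrated default.  The load case splits the total force
(default 0.1 N) equally over the surface nodes of bone regions within
half a disc diameter (default 1 mm) of the load point's surface
projection, directed dorsoventrally; constraint-patch nodes are excluded
from the disc.  The anterior patch is fixed in the load direction only
by default ('all' available); the posterior-ventral patch is fixed in
all DOFs.  Dirichlet elimination + SuperLU direct solve; the relative
residual is checked (<1e-6 raises with a singularity diagnostic).
Because stiffness is linear in E at fixed ν, sweeps assemble one
unit-modulus matrix per region and recombine per grid point.

Strain post-processing: ε_vm = √(⅔ ε_dev:ε_dev), principal strains are
eigenvalues (e₁ ≥ e₂ ≥ e₃), per-suture summaries are tet-volume-weighted
means.  Verification: uniaxial bar with consistent end tractions
reproduces σ/E and −νσ/E to machine precision, a distorted-mesh patch
test is exact to 1e-10, reactions balance to 1e-8 N, and a slender
cantilever (L/h = 10) lands within ~11% of PL³/3EI at the default
refinement of 6 elements through the thickness, converging from above
stiffness as linear tets do.  Solver cost, not accuracy, sets the
default problem sizes: SuperLU handles the ~30–50k-tet phantoms used
throughout in seconds per factorization.

## Suture strain from surface pairs

Per-bone alignment is ICP with point-to-plane correspondences
(linearized 6-DOF update against destination vertex normals).
Point-to-point ICP is retained as an option but is not the default: on
sampled surfaces it locks onto the sampling lattice and cannot recover
tangential slides smaller than the vertex spacing, which are exactly the
motions of interest (tens of µm against ~50 µm spacing).  Convergence:
RMS change < 1e-6 mm or 200 iterations; non-overlapping inputs (initial
RMS beyond half the joint bounding-box diagonal) are rejected.

The estimator meshes the suture region, assigns every suture node that
touches a bone voxel the rigid displacement of that bone (majority of
the 8 incident voxels; smallest label on ties), and solves the
unit-modulus elastic problem with those Dirichlet data — strain from
pure Dirichlet data is modulus-independent, and the elastic fill gives a
smooth field across the gap instead of an arbitrary midline jump.
Reported strains use the nominal (small-strain) tensor of the resulting
displacement field: for a uniform opening Δ over width w it reads
exactly Δ/w at any magnitude, which is the natural scale for suture
strains of order 0.3–8; the Green–Lagrange measure is available but
grows like Δ/w + (Δ/w)²/2 and is only appropriate when comparing against
quantities defined the same way.  A `frame` transform conjugates the
alignments into the model frame, making the report invariant under a
common rigid motion of both scans (exact, since eigenvalues survive
conjugation).

## Gap analysis

Per mediolateral slice: the interface position is the midpoint between
the facing anteroposterior extents of the two bones; each bone's dorsal
edge is its most dorsal voxel within ±20 voxels of the interface (ties
resolved toward the interface); the reported distance is the in-slice
Euclidean center distance minus one voxel, so an n-voxel gap reads
n voxel-lengths — this face-to-face convention is what makes a 95 µm
fixture read 95 µm.  Slices with face-touching bones are excluded as
fused and counted.  Comparison: change ratio
(mean_loaded − mean_unloaded)/mean_unloaded, one-way ANOVA, Levene's
test in the median-centred Brown–Forsythe form, significance stars at
0.05/0.01/0.001; when Levene rejects homogeneity, Welch's ANOVA (own
closed-form implementation; not exposed by scipy/statsmodels) is
reported alongside rather than silently substituted.  Degenerate
zero-variance comparisons return F = 0, p = 1 for identical means.

## Calibration

Percentage difference uses the experimental denominator,
100·|comp − exp|/exp.  Lin's CCC uses population (1/n) moments by
default (sample-moment variant selectable); identical constant vectors
return 1 by convention, a constant y against varying x returns 0.  The
sweep grid is log-spaced, 25 points over 10–7000 MPa.  The objective is
the unweighted mean of per-suture |percentage difference| curves; the
argmin is the calibrated modulus, and both per-suture and mean curves
are retained.  Self-consistency (experiment generated on-grid) recovers
the generating modulus exactly; with 5% multiplicative noise on the rig
the argmin stays within one grid step of the generating modulus in well
over 90% of replicates at 20, 200 and 2000 MPa.

## What the phantoms do and do not show

Phantom plates are geometrically clean wedges, deform exactly rigidly in
registration ground truth, and have sutures several voxels wide; real
calvaria have irregular plate boundaries, locally bending bone (the
failure mode of rigid alignment on heavily loaded soft bone), partial
fusion, and micrometre gaps at the resolution limit.  Passing the suite
therefore demonstrates correctness of the algorithms under their stated
assumptions — rigid bones, resolvable gaps, linear elasticity — not
predictive accuracy on real specimens, where linear isotropic material
models are themselves the dominant approximation.  Strain estimation for
fused sutures is undefined by construction, and the gap measurement only
reflects the superficial (dorsal-edge) part of a suture.

## Known limitations

Voxel meshes have staircase boundaries (mitigated but not removed by the
half-voxel marching-cubes offset for surfaces); linear tets are stiff in
bending and need ~6 elements through a plate thickness; the direct
sparse solver bounds practical mesh sizes at roughly 10⁵ tets on one
CPU; ILU-preconditioned Krylov solvers fail on the 10⁷ stiffness
contrast of the calibrated material set, so no iterative fallback is
offered; multi-parameter joint calibration (brain+suture+bone) is out of
scope — the suture and brain moduli are fixed inputs.
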