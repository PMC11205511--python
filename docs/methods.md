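# Methods

This note documents the geometric model behind `cellshape3d`, the
numerical choices made where the design was genuinely open, and what the
synthetic-data tests do and do not demonstrate about real microscopy data.

## Input model

A segmented volume is a 3D integer grid in (z, y, x) axis order, one label
per cell, 0 = background.  Voxel index *i* along an axis with spacing *s*
occupies the half-open physical interval [*i·s*, (*i*+1)·*s*); its center
is at (*i* + ½)·*s* plus the volume origin.  Labels are taken as given: no
connected-component splitting is performed, and disconnected voxels
sharing a label are treated as one region with a logged warning.
Anisotropic spacing is supported by carrying physical coordinates through
every step; the reference use case is isotropic 0.25 μm spacing with a
1.39 min frame interval.

## Surface reconstruction

The boundary of a region is reconstructed by marching cubes at iso-level
0.5 on the binary mask, zero-padded by one voxel so the surface is always
closed.  Marching cubes on binary data produces a staircase surface whose
area overestimates the true boundary by roughly 9% — and, critically, this
bias does not vanish with resolution, so any descriptor involving *S*
would be systematically depressed (a perfect ball would never score above
~0.92 in general sphericity).  The raw mesh is therefore faired with the
Taubin shrink-free Laplacian filter (λ = 0.5, μ-step 0.53), a standard
two-pass smoother that removes the high-frequency staircase while
approximately preserving volume.  Because the staircase wavelength is
fixed at one voxel while object scale grows, the iteration budget scales
with the region's mean bounding-box extent in voxels (clipped to
[10, 60]); regions smaller than 4 voxels mean extent are left unfaired,
as smoothing would collapse them.

Measured on digitized balls, the faired pipeline gives general sphericity
0.989 / 0.994 / 0.997 at radii 10 / 20 / 40 voxels (monotone convergence
to 1) with volume errors of 0.7% / 0.2% / 0.04%.  The cost of fairing is
mild corner rounding on polyhedral shapes: a digitized box keeps its
volume within 5% of edge-product truth, but its *S*-derived descriptors
(general sphericity, spreading index) read up to ~6–8% high.  Sharp-edged
cells are rare in membrane data; for synthetic validation the tests bound
*S*-derived box descriptors at 8% and everything else at 5%.

Surface area is the sum of triangle areas; volume is the divergence-
theorem signed volume of the closed, outward-oriented mesh (orientation is
fixed by the sign of the total signed volume).  The convex hull is the
Qhull hull of the faired mesh vertices, triangulated and measured with the
same two estimators, which guarantees *V* ≤ *V*<sub>convex</sub>.

## Principal axes

Directions come from the eigenvectors of the covariance matrix of the
occupied voxel-center coordinates (unbiased 1/(n−1) normalization), sorted
by descending eigenvalue.  Exactly degenerate spectra (balls, cubes) admit
any eigenbasis; for determinism the basis closest to the grid axes is
chosen, which never affects descriptors because the corresponding extents
are equal.

Axis lengths *a* ≥ *b* ≥ *c* are the extents of the *raw* (unfaired)
marching-cubes mesh vertices projected onto the three directions — the
edge lengths of the region's oriented bounding box.  The raw mesh is used
here deliberately: its faces lie exactly on the physical boundary planes,
so an axis-aligned W×H×D box of unit voxels measures exactly (W, H, D),
one-voxel-thick slabs keep a positive short axis, and oblique orientations
stay within 3% of the continuous extents at ≥10-voxel radii (the faired
mesh would bulge box faces by a few percent, and voxel-center extents
would need a direction-dependent correction that overshoots by up to ~9%
along diagonals).  A single-voxel region, whose sample covariance is
undefined, is assigned grid-aligned directions with lengths equal to the
sorted spacing.

## The 12 descriptors

All descriptors are dimensionless ratios of {*S*, *V*,
*S*<sub>convex</sub>, *V*<sub>convex</sub>, *a*, *b*, *c*} (table in the
README), hence exactly invariant under isotropic rescaling.  Two points
deserve comment:

* **Hayakawa roundness.**  The source formula is a mean-intercept ratio of
  *V*/*S* to the geometric-mean radius; its normalization constant is not
  recoverable unambiguously.  The implementation uses
  *C*·(*V*/*S*)/(*abc*)^⅓ with *C* configurable and defaulting to 6, which
  calibrates a perfect ball to exactly 1 (*V*/*S* = *R*/3 and
  (*abc*)^⅓ = 2*R*).  The raw un-normalized ratio is recorded alongside;
  any comparison *between* cells is unaffected by the constant.
* **Sphericity above 1.**  Mesh discretization can push sphericities
  marginally above 1.  Values in (1, 1.001] are reported as-is with a
  warning rather than clamped, so downstream tolerance-aware analyses see
  the truth.

CSV outputs round to 6 significant digits; JSON keeps full precision.

## Segmentation-uncertainty protocol

Segmented boundaries are uncertain by about one voxel.  The protocol
dilates (adds every background voxel in direct contact with the region)
and erodes (removes every region voxel in direct contact with background)
by one layer, recomputes all descriptors, and summarizes each triple
(original ξ₁, dilated ξ₂, eroded ξ₃) with η₁ = population SD / mean and
η₂ = range / mean.  For n = 3 the range dominates the population SD, so
η₂ ≥ η₁ ≥ 0 always.  "Direct contact" defaults to face adjacency
(6-connectivity); 18 and 26 are available for sensitivity analysis.  A
region that erodes to nothing falls back to a flagged two-value report so
batch runs survive tiny cells.  Batch summaries expose per-descriptor
means over regions and, when frames are indexed, per time point.

Scale matters intrinsically here: a one-voxel layer moves each axis by two
voxels, so c-ratio descriptors of a region only 10 voxels across swing by
~20% no matter how the geometry is measured.  The robustness guarantee
verified by the tests — every η below 10% — applies to smooth regions with
shortest semiaxis ≥ 10 voxels (≈ 2.5 μm at 0.25 μm spacing); measured
maxima there are ≤ 6.7%.

## Track statistics

* **Migration speed** — ‖Δ mass-center‖ per interval divided by the frame
  interval in minutes (default 1.39 min), units μm/min.  The mass center
  is the unweighted mean of occupied voxel centers.
* **Lifespan normalization** — affine map of a full-lifespan track's times
  to [0, 1] (birth → 0, final pre-division frame → 1); idempotent, with
  linear resampling onto a common grid for cross-track comparison.
* **Elongation at division** — per track, the elongation ratio at the last
  three frames (offsets −2Δt, −Δt, 0); groups at consecutive offsets are
  compared with Welch's two-sample t-test (no variance-homogeneity
  assumption), reporting statistic and p-value without a hard-coded
  verdict.
* **Speed vs descriptor** — each interval speed is paired with the
  descriptor at the interval's *start* frame (the shape precedes the
  displacement; midpoint pairing is available as an option), binned by
  descriptor value, and summarized with type-7 linear-interpolation
  quartiles plus whisker limits at Q1 − 1.5·IQR and Q3 + 1.5·IQR.

## Synthetic shapes

The generator digitizes continuous spheres, ellipsoids, boxes and
dumbbells (two overlapping balls — the constricted-membrane geometry of a
dividing cell) by center inclusion: a voxel is occupied iff its center
lies inside the shape, matching binary-mask semantics.  Grids are sized
per axis so that integer-sized axis-aligned shapes digitize to their exact
voxel counts.  Closed-form descriptor oracles exist for spheres and boxes
(exact) and ellipsoids (Thomsen surface-area approximation, p = 1.6075,
error < 1.1%, folded into test tolerances); dumbbells have none and say
so.

The division sequence interpolates a ball into a thinning-necked dumbbell:
lobe radius shrinks toward the volume-conserving two-daughter value
(2^−⅓ of the initial radius) while lobe separation grows to 1.7 lobe
radii, so the elongation ratio rises monotonically to ≈ 1.85.  Replicate
variability enters as one seeded scale jitter per sequence (5% SD on
separation and radius), preserving within-sequence monotonicity.  The
non-dividing control is a mildly jittered ball (3% SD per semiaxis, drawn
once per track) repeated over frames — a resting cell whose shape does not
change — giving an exact null for the division comparison.  Default sizes
(radius 10 voxels, 5 frames, 20 replicates) keep the full validation suite
under a minute on one core.

What the synthetic tests do **not** show: real membranes have local
protrusions, neighbour-contact facets and imaging noise that no geometric
primitive reproduces; passing these tests demonstrates correctness of the
measurement pipeline, not biological generality of any threshold derived
from real data.

## Known limitations

* Fairing trades a small, shape-dependent bias (corner rounding on
  polyhedra) for the removal of a large shape-independent one (staircase
  area); both are documented above and bounded by the tests.
* The one-voxel perturbation model does not attempt probabilistic boundary
  estimation; η metrics quantify sensitivity, not calibrated error bars.
* Genus is not enforced: a region with internal tunnels or cavities gets
  the descriptors of whatever surface marching cubes reconstructs.
* No membrane segmentation, lineage-tree construction or multi-embryo
  averaging is included; inputs are already-segmented labels plus an
  optional per-frame correspondence table.
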