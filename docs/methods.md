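# Methods

## Geometry and conventions

Masks are boolean occupancy grids with physical geometry: spacing (mm per
voxel along each index axis), origin (physical position of the center of
voxel (0,0,0)) and an orthonormal direction matrix mapping index axes to
patient axes. Patient coordinates are **LPS** (+x Left, +y Posterior,
+z Superior), the convention of ITK/SimpleITK, through which all volume I/O
goes. Two volumes are grid-compatible when shape, spacing, origin and
directions agree within 1e-6 mm; anything else is a hard error, never a
silent resample — a misregistered GTV/CTV pair would corrupt margins
invisibly.

Sub-voxel occupancy is the trilinear interpolation of the 0/1 voxel values;
*inside* means occupancy ≥ 0.5, and beyond the outermost voxel centers the
interpolation blends to background 0. On an axis-aligned face the 0.5 level
falls exactly midway between the last foreground and first background voxel
centers, i.e. on the natural face of the voxelised solid, which is what
makes flat-phantom margins exact.

The mask surface is the set of foreground voxels with at least one
background (or out-of-grid) 6-neighbour, represented by their physical
centers. A marching-cubes mesh would change the ensemble only at sub-voxel
scale while complicating every downstream step; boundary voxels are the
voxel-native surface.

Planar contours (axial polygons in patient mm, one plane position per
record) are rasterized by the even–odd rule at voxel centers: a voxel is
foreground when its center lies inside an odd number of that slice's
polygons, so holes are expressed as nested polygons. Containment is a
vectorised crossing-number test; voxel centers exactly on a polygon edge
follow the half-open crossing rule.

## The directional margin

For direction **d** (unit vector, patient coordinates, built from
anatomical labels like `SA` or given explicitly), one ray is cast from
every GTV surface-voxel center:

1. March along **d** in steps of 0.1 × min(spacing) until the GTV occupancy
   falls below 0.5; bracket and bisect the crossing to 0.01 mm, then apply
   one regula-falsi step inside the converged bracket. This crossing is the
   **vector start** — lengths are boundary-to-boundary, not voxel-center
   based (centers would bias margins by about half a voxel).
2. Continue marching to the first CTV occupancy crossing — the **vector
   end**, refined the same way.
3. **Reject** the ray if any sample more than 0.05 mm past the start
   re-enters the GTV before the end (the vector would cross the GTV
   interior — e.g. across a concavity). The 0.05 mm grace absorbs
   interpolation jitter at the departure point.
4. **Reject** the ray if a barrier mask is given and any sample between
   start and end lies inside it.
5. If the start already lies outside the CTV, the vector is **clamped** to
   length zero and kept: a tighter-than-GTV expert contour means "no
   expansion here", not a missing observation, which keeps the per-expert
   sample complete for the margin deviation.
6. Marching is capped at the grid's physical diagonal; a ray that never
   exits within the cap is a cast failure (counted, and an error for the
   single-ray API).

M(**d**) is the median of the accepted lengths (clamped zeros included; an
even count averages the two central order statistics). A result carries the
full vector set and counters (candidates, interior/barrier rejections,
clamps, failures); fewer than 10 accepted vectors triggers a warning since
medians of very few rays are unstable (threshold configurable via
`CastParams`).

The regula-falsi polish after bisection deserves a note: trilinear
occupancy is exactly linear in the marching parameter within a voxel cell
for axis-aligned rays, so the polish pins flat-face crossings to float
precision (slab margins come out exactly 7.0/2.0 mm rather than ±0.01 mm),
and for oblique rays it simply tightens the bisection tolerance at the cost
of two extra interpolations per ray batch.

The margin deviation CV(**d**) computes M(**d**) against each of K ≥ 2
expert CTVs independently and divides the sample standard deviation (K−1
denominator — expert panels are small samples) by the mean; all-zero
margins give CV = 0 by convention.

### The median on curved surfaces

The ensemble median is *not* the face-on expansion when the surface is
curved. For a sphere of radius r expanded isotropically by m, a ray at
impact parameter ρ has length √((r+m)²−ρ²) − √(r²−ρ²), rising from m at the
pole to √(m²+2rm) at the equator. With surface points uniform in area
(uniform in |cos θ|), the median sits at |cos θ| = ½:

M = √((r+m)² − ¾ r²) − r/2  ( > m ).

For r = 10, m = 5 this is 7.25 mm — a 45 % inflation. The effect is
intrinsic to the median-of-parallel-vectors definition: it vanishes on flat
faces probed along their normal (the clinically intended use: clinicians
choose directions along which the CTV bulges, where the local geometry is
slab-like) and grows with surface obliquity. The synthetic phantoms
therefore record as ground truth the *analytic prediction of the measured
median* (the closed form above for spheres; a continuum surface-integration
oracle for ellipsoid axes; the exact offsets for flat phantoms), and users
comparing margins across shapes should be aware that curvature inflates the
statistic.

### Exactness properties

- Translating both masks by a whole-voxel origin shift leaves M(**d**)
  bit-identical (the computation happens in index space).
- Scaling all physical dimensions by a power of two — spacing, origin and
  the mm-valued resolution parameters (`CastParams.scaled`) — scales
  M(**d**) exactly, because every IEEE operation scales exactly.
- Rotating both masks and **d** by 90° about a grid axis reproduces
  M(**d**) to ~1 ulp (observed ≤ 1e-15 mm) but not bitwise: the rotation
  reflects one index axis, and `fl(b+g)` versus `fl((N−1−b)−g)` can round
  differently. This is a property of floating-point arithmetic, not of the
  algorithm; the tests assert 1e-12 mm.

## STAPLE consensus

Binary STAPLE treats the unknown true segmentation as a latent field and
each rater j as a channel with sensitivity p_j and specificity q_j,
alternating posterior (E) and performance (M) estimates. Package
conventions, all configurable and stated because published STAPLE variants
differ:

- scalar foreground prior, fixed across iterations at the raters' mean
  foreground fraction over the working region;
- initialisation p = q = 0.99999 (avoids the label-swapped fixed point);
- working region restricted to the union bounding box dilated by one voxel
  (otherwise unbounded background dominates the specificity estimates);
  posteriors outside are 0;
- convergence when the mean absolute posterior change drops below 1e-6
  (cap 100 iterations);
- consensus mask at posterior ≥ 0.5.

The per-rater E-step log-likelihood terms are sorted before summation, so
the posterior is exactly invariant under rater permutation despite
floating-point non-associativity. K = 1 reproduces the single rater's mask;
unanimous panels are reproduced with performance parameters within 1e-3
of 1.

## Synthetic phantoms and simulated experts

Phantoms are defined analytically: the GTV is a distance-function test at
voxel centers (sphere, box, grid-spanning slab, or a U-shape with a slot
carved toward +y), and the CTV is the *analytic* direction-dependent
expansion of the same function — co-centered ellipsoid for per-axis sphere
expansion, per-face offset boxes, isotropic distance thresholds — never a
morphological dilation, so the true geometry is exact in mm and independent
of grid resolution. Grid starts snap to spacing multiples so flat faces
placed at spacing multiples land exactly on the trilinear 0.5 level. A
phantom whose CTV would touch the grid boundary (other than a slab's
spanning axes) is a clearance error. Optional barriers are half-space
masks; truth entries for directions heading into the barrier are marked
not-analytically-clean rather than given a number.

Simulated experts expand the GTV by margins drawn from a normal
distribution truncated at zero (the simplest noise model keeping margins
non-negative) via the exact Euclidean distance transform of the voxelised
GTV; draws are reproducible from the seed. Defaults used across tests and
the acceptance script — panel size K = 9, true margin 7 mm, SD 2 mm —
mirror a nine-expert panel with moderate disagreement; phantom grids are
0.5 mm isotropic for recovery tests (finer than clinical CT) and 1 mm for
ensemble-heavy simulations, with a 1.17 × 1.17 × 3 mm anisotropic grid
exercised in the I/O tests.

What the phantoms do **not** emulate: imaging appearance, real bone
anatomy, contour smoothing, or spatially correlated expert disagreement
(each simulated expert errs by a single global margin, whereas real experts
disagree locally). Passing recovery tests therefore demonstrates the
correctness of the measurement pipeline on known geometry, not performance
on clinical contours.

## Study orchestration

A case couples a GTV, expert CTVs, an optional precomputed consensus
(otherwise STAPLE is run), an optional barrier, and labeled probe
directions each tagged with a route-of-spread class. Case evaluation never
aborts on a single direction: failures (e.g. every ray barrier-blocked) are
recorded with their reason and excluded from — but counted alongside —
summaries. Cross-case summaries pool *per direction* within each route
class (one direction = one datum, so a case can contribute to both
intraosseous and extraosseous classes) and report median and (min, max)
range for margins and CVs.

Reports are deterministic (sorted keys, fixed format): per-case JSON and
the tidy study CSV carry full precision; the summary JSON additionally
carries values rounded to the reporting precision of the human tables
(0.1 mm margins, 0.01 CV). Identical inputs produce bit-identical report
files, and summaries are invariant to case order.

## Problem sizes

Recovery tests run on ~60–90³ voxel grids (thousands of surface rays per
direction, fractions of a second per margin); the margin-deviation
recovery averages 20 seeded 9-expert panels on a 1 mm grid; the brute-force
marcher cross-check samples 200 random rays at 0.005 × spacing steps. These
sizes make the whole suite run in well under a minute while keeping
discretization error far below the assertion tolerances.

## Known limitations

- The curvature inflation of the median (above) is inherited from the
  margin definition; margins along directions probing strongly curved
  surface regions should be interpreted accordingly.
- Barrier handling rejects rays, it does not re-route them; a direction
  whose rays are all blocked has no margin (reported as failed).
- Re-entry and barrier checks between the last marching sample and the
  refined crossing are resolved at step resolution (0.1 × min spacing), so
  features thinner than one step can be missed.
- No resampling: all volumes of a case must share one grid.
- Expert masks tighter than the GTV contribute zero-length (clamped)
  vectors; whether the original clinical analyses clamped or excluded such
  contours is unknowable from published descriptions, and clamping was
  chosen because it preserves the panel size K in every direction.
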