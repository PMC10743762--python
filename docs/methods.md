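# Methods

## The extraction method

`voronoitrack` extracts the centerline of a tubular binary segmentation by a
divide-and-conquer reduction of the 3D medial-axis problem to 2D:

1. **Slicing.** The volume is cut into 2D slices perpendicular to each of
   the three coordinate axes.
2. **2D Voronoi skeletons.** Each slice is skeletonized independently.  The
   boundary of every 8-connected foreground component is sampled at the
   0.5 iso-level (marching squares, densified to ≤ 1 px steps) and the
   Voronoi diagram of the samples is built.  Interior Voronoi vertices of
   densely sampled boundary points converge to the medial axis, so the
   skeleton is the set of Voronoi vertices that survive the pruning rules
   below.
3. **Medial surfaces.** Per-slice skeleton points are snapped to the voxel
   lattice and stacked along their slicing direction, giving one voxelized
   medial surface per axis.  For a tube, each surface is roughly the sheet
   swept by the slice-wise centers of the cross-sections.
4. **Intersection.** The three surfaces intersect along the tube's axis.
   Four candidate centerlines are formed: XY-, YZ- and XZ-common (pairwise
   intersections) and XYZ-common (triple intersection).  Because the three
   surfaces are quantized independently, intersection uses a Chebyshev
   distance tolerance (default 1 voxel); tolerance 0 is exact set
   intersection.
5. **Ordering and resampling.** The common point set is ordered by building
   a proximity graph in mm space (edges up to `(2·tol+1)` voxel diagonals),
   bridging any remaining fragments with closest-pair edges, taking the
   minimum spanning tree and walking its longest geodesic path (double
   Dijkstra sweep).  The path is resampled to 1000 uniformly spaced points
   by piecewise-linear arc-length interpolation.

### Skeleton pruning

Voronoi skeletons of pixelated shapes are notoriously unstable: every
sub-pixel bump of the contour grows a medial spur.  Two criteria select the
stable core:

* **Separation angle** (primary, default 120°): a vertex is kept only when
  its generating boundary samples subtend a wide angle at the vertex.
  Points on the medial line of a tube cross-section see boundary contacts
  on opposite sides (≈ 180°); quantization spurs see their generators in a
  narrow cone (measured ≤ ~106° on pixelated disks).  The criterion is
  scale-free, so it behaves identically on a 7 px cap slice and a 30 px
  lumen.
* **Clearance floor** (default `prune_ratio = 0.2`): vertices whose
  clearance (distance to the nearest boundary sample) falls below
  `prune_ratio ×` the component's maximum clearance are dropped.  This is
  deliberately a coarse guard only.  A larger ratio would be harmful: in a
  slice that contains a tapering vessel near-lengthwise, the distal midline
  clearance is the local radius, and any ratio above the taper ratio
  (distal/proximal radius, ≈ 0.3 for coronary-like geometry) amputates the
  distal centerline.

Degenerate components (≤ 3 px, or fewer than 4 boundary samples) contribute
their pixel centroid, so a vessel end-cap slice still yields a point.

### Ordering choices

The common set is a noisy, roughly 1-voxel-thick curve sample.  The MST
longest-path rule drops short lateral spurs automatically (they do not
extend the tree diameter).  Fragments disconnected at the proximity radius
are joined by single-linkage bridges before the MST: every common point is
inside the lumen, so a longitudinal gap between fragments belongs to the
same tube and the shortest crossing edge stays inside it.  Restricting to
the largest component instead can silently discard half a vessel when a
single sub-millimetre gap splits the cloud.  Linear (not spline)
interpolation is used for resampling: at 0.1 mm quantization the difference
is far below the reporting precision of the metrics, and it cannot
overshoot.

## Accuracy metrics

Between an extracted centerline and a radius-annotated reference, both
resampled to n = 1000 points (reference radii interpolated alongside),
with nearest-neighbor Euclidean correspondence thresholded by the local
reference radius in both directions:

* **OV** (total overlap, %) = `(TPM + TPR) / (TPM + TPR + FN + FP)`.
  An extracted point is TPM if it lies within one local vessel radius of
  the reference; a reference point is TPR if an extracted point lies
  within its radius; FP/FN are the complements.  0/0 is reported as 0.
* **OF** (overlap until first error, %): fraction of reference points
  preceding the most proximal false negative, where false negatives within
  the first 5 mm of the reference are forgiven (`--of-skip-mm`).
* **OT** (clinically relevant overlap, %): OV restricted to the reference
  up to its most distal point with diameter > 1.5 mm (radius ≥ 0.75 mm,
  `--ot-min-radius-mm`), and to extracted points matched into that span.
  Reported as not-applicable when no reference point reaches the radius
  threshold, rather than 0, to avoid deflating averages.
* **AI** (average inside distance, mm): mean match distance over the union
  of TPM and TPR correspondences; not-applicable when there are none.  AI
  is bounded above by the mean radius of the matched reference points —
  asserted as a test invariant.

The historical framework these metrics come from does not publish its exact
correspondence algorithm; symmetric nearest-neighbor matching is this
package's stated choice, as is averaging AI over both correspondence
directions.

## Synthetic phantoms

The generator emulates single coronary-artery-like branches of four
classes, one of each per dataset:

| class  | length (mm) | radius start→end (mm) | tortuosity |
|--------|-------------|------------------------|------------|
| RCA    | 55          | 2.8 → 1.1              | 0.04       |
| LAD    | 45          | 2.4 → 0.9              | 0.04       |
| LCX    | 35          | 2.0 → 0.8              | 0.04       |
| BRANCH | 22          | 1.6 → 0.7              | 0.03       |

Lengths and radii are scaled-down but anatomically ordered (real RCA/LAD
run well past 100 mm; lumen radii of 0.5–3 mm are realistic).  Per-vessel
parameters are jittered ±10 % (tortuosity ±20 %) by an RNG stream derived
from `(master seed, dataset index, class index)`, clipped to 20–60 mm and
0.5–3 mm.

A centerline is a curve running predominantly along +x whose transverse
(y, z) components are sums of three random-phase harmonics with amplitudes
`tortuosity · length / k²`; the curve is reparametrized to uniform arc
length (0.2 mm spacing) and truncated at the target length.  Radii taper
linearly in arc length.  Tortuosity values are kept well below the
self-intersection limit — the generator verifies numerically that the
curvature radius everywhere exceeds twice the maximum tube radius and
rejects violating parameter sets.

Voxelization follows the union-of-spheres construction: coordinates and
radii are rounded to one decimal (ties away from zero), and a voxel is
foreground iff its center lies within distance `r_p` (closed inequality) of
some centerline point `p`.  Solid balls are used rather than sampled sphere
surface meshes: a surface sampling is a discretization device whose limit
is the solid-ball test, and hollow shells would change the per-slice
topology (rings instead of disks).  The bounding box covers every ball plus
a margin (default: the maximum radius) and is snapped to the voxel lattice
anchored at the world origin, so at the default 0.1 mm voxel size rounded
coordinates land exactly on voxel centers.

**What the phantoms do not emulate:** bifurcating trees (vessels are single
branches, as in the evaluation this package reproduces), CT intensity,
noise or segmentation error (the binary mask is exact by construction), and
anisotropic voxels.  Passing the benchmark therefore demonstrates the
geometric fidelity of centerline extraction from a correct segmentation; it
says nothing about robustness to segmentation error, which is upstream of
this method by design.

## The benchmark

`benchmark_specs(8, seed)` defines 8 datasets × 4 classes = 32 vessels.
For each vessel the pipeline voxelizes the rounded ground-truth centerline
at 0.1 mm, extracts the requested variants, and evaluates all four metrics
at 1000 points.  Per-class means are taken over datasets and the grand mean
over all 32 vessels; a failed extraction is reported as a row with an error
marker, never dropped.  The full XYZ run takes on the order of two minutes
on one CPU; all four variants about double that.  Timing is logged but
never part of any assertion, since it is hardware-dependent.

## Numerical conventions

* World coordinates are mm; voxel centers carry them; index order is
  `(i, j, k) ↔ (x, y, z)` with no permutation; isotropic voxels only.
* Rounding of continuous coordinates to indices is round-half-away-from-
  zero with a 1e-9 epsilon absorbing binary representation error.
* The ball test uses the closed inequality (distance ≤ r), so a voxel
  center exactly on the sphere is foreground.
* Graph tie-breaks in the ordering step (farthest-node selection) are
  resolved by node index, making extraction fully deterministic; the only
  randomness in the package is the phantom RNG, which is seed-derived.

## Known limitations

* Single-branch tubes only: the longest-path ordering deliberately
  discards side branches, so a bifurcating segmentation yields the longest
  branch path only.
* Medial surfaces from slices nearly tangent to the tube wall can produce
  isolated off-axis points; these are suppressed by the intersection step
  but individual per-axis surfaces are noisier than the common sets.
* The 2D skeleton returns points, not connected medial-axis edges; per-
  slice topology is not preserved.
* Sub-voxel accuracy is bounded by the lattice snap: AI on clean phantoms
  plateaus just below one voxel (≈ 0.08 mm at 0.1 mm voxels).
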