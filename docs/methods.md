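# Methods

This note documents the models, numerical choices and limitations behind
`tubeprint`. Units are millimetres throughout; the frame is right-handed,
the printing plate is z = 0 and the build direction is +z after orientation.

## Geometry carrier and integrity model

Triangle surfaces are `trimesh.Trimesh` objects with 0-based indices and
outward right-hand winding. *Watertight* means every edge is shared by
exactly two faces with consistent winding and there are no boundary loops.
`check_integrity` counts boundary loops (chained from directed boundary
edges), non-manifold edges (incidence > 2), degenerate faces (area <
1e−12 mm²) and intersecting non-adjacent triangle pairs (AABB spatial-hash
broad phase, Möller-style narrow phase; touching within 1e−9 mm is not
counted). Self-intersections are reported, never repaired: detection before
manufacture is what matters, and exact predicates are not required for that.

Healing removes degenerate faces, unifies winding per connected component,
and closes boundary loops of at most `max_hole_edges` (default 100) edges by
constrained Delaunay triangulation of the loop projected on its best-fit
plane (GEOS CDT via shapely). Larger holes signal a failed segmentation
rather than a patchable defect and are reported unresolved, as are
non-manifold regions. Healing is idempotent and never increases the defect
count.

Plane cuts slice the mesh and re-cap the cut cross-section with CDT; ring
nesting (outer contours vs holes, e.g. when a hollow shell is cut) is
resolved by containment depth. Cap vertices are snapped exactly onto the
plane, so cut faces lie on it to machine precision; half volumes sum to the
input volume to well under 0.1 %.

## Reconstruction

Slice stacks are modelled as scalar grids with anisotropic spacing; the
slice axis step (default 3 mm, a typical wide-area clinical compromise) is
honoured in world coordinates without resampling. Segmentation is window
thresholding plus largest 26-connected component — a deliberate stand-in
for whatever clinical tool produced the contours, adequate for binary
contrast and testable against the rasterizer's analytic inside test
(Dice > 0.95 at SNR 20). Surfaces come from marching cubes on the scalar
grid rather than contour stacking: the deliverable (a clean tessellation) is
the same and the degenerate cases are fewer. Smoothing is Taubin's
non-shrinking λ/μ scheme (0.5/−0.53; volume drift < 2 % at the default 10
iterations even on coarse anisotropic grids). Decimation is quadric
edge-collapse with link-condition and normal-flip guards, so closed inputs
stay closed; at a 0.3 face fraction the volume moves by well under 2 %.

## Centerline and segmentation

The medial axis is obtained by voxelizing the interior (per-slice even-odd
parity of section rings), topologically thinning the grid to a curve
skeleton, and walking the longest geodesic path of the skeleton graph
(double Dijkstra sweep, 26-connectivity). Topology-preserving thinning can
collapse a short tube entirely — its topology is a ball's — so the pitch is
automatically refined (×0.6, up to 3 retries) until a usable curve remains.
Default pitch: a quarter of the estimated minimal tube radius. Leaf spurs up
to about twice the local radius are thinning artifacts of lumpy organic
solids and are tolerated; anything longer raises a branching error listing
the branch points, because branched anatomy is out of scope. The path is
smoothed with a non-shrinking (Taubin-style) polyline filter — a plain
Laplacian would straighten bends and bias arc radii — then extended along
the end tangents to the end caps and resampled at the pitch. Per-point
radius is the exact distance to the surface.

Span partitioning is recursive chord bisection (Douglas–Peucker style):
split at the farthest point from the chord (ties at the lower arclength
index), recurse until every span's deviation is ≤ `max_dev`. How many
segments an organ needs is a judgement call in practice; `max_dev` is the
governing knob (default 6 mm in the pipeline config) and the span count is
an output, never a target. Splitting planes are orthogonal to the local
tangent at span junctions; a plane that intersects the tube twice (hairpin)
produces a disconnected piece and is reported with the advice to reduce
`max_dev`.

## Build planning

The plane scan covers φ ∈ [0°, 180°) in `angle_step` increments (library
default 2°, pipeline default 4°) with golden-section refinement around the
best grid angle when its support volume is nonzero. Candidates are ranked
lexicographically: (1) total support volume of both halves placed
cut-face-down, (2) projected envelope area on the plane, maximized, (3)
build height, minimized. Lexicographic ordering avoids inventing weights
between objectives that practice treats as a priority list. Tie tolerances
(2·10⁻³ relative on area, 10⁻³ on height) absorb mesh-faceting and
rasterization noise so a rotationally symmetric segment ties everywhere and
the lowest angle wins deterministically.

Support volume is a column model: on an xy grid (default 0.5 mm, 1–1.5 mm
during optimization) every cell under a flagged overhang face contributes
cell_area × (gap down to the plate or the first surface below), with
surfaces found by sorting all face crossings per cell. A face is an
overhang iff its outward normal points downward and the angle between the
normal and straight-down is less than 90° − critical_angle; the critical
angle defaults to 45°, the de-facto FFF rule (the source workflow never
states one). Faces on the plate are excluded. The model is oracle-tested
against a 0.1 mm dense voxel brute force (≤ 5 % disagreement).

The projected envelope area is evaluated on the *uncut* segment, silhouette
by rasterization at 0.25 mm pixel centres (robust on organic meshes; ≤ 1 %
from a 0.05 mm reference). The open question of whether the criterion should
instead be evaluated per half is noted; on through-axis planes of tubular
segments the two readings agree to first order because both halves project
onto the same plane.

Closing pins are exact CSG on the planar cut face: the cap is retriangulated
with circular openings (32-gon), cylinder barrels and far disks are
appended — no voxel round-trip, so the volume delta is the polygonal
cylinder volume to well under 5 %. Pin defaults (radius 2 mm, height 4 mm,
clearance 0.1 mm, two pins at 25 %/75 % of the cap's principal axis) are
engineering choices, validated by a margin check of one pin radius against
the true cap polygon. Thin-walled variants (the "opened" segment for inner
inspection) offset vertices inward along angle-weighted normals; flipped or
collapsed faces raise an error listing the offending regions. The offset is
vertex-based, so wall thickness is accurate where mesh resolution is much
finer than the local curvature radius — measured by surface sampling against
the inner shell (median within 10 % of nominal at 1 mm). A single isotropic
`shrinkage_scale` hook (default 1.0) exists for material compensation; no
thermal physics is modelled.

## Slicing simulation

Mid-layer sampling: the first layer (default 0.30 mm) is sampled at its
centre, then layers of `layer_height` (0.15 mm `ds1`, 0.16 mm `ds2`)
follow; layer counts differ by one from bottom-plane-sampling slicers.
Staircase cusp per face is `layer_height · |cos θ|` against the build
direction, area-weighted for the summary. Perimeters are inward offsets at
w/2, 3w/2, … (extrusion width default 0.4 mm, the common desktop nozzle
class); regions thinner than the requested loops simply get fewer, logged.
Honeycomb infill is the unique wall-segment set of a hexagon tiling with
side a = 2w/(√3·density), clipped to the innermost offset — wall length per
area of that tiling is 2/(√3 a), which makes the covered-area fraction equal
the density (verified at 15 % ± 2 points by buffered-path coverage). The
cell size follows from density and width because no canonical cell size
exists. Density 0 → no infill; 1 → solid raster. No G-code or machine
control is produced.

## Deviation analysis

Curvature filtering is curvature-aware decimation: the surface-variation
proxy λ₀/(λ₀+λ₁+λ₂) of the k-NN covariance ranks points; the retained
budget (default keep_fraction 0.19, the before/after ratio typical of scan
post-filtering) is split half/half between top-variation points (only those
clearly above the cloud's typical level — twice the median) and a
grid-stratified uniform quota for coverage. On a featureless cloud the
whole budget is stratified, keeping retention spatially uniform.

Alignment is trimmed point-to-plane ICP: exact closest points on the
reference (KD-tree over subdivided-triangle centroids plus exact
point–triangle distances — equal to the all-triangle minimum), per-iteration
trimming to the best 90 % (multi-view scans imply incomplete overlap), a
linearized 6-DoF solve, and step halving whenever a step would raise the
trimmed RMS — making the residual provably monotone. Convergence: RMS
improvement < 1e−5 mm or 100 iterations. Note that trimming places the
converged RMS below the injected noise σ (≈ 0.79 σ at 90 % for Gaussian
residuals).

Signed distances use angle-weighted pseudo-normals at the nearest feature
(face, edge or vertex), the standard robust sign construction; positive =
outside the reference, configurable. Reports use linear-interpolation
percentiles (numpy default), a symmetric band fraction (default ±1 mm), an
optional asymmetric band, and a class histogram at ±0.1/±0.25/±0.5/±1.0 mm
for color mapping. Whether filtering precedes alignment is configurable; the
default order is filter → align (cheaper, and the filter is
pose-independent).

## Synthetic fixtures

The colon-like fixture sweeps modulated cross sections along a cubic-spline
axis with parallel-transport frames:
r(s,θ) = r₀(s)·(1 + a·sin(k_s s)·(1 + b·cos 3θ)). The three angular lobes
approximate taeniae-bounded haustra; parameters are documentation, not
anatomy claims. Defaults (base radius 16 mm, taper 15 %, fold amplitude
0.12, 9 fold cycles, ~357 mm length) size the fixture like real printed
parts so plate constraints are exercised. Specs whose bends are tighter than
the local tube radius are rejected with the violating arclength. Scan
simulation samples the surface area-uniformly, displaces along normals by an
offset field (emulating print shape error), adds Gaussian noise at the
0.04 mm scanner-accuracy class, and applies a rigid transform; all ground
truth is returned. Every generator is seeded and bit-reproducible.

What the fixtures do **not** emulate: imaging physics (partial volume,
modality artifacts), real segmentation ambiguity, scan occlusion and
view-stitching residuals, material shrinkage. Passing tests therefore
demonstrate the correctness of the geometry pipeline under known ground
truth, not clinical accuracy of any particular replica.

## Problem sizes and determinism

Tests and the acceptance script run on reduced fixtures chosen as the
package's own default study sizes: colon fixtures of 120–220 rings × 32–48
sectors, scans of 5·10³–5·10⁴ points, support grids of 0.25–1.5 mm,
optimizer steps of 2–12°. All randomness flows through explicit seeds;
reports are written with sorted keys and fixed float precision, so reruns
are byte-identical.

## Known limitations

- Branched (non-path) anatomy is rejected, not handled.
- The inward offset is vertex-normal based; very thick walls relative to
  local curvature are rejected rather than resolved.
- Boolean operations are limited to plane cuts and the planar-cap pin CSG;
  no general CSG.
- `extract_centerline` assumes genus-0 tubular solids; the skeleton of a
  highly folded tube at too coarse a pitch may shortcut folds (mitigated by
  the adaptive pitch retry).
- DICOM ingestion is deliberately minimal (slice stack + sidecar, NRRD via
  SimpleITK when available); modality-specific reconstruction is out of
  scope.
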