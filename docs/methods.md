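# Methods

## The model

The hippocampus is archicortex: a single folded, curled sheet of grey
matter (GM), 0.5–2 mm thick, with intrinsic anatomical axes — anterior–
posterior (AP, long axis), proximal–distal (PD, from the subiculum border
with medial temporal lobe cortex toward the dentate gyrus) and inner–outer
(IO, laminar depth from the SRLM to the outer boundary).  `unfoldcoords`
assigns every GM voxel a coordinate triplet (AP, PD, IO) ∈ [0,1]³ by
solving Laplace's equation over the GM voxel domain three times, each with
Dirichlet endpoints on a different pair of boundary tissues:

| axis | source (0) | sink (1) |
|------|-----------|----------|
| AP   | HATA      | indusium griseum |
| PD   | MTLc      | DG granule cell layer |
| IO   | SRLM (and cysts) | pial / background |

Harmonic fields are smooth, monotone between their endpoints, and free of
local extrema (discrete maximum principle), which makes the triplet a
well-behaved intrinsic parametrization of the sheet regardless of how it is
folded in any particular subject.

### Discretization

The solver uses a face-neighbour (6-connected) stencil by default, with
no-flux (Neumann) behaviour at domain borders that carry no boundary label:
a domain voxel relaxes to the weighted mean of its in-domain and Dirichlet
neighbours only.  Dirichlet values live on the boundary *label voxels*; the
value is attributed to the shared face, half a voxel from the domain voxel
center, so Dirichlet neighbours enter the average with weight 2.  Under
this finite-volume convention a 1-D slab of n voxels relaxes to exactly
(i + 0.5)/n at voxel centers.  Relaxation is red–black successive
over-relaxation (ω = 1.8, tolerance 1e−5 on the max update, cap 10,000
iterations), initialized from the normalized geodesic-distance field
d_src/(d_src + d_snk) computed by breadth-first propagation inside the
domain; the converged field is initialization-independent to solver
tolerance.  Voxels unreachable from both endpoints are set to 0.5 with a
warning rather than failing the whole solve.

### Equivolumetric depth

By default the IO Laplace field is replaced by an equivolumetric depth:
where the sheet bends, equal-spacing laminae over- or under-represent
volume on the concave/convex side, so the laminar coordinate is remapped to
preserve volume fractions.  With local inner and outer surface areas A_in
and A_out and a cross-section that interpolates linearly between them, the
depth holding volume fraction α is

    ρ(α) = (−A_in + √(α·A_out² + (1−α)·A_in²)) / (A_out − A_in),

with ρ = α in the flat limit A_in = A_out (taken analytically when
|A_out − A_in| < 1e−9·A_in).  The transform is a monotone bijection of
[0,1] for any positive areas.  Per-column areas are estimated by mapping a
coarse 64×32 unfolded grid to native space near the inner (IO = 0.05) and
outer (IO = 0.95) faces through the scattered interpolant and differencing;
voxels look their areas up bilinearly at their own (AP, PD).  The raw
Laplace IO field is available with `io_mode="laplace"`.

## Warps

The unit coordinate cube is scaled to a standard unfolded prism —
256×128×16 voxels (AP, PD, IO) at 0.15625 mm isotropic (40×20×2.5 mm) for
the hippocampus, 256×32×16 for the dentate gyrus — so unfolded space is an
ordinary image grid.  The forward (native→unfolded) displacement field is
read directly off the coordinate fields at GM voxels; outside GM it is
filled with the nearest GM value and the filled region smoothed with a
1-voxel Gaussian (dense fields are required by standard resampling tools;
values outside GM are extrapolation, not anatomy).  The backward
(unfolded→native) field treats GM voxels as scattered samples — position =
scaled unfolded coordinate, value = native world coordinate — and evaluates
Delaunay piecewise-linear interpolation on the unfolded grid, with
nearest-sample fill outside the convex hull.  Sites enter the triangulation
in voxel-index order, making the construction deterministic.  Both fields
serialize as 5-D displacement NIfTIs (X,Y,Z,1,3) carrying the
displacement-vector intent code; ITK-family readers negate the x/y
components of such fields on load, so the file stores NIfTI-convention RAS
mm and ITK tools see correct LPS physical vectors (verified against
SimpleITK in the test suite).

On the default phantom the unfolded→native→unfolded round trip has a
95th-percentile error of ≈0.25 unfolded voxels over interior points
(IO ∈ [0.2, 0.8]); the bound asserted in tests is 1 voxel.

## Surfaces

Unfolded tessellations are uniform grids over the AP×PD rectangle: the
legacy `unfoldiso` densities are 254×126 (32,004 vertices, hippocampus) and
254×30 (7,620, DG), used as-is.  Spacing presets (0.5/1/2 mm average native
vertex spacing) start from a 512×256 grid (512×64 for the DG) and greedily
collapse the globally shortest edge — measured after mapping vertices to
native space through the backward warp — until the median native edge
length reaches the target (tracked incrementally as the count of edges
below target, so the stop is exact and O(1) per collapse).  The surviving
endpoint is chosen corner > boundary > lower index, so boundary vertices
are removed only in favour of other boundary vertices and the four
rectangle corners are pinned; collapses are rejected if they would violate
the link condition (pinch the sheet) or collapse an interior chord between
two boundary vertices.  "Vertex spacing" is interpreted as median native
edge length, a robust statistic; achieved median spacing on the phantom
matches the target to well within 1%.  Vertex counts at spacing presets depend on the
subject's geometry and are not fixed constants.  Each density is
instantiated at IO = 0 / 0.5 / 1 and carried through the backward warp to
give inner, midthickness and outer native surfaces sharing one triangle
array, so vertex correspondence across layers (and across subjects at the
same density) is positional.  Quads split along the (+AP,+PD) diagonal,
fixed and deterministic.

## Dentate gyrus

The DG breaks from the cortical mantle during development and wraps around
CA4, so its PD and IO axes are swapped relative to the rest of the
hippocampus, and it is frequently thinner than one voxel — Laplace fields
cannot be solved on it reliably.  Its coordinate fields are instead carried
in from the template: the template phantom stores analytic DG fields, and
after registration they are resampled (linear) into subject space and
masked to subject DG voxels.  A geodesic fallback (`dg_fallback` logic is
intentionally not a default) is avoided; without injection DG surfaces are
simply skipped.  DG surfaces are built over the narrow 256×32-aspect
unfolded domain; thickness is never computed for the DG (its "depth" axis
is a wrap, not a laminar depth) and requesting it raises.

## Template shape injection

A smooth template labelmap is registered to the subject labelmap and its
labels replace the subject segmentation for unfolding, regularizing
segmentation faults (holes, islands).  Registration is purely label-driven:
each tissue class is binarized, Gaussian-smoothed (σ = 0.6 mm, the scale of
the thinnest tissues — SRLM and DG granule layer), and stacked as channels;
the cost is the summed per-channel MSE, minimized when identical labels
overlap.  The optimizer is a 3-level (÷4, ÷2, ÷1) demons-style flow: the
per-voxel multi-channel demons force is smoothed with a 1.5-voxel Gaussian
("fluid"), scaled by a backtracking step size that guarantees a
non-increasing cost trace within each level, added to the total field, and
the total lightly smoothed (0.2 voxel, "diffusion"); 150 iterations per
level with early stopping when relative improvement stalls below 1e−6.
These parameters were fixed against two synthetic properties: recovery of a
known 2-voxel sinusoidal deformation of nested spheres to per-label
Dice ≥ 0.95, and near-zero displacement (< 0.1 voxel) for identical inputs.
The recovered deformation keeps a positive Jacobian determinant on ≥ 99.9%
of tissue voxels.  Registration runs on the bounding box of the union of
nonzero labels plus an 8-voxel margin.  Injection is idempotent only up to
the residual of one registration plus one nearest-neighbour resampling:
bulky labels (GM) barely move on re-injection, but laminae ~2 voxels thin
can shift by a boundary voxel, which alone costs substantial Dice on such
structures.

## The phantom

The synthetic generator emulates the step the real pipeline consumes: a
tissue labelmap in the cropped oblique space (128×256×128 voxels at 0.3 mm
isotropic).  The GM sheet is a parametric surface X(u,v,w): a circular-arc
cross-section of arc length W (curled by `curl_turns`), extruded over
length L along AP, offset ±T/2 along the cross-section normal, and rippled
by sinusoidal digitations d(u) = A·sin(2π·n·u) along AP.  The map has a
closed-form inverse, so voxels are labelled by mapping their centers to
(u,v,w) and testing ranges — the recorded per-voxel ground truth is exact,
and rasterized GM volume matches the analytic volume (T·L·W for whole
digitation periods, by the Jacobian |det J| = T·L·(W − s·θ)) to within
voxelization error.  Boundary tissues are attached by parameter range:
SRLM beyond the concave face, pial beyond the convex face, HATA/IndGris
caps past the AP ends, an MTLc strip past PD = 0, and a dentate flap — a
tighter arc of radius 1.5 mm wrapping 4 rad around the distal edge,
0.6 mm thick, following the digitations — carrying the DG granule label
and, in the template, analytic DG coordinates.  Optional cyst ellipsoids
carve the GM interior (the only stochastic element; seeded).

Defaults — L = 40 mm, W = 20 mm, T = 1.2 mm, 0.75 curl turns, three 1-mm
digitations — give a sheet whose unfolding is non-trivial (global
gyrification ≈ 1.05, every tissue ≥ 2 voxels thick) while matching the
anatomical scale of a human hippocampus.  The phantom reproduces the
*topology* and scale of hippocampal anatomy, not its shape: real
digitations are irregular, tissue contrast boundaries are noisy, and
segmentations contain errors none of which the phantom models (except via
explicit hole-punching in tests).  Passing phantom tests therefore
validates the geometry engine, not segmentation robustness on real MRI.

## Subfields

A single 2-D label image over the unfolded (AP, PD) plane defines subfield
boundaries for all subjects; lookup is nearest-pixel with hard boundaries.
The bundled schematic atlas is five PD-parallel bands (Sub 25%, CA1 30%,
CA2 10%, CA3 20%, CA4 15% — loose proportions of the subfield layout, a
synthetic stand-in; any labelled unfolded image drops in).  Volumetric
subfields assign each GM voxel the atlas label at its own (AP, PD); voxels
with undefined coordinates fall back to the nearest labelled coordinate
(counted and logged).  Topology checks verify one connected component per
label, full AP extent, and adjacency only between PD-consecutive bands.

## Morphometry

* **Thickness** — Euclidean distance between corresponding inner and outer
  vertices (mm); the layers share vertex indices by construction.
* **Curvature** — discrete mean curvature from the cotangent Laplacian,
  H = |Σ (cot α + cot β)(v_i − v_j)| / (4·A_i) with barycentric vertex
  areas, signed positive toward the outward normal, computed on the
  midthickness surface after neighbourhood-averaging smoothing
  (v ← 0.4·v + 0.6·mean(neighbours), 100 iterations).  Boundary vertices of
  the open sheet report NaN (incomplete one-ring).
* **Vertex area** — the plain average of incident triangle areas (mm²),
  rather than the more common barycentric third-share; on matched
  triangulations the gyrification ratio is insensitive to the convention.
* **Gyrification** — native vertex area / unfolded vertex area
  (dimensionless; > 1 on folds).  Vertices whose unfolded area degenerates
  to zero after decimation report NaN with a warning.
* **Sampling** — trilinear interpolation of a co-registered volume at
  native vertex positions; out-of-volume vertices are NaN and counted.

## QC

GM segmentation quality is summarized by Dice overlap with a user-supplied
reference mask (when injection runs, the injected template GM serves as the
default reference); a subject is flagged when Dice is *strictly* below the
threshold (default 0.7 — a measured Dice of exactly 0.70 passes).  The QC
report (JSON + HTML) lists the Dice and flag, coordinate field ranges,
vertex counts per density, thickness summaries, and per-stage runtimes.

## Numerical and design choices

* Label integers are a package convention (GM=1, SRLM=2, cyst=3,
  DGgranule=4, MTLc=5, pial=6, HATA=7, IndGris=8), overridable by a JSON
  label-scheme file; the class *inventory* is fixed by anatomy.
* Cyst voxels are excluded from the GM solution domain and join the SRLM in
  the IO inner-boundary set — they are internal non-GM tissue and must not
  become holes; a flag restricts the inner set to SRLM only.
* The IO outer boundary defaults to pial ∪ background ("union"); a
  pial-only mode exists because segmentations differ in whether they close
  the outer boundary.
* Left hippocampi are flipped sagittally (index reversal on axis 0 plus
  affine update mirroring world x) before processing, so one coordinate
  convention serves both hemispheres; the flip is an exact involution.
* The unfolded prism origin is (0,0,0) mm in its own space with a diagonal
  0.15625 mm affine — a documented private convention.
* Degenerate triangles are skipped (with a warning) in curvature;
  isolated vertices get zero area with a warning.

## Problem sizes used in tests

The default test and acceptance workloads run the full-resolution phantom
(128×256×128 at 0.3 mm, ≈36k GM voxels), solve all three fields to 1e−5,
build both warps, the 32,004-vertex unfoldiso surfaces and one
spacing-decimated preset, and run injection on the cropped label bounding
box; registration-recovery checks use 48³ nested-sphere volumes.  These
sizes keep a full suite run in a few minutes on one CPU while exercising
every code path at the production grid resolution.

## Known limitations

* Harmonic PD coordinates are not arc-length; metric distortion within the
  sheet is absorbed by the gyrification metric, not removed.
* Dense warps are only anatomically meaningful on GM; outside it they are
  smooth extrapolation and carry no diffeomorphic guarantee.
* The decimation statistic and algorithm are a documented reinterpretation
  ("median native edge length" + greedy half-edge collapse); other
  toolchains will produce different (equally valid) vertex counts.
* The schematic atlas is a synthetic stand-in; scientific use requires a
  histology-derived unfolded atlas.
* No segmentation is performed: the engine starts from a tissue labelmap.
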