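# Methods

## Volumetric representation

A shape is a binary occupancy lattice (1 = object, 0 = background) with
isotropic spacing and a recorded origin, so lattice↔world maps are
exact: world(i, j, k) = origin + (i, j, k)·spacing. All distances are in
world units. An object voxel is a *boundary* voxel when at least one of
its 26 lattice neighbours is background; a one-voxel background margin
is enforced on every face so the 26-neighbourhood test never leaves the
grid.

Meshes are rasterized by ray parity: for every (j, k) lattice column a
ray is cast along x, crossings with the closed surface are located by 2D
barycentric tests in the (y, z) projection, and lattice centres between
odd/even crossings are marked inside. Ray origins are nudged by a
sub-voxel epsilon so rays never pass exactly through triangle edges.
The bounding box is fitted *compactly*: one isotropic scale chosen so
the longest axis spans dims − 3 lattice steps, centred, leaving at
least a one-voxel margin — anisotropic scaling would distort the
distance field, which is the object of study. A consequence used by the
tests: translating the input by integer multiples of the final spacing
reproduces the occupancy bit-for-bit.

PDB input is treated as a union of van der Waals spheres (per-element
radii, configurable table, carbon-like 1.7 Å fallback). This replaces
rolling-probe (solvent-excluded) surface generation, which is out of
scope; for shapes at the 64³ resolutions used here the difference is
sub-voxel except in narrow clefts.

## Landmarks

n = 500 landmarks by default. Lloyd's k-means (k-means++ init, max 300
iterations, tolerance 1e-4, seeded) runs on the boundary world
coordinates; each centroid is snapped to the nearest not-yet-used
boundary voxel, ties broken by lexicographic lattice index, because the
inner-distance step needs on-surface endpoints. When n equals the
boundary size the whole boundary is returned in deterministic order.
Random sampling without replacement is kept as the baseline; a property
test asserts Lloyd's nearest-neighbour spacing varies less.

## Inner distances

The inner distance d_I is the graph metric of the 26-adjacency graph
over *all* object voxels (interior included — this is what
distinguishes it from a surface geodesic), edge weights
spacing·{1, √2, √3}. One single-source Dijkstra per landmark gives the
exact metric; a vectorised Floyd–Warshall implemented independently in
the test-suite (and in the acceptance script) confirms exactness on
random solids. Landmarks in different connected components are a hard
error carrying the component partition: the downstream Gaussian kernel
cannot represent infinite distances, and silently dropping them would
bias the descriptor.

Two numerical facts the tests pin down: d_I ≥ d_E always (an interior
path cannot beat the straight line), and on a convex voxel ball
d_I/d_E ≤ ~1.13 — the 26-connected lattice metric overestimates
Euclidean length by at most ≈ 7.8% in the continuum limit, plus a
few-voxel discretisation slack at short range.

## Diffusion distances

From the landmark inner distances: k(x, y) = exp(−d_I²/σ²) with σ equal
to the mean pairwise inner distance ("auto") unless overridden;
v(x) = Σ_y k(x, y); single-step chain p = k/v; symmetric conjugate
p̃ = k/√(v v′) = D^{1/2} P D^{−1/2}. The full symmetric
eigendecomposition is kept (n = 500 is cheap; truncation would be an
unstated approximation). Eigenpairs are sorted by descending |λ|;
each eigenvector's sign is fixed so its largest-magnitude component is
positive — distances are sign-invariant, but serialized embeddings
stay reproducible. Diffusion-map coordinates are λᵢ^m φᵢ(x) and the
diffusion distance is the Euclidean distance between coordinate rows.

The operational definition is the spectral identity: the embedded
distances must equal the distance between m-step transition profiles,
d_m²(x, y) = Σ_z |p̃⁽ᵐ⁾(x, z) − p̃⁽ᵐ⁾(y, z)|² with p̃⁽ᵐ⁾ computed by
literal m-fold matrix multiplication. The test-suite enforces agreement
to < 1e-8 over random kernels with n ∈ {5, 20, 50}, m ∈ {1, 5, 50};
that identity — not any printed exponent convention — defines which
power of the spectrum enters the coordinates. The profile sum over z is
unweighted (no 1/v(z) stationary measure, as some diffusion-maps
variants use).

Defaults m = 50, σ = auto. A property worth knowing when interpreting
descriptors: with σ at the mean inner distance the kernel is wide and
the chain mixes fast — |λ₂|⁵⁰ is ≲ 1e-8 on every fixture here — so at
m = 50 the embedding is dominated by the stationary component
φ₁ ∝ √v, and the descriptor is effectively a histogram of intrinsic
centrality differences. This is precisely what makes it robust to
contact events (a point contact barely changes the global density
profile) and also what bounds its discriminative power relative to the
full inner-distance distribution (see Limitations).

Joint scaling of all distances and σ by c > 0 leaves the kernel, hence
d_m, unchanged; d_m is an exact metric (it is Euclidean in embedding
space); both are asserted.

## Descriptor

All n(n−1)/2 unordered pairwise values are min–max rescaled to [0, 1]
and counted into 128 equal-width bins, half-open [l, r) except the last
bin closed so 1.0 is counted exactly once; counts are divided by the
number of values so frequencies sum to 1 and descriptors with different
n remain comparable. If max = min (possible at n = 2) all mass goes to
bin 0: any placement is information-free there and a defined answer
beats an exception. Comparison operates directly on bin vectors
(L1, L2, χ² over bins with a + b > 0, Bhattacharyya 1 − Σ√(ab)); a
piecewise-linear view of the histogram is provided for plotting only —
with equal bin counts it adds nothing to the metrics.

### Pose canonicalization

Landmark sampling is seeded on data order, so two 90°-rotated copies of
one grid would be sampled differently and produce histograms differing
by resampling noise. The pipeline therefore first maps a cubic grid to
its canonical representative under the 24 proper lattice rotations (the
image whose flattened bit-string is lexicographically smallest). This
makes the descriptor *bit-identical* under lattice rotations of the
input; off-lattice rotations still change the rasterization itself, and
on the voxelized unit-sphere fixture an arbitrary rotation moves the
descriptor by L1 < 0.25 (resampling noise; documented bound asserted in
the tests). Non-cubic grids skip canonicalization.

## Retrieval evaluation

Every shape queries the database in turn; the query is excluded from
both the ranked database and its own relevant set, so perfect retrieval
scores exactly 1. At retrieval size s, precision = TP/s and
recall = TP/(group − 1); ranking ties break lexicographically by id.
Per-query precision is interpolated at fixed recall levels and averaged
into the PR curve. E-measure follows the first-64-retrieved convention
(capped at the database size); F-measure defaults to retrieval size
group − 1, so a perfect query scores 1. Degenerate precision = recall
= 0 cases are defined as 0. Note that on a database smaller than 64 the
E window spans the whole database, every relevant item is always inside
it, and E becomes ranking-independent — it is reported for completeness
but carries no signal at the bundled benchmark's size.

## Synthetic shapes

The generators produce voxel solids directly from unions of capsules
(deterministic, no meshing), each exposing one articulation parameter
and two *probe* points flanking the forming contact:

* `bent_tube(length=36, thickness=6.5, bend_angle, bow=5, asymmetry=0)`
  — a tube folding at its mid joint. Arms bow outward by `bow` voxels
  at the elbow so that, when folded, the tips approach while mid-arms
  stay apart: the contact is a localized touch, not a progressive
  hinge merge. `asymmetry` shifts the joint so the long arm's tip meets
  the short arm's side, leaving a free tail.
* `clamp(base, prong, thickness, lobe_radius, closing_angle)` — two fat
  lobes on thin prongs above a base bar; closing tilts the prongs until
  the lobes touch and the U becomes a ring. The strongly bimodal mass
  distribution mimics a two-domain protein on a light hinge.
* `tripod(arm_length, thickness, sweep_angle, lobe_radius)` — three
  arms from a hub, one sweeping toward a fixed one with the middle arm
  co-rotating at a third of the rate (scissor motion); optional tip
  lobes give a three-domain trefoil.

`make_series` applies a parameter grid and labels `contact_index` as
the first conformer whose probe-pair inner distance drops by more than
25% relative to its predecessor — a fixture-labeling convention, not a
scientific claim. The bundled benchmark is 3 families × 6 conformers at
64³ (geometry scaled to fill the grid), each family crossing exactly one
just-past-touching contact event at its final conformer.

What the generators emulate: hinge-type conformational series with
large extrinsic deformation and discrete self-contact topology changes,
at realistic grid resolution. What they do not: real molecular surface
texture (pockets, tunnels, rugosity), mass heterogeneity beyond simple
lobes, non-hinge (shear/twist) motions, and database scale (18 shapes
vs thousands). Passing the retrieval tests here shows the machinery
ranks correctly under controlled conditions; it does not predict
absolute retrieval rates on real conformer databases.

### Topology-robustness measurement

Across a contact event two quantities are compared on the tube and
clamp series (n = 300 landmarks at 48³):

* descriptor level — the maximum pairwise L1 between diffusion
  histograms over the *whole* series stays below the L1 between
  inner-distance histograms across the single contact step;
* distance level — probe-tip distances are measured on the min–max
  normalized scale the histograms are built on, averaged over the
  10 landmarks nearest each probe (at m = 50 the raw tip-pair diffusion
  distance sits at the bottom of its range, where self-relative changes
  are sampling noise; the range-normalized change is stable across
  seeds). The inner-distance change is ~0.75–0.85 of the range; the
  diffusion change ~0.02–0.06.

## Numerical and design notes

* Binary-heap Dijkstra (scipy) rather than a Fibonacci heap: the
  contract is exact shortest paths; the queue discipline is a
  constant-factor concern.
* Eigen-solver: dense symmetric `eigh`; failure to converge raises.
* Descriptor determinism: the full pipeline with a fixed seed is
  reproducible bit-for-bit (asserted).
* Disconnected shapes: generators raise; the pipeline raises with the
  sample partition. An option to keep the largest component was
  considered and rejected — silently altering the shape under study is
  worse than failing loudly.
* The voxel text format stores one (i, j) row of '0'/'1' per line plus
  a JSON sidecar (dims, spacing, origin); descriptors are plain JSON.

## Limitations

* At the default m = 50 and σ = auto, the diffusion descriptor reduces
  to an intrinsic-centrality histogram (see above). On the bundled
  benchmark this makes it *more* stable across contact events than the
  inner-distance descriptor (the acceptance measurements show a
  2–3× smaller series drift) but *less* discriminative between the
  small number of families: nearest-neighbour accuracy and F-measure on
  the 18-shape benchmark come out slightly below the inner-distance
  descriptor (≈ 0.78–0.83 vs 0.89 NN; ≈ 0.60 vs 0.73 F across seeds),
  with both well above the Euclidean baseline. Resolving descriptor
  differences of a few percent, as between diffusion- and
  inner-distance methods on real conformer databases, requires database
  scales far beyond a desk-sized synthetic benchmark.
* Retrieval indexing for large databases (beyond linear scan) is out of
  scope, as are solvent-excluded surfaces, multi-resolution grids and
  curvature-adaptive sampling.
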