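# Methods

## Scope and approach

`alveo4d` analyses 4D (t, channel, z, y, x) fluorescence movies of living
lung slices during alveologenesis. Real acquisitions of this kind run to
terabytes and are not redistributable, so the package pairs every analysis
stage with a synthetic scene generator that plants the same cellular
dynamics with exact ground truth. All quantitative claims made by the test
suite are therefore recovery statements: the pipeline recovers what the
generator planted, under controlled noise. What that does and does not say
about real data is discussed under Limitations.

## The synthetic scene generator

A scene is a field of configurable physical size (default desk scale,
96 × 96 × 48 μm at 1 μm isotropic voxels; the instrument-scale 0.45 μm z
step is supported but not default) containing four channels: epithelial
membrane, mesenchymal membrane, nuclei, and endothelial tubes.

**Mesenchymal rings.** `n_rings` closed rings are placed with
non-overlapping centres and near-in-plane normals. Each ring holds an
integer member count drawn uniformly from `cells_per_ring` (default 3–5).
Ring diameter follows d(t) = max(d₀ − c·t, d_min) with contraction rate
c = 0.1 μm/h by default. Live imaging shows the contraction is subtle but
does not quantify a rate, so this default is a placeholder, exposed in the
config and flagged here. Member cells are rendered as overlapping arcs
wrapping the ring circle (half-thickness 2.5 μm); the slight angular
overlap (8%) keeps the rendered loop closed for any member count, which a
straight-ellipsoid rendering cannot do at m = 3.

**Epithelial cells.** Exactly `round(f·n_epithelial)` cells are flagged as
flattening (default f = 0.24, the P14 fraction; ~1/4 at P5). Flattening
cells start clustered just under their assigned ring and extrude along the
ring-plane normal by a distance drawn uniformly from 60–100 μm over the
flattening window. Onsets are asynchronous — uniform over the first half of
the movie — but cells sharing a ring share its event onset with a ±3 h
stagger, since adjoined alveoli form concurrently through one ring. All
cells carry a small Brownian positional jitter.

**Shape schedule.** A flattening cell's ellipsoid interpolates from aspect
(1, 1, 1) to (3, 3, 0.25), semi-axes rescaled every frame so volume is
conserved exactly. Wadell sphericity depends only on aspect; the flat
state's value is Ψ_flat ≈ 0.373. The aspect path is parameterised so that
Ψ(t) declines *linearly* from 1 to Ψ_flat over the flattening duration τ
(default 42 h), matching the steady single-cell decline seen in imaging;
the parameterisation is inverted numerically from a 257-point table of the
closed-form spheroid area. The short axis is oriented along the extrusion
direction.

**Perturbation modes.** `motility_mode` selects the study condition:
`control` as above; `wnt_activated` — fast oscillatory movement (amplitude
4–8 μm, period 3–6 h) with no completed flattening, giving higher speed and
lower processivity than control; `wnt_inhibited` — near-zero movement and no
flattening; `mlck_inhibited` — control behaviour until a switch time
(default 4 h), after which ring contraction and all cell movement arrest.

**Acquisition artifacts.** Degradation applies, in order: a shear of each z
plane along x by tan(θ)·z (the oblique-scan geometry), then a per-frame
random-walk translation (`drift_sd` voxels/frame), with the exact applied
parameters returned for round-trip validation. Noise is Poisson on scaled
intensity followed by additive Gaussian, the standard fluorescence model,
both off by default. Everything is bit-reproducible for a fixed seed; frame
noise uses a per-(seed, frame) generator.

**Boundary clouds.** `alveolus_cloud` emulates the inner boundary of one
alveolus as a sphere with a densely sampled equatorial belt (points evenly
spaced with jitter, as extraction from pixel data yields) plus a sparse
shell. Control clouds expand r₀ → r₁ linearly; Wnt-perturbed clouds do not
expand.

## Preprocessing

De-skew applies the inverse shear by affine resampling; drift is estimated
by phase cross-correlation between *consecutive* frames (robust to slow
content change over days, unlike all-to-first registration) and the pairwise
estimates are accumulated into a cumulative trace; correction translates
each frame by the negated trace. All resampling is linear (order 1):
nearest-neighbour aliases the thin membrane shells, higher orders ring at
sharp edges. Out-of-field voxels are zero-filled. Sub-voxel correction is
the default; integer rounding is available. On noise-free phantoms the
shear round trip stays below 2% of dynamic range and planted drift is
recovered to ≲0.1 voxel at upsample 20.

## Segmentation and surfaces

Local thresholding marks a voxel foreground when it exceeds the mean over a
2D window in its own z plane plus an offset (default 0; the window default
is one third of the x extent, forced odd — the light sheet's Gaussian
profile varies intensity on that scale). A numerical guard (10⁻⁹ of the
dynamic range) prevents separable-filter rounding from marking exactly flat
background. Watershed splits the mask on the negated Euclidean distance
transform, seeded at h-maxima (depth 2 voxels), 26-connected; components
that yield no seed keep their own labels, so the union of labels always
equals the mask.

Surfaces are marching-cubes iso-surfaces of the label indicator at level
0.5. The indicator is Gaussian-smoothed (σ = 1 voxel) first: a binary
iso-surface's staircase facets overestimate a sphere's area by ~9%, while
the smoothed surface is within 0.5% of 4πr² and 1% of the analytic volume
at r = 10 μm, 0.5 μm voxels (the smoothing trades a small curvature-driven
volume shrinkage, ~2.5% on a 10:10:2.5 μm oblate, for that accuracy).
Enclosed volume is the signed tetrahedron sum, area the triangle sum, and
meshes are checked watertight.

## Sphericity and flattening events

Wadell sphericity Ψ = π¹ᐟ³(6V)²ᐟ³/A (1 for a sphere, scale-invariant). The
event detector median-smooths a per-cell Ψ trace (window 3) and reports an
event when the trace leaves its round plateau, crossing below `hi` (0.85)
and later below `lo` (0.6) in a sustained decline; cells already below `hi`
at movie start are pre-flattened and report nothing, and rising-Ψ events
are deliberately not detected (flat cells are never observed to round up).

The reported **duration is the full-transition time**, not the hi→lo
crossing interval: the drop between the pre- and post-transition plateau
levels divided by the decline slope fitted on the interior 80% of the
decline. For a linear decline this is exact, and it is insensitive to the
threshold choice — the thresholds gate *whether* an event exists, the
plateau-to-plateau fit measures *how long* it took. On traces planted at
42 h with Ψ-noise σ = 0.03 the estimate is within 10% in ≈98% of seeded
replicates. Thresholds, smoothing window and the minimum decline span are
all exposed parameters.

Alveologenesis events are scored as clusters of ≥2 cells whose somata start
within 25 μm, whose flattening onsets fall within 24 h, and which each
displace ≥60 μm (the lower bound of the ring-extrusion distance) during
their flattening — a rule-based surrogate for manual blinded scoring, with
every parameter exposed.

## Tracking

Objects are linked frame to frame by optimal bipartite assignment
(Hungarian) on centroid distance — reproducible and order-independent,
unlike greedy linking — with links forbidden beyond `max_gate` (default
15 μm/frame) and gaps up to `max_gap` (default 1 frame) bridged by
constant-velocity prediction. Centroids are unweighted label centroids.
Directional processivity is the straightness index ρ = D/L (net
displacement over path length), 0 by convention for a zero-length path; no
standard competing definition fit the observed "oscillatory, unvectored"
phenotype better, and D ≤ L guarantees ρ ∈ [0, 1].

## Rings

The mesenchymal mask is thinned to a unit-width skeleton; skeleton voxels
form a graph with μm edge weights, redundant diagonal steps removed, and
terminal spurs under 3 μm pruned. Closed rings are independent cycles of
this graph whose equivalent-circle diameter 2√(A/π) (A the enclosed planar
area of the angle-ordered, plane-projected loop — robust to non-circular
rings) lies in a configurable band (default 20–120 μm; no band is
established for real tissue) and whose rms planarity residual is below 20%
of the diameter. Member count is the number of distinct cell labels the
loop passes through. Rings are matched over time by centroid proximity
(10 μm gate) and contraction is the least-squares slope of d(t), optionally
pooled across rings after removing per-ring means. "Ring diameter" has no
operational definition in the imaging literature; the equivalent-circle
diameter is this package's definition.

## Vascular networks

The endothelial mask is thinned; voxels with ≠2 skeleton neighbours become
nodes (mutually adjacent junction voxels merge into one node), chains
between them become filaments with μm arc lengths honouring anisotropic
voxels. Three corrections counter known thinning artifacts: spurs under
3 μm are pruned; terminal filaments are lengthened by the
distance-transform value at the tip, since thinning retracts tips by
roughly the tube radius (a 50 μm tube reads 51.5 μm rather than 47 μm);
and a high-degree crossing that thinning splits into several trivalent
junctions a tube-radius apart is re-merged when the inter-junction chain is
shorter than the sum of the local tube radii. Arc length is measured on a
polyline through every third skeleton voxel rather than raw 26-connected
steps, which overestimate oblique runs by up to ~12% (digital length bias);
with these corrections planted tube lengths are recovered within ~2%.
Branch points are nodes of degree ≥3. The generator plants its vessel
topology as a Euclidean minimum spanning tree over sampled node points with
a tube-clearance filter, so the rendered tubes are disjoint except at
shared nodes and the skeleton's junctions correspond one-to-one to planted
degree-≥3 nodes.

## Alveolar expansion model

Boundary clouds (t, x, y, z) are partitioned by distinct time value, sliced
at |z − Z| ≤ tol (tol default 0.5 μm, one voxel spacing — an exact-z slice
of discrete data would usually be empty), and chained into closed loops:
points are grouped by ε-neighbour connectivity, ordered nearest-neighbour
from the minimal-x point, and accepted when the walk closes on its start,
covers ≥80% of the component (an interior stray point does not invalidate a
loop) and forms a simple polygon (checked with shapely; a self-intersecting
chain falls back to an angular sort and is flagged). The default
ε is 3× the median nearest-neighbour spacing: for an evenly spaced jittered
boundary the largest sequential gap approaches twice the mean spacing, so a
2× radius fragments clean loops. The largest-area loop of the t = 0
snapshot is the alveolus of interest and is followed forward by centroid
proximity (10 μm gate); snapshots with no loop are recorded as flagged gaps.
Polygons are oriented counterclockwise; area is the shoelace sum, perimeter
the closed vertex chain, and R = A/P (units of length) the complexity
index, the opposite of compactness. For a polygon inscribed in a circle of
radius r, R ≤ r/2 with equality in the many-vertex limit.

## Problem sizes

Tests run at desk scale by design: fields of 64–350 μm per axis at 1 μm
voxels, 2–13 rendered frames, and trace-level (unrendered) populations of
up to 200 cells × 100 frames. Recovery tolerances quoted above were chosen
from the closed forms and noise Monte-Carlo at these sizes.

## Limitations

* The generator renders geometric primitives (ellipsoid shells, arcs,
  tubes) without a point-spread function, spectral bleed-through,
  photobleaching or tissue scattering; passing tests demonstrate the
  correctness of the measurement chain, not robustness to real optical
  degradation. PSF convolution is deliberately out of scope.
* Cell shapes are spheroids; real AT1 cells are irregular sheets. Sphericity
  recovery on real meshes is asserted only against closed forms.
* The tracker has no division or lineage handling (proliferation is ~1% in
  this tissue and excluded), and no Bayesian motion model.
* Ring detection assumes rings are resolvable as disjoint skeleton cycles;
  heavily interlocked ring networks can share skeleton branches and are
  deduplicated only by centroid distance.
* The expansion model is strictly planar at z = Z, as defined; no 3D
  surface-area model is attempted.
* The ring contraction rate default and the segmentation threshold offset
  are placeholders/free parameters, not measured constants.
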