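# Methods

This note documents the models, parameters, numerical choices and known
limitations of `canopycce`. The pipeline's stage order is: ground
classification → DTM → height normalization → pit-free CHM → tolerance
watershed → per-segment mean-shift voxelization → connection-center-
evolution (CCE) clustering with automatic scale selection → plantation
merge → per-tree attributes.

## Terrain and canopy height model

**Ground classification.** Pre-classified clouds (LAS class 2) pass
through untouched; this is the recommended path. The built-in fallback is
a minimum-grid classifier: the lowest point of each 1 m cell defines a
TIN minimum surface and points within 0.2 m of it are ground. It is a
simple contract implementation, adequate for gently varying terrain and
for synthetic data; it is *not* a cloth-simulation filter and will
misbehave on cliffs, buildings, or dense low vegetation.

**DTM.** Linear TIN (Delaunay) interpolation of ground points, sampled at
cell centers; cells outside the ground hull are nearest-neighbor filled.
The lattice is registered with the first cell center exactly at the data
minimum, so every sample inside the data extent interpolates between
in-hull centers — this makes DTMs of planar ground exact (a property the
tests rely on) and normalization idempotent. Normalized heights are
`z − DTM(x, y)` by bilinear sampling, clamped at 0; points outside the
DTM extent use the clamped edge value and are counted in a warning.

**Pit-free CHM.** The normalized cloud is sliced at 0/2/5/10/15 m; each
slice is reduced to per-cell highest points, TIN-interpolated, and the
CHM is the cell-wise maximum over slices, additionally clamped from below
by the naive highest-point CHM (so the pit-free CHM ≥ naive CHM holds by
construction, cell-wise). In slices at or above 2 m, triangles with an
edge longer than 3 × cell size are dropped so sparse high slices cannot
bridge between crowns; the factor is configurable. Empty cells are 0.
Default resolution: 0.1 m for point densities ≥ 100 pts/m² (ULS-like),
0.2 m otherwise.

## Watershed initial segmentation

Seeds are CHM local maxima over a (2·ext+1)² window (default ext = 2) at
or above the background cutoff (min_height = 2 m); a flat-topped maximum
contributes one seed, its smallest-(row, col) cell. Flooding is a
priority flood: the highest unlabeled masked cell adjacent to a labeled
cell is labeled next (8-connectivity), taking the label of its highest
labeled neighbor; priority ties break on (row, col) and label ties on the
smaller label, so results are bit-reproducible. After flooding, any
object whose seed rises less than `tolerance` (default 1 m) above its
highest saddle with a neighboring object is merged into the neighbor with
the highest seed; objects are examined in ascending seed height, one
merge per pass, until stable. Points with normalized z ≥ min_height take
the label of their containing cell under half-open cell intervals
[x₀, x₀+cs).

## Mean-shift voxelization

Within each watershed segment, points are reduced ~10× by flat-kernel
mean shift over the anisotropic metric (Δx, Δy, √Vr·Δz) — the same
vertical scaling the clustering distance uses, keeping the two stages
metrically consistent. Shift iterations stop at a 10⁻³ m move or 100
iterations; converged modes within bandwidth/2 merge into one super-point
whose center is the centroid of its members and whose weight is the
member count (mass is conserved exactly: Σnᵢ = n). The default bandwidth
is 0.4 m for ≥ 100 pts/m² clouds and 0.6 m otherwise; 0.4 m was chosen to
land the measured reduction factor at ~9× (range 6–20×) on the default
synthetic crowns. Segments yielding fewer than 10 super-points skip the
CCE stage and are kept whole — matrices that small carry no reliable
crown-shape signal.

## CCE clustering

For one segment's super-points, the weighted anisotropic distance
d_ij = nᵢ·nⱼ·√(Δx² + Δy² + Vr·Δz²) becomes a Gaussian similarity
s̃_ij = exp(−d_ij²/σ²) with unit diagonal, degree-normalized as
S = D̃^(−1/2) S̃ D̃^(−1/2). The sweep visits k = 1, 2, 4, …, 2²⁰ by
repeated squaring. At each k, centers are the indices whose diagonal
entry strictly dominates their row of S^k; every super-point is assigned
to the center c maximizing the relative connectivity S^k[c,j]/S^k[c,c]
(ties to the lowest center index), and the partition's normalized cut is
recorded. The sweep stops early once a single cluster persists for two
consecutive scales.

Numerical choices:

* After each squaring, S^k is renormalized by its maximum entry. The
  center rule, the assignment rule and Ncut are all invariant under
  positive scaling of S^k, and without the renormalization S^k (spectral
  radius ≤ 1) underflows long before the macro scales.
* Symmetry is re-enforced ((M + Mᵀ)/2) after each squaring to keep exact
  ties symmetric.
* Exact diagonal/off-diagonal ties — which arise in mirror-symmetric
  configurations — resolve in favor of the lower index, so degenerate
  inputs still produce a deterministic center set.
* In exact arithmetic, two symmetric far-apart points would remain two
  centers at every finite k; in floating point the contrast decays below
  machine precision and the Perron–Frobenius limit (one center per
  connected component, at the leading-eigenvector argmax) is reached in
  practice, which the tests assert.

Defaults Vr = 1/6 and σ = 30. Note σ is expressed in the *weighted*
distance units: the nᵢ·nⱼ factor makes d's scale depend on super-point
weights (products of ~10×10 times ~0.3 m spacing ≈ 30), which is what
makes σ = 30 a sensible default after ~10× voxelization. For unweighted
point sets, σ should be chosen on the scale of the raw inter-point
distances. A `weight_mode="none"` switch drops the nᵢ·nⱼ factor for
sensitivity analysis.

## Scale selection

A scale is a candidate only if **every** cluster, using its original
member points, passes the three crown-shape tests: |CrownX − CrownY| <
(CrownX + CrownY)/2 (crown-width ratio < 3), and the highest point at
least edge_fraction (default 1/8) of the crown width away from both crown
edges in x and in y (strict inequalities; zero-width clusters fail).
Candidates vote by cluster count m: the m backed by the most candidate
scales wins, ties to the smaller m; within the winning group the lowest
Ncut is selected. If no scale qualifies, the watershed segment is kept as
a single tree — a deliberately conservative fallback that never fabricates
splits. Because the sweep's early stop caps the single-cluster vote at
two scales, a split that stays shape-valid across three or more scales
outvotes it; this biases the stage toward over- rather than
under-segmentation, consistent with the commission/omission trade-off the
watershed refinement is meant to strike.

## Merge rule and attributes

Two detected trees merge when their tops are closer horizontally than the
plot-average crown diameter and their heights differ by less than 10 m
(the height-difference reading of the rule; an absolute-elevation reading
is incompatible with 13–25 m stands). The qualifying pair with the
smallest top-to-top distance merges first, attributes are re-extracted,
and the process repeats. The automatic crown diameter — the mean of
(crown_x + crown_y)/2 over the records — is computed once at entry:
re-deriving it from merged crowns would inflate it after every merge and
cascade until whole plots collapse. With a fixed (user-set) diameter the
operation is exactly idempotent; with the automatic diameter a second
invocation could in principle merge further, since the merged crowns
enlarge the plot mean. Tree attributes come from the highest member point
(top position and height) and per-label x/y extents (crown widths).

## Detection matching and metrics

Matching is the sequential highest-first procedure: detected trees in
descending height; candidates are unmatched reference trees within 5 m
whose relative height difference is ≤ 20 %; the smallest height
difference wins, distance breaking ties; pairing is one-to-one. The two
thresholds are package defaults — the benchmark protocol they stand in
for does not print values. Sequential matching is not guaranteed to reach
the exhaustive-optimal pair count on adversarial layouts (the tests
check it against an exhaustive oracle as a bound, and exactly on layouts
where the two coincide). The five rates follow the standard identities
(R_omission = 1 − R_match, R_commission = 1 − R_match/R_extraction); with
no detected trees the commission rate is reported as 0 with a warning,
and F = 0 when TP = 0. Height accuracy is R² = 1 − SS_res/SS_tot with
SS_tot about the reference-height mean, and RMSE in meters, over matched
pairs (≥ 2 required; zero reference variance is an error).

## Synthetic forest generator

The generator emulates small inventoried ULS/ALS plots: terrain is an
inclined plane (default 5°) plus a smooth 0.3 m sinusoidal undulation;
stems sit on a jittered grid honoring `min_spacing` (a spec error is
raised when the requested density and spacing are jointly infeasible);
apex heights are uniform in 12–22 m and crown radii in 1–2.5 m (the
stands the defaults emulate have 13–25 m mean heights); crowns are cones
(conifer) or ellipsoids (broadleaf), occupying the top half of the stem.
Crown points are sampled with a depth pdf proportional to the crown
cross-section r(d)² — uniform density per crown volume — because a
uniform-in-depth pdf would concentrate 3-D density at the cone apex,
creating super-points of unrealistic weight whose nᵢ·nⱼ-scaled distances
disconnect the similarity graph; real ULS crowns are not apex-dense.
Per-point retention is exp(−0.15 · depth-below-apex), mimicking occlusion
of the lower crown; each tree's apex point is always retained, so the
ground-truth top is exact and detection tests are decoupled from sampling
luck. Ground points are added at one tenth of the crown point density
(default 300 pts/m², a dense-ULS figure). All randomness flows from one
seeded generator in a fixed draw order; outputs are bit-identical per
seed.

What the generator does **not** emulate: multi-return and full-waveform
physics, understory vegetation, crown interpenetration and asymmetry,
species mixtures within a crown, registration and sensor noise. Passing
tests on synthetic plots therefore demonstrate the algorithmic chain —
terrain handling, segmentation, scale selection, matching — not
performance on natural ULS data, where crown shapes violate the cone/
ellipsoid idealization and matched accuracy will be lower.

## Problem sizes used in the tests

The end-to-end suite runs a 30 × 30 m, 0.05 trees/m², 300 pts/m² cone
plantation (~81 k points, 45 trees; the spacing is 4 m — the jittered-grid
pitch at that density, since 45 stems cannot be placed 8 m apart in such a
plot) and a 20 × 20 m, 0.05 trees/m², 150 pts/m² mixed-purpose plot;
oracle equivalence suites use ≤ 30 × 30 CHMs and ≤ 15-point similarity
matrices. These sizes exercise every stage, including multi-tree
segments, while keeping the default suite quick to run.

## Known limitations

* LAZ is not read (no decompressor dependency); LAS support is minimal
  (x, y, z, classification). Labels are exported as a companion CSV
  rather than a LAS extra dimension.
* The watershed reproduces the documented tolerance/ext semantics with a
  deterministic flood; it is not guaranteed pixel-identical to other
  watershed tools.
* The scale-selection vote can over-segment broad irregular crowns (every
  horizontal slice of a cone is itself shape-valid); the plantation merge
  compensates in even-aged stands but not in structurally diverse ones.
* σ = 30 interacts with super-point weights; strongly non-uniform weights
  can disconnect the similarity graph and freeze the sweep above m = 1.
* Crown-width estimates are reported but their accuracy is not assessed.
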