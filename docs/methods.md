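# Methods

This note documents the models, algorithms, numerical conventions, and design
choices behind `conngeo`, in the order the pipeline uses them.

## Graph distances and the node representation

A connectome is a symmetric nonnegative coupling matrix with zero diagonal,
unique node labels, and no isolated nodes; these invariants are enforced at
construction (asymmetry up to `1e-9` is averaged away as I/O noise; diagonal
magnitudes up to `1e-12` are zeroed). A zero weight means *no edge*, not an
infinitely weak one: a fiber count of zero is an absent tract.

Edge length is the reciprocal of coupling strength, and all-pairs shortest
paths are computed by Dijkstra's algorithm from every source
(`scipy.sparse.csgraph`). Disconnected graphs are a hard error rather than an
infinite-distance sentinel, because every downstream object — the node
representation, the embeddings, the cohesion statistic — assumes finite
distances. The result is symmetrized exactly (averaging the last-bit
asymmetry that summation order can introduce) and its diagonal pinned to 0.

Row `i` of the distance matrix is node `i`'s coordinate vector in `ℝⁿ`. All
embeddings start from these rows; two nodes are nearby iff their distance
*patterns* agree, which is a different (and more informative) relation than
being strongly connected to each other.

Nodal path length is the mean of a node's distances to the other `n − 1`
nodes; the structural zero to itself is excluded. Including it would only
rescale every value by `(n−1)/n`.

## Classical MDS

Torgerson MDS double-centers the squared distances,
`B = −½ J D⁽²⁾ J`, `J = I − 11ᵀ/n`, and eigendecomposes `B` with `eigh`. The
top `d` eigenvalues are clamped at zero when negative — graph distances need
not be Euclidean-embeddable — and the number of clamped values is logged and
recorded on the `Embedding`. Coordinates are eigenvectors scaled by the
square roots of the clamped eigenvalues. Two conventions make outputs
bit-reproducible across platforms: each axis is flipped so its
largest-magnitude coordinate is positive, and the coordinates are explicitly
re-centered so the centroid invariant holds to machine precision.

Iterative stress-minimizing MDS (SMACOF) is deliberately not used: the
package contrasts a *linear spectral* embedding against Isomap, whose own
final step is exactly classical MDS, so the comparison isolates the single
modelling difference — straight-line versus geodesic distances.

## Isomap

The k-nearest-neighbor graph is built on Euclidean distances between
representation rows, symmetrized by *union* (an edge survives if either
endpoint lists the other). Union symmetrization guarantees that growing `k`
eventually connects the graph, so the automatic neighborhood search
(`min_connected_k`) terminates; it starts at `k = 3` to avoid degenerate
chain graphs while staying below typical connectivity thresholds. Ties among
equidistant neighbor candidates resolve to the lower node index (stable
argsort), another determinism guarantee. Geodesics are Dijkstra shortest
paths over this graph with Euclidean edge weights; classical MDS of the
geodesic matrix gives the embedding, with the `k` actually used recorded on
the result. An explicitly requested `k` whose graph is disconnected is an
error that names the remedy (`k='auto'`) rather than silently patching the
graph.

The residual variance `1 − r²` between input and embedded pairwise distances
is the standard Isomap fit diagnostic and is exposed for any embedding.

## Nodal metrics

* **Strength** — sum of incident weights.
* **Clustering** — Onnela's weighted coefficient: weights scaled by the
  network maximum, triangle intensities as geometric means of the three cube
  roots, normalized by `k(k−1)` with `k` the binary degree; nodes of degree
  < 2 score 0. Onnela is the common default of the standard brain-network
  toolboxes, which keeps values comparable with published work.
* **Betweenness** — Brandes accumulation on the same inverse-weight edge
  lengths as the distance matrix (consistency matters: a different length
  convention would rank different nodes), endpoints excluded, unnormalized,
  fractional credit for tied shortest paths (via networkx).
* **Embeddedness** — the ratio of nodal efficiency to an
  information-transfer decay rate. The decay rate is estimated as the
  negative slope of `log(mean inverse graph distance to the h-hop shell)`
  against hop count on the binarized graph, by least squares over all
  available shells. This is an explicitly documented *proxy* — the original
  metric's shell definition and fit range are not fully specified in the
  literature we implement from — so the removal interface also accepts a
  caller-supplied ranking that bypasses the proxy entirely. Nodes with fewer
  than two shells or non-positive decay get `+inf` (they are maximally
  "embedded": their efficiency never decays) and are logged.

## Centrality validation and the dimension sweep

Validation regresses per-node distance-to-center on nodal path length by
ordinary least squares with intercept and reports `r²` (squared Pearson
correlation, equivalently OLS `R²`), slope, and intercept. The anatomic
variant uses the centroid of the region coordinates as the center. Constant
inputs are rejected as degenerate rather than returning `r² = 0`.

The dimension sweep re-embeds the representation with Isomap at each target
dimension, repeats the regression, and reports the RMSE of its residuals.
RMSE rather than `1 − r²` keeps the curve in the units of the embedding, so
"leveling off" is directly interpretable as no further geometric information
being recovered.

## Lesion simulations

Node removal is a pure submatrix operation: surviving weights are never
rescaled. After removal the graph distances and the Isomap embedding are
recomputed *from scratch* on the survivor network — each lesion is a new
topology, not a projection of the old embedding. The cohesion statistic `d̄`
is the mean distance of embedded survivors to their embedding center; its
normalized variant multiplies by the surviving network's mean off-diagonal
weight (zeros included). Using the *surviving* network's mean is a modelling
choice with visible consequences: a pre-removal constant could never reorder
schemes between the raw and normalized readouts, whereas scheme-dependent
weight loss can and does.

Targeted schemes remove the top `round(fraction · n)` nodes of a metric
ordering (strength/betweenness/embeddedness descending, clustering/path
length ascending; ties to the lower index), of a flag ordering (rich-club or
subcortical flags first, alphabetical within), or of a custom ranking.
Rounding is half-away-from-zero for cross-platform determinism. Removals
that disconnect the survivors are errors; the random-removal driver catches
them, redraws (up to 100 consecutive failures per trial, with the redraw
count reported for bias assessment), and is fully reproducible from its
seed. The distribution summary reports the mean and the explicit (5th, 95th)
percentile pair.

## Parcellation upsampling

Each labeled region is recursively cut by a plane perpendicular to its
principal axis — the leading covariance eigenvector of its voxel
coordinates, computed in millimetres (voxel indices scaled by voxel size, so
anisotropic voxels do not bias the axis). Eigenvalue ties resolve toward the
+x, then +y, then +z direction; axis signs are fixed by the
largest-component-positive rule.

"Bisected" is interpreted as the *median* split — the cut passes through the
median projection, ties going to the lower side — because a median split
keeps the recursion balanced and guarantees termination; a centroid-plane
variant is available behind `mode="centroid"`. A region splits while it
holds **at least** the threshold number of voxels (a region of exactly 800
splits; subdivision stops once a piece has *dropped below* the threshold).
With the conventional 800-voxel (≈1 cm³) threshold this yields the expected
upsampling arithmetic: a 6400-voxel cuboid produces exactly 16 children of
400 voxels.

With multiple subjects, each subject's region is centroid-aligned and pooled
into a group region; the axis and the cut position are computed on the group
set and applied to every subject, so all subjects split along the same
planes. Non-contiguous regions are treated as plain point sets. Degenerate
pieces (coincident coordinates, or a cut that fails to separate — possible
when projections tie en masse) are left unsplit, flagged, and logged.

## Synthetic data

The generator produces the study conditions every analysis is exercised
under; its defaults were fixed once, from connectomic reasoning, and are not
per-test knobs.

A 200-node network has four communities ("lobes", the first labeled
`subcortical`) and a planted core of 43 nodes — 21.5 % of the network, the
rich-club share of an upsampled whole-brain parcellation — spread evenly
across communities. The structural ingredients, each mirroring a feature of
real structural connectomes that the analyses depend on:

* **Depth within communities.** Each peripheral node carries a latent depth
  in (0, 1); within-community edge probability decays with depth difference
  (e-folding 0.4). Communities thus have shallow gateway members and a deep
  local periphery several weighted hops from anywhere else — the "petals" of
  the embedded geometry.
* **The core as connector hubs.** Core nodes sit at depth 0, are densely
  interconnected (presence 0.9), and couple to *every* community's shallow
  members (presence 0.5, decaying with partner depth, e-folding 0.2). Mean
  core weights (25 core–core, 20 core–periphery) deliberately match the
  within-community scale (20): the core's distinction is *density and reach*,
  not extreme weight. A much heavier core would collapse into a tight clump
  whose distance pattern is an outlier — it would embed as a satellite
  rather than at the center, which is exactly what pilot experiments with
  weight-dominated cores showed.
* **Heavy tails on edges, mild tails on nodes.** Edge weights are log-normal
  with σ = 1.0 around the block mean (fiber counts are positive and
  right-skewed over orders of magnitude); node-level strength propensities
  are mild (σ = 0.2). Carrying the heavy tail on nodes instead would make
  strength, clustering, and path length near-collinear — one latent factor
  driving everything — whereas real connectomes show clustering largely
  decoupled from global position.
* **Local cliquiness at depth.** Deep same-community pairs get an extra
  presence boost (gain 2.0), so the deep periphery is locally clustered but
  globally remote, as sensory cortex is.
* **A weak long-range mesh.** Direct between-community edges exist with
  probability 0.05 at mean weight 2. They carry essentially no shortest path
  (a route through the core is an order of magnitude shorter) and therefore
  do not perturb the geometry, but they keep survivor networks connected
  under every removal scheme.
* **Decoupled anatomy.** Anatomic coordinates are Gaussian clusters (σ =
  10 mm) around random community centers in a ±60 mm box, drawn
  independently of the realized edges. The generator must be *able* to
  exhibit a dissociation between anatomic position and intrinsic geometry;
  baking anatomy into the topology would make that claim circular.

Isolated nodes are reattached within their community and residual components
bridged at the weak-mesh weight, so every output passes connectome
validation. The Swiss-roll generator returns ambient coordinates together
with (arc-length, height) intrinsic coordinates, so true manifold distances
are available in closed form. Label volumes are Voronoi tessellations of the
voxel grid; regions need not be contiguous, matching the subdivision
algorithm's point-set semantics.

**What passing on these fixtures does and does not show.** The synthetic
networks realize the *qualitative* structure the analyses claim to detect —
a planted connector core, modular petals, heavy-tailed weights, decoupled
anatomy — so green tests demonstrate that the pipeline recovers planted
structure of that kind at n = 200. They do not certify quantitative
agreement with any real 620-region connectome: real data have individual
variability, distance-dependent wiring costs, measurement noise from
tractography, and hemispheric symmetry that the generator does not attempt
to emulate.

## Problem sizes and seeds

The evaluation battery runs at n = 200 with five fixed generator seeds
(1–5), 500-trial random-removal distributions, a 1000-point Swiss roll, and
50 random label volumes — sizes at which every planted effect is
unambiguous and the whole suite stays interactive. The pipeline expands its
single seed into per-stage seeds by a fixed counter scheme
(`stage_seed = (seed·1009 + stage_index) mod 2³¹`), so any stage can be
reproduced in isolation from a report's recorded parameters; reports
serialize with sorted keys and are byte-identical across reruns.

## Known limitations

* The embeddedness proxy is one defensible reading of an under-specified
  metric; rankings from it should not be compared across studies without
  stating the proxy. The pass-through ranking exists for exactly that
  reason.
* Classical MDS on strongly non-Euclidean distance matrices discards the
  negative spectrum; the clamped-eigenvalue count on the `Embedding` is the
  honest indicator of how much was discarded.
* `min_connected_k` guarantees connectivity, not short-circuit-freedom: on
  noisy manifolds a too-small `k_start` can still thread geodesics through
  noise. The Swiss-roll check runs noiseless for that reason; noisy
  manifolds may need a caller-chosen `k`.
* The lesion driver redraws disconnecting random subsets, which biases the
  random-removal distribution toward less destructive draws on fragile
  networks; the redraw count in the result is the audit trail.
* Group-mode subdivision aligns subjects by centroid translation only — no
  rotation or scaling — matching its intended use on roughly registered
  label volumes.
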