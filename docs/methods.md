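# Methods

## Contact quantification

A `LabelVolume` is an ordered stack of 2-D integer label images with in-plane
pixel size (nm/px), z-spacing (nm), and an optional inclusive slice range
restricting the analysis to the neuropil. Coordinates are 0-based
(slice, row, col).

Contact between neurons $a$ and $b$ on one slice is directional: the region
of $a$ is dilated by the threshold distance in pixels (exact Euclidean
dilation via a distance transform, so a pixel is covered iff its center lies
within the threshold of some pixel center of $a$), and the pixels of $b$
covered by the dilation are counted. "Expansion" is implemented as isotropic
Euclidean dilation, not homothetic scaling about the centroid: dilation is
the operation whose covered-pixel count has exact distance-threshold
semantics, which is what the adjacency measure needs. Directed counts are
summed over in-region slices and symmetrized by the arithmetic mean; both
directed totals are kept in the `ContactRecord`. The threshold is carried in
both nm and pixels, converted by round-half-up (45 nm at 4.5 nm/px = 10 px).

Contact surface area per pair is the summed perimeter (nm) of the per-slice
overlap masks times the z-spacing. The perimeter estimator counts exposed
unit pixel edges (4-connectivity) — a deliberate, reproducible choice; it
overestimates smooth contours by up to a factor ~4/π, consistently across
pairs, so ranks and percentages are unaffected.

### Threshold calibration

Datasets segmented by different methods need different thresholds to capture
the same physical adjacency. The calibration measures, for each candidate
distance, the mean penetration depth into directly contacting partners:
depth = candidate − inter-membrane gap, where the gap is the minimum
center-to-center pixel distance between the two regions minus one pixel
(apposed membranes have gap 0). The smallest candidate whose mean depth
reaches the target overlap (default 30 nm) is selected. A uniform 15 nm gap
therefore calibrates to 45 nm, the reference threshold for manually
segmented data. "Directly contacting" means a gap of at most 3 px
(configurable) on some slice.

## Diffusion condensation

Initial coordinates are the rows of the adjacency matrix — each neuron's
adjacency profile — so neurons with similar contact partners start close.
(An alternative initialization that row-normalizes the adjacency matrix
itself into the first diffusion operator is available via
`CondensationParams(initial_affinity="adjacency")`.)

Each iteration: Gaussian affinity over current centers with bandwidth
σ, row-normalization to $P = D^{-1}A$, one smoothing step $Y = PX$, then
merging of all centers closer than ε using connected components of the
ε-proximity graph (transitive merging; a pairwise rule would be
order-dependent). New centers are unweighted means of the merged centers.

**Merge threshold ε** is computed once, after the first diffusion step, as
the largest coordinate-wise range divided by 10,000, and held fixed. The
maximum coordinate range equals the maximum pairwise Chebyshev
(coordinate-wise max) distance — the two formulations are identical, which
the test suite verifies by brute force.

**Adaptive bandwidth.** The default rule is `knn`: σ is the median, over
centers, of the Euclidean distance to the 5th-nearest other center (capped
at n−1). This local scale is the standard adaptive-kernel choice in
diffusion-map methods. The global alternative `median` (median nonzero
pairwise distance) is retained as an option but is not the default: when
most center pairs are far apart — exactly the situation in a block-structured
contactome, where cross-block pairs dominate the distance distribution — a
global median bandwidth flattens the kernel (cross-block affinities ~0.6),
diffusion mixes blocks nearly as fast as it contracts them, and the
hierarchy can merge across blocks before blocks finish condensing
internally. With the k-NN bandwidth, planted 4-block matrices are recovered
perfectly in 20/20 seeded runs; with the global median, in only 8/20.

**Modularity** of each iteration's partition is always evaluated on the
fixed original adjacency graph, never the evolving coarse graph, so scores
are comparable across iterations; the weighted Newman–Girvan form is used.
The strata are the clusters at the argmax-modularity iteration (earliest
iteration on ties). Raw adjacency values are used without log or rank
transformation; preprocessing is the caller's responsibility.

The iteration cap defaults to 1,000; hitting it returns the partial trace
with `converged=False` and a machine-parsable warning (`DC_NOT_CONVERGED`),
never a silent truncation.

## C-PHATE

Node set: the singleton neurons (level 0) plus every cluster of every DC
iteration, including iterations where no merge occurred (zero-padding keeps
the trajectory per iteration explicit). Per-level cluster affinities are
block sums of the original adjacency over cluster members — the natural
coarse-graining, conserving total edge weight — normalized symmetrically to
$K_t = D^{-1/2} A_t D^{-1/2}$. Transition blocks between consecutive levels
use the membership-counting rule (fraction of cluster *i*'s neurons landing
in cluster *j*); for merge-only dynamics these rows are point masses, and
lag-2 blocks are the composed product $P_{t,t+1}P_{t+1,t+2}$ (identical to
directly tabulated two-step movements for nested partitions). Lag-1 blocks
are weighted 100 and lag-2 blocks 30, mirrored by transposition so the
connectivity matrix is symmetric.

**Embedding backend.** `embed` accepts any callable
`(affinity, n_components, diffusion_time, seed) -> coords`. The built-in
backend is a compact potential-distance embedding of the PHATE family:
row-normalize the connectivity matrix into a Markov operator, raise it to
the diffusion time (default 50), take −log potentials (floor 1e−7), and
embed the pairwise potential distances by classical multidimensional
scaling. It is fully deterministic — eigenvector signs are fixed by a
largest-entry-positive convention — so identical inputs give bitwise
identical coordinates regardless of seed; the seed is recorded in the
embedding parameters for provenance and for backends that do use it.

## Meshing

Marching cubes at level 0.5 on zero-padded binary masks, vertices scaled by
(pixel size, pixel size, z-spacing) into nm and reordered to (x, y, z) =
(col, row, slice). No smoothing is ever applied; re-running is bitwise
identical. Optional integer downsampling block-reduces the in-plane masks by
max-pooling before triangulation (10-fold is a sensible choice for whole
neurons, 20-fold for a neuropil shell); the default is 1 (off).

The rasterized marching-cubes surface chamfers edges, so measured surface
area converges to the analytic value from below as the object grows; a
10×16×20-voxel cuboid is within ~4% of $2(ab+bc+ca)$, tiny objects deviate
more. Contact patches are triangulated from the stacked per-slice overlap
masks; regions too small to triangulate return `None` with a
`CONTACT_PATCH_TOO_SMALL` warning — a recorded outcome, not an error.

Synapse glyphs: presynaptic sites are blocks (cubes), postsynaptic sites
spheres (icospheres), electrical synapses six-spike octahedral stars (the
star geometry is a fixed package choice), centered at the annotated
coordinates and scaled by the annotation's scale factor times a 100 nm base
size. Alignment across specimens is a 3×3 orthonormal rotation (checked to
1e−6) followed by a positive uniform scale.

OBJ I/O writes `v`/`f` records with 1-based face indices; the reader ignores
other record types and reports parse errors with the line number.

## Synthetic data

The fixtures module generates the study inputs:

- **Tube phantoms** — disks of fixed radius per slice, non-overlapping by
  validation, with analytically known inter-tube gaps. They emulate neurite
  cross-sections well enough to exercise contact counting exactly (an
  exhaustive pixel-pair oracle is part of the module); they do not emulate
  realistic neurite morphology, branching, or segmentation noise, so passing
  tests demonstrate correctness of the counting geometry, not robustness to
  imperfect segmentation.
- **Planted-block adjacency matrices** — default 4 blocks × 10 neurons,
  within-block weights ~N(100, 10), between-block ~N(1, 1), negatives
  clipped to 0 (contact quantities are counts), symmetric with zero
  diagonal, deterministic per seed. The contrast emulates the strong
  within-stratum contact enrichment of a stratified neuropil; real
  contactomes have heavier tails, hub neurons and cross-stratum bridges that
  the generator deliberately omits.
- **Gaussian point clouds** for unit-testing the condensation loop directly.

## Problem sizes

Tests and the acceptance script run on 40–45-neuron planted matrices,
≤ 10-slice phantoms and ≤ 20-voxel-edge mask volumes — sizes chosen so the
entire suite re-runs in seconds while every check is exact or statistically
stable. Runtime scales as O(n²) per DC iteration and O(N³) for the embedding
eigendecomposition (N = total iteration-clusters); nerve-ring-scale inputs
(~180 neurons, N of a few thousand) run in minutes.

## Known limitations

- The adaptive-bandwidth schedule and the per-iteration affinity definition
  in C-PHATE are package choices among several defensible readings; both are
  options behind stable interfaces.
- Modularity-based stratum selection inherits modularity's resolution limit:
  very small strata attached to large ones may not be separated at the
  argmax iteration.
- Surface areas from rasterized meshes and pixel-edge perimeters are
  estimator-specific; compare areas only within one pipeline configuration.
- Stratum ids are arbitrary integers; matching them to named anatomical
  strata requires external reference membership lists.
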