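# Methods

This note documents the model implemented by the package, the choices
made where the design was genuinely open, the synthetic data the tests
run on, and the limitations of both.

## Units, coordinates and inputs

All computation happens in physical micrometres. Raster inputs (nucleus
label images) are converted at read time with the user-supplied voxel
size, so the two physical hyper-parameters — mean cell diameter `D` and
maximum cell radius `r_max` — mean the same thing regardless of pixel
size. 2D data are represented as 3D with z = 0. For anisotropic stacks,
`z_anisotropy_factor` multiplies z before any distance computation
(default 1.0, i.e. distances are isotropic in the stored coordinates).

Every derived length scale recomputes from `D`: the proximity-expression
radius `r_pe = D/2`, the graph edge cutoff `r_knn = D/4`, and the
centroid-vote radius `r_centroid = D/2`. The neighbor caps are fixed
defaults: `k_pe = 40` for the expression kernel, `k_knn = 10` for the
graph, `k_centroid = 15` for the centroid vote; their exact values have
little influence and are exposed in `ComSegConfig` anyway. Unassigned
molecules carry cell id 0, matching the label-image background
convention.

## Proximity-weighted expression and co-expression

The PE vector of molecule `x` sums, per gene, the kernel
`(r_pe − d)/r_pe` over the ≤ `k_pe` nearest neighbors within `r_pe`.
Decisions taken here:

- The anchor is **excluded** from its own neighborhood. Including it
  would add a constant 1 to the anchor's own gene and bias same-gene
  correlations upward.
- The `k_pe` cap applies to the neighborhood as a whole (one KNN query
  across all genes), not per gene.
- Ties at the k-th neighbor distance are broken by molecule index, so
  the computation is deterministic.

The co-expression matrix `W` is the Pearson correlation of PE columns,
computed in double precision over all molecules. A gene whose PE column
has zero variance (never expressed near any molecule) gets correlation
0 with everything, its diagonal included: it carries no co-expression
evidence, and 0-weight edges are inert downstream. An externally
estimated gene × gene matrix (e.g. from scRNA-seq) can replace the
image-derived one; it is validated for symmetry and realigned to the
run's gene order.

## Graph construction and constrained community detection

The molecule graph is the union of directed k-nearest relations
(`k_knn`, max length `r_knn`); mutualization (keeping only reciprocal
pairs) was considered and rejected in favor of the union, which keeps
sparse regions connected. Each edge stores both the co-expression
weight of its gene pair and its Euclidean length; the weight drives
community detection, the length drives the final geodesic assignment.

Nuclei act as priors: all molecules inside one nucleus (raster lookup
when a label image is given, otherwise a sphere of `D/4` around the
centroid) are contracted into a single cell node. Contracted parallel
edges **sum** their co-expression weights — the community-detection
weight of a super-node is the total affinity of its members — but keep
the **minimum** of their Euclidean lengths, because the geodesic
distance from the centroid to an outside molecule should use the
shortest physical link, not the sum of parallel link lengths. Nuclei
containing no molecule still produce (isolated) cell nodes so that
every nucleus yields a cell downstream.

Community detection is a Louvain variant with three modifications:

1. Only positively weighted edges contribute to modularity and to
   merging; negative co-expression (genes of different cell types)
   never pulls molecules together. If no positive edge exists, the
   all-singleton partition with Q = 0 is returned.
2. A community may contain at most one cell node, at every stage of
   every pass; aggregated nodes inherit the flag, so two
   nucleus-anchored communities can never merge.
3. The local-move phase considers, besides the neighboring communities,
   a move into an empty community. Plain Louvain omits this
   "isolation" move, and its output can then be improvable by a single
   node move; since isolation dominates every move to a non-adjacent
   community, including it makes the converged state a genuine local
   optimum over all single-node moves. For the same reason a final
   refinement sweep re-runs local moves at the original-node level
   after the aggregation passes (aggregation alone guarantees
   optimality only over aggregated-node moves). Both additions can only
   increase Q.

Sweep order is drawn from the seeded generator and reshuffled each
sweep; ties in modularity gain break toward the smallest community id,
so runs are reproducible given the seed.

## In-situ clustering and the domain map

Each community's expression vector is the arithmetic mean of its
members' PE rows. Communities of at least `min_community_size = 3`
molecules are clustered: total-sum scaling to the median community
total, `log1p`, PCA when the panel exceeds 30 genes (keeping
min(n_genes − 1, 20) components), a cosine KNN graph (K = 15) whose
edges are weighted by cosine similarity, and Leiden at
`leiden_resolution = 1.0` with the run seed.

Two choices deserve comment:

- **Similarity-weighted KNN edges.** With few communities the KNN graph
  is near-complete, and an unweighted graph then collapses to a single
  Leiden cluster regardless of structure; weighting edges by
  1 − cosine distance (the scanpy/Seurat convention) restores the
  separation.
- **Centroid merging.** Leiden on sparse KNN graphs reliably splits
  homogeneous point masses into several clusters (modularity finds
  "structure" in neighborhood noise). Clusters whose normalized
  expression centroids have cosine similarity ≥
  `cluster_merge_threshold = 0.9` are therefore merged by single
  linkage. For panels with distinct profiles the within/between
  similarity gap is wide (near 1 vs near 0), so the result is
  insensitive to the exact threshold; set it to `None` to disable.

The normalization is a deliberate simplification: community vectors are
continuous kernel sums, not counts, so a count-specific
variance-stabilizing model is not applied here; total-sum + log1p is
the default and configurable.

Communities below the size threshold inherit the majority label of the
`k_small = k_knn` labeled molecules nearest their spatial centroid
(vote over molecules, not over neighboring communities — the other
reading of "nearest neighbors" — because molecule-level voting uses the
actual local density); ties break toward the label of the single
nearest molecule. After this step every molecule carries a profile
label.

## Final assignment

Each nucleus centroid takes the majority profile label of its nuclear
RNAs; an RNA-free nucleus takes the majority label of the ≤
`k_centroid` molecules within `r_centroid` (Euclidean — the vote radius
is read as a Euclidean ball, the graph not being defined at a bare
centroid); a nucleus with no molecule in reach is label-less and
produces an empty cell. Bare cell nodes are bridged to their ≤
`k_centroid` nearest molecules within `r_centroid` (edge length =
Euclidean distance) so the centroid is reachable at all.

Assignment is a multi-source Dijkstra per label over Euclidean edge
lengths: a molecule goes to the same-label centroid with the smallest
geodesic distance, provided that distance is ≤ `r_max`; exact ties go
to the smaller cell id. By default paths are **label-constrained**
(they may only traverse molecules carrying the source label), which
prevents a cell from tunneling through foreign transcriptomic
territory; `label_constrained_paths=False` relaxes this. Nuclear
molecules are always assigned to their own nucleus. `r_max` defaults to
`D` but should be chosen per tissue; it is the only parameter besides
`D` that materially shapes the output.

## The synthetic tissues

The simulator produces label rasters at 0.150 µm/pixel (a typical 60x
objective), nuclei as discs of 3.75 µm radius, and three geometries:

- **Grid**: a checkerboard of 15 µm squares, nucleus concentric — the
  convex control where nearest-nucleus assignment is essentially
  optimal.
- **L-shapes**: pairs of interlocking L-tetromino cells (four 15 µm
  squares each) tiling 2 × 4 blocks, the nucleus at the center of a
  seeded-random one of the four squares — the minimal non-convex
  geometry where nearest-nucleus assignment must fail.
- **Grown tissue**: cytoplasms grown from nucleus seeds (dart-throwing
  placement or experimental rasters) by stochastic frontier dilation
  inside an allowed mask with optional elliptic lacunae. Each cell
  draws a per-round expansion probability once from [0.5, 1.0]; each
  round, in seeded-random cell order, a cell whose coin lands dilates
  by one voxel into free allowed space, contested voxels going to the
  first claimant of the round. The growth law and the contested-voxel
  rule are simulator variants, not measured biology.

Expression: each cell draws a type and an integer profile — constant,
negative-binomial around the type mean (gamma–Poisson, dispersion 20),
or a sampled row of a user-supplied reference matrix — then counts are
multiplied by a capture-scale factor of 3 (droplet scRNA-seq captures
roughly a third of what smFISH detects) with stochastic rounding so
expectations scale exactly. Molecules are placed uniformly over the
cell's voxels with sub-voxel jitter. A seeded fraction of nuclei
(default scenario: 20 %) can be dropped while their cells and RNAs
remain, mimicking nuclei lost to the sectioning plane.

The built-in two-type marker panel (5 exclusive genes per type, mean 5
counts per marker before scaling, zero off-target leak) stands in for a
real marker-gene panel. What the simulations do **not** emulate:
extracellular/background molecules, detection noise and duplicates,
nuclear RNA enrichment, overlapping cells in z, continuous expression
gradients within a type, and realistic panel sizes with leaky markers.
Passing on these fixtures therefore demonstrates the algorithmic
mechanics — not performance on real tissue, where marker separation is
weaker and backgrounds are nonzero.

## Evaluation

Per ground-truth cell c (only cells with a retained nucleus are in
scope): `J_c = |X∩Y|/|X∪Y|`, `WA_c = |Y\X|/|Y|`, `MS_c = |X\Y|/|X|`,
averaged unweighted over cells. A cell with an empty prediction is
excluded from the WA mean (undefined denominator) and scores MS = 1;
cells with an empty true set are out of scope entirely. Matching is by
shared nucleus id on simulations, or by maximal molecule overlap (ties
to the smaller predicted id) otherwise. The watershed baseline assigns
each molecule to the nucleus region at minimal distance (nearest labeled
voxel when a raster is given, else the centroid) under the same maximum
distance used for `r_max`. Cell-type calling normalizes profiles and
reference centroids identically (total-count + log1p by default, an
analytic Pearson-residual option for variance stabilization), keeps
cells with more than 5 molecules, and assigns the argmin-cosine type.
The exactly-one-nucleus filter keeps cells whose overlap with exactly
one nucleus is at least 20 pixels, the rule used to build automatic
ground truth from paired segmentations; "20-pixel width" is implemented
as overlap area ≥ 20 pixels.

## Benchmark-scale choices

`scripts/acceptance.py` and the end-to-end tests use desk-scale
conditions chosen once: grid 10×10 cells (D = 15 µm = the cell size,
r_max = 15 µm), and 32 L-shaped cells with alternating types, 20 %
dropout, three tissue replicates (D = 34 µm, the equivalent-area
diameter of the four-square cell; r_max = 52.5 µm, the maximal
nucleus-to-far-corner geodesic extent, i.e. 3.5 square sides; the
watershed baseline gets the same distance cutoff). Typical molecule
counts are ~7.5k (grid) and ~2.5k (L-shape) per run.

## Numerical details and degenerate inputs

Empty neighborhood → zero PE vector; single-molecule cloud → zero PE
matrix; correlation of a one-row matrix → error; graphs with no
positive edge → singleton partition, Q = 0; all communities below the
size threshold → error advising a larger `D`; nuclei without label or
reachable molecules → empty cells kept as zero rows in the count
matrix. Modularity comparisons use a 1e-12 gain epsilon; Q is
non-decreasing across passes to the same tolerance.

## Known limitations

- Sweep-order randomness can flip a community that straddles two cells
  between runs. On large tissues the effect averages out; on small
  fixtures (tens of cells) a single flipped boundary community can move
  the mean Jaccard by a few hundredths, because each cell is a large
  fraction of the mean. The seed is exposed precisely so such runs are
  reproducible.
- One profile label per cell is assumed implicitly: if Leiden splits
  one biological type into several labels, a centroid claims only
  molecules of its own label and the rest of the cell is missed. The
  centroid-merging step mitigates this for well-separated profiles.
- Cells of the same type in direct contact are separated only by
  geodesic distance, not expression; the boundary between them is
  approximately equidistant, as for any distance-based method.
- The label-constrained Dijkstra runs per label with all same-label
  centroids as sources; paths may in principle pass through another
  same-label centroid node, which can only shorten distances toward
  that centroid and therefore does not change the argmin except in
  exact-tie edge cases.
- No polygon/mask reconstruction of cell boundaries is attempted; the
  output is the molecule-to-cell assignment and the count matrix.
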