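# comseg

Shape-agnostic assignment of RNA molecules to cells for imaging-based
spatial transcriptomics (smFISH, MERFISH, HybISS, ...), using only the
detected RNA coordinates and the nucleus positions. The package also
ships a synthetic-tissue simulator with full ground truth and the
benchmarking metrics used to score any molecule-to-cell assignment, so
the whole method can be exercised and validated without experimental
data.

## Who this is for

Imaging-based spatial transcriptomics yields a point cloud of RNA
molecules (x, y, z, gene) plus a nuclear stain, but no reliable
cytoplasm boundary. Classical segmentation assigns each molecule to the
nearest nucleus, which implicitly assumes convex, roundish cells and
fails badly on elongated or interlocking shapes found in real tissue.
This package groups molecules by the *expression of their local
neighborhood* instead of by raw distance, so cells of different types
can be separated even where their territories interdigitate.

## The method

Given a point cloud with genes g and two physical hyper-parameters —
the mean cell diameter *D* and the maximum cell radius *R*<sub>max</sub>
(µm) — the pipeline runs five steps:

1. **Proximity-weighted expression.** For each molecule *x* and gene
   *g*, sum a linearly decaying kernel over the ≤ 40 nearest neighbors
   *y* within *R*<sub>PE</sub> = D/2:

   V<sub>g</sub>(x) = Σ<sub>y ∈ KNN(x), gene(y)=g</sub> (R<sub>PE</sub> − ‖x−y‖) / R<sub>PE</sub>

   Stacking V(x) gives the PE matrix V ∈ ℝ^(N<sub>x</sub>×N<sub>g</sub>).
2. **Co-expression matrix.** w<sub>ij</sub> = Pearson correlation of
   columns i and j of V. Genes expressed in the same cells correlate
   positively; genes of different cell types correlate negatively. An
   external matrix (e.g. from scRNA-seq) can be supplied instead.
3. **Weighted KNN graph + constrained Louvain.** Molecules become graph
   nodes (K = 10 neighbors, max edge length D/4); each edge carries the
   co-expression weight w<sub>g_u,g_v</sub> and its Euclidean length.
   All molecules inside one nucleus are contracted into a "cell node",
   and a modified Louvain maximizes modularity

   Q = 1/2m Σ<sub>u,v</sub> [w<sub>g_u,g_v</sub> − k<sub>u</sub>k<sub>v</sub>/2m] δ(C<sub>u</sub>, C<sub>v</sub>)

   over positively weighted edges, under the constraint that two cell
   nodes never share a community.
4. **In-situ clustering.** Each community C gets the mean PE vector
   V<sub>C</sub> = 1/#C Σ<sub>x∈C</sub> V(x); communities of ≥ 3 RNAs
   are Leiden-clustered in expression space into profile labels
   L<sub>i</sub> (the *transcriptomic domain map*); smaller communities
   inherit the majority label of their nearest labeled neighbors.
5. **Geodesic assignment.** Every nucleus centroid takes the label of
   its nuclear RNAs (or a local majority vote if it has none) and
   claims same-label molecules by shortest-path (Dijkstra) distance
   through the graph with Euclidean edge lengths. Molecules farther
   than R<sub>max</sub> from every same-label centroid stay unassigned.
   Geodesic rather than straight-line distance is what lets non-convex
   cells claim their distant arms.

The output is a molecule-to-cell assignment plus a sparse cells × genes
count matrix.

## Worked example

Simulate a small tissue of interlocking L-shaped cells of two cell
types (five exclusive marker genes each), drop 20 % of the nuclei to
mimic sectioning losses, then segment and score:

```python
import numpy as np
from comseg import ComSegConfig, ComSegModel
from comseg import evaluate as ev
from comseg import simulate as sim

tissue = sim.simulate_lshapes(8, seed=0)
model = sim.ExpressionModel.marker_panel(n_types=2, markers_per_type=5, mean_count=5.0)
tissue = sim.sample_expression(tissue, model, seed=0, types=np.arange(tissue.n_cells) % 2)
tissue = sim.place_rna(tissue, seed=1)
tissue = sim.drop_nuclei(tissue, 0.2, seed=2)

cfg = ComSegConfig(mean_cell_diameter=34.0, max_cell_radius=52.5, seed=0)
results = ComSegModel(tissue.cloud, tissue.nucleus_landmarks(), cfg).fit()
print(results.summary())

gt = ev.GroundTruth.from_simulation(tissue)
report = ev.jaccard_wa_ms(gt, results.assignment)
baseline = ev.jaccard_wa_ms(
    gt, ev.watershed_baseline(tissue.cloud, tissue.nucleus_landmarks(), max_distance=52.5)
)
print(f"ComSeg    J={report.mean_jaccard:.3f}  WA={report.mean_wa:.3f}  MS={report.mean_ms:.3f}")
print(f"Watershed J={baseline.mean_jaccard:.3f}  WA={baseline.mean_wa:.3f}  MS={baseline.mean_ms:.3f}")
```

which prints

```
ComSeg segmentation results
===========================
molecules:            678
genes:                10
cells (nuclei):       7
assigned molecules:   640 (94.4%)
unassigned molecules: 38
communities:          20
profile labels:       2
modularity Q:         0.9005
mean counts per cell: 91.43

ComSeg    J=0.783  WA=0.121  MS=0.111
Watershed J=0.445  WA=0.400  MS=0.367
```

The 678 molecules fall into 20 graph communities whose expression
vectors cluster into the 2 planted profile labels. Per ground-truth
cell, J is the Jaccard overlap between true and predicted molecule
sets, WA the fraction of a predicted cell's molecules that belong
elsewhere (false discovery), and MS the fraction of a true cell's
molecules that were missed. On these interlocking shapes, the
nearest-nucleus (watershed/Voronoi) baseline wrongly grabs ~40 % of
each cell's molecules, while the graph method keeps both error rates
near 11–12 %.

## Command line

```bash
comseg simulate --scenario lshape --n-cells 32 --dropout 0.2 --out sim/ --seed 1
comseg segment  --points sim/points.csv --nuclei sim/nucleus_mask.tif \
                --diameter 34 --rmax 52.5 --voxel-size 0.15 0.15 1.0 --out seg/
comseg evaluate --pred seg/assignment.csv --truth sim/points.csv --out report.json
comseg coexpr   --points sim/points.csv --diameter 34 --out W.csv
```

`segment` writes the per-molecule assignment table, the MatrixMarket
count matrix with cell/gene index files, and a JSON manifest with the
full configuration.

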