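# simplicomplex

Unmixing bulk tumor genomic data with simplicial complexes.

Bulk genomic assays (RNA-seq expression, copy number, methylation) measure a
mixture of cell populations: normal stroma, immune infiltrate, and one or
more tumor subclones.  Mixed-membership ("unmixing", archetype-analysis)
methods model each tumor profile as a convex combination of unobserved pure
cell-population profiles, so a cohort of tumors forms a point cloud inside a
simplex whose corners are those profiles.  When tumors evolve along the
branches of a common evolutionary tree, each tumor mixes only the cell
states on *its* branch — the point cloud is not one simplex but a **union of
low-dimensional subsimplices glued along shared faces** (shared ancestral
populations): a simplicial complex.  Exploiting this structure lets the
geometry be fitted branch by branch in low dimension, and the glue pattern
itself reads out as a tree over cell populations.

This package is for computational biologists working with a processed
genes × samples matrix who want per-sample mixture fractions, pure-component
expression signatures, and a candidate evolutionary tree among components.

## Model

Given `M ∈ R^{g×s}` (genes × samples, Z-scored per gene), find components
`C` and fractions `F` (columns nonnegative, summing to 1) with
`M ≈ Cᵀ F + ε`.  The pipeline:

0. **Reduce**: PCA to g′ dimensions (default 10) with an exactly invertible
   basis/offset pair.
1. **Cluster**: build the complete graph on samples with squared-Euclidean
   edge weights; shortest-path lengths approximate geodesic distance along
   the cloud, separating subsimplices that are contiguous in space but span
   different subspaces.  Partition with k-medoids (medoid = data point
   nearest its cluster's Euclidean mean).
2. **Unmix each cluster**: fit a bounding simplex `K` by alternating exact
   simplex-constrained least squares for `F` with bounded quasi-Newton
   descent on

   `min_K  Σ_j ‖x_j − K f_j‖_p + γ · log(mst(K))`

   where `mst(K)` is the minimum-spanning-tree length over the vertices — a
   tree-parsimony prior that keeps penalties of different-dimensional
   subsimplices in the same (log-length) units.  Defaults γ = 10, p = 1
   (heavy-tailed noise); the classical `log(vol(K))` penalty is available.
   Ten bootstrap refits give each vertex a positional mean and sd.
3. **Merge**: vertices (within or across clusters) closer than the sum of
   their bootstrap sds are the same population; connected components of this
   relation are merged, gluing the subsimplices into one complex.
4. **Back-project**: merged vertices map through the PCA basis to gene-space
   signatures; fractions are re-solved per sample against its own (merged)
   subsimplex, so components outside a sample's branch are structural zeros.

A minimum spanning tree over the merged vertices is reported as the inferred
phylogeny among cell populations.

## Worked example

Simulate a cohort of 300 tumors from two subtypes, each mixing three cell
populations with one shared ancestral state (two triangles joined at a
point), then unmix:

```python
import simplicomplex as sx

spec = sx.ScenarioSpec(name="C_two_triangles_point", n_samples=300,
                       ambient_dim=600, noise_level=0.1, seed=0)
em, truth = sx.make_scenario(spec)

model = sx.SimplicialComplexModel(em, k_clusters=2)
res = model.fit(seed=0)
print(res.summary())
```

```
Simplicial complex unmixing results
===================================================
samples: 300   genes: 600   PCs: 10   seed: 0
clusters: 2   vertices per cluster: [3, 3]   merged components: 5

 component   cluster(s)         sd  mean fraction
---------------------------------------------------
        v0            0     1.9857         0.1639
        v1            0     1.0169         0.1744
        v2          0,1     2.5524         0.3632
        v3            1     3.1189         0.1412
        v4            1     2.0294         0.1573
---------------------------------------------------
cluster 0: n=161  objective=263.8617  B=10
cluster 1: n=139  objective=231.4206  B=10
shared vertices: [2]
tree (MST): (v2:67.35378634,v3:67.56194097,(v1:67.38846375)v4:65.69321659)v0;
```

The pipeline recovered the true structure: five components forming two
three-vertex subsimplices sharing component `v2` — the ancestral population
present in both subtypes (hence its large mean fraction).  Each component's
`sd` is its bootstrap positional uncertainty in the reduced space;
`res.components` holds the gene-space signatures, `res.fractions_frame()`
the per-tumor mixture proportions, and `res.tree.to_newick()` the component
tree.  `res.save("out/")` writes components.tsv, fractions.tsv,
complex.json, tree.nwk and report.json.

The same pipeline is available from the shell:

```sh
unmix simulate --scenario C --n 300 --dim 600 --noise 0.1 --seed 0 --out data/
unmix run --input data/matrix.tsv --k 2 --seed 0 --out results/
```

## Limitations

Samples are hard-assigned to one subsimplex, so a component absent from a
sample's branch gets exactly zero fraction — wrong when, e.g., immune
infiltration affects all tumors.  Vertex merging compares systematic
position differences against bootstrap *variance*; biases from cluster
boundary placement or sparse corner sampling are not covered by it, so
shared vertices can stay unmerged (see `docs/methods.md` for when this
bites).  The fit is a seeded local search with no global guarantees.
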