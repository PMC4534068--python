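# Methods

## Model and assumptions

Each sample (tumor) profile is modelled as a noisy convex combination of a
small number of unobserved pure cell-population profiles.  Two structural
assumptions go beyond ordinary archetype analysis:

1. **Branch structure.** Samples fall into groups (subtypes) that mix only
   a subset of the populations — geometrically, the cohort occupies a union
   of low-dimensional simplices rather than one high-dimensional simplex.
2. **Shared ancestry.** Different groups share some populations (ancestral
   states), so the subsimplices are glued at shared vertices or faces, and
   the glue pattern carries the evolutionary relationship among populations.

Measurement noise is assumed additive, independent per gene, and
heavy-tailed: the per-point residual enters the objective through an L1
norm by default (`p=1`), the choice implied by log-Laplacian noise; `p=2`
is available for log-Gaussian noise.

## Pipeline stages and parameters

**Z-scoring.** Each gene is centred and scaled to unit sample variance
(ddof=1).  Constant genes have no Z score; they are dropped by default
(`constant_gene_policy="drop"`) or zeroed.  Missing values are a load-time
error: the model assumes complete matrices.

**PCA (`n_pcs`, default 10).** Samples are observations, genes features;
only the per-gene mean is removed (it becomes the reconstruction offset),
so the reduced coordinates remain in Z-score units.  Ten components
slightly upper-bound the number of populations typically sought; the
alternative rule g′ = k − 1 (one less than the target component count) can
be applied by passing `n_pcs` explicitly.  Axis signs are fixed (largest
absolute loading positive) for bit-reproducible runs.

**Geodesic clustering (`k_clusters`, `n_restarts`=20).** The complete graph
on samples is weighted by *squared* Euclidean distances and all-pairs
shortest paths are computed exactly (Floyd–Warshall).  Squaring makes one
long hop dearer than many short ones, so path length approximates distance
travelled through the cloud: within one subsimplex it matches straight-line
distance, across subsimplices it is longer.  k-medoids under this metric
separates branches; the medoid update (cluster member nearest the cluster's
Euclidean mean) keeps centers inside the data's subspaces.  `k` is the
user's call, informed by `cluster_count_scan`, which reports the variance
of cluster sizes across seeded replicates for each candidate `k` (low,
stable variance suggests a natural partition; the scan is a coarse guide,
not a selector).

**Simplex fitting (`gamma`=10, `p`=1, `penalty`="mst").** Each cluster gets
a bounding simplex minimising
`Σ_j ‖x_j − K f_j‖_p + γ·log(mst(K))`.
The log-MST-length prior plays two roles: it regularises against runaway
vertices (a parsimony prior over the tree connecting the vertices), and it
puts subsimplices of different dimension on a common penalty scale so that
sub-fit costs can be summed into one complex-level score — log-volume
penalties of different dimensions are not commensurable.  γ = 10 matches
measurement noise in the low tens of percent; the γ-scan study shows vertex
recovery is essentially flat over γ = 1..15.  Natural logarithms are used
throughout.

Optimisation alternates:

- *F-step*: exact per-point simplex-constrained least squares, solved by
  active-set enumeration (the optimum restricted to its support solves the
  equality-constrained system on that support; with ≤ 8 vertices
  enumerating supports is cheap and exact).  The subproblem is least
  squares even when the reported objective uses p = 1, mirroring the
  described algorithm; the reported objective always uses the configured
  norm.
- *K-step*: L-BFGS-B on the vertices with analytic subgradients for both
  the residual and the MST term (the MST topology is recomputed each
  evaluation; gradient contributions flow along current tree edges), with
  vertex coordinates bounded to the data bounding box inflated by 20%.

Rounds are accepted only when the reported objective improves, so the
objective history is non-increasing by construction; iteration stops when
the improvement falls below `tol` (absolute, 1e-6) or `rel_tol` × objective
(1e-4 — the objective scales with n·g′, so a purely absolute tolerance
makes the tail crawl through ~100 rounds that move vertices by < 0.1%).
`fit_simplex` defaults to 200 rounds; the pipeline uses 30, which the
structure-recovery study showed is indistinguishable from 60 on all four
benchmark scenarios.

**Initialisation.** A minimum-volume-enclosing-simplex style guess: the
cluster's points are projected onto their own top (m−1) principal axes,
vertices are seeded by successive farthest-point selection, and then each
facet is repeatedly translated along its outward normal until it touches
the extreme point on its side (outward where points protrude, inward where
there is slack).  The facet-intersection vertices extrapolate beyond the
sampled extremes toward the true corners, which matters because flat
mixing leaves simplex corners sparsely sampled.  Degenerate requests
(m − 1 above the cluster's affine rank) raise an error directing dimension
reduction.

**Vertex-count heuristic (`eigen_threshold`=0.05).** Per cluster,
m = 1 + the number of covariance eigenvalues holding more than 5% of the
cluster's variance, capped by dimension and cluster size.  A simplex
spanning a q-dimensional set needs q+1 vertices; the threshold separates
structure from noise eigenvalues at low-to-moderate noise but will
undercount when noise approaches the signal scale.

**Bootstrap and merging (`B`=10).** Each cluster is refit on B resamples
(with replacement, same size); replicate vertex sets are aligned to the
first replicate by minimum-cost assignment.  A vertex's positional sd is
the rms deviation of its position across replicates (square root of the
summed per-dimension variances) — a *distance-scale* quantity, directly
comparable to the Euclidean separations the merge rule tests.  Two
vertices merge when their separation is at most the sum of their sds; the
relation's connected components become merged vertices (position = mean of
members, sd = max of members), within-cluster merges allowed.  Merging at
exact equality (≤) makes the boundary deterministic.

**Fraction refit and back-projection.** Merging moves vertices, so each
sample's fractions are re-solved against its cluster's merged vertex set;
components outside a sample's subsimplex are exactly zero by construction.
Merged vertices map to gene space as `K·basis + offset`.

**Phylogeny.** Kruskal's MST over merged vertex positions with ties broken
lexicographically; exported as an edge table and as Newick rooted at the
highest-degree vertex (lowest id on ties).

**Degeneracy guards.** `log(mst)` is floored at `log(1e-9)` during line
searches so a transiently collapsed candidate does not produce −∞; a final
model at the floor is flagged non-converged.  Zero-length MST edges
(coincident vertices) are handled explicitly — including in the geodesic
graph, where coincident samples are kept as zero-weight edges rather than
dropped.

## The synthetic benchmark

Four scenarios emulate cohorts sampled from two-branch evolutionary trees:
two segments sharing an endpoint (3 vertices), two tetrahedra sharing a
vertex (7), two triangles sharing a vertex (5), and two triangles sharing
an edge (4).  Vertices are i.i.d. spherical Gaussian in the ambient space
(scale 1.0); each sample picks a branch uniformly and mixes that branch's
vertices with flat Dirichlet(1, …, 1) weights; noise is per-dimension
Gaussian with sd = `noise_level` × the per-dimension sd of the noiseless
mixture.  Defaults: 400 samples; ambient dimension 25,000 (matching
genome-scale probe counts), reduced to 2,000 in the packaged studies —
after per-gene Z-scoring all geometry scales with √dim, so ratios of
errors, gaps and uncertainties are dimension-stable and 2,000 keeps every
study desk-sized.  The γ-scan study uses 1,000 samples and 3 replicates
per γ for the same reason.

What the generator does *not* emulate: library-size and batch effects,
gene–gene correlation, count noise, unequal subtype prevalence, and any
corner-weighted mixing (real cohorts contain near-pure samples; flat
Dirichlet makes near-pure samples rare).  Passing tests therefore show the
geometry engine works under the stated generative model, not that the
biological assumptions hold on real cohorts.

## Known limitations

- **Bias vs. variance in merging.**  The merge rule compares vertex
  separations against bootstrap *variance*.  Two systematic biases are not
  covered: the k-medoids cut between branches can land away from the true
  joint (truncating one cluster's data short of the shared vertex), and
  flat-Dirichlet corner sparsity pulls every vertex estimate toward its
  own cluster's interior.  Both fits' objectives genuinely prefer these
  biased positions (checked directly: the fitted objective is lower than
  the objective at the true vertices, and the found partition's geodesic
  cost is lower than the true partition's).  Consequently shared vertices
  can remain unmerged — in the packaged studies the two-segment and
  shared-edge scenarios typically over-count (4 and 6 merged vertices
  instead of 3 and 4), while the tetrahedra and point-joined triangles are
  recovered in ~7–8 of 10 runs.  The component positions and fractions
  remain accurate; it is specifically the *identification* of shared
  vertices that is fragile.
- **Hard assignment.** Boundary samples are assigned to one subsimplex;
  their fractions on the other branch's private components are forced to
  zero.
- **Local search.** Both k-medoids and the alternating fit are seeded
  local optimisers; all results are reported under fixed seeds.
- **Sensitivity of the k scan.** Cluster-size variance is a weak signal
  for choosing `k`; it is reported as an aid, never applied automatically.
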