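# Methods

## Model overview

`somscape` treats a genes × cells expression matrix as a population of
gene profiles and learns a two-dimensional ordering of those profiles
with a self-organizing map. The trained map is then read in two
directions: column-wise, each cell's prototype components form an image
of its transcriptome (a *portrait*); and spatially, connected regions of
concerted overexpression (*spots*) mark the transcriptional programs of
specific cell types. Differentiation appears as a displacement of
overexpression from a stemness spot to tissue spots, and the package
summarizes that displacement as explicit paths in gene-state space.

The core assumptions are those of any expression-similarity analysis:
genes with similar profiles across cells belong to a common program;
differentiation changes expression smoothly enough that neighboring
modules on the map capture successive program states; and a snapshot of
many asynchronous cells covers the whole trajectory.

## Preprocessing

Counts are centered per gene: `logFC = log2(x + pseudocount) − row mean`.
Log base 2 is the convention of expression analysis; the pseudocount
(default 1) keeps zeros finite and is configurable. The signed-log
rescale used for trajectory weights is `sign(x) · log2(1 + |x|)`. A
literal signed log of `|logFC|` diverges at zero and inverts ordering on
(−1, 1); the `1 + |x|` form is monotone, odd, total on the reals, and
keeps the fold-change-1 coast-line exactly at zero, which is the property
the rescale exists for. Gene filtering (detected in ≥ `min_cells` cells)
is available but off by default.

## SOM training

Batch SOM, deterministic given the seed. Per epoch every gene is
assigned to its best-matching unit (BMU; Euclidean distance, ties to the
lowest row-major node index) and each prototype is replaced by the
Gaussian-neighborhood-weighted mean of the assigned profiles. Because the
squared grid distance separates into row and column terms, the
neighborhood smoothing is computed as two one-dimensional convolutions,
which keeps a 60 × 60 map cheap. The radius decays linearly from
`max(rows, cols)/2` to 0.5 over the epochs (default 20), so training ends
as a near-k-means refinement of an already ordered map. Prototypes are
initialized on the plane of the first two principal components of the
gene cloud — deterministic and orientation-stable — with a seeded
fallback to sampling data rows when the cloud is degenerate (fewer than
two directions of variance). The quantization error (mean gene-to-BMU
distance) is recorded per epoch; on all data exercised in the test suite
it is non-increasing, and the trained model exposes the history so users
can verify convergence.

Grid default 60 × 60 (3600 metagenes): a few thousand metagenes resolve
dozens of expression modules without the results depending on the exact
number. The test suite uses 10–20 node grids for speed; grid size is a
resolution parameter, not a model change.

## Segmentation

Spots: a node is a member if its value strictly exceeds the per-portrait
quantile threshold (default 0.98) in at least one group portrait;
8-connected (Moore) components of members are spots, each with a kernel
at the maximum of the node-wise maximum over portraits. The quantile
rule is the package's documented spot criterion; it is monotone in the
quantile and yields zero spots on constant portraits. 8-connectivity is
used everywhere on the grid, matching the visual contiguity of spots.

Space-filling segmentation: k-means (k-means++ seeding, 10 restarts,
seeded) on the prototype vectors, default k = 32. Letters are assigned
in order of descending mean metagene variance, so the most variant
tissue modules receive early letters; with k = 32 the labels run
`A … Z, A1 … F1`. Variance classes: clusters holding a spot kernel are
*spot-variant*; among the rest the least variant cluster is *invariant*
(exactly one per segmentation — if every cluster held a kernel the
globally least variant would be re-tagged); the remainder are
*low-variant*.

## Gene-state trajectories

The cluster adjacency graph links clusters with 8-neighboring member
nodes. Edge capacities are `m(c1) + m(c2) − 2·min_c m(c)` with `m(c)`
the mean signed-log expression of cluster c in the lineage portrait (the
mean portrait over all cells of the lineage: root, progenitors and
target tissue). The shift by twice the minimal cluster mean makes
capacities nonnegative without changing their order.

"Path of maximum cumulative expression" admits two readings, and both
are implemented: the default is the **widest path** (maximize the
minimum edge capacity; polynomial via max-min Dijkstra), with ties
broken by maximal capacity sum and then lexicographic cluster order; the
**max-sum path** maximizes the capacity sum outright, which is a
longest-simple-path variant and therefore restricted to graphs of at
most 40 nodes and solved by exhaustive branch-and-bound. The widest-path
tie-break enumerates simple paths inside the widest subgraph under a
500 000-expansion budget and falls back to the deterministic max-min
Dijkstra path (same bottleneck) if the budget is hit.

Topographic paths treat a portrait as elevation: heights are rescaled to
a strictly positive floor (`h − min(h) + 1e−6`; the epsilon prevents
zero-cost steps), each 8-neighbor step costs its geometric length (1 or
√2) times the mean rescaled elevation of its endpoints, and Dijkstra
finds the least-cost route. With the stem-minus-tissue difference
portrait as height the path descends along the valleys of the landscape.
Path costs are invariant under adding a constant to the height.

## Pseudotime

Cells are embedded by their portraits (one feature per metagene). The
kNN graph (default k = 15) uses adaptive Gaussian kernel weights
`exp(−d²/(σ_i σ_j))` with σ_i the distance to the ⌈k/2⌉-th neighbor;
duplicate cells receive weight 1; the graph is symmetrized by
neighborhood union. Pseudotime is the Euclidean distance from the root
centroid in the leading diffusion-map coordinates (top 10 nontrivial
eigenpairs of the symmetrically normalized transition operator, each
scaled by λ/(1−λ)), affinely rescaled so that the root minimum is exactly
0 and the global maximum exactly 1. This deterministic spectral
formulation replaces simulated diffusion random walks; both measure the
expected number of diffusion steps from the root, but the spectral form
is reproducible and directly testable. Eigenvector signs are fixed by
making the largest-magnitude entry positive. If the graph has several
components the largest is used (with a warning) and stranded cells
receive pt = 1; a graph in which every edge has weight 1 (all connected
cells identical) is rejected as degenerate. Branch membership is taken
from the user's cell annotations, not inferred.

Module expression along pt is summarized per lineage by the mean
portrait value over a spot's nodes versus pt, with a LOESS curve
(tricube-weighted local regression, span 0.5) as a guide; with fewer
than 5 cells only points are returned.

## RNA velocity

γ is fitted per gene as the through-origin least-squares slope of
unspliced on spliced over the cells in the bottom and top `quantile`
(default 0.05) of the gene's spliced abundance, where expression is
nearest steady state; genes with all-zero selected spliced values are
flagged unfittable and excluded. Velocity is the residual `v = u − γ s`.
Kinetic rates beyond the γ/β ratio are not modeled.

The projection of a metagene's high-dimensional velocity vector onto a
2-D grid arrow is the package's bridging construction: for each
8-neighbor, the Pearson correlation between the node's velocity vector
and the prototype difference toward that neighbor weights the unit grid
direction; positive contributions are summed and divided by the total
positive weight. Arrows therefore have length ≤ 1 grid unit, shrink when
positively correlated directions disagree, and vanish at zero velocity
(below a 1e−9 numerical floor, guarding the exact-steady-state case),
when no neighbor correlates positively, or when a correlation is
undefined. Magnitudes are not comparable across metagenes after
averaging different member counts, which is why the normalization is by
weight rather than by velocity magnitude.

Attractors are nodes whose arrow is shorter than `tol` (default 1e−3)
and whose summary expression strictly exceeds all 8 neighbors
(strictness keeps flat background from flooding the list). Streamlines
are forward-Euler integrations of the bilinearly interpolated field
(step 0.5 grid units, max 500 steps, stopping at vanishing flow or the
boundary); each start is assigned to the basin of the attractor nearest
its endpoint, and starts whose 8-neighborhood drains to a different
attractor are marked watershed and left unassigned.

## Enrichment

Module gene lists are tested against GMT gene sets with the
hypergeometric upper tail (population = analysis universe); p-values are
Benjamini–Hochberg corrected across sets within each module, and raw p,
FDR and log10 p are all reported. The gene set Z-score per cell group is
the one-sample Z of the set's mean against the all-gene background:
`(mean_set − mean_all) / (sd_all / √n_set)` on per-gene group means; it
is zero for the whole-universe set and undefined (NaN, flagged) for a
zero-variance background.

## Synthetic data

The generator emulates a stem → multi-tissue differentiation snapshot:
each cell has a uniform latent time t ∈ [0, 1] and a lineage; the stem
module follows the activation weight (1 − t)², each tissue module t² in
its own lineage (quadratic curves give the smooth "lava-lamp" transition;
the exponent is configurable); 65% of genes are invariant, matching the
dominant invariant fraction typical of whole-organism snapshots. Counts
are negative binomial around μ = baseline · (1 + a · w) with baseline ~
LogNormal(ln 3, 0.8) (a few counts per cell, scRNA-seq-like), amplitude
a ~ U(2, 5), and gamma-Poisson shape 0.5 (strong overdispersion;
infinite shape gives the Poisson limit). Spliced/unspliced abundances
are the exact closed-form solution of `du/dt = α(t) − β u`,
`ds/dt = β u − γ s` with β = 1, γ ~ U(0.3, 0.8), α switching on at t = 0
for rising modules and off for the stem module, evaluated at kinetic
time 4t so mid-trajectory cells are clearly unsteady; a steady-state
mode sets u and s to the quasi-static fixed point of each cell's current
rate, making `u = (γ/β) s` hold identically. Defaults: 800 cells, 2000
genes, 2 lineages, seed-reproducible to the bit.

What the generator does not emulate: ambient RNA, doublets, batch
effects, library-size variation, branching progenitors shared between
lineages, or measurement noise on the spliced/unspliced layers. Passing
tests therefore demonstrate correctness of the algorithms under the
stated generative model, not robustness to every artifact of real
droplet data.

## Problem sizes

The test suite trains 10–20 node-per-side maps on a few hundred genes;
the end-to-end checks use the generator defaults (800 × 2000, 20 × 20
map) and the structural default check trains the full 60 × 60 map. These
sizes were chosen so the whole suite runs in well under a minute while
exercising every stage at its default parameters.

## Known limitations

* Gene-state paths are source-to-sink only; branched gene-state trees
  are out of scope.
* The widest-path tie-break is best-effort beyond the enumeration
  budget (the bottleneck value itself is always exact).
* The velocity grid projection is a reconstruction of how embedding
  projections work, applied to the SOM grid; no reference construction
  exists for gene-state space.
* Pseudotime assumes a connected landscape dominated by one
  differentiation axis; widely separated cell islands reduce it to a
  per-component ordering.
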