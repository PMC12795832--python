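# Methods

This note documents the models and procedures implemented in `cellplast`,
the defaults they use, and the choices made where the design was open.

## Input processing

Spliced and unspliced counts live on one cells × genes grid
(`CountMatrixPair`; MatrixMarket + TSV sidecars or a single HDF5 container).
QC removes cells with fewer than 100 detected genes (count > 0) **or** more
than 20 % mitochondrial reads (genes matched by the case-insensitive prefix
`mt-`), then genes detected in fewer than 20 of the remaining cells. Both
rules are strict on the "remove" side: a cell with exactly 100 genes, or a
gene in exactly 20 cells, is retained. All masks are computed on the spliced
layer — the standard notion of "expression" — and applied to both layers, so
the pair stays aligned; the filter is idempotent and order-preserving.
Normalization scales each cell's spliced counts to a common depth of 10,000
followed by natural log1p (the ecosystem default); the result is
depth-invariant by construction. Mitochondrial-fraction regression before
scaling is deliberately not performed; clustering, embedding (PHATE or
similar) and batch correction are upstream inputs, not part of this package.

## CCAT entropy (Valley)

CCAT is the per-cell Pearson correlation between normalized log expression
and protein-interaction-network degree, over the intersection of the
expression panel and the degree table (≥ 3 genes required). It is invariant
to positive scaling and constant shifts of a cell's profile. Cells with zero
expression variance over the shared genes are undefined and **excluded** from
group medians rather than imputed as 0, which would bias small clusters
toward the middle of the scale. Cross-species degree tables are supported
through a user-supplied two-column ortholog map (`map_gene_ids`); no ortholog
database is bundled. The Valley component of a (sample, cluster) group is the
plain median of its defined CCAT values, unscaled.

## Velocity lengths (Ridge, factor 1)

Velocity is modelled with the steady-state approximation: for each gene, the
cells in the upper `extreme_quantile` (default 5 %, inclusive threshold) of
total spliced + unspliced abundance are assumed to be at transcriptional
equilibrium, and the splicing ratio γ is the least-squares slope through the
origin, γ = Σu·s / Σs², on that subset (clipped at 0; genes with Σs² = 0 or
fewer than 10 total counts are excluded). Per-cell velocity residuals
v = u − γ∘s are computed on raw counts (the steady-state model's native
scale) and the velocity length is the L2 norm of v over fitted genes, taken
in gene space. Gene space rather than an embedding projection was chosen
because only the magnitude — low at attractors, high in transit — feeds the
Ridge; an embedding projection would entangle the length with local embedding
geometry. kNN smoothing of u and s is intentionally left out of the default
path for the same reason: the group median used downstream is already robust.

## Centrality distance (Ridge, factor 2)

Within each (sample, cluster) group on the embedding: a cell's local density
proxy is the inverse mean distance to its k nearest neighbours
(k = max(5, round(0.05·n)), capped at n − 1; 1 for singletons); the group's
densest cell is its medoid (ties broken by lowest cell id); each cell's raw
distance is the Euclidean distance to that medoid, min-max scaled to [0, 1]
within the group (a geometrically constant group scales to all 0). The
medoid-of-density definition is this package's own operationalization of
"cell centrality distance": it is invariant under rigid motion of the
embedding, exact against an O(n²) brute-force check, and size-adaptive
through k. Degree-weighted alternatives can be slotted in behind the same
contract.

## Valley–Ridge combination

Inverse velocity lengths 1/L (with L = 0 capped at the largest finite
inverse in scope before scaling) and the scaled centrality distances are
min-max scaled across the **global** scope — all cells of all samples
jointly — so VR scores are comparable across the two conditions being
contrasted; a `per_sample` scope is available. The Ridge of a group is the
product of the two group medians (median scaled inverse velocity × median
scaled centrality distance), which keeps Ridge ∈ [0, 1]; taking the median
of per-cell products is exposed as an option (`ridge_aggregation`). VR =
0.9·Valley + 0.1·Ridge by default, so VR ∈ [−0.9, 1.0]. Apexes are clusters
ranked by VR descending per sample; cross-sample differences are reported
per shared cluster as both ΔVR and ΔValley (Δ median CCAT), since either can
be read as the "Δentropy" of a landscape comparison, and sample-unique
clusters are listed separately. The landscape grid rasterizes per-cell VR
(each cell carries its group's score) as a Gaussian-kernel weighted mean on a
regular grid (default 64², bandwidth 5 % of the embedding diagonal, 5 %
bounding-box padding); zones beyond kernel reach take the scope minimum VR so
they render as low ground. 3-D rendering is out of scope — the grid is the
exported artifact.

## Composition, gene-set scores, cell cycle

Cluster proportions are counted per sample over the union of clusters
(absent clusters get 0), and differences between two samples are absolute
Δproportions (they sum to 0 over the union); fold changes are reported with
0-denominators flagged rather than silently dropped. Gene-set scores follow
the binned-control scheme: genes are ordered by mean expression (ties broken
by gene id), cut into 25 nearly equal bins, and for every bin containing a
set gene 50 control genes are sampled without replacement (the whole bin if
smaller) with a seeded generator; the score is mean(set) − mean(controls)
per cell. The protocol is implemented in-package so that it is exactly
reproducible and testable to machine precision; it matches the ecosystem's
behaviour qualitatively (cross-checked against scanpy in the test suite).
Cell-cycle phases use two user-supplied lists (S, G2/M): both scores
negative → G1, otherwise the larger score wins with exact ties broken toward
S. No reference gene lists are bundled.

## Spatial label transfer and clone heterogeneity

scRNA-seq cluster centroids are per-gene means of normalized log expression.
Each spatial unit is Spearman-correlated (average ranks, the standard tie
policy) against every centroid over the genes shared between the spatial
panel and the reference — recomputed and logged per run, since in-situ panels
are small subsets; at least 50 shared genes are required. The best cluster
(ties → lowest cluster id) is assigned only when ρ **strictly** exceeds 0.5;
everything else is flagged unassigned. Cluster centroids (not per-cell
references) are the default comparison target: they are stabler at the small
panel sizes of in-situ assays; a per-cell reference can be emulated by
passing single-cell "centroids". Per-clone composition over retained units
is summarized as richness (distinct clusters) and Shannon entropy in nats
(≤ ln richness, with equality at uniformity).

## Synthetic data

The simulator generates what the analysis assumes, with ground truth
attached, and is the basis of the recovery benchmarks:

* **Topology.** Default tree c0 → {c1, c2}, c1 → c3, c2 → c4 shared by two
  samples ("WT", "KO"), plus root cluster c5 present only in KO — 5–6
  clusters and 200 cells per cluster per sample (~1,000–1,200 cells/sample),
  800 genes.
* **Degrees and programs.** Degrees are lognormal(0, 1) with 10 % of genes
  boosted ×8 into hubs. Root-cluster mean expression is ∝ degree^α (α = 1)
  mixed with a small (15 %) cluster-specific 40-gene marker program — enough
  to make distinct root states distinguishable without destroying their
  hub correlation; internal clusters mix the hub program at weight
  0.8·(1 − depth/max depth); leaves are pure marker programs, uncorrelated
  with degree. CCAT therefore decreases from root to leaf by construction.
* **Two-regime kinetics.** Per-gene γ ~ U(0.2, 1); steady-state cells (roots
  and leaves — the attractors) draw unspliced means γ·μ, transitional cells
  (internal clusters) draw 3·γ·μ. The ×3 surplus puts transitional velocity
  lengths a factor ≳ 2 above steady-state noise, giving the Ridge a real
  signal to detect.
* **Counts and embedding.** Negative-binomial counts with dispersion 0.5
  (var = μ + 0.5μ²), library ≈ 2,000 (lognormal 10 % spread); embedding =
  tree-layout positions (unit spacing) + Gaussian jitter σ = 0.22.
* **Spatial section.** Units sample a cluster from their clone's mixing
  proportions and draw NB counts from that cluster's program restricted to a
  150-gene panel (the genes most variable across cluster programs), at depth
  ≈ 500 — emulating a targeted in-situ panel over a multi-clone tumor
  section.

What the simulator does **not** emulate: gene-regulatory correlation
structure, doublets, ambient RNA, batch effects, continuous within-cluster
pseudotime gradients, or realistic embedding geometry from an actual
manifold learner. Passing recovery tests therefore show that the pipeline
recovers planted root states under the model's own assumptions — not that it
would do so on arbitrary real data.

## Benchmarks and numerical conventions

The recovery benchmark runs 20 independent simulations at the defaults and
requires the planted root to top the VR ranking in ≥ 18, and the KO-unique
root to reach KO's top 3 in ≥ 16 (currently 20/20 on both). These problem
sizes keep a full suite run around ten seconds while leaving the per-cluster
medians well determined.

Conventions for degenerate input: min-max scaling of a constant vector gives
0s; 1/L at L = 0 is capped at the scope's largest finite inverse before
scaling; constant-rank spatial profiles have no defined correlation and are
never retained; medoid and argmax ties break toward the lowest id; group
medians use the mean-of-central-pair rule for even sizes. Oracle-equivalence
tests hold to 1e-12 (exact for medians and counts).
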