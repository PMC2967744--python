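# Methods

## Overview

`phenolink` implements a three-layer network discovery procedure for
translational data: a gene co-expression layer mined across multiple
expression datasets, a clinical feature correlation layer from binned
encounter data, and a knowledge-anchored conceptual layer built by
constructive induction over an ontology. The layers are joined by
semantic cross-links and searched for vertical biomarker–phenotype
complexes. The original study data (expression series retrieved from a
public repository, a private clinical repository extract, licensed
biomedical ontologies, and human expert ratings) are not redistributable,
so a first-class synthetic-data module reproduces the statistical
structure each stage assumes; all reported quantities are recomputed on
those synthetic inputs or on the packaged worked-example fixture.

## Synthetic data model

**Expression panels.** Each planted module *m* is a single latent factor:
for sample *j*, member gene *g* takes
`x[g,j] = loading_g · f_m(j) + δ_g · y(j) + ε`, with `f_m(j) ~ N(0,1)`
per sample, `loading_g ~ U(lo, hi)` per dataset, `ε ~ N(0, noise_sd²)`,
`y(j) ∈ {0,1}` the phenotype label and `δ_g` the phenotype effect size
for designated effect genes. Background genes are N(0, 1) noise. A single
factor per module was chosen because the mining stage assumes only that
module genes share expression profiles; the factor model gives direct
analytic control of the within-module correlation
`ρ ≈ loading²/(loading² + noise_sd²)` and hence of how hard recovery is.
Datasets in a panel share the gene universe and module membership but
draw independent factors, loadings, labels and noise — emulating
independent studies of the same biology. What this does **not** emulate:
probe-level effects, batch/platform effects, heavy-tailed expression
distributions, or correlated background structure; passing recovery tests
therefore demonstrates algorithmic correctness at a controlled
signal-to-noise ratio, not robustness to microarray artifacts.

**Encounter tables.** Correlated variable blocks are realized through a
latent Gaussian copula. A Spearman target ρ_s is converted to the latent
Pearson correlation `r = 2·sin(π·ρ_s/6)` (exact for bivariate normals),
the block is drawn from the corresponding multivariate normal, and
categorical variables are produced by thresholding latents at
equal-probability quantiles. Nulls are placed completely at random; the
original repository's missingness mechanism is undocumented, so no
informative missingness is modeled. Continuous variables with a declared
(low, high) reference range are scaled so roughly two-thirds of values
fall inside the range.

**Ontologies.** A rooted is-a tree (breadth-first filled, so a complete
b-ary shape whenever the concept count allows) plus a configurable number
of random associative relations. Synonyms are token permutations of the
generated names, and a mapping file pairs synthetic data-dictionary
element names with leaf concepts so the lexical mapper has signal.

Every generator is a pure function of its arguments including the integer
seed.

## Gene layer

Anchor lists collect genes whose Pearson ρ against an anchor gene passes
a threshold (default 0.4) with the requested sign. Overlap between two
anchor lists is tested with a one-sided (over-representation)
hypergeometric test: `p = P(X ≥ overlap)` drawing |B| from a universe
containing |A| successes. The published worked examples print 0.263 and
0.0543 for two of the four rows; the one-sided convention reproduces
1 and < 1e-6 exactly for the extreme rows and 0.218 / 0.050 for the
moderate rows. The residual 0.004–0.045 discrepancy is attributable to an
unstated 2×2 construction or tail convention in the original analysis;
we keep the over-representation tail because enrichment is the question
being asked.

Per-dataset graphs connect gene pairs at |ρ| ≥ 0.75 (constant-expression
genes are dropped with a logged count); the summary graph keeps edges
present in ≥ 4 datasets, recording support counts and supporting dataset
identities.

**Dense-subgraph mining.** The miner extracts subgraphs with connectivity
ratio `r = L/(n(n−1)/2)` above a floor (default 0.4) by deterministic
greedy peeling: within each connected component, repeatedly remove the
minimum-degree vertex (ties broken by lexicographic gene order) while
recording the density of every remaining vertex set; the densest snapshot
of at least `min_size` vertices (ties: larger set, then first
encountered) is emitted as a module if its r exceeds the floor, its
vertices are removed, and the remainder is re-mined, so one component can
split into several modules. This choice makes the miner fully
deterministic and oracle-testable: on structured motifs (cliques with
satellites, bridged cliques, barbells, shared-vertex cliques, cycles,
stars, paths) it reaches exactly the decomposition found by exhaustive
subset search. **Known limitation:** min-degree peeling is a greedy
heuristic; on unstructured sparse random graphs its best snapshot can
miss the globally densest subset (e.g. an off-path triangle), which the
test suite documents by asserting only the density bound and the module
invariants there. Co-expression summary graphs at a 0.75 correlation
threshold are strongly clique-like, which is the regime the procedure
targets.

A second-pass coherence filter scores each module by the mean pairwise
Jaccard similarity of its edges' dataset-support sets (1.0 for modules
with < 2 edges) and keeps modules at or above `min_coherence`
(default 0.5, a midpoint chosen because no published value exists):
a coherent module's edges co-occur in the same datasets rather than being
assembled from unrelated pairwise coincidences.

**Phenotype association.** Per-gene Welch two-sample t-tests between
label groups, unadjusted at α = 0.05 by default (a Benjamini–Hochberg
switch is provided); the published analysis states only "significant
differences", so the simplest convention is the default. The classifier
is a diagonal linear discriminant — per-gene class means with pooled
per-gene variance, classifying to the nearest standardized mean —
evaluated by repeated stratified random holdout (default 20% held out,
50 repeats). "Supervised linear classifier" is otherwise unspecified;
DLDA was chosen as the standard linear choice for p ≫ n expression data.

## Clinical layer

Binning: categorical variables get one ordinal code per declared category
(declared order); with more than 8 categories, contiguous category ranges
are merged into 8 near-equal bins. Continuous variables with a reference
range are coded below/within/above; without one, tertiles. Nulls
propagate. Correlations are Spearman with average ranks, computed over
pairwise-complete observations; pairs with fewer than 20 non-null
observations (or a constant restricted column) are declared *undefined*
and reported as such — never coerced to zero. Edges require ρ ≥ 0.95
(one-sided, per the published wording; an |ρ| mode exists but is off by
default). An explicit pre-filter drops attributes that can never form a
defined correlation (fewer than 20 non-null entries overall, or constant
after binning) — the only reduction mechanism the original description
supports for its 182 → 125 attribute count.

**Coarsening attenuates rank correlation.** Discretizing a ρ_s = 0.99
latent block into tertiles yields observed Spearman ≈ 0.94 — *below* the
0.95 edge threshold — while 8-level coding yields ≈ 0.97. The demo and
acceptance blocks therefore use ordered 8-level categoricals, which is
the resolution the binning rule itself preserves; this is a real property
of rank correlation under coarse binning, not a simulation artifact.

Degree structure is summarized by a least-squares line through
(log₁₀ degree, log₁₀ count) over nonzero-count integer-degree bins, with
the Pearson correlation of those points as fit quality. No logarithmic
rebinning is applied. On 500-node preferential-attachment graphs the mean
|R| over seeds is ≈ 0.89; single replicates occasionally dip when an
isolated low-degree bin breaks the trend, so stochastic checks test the
mean.

## Conceptual layer

Elements are mapped to concepts by token-set Jaccard over case-folded,
punctuation-stripped names and synonyms (threshold 0.2 by default; a
curated element→concept mapping file can supplement the lexical matches).
Concept granularity is measured as the shortest is-a path length from any
root; the original description names the idea of granularity control but
not its metric, and shortest-path depth is the simplest well-defined
choice on a DAG. CKC generation enumerates simple relation paths between
concepts mapped from different elements with 1..`max_intermediates`
interior concepts (default 1, i.e. triplets; the packaged worked example
uses 3), keeping a path only if every interior concept is within
`granularity_delta` is-a levels of both endpoints, and deduplicating
reversed chains. Associative relations are traversed in either direction
and is-a in both directions, since published example chains mix relation
directions. Expert validity/meaningfulness ratings are pass-through
annotations, never computed.

## Integration

Semantic links between concepts: `identical` (same id, or labels
resolving to the same concept), `parent_child` (a direct is-a edge in
either direction), `sibling` (≥ 1 shared is-a parent), with precedence in
that order. Cross-linking evaluates all node pairs between the conceptual
layer (the hub) and each of the other layers; direct gene↔clinical links
are supported but off by default. Vertical complexes are simple paths
from start-layer to end-layer nodes over the union of within-layer edges
and cross-links, at most `max_len` hops (default 12, accommodating the
11-hop worked example), sorted by layers spanned (descending), length,
then lexicographic order. Because dense within-layer regions (a mined
module is near-clique) make the exhaustive simple-path set combinatorially
large, `extract_complexes` accepts a `max_paths` cap applied in
deterministic search order; the pipeline driver uses 200, while
oracle-sized fixtures run uncapped. Exports: Graphviz DOT with one
cluster per layer (read back by the package's own reader, so exports
round-trip) and Pajek .net with a .clu layer partition. Layout/energy
minimization is left to the external viewers.

## Operating point and problem sizes

The default configuration is the published operating point: anchor |ρ| ≥
0.4, graph |ρ| ≥ 0.75, clinical ρ ≥ 0.95, ≥ 4 supporting datasets,
r > 0.4, ≥ 20 non-null pairs, ≤ 8 categorical bins, 20% holdout,
α = 0.05. Synthetic runs use desk-scale sizes chosen to keep every stage
exhaustively checkable: 6 datasets × 100 genes × 40 samples with one
10-gene module (noise 0.5, phenotype shift 3 noise-sd on module genes),
500–600 encounters with a 4-variable ρ_s = 0.99 block, and 18–40-concept
ontologies. Study-scale counts from the original analysis (tens of mined
networks, a 51-gene module, thousands of CKCs, expert rating
percentages) depend on the private repositories and human raters and are
deliberately not targets; the property suites cover the same mechanisms
at recoverable scale.

## Degenerate inputs and numerical choices

Constant vectors make Pearson/Spearman undefined and are rejected or
skipped with a logged count, never silently zeroed. Modules with < 2
edges have coherence 1 by convention. Degree fits require ≥ 2 distinct
nonzero degrees. Pooled DLDA variances are floored at 1e-12 to survive
zero-variance training genes. All tie-breaks (peeling order, hub ranking,
path ordering, edge-list serialization with the lexicographically smaller
node first) are lexicographic, making every pipeline output byte-stable
under a fixed seed.
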