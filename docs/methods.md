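# Methods

This note documents the statistical procedures implemented in `dgnet`, the
defaults chosen where the methodology leaves room, and what the synthetic
study does and does not establish.

## Disease interactomes

A disease interactome is defined operationally: the top-*k* disease-associated
genes ranked by gene–disease association (GDA) score (*k* defaults to 100,
the conventional panel size for this kind of analysis), plus every gene
adjacent to a seed in the loaded PPI network, with the full induced subgraph
on those members. Two conventions matter and are fixed here:

- **Ties at the score cut** are broken by ascending lexicographic gene
  symbol, so exactly *k* genes are always returned and the selection is a
  pure function of the table.
- **Seeds absent from the PPI network** remain interactome members (they
  still carry expression signal downstream); they are logged.

Gene identifiers are case-sensitive symbols in a single namespace; no alias
mapping is attempted. PPI tables may be filtered by PSI-MI interaction type
(direct interaction MI:0407 and physical association MI:0915 are the usual
retained classes) and by a confidence score with an **inclusive** threshold
(a named cutoff like "medium confidence 0.63" denotes scores ≥ 0.63). Rows
with no confidence value fail an active confidence filter. Unknown MI codes
are retained only when no MI filter is given.

The gene universe for overlap testing defaults to every symbol incident to at
least one retained edge, and can be overridden.

## Overlap and over-representation statistics

All enrichment tests are one-sided hypergeometric upper tails
P(X ≥ k | N, K, n). The tail is computed by log-space summation of exact
log-pmf terms (`scipy`'s gammaln-based log-pmf combined with `logsumexp`),
because interactome-scale overlaps produce p-values around 10⁻³¹⁰ — below the
smallest normal double — where any linear-space computation returns 0. The
returned p-value may be subnormal; the log₁₀ p is also reported.

Benjamini–Hochberg adjustment is the standard step-up rule (sorted p times
m/rank, monotonicity enforced from the largest rank down, capped at 1),
delegated to `scipy.stats.false_discovery_control` and cross-checked in the
test suite against an independent quadratic-time implementation. Families
are defined per call: one family per cross-disorder panel, per gene-set
collection queried, per module, and one family spanning all sub-cluster ×
affiliation tests in DGN assignment.

## Expression matrix

Replicate RPKM measurements at the same (gene, region, stage) coordinate are
averaged **in linear space first**; a cell becomes missing only when the mean
is exactly zero (the gene was unexpressed in every replicate), otherwise the
value is log₁₀(mean). Zeros therefore participate in replicate averaging and
only an all-zero coordinate becomes missing — partial dropout attenuates a
cell rather than deleting it. Developmental stage order is always supplied
explicitly; stage labels are never sorted lexically.

The optional brain-expression filter keeps genes whose reference expression
(e.g. whole-brain nTPM) **strictly exceeds** a threshold (default 1.0); genes
absent from the reference count as unexpressed. Region gene sets contain the
genes strictly exceeding a log-expression threshold (default 2.0) in at least
one coordinate of the region — the "at least one" aggregation is this
package's choice, since any-stage expression is the weakest defensible notion
of "expressed in region".

## Temporal clustering and DGN assignment

Distances between expression profiles are 1 − r with r the Pearson
correlation over pairwise-complete coordinates; every pair must share at
least 2 observed positions and zero-variance profiles over the shared
positions are an error naming the genes (a constant profile has no
correlation structure). Trees are built with average linkage (UPGMA), which
merges the pair of clusters with the smallest mean cross-pair distance and
produces ultrametric, monotone merge heights — asserted on every output.
The implementation is `scipy.cluster.hierarchy.linkage(method="average")`;
its internal tie-breaking is deterministic, so repeated runs agree exactly.
Flat clusters are obtained by removing the k−1 highest merges
(`scipy.cluster.hierarchy.cut_tree`), with cluster ids assigned in dendrogram
leaf order. The number of primary clusters and sub-clusters is configuration
(defaults 2 and 5) rather than a height threshold: cut counts are
reproducible, height thresholds are not.

Each sub-cluster is tested against each disease-affiliation set (unique to
either interactome, or shared — the three sets must partition the tested
genes) with BH correction across all tests; its label is the most significant
affiliation at adjusted p < 0.05, otherwise "unassigned". Sub-clusters
sharing a label **and** the same dominant PCA quadrant are merged into one
DGN. When no quadrant assignment is supplied, no merging is performed: a
shared label alone is weak evidence — two temporally distinct clusters can be
enriched for the same disease's genes precisely because that disease has two
biological subtypes, and collapsing them would erase the finding. DGNs are
numbered in sub-cluster (leaf) order.

## PCA with missing values and quadrants

Rows (genes) are centred and scaled to unit sample variance (ddof = 1) over
their observed cells; row-wise scaling is the default reading of
"unit-variance scaling" for a genes × coordinates matrix, and a column-wise
alternative is a one-line transpose away. Missing cells are initialised with
column means, then alternately reconstructed from the truncated SVD and
refilled until the largest absolute change of any imputed cell is below
`tol = 1e-6` (at most `max_iter = 500` sweeps; non-convergence is a warning,
not an error, and is flagged on the result). The procedure is deterministic.
On tiny matrices convergence of the imputed cells is linear and slow, so
exact-recovery checks use a tighter `tol`; at the default tolerance the
imputed values are correct to ≈10⁻⁵.

SVD component signs are arbitrary. Each component is oriented so that its
largest-magnitude loading is positive, and the applied flips are recorded, so
an externally published orientation can be matched by a post-hoc flip.
Quadrants are I = (PC1>0, PC2>0), II = (PC1<0, PC2>0), III = (PC1<0, PC2<0),
IV = (PC1>0, PC2<0); exact zero scores resolve to the positive side (logged).

## Enrichment profiles and co-clustering

Profile matrices hold −log₁₀ of the **raw** p-values by default (adjusted
p-values optionally), floored at p = 10⁻³⁰⁰ to stay finite. The z-transform
is the rank-based inverse normal (Blom offsets):
z = Φ⁻¹((r − 3/8)/(m + 1/4)) with average ranks for ties, applied per column
(per entity) by default — "inverse normal transformation" could also be read
as plain standardisation, so per-row and global modes are provided, but the
rank-based form is the default because it is distribution-free and robust to
the heavy right tail of −log₁₀ p values. Profiles are co-clustered with the
same Pearson/UPGMA machinery on both axes; the column cut at k = 2 is
reported as the entity grouping.

## Topological modules

Vertex weight is k_max × density(S), where k_max is the highest core number
in the subgraph induced by the closed neighborhood N[v] and S the subgraph of
vertices attaining it; members of an isolated m-clique weigh m − 1. Modules
grow greedily from the highest-weight unvisited vertex (ties by node label),
admitting neighbors whose weight strictly exceeds (1 − vwp) × seed weight
(default vwp = 0.2). Growth is confined to the seed's closed neighborhood by
default: an unrestricted recursive expansion crosses any single bridge edge
between two equally dense regions (both bridge endpoints inherit the full
weight of their clique's core) and fuses them into one module, which defeats
the purpose of decomposition — two 5-cliques joined by one edge should be two
modules, not one. The classical recursive expansion remains available via
`expand="recursive"`. The haircut option (default on) iteratively removes
members with fewer than two in-module neighbors; fluff (default off) adds
boundary vertices with dense neighborhoods and may place a vertex in several
modules. Modules are scored by density × size and must have ≥ 2 genes
inducing a connected subgraph. Module counts on real interactomes are
sensitive to these parameters and to the network version; they should be
read qualitatively.

## Synthetic study

The generators emulate the *statistical shape* of the real inputs at desk
scale — defaults: 800 genes, 10 regions, 8 stages (4 prenatal), 2 replicates
per coordinate, log₁₀-scale Gaussian noise sd 0.3, 5% dropout, 20 seeds per
disease, planted overlap fraction 0.5.

- **PPI network**: a preferential-attachment backbone (2 edges per new node)
  gives degree heterogeneity; disease communities (40 genes each, internal
  edge probability 0.2) are carved from *low-degree* backbone vertices so
  that two unrelated interactomes do not meet at hubs — at planted overlap 0
  the overlap p-value is calibrated to chance. Overlap is planted by drawing
  a fraction of both diseases' seeds from a shared community. Near-clique
  modules (10 genes, edge probability 0.9) are planted for module detection.
- **Expression**: four temporal archetypes with both a temporal and a
  regional signature — (1) first half of regions at all stages, (2) second
  half of regions postnatally, (3) all regions at the 2nd and 4th postnatal
  stages, (4) all regions prenatally. Active coordinates have mean
  log₁₀-RPKM 2.5, inactive 0.5. The regional component is essential: a
  profile that is uniformly high everywhere is constant up to noise and has
  no correlation structure, so it could not be recovered by correlation
  clustering at all; the chosen geometry also separates the four archetypes
  into the four PCA quadrants. Archetype fractions default to 0.223 / 0.252
  / 0.091 / 0.434, the relative sizes of the four temporal classes observed
  in real disease interactomes. Archetypes 1–2 couple to unique-SZ
  affiliation, 3 to unique-PD, 4 to shared, with purity 0.8 (high enough
  that affiliation enrichment is decisive, low enough that the coupling is
  statistical rather than definitional).
- **GDA table**: planted seeds occupy the top-k scores, with a deliberate
  three-way tie at the cut (two seeds and a lexicographically larger decoy)
  so the tie-break rule is exercised on every generated table.

All generators are pure functions of (config, seed). What passing the
synthetic suite shows: the pipeline recovers planted cluster structure,
affiliations, overlaps and modules under realistic noise, dropout and degree
heterogeneity, with correct error control on decoys. What it does not show:
robustness to region-specific covariance, donor/batch structure,
normalisation artefacts between expression platforms, or symbol-mapping
noise — none of which the generator emulates.

## Problem sizes in the test and acceptance runs

The bundled checks use sizes chosen to exercise every code path while
remaining desk-scale: exhaustive hypergeometric enumeration up to N = 12;
1000 random BH vectors of lengths 1–200; 100 random 8-leaf UPGMA oracles;
20 replicates of the 800-gene synthetic study; 100 + 100 profile
co-clustering trials; and the printed interactome counts
(K = 3200, n = 2662, N = 17992, k = 1232) for the overlap statistic.

## Known limitations

- The interactome model is static; edge confidence is used only as a filter,
  never as a weight.
- UPGMA tie-breaking follows the scipy implementation; on inputs with exact
  distance ties, other UPGMA implementations may produce a different (equally
  valid) tree.
- Sub-cluster counts from tree cuts are configuration, not inference; no
  automatic model selection for k is attempted.
- The module detector's neighborhood-confined growth bounds module diameter
  by 2; very large sparse complexes would be fragmented (the recursive mode
  trades this for bridge-leakage).
- The per-column inverse normal z-transform makes entities comparable by
  rank pattern only; absolute enrichment magnitudes are not preserved.
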