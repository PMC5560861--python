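# Methods

This note documents the models, the defaults and why they are set where
they are, what the synthetic generator does and does not emulate, and the
numerical choices a maintainer would want to know about.

## Microsynteny

Collinearity between two genomes is counted over the single-copy orthologs
shared by the pair: an unordered ortholog pair is collinear when the two
genes are adjacent in both genomes, on the same scaffold, in either
orientation. "Adjacent" by default means consecutive *among the single-copy
ortholog genes* (intervening non-ortholog genes are ignored); this matches
the denominator N_ij of comparable ortholog pairs and is robust to lineage-
specific gene gain. A `mode="strict"` variant requires strict genomic
adjacency.

The null model permutes gene identities over the fixed gene positions of
each genome and recounts, by default over 100 rounds. This preserves
scaffold gene counts exactly and has the same expectation as re-placing
genes uniformly at random. The permutation stream is derived from the
master seed only — common random numbers across species pairs — so null
estimates are directly comparable between pairs: with identical gene
orders, every pair receives identical null draws and the normalised ratio
is exactly 1 for all of them. For two single-scaffold genomes of n genes
the expected shared adjacency count under the null is 2(n−1)/n, which the
tests verify against exhaustive permutation enumeration at n ≤ 6.

Species are ordered for heat maps by Ward clustering on Euclidean distances
between matrix rows, with rows pre-sorted lexicographically so equal-
distance merges break ties deterministically. The matrix diagonal, not
defined by the statistic, is set to 1 (self-synteny is maximal) before
clustering.

## Intron sites

An intron site is (protein-alignment column, codon phase). Phase is the
number of coding nucleotides 5′ of the intron modulo 3. Phase-1/2 introns
anchor to the codon they interrupt; phase-0 introns fall between codons and
anchor to the codon immediately 3′ (the symmetric 5′ convention is
available via `anchor="upstream"`). Sites at the same column but different
phases are distinct characters — they record independent gains.

Site classification uses a 3-column window (the site's column ± 1,
configurable): *conserved* requires every window column to have ≤ 10 % gap
rows and the orthocluster to cover ≥ 80 % of species (boundaries
inclusive); a window column gapped in > 50 % of rows makes the site
*unclassifiable*; anything else is *ambiguous*. Marker orthoclusters are
those single-copy in ≥ 80 % of species, tolerating paralogs in at most one
species (the best-scoring, else longest, copy is kept).

### Two-state model

Presence/absence of each site evolves independently under a continuous-time
chain on {absent, present} with branch-specific gain g_b and loss l_b
(events per unit branch length) and a free root presence probability:

    P(0→1; t) = (g/(g+l)) (1 − e^−(g+l)t)

This deliberately simplifies the richer literature models: there is a
single rate class (no rates-across-sites variation) and no copy-number /
duplication component. The simplification keeps every quantity checkable
against closed forms and brute-force enumeration, which the test suite does
on trees with up to five internal nodes at |Δ log L| < 1e−8.

The likelihood is computed by pruning over unique site patterns with
per-node rescaling, and is conditioned on each site being present in ≥ 1
extant species (all-absent sites are unobservable; without the correction
rates are biased downward). Missing leaf entries are marginalised; the
ascertainment correction is computed per missingness mask. Optimisation is
L-BFGS-B on log-rates (bounds e^−9 … e^4) and the logit root prior, from a
uniform start (g = l = 0.5, root 0.5), up to 1000 iterations. Posterior
ancestral presence and the per-branch joint posteriors P(parent=0, child=1)
(expected gains; losses analogous) come from the standard up–down
recursion; observed leaf states are pinned exactly in the output.

**Identifiability.** Per-branch rates are well determined where the branch
is adjacent to data. On small fully binary trees the deep-branch rate MLEs
carry sampling SDs of ~10 % of the rate even with 5000 sites, so individual
deep-branch estimates should be read with care (the posterior event counts
are much more stable). The parameter-recovery experiment in the acceptance
suite therefore uses an 8-taxon polytomous (star) design, where every
branch is leaf-adjacent and all rates are recovered within 25 % relative
error for branches with ≥ 20 realised events; this is a statement about the
estimator under a well-posed design, not about deep binary-tree branches.

### Summaries

Per node: expected intron count (Σ posterior presence), expected gains and
losses on the branch above, p_G and p_L as percentages of the node's
introns, the signed ratio r = log₁₀((p_G+ε)/(p_L+ε)) with ε = 1e−6 (the
pseudo-count keeps r finite when one side is 0), intron density = count /
CDS kbp of the marker set, and the bootstrap VMR: sites are resampled with
replacement (default 100 replicates), node counts re-inferred, and
variance/mean reported; VMR > 1 flags over-dispersed, less reliable
reconstructions. Rates are kept fixed across bootstrap replicates by
default (`refit=True` re-estimates them, warm-started).

Presence-profile clustering uses distance 1 − Spearman ρ between node
profiles and Ward agglomeration; constant profiles (ρ undefined) are
assigned distance 1 with a logged warning; rows are pre-sorted by node name
for deterministic ties.

### Phylostratigraphy

A site is *recent* when the posterior probability of a gain on the focal
species' terminal branch exceeds 0.5, otherwise *ancestral*. An intron
bears a regulatory site when some interval (e.g. an ATAC-seq peak) overlaps
the intron by ≥ 50 % of the interval's own length. The resulting 2×2 table
(recent/ancestral × without/with sites) is tested with the two-sided Fisher
exact test.

## Domain architectures

Decomposition collapses consecutive repeats then emits all ordered pairs
(d_i, d_j), i < j: A-B-B-C → {A-B, A-C, B-C}. Non-consecutive repeats
survive collapsing, so A-B-A yields the self-pair (A, A) — the literal
consequence of enumerating all ordered pairs. Each (pair, orthocluster) is
a character; occurrence counts per species are kept, but reconstruction
binarises them (the duplication dimension is out of model). Ancestral calls
use a 0.9 posterior threshold.

Per-node diversification reports gains and losses as percentages of the
pairs present at the node; a node is gain- or loss-biased when the
percentages differ by more than 5 points, otherwise in stasis. Family
enrichment among a node's gains is a two-sided Fisher test on {focal node
vs elsewhere} × {pair contains a family domain vs not}; the background is
the gains of all other nodes by default (the caller can restrict or widen
it), and degenerate margins return p = 1 with a warning. Functional domain
subsets (TFs, ECM, signalling, …) are user-supplied lists; no curated list
is bundled.

Dollo parsimony places one gain at the LCA of the carrier species and
losses on every edge from a reconstructed-present node to an all-absent
subtree — provably the minimal loss set for a single-gain history, and
verified against exhaustive placement for all presence patterns on 6-taxon
trees.

## Domain networks

Vertices are domains, edges link domains co-occurring as a pair within a
gene family, with the supporting orthoclusters kept as edge provenance.
Direction is discarded; self-pairs become a vertex attribute rather than a
self-loop; edges are unweighted by default (a weighted mode counts distinct
orthoclusters). Louvain is greedy and order-dependent, so community
detection runs 10 seeded restarts and keeps the best-Q partition —
deterministic for a fixed seed, and equal to the exhaustive-partition
maximum on all fixture graphs with ≤ 8 vertices in the test suite. The
rewiring null performs 10·|E| accepted double-edge swaps per replicate
(rejecting self-loops and parallel edges; the count is configurable since
no canonical value exists), preserving every vertex degree exactly; 100
replicates by default. Subnetworks are orthocluster-mediated: listing a
domain retrieves every edge supported by an orthocluster that contains it
anywhere (vertex-induced restriction is also available).

## TE landscapes

Hits are filtered at ≥ 70 % identity and ≥ 80 bp (boundaries kept),
self-hits dropped, reciprocal duplicates kept unless deduplicated. Identity
histograms use 1 % bins over [70, 100] and count hits (not copies) — each
alignment contributes once. P_qf sorts families by copy count descending
(ties broken lexicographically by family name, which matters exactly at
saturation boundaries) and reports 100·k/N_f for the smallest k families
whose cumulative copies reach q·N_c. Shared-family presence/absence
matrices are Ward-clustered on Euclidean distances.

## Sequence conservation

Cophenetic distance is the sum of branch lengths on the leaf-to-leaf path
(substitutions per alignment position when the gene trees are ML trees).
Distances to the reference species are pooled across gene trees per species
pair (a per-tree-mean mode exists). Group comparisons use the two-sided
Wilcoxon rank-sum test: the exact null when the combined sample is ≤ 25
and tie-free, otherwise the normal approximation with tie and continuity
corrections. Raw p-values are reported; Benjamini–Hochberg adjustment is
available but off by default.

## Synthetic data

All simulators draw from sub-streams derived from one master seed (stream =
hash of a component label mixed with the seed), so outputs are byte-
reproducible and adding a stage never perturbs earlier draws.

- **Intron histories**: root state Bernoulli per site, exact two-state
  transitions along branches, true per-branch flip counts recorded. This is
  the fitting model itself — recovery tests validate the estimator, not the
  model's realism.
- **Gene orders**: ancestral order 1…n on one scaffold; Poisson numbers of
  inversions/translocations per branch (no gene gain/loss, keeping the
  single-copy premise of the synteny statistic).
- **Domain histories**: ordered architectures per orthocluster; gains
  insert a random domain at a random position, losses delete one; the
  implied pair-presence truth and per-branch pair event counts are
  recorded. Pair characters are therefore *correlated* within an
  orthocluster, unlike the independence the reconstruction assumes — which
  is exactly the kind of model violation worth testing against.
- **TE landscapes**: family copy counts follow a rank power law; families
  belong to amplification bursts; within-family hit identities are Normal
  around the burst mean, clipped to [50, 100]; self-hits and sub-threshold
  hits are emitted on purpose (filtering belongs to the consumer).
- **Gene trees**: the species tree with independent LogNormal(0, 0.4)
  branch-rate factors — among-gene rate variation without topology change.

What the generator does **not** emulate: nucleotide/protein sequences (and
hence alignment error), unequal genome sizes, gene gain/loss interacting
with synteny, TE nesting and fragmentation, and gene-tree/species-tree
discordance. Passing tests therefore demonstrate correctness of the
statistics and estimators under their stated models, not robustness to
annotation noise in real genomes.

Default demo sizes (8 taxa, 150 genes, 1500 intron sites, 120
orthoclusters, 25 gene trees, 100-round nulls/bootstraps/rewirings) are
chosen so the full pipeline runs in about two minutes on one core while
every statistic still has enough events to be meaningfully exercised.

## Numerical choices and degenerate inputs

- Likelihood pruning rescales partials per node; site likelihoods are
  floored at 1e−300 before logging.
- L-BFGS-B convergence: relative function tolerance 1e−9, max 1000
  iterations; non-finite likelihoods raise with a parameter dump.
- All-absent site matrices, edgeless graphs, empty TE tables, empty
  Wilcoxon groups and NaN synteny matrices raise errors; constant
  correlation inputs return NaN with a warning; zero bootstrap means give
  VMR = NaN with a warning.
- GFF3 is 1-based inclusive, BED 0-based half-open; interval overlap math
  happens in half-open coordinates with conversion at the boundary.
  Multiple mRNAs per gene: the longest-CDS isoform is kept (a deterministic
  rule; annotation pipelines differ here and no convention is universal).
- Trees may be polytomous; unnamed internal nodes are labelled N1, N2, … in
  postorder; missing branch lengths default to 1.0 with a warning.

## Known limitations

- Single rate class and presence/absence only: lineages with strong
  rates-across-sites heterogeneity or high paralogy will violate the model.
- Deep-branch rate estimates on small binary trees are noisy (see
  *Identifiability*); prefer the posterior event counts and the bootstrap
  VMR when reading node summaries.
- The synteny statistic assumes comparable assembly contiguity; very
  fragmented assemblies deflate c and N together but not identically.
- Louvain with restarts is still a heuristic; optimality is only guaranteed
  where the suite checks it exhaustively (small graphs).
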