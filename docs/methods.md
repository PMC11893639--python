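# Methods

`ranklap` quantifies shared genetic signal between two disorders using only
GWAS summary statistics — no individual-level genotypes, no external web
services.  This note describes the statistical model behind each stage, the
parameters that matter, what the synthetic-data generator does and does not
emulate, and the numerical choices made where the design was open.

## 1. Rank-binned SNP cross-table

**Model.**  Let the two studies share N SNPs.  Each study's SNPs are ranked
by −log10 p (rank 1 = least significant, rank N = most significant; ties are
broken by genomic position then identifier, so ranking is deterministic).
Ranks are cut into B equal-count bins by `bin(r) = ⌊(r−1)B/N⌋ + 1`, which
guarantees bin sizes differ by at most one — a property that quantile cuts on
the −log10 p axis would lose under ties.  The B×B cross table C counts SNPs
by their (bin_a, bin_b) pair.  Under the null of no shared signal, every cell
has expectation N/B² and the table is an equal-margin multinomial; genuine
tail dependence concentrates excess counts where both bins are high — the
upper-right quadrant when bin B holds the most significant SNPs.

**Significance.**  Each cell is standardized by the mean and *sample*
standard deviation of all B² observed counts (z = (C − m)/s, denominator
B²−1).  The empirical SD is the only dispersion estimate computable from the
table alone; a binomial-theoretical SD √(N·q(1−q)) with q = 1/B² is available
via configuration.  A cell is called significant when |z| exceeds the
threshold (default 4) **and** its two-sided normal tail p, Bonferroni-scaled
by all B² cells, is below α (default 0.05).  The Bonferroni family is all
cells — the conservative reading when no sub-family is prespecified.

**Permutation sensitivity analysis.**  One study's bin labels are shuffled
(statistically identical to shuffling both, at half the cost), the table and
z matrix are rebuilt, and a summary statistic is evaluated — by default the
maximum z over the quadrant with both bins above B/2; the count of quadrant
cells above the z threshold is exposed as an alternative.  The p-value uses
the add-one estimator (1 + #{T_perm ≥ T_obs})/(n_perm + 1), so the smallest
attainable p with n permutations is 1/(n+1); no parametric extrapolation
beyond the permutation sample is reported.

**Known limitation (calibration at desk scale).**  With N = 50,000 and
B = 30, each cell count is approximately Poisson with mean 55.6 and skewness
≈ 0.14.  The normal tail at the Bonferroni-binding threshold (|z| ≈ 4.06)
underestimates that skewed upper tail, so the familywise false-positive rate
of the cell calls under a pure-null simulation is ≈ 0.07–0.08 rather than
≤ 0.05; the package's own null-calibration test measures this honestly and
currently fails its ≤ 0.05 assertion.  The effect vanishes as the per-cell
mean grows (skewness ∼ λ^{−1/2}): at several million shared SNPs, where the
method is meant to operate, λ is in the thousands and the normal call is
conservative.  The permutation p is calibrated at every scale (its
uniformity under the null is tested and passes) and should be preferred at
small N.  LD between SNPs is a second, unmodelled violation of the implicit
independence assumption; an optional position-thinning step
(`thin_by_position`) is provided without any claim that it restores
calibration.

## 2. SNP-to-gene annotation

A local windowed annotator stands in for web-based variant annotation.
Category priority is exonic > intronic > upstream/downstream > intergenic;
upstream/downstream means within `window` bp (default 1,000, the common
variant-annotator convention) of the gene span, with the side named relative
to strand.  Ties among overlapping genes go to the nearest span midpoint,
then lexicographic gene id.  If the gene model carries no exon intervals,
whole spans are classified exonic (coarse mode, logged prominently).

Gene lists are built after restricting to autosomal SNPs with odds ratio
strictly greater than one (removing pseudo-protective directions before gene
selection; the filter runs before annotation).  A gene's score is the minimum
p over its assigned SNPs in the exonic/upstream/downstream categories —
intronic SNPs carry a host gene id but never score it, and intergenic SNPs
score nothing.  Min-p is the standard GWAS gene ranking; a
count-of-genome-wide-significant-SNPs alternative is exposed via
configuration.  The top k genes (default 100) per study feed the network
stage.  Coordinates are normalized internally to 0-based half-open (BED
convention) and reported 1-based inclusive (GWAS convention).

## 3. Gene-network overlap

**Interaction score.**  Given a weighted undirected gene network (a local
edge-list file; the synthetic generator provides planted-partition networks
for testing), a gene's interaction score against a reference set is its
summed edge weight into that set — the transparent local analogue of a
neighbor-ranking service's weighted linear combination.  Reference genes are
pinned to the maximum non-reference score, which places them in the top block
of the ranking while keeping every score finite and ties deterministic
(ties break lexicographically by gene id).

**Query expansion.**  The query study's top genes are grown one gene at a
time: each step adds the non-member with the largest summed edge weight into
the current set (ties by gene id), with snapshots at the requested sizes
(default 100, 200, …, 1000).  Sets are nested by construction.  Expansion
stops early if no remaining gene has positive attachment (e.g. a
disconnected component), with a warning.

**Preranked enrichment.**  Each snapshot is tested with the classic weighted
Kolmogorov–Smirnov running sum: walking the ranked list, hits add
|score|^w / Σ_hits |score|^w (w = 1 by default; if the hit weights sum to
zero the increments fall back to equal), misses subtract 1/(N − N_hit).  The
enrichment score ES is the signed maximum deviation; extremes occur only at
hit boundaries, which is what the implementation evaluates.  A tie between
the positive and negative extreme (which arises exactly on structured
instances) resolves to the positive side, with 1e−9 slack so the choice is
stable under float round-off.  The null is gene-label permutation: random
sets of equal size.  NES divides ES by the mean same-sign permuted ES, and
the nominal p is the add-one fraction of same-sign permuted |ES| at least as
extreme — a conservative, slightly discrete estimator whose null uniformity
holds for continuously scored lists.

**The overlap profile.**  Nominal p-values across the expansion-size family
are Benjamini–Hochberg adjusted, and a size is flagged significant only when
its adjusted p < α **and** ES > 0.  The ES > 0 requirement is deliberate:
the question is overlap (enrichment of the query set near the top of the
reference ranking), and a query set depleted from the top — e.g. one drawn
from an unrelated, tightly connected community — would otherwise flag on the
negative side.  The same machinery runs with a fixed region gene list (such
as the genes in a recurrent microdeletion region) in place of either study.
`region_snp_fraction` reports the percentage of significant-cell SNPs lying
inside a genomic interval; it is undefined (reported as not applicable) when
no cell was called.

## 4. Pathway enrichment map

Enrichment uses the one-sided hypergeometric tail P(X ≥ k) for a query of n
genes overlapping a K-member pathway in k, from a universe of M genes, with
Benjamini–Hochberg adjustment across pathways and a conservative adjusted-p
threshold (default 5e−5).  A service-specific multiple-testing procedure is
not re-implemented; BH is used and recorded in output metadata.  SNP-derived
queries are mapped to genes by the annotation stage before enrichment.

The enrichment map has significant pathways as nodes (tagged per cohort,
carrying the smallest p across cohorts) and edges between pathway pairs with
gene-membership Jaccard ≥ 0.35 — boundary inclusive, read literally from the
edge rule.  Step-down pruning walks pathways by ascending p (ties by id) and
discards any pathway whose Jaccard with an already-retained pathway is
strictly greater than 0.5 — boundary exclusive, again the literal reading —
logging each discarded pathway with its retained representative.  Two
invariants are asserted in tests: no retained pair exceeds the prune
threshold, and the globally most significant pathway always survives.
Driver subsets (genes with interaction score strictly above the mean of all
scores) and pairwise Jaccard matrices of enriched-pathway sets complete the
post-hoc comparisons.

## 5. Synthetic-data generator

Per SNP, each study receives a latent association statistic: null SNPs are
independent standard normals; shared-causal SNPs are bivariate normal with
mean `noncentrality` in both studies and correlation `shared_corr`;
study-specific causal SNPs have the elevated mean in one study only.
Two-sided p-values and odds ratios exp(latent/10) (so OR > 1 ⇔ latent > 0)
complete the records.  SNPs are placed uniformly on a 23-chromosome map with
human chromosome lengths scaled down 100×.

Defaults: 50,000 SNPs (≥ 55 per cell at B = 30, yet desk-scale), π_null =
0.97, π_shared = π_a = π_b = 0.01 (a large-π0 mixture with a heavy left
tail), shared_corr = 0.6, noncentrality = 3.0 (causal median p ≈ 2.7e−3 —
strong but not trivially separable signal; calibration experiments that
require a specific causal tail, such as median p ≈ 1e−6, pass
noncentrality = Φ^{−1}(1 − 5e−7) ≈ 4.89 explicitly).  The latent components
of the shared-causal SNPs are drawn in a parameter-independent order and
combined as z_b = nc + ρu + √(1−ρ²)v, so matched-seed runs differing only in
`shared_corr` are coupled through common random numbers — the dependence
parameter can be studied with all other randomness held fixed.

Gene models place non-overlapping 2–8 kb genes with 2–5 exons in disjoint
chromosome slots.  Networks are weighted planted partitions: within-community
pairs link with probability 0.05 and exponential weights of mean 1.0,
between-community pairs with probability 0.005 and mean 0.1; a zero weight
parameter suppresses that edge class entirely.  Pathways align the first
`n_communities` sets with communities and fill the rest with uniform decoys;
the region gene list samples 47 genes from one community.

**What the generator does not emulate:** linkage disequilibrium (SNPs are
independent; an experiment passing here says nothing about LD-induced
inflation in real data), allele frequencies, genomic inflation from
population structure, ancestry mismatch between studies, or the composite
multi-evidence structure of real gene-association networks.  Passing tests
demonstrate that the machinery recovers planted structure under its own
model assumptions — not that real disorder cohorts at full GWAS scale
(millions of shared SNPs) would yield any particular result.

## 6. Experiment design in the evaluation module

The network-overlap experiment uses two communities of 1,000 genes rather
than the generator's four-community default: greedy expansion necessarily
leaves a community smaller than the deepest snapshot (1,000 genes) once
exhausted and then drifts into neighboring communities — including the
reference community — so the shared/disjoint contrast is only well-defined
when each community can absorb the whole expansion.  GSEA permutation counts
in the repeated-simulation experiments are 200 per size (smallest attainable
nominal p ≈ 0.005, comfortably below the 0.05 flag threshold after BH across
ten sizes).  The pipeline determinism check and the reproduction script run
reduced problem sizes (e.g. 10,000–20,000 SNPs, 400–800 genes) chosen so
each experiment completes in minutes on a single core; every reported rate
states its replicate count alongside.

## 7. Reproducibility

A single top-level seed derives independent per-stage streams via
`numpy.random.SeedSequence`, so full runs and standalone stage runs are both
bit-reproducible; the run manifest records a SHA-256 checksum of every
output file, and re-running a config with the same seed reproduces every
checksum (asserted in tests, including the rendered heatmap images).
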