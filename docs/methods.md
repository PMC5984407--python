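# Methods

## The inference problem

Unisexual salamanders of the *Ambystoma laterale*–*jeffersonianum* complex
carry one haploid *A. jeffersonianum* chromosome set (the J haplome) and one
to three *A. laterale* sets (L haplomes): biotypes LJ, LLJ, LLLJ, alongside
sexual LL hosts. They reproduce by kleptogenesis: a female needs sperm from a
sexual host male to trigger egg development, and the sperm genome may be
discarded (clonal offspring), incorporated (ploidy elevation), or swapped for
one of the female's own L haplomes (genome replacement/exchange). Where the
J donor species is absent, the J haplome can only be transmitted clonally, so
it is an internal mutation-only control: any excess of L-haplome diversity
over J-haplome diversity, or the presence of L alleles identical to
high-frequency host alleles but many mutation steps away from the unisexual
allele cluster, is evidence of genome exchange.

The package implements that inference from co-dominant microsatellite
genotypes (plus AFLP presence/absence for cross-validation) and provides a
forward simulator with ground truth to exercise every stage.

## Haplome partitioning and calling

Each locus is declared with a repeat motif length and optional disjoint J/L
allele-size ranges. Alleles are routed to J- or L-"isoloci" by range
membership (`J_ONLY` / `L_ONLY` / `SPLIT_BY_RANGE`); loci with overlapping
ranges stay unpartitioned and are excluded from isolocus analyses. Alleles
outside both declared ranges are kept unpartitioned with a warning rather
than guessed.

Copy numbers per haplome are the maximum distinct-allele count over that
haplome's isoloci (minimum 1 if any allele is present). Microsatellite
dominance means a polyploid showing fewer distinct alleles than its ploidy
("partial heterozygote") under-reports and never over-reports, so the
maximum across loci is the tightest available lower bound; tetraploids are
only called when some locus shows three distinct L alleles (conservative).
Compositions impossible in the study region (two J alleles, no L alleles)
stay `UNCALLED`.

Genetic groups are assigned from the four "multimodal" J-isoloci whose
allele distributions have deep gaps: an individual matching the modal
(consensus) genotype at all four belongs to the consensus group; matching
exactly one group's diagnostic substitution pattern assigns that group;
conflicting or novel patterns give `X`; missing data at any diagnostic locus
gives `UNASSIGNED`. Consensus genotypes are per-locus modes with ties broken
to the lexicographically smallest allele vector.

## Bruvo distances for mixed ploidy

The single-allele dissimilarity follows the stepwise mutation model,
`d(a, b) = 1 − 2^(−x)` with `x = |a − b| / motif` repeat steps (non-integer
differences are rounded to the nearest step with a warning — fragment-size
jitter). For equal ploidy `k`, the genotype distance is the minimum over all
one-to-one allele assignments of the mean allele dissimilarity, enumerated
exhaustively (`k ≤ 4`, so at most 24 assignments).

For unequal ploidy the smaller multiset is completed with virtual alleles:

- **genome addition**: virtual alleles drawn from the smaller genotype's own
  distinct alleles;
- **genome loss**: drawn from the larger genotype's distinct alleles.

Every ordered draw (`m^d` completions for `m` donor alleles and deficit `d`)
is scored as an equal-ploidy distance and the completions are **averaged**,
not minimized; when both models are enabled (the default) their means are
averaged again. Averaging reflects that the true history of the missing
copies is unknown, and makes the combined statistic symmetric in the two
models.

Partial heterozygotes are resolved by enumerating all multiset completions
of the observed alleles up to the biotype-implied copy number; each
completion is weighted by the product of reference allele frequencies of its
duplicated alleles, renormalized. Reference frequencies are estimated from
the dataset with each individual contributing its haplome dose per isolocus
(one certain copy per observed allele; the unresolved remainder split
uniformly). The frequency scope defaults to per-site (exchange partners are
local hosts, so local frequencies are the right prior) and can be set to
global or per-group. Alleles missing from the frequency table get the
smallest observed frequency at the locus, with a warning, rather than zero —
a zero would silently delete completions.

Pairwise matrices average per-isolocus distances over loci scored in both
individuals; a pair sharing no locus is an error. Per-locus matrices are
cached, so locus bootstraps are a cheap resample-and-average.

## Clustering and spatial statistics

Neighbor joining follows Saitou–Nei agglomeration with deterministic
lowest-index tie-breaking (bit-reproducible bootstraps) and clamps negative
branch lengths to zero with a warning. On additive matrices the tree
reproduces all pairwise distances exactly; scikit-bio's `nj` is the
independent cross-check in the tests. Bootstrap support resamples loci with
replacement, rebuilds the matrix and tree per pseudoreplicate, and reports
the percentage of replicates containing each bipartition of the full-data
tree; edges under the collapse threshold (default 50%) become polytomies.
Majority-rule consensus keeps bipartitions in >50% of trees and, in extended
mode, adds remaining compatible bipartitions greedily by frequency.

AFLP profiles are compared by the simple-matching distance (fraction of
mismatching bands). Site composition is compared by Hellinger distance
(square-rooted relative abundances, Euclidean), bounded by √2.

The Mantel test correlates off-diagonal upper triangles and computes a
one-tailed permutation p with the observed statistic counted in both
numerator and denominator (p is never 0). The Mantel correlogram uses
equal-width classes over the observed great-circle (haversine) distance
range; per class the statistic is the Mantel correlation against the
class-membership indicator with the sign flipped so positive values mean
within-class similarity, corrected progressively (Holm over the classes
tested so far). The first-class upper bound is printed so short-range
autocorrelation claims are checkable.

## Genome-exchange diagnostics

**Divergent alleles.** Sorted alleles at each isolocus are chained into
clusters broken at gaps of ≥ 8 mutation steps (configurable; the empirical
gaps are 8–11 steps). The largest cluster is the main distribution, all
others are flagged with their gap; two equally large clusters raise an error
demanding manual designation rather than guessing.

**Carrier frequency** of divergent alleles is reported per isolocus as the
share of haplome copies occupied (unresolved multiplicities split uniformly)
or, alternatively, the share of individuals carrying at least one. The
probability that a group of `n` individuals contains no carrier by chance is
`(1 − p̄)^n` with `p̄` the mean per-individual carrier frequency.

**Ploidy-weighted counts.** A group's haplome count `n` sums copies per
individual (LL = 2L/0J, LJ = 1/1, LLJ = 2/1, LLLJ = 3/1); the weighted
ploidy level divides by group size. A group of three LLJ and one LJ has
n = 7 L-copies and 4 J-copies, weighted ploidy 1.75 and 1.0.

**Alternative alleles per locus.** Allelic richness is rarefied to a common
number of copies by the exact hypergeometric expectation
`Σ_a [1 − C(N−N_a, n)/C(N, n)]`; with fractional (uniformly split) counts
the binomial ratio is evaluated as the corresponding falling-factorial
product, which coincides with the exact value for integers. The clonal
baseline subtracted per locus is the distinct-allele count of the group's
consensus genotype — what strict clonality would show — floored at zero and
averaged over the locus set (8 J-isoloci vs 4 L-isoloci in the default
panel). An alternative baseline (minimum distinct count over individuals) is
available by flag. The rarefaction size defaults to the minimum weighted
haplome count across the units being compared.

**Dispersion partitioning.** The distance matrix is embedded by principal
coordinates keeping negative-eigenvalue axes; squared distances to centroids
are positive-axis contributions minus negative-axis contributions, floored
at zero — the standard treatment of semi-metric dissimilarities in
multivariate dispersion analysis. Per group, `total` is the mean distance to
the group centroid, `intra` the mean distance to the (group × site)
centroid, `inter = total − intra`; inter+intra percentages sum to 100 by
construction. Groups are compared by one-way ANOVA on per-individual
centroid distances with Tukey HSD post hoc, summarized as a compact letter
display (insert-and-absorb). The per-individual quantity compared for the
intra component is the distance to the own-site centroid; the inter
component, being a difference of means, has no exact per-individual analog
and is compared via `d_total − d_intra`.

## The simulator

Discrete non-overlapping generations; within each site × group, a constant
population of parthenogenetic females with Wright–Fisher resampling of
mothers. The resampling matters: it creates within-site shared ancestry, so
isolated clonal sites accumulate *different* mutations and show
among-site-dominated dispersion, while a scheme with exactly one daughter
per female would leave every lineage independent and erase that signature.
Each daughter draws one event — clonal (probability 1 − the rest), genome
replacement (a uniformly chosen L haplome swapped for a host gamete),
elevation (host gamete appended, capped at LLLJ), or reduction (a uniformly
chosen L haplome dropped, floored at LJ) — then every haplome-locus mutates
±1 motif step with its locus rate, reflecting at the configured size bounds.
J haplomes are never exchanged (no J donor species in the region), so no
JJ-bearing genotype can arise. Host populations are stationary
allele-frequency pools — a boundary condition, not an evolving deme — and
host gametes draw one allele per L-amplifying locus.

Preset conditions (rates are not estimable from the study data and are
order-of-magnitude choices): mutation 2 × 10⁻³ per haplome-locus-generation,
except 2.5 × 10⁻⁵ at the four multimodal assignment loci — their empirical
deep allele-size gaps with no intermediate steps are only consistent with a
much lower effective step rate, and stable diagnostics are what makes
multilocus group assignment possible at all. Exchange presets use exchange
0.15, elevation 0.02, reduction 0.02 per female-generation; 80 generations;
site populations of 12 with 10 sampled (without replacement); host pools
carry the divergent alleles (AmaD42-L 241/253, AjeD94 142) at combined
frequencies near 0.8, as in sympatric sexual populations. Four presets cover
the study designs: `clonal_only`, `all_diploid`, `exchange_only`, and
`mixed_sympatry` (a clonal group coexisting with two exchanging groups and
hosts — the discriminating design).

Simulated data emulate clonal divergence, host-derived divergent alleles,
exchange, and ploidy change. They do **not** emulate: genotyping error or
allele dropout, host population evolution or migration, recombination
between haplomes, multi-step mutations, locus-specific motif lengths, or the
W-chromosome constraint on replacement. Passing recovery tests therefore
shows the pipeline inverts its own generative assumptions, not that those
assumptions hold in any particular pond.

An AFLP-like dominant matrix is derived from simulated genotypes by scoring
one band per observed (locus, allele) pair, dropping fixed bands — the
dominant-marker shadow of the same variation, used to test the
cross-validation path (simple-match distances correlate strongly with
microsatellite distances on the same individuals).

## Numerical and testing choices

- Enumerations (assignments, completions) are exhaustive and exact; no
  assignment-problem solver is used since ploidy ≤ 4.
- All randomness flows through seeded `numpy` generators; bootstrap and
  permutation results are bit-reproducible under a fixed seed.
- Permutation p-values use the +1 convention throughout.
- Degenerate inputs fail loudly: constant matrices in Mantel tests,
  zero-abundance sites, equal-size allele clusters, singleton groups (NaN),
  zero within-group variance (F reported as NaN).
- Test problem sizes: Bruvo oracle equivalence on 1,000 random genotype
  pairs (ploidy ≤ 4); rarefaction vs exhaustive subsampling for N ≤ 12; NJ
  inversion of 30 random additive trees of 4–8 taxa; Mantel type-I error
  over 500 null replicates of 10 × 10 matrices at 999 permutations;
  dispersion-comparison power over 200 replicates of 20-point, 10-axis
  clouds with doubled dispersion; preset recovery on the four presets at
  ~30–91 individuals each.

## Known limitations

- Biotype calling cannot exceed the information in distinct allele counts: a
  polyploid whose L haplomes are identical at every locus is called at the
  lower ploidy. Group-level statistics inherit the uniform-split treatment
  of such partial heterozygotes.
- The divergent-allele detector assumes one dominant allele cluster per
  locus; genuinely bimodal loci require manual designation.
- `fractional` rarefaction sizes are rounded to the nearest integer number
  of copies.
- The correlogram's equal-width classes can leave sparse or empty classes
  with small site sets; these are reported as NaN, not interpolated.
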