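# Methods notes

This note records the statistical models, the synthetic-data generator's
assumptions, numerical conventions and the genuinely open design choices.
Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Estimators

**Allele frequencies.** Genotypes are alt-allele dosages 0/1/2 with −1
for missing.  A population's allele count at a SNP is 2 per genotyped
diploid, except on chrX where males are hemizygous: male calls are coded
0/2, contribute one allele each, and a male chrX heterozygote read from
disk is coerced to missing with a warning.  SNPs with zero genotyped
alleles in a population are flagged unavailable there and excluded from
any pairwise statistic involving that population.

**QC.** SNP filters use strict inequalities (MAF > 0.1%, call rate
> 97%), so a SNP exactly at a threshold is removed.  LD pruning is a
greedy per-chromosome pass over 200-SNP windows advanced by 25 SNPs: any
retained pair with squared dosage correlation > 0.4 loses its lower-MAF
member (tie: the later SNP).  Monomorphic SNPs are never drop triggers
and never dropped for LD.  The rule makes the surviving set deterministic;
the thresholds are the conventional ones for array data.

**Weir–Cockerham F_ST.** The 1984 two-population variance components
(a, b, c) are computed per SNP from sample sizes in diploid equivalents,
sample frequencies and observed heterozygote frequencies; θ̂ is the ratio
of averages Σa / Σ(a+b+c) — stable for rare alleles, matching standard
practice — and may be slightly negative for undifferentiated pairs.
Where an F_ST matrix feeds the Mantel suite, negative estimates are
floored at zero so the matrix is a valid distance matrix.

**f3, D and the block jackknife.** f3(O; X, Y) is the plain mean of
(o−x)(o−y) with no finite-sample bias correction and no heterozygosity
normalization (an optional correction is deliberately omitted by default:
the outgroup samples in the intended use are large, and the uncorrected
form keeps the estimator a pure ratio of averages).  D uses the
normalized ABBA–BABA form given in the README; with the outgroup first
and the test population second, shared drift between the test population
and the third population drives D negative.  Standard errors come from a
delete-one-block jackknife over contiguous blocks of at most 500 SNPs
that never span chromosomes; the equal-weight SE formula
((m−1)/m)·Σ(θ₍ⱼ₎−θ̄)² is used, which is valid because blocks are built
with near-equal SNP counts.  Blocks whose deletion would zero the
denominator are merged into a neighbour with a warning.  Jackknifing by
SNP count rather than cM span is a design choice: it keeps the
equal-weight formula exact and changes Z only in late decimals.

**IBD post-processing.** Intervals are half-open [start, end) in cM so
lengths add under merging.  Consensus filtering keeps tracts with
detector score ≤ 1e−10 and unions overlapping or abutting intervals
across the ten runs; gap merging then bridges gaps < 0.5 cM and discards
tracts < 1 cM (both parameters configurable — the original
post-processing algorithm's parameters are not printed, so the defaults
are chosen to remove switch-error-scale breaks without joining distinct
segments).  Length bins are half-open, so a tract of exactly 2.0 cM falls
in the 2–3 cM bin; tracts at or beyond the last edge are excluded.

**IBD permutation test.** The observed statistic is the target
population's mean pairwise sharing with the partner (pair-count
denominator: n_A·n_B across populations, n(n−1)/2 within; the
individual-count alternative is available behind the sharing helpers).
The null resamples individuals, not populations: subsets of the target's
sample size drawn without replacement from the pooled individuals of the
target plus its geographic control populations.  Including the target's
own individuals in the pool makes the test an exact randomization test —
under the null that the target shares like its controls, the observed
subset is one member of the resampling orbit and the p-value is uniform.
Restricting the pool to controls alone (available via
`include_target_in_pool=False`) leaves the null under-dispersed, because
every draw reuses the same control individuals, and measurably inflates
the type-I rate; the default is therefore the exact variant.  p-values
use +1 smoothing and a one-sided upper tail, and the Fig.-4-style
significance matrix colours cells at α = 0.05 (configurable) by the
partner's language family.

**Haplogroup distances.** "Conventional F_ST" on haplogroup frequencies
is Nei's G_ST with unweighted mean within-population heterozygosity — the
cited software reference gives no formulas, and G_ST is the conventional
frequency-based choice.  Φ_ST is a two-level AMOVA with inter-haplotype
distance 1 between distinct haplogroups and 0 within, which is what
"based on haplogroup frequencies" reduces to without molecular distances;
Slatkin's linearization Φ/(1−Φ) is floored at 0 for negative Φ and
flagged missing (NaN, logged) at Φ = 1, where it is infinite.  Note that
G_ST and the δ=1 AMOVA Φ_ST are different statistics — their ratio
approaches 2 as divergence shrinks — so they agree on the absolute scale
only where both are small.  Group TVD is computed between mean copying
profiles (self-copy cells and excluded donors removed, renormalized); a
per-recipient alternative would weight individuals unequally.

**Mantel framework.** The statistic is the Pearson correlation of
lower-triangle vectors; the null permutes labels simultaneously in rows
and columns (the second matrix for the simple test, the first for the
partial test, with r23 invariant).  The alternative is one-sided positive
with +1 smoothing, matching the convention of the standard ecology
tooling; a two-sided tail is available.  Labels with any missing cell are
dropped complete-case before testing, which keeps the permutation
exchangeable — pairwise masking would not.

**Sex-bias ANOVA.** A single admixture pulse with male fraction m and
female fraction f contributes (m+f)/2 of ancestry to autosomes and
(m+2f)/3 to chrX.  Pairs are classified by p(M178-coA) = product of the
two populations' N3-M178 frequencies, with strict thresholds (> 0.10
high, < 0.05 low, the closed interval excluded).  The contrast is OLS of
f3_auto on f3_chrX with a group indicator and interaction;
group and interaction terms are tested by Type-II nested-model F-tests
(the named sums-of-squares type is not specified in the source analysis;
Type II respects marginality for this two-term design).  f3_auto is the
response and f3_chrX the predictor because the question is excess
autosomal affinity relative to chrX.

## Synthetic-data generator

**Frequencies.** A hierarchical Balding–Nichols model: ancestral
frequencies Uniform(0.05, 0.95); one shared "non-African" drift layer
(F = 0.05) common to all study populations; a deeply drifted Siberian
source (F = 0.2–0.25, the magnitude of highly drifted northeast Siberian
groups); independent per-population drift (F = 0.01–0.08, array-data
scale); then admixture of the Siberian source at the population's
sex-resolved fraction — (α_m+α_f)/2 on autosomes, (α_m+2α_f)/3 on chrX.
The default world plants ~0.4 Siberian ancestry in Volga-region
Finno-Ugric speakers and ~0.2 in their Turkic-speaking neighbours, a
west-to-east cline elsewhere, and a mild male bias.  Genotypes are
binomial draws (male chrX Bernoulli, coded 0/2); the genetic map is
uniform at 1 cM/Mb.  Frequencies rather than coalescent simulation
generate genotypes because every analysis consumes frequencies or tract
calls, and Balding–Nichols gives closed-form recovery targets.

**IBD tracts.** Planted directly at the tract-call interface: per sample
pair, tract counts are Poisson with rate
base·exp(−geo_km/3000)·(β if both populations are Uralic); β = 3 in the
default world, 1 in the null world.  Lengths are exponential (mean
1.5 cM) truncated to [1, 5) cM; positions are uniform over the autosomal
map.  The base rate of one tract per cross-population pair in that window
is the order observed for within-Europe array panels.

**Counts.** chrY haplogroup counts are multinomial (n = 50 per
population) around configured frequency vectors; N3-M178 frequencies
follow the published magnitudes (e.g. ~0.33 for Estonians, ~0.9 for
Nganasans).  Chunkcount rows are Dirichlet-multinomial (concentration
100, 1000 chunks) around population copying profiles that decay with the
realized genetic distance; the own-population donor weight is maximal, as
in real chromosome-painting output, so genetically close populations have
small TVD.

**Lexical tree and geography.** The tree is built by UPGMA over the
Uralic-labelled populations on a blend
ρ·(standardized realized genetic distances) + (1−ρ)·(standardized
distances of an independent 2-D latent space), shifted positive.  At
ρ = 0 the lexical distances are independent of the genetic structure;
sampling coordinates are the configured locations (plus optional jitter,
0 by default, which keeps the ρ = 0 conditional-independence property
exact).  The realized population frequency vectors — not the config
parameters — define the genetic structure entering the blend, so the
planted correlation refers to the same drift the genotypes express.

**Seeding.** One master seed feeds a splitmix64 stream that derives a
named child seed per component; the same configuration therefore yields a
bit-identical bundle, and any component can be regenerated alone.

**What the generator does not emulate.** Linkage disequilibrium within
populations (SNPs are independent given the frequency hierarchy, so the
LD pruner is exercised by planted duplicates in tests, not by realistic
decay); ascertainment bias of array SNPs; phasing and detector error
models for IBD (tracts are planted at the call interface); haplogroup
phylogeny below the configured lineages; and population growth or dated
admixture pulses.  Passing tests therefore demonstrate the correctness
and calibration of the estimators under the stated generative model, not
robustness to those real-data complications.

## Replicated studies (sizes and rationale)

The calibration and power suites in `uralpop.experiments` scale the
scenarios so the whole suite runs in minutes on one CPU while keeping
each check's Monte-Carlo error well inside its acceptance window:

* D-statistic null: 200 star-phylogeny replicates, 10,000 SNPs, 20
  jackknife blocks, 25 diploids per population.
* IBD calibration/power: the five-population Baltic/Volga corner of the
  world (15 samples per population), 299 permutations, 200/100
  replicates; power uses the planted β = 3 at study geography.
* Mantel calibration: 200 independent random geometries at n = 30 labels,
  199 permutations; gene-language calibration uses the null world's eight
  Uralic populations with 3,000 autosomal SNPs.
* Gene-language power: a 15-population all-Uralic panel (fixed attributes:
  a west-east ancestry cline with population-specific deviations and
  drift cycling over 0.01–0.08) at ρ = 0.6, 999 permutations, 100
  replicates — the partial Mantel of lexical vs F_ST distances keeping
  geography.
* Sex-bias: disjoint (test, comparison) pairs so the ANOVA rows are
  independent; comparison populations ladder their Siberian fraction over
  [0.6, 1.0] to give the within-group affinity spread the regression
  needs.  Calibration (200 replicates, 6+6 pairs, 6,000/2,500 SNPs) makes
  the two groups genetically identical processes — labels come from N3
  frequencies alone — so the type-I check is exact by exchangeability.
  Power (100 replicates, 8+8 pairs, 25,000/10,000 SNPs, the X panel
  scaled near the study's ~12.5k chrX SNPs) plants α_m = 0.3, α_f = 0 in
  the high-group donors, so only the chrX ancestry fraction (0.10 vs
  0.15) distinguishes the groups.

## Degenerate inputs and numerical conventions

Distance matrices must be symmetric within 1e−9 with zero diagonal;
CSV readers average asymmetries below 1e−6 and reject larger ones.
Matrices are written at 17 significant digits and parsed with a
round-trip float parser, so write→read is exact.  UPGMA breaks ties by
the lexicographically smallest cluster pair (clusters named by their
smallest member), making the tree deterministic for tied inputs.  The
fastIBD-style tract reader takes a configurable column order because the
detector's output dialect is not standardized; records whose interval is
empty after map conversion are dropped and counted.  Permutation p-values
are never zero by construction (+1 smoothing).  Exact-fit Pearson
correlations (|r| = 1) are flagged rather than passed to the t
distribution.

## Known limitations

The published distance matrices behind the original correlation analysis
are distributed only as a spreadsheet attachment; without them the
package can demonstrate the machinery only on synthetic worlds (the
acceptance tests that compare against the published Mantel values load
user-supplied CSV exports from `data/table_s14/`).  The AMOVA Φ_ST here
is the frequency-only δ = 1 form; sequence-level Φ_ST from HVS-I
alignments would need molecular distances that are out of scope.  The
sex-bias ANOVA treats pair-level f3 values as independent observations,
which is exact only for disjoint pairs — with all-pairs tables the
p-values are approximate because pairs sharing a population are
correlated.
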