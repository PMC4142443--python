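# Methods

`ploidpop` implements a population-genomic analysis for mixed-ploidy,
outcrossing plants genotyped by reduced-representation sequencing (GBS).
The motivating system is a widespread allopolyploid grass with two
ecologically differentiated ecotypes (lowland and upland), each split into
regional gene pools, and two common cytotypes (tetraploid, 4X, with
disomic inheritance; octoploid, 8X).  This note records the models,
parameter choices and numerical decisions behind each stage.

## Genotype calling from allele counts

The raw input is a samples × SNPs pair of read-count matrices (allele A,
allele B) for biallelic SNPs on short GBS tags.  Two callers serve
different purposes:

**Pseudo-haploid calls.** One read is sampled per (sample, SNP) cell and
its allele is the call; empty cells are missing.  A pseudo-haploid
genotype is one random genome copy, so two samples' calls can be compared
regardless of their ploidy — the property that makes mixed-cytotype
distance analysis possible.  Sampling draws allele A with probability
`a/(a+b)` using a Philox counter-based generator: the uniform deviate for
each cell sits at a fixed row-major stream position keyed on the seed, so
calls depend only on (seed, sample index, SNP index) and not on traversal
order.

**Diploid calls.** A deterministic six-state truth table: heterozygous
(A:B) requires at least one read of each allele; homozygous (A:A) requires
six or more reads of A and none of B; one to five reads of a single allele
give a partial call (A:NA); no reads give missing.  The six-read
homozygote floor is applied per SNP.  Valid for disomic tetraploids;
octoploids are called with the understanding that their apparent
heterozygosity is inflated (that inflation is itself the quantity of
interest downstream).

**Filters.**
- Samples with fewer than 310 000 total reads are dropped (default
  threshold; below it genotype matrices become missingness-dominated).
- Loci with SNPs at three or more consecutive tag positions are dropped as
  probable indel artefacts.
- SNPs more than 50 bp from the restriction site are dropped ("more than"
  is read strictly: 50 stays, 51 goes); base quality degrades toward tag
  ends.
- A chi-squared SNP filter requires per-sample allele counts to reject a
  monomorphic-locus null in which minor-allele reads are symmetric
  sequencing errors at rate `error_rate` (default 0.01).  Each sample with
  at least two reads contributes the upper-tail probability of its minor
  count under Binomial(n_i, error_rate); smaller samples are pooled into
  one cell; tails are combined with Fisher's method (chi-squared, two
  degrees of freedom per cell) and tested at `alpha` (default 0.05).  The
  combined statistic is conservative under the binomial's discreteness,
  which is what keeps the false-retention rate at or below `alpha` at
  GBS-typical depths where a per-cell Gaussian approximation would be
  wildly anticonservative.  Error rate, alpha and the pooling floor are
  all configurable.

An optional seeded SNP subsampling flag (fraction, default off) mirrors
panel thinning for expensive downstream analyses.

## Homeolog detection with dihaploid controls

In an allopolyploid, the two subgenomic copies of a locus (homeologs) may
coassemble into one GBS tag; fixed inter-subgenome differences then look
like heterozygous SNPs.  Dihaploids carry one chromosome per subgenome and
admit no true heterozygosity, so any heterozygous diploid call in a
dihaploid flags the SNP as a coassembled homeolog.  One heterozygous
dihaploid suffices by default (`min_dihaploids=1`), because the expected
number of true heterozygous calls is zero; the threshold is configurable.
The default policy *retains* flagged SNPs with an annotation: homeologous
SNPs carry real variation, and because dihaploids come from one gene pool,
removal would disproportionately strip variation from that pool.  The
detector is blind to homeologs whose copies differ only in gene pools the
dihaploids do not represent; the synthetic experiments quantify (but do
not correct) this blind spot.

## Diversity

Per-sample heterozygosity is `#HET / #(HET + HOM)` over diploid calls;
partial and missing calls are excluded from the denominator.

Nucleotide diversity per group is the mean pairwise pseudo-haploid
distance among members.  Distance is the raw proportion of differing calls
(p-distance) with pairwise deletion of missing data.  Two samples' pseudo-
haploid genotypes are two random genome copies, so within a random-mating
pool the expected distance at a SNP with allele frequency p is 2p(1−p) —
the pool heterozygosity — and the average over SNPs estimates genome-wide
diversity on the ascertained panel.  Substitution-model corrections are
not meaningful for an ascertained biallelic SNP panel; a two-state JC69
transform is available as a sensitivity option only.  Pairs sharing fewer
than `min_shared=100` genotyped SNPs are masked rather than estimated
(the estimator's variance at fewer shared sites exceeds its signal).
Groups (populations) whose members span several gene pools are split into
per-pool subgroups before averaging, and known admixed samples are removed
via an explicit exclude list — exclusion is an input, not an automatic
classifier.

## Simulated octoploids

To test whether octoploid heterozygosity is explained by genome doubling
alone, pairs of tetraploid samples are combined into synthetic octoploid
genotypes per SNP:

1. heterozygous if both alleles occur across the two calls;
2. homozygous if both calls are homozygous or partial for the same allele;
3. partial if one call is partial and the other missing.

These rules leave the (homozygous, missing) pairs uncovered: allele
information is present but no rule applies.  Completion: such pairs yield
missing, and the full 36-cell table plus an uncovered-cell mask ship in
`ploidy_sim` (and each simulant reports its count of completion-resolved
cells) so sensitivity to this choice can be audited.  Pairings are
unordered without self-pairing, drawn either within each tetraploid gene
pool ("single-lineage" simulants) or across pools ("admixed" simulants);
a seeded `max_pairs` cap handles large cohorts.  The heterozygosity
comparison between simulant classes and real octoploids is descriptive
(means, spreads, mean differences) — no hypothesis test is attached,
since the underlying pairs share parents and are far from independent.

Under the island model the contrast has a closed form used in testing:
with parent-pool frequencies p₁, p₂, the combined genotype is heterozygous
with probability 1 − (1−p₁)²(1−p₂)² − p₁²p₂², which strictly increases
with pool divergence; cross-pool simulants therefore exceed within-pool
simulants in expectation, and the gap grows with F_pool.

## Population structure and isolation by distance

**PCoA** is classical metric scaling: double-center −D²/2, eigendecompose
(scipy `eigh` on the symmetrized Gower matrix), scale eigenvectors by the
square roots of their eigenvalues.  Negative eigenvalues (non-Euclidean
distances) are reported and their axes dropped; proportions explained are
over the positive spectrum.  Masked distance pairs are a hard error —
impute or drop samples first.

**Trees** use BIONJ: neighbour joining with variance-weighted reduction.
Pair selection and branch lengths follow the classical NJ criterion;
when i and j merge into u, the reduced distances are
`d_uk = w·(d_ik − L_i) + (1−w)·(d_jk − L_j)` with the weight
`w = 1/2 + Σ_k(v_jk − v_ik) / (2(n−2)v_ij)` (clamped to [0,1]) minimizing
the variance of the reduced matrix; variances are initialized to the
distances and updated as `v_uk = w·v_ik + (1−w)·v_jk − w(1−w)v_ij`.  On
additive input BIONJ and NJ coincide and recover the true tree exactly,
which is how the implementation is cross-checked against scikit-bio's NJ.
Output is unrooted newick with quoted labels.

**Geographic distance** is great-circle (haversine) on a 6371-km sphere.

**IBD correlations.** The full correlation is Pearson's r over unordered
sample pairs between genetic distance and log geographic distance.
Partial correlations residualize both variables on a pair-level covariate
design — each covariate (ecotype, gene pool, ploidy) becomes a binary
same/different indicator per pair, the standard partial-Mantel encoding;
the encoding is isolated in one function and swappable.  Numerical
choices:

- co-located pairs are floored at 1 km before the log (configurable,
  attrition logged);
- confidence limits are percentile bootstrap over **samples** (n_boot
  default 500, seeded): pairs are non-independent, and resampling pairs
  would understate CI width.  Within a replicate, pairs formed from two
  copies of the same resampled sample are dropped (their distances are
  identically zero and carry no information);
- a Mantel permutation p-value is available but off by default — the
  headline outputs are r and its confidence limits;
- degenerate variance in either residualized variable is an error, not a
  silent NaN.

Within- vs between-ecotype regression slopes (OLS of genetic distance on
log geographic distance per pair class) summarize how much of the IBD
signal lives inside ecotypes; a class with fewer than 3 pairs is omitted.

## Private alleles and hybrid ancestry tracks

An allele is private to an ecotype when the SNP is genotyped in at least
`min_n=10` focal-ecotype individuals with the allele observed, and the
other ecotype either lacks the SNP entirely or has at least `min_n`
genotyped individuals never showing the allele.  "Genotyped" includes
partial calls, and a partial call counts as observing its allele (both
switchable via `count_partial`; single-allele support is weaker evidence).
Hybrid samples' private alleles are laid along reference coordinates via
a locus→interval BED mapping (0-based half-open in; 1-based positions
out, to match genome-browser conventions).  The mapping is consumed as an
input contract — unique best hits per locus — rather than recomputed by
alignment.  Because the more densely sampled ecotype contributes more
private alleles, its entries are thinned (default fraction 0.25) by
per-entry uniform draws keyed on the seed, which makes the fraction-1.0
track a superset of any thinner track under the same seed.

## Synthetic data generator

The generator emulates the assumed study design so that every stage can be
tested against known truth without external data:

- **Structure:** 2 ecotypes × 3 regional pools × 8 samples.  Hierarchical
  Balding–Nichols frequencies: ancestral p ~ Uniform(0.1, 0.9) per SNP,
  ecotype frequencies ~ Beta with FST `f_ecotype=0.35`, pool frequencies
  nested at `f_pool=0.12`.  Ecotype divergence dominates pool divergence,
  the ordering the analysis presumes; F = 0 and F = 1 are handled as the
  copy and fixation limits.
- **Cytotypes:** pool primary ploidies default to (4,4,8) lowland and
  (4,8,8) upland, with a minority-cytotype fraction of 0.125 (one sample
  per pool of the alternate ploidy).  Tetraploids are disomic draws
  Binomial(2, p).  Octoploids are the union of two tetraploid draws — by
  default from two different pools of the same ecotype, emulating origin
  by admixture of diverged lineages (a flag switches to single-lineage
  doubling).
- **Controls and hybrids:** two dihaploids (haploid draws doubled, zero
  true heterozygosity) from the first lowland pool; three F1 hybrids
  carrying one haplotype from a pool of each ecotype.
- **Loci and reads:** ~2000 loci of 1–3 SNPs at random offsets on an
  80-bp tag, laid out on 9 chromosomes for the BED mapping.  Per-cell
  depth ~ NB(mean 8, dispersion 2); reads flip allele with symmetric
  error 0.005 (typical short-read GBS magnitude).  Depth does **not**
  scale with ploidy by default, reflecting per-library normalization; a
  flag enables dosage-proportional depth.
- **Homeologs:** 5% of loci are planted coassembled homeologs — their
  read counts merge an independent shadow locus with its own frequency
  hierarchy, roughly doubling depth there and producing dihaploid
  heterozygosity wherever the two copies diverge.
- **Geography:** pool centroids on a two-latitude grid (southern row =
  lowland) with 0.5° within-pool scatter and two sampling populations per
  pool, giving both between-pool IBD and pool-structure confounding.

All draws flow from one master seed (full bit-determinism; distinct seeds
give exchangeable datasets).  Truth tables — genotype calls, homeolog
flags, octoploid parent pools, hybrid ancestries — are emitted alongside
the counts.

**What the generator does not emulate:** linkage and recombination (SNPs
are exchangeable given frequencies), realistic demographic history,
allele-frequency ascertainment of a real SNP-discovery pipeline,
depth-genotype correlation beyond the NB model, and within-pool spatial
genetic gradients (IBD inside a pool is flat by construction).  Passing
tests therefore certify the estimators' behavior under the island-model
idealization, not their robustness to those real-data features.

## Problem sizes and tolerances in the test suite

The suite runs on a single CPU in a few seconds.  Unit fixtures use a
300-locus × 4-samples-per-pool cohort; end-to-end checks use the full
default design (2000 loci, 51 samples).  Calibration checks use sizes
chosen so Monte-Carlo error sits well inside the asserted band: the
homeolog-sensitivity check compares ~200 planted SNPs against the exact
negative-binomial sampling probability (±3 percentage points); the
octoploid contrast runs at depth 30 with zero error on a 600-locus,
6-sample-per-pool design so the caller is lossless and the island-model
closed form applies (±0.02); pseudo-haploid sampling is checked against
its binomial expectation at 10 000 draws (±0.015, a 3σ band).
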