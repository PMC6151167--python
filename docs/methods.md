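# Methods

## The problem

In female-heterogametic (ZW) taxa such as *Heliconius* butterflies, the
Z chromosome is carried in three copies per breeding pair, so with an
even sex ratio its effective population size is three-quarters that of
the autosomes and Z-linked nucleotide diversity is expected at
π_Z/π_A = 0.75 *at demographic equilibrium*. Elevated Z divergence
between species is often read as evidence for a "large-Z" role in
speciation, but non-equilibrium demography moves both the Z/A diversity
ratio and every Z/A divergence contrast. This package implements the
full analysis chain needed to study that confound: windowed
diversity/divergence statistics from genotype data with hemizygosity
handling, a coalescent simulator of the demographic scenarios, and a
geographic/Mantel inference layer for reduced effective migration on
the Z.

## Statistics (per 50-kb non-overlapping window)

For populations 1 and 2 with n₁ and n₂ haplotypes:

* π_i — mean over all C(nᵢ, 2) haplotype pairs of the per-pair fraction
  of jointly callable sites at which the pair differs.
* π_S = w·π₁ + (1−w)·π₂ with w = n₁/(n₁+n₂) by default (an `equal`
  option exists). The source formulation says "weighted average" without
  defining w; sample-size weighting is our choice.
* π_T — the same mean over all C(n₁+n₂, 2) pooled pairs.
* F_ST = (π_T − π_S)/π_T (Hudson); NaN when π_T = 0.
* d_XY — mean over the n₁·n₂ between-population pairs. We use the
  n₁·n₂ pair count as the denominator (the Nei–Li definition); a
  printed variant with an n₁+n₂ denominator is inconsistent with the
  pooled-π algebra and is treated as a typesetting artifact.
* d_a = d_XY − π_S; negative values are reported, not clamped — they
  indicate post-split diversity growth.
* Tajima's D with the standard 1989 constants; S is counted over sites
  callable in ≥75% of the population's haplotypes, and the n entering
  the constants is the rounded mean callable count over those sites
  (exact when there is no missingness). NaN for n < 4 or S = 0.

Windows pass the inclusion filter only if, in each population
separately, ≥10% of window positions are genotyped in ≥75% of that
population's individuals; failing windows are kept as all-NaN records.

**Missing data.** Every pairwise statistic uses per-pair denominators:
each haplotype pair is normalized by its own jointly callable site
count. With an all-sites VCF this is exact. With variants-only input
(`assume_callable`) the callability of unrepresented positions is
unobservable, so each pair's callable fraction observed at the variant
sites is extrapolated to the window span (denominator =
callable · span / S). Without this correction, genotype-level masking
at variant sites deflates π by roughly the masking rate squared (the
numerator shrinks while the invariant denominator does not); we
verified the corrected estimator is unbiased on simulated studies with
~17% masking. Individual-level d_XY over thinned sites is likewise
rescaled by the genome-wide variant density in variants-only mode.

**Site thinning.** For individual-level d_XY matrices, sites are
selected greedily left-to-right at ≥500 bp spacing, requiring ≥1
genotyped individual per population.

**Genotype filters.** DP ∈ [10, 100] for all calls; GQ ≥ 30 for variant
calls only. Multi-allelic sites are reduced to their two most frequent
alleles (other calls set missing) — all statistics are
pairwise-difference based, so this loses only third-allele information.
Coordinates are 0-based half-open internally.

**Sex handling.** ZW females are hemizygous on the Z; callers emit
their Z genotypes as homozygous diploid calls. Sex is taken from the
population map when declared, otherwise inferred from the heterozygous
fraction over a sample's genotyped Z variant sites: below 0.1× the
cohort male reference level (median over declared males, falling back
to the cohort median) → female. The 0.1 factor and the 100-site minimum
are our choices (the source states only that Z heterozygosity was
used); both are config keys. On Z windows each female then contributes
one haplotype row and residual heterozygous female Z calls — impossible
on a hemizygous chromosome — are set missing. Samples of unknown sex
are excluded from Z statistics.

## Coalescent simulator

An exact Hudson ancestral-recombination-graph walk over a locus of
length L (default 50 kb), with time in generations throughout:

* coalescence at rate k(k−1)/2 per 2N(t) generations within each deme,
  with piecewise-constant N(t);
* backwards migration at a per-generation per-lineage rate m (the
  "proportion of the deme replaced by migrants" convention; an ms-style
  4Nm convention would differ — we expose m directly);
* recombination at rate r·(span of ancestral material, trapped gaps
  included) per lineage, with the physical rate r = ρ/(4·N_ref) fixed
  by the population recombination rate ρ = 0.01/bp **at the baseline
  autosomal size N_ref**, so r is identical across epochs, partitions
  and size-change magnitudes;
* at the split time (backwards) all demes merge.

Each lineage carries intervals `(left, right, birth_time, leaf_bitmask)`.
Coalescence emits, for every overlapping stretch, the two branch
records of the marginal genealogies and retires stretches whose merged
leaf set is the full sample. The flat branch-record list *is* the
marginal tree sequence: infinite-sites mutations are dropped per branch
as Poisson(μ · interval · branch length) with the recorded leaves
carrying the derived allele, and TMRCA/total branch length at any
position are direct queries. Runaway ARGs are guarded by a hard event
cap.

**Mutation model.** Infinite sites at μ = 2e-9/bp/generation, replacing
a finite-site HKY model: at the divergences simulated here
(≤ ~0.03/site) multiple hits are negligible. This is a deliberate
simplification.

**Scenarios.**

* *Single size change*: baseline (pre-change) size Ne; at time t ago
  the size becomes x·Ne forward in time (x < 1 contraction, x > 1
  expansion). The quoted sizes (3e6 autosomal, 2.25e6 Z) are the
  pre-change sizes; we verified this convention reproduces the
  published ratio extremes where the alternative (present-size-quoted)
  convention cannot.
* *Two-population split*: demes of size Ne (2e6 autosomal) splitting T
  generations ago, symmetric migration m ∈ [0, 1e-6].
* *Z runs*: a separate replicate set with every size ×0.75 and
  migration ×(1−d); sample sizes, times, μ and r unchanged. The engine
  accepts k demes with a migration matrix (used by the synthetic-data
  module's stepping-stone studies); the two scenario constructors cover
  the 1–2-deme designs above.

Replicates: 5 diploid individuals (10 haplotypes) per population; a
master seed spawns one child stream per replicate, and grid runners
reuse the same replicate streams in every cell (common random numbers —
a variance-reduction choice for paired contrasts that leaves each
cell's mean unbiased).

**Validation.** Pair TMRCA, total branch length, E[π] = 4Neμ, the
neutral SFS, the isolation d_XY closed form and the size-change TMRCA
distribution are checked against closed forms; distributions of S and π
for constant-size, size-change and split-with-migration scenarios are
checked against msprime (two-sample KS), which serves strictly as a
cross-validation oracle.

## Resampling

* **Block jackknife** over 1-Mb genomic blocks (much longer than
  linkage disequilibrium in *Heliconius*), using the weighted delete-m
  form of Busing et al. (1999) because terminal blocks hold unequal
  window counts; with equal blocks it reduces to the classic delete-one
  jackknife, and on i.i.d. windows with singleton blocks it equals
  s/√n exactly.
* **Mantel tests** correlate upper triangles and permute the second
  matrix's labels jointly; one-sided (positive association) by default,
  matching the directional hypotheses, with a two-sided flag. p =
  (1 + exceedances)/(1 + permutations), or the exact enumeration over
  all n! permutations on request. Reported R² is r² of the Mantel
  correlation. Labels with NaN entries are dropped from both matrices
  (complete-case), since per-pair deletion is ill-defined under label
  permutation.

## Z/A inference layer

Population coordinates are arithmetic means of sample coordinates;
distances are haversine on a spherical Earth (R = 6371 km). The
dXY(Z)/dXY(A) ratio per pair is the ratio of genome-wide mean d_XY
values, not a mean of per-window ratios (per-window Z/A pairing is
undefined). Ratio-vs-distance and ratio-vs-autosomal-d_XY tests negate
the proxy so that positive Mantel r always means "ratio elevated where
gene flow is plausibly higher". Binned summaries use left-closed bins
from 0 (500 km, 1.25e-3 d_XY defaults).

**Saturation of the migration signal.** The d = 0.6 elevation of
dXY(Z)/dXY(A) rises steeply with m, saturates by m ≈ 2.5e-7 (at
T = 2e6, Ne = 2e6) and reverses by m = 1e-6, because sufficiently
strong migration drags *both* partitions toward panmixia and the ratio
back toward the within-population value. Monotonicity of the elevation
therefore holds in the rising regime; our acceptance check uses
m ∈ {0, 1.25e-7, 2.5e-7, 5e-7}.

## Synthetic data

The generator emulates the sampling design of a multi-population ZW
resequencing study: populations on a 1-D transect (300-km spacing),
star split at T = 4e5 generations with migration decaying geometrically
with transect distance (isolation-by-distance emulation), Ne = 2e6,
μ = 2e-9, a Z partition at 0.75·Ne with migration ×(1−d), d = 0.6.
Genotype noise straddles the filters: DP ~ N(35, 10) clipped with 5%
out-of-range draws, GQ uniform with 5% below 30, 2% missing calls;
female Z genotypes are emitted homozygous-diploid so the haploidization
path is exercised. It does **not** emulate reference bias, linked
selection, repeat-driven depth pathologies, or real *Heliconius*
geography — passing pipelines on this data demonstrates estimator and
plumbing correctness, not robustness to those artifacts. truth.json
records the parameters and loose smoke-test recovery bands (±35% on
π_A, ±0.2 on the ratio): they verify correctness of the pipeline, not
simulation precision.

## Problem sizes and numerical choices

Simulation studies run at reduced locus lengths, chosen because the
Z/A ratio of means is invariant to locus length (both partitions scale
with μL) while runtime is not: 5-kb loci for the equilibrium ratio and
the size-change grid, 10-kb for two-population runs (between-population
divergence has a longer correlation length along the genome). The
size-change grid uses x ∈ {0.01, 0.1, 1, 10, 100} and 8 log-spaced t
values in [1e3, 4e6]; with these cells the closed-form surface has its
minimum ≈ 0.42 at (x = 0.01, t ≈ 1.1e5) and maximum ≈ 0.85 at
(x = 100, t = 4e6); the continuous-t minimum is deeper (≈ 0.36), so
the published extremes imply a discrete grid of comparable resolution.
Replicates are allocated stratified: contraction cells (x < 1) get 10×
the base 300 replicates because their per-window diversity is a
heavy-tailed mixture (a window either escapes into the large
pre-change population or coalesces in the small present one; at 5-kb
loci and 300 replicates the minimum cell's ratio has a standard error
of ≈ 0.04, brought to ≈ 0.014 by the boost) while each such replicate
is several-fold cheaper than an expansion-cell replicate — so
equalizing Monte Carlo error also roughly equalizes cost. Ties in Mantel permutations count as exceedances (1e-12
slack); jackknife variances are floored at 0; degenerate inputs (π_T=0,
S=0, n<4, <2 blocks, <4 Mantel labels) return NaN or raise as
documented in the docstrings.

## Known limitations

* Exact-ARG cost grows superlinearly with ρ·L; 50-kb loci at full ρ are
  feasible but slow in pure Python, hence the reduced-length defaults.
* No selection, gene conversion, continuous space, or finite-site
  mutation; ≤2 demes in the published-scenario constructors.
* Tajima's D under heavy, non-random missingness uses an averaged-n
  approximation of the constants.
* The variants-only (`assume_callable`) mode assumes masking is
  independent of allele state; all-sites VCFs are preferred for real
  data.
* Sex inference needs females to be a minority or declared males for a
  reliable reference level.
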