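# Methods

`msatpop` re-implements, as a tested library, the population-genetic
workflow used in studies of riverine tsetse (*Glossina fuscipes
fuscipes*) around Lake Victoria: microsatellite diversity and
temporal-stability statistics, genetic clustering and migrant
assignment, hierarchical differentiation, sex-biased dispersal tests,
isolation-by-distance dispersal estimation, and effective/census
population size — including a sequential Bayesian census estimator
adapted to sampling *without replacement* (lethal trapping).  Because no
genotypes are distributed with the package, a forward-time
Wright–Fisher simulator generates study-shaped synthetic data with
known ground truth; all claims the test suite makes are claims about
estimator behavior on that simulator.

## Data model

Genotypes are diploid microsatellite allele pairs (non-negative integer
repeat numbers, 0 = missing).  A half-missing pair is coerced to fully
missing on construction, so every statistic sees complete pairs.
Populations are sample sites; higher levels (clusters, regions,
island/mainland) are `Grouping` maps from population to label.
Coordinates are WGS84 decimal degrees; all distances are great-circle
(haversine, Earth radius 6371.0088 km) in km.

## Diversity and exact tests

* H_O is the observed heterozygote proportion; H_E = 1 − Σp² (the plain
  estimator, matching the software used in the legacy literature), with
  uH_E = 2n/(2n−1)·H_E also reported.  F_IS = (H_E − H_O)/H_E, undefined
  at monomorphic cells and excluded from across-locus means.
* Allelic richness uses hypergeometric rarefaction to g gene copies;
  the default g is the smallest 2n over population×locus cells.
* The Hardy–Weinberg test is the exact conditional test given allele
  counts: complete enumeration for ≤4 alleles (probability ordering for
  the two-sided test, heterozygote-count ordering for deficit/excess),
  otherwise direct conditional Monte Carlo (shuffling the 2n gene
  copies), p = (b+1)/(B+1).  The Markov-chain sampler used by legacy
  software is replaced by this direct sampler: the estimand is
  identical and convergence is trivial.
* Linkage-disequilibrium and population-differentiation tests are
  Monte-Carlo exact tests on contingency tables (genotype×genotype,
  allele×population, genotype×population), with the Fisher ordering
  (tables as or less probable than observed).  Across loci, p-values
  combine by Fisher's method (−2Σln p ~ χ² with 2L df), with Monte-Carlo
  zeros floored at 1/(B+1).
* Multiple testing uses Benjamini–Hochberg step-up FDR control
  (default q = 0.05).

## F-statistics

Weir–Cockerham θ and the hierarchical F-statistics share one engine:
moment estimation of variance components for allele-indicator variables
in an unbalanced nested design (genes in individuals in populations in
optional higher levels).  Components solve the triangular system built
from the "reduction in sums of squares" quantities T_level and their
coefficient matrix; for the two-level design this reproduces the WC84
per-allele component formulas to machine precision (tested), and for
balanced multi-level designs it reproduces textbook nested-ANOVA mean
squares (tested).  Negative components are retained so slightly
negative θ (as reported for temporally replicated samples) is
representable.  Multilocus statistics are ratios of components summed
over alleles and loci; missing data are handled complete-case per locus.

F_{X/Y} is the sum of components from just below level Y down to X over
the sum from just below Y to the bottom; with populations as the only
level, F_{pop/total} is the usual θ.

Permutation significance: pairwise θ permutes whole individuals between
the two groups; the hierarchical test permutes units of the level below
the tested level among its categories within the enclosing level.  Both
engines precompute per-unit sufficient statistics (gene counts,
allele-count sums, summed squared dosages), so a permutation replicate
costs O(units); defaults are 10,000 permutations for pairwise θ.
A practical caveat discovered in calibration: with two categories the
tested level's F is invariant to label swaps, so the attainable p-value
floor is (number of unordered partitions)⁻¹ — e.g. eight populations in
two regions can never reach p ≤ 0.05.  Null-calibration fixtures use
ten populations.

## Clustering and assignment

Individuals are coded as allele-dosage vectors (0/1/2), missing dosages
imputed by the grand mean (not population means, which would leak
labels into the ordination).  Cluster discovery runs k-means on PCA
scores with BIC(k) = n·ln(WSS_k/n) + k·ln(n); the full PC space is
retained at this step (truncation makes the BIC monotone in k).  The
discriminant step (PCA then LDA on retained PCs) chooses the retained
PC count by the a-score — observed correct-reassignment proportion
minus its mean under cluster-label permutation — and reports
discriminant coordinates and Gaussian posteriors.

Assignment likelihood is log10 P(multilocus genotype | cluster allele
frequencies) under Hardy–Weinberg (p² / 2pq), with the focal
individual's alleles removed from its home cluster before computing
frequencies (leave-one-out) and unobserved alleles floored at
1/(2n+1) (ε = 0.01 optional).  Λ = log10 L(home) − max other; an
individual is flagged as a migrant at threshold T when Λ < T (0.5 and
1.0 by default).  Admixture-model MCMC clustering and iterative
reallocation algorithms are deliberately out of scope; the frequency-
likelihood method covers migrant detection.

## Sex-biased dispersal

Four statistics per sex: among-group F_ST, mean and variance of the
corrected assignment index (AIc = AI − group mean AI; AI is the
leave-one-out home-group log10 genotype likelihood), and mean
within-group pairwise relatedness (mPr).  Relatedness is the
Queller–Goodnight symmetric ratio-of-sums estimator with equal locus
weights; reference allele frequencies exclude the focal dyad, removing
the ≈ −1/n bias of same-sample references (identical-twin dyads still
give exactly r = 1).  Significance is two-sided, by permuting sex
labels within groups (sizes and sex ratios preserved); a Welch t-test
on F–F vs M–M dyads is reported alongside, flagged for the
non-independence of dyads.  Under male-biased dispersal males carry
more immigrant-like genotypes: mAIc(M) < mAIc(F), vAIc(M) > vAIc(F),
and male F_ST and mPr are lower.

## Isolation by distance and dispersal

Linearized pairwise differentiation y = θ/(1−θ) regresses on distance d
(1D model) or ln d (2D), with one-sided Mantel permutation of
population labels.  Negative-θ pairs are retained; θ = 1 and d = 0
pairs are excluded.  Under 2D stepping-stone theory the slope estimates
1/(4πDσ²); the package inverts it with user-supplied effective density
inputs: D = N_E/area (N_E from the LD method, per the study's choice),
σ² = 1/(4πbD), W_N = 4πDσ² = 1/b, σ = √σ²; 1D analogues use
D = N_E/length and σ² = 1/(4bD).  The migration rate is reported as the
stepping-stone identity m = σ²/ε² when an inter-deme distance ε is
given.  Habitat areas and ε have no defaults — they are study inputs.

Validation uses torus stepping-stone simulations compared with the
exact discrete Malécot identity recursion.  Two regimes matter:
nearest-neighbor kernels on small lattices equilibrate to slopes ~30%
below the asymptote (the exact recursion shows this is a property of
the model, not the estimator), while a smooth multi-cell kernel on a
25×25 torus sampled at 1.5–8 dispersal scales attains ≈0.9 of the
asymptotic slope.  The recovery suite therefore tests the latter
regime; real-data slopes at stepping-stone scales should be read with
the same caution.

## Effective population size

*LD method.*  The drift signal is the mean squared Burrows composite
correlation over locus/allele pairs (Δ̂ with the S/(S−1) factor,
normalized by p(1−p)q(1−q)), minus its sampling expectation.  By
default that expectation is estimated empirically: genotypes are
permuted among individuals within each locus pair (12 replicates,
seeded), which matches this exact statistic; the published E[r²|S]
curves are available as an option but were calibrated for a different
weighting and leave a residual that inflates N̂_E substantially (the
subtraction is numerically delicate: a 2% error in the expectation
moves N̂_E by tens of percent).  N_E solves r²′ = 1/(3N_E) − 0.69/N_E²;
r²′ ≤ 0 reports "infinite" (no drift signal).  Alleles below
pcrit = 0.02 are excluded.  CIs by jackknife over loci (default) or
parametric χ².  On Wright–Fisher simulations (N = 100, S = 50, 15
loci) the median estimate is ≈1.2× truth — the residual comes from the
1/(3N) drift approximation for this statistic — within the ±30% band
the recovery suite checks.

*Temporal moment method.*  F_k per locus is the mean standardized
squared frequency change (x−y)²/((x+y)/2 − xy) over alleles, weighted
across loci by allele count; N̂_E = t/(2[F_k − 1/(2S₀) − 1/(2S_t)])
(plan II — sampled individuals do not reproduce, which the simulator
implements literally by removing them), infinite when the bracket is
non-positive.  χ² CI on F_k with Σ(K_l−1) degrees of freedom.

*Temporal pseudo-likelihood.*  Per allele: Beta posterior for the
initial frequency from sample 0 (uniform prior), a moment-matched Beta
drift transition with variance p(1−p)(1−(1−1/2N)^t), and a
beta-binomial likelihood for the later sample count; the profile over
an N_E grid gives the point estimate and a 2-unit support interval.
This pseudo-likelihood (products over alleles and loci) replaces the
full coalescent Bayesian temporal machinery, which is out of scope.

## Census size from removal sampling

Tsetse trapping kills: the classic sequential Bayesian abundance
estimator for *with*-replacement sampling is adapted by replacing its
recapture likelihood with a binomial depletion model — occasion t's
catch is Binomial(N − K_{t−1}, p) with K the cumulative removal and p a
shared per-occasion capture probability.  A uniform grid prior over
N ∈ {K_T,…,n_max} (step 1, default n_max = 10·K_T) and p ∈ (0,1) (512
points) is updated occasion by occasion (identical to the joint
product, tested); outputs are the marginal posterior on N, its mean,
and the shortest-interval 95% HPD.  All-zero surveys are rejected:
under a removal likelihood zero catches are informative about (N, p)
jointly but leave N unidentifiable.  Calibration: with N = 1000,
p = 0.1, 8 occasions, the 95% HPD covers truth in ≈96% of surveys and
the posterior mean is within a few percent of truth in the median.

## The simulator

Forward-time Wright–Fisher over discrete demes: adult migration
(multinomial per deme and sex; male rates scaled by a configurable
multiplier), then random mating within demes (mothers from resident
females, fathers from resident males; each parent transmits one random
allele), then stepwise mutation (±1 repeat, reflecting bounds 5–60 so
labels stay valid 3-digit Genepop codes).  Reproduction is vectorized
across demes; torus lattices use a translation-invariant kernel with a
single displacement draw per individual.  Snapshots can be taken from
the post-dispersal adult pool (what a trap sees — required for migrant
detection and sex-bias signals, since first-generation immigrants must
be present) or from the natal cohort (the sampling assumed by
stepping-stone IBD theory).  Sampling is without replacement; temporal
sampling optionally removes sampled flies from the breeding population,
shrinking the deme (plan II semantics).

Founder structure: demes can be seeded from group-specific Dirichlet
draws around common base frequencies (expected founder F_ST ≈ 1/(c+1)
for concentration c), so realistic between-group differentiation is
available without implausibly long divergence runs.

The study-shaped preset (`paper_like_config`) has 14 lakeside sites in
3 groups (3+4+7), 15 loci, deme size 120, within-group migration ~0.04
per neighbor, weak between-group migration, male dispersal ×3 and
founder divergence c = 6; across seeds it lands mean H_E ≈ 0.39–0.55
and between-group θ ≈ 0.05–0.11, inside the empirical ranges reported
for the study system (H_E 0.30–0.53, between-cluster F_ST
0.036–0.191).  What the simulator does *not* emulate: overlapping
generations and age structure, seasonal abundance cycles, null alleles
and scoring error, selection, and continuous (non-deme) space — so
passing recovery tests demonstrate estimator correctness under the
stated model, not robustness to those realities.

## Problem sizes in the shipped suites

Null calibration runs 500 simulated nulls per test at B = 2000
replicates each (rejection at α = 0.05 checked against binomial 99%
bounds); recovery suites use 100 replicates for the LD and temporal
estimators, 50 torus lattices for the IBD slope, 200 surveys for the
census estimator, and 100 runs for sex-bias power.  The acceptance
script (`scripts/acceptance.py`) recomputes the same quantities at
reduced replicate counts chosen to keep a full run within a few
minutes; replicate counts are recorded in its JSON output.

## Known limitations

* The LD-N_E drift inversion 1/(3N) is approximate for the composite
  statistic; expect ≈+20% median bias at S/N = 0.5.
* The hierarchical permutation test is label-coarse with few units per
  category (documented p-value floor).
* The census model assumes a closed population and a shared capture
  probability across occasions; open-population dynamics between
  occasions will bias N_C.
* Dispersal inversion inherits every uncertainty of N_E and of the
  user-supplied habitat area; W_N = 1/b is the only density-free output.
* Exact replication of legacy software (Markov-chain HWE settings,
  ML relatedness, coalescent temporal estimators, admixture MCMC) is
  intentionally not attempted; the corresponding estimands are covered
  by the methods above.
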