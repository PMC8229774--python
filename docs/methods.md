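# Methods

This note documents the models behind each module, the defaults and why
they were chosen, what the synthetic data do and do not emulate, and the
numerical conventions a maintainer needs.

## Synthetic data model

Source populations follow the Balding–Nichols model: an ancestral
frequency p is drawn uniformly on [0.05, 0.95] per site, and each source k
draws its frequency from Beta(p(1−F_k)/F_k, (1−p)(1−F_k)/F_k), so that
E[p_k] = p and Var[p_k] = F_k·p(1−p). The ancestral range is bounded away
from 0/1 because the analyses operate on segregating SNPs; fully
monomorphic synthetic sites would only be discarded downstream. Default
differentiation uses F = 0.15 for the European source and F = 0.05 for the
two African sources — continental-scale versus within-African
differentiation on the order seen in genome-wide panels. Admixed diploids
are built allele copy by allele copy: each of the two copies picks a
source by the population's ancestry proportions and then a Bernoulli
allele from that source's frequency. The realized per-individual ancestry
draws are returned as truth.

For the Hudson Fst estimator this construction gives E[Fst] ≈ F (the
numerator estimates 2·Var(p_k|p) and the denominator 2·p(1−p), and the
sample-size corrections remove the binomial sampling terms), so
`calibrate_fst` — bisection on F with Monte-Carlo evaluation at the target
sample sizes, at least 1e5 sites internally — typically returns a value
very close to its target. The calibration is kept because it makes the
mapping exact under whatever sample sizes are requested rather than
relying on the approximation.

Haplotype mosaics switch ancestry at geometric distances (mean
1/switch_rate sites), redrawing the source by the mixing proportions and
the donor uniformly within the source; per-site source and donor truth
labels are returned. Note the redraw can land on the same donor, merging
adjacent segments: with K sources of n_k donors this thins visible
segment boundaries by a factor 1 − Σ p_k²/n_k, which the tests account
for.

Y-STR mutation is strict single-step (±1 repeat, equal probability,
uniform locus choice), matching the stepwise model under which the rho
statistic is calibrated; multi-step mutations are ignored. Repeat counts
are floored at 1 by reflecting the offending step upward, since a repeat
count is a physical copy number. Star mode gives each sampled lineage an
independent Poisson(L·μ·g) mutation count — the exchangeable-genealogy
limit in which the rho estimator is unbiased. Wright–Fisher mode holds a
constant male population; sons choose fathers proportionally to mating
success, and when a dominance model is attached the dominant class (fixed
size ⌈d·N⌉) is refilled each generation with fidelity τ from sons of
dominant fathers, lineage sons first, vacancies filled by a seeded random
draw from the remaining sons.

What the generator does *not* emulate: linkage disequilibrium from shared
genealogy (sites are exchangeable given the frequency draws), recombination
maps, mutation-rate heterogeneity across Y-STR loci, sequencing error
beyond the per-genotype depth/quality fields, and any real demography.
Passing tests therefore demonstrate estimator correctness under the
model's assumptions — unbiasedness, calibration, geometry — not robustness
to the full complexity of real cohorts.

## Variant QC

Filter order is fixed: (1) non-autosomal (chromosome name outside 1–22,
with or without a "chr" prefix) and multi-allelic/non-SNP sites are
dropped; (2) genotypes with depth < 3 or quality < 20 are masked to
missing; (3) sites with mean depth ≥ 35 are dropped; (4) sites with more
than 15% missing genotypes — after masking — are dropped. Mask-then-filter
is deliberate: a site whose missingness is pushed over the threshold by
low-quality genotypes is excluded. Applying the cascade twice is a no-op.

The Hardy–Weinberg test is the exact conditional test: given the sample
size and minor-allele count, heterozygote counts of matching parity have
probability proportional to 2^h · n! / (n_AA! h! n_aa!); the two-sided
p-value sums configurations no more probable than the observed one.
Monomorphic sites return p = 1 (nothing to reject). A site is removed only
when it fails (p < 0.05) in at least two populations, which keeps sites
failing in a single group (a local inbreeding or structure artifact). The
implementation is checked against an exact-rational enumeration oracle.

KING-robust kinship uses only heterozygote and opposite-homozygote counts,
making it insensitive to population allele-frequency structure;
self-comparison gives exactly 0.5, parent–offspring pairs concentrate near
0.25. Pruning is greedy: repeatedly drop the sample involved in most
above-threshold pairs (ties: higher missingness, then lexicographically
larger id). The threshold defaults to 0.177, the conventional geometric
boundary between first- and second-degree relationships, and is exposed as
a parameter.

## Haplotype painting

The copying model is a hidden Markov chain over donor haplotypes with a
uniform prior, transition "switch anywhere" probability
ρ = 1 − exp(−switch_scale) per inter-site interval (uniform per-site
spacing: exome-style targets carry no usable genetic map), and emission
1 − mis_copy on allele match. Forward–backward is run in scaled linear
space with per-site normalizers whose logs accumulate the likelihood; this
is underflow-safe for any number of sites. The expected chunk count of a
donor is its initial-state posterior plus the expected number of
transitions into it from a *different* state; with a single donor this is
exactly 1, and summed over donors it approaches the Viterbi segment count
as both noise parameters vanish.

EM updates: the mis-copy rate is the posterior mismatch mass per site; the
switch intensity is estimated from expected visible state changes scaled
by n/(n−1) to account for invisible same-donor switches (a single-donor
panel carries no switch information and contributes nothing). Per-
chromosome counts are pooled weighted by interval/site counts, then
averaged over recipients — identical to the exact pooled M-step when all
recipients share a site list, so the data log-likelihood is non-decreasing
and a decrease beyond 1e-8 raises an internal error. Default starting
values: switch_scale 1e-2, mis_copy 1e-3.

Population copy profiles follow the averaging convention: each recipient's
chunk counts are aggregated over donor populations, row-normalized, and
the profile of a recipient group is the average of its individuals'
profiles.

## Structure

PCA uses Patterson normalization — center each site at 2p and scale by
√(p(1−p)), mean-imputing missing genotypes after normalization (zero
contribution) — and an eigendecomposition of the individual×individual
covariance; scores are eigenvectors scaled by the root eigenvalues. The
admixture model maximizes the binomial likelihood Π Bin(g_is | 2, (QF)_is)
by plain EM from Dirichlet/uniform random starts, best of n restarts; this
shares its likelihood surface with the dedicated block-relaxation tools
and trades their speed for simplicity. Cluster labels are fixed by the
lexicographic order of the frequency vectors. Fst is the Hudson estimator
as a ratio of sums of per-site numerators and denominators (more stable
than averaging per-site ratios), with the (n−1) sample-size corrections;
whether a published pipeline used Hudson or Weir–Cockerham is often
unstated, so the Weir–Cockerham haploid-ANOVA form is provided as an
alternative — on balanced designs the two agree closely.

## Ancestry geometry

TVD is half the L1 distance between normalized copy profiles — a metric on
the profile simplex. NJ is the standard Saitou–Nei agglomeration on the
Q-criterion; negative pendant edges are truncated to zero with the deficit
moved to the sibling so the pair's summed length is preserved, and
additive matrices are reconstructed exactly (verified against an
independent NJ implementation). Bootstrap support resamples individuals
with replacement within populations, rebuilds averaged profiles, TVD and
the tree, and reports the fraction of replicas containing each split of
the main tree.

The tree-geometry estimator measures r = d(target_root, GoG) /
d(GoG, Angolan midpoint) patristically, where a population's "root" is the
internal node where its pendant branch attaches and the Angolan reference
point is the midpoint of the path between the two Angolan roots. The
Gulf-of-Guinea reference enters as its *leaf*: the formula is phrased as a
distance to that population, and using its attachment node instead
degenerates on colinear profiles, where the target's and the reference's
pendants attach at the same node and the ratio collapses to zero. Both
choices are exposed (`gog_node_mode`). The printed formula assigns the
ratio itself to the Gulf-of-Guinea contribution, yet the ratio vanishes
when the target coincides with the Gulf-of-Guinea reference; the default
reading is therefore the complement (GoG = 1 − r), with the literal
reading available (`reading='direct'`). On noise-free linear-mixture
profiles all three estimators (Bernstein, PCA projection, tree geometry)
recover the mixing fraction exactly and are monotone in it.

The PCA projection estimator works in a two-component plane (default
(PC1, PC3), configurable): targets are orthogonally projected onto the
line joining the two group centroids and the contribution of group A is
1 − d(projection, centroid_A)/d(centroid_A, centroid_B), clamped to [0,1].
Which component pair separates a given pair of centroids depends on cohort
composition; the synthetic acceptance cohort has no strongly drifted
outlier population, so its European/African axis is PC1 and its
within-African axis PC2, and the acceptance script projects in (PC1, PC2).

## Diversity

ROH calling reproduces the two-pass windowed algorithm at the standard
parameter set (50-SNP windows with ≤ 1 heterozygote and ≤ 5 missing;
SNP eligible when ≥ 5% of its overlapping windows are homozygous; maximal
eligible runs kept if ≥ 100 SNPs, ≥ 500 kb, mean density ≤ 50 kb/SNP, and
split at inter-SNP gaps > 500 kb). Windows at chromosome ends are
truncated rather than dropped, and eligibility divides by the number of
windows actually overlapping the SNP — a fixed convention of this
implementation. The published LD distance-bin list jumps from 35–40 kb to
> 45 kb; the bins are implemented exactly as printed, with the missing
40–45 kb bin available behind `LD_BINS_FULL`.

LD decay, the folded SFS and Fis downsample to 5 individuals (the smallest
reference panels), redrawn 10 times with seeds derived from the master
seed by replicate index, and averaged. LD r² is the squared genotype-
dosage correlation (the common tool default; with n individuals its null
mean is ≈ 1/(n−1), i.e. 0.25 at n = 5 — a baseline to keep in mind when
reading absolute values). Ho divides an individual's heterozygous sites by
the total SNP count; Fis compares observed homozygosity to its
Hardy–Weinberg expectation with the n/(n−1) small-sample correction.

## Uniparental

Mutational distance between Y-STR haplotypes is Σ|Δ repeat| over loci
(duplicated loci such as DYS385 are maskable and excluded from distances
when present). Descent-cluster delimitation is a breadth-first growth from
the ancestral (modal) haplotype adding sampled haplotypes that differ from
a current member at exactly one locus by one step — an explicit
operationalization of "close mutational neighbors", input-order invariant.
For simulated star genealogies, where the whole sample is the cluster by
construction, `cluster_from_sample` skips delimitation (BFS would drop
lineages whose intermediates are unsampled and bias ρ low). The TMRCA is
ρ/(L·μ) generations with μ = 0.0025 per locus per generation and L = 10
loci by default (11 typed minus the duplicated locus), times a 30-year
generation; the 95% CI uses the star-genealogy standard error
√(ρ/n)/(L·μ), floored at zero years — an approximation that ignores
genealogical correlation but achieves ~92% empirical coverage on simulated
stars. Single-step homoplasy (a +1 followed by −1 at the same locus)
slightly shortens distances, biasing the mean estimate a few percent low
at this time depth.

## Social-selection model

State: p (population frequency of the patriline) and q (fraction of the
dominant class carrying it). Each generation, sons choose fathers with
weight b for the dominant fraction d, so W = bd + 1 − d normalizes and
p' = (b·d·q + (p − d·q))/W. The new dominant class reserves τ·d of its
slots for sons of dominant fathers — lineage sons first — and fills the
rest at random from the remaining sons, which defines q'. Females are not
modelled; polygyny enters only through the male mating-success multiplier,
consistent with a Y-chromosome-focused question. With τ = 1, q0 = 1 the
closed form p_t = 1 − (1 − p0)/W^t holds and the implementation matches it
to 1e-12 over 100 generations; the stochastic Wright–Fisher counterpart
agrees within Monte-Carlo error at N = 1e5.

`required_advantage` bisects b on [1, 1000] for the smallest advantage
reaching a target frequency in T generations; under the default scenario
(d = 0.05, τ = 1, p0 = 0.05, target 0.6 in 16 generations) the closed form
inverts to b\* = 1 + ((0.95/0.4)^{1/16} − 1)/0.05 ≈ 2.111. The recursion
details behind any particular published "3×" figure are generally not
recoverable from a text alone (they depend on τ, p0 and the target
definition), so the model treats such figures as scenarios to locate in
the (d, τ, T) sensitivity grid rather than constants to reproduce; the
grid shows b ≈ 3 is required once the dominant class is smaller or status
transmission leaks.

## Problem sizes and determinism

Unit tests run on 3k–50k-site cohorts; the acceptance checks use the
study-scale 150k SNPs with reference panels of 10 diploids, 9/8-diploid
Fst pairs, and 1000 Y-STR replicates of 24 lineages — sizes at which every
recovery lands within its stated tolerance in seconds per analysis. All
randomness flows from explicit integer seeds (sub-seeds derived by CRC of
the stage or target name), and identical calls are bit-identical.

## Known limitations

Genotype sites are exchangeable — there is no genealogical LD, so the LD
and ROH analyses are validated on explicitly constructed founder/mosaic
structure rather than coalescent output. The painting engine assumes
uniform site spacing and a single switch intensity; the admixture EM is
slower than block-relaxation solvers and is run on pruned subsets; the
bootstrap resamples individuals only (not sites). The rho CI ignores
genealogical correlation beyond the star approximation. None of the
methods model phasing error, as inputs are generated phased.
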