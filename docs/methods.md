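# Methods

`genarch` analyses how genomic architecture — recombination rate and
linked selection — shapes the landscape of genetic diversity,
population structure and phylogenetic signal among three parapatric
populations separated by riverine barriers (labelled by the Amazonian
areas of endemism Tapajos, Xingu and Belem) plus an outgroup. The
package couples per-window summary statistics and structure scans with
a structured-coalescent simulator and simulation-trained neural
networks for demographic model selection and parameter estimation.

## Demographic models

Three 4-population isolation-with-migration histories differ only in
the unrooted ingroup topology:

* topology 1: (outgroup, (Belem, (Xingu, Tapajos)))
* topology 2: (outgroup, (Tapajos, (Xingu, Belem)))
* topology 3: (outgroup, (Xingu, (Tapajos, Belem)))

Each model carries diploid effective sizes for the four sampled demes
and the two internal ancestors, divergence times `t_recent < t_deep <
t_outgroup` in generations, and constant symmetric migration between
the geographically adjacent pairs Tapajos–Xingu and Xingu–Belem.
Migration between the disjunct Tapajos–Belem pair is structurally
forbidden. Migration is specified as the population migration rate
2Nm (migrant lineage pairs per generation, matching how gene-flow
estimates are usually reported) and converted internally to the
backwards per-lineage rate `m = 2Nm / (2 N_receiver)`.

Defaults: mutation rate 2.42e-9 /bp/generation (a passerine pedigree
rate), generation time 1 yr, outgroup split 9.6e6 generations (the
deepest of the three reference TMRCAs at a 1-yr generation time).

### Priors

Parameter draws use wide uniform priors: Ne ~ U(5e4, 2e6)
independently per deme, t_recent ~ U(5e4, 5e5), t_deep uniform between
max(5e4, t_recent) and 2e6, 2Nm ~ U(0, 4) per adjacent pair. These are
substitutes chosen to be "uniform and wide" with magnitudes bracketing
published estimates for Amazonian understory birds; any bound can be
overridden in the YAML config. Single-window inference adds an
intralocus recombination prior U(0, r_max) with r_max = 3.021e-9
(configurable per species).

## Simulation engine

Genealogies come from msprime's structured coalescent (haploid sample
sets under a diploid-size demography, so a sample of two gene copies
in a deme of size N has E[TMRCA] = 2N generations — verified against
that expectation and E[π] = 4Neμ in the test suite). Mutations follow
an infinite-sites model. For non-recombining loci the package drops
mutations itself: Poisson(branch length × μ × L) mutations per branch,
each at a unique uniform position, derived allele below the branch.
This vectorised path is what makes dataset-scale simulation affordable
on one core; recombining loci delegate to msprime's mutation generator
with a continuous genome. Continuous positions are floored to 1-based
integers; rounding collisions are bumped right (a site pushed past L,
which is vanishingly rare, is dropped).

### Landscape generator

The genome-landscape generator emulates sweep-like diversity
suppression without simulating selection trajectories: each window is
assigned one of five classes (hard, linked_hard, soft, linked_soft,
neutral) and its local effective size is multiplied by a per-class
suppression factor in (0, 1] (neutral = 1). This reproduces the
phenomenology that matters downstream — locally reduced diversity and
downward-biased local-Ne estimates in swept classes — and carries
exact truth labels, emitted as a class-probability track (probability
1 for the true class, optionally blurred). What it does **not**
emulate: the site-frequency-spectrum distortions and haplotype
structure specific to genuine sweeps, background selection, or
ascertainment noise in class assignment. Passing tests therefore show
that stratified inference recovers diversity-mediated Ne contrasts,
not that a sweep classifier would be accurate on real data.

## Summary statistics

All statistics tolerate missing data by per-site sample sizes; sites
with fewer than two called haplotypes in a required group are skipped
and counted. The effective length defaults to the simulated
`seq_length` (every non-SNP position is callable in simulated data)
and accepts a callable-site count for real data. Choices worth
noting:

* π uses the unbiased per-site estimator 2c(n−c)/(n(n−1)); Watterson's
  θ applies the harmonic correction per segregating site; Tajima's D
  evaluates the standard constants at the mean called sample size over
  segregating sites (an approximation under missingness).
* F_ST is Hudson's window-level ratio of sums, 1 − Σπ_within/Σπ_between,
  clamped to [0, 1] with the raw value also recorded; a window with no
  between-population diversity is undefined (NaN).
* ABBA-BABA D and f_dM use sample allele frequencies without
  finite-sample correction. f_dM's dynamic-donor denominator replaces
  both copies of the donor with max(p2, p3) when a site's D-numerator
  term is non-negative and with the symmetric P1-donor form (negated)
  otherwise, so P1←P3 gene flow gives negative values; the exact
  branch rules are pinned by a site-wise oracle in the tests.
* The H-scan statistic averages, over haplotype pairs, the length of
  the identity tract containing a focal SNP, bounded by flanking
  mismatches or the first/last SNP positions and truncated at
  inter-SNP gaps above 100 kb (the scan's physical-distance mode). It
  refuses unphased input.

## Local-PCA scan

Windows of a fixed SNP count (default 1000, tolerating 30% missing
genotypes) are summarised by the top-k (default 2) eigenpairs of the
individual×individual covariance of mean-imputed, centred dosages.
Window dissimilarity is the Frobenius distance between rank-k
covariance approximations, computed from eigenpairs without forming
the matrices. Classical MDS (double-centring + eigendecomposition)
embeds the windows; "corners" are the ceil(fraction·n) windows nearest
three extreme points chosen greedily (farthest from the centroid, then
twice the point maximising the minimum distance to those chosen). An
exact O(n³) triple-maximising variant is available for small n.
Corner membership may overlap; overlaps are reported, not forbidden.

## Topology weighting

Window genealogies are built by neighbor joining on pairwise haplotype
Hamming proportions (jointly called sites), with negative branch
lengths clamped to zero. Quartets (one tip per group) are resolved
structurally: zero-length branches are collapsed, unit-branch-length
path distances are computed once per tree, and the integer four-point
condition identifies each quartet's split exactly. Ties (star
quartets) split their vote equally by default; a discard mode exists.
Exact enumeration is used up to 50,000 combinations, seeded uniform
sampling (default 10,000 draws) beyond.

## Neural-network inference

Datasets (or single 100 kb windows) become fixed-order feature
vectors: the mean and variance across loci of 33 per-locus statistics
— segregating sites, π and Watterson's θ per ingroup population and
pooled; Hudson F_ST per pair; shared polymorphic sites per pair;
private polymorphic sites per population and per pair member; fixed
derived sites per population; oppositely fixed sites per pair. Loci
where any population has fewer than 3 called individuals are excluded
and reported. For a single window the variance half is zero and is
dropped by the zero-variance feature filter at training time.

Networks are scikit-learn multilayer perceptrons with 3×32 relu hidden
layers: a softmax classifier over the three topologies (25% held-out
test split, 5% validation fraction) and one rectified-output regressor
per parameter, trained as 10 seeded replicates whose predictions are
averaged. Features are z-scored from the training split only;
zero-variance features are dropped from both simulations and
observations. Regression targets are scaled by their training mean
before fitting — squared loss on mean-scaled targets stands in for a
relative-error objective, and both MAPE and MAE are reported on the
held-out split so the error can be read on either scale. Adam with
learning rate 3e-3, up to 1000 epochs and patience 50 gave reliable
convergence at these data sizes.

Goodness of fit standardizes features, takes the median distance from
the observation to its k=10 nearest simulated vectors, and compares it
with the same statistic for held-out simulated vectors (the p-value is
the null fraction at least as large); a 4-component PCA overlay is
returned for plotting.

Stratified estimation groups windows by confidently assigned sweep
class (max probability strictly above 0.70), subsamples each class to
a cap (seeded), averages per-window regressor predictions and reports
the bootstrap SE of that mean.

### Validity domain of the estimators

Simulation-trained estimators are only meaningful where the training
prior has mass. Stratified estimation on the synthetic landscape
therefore uses a base effective size (default 1.5e6) whose suppressed
windows keep their local size inside the default Ne prior support;
feeding a relu network feature vectors many standard deviations outside
its training distribution produces arbitrary extrapolation, not a
biased-but-usable estimate.

## Problem sizes

The study this package models ran around 10^6 simulations per
demographic model. The package defaults are desk-scale: samples of 20
haplotypes (10 diploid individuals) per ingroup population — the
sampling design the inference problem assumes — with roughly 300
training datasets per topology of 200 independent 10 kb loci each for
genome-wide model selection, about 2000 single 100 kb windows for
recombination-aware regression, and landscape scans of ~100 windows.
These sizes were fixed once, as defaults that complete on a single core
in minutes; every size is a plain function argument, so full-scale runs
only need bigger numbers. Scaled-down training reduces classifier
accuracy and regression R² relative to a 10^6-simulation design — the
qualitative orderings (which parameters are identifiable, how migration
blurs topology) are the reproducible content at this scale. Under the
default wide priors, identifiability itself also binds: when t_deep
approaches t_recent the three topologies converge to a near-trichotomy
no classifier can separate, and when divergence is recent relative to
deme sizes a single window carries little information about present-day
Ne — enlarging the training set does not lift those ceilings.

## Numerical conventions

* VCF positions are 1-based; windows are 0-based half-open; converters
  are tested both ways.
* Unphased diploid genotypes split into pseudo-haplotypes in VCF
  sample order and the matrix is flagged unphased; phase-requiring
  statistics refuse it.
* Multiallelic and indel records are skipped and counted; the geno
  dialect writes missing diploid calls as `N/N`.
* Quantile subsets break ties by genomic order; remainder SNPs after
  the last full fixed-SNP window are dropped.
* All randomness flows through explicit integer seeds; identical seeds
  give bitwise-identical simulations, training splits, network
  initialisations and subsamples.

## Known limitations

* The landscape generator's suppression model is a stand-in for sweep
  dynamics (see above); its truth-label probabilities are optimistic
  relative to a real classifier's output.
* Tajima's D under heavy, uneven missingness uses a mean-sample-size
  approximation for its normalising constants.
* The FPR-adjusted nonneutral fraction is a documented heuristic
  (nonneutral × (1 − FPR)); window-level FPRs do not translate
  uniquely into site-level proportions.
* NJ window trees are a distance-based stand-in for ML gene trees;
  with very few SNPs per window they are noisy, which topology
  weighting absorbs as flatter weights rather than bias.
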