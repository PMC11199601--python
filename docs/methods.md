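# Methods

This note documents the models behind `ploidsv`, the choices made where
the design was genuinely open, and what the synthetic cohort does and
does not establish about real data.

## Dosage model

Genotypes in an autopolyploid of ploidy x take values g = 0..x. Given
ref/alt read counts, the likelihood of each g is beta-binomial:

    L(g) = BetaBin(alt | depth, pi_g, rho),
    pi_g = (g/x)(1 - e) + (1 - g/x) e,

with sequencing error rate e (default 0.01) and overdispersion rho
(default 0.01; rho = 0 degenerates to the binomial). The prior is
Binomial(x, q) with the site allele frequency q estimated by an EM
fixed point (expected alternate copies over total chromosomes,
tolerance 1e-8, at most 200 iterations; the observed-data log-likelihood
is asserted non-decreasing every iteration). Analyses consume the
posterior mean E[G] = sum g P(G=g) — the allelic dosage — rather than a
hard call, so genotype uncertainty propagates. The model deliberately
omits allele-bias and outlier components found in full polyploid
genotypers: any calibrated posterior supports the dosage summary, and
this one is closed-form and oracle-testable. On the default synthetic
cohort (depth ~40, e = 0.01, rho = 0.01), the modal-posterior genotype
matches truth for >= 95 % of tetraploid entries at depth >= 30.

## Diversity statistics

Integer allele counts are the dosage sums rounded half-up (ties toward
the larger count; the discretization is logged when it moves a count by
more than 0.25 copies). Folded spectra bin minor-allele counts over
1..floor(n/2); monomorphic sites are excluded and a count of exactly n/2
is binned once. Tajima's D uses the standard constants computed from the
stratum chromosome count n; singleton exclusion removes bin 1 from both
S and pi before the same formula. Strata of unequal n are never pooled —
cross-ploidy comparisons downsample the larger cohort to the smaller
cohort's chromosome count. Missing calls (at most 20 % per site, enforced)
are imputed per chromosome copy as Bernoulli draws at the site frequency,
with a seeded generator.

The individual-covariance entry for PCA is

    C_ij = (1/m) sum_s (g_is/x_i - p_s)(g_js/x_j - p_s) / (p_s (1 - p_s)),

normalized per haploid copy so diploids and polyploids are comparable;
sites fixed in the sample are excluded, missing entries pairwise. With
all x_i = 2 this is the standard normalized diploid covariance (verified
to 1e-12 against a loop-written oracle). F_ST is Hudson's ratio of
averages; isolation-by-distance uses haversine distances (Earth radius
6371.0088 km) and a seeded Mantel permutation test. TE-style insertion
ages come from F81 divergence K = -B ln(1 - p/B) and T = (K/2)/mu with
mu defaulting to 6.95e-9 per site per year.

## Enrichment and constraint

The null for feature enrichment is bp share: expected_f = N_sv x
bp_f / bp_genome, and the reported statistic is log2(obs/exp) with a
percentile bootstrap over SVs (equivalently a multinomial redraw of
class labels; 1000 replicates, seeded). Zero-count classes get an
explicit, flagged 0.5 continuity correction. Conservation scores are
normalized by each site's attainable maximum (values above 1 are clipped;
negative scores pass through), summarized per gene as the median over
coding sites, and standardized across genes to median 0 and MAD 1 with
the MAD unscaled (no 1.4826 factor). Whether to clip normalized scores
above 1 was an open choice; clipping is documented behavior.

## Association and sweep stand-ins

The genotype–environment scan is a closed-form stand-in with the same
interface and decision rule as MCMC-based scans: population frequencies
(MAF > 0.05, <= 20 % missing, beta-imputed) are centered and whitened by
the Cholesky factor of a population covariance Omega, each standardized
bioclimatic variable likewise, and the per-variant Bayes factor is the
Zellner g-prior quantity BF = (1+g)^((n-2)/2) / (1 + g(1-R^2))^((n-1)/2)
with g = n populations, reported as dB = 10 log10 BF. Each scan runs 10
times under a small seeded frequency jitter (sd 1e-3) and the median dB
is kept; a variant is an outlier when its best variable's median dB is
>= 10 (inclusive). Outputs are labeled `gea_method = "gprior-bf"`: these
are stand-in scores, not reproductions of an MCMC sampler.

Omega is estimated from common (MAF > 0.05) neutral markers as the
population covariance of binomially standardized frequencies, with two
conditioning steps that matter in practice: the constant vector — an
exact null direction of any row-centered estimate, carrying no
between-population contrast — is restored to the bulk eigenvalue level,
and the matrix is shrunk 10 % toward a scaled identity. Without the
first step, whitening amplifies noise along the near-null direction and
can erase genuine clines. The whitening happens after centering, so an
identity Omega is exactly a no-op.

The sweep statistic contrasts the folded SFS of SNPs within 20 kb of an
SV's breakpoints against the genome-wide background spectrum of the same
population: CLR = 2 sum_sites [log p_hat - log q], with p_hat the window
multinomial MLE, clipped at zero, requiring >= 5 window SNPs and
populations of >= 6 samples; the per-SV signal is the maximum over the
ploidy group's populations. Background classes with zero probability but
window occupancy trigger logged add-one smoothing. "Ploidy-specific" is
operationalized as common (MAF > 0.05) in the focal group with fewer
than 0.5 expected alternate copies in the other group (the tolerance
absorbs dosage noise around a true zero); the 2x2 group test is a
two-sided Fisher exact test computed by hypergeometric enumeration.

## Climatic landscapes

RDA is the least-squares projection of column-centered frequency
matrices on standardized predictors, with canonical axes from the SVD of
the fitted values; axis signs are anchored so the largest-magnitude
variable loading is positive. Forward selection admits the candidate
with the largest added R^2 only if its permutation p-value (candidate
rows permuted, selected block fixed, add-one estimator) is below 0.01.
Partial-RDA fractions use Ezekiel-adjusted R^2; negative adjusted values
are reported as-is. Adaptive indices are the grid's standardized
environments (training means/sds) projected on the first two axis
loadings; for cross-class comparability each axis is scaled to unit
variance over the grid before Euclidean distances, which are then
min-max normalized — the convention that makes SV- and SNP-based maps
commensurable, since no canonical normalization exists. Genomic offsets
use the unscaled axes so linearity in the environmental shift holds
exactly; per-population offsets are read at the nearest pixel. The
occurrence grid is an equal-area approximation: 100-km latitude rows
with longitude scaled by the row-center cosine, half-open cell
assignment.

## The synthetic cohort

The generator is the package's study-condition module, not a fixture.
Defaults describe a European-style survey: 2 chromosomes of 500 kb with
20 multi-exon genes (exons ~2 % of the genome), 24 diploid and 24
tetraploid populations of 6 samples on a lon/lat domain, 2000 SVs and
2000 SNPs, read depth Poisson(40) with error 0.01 and overdispersion
0.01, 5 % missing calls. Eleven bioclimatic variables are fixed linear
mixtures of two latent spatial gradients (a narrow pi/8 fan plus
independent noise, sd 0.1), giving the strong inter-correlation real
bioclim layers have — the 11-variable scan behaves like roughly two
effective tests, which is what makes the dB >= 10 rule well calibrated
at this cohort size.

Allele frequencies are hierarchical: a U-shaped global frequency
Beta(0.3, 0.3), a per-ploidy-group logit-normal divergence (sd 0.5 —
diploid and tetraploid lineages are differentiated, and this is the
structure the whitening covariance absorbs), and population-level drift
as Beta draws with concentration 20. Scenario switches plant known
effects: exonic placements retained with probability `exon_thinning`
(the truth class is the class at the start breakpoint, so the planted
deficit is exact against the bp-share null; deletion spans can still
cross boundaries, where span-based classification resolves by
precedence); a masking scenario that replaces a fraction of exonic SV
frequencies in polyploids with a very-low-frequency point mass (one
expected copy per two cohort chromosome sets — the magnitude of the real
effect is unknown, so tests are sign-based only); climate-causal SVs
with a logit slope of 1.5 per environmental SD, drawn from mid-frequency
variants; ploidy-restricted SVs (15 % tetraploid-only, 5 % diploid-only);
and optional constraint-dependent purging of exonic SVs from diploids.
Divergent sequence pairs for insertion-time recovery evolve under an F81
process scaled so K = 2 T mu exactly.

All randomness flows from one root seed through named per-stage
substreams, so every stage is reproducible independently of call order,
and generated VCF/GFF3/TSV outputs round-trip through the readers.

What the generator does not emulate: linkage between SNPs and SVs (so
sweep-GEA correlations are null on synthetic data — a calibration check,
not a power check), coalescent-exact genealogies, TE sequence models,
reference/alignment artifacts, and spatially autocorrelated drift.
Passing tests therefore establish internal correctness and calibration
under the stated models, not performance on any particular empirical
call set.

## Problem sizes of the verification runs

The replicated checks use sizes chosen to make their statistics
well-resolved: 100 cohorts of 20 000 SVs for bootstrap-CI coverage of
the planted exonic deficit; 20 cohorts of 4000 SVs for the masking sign
tests, run on the generator's genotype layer (g ~ Binomial(x, p), dosage
= g) with equal-chromosome strata; 20 cohorts of 2000 SVs each for GEA
null calibration and power, using the truth frequency matrices; a
100 kb alignment for insertion-time recovery; exhaustive folded spectra
with n <= 12 and S <= 6 for the Tajima oracle sweep. The full
read-count -> likelihood -> EM -> dosage path is exercised separately in
the dosage tests and the end-to-end pipeline run.

## Known limitations

* The GEA and sweep statistics are interface-compatible stand-ins; their
  numerical values are not comparable to MCMC Bayes factors or
  sweep-model composite likelihoods beyond rank/decision behavior.
* Depth floors for x = 6, 8 generalize the 10/20-read diploid/tetraploid
  rule as 5 reads per haploid copy; no published rule exists for the
  higher ploidies.
* Feature painting builds a per-bp label array per chromosome — exact
  and simple at megabase scale, memory-heavy for gigabase genomes.
* The beta imputation falls back to resampling observed values when the
  method-of-moments Beta is invalid (variance >= m(1-m)).
* Fisher p-values are exact only for 2x2 tables; larger contingency
  structures are out of scope.
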