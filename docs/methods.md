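# Methods

This package reimplements a genomic-prediction and pleiotropic-QTL-mapping
workflow for multi-trait sheep data: single-trait mixed-model association,
GBLUP and BayesR genomic prediction with sire-family cross-validation,
three multi-trait QTL detection procedures, and an independent validation
of selected SNPs through linear indices.  Because no real genotypes or
phenotypes ship with it, a synthetic population generator with known
ground truth drives every stage.

## The phenotype model

All analyses assume, per trait,

    y = 1 mu + X b + s_i a_i + Z1 a + Z1 Q q + Z2 s.f + e

with fixed effects b (flock, sex, age covariate by default), an optional
single-SNP fixed effect a_i, a polygenic effect a ~ N(0, A sigma2_a) under
the pedigree numerator relationship matrix A, a random breed effect
proportional to the pedigree Merino proportion Q (q ~ N(0, I sigma2_q)), a
sire-by-flock interaction s.f ~ N(0, I sigma2_sf) and a residual.
Heritability is reported as h2 = sigma2_a / (sigma2_a + sigma2_sf +
sigma2_e); the breed term is treated as between-population variance and
excluded from that denominator.

**REML.** Variance components are estimated by maximizing the profiled
restricted likelihood over log variance ratios (Nelder-Mead).  Each
evaluation works in the eigenbasis of A restricted to the phenotyped
animals — computed once and cached — with the low-rank sire-by-flock and
breed terms folded in by the Woodbury identity, so an evaluation is
O(n·L) for L interaction levels rather than O(n^3).  Ratios that converge
below 1e-8 of the residual are reported as exact zeros.

**Adjustment.** The working phenotype for all downstream stages is
y − X b_hat − BLUP(breed) − BLUP(sire-by-flock), centered.  The polygenic
effect is deliberately left in: GWAS, BayesR and the window GWAS each
re-fit it.  Adjustment is not exactly idempotent — re-estimating the
variance components on adjusted data gives boundary estimates near zero
but the GLS fixed-effect fit changes residuals at the 1e-2 SD level on a
600-animal fixture — and the test suite checks a small bound rather than
machine precision.

**GWAS.** A two-stage scheme: adjust once, then score every SNP by exact
GLS in the rotated (eigenbasis-whitened) space with the polygenic
variance ratio held at its REML estimate.  This matches the one-SNP-
at-a-time mixed model on fixtures to 1e-8 (tested against an explicit GLS
oracle) at a fraction of the cost; the rotated genotype block is cached
across traits that share an observed-animal set.  P-values use the normal
reference, appropriate at the sample sizes this pipeline targets; at very
small n the t reference would differ.

**FDR.** For threshold P with A of T tests significant,
FDR% = 100·P(1−A/T)/[(A/T)(1−P)] — the expected false positives at the
threshold divided by the declared positives, with the finite-sample
correction factors.  Estimates above 100% (or A=0) are reported as
unavailable.  This form reproduces, after one-decimal rounding, all the
printed worked examples it is tested against.

## Genomic prediction

The GRM is VanRaden method 1, G = ZZ'/(2 Σ p(1−p)), allele frequencies
from the full supplied genotype set, SNPs with MAF ≤ 0.005 excluded.
GBLUP solves the animal-model equations with validation phenotypes
unknown; it is algebraically identical to SNP-BLUP ridge regression with
lambda = sigma2_e/sigma2_SNP (tested).  sigma2_g is re-estimated by REML
on each training fold (one eigendecomposition per fold, shared across
traits would be possible but is not needed at desk scale) to avoid any
leakage from validation data.

Cross-validation folds respect paternal half-sib structure: crossbred
animals (0.25 < Q ≤ 0.90) and all straightbreds sharing a sire with a
crossbred are permanently in training; the remaining straightbred sire
families are dealt whole into five folds.  Accuracy is
cor(GEBV, adjusted phenotype)/sqrt(h2) per fold, with h2 from the
full-data pedigree REML (whether per-fold h2 would be preferable is
undecidable from the source description; full-data is used), and the SE
of the mean over folds.  On simulations this estimator agrees with the
truth-based cor(GEBV, true BV) within ±0.1 (an acceptance check).

## BayesR

SNP effects follow a four-component normal mixture with variances (0,
1e-4, 1e-3, 1e-2) × sigma2_g.  Single-site Gibbs: class membership from
the marginal likelihood of each class, then an effect draw; Dirichlet
(1,1,1,1) update for the proportions; scaled-inverse-chi-square updates
for sigma2_g, sigma2_e and the polygenic variance; a residual polygenic
effect sampled single-site through the sparse inverse of A (Henderson's
rules, inbreeding included).  The kernel is compiled with numba; a chain
over 2,000 animals × 6,000 SNPs runs ~60 iterations/second on one core.

Two numerical choices deserve note:

- **Mixture-scale prior.** sigma2_g (the scale that defines the class
  variances) carries a moderately informative scaled-inverse-chi-square
  prior (nu=20) centered at the phenotypic variance.  The mixture classes
  are identified only while their variances remain separated from zero;
  with a diffuse prior a signal-free trait lets sigma2_g collapse, after
  which class labels are exchangeable and the "nonzero" posterior
  probability drifts as a reinforcing random walk.  With real signal the
  data term exceeds the anchor by orders of magnitude, so inference on
  informative traits is unaffected.
- **Sparse start.** Proportions start at (0.95, …), as published
  implementations do; under weak separation the proportions mix slowly and
  the start matters for null data.

Even so, pp_nonzero is only weakly calibrated when m SNPs is small
relative to what pins the proportions down: on a permuted (null) desk-
scale trait mean pp is ~0.05, not 0.  The tests bound it accordingly.

Reference-scale settings (40,000 iterations, 20,000 burn-in, 5 chains)
are available through the config; the defaults (10,000/4,000/2) and the
desk-study settings (1,500/500/1) were chosen so the whole multi-trait
analysis runs in minutes while the large-effect classes are stable.
Convergence is reported as between-chain agreement of sigma2_g (warning
only).

GEBV are centered-dosage × posterior-mean effects, the polygenic term
excluded from prediction.  Local GEBV restrict the sum to 250-kb windows
tiling each chromosome half-open from position 0 (the anchoring rule is a
convention; nothing downstream depends on it) and conserve the
whole-genome GEBV exactly.  Dosage centering affects the level of local
GEBV, not their variance.

## The three multi-trait analyses

**multi-GWAS.** chi2_i = t_i' V^-1 t_i with t_i the signed single-trait
t-values of SNP i and V their trait×trait correlation over all SNPs
(including nulls).  Degrees of freedom equal the trait count.  If V is
near-singular it is shrunk toward the identity by the smallest epsilon
restoring a 1e-6 eigenvalue floor, and the epsilon is recorded.  The most
significant SNP with P < 5e-7 per 1-Mb tile is called; ties break to the
smaller position.

**multi-PP.** pp_effect≠0 = 1 − Π_traits pp_effect=0; calls above 0.3,
with contributing traits defined as per-trait pp > 0.05.  Note the 0.3
threshold is calibrated for ~44 traits and half a million SNPs; with 8
desk-scale traits the null product sits higher and this method over-calls
relative to the others.  The threshold is kept as published and the
behavior documented rather than re-tuned.

**multi-LGEBV.** Per 250-kb window, the trait×trait covariance of local
GEBV standardized by phenotypic SDs; windows are ranked by the first
eigenvalue (the variance, in phenotypic-SD units, of the leading trait
combination).  For each selected window the pseudo-trait S_LC = y'x (PC1
eigenvector dotted with the standardized local GEBV; animals missing a
trait use the measured-animal mean) is regressed on every SNP in the
window under a pedigree animal effect whose variance ratio comes from a
one-time REML on S_LC; the SNP with the highest F is the best SNP.  The
desk-scale study selects the top 20 windows (vs 120 of 9,813 at reference
scale — about the same selection fraction).

Cross-method overlap uses exact SNP identity by default, with an optional
proximity merge; SNP-effect correlations across traits and a ±50-kb
candidate-gene interval lookup (closed bounds, 1-based inclusive gene
spans, nearest gene primary) complete the module.

## Missing phenotypes and the linear index

The trait×trait phenotypic covariance of adjusted phenotypes (pairwise-
complete, projected to positive definite with a 1e-8 eigenvalue floor;
the shift is recorded) is inverted once; per missing pattern,
y_n_hat = −(U^nn)^−1 U^nm y_m, which equals the multivariate-normal
conditional expectation Σ_nm Σ_mm^−1 y_m (the equality is tested).  The
covariance is estimated on all animals by default, with the training-only
variant available through the API.

For each selected SNP, the linear index y_I = b' C^−1 y uses the SNP's
training-population effect vector b and the covariance C of raw effect
estimates (not t-values) over all SNPs in training.  Each index is then
regressed on its own SNP in the validation animals under a pedigree
animal effect.  The training-side reference direction of an index on its
own SNP is b'C^−1 b > 0 by construction, so direction agreement is the
sign of the validation effect; under the null it is a fair coin (tested).

## The synthetic population

Three generations: unrelated founders, sires/dams (children of random
founder couples), and the phenotyped offspring (default 50 sires × 10
dams × 4 offspring = 2,000).  Founder haplotypes come from a coalescent
simulation (population size 1,000, recombination 1e-8/bp — livestock-like
LD), restricted to biallelic sites with minor-allele frequency in
[0.05, 0.5]; gene-dropping with Poisson crossovers at 1 cM/Mb and no
interference produces the descendants, so LD decays with distance and
Mendelian consistency is exact (no mutation).

Per trait the phenotypic variance is 1, so all effects are in phenotypic
SD units: sigma2_a = h2, sigma2_sf = 0.05, residual the remainder; fixed
flock/sex/age effects of 0.5 SD (large enough that skipping adjustment is
visible); a 0.3-SD breed-proportion effect.  Default heritabilities span
0.1–0.8 across 8 traits, genetic correlations 0.4, residual correlations
0.25.  Of 20 QTL (MAF ≥ 0.1, ≥ 2 Mb apart), half are pleiotropic with
effect vectors drawn from MVN(0, genetic_corr) and half are private to
single traits; QTL effects are rescaled against their realized offspring
variance so the QTL share of genetic variance is exactly qtl_var_frac
(0.5) per trait, and the polygenic covariance is set to the remainder of
the target genetic covariance (projected to PSD), so the total genetic
correlation matches the configured matrix up to pedigree sampling.
Typical per-QTL variance is then 1–3% of phenotypic variance per trait,
the same order as the largest window variances the method is meant to
detect.  Crossbreeding enters through dams clustered on a subset of
sires, with exactly crossbred_frac of offspring at 0.25 < Q ≤ 0.90.

One seed drives everything via numpy SeedSequence spawning in a fixed
order (pedigree, genotypes, traits), so reruns are byte-identical.

What the generator does NOT emulate: genotyping error and missing calls
(QC is exercised with synthetic corruption in tests), imputation error,
selection, assortative mating, dominance/epistasis, X-linked loci,
age-structured repeated measures, or batch effects.  Passing tests
therefore show the estimators are correct and calibrated under the
generating model, not that real wool data would yield the same accuracy
or QTL counts.

## Desk-scale problem sizes

The shipped studies use: 2,000 phenotyped animals, 3 chromosomes × 50 Mb,
6,000 SNPs (600 windows of 250 kb), 20 QTL, 8 traits, BayesR at 1,500
iterations/1 chain for the window analyses and 6,000 iterations/2 chains
for the single-QTL detection study, and top-20 window selection.  These
sizes keep every stage proportionate to the reference analysis (same
windowing density, same selection fraction) while a full run completes in
minutes on one core.

## Known limitations

- pp_nonzero calibration under the null depends on the SNP count and the
  sigma2_g anchor (see above); multi-PP's absolute threshold is therefore
  scale-sensitive.
- The two-stage GWAS holds variance components fixed at their global REML
  estimates; per-SNP REML would differ slightly for SNPs of large effect.
- Pairwise-complete covariance estimation can be indefinite under extreme
  missingness; the PD projection is logged but changes entries.
- The pedigree A-matrix is dense (tabular method); pedigrees beyond ~2e4
  animals would need a sparse path.
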