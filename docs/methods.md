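# Methods

## The co-association model

`coassoc` tests whether the *joint* relationship of two genes with a binary
disease differs between cases and controls.  Each gene is treated as a latent
variable reflected by its SNPs (additive dosages 0/1/2), and the two latents
are linked by a single path.  With X (n x p) and Y (n x q) the standardized
dosage blocks of genes A and B in one stratum, the two-block PLS path model
(mode-A measurement, centroid inner scheme) estimates outer weights w_A, w_B,
latent scores xi = X w_A / sd(X w_A) and eta = Y w_B / sd(Y w_B), and the
path coefficient

    beta = cor(xi, eta).

The model is direction-free (beta is a correlation), and for two blocks the
alternating Lohmoller iteration has a closed-form fixed point: the unit-norm
weights are the first left/right singular vectors of the p x q
cross-correlation matrix X'Y/(n-1).  The test suite uses this as an
independent oracle for the iterative fit.

Fitting the model separately in cases and controls gives beta_case and
beta_control, and the co-association statistic is

    U = (beta_case - beta_control) / sqrt(Var(beta_case) + Var(beta_control)),

with each variance estimated by a stratified bootstrap (subjects resampled
with replacement within stratum, blocks re-standardized, model refit).  U has
no known asymptotic distribution, so its p-value comes from a random
case/control label-permutation test with the add-one estimator
p = (1 + #{|U*| >= |U|}) / (1 + n_perm).

This subsumes classical interaction testing: a product-term effect between
nearly independent genes and a case/control shift of between-gene LD both
move beta_case away from beta_control.

## Algorithmic choices

* **Moment-space fitting.**  After per-stratum standardization the entire
  iteration depends on the data only through the within- and cross-block
  correlation matrices; resampling loops therefore compute one cross-product
  per replicate and iterate on (p x q) matrices.  The numba kernels in
  `_kernels.py` implement this; `plspm.fit_two_block` is the same computation
  plus scores/loadings on the data scale.
* **Initialization** is w = 1/sqrt(p) per block; a dominant-eigenvector
  start is available for the measure-zero case where the equal-weight vector
  is orthogonal to the solution.  Convergence is max |weight change| < tol
  (default 1e-6, cap 300 iterations).  The stopping rule leaves the weight
  error at the same order as tol, so comparisons against the SVD fixed point
  at 1e-6 are made from fits run at tol = 1e-9.
* **Sign convention.**  Two-block PLS is sign-indeterminate; because U
  subtracts path coefficients across strata, each weight vector is oriented
  so its largest-magnitude component is positive, identically in both strata
  and in every bootstrap/permutation refit.  A zero score correlation (e
  undefined in the centroid rule) is resolved as +1 with a warning rather
  than aborting a resampling loop.
* **Permutation denominator.**  By default permutations recompute only the
  numerator (beta difference); the bootstrap denominator is held at its
  observed value.  The permuted statistic is then a fixed monotone transform
  of |beta_case* - beta_control*|, so the test is exact under exchangeability
  at a fraction of the cost.  `perm_mode="full_recompute"` re-bootstraps
  inside each permutation (inner n_boot capped at 100) for sensitivity
  analysis.
* **Seed streams.**  One master seed is split into named streams (case
  bootstrap, control bootstrap, permutations, per-dataset seeds in the
  harness).  Bootstrap streams are keyed to the stratum's row-index content
  rather than its label, which makes relabeling cases as controls negate U
  exactly (balanced designs) and makes harness results independent of worker
  count.
* **Bootstrap variance behavior.**  When the two blocks truly share a
  leading correlated direction, the bootstrap variance of beta tracks the
  sampling variance closely (re-simulation checks give ratios ~1.0).  When
  the blocks are independent the latent direction is unidentified and the
  bootstrap variance is inflated (up to ~2x) — conservative for reporting,
  and irrelevant to the permutation p-value, whose denominator is constant
  across permutations.

## Comparator implementations

* `snp_logistic`: per SNP pair, Wald z of the product term in
  logit(y) ~ g_j + g_k + g_j g_k (own Newton/IRLS, batched in numba);
  multiplicity handled by min-p/max-T label permutation of the best pair.
* `pca_logistic`: PC1 per gene from the pooled standardized block (sign
  fixed by the largest-|loading| convention), Wald p of the PC1_A x PC1_B
  product term.
* `ccu`: first canonical correlation per stratum (Cholesky-whitened SVD;
  ridge 1e-8 added when a within-block correlation matrix is numerically
  singular), standardized by stratified-bootstrap variances, permutation p.
  The exact standardization of the original publication is not reproduced
  here; the construction is recorded in the result metadata.
* `covariance`: d = vec of the case-minus-control cross-gene covariance
  block (`cross_block` default; `full_joint` optional), statistic
  d' W^- d with W^- the Moore-Penrose pseudo-inverse (singular values
  < 1e-10 sigma_max dropped) of an estimate W of the sampling covariance of
  d, so perfect collinearity between SNPs never makes the statistic
  undefined.  W is estimated by default from an independent batch of label
  permutations: that makes W a label-invariant function of the pooled data,
  and the permutation test (W held fixed across test permutations) exact
  under exchangeability.  A stratified-bootstrap W (the original
  construction) is available via `w_method="bootstrap"`; because it depends
  on the observed labels it is mildly anticonservative for
  high-dimensional d.  Permutation p is primary; the chi-square tail on the
  pseudo-rank is reported alongside.

## The synthetic-data generator

The generator emulates a HapMap-panel pipeline: a phased haplotype panel
fixes MAFs and LD; individuals are two panel haplotypes summed; disease is
Bernoulli with a logistic model on one causal SNP per gene; a large
case/control pool (default 20k + 20k, standing in for a very large
hypothetical population) is subsampled into balanced replicate datasets; the
causal SNPs are removed before testing so association is indirect, through
LD.

The panel is a latent-Gaussian threshold model: allele_j = 1 iff a correlated
standard normal falls below Phi^-1(MAF_j).  Thresholding attenuates
correlation, so latent rho is chosen by inverting the orthant-probability
mapping to hit *empirical* LD targets.  Preset defaults emulate
strong-LD candidate regions of common variants:

* within-gene latent AR(1) rho = 0.98 (adjacent empirical r^2 ~0.76,
  decaying but strong across a 7-10 SNP block);
* cross-gene latent rho = 0.9 between the causal pair for the linked-genes
  presets, with the cross-block structured as rho * a b' (a, b the AR(1)
  profiles around the causal positions, which keeps the joint latent matrix
  positive semi-definite and routes cross-gene LD through the causal pair),
  giving causal-pair empirical r^2 ~0.5;
* gene sizes 8+10 (independent-genes preset) and 7+7 (linked presets),
  causal MAFs 0.43/0.44 and 0.46/0.45, remaining MAFs spread over 0.22-0.48;
* disease prevalence 0.1, with the intercept root-found (Monte-Carlo Brent)
  so the population prevalence matches to well within 0.005;
* scenario type1: interaction OR only (main-effect ORs default 1.0);
  type2: marginal ORs only; type3: 1:1 individual-level mixture of the two
  mechanisms on the same linked panel.

What the generator does *not* emulate: recombination (haplotypes are
resampled whole), rare variants, genotyping error and missingness (simulated
data are complete; mean imputation exists for real inputs), population
structure, and the internal approximations of the legacy simulation tools
this pipeline replaces.

### A note on marginal-effects-only ("Type II") co-association

For common causal variants the case-stratum LD shift induced by a purely
additive logistic model is small: exponentially tilting the haplotype
distribution by the marginal effects changes the allelic correlation at
first order in proportion to (1 - 2 MAF), which is ~0.08 at MAF 0.46.  A
closed-form computation on the preset haplotype frequencies gives a
case-minus-control correlation difference of only about -0.007 (and nearly
constant across marginal-OR pairs with similar products).  Two consequences,
both visible in the power harness: (i) Type-II power of the correlation-based
tests at desk scale is modest and similar for the PLSPM and CCU statistics
(with rank-1 cross-gene LD the first canonical direction carries all the
signal); (ii) after causal-SNP removal the logistic comparators respond to
omitted-variable curvature that loads on the product term, i.e. they reject
the *model*, not an interaction.  Claims that marginal-only co-association
yields high power while product-term logistic tests stay at the nominal
level are not reproduced by this generator's faithful joint logistic
mechanism.

## Problem sizes used by the shipped checks

The test suite and `scripts/acceptance.py` run everything at desk scale,
chosen as the package's own reproducible defaults: null calibration cells
use 500 replicate datasets (500 permutations, 200 bootstraps) from a
20k + 20k pool on a 20k-haplotype panel; the five-method calibration runs
500 datasets at N = 600 with 200 permutations; power-ordering checks use
90-120 datasets per cell with binomial error bands computed at those sizes;
parameter-recovery refits use 100k + 100k samples.

## Known limitations

* Balanced N/2-cases design is the default sampling convention; an arbitrary
  case fraction is available but the exact label-swap antisymmetry of U holds
  only for balanced strata.
* The bootstrap variance of beta is inflated when the between-gene
  correlation is truly zero (unidentified direction); reported U values under
  the null are therefore conservative in magnitude.
* Rare variants: with low-MAF SNPs the latent threshold panel and the
  correlation-based statistics both degrade; the package targets common
  variants.
* No covariate adjustment, no >2-block path models, no formative (mode-B)
  measurement, no multiple-testing machinery across gene pairs beyond the
  per-pair report.
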