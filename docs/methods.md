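# Methods

## The statistical setting

A multi-environment trial (MET) evaluates genotypes j = 1..n in environments
i = 1..q.  Under a sparse-testing design only a subset of the n·q cells is
grown (the *calibration* cells); the rest (the *prediction* cells) are
predicted.  The package models the adjusted cell value y_ij with three nested
Gaussian random-effects models:

- **M1 (E+L):** y_ij = μ + E_i + L_j + e_ij, with E_i ~ iid N(0, σ²_E),
  L_j ~ iid N(0, σ²_L), e_ij ~ iid N(0, σ²_e).
- **M2 (E+L+G):** adds g_j, the genomic value implied by p markers with iid
  effects; marginally g ~ N(0, G σ²_g) with G the genomic relationship
  matrix.  L is retained alongside g so that an iid line effect can absorb
  whatever imperfect marker information leaves unexplained.
- **M3 (E+L+G+GE):** adds the interaction gE_ij with covariance
  (Z_g G Z_g') ∘ (Z_E Z_E') σ²_gE — the reaction-norm (Hadamard) kernel: two
  cells covary through σ²_gE only when they share an environment, and then
  proportionally to the genomic relationship of their genotypes.

Over a fixed ordering of cells the model terms become covariance kernels
K_E (same-environment indicator), K_L (same-genotype indicator),
K_g = Z_g G Z_g' and K_GE = K_g ∘ K_E.

## Two-stage analysis

Stage 1 adjusts plot-level records to per-environment genotype means (BLUEs)
under y_jkl = μ + L_j + r_k + d_l(r) + e_jkl, with genotype fixed and
replicate / incomplete-block-within-replicate random.  Each environment is
fitted strictly on its own.  The variance components are estimated by REML
with a derivative-free profile-likelihood search over the two variance
*ratios* (replicate/error, block/error) on a log10 scale, using the Woodbury
identity so each evaluation costs only the (small) number of replicate and
block levels plus one q×q factorization.  The implementation agrees with
statsmodels' MixedLM to four decimals on simulated layouts (see
`tests/test_blues.py`).  The genotype BLUEs are the generalized-least-squares
solutions of the cell-means parameterization at the estimated components;
these equal μ̂ + L̂_j of any identifiable genotype coding (sum-to-zero,
reference level, …), so no constraint convention needs to be exposed.
Degenerate layouts are handled explicitly: a single replicate (or a single
block per replicate) pins the corresponding component at 0 with a logged
note; constant data yields all-zero components.

## Genomic relationship matrix

VanRaden method 1: markers failing QC are dropped (missing fraction strictly
above 0.5 or MAF strictly below 0.03 — both inequalities strict, so a marker
at exactly 3 % MAF survives), missing dosages are replaced by the marker
mean, columns are centered and scaled by the **population (divisor-n)**
standard deviation, and G = XX'/p.  The divisor-n choice makes
mean(diag(G)) = 1 and trace(G) = n exactly, which in turn puts σ²_g on the
trait scale.  Imputation and the divisor are deliberate configuration-level
decisions; marker-mean imputation is the simplest scheme consistent with
conventional quality control.

## The Gibbs sampler

`GibbsKernelRegressor` fits y = μ1 + Σ_k u_k + e with u_k ~ N(0, K_k σ²_k),
e ~ N(0, I σ²_e) and scaled-inverse-χ² priors on all variances.  Each u_k is
represented in the eigenbasis of its kernel restricted to the calibration
cells (one eigendecomposition per kernel per design).  Because the
eigenvectors are orthonormal, a kernel's coefficients are conditionally
independent given μ and the other kernels' effects, so the sampler draws each
kernel's whole coefficient block jointly per sweep — same stationary
distribution as single-coordinate updating, but each sweep is two matrix-
vector products per kernel.  Prediction uses the joint-Gaussian conditional
mean K_k[test, train] W_k D_k⁻¹ ā_k averaged over retained draws.

Numerical choices:

- **Eigenvalue clipping.** Eigenvalues below 1e-10 of the largest (including
  any negative ones) are dropped; the largest clipped magnitude is recorded
  in `max_eig_clip_`.  Standardized-marker GRMs are routinely rank-deficient,
  so this is the expected path, not an error path.
- **Priors.** All variances get scaled-inv-χ²(df = 5, scale set so the prior
  *modes* split `prior_r2` = 0.5 of var(y) equally among the non-residual
  kernels, remainder to the residual).  These mirror the default behavior
  class of standard Bayesian whole-genome regression software.
- **Chain defaults** n_iter = 12 000, burn_in = 2 000, thin = 5.  The test
  and evaluation suites use shorter chains (400–8 000 iterations) scaled to
  each problem; the effective-sample-size diagnostics (`ess_`) warn when a
  variance chain's ESS drops below 10.
- **Fixed-variance mode.** `fixed_varcomps` freezes any subset of variances,
  which turns the sampler into a draw from the exact conditional posterior
  whose mean is the Henderson mixed-model (BLUP) solution — the basis of the
  oracle tests, where three pooled chains agree with the dense closed form
  within 3 Monte-Carlo standard errors per cell.
- **Intercept** has a flat prior; μ and all u_k are scale-equivariant, so
  multiplying y by c multiplies fitted variances by c² (verified as a
  property test).

A genotype never observed in any environment is predicted only through K_g
(and K_GE): the iid L term has zero covariance with unobserved lines and
contributes nothing — a direct consequence of modeling L as iid.

## Allocation designs and evaluation

`make_design` samples the O (overlapping) genotypes first, then q pairwise
disjoint NO sets from the remainder, all uniformly without replacement;
calibration cells are exactly q·(NO+O) and the cell masks always partition
the full factorial (asserted property).  Repetition r of the cross-validation
re-draws the design with seed base_seed + r; each fit receives an isolated
sampler seed derived through `numpy.random.SeedSequence` so a skipped fit
cannot shift later draws.  Accuracy is the within-environment Pearson
correlation on prediction cells; undefined correlations (constant vectors)
propagate as missing values, never as zeros.  Summaries average first across
environments within a repetition, then across repetitions; the reported
spread is the standard deviation over repetitions of the environment-averaged
value (repetitions only, not repetitions × environments).  The default
composition grid steps the overlap by 10 and ends at NO = 1 (matching the
convention of the reference scenario's printed grid); all-overlap designs
remain constructible directly.

## The synthetic-data generator

`simulate_dataset` draws, in order: independent biallelic dosages
Binomial(2, f_m) with f_m ~ U(maf_range) and optional completely-at-random
missingness; cell values y_ij = μ + E_i + L_j + g_j + gE_ij + e_ij with
g ~ MVN(0, G σ²_g) and gE drawn per environment as an independent
MVN(0, G σ²_gE) vector — exactly the Hadamard-kernel covariance for a
complete one-cell-per-(i,j) layout, at the cost of q small Cholesky
factorizations (G is jittered by +1e-8 on the diagonal first); and optionally
plot records y_jkl = cell + r_k + d_l(r) + noise with genotypes re-partitioned
at random into near-equal incomplete blocks per replicate.

Defaults (chosen once as a desk-scale mirror of a maize hybrid MET):
300 genotypes, 2 000 markers, 3 environments, MAF U(0.05, 0.5), μ = 6.0
(t/ha scale), σ²_E = 0.5, σ²_L = 0.1, σ²_g = 0.3, σ²_gE = 0.5, σ²_e = 0.4.
The implied between-environment phenotypic correlation,
(σ²_L + σ²_g) / (σ²_L + σ²_g + σ²_gE + σ²_e) ≈ 0.31, sits inside the
low-to-moderate range typical of stress-prone maize METs.  The plot stage
defaults to 2 replicates, 5 incomplete blocks, σ²_rep = 0.2,
σ²_block = 0.1, σ²_plot = 0.5 — magnitudes typical of yield trials; no
reference values exist for these, so they are package choices.

### What the generator does *not* emulate — and what that implies

The markers are independent within and **between** genotypes: no linkage
disequilibrium, families, testers or population structure.  Consequently the
realized G is close to the identity (off-diagonals O(1/√p) ≈ 0.02 at
p = 2 000).  Two consequences matter when interpreting test results:

1. **Variance-component splits are weakly identified.**  K_L ≈ K_g and (on
   all-non-overlapping designs, where each genotype is seen once) K_L equals
   the residual kernel exactly on the calibration cells.  The sums
   σ²_L + σ²_g and σ²_gE + σ²_e are recovered well; their splits are
   prior-dominated.  With only 3 environments, σ²_E estimates track the
   *realized* spread of the three drawn environment effects, which is itself
   highly dispersed around the nominal value.  The test suite therefore
   asserts recovery of the identified sums as a property, and records the
   per-component comparison separately.
2. **Accuracy falls, rather than rises, with growing overlap.**  Raising O
   replaces prediction cells whose genotype is observed in another
   environment (predicted through the line term) with never-observed
   genotypes predicted only through G; with essentially unrelated simulated
   genotypes that channel carries accuracy of roughly √(nh²/(nh²+p)) ≈ 0.2.
   In real breeding data, strong family/tester relatedness makes the genomic
   channel far more informative, which is what drives the opposite,
   increasing trend there.  Passing model-ordering tests on synthetic data
   (M3 ≥ M2 ≥ M1; M3 leaves the least variance unexplained) therefore says
   the machinery is correct, not that every field-data trend is reproduced
   by structureless genotypes.

## Problem sizes used by the automated suites

The test suite and `scripts/acceptance.py` run everything at desk scale,
chosen as the package's own trade-off between statistical resolution and
turnaround: design combinatorics at the full reference size (843 genotypes,
3 environments — exact and instant), the sampler-vs-BLUP oracle on a
20-genotype × 2-environment toy with three pooled 8 000-iteration chains,
variance recovery at 300 genotypes × 2 000 markers over five generator
seeds with 4 000-iteration chains, and the model-comparison grid at four
compositions × three models × three repetitions with 1 500-iteration chains.

## Known limitations

- Stage-1 adjustment offers no spatial (row-column/AR1) modeling.
- Only VanRaden method-1 G; no dominance/epistasis kernels, no pedigree
  matrix, no factor-analytic environment covariance, no environmental
  covariates.
- Per-environment sample sizes are equal across environments by construction;
  cost-weighted budgets are out of scope.
- The Gibbs sampler assumes a single trait and homoscedastic residuals across
  environments.
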