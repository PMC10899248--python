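# Methods

## Model

`gcovsem` dissects the covariance of k Z-standardized traits measured on
n unrelated, genotyped individuals into a genetic and a residual part.
Stacking the trait vectors, the model is

    vec(Y) ~ N(0, Σ_A ⊗ G + Σ_E ⊗ I),
    Σ_A = Λ_A Ψ_A Λ_Aᵀ,   Σ_E = Λ_E Ψ_E Λ_Eᵀ,   Ψ_A = Ψ_E = I,

where G is the n × n genetic relationship matrix (GRM) estimated from
standardized SNP dosages and I the identity.  Σ_A is the between-trait
genetic covariance tagged by genotyped variants; Σ_E collects everything
else (environment, error, non-additive and untagged genetic variance).
Because phenotypes enter as deviations from their means with unit
variance, no mean structure is estimated, and the unstandardised and
standardised loadings nearly coincide (they differ only through the
model-implied total variance, which is close to 1 by construction).

Model families differ only in the free-cell pattern of Λ_A and Λ_E:

| family | genetic part | residual part |
|---|---|---|
| Cholesky (saturated) | lower-triangular k × k | lower-triangular k × k |
| independent pathway | n_AC shared columns + diagonal specific block | n_EC shared + diagonal specific |
| IPC (hybrid) | independent-pathway | Cholesky |
| bi-factor | general column + grouping columns + specific block | Cholesky |

Factor variances are fixed to the identity, so factors are orthogonal by
construction and the free parameters are loadings only.  Identification
additionally requires the free-parameter count not to exceed the k(k+1)
identifiable second moments, checked at spec construction, and a sign
convention (the first free loading of every factor column is reported
positive; the likelihood cannot tell a factor from its negation).

Derived quantities, all with delta-method standard errors propagated
from the inverse observed information:

* h²_SNP per trait: Σ_A,tt / Σ_V,tt;
* genetic correlation r_g = σ_g12 / √(σ²_g1 σ²_g2);
* factorial co-heritability f²_g = σ²_g,jt / σ²_g,t — the share of trait
  t's genetic variance carried by genetic factor j; over genetic factors
  these sum to 1 for any trait with positive genetic variance.

## Likelihood evaluation and optimisation

With G = U diag(d) Uᵀ and Ỹ = Uᵀ Y, the rows of Ỹ are independent with
covariance V_i = d_i Σ_A + Σ_E, so one likelihood evaluation costs n
batched k × k Cholesky factorizations instead of one nk × nk solve.
The gradient is analytic: with P_i = V_i⁻¹ and q_i = P_i ỹ_i,
∂ℓ/∂Σ_A = ½ Σ_i d_i (q_i q_iᵀ − P_i) and ∂ℓ/∂Λ_A = 2 (∂ℓ/∂Σ_A) Λ_A
(similarly for the residual part with d_i ≡ 1).  The dense Kronecker
density is retained in the test suite as the correctness oracle; the two
agree to 1e−8 on random instances.

Optimisation is L-BFGS-B on the free loadings with the analytic
gradient, ftol 1e−12 and gradient tolerance 1e−6, starting from Cholesky
factors of half the sample phenotypic covariance per part (EFA loadings
take precedence as starting values when the spec carries them), with
seeded jittered restarts if the first run stalls.  A non-positive-
definite block makes the likelihood return −inf (mapped to a large
finite penalty) so the line search retreats rather than crashing.
Standard errors come from a central-difference Hessian of the analytic
gradient; near-singular information matrices fall back to a
pseudo-inverse with a warning, and solutions with a standardized
communality above 1 are flagged Heywood rather than truncated.

Missing phenotypes are handled complete-case across the modelled traits
(one N per model, as a fit-comparison table requires).  The bivariate
GREML path additionally offers a dense full-information likelihood over
observed entries so individuals phenotyped for a single trait are kept;
this costs O((n₁+n₂)³) per evaluation and is intended for moderate n.

## GREML

Univariate variance components (y ~ N(0, σ²_g G + σ²_e I)) are estimated
on the same rotated likelihood (a 1-trait model with variance rather
than loading parametrisation), components bounded at zero.  The test of
σ²_g = 0 sits on the boundary of the parameter space, so the LRT uses
the ½χ²₀ + ½χ²₁ mixture.  A one-trait saturated SEM fit and univariate
GREML agree on h²_SNP to 1e−4 (tested).  Since phenotypes are
mean-centred with no fixed effects, ML and REML coincide here.

Power for detecting h²_SNP uses SE(ĥ²) = √(2/(n² · Var(G_offdiag))), a
non-centrality (h²/SE)² and a 1-df χ² test; the default off-diagonal GRM
variance 2×10⁻⁵ is typical of genotyping-chip GRMs in ancestry-
homogeneous samples.  At n = 1200, h² = 0.2, α = 0.05 this gives 0.118.

## GRM construction and formats

A_jk = (1/M_jk) Σ_i (x_ij − 2p_i)(x_ik − 2p_i)/(2p_i(1−p_i)) with
in-sample allele frequencies, pairwise-complete missingness (per-pair
SNP counts), monomorphic SNPs dropped with a count.  I/O follows the
GCTA binary dialect (float32 lower triangle in `.grm.bin`, counts in
`.grm.N.bin`, FID/IID text in `.grm.id`), round-tripping losslessly at
float32.  Relatedness pruning is greedy by descending count of
above-cutoff partners (ties by input order; default cutoff 0.05) — not
an exact maximum retained set, but it matches exhaustive search on the
small sparse instances in the test suite and scales linearly in
practice.  Eigenvalues below 1e−10 are clamped to zero with a warning.

## Phenotype preparation

Binary traits: logistic regression on covariates, then deviance
residuals d_i = sign(y−p̂)√(−2[y ln p̂ + (1−y) ln(1−p̂)]); traits are
expected binary with both classes and a warning below 5% prevalence.
Continuous traits: fully-adjusted two-stage rank normalisation —
covariate residuals → rank-based inverse-normal transform → residuals on
the same covariates again — then Z-standardization.  The rank-to-normal
offset is Blom's 3/8 with average ranks for ties; standardization uses
the population (1/n) SD.  Without covariates the continuous pipeline is
exactly idempotent; with covariates re-application can swap adjacent
ranks (the inverse-normal map is nonlinear, so its output regains small
chance correlations with the covariates), which is why the test suite
asserts exact idempotence only in the null-covariate case and high
stability (r > 0.98) otherwise.

## Data-driven model search

1. Fit the saturated Cholesky model; take its implied genetic covariance
   V_A and, by the delta method, the element-wise sampling variances
   Ṽ(V_A).
2. Eigendecompose the genetic correlation matrix.  The number of shared
   factors is the count of eigenvalues that exceed both 1 (Kaiser) and
   the optimal-coordinate prediction — the value extrapolated at
   position i by the straight line through eigenvalues i+1 and k.  The
   conjunction is the automatic surrogate for reading the scree plot.
3. Genetic EFA: least squares on the unique elements of V_A, inverse-
   weighted by Ṽ(V_A) (identity weights give the unweighted variant).
   The printed form of the weighted-least-squares objective in the
   methods literature is linear in S − Σ(θ) and cannot be minimised as
   written; the standard quadratic ½Σ w⁻¹(s−σ)² is used.  Uniquenesses
   are bounded below at −0.25·s_jj: mildly negative values (Heywood
   cases, expected when the analysed matrix is itself an estimate) stay
   representable and flagged, while under-identified doublet factors
   cannot collapse to ψ → −∞.
4. Rotation: varimax, unless the oblimin interfactor correlation exceeds
   0.32 *and* the oblimin zero/nonzero pattern at the 0.10 threshold
   differs from varimax ("similar pattern" is operationalised as
   thresholded-pattern equality up to column permutation).
5. IPC construction: shared cells with EFA |λ| < 0.10 fixed to zero,
   others free with EFA starting values; free specific genetic loadings;
   free residual Cholesky.  After fitting, specific loadings with
   |λ| < 0.01 are fixed to zero and the model refitted once.
6. Comparison: AIC = −2ℓ + 2p, BIC = −2ℓ + p ln(n_individuals), LRTs
   for declared nested pairs; best model is lowest AIC with BIC
   tie-break.  SRMR is the root mean square difference between the
   observed and implied matrices after scaling each to correlation form
   by its own diagonal, over the k(k+1)/2 unique elements, with no
   degrees-of-freedom adjustment; it is isolated in one function so an
   adjusted variant can be swapped in.
7. A mapping variable (e.g. a polygenic score) can be appended as trait
   k+1: free loadings on every shared genetic factor, its own specific
   factor, one new residual Cholesky row; the base structure is frozen.

The multiple-testing utility implements the spectral-decomposition
effective number of tests, M_eff = 1 + (M−1)(1 − Var(λ)/M) on the
eigenvalues of the phenotypic correlation matrix (sample variance), with
threshold α/M_eff.

The phenotypic counterpart pipeline uses a seeded stratified split-half
design: factor count from the full-sample correlation matrix (same rule
as step 2), varimax EFA on half 1, retention of |λ| > 0.10, ML CFA of
the retained orthogonal pattern on half 2 with CFI/TLI/RMSEA
(thresholds 0.95/0.95/0.06), and a full-sample CFA refit on success;
failure is reported as a status ("empirically unidentified"), not an
exception.

## Synthetic data generator

The generator emulates case-only cohort data at the level the models
consume: n unrelated individuals (default 2000), m independent
Hardy–Weinberg causal loci (default 5000; MAF uniform in [0.05, 0.5]),
k traits (default 6) built from shared + specific genetic factors and
independent normal residual factors, 20 replicates per scenario.  Loci
are partitioned equally among the genetic factors; each factor score is
the standardized-dosage sum scaled to unit variance, so a trait's true
h²_SNP is exactly its summed squared genetic loadings and two traits
loading only on one shared factor have r_g = 1 by construction.  Traits
are Z-standardized.  Each replicate redraws genotypes and phenotypes
from a deterministic child seed of the scenario seed.

Shipped scenarios (loadings chosen once, in [0.3, 0.7], with the
documented topology):

* **two_factor_scenario** — six traits; factor 1 loads (0.6, 0.5, 0.4)
  on traits 1–3, factor 2 (0.4, 0.5, 0.6) on traits 4–6, specific
  loadings 0.3, independent residuals; the cross-loading variant adds a
  0.3 loading of trait 3 on factor 2.
* **three_factor_scenario** — eight traits, three orthogonal factors
  with descending strengths (0.7/0.65/0.6, 0.45/0.4/0.4, 0.3/0.5/0.45
  with trait 6 cross-loading).  Strengths descend so the population
  scree separates under the optimal-coordinate rule, and every factor
  keeps three indicators so the genetic EFA is locally identified; a
  two-indicator factor's loading split is undetermined by the covariance
  it generates.

What the generator does **not** emulate: linkage disequilibrium, cryptic
relatedness, ascertainment/collider effects, rare and de-novo variant
classes, covariate structure and missingness patterns of real cohorts.
Passing recovery tests therefore demonstrates correctness of estimation
and of the search pipeline under the model's own assumptions — not
robustness to the violations real cohort data exhibit.

Performance scoring over replicates reports, per free parameter, the
median estimate, median bias, empirical SE (sample SD over replicates)
and 95%-CI coverage (estimate ± 1.96·SE containing the truth), with
Monte-Carlo SEs: 1.2533·SD/√R for the median bias (the asymptotic
normal-theory SE of a median), empSE/√(2(R−1)) for empSE, and
√(c(1−c)/R) for coverage.  Non-convergent replicates are excluded and
counted.  Before scoring, fitted factor columns are sign-aligned to the
truth (and in EFA-to-fit comparisons, to the EFA solution), since the
likelihood is invariant to column sign flips.

## Problem sizes used in the shipped checks

Parameter-recovery runs use n = 2000 individuals and m = 1000 causal
loci over 20 replicates per scenario — m is reduced from the default
5000 since the recovery properties under study are unchanged while the
GRM construction cost drops substantially; the likelihood-oracle suite
uses 50 random instances with n·k ≤ 60; the GREML-equivalence check uses
n = 1000, m = 2000.

## Known limitations

* Complete-case fitting only for the multivariate models; the dense
  full-information path exists only for the bivariate GREML route.
* The SRMR variant is unadjusted for model degrees of freedom.
* Greedy relatedness pruning is not guaranteed maximal.
* The bi-factor grouping pattern must be supplied by the caller; the
  search pipeline constructs IPC models only.
* Delta-method SEs assume an interior optimum; estimates at the zero
  boundary (common for small specific loadings) make the associated
  Wald tests conservative, which is one motivation for the |λ| < 0.01
  trimming pass.
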