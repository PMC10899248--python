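# gcovsem

Structural equation modelling of genome-wide covariance: dissect the SNP
heritability of multiple phenotypes measured on unrelated, genotyped
individuals into **shared** and **trait-specific** genetic factors, and
discover that factor structure from the data itself.

The package is aimed at statistical geneticists working with individual-
level genotype data in cohorts of a few thousand individuals — the
regime where summary-statistic methods (LD-score-based genomic SEM) lack
power but a genetic relationship matrix (GRM) carries enough signal to
model the full genetic covariance directly.

## The model

For k Z-standardized traits on n unrelated individuals,

```
vec(Y) ~ N(0,  Σ_A ⊗ G  +  Σ_E ⊗ I),      Σ_A = Λ_A Λ_Aᵀ,   Σ_E = Λ_E Λ_Eᵀ
```

where G is the GRM estimated from standardized SNP dosages.  Σ_A is the
genetic covariance tagged by genotyped variants, Σ_E the residual
covariance; factor variances are fixed to the identity so all structure
lives in the loading matrices.  Supported families: saturated
**Cholesky**, **independent pathway**, the hybrid **IPC**
(independent-pathway genetic part, Cholesky residual part) and
**bi-factor** models.  Maximum likelihood is evaluated in the GRM
eigenbasis (n independent k × k blocks d_i Σ_A + Σ_E), with analytic
gradients and delta-method standard errors for the standardized
solution: per-trait h²_SNP, genetic correlations
r_g = σ_g12/√(σ²_g1 σ²_g2), and factorial co-heritabilities f²_g (the
share of a trait's genetic variance carried by one factor).

The data-driven search pipeline goes from a saturated fit to a
parsimonious factor model automatically: genetic PCA (optimal-coordinate
∧ Kaiser rule) picks the number of shared factors, a weighted
least-squares genetic EFA of the implied genetic covariance proposes the
structure, |λ| < 0.10 loadings become zero constraints of an IPC model,
near-zero fitted specific loadings (|λ| < 0.01) are trimmed, and
candidates are compared by LRT/AIC/BIC and SRMR.

Supporting modules cover univariate/bivariate GREML (with the boundary
½χ²₀+½χ²₁ heritability test and a power calculator), GCTA-dialect GRM
I/O and relatedness pruning, phenotype preparation (deviance residuals
for binary traits, fully-adjusted two-stage rank normalisation for
continuous ones) and a simulation harness that scores parameter recovery
with median bias, empirical SE, CI coverage and Monte-Carlo SEs.
See `docs/methods.md` for the full methodological account.

## Worked example

Simulate an eight-trait cohort with three orthogonal shared genetic
factors (2000 individuals, 1000 causal loci), then let the pipeline
rediscover the structure:

```python
import numpy as np
from gcovsem import simulate, sem, search
from gcovsem.grm import compute_grm
from gcovsem.greml import fit_univariate

scenario = simulate.three_factor_scenario(n_causal_loci=1000)
geno = simulate.simulate_genotypes(scenario.n_individuals, 1000, seed=7)
phenos = simulate.simulate_phenotypes(scenario, geno, seed=8)
grm = compute_grm(geno)

print(fit_univariate(grm, phenos.values[:, 0]).h2)   # single-trait GREML
run = search.genomic_pipeline(grm, phenos, seed=0)
for line in run["log"]:
    print(line)
std = sem.standardize_solution(run["ipc_fit"])
print(np.round(std.h2, 2), np.round(scenario.true_h2, 2))
```

prints

```
genetic PCA retained 3 factor(s)
rotation choice: varimax: max interfactor |r| = 0.241 <= 0.32
IPC constraints: 15 shared cells fixed to zero by the |λ| < 0.1 rule
best model by AIC: ipc
EFA-predicted vs fitted free shared loadings: r = 0.9997
[0.5  0.46 0.38 0.39 0.32 0.37 0.41 0.3 ]
[0.51 0.45 0.38 0.36 0.32 0.37 0.37 0.32]
```

The pipeline recovers the generative three-factor topology, prefers the
constrained IPC model over the saturated Cholesky by AIC (42319.4 vs
42344.8), and the per-trait h²_SNP estimates track their true values;
constructed trait pairs sharing a factor show the implied genetic
correlations (here r_g(y1, y2) = 0.93, SE 0.03, true value
0.7·0.65/√(0.51·0.45) ≈ 0.95).

A command-line interface mirrors the library:

```bash
gcovsem grm    --geno geno.csv --make-grm --grm-cutoff 0.05 --out mygrm
gcovsem prep   --pheno pheno.csv --covar covar.csv --out prepped.tsv
gcovsem greml  --grm-prefix mygrm --pheno prepped.tsv --trait y1 --out h2.tsv
gcovsem search --grm-prefix mygrm --pheno prepped.tsv --out-dir results/
gcovsem simulate --scenario scenario.yaml --out performance.tsv
```

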