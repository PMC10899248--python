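"""Synthetic genotypes, GRMs and multi-trait phenotypes from factor models.

The generator emulates the proof-of-principle design used to validate the
modelling pipeline: k Z-standardized traits built from shared and
trait-specific genetic factors acting through simulated causal loci
(Hardy–Weinberg binomial dosages, no linkage disequilibrium) plus
independent standard-normal residual factors.  Defaults follow the study
conditions: six traits, two shared genetic factors (with or without one
cross-loading), 2000 individuals, 5000 causal loci, 20 replicates.

Genetic factor scores are sums of standardized causal dosages scaled to
unit variance, with loci partitioned equally among the genetic factors;
because every trait's genetic + residual squared loadings sum to 1, the
true h²_SNP of a trait is exactly its summed squared genetic loadings.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import sem
from .grm import GenotypeMatrix, compute_grm
from .phenoprep import PhenotypeTable

__all__ = [
    "SimulationScenario",
    "PerformanceTable",
    "simulate_genotypes",
    "simulate_phenotypes",
    "run_replicates",
    "summarize_performance",
    "two_factor_scenario",
    "three_factor_scenario",
]

_MEDIAN_SE_FACTOR = np.sqrt(np.pi / 2.0)  # ≈1.2533: SE of a median vs a mean


@dataclass
class SimulationScenario:
    """One generative condition: sizes, allele frequencies and loadings.

    ``genetic_loadings`` is k × (n_shared + k): shared-factor columns
    first, then one specific column per trait (diagonal).  Every trait's
    squared genetic + residual loadings must sum to 1 so phenotypes are
    Z-standardized in expectation.
    """

    genetic_loadings: np.ndarray
    residual_loadings: np.ndarray
    n_individuals: int = 2000
    n_causal_loci: int = 5000
    maf_range: tuple = (0.05, 0.5)
    n_replicates: int = 20
    seed: int = 2024

    def __post_init__(self):
        self.genetic_loadings = np.atleast_2d(np.asarray(self.genetic_loadings, float))
        self.residual_loadings = np.atleast_2d(np.asarray(self.residual_loadings, float))
        if self.n_causal_loci < 1:
            raise ValueError("n_causal_loci must be at least 1")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        total = (self.genetic_loadings**2).sum(axis=1) + (
            self.residual_loadings**2
        ).sum(axis=1)
        if not np.allclose(total, 1.0, atol=1e-8):
            raise ValueError(
                "squared genetic + residual loadings must sum to 1 per trait; "
                f"got {total}"
            )

    @property
    def k(self) -> int:
        return self.genetic_loadings.shape[0]

    @property
    def n_genetic_factors(self) -> int:
        return self.genetic_loadings.shape[1]

    @property
    def n_shared(self) -> int:
        return self.n_genetic_factors - self.k

    @property
    def true_h2(self) -> np.ndarray:
        return (self.genetic_loadings**2).sum(axis=1)

    def to_yaml(self, path) -> None:
        doc = {
            "n_individuals": int(self.n_individuals),
            "n_causal_loci": int(self.n_causal_loci),
            "maf_range": [float(x) for x in self.maf_range],
            "n_replicates": int(self.n_replicates),
            "seed": int(self.seed),
            "genetic_loadings": self.genetic_loadings.tolist(),
            "residual_loadings": self.residual_loadings.tolist(),
        }
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh)

    @classmethod
    def from_yaml(cls, path) -> "SimulationScenario":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        doc["maf_range"] = tuple(doc.get("maf_range", (0.05, 0.5)))
        return cls(**doc)


def _loadings_with_specific(shared: np.ndarray, specific: np.ndarray) -> np.ndarray:
    return np.column_stack([shared, np.diag(specific)])


def two_factor_scenario(cross_loading: bool = False, **overrides) -> SimulationScenario:
    """The shipped six-trait, two-shared-factor condition.

    Factor 1 loads on traits 1–3 (0.6, 0.5, 0.4) and factor 2 on traits
    4–6 (0.4, 0.5, 0.6); each trait adds a specific genetic loading of
    0.3.  With ``cross_loading=True`` trait 3 also loads 0.3 on factor 2.
    Residuals are independent, scaled so each trait has unit variance.
    """
    shared = np.zeros((6, 2))
    shared[:3, 0] = [0.6, 0.5, 0.4]
    shared[3:, 1] = [0.4, 0.5, 0.6]
    if cross_loading:
        shared[2, 1] = 0.3
    specific = np.full(6, 0.3)
    genetic = _loadings_with_specific(shared, specific)
    resid = np.diag(np.sqrt(1.0 - (genetic**2).sum(axis=1)))
    return SimulationScenario(
        genetic_loadings=genetic, residual_loadings=resid, **overrides
    )


def three_factor_scenario(**overrides) -> SimulationScenario:
    """Eight traits, three orthogonal shared genetic factors (for pipeline
    recovery runs); traits 1–3 load on factor 1, traits 4–6 on factor 2
    and traits 6–8 on factor 3 (trait 6 cross-loads).

    Factor strengths descend so the population scree of the genetic
    correlation matrix separates cleanly under the optimal-coordinate ∧
    Kaiser rule (population eigenvalues ≈ 2.9, 2.2, 1.6, then < 0.5),
    and every factor keeps three indicators so the genetic EFA stays
    locally identified (no doublet-factor indeterminacy)."""
    shared = np.zeros((8, 3))
    shared[:3, 0] = [0.7, 0.65, 0.6]
    shared[3:6, 1] = [0.45, 0.4, 0.4]
    shared[5:, 2] = [0.3, 0.5, 0.45]
    specific = np.array([0.15, 0.15, 0.15, 0.4, 0.4, 0.35, 0.35, 0.35])
    genetic = _loadings_with_specific(shared, specific)
    resid = np.diag(np.sqrt(1.0 - (genetic**2).sum(axis=1)))
    return SimulationScenario(
        genetic_loadings=genetic, residual_loadings=resid, **overrides
    )


def simulate_genotypes(n: int, m: int, maf_range=(0.05, 0.5), seed: int = 0) -> GenotypeMatrix:
    """Hardy–Weinberg dosages: per-SNP allele frequency uniform in
    ``maf_range``, genotypes Binomial(2, p), independent across loci."""
    if n < 2 or m < 1:
        raise ValueError("need n ≥ 2 individuals and m ≥ 1 SNPs")
    lo, hi = maf_range
    if not (0.0 < lo <= hi <= 0.5):
        raise ValueError("maf_range must lie within (0, 0.5]")
    rng = np.random.default_rng(seed)
    p = rng.uniform(lo, hi, size=m)
    X = rng.binomial(2, p, size=(n, m)).astype(float)
    ids = np.array([f"ind{i + 1}" for i in range(n)])
    return GenotypeMatrix(dosages=X, sample_ids=ids, allele_freqs=p)


def simulate_phenotypes(
    scenario: SimulationScenario, genotypes: GenotypeMatrix, seed: int = 0
) -> PhenotypeTable:
    """Build traits from genetic factor scores and normal residual factors.

    Causal loci are split evenly across all genetic factors (shared and
    specific); each factor score is the mean-standardized dosage sum of
    its loci divided by √(loci per factor), giving unit variance in
    expectation.  Traits are loadings · factors, then Z-standardized.
    """
    if genotypes.n_snps != scenario.n_causal_loci:
        raise ValueError(
            f"genotypes carry {genotypes.n_snps} loci, scenario expects "
            f"{scenario.n_causal_loci}"
        )
    rng = np.random.default_rng(seed)
    X = genotypes.dosages
    n, m = X.shape
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    Z = (X - X.mean(axis=0)) / sd

    q = scenario.n_genetic_factors
    groups = np.array_split(np.arange(m), q)
    A = np.column_stack(
        [Z[:, g].sum(axis=1) / np.sqrt(len(g)) for g in groups]
    )
    E = rng.standard_normal((n, scenario.residual_loadings.shape[1]))
    Y = A @ scenario.genetic_loadings.T + E @ scenario.residual_loadings.T
    Y = (Y - Y.mean(axis=0)) / Y.std(axis=0)
    return PhenotypeTable(
        values=Y,
        sample_ids=genotypes.sample_ids,
        trait_names=[f"y{t + 1}" for t in range(scenario.k)],
    )


def ipc_spec_for_scenario(scenario: SimulationScenario) -> sem.ModelSpec:
    """IPC model with the scenario's true zero pattern constrained, which
    pins factor labels so fitted and true loadings are comparable."""
    shared_true = scenario.genetic_loadings[:, : scenario.n_shared]
    constraints = [
        ("A", t, j)
        for t in range(scenario.k)
        for j in range(scenario.n_shared)
        if shared_true[t, j] == 0.0
    ]
    return sem.build_model(
        "ipc",
        k=scenario.k,
        n_shared_genetic=scenario.n_shared,
        constraints=constraints,
    )


@dataclass
class PerformanceTable:
    """Per-parameter Monte-Carlo performance over simulation replicates."""

    table: pd.DataFrame
    n_replicates: int
    n_converged: int

    def to_csv(self, path, sep="\t") -> None:
        self.table.to_csv(path, sep=sep, index=False)


def summarize_performance(
    estimates: pd.DataFrame,
    ses: pd.DataFrame,
    truths: dict,
) -> PerformanceTable:
    """Median estimate / median bias / empSE / 95%-CI coverage with MCSEs.

    ``estimates`` and ``ses`` are replicate × parameter frames sharing
    columns; ``truths`` maps parameter label → true value.  Coverage
    counts replicates whose estimate ± 1.96·SE contains the truth; its
    MCSE is the binomial √(c(1−c)/R).  The MCSE of the median bias uses
    1.2533·SD/√R; empSE's MCSE is empSE/√(2(R−1)).
    """
    if list(estimates.columns) != list(ses.columns):
        raise ValueError("estimate and SE frames must share parameter labels")
    missing = [c for c in estimates.columns if c not in truths]
    if missing:
        raise ValueError(f"no true value for parameter(s) {missing}")
    R = len(estimates)
    if R < 2:
        raise ValueError("need at least 2 replicates")
    rows = []
    for name in estimates.columns:
        est = estimates[name].to_numpy()
        se = ses[name].to_numpy()
        truth = truths[name]
        bias = est - truth
        emp_se = est.std(ddof=1)
        covered = (est - 1.96 * se <= truth) & (truth <= est + 1.96 * se)
        cov = covered.mean()
        rows.append(
            {
                "parameter": name,
                "truth": truth,
                "median_estimate": np.median(est),
                "median_bias": np.median(bias),
                "bias_mcse": _MEDIAN_SE_FACTOR * est.std(ddof=1) / np.sqrt(R),
                "emp_se": emp_se,
                "emp_se_mcse": emp_se / np.sqrt(2.0 * (R - 1)),
                "coverage": cov,
                "coverage_mcse": np.sqrt(cov * (1.0 - cov) / R),
                "n_replicates": R,
            }
        )
    return PerformanceTable(table=pd.DataFrame(rows), n_replicates=R, n_converged=R)


def run_replicates(
    scenario: SimulationScenario,
    model: sem.ModelSpec = None,
    shared_only: bool = True,
    compute_vcov: bool = True,
) -> PerformanceTable:
    """Generate → fit → score the scenario over its replicates.

    Each replicate draws fresh genotypes and phenotypes from a child seed
    of the scenario seed, computes the causal-locus GRM, fits ``model``
    (default: the IPC spec matching the scenario topology) and collects
    estimates and Wald SEs.  Fitted shared-factor columns are sign-aligned
    to the truth before scoring (the likelihood cannot tell a factor from
    its negation).  Non-convergent replicates are recorded and excluded
    from the summary, with the convergence count disclosed.
    """
    if model is None:
        model = ipc_spec_for_scenario(scenario)
    truth_LA = np.zeros(model.genetic_free.shape)
    shared_cols = min(scenario.n_shared, model.genetic_free.shape[1])
    truth_LA[:, :shared_cols] = scenario.genetic_loadings[:, :shared_cols]
    spec_cols = model.genetic_free.shape[1] - shared_cols
    if spec_cols == scenario.k:
        truth_LA[:, shared_cols:] = scenario.genetic_loadings[:, scenario.n_shared :]
    labels = model.param_labels
    na = int(model.genetic_free.sum())
    truth_theta = np.concatenate(
        [truth_LA[model.genetic_free], np.full(model.n_par - na, np.nan)]
    )
    truths = dict(zip(labels, truth_theta))

    ss = np.random.SeedSequence(scenario.seed)
    child_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(scenario.n_replicates)]
    est_rows, se_rows, failures = [], [], 0
    for rep_seed in child_seeds:
        geno = simulate_genotypes(
            scenario.n_individuals,
            scenario.n_causal_loci,
            scenario.maf_range,
            seed=rep_seed,
        )
        phenos = simulate_phenotypes(scenario, geno, seed=rep_seed + 1)
        grm = compute_grm(geno)
        try:
            fit = sem.fit(model, grm, phenos, seed=rep_seed, compute_vcov=compute_vcov)
        except RuntimeError:
            failures += 1
            continue
        theta, vcov = _align_signs_to_truth(model, fit.theta, fit.vcov, truth_LA)
        est_rows.append(theta)
        se_rows.append(np.sqrt(np.maximum(np.diag(vcov), 0.0)))
    if len(est_rows) < 2:
        raise RuntimeError(
            f"only {len(est_rows)} of {scenario.n_replicates} replicates converged"
        )
    est = pd.DataFrame(est_rows, columns=labels)
    se = pd.DataFrame(se_rows, columns=labels)
    if shared_only:
        keep = [
            lab
            for lab, tv in truths.items()
            if lab.startswith("A[") and "AC" in lab and np.isfinite(tv)
        ]
        est, se = est[keep], se[keep]
        truths = {lab: truths[lab] for lab in keep}
    else:
        keep = [lab for lab, tv in truths.items() if np.isfinite(tv)]
        est, se = est[keep], se[keep]
        truths = {lab: truths[lab] for lab in keep}
    perf = summarize_performance(est, se, truths)
    perf.n_replicates = scenario.n_replicates
    perf.n_converged = len(est_rows)
    return perf


def _align_signs_to_truth(model, theta, vcov, truth_LA):
    """Flip fitted factor columns whose dot product with truth is negative."""
    LA, LE = model.lambdas(theta)
    for j in range(LA.shape[1]):
        t_col = truth_LA[:, j]
        if np.any(t_col) and LA[:, j] @ t_col < 0:
            LA[:, j] *= -1
    theta_new = model.pack(
        np.where(model.genetic_free, LA, 0), np.where(model.residual_free, LE, 0)
    )
    flips = np.sign(np.where(theta != 0, theta_new / np.where(theta == 0, 1, theta), 1.0))
    return theta_new, vcov * np.outer(flips, flips)
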