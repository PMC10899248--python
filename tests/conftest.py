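import numpy as np
import pytest

from gcovsem import grm as grm_mod
from gcovsem import sem, simulate


@pytest.fixture(scope="session")
def small_dataset():
    """Six-trait two-factor dataset at reduced scale for fast model tests."""
    scenario = simulate.two_factor_scenario(
        n_individuals=800, n_causal_loci=400, seed=11
    )
    geno = simulate.simulate_genotypes(
        scenario.n_individuals, scenario.n_causal_loci, scenario.maf_range, seed=11
    )
    phenos = simulate.simulate_phenotypes(scenario, geno, seed=12)
    grm = grm_mod.compute_grm(geno)
    return scenario, geno, phenos, grm


@pytest.fixture(scope="session")
def small_cholesky_fit(small_dataset):
    scenario, _, phenos, grm = small_dataset
    spec = sem.build_model("cholesky", k=scenario.k)
    return sem.fit(spec, grm, phenos, seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240301)


def random_grm(rng, n, m=60):
    X = rng.binomial(2, rng.uniform(0.1, 0.5, m), size=(n, m)).astype(float)
    geno = grm_mod.GenotypeMatrix(X, [f"i{j}" for j in range(n)])
    return grm_mod.compute_grm(geno)
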