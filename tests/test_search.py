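"""Factor-number selection, genetic EFA, model building and fit indices."""

import numpy as np
import pytest

from gcovsem import search, sem
from gcovsem._factor import congruence, oblimin, varimax, wls_efa
from gcovsem.phenoprep import PhenotypeTable


def _matrix_with_eigenvalues(ev, seed=0):
    rng = np.random.default_rng(seed)
    Q, _ = np.linalg.qr(rng.standard_normal((len(ev), len(ev))))
    return Q @ np.diag(ev) @ Q.T


class TestGeneticPca:
    def test_identity_matrix_no_shared_structure(self):
        res = search.genetic_pca(np.eye(6))
        assert np.allclose(res.eigenvalues, 1.0)
        assert res.n_factors == 0

    def test_hand_computed_optimal_coordinate(self):
        """Eigenvalues {3.2, 1.8, 1.1, 0.45, 0.25, 0.2}: the first three
        exceed both Kaiser and the linear extrapolation through the next
        and last eigenvalues."""
        M = _matrix_with_eigenvalues([3.2, 1.8, 1.1, 0.45, 0.25, 0.2])
        res = search.genetic_pca(M)
        assert res.n_factors == 3
        assert np.allclose(sorted(res.eigenvalues)[::-1], res.eigenvalues)

    def test_non_symmetric_rejected(self):
        M = np.eye(4)
        M[0, 1] = 0.5
        with pytest.raises(ValueError, match="symmetric"):
            search.genetic_pca(M)

    def test_recovers_factor_count_across_replicates(self):
        """Genetic correlations from saturated fits of three-orthogonal-
        factor simulated data yield 3 factors in at least 80% of 20
        replicates."""
        from gcovsem.grm import compute_grm
        from gcovsem.simulate import (
            simulate_genotypes,
            simulate_phenotypes,
            three_factor_scenario,
        )

        sc = three_factor_scenario(n_causal_loci=1000)
        hits = 0
        for seed in range(1000, 1020):
            geno = simulate_genotypes(
                sc.n_individuals, sc.n_causal_loci, sc.maf_range, seed=seed
            )
            phenos = simulate_phenotypes(sc, geno, seed=seed + 5000)
            grm = compute_grm(geno)
            fit = sem.fit(
                sem.build_model("cholesky", sc.k), grm, phenos,
                seed=0, compute_vcov=False,
            )
            SA = fit.sigma_A
            d = np.sqrt(np.diag(SA))
            hits += search.genetic_pca(SA / np.outer(d, d)).n_factors == 3
        assert hits >= 16


class TestGeneticEfa:
    def _construct(self, seed=0):
        L = np.zeros((6, 2))
        L[:3, 0] = [0.7, 0.6, 0.5]
        L[3:, 1] = [0.6, 0.55, 0.5]
        psi = 1 - (L**2).sum(axis=1)
        return L, L @ L.T + np.diag(psi)

    def test_exact_structure_recovered(self):
        L_true, S = self._construct()
        sol = search.efa_genetic(S, None, n_factors=2, rotation="varimax")
        assert sol.discrepancy < 1e-10
        assert congruence(sol.loadings, L_true).min() > 0.999

    def test_weight_scale_invariance(self):
        _, S = self._construct()
        W = np.full_like(S, 0.37)
        a = search.efa_genetic(S, None, n_factors=2, rotation="varimax")
        b = search.efa_genetic(S, W, n_factors=2, rotation="varimax")
        assert np.allclose(a.loadings, b.loadings, atol=1e-6)

    def test_agrees_with_independent_principal_axis_oracle(self):
        """Cross-implementation check: iterated principal-axis factoring
        (implemented here from its textbook definition) reaches the same
        solution as the least-squares extraction."""
        _, S = self._construct()
        psi = np.full(6, 0.3)
        for _ in range(500):
            red = S - np.diag(psi)
            ev, evec = np.linalg.eigh(red)
            L = evec[:, -2:] * np.sqrt(np.maximum(ev[-2:], 0))
            psi_new = np.diag(S) - (L**2).sum(axis=1)
            if np.abs(psi_new - psi).max() < 1e-12:
                break
            psi = psi_new
        mine = search.efa_genetic(S, None, n_factors=2, rotation="none")
        assert congruence(mine.loadings, L).min() > 0.99

    def test_too_many_factors_rejected(self):
        _, S = self._construct()
        with pytest.raises(ValueError, match="df"):
            search.efa_genetic(S, None, n_factors=4)

    def test_heywood_case_flagged_not_fatal(self):
        rng = np.random.default_rng(83)
        L = np.zeros((5, 1))
        L[:, 0] = [0.99, 0.5, 0.4, 0.3, 0.2]
        S = L @ L.T + np.diag(np.maximum(1 - (L**2).sum(axis=1), 0.0) + 0.001)
        S[0, 0] = 0.9  # communality forced above the diagonal
        with pytest.warns(UserWarning, match="Heywood"):
            sol = search.efa_genetic(S, None, n_factors=1)
        assert sol.heywood


class TestRotationChoice:
    def _sol(self, loadings, phi, rotation):
        L = np.asarray(loadings, dtype=float)
        return search.EFASolution(
            n_factors=L.shape[1], loadings=L, rotation=rotation,
            interfactor_corr=np.asarray(phi, dtype=float),
            uniquenesses=np.zeros(L.shape[0]),
            weights_used=np.ones((L.shape[0], L.shape[0])), discrepancy=0.0,
        )

    def test_modest_obliquity_prefers_varimax(self):
        L = [[0.6, 0.0], [0.5, 0.0], [0.0, 0.6]]
        v = self._sol(L, np.eye(2), "varimax")
        o = self._sol(L, [[1, 0.10], [0.10, 1]], "oblimin")
        chosen, reason = search.choose_rotation(o, v)
        assert chosen is v
        assert "0.32" in reason or "matches" in reason

    def test_strong_obliquity_with_different_pattern_prefers_oblimin(self):
        v = self._sol([[0.6, 0.3], [0.5, 0.3], [0.3, 0.6]], np.eye(2), "varimax")
        o = self._sol([[0.6, 0.0], [0.5, 0.0], [0.0, 0.6]],
                      [[1, 0.6], [0.6, 1]], "oblimin")
        chosen, _ = search.choose_rotation(o, v)
        assert chosen is o

    def test_strong_obliquity_with_same_pattern_prefers_varimax(self):
        L = [[0.6, 0.0], [0.5, 0.0], [0.0, 0.6]]
        v = self._sol(L, np.eye(2), "varimax")
        o = self._sol([[0.55, 0.05], [0.45, 0.02], [0.04, 0.58]],
                      [[1, 0.6], [0.6, 1]], "oblimin")
        chosen, _ = search.choose_rotation(o, v)
        assert chosen is v


class TestBuildIpcFromEfa:
    def _efa(self, loadings):
        L = np.asarray(loadings, dtype=float)
        return search.EFASolution(
            n_factors=L.shape[1], loadings=L, rotation="varimax",
            interfactor_corr=np.eye(L.shape[1]),
            uniquenesses=np.zeros(L.shape[0]),
            weights_used=np.ones((L.shape[0], L.shape[0])), discrepancy=0.0,
        )

    def test_small_loadings_fixed_to_zero(self):
        L = np.zeros((6, 2))
        L[:3, 0] = [0.6, 0.5, 0.15]
        L[2:, 1] = [0.4, 0.5, 0.6, 0.05]
        L[0, 1] = 0.05
        spec = search.build_ipc_from_efa(self._efa(L))
        assert not spec.genetic_free[0, 1]   # |0.05| < 0.10 → fixed
        assert spec.genetic_free[2, 0]       # |0.15| ≥ 0.10 → free
        assert not spec.genetic_free[5, 1]
        # starting values carry the EFA loadings on free shared cells
        assert spec.genetic_start[2, 0] == pytest.approx(0.15)

    def test_all_large_loadings_fully_free(self):
        L = np.full((6, 2), 0.3)
        spec = search.build_ipc_from_efa(self._efa(L))
        assert spec.genetic_free[:, :2].all()

    def test_trimming_removes_near_zero_specific_and_refits(self, small_dataset):
        scenario, _, phenos, grm = small_dataset
        L = scenario.genetic_loadings[:, :2].copy()
        spec = search.build_ipc_from_efa(self._efa(L))
        final, fit, log = search.fit_with_trimming(spec, grm, phenos, seed=0)
        if log:  # trimming occurred: one parameter fewer per trimmed cell
            assert final.n_par == spec.n_par - len(log)
        assert fit.converged


class TestCompareModels:
    class _Stub:
        def __init__(self, loglik, n_par, n_ind):
            self.loglik, self.n_par, self.n_ind = loglik, n_par, n_ind

    def test_aic_from_printed_loglik(self):
        """AIC = −2ℓ + 2p reconstructs a three-factor model table row:
        ℓ = −15250.96, p = 53 → 30607.92."""
        fits = {"ipc": self._Stub(-15250.96, 53, 5279)}
        cmp = search.compare_models(fits)
        assert cmp.table.loc["ipc", "AIC"] == pytest.approx(30607.92, abs=0.005)
        assert cmp.table.loc["ipc", "BIC"] == pytest.approx(
            -2 * -15250.96 + 53 * np.log(5279), abs=1e-9
        )

    def test_equal_loglik_lrt_is_null(self):
        fits = {
            "general": self._Stub(-1000.0, 30, 500),
            "restricted": self._Stub(-1000.0, 11, 500),
        }
        cmp = search.compare_models(fits, nesting=[("general", "restricted")])
        row = cmp.lrt.iloc[0]
        assert row["delta_chi2"] == 0.0
        assert row["delta_df"] == 19
        assert row["p"] > 0.99

    def test_ranking_invariant_to_loglik_shift(self):
        fits1 = {"a": self._Stub(-900.0, 10, 300), "b": self._Stub(-905.0, 5, 300)}
        fits2 = {k: self._Stub(f.loglik + 123.0, f.n_par, 300) for k, f in fits1.items()}
        assert search.compare_models(fits1).best == search.compare_models(fits2).best

    def test_non_nested_pair_rejected(self):
        fits = {"a": self._Stub(-900.0, 10, 300), "b": self._Stub(-890.0, 10, 300)}
        with pytest.raises(ValueError, match="more parameters"):
            search.compare_models(fits, nesting=[("a", "b")])


class TestSrmr:
    def _fit_with_sigma(self, SV):
        k = SV.shape[0]
        spec = sem.build_model("cholesky", k)
        LA = np.linalg.cholesky(SV / 2)
        theta = spec.pack(LA, LA)
        return sem.FitResult(spec=spec, theta=theta, vcov=np.eye(spec.n_par),
                             loglik=0.0, n_ind=100, converged=True)

    def test_exact_fit_is_zero(self):
        SV = np.array([[1.0, 0.4], [0.4, 1.0]])
        assert search.srmr(self._fit_with_sigma(SV), SV) == pytest.approx(0.0, abs=1e-12)

    def test_hand_example_two_traits(self):
        """Observed r = 0.5 vs implied r = 0.3 at unit variances:
        √(0.2²/3) = 0.1155 over the three unique elements."""
        implied = np.array([[1.0, 0.3], [0.3, 1.0]])
        observed = np.array([[1.0, 0.5], [0.5, 1.0]])
        got = search.srmr(self._fit_with_sigma(implied), observed)
        assert got == pytest.approx(np.sqrt(0.2**2 / 3), abs=1e-10)

    def test_saturated_cholesky_near_zero(self, small_dataset, small_cholesky_fit):
        _, _, phenos, _ = small_dataset
        S = np.cov(phenos.values, rowvar=False)
        assert search.srmr(small_cholesky_fit, S) < 0.01

    def test_non_pd_observed_rejected(self):
        bad = np.array([[1.0, 1.2], [1.2, 1.0]])
        SV = np.eye(2)
        with pytest.raises(ValueError, match="positive definite"):
            search.srmr(self._fit_with_sigma(SV + 0.1), bad)


class TestMeffSpectral:
    def test_identity_gives_full_count(self):
        meff, thr = search.meff_spectral(np.eye(5))
        assert meff == pytest.approx(5.0)
        assert thr == pytest.approx(0.01)

    def test_perfect_correlation_collapses_to_one(self):
        R = np.array([[1.0, 1.0], [1.0, 1.0]])
        meff, _ = search.meff_spectral(R)
        assert meff == pytest.approx(1.0)

    def test_thirtyfour_independent_measures_threshold(self):
        meff, thr = search.meff_spectral(np.eye(34), alpha=0.05)
        assert thr == pytest.approx(0.05 / 34, abs=1e-12)
        assert round(thr, 4) == 0.0015

    def test_non_psd_rejected(self):
        R = np.array([[1.0, 2.0], [2.0, 1.0]])
        with pytest.raises(ValueError, match="positive semi-definite"):
            search.meff_spectral(R)


class TestPhenotypicPipeline:
    def _factor_phenos(self, n, L, seed):
        rng = np.random.default_rng(seed)
        k, q = L.shape
        F = rng.standard_normal((n, q))
        eps = rng.standard_normal((n, k)) * np.sqrt(1 - (L**2).sum(axis=1))
        Y = F @ L.T + eps
        Y = (Y - Y.mean(0)) / Y.std(0)
        return PhenotypeTable(values=Y, sample_ids=[f"i{j}" for j in range(n)],
                              trait_names=[f"t{j}" for j in range(k)])

    def test_exact_one_factor_model_fits_perfectly(self):
        L = np.full((5, 1), 0.7)
        phenos = self._factor_phenos(2000, L, seed=91)
        res = search.phenotypic_pipeline(phenos, seed=0)
        assert res.status == "ok"
        assert res.cfa_full["cfi"] > 0.99
        assert res.cfa_full["rmsea"] < 0.03

    def test_split_halves_balanced_and_stratified(self):
        L = np.full((4, 1), 0.6)
        phenos = self._factor_phenos(1000, L, seed=92)
        strata = np.repeat([0, 1], 500)
        res = search.phenotypic_pipeline(phenos, seed=5, strata=strata)
        n1, n2 = res.halves
        assert abs(n1 - n2) <= 2

    def test_three_factor_structure_recovered_across_seeds(self):
        # descending factor strengths keep the scree separable under the
        # optimal-coordinate rule (population eigenvalues 2.45, 1.98, 1.60)
        L = np.zeros((9, 3))
        L[:3, 0] = 0.85
        L[3:6, 1] = 0.7
        L[6:, 2] = 0.55
        hits = 0
        for seed in range(20):
            phenos = self._factor_phenos(1200, L, seed=100 + seed)
            res = search.phenotypic_pipeline(phenos, seed=seed)
            pattern_ok = (
                res.n_factors == 3
                and _pattern_matches(res.retained_pattern, L != 0)
            )
            hits += pattern_ok and res.status == "ok"
        assert hits >= 16


def _pattern_matches(pat, truth):
    if pat.shape != truth.shape:
        return False
    from itertools import permutations

    for perm in permutations(range(pat.shape[1])):
        if (pat[:, list(perm)] == truth).all():
            return True
    return False
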