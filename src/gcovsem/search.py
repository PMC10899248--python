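"""Data-driven genomic covariance modelling pipeline and fit indices.

Workflow: fit a saturated (Cholesky) model → eigendecompose its genetic
correlation matrix to pick the number of shared factors (optimal
coordinate ∧ Kaiser) → weighted-least-squares genetic EFA of the implied
genetic covariance (weights = element sampling variances) → rotate
(varimax unless oblimin factors correlate beyond 0.32 and change the
loading pattern) → translate EFA loadings into a constrained hybrid
independent-pathway/Cholesky (IPC) model (|λ| < 0.10 → fixed zero, EFA
values as starting values), trim near-zero specific loadings (|λ| < 0.01)
with a refit → compare candidate models by LRT/AIC/BIC and SRMR.

Also houses the spectral-decomposition effective number of tests and the
split-half phenotypic EFA→CFA pipeline.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import sem
from ._factor import cfa_ml, oblimin, varimax, wls_efa
from .phenoprep import PhenotypeTable

__all__ = [
    "EFASolution",
    "ModelComparison",
    "genetic_pca",
    "cholesky_genetic_covariance",
    "efa_genetic",
    "choose_rotation",
    "build_ipc_from_efa",
    "fit_with_trimming",
    "compare_models",
    "efa_fit_loading_correlation",
    "srmr",
    "meff_spectral",
    "phenotypic_pipeline",
    "genomic_pipeline",
]

ZERO_LOADING = 0.10   # EFA loadings below this are fixed to zero in the IPC
TRIM_LOADING = 0.01   # fitted specific loadings below this are trimmed
OBLIQUE_R = 0.32      # interfactor correlation beyond which oblimin matters


@dataclass
class EFASolution:
    """A rotated genetic EFA solution."""

    n_factors: int
    loadings: np.ndarray
    rotation: str
    interfactor_corr: np.ndarray
    uniquenesses: np.ndarray
    weights_used: np.ndarray
    discrepancy: float
    heywood: bool = False

    @property
    def pattern(self) -> np.ndarray:
        """Thresholded zero/nonzero pattern at the |λ| < 0.10 rule."""
        return np.abs(self.loadings) >= ZERO_LOADING


@dataclass
class PCAResult:
    eigenvalues: np.ndarray
    n_factors: int


def genetic_pca(rg_matrix, kaiser: float = 1.0) -> PCAResult:
    """Number of shared genetic factors from a genetic correlation matrix.

    Eigenvalues are screened with the optimal-coordinate criterion
    (component i is kept if its eigenvalue exceeds the value predicted at
    i by the straight line through eigenvalues i+1 and k) combined with
    Kaiser's rule (eigenvalue > 1) as a conjunction — the automatic
    surrogate for reading a scree plot.
    """
    R = np.asarray(rg_matrix, dtype=float)
    if not np.allclose(R, R.T, atol=1e-8):
        raise ValueError("genetic correlation matrix must be symmetric")
    ev = np.linalg.eigvalsh(R)[::-1]
    k = ev.size
    n = 0
    for i in range(k - 2):
        slope = (ev[k - 1] - ev[i + 1]) / ((k - 1) - (i + 1))
        predicted = ev[i + 1] + slope * (i - (i + 1))
        if ev[i] > predicted and ev[i] > kaiser:
            n += 1
    return PCAResult(eigenvalues=ev, n_factors=n)


def cholesky_genetic_covariance(fit: sem.FitResult):
    """Implied genetic covariance V_A and element-wise sampling variances.

    The variances come from the delta method: Jacobian of vec(Σ_A) in the
    free parameters against the fit's parameter covariance.  These are
    the weights of the genetic EFA.
    """
    spec, theta = fit.spec, fit.theta
    k = spec.k

    def vecA(th):
        LA, _ = spec.lambdas(th)
        return (LA @ LA.T).ravel()

    p = theta.size
    J = np.zeros((k * k, p))
    for j in range(p):
        h = 1e-6 * max(1.0, abs(theta[j]))
        tp, tm = theta.copy(), theta.copy()
        tp[j] += h
        tm[j] -= h
        J[:, j] = (vecA(tp) - vecA(tm)) / (2 * h)
    var = np.einsum("ij,jk,ik->i", J, fit.vcov, J).reshape(k, k)
    return fit.sigma_A, np.maximum(var, 1e-12)


def efa_genetic(
    VA,
    VA_var=None,
    n_factors: int = 1,
    rotation: str = "varimax",
    seed: int = 0,
) -> EFASolution:
    """Genetic EFA of an implied genetic covariance matrix.

    Extraction is least squares on unique elements, inverse-weighted by
    the element sampling variances (diagonal weight matrix); pass
    ``VA_var=None`` for the unweighted variant.  ``rotation`` is
    "varimax", "oblimin" or "none".
    """
    L, psi, disc = wls_efa(VA, n_factors, element_variances=VA_var, seed=seed)
    heywood = bool((psi < 0).any())
    if heywood:
        warnings.warn("negative uniqueness in genetic EFA (Heywood case)")
    if rotation == "varimax":
        L, _ = varimax(L)
        Phi = np.eye(n_factors)
    elif rotation == "oblimin":
        L, Phi = oblimin(L)
    elif rotation == "none":
        Phi = np.eye(n_factors)
    else:
        raise ValueError(f"unknown rotation {rotation!r}")
    W = np.ones_like(np.asarray(VA)) if VA_var is None else np.asarray(VA_var)
    return EFASolution(
        n_factors=n_factors,
        loadings=L,
        rotation=rotation,
        interfactor_corr=Phi,
        uniquenesses=psi,
        weights_used=W,
        discrepancy=disc,
        heywood=heywood,
    )


def choose_rotation(oblimin_sol: EFASolution, varimax_sol: EFASolution):
    """Prefer varimax unless obliquity genuinely changes the model.

    Varimax is chosen when the oblimin interfactor correlations are
    modest (max |r| ≤ 0.32) or when both solutions imply the same
    zero/nonzero pattern at the 0.10 threshold — i.e. when allowing
    correlated factors does not simplify the structure.  Returns
    ``(chosen solution, reason string)``.
    """
    if oblimin_sol.loadings.shape != varimax_sol.loadings.shape:
        raise ValueError("solutions must share trait and factor counts")
    Phi = oblimin_sol.interfactor_corr
    off = np.abs(Phi[~np.eye(Phi.shape[0], dtype=bool)])
    max_r = off.max() if off.size else 0.0
    if max_r <= OBLIQUE_R:
        return varimax_sol, f"varimax: max interfactor |r| = {max_r:.3f} <= {OBLIQUE_R}"
    if _patterns_match(oblimin_sol, varimax_sol):
        return (
            varimax_sol,
            f"varimax: oblimin pattern matches at the {ZERO_LOADING} threshold "
            f"despite |r| = {max_r:.3f}",
        )
    return oblimin_sol, f"oblimin: max interfactor |r| = {max_r:.3f} > {OBLIQUE_R}"


def _patterns_match(a: EFASolution, b: EFASolution) -> bool:
    pa, pb = a.pattern, b.pattern
    q = pa.shape[1]
    cols = list(range(q))
    # try greedy column matching (rotations can permute factors)
    used = []
    for ja in range(q):
        best, best_score = None, -1
        for jb in cols:
            if jb in used:
                continue
            score = (pa[:, ja] == pb[:, jb]).sum()
            if score > best_score:
                best, best_score = jb, score
        used.append(best)
        if best_score < pa.shape[0]:
            return False
    return True


def build_ipc_from_efa(efa: EFASolution, trait_names=None) -> sem.ModelSpec:
    """Translate a genetic EFA solution into a constrained IPC model.

    Shared genetic cells with EFA |λ| < 0.10 are fixed to zero; the rest
    stay free and start at the EFA value.  Each trait keeps a free
    specific genetic loading and the residual part is a free Cholesky.
    """
    L = efa.loadings
    k, q = L.shape
    constraints = [
        ("A", t, j) for t in range(k) for j in range(q) if abs(L[t, j]) < ZERO_LOADING
    ]
    spec = sem.build_model(
        "ipc",
        k=k,
        n_shared_genetic=q,
        constraints=constraints,
        trait_names=trait_names,
    )
    start = np.full(spec.genetic_free.shape, np.nan)
    start[:, : spec.n_shared_genetic] = L[:, : spec.n_shared_genetic]
    spec.genetic_start = np.where(spec.genetic_free, start, np.nan)
    return spec


def fit_with_trimming(
    spec: sem.ModelSpec,
    grm,
    phenos,
    trim_threshold: float = TRIM_LOADING,
    **fit_kwargs,
):
    """Fit an IPC spec, then trim near-zero specific genetic loadings.

    Fitted specific loadings with |λ| below the threshold are fixed to
    zero and the model refitted once; returns ``(final spec, final fit,
    log)`` where the log records each trimming decision.
    """
    log = []
    fitted = sem.fit(spec, grm, phenos, **fit_kwargs)
    n_shared = spec.n_shared_genetic
    LA = fitted.lambda_A
    to_trim = []
    for t in range(spec.k):
        col = n_shared + t
        if col < spec.p_a and spec.genetic_free[t, col] and abs(LA[t, col]) < trim_threshold:
            to_trim.append(("A", t, col))
            log.append(
                f"trimmed specific genetic loading of trait {spec.trait_names[t]} "
                f"(|{LA[t, col]:.4f}| < {trim_threshold})"
            )
    if not to_trim:
        return spec, fitted, log
    gf = spec.genetic_free.copy()
    for _, t, col in to_trim:
        gf[t, col] = False
    trimmed = sem.ModelSpec(
        family=spec.family,
        k=spec.k,
        genetic_free=gf,
        residual_free=spec.residual_free.copy(),
        genetic_fixed=spec.genetic_fixed.copy(),
        residual_fixed=spec.residual_fixed.copy(),
        genetic_start=spec.genetic_start,
        n_shared_genetic=spec.n_shared_genetic,
        trait_names=spec.trait_names,
        genetic_factor_names=spec.genetic_factor_names,
    )
    refit = sem.fit(trimmed, grm, phenos, **fit_kwargs)
    return trimmed, refit, log


def efa_fit_loading_correlation(efa: EFASolution, spec: sem.ModelSpec, fit: sem.FitResult) -> float:
    """Pearson correlation between EFA-predicted and fitted free shared
    loadings, after aligning each fitted factor column's sign to the EFA
    (the likelihood cannot distinguish a factor from its negation)."""
    q = min(efa.loadings.shape[1], spec.n_shared_genetic)
    LA = fit.lambda_A[:, :q].copy()
    for j in range(q):
        if LA[:, j] @ efa.loadings[:, j] < 0:
            LA[:, j] *= -1
    mask = spec.genetic_free[:, :q]
    if mask.sum() < 3:
        raise ValueError("too few free shared loadings to correlate")
    return float(np.corrcoef(efa.loadings[:, :q][mask], LA[mask])[0, 1])


@dataclass
class ModelComparison:
    """AIC/BIC table plus LRTs for declared nested pairs."""

    table: pd.DataFrame
    lrt: pd.DataFrame
    best: str


def compare_models(fits: dict, nesting=None, n_ind: int = None) -> ModelComparison:
    """Fit-index table for named fits, with LRTs for nested pairs.

    ``fits`` maps model name → FitResult; ``nesting`` lists
    ``(general, restricted)`` name pairs.  AIC = −2ℓ + 2p and
    BIC = −2ℓ + p·ln(n); the best model is the lowest AIC with BIC as
    tie-break.  All fits must share one modelled sample.
    """
    names = list(fits)
    ns = {f.n_ind for f in fits.values() if f.n_ind}
    if n_ind is None:
        if len(ns) > 1:
            raise ValueError("fits were computed on different samples")
        n_ind = ns.pop() if ns else None
    rows = []
    for name in names:
        f = fits[name]
        rows.append(
            {
                "model": name,
                "loglik": f.loglik,
                "n_par": f.n_par,
                "AIC": -2.0 * f.loglik + 2.0 * f.n_par,
                "BIC": -2.0 * f.loglik + f.n_par * np.log(n_ind),
            }
        )
    table = pd.DataFrame(rows).set_index("model")
    lrt_rows = []
    for gen, res in nesting or ():
        fg, fr = fits[gen], fits[res]
        ddf = fg.n_par - fr.n_par
        if ddf <= 0:
            raise ValueError(
                f"LRT requires {gen!r} to have more parameters than {res!r}"
            )
        chi2 = 2.0 * (fg.loglik - fr.loglik)
        if chi2 < -1e-6:
            raise ValueError(
                f"restricted model {res!r} out-fits {gen!r}; pair is not nested"
            )
        chi2 = max(chi2, 0.0)
        lrt_rows.append(
            {
                "general": gen,
                "restricted": res,
                "delta_chi2": chi2,
                "delta_df": ddf,
                "p": stats.chi2.sf(chi2, ddf),
            }
        )
    lrt = pd.DataFrame(lrt_rows)
    ordered = table.sort_values(["AIC", "BIC"])
    return ModelComparison(table=table, lrt=lrt, best=ordered.index[0])


def srmr(fit: sem.FitResult, observed_cov) -> float:
    """Standardised root mean square residual of a fitted model.

    Both the observed and the model-implied covariance are scaled to
    correlation form by their own diagonals; the statistic is the root
    mean square of the differences over the k(k+1)/2 unique elements
    (no degrees-of-freedom adjustment — isolated here so an adjusted
    variant can be swapped in).
    """
    S = np.asarray(observed_cov, dtype=float)
    k = S.shape[0]
    if fit.spec.k != k:
        raise ValueError("dimension mismatch between fit and observed matrix")
    if np.linalg.eigvalsh(S).min() <= 0:
        raise ValueError("observed covariance must be positive definite")
    Sigma = fit.sigma_V

    def to_corr(M):
        d = np.sqrt(np.diag(M))
        return M / np.outer(d, d)

    diff = to_corr(S) - to_corr(Sigma)
    il, jl = np.tril_indices(k)
    return float(np.sqrt(np.mean(diff[il, jl] ** 2)))


def meff_spectral(cor_matrix, alpha: float = 0.05):
    """Effective number of independent tests by spectral decomposition.

    M_eff = 1 + (M − 1)(1 − Var(λ)/M) on the eigenvalues λ of the
    phenotypic correlation matrix (sample variance); the adjusted
    threshold is alpha / M_eff.  Returns ``(M_eff, threshold)``.
    """
    R = np.asarray(cor_matrix, dtype=float)
    ev = np.linalg.eigvalsh(R)
    if ev.min() < -1e-8:
        raise ValueError("correlation matrix must be positive semi-definite")
    M = ev.size
    var = ev.var(ddof=1) if M > 1 else 0.0
    meff = 1.0 + (M - 1.0) * (1.0 - var / M)
    return float(meff), float(alpha / meff)


@dataclass
class PhenotypicPipelineResult:
    n_factors: int
    eigenvalues: np.ndarray
    efa_loadings: np.ndarray
    retained_pattern: np.ndarray
    cfa_half: dict
    cfa_full: dict = None
    status: str = "ok"
    halves: tuple = None


def _split_half(n: int, strata, seed: int):
    """Seeded stratified half split; halves differ by at most 1 per stratum."""
    rng = np.random.default_rng(seed)
    strata = np.zeros(n, dtype=int) if strata is None else np.asarray(strata)
    half1 = np.zeros(n, dtype=bool)
    for s in np.unique(strata):
        idx = np.nonzero(strata == s)[0]
        idx = rng.permutation(idx)
        half1[idx[: idx.size // 2 + (idx.size % 2) * rng.integers(0, 2)]] = True
    return half1


def phenotypic_pipeline(
    phenos: PhenotypeTable,
    seed: int = 0,
    strata=None,
    fit_thresholds=(0.95, 0.95, 0.06),
) -> PhenotypicPipelineResult:
    """Split-half phenotypic factor pipeline: PCA → EFA → CFA.

    The factor count comes from the full-sample phenotypic correlation
    (optimal coordinate ∧ Kaiser); EFA (varimax) runs on half 1 and its
    |λ| > 0.10 pattern is confirmed by CFA on half 2 (good fit: CFI and
    TLI above 0.95, RMSEA below 0.06), after which the CFA is refitted on
    the full sample.  Convergence or fit failure is reported as a status,
    not an exception.
    """
    Y = phenos.values
    complete = ~np.isnan(Y).any(axis=1)
    Yc = Y[complete]
    n, k = Yc.shape
    if n < 200:
        raise ValueError("phenotypic pipeline needs at least 200 complete rows")
    R = np.corrcoef(Yc, rowvar=False)
    pca = genetic_pca(R)
    q = max(pca.n_factors, 1)

    strata_c = None if strata is None else np.asarray(strata)[complete]
    half1 = _split_half(n, strata_c, seed)
    R1 = np.corrcoef(Yc[half1], rowvar=False)
    L, psi, _ = wls_efa(R1, q, seed=seed)
    L, _ = varimax(L)
    pattern = np.abs(L) > ZERO_LOADING
    for j in range(q):
        if not pattern[:, j].any():
            pattern[np.argmax(np.abs(L[:, j])), j] = True

    Y2 = Yc[~half1]
    R2 = np.corrcoef(Y2, rowvar=False)
    try:
        cfa2 = cfa_ml(R2, n_obs=Y2.shape[0], pattern=pattern)
    except Exception as exc:
        return PhenotypicPipelineResult(
            n_factors=q, eigenvalues=pca.eigenvalues, efa_loadings=L,
            retained_pattern=pattern, cfa_half=None,
            status=f"empirically unidentified: {exc}", halves=(int(half1.sum()), int((~half1).sum())),
        )
    cfi_t, tli_t, rmsea_t = fit_thresholds
    ok = (
        cfa2["converged"]
        and cfa2["cfi"] > cfi_t
        and cfa2["tli"] > tli_t
        and cfa2["rmsea"] < rmsea_t
    )
    result = PhenotypicPipelineResult(
        n_factors=q,
        eigenvalues=pca.eigenvalues,
        efa_loadings=L,
        retained_pattern=pattern,
        cfa_half=cfa2,
        halves=(int(half1.sum()), int((~half1).sum())),
    )
    if not ok:
        result.status = "confirmation failed on held-out half"
        return result
    result.cfa_full = cfa_ml(R, n_obs=n, pattern=pattern)
    return result


def genomic_pipeline(grm, phenos, seed: int = 0, rotation: str = "auto"):
    """End-to-end data-driven genomic covariance modelling.

    Saturated Cholesky fit → genetic PCA on its r_g matrix → weighted
    genetic EFA (both rotations when ``rotation='auto'``) → constrained
    IPC build, fit and trim → comparison against the Cholesky.  Returns a
    dict with every intermediate product and a decision log.
    """
    log = []
    k = phenos.values.shape[1] if not isinstance(phenos, PhenotypeTable) else phenos.k
    chol_spec = sem.build_model("cholesky", k=k, trait_names=getattr(phenos, "trait_names", None))
    chol_fit = sem.fit(chol_spec, grm, phenos, seed=seed)
    std = sem.standardize_solution(chol_fit)
    pca = genetic_pca(std.rg)
    log.append(f"genetic PCA retained {pca.n_factors} factor(s)")
    if pca.n_factors == 0:
        log.append("no shared structure; pipeline stops at the saturated model")
        return {
            "cholesky": chol_fit, "pca": pca, "efa": None, "ipc_spec": None,
            "ipc_fit": None, "comparison": None, "log": log,
        }
    VA, VA_var = cholesky_genetic_covariance(chol_fit)
    if rotation == "auto":
        sol_v = efa_genetic(VA, VA_var, pca.n_factors, rotation="varimax", seed=seed)
        sol_o = efa_genetic(VA, VA_var, pca.n_factors, rotation="oblimin", seed=seed)
        efa, reason = choose_rotation(sol_o, sol_v)
        log.append(f"rotation choice: {reason}")
    else:
        efa = efa_genetic(VA, VA_var, pca.n_factors, rotation=rotation, seed=seed)
        log.append(f"rotation forced to {rotation}")
    ipc_spec = build_ipc_from_efa(efa, trait_names=chol_spec.trait_names)
    log.append(
        f"IPC constraints: {int((~ipc_spec.genetic_free[:, :pca.n_factors]).sum())} "
        f"shared cells fixed to zero by the |λ| < {ZERO_LOADING} rule"
    )
    final_spec, ipc_fit, trim_log = fit_with_trimming(ipc_spec, grm, phenos, seed=seed)
    log.extend(trim_log)
    comparison = compare_models(
        {"cholesky": chol_fit, "ipc": ipc_fit}, nesting=[("cholesky", "ipc")]
    )
    log.append(f"best model by AIC: {comparison.best}")
    r = efa_fit_loading_correlation(efa, final_spec, ipc_fit)
    log.append(f"EFA-predicted vs fitted free shared loadings: r = {r:.4f}")
    return {
        "cholesky": chol_fit,
        "pca": pca,
        "efa": efa,
        "ipc_spec": final_spec,
        "ipc_fit": ipc_fit,
        "comparison": comparison,
        "loading_correlation": r,
        "log": log,
    }
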