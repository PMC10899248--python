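"""Maximum-likelihood SEM of genetic and residual covariance on a GRM.

The model: k Z-standardized traits on n unrelated individuals follow

    vec(Y) ~ N(0, Σ_A ⊗ G + Σ_E ⊗ I),   Σ_A = Λ_A Λ_Aᵀ,  Σ_E = Λ_E Λ_Eᵀ,

where G is the genetic relationship matrix.  Factor variances are fixed
to the identity, so all structure lives in the loading matrices Λ_A
(genetic) and Λ_E (residual).  Model families:

* ``cholesky`` — saturated: both Λ lower-triangular k × k.
* ``independent_pathway`` — shared factor(s) loading on every trait plus
  one specific factor per trait, in both parts.
* ``ipc`` — hybrid: independent-pathway genetic part, Cholesky residual.
* ``bifactor`` — genetic part with a general factor on all traits,
  orthogonal grouping factors, specific factors; Cholesky residual.

Rotating phenotypes into the GRM eigenbasis (G = U diag(d) Uᵀ) makes the
nk × nk covariance block-diagonal with k × k blocks d_i Σ_A + Σ_E, which
is what makes maximum likelihood tractable at cohort scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .grm import GRMatrix
from .phenoprep import PhenotypeTable

__all__ = [
    "ModelSpec",
    "FitResult",
    "StandardizedSolution",
    "build_model",
    "loglikelihood",
    "fit",
    "standardize_solution",
    "extend_with_mapping",
]

_LOG2PI = np.log(2.0 * np.pi)
_BIG = 1e12

FAMILIES = ("cholesky", "independent_pathway", "ipc", "bifactor")


@dataclass
class ModelSpec:
    """Loading-pattern specification for one GRM-SEM model.

    ``genetic_free``/``residual_free`` are boolean k × p masks of freely
    estimated cells; ``genetic_fixed``/``residual_fixed`` hold the values
    of the non-free cells (structural zeros unless a constraint says
    otherwise).  ``genetic_start`` optionally carries starting values
    (e.g. EFA loadings) for the free genetic cells.
    """

    family: str
    k: int
    genetic_free: np.ndarray
    residual_free: np.ndarray
    genetic_fixed: np.ndarray = None
    residual_fixed: np.ndarray = None
    genetic_start: np.ndarray = None
    n_shared_genetic: int = 0
    n_shared_residual: int = 0
    trait_names: list = None
    genetic_factor_names: list = None
    residual_factor_names: list = None

    def __post_init__(self):
        self.genetic_free = np.asarray(self.genetic_free, dtype=bool)
        self.residual_free = np.asarray(self.residual_free, dtype=bool)
        if self.genetic_fixed is None:
            self.genetic_fixed = np.zeros(self.genetic_free.shape)
        if self.residual_fixed is None:
            self.residual_fixed = np.zeros(self.residual_free.shape)
        self.genetic_fixed = np.asarray(self.genetic_fixed, dtype=float)
        self.residual_fixed = np.asarray(self.residual_fixed, dtype=float)
        if self.trait_names is None:
            self.trait_names = [f"y{t + 1}" for t in range(self.k)]
        if self.genetic_factor_names is None:
            self.genetic_factor_names = [
                f"A{j + 1}" for j in range(self.genetic_free.shape[1])
            ]
        if self.residual_factor_names is None:
            self.residual_factor_names = [
                f"E{j + 1}" for j in range(self.residual_free.shape[1])
            ]
        for M, part in ((self.genetic_free, "genetic"), (self.residual_free, "residual")):
            if M.shape[0] != self.k:
                raise ValueError(f"{part} pattern must have k = {self.k} rows")
        if self.n_par > self.k * (self.k + 1):
            raise ValueError(
                f"{self.n_par} free parameters exceed the k(k+1) = "
                f"{self.k * (self.k + 1)} identifiable covariance moments"
            )

    @property
    def p_a(self) -> int:
        return self.genetic_free.shape[1]

    @property
    def p_e(self) -> int:
        return self.residual_free.shape[1]

    @property
    def n_par(self) -> int:
        return int(self.genetic_free.sum() + self.residual_free.sum())

    @property
    def param_labels(self) -> list:
        labels = []
        for part, mask, fnames in (
            ("A", self.genetic_free, self.genetic_factor_names),
            ("E", self.residual_free, self.residual_factor_names),
        ):
            for t, j in zip(*np.nonzero(mask)):
                labels.append(f"{part}[{self.trait_names[t]},{fnames[j]}]")
        return labels

    def lambdas(self, theta: np.ndarray):
        """Assemble (Λ_A, Λ_E) from the free-parameter vector."""
        theta = np.asarray(theta, dtype=float)
        if theta.size != self.n_par:
            raise ValueError(f"theta has {theta.size} entries, spec needs {self.n_par}")
        na = int(self.genetic_free.sum())
        LA = self.genetic_fixed.copy()
        LA[self.genetic_free] = theta[:na]
        LE = self.residual_fixed.copy()
        LE[self.residual_free] = theta[na:]
        return LA, LE

    def pack(self, LA: np.ndarray, LE: np.ndarray) -> np.ndarray:
        return np.concatenate([LA[self.genetic_free], LE[self.residual_free]])


def _lower_pattern(k: int) -> np.ndarray:
    return np.tril(np.ones((k, k), dtype=bool))


def _ip_pattern(k: int, n_shared: int):
    """Shared columns (all traits) followed by a diagonal specific block."""
    shared = np.ones((k, n_shared), dtype=bool)
    specific = np.eye(k, dtype=bool)
    return np.column_stack([shared, specific])


def build_model(
    family: str,
    k: int,
    n_shared_genetic: int = 1,
    n_shared_residual: int = 1,
    constraints=None,
    grouping: np.ndarray = None,
    trait_names: list = None,
) -> ModelSpec:
    """Construct a validated :class:`ModelSpec` for one model family.

    ``constraints`` is an iterable of ``(part, trait, factor)`` with part
    "A" or "E", or ``(part, trait, factor, value)`` to fix a cell to a
    non-zero value; indices refer to the assembled pattern matrices.
    ``grouping`` (bifactor only) is a k × n_group boolean membership
    pattern for the grouping factors.
    """
    if family not in FAMILIES:
        raise ValueError(f"unknown family {family!r}; expected one of {FAMILIES}")
    if k < 1:
        raise ValueError("k must be at least 1")

    if family == "cholesky":
        gf, rf = _lower_pattern(k), _lower_pattern(k)
        gnames = [f"A{j + 1}" for j in range(k)]
        n_ac = 0
    elif family == "independent_pathway":
        gf = _ip_pattern(k, n_shared_genetic)
        rf = _ip_pattern(k, n_shared_residual)
        gnames = [f"AC{j + 1}" for j in range(n_shared_genetic)] + [
            f"AS{t + 1}" for t in range(k)
        ]
        n_ac = n_shared_genetic
    elif family == "ipc":
        gf = _ip_pattern(k, n_shared_genetic)
        rf = _lower_pattern(k)
        gnames = [f"AC{j + 1}" for j in range(n_shared_genetic)] + [
            f"AS{t + 1}" for t in range(k)
        ]
        n_ac = n_shared_genetic
    else:  # bifactor
        if grouping is None:
            grouping = np.zeros((k, 0), dtype=bool)
        grouping = np.asarray(grouping, dtype=bool)
        gf = np.column_stack(
            [np.ones((k, 1), dtype=bool), grouping, np.eye(k, dtype=bool)]
        )
        rf = _lower_pattern(k)
        gnames = (
            ["Ageneral"]
            + [f"Agroup{j + 1}" for j in range(grouping.shape[1])]
            + [f"AS{t + 1}" for t in range(k)]
        )
        n_ac = 1 + grouping.shape[1]

    g_fixed = np.zeros(gf.shape)
    r_fixed = np.zeros(rf.shape)
    if constraints:
        for con in constraints:
            part, t, j, *rest = con
            value = rest[0] if rest else 0.0
            mask, fixed = (gf, g_fixed) if part == "A" else (rf, r_fixed)
            if t >= mask.shape[0] or j >= mask.shape[1] or not mask[t, j]:
                raise ValueError(
                    f"constraint {con!r} targets a structurally absent cell"
                )
            mask[t, j] = False
            fixed[t, j] = value

    if family in ("independent_pathway", "ipc", "bifactor"):
        for j in range(n_ac):
            if not gf[:, j].any():
                warnings.warn(f"shared genetic factor {j} fully constrained; dropped")
        keep = [j for j in range(n_ac) if gf[:, j].any()] + list(range(n_ac, gf.shape[1]))
        gf, g_fixed = gf[:, keep], g_fixed[:, keep]
        gnames = [gnames[j] for j in keep]
        n_ac = sum(1 for j in keep if j < n_ac)

    return ModelSpec(
        family=family,
        k=k,
        genetic_free=gf,
        residual_free=rf,
        genetic_fixed=g_fixed,
        residual_fixed=r_fixed,
        n_shared_genetic=n_ac,
        n_shared_residual=n_shared_residual if family == "independent_pathway" else 0,
        trait_names=trait_names,
        genetic_factor_names=gnames,
    )


# ---------------------------------------------------------------------------
# Likelihood


def _as_matrix(phenos) -> np.ndarray:
    if isinstance(phenos, PhenotypeTable):
        return phenos.values
    return np.atleast_2d(np.asarray(phenos, dtype=float))


def _loglik_core(SA, SE, d, Yt, want_grad=False):
    """Rotated log-likelihood (and full-matrix gradients wrt Σ_A, Σ_E).

    ``d`` are GRM eigenvalues, ``Yt = Uᵀ Y`` the rotated phenotypes; rows
    are independent with covariance V_i = d_i Σ_A + Σ_E.
    """
    n, k = Yt.shape
    V = d[:, None, None] * SA[None] + SE[None]
    try:
        L = np.linalg.cholesky(V)
    except np.linalg.LinAlgError:
        return (-np.inf, None, None) if want_grad else -np.inf
    logdet = 2.0 * np.log(np.einsum("ijj->ij", L)).sum()
    q = np.linalg.solve(V, Yt[:, :, None])[:, :, 0]
    quad = np.einsum("ij,ij->", Yt, q)
    ll = -0.5 * (n * k * _LOG2PI + logdet + quad)
    if not want_grad:
        return ll
    P = np.linalg.inv(V)
    S = q[:, :, None] * q[:, None, :] - P
    DA = 0.5 * np.einsum("i,ijk->jk", d, S)
    DE = 0.5 * S.sum(axis=0)
    return ll, DA, DE


def loglikelihood(spec: ModelSpec, theta, grm_eigen, phenos) -> float:
    """Gaussian log-likelihood of Z-standardized traits under the model.

    ``grm_eigen`` is a ``(d, U)`` pair or a :class:`GRMatrix` (its cached
    eigendecomposition is used).  Singular k × k blocks yield −inf rather
    than raising, so optimizers can retreat.
    """
    if isinstance(grm_eigen, GRMatrix):
        d, U = grm_eigen.eigen
    else:
        d, U = grm_eigen
    Y = _as_matrix(phenos)
    if np.isnan(Y).any():
        raise ValueError("loglikelihood expects complete data; filter rows first")
    LA, LE = spec.lambdas(theta)
    return _loglik_core(LA @ LA.T, LE @ LE.T, d, U.T @ Y)


def _negloglik_and_grad(theta, spec, d, Yt):
    LA, LE = spec.lambdas(theta)
    ll, DA, DE = _loglik_core(LA @ LA.T, LE @ LE.T, d, Yt, want_grad=True)
    if not np.isfinite(ll):
        return _BIG, np.zeros_like(theta)
    gA = 2.0 * DA @ LA
    gE = 2.0 * DE @ LE
    grad = np.concatenate([gA[spec.genetic_free], gE[spec.residual_free]])
    return -ll, -grad


@dataclass
class FitResult:
    """Maximum-likelihood fit of one :class:`ModelSpec`."""

    spec: ModelSpec
    theta: np.ndarray
    vcov: np.ndarray
    loglik: float
    n_ind: int
    converged: bool
    message: str = ""
    n_iter: int = 0
    grad_norm: float = np.nan
    heywood: bool = False

    @property
    def n_par(self) -> int:
        return self.spec.n_par

    @property
    def lambda_A(self) -> np.ndarray:
        return self.spec.lambdas(self.theta)[0]

    @property
    def lambda_E(self) -> np.ndarray:
        return self.spec.lambdas(self.theta)[1]

    @property
    def sigma_A(self) -> np.ndarray:
        LA = self.lambda_A
        return LA @ LA.T

    @property
    def sigma_E(self) -> np.ndarray:
        LE = self.lambda_E
        return LE @ LE.T

    @property
    def sigma_V(self) -> np.ndarray:
        return self.sigma_A + self.sigma_E

    @property
    def se(self) -> np.ndarray:
        v = np.diag(self.vcov)
        return np.sqrt(np.where(v > 0, v, np.nan))

    @property
    def wald_z(self) -> np.ndarray:
        return self.theta / self.se

    @property
    def wald_p(self) -> np.ndarray:
        return 2.0 * stats.norm.sf(np.abs(self.wald_z))

    @property
    def param_labels(self) -> list:
        return self.spec.param_labels

    @property
    def aic(self) -> float:
        return -2.0 * self.loglik + 2.0 * self.n_par

    def bic(self, n_ind: int = None) -> float:
        n = self.n_ind if n_ind is None else n_ind
        return -2.0 * self.loglik + self.n_par * np.log(n)


def _start_values(spec: ModelSpec, Y: np.ndarray) -> np.ndarray:
    """Starting θ: Cholesky factors of half the phenotypic covariance per
    part, with EFA-provided genetic starts taking precedence when given."""
    k = spec.k
    C = np.cov(Y, rowvar=False).reshape(k, k) + 1e-3 * np.eye(k)
    Lhalf = np.linalg.cholesky(C / 2.0)

    def _part_start(mask, family_block):
        if family_block.shape == mask.shape and mask.shape[1] == k:
            return family_block
        out = np.zeros(mask.shape)
        n_shared = mask.shape[1] - k
        out[:, :n_shared][mask[:, :n_shared]] = 0.35
        diag_target = np.sqrt(np.maximum(np.diag(C) / 2.0 - n_shared * 0.35**2, 0.04))
        for t in range(k):
            col = n_shared + t
            if col < mask.shape[1] and mask[t, col]:
                out[t, col] = diag_target[t]
        return out

    if spec.p_a == k and spec.family == "cholesky":
        A0 = Lhalf.copy()
    else:
        A0 = _part_start(spec.genetic_free, Lhalf if spec.p_a == k else np.empty(0))
    if spec.genetic_start is not None:
        gs = np.asarray(spec.genetic_start, dtype=float)
        A0 = np.where(np.isfinite(gs) & spec.genetic_free, gs, A0)
    if spec.p_e == k:
        E0 = Lhalf.copy()
    else:
        E0 = _part_start(spec.residual_free, np.empty(0))
    return spec.pack(np.where(spec.genetic_free, A0, 0), np.where(spec.residual_free, E0, 0))


def _canonicalize(spec: ModelSpec, theta: np.ndarray, vcov: np.ndarray = None):
    """Flip loading-column signs so the first free loading of every factor
    is positive (the likelihood is invariant to column sign flips)."""
    LA, LE = spec.lambdas(theta)
    for M, mask in ((LA, spec.genetic_free), (LE, spec.residual_free)):
        for j in range(M.shape[1]):
            rows = np.nonzero(mask[:, j] & (np.abs(M[:, j]) > 1e-10))[0]
            if rows.size and M[rows[0], j] < 0:
                M[:, j] = np.where(mask[:, j], -M[:, j], M[:, j])
    theta_new = spec.pack(np.where(spec.genetic_free, LA, 0), np.where(spec.residual_free, LE, 0))
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(theta != 0, theta_new / theta, 1.0)
    flips = np.sign(np.where(np.abs(ratio) > 0, ratio, 1.0))
    if vcov is not None:
        vcov = vcov * np.outer(flips, flips)
    return theta_new, vcov


def _numeric_hessian(fun_grad, theta, args):
    """Central-difference Hessian from the analytic gradient."""
    p = theta.size
    H = np.zeros((p, p))
    for j in range(p):
        h = 1e-5 * max(1.0, abs(theta[j]))
        tp, tm = theta.copy(), theta.copy()
        tp[j] += h
        tm[j] -= h
        gp = fun_grad(tp, *args)[1]
        gm = fun_grad(tm, *args)[1]
        H[:, j] = (gp - gm) / (2.0 * h)
    return (H + H.T) / 2.0


def fit(
    spec: ModelSpec,
    grm: GRMatrix,
    phenos,
    theta0: np.ndarray = None,
    n_restarts: int = 2,
    seed: int = 0,
    gtol: float = 1e-6,
    maxiter: int = 2000,
    compute_vcov: bool = True,
) -> FitResult:
    """Fit the model by maximum likelihood in the GRM eigenbasis.

    Complete-case across the modelled traits: rows with any missing trait
    are dropped (with the GRM subset accordingly) before fitting, so every
    model fitted to the same trait set shares one N_ind.  SEs come from
    the inverse observed information.
    """
    Y = _as_matrix(phenos)
    ids = None
    if isinstance(phenos, PhenotypeTable):
        ids = phenos.sample_ids
        if not np.array_equal(ids, grm.sample_ids):
            raise ValueError("phenotype rows must align with GRM sample IDs")
    if Y.shape[1] != spec.k:
        raise ValueError(f"phenotypes have {Y.shape[1]} traits, spec expects {spec.k}")
    complete = ~np.isnan(Y).any(axis=1)
    if not complete.all():
        idx = np.nonzero(complete)[0]
        Y = Y[idx]
        sub = GRMatrix(
            values=grm.values[np.ix_(idx, idx)],
            sample_ids=grm.sample_ids[idx],
            pair_counts=grm.pair_counts[np.ix_(idx, idx)],
        )
        d, U = sub.eigen
    else:
        d, U = grm.eigen
    n = Y.shape[0]
    if n < 100:
        warnings.warn(f"only {n} complete-case individuals; estimates may be unstable")
    Yt = U.T @ Y

    rng = np.random.default_rng(seed)
    if theta0 is None:
        theta0 = _start_values(spec, Y)
    best = None
    for attempt in range(n_restarts + 1):
        start = theta0 if attempt == 0 else theta0 + rng.normal(0, 0.1, theta0.size)
        res = optimize.minimize(
            _negloglik_and_grad,
            start,
            args=(spec, d, Yt),
            jac=True,
            method="L-BFGS-B",
            options={"maxiter": maxiter, "ftol": 1e-12, "gtol": gtol},
        )
        if best is None or res.fun < best.fun - 1e-9:
            best = res
        if best.fun < _BIG and np.linalg.norm(best.jac, np.inf) < 1e-4:
            break
    if best.fun >= _BIG:
        raise RuntimeError(
            f"optimization failed to find an admissible point: {best.message}"
        )
    theta = best.x
    grad_norm = float(np.linalg.norm(best.jac, np.inf))
    converged = bool(best.success or grad_norm < 1e-3)

    vcov = np.full((spec.n_par, spec.n_par), np.nan)
    if compute_vcov:
        H = _numeric_hessian(_negloglik_and_grad, theta, (spec, d, Yt))
        try:
            vcov = np.linalg.inv(H)
        except np.linalg.LinAlgError:
            vcov = np.linalg.pinv(H)
            warnings.warn("observed information singular; using pseudo-inverse")
        if np.diag(vcov).min() < 0:
            warnings.warn("negative variance in vcov; SEs flagged as unreliable")
    theta, vcov = _canonicalize(spec, theta, vcov)

    fitres = FitResult(
        spec=spec,
        theta=theta,
        vcov=vcov,
        loglik=-best.fun,
        n_ind=n,
        converged=converged,
        message=str(best.message),
        n_iter=int(best.nit),
        grad_norm=grad_norm,
    )
    SV = fitres.sigma_V
    with np.errstate(divide="ignore", invalid="ignore"):
        std_sq = (fitres.lambda_A / np.sqrt(np.diag(SV))[:, None]) ** 2
    fitres.heywood = bool(np.nansum(std_sq, axis=1).max() > 1.0 + 1e-6)
    if not converged:
        raise RuntimeError(
            f"model did not converge (|grad|={grad_norm:.2e}): {best.message}"
        )
    return fitres


# ---------------------------------------------------------------------------
# Standardized solution


@dataclass
class StandardizedSolution:
    """Standardized loadings and derived genetic summaries with SEs."""

    lambda_A: np.ndarray
    lambda_A_se: np.ndarray
    lambda_E: np.ndarray
    lambda_E_se: np.ndarray
    h2: np.ndarray
    h2_se: np.ndarray
    rg: np.ndarray
    rg_se: np.ndarray
    f2: np.ndarray
    f2_se: np.ndarray
    trait_names: list
    genetic_factor_names: list


def _std_quantities(spec: ModelSpec, theta: np.ndarray) -> np.ndarray:
    """Vectorized standardized solution as one flat vector of smooth
    functions of θ (for delta-method SEs)."""
    LA, LE = spec.lambdas(theta)
    SA = LA @ LA.T
    SV = SA + LE @ LE.T
    sd = np.sqrt(np.diag(SV))
    lamA = LA / sd[:, None]
    lamE = LE / sd[:, None]
    h2 = np.diag(SA) / np.diag(SV)
    denom = np.sqrt(np.outer(np.diag(SA), np.diag(SA)))
    rg = SA / denom
    gvar = np.diag(SA)
    f2 = LA**2 / gvar[:, None]
    return np.concatenate([lamA.ravel(), lamE.ravel(), h2, rg.ravel(), f2.ravel()])


def standardize_solution(fit: FitResult) -> StandardizedSolution:
    """Standardized loadings, h²_SNP, genetic correlations r_g and
    factorial co-heritabilities f²_g, with delta-method SEs.

    Standardization divides each loading by the trait's model-implied
    phenotypic SD; r_g = σ_g12/√(σ²_g1 σ²_g2); f²_g is the share of a
    trait's genetic variance carried by one genetic factor.  SEs use a
    central-difference Jacobian of the standardized quantities against
    the fit's parameter covariance.
    """
    spec, theta = fit.spec, fit.theta
    SV = fit.sigma_V
    if np.diag(SV).min() <= 0:
        raise ValueError("a trait has zero implied total variance")
    vals = _std_quantities(spec, theta)

    p = theta.size
    J = np.zeros((vals.size, p))
    for j in range(p):
        h = 1e-6 * max(1.0, abs(theta[j]))
        tp, tm = theta.copy(), theta.copy()
        tp[j] += h
        tm[j] -= h
        J[:, j] = (_std_quantities(spec, tp) - _std_quantities(spec, tm)) / (2 * h)
    var = np.einsum("ij,jk,ik->i", J, fit.vcov, J)
    ses = np.sqrt(np.where(var > 0, var, np.nan))

    k, pa, pe = spec.k, spec.p_a, spec.p_e
    cuts = np.cumsum([k * pa, k * pe, k, k * k, k * pa])
    lamA, lamA_se = vals[: cuts[0]].reshape(k, pa), ses[: cuts[0]].reshape(k, pa)
    lamE = vals[cuts[0] : cuts[1]].reshape(k, pe)
    lamE_se = ses[cuts[0] : cuts[1]].reshape(k, pe)
    h2, h2_se = vals[cuts[1] : cuts[2]], ses[cuts[1] : cuts[2]]
    rg = vals[cuts[2] : cuts[3]].reshape(k, k)
    rg_se = ses[cuts[2] : cuts[3]].reshape(k, k)
    f2 = vals[cuts[3] : cuts[4]].reshape(k, pa)
    f2_se = ses[cuts[3] : cuts[4]].reshape(k, pa)
    return StandardizedSolution(
        lambda_A=lamA,
        lambda_A_se=lamA_se,
        lambda_E=lamE,
        lambda_E_se=lamE_se,
        h2=h2,
        h2_se=h2_se,
        rg=rg,
        rg_se=rg_se,
        f2=f2,
        f2_se=f2_se,
        trait_names=spec.trait_names,
        genetic_factor_names=spec.genetic_factor_names,
    )


def extend_with_mapping(spec: ModelSpec, mapping_name: str = "mapping") -> ModelSpec:
    """Add a mapping variable as trait k+1 to an IPC-style spec.

    The mapping row loads freely on every shared genetic factor, gets its
    own specific genetic factor, and extends the residual Cholesky by one
    row; the base structure (constraints included) is untouched.  Adds
    n_AC + 1 + (k+1) free parameters.
    """
    if spec.family not in ("ipc", "independent_pathway", "bifactor"):
        raise ValueError("mapping extension is defined for shared-factor models")
    k, n_ac = spec.k, spec.n_shared_genetic
    k2 = k + 1

    gf = np.zeros((k2, spec.p_a + 1), dtype=bool)
    gfix = np.zeros((k2, spec.p_a + 1))
    gf[:k, : spec.p_a] = spec.genetic_free
    gfix[:k, : spec.p_a] = spec.genetic_fixed
    gf[k, :n_ac] = True  # mapping row loads on every shared factor
    gf[k, spec.p_a] = True  # its own specific factor

    if spec.p_e == k and spec.residual_free[np.triu_indices(k, 1)].sum() == 0 and (
        spec.residual_free == _lower_pattern(k)
    ).all():
        rf = _lower_pattern(k2)
        rfix = np.zeros((k2, k2))
        rfix[:k, :k] = spec.residual_fixed
        rf[:k, :k] = spec.residual_free
    else:
        rf = np.zeros((k2, spec.p_e + 1), dtype=bool)
        rfix = np.zeros((k2, spec.p_e + 1))
        rf[:k, : spec.p_e] = spec.residual_free
        rfix[:k, : spec.p_e] = spec.residual_fixed
        rf[k, : spec.p_e] = True
        rf[k, spec.p_e] = True

    gstart = None
    if spec.genetic_start is not None:
        gstart = np.full(gf.shape, np.nan)
        gstart[:k, : spec.p_a] = spec.genetic_start
    return ModelSpec(
        family=spec.family,
        k=k2,
        genetic_free=gf,
        residual_free=rf,
        genetic_fixed=gfix,
        residual_fixed=rfix,
        genetic_start=gstart,
        n_shared_genetic=n_ac,
        trait_names=list(spec.trait_names) + [mapping_name],
        genetic_factor_names=list(spec.genetic_factor_names) + [f"AS_{mapping_name}"],
    )
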