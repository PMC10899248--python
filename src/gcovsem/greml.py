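"""Variance-component estimation with a GRM (GREML) and a power formula.

Univariate model: y ~ N(0, σ²_g G + σ²_e I) on Z-standardized scores, so
no fixed effects are estimated.  The GRM eigendecomposition diagonalises
the covariance, making the likelihood a cheap sum over eigenvalues; the
maximum is found by bounded quasi-Newton with components floored at 0.
The test of σ²_g = 0 uses the boundary mixture ½χ²₀ + ½χ²₁.

Bivariate model: two traits with genetic covariance σ_g12 and residual
covariance σ_e12; the genetic correlation is r_g = σ_g12/√(σ²_g1 σ²_g2)
with a delta-method SE.  Individuals phenotyped for only one trait are
kept via a dense full-information likelihood over observed entries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .grm import GRMatrix

__all__ = ["GremlResult", "fit_univariate", "fit_bivariate", "power_greml"]


@dataclass
class GremlResult:
    """Variance components and derived h²_SNP / r_g for one GREML fit."""

    sigma2_g: np.ndarray
    sigma2_e: np.ndarray
    sigma_g12: float = np.nan
    sigma_e12: float = np.nan
    h2: np.ndarray = None
    h2_se: np.ndarray = None
    rg: float = np.nan
    rg_se: float = np.nan
    loglik: float = np.nan
    loglik_null: float = np.nan
    lrt: float = np.nan
    lrt_p: float = np.nan
    n_ind: int = 0
    vcov: np.ndarray = None
    converged: bool = True
    notes: list = field(default_factory=list)


def _uni_negll(params, d, yt2):
    sg, se = params
    v = sg * d + se
    if (v <= 0).any():
        return 1e12
    return 0.5 * (np.log(v).sum() + (yt2 / v).sum() + d.size * np.log(2 * np.pi))


def fit_univariate(grm: GRMatrix, y, tol: float = 1e-6) -> GremlResult:
    """ML variance components for one trait; h²_SNP with SE and boundary LRT.

    ``y`` must be aligned with the GRM's samples; missing entries drop the
    individual (GRM subset accordingly).
    """
    y = np.asarray(y, dtype=float).ravel()
    if y.size != grm.n:
        raise ValueError("trait length must match GRM order")
    keep = ~np.isnan(y)
    if not keep.all():
        idx = np.nonzero(keep)[0]
        grm = GRMatrix(
            values=grm.values[np.ix_(idx, idx)],
            sample_ids=grm.sample_ids[idx],
            pair_counts=grm.pair_counts[np.ix_(idx, idx)],
        )
        y = y[idx]
    n = y.size
    if n < 100:
        warnings.warn(f"only {n} individuals; GREML estimates may be unstable")
    d, U = grm.eigen
    if np.allclose(grm.values, np.eye(n)):
        raise ValueError("G is the identity; σ²_g is not identifiable")
    yt2 = (U.T @ y) ** 2
    vp = y.var()

    best = None
    for h2_start in (0.1, 0.5, 0.9):
        res = optimize.minimize(
            _uni_negll,
            x0=np.array([h2_start * vp, (1 - h2_start) * vp]),
            args=(d, yt2),
            method="L-BFGS-B",
            bounds=[(0.0, None), (1e-12, None)],
            options={"ftol": tol * 1e-3, "gtol": 1e-8, "maxiter": 1000},
        )
        if best is None or res.fun < best.fun - 1e-10:
            best = res
    if not best.success and np.linalg.norm(best.jac, np.inf) > 1e-2:
        raise RuntimeError(f"GREML did not converge: {best.message}; x={best.x}")
    sg, se = best.x
    ll = -best.fun

    null = optimize.minimize_scalar(
        lambda s: _uni_negll((0.0, s), d, yt2), bounds=(1e-8, 10 * vp), method="bounded"
    )
    ll0 = -null.fun
    lrt = max(0.0, 2.0 * (ll - ll0))
    # boundary mixture ½χ²₀ + ½χ²₁
    lrt_p = 1.0 if lrt == 0 else 0.5 * stats.chi2.sf(lrt, 1)

    H = _hess_numeric(lambda p: _uni_negll(p, d, yt2), np.array([sg, se]))
    vcov = _safe_inv(H)
    vt = sg + se
    grad_h2 = np.array([se, -sg]) / vt**2
    h2_var = grad_h2 @ vcov @ grad_h2
    return GremlResult(
        sigma2_g=np.array([sg]),
        sigma2_e=np.array([se]),
        h2=np.array([sg / vt]),
        h2_se=np.array([np.sqrt(max(h2_var, 0.0))]),
        loglik=ll,
        loglik_null=ll0,
        lrt=lrt,
        lrt_p=lrt_p,
        n_ind=n,
        vcov=vcov,
        converged=True,
    )


def _hess_numeric(fun, x, rel=1e-4):
    p = x.size
    H = np.zeros((p, p))
    h = rel * np.maximum(np.abs(x), 1e-3)
    for i in range(p):
        for j in range(i, p):
            xpp = x.copy(); xpp[i] += h[i]; xpp[j] += h[j]
            xpm = x.copy(); xpm[i] += h[i]; xpm[j] -= h[j]
            xmp = x.copy(); xmp[i] -= h[i]; xmp[j] += h[j]
            xmm = x.copy(); xmm[i] -= h[i]; xmm[j] -= h[j]
            H[i, j] = H[j, i] = (fun(xpp) - fun(xpm) - fun(xmp) + fun(xmm)) / (
                4 * h[i] * h[j]
            )
    return H


def _safe_inv(H):
    try:
        return np.linalg.inv(H)
    except np.linalg.LinAlgError:
        return np.linalg.pinv(H)


# ---------------------------------------------------------------------------
# Bivariate


def _biv_theta_to_mats(theta):
    sg1, sg2, cg, se1, se2, ce = theta
    SG = np.array([[sg1, cg], [cg, sg2]])
    SE = np.array([[se1, ce], [ce, se2]])
    return SG, SE


def _biv_negll_rotated(theta, d, Yt):
    SG, SE = _biv_theta_to_mats(theta)
    n = d.size
    V = d[:, None, None] * SG[None] + SE[None]
    sign, logdet = np.linalg.slogdet(V)
    if (sign <= 0).any():
        return 1e12
    q = np.linalg.solve(V, Yt[:, :, None])[:, :, 0]
    quad = np.einsum("ij,ij->", Yt, q)
    return 0.5 * (logdet.sum() + quad + 2 * n * np.log(2 * np.pi))


def _biv_negll_dense(theta, G, Y):
    """Full-information likelihood over the observed entries of Y (n × 2)."""
    SG, SE = _biv_theta_to_mats(theta)
    obs_i, obs_t = np.nonzero(~np.isnan(Y))
    w = Y[obs_i, obs_t]
    V = G[np.ix_(obs_i, obs_i)] * SG[np.ix_(obs_t, obs_t)]
    V += (obs_i[:, None] == obs_i[None, :]) * SE[np.ix_(obs_t, obs_t)]
    sign, logdet = np.linalg.slogdet(V)
    if sign <= 0:
        return 1e12
    sol = np.linalg.solve(V, w)
    return 0.5 * (logdet + w @ sol + w.size * np.log(2 * np.pi))


def fit_bivariate(grm: GRMatrix, y1, y2, tol: float = 1e-6) -> GremlResult:
    """Joint ML for two traits' genetic/residual (co)variance components.

    Complete-overlap data use the fast eigenbasis likelihood; otherwise a
    dense full-information likelihood keeps individuals phenotyped for
    only one trait.  r_g is undefined (flagged) when either genetic
    variance estimate hits the zero boundary.
    """
    y1 = np.asarray(y1, dtype=float).ravel()
    y2 = np.asarray(y2, dtype=float).ravel()
    if y1.size != grm.n or y2.size != grm.n:
        raise ValueError("trait lengths must match GRM order")
    any_obs = ~(np.isnan(y1) & np.isnan(y2))
    if not any_obs.all():
        idx = np.nonzero(any_obs)[0]
        grm = GRMatrix(
            values=grm.values[np.ix_(idx, idx)],
            sample_ids=grm.sample_ids[idx],
            pair_counts=grm.pair_counts[np.ix_(idx, idx)],
        )
        y1, y2 = y1[idx], y2[idx]
    both = ~np.isnan(y1) & ~np.isnan(y2)
    if both.sum() < 100:
        warnings.warn(f"only {int(both.sum())} individuals observed for both traits")
    Y = np.column_stack([y1, y2])

    if both.all():
        d, U = grm.eigen
        Yt = U.T @ Y
        negll = lambda th: _biv_negll_rotated(th, d, Yt)
    else:
        negll = lambda th: _biv_negll_dense(th, grm.values, Y)

    v1 = np.nanvar(y1)
    v2 = np.nanvar(y2)
    c12 = np.nanmean((y1 - np.nanmean(y1)) * (y2 - np.nanmean(y2)))
    x0 = np.array([0.3 * v1, 0.3 * v2, 0.3 * c12, 0.7 * v1, 0.7 * v2, 0.7 * c12])
    bounds = [(0, None), (0, None), (None, None), (1e-8, None), (1e-8, None), (None, None)]
    res = optimize.minimize(
        negll, x0, method="L-BFGS-B", bounds=bounds,
        options={"ftol": 1e-12, "gtol": 1e-7, "maxiter": 2000},
    )
    if both.all():  # cheap evaluations: polish the optimum simplex-style
        refine = optimize.minimize(
            negll, res.x, method="Nelder-Mead",
            options={"xatol": 1e-7, "fatol": tol * 1e-3, "maxiter": 1500},
        )
        if refine.fun < res.fun:
            res = refine
    theta = res.x
    sg1, sg2, cg, se1, se2, ce = theta
    H = _hess_numeric(negll, theta)
    vcov = _safe_inv(H)

    out = GremlResult(
        sigma2_g=np.array([sg1, sg2]),
        sigma2_e=np.array([se1, se2]),
        sigma_g12=cg,
        sigma_e12=ce,
        loglik=-res.fun,
        n_ind=grm.n,
        vcov=vcov,
        converged=bool(res.success),
    )
    vt1, vt2 = sg1 + se1, sg2 + se2
    out.h2 = np.array([sg1 / vt1, sg2 / vt2])
    if min(sg1, sg2) <= 1e-8:
        out.notes.append("a genetic variance is at the zero boundary; r_g undefined")
        return out
    out.rg = cg / np.sqrt(sg1 * sg2)
    # delta method on (σ²_g1, σ²_g2, σ_g12)
    g = np.zeros(6)
    g[0] = -0.5 * cg / (sg1 ** 1.5 * np.sqrt(sg2))
    g[1] = -0.5 * cg / (sg2 ** 1.5 * np.sqrt(sg1))
    g[2] = 1.0 / np.sqrt(sg1 * sg2)
    out.rg_se = float(np.sqrt(max(g @ vcov @ g, 0.0)))
    return out


def power_greml(
    n: int,
    h2: float,
    var_offdiag: float = 2e-5,
    alpha: float = 0.05,
) -> float:
    """Power to detect h²_SNP with a univariate GREML model.

    Uses the standard sampling-variance approximation for a GRM of
    unrelated individuals, SE(ĥ²) = √(2 / (n² · var_offdiag)), a
    non-centrality of (h²/SE)², and a 1-df χ² test at level ``alpha``.
    The default off-diagonal GRM variance 2×10⁻⁵ is typical of
    genotyping-chip GRMs in homogeneous samples.
    """
    if n < 2:
        raise ValueError("n must be at least 2")
    if not 0.0 <= h2 <= 1.0:
        raise ValueError("h2 must lie in [0, 1]")
    if var_offdiag <= 0:
        raise ValueError("var_offdiag must be positive")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    se = np.sqrt(2.0 / (n**2 * var_offdiag))
    ncp = (h2 / se) ** 2
    crit = stats.chi2.isf(alpha, 1)
    return float(stats.ncx2.sf(crit, 1, ncp)) if ncp > 0 else float(alpha)
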