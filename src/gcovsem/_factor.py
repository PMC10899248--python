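"""Factor extraction and rotation primitives.

Weighted least-squares exploratory factor extraction on the unique
elements of a covariance matrix (the weights being element-wise sampling
variances, or unity for unweighted LS), varimax and quartimin-oblimin
rotation via gradient projection, and a small ML confirmatory factor
analysis with the usual absolute fit indices (CFI, TLI, RMSEA).
"""

from __future__ import annotations

import numpy as np
from scipy import optimize, stats

__all__ = [
    "wls_efa",
    "varimax",
    "oblimin",
    "cfa_ml",
    "congruence",
]


def _efa_df(k: int, q: int) -> int:
    """Residual degrees of freedom of a q-factor model for k variables."""
    return ((k - q) ** 2 - (k + q)) // 2


def wls_efa(S, n_factors, element_variances=None, seed=0, n_starts=3):
    """Least-squares factor extraction on unique covariance elements.

    Minimises ½ Σ_{i≥j} (s_ij − σ_ij)² / w_ij with σ = ΛΛᵀ + diag(ψ),
    where w is the element-wise sampling variance (``element_variances``)
    or 1 (unweighted).  Uniquenesses ψ are bounded below at −0.25·s_jj so
    mild Heywood cases (ψ < 0) stay representable and flaggable while
    under-identified doublet factors cannot collapse to ψ → −∞.

    Returns ``(loadings, uniquenesses, discrepancy)`` with the loadings in
    the unrotated (principal-axis-started) orientation.
    """
    S = np.asarray(S, dtype=float)
    k = S.shape[0]
    q = int(n_factors)
    if q < 1:
        raise ValueError("n_factors must be at least 1")
    if _efa_df(k, q) < 0:
        raise ValueError(f"{q} factors over-parameterise {k} variables (df < 0)")
    if not np.allclose(S, S.T, atol=1e-10):
        raise ValueError("covariance matrix must be symmetric")
    if element_variances is None:
        W = np.ones((k, k))
    else:
        W = np.asarray(element_variances, dtype=float)
        if (W[np.tril_indices(k)] <= 0).any():
            raise ValueError("element variances must be positive")
    il, jl = np.tril_indices(k)
    w = W[il, jl]
    s = S[il, jl]

    def objective(x):
        L = x[: k * q].reshape(k, q)
        psi = x[k * q :]
        Sigma = L @ L.T + np.diag(psi)
        r = Sigma[il, jl] - s
        return 0.5 * np.sum(r**2 / w)

    # principal-axis start from the spectral decomposition
    evals, evecs = np.linalg.eigh(S)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    L0 = evecs[:, :q] * np.sqrt(np.maximum(evals[:q], 1e-4))
    psi0 = np.maximum(np.diag(S) - (L0**2).sum(axis=1), 1e-3)
    best = None
    rng = np.random.default_rng(seed)
    for attempt in range(n_starts):
        if attempt == 0:
            x0 = np.concatenate([L0.ravel(), psi0])
        else:
            x0 = np.concatenate(
                [L0.ravel() + rng.normal(0, 0.05, k * q), psi0]
            )
        bounds = [(None, None)] * (k * q) + [
            (-0.25 * S[j, j], None) for j in range(k)
        ]
        res = optimize.minimize(
            objective, x0, method="L-BFGS-B", bounds=bounds,
            options={"maxiter": 5000, "ftol": 1e-14, "gtol": 1e-10},
        )
        if best is None or res.fun < best.fun - 1e-12:
            best = res
    L = best.x[: k * q].reshape(k, q)
    psi = best.x[k * q :]
    # canonical orientation: principal axes of ΛΛᵀ, first loading positive
    if q > 1:
        u, sv, vt = np.linalg.svd(L, full_matrices=False)
        L = u * sv
    for j in range(q):
        lead = np.argmax(np.abs(L[:, j]))
        if L[lead, j] < 0:
            L[:, j] *= -1
    return L, psi, float(best.fun)


def varimax(L, max_iter=200, tol=1e-10):
    """Orthogonal varimax rotation; returns (rotated loadings, rotation)."""
    L = np.asarray(L, dtype=float)
    k, q = L.shape
    if q < 2:
        return L.copy(), np.eye(q)
    R = np.eye(q)
    var_old = 0.0
    for _ in range(max_iter):
        Lr = L @ R
        B = L.T @ (Lr**3 - Lr * (Lr**2).sum(axis=0) / k)
        u, s, vt = np.linalg.svd(B)
        R = u @ vt
        var_new = s.sum()
        if var_new - var_old < tol:
            break
        var_old = var_new
    Lr = L @ R
    for j in range(q):
        lead = np.argmax(np.abs(Lr[:, j]))
        if Lr[lead, j] < 0:
            Lr[:, j] *= -1
            R[:, j] *= -1
    return Lr, R


def _quartimin(L):
    """Quartimin criterion and gradient (the oblimin family at γ = 0)."""
    L2 = L**2
    N = 1.0 - np.eye(L.shape[1])
    f = np.sum(L2 * (L2 @ N)) / 4.0
    G = L * (L2 @ N)
    return f, G


def oblimin(L, max_iter=500, tol=1e-8):
    """Oblique quartimin rotation by gradient projection.

    Returns ``(pattern loadings, factor correlation matrix)``.  The
    algorithm iterates on the rotation matrix T with unit-norm columns
    (Bernaards–Jennrich gradient projection), so factors may correlate;
    Φ = TᵀT.
    """
    A = np.asarray(L, dtype=float)
    k, q = A.shape
    if q < 2:
        return A.copy(), np.eye(q)
    T = np.eye(q)
    Ti = np.linalg.inv(T)
    Lr = A @ Ti.T
    f, Gq = _quartimin(Lr)
    G = -(Lr.T @ Gq @ Ti).T
    al = 1.0
    for _ in range(max_iter):
        Gp = G - T @ np.diag((T * G).sum(axis=0))
        s = np.linalg.norm(Gp)
        if s < tol:
            break
        al *= 2.0
        for _ in range(30):
            X = T - al * Gp
            X = X / np.sqrt((X**2).sum(axis=0))
            Ti = np.linalg.inv(X)
            Lt = A @ Ti.T
            ft, Gq = _quartimin(Lt)
            if ft < f - 0.5 * s**2 * al:
                break
            al /= 2.0
        T, f, Lr = X, ft, Lt
        G = -(Lr.T @ Gq @ np.linalg.inv(T)).T
    Phi = T.T @ T
    for j in range(q):
        lead = np.argmax(np.abs(Lr[:, j]))
        if Lr[lead, j] < 0:
            Lr[:, j] *= -1
            Phi[j, :] *= -1
            Phi[:, j] *= -1
    return Lr, Phi


def congruence(L1, L2):
    """Tucker congruence per factor after greedy column matching; returns
    the matched coefficients (absolute values)."""
    L1 = np.asarray(L1, float)
    L2 = np.asarray(L2, float)
    q = L1.shape[1]
    C = np.zeros((q, q))
    for a in range(q):
        for b in range(q):
            denom = np.sqrt((L1[:, a] ** 2).sum() * (L2[:, b] ** 2).sum())
            C[a, b] = np.abs(L1[:, a] @ L2[:, b]) / denom if denom > 0 else 0.0
    out = []
    used = set()
    for a in range(q):
        b = max((b for b in range(q) if b not in used), key=lambda b: C[a, b])
        used.add(b)
        out.append(C[a, b])
    return np.array(out)


def cfa_ml(S, n_obs, pattern, orthogonal=True):
    """ML confirmatory factor analysis on a covariance/correlation matrix.

    ``pattern`` is a k × q boolean mask of free loadings; uniquenesses are
    free; factor covariances are identity when ``orthogonal`` (free
    correlations otherwise, variances fixed to 1).  Returns a dict with
    loadings, uniquenesses, chi2/df/p and CFI, TLI, RMSEA.
    """
    S = np.asarray(S, dtype=float)
    k = S.shape[0]
    pattern = np.asarray(pattern, dtype=bool)
    q = pattern.shape[1]
    nL = int(pattern.sum())
    n_corr = 0 if orthogonal else q * (q - 1) // 2
    n_free = nL + k + n_corr
    df = k * (k + 1) // 2 - n_free
    if df < 0:
        raise ValueError("CFA model has negative degrees of freedom")
    sign_s, logdet_s = np.linalg.slogdet(S)
    if sign_s <= 0:
        raise ValueError("sample matrix must be positive definite")
    iu = np.triu_indices(q, 1)

    def unpack(x):
        L = np.zeros((k, q))
        L[pattern] = x[:nL]
        psi = x[nL : nL + k]
        Phi = np.eye(q)
        if not orthogonal:
            Phi[iu] = x[nL + k :]
            Phi[(iu[1], iu[0])] = x[nL + k :]
        return L, psi, Phi

    def fml(x):
        L, psi, Phi = unpack(x)
        Sigma = L @ Phi @ L.T + np.diag(np.maximum(psi, 1e-8))
        sign, logdet = np.linalg.slogdet(Sigma)
        if sign <= 0:
            return 1e10
        return logdet - logdet_s + np.trace(np.linalg.solve(Sigma, S)) - k

    x0 = np.concatenate(
        [np.full(nL, 0.5), np.full(k, 0.5), np.zeros(n_corr)]
    )
    res = optimize.minimize(
        fml, x0, method="L-BFGS-B", options={"maxiter": 5000, "ftol": 1e-14}
    )
    L, psi, Phi = unpack(res.x)
    F = max(res.fun, 0.0)
    chi2 = (n_obs - 1) * F
    p = stats.chi2.sf(chi2, df) if df > 0 else np.nan

    # independence baseline
    Rcorr = S / np.sqrt(np.outer(np.diag(S), np.diag(S)))
    F_b = -np.linalg.slogdet(Rcorr)[1]
    chi2_b = (n_obs - 1) * F_b
    df_b = k * (k - 1) // 2
    num = max(chi2 - df, 0.0)
    den = max(chi2_b - df_b, num, 1e-12)
    cfi = 1.0 - num / den
    tli = (
        ((chi2_b / df_b) - (chi2 / df)) / ((chi2_b / df_b) - 1.0)
        if df > 0 and chi2_b > df_b
        else 1.0
    )
    rmsea = np.sqrt(max(chi2 - df, 0.0) / (df * (n_obs - 1))) if df > 0 else 0.0
    return {
        "loadings": L,
        "uniquenesses": psi,
        "factor_corr": Phi,
        "chi2": chi2,
        "df": df,
        "p": p,
        "cfi": cfi,
        "tli": min(tli, 1.0),
        "rmsea": rmsea,
        "converged": bool(res.success),
    }
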