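"""Maximum-likelihood machinery for one-factor covariance structures.

Two likelihood forms are implemented:

* a constant-covariance discrepancy fit,
  F(theta) = log|Sigma| + tr(S Sigma^-1) - log|S| - p,
  for fits summarised by a sample covariance S (complete data); and

* a per-subject log-likelihood for age-moderated structures,
  Sigma_i = D_i + c_i c_i', with c_i[t] = l1[t](1 + l1m[t] a_i) and
  D_i[t] = (l2[t](1 + l2m[t] a_i))^2, evaluated with rank-one
  (Sherman-Morrison) updates in O(n p) per evaluation, supporting
  missing entries (full-information) via an observation mask.

Analytic gradients are provided for both forms; standard errors come from a
finite-difference Hessian of the analytic gradient.
"""

from __future__ import annotations

from typing import Optional, Sequence, Tuple

import numpy as np
from scipy import optimize

__all__ = [
    "HeywoodError",
    "ConvergenceError",
    "factor_sigma",
    "discrepancy",
    "fit_factor_cov",
    "mnlfa_nll",
    "fit_mnlfa",
    "numeric_hessian",
]

_LOG2PI = float(np.log(2.0 * np.pi))


class HeywoodError(RuntimeError):
    """A unique variance collapsed to (near) zero during estimation."""


class ConvergenceError(RuntimeError):
    """The optimizer failed to reach the required gradient tolerance."""


# ------------------------------------------------------- constant-Sigma fit

def factor_sigma(
    lam: np.ndarray, uni: np.ndarray, pairs: Sequence[Tuple[int, int]] = (), rho: Optional[np.ndarray] = None
) -> np.ndarray:
    """Sigma = lam lam' + diag(uni^2) + symmetric pair covariances."""
    sig = np.outer(lam, lam) + np.diag(uni**2)
    if rho is not None:
        for (j, k), r in zip(pairs, rho):
            sig[j, k] += r
            sig[k, j] += r
    return sig


def discrepancy(S: np.ndarray, sigma: np.ndarray) -> float:
    """ML discrepancy F = log|Sigma| + tr(S Sigma^-1) - log|S| - p."""
    p = S.shape[0]
    sign, logdet = np.linalg.slogdet(sigma)
    if sign <= 0:
        return np.inf
    _, logdet_s = np.linalg.slogdet(S)
    return float(logdet + np.trace(np.linalg.solve(sigma, S)) - logdet_s - p)


def _unpack_cov(theta: np.ndarray, p: int, k: int):
    lam = theta[:p]
    uni = theta[p : 2 * p]
    rho = theta[2 * p : 2 * p + k]
    return lam, uni, rho


def _cov_obj_grad(theta, S, p, pairs):
    lam, uni, rho = _unpack_cov(theta, p, len(pairs))
    sig = factor_sigma(lam, uni, pairs, rho)
    try:
        ch = np.linalg.cholesky(sig)
    except np.linalg.LinAlgError:
        # non-PD trial point: large finite value lets the line search backtrack
        return 1e12, np.zeros_like(theta)
    inv = np.linalg.inv(sig)
    logdet = 2.0 * float(np.sum(np.log(np.diag(ch))))
    f = logdet + float(np.sum(inv * S))
    G = inv - inv @ S @ inv
    g_lam = 2.0 * G @ lam
    g_uni = 2.0 * np.diag(G) * uni
    g_rho = np.array([2.0 * G[j, k] for j, k in pairs])
    return f, np.concatenate([g_lam, g_uni, g_rho])


def _start_values(S: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    d = np.sqrt(np.clip(np.diag(S), 1e-12, None))
    R = S / np.outer(d, d)
    ev, evec = np.linalg.eigh(R)
    lam_std = evec[:, -1] * np.sqrt(max(ev[-1] - 1.0 + ev[-1] / len(ev), 0.1))
    lam_std = np.clip(lam_std, -0.95, 0.95)
    if lam_std.sum() < 0:
        lam_std = -lam_std
    lam = lam_std * d
    uni = np.sqrt(np.clip(np.diag(S) - lam**2, 0.05 * np.diag(S), None))
    return lam, uni


def fit_factor_cov(
    S: np.ndarray,
    n: float,
    pairs: Sequence[Tuple[int, int]] = (),
    start: Optional[np.ndarray] = None,
    gtol: float = 1e-7,
    maxiter: int = 2000,
    entry_names: Optional[Sequence[str]] = None,
) -> dict:
    """Fit Sigma = lam lam' + diag(uni^2) (+ pair covariances) to S by ML.

    Returns a dict with loadings, unique SDs, pair covariances, the minimised
    discrepancy ``fmin``, the chi-square ``n * fmin`` and the parameter
    vector/Hessian callable for standard errors.
    """
    S = np.asarray(S, dtype=float)
    p = S.shape[0]
    if start is None:
        lam0, uni0 = _start_values(S)
        theta0 = np.concatenate([lam0, uni0, np.zeros(len(pairs))])
    else:
        theta0 = np.asarray(start, dtype=float)
    res = optimize.minimize(
        _cov_obj_grad,
        theta0,
        args=(S, p, list(pairs)),
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": maxiter, "gtol": gtol, "ftol": 1e-13},
    )
    lam, uni, rho = _unpack_cov(res.x, p, len(pairs))
    lam = lam.copy()
    uni = np.abs(uni)
    if lam.sum() < 0:
        lam = -lam
    floor = 1e-4 * np.sqrt(np.clip(np.diag(S), 1e-12, None))
    if np.any(uni < floor):
        idx = int(np.argmin(uni - floor))
        name = entry_names[idx] if entry_names is not None else str(idx)
        raise HeywoodError(f"unique variance collapsed for tract entry {name!r}")
    # res.fun is logdet Sigma + tr(S Sigma^-1); subtract the saturated value
    _, logdet_s = np.linalg.slogdet(S)
    fmin = float(res.fun - logdet_s - p)
    grad_norm = float(np.max(np.abs(res.jac)))
    return {
        "loadings": lam,
        "unique_sd": uni,
        "pair_cov": rho,
        "pairs": list(pairs),
        "fmin": fmin,
        "chisq": float(n * fmin),
        "theta": np.concatenate([lam, uni, rho]),
        "grad_norm": grad_norm,
        "converged": bool(res.success or grad_norm < 1e-3),
        "n_iter": int(res.nit),
    }


# --------------------------------------------------- moderated per-subject

def _expand(x: np.ndarray, p: int) -> np.ndarray:
    x = np.atleast_1d(np.asarray(x, dtype=float))
    return np.full(p, x[0]) if x.size == 1 else x


def mnlfa_nll(
    lam: np.ndarray,
    uni: np.ndarray,
    l1m,
    l2m,
    E: np.ndarray,
    age_c: np.ndarray,
    mask: Optional[np.ndarray] = None,
    grad_mode: Optional[str] = None,
):
    """Negative log-likelihood (and optionally gradient) of centred residuals
    ``E`` (n x p) under the age-moderated one-factor covariance.

    ``age_c`` is centred age (any linear unit; the moderation slopes are per
    that unit).  ``mask`` marks observed entries (missing = 0) and implements
    full-information evaluation.  ``grad_mode`` in {None, "invariant",
    "tract_specific"} selects whether/which gradient is returned.
    """
    n, p = E.shape
    l1m = _expand(l1m, p)
    l2m = _expand(l2m, p)
    a = age_c[:, None]
    m1 = 1.0 + a * l1m[None, :]
    m2 = 1.0 + a * l2m[None, :]
    if np.any(m2 <= 1e-10):
        bad = np.argwhere(m2 <= 1e-10)[0]
        if grad_mode is None:
            return np.inf
        return np.inf, None
    c = lam[None, :] * m1
    s = uni[None, :] * m2
    d = s**2
    if mask is None:
        M = None
        E0 = E
        pi = np.full(n, float(p))
    else:
        M = mask.astype(float)
        E0 = np.where(mask, E, 0.0)
        pi = M.sum(axis=1)
    cd = c / d
    if M is not None:
        cd = cd * M
    u = np.sum(cd * c, axis=1)
    denom = 1.0 + u
    v = np.sum(cd * E0, axis=1)
    Ed = E0 / d
    w = np.sum(E0 * Ed, axis=1)
    q = w - v**2 / denom
    if M is None:
        logdet = np.sum(np.log(d), axis=1) + np.log(denom)
    else:
        logdet = np.sum(M * np.log(d), axis=1) + np.log(denom)
    nll = 0.5 * float(np.sum(pi * _LOG2PI) + np.sum(logdet) + np.sum(q))
    if grad_mode is None:
        return nll

    k = (v / denom)[:, None]
    f = Ed - cd * k  # Sigma^-1 e (observed coords)
    h = cd / denom[:, None]  # Sigma^-1 c
    sinv_tt = 1.0 / d - (c / d) ** 2 / denom[:, None]  # diag of Sigma^-1
    if M is not None:
        f = f * M
        h = h * M
        sinv_tt = sinv_tt * M
    g_lam = (m1 * (h - f * k)).sum(axis=0)
    g_uni = ((s * m2) * (sinv_tt - f**2)).sum(axis=0)  # d sigma/d l2 = 2 l2 m2^2
    # moderation gradients
    gl1 = (a * lam[None, :]) * (h - f * k)
    gl2 = (a * uni[None, :] * s) * (sinv_tt - f**2)  # a * lam2^2 * m2 * (...)
    if grad_mode == "invariant":
        g_l1m = np.array([gl1.sum()])
        g_l2m = np.array([gl2.sum()])
    else:
        g_l1m = gl1.sum(axis=0)
        g_l2m = gl2.sum(axis=0)
    return nll, np.concatenate([g_lam, g_uni, g_l1m, g_l2m])


def mnlfa_nll_pairs(
    lam, uni, l1m, l2m, rho, pairs, E, age_c, mask=None
) -> float:
    """Per-subject NLL with fixed residual pair covariances.

    Sigma_i = D_i + c_i c_i' + R with R of rank <= 2k for k pairs; evaluated
    with the Woodbury identity in O(n (p m + m^3)) for m = 1 + 2k.  Missing
    rows are handled listwise on this path.
    """
    n, p = E.shape
    l1m = _expand(l1m, p)
    l2m = _expand(l2m, p)
    if mask is not None:
        keep = mask.all(axis=1)
        E = E[keep]
        age_c = age_c[keep]
        n = E.shape[0]
    a = age_c[:, None]
    m2 = 1.0 + a * l2m[None, :]
    if np.any(m2 <= 1e-10):
        return np.inf
    c = lam[None, :] * (1.0 + a * l1m[None, :])  # (n, p)
    d = (uni[None, :] * m2) ** 2                 # (n, p)

    k = len(pairs)
    m = 1 + 2 * k
    # R = U W U' where U's columns are tract indicators (columns 2i, 2i+1
    # point at the i-th pair) and W_i = [[0, r_i], [r_i, 0]];
    # Lambda = blockdiag([1], W_1, ..., W_k)
    cols = np.array([t for pr in pairs for t in pr])  # tract index per U column
    lam_inv = np.zeros((m, m))
    lam_inv[0, 0] = 1.0
    logdet_lambda = 0.0
    sign_lambda = 1.0
    for i, r in enumerate(rho):
        # W^-1 = [[0, 1/r], [1/r, 0]], det W = -r^2
        lam_inv[1 + 2 * i, 2 + 2 * i] = 1.0 / r
        lam_inv[2 + 2 * i, 1 + 2 * i] = 1.0 / r
        logdet_lambda += np.log(r * r)
        sign_lambda *= -1.0
    # V_i = [c_i, U]; A_i = Lambda^{-1} + V' D^{-1} V, built by indexing
    # since U'x just picks the paired tracts' entries
    cd = c / d                                    # (n, p)
    A = np.empty((n, m, m))
    A[:, 0, 0] = 1.0 + np.sum(cd * c, axis=1)
    cU = cd[:, cols]                              # c' D^-1 U
    A[:, 0, 1:] = cU
    A[:, 1:, 0] = cU
    UdU = np.zeros((n, 2 * k, 2 * k))
    same = cols[:, None] == cols[None, :]
    jj, ll = np.nonzero(same)
    UdU[:, jj, ll] = 1.0 / d[:, cols[jj]]
    A[:, 1:, 1:] = lam_inv[None, 1:, 1:] + UdU
    sign_a, logdet_a = np.linalg.slogdet(A)
    if np.any(sign_a * sign_lambda <= 0):
        return np.inf
    # quadratic form via Woodbury
    ed = E / d
    b = np.empty((n, m))
    b[:, 0] = np.sum(cd * E, axis=1)              # c' D^-1 e
    b[:, 1:] = ed[:, cols]                        # U' D^-1 e
    try:
        sol = np.linalg.solve(A, b[:, :, None])[:, :, 0]
    except np.linalg.LinAlgError:
        return np.inf
    q = np.sum(E * ed, axis=1) - np.sum(b * sol, axis=1)
    if np.any(q < -1e-9):  # e' Sigma^-1 e must be non-negative when Sigma is PD
        return np.inf
    q = np.clip(q, 0.0, None)
    logdet = np.sum(np.log(d), axis=1) + logdet_lambda + logdet_a
    return 0.5 * float(n * p * _LOG2PI + np.sum(logdet) + np.sum(q))


def fit_mnlfa(
    E: np.ndarray,
    age_c: np.ndarray,
    mode: str = "invariant",
    start_lam: Optional[np.ndarray] = None,
    start_uni: Optional[np.ndarray] = None,
    pairs: Sequence[Tuple[int, int]] = (),
    rho: Optional[np.ndarray] = None,
    mask: Optional[np.ndarray] = None,
    fix_moderation: bool = False,
    gtol: float = 1e-7,
    maxiter: int = 3000,
    n_restarts: int = 0,
    seed: int = 0,
    entry_names: Optional[Sequence[str]] = None,
) -> dict:
    """Maximise the per-subject likelihood over loadings, unique SDs and
    (unless ``fix_moderation``) the moderation slopes.

    ``mode``: "invariant" (two scalar slopes) or "tract_specific" (2p
    slopes).  Residual pair covariances, if given, are held fixed at ``rho``
    (the likelihood then uses the batched-Cholesky path with numerical
    gradients).  Returns parameter estimates, the maximised log-likelihood
    and a callable objective for Hessian-based standard errors.
    """
    n, p = E.shape
    if start_lam is None or start_uni is None:
        S = np.cov(E, rowvar=False, bias=True) if mask is None else np.ma.cov(
            np.ma.masked_invalid(np.where(mask, E, np.nan)), rowvar=False, bias=True
        ).data
        lam0, uni0 = _start_values(S)
        start_lam = lam0 if start_lam is None else start_lam
        start_uni = uni0 if start_uni is None else start_uni
    nm = 1 if mode == "invariant" else p
    use_pairs = len(pairs) > 0 and rho is not None and np.any(np.asarray(rho) != 0)

    def split(theta):
        lam = theta[:p]
        uni = theta[p : 2 * p]
        if fix_moderation:
            l1m = np.zeros(nm)
            l2m = np.zeros(nm)
        else:
            l1m = theta[2 * p : 2 * p + nm]
            l2m = theta[2 * p + nm : 2 * p + 2 * nm]
        return lam, uni, l1m, l2m

    # infeasible points (a unique SD crossing zero inside the age range) get
    # a large finite value so the line search can backtrack
    _BIG = 1e12

    if use_pairs:
        def obj(theta):
            lam, uni, l1m, l2m = split(theta)
            val = mnlfa_nll_pairs(lam, uni, l1m, l2m, rho, pairs, E, age_c, mask)
            return val if np.isfinite(val) else _BIG
        jac = None
    else:
        def obj(theta):
            lam, uni, l1m, l2m = split(theta)
            val, g = mnlfa_nll(lam, uni, l1m, l2m, E, age_c, mask, grad_mode=mode)
            if not np.isfinite(val):
                return _BIG, np.zeros_like(theta)
            if fix_moderation:
                g = g[: 2 * p]
            return val, g
        jac = True

    theta0 = np.concatenate([start_lam, start_uni] + ([] if fix_moderation else [np.zeros(2 * nm)]))
    starts = [theta0]
    rng = np.random.default_rng(seed)
    for _ in range(n_restarts):
        pert = theta0.copy()
        pert[: 2 * p] *= 1.0 + 0.1 * rng.standard_normal(2 * p)
        starts.append(pert)

    best = None
    for th0 in starts:
        res = optimize.minimize(
            obj,
            th0,
            jac=True if jac else None,
            method="L-BFGS-B",
            options={"maxiter": maxiter, "gtol": gtol, "ftol": 1e-13},
        )
        if best is None or res.fun < best.fun:
            best = res
    assert best is not None
    lam, uni, l1m, l2m = split(best.x)
    lam = lam.copy()
    uni = np.abs(uni)
    if lam.sum() < 0:
        lam = -lam
    floor = 1e-4
    if np.any(uni < floor):
        idx = int(np.argmin(uni))
        name = entry_names[idx] if entry_names is not None else str(idx)
        raise HeywoodError(f"unique variance collapsed for tract entry {name!r}")
    grad_norm = float(np.max(np.abs(np.atleast_1d(best.jac)))) if best.jac is not None else np.nan
    converged = bool(best.success or (np.isfinite(grad_norm) and grad_norm < 1e-2 * max(1.0, n / 100)))
    if not converged:
        raise ConvergenceError(
            f"moderated factor fit did not converge: best nll={best.fun:.6g}, "
            f"max|grad|={grad_norm:.3g}"
        )
    theta_hat = np.concatenate([lam, uni, l1m, l2m]) if not fix_moderation else np.concatenate([lam, uni])

    def nll_at(theta):
        lam_, uni_, l1m_, l2m_ = split(theta)
        if use_pairs:
            return mnlfa_nll_pairs(lam_, uni_, l1m_, l2m_, rho, pairs, E, age_c, mask)
        return mnlfa_nll(lam_, uni_, l1m_, l2m_, E, age_c, mask)

    def grad_at(theta):
        if use_pairs or fix_moderation:
            return optimize.approx_fprime(theta, nll_at, 1e-6)
        lam_, uni_, l1m_, l2m_ = split(theta)
        _, g = mnlfa_nll(lam_, uni_, l1m_, l2m_, E, age_c, mask, grad_mode=mode)
        return g

    return {
        "loadings": lam,
        "unique_sd": uni,
        "loading_moderation": l1m,
        "unique_moderation": l2m,
        "loglik": -float(best.fun),
        "theta": theta_hat,
        "nll": nll_at,
        "grad": grad_at,
        "grad_norm": grad_norm,
        "converged": converged,
        "n_iter": int(best.nit),
        "mode": mode,
    }


def numeric_hessian(grad, theta: np.ndarray, step: float = 1e-5) -> np.ndarray:
    """Central finite-difference Hessian from a gradient callable."""
    k = theta.size
    H = np.zeros((k, k))
    for j in range(k):
        h = step * max(1.0, abs(theta[j]))
        tp = theta.copy(); tp[j] += h
        tm = theta.copy(); tm[j] -= h
        H[:, j] = (grad(tp) - grad(tm)) / (2 * h)
    return 0.5 * (H + H.T)
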