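"""One-factor confirmatory models of tract covariance, and derived analyses.

Each diffusion measure is modelled with a single general factor over the 22
core tract entries, each entry adjusted for age, sex and (for all measures
except FA) age^2.  The factor's variance conditional on the covariates is
fixed at 1 for identification; loadings, unique SDs and optional residual
covariances between specific entry pairs are free.  Estimation profiles the
mean structure (per-entry least squares, which is exact ML here because all
indicators share the same design) and maximises the multivariate-normal
likelihood over the covariance structure.

Also provided: eigen-spectra of the tract correlation matrix, pruning of
weak loadings, greedy residual-covariance augmentation by modification
(score) statistics, regression factor scores, common / independent /
common+independent pathway models for the age effect, and the
thalamic-radiation principal component.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import optimize, stats
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from ._covstruct import (
    discrepancy,
    factor_sigma,
    fit_factor_cov,
    fit_mnlfa,
    numeric_hessian,
    _cov_obj_grad,
)
from .table import TractMetricTable
from .tracts import core_tract_entries

__all__ = [
    "OneFactorModel",
    "EigenSpectrum",
    "PathwayComparison",
    "eigen_spectrum",
    "fit_one_factor",
    "prune_low_loadings",
    "add_residual_covariances",
    "factor_scores",
    "fit_pathway_models",
    "fit_gtr",
    "build_design",
]

THALAMIC_ENTRIES = ["ATR_L", "ATR_R", "STR_L", "STR_R", "PTR_L", "PTR_R"]


def build_design(
    covariates: pd.DataFrame, include_age2: bool, age_center: Optional[float] = None,
    age_scale: Optional[float] = None,
) -> Tuple[pd.DataFrame, float, float]:
    """Design matrix [1, age_z, (age_z^2), sex] from a covariate table.

    Age is standardized by the sample mean/SD unless a fixed center/scale is
    given; sex stays 0/1.
    """
    age = covariates["age"].astype(float)
    c = float(age.mean()) if age_center is None else age_center
    s = float(age.std(ddof=0)) if age_scale is None else age_scale
    az = (age - c) / s
    cols = {"const": 1.0, "age_z": az, "sex": covariates["sex"].astype(float)}
    if include_age2:
        cols["age_z2"] = az**2
    X = pd.DataFrame(cols, index=covariates.index)
    order = ["const", "age_z"] + (["age_z2"] if include_age2 else []) + ["sex"]
    return X[order], c, s


class OneFactorModel(BaseEstimator):
    """One general factor over tract entries with exogenous covariates.

    Parameters
    ----------
    covariate_cols : columns of the fitted frame treated as exogenous
        regressors on every indicator (an intercept is always added).
    residual_pairs : entry-label pairs given a free residual covariance.
    missing : "fiml" (full-information, per-subject likelihood over observed
        entries) or "listwise".
    score_method : "regression" or "bartlett" factor-score estimator.

    Fitted attributes (per scikit-learn convention) include ``loadings_``,
    ``unique_sd_``, ``std_loadings_``, ``covariate_paths_``, ``pair_cov_``,
    ``loglik_``, ``aic_``, ``bic_``, ``chisq_``, ``df_`` and
    ``loadings_se_``.
    """

    def __init__(
        self,
        covariate_cols: Sequence[str] = ("age_z", "sex"),
        residual_pairs: Sequence[Tuple[str, str]] = (),
        missing: str = "fiml",
        score_method: str = "regression",
        compute_se: bool = True,
    ):
        self.covariate_cols = covariate_cols
        self.residual_pairs = residual_pairs
        self.missing = missing
        self.score_method = score_method
        self.compute_se = compute_se

    # -------------------------------------------------------------- fitting
    def fit(self, X: pd.DataFrame, y=None) -> "OneFactorModel":
        cov_cols = list(self.covariate_cols)
        entries = [c for c in X.columns if c not in cov_cols]
        if len(entries) < 3:
            raise ValueError("need at least 3 indicator columns")
        Y = X[entries].to_numpy(dtype=float)
        C = X[cov_cols].to_numpy(dtype=float) if cov_cols else np.empty((len(X), 0))
        D = np.column_stack([np.ones(len(X)), C])
        n, p = Y.shape
        n_mean_params = D.shape[1] * p
        k_cov = 2 * p + len(self.residual_pairs)
        if n < 10 * (k_cov + D.shape[1]):
            warnings.warn(
                f"n={n} is small for {k_cov + D.shape[1]} parameters per indicator block",
                stacklevel=2,
            )
        pairs_idx = [(entries.index(a), entries.index(b)) for a, b in self.residual_pairs]

        obs = np.isfinite(Y)
        complete = bool(obs.all())
        if not complete and self.missing == "listwise":
            keep = obs.all(axis=1)
            Y, D, obs = Y[keep], D[keep], obs[keep]
            n = len(Y)
            complete = True

        # mean structure: per-indicator least squares on available rows
        B = np.zeros((D.shape[1], p))
        E = np.zeros_like(Y)
        for j in range(p):
            m = obs[:, j]
            if m.sum() <= D.shape[1]:
                raise ValueError(f"too few observations for entry {entries[j]!r}")
            bj, *_ = np.linalg.lstsq(D[m], Y[m, j], rcond=None)
            B[:, j] = bj
            E[:, j] = np.where(m, Y[:, j] - D @ bj, 0.0)

        if complete:
            S = E.T @ E / n
            res = fit_factor_cov(S, n, pairs_idx, entry_names=entries)
            lam, uni, rho = res["loadings"], res["unique_sd"], res["pair_cov"]
            sig = factor_sigma(lam, uni, pairs_idx, rho)
            ll = -0.5 * n * (p * np.log(2 * np.pi) + np.linalg.slogdet(sig)[1]
                             + float(np.sum(np.linalg.inv(sig) * S)))
            self.chisq_ = res["chisq"]
            self.df_ = p * (p + 1) // 2 - k_cov
            self.S_ = S
            self._theta_cov = np.concatenate([lam, uni, rho])
            self.converged_ = res["converged"]
            self.grad_norm_ = res["grad_norm"]
        else:
            if pairs_idx:
                raise ValueError(
                    "full-information fitting with residual pairs is not supported; "
                    "use missing='listwise'"
                )
            res = fit_mnlfa(
                E, np.zeros(n), mode="invariant", mask=obs,
                fix_moderation=True, entry_names=entries,
            )
            lam, uni, rho = res["loadings"], res["unique_sd"], np.zeros(0)
            sig = factor_sigma(lam, uni)
            ll = res["loglik"]
            self.chisq_ = np.nan
            self.df_ = p * (p + 1) // 2 - k_cov
            self.S_ = None
            self._theta_cov = np.concatenate([lam, uni])
            self.converged_ = res["converged"]
            self.grad_norm_ = res["grad_norm"]

        self.entries_ = entries
        self.n_ = n
        self.loadings_ = pd.Series(lam, index=entries, name="loading")
        self.unique_sd_ = pd.Series(uni, index=entries, name="unique_sd")
        tot = lam**2 + uni**2
        self.std_loadings_ = pd.Series(lam / np.sqrt(tot), index=entries, name="std_loading")
        self.covariate_paths_ = pd.DataFrame(B, index=["const"] + cov_cols, columns=entries)
        self.pairs_ = list(self.residual_pairs)
        self.pair_cov_ = pd.Series(
            rho, index=[f"{a}~{b}" for a, b in self.residual_pairs], dtype=float
        )
        self.loglik_ = float(ll)
        self.n_params_ = n_mean_params + k_cov
        self.aic_ = -2 * self.loglik_ + 2 * self.n_params_
        self.bic_ = -2 * self.loglik_ + np.log(n) * self.n_params_
        self.sigma_ = pd.DataFrame(sig, index=entries, columns=entries)
        self.variance_explained_ = float(np.mean(lam**2 / tot))
        if self.compute_se and self.S_ is not None:
            self._compute_se(pairs_idx)
        else:
            self.loadings_se_ = pd.Series(np.nan, index=entries)
            self.vcov_cov_ = None
        return self

    def _compute_se(self, pairs_idx) -> None:
        S, n, p = self.S_, self.n_, len(self.entries_)

        def grad(theta):
            return 0.5 * n * _cov_obj_grad(theta, S, p, pairs_idx)[1]

        H = numeric_hessian(grad, self._theta_cov)
        try:
            vcov = np.linalg.inv(H)
        except np.linalg.LinAlgError:
            vcov = np.linalg.pinv(H)
        se = np.sqrt(np.clip(np.diag(vcov), 0, None))
        self.vcov_cov_ = vcov
        self.loadings_se_ = pd.Series(se[:p], index=self.entries_)
        self.unique_sd_se_ = pd.Series(se[p : 2 * p], index=self.entries_)

    # --------------------------------------------------------------- scores
    def transform(self, X: pd.DataFrame, keep: Sequence[str] = ()) -> pd.Series:
        """Factor-score estimates (posterior means for the regression method;
        weighted least squares for Bartlett).  Subjects with no observed
        entries get NaN.

        ``keep`` lists covariates whose indicator contributions are *not*
        removed before scoring (e.g. the age terms, when the scores feed
        later age analyses and must retain the factor's age-related
        variance); by default all covariate paths are residualized out.
        """
        check_is_fitted(self, "loadings_")
        cov_cols = list(self.covariate_cols)
        Y = X[self.entries_].to_numpy(dtype=float)
        C = X[cov_cols].to_numpy(dtype=float) if cov_cols else np.empty((len(X), 0))
        D = np.column_stack([np.ones(len(X)), C])
        B = self.covariate_paths_.to_numpy().copy()
        for name in keep:
            if name in cov_cols:
                B[1 + cov_cols.index(name)] = 0.0
        E = Y - D @ B
        lam = self.loadings_.to_numpy()
        sig = self.sigma_.to_numpy()
        psi = self.unique_sd_.to_numpy() ** 2
        obs = np.isfinite(E)
        scores = np.full(len(X), np.nan)
        complete = obs.all(axis=1)
        if self.score_method == "regression":
            w = np.linalg.solve(sig, lam)
        else:  # bartlett
            wl = lam / psi
            w = wl / (lam @ wl)
        if complete.any():
            scores[complete] = E[complete] @ w
        for i in np.flatnonzero(~complete):
            m = obs[i]
            if m.sum() == 0:
                continue
            if self.score_method == "regression":
                wi = np.linalg.solve(sig[np.ix_(m, m)], lam[m])
            else:
                wl = lam[m] / psi[m]
                wi = wl / (lam[m] @ wl)
            scores[i] = E[i, m] @ wi
        return pd.Series(scores, index=X.index, name="g")

    def to_dict(self) -> dict:
        return {
            "entries": self.entries_,
            "loadings": self.loadings_.round(6).to_dict(),
            "loadings_se": self.loadings_se_.round(6).to_dict(),
            "unique_sd": self.unique_sd_.round(6).to_dict(),
            "std_loadings": self.std_loadings_.round(6).to_dict(),
            "residual_pairs": self.pair_cov_.round(6).to_dict(),
            "covariate_paths": self.covariate_paths_.round(6).to_dict(),
            "loglik": self.loglik_,
            "n_params": self.n_params_,
            "aic": self.aic_,
            "bic": self.bic_,
            "chisq": self.chisq_,
            "df": self.df_,
            "variance_explained": self.variance_explained_,
            "converged": self.converged_,
            "n": self.n_,
        }


# ------------------------------------------------------------- module ops

@dataclass
class EigenSpectrum:
    measure: str
    eigenvalues: np.ndarray  # descending, correlation metric
    first_factor_share: float
    weak_first_factor: bool
    entries: List[str] = field(default_factory=list)


def _nearest_psd_corr(R: np.ndarray) -> np.ndarray:
    ev, evec = np.linalg.eigh(R)
    ev = np.clip(ev, 1e-8, None)
    R2 = evec @ np.diag(ev) @ evec.T
    d = np.sqrt(np.diag(R2))
    return R2 / np.outer(d, d)


def eigen_spectrum(
    table: TractMetricTable,
    measure: str,
    entries: Optional[Sequence[str]] = None,
    weak_threshold: float = 0.15,
) -> EigenSpectrum:
    """Eigen-decomposition of the pairwise-complete tract correlation matrix.

    Flags a weak first factor when the first eigenvalue's share is below
    ``weak_threshold`` (the rule under which no factor score is extracted
    for the mode-of-anisotropy measure).
    """
    wide = table.wide(measure, entries)
    if wide.shape[1] < 2:
        raise ValueError("need at least 2 entries")
    R = wide.corr(min_periods=2).to_numpy()
    if np.isnan(R).any():
        raise ValueError("correlation matrix has undefined cells")
    ev = np.linalg.eigvalsh(R)
    if ev[0] <= 0:
        warnings.warn("pairwise correlation matrix not PSD; projecting to nearest PSD")
        R = _nearest_psd_corr(R)
        ev = np.linalg.eigvalsh(R)
    ev = ev[::-1]
    share = float(ev[0] / len(ev))
    return EigenSpectrum(
        measure=measure,
        eigenvalues=ev,
        first_factor_share=share,
        weak_first_factor=share < weak_threshold,
        entries=list(wide.columns),
    )


def fit_one_factor(
    table: TractMetricTable,
    measure: str,
    entries: Optional[Sequence[str]] = None,
    residual_pairs: Sequence[Tuple[str, str]] = (),
    include_age2: Optional[bool] = None,
    missing: str = "fiml",
    compute_se: bool = True,
) -> OneFactorModel:
    """Fit the one-factor model for a measure on the core tract entries.

    Covariates are age (standardized), sex and — for every measure except FA
    — age^2.  Returns the fitted :class:`OneFactorModel` with ``measure_``
    and the design recorded for downstream scoring.
    """
    if entries is None:
        entries = core_tract_entries()
    if include_age2 is None:
        include_age2 = measure != "FA"
    wide = table.wide(measure, entries)
    design, c, s = build_design(table.covariates.loc[wide.index], include_age2)
    X = pd.concat([wide, design.drop(columns="const")], axis=1)
    model = OneFactorModel(
        covariate_cols=list(design.columns[1:]),
        residual_pairs=residual_pairs,
        missing=missing,
        compute_se=compute_se,
    )
    model.fit(X)
    model.measure_ = measure
    model.age_center_ = c
    model.age_scale_ = s
    model.design_ = X
    return model


def prune_low_loadings(fit: OneFactorModel, threshold: float = 0.3) -> List[str]:
    """Entries whose |standardized loading| falls below ``threshold``."""
    std = fit.std_loadings_.abs()
    return list(std.index[std < threshold])


def _homologue(a: str, b: str) -> bool:
    return a[:-2] == b[:-2] and {a[-1], b[-1]} == {"L", "R"}


def modification_statistics(fit: OneFactorModel) -> pd.Series:
    """Score-test statistic for adding each absent residual covariance."""
    if fit.S_ is None:
        raise ValueError("modification statistics need a complete-data fit")
    S, n = fit.S_, fit.n_
    entries = fit.entries_
    p = len(entries)
    sig = fit.sigma_.to_numpy()
    inv = np.linalg.inv(sig)
    G = inv - inv @ S @ inv
    present = {tuple(sorted(pr)) for pr in fit.pairs_}
    stats_ = {}
    for j in range(p):
        for k in range(j + 1, p):
            if tuple(sorted((entries[j], entries[k]))) in present:
                continue
            # score statistic: gradient of n/2*F along r_jk is n*G_jk;
            # curvature from a central difference of F along the coordinate
            eps = 1e-4
            sp = sig.copy(); sp[j, k] += eps; sp[k, j] += eps
            sm = sig.copy(); sm[j, k] -= eps; sm[k, j] -= eps
            f0 = discrepancy(S, sig)
            h = (discrepancy(S, sp) - 2 * f0 + discrepancy(S, sm)) / eps**2
            if h <= 0:
                continue
            stats_[f"{entries[j]}~{entries[k]}"] = (n * G[j, k]) ** 2 / (0.5 * n * h)
    return pd.Series(stats_).sort_values(ascending=False)


def add_residual_covariances(
    table: TractMetricTable,
    measure: str,
    fit: OneFactorModel,
    max_pairs: int = 10,
    p_threshold: float = 1e-3,
) -> OneFactorModel:
    """Greedy forward addition of residual covariances.

    At each step the absent pair with the largest modification (score)
    statistic is added — bilateral homologues win ties — the model is
    refitted, and the step is kept only if the likelihood-ratio improvement
    has p < ``p_threshold``.  The addition path is recorded on the returned
    fit as ``addition_path_``.
    """
    current = fit
    path = []
    for _ in range(max_pairs):
        mi = modification_statistics(current)
        if mi.empty:
            break
        top = mi.iloc[0]
        near = mi[mi > top - 1e-6]
        cand = None
        for name in near.index:
            a, b = name.split("~")
            if _homologue(a, b):
                cand = (a, b)
                break
        if cand is None:
            a, b = mi.index[0].split("~")
            cand = (a, b)
        new_pairs = list(current.pairs_) + [cand]
        refit = fit_one_factor(
            table, measure, entries=current.entries_, residual_pairs=new_pairs,
            include_age2="age_z2" in current.covariate_cols, compute_se=False,
        )
        lr = 2 * (refit.loglik_ - current.loglik_)
        p_lr = float(stats.chi2.sf(max(lr, 0.0), 1))
        if p_lr > p_threshold:
            break
        path.append({"pair": cand, "lr": lr, "p": p_lr, "mi": float(mi.iloc[0])})
        current = refit
    if current is not fit and fit.compute_se:
        current = fit_one_factor(
            table, measure, entries=current.entries_, residual_pairs=current.pairs_,
            include_age2="age_z2" in current.covariate_cols, compute_se=True,
        )
    current.addition_path_ = path
    return current


def factor_scores(
    fit: OneFactorModel,
    table: Optional[TractMetricTable] = None,
    keep: Sequence[str] = (),
) -> pd.Series:
    """Per-subject factor-score estimates from a fitted one-factor model.

    With ``keep=("age_z", "age_z2")`` the age contributions are left in the
    indicators when scoring, so the scores retain the factor's age-related
    variance (required when the scores feed age analyses downstream).
    """
    if table is None:
        X = fit.design_
    else:
        wide = table.wide(fit.measure_, fit.entries_)
        design, _, _ = build_design(
            table.covariates.loc[wide.index],
            "age_z2" in fit.covariate_cols,
            age_center=fit.age_center_,
            age_scale=fit.age_scale_,
        )
        X = pd.concat([wide, design.drop(columns="const")], axis=1)
    return fit.transform(X, keep=keep)


# ------------------------------------------------------ pathway comparison

@dataclass
class PathwayComparison:
    measure: str
    fits: dict            # name -> summary dict (loglik, n_params, aic, bic)
    selected_paths: List[str]
    lr_tests: pd.DataFrame
    preferred_aic: str
    preferred_bic: str


class _MomentML:
    """ML over mean+covariance structure from sufficient moments."""

    def __init__(self, Sxx, Sxy, Syy, n, p, age_idx: List[int]):
        self.Sxx, self.Sxy, self.Syy = Sxx, Sxy, Syy
        self.n, self.p = n, p
        self.age_idx = age_idx  # rows of the design that age terms occupy
        self.k = Sxx.shape[0]

    def nll(self, B, lam, uni):
        C = (
            self.Syy
            - B.T @ self.Sxy
            - self.Sxy.T @ B
            + B.T @ self.Sxx @ B
        )
        sig = factor_sigma(lam, uni)
        sign, logdet = np.linalg.slogdet(sig)
        if sign <= 0:
            return np.inf
        return 0.5 * self.n * (
            self.p * np.log(2 * np.pi) + logdet + float(np.sum(np.linalg.inv(sig) * C))
        )


def _fit_structured(mm: _MomentML, free_age_entries: List[int], common: bool, start: dict):
    """Fit a pathway model: ``common`` adds loading-proportional age paths
    (gamma per age term); ``free_age_entries`` get direct age paths."""
    p, k = mm.p, mm.k
    age_idx = mm.age_idx
    base_rows = [i for i in range(k) if i not in age_idx]
    n_gamma = len(age_idx) if common else 0
    sel = list(free_age_entries)

    def unpack(theta):
        pos = 0
        Bb = theta[pos : pos + len(base_rows) * p].reshape(len(base_rows), p); pos += len(base_rows) * p
        lam = theta[pos : pos + p]; pos += p
        uni = theta[pos : pos + p]; pos += p
        gamma = theta[pos : pos + n_gamma]; pos += n_gamma
        delta = theta[pos : pos + len(sel) * len(age_idx)].reshape(len(sel), len(age_idx))
        B = np.zeros((k, p))
        B[base_rows] = Bb
        for a, ai in enumerate(age_idx):
            if common:
                B[ai] += gamma[a] * lam
            for s_i, t in enumerate(sel):
                B[ai, t] += delta[s_i, a]
        return B, lam, uni

    def obj(theta):
        B, lam, uni = unpack(theta)
        return mm.nll(B, lam, uni)

    theta0 = np.concatenate(
        [
            start["B"][base_rows].ravel(),
            start["lam"],
            start["uni"],
            np.full(n_gamma, start.get("gamma0", 0.0)),
            np.zeros(len(sel) * len(age_idx)),
        ]
    )
    res = optimize.minimize(obj, theta0, method="L-BFGS-B",
                            options={"maxiter": 4000, "ftol": 1e-12})
    B, lam, uni = unpack(res.x)
    n_params = theta0.size
    ll = -float(res.fun)
    return {
        "loglik": ll,
        "n_params": int(n_params),
        "aic": -2 * ll + 2 * n_params,
        "bic": -2 * ll + np.log(mm.n) * n_params,
        "B": B,
        "lam": lam,
        "uni": uni,
        "converged": bool(res.success),
        "theta": res.x,
    }


def fit_pathway_models(
    table: TractMetricTable,
    measure: str,
    entries: Optional[Sequence[str]] = None,
    select_alpha: float = 0.05,
    max_selected: Optional[int] = None,
) -> PathwayComparison:
    """Compare common, independent and common+independent pathway models for
    the age effect on one measure's tracts.

    In the common model age touches only the latent factor; the independent
    model gives every tract its own age path and none to the factor; the
    common+independent model starts from the common model and forward-selects
    tract-specific age paths (age and age^2 always entering together) by
    likelihood-ratio improvement at ``select_alpha``.
    """
    if entries is None:
        entries = core_tract_entries()
    include_age2 = measure != "FA"
    wide = table.wide(measure, list(entries)).dropna()
    design, _, _ = build_design(table.covariates.loc[wide.index], include_age2)
    Y = wide.to_numpy(dtype=float)
    X = design.to_numpy(dtype=float)
    n, p = Y.shape
    Sxx = X.T @ X / n
    Sxy = X.T @ Y / n
    Syy = Y.T @ Y / n
    age_idx = [list(design.columns).index("age_z")] + (
        [list(design.columns).index("age_z2")] if include_age2 else []
    )
    mm = _MomentML(Sxx, Sxy, Syy, n, p, age_idx)

    # independent model = free B: profile means, fit covariance structure
    B_free = np.linalg.solve(Sxx, Sxy)
    E = Y - X @ B_free
    S = E.T @ E / n
    covfit = fit_factor_cov(S, n, entry_names=list(wide.columns))
    ll_ind = -0.5 * n * (
        p * np.log(2 * np.pi)
        + np.linalg.slogdet(factor_sigma(covfit["loadings"], covfit["unique_sd"]))[1]
        + float(np.sum(np.linalg.inv(factor_sigma(covfit["loadings"], covfit["unique_sd"])) * S))
    )
    k_ind = X.shape[1] * p + 2 * p
    independent = {
        "loglik": float(ll_ind),
        "n_params": int(k_ind),
        "aic": -2 * ll_ind + 2 * k_ind,
        "bic": -2 * ll_ind + np.log(n) * k_ind,
        "lam": covfit["loadings"],
        "uni": covfit["unique_sd"],
        "B": B_free,
    }

    start = {"B": B_free, "lam": covfit["loadings"], "uni": covfit["unique_sd"]}
    # starting gamma: regression of naive factor scores (age left in) on age
    keep = [i for i in range(X.shape[1]) if i not in age_idx]
    resid_noage = Y - X[:, keep] @ B_free[keep]
    scores0 = resid_noage @ np.linalg.solve(
        factor_sigma(covfit["loadings"], covfit["unique_sd"]), covfit["loadings"]
    )
    ax = X[:, age_idx[0]]
    start["gamma0"] = float(np.cov(scores0, ax)[0, 1] / np.var(ax))

    common = _fit_structured(mm, [], common=True, start=start)

    # forward selection of tract-specific paths
    selected: List[int] = []
    current = common
    limit = max_selected if max_selected is not None else p
    while len(selected) < limit:
        B, lam, uni = current["B"], current["lam"], current["uni"]
        sig = factor_sigma(lam, uni)
        grad_B = mm.n * (mm.Sxx @ B - mm.Sxy) @ np.linalg.inv(sig)
        score = np.zeros(p)
        for ai in age_idx:
            score += grad_B[ai] ** 2
        score[selected] = -np.inf
        cand = int(np.argmax(score))
        trial = _fit_structured(mm, selected + [cand], common=True, start=start)
        lr = 2 * (trial["loglik"] - current["loglik"])
        p_lr = float(stats.chi2.sf(max(lr, 0.0), len(age_idx)))
        if p_lr >= select_alpha:
            break
        selected.append(cand)
        current = trial
    combined = current

    names = list(wide.columns)
    rows = []
    for a, b, d in (
        ("common", "common_independent", len(selected) * len(age_idx)),
    ):
        lr = 2 * (combined["loglik"] - common["loglik"])
        rows.append({"comparison": f"{a} vs {b}", "lr": lr, "df": max(d, 0),
                     "p": float(stats.chi2.sf(max(lr, 0.0), max(d, 1))) if d > 0 else np.nan})
    lr_tests = pd.DataFrame(rows)

    fits = {
        "common": {k: v for k, v in common.items() if k in ("loglik", "n_params", "aic", "bic")},
        "independent": {k: v for k, v in independent.items() if k in ("loglik", "n_params", "aic", "bic")},
        "common_independent": {k: v for k, v in combined.items() if k in ("loglik", "n_params", "aic", "bic")},
    }
    aics = {k: v["aic"] for k, v in fits.items()}
    bics = {k: v["bic"] for k, v in fits.items()}
    return PathwayComparison(
        measure=measure,
        fits=fits,
        selected_paths=[names[i] for i in selected],
        lr_tests=lr_tests,
        preferred_aic=min(aics, key=aics.get),
        preferred_bic=min(bics, key=bics.get),
    )


# ---------------------------------------------------- thalamic radiations

def fit_gtr(table: TractMetricTable, measure: str) -> dict:
    """First principal component of the six thalamic-radiation entries
    (anterior, superior, posterior; both hemispheres), sign-aligned so that
    higher scores mean higher tract values.

    Returns ``{"scores": Series (unit variance), "loadings": Series,
    "explained_variance": float}``.
    """
    wide = table.wide(measure, THALAMIC_ENTRIES)
    n_avail = wide.notna().sum(axis=1)
    Z = (wide - wide.mean()) / wide.std(ddof=0)
    R = Z.corr(min_periods=2).to_numpy()
    ev, evec = np.linalg.eigh(R)
    v1 = evec[:, -1]
    if v1.sum() < 0:
        v1 = -v1
    raw = Z.to_numpy() @ v1
    # subjects with partial data: renormalized available weights
    incomplete = (n_avail < len(THALAMIC_ENTRIES)) & (n_avail >= 2)
    if incomplete.any():
        Zn = Z.to_numpy()
        for i in np.flatnonzero(incomplete.to_numpy()):
            m = np.isfinite(Zn[i])
            raw[i] = Zn[i, m] @ v1[m] * (np.sum(v1**2) / np.sum(v1[m] ** 2))
    raw[(n_avail < 2).to_numpy()] = np.nan
    if np.isfinite(raw).sum() == 0:
        raise ValueError("fewer than 2 contributing tracts for every subject")
    scores = pd.Series(raw, index=wide.index, name=f"gTR_{measure}")
    scores = (scores - scores.mean()) / scores.std(ddof=0)
    return {
        "scores": scores,
        "loadings": pd.Series(v1, index=THALAMIC_ENTRIES),
        "explained_variance": float(ev[-1]),
        "explained_share": float(ev[-1] / len(THALAMIC_ENTRIES)),
    }
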