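"""Age-moderated factor models and communality-versus-age trajectories.

The moderated model lets age act on the covariance structure itself: for
measure Y in tract t and subject i,

    Y[t]_i = v[t] + a1[t]*age_i + a2[t]*age_i^2 + a3[t]*sex_i
             + l1[t] * (1 + l1m * age_c_i) * g_i
             + l2[t] * (1 + l2m * age_c_i) * u[t]_i,

so the moderation is proportional to the tract's own loading.  The slopes
l1m/l2m are either tract-invariant (two parameters) or tract-specific (2 x
22 parameters).  Communality at age a is

    h[t](a) = s / (s + u),   s = (l1[t](1 + l1m a_c))^2,
                             u = (l2[t](1 + l2m a_c))^2,

evaluated at 5-year anchor ages with delta-method standard errors and
interpolated to a dense grid with a natural cubic spline.  A kernel-weighted
sequence of unmoderated one-factor fits (local structural equation
modelling) provides a non-parametric check of the same trajectory.

Estimation is two-stage: per-entry least-squares residualization of the mean
structure, then maximum likelihood over the covariance parameters with the
per-subject likelihood (the mean and covariance blocks of the normal
information matrix are orthogonal, so the second stage loses no asymptotic
precision for the moderation parameters).  Age enters the moderation in
decades internally for optimizer conditioning; all reported slopes are per
year.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from scipy.interpolate import CubicSpline
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from ._covstruct import fit_mnlfa, numeric_hessian
from .factors import OneFactorModel, build_design, fit_one_factor
from .table import TractMetricTable
from .tracts import core_tract_entries

__all__ = [
    "ModeratedFactorModel",
    "CommunalityCurve",
    "LosemResult",
    "fit_moderated_factor",
    "communality_curve",
    "communality_delta",
    "fit_losem",
    "test_moderation_significance",
    "moderation_lr_test",
    "ANCHOR_AGES",
]

ANCHOR_AGES = np.arange(45.0, 75.1, 5.0)
_DECADE = 10.0  # internal age unit for the moderation slopes


class ModeratedFactorModel(BaseEstimator):
    """One-factor model whose loadings and unique SDs are moderated by age.

    Parameters
    ----------
    mode : "invariant" (tract-invariant moderation slopes) or
        "tract_specific" (one pair of slopes per entry).
    covariate_cols : exogenous regressors on every indicator.
    age_col : column holding age in years.
    age_center : centering constant for the moderation (years).
    fix_moderation : fit with both slopes pinned at zero (the nested
        unmoderated model on the same likelihood scale).
    residual_pairs/pair_cov : residual covariances held fixed at the values
        from the unmoderated fit (the slow likelihood path).

    Fitted attributes: ``loadings_``, ``unique_sd_``,
    ``loading_moderation_`` / ``unique_moderation_`` (per year, Series),
    ``moderation_se_``, ``loglik_``, ``vcov_``, ``entries_``.
    """

    def __init__(
        self,
        mode: str = "invariant",
        covariate_cols: Sequence[str] = ("age_z", "sex"),
        age_col: str = "age",
        age_center: float = 60.0,
        fix_moderation: bool = False,
        residual_pairs: Sequence[Tuple[str, str]] = (),
        pair_cov: Sequence[float] = (),
        start_loadings: Optional[pd.Series] = None,
        start_unique_sd: Optional[pd.Series] = None,
        n_restarts: int = 0,
        compute_se: bool = True,
        seed: int = 0,
    ):
        self.mode = mode
        self.covariate_cols = covariate_cols
        self.age_col = age_col
        self.age_center = age_center
        self.fix_moderation = fix_moderation
        self.residual_pairs = residual_pairs
        self.pair_cov = pair_cov
        self.start_loadings = start_loadings
        self.start_unique_sd = start_unique_sd
        self.n_restarts = n_restarts
        self.compute_se = compute_se
        self.seed = seed

    def fit(self, X: pd.DataFrame, y=None) -> "ModeratedFactorModel":
        cov_cols = list(self.covariate_cols)
        entries = [c for c in X.columns if c not in cov_cols + [self.age_col]]
        Y = X[entries].to_numpy(dtype=float)
        D = np.column_stack(
            [np.ones(len(X))] + [X[c].to_numpy(dtype=float) for c in cov_cols]
        )
        age_c = (X[self.age_col].to_numpy(dtype=float) - self.age_center) / _DECADE
        n, p = Y.shape
        obs = np.isfinite(Y)
        mask = None if obs.all() else obs

        B = np.zeros((D.shape[1], p))
        E = np.zeros_like(Y)
        for j in range(p):
            m = obs[:, j]
            bj, *_ = np.linalg.lstsq(D[m], Y[m, j], rcond=None)
            B[:, j] = bj
            E[:, j] = np.where(m, Y[:, j] - D @ bj, 0.0)

        pairs_idx = [(entries.index(a), entries.index(b)) for a, b in self.residual_pairs]
        rho = np.asarray(self.pair_cov, dtype=float) if len(self.pair_cov) else None
        res = fit_mnlfa(
            E,
            age_c,
            mode=self.mode,
            start_lam=None if self.start_loadings is None
            else self.start_loadings.reindex(entries).to_numpy(),
            start_uni=None if self.start_unique_sd is None
            else self.start_unique_sd.reindex(entries).to_numpy(),
            pairs=pairs_idx,
            rho=rho,
            mask=mask,
            fix_moderation=self.fix_moderation,
            n_restarts=self.n_restarts,
            seed=self.seed,
            entry_names=entries,
        )
        self.entries_ = entries
        self.n_ = n
        self.loadings_ = pd.Series(res["loadings"], index=entries)
        self.unique_sd_ = pd.Series(res["unique_sd"], index=entries)
        l1m = res["loading_moderation"] / _DECADE  # per year
        l2m = res["unique_moderation"] / _DECADE
        idx = entries if self.mode == "tract_specific" else ["(all)"]
        self.loading_moderation_ = pd.Series(np.broadcast_to(l1m, len(idx)).copy(), index=idx)
        self.unique_moderation_ = pd.Series(np.broadcast_to(l2m, len(idx)).copy(), index=idx)
        self.loglik_ = res["loglik"]
        self.covariate_paths_ = pd.DataFrame(
            B, index=["const"] + cov_cols, columns=entries
        )
        self._theta = res["theta"]  # internal (decade) scale
        self._nm = 1 if self.mode == "invariant" else p
        self.converged_ = res["converged"]
        self.grad_norm_ = res["grad_norm"]
        nm = self._nm
        self.n_params_ = D.shape[1] * p + 2 * p + (0 if self.fix_moderation else 2 * nm) + len(pairs_idx)
        self.aic_ = -2 * self.loglik_ + 2 * self.n_params_
        self.bic_ = -2 * self.loglik_ + np.log(n) * self.n_params_

        # flag (1 + l2m * age) non-positivity over the observed range
        lo, hi = float(X[self.age_col].min()), float(X[self.age_col].max())
        acs = np.array([lo, hi]) - self.age_center
        l2m_full = self.unique_moderation_.to_numpy()
        if self.mode == "invariant":
            l2m_full = np.full(p, l2m_full[0])
        factors = 1.0 + np.outer(acs, l2m_full)
        self.moderation_in_bounds_ = bool((factors > 0).all())
        if not self.moderation_in_bounds_:
            bad = np.argwhere(factors <= 0)[0]
            raise RuntimeError(
                f"unique SD collapses at age {[lo, hi][bad[0]]:.1f} for entry "
                f"{entries[bad[1]]!r}"
            )

        if self.compute_se and not self.fix_moderation:
            H = numeric_hessian(res["grad"], res["theta"])
            try:
                vcov = np.linalg.inv(H)
            except np.linalg.LinAlgError:
                vcov = np.linalg.pinv(H)
            self.vcov_ = vcov  # over [lam, uni, l1m, l2m] on the decade scale
            se = np.sqrt(np.clip(np.diag(vcov), 0, None))
            self.loadings_se_ = pd.Series(se[:p], index=entries)
            self.moderation_se_ = pd.DataFrame(
                {
                    "loading_moderation": se[2 * p : 2 * p + nm] / _DECADE,
                    "unique_moderation": se[2 * p + nm : 2 * p + 2 * nm] / _DECADE,
                },
                index=idx,
            )
        else:
            self.vcov_ = None
            self.moderation_se_ = None
        return self

    # ----------------------------------------------------------- communality
    def _moderation_arrays(self) -> Tuple[np.ndarray, np.ndarray]:
        p = len(self.entries_)
        l1m = self.loading_moderation_.to_numpy()
        l2m = self.unique_moderation_.to_numpy()
        if self.mode == "invariant":
            l1m = np.full(p, l1m[0])
            l2m = np.full(p, l2m[0])
        return l1m, l2m

    def communality(self, ages) -> pd.DataFrame:
        """Per-entry communality h(a) = s/(s+u) at the given ages (years),
        with a ``mean`` column across entries."""
        check_is_fitted(self, "loadings_")
        ages = np.atleast_1d(np.asarray(ages, dtype=float))
        ac = (ages - self.age_center)[:, None]
        lam = self.loadings_.to_numpy()[None, :]
        uni = self.unique_sd_.to_numpy()[None, :]
        l1m, l2m = self._moderation_arrays()
        s = (lam * (1.0 + l1m[None, :] * ac)) ** 2
        u = (uni * (1.0 + l2m[None, :] * ac)) ** 2
        h = s / (s + u)
        out = pd.DataFrame(h, index=ages, columns=self.entries_)
        out["mean"] = h.mean(axis=1)
        return out

    def communality_se(self, ages) -> pd.DataFrame:
        """Delta-method SE of per-entry and mean communality at given ages."""
        check_is_fitted(self, "loadings_")
        if self.vcov_ is None:
            raise ValueError("fit with compute_se=True for communality SEs")
        ages = np.atleast_1d(np.asarray(ages, dtype=float))
        p = len(self.entries_)
        nm = self._nm
        lam = self.loadings_.to_numpy()
        uni = self.unique_sd_.to_numpy()
        l1m, l2m = self._moderation_arrays()
        l1m_dec, l2m_dec = l1m * _DECADE, l2m * _DECADE
        rows = []
        for a in ages:
            ac = (a - self.age_center) / _DECADE  # decade scale matches vcov
            m1 = 1.0 + l1m_dec * ac
            m2 = 1.0 + l2m_dec * ac
            s = (lam * m1) ** 2
            u = (uni * m2) ** 2
            tot2 = (s + u) ** 2
            dh_ds = u / tot2
            dh_du = -s / tot2
            # gradient of each entry's h wrt theta = [lam, uni, l1m, l2m]
            J = np.zeros((p, 2 * p + 2 * nm))
            for t in range(p):
                J[t, t] = dh_ds[t] * 2 * lam[t] * m1[t] ** 2
                J[t, p + t] = dh_du[t] * 2 * uni[t] * m2[t] ** 2
                j1 = 2 * p + (0 if nm == 1 else t)
                j2 = 2 * p + nm + (0 if nm == 1 else t)
                J[t, j1] = dh_ds[t] * 2 * lam[t] ** 2 * m1[t] * ac
                J[t, j2] = dh_du[t] * 2 * uni[t] ** 2 * m2[t] * ac
            cov_h = J @ self.vcov_ @ J.T
            se = np.sqrt(np.clip(np.diag(cov_h), 0, None))
            se_mean = float(np.sqrt(max(np.ones(p) @ cov_h @ np.ones(p), 0)) / p)
            rows.append(np.concatenate([se, [se_mean]]))
        return pd.DataFrame(rows, index=ages, columns=self.entries_ + ["mean"])


@dataclass
class CommunalityCurve:
    ages: np.ndarray                 # dense grid
    mean: np.ndarray                 # mean communality across entries
    se: np.ndarray
    lo95: np.ndarray
    hi95: np.ndarray
    per_tract: pd.DataFrame          # dense grid x entries
    anchor_ages: np.ndarray
    anchor_mean: np.ndarray
    anchor_se: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame(
            {"age": self.ages, "h_mean": self.mean, "se": self.se,
             "lo95": self.lo95, "hi95": self.hi95}
        )
        return pd.concat([out, self.per_tract.reset_index(drop=True)], axis=1)


def fit_moderated_factor(
    table: TractMetricTable,
    measure: str,
    mode: str = "invariant",
    base_fit: Optional[OneFactorModel] = None,
    entries: Optional[Sequence[str]] = None,
    age_center: float = 60.0,
    fix_moderation: bool = False,
    include_age2: Optional[bool] = None,
    compute_se: bool = True,
    n_restarts: int = 0,
) -> ModeratedFactorModel:
    """Fit the age-moderated one-factor model for one measure.

    Starts from the unmoderated fit (supplied or computed), inherits its
    residual covariances as fixed values, and adds the moderation slopes.
    Age^2 covariate paths are included for every measure except FA.
    """
    if entries is None:
        entries = list(base_fit.entries_) if base_fit is not None else core_tract_entries()
    if include_age2 is None:
        include_age2 = measure != "FA"
    if base_fit is None:
        base_fit = fit_one_factor(
            table, measure, entries=entries, include_age2=include_age2, compute_se=False
        )
    wide = table.wide(measure, entries)
    cov = table.covariates.loc[wide.index]
    design, _, _ = build_design(cov, include_age2)
    X = pd.concat([wide, design.drop(columns="const"), cov[["age"]]], axis=1)
    model = ModeratedFactorModel(
        mode=mode,
        covariate_cols=list(design.columns[1:]),
        age_col="age",
        age_center=age_center,
        fix_moderation=fix_moderation,
        residual_pairs=base_fit.pairs_,
        pair_cov=list(base_fit.pair_cov_.to_numpy()),
        start_loadings=base_fit.loadings_,
        start_unique_sd=base_fit.unique_sd_,
        compute_se=compute_se,
        n_restarts=n_restarts,
    )
    model.fit(X)
    model.measure_ = measure
    model.base_loglik_ = base_fit.loglik_
    return model


def communality_curve(
    fit: ModeratedFactorModel,
    grid: Optional[np.ndarray] = None,
    interpolation: str = "spline",
) -> CommunalityCurve:
    """Communality trajectory: exact values and delta-method SEs at the
    5-year anchor ages, interpolated to a dense grid.

    ``interpolation``: "spline" (natural cubic spline through the anchors,
    passes through them exactly) or "cubic" (single least-squares cubic).
    """
    if grid is None:
        grid = np.arange(45.0, 75.0 + 1e-9, 0.25)
    anchors = ANCHOR_AGES
    h_anchor = fit.communality(anchors)
    se_anchor = (
        fit.communality_se(anchors)
        if fit.vcov_ is not None
        else pd.DataFrame(0.0, index=anchors, columns=fit.entries_ + ["mean"])
    )

    def interp(y):
        if interpolation == "spline":
            return CubicSpline(anchors, y, bc_type="natural")(grid)
        coef = np.polyfit(anchors - fit.age_center, y, 3)
        return np.polyval(coef, grid - fit.age_center)

    mean = interp(h_anchor["mean"].to_numpy())
    se = np.clip(interp(se_anchor["mean"].to_numpy()), 0, None)
    per_tract = pd.DataFrame(
        {e: interp(h_anchor[e].to_numpy()) for e in fit.entries_}
    )
    return CommunalityCurve(
        ages=grid,
        mean=np.clip(mean, 0.0, 1.0),
        se=se,
        lo95=np.clip(mean - 1.96 * se, 0.0, 1.0),
        hi95=np.clip(mean + 1.96 * se, 0.0, 1.0),
        per_tract=per_tract.clip(0.0, 1.0),
        anchor_ages=anchors,
        anchor_mean=h_anchor["mean"].to_numpy(),
        anchor_se=se_anchor["mean"].to_numpy(),
    )


def communality_delta(
    fit: ModeratedFactorModel, age_lo: float = 45.0, age_hi: float = 75.0
) -> Tuple[float, float]:
    """Mean-communality difference h(age_hi) - h(age_lo) in percentage
    points, with its delta-method SE."""
    for a in (age_lo, age_hi):
        if not (fit.age_center - 40 <= a <= fit.age_center + 40):
            raise ValueError(f"age {a} outside the fitted range")
    h = fit.communality([age_lo, age_hi])["mean"].to_numpy()
    delta = 100.0 * (h[1] - h[0])
    if fit.vcov_ is None:
        return float(delta), np.nan
    # delta method on the difference via numerical gradient over theta
    theta = fit._theta.copy()
    p = len(fit.entries_)
    nm = fit._nm

    def delta_of(th):
        lam = th[:p]
        uni = th[p : 2 * p]
        l1m = np.broadcast_to(th[2 * p : 2 * p + nm], p)
        l2m = np.broadcast_to(th[2 * p + nm :], p)
        out = []
        for a in (age_lo, age_hi):
            ac = (a - fit.age_center) / _DECADE
            s = (lam * (1 + l1m * ac)) ** 2
            u = (uni * (1 + l2m * ac)) ** 2
            out.append(np.mean(s / (s + u)))
        return 100.0 * (out[1] - out[0])

    eps = 1e-6
    g = np.zeros_like(theta)
    for j in range(theta.size):
        tp = theta.copy(); tp[j] += eps
        tm = theta.copy(); tm[j] -= eps
        g[j] = (delta_of(tp) - delta_of(tm)) / (2 * eps)
    se = float(np.sqrt(max(g @ fit.vcov_ @ g, 0.0)))
    return float(delta), se


def test_moderation_significance(fit: ModeratedFactorModel) -> pd.DataFrame:
    """Wald tests of each moderation slope against zero."""
    check_is_fitted(fit, "loadings_")
    if fit.moderation_se_ is None:
        raise ValueError("fit with compute_se=True for Wald tests")
    rows = []
    for kind, est in (
        ("loading_moderation", fit.loading_moderation_),
        ("unique_moderation", fit.unique_moderation_),
    ):
        se = fit.moderation_se_[kind]
        for name in est.index:
            z = est[name] / se[name] if se[name] > 0 else np.nan
            rows.append(
                {"parameter": kind, "entry": name, "estimate": est[name],
                 "se": se[name], "z": z,
                 "p": float(2 * stats.norm.sf(abs(z))) if np.isfinite(z) else np.nan}
            )
    return pd.DataFrame(rows)


def moderation_lr_test(fit: ModeratedFactorModel, null_fit: ModeratedFactorModel) -> dict:
    """Likelihood-ratio test of a moderated fit against a nested null fit on
    the same data (e.g. moderation fixed at zero)."""
    df = fit.n_params_ - null_fit.n_params_
    lr = 2.0 * (fit.loglik_ - null_fit.loglik_)
    return {"lr": float(lr), "df": int(df), "p": float(stats.chi2.sf(max(lr, 0.0), max(df, 1)))}


# ------------------------------------------------------------------ LOSEM

@dataclass
class LosemResult:
    measure: str
    targets: np.ndarray
    bandwidth: float
    effective_n: np.ndarray
    loadings: pd.DataFrame        # targets x entries
    unique_sd: pd.DataFrame
    communality: pd.DataFrame     # targets x entries (+ "mean")
    flagged: np.ndarray           # targets skipped for low effective n

    @property
    def mean_communality(self) -> pd.Series:
        return self.communality["mean"]


def fit_losem(
    table: TractMetricTable,
    measure: str,
    entries: Optional[Sequence[str]] = None,
    n_targets: int = 300,
    bandwidth: float = 2.0,
    age_lo: float = 45.0,
    age_hi: float = 75.0,
    min_effective_n: float = 50.0,
    include_age2: Optional[bool] = None,
) -> LosemResult:
    """Local structural equation modelling: one-factor fits at kernel-
    weighted age targets.

    At each of ``n_targets`` equally spaced ages, subjects are weighted with
    a Gaussian kernel (SD = ``bandwidth`` years, weight 1 at the target),
    indicators are residualized by weighted least squares on the covariates,
    and the one-factor model is fitted to the weighted covariance with the
    kernel's effective sample size.  Targets whose effective n falls below
    ``min_effective_n`` are flagged and skipped.
    """
    from ._covstruct import fit_factor_cov

    if entries is None:
        entries = core_tract_entries()
    if include_age2 is None:
        include_age2 = measure != "FA"
    wide = table.wide(measure, list(entries)).dropna()
    cov = table.covariates.loc[wide.index]
    design, _, _ = build_design(cov, include_age2)
    Y = wide.to_numpy(dtype=float)
    X = design.to_numpy(dtype=float)
    ages = cov["age"].to_numpy(dtype=float)
    if ages.min() > age_lo or ages.max() < age_hi:
        raise ValueError("observed ages do not span the target range")
    targets = np.linspace(age_lo, age_hi, n_targets)
    p = Y.shape[1]
    lam_rows, uni_rows, h_rows, neff_list, flagged = [], [], [], [], []
    start = None
    for a0 in targets:
        w = np.exp(-0.5 * ((ages - a0) / bandwidth) ** 2)
        neff = float(w.sum())
        neff_list.append(neff)
        if neff < min_effective_n:
            flagged.append(a0)
            lam_rows.append(np.full(p, np.nan))
            uni_rows.append(np.full(p, np.nan))
            h_rows.append(np.full(p, np.nan))
            continue
        Xw = X * w[:, None]
        B = np.linalg.solve(X.T @ Xw, Xw.T @ Y)
        E = Y - X @ B
        S = (E * w[:, None]).T @ E / neff
        res = fit_factor_cov(S, neff, start=start, entry_names=list(wide.columns))
        start = res["theta"]
        lam, uni = res["loadings"], res["unique_sd"]
        lam_rows.append(lam)
        uni_rows.append(uni)
        h_rows.append(lam**2 / (lam**2 + uni**2))
    loadings = pd.DataFrame(lam_rows, index=targets, columns=wide.columns)
    unique_sd = pd.DataFrame(uni_rows, index=targets, columns=wide.columns)
    communality = pd.DataFrame(h_rows, index=targets, columns=wide.columns)
    communality["mean"] = communality.mean(axis=1)
    return LosemResult(
        measure=measure,
        targets=targets,
        bandwidth=bandwidth,
        effective_n=np.array(neff_list),
        loadings=loadings,
        unique_sd=unique_sd,
        communality=communality,
        flagged=np.array(flagged),
    )
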