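"""Mediation of the age-FA association, and elastic-net age prediction.

The multiple-mediator model decomposes the age effect on the FA general
factor into a direct path and indirect paths through the neurite-density
(ICVF) and orientation-dispersion (OD) factors:

    M_j = a_j * X + e_j           (covarying mediators)
    Y   = c' * X + sum_j b_j M_j + e_Y

with total effect c from Y ~ X, indirect effects a_j * b_j, and the exact
linear decomposition c = c' + sum_j a_j b_j.  Proportion mediated is
(c - c') / c.  Inference on the indirect effects uses the percentile
bootstrap (delta-method SEs are also reported).

Age prediction screens a collinear candidate set (five diffusion general
factors plus five volumetric measures) with elastic-net regression
bootstrapped on a training half; predictors selected in more than 60% of
resamples are confirmed by ordinary regression in both halves.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.base import BaseEstimator
from sklearn.linear_model import ElasticNet, ElasticNetCV
from sklearn.model_selection import KFold
from statsmodels.stats.outliers_influence import variance_inflation_factor

__all__ = [
    "MediationResult",
    "EnetSelection",
    "MultipleMediatorModel",
    "BootstrapEnetSelector",
    "fit_multiple_mediator",
    "bootstrap_enet_select",
    "confirm_train_test",
    "thalamus_increment",
]


@dataclass
class MediationResult:
    total: float                  # c
    direct: float                 # c'
    a_paths: np.ndarray
    b_paths: np.ndarray
    indirect: np.ndarray          # a_j * b_j
    indirect_ci: np.ndarray       # (k, 2) percentile bootstrap
    indirect_se: np.ndarray       # delta method
    total_indirect: float
    total_indirect_ci: Tuple[float, float]
    proportion_mediated: float
    proportion_ci: Tuple[float, float]
    proportion_stable: bool
    mediator_residual_corr: float
    n: int
    n_boot: int

    def decomposition_error(self) -> float:
        return abs(self.total - (self.direct + float(np.sum(self.indirect))))


def _zscore(a: np.ndarray) -> np.ndarray:
    return (a - a.mean(0)) / a.std(0, ddof=0)


class MultipleMediatorModel(BaseEstimator):
    """Linear multiple-mediator path model with bootstrap inference.

    ``fit(X, y)`` takes X with the exposure in column 0 and the mediators in
    the remaining columns; all variables are standardized internally.
    """

    def __init__(self, n_boot: int = 2000, seed: int = 0, proportion_floor: float = 0.05):
        self.n_boot = n_boot
        self.seed = seed
        self.proportion_floor = proportion_floor

    @staticmethod
    def _paths(x, M, y):
        k = M.shape[1]
        a = np.empty(k)
        for j in range(k):
            a[j] = np.linalg.lstsq(np.column_stack([np.ones_like(x), x]), M[:, j], rcond=None)[0][1]
        Xf = np.column_stack([np.ones_like(x), x, M])
        bf = np.linalg.lstsq(Xf, y, rcond=None)[0]
        c_prime, b = bf[1], bf[2:]
        c = np.linalg.lstsq(np.column_stack([np.ones_like(x), x]), y, rcond=None)[0][1]
        return c, c_prime, a, b

    def fit(self, X, y) -> "MultipleMediatorModel":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        keep = np.isfinite(X).all(1) & np.isfinite(y)
        X, y = X[keep], y[keep]
        n = len(y)
        if n < 100:
            raise ValueError(f"need >= 100 complete cases, got {n}")
        Z = _zscore(X)
        yz = _zscore(y)
        x, M = Z[:, 0], Z[:, 1:]
        k = M.shape[1]
        mcorr = np.corrcoef(M, rowvar=False)
        offdiag = mcorr[np.triu_indices(k, 1)]
        if np.any(np.abs(offdiag) > 0.999):
            raise ValueError("mediators are (near-)perfectly collinear")
        c, c_prime, a, b = self._paths(x, M, yz)

        rng = np.random.default_rng(self.seed)
        boot = np.empty((self.n_boot, 2 + k))  # c, c', indirect_1..k
        for r in range(self.n_boot):
            idx = rng.integers(0, n, n)
            cb, cpb, ab, bb = self._paths(x[idx], M[idx], yz[idx])
            boot[r, 0] = cb
            boot[r, 1] = cpb
            boot[r, 2:] = ab * bb
        cols_c, cols_cp = boot[:, 0], boot[:, 1]
        cols_ind = boot[:, 2:]
        total_ind = cols_ind.sum(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            prop = (cols_c - cols_cp) / cols_c
        ci = np.percentile(cols_ind, [2.5, 97.5], axis=0).T
        tot_ci = tuple(np.percentile(total_ind, [2.5, 97.5]))
        prop_ci = tuple(np.nanpercentile(prop, [2.5, 97.5]))

        # delta-method SEs for a_j * b_j from the two OLS fits
        se_a = np.empty(k)
        for j in range(k):
            fit_a = sm.OLS(M[:, j], sm.add_constant(x)).fit()
            se_a[j] = fit_a.bse[1]
        fit_y = sm.OLS(yz, sm.add_constant(np.column_stack([x, M]))).fit()
        se_b = fit_y.bse[2:]
        ind_se = np.sqrt(a**2 * se_b**2 + b**2 * se_a**2)

        stable = abs(c) >= self.proportion_floor
        if not stable:
            warnings.warn(
                f"|total effect| = {abs(c):.3f} below floor {self.proportion_floor}; "
                "proportion mediated is unstable"
            )
        self.result_ = MediationResult(
            total=float(c),
            direct=float(c_prime),
            a_paths=a,
            b_paths=np.asarray(b),
            indirect=a * b,
            indirect_ci=ci,
            indirect_se=ind_se,
            total_indirect=float(np.sum(a * b)),
            total_indirect_ci=tot_ci,
            proportion_mediated=float((c - c_prime) / c) if c != 0 else np.nan,
            proportion_ci=prop_ci,
            proportion_stable=stable,
            mediator_residual_corr=float(
                np.corrcoef(M[:, 0] - a[0] * x, M[:, 1] - a[1] * x)[0, 1]
            ) if k == 2 else np.nan,
            n=n,
            n_boot=self.n_boot,
        )
        return self


def fit_multiple_mediator(
    x, y, mediators, n_boot: int = 2000, seed: int = 0, proportion_floor: float = 0.05
) -> MediationResult:
    """Fit the two-mediator (or k-mediator) path model; see
    :class:`MultipleMediatorModel`."""
    X = np.column_stack([np.asarray(x, dtype=float), np.asarray(mediators, dtype=float)])
    model = MultipleMediatorModel(n_boot=n_boot, seed=seed, proportion_floor=proportion_floor)
    model.fit(X, np.asarray(y, dtype=float))
    return model.result_


# --------------------------------------------------------------- elastic net

@dataclass
class EnetSelection:
    candidates: list
    inclusion_frequency: pd.Series
    selected: list
    threshold: float
    n_boot: int
    train_index: np.ndarray
    test_index: np.ndarray
    train_table: Optional[pd.DataFrame] = None
    test_table: Optional[pd.DataFrame] = None
    train_r2: float = np.nan
    test_r2: float = np.nan
    vifs: Optional[pd.Series] = None


class BootstrapEnetSelector(BaseEstimator):
    """Bootstrap stability selection with elastic-net regression.

    The sample is split into equal train/test halves.  On each bootstrap
    resample of the train half an elastic net (mixing ``l1_ratio``, penalty
    chosen by internal cross-validation) predicts the target; predictors
    with nonzero coefficients are recorded.  Predictors appearing in more
    than ``freq_threshold`` of resamples form the selected set, confirmed by
    multiple regression in both halves.

    ``penalty_mode``: "per_resample" re-runs the cross-validated penalty
    search on every bootstrap; "fixed" picks the penalty once on the full
    train half and reuses it.  ``alpha_rule``: "1se" takes the strongest
    penalty whose cross-validated error is within one standard error of the
    minimum (the conventional parsimony rule for selection); "min" takes the
    error-minimising penalty.
    """

    def __init__(
        self,
        n_boot: int = 1000,
        freq_threshold: float = 0.60,
        l1_ratio: float = 0.5,
        cv: int = 10,
        penalty_mode: str = "per_resample",
        alpha_rule: str = "1se",
        split_seed: int = 0,
        seed: int = 0,
        n_alphas: int = 50,
    ):
        self.n_boot = n_boot
        self.freq_threshold = freq_threshold
        self.l1_ratio = l1_ratio
        self.cv = cv
        self.penalty_mode = penalty_mode
        self.alpha_rule = alpha_rule
        self.split_seed = split_seed
        self.seed = seed
        self.n_alphas = n_alphas

    def _cv_alpha(self, Z, t, random_state: int) -> float:
        cvm = ElasticNetCV(
            l1_ratio=self.l1_ratio, alphas=self.n_alphas,
            cv=KFold(self.cv, shuffle=True, random_state=random_state),
        ).fit(Z, t)
        if self.alpha_rule == "min":
            return float(cvm.alpha_)
        mean_mse = cvm.mse_path_.mean(axis=1)
        se_mse = cvm.mse_path_.std(axis=1, ddof=1) / np.sqrt(cvm.mse_path_.shape[1])
        best = int(np.argmin(mean_mse))
        ok = mean_mse <= mean_mse[best] + se_mse[best]
        # alphas_ is descending: the first qualifying index is the strongest
        return float(cvm.alphas_[int(np.flatnonzero(ok)[0])])

    def fit(self, X: pd.DataFrame, y) -> "BootstrapEnetSelector":
        X = pd.DataFrame(X)
        y = np.asarray(y, dtype=float)
        n, k = X.shape
        if n < 10 * k:
            raise ValueError(f"need >= {10 * k} subjects for {k} candidates, got {n}")
        rng_split = np.random.default_rng(self.split_seed)
        perm = rng_split.permutation(n)
        half = n // 2
        train_idx, test_idx = np.sort(perm[:half]), np.sort(perm[half:])
        Xtr = X.iloc[train_idx].to_numpy()
        ytr = y[train_idx]
        rng = np.random.default_rng(self.seed)

        def standardized(A, t):
            mu, sd = A.mean(0), A.std(0, ddof=0)
            return (A - mu) / sd, (t - t.mean()) / t.std(ddof=0)

        fixed_alpha = None
        if self.penalty_mode == "fixed":
            Zs, ts = standardized(Xtr, ytr)
            fixed_alpha = self._cv_alpha(Zs, ts, int(rng.integers(2**31 - 1)))

        counts = np.zeros(k)
        m = len(train_idx)
        for r in range(self.n_boot):
            idx = rng.integers(0, m, m)
            Zb, tb = standardized(Xtr[idx], ytr[idx])
            alpha = fixed_alpha
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                if alpha is None:
                    alpha = self._cv_alpha(Zb, tb, int(rng.integers(2**31 - 1)))
                model = ElasticNet(alpha=alpha, l1_ratio=self.l1_ratio)
                model.fit(Zb, tb)
            counts += np.abs(model.coef_) > 1e-8
        freq = pd.Series(counts / self.n_boot, index=X.columns, name="inclusion_frequency")
        selected = list(freq.index[freq > self.freq_threshold])
        if not selected:
            warnings.warn("no predictor exceeded the inclusion-frequency threshold")
        self.result_ = EnetSelection(
            candidates=list(X.columns),
            inclusion_frequency=freq,
            selected=selected,
            threshold=self.freq_threshold,
            n_boot=self.n_boot,
            train_index=train_idx,
            test_index=test_idx,
        )
        if selected:
            conf = confirm_train_test(
                selected,
                X.iloc[train_idx].assign(_target=y[train_idx]),
                X.iloc[test_idx].assign(_target=y[test_idx]),
                target="_target",
            )
            self.result_.train_table = conf["train"]
            self.result_.test_table = conf["test"]
            self.result_.train_r2 = conf["train_r2"]
            self.result_.test_r2 = conf["test_r2"]
            self.result_.vifs = conf["vifs"]
        return self


def bootstrap_enet_select(
    candidates: pd.DataFrame,
    target,
    n_boot: int = 1000,
    freq_threshold: float = 0.60,
    split_seed: int = 0,
    seed: Optional[int] = None,
    **kwargs,
) -> EnetSelection:
    """Functional wrapper over :class:`BootstrapEnetSelector`."""
    sel = BootstrapEnetSelector(
        n_boot=n_boot,
        freq_threshold=freq_threshold,
        split_seed=split_seed,
        seed=split_seed if seed is None else seed,
        **kwargs,
    )
    sel.fit(candidates, target)
    return sel.result_


def _regress_table(X: pd.DataFrame, y: np.ndarray) -> Tuple[pd.DataFrame, float]:
    Z = (X - X.mean()) / X.std(ddof=0)
    yz = (y - y.mean()) / y.std(ddof=0)
    fit = sm.OLS(yz, sm.add_constant(Z)).fit()
    tab = pd.DataFrame(
        {"beta": fit.params, "se": fit.bse, "p": fit.pvalues,
         "ci_lo": fit.conf_int()[0], "ci_hi": fit.conf_int()[1]}
    ).drop(index="const")
    return tab, float(fit.rsquared)


def confirm_train_test(
    selected: Sequence[str], train: pd.DataFrame, test: pd.DataFrame, target: str
) -> dict:
    """Fit the same multiple regression of the target on the selected
    predictors in the train and test halves; report standardized
    coefficients, R-squared per half and variance inflation factors."""
    if not selected:
        raise ValueError("selected predictor set is empty")
    tr_tab, tr_r2 = _regress_table(train[list(selected)], train[target].to_numpy())
    te_tab, te_r2 = _regress_table(test[list(selected)], test[target].to_numpy())
    Ztr = sm.add_constant((train[list(selected)] - train[list(selected)].mean()) / train[list(selected)].std(ddof=0))
    vifs = pd.Series(
        [variance_inflation_factor(Ztr.to_numpy(), i + 1) for i in range(len(selected))],
        index=list(selected),
        name="vif",
    )
    return {"train": tr_tab, "test": te_tab, "train_r2": tr_r2, "test_r2": te_r2, "vifs": vifs}


def thalamus_increment(thal_volume, gtr, total_brain_volume, age) -> pd.DataFrame:
    """Unique age variance of thalamic volume and the thalamic-radiation
    composite, before and after adjusting for total brain volume.

    Returns a tidy table with one row per model x predictor, plus R-squared.
    """
    df = pd.DataFrame(
        {"thalamic_volume": np.asarray(thal_volume, float),
         "gTR": np.asarray(gtr, float),
         "total_brain_volume": np.asarray(total_brain_volume, float),
         "age": np.asarray(age, float)}
    ).dropna()
    rows = []
    for name, cols in (
        ("thal+gTR", ["thalamic_volume", "gTR"]),
        ("thal+gTR+TBV", ["thalamic_volume", "gTR", "total_brain_volume"]),
    ):
        tab, r2 = _regress_table(df[cols], df["age"].to_numpy())
        for pred, row in tab.iterrows():
            rows.append({"model": name, "predictor": pred, "beta": row["beta"],
                         "se": row["se"], "p": row["p"], "r2": r2})
    return pd.DataFrame(rows)
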