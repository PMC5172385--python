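"""Per-tract age models, dependent-correlation tests and power utilities.

Each tract/measure is regressed on age, age^2, sex, age x sex and (for
bilateral tracts, whose left and right rows are stacked) a hemisphere
indicator.  The outcome and age are z-scored so coefficients are on the
outcome-SD scale; sex and hemisphere stay 0/1 (female = 0, left = 0).  A
quadratic age term is reported only when it improves fit at p < 0.05;
within a model, effects are flagged significant at p < 0.001.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, stats

from .table import TractMetricTable

__all__ = [
    "TractRegressionResult",
    "CorrelationComparison",
    "AgeGroupCorrMatrices",
    "fit_tract_regression",
    "compare_linear_quadratic",
    "williams_t",
    "detectable_effect",
    "age_group_correlations",
    "handedness_check",
]

P_SIGNIFICANT = 0.001  # per-coefficient significance threshold
P_QUADRATIC = 0.05     # linear-vs-quadratic improvement threshold


@dataclass
class TractRegressionResult:
    tract: str
    measure: str
    form: str                      # "linear" | "quadratic" (reported form)
    coefficients: pd.DataFrame     # beta, se, p, significant per term
    n: int
    fit_linear: object = field(repr=False, default=None)
    fit_quadratic: object = field(repr=False, default=None)
    improvement_p: float = np.nan
    cluster_robust: bool = False

    @property
    def beta_age(self) -> float:
        return float(self.coefficients.loc["age_z", "beta"])


def _orthogonal_quadratic(az: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """age^2 orthogonalized against [1, age]; returns (column, projection
    coefficients (g0, g1)) so raw-scale betas can be recovered."""
    X = np.column_stack([np.ones_like(az), az])
    g, *_ = np.linalg.lstsq(X, az**2, rcond=None)
    return az**2 - X @ g, g


def fit_tract_regression(
    table: TractMetricTable,
    tract: str,
    measure: str,
    cluster_robust: bool = False,
) -> TractRegressionResult:
    """Multiple regression of one tract's measure on age, age^2, sex,
    age x sex and hemisphere (bilateral tracts stacked over hemispheres).

    Both the linear and quadratic fits are computed; the reported form is
    quadratic only if the nested improvement test has p < 0.05.  The
    quadratic term enters orthogonalized for stability and its coefficient is
    reported back on the raw-polynomial scale.  With ``cluster_robust``,
    standard errors are clustered by subject (stacked rows reuse subjects).
    """
    rows = table.long[(table.long["tract"] == tract) & (table.long["measure"] == measure)]
    if rows.empty:
        raise ValueError(f"no rows for tract {tract!r}, measure {measure!r}")
    rows = rows.merge(
        table.covariates[["age", "sex"]], left_on="subject_id", right_index=True
    ).dropna(subset=["value", "age", "sex"])
    n = len(rows)
    if n < 50:
        raise ValueError(f"only {n} complete rows for {tract}/{measure}; need >= 50")
    midline = (rows["hemisphere"] == "midline").all()

    y = stats.zscore(rows["value"].to_numpy(), ddof=0)
    az = stats.zscore(rows["age"].to_numpy(), ddof=0)
    sex = rows["sex"].to_numpy(dtype=float)
    q, gproj = _orthogonal_quadratic(az)
    cols = {"age_z": az, "sex": sex, "age_x_sex": az * sex}
    if not midline:
        cols["hemisphere"] = (rows["hemisphere"] == "right").to_numpy(dtype=float)
    Xlin = pd.DataFrame(cols)
    Xquad = Xlin.copy()
    Xquad.insert(1, "age_z2_orth", q)

    def _ols(X):
        Xc = sm.add_constant(X, has_constant="add")
        if np.linalg.matrix_rank(Xc.to_numpy()) < Xc.shape[1]:
            corr = np.corrcoef(X.to_numpy(), rowvar=False)
            bad = [
                f"{X.columns[i]}~{X.columns[j]}"
                for i in range(len(X.columns))
                for j in range(i + 1, len(X.columns))
                if abs(corr[i, j]) > 0.999
            ]
            raise ValueError(f"rank-deficient design; collinear columns: {bad or list(X.columns)}")
        model = sm.OLS(y, Xc)
        if cluster_robust:
            return model.fit(cov_type="cluster", cov_kwds={"groups": rows["subject_id"]})
        return model.fit()

    fit_lin = _ols(Xlin)
    fit_quad = _ols(Xquad)
    form, p_impr = compare_linear_quadratic(fit_lin, fit_quad, return_p=True)
    chosen = fit_quad if form == "quadratic" else fit_lin

    params = chosen.params.copy()
    bse = chosen.bse.copy()
    pvals = chosen.pvalues.copy()
    if form == "quadratic":
        # back-transform: raw age^2 beta is the orthogonal-term beta; the raw
        # age beta subtracts its projection onto age
        b_q = params["age_z2_orth"]
        params["age_z2"] = b_q
        bse["age_z2"] = bse["age_z2_orth"]
        pvals["age_z2"] = pvals["age_z2_orth"]
        params["age_z"] = params["age_z"] - gproj[1] * b_q
        for s_ in (params, bse, pvals):
            s_.drop("age_z2_orth", inplace=True)
    coef = pd.DataFrame({"beta": params, "se": bse, "p": pvals})
    coef["significant"] = coef["p"] < P_SIGNIFICANT
    coef = coef.drop(index="const")
    return TractRegressionResult(
        tract=tract,
        measure=measure,
        form=form,
        coefficients=coef,
        n=n,
        fit_linear=fit_lin,
        fit_quadratic=fit_quad,
        improvement_p=p_impr,
        cluster_robust=cluster_robust,
    )


def compare_linear_quadratic(fit_lin, fit_quad, return_p: bool = False):
    """Nested F-test of the quadratic age term: returns "quadratic" iff the
    improvement has p < 0.05 (boundary exclusive at 0.05)."""
    if fit_quad.df_model < fit_lin.df_model or fit_quad.nobs != fit_lin.nobs:
        raise ValueError("fits are not nested on identical rows")
    if fit_quad.df_model == fit_lin.df_model:
        out = "linear", np.nan
        return out if return_p else out[0]
    f, p, _ = fit_quad.compare_f_test(fit_lin)
    form = "quadratic" if p < P_QUADRATIC else "linear"
    return (form, float(p)) if return_p else form


@dataclass
class CorrelationComparison:
    r_ja: float
    r_ka: float
    r_jk: float
    n: int
    t: float
    p: float
    df: int


def williams_t(r_ja: float, r_ka: float, r_jk: float, n: int) -> CorrelationComparison:
    """Williams's t for two dependent correlations sharing one variable.

    Tests r(j,a) = r(k,a) when j, k and a are measured on the same ``n``
    subjects and r(j,k) is their overlap; df = n - 3, two-sided p.
    """
    for name, r in (("r_ja", r_ja), ("r_ka", r_ka), ("r_jk", r_jk)):
        if not abs(r) < 1:
            raise ValueError(f"{name} must satisfy |r| < 1, got {r}")
    if n <= 3:
        raise ValueError(f"n must exceed 3, got {n}")
    detR = 1.0 - r_ja**2 - r_ka**2 - r_jk**2 + 2.0 * r_ja * r_ka * r_jk
    rbar = 0.5 * (r_ja + r_ka)
    denom = 2.0 * (n - 1.0) / (n - 3.0) * detR + rbar**2 * (1.0 - r_jk) ** 3
    if denom <= 0:
        raise ValueError("degenerate correlation configuration")
    t = (r_ja - r_ka) * np.sqrt((n - 1.0) * (1.0 + r_jk) / denom)
    df = n - 3
    p = float(2.0 * stats.t.sf(abs(t), df))
    return CorrelationComparison(r_ja, r_ka, r_jk, n, float(t), max(p, np.finfo(float).tiny), df)


def _corr_power(rho: float, n: int, alpha: float, method: str) -> float:
    if method == "fisher":
        za = stats.norm.isf(alpha / 2.0)
        return float(stats.norm.sf(za - np.arctanh(rho) * np.sqrt(n - 3)))
    df = n - 2
    tcrit = stats.t.isf(alpha / 2.0, df)
    nc = rho * np.sqrt(n) / np.sqrt(1.0 - rho**2)
    upper = stats.nct.sf(tcrit, df, nc)
    lower = stats.nct.cdf(-tcrit, df, nc)  # numerically 0 for large nc
    return float(upper + (0.0 if not np.isfinite(lower) else lower))


def detectable_effect(n: int, alpha: float, power: float, method: str = "nct") -> float:
    """Smallest standardized bivariate association (correlation) detectable
    two-sided at ``alpha`` with the given power, rounded to 3 decimals.

    ``method``: "nct" (noncentral-t power of the correlation test, default)
    or "fisher" (Fisher-z approximation).
    """
    if n <= 3:
        raise ValueError("n must exceed 3")
    if not (0 < alpha < 1 and 0 < power < 1):
        raise ValueError("alpha and power must lie in (0, 1)")
    if power <= _corr_power(1e-9, n, alpha, method):
        raise ValueError("requested power not above the test's size")
    r = optimize.brentq(lambda rho: _corr_power(rho, n, alpha, method) - power, 1e-9, 0.999)
    return round(float(r), 3)


@dataclass
class AgeGroupCorrMatrices:
    edges: list
    descriptives: pd.DataFrame     # per bin: n, mean, sd
    matrices: dict                 # (measure, bin index) -> DataFrame or None

    def mean_offdiagonal(self, measure: str) -> list:
        out = []
        for b in range(len(self.edges)):
            m = self.matrices.get((measure, b))
            if m is None:
                out.append(np.nan)
                continue
            a = m.to_numpy()
            out.append(float(a[np.triu_indices_from(a, k=1)].mean()))
        return out


def age_group_correlations(
    table: TractMetricTable,
    edges: Sequence[Tuple[float, float]],
    measures: Optional[Sequence[str]] = None,
) -> AgeGroupCorrMatrices:
    """Tract x tract Pearson correlation matrices within each age bin.

    Bins with fewer than 10 subjects trigger a warning; bins with fewer than
    3 subjects have their matrix omitted (None).
    """
    import warnings

    measures = list(measures or table.measures)
    ages = table.covariates["age"]
    desc_rows = []
    matrices = {}
    for b, (lo, hi) in enumerate(edges):
        ids = ages.index[(ages >= lo) & (ages <= hi)]
        nb = len(ids)
        desc_rows.append({"bin": b, "lo": lo, "hi": hi, "n": nb,
                          "mean": float(ages.loc[ids].mean()) if nb else np.nan,
                          "sd": float(ages.loc[ids].std(ddof=1)) if nb > 1 else np.nan})
        if nb < 10:
            warnings.warn(f"age bin {b} [{lo}, {hi}] has only {nb} subjects")
        for m in measures:
            if nb < 3:
                matrices[(m, b)] = None
                continue
            wide = table.wide(m).loc[ids]
            matrices[(m, b)] = wide.corr(min_periods=3)
    return AgeGroupCorrMatrices(
        edges=list(edges), descriptives=pd.DataFrame(desc_rows), matrices=matrices
    )


def handedness_check(table: TractMetricTable, measures: Optional[Sequence[str]] = None) -> pd.DataFrame:
    """Welch t-test and Cohen's d comparing right- versus left-handers for
    every tract entry and measure."""
    hand = table.covariates["handedness"]
    right_ids = hand.index[hand == "right"]
    left_ids = hand.index[hand == "left"]
    if len(right_ids) == 0 or len(left_ids) == 0:
        raise ValueError("both handedness groups must be non-empty")
    rows = []
    for m in measures or table.measures:
        wide = table.wide(m)
        for entry in wide.columns:
            a = wide.loc[right_ids, entry].dropna()
            b = wide.loc[left_ids, entry].dropna()
            t, p = stats.ttest_ind(a, b, equal_var=False)
            sp = np.sqrt(
                ((len(a) - 1) * a.var(ddof=1) + (len(b) - 1) * b.var(ddof=1))
                / (len(a) + len(b) - 2)
            )
            d = (a.mean() - b.mean()) / sp if sp > 0 else 0.0
            rows.append({"measure": m, "entry": entry, "t": float(t), "p": float(p),
                         "cohens_d": float(d), "n_right": len(a), "n_left": len(b)})
    return pd.DataFrame(rows)
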