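"""Synthetic cohort generator with a known latent-factor ground truth.

The generator emulates the statistical structure of tract-averaged diffusion
phenotypes in a middle-aged/older cohort: for each diffusion measure Y and
tract entry t,

    Y[t] = v[t] + a1[t]*age_z + a2[t]*age_z^2 + a3[t]*sex
           + l1[t] * (1 + l1m * age_c) * g
           + l2[t] * (1 + l2m * age_c) * u[t]
           + hemisphere offset + residual-pair contributions,

where ``g`` is the measure's general factor, ``u[t]`` are tract-specific
unique factors (both standard normal conditional on age), ``age_z`` is age
standardized by a fixed center/scale and ``age_c`` is age in years centered
at the same constant.  The moderation slopes ``l1m``/``l2m`` (per centered
year) make communality — the shared-variance proportion
l1(a)^2 / (l1(a)^2 + l2(a)^2) — change with age, which is the
de-differentiation signal the analysis modules are built to recover.

General factors carry age paths of their own, and the FA factor can be
generated through its neurite-density (ICVF) and orientation-dispersion (OD)
factors, giving a known mediated proportion of the age-FA association.
Volumetric phenotypes are linear in age and the factors.  Exclusion flags
reproduce a staged recruitment cascade.
"""

from __future__ import annotations

from collections import OrderedDict
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .table import TractMetricTable
from .tracts import TractSpec, make_tract_catalog

__all__ = [
    "MeasureModel",
    "GeneratingModel",
    "default_generating_model",
    "generate_cohort",
    "apply_exclusion_cascade",
    "true_communality",
    "simulate_mediation",
    "AGE_RANGE",
    "AGE_GROUP_EDGES",
    "AGE_GROUP_WEIGHTS",
    "DEFAULT_FLAG_COUNTS",
]

AGE_RANGE = (44.64, 77.12)

# Six roughly 5-year age groups with the cohort's group sizes; the default
# age distribution samples a group by weight, then uniformly within it.
AGE_GROUP_EDGES = [
    (44.64, 49.98),
    (50.05, 54.99),
    (55.00, 60.00),
    (60.01, 65.00),
    (65.00, 70.00),
    (70.00, 77.12),
]
AGE_GROUP_WEIGHTS = np.array([290, 505, 559, 800, 876, 483], dtype=float)

# Staged exclusion counts for the default raw cohort of 5,455: early-phase
# acquisitions, quality-control failures, neurodegenerative/demyelinating
# diagnoses and consistently-extreme outliers, leaving 3,513.
DEFAULT_FLAG_COUNTS = OrderedDict(
    [("early_phase", 567), ("qc_fail", 1314), ("neuro_diagnosis", 59), ("outlier", 2)]
)
FLAG_ORDER = list(DEFAULT_FLAG_COUNTS)


def _as_series(x: Union[float, dict, pd.Series], entries: Sequence[str]) -> pd.Series:
    if np.isscalar(x):
        return pd.Series(float(x), index=list(entries))
    s = pd.Series(x, dtype=float).reindex(entries)
    if s.isna().any():
        raise ValueError(f"missing per-entry values for {list(s.index[s.isna()])}")
    return s


@dataclass
class MeasureModel:
    """Generating parameters for one diffusion measure over the 27 entries.

    All per-entry fields accept a scalar (broadcast) or a mapping/Series
    keyed by entry label (e.g. ``SLF_L``).  Moderation slopes are per
    centered year of age; ``unique_sd`` must stay positive over the
    supported age range.
    """

    entries: List[str]
    intercept: pd.Series
    age_slope: pd.Series       # per SD of age
    age2_slope: pd.Series      # per squared SD of age
    sex_effect: pd.Series      # male (1) minus female (0)
    loading: pd.Series         # l1[t]: general-factor loading
    unique_sd: pd.Series       # l2[t] > 0: unique-factor loading
    loading_moderation: pd.Series   # l1m (may be constant across entries)
    unique_moderation: pd.Series    # l2m
    hemisphere_offset: float = 0.0  # added to right-hemisphere entries
    residual_pairs: List[Tuple[str, str, float]] = field(default_factory=list)

    @classmethod
    def build(
        cls,
        entries: Sequence[str],
        intercept=0.0,
        age_slope=0.0,
        age2_slope=0.0,
        sex_effect=0.0,
        loading=0.6,
        unique_sd=0.8,
        loading_moderation=0.0,
        unique_moderation=0.0,
        hemisphere_offset=0.0,
        residual_pairs=None,
    ) -> "MeasureModel":
        entries = list(entries)
        return cls(
            entries=entries,
            intercept=_as_series(intercept, entries),
            age_slope=_as_series(age_slope, entries),
            age2_slope=_as_series(age2_slope, entries),
            sex_effect=_as_series(sex_effect, entries),
            loading=_as_series(loading, entries),
            unique_sd=_as_series(unique_sd, entries),
            loading_moderation=_as_series(loading_moderation, entries),
            unique_moderation=_as_series(unique_moderation, entries),
            hemisphere_offset=float(hemisphere_offset),
            residual_pairs=list(residual_pairs or []),
        )


@dataclass
class GeneratingModel:
    """Ground-truth parameters for the synthetic cohort.

    ``factor_age_paths`` are the age coefficients of each measure's general
    factor in residual-unit metric (the factor's variance conditional on age
    is 1, matching the identification used by the fitted models).
    ``fa_mediation``, when set, generates the target measure's factor through
    two mediating factors: ``{"target": "FA", "mediators": ("ICVF", "OD"),
    "c_prime": float, "b": (b1, b2)}``.
    """

    measures: Dict[str, MeasureModel]
    factor_age_paths: Dict[str, float] = field(default_factory=dict)
    fa_mediation: Optional[dict] = None
    age_center: float = 60.0
    age_scale: float = 7.5
    age_range: Tuple[float, float] = AGE_RANGE
    age_distribution: str = "groups"  # "groups" | "uniform"
    volumetrics: Dict[str, dict] = field(default_factory=dict)
    p_male: float = 0.47
    p_left_handed: float = 0.10
    flag_counts: Optional[Dict[str, int]] = None  # disjoint exact counts
    flag_rates: Optional[Dict[str, float]] = None  # independent Bernoulli
    missing_rate: float = 0.0

    # ------------------------------------------------------------ structure
    def factor_basis(self) -> Tuple[List[str], Dict[str, np.ndarray]]:
        """Represent each general factor as coefficients over an orthonormal
        basis [age_z, zeta_m1, zeta_m2, ...] of unit-variance components."""
        names = list(self.measures)
        basis = ["age_z"] + [f"zeta_{m}" for m in names]
        coefs: Dict[str, np.ndarray] = {}
        med = self.fa_mediation
        for m in names:
            vec = np.zeros(len(basis))
            if med is not None and m == med["target"]:
                continue  # filled after its mediators
            gamma = self.factor_age_paths.get(m, 0.0)
            vec[0] = gamma
            vec[basis.index(f"zeta_{m}")] = 1.0
            coefs[m] = vec
        if med is not None:
            m = med["target"]
            m1, m2 = med["mediators"]
            if m1 not in coefs or m2 not in coefs:
                raise ValueError("mediators must be measures without mediated structure")
            b1, b2 = med["b"]
            resid_var = 1.0 - b1**2 - b2**2
            if resid_var <= 0:
                raise ValueError("mediation b-paths imply non-positive factor residual variance")
            vec = med["c_prime"] * np.eye(len(basis))[0] + b1 * coefs[m1] + b2 * coefs[m2]
            vec[basis.index(f"zeta_{m}")] = np.sqrt(resid_var)
            coefs[m] = vec
        return basis, coefs

    def factor_age_coefficient(self, measure: str) -> float:
        """Total coefficient of age_z in the factor (direct plus mediated)."""
        _, coefs = self.factor_basis()
        return float(coefs[measure][0])

    # ------------------------------------------------------------- implied
    def moderated_loadings(self, measure: str, age: float) -> Tuple[pd.Series, pd.Series]:
        mm = self.measures[measure]
        ac = age - self.age_center
        lam = mm.loading * (1.0 + mm.loading_moderation * ac)
        uni = mm.unique_sd * (1.0 + mm.unique_moderation * ac)
        return lam, uni

    def implied_sigma(self, measure: str, age: float) -> pd.DataFrame:
        """Model-implied covariance of the entries at one age, conditional on
        age and sex."""
        mm = self.measures[measure]
        lam, uni = self.moderated_loadings(measure, age)
        sig = np.outer(lam, lam) + np.diag(uni**2)
        sig = pd.DataFrame(sig, index=mm.entries, columns=mm.entries)
        for t1, t2, c in mm.residual_pairs:
            sig.loc[t1, t2] += c
            sig.loc[t2, t1] += c
            sig.loc[t1, t1] += abs(c)
            sig.loc[t2, t2] += abs(c)
        return sig

    def validate(self) -> None:
        """Check positive-definiteness of the implied covariance and
        positivity of the moderated unique SDs across the supported ages."""
        lo, hi = self.age_range
        for m, mm in self.measures.items():
            for age in np.linspace(lo, hi, 9):
                ac = age - self.age_center
                uni = mm.unique_sd * (1.0 + mm.unique_moderation * ac)
                if (uni <= 0).any():
                    bad = list(uni.index[uni <= 0])
                    raise ValueError(
                        f"measure {m}: unique SD non-positive at age {age:.2f} for {bad}"
                    )
                eigmin = float(np.linalg.eigvalsh(self.implied_sigma(m, age))[0])
                if eigmin <= 0:
                    raise ValueError(
                        f"measure {m}: implied covariance not positive definite at age {age:.2f}"
                        f" (min eigenvalue {eigmin:.3g})"
                    )


def true_communality(
    genmodel: GeneratingModel, measure: str, entry: str, age: Union[float, np.ndarray]
):
    """Ground-truth communality s/(s+u) of one entry at the given age(s),
    with s = (l1(1+l1m*age_c))^2 and u = (l2(1+l2m*age_c))^2."""
    lo, hi = genmodel.age_range
    ages = np.asarray(age, dtype=float)
    if np.any(ages < lo - 1.0) or np.any(ages > hi + 1.0):
        raise ValueError(f"age outside supported range {genmodel.age_range}")
    mm = genmodel.measures[measure]
    ac = ages - genmodel.age_center
    s = (mm.loading[entry] * (1.0 + mm.loading_moderation[entry] * ac)) ** 2
    u = (mm.unique_sd[entry] * (1.0 + mm.unique_moderation[entry] * ac)) ** 2
    tot = s + u
    if np.any(tot == 0):
        raise ValueError("zero total variance")
    return s / tot


# ---------------------------------------------------------------- defaults

# Mean first-factor variance shares the defaults are calibrated to.
_MEAN_COMMUNALITY = {"FA": 0.414, "MD": 0.381, "ICVF": 0.682, "ISOVF": 0.308, "OD": 0.201}
# Loading-moderation slope per centered year (de-differentiation strength).
_DEFAULT_L1_MODERATION = {"FA": 0.008, "MD": 0.012, "ICVF": 0.006, "ISOVF": 0.009, "OD": 0.0}
# Standardized age effect of each general factor (used to derive the age path
# in residual-unit metric: gamma = beta / sqrt(1 - beta^2)).
_FACTOR_AGE_BETA = {"MD": 0.368, "ICVF": -0.265, "ISOVF": 0.273, "OD": -0.120}
_SEX_EFFECT = {"FA": 0.12, "MD": -0.05, "ICVF": 0.05, "ISOVF": 0.04, "OD": -0.14}
_HEMI_OFFSET = {"FA": -0.18, "MD": 0.08, "ICVF": -0.05, "ISOVF": 0.10, "OD": 0.05}
_WEAK_LOADING = 0.15

_DEFAULT_VOLUMETRICS = {
    "total_brain_volume": {"age": -0.42, "factors": {"MD": -0.15}},
    "grey_matter_volume": {"age": -0.48, "factors": {"MD": -0.12}},
    "white_matter_volume": {"age": -0.30, "factors": {"FA": 0.15, "MD": -0.15}},
    "hippocampal_volume": {"age": -0.25, "factors": {"MD": -0.10}},
    "thalamic_volume": {"age": -0.35, "factors": {"MD": -0.12}},
}


def _default_measure_model(
    measure: str, catalog: Sequence[TractSpec], moderated: bool
) -> MeasureModel:
    entries = [t.entry for t in catalog]
    h = _MEAN_COMMUNALITY.get(measure, 0.40)
    core = [t for t in catalog if t.core_factor_member]
    # deterministic spread of loadings around the calibration target
    spread = 0.85 + 0.30 * (np.arange(len(core)) % 7) / 6.0
    lam = np.sqrt(h) * spread
    lam *= np.sqrt(h / np.mean(lam**2))
    lam = np.clip(lam, 0.05, 0.92)
    loading = pd.Series(_WEAK_LOADING, index=entries)
    for t, l in zip(core, lam):
        loading[t.entry] = l
    unique_sd = np.sqrt(1.0 - loading**2)

    sign = np.sign(_FACTOR_AGE_BETA.get(measure, -0.25))
    age_slope = pd.Series(0.0, index=entries)
    age2_slope = pd.Series(0.0, index=entries)
    for t in catalog:
        if t.category in ("association", "thalamic_radiation") and t.core_factor_member:
            age_slope[t.entry] = 0.08 * sign
        if measure != "FA":
            age2_slope[t.entry] = 0.03 * sign

    return MeasureModel.build(
        entries=entries,
        intercept=0.0,
        age_slope=age_slope,
        age2_slope=age2_slope,
        sex_effect=_SEX_EFFECT.get(measure, 0.0),
        loading=loading,
        unique_sd=unique_sd,
        loading_moderation=_DEFAULT_L1_MODERATION.get(measure, 0.0) if moderated else 0.0,
        unique_moderation=0.0,
        hemisphere_offset=_HEMI_OFFSET.get(measure, 0.0),
    )


def default_generating_model(
    measures: Sequence[str] = ("FA", "MD", "ICVF", "ISOVF", "OD"),
    moderated: bool = True,
) -> GeneratingModel:
    """Default ground truth: one factor per measure over the 27 entries, five
    weak-loading entries, age-increasing communality, factor-level age paths
    and a mediated age->FA structure through ICVF and OD."""
    catalog = make_tract_catalog()
    mm = {m: _default_measure_model(m, catalog, moderated) for m in measures}
    paths = {
        m: float(b / np.sqrt(1 - b**2))
        for m, b in _FACTOR_AGE_BETA.items()
        if m in measures
    }
    med = None
    if {"FA", "ICVF", "OD"} <= set(measures):
        med = {"target": "FA", "mediators": ("ICVF", "OD"), "c_prime": -0.065, "b": (0.64, 0.18)}
    vol = {
        name: {"age": v["age"], "factors": {m: c for m, c in v["factors"].items() if m in measures}}
        for name, v in _DEFAULT_VOLUMETRICS.items()
    }
    return GeneratingModel(
        measures=mm,
        factor_age_paths=paths,
        fa_mediation=med,
        volumetrics=vol,
        flag_counts=dict(DEFAULT_FLAG_COUNTS),
    )


# -------------------------------------------------------------- generation

def _draw_ages(gm: GeneratingModel, n: int, rng: np.random.Generator) -> np.ndarray:
    lo, hi = gm.age_range
    if gm.age_distribution == "uniform":
        return rng.uniform(lo, hi, size=n)
    w = AGE_GROUP_WEIGHTS / AGE_GROUP_WEIGHTS.sum()
    groups = rng.choice(len(w), size=n, p=w)
    edges = np.array(AGE_GROUP_EDGES)
    return rng.uniform(edges[groups, 0], edges[groups, 1])


def _assign_flags(
    gm: GeneratingModel, n: int, rng: np.random.Generator
) -> pd.DataFrame:
    flags = pd.DataFrame(False, index=range(n), columns=[f"{s}_flag" for s in FLAG_ORDER])
    if gm.flag_rates is not None:
        for s in FLAG_ORDER:
            rate = gm.flag_rates.get(s, 0.0)
            flags[f"{s}_flag"] = rng.random(n) < rate
        return flags
    counts = gm.flag_counts
    if counts is None:
        return flags
    scale = 1.0 if n == sum(counts.values()) + 3513 else n / 5455.0
    order = rng.permutation(n)
    pos = 0
    for s in FLAG_ORDER:
        k = int(round(counts.get(s, 0) * scale)) if scale != 1.0 else counts.get(s, 0)
        k = min(k, n - pos)
        flags.loc[order[pos : pos + k], f"{s}_flag"] = True
        pos += k
    return flags


def generate_cohort(
    genmodel: Optional[GeneratingModel] = None,
    n_raw: int = 5455,
    seed: int = 0,
) -> Tuple[pd.DataFrame, TractMetricTable]:
    """Simulate a raw cohort: subject records (with exclusion flags) and the
    tract metric table for all measures, deterministic given ``seed``.

    Returns ``(subjects, table)``; the exclusion cascade has *not* been
    applied — pass ``subjects`` to :func:`apply_exclusion_cascade` and subset
    the table to the retained ids.
    """
    if genmodel is None:
        genmodel = default_generating_model()
    if n_raw < 50:
        raise ValueError("n_raw must be at least 50")
    genmodel.validate()
    rng = np.random.default_rng(seed)

    ages = _draw_ages(genmodel, n_raw, rng)
    sex = (rng.random(n_raw) < genmodel.p_male).astype(int)
    handed = np.where(rng.random(n_raw) < genmodel.p_left_handed, "left", "right")
    ids = [f"S{i:06d}" for i in range(n_raw)]
    flags = _assign_flags(genmodel, n_raw, rng)
    subjects = pd.DataFrame(
        {"subject_id": ids, "age": ages, "sex": sex, "handedness": handed}
    ).join(flags)

    az = (ages - genmodel.age_center) / genmodel.age_scale
    ac = ages - genmodel.age_center

    basis_names, coefs = genmodel.factor_basis()
    basis = np.empty((n_raw, len(basis_names)))
    basis[:, 0] = az
    basis[:, 1:] = rng.standard_normal((n_raw, len(basis_names) - 1))
    g_scores = {m: basis @ coefs[m] for m in genmodel.measures}

    frames = []
    for m, mm in genmodel.measures.items():
        p = len(mm.entries)
        u = rng.standard_normal((n_raw, p))
        lam = mm.loading.to_numpy()
        uni = mm.unique_sd.to_numpy()
        l1m = mm.loading_moderation.to_numpy()
        l2m = mm.unique_moderation.to_numpy()
        lam_i = lam[None, :] * (1.0 + ac[:, None] * l1m[None, :])
        uni_i = uni[None, :] * (1.0 + ac[:, None] * l2m[None, :])
        vals = (
            mm.intercept.to_numpy()[None, :]
            + mm.age_slope.to_numpy()[None, :] * az[:, None]
            + mm.age2_slope.to_numpy()[None, :] * (az**2)[:, None]
            + mm.sex_effect.to_numpy()[None, :] * sex[:, None]
            + lam_i * g_scores[m][:, None]
            + uni_i * u
        )
        right = np.array([e.endswith("_R") for e in mm.entries])
        vals[:, right] += mm.hemisphere_offset
        for t1, t2, c in mm.residual_pairs:
            e_pair = rng.standard_normal(n_raw)
            j1, j2 = mm.entries.index(t1), mm.entries.index(t2)
            vals[:, j1] += np.sqrt(abs(c)) * e_pair
            vals[:, j2] += np.sign(c) * np.sqrt(abs(c)) * e_pair
        if genmodel.missing_rate > 0:
            mask = rng.random(vals.shape) < genmodel.missing_rate
            vals = np.where(mask, np.nan, vals)
        wide = pd.DataFrame(vals, index=ids, columns=mm.entries)
        long = wide.rename_axis("subject_id").reset_index().melt(
            id_vars="subject_id", var_name="entry", value_name="value"
        )
        tract_hemi = long["entry"].map(
            lambda e: e[:-2] if e.endswith(("_L", "_R")) else e
        )
        hemi = long["entry"].map(
            lambda e: "left" if e.endswith("_L") else ("right" if e.endswith("_R") else "midline")
        )
        frames.append(
            pd.DataFrame(
                {
                    "subject_id": long["subject_id"],
                    "tract": tract_hemi,
                    "hemisphere": hemi,
                    "measure": m,
                    "value": long["value"],
                }
            )
        )
    long_all = pd.concat(frames, ignore_index=True)
    long_all = long_all.dropna(subset=["value"]).reset_index(drop=True)

    vol = None
    if genmodel.volumetrics:
        cols = {}
        for name, spec in genmodel.volumetrics.items():
            vec = spec.get("age", 0.0) * np.eye(len(basis_names))[0]
            for m, c in spec.get("factors", {}).items():
                vec = vec + c * coefs[m]
            var = float(vec @ vec)
            resid = 1.0 - var
            if resid <= 0:
                raise ValueError(f"volumetric {name}: explained variance >= 1")
            cols[name] = basis @ vec + np.sqrt(resid) * rng.standard_normal(n_raw)
        vol = pd.DataFrame(cols, index=pd.Index(ids, name="subject_id"))

    covariates = subjects.set_index("subject_id")
    tab = TractMetricTable(long=long_all, covariates=covariates, volumetrics=vol)
    return subjects, tab


def apply_exclusion_cascade(
    subjects: pd.DataFrame,
) -> Tuple[pd.DataFrame, "OrderedDict[str, int]"]:
    """Apply the staged exclusion cascade in order (early-phase acquisition,
    QC failure, neurological diagnosis, extreme outlier) and return the
    retained records plus per-stage removal counts.

    The counts are order-dependent: a subject is removed at the first stage
    whose flag it carries.
    """
    remaining = subjects.copy()
    counts: "OrderedDict[str, int]" = OrderedDict()
    counts["raw"] = len(remaining)
    for stage in FLAG_ORDER:
        col = f"{stage}_flag"
        flagged = remaining[col].astype(bool) if col in remaining else pd.Series(False, index=remaining.index)
        counts[stage] = int(flagged.sum())
        remaining = remaining[~flagged]
    counts["final"] = len(remaining)
    return remaining.reset_index(drop=True), counts


def simulate_mediation(
    n: int,
    a_paths: Tuple[float, float],
    b_paths: Tuple[float, float],
    c_prime: float,
    seed: int = 0,
    mediator_resid_corr: float = 0.0,
) -> pd.DataFrame:
    """Simulate (x, m1, m2, y) from a two-mediator linear path model with
    standard-normal x and unit-variance structural residuals.

    The generating proportion mediated is
    (a1*b1 + a2*b2) / (c_prime + a1*b1 + a2*b2).
    """
    rng = np.random.default_rng(seed)
    x = rng.standard_normal(n)
    e1 = rng.standard_normal(n)
    e2r = rng.standard_normal(n)
    e2 = mediator_resid_corr * e1 + np.sqrt(1 - mediator_resid_corr**2) * e2r
    ey = rng.standard_normal(n)
    a1, a2 = a_paths
    b1, b2 = b_paths
    m1 = a1 * x + e1
    m2 = a2 * x + e2
    y = c_prime * x + b1 * m1 + b2 * m2 + ey
    return pd.DataFrame({"x": x, "m1": m1, "m2": m2, "y": y})
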