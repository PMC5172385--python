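import numpy as np
import pandas as pd
import pytest

from dediffwm.cohort import (
    GeneratingModel,
    MeasureModel,
    apply_exclusion_cascade,
    default_generating_model,
    generate_cohort,
)
from dediffwm.tracts import core_tract_entries


def single_measure_model(
    measure: str = "FA",
    loading_moderation: float = 0.0,
    unique_moderation: float = 0.0,
    n_entries: int | None = None,
    loading=None,
    age_slope=0.0,
    sex_effect=0.1,
    residual_pairs=None,
    factor_age_path: float = 0.0,
) -> GeneratingModel:
    """A one-measure generating model over the 22 core entries (or a subset)
    with unit total variance per entry at the centering age."""
    entries = core_tract_entries()
    if n_entries is not None:
        entries = entries[:n_entries]
    p = len(entries)
    if loading is None:
        spread = 0.85 + 0.30 * (np.arange(p) % 7) / 6.0
        lam = np.sqrt(0.414) * spread
        lam *= np.sqrt(0.414 / np.mean(lam**2))
        loading = pd.Series(lam, index=entries)
    else:
        loading = pd.Series(loading, index=entries) if np.isscalar(loading) else pd.Series(loading)
    unique_sd = np.sqrt(1.0 - loading**2)
    mm = MeasureModel.build(
        entries=entries,
        age_slope=age_slope,
        sex_effect=sex_effect,
        loading=loading,
        unique_sd=unique_sd,
        loading_moderation=loading_moderation,
        unique_moderation=unique_moderation,
        residual_pairs=residual_pairs,
    )
    return GeneratingModel(
        measures={measure: mm},
        factor_age_paths={measure: factor_age_path} if factor_age_path else {},
        fa_mediation=None,
        volumetrics={},
        flag_counts=None,
    )


@pytest.fixture(scope="session")
def default_cohort():
    """Retained default cohort (all measures, full cascade), n = 3513."""
    gm = default_generating_model()
    subjects, table = generate_cohort(gm, n_raw=5455, seed=11)
    retained, counts = apply_exclusion_cascade(subjects)
    return gm, table.subset_subjects(retained["subject_id"]), counts


@pytest.fixture(scope="session")
def small_cohort():
    """Small single-measure cohort for fast unit tests."""
    gm = single_measure_model(loading_moderation=0.010)
    subjects, table = generate_cohort(gm, n_raw=1200, seed=3)
    return gm, table
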