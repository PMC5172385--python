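"""Per-tract regressions, Williams's t, power utility, age-group heatmaps."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from dediffwm.cohort import generate_cohort
from dediffwm.table import TractMetricTable
from dediffwm.tract_effects import (
    age_group_correlations,
    detectable_effect,
    fit_tract_regression,
    handedness_check,
    williams_t,
)
from conftest import single_measure_model


def _bivariate_table(n=3500, beta=-0.3, seed=0, tract="SLF", measure="FA"):
    """Minimal stacked-hemisphere table with a known standardized age slope."""
    rng = np.random.default_rng(seed)
    age = rng.uniform(44.6, 77.1, n)
    az = (age - age.mean()) / age.std()
    sex = rng.integers(0, 2, n)
    rows = []
    ids = [f"S{i}" for i in range(n)]
    for hemi in ("left", "right"):
        val = beta * az + np.sqrt(1 - beta**2) * rng.standard_normal(n)
        rows.append(pd.DataFrame({
            "subject_id": ids, "tract": tract, "hemisphere": hemi,
            "measure": measure, "value": val,
        }))
    cov = pd.DataFrame({"age": age, "sex": sex}, index=pd.Index(ids, name="subject_id"))
    return TractMetricTable(long=pd.concat(rows, ignore_index=True), covariates=cov)


class TestTractRegression:
    def test_recovers_generating_age_slope(self):
        table = _bivariate_table(beta=-0.3, seed=1)
        res = fit_tract_regression(table, "SLF", "FA")
        assert res.beta_age == pytest.approx(-0.3, abs=0.05)
        assert res.coefficients.loc["age_z", "p"] < 0.001

    def test_bivariate_beta_equals_pearson_r(self):
        # with age as the only informative predictor and balanced noise,
        # the standardized beta of a y ~ age model equals Pearson r
        rng = np.random.default_rng(2)
        n = 500
        age = rng.uniform(45, 77, n)
        y = 0.4 * age + rng.standard_normal(n) * 5
        az = (age - age.mean()) / age.std()
        yz = (y - y.mean()) / y.std()
        beta = np.linalg.lstsq(az[:, None], yz, rcond=None)[0][0]
        assert beta == pytest.approx(stats.pearsonr(age, y)[0], abs=1e-10)

    def test_permuted_outcome_gives_null_effects(self):
        hits = 0
        for rep in range(40):
            table = _bivariate_table(n=3500, beta=0.0, seed=100 + rep)
            res = fit_tract_regression(table, "SLF", "FA")
            if abs(res.beta_age) < 0.05 and res.coefficients["p"].min() >= 0.001:
                hits += 1
        assert hits >= 38  # >= 95% of null replicates clean

    def test_quadratic_type_one_error_controlled(self):
        quad = 0
        reps = 60
        for rep in range(reps):
            table = _bivariate_table(n=800, beta=-0.2, seed=500 + rep)
            res = fit_tract_regression(table, "SLF", "FA")
            quad += res.form == "quadratic"
        assert quad / reps <= 0.12  # nominal 5% improvement test

    def test_strong_curvature_selects_quadratic(self):
        rng = np.random.default_rng(7)
        n = 3500
        age = rng.uniform(44.6, 77.1, n)
        az = (age - age.mean()) / age.std()
        ids = [f"S{i}" for i in range(n)]
        val = 0.2 * az + 0.2 * az**2 + rng.standard_normal(n)
        long = pd.DataFrame({"subject_id": ids, "tract": "FMaj",
                             "hemisphere": "midline", "measure": "MD", "value": val})
        cov = pd.DataFrame({"age": age, "sex": rng.integers(0, 2, n)},
                           index=pd.Index(ids, name="subject_id"))
        res = fit_tract_regression(TractMetricTable(long=long, covariates=cov), "FMaj", "MD")
        assert res.form == "quadratic"
        assert res.coefficients.loc["age_z2", "beta"] == pytest.approx(0.2, abs=0.05)
        assert "hemisphere" not in res.coefficients.index  # midline: no term

    def test_too_few_rows_rejected(self):
        table = _bivariate_table(n=20, seed=3)
        with pytest.raises(ValueError, match="50"):
            fit_tract_regression(table, "SLF", "FA")


class TestWilliamsT:
    def test_zero_when_correlations_equal(self):
        res = williams_t(0.4, 0.4, 0.2, 100)
        assert res.t == 0.0
        assert res.p == pytest.approx(1.0)

    def test_matches_independent_formula(self):
        # independently coded reference: Williams (1959) as given by Steiger
        def reference(rja, rka, rjk, n):
            detR = 1 - rja**2 - rka**2 - rjk**2 + 2 * rja * rka * rjk
            rbar = (rja + rka) / 2
            num = (rja - rka) * np.sqrt((n - 1) * (1 + rjk))
            den = np.sqrt(2 * detR * (n - 1) / (n - 3) + rbar**2 * (1 - rjk) ** 3)
            return num / den

        res = williams_t(0.5, 0.3, 0.6, 100)
        assert res.t == pytest.approx(reference(0.5, 0.3, 0.6, 100), abs=1e-6)
        assert res.df == 97

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        rja=st.floats(-0.8, 0.8),
        rka=st.floats(-0.8, 0.8),
        rjk=st.floats(-0.5, 0.9),
        n=st.integers(10, 5000),
    )
    def test_antisymmetric_under_swap(self, rja, rka, rjk, n):
        try:
            a = williams_t(rja, rka, rjk, n)
            b = williams_t(rka, rja, rjk, n)
        except ValueError:
            return  # degenerate configuration rejected consistently
        assert a.t == pytest.approx(-b.t, abs=1e-12)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            williams_t(1.0, 0.3, 0.2, 100)
        with pytest.raises(ValueError):
            williams_t(0.5, 0.3, 0.2, 3)


class TestDetectableEffect:
    def test_monotone_decreasing_in_n_and_alpha(self):
        ns = [100, 500, 1000, 5000]
        vals = [detectable_effect(n, 0.05, 0.8) for n in ns]
        assert all(a > b for a, b in zip(vals, vals[1:]))
        assert detectable_effect(1000, 0.01, 0.8) > detectable_effect(1000, 0.10, 0.8)

    def test_half_power_matches_fisher_z_critical_point(self):
        # at power 0.5 the detectable effect sits at the critical value
        # z_{0.975}/sqrt(n-3) of the Fisher-z test
        n = 2000
        expected = np.tanh(stats.norm.isf(0.025) / np.sqrt(n - 3))
        assert detectable_effect(n, 0.05, 0.5, method="fisher") == pytest.approx(
            expected, abs=5e-4
        )

    def test_infeasible_inputs_rejected(self):
        with pytest.raises(ValueError):
            detectable_effect(2, 0.05, 0.8)
        with pytest.raises(ValueError):
            detectable_effect(100, 0.05, 1.5)


class TestAgeGroupCorrelations:
    EDGES = [(44.64, 49.98), (50.05, 54.99), (55.0, 60.0),
             (60.01, 65.0), (65.0, 70.0), (70.0, 77.12)]

    def test_moderated_cohort_shows_rising_mean_correlation(self):
        gm = single_measure_model(loading_moderation=0.013)
        _, table = generate_cohort(gm, n_raw=12000, seed=8)
        res = age_group_correlations(table, self.EDGES, measures=["FA"])
        means = res.mean_offdiagonal("FA")
        assert all(b > a for a, b in zip(means, means[1:]))

    def test_unmoderated_cohort_flat(self):
        gm = single_measure_model()
        _, table = generate_cohort(gm, n_raw=12000, seed=9)
        means = age_group_correlations(table, self.EDGES, measures=["FA"]).mean_offdiagonal("FA")
        assert max(means) - min(means) < 0.06

    def test_degenerate_bin_omitted(self):
        gm = single_measure_model()
        _, table = generate_cohort(gm, n_raw=60, seed=1)
        # restrict to a single subject: every matrix undefined
        one = table.subset_subjects(table.covariates.index[:1])
        with pytest.warns(UserWarning):
            res = age_group_correlations(one, [(44.0, 78.0)], measures=["FA"])
        assert res.matrices[("FA", 0)] is None


class TestHandedness:
    def test_identical_groups_give_zero_d(self):
        # left-handers carry byte-identical values to the right-handers
        gm = single_measure_model()
        _, table = generate_cohort(gm, n_raw=100, seed=2)
        base = table.long.copy()
        mirror = base.copy()
        mirror["subject_id"] = "L" + mirror["subject_id"]
        cov_r = table.covariates.copy()
        cov_r["handedness"] = "right"
        cov_l = table.covariates.copy()
        cov_l.index = "L" + cov_l.index
        cov_l["handedness"] = "left"
        tbl = TractMetricTable(
            long=pd.concat([base, mirror], ignore_index=True),
            covariates=pd.concat([cov_r, cov_l]),
        )
        res = handedness_check(tbl)
        assert res["cohens_d"].abs().max() == 0.0
        assert res["t"].abs().max() == 0.0

    def test_planted_difference_recovered(self):
        gm = single_measure_model()
        subjects, table = generate_cohort(gm, n_raw=3500, seed=13)
        cov = table.covariates.copy()
        rng = np.random.default_rng(0)
        cov["handedness"] = np.where(rng.random(len(cov)) < 0.1, "left", "right")
        # plant d = 0.2 on one entry for right-handers
        long = table.long.copy()
        right_ids = set(cov.index[cov["handedness"] == "right"])
        mask = (
            (long["tract"] == "SLF") & (long["hemisphere"] == "left")
            & long["subject_id"].isin(right_ids)
        )
        long.loc[mask, "value"] += 0.2
        tbl = TractMetricTable(long=long, covariates=cov)
        res = handedness_check(tbl)
        row = res[res["entry"] == "SLF_L"].iloc[0]
        assert row["cohens_d"] == pytest.approx(0.2, abs=0.08)

    def test_empty_group_rejected(self):
        gm = single_measure_model()
        _, table = generate_cohort(gm, n_raw=100, seed=1)
        table.covariates["handedness"] = "right"
        with pytest.raises(ValueError, match="non-empty"):
            handedness_check(table)
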