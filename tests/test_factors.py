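"""One-factor models: recovery, pruning, modification, scores, pathways."""

import numpy as np
import pandas as pd
import pytest

from dediffwm.cohort import generate_cohort, true_communality
from dediffwm.factors import (
    add_residual_covariances,
    eigen_spectrum,
    factor_scores,
    fit_gtr,
    fit_one_factor,
    fit_pathway_models,
    prune_low_loadings,
)
from dediffwm.table import TractMetricTable
from dediffwm.tracts import core_tract_entries
from conftest import single_measure_model


class TestEigenSpectrum:
    def test_identity_correlation_gives_unit_eigenvalues(self):
        rng = np.random.default_rng(0)
        gm = single_measure_model(loading=1e-6, n_entries=6)
        _, table = generate_cohort(gm, n_raw=4000, seed=0)
        spec = eigen_spectrum(table, "FA")
        assert spec.eigenvalues == pytest.approx(np.ones(6), abs=0.12)
        assert spec.eigenvalues.sum() == pytest.approx(6.0, abs=1e-8)

    def test_single_factor_share_matches_closed_form(self):
        # uniform loadings: first eigenvalue share = h + (1 - h)/p
        gm = single_measure_model(loading=np.sqrt(0.41))
        _, table = generate_cohort(gm, n_raw=20000, seed=1)
        spec = eigen_spectrum(table, "FA")
        expected = 0.41 + (1 - 0.41) / 22
        assert spec.first_factor_share == pytest.approx(expected, abs=0.02)

    def test_weak_first_factor_flagged(self):
        gm = single_measure_model(loading=0.2, n_entries=10)
        _, table = generate_cohort(gm, n_raw=4000, seed=2)
        spec = eigen_spectrum(table, "FA")
        assert spec.weak_first_factor  # share ~ 0.04 + 0.096 < 0.15


class TestOneFactorFit:
    def test_loadings_recovered_within_tolerance(self):
        gm = single_measure_model()
        _, table = generate_cohort(gm, n_raw=3500, seed=4)
        fit = fit_one_factor(table, "FA", compute_se=False)
        true = gm.measures["FA"].loading.reindex(fit.entries_)
        assert np.max(np.abs(fit.loadings_ - true)) < 0.05
        true_uni = gm.measures["FA"].unique_sd.reindex(fit.entries_)
        assert np.max(np.abs(fit.unique_sd_ - true_uni)) < 0.05

    def test_variance_explained_matches_mean_true_communality(self):
        gm = single_measure_model()
        _, table = generate_cohort(gm, n_raw=10000, seed=5)
        fit = fit_one_factor(table, "FA", compute_se=False)
        truth = np.mean(
            [true_communality(gm, "FA", e, 60.0) for e in fit.entries_]
        )
        assert fit.variance_explained_ == pytest.approx(truth, abs=0.02)

    def test_just_identified_three_tracts(self):
        gm = single_measure_model(n_entries=3)
        _, table = generate_cohort(gm, n_raw=2000, seed=6)
        fit = fit_one_factor(table, "FA", entries=gm.measures["FA"].entries, compute_se=False)
        assert fit.df_ == 0
        assert fit.chisq_ == pytest.approx(0.0, abs=1e-4 * fit.n_)

    def test_default_calibration_variance_shares(self, default_cohort):
        # the default cohort is calibrated so the general factor explains
        # roughly 41% of FA variance and 68% of ICVF variance
        _, table, _ = default_cohort
        fa = fit_one_factor(table, "FA", compute_se=False).variance_explained_
        icvf = fit_one_factor(table, "ICVF", compute_se=False).variance_explained_
        assert fa == pytest.approx(0.414, abs=0.10)
        assert icvf == pytest.approx(0.682, abs=0.10)

    def test_self_consistency_on_resimulated_estimates(self):
        gm = single_measure_model()
        _, table = generate_cohort(gm, n_raw=3000, seed=7)
        fit = fit_one_factor(table, "FA", compute_se=False)
        gm2 = single_measure_model(loading=fit.loadings_)
        _, table2 = generate_cohort(gm2, n_raw=10000, seed=8)
        fit2 = fit_one_factor(table2, "FA", compute_se=False)
        assert np.max(np.abs(fit2.loadings_ - fit.loadings_)) < 0.04


class TestPruning:
    def test_strong_loadings_nothing_pruned(self):
        gm = single_measure_model(loading=0.6, n_entries=8)
        _, table = generate_cohort(gm, n_raw=2000, seed=9)
        fit = fit_one_factor(table, "FA", entries=gm.measures["FA"].entries, compute_se=False)
        assert prune_low_loadings(fit) == []
        assert prune_low_loadings(fit, threshold=0.0) == []

    def test_planted_weak_tracts_flagged(self):
        entries = core_tract_entries()
        loading = pd.Series(0.65, index=entries)
        weak = entries[:5]
        loading[weak] = 0.10
        gm = single_measure_model(loading=loading)
        _, table = generate_cohort(gm, n_raw=3500, seed=10)
        fit = fit_one_factor(table, "FA", compute_se=False)
        assert sorted(prune_low_loadings(fit)) == sorted(weak)


class TestResidualCovariances:
    def test_null_data_adds_no_pairs(self):
        added = 0
        for rep in range(10):
            gm = single_measure_model(n_entries=8)
            _, table = generate_cohort(gm, n_raw=1500, seed=20 + rep)
            fit = fit_one_factor(table, "FA", entries=gm.measures["FA"].entries,
                                 compute_se=False)
            aug = add_residual_covariances(table, "FA", fit, max_pairs=3)
            added += len(aug.pairs_) > 0
        assert added <= 1  # p < 0.001 stop rule keeps null additions rare

    def test_planted_homologue_pair_found_first(self):
        gm = single_measure_model(residual_pairs=[("SLF_L", "SLF_R", 0.25)])
        _, table = generate_cohort(gm, n_raw=3500, seed=30)
        fit = fit_one_factor(table, "FA", compute_se=False)
        aug = add_residual_covariances(table, "FA", fit, max_pairs=3)
        assert len(aug.pairs_) >= 1
        assert tuple(sorted(aug.pairs_[0])) == ("SLF_L", "SLF_R")
        assert aug.loglik_ > fit.loglik_  # adding a real pair helps

    def test_max_pairs_zero_keeps_fit(self):
        gm = single_measure_model(n_entries=6)
        _, table = generate_cohort(gm, n_raw=1000, seed=31)
        fit = fit_one_factor(table, "FA", entries=gm.measures["FA"].entries, compute_se=False)
        aug = add_residual_covariances(table, "FA", fit, max_pairs=0)
        assert aug is fit


class TestFactorScores:
    def test_reliability_bound_against_true_factor(self):
        gm = single_measure_model()
        rng_entries = gm.measures["FA"].entries
        _, table = generate_cohort(gm, n_raw=4000, seed=40)
        fit = fit_one_factor(table, "FA", compute_se=False)
        scores = factor_scores(fit)
        # reconstruct the generating factor from the basis representation
        lam = gm.measures["FA"].loading.reindex(fit.entries_).to_numpy()
        uni = gm.measures["FA"].unique_sd.reindex(fit.entries_).to_numpy()
        rel = (lam**2 / uni**2).sum() / (1 + (lam**2 / uni**2).sum())
        wide = table.wide("FA", fit.entries_)
        resid = wide - wide.mean()
        # proxy truth: factor reconstruction from generating parameters
        g_hat = (resid / uni**2 * lam).sum(axis=1) / (1 + (lam**2 / uni**2).sum())
        r = np.corrcoef(scores, g_hat)[0, 1]
        assert r >= np.sqrt(rel) - 0.03

    def test_single_indicator_score_proportional_to_residual(self):
        gm = single_measure_model(n_entries=3)
        _, table = generate_cohort(gm, n_raw=1000, seed=41)
        fit = fit_one_factor(table, "FA", entries=gm.measures["FA"].entries, compute_se=False)
        # score a frame with two of three entries missing
        X = fit.design_.copy()
        kept = fit.entries_[0]
        for e in fit.entries_[1:]:
            X[e] = np.nan
        s = fit.transform(X)
        resid = fit.design_[kept] - fit.covariate_paths_[kept]["const"] - (
            fit.design_[fit.covariate_cols] @ fit.covariate_paths_[kept][fit.covariate_cols]
        )
        assert abs(np.corrcoef(s, resid)[0, 1]) == pytest.approx(1.0, abs=1e-10)

    def test_score_variance_at_most_one_and_mean_zero(self):
        gm = single_measure_model()
        _, table = generate_cohort(gm, n_raw=3000, seed=42)
        fit = fit_one_factor(table, "FA", compute_se=False)
        s = factor_scores(fit)
        assert abs(s.mean()) < 0.05
        assert s.var() <= 1.0 + 1e-6

    def test_permuted_data_scores_uncorrelated_with_anything(self):
        gm = single_measure_model()
        _, table = generate_cohort(gm, n_raw=2000, seed=43)
        fit = fit_one_factor(table, "FA", compute_se=False)
        rng = np.random.default_rng(0)
        X = fit.design_.copy()
        perm = rng.permutation(len(X))
        X[fit.entries_] = X[fit.entries_].to_numpy()[perm]
        s_perm = fit.transform(X)
        s_orig = factor_scores(fit)
        assert abs(np.corrcoef(s_perm, s_orig)[0, 1]) < 0.06


class TestPathwayModels:
    def test_structural_parameter_ordering(self, small_cohort):
        _, table = small_cohort
        cmp_ = fit_pathway_models(table, "FA", max_selected=2)
        k = {name: f["n_params"] for name, f in cmp_.fits.items()}
        assert k["independent"] > k["common"]
        assert k["common_independent"] >= k["common"]
        ll = {name: f["loglik"] for name, f in cmp_.fits.items()}
        assert ll["common_independent"] >= ll["common"] - 1e-6  # nesting

    def test_common_truth_selects_no_tract_paths(self):
        hits = 0
        for rep in range(5):
            gm = single_measure_model(n_entries=8, factor_age_path=0.4)
            _, table = generate_cohort(gm, n_raw=2500, seed=50 + rep)
            cmp_ = fit_pathway_models(table, "FA", entries=gm.measures["FA"].entries,
                                      max_selected=4)
            if len(cmp_.selected_paths) == 0:
                hits += 1
        assert hits >= 4  # alpha = 0.05 selection on common-truth data

    def test_planted_tract_paths_recovered(self):
        entries = core_tract_entries()[:8]
        age_slope = pd.Series(0.0, index=entries)
        age_slope[["ATR_L", "ATR_R"]] = 0.25
        gm = single_measure_model(n_entries=8, factor_age_path=0.4, age_slope=age_slope)
        _, table = generate_cohort(gm, n_raw=3000, seed=60)
        cmp_ = fit_pathway_models(table, "FA", entries=entries, max_selected=4)
        assert {"ATR_L", "ATR_R"} <= set(cmp_.selected_paths)
        assert cmp_.fits["common_independent"]["bic"] < cmp_.fits["common"]["bic"]


class TestThalamicComposite:
    def test_perfectly_correlated_inputs_equal_zscored_mean(self):
        rng = np.random.default_rng(1)
        n = 500
        base = rng.standard_normal(n)
        ids = [f"S{i}" for i in range(n)]
        rows = []
        for entry in ["ATR_L", "ATR_R", "STR_L", "STR_R", "PTR_L", "PTR_R"]:
            tract, hemi = entry[:-2], {"L": "left", "R": "right"}[entry[-1]]
            rows.append(pd.DataFrame({
                "subject_id": ids, "tract": tract, "hemisphere": hemi,
                "measure": "MD", "value": 2.0 * base + 1.0,
            }))
        cov = pd.DataFrame({"age": rng.uniform(45, 77, n), "sex": rng.integers(0, 2, n)},
                           index=pd.Index(ids, name="subject_id"))
        res = fit_gtr(TractMetricTable(long=pd.concat(rows, ignore_index=True),
                                       covariates=cov), "MD")
        z = (base - base.mean()) / base.std()
        assert np.abs(res["scores"].to_numpy() - z).max() < 1e-8
        assert res["explained_variance"] == pytest.approx(6.0, abs=1e-6)

    def test_symmetric_block_gives_uniform_loadings(self, default_cohort):
        _, table, _ = default_cohort
        res = fit_gtr(table, "MD")
        v = res["loadings"].to_numpy()
        assert np.max(np.abs(np.abs(v) - np.mean(np.abs(v)))) < 0.05
        # component variance equals the top eigenvalue by construction
        wide = table.wide("MD", res["loadings"].index)
        R = wide.corr().to_numpy()
        assert res["explained_variance"] == pytest.approx(np.linalg.eigvalsh(R)[-1], abs=1e-8)
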