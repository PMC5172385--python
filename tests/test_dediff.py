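"""Age-moderated factor models, communality curves and LOSEM."""

import numpy as np
import pytest
from scipy import optimize

from dediffwm._covstruct import mnlfa_nll
from dediffwm.cohort import generate_cohort, true_communality
from dediffwm.dediff import (
    ANCHOR_AGES,
    communality_curve,
    communality_delta,
    fit_losem,
    fit_moderated_factor,
    moderation_lr_test,
)
from dediffwm.dediff import test_moderation_significance as moderation_wald_table
from dediffwm.factors import fit_one_factor
from conftest import single_measure_model


class TestLikelihoodMachinery:
    def test_analytic_gradient_matches_numeric(self):
        rng = np.random.default_rng(0)
        n, p = 300, 5
        lam = rng.uniform(0.4, 0.8, p)
        uni = rng.uniform(0.5, 0.9, p)
        age = rng.uniform(-1.5, 1.5, n)
        E = lam * rng.standard_normal((n, 1)) + uni * rng.standard_normal((n, p))
        for mode, nm in (("invariant", 1), ("tract_specific", p)):
            th = np.concatenate([lam, uni, 0.05 * np.ones(nm), -0.02 * np.ones(nm)])

            def f(t):
                return mnlfa_nll(t[:p], t[p:2*p], t[2*p:2*p+nm], t[2*p+nm:], E, age)

            _, g = mnlfa_nll(th[:p], th[p:2*p], th[2*p:2*p+nm], th[2*p+nm:],
                             E, age, grad_mode=mode)
            gn = optimize.approx_fprime(th, f, 1e-7)
            assert np.max(np.abs(g - gn) / (np.abs(gn) + 1e-4)) < 1e-3

    def test_masked_likelihood_equals_complete_on_full_mask(self):
        rng = np.random.default_rng(1)
        n, p = 100, 4
        E = rng.standard_normal((n, p))
        age = rng.uniform(-1, 1, n)
        lam = np.full(p, 0.6); uni = np.full(p, 0.8)
        full = mnlfa_nll(lam, uni, 0.1, 0.0, E, age)
        masked = mnlfa_nll(lam, uni, 0.1, 0.0, E, age, mask=np.ones((n, p), bool))
        assert full == pytest.approx(masked, rel=1e-12)


class TestModeratedFit:
    def test_null_data_keeps_moderation_near_zero(self):
        gm = single_measure_model()  # no moderation
        _, table = generate_cohort(gm, n_raw=3500, seed=70)
        fit = fit_moderated_factor(table, "FA")
        se = fit.moderation_se_
        assert abs(fit.loading_moderation_.iloc[0]) < 2.5 * se["loading_moderation"].iloc[0] + 1e-4
        null = fit_moderated_factor(table, "FA", fix_moderation=True, compute_se=False)
        lr = moderation_lr_test(fit, null)
        assert lr["lr"] >= -1e-6  # nesting: moderated likelihood never lower
        assert lr["df"] == 2

    def test_moderation_slope_recovered(self):
        gm = single_measure_model(loading_moderation=0.013)
        _, table = generate_cohort(gm, n_raw=3500, seed=71)
        fit = fit_moderated_factor(table, "FA")
        est = fit.loading_moderation_.iloc[0]
        se = fit.moderation_se_["loading_moderation"].iloc[0]
        assert est == pytest.approx(0.013, abs=2.5 * se)
        assert est > 0

    def test_nesting_chain_invariant_subset_tract_specific(self):
        gm = single_measure_model(loading_moderation=0.010)
        _, table = generate_cohort(gm, n_raw=2500, seed=72)
        base = fit_moderated_factor(table, "FA", fix_moderation=True, compute_se=False)
        inv = fit_moderated_factor(table, "FA", compute_se=False)
        ts = fit_moderated_factor(table, "FA", mode="tract_specific", compute_se=False)
        assert base.loglik_ <= inv.loglik_ + 1e-6
        assert inv.loglik_ <= ts.loglik_ + 1e-6

    def test_oracle_equivalence_with_unmoderated_fit(self):
        gm = single_measure_model(loading_moderation=0.010)
        _, table = generate_cohort(gm, n_raw=2000, seed=73)
        one = fit_one_factor(table, "FA", compute_se=False)
        fixed = fit_moderated_factor(table, "FA", base_fit=one, fix_moderation=True,
                                     compute_se=False)
        assert np.max(np.abs(one.loadings_ - fixed.loadings_)) < 1e-4
        assert np.max(np.abs(one.unique_sd_ - fixed.unique_sd_)) < 1e-4

    def test_reparameterization_invariance_of_centering(self):
        # an exact reparameterization maps the center-60 solution onto any
        # other centering; likelihood and communality are unchanged
        gm = single_measure_model(loading_moderation=0.012)
        _, table = generate_cohort(gm, n_raw=2000, seed=74)
        f60 = fit_moderated_factor(table, "FA", age_center=60.0, compute_se=False)
        f55 = fit_moderated_factor(table, "FA", age_center=55.0, compute_se=False)
        assert f60.loglik_ == pytest.approx(f55.loglik_, abs=1e-3)
        ages = np.linspace(46, 74, 15)
        h60 = f60.communality(ages)["mean"].to_numpy()
        h55 = f55.communality(ages)["mean"].to_numpy()
        assert np.max(np.abs(h60 - h55)) < 1e-4

    def test_wald_table_power_on_planted_tract_moderation(self):
        entries = None
        gm = single_measure_model(loading_moderation=0.0)
        mm = gm.measures["FA"]
        planted = mm.entries[:3]
        mm.loading_moderation[planted] = 0.02
        _, table = generate_cohort(gm, n_raw=3500, seed=75)
        fit = fit_moderated_factor(table, "FA", mode="tract_specific")
        tab = moderation_wald_table(fit)
        lt = tab[(tab["parameter"] == "loading_moderation") & tab["entry"].isin(planted)]
        assert (lt["p"] < 0.05).sum() >= 2  # power for l1m' = 0.02/yr
        null_rows = tab[(tab["parameter"] == "loading_moderation")
                        & ~tab["entry"].isin(planted)]
        assert (null_rows["p"] < 0.05).mean() < 0.3


class TestCommunalityCurve:
    def test_flat_without_moderation(self):
        gm = single_measure_model()
        _, table = generate_cohort(gm, n_raw=3000, seed=80)
        fit = fit_moderated_factor(table, "FA", fix_moderation=True, compute_se=False)
        curve = communality_curve(fit)
        assert np.ptp(curve.mean) < 1e-10
        delta, _ = communality_delta(fit)
        assert delta == pytest.approx(0.0, abs=1e-10)

    def test_curve_passes_through_anchors(self):
        gm = single_measure_model(loading_moderation=0.013)
        _, table = generate_cohort(gm, n_raw=2500, seed=81)
        fit = fit_moderated_factor(table, "FA")
        grid = np.arange(45.0, 75.01, 0.25)
        curve = communality_curve(fit, grid=grid)
        for a, h in zip(curve.anchor_ages, curve.anchor_mean):
            j = np.argmin(np.abs(grid - a))
            assert curve.mean[j] == pytest.approx(h, abs=1e-10)

    def test_monotone_between_monotone_anchors(self):
        gm = single_measure_model(loading_moderation=0.013)
        _, table = generate_cohort(gm, n_raw=2500, seed=82)
        fit = fit_moderated_factor(table, "FA")
        curve = communality_curve(fit)
        assert np.all(np.diff(curve.mean) > -1e-9)

    def test_delta_sign_flips_with_negated_moderation(self):
        gm_pos = single_measure_model(loading_moderation=0.010)
        gm_neg = single_measure_model(loading_moderation=-0.010)
        _, t_pos = generate_cohort(gm_pos, n_raw=2500, seed=83)
        _, t_neg = generate_cohort(gm_neg, n_raw=2500, seed=83)
        d_pos, _ = communality_delta(fit_moderated_factor(t_pos, "FA", compute_se=False))
        d_neg, _ = communality_delta(fit_moderated_factor(t_neg, "FA", compute_se=False))
        assert d_pos > 0 > d_neg

    def test_out_of_range_delta_rejected(self):
        gm = single_measure_model()
        _, table = generate_cohort(gm, n_raw=1500, seed=84)
        fit = fit_moderated_factor(table, "FA", compute_se=False)
        with pytest.raises(ValueError, match="range"):
            communality_delta(fit, age_lo=10, age_hi=75)


class TestLosem:
    def test_flat_loadings_without_moderation(self):
        gm = single_measure_model()
        _, table = generate_cohort(gm, n_raw=4000, seed=90)
        res = fit_losem(table, "FA", n_targets=15)
        h = res.mean_communality.to_numpy()
        truth = np.mean([true_communality(gm, "FA", e, 60.0) for e in gm.measures["FA"].entries])
        assert np.nanmax(np.abs(h - truth)) < 0.05

    def test_infinite_bandwidth_recovers_global_fit(self):
        gm = single_measure_model(loading_moderation=0.012)
        _, table = generate_cohort(gm, n_raw=2000, seed=91)
        res = fit_losem(table, "FA", n_targets=5, bandwidth=1e6)
        fit = fit_one_factor(table, "FA", compute_se=False)
        for a0 in res.targets:
            assert np.allclose(
                res.loadings.loc[a0].to_numpy(), fit.loadings_.to_numpy(), atol=5e-3
            )

    def test_trajectory_tracks_truth_on_interior(self):
        gm = single_measure_model(loading_moderation=0.013)
        _, table = generate_cohort(gm, n_raw=3500, seed=92)
        res = fit_losem(table, "FA", n_targets=30)
        truth = np.array([
            np.mean([true_communality(gm, "FA", e, a) for e in gm.measures["FA"].entries])
            for a in res.targets
        ])
        interior = (res.targets >= 48) & (res.targets <= 72)
        dev = np.abs(res.mean_communality.to_numpy() - truth)[interior]
        assert np.nanmax(dev) < 0.04

    def test_low_effective_n_targets_flagged(self):
        gm = single_measure_model()
        _, table = generate_cohort(gm, n_raw=600, seed=93)
        res = fit_losem(table, "FA", n_targets=10, age_lo=50, age_hi=70,
                        min_effective_n=1e5)
        assert len(res.flagged) == 10
        assert res.communality.isna().all().all() or res.communality["mean"].isna().all()
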