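import warnings

import numpy as np
import pandas as pd
import pytest
from scipy.stats import kstest

from cortexmeth import simcohort as sc
from cortexmeth.ewas import (ModelSpec, build_design, fit_site_lmm,
                             joint_pathology_test, per_region_ewas,
                             proportions_vs_pathology, region_interaction_test,
                             run_ewas, vectorized_ols)
from cortexmeth.lmm import fit_random_intercept

from conftest import attach_proportions

COVARS = ("age", "sex", "batch", "prop_NeuN+", "prop_DN")


def _sim_lmm_data(seed, n_donors=120, b=0.5, sd_u=0.8, sd_e=1.0):
    rng = np.random.default_rng(seed)
    donor = np.repeat(np.arange(n_donors), 2)
    n = 2 * n_donors
    X = np.column_stack([np.ones(n), rng.normal(size=n), rng.normal(size=n)])
    y = X @ [1.0, b, -0.3] + sd_u * rng.normal(size=n_donors)[donor] \
        + sd_e * rng.normal(size=n)
    return y, X, donor


class TestRandomInterceptLMM:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_agrees_with_statsmodels_ml(self, seed):
        """Profiled-likelihood fit matches the general mixed-model
        optimizer on coefficients, SEs and log-likelihood."""
        from statsmodels.regression.mixed_linear_model import MixedLM
        y, X, donor = _sim_lmm_data(seed)
        fit = fit_random_intercept(y, X, donor)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ref = MixedLM(y, X, groups=donor).fit(reml=False)
        assert np.allclose(fit.beta, ref.fe_params, atol=1e-5)
        # SEs agree to ~1%; the two fitters scale the fixed-effect
        # covariance slightly differently at the ML optimum
        assert np.allclose(fit.se, ref.bse_fe, rtol=1e-2)
        assert abs(fit.llf - ref.llf) < 1e-5

    @pytest.mark.parametrize("seed", [4, 5, 9])
    def test_zero_group_variance_reduces_to_ols(self, seed):
        """Data generated with no donor variance: fits landing on the
        zero-variance boundary are flagged and reproduce OLS exactly."""
        y, X, donor = _sim_lmm_data(seed, sd_u=0.0)
        fit = fit_random_intercept(y, X, donor)
        assert fit.ols_fallback
        b_ols = np.linalg.lstsq(X, y, rcond=None)[0]
        assert np.allclose(fit.beta, b_ols, atol=1e-6)

    def test_small_variance_estimates_stay_near_ols(self):
        """Even when sampling noise yields a positive variance estimate,
        coefficients remain close to OLS under a true zero variance."""
        for seed in range(4):
            y, X, donor = _sim_lmm_data(seed, sd_u=0.0)
            fit = fit_random_intercept(y, X, donor)
            b_ols = np.linalg.lstsq(X, y, rcond=None)[0]
            assert np.abs(fit.beta - b_ols).max() < 0.02

    def test_zero_variance_response_rejected(self):
        _, X, donor = _sim_lmm_data(4)
        with pytest.raises(ValueError, match="zero variance"):
            fit_random_intercept(np.full(len(donor), 0.5), X, donor)

    def test_wald_internal_consistency(self):
        y, X, donor = _sim_lmm_data(5)
        fit = fit_random_intercept(y, X, donor)
        assert np.all(np.abs(fit.statistic - fit.beta / fit.se) < 1e-6)


class TestFitSiteLMM:
    def test_effect_recovery_coverage(self):
        """y = 0.44 pp per Braak stage + donor effect + noise: the 95% CI
        covers the truth in >= 90% of seeds."""
        rng0 = np.random.default_rng(0)
        patho = sc.make_pathology(300, seed=1)
        covered = 0
        n_seeds = 100
        for _ in range(n_seeds):
            donor = np.repeat(np.arange(300), 2)
            braak = patho["braak_nft"].to_numpy(dtype=float)[donor]
            y = (0.5 + 0.0044 * braak
                 + rng0.normal(0, 0.01, 300)[donor]
                 + rng0.normal(0, 0.02, 600))
            X = np.column_stack([np.ones(600), braak])
            fit = fit_random_intercept(y, X, donor)
            lo = fit.beta[1] * 100 - 1.96 * fit.se[1] * 100
            hi = fit.beta[1] * 100 + 1.96 * fit.se[1] * 100
            covered += lo <= 0.44 <= hi
        assert covered >= 0.9 * n_seeds

    def test_constant_probe_raises_zero_variance(self, cohort):
        pheno = attach_proportions(cohort)
        y = pd.Series(0.5, index=pheno.index)
        spec = ModelSpec(predictors=("braak_nft",), covariates=COVARS)
        with pytest.raises(ValueError, match="zero variance"):
            fit_site_lmm(y, pheno, spec)

    def test_coefficient_table_reports_percentage_points(self, cohort):
        pheno = attach_proportions(cohort)
        y = cohort.beta.iloc[0]
        spec = ModelSpec(predictors=("braak_nft",), covariates=COVARS)
        tab = fit_site_lmm(y, pheno, spec)
        assert {"effect", "se", "statistic", "p_value"} <= set(tab.columns)
        assert tab.loc["braak_nft", "se"] > 0
        assert np.isclose(tab.loc["braak_nft", "statistic"],
                          tab.loc["braak_nft", "effect"]
                          / tab.loc["braak_nft", "se"], atol=1e-6)


class TestModelSpec:
    def test_empty_predictors_rejected(self):
        with pytest.raises(ValueError):
            ModelSpec(predictors=())

    def test_three_proportions_rejected(self):
        with pytest.raises(ValueError, match="two cell-proportion"):
            ModelSpec(covariates=("prop_NeuN+", "prop_DN", "prop_SOX10+"))


class TestJointTest:
    def test_identical_full_and_null_models_give_zero_statistic(self, cohort):
        """When the full model adds nothing over the null, the likelihood
        ratio is exactly 0 and p = 1."""
        from scipy.stats import chi2
        pheno = attach_proportions(cohort)
        y = cohort.beta.iloc[3]
        spec = ModelSpec(predictors=("braak_nft", "cerad", "thal"),
                         covariates=COVARS)
        full_X, pred_cols = build_design(pheno, spec)
        null_X = full_X.drop(columns=pred_cols)
        donors = pheno["donor_id"].to_numpy()
        f1 = fit_random_intercept(y.to_numpy(), null_X.to_numpy(), donors)
        f2 = fit_random_intercept(y.to_numpy(), null_X.to_numpy(), donors)
        stat = max(2 * (f1.llf - f2.llf), 0.0)
        assert stat == 0.0
        assert chi2.sf(stat, 3) == 1.0

    def test_strong_effect_reaches_experiment_wide_significance(self, profiles):
        """A 2 pp/stage cell-confined effect at low noise is detected
        below the experiment-wide threshold 9e-8."""
        targets = [p for p, flag, mu in zip(profiles.probe_ids,
                                            profiles.discriminating_mask[:, 2],
                                            profiles.mean_beta[:, 2])
                   if flag and 0.2 < mu < 0.8][:5]
        espec = sc.make_effect_spec(targets, "DN", mean_effect=2.0,
                                    sd_effect=0.0, p_hyper=1.0, seed=2)
        zero = {c: 0.0 for c in sc.CELLTYPES}
        cohort = sc.make_cohort(profiles, n_donors=300, effect_spec=espec,
                                proportion_coupling=zero, noise_sd=0.01,
                                donor_sd=0.005, seed=3)
        pheno = attach_proportions(cohort)
        spec = ModelSpec(covariates=COVARS)
        for probe in targets:
            _, df, p, _ = joint_pathology_test(cohort.beta.loc[probe], pheno, spec)
            assert df == 3
            assert p < 9e-8


class TestRunEwas:
    def test_planted_dmps_recovered_without_false_positives(self, profiles):
        targets = [p for p, flag, mu in zip(profiles.probe_ids,
                                            profiles.discriminating_mask[:, 2],
                                            profiles.mean_beta[:, 2])
                   if flag and 0.2 < mu < 0.8][:20]
        espec = sc.make_effect_spec(targets, "DN", mean_effect=3.0,
                                    sd_effect=0.0, seed=4)
        zero = {c: 0.0 for c in sc.CELLTYPES}
        cohort = sc.make_cohort(profiles, n_donors=250, effect_spec=espec,
                                proportion_coupling=zero, noise_sd=0.02,
                                donor_sd=0.01, seed=5)
        pheno = attach_proportions(cohort)
        table, sig = run_ewas(cohort.beta, pheno,
                              ModelSpec(covariates=COVARS))
        sens = len(set(sig) & set(targets)) / len(targets)
        assert sens >= 0.9
        assert set(sig) <= set(targets)  # no false positives at 9e-8

    def test_pure_null_has_empty_significant_set(self, null_cohort):
        pheno = attach_proportions(null_cohort)
        _, sig = run_ewas(null_cohort.beta, pheno, ModelSpec(covariates=COVARS))
        assert sig == []

    def test_ordering_deterministic(self, null_cohort):
        pheno = attach_proportions(null_cohort)
        spec = ModelSpec(covariates=COVARS)
        t1, _ = run_ewas(null_cohort.beta.iloc[:40], pheno, spec)
        t2, _ = run_ewas(null_cohort.beta.iloc[:40], pheno, spec)
        assert list(t1.index) == list(t2.index)
        assert (t1["p_value"].to_numpy()[:-1]
                <= t1["p_value"].to_numpy()[1:]).all()

    def test_skipped_probe_recorded_and_run_continues(self, null_cohort):
        pheno = attach_proportions(null_cohort)
        beta = null_cohort.beta.iloc[:10].copy()
        beta.iloc[4] = 0.5
        table, _ = run_ewas(beta, pheno, ModelSpec(covariates=COVARS))
        assert len(table) == 10
        assert table.loc[beta.index[4], "flag"].startswith("skipped")


class TestRegionInteraction:
    def test_single_region_rejected(self, cohort):
        pheno = attach_proportions(cohort)
        sub = pheno[pheno["region"] == "DLPFC"]
        spec = ModelSpec(predictors=("braak_nft",), covariates=COVARS)
        with pytest.raises(ValueError, match="both regions"):
            region_interaction_test(cohort.beta.iloc[0][sub.index], sub, spec)

    def test_equal_effects_give_uniform_interaction_pvalues(self, null_cohort):
        pheno = attach_proportions(null_cohort)
        spec = ModelSpec(predictors=("braak_nft",), covariates=COVARS)
        pvals = [region_interaction_test(null_cohort.beta.iloc[i], pheno,
                                         spec)["p_value"].iloc[0]
                 for i in range(60)]
        assert kstest(pvals, "uniform").pvalue > 0.01

    def test_region_confined_composition_effect_detected(self, profiles):
        """Proportion coupling acts in DLPFC only, so discriminating
        probes carry a region-specific slope the interaction test should
        find (power >= 0.8 across probes)."""
        cohort = sc.make_cohort(profiles, n_donors=200, noise_sd=0.03,
                                donor_sd=0.01, seed=6)
        pheno = cohort.phenotypes  # no proportion covariates: leave the
        # composition path open on purpose
        spec = ModelSpec(predictors=("braak_nft",), covariates=("age", "sex",
                                                                "batch"))
        neun_sites = [p for p, flag in zip(profiles.probe_ids,
                                           profiles.discriminating_mask[:, 0])
                      if flag][:20]
        hits = sum(region_interaction_test(cohort.beta.loc[s], pheno,
                                           spec)["p_value"].iloc[0] < 0.05
                   for s in neun_sites)
        assert hits >= 16


class TestPerRegionEwas:
    def test_equivalent_to_single_probe_ols(self, cohort):
        pheno = attach_proportions(cohort)
        spec = ModelSpec(predictors=("braak_nft",), covariates=COVARS)
        table = per_region_ewas(cohort.beta.iloc[:15], pheno, "DLPFC", spec)
        sub = pheno[pheno["region"] == "DLPFC"]
        ospec = ModelSpec(predictors=("braak_nft",), covariates=COVARS,
                          random_intercept=False)
        for probe in cohort.beta.index[:5]:
            row = fit_site_lmm(cohort.beta.loc[probe, sub.index], sub, ospec)
            assert np.isclose(table.loc[probe, "effect"],
                              row.loc["braak_nft", "effect"], atol=1e-8)
            assert np.isclose(table.loc[probe, "p_value"],
                              row.loc["braak_nft", "p_value"], atol=1e-10)

    def test_vectorized_ols_matches_statsmodels(self):
        import statsmodels.api as smapi
        rng = np.random.default_rng(7)
        X = np.column_stack([np.ones(50), rng.normal(size=50),
                             rng.normal(size=50)])
        Y = rng.normal(size=(5, 50))
        B, se, tstat, pvals = vectorized_ols(Y, X)
        for i in range(5):
            ref = smapi.OLS(Y[i], X).fit()
            assert np.allclose(B[i], ref.params, atol=1e-10)
            assert np.allclose(se[i], ref.bse, atol=1e-10)
            assert np.allclose(pvals[i], ref.pvalues, atol=1e-10)

    def test_more_hits_in_coupled_region(self, profiles):
        """With composition coupled to Braak in DLPFC only and the
        composition path left open, DLPFC shows more small p-values than
        OCC at matched thresholds (aggregated across seeds)."""
        spec = ModelSpec(predictors=("braak_nft",),
                         covariates=("age", "sex", "batch"))
        wins = 0
        for seed in range(10):
            cohort = sc.make_cohort(profiles, n_donors=150, noise_sd=0.05,
                                    donor_sd=0.02, seed=100 + seed)
            d = per_region_ewas(cohort.beta, cohort.phenotypes, "DLPFC", spec)
            o = per_region_ewas(cohort.beta, cohort.phenotypes, "OCC", spec)
            wins += ((d["p_value"] < 1e-5).sum() > (o["p_value"] < 1e-5).sum())
        assert wins >= 8


class TestProportionsVsPathology:
    def test_coupling_recovered_in_dlpfc_not_occ(self, profiles):
        cohort = sc.make_cohort(profiles, n_donors=500, seed=8)
        res_d = proportions_vs_pathology(cohort.true_proportions,
                                         cohort.phenotypes, region="DLPFC")
        res_o = proportions_vs_pathology(cohort.true_proportions,
                                         cohort.phenotypes, region="OCC")
        truth = {"NeuN+": -2.74, "SOX10+": 1.60, "DN": -2.00}
        braak_d = res_d[res_d["measure"] == "braak_nft"].set_index("celltype")
        for ct, t in truth.items():
            assert abs(braak_d.loc[ct, "effect"] - t) < 2 * braak_d.loc[ct, "se"]
            assert braak_d.loc[ct, "bonferroni_significant"]
        braak_o = res_o[res_o["measure"] == "braak_nft"]
        assert not braak_o["bonferroni_significant"].any()

    def test_uncoupled_proportions_give_uniform_pvalues(self):
        prof = sc.make_reference_profiles(100, 3, 10, 0.5, seed=9)
        pvals = []
        zero = {c: 0.0 for c in sc.CELLTYPES}
        for seed in range(30):
            cohort = sc.make_cohort(prof, n_donors=80,
                                    proportion_coupling=zero, seed=200 + seed)
            res = proportions_vs_pathology(cohort.true_proportions,
                                           cohort.phenotypes, region="DLPFC")
            pvals.extend(res["p_value"])
        assert kstest(pvals, "uniform").pvalue > 0.01

    def test_bonferroni_cutoff_is_alpha_over_six(self, cohort):
        res = proportions_vs_pathology(cohort.true_proportions,
                                       cohort.phenotypes, region="DLPFC")
        implied = res["p_value"] < 0.05 / 6
        assert (implied == res["bonferroni_significant"]).all()


class TestMonotonicity:
    def test_doubling_effect_never_decreases_median_logp(self, profiles):
        """Dose-response sanity: larger planted effects give smaller
        median p-values across seeds."""
        targets = [p for p, flag, mu in zip(profiles.probe_ids,
                                            profiles.discriminating_mask[:, 2],
                                            profiles.mean_beta[:, 2])
                   if flag and 0.2 < mu < 0.8][:10]
        zero = {c: 0.0 for c in sc.CELLTYPES}
        spec = ModelSpec(predictors=("braak_nft",),
                         covariates=("age", "sex", "batch"))
        med = []
        for eff in (0.5, 1.0, 2.0):
            logp = []
            for seed in range(3):
                espec = sc.EffectSpec(targets, "DN", eff, 1.0)
                cohort = sc.make_cohort(profiles, n_donors=120,
                                        effect_spec=espec,
                                        proportion_coupling=zero,
                                        noise_sd=0.05, donor_sd=0.02,
                                        seed=300 + seed)
                t = per_region_ewas(cohort.beta.loc[targets],
                                    cohort.phenotypes, "DLPFC", spec)
                logp.extend(-np.log10(t["p_value"]))
            med.append(np.median(logp))
        assert med[0] <= med[1] <= med[2]
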