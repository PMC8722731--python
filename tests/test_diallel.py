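"""REML diallel models: closed-form oracles, recovery, model selection,
derived inbreeding-depression quantities, and the F regression."""

import numpy as np
import pandas as pd
import pytest

from idscan import (
    DiallelFit, PolygenicSpec, SimulationConfig, compute_grms,
    derive_parameters, fit_all_models, fit_diallel, genomic_inbreeding,
    random_pedigree, regress_on_F, select_model, simulate_population,
)
from idscan.simulate import simulate_diallel_gaussian


def _design(n_parents=12, selfed=12, seed=1):
    cfg = SimulationConfig(n_parents=n_parents,
                           selfed_family_sizes=[selfed] * n_parents,
                           seed=seed)
    return random_pedigree(cfg)


RSD = {("outcrossed", "Y1"): 2.0, ("outcrossed", "Y2"): 2.0,
       ("selfed", "Y1"): 2.5, ("selfed", "Y2"): 2.5}


class TestFit:
    def test_pure_noise_gives_null_gca_variance(self):
        ped = _design()
        rng = np.random.default_rng(0)
        ph = ped.copy()
        ph["trait"] = rng.normal(100, 2, len(ped))
        for c in ("row", "col", "shading", "border"):
            ph[c] = 0.0
        fit = fit_diallel(ph, model=2, include_gxe=False)
        est = fit.varcomps["sigma2_GCA"]
        se = fit.varcomp_se["sigma2_GCA"]
        assert est < 0.1 or (np.isfinite(se) and est < 2 * se)

    def test_balanced_one_way_matches_anova_estimator(self):
        # selfed-only balanced families: REML variance among family effects
        # equals the ANOVA expected-mean-squares estimator (MSB - MSW) / m
        P, m = 15, 20
        rows = []
        rng = np.random.default_rng(3)
        fam_eff = rng.normal(0, 1.5, P)
        for i in range(P):
            for j in range(m):
                rows.append((f"I{i}_{j}", f"P{i:03d}", f"P{i:03d}", "selfed",
                             "Y1", 50 + fam_eff[i] + rng.normal(0, 2.0)))
        # two outcross families so the fit's precondition is met, weightless
        rows.append(("ox1", "P000", "P001", "outcrossed", "Y1",
                     50 + rng.normal()))
        rows.append(("ox2", "P002", "P003", "outcrossed", "Y1",
                     50 + rng.normal()))
        ph = pd.DataFrame(rows, columns=["id", "mother", "father",
                                         "progeny_type", "year", "trait"])
        ph_self = ph[ph.progeny_type == "selfed"]
        g = ph_self.groupby("mother")["trait"]
        grand = ph_self["trait"].mean()
        msb = m * np.sum((g.mean() - grand) ** 2) / (P - 1)
        msw = np.sum((ph_self["trait"] - g.transform("mean")) ** 2) / (P * (m - 1))
        anova_s1 = (msb - msw) / m
        fit = fit_diallel(ph, model=2, include_gxe=False, compute_se=False)
        assert fit.varcomps["sigma2_S1"] == pytest.approx(anova_s1, rel=0.05)

    def test_component_recovery_across_replicates(self):
        ped = _design(n_parents=16, selfed=14)
        truth = dict(sigma2_gca=1.0, sigma2_s1=2.0, sigma2_sca=0.5)
        est = []
        for rep in range(12):
            ph = simulate_diallel_gaussian(ped, **truth, cov_gca_s1=0.0,
                                           outcross_mean=100, selfed_mean=92,
                                           resid_sd_by_type_year=RSD,
                                           seed=500 + rep)
            f = fit_diallel(ph, model=2, include_gxe=False, compute_se=False)
            est.append([f.varcomps["sigma2_GCA"], f.varcomps["sigma2_S1"],
                        f.varcomps["sigma2_SCA"]])
        est = np.array(est)
        mc_se = est.std(axis=0, ddof=1) / np.sqrt(len(est))
        for mean, tr, se in zip(est.mean(axis=0),
                                [1.0, 2.0, 0.5], mc_se):
            assert abs(mean - tr) < 3 * se + 0.05 * tr

    def test_restricted_likelihood_respects_nesting(self):
        ped = _design(seed=5)
        ph = simulate_diallel_gaussian(ped, sigma2_gca=1.0, sigma2_s1=2.0,
                                       sigma2_sca=0.4, cov_gca_s1=0.8,
                                       outcross_mean=100, selfed_mean=90,
                                       resid_sd_by_type_year=RSD, seed=77)
        f1, f2, f3 = fit_all_models(ph, models=(1, 2, 3), include_gxe=False,
                                    compute_se=False)
        assert f2.loglik >= f1.loglik - 1e-3
        assert f3.loglik >= f2.loglik - 1e-3

    def test_too_few_families_raises(self):
        ped = _design().head(30)  # selfed families of one parent only
        ped = ped[ped.mother == ped.mother.iloc[0]]
        ped = ped.assign(trait=1.0)
        with pytest.raises(ValueError, match="families"):
            fit_diallel(ped, model=1)


class TestModelSelection:
    def _fits(self, bics):
        return [DiallelFit(model=m, varcomps={}, varcomp_se={}, loglik=0.0,
                           bic=b, n=10, k=1, converged=True,
                           beta=pd.Series(dtype=float),
                           gca_blup=pd.Series(dtype=float),
                           s1_blup=pd.Series(dtype=float),
                           sca_blup=pd.Series(dtype=float),
                           outcross_mean=1.0, selfed_mean=1.0)
                for m, b in bics]

    def test_ties_break_to_simpler_model(self):
        fits = self._fits([(1, 100.0), (2, 100.0), (3, 100.0)])
        assert select_model(fits).model == 1

    def test_minimum_bic_wins(self):
        fits = self._fits([(1, 100.0), (2, 80.0), (3, 90.0)])
        assert select_model(fits).model == 2

    def test_nonconverged_fits_excluded(self):
        fits = self._fits([(1, 100.0), (2, 50.0)])
        fits[1].converged = False
        assert select_model(fits).model == 1

    def test_equal_residuals_prefer_model_1(self):
        ped = _design(seed=8)
        rsd_eq = {k: 2.0 for k in RSD}
        wins = 0
        for rep in range(6):
            ph = simulate_diallel_gaussian(ped, sigma2_gca=1.0, sigma2_s1=1.0,
                                           sigma2_sca=0.3, cov_gca_s1=0.0,
                                           outcross_mean=100, selfed_mean=95,
                                           resid_sd_by_type_year=rsd_eq,
                                           seed=900 + rep)
            fits = fit_all_models(ph, models=(1, 2), include_gxe=False,
                                  compute_se=False)
            wins += select_model(fits).model == 1
        assert wins >= 4

    def test_heteroscedastic_types_prefer_model_2(self):
        ped = _design(seed=8)
        rsd_het = {("outcrossed", "Y1"): 1.5, ("outcrossed", "Y2"): 1.5,
                   ("selfed", "Y1"): 3.0, ("selfed", "Y2"): 3.0}
        wins = 0
        for rep in range(6):
            ph = simulate_diallel_gaussian(ped, sigma2_gca=1.0, sigma2_s1=1.0,
                                           sigma2_sca=0.3, cov_gca_s1=0.0,
                                           outcross_mean=100, selfed_mean=95,
                                           resid_sd_by_type_year=rsd_het,
                                           seed=950 + rep)
            fits = fit_all_models(ph, models=(1, 2), include_gxe=False,
                                  compute_se=False)
            wins += select_model(fits).model == 2
        assert wins >= 4


class TestDerivedParameters:
    def _fit_with(self, vc, out_mean=100.0, self_mean=80.0):
        g = pd.Series(np.random.default_rng(1).normal(size=8))
        return DiallelFit(model=3, varcomps=vc, varcomp_se={}, loglik=0.0,
                          bic=0.0, n=100, k=4, converged=True,
                          beta=pd.Series(dtype=float), gca_blup=g,
                          s1_blup=g * 2, sca_blup=pd.Series(dtype=float),
                          outcross_mean=out_mean, selfed_mean=self_mean)

    def test_additive_variance_is_four_gca(self):
        vc = {"sigma2_GCA": 1.0, "sigma2_SCA": 0.25, "sigma2_S1": 1.0,
              "cov_GCA_S1": 0.5, "resid[O,Y1]": 1.0}
        dp = derive_parameters(self._fit_with(vc))
        assert dp.sigma2_A == pytest.approx(4.0)
        assert dp.sigma2_D == pytest.approx(1.0)

    def test_consistent_additive_dominance_truth_zeroes_inbred_components(self):
        # Cov(GCA,S1) = 0.5 sigma2_A and sigma2_S1 = sigma2_A + 0.25 sigma2_D
        s2A, s2D = 4.0, 1.0
        vc = {"sigma2_GCA": s2A / 4, "sigma2_SCA": s2D / 4,
              "sigma2_S1": s2A + 0.25 * s2D, "cov_GCA_S1": 0.5 * s2A,
              "resid[O,Y1]": 1.0}
        dp = derive_parameters(self._fit_with(vc))
        assert dp.sigma_ADI == pytest.approx(0.0, abs=1e-12)
        assert dp.sigma2_DI == pytest.approx(0.0, abs=1e-12)

    def test_delta_definition(self):
        vc = {"sigma2_GCA": 1.0, "sigma2_SCA": 0.25, "sigma2_S1": 1.0,
              "cov_GCA_S1": 0.5, "resid[O,Y1]": 1.0}
        dp = derive_parameters(self._fit_with(vc, 100.0, 80.0))
        assert dp.delta == pytest.approx(0.20)

    def test_zero_outcross_mean_is_an_error(self):
        vc = {"sigma2_GCA": 1.0, "sigma2_SCA": 0.25, "sigma2_S1": 1.0,
              "cov_GCA_S1": 0.5, "resid[O,Y1]": 1.0}
        with pytest.raises(ValueError, match="delta"):
            derive_parameters(self._fit_with(vc, 0.0, 0.0))

    def test_breeding_value_correlation_near_one_without_dominance(self):
        cfg = SimulationConfig(
            n_parents=12, n_chromosomes=2, chrom_length_cM=100,
            selfed_family_sizes=[20] * 12, seed=31,
            polygenic_spec=PolygenicSpec(n_loci=80, effect_scale=0.5,
                                         mean_dominance=0.0,
                                         freq_beta_a=2, freq_beta_b=3),
            residual_sd_by_type_year={k: 1.0 for k in RSD})
        pop = simulate_population(cfg)
        fit = fit_diallel(pop.phenotypes, model=3, include_gxe=False,
                          compute_se=False)
        dp = derive_parameters(fit)
        assert dp.r_s0s1 > 0.9


class TestRegressionOnF:
    def test_exact_linear_trait_recovered(self, small_pop):
        surv = small_pop.surviving_index()
        grm = compute_grms(small_pop.genotypes[surv],
                           allele_freqs=small_pop.founders.site_freqs)
        F = genomic_inbreeding(grm)
        ph = small_pop.phenotypes.copy()
        ph["trait"] = 50.0 - 3.0 * F
        fit = regress_on_F(ph, F, grm, quadratic=True)
        assert fit.beta_F == pytest.approx(-3.0, abs=1e-4)
        assert fit.beta_F2 == pytest.approx(0.0, abs=1e-4)

    def test_negative_epistasis_detected_in_majority(self):
        neg = 0
        for rep in range(5):
            cfg = SimulationConfig(
                n_parents=12, n_chromosomes=2, chrom_length_cM=100,
                marker_spacing_cM=0.5, selfed_family_sizes=[15] * 12,
                seed=600 + rep, epistasis_b=-30.0,
                polygenic_spec=PolygenicSpec(n_loci=60, effect_scale=0.3,
                                             mean_dominance=0.7),
                residual_sd_by_type_year={k: 2.0 for k in RSD})
            pop = simulate_population(cfg)
            grm = compute_grms(pop.genotypes[pop.surviving_index()],
                               allele_freqs=pop.founders.site_freqs)
            F = genomic_inbreeding(grm)
            fit = regress_on_F(pop.phenotypes, F, grm, quadratic=True)
            neg += fit.beta_F2 < 0
        assert neg >= 4

    def test_no_inbreeding_variation_rejects_quadratic(self, small_pop):
        ph = small_pop.phenotypes
        F = np.zeros(len(ph))
        grm = compute_grms(small_pop.genotypes[small_pop.surviving_index()],
                           allele_freqs=small_pop.founders.site_freqs)
        with pytest.raises(ValueError, match="collinear"):
            regress_on_F(ph, F, grm, quadratic=True)
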