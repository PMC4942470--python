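"""Variance-component estimation: closed forms, fitted components, enumeration."""

import numpy as np
import pytest

from gmanova import (
    GenotypeDataset,
    GroupMeans,
    ModelSpec,
    build_design,
    default_study_config,
    exact_hwe_fixture,
    fit_ols,
    fitted_components,
    params_to_genotypic_values,
    residual_and_total,
    true_varcomp_enumeration,
    varcomp_from_fit,
    varcomp_hwe_closed_form,
)
from gmanova.params import GMAParams
from gmanova.varcomp import allele_freqs_from_probs

from conftest import complete_random_dataset


def hwe_dataset(rng, means_by_cell, sigma, reps=6):
    base = exact_hwe_fixture([0.4, 0.6], scale=25)
    g = np.tile(base.genotypes[0], (reps, 1))
    cell = g.sum(axis=1)
    y = np.asarray(means_by_cell, float)[cell] + rng.normal(0.0, sigma, size=len(g))
    return GenotypeDataset(loci=base.loci, genotypes=[g], phenotype=y)


class TestClosedForm:
    def test_pure_additive_pattern(self):
        means = GroupMeans(
            means=np.array([[1.0, 0.0], [0.0, -1.0]]), freqs=[np.array([0.5, 0.5])]
        )
        V_A, V_D = varcomp_hwe_closed_form(means)
        assert V_A == pytest.approx(0.5)
        assert V_D == pytest.approx(0.0, abs=1e-12)

    def test_pure_dominance_pattern(self):
        means = GroupMeans(
            means=np.array([[1.0, -1.0], [-1.0, 1.0]]), freqs=[np.array([0.5, 0.5])]
        )
        V_A, V_D = varcomp_hwe_closed_form(means)
        assert V_A == pytest.approx(0.0, abs=1e-12)
        assert V_D == pytest.approx(1.0)

    def test_constant_means(self):
        means = GroupMeans(means=np.full((2, 2), 3.3), freqs=[np.array([0.4, 0.6])])
        V_A, V_D = varcomp_hwe_closed_form(means)
        assert V_A == pytest.approx(0.0, abs=1e-12)
        assert V_D == pytest.approx(0.0, abs=1e-12)


class TestFittedComponents:
    def test_components_sum_to_fitted_values(self, rng):
        ds = complete_random_dataset(rng, (3,))
        fit = fit_ols(build_design(ds, ModelSpec(coding="gma", n_loci=1)))
        comps = fitted_components(fit)
        total = fit.beta[0] + sum(comps.values())
        np.testing.assert_allclose(total, fit.fitted, atol=1e-9)

    def test_additive_component_takes_three_values(self, rng):
        ds = complete_random_dataset(rng, (2,))
        fit = fit_ols(build_design(ds, ModelSpec(coding="gma", n_loci=1)))
        comps = fitted_components(fit)
        assert len(np.unique(np.round(comps["A"], 10))) <= 3

    def test_phenotypic_variance_identity_on_exact_fixture(self, rng):
        """V_Y = V_A + V_D + V_eps exactly when every D_jk = 0."""
        ds = hwe_dataset(rng, [2.0, 1.2, 0.0], sigma=1.3)
        fit = fit_ols(build_design(ds, ModelSpec(coding="gma", n_loci=1)))
        vc = varcomp_from_fit(fit)
        assert vc.V_Y == pytest.approx(
            vc.components["A"] + vc.components["D"] + vc.V_eps, abs=1e-10
        )
        assert abs(vc.cov[0, 1]) < 1e-10  # Cov(A, D) = 0
        # agrees with the closed-form HWE estimators
        V_A, V_D = varcomp_hwe_closed_form(ds.group_means())
        assert vc.components["A"] == pytest.approx(V_A, abs=1e-10)
        assert vc.components["D"] == pytest.approx(V_D, abs=1e-10)

    def test_nonnegative_components_on_arbitrary_data(self, rng):
        for ms in ((2,), (3,), (2, 2)):
            ds = complete_random_dataset(rng, ms)
            for coding in ("glm", "gma"):
                fit = fit_ols(build_design(ds, ModelSpec(coding=coding, n_loci=len(ms))))
                vc = varcomp_from_fit(fit)
                assert all(v >= 0.0 for v in vc.components.values())
                assert vc.V_G == pytest.approx(
                    vc.total_component_variance
                    + vc.cov.sum() - np.trace(vc.cov),
                    abs=1e-8,
                )

    def test_covariate_adjusted_components(self, rng):
        """Covariate effects stay out of the genetic components."""
        import pandas as pd
        from gmanova.fit import ModelSpec as MS

        ds = complete_random_dataset(rng, (2,))
        z = rng.normal(size=ds.N)
        ds.covariates = pd.DataFrame({"age": z})
        ds.phenotype = ds.phenotype + 2.0 * z
        spec = MS(coding="gma", n_loci=1, covariates=("age",))
        fit = fit_ols(build_design(ds, spec))
        comps = fitted_components(fit)
        covariate_part = fit.coef["age"] * z
        np.testing.assert_allclose(
            fit.beta[0] + covariate_part + comps["A"] + comps["D"],
            fit.fitted,
            atol=1e-9,
        )
        vc = varcomp_from_fit(fit)
        assert vc.V_G == pytest.approx(np.var(comps["A"] + comps["D"]), abs=1e-10)
        assert vc.V_eps == pytest.approx(fit.mse)  # MSE-based when covariates present

    def test_zero_residual_data(self, rng):
        ds = hwe_dataset(rng, [2.0, 1.0, 0.0], sigma=0.0)
        fit = fit_ols(build_design(ds, ModelSpec(coding="gma", n_loci=1)))
        V_eps, V_Y = residual_and_total(fit)
        assert V_eps == pytest.approx(0.0, abs=1e-12)
        assert V_Y > 0

    def test_pure_noise_residual_share(self):
        rng = np.random.default_rng(5)
        ds = hwe_dataset(rng, [0.0, 0.0, 0.0], sigma=2.0, reps=200)
        fit = fit_ols(build_design(ds, ModelSpec(coding="gma", n_loci=1)))
        V_eps, V_Y = residual_and_total(fit)
        assert V_eps / V_Y > 0.99


class TestEnumeration:
    def test_additive_only_model(self):
        p = np.array([0.3, 0.7])
        gma = GMAParams(mu=0.0, effects={"A": [1.0], "D": [[0.0]]}, m=(2,))
        table = params_to_genotypic_values(gma, [p])
        prob = np.outer(p, p) * (2 - np.eye(2))
        vc = true_varcomp_enumeration(table, prob)
        assert vc.V_G == pytest.approx(vc.components["A"], abs=1e-12)
        assert vc.components["D"] == pytest.approx(0.0, abs=1e-12)

    def test_hwe_independent_covariances_vanish(self):
        cfg = default_study_config()
        table = params_to_genotypic_values(cfg.params, [l.freqs for l in cfg.loci])
        vc = true_varcomp_enumeration(table, cfg.genotype_probs())
        off = vc.cov - np.diag(np.diag(vc.cov))
        assert np.max(np.abs(off)) < 1e-12
        assert vc.covariance_fraction == pytest.approx(0.0, abs=1e-10)

    def test_marginal_allele_freqs(self):
        cfg = default_study_config()
        p1, p2 = allele_freqs_from_probs(cfg.genotype_probs())
        np.testing.assert_allclose(p1, [0.4, 0.6], atol=1e-12)
        np.testing.assert_allclose(p2, [0.2, 0.8], atol=1e-12)

    def test_variance_decomposition_closes_under_hwd(self):
        """V_G = sum V_c + 2 sum Cov holds for a disequilibrium distribution."""
        p = np.array([0.6, 0.4])
        # D_11 = 0.05: p_11 = 0.41, het = 0.38, p_22 = 0.21 (marginal p_1 = 0.6)
        prob = np.array([[0.41, 0.38], [0.38, 0.21]])
        gma = GMAParams(mu=0.0, effects={"A": [1.0], "D": [[0.8]]}, m=(2,))
        table = params_to_genotypic_values(gma, [p])
        vc = true_varcomp_enumeration(table, prob, freqs=[p])
        total = vc.total_component_variance + vc.cov.sum() - np.trace(vc.cov)
        assert vc.V_G == pytest.approx(total, abs=1e-10)
        assert abs(vc.cov[0, 1]) > 1e-4  # confounding is real here


class TestConsistency:
    @pytest.mark.parametrize("n,tol", [(1000, 0.5), (10_000, 0.2)])
    def test_sampled_varcomp_approaches_enumeration(self, n, tol):
        from gmanova import simulate_dataset

        cfg = default_study_config(n=n)
        table = params_to_genotypic_values(cfg.params, [l.freqs for l in cfg.loci])
        truth = true_varcomp_enumeration(table, cfg.genotype_probs())
        ds = simulate_dataset(cfg, seed=np.random.SeedSequence(12))
        fit = fit_ols(build_design(ds, ModelSpec(coding="gma", n_loci=2)))
        vc = varcomp_from_fit(fit)
        assert vc.V_G == pytest.approx(truth.V_G, rel=tol)
        for b in ("A1", "A2", "AA"):
            assert vc.components[b] == pytest.approx(truth.components[b], rel=tol)
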