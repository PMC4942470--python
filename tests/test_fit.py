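"""OLS fitting, closed-form LSE, Type III SS and block F-tests."""

import numpy as np
import pytest
from scipy import stats

from gmanova import (
    ModelSpec,
    build_design,
    closed_form_lse_one_locus,
    closed_form_lse_two_locus,
    exact_hwe_fixture,
    fit_ols,
    group_f_test,
    independent_product_fixture,
    type3_ss,
)
from gmanova.data import GenotypeDataset, GroupMeans

from conftest import complete_random_dataset, make_locus


def fixture_with_phenotype(rng, means_by_cell, sigma=0.0, reps=4):
    """Exact-HWE biallelic fixture with phenotype set per genotype cell."""
    base = exact_hwe_fixture([0.4, 0.6], scale=25)
    g = np.tile(base.genotypes[0], (reps, 1))
    cell = g.sum(axis=1)  # 0: hom 0/0, 1: het, 2: hom ref
    y = np.asarray(means_by_cell, float)[cell]
    if sigma > 0:
        y = y + rng.normal(0.0, sigma, size=len(y))
    return GenotypeDataset(loci=base.loci, genotypes=[g], phenotype=y)


class TestFitOls:
    @pytest.mark.parametrize("coding", ["glm", "gma"])
    def test_saturated_fit_reproduces_cell_means(self, rng, coding):
        ds = complete_random_dataset(rng, (3,))
        fit = fit_ols(build_design(ds, ModelSpec(coding=coding, n_loci=1)))
        means = ds.group_means().means
        g = ds.genotypes[0]
        np.testing.assert_allclose(fit.fitted, means[g[:, 0], g[:, 1]], atol=1e-9)

    def test_glm_and_gma_share_ssr(self, rng):
        ds = complete_random_dataset(rng, (2, 3))
        fits = [
            fit_ols(build_design(ds, ModelSpec(coding=c, n_loci=2)))
            for c in ("glm", "gma")
        ]
        assert fits[0].ssr == pytest.approx(fits[1].ssr, rel=1e-10)
        np.testing.assert_allclose(fits[0].fitted, fits[1].fitted, atol=1e-8)

    def test_ols_matches_statsmodels(self, rng):
        """Independent cross-check of coefficients, MSE and model SS."""
        import statsmodels.api as sm

        ds = complete_random_dataset(rng, (3,))
        design = build_design(ds, ModelSpec(coding="gma", n_loci=1))
        fit = fit_ols(design)
        res = sm.OLS(ds.phenotype, design.X).fit()
        np.testing.assert_allclose(fit.beta, res.params, atol=1e-8)
        assert fit.mse == pytest.approx(res.mse_resid, rel=1e-9)
        assert fit.ssr == pytest.approx(res.ess, rel=1e-9)

    def test_constant_phenotype(self, rng):
        ds = complete_random_dataset(rng, (3,))
        ds.phenotype[:] = 7.0
        fit = fit_ols(build_design(ds, ModelSpec(n_loci=1)))
        np.testing.assert_allclose(fit.beta[1:], 0.0, atol=1e-9)
        assert fit.ssr == pytest.approx(0.0, abs=1e-9)

    def test_rank_deficiency_raises_and_override(self, rng):
        # empty heterozygote cell under a saturated model
        loci = [make_locus(2)]
        g = np.array([[0, 0]] * 5 + [[1, 1]] * 5)
        ds = GenotypeDataset(loci=loci, genotypes=[g], phenotype=rng.normal(size=10))
        design = build_design(ds, ModelSpec(coding="glm", n_loci=1))
        with pytest.raises(np.linalg.LinAlgError):
            fit_ols(design)
        fit = fit_ols(design, allow_rank_deficient=True)
        assert np.isfinite(fit.sse)


class TestClosedForm:
    def test_biallelic_hand_values(self):
        # cell means (y11, y12, y22) = (1, 0, -1) at p = (1/2, 1/2)
        means = GroupMeans(
            means=np.array([[1.0, 0.0], [0.0, -1.0]]),
            freqs=[np.array([0.5, 0.5])],
        )
        gma, glm = closed_form_lse_one_locus(means)
        assert gma.mu == pytest.approx(0.0)
        assert gma.effects["A"][0] == pytest.approx(1.0)
        assert gma.effects["D"][0, 0] == pytest.approx(0.0)
        assert glm.effects["A"][0] == pytest.approx(1.0)  # y12 - y22
        assert glm.effects["D"][0, 0] == pytest.approx(0.0)
        assert glm.mu == pytest.approx(-1.0)

    def test_constant_cells(self):
        means = GroupMeans(means=np.full((3, 3), 4.2), freqs=[np.array([0.2, 0.3, 0.5])])
        gma, _ = closed_form_lse_one_locus(means)
        assert gma.mu == pytest.approx(4.2)
        np.testing.assert_allclose(gma.effects["A"], 0.0, atol=1e-12)

    def test_empty_cell_is_reported(self):
        m = np.full((2, 2), 1.0)
        m[0, 0] = np.nan
        means = GroupMeans(means=m, freqs=[np.array([0.5, 0.5])])
        with pytest.raises(ValueError, match=r"\(0, 0\)"):
            closed_form_lse_one_locus(means)

    @pytest.mark.parametrize("ms", [(2,), (3,), (4,), (2, 2), (3, 2), (3, 4)])
    def test_closed_form_equals_matrix_ols(self, rng, ms):
        """The weighted-group-mean formulas equal the OLS coefficients."""
        ds = complete_random_dataset(rng, ms)
        means = ds.group_means()
        if len(ms) == 1:
            gma, glm = closed_form_lse_one_locus(means)
        else:
            gma, glm = closed_form_lse_two_locus(means)
        for coding, params in (("gma", gma), ("glm", glm)):
            fit = fit_ols(build_design(ds, ModelSpec(coding=coding, n_loci=len(ms))))
            np.testing.assert_allclose(fit.beta, params.to_vector(), atol=1e-8)

    def test_two_locus_param_recovery_from_exact_cells(self, rng):
        """Saturated closed form recovers the generating parameters exactly."""
        from gmanova import default_study_config, params_to_genotypic_values, glm_to_gma

        cfg = default_study_config()
        freqs = [l.freqs for l in cfg.loci]
        table = params_to_genotypic_values(cfg.params, freqs).values
        means = GroupMeans(means=table, freqs=freqs)
        gma, glm = closed_form_lse_two_locus(means)
        assert glm.allclose(cfg.params, atol=1e-10)
        assert gma.allclose(glm_to_gma(cfg.params, freqs), atol=1e-10)
        # the dominance-by-dominance corner coincides across flavors
        np.testing.assert_allclose(
            gma.effects["DD"], glm.effects["DD"], atol=1e-12
        )


class TestOrthogonality:
    def test_xtx_block_diagonal_on_exact_fixture(self, rng):
        ds = fixture_with_phenotype(rng, [1.0, 0.5, 0.0], sigma=1.0)
        design = build_design(ds, ModelSpec(coding="gma", n_loci=1))
        xtx = design.X.T @ design.X
        a = design.block_cols["A"]
        d = design.block_cols["D"]
        assert abs(xtx[0, a[0]]) < 1e-9
        assert abs(xtx[0, d[0]]) < 1e-9
        assert abs(xtx[a[0], d[0]]) < 1e-9

    def test_reduced_model_keeps_gma_estimates(self, rng):
        """Dropping the dominance block leaves mu* and alpha* unchanged (GMA)."""
        ds = fixture_with_phenotype(rng, [2.0, 1.2, 0.0], sigma=0.7)
        full = fit_ols(build_design(ds, ModelSpec(coding="gma", n_loci=1)))
        red = fit_ols(build_design(ds, ModelSpec(coding="gma", n_loci=1, blocks=("A",))))
        np.testing.assert_allclose(full.beta[:2], red.beta[:2], atol=1e-9)

    def test_reduced_model_shifts_glm_estimates(self, rng):
        """The GLM dummy coding does not share the invariance when d != 0."""
        ds = fixture_with_phenotype(rng, [2.0, 1.5, 0.0])  # dominance present
        full = fit_ols(build_design(ds, ModelSpec(coding="glm", n_loci=1)))
        red = fit_ols(build_design(ds, ModelSpec(coding="glm", n_loci=1, blocks=("A",))))
        assert abs(full.beta[1] - red.beta[1]) > 0.05

    def test_two_locus_exclusion_invariance(self, rng):
        """With all joint D = 0, excluding blocks leaves other LSE unchanged."""
        ds1 = exact_hwe_fixture([0.4, 0.6], 25, "L1")
        ds2 = exact_hwe_fixture([0.2, 0.8], 25, "L2")
        both = independent_product_fixture(ds1, ds2)
        y = rng.normal(size=both.N)
        ds = GenotypeDataset(loci=both.loci, genotypes=both.genotypes, phenotype=y)
        full = fit_ols(build_design(ds, ModelSpec(coding="gma", n_loci=2)))
        partial_blocks = ("A1", "A2", "AA")
        red = fit_ols(build_design(ds, ModelSpec(coding="gma", n_loci=2, blocks=partial_blocks)))
        for b in partial_blocks:
            np.testing.assert_allclose(
                full.block_coefs(b), red.block_coefs(b), atol=1e-9
            )


class TestType3AndFTests:
    def test_orthogonal_type3_equals_sequential(self, rng):
        ds = fixture_with_phenotype(rng, [2.0, 1.2, 0.0], sigma=0.5)
        fit = fit_ols(build_design(ds, ModelSpec(coding="gma", n_loci=1)))
        ss_a = type3_ss(fit, "A")
        red = fit_ols(build_design(ds, ModelSpec(coding="gma", n_loci=1, blocks=("A",))))
        assert ss_a == pytest.approx(red.ssr, rel=1e-9)  # sequential SS of A first
        assert ss_a + type3_ss(fit, "D") == pytest.approx(fit.ssr, rel=1e-9)

    def test_type3_sum_bounded_by_ssr(self, rng):
        ds = complete_random_dataset(rng, (3,))
        fit = fit_ols(build_design(ds, ModelSpec(coding="glm", n_loci=1)))
        total = type3_ss(fit, "A") + type3_ss(fit, "D")
        assert total <= fit.ssr + 1e-9

    def test_zero_coefficient_block_has_zero_ss(self, rng):
        # phenotype generated exactly from the additive part only
        ds = complete_random_dataset(rng, (3,))
        design = build_design(ds, ModelSpec(coding="gma", n_loci=1))
        beta = np.zeros(design.X.shape[1])
        beta[0] = 1.0
        beta[design.block_cols["A"]] = [0.5, -0.2]
        y = design.X @ beta
        fit = fit_ols(design, y=y)
        np.testing.assert_allclose(fit.block_coefs("D"), 0.0, atol=1e-9)
        assert type3_ss(fit, "D") == pytest.approx(0.0, abs=1e-9)

    def test_single_df_f_equals_squared_t(self, rng):
        ds = fixture_with_phenotype(rng, [1.0, 0.6, 0.0], sigma=1.0)
        fit = fit_ols(build_design(ds, ModelSpec(coding="gma", n_loci=1)))
        F, (df1, df2), p = group_f_test(fit, "A")
        assert df1 == 1
        j = fit.design.block_cols["A"][0]
        t = fit.beta[j] / np.sqrt(fit.cov_beta[j, j])
        assert F == pytest.approx(t**2, rel=1e-9)

    def test_saturated_noiseless_fit_rejected(self, rng):
        ds = fixture_with_phenotype(rng, [1.0, 0.6, 0.0], sigma=0.0)
        fit = fit_ols(build_design(ds, ModelSpec(coding="gma", n_loci=1)))
        with pytest.raises(ValueError, match="noiseless"):
            group_f_test(fit, "A")

    def test_a_test_size_with_dominance_present(self):
        """GMA A-block F-test keeps its nominal size when only delta* != 0."""
        rng = np.random.default_rng(77)
        base = exact_hwe_fixture([0.4, 0.6], scale=25)
        g = np.tile(base.genotypes[0], (8, 1))
        n = len(g)
        ds0 = GenotypeDataset(loci=base.loci, genotypes=[g], phenotype=np.zeros(n))
        design = build_design(ds0, ModelSpec(coding="gma", n_loci=1))
        dom = design.X[:, design.block_cols["D"][0]]
        reps, hits = 600, 0
        for _ in range(reps):
            y = 1.5 * dom + rng.normal(size=n)
            fit = fit_ols(design, y=y)
            _, _, p = group_f_test(fit, "A")
            hits += p < 0.05
        rate = hits / reps
        se = np.sqrt(0.05 * 0.95 / reps)
        assert abs(rate - 0.05) < 4 * se
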