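import numpy as np
import pandas as pd
import pytest
from scipy.stats import chi2, kstest, norm, pearsonr

from gpn import spa as spa_mod
from gpn.datasets import BINARY, QUANTITATIVE, CovariateDataset, PhenotypeDataset
from gpn.network import (
    GPN,
    build_gpn,
    build_gpn_from_summary,
    residualize,
    score_test,
    spa_pvalue,
    strength_from_p,
)
from gpn.simulate import FactorModelConfig, simulate_dataset


class TestResidualize:
    def test_empty_covariates_center(self):
        out = residualize(np.array([1.0, 2.0, 3.0]), None)
        np.testing.assert_allclose(out[:, 0], [-1, 0, 1], atol=1e-12)

    def test_perfect_fit_gives_zero(self):
        x = np.array([[1.0], [2.0], [4.0], [7.0]])
        out = residualize(x, x.copy())
        np.testing.assert_allclose(out, 0.0, atol=1e-12)

    def test_orthogonal_covariate_leaves_centered_column(self, rng):
        # generic least-squares oracle on a 4-sample fixture
        y = np.array([1.0, -2.0, 0.5, 0.5])
        c = np.array([[1.0], [1.0], [-1.0], [-1.0]])
        yc = y - y.mean()
        yc -= c[:, 0] * (c[:, 0] @ yc) / (c[:, 0] @ c[:, 0])  # oracle projection
        out = residualize(y, c)
        np.testing.assert_allclose(out[:, 0], yc, atol=1e-12)

    def test_matches_lstsq_oracle(self, rng):
        n, p, q = 40, 3, 2
        c = rng.standard_normal((n, p))
        y = rng.standard_normal((n, q))
        x = np.column_stack([np.ones(n), c])
        beta, *_ = np.linalg.lstsq(x, y, rcond=None)
        np.testing.assert_allclose(residualize(y, c), y - x @ beta, atol=1e-10)

    def test_residuals_orthogonal_to_covariates(self, rng):
        n = 50
        c = rng.standard_normal((n, 2))
        out = residualize(rng.standard_normal((n, 3)), c)
        assert np.abs(c.T @ out).max() < 1e-8 * n
        assert np.abs(out.sum(axis=0)).max() < 1e-8 * n

    def test_collinear_design_rejected(self):
        c = CovariateDataset(["a", "b", "c", "d"], ["x1", "x2"],
                             np.array([[1.0, 2.0], [2.0, 4.0], [3.0, 6.0], [4.0, 8.0]]))
        with pytest.raises(ValueError, match="rank deficient"):
            residualize(np.arange(4.0), c)


class TestScoreTest:
    def test_hand_worked_example(self):
        res = score_test([1.0, 2.0, 3.0], [0.0, 1.0, 2.0])
        assert res.S == pytest.approx(2.0)
        assert res.sigma2 == pytest.approx(4.0 / 3.0)
        assert res.z == pytest.approx(np.sqrt(3.0))
        assert res.p == pytest.approx(2 * norm.sf(np.sqrt(3.0)), rel=1e-12)

    def test_constant_trait_is_degenerate_not_an_error(self):
        res = score_test([1.0, 1.0, 1.0], [0.0, 1.0, 2.0])
        assert (res.S, res.z, res.p) == (0.0, 0.0, 1.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_z_equals_sqrt_n_times_pearson(self, seed):
        rng = np.random.default_rng(seed)
        n = 37
        y, g = rng.standard_normal(n), rng.binomial(2, 0.3, n).astype(float)
        res = score_test(y, g)
        assert res.z == pytest.approx(np.sqrt(n) * pearsonr(y, g).statistic, rel=1e-10)


class TestSaddlepoint:
    def test_zero_score_gives_one(self, rng):
        g = rng.standard_normal(10)
        assert spa_mod.spa_two_sided(0.0, g, np.full(10, 0.3)) == 1.0

    def test_matches_enumeration_oracle_small_n(self):
        # fixed fixture: exhaustive 2^12 enumeration of case patterns
        g = np.array([1.32, -0.77, 0.64, 0.12, -1.52, 0.91,
                      -0.38, 2.01, -1.11, 0.47, -0.25, 0.84])
        g = g - g.mean()
        mu = np.full(12, 0.3)
        for s in [0.8, 1.5, 2.2, 3.0]:
            p_spa = spa_mod.spa_two_sided(s, g, mu)
            p_exact = spa_mod.exact_two_sided(s, g, mu)
            assert p_spa == pytest.approx(p_exact, rel=0.10)

    def test_balanced_large_n_agrees_with_normal(self, rng):
        n = 2000
        mu = np.full(n, 0.5)
        g = rng.standard_normal(n)
        g -= g.mean()
        sd = np.sqrt((g**2 * 0.25).sum())
        for z in [0.3, 0.7, 0.95]:
            p_spa = spa_mod.spa_two_sided(z * sd, g, mu)
            assert abs(p_spa - 2 * norm.sf(z)) < 0.01

    def test_batch_agrees_with_scalar(self, rng):
        n, m = 300, 25
        mu = np.full(n, 0.05)
        G = rng.standard_normal((n, m))
        G -= G.mean(axis=0)
        s = rng.normal(0, 2.0, m) * np.sqrt((G**2 * 0.0475).sum(axis=0)) / np.sqrt(n)
        batch = spa_mod.spa_two_sided_batch(s, G, mu)
        scalar = np.array([spa_mod.spa_two_sided(s[j], G[:, j], mu) for j in range(m)])
        np.testing.assert_allclose(batch, scalar, rtol=1e-8)

    def test_spa_pvalue_sign_and_method(self, rng):
        n = 400
        y = (rng.random(n) < 0.1).astype(float)
        g = rng.standard_normal(n)
        res = spa_pvalue(y, g - g.mean(), np.full(n, y.mean()))
        assert res.method == "spa" and 0 < res.p <= 1
        assert np.sign(res.S) in (-1.0, 0.0, 1.0)


class TestBuildGPN:
    def test_chi_square_strength_map(self):
        assert strength_from_p(np.array([0.5]), np.array([1]))[0] == pytest.approx(0.45494, abs=1e-5)
        assert strength_from_p(np.array([0.05]), np.array([-1]))[0] == pytest.approx(-3.84146, abs=1e-5)

    def test_tiny_p_maps_to_finite_strength(self):
        t = strength_from_p(np.array([1e-300]), np.array([1]))
        assert np.isfinite(t[0]) and t[0] > 1000

    def test_null_strengths_mean_one_and_uniform_pvalues(self):
        # K*M >= 1e5 entries under the global null: E|T| = E[chi2_1] = 1.
        # Independent traits keep the Monte-Carlo error of the mean small.
        cfg = FactorModelConfig(
            N=1000, M=2000, K=60, C=5, beta=0.0, mode="quantitative",
            c0_sq=0.0, rho=0.0, rho_f=0.0,
        )
        data = simulate_dataset(cfg, seed=5)
        t = GPN(engine="normal").fit(data.genotypes, data.phenotypes, align=False).T_
        assert abs(np.abs(t.T).mean() - 1.0) < 0.02
        assert kstest(t.pvals.ravel(), "uniform").statistic < 0.01

    def test_negating_a_trait_negates_its_row(self, small_dataset):
        geno, pheno = small_dataset
        t1 = build_gpn(geno, pheno, engine="normal")
        flipped = PhenotypeDataset(
            pheno.sample_ids, pheno.trait_ids,
            pheno.values * np.array([-1, 1, 1, 1]), list(pheno.trait_kind),
        )
        t2 = build_gpn(geno, flipped, engine="normal")
        np.testing.assert_allclose(t2.T[0], -t1.T[0], atol=1e-10)
        np.testing.assert_allclose(t2.T[1:], t1.T[1:], atol=1e-10)

    def test_zero_variance_snp_column_zeroed(self, rng):
        from gpn.datasets import GenotypeDataset

        counts = rng.binomial(2, 0.4, size=(50, 3)).astype(float)
        counts[:, 1] = 1.0
        geno = GenotypeDataset([f"s{i}" for i in range(50)], ["a", "b", "c"], counts)
        pheno = PhenotypeDataset([f"s{i}" for i in range(50)], ["t"],
                                 rng.standard_normal((50, 1)), [QUANTITATIVE])
        t = build_gpn(geno, pheno, engine="normal")
        np.testing.assert_array_equal(t.T[:, 1], 0.0)

    def test_engine_auto_uses_spa_for_binary_extremes(self, rng):
        from gpn.datasets import GenotypeDataset

        n = 800
        counts = rng.binomial(2, 0.3, size=(n, 40)).astype(float)
        geno = GenotypeDataset([f"s{i}" for i in range(n)], [f"v{j}" for j in range(40)], counts)
        y = np.zeros((n, 1))
        y[:40, 0] = 1.0
        pheno = PhenotypeDataset([f"s{i}" for i in range(n)], ["d"], y, [BINARY])
        model = GPN(engine="auto").fit(geno, pheno, align=False)
        assert model.method_[0] == "spa"
        norm_p = GPN(engine="normal").fit(geno, pheno, align=False).T_.pvals
        redo = np.abs(norm.isf(norm_p[0] / 2)) >= 2.0
        assert redo.any()
        assert not np.allclose(model.T_.pvals[0, redo], norm_p[0, redo])


class TestSummaryBuild:
    def test_direction_and_quantile(self):
        df = pd.DataFrame(
            {"trait_id": ["a", "a"], "snp_id": ["s1", "s2"],
             "direction": [1, -1], "p_value": [1.0, 0.05]}
        )
        t = build_gpn_from_summary(df)
        assert t.T[0, 0] == 0.0
        assert t.T[0, 1] == pytest.approx(-3.84146, abs=1e-5)

    def test_consistent_with_individual_level_build(self, small_dataset):
        geno, pheno = small_dataset
        t_ind = build_gpn(geno, pheno, engine="normal")
        rows = [
            (tr, sn, int(t_ind.signs[i, j]) or 1, t_ind.pvals[i, j])
            for i, tr in enumerate(t_ind.trait_ids)
            for j, sn in enumerate(t_ind.snp_ids)
        ]
        df = pd.DataFrame(rows, columns=["trait_id", "snp_id", "direction", "p_value"])
        t_sum = build_gpn_from_summary(df, t_ind.trait_ids, t_ind.snp_ids)
        np.testing.assert_allclose(t_sum.T, t_ind.T, atol=1e-10)

    def test_missing_pairs_are_zero(self):
        df = pd.DataFrame(
            {"trait_id": ["a"], "snp_id": ["s1"], "direction": [1], "p_value": [0.01]}
        )
        t = build_gpn_from_summary(df, ["a", "b"], ["s1", "s2"])
        assert t.T[1, 0] == 0.0 and t.T[0, 1] == 0.0 and t.T[0, 0] > 0
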