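import numpy as np
import pytest
from scipy.stats import cauchy, chi2, kstest, norm

from gpn import assoc
from gpn.datasets import ModulePartition


def _random_corr(rng, k):
    a = rng.standard_normal((k, k + 5))
    return np.corrcoef(a)


class TestOBrien:
    def test_single_trait_reduction(self):
        out = assoc.obrien(np.array([1.7]), np.eye(1))
        assert out.statistic == pytest.approx(1.7)
        assert out.p == pytest.approx(2 * norm.sf(1.7))

    def test_identity_correlation_equal_z(self):
        out = assoc.obrien(np.full(4, 0.9), np.eye(4))
        assert out.statistic == pytest.approx(2 * 0.9)  # sqrt(4) * c

    def test_gls_oracle(self, rng):
        z = rng.standard_normal(4)
        r = _random_corr(rng, 4)
        ri = np.linalg.inv(r)  # independent explicit-inverse route
        expected = np.ones(4) @ ri @ z / np.sqrt(np.ones(4) @ ri @ np.ones(4))
        assert assoc.obrien(z, r).statistic == pytest.approx(expected, abs=1e-12)


class TestOmnibus:
    def test_identity_correlation_sum_of_squares(self, rng):
        z = rng.standard_normal(6)
        out = assoc.omnibus(z, np.eye(6))
        assert out.statistic == pytest.approx((z**2).sum())
        assert out.df == 6

    def test_single_trait_chi1(self):
        out = assoc.omnibus(np.array([2.0]), np.eye(1))
        assert out.p == pytest.approx(chi2.sf(4.0, 1))


class TestCLC:
    def test_identity_indicator_reduces_to_omnibus(self, rng):
        z = rng.standard_normal(5)
        r = _random_corr(rng, 5)
        clc = assoc.clc(z, r, np.eye(5))
        omn = assoc.omnibus(z, r)
        assert clc.statistic == pytest.approx(omn.statistic, abs=1e-12)

    def test_single_cluster_reduces_to_obrien_squared(self, rng):
        z = rng.standard_normal(5)
        r = _random_corr(rng, 5)
        clc = assoc.clc(z, r, np.ones((5, 1)))
        obr = assoc.obrien(z, r)
        assert clc.statistic == pytest.approx(obr.statistic**2, abs=1e-12)

    def test_quadratic_form_oracle_two_clusters(self, rng):
        z = rng.standard_normal(5)
        r = _random_corr(rng, 5)
        u = assoc.labels_to_indicator(np.array([0, 0, 1, 1, 1]))
        ri = np.linalg.inv(r)
        a = u.T @ ri @ z
        expected = a @ np.linalg.inv(u.T @ ri @ u) @ a
        out = assoc.clc(z, r, u)
        assert out.statistic == pytest.approx(expected, abs=1e-12)
        assert out.df == 2

    def test_empty_cluster_rejected(self, rng):
        u = np.zeros((3, 2))
        u[:, 0] = 1
        with pytest.raises(ValueError, match="empty cluster"):
            assoc.clc(rng.standard_normal(3), np.eye(3), u)


class TestACAT:
    def test_identical_pvalues_fixed_point(self):
        assert assoc.acat(np.full(7, 0.037)) == pytest.approx(0.037, rel=1e-10)

    def test_single_p_identity(self):
        assert assoc.acat([0.2]) == pytest.approx(0.2)

    def test_cauchy_cdf_oracle(self):
        stat = np.tan((0.5 - np.array([0.01, 0.04])) * np.pi).mean()
        assert assoc.acat([0.01, 0.04]) == pytest.approx(cauchy.sf(stat), rel=1e-12)
        assert assoc.acat([0.01, 0.04]) == pytest.approx(0.016, abs=5e-4)

    def test_monotone_in_each_argument(self):
        base = assoc.acat([0.02, 0.3])
        assert assoc.acat([0.01, 0.3]) < base < assoc.acat([0.05, 0.3])

    def test_boundary_values_clipped_with_warning(self):
        with pytest.warns(UserWarning):
            p = assoc.acat([1.0, 0.5])
        assert 0 < p <= 1


class TestDendrogramCombinations:
    def test_single_trait_reductions(self):
        for fn in (assoc.ceclc, assoc.hclc, assoc.clc_default):
            out = fn(np.array([1.5]), np.eye(1))
            assert out.p == pytest.approx(chi2.sf(2.25, 1))

    def test_two_traits_hclc_equals_single_level_clc(self, rng):
        # one merge only: HCLC's level set is the single 1-cluster partition
        z = rng.standard_normal(2)
        r = _random_corr(rng, 2)
        h = assoc.hclc(z, r)
        c = assoc.clc(z, r, np.ones((2, 1)))
        assert h.p == pytest.approx(c.p, rel=1e-10)

    def test_null_calibration_at_five_percent(self, rng):
        # z ~ N(0, R): empirical size within the binomial band for 2e4 draws
        k = 8
        r = _random_corr(rng, k)
        chol = np.linalg.cholesky(r)
        z = rng.standard_normal((20_000, k)) @ chol.T
        pvals = assoc.batch_test(z, r, tests=("ceclc", "hclc", "omnibus", "obrien"))
        half = 1.96 * np.sqrt(0.05 * 0.95 / 20_000)
        for t, p in pvals.items():
            assert abs((p <= 0.05).mean() - 0.05) < half + 0.002, t


class TestBatchConsistency:
    def test_batch_matches_per_snp_functions(self, rng):
        m, k = 12, 6
        z = rng.standard_normal((m, k))
        r = _random_corr(rng, k)
        batch = assoc.batch_test(z, r, tests=("obrien", "omnibus", "clc", "ceclc", "hclc"))
        for j in range(m):
            assert batch["obrien"][j] == pytest.approx(assoc.obrien(z[j], r).p, rel=1e-8)
            assert batch["omnibus"][j] == pytest.approx(assoc.omnibus(z[j], r).p, rel=1e-8)
            assert batch["clc"][j] == pytest.approx(assoc.clc_default(z[j], r).p, rel=1e-8)
            assert batch["ceclc"][j] == pytest.approx(assoc.ceclc(z[j], r).p, rel=1e-8)
            assert batch["hclc"][j] == pytest.approx(assoc.hclc(z[j], r).p, rel=1e-8)

    def test_batch_net_matches_module_loop(self, rng):
        m, k = 8, 6
        z = rng.standard_normal((m, k))
        r = _random_corr(rng, k)
        labels = np.array([0, 0, 1, 1, 1, 2])
        batch = assoc.batch_test(z, r, labels=labels, tests=("omnibus",))
        part = ModulePartition(labels, [f"t{i}" for i in range(k)], np.ones(k), 3)
        for j in range(m):
            rep = assoc.test_snp_net(z[j], r, part, "omnibus")
            assert batch["omnibus"][j] == pytest.approx(rep.combined_p, rel=1e-8)


class TestNetMode:
    def test_single_module_equals_no_mode(self, rng):
        z = rng.standard_normal(5)
        r = _random_corr(rng, 5)
        rep = assoc.test_snp_net(z, r, np.zeros(5, dtype=int), "ceclc")
        assert rep.combined_p == pytest.approx(assoc.test_snp_no(z, r, "ceclc").p)

    def test_bonferroni_combination(self, rng):
        # module p's (0.001, 0.5, 0.2) with C = 3 modules -> 0.003
        outcome_ps = [0.001, 0.5, 0.2]
        combined = min(1.0, 3 * min(outcome_ps))
        assert combined == pytest.approx(0.003)
        z = rng.standard_normal(6)
        r = np.eye(6)
        rep = assoc.test_snp_net(z, r, np.array([0, 0, 1, 1, 2, 2]), "omnibus")
        expected = min(1.0, 3 * min(o.p for o in rep.outcomes))
        assert rep.combined_p == pytest.approx(expected)

    def test_combined_p_is_valid_under_null(self, rng):
        k = 6
        r = _random_corr(rng, k)
        chol = np.linalg.cholesky(r)
        z = rng.standard_normal((10_000, k)) @ chol.T
        labels = np.array([0, 0, 1, 1, 2, 2])
        p = assoc.batch_test(z, r, labels=labels, tests=("omnibus",))["omnibus"]
        for alpha in (0.01, 0.05, 0.2):
            assert (p <= alpha).mean() <= alpha + 1.96 * np.sqrt(alpha / 10_000) + 0.003


class TestEstimateR:
    def test_independent_columns_near_identity(self, rng):
        y = rng.standard_normal((100_000, 4))
        r = assoc.estimate_R(y)
        off = r[~np.eye(4, dtype=bool)]
        assert np.abs(off).max() < 0.01 + 3 / np.sqrt(100_000)

    def test_duplicated_column_floored_invertible(self, rng):
        y = rng.standard_normal((200, 3))
        y = np.column_stack([y, y[:, 0]])
        r = assoc.estimate_R(y)
        assert np.linalg.eigvalsh(r).min() > 0
        np.linalg.inv(r)

    def test_constant_column_rejected(self, rng):
        y = rng.standard_normal((50, 2))
        y[:, 1] = 3.0
        with pytest.raises(ValueError, match="constant"):
            assoc.estimate_R(y)


class TestUnivariateZ:
    def test_quantitative_reuses_score_machinery(self):
        z = assoc.univariate_z(np.array([1.0, 2.0, 3.0]), np.array([0.0, 1.0, 2.0]))
        assert z == pytest.approx(np.sqrt(3.0))

    def test_quantile_magnitude_from_p(self):
        assert norm.isf(1.0 / 2.0) == pytest.approx(0.0)  # p = 1 -> z = 0
        assert -norm.isf(0.05 / 2.0) == pytest.approx(-1.95996, abs=1e-5)

    def test_binary_trait_sign_and_magnitude(self, rng):
        n = 500
        g = rng.binomial(2, 0.3, n).astype(float)
        y = np.zeros(n)
        y[np.argsort(-g)[:50]] = 1.0  # cases enriched for minor alleles
        z = assoc.univariate_z(y, g, trait_kind="binary")
        assert z > 2.0


class TestMultiPhen:
    def test_strong_effect_detected(self, rng):
        n = 400
        y = rng.standard_normal(n)
        g = (y + rng.standard_normal(n) * 0.4 > 0.4).astype(float) + (
            y + rng.standard_normal(n) * 0.4 > 1.2
        )
        out = assoc.multiphen(g, y[:, None])
        assert out.p < 1e-4 and out.df == 1

    def test_constant_genotype_returns_nan(self, rng):
        out = assoc.multiphen(np.ones(50), rng.standard_normal((50, 2)))
        assert np.isnan(out.p)

    def test_permutation_null_uniform(self, rng):
        n = 300
        g = rng.binomial(2, 0.3, n).astype(float)
        y = rng.standard_normal((n, 2))
        ps = []
        for _ in range(150):
            ps.append(assoc.multiphen(g, y[rng.permutation(n)]).p)
        assert kstest(np.array(ps), "uniform").pvalue > 0.01
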