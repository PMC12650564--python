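import numpy as np
import pytest

from gpcomp import (
    SimConfig,
    compare_g,
    compressed_g,
    gblup_predict,
    reml_variance_components,
    simulate_genotypes,
    solve_mme,
    vanraden_g,
)
from gpcomp.errors import ConsistencyError, EmptyDataError
from gpcomp.kinship_gblup import KinshipMatrix, VarianceComponents


def brute_vanraden(m):
    m = np.asarray(m, dtype=float)
    p = m.mean(axis=0) / 2
    w = m - 2 * p
    return w @ w.T / np.sum(2 * p * (1 - p))


class TestVanRaden:
    def test_toy_against_brute_force(self, toy_matrix):
        g = vanraden_g(toy_matrix)
        np.testing.assert_allclose(g.values, brute_vanraden(toy_matrix.values))

    def test_identical_individuals(self):
        m = np.array([[0, 1, 2, 1], [0, 1, 2, 1], [2, 1, 0, 1]], dtype=np.int8)
        g = vanraden_g(m).values
        assert g[0, 0] == pytest.approx(g[1, 1])
        assert g[0, 1] == pytest.approx(g[0, 0])

    def test_mean_diagonal_near_one_under_hwe(self):
        g = simulate_genotypes(
            SimConfig(n_individuals=200, m_snps=5000, n_qtl=10, seed=42)
        )
        k = vanraden_g(g)
        assert k.values.diagonal().mean() == pytest.approx(1.0, abs=0.05)

    def test_monomorphic_rejected(self):
        with pytest.raises(EmptyDataError):
            vanraden_g(np.zeros((3, 4), dtype=np.int8))


class TestCompressedG:
    def test_toy_against_brute_force(self):
        x = np.array([[0.1, 0.9], [0.5, 0.2], [0.8, 0.6]])
        z = (x - x.mean(0)) / x.std(0, ddof=1)
        np.testing.assert_allclose(compressed_g(x).values, z @ z.T / 2)

    def test_mean_diagonal_standardization_identity(self):
        # mean diagonal = average column variance after scaling:
        # exactly (n-1)/n with the sample-sd denominator, 1 with ddof=0
        rng = np.random.default_rng(0)
        x = rng.uniform(size=(50, 200))
        assert compressed_g(x).values.diagonal().mean() == pytest.approx(
            49 / 50, abs=1e-12
        )
        assert compressed_g(x, ddof=0).values.diagonal().mean() == pytest.approx(
            1.0, abs=1e-12
        )

    def test_duplicated_rows(self):
        rng = np.random.default_rng(1)
        x = rng.uniform(size=(5, 20))
        x[1] = x[0]
        g = compressed_g(x).values
        assert g[0, 1] == pytest.approx(g[0, 0])

    def test_zero_variance_columns_dropped(self):
        rng = np.random.default_rng(2)
        x = rng.uniform(size=(10, 5))
        x[:, 2] = 0.5
        g = compressed_g(x)
        assert g.n_features == 4

    def test_all_constant_rejected(self):
        with pytest.raises(EmptyDataError):
            compressed_g(np.full((5, 3), 0.7))


class TestCompareG:
    def test_self_is_one(self, toy_matrix):
        g = vanraden_g(toy_matrix)
        assert compare_g(g, g) == pytest.approx(1.0)

    def test_scale_invariance(self, toy_matrix):
        g = vanraden_g(toy_matrix)
        g2 = KinshipMatrix(2 * g.values, g.flavor, g.n_features)
        assert compare_g(g, g2) == pytest.approx(1.0)

    def test_negation(self, toy_matrix):
        g = vanraden_g(toy_matrix)
        g2 = KinshipMatrix(-g.values, g.flavor, g.n_features)
        assert compare_g(g, g2) == pytest.approx(-1.0)

    def test_symmetric_in_arguments(self):
        rng = np.random.default_rng(3)
        a = rng.normal(size=(6, 6)); a = a @ a.T
        b = rng.normal(size=(6, 6)); b = b @ b.T
        assert compare_g(a, b) == pytest.approx(compare_g(b, a))

    def test_dimension_mismatch(self):
        with pytest.raises(ConsistencyError):
            compare_g(np.eye(3), np.eye(4))


@pytest.fixture(scope="module")
def reml_panel():
    g = simulate_genotypes(SimConfig(n_individuals=500, m_snps=2000, n_qtl=50, seed=11))
    G = vanraden_g(g)
    w, u = np.linalg.eigh(G.stabilized())
    L = u * np.sqrt(np.clip(w, 0, None))
    return G, L


class TestREML:
    def test_h2_recovery(self, reml_panel):
        G, L = reml_panel
        ests = []
        for rep in range(20):
            rng = np.random.default_rng(100 + rep)
            a = L @ rng.normal(size=500)
            y = a + rng.normal(size=500)  # sigma_a2 ~ 1 (diag ~ 1), sigma_e2 = 1
            ests.append(reml_variance_components(y, None, G).h2)
        assert np.mean(ests) == pytest.approx(0.5, abs=0.1)

    def test_pure_noise_low_h2(self, reml_panel):
        G, _ = reml_panel
        ests = []
        for rep in range(20):
            rng = np.random.default_rng(500 + rep)
            y = rng.normal(size=500)
            with np.errstate(all="ignore"):
                import warnings

                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    ests.append(reml_variance_components(y, None, G).h2)
        assert np.mean(ests) < 0.15

    def test_identity_kinship_warns(self):
        rng = np.random.default_rng(0)
        y = rng.normal(size=50)
        G = KinshipMatrix(np.eye(50), "vanraden", 10)
        with pytest.warns(UserWarning, match="identifiable"):
            reml_variance_components(y, None, G)

    def test_scaling_invariance(self, reml_panel):
        G, L = reml_panel
        rng = np.random.default_rng(7)
        y = L @ rng.normal(size=500) + rng.normal(size=500)
        vc1 = reml_variance_components(y, None, G)
        vc2 = reml_variance_components(3.0 * y, None, G)
        assert vc2.h2 == pytest.approx(vc1.h2, abs=1e-4)
        assert vc2.sigma_a2 == pytest.approx(9.0 * vc1.sigma_a2, rel=1e-3)


class TestSolveMme:
    def test_matches_rr_blup(self, small_panel):
        """GBLUP == ridge SNP-BLUP, the classical equivalence oracle."""
        g = small_panel.genotypes
        y = small_panel.phenotypes.trait_vector("trait", g.individual_ids)
        G = vanraden_g(g)
        vc = reml_variance_components(y, None, G)
        mask = np.ones(g.n_individuals, bool)
        mask[:30] = False
        res = solve_mme(y[mask], None, G, vc, mask)

        m = g.values.astype(float)
        p = m.mean(0) / 2
        w = m - 2 * p
        c = np.sum(2 * p * (1 - p))
        lam = vc.sigma_e2 / (vc.sigma_a2 / c)
        wo = w[mask]
        x1 = np.ones((mask.sum(), 1))
        lhs = np.block(
            [[x1.T @ x1, x1.T @ wo], [wo.T @ x1, wo.T @ wo + lam * np.eye(w.shape[1])]]
        )
        rhs = np.concatenate([x1.T @ y[mask], wo.T @ y[mask]])
        sol = np.linalg.solve(lhs, rhs)
        np.testing.assert_allclose(res.breeding_values, w @ sol[1:], atol=1e-6)
        assert res.fixed_effects[0] == pytest.approx(sol[0], abs=1e-6)

    def test_tiny_closed_form(self):
        # 2 observed individuals, G = I: a_i = shrunken centered phenotype,
        # verified against a direct dense solve of the joint GLS system
        y = np.array([1.0, 3.0])
        G = KinshipMatrix(np.eye(2), "vanraden", 2)
        vc = VarianceComponents(2.0, 1.0, 0.0)
        res = solve_mme(y, None, G, vc, None)
        # direct: V = 2I + I = 3I; mu = mean; a = 2 * (y - mu) / 3
        np.testing.assert_allclose(res.fixed_effects, [2.0], atol=1e-10)
        np.testing.assert_allclose(res.breeding_values, [-2 / 3, 2 / 3], atol=1e-10)

    def test_ridge_limit(self):
        rng = np.random.default_rng(4)
        n = 20
        a = rng.normal(size=(n, n))
        G = KinshipMatrix(a @ a.T / n, "vanraden", n)
        y = rng.normal(size=n)
        vc = VarianceComponents(1e-10, 1.0, 0.0)
        res = solve_mme(y, None, G, vc, None)
        np.testing.assert_allclose(res.breeding_values, 0.0, atol=1e-6)
        assert res.fixed_effects[0] == pytest.approx(y.mean(), abs=1e-6)

    def test_translation_equivariance(self, small_panel):
        g = small_panel.genotypes
        y = small_panel.phenotypes.trait_vector("trait", g.individual_ids)
        G = vanraden_g(g)
        vc = VarianceComponents(1.0, 1.0, 0.0)
        r1 = solve_mme(y, None, G, vc, None)
        r2 = solve_mme(y + 5.0, None, G, vc, None)
        np.testing.assert_allclose(r1.breeding_values, r2.breeding_values, atol=1e-8)
        assert r2.fixed_effects[0] - r1.fixed_effects[0] == pytest.approx(5.0, abs=1e-8)


class TestGblupPredict:
    def test_identical_rows_identical_gebv(self):
        g = simulate_genotypes(SimConfig(n_individuals=60, m_snps=200, n_qtl=20, seed=5))
        vals = g.values.copy()
        vals[1] = vals[0]
        rng = np.random.default_rng(0)
        y = rng.normal(size=60)
        gebv = gblup_predict(vals, y, flavor="vanraden")
        assert gebv[0] == pytest.approx(gebv[1], abs=1e-8)

    def test_accuracy_increases_with_h2(self):
        from gpcomp import simulate

        accs = {}
        for h2 in (0.1, 0.9):
            vals = []
            for seed in range(3):
                res = simulate(
                    SimConfig(n_individuals=150, m_snps=400, n_qtl=40, h2=h2, seed=seed)
                )
                y = res.phenotypes.trait_vector("trait", res.genotypes.individual_ids)
                mask = np.ones(150, bool)
                mask[:40] = False
                gebv = gblup_predict(res.genotypes, y, observed_mask=mask)
                vals.append(np.corrcoef(gebv[:40], y[:40])[0, 1])
            accs[h2] = np.mean(vals)
        assert accs[0.9] > accs[0.1]

    def test_compressed_vs_vanraden_on_mild_compression(self):
        # a family-structured panel has real off-diagonal relatedness for
        # the compressed kinship to preserve; unrelated panels leave the
        # off-diagonal dominated by marker-sampling noise
        from gpcomp import AutoencoderSpec, SimConfig, compress_all, divide_chunks, simulate

        res = simulate(SimConfig(
            n_individuals=120, m_snps=300, n_qtl=30, h2=0.5,
            n_families=8, ld_rho=0.5, seed=3,
        ))
        g = res.genotypes
        cs = divide_chunks(g, 10)
        spec = AutoencoderSpec(encoder_layer_sizes=(40, 20), epochs=60, seed=0)
        cm = compress_all(cs, spec, g.individual_ids)
        r = compare_g(compressed_g(cm), vanraden_g(g))
        assert r > 0.8
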