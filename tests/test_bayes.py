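import numpy as np
import pytest

from gpcomp import (
    BayesConfig,
    bayes_a,
    bayes_b,
    bayes_cpi,
    bayes_lasso,
    gebv_from_posterior,
)
from gpcomp.bayes import effective_sample_size
from gpcomp.errors import ConfigurationError, ConsistencyError


@pytest.fixture(scope="module")
def sparse_sim():
    """n=400, d=200, 5 strong QTL, h2 ~ 0.6."""
    rng = np.random.default_rng(21)
    x = rng.integers(0, 3, size=(400, 200)).astype(float)
    beta = np.zeros(200)
    qtl = np.array([10, 50, 90, 130, 170])
    beta[qtl] = rng.normal(scale=2.0, size=5)
    g = (x - x.mean(0)) @ beta
    e = rng.normal(scale=np.sqrt(np.var(g) * 0.4 / 0.6), size=400)
    return x, g + e, qtl


SHORT = dict(n_iterations=1200, burn_in=300)


class TestConfig:
    def test_burn_in_bounds(self):
        with pytest.raises(ConfigurationError):
            BayesConfig(n_iterations=100, burn_in=100)

    def test_pi_range(self):
        with pytest.raises(ConfigurationError):
            BayesConfig(pi=1.5)

    def test_retained_draw_accounting(self):
        cfg = BayesConfig(n_iterations=1000, burn_in=300, thinning=7)
        assert cfg.n_retained == (1000 - 300) // 7


class TestBayesA:
    def test_conjugate_oracle_single_feature(self):
        """With both variances fixed, beta's conditional is exact normal."""
        rng = np.random.default_rng(5)
        x = rng.normal(size=(200, 1))
        y = 0.7 * x[:, 0] + rng.normal(scale=0.5, size=200)
        cfg = BayesConfig(
            method="A", n_iterations=11_000, burn_in=1_000,
            fix_residual_variance=0.25, fix_effect_variance=10.0, seed=2,
        )
        s = bayes_a(x, y, cfg)
        xc = x[:, 0] - x[:, 0].mean()
        c = xc @ xc + 0.25 / 10.0
        analytic_mean = (xc @ (y - y.mean())) / c
        mc_se = np.sqrt(0.25 / c) / np.sqrt(s.ess("sigma_e2") + 1)
        # 3 MC standard errors with a generous floor for mu-coupling noise
        assert abs(s.effects[0] - analytic_mean) < max(3 * mc_se, 5e-3)

    def test_shuffled_y_shrinks_effects(self, sparse_sim):
        x, y, _ = sparse_sim
        cfg = BayesConfig(method="A", seed=4, **SHORT)
        fit = bayes_a(x, y, cfg)
        rng = np.random.default_rng(0)
        fit_null = bayes_a(x, rng.permutation(y), cfg)
        assert np.mean(np.abs(fit_null.effects)) < np.mean(np.abs(fit.effects))

    def test_zero_variance_y_degenerates(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(50, 5))
        with pytest.warns(UserWarning, match="zero variance|boundary"):
            s = bayes_a(x, np.full(50, 2.0), BayesConfig(method="A", n_iterations=300, burn_in=100, seed=0))
        assert np.abs(s.effects).max() < 1e-2

    def test_seed_reproducibility(self, sparse_sim):
        x, y, _ = sparse_sim
        cfg = BayesConfig(method="A", seed=9, n_iterations=400, burn_in=100)
        a = bayes_a(x[:100, :50], y[:100], cfg)
        b = bayes_a(x[:100, :50], y[:100], cfg)
        np.testing.assert_array_equal(a.effects, b.effects)

    def test_grid_oracle_two_markers(self):
        """Long-run posterior means match brute-force grid integration.

        Two markers, fixed residual variance; the flat intercept is
        integrated out analytically in the oracle by projecting out the
        mean, and each marker variance marginalizes to a scaled-t prior.
        """
        from scipy import stats

        rng = np.random.default_rng(12)
        x = rng.normal(size=(30, 2))
        y = 0.5 * x[:, 0] - 0.3 * x[:, 1] + rng.normal(scale=0.6, size=30)
        sigma_e2 = 0.36
        nu, s_eff = 4.2, 0.5
        cfg = BayesConfig(
            method="A", n_iterations=40_000, burn_in=2_000,
            fix_residual_variance=sigma_e2, df_effect=nu, scale_effect=s_eff,
            seed=3,
        )
        fit = bayes_a(x, y, cfg)

        proj = np.eye(30) - np.full((30, 30), 1 / 30)
        grid = np.linspace(-1.5, 1.5, 121)
        b1, b2 = np.meshgrid(grid, grid, indexing="ij")
        log_post = np.empty_like(b1)
        t_scale = np.sqrt(s_eff)
        for i in range(grid.size):
            resid = proj @ (
                y[None, :] - np.outer(b1[i], x[:, 0]) - b2[i][:, None] * x[None, :, 1]
            ).T
            rss = (resid ** 2).sum(axis=0)
            log_post[i] = (
                -rss / (2 * sigma_e2)
                + stats.t.logpdf(b1[i] / t_scale, df=nu)
                + stats.t.logpdf(b2[i] / t_scale, df=nu)
            )
        w = np.exp(log_post - log_post.max())
        w /= w.sum()
        oracle = (w * b1).sum(), (w * b2).sum()
        assert fit.effects[0] == pytest.approx(oracle[0], abs=0.03)
        assert fit.effects[1] == pytest.approx(oracle[1], abs=0.03)


class TestBayesB:
    def test_pi_one_forces_zero(self, sparse_sim):
        x, y, _ = sparse_sim
        cfg = BayesConfig(method="B", pi=1.0, n_iterations=300, burn_in=100, seed=0)
        s = bayes_b(x[:100], y[:100], cfg)
        assert (s.effects == 0).all()
        pred = gebv_from_posterior(s, x[:100])
        np.testing.assert_allclose(pred, s.intercept)

    def test_pi_zero_close_to_bayes_a(self, sparse_sim):
        x, y, _ = sparse_sim
        xs, ys = x[:150, :60], y[:150]
        cfg_b = BayesConfig(method="B", pi=0.0, seed=6, **SHORT)
        cfg_a = BayesConfig(method="A", seed=6, **SHORT)
        fb = bayes_b(xs, ys, cfg_b)
        fa = bayes_a(xs, ys, cfg_a)
        pa = gebv_from_posterior(fa, xs)
        pb = gebv_from_posterior(fb, xs)
        assert np.corrcoef(pa, pb)[0, 1] > 0.98

    def test_true_qtl_get_higher_inclusion(self, sparse_sim):
        x, y, qtl = sparse_sim
        cfg = BayesConfig(method="B", pi=0.9, seed=8, **SHORT)
        s = bayes_b(x, y, cfg)
        null = np.setdiff1d(np.arange(x.shape[1]), qtl)
        assert s.inclusion_prob[qtl].mean() > s.inclusion_prob[null].mean()

    def test_variance_draws_positive(self, sparse_sim):
        x, y, _ = sparse_sim
        cfg = BayesConfig(method="B", pi=0.9, n_iterations=300, burn_in=100, seed=0)
        s = bayes_b(x[:80, :40], y[:80], cfg)
        assert (s.samples["sigma_e2"] > 0).all()


class TestBayesCpi:
    def test_recovers_nonnull_fraction(self):
        rng = np.random.default_rng(9)
        n, d = 500, 300
        x = rng.normal(size=(n, d))
        idx = rng.choice(d, 30, replace=False)
        beta = np.zeros(d)
        beta[idx] = rng.normal(size=30)
        y = x @ beta + rng.normal(size=n)
        cfg = BayesConfig(method="Cpi", pi=0.5, n_iterations=2500, burn_in=500, seed=3)
        s = bayes_cpi(x, y, cfg)
        assert 1.0 - s.pi_mean == pytest.approx(0.10, abs=0.1)

    def test_all_null_high_pi(self):
        # n >> d so the data carry clear evidence of nullity; with n ~ d
        # the uniform Beta prior leaves pi diffuse around 0.85
        rng = np.random.default_rng(10)
        x = rng.normal(size=(800, 100))
        y = rng.normal(size=800)
        cfg = BayesConfig(method="Cpi", pi=0.5, n_iterations=2500, burn_in=500, seed=1)
        s = bayes_cpi(x, y, cfg)
        assert s.pi_mean > 0.9

    def test_inclusion_count_bounds(self, sparse_sim):
        x, y, _ = sparse_sim
        cfg = BayesConfig(method="Cpi", pi=0.5, n_iterations=400, burn_in=100, seed=2)
        s = bayes_cpi(x[:100], y[:100], cfg)
        assert (s.inclusion_prob >= 0).all() and (s.inclusion_prob <= 1).all()


class TestBayesLasso:
    def test_huge_lambda_shrinks_to_zero(self, sparse_sim):
        x, y, _ = sparse_sim
        cfg = BayesConfig(
            method="Lasso", gamma_shape=1e6, gamma_rate=1e-2,  # prior mass on huge lambda
            n_iterations=600, burn_in=200, seed=0,
        )
        s = bayes_lasso(x[:100, :50], y[:100], cfg)
        assert np.abs(s.effects).max() < 0.05

    def test_shrinks_below_ols(self):
        rng = np.random.default_rng(11)
        x = rng.normal(size=(100, 1))
        y = 0.8 * x[:, 0] + rng.normal(scale=1.0, size=100)
        cfg = BayesConfig(method="Lasso", seed=5, **SHORT)
        s = bayes_lasso(x, y, cfg)
        xc = x[:, 0] - x[:, 0].mean()
        ols = (xc @ (y - y.mean())) / (xc @ xc)
        assert 0 < abs(s.effects[0]) < abs(ols)

    def test_gebv_bookkeeping(self, sparse_sim):
        x, y, _ = sparse_sim
        cfg = BayesConfig(method="Lasso", n_iterations=400, burn_in=100, seed=1)
        s = bayes_lasso(x[:80, :30], y[:80], cfg)
        manual = (x[:80, :30] - s.column_means) / s.column_scales @ s.effects + s.intercept
        np.testing.assert_allclose(gebv_from_posterior(s, x[:80, :30]), manual)


class TestGebvFromPosterior:
    def test_identical_rows(self, sparse_sim):
        x, y, _ = sparse_sim
        cfg = BayesConfig(method="A", n_iterations=300, burn_in=100, seed=0)
        s = bayes_a(x[:60, :20], y[:60], cfg)
        x_new = np.vstack([x[0, :20], x[0, :20]])
        pred = gebv_from_posterior(s, x_new)
        assert pred[0] == pred[1]

    def test_translation_invariance_of_contrasts(self, sparse_sim):
        x, y, _ = sparse_sim
        cfg = BayesConfig(method="A", n_iterations=300, burn_in=100, seed=0)
        s = bayes_a(x[:60, :20], y[:60], cfg)
        p1 = gebv_from_posterior(s, x[60:80, :20])
        p2 = gebv_from_posterior(s, x[60:80, :20] + 0.0)  # same columns
        np.testing.assert_allclose(np.diff(p1), np.diff(p2))

    def test_column_mismatch(self, sparse_sim):
        x, y, _ = sparse_sim
        cfg = BayesConfig(method="A", n_iterations=300, burn_in=100, seed=0)
        s = bayes_a(x[:60, :20], y[:60], cfg)
        with pytest.raises(ConsistencyError):
            gebv_from_posterior(s, x[:5, :19])


class TestDiagnostics:
    def test_ess_iid_close_to_n(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=2000)
        assert effective_sample_size(x) > 1000

    def test_ess_correlated_much_smaller(self):
        rng = np.random.default_rng(0)
        n = 2000
        x = np.empty(n)
        x[0] = 0
        for i in range(1, n):
            x[i] = 0.98 * x[i - 1] + rng.normal()
        assert effective_sample_size(x) < 300
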