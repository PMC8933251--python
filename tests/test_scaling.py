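"""Model density, collapsed marginal, diagnostics, and posterior derivations."""

import math

import numpy as np
import pytest
from scipy import stats

from coralscale import scaling as sc
from coralscale import synthdata as sd


def tiny_data(n=5, n_species=2, seed=0):
    rng = np.random.default_rng(seed)
    return sc.ModelData(
        ln_rate=rng.normal(-2, 1, n),
        ln_area=rng.uniform(2, 7, n),
        species_idx=rng.integers(0, n_species, n),
        species=tuple(f"sp{i}" for i in range(n_species)),
    )


def params(n_species=2, **kw):
    defaults = dict(ln_alpha=-6.0, beta=0.9, sigma=0.3, sigma_zeta=(0.5, 0.1),
                    rho=-0.5, delta=np.full((n_species, 2), 0.3))
    defaults.update(kw)
    return sc.ScalingParams(**defaults)


class TestLogPosterior:
    def test_matches_term_by_term_oracle(self):
        # Independent density-sum oracle: every term via scipy frozen
        # distributions, zeta assembled from the explicit 2x2 Cholesky.
        data = tiny_data(5, 2, seed=1)
        p = params(2, delta=np.array([[0.4, -1.2], [0.1, 0.8]]))
        s1, s2 = p.sigma_zeta
        chol = np.array([[s1, 0.0], [s2 * p.rho, s2 * math.sqrt(1 - p.rho ** 2)]])
        zeta = p.delta @ chol.T
        expected = 0.0
        for i in range(data.n_obs):
            s = data.species_idx[i]
            mu = (p.ln_alpha + zeta[s, 0]) + (p.beta + zeta[s, 1]) * data.ln_area[i]
            expected += stats.norm(mu, p.sigma).logpdf(data.ln_rate[i])
        expected += stats.norm(0, 5).logpdf(p.ln_alpha) + stats.norm(0, 5).logpdf(p.beta)
        expected += stats.gamma(2, scale=10).logpdf(p.sigma)
        expected += stats.gamma(2, scale=10).logpdf(s1) + stats.gamma(2, scale=10).logpdf(s2)
        expected += math.log(0.5)  # LKJ(1) for a 2x2: uniform on (-1, 1)
        expected += stats.norm(0, 1).logpdf(p.delta).sum()
        assert sc.log_posterior(p, data) == pytest.approx(expected, rel=1e-10)

    def test_unit_area_reduces_to_intercept_density(self):
        data = sc.ModelData(ln_rate=np.array([-5.5]), ln_area=np.array([0.0]),
                            species_idx=np.array([0]), species=("sp0",))
        p = params(1, delta=np.zeros((1, 2)))
        lp = sc.log_posterior(p, data)
        p0 = params(1, beta=0.0, delta=np.zeros((1, 2)))
        # beta only enters through beta * ln(area) = 0: same density.
        assert lp == pytest.approx(sc.log_posterior(p0, data) - (
            stats.norm(0, 5).logpdf(0.0) - stats.norm(0, 5).logpdf(0.9)), rel=1e-12)

    def test_zero_hierarchy_collapses_to_pooled_regression(self):
        # With sigma_zeta = 0 the data term differences across beta are
        # exactly those of the single-level pooled model.
        data = tiny_data(20, 3, seed=2)
        deltas = np.ones((3, 2))

        def pooled_data_term(beta):
            mu = -6.0 + beta * data.ln_area
            return stats.norm(mu, 0.3).logpdf(data.ln_rate).sum()

        lp_a = sc.log_posterior(params(3, beta=0.8, sigma_zeta=(0.0, 0.0), delta=deltas), data)
        lp_b = sc.log_posterior(params(3, beta=1.1, sigma_zeta=(0.0, 0.0), delta=deltas), data)
        prior_diff = stats.norm(0, 5).logpdf(0.8) - stats.norm(0, 5).logpdf(1.1)
        assert lp_a - lp_b == pytest.approx(
            pooled_data_term(0.8) - pooled_data_term(1.1) + prior_diff, rel=1e-10)

    def test_invalid_parameters_rejected(self):
        data = tiny_data()
        with pytest.raises(ValueError):
            sc.log_posterior(params(sigma=-1.0), data)
        with pytest.raises(ValueError):
            sc.log_posterior(params(rho=1.5), data)


class TestCollapsedMarginal:
    def test_matches_full_gaussian_integral_oracle(self):
        # Oracle: with coefficients integrated out, ln R ~ N(0, C) with
        # C = sigma^2 I + X V0 X^T built explicitly (n x n).
        data = tiny_data(12, 3, seed=3)
        model = sc._CollapsedModel(data, sc.PriorSpec())
        n, s = data.n_obs, data.n_species
        x = np.zeros((n, 2 + 2 * s))
        x[:, 0] = 1.0
        x[:, 1] = data.ln_area
        x[np.arange(n), 2 + data.species_idx] = 1.0
        x[np.arange(n), 2 + s + data.species_idx] = data.ln_area
        for sigma, s1, s2, rho in [(0.3, 0.5, 0.1, -0.5), (1.2, 0.01, 2.0, 0.9),
                                   (0.05, 1e-8, 1e-8, 0.0)]:
            v0 = np.zeros((2 + 2 * s, 2 + 2 * s))
            v0[0, 0] = 25.0
            v0[1, 1] = 25.0
            for j in range(s):
                v0[2 + j, 2 + j] = s1 ** 2
                v0[2 + s + j, 2 + s + j] = s2 ** 2
                v0[2 + j, 2 + s + j] = v0[2 + s + j, 2 + j] = rho * s1 * s2
            cov = sigma ** 2 * np.eye(n) + x @ v0 @ x.T
            oracle = stats.multivariate_normal(np.zeros(n), cov).logpdf(data.ln_rate)
            ours = model.marginal_loglik(sigma, s1, s2, rho)
            assert ours == pytest.approx(oracle, rel=1e-9)

    def test_conditional_coefficient_draws_match_analytic_posterior(self):
        # Moments of the exact Gaussian conditional, Monte-Carlo checked.
        data = tiny_data(30, 2, seed=4)
        model = sc._CollapsedModel(data, sc.PriorSpec())
        sigma, s1, s2, rho = 0.4, 0.6, 0.2, -0.3
        rng = np.random.default_rng(11)
        draws = np.array([model.draw_coefficients(sigma, s1, s2, rho, rng)
                          for _ in range(20_000)])
        n, s = data.n_obs, data.n_species
        x = np.zeros((n, model.p))
        x[:, 0] = 1.0
        x[:, 1] = data.ln_area
        x[np.arange(n), 2 + data.species_idx] = 1.0
        x[np.arange(n), 2 + s + data.species_idx] = data.ln_area
        v0 = np.diag([25.0, 25.0, s1 ** 2, s1 ** 2, s2 ** 2, s2 ** 2]).astype(float)
        for j in range(s):
            v0[2 + j, 2 + s + j] = v0[2 + s + j, 2 + j] = rho * s1 * s2
        prec = x.T @ x / sigma ** 2 + np.linalg.inv(v0)
        cov = np.linalg.inv(prec)
        mean = cov @ (x.T @ data.ln_rate / sigma ** 2)
        tol = 4 * np.sqrt(np.diag(cov) / 20_000) + 1e-3
        assert (np.abs(draws.mean(axis=0) - mean) <= tol).all()
        np.testing.assert_allclose(np.cov(draws.T), cov, atol=0.05 * float(np.abs(cov).max()))


class TestRhat:
    def test_same_distribution_chains_near_one(self, rng):
        x = rng.normal(0, 1, (2, 5000))
        assert sc.rhat(x) < 1.01

    def test_separated_chains_flagged(self, rng):
        x = np.stack([rng.normal(0, 1, 1000), rng.normal(100, 1, 1000)])
        assert sc.rhat(x) > 10

    def test_constant_chains_undefined(self):
        assert math.isnan(sc.rhat(np.ones((2, 100))))

    def test_agrees_with_reference_implementation(self, rng):
        az = pytest.importorskip("arviz")
        x = rng.normal(0, 1, (3, 400)) + np.linspace(0, 0.5, 3)[:, None]
        ours = sc.rhat(x)
        theirs = float(az.rhat(az.convert_to_dataset(x))["x"].values)
        assert ours == pytest.approx(theirs, abs=0.01)


def manual_draws(beta_flat, n_chains=2, species=("sp0",), config=None):
    """PosteriorDraws with hand-set beta values and inert everything else."""
    beta = np.asarray(beta_flat, dtype=float).reshape(n_chains, -1)
    c, t = beta.shape
    cfg = config or sc.FitConfig(n_chains=c, draws_per_chain=t + 1, warmup=1)
    s = len(species)
    shape = (c, t)
    return sc.PosteriorDraws(
        ln_alpha=np.zeros(shape), beta=beta, sigma=np.full(shape, 0.3),
        sigma_zeta=np.zeros(shape + (2,)), rho=np.zeros(shape),
        delta=np.zeros(shape + (s, 2)), species=tuple(species), config=cfg,
    )


class TestPosteriorDerivations:
    def test_summary_on_known_draws(self):
        draws = manual_draws(np.arange(1.0, 101.0))
        row = sc.summarize_posterior(draws).set_index("parameter").loc["beta"]
        assert row["mean"] == pytest.approx(50.5)
        assert row["q2.5"] == pytest.approx(np.quantile(np.arange(1.0, 101.0), 0.025))

    def test_summary_constant_draws_degenerate(self):
        draws = manual_draws(np.full(100, 3.3))
        row = sc.summarize_posterior(draws).set_index("parameter").loc["beta"]
        assert row["mean"] == row["q2.5"] == row["q97.5"] == pytest.approx(3.3)

    def test_area_specific_exponent_is_one_minus_beta(self):
        draws = manual_draws([1.0, 0.881, 0.5, 1.2])
        np.testing.assert_allclose(sc.area_specific_exponent(draws),
                                   [0.0, 0.119, 0.5, -0.2], atol=1e-12)
        assert np.mean(sc.area_specific_exponent(draws)) == pytest.approx(
            1 - draws.flat(draws.beta).mean())

    def test_prob_isometry_counts_tail(self):
        draws = manual_draws([0.9, 1.0, 1.1, 1.2])
        assert sc.prob_isometry(draws) == 0.75
        assert sc.prob_isometry(manual_draws([0.5, 0.8, 0.9, 0.99])) == 0.0

    def test_prob_isometry_matches_gaussian_tail(self, rng):
        draws = manual_draws(rng.normal(0.9, 0.05, 100_000))
        assert sc.prob_isometry(draws) == pytest.approx(stats.norm.sf(2.0), abs=0.01)

    def test_predict_rate_at_unit_area_is_intercept(self, fitted_draws):
        pred = sc.predict_rate(fitted_draws, fitted_draws.species[0], 1.0)
        expected = np.exp(fitted_draws.flat(fitted_draws.species_intercept)[:, 0])
        np.testing.assert_allclose(pred, expected, rtol=1e-12)

    def test_predict_rate_point_value(self):
        # alpha = 0.26, beta = 0.85 at 100 cm^2 -> 0.26 * 100^0.85 = 13.03.
        draws = manual_draws([0.85, 0.85])
        draws.ln_alpha[:] = math.log(0.26)
        pred = sc.predict_rate(draws, "sp0", 100.0)
        np.testing.assert_allclose(pred, 0.26 * 100 ** 0.85, rtol=1e-12)

    def test_predict_monotone_in_area_for_positive_slopes(self, fitted_draws):
        sp = fitted_draws.species[0]
        lo = sc.predict_rate(fitted_draws, sp, 50.0)
        hi = sc.predict_rate(fitted_draws, sp, 500.0)
        pos = fitted_draws.flat(fitted_draws.species_slope)[:, 0] > 0
        assert (hi[pos] > lo[pos]).all()

    def test_unknown_species_lists_fitted_set(self, fitted_draws):
        with pytest.raises(KeyError, match="not in fitted set"):
            sc.predict_rate(fitted_draws, "Not a coral", 100.0)

    def test_bayes_r2_zero_when_flat(self):
        data = tiny_data(20, 1, seed=5)
        draws = manual_draws([0.0, 0.0], species=("sp0",))
        r2 = sc.bayes_r2(draws, data)
        np.testing.assert_allclose(r2, 0.0, atol=1e-12)

    def test_bayes_r2_matches_variance_decomposition(self):
        # Data built with known signal and noise variances: mean R^2
        # within 0.03 of v_s / (v_s + v_n).
        truth = sd.TruthParams(ln_alpha=-6.126, beta=0.881, sigma=0.3,
                               sigma_zeta=(0.0, 0.0), rho=0.0, seed=31)
        df = sd.gen_colonies(truth, n_per_species=80, seed=31)
        df = df.rename(columns={"surface_area_3d_cm2": "area_cm2"})
        data = sc.ModelData.from_frame(df, "true_rate")
        v_s = np.var(truth.beta * data.ln_area)
        v_n = truth.sigma ** 2
        cfg = sc.FitConfig(draws_per_chain=1000, warmup=500, seed=2)
        draws = sc.sample_posterior(data, cfg=cfg)
        assert np.mean(sc.bayes_r2(draws, data)) == pytest.approx(
            v_s / (v_s + v_n), abs=0.03)


class TestSampler:
    def test_bookkeeping_and_support(self, fitted_draws):
        cfg = fitted_draws.config
        assert fitted_draws.n_retained == cfg.n_chains * (cfg.draws_per_chain - cfg.warmup)
        assert (fitted_draws.sigma > 0).all()
        assert (fitted_draws.sigma_zeta > 0).all()
        assert (np.abs(fitted_draws.rho) <= 1).all()

    def test_determinism_under_seed(self, colony_table):
        data = sc.ModelData.from_frame(colony_table, "true_rate")
        cfg = sc.FitConfig(draws_per_chain=1000, warmup=500, seed=7)
        a = sc.sample_posterior(data, cfg=cfg)
        b = sc.sample_posterior(data, cfg=cfg)
        np.testing.assert_array_equal(a.flat(a.beta), b.flat(b.beta))
        np.testing.assert_array_equal(a.flat(a.delta), b.flat(b.delta))

    def test_convergence_and_recovery_on_synthetic_truth(self, fitted_draws, default_truth):
        assert fitted_draws.converged
        assert max(fitted_draws.rhat_values.values()) < 1.05
        b = fitted_draws.flat(fitted_draws.beta)
        lo, hi = np.quantile(b, [0.025, 0.975])
        assert lo <= default_truth.beta <= hi
        la = fitted_draws.flat(fitted_draws.ln_alpha)
        lo, hi = np.quantile(la, [0.025, 0.975])
        assert lo <= default_truth.ln_alpha <= hi

    def test_nonpositive_rates_dropped_with_warning(self, colony_table):
        df = colony_table.copy()
        df.loc[df.index[:3], "true_rate"] = -1.0
        with pytest.warns(UserWarning, match="dropping 3 rows"):
            data = sc.ModelData.from_frame(df, "true_rate")
        assert data.n_obs == len(df) - 3

    def test_config_validation(self):
        with pytest.raises(ValueError):
            sc.FitConfig(draws_per_chain=100, warmup=100)
        with pytest.raises(ValueError):
            sc.FitConfig(n_chains=1)
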