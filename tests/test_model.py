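"""Likelihoods, diagnostics and the MCMC engine."""

import numpy as np
import pandas as pd
import pytest
import scipy.integrate
import scipy.stats

from phylofa.model import (MCMCSettings, ModelSpec, Predictor,
                           average_marginal_effect, beta_loglik,
                           credible_interval, fit, phylo_prior_loglik,
                           prepare_design, rhat, squeeze_proportions)
from phylofa.phylogeny import vcv
from phylofa.synthetic import (simulate_phylo_effect, simulate_proportion,
                               simulate_tree)

QUICK_MCMC = MCMCSettings(chains=4, iterations=1500, burn_in=500, thinning=2, seed=3)


def species_frame(columns: dict) -> pd.DataFrame:
    n = len(next(iter(columns.values())))
    return pd.DataFrame(columns, index=[f"sp{i:03d}" for i in range(n)])


class TestPrepareDesign:
    def test_standardization_to_unit_sd(self):
        traits = species_frame({"y": [10.0, 20.0, 30.0, 40.0],
                                "x": [1.0, 2.0, 3.0, 4.0]})
        spec = ModelSpec("y", "gaussian", (Predictor("x"),), include_phylo=False)
        d = prepare_design(traits, None, spec)
        np.testing.assert_allclose(
            d.X[:, 1], (np.array([1, 2, 3, 4.0]) - 2.5) / np.std([1, 2, 3, 4.0], ddof=1))

    def test_molpercent_to_fraction(self):
        traits = species_frame({"y": [50.0, 25.0, 10.0, 80.0],
                                "x": [1.0, 2.0, 3.0, 4.0]})
        spec = ModelSpec("y", "beta", (Predictor("x"),), include_phylo=False)
        d = prepare_design(traits, None, spec)
        np.testing.assert_allclose(d.y, [0.5, 0.25, 0.10, 0.80])
        assert not d.squeezed

    def test_boundary_proportion_squeezed(self):
        traits = species_frame({"y": [0.0, 25.0, 10.0, 80.0],
                                "x": [1.0, 2.0, 3.0, 4.0]})
        spec = ModelSpec("y", "beta", (Predictor("x"),), include_phylo=False)
        d = prepare_design(traits, None, spec)
        assert d.squeezed
        assert np.all((d.y > 0) & (d.y < 1))
        n = 4
        np.testing.assert_allclose(d.y, (np.array([0, .25, .10, .80]) * (n - 1) + 0.5) / n)

    def test_zero_variance_predictor_rejected(self):
        traits = species_frame({"y": [1.0, 2.0, 3.0, 4.0],
                                "x": [5.0, 5.0, 5.0, 5.0]})
        spec = ModelSpec("y", "gaussian", (Predictor("x"),), include_phylo=False)
        with pytest.raises(ValueError, match="zero-variance"):
            prepare_design(traits, None, spec)

    def test_missing_values_dropped(self):
        traits = species_frame({"y": [1.0, 2.0, np.nan, 4.0, 2.5, 3.5],
                                "x": [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]})
        spec = ModelSpec("y", "gaussian", (Predictor("x"),), include_phylo=False)
        d = prepare_design(traits, None, spec)
        assert d.n_dropped == 1 and len(d.species) == 5

    def test_log_transform_applied_before_standardization(self):
        x = np.array([1.0, 10.0, 100.0, 1000.0])
        traits = species_frame({"y": [1.0, 2.0, 3.0, 4.0], "x": x})
        spec = ModelSpec("y", "gaussian", (Predictor("x", log=True),),
                         include_phylo=False)
        d = prepare_design(traits, None, spec)
        lx = np.log(x)
        np.testing.assert_allclose(d.X[:, 1], (lx - lx.mean()) / lx.std(ddof=1))


class TestBetaLoglik:
    def test_uniform_density_is_zero(self):
        # mu=0.5, phi=2 is Beta(1,1), the uniform
        X = np.zeros((1, 1))
        assert beta_loglik(np.array([0.5]), X, np.array([0.0]),
                           np.array([0.0]), 2.0) == pytest.approx(0.0)

    def test_density_integrates_to_one(self):
        mu, phi = 0.3, 7.0
        eta = np.log(mu / (1 - mu))
        X = np.ones((1, 1))

        def dens(y):
            return np.exp(beta_loglik(np.array([y]), X, np.array([eta]),
                                      np.array([0.0]), phi))

        total, err = scipy.integrate.quad(dens, 1e-12, 1 - 1e-12)
        assert total == pytest.approx(1.0, abs=1e-8)

    def test_maximized_near_truth_on_iid_sample(self):
        rng = np.random.default_rng(7)
        n, b0, b1, phi = 4000, -0.5, 0.8, 12.0
        x = rng.normal(size=n)
        X = np.column_stack([np.ones(n), x])
        mu = 1 / (1 + np.exp(-(b0 + b1 * x)))
        y = np.clip(rng.beta(mu * phi, (1 - mu) * phi), 1e-12, 1 - 1e-12)
        u = np.zeros(n)
        grid = np.linspace(0.5, 1.1, 25)
        lls = [beta_loglik(y, X, np.array([b0, b]), u, phi) for b in grid]
        assert abs(grid[int(np.argmax(lls))] - b1) < 0.05

    def test_boundary_rejected(self):
        with pytest.raises(ValueError, match="strictly"):
            beta_loglik(np.array([0.0]), np.ones((1, 1)), np.array([0.0]),
                        np.array([0.0]), 2.0)


class TestPhyloPriorLoglik:
    def test_zero_vector_gives_normalizing_constant(self):
        C = np.eye(3)
        got = phylo_prior_loglik(np.zeros(3), 2.0, C)
        expected = scipy.stats.multivariate_normal(np.zeros(3), 4.0 * C).logpdf(np.zeros(3))
        assert got == pytest.approx(expected)

    def test_identity_covariance_is_independent_normals(self):
        rng = np.random.default_rng(0)
        u = rng.normal(size=5)
        got = phylo_prior_loglik(u, 1.5, np.eye(5))
        expected = scipy.stats.norm(0, 1.5).logpdf(u).sum()
        assert got == pytest.approx(expected)

    def test_worked_tree_matches_dense_oracle(self, worked_tree):
        C = vcv(worked_tree, normalize=True).matrix
        u = np.array([0.3, -0.2, 0.5])
        got = phylo_prior_loglik(u, 0.7, C)
        expected = scipy.stats.multivariate_normal(np.zeros(3), 0.49 * C).logpdf(u)
        assert got == pytest.approx(expected)

    def test_non_psd_rejected(self):
        C = np.array([[1.0, 2.0], [2.0, 1.0]])  # indefinite
        with pytest.raises(ValueError, match="positive definite"):
            phylo_prior_loglik(np.zeros(2), 1.0, C)


class TestRhat:
    def test_identical_constant_chains(self):
        assert rhat(np.full((3, 50), 2.5)) == 1.0

    def test_iid_normal_chains_near_one(self):
        rng = np.random.default_rng(1)
        assert abs(rhat(rng.normal(size=(4, 10_000))) - 1.0) < 0.01

    def test_textbook_formula_on_hand_fixture(self):
        rng = np.random.default_rng(2)
        x = np.vstack([rng.normal(0, 1, 10), rng.normal(5, 1, 10)])
        m, n = x.shape
        W = np.mean([np.var(x[c], ddof=1) for c in range(m)])
        B = n * np.var(x.mean(axis=1), ddof=1)
        expected = np.sqrt(((n - 1) / n * W + B / n) / W)
        assert rhat(x) == pytest.approx(expected, rel=1e-12)

    def test_single_chain_rejected(self):
        with pytest.raises(ValueError, match="chains"):
            rhat(np.ones((1, 100)))


class TestCredibleInterval:
    def test_matches_sort_based_oracle(self):
        draws = np.arange(1.0, 1001.0)
        lo, hi = credible_interval(draws)
        s = np.sort(draws)

        def interp_quantile(q):  # linear interpolation of order statistics
            h = (len(s) - 1) * q
            f = int(np.floor(h))
            return s[f] + (h - f) * (s[min(f + 1, len(s) - 1)] - s[f])

        assert lo == pytest.approx(interp_quantile(0.025))
        assert hi == pytest.approx(interp_quantile(0.975))

    def test_symmetric_draws_give_symmetric_interval(self):
        rng = np.random.default_rng(3)
        draws = rng.standard_normal(200_00)
        lo, hi = credible_interval(draws)
        assert lo == pytest.approx(-hi, abs=0.05)

    def test_requires_enough_draws(self):
        with pytest.raises(ValueError, match="100"):
            credible_interval(np.arange(50.0))


def gaussian_fixture(n=60, seed=5, with_phylo=False):
    rng = np.random.default_rng(seed)
    x = rng.normal(size=n)
    y = 1.0 + 0.6 * x + rng.normal(0, 0.8, n)
    traits = species_frame({"y": y, "x": x})
    return traits


class TestFit:
    def test_gaussian_flat_prior_matches_ols(self):
        traits = gaussian_fixture()
        spec = ModelSpec("y", "gaussian", (Predictor("x"),), include_phylo=False,
                         standardize_response=False, mcmc=QUICK_MCMC)
        d = prepare_design(traits, None, spec)
        post = fit(spec, d)
        ols = np.linalg.solve(d.X.T @ d.X, d.X.T @ d.y)
        got = post.beta.reshape(-1, 2).mean(axis=0)
        np.testing.assert_allclose(got, ols, atol=0.05)

    def test_retained_draw_count_contract(self):
        traits = gaussian_fixture(n=30)
        mc = MCMCSettings(chains=3, iterations=600, burn_in=200, thinning=4, seed=1)
        spec = ModelSpec("y", "gaussian", (Predictor("x"),), include_phylo=False,
                         mcmc=mc)
        post = fit(spec, prepare_design(traits, None, spec))
        assert post.beta.shape == (3, (600 - 200) // 4, 2)
        assert post.n_draws == mc.n_retained

    def test_indivisible_thinning_rejected(self):
        with pytest.raises(ValueError, match="divisible"):
            MCMCSettings(chains=2, iterations=1001, burn_in=0, thinning=2)

    def test_identical_seeds_identical_draws(self):
        traits = gaussian_fixture(n=40)
        spec = ModelSpec("y", "gaussian", (Predictor("x"),), include_phylo=False,
                         mcmc=MCMCSettings(2, 400, 200, 2, seed=9))
        d = prepare_design(traits, None, spec)
        a = fit(spec, d)
        b = fit(spec, d)
        np.testing.assert_array_equal(a.beta, b.beta)
        np.testing.assert_array_equal(a.dispersion, b.dispersion)

    def test_positive_variance_parameters(self):
        tree = simulate_tree(40, seed=2)
        C = vcv(tree, normalize=True)
        u = simulate_phylo_effect(tree, 0.4, seed=3)
        rng = np.random.default_rng(4)
        x = rng.normal(size=40)
        y = simulate_proportion(np.column_stack([np.ones(40), x]),
                                np.array([-1.0, 0.3]), u.to_numpy(), 40.0, seed=5)
        traits = pd.DataFrame({"y": 100 * y, "x": x}, index=C.labels)
        spec = ModelSpec("y", "beta", (Predictor("x"),), mcmc=QUICK_MCMC)
        d = prepare_design(traits, C, spec)
        post = fit(spec, d)
        assert (post.sigma_p > 0).all() and (post.dispersion > 0).all()
        assert post.u.shape[-1] == 40

    def test_standardization_leaves_significance_invariant(self):
        rng = np.random.default_rng(11)
        n = 80
        x = np.exp(rng.normal(size=n))  # positive, skewed covariate
        z = np.log(x)
        zstd = (z - z.mean()) / z.std(ddof=1)
        y = simulate_proportion(np.column_stack([np.ones(n), zstd]),
                                np.array([-1.0, 0.5]), np.zeros(n), 30.0, seed=12)
        traits = species_frame({"y": 100 * y, "x": x})
        flags = []
        for standardize in (True, False):
            spec = ModelSpec("y", "beta",
                             (Predictor("x", log=True, standardize=standardize),),
                             include_phylo=False, mcmc=QUICK_MCMC)
            d = prepare_design(traits, None, spec)
            post = fit(spec, d)
            flags.append(average_marginal_effect(post, d, "x").significant)
        assert flags[0] == flags[1] == True  # noqa: E712 — planted effect present


class TestAverageMarginalEffect:
    def _beta_posterior(self, n=25, seed=1):
        tree = simulate_tree(n, seed=seed)
        C = vcv(tree, normalize=True)
        rng = np.random.default_rng(seed)
        x = rng.normal(size=n)
        u = simulate_phylo_effect(tree, 0.3, seed=seed + 1)
        y = simulate_proportion(np.column_stack([np.ones(n), x]),
                                np.array([-0.8, 0.4]), u.to_numpy(), 30.0,
                                seed=seed + 2)
        traits = pd.DataFrame({"y": 100 * y, "x": x}, index=C.labels)
        spec = ModelSpec("y", "beta", (Predictor("x"),), mcmc=QUICK_MCMC)
        d = prepare_design(traits, C, spec)
        return fit(spec, d), d

    def test_gaussian_ame_equals_coefficient_draws(self):
        traits = gaussian_fixture(n=40)
        spec = ModelSpec("y", "gaussian", (Predictor("x"),), include_phylo=False,
                         mcmc=QUICK_MCMC)
        d = prepare_design(traits, None, spec)
        post = fit(spec, d)
        eff = average_marginal_effect(post, d, "x")
        draws = post.beta.reshape(-1, 2)[:, 1]
        assert eff.mean == pytest.approx(draws.mean())
        lo, hi = credible_interval(draws)
        assert (eff.lower, eff.upper) == (pytest.approx(lo), pytest.approx(hi))

    def test_zero_coefficient_gives_zero_effect(self):
        post, d = self._beta_posterior()
        post.beta[:, :, 1] = 0.0
        eff = average_marginal_effect(post, d, "x")
        assert eff.mean == 0.0 and (eff.lower, eff.upper) == (0.0, 0.0)
        assert not eff.significant

    def test_matches_finite_difference_oracle(self):
        post, d = self._beta_posterior()
        eff = average_marginal_effect(post, d, "x")
        # oracle: central finite difference of the posterior-mean response
        h = 1e-5
        j = d.coef_names.index("x")
        beta_flat = post.beta.reshape(-1, post.beta.shape[-1])
        u_flat = post.u.reshape(-1, len(d.species))
        ames = []
        for sgn in (+1, -1):
            Xp = d.X.copy()
            Xp[:, j] += sgn * h
            mu = 1 / (1 + np.exp(-(beta_flat @ Xp.T + u_flat)))
            ames.append(mu.mean(axis=1))
        fd = (ames[0] - ames[1]) / (2 * h)
        assert eff.mean == pytest.approx(fd.mean(), rel=1e-4)

    def test_unknown_predictor_rejected(self):
        post, d = self._beta_posterior()
        with pytest.raises(KeyError, match="nope"):
            average_marginal_effect(post, d, "nope")


def test_squeeze_only_when_boundaries_present():
    y = np.array([0.2, 0.5, 0.9])
    out, applied = squeeze_proportions(y)
    assert not applied
    np.testing.assert_array_equal(out, y)
    out2, applied2 = squeeze_proportions(np.array([0.0, 0.5, 1.0]))
    assert applied2 and np.all((out2 > 0) & (out2 < 1))
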