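import numpy as np
import pytest

import mgppm as mg
from mgppm.em import EMConfig, fit_em_quadrature
from mgppm.mcmc import (
    MCMCConfig,
    PosteriorSummary,
    lkj_log_norm,
    lkj_logpdf,
    log_posterior,
    run_mcmc,
    split_rhat,
    vine_to_corr,
    _vine_layer_betas,
)

from conftest import make_block


def _tiny_dataset(n=200, seed=5):
    blocks = mg.build_design(n_traits=2, statements_per_trait=6, block_size=3)
    blocks = mg.apply_keyed_directions(blocks, "mixed")
    cond = mg.SimulationCondition("medium", "mixed", "triplet", n, seed=seed)
    rng = np.random.default_rng(seed)
    R = np.array([[1.0, 0.4], [0.4, 1.0]])
    params = mg.draw_item_parameters(blocks, cond, rng, R=R)
    th = mg.draw_thetas(n, R, rng)
    resp = mg.simulate_responses(blocks, params, th, rng)
    return blocks, params, th, resp


class TestLkjPrior:
    def test_identity_matrix_density_is_normalizing_constant(self):
        # at R = I the determinant term vanishes, leaving -log c_D(eta)
        for D in (2, 3, 5):
            assert lkj_logpdf(np.eye(D), 4.0) == pytest.approx(-lkj_log_norm(D, 4.0))

    def test_d2_constant_closed_form(self):
        # c_2(eta) = int_{-1}^{1} (1-r^2)^(eta-1) dr = 2^(2 eta - 1) B(eta, eta)
        from scipy.special import betaln
        eta = 4.0
        assert lkj_log_norm(2, eta) == pytest.approx((2 * eta - 1) * np.log(2)
                                                     + betaln(eta, eta))

    def test_d3_constant_against_monte_carlo(self):
        """Brute-force oracle: integrate det(R)^(eta-1) over the PD cube."""
        rng = np.random.default_rng(0)
        r = rng.uniform(-1, 1, size=(2_000_000, 3))
        det = 1 - (r ** 2).sum(axis=1) + 2 * r.prod(axis=1)
        val = np.where(det > 0, np.maximum(det, 0) ** 3.0, 0.0)  # eta = 4
        log_c_mc = np.log(val.mean() * 8.0)
        assert lkj_log_norm(3, 4.0) == pytest.approx(log_c_mc, abs=0.02)

    def test_vine_parameterization_always_pd(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            y = rng.normal(0, 1.5, size=10)
            R = vine_to_corr(np.tanh(y), 5)
            assert np.linalg.eigvalsh(R).min() > 0
            assert np.allclose(np.diag(R), 1.0)

    def test_vine_betas_reproduce_lkj_moments(self):
        """Sampling partials from the layer Betas must reproduce the LKJ
        distribution; check E[log det] against a weighted-MC oracle."""
        rng = np.random.default_rng(2)
        m = 4000
        betas = _vine_layer_betas(3, 4.0)
        lds = []
        for _ in range(m):
            p = 2 * rng.beta(betas, betas) - 1
            lds.append(np.linalg.slogdet(vine_to_corr(p, 3))[1])
        r = rng.uniform(-1, 1, size=(2_000_000, 3))
        det = 1 - (r ** 2).sum(axis=1) + 2 * r.prod(axis=1)
        w = np.where(det > 0, np.maximum(det, 0) ** 3.0, 0.0)
        ref = float((np.log(np.maximum(det, 1e-300)) * w)[det > 0].sum() / w.sum())
        assert np.mean(lds) == pytest.approx(ref, abs=0.03)


class TestLogPosterior:
    def test_prior_only_reduces_to_log_priors(self):
        """With no responses the posterior is the prior; check the slope
        term against the lognormal density."""
        b = make_block([1.5, -0.8], [0.0, 0.3], traits=[0, 1])
        params = mg.ParameterSet([np.array([1.5, -0.8])],
                                 [np.array([0.0, 0.3])], np.eye(2))
        th = np.zeros((1, 2))
        resp = np.zeros((1, 0), dtype=int)
        lp = log_posterior([b], params, th, resp)
        from scipy.stats import lognorm, norm
        expected = (
            lognorm.logpdf(1.5, 2.0).sum() + lognorm.logpdf(0.8, 2.0)
            + norm.logpdf(0.3, scale=3.0)
            + lkj_logpdf(np.eye(2), 4.0)
            + norm.logpdf(0.0) * 2  # standard MVN at 0 with identity R
        )
        assert lp == pytest.approx(expected)

    def test_sign_violation_rejected(self):
        b = make_block([1.5, -0.8], [0.0, 0.3], traits=[0, 1])
        flipped = mg.ParameterSet([np.array([-1.5, -0.8])],
                                  [np.array([0.0, 0.3])], np.eye(2))
        lp = log_posterior([b], flipped, np.zeros((1, 2)),
                           np.zeros((1, 0), dtype=int))
        assert lp == -np.inf

    def test_theta_difference_is_likelihood_plus_prior_difference(self):
        blocks, params, th, resp = _tiny_dataset(n=5)
        from mgppm.em import _person_loglik, make_engines, mvn_logpdf
        engines = make_engines(blocks)
        th1 = np.zeros((5, 2))
        th2 = np.full((5, 2), 0.6)
        d_post = (log_posterior(blocks, params, th2, resp)
                  - log_posterior(blocks, params, th1, resp))
        codes0 = resp - 1
        d_direct = (np.sum(_person_loglik(blocks, engines, params, th2, codes0))
                    + np.sum(mvn_logpdf(th2, params.R))
                    - np.sum(_person_loglik(blocks, engines, params, th1, codes0))
                    - np.sum(mvn_logpdf(th1, params.R)))
        assert d_post == pytest.approx(d_direct)


class TestSampler:
    def test_prior_predictive_recovers_prior_moments(self):
        """With zero observations the sampler reproduces the priors:
        log slope magnitudes Normal(0, 2), intercepts Normal(0, 3), and a
        D=2 correlation with SD 1/sqrt(2 eta + 1) under LKJ(eta)."""
        b = make_block([1.0, 1.0], [0.0, 0.0], traits=[0, 1])
        resp = np.zeros((0, 1), dtype=int)
        cfg = MCMCConfig(chains=2, iterations=9000, burnin=1000, seed=3)
        post = run_mcmc(resp, [b], cfg)
        pooled = post.draws.reshape(-1, post.draws.shape[-1])
        log_mag = np.log(np.abs(pooled[:, :2]))
        assert np.abs(log_mag.mean()) < 0.3
        assert log_mag.std() == pytest.approx(2.0, rel=0.15)
        assert np.abs(pooled[:, 2].mean()) < 0.4
        assert pooled[:, 2].std() == pytest.approx(3.0, rel=0.15)
        r12 = pooled[:, 3]
        assert np.abs(r12.mean()) < 0.05
        assert r12.std() == pytest.approx(1.0 / 3.0, rel=0.15)

    def test_posterior_means_match_em_within_three_sds(self):
        blocks, params, th, resp = _tiny_dataset(n=200)
        em = fit_em_quadrature(resp, blocks, EMConfig(max_cycles=300))
        cfg = MCMCConfig(chains=2, iterations=2500, burnin=1200, seed=11)
        post = run_mcmc(resp, blocks, cfg)
        ev = em.params.item_vector(blocks)
        mv = post.params.item_vector(blocks)
        p = len(ev)
        assert np.all(np.abs(mv - ev) <= 3.0 * np.maximum(post.sd[:p], 0.05))
        assert abs(post.params.R[0, 1] - em.params.R[0, 1]) <= \
            3.0 * max(post.sd[p], 0.05)

    def test_pooled_estimate_invariant_to_chain_order(self):
        blocks, params, th, resp = _tiny_dataset(n=60)
        cfg = MCMCConfig(chains=2, iterations=600, burnin=300, seed=4)
        post = run_mcmc(resp, blocks, cfg)
        flipped = post.draws[::-1]
        assert np.allclose(flipped.reshape(-1, flipped.shape[-1]).mean(axis=0),
                           post.mean)

    def test_rhat_near_one_on_well_identified_problem(self):
        """Two chains from different starting seeds agree on a small,
        strongly informative problem."""
        blocks, params, th, resp = _tiny_dataset(n=400, seed=9)
        cfg = MCMCConfig(chains=2, iterations=3000, burnin=1500, seed=21)
        post = run_mcmc(resp, blocks, cfg)
        assert np.max(post.rhat) < 1.2
        assert isinstance(post, PosteriorSummary)


class TestSplitRhat:
    def test_identical_chains_give_unit_rhat(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(1, 1000, 3))
        draws = np.concatenate([x, x], axis=0)
        r = split_rhat(draws)
        assert np.all(r < 1.01)

    def test_disjoint_chains_flagged(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0, 1, size=(1, 500, 1))
        b = rng.normal(8, 1, size=(1, 500, 1))
        r = split_rhat(np.concatenate([a, b], axis=0))
        assert r[0] > 1.5
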