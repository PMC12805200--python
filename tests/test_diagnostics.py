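import numpy as np
import pytest

import mgppm as mg
from mgppm.blocks import InvalidBlockError, enumerate_patterns
from mgppm.diagnostics import (
    expected_item_trait_score,
    item_fit_z,
    ld_cramers_v,
    model_implied_tables,
    srmsr,
)
from mgppm.model import pattern_probabilities
from mgppm.rank2plm import SequentialEngine, triplet2plm_probabilities
from mgppm.scoring import map_score

from conftest import make_block


class TestSequentialModel:
    def test_uniform_under_null_parameters(self):
        b = make_block([0.0] * 3, [0.0] * 3)
        P = triplet2plm_probabilities(b, np.zeros(3))
        assert np.allclose(P, 1 / 6)

    def test_probabilities_sum_to_one(self, rng):
        b = make_block(rng.normal(0, 1.3, 3).tolist(), rng.normal(0, 1, 3).tolist())
        th = rng.normal(0, 1, 3)
        assert triplet2plm_probabilities(b, th).sum() == pytest.approx(1.0)

    def test_two_stage_enumeration_oracle(self, rng):
        """Product of the two normalized selection stages, enumerated by
        hand for every pattern."""
        slopes = rng.normal(0, 1.2, 3)
        intercepts = np.array([0.0, *rng.normal(0, 1, 2)])
        b = make_block(slopes.tolist(), intercepts.tolist())
        th = rng.normal(0, 1, 3)
        u = slopes * th + intercepts
        P = triplet2plm_probabilities(b, th)
        for j, pat in enumerate(enumerate_patterns(3)):
            k1, k2, k3 = (s - 1 for s in pat)
            stage1 = np.exp(u[k1]) / np.exp(u).sum()
            stage2 = np.exp(u[k2]) / (np.exp(u[k2]) + np.exp(u[k3]))
            assert P[j] == pytest.approx(stage1 * stage2)

    def test_pairs_coincide_with_pattern_model(self, rng):
        """For block size 2 the sequential and pattern models are the same
        logistic model in the utility difference."""
        b = make_block(rng.normal(0, 1, 2).tolist(), [0.0, 0.4], traits=[0, 1])
        th = rng.normal(0, 1, 2)
        assert np.allclose(triplet2plm_probabilities(b, th),
                           pattern_probabilities(b, th))

    def test_block_size_above_three_unsupported(self, tetrad):
        with pytest.raises(InvalidBlockError):
            SequentialEngine(tetrad)

    def test_gradients_match_finite_differences(self, rng):
        b = make_block(rng.normal(0, 1, 3).tolist(), rng.normal(0, 1, 3).tolist())
        eng = SequentialEngine(b)
        U = rng.normal(0, 1, (2, 3))
        W = np.abs(rng.normal(0, 1, (2, 6)))
        g, H = eng.weighted_grad_hess(U, W)
        eps = 1e-6
        for k in range(3):
            dU = np.zeros((2, 3))
            dU[:, k] = eps
            fp = np.sum(W * eng.log_response_probs(U + dU), axis=1)
            fm = np.sum(W * eng.log_response_probs(U - dU), axis=1)
            assert np.allclose(g[:, k], (fp - fm) / (2 * eps), atol=1e-6)
            gp, _ = eng.weighted_grad_hess(U + dU, W)
            gm, _ = eng.weighted_grad_hess(U - dU, W)
            assert np.allclose(H[:, :, k], (gp - gm) / (2 * eps), atol=1e-6)


def _fitted_null_study(n=1000, seed=5, n_blocks=4):
    """Simulated responses scored at the generating parameters."""
    blocks = mg.build_design(n_traits=2, statements_per_trait=3 * n_blocks // 2,
                             block_size=3)
    blocks = mg.apply_keyed_directions(blocks, "mixed")
    cond = mg.SimulationCondition("medium", "mixed", "triplet", n, seed=seed)
    rng = np.random.default_rng(seed)
    R = np.array([[1.0, 0.4], [0.4, 1.0]])
    params = mg.draw_item_parameters(blocks, cond, rng, R=R)
    th = mg.draw_thetas(n, R, rng)
    resp = mg.simulate_responses(blocks, params, th, rng)
    return blocks, params, th, resp


class TestLocalDependence:
    def test_null_pairs_have_small_v(self):
        blocks, params, th, resp = _fitted_null_study(n=1000)
        tab = ld_cramers_v(resp, blocks, params, seed=1)
        assert tab["cramers_v"].mean() < 0.1
        assert not tab["flag"].any()

    def test_duplicated_block_gives_v_of_one(self):
        """Copying a block's responses creates perfect dependence."""
        b1 = make_block([0.0] * 3, [0.0] * 3, block_id=1)
        b2 = make_block([0.0] * 3, [0.0] * 3, traits=[0, 1, 2], block_id=2)
        params = mg.ParameterSet([np.zeros(3)] * 2, [np.zeros(3)] * 2, np.eye(3))
        col = np.repeat(np.arange(1, 7), 300)       # exactly uniform margins
        resp = np.column_stack([col, col])
        tab = ld_cramers_v(resp, [b1, b2], params, seed=0)
        assert tab["cramers_v"].iloc[0] == pytest.approx(1.0, abs=0.02)
        assert bool(tab["flag"].iloc[0])

    def test_v_within_unit_interval(self):
        blocks, params, th, resp = _fitted_null_study(n=300, seed=8)
        tab = ld_cramers_v(resp, blocks, params, seed=2)
        assert ((tab["cramers_v"] >= 0) & (tab["cramers_v"] <= 1)).all()


class TestItemFit:
    def test_null_flag_rate_at_or_below_nominal(self):
        """Model-consistent data should flag at most ~5% of items."""
        flags = 0
        total = 0
        for seed in (1, 2, 3):
            blocks, params, th, resp = _fitted_null_study(n=800, seed=seed,
                                                          n_blocks=6)
            sc = map_score(resp, blocks, params)
            z = item_fit_z(resp, blocks, params, sc)
            flags += int(z["flag"].sum())
            total += len(z)
        assert flags / total <= 0.12

    def test_constructed_misfit_strongly_negative(self):
        blocks, params, th, resp = _fitted_null_study(n=600)
        sc = map_score(resp, blocks, params)
        bad = resp.copy()
        from mgppm.model import response_log_probabilities
        # replace one item's responses by each person's least likely pattern
        L = response_log_probabilities(blocks[0], sc.theta,
                                       params.slopes[0], params.intercepts[0])
        bad[:, 0] = np.argmin(L, axis=1) + 1
        z = item_fit_z(bad, blocks, params, sc)
        assert z["z"].iloc[0] < -10
        assert bool(z["flag"].iloc[0])
        assert not z["flag"].iloc[1:].any()


class TestSrmsr:
    def test_zero_when_observed_equals_expected(self):
        """A synthetic dataset whose empirical tables equal the uniform
        model-implied tables exactly."""
        b1 = make_block([0.0] * 2, [0.0] * 2, block_id=1)
        b2 = make_block([0.0] * 2, [0.0] * 2, traits=[0, 1], block_id=2)
        params = mg.ParameterSet([np.zeros(2)] * 2, [np.zeros(2)] * 2, np.eye(2))
        # all four joint outcomes equally often -> matches independence
        resp = np.array([[1, 1], [1, 2], [2, 1], [2, 2]] * 50)
        assert srmsr(resp, [b1, b2], params, seed=0) == pytest.approx(0.0, abs=1e-6)

    def test_null_fit_below_close_fit_threshold(self):
        blocks, params, th, resp = _fitted_null_study(n=5000, seed=3)
        val = srmsr(resp, blocks, params, seed=1)
        assert 0.0 <= val < 0.027

    def test_nonnegative(self):
        blocks, params, th, resp = _fitted_null_study(n=200, seed=9)
        assert srmsr(resp, blocks, params, seed=1) >= 0.0


class TestItemTraitCurves:
    def test_symmetric_triplet_centre_score(self):
        """Three exchangeable statements: expected score 1.0 at the centre
        (scores 2/1/0 are symmetric)."""
        b = make_block([1.1, 1.1, 1.1], [0.0, 0.0, 0.0])
        R = np.full((3, 3), 0.3)
        np.fill_diagonal(R, 1.0)
        params = mg.ParameterSet([b.slopes], [b.intercepts], R)
        grid, curve = expected_item_trait_score(b, params, focal_statement=1)
        assert len(grid) == 31 and grid[0] == -3.0 and grid[-1] == 3.0
        centre = np.where(grid == 0.0)[0][0]
        assert curve[centre] == pytest.approx(1.0, abs=1e-8)

    def test_positive_slopes_give_nondecreasing_curve(self):
        # with independent traits the competing statements' conditional
        # distribution is flat in the focal trait, so the curve must rise;
        # under strong intertrait correlation monotonicity can genuinely
        # fail for a weak focal slope facing stronger competitors
        b = make_block([0.64, 1.28, 2.0], [0.0, 0.4, -0.3])
        params = mg.ParameterSet([b.slopes], [b.intercepts], np.eye(3))
        for focal in (1, 2, 3):
            _, curve = expected_item_trait_score(b, params, focal_statement=focal)
            assert np.all(np.diff(curve) > -1e-10)

    def test_refined_grid_agreement(self):
        """31-point averaging grid against a 101-point recomputation."""
        b = make_block([0.9, 1.3, 0.7], [0.0, 0.2, -0.4])
        params = mg.ParameterSet([b.slopes], [b.intercepts],
                                 mg.default_correlations(3))
        g31, c31 = expected_item_trait_score(b, params, 2, n_points=31)
        g101, c101 = expected_item_trait_score(b, params, 2, n_points=101)
        assert np.max(np.abs(np.interp(g31, g101, c101) - c31)) < 0.01


class TestCompareModels:
    def test_report_structure_and_equal_parameter_counts(self):
        """Both models fitted on identical codings: AIC and BIC differences
        coincide, and trait scores agree closely on pattern-model data."""
        from mgppm.diagnostics import compare_models
        from mgppm.em import EMConfig
        blocks, params, th, resp = _fitted_null_study(n=500, seed=17, n_blocks=6)
        rep = compare_models(resp, blocks, EMConfig(seed=3, max_cycles=300))
        assert rep.fit_mgppm.n_free == rep.fit_sequential.n_free
        assert rep.aic_difference == pytest.approx(rep.bic_difference, abs=1e-9)
        assert np.all(rep.score_correlations > 0.95)
        assert rep.reliability_mgppm.shape == (2,)
        assert np.all((rep.reliability_mgppm >= 0) & (rep.reliability_mgppm <= 1))


class TestImpliedTables:
    def test_margins_match_direct_integration(self):
        blocks, params, th, resp = _fitted_null_study(n=10, seed=2)
        margins, joints = model_implied_tables(blocks, params, n_draws=40000, seed=3)
        for m in margins:
            assert m.sum() == pytest.approx(1.0)
        for tab in joints.values():
            assert tab.sum() == pytest.approx(1.0)
        # empirical frequencies at large n approximate the implied margins
        blocks2, params2, th2, resp2 = _fitted_null_study(n=20000, seed=2)
        obs = np.bincount(resp2[:, 0] - 1, minlength=6) / 20000
        assert np.abs(obs - margins[0]).max() < 0.015
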