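import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mgppm.blocks import InvalidResponseError, enumerate_patterns
from mgppm.model import (
    PatternEngine,
    conditional_logit,
    log_density_gradients,
    marginal_response_probability,
    pattern_log_probabilities,
    pattern_mean_utility,
    pattern_probabilities,
    response_log_probabilities,
    utilities,
)

from conftest import make_block


def brute_force_probs(slopes, intercepts, traits, theta):
    """Independent softmax oracle: enumerate utilities by direct arithmetic."""
    B = len(slopes)
    V = []
    for pat in itertools.permutations(range(1, B + 1)):
        v = 0.0
        for rank, sid in enumerate(pat, start=1):
            s = B - rank
            k = sid - 1
            v += s * (slopes[k] * theta[traits[k]] + intercepts[k])
        V.append(v)
    V = np.array(V)
    e = np.exp(V - V.max())
    return e / e.sum(), V


class TestMeanUtility:
    def test_triplet_identity_pattern(self):
        # pattern (1,2,3): 2*(a1 th1 + c1) + 1*(a2 th2 + c2) + 0
        b = make_block([0.64, 1.28, 2.0], [0.0, 0.3, -0.2])
        th = np.array([1.0, -0.5, 0.7])
        expected = 2 * (0.64 * 1.0 + 0.0) + 1 * (1.28 * -0.5 + 0.3)
        assert pattern_mean_utility(b, (1, 2, 3), th) == pytest.approx(expected)

    def test_null_parameters_give_zero(self):
        b = make_block([0.0, 0.0, 0.0], [0.0, 0.0, 0.0])
        th = np.array([0.3, -1.2, 0.5])
        for code in range(1, 7):
            assert pattern_mean_utility(b, code, th) == pytest.approx(0.0)

    def test_hand_computed_example(self):
        # a=(0.64,1.28,2.0), c=0, theta=(1,0,-1), pattern (1,2,3):
        # 2*0.64*1 + 1*1.28*0 + 0*2.0*(-1) = 1.28
        b = make_block([0.64, 1.28, 2.0], [0.0, 0.0, 0.0])
        th = np.array([1.0, 0.0, -1.0])
        assert pattern_mean_utility(b, (1, 2, 3), th) == pytest.approx(1.28)

    def test_dimension_mismatch_raises(self):
        b = make_block([1.0, 1.0, 1.0], [0.0, 0.0, 0.0])
        with pytest.raises(ValueError):
            utilities(b, np.array([0.1, 0.2]))


class TestPatternProbabilities:
    def test_uniform_under_null_parameters(self):
        b = make_block([0.0] * 3, [0.0] * 3)
        P = pattern_probabilities(b, np.zeros(3))
        assert np.allclose(P, 1.0 / 6.0)

    def test_pair_reduces_to_logistic(self, pair):
        th = np.array([0.8, -0.4])
        P = pattern_probabilities(pair, th)
        diff = (1.0 * 0.8 + 0.0) - (1.3 * -0.4 - 0.25)
        assert P[0] == pytest.approx(1.0 / (1.0 + np.exp(-diff)))

    @pytest.mark.parametrize("B", [2, 3, 4])
    def test_matches_brute_force_softmax(self, B, rng):
        slopes = rng.normal(0, 1.2, B)
        intercepts = rng.normal(0, 0.6, B)
        intercepts[0] = 0.0
        traits = list(range(B))
        b = make_block(slopes.tolist(), intercepts.tolist())
        th = rng.normal(0, 1, B)
        expected, _ = brute_force_probs(slopes, intercepts, traits, th)
        assert np.allclose(pattern_probabilities(b, th), expected, atol=1e-12)

    @pytest.mark.parametrize("B", [2, 3, 4, 5])
    def test_normalization_random_parameters(self, B, rng):
        for _ in range(5):
            slopes = rng.normal(0, 1.5, B)
            b = make_block(slopes.tolist(), rng.normal(0, 1, B).tolist())
            th = rng.normal(0, 1, B)
            P = pattern_probabilities(b, th)
            assert abs(P.sum() - 1.0) < 1e-12
            assert (P > 0).all() and (P < 1).all()

    def test_translation_invariance(self, rng):
        # adding a constant to every intercept adds the same constant
        # (times the fixed score total) to every pattern utility, so
        # probabilities are unchanged
        intercepts = np.array([0.0, 0.4, -0.2])
        b = make_block([1.0, -0.7, 1.3], intercepts.tolist())
        th = rng.normal(0, 1, 3)
        for shift in (3.7, 250.0):
            b2 = make_block([1.0, -0.7, 1.3], (intercepts + shift).tolist())
            assert np.allclose(pattern_probabilities(b, th),
                               pattern_probabilities(b2, th), atol=1e-10)

    def test_extreme_utilities_stable(self):
        b = make_block([50.0, 50.0, 50.0], [0.0, 0.0, 0.0])
        P = pattern_probabilities(b, np.array([8.0, -8.0, 0.0]))
        assert np.isfinite(P).all() and abs(P.sum() - 1.0) < 1e-12

    def test_relabeling_equivariance(self, rng):
        """Permuting statement labels permutes pattern probabilities."""
        slopes = [0.9, -1.4, 1.1]
        intercepts = [0.2, -0.3, 0.5]
        th = rng.normal(0, 1, 3)
        b = make_block(slopes, intercepts)
        P = pattern_probabilities(b, th)
        perm = (2, 0, 1)    # statement k of the new block is old statement perm[k]
        b2 = make_block([slopes[p] for p in perm], [intercepts[p] for p in perm],
                        traits=[perm[k] for k in range(3)])
        P2 = pattern_probabilities(b2, th)
        pats = enumerate_patterns(3)
        inv = {old: new for new, old in enumerate(perm)}
        for j, pat in enumerate(pats):
            relabeled = tuple(inv[sid - 1] + 1 for sid in pat)
            assert P2[pats.index(relabeled)] == pytest.approx(P[j])


class TestConditionalLogit:
    def test_one_rank_swap(self):
        b = make_block([0.64, 1.28, 2.0], [0.0, 0.3, -0.2])
        th = np.array([1.0, -0.5, 0.7])
        # (1,2,3) vs (2,1,3): swap of ranks 1 and 2
        expected = (0.64 * 1.0 + 0.0) - (1.28 * -0.5 + 0.3)
        got = conditional_logit(b, th, 1, 3)
        assert got == pytest.approx(expected)

    def test_two_rank_swap(self):
        b = make_block([0.64, 1.28, 2.0], [0.0, 0.3, -0.2])
        th = np.array([1.0, -0.5, 0.7])
        # (1,2,3) vs (3,2,1): statements 1 and 3 move two rank levels
        expected = 2 * (0.64 * 1.0 + 0.0) - 2 * (2.0 * 0.7 - 0.2)
        pats = enumerate_patterns(3)
        code_321 = pats.index((3, 2, 1)) + 1
        assert conditional_logit(b, th, 1, code_321) == pytest.approx(expected)

    def test_identical_codes_zero(self, triplet):
        assert conditional_logit(triplet, np.zeros(3), 4, 4) == 0.0

    def test_equals_log_probability_ratio(self, rng):
        b = make_block(rng.normal(0, 1, 4).tolist(), rng.normal(0, 1, 4).tolist())
        th = rng.normal(0, 1, 4)
        L = pattern_log_probabilities(b, th)
        assert conditional_logit(b, th, 5, 17) == pytest.approx(L[4] - L[16])


class TestMarginalization:
    def test_tetrad_pick_sums_six_patterns(self, tetrad, rng):
        th = rng.normal(0, 1, 4)
        P = pattern_probabilities(tetrad, th)
        pats = enumerate_patterns(4)
        manual = sum(P[j] for j, p in enumerate(pats) if p[0] == 1)
        got = marginal_response_probability(tetrad, ("pick", 1), th)
        assert sum(1 for p in pats if p[0] == 1) == 6
        assert got == pytest.approx(manual)

    def test_tetrad_mole_compatible_set(self, tetrad, rng):
        th = rng.normal(0, 1, 4)
        P = pattern_probabilities(tetrad, th)
        pats = enumerate_patterns(4)
        compat = [j for j, p in enumerate(pats) if p[0] == 1 and p[-1] == 2]
        assert len(compat) == math.factorial(4 - 2)
        got = marginal_response_probability(tetrad, ("mole", 1, 2), th)
        assert got == pytest.approx(sum(P[j] for j in compat))

    def test_pair_pick_equals_rank(self, pair, rng):
        th = rng.normal(0, 1, 2)
        assert marginal_response_probability(pair, ("pick", 1), th) == \
            pytest.approx(marginal_response_probability(pair, ("rank", 1), th))

    def test_pick_probabilities_sum_to_one(self, tetrad, rng):
        th = rng.normal(0, 1, 4)
        total = sum(marginal_response_probability(tetrad, ("pick", s), th)
                    for s in range(1, 5))
        assert total == pytest.approx(1.0)

    def test_mole_probabilities_sum_to_one(self, tetrad, rng):
        th = rng.normal(0, 1, 4)
        total = sum(
            marginal_response_probability(tetrad, ("mole", m, l), th)
            for m in range(1, 5) for l in range(1, 5) if m != l
        )
        assert total == pytest.approx(1.0)

    def test_contradictory_mole_rejected(self, tetrad):
        with pytest.raises(InvalidResponseError):
            marginal_response_probability(tetrad, ("mole", 2, 2), np.zeros(4))

    def test_full_rank_returns_single_pattern(self, triplet, rng):
        th = rng.normal(0, 1, 3)
        P = pattern_probabilities(triplet, th)
        assert marginal_response_probability(triplet, ("rank", 4), th) == \
            pytest.approx(P[3])


class TestGradients:
    def test_null_parameters_intercept_gradient(self):
        # at a=c=0: d logP / d c_k = s(rank_k) - mean over patterns of s(rank of k)
        b = make_block([0.0] * 3, [0.0] * 3)
        th = np.zeros(3)
        S = b.score_matrix
        for code in range(1, 7):
            g = log_density_gradients(b, th, code)
            expected = S[code - 1] - S.mean(axis=0)
            assert np.allclose(g["intercept"], expected)

    @pytest.mark.parametrize("fmt,B", [("RANK", 3), ("RANK", 4), ("PICK", 4),
                                       ("MOLE", 4)])
    def test_gradients_match_finite_differences(self, fmt, B, rng):
        slopes = rng.normal(0, 1.2, B)
        intercepts = rng.normal(0, 0.6, B)
        intercepts[0] = 0.0
        b = make_block(slopes.tolist(), intercepts.tolist(), fmt=fmt)
        th = rng.normal(0, 1, B)
        code = int(rng.integers(1, b.n_responses + 1))
        g = log_density_gradients(b, th, code)

        def logp(sl, ic, t):
            bb = make_block(sl.tolist(), ic.tolist(), fmt=fmt)
            return response_log_probabilities(bb, t)[code - 1]

        eps = 1e-6
        for k in range(B):
            for which, vec in (("slope", slopes), ("intercept", intercepts)):
                dv = np.zeros(B)
                dv[k] = eps
                if which == "slope":
                    fd = (logp(slopes + dv, intercepts, th)
                          - logp(slopes - dv, intercepts, th)) / (2 * eps)
                else:
                    fd = (logp(slopes, intercepts + dv, th)
                          - logp(slopes, intercepts - dv, th)) / (2 * eps)
                assert g[which][k] == pytest.approx(fd, rel=1e-5, abs=1e-8)
            dt = np.zeros(B)
            dt[k] = eps
            fd = (logp(slopes, intercepts, th + dt)
                  - logp(slopes, intercepts, th - dt)) / (2 * eps)
            assert g["theta"][k] == pytest.approx(fd, rel=1e-5, abs=1e-8)

    def test_engine_hessian_matches_finite_difference_of_gradient(self, rng):
        b = make_block(rng.normal(0, 1, 3).tolist(), rng.normal(0, 1, 3).tolist())
        eng = PatternEngine(b)
        U = rng.normal(0, 1, (1, 3))
        W = np.abs(rng.normal(0, 1, (1, 6)))
        _, H = eng.weighted_grad_hess(U, W)
        eps = 1e-6
        for k in range(3):
            dU = np.zeros((1, 3))
            dU[0, k] = eps
            gp, _ = eng.weighted_grad_hess(U + dU, W)
            gm, _ = eng.weighted_grad_hess(U - dU, W)
            assert np.allclose(H[0, :, k], (gp - gm)[0] / (2 * eps), atol=1e-6)


class TestMonotonicity:
    def test_expected_rank_score_nondecreasing_in_own_trait(self):
        """Dominance: a positively keyed statement's expected score rises
        with its trait, other traits fixed."""
        b = make_block([1.2, 0.9, 1.5], [0.0, 0.2, -0.1])
        S = b.score_matrix
        grid = np.linspace(-3, 3, 25)
        prev = -np.inf
        for t in grid:
            th = np.array([t, 0.3, -0.4])
            es = float(pattern_probabilities(b, th) @ S[:, 0])
            assert es >= prev - 1e-12
            prev = es


class TestAlternativeVariant:
    def test_rank_specific_intercepts_enter_utility(self):
        import numpy as np
        from mgppm.blocks import Block, Statement
        stmts = [Statement(k + 1, k, slope=1.0) for k in range(3)]
        C = np.zeros((3, 2))
        C[1, 0] = 0.7      # statement 2 at rank 1
        C[2, 1] = -0.4     # statement 3 at rank 2
        b = Block(1, stmts, variant="alternative", rank_intercepts=C)
        th = np.array([0.5, -0.2, 0.1])
        # pattern (2,3,1): stmt2 rank1 (score 2), stmt3 rank2 (score 1), stmt1 rank3
        v = pattern_mean_utility(b, (2, 3, 1), th)
        expected = 2 * 1.0 * th[1] + C[1, 0] + 1 * 1.0 * th[2] + C[2, 1]
        assert v == pytest.approx(expected)

    def test_statement_one_rank_intercepts_fixed_zero_by_default(self):
        from mgppm.blocks import Block, Statement
        stmts = [Statement(k + 1, k, slope=1.0) for k in range(3)]
        b = Block(1, stmts, variant="alternative")
        assert b.rank_intercepts.shape == (3, 2)
        assert np.all(b.rank_intercepts[0] == 0.0)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(
    B=st.integers(min_value=2, max_value=4),
    seed=st.integers(min_value=0, max_value=10_000),
)
def test_probability_normalization_property(B, seed):
    rng = np.random.default_rng(seed)
    b = make_block(rng.normal(0, 2, B).tolist(), rng.normal(0, 1, B).tolist())
    th = rng.normal(0, 2, B)
    P = pattern_probabilities(b, th)
    assert abs(P.sum() - 1.0) < 1e-12
    assert (P > 0).all()
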