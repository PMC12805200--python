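"""Ranking-pattern probabilities, conditional logits, and gradients.

The model assigns each ranking pattern ``j`` of a block the mean utility

    V_j(theta) = sum_k s(rank_jk) * (a_k * theta_{trait(k)} + c_k)

where ``s(r) = B - r`` is the rank score (primary scheme).  Pattern
probabilities are the softmax of the mean utilities,

    P_j(theta) = exp(V_j) / sum_j' exp(V_j'),

which follows from assuming extreme-value (Gumbel) pattern errors.  The log
ratio of two pattern probabilities is the difference of their mean
utilities, an adjacent-category (partial-credit) logit: each one-rank
advancement of a statement contributes one increment of ``a_k theta + c_k``.

The ``alternative`` scheme variant replaces the constant per-rank increment
with rank-specific intercepts ``c_{k,r}`` (slope part unchanged).

Reduced formats (PICK, MOLE) observe a coarsening of the pattern space:
their response probabilities are sums of pattern probabilities over the
compatible set, exactly as full rankings with planned missing data.
"""

from __future__ import annotations

import numpy as np
from scipy.special import logsumexp

from .blocks import Block, InvalidResponseError, pattern_code

__all__ = [
    "utilities",
    "pattern_mean_utility",
    "pattern_log_probabilities",
    "pattern_probabilities",
    "conditional_logit",
    "marginal_response_probability",
    "response_log_probabilities",
    "log_density_gradients",
    "PatternEngine",
]


def _as_2d(theta: np.ndarray) -> tuple[np.ndarray, bool]:
    theta = np.asarray(theta, dtype=float)
    if theta.ndim == 1:
        return theta[None, :], True
    return theta, False


def utilities(block: Block, theta: np.ndarray,
              slopes: np.ndarray | None = None,
              intercepts: np.ndarray | None = None) -> np.ndarray:
    """Per-statement utilities ``a_k theta_{trait(k)} + c_k``, shape (n, B)."""
    theta2, _ = _as_2d(theta)
    a = block.slopes if slopes is None else np.asarray(slopes, dtype=float)
    c = block.intercepts if intercepts is None else np.asarray(intercepts, dtype=float)
    if theta2.shape[1] <= block.traits.max():
        raise ValueError(
            f"theta has {theta2.shape[1]} traits but block {block.block_id} "
            f"references trait index {block.traits.max()}"
        )
    return theta2[:, block.traits] * a + c


def _alternative_offsets(block: Block) -> np.ndarray:
    """Pattern offsets ``sum_k c_{k, rank_jk}`` of the alternative variant."""
    C = np.asarray(block.rank_intercepts, dtype=float)
    B = block.size
    offs = np.zeros(block.n_patterns)
    for j, pat in enumerate(block.patterns):
        for rank, sid in enumerate(pat, start=1):
            if rank < B:
                offs[j] += C[sid - 1, rank - 1]
    return offs


def pattern_mean_utility(block: Block, pattern, theta: np.ndarray,
                         slopes: np.ndarray | None = None,
                         intercepts: np.ndarray | None = None) -> float:
    """Mean utility ``V_j`` of one ranking pattern at one theta vector.

    ``pattern`` is either a 1-based code or an explicit statement ordering.
    """
    if isinstance(pattern, (int, np.integer)):
        code = int(pattern)
    else:
        code = pattern_code(tuple(pattern))
    V = pattern_log_utilities(block, theta, slopes, intercepts)
    return float(V[0, code - 1])


def pattern_log_utilities(block: Block, theta: np.ndarray,
                          slopes: np.ndarray | None = None,
                          intercepts: np.ndarray | None = None) -> np.ndarray:
    """Mean utilities of all patterns, shape (n, n_patterns)."""
    theta2, _ = _as_2d(theta)
    S = block.score_matrix
    if block.variant == "alternative":
        a = block.slopes if slopes is None else np.asarray(slopes, dtype=float)
        U = theta2[:, block.traits] * a
        return U @ S.T + _alternative_offsets(block)[None, :]
    U = utilities(block, theta2, slopes, intercepts)
    return U @ S.T


def pattern_log_probabilities(block: Block, theta: np.ndarray,
                              slopes: np.ndarray | None = None,
                              intercepts: np.ndarray | None = None) -> np.ndarray:
    """Log probabilities of all patterns, shape (n, n_patterns) or (n_patterns,)."""
    theta2, squeeze = _as_2d(theta)
    V = pattern_log_utilities(block, theta2, slopes, intercepts)
    if not np.all(np.isfinite(V)):
        raise FloatingPointError("non-finite pattern utilities")
    L = V - logsumexp(V, axis=1, keepdims=True)
    return L[0] if squeeze else L


def pattern_probabilities(block: Block, theta: np.ndarray,
                          slopes: np.ndarray | None = None,
                          intercepts: np.ndarray | None = None) -> np.ndarray:
    """Softmax pattern probabilities; rows sum to 1."""
    return np.exp(pattern_log_probabilities(block, theta, slopes, intercepts))


def conditional_logit(block: Block, theta: np.ndarray, code_j: int, code_jp: int) -> float:
    """Log odds ``log(P_j / P_j') = V_j - V_j'`` of two ranking patterns."""
    for c in (code_j, code_jp):
        if not (1 <= int(c) <= block.n_patterns):
            raise InvalidResponseError(f"pattern code {c} outside 1..{block.n_patterns}")
    V = pattern_log_utilities(block, theta)
    return float(V[0, code_j - 1] - V[0, code_jp - 1])


def _compatible_indices(block: Block, response) -> np.ndarray:
    """Indices of patterns compatible with a (possibly partial) response."""
    pats = block.patterns
    if isinstance(response, (int, np.integer)):
        groups = block.response_groups
        block.validate_code(int(response))
        return groups[int(response) - 1]
    kind = str(response[0]).lower()
    if block.fmt not in ("RANK", "PICK", "MOLE"):
        raise InvalidResponseError(f"partial responses undefined for format {block.fmt}")
    if kind == "rank":
        code = int(response[1]) if isinstance(response[1], (int, np.integer)) \
            else pattern_code(tuple(response[1]))
        if not (1 <= code <= block.n_patterns):
            raise InvalidResponseError(f"pattern code {code} outside 1..{block.n_patterns}")
        return np.array([code - 1])
    if kind == "pick":
        sid = int(response[1])
        if not (1 <= sid <= block.size):
            raise InvalidResponseError(f"PICK statement {sid} outside 1..{block.size}")
        return np.array([j for j, p in enumerate(pats) if p[0] == sid])
    if kind == "mole":
        most, least = (int(response[1]), int(response[2])) if len(response) == 3 \
            else (int(response[1][0]), int(response[1][1]))
        if most == least:
            raise InvalidResponseError("MOLE most and least statements must differ")
        for sid in (most, least):
            if not (1 <= sid <= block.size):
                raise InvalidResponseError(f"MOLE statement {sid} outside 1..{block.size}")
        return np.array([j for j, p in enumerate(pats) if p[0] == most and p[-1] == least])
    raise InvalidResponseError(f"unknown response kind {response!r}")


def marginal_response_probability(block: Block, response, theta: np.ndarray) -> float:
    """Probability of a full or partial response at one theta vector.

    PICK and MOLE probabilities are sums of pattern probabilities over the
    compatible-pattern set; a full RANK response returns the single pattern
    probability.
    """
    idx = _compatible_indices(block, response)
    L = pattern_log_probabilities(block, np.atleast_2d(theta))
    return float(np.exp(logsumexp(L[0, idx])))


def response_log_probabilities(block: Block, theta: np.ndarray,
                               slopes: np.ndarray | None = None,
                               intercepts: np.ndarray | None = None) -> np.ndarray:
    """Log probabilities over the block's observable response space."""
    theta2, squeeze = _as_2d(theta)
    L = pattern_log_probabilities(block, theta2, slopes, intercepts)
    groups = block.response_groups
    if all(len(g) == 1 for g in groups):
        out = L[:, [g[0] for g in groups]]
    else:
        out = np.column_stack([logsumexp(L[:, g], axis=1) for g in groups])
    return out[0] if squeeze else out


def log_density_gradients(block: Block, theta: np.ndarray, code: int,
                          n_traits: int | None = None) -> dict[str, np.ndarray]:
    """Analytic gradients of ``log P(code)`` at one theta vector.

    Returns partials with respect to every slope, every intercept (including
    the conventionally fixed first one), and every component of theta.  For
    the observed response the slope/intercept gradients follow from the
    score-residual form ``E[s_k | response] - E[s_k]``.
    """
    theta1 = np.asarray(theta, dtype=float)
    if n_traits is None:
        n_traits = theta1.shape[-1]
    eng = PatternEngine(block)
    U = utilities(block, theta1[None, :])
    resid = eng.score_residuals(U, np.array([int(code) - 1]))[0]  # (B,)
    a = block.slopes
    d_slope = resid * theta1[block.traits]
    d_intercept = resid.copy()
    d_theta = np.zeros(n_traits)
    np.add.at(d_theta, block.traits, resid * a)
    return {"slope": d_slope, "intercept": d_intercept, "theta": d_theta}


class PatternEngine:
    """Vectorized likelihood engine for one block under the pattern model.

    Works on utility matrices ``U`` of shape (n, B) and response codes
    (0-based indices into the block's response space), providing the
    log-likelihood terms and their derivatives with respect to ``U`` that
    the estimation routines need.  Reduced formats are handled through the
    compatible-pattern groups.
    """

    def __init__(self, block: Block):
        if block.variant != "primary":
            raise NotImplementedError("estimation engine supports the primary scheme variant")
        self.block = block
        self.S = block.score_matrix                      # (M, B)
        groups = block.response_groups
        self.singleton = all(len(g) == 1 for g in groups)
        self.group_idx = [np.asarray(g) for g in groups]
        M = block.n_patterns
        G = np.zeros((len(groups), M))
        for m, g in enumerate(groups):
            G[m, g] = 1.0
        self.G = G                                        # (n_resp, M)

    @property
    def n_responses(self) -> int:
        return len(self.group_idx)

    # -- probabilities -------------------------------------------------
    def log_pattern_probs(self, U: np.ndarray) -> np.ndarray:
        V = U @ self.S.T
        return V - logsumexp(V, axis=1, keepdims=True)

    def response_probs(self, U: np.ndarray) -> np.ndarray:
        P = np.exp(self.log_pattern_probs(U))
        if self.singleton and self.G.shape[0] == self.G.shape[1]:
            return P
        return P @ self.G.T

    def log_response_probs(self, U: np.ndarray) -> np.ndarray:
        L = self.log_pattern_probs(U)
        if self.singleton and self.G.shape[0] == self.G.shape[1]:
            return L
        return np.column_stack([logsumexp(L[:, g], axis=1) for g in self.group_idx])

    def loglik(self, U: np.ndarray, codes: np.ndarray) -> np.ndarray:
        """Per-row log likelihood of observed response codes (0-based)."""
        return self.log_response_probs(U)[np.arange(U.shape[0]), codes]

    # -- derivatives w.r.t. utilities ---------------------------------
    def score_residuals(self, U: np.ndarray, codes: np.ndarray) -> np.ndarray:
        """``d log P(code) / d u`` per row: ``E[s | response] - E[s]``, (n, B)."""
        P = np.exp(self.log_pattern_probs(U))
        Es = P @ self.S
        if self.singleton:
            obs = np.array([self.group_idx[c][0] for c in codes])
            return self.S[obs] - Es
        out = np.empty_like(Es)
        for i, c in enumerate(codes):
            g = self.group_idx[c]
            w = P[i, g]
            out[i] = (w @ self.S[g]) / w.sum() - Es[i]
        return out

    def weighted_grad_hess(self, U: np.ndarray, W: np.ndarray
                           ) -> tuple[np.ndarray, np.ndarray]:
        """Gradient and Hessian w.r.t. ``U`` of ``sum_m W[:, m] log P_m``.

        ``W`` has shape (n, n_responses) of nonnegative weights (expected
        counts).  Returns gradient (n, B) and Hessian (n, B, B); the Hessian
        of a response's log probability is ``Cov(s | response) - Cov(s)``.
        """
        P = np.exp(self.log_pattern_probs(U))          # (n, M)
        N = W.sum(axis=1)                              # (n,)
        Es = P @ self.S                                # (n, B)
        Ess = np.einsum("nj,ji,jk->nik", P, self.S, self.S)
        cov = Ess - Es[:, :, None] * Es[:, None, :]
        if self.singleton:
            WP = W @ self.G                            # pattern-level weights
            grad = WP @ self.S - N[:, None] * Es
            hess = -N[:, None, None] * cov
            return grad, hess
        denom = P @ self.G.T                           # (n, n_resp)
        denom = np.maximum(denom, 1e-300)
        # pattern-level weights omega_nj = sum_m W_nm G_mj P_nj / denom_nm
        omega = ((W / denom) @ self.G) * P             # (n, M)
        cond_mean = np.einsum("mj,nj,jb->nmb", self.G, P, self.S) / denom[:, :, None]
        grad = omega @ self.S - N[:, None] * Es
        cond_ss = np.einsum("nj,ji,jk->nik", omega, self.S, self.S)
        wm = W[:, :, None, None] * (cond_mean[:, :, :, None] * cond_mean[:, :, None, :])
        hess = cond_ss - wm.sum(axis=1) - N[:, None, None] * cov
        return grad, hess

    # convenience for simulation
    def sample(self, U: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        """Draw one observed response code (0-based) per row of ``U``."""
        Pr = self.response_probs(U)
        cum = np.cumsum(Pr, axis=1)
        r = rng.random(U.shape[0])[:, None]
        return np.minimum((cum < r).sum(axis=1), Pr.shape[1] - 1)
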