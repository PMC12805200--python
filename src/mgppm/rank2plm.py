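"""Sequential-selection baseline for triplets (Triplet-2PLM).

The baseline assumes respondents rank a block by repeated choice: first
pick the most favourable statement from all ``B``, then the next from the
remaining ones.  Each stage is a normalized logistic choice on the
statement utilities ``u_k = a_k theta_{trait(k)} + c_k``, so a triplet
pattern ``(k1, k2, k3)`` has probability

    P = [e^{u_k1} / (e^{u_1}+e^{u_2}+e^{u_3})] * [e^{u_k2} / (e^{u_k2}+e^{u_k3})].

One intercept per block is fixed at 0, leaving the same free-parameter
count as the pattern model, which makes AIC differences equal BIC
differences on common data.  For pairs the single stage coincides exactly
with the pattern model, so only blocks of size 2 and 3 are supported.
"""

from __future__ import annotations

import numpy as np
from scipy.special import logsumexp

from .blocks import Block, InvalidBlockError

__all__ = ["SequentialEngine", "triplet2plm_probabilities"]


class SequentialEngine:
    """Vectorized likelihood engine for the sequential-selection model.

    Same interface as :class:`mgppm.model.PatternEngine`; responses are
    full ranking codes only.
    """

    def __init__(self, block: Block):
        if block.size > 3:
            raise InvalidBlockError("sequential baseline supports block sizes 2 and 3 only")
        if block.fmt != "RANK":
            raise InvalidBlockError("sequential baseline supports the RANK format only")
        self.block = block
        self.patterns = block.patterns
        self.singleton = True
        B = block.size
        # remaining-statement masks per first choice (0-based statement index)
        self.rem_masks = []
        for first in range(B):
            mask = np.ones(B, dtype=bool)
            mask[first] = False
            self.rem_masks.append(mask)

    @property
    def n_responses(self) -> int:
        return len(self.patterns)

    def log_response_probs(self, U: np.ndarray) -> np.ndarray:
        B = self.block.size
        lse_all = logsumexp(U, axis=1)
        out = np.empty((U.shape[0], len(self.patterns)))
        for j, pat in enumerate(self.patterns):
            k1 = pat[0] - 1
            lp = U[:, k1] - lse_all
            if B == 3:
                k2, k3 = pat[1] - 1, pat[2] - 1
                lp = lp + U[:, k2] - np.logaddexp(U[:, k2], U[:, k3])
            out[:, j] = lp
        return out

    log_pattern_probs = log_response_probs

    def response_probs(self, U: np.ndarray) -> np.ndarray:
        return np.exp(self.log_response_probs(U))

    def loglik(self, U: np.ndarray, codes: np.ndarray) -> np.ndarray:
        return self.log_response_probs(U)[np.arange(U.shape[0]), codes]

    # -- derivatives ---------------------------------------------------
    def _stage_probs(self, U: np.ndarray) -> tuple[np.ndarray, list[np.ndarray]]:
        """Stage-1 softmax over all statements and stage-2 softmax per first choice."""
        p_all = np.exp(U - logsumexp(U, axis=1, keepdims=True))
        p_rem = []
        for mask in self.rem_masks:
            sub = U[:, mask]
            psub = np.exp(sub - logsumexp(sub, axis=1, keepdims=True))
            full = np.zeros_like(U)
            full[:, mask] = psub
            p_rem.append(full)
        return p_all, p_rem

    def score_residuals(self, U: np.ndarray, codes: np.ndarray) -> np.ndarray:
        B = self.block.size
        p_all, p_rem = self._stage_probs(U)
        out = -p_all.copy()
        rows = np.arange(U.shape[0])
        for j, pat in enumerate(self.patterns):
            sel = codes == j
            if not np.any(sel):
                continue
            out[sel, pat[0] - 1] += 1.0
            if B == 3:
                out[sel, pat[1] - 1] += 1.0
                out[sel] -= p_rem[pat[0] - 1][sel]
        return out

    def weighted_grad_hess(self, U: np.ndarray, W: np.ndarray
                           ) -> tuple[np.ndarray, np.ndarray]:
        B = self.block.size
        n = U.shape[0]
        N = W.sum(axis=1)
        p_all, p_rem = self._stage_probs(U)
        grad = -N[:, None] * p_all
        cov_all = p_all[:, :, None] * (np.eye(B) - p_all[:, None, :])
        hess = -N[:, None, None] * cov_all
        for j, pat in enumerate(self.patterns):
            w = W[:, j]
            grad[:, pat[0] - 1] += w
            if B == 3:
                grad[:, pat[1] - 1] += w
        if B == 3:
            # stage-2 terms grouped by first choice
            Wf = np.zeros((n, B))
            for j, pat in enumerate(self.patterns):
                Wf[:, pat[0] - 1] += W[:, j]
            for first in range(B):
                pr = p_rem[first]
                grad -= Wf[:, first, None] * pr
                cov_r = pr[:, :, None] * (np.eye(B) - pr[:, None, :])
                # zero rows/cols outside the remaining set are already zero in pr
                cov_r[:, ~self.rem_masks[first], :] = 0.0
                cov_r[:, :, ~self.rem_masks[first]] = 0.0
                hess -= Wf[:, first, None, None] * cov_r
        return grad, hess

    def sample(self, U: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        Pr = self.response_probs(U)
        cum = np.cumsum(Pr, axis=1)
        r = rng.random(U.shape[0])[:, None]
        return np.minimum((cum < r).sum(axis=1), Pr.shape[1] - 1)


def triplet2plm_probabilities(block: Block, theta: np.ndarray,
                              slopes: np.ndarray | None = None,
                              intercepts: np.ndarray | None = None) -> np.ndarray:
    """Sequential-selection probabilities over the block's ranking patterns."""
    from .model import utilities
    theta2 = np.atleast_2d(np.asarray(theta, dtype=float))
    U = utilities(block, theta2, slopes, intercepts)
    out = SequentialEngine(block).response_probs(U)
    return out[0] if np.asarray(theta).ndim == 1 else out
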