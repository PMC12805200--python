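"""Marginal maximum likelihood estimation (Bock-Aitkin EM and MHRM).

Item parameters and the intertrait correlation matrix are estimated by
maximising the marginal likelihood: each person's ranking-pattern
probabilities are integrated over the standard multivariate normal trait
population.  Two integration backends are provided:

* fixed-grid quadrature (equidistant points on [-6, 6] per dimension) for
  up to four traits, driving a classical EM with per-block Newton M-steps;
* a stochastic-approximation scheme in the Metropolis-Hastings
  Robbins-Monro (MHRM) family for any number of traits: each cycle draws
  person traits from their posterior by random-walk Metropolis-Hastings
  and applies a gain-damped Newton update using complete-data gradients.

Both return a :class:`FitResult` with estimates, Fisher-identity standard
errors, the marginal log-likelihood, and AIC/BIC.  The same machinery fits
the pattern model (MGPPM) and the sequential-selection baseline; pick the
engine with ``model="mgppm"`` or ``"sequential"``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .blocks import Block
from .model import PatternEngine, utilities
from .params import ParameterSet, nearest_correlation
from .rank2plm import SequentialEngine

__all__ = [
    "EMConfig",
    "FitResult",
    "make_engines",
    "starting_values",
    "marginal_loglikelihood",
    "fit_em_quadrature",
    "fit_mhrm",
    "fit",
    "theta_grid",
    "mvn_logpdf",
]


@dataclass
class EMConfig:
    """Settings for marginal maximum likelihood estimation."""

    method: str = "auto"             # quadrature | mhrm | auto (quadrature iff D <= 3)
    model: str = "mgppm"             # mgppm | sequential
    # quadrature
    n_quad: int = 21
    quad_range: tuple[float, float] = (-6.0, 6.0)
    max_cycles: int = 500
    tol: float = 1e-4
    # MHRM
    burnin: int = 150
    mhrm_max_cycles: int = 3000
    mhrm_min_cycles: int = 250
    gain_exponent: float = 0.75
    mh_steps: int = 1
    proposal_sd: float = 1.0
    window: int = 20
    mhrm_tol: float = 5e-4
    # shared
    fix_correlations: bool = False
    seed: int = 0
    se_draws: int = 50               # posterior draws per person for SEs (MHRM)
    loglik_draws: int = 512          # importance draws per person when D > 4
    verbose: bool = False


@dataclass
class FitResult:
    """Estimates, standard errors, fit statistics, and convergence status."""

    params: ParameterSet
    se_items: np.ndarray
    se_correlations: np.ndarray
    item_labels: list[str]
    loglik: float
    n_free: int
    n_persons: int
    converged: bool
    n_cycles: int
    method: str
    model: str
    trace: list = field(default_factory=list)
    messages: list = field(default_factory=list)

    @property
    def aic(self) -> float:
        return -2.0 * self.loglik + 2.0 * self.n_free

    @property
    def bic(self) -> float:
        return -2.0 * self.loglik + self.n_free * np.log(self.n_persons)


def make_engines(blocks: list[Block], model: str = "mgppm"):
    if model == "mgppm":
        return [PatternEngine(b) for b in blocks]
    if model == "sequential":
        return [SequentialEngine(b) for b in blocks]
    raise ValueError(f"unknown model {model!r}")


def starting_values(blocks: list[Block], n_traits: int,
                    R: np.ndarray | None = None) -> ParameterSet:
    """Slopes +/-1 by keyed sign, intercepts 0, correlations 0.25."""
    slopes = [b.keyed_signs.astype(float) for b in blocks]
    intercepts = [np.zeros(b.size) for b in blocks]
    if R is None:
        R = np.full((n_traits, n_traits), 0.25)
        np.fill_diagonal(R, 1.0)
    return ParameterSet(slopes, intercepts, np.asarray(R, dtype=float))


# ----------------------------------------------------------------------
# shared numerics
# ----------------------------------------------------------------------

def mvn_logpdf(theta: np.ndarray, R: np.ndarray) -> np.ndarray:
    """Log density of MVN(0, R) at each row of ``theta``."""
    from scipy.linalg import solve_triangular
    theta = np.atleast_2d(theta)
    D = R.shape[0]
    L = np.linalg.cholesky(R)
    z = solve_triangular(L, theta.T, lower=True)
    quad = np.sum(z ** 2, axis=0)
    logdet = 2.0 * np.sum(np.log(np.diag(L)))
    return -0.5 * (D * np.log(2.0 * np.pi) + logdet + quad)


def theta_grid(n_traits: int, n_points: int = 21,
               lo: float = -6.0, hi: float = 6.0) -> np.ndarray:
    """Equidistant tensor grid over [lo, hi]^D, shape (n_points**D, D)."""
    pts = np.linspace(lo, hi, n_points)
    mesh = np.meshgrid(*([pts] * n_traits), indexing="ij")
    return np.column_stack([m.ravel() for m in mesh])


def _person_loglik(blocks, engines, params, theta, codes0) -> np.ndarray:
    """Sum over blocks of log response probabilities, per row of ``theta``."""
    total = np.zeros(theta.shape[0])
    for j, (b, eng) in enumerate(zip(blocks, engines)):
        U = utilities(b, theta, params.slopes[j], params.intercepts[j])
        total += eng.loglik(U, codes0[:, j])
    return total


def _grid_loglik(blocks, engines, params, grid, codes0) -> np.ndarray:
    """(n_persons, Q) log likelihood of each person's responses at each node."""
    n, Q = codes0.shape[0], grid.shape[0]
    LL = np.zeros((n, Q))
    for j, (b, eng) in enumerate(zip(blocks, engines)):
        U = utilities(b, grid, params.slopes[j], params.intercepts[j])
        Lj = eng.log_response_probs(U)          # (Q, n_resp)
        LL += Lj[:, codes0[:, j]].T
    return LL


def _block_grad_hess(engine, block, theta, W, a, c):
    """Gradient/Hessian of the weighted block log likelihood in (a, c_free)."""
    U = theta[:, block.traits] * a + c
    g_u, H_u = engine.weighted_grad_hess(U, W)
    T = theta[:, block.traits]                   # (n, B)
    free = block.free_intercepts
    g_a = np.sum(g_u * T, axis=0)
    g_c = np.sum(g_u, axis=0)[free]
    H_aa = np.einsum("qk,qkl,ql->kl", T, H_u, T)
    H_ac = np.einsum("qk,qkl->kl", T, H_u)[:, free]
    H_cc = H_u.sum(axis=0)[np.ix_(free, free)]
    grad = np.concatenate([g_a, g_c])
    H = np.block([[H_aa, H_ac], [H_ac.T, H_cc]])
    return grad, H


def _block_objective(engine, block, theta, W, a, c) -> float:
    U = theta[:, block.traits] * a + c
    L = engine.log_response_probs(U)
    return float(np.sum(W * L))


def _unpack_beta(block, beta):
    B = block.size
    a = beta[:B]
    c = np.zeros(B)
    c[block.free_intercepts] = beta[B:]
    return a, c


def _newton_maximize_block(engine, block, theta, W, a0, c0,
                           n_iter: int = 8, tol: float = 1e-8):
    """Damped Newton ascent of the weighted block log likelihood."""
    beta = np.concatenate([a0, c0[block.free_intercepts]])
    f = _block_objective(engine, block, theta, W, *_unpack_beta(block, beta))
    for _ in range(n_iter):
        a, c = _unpack_beta(block, beta)
        grad, H = _block_grad_hess(engine, block, theta, W, a, c)
        try:
            step = np.linalg.solve(-H, grad)
        except np.linalg.LinAlgError:
            step = grad / max(1.0, np.abs(np.diag(H)).max())
        if not np.all(np.isfinite(step)):
            step = grad
        # step halving
        t = 1.0
        for _ in range(20):
            cand = beta + t * step
            fc = _block_objective(engine, block, theta, W, *_unpack_beta(block, cand))
            if fc >= f - 1e-12:
                break
            t *= 0.5
        else:
            break
        beta, fnew = cand, fc
        if abs(fnew - f) < tol * (abs(f) + 1.0):
            f = fnew
            break
        f = fnew
    return _unpack_beta(block, beta)


# ----------------------------------------------------------------------
# marginal log likelihood
# ----------------------------------------------------------------------

def marginal_loglikelihood(responses: np.ndarray, blocks: list[Block],
                           params: ParameterSet, *, model: str = "mgppm",
                           method: str = "auto", n_quad: int = 21,
                           quad_range: tuple[float, float] = (-6.0, 6.0),
                           n_draws: int = 512, seed: int = 0) -> float:
    """Observed-data (marginal) log likelihood of a fitted or true model.

    Quadrature (default for up to four traits) sums the per-person response
    probability over an equidistant grid weighted by the normalized trait
    density; higher dimensions use importance sampling from a per-person
    Laplace (normal-at-the-mode) proposal, deterministic given ``seed``.
    """
    codes0 = np.asarray(responses, dtype=int) - 1
    engines = make_engines(blocks, model)
    D = params.n_traits
    if method == "auto":
        method = "quadrature" if D <= 4 else "mc"
    if method == "quadrature":
        grid = theta_grid(D, n_quad, *quad_range)
        logw = mvn_logpdf(grid, params.R)
        logw = logw - logsumexp(logw)
        LL = _grid_loglik(blocks, engines, params, grid, codes0)
        return float(np.sum(logsumexp(LL + logw[None, :], axis=1)))
    # Laplace importance sampling
    from .scoring import map_score
    sc = map_score(codes0 + 1, blocks, params, model=model)
    rng = np.random.default_rng(seed)
    n = codes0.shape[0]
    total = 0.0
    chunk = max(1, 200_000 // max(1, n_draws))
    for start in range(0, n, chunk):
        sl = slice(start, min(n, start + chunk))
        m = sc.theta[sl]                               # (c, D)
        cov = sc.covariances[sl] * 1.3                 # inflate for tail cover
        Ls = np.linalg.cholesky(cov)
        c = m.shape[0]
        Z = rng.standard_normal((n_draws, c, D))
        draws = m[None] + np.einsum("cij,kcj->kci", Ls, Z)
        # evaluate per draw-layer to keep the response indexing aligned
        lw = np.zeros((n_draws, c))
        logdet = np.log(np.diagonal(Ls, axis1=1, axis2=2)).sum(axis=1)
        for k in range(n_draws):
            th = draws[k]
            lw[k] = _person_loglik(blocks, engines, params, th, codes0[sl])
            lw[k] += mvn_logpdf(th, params.R)
            logq = -0.5 * D * np.log(2 * np.pi) - logdet - 0.5 * np.sum(Z[k] ** 2, axis=1)
            lw[k] -= logq
        total += float(np.sum(logsumexp(lw, axis=0) - np.log(n_draws)))
    return total


# ----------------------------------------------------------------------
# quadrature EM
# ----------------------------------------------------------------------

def fit_em_quadrature(responses: np.ndarray, blocks: list[Block],
                      config: EMConfig | None = None,
                      start: ParameterSet | None = None,
                      true_R: np.ndarray | None = None) -> FitResult:
    """Bock-Aitkin EM with fixed quadrature (up to four traits).

    E-step: posterior weights of every person over the trait grid.
    M-step: per-block damped Newton on the expected complete-data log
    likelihood; the correlation matrix is updated from posterior second
    moments (or held at ``true_R`` when ``fix_correlations``).
    """
    config = config or EMConfig()
    codes0 = np.asarray(responses, dtype=int) - 1
    n = codes0.shape[0]
    n_traits = int(max(b.traits.max() for b in blocks)) + 1
    if n_traits > 4:
        raise ValueError("quadrature EM supports at most four traits; use fit_mhrm")
    engines = make_engines(blocks, config.model)
    params = start.copy() if start is not None else starting_values(blocks, n_traits)
    if config.fix_correlations and true_R is not None:
        params.R = np.asarray(true_R, dtype=float)
    grid = theta_grid(n_traits, config.n_quad, *config.quad_range)
    messages: list[str] = []
    trace: list[float] = []
    converged = False
    cycle = 0
    for cycle in range(1, config.max_cycles + 1):
        logw = mvn_logpdf(grid, params.R)
        logw = logw - logsumexp(logw)
        LL = _grid_loglik(blocks, engines, params, grid, codes0)
        joint = LL + logw[None, :]
        lse = logsumexp(joint, axis=1)
        trace.append(float(np.sum(lse)))
        W = np.exp(joint - lse[:, None])               # (n, Q)
        old = np.concatenate([params.item_vector(blocks), params.offdiag()])
        # M-step: item parameters block by block
        Wq = W.sum(axis=0)
        for j, (b, eng) in enumerate(zip(blocks, engines)):
            Rj = np.zeros((grid.shape[0], eng.n_responses))
            for m in range(Rj.shape[1]):
                sel = codes0[:, j] == m
                if np.any(sel):
                    Rj[:, m] = W[sel].sum(axis=0)
            a, c = _newton_maximize_block(eng, b, grid, Rj,
                                          params.slopes[j], params.intercepts[j])
            params.slopes[j], params.intercepts[j] = a, c
        # correlation update from posterior second moments
        if not config.fix_correlations:
            M2 = (grid.T * Wq) @ grid / n
            params.R = nearest_correlation(M2)
        new = np.concatenate([params.item_vector(blocks), params.offdiag()])
        if np.max(np.abs(new - old)) < config.tol:
            converged = True
            break
    # final log likelihood and SEs
    loglik = marginal_loglikelihood(codes0 + 1, blocks, params, model=config.model,
                                    method="quadrature", n_quad=config.n_quad,
                                    quad_range=config.quad_range)
    se_items, se_corr = _quadrature_se(blocks, engines, params, grid, codes0,
                                       config.fix_correlations)
    return FitResult(
        params=params, se_items=se_items, se_correlations=se_corr,
        item_labels=params.item_labels(blocks), loglik=loglik,
        n_free=params.n_free(blocks, include_correlations=not config.fix_correlations),
        n_persons=n, converged=converged, n_cycles=cycle,
        method="quadrature", model=config.model, trace=trace, messages=messages,
    )


def _corr_scores(E_outer: np.ndarray, R: np.ndarray) -> np.ndarray:
    """Per-person scores of the log likelihood w.r.t. off-diagonal correlations.

    Fisher identity: the observed score equals the posterior expectation of
    the complete-data score ``0.5 (P theta theta' P - P)`` with
    ``P = R^{-1}``; off-diagonal entries count twice by symmetry.
    """
    P = np.linalg.inv(R)
    M = 0.5 * (np.einsum("ab,nbc,cd->nad", P, E_outer, P) - P[None])
    iu = np.triu_indices(R.shape[0], k=1)
    return 2.0 * M[:, iu[0], iu[1]]


def _item_scores_from_weights(blocks, engines, params, nodes, W, codes0):
    """Per-person item-parameter scores via the Fisher identity.

    ``nodes`` are integration nodes (Q, D) and ``W`` posterior weights
    (n, Q).  Returns (n, p_items).
    """
    n = codes0.shape[0]
    parts = []
    for j, (b, eng) in enumerate(zip(blocks, engines)):
        U = utilities(b, nodes, params.slopes[j], params.intercepts[j])
        M = eng.n_responses
        # residual tensor for every node x response
        res = np.stack([
            eng.score_residuals(U, np.full(nodes.shape[0], m, dtype=int))
            for m in range(M)
        ])                                             # (M, Q, B)
        T = nodes[:, b.traits]                         # (Q, B)
        free = b.free_intercepts
        s_a = np.zeros((n, b.size))
        s_c = np.zeros((n, b.size))
        for m in range(M):
            sel = codes0[:, j] == m
            if not np.any(sel):
                continue
            s_a[sel] = W[sel] @ (T * res[m])
            s_c[sel] = W[sel] @ res[m]
        parts.append(np.column_stack([s_a, s_c[:, free]]))
    return np.column_stack(parts)


def _quadrature_se(blocks, engines, params, grid, codes0, fix_correlations):
    logw = mvn_logpdf(grid, params.R)
    logw = logw - logsumexp(logw)
    LL = _grid_loglik(blocks, engines, params, grid, codes0)
    joint = LL + logw[None, :]
    W = np.exp(joint - logsumexp(joint, axis=1, keepdims=True))
    scores = _item_scores_from_weights(blocks, engines, params, grid, W, codes0)
    if not fix_correlations:
        outers = np.einsum("qa,qb->qab", grid, grid)
        E_outer = np.einsum("nq,qab->nab", W, outers)
        scores = np.column_stack([scores, _corr_scores(E_outer, params.R)])
    return _se_from_scores(scores, blocks, params, fix_correlations)


def _se_from_scores(scores, blocks, params, fix_correlations):
    info = scores.T @ scores
    p_items = len(params.item_labels(blocks))
    try:
        cov = np.linalg.inv(info)
        se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    except np.linalg.LinAlgError:
        se = np.full(info.shape[0], np.nan)
    se_items = se[:p_items]
    se_corr = se[p_items:] if not fix_correlations else np.zeros(0)
    return se_items, se_corr


# ----------------------------------------------------------------------
# MHRM
# ----------------------------------------------------------------------

def fit_mhrm(responses: np.ndarray, blocks: list[Block],
             config: EMConfig | None = None,
             start: ParameterSet | None = None,
             true_R: np.ndarray | None = None) -> FitResult:
    """Stochastic-approximation MML estimation for any trait dimension.

    Each cycle (i) advances a per-person Metropolis-Hastings chain on the
    trait posteriors, (ii) applies a Robbins-Monro damped Newton update of
    the item parameters using complete-data gradients, and (iii) moves the
    intertrait correlations toward the sampled traits' correlation.  The
    gain is constant during burn-in and decays as ``t^-gain_exponent``
    afterwards; convergence is judged on drift of the gain-smoothed
    parameter vector over a trailing window.
    """
    config = config or EMConfig()
    rng = np.random.default_rng(config.seed)
    codes0 = np.asarray(responses, dtype=int) - 1
    n = codes0.shape[0]
    n_traits = int(max(b.traits.max() for b in blocks)) + 1
    engines = make_engines(blocks, config.model)
    params = start.copy() if start is not None else starting_values(blocks, n_traits)
    if config.fix_correlations:
        if true_R is not None:
            params.R = np.asarray(true_R, dtype=float)
    # one-hot response weights per block (constant across cycles)
    onehots = []
    for j, (b, eng) in enumerate(zip(blocks, engines)):
        M = eng.n_responses
        Wj = np.zeros((n, M))
        Wj[np.arange(n), codes0[:, j]] = 1.0
        onehots.append(Wj)

    theta = np.zeros((n, n_traits))
    cur_ll = _person_loglik(blocks, engines, params, theta, codes0) \
        + mvn_logpdf(theta, params.R)
    prop_sd = config.proposal_sd
    p_per_block = [b.size + int(b.free_intercepts.sum()) for b in blocks]
    Hbar = [np.eye(p) * -(n * 0.1) for p in p_per_block]
    Sigma_bar = params.R.copy()
    history: list[np.ndarray] = []
    messages: list[str] = []
    converged = False
    cycle = 0
    nonpd = 0
    for cycle in range(1, config.mhrm_max_cycles + 1):
        in_burn = cycle <= config.burnin
        gamma = 1.0 if in_burn else (cycle - config.burnin) ** (-config.gain_exponent)
        gamma_h = 0.5 if in_burn else gamma
        # --- MH sampling of person traits --------------------------------
        acc_total = 0.0
        for _ in range(config.mh_steps):
            prop = theta + rng.standard_normal(theta.shape) * prop_sd
            prop_ll = _person_loglik(blocks, engines, params, prop, codes0) \
                + mvn_logpdf(prop, params.R)
            accept = np.log(rng.random(n)) < (prop_ll - cur_ll)
            theta[accept] = prop[accept]
            cur_ll[accept] = prop_ll[accept]
            acc_total += accept.mean()
        acc = acc_total / config.mh_steps
        if in_burn:
            prop_sd = float(np.clip(prop_sd * np.exp(0.2 * (acc - 0.35)), 0.05, 4.0))
        # --- Robbins-Monro damped Newton update --------------------------
        for j, (b, eng) in enumerate(zip(blocks, engines)):
            grad, H = _block_grad_hess(eng, b, theta, onehots[j],
                                       params.slopes[j], params.intercepts[j])
            Hbar[j] = Hbar[j] + gamma_h * (H - Hbar[j])
            try:
                step = np.linalg.solve(-Hbar[j], grad)
            except np.linalg.LinAlgError:
                step = grad / n
            step = np.clip(step, -0.5, 0.5)
            beta = np.concatenate([params.slopes[j],
                                   params.intercepts[j][b.free_intercepts]])
            beta = beta + (min(gamma, 0.5) if in_burn else gamma) * step
            params.slopes[j], params.intercepts[j] = _unpack_beta(b, beta)
        if not config.fix_correlations:
            S2 = theta.T @ theta / n
            Sigma_bar = Sigma_bar + gamma * (S2 - Sigma_bar)
            try:
                params.R = nearest_correlation(Sigma_bar)
            except np.linalg.LinAlgError:
                nonpd += 1
            # theta prior changed: refresh cached posterior values
        cur_ll = _person_loglik(blocks, engines, params, theta, codes0) \
            + mvn_logpdf(theta, params.R)
        vec = np.concatenate([params.item_vector(blocks), params.offdiag()])
        history.append(vec)
        # --- convergence: updates stay small over a trailing window ------
        W = config.window
        if (not in_burn and cycle - config.burnin >= max(config.mhrm_min_cycles, 2 * W)):
            changes = np.array(history[-(W + 1):])
            step_sizes = np.max(np.abs(np.diff(changes, axis=0)), axis=1)
            if np.all(step_sizes < config.mhrm_tol):
                converged = True
                break
    if nonpd > config.mhrm_max_cycles // 4:
        converged = False
        messages.append("intertrait correlation updates repeatedly left the PD cone")
    # tail-average the RM iterates for the final estimate
    W = min(config.window, len(history))
    final = np.mean(history[-W:], axis=0)
    n_off = n_traits * (n_traits - 1) // 2
    params.set_item_vector(blocks, final[:len(final) - n_off])
    if not config.fix_correlations:
        iu = np.triu_indices(n_traits, k=1)
        R = np.eye(n_traits)
        R[iu] = final[-n_off:]
        R = R + R.T - np.eye(n_traits)
        params.R = nearest_correlation(R)
    loglik = marginal_loglikelihood(codes0 + 1, blocks, params, model=config.model,
                                    method="auto", n_draws=config.loglik_draws,
                                    seed=config.seed + 1)
    se_items, se_corr = _mhrm_se(blocks, engines, params, codes0, theta, cur_ll,
                                 rng, config, prop_sd)
    return FitResult(
        params=params, se_items=se_items, se_correlations=se_corr,
        item_labels=params.item_labels(blocks), loglik=loglik,
        n_free=params.n_free(blocks, include_correlations=not config.fix_correlations),
        n_persons=n, converged=converged, n_cycles=cycle,
        method="mhrm", model=config.model,
        trace=[float(np.max(np.abs(h))) for h in history[-5:]], messages=messages,
    )


def _mhrm_se(blocks, engines, params, codes0, theta, cur_ll, rng, config, prop_sd):
    """Fisher-identity SEs from continued posterior MH draws."""
    n = codes0.shape[0]
    D = params.n_traits
    theta = theta.copy()
    cur_ll = cur_ll.copy()
    K = config.se_draws
    p_items = len(params.item_labels(blocks))
    n_off = 0 if config.fix_correlations else D * (D - 1) // 2
    scores = np.zeros((n, p_items + n_off))
    thin = 3
    for k in range(K * thin):
        prop = theta + rng.standard_normal(theta.shape) * prop_sd
        prop_ll = _person_loglik(blocks, engines, params, prop, codes0) \
            + mvn_logpdf(prop, params.R)
        accept = np.log(rng.random(n)) < (prop_ll - cur_ll)
        theta[accept] = prop[accept]
        cur_ll[accept] = prop_ll[accept]
        if k % thin != thin - 1:
            continue
        cols = []
        for j, (b, eng) in enumerate(zip(blocks, engines)):
            U = utilities(b, theta, params.slopes[j], params.intercepts[j])
            res = eng.score_residuals(U, codes0[:, j])   # (n, B)
            T = theta[:, b.traits]
            cols.append(np.column_stack([res * T, res[:, b.free_intercepts]]))
        s = np.column_stack(cols)
        if n_off:
            E_outer = np.einsum("na,nb->nab", theta, theta)
            s = np.column_stack([s, _corr_scores(E_outer, params.R)])
        scores += s
    scores /= K
    return _se_from_scores(scores, blocks, params, config.fix_correlations)


def fit(responses: np.ndarray, blocks: list[Block],
        config: EMConfig | None = None,
        start: ParameterSet | None = None,
        true_R: np.ndarray | None = None) -> FitResult:
    """Dispatch to quadrature EM (up to 3 traits) or MHRM."""
    config = config or EMConfig()
    n_traits = int(max(b.traits.max() for b in blocks)) + 1
    method = config.method
    if method == "auto":
        method = "quadrature" if n_traits <= 3 else "mhrm"
    if method == "quadrature":
        return fit_em_quadrature(responses, blocks, config, start, true_R)
    return fit_mhrm(responses, blocks, config, start, true_R)
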