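"""Latent-trait scoring: MAP and EAP estimates, standard errors, reliability.

Given fixed item parameters, each person's trait vector is estimated by
maximising the log posterior (sum of block log response probabilities plus
the multivariate-normal population log density).  MAP standard errors come
from the inverse negative Hessian at the mode.  EAP (posterior mean) is
offered as a cross-check.  Empirical reliability of a trait's estimates is
``V(theta_hat) / (V(theta_hat) + mean(SE^2))``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .blocks import Block
from .model import utilities
from .params import ParameterSet

__all__ = ["ScoreResult", "map_score", "eap_score", "empirical_reliability"]


@dataclass
class ScoreResult:
    """Per-person trait estimates with standard errors."""

    theta: np.ndarray          # (n, D)
    se: np.ndarray             # (n, D)
    covariances: np.ndarray    # (n, D, D) posterior/curvature covariance
    estimator: str             # MAP | EAP
    converged: np.ndarray | None = None


def _posterior_terms(blocks, engines, params, theta, codes0):
    """Log posterior value, gradient, and Hessian for every person."""
    from .em import mvn_logpdf
    n, D = theta.shape
    Rinv = np.linalg.inv(params.R)
    value = mvn_logpdf(theta, params.R)
    grad = -theta @ Rinv
    hess = np.broadcast_to(-Rinv, (n, D, D)).copy()
    for j, (b, eng) in enumerate(zip(blocks, engines)):
        a = params.slopes[j]
        U = utilities(b, theta, a, params.intercepts[j])
        value += eng.loglik(U, codes0[:, j])
        W = np.zeros((n, eng.n_responses))
        W[np.arange(n), codes0[:, j]] = 1.0
        g_u, H_u = eng.weighted_grad_hess(U, W)
        tr = b.traits
        for k in range(b.size):
            grad[:, tr[k]] += a[k] * g_u[:, k]
            for l in range(b.size):
                hess[:, tr[k], tr[l]] += a[k] * a[l] * H_u[:, k, l]
    return value, grad, hess


def _newton_map(blocks, engines, params, codes0, theta0,
                tol: float, max_iter: int):
    theta = theta0.copy()
    value, grad, hess = _posterior_terms(blocks, engines, params, theta, codes0)
    for _ in range(max_iter):
        gnorm = np.linalg.norm(grad, axis=1)
        active = gnorm > tol
        if not active.any():
            break
        try:
            step = np.linalg.solve(-hess, grad[:, :, None])[:, :, 0]
        except np.linalg.LinAlgError:
            step = grad.copy()
        step = np.clip(step, -2.0, 2.0)
        t = np.ones(theta.shape[0])
        for _ in range(25):
            cand = theta + (t * active)[:, None] * step
            v_new, g_new, h_new = _posterior_terms(blocks, engines, params, cand, codes0)
            worse = active & (v_new < value - 1e-10)
            if not worse.any():
                break
            t[worse] *= 0.5
        improved = v_new >= value - 1e-10
        theta[improved] = cand[improved]
        value = np.where(improved, v_new, value)
        grad[improved] = g_new[improved]
        hess[improved] = h_new[improved]
    converged = np.linalg.norm(grad, axis=1) <= max(tol, 1e-4)
    return theta, value, hess, converged


def map_score(responses: np.ndarray, blocks: list[Block], params: ParameterSet,
              *, model: str = "mgppm", tol: float = 1e-6,
              max_iter: int = 100) -> ScoreResult:
    """Maximum a posteriori trait scores with curvature standard errors.

    Damped Newton ascent run from the prior mode and from one perturbed
    start, keeping the better mode per person.  Persons whose optimisation
    fails fall back to EAP with a warning.
    """
    from .em import make_engines
    codes0 = np.asarray(responses, dtype=int) - 1
    n = codes0.shape[0]
    D = params.n_traits
    engines = make_engines(blocks, model)
    th0 = np.zeros((n, D))
    t1, v1, h1, c1 = _newton_map(blocks, engines, params, codes0, th0, tol, max_iter)
    th_pert = np.full((n, D), 0.5)
    t2, v2, h2, c2 = _newton_map(blocks, engines, params, codes0, th_pert, tol, max_iter)
    take2 = v2 > v1 + 1e-10
    theta = np.where(take2[:, None], t2, t1)
    hess = np.where(take2[:, None, None], h2, h1)
    converged = np.where(take2, c2, c1)
    cov = np.linalg.inv(-hess)
    se = np.sqrt(np.clip(np.diagonal(cov, axis1=1, axis2=2), 0.0, None))
    if not converged.all():
        bad = np.flatnonzero(~converged)
        warnings.warn(f"MAP optimisation failed for {bad.size} persons; using EAP for them")
        eap = eap_score(responses, blocks, params, model=model)
        theta[bad] = eap.theta[bad]
        se[bad] = eap.se[bad]
        cov[bad] = eap.covariances[bad]
    return ScoreResult(theta=theta, se=se, covariances=cov,
                       estimator="MAP", converged=converged)


def eap_score(responses: np.ndarray, blocks: list[Block], params: ParameterSet,
              *, model: str = "mgppm", n_quad: int = 31, n_draws: int = 4000,
              seed: int = 0) -> ScoreResult:
    """Expected a posteriori trait scores (posterior mean and SD).

    Uses an equidistant grid for up to three traits and Monte Carlo draws
    from the trait population otherwise.
    """
    from .em import make_engines, theta_grid, mvn_logpdf, _grid_loglik
    codes0 = np.asarray(responses, dtype=int) - 1
    engines = make_engines(blocks, model)
    D = params.n_traits
    if D <= 3:
        nodes = theta_grid(D, n_quad, -6.0, 6.0)
        logw = mvn_logpdf(nodes, params.R)
    else:
        rng = np.random.default_rng(seed)
        L = np.linalg.cholesky(params.R)
        nodes = rng.standard_normal((n_draws, D)) @ L.T
        logw = np.zeros(n_draws)
    LL = _grid_loglik(blocks, engines, params, nodes, codes0)
    joint = LL + logw[None, :]
    W = np.exp(joint - logsumexp(joint, axis=1, keepdims=True))
    mean = W @ nodes
    Eout = np.einsum("nq,qa,qb->nab", W, nodes, nodes)
    cov = Eout - np.einsum("na,nb->nab", mean, mean)
    se = np.sqrt(np.clip(np.diagonal(cov, axis1=1, axis2=2), 0.0, None))
    return ScoreResult(theta=mean, se=se, covariances=cov, estimator="EAP")


def empirical_reliability(scores: ScoreResult) -> np.ndarray:
    """Per-trait empirical reliability of score estimates.

    ``V(theta_hat) / (V(theta_hat) + mean_i SE_i^2)`` where ``V`` is the
    sample variance of the trait's estimates.  Returns 0 (with a warning)
    for a trait whose estimates have no variance.
    """
    if scores.theta.shape[0] < 2:
        raise ValueError("reliability needs at least two persons")
    var = np.var(scores.theta, axis=0, ddof=1)
    err = np.mean(scores.se ** 2, axis=0)
    out = np.zeros_like(var)
    for d in range(var.size):
        if var[d] <= 0.0:
            warnings.warn(f"trait {d}: zero score variance; reliability set to 0")
            continue
        out[d] = var[d] / (var[d] + err[d])
    return out
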