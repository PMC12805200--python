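"""Bayesian estimation by adaptive Metropolis-within-Gibbs sampling.

The target is the joint posterior of item parameters, person traits, and
intertrait correlations: lognormal(0, 2) priors on slope magnitudes (signs
fixed by keyed direction), Normal(0, 3) on free intercepts, an LKJ prior
(shape 4) on the correlation matrix, and the standard multivariate normal
population on traits, times the ranking-pattern likelihood.

Correlations are sampled through canonical partial correlations mapped to
a Cholesky factor, with tanh-unconstrained coordinates; under LKJ(eta) the
partial correlations are independent scaled Beta variables, giving an
exact closed-form prior in the sampling space.  Item parameters and
partial correlations update component-wise and traits per person
(vectorized), all with scale adaptation during burn-in.

Estimates are posterior means of the pooled post-burn-in draws across
chains; convergence requires split R-hat below 1.01 and bulk effective
sample size above 400 for every parameter.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import betaln

from .blocks import Block
from .em import _person_loglik, make_engines, mvn_logpdf
from .model import utilities
from .params import ParameterSet

__all__ = [
    "MCMCConfig",
    "PosteriorSummary",
    "lkj_logpdf",
    "vine_to_corr",
    "log_posterior",
    "run_mcmc",
    "split_rhat",
]


@dataclass
class MCMCConfig:
    """Sampler settings and prior hyperparameters."""

    chains: int = 4
    iterations: int = 8000
    burnin: int = 4000
    seed: int = 0
    slope_log_sd: float = 2.0       # lognormal prior SD on |a|, log scale
    intercept_sd: float = 3.0       # normal prior SD on intercepts
    lkj_shape: float = 4.0
    adapt_interval: int = 25
    target_acceptance: float = 0.3
    fix_correlations: bool = False
    thin: int = 1

    def __post_init__(self) -> None:
        if self.burnin >= self.iterations:
            raise ValueError("burnin must be smaller than iterations")


@dataclass
class PosteriorSummary:
    """Pooled posterior means/SDs with convergence diagnostics."""

    labels: list[str]
    mean: np.ndarray
    sd: np.ndarray
    rhat: np.ndarray
    ess_bulk: np.ndarray
    converged: bool
    params: ParameterSet
    draws: np.ndarray               # (chains, kept, p)


# ----------------------------------------------------------------------
# LKJ prior machinery
# ----------------------------------------------------------------------

def lkj_log_norm(D: int, eta: float) -> float:
    """Log normalizing constant of the LKJ correlation density."""
    logc = 0.0
    for k in range(1, D):
        b = eta + (D - k - 1) / 2.0
        logc += (D - k) * ((2.0 * eta - 2.0 + D - k) * np.log(2.0) + betaln(b, b))
    return logc


def lkj_logpdf(R: np.ndarray, eta: float) -> float:
    """Log density of the LKJ distribution at a correlation matrix."""
    D = R.shape[0]
    sign, logdet = np.linalg.slogdet(R)
    if sign <= 0:
        return -np.inf
    return (eta - 1.0) * logdet - lkj_log_norm(D, eta)


def _vine_pairs(D: int) -> list[tuple[int, int]]:
    """Canonical-partial-correlation ordering: row-major lower triangle.

    Entry ``(i, j)`` with ``j < i`` is the partial correlation of variables
    ``i`` and ``j`` given variables ``0..j-1``.
    """
    return [(i, j) for i in range(1, D) for j in range(i)]


def vine_to_corr(partials: np.ndarray, D: int) -> np.ndarray:
    """Correlation matrix from canonical partial correlations in (-1, 1).

    Builds the Cholesky factor row by row (each CPC spends the remaining
    length of its row), so any values in (-1, 1) yield a positive-definite
    correlation matrix with unit diagonal.
    """
    z = np.asarray(partials, dtype=float)
    L = np.zeros((D, D))
    L[0, 0] = 1.0
    pos = 0
    for i in range(1, D):
        rem = 1.0
        for j in range(i):
            L[i, j] = z[pos] * np.sqrt(rem)
            rem -= L[i, j] ** 2
            pos += 1
        L[i, i] = np.sqrt(max(rem, 0.0))
    return L @ L.T


def _vine_layer_betas(D: int, eta: float) -> np.ndarray:
    """Beta shape per canonical partial correlation equivalent to LKJ(eta).

    The CPC of pair ``(i, j)`` conditions on ``j`` earlier variables and
    belongs to vine tree ``j + 1``, whose LKJ-consistent scaled-Beta shape
    is ``eta + (D - 2 - j) / 2``.
    """
    return np.array([eta + (D - 2 - j) / 2.0
                     for i in range(1, D) for j in range(i)])


def _vine_log_prior_y(y: np.ndarray, betas: np.ndarray) -> float:
    """Log prior of tanh-unconstrained partials, Jacobian included.

    With ``p = tanh(y)`` and layer prior ``(1-p^2)^(beta-1)`` (scaled
    Beta), the density in ``y`` is proportional to ``(1-p^2)^beta``.
    """
    p2 = np.tanh(y) ** 2
    return float(np.sum(betas * np.log1p(-p2)))


# ----------------------------------------------------------------------
# posterior pieces
# ----------------------------------------------------------------------

def log_posterior(blocks: list[Block], params: ParameterSet,
                  thetas: np.ndarray, responses: np.ndarray,
                  config: MCMCConfig | None = None,
                  model: str = "mgppm") -> float:
    """Complete-data log posterior: priors + trait density + likelihood.

    Slope signs must match the blocks' keyed directions; a violation has
    prior probability zero and returns ``-inf``.
    """
    config = config or MCMCConfig()
    codes0 = np.asarray(responses, dtype=int) - 1
    engines = make_engines(blocks, model)
    lp = 0.0
    for j, b in enumerate(blocks):
        a = params.slopes[j]
        if np.any(np.sign(a) != b.keyed_signs):
            return -np.inf
        lam = np.log(np.abs(a))
        # lognormal density of |a| in the natural parameterization
        lp += float(np.sum(-0.5 * (lam / config.slope_log_sd) ** 2 - lam
                           - np.log(config.slope_log_sd) - 0.5 * np.log(2 * np.pi)))
        c = params.intercepts[j][b.free_intercepts]
        lp += float(np.sum(-0.5 * (c / config.intercept_sd) ** 2
                           - np.log(config.intercept_sd) - 0.5 * np.log(2 * np.pi)))
    lp += lkj_logpdf(params.R, config.lkj_shape)
    lp += float(np.sum(mvn_logpdf(thetas, params.R)))
    if codes0.size:
        lp += float(np.sum(_person_loglik(blocks, engines, params, thetas, codes0)))
    return lp


# ----------------------------------------------------------------------
# sampler
# ----------------------------------------------------------------------

def _item_log_prior(lam, c_free, config):
    return (-0.5 * np.sum((lam / config.slope_log_sd) ** 2)
            - 0.5 * np.sum((c_free / config.intercept_sd) ** 2))


def _run_chain(blocks, engines, codes0, config, seed, n_traits, model,
               true_R=None):
    rng = np.random.default_rng(seed)
    n = codes0.shape[0]
    J = len(blocks)
    D = n_traits
    n_off = D * (D - 1) // 2
    betas = _vine_layer_betas(D, config.lkj_shape)
    # state
    lam = [rng.normal(0.0, 0.3, size=b.size) for b in blocks]
    c = [np.zeros(b.size) for b in blocks]
    for j, b in enumerate(blocks):
        c[j][b.free_intercepts] = rng.normal(0.0, 0.3, size=int(b.free_intercepts.sum()))
    y = rng.normal(0.0, 0.2, size=n_off)
    R = vine_to_corr(np.tanh(y), D) if not config.fix_correlations else np.asarray(true_R, float)
    theta = rng.standard_normal((n, D)) * 0.5

    def slopes(j):
        return np.exp(lam[j]) * blocks[j].keyed_signs

    # cached per-block log likelihood at current theta/items
    def block_ll(j, lam_j=None, c_j=None, th=None):
        a = np.exp(lam[j] if lam_j is None else lam_j) * blocks[j].keyed_signs
        cc = c[j] if c_j is None else c_j
        U = utilities(blocks[j], theta if th is None else th, a, cc)
        return engines[j].loglik(U, codes0[:, j])

    bll = np.stack([block_ll(j) for j in range(J)])          # (J, n)
    prior_th = mvn_logpdf(theta, R)

    n_item = [b.size + int(b.free_intercepts.sum()) for b in blocks]
    sd_item = [np.full(p, 0.2) for p in n_item]
    sd_theta = 0.5
    sd_y = np.full(n_off, 0.2)
    acc_item = [np.zeros(p) for p in n_item]
    acc_theta = 0.0
    acc_y = np.zeros(n_off)
    kept = []
    n_keep = (config.iterations - config.burnin) // config.thin
    for it in range(config.iterations):
        in_burn = it < config.burnin
        # --- person traits (vectorized random walk) ---------------------
        prop = theta + rng.standard_normal((n, D)) * sd_theta
        bll_prop = np.empty_like(bll)
        for j in range(J):
            bll_prop[j] = block_ll(j, th=prop)
        prior_prop = mvn_logpdf(prop, R)
        logr = bll_prop.sum(axis=0) + prior_prop - bll.sum(axis=0) - prior_th
        accept = np.log(rng.random(n)) < logr
        theta[accept] = prop[accept]
        bll[:, accept] = bll_prop[:, accept]
        prior_th[accept] = prior_prop[accept]
        acc_theta += accept.mean() if n else config.target_acceptance
        # --- item parameters, component-wise random walk ----------------
        for j, b in enumerate(blocks):
            free_ix = np.flatnonzero(b.free_intercepts)
            for p in range(n_item[j]):
                lam_p, c_p = lam[j], c[j]
                if p < b.size:
                    lam_p = lam[j].copy()
                    lam_p[p] += rng.normal(0.0, sd_item[j][p])
                else:
                    c_p = c[j].copy()
                    c_p[free_ix[p - b.size]] += rng.normal(0.0, sd_item[j][p])
                ll_p = block_ll(j, lam_j=lam_p, c_j=c_p)
                free = b.free_intercepts
                logr = (ll_p.sum() + _item_log_prior(lam_p, c_p[free], config)
                        - bll[j].sum() - _item_log_prior(lam[j], c[j][free], config))
                if np.log(rng.random()) < logr:
                    lam[j], c[j] = lam_p, c_p
                    bll[j] = ll_p
                    acc_item[j][p] += 1.0
        # --- correlations through vine partials, component-wise ---------
        if not config.fix_correlations:
            for p in range(n_off):
                y_p = y.copy()
                y_p[p] += rng.normal(0.0, sd_y[p])
                R_p = vine_to_corr(np.tanh(y_p), D)
                prior_th_p = mvn_logpdf(theta, R_p)
                logr = (prior_th_p.sum() + _vine_log_prior_y(y_p, betas)
                        - prior_th.sum() - _vine_log_prior_y(y, betas))
                if np.log(rng.random()) < logr:
                    y, R, prior_th = y_p, R_p, prior_th_p
                    acc_y[p] += 1.0
        # --- adaptation -------------------------------------------------
        if in_burn and (it + 1) % config.adapt_interval == 0:
            w = config.adapt_interval
            tgt = config.target_acceptance
            sd_theta = float(np.clip(
                sd_theta * np.exp(0.3 * (acc_theta / w - tgt)), 1e-3, 5.0))
            for j in range(J):
                sd_item[j] = np.clip(
                    sd_item[j] * np.exp(0.5 * (acc_item[j] / w - tgt)), 1e-3, 3.0)
                acc_item[j][:] = 0.0
            sd_y = np.clip(sd_y * np.exp(0.5 * (acc_y / w - tgt)), 1e-3, 3.0)
            acc_theta = 0.0
            acc_y[:] = 0.0
        if not in_burn and (it - config.burnin) % config.thin == 0:
            vec = []
            for j, b in enumerate(blocks):
                vec.append(np.exp(lam[j]) * b.keyed_signs)
                vec.append(c[j][b.free_intercepts])
            iu = np.triu_indices(D, k=1)
            vec.append(R[iu])
            kept.append(np.concatenate(vec))
    return np.array(kept[:n_keep] if n_keep else kept)


def split_rhat(draws: np.ndarray) -> np.ndarray:
    """Split R-hat per parameter from draws of shape (chains, iters, p)."""
    C, T, P = draws.shape
    half = T // 2
    seq = draws[:, : 2 * half].reshape(C * 2, half, P)
    m = seq.mean(axis=1)
    W = seq.var(axis=1, ddof=1).mean(axis=0)
    B = half * m.var(axis=0, ddof=1)
    var_plus = (half - 1) / half * W + B / half
    return np.sqrt(var_plus / np.maximum(W, 1e-300))


def run_mcmc(responses: np.ndarray, blocks: list[Block],
             config: MCMCConfig | None = None, *, model: str = "mgppm",
             true_R: np.ndarray | None = None) -> PosteriorSummary:
    """Sample the joint posterior and summarize it.

    Runs ``config.chains`` independent chains (seeded from ``config.seed``),
    pools post-burn-in draws, and reports posterior means as estimates and
    posterior SDs as standard errors.  Non-convergence (any split R-hat at
    or above 1.01 or bulk ESS at or below 400) sets ``converged=False``
    rather than raising.
    """
    config = config or MCMCConfig()
    codes0 = np.asarray(responses, dtype=int) - 1
    engines = make_engines(blocks, model)
    n_traits = int(max(b.traits.max() for b in blocks)) + 1
    draws = np.stack([
        _run_chain(blocks, engines, codes0, config, config.seed + 1000 * ch,
                   n_traits, model, true_R)
        for ch in range(config.chains)
    ])
    pooled = draws.reshape(-1, draws.shape[-1])
    mean = pooled.mean(axis=0)
    sd = pooled.std(axis=0, ddof=1)
    rhat = split_rhat(draws)
    try:
        import arviz as az
        ess = np.array([
            az.ess(draws[:, :, p], method="bulk") for p in range(draws.shape[-1])
        ])
    except Exception:                                     # pragma: no cover
        ess = np.full(draws.shape[-1], np.nan)
    varying = sd > 1e-12            # fixed quantities carry no MCMC error
    converged = bool(np.all(rhat[varying] < 1.01) and np.all(ess[varying] > 400)) \
        if config.chains >= 2 else bool(np.all(ess[varying] > 400))
    # rebuild a ParameterSet from posterior means
    params = ParameterSet(
        slopes=[np.zeros(b.size) for b in blocks],
        intercepts=[np.zeros(b.size) for b in blocks],
        R=np.eye(n_traits),
    )
    pos = 0
    for j, b in enumerate(blocks):
        params.slopes[j] = mean[pos: pos + b.size].copy()
        pos += b.size
        nf = int(b.free_intercepts.sum())
        cvec = np.zeros(b.size)
        cvec[b.free_intercepts] = mean[pos: pos + nf]
        params.intercepts[j] = cvec
        pos += nf
    iu = np.triu_indices(n_traits, k=1)
    R = np.eye(n_traits)
    R[iu] = mean[pos:]
    params.R = R + R.T - np.eye(n_traits)
    labels = params.item_labels(blocks) + [f"r{i+1}{j+1}" for i, j in zip(*iu)]
    return PosteriorSummary(labels=labels, mean=mean, sd=sd, rhat=rhat,
                            ess_bulk=ess, converged=converged, params=params,
                            draws=draws)
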