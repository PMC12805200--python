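"""Model comparison and fit diagnostics for forced-choice IRT fits.

Covers the sequential-selection baseline comparison (AIC/BIC on identical
response codings, cross-model score agreement, reliabilities), pairwise
local-dependence screening via Pearson chi-square transformed to Cramer's
V, a standardized item log-likelihood fit statistic, a standardized
root-mean-square residual (SRMSR) over univariate and bivariate pattern
margins, and item trait characteristic curves (expected rank score of a
focal statement against its trait).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .blocks import Block
from .em import EMConfig, FitResult, fit, make_engines, mvn_logpdf
from .model import utilities
from .params import ParameterSet
from .scoring import ScoreResult, empirical_reliability, map_score

__all__ = [
    "ComparisonReport",
    "compare_models",
    "model_implied_tables",
    "ld_cramers_v",
    "item_fit_z",
    "srmsr",
    "expected_item_trait_score",
]


# ----------------------------------------------------------------------
# model-implied margins via trait-distribution integration
# ----------------------------------------------------------------------

def _population_response_probs(blocks, params, model, n_draws, seed):
    """Response probabilities per block at Monte Carlo population draws.

    Returns a list of (n_draws, M_j) arrays sharing the same trait draws,
    so products across blocks integrate the joint distribution.
    """
    engines = make_engines(blocks, model)
    rng = np.random.default_rng(seed)
    L = np.linalg.cholesky(params.R)
    theta = rng.standard_normal((n_draws, params.n_traits)) @ L.T
    out = []
    for j, (b, eng) in enumerate(zip(blocks, engines)):
        U = utilities(b, theta, params.slopes[j], params.intercepts[j])
        out.append(eng.response_probs(U))
    return out


def model_implied_tables(blocks: list[Block], params: ParameterSet,
                         *, model: str = "mgppm", n_draws: int = 20000,
                         seed: int = 0):
    """Model-implied univariate margins and bivariate cross tables.

    Integrates response probabilities over the trait population (Monte
    Carlo, deterministic given ``seed``).  Returns ``(margins, joints)``
    where ``margins[j]`` is the probability vector of block ``j`` and
    ``joints[(i, j)]`` the joint probability table of block pair ``i < j``.
    """
    P = _population_response_probs(blocks, params, model, n_draws, seed)
    margins = [p.mean(axis=0) for p in P]
    joints = {}
    for i in range(len(blocks)):
        for j in range(i + 1, len(blocks)):
            joints[(i, j)] = np.einsum("na,nb->ab", P[i], P[j]) / P[i].shape[0]
    return margins, joints


def _observed_tables(responses: np.ndarray, sizes: list[int]):
    codes0 = np.asarray(responses, dtype=int) - 1
    n, J = codes0.shape
    margins = [np.bincount(codes0[:, j], minlength=sizes[j]) / n for j in range(J)]
    joints = {}
    for i in range(J):
        for j in range(i + 1, J):
            tab = np.zeros((sizes[i], sizes[j]))
            np.add.at(tab, (codes0[:, i], codes0[:, j]), 1.0)
            joints[(i, j)] = tab / n
    return margins, joints


def _merge_sparse(obs: np.ndarray, exp: np.ndarray, n: int, min_expected: float):
    """Merge sparse rows/columns until all expected counts reach a floor.

    Repeatedly collapses the two smallest-margin rows (or columns) of the
    dimension containing the smallest expected cell, never shrinking below
    2 x 2.  Observed and expected tables are merged identically.
    """
    obs = obs.copy()
    exp = exp.copy()
    while (exp * n).min() < min_expected and max(obs.shape) > 2:
        r, c = np.unravel_index(np.argmin(exp), exp.shape)
        axis = 0 if (exp.shape[0] > 2 and (exp.shape[1] <= 2
                     or exp.sum(axis=1).min() <= exp.sum(axis=0).min())) else 1
        margins = exp.sum(axis=1 - axis)
        order = np.argsort(margins)
        keep, drop = sorted(order[:2])
        obs = _collapse(obs, axis, keep, drop)
        exp = _collapse(exp, axis, keep, drop)
    return obs, exp


def _collapse(tab: np.ndarray, axis: int, keep: int, drop: int) -> np.ndarray:
    tab = np.swapaxes(tab, 0, axis)
    tab[keep] += tab[drop]
    tab = np.delete(tab, drop, axis=0)
    return np.swapaxes(tab, 0, axis)


def ld_cramers_v(responses: np.ndarray, blocks: list[Block],
                 params: ParameterSet, *, model: str = "mgppm",
                 n_draws: int = 20000, seed: int = 0,
                 flag_threshold: float = 0.3,
                 min_expected: float = 1.0) -> pd.DataFrame:
    """Pairwise local-dependence screen via Pearson chi-square / Cramer's V.

    For every block pair, the observed joint response table is compared to
    the model-implied table (trait-distribution integration at the supplied
    parameters) with Pearson X2; ``V = sqrt(X2 / (N (min(r, c) - 1)))``,
    clipped to [0, 1].  Pairs with ``V`` above ``flag_threshold`` are
    flagged as strongly locally dependent.  Sparse cells are merged by the
    documented smallest-margin rule before X2.
    """
    codes0 = np.asarray(responses, dtype=int) - 1
    n = codes0.shape[0]
    engines = make_engines(blocks, model)
    sizes = [e.n_responses for e in engines]
    obs_m, obs_j = _observed_tables(responses, sizes)
    _, exp_j = model_implied_tables(blocks, params, model=model,
                                    n_draws=n_draws, seed=seed)
    rows = []
    for (i, j), exp in exp_j.items():
        obs, exp2 = _merge_sparse(obs_j[(i, j)], exp, n, min_expected)
        x2 = n * np.sum((obs - exp2) ** 2 / np.maximum(exp2, 1e-12))
        k = min(obs.shape) - 1
        v = float(np.clip(np.sqrt(x2 / (n * max(k, 1))), 0.0, 1.0))
        rows.append({
            "block_i": blocks[i].block_id, "block_j": blocks[j].block_id,
            "x2": float(x2), "cramers_v": v, "flag": v > flag_threshold,
        })
    return pd.DataFrame(rows)


def item_fit_z(responses: np.ndarray, blocks: list[Block],
               params: ParameterSet, scores: ScoreResult,
               *, model: str = "mgppm",
               flag_threshold: float = -1.64) -> pd.DataFrame:
    """Standardized item log-likelihood fit statistic (lower one-sided).

    For item ``j``, ``L_j = sum_i log P(x_ij | theta_hat_i)`` is compared
    to its model-implied mean and variance at the same trait estimates:
    ``z_j = (L_j - E[L_j]) / sqrt(Var[L_j])``.  Structural misfit makes
    observed responses less likely than the model expects, driving ``z``
    negative; items with ``z`` below ``flag_threshold`` are flagged.
    """
    codes0 = np.asarray(responses, dtype=int) - 1
    engines = make_engines(blocks, model)
    rows = []
    for j, (b, eng) in enumerate(zip(blocks, engines)):
        U = utilities(b, scores.theta, params.slopes[j], params.intercepts[j])
        L = eng.log_response_probs(U)                   # (n, M)
        P = np.exp(L)
        obs = L[np.arange(L.shape[0]), codes0[:, j]].sum()
        mean_i = np.sum(P * L, axis=1)
        var_i = np.sum(P * L ** 2, axis=1) - mean_i ** 2
        var = var_i.sum()
        if var <= 1e-12:
            rows.append({"block": b.block_id, "z": np.nan, "flag": False})
            continue
        z = float((obs - mean_i.sum()) / np.sqrt(var))
        rows.append({"block": b.block_id, "z": z, "flag": z < flag_threshold})
    return pd.DataFrame(rows)


def srmsr(responses: np.ndarray, blocks: list[Block], params: ParameterSet,
          *, model: str = "mgppm", n_draws: int = 20000, seed: int = 0) -> float:
    """Standardized root mean squared residual over pattern margins.

    Root mean square of ``(p_obs - p_exp) / sqrt(p_exp (1 - p_exp))`` over
    all univariate pattern margins and all bivariate cross-table cells,
    with model-implied proportions from trait-distribution integration.
    """
    engines = make_engines(blocks, model)
    sizes = [e.n_responses for e in engines]
    obs_m, obs_j = _observed_tables(responses, sizes)
    exp_m, exp_j = model_implied_tables(blocks, params, model=model,
                                        n_draws=n_draws, seed=seed)
    res = []
    for o, e in zip(obs_m, exp_m):
        denom = np.sqrt(np.maximum(e * (1.0 - e), 1e-12))
        res.append(((o - e) / denom).ravel())
    for key in obs_j:
        e = exp_j[key]
        denom = np.sqrt(np.maximum(e * (1.0 - e), 1e-12))
        res.append(((obs_j[key] - e) / denom).ravel())
    allres = np.concatenate(res)
    return float(np.sqrt(np.mean(allres ** 2)))


def expected_item_trait_score(block: Block, params: ParameterSet,
                              focal_statement: int, *,
                              slopes: np.ndarray | None = None,
                              intercepts: np.ndarray | None = None,
                              n_points: int = 31,
                              trait_range: tuple[float, float] = (-3.0, 3.0)
                              ) -> tuple[np.ndarray, np.ndarray]:
    """Item trait characteristic curve of a focal statement.

    At each of ``n_points`` equally spaced focal-trait values, returns the
    expectation of the focal statement's rank score (``B-1`` down to 0)
    under the pattern probabilities, averaging the non-focal traits with
    normalized multivariate-normal weights on the same grid.  Returns
    ``(grid, curve)``.
    """
    from .model import pattern_log_probabilities
    B = block.size
    traits = block.traits
    if len(set(traits.tolist())) != B:
        raise ValueError("trait characteristic curves require distinct traits per block")
    pts = np.linspace(*trait_range, n_points)
    mesh = np.meshgrid(*([pts] * B), indexing="ij")
    sub = np.column_stack([m.ravel() for m in mesh])      # (n_points**B, B) block-trait space
    Rsub = params.R[np.ix_(traits, traits)]
    logw = mvn_logpdf(sub, Rsub)
    theta = np.zeros((sub.shape[0], params.n_traits))
    theta[:, traits] = sub
    a = slopes if slopes is not None else block.slopes
    c = intercepts if intercepts is not None else block.intercepts
    L = pattern_log_probabilities(block, theta, a, c)
    S = block.score_matrix
    k = focal_statement - 1
    mean_score = np.exp(L) @ S[:, k]                      # (n_points**B,)
    mean_score = mean_score.reshape([n_points] * B)
    W = np.exp(logw).reshape([n_points] * B)
    axes = tuple(i for i in range(B) if i != k)
    num = np.sum(mean_score * W, axis=axes)
    den = np.sum(W, axis=axes)
    return pts, num / den


@dataclass
class ComparisonReport:
    """Side-by-side fit of the pattern model and the sequential baseline."""

    fit_mgppm: FitResult
    fit_sequential: FitResult
    aic_difference: float          # AIC(sequential) - AIC(mgppm)
    bic_difference: float
    score_correlations: np.ndarray   # per trait, across persons
    reliability_mgppm: np.ndarray
    reliability_sequential: np.ndarray
    scores_mgppm: ScoreResult = None
    scores_sequential: ScoreResult = None


def compare_models(responses: np.ndarray, blocks: list[Block],
                   config: EMConfig | None = None,
                   config_sequential: EMConfig | None = None) -> ComparisonReport:
    """Fit both models on identical response codings and compare.

    Both models are fitted with the same marginal-maximum-likelihood
    machinery and have identical free-parameter counts, so the AIC
    difference equals the BIC difference.  MAP trait scores under each
    fitted model are correlated per trait across persons.
    """
    import dataclasses
    cfg_m = config or EMConfig()
    cfg_m = dataclasses.replace(cfg_m, model="mgppm")
    cfg_s = config_sequential or dataclasses.replace(cfg_m, model="sequential",
                                                     seed=cfg_m.seed + 1)
    fit_m = fit(responses, blocks, cfg_m)
    fit_s = fit(responses, blocks, cfg_s)
    sc_m = map_score(responses, blocks, fit_m.params, model="mgppm")
    sc_s = map_score(responses, blocks, fit_s.params, model="sequential")
    D = fit_m.params.n_traits
    cors = np.array([
        np.corrcoef(sc_m.theta[:, d], sc_s.theta[:, d])[0, 1] for d in range(D)
    ])
    return ComparisonReport(
        fit_mgppm=fit_m, fit_sequential=fit_s,
        aic_difference=fit_s.aic - fit_m.aic,
        bic_difference=fit_s.bic - fit_m.bic,
        score_correlations=cors,
        reliability_mgppm=empirical_reliability(sc_m),
        reliability_sequential=empirical_reliability(sc_s),
        scores_mgppm=sc_m, scores_sequential=sc_s,
    )
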