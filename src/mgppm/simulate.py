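"""Synthetic forced-choice study generator.

Emulates a parameter-recovery study for correlated latent traits measured
by forced-choice blocks: 1000 test takers, 5 standard-normal traits with a
fixed heterogeneous correlation matrix, 12 statements per trait assembled
into 20 triplets or 15 tetrads, slope magnitudes lognormal with natural-
scale mean 0.64 / 1.28 / 2.0 (low / medium / high) and natural-scale SD
0.29, intercepts Normal(-0.05, 0.54) with the first intercept per block
fixed at 0, and same- versus mixed-keyed-direction designs.  All defaults
can be overridden for arbitrary user designs.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np

from .blocks import Block, InvalidBlockError, Statement
from .model import PatternEngine, utilities
from .params import ParameterSet

__all__ = [
    "SLOPE_LEVELS",
    "SLOPE_SD",
    "INTERCEPT_MEAN",
    "INTERCEPT_SD",
    "SimulationCondition",
    "SimulatedStudy",
    "default_correlations",
    "build_design",
    "apply_keyed_directions",
    "draw_item_parameters",
    "draw_thetas",
    "simulate_responses",
    "simulate_condition",
    "lognormal_log_params",
]

SLOPE_LEVELS = {"low": 0.64, "medium": 1.28, "high": 2.0}
SLOPE_SD = 0.29
INTERCEPT_MEAN = -0.05
INTERCEPT_SD = 0.54


@dataclass
class SimulationCondition:
    """One cell of the crossed slope-level x keyed-direction design."""

    slope_level: str = "medium"          # low | medium | high
    direction: str = "mixed"             # same | mixed
    item_format: str = "triplet"         # triplet | tetrad
    n_persons: int = 1000
    seed: int = 0

    @property
    def slope_mean(self) -> float:
        return SLOPE_LEVELS[self.slope_level]

    @property
    def block_size(self) -> int:
        return {"triplet": 3, "tetrad": 4}[self.item_format]


@dataclass
class SimulatedStudy:
    """A simulated dataset with its generating truth."""

    blocks: list[Block]
    params: ParameterSet
    thetas: np.ndarray           # (n_persons, D)
    responses: np.ndarray        # (n_persons, n_blocks) 1-based codes
    condition: SimulationCondition | None = None


def lognormal_log_params(mean: float, sd: float) -> tuple[float, float]:
    """Log-scale (mu, sigma) of a lognormal with given natural-scale moments."""
    sigma2 = math.log1p((sd / mean) ** 2)
    return math.log(mean) - sigma2 / 2.0, math.sqrt(sigma2)


def default_correlations(n_traits: int = 5) -> np.ndarray:
    """Default heterogeneous positive-definite intertrait correlations.

    For 5 traits the 10 off-diagonals take the values 0.10, 0.15, ..., 0.55,
    arranged in a banded decaying pattern (larger correlations between
    adjacent traits) that is verifiably positive definite.  Heterogeneity
    keeps correlation-recovery summaries (correlation with true values)
    well defined.
    """
    if n_traits == 1:
        return np.eye(1)
    n_off = n_traits * (n_traits - 1) // 2
    vals = 0.55 - 0.05 * np.arange(n_off)
    if vals.min() <= 0.0:
        vals = np.linspace(0.55, 0.05, n_off)
    R = np.eye(n_traits)
    pairs = sorted(
        itertools.combinations(range(n_traits), 2),
        key=lambda ij: (ij[1] - ij[0], ij[0]),
    )
    for (i, j), v in zip(pairs, vals):
        R[i, j] = R[j, i] = v
    if np.linalg.eigvalsh(R).min() <= 0:
        raise ValueError("default correlation construction is not positive definite")
    return R


def build_design(n_traits: int = 5, statements_per_trait: int = 12,
                 block_size: int = 3) -> list[Block]:
    """Assemble blocks from repeated trait combinations.

    Every size-``block_size`` combination of the traits is repeated equally
    often, so each trait ends up on exactly ``statements_per_trait``
    statements (20 triplets or 15 tetrads for 5 traits with 12 each).
    Statements start positively keyed with unit slopes; apply a keyed-
    direction scheme and draw parameters separately.
    """
    total = n_traits * statements_per_trait
    if total % block_size != 0:
        raise InvalidBlockError(
            f"{n_traits} traits x {statements_per_trait} statements "
            f"not divisible into blocks of {block_size}"
        )
    n_blocks = total // block_size
    if block_size > n_traits:
        # fewer traits than statements per block: deal traits round-robin
        blocks, counter = [], 0
        for bid in range(1, n_blocks + 1):
            stmts = []
            for k in range(block_size):
                stmts.append(Statement(statement_id=k + 1, trait=counter % n_traits))
                counter += 1
            blocks.append(Block(block_id=bid, statements=stmts))
        return blocks
    combos = list(itertools.combinations(range(n_traits), block_size))
    if n_blocks % len(combos) != 0:
        raise InvalidBlockError(
            f"{n_blocks} blocks cannot repeat the {len(combos)} trait combinations equally"
        )
    reps = n_blocks // len(combos)
    blocks = []
    bid = 1
    for _ in range(reps):
        for combo in combos:
            stmts = [Statement(statement_id=k + 1, trait=t) for k, t in enumerate(combo)]
            blocks.append(Block(block_id=bid, statements=stmts))
            bid += 1
    return blocks


def _same_direction_signs(blocks: list[Block]) -> list[np.ndarray]:
    """All-positive first half (rounded up), all-negative second half."""
    n_pos = math.ceil(len(blocks) / 2)
    return [
        np.full(b.size, 1 if j < n_pos else -1, dtype=int)
        for j, b in enumerate(blocks)
    ]


def _mixed_direction_signs(blocks: list[Block]) -> list[np.ndarray]:
    """Flip keyed directions per the mixed-direction design.

    Triplets: one statement flipped in half the items, balanced so that five
    positive and five negative items each get one flip and each trait is
    flipped once within each group.  Tetrads: the last two statements
    flipped in items 1-3 and 12-15 (1-based), i.e. 7 of the 15 items.
    """
    signs = _same_direction_signs(blocks)
    B = blocks[0].size
    if B == 3:
        n_traits = max(b.traits.max() for b in blocks) + 1
        n_pos = math.ceil(len(blocks) / 2)
        for group in (range(0, n_pos), range(n_pos, len(blocks))):
            needed = set(range(n_traits))
            for j in group:
                if not needed:
                    break
                for k, t in enumerate(blocks[j].traits):
                    if t in needed:
                        signs[j][k] *= -1
                        needed.discard(int(t))
                        break
    elif B == 4:
        flip = set(range(0, 3)) | set(range(11, len(blocks)))
        for j in flip:
            signs[j][-2:] *= -1
    else:
        raise InvalidBlockError(f"no mixed-direction scheme defined for block size {B}")
    return signs


def apply_keyed_directions(blocks: list[Block], direction: str) -> list[Block]:
    """Return blocks with statement keyed signs set for a condition."""
    signs = _same_direction_signs(blocks) if direction == "same" \
        else _mixed_direction_signs(blocks)
    out = []
    for b, s in zip(blocks, signs):
        stmts = [
            Statement(st.statement_id, st.trait, slope=float(sig), intercept=0.0)
            for st, sig in zip(b.statements, s)
        ]
        out.append(Block(b.block_id, stmts, fmt=b.fmt, n_categories=b.n_categories))
    return out


def draw_item_parameters(blocks: list[Block], condition: SimulationCondition,
                         rng: np.random.Generator | int | None = None,
                         R: np.ndarray | None = None) -> ParameterSet:
    """Draw slopes and intercepts for a design under a study condition.

    Slope magnitudes are lognormal with natural-scale mean equal to the
    condition's slope level and natural-scale SD 0.29 (moment-matched
    log-scale parameters), signed by the blocks' keyed directions.
    Intercepts are Normal(-0.05, 0.54) with the first per block reset to 0
    for identification.
    """
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    mu, sigma = lognormal_log_params(condition.slope_mean, SLOPE_SD)
    slopes, intercepts = [], []
    for b in blocks:
        mag = rng.lognormal(mu, sigma, size=b.size)
        slopes.append(mag * b.keyed_signs)
        c = rng.normal(INTERCEPT_MEAN, INTERCEPT_SD, size=b.size)
        c[0] = 0.0
        intercepts.append(c)
    n_traits = int(max(b.traits.max() for b in blocks)) + 1
    if R is None:
        R = default_correlations(n_traits)
    return ParameterSet(slopes, intercepts, np.asarray(R, dtype=float))


def draw_thetas(n_persons: int, R: np.ndarray,
                rng: np.random.Generator | int | None = None) -> np.ndarray:
    """IID draws from the standard multivariate normal trait population."""
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    L = np.linalg.cholesky(np.asarray(R, dtype=float))
    Z = rng.standard_normal((n_persons, R.shape[0]))
    return Z @ L.T


def simulate_responses(blocks: list[Block], params: ParameterSet,
                       thetas: np.ndarray,
                       rng: np.random.Generator | int | None = None) -> np.ndarray:
    """Sample one response code per person and block, shape (n, J), 1-based.

    Codes index each block's observable response space (ranking-pattern
    codes for RANK, statement ids for PICK, most/least pair codes for MOLE,
    rating-vector codes for HFCL).
    """
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    thetas = np.asarray(thetas, dtype=float)
    out = np.empty((thetas.shape[0], len(blocks)), dtype=int)
    for j, b in enumerate(blocks):
        U = utilities(b, thetas, params.slopes[j], params.intercepts[j])
        out[:, j] = PatternEngine(b).sample(U, rng) + 1
    return out


def simulate_condition(condition: SimulationCondition,
                       R: np.ndarray | None = None,
                       n_traits: int = 5,
                       statements_per_trait: int = 12) -> SimulatedStudy:
    """Generate one full replicate dataset for a study condition.

    Item and person parameters are redrawn on every call; pass distinct
    seeds for distinct replicates.
    """
    rng = np.random.default_rng(condition.seed)
    blocks = build_design(n_traits, statements_per_trait, condition.block_size)
    blocks = apply_keyed_directions(blocks, condition.direction)
    params = draw_item_parameters(blocks, condition, rng, R=R)
    thetas = draw_thetas(condition.n_persons, params.R, rng)
    responses = simulate_responses(blocks, params, thetas, rng)
    return SimulatedStudy(blocks, params, thetas, responses, condition)
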