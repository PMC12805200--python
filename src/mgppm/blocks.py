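"""Forced-choice blocks and their ranking-pattern spaces.

A forced-choice *block* (item) presents ``B`` statements that a respondent
must order from most to least descriptive of themselves, with no ties.  Each
statement measures one latent trait through a linear utility
``a_k * theta_{trait(k)} + c_k`` (slope ``a_k``, intercept ``c_k``).  The
observable response is a *ranking pattern* — a permutation of the block's
statements — coded as an integer.

Besides full rankings (RANK) a block may be administered in reduced formats:
PICK (choose the most descriptive statement), MOLE (choose the most and the
least), GRADED (a pair rated on a single graded scale), and HFCL (each
statement rated on a Likert scale with ties forbidden).  All formats share
the same underlying pattern space; reduced formats observe a coarsening of
it.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from functools import lru_cache

import numpy as np

__all__ = [
    "InvalidBlockError",
    "InvalidResponseError",
    "Statement",
    "Block",
    "enumerate_patterns",
    "pattern_code",
    "rank_score_matrix",
    "hfcl_pattern_space",
    "graded_score_matrix",
]


class InvalidBlockError(ValueError):
    """A block definition violates a structural requirement."""


class InvalidResponseError(ValueError):
    """A response code is outside the block's legal response space."""


@lru_cache(maxsize=None)
def enumerate_patterns(block_size: int) -> tuple[tuple[int, ...], ...]:
    """All ``B!`` ranking patterns of a block, in lexicographic order.

    Each pattern is a tuple of 1-based statement ids ordered from rank 1
    (most favourable) to rank ``B``.  Codes are 1-based positions in this
    list, so code 1 for a triplet is the pattern ``(1, 2, 3)``.
    """
    if block_size < 2:
        raise InvalidBlockError(f"block size must be >= 2, got {block_size}")
    return tuple(itertools.permutations(range(1, block_size + 1)))


@lru_cache(maxsize=None)
def _pattern_index(block_size: int) -> dict[tuple[int, ...], int]:
    return {p: i for i, p in enumerate(enumerate_patterns(block_size))}


def pattern_code(order: tuple[int, ...]) -> int:
    """1-based canonical code of a ranking pattern."""
    idx = _pattern_index(len(order))
    try:
        return idx[tuple(order)] + 1
    except KeyError:
        raise InvalidResponseError(f"{order!r} is not a permutation of 1..{len(order)}")


@lru_cache(maxsize=None)
def rank_score_matrix(block_size: int) -> np.ndarray:
    """Score matrix ``S`` of the primary rank scoring scheme.

    ``S[j, k-1] = B - rank of statement k in pattern j``: the least
    favourable statement scores 0 and every one-rank advancement adds 1.
    Shape ``(B!, B)``; read-only.
    """
    patterns = enumerate_patterns(block_size)
    S = np.zeros((len(patterns), block_size))
    for j, pat in enumerate(patterns):
        for rank, sid in enumerate(pat, start=1):
            S[j, sid - 1] = block_size - rank
    S.flags.writeable = False
    return S


@lru_cache(maxsize=None)
def hfcl_pattern_space(block_size: int, n_categories: int) -> tuple[tuple[int, ...], ...]:
    """Legal rating vectors of a hybrid forced-choice/Likert block.

    Every vector in ``{1..C}^B`` with pairwise-distinct entries, in
    lexicographic order.  A vector's statement scores are ``rating - 1``.
    """
    if block_size < 2:
        raise InvalidBlockError(f"block size must be >= 2, got {block_size}")
    if n_categories < block_size:
        raise InvalidBlockError(
            f"HFCL needs at least as many categories ({n_categories}) as statements ({block_size})"
        )
    return tuple(itertools.permutations(range(1, n_categories + 1), block_size))


def graded_score_matrix(n_categories: int) -> np.ndarray:
    """Default scoring for a graded pair with ``C`` categories.

    Category ``g`` (1-based) maps to statement scores ``(C - g, g - 1)``:
    the lowest category fully favours statement 1, the highest fully
    favours statement 2.  Override ``Block.score_matrix`` for other schemes.
    """
    g = np.arange(1, n_categories + 1)
    return np.column_stack([n_categories - g, g - 1]).astype(float)


@dataclass
class Statement:
    """One statement in a block: its trait, slope and intercept.

    ``trait`` is a 0-based trait index.  The keyed direction (positive or
    negative wording) is the sign of the slope.
    """

    statement_id: int
    trait: int
    slope: float = 1.0
    intercept: float = 0.0

    @property
    def keyed_sign(self) -> int:
        return 1 if self.slope >= 0 else -1


@dataclass
class Block:
    """A forced-choice block: ordered statements plus format and scheme.

    The first statement's intercept is conventionally fixed at 0 for
    identification (``free_intercepts`` marks the estimable ones).  For the
    ``alternative`` scheme variant, ``rank_intercepts[k, r-1]`` is the
    rank-specific intercept of statement ``k+1`` at rank ``r`` (ranks
    ``1..B-1``; the last rank contributes 0); statement 1's rank intercepts
    are fixed at 0.
    """

    block_id: int | str
    statements: list[Statement]
    fmt: str = "RANK"
    n_categories: int | None = None
    variant: str = "primary"
    rank_intercepts: np.ndarray | None = None
    custom_score_matrix: np.ndarray | None = None

    def __post_init__(self) -> None:
        if len(self.statements) < 2:
            raise InvalidBlockError("a block needs at least two statements")
        if self.fmt not in ("RANK", "PICK", "MOLE", "GRADED", "HFCL"):
            raise InvalidBlockError(f"unknown format {self.fmt!r}")
        if self.fmt == "GRADED" and len(self.statements) != 2:
            raise InvalidBlockError("GRADED format applies to pairs only")
        if self.fmt in ("GRADED", "HFCL") and self.n_categories is None:
            raise InvalidBlockError(f"{self.fmt} format requires n_categories")
        if self.variant not in ("primary", "alternative"):
            raise InvalidBlockError(f"unknown scheme variant {self.variant!r}")
        if self.variant == "alternative" and self.rank_intercepts is None:
            B = len(self.statements)
            self.rank_intercepts = np.zeros((B, B - 1))

    # -- structure -----------------------------------------------------
    @property
    def size(self) -> int:
        return len(self.statements)

    @property
    def traits(self) -> np.ndarray:
        return np.array([s.trait for s in self.statements])

    @property
    def slopes(self) -> np.ndarray:
        return np.array([s.slope for s in self.statements])

    @property
    def intercepts(self) -> np.ndarray:
        return np.array([s.intercept for s in self.statements])

    @property
    def keyed_signs(self) -> np.ndarray:
        return np.array([s.keyed_sign for s in self.statements])

    @property
    def free_intercepts(self) -> np.ndarray:
        """Boolean mask of estimable intercepts (statement 1 fixed at 0)."""
        mask = np.ones(self.size, dtype=bool)
        mask[0] = False
        return mask

    # -- pattern space -------------------------------------------------
    @property
    def patterns(self) -> tuple[tuple[int, ...], ...]:
        """Labels of the underlying pattern space.

        Ranking permutations for RANK/PICK/MOLE, category indices for
        GRADED, rating vectors for HFCL.
        """
        if self.fmt in ("RANK", "PICK", "MOLE"):
            return enumerate_patterns(self.size)
        if self.fmt == "GRADED":
            return tuple((g,) for g in range(1, self.n_categories + 1))
        return hfcl_pattern_space(self.size, self.n_categories)

    @property
    def n_patterns(self) -> int:
        return len(self.patterns)

    @property
    def score_matrix(self) -> np.ndarray:
        """Statement-score matrix ``S`` of shape ``(n_patterns, B)``."""
        if self.custom_score_matrix is not None:
            return np.asarray(self.custom_score_matrix, dtype=float)
        if self.fmt in ("RANK", "PICK", "MOLE"):
            return rank_score_matrix(self.size)
        if self.fmt == "GRADED":
            return graded_score_matrix(self.n_categories)
        return np.array(hfcl_pattern_space(self.size, self.n_categories), dtype=float) - 1.0

    # -- observed-response space ----------------------------------------
    @property
    def response_labels(self) -> list:
        """Labels of observable responses, aligned with ``response_groups``."""
        if self.fmt == "PICK":
            return list(range(1, self.size + 1))
        if self.fmt == "MOLE":
            return [
                (m, l)
                for m in range(1, self.size + 1)
                for l in range(1, self.size + 1)
                if m != l
            ]
        return list(range(1, self.n_patterns + 1))

    @property
    def response_groups(self) -> list[np.ndarray]:
        """For each observable response, indices of compatible patterns.

        RANK/GRADED/HFCL responses identify a single pattern; PICK and MOLE
        responses are compatible with every full ranking they do not
        contradict.
        """
        pats = self.patterns
        if self.fmt == "PICK":
            return [
                np.array([j for j, p in enumerate(pats) if p[0] == sid])
                for sid in range(1, self.size + 1)
            ]
        if self.fmt == "MOLE":
            return [
                np.array([j for j, p in enumerate(pats) if p[0] == m and p[-1] == l])
                for (m, l) in self.response_labels
            ]
        return [np.array([j]) for j in range(self.n_patterns)]

    @property
    def n_responses(self) -> int:
        return len(self.response_labels)

    def validate_code(self, code: int) -> None:
        """Raise :class:`InvalidResponseError` unless ``code`` is legal."""
        if not (1 <= int(code) <= self.n_responses):
            raise InvalidResponseError(
                f"block {self.block_id}: response code {code} outside 1..{self.n_responses}"
            )
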