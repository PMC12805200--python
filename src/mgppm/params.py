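"""Parameter containers shared by simulation, estimation, and scoring."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .blocks import Block

__all__ = ["ParameterSet", "nearest_correlation"]


def nearest_correlation(R: np.ndarray, eig_floor: float = 1e-6) -> np.ndarray:
    """Project a symmetric matrix to the positive-definite correlation cone.

    Symmetrizes, clips eigenvalues at ``eig_floor``, and rescales to unit
    diagonal.  Used to keep intertrait-correlation updates valid.
    """
    R = 0.5 * (np.asarray(R, dtype=float) + np.asarray(R, dtype=float).T)
    w, V = np.linalg.eigh(R)
    if w.min() < eig_floor:
        w = np.clip(w, eig_floor, None)
        R = (V * w) @ V.T
    d = np.sqrt(np.diag(R))
    R = R / np.outer(d, d)
    np.fill_diagonal(R, 1.0)
    return R


@dataclass
class ParameterSet:
    """Slopes and intercepts for every block plus the intertrait correlations.

    ``slopes[j]`` and ``intercepts[j]`` align with the statements of block
    ``j`` in the accompanying design; intercepts marked fixed by the block
    (the first statement's) are stored but never counted as free.  ``R`` is
    the D x D correlation matrix of the standard multivariate normal trait
    population.
    """

    slopes: list[np.ndarray]
    intercepts: list[np.ndarray]
    R: np.ndarray

    @property
    def n_traits(self) -> int:
        return self.R.shape[0]

    @classmethod
    def from_blocks(cls, blocks: list[Block], R: np.ndarray) -> "ParameterSet":
        return cls(
            slopes=[b.slopes.astype(float) for b in blocks],
            intercepts=[b.intercepts.astype(float) for b in blocks],
            R=np.asarray(R, dtype=float),
        )

    def copy(self) -> "ParameterSet":
        return ParameterSet(
            [a.copy() for a in self.slopes],
            [c.copy() for c in self.intercepts],
            self.R.copy(),
        )

    # -- free-parameter bookkeeping ------------------------------------
    def item_vector(self, blocks: list[Block]) -> np.ndarray:
        """Free item parameters (all slopes, then free intercepts, per block)."""
        parts = []
        for j, b in enumerate(blocks):
            parts.append(self.slopes[j])
            parts.append(self.intercepts[j][b.free_intercepts])
        return np.concatenate(parts)

    def set_item_vector(self, blocks: list[Block], vec: np.ndarray) -> None:
        pos = 0
        for j, b in enumerate(blocks):
            B = b.size
            self.slopes[j] = np.array(vec[pos:pos + B], dtype=float)
            pos += B
            free = b.free_intercepts
            c = np.zeros(B)
            c[free] = vec[pos:pos + free.sum()]
            self.intercepts[j] = c
            pos += int(free.sum())

    def item_labels(self, blocks: list[Block]) -> list[str]:
        labels = []
        for j, b in enumerate(blocks):
            for k in range(b.size):
                labels.append(f"block{b.block_id}_a{k + 1}")
            for k in np.flatnonzero(b.free_intercepts):
                labels.append(f"block{b.block_id}_c{k + 1}")
        return labels

    def n_free(self, blocks: list[Block], include_correlations: bool = True) -> int:
        p = sum(b.size + int(b.free_intercepts.sum()) for b in blocks)
        if include_correlations:
            D = self.n_traits
            p += D * (D - 1) // 2
        return p

    def offdiag(self) -> np.ndarray:
        """The D(D-1)/2 upper-triangular intertrait correlations."""
        iu = np.triu_indices(self.n_traits, k=1)
        return self.R[iu]
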