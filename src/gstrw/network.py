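"""Similarity-network construction and global (whole-network) similarity.

The miRNA network fuses functional similarity with family membership:
``SIM(i, j) = SM(i, j) * (1 + SMfam(i, j))``, so same-family pairs score
exactly twice their functional similarity. Global similarity between an
entity and the rest of its network is the Laplacian-score smoothing

    g = (1 - alpha) * (I - alpha * S_bar)^{-1} * e,

where ``S_bar`` is the column-normalized similarity matrix, ``e`` the unit
indicator of the query entity, and ``alpha`` in (0, 1) balances network
propagation against fidelity to the query. Stacking the solutions for
every unit seed gives the global-similarity matrix computed here in one
linear solve.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_formats import FamilyTable, LabeledSquareMatrix

__all__ = [
    "fuse_mirna_similarity",
    "column_normalize",
    "global_similarity",
    "fixed_point_oracle",
    "GlobalSimilarity",
]


@dataclass
class GlobalSimilarity:
    """Global-similarity matrices of the two networks.

    ``sim_d`` is over diseases, ``sim_m`` over miRNAs; column j of each is
    the smoothed profile of entity j.
    """

    sim_d: LabeledSquareMatrix
    sim_m: LabeledSquareMatrix


def fuse_mirna_similarity(sm: LabeledSquareMatrix, fam: FamilyTable) -> LabeledSquareMatrix:
    """Boost same-family miRNA pairs: SIM = SM * (1 + SMfam).

    The family indicator has zero diagonal, so self-similarities are
    untouched; miRNAs without a family assignment keep their functional
    similarities unchanged. Entries of the fused matrix may exceed 1 (at
    most 2): downstream column normalization absorbs the scale.
    """
    sm.validate_similarity()
    fam_matrix = fam.family_matrix(sm.labels)
    return LabeledSquareMatrix(list(sm.labels), sm.values * (1.0 + fam_matrix))


def column_normalize(m: LabeledSquareMatrix) -> LabeledSquareMatrix:
    """Divide every nonzero column by its sum; zero columns stay zero."""
    values = np.asarray(m.values, dtype=float)
    if np.any(values < 0):
        raise ValueError("negative entries cannot be column-normalized")
    sums = values.sum(axis=0)
    safe = np.where(sums > 0, sums, 1.0)
    return LabeledSquareMatrix(list(m.labels), values / safe)


def global_similarity(s: LabeledSquareMatrix, balance: float) -> LabeledSquareMatrix:
    """Global-similarity matrix G = (1 - balance) * (I - balance * S_bar)^{-1}.

    Column j of G solves the smoothing problem for the unit seed of entity
    j. ``balance`` (alpha for the disease network, beta for the miRNA
    network) must lie strictly inside (0, 1); since S_bar is column
    sub-stochastic its spectral radius is at most 1, so the system is
    nonsingular for every such balance. Computed with a dense linear solve,
    never an explicit inverse.
    """
    if not 0.0 < balance < 1.0:
        raise ValueError(f"balance must be in (0, 1), got {balance}")
    s_bar = column_normalize(s)
    n = s_bar.n
    system = np.eye(n) - balance * s_bar.values
    g = (1.0 - balance) * np.linalg.solve(system, np.eye(n))
    if not np.all(np.isfinite(g)):
        raise ArithmeticError("global-similarity solve produced non-finite values")
    # Neumann series of a nonnegative matrix: tiny negatives are roundoff
    g[(g < 0) & (g > -1e-12)] = 0.0
    if np.any(g < 0):
        raise ArithmeticError("global-similarity solve produced negative values")
    return LabeledSquareMatrix(list(s.labels), g)


def fixed_point_oracle(
    s_bar: np.ndarray, seed_vector: np.ndarray, balance: float, tol: float = 1e-10
) -> np.ndarray:
    """Iterative reference for one global-similarity column (tests only).

    Iterates ``x <- balance * S_bar @ x + (1 - balance) * d`` to its fixed
    point, the same vector :func:`global_similarity` obtains by a direct
    solve.
    """
    s_bar = np.asarray(s_bar, dtype=float)
    d = (1.0 - balance) * np.asarray(seed_vector, dtype=float)
    x = d.copy()
    for _ in range(100_000):
        x_next = balance * (s_bar @ x) + d
        if np.sum(np.abs(x_next - x)) < tol:
            return x_next
        x = x_next
    raise ArithmeticError("fixed-point iteration did not converge")
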