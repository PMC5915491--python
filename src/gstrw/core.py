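"""The two-tier global-similarity random-walk predictor.

Given a fused miRNA similarity network SIM, a disease similarity network
SD and a binary association matrix A, the method scores every
(miRNA, disease) pair in four deterministic steps:

1. *Global similarity.* Laplacian-score smoothing of each network gives
   simM~ (miRNAs) and simD~ (diseases); column j is the whole-network
   similarity profile of entity j.
2. *Seed optimization.* The query disease's association vector is
   augmented with the similarity-weighted association vectors of the other
   diseases, ``D~_i = D_i + lam * sum_{j != i} simD~(d_i, d_j) * D_j``,
   so an orphan disease (all-zero D_i) still gets a usable seed borrowed
   from its phenotypic neighbours. miRNA seeds mirror this with weight
   ``eta`` on simM~.
3. *Restart random walk.* Each disease seed walks on the column-normalized
   miRNA network (restart gamma), each miRNA seed on the disease network
   (restart theta), iterating ``x <- (1 - r) * S_bar @ x + r * seed`` until
   the L1 change drops below ``tol``.
4. *Profile scoring and fusion.* A stationary vector is scored against
   every column of the corresponding global-similarity matrix by Pearson
   correlation, giving the miRNA-network tier F_m (disease x miRNA) and
   the disease-network tier F_d (miRNA x disease); the final score is
   ``F = w * F_m^T + (1 - w) * F_d``.

Everything is dense linear algebra on networks of 10^2-10^3 nodes; there
is no randomness anywhere in the predictor.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .io_formats import AssociationMatrix, LabeledSquareMatrix
from .network import column_normalize, global_similarity

__all__ = [
    "GstrwParams",
    "ScoreMatrix",
    "GstrwModel",
    "optimize_disease_seed",
    "optimize_mirna_seed",
    "random_walk_restart",
    "pearson_profile_scores",
    "predict",
]


@dataclass(frozen=True)
class GstrwParams:
    """All scalar knobs of the predictor.

    gamma, theta : restart probabilities of the disease-seed walk (on the
        miRNA network) and the miRNA-seed walk (on the disease network).
    alpha, beta : Laplacian balance factors of the disease and miRNA
        global-similarity smoothing.
    lam, eta : seed-optimization weights for disease and miRNA seeds.
    w : weight of the miRNA-network tier in the final fusion, in [0, 1].
    tol : L1 convergence threshold of the walks.
    max_iter : walk iteration cap.
    """

    gamma: float = 0.2
    theta: float = 0.2
    alpha: float = 0.8
    beta: float = 0.8
    lam: float = 0.2
    eta: float = 0.2
    w: float = 0.6
    tol: float = 1e-6
    max_iter: int = 1000

    def __post_init__(self) -> None:
        for name in ("gamma", "theta", "alpha", "beta"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must be in (0, 1), got {v}")
        for name in ("lam", "eta"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.w <= 1.0:
            raise ValueError(f"w must be in [0, 1], got {self.w}")
        if self.tol <= 0 or self.max_iter < 1:
            raise ValueError("tol must be positive and max_iter >= 1")

    def with_(self, **kwargs) -> "GstrwParams":
        return replace(self, **kwargs)


@dataclass
class ScoreMatrix:
    """Real-valued miRNA x disease (or disease x miRNA) score matrix."""

    row_labels: list[str]
    col_labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.row_labels), len(self.col_labels)):
            raise ValueError("score matrix shape does not match labels")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite scores")


# ---------------------------------------------------------------------------
# seed optimization
# ---------------------------------------------------------------------------

def _optimized_seeds(profiles: np.ndarray, global_sim: np.ndarray, weight: float) -> np.ndarray:
    """Optimized seed columns for every query at once.

    ``profiles`` holds one association profile per column (column i is the
    query entity's known-association indicator); the optimized seed adds
    ``weight * sum_{j != i} G[j, i] * profiles[:, j]``, reading the query's
    own global-similarity column and excluding the self term. Each nonzero
    seed is L1-normalized to a probability vector; all-zero seeds (fully
    orphan queries in an empty neighbourhood) are left zero.
    """
    boost = profiles @ global_sim - profiles * np.diag(global_sim)
    seeds = profiles + weight * boost
    sums = seeds.sum(axis=0)
    safe = np.where(sums > 0, sums, 1.0)
    return seeds / safe


def optimize_disease_seed(
    a: AssociationMatrix, sim_d_global: LabeledSquareMatrix, lam: float, disease_index: int
) -> np.ndarray:
    """Optimized walk seed of one disease, a probability vector over miRNAs.

    ``D~_i = D_i + lam * sum_{j != i} simD~(d_i, d_j) * D_j`` followed by
    L1 normalization; simD~(d_i, d_j) is read from disease i's own global
    profile (column i of simD~). Returns the all-zero vector when neither
    the disease nor any similar disease has known miRNAs.
    """
    if not 0 <= disease_index < a.n_disease:
        raise IndexError(f"disease_index {disease_index} out of range")
    seeds = _optimized_seeds(a.values, sim_d_global.values, lam)
    return seeds[:, disease_index]


def optimize_mirna_seed(
    a: AssociationMatrix, sim_m_global: LabeledSquareMatrix, eta: float, mirna_index: int
) -> np.ndarray:
    """Optimized walk seed of one miRNA, a probability vector over diseases.

    Mirror of :func:`optimize_disease_seed`:
    ``M~_j = M_j + eta * sum_{i != j} simM~(m_j, m_i) * M_i``.
    """
    if not 0 <= mirna_index < a.n_mirna:
        raise IndexError(f"mirna_index {mirna_index} out of range")
    seeds = _optimized_seeds(a.values.T, sim_m_global.values, eta)
    return seeds[:, mirna_index]


# ---------------------------------------------------------------------------
# restart random walk
# ---------------------------------------------------------------------------

def random_walk_restart(
    s_bar: np.ndarray | LabeledSquareMatrix,
    seed: np.ndarray,
    restart: float,
    tol: float = 1e-6,
    max_iter: int = 1000,
) -> np.ndarray:
    """Stationary vector of ``x <- (1 - restart) * S_bar @ x + restart * seed``.

    ``seed`` may be a single probability vector or a matrix whose columns
    are independent walks (all iterated together). Iteration starts at the
    seed and stops when the L1 change of every column falls below ``tol``,
    the stability rule of the method (threshold 1e-6 by default). All-zero
    seed columns stay identically zero. Raises if ``max_iter`` is hit,
    reporting the last residual.
    """
    if isinstance(s_bar, LabeledSquareMatrix):
        s_bar = s_bar.values
    s_bar = np.asarray(s_bar, dtype=float)
    seed = np.asarray(seed, dtype=float)
    squeeze = seed.ndim == 1
    x = seed.reshape(-1, 1) if squeeze else seed.copy()
    sums = x.sum(axis=0)
    if not np.all((np.abs(sums - 1.0) < 1e-9) | (sums == 0.0)):
        raise ValueError("each seed column must sum to 1 or be all-zero")
    if not 0.0 < restart <= 1.0:
        raise ValueError(f"restart must be in (0, 1], got {restart}")
    carry = 1.0 - restart
    target = restart * x
    for _ in range(max_iter):
        x_next = carry * (s_bar @ x) + target
        residual = np.abs(x_next - x).sum(axis=0).max()
        x = x_next
        if residual < tol:
            return x[:, 0] if squeeze else x
    raise ArithmeticError(
        f"random walk did not converge in {max_iter} iterations (last L1 residual {residual:g})"
    )


# ---------------------------------------------------------------------------
# Pearson profile scoring
# ---------------------------------------------------------------------------

def _pearson_columns(stationary: np.ndarray, profiles: np.ndarray) -> np.ndarray:
    """Pearson correlation of each stationary column with each profile column.

    Returns a (walks x entities) matrix. Zero-variance columns on either
    side yield a correlation of 0 instead of NaN.
    """
    s = stationary - stationary.mean(axis=0)
    g = profiles - profiles.mean(axis=0)
    s_norm = np.linalg.norm(s, axis=0)
    g_norm = np.linalg.norm(g, axis=0)
    denom = np.outer(s_norm, g_norm)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = (s.T @ g) / denom
    corr[denom == 0] = 0.0
    return np.clip(corr, -1.0, 1.0)


def pearson_profile_scores(stationary: np.ndarray, global_sim: LabeledSquareMatrix) -> np.ndarray:
    """Score a stationary vector against every global-similarity profile.

    Entry k is the Pearson correlation between the walk's stationary
    distribution and column k of the global-similarity matrix; a constant
    vector on either side scores 0 by convention.
    """
    stationary = np.asarray(stationary, dtype=float)
    if stationary.shape != (global_sim.n,):
        raise ValueError(
            f"stationary length {stationary.shape} does not match matrix dimension {global_sim.n}"
        )
    return _pearson_columns(stationary.reshape(-1, 1), global_sim.values)[0]


# ---------------------------------------------------------------------------
# full pipeline
# ---------------------------------------------------------------------------

class GstrwModel:
    """Predictor with the association-independent pieces precomputed.

    The global-similarity matrices and the column-normalized walk networks
    depend only on SIM and SD, so they are built once and reused across
    the many association variants evaluation protocols run (leave-one-out
    folds, zeroed orphan columns, zeroed new-miRNA rows).
    """

    def __init__(
        self,
        sim_m_fused: LabeledSquareMatrix,
        sd: LabeledSquareMatrix,
        params: GstrwParams | None = None,
    ):
        self.params = params or GstrwParams()
        self.mirna_labels = list(sim_m_fused.labels)
        self.disease_labels = list(sd.labels)
        self.sim_d_global = global_similarity(sd, self.params.alpha)
        self.sim_m_global = global_similarity(sim_m_fused, self.params.beta)
        self.sim_bar = column_normalize(sim_m_fused).values  # miRNA walk network
        self.sd_bar = column_normalize(sd).values  # disease walk network

    def predict(self, a: AssociationMatrix) -> tuple[ScoreMatrix, ScoreMatrix, ScoreMatrix]:
        """Score every pair; returns (F, F_m, F_d).

        F_m is disease x miRNA (disease seeds walking the miRNA network),
        F_d is miRNA x disease (miRNA seeds walking the disease network),
        and F = w * F_m^T + (1 - w) * F_d is miRNA x disease.
        """
        if a.mirna_labels != self.mirna_labels or a.disease_labels != self.disease_labels:
            raise ValueError("association labels do not match the similarity networks")
        p = self.params

        # tier 1: disease seeds on the miRNA network
        disease_seeds = _optimized_seeds(a.values, self.sim_d_global.values, p.lam)
        stat_d = random_walk_restart(self.sim_bar, disease_seeds, p.gamma, p.tol, p.max_iter)
        f_m = _pearson_columns(stat_d, self.sim_m_global.values)  # disease x miRNA

        # tier 2: miRNA seeds on the disease network
        mirna_seeds = _optimized_seeds(a.values.T, self.sim_m_global.values, p.eta)
        stat_m = random_walk_restart(self.sd_bar, mirna_seeds, p.theta, p.tol, p.max_iter)
        f_d = _pearson_columns(stat_m, self.sim_d_global.values)  # miRNA x disease

        fused = p.w * f_m.T + (1.0 - p.w) * f_d
        return (
            ScoreMatrix(self.mirna_labels, self.disease_labels, fused),
            ScoreMatrix(self.disease_labels, self.mirna_labels, f_m),
            ScoreMatrix(self.mirna_labels, self.disease_labels, f_d),
        )


def predict(
    a: AssociationMatrix,
    sim_m_fused: LabeledSquareMatrix,
    sd: LabeledSquareMatrix,
    params: GstrwParams | None = None,
) -> tuple[ScoreMatrix, ScoreMatrix, ScoreMatrix]:
    """One-shot prediction: build the model and score every pair.

    See :class:`GstrwModel` for the returned (F, F_m, F_d) conventions.
    """
    return GstrwModel(sim_m_fused, sd, params).predict(a)
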