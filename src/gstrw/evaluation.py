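"""Evaluation protocols: leave-one-out, orphan-disease, and new-miRNA.

All three protocols hold out known associations, rerun the predictor, and
summarize how the held-out pairs rank against pairs that were never known.
Positives and negatives are always scored by the *same* fold model —
comparing scores produced by differently trained models would mix score
scales — and never-known pairs serve as the negative class. They are
unlabeled rather than verified negatives: the standard compromise in
association prediction, where experimentally confirmed non-associations
do not exist.

ROC and precision-recall curves are computed in-house by a full threshold
sweep; ties get Mann-Whitney half credit, so a constant predictor scores
an AUC of exactly 0.5 and the trapezoidal area under the ROC curve equals
the normalized U statistic ``P(s+ > s-) + 0.5 * P(s+ = s-)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import GstrwModel, GstrwParams
from .io_formats import AssociationMatrix, LabeledSquareMatrix

__all__ = [
    "EvalResult",
    "roc_auc",
    "precision_recall",
    "loocv",
    "orphan_disease_eval",
    "new_mirna_eval",
    "parameter_sweep",
]


@dataclass
class EvalResult:
    """Outcome of one evaluation protocol.

    ``per_query_ranks`` maps each held-out pair to its Mann-Whitney rank
    (1 = best, ties averaged) among the never-known candidates of its own
    disease column (miRNA row for the new-miRNA protocol), scored in the
    same fold; ``pool_sizes`` gives the size of that pool including the
    pair itself.
    """

    protocol: str
    roc_points: list[tuple[float, float]]
    auc: float
    pr_points: list[tuple[float, float]]
    per_query_ranks: dict[tuple[str, str], float]
    pool_sizes: dict[tuple[str, str], int]


# ---------------------------------------------------------------------------
# ROC / PR primitives
# ---------------------------------------------------------------------------

def _sweep_counts(pos: np.ndarray, neg: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """True/false positive counts at every distinct threshold, descending."""
    thresholds = np.unique(np.concatenate([pos, neg]))[::-1]
    pos_sorted = np.sort(pos)
    neg_sorted = np.sort(neg)
    # count of scores >= t, vectorized over descending thresholds
    tp = pos.size - np.searchsorted(pos_sorted, thresholds, side="left")
    fp = neg.size - np.searchsorted(neg_sorted, thresholds, side="left")
    return thresholds, tp, fp


def roc_auc(pos_scores, neg_scores) -> tuple[list[tuple[float, float]], float]:
    """ROC points and AUC from a full threshold sweep.

    One (FPR, TPR) point per distinct score, thresholding at "score >= t"
    with t descending, prefixed by (0, 0). Tied positive and negative
    scores fall on the same point, so the trapezoidal area gives each tie
    half credit.
    """
    pos = np.asarray(pos_scores, dtype=float).ravel()
    neg = np.asarray(neg_scores, dtype=float).ravel()
    if pos.size == 0 or neg.size == 0:
        raise ValueError("need at least one positive and one negative score")
    _, tp, fp = _sweep_counts(pos, neg)
    tpr = tp / pos.size
    fpr = fp / neg.size
    points = [(0.0, 0.0)] + list(zip(fpr.tolist(), tpr.tolist()))
    xs = np.array([p[0] for p in points])
    ys = np.array([p[1] for p in points])
    auc = float(np.trapezoid(ys, xs))
    return points, auc


def precision_recall(pos_scores, neg_scores) -> list[tuple[float, float]]:
    """(recall, precision) at every distinct threshold, best scores first."""
    pos = np.asarray(pos_scores, dtype=float).ravel()
    neg = np.asarray(neg_scores, dtype=float).ravel()
    if pos.size == 0 or neg.size == 0:
        raise ValueError("need at least one positive and one negative score")
    _, tp, fp = _sweep_counts(pos, neg)
    recall = tp / pos.size
    precision = tp / np.maximum(tp + fp, 1)
    return list(zip(recall.tolist(), precision.tolist()))


def _mann_whitney_rank(score: float, pool: np.ndarray) -> float:
    """Rank of ``score`` among competitors (1 = best, ties averaged)."""
    return 1.0 + float((pool > score).sum()) + 0.5 * float((pool == score).sum())


# ---------------------------------------------------------------------------
# shared fold machinery
# ---------------------------------------------------------------------------

def _assemble(
    protocol: str,
    positives: dict[tuple[str, str], float],
    negative_sets: list[np.ndarray],
    ranks: dict[tuple[str, str], float],
    pools: dict[tuple[str, str], int],
) -> EvalResult:
    pos_values = np.array(list(positives.values()))
    neg_values = np.concatenate(negative_sets)
    roc_points, auc = roc_auc(pos_values, neg_values)
    pr_points = precision_recall(pos_values, neg_values)
    return EvalResult(protocol, roc_points, auc, pr_points, ranks, pools)


def _run_protocol(
    protocol: str,
    a: AssociationMatrix,
    sim_m_fused: LabeledSquareMatrix,
    sd: LabeledSquareMatrix,
    params: GstrwParams | None,
    pooling: str,
    folds: list[tuple[list[tuple[int, int]], np.ndarray]],
    axis: int,
) -> EvalResult:
    """Run held-out folds and pool the comparisons.

    Each fold is (held-out cells, training matrix). For every fold the
    predictor is rerun on the training matrix; held-out cells become
    positives and the fold's never-known pairs become negatives —
    all of them under ``pooling="global"``, only those sharing the query's
    disease column (``axis=0``) or miRNA row (``axis=1``) under
    ``pooling="per_query"``. Per-query ranks are always within the query's
    own column/row.
    """
    if pooling not in ("global", "per_query"):
        raise ValueError(f"unknown pooling mode {pooling!r}")
    model = GstrwModel(sim_m_fused, sd, params)
    unknown = a.values == 0
    positives: dict[tuple[str, str], float] = {}
    negative_sets: list[np.ndarray] = []
    ranks: dict[tuple[str, str], float] = {}
    pools: dict[tuple[str, str], int] = {}
    for cells, train in folds:
        f, _, _ = model.predict(train)
        if pooling == "global":
            negative_sets.append(f.values[unknown])
        for i, j in cells:
            pair = (a.mirna_labels[i], a.disease_labels[j])
            score = float(f.values[i, j])
            positives[pair] = score
            if axis == 0:
                pool = f.values[unknown[:, j], j]
            else:
                pool = f.values[i, unknown[i, :]]
            if pooling == "per_query":
                negative_sets.append(pool)
            ranks[pair] = _mann_whitney_rank(score, pool)
            pools[pair] = int(pool.size) + 1
    if not positives:
        raise ValueError("no held-out pairs: association matrix has no known pairs")
    return _assemble(protocol, positives, negative_sets, ranks, pools)


# ---------------------------------------------------------------------------
# protocols
# ---------------------------------------------------------------------------

def loocv(
    a: AssociationMatrix,
    sim_m_fused: LabeledSquareMatrix,
    sd: LabeledSquareMatrix,
    params: GstrwParams | None = None,
    pooling: str = "global",
) -> EvalResult:
    """Leave-one-out cross-validation over known pairs.

    Each known pair is zeroed in turn and the predictor rerun on the
    reduced matrix; the held-out pair's score is the fold's positive and
    the never-known pairs' scores from the same run are its negatives.
    Global similarities are computed once: they depend only on the
    similarity networks, never on the association matrix.
    """
    pairs = a.pairs()
    if len(pairs) < 2:
        raise ValueError("leave-one-out needs at least 2 known pairs")
    m_idx = {l: i for i, l in enumerate(a.mirna_labels)}
    d_idx = {l: j for j, l in enumerate(a.disease_labels)}
    folds = []
    for mirna, disease in pairs:
        i, j = m_idx[mirna], d_idx[disease]
        train = a.copy()
        train.values[i, j] = 0.0
        folds.append(([(i, j)], train))
    return _run_protocol("loocv_pairs", a, sim_m_fused, sd, params, pooling, folds, axis=0)


def orphan_disease_eval(
    a: AssociationMatrix,
    sim_m_fused: LabeledSquareMatrix,
    sd: LabeledSquareMatrix,
    params: GstrwParams | None = None,
    pooling: str = "global",
) -> EvalResult:
    """Isolated-disease protocol.

    Each disease with at least one known miRNA is made an orphan by
    zeroing its entire column; the scores of its removed pairs in that
    fold are the positives. The optimized seed then rests entirely on
    similar diseases' associations.
    """
    if a.n_disease < 2:
        raise ValueError("orphan-disease evaluation needs at least 2 diseases")
    folds = []
    for j in range(a.n_disease):
        known = np.nonzero(a.values[:, j])[0]
        if known.size == 0:
            continue
        train = a.copy()
        train.values[:, j] = 0.0
        folds.append(([(int(i), j) for i in known], train))
    if not folds:
        raise ValueError("no disease has any known association")
    return _run_protocol("orphan_disease", a, sim_m_fused, sd, params, pooling, folds, axis=0)


def new_mirna_eval(
    a: AssociationMatrix,
    sim_m_fused: LabeledSquareMatrix,
    sd: LabeledSquareMatrix,
    params: GstrwParams | None = None,
    pooling: str = "global",
) -> EvalResult:
    """New-miRNA protocol: mirror of the orphan-disease one over rows."""
    if a.n_mirna < 2:
        raise ValueError("new-miRNA evaluation needs at least 2 miRNAs")
    folds = []
    for i in range(a.n_mirna):
        known = np.nonzero(a.values[i, :])[0]
        if known.size == 0:
            continue
        train = a.copy()
        train.values[i, :] = 0.0
        folds.append(([(i, int(j)) for j in known], train))
    if not folds:
        raise ValueError("no miRNA has any known association")
    return _run_protocol("new_mirna", a, sim_m_fused, sd, params, pooling, folds, axis=1)


_PROTOCOLS = {
    "loocv": loocv,
    "orphan_disease": orphan_disease_eval,
    "new_mirna": new_mirna_eval,
}


def parameter_sweep(
    a: AssociationMatrix,
    sim_m_fused: LabeledSquareMatrix,
    sd: LabeledSquareMatrix,
    grid: dict[str, list[float]],
    protocol: str = "loocv",
    base_params: GstrwParams | None = None,
) -> pd.DataFrame:
    """Vary one parameter group at a time, holding the others fixed.

    ``grid`` maps a parameter name — or a comma-joined group such as
    ``"gamma,theta"`` that moves in lockstep — to the values to try.
    Returns a tidy table with columns (parameter, value, auc).
    """
    if protocol not in _PROTOCOLS:
        raise ValueError(f"unknown protocol {protocol!r}")
    evaluate = _PROTOCOLS[protocol]
    base = base_params or GstrwParams()
    rows = []
    for group, values in grid.items():
        names = [n.strip() for n in group.split(",")]
        for v in values:
            params = base.with_(**{n: v for n in names})
            result = evaluate(a, sim_m_fused, sd, params)
            rows.append({"parameter": group, "value": v, "auc": result.auc})
    return pd.DataFrame(rows, columns=["parameter", "value", "auc"])
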