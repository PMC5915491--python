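"""Labeled matrix containers and the TSV dialects they are stored in.

Three on-disk formats are supported, all tab-separated UTF-8 with '.'
decimals and no quoting:

* similarity matrix — header row of labels (first cell ignored), one
  leading label column, numeric square body;
* association edge list — two columns ``miRNA_id<TAB>disease_id``, one
  known pair per line;
* family table — two columns ``miRNA_id<TAB>family_id``.

Loaders validate shape, symmetry and referential integrity so that the
numerical layers can assume clean inputs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "LabeledSquareMatrix",
    "AssociationMatrix",
    "FamilyTable",
    "read_similarity_matrix",
    "write_similarity_matrix",
    "read_associations",
    "write_associations",
    "read_family_table",
    "write_family_table",
    "write_scores",
]

#: absolute asymmetry below which a similarity matrix is silently averaged
SYMMETRY_TOL = 1e-6


@dataclass
class LabeledSquareMatrix:
    """A square real matrix with one ordered label per row/column."""

    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise ValueError(f"matrix is non-square: shape {self.values.shape}")
        if self.values.shape[0] != len(self.labels):
            raise ValueError(
                f"{len(self.labels)} labels for a "
                f"{self.values.shape[0]}x{self.values.shape[1]} matrix"
            )
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("duplicate labels")

    @property
    def n(self) -> int:
        return len(self.labels)

    def index_of(self, label: str) -> int:
        return self.labels.index(label)

    def loc(self, row: str, col: str) -> float:
        return float(self.values[self.index_of(row), self.index_of(col)])

    def validate_similarity(self) -> None:
        """Check the invariants of an input similarity matrix."""
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite entries")
        if np.any(self.values < 0):
            raise ValueError("negative similarity entries")
        asym = np.max(np.abs(self.values - self.values.T))
        if asym > 1e-8:
            raise ValueError(f"matrix not symmetric (max asymmetry {asym:g})")

    def reorder(self, labels: list[str]) -> "LabeledSquareMatrix":
        """Return a copy restricted to ``labels``, in that order."""
        idx = [self.index_of(l) for l in labels]
        return LabeledSquareMatrix(list(labels), self.values[np.ix_(idx, idx)])


@dataclass
class AssociationMatrix:
    """Binary miRNA x disease association matrix A.

    Rows are miRNA profiles (which diseases a miRNA is linked to) and
    columns are disease profiles (which miRNAs a disease is linked to).
    """

    mirna_labels: list[str]
    disease_labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.mirna_labels), len(self.disease_labels)):
            raise ValueError(
                f"association matrix shape {self.values.shape} does not match "
                f"{len(self.mirna_labels)} miRNAs x {len(self.disease_labels)} diseases"
            )
        if not np.isin(self.values, (0.0, 1.0)).all():
            raise ValueError("association entries must be 0 or 1")

    @property
    def n_mirna(self) -> int:
        return len(self.mirna_labels)

    @property
    def n_disease(self) -> int:
        return len(self.disease_labels)

    def pairs(self) -> list[tuple[str, str]]:
        """Known (miRNA, disease) pairs in row-major order."""
        rows, cols = np.nonzero(self.values)
        return [(self.mirna_labels[i], self.disease_labels[j]) for i, j in zip(rows, cols)]

    def copy(self) -> "AssociationMatrix":
        return AssociationMatrix(
            list(self.mirna_labels), list(self.disease_labels), self.values.copy()
        )


@dataclass
class FamilyTable:
    """miRNA -> family assignments (one family per miRNA, gaps allowed)."""

    assignments: dict[str, str] = field(default_factory=dict)

    def family_matrix(self, labels: list[str]) -> np.ndarray:
        """Same-family indicator matrix over ``labels``.

        Entry (i, j) is 1 iff both miRNAs are assigned to the same family
        and i != j; the diagonal stays 0 and unassigned miRNAs get all-zero
        rows.
        """
        n = len(labels)
        fam = np.zeros((n, n))
        by_family: dict[str, list[int]] = {}
        for k, lab in enumerate(labels):
            f = self.assignments.get(lab)
            if f is not None:
                by_family.setdefault(f, []).append(k)
        for members in by_family.values():
            for i in members:
                for j in members:
                    if i != j:
                        fam[i, j] = 1.0
        return fam


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_similarity_matrix(path) -> LabeledSquareMatrix:
    """Read a labeled similarity matrix from TSV.

    The body must be square and numeric. Asymmetries up to
    :data:`SYMMETRY_TOL` are repaired as (M + M.T) / 2 with a warning;
    anything larger is an error.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    labels = [str(c) for c in df.columns]
    row_labels = [str(r) for r in df.index]
    if len(labels) != len(row_labels):
        raise ValueError(
            f"{path}: non-square body ({len(row_labels)} rows x {len(labels)} columns)"
        )
    if row_labels != labels:
        raise ValueError(f"{path}: row labels do not match column labels")
    if len(set(labels)) != len(labels):
        raise ValueError(f"{path}: duplicate labels")
    try:
        values = df.to_numpy(dtype=float)
    except ValueError as exc:
        raise ValueError(f"{path}: non-numeric cell ({exc})") from exc
    if not np.all(np.isfinite(values)):
        raise ValueError(f"{path}: non-finite entries")
    asym = np.max(np.abs(values - values.T)) if values.size else 0.0
    if asym > SYMMETRY_TOL:
        raise ValueError(f"{path}: matrix is grossly asymmetric (max deviation {asym:g})")
    if asym > 0:
        warnings.warn(f"{path}: symmetrizing (max asymmetry {asym:g})", stacklevel=2)
        values = (values + values.T) / 2.0
    if np.any(values < 0):
        raise ValueError(f"{path}: negative similarity entries")
    return LabeledSquareMatrix(labels, values)


def write_similarity_matrix(path, m: LabeledSquareMatrix) -> None:
    pd.DataFrame(m.values, index=m.labels, columns=m.labels).to_csv(
        path, sep="\t", float_format="%.17g"
    )


def read_associations(path, mirna_labels: list[str], disease_labels: list[str]) -> AssociationMatrix:
    """Read a two-column (miRNA, disease) edge list into a binary matrix.

    Duplicate lines collapse to one entry; identifiers outside the given
    universes are errors. An empty file yields an all-zero matrix (with a
    warning) so that orphan scenarios remain expressible.
    """
    try:
        df = pd.read_csv(path, sep="\t", header=None, dtype=str)
    except pd.errors.EmptyDataError:
        warnings.warn(f"{path}: empty association file", stacklevel=2)
        df = pd.DataFrame(columns=[0, 1])
    if df.shape[1] != 2:
        raise ValueError(f"{path}: expected 2 columns, got {df.shape[1]}")
    m_idx = {l: i for i, l in enumerate(mirna_labels)}
    d_idx = {l: j for j, l in enumerate(disease_labels)}
    values = np.zeros((len(mirna_labels), len(disease_labels)))
    for mirna, disease in df.itertuples(index=False):
        if mirna not in m_idx:
            raise ValueError(f"{path}: unknown miRNA identifier {mirna!r}")
        if disease not in d_idx:
            raise ValueError(f"{path}: unknown disease identifier {disease!r}")
        values[m_idx[mirna], d_idx[disease]] = 1.0
    return AssociationMatrix(list(mirna_labels), list(disease_labels), values)


def write_associations(path, a: AssociationMatrix) -> None:
    pd.DataFrame(a.pairs()).to_csv(path, sep="\t", header=False, index=False)


def read_family_table(path) -> FamilyTable:
    """Read a two-column (miRNA, family) table.

    A miRNA may be listed more than once only if every line agrees on its
    family; conflicting assignments are an error.
    """
    try:
        df = pd.read_csv(path, sep="\t", header=None, dtype=str)
    except pd.errors.EmptyDataError:
        return FamilyTable({})
    if df.shape[1] != 2:
        raise ValueError(f"{path}: expected 2 columns, got {df.shape[1]}")
    assignments: dict[str, str] = {}
    for mirna, family in df.itertuples(index=False):
        if mirna in assignments and assignments[mirna] != family:
            raise ValueError(
                f"{path}: {mirna!r} assigned to both {assignments[mirna]!r} and {family!r}"
            )
        assignments[mirna] = family
    return FamilyTable(assignments)


def write_family_table(path, fam: FamilyTable) -> None:
    pd.DataFrame(sorted(fam.assignments.items())).to_csv(
        path, sep="\t", header=False, index=False
    )


def write_scores(path, scores, a: AssociationMatrix) -> None:
    """Write a long-format score table.

    Columns: miRNA_id, disease_id, score, rank_within_disease (1 = best,
    ties broken by miRNA order), known_flag (1 if the pair is a known
    association in ``a``).
    """
    values = np.asarray(scores, dtype=float)
    # rank 1 = highest score within each disease column; stable on ties
    order = np.argsort(-values, axis=0, kind="stable")
    ranks = np.empty_like(order)
    for j in range(values.shape[1]):
        ranks[order[:, j], j] = np.arange(1, values.shape[0] + 1)
    rows = []
    for i, mirna in enumerate(a.mirna_labels):
        for j, disease in enumerate(a.disease_labels):
            rows.append(
                (mirna, disease, values[i, j], int(ranks[i, j]), int(a.values[i, j]))
            )
    pd.DataFrame(
        rows, columns=["miRNA_id", "disease_id", "score", "rank_within_disease", "known_flag"]
    ).to_csv(path, sep="\t", index=False, float_format="%.17g")


def reconcile_labels(
    sm: LabeledSquareMatrix, sd: LabeledSquareMatrix, a: AssociationMatrix
) -> tuple[LabeledSquareMatrix, LabeledSquareMatrix, AssociationMatrix]:
    """Check that the three inputs agree on their label universes.

    The similarity matrices are authoritative: the association matrix must
    be indexed by exactly the same miRNAs and diseases, in the same order
    (loaders already build it that way). Raises on any mismatch.
    """
    if a.mirna_labels != sm.labels:
        raise ValueError("association miRNA labels do not match the miRNA similarity matrix")
    if a.disease_labels != sd.labels:
        raise ValueError("association disease labels do not match the disease similarity matrix")
    return sm, sd, a
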