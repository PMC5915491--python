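"""Synthetic fixtures with the block structure the predictor assumes.

Real inputs to the method are (i) a miRNA functional-similarity matrix,
(ii) a disease phenotype-similarity matrix, (iii) miRNA family
assignments, and (iv) a sparse binary association matrix. The generator
emulates their joint statistical structure: miRNAs and diseases fall into
latent blocks (functional modules / disease classes), similarity is high
within a block and low between blocks, families are small same-block
miRNA groups, and true associations concentrate on matched
(miRNA-block, disease-block) pairs with a small off-block noise rate.

One integer seed drives independent per-component substreams (miRNA
similarity, disease similarity, families, associations) via
``numpy.random.SeedSequence.spawn``, so any component can be regenerated
on its own and the whole fixture is bit-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .io_formats import AssociationMatrix, FamilyTable, LabeledSquareMatrix

__all__ = ["SyntheticSpec", "generate", "mask_associations", "permute_associations"]

#: half-width of the uniform noise added around block similarity means
SIM_NOISE = 0.05


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic dataset.

    Defaults produce the strong-signal fixture used throughout the test
    suite: 60 miRNAs and 30 diseases in 3 aligned blocks, within-block
    similarity 0.7 vs 0.1 between blocks, half the miRNAs carrying family
    labels, associations at density 0.5 on matched block pairs and 0.02
    elsewhere.
    """

    n_mirna: int = 60
    n_disease: int = 30
    n_mirna_blocks: int = 3
    n_disease_blocks: int = 3
    within_sim: float = 0.7
    between_sim: float = 0.1
    family_frac: float = 0.5
    assoc_density: float = 0.5
    noise_density: float = 0.02
    rng_seed: int = 1

    def __post_init__(self) -> None:
        if self.n_mirna_blocks > self.n_mirna or self.n_disease_blocks > self.n_disease:
            raise ValueError("more blocks than entities")
        for name in ("within_sim", "between_sim"):
            if not 0.0 < getattr(self, name) < 1.0:
                raise ValueError(f"{name} must be in (0, 1)")
        for name in ("family_frac", "assoc_density", "noise_density"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")


def _block_assignment(n: int, n_blocks: int) -> np.ndarray:
    """Block index per entity, blocks of near-equal size, contiguous."""
    return np.concatenate([np.full(len(c), b) for b, c in enumerate(np.array_split(np.arange(n), n_blocks))])


def _block_similarity(
    blocks: np.ndarray, within: float, between: float, rng: np.random.Generator
) -> np.ndarray:
    """Symmetric similarity matrix with unit diagonal and block means."""
    n = blocks.size
    mean = np.where(blocks[:, None] == blocks[None, :], within, between)
    noise = rng.uniform(-SIM_NOISE, SIM_NOISE, size=(n, n))
    noise = np.triu(noise, 1)
    values = np.clip(mean + noise + noise.T, 0.0, 1.0)
    np.fill_diagonal(values, 1.0)
    return values


def _families(
    labels: list[str], blocks: np.ndarray, frac: float, rng: np.random.Generator
) -> FamilyTable:
    """Assign ``frac`` of each miRNA block to families of size 2-4."""
    assignments: dict[str, str] = {}
    fam_counter = 0
    for b in np.unique(blocks):
        members = np.nonzero(blocks == b)[0]
        k = int(round(frac * members.size))
        if k < 2:
            continue
        chosen = rng.choice(members, size=k, replace=False)
        rng.shuffle(chosen)
        pos = 0
        while k - pos >= 2:
            size = int(rng.integers(2, 5))
            size = min(size, k - pos)
            if k - pos - size == 1:  # never strand a singleton
                size += 1
            group = chosen[pos : pos + size]
            fam = f"fam{fam_counter}"
            fam_counter += 1
            for idx in group:
                assignments[labels[idx]] = fam
            pos += size
    return FamilyTable(assignments)


def generate(
    spec: SyntheticSpec,
) -> tuple[LabeledSquareMatrix, LabeledSquareMatrix, FamilyTable, AssociationMatrix]:
    """Generate (sm, sd, family, a) from a spec, reproducibly.

    miRNA block k is matched to disease block ``k % n_disease_blocks``;
    A(m, d) is Bernoulli(assoc_density) on matched block pairs and
    Bernoulli(noise_density) elsewhere.
    """
    streams = np.random.SeedSequence(spec.rng_seed).spawn(4)
    rng_sm, rng_sd, rng_fam, rng_a = (np.random.default_rng(s) for s in streams)

    mirna_labels = [f"mir-{i + 1:03d}" for i in range(spec.n_mirna)]
    disease_labels = [f"disease-{j + 1:03d}" for j in range(spec.n_disease)]
    m_blocks = _block_assignment(spec.n_mirna, spec.n_mirna_blocks)
    d_blocks = _block_assignment(spec.n_disease, spec.n_disease_blocks)

    sm = LabeledSquareMatrix(
        mirna_labels, _block_similarity(m_blocks, spec.within_sim, spec.between_sim, rng_sm)
    )
    sd = LabeledSquareMatrix(
        disease_labels, _block_similarity(d_blocks, spec.within_sim, spec.between_sim, rng_sd)
    )
    family = _families(mirna_labels, m_blocks, spec.family_frac, rng_fam)

    matched = (m_blocks[:, None] % spec.n_disease_blocks) == d_blocks[None, :]
    prob = np.where(matched, spec.assoc_density, spec.noise_density)
    values = (rng_a.random(prob.shape) < prob).astype(float)
    a = AssociationMatrix(mirna_labels, disease_labels, values)
    return sm, sd, family, a


def matched_block_mask(spec: SyntheticSpec) -> np.ndarray:
    """Boolean miRNA x disease mask of the matched (planted) block pairs."""
    m_blocks = _block_assignment(spec.n_mirna, spec.n_mirna_blocks)
    d_blocks = _block_assignment(spec.n_disease, spec.n_disease_blocks)
    return (m_blocks[:, None] % spec.n_disease_blocks) == d_blocks[None, :]


def permute_associations(a: AssociationMatrix, rng_seed: int) -> AssociationMatrix:
    """Null control: shuffle all association cells uniformly at random.

    The number of known pairs is preserved but every alignment between the
    associations and the similarity block structure — on both the miRNA
    and the disease side — is destroyed, so downstream evaluation should
    hover near chance. (Permuting whole rows or columns would not do this:
    a common row permutation leaves the correlations between disease
    association profiles intact.)
    """
    rng = np.random.default_rng(rng_seed)
    flat = a.values.flatten()
    rng.shuffle(flat)
    return AssociationMatrix(
        list(a.mirna_labels), list(a.disease_labels), flat.reshape(a.values.shape)
    )


def mask_associations(
    a: AssociationMatrix, fraction: float, rng_seed: int
) -> tuple[AssociationMatrix, list[tuple[str, str]]]:
    """Hold out ``ceil(fraction * n_pairs)`` known pairs uniformly at random.

    Returns the training matrix (held-out entries zeroed) and the held-out
    pairs; together they partition the known pairs exactly.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must be in [0, 1]")
    pairs = a.pairs()
    n_out = math.ceil(fraction * len(pairs))
    rng = np.random.default_rng(rng_seed)
    chosen = rng.choice(len(pairs), size=n_out, replace=False) if n_out else np.array([], dtype=int)
    held_out = [pairs[k] for k in sorted(chosen)]
    train = a.copy()
    m_idx = {l: i for i, l in enumerate(a.mirna_labels)}
    d_idx = {l: j for j, l in enumerate(a.disease_labels)}
    for mirna, disease in held_out:
        train.values[m_idx[mirna], d_idx[disease]] = 0.0
    return train, held_out
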