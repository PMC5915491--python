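# Methods

## Model and assumptions

The predictor treats miRNA–disease association as a bipartite link
prediction problem on two similarity networks. Its working hypothesis is
that functionally similar miRNAs associate with phenotypically similar
diseases, and that *global* network similarity — how two entities relate
through the whole network, not just direct neighbours — carries more
signal than local similarity. Known associations are treated as a binary
matrix `A` (rows miRNAs, columns diseases); unknown pairs are unlabeled,
not negative: no negative training samples are assumed to exist.

Global similarity is the Laplacian-score smoothing
`g = (1 − α)(I − α S̄)⁻¹ e` of a unit query indicator over the
column-normalized network `S̄`. Because `S̄` is column sub-stochastic, the
spectral radius of `α S̄` is below 1 for every α in (0, 1), the Neumann
series converges, and the system has a unique nonnegative solution; the
implementation uses one dense LU solve per network and asserts finiteness
and nonnegativity of the result. Entities with all-zero similarity columns
keep zero columns after normalization and simply retain their own unit
mass.

The two-tier architecture scores a pair from both directions: the disease
view (its optimized seed walks the miRNA network, and the stationary
distribution is correlated with each miRNA's global profile) and the miRNA
view (the mirror walk on the disease network). The fusion weight `w`
interpolates between them; `w ∈ {0, 1}` recovers the single-network
ablations exactly.

## Parameters

| parameter | meaning | default |
|---|---|---|
| γ, θ | restart probability of the walks (probability per step of jumping back to the seed); higher values localize the walk around the seed | 0.2 |
| α, β | global-similarity balance: weight of network propagation vs fidelity to the query indicator | 0.8 |
| λ, η | seed-optimization weight on similarity-borrowed association vectors | 0.2 |
| w | weight of the miRNA-network tier in the final score, in [0, 1] | 0.6 |
| tol | L1 convergence threshold of the walks | 1e-6 |
| max_iter | walk iteration cap (convergence takes tens of iterations at γ = 0.2; exceeding the cap is an error, never a silent truncation) | 1000 |

All defaults are the reference operating point of the method; a
`parameter_sweep` utility varies one parameter group at a time (e.g.
γ = θ jointly over 0.1…0.9) holding the others fixed.

## Numerical conventions

- **Seed orientation.** The similarity weight `simD̃(d_i, d_j)` is read
  from the query's own global profile (column *i* of `simD̃`); the matrix
  is generally asymmetric because the underlying network is
  column-normalized.
- **Self term.** The seed sums exclude `j = i`: including it would re-add
  the query's own association vector scaled by its self-similarity,
  double-counting the first term.
- **Seed normalization.** Optimized seeds are L1-normalized so the walk
  iterates probability vectors; an all-zero seed (an orphan query whose
  neighbours are also silent) short-circuits to an all-zero stationary
  vector and, via the zero-variance rule, to scores of 0.
- **Convergence norm.** The walk stops when the L1 change of the iterate
  drops below `tol`; batched walks (all queries iterated as one matrix)
  stop when every column has converged, which only tightens the per-column
  residual.
- **Zero-variance guard.** Pearson correlation against a constant vector
  is defined as 0, never NaN.
- **Family matrix.** Same-family indicator with zero diagonal; miRNAs
  absent from the family table get all-zero rows; fused similarities may
  exceed 1 (bounded by 2) and are not clamped — column normalization
  absorbs the scale.
- **Symmetry repair.** Input similarity matrices with asymmetry ≤ 1e-6
  are averaged with a warning; larger asymmetry is an error.

## Evaluation protocols

Leave-one-out zeroes each known pair in turn; the orphan-disease and
new-miRNA protocols zero an entire column or row. In every protocol the
held-out pair's score and its competitors' scores come from the **same
fold model**, because scores from differently trained models are not on a
common scale. The default pooling is global: one score list of held-out
positives against the never-known pairs of each fold, summarized by a
threshold-sweep ROC whose trapezoidal area equals the Mann–Whitney
U statistic (ties get half credit, so a constant predictor scores exactly
0.5); a per-query pooling mode restricts each positive's competitors to
its own disease column (or miRNA row). Per-query ranks are always reported
within the query's own column/row. Global-similarity matrices and the
normalized walk networks are computed once per dataset — they do not
depend on `A` — so hold-out folds only redo seeds, walks and scoring.

## Synthetic data

The generator emulates the joint structure of the real inputs: latent
blocks (functional modules / disease classes) with mean within-block
similarity 0.7 and between-block 0.1 plus uniform ±0.05 noise truncated to
[0, 1] and unit diagonals; families as random same-block miRNA groups of
size 2–4 covering half of each block by default; and associations drawn
Bernoulli(0.5) on matched block pairs and Bernoulli(0.02) elsewhere. The
default 60 miRNAs × 30 diseases with 3 aligned blocks yields ≈325 known
pairs, a deliberately desk-scale instance: protocols that refit per fold
finish in seconds while leaving enough pairs for stable rank statistics.
One integer seed drives independent `SeedSequence`-spawned substreams per
component, so outputs are bit-reproducible and any component can be
regenerated alone. A shuffle of all association cells
(`permute_associations`) provides the matched null: shuffling cells — not
rows or columns, which preserve profile correlations on one side —
destroys the alignment with both similarity networks.

What the generator does **not** emulate: the heavy-tailed degree
distribution of real association catalogs, similarity scores built from
shared-target or ontology semantics (block means stand in for both),
inter-block similarity gradients, and database-curation artifacts. Passing
tests therefore demonstrate that the machinery recovers planted
block-structured signal and degrades to chance on shuffled labels — not
performance on any real benchmark.

## Known limitations

- Scores are Pearson correlations in [−1, 1]; they rank candidates but
  have no probabilistic calibration.
- Dense solves put the practical ceiling around a few thousand entities
  per network, the intended regime.
- On the strong-signal fixture the disease-network tier alone slightly
  outperforms the default fusion weight (w = 0.6 favours the miRNA tier);
  the sweep utility exposes this trade-off, and the default is kept as the
  method's reference setting.
- Only Pearson profile scoring is implemented; no alternative correlation
  measures or multi-network extensions.
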