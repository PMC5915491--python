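# gstrw

Prediction of miRNA–disease associations by a **g**lobal-**s**imilarity
**t**wo-tier **r**andom **w**alk. Given a miRNA functional-similarity
network, a disease similarity network, miRNA family assignments, and a
sparse table of experimentally known miRNA–disease pairs, `gstrw` scores
every candidate pair — including pairs involving *orphan diseases* (no
known miRNAs) and *new miRNAs* (no known diseases), for which
neighbourhood-based methods produce nothing. It is aimed at computational
biologists prioritizing candidate miRNAs for experimental follow-up.

## Method

1. **Similarity fusion.** miRNA functional similarity SM is boosted by
   family membership: `SIM(i,j) = SM(i,j) · (1 + SMfam(i,j))`, so miRNAs
   of the same miRBase family count twice their functional score.
2. **Global similarity.** Each network is smoothed by the Laplacian score
   of graphs: with `S̄` the column-normalized similarity matrix, the
   global-similarity profile of entity *j* is
   `g_j = (1 − α)(I − α S̄)⁻¹ e_j`, balancing whole-network propagation
   (weight α) against fidelity to the query. Columns of `simD̃` (diseases,
   balance α) and `simM̃` (miRNAs, balance β) stack these solutions.
3. **Seed optimization.** The walk seed of disease *i* augments its known
   association vector with those of similar diseases,
   `D̃_i = D_i + λ Σ_{j≠i} simD̃(d_i,d_j) · D_j`, then L1-normalizes; an
   orphan disease thus inherits a seed from its phenotypic neighbours.
   miRNA seeds mirror this with weight η on `simM̃`.
4. **Restart random walks.** Disease seeds walk on the miRNA network,
   miRNA seeds on the disease network:
   `x_{t+1} = (1 − γ) S̄ x_t + γ · seed`, iterated until the L1 change
   falls below 10⁻⁶.
5. **Scoring and fusion.** Each stationary vector is scored against every
   global-similarity profile by Pearson correlation, giving the
   miRNA-network tier `F_m` and the disease-network tier `F_d`; the final
   score is `F = w · F_mᵀ + (1 − w) · F_d`.

Defaults are γ = θ = 0.2, α = β = 0.8, λ = η = 0.2, w = 0.6. The whole
pipeline is deterministic dense linear algebra; networks of 10²–10³ nodes
run in milliseconds.

## Worked example

```python
from gstrw import (SyntheticSpec, generate, fuse_mirna_similarity,
                   predict, loocv, orphan_disease_eval)

# 60 miRNAs x 30 diseases in 3 aligned blocks; associations concentrate
# on matched (miRNA-block, disease-block) pairs
spec = SyntheticSpec()                       # rng_seed=1
sm, sd, family, a = generate(spec)
sim = fuse_mirna_similarity(sm, family)

F, F_m, F_d = predict(a, sim, sd)            # default parameters
print(int(a.values.sum()))                   # 325 known pairs
print(round(float(F.values[a.values == 1].mean()), 3))   # 0.443
print(round(float(F.values[a.values == 0].mean()), 3))   # -0.097

print(round(loocv(a, sim, sd).auc, 4))               # 0.8499
print(round(orphan_disease_eval(a, sim, sd).auc, 4)) # 0.9059
```

Known pairs score far above unknown pairs (mean 0.443 vs −0.097).
Leave-one-out cross-validation — each known pair removed in turn, rescored,
and ranked against all never-known pairs — gives AUC 0.8499; removing a
disease's *entire* association column before rescoring (the orphan-disease
protocol) still recovers its true miRNAs with AUC 0.9059.

The same workflows are available from the shell:

```sh
gstrw simulate --out-dir data/
gstrw predict --assoc data/associations.tsv --mirna-sim data/mirna_similarity.tsv \
      --disease-sim data/disease_similarity.tsv --family data/family.tsv \
      --out scores.tsv
gstrw loocv   --assoc data/associations.tsv --mirna-sim data/mirna_similarity.tsv \
      --disease-sim data/disease_similarity.tsv --family data/family.tsv \
      --out metrics.json
```

Every run writes a JSON manifest (resolved parameters, input digests,
version) beside its output.

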