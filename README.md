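# intercell

Iterative multi-view graph modelling of **intercellular gene regulation**
from spatial transcriptomics.

Spatially resolved transcriptomics measures where cells are and what they
express, which makes it possible to ask not just *what* a cell transcribes
but *why*: how much of a gene's expression is the cell type talking, and
how much is the neighbourhood — ligands secreted by nearby cells binding
receptors and rewiring transcription downstream. `intercell` answers that
question per cell, per gene, per ligand-receptor (LR) pair, for
cell-resolution platforms (Slide-seq, Stereo-seq) and spot-resolution ones
(10x Visium, via cell-type proportions) alike.

## Model

Given observed counts `X_obs ∈ R^{n×m}` (sparse), coordinates
`C ∈ R^{n×2}` and a cell-type matrix `T ∈ R^{n×t}`, expression is imputed
as a cell-type baseline plus one micro-environment component per active LR
pair:

```
X̂ = X̂_b + Σ_{lr ∈ LR_θ} X̂_s^{lr′}
```

- An LR pair is **active** when its ligand and receptor (geometric mean
  over complex subunits) are each detected in > θ of cells (θ = 0.15).
- Each active pair defines a directed **communication graph** with
  sender→receiver weight `E_l[i]·E_r[j] / D[i,j]`, sparsified to each
  sender's k = 5 nearest neighbours.
- A per-view **GNN** (graph-transformer by default, 2 layers, d = 32)
  embeds cells from `T` over that graph; a shared decoder MLP maps
  embeddings to genes, optionally masked by a GRN/PPI prior so a pair can
  only regulate genes reachable from its receptor; `X̂_b = MLP(T)`.
- Training minimises MSE over the **non-zero** entries of `X_obs` (Adam,
  lr 0.01, early stopping with patience 10).
- **Iterative refinement**: the dense imputation re-activates LR pairs
  invisible in the sparse data; re-estimated graphs are blended
  `α·old + (1−α)·new` (α = 0.2) and the loop repeats until no new view
  appears.
- The **regulatory score** `ψ(lr, c, g) = X̂_s^{lr′}[c, g]` ranks LR pairs
  by their contribution to gene g in cell c.

A synthetic benchmark generator plants known cell types, communication
zones and ligand→target regulation (negative-binomial counts, 20% observed
density, nine preset parameterisations), so the entire method is testable
end to end without any external download. See `docs/methods.md` for the
full description and design rationale.

## Worked example

```python
from intercell import (ModelConfig, build_masks, generate, preset_config,
                       rank_lr_pairs, run)

sim = generate(preset_config(1, n_cells=300, n_lr_pairs=20, seed=1))
masks = build_masks(sim.prior, sim.lr_table, sim.data.gene_names, hops=2)
result, multiview, history = run(
    sim.data, sim.lr_table, masks, ModelConfig(seed=1),
    theta=0.15, k=5, alpha=0.2)

for h in history:
    print(f"iteration {h['iteration']}: {h['n_views']} views "
          f"({h['n_new_views']} new), train MSE {h['train_loss']:.3f}")

(cell, gene), true_pairs = sorted(sim.truth.items())[0]
ranking = rank_lr_pairs(result, cell, gene)
print(f"cell {cell}, gene g{gene}: true regulator {sorted(true_pairs)}")
for lr_id, psi in ranking.ranked[:3]:
    print(f"  {lr_id}  psi = {psi:.3f}")
```

prints

```
iteration 0: 18 views (18 new), train MSE 5.590
iteration 1: 20 views (2 new), train MSE 4.232
iteration 1: 20 views (0 new), train MSE 4.232
cell 3, gene g44: true regulator ['LR11']
  LR06  psi = 1.282
  LR11  psi = 0.078
  LR01  psi = 0.000
```

Reading this: 18 of the 20 planted LR pairs are visible in the sparse
observations; the first refinement recovers the remaining 2 from the dense
imputation and the loop then converges (0 new views). For the first
cell-gene pair with planted regulation, the true pair `LR11` is ranked 2nd
of 20 by its contribution ψ to the imputed expression, and pairs whose
prior mask excludes `g44` score exactly 0. Scored with the benchmark
harness (`intercell.evaluate.run_variant`, which adds a held-out split),
this same dataset and configuration reach NDCG ≈ 0.83 against the planted
truth, averaged over evaluated cell-gene pairs, versus ≈ 0.35 for a
random ranking.

## Command line

```
intercell simulate --out-dir sim --setting 1 --seed 7
intercell run      --data-dir sim --out-dir out --seed 7
intercell evaluate --data-dir sim --out-dir eval --replicates 5
intercell ablate   --out-dir ablation --replicates 5
```

Ablation variants (`--ablation no-grn | no-iterate | shared-gnn |
per-view-decoder`) are first-class flags on `run` and swept by `ablate`.

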