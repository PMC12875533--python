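# hrnetx

Hierarchical regulatory network inference from paired single-cell
multi-omics, with cell-fate decoding by in-silico perturbation.

Cell fate is controlled by a hierarchy in which transcription factors
(TFs) cooperate, bind cis-regulatory elements (CREs, ATAC peaks or
enhancer-like intervals), couple those elements over long genomic
distances, and finally set the expression of target genes (TGs).
`hrnetx` reconstructs this four-layer hierarchical regulatory network
(**HRNet**: TF–TF, TF–CRE, CRE–CRE, CRE–TG) from metacell-level
expression and accessibility matrices plus prior candidate edge lists,
and then uses the inferred network to rank driver regulators, predict
target-gene expression, and simulate knockout / overexpression
experiments. It is aimed at computational biologists working with paired
scRNA-seq + scATAC-seq data who want an interpretable, testable network
model rather than a black-box embedding.

## The model

**Encoder.** Node features are the metacell profiles (node × metacell,
z-scored). Per layer *l* the three node types are updated along the fixed
meta-path that mirrors the flow of regulatory information:

1. TF ← TF–TF by graph convolution
   `H_t = σ(D̃^{-1/2} Ã D̃^{-1/2} H W)`, `Ã = A + I`;
2. CRE ← TF→CRE, 3. CRE ← CRE↔CRE, 4. TG ← CRE→TG by heterogeneous
   graph-transformer blocks — per-head key/query/value projections,
   edge-type-specific bilinear attention with scaled dot product,
   softmax over each target's in-neighbors, multi-head concatenation,
   and a gated residual `H_t = g·H̃_t + (1−g)·H_t^{prev}`,
   `g = sigmoid(θ)` with a trainable scalar θ per block;
3. TG ← TG–TG (protein-interaction loop) by GraphSAGE,
   `H_t = ReLU(W·[H_t ; mean(H_neighbors)])`.

**Semi-supervised labels.** High-correlation candidate TF–CRE and
CRE–CRE pairs (Pearson r ≥ 0.3 across metacells) are pseudo-positives;
pseudo-negatives are sampled outside the candidate prior, with hard
(endpoint-corrupted) negatives re-drawn each epoch during training.

**Dual-task loss.** `L = λ·L_MSE + (1−λ)·L_BLCE` with
`L_MSE = (1/N) Σ (x − x̂)²` on TG expression (4-layer decoder,
16→32→32→32→N_cells) and the class-balanced cross-entropy
`L_BLCE = −(1/L) Σ [α y log ŷ + (1−α)(1−y) log(1−ŷ)]`,
`α = |neg|/(|pos|+|neg|)`, on the cosine edge decoder
`ŷ = sigmoid(τ·cos(z_u, z_v))`. Training runs several restarts and
ensembles their edge scores.

**Downstream.**
- `mrwr_cts` / `mrwr_pert`: multilayer random walk with restart,
  `s = (1−β) W s + β s₀` on the column-stochastic HRNet transition
  matrix — reverse walks from a cluster's differentially expressed genes
  rank driver TFs/CREs, forward walks from a TF rank perturbation
  targets.
- `build_masks` / `fit` / `perturb_predict`: a gene-specific masked
  network (connectivity = the gene's HRNet sub-network) predicts its
  expression from TF expression + CRE accessibility; multiplying a
  node's input by a fold (0 = knockout, >1 = overexpression) gives the
  per-metacell response, and `vector_field` projects responses onto a
  2-D embedding.
- `louvain_modules` / `extract_hubs` / `locus_enrichment` /
  `assign_hcg`: co-CRE modules, hub elements, permutation-based locus
  enrichment and hub-regulated gene assignment (±2 Mbp around hub CREs).

A seeded synthetic-data generator (`hrnetx.synthetic`) plants the whole
causal hierarchy with decoy edges and known cluster-master TFs, so every
claim above is tested against ground truth without any download.

## Worked example

```bash
python examples/02_train_and_extract_hrnet.py
python examples/03_rank_drivers.py
```

prints (seed 7 fixture; a couple of minutes on one CPU):

```
best validation AUPR 0.572 (epoch 73, 5 restarts)
HRNet edges: {'TF-CRE': 240, 'CRE-CRE': 15, 'TF-TF': 15, 'CRE-TG': 420}
held-out planted TF-CRE AUPR 0.473 (prevalence 0.112, AUROC 0.843)
cluster 0: top driver TFs ['TF000', 'TF006', 'TF003'] (planted master: TF000, recovered)
cluster 1: top driver TFs ['TF001', 'TF005', 'TF018'] (planted master: TF001, recovered)
cluster 2: top driver TFs ['TF002', 'TF011', 'TF005'] (planted master: TF002, recovered)
forward walk from TF000: 7/10 of the top targets are planted downstream genes (12/100 in the universe)
```

The held-out AUPR of 0.47 against a planted-edge prevalence of 0.11
means the trained model ranks true regulator–element pairs roughly
four-fold better than chance on labels it never saw; the reverse walks
then place each cluster's planted master TF at the top of its driver
ranking. `examples/04_perturb_expression.py` continues the session:
knocking out a master TF lowers its program gene's predicted expression
in 100% of metacells, and overexpression raises it, reproducing the
expected dose logic.

The same stages are available as a thin CLI
(`hrnetx simulate|train|eval|drivers|predict-expression|perturb|pert-targets|cocre`,
YAML config via `--config`, every run seeded and stamped).

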