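# Methods

This note documents the models, numerical choices and open design
decisions behind `hrnetx`, and what the synthetic benchmark does and
does not establish.

## Data model and assumptions

The unit of observation is the **metacell**: an aggregate of
transcriptionally similar cells with paired, denoised expression and
accessibility profiles. Inputs are three non-negative metacell × node
matrices (TF expression, TG expression, CRE accessibility), five typed
prior edge lists (TF–TF and TG–TG protein-interaction-like priors,
motif-derived TF–CRE candidates, distance-window CRE–CRE candidates,
proximity-based CRE–TG candidates) and CRE genomic intervals (BED,
0-based half-open; CRE ids are rendered `chrom:start-end`; strand is
ignored). Candidate edge lists are assumed to be supersets of the true
regulatory edges — the method's job is ranking within them, not
proposing edges de novo. Matrices are accepted as given
(pre-normalized); inside the encoder each node's profile is z-scored
across metacells, so only relative variation matters. A gene may appear
as both TF and TG; the two roles are distinct nodes that share an
expression profile.

## Encoder

Embedding dimension 16, hidden dimension 32, 2 layers, 2 heads. The
input projection is one linear map per node type from metacell space to
the embedding. Each encoder layer updates node types in the fixed
meta-path order TF–TF → TF–CRE → CRE–CRE → CRE–TG (→ TG–TG), so by
construction information can only flow down the regulatory hierarchy
within a layer.

* **TF–TF**: spectrally-normalized graph convolution with self-loops.
  Activation is `tanh` by default: the decoder is a similarity on
  embeddings, and a one-sided activation (ReLU) would confine all TF
  embeddings to the positive orthant, destroying anti-correlation
  information. A heterogeneous-transformer alternative is available
  (`tf_tf_encoder="hgt"`).
* **HGT blocks**: per-head type-specific key/query/value maps, an
  edge-type-specific bilinear form scaled by `1/sqrt(d_head)`, softmax
  per target node, message aggregation, multi-head concat, output
  projection. Undirected CRE–CRE pairs are expanded to both directions;
  the pair's recorded attention is the mean of both.
* **Residual gate**: the published formulation places a trainable θ and
  a ReLU inside the update `θ(ReLU(H̃))·H̃ + (θ−1)·H_prev`, which read
  literally subtracts the previous embedding (θ ∈ (0,1) ⇒ θ−1 < 0).
  We implement the convex combination `g·H̃ + (1−g)·H_prev` with
  `g = sigmoid(θ)`, θ initialized in (0, 1) and trainable without
  bounds. The default `gate_mode="signed"` applies the gate to the
  *un-activated* message (the ReLU reading is available as
  `gate_mode="relu"`); keeping the message signed matters for the same
  anti-correlation reason as above.
* **Loop encoder**: GraphSAGE over the TG–TG prior with mean
  aggregation (max-pool available; an order-dependent LSTM aggregator
  is deliberately excluded). Nodes without neighbors aggregate a zero
  vector.
* An optional spectral initialization (`init="spectral"`) starts the
  projections at the shared principal-component basis of all profiles
  and the message branches at zero (identity-preserving, ReZero-style).
  It raises the untrained model to the level of a rank-16 denoised
  correlation ranking, but because the initialization — not learning —
  then carries the performance, a shuffled-label control becomes
  indistinguishable from real training; the default is therefore random
  initialization.

## Labels, loss, training

Pseudo-positives are candidate edges with Pearson correlation ≥ 0.3
across metacells (configurable per edge type; `grid_search_threshold`
supports tuning against validation AUPR over e.g. {0.1..0.7}).
Pseudo-negatives are a uniform seeded sample of node pairs outside the
candidate prior, 5 per positive; the class weight α = |neg|/L makes the
two classes contribute equally to the cross-entropy. Labels exist only
for TF–CRE and CRE–CRE; the TF–TF and CRE–TG priors are trusted. Labels
are split 80/10/10 (edge-level, stratified, seeded); additionally 20% of
each candidate set is held out of labeling entirely for candidate-level
evaluation.

During training the pseudo-negatives of the train split are re-drawn
each epoch by *endpoint corruption*: one side of a random training
positive is replaced by a random node, rejecting candidate-prior pairs
and pairs fixed in any split. Against uniform negatives a model can
separate the classes from node identity alone (positives concentrate on
particular nodes) without learning pair compatibility; corrupted
negatives share an endpoint with a positive and close that shortcut.
For the same reason the edge decoder defaults to the cosine form
`sigmoid(τ·cos(z_u, z_v))` with trainable temperature τ (init 5): the
raw dot product admits embedding-norm shortcuts. The plain dot-product
decoder remains available.

Loss: `λ·MSE + (1−λ)·BLCE`, λ = 0.5. Optimizer: Adam, learning rate
1e-3, weight decay 1e-5, at most 300 epochs, early stopping after 60
epochs without validation-AUPR improvement, probabilities clamped to
[1e-7, 1−1e-7]. Full-batch training of a small graph transformer is
sensitive to initialization, so `train` runs 5 independent seeded
restarts; the best-validation member is returned and all members are
kept, with downstream edge scores and attention averaged over them.

## HRNet extraction

* **TF–CRE**: keep candidates with ensemble decoder probability ≥ 0.8
  (the retention threshold used for expression prediction in the
  source study) plus, unconditionally, each CRE's single
  highest-probability in-edge — no element loses its best-supported
  regulator. Edge weight is the decoder's per-CRE routing distribution:
  odds `p/(1−p)` normalized over the CRE's retained candidates
  (equivalently a softmax of the decoder logits). Attention averaged
  over layers/heads/restarts was evaluated for this role and proved
  much less reproducible across simulation seeds than the decoder
  probabilities; attention remains exported and contract-tested.
* **CRE–CRE**: top 2% of candidates by ensemble-averaged attention.
* **TF–TF, CRE–TG**: prior edges re-weighted by decoder probability
  (attention exists only where an HGT block ran).

All retained weights lie in [0, 1]; layers export as TSV and round-trip
through the edge-list reader.

## Multilayer random walk

Nodes of the three layers form one state space. Edge weights populate a
column-stochastic transition matrix; at a node with both within-layer
and cross-layer out-edges the mass is split 0.5/0.5 between the groups
before edge-level normalization (configurable; the exact published
scheme is not specified in the main text). Forward walks use TF→CRE→TG
(within-layer edges bidirectional); reverse walks transpose every
block. Dangling nodes restart: the solver redirects their mass to the
seed distribution, keeping Σs = 1 at every iteration. The fixed point
of `s = (1−β)Ws + βs₀` (β = 0.3, L1 tolerance 1e-8, ≤1000 iterations)
is also available as the closed-form solve
`s = β(I−(1−β)W)^{-1}s₀` for cross-checking.

Driver ranking seeds the reverse walk uniformly on a cluster's
filtered DEGs (log2FC > 0.5, FDR < 0.01, pct1−pct2 > 0.3). Cell-type-
specific differential expression enters twice: transition weights are
multiplied by `(1 + |log2FC|)` of DEG endpoints, and the final scores
of the requested layer are scaled by the same factor for layer nodes in
the filtered table. The second application is necessary because
column normalization cancels any multiplicative weighting wherever a
node has a single out-edge — exactly the argmax-retained TF–CRE
columns. Ties in all rankings break lexicographically.

## Masked expression networks and perturbation

For a gene, retained CREs are those reaching it via CRE–TG directly or
through one CRE–CRE hop; retained TFs are those wired to a retained
CRE. The network is input → TF–CRE masked layer (each CRE unit also
receives its own accessibility through a trainable gain) → CRE–CRE
masked layer (self-connections pass units through) → masked linear
readout. Leaky ReLU (slope 0.01) replaces ReLU between the masked
layers: the readout path is often 1–3 units wide and plain ReLU units
die irrecoverably there. Mask-0 weights are exactly zero at all times
(the forward pass multiplies by the mask, so their gradients vanish
identically). TF inputs are standardized with statistics frozen from
the training split; perturbations scale the *raw* inputs, so knockout
maps to the standardized value of zero expression. Accessibility inputs
are randomly dropped (rate 0.3, seeded) during fitting: a CRE's
accessibility and its regulators' expression are collinear by
construction, and without the dropout the fit may place
arbitrary-signed weight on the redundant TF path, making TF
perturbations meaningless. Fitting uses Adam (lr 5e-3, 400 epochs) on a
75/25 metacell split and reports the held-out Pearson correlation.
Predictions are not clamped at zero (the sign of a perturbation
response matters); a clamp flag exists for display. Gene-specific
networks keep connections with |weight| > 0.15.

Perturbation responses are single-pass: inputs are scaled, the network
re-evaluated, and the difference reported; no iterative propagation of
the perturbation through the full graph is performed. A caveat learned
from the noiseless benchmark: when a gene's planted CREs are strongly
correlated, only the *sum* of their readout weights is identified, so
individual CRE dose–response signs are not meaningful — TF-level
dose–response is, and that is what the tests assert.

The vector-field projection scores each metacell's predicted expression
shift against the expression difference to its k = 15 nearest embedding
neighbors (Pearson), softmax-normalizes the scores, takes the weighted
mean of neighbor directions and subtracts the uniform-kernel mean, so
an uninformative shift yields exactly zero displacement.

## Co-CRE modules and enrichment

Louvain (resolution 1.0, seeded node order) on the weighted CRE–CRE
layer; the reported modularity is computed on the same graph. Hubs:
endpoints of the global top-N pairs (network hubs, N = 100 default),
per-module top-N pairs (module hubs), and top weighted degree (degree
hubs, N = 50). Locus enrichment is the fold ratio of overlap fractions
(hubs vs all CREs) with an empirical p-value from seeded permutations
of equally sized CRE sets (default 1000; the add-one estimator, so the
smallest attainable p is 1/(n+1)). The statistic is deliberately
simple and fully specified here; it is comparative, not claimed
identical to any published enrichment score. Hub-CRE-regulated genes
are those with a TSS within the half-open window
`[start − 2 Mb, end + 2 Mb)` of any hub CRE, clipped at zero.

## Synthetic benchmark

Defaults: 20 TFs, 200 CREs, 100 TGs, 200 metacells, 3 clusters, decoy
multiplier 5 (2 for CRE–TG), noise sd 0.3, seed 7. TF log-expression is
cluster-specific lognormal: per-(TF, cluster) means (sd 0.5 around a
per-TF base), plus 4 shared latent cell-state factors for
within-cluster covariation (loading sd 0.35) and iid noise (sd 0.2).
The latent factors matter: metacell profiles in real data vary along a
low-dimensional state manifold, and it is exactly this low-rank
covariation that a 16-dimensional embedding can represent; with purely
iid per-cell noise the planted correlations would be information-
theoretically invisible to the model. Each cluster has a master TF
upregulated 4-fold in its own cluster (and exempt from random cluster
shifts — the upregulation *is* its cluster identity), driving 10
dedicated CREs that in turn drive 8 dedicated TGs per cluster.
Accessibility is a logistic function of the regulators' standardized
expression, coupled across planted CRE–CRE pairs by averaging, plus
noise, clipped to [0, 1]. TG expression is linear in the planted
accessibilities with an intercept that keeps it non-negative, so at
zero noise every gene is exactly reconstructable. DEGs (for TGs *and*
TFs) come from rank-sum tests with Benjamini–Hochberg correction.
GWAS-like loci are planted inside 70% of the designated hub CREs plus
~5% background; the 2-D embedding is a PCA of TG expression.

What passing these tests shows: the full chain — labeling, encoding,
extraction, walking, masked prediction, perturbation — recovers planted
structure under realistic noise, at desk scale, deterministically. What
it does not show: performance against experimental ChIP/Hi-C truth,
robustness to batch effects, read-level sparsity, doublets, or genome-
scale inputs; the generator's clusters are balanced and its decoys
unstructured beyond genomic placement, both kinder than real data.

## Problem sizes and determinism

All shipped analyses run on the 20/200/100-node, 200-metacell system:
training ≈ 40 s (5 restarts), the full test suite ≈ 1 min, the
acceptance script ≈ 1 min on one CPU. Every stochastic step draws from
an explicit seed; the pipeline writes a config stamp per stage,
re-running a completed stage is a no-op unless forced, and two runs
with the same seed produce byte-identical metric files.
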