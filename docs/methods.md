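# Methods

This note records the model and data-generation choices behind the package,
the parameters that matter, and the numerical decisions that were genuinely
open.

## Problem and model

Given paired measurements `X_g` (cells x genes RNA counts) and `X_p`
(cells x proteins surface levels), the package learns `f_theta` minimizing
the mean squared error of `X̂_p = f_theta(X_g)`. The hypothesis class is a
heterogeneous-graph network over three node types:

* **Graph.** Within-modality blocks `Ag`, `Ap` come from a knowledge base of
  weighted edges (confidence scores in (0, 1], kept as weights; no score
  threshold by default, `min_score` configurable). External IDs are resolved
  via an alias map; an ID matching several display names duplicates the edge
  onto all of them (coverage is preferred over precision; multiplicity is
  logged). Duplicate pairs keep the maximum weight, self-loops are removed,
  and features absent from the knowledge base remain isolated nodes — node
  counts are fixed by the dataset, never by knowledge-base coverage; the
  global attention block is what lets uncovered features still exchange
  information. `S` is binary symbol matching (compound names split on the
  last underscore). `A_RNA[c,g] = log1p(scale * count / total)` with
  `scale = 1e4`, so zero counts carry no edge and rows are invariant to
  library size.
* **Features.** Cells: SVD scores `U·Σ` of the library-size-normalized,
  `log1p`-transformed, per-gene-centered matrix. Centering is per gene
  (per-cell centering would destroy the library-size invariance the
  normalization just established). The SVD is a dense LAPACK decomposition:
  at the problem sizes this package targets there is no benefit to a
  randomized solver, and determinism is free. Genes: `X̄ᵀ h_c⁰` (normalized
  counts as weights). Target-modality nodes: a seeded index-keyed embedding
  table, learned with the rest of the model.
* **Towers.** Gene/protein towers are graph-transformer layers
  `h ← MLP(GNN(h, A) + Attn(h))`: one degree-normalized weighted
  message-passing convolution in parallel with global softmax attention
  (values are the input embeddings; an output projection closes the branch),
  summed, then a 2-layer MLP (hidden width `2·d`, GELU). No extra residual
  is added around the MLP — the update is implemented exactly as the sum of
  the two branches through the MLP; the cell row's `FC(h_c)` term and the
  bridge messages already provide skip paths. The cell tower uses
  kernelized linear attention (positive random features, one fixed seeded
  draw per model instance; optional per-forward redraw) computed in the
  factored order `D̂⁻¹ Q′(K′ᵀ h)` so no cells x cells matrix ever exists.
  A shared detached offset stabilizes the feature exponentials; it cancels
  exactly in the normalization. Linear attention is used for cells only —
  gene and protein sets are small enough for exact attention.
* **Bridges.** GraphSAGE: neighborhood mean (optionally weighted by the
  block, or a max-pool aggregator behind `sage_aggregator="pool"`), concat
  with the destination embedding, linear update, then per-node L2
  normalization (`sage_norm`, on by default).
* **Fusion.** `concurrent` (default): towers and bridges read the same
  layer-ℓ states and their outputs are summed. `gnn_first`: bridge messages
  are added to the inputs before the tower. `mixed`: concurrent for
  gene/protein nodes, GNN-first for cells.
* **Readout.** Concatenated per-layer cell embeddings through one final
  linear layer. Only cell states feed predictions.

### Depth and information flow

Because the readout is cell-only and all updates within a layer are
concurrent, information needs one layer per bridge hop: gene-tower outputs
reach predictions from depth L >= 2, protein-tower outputs from L >= 3
(protein -> gene -> cell). At the default L = 2 the protein *embeddings*
still influence predictions (through the layer-0 protein->gene bridge), but
the protein transformer itself cannot; its final-layer instances receive no
gradient. This is a property of the printed update equations, not a bug;
the wiring tests therefore assert gradient flow per functional parameter
group at L = 3. Similarly, exact batching-invariance of predictions holds
only when no cross-cell path is active (L = 1 with the cell transformer
ablated); in all other configurations attention and the cell->gene bridge
couple cells within a batch, so mini-batching is a training-time
approximation, as it is for any transformer trained on batches of tokens.

### Ablations

"Keeping only one transformer" removes the attention branch of the other
towers: an ablated gene/protein tower becomes `MLP(GNN(h, A))`, an ablated
cell tower drops its attention+MLP block entirely (the `FC` skip and the
bridges remain). `no_transformers` is then a pure GNN on the same graph —
the natural GNN-prior baseline. The ablation-only graph variants add a
cosine k-NN cell-cell block and/or a cell-protein block weighted by
measured target levels; the latter deliberately leaks the target for
training cells (held-out cells keep empty rows) to demonstrate the
overfitting failure mode. In the ADT->GEX direction the roles swap: cells
connect to protein nodes through measured protein levels, gene nodes become
the learnable target tower, and any cell-gene edges are rejected as target
leakage.

## Positional encodings

Laplacian PE: eigenvectors of `I − D^{-1/2} A D^{-1/2}` for the k smallest
eigenvalues above `1e-8` (one trivial mode per connected component),
computed densely on the non-isolated subgraph, unit-norm columns, sign fixed
so the largest-magnitude entry (first on ties) is positive; degenerate
blocks keep ascending index order. Random-walk PE: diagonal of powers of
`A D^{-1}`. Both use edge weights by default (`binarize` switch), give
isolated nodes zero rows, zero-pad when fewer than k non-trivial pairs
exist, and default to `k = 8` (an unconstrained choice, exposed in config).
The encodings enter through a zero-initialized learned projection, so a
freshly built model is exactly PE-free until training moves those weights.

## Synthetic data

The generator emulates the statistical shape of CITE-seq data:

* RNA: negative binomial (gamma-Poisson) with mean
  `softplus(Z Gᵀ) · library_size`, `Z` a latent cell state
  (`n_latent = 10`), lognormal library sizes (`log_mean 8.5`, `log_sd
  0.35`), dispersion 2.0. A single global multiplier on the means is
  solved by bisection so the expected zero fraction hits
  `rna_zero_rate_target` (default 0.75, configurable — public datasets vary
  widely in zero rate and no canonical value exists); an unreachable target
  warns and reports the achieved rate.
* Proteins: `W · log1p(1e4 · count/total)` per cell with `W` sparse
  (5 driver genes per protein, the first driver lending the protein its
  symbol — which is what creates the gene->protein encoding links), plus an
  additive per-batch shift (3 batches, sd 0.3) and Gaussian noise
  (sd 0.1). Proteins are linear in *log-normalized* RNA, matching the
  model's own preprocessing, so recovery is well-posed: with noise off and
  one batch, a linear regression on driver genes is exact by construction.
* Knowledge base: true gene edges are the strongest |cosine| pairs of the
  loading rows; protein edges share driver genes (Jaccard weights). Only a
  `kg_coverage` fraction of features (rounded, exact by construction)
  receive an external ID whose alias list contains their display name;
  uncovered features get decoy aliases only. A low-confidence ring among
  covered features guarantees each appears in at least one edge, so ID
  resolution recovers exactly the covered set.

What the generator does **not** emulate: real pathway topology, ambient
RNA/doublets, nonlinear gene->protein regulation, or batch effects on the
RNA counts themselves. Passing the recovery tests therefore shows the
architecture and training loop can extract a sparse linear signal through
the graph machinery under realistic sparsity — not that it matches
state-of-the-art accuracy on real CITE-seq data.

## Training and evaluation

Adam (lr `1e-3` by default; the desk-scale experiments in this repository
use `3e-3`, which converges faster at these matrix sizes), MSE loss,
80/20 train/validation split stratified by batch when batch labels exist,
mini-batches of up to 8000 cells (full-batch at desk scale), best-validation
checkpoint, early stopping on validation RMSE with patience 10 (experiments
here use longer patience since epochs are cheap). Metrics: RMSE and MAE
over all entries, mean per-cell Pearson (constant rows contribute 0 and are
counted), per-protein column-wise RMSE. The experiment-grid driver varies
exactly one axis (PE kind, fusion, graph variant, or ablation) over a list
of seeds and reports mean +/- std per setting.

## Problem sizes

The package's experiments run on a single CPU at deliberately desk-scale
sizes: the standard recovery dataset is 1,000 cells x 200 genes x 12
proteins with `d_hidden = 64`, `L = 2`, kernel dimension `r = 64`, and
full-rank SVD features (`d0 = 200` — with a 200-gene panel truncation would
only discard signal; the rank-128 default exists for panels with tens of
thousands of genes). Grids and unit fixtures are smaller. The numpy
autodiff engine handles these sizes in seconds per training run; the
architecture itself (linear attention, cell mini-batching) is what scales
to competition-sized data under a framework with GPU support.

## Known limitations

* Multi-head attention is implemented for the softmax towers; the linear
  cell attention is single-head.
* The pool SAGE aggregator is a reference implementation (per-destination
  Python loop); mean aggregation is the fast path.
* Eigenvector-based PEs are only permutation-equivariant up to sign/rotation
  within degenerate eigenvalue blocks; the deterministic sign and ordering
  rules make results reproducible but are still a convention.
* `svd_reduce` accepts a seed for interface stability though the dense
  decomposition ignores it.
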