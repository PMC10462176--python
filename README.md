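# scmoformer

Multimodal single-cell experiments such as CITE-seq measure gene expression
(GEX) and surface-protein abundance (ADT) in the same cells. A recurring
analysis task is **modality prediction**: learn a map `f_theta` with
`X̂_p = f_theta(X_g)` from paired training cells, so protein levels can be
inferred for cells where only RNA was measured. This package implements a
heterogeneous-graph multimodal transformer for that task, together with a
seeded synthetic-data generator that makes every stage testable end to end
without external downloads.

## The model

Cells, genes and proteins are the three node types of one heterogeneous
graph with block adjacency (node order `[proteins | genes | cells]`)

```
A = [ Ap    Sᵀ      0     ]
    [ S     Ag      A_RNAᵀ]
    [ 0     A_RNA   0     ]
```

where `Ap` / `Ag` are protein–protein and gene–gene interaction graphs taken
from a STRING-style knowledge base (combined confidence scores as weights,
external IDs resolved to dataset display names through an alias map),
`S[g,p] = 1` iff gene *g* encodes protein *p* (symbol match), and
`A_RNA[c,g] = ln(1 + 10⁴ · count/total)` links each cell to its expressed
genes. There is deliberately no cell–cell block (attention learns those
relations) and no cell–protein block (it would leak the prediction target).

Each node type gets its own tower, bridged by GraphSAGE message passing
(`MPG`). Per layer ℓ:

```
h_g ← GT_g(h_g, Ag) + MPG_{p→g}(h_p) + MPG_{c→g}(h_c)
h_c ← Trans_c(h_c)  + MPG_{g→c}(h_g) + FC(h_c)
h_p ← GT_p(h_p, Ap) + MPG_{g→p}(h_g)
```

`GT` is a graph-transformer layer: a degree-normalized message-passing block
over the knowledge graph plus a global softmax attention block, computed in
parallel, summed and passed through a 2-layer MLP. Gene/protein nodes can
additionally carry Laplacian or random-walk positional encodings. `Trans_c`
is a transformer over cells with **kernelized linear attention**
(`D̂⁻¹ Q′(K′ᵀ h)` with positive random features `φ(x) = exp(Wx − ‖x‖²/2)/√r`),
so its cost is linear rather than quadratic in the number of cells. The
prediction head concatenates the cell embeddings of all `L` layers and
applies one fully connected layer; training minimizes the MSE
`(1/(Np·Nc)) Σ (X_p − X̂_p)²` with Adam. Alternative fusion orders
(GNN-first, mixed), single-transformer ablations, the reverse ADT→GEX
direction and the ablation-only cell–cell / cell–protein graph variants are
all configuration switches.

The network runs on a small numpy reverse-mode autodiff engine bundled with
the package (`scmoformer.autodiff`); there is no deep-learning framework
dependency.

## Worked example

```python
from scmoformer import SimConfig
from scmoformer.model import ModelConfig
from scmoformer.pipeline import fit, prepare_synthetic
from scmoformer.train_eval import TrainConfig, evaluate

sim = SimConfig(n_cells=400, n_genes=80, n_proteins=8, seed=0)
prepared, truth = prepare_synthetic(sim, d0=80, d_emb=48)
result = fit(prepared,
             ModelConfig(L=2, d_hidden=48, attention={"kind": "linear", "r": 48}),
             TrainConfig(epochs=150, learning_rate=3e-3, early_stop_patience=30))
report = evaluate(result.model, prepared.graph, prepared.feats,
                  prepared.target, cell_idx=result.val_idx)
```

Running this (`python examples/05_train_and_evaluate.py`) prints:

```
trained 121 epochs in 10s (best epoch 90)
validation RMSE 1.990  MAE 1.558  per-cell Pearson 0.964
per-protein-mean baseline RMSE 6.544
```

The synthetic proteins are a sparse linear function of log-normalized driver
genes plus batch shifts and noise, so a per-cell Pearson of 0.96 means the
model recovered each cell's protein profile almost exactly up to scale — the
Pearson metric is invariant to the additive per-batch shifts, unlike RMSE,
which is why both are reported. The baseline predicts every cell as the
per-protein training mean; beating it by 3x shows the model uses
cell-specific expression, not just protein marginals.

The `examples/` directory has one short script per capability (simulation,
graph assembly, positional encodings, linear attention, training,
experiment grids), and the same stages are exposed as a thin CLI:
`scmoformer simulate | build-graph | train | predict | eval | grid`.

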