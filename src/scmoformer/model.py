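"""The multimodal transformer network.

Three towers process the three node types: gene and protein nodes go through
graph-transformer layers (a message-passing GNN block over the knowledge
graph plus a global softmax attention block, computed in parallel, summed and
passed through a 2-layer MLP), while cell nodes go through a kernelized
linear-attention transformer whose cost is linear in the number of cells.
GraphSAGE-style message-passing bridges carry information across modalities:
between genes and proteins over the encoding links S, and between cells and
the source modality over the expression-derived bipartite block.  Per layer,

    h_g <- GT_g(h_g, Ag) + MPG_{p->g}(h_p) + MPG_{c->g}(h_c)
    h_c <- Trans_c(h_c)  + MPG_{g->c}(h_g) + FC(h_c)
    h_p <- GT_p(h_p, Ap) + MPG_{g->p}(h_g)

(the "concurrent" fusion; "gnn_first" sums bridge messages into the inputs
before the tower transformer, "mixed" applies gnn_first to cells only).
The prediction head concatenates the cell embeddings of all L layers and
applies one final fully connected layer; training minimizes mean squared
error against the target modality.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, asdict

import numpy as np
import scipy.sparse as sp

from . import autodiff as ad
from .autodiff import Tensor
from .knowledge_graph import HeteroGraph
from .preprocess import NodeFeatures, init_protein_features

CHECKPOINT_VERSION = "scmoformer-ckpt-1"

FUSIONS = ("concurrent", "gnn_first", "mixed")
ABLATIONS = ("full", "cell_only", "gene_only", "protein_only", "no_transformers")
DIRECTIONS = ("gex2adt", "adt2gex")


@dataclass
class PEConfig:
    kind: str = "none"          # laplacian | random_walk | none
    k: int = 8
    binarize: bool = False


@dataclass
class AttnConfig:
    kind: str = "linear"        # cell attention: linear | softmax
    r: int = 64                 # kernel feature dimension
    heads: int = 1              # tower softmax attention heads
    seed: int = 0               # random-feature draw
    redraw: bool = False        # redraw features each forward pass


@dataclass
class ModelConfig:
    L: int = 2
    d_hidden: int = 512
    pe: PEConfig = field(default_factory=PEConfig)
    attention: AttnConfig = field(default_factory=AttnConfig)
    fusion: str = "concurrent"
    sage_aggregator: str = "mean"       # mean | pool
    dropout: float = 0.1
    use_edge_weights: bool = True
    sage_norm: bool = True
    ablation: str = "full"
    direction: str = "gex2adt"
    seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.pe, dict):
            self.pe = PEConfig(**self.pe)
        if isinstance(self.attention, dict):
            self.attention = AttnConfig(**self.attention)
        if self.L < 1:
            raise ValueError("L must be >= 1")
        if self.fusion not in FUSIONS:
            raise ValueError(f"fusion must be one of {FUSIONS}")
        if self.ablation not in ABLATIONS:
            raise ValueError(f"ablation must be one of {ABLATIONS}")
        if self.direction not in DIRECTIONS:
            raise ValueError(f"direction must be one of {DIRECTIONS}")
        if self.sage_aggregator not in ("mean", "pool"):
            raise ValueError("sage_aggregator must be 'mean' or 'pool'")
        if self.attention.kind == "linear" and self.attention.heads != 1:
            raise ValueError("linear cell attention is single-head")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        return cls(**d)


@dataclass
class LayerState:
    """Per-layer embeddings captured during a forward pass."""

    h_gene: list[np.ndarray] = field(default_factory=list)
    h_cell: list[np.ndarray] = field(default_factory=list)
    h_protein: list[np.ndarray] = field(default_factory=list)


# ---------------------------------------------------------------------------
# parameterized building blocks
# ---------------------------------------------------------------------------

class Module:
    def __init__(self) -> None:
        self._params: dict[str, Tensor] = {}
        self._children: dict[str, "Module"] = {}

    def add_param(self, name: str, value: np.ndarray) -> Tensor:
        t = Tensor(value, requires_grad=True, name=name)
        self._params[name] = t
        return t

    def add_child(self, name: str, module: "Module") -> "Module":
        self._children[name] = module
        return module

    def parameters(self, prefix: str = "") -> dict[str, Tensor]:
        out = {prefix + k: v for k, v in self._params.items()}
        for name, child in self._children.items():
            out.update(child.parameters(prefix + name + "."))
        return out


class Linear(Module):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator,
                 zero_init: bool = False):
        super().__init__()
        if zero_init:
            W = np.zeros((d_in, d_out))
        else:
            W = rng.normal(scale=1.0 / np.sqrt(d_in), size=(d_in, d_out))
        self.W = self.add_param("W", W)
        self.b = self.add_param("b", np.zeros(d_out))

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.W + self.b

    def zero_(self) -> None:
        self.W.data[:] = 0.0
        self.b.data[:] = 0.0


class MLP(Module):
    """2-layer MLP, hidden width 2*d, GELU activation."""

    def __init__(self, d: int, rng: np.random.Generator):
        super().__init__()
        self.fc1 = self.add_child("fc1", Linear(d, 2 * d, rng))
        self.fc2 = self.add_child("fc2", Linear(2 * d, d, rng))

    def __call__(self, x: Tensor) -> Tensor:
        return self.fc2(ad.gelu(self.fc1(x)))


def normalize_adjacency(A: sp.spmatrix, use_weights: bool) -> sp.csr_matrix:
    """Symmetric degree normalization D^{-1/2} A D^{-1/2}; isolated rows stay 0."""
    A = sp.csr_matrix(A, dtype=float)
    if not use_weights and A.nnz:
        A = sp.csr_matrix((np.ones_like(A.data), A.indices, A.indptr),
                          shape=A.shape)
    deg = np.asarray(A.sum(axis=1)).ravel()
    inv = np.where(deg > 0, 1.0 / np.sqrt(np.where(deg > 0, deg, 1.0)), 0.0)
    D = sp.diags(inv)
    return sp.csr_matrix(D @ A @ D)


def row_normalize(B: sp.spmatrix, use_weights: bool) -> sp.csr_matrix:
    """Row-stochastic neighborhood averaging operator (zero rows preserved)."""
    B = sp.csr_matrix(B, dtype=float)
    if not use_weights and B.nnz:
        B = sp.csr_matrix((np.ones_like(B.data), B.indices, B.indptr),
                          shape=B.shape)
    s = np.asarray(B.sum(axis=1)).ravel()
    inv = np.where(s > 0, 1.0 / np.where(s > 0, s, 1.0), 0.0)
    return sp.csr_matrix(sp.diags(inv) @ B)


class GNNBlock(Module):
    """One degree-normalized weighted message-passing convolution."""

    def __init__(self, d: int, rng: np.random.Generator, use_weights: bool):
        super().__init__()
        self.lin = self.add_child("lin", Linear(d, d, rng))
        self.use_weights = use_weights

    def __call__(self, h: Tensor, A: sp.spmatrix) -> Tensor:
        return ad.spmm(normalize_adjacency(A, self.use_weights), self.lin(h))

    def zero_(self) -> None:
        self.lin.zero_()


class SoftmaxAttnBlock(Module):
    """Global scaled dot-product self-attention with an output projection.

    Values are the input embeddings themselves; multiple heads split the
    embedding columns.  Zeroing the output projection silences the branch.
    """

    def __init__(self, d: int, rng: np.random.Generator, heads: int = 1):
        super().__init__()
        if d % heads:
            raise ValueError(f"d_hidden={d} not divisible by heads={heads}")
        self.heads = heads
        self.wq = self.add_child("wq", Linear(d, d, rng))
        self.wk = self.add_child("wk", Linear(d, d, rng))
        self.wo = self.add_child("wo", Linear(d, d, rng))

    def __call__(self, h: Tensor) -> Tensor:
        Q, K = self.wq(h), self.wk(h)
        dh = h.shape[1] // self.heads
        outs = []
        for m in range(self.heads):
            sl = slice(m * dh, (m + 1) * dh)
            Qm = Tensor(Q.data[:, sl], parents=(Q,))
            Qm._backward = _slice_bw(Q, sl)
            Km = Tensor(K.data[:, sl], parents=(K,))
            Km._backward = _slice_bw(K, sl)
            hm = Tensor(h.data[:, sl], parents=(h,))
            hm._backward = _slice_bw(h, sl)
            scores = (Qm @ Km.t()) * (1.0 / np.sqrt(dh))
            outs.append(ad.softmax_rows(scores) @ hm)
        cat = outs[0] if self.heads == 1 else ad.concat_cols(outs)
        return self.wo(cat)

    def zero_(self) -> None:
        self.wo.zero_()


def _slice_bw(parent: Tensor, sl: slice):
    def bw(g):
        full = np.zeros_like(parent.data)
        full[:, sl] = g
        parent._accumulate(full)
    return bw


class LinearAttnBlock(Module):
    """Kernelized (Performer-style) self-attention for the cell tower.

    The positive random-feature matrix is drawn once per model instance
    (seeded); optionally redrawn each forward pass.  The factored order
    ``D^{-1} Q'(K'^T h)`` keeps cost linear in the number of cells.
    """

    def __init__(self, d: int, r: int, rng: np.random.Generator,
                 feature_seed: int, redraw: bool = False):
        super().__init__()
        self.wq = self.add_child("wq", Linear(d, d, rng))
        self.wk = self.add_child("wk", Linear(d, d, rng))
        self.wo = self.add_child("wo", Linear(d, d, rng))
        self.r, self.d = r, d
        self.feature_seed = feature_seed
        self.redraw = redraw
        self._Wf = np.random.default_rng(feature_seed).standard_normal((r, d))
        self._redraw_count = 0

    def _features(self) -> np.ndarray:
        if self.redraw:
            self._redraw_count += 1
            return np.random.default_rng(
                self.feature_seed + self._redraw_count).standard_normal(
                    (self.r, self.d))
        return self._Wf

    def __call__(self, h: Tensor) -> Tensor:
        scale = self.d ** -0.25
        Q = self.wq(h) * scale
        K = self.wk(h) * scale
        Wf = Tensor(self._features())
        expQ = Q @ Wf.t() - (Q * Q).sum(axis=1, keepdims=True) * 0.5
        expK = K @ Wf.t() - (K * K).sum(axis=1, keepdims=True) * 0.5
        # a shared detached offset cancels in the normalization but keeps exp finite
        c = float(max(expQ.data.max(), expK.data.max()))
        Qp = (expQ - c).exp()
        Kp = (expK - c).exp()
        ones = Tensor(np.ones((h.shape[0], 1)))
        denom = Qp @ (Kp.t() @ ones)
        context = Kp.t() @ h
        return self.wo((Qp @ context) / denom)

    def zero_(self) -> None:
        self.wo.zero_()


class GraphTransformerLayer(Module):
    """GNN block + global attention in parallel, summed, then a 2-layer MLP.

    ``use_attention=False`` reduces the layer to its message-passing half
    (used by the single-transformer ablations and the GNN-only baseline).
    """

    def __init__(self, d: int, rng: np.random.Generator, heads: int,
                 use_weights: bool, use_attention: bool = True):
        super().__init__()
        self.gnn = self.add_child("gnn", GNNBlock(d, rng, use_weights))
        self.use_attention = use_attention
        if use_attention:
            self.attn = self.add_child("attn", SoftmaxAttnBlock(d, rng, heads))
        self.mlp = self.add_child("mlp", MLP(d, rng))

    def __call__(self, h: Tensor, A: sp.spmatrix) -> Tensor:
        hm = self.gnn(h, A)
        if self.use_attention:
            hm = hm + self.attn(h)
        return self.mlp(hm)


class CellTransformerLayer(Module):
    """Attention (linear or softmax) over cells followed by the MLP."""

    def __init__(self, d: int, rng: np.random.Generator, cfg: AttnConfig,
                 layer_index: int):
        super().__init__()
        if cfg.kind == "linear":
            self.attn = self.add_child(
                "attn", LinearAttnBlock(d, cfg.r, rng,
                                        feature_seed=cfg.seed + layer_index,
                                        redraw=cfg.redraw))
        elif cfg.kind == "softmax":
            self.attn = self.add_child("attn", SoftmaxAttnBlock(d, rng, cfg.heads))
        else:
            raise ValueError(f"unknown cell attention kind {cfg.kind!r}")
        self.mlp = self.add_child("mlp", MLP(d, rng))

    def __call__(self, h: Tensor) -> Tensor:
        return self.mlp(self.attn(h))


class SAGEBridge(Module):
    """GraphSAGE message passing across one bipartite block.

    Aggregates source-node embeddings over the neighborhoods given by B
    (mean by default, optionally weighted by B, or elementwise max after a
    learned projection for the 'pool' aggregator), concatenates the summary
    with the destination embedding, applies a linear update and L2-normalizes
    each node.  Destinations with no neighbors get a zero summary.
    """

    def __init__(self, d: int, rng: np.random.Generator,
                 aggregator: str = "mean", use_weights: bool = True,
                 norm: bool = True):
        super().__init__()
        self.aggregator = aggregator
        self.use_weights = use_weights
        self.norm = norm
        if aggregator == "pool":
            self.pool = self.add_child("pool", Linear(d, d, rng))
        self.update = self.add_child("update", Linear(2 * d, d, rng))

    def neighborhood(self, h_src: Tensor, B: sp.spmatrix) -> Tensor:
        if self.aggregator == "mean":
            return ad.spmm(row_normalize(B, self.use_weights), h_src)
        return _neighbor_max(sp.csr_matrix(B), ad.relu(self.pool(h_src)))

    def __call__(self, h_dst: Tensor, h_src: Tensor, B: sp.spmatrix) -> Tensor:
        hn = self.neighborhood(h_src, B)
        out = self.update(ad.concat_cols([h_dst, hn]))
        return ad.l2_normalize_rows(out) if self.norm else out

    def zero_(self) -> None:
        self.update.zero_()


def _neighbor_max(B: sp.csr_matrix, x: Tensor) -> Tensor:
    """Elementwise max over each destination's neighbors (SAGE-pool)."""
    n_dst, d = B.shape[0], x.data.shape[1]
    out = np.zeros((n_dst, d))
    arg = np.full((n_dst, d), -1, dtype=np.int64)
    for i in range(n_dst):
        nbrs = B.indices[B.indptr[i]:B.indptr[i + 1]]
        if nbrs.size == 0:
            continue
        vals = x.data[nbrs]
        idx = np.argmax(vals, axis=0)
        out[i] = vals[idx, np.arange(d)]
        arg[i] = nbrs[idx]
    t = Tensor(out, parents=(x,))

    def bw(g):
        gx = np.zeros_like(x.data)
        for i in range(n_dst):
            for j in range(d):
                if arg[i, j] >= 0:
                    gx[arg[i, j], j] += g[i, j]
        x._accumulate(gx)
    t._backward = bw
    return t


class PEInjector(Module):
    """Adds a learned projection of positional encodings; identity at init."""

    def __init__(self, k: int, d: int, rng: np.random.Generator):
        super().__init__()
        self.proj = self.add_child("proj", Linear(k, d, rng, zero_init=True))

    def __call__(self, h: Tensor, pe: np.ndarray | None) -> Tensor:
        if pe is None or pe.shape[1] == 0:
            return h
        return h + self.proj(Tensor(pe))


# ---------------------------------------------------------------------------
# the full network
# ---------------------------------------------------------------------------

class ScMoFormer(Module):
    """End-to-end network mapping the source modality to the target one.

    Parameters
    ----------
    config
        Architecture configuration.
    d0_cell, d0_src
        Input feature widths of cell and source-tower nodes.
    n_target_nodes
        Number of target-modality nodes (index-keyed learnable embeddings).
    n_out
        Output width of the prediction head (number of target features).
    """

    def __init__(self, config: ModelConfig, d0_cell: int, d0_src: int,
                 n_target_nodes: int, n_out: int,
                 gene_names: list[str] | None = None,
                 protein_names: list[str] | None = None):
        super().__init__()
        cfg = config
        self.config = cfg
        self.gene_names = gene_names or []
        self.protein_names = protein_names or []
        self.d0_cell, self.d0_src = d0_cell, d0_src
        self.n_target_nodes, self.n_out = n_target_nodes, n_out
        rng = np.random.default_rng(cfg.seed)
        d = cfg.d_hidden

        self.proj_cell = self.add_child("proj_cell", Linear(d0_cell, d, rng))
        self.proj_src = self.add_child("proj_src", Linear(d0_src, d, rng))
        self.emb_target = self.add_param(
            "emb_target", init_protein_features(n_target_nodes, d, seed=cfg.seed))
        if cfg.pe.kind != "none":
            self.pe_gene = self.add_child("pe_gene", PEInjector(cfg.pe.k, d, rng))
            self.pe_protein = self.add_child("pe_protein", PEInjector(cfg.pe.k, d, rng))

        abl = cfg.ablation
        gene_attn = abl in ("full", "gene_only")
        prot_attn = abl in ("full", "protein_only")
        self.use_cell_transformer = abl in ("full", "cell_only")

        self.gt_gene, self.gt_protein, self.trans_cell, self.fc_cell = [], [], [], []
        self.mpg_p2g, self.mpg_g2p, self.mpg_c2src, self.mpg_src2c = [], [], [], []
        self.mpg_c2c, self.mpg_t2c, self.mpg_c2t = [], [], []
        for layer in range(cfg.L):

            def sage():
                return SAGEBridge(d, rng, cfg.sage_aggregator,
                                  cfg.use_edge_weights, cfg.sage_norm)

            self.gt_gene.append(self.add_child(
                f"layer{layer}.gt_gene",
                GraphTransformerLayer(d, rng, cfg.attention.heads,
                                      cfg.use_edge_weights, gene_attn)))
            self.gt_protein.append(self.add_child(
                f"layer{layer}.gt_protein",
                GraphTransformerLayer(d, rng, cfg.attention.heads,
                                      cfg.use_edge_weights, prot_attn)))
            if self.use_cell_transformer:
                self.trans_cell.append(self.add_child(
                    f"layer{layer}.trans_cell",
                    CellTransformerLayer(d, rng, cfg.attention, layer)))
            self.fc_cell.append(self.add_child(f"layer{layer}.fc_cell",
                                               Linear(d, d, rng)))
            self.mpg_p2g.append(self.add_child(f"layer{layer}.mpg_p2g", sage()))
            self.mpg_g2p.append(self.add_child(f"layer{layer}.mpg_g2p", sage()))
            self.mpg_c2src.append(self.add_child(f"layer{layer}.mpg_c2src", sage()))
            self.mpg_src2c.append(self.add_child(f"layer{layer}.mpg_src2c", sage()))
            self.mpg_c2c.append(self.add_child(f"layer{layer}.mpg_c2c", sage()))
            self.mpg_t2c.append(self.add_child(f"layer{layer}.mpg_t2c", sage()))
            self.mpg_c2t.append(self.add_child(f"layer{layer}.mpg_c2t", sage()))

        self.readout = self.add_child("readout", Linear(cfg.L * d, n_out, rng))

    # -- forward -----------------------------------------------------------

    def _bridge_blocks(self, graph: HeteroGraph):
        """Data-derived bipartite blocks for the configured direction."""
        if self.config.direction == "gex2adt":
            return graph.A_RNA, "gene"
        if graph.A_RNA is not None and graph.A_RNA.nnz:
            raise ValueError(
                "adt2gex direction forbids cell-gene edges (target leakage)")
        if graph.A_cell_protein is None:
            raise ValueError("adt2gex direction requires the cell-protein block")
        return graph.A_cell_protein, "protein"

    def forward_tensors(self, graph: HeteroGraph, feats: NodeFeatures,
                        pe_gene: np.ndarray | None = None,
                        pe_protein: np.ndarray | None = None,
                        training: bool = False,
                        rng: np.random.Generator | None = None,
                        ) -> tuple[Tensor, LayerState]:
        cfg = self.config
        B_data, src = self._bridge_blocks(graph)
        drop_rng = rng if training and cfg.dropout > 0 else None

        h_c = self.proj_cell(Tensor(feats.h_cell0))
        if src == "gene":
            h_g = self.proj_src(Tensor(feats.h_gene0))
            h_p = Tensor(self.emb_target.data, parents=(self.emb_target,))
            h_p._backward = lambda g: self.emb_target._accumulate(g)
        else:
            h_p = self.proj_src(Tensor(feats.h_protein0))
            h_g = Tensor(self.emb_target.data, parents=(self.emb_target,))
            h_g._backward = lambda g: self.emb_target._accumulate(g)
        if cfg.pe.kind != "none":
            h_g = self.pe_gene(h_g, pe_gene)
            h_p = self.pe_protein(h_p, pe_protein)

        state = LayerState()
        cell_readouts: list[Tensor] = []
        S = graph.S

        def drop(t: Tensor) -> Tensor:
            return ad.dropout(t, cfg.dropout, drop_rng)

        for layer in range(cfg.L):
            concurrent_gp = cfg.fusion in ("concurrent", "mixed")
            concurrent_c = cfg.fusion == "concurrent"

            msg_p2g = drop(self.mpg_p2g[layer](h_g, h_p, S))
            msg_g2p = drop(self.mpg_g2p[layer](h_p, h_g, S.T))
            if src == "gene":
                msg_c2src = drop(self.mpg_c2src[layer](h_g, h_c, B_data.T))
                msg_src2c = drop(self.mpg_src2c[layer](h_c, h_g, B_data))
            else:
                msg_c2src = drop(self.mpg_c2src[layer](h_p, h_c, B_data.T))
                msg_src2c = drop(self.mpg_src2c[layer](h_c, h_p, B_data))

            extra_c = []
            if graph.A_cell_cell is not None and graph.A_cell_cell.nnz:
                extra_c.append(drop(self.mpg_c2c[layer](
                    h_c, h_c, graph.A_cell_cell)))
            leaky = (cfg.direction == "gex2adt" and
                     graph.A_cell_protein is not None and
                     graph.A_cell_protein.nnz)
            msg_t2c = drop(self.mpg_t2c[layer](h_c, h_p, graph.A_cell_protein)) \
                if leaky else None
            msg_c2t = drop(self.mpg_c2t[layer](h_p, h_c, graph.A_cell_protein.T)) \
                if leaky else None

            # gene tower
            if concurrent_gp:
                bridges_g = [msg_p2g] + ([msg_c2src] if src == "gene" else [])
                g_in = h_g
            else:
                bridges_g = []
                g_in = h_g + msg_p2g
                if src == "gene":
                    g_in = g_in + msg_c2src
            g_next = drop(self.gt_gene[layer](g_in, graph.Ag))
            for m in bridges_g:
                g_next = g_next + m

            # protein tower
            if concurrent_gp:
                bridges_p = [msg_g2p] + ([msg_c2src] if src == "protein" else []) \
                    + ([msg_c2t] if msg_c2t is not None else [])
                p_in = h_p
            else:
                bridges_p = []
                p_in = h_p + msg_g2p
                if src == "protein":
                    p_in = p_in + msg_c2src
                if msg_c2t is not None:
                    p_in = p_in + msg_c2t
            p_next = drop(self.gt_protein[layer](p_in, graph.Ap))
            for m in bridges_p:
                p_next = p_next + m

            # cell tower
            c_bridges = [msg_src2c] + extra_c \
                + ([msg_t2c] if msg_t2c is not None else [])
            if concurrent_c:
                c_in = h_c
                c_terms = list(c_bridges)
            else:
                c_in = h_c
                for m in c_bridges:
                    c_in = c_in + m
                c_terms = []
            c_next = self.fc_cell[layer](h_c)
            if self.use_cell_transformer:
                c_next = c_next + drop(self.trans_cell[layer](c_in))
            for m in c_terms:
                c_next = c_next + m

            h_g, h_c, h_p = g_next, c_next, p_next
            for name, t in (("gene", h_g), ("cell", h_c), ("protein", h_p)):
                if not np.all(np.isfinite(t.data)):
                    raise FloatingPointError(
                        f"non-finite {name} embeddings at layer {layer}")
            state.h_gene.append(h_g.data.copy())
            state.h_cell.append(h_c.data.copy())
            state.h_protein.append(h_p.data.copy())
            cell_readouts.append(h_c)

        concat = cell_readouts[0] if cfg.L == 1 else ad.concat_cols(cell_readouts)
        pred = self.readout(concat)
        return pred, state

    def predict(self, graph: HeteroGraph, feats: NodeFeatures,
                pe_gene: np.ndarray | None = None,
                pe_protein: np.ndarray | None = None) -> np.ndarray:
        pred, _ = self.forward_tensors(graph, feats, pe_gene, pe_protein,
                                       training=False)
        return pred.data

    def forward(self, graph: HeteroGraph, feats: NodeFeatures,
                pe_gene: np.ndarray | None = None,
                pe_protein: np.ndarray | None = None
                ) -> tuple[np.ndarray, LayerState]:
        pred, state = self.forward_tensors(graph, feats, pe_gene, pe_protein)
        return pred.data, state


def mse_loss(pred, target) -> float | Tensor:
    """Mean squared error over all entries; Tensor-aware for training."""
    if isinstance(pred, Tensor):
        t = target if isinstance(target, Tensor) else Tensor(target)
        if pred.shape != t.shape:
            raise ValueError(f"shape mismatch {pred.shape} vs {t.shape}")
        diff = pred - t
        return (diff * diff).mean()
    pred = np.asarray(pred, dtype=float)
    target = np.asarray(target, dtype=float)
    if pred.shape != target.shape:
        raise ValueError(f"shape mismatch {pred.shape} vs {target.shape}")
    return float(np.mean((pred - target) ** 2))


# ---------------------------------------------------------------------------
# persistence
# ---------------------------------------------------------------------------

def save_model(model: ScMoFormer, path: str) -> None:
    """Write parameters (npz) and config + metadata (JSON) under ``path``."""
    os.makedirs(path, exist_ok=True)
    params = model.parameters()
    np.savez(os.path.join(path, "params.npz"),
             **{k: v.data for k, v in params.items()})
    meta = {
        "version": CHECKPOINT_VERSION,
        "config": model.config.to_dict(),
        "d0_cell": model.d0_cell, "d0_src": model.d0_src,
        "n_target_nodes": model.n_target_nodes, "n_out": model.n_out,
        "gene_names": model.gene_names, "protein_names": model.protein_names,
    }
    with open(os.path.join(path, "model.json"), "w") as fh:
        json.dump(meta, fh, indent=1)


def load_model(path: str, gene_names: list[str] | None = None,
               protein_names: list[str] | None = None) -> ScMoFormer:
    """Rebuild a saved model; optionally check feature names against data."""
    with open(os.path.join(path, "model.json")) as fh:
        meta = json.load(fh)
    if meta.get("version") != CHECKPOINT_VERSION:
        raise ValueError(f"checkpoint version {meta.get('version')!r} is not "
                         f"{CHECKPOINT_VERSION!r}")
    if gene_names is not None and list(gene_names) != meta["gene_names"]:
        raise ValueError("gene names do not match the checkpoint")
    if protein_names is not None and list(protein_names) != meta["protein_names"]:
        raise ValueError("protein names do not match the checkpoint")
    model = ScMoFormer(ModelConfig.from_dict(meta["config"]),
                       d0_cell=meta["d0_cell"], d0_src=meta["d0_src"],
                       n_target_nodes=meta["n_target_nodes"],
                       n_out=meta["n_out"],
                       gene_names=meta["gene_names"],
                       protein_names=meta["protein_names"])
    arrays = np.load(os.path.join(path, "params.npz"))
    params = model.parameters()
    for k, t in params.items():
        t.data[:] = arrays[k]
    return model
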