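"""Training loop, metrics, and experiment drivers.

Training minimizes the mean-squared error of the predicted target modality
with Adam, mini-batching over cells (gene/protein nodes and their knowledge
graphs are batch-independent and always kept whole).  Evaluation reports
RMSE and MAE over all matrix entries, the mean per-cell Pearson correlation
(a scale-free metric robust to per-cell batch effects), and per-protein
RMSE.  `run_experiment_grid` sweeps positional encodings, fusion strategies,
graph variants and single-transformer ablations over multiple seeds and
emits a tidy mean +/- std table.
"""

from __future__ import annotations

import copy
import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .autodiff import Adam
from .encodings import compute_pe
from .knowledge_graph import HeteroGraph, build_knn_cell_graph
from .model import ModelConfig, ScMoFormer, mse_loss
from .preprocess import NodeFeatures

logger = logging.getLogger(__name__)


@dataclass
class TrainConfig:
    epochs: int = 100
    learning_rate: float = 1e-3
    weight_decay: float = 0.0
    cell_batch_size: int = 8000
    val_fraction: float = 0.2
    early_stop_patience: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.val_fraction < 1.0:
            raise ValueError("val_fraction must be in (0, 1)")
        if self.cell_batch_size < 1:
            raise ValueError("cell_batch_size must be >= 1")


@dataclass
class EvalReport:
    rmse: float
    mae: float
    corr: float
    per_protein_rmse: dict[str, float]
    n_cells: int
    n_degenerate_cells: int = 0

    def as_dict(self) -> dict:
        return {"rmse": self.rmse, "mae": self.mae, "corr": self.corr,
                "n_cells": self.n_cells,
                "n_degenerate_cells": self.n_degenerate_cells,
                "per_protein_rmse": self.per_protein_rmse}


def minibatch_cells(graph: HeteroGraph, feats: NodeFeatures,
                    batch_idx: np.ndarray) -> tuple[HeteroGraph, NodeFeatures]:
    """Restrict cell nodes to ``batch_idx``; feature graphs are kept whole."""
    batch_idx = np.asarray(batch_idx, dtype=int)
    if batch_idx.size == 0:
        raise ValueError("empty cell batch")
    sub = HeteroGraph(
        protein_names=graph.protein_names, gene_names=graph.gene_names,
        cell_ids=[graph.cell_ids[i] for i in batch_idx],
        Ap=graph.Ap, Ag=graph.Ag, S=graph.S,
        A_RNA=sp.csr_matrix(graph.A_RNA[batch_idx]),
        A_cell_cell=(sp.csr_matrix(graph.A_cell_cell[np.ix_(batch_idx, batch_idx)])
                     if graph.A_cell_cell is not None else None),
        A_cell_protein=(sp.csr_matrix(graph.A_cell_protein[batch_idx])
                        if graph.A_cell_protein is not None else None))
    subfeats = NodeFeatures(h_cell0=feats.h_cell0[batch_idx],
                            h_gene0=feats.h_gene0,
                            h_protein0=feats.h_protein0, d0=feats.d0)
    return sub, subfeats


def train_val_split(n: int, val_fraction: float, rng: np.random.Generator,
                    stratify: np.ndarray | None = None
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Random split, stratified by batch labels when available."""
    if stratify is None:
        perm = rng.permutation(n)
        n_val = max(1, int(round(val_fraction * n)))
        return np.sort(perm[n_val:]), np.sort(perm[:n_val])
    train_idx, val_idx = [], []
    for label in np.unique(stratify):
        members = np.flatnonzero(stratify == label)
        perm = rng.permutation(members)
        n_val = max(1, int(round(val_fraction * members.size)))
        val_idx.extend(perm[:n_val])
        train_idx.extend(perm[n_val:])
    return np.sort(np.array(train_idx)), np.sort(np.array(val_idx))


@dataclass
class TrainResult:
    model: ScMoFormer
    loss_curve: list[float]
    val_rmse_curve: list[float]
    train_idx: np.ndarray
    val_idx: np.ndarray
    best_epoch: int


def _graph_pe(graph: HeteroGraph, config: ModelConfig):
    if config.pe.kind == "none":
        return None, None
    pe_g = compute_pe(graph.Ag, config.pe.kind, config.pe.k, config.pe.binarize)
    pe_p = compute_pe(graph.Ap, config.pe.kind, config.pe.k, config.pe.binarize)
    return pe_g.values, pe_p.values


def train(graph: HeteroGraph, feats: NodeFeatures, target: np.ndarray,
          model_config: ModelConfig, train_config: TrainConfig,
          batch_labels: np.ndarray | None = None,
          log_path: str | None = None) -> TrainResult:
    """Fit the network on an 80/20 (by default) cell split.

    Returns the parameters of the best-validation epoch.  Two calls with
    identical inputs and seeds produce identical loss curves.
    """
    tc, mc = train_config, model_config
    target = np.asarray(target, dtype=float)
    n_cells = target.shape[0]
    rng = np.random.default_rng(tc.seed)
    train_idx, val_idx = train_val_split(n_cells, tc.val_fraction, rng,
                                         stratify=batch_labels)

    n_target_nodes = graph.Ng if mc.direction == "adt2gex" else graph.Np
    d0_src = feats.h_protein0.shape[1] if mc.direction == "adt2gex" \
        else feats.h_gene0.shape[1]
    model = ScMoFormer(mc, d0_cell=feats.h_cell0.shape[1], d0_src=d0_src,
                       n_target_nodes=n_target_nodes, n_out=target.shape[1],
                       gene_names=graph.gene_names,
                       protein_names=graph.protein_names)
    pe_g, pe_p = _graph_pe(graph, mc)
    params = model.parameters()
    opt = Adam(list(params.values()), lr=tc.learning_rate,
               weight_decay=tc.weight_decay)

    val_graph, val_feats = minibatch_cells(graph, feats, val_idx)
    best = {"rmse": np.inf, "epoch": -1, "params": None}
    loss_curve: list[float] = []
    val_curve: list[float] = []
    log_fh = open(log_path, "w") if log_path else None
    try:
        for epoch in range(tc.epochs):
            order = rng.permutation(train_idx)
            epoch_losses = []
            for start in range(0, order.size, tc.cell_batch_size):
                batch = np.sort(order[start:start + tc.cell_batch_size])
                sub, subfeats = minibatch_cells(graph, feats, batch)
                pred, _ = model.forward_tensors(sub, subfeats, pe_g, pe_p,
                                                training=True, rng=rng)
                loss = mse_loss(pred, target[batch])
                if not np.isfinite(loss.data):
                    raise FloatingPointError(f"training diverged at epoch {epoch}")
                opt.zero_grad()
                loss.backward()
                opt.step()
                epoch_losses.append(float(loss.data))
            loss_curve.append(float(np.mean(epoch_losses)))

            val_pred = model.predict(val_graph, val_feats, pe_g, pe_p)
            val_rmse = float(np.sqrt(mse_loss(val_pred, target[val_idx])))
            val_curve.append(val_rmse)
            if log_fh:
                log_fh.write(json.dumps(
                    {"epoch": epoch, "train_mse": loss_curve[-1],
                     "val_rmse": val_rmse, "seed": tc.seed}) + "\n")
            if val_rmse < best["rmse"]:
                best = {"rmse": val_rmse, "epoch": epoch,
                        "params": {k: v.data.copy() for k, v in params.items()}}
            elif epoch - best["epoch"] >= tc.early_stop_patience:
                logger.info("early stop at epoch %d (best %d)", epoch,
                            best["epoch"])
                break
    finally:
        if log_fh:
            log_fh.close()

    if best["params"] is not None:
        for k, t in params.items():
            t.data[:] = best["params"][k]
    return TrainResult(model=model, loss_curve=loss_curve,
                       val_rmse_curve=val_curve, train_idx=train_idx,
                       val_idx=val_idx, best_epoch=best["epoch"])


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def cellwise_pearson(pred: np.ndarray, target: np.ndarray
                     ) -> tuple[np.ndarray, int]:
    """Per-cell Pearson correlation; zero-variance rows score 0 (counted)."""
    p = pred - pred.mean(axis=1, keepdims=True)
    t = target - target.mean(axis=1, keepdims=True)
    sp_ = np.sqrt((p * p).sum(axis=1))
    st = np.sqrt((t * t).sum(axis=1))
    ok = (sp_ > 0) & (st > 0)
    corr = np.zeros(pred.shape[0])
    corr[ok] = (p[ok] * t[ok]).sum(axis=1) / (sp_[ok] * st[ok])
    n_degenerate = int(np.sum(~ok))
    if n_degenerate:
        logger.info("%d constant prediction/target rows scored as 0",
                    n_degenerate)
    return corr, n_degenerate


def compute_metrics(pred: np.ndarray, target: np.ndarray,
                    protein_names: list[str] | None = None) -> EvalReport:
    pred = np.asarray(pred, dtype=float)
    target = np.asarray(target, dtype=float)
    if pred.shape != target.shape:
        raise ValueError(f"shape mismatch {pred.shape} vs {target.shape}")
    rmse = float(np.sqrt(np.mean((pred - target) ** 2)))
    mae = float(np.mean(np.abs(pred - target)))
    corr, n_deg = cellwise_pearson(pred, target)
    names = protein_names or [f"p{j}" for j in range(pred.shape[1])]
    per_protein = {
        name: float(np.sqrt(np.mean((pred[:, j] - target[:, j]) ** 2)))
        for j, name in enumerate(names)}
    return EvalReport(rmse=rmse, mae=mae, corr=float(corr.mean()),
                      per_protein_rmse=per_protein, n_cells=pred.shape[0],
                      n_degenerate_cells=n_deg)


def evaluate(model: ScMoFormer, graph: HeteroGraph, feats: NodeFeatures,
             target: np.ndarray,
             cell_idx: np.ndarray | None = None) -> EvalReport:
    """Predict (optionally on a subset of cells) and score against targets."""
    pe_g, pe_p = _graph_pe(graph, model.config)
    if cell_idx is not None:
        graph, feats = minibatch_cells(graph, feats, cell_idx)
        target = target[cell_idx]
    pred = model.predict(graph, feats, pe_g, pe_p)
    return compute_metrics(pred, np.asarray(target, dtype=float),
                           model.protein_names
                           if model.config.direction == "gex2adt" else None)


def per_protein_mean_baseline(target_train: np.ndarray, n_cells: int
                              ) -> np.ndarray:
    """Predict every cell as the training-set mean of each protein."""
    return np.tile(target_train.mean(axis=0), (n_cells, 1))


# ---------------------------------------------------------------------------
# experiment grids
# ---------------------------------------------------------------------------

GRAPH_VARIANTS = ("neither", "cell_cell", "cell_protein", "both")


def apply_graph_variant(graph: HeteroGraph, feats: NodeFeatures,
                        target: np.ndarray, train_idx: np.ndarray,
                        variant: str, knn_k: int = 5) -> HeteroGraph:
    """Attach the ablation-only cell-cell / cell-protein blocks.

    The cell-protein block carries measured target levels for TRAINING cells
    only (held-out cells keep empty rows) — it exists to demonstrate the
    target-leakage failure mode, not as a modeling recommendation.
    """
    if variant not in GRAPH_VARIANTS:
        raise ValueError(f"variant must be one of {GRAPH_VARIANTS}")
    A_cc = A_cp = None
    if variant in ("cell_cell", "both"):
        A_cc = build_knn_cell_graph(feats.h_cell0, k=knn_k)
    if variant in ("cell_protein", "both"):
        target = np.asarray(target, dtype=float)
        levels = np.zeros_like(target)
        # shift to positive on training rows only; held-out rows stay empty
        lo = target[train_idx].min()
        levels[train_idx] = target[train_idx] - lo + 1e-3
        A_cp = sp.csr_matrix(levels)
    return HeteroGraph(protein_names=graph.protein_names,
                       gene_names=graph.gene_names, cell_ids=graph.cell_ids,
                       Ap=graph.Ap, Ag=graph.Ag, S=graph.S, A_RNA=graph.A_RNA,
                       A_cell_cell=A_cc, A_cell_protein=A_cp)


def run_experiment_grid(grid: dict, graph: HeteroGraph, feats: NodeFeatures,
                        target: np.ndarray, model_config: ModelConfig,
                        train_config: TrainConfig,
                        test_idx: np.ndarray | None = None,
                        batch_labels: np.ndarray | None = None) -> pd.DataFrame:
    """Sweep one model axis over several seeds and tabulate mean +/- std.

    ``grid`` holds exactly one of the keys ``pe_kind``, ``fusion``,
    ``graph_variant`` or ``ablation`` (a list of settings) plus ``seeds``
    (a list of integers).  Each run trains from scratch; metrics are computed
    on ``test_idx`` cells (default: the validation split).
    """
    axes = [k for k in ("pe_kind", "fusion", "graph_variant", "ablation")
            if k in grid]
    if len(axes) != 1:
        raise ValueError(f"grid must vary exactly one axis, got {axes}")
    axis = axes[0]
    seeds = list(grid.get("seeds", [train_config.seed]))
    rows = []
    for setting in grid[axis]:
        metrics = {"rmse": [], "mae": [], "corr": []}
        for seed in seeds:
            mc = copy.deepcopy(model_config)
            tc = copy.deepcopy(train_config)
            mc.seed, tc.seed = seed, seed
            g = graph
            if axis == "pe_kind":
                mc.pe.kind = setting
            elif axis == "fusion":
                mc.fusion = setting
            elif axis == "ablation":
                mc.ablation = setting
            elif axis == "graph_variant":
                rng = np.random.default_rng(seed)
                tr, _ = train_val_split(target.shape[0], tc.val_fraction,
                                        rng, stratify=batch_labels)
                g = apply_graph_variant(graph, feats, target, tr, setting)
            result = train(g, feats, target, mc, tc,
                           batch_labels=batch_labels)
            idx = test_idx if test_idx is not None else result.val_idx
            report = evaluate(result.model, g, feats, target, cell_idx=idx)
            metrics["rmse"].append(report.rmse)
            metrics["mae"].append(report.mae)
            metrics["corr"].append(report.corr)
        row = {axis: setting, "n_runs": len(seeds)}
        for m, vals in metrics.items():
            row[f"{m}_mean"] = float(np.mean(vals))
            row[f"{m}_std"] = float(np.std(vals))
        rows.append(row)
    return pd.DataFrame(rows)
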