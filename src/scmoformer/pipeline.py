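"""High-level composition of the stages: data -> graph -> features -> model.

These helpers wire the individual modules together for the common case of
predicting protein levels from RNA on a dataset accompanied by a partial
knowledge base, and are what the CLI, the examples and the end-to-end tests
run.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import ExpressionMatrix
from .knowledge_graph import (HeteroGraph, IdAliasMap, WeightedEdgeList,
                              build_graph_from_dataset)
from .model import ModelConfig
from .preprocess import NodeFeatures, initialize_node_features
from .simdata import KnowledgeBase, SimConfig, SimTruth, simulate_knowledge_base, simulate_multiome
from .train_eval import TrainConfig, TrainResult, train


@dataclass
class PreparedData:
    graph: HeteroGraph
    feats: NodeFeatures
    target: np.ndarray
    rna: ExpressionMatrix
    protein: ExpressionMatrix
    mapping_report: dict
    batch_labels: np.ndarray | None = None


def prepare_from_matrices(rna: ExpressionMatrix, protein: ExpressionMatrix,
                          gene_edges: WeightedEdgeList,
                          protein_edges: WeightedEdgeList,
                          aliases: IdAliasMap,
                          d0: int = 64, d_emb: int = 64, seed: int = 0,
                          min_score: float = 0.0,
                          batch_labels: np.ndarray | None = None
                          ) -> PreparedData:
    """Resolve the knowledge base, build the graph and initialize features."""
    graph, report = build_graph_from_dataset(
        rna, protein.feature_names, gene_edges, protein_edges, aliases,
        min_score=min_score)
    feats = initialize_node_features(rna, protein.n_features, d0=d0,
                                     d_emb=d_emb, seed=seed)
    return PreparedData(graph=graph, feats=feats, target=protein.toarray(),
                        rna=rna, protein=protein, mapping_report=report,
                        batch_labels=batch_labels)


def kb_edge_lists(kb: KnowledgeBase) -> tuple[WeightedEdgeList,
                                              WeightedEdgeList, IdAliasMap]:
    gene_edges = WeightedEdgeList(
        [(a, b, float(w)) for a, b, w in kb.gene_edges.itertuples(index=False)])
    protein_edges = WeightedEdgeList(
        [(a, b, float(w)) for a, b, w in
         kb.protein_edges.itertuples(index=False)])
    aliases = IdAliasMap({row.external_id: row.aliases.split(",")
                          for row in kb.aliases.itertuples()})
    return gene_edges, protein_edges, aliases


def prepare_synthetic(sim_config: SimConfig, d0: int = 64, d_emb: int = 64
                      ) -> tuple[PreparedData, SimTruth]:
    """One call from a simulation config to model-ready inputs."""
    rna, protein, truth = simulate_multiome(sim_config)
    kb = simulate_knowledge_base(truth, sim_config)
    gene_edges, protein_edges, aliases = kb_edge_lists(kb)
    prepared = prepare_from_matrices(
        rna, protein, gene_edges, protein_edges, aliases,
        d0=d0, d_emb=d_emb, seed=sim_config.seed,
        batch_labels=truth.batch_of_cell if sim_config.n_batches > 1 else None)
    return prepared, truth


def fit(prepared: PreparedData, model_config: ModelConfig,
        train_config: TrainConfig, log_path: str | None = None) -> TrainResult:
    return train(prepared.graph, prepared.feats, prepared.target,
                 model_config, train_config,
                 batch_labels=prepared.batch_labels, log_path=log_path)
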