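import numpy as np
import pytest

from scmoformer.model import ModelConfig, ScMoFormer
from scmoformer.pipeline import prepare_synthetic
from scmoformer.simdata import SimConfig
from scmoformer.train_eval import TrainConfig


@pytest.fixture(scope="session")
def tiny_sim():
    """A small but complete synthetic dataset shared across tests."""
    cfg = SimConfig(n_cells=120, n_genes=40, n_proteins=6, seed=7,
                    protein_noise_sd=0.05, n_batches=2,
                    n_driver_genes_per_protein=4)
    prepared, truth = prepare_synthetic(cfg, d0=30, d_emb=16)
    return cfg, prepared, truth


@pytest.fixture()
def small_model_config():
    return ModelConfig(L=2, d_hidden=16, dropout=0.0,
                       attention={"kind": "linear", "r": 16, "seed": 3},
                       pe={"kind": "none"}, seed=1)


@pytest.fixture()
def quick_train_config():
    return TrainConfig(epochs=5, learning_rate=3e-3, seed=2,
                       early_stop_patience=10, val_fraction=0.25)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def make_model(prepared, config) -> ScMoFormer:
    """Build a model sized for a PreparedData bundle (shared test helper)."""
    return ScMoFormer(config,
                      d0_cell=prepared.feats.h_cell0.shape[1],
                      d0_src=prepared.feats.h_gene0.shape[1],
                      n_target_nodes=prepared.graph.Np,
                      n_out=prepared.target.shape[1],
                      gene_names=prepared.graph.gene_names,
                      protein_names=prepared.graph.protein_names)
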