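"""Mini-batching semantics, metric definitions, training reproducibility and
the experiment-grid driver."""

import numpy as np
import pytest

from scmoformer.model import ModelConfig
from scmoformer.train_eval import (TrainConfig, apply_graph_variant,
                                   cellwise_pearson, compute_metrics,
                                   evaluate, minibatch_cells,
                                   per_protein_mean_baseline,
                                   run_experiment_grid, train,
                                   train_val_split)
from conftest import make_model


class TestMinibatch:
    def test_full_batch_equals_full_graph(self, tiny_sim):
        _, prepared, _ = tiny_sim
        idx = np.arange(prepared.graph.Nc)
        sub, subfeats = minibatch_cells(prepared.graph, prepared.feats, idx)
        assert (sub.A_RNA != prepared.graph.A_RNA).nnz == 0
        assert sub.cell_ids == prepared.graph.cell_ids
        assert np.array_equal(subfeats.h_cell0, prepared.feats.h_cell0)
        assert sub.Ag is prepared.graph.Ag     # feature graphs kept whole

    def test_disjoint_batches_partition_rna_rows(self, tiny_sim):
        _, prepared, _ = tiny_sim
        n = prepared.graph.Nc
        b1, b2 = np.arange(0, n // 2), np.arange(n // 2, n)
        s1, _ = minibatch_cells(prepared.graph, prepared.feats, b1)
        s2, _ = minibatch_cells(prepared.graph, prepared.feats, b2)
        import scipy.sparse as sp
        stacked = sp.vstack([s1.A_RNA, s2.A_RNA])
        assert (stacked != prepared.graph.A_RNA).nnz == 0

    def test_empty_batch_fails(self, tiny_sim):
        _, prepared, _ = tiny_sim
        with pytest.raises(ValueError):
            minibatch_cells(prepared.graph, prepared.feats, np.array([]))

    def test_batched_predictions_match_when_cells_are_independent(
            self, tiny_sim, small_model_config):
        # cross-cell coupling enters through cell attention and, from the
        # second layer on, through gene states aggregated over batch cells;
        # a one-layer model without the cell transformer is therefore the
        # configuration in which predictions are exactly batching-invariant
        _, prepared, _ = tiny_sim
        cfg = ModelConfig(**{**small_model_config.to_dict(),
                             "ablation": "no_transformers", "L": 1})
        model = make_model(prepared, cfg)
        full = model.predict(prepared.graph, prepared.feats)
        rows = []
        for start in range(0, prepared.graph.Nc, 50):
            idx = np.arange(start, min(start + 50, prepared.graph.Nc))
            sub, subfeats = minibatch_cells(prepared.graph, prepared.feats, idx)
            rows.append(model.predict(sub, subfeats))
        assert np.allclose(np.vstack(rows), full, atol=1e-10)


class TestSplit:
    def test_split_is_disjoint_and_covering(self, rng):
        tr, va = train_val_split(100, 0.2, rng)
        assert len(tr) == 80 and len(va) == 20
        assert not set(tr) & set(va)

    def test_stratified_split_balances_batches(self, rng):
        labels = np.repeat([0, 1, 2], 40)
        tr, va = train_val_split(120, 0.25, rng, stratify=labels)
        for b in range(3):
            assert np.sum(labels[va] == b) == 10


class TestMetrics:
    def test_perfect_prediction(self, rng):
        y = rng.normal(size=(10, 4))
        rep = compute_metrics(y, y)
        assert rep.rmse == 0 and rep.mae == 0 and rep.corr == pytest.approx(1)

    def test_corr_invariant_to_per_cell_affine_but_rmse_not(self, rng):
        y = rng.normal(size=(20, 5))
        distorted = 2 * y + 3
        rep = compute_metrics(distorted, y)
        assert rep.corr == pytest.approx(1.0)
        assert rep.rmse > 0

    def test_hand_example(self):
        target = np.array([[0.0, 2.0], [1.0, 3.0]])
        pred = np.ones((2, 2))
        rep = compute_metrics(pred, target)
        assert rep.rmse == pytest.approx(np.sqrt(1.5))

    def test_constant_rows_score_zero_and_are_counted(self):
        target = np.array([[1.0, 1.0], [0.0, 2.0]])
        pred = np.array([[0.3, 0.9], [0.1, 0.7]])
        corr, n_bad = cellwise_pearson(pred, target)
        assert n_bad == 1 and corr[0] == 0.0

    def test_per_protein_rmse_is_columnwise(self, rng):
        y = rng.normal(size=(15, 3))
        pred = y.copy()
        pred[:, 1] += 2.0
        rep = compute_metrics(pred, y, ["a", "b", "c"])
        assert rep.per_protein_rmse["a"] == pytest.approx(0.0)
        assert rep.per_protein_rmse["b"] == pytest.approx(2.0)


class TestTraining:
    def test_loss_decreases_and_same_seed_reproduces(self, tiny_sim,
                                                     small_model_config,
                                                     quick_train_config):
        _, prepared, _ = tiny_sim
        r1 = train(prepared.graph, prepared.feats, prepared.target,
                   small_model_config, quick_train_config,
                   batch_labels=prepared.batch_labels)
        r2 = train(prepared.graph, prepared.feats, prepared.target,
                   small_model_config, quick_train_config,
                   batch_labels=prepared.batch_labels)
        assert r1.loss_curve[-1] < r1.loss_curve[0]
        assert r1.loss_curve == r2.loss_curve
        assert r1.val_rmse_curve == r2.val_rmse_curve

    def test_minibatched_training_runs(self, tiny_sim, small_model_config):
        _, prepared, _ = tiny_sim
        tc = TrainConfig(epochs=2, cell_batch_size=40, seed=0,
                         learning_rate=1e-3)
        res = train(prepared.graph, prepared.feats, prepared.target,
                    small_model_config, tc)
        assert len(res.loss_curve) == 2

    def test_noise_free_data_is_learned_to_high_pearson(self):
        from scmoformer.pipeline import prepare_synthetic
        from scmoformer.simdata import SimConfig
        cfg = SimConfig(n_cells=250, n_genes=50, n_proteins=6, seed=5,
                        protein_noise_sd=0.0, n_batches=1, kg_coverage=1.0)
        prepared, _ = prepare_synthetic(cfg, d0=50, d_emb=48)
        mc = ModelConfig(L=2, d_hidden=48, dropout=0.0,
                         attention={"kind": "linear", "r": 32}, seed=0)
        tc = TrainConfig(epochs=300, learning_rate=3e-3, seed=0,
                         early_stop_patience=60)
        res = train(prepared.graph, prepared.feats, prepared.target, mc, tc)
        rep = evaluate(res.model, prepared.graph, prepared.feats,
                       prepared.target, cell_idx=res.val_idx)
        assert rep.corr > 0.95

    def test_mean_baseline_shape_and_values(self, rng):
        ytr = rng.normal(size=(30, 4))
        pred = per_protein_mean_baseline(ytr, 7)
        assert pred.shape == (7, 4)
        assert np.allclose(pred[0], ytr.mean(axis=0))


class TestExperimentGrid:
    def test_pe_grid_rows_and_determinism(self, tiny_sim, small_model_config,
                                          quick_train_config):
        _, prepared, _ = tiny_sim
        grid = {"pe_kind": ["laplacian", "random_walk", "none"],
                "seeds": [0, 1]}
        t1 = run_experiment_grid(grid, prepared.graph, prepared.feats,
                                 prepared.target, small_model_config,
                                 quick_train_config)
        assert list(t1["pe_kind"]) == grid["pe_kind"]
        assert (t1["n_runs"] == 2).all()
        assert {"rmse_mean", "rmse_std", "mae_mean", "corr_mean"} <= \
            set(t1.columns)
        t2 = run_experiment_grid(grid, prepared.graph, prepared.feats,
                                 prepared.target, small_model_config,
                                 quick_train_config)
        assert t1.equals(t2)

    def test_identical_seeds_give_zero_std(self, tiny_sim, small_model_config,
                                           quick_train_config):
        _, prepared, _ = tiny_sim
        t = run_experiment_grid({"fusion": ["concurrent"], "seeds": [3, 3]},
                                prepared.graph, prepared.feats,
                                prepared.target, small_model_config,
                                quick_train_config)
        assert t.loc[0, "rmse_std"] == 0.0

    def test_graph_variant_attaches_expected_blocks(self, tiny_sim):
        _, prepared, _ = tiny_sim
        tr = np.arange(0, prepared.graph.Nc // 2)
        g = apply_graph_variant(prepared.graph, prepared.feats,
                                prepared.target, tr, "both")
        assert g.A_cell_cell is not None and g.A_cell_cell.nnz > 0
        assert g.A_cell_protein is not None
        # held-out cells carry no target information
        held_out = np.arange(prepared.graph.Nc // 2, prepared.graph.Nc)
        assert g.A_cell_protein[held_out].nnz == 0

    def test_two_axes_rejected(self, tiny_sim, small_model_config,
                               quick_train_config):
        _, prepared, _ = tiny_sim
        with pytest.raises(ValueError):
            run_experiment_grid({"pe_kind": ["none"], "fusion": ["mixed"]},
                                prepared.graph, prepared.feats,
                                prepared.target, small_model_config,
                                quick_train_config)
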