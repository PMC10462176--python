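"""Layer-level behaviour against straight-line dense references, and the
structural invariants of the full network wiring (readout depends on cells
only, fusion orders differ, gradients reach every active parameter group,
checkpoints round-trip bit-identically)."""

import numpy as np
import pytest
import scipy.sparse as sp
from scipy.special import ndtr

from scmoformer.autodiff import Adam, Tensor
from scmoformer.knowledge_graph import HeteroGraph
from scmoformer.model import (GraphTransformerLayer, ModelConfig, SAGEBridge,
                              ScMoFormer, load_model, mse_loss,
                              normalize_adjacency, save_model)
from scmoformer.train_eval import minibatch_cells, train
from conftest import make_model


class TestGraphTransformerLayer:
    def _dense_reference(self, layer, h, A):
        """Straight-line reimplementation: MLP(GNN(h,A) + Attn(h))."""
        p = {k: v.data for k, v in layer.parameters().items()}
        An = normalize_adjacency(A, True).toarray()
        hM = An @ (h @ p["gnn.lin.W"] + p["gnn.lin.b"])
        Q = h @ p["attn.wq.W"] + p["attn.wq.b"]
        K = h @ p["attn.wk.W"] + p["attn.wk.b"]
        scores = Q @ K.T / np.sqrt(h.shape[1])
        w = np.exp(scores - scores.max(axis=1, keepdims=True))
        w /= w.sum(axis=1, keepdims=True)
        hT = (w @ h) @ p["attn.wo.W"] + p["attn.wo.b"]
        z = hM + hT
        z1 = z @ p["mlp.fc1.W"] + p["mlp.fc1.b"]
        z1 = z1 * ndtr(z1)
        return z1 @ p["mlp.fc2.W"] + p["mlp.fc2.b"]

    def test_matches_dense_reference(self, rng):
        d = 6
        layer = GraphTransformerLayer(d, np.random.default_rng(1), heads=1,
                                      use_weights=True)
        A = sp.random(6, 6, density=0.5, random_state=2)
        A = sp.csr_matrix(A + A.T)
        h = rng.normal(size=(6, d))
        out = layer(Tensor(h), A)
        assert np.allclose(out.data, self._dense_reference(layer, h, A),
                           atol=1e-6)

    def test_zeroed_attention_leaves_gnn_path(self, rng):
        d = 4
        layer = GraphTransformerLayer(d, np.random.default_rng(3), heads=1,
                                      use_weights=True)
        A = sp.csr_matrix(np.array([[0, 1.0], [1.0, 0]]))
        h = rng.normal(size=(2, d))
        layer.attn.zero_()
        out = layer(Tensor(h), A)
        p = {k: v.data for k, v in layer.parameters().items()}
        An = normalize_adjacency(A, True).toarray()
        z = An @ (h @ p["gnn.lin.W"] + p["gnn.lin.b"])
        z1 = z @ p["mlp.fc1.W"] + p["mlp.fc1.b"]
        z1 = z1 * ndtr(z1)
        expect = z1 @ p["mlp.fc2.W"] + p["mlp.fc2.b"]
        assert np.allclose(out.data, expect, atol=1e-10)

    def test_empty_graph_and_zeroed_gnn_leaves_attention_path(self, rng):
        d = 4
        layer = GraphTransformerLayer(d, np.random.default_rng(4), heads=1,
                                      use_weights=True)
        layer.gnn.zero_()
        h = rng.normal(size=(3, d))
        out = layer(Tensor(h), sp.csr_matrix((3, 3)))
        full = self._dense_reference(layer, h, sp.csr_matrix((3, 3)))
        assert np.allclose(out.data, full, atol=1e-10)


class TestSAGEBridge:
    def test_mean_neighborhood_hand_example(self):
        bridge = SAGEBridge(2, np.random.default_rng(0), use_weights=False)
        h_src = Tensor(np.array([[1.0, 0.0], [3.0, 2.0]]))
        B = sp.csr_matrix(np.array([[1.0, 1.0]]))
        assert np.allclose(bridge.neighborhood(h_src, B).data, [[2.0, 1.0]])

    def test_no_neighbors_gives_zero_summary(self):
        bridge = SAGEBridge(2, np.random.default_rng(0))
        h_src = Tensor(np.ones((2, 2)))
        B = sp.csr_matrix((1, 2))
        assert np.array_equal(bridge.neighborhood(h_src, B).data, [[0.0, 0.0]])

    def test_single_neighbor_summary_is_that_embedding(self):
        bridge = SAGEBridge(2, np.random.default_rng(0))
        h_src = Tensor(np.array([[0.5, -1.5], [9.0, 9.0]]))
        B = sp.csr_matrix(np.array([[0.7, 0.0]]))
        assert np.allclose(bridge.neighborhood(h_src, B).data, [[0.5, -1.5]])

    def test_weighted_mean_uses_edge_weights(self):
        bridge = SAGEBridge(2, np.random.default_rng(0), use_weights=True)
        h_src = Tensor(np.array([[1.0, 0.0], [3.0, 2.0]]))
        B = sp.csr_matrix(np.array([[1.0, 3.0]]))
        assert np.allclose(bridge.neighborhood(h_src, B).data, [[2.5, 1.5]])

    def test_pool_aggregator_takes_elementwise_max(self):
        bridge = SAGEBridge(2, np.random.default_rng(0), aggregator="pool")
        bridge.pool.W.data[:] = np.eye(2)     # identity projection
        bridge.pool.b.data[:] = 0.0
        h_src = Tensor(np.array([[1.0, 5.0], [4.0, 2.0]]))
        B = sp.csr_matrix(np.array([[1.0, 1.0]]))
        assert np.allclose(bridge.neighborhood(h_src, B).data, [[4.0, 5.0]])


class TestMseLoss:
    def test_exact_values(self):
        assert mse_loss(np.ones((2, 2)), np.ones((2, 2))) == 0.0
        assert mse_loss(np.ones((2, 2)) + 1.0, np.ones((2, 2))) == 1.0
        pred = np.array([[0.0, 1.0], [2.0, 3.0]])
        assert mse_loss(pred, np.zeros((2, 2))) == pytest.approx(3.5)

    def test_shape_mismatch_fails(self):
        with pytest.raises(ValueError):
            mse_loss(np.ones((2, 2)), np.ones((2, 3)))


class TestForward:
    def test_readout_width_is_layers_times_hidden(self, tiny_sim,
                                                  small_model_config):
        _, prepared, _ = tiny_sim
        for L in (1, 2, 3):
            cfg = ModelConfig(**{**small_model_config.to_dict(), "L": L})
            model = make_model(prepared, cfg)
            assert model.readout.W.shape == (L * cfg.d_hidden,
                                             prepared.target.shape[1])

    def test_prediction_rows_permute_with_cells(self, tiny_sim,
                                                small_model_config, rng):
        _, prepared, _ = tiny_sim
        model = make_model(prepared, small_model_config)
        pred = model.predict(prepared.graph, prepared.feats)
        perm = rng.permutation(prepared.graph.Nc)
        g2, f2 = minibatch_cells(prepared.graph, prepared.feats, perm)
        pred2 = model.predict(g2, f2)
        assert np.allclose(pred2, pred[perm], atol=1e-8)

    def test_readout_is_cell_only_when_bridges_to_cells_are_zeroed(
            self, tiny_sim, small_model_config, rng):
        _, prepared, _ = tiny_sim
        model = make_model(prepared, small_model_config)
        for layer in range(model.config.L):
            model.mpg_src2c[layer].zero_()
        pred = model.predict(prepared.graph, prepared.feats)
        # perturbing the gene/protein towers must not move predictions
        for mods in (model.gt_gene, model.gt_protein):
            for m in mods:
                for t in m.parameters().values():
                    t.data += rng.normal(scale=0.5, size=t.data.shape)
        model.emb_target.data += 1.0
        assert np.allclose(model.predict(prepared.graph, prepared.feats),
                           pred, atol=1e-10)

    @pytest.mark.parametrize("other", ["gnn_first", "mixed"])
    def test_fusion_orders_differ_unless_bridges_zeroed(self, tiny_sim,
                                                        small_model_config,
                                                        other):
        _, prepared, _ = tiny_sim
        base = small_model_config.to_dict()
        m1 = make_model(prepared, ModelConfig(**{**base, "fusion": "concurrent"}))
        m2 = make_model(prepared, ModelConfig(**{**base, "fusion": other}))
        p1 = m1.predict(prepared.graph, prepared.feats)
        p2 = m2.predict(prepared.graph, prepared.feats)
        assert not np.allclose(p1, p2)
        for m in (m1, m2):
            for layer in range(m.config.L):
                for bridge in (m.mpg_p2g[layer], m.mpg_g2p[layer],
                               m.mpg_c2src[layer], m.mpg_src2c[layer]):
                    bridge.zero_()
        assert np.allclose(m1.predict(prepared.graph, prepared.feats),
                           m2.predict(prepared.graph, prepared.feats),
                           atol=1e-12)

    def test_gradient_reaches_every_functional_parameter_group(
            self, tiny_sim):
        # protein-tower information reaches the cell readout only after two
        # bridge hops (protein -> gene -> cell), so all functional groups
        # carry gradient from depth L=3 on; groups aggregate over layers
        _, prepared, _ = tiny_sim
        cfg = ModelConfig(L=3, d_hidden=16, dropout=0.0,
                          attention={"kind": "linear", "r": 16},
                          pe={"kind": "random_walk", "k": 4}, seed=0)
        model = make_model(prepared, cfg)
        from scmoformer.train_eval import _graph_pe
        pe_g, pe_p = _graph_pe(prepared.graph, cfg)
        pred, _ = model.forward_tensors(prepared.graph, prepared.feats,
                                        pe_g, pe_p)
        loss = mse_loss(pred, prepared.target)
        loss.backward()
        groups = ["proj_cell", "proj_src", "emb_target", "pe_gene",
                  "pe_protein", "readout", "gt_gene", "gt_protein",
                  "trans_cell", "fc_cell", "mpg_p2g", "mpg_g2p",
                  "mpg_c2src", "mpg_src2c"]
        params = model.parameters()
        for group in groups:
            members = {k: v for k, v in params.items()
                       if k.startswith(group) or f".{group}." in k}
            assert members, group
            peak = max(0.0 if v.grad is None else float(np.abs(v.grad).max())
                       for v in members.values())
            assert peak > 0, f"no gradient reached {group}"

    def test_nan_input_fails_with_layer_index(self, tiny_sim,
                                              small_model_config):
        _, prepared, _ = tiny_sim
        model = make_model(prepared, small_model_config)
        feats = prepared.feats
        bad = feats.h_cell0.copy()
        bad[0, 0] = np.nan
        from scmoformer.preprocess import NodeFeatures
        with pytest.raises(FloatingPointError, match="layer 0"):
            model.predict(prepared.graph,
                          NodeFeatures(bad, feats.h_gene0, feats.h_protein0,
                                       feats.d0))

    def test_adt2gex_rejects_cell_gene_edges(self, tiny_sim,
                                             small_model_config):
        _, prepared, _ = tiny_sim
        cfg = ModelConfig(**{**small_model_config.to_dict(),
                             "direction": "adt2gex"})
        model = ScMoFormer(cfg, d0_cell=prepared.feats.h_cell0.shape[1],
                           d0_src=prepared.feats.h_protein0.shape[1],
                           n_target_nodes=prepared.graph.Ng,
                           n_out=prepared.graph.Ng)
        with pytest.raises(ValueError, match="leakage"):
            model.predict(prepared.graph, prepared.feats)

    def test_linear_attention_rejects_multiple_heads(self):
        with pytest.raises(ValueError, match="single-head"):
            ModelConfig(attention={"kind": "linear", "heads": 2})


class TestPersistence:
    def test_round_trip_predictions_bit_identical(self, tiny_sim,
                                                  small_model_config,
                                                  tmp_path):
        _, prepared, _ = tiny_sim
        model = make_model(prepared, small_model_config)
        pred = model.predict(prepared.graph, prepared.feats)
        save_model(model, str(tmp_path / "ckpt"))
        loaded = load_model(str(tmp_path / "ckpt"))
        assert loaded.config.to_dict() == model.config.to_dict()
        assert np.array_equal(loaded.predict(prepared.graph, prepared.feats),
                              pred)

    def test_mismatched_feature_names_rejected(self, tiny_sim,
                                               small_model_config, tmp_path):
        _, prepared, _ = tiny_sim
        model = make_model(prepared, small_model_config)
        save_model(model, str(tmp_path / "ckpt"))
        with pytest.raises(ValueError, match="gene names"):
            load_model(str(tmp_path / "ckpt"),
                       gene_names=["not", "the", "same"])

    def test_version_mismatch_rejected(self, tiny_sim, small_model_config,
                                       tmp_path):
        import json
        _, prepared, _ = tiny_sim
        model = make_model(prepared, small_model_config)
        save_model(model, str(tmp_path / "ckpt"))
        meta_path = tmp_path / "ckpt" / "model.json"
        meta = json.loads(meta_path.read_text())
        meta["version"] = "other-version"
        meta_path.write_text(json.dumps(meta))
        with pytest.raises(ValueError, match="version"):
            load_model(str(tmp_path / "ckpt"))
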