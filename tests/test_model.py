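"""Attention primitives against brute-force oracles; training contracts."""

import math

import numpy as np
import pytest

from conftest import (
    brute_layer_forward,
    brute_subgraph_embed,
    random_hypergraph,
)
from safer.autodiff import Tensor, bce_with_logits, masked_softmax
from safer.features import IncidenceHypergraph
from safer.model import (
    AttentionParams,
    ModelConfig,
    SynergyModel,
    SynergySubjectBatch,
    attention_state,
    hyperedge_attention,
    layer_forward,
    node_attention,
    subgraph_embed,
    train,
)


class TestAttentionWeights:
    def test_softmax_sums_to_one_and_shift_invariant(self, rng):
        scores = Tensor(rng.normal(size=(5, 4)))
        mask = rng.random((5, 4)) < 0.6
        mask[:, 0] = True  # no empty column
        w = masked_softmax(scores, mask, axis=0)
        np.testing.assert_allclose(w.data.sum(axis=0), 1.0, atol=1e-12)
        shifted = masked_softmax(scores + 7.3, mask, axis=0)
        np.testing.assert_allclose(w.data, shifted.data, atol=1e-9)

    def test_single_incident_node_gets_full_weight(self):
        scores = Tensor(np.array([[0.7], [2.0]]))
        inc = np.array([[1.0], [0.0]])
        w = hyperedge_attention(scores, inc)
        np.testing.assert_allclose(w.data, [[1.0], [0.0]])

    def test_identical_states_uniform(self):
        scores = Tensor(np.full((3, 1), 0.42))
        w = hyperedge_attention(scores, np.ones((3, 1)))
        np.testing.assert_allclose(w.data, 1.0 / 3.0)

    def test_hand_softmax_ln2(self):
        # scores (ln 2, 0) -> weights (2/3, 1/3)
        scores = Tensor(np.array([[math.log(2.0)], [0.0]]))
        w = hyperedge_attention(scores, np.ones((2, 1)))
        np.testing.assert_allclose(w.data[:, 0], [2.0 / 3.0, 1.0 / 3.0], atol=1e-12)

    def test_node_attention_duality(self):
        scores = Tensor(np.array([[1.0, 1.0]]))
        w = node_attention(scores, np.ones((1, 2)))
        np.testing.assert_allclose(w.data, [[0.5, 0.5]])

    def test_node_attention_matches_enumeration(self, rng):
        # a node in four edges: weights must equal a direct softmax
        scores_data = rng.normal(size=(1, 4))
        w = node_attention(Tensor(scores_data), np.ones((1, 4)))
        e = np.exp(scores_data[0])
        np.testing.assert_allclose(w.data[0], e / e.sum(), atol=1e-12)

    def test_empty_edge_and_isolated_node_rejected(self):
        with pytest.raises(ValueError, match="empty hyperedge"):
            hyperedge_attention(Tensor(np.zeros((2, 1))), np.zeros((2, 1)))
        with pytest.raises(ValueError, match="isolated node"):
            node_attention(Tensor(np.zeros((1, 2))), np.zeros((1, 2)))


class TestLayerForward:
    def test_matches_brute_force(self, rng):
        for _ in range(20):
            n_v, n_e, d = rng.integers(2, 9), rng.integers(1, 6), 4
            hg = random_hypergraph(rng, n_v, n_e)
            params = AttentionParams.init(d, rng)
            hv = Tensor(rng.normal(size=(n_v, d)))
            he = Tensor(rng.normal(size=(n_e, d)))
            hv_new, he_new = layer_forward(hv, he, hg, params)
            bv, be = brute_layer_forward(
                hv.data, he.data, hg.incidence,
                params.w_node.data, params.w_edge.data, params.context.data[:, 0],
            )
            np.testing.assert_allclose(hv_new.data, bv, atol=1e-9)
            np.testing.assert_allclose(he_new.data, be, atol=1e-9)

    def test_disconnected_components_do_not_interact(self, rng):
        inc = np.array([[1.0, 0.0], [1.0, 0.0], [0.0, 1.0], [0.0, 1.0]])
        hg = IncidenceHypergraph(["a", "b", "c", "d"], ["e0", "e1"], inc)
        params = AttentionParams.init(3, rng)
        hv = rng.normal(size=(4, 3))
        he = rng.normal(size=(2, 3))
        base_v, _ = layer_forward(Tensor(hv), Tensor(he), hg, params)
        hv2 = hv.copy()
        hv2[2:] += 5.0  # perturb component B only
        he2 = he.copy()
        he2[1] -= 3.0
        pert_v, _ = layer_forward(Tensor(hv2), Tensor(he2), hg, params)
        np.testing.assert_allclose(base_v.data[:2], pert_v.data[:2], atol=1e-12)

    def test_node_permutation_equivariance(self, rng):
        hg = random_hypergraph(rng, 6, 3)
        params = AttentionParams.init(4, rng)
        hv = rng.normal(size=(6, 4))
        he = rng.normal(size=(3, 4))
        base_v, base_e = layer_forward(Tensor(hv), Tensor(he), hg, params)
        perm = rng.permutation(6)
        hg_p = IncidenceHypergraph(
            [hg.node_names[i] for i in perm], hg.edge_names, hg.incidence[perm]
        )
        perm_v, perm_e = layer_forward(Tensor(hv[perm]), Tensor(he), hg_p, params)
        np.testing.assert_allclose(perm_v.data, base_v.data[perm], atol=1e-10)
        np.testing.assert_allclose(perm_e.data, base_e.data, atol=1e-10)


class TestSubgraphEmbed:
    def test_singleton_support_full_weight(self, rng):
        hv = Tensor(rng.normal(size=(4, 3)))
        b = Tensor(rng.normal(size=(3, 1)))
        f = np.array([[0.0, 2.0, 0.0, 0.0]])
        emb, attn = subgraph_embed(f, hv, b)
        np.testing.assert_allclose(attn.data, [[0.0, 1.0, 0.0, 0.0]], atol=1e-12)
        np.testing.assert_allclose(emb.data[0], np.maximum(hv.data[1], 0.0))

    def test_zero_bias_uniform_over_support(self, rng):
        hv = Tensor(rng.normal(size=(5, 3)))
        b = Tensor(np.zeros((3, 1)))
        f = np.array([[1.0, 0.0, 2.0, 0.0, 3.0]])
        _, attn = subgraph_embed(f, hv, b)
        np.testing.assert_allclose(attn.data[0, [0, 2, 4]], 1.0 / 3.0, atol=1e-12)

    def test_matches_brute_force(self, rng):
        for _ in range(20):
            n_v, d = int(rng.integers(2, 8)), 4
            hv = Tensor(rng.normal(size=(n_v, d)))
            b = Tensor(rng.normal(size=(d, 1)))
            f = rng.normal(size=n_v) * (rng.random(n_v) < 0.7)
            if not f.any():
                f[0] = 1.0
            emb, _ = subgraph_embed(f[None, :], hv, b)
            expected = brute_subgraph_embed(f, hv.data, b.data[:, 0])
            np.testing.assert_allclose(emb.data[0], expected, atol=1e-9)

    def test_empty_support_rejected(self, rng):
        with pytest.raises(ValueError, match="empty subgraph"):
            subgraph_embed(np.zeros((1, 4)), Tensor(rng.normal(size=(4, 2))), Tensor(np.zeros((2, 1))))

    def test_positive_feature_scaling_acts_through_scores(self, rng):
        # with b.hV >= 0 on the support, scaling F by c > 1 sharpens the
        # softmax towards the top-scored node: its weight cannot drop
        hv = Tensor(np.abs(rng.normal(size=(5, 3))))
        b = Tensor(np.abs(rng.normal(size=(3, 1))))
        f = np.array([[0.5, 1.0, 2.0, 0.0, 0.3]])
        _, attn = subgraph_embed(f, hv, b)
        _, attn_scaled = subgraph_embed(3.0 * f, hv, b)
        top = np.argmax(attn.data[0])
        assert attn_scaled.data[0, top] >= attn.data[0, top] - 1e-12

    def test_attention_state_bounded_and_zero_for_zero_map(self, rng):
        params = AttentionParams.init(3, rng)
        s = attention_state(Tensor(rng.normal(size=(1, 3))), Tensor(rng.normal(size=(1, 3))), params)
        assert np.all(np.abs(s.data) < 1.0)
        zero = AttentionParams(
            Tensor(np.zeros((3, 3))), Tensor(np.zeros((3, 3))), Tensor(np.zeros((3, 1)))
        )
        s0 = attention_state(Tensor(rng.normal(size=(1, 3))), Tensor(rng.normal(size=(1, 3))), zero)
        np.testing.assert_allclose(s0.data, 0.0)


def _toy_problem(rng, n=60):
    cell_hg = random_hypergraph(rng, 6, 4)
    drug_hg = random_hypergraph(rng, 8, 3)
    f_cell = rng.normal(size=(n, 6))
    f_cell[f_cell == 0] = 0.5
    f_drug = np.abs(rng.normal(size=(n, 8))) + 0.1
    cov = rng.normal(size=(n, 3))
    # separable signal carried by the covariates and the first cell feature
    labels = (cov[:, 0] + 0.5 * cov[:, 1] + 0.2 * f_cell[:, 0] > 0).astype(int)
    batch = SynergySubjectBatch(f_cell, f_drug, cov, labels)
    cfg = ModelConfig(embed_dim=8, hidden_dim=24, epochs=15, batch_size=16, lr=1e-2, seed=5)
    return cell_hg, drug_hg, batch, cfg


class TestModelForward:
    def test_eval_mode_deterministic(self, rng):
        cell_hg, drug_hg, batch, cfg = _toy_problem(rng)
        model = SynergyModel(cell_hg, drug_hg, 3, cfg)
        a = model.forward(batch, train_mode=False).data
        b = model.forward(batch, train_mode=False).data
        np.testing.assert_array_equal(a, b)
        assert np.isfinite(a).all()

    def test_gradients_match_finite_differences(self, rng):
        cell_hg, drug_hg, batch, cfg = _toy_problem(rng, n=2)
        model = SynergyModel(cell_hg, drug_hg, 3, cfg)

        def loss_value():
            return float(bce_with_logits(model.forward(batch, train_mode=False), batch.labels).data)

        loss = bce_with_logits(model.forward(batch, train_mode=False), batch.labels)
        for p in model.params:
            p.grad = None
        loss.backward()
        check_rng = np.random.default_rng(0)
        for p in model.params:
            assert p.grad is not None
            idx = tuple(int(check_rng.integers(0, s)) for s in p.data.shape)
            analytic = p.grad[idx]
            eps = 1e-6
            orig = p.data[idx]
            p.data[idx] = orig + eps
            up = loss_value()
            p.data[idx] = orig - eps
            down = loss_value()
            p.data[idx] = orig
            numeric = (up - down) / (2 * eps)
            assert analytic == pytest.approx(numeric, rel=1e-4, abs=1e-7)


class TestTraining:
    def test_zero_epochs_returns_initial_params(self, rng):
        cell_hg, drug_hg, batch, cfg = _toy_problem(rng)
        cfg.epochs = 0
        model = SynergyModel(cell_hg, drug_hg, 3, cfg)
        before = model.state_dict()
        history = train(model, batch, None, cfg)
        assert history.train_loss == []
        for a, b in zip(before, model.state_dict()):
            np.testing.assert_array_equal(a, b)

    def test_same_seed_identical_history(self, rng):
        cell_hg, drug_hg, batch, cfg = _toy_problem(rng)
        h1 = train(SynergyModel(cell_hg, drug_hg, 3, cfg), batch, batch, cfg)
        h2 = train(SynergyModel(cell_hg, drug_hg, 3, cfg), batch, batch, cfg)
        assert h1.train_loss == h2.train_loss
        assert h1.val_auprc == h2.val_auprc

    def test_single_class_training_rejected(self, rng):
        cell_hg, drug_hg, batch, cfg = _toy_problem(rng)
        bad = SynergySubjectBatch(
            batch.f_cell, batch.f_drug, batch.covariates, np.ones_like(batch.labels)
        )
        model = SynergyModel(cell_hg, drug_hg, 3, cfg)
        with pytest.raises(ValueError, match="single class"):
            train(model, bad, None, cfg)

    def test_planted_separable_signal_is_learned(self, rng):
        from safer.evaluation import auroc

        cell_hg, drug_hg, batch, cfg = _toy_problem(rng)
        model = SynergyModel(cell_hg, drug_hg, 3, cfg)
        history = train(model, batch, None, cfg)
        assert history.train_loss[-1] < history.train_loss[0]
        assert auroc(model.predict_scores(batch), batch.labels) > 0.95
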