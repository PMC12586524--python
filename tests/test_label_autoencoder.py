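import numpy as np
import pytest

from fedgat.graph_data import LabelSpace
from fedgat.label_autoencoder import (MultiScaleLabelAutoencoder, attend,
                                      attention_coefficients, multi_head_feature,
                                      neural_similarity, reconstruction_loss)
from fedgat.label_semantics import (build_label_graph, compute_label_weights,
                                    embed_labels, weight_embeddings)


def label_graph_fixture(C=6, dim=8, seed=0, freqs=None):
    space = LabelSpace(tuple(f"label{i}" for i in range(C)))
    emb = embed_labels(space, dim=dim)
    f = freqs if freqs is not None else (np.arange(C) + 1)
    w = compute_label_weights(f)
    return build_label_graph(weight_embeddings(emb, w))


class TestAttentionPieces:
    def test_uniform_over_equal_scores(self):
        a = attention_coefficients(np.zeros((1, 5)))
        assert np.allclose(a, 0.2)

    def test_single_neighbor_gets_everything(self):
        mask = np.array([[False, True, False]])
        a = attention_coefficients(np.array([[9.0, 1.2, -3.0]]), mask)
        assert np.allclose(a, [[0.0, 1.0, 0.0]])

    def test_closed_form_softmax(self):
        a = attention_coefficients(np.array([[np.log(2.0), 0.0]]))
        assert np.allclose(a, [[2 / 3, 1 / 3]])

    def test_rows_sum_to_one_on_random_graphs(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            n = int(rng.integers(2, 9))
            scores = rng.standard_normal((n, n)) * 5
            mask = rng.random((n, n)) < 0.4
            a = attention_coefficients(scores, mask)
            assert np.allclose(a.sum(axis=1), 1.0)

    def test_attend_identity_value_map(self):
        L = np.array([[0.5, -0.2], [0.3, 0.8]])
        alpha = np.array([[0.0, 1.0], [0.0, 1.0]])
        out = attend(alpha, np.eye(2), L)
        assert np.allclose(out[0], np.maximum(L[1], 0.0))

    def test_attend_uniform_is_relu_of_mean(self):
        L = np.abs(np.random.default_rng(0).standard_normal((4, 3)))
        alpha = np.full((4, 4), 0.25)
        assert np.allclose(attend(alpha, np.eye(3), L), L.mean(axis=0))

    def test_identical_heads_equal_single_head(self):
        rng = np.random.default_rng(2)
        L = rng.standard_normal((5, 3))
        V = rng.standard_normal((3, 4))
        alpha = attention_coefficients(rng.standard_normal((5, 5)))
        single = attend(alpha, V, L)
        multi = multi_head_feature([alpha] * 4, [V] * 4, L)
        assert np.allclose(multi, single)

    def test_opposite_heads_cancel(self):
        L = np.ones((2, 2))
        V = np.ones((2, 2))
        alpha = np.full((2, 2), 0.5)
        out = multi_head_feature([alpha, alpha], [V, -V], L)
        assert np.all(out == 0.0)


class TestReconstructionLoss:
    def test_exact_reconstruction_is_zero(self):
        X = np.random.default_rng(0).standard_normal((4, 3))
        assert reconstruction_loss(X, X) == 0.0

    def test_single_node_sum_over_dims(self):
        assert reconstruction_loss([[1.0, 0.0]], [[0.0, 0.0]]) == pytest.approx(1.0)

    def test_quadratic_scaling(self):
        X = np.zeros((3, 2))
        R = np.random.default_rng(1).standard_normal((3, 2))
        assert reconstruction_loss(X, 2 * R) == pytest.approx(4 * reconstruction_loss(X, R))


class TestNeuralSimilarity:
    def test_zero_scorer_gives_zero_scores(self):
        g = label_graph_fixture()
        ae = MultiScaleLabelAutoencoder(dim=8, hidden_dim=4, n_heads=2, seed=0)
        for k in range(2):
            ae.params[f"sc1_s1h{k}"].data[:] = 0
            ae.params[f"sc2_s1h{k}"].data[:] = 0
        A = g.scale_adjacencies[1]
        assert neural_similarity(ae, A, g.node_embeddings, 0, 3) == 0.0

    def test_asymmetric_in_argument_order(self):
        g = label_graph_fixture()
        ae = MultiScaleLabelAutoencoder(dim=8, hidden_dim=4, seed=1)
        A = g.scale_adjacencies[1]
        s_ij = neural_similarity(ae, A, g.node_embeddings, 0, 3)
        s_ji = neural_similarity(ae, A, g.node_embeddings, 3, 0)
        assert s_ij != pytest.approx(s_ji)  # concat order matters

    def test_deterministic_across_runs(self):
        g = label_graph_fixture()
        a = MultiScaleLabelAutoencoder(dim=8, hidden_dim=4, seed=7)
        b = MultiScaleLabelAutoencoder(dim=8, hidden_dim=4, seed=7)
        A = g.scale_adjacencies[1]
        assert (neural_similarity(a, A, g.node_embeddings, 1, 2)
                == neural_similarity(b, A, g.node_embeddings, 1, 2))


class TestEncoder:
    def test_single_label_degenerate_graph(self):
        g = label_graph_fixture(C=1)
        ae = MultiScaleLabelAutoencoder(dim=8, hidden_dim=4, seed=0)
        F = ae.encode(g)
        assert F.F.shape == (1, 3 * 4)  # self-loop fallback, 3 scales concatenated
        assert F.flat_dim == 12

    def test_permutation_equivariant_over_labels(self):
        g = label_graph_fixture(C=6, seed=0)
        ae = MultiScaleLabelAutoencoder(dim=8, hidden_dim=4, seed=3)
        F = ae.encode(g).F
        perm = np.random.default_rng(0).permutation(6)
        import copy

        gp = copy.deepcopy(g)
        gp.node_embeddings = g.node_embeddings[perm]
        gp.edge_weights = g.edge_weights[np.ix_(perm, perm)]
        gp.scale_adjacencies = {s: a[np.ix_(perm, perm)]
                                for s, a in g.scale_adjacencies.items()}
        Fp = ae.encode(gp).F
        assert np.allclose(Fp, F[perm], atol=1e-12)

    def test_encode_deterministic(self):
        g = label_graph_fixture()
        ae = MultiScaleLabelAutoencoder(dim=8, hidden_dim=4, seed=5)
        assert np.array_equal(ae.encode(g).F, ae.encode(g).F)


class TestTraining:
    def test_zero_lr_keeps_eval_loss_constant(self):
        g = label_graph_fixture()
        ae = MultiScaleLabelAutoencoder(dim=8, hidden_dim=4, seed=0)
        trace = ae.train(g, epochs=5, lr=0.0, seed=0)
        assert np.allclose(trace["eval_loss"], trace["eval_loss"][0])

    def test_seeded_training_reproducible(self):
        g = label_graph_fixture()
        t1 = MultiScaleLabelAutoencoder(dim=8, hidden_dim=4, seed=2).train(g, 10, 1e-3, seed=4)
        t2 = MultiScaleLabelAutoencoder(dim=8, hidden_dim=4, seed=2).train(g, 10, 1e-3, seed=4)
        assert np.array_equal(t1["train_loss"], t2["train_loss"])

    def test_loss_decreases_on_small_fixture(self):
        g = label_graph_fixture(C=5, dim=6)
        ae = MultiScaleLabelAutoencoder(dim=6, hidden_dim=4, n_heads=2, seed=1)
        trace = ae.train(g, epochs=60, lr=2e-3, seed=2)
        assert trace["final_loss"] < trace["eval_loss"][0]

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            MultiScaleLabelAutoencoder(dim=4, n_heads=0)
        with pytest.raises(ValueError):
            MultiScaleLabelAutoencoder(dim=4, mask_rate=1.0)
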