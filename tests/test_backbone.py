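import numpy as np
import pytest

from fedgat.backbone import (MultiLabelGATClassifier, gat_attention, pad_batch,
                             readout, total_loss)
from fedgat.graph_data import MultiLabelGraph

from conftest import make_graph


def tiny_model(C=2, ctx=4, spec=6, seed=0):
    return MultiLabelGATClassifier(in_dim=3, n_labels=C, context_dim=ctx,
                                   spectral_dim=spec, hidden=(5, 4), heads=(2, 2, 1),
                                   head_hidden=6, seed=seed)


class TestAttentionScore:
    def test_zero_attention_vector_gives_zero_scores(self):
        W = np.random.default_rng(0).standard_normal((3, 4))
        assert gat_attention([1.0, 2, 3], [0.5, 1, 0], W, np.zeros(8)) == 0.0

    def test_positive_preactivation_passes_through(self):
        W = np.eye(2)
        a = np.array([1.0, 0, 0, 1.0])
        assert gat_attention([2.0, 0], [0, 3.0], W, a) == pytest.approx(5.0)

    def test_leaky_slope_on_negative(self):
        W = np.eye(1)
        assert gat_attention([-1.0], [0.0], W, np.array([1.0, 0.0]),
                             slope=0.2) == pytest.approx(-0.2)


class TestReadout:
    def test_single_node(self):
        assert np.array_equal(readout([[1.0, 2.0]]), [1.0, 2.0])

    def test_duplicate_rows_and_linearity(self):
        H = np.array([[1.0, 2.0], [1.0, 2.0]])
        assert np.array_equal(readout(H), [1.0, 2.0])
        assert np.allclose(readout(3 * H), 3 * readout(H))


class TestForward:
    def test_output_length_and_sigmoid_at_zero_head(self):
        m = tiny_model()
        for k in ("head_W1", "head_b1", "head_W2", "head_b2"):
            m.params[k].data[:] = 0
        g = make_graph("g", [[0, 1], [1, 0]], [1, 0])
        pred = m.predict_graphs([g], np.zeros(4), np.zeros((1, 6)))
        assert pred.probabilities.shape == (1, 2)
        assert np.allclose(pred.probabilities, 0.5)  # sigmoid(0)

    def test_node_permutation_invariance_of_graph_prediction(self):
        rng = np.random.default_rng(0)
        A = (rng.random((6, 6)) < 0.5).astype(float)
        A = np.triu(A, 1)
        A = A + A.T
        X = rng.standard_normal((6, 3))
        g = MultiLabelGraph("g", A, X, np.array([1, 0]))
        perm = rng.permutation(6)
        gp = MultiLabelGraph("gp", A[np.ix_(perm, perm)], X[perm], np.array([1, 0]))
        m = tiny_model(seed=4)
        ctx, sp = rng.standard_normal(4), rng.standard_normal((1, 6))
        p1 = m.predict_graphs([g], ctx, sp).logits
        p2 = m.predict_graphs([gp], ctx, sp).logits
        assert np.allclose(p1, p2, atol=1e-10)

    def test_gat_layer_permutation_equivariance(self):
        rng = np.random.default_rng(1)
        m = tiny_model(seed=2)
        g = make_graph("g", [[0, 1, 0], [1, 0, 1], [0, 1, 0]], [1, 0], seed=3)
        X, _, nm, am, _ = pad_batch([g])
        from fedgat.autodiff import Tensor

        H1 = m._gat_layer(Tensor(X), am, 0, activate=True).data
        perm = rng.permutation(3)
        gp = MultiLabelGraph("gp", g.adjacency[np.ix_(perm, perm)],
                             g.node_features[perm], g.labels)
        Xp, _, nmp, amp, _ = pad_batch([gp])
        H2 = m._gat_layer(Tensor(Xp), amp, 0, activate=True).data
        assert np.allclose(H2[0], H1[0][perm], atol=1e-12)

    def test_ablations_zero_out_fusion_blocks(self):
        m = tiny_model(seed=1)
        g = make_graph("g", [[0, 1], [1, 0]], [1, 0])
        rng = np.random.default_rng(0)
        ctx1, ctx2 = rng.standard_normal(4), rng.standard_normal(4)
        sp = rng.standard_normal((1, 6))
        with_f1 = m.predict_graphs([g], ctx1, sp, ablate_graph=True).logits
        with_f2 = m.predict_graphs([g], ctx2, sp, ablate_graph=True).logits
        assert np.array_equal(with_f1, with_f2)  # F no longer influences output
        s1 = m.predict_graphs([g], ctx1, sp, ablate_spectral=True).logits
        s2 = m.predict_graphs([g], ctx1, 5 * sp, ablate_spectral=True).logits
        assert np.array_equal(s1, s2)

    def test_identical_isolated_nodes_share_output_rows(self):
        g = MultiLabelGraph("g", np.zeros((3, 3)), np.ones((3, 2)), np.array([1]))
        m = MultiLabelGATClassifier(2, 1, 2, 2, hidden=(4, 4), heads=(1, 1, 1), seed=0)
        X, _, nm, am, _ = pad_batch([g])
        from fedgat.autodiff import Tensor

        H = m._gat_layer(Tensor(X), am, 0, activate=True).data[0]
        assert np.allclose(H[0], H[1]) and np.allclose(H[1], H[2])


class TestLoss:
    def test_perfect_prediction_zero_loss(self):
        logits = np.array([[50.0, -50.0]])
        assert total_loss(logits, [[1, 0]], 0.0) == pytest.approx(0.0, abs=1e-12)

    def test_chance_prediction_closed_form(self):
        C = 7
        logits = np.zeros((3, C))
        assert total_loss(logits, np.ones((3, C)), 0.0) == pytest.approx(C * np.log(2))

    def test_nonnegative_and_ae_offset(self):
        rng = np.random.default_rng(0)
        logits = rng.standard_normal((5, 4))
        y = (rng.random((5, 4)) < 0.5).astype(float)
        base = total_loss(logits, y, 0.0)
        assert base >= 0
        assert total_loss(logits, y, 1.5) == pytest.approx(base + 1.5)


def test_gradient_matches_finite_difference_on_three_node_fixture():
    """Autodiff gradient of the fused loss vs central finite differences."""
    g = make_graph("g", [[0, 1, 0], [1, 0, 1], [0, 1, 0]], [1, 0], seed=5)
    m = MultiLabelGATClassifier(3, 2, 3, 4, hidden=(3, 3), heads=(2, 2, 1),
                                head_hidden=4, seed=8)
    rng = np.random.default_rng(2)
    ctx, sp = rng.standard_normal(3), rng.standard_normal((1, 4))
    X, _, nm, am, Y = pad_batch([g])

    def loss_value():
        return total_loss(m.forward(X, am, nm, ctx, sp), Y, 0.25).item()

    loss = total_loss(m.forward(X, am, nm, ctx, sp), Y, 0.25)
    loss.backward()
    for name, p in m.params.items():
        fd = np.zeros_like(p.data)
        it = np.nditer(p.data, flags=["multi_index"])
        for _ in it:
            idx = it.multi_index
            orig = p.data[idx]
            p.data[idx] = orig + 1e-6
            fp = loss_value()
            p.data[idx] = orig - 1e-6
            fm = loss_value()
            p.data[idx] = orig
            fd[idx] = (fp - fm) / 2e-6
        denom = max(np.linalg.norm(fd), 1e-8)
        rel = np.linalg.norm(fd - p.grad) / denom
        assert rel <= 1e-4, f"{name}: relative gradient error {rel:.2e}"
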