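"""Three-layer multi-label graph attention classifier with feature fusion.

Node features pass through three GAT layers (multi-head scores
LeakyReLU(a · [Wh_i || Wh_j]), softmax-normalized over neighborhoods,
heads averaged). A mean readout pools nodes to one graph vector, which
is concatenated with the flattened label-context embedding F and the
per-graph spectral feature g and fed to an MLP head with one sigmoid
output per label. Training minimizes per-label binary cross-entropy plus
the (constant or jointly computed) autoencoder reconstruction loss.

Graphs are processed in padded batches (B, n_max, ·) with node masks, so
variable-size graphs share one forward pass.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, concat, glorot
from .label_autoencoder import ensure_self_edges, masked_softmax

__all__ = [
    "Prediction",
    "MultiLabelGATClassifier",
    "gat_attention",
    "readout",
    "total_loss",
    "pad_batch",
]


@dataclass
class Prediction:
    logits: np.ndarray
    probabilities: np.ndarray

    def __post_init__(self):
        self.logits = np.asarray(self.logits, dtype=np.float64)
        self.probabilities = np.asarray(self.probabilities, dtype=np.float64)


def gat_attention(h_i, h_j, W, a, slope: float = 0.2) -> float:
    """Unnormalized attention score LeakyReLU(a · [W h_i || W h_j])."""
    W = np.asarray(W, dtype=np.float64)
    a = np.asarray(a, dtype=np.float64)
    z = np.concatenate([W.T @ np.asarray(h_i), W.T @ np.asarray(h_j)])
    pre = float(a @ z)
    return pre if pre > 0 else slope * pre


def readout(H) -> np.ndarray:
    """Mean pooling over node rows (graph-level, size-invariant)."""
    H = np.asarray(H, dtype=np.float64)
    return H.mean(axis=0)


def pad_batch(graphs):
    """Pad a list of MultiLabelGraph to (B, n_max, ·) arrays plus masks."""
    B = len(graphs)
    n_max = max(g.n_nodes for g in graphs)
    d = graphs[0].node_features.shape[1]
    X = np.zeros((B, n_max, d))
    A = np.zeros((B, n_max, n_max))
    node_mask = np.zeros((B, n_max), dtype=bool)
    Y = np.stack([g.labels for g in graphs]).astype(np.float64)
    for b, g in enumerate(graphs):
        n = g.n_nodes
        X[b, :n] = g.node_features
        A[b, :n, :n] = g.adjacency
        node_mask[b, :n] = True
    # attention support: edges plus self-loops on real nodes; padded nodes
    # get a self-loop so their (ignored) softmax stays defined
    att_mask = (A > 0) | np.eye(n_max, dtype=bool)[None, :, :]
    att_mask &= node_mask[:, None, :] & node_mask[:, :, None]
    att_mask = ensure_self_edges(att_mask)
    return X, A, node_mask, att_mask, Y


def total_loss(logits, labels, ae_loss: float = 0.0):
    """Mean over graphs of [ae_loss + per-label BCE summed over classes].

    Works on a Tensor (training) or ndarray (evaluation) of logits; BCE is
    computed from logits via softplus for numerical stability.
    """
    if isinstance(logits, Tensor):
        y = np.asarray(labels, dtype=np.float64)
        bce = (logits.softplus() - Tensor(y) * logits).sum(axis=-1).mean()
        return bce + float(ae_loss)
    z = np.asarray(logits, dtype=np.float64)
    y = np.asarray(labels, dtype=np.float64)
    bce = np.logaddexp(0.0, z) - y * z
    return float(np.mean(bce.sum(axis=-1)) + ae_loss)


class MultiLabelGATClassifier:
    """GAT backbone + fusion head; the federated model whose weights travel."""

    def __init__(self, in_dim: int, n_labels: int, context_dim: int, spectral_dim: int,
                 hidden=(64, 64), heads=(4, 4, 1), leaky_slope: float = 0.2,
                 head_hidden: int = 64, seed: int = 0):
        if len(hidden) != 2 or len(heads) != 3:
            raise ValueError("expected 2 hidden widths and 3 head counts")
        self.in_dim = in_dim
        self.C = n_labels
        self.context_dim = context_dim
        self.spectral_dim = spectral_dim
        self.heads = tuple(heads)
        self.slope = leaky_slope
        self.layer_dims = [(in_dim, hidden[0]), (hidden[0], hidden[1]), (hidden[1], n_labels)]
        rng = np.random.default_rng(seed)
        p: dict[str, Tensor] = {}
        for l, (din, dout) in enumerate(self.layer_dims):
            for k in range(heads[l]):
                p[f"W{l}h{k}"] = glorot(rng, din, dout)
                p[f"a_src{l}h{k}"] = glorot(rng, dout, 1, shape=(dout, 1))
                p[f"a_dst{l}h{k}"] = glorot(rng, dout, 1, shape=(dout, 1))
        fuse_dim = n_labels + context_dim + spectral_dim
        p["head_W1"] = glorot(rng, fuse_dim, head_hidden)
        p["head_b1"] = Tensor(np.zeros(head_hidden), requires_grad=True)
        p["head_W2"] = glorot(rng, head_hidden, n_labels)
        p["head_b2"] = Tensor(np.zeros(n_labels), requires_grad=True)
        self.params = p

    # -- weights as a flat named map (FedAvg arithmetic happens on these) ------
    def parameters(self) -> dict:
        return self.params

    def state_dict(self) -> dict:
        return {k: v.data.copy() for k, v in self.params.items()}

    def load_state_dict(self, state: dict) -> None:
        if set(state) != set(self.params):
            raise ValueError("parameter name signature mismatch")
        for k, v in state.items():
            if np.shape(v) != self.params[k].data.shape:
                raise ValueError(f"parameter {k} shape mismatch")
            self.params[k].data = np.asarray(v, dtype=np.float64).copy()

    # -- forward ---------------------------------------------------------------
    def _gat_layer(self, H: Tensor, att_mask: np.ndarray, layer: int,
                   activate: bool) -> Tensor:
        B, n, _ = H.shape
        dout = self.layer_dims[layer][1]
        pre = None
        for k in range(self.heads[layer]):
            HW = H @ self.params[f"W{layer}h{k}"]  # (B, n, dout)
            s_src = HW @ self.params[f"a_src{layer}h{k}"]  # (B, n, 1)
            s_dst = HW @ self.params[f"a_dst{layer}h{k}"]
            scores = (s_src.reshape(B, n, 1) + s_dst.reshape(B, 1, n)).leaky_relu(self.slope)
            alpha = masked_softmax(scores, att_mask)
            term = alpha @ HW
            pre = term if pre is None else pre + term
        out = pre / float(self.heads[layer])
        return out.relu() if activate else out

    def forward(self, X, att_mask, node_mask, context, spectral,
                ablate_graph: bool = False, ablate_spectral: bool = False) -> Tensor:
        """Batched forward pass to logits.

        context: flattened F (context_dim,) shared by the batch, or (B, context_dim);
        spectral: per-graph features (B, spectral_dim).
        """
        B = X.shape[0]
        H = Tensor(np.asarray(X, dtype=np.float64))
        H = self._gat_layer(H, att_mask, 0, activate=True)
        H = self._gat_layer(H, att_mask, 1, activate=True)
        H = self._gat_layer(H, att_mask, 2, activate=False)
        # mean readout over real nodes
        m = node_mask.astype(np.float64)
        pooled = (H * m[:, :, None]).sum(axis=1) / m.sum(axis=1)[:, None]

        ctx = np.asarray(context, dtype=np.float64)
        if ctx.ndim == 1:
            ctx = np.broadcast_to(ctx, (B, ctx.shape[0]))
        if ablate_graph:
            ctx = np.zeros_like(ctx)
        g = np.asarray(spectral, dtype=np.float64)
        if ablate_spectral:
            g = np.zeros_like(g)
        fused = concat([pooled, Tensor(ctx), Tensor(g)], axis=-1)
        h = (fused @ self.params["head_W1"] + self.params["head_b1"]).relu()
        return h @ self.params["head_W2"] + self.params["head_b2"]

    def predict_graphs(self, graphs, context, spectral, **ablate) -> Prediction:
        """Forward a list of graphs to per-label probabilities (no gradients)."""
        X, _, node_mask, att_mask, _ = pad_batch(graphs)
        logits = self.forward(X, att_mask, node_mask, context,
                              np.asarray(spectral, dtype=np.float64), **ablate).data
        return Prediction(logits, 1.0 / (1.0 + np.exp(-logits)))
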