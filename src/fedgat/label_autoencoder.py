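"""Multi-scale graph attention autoencoder over the weighted label graph.

The encoder scores label pairs with a small neural similarity network
applied to graph-propagated linear projections of the weighted label
embeddings, softmax-normalizes the scores over each node's neighborhood
at scales 1..3, averages the per-head attention features (AMHA), and
concatenates the per-scale features into the label-context embedding F.
Training minimizes a masked reconstruction loss: edges of the label
graph are randomly dropped each epoch and a single-scale attention
decoder must reproduce the unmasked weighted embeddings.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Adam, Tensor, concat, glorot
from .label_semantics import LabelSemanticGraph, build_label_graph  # noqa: F401

__all__ = [
    "LabelContextEmbedding",
    "MultiScaleLabelAutoencoder",
    "attention_coefficients",
    "attend",
    "multi_head_feature",
    "neural_similarity",
    "reconstruction_loss",
    "masked_softmax",
    "ensure_self_edges",
]


@dataclass
class LabelContextEmbedding:
    """Per-label encodings, multi-scale concatenated: F is (C, n_scales * d_h)."""

    F: np.ndarray

    def __post_init__(self):
        self.F = np.asarray(self.F, dtype=np.float64)
        if not np.all(np.isfinite(self.F)):
            raise ValueError("label context embedding must be finite")

    @property
    def flat_dim(self) -> int:
        return self.F.size

    def flatten(self) -> np.ndarray:
        return self.F.ravel()


# --------------------------------------------------------------------------
# Functional pieces (also used by tests as the contract surface)
# --------------------------------------------------------------------------

def ensure_self_edges(mask: np.ndarray) -> np.ndarray:
    """Add a self-edge to every row with an empty neighborhood."""
    mask = mask.astype(bool).copy()
    empty = ~mask.any(axis=-1)
    if mask.ndim == 2:
        idx = np.where(empty)[0]
        mask[idx, idx] = True
    else:  # batched (B, n, n)
        b, i = np.where(empty)
        mask[b, i, i] = True
    return mask


def masked_softmax(scores: Tensor, mask: np.ndarray) -> Tensor:
    """Softmax over the last axis restricted to `mask`; rows sum to 1.

    `mask` must have a nonempty support in every row (use ensure_self_edges).
    """
    mask = np.broadcast_to(mask.astype(bool), scores.shape)
    neg = np.where(mask, scores.data, -np.inf)
    mx = neg.max(axis=-1, keepdims=True)  # constant shift for stability
    p = (scores - mx).exp() * mask.astype(np.float64)
    return p / p.sum(axis=-1, keepdims=True)


def attention_coefficients(scores, mask=None) -> np.ndarray:
    """Softmax attention coefficients over each node's neighborhood."""
    scores = np.asarray(scores, dtype=np.float64)
    if mask is None:
        mask = np.ones_like(scores, dtype=bool)
    mask = ensure_self_edges(np.broadcast_to(mask, scores.shape))
    return masked_softmax(Tensor(scores), mask).data


def attend(alpha, V, embeddings, adj=None) -> np.ndarray:
    """Single-head attention feature f_i = ReLU(sum_j alpha_ij V l̃_j)."""
    alpha = np.asarray(alpha, dtype=np.float64)
    if adj is not None:
        alpha = alpha * (np.asarray(adj) != 0)
    return np.maximum(alpha @ (np.asarray(embeddings) @ np.asarray(V)), 0.0)


def multi_head_feature(alphas, Vs, embeddings, adj=None) -> np.ndarray:
    """Averaged multi-head attention: ReLU of the mean pre-activation over heads."""
    embeddings = np.asarray(embeddings, dtype=np.float64)
    pre = np.zeros((embeddings.shape[0], np.asarray(Vs[0]).shape[1]))
    for alpha, V in zip(alphas, Vs):
        a = np.asarray(alpha, dtype=np.float64)
        if adj is not None:
            a = a * (np.asarray(adj) != 0)
        pre += a @ (embeddings @ np.asarray(V))
    return np.maximum(pre / len(alphas), 0.0)


def reconstruction_loss(X, recon) -> float:
    """Mean over nodes of the squared reconstruction error (summed over dims)."""
    X = np.asarray(X, dtype=np.float64)
    recon = np.asarray(recon, dtype=np.float64)
    if X.shape != recon.shape:
        raise ValueError("shape mismatch")
    return float(np.mean(np.sum((X - recon) ** 2, axis=-1)))


def _row_normalized(adj: np.ndarray) -> np.ndarray:
    """Row-normalize adj + I (the propagation operator of the pre-transform)."""
    A = adj.astype(np.float64) + np.eye(adj.shape[0])
    return A / A.sum(axis=1, keepdims=True)


def _scale_adjacencies(adj1: np.ndarray, scales) -> dict:
    """s-hop reachability adjacencies of adj1 (nested, no self-loops)."""
    C = adj1.shape[0]
    off = ~np.eye(C, dtype=bool)
    reach = adj1.astype(bool) | np.eye(C, dtype=bool)
    power = np.eye(C, dtype=bool)
    out = {}
    for s in range(1, max(scales) + 1):
        power = power @ reach
        if s in scales:
            out[s] = (power & off).astype(np.int8)
    return out


# --------------------------------------------------------------------------
# The autoencoder
# --------------------------------------------------------------------------

class MultiScaleLabelAutoencoder:
    """Attention autoencoder over a weighted label semantic graph.

    Parameters
    ----------
    dim : embedding dimension d of the weighted label embeddings.
    hidden_dim : per-head feature width d_h.
    n_heads : attention heads per scale (averaged, not concatenated).
    scales : neighborhood scales; F is the concatenation over these.
    mask_rate : per-epoch Bernoulli edge-dropout rate of the label graph.
    """

    def __init__(self, dim: int, hidden_dim: int = 32, n_heads: int = 4,
                 scales=(1, 2, 3), mask_rate: float = 0.15, seed: int = 0):
        if n_heads < 1:
            raise ValueError("need at least one attention head")
        if not 0.0 <= mask_rate < 1.0:
            raise ValueError("mask_rate must be in [0, 1)")
        self.dim = dim
        self.hidden_dim = hidden_dim
        self.n_heads = n_heads
        self.scales = tuple(scales)
        self.mask_rate = mask_rate
        rng = np.random.default_rng(seed)
        d, h = dim, hidden_dim
        p: dict[str, Tensor] = {"W": glorot(rng, d, h)}  # shared projection (pre-transform)
        for s in self.scales:
            for k in range(n_heads):
                tag = f"s{s}h{k}"
                p[f"V_{tag}"] = glorot(rng, d, h)
                p[f"sc1_{tag}"] = glorot(rng, 2 * h, h)
                p[f"sb1_{tag}"] = Tensor(np.zeros(h), requires_grad=True)
                p[f"sc2_{tag}"] = glorot(rng, h, 1)
                p[f"sb2_{tag}"] = Tensor(np.zeros(1), requires_grad=True)
        # decoder: one attention layer at scale 1 over F, then linear back to d
        dF = len(self.scales) * h
        p["W_dec"] = glorot(rng, dF, h)
        p["V_dec"] = glorot(rng, dF, h)
        p["dc1"] = glorot(rng, 2 * h, h)
        p["db1"] = Tensor(np.zeros(h), requires_grad=True)
        p["dc2"] = glorot(rng, h, 1)
        p["db2"] = Tensor(np.zeros(1), requires_grad=True)
        p["W_out"] = glorot(rng, h, d)
        p["b_out"] = Tensor(np.zeros(d), requires_grad=True)
        self.params = p

    # -- parameter plumbing ---------------------------------------------------
    def parameters(self) -> dict:
        return self.params

    def state_dict(self) -> dict:
        return {k: v.data.copy() for k, v in self.params.items()}

    def load_state_dict(self, state: dict) -> None:
        for k, v in state.items():
            self.params[k].data = np.asarray(v, dtype=np.float64).copy()

    # -- forward pieces --------------------------------------------------------
    def _pair_scores(self, Z: Tensor, scale: int, head: int) -> Tensor:
        """Neural similarity scores for all label pairs: MLP(concat(Z_i, Z_j))."""
        C = Z.shape[0]
        zeros = np.zeros((C, C, self.hidden_dim))
        Zi = Z.reshape(C, 1, self.hidden_dim) + zeros
        Zj = Z.reshape(1, C, self.hidden_dim) + zeros
        pair = concat([Zi, Zj], axis=-1)
        tag = f"s{scale}h{head}"
        h1 = (pair @ self.params[f"sc1_{tag}"] + self.params[f"sb1_{tag}"]).leaky_relu(0.2)
        return (h1 @ self.params[f"sc2_{tag}"] + self.params[f"sb2_{tag}"]).reshape(C, C)

    def _encode_t(self, L_tilde: np.ndarray, adjs: dict) -> Tensor:
        """Differentiable encoder: returns F as a (C, n_scales * d_h) Tensor."""
        Lt = Tensor(L_tilde)
        Ahat = _row_normalized(adjs[self.scales[0]])
        Z = Tensor(Ahat) @ (Lt @ self.params["W"])  # propagated projection (shared)
        feats = []
        for s in self.scales:
            mask = ensure_self_edges(adjs[s])
            pre = None
            for k in range(self.n_heads):
                alpha = masked_softmax(self._pair_scores(Z, s, k), mask)
                term = alpha @ (Lt @ self.params[f"V_s{s}h{k}"])
                pre = term if pre is None else pre + term
            feats.append((pre / float(self.n_heads)).relu())
        return concat(feats, axis=-1)

    def _decode_t(self, F: Tensor, adj1: np.ndarray) -> Tensor:
        C = F.shape[0]
        Ahat = _row_normalized(adj1)
        Z = Tensor(Ahat) @ (F @ self.params["W_dec"])
        zeros = np.zeros((C, C, self.hidden_dim))
        Zi = Z.reshape(C, 1, self.hidden_dim) + zeros
        Zj = Z.reshape(1, C, self.hidden_dim) + zeros
        pair = concat([Zi, Zj], axis=-1)
        h1 = (pair @ self.params["dc1"] + self.params["db1"]).leaky_relu(0.2)
        scores = (h1 @ self.params["dc2"] + self.params["db2"]).reshape(C, C)
        alpha = masked_softmax(scores, ensure_self_edges(adj1))
        attended = (alpha @ (F @ self.params["V_dec"])).relu()
        return attended @ self.params["W_out"] + self.params["b_out"]

    # -- public API -------------------------------------------------------------
    def neural_similarity(self, A_masked: np.ndarray, L_tilde: np.ndarray,
                          i: int, j: int, scale: int = None, head: int = 0) -> float:
        """Score of the ordered pair (i, j) under the masked-graph pre-transform."""
        scale = self.scales[0] if scale is None else scale
        Lt = Tensor(np.asarray(L_tilde, dtype=np.float64))
        Z = Tensor(_row_normalized(np.asarray(A_masked))) @ (Lt @ self.params["W"])
        return float(self._pair_scores(Z, scale, head).data[i, j])

    def encode(self, graph: LabelSemanticGraph) -> LabelContextEmbedding:
        """Deterministic (unmasked) encoding of the label graph into F."""
        adjs = {s: graph.scale_adjacencies[s] for s in self.scales}
        return LabelContextEmbedding(self._encode_t(graph.node_embeddings, adjs).data)

    def _loss_t(self, L_tilde: np.ndarray, adjs: dict) -> Tensor:
        F = self._encode_t(L_tilde, adjs)
        recon = self._decode_t(F, adjs[self.scales[0]])
        err = recon - Tensor(L_tilde)
        return (err * err).sum(axis=-1).mean()

    def evaluate_loss(self, graph: LabelSemanticGraph) -> float:
        adjs = {s: graph.scale_adjacencies[s] for s in self.scales}
        return self._loss_t(graph.node_embeddings, adjs).item()

    def _masked_adjacencies(self, adj1: np.ndarray, rng: np.random.Generator) -> dict:
        """Drop each undirected edge of adj1 with prob mask_rate, rebuild scales."""
        C = adj1.shape[0]
        keep = rng.random((C, C)) >= self.mask_rate
        keep = np.triu(keep, k=1)
        masked = (np.triu(adj1, k=1) * keep)
        masked = masked + masked.T
        return _scale_adjacencies(masked, self.scales)

    def train(self, graph: LabelSemanticGraph, epochs: int = 200, lr: float = 1e-3,
              seed: int = 0) -> dict:
        """Train on one label graph; returns train/eval loss traces."""
        if epochs < 1:
            raise ValueError("epochs must be >= 1")
        rng = np.random.default_rng(seed)
        opt = Adam(self.params, lr=lr)
        adj1 = graph.scale_adjacencies[self.scales[0]]
        train_trace, eval_trace = [], []
        for epoch in range(epochs):
            adjs = self._masked_adjacencies(adj1, rng)
            loss = self._loss_t(graph.node_embeddings, adjs)
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"autoencoder diverged at epoch {epoch}: loss={loss.data!r}"
                )
            opt.zero_grad()
            loss.backward()
            opt.step()
            train_trace.append(loss.item())
            eval_trace.append(self.evaluate_loss(graph))
        return {"train_loss": np.array(train_trace), "eval_loss": np.array(eval_trace),
                "final_loss": eval_trace[-1]}


def neural_similarity(model: MultiScaleLabelAutoencoder, A_masked, L_tilde,
                      i: int, j: int, scale: int = None, head: int = 0) -> float:
    """Functional wrapper over MultiScaleLabelAutoencoder.neural_similarity."""
    return model.neural_similarity(A_masked, L_tilde, i, j, scale=scale, head=head)
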