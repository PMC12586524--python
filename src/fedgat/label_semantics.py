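"""Client-specific label semantics.

Each client weights a shared set of label embeddings by its own label
frequencies, then builds a weighted label semantic graph whose nodes are
the weighted embeddings and whose edges are cosine similarities. The
graph carries a nested family of binary adjacencies at scales 1..3
(s-hop reachability of the thresholded similarity graph) consumed by the
multi-scale autoencoder.

The default embedding provider produces deterministic pseudo-random unit
vectors seeded by a stable hash of the label string; any callable
mapping a label name to a vector (e.g. a real text encoder) can be
plugged in instead.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

import numpy as np

from .graph_data import ClientShard, LabelSpace

__all__ = [
    "LabelEmbeddingSet",
    "LabelDistribution",
    "LabelSemanticGraph",
    "count_label_frequencies",
    "compute_label_weights",
    "embed_labels",
    "weight_embeddings",
    "build_label_graph",
    "hash_embedding_provider",
]


@dataclass
class LabelEmbeddingSet:
    """C x d matrix of label embeddings, one row per label in space order."""

    vectors: np.ndarray
    dim: int

    def __post_init__(self):
        self.vectors = np.asarray(self.vectors, dtype=np.float64)
        if self.vectors.ndim != 2 or self.vectors.shape[1] != self.dim:
            raise ValueError("vectors must be (C, dim)")
        if not np.all(np.isfinite(self.vectors)):
            raise ValueError("embeddings must be finite")


@dataclass
class LabelDistribution:
    """Per-client label frequencies and their smoothed-ratio weights."""

    frequencies: np.ndarray
    weights: np.ndarray
    smoothing: float

    def __post_init__(self):
        self.frequencies = np.asarray(self.frequencies)
        self.weights = np.asarray(self.weights, dtype=np.float64)
        if abs(self.weights.sum() - 1.0) > 1e-12:
            raise ValueError("label weights must sum to 1")


@dataclass
class LabelSemanticGraph:
    node_embeddings: np.ndarray  # (C, d) weighted embeddings
    edge_weights: np.ndarray  # (C, C) cosine similarities
    scale_adjacencies: dict  # scale -> binary (C, C), no self-loops


def count_label_frequencies(shard: ClientShard) -> np.ndarray:
    """f_k = number of graphs in the shard that carry label k."""
    return np.sum([g.labels for g in shard.graphs], axis=0).astype(np.int64)


def compute_label_weights(f, eps: float = 1.0, mode: str = "ratio") -> np.ndarray:
    """Normalize label frequencies into weights summing to 1.

    ``ratio`` (default) is the smoothed ratio w_k = (f_k + eps) / sum_j (f_j + eps);
    ``softmax`` exponentiates the frequencies first (an alternative reading of
    "softmax normalization", off by default).
    """
    f = np.asarray(f, dtype=np.float64)
    if eps <= 0:
        raise ValueError("smoothing eps must be > 0")
    if mode == "ratio":
        num = f + eps
    elif mode == "softmax":
        num = np.exp(f - f.max())
    else:
        raise ValueError(f"unknown weight mode {mode!r}")
    return num / num.sum()


def hash_embedding_provider(dim: int = 64):
    """Deterministic stub encoder: unit vectors seeded by a hash of the name."""

    def provider(name: str) -> np.ndarray:
        digest = hashlib.sha256(name.encode("utf-8")).digest()
        seed = int.from_bytes(digest[:4], "big")
        rng = np.random.default_rng(seed)
        v = rng.standard_normal(dim)
        return v / np.linalg.norm(v)

    return provider


def embed_labels(space: LabelSpace, provider="hash", dim: int = 64) -> LabelEmbeddingSet:
    """Embed each label name; rows are L2-normalized.

    ``provider`` is either the string "hash" (default deterministic stub) or
    any callable mapping a label name to a vector. A provider failure is
    raised, never silently replaced.
    """
    if provider == "hash":
        provider = hash_embedding_provider(dim)
    elif not callable(provider):
        raise ValueError(f"unknown embedding provider {provider!r}")
    rows = []
    for name in space.names:
        v = np.asarray(provider(name), dtype=np.float64).ravel()
        if not np.all(np.isfinite(v)):
            raise ValueError(f"embedding provider returned non-finite vector for {name!r}")
        norm = np.linalg.norm(v)
        if norm == 0:
            raise ValueError(f"embedding provider returned a zero vector for {name!r}")
        rows.append(v / norm)
    vectors = np.vstack(rows)
    return LabelEmbeddingSet(vectors, vectors.shape[1])


def weight_embeddings(embeddings: LabelEmbeddingSet, w) -> np.ndarray:
    """l̃_k = w_k * l_k (per-label scaling)."""
    w = np.asarray(w, dtype=np.float64)
    if w.shape[0] != embeddings.vectors.shape[0]:
        raise ValueError("weight vector length must equal the number of labels")
    return embeddings.vectors * w[:, None]


def cosine_matrix(X: np.ndarray) -> np.ndarray:
    """Pairwise cosine similarities; rows with zero norm get all-zero entries."""
    X = np.asarray(X, dtype=np.float64)
    norms = np.linalg.norm(X, axis=1)
    safe = np.where(norms > 0, norms, 1.0)
    S = (X / safe[:, None]) @ (X / safe[:, None]).T
    S = np.clip(S, -1.0, 1.0)
    zero = norms == 0
    S[zero, :] = 0.0
    S[:, zero] = 0.0
    return S


def build_label_graph(weighted_embeddings, scales=(1, 2, 3), threshold="mean") -> LabelSemanticGraph:
    """Build the weighted label semantic graph and its multi-scale adjacencies.

    adj_1 keeps edge (i, j), i != j, iff cosine(l̃_i, l̃_j) >= tau, where tau is
    the mean off-diagonal similarity ("mean", default) or an absolute float.
    adj_s is s-hop reachability of adj_1 (support of (adj_1 + I)^s, diagonal
    removed), so edge sets are nested across scales.
    """
    X = np.asarray(weighted_embeddings, dtype=np.float64)
    C = X.shape[0]
    S = cosine_matrix(X)

    off = ~np.eye(C, dtype=bool)
    if threshold == "mean":
        tau = float(S[off].mean()) if C > 1 else 0.0
    else:
        tau = float(threshold)
    adj1 = ((S >= tau) & off).astype(np.int8)
    adj1 = np.maximum(adj1, adj1.T)  # S symmetric, but be explicit

    adjacencies = {}
    reach = adj1.astype(bool) | np.eye(C, dtype=bool)
    power = np.eye(C, dtype=bool)
    for s in range(1, max(scales) + 1):
        power = power @ reach
        if s in scales:
            adjacencies[s] = (power & off).astype(np.int8)
    return LabelSemanticGraph(X, S, adjacencies)
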