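"""The federated learning engine.

Each round, every client runs the local pipeline (label semantics →
autoencoder → backbone training) from the current global weights and
transmits its updated weights together with a privatized spectral summary
of its graphs. The server builds a cosine similarity matrix between the
summaries, spectral-clusters the clients into structurally similar
groups, federated-averages within each group, and fuses the group models
with trace-gated coefficients. An asynchronous mode simulates staggered
client arrivals: each group aggregates as soon as all of its members'
reports arrive and the gated fusion re-runs after every group update.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import SpectralClustering

from .autodiff import Adam
from .backbone import MultiLabelGATClassifier, pad_batch, total_loss
from .config import ExperimentConfig
from .evaluation import evaluate_scores
from .graph_data import ClientShard, FederatedDataset
from .label_autoencoder import MultiScaleLabelAutoencoder
from .label_semantics import (build_label_graph, compute_label_weights,
                              count_label_frequencies, embed_labels, weight_embeddings)
from .spectral import (PrivatizedClientSummary, client_spectral_summary,
                       default_sensitivity, graph_spectral_feature, privatize)

logger = logging.getLogger(__name__)

__all__ = [
    "ClientReport", "GroupAssignment", "ClientState", "FederationHistory",
    "local_train", "similarity_matrix", "cluster_clients", "group_average",
    "gated_fusion", "fedavg", "run_federation", "global_objective",
]


@dataclass
class ClientReport:
    client_id: str
    weights: dict  # name -> ndarray, identical signature across clients
    summary: PrivatizedClientSummary
    n_samples: int
    round: int
    arrival_time: float = 0.0
    failed: bool = False
    train_loss: float = float("nan")


@dataclass
class GroupAssignment:
    groups: list  # list of lists of client ids (disjoint cover)
    similarity: np.ndarray  # (K, K)
    client_ids: list

    def group_of(self, client_id: str) -> int:
        for p, members in enumerate(self.groups):
            if client_id in members:
                return p
        raise KeyError(client_id)


# --------------------------------------------------------------------------
# Server-side aggregation
# --------------------------------------------------------------------------

def _check_signatures(weight_maps):
    sig = {k: v.shape for k, v in weight_maps[0].items()}
    for w in weight_maps[1:]:
        if {k: v.shape for k, v in w.items()} != sig:
            raise ValueError("client weight signatures do not match")


def fedavg(weight_maps, sample_sizes=None) -> dict:
    """(Weighted) federated average of named weight maps."""
    if not weight_maps:
        raise ValueError("nothing to average")
    _check_signatures(weight_maps)
    if sample_sizes is None:
        coef = np.full(len(weight_maps), 1.0 / len(weight_maps))
    else:
        coef = np.asarray(sample_sizes, dtype=np.float64)
        coef = coef / coef.sum()
    return {k: sum(c * w[k] for c, w in zip(coef, weight_maps))
            for k in weight_maps[0]}


def similarity_matrix(summaries) -> np.ndarray:
    """Cosine similarities between client summaries; zero vectors give zero rows."""
    G = np.stack([np.asarray(s, dtype=np.float64) for s in summaries])
    norms = np.linalg.norm(G, axis=1)
    safe = np.where(norms > 0, norms, 1.0)
    S = (G / safe[:, None]) @ (G / safe[:, None]).T
    S = np.clip(S, -1.0, 1.0)
    zero = norms == 0
    S[zero, :] = 0.0
    S[:, zero] = 0.0
    return S


def _eigengap_n_groups(affinity: np.ndarray, cap: int) -> int:
    """Pick the group count at the largest eigengap of the normalized Laplacian."""
    K = affinity.shape[0]
    deg = affinity.sum(axis=1)
    inv = np.where(deg > 0, 1.0 / np.sqrt(deg), 0.0)
    L = np.eye(K) - inv[:, None] * affinity * inv[None, :]
    vals = np.linalg.eigvalsh(L)  # ascending
    gaps = np.diff(vals)[:cap]
    return int(np.argmax(gaps)) + 1 if len(gaps) else 1


def cluster_clients(S: np.ndarray, client_ids, n_groups="auto", seed: int = 0) -> GroupAssignment:
    """Spectral clustering of clients on their summary-similarity matrix.

    "auto" selects the group count by the largest eigengap of the
    similarity-graph Laplacian, capped at ceil(K/2).
    """
    client_ids = list(client_ids)
    K = len(client_ids)
    if S.shape != (K, K):
        raise ValueError("similarity matrix shape does not match client count")
    if K == 1:
        return GroupAssignment([[client_ids[0]]], S, client_ids)
    affinity = np.clip(S, 0.0, None)
    if n_groups == "auto":
        n_groups = _eigengap_n_groups(affinity, cap=int(np.ceil(K / 2)))
    n_groups = int(n_groups)
    if n_groups <= 1:
        return GroupAssignment([list(client_ids)], S, client_ids)
    if n_groups >= K:
        return GroupAssignment([[c] for c in client_ids], S, client_ids)
    affinity = affinity + 1e-12 * np.eye(K)  # keep fully-disconnected rows valid
    labels = SpectralClustering(
        n_clusters=n_groups, affinity="precomputed", random_state=int(seed),
        assign_labels="kmeans", n_init=10,
    ).fit_predict(affinity)
    groups = [[client_ids[i] for i in np.where(labels == p)[0]]
              for p in range(n_groups)]
    groups = [g for g in groups if g]
    return GroupAssignment(groups, S, client_ids)


def group_average(reports, weighted: bool = False) -> dict:
    """Within-group FedAvg; unweighted mean by default, sample-weighted optionally."""
    if not reports:
        raise ValueError("empty group")
    sizes = [r.n_samples for r in reports] if weighted else None
    return fedavg([r.weights for r in reports], sizes)


def gated_fusion(group_weights, assignment: GroupAssignment, gating: str = "trace"):
    """Fuse group models: W_global = sum_p beta_p W_Gp.

    beta_p = trace(S_Gp) / sum_q trace(S_Gq) with S_Gp the intra-group
    similarity submatrix; the "offdiag_mean" variant uses mean off-diagonal
    similarity instead (singletons count 1). Zero total trace falls back to
    uniform coefficients with a logged warning.
    """
    idx = {c: i for i, c in enumerate(assignment.client_ids)}
    stats = []
    for members in assignment.groups:
        ii = [idx[c] for c in members]
        sub = assignment.similarity[np.ix_(ii, ii)]
        if gating == "trace":
            stats.append(float(np.trace(sub)))
        elif gating == "offdiag_mean":
            m = len(ii)
            stats.append(1.0 if m == 1 else float(sub[~np.eye(m, dtype=bool)].mean()))
        else:
            raise ValueError(f"unknown gating {gating!r}")
    stats = np.asarray(stats, dtype=np.float64)
    if stats.sum() <= 0:
        logger.warning("gated_fusion: all gating statistics are zero; using uniform beta")
        beta = np.full(len(stats), 1.0 / len(stats))
    else:
        beta = stats / stats.sum()
    fused = {k: sum(b * w[k] for b, w in zip(beta, group_weights))
             for k in group_weights[0]}
    return fused, beta


def global_objective(reports, total_samples: int = None) -> float:
    """Sample-weighted global objective: sum_i (M^i / |M|) L_i."""
    ok = [r for r in reports if not r.failed and np.isfinite(r.train_loss)]
    if not ok:
        return float("nan")
    total = total_samples or sum(r.n_samples for r in ok)
    return float(sum(r.n_samples / total * r.train_loss for r in ok))


# --------------------------------------------------------------------------
# Client-side state and local training
# --------------------------------------------------------------------------

class ClientState:
    """Per-client cache: data split, label pipeline outputs, spectral summary.

    The label-context embedding F and the spectral features depend only on
    the client's data, so they are computed once and reused every round.
    """

    def __init__(self, shard: ClientShard, config: ExperimentConfig, seed: int):
        self.shard = shard
        self.config = config
        self.seed = int(seed)
        rng = np.random.default_rng(self.seed)
        n = shard.n_samples
        n_test = max(1, int(round(config.federation.test_fraction * n))) if n > 1 else 0
        perm = rng.permutation(n)
        self.test_graphs = [shard.graphs[i] for i in perm[:n_test]]
        self.train_graphs = [shard.graphs[i] for i in perm[n_test:]]

        self._prepare_label_pipeline(rng)
        self._prepare_spectral()

    def _prepare_label_pipeline(self, rng):
        cfg = self.config
        C = self.shard.label_space.C
        scales = cfg.ae_scales
        self.context_dim = C * len(scales) * cfg.ae.hidden_dim
        if cfg.ablate.graph:
            self.context = np.zeros(self.context_dim)
            self.ae_loss = 0.0
            self.autoencoder = None
            self.label_graph = None
            return
        emb = embed_labels(self.shard.label_space, provider=cfg.labels.embedding_provider,
                           dim=cfg.labels.embedding_dim)
        if cfg.ablate.weighted:
            weighted = emb.vectors  # ablation: skip the frequency weighting
        else:
            f = count_label_frequencies(self.shard)
            w = compute_label_weights(f, eps=cfg.labels.smoothing_eps,
                                      mode=cfg.labels.weight_mode)
            weighted = weight_embeddings(emb, w)
        self.label_graph = build_label_graph(weighted, scales=scales,
                                             threshold=cfg.labels.similarity_threshold)
        self.autoencoder = MultiScaleLabelAutoencoder(
            dim=cfg.labels.embedding_dim, hidden_dim=cfg.ae.hidden_dim,
            n_heads=cfg.ae.heads, scales=scales, mask_rate=cfg.ae.mask_rate,
            seed=int(rng.integers(2**31)))
        trace = self.autoencoder.train(self.label_graph, epochs=cfg.ae.epochs,
                                       lr=cfg.ae.lr, seed=int(rng.integers(2**31)))
        self.ae_loss = trace["final_loss"]
        self.context = self.autoencoder.encode(self.label_graph).flatten()

    def _prepare_spectral(self):
        sp = self.config.spectral
        feats = {g.graph_id: graph_spectral_feature(g.adjacency, sp.M, sp.N_max)
                 for g in self.shard.graphs}
        self.spectral_features = feats
        self.summary_mean = client_spectral_summary(
            [feats[g.graph_id] for g in self.train_graphs or self.shard.graphs])
        if sp.delta_f == "auto":
            self.delta_f = default_sensitivity(sp.M, len(self.train_graphs or self.shard.graphs))
        else:
            self.delta_f = float(sp.delta_f)

    def spectral_batch(self, graphs) -> np.ndarray:
        return np.stack([self.spectral_features[g.graph_id].g for g in graphs])

    def make_model(self, seed: int = 0) -> MultiLabelGATClassifier:
        bb = self.config.backbone
        sp = self.config.spectral
        return MultiLabelGATClassifier(
            in_dim=self.shard.graphs[0].node_features.shape[1],
            n_labels=self.shard.label_space.C,
            context_dim=self.context_dim,
            spectral_dim=sp.N_max * sp.M,
            hidden=bb.hidden, heads=bb.heads, leaky_slope=bb.leaky_slope,
            head_hidden=bb.head_hidden, seed=seed)


def local_train(state: ClientState, global_weights: dict, config: ExperimentConfig,
                seed: int, round_idx: int = 0) -> ClientReport:
    """One client's round: load global weights, train locally, privatize summary."""
    rng = np.random.default_rng(seed)
    model = state.make_model(seed=0)
    model.load_state_dict(global_weights)

    graphs = state.train_graphs or state.shard.graphs
    joint = config.federation.loss_mode == "joint" and state.autoencoder is not None
    params = dict(model.parameters())
    if joint:
        params.update({f"ae:{k}": v for k, v in state.autoencoder.parameters().items()})
    opt = Adam(params, lr=config.federation.lr)
    bs = config.federation.batch_size
    failed = False
    last_loss = float("nan")
    epoch_losses = []
    for _ in range(config.federation.local_epochs):
        order = rng.permutation(len(graphs))
        batch_losses = []
        for start in range(0, len(order), bs):
            batch = [graphs[i] for i in order[start:start + bs]]
            X, _, node_mask, att_mask, Y = pad_batch(batch)
            if joint:
                adjs = {s: state.label_graph.scale_adjacencies[s]
                        for s in state.autoencoder.scales}
                ae_t = state.autoencoder._loss_t(state.label_graph.node_embeddings, adjs)
                context = state.autoencoder._encode_t(
                    state.label_graph.node_embeddings, adjs).data.ravel()
                logits = model.forward(X, att_mask, node_mask, context,
                                       state.spectral_batch(batch),
                                       ablate_graph=config.ablate.graph)
                loss = total_loss(logits, Y, 0.0) + ae_t
            else:
                logits = model.forward(X, att_mask, node_mask, state.context,
                                       state.spectral_batch(batch),
                                       ablate_graph=config.ablate.graph)
                loss = total_loss(logits, Y, state.ae_loss)
            if not np.isfinite(loss.data):
                failed = True
                logger.warning("client %s diverged (non-finite loss); report excluded",
                               state.shard.client_id)
                break
            opt.zero_grad()
            loss.backward()
            opt.step()
            batch_losses.append(loss.item())
        if failed:
            break
        epoch_losses.append(float(np.mean(batch_losses)))
        last_loss = epoch_losses[-1]

    summary = privatize(state.summary_mean, epsilon=config.spectral.epsilon,
                        delta_f=state.delta_f, rng=rng)
    return ClientReport(
        client_id=state.shard.client_id,
        weights=model.state_dict(),
        summary=summary,
        n_samples=len(graphs),
        round=round_idx,
        arrival_time=float(rng.random()),
        failed=failed,
        train_loss=last_loss,
    )


# --------------------------------------------------------------------------
# The round loop
# --------------------------------------------------------------------------

@dataclass
class FederationHistory:
    rounds: list = field(default_factory=list)
    final_weights: dict = None

    def to_jsonl(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            for rec in self.rounds:
                fh.write(json.dumps(rec) + "\n")

    @property
    def final_metrics(self) -> dict:
        return self.rounds[-1]["metrics"] if self.rounds else {}


def _evaluate_global(states, weights, config) -> dict:
    scores, truths = [], []
    for st in states:
        graphs = st.test_graphs or st.train_graphs
        model = st.make_model(seed=0)
        model.load_state_dict(weights)
        pred = model.predict_graphs(graphs, st.context, st.spectral_batch(graphs),
                                    ablate_graph=config.ablate.graph)
        scores.append(pred.probabilities)
        truths.append(np.stack([g.labels for g in graphs]))
    scores = np.vstack(scores)
    truths = np.vstack(truths)
    try:
        res = evaluate_scores(scores, truths)
        return res.as_dict()
    except ValueError as exc:  # every label degenerate in the test pool
        logger.warning("round evaluation skipped: %s", exc)
        return {}


def run_federation(dataset: FederatedDataset, config: ExperimentConfig = None,
                   seed: int = 0, rounds: int = None) -> FederationHistory:
    """Run T communication rounds; fully reproducible from `seed`."""
    config = config or ExperimentConfig()
    T = config.federation.rounds if rounds is None else rounds
    ss = np.random.SeedSequence(seed)
    state_seeds, init_seed, round_entropy = ss.spawn(3)
    state_children = state_seeds.spawn(dataset.K)
    states = [ClientState(shard, config, int(cs.generate_state(1)[0] % 2**31))
              for shard, cs in zip(dataset.shards, state_children)]

    template = states[0].make_model(seed=int(init_seed.generate_state(1)[0] % 2**31))
    global_weights = template.state_dict()
    total = dataset.total_samples
    history = FederationHistory()
    round_seeds = round_entropy.spawn(T)

    for t in range(T):
        rseed = round_seeds[t]
        client_seeds = rseed.spawn(dataset.K + 1)
        reports = [
            local_train(st, global_weights, config,
                        int(cs.generate_state(1)[0] % 2**31), round_idx=t)
            for st, cs in zip(states, client_seeds[:dataset.K])
        ]
        ok = [r for r in reports if not r.failed]
        if not ok:
            logger.warning("round %d: no successful client reports; round skipped", t)
            history.rounds.append({"round": t, "skipped": True})
            continue

        record = {"round": t, "n_reports": len(ok)}
        if config.ablate.asyagg:
            # ablation: plain sample-weighted FedAvg over all reports
            global_weights = fedavg([r.weights for r in ok], [r.n_samples for r in ok])
            record["aggregation"] = "fedavg"
        else:
            S = similarity_matrix([r.summary.g_tilde for r in ok])
            assignment = cluster_clients(
                S, [r.client_id for r in ok], n_groups=config.federation.n_groups,
                seed=int(client_seeds[-1].generate_state(1)[0] % 2**31))
            by_id = {r.client_id: r for r in ok}
            if config.federation.mode == "async":
                # groups aggregate as their last member arrives; fusion re-runs
                # after every group update using the latest W_Gp of each group
                group_w = [global_weights for _ in assignment.groups]
                order = np.argsort([max(by_id[c].arrival_time for c in members)
                                    for members in assignment.groups])
                fusion_events = []
                for p in order:
                    members = assignment.groups[p]
                    group_w[p] = group_average(
                        [by_id[c] for c in members],
                        weighted=config.federation.weighted_group_average)
                    global_weights, beta = gated_fusion(group_w, assignment,
                                                        gating=config.federation.gating)
                    fusion_events.append({"group": int(p), "beta": beta.tolist()})
                record["fusion_events"] = fusion_events
            else:
                group_w = [group_average([by_id[c] for c in members],
                                         weighted=config.federation.weighted_group_average)
                           for members in assignment.groups]
                global_weights, beta = gated_fusion(group_w, assignment,
                                                    gating=config.federation.gating)
                record["beta"] = beta.tolist()
            record["groups"] = assignment.groups
            record["aggregation"] = "clustered"
        record["global_loss"] = global_objective(ok, total)
        record["metrics"] = _evaluate_global(states, global_weights, config)
        history.rounds.append(record)

    history.final_weights = global_weights
    return history
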