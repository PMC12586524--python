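"""Client-specific label semantics: frequency weighting, the weighted label
graph, and the multi-scale attention autoencoder that turns it into a
label-context embedding F.

Labels a client sees often get larger weights (smoothed ratio of
frequencies), which scale the label embeddings before the cosine label
graph is built; the autoencoder then learns per-label context vectors by
reconstructing the weighted embeddings from masked versions of the graph.
"""

import numpy as np

from fedgat import (MultiScaleLabelAutoencoder, SyntheticSpec, build_label_graph,
                    compute_label_weights, count_label_frequencies, embed_labels,
                    generate, weight_embeddings)

ds, _ = generate(SyntheticSpec(), seed=0)
shard = ds.shards[0]

f = count_label_frequencies(shard)
w = compute_label_weights(f, eps=1.0)
print("label frequencies:", f, f"(of {shard.n_samples} graphs)")
print("label weights    :", w.round(3), "(sum =", round(w.sum(), 12), ")")

emb = embed_labels(shard.label_space, dim=64)
graph = build_label_graph(weight_embeddings(emb, w))
print("\nlabel-graph cosine similarities:\n", graph.edge_weights.round(2))
print("edges per scale:",
      {s: int(a.sum() // 2) for s, a in graph.scale_adjacencies.items()},
      "(scale s = s-hop reachability, nested)")

ae = MultiScaleLabelAutoencoder(dim=64, hidden_dim=32, n_heads=4, seed=0)
trace = ae.train(graph, epochs=100, lr=1e-3, seed=1)
F = ae.encode(graph)
print(f"\nreconstruction loss: {trace['eval_loss'][0]:.4f} -> {trace['final_loss']:.4f}"
      " (lower = label context captured)")
print("label-context embedding F:", F.F.shape, "-> flattened", F.flat_dim,
      "values fed to every classifier forward pass of this client")
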