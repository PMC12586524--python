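# fedgat — federated multi-label graph classification

`fedgat` is a library plus a single-process simulator for **federated
multi-label graph classification** under the two heterogeneities that break
plain FedAvg on graph data: clients whose **graph structures** come from
different distributions, and clients whose **label distributions** are
skewed. The intended users are researchers in cheminformatics and federated
graph learning who want a tested, dependency-light reference implementation
that runs end to end on synthetic data with no downloads.

## The method

K clients share a label space of C classes; each graph `x` carries a binary
label vector `y ∈ {0,1}^C`. The federated objective is the sample-weighted
sum of client risks, `W* = argmin_W Σ_i (Mⁱ/|M|) L_i(W)`. Around a shared
three-layer graph-attention (GAT) backbone, three components address the
heterogeneity:

1. **Client-specific label semantics.** Each client counts label frequencies
   `f_k = Σ_i 1[y_k ∈ Y_i]`, normalizes them with a smoothed ratio
   `w_k = (f_k + ε) / Σ_j (f_j + ε)`, and scales label embeddings
   `l̃_k = w_k · l_k`. A weighted label semantic graph (cosine similarities
   between the `l̃_k`) is encoded by a **multi-scale graph attention
   autoencoder**: a neural scorer `MLP(concat(A·W·l̃_i, A·W·l̃_j))` feeds
   softmax attention `α_ij = exp(s_ij)/Σ_j' exp(s_ij')`, per-head features
   `f_i = ReLU(Σ_j α_ij V l̃_j)` are averaged over heads and concatenated
   over neighborhood scales s ∈ {1,2,3}, trained with a masked
   reconstruction loss `(1/N) Σ_n (X_n − Recon_n)²`. The encoding `F` is a
   constant extra input to the client's classifier.

2. **Structure-sensitive spectral features.** Per graph, the unnormalized
   Laplacian `L = D − A` is truncated to its top-M eigenpairs and the
   eigenvector block is flattened into a fixed-length feature `g` (sorted,
   sign-canonicalized value profiles on a fixed node budget). The classifier
   head sees `concat(x_pool, flatten(F), g)` with a sigmoid output per label,
   trained with per-label binary cross-entropy plus the autoencoder loss.

3. **Clustered, privacy-aware aggregation.** Each client transmits its
   weights together with the mean spectral feature of its graphs, privatized
   by the Gaussian mechanism `g̃ = ḡ + N(0, σ²I)`, `σ = Δf/ε` (default
   ε = 10). The server builds the cosine similarity matrix
   `S_ij = g̃_i·g̃_j / (‖g̃_i‖‖g̃_j‖)`, spectral-clusters clients into groups,
   FedAvg-averages within each group (`W_Gp = (1/|G_p|) Σ_{k∈G_p} W_k`), and
   fuses group models with trace-gated coefficients
   `β_p = trace(S_Gp) / Σ_q trace(S_Gq)`. A simulated-clock asynchronous
   mode aggregates each group as its last member arrives and re-fuses after
   every group update.

The neural pieces run on a small reverse-mode autodiff engine over numpy
(`fedgat.autodiff`), verified by finite-difference gradient checks.

## Worked example

`examples/04_federated_training.py` runs five federated rounds on the
default synthetic conditions (8 clients, Erdős–Rényi vs Barabási–Albert
structural families, Dirichlet-skewed labels, C=6) with a reduced model:

```
round  AUC    O-F1   C-F1   groups  beta
    0  0.576  0.646  0.437  [8]  [1.0]
    1  0.614  0.665  0.471  [8]  [1.0]
    2  0.680  0.679  0.497  [8]  [1.0]
    3  0.727  0.674  0.488  [8]  [1.0]
    4  0.767  0.691  0.519  [8]  [1.0]
```

Macro ROC-AUC on pooled held-out test graphs climbs from near chance to
0.77 in five rounds (the full default configuration reaches ≈0.96 by round
ten); `groups`/`beta` show the server's client partition and the gated
fusion weights (here the automatic eigengap rule kept one group; example
03 shows the two planted families being recovered exactly when the group
count is given). The other examples each demonstrate one capability:
dataset generation (01), label semantics + autoencoder (02), spectral
features + differential privacy + client clustering (03), and the metric
suite (05).

A thin CLI wraps the same library:

```bash
fedgat gen-data --out data.jsonl --seed 0
fedgat run --data data.jsonl --out runs/demo --rounds 10
fedgat evaluate --run runs/demo
fedgat ablate --which asyagg --data data.jsonl --out runs/abl --rounds 10
```

## Repository layout

```
src/fedgat/        graph_data, label_semantics, label_autoencoder, spectral,
                   backbone, federation, synthetic_data, evaluation,
                   autodiff, config, cli
examples/          one short narrative script per capability
tests/             unit + property tests, tests/test_acceptance.py
docs/methods.md    model, assumptions, parameter choices, limitations
```
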