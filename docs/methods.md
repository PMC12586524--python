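# Methods

This note documents the models, the numerical choices and the synthetic
study conditions implemented in `fedgat`, and what the tests do and do not
establish.

## Problem setting

K clients each hold a private collection of attributed, undirected graphs;
every graph carries a binary label vector over a shared, ordered label space
of C classes. The global objective is the sample-weighted federated risk
`Σ_i (Mⁱ/|M|) L_i(W)` over the shared classifier weights W. Two
heterogeneities are modeled explicitly: clients draw graphs from different
structural distributions, and clients' label prevalences differ.

## Client pipeline

### Label weighting and the label semantic graph

Label frequencies are counted per client (`f_k` = number of graphs carrying
label k) and normalized by the smoothed ratio `w_k = (f_k + ε)/Σ_j (f_j + ε)`
with ε = 1 (Laplace smoothing; configurable). An exponential-softmax variant
exists behind `labels.weight_mode = "softmax"` but is off by default: the
ratio form is monotone, scale-free in N, and does not saturate for frequent
labels. Label embeddings default to deterministic pseudo-random unit vectors
(d = 64) seeded by a stable hash of the label string; any callable
name → vector (e.g. a pretrained text encoder) can be injected, and a failing
provider raises rather than silently falling back. Weighted embeddings
`l̃_k = w_k l_k` form the nodes of the label semantic graph; edges are cosine
similarities, with cosine against a zero vector defined as 0 to avoid 0/0.

The binary adjacency at scale 1 keeps edges with similarity at or above a
threshold (default: the mean off-diagonal similarity of that client's
matrix, so the graph is never empty or complete by construction); scale s is
s-hop reachability of scale 1 (support of `(adj₁ + I)^s` minus the
diagonal), which makes the scale family nested — a property the tests
assert.

### Multi-scale label autoencoder

The encoder propagates the projected embeddings one step over the
row-normalized (self-loop-augmented) scale-1 adjacency, scores ordered label
pairs with a one-hidden-layer MLP on the concatenated propagated
projections, softmax-normalizes scores over each node's neighborhood at each
scale, and averages per-head attention features before a ReLU (averaged
multi-head attention). Per-scale features are **concatenated** (not summed),
so F has a well-defined flat dimension `C · n_scales · d_h` and scale
information stays separable. Defaults: 4 heads, hidden width d_h = 32.

Training masks the label graph each epoch — every undirected scale-1 edge is
dropped independently with probability 0.15 and the scale family is rebuilt
from the masked graph — and reconstructs the *unmasked* weighted embeddings
through a single-scale attention decoder followed by a linear map. The loss
is the mean over label nodes of the squared error summed over dimensions.
Nodes whose neighborhood becomes empty at any scale receive a self-edge so
the softmax stays defined. The loss is evaluated on the unmasked graph after
every epoch; this evaluation trace is what convergence assertions use, since
the per-epoch training loss is noisy under random masking.

### Backbone classifier and fusion

A three-layer GAT transforms node features (widths 64 → 64 → C; heads
4/4/1, averaged; LeakyReLU slope 0.2 on attention scores; ReLU between
layers, linear final layer). Attention operates on the adjacency support
plus self-loops; isolated nodes keep a self-loop. Graphs are processed as
padded batches with node masks; mean readout over real nodes yields the
graph vector, which is concatenated with the flattened label-context
embedding F (constant per client) and the per-graph spectral feature g and
passed to a one-hidden-layer classifier head with a sigmoid per label.
Training loss is per-label binary cross-entropy (computed from logits via
softplus) plus the autoencoder loss. By default the autoencoder is trained
first and its final loss enters as a constant (`two_stage`); `joint` mode
recomputes it per batch and lets gradients flow into the (client-private)
autoencoder.

All neural components run on a small reverse-mode autodiff engine over
float64 numpy arrays; an acceptance test checks the full fused-loss gradient
against central finite differences (≤ 1e-4 relative error).

## Spectral features and privacy

Per graph: unnormalized Laplacian `L = D − A` exactly (not
symmetric-normalized), dense symmetric eigendecomposition, top M = 8
eigenvalues kept. Eigenvectors are sign-canonicalized (largest-magnitude
entry positive; ties to the first such index) and numerically tied
eigenvalues are ordered by lexicographic eigenvector order, so the feature
is deterministic across runs and edge-list orders.

Variable graph size is the main commensurability problem: flattened
eigenvector blocks of different n cannot be compared directly. The pipeline
therefore sorts each eigenvector's entries in descending order and linearly
resamples the value profile onto a fixed node budget N_max = 32,
renormalizing columns to unit norm. Two measured pathologies motivated
this: with raw node order, node-exchangeable graph families (e.g.
Erdős–Rényi) produce client means that decorrelate entirely (cosine ≈ 0);
with zero-padding, the padding block encodes graph size, which leaks label
skew into the structural summaries whenever labels correlate with size. The
sorted-resampled profile is invariant under node relabeling and nearly
size-free. The lower-level `spectral_feature` operation retains the plain
pad/truncate contract for callers that want it.

A client's summary is the arithmetic mean of its training graphs' features,
privatized with the Gaussian mechanism `g̃ = ḡ + N(0, σ²I)`, `σ = Δf/ε`,
ε = 10 by default. The default sensitivity is the replace-one L2 bound for
a mean of n column-unit-norm blocks, `Δf = 2√M / n` (override configurable).
Noise is re-drawn at every transmission.

## Server aggregation

The similarity matrix is plain cosine between privatized summaries (zero
summaries give zero rows). Grouping uses spectral clustering on the
clipped-nonnegative similarities; the group count is a config knob, with an
`"auto"` rule (largest eigengap of the normalized similarity-graph
Laplacian, capped at ⌈K/2⌉). A known limitation: under DP noise the
similarity scale is compressed (within-family ≈ 0.99 vs cross ≈ 0.95 under
the default synthetic conditions), so the eigengap rule tends to return a
single group even when a given group count of 2 recovers the planted
partition exactly; automatic selection of the group count from noisy
summaries is unreliable and the evaluation of group recovery supplies the
planted count, as is standard for ARI protocols.

Within-group aggregation is the unweighted mean of member weights, as the
clustered-FedAvg update is stated; a config flag switches to Mⁱ-weighted
averaging to match the global objective's weighting (the two conventions
are not reconcilable from the method description alone, so both are
exposed). Group models are fused with `β_p = trace(S_Gp)/Σ_q trace(S_Gq)`;
since S has unit diagonal, β_p is proportional to group size — an
`offdiag_mean` gating variant uses the mean off-diagonal similarity
("consistency strength") instead. All-zero gates fall back to uniform with
a logged warning.

The default round loop is synchronous (every client reports every round).
The asynchronous mode draws a per-round arrival time per client, aggregates
a group when its last member arrives, and re-runs the gated fusion after
every group update using the latest model of every group; this is a
simulated-clock model, not real networking. Clients whose local training
produces a non-finite loss are flagged and excluded from that round's
aggregation without reweighting. Ablation switches: `weighted` (skip the
frequency weighting), `graph` (zero the label-context embedding),
`multiscale` (single-scale autoencoder), `asyagg` (plain sample-weighted
FedAvg instead of clustered gated fusion).

Defaults follow the stated training configuration: T = 60 rounds, 10 local
epochs of Adam at learning rate 5e-4, batch size 16. Tests and the
acceptance script run 1–10 rounds, which is where learning is already
clearly above chance on the synthetic conditions.

## Synthetic study conditions

The generator plants: (a) structural client groups — clients assigned
round-robin to graph families, default Erdős–Rényi (p = 0.3) vs
Barabási–Albert (m = 2), 60 graphs/client, 12–24 nodes; (b) label skew —
each client draws a Dirichlet(α = 0.3) tilt and candidate graphs are
rejection-sampled with acceptance `0.02 + 0.98·min(1, (y·t)/max(t))³`, so
prevalences tilt toward each client's favored labels while every label stays
a deterministic function of structure; after 40 attempts a candidate is
accepted unconditionally (counted in the manifest); (c) learnable signal —
label k is a structural predicate (mean degree, density, transitivity,
max-degree fraction, size, degree spread, thresholds near the pooled
two-family medians) XOR Bernoulli(0.1) noise, and node features are a fixed
random linear projection of the final label vector plus unit Gaussian noise.
The cubic, max-normalized acceptance was chosen so a concentrated tilt
produces prevalence gaps > 0.3 between clients while a uniform tilt (the
match saturates at 1) leaves prevalences equal up to sampling noise; both
behaviors are asserted by Monte-Carlo tests.

What the generator does **not** emulate: molecular realism (atom/bond
chemistry), graphs whose labels are not functions of structure, feature
distributions that differ across clients beyond the label signal, and
client dropout. Passing tests therefore show that the pipeline's mechanisms
work as specified under controlled heterogeneity — not that the method
reaches any particular accuracy on real chemical or image-derived
benchmarks.

## Evaluation

Per-label ROC-AUC (midrank tie handling) macro-averaged over labels that
have both positives and negatives (degenerate labels are excluded with a
log message; all-degenerate input is an error). Precision/recall/F1 are
computed from confusion counts at threshold 0.5 (configurable): C-metrics
average per-label values (zero-denominator labels contribute 0, logged);
O-metrics pool counts over all (graph, label) slots, with O-F1 the harmonic
mean of O-P and O-R. C-F1 is the mean of per-label F1 values (not the F1 of
mean P and R). Average precision is the standard non-interpolated form;
mAP averages over labels with at least one positive.

## Known limitations

- Dense eigendecomposition and dense attention limit graphs to a few
  hundred nodes; that covers the molecular and synthetic regimes targeted.
- The autodiff engine is minimal by design (no GPU, no kernel fusion);
  local training cost is what bounds simulator scale.
- The "auto" group count is conservative under DP noise (see above).
- The DP accounting covers only the spectral summaries; model weights are
  transmitted in the clear, as in the method being implemented.
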