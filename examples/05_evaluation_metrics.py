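"""The multi-label metric suite on a hand-checkable example.

Per-label ROC-AUC macro-averaged over non-degenerate labels; per-class
(C-) and overall/pooled (O-) precision, recall, F1 at threshold 0.5; and
non-interpolated average precision (mAP).
"""

import numpy as np

from fedgat import evaluate_scores

# 6 graphs, 3 labels; scores are sigmoid probabilities (deliberately
# imperfect: label 1 has a miss, label 2 a false alarm and a swap)
scores = np.array([
    [0.9, 0.2, 0.6],
    [0.8, 0.7, 0.7],
    [0.7, 0.1, 0.3],
    [0.3, 0.4, 0.3],
    [0.2, 0.8, 0.8],
    [0.1, 0.4, 0.2],
])
truths = np.array([
    [1, 0, 1],
    [1, 1, 0],
    [1, 0, 1],
    [0, 1, 0],
    [0, 1, 1],
    [0, 0, 0],
])

res = evaluate_scores(scores, truths)
print("per-label AUC:", res.auc_per_label.round(3), "-> macro", round(res.auc_macro, 3))
print("per-label AP :", res.ap_per_label.round(3), "-> mAP ", round(res.map, 3))
for k, v in res.as_dict().items():
    print(f"{k:>10}: {v:.3f}" if isinstance(v, float) else f"{k:>10}: {v}")
print("\nC-metrics average per-label scores (every label counts equally); "
      "O-metrics pool all (graph, label) decisions (frequent labels dominate).")
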