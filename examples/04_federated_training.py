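"""A short federated run: local training, clustered aggregation, fusion.

Each round every client trains the shared GAT classifier locally (its own
label-context embedding F and per-graph spectral features are fused into
the classifier head), the server clusters clients by their private
spectral summaries, federated-averages within each group, and fuses the
group models with trace-gated coefficients. Metrics are on pooled
held-out test graphs. Five rounds with a reduced model keep this example
around a minute; see the README for the full default configuration.
"""

from fedgat import ExperimentConfig, SyntheticSpec, generate, run_federation

ds, _ = generate(SyntheticSpec(), seed=0)

cfg = ExperimentConfig()
cfg.federation.local_epochs = 4     # default 10
cfg.backbone.hidden = (32, 32)      # default (64, 64)
cfg.ae.epochs = 50                  # default 100

history = run_federation(ds, cfg, seed=0, rounds=5)

print("round  AUC    O-F1   C-F1   groups  beta")
for rec in history.rounds:
    m = rec["metrics"]
    sizes = [len(g) for g in rec["groups"]]
    beta = [round(b, 2) for b in rec["beta"]]
    print(f"{rec['round']:5d}  {m['AUC']:.3f}  {m['O-F1']:.3f}  {m['C-F1']:.3f}"
          f"  {sizes}  {beta}")

print("\nMacro ROC-AUC rises above the 0.5 chance floor within a few rounds; "
      "beta weights the group models by the trace of their similarity blocks.")
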