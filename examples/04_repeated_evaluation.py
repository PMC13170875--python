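"""The repeated-iteration evaluation protocol with bootstrap CIs.

Re-partitions the training pool 9:1 five times, trains the model each time,
evaluates on the fixed prospective set, and prints per-label means with 95%
percentile-bootstrap confidence intervals over the iterations. (The full
protocol uses 100 iterations; five keeps this example quick.)
"""

from crisisdetect import (
    CohortConfig,
    EmbeddingConfig,
    ModelConfig,
    generate_synthetic_cohort,
    run_repeated_iterations,
)

cohort = generate_synthetic_cohort(
    CohortConfig(n_high_risk=150, n_control=150, seed=0),
    EmbeddingConfig(text_dim=64, audio_dim=32, text_snr=6.0, audio_snr=0.1, seed=1),
)
report, per_iteration = run_repeated_iterations(
    cohort,
    ModelConfig(input_dim=64, encoder_hidden=32, latent_dim=16, seed=0),
    mode="text_only",
    n_iter=5,
    seed=0,
)
f1 = report.table[report.table.metric == "f1"]
for row in f1.itertuples():
    print(f"{row.label:18s} F1 {row.mean:.3f} [{row.ci_low:.3f}, {row.ci_high:.3f}]")
# The interval width reflects variability across random train/validation
# re-partitions, not across prospective calls: that is the protocol's notion
# of model stability.
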