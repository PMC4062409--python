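"""Benchmark gene-selection strategies across an effect-size grid.

Runs the SIMU1-style design (n = 10 per group, unbalanced 60/40 structure)
at three effect sizes for several normalization strategies, with the pooled
t-test and Bonferroni adjustment, and prints mean true/false positives over
replicates. Normalization helps at small effects (variance reduction) but
inflates false positives at large effects (induced bias) — the central
bias-variance trade-off.
"""

from normbench import Strategy, run_grid

strategies = [
    Strategy("none", "t", "bonf"),
    Strategy("global", "t", "bonf"),
    Strategy("quantile", "t", "bonf"),
    Strategy("delta", "t", "bonf"),
]

df = run_grid(
    "SIMU1", "unbalanced", tuning_grid=[0.6, 1.0, 1.8],
    strategies=strategies, reps=10, seed=1,
)
cols = ["tuning", "normalization", "mean_tp", "sd_tp", "mean_fp", "sd_fp"]
print(df[cols].round(2).to_string(index=False))
print("\nmean_tp is out of 100 true DEGs, mean_fp out of 900 null genes.")
print("Note the false-positive growth of global/quantile at effect 1.8 while")
print("delta's false positives stay flat across the grid.")
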