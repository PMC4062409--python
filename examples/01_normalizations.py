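"""Apply each matrix-level normalization to simulated correlated data.

Builds one draw from the random-effect model (a strong shared per-array
effect gives intergene correlation ~0.9), applies each normalization, and
prints the average within-group per-gene variance. Global normalization
removes the shared effect almost completely; quantile normalization also
shrinks it but less so on purely additive noise; rank maps values to [0, 1]
so its variance lives on a different scale.
"""

import numpy as np

from normbench import (
    NORMALIZERS,
    RandomEffectConfig,
    predict_var_global,
    simulate_random_effect,
)

cfg = RandomEffectConfig(
    G=1000, n=10, n_up=60, n_down=40, mu_up=1.8, mu_down=-1.8,
    sigma2=0.1286, rho=0.894,
)
REPS = 10  # the realized shared-effect variance is chi^2 with few df, so average


def within_group_variance(mat):
    return np.mean([mat.group_values(k).var(axis=1, ddof=1).mean() for k in "AB"])


matrices = [simulate_random_effect(cfg.replace(seed=s))[0] for s in range(1, REPS + 1)]
print(f"simulated {REPS} x ({cfg.G} genes x {2 * cfg.n} arrays), "
      f"sigma2={cfg.sigma2}, rho={cfg.rho}")
print(f"{'method':<10} {'within-group variance':>22}")
for name, fn in NORMALIZERS.items():
    v = np.mean([within_group_variance(fn(m)) for m in matrices])
    print(f"{name:<10} {v:>22.5f}")

pred = predict_var_global(cfg.sigma2, cfg.rho, cfg.G)
print(f"\nclosed-form prediction for global: sigma2*(1-rho)*(1-1/G) = {pred:.5f}")
print("The shared array effect accounts for ~90% of each gene's variance;")
print("column centering removes it, which is the power gain normalization buys.")
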