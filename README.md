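# normbench

Bias-variance benchmarking of post-summarization normalization procedures
for two-group gene differential expression studies.

## The problem

In microarray (and more generally log-scale expression) studies, arrays carry
a strong shared technical component: a per-array effect that shifts every gene
on that array together and induces intergene correlations near 0.9.
Normalization procedures remove this component, shrinking per-gene noise
variance and boosting testing power — but every such procedure also perturbs
the expected group differences, introducing a *bias* that can surface as false
positives when effect sizes or sample sizes are large. `normbench` implements
both sides of this trade-off as a reusable, tested pipeline for statisticians
and computational biologists who want to choose (or study) a gene-selection
strategy quantitatively.

## The model

Observed log2 expression of gene *g* on array *j* of phenotype group
*k* ∈ {A, B} is modelled as

    X_gjk = μ_gk + b_jk + e_gjk,

with a per-array effect b_jk ~ N(0, ρσ²) shared by all genes, independent
gene noise e_gjk ~ N(0, (1−ρ)σ²), and mean structure μ_gB = 0,
μ_gA ∈ {μ₊, 0, μ₋} for up-regulated (Γ₊), null (Γ₀) and down-regulated (Γ₋)
genes. Every distinct gene pair has correlation ρ and every gene variance σ².
The central bias constant is

    δ̄ = γ₊μ₊ + γ₋μ₋,

the mean DEG contribution to an array average (γ± are the DEG fractions).
Global normalization (column-mean subtraction) shifts every expected group
difference by −δ̄ and reduces within-group variance from σ² to
σ²(1−ρ)(1−1/G); quantile normalization roughly halves effect sizes and biases
null genes by −δ̄/2; the Δ-sequence cancels the array effect by differencing
variance-matched gene pairs; SVA removes estimated latent array-level factors
inside a per-gene regression.

## What is implemented

- **Normalizations**: none, global, rank (fractional ranks), quantile,
  Δ-sequence (with pair-breaking via two offset pairings), SVA
  (residual-SVD surrogate variables + nested-model F-test).
- **Tests**: pooled two-sample t, empirical-Bayes moderated t (verified
  against R/limma to machine precision), Wilcoxon rank-sum (exact and
  approximate), N-statistic permutation test with Euclidean kernel.
- **Multiple testing**: Bonferroni and Benjamini-Hochberg, strict rejection
  at adjusted p < α.
- **Theory**: exact global-bias predictor, closed-form post-global variance,
  approximate quantile-bias predictor, Monte-Carlo predictors for the rest.
- **Simulators**: the equicorrelated random-effect model with presets SIMU1-3
  (effect-size sweep at n = 10; sample-size sweeps at effects 1.0 and 1.8);
  a resampling simulator that permutes a seed matrix into null pseudo-groups
  and spikes in recorded effects; and a synthetic seed-matrix generator with
  non-additive per-array scale distortion.
- **Evaluation**: strategy runner (normalization × test × MTP), TP/FP grids
  with replicate means/SDs, ROC threshold sweeps.

## Worked example

```python
import numpy as np
from normbench import RandomEffectConfig, simulate_random_effect, \
    normalize_global, predict_var_global

cfg = RandomEffectConfig(G=1000, n=10, n_up=60, n_down=40,
                         mu_up=1.8, mu_down=-1.8,
                         sigma2=0.1286, rho=0.894, seed=1)
m, truth = simulate_random_effect(cfg)
g = normalize_global(m)
post = np.mean([g.group_values(k).var(axis=1, ddof=1).mean() for k in "AB"])
print(round(post, 5), round(predict_var_global(0.1286, 0.894, 1000), 5))
```

prints

```
0.01354 0.01362
```

— the within-group per-gene variance after global normalization on one
simulated dataset, next to the closed-form prediction σ²(1−ρ)(1−1/G): column
centering strips the shared array effect, leaving essentially only the
idiosyncratic noise (a ~9.5× variance reduction here). The scripts in
`examples/` walk through each capability the same way: normalization variance
reduction, the four tests with both MTPs, bias predictors vs Monte Carlo,
benchmark grids, and ROC curves, each printing the numbers it computes and a
line on how to read them.

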