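"""Per-gene two-sample tests: pooled t, moderated t, Wilcoxon, and the N-test.

All four tests compare group A against group B gene by gene and return
two-sided p-values. They are shift-invariant: adding a constant to every
value changes no p-value, which is why the simulators may set the reference
group's mean expression to zero without loss of generality.

The pooled-variance t is used rather than Welch's because the random-effect
model underlying the benchmark has a common within-group variance for the
two phenotypes; this also matches the theoretical bias/variance predictors.
"""

from __future__ import annotations

import logging
from typing import Callable, Dict

import numpy as np
from scipy import special, stats

from .core_data import ExpressionMatrix, TestResult

__all__ = ["t_test", "moderated_t", "wilcoxon", "n_statistic", "n_test", "TESTS"]

logger = logging.getLogger(__name__)


def _group_split(m: ExpressionMatrix):
    a = m.group_values("A")
    b = m.group_values("B")
    return a, b


def _pooled_t(a: np.ndarray, b: np.ndarray):
    """Pooled two-sample t statistics, per row; returns (t, s2_pooled, df)."""
    na, nb = a.shape[1], b.shape[1]
    df = na + nb - 2
    s2 = ((na - 1) * a.var(axis=1, ddof=1) + (nb - 1) * b.var(axis=1, ddof=1)) / df
    diff = a.mean(axis=1) - b.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / np.sqrt(s2 * (1.0 / na + 1.0 / nb))
    return t, s2, df, diff


def t_test(m: ExpressionMatrix) -> TestResult:
    """Classical pooled-variance two-sample t-test, two-sided.

    Degenerate genes with zero pooled variance get p = 1 when the group
    means agree and p = 0 otherwise (logged).
    """
    a, b = _group_split(m)
    t, s2, df, diff = _pooled_t(a, b)
    p = 2.0 * stats.t.sf(np.abs(t), df)
    degenerate = s2 <= 0
    if degenerate.any():
        logger.warning(
            "%d gene(s) with zero pooled variance; applying degenerate-input rule",
            int(degenerate.sum()),
        )
        p = np.where(degenerate, np.where(diff == 0, 1.0, 0.0), p)
        signed_inf = np.where(diff > 0, np.inf, -np.inf)
        t = np.where(degenerate, np.where(diff == 0, 0.0, signed_inf), t)
    return TestResult(m.gene_ids, t, p)


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x = x + dif
        if -dif / x < 1e-8:
            break
    return float(x)


def fit_variance_prior(s2: np.ndarray, df: float):
    """Moment-match an inverse-chi-square prior to observed gene variances.

    Under the hierarchical model s_g² | σ_g² ~ σ_g²·χ²_d/d with
    1/σ_g² ~ χ²_{d0}/(d0·s0²), the log sample variances satisfy
    E[log s²] = log s0² + ψ(d/2) − log(d/2) + ψ(d0/2) − log(d0/2) and
    Var[log s²] = ψ'(d/2) + ψ'(d0/2). Matching the empirical mean and
    variance of log s_g² across genes yields the prior df d0 and prior
    value s0². When the empirical spread is no larger than expected from
    sampling alone, d0 = inf and every gene shares s0².

    Returns ``(d0, s02)``; ``d0`` may be ``np.inf``.
    """
    s2 = np.asarray(s2, dtype=float)
    if len(s2) < 2:
        raise ValueError("need at least 2 genes to estimate the variance prior")
    if (s2 <= 0).any():
        raise ValueError("zero sample variances: cannot fit a log-variance prior")
    z = np.log(s2)
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = e.mean()
    evar = e.var(ddof=1) - special.polygamma(1, df / 2.0)
    if evar > 0:
        d0 = 2.0 * _trigamma_inverse(evar)
        s02 = float(np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    else:
        d0 = np.inf
        s02 = float(s2.mean())
    return d0, s02


def moderated_t(m: ExpressionMatrix, prior_df: float | None = None) -> TestResult:
    """Empirical-Bayes moderated t-test.

    Per-gene pooled variances are shrunk toward a prior value s0² with prior
    degrees of freedom d0, both estimated by moment-matching the log sample
    variances across genes (:func:`fit_variance_prior`). The statistic
    divides the group mean difference by the shrunken standard error and is
    referred to a t distribution with d + d0 degrees of freedom (normal when
    d0 is infinite).

    ``prior_df`` overrides the estimated d0; ``prior_df=0`` disables
    shrinkage and recovers the ordinary pooled t.
    """
    a, b = _group_split(m)
    na, nb = a.shape[1], b.shape[1]
    df = na + nb - 2
    _, s2, _, diff = _pooled_t(a, b)
    if prior_df is None:
        d0, s02 = fit_variance_prior(s2, df)
    elif prior_df == 0:
        d0, s02 = 0.0, 0.0
    else:
        d0 = float(prior_df)
        _, s02 = fit_variance_prior(s2, df)
    if np.isinf(d0):
        s2_post = np.full_like(s2, s02)
        total_df = np.inf
    else:
        s2_post = (d0 * s02 + df * s2) / (d0 + df)
        total_df = df + d0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / np.sqrt(s2_post * (1.0 / na + 1.0 / nb))
    if np.isinf(total_df):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), total_df)
    return TestResult(m.gene_ids, t, p)


def wilcoxon(m: ExpressionMatrix, exact: bool | None = None) -> TestResult:
    """Wilcoxon rank-sum test per gene, two-sided.

    P-values are exact (by enumeration of allocations) when the combined
    sample size is at most 12 and the gene has no ties; otherwise the normal
    approximation with tie and continuity corrections is used. ``exact``
    forces one or the other. The reported statistic is the rank sum of
    group A.
    """
    a, b = _group_split(m)
    na, nb = a.shape[1], b.shape[1]
    stat = np.empty(m.n_genes)
    p = np.empty(m.n_genes)
    for i in range(m.n_genes):
        x, y = a[i], b[i]
        has_ties = len(np.unique(np.concatenate([x, y]))) < na + nb
        if exact is None:
            method = "exact" if (na + nb <= 12 and not has_ties) else "asymptotic"
        else:
            method = "exact" if exact else "asymptotic"
        res = stats.mannwhitneyu(
            x, y, alternative="two-sided", method=method, use_continuity=True
        )
        stat[i] = res.statistic + na * (na + 1) / 2.0  # U -> rank sum of group A
        p[i] = res.pvalue
    return TestResult(m.gene_ids, stat, np.minimum(p, 1.0))


def n_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """N-statistic with Euclidean kernel between two samples.

    N = (2/nm)·ΣΣ|x_i−y_j| − (1/n²)·ΣΣ|x_i−x_i'| − (1/m²)·ΣΣ|y_j−y_j'|,
    with the double sums running over all index pairs (diagonals included).
    For the Euclidean (negative-definite) kernel N ≥ 0, with equality when
    the two samples coincide as multisets; N is invariant under a common
    shift of both samples.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("samples must be non-empty")
    n, mm = len(x), len(y)
    cross = np.abs(x[:, None] - y[None, :]).sum()
    within_x = np.abs(x[:, None] - x[None, :]).sum()
    within_y = np.abs(y[:, None] - y[None, :]).sum()
    return float(2.0 * cross / (n * mm) - within_x / n**2 - within_y / mm**2)


def n_test(
    m: ExpressionMatrix, n_perm: int = 10000, seed: int = 0
) -> TestResult:
    """Permutation test of the per-gene N-statistic with Euclidean kernel.

    Group labels are permuted uniformly at random ``n_perm`` times (the same
    permutations are applied to every gene); the p-value uses the add-one
    convention p = (1 + #{N_perm ≥ N_obs}) / (1 + n_perm), so the smallest
    attainable p is 1/(n_perm+1). Identical seeds give identical p-values.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be at least 1")
    rng = np.random.default_rng(seed)
    cols_a = m.group_columns("A")
    n_arr = m.n_arrays
    na = len(cols_a)
    perms = np.array([rng.permutation(n_arr)[:na] for _ in range(n_perm)])

    stat = np.empty(m.n_genes)
    p = np.empty(m.n_genes)
    obs_a = cols_a
    for i in range(m.n_genes):
        v = m.values[i]
        d = np.abs(v[:, None] - v[None, :])
        total = d.sum()
        n_obs = _n_from_subset(d, obs_a, total, n_arr)
        # gather the within-A block for every permutation at once
        block = d[perms[:, :, None], perms[:, None, :]].sum(axis=(1, 2))
        n_perm_vals = _n_from_blocks(d, perms, block, total, n_arr)
        stat[i] = n_obs
        p[i] = (1.0 + np.count_nonzero(n_perm_vals >= n_obs - 1e-12)) / (1.0 + n_perm)
    return TestResult(m.gene_ids, stat, p)


def _n_from_subset(d: np.ndarray, idx_a: np.ndarray, total: float, n_arr: int) -> float:
    na = len(idx_a)
    nb = n_arr - na
    within_a = d[np.ix_(idx_a, idx_a)].sum()
    mask = np.ones(n_arr, dtype=bool)
    mask[idx_a] = False
    idx_b = np.nonzero(mask)[0]
    within_b = d[np.ix_(idx_b, idx_b)].sum()
    cross = (total - within_a - within_b) / 2.0
    return float(2.0 * cross / (na * nb) - within_a / na**2 - within_b / nb**2)


def _n_from_blocks(
    d: np.ndarray, perms: np.ndarray, within_a: np.ndarray, total: float, n_arr: int
) -> np.ndarray:
    """Vectorized N over permutations given each permutation's within-A sum."""
    na = perms.shape[1]
    nb = n_arr - na
    # Each permutation's A-vs-B mass by inclusion-exclusion: summing the full
    # row masses of the A rows counts within-A once and A-vs-B once.
    row_mass = d.sum(axis=1)
    a_rows = row_mass[perms].sum(axis=1)
    cross = a_rows - within_a
    within_b = total - within_a - 2.0 * cross
    return 2.0 * cross / (na * nb) - within_a / na**2 - within_b / nb**2


TESTS: Dict[str, Callable[..., TestResult]] = {
    "t": t_test,
    "modt": moderated_t,
    "wilcox": wilcoxon,
    "nstat": n_test,
}
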