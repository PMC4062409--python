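"""Post-summarization normalization procedures.

Five procedures plus the identity are provided, all operating on log2-scale
:class:`~normbench.core_data.ExpressionMatrix` objects:

``none``
    no transformation (the comparison baseline).
``global``
    subtract each array's mean over all genes (column centering). Removes an
    additive per-array effect exactly, at the cost of a bias −δ̄ = −(γ+μ+ + γ−μ−)
    in every gene's expected group difference.
``rank``
    replace each value by its fractional rank R/G within the array (midranks
    for ties). Invariant under any strictly increasing per-array distortion.
``quantile``
    map every array onto a common reference of averaged order statistics, so
    all arrays share one empirical distribution.
``delta``
    the Δ-sequence: sort genes by sample variance, difference consecutive
    pairs so that the shared array effect cancels, test the pair differences,
    and break pairs by intersecting two offset pairings.
``sva``
    surrogate variable analysis: estimate latent array-level factors from the
    residuals of the group-mean model and include them as covariates in a
    per-gene regression F-test.

The matrix→matrix maps are also reachable through :data:`NORMALIZERS` by name.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Tuple

import numpy as np
from scipy import stats

from .core_data import (
    AdjustedResult,
    ExpressionMatrix,
    QuantileReference,
    TestResult,
)

__all__ = [
    "PairedDifferences",
    "SurrogateVariables",
    "normalize_none",
    "normalize_global",
    "normalize_rank",
    "quantile_reference",
    "normalize_quantile",
    "delta_pair",
    "delta_select",
    "estimate_surrogates",
    "sva_test",
    "NORMALIZERS",
]


def normalize_none(m: ExpressionMatrix) -> ExpressionMatrix:
    """Identity: return a copy with unchanged values."""
    return m.with_values(m.values.copy())


def normalize_global(m: ExpressionMatrix) -> ExpressionMatrix:
    """Subtract each array's mean expression from every value on that array.

    After the transform every column has mean zero, so a purely additive
    per-array effect is removed exactly.
    """
    return m.with_values(m.values - m.values.mean(axis=0, keepdims=True))


def normalize_rank(m: ExpressionMatrix) -> ExpressionMatrix:
    """Replace each value by its fractional rank R/G within its array.

    Ties receive the average (mid-) fractional rank, which keeps a downstream
    Wilcoxon test consistent with the usual midrank convention.
    """
    g = m.n_genes
    ranks = np.empty_like(m.values)
    for j in range(m.n_arrays):
        ranks[:, j] = stats.rankdata(m.values[:, j], method="average") / g
    return m.with_values(ranks)


def quantile_reference(m: ExpressionMatrix) -> QuantileReference:
    """Reference array of empirical quantiles, averaged over all arrays.

    The k-th entry is the mean over all arrays (both groups pooled) of each
    array's k-th order statistic.
    """
    return QuantileReference(np.sort(m.values, axis=0).mean(axis=1))


def normalize_quantile(
    m: ExpressionMatrix, reference: QuantileReference | None = None
) -> ExpressionMatrix:
    """Replace each array's values by the reference entries with the same rank.

    Every column of the output has exactly the reference as its sorted values
    while preserving the within-column rank order. Ties are resolved by a
    stable sort on the original gene index, so the map is deterministic.
    """
    if reference is None:
        reference = quantile_reference(m)
    q = reference.q
    if len(q) != m.n_genes:
        raise ValueError("reference length does not match gene count")
    out = np.empty_like(m.values)
    for j in range(m.n_arrays):
        order = np.argsort(m.values[:, j], kind="stable")
        out[order, j] = q
    return m.with_values(out)


@dataclass
class PairedDifferences:
    """Δ-sequence pairings and their per-array differences.

    Genes are sorted ascending by sample variance (computed across all
    arrays, groups pooled; ties broken by original index). Offset-0 pairs
    are (1,2), (3,4), …; offset-1 pairs are (2,3), (4,5), …, (G,1) — the
    last gene wraps around to the first. Differences are later-minus-earlier
    in the sorted order (for the wrap-around pair, first-minus-last).
    """

    order: np.ndarray
    diffs0: np.ndarray
    diffs1: np.ndarray
    pair_members0: List[Tuple[str, str]]
    pair_members1: List[Tuple[str, str]]
    template: ExpressionMatrix

    def to_matrix(self, offset: int) -> ExpressionMatrix:
        """The pair differences of one offset as an ExpressionMatrix.

        Pair ids are ``d{offset}_{k:05d}``; array ids and group labels are
        inherited from the source matrix.
        """
        diffs = {0: self.diffs0, 1: self.diffs1}[offset]
        ids = [f"d{offset}_{k:05d}" for k in range(diffs.shape[0])]
        return ExpressionMatrix(
            diffs, ids, self.template.array_ids, self.template.group_of
        )


def delta_pair(m: ExpressionMatrix) -> PairedDifferences:
    """Sort genes by sample variance and difference consecutive pairs.

    The procedure assumes an even gene count; with odd G the lowest-variance
    gene is dropped with a warning. Because the shared array effect is common
    to both members of a pair, it cancels exactly in the differences.
    """
    variances = m.values.var(axis=1, ddof=1)
    order = np.argsort(variances, kind="stable")
    values = m.values
    if len(order) % 2 == 1:
        warnings.warn(
            "odd gene count: dropping lowest-variance gene "
            f"{m.gene_ids[order[0]]} to form pairs",
            stacklevel=2,
        )
        order = order[1:]
    sorted_vals = values[order]
    ids = [m.gene_ids[i] for i in order]
    diffs0 = sorted_vals[1::2] - sorted_vals[0::2]
    # offset-1 pairing starts at the second gene and wraps the last to the first
    rolled = np.roll(sorted_vals, -1, axis=0)
    diffs1 = (rolled[1::2] - sorted_vals[1::2])
    members0 = [(ids[2 * k], ids[2 * k + 1]) for k in range(len(ids) // 2)]
    members1 = [
        (ids[(2 * k + 1)], ids[(2 * k + 2) % len(ids)]) for k in range(len(ids) // 2)
    ]
    return PairedDifferences(order, diffs0, diffs1, members0, members1, m)


def delta_select(
    res0: AdjustedResult, res1: AdjustedResult, pd_: PairedDifferences
) -> set:
    """Break pairs: report genes whose pairs are rejected under BOTH offsets.

    ``res0``/``res1`` must be the adjusted results of the same test and MTP
    applied to the offset-0 and offset-1 pair differences respectively.
    """
    if len(res0.p_adj) != len(pd_.pair_members0) or len(res1.p_adj) != len(
        pd_.pair_members1
    ):
        raise ValueError("adjusted results do not match the pairings")
    hit0: set = set()
    for rej, (a, b) in zip(res0.rejected, pd_.pair_members0):
        if rej:
            hit0.update((a, b))
    hit1: set = set()
    for rej, (a, b) in zip(res1.rejected, pd_.pair_members1):
        if rej:
            hit1.update((a, b))
    return hit0 & hit1


@dataclass
class SurrogateVariables:
    """Orthonormal array-level surrogate variables (arrays × K)."""

    H: np.ndarray

    def __post_init__(self) -> None:
        self.H = np.asarray(self.H, dtype=float)
        if self.H.ndim != 2:
            raise ValueError("H must be 2-D (arrays x K)")
        k = self.H.shape[1]
        if k and not np.allclose(self.H.T @ self.H, np.eye(k), atol=1e-8):
            raise ValueError("surrogate variable columns must be orthonormal")


def estimate_surrogates(m: ExpressionMatrix, K: int = 2) -> SurrogateVariables:
    """Top-K right singular vectors of the group-mean-model residuals.

    Each gene is residualized on its two group means; the right singular
    vectors of the residual matrix estimate latent array-level factors not
    explained by the phenotype. ``K`` must leave at least two residual
    degrees of freedom for the downstream F-test.
    """
    if K < 0:
        raise ValueError("K must be nonnegative")
    if K >= m.n_arrays - 2:
        raise ValueError(f"K={K} too large for {m.n_arrays} arrays")
    if K == 0:
        return SurrogateVariables(np.empty((m.n_arrays, 0)))
    resid = m.values.copy()
    for grp in ("A", "B"):
        cols = m.group_columns(grp)
        resid[:, cols] -= resid[:, cols].mean(axis=1, keepdims=True)
    _, _, vt = np.linalg.svd(resid, full_matrices=False)
    return SurrogateVariables(vt[:K].T)


def sva_test(m: ExpressionMatrix, sv: SurrogateVariables) -> TestResult:
    """Per-gene nested-model F-test for the group label given the surrogates.

    The null model regresses each gene on an intercept plus the surrogate
    variables; the full model adds the group indicator. The statistic is the
    ordinary least-squares F for the one added regressor; with K=0 it reduces
    to the square of the pooled two-sample t.
    """
    n = m.n_arrays
    group = np.zeros(n)
    group[m.group_columns("A")] = 1.0
    x0 = np.column_stack([np.ones(n), sv.H])
    x1 = np.column_stack([x0, group])
    if np.linalg.matrix_rank(x1) < x1.shape[1]:
        raise ValueError("design matrix (intercept + surrogates + group) is rank-deficient")
    df_resid = n - x1.shape[1]
    if df_resid < 1:
        raise ValueError("no residual degrees of freedom for the F-test")
    q0, _ = np.linalg.qr(x0)
    q1, _ = np.linalg.qr(x1)
    y = m.values
    total = (y * y).sum(axis=1)
    rss0 = total - ((y @ q0) ** 2).sum(axis=1)
    rss1 = total - ((y @ q1) ** 2).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (rss0 - rss1) / (rss1 / df_resid)
    f = np.where(rss1 <= 0, np.inf, np.maximum(f, 0.0))
    p = stats.f.sf(f, 1, df_resid)
    p = np.where(np.isinf(f), 0.0, p)
    return TestResult(m.gene_ids, f, p)


NORMALIZERS: Dict[str, object] = {
    "none": normalize_none,
    "global": normalize_global,
    "rank": normalize_rank,
    "quantile": normalize_quantile,
}
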