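"""Gene-selection strategy runner, TP/FP accounting, grids and ROC curves.

A :class:`Strategy` is one cell of the benchmark design: a normalization
(none / global / rank / quantile / delta / sva) combined with a test
(t / modt / wilcox / nstat) and a multiple-testing procedure (bonf / bh) at
a significance level. Delta wraps the chosen test and MTP around the paired
differences of the Δ-sequence (selecting genes whose pairs are significant
under both offset pairings); SVA is tied to the regression F-test, so it
only combines with ``test="t"``.

:func:`run_grid` evaluates strategies across a tuning grid of a simulation
preset, with per-replicate seeds derived deterministically from a master
seed through :class:`numpy.random.SeedSequence`, and reports the mean and
standard deviation of true and false positive counts across replicates —
the layout of the benchmark's summary tables.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, List, Sequence, Tuple

import numpy as np
import pandas as pd

from .core_data import AdjustedResult, ExpressionMatrix, TruthSet
from .detests import TESTS, moderated_t, n_test, t_test, wilcoxon
from .mtp import MTPS
from .normalization import (
    NORMALIZERS,
    delta_pair,
    delta_select,
    estimate_surrogates,
    sva_test,
)
from .synthetic_data import simu_preset, simulate_random_effect

__all__ = ["Strategy", "ROCCurve", "run_strategy", "run_grid", "roc_curve"]

_NORMS = set(NORMALIZERS) | {"delta", "sva"}


@dataclass(frozen=True)
class Strategy:
    """One gene-selection strategy: normalization × test × MTP at level alpha."""

    normalization: str = "none"
    test: str = "t"
    mtp: str = "bonf"
    alpha: float = 0.05
    n_perm: int = 10000
    n_sv: int = 2

    def __post_init__(self) -> None:
        if self.normalization not in _NORMS:
            raise ValueError(f"unknown normalization {self.normalization!r}")
        if self.test not in TESTS:
            raise ValueError(f"unknown test {self.test!r}")
        if self.mtp not in MTPS:
            raise ValueError(f"unknown MTP {self.mtp!r}")
        if self.normalization == "sva" and self.test != "t":
            raise ValueError("sva combines only with the regression F-test (test='t')")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")

    @property
    def label(self) -> str:
        return f"{self.normalization}+{self.test}+{self.mtp}"


def _run_test(m: ExpressionMatrix, s: Strategy, seed: int):
    if s.test == "nstat":
        return n_test(m, n_perm=s.n_perm, seed=seed)
    if s.test == "t":
        return t_test(m)
    if s.test == "modt":
        return moderated_t(m)
    return wilcoxon(m)


def run_strategy(
    m: ExpressionMatrix, t: TruthSet, s: Strategy, seed: int = 0
) -> Tuple[AdjustedResult, int, int]:
    """Apply a strategy to one dataset and count true/false positives.

    Returns the per-gene adjusted result plus tp = rejected true DEGs and
    fp = rejected null genes. For delta, the per-gene adjusted p-value is
    the larger of the gene's two pair-level adjusted p-values, so the strict
    rejection rule reproduces the pair-intersection selection exactly.
    """
    adjust = MTPS[s.mtp]
    if s.normalization == "delta":
        pd_ = delta_pair(m)
        res0 = _run_test(pd_.to_matrix(0), s, seed)
        res1 = _run_test(pd_.to_matrix(1), s, seed)
        adj0 = adjust(res0.p_raw, s.alpha)
        adj1 = adjust(res1.p_raw, s.alpha)
        selected = delta_select(adj0, adj1, pd_)
        # per-gene p: max of the gene's two pair-level adjusted p-values
        p_gene = {}
        for padj, members in (
            (adj0.p_adj, pd_.pair_members0),
            (adj1.p_adj, pd_.pair_members1),
        ):
            for q, (ga, gb) in zip(padj, members):
                for g in (ga, gb):
                    p_gene[g] = max(p_gene.get(g, 0.0), q)
        p_adj = np.array([p_gene.get(g, 1.0) for g in m.gene_ids])
        adj = AdjustedResult(m.gene_ids, p_adj, p_adj < s.alpha, s.alpha)
        assert adj.rejected_ids() == selected
    elif s.normalization == "sva":
        sv = estimate_surrogates(m, s.n_sv)
        res = sva_test(m, sv)
        adj = adjust(res.p_raw, s.alpha, gene_ids=m.gene_ids)
    else:
        normed = NORMALIZERS[s.normalization](m)
        res = _run_test(normed, s, seed)
        adj = adjust(res.p_raw, s.alpha, gene_ids=m.gene_ids)

    rejected = adj.rejected_ids()
    degs = t.deg_ids()
    tp = len(rejected & degs)
    fp = len(rejected - degs)
    return adj, tp, fp


def run_grid(
    preset: str,
    structure: str,
    tuning_grid: Sequence,
    strategies: Iterable[Strategy],
    reps: int = 20,
    seed: int = 1,
) -> pd.DataFrame:
    """Mean/SD of TP and FP per (tuning value, strategy) over replicates.

    Per-replicate seeds are spawned deterministically from the master seed
    with :class:`numpy.random.SeedSequence`, so grid cells are independent
    and the whole table is reproducible bit for bit.
    """
    if reps < 2:
        raise ValueError("need at least 2 replicates for standard deviations")
    strategies = list(strategies)
    rows: List[dict] = []
    for ti, tuning in enumerate(tuning_grid):
        cfg = simu_preset(preset, structure, tuning)
        rep_seeds = [
            int(s.generate_state(1)[0] % (2**31))
            for s in np.random.SeedSequence([seed, ti]).spawn(reps)
        ]
        results = {s.label: {"tp": [], "fp": []} for s in strategies}
        for r in range(reps):
            m, truth = simulate_random_effect(cfg.replace(seed=rep_seeds[r]))
            for s in strategies:
                _, tp, fp = run_strategy(m, truth, s, seed=rep_seeds[r])
                results[s.label]["tp"].append(tp)
                results[s.label]["fp"].append(fp)
        for s in strategies:
            tp = np.array(results[s.label]["tp"], dtype=float)
            fp = np.array(results[s.label]["fp"], dtype=float)
            rows.append(
                {
                    "preset": preset,
                    "structure": structure,
                    "tuning": tuning,
                    "normalization": s.normalization,
                    "test": s.test,
                    "mtp": s.mtp,
                    "mean_tp": tp.mean(),
                    "sd_tp": tp.std(ddof=1),
                    "mean_fp": fp.mean(),
                    "sd_fp": fp.std(ddof=1),
                }
            )
    return pd.DataFrame(rows)


@dataclass
class ROCCurve:
    """True/false positive counts along a p-value threshold sweep.

    Thresholds run from most to least stringent (ascending p cutoffs), so
    both count vectors are nondecreasing. A gene is selected at a threshold
    when its p-value is ≤ the cutoff; tied p-values enter together.
    """

    thresholds: np.ndarray
    tp_counts: np.ndarray
    fp_counts: np.ndarray

    def __post_init__(self) -> None:
        self.thresholds = np.asarray(self.thresholds, dtype=float)
        self.tp_counts = np.asarray(self.tp_counts, dtype=int)
        self.fp_counts = np.asarray(self.fp_counts, dtype=int)
        if (np.diff(self.tp_counts) < 0).any() or (np.diff(self.fp_counts) < 0).any():
            raise ValueError("counts must be nondecreasing along the sweep")


def roc_curve(p: Sequence[float], t: TruthSet, gene_ids: Sequence[str]) -> ROCCurve:
    """Threshold sweep of raw p-values against the truth.

    Raw (unadjusted) p-values are swept because monotone MTPs preserve the
    gene ranking, so the curve is identical either way.
    """
    p = np.asarray(p, dtype=float)
    if not np.isfinite(p).all():
        raise ValueError("p-values must be finite")
    classes = t.classes(gene_ids)
    is_deg = classes != "null"
    thresholds = np.unique(p)
    # counts of p <= threshold among DEGs / null genes, via sorted insertion
    order = np.argsort(p, kind="stable")
    p_sorted = p[order]
    deg_sorted = is_deg[order].astype(int)
    cum_deg = np.cumsum(deg_sorted)
    idx = np.searchsorted(p_sorted, thresholds, side="right")
    tp = cum_deg[idx - 1]
    fp = idx - tp
    return ROCCurve(thresholds, tp, fp)
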