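"""Multiple testing procedures: Bonferroni (FWER) and Benjamini-Hochberg (FDR).

Both return adjusted p-values; rejection uses the strict rule
``p_adj < alpha`` (the distinction from ``<=`` only matters for discrete
permutation p-values). Default significance level: 0.05.
"""

from __future__ import annotations

from typing import Callable, Dict, Sequence

import numpy as np

from .core_data import AdjustedResult

__all__ = ["adjust_bonferroni", "adjust_bh", "MTPS"]


def _prepare(p, gene_ids):
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    if gene_ids is None:
        gene_ids = [f"g{i:05d}" for i in range(len(p))]
    return p, list(gene_ids)


def adjust_bonferroni(
    p: Sequence[float], alpha: float = 0.05, gene_ids: Sequence[str] | None = None
) -> AdjustedResult:
    """Bonferroni adjustment: p_adj = min(1, G·p). Controls the FWER."""
    p, gene_ids = _prepare(p, gene_ids)
    p_adj = np.minimum(1.0, len(p) * p)
    return AdjustedResult(gene_ids, p_adj, p_adj < alpha, alpha)


def adjust_bh(
    p: Sequence[float], alpha: float = 0.05, gene_ids: Sequence[str] | None = None
) -> AdjustedResult:
    """Benjamini-Hochberg step-up adjustment. Controls the FDR.

    With p_(1) ≤ … ≤ p_(G), the adjusted values are
    q_(i) = min_{j ≥ i} ( G·p_(j) / j ), capped at 1, mapped back to the
    original gene order. The rejection set coincides with the classical
    step-up rule (reject the largest k with p_(k) ≤ k·alpha/G) except on the
    measure-zero boundary where the strict-inequality rejection rule bites.
    """
    p, gene_ids = _prepare(p, gene_ids)
    g = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * g / np.arange(1, g + 1)
    q = np.minimum(1.0, np.minimum.accumulate(ranked[::-1])[::-1])
    p_adj = np.empty(g)
    p_adj[order] = q
    return AdjustedResult(gene_ids, p_adj, p_adj < alpha, alpha)


MTPS: Dict[str, Callable[..., AdjustedResult]] = {
    "bonf": adjust_bonferroni,
    "bh": adjust_bh,
}
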