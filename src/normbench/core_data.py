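"""Domain containers and plain-text I/O shared by every stage of the pipeline.

The central object is :class:`ExpressionMatrix`: a genes × arrays matrix of
log2-scale expression values together with a two-level group assignment
(group ``A`` is the phenotype of interest, group ``B`` the reference).
:class:`TruthSet` records, for simulated data, which genes are truly up- or
down-regulated and by how much; the remaining containers carry per-gene test
results through multiple-testing adjustment.

All files are tab-separated text: matrices have a header row of array ids and
a first column of gene ids under the header token ``gene_id``; labels and
truth tables are two/three-column TSV. Values are assumed to be already
log2-transformed; no transform is applied on read.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "TruthSet",
    "TestResult",
    "AdjustedResult",
    "QuantileReference",
    "MatrixParseError",
    "read_matrix",
    "write_matrix",
    "read_truth",
    "write_truth",
]

GROUPS = ("A", "B")
GENE_CLASSES = ("null", "up", "down")


class MatrixParseError(ValueError):
    """Raised when a TSV input violates the matrix/label/truth contracts."""


@dataclass
class ExpressionMatrix:
    """Log2 expression values for ``G`` genes across labelled arrays.

    Parameters
    ----------
    values : ndarray, shape (G, n_arrays)
        Log2-scale expression values; must be finite.
    gene_ids : sequence of str
        Unique gene identifiers, one per row.
    array_ids : sequence of str
        Unique array identifiers, one per column.
    group_of : mapping array_id -> {"A", "B"}
        Group ``A`` is the phenotype of interest; both groups need at least
        two arrays so that within-group variances exist.
    """

    values: np.ndarray
    gene_ids: Sequence[str]
    array_ids: Sequence[str]
    group_of: Mapping[str, str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = list(map(str, self.gene_ids))
        self.array_ids = list(map(str, self.array_ids))
        self.group_of = dict(self.group_of)
        if self.values.ndim != 2:
            raise MatrixParseError("values must be a 2-D genes x arrays matrix")
        g, a = self.values.shape
        if g < 2:
            raise MatrixParseError(f"need at least 2 genes, got {g}")
        if len(self.gene_ids) != g or len(self.array_ids) != a:
            raise MatrixParseError("id lists do not match matrix shape")
        if len(set(self.gene_ids)) != g:
            raise MatrixParseError("gene ids are not unique")
        if len(set(self.array_ids)) != a:
            raise MatrixParseError("array ids are not unique")
        if not np.isfinite(self.values).all():
            bad = np.argwhere(~np.isfinite(self.values))[0]
            raise MatrixParseError(
                f"non-finite value at gene {self.gene_ids[bad[0]]}, "
                f"array {self.array_ids[bad[1]]}"
            )
        for aid in self.array_ids:
            if aid not in self.group_of:
                raise MatrixParseError(f"array {aid!r} missing from group labels")
            if self.group_of[aid] not in GROUPS:
                raise MatrixParseError(
                    f"array {aid!r} has unknown group {self.group_of[aid]!r}"
                )
        for grp in GROUPS:
            if len(self.group_columns(grp)) < 2:
                raise MatrixParseError(f"group {grp} has fewer than 2 arrays")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_arrays(self) -> int:
        return self.values.shape[1]

    def group_columns(self, group: str) -> np.ndarray:
        """Column indices of the arrays belonging to ``group``."""
        return np.array(
            [j for j, aid in enumerate(self.array_ids) if self.group_of[aid] == group],
            dtype=int,
        )

    def group_values(self, group: str) -> np.ndarray:
        """Genes × arrays submatrix for one group."""
        return self.values[:, self.group_columns(group)]

    def with_values(self, values: np.ndarray) -> "ExpressionMatrix":
        """Copy of this matrix with replaced values (ids and labels kept)."""
        return ExpressionMatrix(values, self.gene_ids, self.array_ids, self.group_of)


@dataclass
class TruthSet:
    """Ground-truth gene classes and the common effect sizes.

    ``class_of`` maps every gene id to ``"null"``, ``"up"`` or ``"down"``.
    Up-regulated genes have expected group A−B difference ``mu_up`` (> 0,
    log2 units) and down-regulated genes ``mu_down`` (< 0); null genes have
    no expected difference.
    """

    class_of: Mapping[str, str]
    mu_up: float
    mu_down: float

    def __post_init__(self) -> None:
        self.class_of = dict(self.class_of)
        for gid, cls in self.class_of.items():
            if cls not in GENE_CLASSES:
                raise ValueError(f"gene {gid!r} has unknown class {cls!r}")
        if not self.mu_up > 0:
            raise ValueError("mu_up must be positive (log2 units)")
        if not self.mu_down < 0:
            raise ValueError("mu_down must be negative (log2 units)")

    @property
    def n_genes(self) -> int:
        return len(self.class_of)

    def count(self, cls: str) -> int:
        return sum(1 for c in self.class_of.values() if c == cls)

    @property
    def gamma_up(self) -> float:
        """Fraction of up-regulated genes among all genes."""
        return self.count("up") / self.n_genes

    @property
    def gamma_down(self) -> float:
        """Fraction of down-regulated genes among all genes."""
        return self.count("down") / self.n_genes

    @property
    def delta_bar(self) -> float:
        """Mean DEG contribution to an array average: γ+μ+ + γ−μ−."""
        return self.gamma_up * self.mu_up + self.gamma_down * self.mu_down

    def classes(self, gene_ids: Sequence[str]) -> np.ndarray:
        """Gene classes aligned to ``gene_ids`` as a string array."""
        return np.array([self.class_of[g] for g in gene_ids])

    def deg_ids(self) -> set:
        return {g for g, c in self.class_of.items() if c != "null"}


@dataclass
class TestResult:
    """Per-gene test statistic and raw two-sided p-value."""

    gene_ids: Sequence[str]
    statistic: np.ndarray
    p_raw: np.ndarray

    def __post_init__(self) -> None:
        self.gene_ids = list(self.gene_ids)
        self.statistic = np.asarray(self.statistic, dtype=float)
        self.p_raw = np.asarray(self.p_raw, dtype=float)
        if not (len(self.gene_ids) == len(self.statistic) == len(self.p_raw)):
            raise ValueError("gene_ids, statistic and p_raw lengths differ")
        if ((self.p_raw < 0) | (self.p_raw > 1)).any():
            raise ValueError("raw p-values must lie in [0, 1]")


@dataclass
class AdjustedResult:
    """Multiplicity-adjusted p-values and the rejection set at level alpha.

    Rejection uses the strict rule ``p_adj < alpha``: a gene is declared
    differentially expressed when its adjusted p-value is strictly below the
    prespecified significance level. The distinction from ``<=`` only matters
    for discrete (permutation) p-values.
    """

    gene_ids: Sequence[str]
    p_adj: np.ndarray
    rejected: np.ndarray
    alpha: float

    def __post_init__(self) -> None:
        self.gene_ids = list(self.gene_ids)
        self.p_adj = np.asarray(self.p_adj, dtype=float)
        self.rejected = np.asarray(self.rejected, dtype=bool)
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if len(self.p_adj) != len(self.rejected) or len(self.p_adj) != len(self.gene_ids):
            raise ValueError("field lengths differ")
        if ((self.p_adj < 0) | (self.p_adj > 1)).any():
            raise ValueError("adjusted p-values must lie in [0, 1]")
        if not np.array_equal(self.rejected, self.p_adj < self.alpha):
            raise ValueError("rejected must equal (p_adj < alpha)")

    def rejected_ids(self) -> set:
        return {g for g, r in zip(self.gene_ids, self.rejected) if r}


@dataclass
class QuantileReference:
    """Reference array of averaged order statistics (log2 units)."""

    q: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        if (np.diff(self.q) < 0).any():
            raise ValueError("quantile reference must be nondecreasing")


# ---------------------------------------------------------------------------
# TSV I/O


def read_matrix(path, labels_path) -> ExpressionMatrix:
    """Read a genes × arrays TSV plus a two-column array→group label TSV.

    The matrix header row holds array ids with the first column of gene ids
    under the token ``gene_id``. Any non-numeric cell, duplicate id, or array
    without a label raises :class:`MatrixParseError` naming the offender.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if df.columns[0] != "gene_id":
        raise MatrixParseError(
            f"first column header must be 'gene_id', got {df.columns[0]!r}"
        )
    gene_ids = df["gene_id"].tolist()
    array_ids = list(df.columns[1:])
    raw = df.iloc[:, 1:]
    # detect non-numeric cells first (named error), then parse with numpy's
    # correctly rounded strtod so written values round-trip bit-exactly
    probe = raw.apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)
    bad = np.argwhere(np.isnan(probe))
    if bad.size:
        i, j = bad[0]
        raise MatrixParseError(
            f"non-numeric cell {raw.iat[i, j]!r} at gene {gene_ids[i]}, "
            f"array {array_ids[j]}"
        )
    values = raw.to_numpy().astype(float)

    labels = pd.read_csv(labels_path, sep="\t", dtype=str, keep_default_na=False)
    if list(labels.columns[:2]) != ["array_id", "group"]:
        raise MatrixParseError("labels file must have columns array_id, group")
    group_of = dict(zip(labels["array_id"], labels["group"]))
    for aid in array_ids:
        if aid not in group_of:
            raise MatrixParseError(f"array {aid!r} missing from labels file")
    return ExpressionMatrix(values, gene_ids, array_ids, group_of)


def write_matrix(m: ExpressionMatrix, path, labels_path=None) -> None:
    """Write the matrix (and optionally its labels) as round-trippable TSV.

    Values are written with ``repr``-level precision so that
    ``read_matrix(write_matrix(m))`` reproduces them bit-exactly.
    """
    df = pd.DataFrame(m.values, columns=m.array_ids)
    df.insert(0, "gene_id", m.gene_ids)
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")
    if labels_path is not None:
        lab = pd.DataFrame(
            {"array_id": m.array_ids, "group": [m.group_of[a] for a in m.array_ids]}
        )
        lab.to_csv(labels_path, sep="\t", index=False)


def read_truth(path) -> TruthSet:
    """Read a gene_id / class / effect TSV into a :class:`TruthSet`."""
    df = pd.read_csv(
        path, sep="\t", dtype={"gene_id": str, "class": str}, keep_default_na=False
    )
    for col in ("gene_id", "class", "effect"):
        if col not in df.columns:
            raise MatrixParseError(f"truth file missing column {col!r}")
    ups = df.loc[df["class"] == "up", "effect"]
    downs = df.loc[df["class"] == "down", "effect"]
    mu_up = float(ups.mean()) if len(ups) else 1.0
    mu_down = float(downs.mean()) if len(downs) else -1.0
    return TruthSet(dict(zip(df["gene_id"], df["class"])), mu_up, mu_down)


def write_truth(t: TruthSet, path) -> None:
    effect = {"null": 0.0, "up": t.mu_up, "down": t.mu_down}
    df = pd.DataFrame(
        {
            "gene_id": list(t.class_of),
            "class": list(t.class_of.values()),
            "effect": [effect[c] for c in t.class_of.values()],
        }
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")
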