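"""Threshold classification and subpopulation analysis of single-cell RNA FISH counts.

Cells are called (+) or (-) per gene by a transcript-count cutoff: a cell is
negative for a gene iff its count is *strictly less* than the cutoff (a cell
at exactly the cutoff is positive).  On top of the calls the module
summarizes the nested "Russian doll" subpopulation structure (e.g. cells low
in Nanog, a subset of which are also low in Oct4, a subset of which express
lineage markers), tabulates co-expression of gene pairs, scores the observed
overlap against an independence null with a hypergeometric tail, and
computes fold changes in a gene's mean (or median) count between
subpopulations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Literal

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .errors import ConfigError, InputError

__all__ = [
    "ThresholdScheme",
    "CellLabelTable",
    "HierarchySummary",
    "CoexpressionTable",
    "FoldChangeResult",
    "classify_cells",
    "summarize_hierarchy",
    "coexpression_contingency",
    "overlap_probability",
    "subpopulation_fold_change",
]


@dataclass(frozen=True)
class ThresholdScheme:
    """Per-gene positivity cutoffs.

    A cell is (-) for a gene iff count < cutoff.
    """

    cutoffs: dict[str, int]

    def __post_init__(self) -> None:
        for gene, cut in self.cutoffs.items():
            if int(cut) < 1:
                raise ConfigError(f"cutoff for {gene!r} must be >= 1, got {cut}")

    def __getitem__(self, gene: str) -> int:
        try:
            return int(self.cutoffs[gene])
        except KeyError:
            raise InputError(f"no cutoff defined for gene {gene!r}") from None

    @property
    def genes(self) -> tuple[str, ...]:
        return tuple(self.cutoffs)


@dataclass(frozen=True)
class CellLabelTable:
    """Raw counts plus boolean positivity calls per (cell, gene).

    ``calls[g]`` is True where the cell is (+) for gene ``g``; ``counts``
    retains the raw table.
    """

    counts: pd.DataFrame
    calls: pd.DataFrame
    scheme: ThresholdScheme

    @property
    def n_cells(self) -> int:
        return len(self.calls)

    def positive(self, gene: str) -> pd.Series:
        if gene not in self.calls.columns:
            raise InputError(f"gene {gene!r} not classified")
        return self.calls[gene]

    def negative(self, gene: str) -> pd.Series:
        return ~self.positive(gene)


@dataclass(frozen=True)
class HierarchySummary:
    """Counts of cells negative for successive prefixes of a nesting order.

    ``counts[0]`` is the total cell number; ``counts[k]`` (k >= 1) the number
    of cells negative for all of the first k genes.  The sequence is weakly
    decreasing.  ``fractions[k]`` is the conditional fraction
    ``counts[k] / counts[k-1]`` (NaN when the parent level is empty).
    """

    nesting: tuple[str, ...]
    counts: tuple[int, ...]
    fractions: tuple[float, ...]

    def as_dict(self) -> dict:
        return {
            "nesting": list(self.nesting),
            "counts": list(self.counts),
            "fractions": list(self.fractions),
        }


@dataclass(frozen=True)
class CoexpressionTable:
    """2x2 cross-tabulation of positivity calls for a gene pair."""

    gene_a: str
    gene_b: str
    pp: int  # a(+) b(+)
    pn: int  # a(+) b(-)
    np_: int  # a(-) b(+)
    nn: int  # a(-) b(-)

    @property
    def total(self) -> int:
        return self.pp + self.pn + self.np_ + self.nn

    @property
    def overlap(self) -> int:
        return self.pp

    @property
    def marginal_a(self) -> int:
        return self.pp + self.pn

    @property
    def marginal_b(self) -> int:
        return self.pp + self.np_

    def as_dict(self) -> dict:
        return {
            "gene_a": self.gene_a,
            "gene_b": self.gene_b,
            "counts": {"++": self.pp, "+-": self.pn, "-+": self.np_, "--": self.nn},
            "total": self.total,
        }


@dataclass(frozen=True)
class FoldChangeResult:
    """Between-subpopulation fold change with its zero-guard provenance."""

    ratio: float
    center: str
    center_a: float
    center_b: float
    n_a: int
    n_b: int
    pseudocount_used: bool


def classify_cells(table: pd.DataFrame, scheme: ThresholdScheme) -> CellLabelTable:
    """Call each cell (+)/(-) per gene by the scheme's transcript cutoffs.

    Every scheme gene must be a column of ``table``; counts must be
    non-negative integers.  The call is a total partition: (+) iff
    count >= cutoff, (-) iff count < cutoff.
    """
    calls = {}
    for gene in scheme.genes:
        if gene not in table.columns:
            raise InputError(f"count table has no column for gene {gene!r}")
        col = table[gene]
        arr = col.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.all(np.equal(np.mod(arr, 1), 0)):
                raise InputError(f"non-integer counts in column {gene!r}")
            arr = arr.astype(np.int64)
        if (arr < 0).any():
            raise InputError(f"negative counts in column {gene!r}")
        calls[gene] = arr >= scheme[gene]
    call_df = pd.DataFrame(calls, index=table.index)
    return CellLabelTable(counts=table, calls=call_df, scheme=scheme)


def summarize_hierarchy(
    labels: CellLabelTable, nesting: list[str] | tuple[str, ...]
) -> HierarchySummary:
    """Count cells negative for successive prefixes of ``nesting``.

    The level-k count is the number of cells that are (-) for *all* of the
    first k genes, so the counts are monotone non-increasing with depth.
    """
    if not nesting:
        raise InputError("nesting order must name at least one gene")
    counts = [labels.n_cells]
    mask = np.ones(labels.n_cells, dtype=bool)
    for gene in nesting:
        mask &= labels.negative(gene).to_numpy()
        counts.append(int(mask.sum()))
    fractions = [
        counts[k + 1] / counts[k] if counts[k] > 0 else float("nan")
        for k in range(len(nesting))
    ]
    return HierarchySummary(
        nesting=tuple(nesting), counts=tuple(counts), fractions=tuple(fractions)
    )


def coexpression_contingency(
    labels: CellLabelTable, gene_a: str, gene_b: str
) -> CoexpressionTable:
    """2x2 cross-tabulation of calls for two genes over all cells."""
    if gene_a == gene_b:
        raise InputError(f"need two distinct genes, got {gene_a!r} twice")
    a = labels.positive(gene_a).to_numpy()
    b = labels.positive(gene_b).to_numpy()
    return CoexpressionTable(
        gene_a=gene_a,
        gene_b=gene_b,
        pp=int((a & b).sum()),
        pn=int((a & ~b).sum()),
        np_=int((~a & b).sum()),
        nn=int((~a & ~b).sum()),
    )


def overlap_probability(ct: CoexpressionTable) -> float:
    """Hypergeometric tail P(overlap >= observed) under an independence null.

    Given N cells with marginals m_a and m_b, the null places the m_b
    positives uniformly at random among the N cells; the returned value is
    the probability of at least the observed number of double positives.
    For the worked three-marker example (N=764, marginals 7 and 2, overlap 2)
    this is C(7,2)/C(764,2).
    """
    n = ct.total
    if ct.marginal_a > n or ct.marginal_b > n:
        raise InputError("marginals exceed the total cell count")
    if ct.overlap == 0:
        return 1.0
    # P(X >= k) for X ~ Hypergeom(N=n, K=marginal_a, n=marginal_b)
    return float(hypergeom.sf(ct.overlap - 1, n, ct.marginal_a, ct.marginal_b))


def subpopulation_fold_change(
    table: pd.DataFrame,
    labels: CellLabelTable,
    gene: str,
    group_a: Callable[[CellLabelTable], pd.Series] | pd.Series | np.ndarray,
    group_b: Callable[[CellLabelTable], pd.Series] | pd.Series | np.ndarray,
    center: Literal["mean", "median"] = "mean",
) -> FoldChangeResult:
    """Fold change of a gene's transcript level between two cell groups.

    ``group_a`` / ``group_b`` are boolean masks over cells, or callables
    producing them from the label table (e.g.
    ``lambda lb: lb.negative("Nanog")``).  Returns
    ``center(counts_a) / center(counts_b)``; when either center is zero a
    pseudocount of 1 is added to both centers and the result is flagged.
    """
    if gene not in table.columns:
        raise InputError(f"gene {gene!r} not in the count table")
    if center not in ("mean", "median"):
        raise InputError(f"center must be 'mean' or 'median', got {center!r}")
    mask_a = np.asarray(group_a(labels) if callable(group_a) else group_a, dtype=bool)
    mask_b = np.asarray(group_b(labels) if callable(group_b) else group_b, dtype=bool)
    if not mask_a.any():
        raise InputError("group_a selects no cells")
    if not mask_b.any():
        raise InputError("group_b selects no cells")
    vals = table[gene].to_numpy(dtype=float)
    fn = np.mean if center == "mean" else np.median
    c_a = float(fn(vals[mask_a]))
    c_b = float(fn(vals[mask_b]))
    if c_a > 0 and c_b > 0:
        return FoldChangeResult(
            ratio=c_a / c_b, center=center, center_a=c_a, center_b=c_b,
            n_a=int(mask_a.sum()), n_b=int(mask_b.sum()), pseudocount_used=False,
        )
    return FoldChangeResult(
        ratio=(c_a + 1.0) / (c_b + 1.0), center=center, center_a=c_a, center_b=c_b,
        n_a=int(mask_a.sum()), n_b=int(mask_b.sum()), pseudocount_used=True,
    )
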