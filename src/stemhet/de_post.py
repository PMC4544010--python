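"""Post-processing of differential-expression comparison tables.

Consumes per-gene log2 fold changes and p-values from any upstream test and
provides: Benjamini-Hochberg FDR adjustment and hit calling at a stated FDR
(10% in the motivating analyses), joint coherent/incoherent quadrant
classification of genes that are hits in two contrasts, transcription-factor
binding-overlap fractions, and directional summaries of designated gene
sets (e.g. ESC-specific lincRNAs).

Sign convention: positive log2 fold change means higher expression in the
second condition of the contrast (e.g. higher in the marker-negative or
differentiated sample).  A gene pair of contrasts is *coherent* when the
fold-change signs agree and *incoherent* when they disagree; joint hits with
a zero fold change in either contrast are excluded from quadrants and
flagged rather than assigned arbitrarily.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .errors import InputError

__all__ = [
    "ComparisonTable",
    "QuadrantSummary",
    "benjamini_hochberg",
    "call_hits",
    "quadrant_classify",
    "binding_overlap_fraction",
    "gene_set_directional_summary",
]


@dataclass
class ComparisonTable:
    """Per-gene comparison results for one contrast.

    ``data`` is indexed by gene with columns ``log2fc`` and ``pvalue``;
    ``padj`` and ``hit`` are added by :func:`call_hits`.  Genes with missing
    p-values are excluded from adjustment and flagged in ``excluded``.
    """

    data: pd.DataFrame
    fdr: float | None = None
    excluded: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        for col in ("log2fc", "pvalue"):
            if col not in self.data.columns:
                raise InputError(f"comparison table lacks column {col!r}")
        p = self.data["pvalue"].dropna()
        if ((p < 0) | (p > 1)).any():
            raise InputError("p-values must lie in [0, 1]")

    @property
    def genes(self) -> pd.Index:
        return self.data.index

    @property
    def hits(self) -> set[str]:
        if "hit" not in self.data.columns:
            raise InputError("hits not called yet; run call_hits first")
        return set(self.data.index[self.data["hit"]])

    @classmethod
    def from_arrays(cls, genes, log2fc, pvalue) -> "ComparisonTable":
        df = pd.DataFrame(
            {"log2fc": np.asarray(log2fc, dtype=float),
             "pvalue": np.asarray(pvalue, dtype=float)},
            index=pd.Index(genes, name="gene"),
        )
        return cls(data=df)


def benjamini_hochberg(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (clipped at 1).

    NaN entries are left NaN and excluded from the adjustment (they do not
    count toward m).
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise InputError("pvalues must be one-dimensional")
    valid = ~np.isnan(p)
    if ((p[valid] < 0) | (p[valid] > 1)).any():
        raise InputError("p-values must lie in [0, 1]")
    out = np.full_like(p, np.nan)
    if valid.sum():
        out[valid] = multipletests(p[valid], method="fdr_bh")[1]
    return out


def call_hits(table: ComparisonTable, fdr: float = 0.10) -> ComparisonTable:
    """Adjust p-values and flag hits at adjusted p <= fdr (inclusive boundary).

    Returns a new ComparisonTable whose ``data`` carries ``padj`` and
    ``hit`` columns; genes with missing p-values are recorded in
    ``excluded`` and are never hits.
    """
    if not (0.0 < fdr < 1.0):
        raise InputError(f"fdr must be in (0, 1), got {fdr}")
    data = table.data.copy()
    padj = benjamini_hochberg(data["pvalue"].to_numpy())
    data["padj"] = padj
    data["hit"] = np.where(np.isnan(padj), False, padj <= fdr)
    excluded = tuple(data.index[np.isnan(padj)])
    return ComparisonTable(data=data, fdr=fdr, excluded=excluded)


@dataclass(frozen=True)
class QuadrantSummary:
    """Joint-hit quadrant classification across two contrasts.

    Quadrants: ``coherent-up`` (both fold changes positive),
    ``coherent-down`` (both negative), ``incoherent-A-up`` (up in A, down in
    B), ``incoherent-B-up`` (down in A, up in B).  ``excluded_zero_fc``
    lists joint hits with a zero fold change in either contrast.
    """

    assignments: pd.Series
    excluded_zero_fc: tuple[str, ...]
    counts: dict[str, int] = field(default_factory=dict)

    @property
    def n_joint_hits(self) -> int:
        return len(self.assignments) + len(self.excluded_zero_fc)

    @property
    def coherent_fraction(self) -> float:
        n = len(self.assignments)
        if n == 0:
            return float("nan")
        coh = self.counts.get("coherent-up", 0) + self.counts.get("coherent-down", 0)
        return coh / n


def quadrant_classify(
    table_a: ComparisonTable, table_b: ComparisonTable
) -> QuadrantSummary:
    """Classify genes that are hits in both contrasts by fold-change signs."""
    shared = table_a.genes.intersection(table_b.genes)
    if len(shared) == 0:
        raise InputError("the two comparison tables share no genes")
    joint = sorted(table_a.hits & table_b.hits & set(shared))
    lfc_a = table_a.data.loc[joint, "log2fc"]
    lfc_b = table_b.data.loc[joint, "log2fc"]
    labels: dict[str, str] = {}
    excluded: list[str] = []
    for g in joint:
        a, b = lfc_a[g], lfc_b[g]
        if a == 0 or b == 0:
            excluded.append(g)
        elif a > 0 and b > 0:
            labels[g] = "coherent-up"
        elif a < 0 and b < 0:
            labels[g] = "coherent-down"
        elif a > 0:
            labels[g] = "incoherent-A-up"
        else:
            labels[g] = "incoherent-B-up"
    assignments = pd.Series(labels, dtype=object)
    counts = assignments.value_counts().to_dict() if len(labels) else {}
    return QuadrantSummary(
        assignments=assignments, excluded_zero_fc=tuple(excluded), counts=counts
    )


def binding_overlap_fraction(
    binding: dict[str, set[str]],
    hit_sets: dict[str, set[str]],
    universe: set[str],
) -> pd.DataFrame:
    """Fraction of each factor's bound genes that are hits of each type.

    For every (factor, hit-type): ``fraction = |bound ∩ hits| / |bound|``;
    the per-hit-type background is ``|hits| / |universe|``.  Factors with no
    bound genes get NaN and an ``undefined`` flag.  Hit sets must be subsets
    of the universe; bound genes are intersected with the universe first.
    """
    if not universe:
        raise InputError("empty gene universe")
    for name, hits in hit_sets.items():
        stray = hits - universe
        if stray:
            raise InputError(
                f"hit set {name!r} contains genes outside the universe: "
                f"{sorted(stray)[:5]}"
            )
    rows = []
    for factor, bound in binding.items():
        bound_in = bound & universe
        for hit_type, hits in hit_sets.items():
            if not bound_in:
                rows.append(
                    {"factor": factor, "hit_type": hit_type, "n_bound": 0,
                     "fraction": float("nan"), "undefined": True,
                     "background": len(hits) / len(universe)}
                )
            else:
                rows.append(
                    {"factor": factor, "hit_type": hit_type,
                     "n_bound": len(bound_in),
                     "fraction": len(bound_in & hits) / len(bound_in),
                     "undefined": False,
                     "background": len(hits) / len(universe)}
                )
    return pd.DataFrame(rows)


def gene_set_directional_summary(
    gene_set: set[str], table: ComparisonTable
) -> dict[str, float]:
    """Hit counts and directional bias of a designated gene set.

    Returns n_in_set, n_hits, n_up, n_down (hits with positive / negative
    fold change), n_zero (hits with zero fold change), hit_fraction, and
    directional bias (up - down) / (up + down) in [-1, 1] (NaN when no
    directed hits).
    """
    if not gene_set:
        raise InputError("empty gene set")
    stray = gene_set - set(table.genes)
    if stray:
        raise InputError(
            f"gene set contains genes outside the universe: {sorted(stray)[:5]}"
        )
    members = sorted(gene_set)
    sub = table.data.loc[members]
    hits = sub[sub["hit"]] if "hit" in sub.columns else sub.iloc[0:0]
    n_up = int((hits["log2fc"] > 0).sum())
    n_down = int((hits["log2fc"] < 0).sum())
    n_zero = int((hits["log2fc"] == 0).sum())
    directed = n_up + n_down
    return {
        "n_in_set": len(members),
        "n_hits": len(hits),
        "n_up": n_up,
        "n_down": n_down,
        "n_zero": n_zero,
        "hit_fraction": len(hits) / len(members),
        "bias": (n_up - n_down) / directed if directed else float("nan"),
    }
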