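"""Greedy gene-ontology summarization of a gene set of interest.

Conventional GO enrichment returns long lists of redundant, overlapping
terms.  The greedy summarization here instead builds a short ranked list:
among categories whose original annotation size exceeds a minimum (the root
is always eligible), repeatedly select the category with the highest
*concentration* of interest genes — the fraction of its not-yet-claimed
genes that are still-unclaimed interest genes — then remove the selected
category's remaining genes from every category and from the interest set,
until the root category is selected.  Because each gene can be claimed only
once, closely related terms cannot crowd the list by re-counting the same
evidence.

After selection, any gene is assigned ("falls") to the earliest-selected
category whose original annotation contains it; genes annotated only to the
root fall to the root.  Assignment uses original membership, so it is
well-defined for genes outside the interest set too.

Tie-breaking is deterministic: equal concentrations resolve by larger
residual category size, then lexicographic category id.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .errors import InputError

__all__ = [
    "GoAnnotationMap",
    "GreedySelection",
    "greedy_select",
    "assign_genes",
    "category_report",
]


@dataclass(frozen=True)
class GoAnnotationMap:
    """Category -> gene-set annotations with a designated root category.

    The root must annotate every gene in the universe (for GO biological
    process this is GO:0008150).  ``original_size`` records sizes before any
    greedy removals.
    """

    categories: dict[str, frozenset[str]]
    root_id: str

    def __post_init__(self) -> None:
        if self.root_id not in self.categories:
            raise InputError(f"root category {self.root_id!r} not in annotations")
        universe = self.universe
        root = self.categories[self.root_id]
        if root != universe:
            missing = universe - root
            raise InputError(
                f"root category must annotate every gene; missing {sorted(missing)[:5]}..."
                if len(missing) > 5
                else f"root category must annotate every gene; missing {sorted(missing)}"
            )

    @property
    def universe(self) -> frozenset[str]:
        out: set[str] = set()
        for members in self.categories.values():
            out |= members
        return frozenset(out)

    def original_size(self, category: str) -> int:
        return len(self.categories[category])

    @classmethod
    def from_sets(cls, categories: dict[str, set[str]], root_id: str) -> "GoAnnotationMap":
        return cls(
            categories={k: frozenset(v) for k, v in categories.items()},
            root_id=root_id,
        )


@dataclass(frozen=True)
class SelectionStep:
    """One greedy selection: the category, its concentration at selection
    time, and the genes it claimed (removed from play)."""

    category: str
    concentration: float
    claimed: frozenset[str]


@dataclass(frozen=True)
class GreedySelection:
    """Ordered greedy selections; the last entry is always the root."""

    steps: tuple[SelectionStep, ...]
    min_size: int
    interest: frozenset[str]

    @property
    def order(self) -> tuple[str, ...]:
        return tuple(s.category for s in self.steps)

    def rank(self, category: str) -> int:
        return self.order.index(category)


def greedy_select(
    annot: GoAnnotationMap, interest: set[str], min_size: int = 750
) -> GreedySelection:
    """Greedily rank categories by concentration of interest genes.

    Only categories with original size strictly greater than ``min_size``
    compete (the root is always eligible).  At each step the eligible
    category maximizing |remaining genes ∩ remaining interest| /
    |remaining genes| is selected; its remaining genes are removed from all
    categories and from the interest set.  Selection of the root terminates
    the loop; when the best concentration is 0 the root is selected
    immediately.  The default minimum size of 750 genes matches the scale at
    which broad biological-process terms (development, adhesion, ...)
    survive while narrow redundant terms are excluded.
    """
    if min_size < 1:
        raise InputError(f"min_size must be >= 1, got {min_size}")
    universe = annot.universe
    stray = set(interest) - universe
    if stray:
        raise InputError(f"interest genes outside the universe: {sorted(stray)[:5]}")

    eligible = [
        c
        for c in annot.categories
        if c == annot.root_id or annot.original_size(c) > min_size
    ]
    remaining = {c: set(annot.categories[c]) for c in eligible}
    remaining_interest = set(interest)
    steps: list[SelectionStep] = []

    while True:
        best: tuple[float, int, str] | None = None
        for c in eligible:
            genes = remaining[c]
            if not genes:
                continue  # emptied by removals; skipped silently
            conc = len(genes & remaining_interest) / len(genes)
            # maximize concentration, then residual size, then reversed id
            # (so that the lexicographically smaller id wins the final tie)
            key = (conc, len(genes), _NegStr(c))
            if best is None or key > best:
                best = key
                best_cat = c
                best_conc = conc
        if best is None or best_conc == 0.0:
            best_cat = annot.root_id
            root_rem = remaining[annot.root_id]
            best_conc = (
                len(root_rem & remaining_interest) / len(root_rem) if root_rem else 0.0
            )
        claimed = frozenset(remaining[best_cat])
        steps.append(
            SelectionStep(category=best_cat, concentration=best_conc, claimed=claimed)
        )
        if best_cat == annot.root_id:
            break
        for c in eligible:
            remaining[c] -= claimed
        remaining_interest -= claimed

    return GreedySelection(
        steps=tuple(steps), min_size=min_size, interest=frozenset(interest)
    )


class _NegStr(str):
    """String with reversed ordering, for lexicographic tie-breaks inside a
    max-key tuple."""

    def __lt__(self, other):  # noqa: D105
        return str.__gt__(self, other)

    def __gt__(self, other):  # noqa: D105
        return str.__lt__(self, other)


def assign_genes(
    sel: GreedySelection, annot: GoAnnotationMap, genes: set[str]
) -> dict[str, str]:
    """Assign each gene to the earliest-selected category annotating it.

    Membership is evaluated on the ORIGINAL annotations; genes annotated to
    no selected non-root category fall to the root.
    """
    universe = annot.universe
    stray = set(genes) - universe
    if stray:
        raise InputError(f"genes outside the universe: {sorted(stray)[:5]}")
    assignment: dict[str, str] = {}
    order = sel.order
    for g in genes:
        for c in order:
            if g in annot.categories[c]:
                assignment[g] = c
                break
        else:
            assignment[g] = annot.root_id
    return assignment


def category_report(
    sel: GreedySelection,
    assignment: dict[str, str],
    hit_flags: dict[str, bool] | set[str],
    annot: GoAnnotationMap,
) -> pd.DataFrame:
    """Per selected category: hit fraction and number of hit genes that fell in.

    ``hit_fraction`` is the fraction of the category's ORIGINAL genes that
    are hits; ``n_fallen_hits`` counts hit genes whose assignment is this
    category.  Summed over the selection, ``n_fallen_hits`` equals the
    number of assigned hit genes.
    """
    if isinstance(hit_flags, set):
        hits = hit_flags
    else:
        hits = {g for g, flag in hit_flags.items() if flag}
    rows = []
    for rank, step in enumerate(sel.steps):
        members = annot.categories[step.category]
        n_hit = len(members & hits)
        fallen = sum(
            1 for g, c in assignment.items() if c == step.category and g in hits
        )
        rows.append(
            {
                "rank": rank,
                "category": step.category,
                "concentration": step.concentration,
                "original_size": len(members),
                "hit_fraction": n_hit / len(members) if members else float("nan"),
                "n_fallen_hits": fallen,
            }
        )
    return pd.DataFrame(rows)
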