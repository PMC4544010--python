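"""Shared fixtures and independent reference implementations (oracles).

The oracles here are deliberately literal, step-by-step implementations kept
separate from the package code paths they check.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings
from scipy import stats

from stemhet import fixtures
from stemhet.de_post import ComparisonTable
from stemhet.fish_hierarchy import classify_cells
from stemhet.synthetic_data import generate_fish_fixture

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


# ---------------------------------------------------------------- fixtures

@pytest.fixture(scope="session")
def fig4a_table():
    return generate_fish_fixture(fixtures.load_fixture_config("fig4a"))


@pytest.fixture(scope="session")
def fig4a_labels(fig4a_table):
    return classify_cells(fig4a_table, fixtures.CUTOFFS["fig4a"])


@pytest.fixture(scope="session")
def fig4b_labels():
    table = generate_fish_fixture(fixtures.load_fixture_config("fig4b"))
    return classify_cells(table, fixtures.CUTOFFS["fig4b"])


@pytest.fixture(scope="session")
def fig4c_labels():
    table = generate_fish_fixture(fixtures.load_fixture_config("fig4c"))
    return classify_cells(table, fixtures.CUTOFFS["fig4c"])


# ----------------------------------------------------------------- oracles

def bh_stepup_reference(pvalues: np.ndarray) -> np.ndarray:
    """Textbook Benjamini-Hochberg step-up: sort, scale by m/rank, take the
    running minimum from the largest p down, clip at 1."""
    p = np.asarray(pvalues, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    adj = np.empty(m)
    running_min = 1.0
    for rank_from_top in range(m, 0, -1):
        idx = order[rank_from_top - 1]
        val = p[idx] * m / rank_from_top
        running_min = min(running_min, val)
        adj[idx] = min(running_min, 1.0)
    return adj


def greedy_select_reference(
    categories: dict[str, set[str]], root_id: str, interest: set[str], min_size: int
) -> list[tuple[str, float]]:
    """Literal step-by-step greedy GO selection.

    Eligibility by original size (> min_size; root always); concentration =
    remaining interest in category / remaining category genes; ties broken by
    larger residual size then lexicographic id; selected genes removed from
    all categories and the interest set; stops when the root is selected,
    immediately if the best concentration is zero.
    """
    eligible = [
        c for c in categories if c == root_id or len(categories[c]) > min_size
    ]
    remaining = {c: set(categories[c]) for c in eligible}
    left = set(interest)
    out: list[tuple[str, float]] = []
    while True:
        scored = []
        for c in eligible:
            if not remaining[c]:
                continue
            conc = len(remaining[c] & left) / len(remaining[c])
            scored.append((conc, len(remaining[c]), c))
        best_conc = max((s[0] for s in scored), default=0.0)
        if best_conc == 0.0:
            rem_root = remaining[root_id]
            conc_root = len(rem_root & left) / len(rem_root) if rem_root else 0.0
            out.append((root_id, conc_root))
            return out
        tied = [s for s in scored if s[0] == best_conc]
        tied.sort(key=lambda s: (-s[1], s[2]))
        _, _, chosen = tied[0]
        out.append((chosen, best_conc))
        if chosen == root_id:
            return out
        claimed = set(remaining[chosen])
        for c in eligible:
            remaining[c] -= claimed
        left -= claimed


def assign_genes_reference(
    order: list[str], categories: dict[str, set[str]], root_id: str, genes: set[str]
) -> dict[str, str]:
    """Earliest-selected original-membership assignment, by direct scan."""
    out = {}
    for g in genes:
        assigned = root_id
        for c in order:
            if g in categories[c]:
                assigned = c
                break
        out[g] = assigned
    return out


def naive_per_gene_test(
    counts: pd.DataFrame, cond1: str = "A", cond2: str = "B"
) -> ComparisonTable:
    """Simple per-gene two-sample t-test on log2(count+1) — a simulation
    driver for FDR-control checks, not a DE method."""
    import warnings

    a = np.log2(counts.filter(like=f"{cond1}_").to_numpy() + 1.0)
    b = np.log2(counts.filter(like=f"{cond2}_").to_numpy() + 1.0)
    with np.errstate(all="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        _, p = stats.ttest_ind(a, b, axis=1)
    p = np.where(np.isnan(p), 1.0, p)
    lfc = b.mean(axis=1) - a.mean(axis=1)
    return ComparisonTable.from_arrays(counts.index, lfc, p)


def random_go_universe(rng: np.random.Generator, max_categories: int = 10,
                       max_genes: int = 50):
    """Small random annotation universe for oracle-equivalence checks."""
    n_genes = int(rng.integers(5, max_genes + 1))
    genes = [f"g{i}" for i in range(n_genes)]
    n_cat = int(rng.integers(1, max_categories))
    categories: dict[str, set[str]] = {}
    for k in range(n_cat):
        size = int(rng.integers(1, n_genes + 1))
        categories[f"C{k}"] = set(rng.choice(genes, size=size, replace=False))
    categories["ROOT"] = set(genes)
    n_int = int(rng.integers(0, n_genes + 1))
    interest = set(rng.choice(genes, size=n_int, replace=False))
    min_size = int(rng.integers(1, max(2, n_genes // 2)))
    return categories, interest, min_size
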