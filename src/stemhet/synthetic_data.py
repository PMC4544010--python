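"""Synthetic single-cell and bulk count data emulating ESC heterogeneity experiments.

This module generates every input the analysis pipeline consumes:

* per-cell transcript-count tables with a nested ("Russian doll") latent
  subpopulation structure, as measured by single-molecule RNA FISH;
* reporter-infidelity tables pairing a gene's own mRNA count with the count of
  a destabilized fluorescent reporter (VNP) transcribed from the same locus,
  where a configurable fraction of mRNA-positive cells are reporter-negative;
* bulk negative-binomial count matrices in two conditions with planted
  differential expression;
* gene-ontology-style universes with planted enriched categories;

All generators are deterministic functions of an explicit integer seed; there
is no global random state.  Class compositions are stratified-exact: a class
configured with ``n_cells`` contributes exactly that many rows, so printed
population compositions can be encoded verbatim in a fixture config.

Within-class count distributions are configurable (the underlying experiments
report thresholds and a few fold changes, not distribution families); marker
positive classes default to rounded lognormals and near-zero classes to
negative binomials.  An optional *guard* per (class, gene) rejection-samples
counts onto the class's side of a positivity cutoff so that downstream
threshold classification recovers the latent labels exactly.  Guarded
fixtures test pipeline plumbing, not distributional realism.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError

__all__ = [
    "GuardSpec",
    "GeneDistSpec",
    "CellClassSpec",
    "FixtureConfig",
    "ReporterConfig",
    "BulkCountConfig",
    "GoUniverseConfig",
    "generate_fish_fixture",
    "generate_reporter_table",
    "generate_bulk_counts",
    "generate_go_universe",
]

_FAMILIES = ("negative-binomial", "lognormal-rounded", "constant")

# Redraw rounds for guard rejection sampling before giving up.  A guard whose
# acceptance probability is so low that 10k vectorized rounds fail indicates a
# misconfigured distribution, not bad luck.
_MAX_REJECTION_ROUNDS = 10_000


@dataclass(frozen=True)
class GuardSpec:
    """Constrain class-conditional counts to one side of a positivity cutoff.

    side "+" keeps counts at or above ``cutoff * (1 + margin)``;
    side "-" keeps counts strictly below ``cutoff * (1 - margin)``.
    The margin comes from the owning class's ``guard_margin``.
    """

    cutoff: int
    side: str  # "+" or "-"

    def __post_init__(self) -> None:
        if self.cutoff < 1:
            raise ConfigError(f"guard cutoff must be >= 1, got {self.cutoff}")
        if self.side not in ("+", "-"):
            raise ConfigError(f"guard side must be '+' or '-', got {self.side!r}")

    def accepts(self, counts: np.ndarray, margin: float) -> np.ndarray:
        if self.side == "+":
            return counts >= self.cutoff * (1.0 + margin)
        return counts < self.cutoff * (1.0 - margin)


@dataclass(frozen=True)
class GeneDistSpec:
    """Count distribution for one gene within one latent cell class.

    family:
        "negative-binomial" — mean ``loc``, variance ``loc + shape * loc**2``
        (``shape`` is the NB dispersion alpha; alpha = 0 gives Poisson);
        "lognormal-rounded" — round(LogNormal(median=``loc``, sigma=``shape``));
        "constant" — every cell gets exactly ``loc`` transcripts.
    """

    family: str
    loc: float
    shape: float = 0.0
    guard: GuardSpec | None = None

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise ConfigError(
                f"unknown distribution family {self.family!r}; "
                f"expected one of {_FAMILIES}"
            )
        if self.loc < 0:
            raise ConfigError(f"location parameter must be >= 0, got {self.loc}")
        if self.shape < 0:
            raise ConfigError(f"shape parameter must be >= 0, got {self.shape}")

    def draw(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if self.family == "constant":
            return np.full(n, int(round(self.loc)), dtype=np.int64)
        if self.family == "negative-binomial":
            return _draw_nb(self.loc, self.shape, n, rng)
        # lognormal-rounded: loc is the median on the count scale
        if self.loc == 0:
            return np.zeros(n, dtype=np.int64)
        raw = rng.lognormal(mean=np.log(self.loc), sigma=self.shape, size=n)
        return np.round(raw).astype(np.int64)

    def draw_guarded(self, n: int, margin: float, rng: np.random.Generator) -> np.ndarray:
        counts = self.draw(n, rng)
        if self.guard is None:
            return counts
        bad = ~self.guard.accepts(counts, margin)
        rounds = 0
        while bad.any():
            rounds += 1
            if rounds > _MAX_REJECTION_ROUNDS:
                raise ConfigError(
                    f"guard {self.guard} rejects essentially all draws from "
                    f"{self.family}(loc={self.loc}, shape={self.shape}); "
                    "adjust the distribution or the guard"
                )
            redraw = self.draw(int(bad.sum()), rng)
            counts[bad] = redraw
            bad = ~self.guard.accepts(counts, margin)
        return counts


def _draw_nb(mean: float, alpha: float, n: int, rng: np.random.Generator) -> np.ndarray:
    """NB draws parameterized by mean and dispersion alpha (var = m + alpha m^2)."""
    if mean == 0:
        return np.zeros(n, dtype=np.int64)
    if alpha == 0:
        return rng.poisson(mean, size=n).astype(np.int64)
    size = 1.0 / alpha  # NB number-of-successes parameter
    p = size / (size + mean)
    return rng.negative_binomial(size, p, size=n).astype(np.int64)


@dataclass(frozen=True)
class CellClassSpec:
    """One latent cell class: an exact cell count and per-gene distributions."""

    class_name: str
    n_cells: int
    per_gene_dist: dict[str, GeneDistSpec]
    guard_margin: float = 0.0

    def __post_init__(self) -> None:
        if self.n_cells < 0:
            raise ConfigError(f"n_cells must be >= 0, got {self.n_cells}")
        if not (0.0 <= self.guard_margin < 1.0):
            raise ConfigError(
                f"guard_margin must be in [0, 1), got {self.guard_margin}"
            )


@dataclass(frozen=True)
class FixtureConfig:
    """An ordered set of cell classes plus the gene list and seed."""

    classes: tuple[CellClassSpec, ...]
    seed: int
    genes: tuple[str, ...]

    def __post_init__(self) -> None:
        names = [c.class_name for c in self.classes]
        if len(set(names)) != len(names):
            raise ConfigError(f"class names must be unique, got {names}")
        for cls in self.classes:
            missing = [g for g in self.genes if g not in cls.per_gene_dist]
            if missing:
                raise ConfigError(
                    f"class {cls.class_name!r} lacks distributions for genes {missing}"
                )

    @property
    def total_cells(self) -> int:
        return sum(c.n_cells for c in self.classes)

    @classmethod
    def from_dict(cls, d: dict) -> "FixtureConfig":
        """Build from a plain (YAML/JSON-shaped) mapping."""
        try:
            genes = tuple(d["genes"])
            default_margin = float(d.get("guard_margin", 0.0))
            classes = []
            for cspec in d["classes"]:
                dists = {}
                for gene, gd in cspec["genes"].items():
                    guard = gd.get("guard")
                    guard_spec = (
                        GuardSpec(cutoff=int(guard["cutoff"]), side=str(guard["side"]))
                        if guard
                        else None
                    )
                    dists[gene] = GeneDistSpec(
                        family=gd["family"],
                        loc=float(gd["loc"]),
                        shape=float(gd.get("shape", 0.0)),
                        guard=guard_spec,
                    )
                classes.append(
                    CellClassSpec(
                        class_name=cspec["name"],
                        n_cells=int(cspec["n_cells"]),
                        per_gene_dist=dists,
                        guard_margin=float(cspec.get("guard_margin", default_margin)),
                    )
                )
            return cls(classes=tuple(classes), seed=int(d["seed"]), genes=genes)
        except KeyError as exc:
            raise ConfigError(f"fixture config missing required key: {exc}") from exc


def generate_fish_fixture(
    config: FixtureConfig, seed: int | None = None
) -> pd.DataFrame:
    """Generate a per-cell transcript-count table with latent class labels.

    Returns a DataFrame with columns ``cell_id``, ``cell_class`` and one
    integer count column per gene.  Class sizes are stratified-exact and the
    output is a deterministic function of the seed.

    Parameters
    ----------
    config : FixtureConfig
    seed : int, optional
        Overrides ``config.seed``.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    return _generate_with_rng(config, rng)


@dataclass(frozen=True)
class ReporterConfig:
    """Reporter-infidelity experiment: mRNA counts vs. reporter (VNP) counts.

    Among cells positive for the tracked mRNA, a Bernoulli(``fn_fraction``)
    subset has its reporter counts replaced by draws from ``fn_reporter_dist``
    (below the reporter cutoff) while the mRNA counts are untouched — these
    are the reporter false negatives, which keep the mRNA-positive count
    distribution.
    """

    fn_fraction: float
    n_cells: int
    base_classes: FixtureConfig
    mrna_gene: str = "Nanog"
    reporter_gene: str = "VNP"
    mrna_cutoff: int = 30
    reporter_cutoff: int = 30
    fn_reporter_dist: GeneDistSpec = field(
        default_factory=lambda: GeneDistSpec(
            family="negative-binomial", loc=5.0, shape=0.3,
            guard=GuardSpec(cutoff=30, side="-"),
        )
    )

    def __post_init__(self) -> None:
        if not (0.0 <= self.fn_fraction <= 1.0):
            raise ConfigError(
                f"fn_fraction must be in [0, 1], got {self.fn_fraction}"
            )
        if self.n_cells != self.base_classes.total_cells:
            raise ConfigError(
                f"n_cells={self.n_cells} does not match the base class "
                f"total of {self.base_classes.total_cells}"
            )
        for gene in (self.mrna_gene, self.reporter_gene):
            if gene not in self.base_classes.genes:
                raise ConfigError(f"gene {gene!r} missing from base_classes.genes")

    @property
    def implied_fn_among_reporter_negative(self) -> float:
        """P(mRNA-positive | reporter-negative) implied by the class mix.

        Assumes base classes are guarded so that mRNA-negative classes are
        also reporter-negative and mRNA-positive classes reporter-positive
        before infidelity is applied.
        """
        n_pos = sum(
            c.n_cells
            for c in self.base_classes.classes
            if _is_positive_class(c, self.mrna_gene)
        )
        n_neg = self.base_classes.total_cells - n_pos
        expected_fn = self.fn_fraction * n_pos
        denom = expected_fn + n_neg
        return expected_fn / denom if denom > 0 else float("nan")

    @classmethod
    def from_dict(cls, d: dict) -> "ReporterConfig":
        base = FixtureConfig.from_dict(d["base_classes"])
        kwargs = {}
        if "fn_reporter_dist" in d:
            gd = d["fn_reporter_dist"]
            guard = gd.get("guard")
            kwargs["fn_reporter_dist"] = GeneDistSpec(
                family=gd["family"],
                loc=float(gd["loc"]),
                shape=float(gd.get("shape", 0.0)),
                guard=GuardSpec(int(guard["cutoff"]), str(guard["side"]))
                if guard
                else None,
            )
        return cls(
            fn_fraction=float(d["fn_fraction"]),
            n_cells=int(d["n_cells"]),
            base_classes=base,
            mrna_gene=d.get("mrna_gene", "Nanog"),
            reporter_gene=d.get("reporter_gene", "VNP"),
            mrna_cutoff=int(d.get("mrna_cutoff", 30)),
            reporter_cutoff=int(d.get("reporter_cutoff", 30)),
            **kwargs,
        )


def _is_positive_class(cls: CellClassSpec, gene: str) -> bool:
    spec = cls.per_gene_dist[gene]
    if spec.guard is not None:
        return spec.guard.side == "+"
    raise ConfigError(
        f"class {cls.class_name!r} has no guard on {gene!r}; reporter configs "
        "require guarded mRNA distributions so the latent polarity is defined"
    )


def generate_reporter_table(
    config: ReporterConfig, seed: int | None = None
) -> pd.DataFrame:
    """Generate a per-cell table with both mRNA and reporter counts.

    Adds a boolean ``reporter_false_negative`` column marking the cells whose
    reporter counts were suppressed.
    """
    rng = np.random.default_rng(
        config.base_classes.seed if seed is None else seed
    )
    table = _generate_with_rng(config.base_classes, rng)
    mrna_pos = np.zeros(len(table), dtype=bool)
    for cls in config.base_classes.classes:
        if _is_positive_class(cls, config.mrna_gene):
            mrna_pos |= (table["cell_class"] == cls.class_name).to_numpy()
    flip = rng.random(len(table)) < config.fn_fraction
    fn_mask = mrna_pos & flip
    n_fn = int(fn_mask.sum())
    if n_fn:
        low = config.fn_reporter_dist.draw_guarded(n_fn, 0.0, rng)
        counts = table[config.reporter_gene].to_numpy().copy()
        counts[fn_mask] = low
        table[config.reporter_gene] = counts
    table["reporter_false_negative"] = fn_mask
    return table


def _generate_with_rng(config: FixtureConfig, rng: np.random.Generator) -> pd.DataFrame:
    blocks = []
    offset = 0
    for cls in config.classes:
        data: dict[str, object] = {
            "cell_id": [f"cell_{i:05d}" for i in range(offset, offset + cls.n_cells)],
            "cell_class": [cls.class_name] * cls.n_cells,
        }
        for gene in config.genes:
            data[gene] = cls.per_gene_dist[gene].draw_guarded(
                cls.n_cells, cls.guard_margin, rng
            )
        blocks.append(pd.DataFrame(data))
        offset += cls.n_cells
    if not blocks:
        return pd.DataFrame(columns=["cell_id", "cell_class", *config.genes])
    return pd.concat(blocks, ignore_index=True)


@dataclass(frozen=True)
class BulkCountConfig:
    """Two-condition bulk RNA count matrix with planted fold changes.

    Counts are negative binomial with per-gene baseline means and a common
    dispersion alpha (variance = m + alpha m^2).  A ``de_fraction`` of genes
    gets a condition-2 mean of ``baseline * 2**planted_log2fc``.
    ``baseline_mean`` is either a scalar or a (low, high) pair, in which case
    per-gene baselines are drawn log-uniformly.
    """

    n_genes: int
    conditions: tuple[str, str] = ("A", "B")
    replicates_per_condition: int = 3
    baseline_mean: float | tuple[float, float] = 100.0
    dispersion: float = 0.1
    de_fraction: float = 0.0
    planted_log2fc: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.replicates_per_condition < 2:
            raise ConfigError("replicates_per_condition must be >= 2")
        if self.dispersion < 0:
            raise ConfigError("dispersion must be >= 0")
        if not (0.0 <= self.de_fraction <= 1.0):
            raise ConfigError("de_fraction must be in [0, 1]")
        if len(self.conditions) != 2:
            raise ConfigError("exactly two condition labels required")


def generate_bulk_counts(
    config: BulkCountConfig, seed: int | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate a gene x sample count matrix plus the planted-truth table.

    Returns ``(counts, truth)``: counts indexed by gene with columns
    ``<cond>_rep<i>``; truth has one row per planted gene with its log2 fold
    change (empty when ``de_fraction == 0``).
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    genes = [f"gene_{i:05d}" for i in range(config.n_genes)]
    if isinstance(config.baseline_mean, tuple):
        lo, hi = config.baseline_mean
        base = np.exp(rng.uniform(np.log(lo), np.log(hi), size=config.n_genes))
    else:
        base = np.full(config.n_genes, float(config.baseline_mean))

    n_de = int(round(config.de_fraction * config.n_genes))
    de_idx = rng.choice(config.n_genes, size=n_de, replace=False) if n_de else np.array([], dtype=int)
    mean2 = base.copy()
    mean2[de_idx] = base[de_idx] * 2.0 ** config.planted_log2fc

    cols = {}
    cond1, cond2 = config.conditions
    for r in range(config.replicates_per_condition):
        cols[f"{cond1}_rep{r + 1}"] = _draw_nb_vector(base, config.dispersion, rng)
    for r in range(config.replicates_per_condition):
        cols[f"{cond2}_rep{r + 1}"] = _draw_nb_vector(mean2, config.dispersion, rng)
    counts = pd.DataFrame(cols, index=pd.Index(genes, name="gene"))

    truth = pd.DataFrame(
        {
            "gene": [genes[i] for i in sorted(de_idx)],
            "log2fc": config.planted_log2fc,
        }
    ) if n_de else pd.DataFrame(columns=["gene", "log2fc"])
    return counts, truth


def _draw_nb_vector(
    means: np.ndarray, alpha: float, rng: np.random.Generator
) -> np.ndarray:
    if alpha == 0:
        return rng.poisson(means).astype(np.int64)
    size = 1.0 / alpha
    p = size / (size + means)
    return rng.negative_binomial(size, p).astype(np.int64)


@dataclass(frozen=True)
class GoUniverseConfig:
    """Random GO-style universe with planted enriched categories.

    ``planted`` lists ``(category_index, concentration)`` pairs: that
    category's interest-gene fraction is hit exactly, by construction.
    Planted categories draw only previously-unused genes so the exact
    concentration cannot be diluted by overlap.  Non-planted, non-root genes
    are interest genes at ``background_rate``.
    """

    n_genes: int
    n_categories: int
    size_range: tuple[int, int] = (5, 20)
    overlap_rate: float = 0.0
    planted: tuple[tuple[int, float], ...] = ()
    root_id: str = "GO:ROOT"
    background_rate: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.size_range[0] < 1 or self.size_range[1] < self.size_range[0]:
            raise ConfigError(f"bad size_range {self.size_range}")
        if not (0.0 <= self.overlap_rate <= 1.0):
            raise ConfigError("overlap_rate must be in [0, 1]")
        for idx, conc in self.planted:
            if not (0 <= idx < self.n_categories):
                raise ConfigError(f"planted index {idx} out of range")
            if not (0.0 <= conc <= 1.0):
                raise ConfigError(f"planted concentration {conc} not in [0, 1]")


def generate_go_universe(
    config: GoUniverseConfig, seed: int | None = None
) -> tuple[dict[str, set[str]], str, set[str]]:
    """Generate ``(categories, root_id, interest_genes)``.

    ``categories`` maps category id -> gene set and includes the root, which
    annotates every gene in the universe.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    genes = [f"g{i:05d}" for i in range(config.n_genes)]
    planted_map = dict(config.planted)

    unused = list(genes)
    rng.shuffle(unused)
    used: list[str] = []
    categories: dict[str, set[str]] = {}
    interest: set[str] = set()

    for k in range(config.n_categories):
        size = int(rng.integers(config.size_range[0], config.size_range[1] + 1))
        is_planted = k in planted_map
        n_shared = 0 if is_planted else int(round(size * config.overlap_rate))
        n_shared = min(n_shared, len(used))
        n_fresh = size - n_shared
        if n_fresh > len(unused):
            raise ConfigError(
                f"universe of {config.n_genes} genes too small for "
                f"{config.n_categories} categories of sizes {config.size_range}"
            )
        members = set()
        if n_shared:
            members.update(rng.choice(used, size=n_shared, replace=False))
        fresh = [unused.pop() for _ in range(n_fresh)]
        members.update(fresh)
        used.extend(fresh)
        categories[f"GO:{k:07d}"] = members
        if is_planted:
            n_int = int(round(planted_map[k] * size))
            if n_int > len(fresh):
                raise ConfigError(
                    f"planted concentration {planted_map[k]} infeasible for "
                    f"category of size {size}"
                )
            interest.update(fresh[:n_int])

    # background interest among genes not in any planted category
    planted_genes = set().union(
        *(categories[f"GO:{k:07d}"] for k in planted_map)
    ) if planted_map else set()
    for g in genes:
        if g in planted_genes:
            continue
        if rng.random() < config.background_rate:
            interest.add(g)

    categories[config.root_id] = set(genes)
    return categories, config.root_id, interest
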