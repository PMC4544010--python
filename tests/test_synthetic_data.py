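"""Generators: determinism, stratified exactness, guards, moments, planting."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from stemhet import fixtures
from stemhet.errors import ConfigError
from stemhet.fish_hierarchy import classify_cells
from stemhet.synthetic_data import (
    BulkCountConfig,
    CellClassSpec,
    FixtureConfig,
    GeneDistSpec,
    GoUniverseConfig,
    GuardSpec,
    ReporterConfig,
    generate_bulk_counts,
    generate_fish_fixture,
    generate_go_universe,
    generate_reporter_table,
)


def _single_class_config(dist: GeneDistSpec, n_cells=10, margin=0.0, seed=1):
    cls = CellClassSpec("only", n_cells, {"G": dist}, guard_margin=margin)
    return FixtureConfig(classes=(cls,), seed=seed, genes=("G",))


class TestFishFixture:
    @pytest.mark.parametrize("name", ["fig4a", "fig4b", "fig4c"])
    def test_stratified_class_counts_are_exact(self, name):
        cfg = fixtures.load_fixture_config(name)
        table = generate_fish_fixture(cfg)
        counts = table["cell_class"].value_counts()
        for cls in cfg.classes:
            assert counts[cls.class_name] == cls.n_cells
        assert len(table) == cfg.total_cells

    @pytest.mark.parametrize("name", ["fig4a", "fig4b", "fig4c"])
    def test_same_seed_reproduces_table_byte_identically(self, name):
        cfg = fixtures.load_fixture_config(name)
        a = generate_fish_fixture(cfg).to_csv(sep="\t")
        b = generate_fish_fixture(cfg).to_csv(sep="\t")
        assert a == b

    def test_different_seed_changes_counts(self):
        cfg = fixtures.load_fixture_config("fig4a")
        a = generate_fish_fixture(cfg, seed=1)
        b = generate_fish_fixture(cfg, seed=2)
        assert not a["Nanog"].equals(b["Nanog"])

    def test_constant_zero_distribution_gives_identical_zero_rows(self):
        cfg = _single_class_config(GeneDistSpec("constant", 0.0))
        table = generate_fish_fixture(cfg)
        assert len(table) == 10
        assert (table["G"] == 0).all()

    def test_guard_margin_keeps_counts_on_class_side_of_cutoff(self):
        """Brute-force scan: every guarded count strictly on its class's side."""
        cfg = fixtures.load_fixture_config("fig4a")
        table = generate_fish_fixture(cfg)
        for cls in cfg.classes:
            sub = table[table["cell_class"] == cls.class_name]
            for gene, spec in cls.per_gene_dist.items():
                guard = spec.guard
                if guard.side == "+":
                    assert sub[gene].min() >= guard.cutoff * (1 + cls.guard_margin)
                else:
                    assert sub[gene].max() < guard.cutoff * (1 - cls.guard_margin)

    @pytest.mark.parametrize("name", ["fig4a", "fig4b", "fig4c"])
    def test_classification_recovers_latent_labels_exactly(self, name):
        """Guarded fixtures: threshold calls reproduce the latent class."""
        cfg = fixtures.load_fixture_config(name)
        table = generate_fish_fixture(cfg)
        labels = classify_cells(table, fixtures.CUTOFFS[name])
        for cls in cfg.classes:
            mask = (table["cell_class"] == cls.class_name).to_numpy()
            for gene, spec in cls.per_gene_dist.items():
                want_positive = spec.guard.side == "+"
                got = labels.positive(gene).to_numpy()[mask]
                assert (got == want_positive).all()

    def test_unknown_family_rejected(self):
        with pytest.raises(ConfigError, match="family"):
            GeneDistSpec("gamma", 10.0)

    def test_gene_missing_from_class_distributions_rejected(self):
        cls = CellClassSpec("c", 5, {"A": GeneDistSpec("constant", 1.0)})
        with pytest.raises(ConfigError, match="lacks distributions"):
            FixtureConfig(classes=(cls,), seed=0, genes=("A", "B"))

    def test_impossible_guard_raises_config_error(self):
        dist = GeneDistSpec("constant", 5.0, guard=GuardSpec(cutoff=30, side="+"))
        cfg = _single_class_config(dist)
        with pytest.raises(ConfigError, match="guard"):
            generate_fish_fixture(cfg)


class TestReporterTable:
    def _base(self, n_pos, n_neg, seed=11):
        pos = CellClassSpec(
            "NanogPos", n_pos,
            {"Nanog": GeneDistSpec("lognormal-rounded", 300, 0.4,
                                   GuardSpec(30, "+")),
             "VNP": GeneDistSpec("lognormal-rounded", 150, 0.4,
                                 GuardSpec(30, "+"))},
            guard_margin=0.1,
        )
        neg = CellClassSpec(
            "NanogNeg", n_neg,
            {"Nanog": GeneDistSpec("negative-binomial", 5, 0.5, GuardSpec(30, "-")),
             "VNP": GeneDistSpec("negative-binomial", 5, 0.5, GuardSpec(30, "-"))},
            guard_margin=0.1,
        )
        return FixtureConfig(classes=(pos, neg), seed=seed, genes=("Nanog", "VNP"))

    def test_zero_infidelity_means_reporter_matches_mrna(self):
        cfg = ReporterConfig(fn_fraction=0.0, n_cells=200, base_classes=self._base(150, 50))
        table = generate_reporter_table(cfg)
        labels = classify_cells(table, fixtures.CUTOFFS["reporter"])
        assert labels.positive("Nanog").equals(labels.positive("VNP"))
        assert not table["reporter_false_negative"].any()

    def test_total_infidelity_makes_every_positive_cell_reporter_negative(self):
        cfg = ReporterConfig(fn_fraction=1.0, n_cells=100, base_classes=self._base(100, 0))
        table = generate_reporter_table(cfg)
        labels = classify_cells(table, fixtures.CUTOFFS["reporter"])
        assert labels.positive("Nanog").all()
        assert (~labels.positive("VNP")).all()

    def test_false_negatives_keep_positive_mrna_distribution(self):
        """Suppressing the reporter must leave Nanog counts untouched."""
        cfg = ReporterConfig(fn_fraction=0.5, n_cells=400, base_classes=self._base(300, 100))
        table = generate_reporter_table(cfg)
        fn = table[table["reporter_false_negative"]]
        assert (fn["Nanog"] >= 30).all()
        assert (fn["VNP"] < 30).all()

    def test_half_infidelity_fraction_within_binomial_interval(self):
        """Empirical P(Nanog+ | VNP-) lies in the 99% binomial band of the
        config-implied value (fn=0.5 example at n=2000)."""
        cfg = ReporterConfig(fn_fraction=0.5, n_cells=2000,
                             base_classes=self._base(1500, 500, seed=17))
        table = generate_reporter_table(cfg)
        labels = classify_cells(table, fixtures.CUTOFFS["reporter"])
        vnp_neg = labels.negative("VNP").to_numpy()
        nanog_pos = labels.positive("Nanog").to_numpy()
        n_vneg = int(vnp_neg.sum())
        k = int((vnp_neg & nanog_pos).sum())
        p_implied = cfg.implied_fn_among_reporter_negative
        lo, hi = stats.binom.interval(0.99, n_vneg, p_implied)
        assert lo <= k <= hi

    def test_fn_fraction_out_of_range_rejected(self):
        with pytest.raises(ConfigError, match="fn_fraction"):
            ReporterConfig(fn_fraction=1.5, n_cells=200, base_classes=self._base(150, 50))


class TestBulkCounts:
    def test_poisson_limit_variance_matches_mean(self):
        cfg = BulkCountConfig(n_genes=50, replicates_per_condition=200,
                              baseline_mean=100.0, dispersion=0.0, seed=3)
        counts, _ = generate_bulk_counts(cfg)
        samples = counts.filter(like="A_").to_numpy()
        ratio = samples.var(axis=1, ddof=1).mean() / samples.mean()
        assert ratio == pytest.approx(1.0, rel=0.1)

    def test_nb_moments_match_mean_and_dispersion(self):
        """Var = mu + alpha mu^2 at mu=100, alpha=0.1, 10^4 draws, 10% tol."""
        cfg = BulkCountConfig(n_genes=2, replicates_per_condition=10_000,
                              baseline_mean=100.0, dispersion=0.1, seed=4)
        counts, _ = generate_bulk_counts(cfg)
        draws = counts.filter(like="A_").to_numpy()[0]
        assert draws.mean() == pytest.approx(100.0, rel=0.1)
        assert draws.var(ddof=1) == pytest.approx(100 + 0.1 * 100**2, rel=0.1)

    def test_planted_genes_shift_condition_two_mean(self):
        cfg = BulkCountConfig(n_genes=400, replicates_per_condition=50,
                              baseline_mean=100.0, dispersion=0.02,
                              de_fraction=0.25, planted_log2fc=2.0, seed=5)
        counts, truth = generate_bulk_counts(cfg)
        assert len(truth) == 100
        planted = counts.loc[truth["gene"]]
        ratio = (planted.filter(like="B_").to_numpy().mean()
                 / planted.filter(like="A_").to_numpy().mean())
        assert ratio == pytest.approx(4.0, rel=0.05)

    def test_no_planted_fraction_gives_empty_truth(self):
        cfg = BulkCountConfig(n_genes=20, de_fraction=0.0, seed=6)
        _, truth = generate_bulk_counts(cfg)
        assert truth.empty

    def test_too_few_replicates_rejected(self):
        with pytest.raises(ConfigError, match="replicates"):
            BulkCountConfig(n_genes=10, replicates_per_condition=1)


class TestGoUniverse:
    def test_root_annotates_every_gene(self):
        cats, root, _ = generate_go_universe(
            GoUniverseConfig(n_genes=100, n_categories=4, seed=8))
        universe = set().union(*cats.values())
        assert cats[root] == universe

    def test_zero_overlap_gives_pairwise_disjoint_categories(self):
        cats, root, _ = generate_go_universe(
            GoUniverseConfig(n_genes=200, n_categories=6, overlap_rate=0.0, seed=9))
        names = [c for c in cats if c != root]
        for i, a in enumerate(names):
            for b in names[i + 1:]:
                assert not (cats[a] & cats[b])

    def test_planted_concentration_is_exact(self):
        cfg = GoUniverseConfig(n_genes=300, n_categories=5, size_range=(20, 20),
                               planted=((1, 0.9),), background_rate=0.0, seed=10)
        cats, _, interest = generate_go_universe(cfg)
        planted = cats["GO:0000001"]
        assert len(planted & interest) == 18  # 0.9 * 20

    def test_seed_determinism(self):
        cfg = GoUniverseConfig(n_genes=150, n_categories=5, planted=((0, 0.5),), seed=12)
        a = generate_go_universe(cfg)
        b = generate_go_universe(cfg)
        assert a == b

    def test_infeasible_planting_rejected(self):
        with pytest.raises(ConfigError):
            GoUniverseConfig(n_genes=100, n_categories=2, planted=((0, 1.5),))
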