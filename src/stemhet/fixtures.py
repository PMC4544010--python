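"""Shipped fixture configs encoding the printed single-cell experiments.

Four YAML configs live under ``stemhet/configs``:

* ``fig4a.yaml`` — 1189 cells, genes Nanog/Oct4, composition 1129 / 16 / 44
  (Nanog+Oct4+, Nanog-Oct4+, Nanog-Oct4-); cutoffs 30 and 80 transcripts.
* ``fig4b.yaml`` — 2360 cells, genes Nanog/Crabp2/T; exactly two cells
  positive for both lineage markers Crabp2 (cutoff 30) and T (cutoff 50).
* ``fig4c.yaml`` — 764 cells, genes Tbx6/T/Oct4; two Tbx6(+) cells (cutoff
  10) nested inside the seven T(+) cells (cutoff 50).
* ``reporter.yaml`` — 2000 cells with paired Nanog mRNA and Nanog:VNP
  reporter counts; the class mix implies that half of the reporter-negative
  cells are truly Nanog-positive.

All class compositions are stratified-exact and all distributions are
guarded, so threshold classification recovers the latent labels exactly;
the compositions are data, the distribution families are plumbing.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import yaml

from .fish_hierarchy import ThresholdScheme
from .synthetic_data import FixtureConfig, ReporterConfig

__all__ = [
    "fixture_names",
    "fixture_config_path",
    "load_fixture_dict",
    "load_fixture_config",
    "load_reporter_config",
    "CUTOFFS",
]

# Positivity cutoffs (transcripts per cell) used by each fixture's markers.
CUTOFFS: dict[str, ThresholdScheme] = {
    "fig4a": ThresholdScheme({"Nanog": 30, "Oct4": 80}),
    "fig4b": ThresholdScheme({"Nanog": 30, "Crabp2": 30, "T": 50}),
    "fig4c": ThresholdScheme({"Tbx6": 10, "T": 50, "Oct4": 80}),
    "reporter": ThresholdScheme({"Nanog": 30, "VNP": 30}),
}


def fixture_names() -> tuple[str, ...]:
    return ("fig4a", "fig4b", "fig4c", "reporter")


def fixture_config_path(name: str) -> Path:
    """Filesystem path of a shipped fixture config."""
    if name not in fixture_names():
        raise KeyError(f"unknown fixture {name!r}; choose from {fixture_names()}")
    return Path(str(resources.files("stemhet") / "configs" / f"{name}.yaml"))


def load_fixture_dict(name: str) -> dict:
    with fixture_config_path(name).open("r", encoding="utf-8") as fh:
        return yaml.safe_load(fh)


def load_fixture_config(name: str) -> FixtureConfig:
    """Load one of the cell-class fixtures (fig4a, fig4b, fig4c)."""
    return FixtureConfig.from_dict(load_fixture_dict(name))


def load_reporter_config() -> ReporterConfig:
    return ReporterConfig.from_dict(load_fixture_dict("reporter"))
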