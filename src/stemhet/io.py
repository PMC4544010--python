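"""Readers and writers for the TSV/GMT dialects used across the package.

All tables are UTF-8, tab-separated, Unix newlines.  Gene and cell ids are
opaque case-sensitive strings.  Readers validate and reject malformed input
(naming the offending line) rather than coercing; writers round-trip.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import InputError, ParseError

__all__ = [
    "read_count_table",
    "write_count_table",
    "read_gmt",
    "write_gmt",
    "read_annotations",
    "read_gene_list",
    "read_time_course",
    "write_time_course",
    "load_config",
    "RunManifest",
    "write_manifest",
]


def read_count_table(path: str | Path) -> pd.DataFrame:
    """Read a per-cell count table (or gene x sample matrix) from TSV.

    Per-cell dialect: header ``cell_id<TAB>[cell_class<TAB>]<gene1>...`` and
    one row per cell.  Gene-by-sample dialect: first column named ``gene``.
    Count cells must be non-negative integers; violations raise
    :class:`ParseError` naming the line; duplicate ids raise
    :class:`InputError`.
    """
    path = Path(path)
    with path.open("r", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n")
        if not header:
            raise ParseError(f"{path}: empty file")
        cols = header.split("\t")
        id_col = cols[0]
        if id_col not in ("cell_id", "gene"):
            raise ParseError(
                f"{path}: first column must be 'cell_id' or 'gene', got {id_col!r}"
            )
        meta_cols = {"cell_class", "reporter_false_negative"}
        rows = []
        ids = []
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != len(cols):
                raise ParseError(
                    f"{path}:{lineno}: expected {len(cols)} fields, got {len(fields)}"
                )
            row = {}
            for name, value in zip(cols, fields):
                if name == id_col or name in meta_cols:
                    row[name] = value
                else:
                    try:
                        count = int(value)
                    except ValueError:
                        raise ParseError(
                            f"{path}:{lineno}: non-integer count {value!r} "
                            f"in column {name!r}"
                        ) from None
                    if count < 0:
                        raise ParseError(
                            f"{path}:{lineno}: negative count {count} "
                            f"in column {name!r}"
                        )
                    row[name] = count
            ids.append(fields[0])
            rows.append(row)
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise InputError(f"{path}: duplicate ids {dupes[:5]}")
    df = pd.DataFrame(rows, columns=cols)
    if "reporter_false_negative" in df.columns:
        df["reporter_false_negative"] = df["reporter_false_negative"] == "True"
    if id_col == "gene":
        df = df.set_index("gene")
    return df


def write_count_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write a count table in the TSV dialect read by :func:`read_count_table`."""
    path = Path(path)
    if table.index.name == "gene":
        table.to_csv(path, sep="\t", lineterminator="\n")
    else:
        table.to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Read GMT gene sets: ``name<TAB>description<TAB>gene1<TAB>...`` per line."""
    path = Path(path)
    sets: dict[str, set[str]] = {}
    with path.open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"{path}:{lineno}: GMT line has no genes "
                    f"(need name, description, >=1 gene)"
                )
            name = fields[0]
            if name in sets:
                raise InputError(f"{path}:{lineno}: duplicate set name {name!r}")
            sets[name] = set(fields[2:])
    return sets


def write_gmt(sets: dict[str, set[str]], path: str | Path,
              description: str = "stemhet") -> None:
    with Path(path).open("w", encoding="utf-8", newline="\n") as fh:
        for name in sets:
            genes = sorted(sets[name])
            fh.write("\t".join([name, description, *genes]) + "\n")


def read_annotations(path: str | Path) -> dict[str, set[str]]:
    """Read two-column (gene, category) TSV annotations into category -> genes."""
    path = Path(path)
    out: dict[str, set[str]] = {}
    with path.open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ParseError(
                    f"{path}:{lineno}: expected two tab-separated columns"
                )
            gene, cat = fields
            out.setdefault(cat, set()).add(gene)
    return out


def read_gene_list(path: str | Path) -> set[str]:
    """One gene per line; blank lines and '#' comments ignored."""
    genes = set()
    with Path(path).open("r", encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                genes.add(line)
    return genes


def read_time_course(path: str | Path):
    """TSV with columns time, fraction_positive[, n_cells]."""
    from .state_dynamics import TimeCourse

    df = pd.read_csv(path, sep="\t")
    for col in ("time", "fraction_positive"):
        if col not in df.columns:
            raise ParseError(f"{path}: missing column {col!r}")
    size = df["n_cells"].to_numpy(float) if "n_cells" in df.columns else None
    return TimeCourse(
        times=df["time"].to_numpy(float),
        fraction_positive=df["fraction_positive"].to_numpy(float),
        population_size=size,
    )


def write_time_course(tc, path: str | Path) -> None:
    data = {"time": tc.times, "fraction_positive": tc.fraction_positive}
    if tc.population_size is not None:
        data["n_cells"] = tc.population_size
    pd.DataFrame(data).to_csv(path, sep="\t", index=False, lineterminator="\n")


def load_config(path: str | Path) -> dict:
    """Load a YAML (or JSON, a YAML subset) config file into a dict."""
    with Path(path).open("r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ParseError(f"{path}: config must be a mapping")
    return data


def config_hash(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


@dataclass(frozen=True)
class RunManifest:
    """Provenance record emitted once per CLI run."""

    command: str
    config_hash: str | None
    seed: int | None
    inputs: tuple[str, ...]
    outputs: tuple[str, ...]
    package_version: str
    timestamp: str


def write_manifest(manifest: RunManifest, path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8", newline="\n") as fh:
        json.dump(asdict(manifest), fh, indent=2)
        fh.write("\n")


def make_manifest(command: str, *, config: str | Path | None = None,
                  seed: int | None = None, inputs=(), outputs=()) -> RunManifest:
    from . import __version__

    return RunManifest(
        command=command,
        config_hash=config_hash(config) if config else None,
        seed=seed,
        inputs=tuple(str(p) for p in inputs),
        outputs=tuple(str(p) for p in outputs),
        package_version=__version__,
        timestamp=time.strftime("%Y-%m-%dT%H:%M:%S%z"),
    )
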