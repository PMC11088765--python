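"""Readers and writers for the pipeline's tab-separated tables and GMT sets.

All tables are TSV with header rows (schemas in docs/formats.md); gene sets
use the standard GMT dialect (name, description, then genes, tab-separated);
configuration files are YAML.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

from .ligand_activity import DEG_COLUMNS

__all__ = [
    "read_deg_table",
    "write_deg_table",
    "read_deg_tables",
    "write_deg_tables",
    "read_gmt",
    "write_gmt",
    "load_config",
]


def read_deg_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(DEG_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"DEG table {path} lacks columns: {sorted(missing)}")
    return df[DEG_COLUMNS]


def write_deg_table(df: pd.DataFrame, path) -> None:
    df[DEG_COLUMNS].to_csv(path, sep="\t", index=False)


def read_deg_tables(directory) -> dict[str, pd.DataFrame]:
    """Read every ``deg_*.tsv`` in a directory, keyed by cancer label."""
    out: dict[str, pd.DataFrame] = {}
    for path in sorted(Path(directory).glob("deg_*.tsv")):
        df = read_deg_table(path)
        for cancer, sub in df.groupby("cancer"):
            out[cancer] = sub.reset_index(drop=True)
    return out


def write_deg_tables(tables: Mapping[str, pd.DataFrame], directory) -> list[Path]:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for cancer in sorted(tables):
        p = directory / f"deg_{cancer}.tsv"
        write_deg_table(tables[cancer], p)
        paths.append(p)
    return paths


def read_gmt(path) -> dict[str, list[str]]:
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                continue
            sets[fields[0]] = [g for g in fields[2:] if g]
    return sets


def write_gmt(sets: Mapping[str, list[str]], path) -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, ""] + list(genes)) + "\n")


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"config {path} must be a YAML mapping")
    return cfg
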