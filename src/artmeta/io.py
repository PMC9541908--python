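"""Readers and writers for the delimited interchange formats.

Effect-size tables are comma-separated UTF-8 with a fixed header
(:data:`artmeta.meta.EFFECT_COLUMNS`); missing moderators are empty fields.
Allometry tables are one CSV per study with columns individual_id, tactic,
body_mass, testes_mass.  Trees are Newick.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .allometry import AllometryTable
from .meta import EFFECT_COLUMNS, MetaDataset
from .phylo import read_tree

__all__ = [
    "read_effects_table",
    "write_effects_table",
    "read_allometry_table",
    "read_allometry_dir",
    "load_dataset",
]

_NUMERIC = {"d": float, "var": float, "sneaker_freq": float, "pub_year": float}


def read_effects_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = set(EFFECT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"effects table {path} missing columns: {sorted(missing)}")
    for col, typ in _NUMERIC.items():
        df[col] = pd.to_numeric(df[col].replace({"": None, "nan": None}), errors="raise")
    df["directionless"] = df["directionless"].str.lower().isin(("true", "1", "yes"))
    return df[EFFECT_COLUMNS]


def write_effects_table(df: pd.DataFrame, path) -> None:
    df[EFFECT_COLUMNS].to_csv(path, index=False)


def read_allometry_table(path, study_id: str | None = None, species: str = "") -> AllometryTable:
    data = pd.read_csv(path)
    sid = study_id or Path(path).stem
    return AllometryTable(data, study_id=sid, species=species)


def read_allometry_dir(directory) -> list[AllometryTable]:
    tables = []
    for path in sorted(Path(directory).glob("*.csv")):
        tables.append(read_allometry_table(path))
    if not tables:
        raise ValueError(f"no allometry tables (*.csv) found in {directory}")
    return tables


def load_dataset(effects_path, tree_path=None, rho: float = 0.5) -> MetaDataset:
    """Bind an effects table and an optional Newick tree into a MetaDataset."""
    effects = read_effects_table(effects_path)
    tree = read_tree(str(tree_path)) if tree_path else None
    return MetaDataset(effects, tree=tree, rho=rho)
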