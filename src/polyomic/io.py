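"""TSV / GMT / manifest readers and writers.

All tabular artifacts are plain tab-separated text with a header row.
Expression matrices are written features x samples with the index column
named ``feature_id``; sample groups as a two-column table
(``sample_id``, ``group``).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .errors import DataError


def write_matrix(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index_label="feature_id")


def read_matrix(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.duplicated().any():
        raise DataError(f"duplicated feature ids in {path}")
    return df


def write_groups(groups: pd.Series, path: str | Path) -> None:
    groups.rename_axis("sample_id").rename("group").to_csv(path, sep="\t")


def read_groups(path: str | Path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.iloc[:, 0].astype(str)


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


# -- GMT ----------------------------------------------------------------
# Broad's GMT: one set per line -- id, description, then member ids, all
# tab-separated.  No installed library parses it, so the (trivial) parser
# lives here.

def write_gmt(sets: Mapping[str, tuple[str, Iterable[str]]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for set_id, (name, members) in sets.items():
            fh.write("\t".join([set_id, name, *sorted(members)]) + "\n")


def read_gmt(path: str | Path) -> dict[str, tuple[str, frozenset[str]]]:
    out: dict[str, tuple[str, frozenset[str]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise DataError(f"{path}:{lineno}: GMT line needs id, name and >=1 member")
            out[parts[0]] = (parts[1], frozenset(parts[2:]))
    return out


def write_manifest(entries: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(entries, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_manifest(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)
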