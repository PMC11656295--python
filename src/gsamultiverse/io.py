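"""Readers and writers for the plain-text interchange formats.

Count matrices, labels and ID tables are tab-delimited; gene set databases
use GMT (set name, description, then member IDs, tab-separated).  All
functions round-trip with their counterpart.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .datasets import GeneSetDatabase, IdConversionTable, LabelAssignment

__all__ = [
    "read_counts",
    "write_counts",
    "read_labels",
    "write_labels",
    "read_gmt",
    "write_gmt",
    "read_id_table",
    "write_id_table",
]


def read_counts(path: str | Path) -> pd.DataFrame:
    """Tab-delimited counts: first column gene ID, header row sample IDs."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        raise ValueError(f"duplicate gene IDs in {path}")
    if (df.values < 0).any():
        raise ValueError(f"negative counts in {path}")
    return df.astype("int64")


def write_counts(counts: pd.DataFrame, path: str | Path) -> None:
    counts.to_csv(path, sep="\t", index_label="gene_id")


def read_labels(path: str | Path, reference: str | None = None) -> LabelAssignment:
    """Two-column tab-delimited (sample ID, condition).

    The reference level defaults to the condition of the first row.
    """
    df = pd.read_csv(path, sep="\t", header=None, names=["sample_id", "condition"], dtype=str)
    ref = reference if reference is not None else df["condition"].iloc[0]
    return LabelAssignment(
        sample_ids=tuple(df["sample_id"]),
        labels=tuple(df["condition"]),
        reference=ref,
        origin="true",
    )


def write_labels(labels: LabelAssignment, path: str | Path) -> None:
    with open(path, "w") as fh:
        for sid, lab in zip(labels.sample_ids, labels.labels):
            fh.write(f"{sid}\t{lab}\n")


def read_gmt(path: str | Path, name: str | None = None) -> GeneSetDatabase:
    sets: dict[str, tuple[str, ...]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"malformed GMT line (need >=3 fields): {line[:80]!r}")
            set_name, _description, *members = fields
            members = [m for m in members if m]
            sets[set_name] = tuple(members)
    return GeneSetDatabase(name=name or Path(path).stem, sets=sets)


def write_gmt(db: GeneSetDatabase, path: str | Path) -> None:
    with open(path, "w") as fh:
        for set_name, members in db.sets.items():
            fh.write("\t".join([set_name, db.name, *members]) + "\n")


def read_id_table(path: str | Path) -> IdConversionTable:
    """Two-column tab-delimited (source ID, target ID); sources unique."""
    df = pd.read_csv(path, sep="\t", header=None, names=["source", "target"], dtype=str)
    if df["source"].duplicated().any():
        dup = df["source"][df["source"].duplicated()].iloc[0]
        raise ValueError(f"source ID appears more than once: {dup!r}")
    return IdConversionTable(mapping=dict(zip(df["source"], df["target"])))


def write_id_table(table: IdConversionTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        for src, tgt in table.mapping.items():
            fh.write(f"{src}\t{tgt}\n")
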