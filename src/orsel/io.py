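"""Tabular file formats shared by the CLI stages (all plain TSV)."""

from __future__ import annotations

import pandas as pd

from .errors import FormatError
from .selection_enrichment import RECORD_COLUMNS, TransitionSet, records_from_frame

GENE_TREES_COLUMNS = ["dataset_id", "gene_tree_id", "newick"]
MAP_COLUMNS = ["dataset_id", "gene_tree_id", "gene_branch_id",
               "species_branch_id", "event", "branch_length"]


def read_tsv(path, required=None) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if required:
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise FormatError(f"{path}: missing columns {missing}")
    return df


def write_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_branch_tests(path) -> pd.DataFrame:
    return records_from_frame(read_tsv(path, RECORD_COLUMNS))


def read_gene_trees_table(path) -> pd.DataFrame:
    return read_tsv(path, GENE_TREES_COLUMNS)


def read_transitions(path) -> list[TransitionSet]:
    df = read_tsv(path, ["label", "dataset_id", "species_branch_id"])
    out = []
    for label, grp in df.groupby("label", sort=True):
        members = [(str(r.dataset_id), _branch_id(r.species_branch_id))
                   for r in grp.itertuples()]
        out.append(TransitionSet(label=str(label), members=members))
    return out


def write_transitions(transitions: list[TransitionSet], path) -> None:
    rows = [{"label": t.label, "dataset_id": d, "species_branch_id": b}
            for t in transitions for d, b in t.members]
    write_tsv(pd.DataFrame(rows, columns=["label", "dataset_id", "species_branch_id"]), path)


def read_counts(path) -> pd.DataFrame:
    df = read_tsv(path)
    if df.columns[0] != "species":
        raise FormatError(f"{path}: first column must be 'species'")
    df = df.set_index("species")
    if (df < 0).any().any() or not all(df.dtypes.apply(pd.api.types.is_integer_dtype)):
        raise FormatError(f"{path}: counts must be nonnegative integers")
    return df


def read_traits(path) -> pd.DataFrame:
    df = read_tsv(path)
    if df.columns[0] != "species":
        raise FormatError(f"{path}: first column must be 'species'")
    return df.set_index("species")


def _branch_id(x):
    """Species branch ids are integers except the synthetic 'root'."""
    s = str(x)
    return s if s == "root" else int(x)
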