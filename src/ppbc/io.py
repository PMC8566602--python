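"""Readers and writers for the plain-text formats the pipeline exchanges.

Counts are genes x samples TSV (first column = gene symbol, header row =
sample IDs); metadata is CSV keyed on ``sample_id``; gene sets use standard
GMT (name, description, members, tab-separated); regulon networks are long
TSV (tf, target, mode, likelihood); clonotype tables use AIRR-compatible
column names (sample_id, clonotype_key, duplicate_count); score tables are
long TSV (sample_id, score_name, value).
"""

from __future__ import annotations

import pandas as pd

from .enrichment import GeneSet
from .regulon import Regulon


def read_counts(path) -> pd.DataFrame:
    """Read a genes x samples integer count matrix from TSV."""
    counts = pd.read_csv(path, sep="\t", index_col=0)
    counts.index.name = "gene"
    counts.columns.name = "sample_id"
    return counts


def write_counts(counts: pd.DataFrame, path) -> None:
    counts.to_csv(path, sep="\t", index_label="gene")


def read_meta(path) -> pd.DataFrame:
    return pd.read_csv(path).set_index("sample_id")


def write_meta(meta: pd.DataFrame, path) -> None:
    meta.to_csv(path, index_label="sample_id")


def read_gmt(path) -> list[GeneSet]:
    """Parse a GMT file: one set per line, ``name TAB description TAB genes...``."""
    sets = []
    with open(path) as fh:
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3 or not fields[0]:
                continue
            sets.append(GeneSet(name=fields[0], members=frozenset(g for g in fields[2:] if g)))
    return sets


def write_gmt(gene_sets, path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for gs in gene_sets:
            fh.write("\t".join([gs.name, description, *sorted(gs.members)]) + "\n")


def read_regulons(path) -> list[Regulon]:
    """Read a long-format regulon network TSV (tf, target, mode, likelihood)."""
    table = pd.read_csv(path, sep="\t")
    return [
        Regulon(tf=tf, targets=sub[["target", "mode", "likelihood"]].reset_index(drop=True))
        for tf, sub in table.groupby("tf", sort=True)
    ]


def write_regulons(regulons, path) -> None:
    rows = []
    for reg in regulons:
        sub = reg.targets.copy()
        sub.insert(0, "tf", reg.tf)
        rows.append(sub)
    pd.concat(rows, ignore_index=True).to_csv(path, sep="\t", index=False)


def read_clonotypes(path) -> pd.DataFrame:
    """Read a clonotype table; accepts ``duplicate_count`` or ``count``."""
    table = pd.read_csv(path, sep="\t")
    if "duplicate_count" not in table.columns and "count" in table.columns:
        table = table.rename(columns={"count": "duplicate_count"})
    return table[["sample_id", "clonotype_key", "duplicate_count"]]


def write_clonotypes(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_scores(path) -> pd.DataFrame:
    """Read a long score TSV into a wide samples x score-name frame."""
    long = pd.read_csv(path, sep="\t")
    return long.pivot(index="sample_id", columns="score_name", values="value")


def write_scores(scores: pd.DataFrame, path) -> None:
    long = scores.rename_axis("sample_id").reset_index().melt(
        id_vars="sample_id", var_name="score_name", value_name="value"
    )
    long.to_csv(path, sep="\t", index=False)
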