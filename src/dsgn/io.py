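"""Readers and writers for the pipeline's plain-text formats.

Matrices are TSV with a header row of cell-line ids and the entity id as the
first column; graphs are 2-column TSV edge lists or SIF; gene-set
collections are GMT (name, description, tab-separated members); annotation
labels are 2-column (id, label) TSV with repeated rows for multi-label.
All files are UTF-8 with header rows, identifiers are opaque strings.
"""

from __future__ import annotations

import logging
from pathlib import Path

import networkx as nx
import pandas as pd

from .screen import CorrelationRecord

logger = logging.getLogger(__name__)


def read_matrix(path: str | Path) -> pd.DataFrame:
    """Entity-by-cell-line TSV matrix (first column = entity id)."""
    return pd.read_csv(path, sep="\t", index_col=0)


def write_matrix(df: pd.DataFrame, path: str | Path, index_name: str = "id") -> None:
    df = df.rename_axis(index_name)
    df.to_csv(path, sep="\t")


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """GMT gene-set collection: name, description, then members.

    Duplicate members collapse; a line with fewer than 3 fields, or a set
    with no members, is an error naming the line.
    """
    collection: dict[str, set[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line needs >= 3 tab-separated fields, got {len(fields)}")
            name = fields[0]
            members = {m for m in fields[2:] if m}
            if not members:
                raise ValueError(f"{path}:{lineno}: gene set {name!r} has no members")
            collection[name] = members
    return collection


def write_gmt(collection: dict[str, set[str]], path: str | Path, description: str = "na") -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name in sorted(collection):
            members = "\t".join(sorted(collection[name]))
            fh.write(f"{name}\t{description}\t{members}\n")


def read_edge_list(path: str | Path, format: str = "tsv") -> nx.Graph:
    """Simple undirected graph from a 2-column TSV or a SIF file.

    Self-loops are dropped with a logged count; malformed lines are errors
    naming the line number.
    """
    if format not in ("tsv", "sif"):
        raise ValueError(f"format must be 'tsv' or 'sif', got {format!r}")
    g = nx.Graph()
    dropped = 0
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if format == "tsv":
                if len(fields) != 2:
                    raise ValueError(f"{path}:{lineno}: expected 2 tab-separated columns, got {len(fields)}")
                pairs = [(fields[0], fields[1])]
            else:
                if len(fields) < 3:
                    raise ValueError(f"{path}:{lineno}: SIF line needs >= 3 fields (node, relation, node...), got {len(fields)}")
                pairs = [(fields[0], t) for t in fields[2:]]
            for u, v in pairs:
                if not u or not v:
                    raise ValueError(f"{path}:{lineno}: empty node identifier")
                if u == v:
                    dropped += 1
                    continue
                g.add_edge(u, v)
    if dropped:
        logger.info("read_edge_list: dropped %d self-loop(s) from %s", dropped, path)
    return g


def write_edge_list(g: nx.Graph, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for u, v in sorted(tuple(sorted(e)) for e in g.edges):
            fh.write(f"{u}\t{v}\n")


def read_labels(path: str | Path) -> dict[str, set[str]]:
    """2-column (id, label) TSV with a header; repeated ids accumulate labels."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] != 2:
        raise ValueError(f"{path}: expected 2 columns (id, label), got {df.shape[1]}")
    out: dict[str, set[str]] = {}
    for ident, label in df.itertuples(index=False):
        out.setdefault(str(ident), set()).add(str(label))
    return out


def write_labels(labels: dict[str, set[str]], path: str | Path, columns: tuple[str, str] = ("id", "label")) -> None:
    rows = [(i, l) for i in sorted(labels) for l in sorted(labels[i])]
    pd.DataFrame(rows, columns=list(columns)).to_csv(path, sep="\t", index=False)


def read_records(path: str | Path) -> list[CorrelationRecord]:
    """CorrelationRecord table: drug_id, gene_id, pcc, p_value, n_obs."""
    df = pd.read_csv(path, sep="\t")
    return [
        CorrelationRecord(str(r.drug_id), str(r.gene_id), float(r.pcc), float(r.p_value), int(r.n_obs))
        for r in df.itertuples(index=False)
    ]


def write_records(records: list[CorrelationRecord], path: str | Path) -> None:
    pd.DataFrame(
        [(r.drug_id, r.gene_id, r.pcc, r.p_value, r.n_obs) for r in records],
        columns=["drug_id", "gene_id", "pcc", "p_value", "n_obs"],
    ).to_csv(path, sep="\t", index=False)


def read_gene_list(path: str | Path) -> set[str]:
    """One gene id per line."""
    with open(path, encoding="utf-8") as fh:
        return {line.strip() for line in fh if line.strip()}


def read_bipartite_pairs(path: str | Path) -> list[tuple[str, str]]:
    """2-column (drug, gene) TSV with a header row."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] != 2:
        raise ValueError(f"{path}: expected 2 columns (drug, gene), got {df.shape[1]}")
    return [(str(d), str(g)) for d, g in df.itertuples(index=False)]


def write_bipartite_pairs(pairs, path: str | Path) -> None:
    pd.DataFrame(sorted(pairs), columns=["drug", "gene"]).to_csv(path, sep="\t", index=False)
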