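"""Readers and writers for the plain-text formats used throughout.

All tables are TSV; gene sets use the GMT convention (term, description,
members...); networks are additionally exported as SIF for Cytoscape import.
"""

from __future__ import annotations

import os

import pandas as pd

from .containers import ConfigurationError, CountMatrix, ExpressionMatrix


def read_counts(counts_path: str, samples_path: str) -> CountMatrix:
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    counts.index.name = "gene_id"
    samples = read_sample_sheet(samples_path)
    return CountMatrix(counts=counts.astype(int), samples=samples)


def read_sample_sheet(path: str) -> pd.DataFrame:
    samples = pd.read_csv(path, sep="\t", index_col=0)
    samples.index = samples.index.astype(str)
    if "condition" not in samples.columns:
        raise ConfigurationError(f"{path}: sample sheet needs a 'condition' column")
    return samples


def read_expression(expr_path: str, samples_path: str) -> ExpressionMatrix:
    values = pd.read_csv(expr_path, sep="\t", index_col=0)
    values.index.name = "gene_id"
    return ExpressionMatrix(values=values, samples=read_sample_sheet(samples_path))


def write_matrix(df: pd.DataFrame, path: str, index_label: str = "gene_id") -> None:
    df.to_csv(path, sep="\t", index_label=index_label)


def write_table(df: pd.DataFrame, path: str) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_gene_list(path: str) -> list[str]:
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


def write_gene_list(genes, path: str) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g}\n")


def read_gmt(path: str) -> dict[str, tuple[str, set[str]]]:
    """Parse a GMT file into term_id -> (description, member set)."""
    sets: dict[str, tuple[str, set[str]]] = {}
    with open(path) as fh:
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3 or not fields[0]:
                continue
            members = {g for g in fields[2:] if g}
            if not members:
                continue
            sets[fields[0]] = (fields[1], members)
    if not sets:
        raise ConfigurationError(f"{path}: no gene sets parsed")
    return sets


def write_gmt(sets: dict[str, tuple[str, set[str]]], path: str) -> None:
    with open(path, "w") as fh:
        for term, (desc, members) in sets.items():
            fh.write("\t".join([term, desc, *sorted(members)]) + "\n")


def write_sif(edges: pd.DataFrame, path: str, interaction: str = "pcit") -> None:
    """Write an edge table (gene_a, gene_b columns) as SIF."""
    with open(path, "w") as fh:
        for a, b in zip(edges["gene_a"], edges["gene_b"]):
            fh.write(f"{a}\t{interaction}\t{b}\n")


def read_edges(path: str) -> pd.DataFrame:
    edges = pd.read_csv(path, sep="\t")
    need = {"gene_a", "gene_b"}
    if not need.issubset(edges.columns):
        raise ConfigurationError(f"{path}: edge table needs columns {sorted(need)}")
    return edges


def ensure_dir(path: str) -> str:
    os.makedirs(path, exist_ok=True)
    return path
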