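"""Readers and writers for the plain-text formats the pipeline consumes.

Formats: one-symbol-per-line gene lists, tab-separated expression matrices
(first column gene symbols, header row of sample ids), STRING-dialect edge
tables (``protein1\\tprotein2\\tcombined_score``), GMT gene-set collections
and sample-annotation tables.
"""

from __future__ import annotations

import csv
from pathlib import Path

import numpy as np
import pandas as pd

from .types import (
    ExpressionMatrix,
    GeneSet,
    GeneSetCollection,
    InteractionNetwork,
    SampleAnnotation,
    normalize_symbol,
)

#: STRING "medium confidence" cutoff; the conventional default.
DEFAULT_MIN_SCORE = 400


def read_gene_list(path: str | Path, name: str | None = None) -> GeneSet:
    """Read a one-symbol-per-line gene list.

    A first line that looks like a header (``gene``, ``symbol``, ...) is
    skipped.  Symbols are uppercased, trimmed and de-duplicated preserving
    first occurrence.
    """
    path = Path(path)
    lines = [ln.strip() for ln in path.read_text().splitlines()]
    lines = [ln for ln in lines if ln]
    if lines and lines[0].lower() in {"gene", "genes", "symbol", "gene_symbol"}:
        lines = lines[1:]
    if not lines:
        raise ValueError(f"empty gene list: {path}")
    return GeneSet(name or path.stem, lines)


def write_gene_list(geneset: GeneSet, path: str | Path) -> None:
    Path(path).write_text("\n".join(geneset.genes) + "\n")


def read_expression_matrix(
    path: str | Path,
    mode: str = "intensity",
    collapse: str = "max_mean",
) -> ExpressionMatrix:
    """Read a genes × samples TSV.

    Duplicate gene rows (multiple probes per symbol) are collapsed by
    ``collapse``: ``"max_mean"`` keeps the row with the largest mean value
    (the conventional probe-collapse rule), ``"error"`` raises.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.isna().any().any():
        raise ValueError(f"ragged or missing values in matrix: {path}")
    df.index = [normalize_symbol(str(g)) for g in df.index]
    if df.index.duplicated().any():
        if collapse == "error":
            raise ValueError(f"duplicate gene rows in {path}")
        if collapse != "max_mean":
            raise ValueError(f"unknown collapse rule {collapse!r}")
        means = df.mean(axis=1)
        order = np.argsort(-means.to_numpy(), kind="stable")
        df = df.iloc[order]
        df = df[~df.index.duplicated(keep="first")]
    if mode == "counts":
        arr = df.to_numpy()
        if not np.allclose(arr, np.round(arr)):
            raise ValueError(f"non-integer values in counts matrix: {path}")
        df = df.round().astype(np.int64)
    return ExpressionMatrix(df, mode=mode)


def write_expression_matrix(matrix: ExpressionMatrix, path: str | Path) -> None:
    matrix.values.to_csv(path, sep="\t", index_label="gene")


def read_sample_annotation(path: str | Path) -> SampleAnnotation:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "age" in df.columns:
        df["age"] = pd.to_numeric(df["age"], errors="coerce").astype("Int64")
    return SampleAnnotation(df)


def write_sample_annotation(annotation: SampleAnnotation, path: str | Path) -> None:
    annotation.table.to_csv(path, sep="\t", index=False)


def read_interaction_tsv(
    path: str | Path, min_score: int = DEFAULT_MIN_SCORE
) -> InteractionNetwork:
    """Read a STRING-export edge table.

    Requires columns ``protein1, protein2, combined_score``.  Edges below
    ``min_score`` are dropped; duplicate/reversed pairs are merged keeping
    the maximum score; self-loops are removed.
    """
    df = pd.read_csv(path, sep="\t")
    required = {"protein1", "protein2", "combined_score"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"interaction table missing columns: {sorted(missing)}")
    df = df[df["combined_score"] >= min_score]
    triples = zip(df["protein1"], df["protein2"], df["combined_score"].astype(float))
    return InteractionNetwork.from_edges(triples)


def write_interaction_tsv(network: InteractionNetwork, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["protein1", "protein2", "combined_score"])
        for a, b, score in network.edges():
            w.writerow([a, b, int(score)])


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file: ``name<TAB>description<TAB>member...`` per line."""
    sets: dict[str, GeneSet] = {}
    descriptions: dict[str, str] = {}
    for i, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        if not raw.strip():
            continue
        fields = raw.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"GMT line {i} has fewer than 3 fields")
        name, desc, *members = fields
        members = [m for m in members if m.strip()]
        if not members:
            raise ValueError(f"GMT line {i} ({name!r}) has no members")
        if name in sets:
            raise ValueError(f"duplicate GMT term {name!r}")
        sets[name] = GeneSet(name, members)
        descriptions[name] = desc
    return GeneSetCollection(sets, descriptions)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name in collection:
            desc = collection.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *collection[name].genes]) + "\n")
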