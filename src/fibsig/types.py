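"""Core domain containers shared by every pipeline stage.

The currency of the pipeline is the :class:`GeneSet` — a named, ordered,
de-duplicated collection of uppercase gene symbols.  Expression data travel
as :class:`ExpressionMatrix` (a genes × samples table in either ``counts``
or ``intensity`` mode), sample metadata as :class:`SampleAnnotation`
(paired ileal/sigmoid biopsies per patient), interaction data as
:class:`InteractionNetwork` (an undirected, score-weighted edge set), and
pathway databases as :class:`GeneSetCollection`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

import networkx as nx
import numpy as np
import pandas as pd

TISSUES = ("ILEAL", "SIGMOID")
CONDITIONS = ("CD", "UC", "CI")
#: Historical alias: control individuals are sometimes labelled HI (healthy).
_CONDITION_ALIASES = {"HI": "CI", "CONTROL": "CI", "HC": "CI"}


def normalize_symbol(symbol: str) -> str:
    """Canonical gene-symbol form: whitespace-trimmed, uppercase."""
    return symbol.strip().upper()


class GeneSet:
    """Named, ordered, duplicate-free collection of gene symbols.

    Symbols are normalized (trimmed, uppercased) on construction; the first
    occurrence wins on duplicates.  Equality is order-independent — two
    GeneSets are equal when they contain the same symbols, regardless of
    name or ordering.
    """

    __slots__ = ("name", "genes", "_set")

    def __init__(self, name: str, genes: Iterable[str]):
        seen: dict[str, None] = {}
        for g in genes:
            s = normalize_symbol(g)
            if not s:
                raise ValueError("empty gene symbol in gene set %r" % name)
            seen.setdefault(s, None)
        self.name = name
        self.genes: tuple[str, ...] = tuple(seen)
        self._set = frozenset(self.genes)

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self) -> Iterator[str]:
        return iter(self.genes)

    def __contains__(self, symbol: object) -> bool:
        return normalize_symbol(str(symbol)) in self._set

    def __eq__(self, other: object) -> bool:
        if isinstance(other, GeneSet):
            return self._set == other._set
        return NotImplemented

    def __hash__(self) -> int:
        return hash(self._set)

    def __repr__(self) -> str:
        return f"GeneSet({self.name!r}, n={len(self)})"

    def as_set(self) -> frozenset[str]:
        return self._set

    def intersection(self, other: "GeneSet", name: str | None = None) -> "GeneSet":
        """Intersection, preserving this set's ordering."""
        other_set = other._set
        return GeneSet(
            name or f"{self.name}&{other.name}",
            (g for g in self.genes if g in other_set),
        )

    def union(self, other: "GeneSet", name: str | None = None) -> "GeneSet":
        return GeneSet(name or f"{self.name}|{other.name}",
                       list(self.genes) + list(other.genes))

    def issubset(self, other: "GeneSet") -> bool:
        return self._set <= other._set


@dataclass
class SampleAnnotation:
    """Per-sample metadata for the paired-biopsy design.

    Wraps a DataFrame with columns ``sample_id, patient_id, tissue,
    condition, sex, age``.  Validation enforces unique sample ids, the
    tissue/condition vocabularies, and the paired design: every patient
    appearing twice contributes exactly one ILEAL and one SIGMOID sample.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.table.copy()
        required = ["sample_id", "patient_id", "tissue", "condition"]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise ValueError(f"annotation missing columns: {missing}")
        if df["sample_id"].duplicated().any():
            raise ValueError("duplicate sample_id in annotation")
        df["tissue"] = df["tissue"].str.strip().str.upper()
        df["condition"] = (
            df["condition"].str.strip().str.upper().replace(_CONDITION_ALIASES)
        )
        bad_t = set(df["tissue"]) - set(TISSUES)
        if bad_t:
            raise ValueError(f"unknown tissue values: {sorted(bad_t)}")
        bad_c = set(df["condition"]) - set(CONDITIONS)
        if bad_c:
            raise ValueError(f"unknown condition values: {sorted(bad_c)}")
        if "sex" not in df.columns:
            df["sex"] = "unknown"
        if "age" not in df.columns:
            df["age"] = pd.NA
        for pid, grp in df.groupby("patient_id"):
            if len(grp) == 2 and sorted(grp["tissue"]) != ["ILEAL", "SIGMOID"]:
                raise ValueError(
                    f"patient {pid!r} has two samples but not one per tissue"
                )
        self.table = df.reset_index(drop=True)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table["sample_id"])

    def stratum_samples(self, tissue: str, condition: str) -> list[str]:
        """Sample ids of one tissue × condition stratum."""
        t = tissue.strip().upper()
        c = _CONDITION_ALIASES.get(condition.strip().upper(),
                                   condition.strip().upper())
        m = (self.table["tissue"] == t) & (self.table["condition"] == c)
        return list(self.table.loc[m, "sample_id"])

    def strata(self) -> list[tuple[str, str]]:
        """All (tissue, condition) strata present, in a fixed order."""
        present = set(zip(self.table["tissue"], self.table["condition"]))
        return [(t, c) for c in CONDITIONS for t in TISSUES if (t, c) in present]


@dataclass
class ExpressionMatrix:
    """Genes × samples numeric table.

    ``mode`` is ``"counts"`` (finite non-negative integers) or
    ``"intensity"`` (reals, e.g. log-scale microarray intensities).
    """

    values: pd.DataFrame
    mode: str = "intensity"
    annotation: SampleAnnotation | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("counts", "intensity"):
            raise ValueError(f"unknown mode {self.mode!r}")
        df = self.values
        if df.index.duplicated().any():
            raise ValueError("duplicate gene row labels")
        if df.columns.duplicated().any():
            raise ValueError("duplicate sample column labels")
        arr = df.to_numpy()
        if self.mode == "counts":
            if not np.isfinite(arr).all():
                raise ValueError("counts matrix contains non-finite values")
            if (arr < 0).any():
                raise ValueError("counts matrix contains negative values")
            if not np.allclose(arr, np.round(arr)):
                raise ValueError("counts matrix contains non-integer values")
        if self.annotation is not None:
            extra = set(df.columns) - set(self.annotation.sample_ids)
            if extra:
                raise ValueError(
                    f"samples absent from annotation: {sorted(extra)[:5]}"
                )

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    def restrict(self, genes: GeneSet) -> "ExpressionMatrix":
        """Rows restricted to a gene set (order of the matrix preserved)."""
        keep = [g for g in self.values.index if g in genes]
        return ExpressionMatrix(self.values.loc[keep], self.mode, self.annotation)


class InteractionNetwork:
    """Undirected protein–protein interaction network.

    Edges carry a confidence ``score`` in [0, 1000] (STRING convention);
    self-loops are forbidden and each unordered pair appears at most once.
    Backed by a :class:`networkx.Graph`.
    """

    def __init__(self, graph: nx.Graph | None = None):
        self.graph = graph if graph is not None else nx.Graph()

    @classmethod
    def from_edges(cls, edges: Iterable[tuple[str, str, float]]) -> "InteractionNetwork":
        """Build from (gene, gene, score) triples.

        Duplicate / reversed pairs are merged keeping the maximum score;
        self-loops are dropped.
        """
        g = nx.Graph()
        for a, b, score in edges:
            a, b = normalize_symbol(a), normalize_symbol(b)
            if not (0 <= score <= 1000):
                raise ValueError(f"score {score} outside [0, 1000]")
            if a == b:
                continue
            if g.has_edge(a, b):
                g[a][b]["score"] = max(g[a][b]["score"], score)
            else:
                g.add_edge(a, b, score=score)
        return cls(g)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    @property
    def nodes(self) -> list[str]:
        return sorted(self.graph.nodes)

    def edges(self) -> list[tuple[str, str, float]]:
        """Edge triples with endpoints sorted, in deterministic order."""
        out = []
        for a, b, d in self.graph.edges(data=True):
            a, b = sorted((a, b))
            out.append((a, b, d["score"]))
        return sorted(out)


@dataclass
class GeneSetCollection:
    """Named gene sets (pathway terms), e.g. parsed from a GMT file."""

    sets: Mapping[str, GeneSet]
    descriptions: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.sets = dict(self.sets)
        self.descriptions = dict(self.descriptions)

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, term: str) -> GeneSet:
        return self.sets[term]

    def __iter__(self) -> Iterator[str]:
        return iter(self.sets)

    def all_genes(self, name: str = "collection_universe") -> GeneSet:
        """Union of every term's members."""
        out: list[str] = []
        for gs in self.sets.values():
            out.extend(gs.genes)
        return GeneSet(name, out)
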