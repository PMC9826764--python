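"""Over-representation analysis with Benjamini-Hochberg correction.

Each pathway term is tested with a hypergeometric upper tail: with a
background universe of N genes, a term covering K of them and a query of
n genes, the p-value of an overlap of x genes is P(X >= x) for
X ~ Hypergeom(N, K, n).  Term p-values are adjusted by step-up BH.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .types import GeneSet, GeneSetCollection


@dataclass
class OraConfig:
    min_term_size: int = 10
    max_term_size: int = 500
    drop_zero_overlap: bool = True


def bh_adjust(p_values) -> np.ndarray:
    """Step-up Benjamini-Hochberg q-values, input order preserved."""
    p = np.asarray(p_values, float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def hypergeometric_ora(
    query: GeneSet,
    collection: GeneSetCollection,
    background: GeneSet | None = None,
    config: OraConfig | None = None,
) -> pd.DataFrame:
    """ORA of a gene list against a GMT collection.

    The background defaults to the union of all collection members and
    the query.  Query genes outside the background are dropped with a
    warning; term members are intersected with the background.  Returns a
    DataFrame sorted by q then p then term name.
    """
    config = config or OraConfig()
    if background is None:
        background = collection.all_genes().union(query, name="background")
    if len(background) == 0:
        raise ValueError("empty background")
    bg = background.as_set()
    q_in = [g for g in query if g in bg]
    if len(q_in) < len(query):
        warnings.warn(
            f"{len(query) - len(q_in)} query genes outside background dropped"
        )
    query_set = set(q_in)
    N, n = len(bg), len(query_set)
    rows = []
    for term in collection:
        members = collection[term].as_set() & bg
        K = len(members)
        if not config.min_term_size <= K <= config.max_term_size:
            continue
        overlap = sorted(members & query_set)
        x = len(overlap)
        if x == 0 and config.drop_zero_overlap:
            continue
        p = float(stats.hypergeom.sf(x - 1, N, K, n)) if x > 0 else 1.0
        rows.append(
            {
                "term": term,
                "overlap_count": x,
                "term_size": K,
                "query_size": n,
                "background_n": N,
                "gene_ratio": x / n if n else 0.0,
                "p": min(p, 1.0),
                "overlap_genes": "/".join(overlap),
            }
        )
    out = pd.DataFrame(
        rows,
        columns=["term", "overlap_count", "term_size", "query_size",
                 "background_n", "gene_ratio", "p", "overlap_genes"],
    )
    if len(out):
        out["q"] = bh_adjust(out["p"].to_numpy())
        out = out.sort_values(["q", "p", "term"], kind="stable").reset_index(drop=True)
    else:
        out["q"] = pd.Series(dtype=float)
    return out
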