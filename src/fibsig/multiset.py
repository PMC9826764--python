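"""Signature construction by k-of-n multiset intersection with exact statistics.

A gene enters a disease pool when it is significant in at least k of the
n cohorts of that pool — equivalently, when it lies in the full
intersection of at least one cohort subset of size >= k.  The two pools
(Crohn's disease; other fibrotic disorders) are intersected to form the
cross-disease signature, and the overlap is scored with the exact
distribution of an m-set intersection under independent uniform draws of
fixed-size subsets from a common background.
"""

from __future__ import annotations

import itertools
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .types import GeneSet


@dataclass
class CombinationScheme:
    """At-least-k-of-n cohort voting scheme."""

    n_lists: int
    min_k: int

    def __post_init__(self) -> None:
        if self.n_lists < 1:
            raise ValueError("n_lists must be >= 1")
        if not 1 <= self.min_k <= self.n_lists:
            raise ValueError("min_k must satisfy 1 <= min_k <= n_lists")


@dataclass
class IntersectionStat:
    """Observed m-set overlap with its exact null distribution summary.

    ``expected`` is N·∏(n_j/N) — the mean intersection size when each set
    is an independent uniform draw; ``p_value`` is P(X >= observed) under
    that null.
    """

    set_sizes: tuple[int, ...]
    background_n: int
    observed: int
    expected: float
    fold_enrichment: float
    p_value: float


@dataclass
class SignatureResult:
    geneset1: GeneSet
    geneset2: GeneSet
    fibsig: GeneSet
    stats: IntersectionStat = None  # type: ignore[assignment]
    extra: dict = field(default_factory=dict)


def enumerate_combinations(scheme: CombinationScheme) -> list[tuple[int, ...]]:
    """All cohort-index subsets of size >= min_k, lexicographic order."""
    out: list[tuple[int, ...]] = []
    for size in range(scheme.min_k, scheme.n_lists + 1):
        out.extend(itertools.combinations(range(scheme.n_lists), size))
    return out


def membership_matrix(gene_lists: list[GeneSet]) -> pd.DataFrame:
    """Genes × cohorts boolean table from per-cohort significant-gene lists.

    Row order: first appearance across the lists.  Cohort names must be
    unique (GeneSet names are used as columns).
    """
    names = [gs.name for gs in gene_lists]
    if len(set(names)) != len(names):
        raise ValueError("cohort names must be unique")
    genes: dict[str, None] = {}
    for gs in gene_lists:
        for g in gs:
            genes.setdefault(g, None)
    index = list(genes)
    data = {gs.name: [g in gs for g in index] for gs in gene_lists}
    return pd.DataFrame(data, index=index, dtype=bool)


def k_of_n_filter(
    membership: pd.DataFrame, scheme: CombinationScheme, name: str = "pool"
) -> GeneSet:
    """Genes significant in at least min_k of the n cohorts."""
    if membership.shape[1] != scheme.n_lists:
        raise ValueError(
            f"membership has {membership.shape[1]} cohorts, scheme expects "
            f"{scheme.n_lists}"
        )
    keep = membership.sum(axis=1) >= scheme.min_k
    return GeneSet(name, list(membership.index[keep]))


def subset_union_filter(
    membership: pd.DataFrame, scheme: CombinationScheme, name: str = "pool"
) -> GeneSet:
    """Union over all size->=k cohort subsets of their full intersections.

    Semantically identical to :func:`k_of_n_filter`; kept as the explicit
    combination-enumeration form for cross-validation.
    """
    cols = list(membership.columns)
    hit = np.zeros(len(membership), dtype=bool)
    arr = membership.to_numpy(bool)
    for combo in enumerate_combinations(scheme):
        hit |= arr[:, list(combo)].all(axis=1)
    return GeneSet(name, list(membership.index[hit]))


def exact_intersection_test(
    set_sizes: list[int] | tuple[int, ...],
    observed: int,
    background_n: int,
) -> IntersectionStat:
    """Exact p-value for the intersection of m fixed-size random subsets.

    The null distribution of the m-set intersection size is built by
    sequential hypergeometric conditioning: D_1 is a point mass at n_1,
    and D_{j+1}(i') = Σ_i D_j(i)·P(Hypergeom(N, i, n_{j+1}) = i').
    PMF values are evaluated in log space.
    """
    sizes = tuple(int(n) for n in set_sizes)
    N = int(background_n)
    if len(sizes) < 1:
        raise ValueError("need at least one set")
    if any(not 0 <= n <= N for n in sizes):
        raise ValueError("each set size must satisfy 0 <= n_j <= N")
    if not 0 <= observed <= min(sizes):
        raise ValueError("observed must satisfy 0 <= observed <= min(n_j)")
    dist = intersection_distribution(sizes, N)
    p_value = float(dist[observed:].sum())
    p_value = min(1.0, p_value)
    expected = N * float(np.prod([n / N for n in sizes]))
    fold = observed / expected if expected > 0 else np.inf
    return IntersectionStat(
        set_sizes=sizes,
        background_n=N,
        observed=int(observed),
        expected=expected,
        fold_enrichment=fold,
        p_value=p_value,
    )


def intersection_distribution(
    set_sizes: tuple[int, ...], background_n: int
) -> np.ndarray:
    """Exact PMF of the m-set intersection size; index = overlap size."""
    N = background_n
    support = min(set_sizes)
    dist = np.zeros(set_sizes[0] + 1)
    dist[set_sizes[0]] = 1.0
    for n_j in set_sizes[1:]:
        new = np.zeros(len(dist))
        for i in np.flatnonzero(dist > 0):
            # overlap with a uniform n_j-subset of N, given i marked genes
            hi = min(i, n_j)
            ks = np.arange(0, hi + 1)
            with np.errstate(divide="ignore"):
                pmf = np.exp(stats.hypergeom.logpmf(ks, N, i, n_j))
            new[ks] += dist[i] * pmf
        dist = new
    return dist[: support + 1]


def mc_intersection_oracle(
    set_sizes: list[int] | tuple[int, ...],
    background_n: int,
    draws: int,
    seed: int,
) -> Counter:
    """Monte-Carlo tally of m-set intersection sizes (validation oracle)."""
    if draws < 1000:
        raise ValueError("draws must be >= 1000")
    rng = np.random.default_rng(seed)
    N = int(background_n)
    tally: Counter = Counter()
    for _ in range(draws):
        common: set[int] | None = None
        for n_j in set_sizes:
            s = set(rng.choice(N, size=n_j, replace=False).tolist())
            common = s if common is None else (common & s)
            if not common:
                break
        tally[len(common) if common else 0] += 1
    return tally


def build_signature(
    gs1: GeneSet, gs2: GeneSet, background_n: int, name: str = "FIBSig"
) -> SignatureResult:
    """Intersect the two disease pools and attach the exact overlap statistic."""
    union_size = len(gs1.as_set() | gs2.as_set())
    if background_n < union_size:
        raise ValueError(
            f"background_n={background_n} smaller than pool union ({union_size})"
        )
    fibsig = gs1.intersection(gs2, name=name)
    stat = exact_intersection_test(
        [len(gs1), len(gs2)], len(fibsig), background_n
    )
    return SignatureResult(geneset1=gs1, geneset2=gs2, fibsig=fibsig, stats=stat)
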