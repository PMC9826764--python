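"""Co-expression module discovery and module-vs-stratum enrichment.

The network construction follows the weighted co-expression convention:
gene–gene correlations are raised to a soft-threshold power chosen for
approximate scale-free topology, converted to a topological overlap
matrix (TOM), and clustered by average-linkage hierarchical clustering
with a static tree cut.  Modules are labelled M1, M2, ... by decreasing
size.  Module–stratum association uses a preranked GSEA: genes are ranked
by a stratum z-score and the module is tested as the gene set, with
gene-label permutations providing the normalized enrichment score (NES)
and its p-value.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from scipy.stats import rankdata

from .counts import NormalizedMatrix
from .types import GeneSet, SampleAnnotation


@dataclass
class CoexpressionConfig:
    correlation: str = "pearson"  # "pearson" | "spearman"
    beta_grid: tuple[int, ...] = tuple(range(1, 21))
    rsq_target: float = 0.8
    min_module_size: int = 20
    network_sign: str = "unsigned"  # "unsigned" | "signed"
    merge_height: float = 0.9
    min_mean_connectivity: float = 2.0

    def __post_init__(self) -> None:
        if not self.beta_grid:
            raise ValueError("beta grid must be nonempty")
        if self.min_module_size < 3:
            raise ValueError("min_module_size must be >= 3")
        if not 0 < self.merge_height < 1:
            raise ValueError("merge_height must be in (0, 1)")
        if self.correlation not in ("pearson", "spearman"):
            raise ValueError(f"unknown correlation {self.correlation!r}")
        if self.network_sign not in ("unsigned", "signed"):
            raise ValueError(f"unknown network sign {self.network_sign!r}")


@dataclass
class CoexpressionResult:
    beta: int
    rsq: float
    assignments: pd.Series  # gene -> "M1" | "M2" | ... | "unassigned"
    eigengenes: pd.DataFrame  # modules × samples
    tom: pd.DataFrame = field(repr=False, default=None)

    def module_genes(self, module: str) -> GeneSet:
        return GeneSet(module, list(self.assignments.index[self.assignments == module]))

    @property
    def modules(self) -> list[str]:
        return [m for m in self.eigengenes.index]


def correlation_matrix(norm: NormalizedMatrix, method: str = "pearson") -> pd.DataFrame:
    """Gene × gene correlation matrix; zero-variance genes are dropped."""
    if len(norm.samples) < 4:
        raise ValueError("need >=4 samples for co-expression")
    x = norm.values.to_numpy(float)
    sd = x.std(axis=1)
    keep = sd > 0
    if not keep.all():
        warnings.warn(f"dropping {int((~keep).sum())} zero-variance genes")
    x = x[keep]
    genes = norm.values.index[keep]
    if method == "spearman":
        x = np.apply_along_axis(rankdata, 1, x)
    r = np.corrcoef(x)
    r = np.clip(r, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    return pd.DataFrame(r, index=genes, columns=genes)


def _adjacency(corr: np.ndarray, beta: int, sign: str) -> np.ndarray:
    if sign == "signed":
        a = ((1.0 + corr) / 2.0) ** beta
    else:
        a = np.abs(corr) ** beta
    np.fill_diagonal(a, 1.0)
    return a


def _scale_free_rsq(degrees: np.ndarray, n_bins: int = 10) -> tuple[float, int]:
    """R² of log10 frequency vs log10 mean degree over occupied bins."""
    k = degrees[degrees > 0]
    if k.size < 2 or np.ptp(k) <= 0:
        return 0.0, 0
    edges = np.linspace(k.min(), k.max() + 1e-12, n_bins + 1)
    idx = np.clip(np.digitize(k, edges) - 1, 0, n_bins - 1)
    xs, ys = [], []
    for b in range(n_bins):
        m = idx == b
        if m.any():
            xs.append(k[m].mean())
            ys.append(m.sum() / k.size)
    if len(xs) < 2:
        return 0.0, len(xs)
    lx, ly = np.log10(xs), np.log10(ys)
    if np.ptp(lx) <= 0 or np.ptp(ly) <= 0:
        return 0.0, len(xs)
    r = np.corrcoef(lx, ly)[0, 1]
    # signed fit index: a positive slope is not scale-free topology
    return float(-np.sign(r) * r**2), len(xs)


def select_soft_threshold(
    corr: pd.DataFrame, config: CoexpressionConfig | None = None
) -> tuple[int, float]:
    """Smallest power whose scale-free fit R² reaches the target.

    The fit index is signed (a positive log-log slope counts against the
    fit) and a candidate power must keep at least 5 occupied degree bins
    and a mean connectivity above ``min_mean_connectivity`` — at very high
    powers every adjacency collapses toward zero and the fit index becomes
    an artifact of vanishing connectivity.  When no power in the grid
    qualifies, selection falls back to the conventional unsigned-network
    default, beta = 6, with a warning.
    """
    config = config or CoexpressionConfig()
    c = corr.to_numpy(float)
    fallback_beta = 6
    fallback_rsq = 0.0
    any_valid = False
    for beta in config.beta_grid:
        a = _adjacency(c, beta, config.network_sign)
        degrees = a.sum(axis=0) - 1.0  # exclude self-adjacency
        rsq, n_occ = _scale_free_rsq(degrees)
        if n_occ >= 5 and degrees.mean() >= config.min_mean_connectivity:
            any_valid = True
            if rsq >= config.rsq_target:
                return int(beta), float(rsq)
        if beta == fallback_beta:
            fallback_rsq = rsq
    if not any_valid:
        warnings.warn("degenerate degree distribution at all powers; using beta=6")
        return fallback_beta, 0.0
    warnings.warn(
        f"no power reached scale-free fit R^2 >= {config.rsq_target}; "
        f"using default beta={fallback_beta}"
    )
    return fallback_beta, float(fallback_rsq)


def adjacency_to_tom(adjacency: pd.DataFrame | np.ndarray) -> pd.DataFrame | np.ndarray:
    """Topological overlap: TOM_ij = (l_ij + a_ij)/(min(k_i,k_j) + 1 − a_ij).

    l_ij sums a_iu·a_uj over shared neighbours u ∉ {i, j}; connectivity k
    excludes the diagonal.  TOM_ii = 1.
    """
    labels = None
    a = adjacency
    if isinstance(a, pd.DataFrame):
        labels = a.index
        a = a.to_numpy(float)
    if not np.allclose(a, a.T):
        raise ValueError("adjacency must be symmetric")
    a = a.copy()
    np.fill_diagonal(a, 1.0)
    l = a @ a - 2.0 * a  # remove u=i and u=j terms (diagonal is 1)
    k = a.sum(axis=0) - 1.0
    denom = np.minimum.outer(k, k) + 1.0 - a
    with np.errstate(invalid="ignore", divide="ignore"):
        tom = (l + a) / denom
    tom = np.where(denom > 0, tom, 0.0)
    tom = np.clip(tom, 0.0, 1.0)
    tom = (tom + tom.T) / 2.0
    np.fill_diagonal(tom, 1.0)
    if labels is not None:
        return pd.DataFrame(tom, index=labels, columns=labels)
    return tom


def cluster_modules(
    tom: pd.DataFrame, config: CoexpressionConfig | None = None
) -> pd.Series:
    """Average-linkage clustering of 1−TOM with a static cut.

    Clusters below ``min_module_size`` become "unassigned"; survivors are
    relabelled M1, M2, ... by decreasing size (ties broken by the
    alphabetically first member gene).
    """
    config = config or CoexpressionConfig()
    genes = list(tom.index)
    d = 1.0 - tom.to_numpy(float)
    np.fill_diagonal(d, 0.0)
    d = np.clip((d + d.T) / 2.0, 0.0, None)
    z = hierarchy.linkage(squareform(d, checks=False), method="average")
    raw = hierarchy.fcluster(z, t=config.merge_height, criterion="distance")
    labels = pd.Series("unassigned", index=genes, dtype=object)
    clusters: dict[int, list[str]] = {}
    for g, c in zip(genes, raw):
        clusters.setdefault(int(c), []).append(g)
    surviving = [
        members for members in clusters.values()
        if len(members) >= config.min_module_size
    ]
    if not surviving:
        warnings.warn("no cluster reached min_module_size; all genes unassigned")
        return labels
    surviving.sort(key=lambda m: (-len(m), min(m)))
    for i, members in enumerate(surviving, start=1):
        labels.loc[members] = f"M{i}"
    return labels


def module_eigengene(
    norm: NormalizedMatrix, assignments: pd.Series, module: str
) -> pd.Series:
    """First principal component of the gene-standardized module submatrix.

    Sign-oriented so the eigengene correlates positively with the module's
    mean expression profile.
    """
    genes = list(assignments.index[assignments == module])
    if not genes:
        raise ValueError(f"module {module!r} is empty")
    x = norm.values.loc[genes].to_numpy(float)
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    xs = (x - mu) / sd
    _, _, vt = np.linalg.svd(xs, full_matrices=False)
    eig = vt[0]
    mean_profile = xs.mean(axis=0)
    if np.dot(eig, mean_profile) < 0:
        eig = -eig
    return pd.Series(eig, index=norm.samples, name=module)


def discover_modules(
    norm: NormalizedMatrix, config: CoexpressionConfig | None = None
) -> CoexpressionResult:
    """Full module-discovery chain: correlation → β → TOM → clustering."""
    config = config or CoexpressionConfig()
    corr = correlation_matrix(norm, config.correlation)
    beta, rsq = select_soft_threshold(corr, config)
    adj = _adjacency(corr.to_numpy(float), beta, config.network_sign)
    tom = adjacency_to_tom(pd.DataFrame(adj, index=corr.index, columns=corr.columns))
    assignments = cluster_modules(tom, config)
    modules = sorted(
        {m for m in assignments if m != "unassigned"},
        key=lambda m: int(m[1:]),
    )
    eig = pd.DataFrame(
        [module_eigengene(norm, assignments, m) for m in modules],
        columns=norm.samples,
    )
    eig.index = modules
    return CoexpressionResult(beta=beta, rsq=rsq, assignments=assignments,
                              eigengenes=eig, tom=tom)


# ---------------------------------------------------------------------------
# Module-vs-stratum enrichment (preranked GSEA)


def class_ranked_list(
    norm: NormalizedMatrix,
    annotation: SampleAnnotation,
    tissue: str,
    condition: str,
) -> pd.Series:
    """Gene ranking for one tissue × condition stratum.

    Score = (mean within stratum − overall mean) / overall sd, ranked
    descending with ties broken by gene symbol.  Constant genes score 0.
    """
    stratum = annotation.stratum_samples(tissue, condition)
    stratum = [s for s in stratum if s in norm.values.columns]
    if len(stratum) < 2:
        raise ValueError(f"stratum {tissue}/{condition} has <2 samples")
    x = norm.values.to_numpy(float)
    mu = x.mean(axis=1)
    sd = x.std(axis=1)
    cls = norm.values[stratum].to_numpy(float).mean(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        score = np.where(sd > 0, (cls - mu) / sd, 0.0)
    s = pd.Series(score, index=norm.values.index, name=f"{condition}_{tissue}")
    order = sorted(s.index, key=lambda g: (-s[g], g))
    return s.loc[order]


def _enrichment_score(scores: np.ndarray, hit: np.ndarray) -> float:
    """Weighted KS enrichment score (weight exponent 1 on |score|)."""
    n = scores.size
    nh = int(hit.sum())
    w = np.abs(scores) * hit
    total_w = w.sum()
    if total_w <= 0:
        # all hit scores zero: fall back to unweighted hits
        w = hit.astype(float)
        total_w = w.sum()
    p_hit = np.cumsum(w) / total_w
    p_miss = np.cumsum(~hit) / max(n - nh, 1)
    dev = p_hit - p_miss
    i = int(np.argmax(np.abs(dev)))
    return float(dev[i])


@dataclass
class ModuleEnrichment:
    module: str
    tissue: str
    condition: str
    es: float
    nes: float
    p: float
    n_hits: int


def gsea_module_class(
    ranking: pd.Series,
    module_genes: GeneSet,
    n_perm: int = 1000,
    seed: int = 0,
    module: str = "M1",
    tissue: str = "",
    condition: str = "",
) -> ModuleEnrichment:
    """Preranked GSEA of a module against a stratum-derived ranking.

    NES = ES / mean(|ES_perm|) over gene-label permutations whose ES has
    the same sign as the observed ES; p is the same-sign tail fraction
    with +1 smoothing.  Positive NES ⟺ module over-expressed in the
    stratum.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    scores = ranking.to_numpy(float)
    hit = np.array([g in module_genes for g in ranking.index])
    nh = int(hit.sum())
    if nh == 0:
        raise ValueError("module has no genes in the ranking")
    es = _enrichment_score(scores, hit)
    rng = np.random.default_rng(seed)
    n = scores.size
    perm_es = np.empty(n_perm)
    for i in range(n_perm):
        ph = np.zeros(n, dtype=bool)
        ph[rng.choice(n, size=nh, replace=False)] = True
        perm_es[i] = _enrichment_score(scores, ph)
    same_sign = perm_es * np.sign(es) > 0 if es != 0 else np.ones(n_perm, bool)
    denom = np.abs(perm_es[same_sign]).mean() if same_sign.any() else np.nan
    nes = es / denom if denom and np.isfinite(denom) and denom > 0 else 0.0
    n_extreme = int((np.abs(perm_es[same_sign]) >= abs(es)).sum())
    p = (1 + n_extreme) / (1 + int(same_sign.sum()))
    return ModuleEnrichment(module=module, tissue=tissue, condition=condition,
                            es=es, nes=float(nes), p=float(min(p, 1.0)),
                            n_hits=nh)


def module_class_nes_table(
    norm: NormalizedMatrix,
    annotation: SampleAnnotation,
    result: CoexpressionResult,
    n_perm: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """NES of every module against every tissue × condition stratum."""
    rows = []
    for j, (tissue, condition) in enumerate(annotation.strata()):
        ranking = class_ranked_list(norm, annotation, tissue, condition)
        for module in result.modules:
            enr = gsea_module_class(
                ranking, result.module_genes(module),
                n_perm=n_perm, seed=seed + j, module=module,
                tissue=tissue, condition=condition,
            )
            rows.append(
                {"module": module, "tissue": tissue, "condition": condition,
                 "es": enr.es, "nes": enr.nes, "p": enr.p}
            )
    return pd.DataFrame(rows)
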