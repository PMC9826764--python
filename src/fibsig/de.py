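"""Two-group differential expression with an empirical-Bayes moderated t.

Per-gene residual variances are shrunk toward a common prior fitted by
moment matching on log-variances (the scaled inverse-chi-square hierarchy
used by limma-style analyses): given per-gene sample variances s²_g on d_g
residual degrees of freedom, the prior (d0, s0²) is chosen so that the
theoretical mean and variance of log s² match their empirical moments.
The moderated statistic uses the posterior variance

    s̃²_g = (d0·s0² + d_g·s²_g) / (d0 + d_g)

and is referred to a t distribution on d0 + d_g degrees of freedom
(the normal limit when d0 = ∞).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .types import ExpressionMatrix, GeneSet


@dataclass
class DEConfig:
    """Significance settings: raw p < 0.05 by default, BH optional."""

    p_threshold: float = 0.05
    adjust: str = "none"  # "none" | "BH"

    def __post_init__(self) -> None:
        if not 0 < self.p_threshold < 1:
            raise ValueError("p_threshold must be in (0, 1)")
        if self.adjust not in ("none", "BH"):
            raise ValueError(f"unknown adjustment {self.adjust!r}")


@dataclass
class ModeratedTParams:
    """Prior degrees of freedom and prior variance of the variance model."""

    d0: float  # may be +inf
    s0_sq: float

    def __post_init__(self) -> None:
        if not self.d0 > 0:
            raise ValueError("d0 must be positive")
        if not self.s0_sq > 0:
            raise ValueError("s0_sq must be positive")


def fit_group_stats(
    matrix: ExpressionMatrix,
    group1: list[str],
    group2: list[str],
) -> pd.DataFrame:
    """Per-gene mean difference and pooled residual variance.

    Returns a DataFrame indexed by gene with columns ``log_fc`` (mean of
    group1 minus mean of group2), ``s_sq`` (pooled variance), ``df_resid``
    (n1 + n2 - 2), ``n1``, ``n2``.
    """
    if matrix.mode != "intensity":
        raise ValueError("differential expression expects intensity mode")
    if len(group1) < 2 or len(group2) < 2:
        raise ValueError("insufficient replication: each group needs >=2 samples")
    x1 = matrix.values[group1].to_numpy(float)
    x2 = matrix.values[group2].to_numpy(float)
    n1, n2 = x1.shape[1], x2.shape[1]
    diff = x1.mean(axis=1) - x2.mean(axis=1)
    ss1 = ((x1 - x1.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    ss2 = ((x2 - x2.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    df_resid = n1 + n2 - 2
    s_sq = (ss1 + ss2) / df_resid
    return pd.DataFrame(
        {"log_fc": diff, "s_sq": s_sq, "df_resid": df_resid, "n1": n1, "n2": n2},
        index=matrix.values.index,
    )


def _trigamma(x: np.ndarray | float) -> np.ndarray | float:
    return special.polygamma(1, x)


def _trigamma_inverse(y: float, tol: float = 1e-8) -> float:
    """Solve trigamma(x) = y for x > 0 by bisection.

    trigamma is strictly decreasing on (0, inf); the search bracket covers
    x = d0/2 for d0 in (0.01, 1e6].
    """
    lo, hi = 0.005, 5e5
    if y >= _trigamma(lo):
        return lo
    if y <= _trigamma(hi):
        return hi
    while hi - lo > tol * max(1.0, lo):
        mid = 0.5 * (lo + hi)
        if _trigamma(mid) > y:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def estimate_prior(s_sq: np.ndarray, df_resid: np.ndarray | float) -> ModeratedTParams:
    """Fit (d0, s0²) by moment matching on log sample variances.

    With s² | σ² ~ σ²·χ²_d/d and σ² ~ scaled-inv-χ²(d0, s0²), the statistic
    e_g = log s²_g − ψ(d_g/2) + log(d_g/2) has mean log s0² + ψ(d0/2) −
    log(d0/2) and excess variance ψ′(d0/2) beyond the ψ′(d_g/2) implied by
    sampling alone.  If the empirical spread does not exceed the sampling
    spread, the prior is degenerate: d0 = +inf, s0² = exp(mean e).
    """
    s_sq = np.asarray(s_sq, float)
    d = np.broadcast_to(np.asarray(df_resid, float), s_sq.shape)
    ok = s_sq > 0
    if ok.sum() < 10:
        raise ValueError("degenerate variances: need >=10 genes with s_sq > 0")
    z = np.log(s_sq[ok])
    dg = d[ok]
    e = z - special.digamma(dg / 2) + np.log(dg / 2)
    e_mean = e.mean()
    e_var = e.var(ddof=1) - float(np.mean(_trigamma(dg / 2)))
    if e_var <= 0:
        return ModeratedTParams(d0=np.inf, s0_sq=float(np.exp(e_mean)))
    half_d0 = _trigamma_inverse(e_var)
    d0 = 2 * half_d0
    s0_sq = float(np.exp(e_mean + special.digamma(half_d0) - np.log(half_d0)))
    return ModeratedTParams(d0=d0, s0_sq=s0_sq)


def moderated_t(
    stats_df: pd.DataFrame,
    params: ModeratedTParams,
    config: DEConfig | None = None,
) -> pd.DataFrame:
    """Moderated t statistics and two-sided p-values.

    ``params.d0 = 0`` is accepted as the no-moderation limit (ordinary
    pooled t-test); ``d0 = +inf`` gives the fully pooled normal limit.
    """
    config = config or DEConfig()
    d0, s0 = params.d0, params.s0_sq
    s_sq = stats_df["s_sq"].to_numpy(float)
    dg = stats_df["df_resid"].to_numpy(float)
    n1 = stats_df["n1"].to_numpy(float)
    n2 = stats_df["n2"].to_numpy(float)
    diff = stats_df["log_fc"].to_numpy(float)
    if np.isinf(d0):
        s_tilde = np.full_like(s_sq, s0)
        df_total = np.full_like(s_sq, np.inf)
    else:
        s_tilde = (d0 * s0 + dg * s_sq) / (d0 + dg)
        df_total = d0 + dg
    se = np.sqrt(s_tilde * (1 / n1 + 1 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, diff / se, np.where(diff == 0, 0.0, np.inf * np.sign(diff)))
    if np.isinf(d0):
        p = 2 * stats.norm.sf(np.abs(t))
    else:
        p = 2 * stats.t.sf(np.abs(t), df_total)
    out = stats_df.copy()
    out["s_tilde_sq"] = s_tilde
    out["t_mod"] = t
    out["df_total"] = df_total
    out["p"] = p
    if config.adjust == "BH":
        out["p_adj"] = multipletests(p, method="fdr_bh")[1]
    else:
        out["p_adj"] = p
    out["significant"] = out["p_adj"] < config.p_threshold
    return out


def significant_genes(result: pd.DataFrame, name: str) -> GeneSet:
    """Genes flagged significant, as a GeneSet named by cohort."""
    return GeneSet(name, list(result.index[result["significant"]]))


def run_de(
    matrix: ExpressionMatrix,
    group1: list[str],
    group2: list[str],
    config: DEConfig | None = None,
    params: ModeratedTParams | None = None,
) -> pd.DataFrame:
    """Fit group stats, estimate the prior and compute moderated t."""
    config = config or DEConfig()
    stats_df = fit_group_stats(matrix, group1, group2)
    if params is None:
        params = estimate_prior(
            stats_df["s_sq"].to_numpy(), stats_df["df_resid"].to_numpy()
        )
    return moderated_t(stats_df, params, config)
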