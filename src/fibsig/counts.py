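"""Count normalization (median-of-ratios) and PCA for the paired biopsies.

Size factors follow the median-of-ratios convention: for each sample the
factor is the median, over genes whose geometric mean across samples is
positive, of the gene's count divided by that geometric mean.  Counts are
then shifted-log transformed, value = log2(count / s_j + 1), and PCA is a
gene-centered SVD across samples.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .types import ExpressionMatrix, GeneSet


@dataclass
class NormalizedMatrix:
    """log2(count/s + 1) values with the size factors that produced them."""

    values: pd.DataFrame
    size_factors: pd.Series
    transform: str = "log2_plus1"

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    def restrict(self, genes: GeneSet) -> "NormalizedMatrix":
        keep = [g for g in self.values.index if g in genes]
        return NormalizedMatrix(self.values.loc[keep], self.size_factors,
                                self.transform)


@dataclass
class PcaSummary:
    """Per-sample component scores and variance fractions."""

    scores: pd.DataFrame  # samples × components
    variance_fraction: np.ndarray
    loadings: pd.DataFrame = field(repr=False, default=None)  # genes × components


def median_ratio_size_factors(counts: ExpressionMatrix) -> pd.Series:
    """Median-of-ratios size factors, one per sample.

    Genes with a zero geometric mean (any zero count) are excluded from
    the reference; at least one all-positive gene is required.
    """
    if counts.mode != "counts":
        raise ValueError("size factors require counts mode")
    arr = counts.values.to_numpy(float)
    positive = (arr > 0).all(axis=1)
    if not positive.any():
        raise ValueError("cannot normalize: no gene has all-positive counts")
    log_ref = np.log(arr[positive]).mean(axis=1, keepdims=True)
    log_ratios = np.log(arr[positive]) - log_ref
    factors = np.exp(np.median(log_ratios, axis=0))
    return pd.Series(factors, index=counts.values.columns, name="size_factor")


def log_normalize(
    counts: ExpressionMatrix, size_factors: pd.Series | None = None
) -> NormalizedMatrix:
    """Shifted-log transform of size-factor-scaled counts."""
    if size_factors is None:
        size_factors = median_ratio_size_factors(counts)
    scaled = counts.values.to_numpy(float) / size_factors.to_numpy(float)
    values = pd.DataFrame(
        np.log2(scaled + 1.0),
        index=counts.values.index,
        columns=counts.values.columns,
    )
    return NormalizedMatrix(values, size_factors)


def pca_summary(norm: NormalizedMatrix, n_components: int = 2) -> PcaSummary:
    """Gene-centered SVD PCA of samples.

    Sign convention: each component is oriented so its first nonzero gene
    loading is positive.  A constant matrix yields all-zero variance
    fractions with a warning.
    """
    if len(norm.samples) < 2:
        raise ValueError("PCA needs at least 2 samples")
    x = norm.values.to_numpy(float).T  # samples × genes
    x = x - x.mean(axis=0, keepdims=True)
    n_components = min(n_components, min(x.shape))
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    total = float((s**2).sum())
    if total <= 1e-12:
        warnings.warn("all samples identical: PCA variance undefined, set to 0")
        frac = np.zeros(n_components)
        scores = pd.DataFrame(
            np.zeros((x.shape[0], n_components)),
            index=norm.samples,
            columns=[f"PC{i+1}" for i in range(n_components)],
        )
        return PcaSummary(scores, frac, loadings=None)
    # orient: first nonzero loading of each component positive
    for i in range(vt.shape[0]):
        nz = np.flatnonzero(np.abs(vt[i]) > 1e-12)
        if nz.size and vt[i, nz[0]] < 0:
            vt[i] *= -1
            u[:, i] *= -1
    frac = (s**2 / total)[:n_components]
    cols = [f"PC{i+1}" for i in range(n_components)]
    scores = pd.DataFrame(
        (u[:, :n_components] * s[:n_components]), index=norm.samples, columns=cols
    )
    loadings = pd.DataFrame(vt[:n_components].T, index=norm.genes, columns=cols)
    return PcaSummary(scores, frac, loadings)
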