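"""Dataset-level structure summaries: PCA treatment-displacement vectors,
strongest-evidence gene selection, hierarchical clustering of fold-change
profiles, and loess-smoothed fold-change trends.

PCA operates on log2(FPKM + 1), gene-centered, so that treatment
displacements — the vector from the control samples' bivariate mean to each
treated group's mean in component space — summarize overall effect size and
direction per treatment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from statsmodels.nonparametric.smoothers_lowess import lowess

__all__ = [
    "PCAResult",
    "pca_scores",
    "select_strong_genes",
    "HclustResult",
    "hclust_fc",
    "loess_fc_trend",
]


@dataclass
class PCAResult:
    scores: pd.DataFrame  # sample × component
    variance_fraction: np.ndarray
    displacements: pd.DataFrame  # group × component, relative to reference mean
    loadings: pd.DataFrame  # component × gene; scores @ loadings reconstructs centered data
    reference_group: str


def pca_scores(
    expression: pd.DataFrame,
    design: pd.Series,
    n_components: Optional[int] = None,
    reference_group: str = "CTL",
    log_transform: bool = True,
) -> PCAResult:
    """Principal-component scores and per-treatment displacement vectors.

    ``expression`` is a gene × sample abundance table (FPKM unless already
    transformed); by default it is mapped to log2(x+1) and gene-centered
    before the SVD. Scores carry a deterministic sign convention (largest-
    magnitude loading of each component is positive). Displacements are the
    group mean score minus the reference-group mean, and are exactly zero
    for the reference group itself.
    """
    n_samples = expression.shape[1]
    n_genes = expression.shape[0]
    max_rank = min(n_samples, n_genes)
    if n_components is None:
        n_components = min(12, max_rank)
    if n_components > max_rank:
        raise ValueError(f"n_components={n_components} exceeds min(genes, samples)={max_rank}")
    if n_samples < 2:
        raise ValueError("PCA requires at least 2 samples")
    X = expression.to_numpy(float).T  # samples × genes
    if log_transform:
        X = np.log2(X + 1.0)
    X = X - X.mean(axis=0, keepdims=True)
    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    # deterministic sign: flip so the largest-|loading| entry is positive
    for i in range(Vt.shape[0]):
        pivot = np.argmax(np.abs(Vt[i]))
        if Vt[i, pivot] < 0:
            Vt[i] *= -1.0
            U[:, i] *= -1.0
    scores = U * S
    total_var = np.sum(S**2)
    var_frac = (S**2 / total_var) if total_var > 0 else np.zeros_like(S)
    cols = [f"PC{i}" for i in range(1, n_components + 1)]
    scores_df = pd.DataFrame(scores[:, :n_components], index=expression.columns, columns=cols)
    loadings_df = pd.DataFrame(Vt[:n_components], index=cols, columns=expression.index)

    design = design.reindex(expression.columns)
    if reference_group not in set(design):
        raise ValueError(f"reference group {reference_group!r} not present in design")
    group_means = scores_df.groupby(design, sort=False).mean()
    displacements = group_means - group_means.loc[reference_group]
    return PCAResult(
        scores=scores_df,
        variance_fraction=var_frac[:n_components],
        displacements=displacements,
        loadings=loadings_df,
        reference_group=reference_group,
    )


def select_strong_genes(de_tables: Sequence[pd.DataFrame], target_n: int) -> list:
    """Genes with the strongest differential-expression evidence in any one
    comparison: evidence score = min raw p across tables; the ``target_n``
    smallest scores are returned (ties broken by gene id)."""
    if not len(de_tables):
        raise ValueError("need at least one DE table")
    min_p = None
    for table in de_tables:
        p = table.loc[table["tested"].astype(bool), "p"]
        min_p = p if min_p is None else pd.concat([min_p, p], axis=1).min(axis=1)
    min_p = min_p.dropna()
    if target_n > len(min_p):
        warnings.warn(f"target_n={target_n} exceeds the {len(min_p)}-gene universe; returning all")
        target_n = len(min_p)
    order = sorted(min_p.index, key=lambda g: (min_p[g], g))
    return order[:target_n]


@dataclass
class HclustResult:
    leaf_order: list
    linkage: np.ndarray
    newick: str


def _to_newick(Z: np.ndarray, labels: Sequence[str]) -> str:
    n = len(labels)

    def build(node: int) -> str:
        if node < n:
            return labels[node]
        left, right, height, _ = Z[node - n]
        return f"({build(int(left))},{build(int(right))}):{height:.6g}"

    return build(2 * n - 2) + ";"


def hclust_fc(fc_matrix: pd.DataFrame) -> HclustResult:
    """Agglomerative clustering of log2FC profiles (Euclidean distance,
    average linkage), with a deterministic leaf order.

    Rows are sorted by gene id before clustering so permuting the input
    row order cannot change merge heights or the leaf ordering.
    """
    if fc_matrix.shape[0] < 2:
        raise ValueError("need at least 2 genes to cluster")
    if fc_matrix.isna().any().any():
        bad = fc_matrix.index[fc_matrix.isna().any(axis=1)]
        raise ValueError(f"missing fold changes for genes: {list(bad[:10])}")
    ordered = fc_matrix.sort_index(kind="mergesort")
    Z = linkage(ordered.to_numpy(float), method="average", metric="euclidean")
    leaves = leaves_list(Z)
    leaf_order = [ordered.index[i] for i in leaves]
    return HclustResult(leaf_order=leaf_order, linkage=Z, newick=_to_newick(Z, list(ordered.index)))


def loess_fc_trend(values, span: float = 0.05, positions=None) -> np.ndarray:
    """Loess-smoothed trend of ordered fold changes.

    Local linear regression with tricube weights over the ordered positions
    (``statsmodels`` lowess). ``span`` is the fraction of points per local
    window; the effective window must cover at least 3 points.
    """
    y = np.asarray(values, dtype=float)
    n = y.size
    if n < 5:
        raise ValueError("need at least 5 points to smooth")
    if not 0 < span <= 1:
        raise ValueError("span must lie in (0, 1]")
    if int(span * n) < 3:
        raise ValueError(f"span {span} covers fewer than 3 of {n} points")
    x = np.arange(n, dtype=float) if positions is None else np.asarray(positions, dtype=float)
    smoothed = lowess(y, x, frac=span, it=1, return_sorted=False)
    return np.asarray(smoothed, dtype=float)
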