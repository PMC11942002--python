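"""Comparative signature statistics for ranked gene lists and gene sets.

This module houses the study-style comparative statistics:

* a cumulative-overlap **area enrichment** statistic — the signed area
  between a gene set's cumulative-overlap curve along a ranked list and the
  diagonal expected under uniform placement, with a set-membership
  permutation p-value and a rank-sum normal approximation;
* a **resampling null for gene-set mean fold change** — the observed mean FC
  of a signature set judged against the mean FC of random same-size sets;
* **rank-overlap** curves between two rankings with a hypergeometric
  (Fisher) test at a chosen cutoff;
* signature extraction (top-k lowest-p genes with a direction-consistent
  FC), time-course slope ranking, log-space hypergeometric tails, and
  Spearman correlation of fold-change profiles.

The area statistic has an exact closed form in terms of the mean rank of the
set, A = ((N+1)/2 − r̄)/N, which ties it to the Wilcoxon rank-sum statistic;
the permutation and normal p-values both build on this identity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp
from scipy.stats import norm, spearmanr

from .genesets import GeneSet

__all__ = [
    "RankedList",
    "AreaEnrichmentResult",
    "ResamplingResult",
    "RankOverlapResult",
    "SpearmanResult",
    "rank_by_fc",
    "cumulative_overlap_curve",
    "area_from_ranks",
    "area_enrichment",
    "mean_fc_resampling",
    "select_top_signature",
    "slope_ranking",
    "fisher_overlap",
    "rank_overlap",
    "fc_spearman",
]


# ---------------------------------------------------------------------------
# containers


@dataclass(frozen=True)
class RankedList:
    """Ordered gene identifiers, rank 1 = strongest by the stated criterion."""

    genes: tuple
    criterion: str = ""

    def __post_init__(self):
        genes = tuple(self.genes)
        if len(set(genes)) != len(genes):
            raise ValueError("ranked list contains duplicate gene ids")
        object.__setattr__(self, "genes", genes)

    @property
    def N(self) -> int:
        return len(self.genes)

    def reversed(self) -> "RankedList":
        return RankedList(genes=self.genes[::-1], criterion=f"reversed({self.criterion})")


@dataclass
class AreaEnrichmentResult:
    area: float
    p_perm: float
    p_normal: float
    n_perm: int
    seed: Optional[int]
    curve: np.ndarray
    m: int
    N: int
    alternative: str


@dataclass
class ResamplingResult:
    observed_mean_fc: float
    percent_shift: float
    p: float
    n_resamples: int
    seed: Optional[int]
    alternative: str
    mode: str
    m: int
    null_mean: float
    null_sd: float
    null_q025: float
    null_q975: float


@dataclass
class RankOverlapResult:
    overlap: np.ndarray  # overlap count at each rank k = 1..K
    K: int
    N: int
    contingency: np.ndarray  # 2x2 table at k = K
    fisher_p: float


@dataclass
class SpearmanResult:
    r: float
    p: float
    n: int


# ---------------------------------------------------------------------------
# ranking


def rank_by_fc(de: pd.DataFrame, direction: str = "up") -> RankedList:
    """Rank tested genes by fold change.

    ``direction='up'`` sorts by descending FC (rank 1 = most increased),
    ``'down'`` by ascending FC. Ties are broken by ascending raw p-value and
    then lexicographic gene id, so the ranking is deterministic.
    """
    if direction not in ("up", "down"):
        raise ValueError(f"direction must be 'up' or 'down', got {direction!r}")
    t = de[de["tested"].astype(bool)] if "tested" in de.columns else de
    if t.empty:
        raise ValueError("no tested genes to rank")
    t = t.reset_index().rename(columns={t.index.name or "index": "gene"})
    t = t.sort_values(
        by=["fc", "p", "gene"],
        ascending=[direction == "down", True, True],
        kind="mergesort",
    )
    return RankedList(genes=tuple(t["gene"]), criterion=f"fc_{direction}")


# ---------------------------------------------------------------------------
# cumulative-overlap area statistic


def _membership(ranked: RankedList, gene_set: GeneSet) -> np.ndarray:
    members = gene_set.as_set() if isinstance(gene_set, GeneSet) else frozenset(gene_set)
    universe = set(ranked.genes)
    dropped = members - universe
    if dropped:
        warnings.warn(
            f"{len(dropped)} gene(s) of set "
            f"{getattr(gene_set, 'name', '?')!r} absent from the ranked universe; dropped"
        )
        members = members - dropped
    if not members:
        raise ValueError("gene set has no members in the ranked universe")
    return np.fromiter((g in members for g in ranked.genes), dtype=bool, count=ranked.N)


def cumulative_overlap_curve(ranked: RankedList, gene_set: GeneSet) -> np.ndarray:
    """C(k) = |set ∩ top-k| / m for k = 1..N (nondecreasing, C(N) = 1)."""
    mask = _membership(ranked, gene_set)
    return np.cumsum(mask) / mask.sum()


def area_from_ranks(ranks, N: int) -> float:
    """Closed-form area: A = ((N+1)/2 − mean rank of the set)/N."""
    ranks = np.asarray(ranks, dtype=float)
    return float(((N + 1) / 2.0 - ranks.mean()) / N)


def _sample_mean_ranks(rng: np.random.Generator, N: int, m: int, n_draws: int) -> np.ndarray:
    """Mean rank of ``n_draws`` random size-m subsets of {1..N}, without
    replacement, vectorized in memory-bounded chunks."""
    out = np.empty(n_draws)
    chunk = max(1, int(4_000_000 // max(N, 1)))
    done = 0
    while done < n_draws:
        take = min(chunk, n_draws - done)
        keys = rng.random((take, N))
        idx = np.argpartition(keys, m - 1, axis=1)[:, :m]
        out[done : done + take] = idx.mean(axis=1) + 1.0
        done += take
    return out


def area_enrichment(
    ranked: RankedList,
    gene_set: GeneSet,
    n_perm: int = 10000,
    seed: Optional[int] = None,
    alternative: str = "two-sided",
) -> AreaEnrichmentResult:
    """Area between the cumulative-overlap curve and the diagonal, with a
    set-membership permutation p-value.

    A > 0 means the set is concentrated toward the top of the ranking (e.g.
    differentiation-increased genes enriched among treatment-increased
    genes); A < 0 toward the bottom. The permutation null redraws size-m
    gene sets uniformly from the ranked universe; the default two-sided
    p-value is (1 + #{|A_null| ≥ |A_obs|})/(n_perm + 1). A normal
    approximation based on the Wilcoxon rank-sum variance of the mean set
    rank is reported alongside.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if alternative not in ("two-sided", "greater", "less"):
        raise ValueError(f"unknown alternative {alternative!r}")
    mask = _membership(ranked, gene_set)
    N, m = ranked.N, int(mask.sum())
    curve = np.cumsum(mask) / m
    area = float(np.sum(curve - np.arange(1, N + 1) / N) / N)

    rng = np.random.default_rng(seed)
    null_mean_ranks = _sample_mean_ranks(rng, N, m, n_perm)
    null_areas = ((N + 1) / 2.0 - null_mean_ranks) / N
    if alternative == "two-sided":
        exceed = np.abs(null_areas) >= abs(area) - 1e-12
    elif alternative == "greater":
        exceed = null_areas >= area - 1e-12
    else:
        exceed = null_areas <= area + 1e-12
    p_perm = (1.0 + int(exceed.sum())) / (n_perm + 1.0)

    var_area = (N - m) * (N + 1) / (12.0 * m * N * N) if N > m else 0.0
    if var_area > 0:
        z = area / np.sqrt(var_area)
        if alternative == "two-sided":
            p_normal = float(2.0 * norm.sf(abs(z)))
        elif alternative == "greater":
            p_normal = float(norm.sf(z))
        else:
            p_normal = float(norm.cdf(z))
    else:
        p_normal = 1.0

    return AreaEnrichmentResult(
        area=area,
        p_perm=float(p_perm),
        p_normal=p_normal,
        n_perm=n_perm,
        seed=seed,
        curve=curve,
        m=m,
        N=N,
        alternative=alternative,
    )


# ---------------------------------------------------------------------------
# resampling null for gene-set mean fold change


def mean_fc_resampling(
    fc_map: pd.Series,
    gene_set: GeneSet,
    n_resamples: int = 10000,
    seed: Optional[int] = None,
    alternative: str = "two-sided",
    mode: str = "arithmetic",
) -> ResamplingResult:
    """Observed mean fold change of a gene set against a resampling null.

    The null distribution is the mean FC of ``n_resamples`` random gene sets
    of matched size drawn without replacement from all genes in ``fc_map``.
    The default two-sided p-value compares distances from the null mean with
    an add-one correction; ``percent_shift`` reports (mean FC − 1)·100, so a
    set decreased by 12% on average has percent_shift ≈ −12. ``mode``
    selects the arithmetic (default, matching a linear FC axis) or geometric
    mean.
    """
    if alternative not in ("two-sided", "greater", "less"):
        raise ValueError(f"unknown alternative {alternative!r}")
    if mode not in ("arithmetic", "geometric"):
        raise ValueError(f"unknown mode {mode!r}")
    if n_resamples < 1:
        raise ValueError("n_resamples must be >= 1")
    fc_map = fc_map.dropna()
    members = gene_set.as_set() if isinstance(gene_set, GeneSet) else frozenset(gene_set)
    present = [g for g in fc_map.index if g in members]
    dropped = len(members) - len(present)
    if dropped:
        warnings.warn(f"{dropped} gene(s) of the set absent from the FC universe; dropped")
    m = len(present)
    N = fc_map.size
    if m == 0:
        raise ValueError("gene set has no members in the FC universe")
    if m > N:
        raise ValueError("gene set larger than the FC universe")

    values = fc_map.to_numpy(float)
    if mode == "geometric":
        logs = np.log(values)
        observed = float(np.exp(np.mean(logs[fc_map.index.isin(present)])))
    else:
        observed = float(values[fc_map.index.isin(present)].mean())

    rng = np.random.default_rng(seed)
    null_means = np.empty(n_resamples)
    chunk = max(1, int(4_000_000 // max(N, 1)))
    done = 0
    basis = logs if mode == "geometric" else values
    while done < n_resamples:
        take = min(chunk, n_resamples - done)
        keys = rng.random((take, N))
        idx = np.argpartition(keys, m - 1, axis=1)[:, :m]
        null_means[done : done + take] = basis[idx].mean(axis=1)
        done += take
    if mode == "geometric":
        null_means = np.exp(null_means)

    null_center = float(null_means.mean())
    if alternative == "two-sided":
        exceed = np.abs(null_means - null_center) >= abs(observed - null_center) - 1e-12
    elif alternative == "greater":
        exceed = null_means >= observed - 1e-12
    else:
        exceed = null_means <= observed + 1e-12
    p = (1.0 + int(exceed.sum())) / (n_resamples + 1.0)

    return ResamplingResult(
        observed_mean_fc=observed,
        percent_shift=(observed - 1.0) * 100.0,
        p=float(p),
        n_resamples=n_resamples,
        seed=seed,
        alternative=alternative,
        mode=mode,
        m=m,
        null_mean=null_center,
        null_sd=float(null_means.std(ddof=1)) if n_resamples > 1 else 0.0,
        null_q025=float(np.quantile(null_means, 0.025)),
        null_q975=float(np.quantile(null_means, 0.975)),
    )


# ---------------------------------------------------------------------------
# signature extraction and slope ranking


def select_top_signature(
    de: pd.DataFrame,
    k: int,
    direction: str = "up",
    name: Optional[str] = None,
) -> GeneSet:
    """Top-k signature genes of a reference contrast.

    Filters to direction-consistent fold changes (FC > 1 for ``'up'``,
    FC < 1 for ``'down'``), sorts by ascending raw p-value (ties by gene
    id), and returns the first ``k``. If fewer than ``k`` genes qualify,
    all qualifying genes are returned with a warning.
    """
    if k < 0:
        raise ValueError("k must be >= 0")
    if direction not in ("up", "down"):
        raise ValueError(f"direction must be 'up' or 'down', got {direction!r}")
    t = de[de["tested"].astype(bool)] if "tested" in de.columns else de
    qual = t[t["fc"] > 1.0] if direction == "up" else t[t["fc"] < 1.0]
    qual = qual.reset_index().rename(columns={qual.index.name or "index": "gene"})
    qual = qual.sort_values(by=["p", "gene"], kind="mergesort")
    if len(qual) < k:
        warnings.warn(f"only {len(qual)} genes qualify for a top-{k} signature; returning all")
    genes = tuple(qual["gene"].head(k)) if k else tuple()
    return GeneSet(name=name or f"top{k}_{direction}", genes=genes, direction=direction)


def slope_ranking(
    timecourse: Sequence[pd.DataFrame],
    days: Optional[Sequence[float]] = None,
) -> tuple:
    """Rank genes by the OLS slope of log2FC against day index.

    Genes missing from any day are dropped with a warning. Returns
    ``(RankedList, slopes)`` with slopes as a Series; the ranking is by
    descending slope with ties broken by gene id.
    """
    if len(timecourse) < 2:
        raise ValueError("slope ranking needs at least 2 time points")
    if days is None:
        days = np.arange(1, len(timecourse) + 1, dtype=float)
    else:
        days = np.asarray(days, dtype=float)
    common = timecourse[0].index
    for table in timecourse[1:]:
        common = common.intersection(table.index)
    dropped = max(len(t.index) for t in timecourse) - len(common)
    if dropped > 0:
        warnings.warn(f"{dropped} gene(s) missing from at least one day; dropped")
    Y = np.column_stack([t.loc[common, "log2fc"].to_numpy(float) for t in timecourse])
    d_centered = days - days.mean()
    slopes = Y @ d_centered / np.sum(d_centered**2)
    slopes = pd.Series(slopes, index=common, name="slope")
    order = sorted(common, key=lambda g: (-slopes[g], g))
    return RankedList(genes=tuple(order), criterion="timecourse_slope"), slopes


# ---------------------------------------------------------------------------
# hypergeometric overlap


def fisher_overlap(k: int, m1: int, m2: int, N: int) -> float:
    """One-sided (enrichment) hypergeometric tail P(X ≥ k).

    X counts successes among ``m2`` draws without replacement from a
    universe of ``N`` containing ``m1`` successes. Computed by log-space
    summation (gammaln + logsumexp) so that extreme tails (p ~ 1e-100)
    remain accurate.
    """
    k, m1, m2, N = int(k), int(m1), int(m2), int(N)
    if min(k, m1, m2, N) < 0 or m1 > N or m2 > N or k > min(m1, m2):
        raise ValueError(f"inconsistent overlap counts k={k}, m1={m1}, m2={m2}, N={N}")
    k_min = max(0, m1 + m2 - N)
    if k < k_min:
        raise ValueError(f"overlap k={k} below the minimum possible {k_min}")
    if k == k_min:
        return 1.0
    i = np.arange(k, min(m1, m2) + 1, dtype=float)

    def log_comb(n, r):
        return gammaln(n + 1) - gammaln(r + 1) - gammaln(n - r + 1)

    log_terms = log_comb(m1, i) + log_comb(N - m1, m2 - i) - log_comb(N, m2)
    return float(min(1.0, np.exp(logsumexp(log_terms))))


def rank_overlap(ranking_a: RankedList, ranking_b: RankedList, K: int) -> RankOverlapResult:
    """Overlap of the top-k genes of two rankings for k = 1..K.

    The two rankings are restricted to their shared universe (with a warning
    if they differ); the contingency table and one-sided Fisher test are
    evaluated at k = K.
    """
    shared = set(ranking_a.genes) & set(ranking_b.genes)
    if len(shared) != ranking_a.N or len(shared) != ranking_b.N:
        warnings.warn("rankings have different universes; restricted to the intersection")
    genes_a = [g for g in ranking_a.genes if g in shared]
    genes_b = [g for g in ranking_b.genes if g in shared]
    N = len(shared)
    if K > N:
        raise ValueError(f"K={K} exceeds the shared universe size N={N}")
    if K < 1:
        raise ValueError("K must be >= 1")
    rank_b = {g: i + 1 for i, g in enumerate(genes_b)}
    max_rank = np.array([max(i + 1, rank_b[g]) for i, g in enumerate(genes_a)])
    counts = np.bincount(max_rank, minlength=N + 1)
    overlap = np.cumsum(counts)[1 : K + 1]
    k_obs = int(overlap[-1])
    table = np.array([[k_obs, K - k_obs], [K - k_obs, N - 2 * K + k_obs]])
    p = fisher_overlap(k_obs, K, K, N)
    return RankOverlapResult(overlap=overlap, K=K, N=N, contingency=table, fisher_p=p)


# ---------------------------------------------------------------------------
# fold-change profile correlation


def fc_spearman(de_a: pd.DataFrame, de_b: pd.DataFrame) -> SpearmanResult:
    """Spearman rank correlation between two comparisons' fold changes.

    Computed on the genes tested in both tables, with average-rank handling
    of ties and the large-sample p-value.
    """
    ta = de_a[de_a["tested"].astype(bool)] if "tested" in de_a.columns else de_a
    tb = de_b[de_b["tested"].astype(bool)] if "tested" in de_b.columns else de_b
    shared = ta.index.intersection(tb.index)
    if len(shared) < 3:
        raise ValueError("fewer than 3 shared tested genes")
    r, p = spearmanr(ta.loc[shared, "fc"], tb.loc[shared, "fc"])
    return SpearmanResult(r=float(r), p=float(p), n=len(shared))
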