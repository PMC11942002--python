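"""Synthetic study generator: count matrices, reference time-course DE
tables and signature/annotation libraries with known planted structure.

The generator emulates a four-arm treatment study on a reconstructed skin
model — control plus three compounds (CTL, LYS, CDL, ZDL), three replicates
per arm — over a transcriptome-scale universe of detectable genes. Counts
are negative-binomial with log-uniform baseline abundances, gene-wise (or
constant) dispersion and unequal library sizes; treatment effects are
planted on named gene sets as log2 fold-change draws, and every planted
quantity is recorded in a :class:`SyntheticTruth` object for downstream
recovery testing.

Default planted effects mirror the study conditions the pipeline is built
to analyse: a late-differentiation program up-regulated by the zinc-salt
arm (ZDL), an early-differentiation program modestly down-regulated by it,
a disease (melanoma-up) signature decreased ~12% on average, a disease-down
signature increased ~5%, a moderate CDL response, and a minimal LYS
response. Senescence sets are planted as memberships with no expression
effect (no overall shift), matching the reported behaviour of those panels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.stats import norm

from .expression import ExpressionMatrix, bh_adjust
from .genesets import GeneSet, SignatureLibrary
from .seeding import stage_rng

__all__ = [
    "PlantedEffect",
    "SyntheticConfig",
    "SyntheticTruth",
    "nb_counts",
    "generate_counts",
    "generate_timecourse_reference",
    "generate_signature_library",
    "default_planted_effects",
]


@dataclass(frozen=True)
class PlantedEffect:
    """A named gene set with a planted treatment effect.

    ``log2fc_mean``/``log2fc_sd`` parameterize the normal draw of per-gene
    log2 fold changes applied in the listed treatment groups. A mean of 0
    with sd 0 plants set membership only (no expression shift). ``direction``
    is a display label; when omitted it is inferred from the sign of
    ``log2fc_mean``. ``min_baseline_mean`` restricts the set to genes whose
    baseline mean count is at least that value — appropriate for marker
    programs (e.g. cornified-envelope genes) that are abundant transcripts
    and for which fold changes are meaningfully measurable at small n.
    """

    name: str
    size: int
    groups: Tuple[str, ...]
    log2fc_mean: float = 0.0
    log2fc_sd: float = 0.0
    direction: Optional[str] = None
    min_baseline_mean: Optional[float] = None

    def __post_init__(self):
        if self.size < 0:
            raise ValueError("planted set size must be >= 0")
        if self.log2fc_sd < 0:
            raise ValueError("log2fc_sd must be >= 0")
        if self.direction is None:
            inferred = "up" if self.log2fc_mean >= 0 else "down"
            object.__setattr__(self, "direction", inferred)
        object.__setattr__(self, "groups", tuple(self.groups))


def default_planted_effects(groups: Sequence[str] = ("CTL", "LYS", "CDL", "ZDL")) -> List[PlantedEffect]:
    """Planted effects emulating the study conditions (see module docstring)."""
    _, lys, cdl, zdl = groups[0], groups[1], groups[2], groups[3]
    return [
        PlantedEffect("late_diff", 50, (zdl,), +1.0, 0.5, "up", min_baseline_mean=50.0),
        PlantedEffect("early_diff", 50, (zdl,), -0.43, 0.30, "down", min_baseline_mean=50.0),
        PlantedEffect("melanoma_up", 200, (zdl,), -0.19, 0.20, "down"),
        PlantedEffect("melanoma_down", 200, (zdl,), +0.07, 0.20, "up"),
        PlantedEffect("cdl_response_up", 150, (cdl,), +0.70, 0.40, "up"),
        PlantedEffect("cdl_response_down", 150, (cdl,), -0.70, 0.40, "down"),
        PlantedEffect("lys_response", 20, (lys,), +0.80, 0.30, "up"),
        PlantedEffect("pro_senescence", 50, (), 0.0, 0.0, "up"),
        PlantedEffect("anti_senescence", 50, (), 0.0, 0.0, "down"),
        PlantedEffect("mitosis_markers", 10, (), 0.0, 0.0),
        PlantedEffect("basal_markers", 10, (), 0.0, 0.0),
    ]


@dataclass
class SyntheticConfig:
    """Configuration of the synthetic study.

    Defaults reproduce the emulated study design: 4 treatment groups × 3
    replicates over 14,600 detectable genes, NB dispersion 0.1, log-uniform
    baseline abundances, unequal library sizes and a 7-day reference time
    course.
    """

    n_genes: int = 14600
    groups: Tuple[str, ...] = ("CTL", "LYS", "CDL", "ZDL")
    n_replicates: int = 3
    #: natural-log bounds of the log-uniform baseline mean counts
    baseline_logmean_range: Tuple[float, float] = (np.log(2.0), np.log(2000.0))
    #: NB dispersion phi (variance = mu + phi*mu^2); scalar or per-gene array
    dispersion: float = 0.1
    #: total-count bounds per sample; None = (0.8, 1.6) × expected gene total
    libsize_range: Optional[Tuple[float, float]] = None
    planted_effects: Optional[List[PlantedEffect]] = None
    timecourse_days: int = 7
    #: log2FC-per-day slope bounds for late-program genes
    late_slope_range: Tuple[float, float] = (0.3, 1.0)
    #: day-1 log2FC amplitude bounds for early-program genes
    early_amplitude_range: Tuple[float, float] = (1.0, 2.5)
    #: sampling noise scale for time-course log2FC → p conversion
    timecourse_sigma: float = 0.25
    #: sizes / overlap of the five annotation source lists
    n_sources: int = 5
    source_size: int = 100
    source_overlap: float = 0.4
    marker_panel_size: int = 10
    seed: int = 0

    def __post_init__(self):
        if self.n_replicates < 2:
            raise ValueError("n_replicates must be >= 2")
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if np.any(np.asarray(self.dispersion) <= 0):
            raise ValueError("dispersion must be > 0")
        if self.timecourse_days < 2:
            raise ValueError("timecourse_days must be >= 2")
        if self.libsize_range is not None and min(self.libsize_range) <= 0:
            raise ValueError("libsize_range must be positive")
        self.groups = tuple(self.groups)
        if self.planted_effects is None:
            # the default study-like effects assume the four-arm design
            self.planted_effects = (
                default_planted_effects(self.groups) if len(self.groups) >= 4 else []
            )
        self.planted_effects = [
            e if isinstance(e, PlantedEffect) else PlantedEffect(**e) for e in self.planted_effects
        ]
        total = sum(e.size for e in self.planted_effects)
        if total > self.n_genes:
            raise ValueError(
                f"planted sets need {total} genes but only {self.n_genes} are generated"
            )
        for effect in self.planted_effects:
            unknown = set(effect.groups) - set(self.groups)
            if unknown:
                raise ValueError(f"planted effect {effect.name!r} targets unknown group(s) {unknown}")

    @property
    def gene_ids(self) -> pd.Index:
        width = max(6, len(str(self.n_genes)))
        return pd.Index([f"G{i:0{width}d}" for i in range(1, self.n_genes + 1)], name="gene")

    @property
    def sample_ids(self) -> List[str]:
        return [f"{g}_{r}" for g in self.groups for r in range(1, self.n_replicates + 1)]


@dataclass
class SyntheticTruth:
    """Planted per-gene effects and set memberships.

    ``true_log2fc`` is a gene × group table (0 outside planted sets);
    ``memberships`` maps set name → gene tuple; ``timecourse_slopes`` holds
    the planted per-gene log2FC/day slope (0 until the time-course generator
    fills it).
    """

    true_log2fc: pd.DataFrame
    memberships: Dict[str, tuple]
    timecourse_slopes: pd.Series

    def members(self, name: str) -> GeneSet:
        if name not in self.memberships:
            raise KeyError(f"no planted set named {name!r}")
        return GeneSet(name=name, genes=self.memberships[name])


# ---------------------------------------------------------------------------
# count generation


def nb_counts(rng: np.random.Generator, mean, dispersion) -> np.ndarray:
    """Negative-binomial draws parameterized by mean and dispersion phi
    (variance = mean + phi·mean²). Zero means yield zero counts."""
    mean = np.asarray(mean, dtype=float)
    phi = np.broadcast_to(np.asarray(dispersion, dtype=float), mean.shape)
    r = 1.0 / phi
    out = np.zeros(mean.shape, dtype=np.int64)
    pos = mean > 0
    p = r[pos] / (r[pos] + mean[pos])
    out[pos] = rng.negative_binomial(r[pos], p)
    return out


def generate_counts(config: SyntheticConfig) -> Tuple[ExpressionMatrix, SyntheticTruth]:
    """Generate the count matrix and its planted truth.

    Baseline abundances are log-uniform; per-sample expected counts are the
    library size times the sample's normalized gene proportions (so planted
    effects shift group means by 2^log2FC while library sizes stay at their
    drawn totals in expectation); counts are NB draws around those means.
    Identical configs (including seed) give identical output.
    """
    genes = config.gene_ids
    samples = config.sample_ids
    design = pd.Series(
        [g for g in config.groups for _ in range(config.n_replicates)], index=samples
    )

    rng = stage_rng(config.seed, "counts")
    lo, hi = config.baseline_logmean_range
    mu = np.exp(rng.uniform(lo, hi, config.n_genes))
    lengths = np.exp(rng.uniform(np.log(500.0), np.log(10_000.0), config.n_genes))
    lengths = np.round(lengths).astype(int)

    lfc = pd.DataFrame(0.0, index=genes, columns=list(config.groups))
    memberships: Dict[str, tuple] = {}
    pool = list(range(config.n_genes))
    for effect in config.planted_effects:
        if effect.min_baseline_mean is not None:
            candidates = [i for i in pool if mu[i] >= effect.min_baseline_mean]
        else:
            candidates = pool
        if len(candidates) < effect.size:
            raise ValueError(
                f"planted set {effect.name!r} needs {effect.size} genes but only "
                f"{len(candidates)} eligible genes remain"
            )
        chosen = rng.choice(len(candidates), size=effect.size, replace=False)
        chosen_idx = sorted(candidates[i] for i in chosen)
        pool = [g for i, g in enumerate(pool) if g not in set(chosen_idx)]
        member_genes = tuple(genes[i] for i in chosen_idx)
        memberships[effect.name] = member_genes
        if effect.groups and (effect.log2fc_mean != 0 or effect.log2fc_sd != 0):
            draws = rng.normal(effect.log2fc_mean, effect.log2fc_sd, effect.size)
            for group in effect.groups:
                lfc.loc[list(member_genes), group] = draws

    if config.libsize_range is None:
        expected_total = mu.sum()
        lib_lo, lib_hi = 0.8 * expected_total, 1.6 * expected_total
    else:
        lib_lo, lib_hi = config.libsize_range
    lib_targets = rng.uniform(lib_lo, lib_hi, len(samples))

    counts = np.empty((config.n_genes, len(samples)), dtype=np.int64)
    for j, sample in enumerate(samples):
        group = design[sample]
        weights = mu * np.exp2(lfc[group].to_numpy())
        p = weights / weights.sum()
        means = lib_targets[j] * p
        counts[:, j] = nb_counts(rng, means, config.dispersion)

    matrix = ExpressionMatrix(
        counts=pd.DataFrame(counts, index=genes, columns=samples),
        gene_lengths=pd.Series(lengths, index=genes, dtype=float),
        design=design,
    )
    truth = SyntheticTruth(
        true_log2fc=lfc,
        memberships=memberships,
        timecourse_slopes=pd.Series(0.0, index=genes, name="slope"),
    )
    return matrix, truth


# ---------------------------------------------------------------------------
# reference time course


def generate_timecourse_reference(
    config: SyntheticConfig,
    truth: Optional[SyntheticTruth] = None,
) -> Tuple[List[pd.DataFrame], SyntheticTruth]:
    """Per-day DE tables emulating a processed epidermal-regeneration
    reference time course.

    Genes in the planted "late program" (``late_diff`` membership) follow a
    deterministic monotone ramp, log2FC = slope·day, with slopes drawn from
    ``late_slope_range``; the "early program" (``early_diff``) peaks on day
    1 and decays linearly to zero. Background genes draw z ~ N(0,1) per day
    with log2FC = sigma·z, so their p-values (two-sided normal) are exactly
    uniform under the null. Planted slopes are recorded in the returned
    truth.

    Returns ``(tables, truth)`` — one DE table per day with ``fc``,
    ``log2fc``, ``p`` and ``tested`` columns.
    """
    if truth is None:
        truth = SyntheticTruth(
            true_log2fc=pd.DataFrame(index=config.gene_ids, columns=list(config.groups), data=0.0),
            memberships={},
            timecourse_slopes=pd.Series(0.0, index=config.gene_ids, name="slope"),
        )
    genes = truth.true_log2fc.index
    rng = stage_rng(config.seed, "timecourse")
    sigma = config.timecourse_sigma
    days = np.arange(1, config.timecourse_days + 1)

    late = list(truth.memberships.get("late_diff", ()))
    early = list(truth.memberships.get("early_diff", ()))
    slopes = pd.Series(0.0, index=genes, name="slope")
    late_slopes = rng.uniform(*config.late_slope_range, len(late))
    early_amp = rng.uniform(*config.early_amplitude_range, len(early))
    slopes[late] = late_slopes
    # early program: log2FC_d = amp·(D - d)/(D - 1) → OLS slope = -amp/(D-1)
    slopes[early] = -early_amp / (config.timecourse_days - 1)
    truth.timecourse_slopes = slopes

    lookup = pd.Series(np.arange(len(genes)), index=genes)
    tables: List[pd.DataFrame] = []
    for d in days:
        z = rng.standard_normal(len(genes))
        log2fc = sigma * z
        if late:
            log2fc[lookup[late].to_numpy()] = late_slopes * d
        if early:
            log2fc[lookup[early].to_numpy()] = early_amp * (config.timecourse_days - d) / (
                config.timecourse_days - 1
            )
        p = 2.0 * norm.sf(np.abs(log2fc) / sigma)
        table = pd.DataFrame(
            {
                "fc": np.exp2(log2fc),
                "log2fc": log2fc,
                "p": np.minimum(p, 1.0),
                "fdr": np.nan,
                "tested": True,
            },
            index=genes,
        )
        table["fdr"] = bh_adjust(table["p"].to_numpy())
        table.index.name = "gene"
        table.attrs["day"] = int(d)
        tables.append(table)
    return tables, truth


# ---------------------------------------------------------------------------
# signature library


def generate_signature_library(
    truth: SyntheticTruth,
    config: SyntheticConfig,
) -> SignatureLibrary:
    """Directional disease signatures, five partially overlapping annotation
    source lists, senescence sets, and four marker panels.

    Disease and senescence sets are the planted memberships when present
    (falling back to random background genes otherwise). Each annotation
    source list shares a common core of ``round(source_overlap ×
    source_size)`` genes — with overlap 0 the five lists are pairwise
    disjoint; core genes therefore appear in all five sources and survive a
    ≥3-of-5 evidence filter.
    """
    genes = list(truth.true_log2fc.index)
    rng = stage_rng(config.seed, "signature_library")
    planted = set(g for members in truth.memberships.values() for g in members)
    background = [g for g in genes if g not in planted]

    def take_background(n: int) -> list:
        if n > len(background):
            raise ValueError(f"requested {n} signature genes but only {len(background)} remain")
        chosen = rng.choice(len(background), size=n, replace=False)
        chosen = sorted(chosen, reverse=True)
        return [background.pop(i) for i in chosen][::-1]

    def planted_or_background(name: str, n: int) -> tuple:
        if name in truth.memberships:
            return tuple(truth.memberships[name])
        return tuple(take_background(n))

    library = SignatureLibrary()
    library.add(
        GeneSet("disease_up", planted_or_background("melanoma_up", 200), direction="up", source="synthetic")
    )
    library.add(
        GeneSet("disease_down", planted_or_background("melanoma_down", 200), direction="down", source="synthetic")
    )
    library.add(GeneSet("pro_senescence", planted_or_background("pro_senescence", 50), source="synthetic"))
    library.add(GeneSet("anti_senescence", planted_or_background("anti_senescence", 50), source="synthetic"))

    core_size = int(round(config.source_overlap * config.source_size))
    core = take_background(core_size)
    for i in range(1, config.n_sources + 1):
        unique = take_background(config.source_size - core_size)
        library.add(GeneSet(f"aging_source_{i}", tuple(core + unique), source=f"source{i}"))

    panel_n = config.marker_panel_size
    for panel, origin in (
        ("mitosis_panel", "mitosis_markers"),
        ("basal_panel", "basal_markers"),
        ("early_panel", "early_diff"),
        ("late_panel", "late_diff"),
    ):
        if origin in truth.memberships:
            members = truth.memberships[origin][:panel_n]
        else:
            members = tuple(take_background(panel_n))
        library.add(GeneSet(panel, tuple(members), source="marker_panel"))
    return library
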