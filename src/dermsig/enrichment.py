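"""Overrepresentation testing, evidence aggregation, marker-panel reports,
senescence summaries, qPCR relative quantification and LSD letter displays.

Overrepresentation analysis (ORA) is a hypergeometric upper-tail test of a
query gene set against each term of a user-supplied term library, evaluated
within an explicit gene universe (by default the comparison's
detectability-filtered tested universe) with Benjamini–Hochberg correction
across terms. Terms are taken as given — no ontology propagation is
performed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .expression import bh_adjust
from .genesets import GeneSet
from .signatures import ResamplingResult, fisher_overlap, mean_fc_resampling

__all__ = [
    "ora_test",
    "evidence_table",
    "aggregate_evidence",
    "panel_report",
    "SenescenceSummary",
    "senescence_summary",
    "DdctResult",
    "ddct",
    "LSDResult",
    "lsd_groups",
]


# ---------------------------------------------------------------------------
# overrepresentation


def ora_test(
    query,
    universe: Sequence[str],
    library: Mapping[str, GeneSet],
    max_examples: int = 10,
) -> pd.DataFrame:
    """Hypergeometric overrepresentation of a query set in each library term.

    Terms are intersected with the universe (terms with zero universe
    overlap are dropped); the query is restricted to the universe. Returns a
    DataFrame sorted by p with columns term, term_size, overlap, expected,
    enrichment_ratio, p, fdr, example_genes.
    """
    universe = pd.Index(pd.unique(pd.Series(list(universe))))
    if universe.empty:
        raise ValueError("empty gene universe")
    uni = set(universe)
    query_genes = set(query.genes if isinstance(query, GeneSet) else query)
    outside = query_genes - uni
    if outside:
        warnings.warn(f"{len(outside)} query gene(s) outside the universe; dropped")
        query_genes &= uni
    N, q = len(uni), len(query_genes)
    rows = []
    for name in library:
        term = library[name]
        term_genes = term.as_set() & uni
        if not term_genes:
            continue
        overlap = term_genes & query_genes
        k, t = len(overlap), len(term_genes)
        expected = t * q / N
        rows.append(
            {
                "term": name,
                "term_size": t,
                "overlap": k,
                "expected": expected,
                "enrichment_ratio": k / expected if expected > 0 else np.nan,
                "p": fisher_overlap(k, t, q, N),
                "example_genes": ";".join(sorted(overlap)[:max_examples]),
            }
        )
    result = pd.DataFrame(rows)
    if result.empty:
        return result
    result["fdr"] = bh_adjust(result["p"].to_numpy())
    result = result.sort_values(["p", "term"], kind="mergesort").reset_index(drop=True)
    return result[["term", "term_size", "overlap", "expected", "enrichment_ratio", "p", "fdr", "example_genes"]]


# ---------------------------------------------------------------------------
# multi-source evidence aggregation


def evidence_table(sources: Mapping[str, Iterable[str]]) -> pd.DataFrame:
    """Gene → supporting source labels, one row per gene.

    Columns: ``sources`` (semicolon-joined sorted labels) and ``n_sources``.
    """
    support: Dict[str, set] = {}
    for label in sources:
        for gene in sources[label]:
            support.setdefault(gene, set()).add(label)
    rows = [
        {"gene": gene, "sources": ";".join(sorted(labels)), "n_sources": len(labels)}
        for gene, labels in support.items()
    ]
    table = pd.DataFrame(rows, columns=["gene", "sources", "n_sources"])
    return table.sort_values(["n_sources", "gene"], ascending=[False, True], kind="mergesort").set_index("gene")


def aggregate_evidence(
    sources: Mapping[str, Iterable[str]],
    min_sources: int = 3,
    expressed: Optional[Iterable[str]] = None,
    name: str = "aggregated_evidence",
) -> GeneSet:
    """Genes supported by at least ``min_sources`` of the source lists and
    (when given) present in the expressed-gene universe."""
    if min_sources < 1:
        raise ValueError("min_sources must be >= 1")
    table = evidence_table(sources)
    keep = table.index[table["n_sources"] >= min_sources]
    if expressed is not None:
        expressed_set = set(expressed)
        keep = [g for g in keep if g in expressed_set]
    return GeneSet(name=name, genes=tuple(sorted(keep)))


# ---------------------------------------------------------------------------
# marker-panel report


def panel_report(
    de_tables: Mapping[str, pd.DataFrame],
    panels: Mapping[str, GeneSet],
    *,
    fdr_threshold: float = 0.10,
    p_threshold: float = 0.05,
) -> pd.DataFrame:
    """Per-panel fold-change table with significance flags.

    For each panel gene and treatment: FC, ``'**'`` if FDR < 0.10, else
    ``'*'`` if p < 0.05, else no flag; plus an increased/decreased direction
    annotation. Genes absent from a comparison are flagged
    ``present=False``.
    """
    rows = []
    for panel_name in panels:
        for gene in panels[panel_name].genes:
            for treatment in de_tables:
                de = de_tables[treatment]
                present = gene in de.index and bool(de.loc[gene, "tested"])
                if present:
                    fc = float(de.loc[gene, "fc"])
                    p = float(de.loc[gene, "p"])
                    fdr = float(de.loc[gene, "fdr"])
                    if fdr < fdr_threshold:
                        flag = "**"
                    elif p < p_threshold:
                        flag = "*"
                    else:
                        flag = ""
                    direction = "increased" if fc > 1 else ("decreased" if fc < 1 else "unchanged")
                else:
                    fc = p = fdr = np.nan
                    flag, direction = "", "absent"
                rows.append(
                    {
                        "panel": panel_name,
                        "gene": gene,
                        "treatment": treatment,
                        "fc": fc,
                        "p": p,
                        "fdr": fdr,
                        "flag": flag,
                        "direction": direction,
                        "present": present,
                    }
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# senescence sets


@dataclass
class SenescenceSummary:
    pro: ResamplingResult
    anti: ResamplingResult
    table: pd.DataFrame


def senescence_summary(
    de: pd.DataFrame,
    pro: GeneSet,
    anti: GeneSet,
    n_resamples: int = 10000,
    seed: Optional[int] = None,
) -> SenescenceSummary:
    """Mean-FC resampling tests of pro- and anti-senescence sets plus the
    per-gene FC/p/FDR listing of their tested members."""
    tested = de[de["tested"].astype(bool)]
    fc_map = tested["fc"]
    pro_result = mean_fc_resampling(fc_map, pro, n_resamples=n_resamples, seed=seed)
    anti_result = mean_fc_resampling(
        fc_map, anti, n_resamples=n_resamples, seed=None if seed is None else seed + 1
    )
    rows = []
    for set_name, gene_set in (("pro_senescence", pro), ("anti_senescence", anti)):
        members = [g for g in gene_set.genes if g in tested.index]
        sub = tested.loc[members, ["fc", "p", "fdr"]].copy()
        sub.insert(0, "set", set_name)
        rows.append(sub)
    table = pd.concat(rows) if rows else pd.DataFrame(columns=["set", "fc", "p", "fdr"])
    table.index.name = "gene"
    return SenescenceSummary(pro=pro_result, anti=anti_result, table=table)


# ---------------------------------------------------------------------------
# qPCR relative quantification


@dataclass
class DdctResult:
    samples: pd.DataFrame  # per-sample dct, ddct, relative expression
    group_means: pd.DataFrame  # gene × group mean relative expression


def ddct(
    qpcr: pd.DataFrame,
    reference_gene: str = "GAPDH",
    control_group: str = "CTL",
) -> DdctResult:
    """ΔΔCt relative quantification.

    Per sample: ΔCt = Ct_target − Ct_reference; per gene: ΔΔCt = ΔCt −
    mean ΔCt over the control group; relative quantity = 2^(−ΔΔCt), rescaled
    so the control-group mean is exactly 1. Input columns: ``sample``,
    ``group``, ``gene``, ``ct``.
    """
    required = {"sample", "group", "gene", "ct"}
    missing_cols = required - set(qpcr.columns)
    if missing_cols:
        raise ValueError(f"qPCR table lacks column(s) {sorted(missing_cols)}")
    if (qpcr["ct"] <= 0).any():
        raise ValueError("Ct values must be > 0")
    ref = qpcr[qpcr["gene"] == reference_gene].set_index("sample")["ct"]
    targets = qpcr[qpcr["gene"] != reference_gene]
    for sample in targets["sample"].unique():
        if sample not in ref.index:
            raise ValueError(f"sample {sample!r} has no Ct for reference gene {reference_gene!r}")
    control_samples = set(qpcr.loc[qpcr["group"] == control_group, "sample"])
    if not control_samples:
        raise ValueError(f"control group {control_group!r} has no samples")

    out = targets.copy()
    out["dct"] = out["ct"].to_numpy() - ref.loc[out["sample"]].to_numpy()
    rel_rows = []
    for gene, sub in out.groupby("gene", sort=True):
        ctl = sub[sub["sample"].isin(control_samples)]
        if ctl.empty:
            raise ValueError(f"gene {gene!r} has no control-group measurement")
        ddct_values = sub["dct"] - ctl["dct"].mean()
        rel = np.exp2(-ddct_values)
        rel = rel / rel[sub["sample"].isin(control_samples)].mean()
        sub = sub.assign(ddct=ddct_values, rel_expr=rel)
        rel_rows.append(sub)
    samples = pd.concat(rel_rows).reset_index(drop=True)
    group_means = samples.pivot_table(index="gene", columns="group", values="rel_expr", aggfunc="mean")
    return DdctResult(samples=samples, group_means=group_means)


# ---------------------------------------------------------------------------
# Fisher's LSD letter groupings


@dataclass
class LSDResult:
    letters: Dict[str, str]
    pairwise: pd.DataFrame  # group_a, group_b, mean_diff, t, p, significant
    anova_f: float
    anova_p: float
    mse: float
    df_resid: int


def lsd_groups(values: Mapping[str, Sequence[float]], alpha: float = 0.05) -> LSDResult:
    """Fisher's least-significant-difference letters.

    One-way ANOVA pooled variance, pairwise LSD t-tests at ``alpha``, and a
    greedy letter assignment: groups are sorted by decreasing mean, each
    letter extends from its anchor group over consecutive groups until the
    first group differing significantly from the anchor, which starts the
    next letter. Groups sharing no letter differ significantly.
    """
    groups = sorted(values, key=lambda g: (-np.mean(values[g]), g))
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    arrays = {g: np.asarray(values[g], dtype=float) for g in groups}
    for g, arr in arrays.items():
        if arr.size < 2:
            raise ValueError(f"group {g!r} has fewer than 2 replicates")
    n_total = sum(arr.size for arr in arrays.values())
    k = len(groups)
    df_resid = n_total - k
    means = {g: arr.mean() for g, arr in arrays.items()}
    mse = sum((arr.size - 1) * arr.var(ddof=1) for arr in arrays.values()) / df_resid

    degenerate = mse == 0.0
    if degenerate and len({round(m, 12) for m in means.values()}) > 1:
        warnings.warn("zero pooled variance with unequal means; all pairs flagged significant")

    def pair_p(a: str, b: str) -> float:
        if degenerate:
            return 1.0 if means[a] == means[b] else 0.0
        se = np.sqrt(mse * (1.0 / arrays[a].size + 1.0 / arrays[b].size))
        t = (means[a] - means[b]) / se
        return float(2.0 * stats.t.sf(abs(t), df_resid))

    rows = []
    pvals = {}
    for i, a in enumerate(groups):
        for b in groups[i + 1 :]:
            p = pair_p(a, b)
            pvals[(a, b)] = pvals[(b, a)] = p
            se = np.sqrt(mse * (1.0 / arrays[a].size + 1.0 / arrays[b].size)) if not degenerate else np.nan
            rows.append(
                {
                    "group_a": a,
                    "group_b": b,
                    "mean_diff": means[a] - means[b],
                    "t": (means[a] - means[b]) / se if se and np.isfinite(se) and se > 0 else np.nan,
                    "p": p,
                    "significant": p < alpha,
                }
            )
    pairwise = pd.DataFrame(rows)

    letters = {g: "" for g in groups}
    anchor = 0
    letter_idx = 0
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    while anchor < k:
        ch = alphabet[letter_idx % len(alphabet)]
        letters[groups[anchor]] += ch
        next_anchor = None
        for j in range(anchor + 1, k):
            if pvals[(groups[anchor], groups[j])] < alpha:
                next_anchor = j
                break
            letters[groups[j]] += ch
        if next_anchor is None:
            break
        anchor = next_anchor
        letter_idx += 1

    f_stat, f_p = stats.f_oneway(*(arrays[g] for g in groups))
    return LSDResult(
        letters=letters,
        pairwise=pairwise,
        anova_f=float(f_stat),
        anova_p=float(f_p),
        mse=float(mse),
        df_resid=df_resid,
    )
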