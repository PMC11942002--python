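"""Configuration-driven orchestration of the full analysis.

A run executes, per treatment-vs-control comparison: detectability
filtering → differential expression → DEG tier classification →
overrepresentation against the supplied (or generated) term library →
signature statistics against every reference signature (time-course area
enrichment, slope-ranking overlap, disease-set mean-FC resampling) → marker
panel and evidence reports → dataset-level structure overview; and writes a
JSON manifest with seeds, universe sizes and output checksums.

One run-level seed is split deterministically per stage
(:mod:`dermsig.seeding`), and the integrated run writes the synthetic
dataset to disk and re-reads it before analysing, so running the stages
separately on the emitted files reproduces the integrated run's outputs
byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from . import expression as ex
from . import signatures as sig
from . import enrichment as en
from . import overview as ov
from .genesets import GeneSet, SignatureLibrary, read_gmt, write_gmt
from .seeding import stage_seed
from .synthetic import (
    SyntheticConfig,
    generate_counts,
    generate_signature_library,
    generate_timecourse_reference,
)
from .tableio import read_tsv, write_tsv

__all__ = ["RunConfig", "run_pipeline", "write_synthetic_dataset"]

log = logging.getLogger("dermsig")


@dataclass
class RunConfig:
    """Pipeline run configuration.

    Either ``synthetic`` (a :class:`SyntheticConfig`) or explicit input
    paths (``counts_path``/``design_path``, optionally dataset companions
    written by :func:`write_synthetic_dataset`) must be provided.
    """

    outdir: Path
    seed: int = 0
    synthetic: Optional[SyntheticConfig] = None
    counts_path: Optional[Path] = None
    design_path: Optional[Path] = None
    signatures_path: Optional[Path] = None  # GMT signature library
    timecourse_dir: Optional[Path] = None  # per-day DE TSVs (timecourse_day*.tsv)
    comparisons: Tuple[Tuple[str, str], ...] = (("LYS", "CTL"), ("CDL", "CTL"), ("ZDL", "CTL"))
    fc_up: float = 1.50
    fc_down: float = 0.67
    fdr_threshold: float = 0.10
    p_threshold: float = 0.05
    n_perm: int = 2000
    n_resamples: int = 2000
    mean_fc_mode: str = "arithmetic"
    top_signature_size: int = 50
    rank_overlap_k: int = 1000
    strong_gene_target: int = 2000
    pca_components: int = 12
    min_evidence_sources: int = 3

    def __post_init__(self):
        self.outdir = Path(self.outdir)
        if self.synthetic is None and (self.counts_path is None or self.design_path is None):
            raise ValueError("config needs either a synthetic section or counts/design paths")

    @classmethod
    def from_yaml(cls, path, outdir=None, seed=None) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        syn = raw.pop("synthetic", None)
        if syn is not None:
            syn = SyntheticConfig(**syn)
        if "comparisons" in raw:
            raw["comparisons"] = tuple(tuple(pair) for pair in raw["comparisons"])
        for key in ("counts_path", "design_path", "signatures_path", "timecourse_dir"):
            if raw.get(key):
                raw[key] = Path(raw[key])
        if outdir is not None:
            raw["outdir"] = outdir
        if seed is not None:
            raw["seed"] = seed
        return cls(synthetic=syn, **raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _setup_logging(outdir: Path) -> None:
    log.setLevel(logging.INFO)
    for handler in list(log.handlers):
        log.removeHandler(handler)
    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s [%(stage)s] %(message)s"))
    log.addHandler(handler)


def _log(stage: str, message: str) -> None:
    log.info(message, extra={"stage": stage})


def write_synthetic_dataset(config: SyntheticConfig, outdir) -> Dict[str, Path]:
    """Generate and write the synthetic dataset (counts, design, truth,
    time-course DE tables and signature library). Returns the file map."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    matrix, truth = generate_counts(config)
    timecourse, truth = generate_timecourse_reference(config, truth)
    library = generate_signature_library(truth, config)

    paths: Dict[str, Path] = {}
    paths["counts"] = outdir / "counts.tsv"
    paths["design"] = outdir / "design.tsv"
    ex.write_expression(matrix, paths["counts"], paths["design"])
    paths["signatures"] = outdir / "signatures.gmt"
    write_gmt(library, paths["signatures"])
    truth_table = truth.true_log2fc.copy()
    truth_table["timecourse_slope"] = truth.timecourse_slopes
    paths["truth"] = outdir / "truth.tsv"
    write_tsv(truth_table, paths["truth"], metadata={"seed": config.seed})
    memberships = SignatureLibrary.from_sets(
        GeneSet(name, genes) for name, genes in truth.memberships.items()
    )
    paths["memberships"] = outdir / "memberships.gmt"
    write_gmt(memberships, paths["memberships"])
    for i, table in enumerate(timecourse, start=1):
        p = outdir / f"timecourse_day{i}.tsv"
        write_tsv(table, p, metadata={"day": i, "seed": config.seed})
        paths[f"timecourse_day{i}"] = p
    return paths


def _load_timecourse(timecourse_dir: Path) -> List[pd.DataFrame]:
    tables = []
    for path in sorted(timecourse_dir.glob("timecourse_day*.tsv"), key=lambda p: int(p.stem.split("day")[1])):
        df, meta = read_tsv(path)
        df["tested"] = df["tested"].astype(bool)
        df.attrs["day"] = int(meta.get("day", 0))
        tables.append(df)
    return tables


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full pipeline; returns (and writes) the run manifest."""
    outdir = config.outdir
    outdir.mkdir(parents=True, exist_ok=True)
    _setup_logging(outdir)
    manifest: dict = {
        "seed": config.seed,
        "comparisons": [list(c) for c in config.comparisons],
        "universe_sizes": {},
        "outputs": {},
        "stages": [],
    }

    # ---- stage: data ----------------------------------------------------
    try:
        if config.synthetic is not None:
            _log("data", f"simulating dataset: {config.synthetic.n_genes} genes")
            data_dir = outdir / "data"
            paths = write_synthetic_dataset(config.synthetic, data_dir)
            counts_path, design_path = paths["counts"], paths["design"]
            signatures_path = paths["signatures"]
            timecourse_dir = data_dir
        else:
            counts_path, design_path = config.counts_path, config.design_path
            signatures_path = config.signatures_path
            timecourse_dir = config.timecourse_dir
        matrix = ex.read_expression(counts_path, design_path)
        library = read_gmt(signatures_path) if signatures_path else SignatureLibrary()
        timecourse = _load_timecourse(Path(timecourse_dir)) if timecourse_dir else []
        manifest["stages"].append("data")
        manifest["inputs"] = {"counts": str(counts_path), "design": str(design_path)}
    except Exception as err:
        manifest["failed_stage"] = "data"
        raise RuntimeError(f"stage 'data' failed: {err}") from err

    fpkm = ex.compute_fpkm(matrix)
    de_tables: Dict[str, pd.DataFrame] = {}

    source_lists = {
        name: list(library[name].genes) for name in library if name.startswith("aging_source_")
    }
    panels = {name: library[name] for name in library if name.endswith("_panel")}

    slope_ranked = None
    if timecourse:
        slope_ranked, _slopes = sig.slope_ranking(timecourse)

    # ---- per-comparison analyses ----------------------------------------
    for trt, ctl in config.comparisons:
        stage = f"de:{trt}_vs_{ctl}"
        try:
            universe = ex.detectability_filter(matrix, trt, ctl)
            manifest["universe_sizes"][f"{trt}_vs_{ctl}"] = int(len(universe))
            _log(stage, f"universe size {len(universe)}")
            de = ex.de_test(matrix, trt, ctl, universe)
            tiers = ex.classify_degs(
                de,
                fc_up=config.fc_up,
                fc_down=config.fc_down,
                fdr_threshold=config.fdr_threshold,
                p_threshold=config.p_threshold,
            )
            out = de.copy()
            out["tier"] = ex.tier_labels(de, tiers)
            write_tsv(
                out,
                outdir / f"de_{trt}_vs_{ctl}.tsv",
                metadata={
                    "comparison": f"{trt}_vs_{ctl}",
                    "universe_size": len(universe),
                    "stringent_degs": len(tiers.stringent),
                    "permissive_degs": len(tiers.permissive),
                },
            )
            de_tables[trt] = de
        except Exception as err:
            manifest["failed_stage"] = stage
            raise RuntimeError(f"stage {stage!r} failed: {err}") from err

        stage = f"ora:{trt}_vs_{ctl}"
        if source_lists:
            term_library = {n: library[n] for n in library if n.startswith("aging_source_")}
            for direction, query in (("up", tiers.permissive_up), ("down", tiers.permissive_down)):
                if not query:
                    continue
                result = en.ora_test(
                    GeneSet(f"{trt}_{direction}", tuple(sorted(query))), list(universe), term_library
                )
                write_tsv(
                    result,
                    outdir / f"ora_{trt}_{direction}.tsv",
                    metadata={"comparison": f"{trt}_vs_{ctl}", "direction": direction, "universe_size": len(universe)},
                    index=False,
                )
            _log(stage, "overrepresentation written")

        stage = f"signatures:{trt}_vs_{ctl}"
        try:
            tested = de[de["tested"].astype(bool)]
            fc_map = tested["fc"]
            ranked_up = sig.rank_by_fc(de, "up")
            if timecourse:
                rows = []
                for table in timecourse:
                    day = table.attrs.get("day", 0)
                    top = sig.select_top_signature(table, config.top_signature_size, "up", name=f"day{day}_top")
                    seed_d = stage_seed(config.seed, "area", trt, ctl, day)
                    area = sig.area_enrichment(ranked_up, top, n_perm=config.n_perm, seed=seed_d)
                    set_fc = fc_map.reindex([g for g in top.genes if g in fc_map.index]).dropna()
                    rows.append(
                        {
                            "day": day,
                            "area": area.area,
                            "p_perm": area.p_perm,
                            "p_normal": area.p_normal,
                            "mean_fc": float(set_fc.mean()),
                            "frac_fc_gt1": float((set_fc > 1).mean()),
                            "n_perm": area.n_perm,
                            "seed": area.seed,
                        }
                    )
                write_tsv(
                    pd.DataFrame(rows),
                    outdir / f"timecourse_area_{trt}.tsv",
                    metadata={"comparison": f"{trt}_vs_{ctl}", "n_perm": config.n_perm},
                    index=False,
                )
            if slope_ranked is not None:
                shared = len(set(slope_ranked.genes) & set(ranked_up.genes))
                K = min(config.rank_overlap_k, max(1, shared // 2))
                overlap = sig.rank_overlap(slope_ranked, ranked_up, K)
                write_tsv(
                    pd.DataFrame({"k": np.arange(1, K + 1), "overlap": overlap.overlap}),
                    outdir / f"rank_overlap_{trt}.tsv",
                    metadata={
                        "comparison": f"{trt}_vs_{ctl}",
                        "K": K,
                        "N": overlap.N,
                        "overlap_at_K": int(overlap.overlap[-1]),
                        "fisher_p": overlap.fisher_p,
                    },
                    index=False,
                )
            res_rows = []
            for set_name in ("disease_up", "disease_down"):
                if set_name not in library:
                    continue
                seed_r = stage_seed(config.seed, "resample", trt, ctl, set_name)
                res = sig.mean_fc_resampling(
                    fc_map,
                    library[set_name],
                    n_resamples=config.n_resamples,
                    seed=seed_r,
                    mode=config.mean_fc_mode,
                )
                res_rows.append(
                    {
                        "set": set_name,
                        "observed_mean_fc": res.observed_mean_fc,
                        "percent_shift": res.percent_shift,
                        "p": res.p,
                        "null_mean": res.null_mean,
                        "null_q025": res.null_q025,
                        "null_q975": res.null_q975,
                        "m": res.m,
                        "n_resamples": res.n_resamples,
                        "seed": res.seed,
                    }
                )
            if res_rows:
                write_tsv(
                    pd.DataFrame(res_rows),
                    outdir / f"resampling_{trt}.tsv",
                    metadata={"comparison": f"{trt}_vs_{ctl}", "mode": config.mean_fc_mode},
                    index=False,
                )
            if "pro_senescence" in library and "anti_senescence" in library:
                seed_s = stage_seed(config.seed, "senescence", trt, ctl)
                summary = en.senescence_summary(
                    de,
                    library["pro_senescence"],
                    library["anti_senescence"],
                    n_resamples=config.n_resamples,
                    seed=seed_s,
                )
                write_tsv(
                    summary.table,
                    outdir / f"senescence_{trt}.tsv",
                    metadata={
                        "comparison": f"{trt}_vs_{ctl}",
                        "pro_mean_fc": summary.pro.observed_mean_fc,
                        "pro_p": summary.pro.p,
                        "anti_mean_fc": summary.anti.observed_mean_fc,
                        "anti_p": summary.anti.p,
                        "seed": seed_s,
                    },
                )
            _log(stage, "signature statistics written")
        except Exception as err:
            manifest["failed_stage"] = stage
            raise RuntimeError(f"stage {stage!r} failed: {err}") from err

    # ---- cross-comparison reports ---------------------------------------
    stage = "reports"
    try:
        if panels and de_tables:
            report = en.panel_report(
                de_tables, panels, fdr_threshold=config.fdr_threshold, p_threshold=config.p_threshold
            )
            write_tsv(report, outdir / "panel_report.tsv", index=False)
        if source_lists:
            expressed = set()
            for de in de_tables.values():
                expressed |= set(de.index[de["tested"].astype(bool)])
            evidence = en.aggregate_evidence(
                source_lists, min_sources=config.min_evidence_sources, expressed=expressed
            )
            table = en.evidence_table(source_lists)
            table["aggregated"] = table.index.isin(set(evidence.genes))
            write_tsv(
                table,
                outdir / "evidence.tsv",
                metadata={"min_sources": config.min_evidence_sources, "n_aggregated": len(evidence)},
            )
        if len(de_tables) >= 2:
            treatments = list(de_tables)
            rows = []
            for i, a in enumerate(treatments):
                for b in treatments[i + 1 :]:
                    res = sig.fc_spearman(de_tables[a], de_tables[b])
                    rows.append({"treatment_a": a, "treatment_b": b, "spearman_r": res.r, "p": res.p, "n": res.n})
            write_tsv(pd.DataFrame(rows), outdir / "fc_spearman.tsv", index=False)
        manifest["stages"].append("reports")
    except Exception as err:
        manifest["failed_stage"] = stage
        raise RuntimeError(f"stage 'reports' failed: {err}") from err

    # ---- stage: overview -------------------------------------------------
    stage = "overview"
    try:
        control = config.comparisons[0][1]
        n_comp = min(config.pca_components, matrix.counts.shape[1], matrix.counts.shape[0])
        pca = ov.pca_scores(fpkm, matrix.design, n_components=n_comp, reference_group=control)
        write_tsv(pca.scores, outdir / "pca_scores.tsv")
        write_tsv(
            pd.DataFrame(
                {"component": pca.scores.columns, "variance_fraction": pca.variance_fraction}
            ),
            outdir / "pca_variance.tsv",
            index=False,
        )
        write_tsv(pca.displacements, outdir / "pca_displacements.tsv")
        if de_tables:
            strong = ov.select_strong_genes(list(de_tables.values()), config.strong_gene_target)
            fc_matrix = pd.DataFrame(
                {trt: de.loc[strong, "log2fc"] for trt, de in de_tables.items()}
            )
            clustering = ov.hclust_fc(fc_matrix)
            leaf_df = pd.DataFrame({"gene": clustering.leaf_order})
            leaf_df["position"] = np.arange(len(clustering.leaf_order))
            write_tsv(leaf_df, outdir / "hclust_leaf_order.tsv", index=False)
            (outdir / "hclust_tree.nwk").write_text(clustering.newick + "\n")
            span = max(0.05, 3.0 / len(clustering.leaf_order))
            trends = pd.DataFrame(index=pd.Index(clustering.leaf_order, name="gene"))
            for trt, de in de_tables.items():
                ordered = de.loc[clustering.leaf_order, "log2fc"].to_numpy()
                trends[trt] = ov.loess_fc_trend(ordered, span=span)
            write_tsv(trends, outdir / "fc_trends.tsv", metadata={"span": span})
        manifest["stages"].append("overview")
        _log(stage, "overview written")
    except Exception as err:
        manifest["failed_stage"] = stage
        raise RuntimeError(f"stage 'overview' failed: {err}") from err

    # ---- manifest --------------------------------------------------------
    for path in sorted(outdir.rglob("*")):
        if path.is_file() and path.name not in ("run.log", "manifest.json"):
            manifest["outputs"][str(path.relative_to(outdir))] = _sha256(path)
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
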