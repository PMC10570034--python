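"""End-to-end orchestration of the methylation analysis.

Stage order: load -> conversion -> genome-wide levels -> calls -> degeneracy
annotation -> feature summary -> housekeeping join -> statistics -> profile.
Each stage logs its input/output sizes; a failure aborts with the stage name.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import expression as expr
from . import genome as gen
from . import methylation as meth
from . import stats as st

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    genome: str
    gff: str
    cytosine_report: str
    out_dir: str
    te_bed: str | None = None
    expression: list[str] = field(default_factory=list)  # value TSVs
    sample_maps: list[str] = field(default_factory=list)  # sidecar sample->dataset TSVs
    spike_chrom: str = "spike"
    min_cov: int = 10
    alpha: float = 0.05
    high_threshold: float = 0.7
    min_expr: float = 0.0
    profile_flank_bp: int = 2000
    profile_body_bins: int = 20
    profile_flank_bins: int = 10
    contrast_adjust: str = "single_step"
    intergenic_window: int = 2000
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _test_result_dict(t: st.TestResult) -> dict:
    return {"statistic": t.statistic, "df": t.df, "p_value": t.p_value, "method": t.method}


def _contrasts_frame(contrasts: list[st.PairwiseContrast]) -> pd.DataFrame:
    return pd.DataFrame([dataclasses.asdict(c) for c in contrasts])


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and write the declared artifacts; returns the summary."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logger.info("parameters: %s", dataclasses.asdict(config))
    summary: dict = {"parameters": dataclasses.asdict(config)}

    def stage(name):
        logger.info("stage %s", name)
        return name

    try:
        name = stage("load")
        genome = gen.load_genome(config.genome)
        genes = gen.load_annotation(config.gff, genome)
        te = gen.load_bed(config.te_bed) if config.te_bed else []
        records = meth.load_cytosine_report(config.cytosine_report)
        logger.info(
            "loaded %d sequences, %d genes, %d TE intervals, %d cytosine records",
            len(genome), len(genes), len(te), len(records),
        )
    except Exception as e:  # noqa: BLE001 - stage boundary
        raise StageError(name, e) from e

    try:
        name = stage("conversion")
        conv = meth.estimate_conversion(records, config.spike_chrom)
        summary["conversion"] = {
            "efficiency": conv.efficiency, "error_rate": conv.error_rate,
            "n_sites": conv.n_sites, "total_reads": conv.total_reads,
        }
    except Exception as e:
        raise StageError(name, e) from e

    try:
        name = stage("genome_wide_levels")
        summary["context_levels_pct"] = {
            ctx: meth.genome_wide_level(records, conv, ctx, spike_chrom=config.spike_chrom)
            for ctx in ("CpG", "CHG", "CHH")
        }
    except Exception as e:
        raise StageError(name, e) from e

    try:
        name = stage("calls")
        calls = meth.call_methylated(
            records, conv.error_rate, min_cov=config.min_cov,
            alpha=config.alpha, spike_chrom=config.spike_chrom,
        )
        calls.to_csv(out / "calls.tsv", sep="\t", index=False)
        summary["n_tested"] = int(len(calls))
        summary["n_methylated"] = int(calls["methylated"].sum())
    except Exception as e:
        raise StageError(name, e) from e

    try:
        name = stage("degeneracy")
        sites, ann_stats = gen.annotate_coding_sites(genes, genome)
        gen.write_coding_sites_tsv(sites, out / "coding_sites.tsv")
        summary["coding_sites"] = {
            "n_annotated": len(sites),
            "n_conflict_positions": ann_stats.n_conflict_positions,
            "n_stop_positions": ann_stats.n_stop_positions,
        }
    except Exception as e:
        raise StageError(name, e) from e

    try:
        name = stage("feature_summary")
        index = gen.FeatureIndex(
            genome, genes, te,
            intergenic_window=config.intergenic_window,
            exclude_chroms=(config.spike_chrom,),
        )
        feat = meth.feature_methylation_summary(
            records, genome, genes, te, spike_chrom=config.spike_chrom, index=index
        )
        feat.to_csv(out / "feature_methylation.tsv", sep="\t", index=False)
        gene_levels = feat[feat["category"] == "gene_body"].reset_index(drop=True)
        conv_for_class = conv
        gene_classes = meth.classify_gene_methylation(
            gene_levels, conv_for_class, high_threshold=config.high_threshold
        )
        gene_classes.to_csv(out / "gene_methylation.tsv", sep="\t", index=False)
        summary["gene_classes"] = (
            gene_classes["methylation_class"].value_counts().to_dict()
        )
    except Exception as e:
        raise StageError(name, e) from e

    try:
        name = stage("housekeeping")
        hk_join = None
        if config.expression:
            mats = [
                expr.load_expression(v, s)
                for v, s in zip(config.expression, config.sample_maps)
            ]
            hk = expr.identify_housekeeping(mats, min_expr=config.min_expr)
            expressed = expr.expressed_genes(mats)
            hk_join = expr.join_methylation(hk, gene_levels, expressed)
            hk_join.to_csv(out / "housekeeping.tsv", sep="\t", index=False)
            summary["n_housekeeping"] = int(hk_join["is_housekeeping"].sum())
            summary["n_other_expressed"] = int((~hk_join["is_housekeeping"]).sum())
    except Exception as e:
        raise StageError(name, e) from e

    try:
        name = stage("statistics")
        stats_out: dict = {}
        if hk_join is not None and hk_join["is_housekeeping"].nunique() == 2:
            a = hk_join.loc[hk_join["is_housekeeping"], "weighted_level"]
            b = hk_join.loc[~hk_join["is_housekeeping"], "weighted_level"]
            stats_out["welch_hk_vs_other"] = _test_result_dict(st.welch_t(a, b))

            sites_df = pd.DataFrame(
                [(s.chrom, s.pos, s.gene_id, s.degeneracy) for s in sites],
                columns=["chrom", "pos", "gene_id", "degeneracy"],
            )
            hk_map = dict(zip(hk_join["gene_id"], hk_join["is_housekeeping"]))
            obs = calls.merge(sites_df, on=["chrom", "pos"], how="inner")
            obs["housekeeping"] = obs["gene_id"].map(hk_map)
            obs = obs.dropna(subset=["housekeeping"])
            obs = obs.rename(columns={"methylated": "methylated"})
            if len(obs) and obs["degeneracy"].nunique() >= 2:
                fit = st.fit_methylation_model(
                    obs[["methylated", "degeneracy", "housekeeping"]]
                )
                stats_out["logistic_terms"] = {
                    k: _test_result_dict(v) for k, v in fit.term_tests.items()
                }
                stats_out["separation"] = fit.separation
                contrasts = st.pairwise_contrasts(
                    fit, adjust=config.contrast_adjust,
                    at_housekeeping=True, seed=config.seed + 7,
                )
                _contrasts_frame(contrasts).to_csv(
                    out / "degeneracy_contrasts.tsv", sep="\t", index=False
                )
                stats_out["degeneracy_contrasts"] = [
                    dataclasses.asdict(c) for c in contrasts
                ]
        kw, dunn = st.exon_rank_kruskal(feat)
        stats_out["kruskal_exon_ranks"] = _test_result_dict(kw)
        stats_out["dunn_exon_ranks"] = [dataclasses.asdict(c) for c in dunn]
        kw_te, dunn_te = st.te_intergenic_dunn(feat)
        stats_out["kruskal_te_intergenic"] = _test_result_dict(kw_te)
        stats_out["dunn_te_intergenic"] = [dataclasses.asdict(c) for c in dunn_te]
        summary["statistics"] = stats_out
        with open(out / "stats_summary.json", "w") as fh:
            json.dump(stats_out, fh, indent=2, default=float)
    except Exception as e:
        raise StageError(name, e) from e

    try:
        name = stage("profile")
        gene_spans = [(g.chrom, *g.span) for g in genes]
        profile = meth.methylation_profile(
            records, gene_spans, genome,
            flank_bp=config.profile_flank_bp,
            n_body_bins=config.profile_body_bins,
            n_flank_bins=config.profile_flank_bins,
        )
        profile.to_csv(out / "profile.tsv", sep="\t", index=False)
        summary["profile_truncated_intervals"] = profile.attrs["n_truncated"]
    except Exception as e:
        raise StageError(name, e) from e

    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, default=float)
    logger.info("pipeline complete; artifacts in %s", out)
    return summary
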