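"""Spike-in-calibrated CpG methylation calling and weighted methylation levels.

The canonical in-memory container for per-cytosine counts is a pandas
DataFrame with columns ``chrom, pos, strand, context, n_meth, n_unmeth``
(``pos`` 0-based), produced by :func:`load_cytosine_report` or by the
synthetic-data generator.

Calibration uses a fully unmethylated spike-in contig: its apparent
methylation is pure bisulfite non-conversion, giving the error rate
``1 - efficiency`` that (a) is subtracted from raw genome-wide levels and
(b) serves as the null success probability of the per-site binomial test.
A site is called methylated when its Benjamini-Hochberg q-value is at most
alpha (default 0.05) at a minimum coverage of 10x.

The weighted methylation level of a region is sum(methylated reads) /
sum(all reads) over the region's CpGs — coverage-weighted, not a mean of
per-site fractions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .genome import (
    CAT_EXON,
    CAT_INTERGENIC,
    CAT_INTRON,
    CAT_TE,
    FeatureIndex,
    GeneModel,
)
from .stats import bh_adjust

logger = logging.getLogger(__name__)

REPORT_COLUMNS = ["chrom", "pos", "strand", "n_meth", "n_unmeth", "context", "trinucleotide"]
RECORD_COLUMNS = ["chrom", "pos", "strand", "context", "n_meth", "n_unmeth"]
VALID_CONTEXTS = {"CpG", "CHG", "CHH"}


@dataclass
class ConversionStats:
    """Bisulfite conversion efficiency estimated from the spike-in."""

    efficiency: float
    n_sites: int
    total_reads: int

    @property
    def error_rate(self) -> float:
        return 1.0 - self.efficiency


@dataclass
class RegionMethylation:
    region_id: str
    category: str
    n_cpg: int
    sum_meth: int
    sum_total: int

    @property
    def weighted_level(self) -> float | None:
        if self.sum_total == 0:
            return None
        return self.sum_meth / self.sum_total


def load_cytosine_report(path) -> pd.DataFrame:
    """Parse a Bismark-style cytosine report (7 TSV columns, 1-based positions).

    Zero-coverage rows are retained; positions are converted to 0-based.
    """
    try:
        df = pd.read_csv(
            path, sep="\t", header=None, names=REPORT_COLUMNS,
            dtype={"chrom": str, "strand": str, "context": str, "trinucleotide": str},
        )
    except pd.errors.EmptyDataError:
        logger.warning("cytosine report %s is empty", path)
        return pd.DataFrame(columns=RECORD_COLUMNS).astype(
            {"pos": int, "n_meth": int, "n_unmeth": int}
        )
    for col in ("pos", "n_meth", "n_unmeth"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() | (vals < 0) | (vals != vals.round())
        if col == "pos":
            bad |= vals < 1
        if bad.any():
            raise ValueError(
                f"{path}: invalid {col} value at line {int(np.flatnonzero(bad)[0]) + 1}"
            )
        df[col] = vals.astype(int)
    bad_strand = ~df["strand"].isin(["+", "-"])
    if bad_strand.any():
        raise ValueError(
            f"{path}: malformed strand at line {int(np.flatnonzero(bad_strand)[0]) + 1}"
        )
    bad_ctx = ~df["context"].isin(VALID_CONTEXTS)
    if bad_ctx.any():
        raise ValueError(
            f"{path}: malformed context at line {int(np.flatnonzero(bad_ctx)[0]) + 1}"
        )
    df["pos"] = df["pos"] - 1
    return df[RECORD_COLUMNS]


def estimate_conversion(records: pd.DataFrame, spike_chrom: str) -> ConversionStats:
    """Conversion efficiency = converted reads / all reads on the spike-in.

    All cytosine contexts of the spike-in are used (the control is fully
    unmethylated in every context).
    """
    spike = records[records["chrom"] == spike_chrom]
    total = int(spike["n_meth"].sum() + spike["n_unmeth"].sum())
    if total == 0:
        raise ValueError(
            f"no covered cytosines on spike-in contig {spike_chrom!r}; "
            "cannot estimate conversion efficiency"
        )
    covered = int(((spike["n_meth"] + spike["n_unmeth"]) > 0).sum())
    eff = float(spike["n_unmeth"].sum()) / total
    return ConversionStats(efficiency=eff, n_sites=covered, total_reads=total)


def genome_wide_level(
    records: pd.DataFrame,
    stats: ConversionStats,
    context: str,
    spike_chrom: str | None = None,
) -> float | None:
    """Genome-wide methylation percentage for one context.

    Raw percentage of methylation-supporting reads minus the spike-in
    non-conversion percentage, clamped at zero.  Returns None when the
    context has no coverage.
    """
    sub = records[records["context"] == context]
    if spike_chrom is not None:
        sub = sub[sub["chrom"] != spike_chrom]
    total = int(sub["n_meth"].sum() + sub["n_unmeth"].sum())
    if total == 0:
        return None
    raw = float(sub["n_meth"].sum()) / total
    return max(0.0, 100.0 * (raw - stats.error_rate))


def binomial_tail_pvalues(n_meth, coverage, error_rate: float) -> np.ndarray:
    """P(Binomial(coverage, error_rate) >= n_meth), exact upper tail."""
    n_meth = np.asarray(n_meth)
    coverage = np.asarray(coverage)
    if error_rate == 0.0:  # degenerate null: any methylated read is impossible
        return np.where(n_meth > 0, 0.0, 1.0)
    return sps.binom.sf(n_meth - 1, coverage, error_rate)


def call_methylated(
    records: pd.DataFrame,
    error_rate: float,
    min_cov: int = 10,
    alpha: float = 0.05,
    spike_chrom: str | None = None,
) -> pd.DataFrame:
    """Call methylated CpGs by a one-sided binomial test against the spike-in
    error rate, with BH correction over all tested sites genome-wide.

    Only CpG-context sites with coverage >= min_cov are tested; a site is
    methylated when q <= alpha.
    """
    if not 0.0 <= error_rate < 1.0:
        raise ValueError(f"error_rate must be in [0, 1), got {error_rate}")
    sub = records[records["context"] == "CpG"]
    if spike_chrom is not None:
        sub = sub[sub["chrom"] != spike_chrom]
    cov = sub["n_meth"] + sub["n_unmeth"]
    tested = sub[cov >= min_cov].copy()
    tested["coverage"] = (tested["n_meth"] + tested["n_unmeth"]).astype(int)
    p = binomial_tail_pvalues(
        tested["n_meth"].to_numpy(), tested["coverage"].to_numpy(), error_rate
    )
    tested["p"] = p
    tested["q"] = bh_adjust(p) if len(p) else p
    tested["methylated"] = tested["q"] <= alpha
    return tested[["chrom", "pos", "strand", "coverage", "n_meth", "p", "q", "methylated"]]


def weighted_methylation(
    records: pd.DataFrame,
    chrom: str,
    positions,
    region_id: str = "region",
    category: str = "region",
) -> RegionMethylation:
    """Weighted methylation of one region given its CpG positions.

    Uncovered CpGs contribute 0 to both numerator and denominator but are
    counted in n_cpg; the level is undefined (None) at zero total coverage.
    """
    positions = list(positions)
    sub = records[
        (records["chrom"] == chrom)
        & (records["context"] == "CpG")
        & (records["pos"].isin(positions))
    ]
    return RegionMethylation(
        region_id=region_id,
        category=category,
        n_cpg=len(positions),
        sum_meth=int(sub["n_meth"].sum()),
        sum_total=int(sub["n_meth"].sum() + sub["n_unmeth"].sum()),
    )


def feature_methylation_summary(
    records: pd.DataFrame,
    genome: dict[str, str],
    genes: list[GeneModel],
    te_intervals: list[tuple[str, int, int]] | None = None,
    spike_chrom: str | None = None,
    intergenic_window: int = 2000,
    index: FeatureIndex | None = None,
) -> pd.DataFrame:
    """Weighted methylation per feature instance.

    Emits one row per exon instance (with its transcription-order rank), per
    intron, per TE interval, per intergenic window and per gene body, with
    columns ``region_id, category, n_cpg, sum_meth, sum_total, weighted_level``.
    Category precedence per CpG is exon > intron > TE > intergenic; the gene
    body row pools every CpG inside the gene span regardless of exon/intron.
    """
    if index is None:
        index = FeatureIndex(
            genome, genes, te_intervals,
            intergenic_window=intergenic_window,
            exclude_chroms=(spike_chrom,) if spike_chrom else (),
        )
    cpg = records[records["context"] == "CpG"]
    if spike_chrom is not None:
        cpg = cpg[cpg["chrom"] != spike_chrom]

    n_inst = len(index.instance_table)
    inst_cpg = np.zeros(n_inst, dtype=np.int64)
    inst_meth = np.zeros(n_inst, dtype=np.int64)
    inst_total = np.zeros(n_inst, dtype=np.int64)
    gene_cpg = np.zeros(len(genes), dtype=np.int64)
    gene_meth = np.zeros(len(genes), dtype=np.int64)
    gene_total = np.zeros(len(genes), dtype=np.int64)

    for chrom, grp in cpg.groupby("chrom", sort=False):
        if chrom not in index.instance:
            continue
        pos = grp["pos"].to_numpy()
        meth = grp["n_meth"].to_numpy()
        tot = meth + grp["n_unmeth"].to_numpy()
        iid = index.instance[chrom][pos]
        ok = iid >= 0
        np.add.at(inst_cpg, iid[ok], 1)
        np.add.at(inst_meth, iid[ok], meth[ok])
        np.add.at(inst_total, iid[ok], tot[ok])
        gi = index.gene_idx[chrom][pos]
        gok = gi >= 0
        np.add.at(gene_cpg, gi[gok], 1)
        np.add.at(gene_meth, gi[gok], meth[gok])
        np.add.at(gene_total, gi[gok], tot[gok])

    rows = []
    for i, (region_id, cat, _gene) in enumerate(index.instance_table):
        rows.append((region_id, cat, inst_cpg[i], inst_meth[i], inst_total[i]))
    for gi, gene in enumerate(genes):
        rows.append(
            (gene.gene_id, "gene_body", gene_cpg[gi], gene_meth[gi], gene_total[gi])
        )
    df = pd.DataFrame(
        rows, columns=["region_id", "category", "n_cpg", "sum_meth", "sum_total"]
    )
    df["weighted_level"] = np.where(
        df["sum_total"] > 0, df["sum_meth"] / df["sum_total"].replace(0, 1), np.nan
    )
    return df


def classify_gene_methylation(
    gene_levels: pd.DataFrame,
    stats: ConversionStats,
    high_threshold: float = 0.7,
) -> pd.DataFrame:
    """Classify genes by weighted level.

    highly_methylated: level > high_threshold; methylated: level > error rate;
    unmethylated: level == 0; background: 0 < level <= error rate (apparent
    methylation indistinguishable from non-conversion).  Genes with undefined
    level (no coverage) are excluded; the count is logged.
    """
    df = gene_levels.copy()
    undefined = df["weighted_level"].isna()
    if undefined.any():
        logger.info("excluding %d genes with undefined methylation level", int(undefined.sum()))
    df = df[~undefined].copy()
    lvl = df["weighted_level"]
    df["methylation_class"] = np.select(
        [lvl > high_threshold, lvl > stats.error_rate, lvl == 0],
        ["highly_methylated", "methylated", "unmethylated"],
        default="background",
    )
    return df


def methylation_profile(
    records: pd.DataFrame,
    intervals: list[tuple[str, int, int]],
    genome: dict[str, str],
    flank_bp: int = 2000,
    n_body_bins: int = 20,
    n_flank_bins: int = 10,
) -> pd.DataFrame:
    """Binned methylation metaplot over a set of intervals.

    Each interval body is rescaled to ``n_body_bins``; the fixed-width flanks
    get ``n_flank_bins`` each.  Bin values are weighted methylation pooled
    across intervals; bins with no CpGs are NaN.  Flanks running off a
    chromosome end are truncated (flagged via the ``n_truncated`` attribute).
    """
    n_bins = n_body_bins + 2 * n_flank_bins
    sum_meth = np.zeros(n_bins)
    sum_total = np.zeros(n_bins)
    n_cpg = np.zeros(n_bins, dtype=int)
    n_truncated = 0

    cpg = records[records["context"] == "CpG"]
    by_chrom = {c: g for c, g in cpg.groupby("chrom", sort=False)}

    for chrom, start, end in intervals:
        grp = by_chrom.get(chrom)
        if grp is None:
            continue
        clen = len(genome[chrom])
        lo, hi = start - flank_bp, end + flank_bp
        if lo < 0 or hi > clen:
            n_truncated += 1
            lo, hi = max(0, lo), min(clen, hi)
        pos = grp["pos"].to_numpy()
        meth = grp["n_meth"].to_numpy()
        tot = meth + grp["n_unmeth"].to_numpy()
        sel = (pos >= lo) & (pos < hi)
        pos, meth, tot = pos[sel], meth[sel], tot[sel]

        up = pos < start
        body = (pos >= start) & (pos < end)
        down = pos >= end
        bins = np.empty(pos.shape, dtype=int)
        bins[up] = np.clip(
            ((pos[up] - (start - flank_bp)) * n_flank_bins) // flank_bp, 0, n_flank_bins - 1
        )
        bins[body] = n_flank_bins + ((pos[body] - start) * n_body_bins) // max(end - start, 1)
        bins[down] = (
            n_flank_bins + n_body_bins
            + np.clip(((pos[down] - end) * n_flank_bins) // flank_bp, 0, n_flank_bins - 1)
        )
        np.add.at(sum_meth, bins, meth)
        np.add.at(sum_total, bins, tot)
        np.add.at(n_cpg, bins, 1)

    level = np.where(sum_total > 0, sum_meth / np.maximum(sum_total, 1), np.nan)
    segment = (
        ["upstream"] * n_flank_bins + ["body"] * n_body_bins + ["downstream"] * n_flank_bins
    )
    out = pd.DataFrame(
        {"bin": np.arange(n_bins), "segment": segment, "n_cpg": n_cpg,
         "sum_meth": sum_meth.astype(int), "sum_total": sum_total.astype(int),
         "weighted_level": level}
    )
    out.attrs["n_truncated"] = n_truncated
    return out
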