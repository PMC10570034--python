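"""Synthetic genomes, methylomes and expression matrices with known truth.

The generator emulates the statistical structure of a whole-genome bisulfite
experiment on an annotated invertebrate genome:

* multi-chromosome random genome (40% GC) plus a fully unmethylated
  lambda-like spike-in contig named ``spike``;
* non-overlapping stranded genes with valid ORFs (ATG start, single terminal
  stop, CDS length divisible by three) split across several exons;
* per-CpG methylation probabilities set by feature class — housekeeping gene
  body, other gene body, TE, intergenic — with optional logit shifts at
  0-fold / 2-fold degenerate coding sites;
* an observation model per cytosine: coverage n ~ Poisson(depth) and
  methylated count k ~ Binomial(n, pi + (1 - pi) * epsilon), i.e. a truly
  methylated read always reads methylated while an unmethylated read reads
  methylated with the bisulfite non-conversion probability epsilon;
* expression matrices in which flagged housekeeping genes are positive in
  every sample and other genes suffer per-sample dropout.

Everything is deterministic under the config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .expression import ExpressionMatrix
from .genome import (
    CAT_EXON,
    CAT_INTRON,
    CAT_TE,
    FeatureIndex,
    GeneModel,
    annotate_coding_sites,
    reverse_complement,
    CODON_TO_AA,
    STOP_CODONS,
)

BASES = np.frombuffer(b"ACGT", dtype="S1")
BASE_PROBS = np.array([0.30, 0.20, 0.20, 0.30])  # 40% GC
NON_STOP_CODONS = sorted(set(CODON_TO_AA) - STOP_CODONS)


@dataclass
class SimulationConfig:
    """Study-condition knobs of the generator (all randomness under `seed`)."""

    seed: int
    n_chrom: int = 2
    chrom_len: int = 300_000
    n_genes: int = 150
    exons_per_gene: tuple[int, int] = (4, 8)
    cds_len: tuple[int, int] = (300, 1500)
    intron_len: tuple[int, int] = (60, 200)
    gene_gap: tuple[int, int] = (500, 3000)
    te_fraction: float = 0.15
    te_len: tuple[int, int] = (300, 1500)
    spike_len: int = 10_000
    depth: float = 30.0
    error_rate: float = 0.01
    pi_housekeeping: float = 0.7
    pi_other: float = 0.2
    pi_te: float = 0.01
    pi_intergenic: float = 0.05
    delta_zero_fold: float = 0.0  # logit shift at 0-fold degenerate CpGs
    delta_two_fold: float = 0.0
    hk_fraction: float = 0.35
    n_datasets: int = 2
    samples_per_dataset: int = 4
    dropout_prob: float = 0.3
    spike_chrom: str = "spike"

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        for key in ("exons_per_gene", "cds_len", "intron_len", "gene_gap", "te_len"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


@dataclass
class TruthTables:
    """Ground truth: per-cytosine methylation probability and gene flags."""

    pi: pd.DataFrame  # chrom, pos, strand, context, pi
    housekeeping: dict[str, bool]
    spike_chrom: str


@dataclass
class SimulatedDataset:
    config: SimulationConfig
    genome: dict[str, str]
    genes: list[GeneModel]
    te_intervals: list[tuple[str, int, int]]
    truth: TruthTables
    records: pd.DataFrame  # cytosine report records (0-based)
    trinucleotides: pd.Series
    expression: list[ExpressionMatrix]
    index: FeatureIndex


def _rng(seed) -> np.random.Generator:
    return np.random.default_rng(seed)


def simulate_genome(config: SimulationConfig, rng=None) -> dict[str, np.ndarray]:
    """Random chromosomes plus the unmethylated spike-in contig.

    Returned as mutable byte arrays; gene placement overwrites CDS regions
    before the genome is frozen to strings.
    """
    rng = rng or _rng(config.seed)
    genome = {}
    for i in range(config.n_chrom):
        genome[f"chr{i + 1}"] = rng.choice(BASES, size=config.chrom_len, p=BASE_PROBS)
    genome[config.spike_chrom] = rng.choice(BASES, size=config.spike_len, p=BASE_PROBS)
    return genome


def _random_cds(rng, length: int) -> str:
    """ATG + random non-stop codons + one stop codon; length % 3 == 0."""
    n_codons = length // 3
    middle = rng.choice(NON_STOP_CODONS, size=n_codons - 2)
    stop = rng.choice(sorted(STOP_CODONS))
    return "ATG" + "".join(middle) + stop


def simulate_genes(
    config: SimulationConfig, genome: dict[str, np.ndarray], rng=None
) -> list[GeneModel]:
    """Place non-overlapping multi-exon genes on both strands.

    Each CDS is generated as a valid ORF, split into the gene's exons and
    written into the genome at the chosen coordinates (exon intervals equal
    CDS intervals; no UTRs).  Housekeeping flags are drawn per gene.
    """
    rng = rng or _rng(config.seed + 1)
    chroms = [c for c in genome if c != config.spike_chrom]
    genes: list[GeneModel] = []
    ci, cursor = 0, 0

    for g in range(config.n_genes):
        n_exons = int(rng.integers(config.exons_per_gene[0], config.exons_per_gene[1] + 1))
        cds_len = int(rng.integers(config.cds_len[0] // 3, config.cds_len[1] // 3 + 1)) * 3
        cds_len = max(cds_len, 3 * (n_exons + 2))  # every exon needs >= 1 codon of room
        introns = rng.integers(config.intron_len[0], config.intron_len[1] + 1, size=n_exons - 1)
        span = cds_len + int(introns.sum())
        gap = int(rng.integers(config.gene_gap[0], config.gene_gap[1] + 1))

        while ci < len(chroms) and cursor + gap + span > len(genome[chroms[ci]]):
            ci, cursor = ci + 1, 0
        if ci >= len(chroms):
            raise ValueError(
                f"insufficient genome space for {config.n_genes} genes; "
                "reduce n_genes or enlarge chrom_len"
            )
        chrom = chroms[ci]
        start = cursor + gap

        # split the CDS into n_exons pieces (coding order), each >= 3 bp
        if n_exons > 1:
            cuts = np.sort(rng.choice(np.arange(1, cds_len // 3), size=n_exons - 1, replace=False)) * 3
            pieces = np.diff(np.concatenate([[0], cuts, [cds_len]])).astype(int)
        else:
            pieces = np.array([cds_len])

        strand = "+" if rng.random() < 0.5 else "-"
        cds_seq = _random_cds(rng, cds_len)
        written = cds_seq if strand == "+" else reverse_complement(cds_seq)
        genomic_pieces = pieces if strand == "+" else pieces[::-1]

        intervals, p, w = [], start, 0
        for k, plen in enumerate(genomic_pieces):
            seg = written[w:w + plen]
            genome[chrom][p:p + plen] = np.frombuffer(seg.encode(), dtype="S1")
            intervals.append((p, p + int(plen)))
            w += int(plen)
            if k < n_exons - 1:
                p += int(plen) + int(introns[k])
            else:
                p += int(plen)

        genes.append(
            GeneModel(
                gene_id=f"gene{g + 1:04d}", chrom=chrom, strand=strand,
                exon_intervals=intervals, cds_intervals=list(intervals),
                is_housekeeping=bool(rng.random() < config.hk_fraction),
            )
        )
        cursor = intervals[-1][1]
    return genes


def simulate_te_intervals(
    config: SimulationConfig,
    genome: dict[str, str],
    genes: list[GeneModel],
    rng=None,
) -> list[tuple[str, int, int]]:
    """TE intervals sampled inside intergenic space up to te_fraction of the genome."""
    rng = rng or _rng(config.seed + 2)
    target = config.te_fraction * sum(
        len(genome[c]) for c in genome if c != config.spike_chrom
    )
    # free runs = complement of gene spans
    runs: list[tuple[str, int, int]] = []
    for chrom in genome:
        if chrom == config.spike_chrom:
            continue
        spans = sorted(g.span for g in genes if g.chrom == chrom)
        prev = 0
        for s, e in spans:
            if s > prev:
                runs.append((chrom, prev, s))
            prev = max(prev, e)
        if prev < len(genome[chrom]):
            runs.append((chrom, prev, len(genome[chrom])))

    tes, total = [], 0
    order = rng.permutation(len(runs))
    for idx in np.tile(order, 4):  # several passes until the target is met
        chrom, s, e = runs[idx]
        max_len = min(config.te_len[1], e - s)
        if max_len < config.te_len[0] or total >= target:
            continue
        tlen = int(rng.integers(config.te_len[0], max_len + 1))
        t0 = int(rng.integers(s, e - tlen + 1))
        if any(c == chrom and not (t1e <= t0 or t0 + tlen <= t1s) for c, t1s, t1e in tes):
            continue
        tes.append((chrom, t0, t0 + tlen))
        total += tlen
        if total >= target:
            break
    return sorted(tes)


def _cytosine_table(genome: dict[str, str]) -> pd.DataFrame:
    """All cytosines on both strands with context and trinucleotide."""
    frames = []
    for chrom, seq in genome.items():
        arr = np.frombuffer(seq.encode(), dtype="S1")
        n = len(arr)
        is_c = arr == b"C"
        is_g = arr == b"G"
        nxt1 = np.roll(arr, -1)
        nxt2 = np.roll(arr, -2)
        prv1 = np.roll(arr, 1)
        prv2 = np.roll(arr, 2)
        nxt1[-1] = b"N"
        nxt2[-2:] = b"N"
        prv1[0] = b"N"
        prv2[:2] = b"N"

        # plus-strand cytosines
        pos_p = np.flatnonzero(is_c)
        ctx_p = np.where(
            nxt1[pos_p] == b"G", "CpG", np.where(nxt2[pos_p] == b"G", "CHG", "CHH")
        )
        tri_p = np.char.add(
            np.char.add(arr[pos_p].astype("U1"), nxt1[pos_p].astype("U1")),
            nxt2[pos_p].astype("U1"),
        )
        # minus-strand cytosines are genomic Gs; context read 3'->5' on top strand
        pos_m = np.flatnonzero(is_g)
        ctx_m = np.where(
            prv1[pos_m] == b"C", "CpG", np.where(prv2[pos_m] == b"C", "CHG", "CHH")
        )
        comp = {b"A": "T", b"C": "G", b"G": "C", b"T": "A", b"N": "N"}
        tri_m = np.array(
            [comp[x] for x in arr[pos_m]], dtype="U1"
        )
        tri_m = np.char.add(
            np.char.add(tri_m, np.array([comp[x] for x in prv1[pos_m]], dtype="U1")),
            np.array([comp[x] for x in prv2[pos_m]], dtype="U1"),
        )
        frames.append(pd.DataFrame({
            "chrom": chrom,
            "pos": np.concatenate([pos_p, pos_m]),
            "strand": ["+"] * len(pos_p) + ["-"] * len(pos_m),
            "context": np.concatenate([ctx_p, ctx_m]),
            "trinucleotide": np.concatenate([tri_p, tri_m]),
        }))
    out = pd.concat(frames, ignore_index=True)
    return out.sort_values(["chrom", "pos", "strand"], kind="stable").reset_index(drop=True)


def simulate_methylome(
    config: SimulationConfig,
    genome: dict[str, str],
    genes: list[GeneModel],
    te_intervals: list[tuple[str, int, int]],
    index: FeatureIndex | None = None,
) -> tuple[TruthTables, pd.DataFrame, FeatureIndex]:
    """Assign a true methylation probability to every cytosine.

    CpG cytosines take the class probability of their position (housekeeping
    body / other body / TE / intergenic); 0-fold and 2-fold degenerate coding
    CpGs receive the configured logit shifts.  Non-CpG cytosines and the whole
    spike-in have pi = 0.
    """
    if index is None:
        index = FeatureIndex(genome, genes, te_intervals, exclude_chroms=(config.spike_chrom,))
    table = _cytosine_table(genome)

    pi = np.zeros(len(table))
    is_cpg = (table["context"] == "CpG").to_numpy()
    not_spike = (table["chrom"] != config.spike_chrom).to_numpy()
    hk_by_idx = np.array([bool(g.is_housekeeping) for g in genes])

    for chrom, grp_idx in table.groupby("chrom", sort=False).indices.items():
        if chrom == config.spike_chrom:
            continue
        pos = table["pos"].to_numpy()[grp_idx]
        cat = index.category[chrom][pos]
        gidx = index.gene_idx[chrom][pos]
        cls_pi = np.full(len(grp_idx), config.pi_intergenic)
        cls_pi[cat == CAT_TE] = config.pi_te
        in_gene = gidx >= 0
        cls_pi[in_gene] = np.where(
            hk_by_idx[gidx[in_gene]], config.pi_housekeeping, config.pi_other
        )
        pi[grp_idx] = cls_pi
    pi[~(is_cpg & not_spike)] = 0.0

    if config.delta_zero_fold or config.delta_two_fold:
        sites, _ = annotate_coding_sites(genes, genome)
        deg_by_pos = {(a.chrom, a.pos): a.degeneracy for a in sites}
        keys = list(zip(table["chrom"], table["pos"]))
        deg = np.array([deg_by_pos.get(k, -1) for k in keys])
        shift = np.zeros(len(table))
        shift[deg == 0] = config.delta_zero_fold
        shift[deg == 2] = config.delta_two_fold
        apply = is_cpg & not_spike & (shift != 0) & (pi > 0) & (pi < 1)
        logit = np.log(pi[apply] / (1 - pi[apply])) + shift[apply]
        pi[apply] = 1.0 / (1.0 + np.exp(-logit))

    table["pi"] = pi
    truth = TruthTables(
        pi=table[["chrom", "pos", "strand", "context", "pi"]].copy(),
        housekeeping={g.gene_id: bool(g.is_housekeeping) for g in genes},
        spike_chrom=config.spike_chrom,
    )
    return truth, table, index


def simulate_cytosine_report(
    truth_table: pd.DataFrame, config: SimulationConfig, rng=None
) -> pd.DataFrame:
    """Draw the observed counts: n ~ Poisson(depth), k ~ Binom(n, pi + (1-pi)*eps).

    One row per cytosine on each strand; zero-coverage rows are kept.
    """
    rng = rng or _rng(config.seed + 3)
    n = rng.poisson(config.depth, size=len(truth_table))
    p_obs = truth_table["pi"].to_numpy()
    p_obs = p_obs + (1.0 - p_obs) * config.error_rate
    k = rng.binomial(n, p_obs)
    out = truth_table[["chrom", "pos", "strand", "context"]].copy()
    out["n_meth"] = k
    out["n_unmeth"] = n - k
    return out


def simulate_expression(
    config: SimulationConfig, genes: list[GeneModel], rng=None
) -> list[ExpressionMatrix]:
    """Expression matrices where housekeeping genes are positive everywhere.

    Values are log-normal; each non-housekeeping gene is independently zeroed
    in each sample with probability dropout_prob.
    """
    rng = rng or _rng(config.seed + 4)
    gene_ids = [g.gene_id for g in genes]
    hk = np.array([bool(g.is_housekeeping) for g in genes])
    dataset_names = ["developmental", "environmental"] + [
        f"dataset{i}" for i in range(3, config.n_datasets + 1)
    ]
    matrices = []
    for d in range(config.n_datasets):
        name = dataset_names[d]
        samples = [f"{name}_s{j + 1}" for j in range(config.samples_per_dataset)]
        vals = rng.lognormal(mean=3.0, sigma=1.0, size=(len(gene_ids), len(samples)))
        drop = rng.random(vals.shape) < config.dropout_prob
        drop[hk, :] = False
        vals[drop] = 0.0
        df = pd.DataFrame(vals, index=pd.Index(gene_ids, name="gene_id"), columns=samples)
        labels = pd.Series(name, index=samples)
        matrices.append(ExpressionMatrix(values=df, dataset_labels=labels))
    return matrices


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Run the whole generator: genome, genes, TEs, methylome, report, expression."""
    rng = _rng(config.seed)
    raw = simulate_genome(config, rng)
    genes = simulate_genes(config, raw, rng)
    genome = {c: raw[c].tobytes().decode() for c in raw}
    te_intervals = simulate_te_intervals(config, genome, genes, rng)
    truth, table, index = simulate_methylome(config, genome, genes, te_intervals)
    records = simulate_cytosine_report(table, config, rng)
    expression = simulate_expression(config, genes, rng)
    return SimulatedDataset(
        config=config, genome=genome, genes=genes, te_intervals=te_intervals,
        truth=truth, records=records, trinucleotides=table["trinucleotide"],
        expression=expression, index=index,
    )


def simulate_null_cpg_records(
    n_sites: int, depth: float, error_rate: float, rng, chrom: str = "chr1"
) -> pd.DataFrame:
    """Fully unmethylated CpG records (pi = 0): apparent methylation is pure
    non-conversion error — the null for FDR-calibration checks."""
    n = rng.poisson(depth, size=n_sites)
    k = rng.binomial(n, error_rate)
    return pd.DataFrame({
        "chrom": chrom, "pos": np.arange(n_sites) * 2, "strand": "+",
        "context": "CpG", "n_meth": k, "n_unmeth": n - k,
    })


def simulate_site_observations(
    n_sites: int,
    rng,
    p_base: float = 0.2,
    hk_logit_effect: float = 0.0,
    deg_shifts: dict[int, float] | None = None,
    hk_fraction: float = 0.5,
    deg_probs: dict[int, float] | None = None,
) -> pd.DataFrame:
    """Per-site methylation-status observations for the regression models.

    Each site gets a degeneracy class (realistic coding-site mix by default),
    a housekeeping flag, and a methylated Bernoulli draw with probability
    sigmoid(logit(p_base) + hk_effect*hk + shift[degeneracy]).
    """
    deg_shifts = deg_shifts or {}
    deg_probs = deg_probs or {0: 0.55, 2: 0.20, 3: 0.05, 4: 0.20}
    levels = sorted(deg_probs)
    probs = np.array([deg_probs[lv] for lv in levels])
    probs = probs / probs.sum()
    deg = rng.choice(levels, size=n_sites, p=probs)
    hk = rng.random(n_sites) < hk_fraction
    logit = np.log(p_base / (1 - p_base)) + hk_logit_effect * hk
    logit = logit + np.array([deg_shifts.get(int(d), 0.0) for d in deg])
    p = 1.0 / (1.0 + np.exp(-logit))
    meth = rng.random(n_sites) < p
    return pd.DataFrame({"methylated": meth, "degeneracy": deg, "housekeeping": hk})


# ---------------------------------------------------------------------------
# writers

def write_fasta(genome: dict[str, str], path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def write_gff3(genes: list[GeneModel], path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            s0, e0 = g.span
            fh.write(
                f"{g.chrom}\tgbmeth\tgene\t{s0 + 1}\t{e0}\t.\t{g.strand}\t.\tID={g.gene_id}\n"
            )
            tid = f"{g.gene_id}.t1"
            fh.write(
                f"{g.chrom}\tgbmeth\tmRNA\t{s0 + 1}\t{e0}\t.\t{g.strand}\t.\t"
                f"ID={tid};Parent={g.gene_id}\n"
            )
            for s, e in g.exon_intervals:
                fh.write(
                    f"{g.chrom}\tgbmeth\texon\t{s + 1}\t{e}\t.\t{g.strand}\t.\tParent={tid}\n"
                )
            for s, e in g.cds_intervals:
                fh.write(
                    f"{g.chrom}\tgbmeth\tCDS\t{s + 1}\t{e}\t.\t{g.strand}\t0\tParent={tid}\n"
                )


def write_bed(intervals: list[tuple[str, int, int]], path) -> None:
    with open(path, "w") as fh:
        for chrom, s, e in intervals:
            fh.write(f"{chrom}\t{s}\t{e}\n")


def write_cytosine_report(records: pd.DataFrame, trinucleotides, path) -> None:
    out = records.copy()
    out["pos"] = out["pos"] + 1  # report dialect is 1-based
    out["trinucleotide"] = np.asarray(trinucleotides)
    out[["chrom", "pos", "strand", "n_meth", "n_unmeth", "context", "trinucleotide"]].to_csv(
        path, sep="\t", header=False, index=False
    )


def write_expression(matrices: list[ExpressionMatrix], prefix: Path) -> list[tuple[Path, Path]]:
    paths = []
    for i, m in enumerate(matrices, 1):
        vp = Path(f"{prefix}_expr{i}.tsv")
        sp = Path(f"{prefix}_expr{i}_samples.tsv")
        m.values.to_csv(vp, sep="\t")
        m.dataset_labels.rename("dataset").rename_axis("sample").to_csv(sp, sep="\t")
        paths.append((vp, sp))
    return paths


def write_dataset(ds: SimulatedDataset, outdir) -> dict[str, object]:
    """Write the whole simulated dataset as plain-text files; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, object] = {
        "genome": outdir / "genome.fasta",
        "gff": outdir / "genes.gff3",
        "te_bed": outdir / "te.bed",
        "report": outdir / "cytosine_report.tsv",
        "truth": outdir / "truth_pi.tsv",
        "housekeeping": outdir / "truth_housekeeping.tsv",
    }
    write_fasta(ds.genome, paths["genome"])
    write_gff3(ds.genes, paths["gff"])
    write_bed(ds.te_intervals, paths["te_bed"])
    write_cytosine_report(ds.records, ds.trinucleotides, paths["report"])
    ds.truth.pi.to_csv(paths["truth"], sep="\t", index=False)
    pd.Series(ds.truth.housekeeping, name="is_housekeeping").rename_axis("gene_id").to_csv(
        paths["housekeeping"], sep="\t"
    )
    paths["expression"] = write_expression(ds.expression, outdir / "sim")
    return paths
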