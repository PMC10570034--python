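"""Genome, gene-model and codon-degeneracy machinery.

Coordinates are 0-based half-open internally.  GFF3 is read as 1-based
inclusive and BED as 0-based half-open; the conversion happens at the file
boundary and nowhere else.

Degeneracy of a coding position follows the standard genetic code: a site is
*d*-fold degenerate when *d* of the four bases at that codon offset encode the
same amino acid (a substitution producing a stop codon counts as changing the
amino acid).  Zero-fold sites are fully exposed to selection; four-fold sites
are putatively neutral.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO
from Bio.Data import CodonTable

logger = logging.getLogger(__name__)

VALID_BASES = set("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

_STANDARD = CodonTable.unambiguous_dna_by_id[1]
STOP_CODONS = frozenset(_STANDARD.stop_codons)
CODON_TO_AA = dict(_STANDARD.forward_table)

# Feature category codes used by FeatureIndex arrays.
CAT_INTERGENIC, CAT_TE, CAT_INTRON, CAT_EXON = 0, 1, 2, 3
CATEGORY_NAMES = {
    CAT_INTERGENIC: "intergenic",
    CAT_TE: "TE",
    CAT_INTRON: "intron",
    CAT_EXON: "exon",
}


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class GeneModel:
    """A stranded gene with ordered exon and CDS intervals (0-based half-open)."""

    gene_id: str
    chrom: str
    strand: str
    exon_intervals: list[tuple[int, int]]
    cds_intervals: list[tuple[int, int]]
    is_housekeeping: bool | None = None

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"gene {self.gene_id}: strand must be + or -")
        for name, ivs in (("exon", self.exon_intervals), ("cds", self.cds_intervals)):
            for s, e in ivs:
                if e <= s:
                    raise ValueError(
                        f"gene {self.gene_id}: {name} interval [{s},{e}) is empty or reversed"
                    )
            for (s1, e1), (s2, e2) in itertools.pairwise(ivs):
                if s2 < e1:
                    raise ValueError(
                        f"gene {self.gene_id}: {name} intervals overlap or are unsorted"
                    )
        if self.cds_length == 0:
            raise ValueError(f"gene {self.gene_id}: total CDS length is zero")

    @property
    def cds_length(self) -> int:
        return sum(e - s for s, e in self.cds_intervals)

    @property
    def span(self) -> tuple[int, int]:
        ivs = self.exon_intervals or self.cds_intervals
        return ivs[0][0], ivs[-1][1]

    def exon_rank_intervals(self) -> list[tuple[int, tuple[int, int]]]:
        """(rank, interval) pairs; rank 1 is the 5'-most exon of the transcript."""
        ivs = self.exon_intervals
        order = ivs if self.strand == "+" else list(reversed(ivs))
        return [(k + 1, iv) for k, iv in enumerate(order)]

    def cds_genomic_positions(self) -> np.ndarray:
        """Genomic positions of CDS bases in coding (5'->3') order."""
        pos = np.concatenate([np.arange(s, e) for s, e in self.cds_intervals])
        return pos if self.strand == "+" else pos[::-1]


@dataclass
class CodingSiteAnnotation:
    chrom: str
    pos: int
    gene_id: str
    codon: str
    codon_offset: int
    degeneracy: int


@dataclass
class FeatureLabel:
    category: str  # "exon_rank_<k>", "intron", "TE" or "intergenic"
    gene_id: str | None = None


def load_genome(path) -> dict[str, str]:
    """Load a FASTA file into an ordered {name: uppercase sequence} mapping.

    Duplicate record names and characters outside {A,C,G,T,N} are errors.
    """
    genome: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in genome:
            raise ValueError(f"duplicate FASTA record name: {rec.id!r}")
        seq = str(rec.seq).upper()
        if not seq:
            raise ValueError(f"record {rec.id!r} has an empty sequence")
        bad = set(seq) - VALID_BASES
        if bad:
            raise ValueError(
                f"record {rec.id!r} contains invalid characters: {sorted(bad)}"
            )
        genome[rec.id] = seq
    return genome


def _gff_attributes(field9: str) -> dict[str, str]:
    out = {}
    for part in field9.strip().split(";"):
        if part and "=" in part:
            k, v = part.split("=", 1)
            out[k.strip()] = v.strip()
    return out


def load_annotation(path, genome: dict[str, str]) -> list[GeneModel]:
    """Parse GFF3 gene/mRNA/exon/CDS features into one GeneModel per gene.

    When a gene has several mRNAs the transcript with the longest total CDS is
    kept (ties broken by lexicographically smallest transcript ID).
    """
    mrna_parent: dict[str, str] = {}  # mRNA id -> gene id
    gene_meta: dict[str, tuple[str, str]] = {}  # gene id -> (chrom, strand)
    exons: dict[str, list[tuple[int, int]]] = {}
    cdss: dict[str, list[tuple[int, int]]] = {}

    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise ValueError(f"{path}:{lineno}: expected 9 GFF3 columns")
            chrom, _, ftype, start, end, _, strand, _, attrs = cols
            if ftype not in ("gene", "mRNA", "exon", "CDS"):
                continue
            s, e = int(start) - 1, int(end)  # 1-based inclusive -> 0-based half-open
            if e <= s:
                raise ValueError(f"{path}:{lineno}: interval end < start")
            if chrom not in genome:
                raise ValueError(f"{path}:{lineno}: unknown chromosome {chrom!r}")
            if e > len(genome[chrom]):
                raise ValueError(
                    f"{path}:{lineno}: interval [{s},{e}) exceeds length of {chrom}"
                )
            a = _gff_attributes(attrs)
            if ftype == "gene":
                gene_meta[a["ID"]] = (chrom, strand)
            elif ftype == "mRNA":
                mrna_parent[a["ID"]] = a.get("Parent", a["ID"])
                gene_meta.setdefault(a.get("Parent", a["ID"]), (chrom, strand))
            elif ftype == "exon":
                exons.setdefault(a["Parent"], []).append((s, e))
            else:  # CDS
                parent = a.get("Parent")
                if parent is None:
                    raise ValueError(f"{path}:{lineno}: CDS with no Parent attribute")
                cdss.setdefault(parent, []).append((s, e))

    for tid in cdss:
        if tid not in mrna_parent and tid not in gene_meta:
            raise ValueError(f"CDS parent {tid!r} resolves to no mRNA or gene")

    # Pick one transcript per gene: longest total CDS, ties by transcript id.
    by_gene: dict[str, list[str]] = {}
    for tid in cdss:
        gid = mrna_parent.get(tid, tid)
        by_gene.setdefault(gid, []).append(tid)

    genes = []
    for gid in gene_meta:
        tids = by_gene.get(gid)
        if not tids:
            continue
        tid = min(tids, key=lambda t: (-sum(e - s for s, e in cdss[t]), t))
        chrom, strand = gene_meta[gid]
        cds = sorted(cdss[tid])
        exon = sorted(exons.get(tid, cds))
        genes.append(
            GeneModel(
                gene_id=gid, chrom=chrom, strand=strand,
                exon_intervals=exon, cds_intervals=cds,
            )
        )
    return genes


def extract_cds(gene: GeneModel, genome: dict[str, str]) -> tuple[str, bool]:
    """Return (CDS nucleotide string in coding orientation, length-valid flag).

    Segments are concatenated in genomic order and the whole string is
    reverse-complemented for minus-strand genes.  Ns are retained; the
    positions of any codon containing an N are skipped downstream rather than
    failing here.
    """
    chrom_seq = genome[gene.chrom]
    seq = "".join(chrom_seq[s:e] for s, e in gene.cds_intervals)
    if gene.strand == "-":
        seq = reverse_complement(seq)
    return seq, len(seq) % 3 == 0


def codon_degeneracy(codon: str, offset: int) -> int:
    """Degeneracy class {0,2,3,4} of position `offset` of `codon`.

    Counts how many of the three alternative bases at `offset` encode the
    same amino acid; substitutions producing a stop codon count as changing.
    d alternatives preserved -> {0: 0-fold, 1: 2-fold, 2: 3-fold, 3: 4-fold}.
    """
    codon = codon.upper()
    if offset not in (0, 1, 2):
        raise ValueError(f"codon offset must be 0, 1 or 2, got {offset}")
    if set(codon) - set("ACGT") or len(codon) != 3:
        raise ValueError(f"ambiguous or invalid codon: {codon!r}")
    if codon in STOP_CODONS:
        raise ValueError(f"stop codon {codon} has no degeneracy class")
    aa = CODON_TO_AA[codon]
    preserved = 0
    for base in "ACGT":
        if base == codon[offset]:
            continue
        alt = codon[:offset] + base + codon[offset + 1:]
        if alt not in STOP_CODONS and CODON_TO_AA[alt] == aa:
            preserved += 1
    return {0: 0, 1: 2, 2: 3, 3: 4}[preserved]


@dataclass
class AnnotationStats:
    n_conflict_positions: int = 0
    n_stop_positions: int = 0
    n_skipped_n: int = 0
    n_invalid_genes: int = 0


def annotate_coding_sites(
    genes: list[GeneModel], genome: dict[str, str]
) -> tuple[list[CodingSiteAnnotation], AnnotationStats]:
    """Assign a degeneracy class to every coding genomic position.

    Genes whose CDS length is not a multiple of three are skipped.  Stop-codon
    positions are excluded, codons containing N are skipped, and positions
    claimed by more than one gene with *conflicting* degeneracy are dropped
    (agreeing assignments are kept once).
    """
    stats = AnnotationStats()
    by_pos: dict[tuple[str, int], CodingSiteAnnotation] = {}
    conflicted: set[tuple[str, int]] = set()

    for gene in genes:
        seq, valid = extract_cds(gene, genome)
        if not valid:
            stats.n_invalid_genes += 1
            continue
        gpos = gene.cds_genomic_positions()
        for i in range(0, len(seq), 3):
            codon = seq[i:i + 3]
            if "N" in codon:
                stats.n_skipped_n += 3
                continue
            if codon in STOP_CODONS:
                stats.n_stop_positions += 3
                continue
            for off in range(3):
                key = (gene.chrom, int(gpos[i + off]))
                deg = codon_degeneracy(codon, off)
                prev = by_pos.get(key)
                if prev is None:
                    if key not in conflicted:
                        by_pos[key] = CodingSiteAnnotation(
                            chrom=key[0], pos=key[1], gene_id=gene.gene_id,
                            codon=codon, codon_offset=off, degeneracy=deg,
                        )
                elif prev.degeneracy != deg:
                    del by_pos[key]
                    conflicted.add(key)

    stats.n_conflict_positions = len(conflicted)
    annotations = sorted(by_pos.values(), key=lambda a: (a.chrom, a.pos))
    return annotations, stats


class FeatureIndex:
    """Per-base feature classification of a genome.

    Precedence is exon > intron > TE > intergenic, so every position falls in
    exactly one category.  Besides point classification the index exposes
    per-base arrays (category, exon rank, gene index, region-instance id) used
    for vectorised feature summaries; intergenic stretches are split into
    fixed-width windows so the background contributes many observations.
    """

    def __init__(
        self,
        genome: dict[str, str],
        genes: list[GeneModel],
        te_intervals: list[tuple[str, int, int]] | None = None,
        intergenic_window: int = 2000,
        exclude_chroms: tuple[str, ...] = (),
    ) -> None:
        self.genes = genes
        self.chroms = [c for c in genome if c not in exclude_chroms]
        self.category: dict[str, np.ndarray] = {}
        self.exon_rank: dict[str, np.ndarray] = {}
        self.gene_idx: dict[str, np.ndarray] = {}
        self.instance: dict[str, np.ndarray] = {}
        self.instance_table: list[tuple[str, str, str | None]] = []  # (region_id, category, gene)

        for chrom in self.chroms:
            n = len(genome[chrom])
            self.category[chrom] = np.zeros(n, dtype=np.int8)
            self.exon_rank[chrom] = np.zeros(n, dtype=np.int32)
            self.gene_idx[chrom] = np.full(n, -1, dtype=np.int32)
            self.instance[chrom] = np.full(n, -1, dtype=np.int32)

        def new_instance(region_id, cat, gene_id=None) -> int:
            self.instance_table.append((region_id, cat, gene_id))
            return len(self.instance_table) - 1

        for chrom, s, e in te_intervals or []:
            if chrom not in self.category:
                continue
            iid = new_instance(f"{chrom}:{s}-{e}", "TE")
            self.category[chrom][s:e] = CAT_TE
            self.instance[chrom][s:e] = iid

        for gi, gene in enumerate(genes):
            if gene.chrom not in self.category:
                continue
            cat = self.category[gene.chrom]
            s0, e0 = gene.span
            # introns: gene span minus exons
            intron_no = 0
            prev_end = None
            for s, e in gene.exon_intervals:
                if prev_end is not None and s > prev_end:
                    intron_no += 1
                    iid = new_instance(
                        f"{gene.gene_id}:intron{intron_no}", "intron", gene.gene_id
                    )
                    cat[prev_end:s] = CAT_INTRON
                    self.instance[gene.chrom][prev_end:s] = iid
                prev_end = e
            for rank, (s, e) in gene.exon_rank_intervals():
                iid = new_instance(
                    f"{gene.gene_id}:exon{rank}", f"exon_rank_{rank}", gene.gene_id
                )
                cat[s:e] = CAT_EXON
                self.exon_rank[gene.chrom][s:e] = rank
                self.instance[gene.chrom][s:e] = iid
            self.gene_idx[gene.chrom][s0:e0] = gi

        # intergenic windows over whatever is left
        for chrom in self.chroms:
            free = np.flatnonzero(self.category[chrom] == CAT_INTERGENIC)
            if free.size == 0:
                continue
            breaks = np.flatnonzero(np.diff(free) > 1)
            runs = np.split(free, breaks + 1)
            for run in runs:
                for w0 in range(0, run.size, intergenic_window):
                    chunk = run[w0:w0 + intergenic_window]
                    iid = new_instance(
                        f"{chrom}:{chunk[0]}-{chunk[-1] + 1}", "intergenic"
                    )
                    self.instance[chrom][chunk] = iid

    def classify(self, chrom: str, pos: int) -> FeatureLabel:
        cat = int(self.category[chrom][pos])
        if cat == CAT_EXON:
            rank = int(self.exon_rank[chrom][pos])
            gid = self.genes[self.gene_idx[chrom][pos]].gene_id
            return FeatureLabel(category=f"exon_rank_{rank}", gene_id=gid)
        if cat == CAT_INTRON:
            gid = self.genes[self.gene_idx[chrom][pos]].gene_id
            return FeatureLabel(category="intron", gene_id=gid)
        return FeatureLabel(category=CATEGORY_NAMES[cat])


def classify_position(
    pos: int,
    chrom: str,
    genes: list[GeneModel],
    te_intervals: list[tuple[str, int, int]],
    genome: dict[str, str] | None = None,
    index: FeatureIndex | None = None,
) -> FeatureLabel:
    """Classify one genomic position (exon > intron > TE > intergenic).

    For repeated queries build a :class:`FeatureIndex` once and pass it in.
    """
    if index is None:
        if genome is None:
            raise ValueError("either a genome or a prebuilt FeatureIndex is required")
        index = FeatureIndex(genome, genes, te_intervals)
    return index.classify(chrom, pos)


def load_bed(path) -> list[tuple[str, int, int]]:
    """Read BED3 intervals (already 0-based half-open)."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            chrom, s, e = line.split("\t")[:3]
            out.append((chrom, int(s), int(e)))
    return out


def write_coding_sites_tsv(annotations: list[CodingSiteAnnotation], path) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tpos\tgene_id\tcodon\tcodon_offset\tdegeneracy\n")
        for a in annotations:
            fh.write(
                f"{a.chrom}\t{a.pos}\t{a.gene_id}\t{a.codon}\t{a.codon_offset}\t{a.degeneracy}\n"
            )
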