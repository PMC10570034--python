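"""The whole pipeline on files, as the CLI runs it.

Writes a simulated dataset to disk (FASTA, GFF3, BED, cytosine report,
expression TSVs), then runs every stage — calibration, calling, degeneracy
annotation, feature summary, housekeeping join, statistics, metaplot — and
prints the summary.  Equivalent shell usage:

    gbmeth simulate --seed 11 --out simdata
    gbmeth run --config pipeline.yaml
"""

import json
import tempfile
from pathlib import Path

from gbmeth import PipelineConfig, SimulationConfig, run_pipeline, simulate_dataset
from gbmeth.simulate import write_dataset

tmp = Path(tempfile.mkdtemp())
cfg = SimulationConfig(seed=11, n_chrom=1, chrom_len=100_000, n_genes=25,
                       spike_len=5_000)
paths = write_dataset(simulate_dataset(cfg), tmp / "simdata")

pipeline_cfg = PipelineConfig(
    genome=str(paths["genome"]),
    gff=str(paths["gff"]),
    cytosine_report=str(paths["report"]),
    te_bed=str(paths["te_bed"]),
    expression=[str(v) for v, _ in paths["expression"]],
    sample_maps=[str(s) for _, s in paths["expression"]],
    out_dir=str(tmp / "out"),
)
summary = run_pipeline(pipeline_cfg)

print(json.dumps({
    "conversion": summary["conversion"],
    "context_levels_pct": summary["context_levels_pct"],
    "n_tested": summary["n_tested"],
    "n_methylated": summary["n_methylated"],
    "gene_classes": summary["gene_classes"],
    "kruskal_exon_ranks": summary["statistics"]["kruskal_exon_ranks"],
}, indent=2))
print(f"\nartifacts in {tmp / 'out'}")
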