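"""Housekeeping-gene identification from multi-dataset expression matrices.

A putative housekeeping gene is one detected as expressed in every sample of
every supplied dataset (e.g. developmental landmarks plus environmental
exposures).  "Expressed" defaults to strictly positive; a minimum-expression
threshold can be supplied instead.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass
class ExpressionMatrix:
    """Gene x sample non-negative expression with a dataset label per sample."""

    values: pd.DataFrame  # genes in rows, samples in columns
    dataset_labels: pd.Series  # sample -> dataset name

    def __post_init__(self) -> None:
        if self.values.columns.duplicated().any():
            raise ValueError("duplicate sample identifiers")
        if self.values.index.duplicated().any():
            raise ValueError("duplicate gene identifiers")
        missing = set(self.values.columns) - set(self.dataset_labels.index)
        if missing:
            raise ValueError(f"samples with no dataset label: {sorted(missing)}")
        if (self.values.to_numpy() < 0).any():
            raise ValueError("expression values must be non-negative")


def load_expression(path, sample_map_path) -> ExpressionMatrix:
    """Read a gene x sample TSV plus a sample->dataset sidecar mapping.

    Missing values ("NA"/empty) are treated as not expressed (0), with a
    logged count.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"{path}: duplicate gene id {dup!r}")
    n_na = int(df.isna().sum().sum())
    if n_na:
        logger.warning("%s: %d missing values treated as 0 (not expressed)", path, n_na)
        df = df.fillna(0.0)
    if (df.to_numpy() < 0).any():
        raise ValueError(f"{path}: negative expression value")
    smap = pd.read_csv(sample_map_path, sep="\t", index_col=0).iloc[:, 0]
    return ExpressionMatrix(values=df.astype(float), dataset_labels=smap)


def identify_housekeeping(
    matrices: list[ExpressionMatrix], min_expr: float = 0.0
) -> set[str]:
    """Genes expressed in every sample of every matrix.

    With ``min_expr == 0`` a gene must be strictly positive everywhere;
    otherwise it must reach ``min_expr`` in every sample.  Genes absent from
    any matrix are not housekeeping.
    """
    if not matrices:
        raise ValueError("at least one expression matrix is required")
    if min_expr < 0:
        raise ValueError("min_expr must be non-negative")
    hk: set[str] | None = None
    for m in matrices:
        vals = m.values
        ok = (vals > 0).all(axis=1) if min_expr == 0 else (vals >= min_expr).all(axis=1)
        genes = set(vals.index[ok])
        hk = genes if hk is None else hk & genes
    return hk or set()


def join_methylation(
    hk_set: set[str],
    gene_levels: pd.DataFrame,
    expressed_set: set[str],
) -> pd.DataFrame:
    """Join housekeeping status onto gene weighted methylation levels.

    Keeps only genes with a defined weighted level AND detectable expression;
    the number excluded is recorded in ``.attrs['n_excluded']``.  Output
    columns: gene_id, weighted_level, is_housekeeping.
    """
    df = gene_levels[["region_id", "weighted_level"]].rename(
        columns={"region_id": "gene_id"}
    )
    keep = df["weighted_level"].notna() & df["gene_id"].isin(expressed_set)
    out = df[keep].copy()
    out["is_housekeeping"] = out["gene_id"].isin(hk_set)
    out = out.reset_index(drop=True)
    out.attrs["n_excluded"] = int((~keep).sum())
    return out


def expressed_genes(matrices: list[ExpressionMatrix]) -> set[str]:
    """Genes with detectable expression (positive in at least one sample)."""
    out: set[str] = set()
    for m in matrices:
        out |= set(m.values.index[(m.values > 0).any(axis=1)])
    return out
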