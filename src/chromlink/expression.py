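"""Expression-level computations: RPKM, differential-expression labels, quartiles.

Differential testing itself happens upstream (this module consumes a
table with per-condition RPKM, log2 fold change and FDR); here we apply
the expression filter (RPKM >= 1 in at least one condition), the effect
and significance thresholds (|log2FC| >= 0.5, FDR <= 0.05, all
inclusive), and quartile binning of expressed genes.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

RPKM_EXPRESSED = 1.0
LOG2FC_THRESHOLD = 0.5
FDR_THRESHOLD = 0.05

DE_STATUSES = ("down", "up", "unchanged", "not_expressed")


def rpkm(count: float, exon_length_sum: int, library_size: float) -> float:
    """Reads per kilobase of merged exon per million mapped reads."""
    if exon_length_sum <= 0:
        raise ValueError("exon_length_sum must be positive")
    if library_size <= 0:
        raise ValueError("library_size must be positive")
    return count / (exon_length_sum / 1e3) / (library_size / 1e6)


def assign_de_status(
    table: pd.DataFrame,
    rpkm_expressed: float = RPKM_EXPRESSED,
    log2fc_threshold: float = LOG2FC_THRESHOLD,
    fdr_threshold: float = FDR_THRESHOLD,
) -> pd.DataFrame:
    """Add a ``de_status`` column partitioning genes.

    A gene is expressed iff max(rpkm_ctrl, rpkm_ko) >= 1; expressed genes
    are ``down``/``up`` when the fold-change and FDR thresholds are met
    (boundaries inclusive) and ``unchanged`` otherwise. Records with
    missing FDR are treated as unchanged with a warning.
    """
    df = table.copy()
    missing = df["fdr"].isna()
    if missing.any():
        warnings.warn(
            f"{int(missing.sum())} records lack an FDR value; "
            "treated as unchanged"
        )
    expressed = df[["rpkm_ctrl", "rpkm_ko"]].max(axis=1) >= rpkm_expressed
    sig = (df["fdr"] <= fdr_threshold) & ~missing
    down = expressed & sig & (df["log2fc"] <= -log2fc_threshold)
    up = expressed & sig & (df["log2fc"] >= log2fc_threshold)
    status = np.where(
        ~expressed, "not_expressed",
        np.where(down, "down", np.where(up, "up", "unchanged")),
    )
    df["de_status"] = status
    return df


def expression_quartiles(
    records: pd.DataFrame, rpkm_column: str = "rpkm_ctrl"
) -> pd.Series:
    """Quartile label (1 = bottom, 4 = top) for each expressed gene.

    Genes are ranked by control-condition RPKM and split into four
    equal-count groups (sizes differing by at most one); ties are broken
    by stable gene_id order.
    """
    if len(records) < 4:
        raise ValueError("need at least 4 expressed genes for quartiles")
    order = records.sort_values(
        [rpkm_column, "gene_id"], kind="stable"
    ).index
    n = len(order)
    bounds = [round(i * n / 4) for i in range(5)]
    labels = pd.Series(0, index=records.index, name="quartile")
    for q in range(4):
        labels.loc[order[bounds[q]:bounds[q + 1]]] = q + 1
    return labels


def read_expression_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"gene_id", "rpkm_ctrl", "rpkm_ko", "log2fc", "fdr"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"expression table missing columns: {sorted(missing)}")
    return df
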