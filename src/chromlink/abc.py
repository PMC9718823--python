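"""Adapted Activity-by-Contact scoring of candidate enhancer-gene pairs.

Every H3K27ac peak (including promoter peaks) is a candidate enhancer.
For a gene g, candidates are the enhancers whose peak midpoint falls in a
5 Mb window centered on the gene's most-5' TSS (left boundary inclusive,
right exclusive); sex chromosomes are excluded. Each candidate pair is
scored by

    score(e, g) = A_eg * C_eg / sum_i in E_g  A_ig * C_ig

where C_eg is the balanced Hi-C contact between the enhancer-midpoint bin
and the TSS bin, and the gene-specific activity distributes the peak
signal A_e over the enhancer's own candidate target genes G_e:

    A_eg = A_e * C_eg / sum_j in G_e  C_ej

Scores are relative contributions: per gene they sum to one whenever at
least one candidate has non-zero contact. Pairs with score >= 0.02
(inclusive) constitute the regulatory map.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .annotation import GeneModel
from .hic import ContactMatrix, contact
from .intervals import GenomicInterval

ABC_WINDOW = 5_000_000
ABC_THRESHOLD = 0.02


@dataclass
class Enhancer:
    """A candidate regulatory element: an H3K27ac peak with its signal."""

    name: str
    interval: GenomicInterval
    activity: float  # narrowPeak signalValue

    def __post_init__(self) -> None:
        if self.activity < 0:
            raise ValueError(f"enhancer {self.name}: negative activity")

    @property
    def midpoint(self) -> int:
        return self.interval.midpoint

    @property
    def chrom(self) -> str:
        return self.interval.chrom


def read_narrowpeak(path: str | Path) -> list[Enhancer]:
    """Read ENCODE narrowPeak; signalValue is column 7."""
    out: list[Enhancer] = []
    with open(path) as fh:
        for k, line in enumerate(fh):
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 7:
                raise ValueError(
                    f"{path}: narrowPeak needs >= 7 columns, got {len(f)}"
                )
            name = f[3] if f[3] not in (".", "") else f"peak{k}"
            out.append(
                Enhancer(name, GenomicInterval(f[0], int(f[1]), int(f[2])),
                         float(f[6]))
            )
    return out


def in_window(tss: int, midpoint: int, window: int = ABC_WINDOW) -> bool:
    """Window membership: midpoint in [tss - w/2, tss + w/2)."""
    half = window // 2
    return tss - half <= midpoint < tss + half


def candidate_enhancers(
    gene: GeneModel,
    enhancers: Sequence[Enhancer],
    window: int = ABC_WINDOW,
) -> list[Enhancer]:
    """E_g: enhancers whose midpoints lie in the gene's scoring window."""
    if not gene.is_autosomal:
        warnings.warn(
            f"gene {gene.gene_id} on {gene.chrom}: sex chromosomes are "
            "excluded from ABC scoring"
        )
        return []
    return [
        e for e in enhancers
        if e.chrom == gene.chrom and in_window(gene.tss, e.midpoint, window)
    ]


def gene_specific_activity(
    enhancer: Enhancer,
    gene: GeneModel,
    contacts: ContactMatrix,
    target_genes: Sequence[GeneModel],
) -> float:
    """A_eg: peak signal shared across the enhancer's candidate targets."""
    if all(g.gene_id != gene.gene_id for g in target_genes):
        raise ValueError(
            f"gene {gene.gene_id} is not among the candidate targets of "
            f"enhancer {enhancer.name}"
        )
    c_eg = contact(contacts, enhancer.midpoint, gene.tss)
    total = sum(contact(contacts, enhancer.midpoint, g.tss)
                for g in target_genes)
    if total == 0:
        return 0.0
    return enhancer.activity * c_eg / total


def abc_scores(
    gene: GeneModel,
    candidates: Sequence[Enhancer],
    contacts: ContactMatrix,
    all_genes: Sequence[GeneModel],
    window: int = ABC_WINDOW,
    condition: str = "ctrl",
) -> pd.DataFrame:
    """Score all candidates of one gene (see module docstring)."""
    rows = []
    for e in candidates:
        targets = [
            g for g in all_genes
            if g.chrom == e.chrom and g.is_autosomal
            and in_window(g.tss, e.midpoint, window)
        ]
        a_eg = gene_specific_activity(e, gene, contacts, targets)
        c_eg = contact(contacts, e.midpoint, gene.tss)
        rows.append(
            {
                "enhancer": e.name, "chrom": e.chrom,
                "start": e.interval.start, "end": e.interval.end,
                "gene_id": gene.gene_id, "activity": e.activity,
                "contact": c_eg, "gene_specific_activity": a_eg,
                "product": a_eg * c_eg, "condition": condition,
            }
        )
    df = pd.DataFrame(
        rows, columns=["enhancer", "chrom", "start", "end", "gene_id",
                       "activity", "contact", "gene_specific_activity",
                       "product", "condition"],
    )
    total = df["product"].sum()
    df["abc_score"] = df["product"] / total if total > 0 else 0.0
    return df.drop(columns=["product"])


def score_all(
    genes: Sequence[GeneModel],
    enhancers: Sequence[Enhancer],
    matrices: Mapping[str, ContactMatrix],
    window: int = ABC_WINDOW,
    condition: str = "ctrl",
) -> pd.DataFrame:
    """Vectorized scoring of every autosomal gene against every enhancer.

    Equivalent to calling :func:`abc_scores` per gene, but with the
    contact lookups and the per-enhancer contact normalization computed
    once per chromosome.
    """
    half = window // 2
    frames = []
    for chrom, cm in matrices.items():
        if cm.balanced is None:
            raise ValueError(f"{chrom}: matrix not balanced")
        cgenes = [g for g in genes if g.chrom == chrom and g.is_autosomal]
        cenh = [e for e in enhancers if e.chrom == chrom]
        if not cgenes or not cenh:
            continue
        tss = np.array([g.tss for g in cgenes])
        mids = np.array([e.midpoint for e in cenh])
        acts = np.array([e.activity for e in cenh])
        tss_bins = np.clip(tss // cm.resolution, 0, cm.n_bins - 1)
        mid_bins = np.clip(mids // cm.resolution, 0, cm.n_bins - 1)
        c = cm.balanced[np.ix_(mid_bins, tss_bins)]  # enhancer x gene
        member = (tss[None, :] - half <= mids[:, None]) & (
            mids[:, None] < tss[None, :] + half
        )
        c = np.where(member, c, 0.0)
        denom_e = c.sum(axis=1, keepdims=True)  # sum over G_e
        with np.errstate(invalid="ignore", divide="ignore"):
            a_eg = np.where(denom_e > 0, acts[:, None] * c / denom_e, 0.0)
        prod = a_eg * c
        denom_g = prod.sum(axis=0, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            score = np.where(denom_g > 0, prod / denom_g, 0.0)
        e_idx, g_idx = np.nonzero(member)
        frames.append(
            pd.DataFrame(
                {
                    "enhancer": [cenh[i].name for i in e_idx],
                    "chrom": chrom,
                    "start": [cenh[i].interval.start for i in e_idx],
                    "end": [cenh[i].interval.end for i in e_idx],
                    "gene_id": [cgenes[j].gene_id for j in g_idx],
                    "activity": acts[e_idx],
                    "contact": c[e_idx, g_idx],
                    "gene_specific_activity": a_eg[e_idx, g_idx],
                    "condition": condition,
                    "abc_score": score[e_idx, g_idx],
                }
            )
        )
    if not frames:
        return pd.DataFrame(
            columns=["enhancer", "chrom", "start", "end", "gene_id",
                     "activity", "contact", "gene_specific_activity",
                     "condition", "abc_score"]
        )
    return pd.concat(frames, ignore_index=True)


def filter_interactions(
    interactions: pd.DataFrame, threshold: float = ABC_THRESHOLD
) -> pd.DataFrame:
    """Keep pairs with score >= threshold (inclusive)."""
    return interactions[interactions["abc_score"] >= threshold].reset_index(
        drop=True
    )


def flag_promoter_overlaps(
    interactions: pd.DataFrame, genes: Sequence[GeneModel]
) -> pd.DataFrame:
    """Mark surviving enhancers that overlap any gene promoter."""
    proms: dict[str, list[tuple[int, int]]] = {}
    for g in genes:
        proms.setdefault(g.chrom, []).append((g.promoter.start,
                                              g.promoter.end))
    starts = {c: np.array(sorted(s for s, _ in v)) for c, v in proms.items()}
    ends = {c: np.array(sorted(e for _, e in v)) for c, v in proms.items()}
    flags = []
    for _, row in interactions.iterrows():
        c = row["chrom"]
        if c not in starts:
            flags.append(False)
            continue
        n = starts[c].size
        n_before = np.searchsorted(ends[c], row["start"], "right")
        n_after = n - np.searchsorted(starts[c], row["end"], "left")
        flags.append(bool(n - n_before - n_after > 0))
    out = interactions.copy()
    out["overlaps_promoter"] = flags
    return out
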