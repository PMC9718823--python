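"""Gene annotation model: GTF parsing, promoters, and exclusive feature labels.

A gene is represented at gene level only: its body spans from the most 5'
to the most 3' annotated coordinate, its TSS is the most 5' position in
gene orientation, and its promoter is a fixed 400 bp window centered on
that TSS. Every base of the genome receives exactly one label out of
{promoter/TSS, UTR, exon, intron, intergenic}, with precedence
promoter > UTR > exon > intron evaluated jointly over all genes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .intervals import GenomicInterval, union_length

PROMOTER_HALF_WIDTH = 200  # promoter = +/-200 bp around the most-5' TSS

# feature-map label codes, in increasing precedence
INTERGENIC, INTRON, EXON, UTR, PROMOTER = 0, 1, 2, 3, 4
LABEL_NAMES = {
    INTERGENIC: "intergenic",
    INTRON: "intron",
    EXON: "exon",
    UTR: "UTR",
    PROMOTER: "promoter/TSS",
}

SEX_CHROMOSOMES = frozenset({"chrX", "chrY", "X", "Y"})


class GtfParseError(ValueError):
    pass


@dataclass
class GeneModel:
    """A gene with strand-aware most-5' TSS, merged exons, and promoter."""

    gene_id: str
    chrom: str
    strand: str
    exons: list[GenomicInterval]
    utrs: list[GenomicInterval] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be + or -")
        if not self.exons:
            raise ValueError(f"gene {self.gene_id}: no exons")
        start = min(e.start for e in self.exons)
        end = max(e.end for e in self.exons)
        self.gene_body = GenomicInterval(self.chrom, start, end, self.strand)
        self.tss = start if self.strand == "+" else end
        self.promoter = GenomicInterval(
            self.chrom,
            max(0, self.tss - PROMOTER_HALF_WIDTH),
            self.tss + PROMOTER_HALF_WIDTH,
            self.strand,
        )
        self.exon_length_sum = union_length(
            (e.start, e.end) for e in self.exons
        )

    @property
    def is_autosomal(self) -> bool:
        return self.chrom not in SEX_CHROMOSOMES


def _parse_attributes(attr: str) -> dict[str, str]:
    out: dict[str, str] = {}
    for part in attr.strip().split(";"):
        part = part.strip()
        if not part:
            continue
        key, _, value = part.partition(" ")
        out[key] = value.strip().strip('"')
    return out


def parse_gtf(path: str | Path) -> list[GeneModel]:
    """Read a GENCODE-dialect GTF into gene-level models.

    GTF coordinates (1-based inclusive) are converted to 0-based half-open.
    Exons are collected per ``gene_id``; ``UTR`` / ``five_prime_utr`` /
    ``three_prime_utr`` features populate the UTR list. Genes with no exon
    feature are skipped with a warning.
    """
    exons: dict[str, list[GenomicInterval]] = {}
    utrs: dict[str, list[GenomicInterval]] = {}
    meta: dict[str, tuple[str, str]] = {}
    order: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                raise GtfParseError(
                    f"{path}: malformed GTF line {lineno}: "
                    f"expected 9 tab-separated fields, got {len(fields)}"
                )
            chrom, _, feature, start_s, end_s, _, strand, _, attr = fields[:9]
            try:
                start = int(start_s) - 1  # to 0-based half-open
                end = int(end_s)
            except ValueError as exc:
                raise GtfParseError(
                    f"{path}: malformed coordinates on line {lineno}"
                ) from exc
            if feature not in ("gene", "exon", "UTR", "five_prime_utr",
                               "three_prime_utr"):
                continue
            gene_id = _parse_attributes(attr).get("gene_id")
            if gene_id is None:
                raise GtfParseError(
                    f"{path}: line {lineno} lacks a gene_id attribute"
                )
            if gene_id not in meta:
                meta[gene_id] = (chrom, strand)
                order.append(gene_id)
            if feature == "exon":
                exons.setdefault(gene_id, []).append(
                    GenomicInterval(chrom, start, end, strand)
                )
            elif feature != "gene":
                utrs.setdefault(gene_id, []).append(
                    GenomicInterval(chrom, start, end, strand)
                )
    genes: list[GeneModel] = []
    for gene_id in order:
        chrom, strand = meta[gene_id]
        if gene_id not in exons:
            warnings.warn(f"gene {gene_id} has no exons; skipped")
            continue
        genes.append(
            GeneModel(gene_id, chrom, strand, exons[gene_id],
                      utrs.get(gene_id, []))
        )
    return genes


def write_gtf(genes: Sequence[GeneModel], path: str | Path) -> None:
    """Write gene/exon/UTR records back to GTF (1-based inclusive)."""
    with open(path, "w") as fh:
        for g in genes:
            attr = f'gene_id "{g.gene_id}";'
            rows = [("gene", g.gene_body)]
            rows += [("exon", e) for e in g.exons]
            rows += [("UTR", u) for u in g.utrs]
            for feature, iv in rows:
                fh.write(
                    f"{g.chrom}\tchromlink\t{feature}\t{iv.start + 1}\t"
                    f"{iv.end}\t.\t{g.strand}\t.\t{attr}\n"
                )


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "size"])
    return dict(zip(df["chrom"].astype(str), df["size"].astype(int)))


def write_chrom_sizes(sizes: Mapping[str, int], path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, size in sizes.items():
            fh.write(f"{chrom}\t{size}\n")


def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read BED3/BED6 intervals (column 6 = strand when present)."""
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            fields = line.split("\t")
            strand = fields[5].strip() if len(fields) > 5 else "."
            out.append(
                GenomicInterval(fields[0], int(fields[1]), int(fields[2]),
                                strand if strand in "+-" else ".")
            )
    return out


def write_bed(
    intervals: Sequence[GenomicInterval],
    path: str | Path,
    names: Sequence[str] | None = None,
) -> None:
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            name = names[i] if names is not None else f"iv{i}"
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t0\t{iv.strand}\n"
            )


class FeatureMap:
    """Exclusive per-base feature labels for a genome.

    Stores one uint8 array per chromosome; adequate for the compact
    genomes this package targets (labels cost 1 byte/bp).
    """

    def __init__(self, labels: dict[str, np.ndarray]):
        self.labels = labels

    def label_at(self, chrom: str, pos: int) -> str:
        return LABEL_NAMES[int(self.labels[chrom][pos])]


def build_feature_map(
    genes: Sequence[GeneModel], chrom_sizes: Mapping[str, int]
) -> FeatureMap:
    """Assign each base exactly one label.

    Layers are painted in increasing precedence (gene body as intron,
    then exon, UTR, promoter), jointly over all genes, so any gene's
    promoter beats any gene's exon regardless of input order.
    """
    arrays = {
        chrom: np.zeros(size, dtype=np.uint8)
        for chrom, size in chrom_sizes.items()
    }
    for g in genes:
        if g.chrom not in arrays:
            raise ValueError(f"gene {g.gene_id} on unknown chromosome {g.chrom}")
        if g.gene_body.end > chrom_sizes[g.chrom]:
            raise ValueError(
                f"gene {g.gene_id} extends beyond {g.chrom} "
                f"({g.gene_body.end} > {chrom_sizes[g.chrom]})"
            )
    layers = [
        (INTRON, [(g.chrom, g.gene_body.start, g.gene_body.end) for g in genes]),
        (EXON, [(g.chrom, e.start, e.end) for g in genes for e in g.exons]),
        (UTR, [(g.chrom, u.start, u.end) for g in genes for u in g.utrs]),
        (PROMOTER, [(g.chrom, g.promoter.start, g.promoter.end) for g in genes]),
    ]
    for code, regions in layers:
        for chrom, start, end in regions:
            arr = arrays[chrom]
            arr[start:min(end, arr.size)] = code
    return FeatureMap(arrays)


def peak_feature_distribution(
    peaks: Sequence[GenomicInterval], fmap: FeatureMap
) -> dict[str, float]:
    """Per-base-pair genomic distribution of a peak set.

    Every base of every peak is looked up in the feature map; the returned
    fractions (over all peak bases) sum to 1.
    """
    if not peaks:
        raise ValueError("empty peak list")
    counts = np.zeros(5, dtype=np.int64)
    for p in peaks:
        if p.chrom not in fmap.labels:
            raise ValueError(f"peak on chromosome {p.chrom} not in feature map")
        arr = fmap.labels[p.chrom]
        seg = arr[p.start:min(p.end, arr.size)]
        counts += np.bincount(seg, minlength=5)
    total = counts.sum()
    return {LABEL_NAMES[code]: counts[code] / total for code in LABEL_NAMES}
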