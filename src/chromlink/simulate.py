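"""Synthetic multi-chromosome genome with planted regulatory truth.

The generator emulates the statistical structure the integration
pipeline assumes: a compact genome (two 10 Mb autosomes plus a 5 Mb X
chromosome) with non-overlapping genes; condition-specific H3K79me2
reads and peaks; H3K27ac peaks in both conditions; differential-peak
calls; a distance-decaying Hi-C contact matrix with planted
enhancer-promoter loops; a differential-expression table produced by the
generator's own naive count model and test (mirroring the division of
labor in which DE testing happens upstream of the pipeline); and
motif-seeded RE sequences.

Planted gene classes:

* ``gb_re_down``    - gene-body methylated, activating K79-REs, downregulated
                      on knockout (a "many-RE" subset carries >= 6 REs and an
                      extra effect);
* ``gb_only_down``  - gene-body methylated, only plain (non-K79) REs,
                      moderately downregulated;
* ``silencing_re_up`` - no gene-body signal, silencing K79-REs carrying a
                      planted motif, upregulated on knockout;
* ``null``          - unchanged (a small subset is not expressed). All X
                      chromosome genes are null, to exercise the
                      autosome-only ABC rule.

Every output file is a pure function of the configuration and its seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import motifs as motifs_mod
from .annotation import (GeneModel, write_bed, write_chrom_sizes, write_gtf)
from .expression import rpkm as rpkm_of
from .intervals import GenomicInterval
from .motifs import bh_adjust, write_jaspar

CLASS_GB_RE_DOWN = "gb_re_down"
CLASS_GB_ONLY_DOWN = "gb_only_down"
CLASS_SILENCING_UP = "silencing_re_up"
CLASS_NULL = "null"


@dataclass
class TruthConfig:
    """All knobs of the generator; defaults define the study conditions."""

    seed: int = 0
    n_genes: int = 300
    chrom_sizes: dict = field(
        default_factory=lambda: {
            "chr1": 10_000_000, "chr2": 10_000_000, "chrX": 5_000_000,
        }
    )
    resolution: int = 5000
    # planted class proportions over autosomal genes (sum to 1)
    class_proportions: dict = field(
        default_factory=lambda: {
            CLASS_GB_RE_DOWN: 0.15, CLASS_GB_ONLY_DOWN: 0.05,
            CLASS_SILENCING_UP: 0.15, CLASS_NULL: 0.65,
        }
    )
    # true log2 fold-change (mean, sd) per class
    effect_sizes: dict = field(
        default_factory=lambda: {
            CLASS_GB_RE_DOWN: (-1.5, 0.3), CLASS_GB_ONLY_DOWN: (-0.7, 0.3),
            CLASS_SILENCING_UP: (1.0, 0.3), CLASS_NULL: (0.0, 0.15),
        }
    )
    many_re_fraction: float = 0.5  # of gb_re_down genes get >= 6 REs ...
    many_re_extra_log2fc: float = -0.5  # ... and this extra shift
    gene_length_log_median: float = np.log(20_000)
    gene_length_log_sd: float = 0.45
    # Hi-C: counts ~ Poisson(mu * (|i-j|+1)^-alpha), loops boosted x5
    hic_mu: float = 100.0
    hic_alpha: float = 1.0
    loop_boost: float = 5.0
    hic_max_distance_bins: int = 1000
    # H3K27ac peak signal (lognormal) and RE geometry
    peak_signal_log_mean: float = np.log(10.0)
    peak_signal_log_sd: float = 0.5
    background_res_per_mb: float = 21.0  # ~52k acetylation peaks / 2.5 Gb
    re_min_length: int = 400
    re_max_length: int = 1200
    # planted REs sit in a tight TSS neighborhood: with the multiplicative
    # loop boost the relative ABC score falls roughly with the square of
    # contact, so elements much farther than ~60 kb from their own gene
    # would not survive the 0.02 score cut against their nearer siblings
    re_min_tss_distance: int = 15_000
    re_max_tss_distance: int = 60_000
    # expression model
    nb_dispersion: float = 0.02
    n_replicates: int = 3
    library_size: float = 2e7
    not_expressed_fraction: float = 0.05  # of null genes
    gb_null_fraction: float = 0.4  # of null genes also gene-body methylated
    # differential H3K27ac planting
    diff_k27_up_fraction: float = 0.3  # of silencing REs
    diff_k27_down_fraction: float = 0.2  # of activating REs
    n_ko_only_res: int = 3  # per autosome; cKO-only, diff-up
    # motif planting
    planted_motif: str = "TGACGTCA"
    n_sites_per_silencing_re: int = 5
    n_decoy_pwms: int = 19
    re_gc_content: float = 0.45

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, default=str)


# ---------------------------------------------------------------------------
# genome


def generate_genome(
    cfg: TruthConfig, outdir: str | Path | None = None
) -> tuple[list[GeneModel], dict[str, int]]:
    """Non-overlapping genes with 1-10 exons on mixed strands.

    Gene counts per chromosome are proportional to chromosome size;
    lengths are lognormal (median ~20 kb). Writes ``genes.gtf`` and
    ``chrom.sizes`` when ``outdir`` is given.
    """
    rng = np.random.default_rng(cfg.seed)
    total = sum(cfg.chrom_sizes.values())
    genes: list[GeneModel] = []
    gene_no = 0
    for chrom, size in cfg.chrom_sizes.items():
        n_chrom = int(round(cfg.n_genes * size / total))
        lengths = np.exp(
            rng.normal(cfg.gene_length_log_median, cfg.gene_length_log_sd,
                       n_chrom)
        ).astype(int)
        lengths = np.clip(lengths, 2_000, None)
        if lengths.sum() > 0.75 * size:
            raise ValueError(
                f"{chrom}: genes do not fit ({lengths.sum()} bp of genes on "
                f"a {size} bp chromosome); enlarge the genome"
            )
        # random non-overlapping placement: distribute leftover space as gaps
        free = size - lengths.sum() - 20_000
        gaps = rng.dirichlet(np.ones(n_chrom + 1)) * free
        pos = 10_000
        for k in range(n_chrom):
            pos += int(gaps[k])
            start, length = pos, int(lengths[k])
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append(
                _make_gene(f"G{gene_no:04d}", chrom, strand, start, length,
                           rng)
            )
            gene_no += 1
            pos += length
    sizes = dict(cfg.chrom_sizes)
    if outdir is not None:
        outdir = Path(outdir)
        write_gtf(genes, outdir / "genes.gtf")
        write_chrom_sizes(sizes, outdir / "chrom.sizes")
    return genes, sizes


def _make_gene(
    gene_id: str, chrom: str, strand: str, start: int, length: int,
    rng: np.random.Generator,
) -> GeneModel:
    n_exons = int(rng.integers(1, 11))
    n_seg = 2 * n_exons - 1  # exon, intron, ..., exon
    weights = rng.dirichlet(np.ones(n_seg))
    bounds = np.concatenate([[0], np.cumsum(weights)]) * length
    bounds = np.round(bounds).astype(int)
    bounds[-1] = length
    exons, utrs = [], []
    for k in range(n_seg):
        s, e = start + bounds[k], start + bounds[k + 1]
        if k % 2 == 0 and e > s:
            exons.append(GenomicInterval(chrom, s, e, strand))
    if not exons:  # degenerate rounding; one exon spanning the gene
        exons = [GenomicInterval(chrom, start, start + length, strand)]
    # terminal 100 bp of the outermost exons as UTRs (when long enough)
    if len(exons) >= 2:
        first, last = exons[0], exons[-1]
        if first.length > 200:
            utrs.append(GenomicInterval(chrom, first.start,
                                        first.start + 100, strand))
        if last.length > 200:
            utrs.append(GenomicInterval(chrom, last.end - 100, last.end,
                                        strand))
    return GeneModel(gene_id, chrom, strand, exons, utrs)


# ---------------------------------------------------------------------------
# truth assignment


def plant_truth(
    cfg: TruthConfig, genes: list[GeneModel]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Assign planted classes to genes and plant regulatory elements.

    Gene-body-only genes are confined to the first 1.8 Mb of each
    autosome with K79-RE-bearing classes kept beyond 2.6 Mb, so that no
    K79-RE can acquire an ABC link to a planted RE-negative gene.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    rows = []
    res_rows = []
    re_no = 0
    autosomal = [g for g in genes if g.is_autosomal]
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in autosomal:
        by_chrom.setdefault(g.chrom, []).append(g)
    n_auto = len(autosomal)
    targets = {
        c: int(round(p * n_auto))
        for c, p in cfg.class_proportions.items() if c != CLASS_NULL
    }
    assigned: dict[str, str] = {}
    for chrom, cgenes in by_chrom.items():
        share = len(cgenes) / n_auto
        # RE-negative classes live in a 5' zone separated from K79-RE
        # territory by a 600 kb buffer, so no planted K79-RE (placed
        # within 150 kb of its gene) can reach an RE-negative gene with
        # appreciable contact
        size = cfg.chrom_sizes[chrom]
        zone_a_end = min(int(0.2 * size), 1_800_000)
        zone_a = [g for g in cgenes if g.tss < zone_a_end]
        zone_b = [g for g in cgenes if g.tss > zone_a_end + 600_000]
        n_gb_only = int(round(targets[CLASS_GB_ONLY_DOWN] * share))
        n_gb_re = int(round(targets[CLASS_GB_RE_DOWN] * share))
        n_sil = int(round(targets[CLASS_SILENCING_UP] * share))
        if len(zone_a) < n_gb_only or len(zone_b) < n_gb_re + n_sil:
            raise ValueError(
                f"{chrom}: not enough genes in the class zones; increase "
                "n_genes or chromosome sizes"
            )
        picks_a = rng.choice(len(zone_a), n_gb_only, replace=False)
        for i in picks_a:
            assigned[zone_a[i].gene_id] = CLASS_GB_ONLY_DOWN
        picks_b = rng.choice(len(zone_b), n_gb_re + n_sil, replace=False)
        for k, i in enumerate(picks_b):
            assigned[zone_b[i].gene_id] = (
                CLASS_GB_RE_DOWN if k < n_gb_re else CLASS_SILENCING_UP
            )
    gb_re_ids = [g for g, c in assigned.items() if c == CLASS_GB_RE_DOWN]
    n_many = int(round(cfg.many_re_fraction * len(gb_re_ids)))
    many_ids = set(
        rng.choice(gb_re_ids, n_many, replace=False) if n_many else []
    )
    null_auto = [g for g in autosomal if g.gene_id not in assigned]
    n_not_expr = int(round(cfg.not_expressed_fraction * len(null_auto)))
    not_expr = set(
        rng.choice([g.gene_id for g in null_auto], n_not_expr, replace=False)
        if n_not_expr else []
    )
    gb_null = {
        g.gene_id for g in null_auto + [x for x in genes if not x.is_autosomal]
        if g.gene_id not in not_expr and rng.random() < cfg.gb_null_fraction
    }
    tss_by_chrom = {
        c: np.sort([g.tss for g in genes if g.chrom == c])
        for c in cfg.chrom_sizes
    }
    for g in genes:
        cls = assigned.get(g.gene_id, CLASS_NULL)
        many = g.gene_id in many_ids
        mean, sd = cfg.effect_sizes[cls]
        true_l2fc = rng.normal(mean, sd)
        if many:
            true_l2fc += cfg.many_re_extra_log2fc
        if cls == CLASS_GB_RE_DOWN:
            gb_frac = rng.uniform(0.5, 0.95)
            # many-RE genes are planted above the >=6 boundary so that a
            # single unlinked element cannot flip their stratum
            n_res = int(rng.integers(7, 10) if many else rng.integers(2, 5))
            re_type = "activating"
        elif cls == CLASS_GB_ONLY_DOWN:
            gb_frac = rng.uniform(0.25, 0.6)
            n_res = int(rng.integers(2, 4))
            re_type = "plain"
        elif cls == CLASS_SILENCING_UP:
            gb_frac = 0.0
            n_res = int(rng.integers(2, 5))
            re_type = "silencing"
        else:
            gb_frac = (
                rng.uniform(0.25, 0.9) if g.gene_id in gb_null else 0.0
            )
            n_res, re_type = 0, ""
        if g.gene_id in not_expr:
            baseline = rng.uniform(0.05, 0.8)
            expected_de = "not_expressed"
        elif cls in (CLASS_GB_RE_DOWN, CLASS_GB_ONLY_DOWN):
            baseline = float(np.exp(rng.normal(np.log(40), 0.6)))
            expected_de = "down"
        elif cls == CLASS_SILENCING_UP:
            baseline = max(1.2, float(np.exp(rng.normal(np.log(1.8), 0.4))))
            expected_de = "up"
        else:
            baseline = max(1.1, float(np.exp(rng.normal(np.log(8), 1.0))))
            expected_de = "unchanged"
        for _ in range(n_res):
            iv = _place_re(cfg, g, tss_by_chrom[g.chrom], rng,
                           cfg.chrom_sizes[g.chrom])
            res_rows.append(
                {"re_id": f"RE{re_no:05d}", "chrom": iv.chrom,
                 "start": iv.start, "end": iv.end, "re_type": re_type,
                 "gene_id": g.gene_id}
            )
            re_no += 1
        rows.append(
            {
                "gene_id": g.gene_id, "chrom": g.chrom, "class": cls,
                "many_re": many, "true_log2fc": float(true_l2fc),
                "baseline_rpkm": baseline, "expected_de": expected_de,
                "gb_target_fraction": float(gb_frac), "n_planted_res": n_res,
            }
        )
    # background REs: anywhere except differential-H3K79me2 territory
    # (methylated covered regions, planted-RE footprints - a background RE
    # there would silently become a K79-RE and break the truth tables)
    # and the immediate TSS surroundings; introns/exons of unmethylated
    # genes and intergenic space are all fair game, mirroring the broad
    # genomic distribution of acetylation peaks
    gmap_all = {g.gene_id: g for g in genes}
    frac_by_gene = dict(zip((r["gene_id"] for r in rows),
                            (r["gb_target_fraction"] for r in rows)))
    excluded: dict[str, list[tuple[int, int]]] = {c: [] for c in
                                                  cfg.chrom_sizes}
    for r in res_rows:
        excluded[r["chrom"]].append((r["start"] - 500, r["end"] + 500))
    for g in genes:
        frac = frac_by_gene.get(g.gene_id, 0.0)
        if frac > 0:
            lo, hi = _covered_region(g, frac)
            excluded[g.chrom].append((lo - 500, hi + 500))
        excluded[g.chrom].append((g.tss - 2_000, g.tss + 2_000))
    for chrom, size in cfg.chrom_sizes.items():
        n_bg = int(round(cfg.background_res_per_mb * size / 1e6))
        spans = sorted(excluded[chrom])
        starts = np.array([s for s, _ in spans])
        ends = np.array([e for _, e in spans])
        if ends.size:
            ends = np.maximum.accumulate(ends)  # spans may overlap
        placed = 0
        attempts = 0
        while placed < n_bg and attempts < 50 * n_bg:
            attempts += 1
            length = int(rng.integers(cfg.re_min_length, cfg.re_max_length))
            start = int(rng.integers(10_000, size - length - 10_000))
            if starts.size:
                j = np.searchsorted(starts, start + length)
                if j > 0 and ends[j - 1] > start:
                    continue  # overlaps an excluded span
            res_rows.append(
                {"re_id": f"RE{re_no:05d}", "chrom": chrom, "start": start,
                 "end": start + length, "re_type": "background",
                 "gene_id": ""}
            )
            re_no += 1
            placed += 1
    # cKO-only REs near silencing genes (exercise the cKO-only mapping rule)
    sil_genes = [g for g in genes
                 if assigned.get(g.gene_id) == CLASS_SILENCING_UP]
    for chrom in [c for c in cfg.chrom_sizes if c not in ("chrX", "X")]:
        cands = [g for g in sil_genes if g.chrom == chrom]
        for g in list(cands)[: cfg.n_ko_only_res]:
            iv = _place_re(cfg, g, tss_by_chrom[chrom], rng,
                           cfg.chrom_sizes[chrom])
            res_rows.append(
                {"re_id": f"RE{re_no:05d}", "chrom": iv.chrom,
                 "start": iv.start, "end": iv.end, "re_type": "ko_only",
                 "gene_id": g.gene_id}
            )
            re_no += 1
    gene_truth = pd.DataFrame(rows)
    re_truth = pd.DataFrame(res_rows)
    return gene_truth, re_truth


def _covered_region(gene: GeneModel, frac: float) -> tuple[int, int]:
    """The 5'-anchored gene-body region carrying planted methylation."""
    body = gene.gene_body
    cov_len = max(500, int(frac * body.length))
    if gene.strand == "+":
        return body.start, body.start + cov_len
    return body.end - cov_len, body.end


def _place_re(
    cfg: TruthConfig, gene: GeneModel, tss_sorted: np.ndarray,
    rng: np.random.Generator, chrom_size: int,
) -> GenomicInterval:
    """An RE 15-150 kb from the gene's TSS, >= 6 kb from any other TSS."""
    for _ in range(200):
        length = int(rng.integers(cfg.re_min_length, cfg.re_max_length))
        dist = int(rng.integers(cfg.re_min_tss_distance,
                                cfg.re_max_tss_distance))
        side = 1 if rng.random() < 0.5 else -1
        mid = gene.tss + side * dist
        start = mid - length // 2
        if start < 0 or start + length > chrom_size:
            continue
        k = np.searchsorted(tss_sorted, mid)
        near = [abs(mid - tss_sorted[j]) for j in (k - 1, k)
                if 0 <= j < tss_sorted.size]
        if near and min(near) < 6_000 and min(near) != dist:
            continue
        return GenomicInterval(gene.chrom, start, start + length)
    raise RuntimeError(f"could not place an RE for gene {gene.gene_id}")


# ---------------------------------------------------------------------------
# peaks and reads


def generate_peaks_and_reads(
    cfg: TruthConfig,
    genes: list[GeneModel],
    gene_truth: pd.DataFrame,
    re_truth: pd.DataFrame,
    outdir: str | Path,
) -> dict[str, Path]:
    """Write narrowPeak, differential BED, and read BED files.

    Gene-body methylated genes receive two replicates of tiled control
    H3K79me2 reads over a contiguous 5'-anchored region of the planted
    fraction (>= 60 reads per replicate) and essentially nothing in the
    knockout; planted/ background REs receive H3K27ac peaks in both
    conditions; K79-REs receive differential H3K79me2 intervals covering
    30-80% of their length.
    """
    rng = np.random.default_rng(cfg.seed + 2)
    outdir = Path(outdir)
    gmap = {g.gene_id: g for g in genes}
    truth = gene_truth.set_index("gene_id")
    reads_rep: dict[int, list[GenomicInterval]] = {1: [], 2: []}
    reads_ko: list[GenomicInterval] = []
    k79_peaks: list[tuple[GenomicInterval, float]] = []
    diff_k79: list[GenomicInterval] = []
    for gene_id, row in truth.iterrows():
        frac = row["gb_target_fraction"]
        if frac <= 0:
            continue
        g = gmap[gene_id]
        lo, hi = _covered_region(g, frac)
        cov_len = hi - lo
        for rep in (1, 2):
            n_reads = max(60, cov_len // 150)
            starts = np.linspace(lo, hi - 100, n_reads).astype(int)
            starts += rng.integers(-20, 21, n_reads)
            starts = np.clip(starts, lo, max(lo, hi - 100))
            reads_rep[rep] += [
                GenomicInterval(g.chrom, int(s), int(s) + 100)
                for s in starts
            ]
        # a trace of knockout signal (a few residual reads)
        for s in rng.integers(lo, max(lo + 1, hi - 100), 3):
            reads_ko.append(GenomicInterval(g.chrom, int(s), int(s) + 100))
        peak = GenomicInterval(g.chrom, lo, hi)
        k79_peaks.append((peak, float(np.exp(rng.normal(np.log(20), 0.4)))))
        diff_k79.append(peak)
    # differential H3K79me2 over K79-REs (activating + silencing)
    k79_re = re_truth[re_truth["re_type"].isin(["activating", "silencing"])]
    for _, r in k79_re.iterrows():
        length = r["end"] - r["start"]
        cover = int(rng.uniform(0.3, 0.8) * length)
        offset = int(rng.integers(0, max(1, length - cover)))
        diff_k79.append(
            GenomicInterval(r["chrom"], r["start"] + offset,
                            r["start"] + offset + max(cover, 1))
        )
    # H3K27ac peaks: planted + background in both conditions; ko-only extra
    signals = np.exp(
        rng.normal(cfg.peak_signal_log_mean, cfg.peak_signal_log_sd,
                   len(re_truth))
    )
    k27_ctrl, k27_ko = [], []
    for (idx, r), sig in zip(re_truth.iterrows(), signals):
        iv = GenomicInterval(r["chrom"], r["start"], r["end"])
        entry = (iv, r["re_id"], float(sig))
        if r["re_type"] == "ko_only":
            k27_ko.append(entry)
        else:
            k27_ctrl.append(entry)
            k27_ko.append(entry)
    # differential H3K27ac: subsets of silencing (up) / activating (down)
    sil = re_truth[re_truth["re_type"] == "silencing"]
    act = re_truth[re_truth["re_type"] == "activating"]
    n_up = int(round(cfg.diff_k27_up_fraction * len(sil)))
    n_dn = int(round(cfg.diff_k27_down_fraction * len(act)))
    up_ids = set(rng.choice(sil["re_id"], n_up, replace=False)) if n_up else set()
    dn_ids = set(rng.choice(act["re_id"], n_dn, replace=False)) if n_dn else set()
    up_ids |= set(re_truth.loc[re_truth["re_type"] == "ko_only", "re_id"])
    diff_up, diff_dn = [], []
    for _, r in re_truth.iterrows():
        if r["re_id"] not in up_ids and r["re_id"] not in dn_ids:
            continue
        length = r["end"] - r["start"]
        cover = max(1, int(rng.uniform(0.2, 0.8) * length))
        offset = int(rng.integers(0, max(1, length - cover)))
        iv = GenomicInterval(r["chrom"], r["start"] + offset,
                             r["start"] + offset + cover)
        (diff_up if r["re_id"] in up_ids else diff_dn).append(iv)
    re_truth["k27_diff_planted"] = [
        "up" if r in up_ids else ("down" if r in dn_ids else "none")
        for r in re_truth["re_id"]
    ]
    paths = {}

    def _write_np(entries, name):
        p = outdir / name
        with open(p, "w") as fh:
            for iv, peak_name, sig in entries:
                fh.write(
                    f"{iv.chrom}\t{iv.start}\t{iv.end}\t{peak_name}\t0\t.\t"
                    f"{sig:.4f}\t-1\t-1\t-1\n"
                )
        paths[name] = p

    _write_np([(iv, f"k79p{i}", s) for i, (iv, s) in enumerate(k79_peaks)],
              "k79_ctrl.narrowPeak")
    _write_np([], "k79_ko.narrowPeak")
    _write_np(k27_ctrl, "k27_ctrl.narrowPeak")
    _write_np(k27_ko, "k27_ko.narrowPeak")
    for name, ivs in [
        ("diff_k79.bed", diff_k79), ("diff_k27_up.bed", diff_up),
        ("diff_k27_down.bed", diff_dn),
        ("k79_reads_ctrl_rep1.bed", reads_rep[1]),
        ("k79_reads_ctrl_rep2.bed", reads_rep[2]),
        ("k79_reads_ko_rep1.bed", reads_ko),
    ]:
        write_bed(ivs, outdir / name)
        paths[name] = outdir / name
    return paths


# ---------------------------------------------------------------------------
# Hi-C


def generate_hic(
    cfg: TruthConfig,
    genes: list[GeneModel],
    re_truth: pd.DataFrame,
    outdir: str | Path,
) -> dict[str, Path]:
    """Per-chromosome triplet dumps with planted enhancer-promoter loops.

    Counts at bin distance d are Poisson(mu * (d+1)^-alpha); each planted
    RE-gene bin pair receives an independent extra Poisson(mu_d * (boost-1))
    so its mean is exactly ``loop_boost`` times the distance-matched
    background.
    """
    rng = np.random.default_rng(cfg.seed + 3)
    outdir = Path(outdir)
    tss = {g.gene_id: g.tss for g in genes}
    paths = {}
    for chrom, size in cfg.chrom_sizes.items():
        n = size // cfg.resolution
        max_d = min(cfg.hic_max_distance_bins, n - 1)
        rows_i, rows_j, rows_v = [], [], []
        for d in range(max_d + 1):
            lam = cfg.hic_mu / (d + 1) ** cfg.hic_alpha
            counts = rng.poisson(lam, n - d)
            nz = np.nonzero(counts)[0]
            rows_i.append(nz)
            rows_j.append(nz + d)
            rows_v.append(counts[nz])
        i = np.concatenate(rows_i)
        j = np.concatenate(rows_j)
        v = np.concatenate(rows_v).astype(float)
        # planted loops
        planted = re_truth[
            (re_truth["chrom"] == chrom) & (re_truth["gene_id"] != "")
        ]
        extra_i, extra_j, extra_v = [], [], []
        for _, r in planted.iterrows():
            bi = ((r["start"] + r["end"]) // 2) // cfg.resolution
            bj = tss[r["gene_id"]] // cfg.resolution
            lo, hi = min(bi, bj), max(bi, bj)
            lam = cfg.hic_mu / (hi - lo + 1) ** cfg.hic_alpha
            boost = rng.poisson(lam * (cfg.loop_boost - 1))
            if boost > 0:
                extra_i.append(lo)
                extra_j.append(hi)
                extra_v.append(float(boost))
        if extra_i:
            i = np.concatenate([i, extra_i])
            j = np.concatenate([j, extra_j])
            v = np.concatenate([v, extra_v])
        df = (
            pd.DataFrame(
                {"pos1": i * cfg.resolution, "pos2": j * cfg.resolution,
                 "value": v}
            )
            .groupby(["pos1", "pos2"], as_index=False)["value"].sum()
        )
        p = outdir / f"hic_{chrom}.txt"
        df.to_csv(p, sep="\t", header=False, index=False,
                  float_format="%.1f")
        paths[chrom] = p
    return paths


# ---------------------------------------------------------------------------
# expression


def generate_expression(
    cfg: TruthConfig,
    genes: list[GeneModel],
    gene_truth: pd.DataFrame,
    outdir: str | Path | None = None,
) -> pd.DataFrame:
    """Replicate counts, naive DE test, and the resulting DE table.

    Counts are negative binomial (gamma-Poisson) around the planted
    expression; the knockout mean is shifted by the planted log2 fold
    change; p-values come from a two-sample t-test on log2 counts with
    BH adjustment. This simplistic testing lives in the generator so the
    pipeline's expression module remains a consumer of a DE table.
    """
    rng = np.random.default_rng(cfg.seed + 4)
    gmap = {g.gene_id: g for g in genes}
    n_rep = cfg.n_replicates
    rows = []
    pvals = []
    for _, r in gene_truth.iterrows():
        g = gmap[r["gene_id"]]
        exon_kb = g.exon_length_sum / 1e3
        mu_ctrl = r["baseline_rpkm"] * exon_kb * cfg.library_size / 1e6
        mu_ko = mu_ctrl * 2.0 ** r["true_log2fc"]
        shape = 1.0 / cfg.nb_dispersion
        c_ctrl = rng.poisson(rng.gamma(shape, mu_ctrl / shape, n_rep))
        c_ko = rng.poisson(rng.gamma(shape, mu_ko / shape, n_rep))
        rpkm_ctrl = rpkm_of(c_ctrl.mean(), g.exon_length_sum,
                            cfg.library_size)
        rpkm_ko = rpkm_of(c_ko.mean(), g.exon_length_sum, cfg.library_size)
        log2fc = float(np.log2((rpkm_ko + 0.01) / (rpkm_ctrl + 0.01)))
        t = stats.ttest_ind(np.log2(c_ko + 0.5), np.log2(c_ctrl + 0.5))
        p = float(t.pvalue) if np.isfinite(t.pvalue) else 1.0
        pvals.append(p)
        rows.append(
            {"gene_id": r["gene_id"], "rpkm_ctrl": rpkm_ctrl,
             "rpkm_ko": rpkm_ko, "log2fc": log2fc}
        )
    table = pd.DataFrame(rows)
    table["fdr"] = bh_adjust(pvals)
    if outdir is not None:
        table.to_csv(Path(outdir) / "expression.tsv", sep="\t", index=False,
                     float_format="%.6g")
    return table


# ---------------------------------------------------------------------------
# sequences and motifs


def _random_sequence(length: int, gc: float, rng: np.random.Generator) -> str:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGT"), length, p=probs))


def generate_re_sequences(
    cfg: TruthConfig,
    re_truth: pd.DataFrame,
    outdir: str | Path | None = None,
) -> tuple[dict[str, str], list[str], np.ndarray]:
    """GC-matched random RE sequences, motif-seeded in silencing REs.

    Silencing K79-REs receive ``n_sites_per_silencing_re`` copies of the
    planted consensus at random positions and strands; all other REs are
    plain random sequence. Also emits the PWM set (planted motif plus
    decoys) and a TF-to-gene mapping used by the expressed-TF filter.
    """
    rng = np.random.default_rng(cfg.seed + 5)
    motif = cfg.planted_motif.upper()
    w = len(motif)
    seqs: dict[str, str] = {}
    for _, r in re_truth.iterrows():
        length = int(r["end"] - r["start"])
        seq = list(_random_sequence(length, cfg.re_gc_content, rng))
        if r["re_type"] == "silencing" and cfg.n_sites_per_silencing_re > 0:
            n_slots = max(1, length // (2 * w))
            starts = rng.choice(
                n_slots, min(cfg.n_sites_per_silencing_re, n_slots),
                replace=False,
            ) * 2 * w
            for s in starts:
                site = (motif if rng.random() < 0.5
                        else motifs_mod.reverse_complement(motif))
                seq[s:s + w] = list(site)
        seqs[r["re_id"]] = "".join(seq)
    # PWM set: planted motif first, then decoy consensus motifs
    names = ["TF_PLANTED"] + [f"TF_DECOY{i:02d}"
                              for i in range(cfg.n_decoy_pwms)]
    base_idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    counts_list = []
    consensi = [motif]
    while len(consensi) < len(names):
        cand = "".join(rng.choice(list("ACGT"), w))
        if cand not in consensi:
            consensi.append(cand)
    for cons in consensi:
        counts = np.full((len(cons), 4), 5.0)
        for i, b in enumerate(cons):
            counts[i, base_idx[b]] = 85.0
        counts_list.append(counts)
    if outdir is not None:
        outdir = Path(outdir)
        with open(outdir / "re_sequences.fasta", "w") as fh:
            for name, seq in seqs.items():
                fh.write(f">{name}\n{seq}\n")
        write_jaspar(names, counts_list, outdir / "pwms.jaspar")
    return seqs, names, np.array(counts_list, dtype=object)


def write_tf_to_gene(
    names: list[str], expression: pd.DataFrame, path: str | Path
) -> dict[str, str]:
    """Map each TF to a well-expressed gene (round robin over top genes)."""
    top = (
        expression.sort_values("rpkm_ctrl", ascending=False)["gene_id"]
        .head(max(len(names), 10)).tolist()
    )
    mapping = {name: top[i % len(top)] for i, name in enumerate(names)}
    pd.DataFrame(
        {"tf_name": list(mapping), "gene_id": list(mapping.values())}
    ).to_csv(path, sep="\t", index=False)
    return mapping


# ---------------------------------------------------------------------------
# orchestration


def generate_all(cfg: TruthConfig, outdir: str | Path) -> dict:
    """Generate the full synthetic data set into ``outdir``.

    Returns a manifest dict with file paths and in-memory truth tables.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genes, sizes = generate_genome(cfg, outdir)
    gene_truth, re_truth = plant_truth(cfg, genes)
    peak_paths = generate_peaks_and_reads(cfg, genes, gene_truth, re_truth,
                                          outdir)
    hic_paths = generate_hic(cfg, genes, re_truth, outdir)
    expression = generate_expression(cfg, genes, gene_truth, outdir)
    generate_re_sequences(cfg, re_truth, outdir)
    tf2gene = write_tf_to_gene(
        ["TF_PLANTED"] + [f"TF_DECOY{i:02d}" for i in range(cfg.n_decoy_pwms)],
        expression, outdir / "tf2gene.tsv",
    )
    gene_truth.to_csv(outdir / "truth_genes.tsv", sep="\t", index=False)
    re_truth.to_csv(outdir / "truth_res.tsv", sep="\t", index=False)
    (outdir / "truth_config.json").write_text(cfg.to_json())
    return {
        "outdir": outdir, "genes": genes, "chrom_sizes": sizes,
        "gene_truth": gene_truth, "re_truth": re_truth,
        "expression": expression, "tf2gene": tf2gene,
        "peak_paths": peak_paths, "hic_paths": hic_paths,
        "gtf": outdir / "genes.gtf",
        "chrom_sizes_path": outdir / "chrom.sizes",
    }
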