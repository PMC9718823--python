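"""Integration of differential ChIP-seq signal with the regulatory map.

A regulatory element (RE) is an H3K27ac peak that survived ABC
filtering. An RE is "differential" for a mark when at least 10% of its
length is covered by the union of that mark's differential peaks
(K79-REs for differential H3K79me2; up/down labels for differential
H3K27ac). Differential-H3K27ac REs are attributed to the genes they were
linked to in the control regulatory map, or - for REs with no control
links at all - to their cKO-only target genes. Genes are then placed in
UpSet-style categories combining DE direction, gene-body methylation, and
K79-RE / differential-H3K27ac linkage, and effect sizes are compared
between strata with two-tailed Kolmogorov-Smirnov tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .intervals import GenomicInterval, clipped_union_length

DIFF_OVERLAP_FRACTION = 0.10


@dataclass
class RegulatoryElement:
    name: str
    interval: GenomicInterval
    is_k79_re: bool = False
    k27_diff: str = "none"  # {"up", "down", "none"}
    overlaps_promoter: bool = False


def differential_overlap_fraction(
    re: GenomicInterval, diff_peaks: Sequence[GenomicInterval]
) -> float:
    """Fraction of the RE's length covered by the union of diff peaks."""
    if re.length <= 0:
        raise ValueError("zero-length regulatory element")
    same = [(p.start, p.end) for p in diff_peaks if p.chrom == re.chrom]
    return clipped_union_length(same, re.start, re.end) / re.length


def flag_res(
    res: Mapping[str, GenomicInterval],
    diff_k79: Sequence[GenomicInterval],
    diff_k27_up: Sequence[GenomicInterval],
    diff_k27_down: Sequence[GenomicInterval],
    min_fraction: float = DIFF_OVERLAP_FRACTION,
) -> list[RegulatoryElement]:
    """Attach K79-RE and differential-H3K27ac flags to each RE.

    Both flags use the >= 10% covered-length rule (inclusive). An RE
    reaching the threshold for both H3K27ac directions is labelled by the
    larger covered fraction, ties going to "down".
    """
    by_chrom_79: dict[str, list[GenomicInterval]] = {}
    for p in diff_k79:
        by_chrom_79.setdefault(p.chrom, []).append(p)
    out = []
    for name, iv in res.items():
        f79 = differential_overlap_fraction(iv, by_chrom_79.get(iv.chrom, []))
        fup = differential_overlap_fraction(iv, diff_k27_up)
        fdn = differential_overlap_fraction(iv, diff_k27_down)
        if fdn >= min_fraction and fdn >= fup:
            k27 = "down"
        elif fup >= min_fraction:
            k27 = "up"
        else:
            k27 = "none"
        out.append(
            RegulatoryElement(name, iv, is_k79_re=f79 >= min_fraction,
                              k27_diff=k27)
        )
    return out


def map_diff_k27_to_genes(
    res: Sequence[RegulatoryElement],
    interactions_ctrl: pd.DataFrame,
    interactions_ko: pd.DataFrame,
) -> dict[str, set[str]]:
    """Genes carrying each differential-H3K27ac RE.

    An RE with any control-map link is attributed to its control-linked
    genes; an RE present only in the cKO map is attributed to its
    cKO-linked genes.
    """
    ctrl_links = (
        interactions_ctrl.groupby("enhancer")["gene_id"].agg(set).to_dict()
    )
    ko_links = (
        interactions_ko.groupby("enhancer")["gene_id"].agg(set).to_dict()
    )
    gene_res: dict[str, set[str]] = {}
    for re in res:
        if re.k27_diff == "none":
            continue
        if re.name in ctrl_links:
            targets = ctrl_links[re.name]
        else:
            targets = ko_links.get(re.name, set())
        for gene_id in targets:
            gene_res.setdefault(gene_id, set()).add(re.name)
    return gene_res


def build_gene_profiles(
    expression: pd.DataFrame,
    gb_table: pd.DataFrame,
    res: Sequence[RegulatoryElement],
    interactions_ctrl: pd.DataFrame,
    interactions_ko: pd.DataFrame,
) -> pd.DataFrame:
    """Per-gene regulatory profile joining DE, gene-body, and RE evidence.

    ``n_k79_res`` counts distinct K79-REs linked in the control map (gene
    categories are defined on the control regulatory state);
    ``n_diff_k27_res`` follows the differential-H3K27ac attribution rule.
    """
    k79_names = {r.name for r in res if r.is_k79_re}
    ctrl_k79 = interactions_ctrl[
        interactions_ctrl["enhancer"].isin(k79_names)
    ]
    n_k79 = ctrl_k79.groupby("gene_id")["enhancer"].nunique()
    diff_map = map_diff_k27_to_genes(res, interactions_ctrl, interactions_ko)
    df = expression.merge(
        gb_table[["gene_id", "read_count", "fraction_covered", "gb_k79"]],
        on="gene_id", how="left",
    )
    df["gb_k79"] = df["gb_k79"].fillna(False).astype(bool)
    df["fraction_covered"] = df["fraction_covered"].fillna(0.0)
    df["n_k79_res"] = (
        df["gene_id"].map(n_k79).fillna(0).astype(int)
    )
    df["n_diff_k27_res"] = (
        df["gene_id"].map({g: len(s) for g, s in diff_map.items()})
        .fillna(0).astype(int)
    )
    df["category"] = [
        _category(s, gb, nre, ndk)
        for s, gb, nre, ndk in zip(df["de_status"], df["gb_k79"],
                                   df["n_k79_res"], df["n_diff_k27_res"])
    ]
    return df


def _category(de_status: str, gb: bool, n_res: int, n_diff_k27: int) -> str:
    if de_status not in ("down", "up"):
        return de_status
    parts = ["GB+" if gb else "GB-", "RE+" if n_res > 0 else "RE-"]
    if n_diff_k27 > 0:
        parts.append("diffK27+")
    return "".join(parts)


def categorize_genes(
    profiles: pd.DataFrame, include_diff_k27: bool = False
) -> pd.DataFrame:
    """UpSet table: gene counts and percentages per category x direction.

    Each DE gene lands in exactly one GBxRE (optionally x diffK27)
    category; percentages sum to 100 within each direction.
    """
    de = profiles[profiles["de_status"].isin(["down", "up"])].copy()
    if include_diff_k27:
        cats = de["category"]
    else:
        cats = de["category"].str.replace("diffK27+", "", regex=False)
    table = (
        pd.DataFrame({"direction": de["de_status"], "category": cats})
        .groupby(["direction", "category"]).size().rename("n_genes")
        .reset_index()
    )
    totals = table.groupby("direction")["n_genes"].transform("sum")
    table["percent"] = 100.0 * table["n_genes"] / totals
    return table


def ks_two_sample(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Two-tailed two-sample KS test.

    D is the supremum ECDF distance; the p-value comes from the
    asymptotic Kolmogorov distribution at effective size nm/(n+m).
    """
    x, y = np.asarray(x, float), np.asarray(y, float)
    if x.size == 0 or y.size == 0:
        raise ValueError("KS test requires non-empty samples")
    res = stats.ks_2samp(x, y, alternative="two-sided", method="asymp")
    return float(res.statistic), float(res.pvalue)


GB_FRACTION_STRATA = (
    ("GB fraction < 1/3", lambda d: d["fraction_covered"] < 1 / 3),
    ("GB fraction 1/3-2/3", lambda d: (d["fraction_covered"] >= 1 / 3)
     & (d["fraction_covered"] < 2 / 3)),
    ("GB fraction >= 2/3", lambda d: d["fraction_covered"] >= 2 / 3),
)

K79_RE_COUNT_STRATA = (
    ("0 K79-REs", lambda d: d["n_k79_res"] == 0),
    ("1-5 K79-REs", lambda d: (d["n_k79_res"] >= 1) & (d["n_k79_res"] <= 5)),
    (">=6 K79-REs", lambda d: d["n_k79_res"] >= 6),
)

GB_POS_RE_STRATA = (
    ("GB+ without K79-REs", lambda d: d["gb_k79"] & (d["n_k79_res"] == 0)),
    ("GB+ with K79-REs", lambda d: d["gb_k79"] & (d["n_k79_res"] >= 1)),
)

DEFAULT_STRATIFICATIONS: dict[str, tuple] = {
    "gb_fraction": GB_FRACTION_STRATA,
    "k79_re_count": K79_RE_COUNT_STRATA,
    "gb_pos_by_re": GB_POS_RE_STRATA,
}


@dataclass
class StratifiedCDF:
    stratification: str
    stratum: str
    values: np.ndarray

    def ecdf(self, grid: np.ndarray) -> np.ndarray:
        return np.searchsorted(np.sort(self.values), grid, "right") / max(
            self.values.size, 1
        )


def stratified_cdf_analysis(
    profiles: pd.DataFrame,
    stratifications: Mapping[str, tuple] | None = None,
) -> tuple[list[StratifiedCDF], pd.DataFrame]:
    """Cumulative log2FC distributions per stratum with pairwise KS tests.

    Default strata: gene-body methylated fraction thirds (half-open on
    the right), K79-RE counts {0, 1-5, >=6}, and gene-body-positive genes
    split by K79-RE presence. Strata with fewer than two genes are
    skipped from testing with a warning.
    """
    if stratifications is None:
        stratifications = DEFAULT_STRATIFICATIONS
    expressed = profiles[profiles["de_status"] != "not_expressed"]
    cdfs: list[StratifiedCDF] = []
    rows = []
    for name, strata in stratifications.items():
        members = []
        for label, pred in strata:
            vals = expressed.loc[pred(expressed), "log2fc"].to_numpy(float)
            cdfs.append(StratifiedCDF(name, label, vals))
            members.append((label, vals))
        for (la, va), (lb, vb) in combinations(members, 2):
            if va.size < 2 or vb.size < 2:
                warnings.warn(
                    f"{name}: stratum pair ({la}, {lb}) has <2 genes; "
                    "KS test skipped"
                )
                continue
            d, p = ks_two_sample(va, vb)
            rows.append(
                {"stratification": name, "stratum_a": la, "stratum_b": lb,
                 "n_a": va.size, "n_b": vb.size, "ks_D": d, "ks_p": p}
            )
    return cdfs, pd.DataFrame(
        rows, columns=["stratification", "stratum_a", "stratum_b", "n_a",
                       "n_b", "ks_D", "ks_p"],
    )
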