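"""TRAP transcription-factor affinities and rank-based motif enrichment.

TRAP treats a position weight matrix as a biophysical binding model: for
each sequence window i (both strands), the mismatch energy relative to
the consensus is

    E_i = (1/lambda) * sum_j ln(p_max,j / p_b(i,j),j)

and the window's occupancy probability is P_i = R0 e^-E_i / (1 + R0 e^-E_i),
with lambda = 0.7 and ln R0 = 0.584 * W - 5.66 (the published TRAP
defaults; W is motif width). The affinity of a sequence is the sum of
P_i over all windows on both strands; windows containing N contribute 0.

Affinities of two RE groups are compared per TF with a one-tailed
Mann-Whitney U test (each direction separately) and Benjamini-Hochberg
adjustment; adjusted p <= 0.05 is called significant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO, motifs as bio_motifs
from Bio.Seq import Seq
from scipy import stats
from statsmodels.stats.multitest import multipletests

TRAP_LAMBDA = 0.7
UNIFORM_BACKGROUND = np.full(4, 0.25)
_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}
_COMPLEMENT = np.array([3, 2, 1, 0, 4])  # A<->T, C<->G, N->N


def default_ln_r0(width: int) -> float:
    return 0.584 * width - 5.66


@dataclass
class PWM:
    """Pseudocounted per-position base probabilities for one TF motif."""

    tf_name: str
    probabilities: np.ndarray  # (W, 4) rows sum to 1, all > 0
    background: np.ndarray = None

    def __post_init__(self) -> None:
        self.probabilities = np.asarray(self.probabilities, float)
        if self.background is None:
            self.background = UNIFORM_BACKGROUND.copy()
        if self.probabilities.ndim != 2 or self.probabilities.shape[1] != 4:
            raise ValueError("PWM probabilities must be (W, 4)")
        if not np.allclose(self.probabilities.sum(axis=1), 1.0):
            raise ValueError("PWM columns must sum to 1")
        if (self.probabilities <= 0).any():
            raise ValueError("PWM probabilities must be positive "
                             "(apply a pseudocount)")

    @property
    def width(self) -> int:
        return self.probabilities.shape[0]

    @classmethod
    def from_counts(
        cls, tf_name: str, counts: np.ndarray, pseudocount: float = 1.0
    ) -> "PWM":
        counts = np.asarray(counts, float) + pseudocount
        return cls(tf_name, counts / counts.sum(axis=1, keepdims=True))


def read_jaspar(path: str | Path, pseudocount: float = 1.0) -> list[PWM]:
    """Read JASPAR PFM count matrices (via Biopython) into PWMs."""
    with open(path) as fh:
        records = bio_motifs.parse(fh, "jaspar")
    out = []
    for m in records:
        counts = np.array(
            [[m.counts[b][i] for b in "ACGT"] for i in range(m.length)]
        )
        name = m.name or m.matrix_id
        out.append(PWM.from_counts(str(name), counts, pseudocount))
    return out


def write_jaspar(
    names: Sequence[str], count_matrices: Sequence[np.ndarray],
    path: str | Path,
) -> None:
    """Write integer count matrices in JASPAR PFM format."""
    with open(path, "w") as fh:
        for name, counts in zip(names, count_matrices):
            fh.write(f">{name} {name}\n")
            for bi, base in enumerate("ACGT"):
                row = " ".join(str(int(v)) for v in counts[:, bi])
                fh.write(f"{base} [ {row} ]\n")


def encode_sequence(seq: str) -> np.ndarray:
    return np.array([_BASE_INDEX.get(b, 4) for b in seq.upper()],
                    dtype=np.int8)


def _window_probs(
    encoded: np.ndarray, log_ratio: np.ndarray, lam: float, ln_r0: float
) -> np.ndarray:
    """Occupancy probability per window for one strand.

    ``log_ratio`` is (W, 5): ln(p_max/p_base) per motif position, with
    the N column flagged NaN so N-containing windows drop out.
    """
    w = log_ratio.shape[0]
    if encoded.size < w:
        return np.zeros(0)
    windows = np.lib.stride_tricks.sliding_window_view(encoded, w)
    energies = log_ratio[np.arange(w)[None, :], windows].sum(axis=1) / lam
    log_odds = ln_r0 - energies
    with np.errstate(over="ignore"):
        probs = 1.0 / (1.0 + np.exp(-log_odds))
    return np.where(np.isnan(energies), 0.0, probs)


def trap_affinity(
    pwm: PWM,
    seq: str,
    lam: float = TRAP_LAMBDA,
    ln_r0: float | None = None,
) -> float:
    """TRAP affinity: summed occupancy probabilities over both strands."""
    if ln_r0 is None:
        ln_r0 = default_ln_r0(pwm.width)
    encoded = encode_sequence(seq)
    if encoded.size < pwm.width:
        warnings.warn(
            f"sequence shorter than motif width {pwm.width}; affinity 0"
        )
        return 0.0
    p_max = pwm.probabilities.max(axis=1, keepdims=True)
    log_ratio = np.full((pwm.width, 5), np.nan)
    log_ratio[:, :4] = np.log(p_max / pwm.probabilities)
    fwd = _window_probs(encoded, log_ratio, lam, ln_r0)
    # reverse strand == scanning with the reverse-complemented matrix
    rc_log_ratio = log_ratio[::-1, _COMPLEMENT]
    rev = _window_probs(encoded, rc_log_ratio, lam, ln_r0)
    return float(fwd.sum() + rev.sum())


def affinity_table(
    pwms: Sequence[PWM], sequences: Mapping[str, str]
) -> pd.DataFrame:
    """Affinities for every (TF, sequence) pair; rows = sequences."""
    data = {
        pwm.tf_name: [trap_affinity(pwm, s) for s in sequences.values()]
        for pwm in pwms
    }
    return pd.DataFrame(data, index=list(sequences.keys()))


def filter_expressed_tfs(
    pwms: Sequence[PWM],
    expression: pd.DataFrame,
    tf_to_gene: Mapping[str, str] | None = None,
    min_rpkm: float = 1.0,
) -> list[PWM]:
    """Keep motifs whose TF gene has RPKM >= 1 in either condition."""
    expr = expression.set_index("gene_id")[["rpkm_ctrl", "rpkm_ko"]].max(
        axis=1
    )
    kept = []
    for pwm in pwms:
        gene = (tf_to_gene or {}).get(pwm.tf_name, pwm.tf_name)
        if gene not in expr.index:
            warnings.warn(
                f"TF {pwm.tf_name}: no expression record for gene "
                f"{gene!r}; motif dropped"
            )
            continue
        if expr[gene] >= min_rpkm:
            kept.append(pwm)
    return kept


def mann_whitney_one_tailed(
    a: Sequence[float], b: Sequence[float]
) -> tuple[float, float]:
    """One-tailed Mann-Whitney U (alternative: a shifted greater than b).

    U uses midranks for ties. The p-value is exact (distribution
    enumeration) when the pooled size is <= 12 and there are no ties,
    otherwise the normal approximation with tie and continuity
    corrections is used. Two identical constant samples give p = 1.
    """
    a, b = np.asarray(a, float), np.asarray(b, float)
    if a.size == 0 or b.size == 0:
        raise ValueError("Mann-Whitney requires non-empty samples")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return float(a.size * b.size / 2.0), 1.0
    ties = np.unique(pooled).size < pooled.size
    method = "exact" if (a.size + b.size <= 12 and not ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="greater", method=method,
                             use_continuity=True)
    return float(res.statistic), float(res.pvalue)


def bh_adjust(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (order-preserving)."""
    pvals = np.asarray(pvals, float)
    if pvals.size == 0:
        return pvals
    return multipletests(pvals, method="fdr_bh")[1]


def enrichment_analysis(
    pwms: Sequence[PWM],
    group_a: Mapping[str, str],
    group_b: Mapping[str, str],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Rank TFs by differential affinity between two RE sequence groups.

    For each TF the one-tailed Mann-Whitney test is run in both
    directions (A enriched over B, and B over A); all resulting p-values
    are BH-adjusted as one family. A TF is significant when its
    smaller adjusted p is <= alpha (inclusive); ``direction`` names the
    enriched group.
    """
    rows = []
    for pwm in pwms:
        aff_a = np.array([trap_affinity(pwm, s) for s in group_a.values()])
        aff_b = np.array([trap_affinity(pwm, s) for s in group_b.values()])
        u_a, p_a = mann_whitney_one_tailed(aff_a, aff_b)
        u_b, p_b = mann_whitney_one_tailed(aff_b, aff_a)
        rows.append(
            {
                "tf_name": pwm.tf_name,
                "median_affinity_a": float(np.median(aff_a)),
                "median_affinity_b": float(np.median(aff_b)),
                "U_a_greater": u_a, "p_a_greater": p_a,
                "U_b_greater": u_b, "p_b_greater": p_b,
            }
        )
    df = pd.DataFrame(rows)
    if len(df):
        # one BH family over all resulting p-values (both directions)
        adj = bh_adjust(np.concatenate([df["p_a_greater"],
                                        df["p_b_greater"]]))
        df["padj_a_greater"] = adj[: len(df)]
        df["padj_b_greater"] = adj[len(df):]
        a_wins = df["padj_a_greater"] <= df["padj_b_greater"]
        df["direction"] = np.where(a_wins, "A", "B")
        df["p_adjusted"] = np.where(
            a_wins, df["padj_a_greater"], df["padj_b_greater"]
        )
        df["significant"] = df["p_adjusted"] <= alpha
        df = df.sort_values("p_adjusted", kind="stable").reset_index(
            drop=True
        )
    return df


def read_fasta(path: str | Path) -> dict[str, str]:
    return {
        rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")
    }


def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())
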