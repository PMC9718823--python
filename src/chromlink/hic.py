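"""Binned intra-chromosomal Hi-C contact matrices with Knight-Ruiz balancing.

Contacts are loaded from plain-text triplet dumps ("pos1 pos2 count" with
positions at bin starts) into a dense symmetric per-chromosome matrix.
Balancing rescales the matrix symmetrically, b_ij = s_i * m_ij * s_j, so
that every unmasked row sums to the same value; all-zero bins are masked
and excluded. The primary solver is the Knight-Ruiz inner-outer Newton
iteration; a damped Sinkhorn-Knopp fixed-point iteration is the fallback
when Newton fails to converge.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

DEFAULT_RESOLUTION = 5000


class BalanceError(RuntimeError):
    pass


@dataclass
class ContactMatrix:
    chrom: str
    resolution: int
    matrix: np.ndarray  # dense symmetric raw counts
    balanced: np.ndarray | None = None
    scaling: np.ndarray | None = None  # per-bin factor, NaN for masked bins
    masked_bins: np.ndarray = field(default_factory=lambda: np.array([], int))

    @property
    def n_bins(self) -> int:
        return self.matrix.shape[0]

    def bin_of(self, pos: int) -> int:
        return int(pos // self.resolution)


def load_triplets(
    path: str | Path,
    chrom: str,
    resolution: int = DEFAULT_RESOLUTION,
    n_bins: int | None = None,
) -> ContactMatrix:
    """Load a "pos1 pos2 value" triplet dump into a symmetric matrix.

    Positions must be multiples of the resolution (bin starts); duplicate
    pairs are summed. ``n_bins`` may be given to fix the matrix size
    (e.g. from the chromosome length); otherwise it is inferred.
    """
    try:
        df = pd.read_csv(
            path, sep=r"\s+", header=None,
            names=["pos1", "pos2", "value"], comment="#",
        )
    except pd.errors.EmptyDataError:
        df = pd.DataFrame(columns=["pos1", "pos2", "value"])
    if len(df):
        pos = df[["pos1", "pos2"]].to_numpy()
        if (pos % resolution).any():
            bad = pos[(pos % resolution).any(axis=1)][0]
            raise ValueError(
                f"{path}: position {bad} not a multiple of resolution "
                f"{resolution}"
            )
        if (df["value"] < 0).any():
            raise ValueError(f"{path}: negative contact value")
    if n_bins is None:
        n_bins = int(pos.max() // resolution) + 1 if len(df) else 0
    m = np.zeros((n_bins, n_bins))
    if len(df):
        i = (df["pos1"] // resolution).to_numpy(int)
        j = (df["pos2"] // resolution).to_numpy(int)
        v = df["value"].to_numpy(float)
        np.add.at(m, (i, j), v)
        np.add.at(m, (j, i), v)
        # diagonal entries were added twice
        np.fill_diagonal(m, np.diag(m) / 2)
    cm = ContactMatrix(chrom, resolution, m)
    cm.masked_bins = np.flatnonzero(m.sum(axis=1) == 0)
    return cm


def write_triplets(cm: ContactMatrix, path: str | Path,
                   balanced: bool = False) -> None:
    m = cm.balanced if balanced else cm.matrix
    i, j = np.nonzero(np.triu(m))
    pd.DataFrame(
        {"pos1": i * cm.resolution, "pos2": j * cm.resolution,
         "value": m[i, j]}
    ).to_csv(path, sep="\t", header=False, index=False)


def _kr_factors(a: np.ndarray, tol: float, max_outer: int) -> np.ndarray:
    """Knight-Ruiz (2013) inner-outer Newton iteration.

    Returns x > 0 with diag(x) a diag(x) having unit row sums, for a
    symmetric nonnegative fully supported matrix.
    """
    n = a.shape[0]
    e = np.ones(n)
    x = e.copy()
    delta, bound = 0.1, 3.0
    g, etamax = 0.9, 0.1
    eta = etamax
    rt = tol ** 2
    v = x * (a @ x)
    rk = 1 - v
    rho_km1 = rk @ rk
    rout = rold = rho_km1
    outer = 0
    while rout > rt:
        outer += 1
        if outer > max_outer:
            raise BalanceError(
                f"KR outer iteration failed to converge; residual "
                f"{np.sqrt(rout):.3e}"
            )
        k = 0
        y = e.copy()
        innertol = max(eta ** 2 * rout, rt)
        rho_km2 = rho_km1
        while rho_km1 > innertol:
            k += 1
            if k == 1:
                z = rk / v
                p = z.copy()
                rho_km1 = rk @ z
            else:
                beta = rho_km1 / rho_km2
                p = z + beta * p
            w = x * (a @ (x * p)) + v * p
            denom = p @ w
            if denom <= 0:
                break
            alpha = rho_km1 / denom
            ap = alpha * p
            ynew = y + ap
            if ynew.min() <= delta:
                neg = ap < 0
                if not neg.any():
                    break
                gamma = np.min((delta - y[neg]) / ap[neg])
                y = y + gamma * ap
                break
            if ynew.max() >= bound:
                big = ynew > bound
                gamma = np.min((bound - y[big]) / ap[big])
                y = y + gamma * ap
                break
            y = ynew
            rk = rk - alpha * w
            rho_km2 = rho_km1
            z = rk / v
            rho_km1 = rk @ z
            if k > n:
                break
        x = x * y
        v = x * (a @ x)
        rk = 1 - v
        rho_km1 = rk @ rk
        rout = rho_km1
        rat = rout / rold
        rold = rout
        res_norm = np.sqrt(rout)
        eta = g * rat
        if g * eta ** 2 > 0.1:
            eta = max(eta, g * eta ** 2)
        eta = max(min(eta, etamax), 0.5 * tol / max(res_norm, tol))
        if not np.all(np.isfinite(x)) or x.min() <= 0:
            raise BalanceError("KR iterate left the positive cone")
    return x


def _sinkhorn_factors(a: np.ndarray, tol: float, max_iter: int) -> np.ndarray:
    """Damped symmetric Sinkhorn-Knopp: x <- sqrt(x / (a x))."""
    n = a.shape[0]
    x = np.ones(n)
    for _ in range(max_iter):
        s = a @ x
        if (s <= 0).any():
            raise BalanceError("zero row sum during Sinkhorn iteration")
        x = np.sqrt(x / s)
        rows = x * (a @ x)
        cv = rows.std() / rows.mean()
        if cv < tol:
            return x / np.sqrt(rows.mean())
    raise BalanceError(
        f"Sinkhorn fallback failed to converge; row-sum CV {cv:.3e}"
    )


def _row_sum_cv(rows: np.ndarray) -> float:
    return float(rows.std() / rows.mean())


def kr_balance(
    cm: ContactMatrix, tol: float = 1e-6, max_iter: int = 3000
) -> ContactMatrix:
    """Balance the matrix so unmasked row sums are equal (unit row sums).

    All-zero bins are masked and excluded from the solve. If the KR
    Newton iteration does not reach a row-sum coefficient of variation
    below ``tol``, the Sinkhorn fallback is run; failure of both raises
    :class:`BalanceError` with the residual.
    """
    m = cm.matrix
    if not np.allclose(m, m.T):
        raise ValueError("contact matrix is not symmetric")
    if (m < 0).any():
        raise ValueError("negative contact counts")
    keep = np.flatnonzero(m.sum(axis=1) > 0)
    cm.masked_bins = np.setdiff1d(np.arange(cm.n_bins), keep)
    scaling = np.full(cm.n_bins, np.nan)
    balanced = np.zeros_like(m)
    if keep.size:
        sub = m[np.ix_(keep, keep)]
        x = None
        try:
            x = _kr_factors(sub, tol, max_outer=max_iter)
            rows = x * (sub @ x)
            if _row_sum_cv(rows) >= tol:
                x = None
        except BalanceError:
            x = None
        if x is None:
            x = _sinkhorn_factors(sub, tol, max_iter)
        bal = (x[:, None] * sub) * x[None, :]
        scaling[keep] = x
        balanced[np.ix_(keep, keep)] = bal
    cm.scaling = scaling
    cm.balanced = balanced
    return cm


def contact(
    cm: ContactMatrix,
    pos_a: int,
    pos_b: int,
    chrom_a: str | None = None,
    chrom_b: str | None = None,
) -> float:
    """Balanced contact frequency between the bins of two positions.

    Returns 0 for masked or out-of-range bins. Positions must be on the
    matrix's chromosome (intra-chromosomal only).
    """
    for c in (chrom_a, chrom_b):
        if c is not None and c != cm.chrom:
            raise ValueError(
                f"position on {c} queried against {cm.chrom} matrix "
                "(intra-chromosomal contacts only)"
            )
    if cm.balanced is None:
        raise ValueError("matrix not balanced; call kr_balance first")
    i, j = cm.bin_of(pos_a), cm.bin_of(pos_b)
    if not (0 <= i < cm.n_bins and 0 <= j < cm.n_bins):
        return 0.0
    return float(cm.balanced[i, j])
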