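"""Patterson's D and the window f_d admixture-proportion statistic.

For the quartet tree (((P1, P2), P3), O) with per-site derived-allele
frequencies p1, p2, p3, pO, the frequency-weighted site pattern weights are

    abba = (1 - p1) * p2 * p3 * (1 - pO)
    baba = p1 * (1 - p2) * p3 * (1 - pO)

and D over a region is sum(abba - baba) / sum(abba + baba).  A site is
"informative" when abba + baba > 0.  Genome-wide significance uses a
delete-one block jackknife over fixed physical spans.

f_d rescales the numerator by its value under complete replacement of the
recipient by the donor: in the denominator both P2 and P3 are replaced by
the donor frequency pD = max(p2, p3).  f_d is computed in non-overlapping
windows of a fixed number of informative sites (default 50), and windows
with non-positive numerator are assigned f_d = 0 (the raw value is kept).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import SiteFrequencyTable
from .layout import GenomeLayout

__all__ = [
    "site_pattern", "pattern_weights", "compute_D", "jackknife_D",
    "window_fd", "genome_mean_fd", "SitePatternWeights", "DResult",
]


class DomainError(ValueError):
    pass


@dataclass(frozen=True)
class SitePatternWeights:
    abba: float
    baba: float

    @property
    def informative(self) -> bool:
        return self.abba + self.baba > 0


@dataclass(frozen=True)
class DResult:
    """Genome (or chromosome) D with block-jackknife uncertainty."""

    D: float
    se: float
    Z: float
    p: float
    block_size_bp: int
    n_blocks: int
    n_informative: int
    degenerate: bool = False

    def to_dict(self) -> dict:
        return {
            "D": self.D, "se": self.se, "Z": self.Z, "p": self.p,
            "block_size_bp": self.block_size_bp, "n_blocks": self.n_blocks,
            "n_informative": self.n_informative, "degenerate": self.degenerate,
        }


def site_pattern(p1: float, p2: float, p3: float, pO: float) -> SitePatternWeights:
    """ABBA/BABA weights for a single site from the four derived frequencies."""
    for name, p in zip("p1 p2 p3 pO".split(), (p1, p2, p3, pO)):
        if not 0.0 <= p <= 1.0:
            raise DomainError(f"{name} = {p} outside [0, 1]")
    abba = (1 - p1) * p2 * p3 * (1 - pO)
    baba = p1 * (1 - p2) * p3 * (1 - pO)
    return SitePatternWeights(abba, baba)


def pattern_weights(table: SiteFrequencyTable) -> pd.DataFrame:
    """Vectorized per-site weights for a whole table.

    Sites with any missing taxon are excluded from both the weights and the
    informative-site count.  Columns: chrom, pos, abba, baba, abba_d,
    baba_d (donor-substituted denominator weights), informative.
    """
    freq = table.frequencies()
    p1 = freq["p1"].to_numpy()
    p2 = freq["p2"].to_numpy()
    p3 = freq["p3"].to_numpy()
    pO = freq["o"].to_numpy()
    ok = ~(np.isnan(p1) | np.isnan(p2) | np.isnan(p3) | np.isnan(pO))
    out = freq.loc[ok, ["chrom", "pos"]].reset_index(drop=True)
    p1, p2, p3, pO = p1[ok], p2[ok], p3[ok], pO[ok]
    out["abba"] = (1 - p1) * p2 * p3 * (1 - pO)
    out["baba"] = p1 * (1 - p2) * p3 * (1 - pO)
    pD = np.maximum(p2, p3)
    out["abba_d"] = (1 - p1) * pD * pD * (1 - pO)
    out["baba_d"] = p1 * (1 - pD) * pD * (1 - pO)
    out["informative"] = (out["abba"] + out["baba"]) > 0
    return out


def compute_D(weights: pd.DataFrame) -> float:
    """D = sum(abba - baba) / sum(abba + baba) over the given sites."""
    num = float(weights["abba"].sum() - weights["baba"].sum())
    den = float(weights["abba"].sum() + weights["baba"].sum())
    if den == 0:
        raise DomainError("D undefined: no informative sites")
    return num / den


def jackknife_D(
    table: SiteFrequencyTable,
    block_size_bp: int = 5_000_000,
    layout: GenomeLayout | None = None,
    chromosomes: list[str] | None = None,
) -> DResult:
    """Patterson's D with a delete-one block jackknife.

    Blocks are non-overlapping physical spans of ``block_size_bp`` aligned
    to chromosome starts (position 1); blocks without informative sites are
    skipped.  SE^2 = ((m-1)/m) * sum_i (D_{-i} - mean(D_{-.}))^2 over the m
    retained blocks; Z = D / SE with a two-sided normal p-value.
    """
    weights = pattern_weights(table)
    if chromosomes is not None:
        weights = weights[weights["chrom"].isin(chromosomes)]
    info = weights[weights["informative"]]
    if len(info) == 0:
        raise DomainError("no informative sites")
    block = (
        info["chrom"].astype(str)
        + ":"
        + ((info["pos"] - 1) // block_size_bp).astype(str)
    )
    g = info.groupby(block.to_numpy(), sort=False)[["abba", "baba"]].sum()
    num_b = (g["abba"] - g["baba"]).to_numpy()
    den_b = (g["abba"] + g["baba"]).to_numpy()
    keep = den_b > 0
    num_b, den_b = num_b[keep], den_b[keep]
    m = len(num_b)
    if m < 2:
        raise DomainError(f"need >= 2 non-empty blocks, got {m}")
    num, den = num_b.sum(), den_b.sum()
    D = num / den
    d_minus = (num - num_b) / (den - den_b)
    se = math.sqrt((m - 1) / m * np.sum((d_minus - d_minus.mean()) ** 2))
    degenerate = se == 0
    if degenerate:
        z = 0.0 if D == 0 else math.nan
        p = 1.0 if D == 0 else math.nan
    else:
        z = D / se
        p = 2 * stats.norm.sf(abs(z))
    return DResult(
        D=float(D), se=float(se), Z=float(z), p=float(p),
        block_size_bp=block_size_bp, n_blocks=m,
        n_informative=int(len(info)), degenerate=degenerate,
    )


def window_fd(table: SiteFrequencyTable, w: int = 50) -> pd.DataFrame:
    """Non-overlapping windows of ``w`` informative sites with f_d per window.

    Windows never span chromosomes; a trailing group of fewer than ``w``
    informative sites is dropped.  Columns: chrom, window (0-based index
    per chromosome), start, end (first/last informative-site positions,
    1-based bp), n_sites, fd (clamped to [0, 1]), fd_raw, D_window.
    """
    if w < 2:
        raise DomainError(f"window size w must be >= 2, got {w}")
    weights = pattern_weights(table)
    info = weights[weights["informative"]]
    rows = []
    for chrom, grp in info.groupby("chrom", sort=False):
        n_win = len(grp) // w
        for k in range(n_win):
            win = grp.iloc[k * w : (k + 1) * w]
            num = float(win["abba"].sum() - win["baba"].sum())
            den_d = float(win["abba_d"].sum() - win["baba_d"].sum())
            den = float(win["abba"].sum() + win["baba"].sum())
            d_win = num / den if den > 0 else math.nan
            fd_raw = num / den_d if den_d != 0 else math.nan
            fd = 0.0 if (num <= 0 or not math.isfinite(fd_raw)) else fd_raw
            rows.append(
                {
                    "chrom": chrom, "window": k,
                    "start": int(win["pos"].iloc[0]),
                    "end": int(win["pos"].iloc[-1]),
                    "n_sites": w, "fd": fd, "fd_raw": fd_raw,
                    "D_window": d_win,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["chrom", "window", "start", "end", "n_sites", "fd", "fd_raw", "D_window"],
    )


def genome_mean_fd(windows: pd.DataFrame) -> float:
    """Unweighted mean of window f_d values: the introgressed proportion."""
    if len(windows) == 0:
        raise DomainError("no windows")
    return float(windows["fd"].mean())
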