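"""Genetic-map construction from an F2 ABH genotype matrix.

The pipeline mirrors standard intercross practice: filter markers to
segregating sites (A-allele frequency strictly between 0.2 and 0.8, with
heterozygotes at half weight) and thin them to a minimum physical spacing;
clean the calls per individual (fill missing runs flanked by identical
calls, flip short interspersed runs bounded on both sides by a common
different call); estimate adjacent-pair recombination fractions by EM over
the phase-ambiguous double-heterozygote class; and chain Kosambi distances
into per-chromosome map positions.

Adjacent-pair (two-point) estimation is used instead of full multipoint
EM; with dense, cleaned F2 data the chained two-point Kosambi map converges
to the multipoint answer while staying transparent and fast.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import MISSING, F2GenotypeMatrix

__all__ = [
    "filter_markers", "clean_genotypes", "est_recfrac",
    "kosambi_cM", "inverse_kosambi", "build_map",
    "collapse_duplicate_markers", "CleaningReport",
]


class LinkageError(ValueError):
    pass


class LowInformationWarning(UserWarning):
    """Fewer informative individuals than is comfortable for a two-point r."""


# ---------------------------------------------------------------------------
# Marker filtering
# ---------------------------------------------------------------------------

def a_allele_frequency(matrix: F2GenotypeMatrix) -> np.ndarray:
    """Per-marker A-allele frequency (2 n_A + n_H) / (2 n_called)."""
    nA = (matrix.calls == "A").sum(axis=0)
    nH = (matrix.calls == "H").sum(axis=0)
    n_called = (matrix.calls != MISSING).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(n_called > 0, (2 * nA + nH) / (2 * np.maximum(n_called, 1)), np.nan)


def filter_markers(
    matrix: F2GenotypeMatrix,
    maf_low: float = 0.2,
    maf_high: float = 0.8,
    min_spacing_bp: int = 1000,
) -> F2GenotypeMatrix:
    """Keep segregating markers and thin to a minimum physical spacing.

    A marker is segregating when its A-allele frequency lies strictly in
    (maf_low, maf_high).  Thinning is greedy left-to-right within each
    chromosome: a marker is retained only if it lies at least
    ``min_spacing_bp`` beyond the previously retained marker.
    """
    freq = a_allele_frequency(matrix)
    seg = (freq > maf_low) & (freq < maf_high)
    keep: list[int] = []
    for chrom in matrix.chromosomes:
        last_pos: int | None = None
        for j in matrix.marker_index(chrom):
            if not seg[j]:
                continue
            if last_pos is None or matrix.pos[j] - last_pos >= min_spacing_bp:
                keep.append(int(j))
                last_pos = int(matrix.pos[j])
    if not keep:
        raise LinkageError("all markers removed by filtering")
    return matrix.subset_markers(np.array(keep))


# ---------------------------------------------------------------------------
# Genotype cleaning
# ---------------------------------------------------------------------------

@dataclass
class CleaningReport:
    missing_before: float
    missing_after: float
    class_proportions: dict[str, float] = field(default_factory=dict)
    n_filled: int = 0
    n_corrected: int = 0
    n_passes: int = 0

    def to_dict(self) -> dict:
        return {
            "missing_before": self.missing_before,
            "missing_after": self.missing_after,
            "class_proportions": self.class_proportions,
            "n_filled": self.n_filled,
            "n_corrected": self.n_corrected,
            "n_passes": self.n_passes,
        }


def _runs(seq: np.ndarray) -> list[tuple[int, int, str]]:
    """Run-length encode a call vector as (start, stop_exclusive, symbol)."""
    out = []
    start = 0
    for i in range(1, len(seq) + 1):
        if i == len(seq) or seq[i] != seq[start]:
            out.append((start, i, seq[start]))
            start = i
    return out


def _clean_sequence(seq: np.ndarray, max_hap: int) -> tuple[np.ndarray, int, int]:
    """One pass of (i) flanked missing fill then (ii) interspersed-run flip."""
    seq = seq.copy()
    filled = corrected = 0
    runs = _runs(seq)
    # (i) missing runs flanked by identical calls
    for k, (a, b, sym) in enumerate(runs):
        if sym == MISSING and 0 < k < len(runs) - 1:
            left, right = runs[k - 1][2], runs[k + 1][2]
            if left == right and left != MISSING:
                seq[a:b] = left
                filled += b - a
    runs = _runs(seq)
    # (ii) short runs flanked on both sides by a common different call
    for k, (a, b, sym) in enumerate(runs):
        if sym == MISSING or not 0 < k < len(runs) - 1:
            continue
        left, right = runs[k - 1][2], runs[k + 1][2]
        if left == right and left not in (sym, MISSING) and b - a < max_hap:
            seq[a:b] = left
            corrected += b - a
    return seq, filled, corrected


def clean_genotypes(
    matrix: F2GenotypeMatrix, max_hap: int = 6, max_passes: int = 10
) -> tuple[F2GenotypeMatrix, CleaningReport]:
    """Impute flanked missing runs and flip short interspersed runs.

    Both rules operate per individual within a chromosome, in physical
    marker order, and are repeated until a fixed point (at most
    ``max_passes`` passes).  Runs shorter than ``max_hap`` markers flanked
    on both sides by a common different call are treated as call errors.
    """
    calls = matrix.calls.copy()
    report = CleaningReport(
        missing_before=float((calls == MISSING).mean()) if calls.size else 0.0,
        missing_after=0.0,
    )
    chrom_blocks = [matrix.marker_index(c) for c in matrix.chromosomes]
    for _ in range(max_passes):
        changed = False
        report.n_passes += 1
        for i in range(calls.shape[0]):
            for idx in chrom_blocks:
                cleaned, nf, nc = _clean_sequence(calls[i, idx], max_hap)
                if nf or nc:
                    calls[i, idx] = cleaned
                    report.n_filled += nf
                    report.n_corrected += nc
                    changed = True
        if not changed:
            break
    report.missing_after = float((calls == MISSING).mean()) if calls.size else 0.0
    n_called = (calls != MISSING).sum()
    for sym in "ABH":
        report.class_proportions[sym] = (
            float((calls == sym).sum() / n_called) if n_called else math.nan
        )
    out = F2GenotypeMatrix(
        calls, list(matrix.markers), matrix.chrom, matrix.pos, list(matrix.individuals)
    )
    return out, report


# ---------------------------------------------------------------------------
# Two-point recombination fraction (EM)
# ---------------------------------------------------------------------------

_GENO_CODE = {"A": 0, "H": 1, "B": 2}


def two_locus_counts(g1: np.ndarray, g2: np.ndarray) -> np.ndarray:
    """3x3 joint genotype counts (rows locus 1, cols locus 2; A/H/B order)."""
    counts = np.zeros((3, 3), dtype=int)
    for a, b in zip(g1, g2):
        if a in _GENO_CODE and b in _GENO_CODE:
            counts[_GENO_CODE[a], _GENO_CODE[b]] += 1
    return counts


# number of recombinant gametes carried by each joint genotype class
# (coupling-phase F1); the double heterozygote (1,1) is a mixture of 0 and 2.
_RECOMB_GAMETES = np.array([[0, 1, 2], [1, -1, 1], [2, 1, 0]])


def f2_joint_probabilities(r: float) -> np.ndarray:
    """Exact 3x3 joint genotype probabilities for an F2 at recombination r."""
    s = (1 - r) / 2  # parental gamete prob (per type)
    t = r / 2        # recombinant gamete prob (per type)
    p = np.empty((3, 3))
    p[0, 0] = p[2, 2] = s * s
    p[0, 2] = p[2, 0] = t * t
    p[0, 1] = p[1, 0] = p[1, 2] = p[2, 1] = 2 * s * t
    p[1, 1] = 2 * (s * s + t * t)
    return p


def est_recfrac(
    counts: np.ndarray,
    tol: float = 1e-8,
    max_iter: int = 1000,
    r0: float = 0.25,
) -> float:
    """Maximum-likelihood recombination fraction from a 3x3 F2 count table.

    EM treats the phase-ambiguous double heterozygote as a mixture of 0 and
    2 recombinant gametes; all other classes carry a known recombinant
    count.  The estimate is clamped to [0, 0.5].
    """
    counts = np.asarray(counts, dtype=float)
    n = counts.sum()
    if n == 0:
        raise LinkageError("empty two-locus count table")
    if n < 10:
        warnings.warn(
            f"only {int(n)} informative individuals for two-point r",
            LowInformationWarning, stacklevel=2,
        )
    known = float((counts * np.where(_RECOMB_GAMETES >= 0, _RECOMB_GAMETES, 0)).sum())
    n_hh = float(counts[1, 1])
    r = r0
    for _ in range(max_iter):
        denom = r * r + (1 - r) * (1 - r)
        e_hh = 2 * n_hh * (r * r / denom) if denom > 0 else 0.0
        r_new = (known + e_hh) / (2 * n)
        r_new = min(max(r_new, 0.0), 0.5)
        if abs(r_new - r) < tol:
            r = r_new
            break
        r = r_new
    return float(r)


def f2_log_likelihood(counts: np.ndarray, r: float) -> float:
    """Exact two-locus F2 log-likelihood at recombination fraction r."""
    p = f2_joint_probabilities(r)
    counts = np.asarray(counts, float)
    with np.errstate(divide="ignore", invalid="ignore"):
        ll = np.where(counts > 0, counts * np.log(np.maximum(p, 1e-300)), 0.0)
    return float(ll.sum())


# ---------------------------------------------------------------------------
# Kosambi mapping function
# ---------------------------------------------------------------------------

def kosambi_cM(r: float) -> float:
    """Kosambi map distance d = 25 ln((1+2r)/(1-2r)) cM for r in [0, 0.5)."""
    if not 0 <= r < 0.5:
        raise LinkageError(f"r = {r} outside [0, 0.5): map distance infinite")
    return 25.0 * math.log((1 + 2 * r) / (1 - 2 * r))


def inverse_kosambi(d_cM: float) -> float:
    """Recombination fraction r = tanh(d/50)/2 for map distance d >= 0 cM."""
    if d_cM < 0:
        raise LinkageError(f"map distance {d_cM} < 0")
    return 0.5 * math.tanh(d_cM / 50.0)


# ---------------------------------------------------------------------------
# Map construction
# ---------------------------------------------------------------------------

def collapse_duplicate_markers(matrix: F2GenotypeMatrix) -> F2GenotypeMatrix:
    """Drop markers whose call vector duplicates an earlier marker's.

    Duplicates carry no extra two-point information; the leftmost
    representative of each identical pattern is kept (per chromosome).
    """
    keep: list[int] = []
    for chrom in matrix.chromosomes:
        seen: set[tuple] = set()
        for j in matrix.marker_index(chrom):
            pattern = tuple(matrix.calls[:, j])
            if pattern not in seen:
                seen.add(pattern)
                keep.append(int(j))
    return matrix.subset_markers(np.array(keep))


def build_map(
    matrix: F2GenotypeMatrix, collapse_duplicates: bool = True
) -> pd.DataFrame:
    """Chain adjacent-pair Kosambi distances into per-chromosome positions.

    Returns a genetic map DataFrame (marker, chrom, pos_bp, pos_cM) with the
    first marker of each chromosome at 0 cM.  Physical order is taken as
    the marker order (as anchored to the reference assembly).
    """
    if collapse_duplicates:
        matrix = collapse_duplicate_markers(matrix)
    rows = []
    for chrom in matrix.chromosomes:
        idx = matrix.marker_index(chrom)
        if len(idx) == 1:
            warnings.warn(
                f"chromosome {chrom!r} has a single marker: zero-length map",
                UserWarning, stacklevel=2,
            )
        cm = 0.0
        prev = None
        for j in idx:
            if prev is not None:
                counts = two_locus_counts(matrix.calls[:, prev], matrix.calls[:, j])
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore", LowInformationWarning)
                    r = est_recfrac(counts)
                r = min(r, 0.4999)  # unlinked adjacent pair: keep distance finite
                cm += kosambi_cM(r)
            rows.append(
                {
                    "marker": matrix.markers[int(j)],
                    "chrom": chrom,
                    "pos_bp": int(matrix.pos[int(j)]),
                    "pos_cM": cm,
                }
            )
            prev = j
    return pd.DataFrame(rows)


def map_summary(gmap: pd.DataFrame) -> pd.DataFrame:
    """Per-chromosome map length (cM), marker count and physical span (bp)."""
    out = []
    for chrom, grp in gmap.groupby("chrom", sort=False):
        out.append(
            {
                "chrom": chrom,
                "n_markers": len(grp),
                "map_length_cM": float(grp["pos_cM"].max()),
                "span_bp": int(grp["pos_bp"].max() - grp["pos_bp"].min()),
            }
        )
    return pd.DataFrame(out)
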