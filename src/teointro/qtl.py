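"""Single-QTL genome scan for an F2 intercross.

Genotype probabilities at markers and pseudomarkers come from
forward-backward smoothing of a three-state (AA/AB/BB) Markov chain whose
transition probabilities derive from inverse-Kosambi recombination
fractions between positions; genotyping error enters through the emission
model (correct call with probability 1 - eps, errors split evenly), and
missing calls emit uniformly.

The scan itself is Haley-Knott regression: at each position the trait is
regressed on additive and dominance predictors built from the probability
triple, and LOD = (n/2) log10(RSS0 / RSS1).  Genome-wide significance uses
the permutation distribution of the maximum LOD; support intervals are
1.5-LOD-drop regions; percent variance explained uses the closed form
100 (1 - 10^(-2 LOD / n)).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import F2GenotypeMatrix
from .linkage import inverse_kosambi

__all__ = [
    "genoprob", "scan_hk", "permutation_threshold", "support_interval",
    "pve", "scan_trait", "GenotypeProbabilities", "QTLResult",
]

F2_PRIOR = np.array([0.25, 0.5, 0.25])
_CALL_STATE = {"A": 0, "H": 1, "B": 2}


class QTLError(ValueError):
    pass


def f2_transition(r: float) -> np.ndarray:
    """3-state transition matrix over one interval with recombination r."""
    s, t = 1 - r, r
    return np.array(
        [
            [s * s, 2 * s * t, t * t],
            [s * t, s * s + t * t, s * t],
            [t * t, 2 * s * t, s * s],
        ]
    )


@dataclass
class ChromosomeProbs:
    positions_cM: np.ndarray
    positions_bp: np.ndarray
    is_marker: np.ndarray
    probs: np.ndarray  # (n_ind, n_pos, 3)


@dataclass
class GenotypeProbabilities:
    """Smoothed genotype probabilities on a marker + pseudomarker grid."""

    chromosomes: dict[str, ChromosomeProbs]
    eps: float
    step_cM: float
    individuals: list[str] = field(default_factory=list)

    @property
    def n_individuals(self) -> int:
        first = next(iter(self.chromosomes.values()))
        return first.probs.shape[0]

    def positions(self) -> pd.DataFrame:
        rows = []
        for chrom, cp in self.chromosomes.items():
            for k in range(len(cp.positions_cM)):
                rows.append(
                    {
                        "chrom": chrom,
                        "pos_cM": cp.positions_cM[k],
                        "pos_bp": cp.positions_bp[k],
                        "is_marker": bool(cp.is_marker[k]),
                    }
                )
        return pd.DataFrame(rows)


def _position_grid(marker_cM: np.ndarray, step_cM: float) -> tuple[np.ndarray, np.ndarray]:
    """Merge marker positions with a regular step grid; flag the markers."""
    if step_cM <= 0:
        return marker_cM.copy(), np.ones(len(marker_cM), bool)
    grid = np.arange(0.0, marker_cM[-1] + 1e-9, step_cM)
    pos = np.concatenate([marker_cM, grid])
    flag = np.concatenate([np.ones(len(marker_cM), bool), np.zeros(len(grid), bool)])
    order = np.argsort(pos, kind="stable")
    pos, flag = pos[order], flag[order]
    # drop pseudomarkers within 1e-6 cM of the previously kept position
    keep = np.ones(len(pos), bool)
    last = -math.inf
    for i in range(len(pos)):
        if pos[i] - last < 1e-6 and not flag[i]:
            keep[i] = False
        else:
            last = pos[i]
    return pos[keep], flag[keep]


def genoprob(
    matrix: F2GenotypeMatrix,
    gmap: pd.DataFrame,
    eps: float = 1e-4,
    step_cM: float = 1.0,
) -> GenotypeProbabilities:
    """Forward-backward genotype probabilities along each chromosome.

    ``gmap`` (marker, chrom, pos_bp, pos_cM) must cover exactly the markers
    of ``matrix`` in the same per-chromosome order.  Pseudomarkers are
    inserted every ``step_cM`` (``step_cM=0`` evaluates at markers only).
    """
    chrom_out: dict[str, ChromosomeProbs] = {}
    n_ind = matrix.n_individuals
    map_by_chrom = {str(c): grp for c, grp in gmap.groupby("chrom", sort=False)}
    for chrom in matrix.chromosomes:
        idx = matrix.marker_index(chrom)
        sub = map_by_chrom.get(str(chrom))
        if sub is None or list(sub["marker"]) != [matrix.markers[int(j)] for j in idx]:
            raise QTLError(
                f"genetic map does not match matrix markers on chromosome {chrom!r}"
            )
        marker_cM = sub["pos_cM"].to_numpy(float)
        marker_bp = sub["pos_bp"].to_numpy(float)
        pos, is_marker = _position_grid(marker_cM, step_cM)
        n_pos = len(pos)
        # emission likelihoods: (n_ind, n_pos, 3); uniform at pseudomarkers
        emit = np.ones((n_ind, n_pos, 3))
        marker_slots = np.flatnonzero(is_marker)
        for k_local, slot in enumerate(marker_slots):
            calls = matrix.calls[:, idx[k_local]]
            e = np.ones((n_ind, 3))
            for call, state in _CALL_STATE.items():
                obs = calls == call
                if obs.any():
                    e[obs] = eps / 2
                    e[obs, state] = 1 - eps
            emit[:, slot, :] = e
        # interval transition matrices
        trans = []
        for k in range(n_pos - 1):
            r = inverse_kosambi(pos[k + 1] - pos[k])
            trans.append(f2_transition(r))
        # forward-backward, scaled, vectorized over individuals
        alpha = np.empty((n_ind, n_pos, 3))
        scale = np.empty((n_ind, n_pos))
        a = F2_PRIOR[None, :] * emit[:, 0, :]
        scale[:, 0] = a.sum(axis=1)
        alpha[:, 0, :] = a / scale[:, 0, None]
        for k in range(1, n_pos):
            a = (alpha[:, k - 1, :] @ trans[k - 1]) * emit[:, k, :]
            scale[:, k] = a.sum(axis=1)
            alpha[:, k, :] = a / scale[:, k, None]
        beta = np.empty((n_ind, n_pos, 3))
        beta[:, -1, :] = 1.0
        for k in range(n_pos - 2, -1, -1):
            b = (beta[:, k + 1, :] * emit[:, k + 1, :]) @ trans[k].T
            beta[:, k, :] = b / scale[:, k + 1, None]
        post = alpha * beta
        post /= post.sum(axis=2, keepdims=True)
        pos_bp = np.interp(pos, marker_cM, marker_bp)
        chrom_out[str(chrom)] = ChromosomeProbs(pos, pos_bp, is_marker, post)
    return GenotypeProbabilities(
        chrom_out, eps=eps, step_cM=step_cM, individuals=list(matrix.individuals)
    )


# ---------------------------------------------------------------------------
# Haley-Knott regression scan
# ---------------------------------------------------------------------------

def _scan_matrix(probs: GenotypeProbabilities, Y: np.ndarray) -> np.ndarray:
    """LOD for each position (rows) and each trait column of Y (no NaNs)."""
    n, k = Y.shape
    yty = (Y**2).sum(axis=0)
    ybar = Y.mean(axis=0)
    rss0 = yty - n * ybar**2
    lods = []
    for cp in probs.chromosomes.values():
        for j in range(cp.probs.shape[1]):
            p = cp.probs[:, j, :]
            X = np.column_stack([np.ones(n), p[:, 0] - p[:, 2], p[:, 1]])
            Q, _ = np.linalg.qr(X)
            qty = Q.T @ Y
            rss1 = np.maximum(yty - (qty**2).sum(axis=0), 1e-12)
            with np.errstate(divide="ignore", invalid="ignore"):
                lod = 0.5 * n * np.log10(np.maximum(rss0, 1e-12) / rss1)
            lods.append(np.maximum(lod, 0.0))
    return np.asarray(lods)


def scan_hk(probs: GenotypeProbabilities, trait: np.ndarray) -> pd.DataFrame:
    """Single-QTL Haley-Knott scan of one trait.

    Individuals with a missing (NaN) trait value are dropped.  Returns a
    DataFrame (chrom, pos_cM, pos_bp, is_marker, lod).
    """
    trait = np.asarray(trait, float)
    ok = ~np.isnan(trait)
    if ok.sum() < 10:
        raise QTLError(f"only {int(ok.sum())} individuals with trait values")
    sub = _subset_probs(probs, ok)
    y = trait[ok]
    out = probs.positions()
    if np.ptp(y) == 0:
        warnings.warn("trait has zero variance; LOD curve is all zero",
                      UserWarning, stacklevel=2)
        out["lod"] = 0.0
        return out
    out["lod"] = _scan_matrix(sub, y[:, None])[:, 0]
    return out


def _subset_probs(probs: GenotypeProbabilities, ok: np.ndarray) -> GenotypeProbabilities:
    if ok.all():
        return probs
    chroms = {
        c: ChromosomeProbs(cp.positions_cM, cp.positions_bp, cp.is_marker, cp.probs[ok])
        for c, cp in probs.chromosomes.items()
    }
    inds = [i for i, keep in zip(probs.individuals, ok) if keep]
    return GenotypeProbabilities(chroms, probs.eps, probs.step_cM, inds)


def permutation_threshold(
    probs: GenotypeProbabilities,
    trait: np.ndarray,
    n_perm: int = 1000,
    alpha: float = 0.05,
    rng: np.random.Generator | int | None = None,
) -> float:
    """Genome-wide LOD threshold from the permutation null.

    The trait is permuted across individuals ``n_perm`` times; the
    threshold is the empirical (1 - alpha) quantile of the genome-wide
    maximum LOD (alpha = 1 returns the minimum permuted maximum).
    """
    if n_perm < 100:
        raise QTLError(f"n_perm must be >= 100, got {n_perm}")
    rng = np.random.default_rng(rng)
    trait = np.asarray(trait, float)
    ok = ~np.isnan(trait)
    y = trait[ok]
    sub = _subset_probs(probs, ok)
    Y = np.column_stack([rng.permutation(y) for _ in range(n_perm)])
    max_lod = _scan_matrix(sub, Y).max(axis=0)
    return float(np.quantile(max_lod, 1 - alpha, method="higher"))


def support_interval(scan: pd.DataFrame, drop: float = 1.5) -> dict:
    """LOD-drop support interval around the genome-wide peak.

    The interval is the widest contiguous run of positions on the peak
    chromosome with LOD >= peak - drop that contains the peak, reported in
    cM and in bp (via the Marey interpolation carried by the scan grid).
    A flat curve yields the whole chromosome with a warning.
    """
    if not np.isfinite(scan["lod"]).any():
        raise QTLError("no finite LOD values")
    peak_row = scan.loc[scan["lod"].idxmax()]
    chrom = peak_row["chrom"]
    sub = scan[scan["chrom"] == chrom].reset_index(drop=True)
    if np.ptp(sub["lod"].to_numpy()) == 0:
        warnings.warn("flat LOD curve; interval covers the whole chromosome",
                      UserWarning, stacklevel=2)
    thr = float(peak_row["lod"]) - drop
    above = sub["lod"].to_numpy() >= thr
    k = int(sub["lod"].idxmax())
    i = k
    while i > 0 and above[i - 1]:
        i -= 1
    j = k
    while j < len(sub) - 1 and above[j + 1]:
        j += 1
    return {
        "chrom": str(chrom),
        "peak_cM": float(peak_row["pos_cM"]),
        "peak_bp": float(peak_row["pos_bp"]),
        "peak_lod": float(peak_row["lod"]),
        "lo_cM": float(sub["pos_cM"].iloc[i]),
        "hi_cM": float(sub["pos_cM"].iloc[j]),
        "lo_bp": float(sub["pos_bp"].iloc[i]),
        "hi_bp": float(sub["pos_bp"].iloc[j]),
    }


def pve(peak_lod: float, n: int) -> float:
    """Percent trait variance explained: 100 (1 - 10^(-2 LOD / n))."""
    return 100.0 * (1.0 - 10.0 ** (-2.0 * peak_lod / n))


@dataclass
class QTLResult:
    trait: str
    scan: pd.DataFrame
    threshold: float
    interval: dict
    percent_variance: float
    significant: bool

    def summary(self) -> dict:
        return {
            "trait": self.trait,
            "chrom": self.interval["chrom"],
            "peak_bp": self.interval["peak_bp"],
            "peak_cM": self.interval["peak_cM"],
            "lod": self.interval["peak_lod"],
            "threshold": self.threshold,
            "significant": self.significant,
            "interval_bp": (self.interval["lo_bp"], self.interval["hi_bp"]),
            "percent_variance": self.percent_variance,
        }


def scan_trait(
    probs: GenotypeProbabilities,
    trait: np.ndarray,
    name: str = "trait",
    n_perm: int = 1000,
    alpha: float = 0.05,
    drop: float = 1.5,
    rng: np.random.Generator | int | None = None,
) -> QTLResult:
    """Full single-trait workflow: scan, permutation threshold, interval."""
    scan = scan_hk(probs, trait)
    thr = permutation_threshold(probs, trait, n_perm=n_perm, alpha=alpha, rng=rng)
    interval = support_interval(scan, drop=drop)
    n = int((~np.isnan(np.asarray(trait, float))).sum())
    return QTLResult(
        trait=name, scan=scan, threshold=thr, interval=interval,
        percent_variance=pve(interval["peak_lod"], n),
        significant=interval["peak_lod"] >= thr,
    )
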