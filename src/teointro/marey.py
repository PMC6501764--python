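"""Marey maps: smoothed genetic-vs-physical curves and local recombination.

A Marey map plots genetic position (cM) against physical position (Mb); its
derivative is the local recombination rate (RR, cM/Mb).  Each chromosome is
fitted with a cubic smoothing spline whose penalty is calibrated so the
effective degrees of freedom (trace of the smoother matrix) hit a target
(default 10).  Markers that force the fitted derivative negative are then
removed greedily — at each step the marker whose deletion most increases
the minimum fitted derivative — until the curve is monotone; this automates
the manual removal of map-distorting markers.  Remaining tiny negative
excursions are clamped to zero when RR is evaluated.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.interpolate import BSpline, make_smoothing_spline

from .events import IntrogressionEvent
from .layout import GenomeLayout

__all__ = [
    "fit_marey", "fit_all_chromosomes", "rr_at", "rr_grid",
    "detect_pericentromere", "rr_event_association", "compare_maps",
    "pericentromere_enrichment", "MareyCurve", "RRProfile",
    "PericentromericRegion",
]


class MareyError(ValueError):
    pass


@dataclass
class MareyCurve:
    """Monotone smoothed cM(x) for one chromosome (x in bp internally)."""

    chrom: str
    spline: BSpline
    x_min: float  # bp
    x_max: float  # bp
    lam: float
    effective_df: float
    markers_used: np.ndarray  # positions (bp) retained in the fit
    markers_removed: np.ndarray = field(default_factory=lambda: np.array([]))

    def genetic_position(self, pos_bp: float | np.ndarray) -> np.ndarray:
        x = np.clip(np.asarray(pos_bp, float), self.x_min, self.x_max) / 1e6
        return self.spline(x)

    def rate(self, pos_bp: float | np.ndarray) -> np.ndarray:
        """RR (cM/Mb) at physical position(s), clamped at zero."""
        x = np.clip(np.asarray(pos_bp, float), self.x_min, self.x_max) / 1e6
        return np.maximum(self.spline.derivative()(x), 0.0)


@dataclass
class RRProfile:
    """Local recombination rate on a regular physical grid."""

    chrom: str
    positions: np.ndarray  # bp
    rr: np.ndarray  # cM/Mb
    step_bp: int

    def __len__(self) -> int:
        return len(self.positions)


@dataclass(frozen=True)
class PericentromericRegion:
    """Contiguous low-RR span containing the centromere (1-based bp)."""

    chrom: str
    start: int
    end: int
    threshold: float

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def contains(self, pos: float) -> bool:
        return self.start <= pos <= self.end


# ---------------------------------------------------------------------------
# Spline fitting with an effective-df target
# ---------------------------------------------------------------------------

def _effective_df(x: np.ndarray, lam: float) -> float:
    """Trace of the smoother matrix: sum over unit-response fits."""
    n = len(x)
    tr = 0.0
    e = np.zeros(n)
    for i in range(n):
        e[i] = 1.0
        tr += float(make_smoothing_spline(x, e, lam=lam)(x[i]))
        e[i] = 0.0
    return tr


def _calibrate_lambda(x: np.ndarray, target_df: float) -> tuple[float, float]:
    """Bisection on log10(lambda) so that effective df matches the target."""
    n = len(x)
    target = min(max(target_df, 2.0), n - 0.5)
    lo, hi = -10.0, 8.0  # df decreases with lambda
    df_lo = _effective_df(x, 10.0 ** lo)
    df_hi = _effective_df(x, 10.0 ** hi)
    if target >= df_lo:
        return 10.0 ** lo, df_lo
    if target <= df_hi:
        return 10.0 ** hi, df_hi
    for _ in range(40):
        mid = 0.5 * (lo + hi)
        df_mid = _effective_df(x, 10.0 ** mid)
        if df_mid > target:
            lo = mid
        else:
            hi = mid
        if abs(df_mid - target) < 1e-3:
            return 10.0 ** mid, df_mid
    mid = 0.5 * (lo + hi)
    return 10.0 ** mid, _effective_df(x, 10.0 ** mid)


def _dedupe(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Average genetic positions at duplicated physical positions."""
    order = np.argsort(x, kind="stable")
    x, y = x[order], y[order]
    ux, inv = np.unique(x, return_inverse=True)
    uy = np.bincount(inv, weights=y) / np.bincount(inv)
    return ux, uy


def _min_derivative(spl: BSpline, x0: float, x1: float, n_grid: int = 400) -> float:
    grid = np.linspace(x0, x1, n_grid)
    return float(spl.derivative()(grid).min())


def fit_marey(
    gmap: pd.DataFrame,
    chrom: str,
    df: float = 10.0,
    spar: float = 0.05,
    monotone_tol: float = 1e-6,
    max_removed_frac: float = 0.2,
) -> MareyCurve:
    """Fit the Marey curve for one chromosome.

    ``gmap`` is a genetic map table (marker, chrom, pos_bp, pos_cM).  The
    smoothing penalty is calibrated to the target effective df; ``spar`` is
    advisory only (the df target is binding) and is recorded for
    provenance.  Needs at least 5 markers.
    """
    sub = gmap[gmap["chrom"] == chrom]
    x_bp = sub["pos_bp"].to_numpy(float)
    y = sub["pos_cM"].to_numpy(float)
    x, y = _dedupe(x_bp / 1e6, y)  # fit in Mb so the derivative is cM/Mb
    if len(x) < 5:
        raise MareyError(f"chromosome {chrom!r}: need >= 5 markers, got {len(x)}")
    lam, eff_df = _calibrate_lambda(x, df)
    removed: list[float] = []
    max_removed = max(1, int(max_removed_frac * len(x)))
    while True:
        spl = make_smoothing_spline(x, y, lam=lam)
        if _min_derivative(spl, x[0], x[-1]) >= -monotone_tol:
            break
        if len(removed) >= max_removed or len(x) <= 5:
            warnings.warn(
                f"chromosome {chrom!r}: monotonicity cleaning hit its removal "
                "cap; derivative will be clamped at 0",
                UserWarning, stacklevel=2,
            )
            break
        # remove the marker whose deletion most raises the minimum derivative
        best_j, best_min = -1, -math.inf
        for j in range(len(x)):
            xs = np.delete(x, j)
            ys = np.delete(y, j)
            trial = make_smoothing_spline(xs, ys, lam=lam)
            m = _min_derivative(trial, xs[0], xs[-1])
            if m > best_min:
                best_min, best_j = m, j
        removed.append(float(x[best_j] * 1e6))
        x = np.delete(x, best_j)
        y = np.delete(y, best_j)
    return MareyCurve(
        chrom=str(chrom), spline=spl,
        x_min=float(x[0] * 1e6), x_max=float(x[-1] * 1e6),
        lam=lam, effective_df=eff_df,
        markers_used=x * 1e6, markers_removed=np.asarray(removed),
    )


def fit_all_chromosomes(gmap: pd.DataFrame, **kwargs) -> dict[str, MareyCurve]:
    return {
        str(c): fit_marey(gmap, c, **kwargs)
        for c in dict.fromkeys(gmap["chrom"])
    }


# ---------------------------------------------------------------------------
# RR evaluation
# ---------------------------------------------------------------------------

def rr_at(curve: MareyCurve, position: float, layout: GenomeLayout | None = None) -> float:
    """Local recombination rate (cM/Mb) at one physical position."""
    if layout is not None and not layout.contains(curve.chrom, int(position), int(position)):
        raise MareyError(f"position {position} outside chromosome {curve.chrom!r}")
    if position < 1:
        raise MareyError(f"position {position} < 1")
    return float(curve.rate(position))


def rr_grid(
    curve: MareyCurve,
    chrom_length: int,
    step_bp: int = 500_000,
) -> RRProfile:
    """RR on a regular grid of bin midpoints (default every 500 kb)."""
    positions = np.arange(step_bp / 2, chrom_length, step_bp)
    return RRProfile(
        chrom=curve.chrom,
        positions=positions,
        rr=curve.rate(positions),
        step_bp=step_bp,
    )


def integrate_rr(profile: RRProfile) -> float:
    """Trapezoidal integral of RR over the grid, in cM."""
    return float(np.trapezoid(profile.rr, profile.positions / 1e6))


# ---------------------------------------------------------------------------
# Pericentromere detection
# ---------------------------------------------------------------------------

def detect_pericentromere(
    profile: RRProfile, centromere: int, rho: float = 0.2
) -> PericentromericRegion | None:
    """Maximal contiguous low-RR run (RR <= rho) containing the centromere.

    Returns ``None`` when the rate at the centromere exceeds the threshold.
    Span endpoints are the outer edges of the first/last qualifying grid
    bins.
    """
    low = profile.rr <= rho
    if not low.any():
        return None
    half = profile.step_bp / 2
    # index of the grid bin containing the centromere
    k = int(np.clip(np.searchsorted(profile.positions + half, centromere), 0, len(low) - 1))
    if not low[k]:
        return None
    i = k
    while i > 0 and low[i - 1]:
        i -= 1
    j = k
    while j < len(low) - 1 and low[j + 1]:
        j += 1
    start = max(1, int(profile.positions[i] - half) + 1)
    end = int(profile.positions[j] + half)
    return PericentromericRegion(profile.chrom, start, end, rho)


# ---------------------------------------------------------------------------
# RR-based comparisons
# ---------------------------------------------------------------------------

def rr_event_association(
    events: list[IntrogressionEvent],
    curves: dict[str, MareyCurve],
    size_class_edges_mb: tuple[float, ...] = (0.25, 0.5, 1.0),
) -> dict:
    """Midpoint RR per event, grouped into size classes, with a rank test.

    Returns the per-event table, the per-class RR samples, and the
    Kruskal-Wallis H and p over classes with at least one event (classes
    with zero events are dropped with a warning).
    """
    rows = []
    edges = np.asarray(size_class_edges_mb, float)
    for ev in events:
        rr = float(curves[ev.chrom].rate(ev.midpoint))
        size_mb = ev.size / 1e6
        rows.append(
            {
                "event_id": ev.event_id, "chrom": ev.chrom,
                "size_mb": size_mb, "midpoint": ev.midpoint, "rr": rr,
                "size_class": int(np.digitize(size_mb, edges)),
            }
        )
    table = pd.DataFrame(rows)
    groups = [
        grp["rr"].to_numpy() for _, grp in table.groupby("size_class", sort=True)
    ]
    n_classes_expected = len(edges) + 1
    if len(groups) < n_classes_expected:
        warnings.warn(
            f"{n_classes_expected - len(groups)} size class(es) with zero "
            "events dropped from the rank test",
            UserWarning, stacklevel=2,
        )
    if len(groups) < 2 or all(np.ptp(np.concatenate(groups)) == 0 for _ in [0]):
        stat, p = 0.0, 1.0
    else:
        try:
            stat, p = stats.kruskal(*groups)
        except ValueError:  # all values identical
            stat, p = 0.0, 1.0
    return {"events": table, "H": float(stat), "p": float(p)}


def compare_maps(
    rr_a: np.ndarray, rr_b: np.ndarray, alternative: str = "less"
) -> dict:
    """Paired signed-rank test of RR profile A against profile B.

    ``alternative='less'`` tests whether A is systematically below B at the
    paired positions.  Zero differences are handled by the zero-split rule;
    an all-tie input returns p = 1 with a degenerate flag.
    """
    rr_a = np.asarray(rr_a, float)
    rr_b = np.asarray(rr_b, float)
    if len(rr_a) != len(rr_b):
        raise MareyError("profiles must be evaluated at the same positions")
    if len(rr_a) < 5:
        raise MareyError(f"need >= 5 paired positions, got {len(rr_a)}")
    diffs = rr_a - rr_b
    if np.all(diffs == 0):
        return {"statistic": math.nan, "p": 1.0, "n": len(diffs), "degenerate": True}
    if np.any(diffs == 0):
        # zero differences: split their ranks between the two sides
        res = stats.wilcoxon(rr_a, rr_b, alternative=alternative, zero_method="zsplit")
    else:
        # exact null distribution when feasible; tie-corrected normal
        # approximation for larger samples
        method = "exact" if len(diffs) <= 25 else "auto"
        res = stats.wilcoxon(rr_a, rr_b, alternative=alternative, method=method)
    return {
        "statistic": float(res.statistic), "p": float(res.pvalue),
        "n": len(diffs), "degenerate": False,
    }


def pericentromere_enrichment(
    large_events: list[IntrogressionEvent],
    pericentromeres: dict[str, PericentromericRegion | None],
    layout: GenomeLayout,
) -> dict:
    """Goodness-of-fit test for large events concentrating near centromeres.

    Observed = events whose midpoint falls inside the pericentromere of
    their chromosome; expected counts are proportional to the
    pericentromeric fraction of total genome length.  2 cells, df = 1.
    """
    if not large_events:
        raise MareyError("no events at or above the size cutoff")
    peri_len = sum(
        r.length for r in pericentromeres.values() if r is not None
    )
    frac = peri_len / layout.total_length
    n = len(large_events)
    obs_in = sum(
        1
        for ev in large_events
        if (r := pericentromeres.get(ev.chrom)) is not None and r.contains(ev.midpoint)
    )
    obs = np.array([obs_in, n - obs_in], float)
    exp = np.array([n * frac, n * (1 - frac)], float)
    if (exp < 1).any():
        warnings.warn(
            "expected cell below 1; chi-square approximation is unreliable",
            UserWarning, stacklevel=2,
        )
    chi2 = float(((obs - exp) ** 2 / exp).sum())
    return {
        "chi2": chi2, "df": 1, "p": float(stats.chi2.sf(chi2, 1)),
        "observed_inside": int(obs_in), "n_events": n,
        "expected_inside": float(exp[0]),
        "pericentromeric_fraction": float(frac),
    }
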