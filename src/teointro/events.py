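"""Calling discrete introgression events from the f_d window scan.

Windows in the upper tail of the genome-wide f_d distribution (top 1% and
top 10% by default) are flagged as positive for introgression; maximal runs
of index-adjacent flagged windows on a chromosome are concatenated into
events.  Event spans run from the first member window's start to the last
member's end, so inter-window gaps inside an event count toward its size.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .layout import GenomeLayout

__all__ = [
    "flag_outliers", "outlier_threshold", "concatenate_events",
    "summarize_events", "IntrogressionEvent", "SIZE_CLASS_EDGES_MB",
]

#: histogram bins for event sizes: [0, 0.5), [0.5, 1), [1, inf) Mb
SIZE_CLASS_EDGES_MB = (0.5, 1.0)


@dataclass(frozen=True)
class IntrogressionEvent:
    """A maximal run of adjacent outlier f_d windows (1-based inclusive span)."""

    event_id: str
    chrom: str
    start: int
    end: int
    n_windows: int
    mean_fd: float
    max_fd: float
    tier: float  # the outlier fraction q used to flag the member windows

    @property
    def size(self) -> int:
        return self.end - self.start + 1

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.start + self.end)


def outlier_threshold(fd: np.ndarray, q: float) -> float:
    """Upper-tail threshold: the (floor((1-q) n) + 1)-th smallest f_d.

    This nearest-rank rule flags exactly the ceil(q*n) largest values when
    all values are distinct; ties at the threshold are all included.
    """
    if not 0 < q < 0.5:
        raise ValueError(f"outlier fraction q must be in (0, 0.5), got {q}")
    fd = np.sort(np.asarray(fd, float))
    n = len(fd)
    if n == 0:
        raise ValueError("no windows")
    rank = min(int(math.floor((1 - q) * n)), n - 1)
    return float(fd[rank])


def flag_outliers(windows: pd.DataFrame, q: float) -> pd.DataFrame:
    """Return a copy of the window table with an ``outlier`` flag column."""
    thr = outlier_threshold(windows["fd"].to_numpy(), q)
    out = windows.copy()
    out["outlier"] = out["fd"].to_numpy() >= thr
    out.attrs["threshold"] = thr
    out.attrs["q"] = q
    return out


def concatenate_events(
    flagged: pd.DataFrame, q: float | None = None, max_gap_windows: int = 0
) -> list[IntrogressionEvent]:
    """Concatenate runs of adjacent flagged windows into events.

    Adjacency means consecutive per-chromosome window indices; a gap of up
    to ``max_gap_windows`` intervening non-outlier windows may be bridged
    (default 0: any non-outlier window breaks the event).
    """
    if q is None:
        q = flagged.attrs.get("q", float("nan"))
    events: list[IntrogressionEvent] = []
    counter = 0
    for chrom, grp in flagged.groupby("chrom", sort=False):
        grp = grp.sort_values("window")
        run: list[pd.Series] = []
        last_idx: int | None = None
        for _, row in grp[grp["outlier"]].iterrows():
            idx = int(row["window"])
            if last_idx is not None and idx - last_idx <= 1 + max_gap_windows:
                run.append(row)
            else:
                if run:
                    counter += 1
                    events.append(_make_event(run, chrom, q, counter))
                run = [row]
            last_idx = idx
        if run:
            counter += 1
            events.append(_make_event(run, chrom, q, counter))
    return events


def _make_event(run: list[pd.Series], chrom: str, q: float, counter: int) -> IntrogressionEvent:
    fds = [float(r["fd"]) for r in run]
    return IntrogressionEvent(
        event_id=f"event_{counter}",
        chrom=str(chrom),
        start=int(run[0]["start"]),
        end=int(run[-1]["end"]),
        n_windows=len(run),
        mean_fd=float(np.mean(fds)),
        max_fd=float(np.max(fds)),
        tier=q,
    )


def summarize_events(
    events: list[IntrogressionEvent],
    layout: GenomeLayout,
    size_class_edges_mb: tuple[float, ...] = SIZE_CLASS_EDGES_MB,
) -> dict:
    """Per-chromosome and total event counts, sizes and genome coverage.

    Returns a dict with keys ``per_chromosome`` (DataFrame: chrom, n_events,
    total_size_bp, pct_of_chromosome, pct_of_total_event_size), ``total``
    (n_events, total_size_bp, pct_of_genome) and ``size_class_counts``
    (histogram over [0, e1), [e1, e2), ..., [ek, inf) Mb).
    """
    for ev in events:
        layout.check_interval(ev.chrom, ev.start, ev.end, what=f"event {ev.event_id}")
    total_size = sum(ev.size for ev in events)
    rows = []
    for chrom in layout.chromosomes:
        evs = [e for e in events if e.chrom == chrom]
        size = sum(e.size for e in evs)
        rows.append(
            {
                "chrom": chrom,
                "n_events": len(evs),
                "total_size_bp": size,
                "pct_of_chromosome": 100.0 * size / layout.lengths[chrom],
                "pct_of_total_event_size": (
                    100.0 * size / total_size if total_size else 0.0
                ),
            }
        )
    per_chrom = pd.DataFrame(rows)
    edges_bp = [e * 1e6 for e in size_class_edges_mb]
    bins = [0.0, *edges_bp, math.inf]
    counts, _ = np.histogram([ev.size for ev in events], bins=bins)
    labels = (
        [f"<{size_class_edges_mb[0]} Mb"]
        + [
            f"{a}-{b} Mb"
            for a, b in zip(size_class_edges_mb, size_class_edges_mb[1:])
        ]
        + [f">={size_class_edges_mb[-1]} Mb"]
    )
    return {
        "per_chromosome": per_chrom,
        "total": {
            "n_events": len(events),
            "total_size_bp": int(total_size),
            "pct_of_genome": 100.0 * total_size / layout.total_length,
        },
        "size_class_counts": dict(zip(labels, counts.tolist())),
    }
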