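"""Gene-level context of introgression events: overlap, density, enrichment.

Covers gene/event interval overlap (any-overlap, >= 1 bp), the cumulative
gene-density expectation under a uniform spatial distribution, F_ST and
gene-list enrichment (continuity-corrected chi-square and rank-sum tests),
and SNP fixation-pattern classification across taxa.

The continuity correction subtracts min(0.5, |O - E|) from each |O - E|
deviation, so a perfectly proportional table yields exactly 0 — unlike the
plain Yates correction, which can go negative-in-spirit at O = E.
"""

from __future__ import annotations

import warnings
from collections import Counter
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from .events import IntrogressionEvent
from .layout import GeneModel, GenomeLayout

__all__ = [
    "overlap_genes", "cumulative_density", "contingency_enrichment",
    "corrected_chi2_from_counts", "fst_compare", "classify_fixation",
    "pattern_crosstab", "candidate_list_overlap",
]

EFFECT_CLASSES = ("high", "moderate", "low", "modifier")
FIXATION_STATUSES = ("fixed_alt", "fixed_ref", "segregating", "not_called")


class AnnotationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Interval overlap
# ---------------------------------------------------------------------------

def _event_trees(events: Iterable[IntrogressionEvent]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for ev in events:
        # IntervalTree is half-open; +1 converts the inclusive end
        trees.setdefault(ev.chrom, IntervalTree()).addi(ev.start, ev.end + 1)
    return trees


def overlap_genes(
    events: Iterable[IntrogressionEvent],
    genes: Sequence[GeneModel],
    mode: str = "any",
) -> pd.DataFrame:
    """Flag each gene as inside/outside the event set.

    ``mode='any'``: a gene is inside if its span intersects any event span
    by at least 1 bp (both 1-based inclusive).  ``mode='midpoint'``
    requires the gene midpoint to fall inside an event.
    """
    if mode not in ("any", "midpoint"):
        raise AnnotationError(f"unknown overlap mode {mode!r}")
    trees = _event_trees(events)
    rows = []
    for g in genes:
        tree = trees.get(g.chrom)
        if tree is None:
            inside = False
        elif mode == "any":
            inside = bool(tree.overlap(g.start, g.end + 1))
        else:
            inside = bool(tree.at(g.midpoint))
        rows.append({"gene_id": g.gene_id, "chrom": g.chrom, "inside": inside})
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "inside"])


def genes_in_event(event: IntrogressionEvent, genes: Sequence[GeneModel]) -> int:
    return sum(
        1
        for g in genes
        if g.chrom == event.chrom and g.start <= event.end and g.end >= event.start
    )


# ---------------------------------------------------------------------------
# Cumulative gene density
# ---------------------------------------------------------------------------

def cumulative_density(
    events: Sequence[IntrogressionEvent],
    genes: Sequence[GeneModel],
    layout: GenomeLayout,
) -> pd.DataFrame:
    """Observed vs expected cumulative gene count over size-ordered events.

    Events are ordered by increasing size; the expectation at cumulative
    physical size S is S * (total genes / genome size), i.e. a uniform
    spatial gene distribution.
    """
    ordered = sorted(events, key=lambda e: e.size)
    density = len(genes) / layout.total_length
    rows = []
    cum_size = 0
    cum_genes = 0
    for ev in ordered:
        cum_size += ev.size
        cum_genes += genes_in_event(ev, genes)
        rows.append(
            {
                "event_id": ev.event_id,
                "size_bp": ev.size,
                "cumulative_size_bp": cum_size,
                "observed_cumulative_genes": cum_genes,
                "expected_cumulative_genes": cum_size * density,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Contingency enrichment
# ---------------------------------------------------------------------------

def contingency_enrichment(table: np.ndarray) -> dict:
    """Continuity-corrected Pearson chi-square for a 2x2 table.

    Each cell contributes (|O - E| - min(0.5, |O - E|))^2 / E with E the
    product-of-marginals expectation; df = 1, upper-tail p.  All marginals
    must be positive.
    """
    table = np.asarray(table, float)
    if table.shape != (2, 2):
        raise AnnotationError(f"need a 2x2 table, got shape {table.shape}")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise AnnotationError("zero marginal in contingency table")
    n = table.sum()
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / n
    dev = np.abs(table - expected)
    corrected = dev - np.minimum(0.5, dev)
    chi2 = float((corrected**2 / expected).sum())
    return {"chi2": chi2, "df": 1, "p": float(stats.chi2.sf(chi2, 1))}


def corrected_chi2_from_counts(
    labeled_inside: int, labeled_total: int, all_inside: int, all_total: int
) -> dict:
    """Enrichment test for a labeled gene subset against the full gene set.

    Builds the 2x2 table (labeled vs unlabeled) x (inside vs outside
    events) from the four summary counts and applies
    :func:`contingency_enrichment`.
    """
    table = np.array(
        [
            [labeled_inside, labeled_total - labeled_inside],
            [
                all_inside - labeled_inside,
                (all_total - labeled_total) - (all_inside - labeled_inside),
            ],
        ]
    )
    out = contingency_enrichment(table)
    out["proportion_labeled_inside"] = labeled_inside / labeled_total
    out["proportion_all_inside"] = all_inside / all_total
    return out


# ---------------------------------------------------------------------------
# F_ST comparison
# ---------------------------------------------------------------------------

def fst_compare(
    membership: pd.DataFrame,
    fst: Mapping[str, float],
    per_chromosome: bool = True,
    min_group: int = 3,
) -> pd.DataFrame:
    """Rank-sum comparison of per-gene F_ST inside vs outside events.

    ``membership`` is the output of :func:`overlap_genes`; ``fst`` maps
    gene id to its F_ST.  Every gene in the comparison must have an F_ST.
    Rows: genome-wide plus (optionally) one per chromosome; comparisons
    with fewer than ``min_group`` genes on either side are skipped.
    """
    df = membership.copy()
    missing = [g for g in df["gene_id"] if g not in fst]
    if missing:
        raise AnnotationError(
            f"{len(missing)} genes lack an F_ST value (first: {missing[0]!r})"
        )
    df["fst"] = [fst[g] for g in df["gene_id"]]
    scopes = [("genome", df)]
    if per_chromosome:
        scopes += [(str(c), grp) for c, grp in df.groupby("chrom", sort=False)]
    rows = []
    for scope, grp in scopes:
        inside = grp.loc[grp["inside"], "fst"].to_numpy()
        outside = grp.loc[~grp["inside"], "fst"].to_numpy()
        if len(inside) < min_group or len(outside) < min_group:
            warnings.warn(
                f"{scope}: fewer than {min_group} genes on one side; skipped",
                UserWarning, stacklevel=2,
            )
            continue
        if np.ptp(np.concatenate([inside, outside])) == 0:
            # tie-degenerate: every gene shares one F_ST value
            stat, p = float("nan"), 1.0
        else:
            stat, p = stats.mannwhitneyu(inside, outside, alternative="two-sided")
        rows.append(
            {
                "scope": scope,
                "n_inside": len(inside), "n_outside": len(outside),
                "median_inside": float(np.median(inside)),
                "median_outside": float(np.median(outside)),
                "statistic": float(stat), "p": float(p),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Fixation patterns
# ---------------------------------------------------------------------------

def classify_fixation(calls: Sequence[int | None]) -> str:
    """Classify a group's diploid calls at one SNP.

    ``calls`` holds alternate-allele dosages (0, 1, 2) or ``None`` for
    uncalled individuals.  fixed_alt: every called genotype is homozygous
    alternate; fixed_ref: every called genotype is homozygous reference;
    segregating: both alleles observed; not_called: no calls at all.
    """
    called = [c for c in calls if c is not None]
    if not called:
        return "not_called"
    if all(c == 2 for c in called):
        return "fixed_alt"
    if all(c == 0 for c in called):
        return "fixed_ref"
    return "segregating"


def pattern_crosstab(
    records: pd.DataFrame,
    group_columns: Sequence[str] = ("lowland", "mexicana", "parviglumis", "tripsacum"),
    effect_classes: Sequence[str] = ("high", "moderate"),
    min_count: int = 25,
    require_highland_fixed_alt: bool = True,
) -> dict:
    """Cross-tabulate joint fixation patterns of highland-fixed SNPs.

    ``records`` needs columns ``effect`` and ``highland`` plus one status
    column per non-highland group.  SNPs are restricted to the chosen
    effect classes and (by default) to those fixed for the alternate allele
    in highland maize; counts <= ``min_count`` are suppressed from the
    displayed table but retained in the full one.
    """
    df = records[records["effect"].isin(effect_classes)]
    if require_highland_fixed_alt:
        df = df[df["highland"] == "fixed_alt"]
    counts = Counter(tuple(row) for row in df[list(group_columns)].to_numpy())
    full = pd.DataFrame(
        [dict(zip(group_columns, k), count=v) for k, v in counts.items()]
    )
    if len(full):
        full = full.sort_values("count", ascending=False).reset_index(drop=True)
        displayed = full[full["count"] > min_count].reset_index(drop=True)
    else:
        displayed = full
    return {"full": full, "displayed": displayed, "n_snps": int(len(df))}


# ---------------------------------------------------------------------------
# Candidate gene lists
# ---------------------------------------------------------------------------

def candidate_list_overlap(
    membership: pd.DataFrame, candidates: Sequence[str]
) -> dict:
    """Proportion of a candidate gene list inside events, with enrichment.

    Candidate identifiers not present in the gene table are reported and
    excluded.  The chi-square contrasts candidates against all remaining
    genes (continuity-corrected, df = 1).
    """
    if len(candidates) == 0:
        raise AnnotationError("empty candidate list")
    known = set(membership["gene_id"])
    resolved = [c for c in candidates if c in known]
    unresolved = [c for c in candidates if c not in known]
    if not resolved:
        raise AnnotationError("no candidate identifiers resolve against the gene table")
    is_cand = membership["gene_id"].isin(set(resolved)).to_numpy()
    inside = membership["inside"].to_numpy()
    table = np.array(
        [
            [int((is_cand & inside).sum()), int((is_cand & ~inside).sum())],
            [int((~is_cand & inside).sum()), int((~is_cand & ~inside).sum())],
        ]
    )
    test = contingency_enrichment(table)
    return {
        "n_candidates": len(resolved),
        "n_unresolved": len(unresolved),
        "unresolved": unresolved,
        "n_inside": int(table[0, 0]),
        "proportion_inside": table[0, 0] / len(resolved),
        "genomewide_proportion": float(inside.mean()),
        **test,
    }
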