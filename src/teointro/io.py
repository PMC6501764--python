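"""Readers and writers for the tabular formats the pipeline touches.

Formats
-------
* site table TSV — per-site derived-allele counts for the four taxa
  (columns ``chrom pos p1_der p1_tot p2_der p2_tot p3_der p3_tot o_der o_tot``)
* GFF3 gene annotations (only ``gene`` records are used)
* BED for called introgression events (0-based half-open at the boundary)
* ABH CSV for F2 genotype matrices, with ``chrom``/``pos`` metadata rows
* genetic map TSV (``marker chrom pos_bp pos_cM``)

Internal coordinates are 1-based inclusive throughout; BED conversion is
performed only here.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Sequence

import numpy as np
import pandas as pd

from .layout import GeneModel, GenomeLayout, LayoutError, sort_genes

if TYPE_CHECKING:  # pragma: no cover
    from .events import IntrogressionEvent

SITE_COLUMNS = [
    "chrom", "pos",
    "p1_der", "p1_tot", "p2_der", "p2_tot",
    "p3_der", "p3_tot", "o_der", "o_tot",
]

TAXA = ("p1", "p2", "p3", "o")

ABH_ALPHABET = frozenset({"A", "B", "H", "-"})
MISSING = "-"


class ParseError(ValueError):
    """Malformed or invariant-violating input."""


# ---------------------------------------------------------------------------
# Site frequency tables
# ---------------------------------------------------------------------------

@dataclass
class SiteFrequencyTable:
    """Per-site derived-allele counts for the quartet (((P1,P2),P3),O).

    ``data`` is a DataFrame with :data:`SITE_COLUMNS`; a taxon with called
    total 0 at a site is missing there, and the site is unusable for D/f_d.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        missing_cols = [c for c in SITE_COLUMNS if c not in df.columns]
        if missing_cols:
            raise ParseError(f"site table missing columns: {missing_cols}")
        self.data = df = df.loc[:, SITE_COLUMNS].reset_index(drop=True)
        if (df["pos"] < 1).any():
            row = int(df.index[df["pos"] < 1][0])
            raise ParseError(f"row {row}: position < 1")
        for taxon in TAXA:
            der, tot = df[f"{taxon}_der"], df[f"{taxon}_tot"]
            bad = (der < 0) | (tot < 0) | (der > tot)
            if bad.any():
                row = int(df.index[bad][0])
                raise ParseError(
                    f"row {row}: {taxon} derived count outside [0, total]"
                )
        dup = df.duplicated(subset=["chrom", "pos"])
        if dup.any():
            row = int(df.index[dup][0])
            raise ParseError(f"row {row}: duplicate (chrom, pos)")
        # sorted by position within each chromosome, chromosomes contiguous
        chrom = df["chrom"].to_numpy()
        pos = df["pos"].to_numpy()
        seen: set[str] = set()
        last: str | None = None
        for i in range(len(df)):
            c = chrom[i]
            if c != last:
                if c in seen:
                    raise ParseError(
                        f"row {i}: chromosome {c!r} rows are not contiguous"
                    )
                seen.add(c)
                last = c
            elif pos[i] <= pos[i - 1]:
                raise ParseError(
                    f"row {i}: positions not strictly increasing on {c!r}"
                )

    def __len__(self) -> int:
        return len(self.data)

    @property
    def chromosomes(self) -> list[str]:
        return list(dict.fromkeys(self.data["chrom"]))

    def frequencies(self) -> pd.DataFrame:
        """Per-site derived-allele frequencies; NaN where a taxon is missing."""
        out = self.data[["chrom", "pos"]].copy()
        for taxon in TAXA:
            tot = self.data[f"{taxon}_tot"].to_numpy(float)
            der = self.data[f"{taxon}_der"].to_numpy(float)
            with np.errstate(invalid="ignore", divide="ignore"):
                out[taxon] = np.where(tot > 0, der / np.where(tot > 0, tot, 1), np.nan)
        return out


def read_site_table(path: str | os.PathLike) -> SiteFrequencyTable:
    try:
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    except Exception as exc:  # noqa: BLE001 - re-raise with context
        raise ParseError(f"cannot parse site table {path}: {exc}") from exc
    for col in SITE_COLUMNS[1:]:
        if col in df.columns and not pd.api.types.is_integer_dtype(df[col]):
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = coerced.isna() | (coerced != coerced.round())
            if bad.any():
                raise ParseError(
                    f"{path}: line {int(df.index[bad][0]) + 2}: non-integer value in {col}"
                )
            df[col] = coerced.astype(int)
    try:
        return SiteFrequencyTable(df)
    except ParseError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def write_site_table(table: SiteFrequencyTable, path: str | os.PathLike) -> None:
    table.data.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# GFF3 gene models
# ---------------------------------------------------------------------------

def read_gff3_genes(
    path: str | os.PathLike, layout: GenomeLayout | None = None
) -> list[GeneModel]:
    """Read ``gene`` records from a GFF3 file as :class:`GeneModel` objects.

    Only records of type ``gene`` are used; coordinates are kept 1-based
    inclusive and the result is sorted by (chromosome, start).
    """
    import gffutils

    if os.path.getsize(path) == 0:
        return []
    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", force=True,
        keep_order=True,
    )
    genes: list[GeneModel] = []
    for feat in db.features_of_type("gene"):
        ids = feat.attributes.get("ID")
        if not ids:
            raise ParseError(
                f"{path}: gene at {feat.seqid}:{feat.start}-{feat.end} lacks ID"
            )
        genes.append(GeneModel(ids[0], str(feat.seqid), int(feat.start), int(feat.end)))
    genes = sort_genes(genes)
    if layout is not None:
        for g in genes:
            if not layout.contains(g.chrom, g.start, g.end):
                raise ParseError(f"{path}: gene {g.gene_id} outside genome layout")
    return genes


def write_gff3_genes(genes: Sequence[GeneModel], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in sort_genes(genes):
            fh.write(
                f"{g.chrom}\tteointro\tgene\t{g.start}\t{g.end}\t.\t+\t.\tID={g.gene_id}\n"
            )


# ---------------------------------------------------------------------------
# Events BED
# ---------------------------------------------------------------------------

def write_events_bed(
    events: Sequence["IntrogressionEvent"], path: str | os.PathLike
) -> None:
    """Write events as BED (0-based half-open); score = mean window f_d x 1000.

    Events must be sorted and non-overlapping per chromosome.
    """
    by_chrom: dict[str, list] = {}
    for ev in events:
        by_chrom.setdefault(ev.chrom, []).append(ev)
    for chrom, evs in by_chrom.items():
        for a, b in zip(evs, evs[1:]):
            if b.start <= a.end:
                raise ParseError(
                    f"overlapping or unsorted events on {chrom}: "
                    f"{a.start}-{a.end} then {b.start}-{b.end}"
                )
    with open(path, "w") as fh:
        for ev in events:
            score = int(min(1000, max(0, round(ev.mean_fd * 1000))))
            fh.write(f"{ev.chrom}\t{ev.start - 1}\t{ev.end}\t{ev.event_id}\t{score}\n")


def read_events_bed(path: str | os.PathLike) -> pd.DataFrame:
    """Read an events BED back to 1-based inclusive spans."""
    if os.path.getsize(path) == 0:
        return pd.DataFrame(columns=["chrom", "start", "end", "name", "score"])
    df = pd.read_csv(
        path, sep="\t", header=None,
        names=["chrom", "start", "end", "name", "score"],
        dtype={"chrom": str},
    )
    df["start"] = df["start"].astype(int) + 1
    df["end"] = df["end"].astype(int)
    return df


# ---------------------------------------------------------------------------
# F2 genotype matrices (ABH coding)
# ---------------------------------------------------------------------------

@dataclass
class F2GenotypeMatrix:
    """Individuals x markers F2 genotype calls in ABH coding.

    ``calls`` holds single characters from ``{A, B, H, -}`` (``-`` missing);
    A is homozygous parent-1 (highland PT), B homozygous parent-2 (lowland
    RV), H heterozygous.  Markers are sorted by (chromosome, position).
    """

    calls: np.ndarray  # (n_ind, n_mark) of '<U1'
    markers: list[str]
    chrom: np.ndarray  # (n_mark,) str
    pos: np.ndarray  # (n_mark,) int, bp
    individuals: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype="<U1")
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=int)
        n_ind, n_mark = self.calls.shape
        if not self.individuals:
            self.individuals = [f"ind{i + 1}" for i in range(n_ind)]
        if len(self.markers) != n_mark or len(self.chrom) != n_mark or len(self.pos) != n_mark:
            raise ParseError("marker metadata length mismatch")
        if len(self.individuals) != n_ind:
            raise ParseError("individual id length mismatch")
        bad = ~np.isin(self.calls, list(ABH_ALPHABET))
        if bad.any():
            i, j = map(int, np.argwhere(bad)[0])
            raise ParseError(
                f"invalid genotype symbol {self.calls[i, j]!r} for individual "
                f"{self.individuals[i]!r} at marker {self.markers[j]!r}"
            )
        order = np.lexsort((self.pos, np.asarray([str(c) for c in self.chrom])))
        if not np.array_equal(order, np.arange(n_mark)):
            raise ParseError("markers must be sorted by (chromosome, position)")

    @property
    def n_individuals(self) -> int:
        return self.calls.shape[0]

    @property
    def n_markers(self) -> int:
        return self.calls.shape[1]

    @property
    def chromosomes(self) -> list[str]:
        return list(dict.fromkeys(self.chrom))

    def marker_index(self, chrom: str) -> np.ndarray:
        return np.flatnonzero(np.asarray(self.chrom) == chrom)

    def class_proportions(self) -> pd.DataFrame:
        """Per-marker proportions of A/B/H among called individuals."""
        called = self.calls != MISSING
        n_called = called.sum(axis=0)
        rows = {}
        for sym in "ABH":
            with np.errstate(invalid="ignore"):
                rows[sym] = np.where(
                    n_called > 0, (self.calls == sym).sum(axis=0) / np.maximum(n_called, 1), np.nan
                )
        return pd.DataFrame(rows, index=self.markers).assign(n_called=n_called)

    def subset_markers(self, keep: np.ndarray) -> "F2GenotypeMatrix":
        keep = np.asarray(keep)
        return F2GenotypeMatrix(
            self.calls[:, keep],
            [self.markers[int(k)] for k in keep],
            self.chrom[keep],
            self.pos[keep],
            list(self.individuals),
        )


def read_abh_csv(path: str | os.PathLike) -> F2GenotypeMatrix:
    """Read an ABH genotype CSV.

    Layout: header row of marker names (first cell ``id``), then metadata
    rows ``chrom`` and ``pos``, then one row per individual.  Empty cells,
    ``-``, ``N`` and ``NA`` are treated as missing.
    """
    df = pd.read_csv(path, index_col=0, dtype=str, keep_default_na=False)
    for meta in ("chrom", "pos"):
        if meta not in df.index:
            raise ParseError(f"{path}: metadata row {meta!r} missing")
    chrom = df.loc["chrom"].to_numpy()
    pos_raw = df.loc["pos"]
    try:
        pos = pos_raw.astype(int).to_numpy()
    except ValueError as exc:
        bad = [m for m, v in pos_raw.items() if not str(v).strip().lstrip("-").isdigit()]
        raise ParseError(f"{path}: marker without integer position: {bad[:3]}") from exc
    body = df.drop(index=["chrom", "pos"])
    calls = body.to_numpy(dtype=object)
    norm = np.vectorize(lambda s: MISSING if str(s).strip() in ("", "-", "N", "NA") else str(s).strip())
    calls = norm(calls).astype("<U1") if calls.size else np.empty(body.shape, "<U1")
    try:
        return F2GenotypeMatrix(
            calls, list(df.columns), chrom, pos, list(body.index.astype(str))
        )
    except ParseError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def write_abh_csv(matrix: F2GenotypeMatrix, path: str | os.PathLike) -> None:
    meta = pd.DataFrame(
        [list(matrix.chrom), [str(p) for p in matrix.pos]],
        index=["chrom", "pos"], columns=matrix.markers,
    )
    body = pd.DataFrame(matrix.calls, index=matrix.individuals, columns=matrix.markers)
    out = pd.concat([meta, body])
    out.index.name = "id"
    out.to_csv(path)


# ---------------------------------------------------------------------------
# Genetic map TSV
# ---------------------------------------------------------------------------

def read_genetic_map(path: str | os.PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"marker": str, "chrom": str})
    need = {"marker", "chrom", "pos_bp", "pos_cM"}
    if not need.issubset(df.columns):
        raise ParseError(f"{path}: genetic map must have columns {sorted(need)}")
    return df


def write_genetic_map(gmap: pd.DataFrame, path: str | os.PathLike) -> None:
    gmap.to_csv(path, sep="\t", index=False)
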