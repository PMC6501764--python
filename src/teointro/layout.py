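"""Genome layout and gene-model containers.

All coordinates in this package are 1-based inclusive base pairs, matching
GFF3 and the conventions of maize physical maps.  Conversion to BED's
0-based half-open convention happens only at the file boundary
(:mod:`teointro.io`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence


class LayoutError(ValueError):
    """Raised when coordinates are inconsistent with the genome layout."""


@dataclass(frozen=True)
class GenomeLayout:
    """Ordered chromosomes with physical lengths and centromere positions.

    Parameters
    ----------
    chromosomes
        Chromosome identifiers in genome order.
    lengths
        Physical length of each chromosome in bp.
    centromeres
        Centromere position per chromosome in bp (optional; required only
        for pericentromere detection).
    """

    chromosomes: tuple[str, ...]
    lengths: Mapping[str, int]
    centromeres: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "chromosomes", tuple(self.chromosomes))
        object.__setattr__(self, "lengths", dict(self.lengths))
        object.__setattr__(self, "centromeres", dict(self.centromeres))
        for chrom in self.chromosomes:
            if chrom not in self.lengths:
                raise LayoutError(f"no length given for chromosome {chrom!r}")
            if self.lengths[chrom] <= 0:
                raise LayoutError(f"chromosome {chrom!r} has non-positive length")
        for chrom, pos in self.centromeres.items():
            if chrom not in self.lengths:
                raise LayoutError(f"centromere on unknown chromosome {chrom!r}")
            if not 1 <= pos <= self.lengths[chrom]:
                raise LayoutError(
                    f"centromere of {chrom!r} at {pos} outside [1, {self.lengths[chrom]}]"
                )

    @property
    def total_length(self) -> int:
        return sum(self.lengths[c] for c in self.chromosomes)

    def contains(self, chrom: str, start: int, end: int) -> bool:
        return (
            chrom in self.lengths
            and 1 <= start <= end <= self.lengths[chrom]
        )

    def check_interval(self, chrom: str, start: int, end: int, what: str = "interval") -> None:
        if not self.contains(chrom, start, end):
            raise LayoutError(
                f"{what} {chrom}:{start}-{end} outside genome layout"
            )


@dataclass(frozen=True)
class GeneModel:
    """A gene span on the physical map (1-based inclusive)."""

    gene_id: str
    chrom: str
    start: int
    end: int
    labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise LayoutError(
                f"gene {self.gene_id}: start {self.start} > end {self.end}"
            )
        if self.start < 1:
            raise LayoutError(f"gene {self.gene_id}: start {self.start} < 1")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.start + self.end)


def sort_genes(genes: Iterable[GeneModel]) -> list[GeneModel]:
    """Stable ordering by (chromosome, start) used by all gene readers."""
    return sorted(genes, key=lambda g: (g.chrom, g.start, g.end, g.gene_id))


def validate_genes(genes: Sequence[GeneModel], layout: GenomeLayout) -> None:
    for g in genes:
        layout.check_interval(g.chrom, g.start, g.end, what=f"gene {g.gene_id}")
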