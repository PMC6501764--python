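"""Synthetic inputs with planted truth for every pipeline stage.

The generator emulates the study design end-to-end at desk scale:

* a four-taxon diploid panel — 3 lowland maize (P1), 3 highland maize
  (P2), 2 teosinte *mexicana* (P3), 1 *Tripsacum* outgroup — with
  derived-allele frequencies evolved by bounded drift down the tree
  (((P1, P2), P3), O) and teosinte introgression planted as tracts in
  which the highland population frequency is pulled toward the donor;
* a 170-individual F2 genotyped at ~1,166 markers over 10 chromosomes,
  with crossovers placed as a Poisson process on the genetic scale,
  optional centromere-suppressed recombination, call errors and missingness;
* uniform gene annotations, per-gene F_ST with a tract-linked shift, and
  per-SNP effect classes with highland fixation patterns enriched in
  tracts;
* quantitative traits controlled by known QTL at a stated heritability.

Drift along each branch uses the Balding-Nichols parameterization: the
child frequency is Beta-distributed with mean equal to the parent
frequency and variance F p (1 - p).  This is a bounded-perturbation
approximation chosen for speed and direct control of the planted signal,
not a coalescent.

All generators are pure functions of their scenario and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .io import F2GenotypeMatrix, SiteFrequencyTable
from .layout import GeneModel, GenomeLayout, LayoutError

__all__ = [
    "Scenario", "Tract", "TruthSet", "default_layout",
    "simulate_sitefreq", "simulate_f2", "simulate_annotation",
    "simulate_trait", "true_map_table",
]


@dataclass(frozen=True)
class Tract:
    """A planted introgression tract: P2 receives donor ancestry at rate f."""

    chrom: str
    start: int
    end: int
    f: float

    def __post_init__(self) -> None:
        if not 0 <= self.f <= 1:
            raise LayoutError(f"tract donor fraction f = {self.f} outside [0, 1]")
        if self.start > self.end:
            raise LayoutError("tract start > end")


@dataclass
class Scenario:
    """Study conditions for the four-taxon site-frequency simulation.

    Defaults mirror the study panel: allele counts 6/6/4/2 (three lowland,
    three highland, two *mexicana* diploids and one *Tripsacum*), with
    branch drift strong enough that a realistic fraction of sites is
    ABBA/BABA-informative.
    """

    layout: GenomeLayout
    site_density_per_mb: float = 1300.0
    panel_sizes: tuple[int, int, int, int] = (3, 3, 2, 1)  # diploids per taxon
    drift_root_to_p12: float = 0.10
    drift_root_to_p3: float = 0.40
    drift_p12_to_p1: float = 0.05
    drift_p12_to_p2: float = 0.05
    drift_donor: float = 0.02  # drift of the introgressing haplotype off P3
    outgroup_polymorphic_rate: float = 0.0
    sfs_beta: tuple[float, float] = (0.4, 1.2)  # ancestral frequency law
    tracts: tuple[Tract, ...] = ()

    def __post_init__(self) -> None:
        self.tracts = tuple(self.tracts)
        by_chrom: dict[str, list[Tract]] = {}
        for t in self.tracts:
            self.layout.check_interval(t.chrom, t.start, t.end, what="tract")
            by_chrom.setdefault(t.chrom, []).append(t)
        for chrom, ts in by_chrom.items():
            ts = sorted(ts, key=lambda t: t.start)
            for a, b in zip(ts, ts[1:]):
                if b.start <= a.end:
                    raise LayoutError(f"overlapping tracts on {chrom}")


@dataclass
class TruthSet:
    """Planted truth sufficient to score every pipeline stage."""

    tracts: tuple[Tract, ...] = ()
    genetic_map: pd.DataFrame | None = None
    qtl: list[dict] = field(default_factory=list)
    gene_labels: pd.DataFrame | None = None


def default_layout(
    n_chrom: int = 10, length_bp: int = 60_000_000, centromere_frac: float = 0.45
) -> GenomeLayout:
    """A compact 10-chromosome stand-in for the maize physical map."""
    chroms = [f"chr{i + 1}" for i in range(n_chrom)]
    return GenomeLayout(
        tuple(chroms),
        {c: length_bp for c in chroms},
        {c: int(length_bp * centromere_frac) for c in chroms},
    )


def _drift(p: np.ndarray, F: float, rng: np.random.Generator) -> np.ndarray:
    """Balding-Nichols step: Beta with mean p and variance F p (1-p)."""
    if F <= 0:
        return p.copy()
    k = (1 - F) / F
    a = np.maximum(p * k, 1e-6)
    b = np.maximum((1 - p) * k, 1e-6)
    out = rng.beta(a, b)
    fixed = (p <= 0) | (p >= 1)
    out[fixed] = p[fixed]
    return out


def simulate_sitefreq(
    scenario: Scenario, seed: int | np.random.Generator
) -> tuple[SiteFrequencyTable, TruthSet]:
    """Four-taxon site table with planted introgression tracts.

    Ancestral derived-allele frequencies are drawn from a low-frequency-
    skewed Beta law (the derived allele is defined against the outgroup,
    which is kept near-monomorphic ancestral); population frequencies then
    drift independently down each branch.  Inside a tract with donor
    fraction f the highland frequency becomes (1 - f) p2 + f q with q a
    lightly drifted copy of the *mexicana* frequency.  Finally, panel
    allele counts are binomial draws at the stated panel sizes.
    """
    rng = np.random.default_rng(seed)
    layout = scenario.layout
    rows = []
    n1, n2, n3, nO = (2 * k for k in scenario.panel_sizes)
    for chrom in layout.chromosomes:
        length = layout.lengths[chrom]
        n_sites = rng.poisson(scenario.site_density_per_mb * length / 1e6)
        pos = np.sort(rng.choice(length, size=n_sites, replace=False) + 1)
        p_root = rng.beta(*scenario.sfs_beta, size=n_sites)
        p3 = _drift(p_root, scenario.drift_root_to_p3, rng)
        p12 = _drift(p_root, scenario.drift_root_to_p12, rng)
        p1 = _drift(p12, scenario.drift_p12_to_p1, rng)
        p2 = _drift(p12, scenario.drift_p12_to_p2, rng)
        if scenario.outgroup_polymorphic_rate > 0:
            poly = rng.random(n_sites) < scenario.outgroup_polymorphic_rate
            pO = np.where(poly, rng.beta(0.5, 8.0, size=n_sites), 0.0)
        else:
            pO = np.zeros(n_sites)
        for t in scenario.tracts:
            if t.chrom != chrom:
                continue
            inside = (pos >= t.start) & (pos <= t.end)
            if inside.any():
                q = _drift(p3[inside], scenario.drift_donor, rng)
                p2[inside] = (1 - t.f) * p2[inside] + t.f * q
        df = pd.DataFrame(
            {
                "chrom": chrom, "pos": pos,
                "p1_der": rng.binomial(n1, p1), "p1_tot": n1,
                "p2_der": rng.binomial(n2, p2), "p2_tot": n2,
                "p3_der": rng.binomial(n3, p3), "p3_tot": n3,
                "o_der": rng.binomial(nO, pO), "o_tot": nO,
            }
        )
        rows.append(df)
    table = SiteFrequencyTable(pd.concat(rows, ignore_index=True))
    return table, TruthSet(tracts=scenario.tracts)


# ---------------------------------------------------------------------------
# F2 genotypes
# ---------------------------------------------------------------------------

def true_map_table(
    layout: GenomeLayout,
    markers_per_chrom: int = 117,
    map_length_cM: float = 127.5,
    rng: np.random.Generator | int | None = None,
) -> pd.DataFrame:
    """A true genetic map: evenly spread markers, linear cM over bp.

    Defaults give ~1,170 markers over 10 chromosomes and a ~1,275 cM total
    map, matching the scale of the study's F2 panel.
    """
    rng = np.random.default_rng(rng)
    rows = []
    for chrom in layout.chromosomes:
        length = layout.lengths[chrom]
        pos = np.sort(rng.choice(
            np.arange(1000, length, 1000), size=markers_per_chrom, replace=False
        ))
        cm = (pos - pos[0]) / (pos[-1] - pos[0]) * map_length_cM
        for k in range(markers_per_chrom):
            rows.append(
                {
                    "marker": f"{chrom}_m{k + 1}", "chrom": chrom,
                    "pos_bp": int(pos[k]), "pos_cM": float(cm[k]),
                }
            )
    return pd.DataFrame(rows)


def _interval_cM(
    sub: pd.DataFrame,
    layout: GenomeLayout,
    suppression: float,
    suppress_window_bp: int,
) -> np.ndarray:
    """Per-interval genetic lengths, optionally shrunk around the centromere."""
    chrom = sub["chrom"].iloc[0]
    d = np.diff(sub["pos_cM"].to_numpy(float))
    if suppression < 1.0 and chrom in layout.centromeres:
        cen = layout.centromeres[chrom]
        mid = 0.5 * (sub["pos_bp"].to_numpy(float)[1:] + sub["pos_bp"].to_numpy(float)[:-1])
        near = np.abs(mid - cen) <= suppress_window_bp / 2
        d = np.where(near, d * suppression, d)
    return d


def simulate_f2(
    true_map: pd.DataFrame,
    n: int = 170,
    error_rate: float = 0.01,
    missing_rate: float = 0.05,
    centromere_suppression: float = 1.0,
    suppress_window_bp: int = 20_000_000,
    layout: GenomeLayout | None = None,
    seed: int | np.random.Generator = 0,
) -> tuple[F2GenotypeMatrix, TruthSet]:
    """F2 genotypes from a known map (Poisson crossovers, no interference).

    Each gamete switches parental phase between adjacent markers with
    probability (1 - exp(-2 d / 100)) / 2 for an interval of d cM (the odd-
    crossover probability of a Poisson process on the genetic scale).
    ``centromere_suppression`` < 1 shrinks d inside a window around each
    centromere.  Calls are then corrupted at ``error_rate`` (replaced by a
    different random call) and masked at ``missing_rate``.
    """
    rng = np.random.default_rng(seed)
    if layout is None:
        chroms = list(dict.fromkeys(true_map["chrom"]))
        layout = GenomeLayout(
            tuple(chroms),
            {c: int(true_map.loc[true_map["chrom"] == c, "pos_bp"].max()) + 1000
             for c in chroms},
        )
    all_calls = []
    markers: list[str] = []
    chrom_col: list[str] = []
    pos_col: list[int] = []
    for chrom, sub in true_map.groupby("chrom", sort=False):
        sub = sub.sort_values("pos_bp")
        m = len(sub)
        d = _interval_cM(sub, layout, centromere_suppression, suppress_window_bp)
        r = 0.5 * (1 - np.exp(-2 * d / 100))
        # phase per gamete: start uniform, switch with prob r per interval
        gametes = np.empty((2 * n, m), dtype=np.int8)
        gametes[:, 0] = rng.integers(0, 2, size=2 * n)
        switches = rng.random((2 * n, m - 1)) < r[None, :]
        gametes[:, 1:] = gametes[:, [0]] ^ (np.cumsum(switches, axis=1) % 2).astype(np.int8)
        geno = gametes[0::2] + gametes[1::2]  # 0=AA, 1=H, 2=BB
        calls = np.array(["A", "H", "B"])[geno]
        all_calls.append(calls)
        markers.extend(sub["marker"])
        chrom_col.extend([str(chrom)] * m)
        pos_col.extend(int(p) for p in sub["pos_bp"])
    calls = np.concatenate(all_calls, axis=1)
    if error_rate > 0:
        err = rng.random(calls.shape) < error_rate
        if err.any():
            alts = {"A": "HB", "H": "AB", "B": "AH"}
            flat = calls[err]
            calls[err] = [alts[c][rng.integers(0, 2)] for c in flat]
    if missing_rate > 0:
        calls[rng.random(calls.shape) < missing_rate] = "-"
    matrix = F2GenotypeMatrix(calls, markers, np.array(chrom_col, object),
                              np.array(pos_col), [f"F2_{i + 1}" for i in range(n)])
    return matrix, TruthSet(genetic_map=true_map.copy())


# ---------------------------------------------------------------------------
# Annotation, F_ST and effect classes
# ---------------------------------------------------------------------------

DEFAULT_EFFECT_RATES = {"high": 0.005, "moderate": 0.05, "low": 0.25, "modifier": 0.695}


def simulate_annotation(
    layout: GenomeLayout,
    tracts: Sequence[Tract] = (),
    gene_density_per_mb: float = 10.0,
    gene_length_bp: int = 4000,
    fst_shift: float = 0.0,
    fst_beta: tuple[float, float] = (1.2, 12.0),
    effect_rates: dict[str, float] = DEFAULT_EFFECT_RATES,
    snp_density_per_mb: float = 20.0,
    highland_fixation_boost: float = 0.6,
    seed: int | np.random.Generator = 0,
) -> tuple[list[GeneModel], pd.DataFrame, pd.DataFrame, TruthSet]:
    """Uniform genes, per-gene F_ST and per-SNP effect/fixation records.

    F_ST is Beta-distributed with a constant upward ``fst_shift`` added to
    genes whose span intersects a planted tract (clipped to [0, 1]).  SNP
    effect classes are drawn at the stated rates; SNPs inside tracts are
    fixed-alternate in highland with probability ``highland_fixation_boost``
    (versus a low background), with *mexicana* matching the highland state
    inside tracts.
    """
    rng = np.random.default_rng(seed)
    genes: list[GeneModel] = []
    k = 0
    for chrom in layout.chromosomes:
        length = layout.lengths[chrom]
        n_genes = rng.poisson(gene_density_per_mb * length / 1e6)
        starts = np.sort(rng.integers(1, max(2, length - gene_length_bp), size=n_genes))
        for s in starts:
            k += 1
            genes.append(GeneModel(f"gene{k:05d}", chrom, int(s),
                                   int(min(s + gene_length_bp - 1, length))))

    def in_tract(chrom: str, start: int, end: int) -> bool:
        return any(
            t.chrom == chrom and start <= t.end and end >= t.start for t in tracts
        )

    inside = np.array([in_tract(g.chrom, g.start, g.end) for g in genes])
    fst = rng.beta(*fst_beta, size=len(genes))
    fst = np.clip(fst + fst_shift * inside, 0.0, 1.0)
    fst_table = pd.DataFrame(
        {"gene_id": [g.gene_id for g in genes], "fst": fst, "in_tract": inside}
    )

    classes = list(effect_rates)
    probs = np.array([effect_rates[c] for c in classes], float)
    probs = probs / probs.sum()
    snp_rows = []
    statuses = np.array(["fixed_alt", "fixed_ref", "segregating", "not_called"])
    background = np.array([0.05, 0.55, 0.3, 0.1])
    for chrom in layout.chromosomes:
        length = layout.lengths[chrom]
        n_snp = rng.poisson(snp_density_per_mb * length / 1e6)
        pos = np.sort(rng.choice(length, size=n_snp, replace=False) + 1)
        eff = rng.choice(classes, size=n_snp, p=probs)
        tract_mask = np.zeros(n_snp, bool)
        for t in tracts:
            if t.chrom == chrom:
                tract_mask |= (pos >= t.start) & (pos <= t.end)
        p_fix = np.where(tract_mask, highland_fixation_boost, 0.05)
        highland = np.where(
            rng.random(n_snp) < p_fix, "fixed_alt",
            rng.choice(statuses, size=n_snp, p=background),
        )
        mexicana = np.where(
            (highland == "fixed_alt") & tract_mask, "fixed_alt",
            rng.choice(statuses, size=n_snp, p=background),
        )
        snp_rows.append(
            pd.DataFrame(
                {
                    "chrom": chrom, "pos": pos, "effect": eff,
                    "highland": highland, "lowland": rng.choice(
                        statuses, size=n_snp, p=[0.02, 0.63, 0.25, 0.1]),
                    "mexicana": mexicana,
                    "parviglumis": rng.choice(
                        statuses, size=n_snp, p=[0.05, 0.5, 0.35, 0.1]),
                    "tripsacum": rng.choice(
                        statuses, size=n_snp, p=[0.02, 0.58, 0.1, 0.3]),
                    "in_tract": tract_mask,
                }
            )
        )
    effects = pd.concat(snp_rows, ignore_index=True)
    truth = TruthSet(tracts=tuple(tracts), gene_labels=fst_table)
    return genes, fst_table, effects, truth


# ---------------------------------------------------------------------------
# Traits
# ---------------------------------------------------------------------------

def simulate_trait(
    matrix: F2GenotypeMatrix,
    qtl: Sequence[dict],
    heritability: float = 0.3,
    ordinal_levels: int | None = None,
    seed: int | np.random.Generator = 0,
) -> tuple[np.ndarray, TruthSet]:
    """Trait values from known QTL at the stated (broad-sense) heritability.

    Each QTL is a dict with keys ``marker``, ``additive`` and (optionally)
    ``dominance``; the genetic value at a marker is -a, d, +a for calls
    B, H, A (A being the highland allele).  Gaussian noise is scaled so
    the genetic variance is the ``heritability`` fraction of the total.
    Missing calls contribute the F2 mean effect.  ``ordinal_levels``
    discretizes the result onto a 0..(levels-1) scale.
    """
    if not 0 <= heritability < 1:
        raise ValueError(f"heritability {heritability} outside [0, 1)")
    rng = np.random.default_rng(seed)
    n = matrix.n_individuals
    g = np.zeros(n)
    marker_lookup = {m: j for j, m in enumerate(matrix.markers)}
    for q in qtl:
        j = marker_lookup[q["marker"]]
        a = float(q["additive"])
        d = float(q.get("dominance", 0.0))
        calls = matrix.calls[:, j]
        val = np.where(calls == "A", a, np.where(calls == "B", -a, np.where(calls == "H", d, d / 2)))
        g = g + val
    if heritability == 0 or np.var(g) == 0:
        trait = rng.standard_normal(n)
    else:
        sigma2 = np.var(g) * (1 - heritability) / heritability
        trait = g + rng.normal(0, np.sqrt(sigma2), size=n)
    if ordinal_levels is not None:
        ranks = np.argsort(np.argsort(trait))
        trait = np.floor(ranks / n * ordinal_levels).astype(float)
    return trait, TruthSet(qtl=list(qtl))
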