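# Methods

This note documents the models, estimators and numerical choices behind
`teointro`, and what the synthetic-data generator does and does not
emulate.

## Four-taxon scan

For the quartet (((P1, P2), P3), O) with per-site derived-allele
frequencies `p1, p2, p3, pO` (derived defined against the outgroup), the
frequency-weighted site-pattern weights are

    abba = (1 − p1) · p2 · p3 · (1 − pO)
    baba = p1 · (1 − p2) · p3 · (1 − pO)

A site is *informative* when `abba + baba > 0`; sites where any taxon has
zero called alleles are excluded from both the weights and the
informative count. Patterson's D over a region is
`Σ(abba − baba) / Σ(abba + baba)`, which is antisymmetric under swapping
P1 and P2.

**Jackknife.** Genome-wide significance uses a delete-one block
jackknife over non-overlapping physical spans (5 Mb genome-wide, 1 Mb
for per-chromosome values), aligned to chromosome starts; empty blocks
are skipped. With m retained blocks,
`SE² = ((m−1)/m) · Σᵢ (D₍₋ᵢ₎ − mean)²`, `Z = D/SE`, and the p-value is
the two-sided normal tail. With few blocks the normal approximation is
slightly anti-conservative (a t-like statistic with m−1 df); the null
calibration suite therefore uses a genome giving ~100 blocks, where the
empirical |Z| > 1.96 rate sits at ~5–6%.

**f_d.** In windows of exactly w = 50 informative sites (never spanning
a chromosome; a short trailing group is dropped), the admixture
proportion is estimated as `Σ(abba − baba) / Σ(abba_D − baba_D)`, where
the denominator substitutes the donor frequency `p_D = max(p2, p3)` for
both P2 and P3. The estimator is defined for windows with positive
numerator; windows with numerator ≤ 0 are assigned f_d = 0 and the raw
(pre-clamp) value is kept in the `fd_raw` column so nothing is hidden.
The genome-wide introgression proportion is the unweighted mean of the
clamped window values. At the study's panel sizes (6/6/4/2 called
alleles) the `max` in the denominator is upward-biased by sampling
noise, so window f_d systematically understates the true donor fraction;
this is a property of the estimator at small panels, which is why
mean-f_d-based genome proportions read as conservative.

## Event calling

Outlier windows are those with f_d at or above the empirical upper-tail
quantile, computed genome-wide (not per chromosome) by a nearest-rank
rule — the (⌊(1−q)·n⌋+1)-th smallest value — so that exactly the
⌈q·n⌉ largest windows are flagged when values are distinct, and ties at
the threshold are all included. Maximal runs of index-consecutive
flagged windows on a chromosome are concatenated into events; an
intervening non-outlier window breaks the run by default
(`max_gap_windows = 0`), since closely spaced but separate events are a
real feature of the data. Event spans run from the first member
window's first informative site to the last member's last one, so
inter-window gaps inside an event count toward its size. Summaries
report per-chromosome counts and sizes, percent genome coverage, and a
size histogram with bins [0, 0.5), [0.5, 1), [1, ∞) Mb.

## Linkage map

Marker filtering keeps sites whose A-allele frequency
`(2·nA + nH) / (2·n_called)` lies strictly in (0.2, 0.8), then thins
greedily left-to-right to ≥ 1 kb spacing. Cleaning operates per
individual within a chromosome, iterated to a fixed point (≤ 10
passes): missing runs flanked by identical calls are filled; runs of
identical calls shorter than `max_hap = 6` markers flanked on both
sides by a common different call are replaced by the flanking call.
Both rules decide on a per-pass snapshot, so the result does not depend
on scan direction.

Cleaning is *not* exactly the identity on error-free data: a genuine
double crossover on one gamete that reverts within six markers is
indistinguishable from a call error and is erased. At ~1 cM marker
spacing this removes a few percent of true crossovers and deflates the
map accordingly; at ~0.5 cM spacing the deflation is well under 10%.
The map-recovery suite therefore uses 300 markers per 150 cM
chromosome, where the estimated length stays within 15% of truth.

Recombination fractions for adjacent marker pairs come from EM over the
3×3 F2 genotype table: every class except the double heterozygote
carries a known number of recombinant gametes; the double heterozygote
is a coupling/repulsion mixture contributing `2r²/(r² + (1−r)²)`
expected recombinant gametes. Convergence is |Δr| < 1e−8 or 1,000
iterations from r₀ = 0.25, clamped to [0, 0.5]; estimates match a
5e−4-step grid search of the exact two-locus likelihood. Map positions
chain Kosambi distances `d = 25 ln((1+2r)/(1−2r))` cM over adjacent
pairs after collapsing duplicate call patterns (the leftmost
representative is kept). Adjacent-pair two-point estimation is used in
place of full multipoint EM: with dense, cleaned F2 data the chained
two-point map converges to the multipoint answer and keeps the
implementation transparent; it is documented as an approximation.

## Marey maps and recombination rates

Each chromosome's (physical, genetic) marker pairs are fitted with a
cubic smoothing spline, fitted in Mb so the derivative is directly
cM/Mb. The penalty λ is calibrated by bisection so the effective
degrees of freedom (trace of the smoother matrix, computed by fitting
unit-response vectors) hit the target df = 10; a `spar`-like smoothing
fraction is over-determined once df is fixed, so df is binding and the
achieved effective df is recorded on the curve object. Duplicate
physical positions are averaged before fitting.

Monotonicity is enforced by automated greedy cleaning: while the fitted
derivative is negative anywhere (on a 400-point grid), the marker whose
deletion most increases the minimum derivative is removed and the curve
refitted at the same λ, up to 20% of markers. This automates the manual
removal of map-distorting markers reproducibly. Any remaining tiny
negative excursions are clamped to zero when RR is evaluated.

RR profiles are evaluated on 500-kb bin midpoints; evaluation outside
the marker span uses constant extrapolation of the edge rate. The
trapezoidal integral of RR over a chromosome reproduces its map length
within 5% on noiseless fits. The pericentromere is the maximal
contiguous run of grid bins with RR ≤ 0.2 cM/Mb containing the
centromere (empty if the rate at the centromere exceeds the threshold);
the region grows monotonically with the threshold.

Event-size/RR association takes each event's RR at its midpoint, groups
events into size classes and applies the Kruskal–Wallis test (classes
with zero events are dropped with a warning). Map-vs-map comparison
uses the paired Wilcoxon signed-rank test, exact when n ≤ 25 paired
positions, zero-differences handled by rank splitting, and an all-tie
input reported as degenerate with p = 1. Pericentromere enrichment of
large events is a two-cell goodness-of-fit χ² (df = 1) against the
expectation proportional to the pericentromeric fraction of genome
length, with event position taken as the midpoint; a 2×2 form was not
used because no second classification axis exists for single events.

## Enrichment statistics

Gene membership in events is any-overlap (≥ 1 bp, both 1-based
inclusive); a midpoint mode is available. The cumulative gene-density
expectation orders events by increasing size and compares cumulative
observed gene counts with `cumulative size × (total genes / genome
size)`. The 2×2 enrichment χ² subtracts `min(0.5, |O − E|)` from each
deviation before squaring, so exactly proportional tables give 0; with
the printed counts of the motivating analysis (62 of 409 significant
genes inside events, 636 of 21,029 genes inside overall) this
convention reproduces the published integer statistic of 205, which the
plain Yates correction does not vanish-match at O = E. F_ST comparisons
use the two-sided rank-sum test genome-wide and per chromosome,
skipping sides with fewer than 3 genes. Fixation classification per
taxon group is: fixed-alternate (all called genotypes homozygous
alternate), fixed-reference (symmetric), segregating (both alleles
observed), not-called; the cross-tabulation restricts to chosen effect
classes (default high + moderate) and highland fixed-alternate SNPs,
suppressing patterns with ≤ 25 SNPs from the displayed table while
keeping the full table.

## QTL scan

Genotype probabilities come from forward–backward smoothing of the
three-state F2 chain (AA/AB/BB) on each chromosome, with pseudomarkers
inserted every 1 cM. Transitions over an interval of d cM use the
inverse-Kosambi recombination fraction `r = tanh(d/50)/2` and the
standard F2 two-gamete transition matrix; emissions give the observed
call probability 1−ε (ε = 1e−4 by default) with errors split evenly,
and missing calls emit uniformly. At ε = 0 the chain interpolates
observed calls exactly; a fully missing individual receives the F2
prior (¼, ½, ¼).

The scan is Haley–Knott regression of the trait on an intercept, the
additive predictor `P(AA) − P(BB)` and the dominance predictor `P(AB)`,
with `LOD = (n/2) log10(RSS0/RSS1)`; the implementation solves each
position by QR and supports a trait *matrix*, so the permutation null
(genome-wide maximum LOD over trait permutations) is computed in one
vectorized pass. The 5% threshold is the empirical 95th percentile
(upper interpolation, so α = 1 returns the minimum permuted maximum).
Semi-quantitative ordinal traits are treated as numeric. Support
intervals are 1.5-LOD drops around the peak, projected to bp through
the scan grid's Marey interpolation, and variance explained uses the
closed form `100 (1 − 10^(−2·LOD/n))`. Haley–Knott was chosen over EM
interval mapping for speed and determinism; for a single scan on
cleaned data the difference is negligible.

## Synthetic data

The generator emulates the study design, not maize sequence evolution:

* **Site frequencies.** Ancestral derived-allele frequencies follow
  Beta(0.4, 1.2) (low-frequency-skewed, derived defined against a
  near-monomorphic outgroup). Each branch applies a Balding–Nichols
  drift step — Beta with mean p and variance F·p(1−p) — with defaults
  F = 0.10 (root → maize ancestor), 0.05 (ancestor → each maize
  population) and 0.40 (root → *mexicana* panel). The *mexicana* value
  is deliberately high: it describes the allele-frequency divergence of
  a *sampled panel* of two highly inbred teosinte genomes, not the
  population-level F_ST. Inside a planted tract with donor fraction f
  the highland frequency becomes `(1−f)·p2 + f·q` with q a lightly
  drifted (F = 0.02) copy of the *mexicana* frequency. Panel counts are
  binomial at 6/6/4/2 alleles. The default site density of 1,300/Mb
  yields ~110-kb windows of 50 informative sites, matching the physical
  resolution of the motivating scan. What is *not* modeled: linkage
  disequilibrium between sites, haplotype structure of introgressed
  segments, ascertainment of SNP calling, or coalescent variance — so
  passing tests demonstrate correct estimator behavior under the
  frequency model, not robustness to real LD structure.
* **F2 genotypes.** Per gamete, phase switches between adjacent markers
  with the odd-crossover probability `(1 − e^(−2d/100))/2` of a Poisson
  process on the genetic scale (no interference); a suppression factor
  < 1 shrinks d inside a window around the centromere. Calls are
  corrupted at the error rate and masked at the missing rate. Defaults
  (n = 170, ~117 markers per chromosome, ~127.5 cM per chromosome)
  match the scale of the study's intercross.
* **Annotation.** Genes are uniform with Poisson counts at 10/Mb and a
  fixed 4-kb length; per-gene F_ST is Beta(1.2, 12) plus a constant
  shift inside tracts; SNP effect classes follow typical
  variant-annotation rates (high 0.5%, moderate 5%, low 25%, modifier
  the rest); highland fixed-alternate status is boosted to 0.6 inside
  tracts (background 5%) with *mexicana* matching the highland state
  there.
* **Traits.** Genetic values −a/d/+a for B/H/A calls at the planted
  QTL, Gaussian noise scaled to the stated broad-sense heritability,
  optional rank-based discretization to ordinal scales.

All generators are pure functions of (scenario, seed); emitted tables
pass the package's own validators.

## Problem sizes in the test and acceptance suites

Simulation-based checks are desk-scale by design: null D calibration
uses 200 replicates of a 500-Mb genome at 100 sites/Mb (≈100 jackknife
blocks); tract recovery plants ten 1.2-Mb tracts (f = 0.8) on a 200-Mb
genome at the default density; map recovery uses 20 replicates of a
150-cM chromosome with 300 markers and n = 170; QTL type-I calibration
uses 200 outer replicates with 100-permutation thresholds on a
two-chromosome genome. These sizes give the property suites stable
pass/fail behavior while keeping any single suite to a few minutes.

## Known limitations

* The frequency simulator has no linkage disequilibrium; window
  statistics on real data are more autocorrelated than simulated ones.
* Two-point map construction ignores multipoint information; with
  sparse or noisy markers it is noisier than `est.map`-style EM.
* The genotype-cleaning rules erase genuine short double crossovers
  (see above), a bias shared with the run-correction tools they mirror.
* The spline derivative is unreliable beyond the outermost markers;
  constant extrapolation of the edge rate is a pragmatic choice.
* The pericentromere is grid-resolution limited (500 kb by default).
* Ordinal traits are scanned as numeric; no threshold-model likelihood.
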