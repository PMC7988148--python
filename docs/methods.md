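# Methods

This note documents the models and procedures implemented in `recat`, the
assumptions behind them, the defaults that matter, and what the synthetic
data can and cannot show about real data.

## Coordinates and formats

All internal coordinates are 0-based half-open (BED convention); GFF3 is
converted at the I/O boundary (1-based inclusive → half-open; the TSS of a
`+` transcript is its converted start, of a `-` transcript its `end − 1`).
Regulatory elements are unstranded.  Interval queries run on sorted
per-chromosome arrays with binary search; catalogs, peak sets and TADs are
stored disjoint, so no interval-tree machinery is needed.

## RE catalog construction

Active chromatin states default to {1–6, 8, 9, 11} of a 14-state
segmentation (promoter-, TSS-flanking-, and enhancer-associated states);
states 12–13 (polycomb-repressed) and 14 (low signal) are inactive.
Within one tissue, consecutive or abutting active segments merge into
maximal runs; merging across tissues is also bookended, matching BEDTools
`merge` defaults.  Merging across tissues before classification avoids
splitting a promoter into fragments when, say, an H3K27ac-defined state
extends past an H3K4me3-defined one in a subset of tissues.

Classification precedence:

1. **TSS-proximal** — the RE comes within 2,000 bp (inclusive) of a
   protein-coding TSS.  Distance is measured from the nearest RE edge to
   the TSS base; equivalently the RE overlaps the window
   `[tss − 2000, tss + 2000]`.
2. **excluded** — otherwise within 2 kb of a non-coding transcript TSS or
   of a supplied list of unannotated TSS positions.  The exclusion exists
   to keep non-coding-gene promoters out of the enhancer classes; it
   deliberately does *not* outrank coding-TSS proximity, since an RE at a
   coding TSS cannot be mistaken for an enhancer in the first place.
3. **genic** — overlaps a gene body by ≥ 1 bp.
4. **intergenic** — everything else.

`open_chromatin_support` is tissue-matched: an RE counts as supported only
if an accessibility peak overlaps it in at least one tissue where the RE
is active.  `state_feature_enrichment` is the usual fold enrichment
`(state∩feature / state) / (feature / genome)`, with NaN for absent
states.

## TAD prediction from CTCF orientation

The caller assumes loop anchors are convergently oriented CTCF sites.
PWM scores are `Σ log2(p′/0.25)` with pseudocount 1e-3 renormalized per
row.  The score threshold for the scanning p-value (default 1e-4) comes
from exact dynamic programming over the null score distribution
discretized at 1e-3 bits — deterministic, no sampling.  Only peak spans
are scanned (sites are defined by hits inside peaks), each peak keeps its
single best hit (ties: smaller start, then `+` strand), and every forward
site pairs with its *nearest* downstream reverse site within `max_span`
(default 1 Mb).  The cited orientation-pairing approach leaves open
whether one forward site may pair with several reverse sites and whether
a span cap applies; nearest-partner with a configurable cap is the
implementation's reading of loop-extrusion logic, and both choices are
exposed as parameters.  Overlapping and nested loops merge transitively;
bookended loops do not (two domains sharing a boundary remain distinct).

## TMM normalization and linking

`tmm_factors` reimplements trimmed-mean-of-M-values: reference = sample
whose upper-quartile of library-scaled counts is closest to the mean
upper quartile; per sample, rows positive in both contribute
M = log2 ratio and A = mean log2 abundance; the outer 30% tails of M and
5% tails of A are trimmed; the factor is 2^(precision-weighted mean M)
with inverse asymptotic binomial variance weights; factors are scaled to
geometric mean 1.  CPM = counts / (library size × factor) × 1e6.  Note
the sign convention this implies: a sample carrying extra composition
(a few inflated rows) gets a factor *below* its companions so that its
effective library shrinks — the same direction edgeR produces (verified
against `calcNormFactors` in the test suite).  Because the trim weights
depend on library size, exactly doubling a sample's counts leaves all
count/library ratios unchanged but can still move that sample's factor by
a few percent; the unperturbed samples move only by the geometric-mean
renormalization.

The variance prefilter keeps rows whose max/min ratio across samples
exceeds 6 (rows reaching from 0 to a positive value count as infinite
ratio and are kept; all-zero rows are dropped).  The threshold is a ratio,
not a variance, following the procedure's operational definition.

Link testing: an RE belongs to a TAD if its midpoint does; a gene if its
5′-most protein-coding TSS does.  Correlation is Spearman across all
16 samples (8 tissues × 2 replicates) — replicates add information and a
tissue-mean mode would halve n; p-values use the t-approximation on n − 2
df; BH runs once over all tests genome-wide (no per-TAD or per-chromosome
stratification, since nothing in the procedure suggests strata); retained
pairs need q < 0.05 and ρ > 0.  Positivity is the default because the
predictive signal is an activating mark; `positive_only=False` disables
it.  Zero-variance rows yield skipped tests, counted in the summary
rather than propagating NaN.  The naive baseline pairs genic REs with
every overlapped gene and intergenic REs with the nearest TSS (ties:
smaller distance, then lexicographic gene id).

## Conservation

Alignment maps are gapless co-linear block pairs; source blocks are
disjoint.  An interval maps if ≥ 1 of its bases is aligned (most
permissive reading; `--min-mapped-frac` tightens it).  Within `-` strand
blocks positions are mirrored before the min–max span is taken.  If an
interval's aligned bases scatter over several target chromosomes, the
chromosome receiving the most bases wins (ties: lexicographic) — a
documented choice for paralogous placements, logged per RE rather than
rejected.  Conservation = mapped span overlaps a target-catalog RE by
≥ 1 bp; rates are mapped/total and conserved/mapped.

## QC metrics

Duplicate identity for NRF/PBC is the full (chrom, start, end, strand)
tuple — the standard ENCODE definition.  PBC2 with no doubly-hit location
is reported as +inf.  JSD bins read *starts* into fixed windows (default
500 bp, matching the binning convention of the deepTools family),
restricts to bins hit by either library, normalizes each to a probability
vector and returns the base-2 Jensen–Shannon distance (square root of the
divergence, hence in [0, 1]).  Raw binned coverage is used, not
input-subtracted coverage — a dialect choice; the input library enters as
the comparison distribution itself.

## Statistics

`spearman` average-ranks ties and computes Pearson on ranks; |ρ| = 1 maps
to p = 0; an exact-permutation cross-check at small n lives in the tests.
`bh_adjust` is the step-up `q(i) = min_{j≥i} m·p(j)/j` capped at 1.
`fisher_exact_2x2` enumerates the full hypergeometric support; the
two-sided p sums probabilities ≤ the observed table's with a *relative*
tie tolerance (1e-7) — an absolute tolerance would sweep in every
far-tail table once the observed pmf is smaller than it, inflating p for
large tables.

## The synthetic-data generator

`SimConfig` defaults define the study conditions: 2 chromosomes × 10 Mb,
8 named tissues × 2 replicates (16 samples), 300 genes, 600 REs, 40 TADs,
60 true RE→gene links (10%), `link_rho = 0.9`, NB dispersion 0.05,
library depths spanning 3.5-fold, 50% planted conservation among mapped
REs, SNP-in-RE odds 2.5.  All randomness flows from one seed through
fixed per-component child generators, so every product is byte-identical
across runs and platforms and independent of generation order.

Key constructions:

* **Segmentations.** REs are planted on a 200-bp grid and written as 1–3
  abutting active-state segments per active tissue, against a background
  of state 14 interleaved with 12/13; per-tissue records tile each
  chromosome exactly.  Planted REs are ≥ 600 bp apart so consolidation
  recovers them exactly — recovery is a property of the planting
  geometry, not an accident.
* **Counts.** Both expression and RE signal are negative binomial
  (variance μ + φμ²); φ = 0 is the deterministic rounded-mean limit used
  by noiseless construction tests.  For a linked pair, one per-sample
  latent activity (60% tissue-level, 40% replicate-level variance) drives
  both means through the same log-linear response.  The latent coupling is
  set from the target Spearman via the bivariate-normal relation
  `r = 2 sin(π·ρ/6)` and then inflated by the analytically computed
  counting-noise attenuation `λ = s/√(s² + ln(1 + φ + 1/μ₀))` per feature
  (capped at perfect coupling), so the *observable* correlation realizes
  ≈ `link_rho` rather than an eroded value.  Unlinked features vary
  independently across samples, which keeps the all-null configuration's
  p-values honest; tissue-structured "marker" genes (for the
  expressed/tissue-specific flag logic) are planted outside TADs so they
  cannot contaminate the null of the linking test.
* **CTCF architecture.** TAD boundaries are exact consensus embeddings of
  a non-palindromic 19-bp CTCF-like motif (forward at the left anchor,
  reverse complement at the right); decoy peaks are resampled until they
  contain no hit at the scanning threshold.  Prediction is therefore
  expected to equal the planted domains exactly, which the tests assert
  seed by seed.
* **Alignment maps.** Unmappable REs fall wholly inside alignment gaps;
  all other REs are fully covered by blocks and the conserved subset
  receives a target RE exactly at its image.  Generated maps are `+`
  strand; `-` strand mapping is exercised by hand-built maps in the unit
  tests.
* **SNPs.** Categorized SNPs land in REs with the configured odds against
  a 5% uncategorized baseline; in-RE p-values are Beta(0.4, 1)-skewed,
  out-of-RE p-values Uniform(0, 1); ~5% of categorized SNPs carry a second
  category.

What the generator does **not** emulate: realistic chromatin-state
transition statistics (background segments are exchangeable, not
HMM-like); read-level data (no FASTQ; QC reads are sampled intervals);
sequence-driven signal (counts are independent of the FASTA); gene
families/paralogy in the alignment maps; linkage disequilibrium between
SNPs.  Passing tests therefore demonstrate algorithmic correctness and
statistical calibration of each stage under its stated model — not
robustness to artifacts of real libraries (mappability, GC bias,
copy-number effects), which must be assessed on real data.

## Problem sizes and numerics

Tests and the acceptance script run the default 2 × 10 Mb scenario (and a
2 × 2 Mb variant for sequence-heavy stages), 20 independent scenarios for
link recovery and null calibration, 100 for the Fisher null-rate check,
and 20,000 SNPs per group for the enrichment recovery — sizes chosen so
the whole suite completes in well under a minute per stage on one CPU
while keeping Monte Carlo error far below the asserted margins.
Notable numeric choices: PWM pseudocount 1e-3 with a 1e-3-bit DP
granularity; BH implemented via a reversed cumulative minimum; Fisher tie
tolerance relative 1e-7; TMM weight denominators floored at 1e-12 to keep
one-row matrices finite; JSD clamped to [0, 1] against square-root
round-off.
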