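# Methods

## Scope and assumptions

The package post-processes upstream caller output; it does not align reads
or call variants de novo. Somatic status of small variants is accepted from
the upstream tumor–normal caller (an optional sanity predicate requiring
normal AF < 2% can be enabled via `FilterConfig.require_normal_absence`).
SV type/state vocabulary is passed through from the paired-end caller
unchanged. All internal interval arithmetic is 0-based half-open; report
tables print 1-based inclusive coordinates with space-grouped digits.

## Small-variant filtration

The four rules are pure predicates, so the kept/removed decision is
independent of evaluation order; the cascade evaluates all of them and
records every failure. Choices on points the rule statements leave open:

- **Frequency boundary.** ">0.1%" is read as a strict inequality: a variant
  at exactly 0.001 in a panel passes. Absence from a panel counts as
  frequency 0 (novelty is what the rule targets). Configurable
  (`max_panel_frequency`).
- **Homopolymer adjacency** is checked on both flanks, outward from the
  variant; a mononucleotide indel extends the run it sits in, so its own
  bases count toward the run length (a GG deletion beside GGG is treated as
  a homopolymer-5 context). The homopolymer check precedes the
  identical-repeat check so that mononucleotide cases report the sharper
  reason; the kept/removed outcome does not depend on this ordering.
- **Identical adjacent repeat** requires one immediately adjacent tandem
  copy of the inserted/deleted sequence in either flank; one copy is the
  implemented minimum.
- **Missing flanking context** makes the context rule *inconclusive*, not a
  failure: the record is kept with a warning, because silently dropping
  unannotated indels would bias against regions with no context available.
- Simple-repeat and segmental-duplication masks are runtime inputs (BED);
  no particular track provenance is baked in.

## CNV calling

Model: with N and T total mapped reads in normal and tumor, the normal
defines p_w = n_w/N per window and the tumor count is referred to
Binomial(T, p_w). Because the ratio gates are themselves one-sided, the
test is one-sided in the direction of the observed adjusted ratio
(two-sided mode available via `CnvConfig.two_sided`). Tail probabilities
use scipy's regularized incomplete beta (`binom.sf`/`binom.cdf`), stable at
read totals of order 1e7; values below ~1e-308 underflow to 0, which only
strengthens a call. No multiple-testing correction is applied: the fixed
1e-8 threshold is the genome-wide stringency.

- **Masked windows.** n_w = 0 leaves p_w undefined; such windows are
  reported untestable (mapability artifact), never as losses.
- **Merging.** Overlapping or book-ended flagged windows of one direction
  merge; the segment ratio is recomputed from counts summed over the
  constituent windows (overlap double-counting cancels between numerator
  and denominator). Because the 10-kb-step windows overlap, constituent
  tests are correlated; the segment reports min-p of its windows, not a
  combined statistic.
- **Dosage** = round-half-up(2 × segment ratio). This maps ratio ≈1.5 to
  dosage 3, ≈2.5 to 5 and ≈0.5 to 1; dosage-2 results are suppressed as
  inconsistent with a confident copy-number call (the gates make them
  nearly impossible anyway).
- Totals are genome-wide mapped-read totals (not per-chromosome); window
  boundaries come from the tiling grid, so segment edges snap to the 10-kb
  step.

## SV filtering

"Support in the normal" is interpreted structurally: a tumor call is
subtracted when a same-type normal call surviving the 3-read threshold
overlaps *both* of its breakpoint intervals (corresponding breakpoints,
zero slop by default; both configurable). Centromere masking removes a call
when either breakpoint touches the centromere interval set. Raising the
tumor threshold can only shrink the surviving set, and subtraction is
idempotent; both properties are tested.

## Zygosity and LOH

Percentages are rounded half-up to one decimal (61/62 → 98.4%). Zygosity
labels partition: low-depth (<20×) first, then absent (0 alt reads),
homozygous (AF ≥ 0.90), high-AF (AF > 0.60), heterozygous otherwise. The
0.90/20× homozygosity definition is a package choice — any reasonable
cutoff classifies a 98.4% site identically — and is configurable.

The LOH screen selects sites heterozygous in the normal (normal AF in
[0.35, 0.65] at ≥20×) and examines tumor allele fractions. Under LOH the
retained parental allele is the alt or the ref allele per site, so tumor
AFs shift toward 1 *or* 0 depending on phase; a raw median of tumor AF can
therefore sit near 0.5 under strong imbalance whenever the two directions
balance. The decision statistic is consequently the median *major-allele*
(folded) fraction |AF − 0.5| + 0.5: ~0.54 at depth 60 under heterozygosity,
→ ~0.9 under loss of one allele. `no_loh` when the median stays ≤ 0.65,
`loh_suspected` beyond, `uninformative` below 3 informative sites. With 10
informative sites at 60×, both error rates are far below 5% (measured by
the acceptance script).

## Synthetic data generator

The generator's defaults are the study conditions at desk scale: a 20-Mb
genome (2 × 10-Mb chromosomes) tiled into 100-kb/10-kb-step windows
(~1,980 windows), genome-wide totals of 1.48M normal and 1.54M tumor reads
(the ~7.4×/7.7× low-pass design at 100-bp reads), exome-like variant depths
(~120×/~90×), and per-tile mapping probabilities drawn from a symmetric
Dirichlet with squared coefficient of variation 0.01 (~10% mapability
heterogeneity; the real study reports no mapability statistics, so this is
a testability choice, not a fidelity claim).

Reads are distributed over non-overlapping 10-kb tiles by a multinomial;
sliding windows are tile sums, so overlapping windows are consistent and
correlated as in real data. The tumor shares the normal's tile
probabilities rescaled by dosage/2 inside embedded CNV segments and then
renormalized — physically, a CNV adds or removes tumor read mass
genome-wide.

**A discovered power condition for recovery.** The renormalization factor
is norm = 1 + Σ_s frac_s·(d_s/2 − 1) over embedded segments. A *lone*
dosage-3 gain has expected adjusted ratio 1.5/norm with norm > 1 — strictly
below the inclusive ≥1.5 gate — and even at norm = 1 it sits exactly on the
gate, so each window clears it with probability ≈50% regardless of depth.
The same holds for a lone dosage-1 loss against the ≤0.5 gate. Recovery of
boundary-dosage events is therefore only statistically guaranteed when the
expected ratio sits inside the gate by several standard errors; the
recovery test tracks arrange this with a strong opposite-direction co-event
(dosage-3 gain + dosage-0 deletion gives norm ≈ 0.93, expected ratio ≈1.61,
~5σ inside the gate at the default totals; dosage-1 loss + dosage-5 gain
gives norm ≈ 1.07, expected ratio ≈0.467). Non-boundary dosages (0, 4, 5,
...) need no such arrangement.

Variant tables are plan-driven: each planned category fixes origin
(somatic/germline), class, consequence, panel-frequency class (novel /
rare ≤0.1% / common >0.1%) and indel context class (clean / simple-repeat /
identical-repeat / homopolymer); flanks are literal short strings
constructed to realize exactly the planned context (clean flanks are
rotated ACGT cycles with guarded first/last bases, so they can never
accidentally form a disqualifying context). Companion BED masks cover
exactly the records planned as segmental-duplication or simple-repeat
failures. Somatic tumor AFs draw from Beta(8, 12) (mean 0.4); germline
sites are heterozygous (AF 0.5) or homozygous (AF 1.0, 20%). SV support
counts are Poisson around configured means.

What the generator does **not** emulate: read-level errors, GC bias,
tumor purity/subclonality, realistic repeat landscapes, linkage between
variants, or inter-chromosomal SV breakpoint clustering. Passing tests
therefore demonstrate correctness of the decision rules and calibration of
the statistics under the stated model, not performance on real sequencing
artifacts.

## Problem sizes and determinism

Test and acceptance problem sizes: ~1,980 windows per track, 100 null
replicates, 20 recovery seeds × 2 tracks, 200 LOH replicates per scenario,
150-point binomial oracle grid (T ≤ 1,000), 200-call SV brute-force lists.
The full suite runs in a few seconds. All generators are driven by a single
integer seed through `numpy.random.default_rng`; identical config + seed
reproduces output byte for byte, and the pipeline writes no timestamps
unless asked.
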