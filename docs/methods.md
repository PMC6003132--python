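# Methods

## The problem and the model

Urothelial (bladder) tumours shed cells into urine, and those cells carry
the genome-wide copy-number distortions characteristic of chromosomal
instability. Shallow whole-genome sequencing (~5 million reads per sample,
here after whole-genome amplification of trace DNA from urine pellets or
tumour tissue) is too sparse to call individual variants, but it measures
relative DNA dosage well when reads are aggregated into large windows.
`ciascore` turns such data into a single chromosomal-imbalance score and a
binary positive/negative call.

The pipeline:

1. **Binning.** The reference genome is tiled into non-overlapping 1-Mb
   windows (hg19 autosomes: 2,897 bins). Each retained read increments the
   bin containing its leftmost aligned base. "Usable" reads are mapped,
   primary, non-supplementary, non-duplicate alignments with MAPQ >= 30 —
   MAPQ 30 is the conventional proxy for unique mapping; the leftmost-base
   rule is the standard read-depth convention and is deterministic.
2. **GC normalization.** Expected count is fitted as a smooth function of
   window GC fraction (LOESS, span 0.3, over usable bins; a
   median-within-GC-decile fallback is used below 500 usable bins, where a
   local regression is under-determined). Corrected depth is
   `count / fit(gc) * median(count)`, keeping the raw-count scale.
3. **Reference normalization.** A panel of presumed-diploid samples, each
   GC-corrected and scaled to its own median, is summarized by the per-bin
   median. Bins with reference < 0.1 or coefficient of variation > 0.5
   across the panel are masked as unstable. Dividing a sample by this
   reference cancels locus-specific mappability and amplification bias. A
   flat pseudo-reference is available (with a warning) so the tool can run
   without a panel.
4. **Relative copy number.** `xi = 2 * (depth / median depth) / reference`,
   recentred so the median over autosomal usable bins is exactly 2. Sex
   chromosomes are masked by default: cohorts mix sexes, and X dosage would
   read as imbalance; a flag includes them for same-sex panels. Masked bins
   are excluded from all downstream rank computations, never imputed.
5. **Per-bin deviation.** `Z_i = sqrt(|log2(xi_i / 2)|)`: zero exactly at
   diploid, symmetric in gains and losses on the log scale, with the square
   root damping the influence of extreme bins.
6. **Score.** Usable bins are sorted ascending by Z (ties broken by genomic
   order) and the score is the sum of Z over 1-based ranks
   `ceil(m/100 * N) .. floor(p/100 * N)` inclusive, defaults m = 95,
   p = 99 (~4% of bins; ~115 of 2,897). Ascending rank order is the only
   direction under which excluding the top 1% — the bins most exposed to
   isolated artefacts — makes sense, and it makes the score focus on the
   high-imbalance tail rather than the genome-wide average.
7. **Call.** Positive iff score strictly exceeds the cutoff (default 24).

## Cutoff selection and evaluation

`roc_and_cutoff` builds the ROC over all distinct score thresholds with the
same strict-greater rule, computes AUC by the trapezoid rule (identical to
Mann–Whitney pair counting, which the tests verify), and picks the cutoff
maximizing Youden's J = sensitivity + specificity − 1, breaking ties toward
the larger cutoff (higher specificity). Fixed-cutoff metrics come from
`confusion_metrics`; metrics with a zero denominator are reported absent,
not zero.

Concordance between two binary tests on the same samples uses observed
agreement, Cohen's kappa `(po − pe) / (1 − pe)` (kappa's p-value is the
large-sample normal approximation and is informational only), and the exact
McNemar test `p = min(1, 2 P(X <= min(b, c)))`, `X ~ Binomial(b + c, 1/2)`
on the discordant counts — the exact binomial form, not the chi-square
approximation. Fisher's exact test covers 2×2 tables by the hypergeometric
point-probability rule and r×c tables by Freeman–Halton enumeration over
all margin-preserving tables (exact up to total 500; beyond that a seeded
Monte Carlo over random tables with the observed margins, using the
Patefield sampler).

## Synthetic data

The generator emulates the statistical structure the method assumes, so
every stage is testable without external data. Per-bin expected count is
proportional to `bin width × mixture copy number / 2 × gc_response(gc)`,
scaled to a target read total; the mixture copy number for a bin inside an
event of tumour copy number c at tumour fraction t is `t·c + (1 − t)·2`.
Counts are negative-binomial (gamma–Poisson) with variance/mean = 1.3 by
default — shallow-WGS libraries are mildly overdispersed relative to
Poisson — with Poisson available for analytic checks. The GC response is a
mild unimodal curve peaking at GC 0.45, mimicking library-prep bias.
`simulate_alignments` realizes a count profile as a coordinate-sorted
SAM/BAM (uniform positions within each bin, MAPQ 60) whose round trip
through `count_reads` is exact. Identical config + seed is bit-reproducible.

Defaults: 5 million reads per sample; a toy genome of 10 chromosomes ×
30 Mb (300 bins) keeps the test suite under a minute, with hg19-scale
(2,897-bin) runs used where a property concerns genome-scale behaviour.
Cohort simulations in tests and the acceptance script use 1–2 million reads
per sample at 12–60 samples per arm — sizes chosen so each check's
Monte Carlo error is small relative to its assertion band.

What the generator does **not** model: amplification chemistry, mappability
holes and segmental duplications, base-level errors, contamination, and
subclonal structure beyond a single tumour fraction. Passing tests
therefore demonstrate the pipeline's statistical correctness under its own
assumptions, not its clinical accuracy on real urine libraries.

## Numerical and design choices

- Coordinates are 0-based half-open internally; bin maps serialize as BED
  with GC and usability columns; profiles and references as TSV.
- The score formula's |Z| is implemented as Z, which is non-negative by
  construction.
- Rank boundaries and tie rules (above) are conventions this package fixes
  explicitly; alternative readings shift the window by at most one bin.
- Percentile scoring requires >= 100 usable bins; GC fitting requires
  >= 50. Zero-count bins get corrected depth 0 and are masked out of xi
  (where positivity is required) rather than erroring.
- The LOESS fit is floored at 1% of its median to avoid division blow-ups
  in sparse GC regions.
- A per-sample minimum usable-read QC (default 1M) is the caller's
  responsibility; the library does not silently drop samples.

## Known limitations

- **The cutoff is regime-specific.** At 2,897 bins and 5 million reads
  (~1,700 reads/bin), counting noise alone puts a diploid sample's score
  near 31 (Poisson) to 36 (dispersion 1.3): the percentile window sums
  ~115 bins whose Z reflects ~2.5% depth noise. A fixed cutoff of 24 is
  therefore meaningful only for a particular library preparation, depth and
  normalization pipeline; for any new data regime the cutoff should be
  re-derived with `roc_and_cutoff` on labelled samples. In the toy regime
  used by the test suite (300 bins, ~16,700 reads/bin) diploid samples
  score ~2 and the same cutoff separates cleanly.
- Segmentation-based callers (CBS/HMM) would detect focal events more
  sensitively; the score here deliberately operates on per-bin values.
- The reference panel's composition matters: a panel sharing the sample's
  library chemistry is assumed, and the pseudo-reference leaves
  locus-specific bias uncorrected.
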