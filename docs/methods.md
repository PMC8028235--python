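# Methods

## Statistical model

The caller treats each target position independently. The control-cohort
model supplies, per position and strand, alternate and reference
nucleotide counts (c, d); the test sample supplies (a, b) for the
candidate alternate — the non-reference nucleotide with the largest VAF,
with ties broken in fixed order A<C<G<T so exactly one candidate is
tested per position. Each strand's 2×2 table is tested with a one-sided
Fisher's exact test, alternative "sample alternate proportion greater
than model proportion": only enrichment of the alternate over the
empirical error background is evidence of a variant, and the one-sided
form reproduces the analytic detection-limit series below. The p-value is
the exact hypergeometric upper tail P(X ≥ a), computed via the
hypergeometric survival function; a strand with no sample coverage
(a + b = 0) yields a no-test sentinel.

Strand p-values are combined with Stouffer's method using one-sided
z-scores: z_s = Φ⁻¹(1 − p_s), z = (z_fwd + z_rev)/√2, p_comb = 1 − Φ(z).
Inputs are clamped to [1e-300, 1 − 1e-16] before the quantile transform
and the output is floored at 1e-300, so p_comb stays in (0, 1] in double
precision. Positions where either strand is uncovered are reported but
flagged and never pass — the combination requires both strands, which is
what makes the caller robust to strand-specific context error.

Multiple testing is controlled by Bonferroni over the model's position
count (every model position is a potential test, whether or not the
sample nominates a candidate there): p_adj = min(1, p_comb · n_tests),
compared against alpha = 0.05 by default. `n_tests="auto"` resolves to
the model's n_positions; both are overridable.

The test reference count b is the count of the reference nucleotide
specifically, not depth minus alternate; the VAF denominator is the sum
of all eight strand/nucleotide counts at the position. A (chrom, pos,
alt) blacklist hook drops candidate alleles before testing, standing in
for downstream population-frequency filtering without bundling any
external database. Germline variants present in the control cohort are
deliberately *not* masked from the model: positions carrying them demand
a higher VAF, which is the intended behaviour when the phenotype of
interest is absent from the controls.

## Model construction and transformations

Counting from alignments uses two quality gates: reads require mapping
quality strictly greater than `min_mapq` (default 20) and bases require
quality at least `min_baseq` (default 0). Unmapped, secondary,
supplementary and QC-fail records are always skipped; duplicate-flagged
records are skipped by default but this is a flag, since upstream
pipelines differ in whether duplicates are marked. Mates of a pair are
counted independently — no overlap de-duplication — which users should
weigh when insert sizes are short relative to read length. Only aligned
matches are counted (SNV-only): deletions, reference skips and insertions
contribute nothing. BED input is 0-based half-open; everything reported
downstream is 1-based. Positions in the BED with zero cohort coverage are
retained as all-zero rows: they still belong to the position universe and
to the Bonferroni burden.

Aggregation is an element-wise sum over samples, so it is associative and
order-independent, and each model cell equals the sum of the per-sample
cells. Reference bases come from a user-supplied FASTA; a majority-base
fallback exists for exploratory use. Conflicting reference assignments
are a hard error.

Model scaling multiplies every cell by a factor in [0, 1] and rounds
half-up to an integer, preserving alt:ref proportions approximately while
shrinking evidence mass — a stand-in for a smaller control cohort.
Round-half-up is the documented convention (the composition
scale(scale(m, x), y) can therefore differ from scale(m, xy) by at most
one count per cell, which the tests assert). Counts that round to zero
stay zero.

The on-disk model is a TSV with `#key=value` metadata lines (cohort size,
quality gates, position count) and one row per position: chrom, pos, ref,
then the eight strand-split counts. Parsing validates integer
non-negative counts, known reference bases, unique positions and a
consistent position count, and errors name the offending line.

## Detection limits

For query counts (c, d) and an even test depth, the minimum detectable
VAF is the smallest total alternate count a such that the two per-strand
tables reach Stouffer-combined significance at alpha/n_tests. The search
increments a by one read, alternating strands starting with the reverse
strand, so the allocation after a increments is (ceil(a/2), floor(a/2));
model counts are halved across strands with the forward strand taking the
ceiling of odd counts. Defaults for the idealized query are model_ref =
26,082 and n_tests = 28,119 — the mean reference count and position count
of an 11-gene, ~29 kb overgrowth panel modeled from a 502-exome control
cohort, retained here as the canonical reference configuration; both are
parameters. Under those defaults the series over depths 150/300/600/1200
is 0.0400, 0.0233, 0.0133, 0.0092 (6, 7, 8 and 11 alternate reads). If no
a ≤ depth reaches significance the query returns NaN ("undetectable").

The per-position scan applies the same search using each model position's
own strand-split counts (no halving) for every alternate of every
position, optionally excluding e.g. known heterozygous sites; class
summaries average the per-position limits within the twelve ref>alt
substitution classes, dropping undetectable entries. The search is
vectorized across positions, resolving all open rows per increment of a.

## Synthetic data

The cohort generator emulates a control cohort at the counts level. Per
sample, per strand, depth is Poisson(mean_depth/2); error bases are an
exact multinomial (conditional-binomial decomposition) over the three
alternates at the position's substitution rates; remaining reads report
the reference. Rates come from an `ErrorProfile`: base rate 0.001 (the
canonical short-read error scale), 2% of positions "hot" at 0.005
(position-specific recurrent error — the structure the model exists to
absorb), optional per-class bias (e.g. C>A enrichment) and strand
asymmetry. The realized hot-position placement is part of the seeded
randomness, and the error field is returned so test samples can be drawn
from exactly the cohort's error process. Default cohort scale is 502
samples at 53× each, giving aggregate coverage in the mid tens of
thousands per position.

Count-level spike-in moves round(target_vaf × depth) reads (minimum one
for a positive target) from the reference base to the alternate, split
across strands proportionally to strand coverage; the achieved VAF is
reported exactly. BAM-level spike-in rewrites the base of a seeded
uniform subset of reads carrying an aligned base at the position,
preserving base qualities; read selection ignores strand, so spiked
reads land on both strands in proportion to coverage, which the
dual-strand test requires. Down-sampling keeps each read independently
with probability target/current (binomial thinning; VAFs preserved in
expectation); depth-doubling self-merges the file with renamed read
copies, doubling counts exactly and leaving VAFs unchanged. The read
simulator writes single-end 100 bp reads at constant Q30 — sufficient for
the counts statistics the caller consumes; it does not emulate paired
inserts, quality decay along the read, or indels.

What the synthetic data does not capture: real library chemistry,
alignment artifacts, mappability structure, and cohort germline
variation beyond what the hot-position mechanism mimics. Passing tests
demonstrate the statistical machinery behaves as specified under a known
error process, not that any particular real panel achieves the same
sensitivity.

## Evaluation

Sensitivity is true positives over total simulated variants; a true
positive is a truth entry matched by a *passed* call on (chrom, pos, alt)
— matching requires the allele, which is stricter than position-only and
unambiguous. The proxy positive predictive value is true positives over
all passed calls; it is undefined (None) with zero calls and 0 with a
warning when calls and truth are disjoint. VAF bins are lower-inclusive,
upper-exclusive with width 0.01; replicate summaries use the n−1 standard
deviation over √n.

## Problem sizes and numerical choices

The test suite and the end-to-end experiments run on a 3 kb two-gene
synthetic panel with a 502 × 53× cohort, ~150 spiked variants per depth
at VAF uniform on [0, 0.06], and depths 150/300/600/1200 — the full
cohort scale over a compact panel, which keeps every experiment
deterministic and fast while preserving per-position count magnitudes.
False-positive control is checked over 100 seeded unspiked 600× samples
drawn from the model's own error process (≥ 95 runs must produce zero
passed calls, the family-wise error bound at alpha 0.05).

Fisher p-values are computed with scipy's hypergeometric survival
function and cross-checked in the tests against exact integer-arithmetic
tail enumeration (relative error < 1e-9); the Stouffer transform is
cross-checked against an erfc-based normal CDF with bisection inverse.
The detection-limit search is exact integer iteration, not a continuous
approximation, so returned limits are always multiples of 1/depth.

## Known limitations

- SNVs only; no indels, MNVs, or multi-allelic candidates (one candidate
  per position by construction).
- No matched-normal mode and no pathogenicity annotation; the blacklist
  hook is the only downstream-filter integration point.
- Overlapping read pairs double-count; model and sample should be counted
  with the same convention.
- The Stouffer combination treats strands as independent; barcode-level
  or UMI dependence is not modeled.
- Scan runtime grows with depth × positions; the vectorized search is
  sized for panels of tens of kilobases, not exomes.
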