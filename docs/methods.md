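# Methods

## Data model

Methylation enrichment is represented as per-sample, per-bin read
counts on a fixed grid: bin *b* of a chromosome covers
`[b·100, (b+1)·100)` bp (the last bin may be short). Binning follows
the "whole or part" rule: a read increments every bin it overlaps by
at least one base pair, so a 36-bp read spanning a bin boundary counts
in both bins and column sums can exceed the read count. All
coordinates are 0-based half-open (BED convention), including the DMR
output table.

## Normalization

**Linear.** `N_i = U_i · N_bin / N_U`, with `U_i` the raw count in bin
i, `N_U` the library's unique mapped reads and `N_bin` the total
number of bins in the genome. A library whose reads all fall in
counted bins then has genome-wide mean intensity exactly 1, which
anchors the downstream intensity thresholds (`min_reads` 0.3,
frequency thresholds 1–2). `total_unique_reads` can be overridden when
the library includes reads outside the analyzed chromosomes.

*Known limitation (composition bias).* Because `N_U` includes reads in
differential regions, a large hypermethylated region inflates a
sample's library size and depresses its normalized background
everywhere else. On real genomes the effect is negligible (a kilobase
is ~3·10⁻⁷ of the genome); on the desk-scale synthetic genomes used in
the tests an 8-fold kilobase implant on 60 kb shifts the treated
background by ~10%, which surfaces as scattered weak hypo-calls far
from the implant. This is a property of library-size normalization,
not of the scan.

**Quantile.** One group is the reference; every target value is
mapped through `x → F_ref⁻¹(F_tgt(x))`. Both empirical distributions
pool all bins of all samples in the group (zero bins included — they
dominate enrichment data). The ECDF uses plotting position
`(rank − 0.5)/n` with ties at their average rank, and the reference
quantile function interpolates linearly between order statistics,
clamping beyond the extremes. Consequences: rank order is preserved,
a constant target maps to the reference median, and a target whose
distribution already equals the reference is returned unchanged. In
the DMR pipeline the reference group (control by default) is left on
its own scale and only the other group is transformed.

## DMR scan

Windows of `region_length` (default 1000 bp = 10 bins) start at 0 and
advance by `region_step` (default 500 bp) per chromosome; a terminal
window clipped below half the region length is dropped. Per window:

1. Intensities above `max_reads` (default 100) are removed per sample
   and bin (pile-up guard). Per-bin group means `a_j`, `b_j` are taken
   over the remaining samples; bins missing in either group are
   dropped pairwise. Fewer than 2 surviving bins → untestable.
2. If `max(A_R,A, A_R,B) < min_reads` (default 0.3) the window is
   skipped — a region essentially unmethylated in both groups carries
   no signal. The gate uses the max so that one-sided methylation is
   still tested.
3. The statistic compares the paired vectors `a` and `b` across bins:
   two-sided paired *t*-test (default), two-sided Wilcoxon signed-rank
   (exact null distribution up to 25 non-zero differences, normal
   approximation with continuity correction above; zero differences
   dropped), or Pearson *r* of `a` against `b`. Pairing across bins
   (rather than samples) keeps all three methods on the same footing
   and is well-defined for unequal group sizes.
4. A window is reported when the statistic falls below `p_threshold`
   (default 0.01). For Pearson the comparison applies to *r* itself —
   a low or negative correlation between the group profiles marks
   discordant methylation, so 0.3 is the recommended threshold and
   negative *r* is always reported at that level.

Degenerate windows: identically zero paired differences give p = 1
(no evidence); constant non-zero differences give p = 0 with a
warning (an exact shift with no within-window variance); a constant
profile makes Pearson undefined and the window untestable. Windows
with a significant statistic but exactly zero mean difference carry
no direction and are not reported.

Each record carries type (1 = hyper iff the difference
`A_R,A − A_R,B` is positive, else 2), the statistic, the difference,
and the ratio (difference over the control mean; signed infinity when
the control mean is 0). Overlapping significant windows are emitted
individually — no merging — and raw statistics are reported without
multiple-testing correction, matching the interactive use-case where
the threshold is the user's significance level; `dmr_scan` output can
be post-filtered if FDR control is wanted.

Calibration: on a null cohort (both groups Poisson(2), 5 samples per
group, 1000 disjoint 1-kb windows) the acceptance script measures a
positive-window fraction of ~0.010 at α = 0.01 and ~0.043–0.046 at
α = 0.05, inside the 99% binomial envelopes.

Power boundary: a window that overlaps a strong differential region in
only half of its bins has a bimodal difference vector whose
between-cluster variance caps the paired-t statistic near
`√(m·f²/(f(1−f)))` (t ≈ 3.0 for m = 10, f = 0.5, p ≈ 0.015)
*regardless of effect size*. With the default 500-bp step, the two
flanking windows of a 1-kb region therefore hover just above the 0.01
default threshold while every fully contained window is recovered with
p ≪ 0.01. Users who want flanking windows flagged should use
α = 0.05 (the recommended t-test level) or a step equal to the window
length.

## Summary tracks

Mean: per-bin arithmetic mean over the group's normalized tracks.
Simple frequency: per-bin fraction of samples strictly above threshold
2. Segmented frequency: per sample, (i) binarize at intensity ≥ 1,
(ii) take runs of 1s, (iii) bridge gaps of exactly one bin (≤ 200 bp
at 100-bp bins; two-bin gaps are not bridged), (iv) delete remaining
single-bin runs whose own intensity is below 3; a sample then counts
toward a bin where its mask is 1 *and* its intensity exceeds 1.0.
Step (iv) compares the same values the mask was built from. The mask
is idempotent on its own support, and segmented frequency is bounded
above by simple frequency at threshold 1. Frequencies are reported as
fractions in [0, 1] for cross-cohort comparability (`--counts` emits
raw counts). Difference tracks subtract same-kind summaries (treated
minus control).

## Promoter analysis

The TSS is txStart on `+` and txEnd on `-`; the promoter window is
`[TSS − 2000, TSS + 2000)` clipped to the chromosome and snapped
outward to bin boundaries (data exist only at 100-bp resolution, so
boundary bins are included whole). Each annotation row (accession) is
its own matrix row; `collapse` keeps the longest transcript per
symbol. A promoter is CpG-flagged when any island interval overlaps
the window by ≥ 1 bp (half-open semantics).

Correlated genes: Pearson correlation of the query row against every
other row, pairwise-complete over samples present in both rows
(minimum 3); only ρ ≥ `min_rho` (default 0.4) qualifies —
anticorrelated genes are never listed — ranked by descending ρ with
ties broken by accession, truncated to `k` (default 40). The null
tail of the floor is computed exactly via
`t = r·√(n−2)/√(1−r²) ~ t(n−2)`, two-sided: 2.5e-10 at ρ = 0.4,
n = 232. (A one-sided normal approximation of the same tail is
~7e-11; the exact two-sided value is the honest figure and is what
the package reports.)

## Synthetic cohorts

`simulate_cohort` draws per-bin counts i.i.d. Poisson at a background
rate (default 2 reads per bin — typical enrichment libraries leave
most 100-bp bins below intensity 2 after normalization), multiplied
inside implanted intervals for the designated group. Defaults: one
60-kb chromosome, 5 samples per group, implant multiplier 8. A
`dispersion` parameter switches to negative-binomial draws for
overdispersion stress tests. All randomness flows from the spec seed
through one generator; identical seeds give identical cohorts.

What the generator does *not* model: CpG-density-coupled capture
efficiency, GC bias, fragment-length autocorrelation between adjacent
bins, copy-number variation, or sample-to-sample biological variance
beyond Poisson noise. Passing tests therefore demonstrate statistical
correctness and calibration of the machinery, not end-to-end accuracy
on clinical methylomes.

`simulate_annotations` places TSSs deterministically at the centers of
equal slots (≥ 4.2 kb per gene enforced) with random strands, so the
4-kb promoter windows of distinct genes never share a CpG island and
the flagged-promoter fraction is exact by construction; fully random
gene placement would make that fraction only approximate.

## Problem sizes

The shipped tests and acceptance script use a 1-Mb single-chromosome
genome (10⁴ bins, 1000 windows) for calibration, 60-kb genomes for
recovery experiments across 20 seeds, 100 random regions for
statistic-oracle agreement, 10⁴-bin pools for quantile fidelity, and
1000 randomized format round-trips; the whole suite completes in well
under a minute on one CPU.
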